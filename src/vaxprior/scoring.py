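"""Regional pathogen score matrices and quantitative level assignment.

A score matrix holds, for one region, every pathogen's ordinal level
(1..5 by default) on every criterion, together with a provenance code
recording whether a score came from regional data, was inferred from
other regions, or is preliminary (e.g. cytomegalovirus burden scores,
for which no systematic estimates exist).  Provenance propagates into
reports but never changes arithmetic.

Quantitative criteria (deaths and years lived with disability) are
scored by comparing pathogens *within* a region: the default rule bins
pathogens into rank-based quintiles, ties sharing the lower level.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scheme import CriterionScheme, QUANTITATIVE_CRITERIA

#: The 26 pathogens of the default prioritisation panel.
DEFAULT_PATHOGENS: tuple[str, ...] = (
    "Chikungunya virus",
    "Chlamydia trachomatis",
    "Cytomegalovirus",
    "Dengue virus",
    "Extra-intestinal pathogenic E coli",
    "Group A streptococcus",
    "Group B streptococcus",
    "Hepatitis C virus",
    "Herpes simplex virus",
    "Hookworm",
    "HIV-1",
    "Influenza virus",
    "Intestinal pathogenic E coli",
    "Klebsiella pneumoniae",
    "Leishmania species",
    "Mycobacterium leprae",
    "Mycobacterium tuberculosis",
    "Neisseria gonorrhoeae",
    "Non-typhoidal Salmonella",
    "Norovirus",
    "Plasmodium falciparum",
    "Respiratory syncytial virus",
    "Salmonella Paratyphi",
    "Schistosomes",
    "Shigella species",
    "Staphylococcus aureus",
)

#: The six WHO regions used for regional surveys and score matrices.
DEFAULT_REGIONS: tuple[str, ...] = (
    "Africa",
    "Americas",
    "Eastern Mediterranean",
    "Europe",
    "South-East Asia",
    "Western Pacific",
)

PROVENANCE_CODES = ("regional_data", "inferred", "preliminary")


class DegenerateBinningError(ValueError):
    """Fewer pathogens than requested levels: quantile binning is degenerate."""


@dataclass
class ScoreMatrix:
    """Ordinal pathogen scores for one region.

    ``levels[p, c]`` is the level of pathogen ``p`` on criterion ``c``
    (1-based levels); ``provenance[p, c]`` is a provenance code string.
    """

    region: str
    pathogens: list[str]
    scheme: CriterionScheme
    levels: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        P, C = len(self.pathogens), self.scheme.n_criteria
        if self.levels.shape != (P, C):
            raise ValueError(
                f"levels shape {self.levels.shape} != ({P} pathogens, {C} criteria)"
            )
        if self.provenance is None:
            self.provenance = np.full((P, C), "regional_data", dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
            if self.provenance.shape != (P, C):
                raise ValueError("provenance shape must match levels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.levels, index=self.pathogens, columns=list(self.scheme.criteria)
        )

    # -- CSV round-trip (cells are "level" or "level:provenance") ------

    def to_csv(self, path_or_buf=None):
        cells = np.empty(self.levels.shape, dtype=object)
        for p in range(self.levels.shape[0]):
            for c in range(self.levels.shape[1]):
                prov = self.provenance[p, c]
                cell = str(self.levels[p, c])
                if prov != "regional_data":
                    cell += f":{prov}"
                cells[p, c] = cell
        df = pd.DataFrame(
            cells, index=self.pathogens, columns=list(self.scheme.criteria)
        )
        df.index.name = "pathogen"
        return df.to_csv(path_or_buf)

    @classmethod
    def from_csv(cls, path_or_buf, region: str, scheme: CriterionScheme | None = None):
        if isinstance(path_or_buf, str) and "\n" in path_or_buf:
            path_or_buf = io.StringIO(path_or_buf)
        df = pd.read_csv(path_or_buf, index_col="pathogen", dtype=str)
        if scheme is None:
            scheme = CriterionScheme(criteria=tuple(df.columns))
        df = df[list(scheme.criteria)]
        P, C = df.shape
        levels = np.zeros((P, C), dtype=int)
        prov = np.full((P, C), "regional_data", dtype=object)
        for p in range(P):
            for c in range(C):
                cell = df.iat[p, c]
                if pd.isna(cell) or str(cell).strip() == "":
                    levels[p, c] = 0  # sentinel: reported by validate_matrix
                    continue
                if ":" in cell:
                    lvl, code = cell.split(":", 1)
                    prov[p, c] = code
                else:
                    lvl = cell
                levels[p, c] = int(lvl)
        return cls(
            region=region,
            pathogens=list(df.index),
            scheme=scheme,
            levels=levels,
            provenance=prov,
        )

    def preliminary_pathogens(self) -> list[str]:
        """Pathogens with any 'preliminary' provenance (flagged downstream)."""
        mask = (self.provenance == "preliminary").any(axis=1)
        return [p for p, m in zip(self.pathogens, mask) if m]


@dataclass
class BurdenTable:
    """Quantitative burden inputs per pathogen and region.

    ``data`` is a long DataFrame with columns
    ``pathogen, region, deaths_under5, deaths_over5, ylds``
    (annual deaths as counts, years lived with disability in years).
    """

    data: pd.DataFrame

    REQUIRED = ("pathogen", "region", "deaths_under5", "deaths_over5", "ylds")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"burden table missing columns: {missing}")
        vals = self.data[list(QUANTITATIVE_CRITERIA)].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("burden values must be finite")
        if (vals < 0).any():
            raise ValueError("burden values must be non-negative")

    def region(self, region: str) -> pd.DataFrame:
        sub = self.data[self.data["region"] == region]
        if sub.empty:
            raise KeyError(f"no burden data for region {region!r}")
        return sub.set_index("pathogen")


def quantile_levels(values: np.ndarray, n_levels: int = 5) -> np.ndarray:
    """Rank-based ordinal binning: equal values share the lower level.

    Pathogens are ranked ascending (rank 1 = lowest burden, ties take
    the minimum rank) and ranks are sliced into ``n_levels`` equal
    spans: ``level = 1 + floor(n_levels * (rank - 1) / n)``.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < n_levels:
        raise DegenerateBinningError(
            f"{n} pathogens cannot be binned into {n_levels} levels"
        )
    ranks = pd.Series(values).rank(method="min").to_numpy()
    return (1 + np.floor(n_levels * (ranks - 1) / n)).astype(int)


def log_threshold_levels(
    values: np.ndarray, n_levels: int = 5, floor: float = 1.0
) -> np.ndarray:
    """Alternative binning on log-spaced absolute thresholds.

    Thresholds are spaced evenly in log10 between ``floor`` and the
    maximum value; values at or below ``floor`` map to level 1.
    """
    values = np.asarray(values, dtype=float)
    top = values.max()
    if top <= floor:
        return np.ones(len(values), dtype=int)
    edges = np.logspace(np.log10(floor), np.log10(top), n_levels + 1)[1:-1]
    return (1 + np.searchsorted(edges, values, side="left")).astype(int)


def assign_quantitative_levels(
    burden: BurdenTable,
    region: str,
    scheme: CriterionScheme | None = None,
    n_levels: int = 5,
    mode: str = "quantile",
) -> ScoreMatrix:
    """Score the quantitative criteria for one region from burden data.

    Returns a partial :class:`ScoreMatrix` restricted to the
    quantitative criteria, with all provenance ``regional_data``.
    Qualitative criteria are input data (scored against an external
    rubric) and are merged in separately.
    """
    sub = burden.region(region)
    binner = {"quantile": quantile_levels, "log_threshold": log_threshold_levels}[mode]
    crits = [c for c in QUANTITATIVE_CRITERIA]
    if scheme is None:
        scheme = CriterionScheme(criteria=tuple(crits), n_levels=n_levels)
    levels = np.column_stack(
        [binner(sub[c].to_numpy(), n_levels) for c in crits]
    )
    return ScoreMatrix(
        region=region,
        pathogens=list(sub.index),
        scheme=scheme,
        levels=levels,
    )


@dataclass(frozen=True)
class Violation:
    kind: str  # missing_cell | out_of_range | bad_provenance
    pathogen: str
    criterion: str
    detail: str = ""


def validate_matrix(matrix: ScoreMatrix, scheme: CriterionScheme) -> list[Violation]:
    """Report every validity violation of a score matrix; empty iff valid."""
    report: list[Violation] = []
    mat_crits = list(matrix.scheme.criteria)
    for c in scheme.criteria:
        if c not in mat_crits:
            for p in matrix.pathogens:
                report.append(Violation("missing_cell", p, c, "criterion absent"))
    for pi, p in enumerate(matrix.pathogens):
        for c in scheme.criteria:
            if c not in mat_crits:
                continue
            ci = mat_crits.index(c)
            lvl = matrix.levels[pi, ci]
            if lvl == 0:
                report.append(Violation("missing_cell", p, c, "empty cell"))
                continue
            if not (1 <= lvl <= scheme.n_levels):
                report.append(
                    Violation(
                        "out_of_range", p, c, f"level {lvl} outside 1..{scheme.n_levels}"
                    )
                )
            prov = matrix.provenance[pi, ci]
            if prov not in PROVENANCE_CODES:
                report.append(
                    Violation("bad_provenance", p, c, f"unknown code {prov!r}")
                )
    return report
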