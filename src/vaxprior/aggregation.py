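"""Regional and global priority lists from respondent value systems.

Regional criterion weights are the arithmetic means of individual
respondents' weights (the mean is taken over the full point-value
tables, so heterogeneity in level spacing is preserved; by linearity
this equals averaging per-respondent totals).  Applying mean point
values to a region's score matrix ranks its pathogens; the top ten of
each region are combined into the global priority list.  Robustness is
assessed by recomputing the global list with one criterion omitted at
a time, and by re-running the pipeline on respondent subsets (e.g. one
preference cluster at a time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .paprika import ValueSystem, rank_alternatives
from .scheme import CriterionScheme
from .scoring import ScoreMatrix


@dataclass
class RegionalWeights:
    """Mean point values and criterion weights for one region."""

    region: str
    scheme: CriterionScheme
    mean_values: np.ndarray  # (n_criteria, n_levels)
    sd_weights: np.ndarray  # per-criterion SD of top-level weights
    n_respondents: int

    @property
    def mean_weights(self) -> np.ndarray:
        return self.mean_values[:, -1]

    def as_value_system(self) -> ValueSystem:
        return ValueSystem(scheme=self.scheme, values=self.mean_values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": list(self.scheme.criteria),
                "mean_weight": self.mean_weights,
                "sd_weight": self.sd_weights,
            }
        )


@dataclass
class PriorityList:
    """Pathogens of one region ranked by total weight."""

    region: str
    table: pd.DataFrame  # pathogen, total_weight, rank, in_top_k, tied_at_cutoff
    k: int

    @property
    def top(self) -> list[str]:
        return list(self.table.loc[self.table["in_top_k"], "pathogen"])

    def rank_of(self, pathogen: str) -> int:
        row = self.table[self.table["pathogen"] == pathogen]
        if row.empty:
            raise KeyError(pathogen)
        return int(row["rank"].iloc[0])


@dataclass
class GlobalList:
    """Union of regional top-k lists with per-pathogen region membership."""

    table: pd.DataFrame  # pathogen, region_count, regions, best_rank
    regions: tuple[str, ...]

    @property
    def pathogens(self) -> list[str]:
        return list(self.table["pathogen"])

    def members(self) -> set[str]:
        return set(self.table["pathogen"])


def regional_mean_weights(
    value_systems: list[ValueSystem], region: str = ""
) -> RegionalWeights:
    """Average individual value systems into regional mean weights."""
    if not value_systems:
        raise ValueError("need at least one value system")
    scheme = value_systems[0].scheme
    for vs in value_systems[1:]:
        if vs.scheme != scheme:
            raise ValueError("all value systems must share one scheme")
    stack = np.stack([vs.values for vs in value_systems])
    mean_values = stack.mean(axis=0)
    sd_weights = stack[:, :, -1].std(axis=0, ddof=0)
    return RegionalWeights(
        region=region,
        scheme=scheme,
        mean_values=mean_values,
        sd_weights=sd_weights,
        n_respondents=len(value_systems),
    )


def regional_top_k(
    weights: RegionalWeights, matrix: ScoreMatrix, k: int = 10
) -> PriorityList:
    """Rank a region's pathogens and truncate to the top ``k``.

    Pathogens tied with the pathogen at rank ``k`` are all included and
    annotated (``tied_at_cutoff``) rather than dropped arbitrarily.
    """
    if k > len(matrix.pathogens):
        raise ValueError(
            f"k={k} exceeds the {len(matrix.pathogens)}-pathogen panel"
        )
    ranked = rank_alternatives(weights.as_value_system(), matrix)
    cutoff = ranked["total_weight"].iloc[k - 1]
    in_top = ranked["total_weight"] >= cutoff - 1e-12
    tied = ranked["total_weight"].round(12).duplicated(keep=False)
    at_cutoff = np.abs(ranked["total_weight"] - cutoff) <= 1e-12
    ranked = ranked.assign(
        in_top_k=in_top,
        tied=tied,
        tied_at_cutoff=tied & at_cutoff & (in_top.sum() > k),
    )
    return PriorityList(region=weights.region, table=ranked, k=k)


def build_global_list(regional_lists: list[PriorityList]) -> GlobalList:
    """Union the regional top-k lists into the global priority list.

    Ordered by number of regions listing the pathogen (descending),
    then best regional rank (ascending), then name.
    """
    if not regional_lists:
        raise ValueError("need at least one regional list")
    rows: dict[str, dict] = {}
    for pl in regional_lists:
        for p in pl.top:
            entry = rows.setdefault(
                p, {"pathogen": p, "regions": [], "best_rank": np.inf}
            )
            entry["regions"].append(pl.region)
            entry["best_rank"] = min(entry["best_rank"], pl.rank_of(p))
    table = pd.DataFrame(
        sorted(
            rows.values(),
            key=lambda r: (-len(r["regions"]), r["best_rank"], r["pathogen"]),
        )
    )
    table["region_count"] = table["regions"].map(len)
    table["best_rank"] = table["best_rank"].astype(int)
    table["regions"] = table["regions"].map(tuple)
    table = table[["pathogen", "region_count", "regions", "best_rank"]]
    return GlobalList(table=table, regions=tuple(pl.region for pl in regional_lists))


def _omit_criterion(weights: RegionalWeights, criterion: str) -> RegionalWeights:
    idx = weights.scheme.criterion_index(criterion)
    vals = weights.mean_values.copy()
    vals[idx, :] = 0.0  # removing a criterion == zeroing its contribution
    return RegionalWeights(
        region=weights.region,
        scheme=weights.scheme,
        mean_values=vals,
        sd_weights=weights.sd_weights,
        n_respondents=weights.n_respondents,
    )


@dataclass
class RobustnessReport:
    """Per-omitted-criterion changes to the global priority list."""

    baseline: GlobalList
    deltas: dict[str, dict]  # criterion -> {"dropped": [...], "added": [...]}

    @property
    def stable_pathogens(self) -> list[str]:
        """Baseline pathogens unaffected by any single-criterion omission."""
        dropped = set()
        for d in self.deltas.values():
            dropped.update(d["dropped"])
        return [p for p in self.baseline.pathogens if p not in dropped]

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.pathogens,
            "deltas": {
                c: {"dropped": d["dropped"], "added": d["added"]}
                for c, d in self.deltas.items()
            },
            "stable": self.stable_pathogens,
        }


def robustness_leave_one_out(
    weights_by_region: dict[str, RegionalWeights],
    matrices: dict[str, ScoreMatrix],
    k: int = 10,
) -> RobustnessReport:
    """Recompute the global list omitting one criterion at a time.

    Omission removes the criterion's additive contribution without
    renormalising the remaining weights — rankings are scale-free, so
    renormalisation could not change the order.
    """
    scheme = next(iter(weights_by_region.values())).scheme
    if scheme.n_criteria < 2:
        raise ValueError("need at least 2 criteria")

    def global_for(transform) -> GlobalList:
        lists = [
            regional_top_k(transform(weights_by_region[r]), matrices[r], k=k)
            for r in weights_by_region
        ]
        return build_global_list(lists)

    baseline = global_for(lambda w: w)
    base_set = baseline.members()
    deltas: dict[str, dict] = {}
    for criterion in scheme.criteria:
        gl = global_for(lambda w: _omit_criterion(w, criterion))
        new_set = gl.members()
        deltas[criterion] = {
            "dropped": sorted(base_set - new_set),
            "added": sorted(new_set - base_set),
        }
    return RobustnessReport(baseline=baseline, deltas=deltas)


def subset_reanalysis(
    value_systems_by_region: dict[str, list[ValueSystem]],
    matrices: dict[str, ScoreMatrix],
    k: int = 10,
) -> GlobalList:
    """Re-run the regional-means → top-k → global pipeline on a subset.

    Used for cluster-restricted reanalyses: pass only the value systems
    of the respondents in one cluster.
    """
    if not any(value_systems_by_region.values()):
        raise ValueError("subset is empty")
    lists = []
    for region, systems in value_systems_by_region.items():
        if not systems:
            continue
        rw = regional_mean_weights(systems, region=region)
        lists.append(regional_top_k(rw, matrices[region], k=k))
    return build_global_list(lists)
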