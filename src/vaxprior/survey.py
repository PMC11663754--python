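"""Response hygiene and participant statistics for MCDA surveys.

Covers the survey-side statistics of the prioritisation pipeline:
exclusion of incomplete, duplicate and straight-lined responses;
exact tests for differences in participant characteristics between
regions; per-criterion adjusted mean differences in weights by
multivariate linear regression; and a completion-bias check fitting a
logistic GEE over repeated submissions per respondent.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import build_design


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (as reported)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def identity_hash(name: str, email: str) -> str:
    """Deterministic privacy-preserving respondent identity.

    Case-folded, whitespace-stripped name+email hashed with SHA-1;
    stands in for the study's manual screening of names and addresses.
    """
    key = f"{str(name).strip().casefold()}|{str(email).strip().casefold()}"
    return hashlib.sha1(key.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------


@dataclass
class ExclusionReport:
    received: int
    complete: int
    incomplete: int
    duplicates: int
    straightlined: int
    other_invalid: int
    analysed: int

    @property
    def invalid(self) -> int:
        """Complete responses excluded after completion screening."""
        return self.duplicates + self.straightlined + self.other_invalid

    @property
    def pct_complete(self) -> int:
        return round_half_up(100 * self.complete / self.received)

    @property
    def pct_analysed(self) -> int:
        return round_half_up(100 * self.analysed / self.received)

    def check(self) -> None:
        assert self.analysed == self.complete - self.invalid
        assert (
            self.received
            == self.analysed
            + self.incomplete
            + self.duplicates
            + self.straightlined
            + self.other_invalid
        )

    def to_dict(self) -> dict:
        return {
            "received": self.received,
            "complete": self.complete,
            "incomplete": self.incomplete,
            "duplicates": self.duplicates,
            "straightlined": self.straightlined,
            "other_invalid": self.other_invalid,
            "invalid": self.invalid,
            "analysed": self.analysed,
            "pct_complete": self.pct_complete,
            "pct_analysed": self.pct_analysed,
        }


def is_straightlined(verdicts) -> bool:
    """True when every trade-off was answered with the same option."""
    vs = [str(v) for v in verdicts]
    return len(vs) > 0 and len(set(vs)) == 1 and vs[0] in ("first", "second")


def apply_exclusions(responses: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Screen raw survey responses down to the analysed set.

    ``responses`` must have one row per submission, in submission
    order, with columns ``complete`` (bool) and either ``identity`` or
    both ``name`` and ``email``; straight-lining is read from a
    ``verdicts`` column (sequence of 'first'/'second'/'indifferent') or
    a precomputed boolean ``straightlined`` column.  An optional
    boolean ``invalid`` column marks responses invalid for other
    reasons.  The first fully-completed, valid submission per
    respondent is kept.
    """
    df = responses.copy()
    if "identity" not in df.columns:
        df["identity"] = [
            identity_hash(n, e) for n, e in zip(df["name"], df["email"])
        ]
    if "straightlined" not in df.columns:
        df["straightlined"] = df["verdicts"].map(is_straightlined)
    if "invalid" not in df.columns:
        df["invalid"] = False
    df["invalid"] = df["invalid"].map(lambda v: bool(v) and not pd.isna(v))
    df["complete"] = df["complete"].map(lambda v: bool(v) and not pd.isna(v))

    received = len(df)
    complete = int(df["complete"].sum())
    incomplete = received - complete

    kept_rows = []
    n_dup = n_straight = n_other = 0
    seen: set[str] = set()
    for _, row in df[df["complete"]].iterrows():
        if row["identity"] in seen:
            n_dup += 1
            continue
        seen.add(row["identity"])
        if row["straightlined"]:
            n_straight += 1
            continue
        if row["invalid"]:
            n_other += 1
            continue
        kept_rows.append(row)

    analysed = (
        pd.DataFrame(kept_rows).reset_index(drop=True)
        if kept_rows
        else df.iloc[0:0]
    )
    report = ExclusionReport(
        received=received,
        complete=complete,
        incomplete=incomplete,
        duplicates=n_dup,
        straightlined=n_straight,
        other_invalid=n_other,
        analysed=len(analysed),
    )
    report.check()
    return analysed, report


# ---------------------------------------------------------------------------
# Exact and descriptive tests
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, by direct enumeration.

    The two-sided p-value is the total hypergeometric probability of
    all tables (with the observed margins) no more probable than the
    observed one — the standard probability-mass definition.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    a, b = t[0]
    c, d = t[1]
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("Fisher test undefined for a zero margin")
    rv = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(c1, r1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def chi_square_2x2(table, correction: bool = True) -> float:
    """Pearson chi-square p-value for a 2x2 table (Yates-corrected)."""
    _, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=correction)
    return float(p)


def welch_t_test(x, y) -> float:
    """Two-sided Welch t-test p-value for a difference in means."""
    return float(stats.ttest_ind(np.asarray(x), np.asarray(y), equal_var=False).pvalue)


# ---------------------------------------------------------------------------
# Adjusted mean differences in criteria weights
# ---------------------------------------------------------------------------


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    """Columns linearly dependent on the preceding ones (with intercept)."""
    cols = list(X.columns)
    base = np.ones((len(X), 1))
    kept = base
    aliased = []
    for col in cols:
        cand = np.column_stack([kept, X[col].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(kept):
            kept = cand
        else:
            aliased.append(col)
    return aliased


def adjusted_mean_differences(
    weights: pd.DataFrame,
    covariates: pd.DataFrame,
    reference_levels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-criterion OLS of weights on the full covariate set.

    ``weights`` has one column per criterion (percent weights per
    respondent).  Returns a long table with the adjusted mean
    difference (aMD) and normal-theory 95% CI for every non-reference
    covariate level; perfectly collinear (aliased) terms are dropped
    from the fit and reported with ``aliased=True``.
    """
    import statsmodels.api as sm

    X, refs = build_design(covariates, reference_levels)
    aliased = _aliased_columns(X)
    Xf = X.drop(columns=aliased)
    n, p = Xf.shape
    if n <= p + 1:
        raise ValueError("more model terms than observations")
    Xc = sm.add_constant(Xf, has_constant="add")
    rows = []
    for criterion in weights.columns:
        fit = sm.OLS(weights[criterion].to_numpy(dtype=float), Xc).fit()
        for term in X.columns:
            if term in aliased:
                rows.append(
                    {
                        "criterion": criterion,
                        "term": term,
                        "amd": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p_value": np.nan,
                        "aliased": True,
                    }
                )
                continue
            est = fit.params[term]
            se = fit.bse[term]
            rows.append(
                {
                    "criterion": criterion,
                    "term": term,
                    "amd": float(est),
                    "ci_low": float(est - 1.959963984540054 * se),
                    "ci_high": float(est + 1.959963984540054 * se),
                    "p_value": float(fit.pvalues[term]),
                    "aliased": False,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["reference_levels"] = refs
    return out


# ---------------------------------------------------------------------------
# Completion bias (GEE over repeated submissions)
# ---------------------------------------------------------------------------


def completion_bias_gee(
    responses: pd.DataFrame,
    covariate_columns: list[str],
    reference_levels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Associations between participant characteristics and completion.

    Fits a logistic GEE with an exchangeable working correlation over
    repeated submissions per respondent (``identity`` column), with
    robust sandwich standard errors.  With one submission per
    respondent this reduces to ordinary logistic regression.  Returns a
    table of odds ratios with 95% CIs.
    """
    import statsmodels.api as sm

    df = responses.copy()
    if "identity" not in df.columns:
        df["identity"] = [
            identity_hash(n, e) for n, e in zip(df["name"], df["email"])
        ]
    y = df["complete"].astype(float).to_numpy()
    X, refs = build_design(df[covariate_columns], reference_levels)
    aliased = _aliased_columns(X)
    Xf = X.drop(columns=aliased)
    Xc = sm.add_constant(Xf, has_constant="add")
    groups = df["identity"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(
            y,
            Xc,
            groups=groups,
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        fit = model.fit(maxiter=100)
    rows = []
    for term in Xf.columns:
        beta = fit.params[term]
        se = fit.bse[term]
        lo = np.clip(beta - 1.959963984540054 * se, -700, 700)
        hi = np.clip(beta + 1.959963984540054 * se, -700, 700)
        rows.append(
            {
                "term": term,
                "odds_ratio": float(np.exp(np.clip(beta, -700, 700))),
                "ci_low": float(np.exp(lo)),
                "ci_high": float(np.exp(hi)),
                "p_value": float(fit.pvalues[term]),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["reference_levels"] = refs
    out.attrs["aliased"] = aliased
    out.attrs["converged"] = bool(getattr(fit, "converged", True))
    return out
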