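"""Cluster structure in respondent weights, and the design's power bound.

Respondents' value systems are summarised by a composite indicator: the
point values at the Medium and Very High levels of each criterion (16
features for the 8-criterion scheme), standardised and decomposed by
PCA, keeping the smallest prefix of components explaining at least 80%
of variance (this sidesteps the collinearity built into weights that
sum to 100).  K-means is run on the retained component scores for a
range of candidate k; the number of clusters is chosen by consensus of
four selectors — the elbow (maximum curvature of the within-cluster
sum of squares), the mean silhouette, the gap statistic, and a
two-index battery (Calinski–Harabasz and Davies–Bouldin).

Cluster membership is then related to respondent characteristics with
a binomial GLM (logit link), and the design's sensitivity is
characterised by the minimum detectable odds ratio: the smallest and
largest odds ratios detectable at given power and significance with
the observed cluster sizes, from the continuity-corrected two-sample
proportion power equation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)
from sklearn.preprocessing import StandardScaler

from .paprika import ValueSystem


# ---------------------------------------------------------------------------
# Composite indicator
# ---------------------------------------------------------------------------


@dataclass
class CompositeIndicator:
    scores: np.ndarray  # (n_respondents, n_retained)
    explained_variance_ratio: np.ndarray  # all components
    n_retained: int
    feature_names: list[str]
    dropped_features: list[str] = field(default_factory=list)

    @property
    def cumulative_explained(self) -> float:
        return float(self.explained_variance_ratio[: self.n_retained].sum())


def composite_features(value_systems: list[ValueSystem]) -> pd.DataFrame:
    """Medium- and top-level point values per criterion, per respondent."""
    scheme = value_systems[0].scheme
    med = scheme.medium_level - 1
    top = scheme.n_levels - 1
    cols = {}
    for i, c in enumerate(scheme.criteria):
        cols[f"{c}__medium"] = [vs.values[i, med] for vs in value_systems]
        cols[f"{c}__very_high"] = [vs.values[i, top] for vs in value_systems]
    return pd.DataFrame(cols)


def build_composite(
    value_systems: list[ValueSystem], min_explained: float = 0.80
) -> CompositeIndicator:
    """PCA composite of Medium/Very-High level values (retain >=80% EVR)."""
    if len(value_systems) < 3:
        raise ValueError("need at least 3 respondents")
    return composite_from_features(
        composite_features(value_systems), min_explained
    )


def composite_from_features(
    feats: pd.DataFrame, min_explained: float = 0.80
) -> CompositeIndicator:
    """PCA composite from an arbitrary respondent-by-feature table."""
    variances = feats.var(axis=0, ddof=0)
    dropped = list(feats.columns[variances <= 1e-12])
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}")
        feats = feats.drop(columns=dropped)
    X = StandardScaler().fit_transform(feats.to_numpy())
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    n_ret = int(np.searchsorted(np.cumsum(evr), min_explained - 1e-12) + 1)
    n_ret = min(n_ret, scores.shape[1])
    return CompositeIndicator(
        scores=scores[:, :n_ret],
        explained_variance_ratio=evr,
        n_retained=n_ret,
        feature_names=list(feats.columns),
        dropped_features=dropped,
    )


# ---------------------------------------------------------------------------
# Consensus choice of k
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    k: int
    assignments: np.ndarray  # 1-based cluster labels
    centroids: np.ndarray
    diagnostics: pd.DataFrame  # per-candidate-k indices
    votes: dict[str, int]
    annotations: list[str] = field(default_factory=list)

    def sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.assignments, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def _gap_statistic(
    X: np.ndarray, k_values: list[int], rng: np.random.Generator, n_ref: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Tibshirani gap statistic against uniform draws over the bounding box."""
    lo, hi = X.min(axis=0), X.max(axis=0)

    def log_wk(data: np.ndarray, k: int) -> float:
        if k == 1:
            centroid = data.mean(axis=0)
            return float(np.log(((data - centroid) ** 2).sum()))
        km = KMeans(n_clusters=k, n_init=5, random_state=0).fit(data)
        return float(np.log(km.inertia_))

    gaps = np.zeros(len(k_values))
    sks = np.zeros(len(k_values))
    ref_logs = np.zeros((n_ref, len(k_values)))
    for b in range(n_ref):
        ref = rng.uniform(lo, hi, size=X.shape)
        for i, k in enumerate(k_values):
            ref_logs[b, i] = log_wk(ref, k)
    for i, k in enumerate(k_values):
        obs = log_wk(X, k)
        gaps[i] = ref_logs[:, i].mean() - obs
        sks[i] = ref_logs[:, i].std(ddof=0) * np.sqrt(1 + 1 / n_ref)
    return gaps, sks


def _elbow_k(k_values: list[int], wss: np.ndarray) -> int:
    """Maximum-curvature elbow: largest discrete second difference of WSS.

    ``k_values`` must include the single-cluster point so that an elbow
    at the smallest candidate k is detectable; the returned k is always
    a candidate (>= the second entry).
    """
    if len(k_values) < 3:
        return k_values[-1]
    curv = wss[:-2] - 2 * wss[1:-1] + wss[2:]
    return k_values[1 + int(np.argmax(curv))]


def choose_k(
    scores: np.ndarray,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    n_init: int = 10,
    n_ref: int = 50,
) -> ClusterModel:
    """K-means with the cluster number chosen by consensus of four selectors.

    The consensus k is the mode of the selectors' votes (elbow,
    silhouette, gap statistic, and the Calinski–Harabasz /
    Davies–Bouldin battery); ties go to the smaller k.  The gap
    statistic uses Tibshirani's one-standard-error rule including the
    single-cluster model; if it prefers one cluster, it votes for the
    smallest candidate k and the decision is annotated.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 observations")
    k_lo, k_hi = k_range
    k_hi = min(k_hi, n - 1, 25)
    if not (2 <= k_lo <= k_hi):
        raise ValueError(f"invalid k range ({k_lo}, {k_hi})")
    k_values = list(range(k_lo, k_hi + 1))

    rng = np.random.default_rng(seed)
    fits: dict[int, KMeans] = {}
    rows = []
    for k in k_values:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        fits[k] = km
        labels = km.labels_
        rows.append(
            {
                "k": k,
                "wss": km.inertia_,
                "silhouette": silhouette_score(X, labels),
                "calinski_harabasz": calinski_harabasz_score(X, labels),
                "davies_bouldin": davies_bouldin_score(X, labels),
            }
        )
    diag = pd.DataFrame(rows).set_index("k")

    gap_ks = [1] + k_values
    gaps, sks = _gap_statistic(X, gap_ks, rng, n_ref=n_ref)
    diag["gap"] = gaps[1:]
    diag["gap_se"] = sks[1:]

    annotations: list[str] = []

    # Selector votes -------------------------------------------------
    votes: dict[str, int] = {}
    wss1 = float(((X - X.mean(axis=0)) ** 2).sum())
    votes["elbow"] = _elbow_k(
        [1] + k_values, np.concatenate([[wss1], diag["wss"].to_numpy()])
    )
    votes["silhouette"] = int(diag["silhouette"].idxmax())
    # Gap: smallest k with gap[k] >= gap[k+1] - se[k+1] (incl. k=1).
    gap_choice = gap_ks[-1]
    for i in range(len(gap_ks) - 1):
        if gaps[i] >= gaps[i + 1] - sks[i + 1]:
            gap_choice = gap_ks[i]
            break
    if gap_choice == 1:
        annotations.append(
            "gap statistic prefers a single cluster; voting for the smallest candidate k"
        )
        gap_choice = k_values[0]
    votes["gap"] = int(gap_choice)
    # Index battery: Calinski-Harabasz max and Davies-Bouldin min;
    # the battery's vote is the smaller when they disagree.
    ch = int(diag["calinski_harabasz"].idxmax())
    db = int(diag["davies_bouldin"].idxmin())
    votes["index_battery"] = min(ch, db) if ch != db else ch

    tally = pd.Series(list(votes.values())).value_counts()
    best = tally.max()
    consensus = int(min(k for k, c in tally.items() if c == best))
    if (tally == best).sum() > 1:
        annotations.append("selector votes tied; smaller k chosen")

    km = fits[consensus]
    return ClusterModel(
        k=consensus,
        assignments=km.labels_ + 1,
        centroids=km.cluster_centers_,
        diagnostics=diag.reset_index(),
        votes=votes,
        annotations=annotations,
    )


def cluster_profiles(
    assignments: np.ndarray, value_systems: list[ValueSystem], top_n: int = 2
) -> dict[int, tuple[str, ...]]:
    """Identify clusters by which criteria dominate their mean weights.

    Downstream reports use these profiles, not the arbitrary k-means
    label indices, so results are invariant to label permutation.
    """
    scheme = value_systems[0].scheme
    W = np.stack([vs.weights for vs in value_systems])
    out: dict[int, tuple[str, ...]] = {}
    for lab in np.unique(assignments):
        mean_w = W[np.asarray(assignments) == lab].mean(axis=0)
        order = np.argsort(mean_w)[::-1][:top_n]
        out[int(lab)] = tuple(scheme.criteria[i] for i in order)
    return out


# ---------------------------------------------------------------------------
# Membership GLM
# ---------------------------------------------------------------------------


@dataclass
class MembershipModel:
    table: pd.DataFrame  # term, odds_ratio, ci_low, ci_high, p_value, reference
    separation: bool
    separated_terms: list[str]
    reference_levels: dict[str, str]


def build_design(
    covariates: pd.DataFrame, reference_levels: dict[str, str] | None = None
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Dummy-code a covariate frame, dropping stated reference levels.

    Boolean and numeric columns pass through; categorical columns are
    expanded with the reference level (default: first sorted level)
    omitted.
    """
    reference_levels = dict(reference_levels or {})
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == bool:
            parts.append(s.astype(float).rename(col))
            reference_levels.setdefault(col, "False")
        elif np.issubdtype(s.dtype, np.number):
            parts.append(s.astype(float))
        else:
            levels = sorted(s.astype(str).unique())
            ref = reference_levels.setdefault(col, levels[0])
            for lev in levels:
                if lev == ref:
                    continue
                parts.append(
                    (s.astype(str) == lev).astype(float).rename(f"{col}[{lev}]")
                )
    X = pd.concat(parts, axis=1)
    return X, reference_levels


def fit_membership_glm(
    assignments: np.ndarray,
    covariates: pd.DataFrame,
    reference_levels: dict[str, str] | None = None,
    target_cluster: int | None = None,
) -> MembershipModel:
    """Binomial GLM (logit) of cluster membership on respondent covariates.

    ``assignments`` must be two-cluster labels; membership in
    ``target_cluster`` (default: the smaller cluster) is the outcome.
    Perfect separation is detected and the affected terms reported as
    non-estimable instead of returning meaningless huge odds ratios.
    """
    import statsmodels.api as sm

    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    if len(labels) != 2:
        raise ValueError("membership model requires exactly two clusters")
    if target_cluster is None:
        sizes = {lab: (assignments == lab).sum() for lab in labels}
        target_cluster = min(sizes, key=sizes.get)
    y = (assignments == target_cluster).astype(float)
    if covariates.isna().any().any():
        raise ValueError("covariates must be complete")
    X, refs = build_design(covariates, reference_levels)

    # Perfect separation screen: a dummy column whose two values split y.
    separated = []
    for col in X.columns:
        x = X[col]
        if x.nunique() <= 2:
            tab = pd.crosstab(x, y)
            if tab.shape == (2, 2) and (tab == 0).any().any() and tab.sum().min() > 0:
                grp = tab.to_numpy()
                # separation only if some x level is pure in y
                if (grp[0] == 0).any() or (grp[1] == 0).any():
                    separated.append(col)

    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=100)
            converged = fit.converged
        except Exception:
            fit, converged = None, False

    rows = []
    for term in X.columns:
        if fit is None or term in separated or not converged:
            rows.append(
                {
                    "term": term,
                    "odds_ratio": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": np.nan,
                    "estimable": False,
                }
            )
            continue
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
                "estimable": True,
            }
        )
    return MembershipModel(
        table=pd.DataFrame(rows),
        separation=bool(separated) or not converged,
        separated_terms=separated,
        reference_levels=refs,
    )


# ---------------------------------------------------------------------------
# Minimum detectable odds ratio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerSpec:
    """Design for the two-cluster minimum-detectable-odds-ratio bound.

    ``n1`` is the comparison cluster, ``n2`` the reference cluster in
    which a background characteristic has prevalence ``p0``.
    """

    n1: int
    n2: int
    p0: float
    power: float = 0.80
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.p0 < 1):
            raise ValueError("p0 must be in (0, 1)")
        if not (0 < self.power < 1):
            raise ValueError("power must be in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("group sizes must be positive")


def two_proportion_power(
    p1: float,
    p2: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    continuity: bool = True,
) -> float:
    """Power of the two-sided two-sample proportion test (normal approx.).

    Uses the pooled-variance null standard error and, by default, the
    Fleiss continuity correction ``(1/n1 + 1/n2)/2`` on the detectable
    difference.
    """
    za = stats.norm.ppf(1 - alpha / 2)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    se1 = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    diff = abs(p1 - p2)
    if continuity:
        diff -= (1 / n1 + 1 / n2) / 2
    return float(stats.norm.cdf((diff - za * se0) / se1))


def min_detectable_or(
    spec: PowerSpec, tol: float = 1e-6, continuity: bool = True
) -> tuple[float, float]:
    """Minimum detectable odds ratios (below and above 1) for the design.

    Solves the continuity-corrected power equation by bisection for the
    comparison-cluster prevalence nearest the reference prevalence
    ``p0`` (upward and downward) that still achieves the target power,
    then converts each prevalence to an odds ratio against ``p0``.
    """
    p0 = spec.p0

    def gap(p1: float) -> float:
        return (
            two_proportion_power(
                p1, p0, spec.n1, spec.n2, alpha=spec.alpha, continuity=continuity
            )
            - spec.power
        )

    hi_edge = 1 - 1e-9
    lo_edge = 1e-9
    if gap(hi_edge) < 0 or gap(lo_edge) < 0:
        raise ValueError("no detectable prevalence in (0, 1) at this power")
    p_hi = brentq(gap, p0 + 1e-9, hi_edge, xtol=tol)
    p_lo = brentq(gap, lo_edge, p0 - 1e-9, xtol=tol)

    def odds_ratio(p: float) -> float:
        return (p / (1 - p)) / (p0 / (1 - p0))

    return odds_ratio(p_lo), odds_ratio(p_hi)
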