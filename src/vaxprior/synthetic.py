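"""Seeded synthetic MCDA studies for end-to-end testing.

Emulates the statistical structure the analysis pipeline assumes:
respondents drawn from two latent weight-profile clusters (a majority
profile weighting antimicrobial resistance and outbreak disruption
most heavily, and a minority profile weighting the mortality criteria),
realistic biographical covariates drawn independently of cluster,
choice error and occasional indifference in the trade-off answers,
logistic noncompletion, duplicate submissions, straight-lined sessions,
and regional pathogen score matrices with cross-region correlation and
a configurable globally dominant pathogen subset.

Everything is driven by a single integer seed: identical configuration
and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paprika import (
    InconsistentAnswerError,
    RespondentSession,
    Verdict,
)
from .scheme import CriterionScheme
from .scoring import (
    DEFAULT_PATHOGENS,
    DEFAULT_REGIONS,
    QUANTITATIVE_CRITERIA,
    ScoreMatrix,
    quantile_levels,
)

#: Mean criterion weights (percent) of the two latent preference profiles.
#: Profile 1 (majority) puts the greatest weight on contribution to AMR
#: and disruption due to outbreaks; profile 2 on the two mortality
#: criteria.  Magnitudes mirror the 10-19% range typical of
#: eight-criterion weight elicitations.
CLUSTER_MEAN_WEIGHTS: dict[int, tuple[float, ...]] = {
    1: (10.0, 10.0, 11.0, 11.0, 17.0, 12.0, 18.0, 11.0),
    2: (19.0, 17.0, 12.0, 11.0, 9.0, 11.0, 10.0, 11.0),
}

#: Regional sampling weights for survey responses (sum to 1).
DEFAULT_REGION_WEIGHTS: tuple[float, ...] = (
    0.20,
    0.16,
    0.15,
    0.10,
    0.15,
    0.24,
)

DEFAULT_LANGUAGES: tuple[str, ...] = (
    "English",
    "French",
    "Spanish",
    "Arabic",
    "Chinese",
    "Russian",
    "Portuguese",
)
DEFAULT_LANGUAGE_WEIGHTS = (0.55, 0.10, 0.10, 0.07, 0.08, 0.05, 0.05)

EXPERTISE_AREAS: tuple[str, ...] = (
    "expertise_epidemiology",
    "expertise_vaccine_rd",
    "expertise_health_policy",
    "expertise_clinical",
    "expertise_laboratory",
    "expertise_programme_delivery",
)
EXPERTISE_PROBS = (0.52, 0.45, 0.39, 0.30, 0.22, 0.25)

ORGANISATION_TYPES: tuple[str, ...] = (
    "org_academic",
    "org_government",
    "org_ngo",
    "org_pharma",
    "org_who",
    "org_other_un",
    "org_funder",
    "org_healthcare",
    "org_other",
)
ORGANISATION_PROBS = (0.39, 0.33, 0.12, 0.07, 0.08, 0.05, 0.04, 0.15, 0.08)

EXPERIENCE_BANDS: tuple[str, ...] = ("up to 10 years", "11-20 years", "over 20 years")
EXPERIENCE_WEIGHTS = (0.40, 0.35, 0.25)

INCOME_GROUPS: tuple[str, ...] = (
    "high",
    "upper middle",
    "lower middle",
    "low",
)
INCOME_WEIGHTS = (0.35, 0.25, 0.25, 0.15)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the real survey: 577 responses, ~49% completion,
    a 65/35 two-cluster preference mixture, about 4% of complete
    responses contaminated by duplicates or straight-lining, 26
    pathogens scored per region with strong cross-region correlation
    and 5 globally dominant pathogens.
    """

    n_respondents: int = 577
    scheme: CriterionScheme = field(default_factory=CriterionScheme)
    regions: tuple[str, ...] = DEFAULT_REGIONS
    region_weights: tuple[float, ...] = DEFAULT_REGION_WEIGHTS
    cluster_proportions: tuple[float, ...] = (0.65, 0.35)
    cluster_mean_weights: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(CLUSTER_MEAN_WEIGHTS)
    )
    concentration: float = 40.0
    choice_error: float = 0.05
    allow_indifference: bool = True
    completion_intercept: float = -0.031  # logit of the ~49% completion rate
    completion_coefficients: dict[str, float] = field(default_factory=dict)
    duplicate_rate: float = 0.02
    straightliner_rate: float = 0.02
    pathogens: tuple[str, ...] = DEFAULT_PATHOGENS
    cross_region_rho: float = 0.8
    dominant_pathogens: tuple[str, ...] = (
        "Mycobacterium tuberculosis",
        "HIV-1",
        "Klebsiella pneumoniae",
        "Staphylococcus aureus",
        "Extra-intestinal pathogenic E coli",
    )
    dominant_boost: float = 2.0

    def __post_init__(self) -> None:
        if abs(sum(self.cluster_proportions) - 1) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        for k, v in self.cluster_mean_weights.items():
            if len(v) != self.scheme.n_criteria:
                raise ValueError(f"profile {k} has wrong length")
            if abs(sum(v) - 100) > 1e-6:
                raise ValueError(f"profile {k} weights must sum to 100")
        if not (0 <= self.choice_error < 0.5):
            raise ValueError("choice error must be in [0, 0.5)")
        if not (0 <= self.cross_region_rho <= 1):
            raise ValueError("cross-region correlation must be in [0, 1]")
        if abs(sum(self.region_weights) - 1) > 1e-9:
            raise ValueError("region weights must sum to 1")
        unknown = set(self.dominant_pathogens) - set(self.pathogens)
        if unknown:
            raise ValueError(f"dominant pathogens not in panel: {sorted(unknown)}")


@dataclass
class TrueRespondent:
    """A simulated respondent's latent state."""

    index: int
    cluster: int
    values: np.ndarray  # true point values (n_criteria, n_levels), percent
    covariates: dict
    completion_prob: float
    completes: bool
    straightliner: bool
    duplicate: bool

    @property
    def weights(self) -> np.ndarray:
        return self.values[:, -1]


def _true_values(
    scheme: CriterionScheme, mean_weights, concentration: float, rng
) -> np.ndarray:
    """Simplex-constrained weights + ordered level spacings.

    Criterion weights are Dirichlet around the profile mean (so they
    sum to 100 by construction); interior level values are cumulative
    Dirichlet increments of each criterion's weight.
    """
    C, L = scheme.n_criteria, scheme.n_levels
    alpha = np.asarray(mean_weights, dtype=float) / 100.0 * concentration
    if (alpha <= 0).any():
        raise ValueError("profile mean weights must be positive")
    if np.isinf(concentration):
        w = np.asarray(mean_weights, dtype=float)
    else:
        w = rng.dirichlet(alpha) * 100.0
    values = np.zeros((C, L))
    for c in range(C):
        inc = rng.dirichlet(np.ones(L - 1)) * w[c]
        values[c, 1:] = np.cumsum(inc)
    values[:, -1] = w  # exact top values
    return values


def _sample_covariates(config: GeneratorConfig, rng) -> dict:
    cov: dict = {}
    cov["region"] = str(rng.choice(config.regions, p=config.region_weights))
    cov["language"] = str(rng.choice(DEFAULT_LANGUAGES, p=DEFAULT_LANGUAGE_WEIGHTS))
    cov["experience_band"] = str(rng.choice(EXPERIENCE_BANDS, p=EXPERIENCE_WEIGHTS))
    for area, p in zip(EXPERTISE_AREAS, EXPERTISE_PROBS):
        cov[area] = bool(rng.random() < p)
    for org, p in zip(ORGANISATION_TYPES, ORGANISATION_PROBS):
        cov[org] = bool(rng.random() < p)
    cov["gavi_eligible"] = bool(rng.random() < 0.25)
    cov["income_group"] = str(rng.choice(INCOME_GROUPS, p=INCOME_WEIGHTS))
    cov["survey_ease"] = str(rng.choice(["easy", "neutral", "difficult"], p=[0.6, 0.3, 0.1]))
    cov["weights_order_ok"] = str(rng.choice(["yes", "no"], p=[0.9, 0.1]))
    cov["rankings_reasonable"] = str(rng.choice(["yes", "no"], p=[0.85, 0.15]))
    return cov


def _completion_prob(config: GeneratorConfig, cov: dict) -> float:
    logit = config.completion_intercept
    for key, coef in config.completion_coefficients.items():
        if "=" in key:
            col, val = key.split("=", 1)
            x = float(str(cov[col]) == val)
        else:
            x = float(bool(cov[key]))
        logit += coef * x
    return float(1.0 / (1.0 + np.exp(-logit)))


def sample_respondents(
    config: GeneratorConfig, rng: np.random.Generator
) -> list[TrueRespondent]:
    """Draw the latent respondent population for one synthetic study."""
    profiles = sorted(config.cluster_mean_weights)
    props = np.asarray(config.cluster_proportions)
    out = []
    for i in range(config.n_respondents):
        cluster = int(rng.choice(profiles, p=props))
        values = _true_values(
            config.scheme,
            config.cluster_mean_weights[cluster],
            config.concentration,
            rng,
        )
        cov = _sample_covariates(config, rng)
        p_complete = _completion_prob(config, cov)
        completes = bool(rng.random() < p_complete)
        out.append(
            TrueRespondent(
                index=i,
                cluster=cluster,
                values=values,
                covariates=cov,
                completion_prob=p_complete,
                completes=completes,
                straightliner=bool(completes and rng.random() < config.straightliner_rate),
                duplicate=bool(completes and rng.random() < config.duplicate_rate),
            )
        )
    return out


def make_answer_fn(
    respondent: TrueRespondent,
    scheme: CriterionScheme,
    choice_error: float,
    rng: np.random.Generator,
    allow_indifference: bool = True,
):
    """Answer questions from true value sums, with verdict-flip noise.

    With probability ``choice_error`` the verdict is flipped; if a
    flipped (or even true) verdict would contradict the session's
    recorded preferences the session rejects it, so callers fall back
    through the remaining verdicts (see :func:`simulate_session`).
    """
    vals = respondent.values

    def f(q):
        a, b = q.active_criteria
        ia, ib = scheme.criterion_index(a), scheme.criterion_index(b)
        d = (
            vals[ia, q.first.levels[a] - 1]
            - vals[ia, q.second.levels[a] - 1]
            + vals[ib, q.first.levels[b] - 1]
            - vals[ib, q.second.levels[b] - 1]
        )
        if abs(d) < 1e-12:
            return (
                Verdict.INDIFFERENT if allow_indifference else Verdict.FIRST
            )
        verdict = Verdict.FIRST if d > 0 else Verdict.SECOND
        if choice_error > 0 and rng.random() < choice_error:
            verdict = (
                Verdict.SECOND if verdict is Verdict.FIRST else Verdict.FIRST
            )
        return verdict

    return f


def straightline_fn(_q) -> Verdict:
    return Verdict.FIRST


def simulate_session(
    respondent: TrueRespondent,
    scheme: CriterionScheme,
    choice_error: float,
    rng: np.random.Generator,
    allow_indifference: bool = True,
    max_questions: int | None = None,
) -> RespondentSession:
    """Run a full (or truncated) elicitation session for one respondent.

    Straight-liners always choose the first alternative (a consistent,
    lexicographic-style preference, so the session never rejects it).
    If a noise-flipped verdict is rejected as inconsistent, the true
    verdict is recorded instead (and failing that, any verdict the
    session accepts).
    """
    session = RespondentSession(scheme)
    if respondent.straightliner:
        answer = straightline_fn
    else:
        answer = make_answer_fn(
            respondent, scheme, choice_error, rng, allow_indifference
        )
    true_answer = make_answer_fn(respondent, scheme, 0.0, rng, allow_indifference)
    n = 0
    while True:
        if max_questions is not None and n >= max_questions:
            session.abandon()
            break
        q = session.next_question()
        if q is None:
            break
        candidates = [answer(q), true_answer(q), Verdict.FIRST, Verdict.SECOND,
                      Verdict.INDIFFERENT]
        for verdict in candidates:
            try:
                session.record_answer(verdict)
                break
            except InconsistentAnswerError:
                continue
        else:  # pragma: no cover - cannot happen: one verdict is always consistent
            raise RuntimeError("no consistent verdict accepted")
        n += 1
    return session


def sample_score_matrices(
    config: GeneratorConfig, rng: np.random.Generator
) -> dict[str, ScoreMatrix]:
    """Regional score matrices from correlated latent severities.

    Latent pathogen severities per criterion are shared across regions
    with correlation ``cross_region_rho``; the first ``n_dominant``
    pathogens receive a latent boost on every criterion, emulating the
    handful of pathogens that reach every regional top-ten.  Latents
    are mapped to quintile levels within each region.
    """
    P = len(config.pathogens)
    C = config.scheme.n_criteria
    rho = config.cross_region_rho
    z_global = rng.standard_normal((P, C))
    boost = np.zeros((P, C))
    dom_idx = [config.pathogens.index(p) for p in config.dominant_pathogens]
    boost[dom_idx, :] = config.dominant_boost
    out: dict[str, ScoreMatrix] = {}
    for region in config.regions:
        z = np.sqrt(rho) * z_global + np.sqrt(1 - rho) * rng.standard_normal((P, C))
        z = z + boost
        levels = np.column_stack(
            [
                quantile_levels(z[:, c], config.scheme.n_levels)
                for c in range(C)
            ]
        )
        prov = np.full((P, C), "regional_data", dtype=object)
        for c, crit in enumerate(config.scheme.criteria):
            if crit not in QUANTITATIVE_CRITERIA:
                inferred = rng.random(P) < 0.2
                prov[inferred, c] = "inferred"
        for p, name in enumerate(config.pathogens):
            if name == "Cytomegalovirus":
                for c, crit in enumerate(config.scheme.criteria):
                    if crit in QUANTITATIVE_CRITERIA:
                        prov[p, c] = "preliminary"
        out[region] = ScoreMatrix(
            region=region,
            pathogens=list(config.pathogens),
            scheme=config.scheme,
            levels=levels,
            provenance=prov,
        )
    return out


@dataclass
class SyntheticStudy:
    """Everything one simulated study produces."""

    config: GeneratorConfig
    seed: int
    respondents: list[TrueRespondent]
    responses: pd.DataFrame  # one row per submission
    sessions: dict[int, RespondentSession]  # response row index -> session
    score_matrices: dict[str, ScoreMatrix]


def simulate_study(config: GeneratorConfig, seed: int) -> SyntheticStudy:
    """Generate a complete synthetic study from a single seed.

    The responses table has one row per *submission*: completers with a
    duplicate flag appear twice under the same identity, and
    non-completers contribute an incomplete (abandoned) session.
    """
    rng = np.random.default_rng(seed)
    respondents = sample_respondents(config, rng)
    score_matrices = sample_score_matrices(config, rng)

    rows = []
    sessions: dict[int, RespondentSession] = {}
    for r in respondents:
        if r.completes:
            session = simulate_session(
                r,
                config.scheme,
                config.choice_error,
                rng,
                config.allow_indifference,
            )
        else:
            n_q = int(rng.integers(3, 30))
            session = simulate_session(
                r,
                config.scheme,
                config.choice_error,
                rng,
                config.allow_indifference,
                max_questions=n_q,
            )
        n_submissions = 2 if (r.completes and r.duplicate) else 1
        for _ in range(n_submissions):
            idx = len(rows)
            sessions[idx] = session
            row = {
                "response_id": idx,
                "respondent_index": r.index,
                "identity": f"resp{r.index:04d}",
                "complete": r.completes,
                "straightlined": bool(
                    r.straightliner
                    and all(
                        a.verdict is Verdict.FIRST for a in session.answers
                    )
                ),
                "invalid": False,
                "cluster_true": r.cluster,
                "verdicts": tuple(a.verdict.value for a in session.answers),
            }
            row.update(r.covariates)
            rows.append(row)
    responses = pd.DataFrame(rows)
    return SyntheticStudy(
        config=config,
        seed=seed,
        respondents=respondents,
        responses=responses,
        sessions=sessions,
        score_matrices=score_matrices,
    )
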