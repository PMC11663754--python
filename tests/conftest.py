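import itertools

import numpy as np
import pytest

from vaxprior.paprika import RespondentSession, Verdict
from vaxprior.scheme import CriterionScheme


def random_true_values(scheme: CriterionScheme, rng) -> np.ndarray:
    """Random additive value system: Dirichlet weights, Dirichlet spacings."""
    C, L = scheme.n_criteria, scheme.n_levels
    w = rng.dirichlet(np.ones(C)) * 100.0
    values = np.zeros((C, L))
    for c in range(C):
        inc = rng.dirichlet(np.ones(L - 1)) * w[c]
        values[c, 1:] = np.cumsum(inc)
    return values


def consistent_answer_fn(values: np.ndarray, scheme: CriterionScheme):
    """Answer every question from the true value sums (no noise)."""

    def f(q):
        a, b = q.active_criteria
        ia, ib = scheme.criterion_index(a), scheme.criterion_index(b)
        d = (
            values[ia, q.first.levels[a] - 1]
            - values[ia, q.second.levels[a] - 1]
            + values[ib, q.first.levels[b] - 1]
            - values[ib, q.second.levels[b] - 1]
        )
        if abs(d) < 1e-12:
            return Verdict.INDIFFERENT
        return Verdict.FIRST if d > 0 else Verdict.SECOND

    return f


def run_consistent_session(scheme: CriterionScheme, values: np.ndarray):
    return RespondentSession(scheme).run(consistent_answer_fn(values, scheme))


def brute_force_two_criterion_relation(scheme: CriterionScheme, values: np.ndarray):
    """Exhaustively rank every undominated two-criterion alternative pair.

    Independent oracle: enumerates all alternative pairs that differ on
    exactly two criteria with no dominance, and compares true total
    values directly.  Keys are canonical level tuples.
    """
    relation = {}
    C, L = scheme.n_criteria, scheme.n_levels
    for ca, cb in itertools.combinations(range(C), 2):
        for lo_a, hi_a in itertools.combinations(range(1, L + 1), 2):
            for lo_b, hi_b in itertools.combinations(range(1, L + 1), 2):
                # first alternative better on ca, second better on cb
                d = (
                    values[ca, hi_a - 1]
                    - values[ca, lo_a - 1]
                    - (values[cb, hi_b - 1] - values[cb, lo_b - 1])
                )
                if abs(d) < 1e-12:
                    verdict = "indifferent"
                else:
                    verdict = "first" if d > 0 else "second"
                relation[(ca, hi_a, lo_a, cb, hi_b, lo_b)] = verdict
    return relation


def session_relation_by_key(session: RespondentSession):
    """The session's implied relation keyed like the brute-force oracle."""
    out = {}
    nodes = session._nodes
    for (i, j), verdict in session.implied_relation().items():
        ca, hi_a, lo_a = nodes[i]
        cb, hi_b, lo_b = nodes[j]
        out[(ca, hi_a, lo_a, cb, hi_b, lo_b)] = verdict
    return out


@pytest.fixture(scope="session")
def scheme8x5() -> CriterionScheme:
    return CriterionScheme()


@pytest.fixture(scope="session")
def scheme3x3() -> CriterionScheme:
    return CriterionScheme(criteria=("c1", "c2", "c3"), n_levels=3)


@pytest.fixture(scope="session")
def small_study():
    """A modest synthetic study shared across tests (seeded, n=120)."""
    from vaxprior.synthetic import GeneratorConfig, simulate_study

    return simulate_study(GeneratorConfig(n_respondents=120), seed=11)
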