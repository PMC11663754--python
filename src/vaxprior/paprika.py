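"""PAPRIKA pairwise preference elicitation and additive value solving.

PAPRIKA ("Potentially All Pairwise RanKings of all possible
Alternatives") elicits an additive multi-criteria value model by asking
a respondent to choose between pairs of hypothetical alternatives that
differ on exactly two criteria, with neither alternative dominating the
other.  Each answer is a linear ordering fact about the model's point
values; transitive implications of the answers (together with level
monotonicity) determine further pairwise rankings, so far fewer
questions are asked than the total number of undominated comparisons.

The trick used here to make transitivity cheap is that every
undominated two-criterion comparison reduces, after cancelling the tied
criteria, to an ordering of two *level differences*

    D[c, hi, lo]  =  v[c, hi] - v[c, lo]          (hi > lo)

on different criteria: choosing the alternative better on criterion
``a`` asserts ``D[a, ...] > D[b, ...]``.  A session therefore maintains
strict and weak reachability over the small set of level-difference
quantities (10 per criterion for a 5-level scheme).  Level monotonicity
seeds the relation: a nested difference (wider level interval on the
same criterion) is weakly at least as large as the difference it
contains.  This closure is sound — every implied ranking is a genuine
consequence of the answers under the additive model — though it does
not chase implications that require re-summing differences across
interval decompositions; those comparisons are simply asked.

Once every cross-criterion difference pair is determined, point values
are solved by linear programming: answers become gap or equality
constraints, the minimum strict gap is maximised (max–min separation),
and values are normalised so the criterion weights — the point values
of the top levels — sum to 100 percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Mapping

import numpy as np
from scipy.optimize import linprog

from .scheme import CriterionScheme


class SessionError(RuntimeError):
    """Operation invalid for the session's current state."""


class InconsistentAnswerError(ValueError):
    """The answer contradicts the preferences already recorded."""


class Verdict(str, Enum):
    FIRST = "first"
    SECOND = "second"
    INDIFFERENT = "indifferent"


@dataclass(frozen=True)
class HypotheticalAlternative:
    """A hypothetical pathogen profile: one level per criterion."""

    levels: Mapping[str, int]

    def level(self, criterion: str) -> int:
        return self.levels[criterion]


@dataclass(frozen=True)
class ChoiceQuestion:
    """A two-criterion trade-off between hypothetical alternatives.

    The two alternatives are tied on every criterion except the two
    ``active_criteria``; the first is better on ``active_criteria[0]``
    and the second on ``active_criteria[1]``.
    """

    first: HypotheticalAlternative
    second: HypotheticalAlternative
    active_criteria: tuple[str, str]
    index: int  # position in the session's canonical comparison order

    def __post_init__(self) -> None:
        a, b = self.active_criteria
        diffs = [
            c
            for c in self.first.levels
            if self.first.levels[c] != self.second.levels[c]
        ]
        if sorted(diffs) != sorted((a, b)):
            raise ValueError("alternatives must differ on exactly the active criteria")
        if not (
            self.first.levels[a] > self.second.levels[a]
            and self.first.levels[b] < self.second.levels[b]
        ):
            raise ValueError("neither alternative may dominate the other")


@dataclass(frozen=True)
class Answer:
    question: ChoiceQuestion
    verdict: Verdict


@dataclass
class ValueSystem:
    """Solved point values of an additive value model, on a percent scale.

    ``values[c, l-1]`` is the point value of level ``l`` of criterion
    ``c``; ``values[:, 0] == 0`` and a top-level-everywhere alternative
    totals 100.  A criterion's weight is its top level's point value.
    """

    scheme: CriterionScheme
    values: np.ndarray  # (n_criteria, n_levels)
    consistent: bool = True  # False if answers required elastic relaxation

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.scheme.n_criteria, self.scheme.n_levels):
            raise ValueError("values shape does not match scheme")

    @property
    def weights(self) -> np.ndarray:
        """Criterion weights (percent): point values of the top levels."""
        return self.values[:, -1]

    def weight(self, criterion: str) -> float:
        return float(self.weights[self.scheme.criterion_index(criterion)])

    def total_weight(self, levels: Mapping[str, int]) -> float:
        """Total weight of an alternative scored at the given levels."""
        t = 0.0
        for i, c in enumerate(self.scheme.criteria):
            lvl = int(levels[c])
            self.scheme.validate_level(lvl)
            t += self.values[i, lvl - 1]
        return t

    def to_frame(self):
        """Long-format table (criterion, level, value)."""
        import pandas as pd

        rows = [
            {"criterion": c, "level": l + 1, "value": self.values[i, l]}
            for i, c in enumerate(self.scheme.criteria)
            for l in range(self.scheme.n_levels)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Session engine
# ---------------------------------------------------------------------------


class RespondentSession:
    """One respondent's elicitation session.

    Questions are issued in a deterministic canonical order: increasing
    total level span (adjacent-level trade-offs first), then
    lexicographic by criterion pair and level indices.  A question is
    skipped when its answer is already determined, explicitly or by
    transitive implication.
    """

    IN_PROGRESS = "in_progress"
    COMPLETE = "complete"
    ABANDONED = "abandoned"

    def __init__(self, scheme: CriterionScheme):
        self.scheme = scheme
        C, L = scheme.n_criteria, scheme.n_levels

        # Level-difference nodes: (criterion index, hi, lo), hi > lo.
        self._nodes: list[tuple[int, int, int]] = [
            (c, hi, lo)
            for c in range(C)
            for lo in range(1, L + 1)
            for hi in range(lo + 1, L + 1)
        ]
        self._node_index = {n: i for i, n in enumerate(self._nodes)}
        n = len(self._nodes)

        # Weak / strict reachability over difference nodes.  Seeded with
        # nested-interval dominance: D[c,hi,lo] >= D[c,hi',lo'] whenever
        # [lo', hi'] is contained in [lo, hi] (level monotonicity).
        self._W = np.zeros((n, n), dtype=bool)
        self._S = np.zeros((n, n), dtype=bool)
        for i, (c, hi, lo) in enumerate(self._nodes):
            for j, (c2, hi2, lo2) in enumerate(self._nodes):
                if i != j and c == c2 and lo <= lo2 and hi >= hi2:
                    self._W[i, j] = True

        # Canonical comparison order: every cross-criterion pair of
        # difference nodes, sorted by span then lexicographically.
        comps: list[tuple[int, int]] = []
        for i, (c1, hi1, lo1) in enumerate(self._nodes):
            for j, (c2, hi2, lo2) in enumerate(self._nodes):
                if c1 < c2:
                    comps.append((i, j))
        comps.sort(key=lambda ij: (self._span(*ij), self._lex(*ij)))
        self._comparisons = comps
        self._cursor = 0

        self.answers: list[Answer] = []
        self._pending: ChoiceQuestion | None = None
        self.status = self.IN_PROGRESS

    # -- canonical ordering helpers ------------------------------------

    def _span(self, i: int, j: int) -> int:
        _, hi1, lo1 = self._nodes[i]
        _, hi2, lo2 = self._nodes[j]
        return (hi1 - lo1) + (hi2 - lo2)

    def _lex(self, i: int, j: int) -> tuple:
        c1, hi1, lo1 = self._nodes[i]
        c2, hi2, lo2 = self._nodes[j]
        return (c1, c2, lo1, hi1, lo2, hi2)

    @property
    def n_comparisons(self) -> int:
        """Total number of undominated two-criterion comparisons."""
        return len(self._comparisons)

    @property
    def n_questions_asked(self) -> int:
        return len(self.answers)

    # -- reachability --------------------------------------------------

    def _determined(self, i: int, j: int) -> bool:
        return bool(
            self._S[i, j]
            or self._S[j, i]
            or (self._W[i, j] and self._W[j, i])
        )

    def _reach_from(self, u: int) -> np.ndarray:
        col = self._W[:, u].copy()
        col[u] = True
        return col

    def _reach_to(self, v: int) -> np.ndarray:
        row = self._W[v, :].copy()
        row[v] = True
        return row

    def _add_strict(self, u: int, v: int) -> None:
        if self._W[v, u]:  # any v >= u fact contradicts u > v
            raise InconsistentAnswerError(
                "strict preference contradicts recorded preferences"
            )
        left, right = self._reach_from(u), self._reach_to(v)
        block = np.outer(left, right)
        self._S |= block
        self._W |= block

    def _add_weak(self, u: int, v: int) -> None:
        if self._S[v, u]:
            raise InconsistentAnswerError(
                "indifference contradicts a recorded strict preference"
            )
        left, right = self._reach_from(u), self._reach_to(v)
        self._W |= np.outer(left, right)
        sl = self._S[:, u]
        sr = self._S[v, :]
        self._S |= np.outer(sl, right) | np.outer(left, sr)

    def _add_equal(self, u: int, v: int) -> None:
        if self._S[u, v] or self._S[v, u]:
            raise InconsistentAnswerError(
                "indifference contradicts a recorded strict preference"
            )
        self._add_weak(u, v)
        self._add_weak(v, u)

    # -- public protocol ----------------------------------------------

    def _question_from_comparison(self, idx: int) -> ChoiceQuestion:
        i, j = self._comparisons[idx]
        c1, hi1, lo1 = self._nodes[i]
        c2, hi2, lo2 = self._nodes[j]
        a, b = self.scheme.criteria[c1], self.scheme.criteria[c2]
        base = {c: 1 for c in self.scheme.criteria}
        first = dict(base)
        first[a], first[b] = hi1, lo2
        second = dict(base)
        second[a], second[b] = lo1, hi2
        return ChoiceQuestion(
            first=HypotheticalAlternative(first),
            second=HypotheticalAlternative(second),
            active_criteria=(a, b),
            index=idx,
        )

    def next_question(self) -> ChoiceQuestion | None:
        """The next undetermined trade-off, or None when exhausted."""
        if self.status != self.IN_PROGRESS:
            raise SessionError(f"session is {self.status}")
        if self._pending is not None:
            return self._pending
        while self._cursor < len(self._comparisons):
            i, j = self._comparisons[self._cursor]
            if not self._determined(i, j):
                self._pending = self._question_from_comparison(self._cursor)
                return self._pending
            self._cursor += 1
        self.status = self.COMPLETE
        return None

    def record_answer(self, verdict: Verdict | str) -> None:
        """Record the verdict for the most recently issued question."""
        if self.status != self.IN_PROGRESS:
            raise SessionError(f"session is {self.status}")
        if self._pending is None:
            raise SessionError("no question pending; call next_question() first")
        verdict = Verdict(verdict)
        i, j = self._comparisons[self._pending.index]
        if verdict is Verdict.FIRST:
            self._add_strict(i, j)
        elif verdict is Verdict.SECOND:
            self._add_strict(j, i)
        else:
            self._add_equal(i, j)
        self.answers.append(Answer(self._pending, verdict))
        self._pending = None

    def abandon(self) -> None:
        if self.status == self.IN_PROGRESS:
            self.status = self.ABANDONED

    def run(self, answer_fn) -> "RespondentSession":
        """Drive the session to completion with a callable answering each question."""
        while True:
            q = self.next_question()
            if q is None:
                break
            self.record_answer(answer_fn(q))
        return self

    # -- inspection ----------------------------------------------------

    def implied_relation(self) -> dict[tuple[int, int], str]:
        """Determined verdicts for every cross-criterion comparison.

        Keys are (node_i, node_j) pairs in canonical order; values are
        'first' (D_i > D_j), 'second', 'indifferent' or 'undetermined'.
        """
        out: dict[tuple[int, int], str] = {}
        for i, j in self._comparisons:
            if self._S[i, j]:
                out[(i, j)] = "first"
            elif self._S[j, i]:
                out[(i, j)] = "second"
            elif self._W[i, j] and self._W[j, i]:
                out[(i, j)] = "indifferent"
            else:
                out[(i, j)] = "undetermined"
        return out

    def comparison_nodes(self) -> list[tuple[tuple[int, int, int], tuple[int, int, int]]]:
        """The (criterion, hi, lo) difference pairs in canonical order."""
        return [(self._nodes[i], self._nodes[j]) for i, j in self._comparisons]


# ---------------------------------------------------------------------------
# Value solving
# ---------------------------------------------------------------------------

#: Tolerance for constraint-satisfaction checks.
CONSTRAINT_TOL = 1e-9
#: Tolerance for reported invariants (weights summing to 100, etc.).
REPORT_TOL = 1e-6
#: Target gap (percent points) for the soft-margin solve of contradictory sessions.
SOFT_MARGIN = 1.0


def solve_values(session: RespondentSession) -> ValueSystem:
    """Solve point values from a completed session by linear programming.

    Decision variables are ``v[c, l]`` for levels 2..L (level 1 is
    pinned at 0).  Constraints: level monotonicity, each strict answer
    as a value gap of at least ``eps``, each indifference as an
    equality, and top-level values summing to 100.  The LP maximises
    ``eps`` (max–min separation of strict preferences), which makes the
    solution deterministic and well-separated.

    The maximin gap alone leaves the solution underdetermined (any
    vertex of the optimal face), so a second stage selects, among
    maximin-optimal solutions, the one closest in L1 distance to the
    uniform value system (equal weights, equal level spacing) — a
    deterministic, least-committal central estimate.

    A respondent whose answers contradict each other (noise that
    slipped past the deliberately conservative closure) has no system
    with a positive minimum gap; forcing all answers to hold weakly
    would let the handful of wrong answers warp the solution, so such
    sessions are solved with a soft-margin (hinge-loss) program
    instead: minimise the total shortfall below a one-point target gap,
    letting a few wrong answers be violated outright while the rest are
    satisfied with a margin.  The result is flagged
    ``consistent=False``.
    """
    if session.status != RespondentSession.COMPLETE:
        raise SessionError("session must be complete before solving values")
    scheme = session.scheme
    C, L = scheme.n_criteria, scheme.n_levels
    nv = C * (L - 1)  # v[c,l] for l=2..L

    def vid(c: int, l: int) -> int:
        # l in 2..L
        return c * (L - 1) + (l - 2)

    def diff_coeffs(node: tuple[int, int, int]) -> list[tuple[int, float]]:
        c, hi, lo = node
        coeffs = [(vid(c, hi), 1.0)]
        if lo >= 2:
            coeffs.append((vid(c, lo), -1.0))
        return coeffs

    strict_rows: list[np.ndarray] = []
    eq_rows: list[np.ndarray] = []
    for ans in session.answers:
        q = ans.question
        i, j = session._comparisons[q.index]
        row = np.zeros(nv)
        for k, w in diff_coeffs(session._nodes[i]):
            row[k] += w
        for k, w in diff_coeffs(session._nodes[j]):
            row[k] -= w
        if ans.verdict is Verdict.FIRST:
            strict_rows.append(row)
        elif ans.verdict is Verdict.SECOND:
            strict_rows.append(-row)
        else:
            eq_rows.append(row)

    mono_rows: list[np.ndarray] = []
    for c in range(C):
        for l in range(2, L):
            row = np.zeros(nv)
            row[vid(c, l + 1)] = 1.0
            row[vid(c, l)] = -1.0
            mono_rows.append(row)

    norm_row = np.zeros(nv)
    for c in range(C):
        norm_row[vid(c, L)] = 1.0

    # Stage A: maximise the minimum strict-preference gap eps.  eps is
    # allowed to be negative so a contradictory answer set solves to
    # the least-violated system instead of failing.
    A_ub = []
    b_ub = []
    for row in strict_rows:
        A_ub.append(np.concatenate([-row, [1.0]]))  # eps - d.v <= 0
        b_ub.append(0.0)
    for row in mono_rows:
        A_ub.append(np.concatenate([-row, [0.0]]))
        b_ub.append(0.0)
    A_eq = [np.concatenate([norm_row, [0.0]])]
    b_eq = [100.0]
    for row in eq_rows:
        A_eq.append(np.concatenate([row, [0.0]]))
        b_eq.append(0.0)
    c_obj = np.zeros(nv + 1)
    c_obj[-1] = -1.0
    bounds = [(0.0, 100.0)] * nv + [(-200.0, 100.0)]
    res = linprog(
        c_obj,
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=np.array(A_eq),
        b_eq=np.array(b_eq),
        bounds=bounds,
        method="highs",
    )
    if res.success:
        eps_star = float(res.x[-1])
        consistent = eps_star > CONSTRAINT_TOL
        stage_a_feasible = True
    else:
        # Hard indifference constraints can be jointly unsatisfiable
        # (e.g. an everywhere-indifferent respondent forces a flat
        # value function, contradicting the 100-point normalisation);
        # fall through to the soft-margin solve with soft equalities.
        eps_star = float("-inf")
        consistent = False
        stage_a_feasible = False
    n_strict = len(strict_rows)

    uniform = np.zeros(nv)
    for c in range(C):
        for l in range(2, L + 1):
            uniform[vid(c, l)] = (100.0 / C) * (l - 1) / (L - 1)

    def refine(hinge_margin: float | None, soft_eq: bool = False) -> np.ndarray | None:
        """L1 projection of the uniform system onto the optimal face.

        With ``hinge_margin=None`` the face is {every strict gap >=
        eps*}; otherwise it is {total shortfall below hinge_margin <=
        its minimum}, with the minimum found by a preliminary solve.
        ``soft_eq`` turns indifference equalities into hinge terms too.
        Variables: [v, xi (hinge slacks), t (|v - uniform|)].
        """
        nxi = 0
        if hinge_margin is not None:
            nxi = n_strict + (len(eq_rows) if soft_eq else 0)
        ntot = nv + nxi + nv
        A_ub2, b_ub2 = [], []
        for s, row in enumerate(strict_rows):
            r = np.zeros(ntot)
            r[:nv] = -row
            if hinge_margin is None:
                target = eps_star - 1e-7
            else:
                r[nv + s] = -1.0  # d.v + xi_s >= margin
                target = hinge_margin
            A_ub2.append(r)
            b_ub2.append(-target)
        for row in mono_rows:
            r = np.zeros(ntot)
            r[:nv] = -row
            A_ub2.append(r)
            b_ub2.append(0.0)
        A_eq2 = [np.zeros(ntot)]
        A_eq2[0][:nv] = norm_row
        b_eq2 = [100.0]
        for s, row in enumerate(eq_rows):
            if hinge_margin is not None and soft_eq:
                for sign in (1.0, -1.0):  # |d.v| <= xi_s
                    r = np.zeros(ntot)
                    r[:nv] = sign * row
                    r[nv + n_strict + s] = -1.0
                    A_ub2.append(r)
                    b_ub2.append(0.0)
                continue
            r = np.zeros(ntot)
            r[:nv] = row
            A_eq2.append(r)
            b_eq2.append(0.0)
        bounds2 = (
            [(0.0, 100.0)] * nv
            + [(0.0, None)] * nxi
            + [(0.0, None)] * nv
        )
        if hinge_margin is not None:
            c1 = np.zeros(ntot)
            c1[nv : nv + nxi] = 1.0  # minimise total shortfall
            res1 = linprog(
                c1,
                A_ub=np.array(A_ub2),
                b_ub=np.array(b_ub2),
                A_eq=np.array(A_eq2),
                b_eq=np.array(b_eq2),
                bounds=bounds2,
                method="highs",
            )
            if not res1.success:
                return None
            cap = np.zeros(ntot)
            cap[nv : nv + nxi] = 1.0
            A_ub2.append(cap)
            b_ub2.append(float(res1.fun) * (1 + 1e-9) + 1e-6)
        for k in range(nv):  # |v_k - u_k| <= t_k
            r = np.zeros(ntot)
            r[k], r[nv + nxi + k] = 1.0, -1.0
            A_ub2.append(r)
            b_ub2.append(uniform[k])
            r = np.zeros(ntot)
            r[k], r[nv + nxi + k] = -1.0, -1.0
            A_ub2.append(r)
            b_ub2.append(-uniform[k])
        c2 = np.zeros(ntot)
        c2[nv + nxi :] = 1.0
        res2 = linprog(
            c2,
            A_ub=np.array(A_ub2),
            b_ub=np.array(b_ub2),
            A_eq=np.array(A_eq2),
            b_eq=np.array(b_eq2),
            bounds=bounds2,
            method="highs",
        )
        return res2.x[:nv] if res2.success else None

    if consistent:
        x = refine(None)
    else:
        # one percentage point: a modest target separation on the 0-100 scale
        x = refine(SOFT_MARGIN, soft_eq=not stage_a_feasible)
    if x is None and stage_a_feasible:
        x = res.x[:nv]  # stage A solution as fallback
    if x is None:
        raise RuntimeError("value LP failed in every formulation")

    values = np.zeros((C, L))
    for c in range(C):
        for l in range(2, L + 1):
            values[c, l - 1] = x[vid(c, l)]
    values = np.maximum(values, 0.0)
    values = np.maximum.accumulate(values, axis=1)  # clip tiny LP noise
    values *= 100.0 / values[:, -1].sum()
    return ValueSystem(scheme=scheme, values=values, consistent=consistent)


# ---------------------------------------------------------------------------
# Ranking scored alternatives
# ---------------------------------------------------------------------------


def rank_alternatives(values: ValueSystem, score_matrix) -> "pd.DataFrame":
    """Rank scored alternatives by total weight under a value system.

    ``score_matrix`` is anything with ``pathogens`` and an integer level
    array ``levels`` of shape (n_pathogens, n_criteria) on the same
    scheme (see :mod:`vaxprior.scoring`), or a pandas DataFrame indexed
    by pathogen with criterion columns.  Returns a DataFrame with
    columns ``pathogen, total_weight, rank`` sorted by total weight
    descending (ties share the better rank; name breaks presentation
    order only).
    """
    import pandas as pd

    scheme = values.scheme
    if hasattr(score_matrix, "levels"):
        levels = np.asarray(score_matrix.levels, dtype=int)
        names = list(score_matrix.pathogens)
    else:
        df = pd.DataFrame(score_matrix)
        df = df[list(scheme.criteria)]
        levels = df.to_numpy(dtype=int)
        names = list(df.index)
    if levels.min() < 1 or levels.max() > scheme.n_levels:
        raise ValueError("score level outside scheme bounds")
    totals = np.take_along_axis(
        values.values, levels.T - 1, axis=1
    ).sum(axis=0)
    out = pd.DataFrame({"pathogen": names, "total_weight": totals})
    out = out.sort_values(
        ["total_weight", "pathogen"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    # Competition ranking: equal totals share the best rank of the run.
    out["rank"] = (
        out["total_weight"].rank(method="min", ascending=False).astype(int)
    )
    return out


def iter_all_alternatives(scheme: CriterionScheme) -> Iterator[dict[str, int]]:
    """Every possible alternative of a scheme (use only for tiny schemes)."""
    import itertools

    for combo in itertools.product(
        range(1, scheme.n_levels + 1), repeat=scheme.n_criteria
    ):
        yield dict(zip(scheme.criteria, combo))
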