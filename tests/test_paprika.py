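"""PAPRIKA engine: question flow, transitive closure, and value solving."""

import itertools

import numpy as np
import pytest
from scipy.stats import kendalltau

from vaxprior.paprika import (
    InconsistentAnswerError,
    RespondentSession,
    SessionError,
    ValueSystem,
    Verdict,
    rank_alternatives,
    solve_values,
)
from vaxprior.scheme import CriterionScheme

from conftest import (
    brute_force_two_criterion_relation,
    random_true_values,
    run_consistent_session,
    session_relation_by_key,
)


class TestQuestionFlow:
    def test_two_by_two_has_exactly_one_question(self):
        scheme = CriterionScheme(criteria=("a", "b"), n_levels=2)
        session = RespondentSession(scheme)
        assert session.n_comparisons == 1
        q = session.next_question()
        assert q is not None
        assert set(q.active_criteria) == {"a", "b"}
        session.record_answer(Verdict.FIRST)
        assert session.next_question() is None
        assert session.status == RespondentSession.COMPLETE

    def test_completed_session_rejects_further_interaction(self):
        scheme = CriterionScheme(criteria=("a", "b"), n_levels=2)
        session = RespondentSession(scheme)
        session.next_question()
        session.record_answer(Verdict.FIRST)
        session.next_question()
        with pytest.raises(SessionError):
            session.next_question()
        with pytest.raises(SessionError):
            session.record_answer(Verdict.FIRST)

    def test_answer_without_pending_question_is_an_error(self):
        session = RespondentSession(CriterionScheme(criteria=("a", "b"), n_levels=2))
        with pytest.raises(SessionError):
            session.record_answer(Verdict.FIRST)

    def test_never_asks_a_determined_comparison(self, scheme3x3):
        """Replaying the session, every question must be undetermined at
        the moment it is asked, verified against an incrementally
        rebuilt relation."""
        rng = np.random.default_rng(5)
        values = random_true_values(scheme3x3, rng)
        session = run_consistent_session(scheme3x3, values)
        asked = [a.question.index for a in session.answers]
        assert len(asked) == len(set(asked)), "a comparison was asked twice"

        replay = RespondentSession(scheme3x3)
        for ans in session.answers:
            q = replay.next_question()
            i, j = replay._comparisons[q.index]
            assert not replay._determined(i, j)
            replay.record_answer(ans.verdict)

    def test_transitivity_reduces_questions_asked(self, scheme3x3, scheme8x5):
        rng = np.random.default_rng(0)
        for scheme in (scheme3x3, scheme8x5):
            values = random_true_values(scheme, rng)
            session = run_consistent_session(scheme, values)
            assert session.status == RespondentSession.COMPLETE
            assert session.n_questions_asked < session.n_comparisons


class TestClosure:
    def test_strict_chain_is_implied_and_not_asked(self):
        """a>b and c>a recorded; b-versus-c is implied by transitivity
        (c>b) and the session completes after only two questions."""
        scheme = CriterionScheme(criteria=("a", "b", "c"), n_levels=2)
        session = RespondentSession(scheme)
        q = session.next_question()
        assert set(q.active_criteria) == {"a", "b"}
        session.record_answer(Verdict.FIRST)  # D[a] > D[b]
        q = session.next_question()
        assert set(q.active_criteria) == {"a", "c"}
        session.record_answer(Verdict.SECOND)  # D[c] > D[a]
        assert session.next_question() is None  # (b, c) implied: c > b
        rel = session_relation_by_key(session)
        assert rel[(1, 2, 1, 2, 2, 1)] == "second"  # c beats b
        assert session.n_questions_asked == 2 < session.n_comparisons

    def test_indifference_substitutes_through_equalities(self):
        """a~b and a>c implies b>c without asking."""
        scheme = CriterionScheme(criteria=("a", "b", "c"), n_levels=2)
        session = RespondentSession(scheme)
        session.next_question()
        session.record_answer(Verdict.INDIFFERENT)  # D[a] = D[b]
        session.next_question()
        session.record_answer(Verdict.FIRST)  # D[a] > D[c]
        assert session.next_question() is None
        rel = session_relation_by_key(session)
        assert rel[(1, 2, 1, 2, 2, 1)] == "first"  # b beats c by substitution

    def test_contradictory_answer_rejected_without_breaking_session(self):
        """After equalities tie all adjacent-level trade-offs together, a
        wider trade-off is weakly determined by monotonicity; answering
        against it must be rejected, and an allowed verdict accepted."""
        scheme = CriterionScheme(criteria=("a", "b"), n_levels=3)
        session = RespondentSession(scheme)

        def span(q):
            a, b = q.active_criteria
            return abs(q.first.levels[a] - q.second.levels[a]) + abs(
                q.first.levels[b] - q.second.levels[b]
            )

        # declare every adjacent-level (span 2) trade-off indifferent
        while (q := session.next_question()) is not None and span(q) == 2:
            session.record_answer(Verdict.INDIFFERENT)
        # q is now a span-3 trade-off: a one-step difference against a
        # two-step difference that weakly contains an equal one-step
        # difference, so strictly preferring the one-step side is
        # contradictory.
        assert q is not None and span(q) == 3
        with pytest.raises(InconsistentAnswerError):
            session.record_answer(Verdict.FIRST)
        session.record_answer(Verdict.INDIFFERENT)  # plateaus are allowed

    @pytest.mark.parametrize(
        "n_criteria,n_levels",
        [(2, 2), (2, 3), (3, 2), (3, 3)],
    )
    def test_implied_relation_matches_exhaustive_oracle(self, n_criteria, n_levels):
        """On every scheme up to 3x3, the completed session's implied
        relation equals brute-force enumeration of all undominated
        two-criterion alternative pairs under the true values."""
        scheme = CriterionScheme(
            criteria=tuple(f"c{i}" for i in range(n_criteria)), n_levels=n_levels
        )
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            values = random_true_values(scheme, rng)
            session = run_consistent_session(scheme, values)
            expected = brute_force_two_criterion_relation(scheme, values)
            got = session_relation_by_key(session)
            assert got == expected


class TestSolveValues:
    def test_requires_completed_session(self, scheme3x3):
        with pytest.raises(SessionError):
            solve_values(RespondentSession(scheme3x3))

    def test_normalisation_and_monotonicity(self, scheme8x5):
        rng = np.random.default_rng(2)
        values = random_true_values(scheme8x5, rng)
        vs = solve_values(run_consistent_session(scheme8x5, values))
        assert vs.consistent
        assert abs(vs.weights.sum() - 100.0) < 1e-6
        assert (np.diff(vs.values, axis=1) >= -1e-9).all()
        assert np.allclose(vs.values[:, 0], 0.0)
        assert (vs.values >= -1e-9).all()
        assert (vs.values <= vs.weights[:, None] + 1e-9).all()

    def test_lexical_priority_gives_maximal_weight(self):
        """A respondent who always prefers the alternative better on one
        criterion, and is indifferent otherwise, reveals that criterion
        as the heaviest."""
        scheme = CriterionScheme(criteria=("x", "y", "z"), n_levels=3)

        def answer(q):
            a, b = q.active_criteria
            if a == "x":
                return Verdict.FIRST
            if b == "x":
                return Verdict.SECOND
            return Verdict.INDIFFERENT

        vs = solve_values(RespondentSession(scheme).run(answer))
        assert vs.weight("x") == max(vs.weights)
        assert vs.weight("x") > vs.weight("y") - 1e-9

    def test_always_indifferent_splits_weights_equally(self, scheme8x5):
        vs = solve_values(
            RespondentSession(scheme8x5).run(lambda q: Verdict.INDIFFERENT)
        )
        assert np.allclose(vs.weights, 12.5, atol=1e-6)

    def test_noiseless_solution_reproduces_elicited_ranking(self, scheme3x3):
        """The solved system ranks every undominated two-criterion pair
        exactly as the respondent's true values do."""
        rng = np.random.default_rng(42)
        values = random_true_values(scheme3x3, rng)
        session = run_consistent_session(scheme3x3, values)
        vs = solve_values(session)
        expected = brute_force_two_criterion_relation(scheme3x3, values)
        got = brute_force_two_criterion_relation(scheme3x3, vs.values)
        mismatches = {
            k: (got[k], v)
            for k, v in expected.items()
            if v != "indifferent" and got[k] != v
        }
        assert not mismatches

    def test_weight_recovery_under_choice_error(self, scheme8x5):
        """Regression guard: Kendall tau between true and solved weights
        is 1 without noise and stays above 0.7 (median) at a 10% flip
        rate."""
        from vaxprior.synthetic import TrueRespondent, simulate_session

        rng = np.random.default_rng(7)
        taus = []
        for i in range(30):
            values = random_true_values(scheme8x5, rng)
            resp = TrueRespondent(
                index=i,
                cluster=1,
                values=values,
                covariates={},
                completion_prob=1.0,
                completes=True,
                straightliner=False,
                duplicate=False,
            )
            session = simulate_session(resp, scheme8x5, 0.1, rng)
            vs = solve_values(session)
            taus.append(kendalltau(values[:, -1], vs.weights).statistic)
        assert np.median(taus) > 0.7


class TestRankAlternatives:
    @pytest.fixture()
    def toy_values(self):
        scheme = CriterionScheme(criteria=("a", "b"), n_levels=3)
        values = np.array([[0.0, 30.0, 60.0], [0.0, 10.0, 40.0]])
        return ValueSystem(scheme=scheme, values=values)

    def test_extreme_profiles_hit_bounds(self, toy_values):
        import pandas as pd

        scores = pd.DataFrame(
            {"a": [3, 1], "b": [3, 1]}, index=["everything", "nothing"]
        )
        ranked = rank_alternatives(toy_values, scores)
        assert ranked.loc[ranked["pathogen"] == "everything", "total_weight"].iloc[0] == pytest.approx(100.0)
        assert ranked.loc[ranked["pathogen"] == "nothing", "total_weight"].iloc[0] == pytest.approx(0.0)

    def test_toy_totals_match_hand_computation(self, toy_values):
        import pandas as pd

        scores = pd.DataFrame(
            {"a": [2, 3, 1], "b": [2, 1, 3]}, index=["p1", "p2", "p3"]
        )
        ranked = rank_alternatives(toy_values, scores).set_index("pathogen")
        assert ranked.loc["p1", "total_weight"] == pytest.approx(40.0)  # 30+10
        assert ranked.loc["p2", "total_weight"] == pytest.approx(60.0)  # 60+0
        assert ranked.loc["p3", "total_weight"] == pytest.approx(40.0)  # 0+40
        assert ranked.loc["p2", "rank"] == 1
        assert ranked.loc["p1", "rank"] == ranked.loc["p3", "rank"] == 2

    def test_out_of_range_level_rejected(self, toy_values):
        import pandas as pd

        scores = pd.DataFrame({"a": [4], "b": [1]}, index=["bad"])
        with pytest.raises(ValueError):
            rank_alternatives(toy_values, scores)

    def test_improving_one_criterion_never_decreases_total(self, scheme3x3):
        rng = np.random.default_rng(3)
        values = random_true_values(scheme3x3, rng)
        vs = ValueSystem(scheme=scheme3x3, values=values)
        for combo in itertools.product(range(1, 4), repeat=3):
            base = dict(zip(scheme3x3.criteria, combo))
            t0 = vs.total_weight(base)
            for c in scheme3x3.criteria:
                if base[c] < 3:
                    better = dict(base)
                    better[c] += 1
                    assert vs.total_weight(better) >= t0 - 1e-12
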