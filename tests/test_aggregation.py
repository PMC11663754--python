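"""Regional means, top-k lists, the global union, and robustness."""

import numpy as np
import pandas as pd
import pytest

from vaxprior.aggregation import (
    build_global_list,
    regional_mean_weights,
    regional_top_k,
    robustness_leave_one_out,
    subset_reanalysis,
)
from vaxprior.paprika import ValueSystem, rank_alternatives
from vaxprior.scheme import CriterionScheme
from vaxprior.scoring import ScoreMatrix

from conftest import random_true_values


def vs_from_weights(scheme, weights, spacing=None):
    """Value system with given top weights and linear level spacing."""
    C, L = scheme.n_criteria, scheme.n_levels
    values = np.zeros((C, L))
    for c in range(C):
        values[c] = np.linspace(0, weights[c], L)
    return ValueSystem(scheme=scheme, values=values)


@pytest.fixture()
def scheme2():
    return CriterionScheme(criteria=("a", "b"), n_levels=5)


class TestRegionalMeans:
    def test_single_respondent_mean_is_itself(self, scheme2):
        vs = vs_from_weights(scheme2, [30, 70])
        rw = regional_mean_weights([vs], region="Africa")
        assert np.allclose(rw.mean_values, vs.values)
        assert np.allclose(rw.sd_weights, 0.0)
        assert rw.n_respondents == 1

    def test_symmetric_pair_averages_to_even_split(self, scheme2):
        rw = regional_mean_weights(
            [vs_from_weights(scheme2, [20, 80]), vs_from_weights(scheme2, [80, 20])]
        )
        assert np.allclose(rw.mean_weights, [50.0, 50.0])
        assert abs(rw.mean_weights.sum() - 100) < 1e-6

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            regional_mean_weights([])

    def test_mixture_means_recovered_from_generator(self):
        """50 synthetic respondents: empirical mean weights sit within 3
        standard errors of the cluster-mixture expectation."""
        from vaxprior.synthetic import GeneratorConfig, sample_respondents

        config = GeneratorConfig(n_respondents=50)
        rng = np.random.default_rng(9)
        respondents = sample_respondents(config, rng)
        systems = [
            ValueSystem(scheme=config.scheme, values=r.values) for r in respondents
        ]
        rw = regional_mean_weights(systems)
        p1, p2 = config.cluster_proportions
        expected = p1 * np.array(config.cluster_mean_weights[1]) + p2 * np.array(
            config.cluster_mean_weights[2]
        )
        W = np.stack([r.weights for r in respondents])
        se = W.std(axis=0, ddof=1) / np.sqrt(len(respondents))
        assert (np.abs(rw.mean_weights - expected) <= 3 * se + 1e-9).all()


def toy_region(scheme, region, levels, pathogens=None):
    levels = np.asarray(levels)
    pathogens = pathogens or [f"p{i}" for i in range(len(levels))]
    return ScoreMatrix(
        region=region, pathogens=pathogens, scheme=scheme, levels=levels
    )


class TestRegionalTopK:
    def test_k_equal_to_panel_returns_full_ranking(self, scheme2):
        rw = regional_mean_weights([vs_from_weights(scheme2, [50, 50])], region="R")
        matrix = toy_region(scheme2, "R", [[1, 2], [3, 4], [5, 5]])
        pl = regional_top_k(rw, matrix, k=3)
        assert len(pl.top) == 3
        assert pl.table["in_top_k"].all()

    def test_identical_rows_tie_and_are_annotated(self, scheme2):
        rw = regional_mean_weights([vs_from_weights(scheme2, [50, 50])], region="R")
        matrix = toy_region(scheme2, "R", [[2, 3], [2, 3], [1, 1]])
        pl = regional_top_k(rw, matrix, k=2)
        t = pl.table.set_index("pathogen")
        assert t.loc["p0", "total_weight"] == t.loc["p1", "total_weight"]
        assert t.loc["p0", "rank"] == t.loc["p1", "rank"] == 1
        assert t.loc["p0", "tied"] and t.loc["p1", "tied"]

    def test_boundary_ties_are_included_not_dropped(self, scheme2):
        rw = regional_mean_weights([vs_from_weights(scheme2, [50, 50])], region="R")
        matrix = toy_region(scheme2, "R", [[5, 5], [3, 3], [3, 3], [1, 1]])
        pl = regional_top_k(rw, matrix, k=2)
        assert set(pl.top) == {"p0", "p1", "p2"}
        assert pl.table.set_index("pathogen").loc[["p1", "p2"], "tied_at_cutoff"].all()

    def test_top3_matches_hand_computation(self, scheme2):
        # weights 60/40, linear spacing: level values a: 0,15,30,45,60; b: 0,10,20,30,40
        rw = regional_mean_weights([vs_from_weights(scheme2, [60, 40])], region="R")
        levels = [[5, 1], [1, 5], [3, 3], [4, 2], [2, 4], [1, 1]]
        matrix = toy_region(scheme2, "R", levels)
        pl = regional_top_k(rw, matrix, k=3)
        totals = pl.table.set_index("pathogen")["total_weight"]
        assert totals["p0"] == pytest.approx(60.0)
        assert totals["p1"] == pytest.approx(40.0)
        assert totals["p2"] == pytest.approx(50.0)
        assert totals["p3"] == pytest.approx(55.0)
        assert totals["p4"] == pytest.approx(45.0)
        assert pl.top == ["p0", "p3", "p2"]

    def test_k_beyond_panel_rejected(self, scheme2):
        rw = regional_mean_weights([vs_from_weights(scheme2, [50, 50])], region="R")
        matrix = toy_region(scheme2, "R", [[1, 1], [2, 2]])
        with pytest.raises(ValueError):
            regional_top_k(rw, matrix, k=3)


class TestGlobalList:
    def make_lists(self, scheme, region_levels, k=2):
        lists = []
        for region, levels in region_levels.items():
            rw = regional_mean_weights(
                [vs_from_weights(scheme, [50, 50])], region=region
            )
            lists.append(regional_top_k(rw, toy_region(scheme, region, levels), k=k))
        return lists

    def test_identical_regions_collapse_to_k(self, scheme2):
        levels = [[5, 5], [4, 4], [1, 1], [1, 2]]
        gl = build_global_list(
            self.make_lists(scheme2, {"R1": levels, "R2": levels, "R3": levels})
        )
        assert len(gl.pathogens) == 2
        assert (gl.table["region_count"] == 3).all()

    def test_disjoint_regions_union_fully(self, scheme2):
        gl = build_global_list(
            self.make_lists(
                scheme2,
                {
                    "R1": [[5, 5], [4, 4], [1, 1], [1, 1]],
                    "R2": [[1, 1], [1, 1], [5, 5], [4, 4]],
                },
            )
        )
        assert len(gl.pathogens) == 4
        assert set(gl.table["region_count"]) == {1}

    def test_shared_pathogens_sort_first(self):
        """Engineered 6-region study: the 5 globally dominant pathogens
        head the global list, present in every region."""
        from vaxprior.synthetic import GeneratorConfig, sample_score_matrices

        config = GeneratorConfig()
        rng = np.random.default_rng(12)
        matrices = sample_score_matrices(config, rng)
        systems = [
            ValueSystem(
                scheme=config.scheme,
                values=np.stack(
                    [
                        np.linspace(0, w, config.scheme.n_levels)
                        for w in config.cluster_mean_weights[1]
                    ]
                ),
            )
        ]
        lists = [
            regional_top_k(
                regional_mean_weights(systems, region=r), matrices[r], k=10
            )
            for r in config.regions
        ]
        gl = build_global_list(lists)
        head = set(gl.pathogens[: len(config.dominant_pathogens)])
        assert head == set(config.dominant_pathogens)
        assert (
            gl.table.set_index("pathogen")
            .loc[list(config.dominant_pathogens), "region_count"]
            .eq(len(config.regions))
            .all()
        )

    def test_union_size_bounds(self, scheme2):
        lists = self.make_lists(
            scheme2,
            {
                "R1": [[5, 5], [4, 4], [1, 1], [2, 1]],
                "R2": [[1, 1], [4, 4], [5, 5], [2, 1]],
            },
        )
        gl = build_global_list(lists)
        assert 2 <= len(gl.pathogens) <= 4


class TestRobustness:
    def test_constant_criterion_omission_changes_nothing(self, scheme2):
        rw = {
            "R": regional_mean_weights([vs_from_weights(scheme2, [50, 50])], region="R")
        }
        # criterion b identical for everyone: omitting it shifts all totals equally
        mats = {"R": toy_region(scheme2, "R", [[5, 3], [4, 3], [1, 3], [2, 3]])}
        rep = robustness_leave_one_out(rw, mats, k=2)
        assert rep.deltas["b"] == {"dropped": [], "added": []}

    def test_single_criterion_advantage_drops_with_it(self, scheme2):
        rw = {
            "R": regional_mean_weights([vs_from_weights(scheme2, [50, 50])], region="R")
        }
        # p0 leads only through criterion a
        mats = {"R": toy_region(scheme2, "R", [[5, 1], [2, 3], [2, 3], [1, 2]])}
        rep = robustness_leave_one_out(rw, mats, k=1)
        assert "p0" in rep.deltas["a"]["dropped"]

    def test_deltas_match_column_zeroing_oracle(self):
        """Seeded six-region study: the report's per-criterion deltas
        equal an independent recomputation that zeroes the omitted
        criterion's point values and rebuilds the union from scratch."""
        from vaxprior.synthetic import GeneratorConfig, sample_score_matrices

        config = GeneratorConfig()
        rng = np.random.default_rng(21)
        matrices = sample_score_matrices(config, rng)
        weights = {}
        for i, r in enumerate(config.regions):
            vals = random_true_values(config.scheme, np.random.default_rng(100 + i))
            weights[r] = regional_mean_weights(
                [ValueSystem(scheme=config.scheme, values=vals)], region=r
            )
        rep = robustness_leave_one_out(weights, matrices, k=10)

        def union_for(omit=None):
            union = {}
            for r in config.regions:
                vals = weights[r].mean_values.copy()
                if omit is not None:
                    vals[config.scheme.criterion_index(omit)] = 0.0
                m = matrices[r]
                totals = np.array(
                    [
                        sum(
                            vals[c, m.levels[p, c] - 1]
                            for c in range(config.scheme.n_criteria)
                        )
                        for p in range(len(m.pathogens))
                    ]
                )
                cutoff = np.sort(totals)[::-1][9]
                for p in np.nonzero(totals >= cutoff - 1e-12)[0]:
                    union.setdefault(m.pathogens[p], set()).add(r)
            return set(union)

        base = union_for()
        assert base == rep.baseline.members()
        for criterion in config.scheme.criteria:
            omitted = union_for(criterion)
            assert sorted(base - omitted) == rep.deltas[criterion]["dropped"]
            assert sorted(omitted - base) == rep.deltas[criterion]["added"]


class TestSubsetAndInvariance:
    def test_subset_of_everyone_is_baseline(self, scheme2):
        systems = {
            "R1": [vs_from_weights(scheme2, [60, 40]), vs_from_weights(scheme2, [40, 60])],
            "R2": [vs_from_weights(scheme2, [50, 50])],
        }
        mats = {
            "R1": toy_region(scheme2, "R1", [[5, 1], [1, 5], [3, 3], [1, 1]]),
            "R2": toy_region(scheme2, "R2", [[2, 5], [5, 2], [4, 4], [1, 1]]),
        }
        full = subset_reanalysis(systems, mats, k=2)
        again = subset_reanalysis(systems, mats, k=2)
        assert full.table.equals(again.table)

    def test_single_respondent_subset_is_their_ranking(self, scheme2):
        vs = vs_from_weights(scheme2, [80, 20])
        mats = {"R1": toy_region(scheme2, "R1", [[5, 1], [1, 5], [3, 3], [1, 1]])}
        gl = subset_reanalysis({"R1": [vs]}, mats, k=2)
        personal = rank_alternatives(vs, mats["R1"])
        assert gl.pathogens[0] == personal["pathogen"].iloc[0]

    def test_empty_subset_rejected(self, scheme2):
        mats = {"R1": toy_region(scheme2, "R1", [[5, 1], [1, 5]])}
        with pytest.raises(ValueError):
            subset_reanalysis({"R1": []}, mats, k=1)

    def test_rescaling_point_values_leaves_ranking_unchanged(self, scheme2):
        rng = np.random.default_rng(4)
        vals = random_true_values(scheme2, rng)
        matrix = toy_region(
            scheme2, "R", rng.integers(1, 6, size=(8, 2)), pathogens=[f"p{i}" for i in range(8)]
        )
        base = rank_alternatives(ValueSystem(scheme=scheme2, values=vals), matrix)
        scaled = rank_alternatives(
            ValueSystem(scheme=scheme2, values=vals * 3.7), matrix
        )
        assert list(base["pathogen"]) == list(scaled["pathogen"])

    def test_mean_of_weights_equals_weight_of_means(self, scheme2):
        """Ranking by averaged point values equals averaging the
        per-respondent totals (linearity)."""
        rng = np.random.default_rng(6)
        systems = [
            ValueSystem(scheme=scheme2, values=random_true_values(scheme2, rng))
            for _ in range(7)
        ]
        matrix = toy_region(
            scheme2,
            "R",
            rng.integers(1, 6, size=(10, 2)),
            pathogens=[f"p{i}" for i in range(10)],
        )
        rw = regional_mean_weights(systems, region="R")
        by_mean = (
            rank_alternatives(rw.as_value_system(), matrix)
            .set_index("pathogen")["total_weight"]
            .sort_index()
        )
        mean_totals = pd.concat(
            [
                rank_alternatives(vs, matrix)
                .set_index("pathogen")["total_weight"]
                .sort_index()
                for vs in systems
            ],
            axis=1,
        ).mean(axis=1)
        assert np.allclose(by_mean.to_numpy(), mean_totals.to_numpy())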