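import numpy as np
import pandas as pd
import pytest
from scipy.stats import gaussian_kde

from spagi.activity_scoring import (
    ExpressionProfile,
    PathwayActivity,
    activity_table,
    average_replicates,
    default_high_threshold,
    filter_potential_paths,
    pathway_activity,
    rank_pathways,
    select_high_ranked,
)
from spagi.path_enumeration import PathwayBackground, SignalingPath
from spagi.synthetic_data import SyntheticSpec, generate_expression, generate_network
from spagi.ppi_graph import build_signaling_graph, filter_interactions
from spagi.path_enumeration import shortest_rk_tf_paths


class TestAverageReplicates:
    def test_arithmetic_mean(self):
        matrix = pd.DataFrame({"A1": [2.0], "A2": [4.0]}, index=["G1"])
        profiles = average_replicates(matrix, {"A1": "c", "A2": "c"})
        assert profiles["c"].values["G1"] == 3.0

    def test_single_replicate_unchanged(self):
        matrix = pd.DataFrame({"A1": [2.5]}, index=["G1"])
        assert average_replicates(matrix, {"A1": "c"})["c"].values["G1"] == 2.5

    def test_missing_sample_errors(self):
        matrix = pd.DataFrame({"A1": [2.0], "A2": [4.0]}, index=["G1"])
        with pytest.raises(ValueError, match="missing from replicate grouping"):
            average_replicates(matrix, {"A1": "c"})

    def test_three_conditions_match_columnwise_means(self):
        rng = np.random.default_rng(5)
        matrix = pd.DataFrame(
            rng.uniform(0, 8, size=(6, 6)),
            index=[f"G{i}" for i in range(6)],
            columns=[f"S{j}" for j in range(6)],
        )
        groups = {f"S{j}": f"c{j % 3}" for j in range(6)}
        profiles = average_replicates(matrix, groups)
        assert set(profiles) == {"c0", "c1", "c2"}
        for cond, profile in profiles.items():
            cols = [s for s, c in groups.items() if c == cond]
            brute = matrix[cols].to_numpy().mean(axis=1)
            assert np.allclose([profile.values[g] for g in matrix.index], brute)
            assert set(profile.values) == set(matrix.index)


class TestFilterPotentialPaths:
    def test_toy_t1_with_e1(self, t1_background, e1_profile):
        potential = filter_potential_paths(t1_background, e1_profile)
        assert list(potential.pathways) == ["R1"]
        assert [p.nodes for p in potential.pathways["R1"]] == [("R1", "K1", "TF1")]

    def test_full_expression_is_identity(self, t1_background):
        profile = ExpressionProfile(
            values={g: 5.0 for p in t1_background.all_paths() for g in p.nodes}
        )
        assert filter_potential_paths(t1_background, profile) == t1_background

    def test_empty_profile_empties_background(self, t1_background):
        profile = ExpressionProfile(values={})
        assert filter_potential_paths(t1_background, profile).pathways == {}

    def test_absent_gene_counts_as_unexpressed(self, t1_background):
        profile = ExpressionProfile(values={"R1": 5.0, "K1": 5.0})  # no TFs
        assert filter_potential_paths(t1_background, profile).pathways == {}

    def test_monotone_in_cutoff(self, t1_background):
        values = {"R1": 5, "K1": 4, "K2": 2, "TF1": 6, "TF2": 1.0, "R2": 0.5}
        previous = t1_background.n_paths
        for cutoff in (0.0, 0.5, 1.5, 2.5, 4.5, 7.0):
            profile = ExpressionProfile(values=values, cutoff=cutoff)
            n = filter_potential_paths(t1_background, profile).n_paths
            assert n <= previous
            previous = n


class TestDefaultHighThreshold:
    def test_peak_located_within_grid_cell_of_fine_argmax(self):
        rng = np.random.default_rng(42)
        values = np.concatenate(
            [rng.normal(4.0, 0.15, size=200), rng.uniform(1.5, 8.0, size=40)]
        )
        values = np.clip(values, 1.5, None)
        profile = ExpressionProfile(values={f"G{i}": v for i, v in enumerate(values)})
        got = default_high_threshold(profile)
        expressed = profile.expressed_values()
        kde = gaussian_kde(expressed)
        fine = np.linspace(expressed.min(), expressed.max(), 5120)
        brute = fine[np.argmax(kde(fine))]
        cell = (expressed.max() - expressed.min()) / 511
        assert abs(got - brute) <= cell
        assert abs(got - 4.0) < 0.25

    def test_degenerate_point_mass(self):
        profile = ExpressionProfile(values={f"G{i}": 3.0 for i in range(20)})
        assert default_high_threshold(profile) == 3.0

    def test_too_few_expressed_genes_errors(self):
        profile = ExpressionProfile(values={f"G{i}": 2.0 for i in range(9)})
        with pytest.raises(ValueError, match="explicit high threshold"):
            default_high_threshold(profile)

    def test_only_expressed_values_considered(self):
        # mass below the cutoff must not drag the peak down
        values = {f"L{i}": 0.1 for i in range(500)}
        values.update({f"H{i}": 5.0 + 0.001 * i for i in range(30)})
        profile = ExpressionProfile(values=values, cutoff=1.5)
        assert default_high_threshold(profile) > 4.5


class TestPathwayActivity:
    def test_single_path_worked_example(self, t1_background, e1_profile):
        potential = filter_potential_paths(t1_background, e1_profile)
        activities = pathway_activity(potential, e1_profile, high_threshold=4.5)
        assert len(activities) == 1
        act = activities[0]
        assert (act.receptor, act.n) == ("R1", 1)
        assert act.proportions == (2 / 3,)
        assert act.activity_score == 2 / 3

    def test_mean_of_path_proportions(self):
        bg = PathwayBackground.from_paths(
            [
                SignalingPath(("R1", "K1", "TF1"), ("R", "K", "TF"), 10),
                SignalingPath(("R1", "K1", "K2", "TF2"), ("R", "K", "K", "TF"), 20),
            ]
        )
        profile = ExpressionProfile(
            values={"R1": 9, "K1": 9, "K2": 2, "TF1": 9, "TF2": 9}
        )
        acts = pathway_activity(bg, profile, high_threshold=5.0)
        assert sorted(acts[0].proportions) == [0.75, 1.0]
        assert acts[0].activity_score == pytest.approx(0.875)

    def test_zero_when_nothing_highly_expressed(self, t1_background):
        profile = ExpressionProfile(
            values={g: 2.0 for p in t1_background.all_paths() for g in p.nodes}
        )
        acts = pathway_activity(t1_background, profile, high_threshold=9.0)
        assert all(a.activity_score == 0.0 for a in acts)
        assert all(p == 0.0 for a in acts for p in a.proportions)

    def test_score_bounds_and_n_equals_tf_count(self, t1_background, e1_profile):
        profile = ExpressionProfile(
            values={g: 5.0 for p in t1_background.all_paths() for g in p.nodes}
        )
        for a in pathway_activity(t1_background, profile, 4.0):
            assert 0.0 <= a.activity_score <= 1.0
            assert a.n == len(a.paths) == len({p.terminal_tf for p in a.paths})

    def test_monotone_in_high_threshold(self, t1_background):
        profile = ExpressionProfile(
            values={"R1": 5, "K1": 4, "K2": 2, "TF1": 6, "TF2": 3, "R2": 2}
        )
        previous = None
        for threshold in (1.5, 2.0, 3.0, 4.0, 5.0, 6.5):
            acts = {
                a.receptor: a.activity_score
                for a in pathway_activity(t1_background, profile, threshold)
            }
            if previous is not None:
                assert all(acts[r] <= previous[r] for r in acts)
            previous = acts

    def test_invariant_under_gene_reordering(self, t1_background, e1_profile):
        reversed_values = dict(reversed(list(e1_profile.values.items())))
        profile = ExpressionProfile(values=reversed_values, cutoff=e1_profile.cutoff)
        a1 = pathway_activity(t1_background, e1_profile, 4.5)
        a2 = pathway_activity(t1_background, profile, 4.5)
        assert a1 == a2


def _activity(receptor, n, score):
    return PathwayActivity(
        receptor=receptor, n=n, proportions=(score,) * n, activity_score=score
    )


class TestRanking:
    def test_sort_key(self):
        acts = [_activity("Z", 9, 0.3), _activity("Y", 2, 0.9), _activity("X", 5, 0.9)]
        assert [a.receptor for a in rank_pathways(acts)] == ["X", "Y", "Z"]

    def test_symbol_breaks_full_ties(self):
        acts = [_activity("B", 3, 0.5), _activity("A", 3, 0.5)]
        assert [a.receptor for a in rank_pathways(acts)] == ["A", "B"]

    def test_matches_brute_force_comparator(self):
        rng = np.random.default_rng(17)
        acts = [
            _activity(f"R{i:02d}", int(rng.integers(1, 9)), float(rng.choice([0.2, 0.5, 0.9])))
            for i in range(20)
        ]
        import functools

        def cmp(a, b):
            if a.activity_score != b.activity_score:
                return -1 if a.activity_score > b.activity_score else 1
            if a.n != b.n:
                return -1 if a.n > b.n else 1
            return -1 if a.receptor < b.receptor else 1

        assert rank_pathways(acts) == sorted(acts, key=functools.cmp_to_key(cmp))

    def test_empty_and_singleton(self):
        assert rank_pathways([]) == []
        one = [_activity("A", 1, 0.5)]
        assert rank_pathways(one) == one

    def test_activity_table_layout(self):
        table = activity_table([_activity("A", 2, 0.4), _activity("B", 5, 0.8)])
        assert list(table.index) == ["B", "A"]
        assert list(table.columns) == ["n", "activity_score"]


class TestSelectHighRanked:
    def test_identical_scores_all_pass_quantile(self):
        acts = [_activity(f"R{i}", i + 1, 0.5) for i in range(8)]
        selected = select_high_ranked(acts, score_quantile=0.75, min_tfs=5)
        assert {a.receptor for a in selected} == {a.receptor for a in acts if a.n >= 5}

    def test_single_pathway_returned(self):
        acts = [_activity("A", 6, 0.9)]
        assert select_high_ranked(acts) == acts

    def test_matches_brute_force_refilter(self):
        rng = np.random.default_rng(23)
        acts = [
            _activity(f"R{i:02d}", int(rng.integers(1, 12)), float(rng.uniform(0, 1)))
            for i in range(30)
        ]
        q, m = 0.6, 4
        threshold = float(np.quantile([a.activity_score for a in acts], q))
        expected = {a.receptor for a in acts if a.activity_score >= threshold and a.n >= m}
        assert {a.receptor for a in select_high_ranked(acts, q, m)} == expected

    def test_quantile_out_of_range(self):
        with pytest.raises(ValueError):
            select_high_ranked([_activity("A", 5, 0.5)], score_quantile=1.0)

    def test_empty_input(self):
        assert select_high_ranked([]) == []


class TestPlantedSeparation:
    def test_planted_receptors_strictly_outrank_background(self):
        spec = SyntheticSpec(
            n_receptors=8,
            n_kinases=16,
            n_tfs=10,
            planted_receptors=("R001", "R002"),
            n_planted_routes=3,
            noise_sd=0.2,
            expressed_mean=3.0,
            active_mean=6.0,
            silent_mean=0.2,
            edge_density={"rr": 0.02, "rk": 0.04, "kk": 0.05, "ktf": 0.06},
            seed=3,
        )
        interactions, roles = generate_network(spec)
        graph = build_signaling_graph(filter_interactions(interactions, 700), roles)
        background = shortest_rk_tf_paths(graph)
        matrix, truth = generate_expression(interactions, roles, spec)
        profile = average_replicates(matrix, {c: "q" for c in matrix.columns})["q"]
        acts = pathway_activity(
            filter_potential_paths(background, profile),
            profile,
            truth["suggested_high_threshold"],
        )
        scores = {a.receptor: a.activity_score for a in acts}
        planted = [scores[r] for r in truth["planted_receptors"]]
        others = [s for r, s in scores.items() if r not in truth["planted_receptors"]]
        assert min(planted) > max(others, default=0.0)


class TestExpressionProfileValidation:
    def test_high_threshold_below_cutoff_rejected(self):
        with pytest.raises(ValueError):
            ExpressionProfile(values={"G": 2.0}, cutoff=1.5, high_threshold=1.0)

    def test_non_finite_value_rejected(self):
        with pytest.raises(ValueError):
            ExpressionProfile(values={"G": float("nan")})
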