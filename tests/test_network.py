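"""Correlation-network oracles: partial Spearman against the recursive
partial-correlation formula, bootstrap recovery and null calibration,
threshold semantics, modularity against exhaustive search, centralities."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from somnospec import (
    CohortSynthesisSpec,
    bootstrap_correlations,
    bootstrap_matrix,
    centrality_measures,
    layout_fruchterman_reingold,
    modularity_partition,
    partial_spearman,
    radar_summary,
    synthesize_cohort,
    threshold_network,
)
from somnospec.network import node_set
from somnospec.synthetic import planted_correlation

from _oracles import exhaustive_modularity as _exhaustive_modularity
from _oracles import make_matrix as _matrix


def _brute_force_partial(x, y, z1, z2):
    """Second-order partial correlation by the recursive formula on the
    Spearman matrix (independent oracle)."""

    def partial1(rxy, rxz, ryz):
        return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))

    def rho(a, b):
        return spearmanr(a, b).statistic

    rxy_1 = partial1(rho(x, y), rho(x, z1), rho(y, z1))
    rxz2_1 = partial1(rho(x, z2), rho(x, z1), rho(z2, z1))
    ryz2_1 = partial1(rho(y, z2), rho(y, z1), rho(z2, z1))
    return partial1(rxy_1, rxz2_1, ryz2_1)


class TestPartialSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.5, 3.0, 7.0, 9.0, 20.0])
        assert partial_spearman(x, x**3) == pytest.approx(1.0)

    def test_constant_covariates_dropped(self):
        x = np.arange(6.0)
        cov = np.ones((6, 2))
        assert partial_spearman(x, 2 * x + 1, cov) == pytest.approx(1.0)

    def test_age_confound_removed(self, rng):
        age = rng.uniform(5, 9, size=200)
        x = age + 0.3 * rng.normal(size=200)
        y = age + 0.3 * rng.normal(size=200)
        raw = spearmanr(x, y).statistic
        partial = partial_spearman(x, y, age)
        assert abs(raw) > 0.4
        assert abs(partial) < 0.15

    def test_matches_recursive_formula(self, rng):
        """Six-point table: residual route equals the recursive formula."""
        x = np.array([2.0, 4.0, 3.0, 9.0, 6.0, 5.0])
        y = np.array([1.0, 3.0, 7.0, 8.0, 2.0, 9.0])
        z1 = np.array([5.0, 1.0, 4.0, 2.0, 8.0, 3.0])
        z2 = np.array([2.0, 9.0, 1.0, 4.0, 6.0, 7.0])
        ours = partial_spearman(x, y, np.column_stack([z1, z2]))
        oracle = _brute_force_partial(x, y, z1, z2)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match=">= 4"):
            partial_spearman([1, 2, 3], [3, 2, 1])

    def test_constant_variable_undefined(self):
        assert np.isnan(partial_spearman(np.ones(10), np.arange(10.0)))


@pytest.fixture(scope="module")
def planted_group():
    """One severity group of the reference size (176) with a planted
    WASO-DAS Spearman correlation of 0.6."""
    res = synthesize_cohort(
        CohortSynthesisSpec(
            group_sizes=(176, 0, 0),
            seed=77,
            latent_correlation=planted_correlation({("WASO", "DAS"): 0.6}),
        )
    )
    return res.table


class TestBootstrap:
    def test_perfect_rank_correlation_degenerate(self):
        rng = np.random.default_rng(0)
        a = rng.permutation(10).astype(float)  # not collinear with age
        df = pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(10)],
                "age": np.linspace(5, 9, 10),
                "sex": ["M", "F"] * 5,
                "a": a,
                "b": a**3,
            }
        )
        mat = bootstrap_correlations(df, ["a", "b"], n_boot=50, seed=0)
        assert mat.median[0, 1] == pytest.approx(1.0)
        assert mat.p97_5[0, 1] - mat.p2_5[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_determinism_under_seed(self, planted_group):
        kw = dict(columns=["WASO", "DAS", "PPVT3"], n_boot=200, seed=9)
        a = bootstrap_correlations(planted_group, **kw)
        b = bootstrap_correlations(planted_group, **kw)
        np.testing.assert_array_equal(a.median, b.median)
        np.testing.assert_array_equal(a.p2_5, b.p2_5)

    def test_row_order_invariance(self, planted_group):
        shuffled = planted_group.sample(frac=1.0, random_state=3)
        kw = dict(columns=["WASO", "DAS"], n_boot=100, seed=4)
        a = bootstrap_correlations(planted_group, **kw)
        b = bootstrap_correlations(shuffled, **kw)
        np.testing.assert_array_equal(a.median, b.median)

    def test_planted_rho_recovered(self, planted_group):
        mat = bootstrap_correlations(
            planted_group, ["WASO", "DAS"], n_boot=1000, n_subsample=20, seed=1
        )
        med = mat.median[0, 1]
        assert abs(med - 0.6) < 0.15
        assert mat.p2_5[0, 1] <= 0.6 <= mat.p97_5[0, 1]

    def test_percentiles_bracket_median(self, planted_group):
        mat = bootstrap_correlations(
            planted_group, ["WASO", "DAS", "AHI", "Tow"], n_boot=300, seed=2
        )
        assert (mat.p2_5 <= mat.median + 1e-12).all()
        assert (mat.median <= mat.p97_5 + 1e-12).all()
        assert (np.abs(mat.median) <= 1.0 + 1e-12).all()

    def test_null_calibration_thresholded_fraction(self):
        """Under the null, bootstrap medians rarely clear the 0.30 threshold.

        The 20-subject resamples are drawn from a full-size control group
        (n=176): the bootstrap median concentrates on the group sample
        correlation, whose null spread shrinks with the group size.
        """
        exceed = []
        for seed in range(20):
            res = synthesize_cohort(
                CohortSynthesisSpec(group_sizes=(176, 0, 0), seed=300 + seed)
            )
            mat = bootstrap_correlations(
                res.table,
                ["AHI", "AR", "AS", "Nadir_SpO2", "WASO", "SleepEff",
                 "DAS", "PPVT3", "EVT", "DesCop", "PhPro", "Tow"],
                n_boot=200,
                n_subsample=20,
                seed=seed,
            )
            off = np.abs(mat.median[np.triu_indices(12, 1)])
            exceed.append((off >= 0.30).mean())
        assert np.mean(exceed) < 0.10


class TestThreshold:
    def test_inclusive_boundary(self):
        mat = _matrix(
            ["a", "b", "c", "d"],
            {("a", "b"): 0.29, ("a", "c"): 0.30, ("b", "d"): -0.31},
        )
        net = threshold_network(mat, threshold=0.30)
        assert net.graph.number_of_edges() == 2
        assert net.graph.has_edge("a", "c")
        assert net.graph.has_edge("b", "d")
        assert net.graph["b"]["d"]["weight"] == pytest.approx(-0.31)

    def test_identity_matrix_all_isolated(self):
        nodes = node_set("rp")
        mat = _matrix(nodes, {})
        net = threshold_network(mat)
        assert len(nodes) == 76
        assert net.graph.number_of_nodes() == 76
        assert net.graph.number_of_edges() == 0

    def test_saturated_matrix_complete_graph(self):
        nodes = node_set("specen")
        n = len(nodes)
        med = np.where(np.random.default_rng(0).random((n, n)) < 0.5, 1.0, -1.0)
        med = np.triu(med, 1)
        med = med + med.T + np.eye(n)
        mat = _matrix(nodes, {})
        mat.median = med
        net = threshold_network(mat)
        assert net.graph.number_of_edges() == 76 * 75 // 2


class TestLayout:
    def test_deterministic(self):
        mat = _matrix(["a", "b", "c"], {("a", "b"): 0.8})
        net = threshold_network(mat)
        p1 = layout_fruchterman_reingold(net, iterations=100, seed=5)
        p2 = layout_fruchterman_reingold(net, iterations=100, seed=5)
        assert p1 == p2
        assert all(np.isfinite(v).all() for v in (np.array(list(p1.values())),))

    def test_single_node_at_origin(self):
        mat = _matrix(["only"], {})
        net = threshold_network(mat)
        assert layout_fruchterman_reingold(net)["only"] == (0.0, 0.0)

    def test_edge_pulls_nodes_together(self):
        nodes = list("abcdef")
        mat = _matrix(nodes, {("a", "b"): 0.9})
        net = threshold_network(mat)
        gaps_edge, gaps_non = [], []
        for seed in range(10):
            pos = layout_fruchterman_reingold(net, iterations=200, seed=seed)
            xy = {k: np.array(v) for k, v in pos.items()}
            gaps_edge.append(np.linalg.norm(xy["a"] - xy["b"]))
            non = [
                np.linalg.norm(xy[u] - xy[v])
                for u, v in itertools.combinations(nodes, 2)
                if {u, v} != {"a", "b"}
            ]
            gaps_non.append(np.mean(non))
        assert np.mean(gaps_edge) < np.mean(gaps_non)


class TestModularity:
    def test_two_triangles(self):
        mat = _matrix(
            list("abcdef"),
            {(u, v): 0.8 for u, v in
             [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("d", "f"), ("e", "f")]},
        )
        net = threshold_network(mat)
        modules, q = modularity_partition(net)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert len(set(modules.values())) == 2
        assert modules["a"] == modules["b"] == modules["c"]
        assert modules["d"] == modules["e"] == modules["f"]

    def test_complete_uniform_graph_no_structure(self):
        nodes = list("abcde")
        mat = _matrix(nodes, {p: 0.7 for p in itertools.combinations(nodes, 2)})
        net = threshold_network(mat)
        modules, q = modularity_partition(net)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert len(set(modules.values())) == 1

    def test_empty_edges_singletons(self):
        mat = _matrix(list("abcd"), {})
        net = threshold_network(mat)
        modules, q = modularity_partition(net)
        assert q == 0.0
        assert len(set(modules.values())) == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search(self, seed):
        """Greedy + refinement equals brute force on random weighted graphs."""
        rng = np.random.default_rng(seed)
        nodes = list("abcdefg")
        entries = {
            p: round(float(rng.uniform(0.3, 1.0)), 2)
            for p in itertools.combinations(nodes, 2)
            if rng.random() < 0.4
        }
        mat = _matrix(nodes, entries)
        net = threshold_network(mat)
        _, q = modularity_partition(net)
        if net.graph.number_of_edges() == 0:
            assert q == 0.0
        else:
            assert q == pytest.approx(_exhaustive_modularity(net.graph), abs=1e-9)

    def test_planted_blocks_recovered(self):
        """Two planted correlation blocks are recovered exactly."""
        from sklearn.metrics import adjusted_rand_score

        block1 = ("AHI", "AR", "AS", "Nadir_SpO2")
        block2 = ("DAS", "PPVT3", "EVT", "DesCop")
        pairs = {p: 0.7 for b in (block1, block2) for p in itertools.combinations(b, 2)}
        pairs.update(
            {(u, v): 0.05 for u in block1 for v in block2}
        )
        res = synthesize_cohort(
            CohortSynthesisSpec(
                group_sizes=(20, 0, 0), seed=8, latent_correlation=planted_correlation(pairs)
            )
        )
        mat = bootstrap_correlations(
            res.table, block1 + block2, n_boot=500, n_subsample=20, seed=3
        )
        net = threshold_network(mat, threshold=0.30)
        modules, _ = modularity_partition(net)
        truth = [0] * 4 + [1] * 4
        found = [modules[n] for n in block1 + block2]
        assert adjusted_rand_score(truth, found) == 1.0

    def test_q_declines_with_cross_block_correlation(self):
        """Stronger between-block correlation erodes modularity."""
        from somnospec.synthetic import COHORT_VARIABLES

        block1 = ("AHI", "AR", "AS", "Nadir_SpO2")
        block2 = ("DAS", "PPVT3", "EVT", "DesCop")
        qs = []
        for between in (0.05, 0.5):
            pairs = {p: 0.7 for b in (block1, block2) for p in itertools.combinations(b, 2)}
            pairs.update({(u, v): between for u in block1 for v in block2})
            res = synthesize_cohort(
                CohortSynthesisSpec(
                    group_sizes=(20, 0, 0),
                    seed=15,
                    latent_correlation=planted_correlation(pairs),
                )
            )
            mat = bootstrap_correlations(
                res.table, block1 + block2, n_boot=300, n_subsample=20, seed=6
            )
            net = threshold_network(mat, threshold=0.30)
            _, q = modularity_partition(net)
            qs.append(q)
        assert qs[1] <= qs[0]


class TestCentrality:
    def test_path_betweenness(self):
        mat = _matrix(["a", "b", "c"], {("a", "b"): 1.0, ("b", "c"): 1.0})
        net = threshold_network(mat)
        cent = centrality_measures(net)
        assert cent.loc["b", "betweenness"] == pytest.approx(1.0)
        assert cent.loc["a", "betweenness"] == 0.0

    def test_star_hub_strength(self):
        leaves = ["l1", "l2", "l3", "l4", "l5"]
        mat = _matrix(["hub"] + leaves, {("hub", leaf): 1.0 for leaf in leaves})
        net = threshold_network(mat)
        cent = centrality_measures(net)
        assert cent.loc["hub", "strength"] == pytest.approx(5.0)

    def test_isolated_node_zeroes(self):
        mat = _matrix(["a", "b", "iso"], {("a", "b"): 0.5})
        cent = centrality_measures(threshold_network(mat))
        assert cent.loc["iso"].tolist() == [0.0, 0.0, 0.0]


class TestRadarSummary:
    def test_constant_block_mean(self):
        nodes = node_set("rp")
        theta_nodes = [n for n in nodes if n.startswith("rp_theta_")]
        from somnospec.network import NON_EEG_NODES

        entries = {(t, v): 0.31 for t in theta_nodes for v in NON_EEG_NODES[:6]}
        mat = _matrix(nodes, entries)
        radar = radar_summary(mat)
        for psg in NON_EEG_NODES[:6]:
            assert radar.band_vs_variable.loc["theta", psg] == pytest.approx(0.31)

    def test_zero_matrix_all_zero(self):
        mat = _matrix(node_set("specen"), {})
        radar = radar_summary(mat)
        assert (radar.band_vs_variable.to_numpy() == 0).all()
        assert (radar.psg_vs_cognitive == 0).all()

    def test_hand_computed_toy(self):
        """Four-channel toy: summaries equal hand-computed means exactly."""
        nodes = [f"rp_delta1_{c}" for c in ("F3", "F4", "C3", "C4")] + ["AHI", "DAS"]
        entries = {
            ("rp_delta1_F3", "AHI"): 0.4,
            ("rp_delta1_F4", "AHI"): -0.2,
            ("rp_delta1_C3", "AHI"): 0.1,
            ("rp_delta1_C4", "AHI"): 0.3,
            ("AHI", "DAS"): -0.5,
        }
        radar = radar_summary(_matrix(nodes, entries))
        assert radar.band_vs_variable.loc["delta1", "AHI"] == pytest.approx(
            (0.4 + 0.2 + 0.1 + 0.3) / 4, abs=1e-12
        )
        assert radar.psg_vs_cognitive["AHI"] == pytest.approx(0.5, abs=1e-12)
        assert radar.cognitive_vs_psg["DAS"] == pytest.approx(0.5, abs=1e-12)
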