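import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comethnet.network import (
    ModuleAssignment,
    adjacency_from_correlation,
    detect_modules,
    pairwise_correlation,
    pick_soft_power,
    scale_free_fit,
    soft_threshold_scan,
    topological_overlap,
)
from tests.conftest import random_correlation


def tom_bruteforce(adj: np.ndarray) -> np.ndarray:
    """Triple-loop oracle for the topological overlap formula."""
    n = adj.shape[0]
    k = adj.sum(axis=0)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(adj[i, u] * adj[u, j] for u in range(n))
            out[i, j] = (shared + adj[i, j]) / (min(k[i], k[j]) + 1 - adj[i, j])
    return out


def graph_adjacency(n, edges):
    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    ids = [f"p{i}" for i in range(n)]
    return pd.DataFrame(a, index=ids, columns=ids)


class TestPairwiseCorrelation:
    def test_self_correlation_is_one(self, rng):
        res = pd.DataFrame(rng.standard_normal((5, 40)))
        cor = pairwise_correlation(res)
        assert np.allclose(np.diag(cor), 1.0)

    def test_negated_probe(self, rng):
        x = rng.standard_normal(30)
        res = pd.DataFrame([x, -x], index=["a", "b"])
        cor = pairwise_correlation(res)
        assert cor.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_textbook_oracle(self, rng):
        res = pd.DataFrame(rng.standard_normal((200, 50)))
        cor = pairwise_correlation(res).to_numpy()
        X = res.to_numpy()
        Xc = X - X.mean(axis=1, keepdims=True)
        denom = np.sqrt((Xc**2).sum(axis=1))
        oracle = (Xc @ Xc.T) / np.outer(denom, denom)
        np.fill_diagonal(oracle, 1.0)
        assert np.max(np.abs(cor - oracle)) < 1e-12

    def test_pairwise_complete_with_missing(self, rng):
        res = pd.DataFrame(rng.standard_normal((4, 30)))
        res.iloc[0, :10] = np.nan
        cor = pairwise_correlation(res)
        a = res.iloc[0, 10:]
        b = res.iloc[1, 10:]
        assert cor.iloc[0, 1] == pytest.approx(np.corrcoef(a, b)[0, 1])

    def test_low_overlap_set_to_zero(self, rng):
        res = pd.DataFrame(rng.standard_normal((2, 10)))
        res.iloc[0, :8] = np.nan  # overlap 2 < 3
        with pytest.warns(UserWarning):
            cor = pairwise_correlation(res)
        assert cor.iloc[0, 1] == 0.0

    def test_zero_variance_probe_correlation_zero(self, rng):
        res = pd.DataFrame([np.ones(20), rng.standard_normal(20)], index=["c", "x"])
        with pytest.warns(UserWarning):
            cor = pairwise_correlation(res)
        assert cor.loc["c", "x"] == 0.0


class TestScaleFreeFit:
    def test_perfectly_collinear_negative_slope(self):
        # freq(k) = 64/k over k in {1, 2, 4, 8}: exact power law, slope -1
        k = np.concatenate(
            [np.full(c, center) for c, center in [(64, 1.0), (32, 2.0), (16, 4.0), (8, 8.0)]]
        )
        assert scale_free_fit(k, n_bins=8) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_bins_occupied_raises(self):
        with pytest.raises(ValueError):
            scale_free_fit(np.full(100, 3.0), n_bins=10)

    def test_n_bins_too_small_raises(self, rng):
        with pytest.raises(ValueError, match="n_bins"):
            scale_free_fit(rng.uniform(1, 10, 100), n_bins=2)

    def test_preferential_attachment_degrees_fit_well(self):
        import networkx as nx

        g = nx.barabasi_albert_graph(2000, 2, seed=4)
        degrees = np.array([d for _, d in g.degree()], dtype=float)
        assert scale_free_fit(degrees) > 0.8

    def test_positive_slope_gives_negative_index(self, rng):
        # frequency increasing with k -> positive slope -> negative index
        k = np.concatenate([np.full(c, center) for c, center in
                            zip([5, 10, 20, 40, 80], np.arange(1, 6))])
        assert scale_free_fit(k, n_bins=5) < 0


class TestPickSoftPower:
    def test_lowest_power_above_threshold(self, monkeypatch):
        scan = pd.DataFrame(
            {"power": [1, 2, 3, 4], "scale_free_r2": [0.5, 0.85, 0.93, 0.95],
             "mean_connectivity": [10, 5, 2, 1]}
        )
        monkeypatch.setattr(
            "comethnet.network.soft_threshold_scan", lambda *a, **k: scan
        )
        choice = pick_soft_power(pd.DataFrame(np.eye(3)), powers=[1, 2, 3, 4])
        assert choice.power == 3
        assert not choice.below_threshold

    def test_fallback_to_argmax_with_warning(self, monkeypatch):
        scan = pd.DataFrame(
            {"power": [1, 2, 3], "scale_free_r2": [0.1, 0.6, 0.4],
             "mean_connectivity": [9, 4, 2]}
        )
        monkeypatch.setattr(
            "comethnet.network.soft_threshold_scan", lambda *a, **k: scan
        )
        with pytest.warns(UserWarning, match="argmax"):
            choice = pick_soft_power(pd.DataFrame(np.eye(3)), powers=[1, 2, 3])
        assert choice.power == 2
        assert choice.below_threshold

    def test_zero_threshold_picks_first_power(self, rng):
        cor = random_correlation(60, rng)
        choice = pick_soft_power(cor, powers=[1, 2, 3], r2_threshold=-1.1)
        assert choice.power == 1

    def test_empty_powers_raises(self, rng):
        with pytest.raises(ValueError):
            pick_soft_power(random_correlation(10, rng), powers=[])


class TestAdjacency:
    def test_power_one_is_absolute_correlation(self, rng):
        cor = random_correlation(20, rng)
        adj = adjacency_from_correlation(cor, 1)
        expected = np.abs(cor.to_numpy())
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(adj.to_numpy(), expected)

    def test_monotone_in_power(self, rng):
        cor = random_correlation(15, rng)
        a2 = adjacency_from_correlation(cor, 2).to_numpy()
        a3 = adjacency_from_correlation(cor, 3).to_numpy()
        assert (a3 <= a2 + 1e-15).all()


class TestTopologicalOverlap:
    def test_complete_graph(self):
        adj = graph_adjacency(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
        tom = topological_overlap(adj).to_numpy()
        assert np.allclose(tom, 1.0)

    def test_printed_small_graph(self):
        # edges {12, 13, 23, 34} on 4 nodes (1-based)
        adj = graph_adjacency(4, [(0, 1), (0, 2), (1, 2), (2, 3)])
        tom = topological_overlap(adj)
        oracle = tom_bruteforce(adj.to_numpy())
        assert np.allclose(tom.to_numpy(), oracle, atol=1e-12)
        assert tom.iloc[0, 1] == pytest.approx(1.0)
        assert tom.iloc[0, 3] == pytest.approx(0.5)
        assert tom.iloc[2, 3] == pytest.approx(1.0)

    def test_empty_graph(self):
        adj = graph_adjacency(6, [])
        tom = topological_overlap(adj).to_numpy()
        off = tom[~np.eye(6, dtype=bool)]
        assert (off == 0).all()
        assert np.allclose(np.diag(tom), 1.0)

    def test_asymmetric_raises(self):
        a = np.zeros((4, 4))
        a[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(pd.DataFrame(a))

    def test_matches_bruteforce_on_random_weighted(self, rng):
        for _ in range(5):
            cor = random_correlation(25, rng)
            adj = adjacency_from_correlation(cor, 3)
            tom = topological_overlap(adj).to_numpy()
            assert np.max(np.abs(tom - tom_bruteforce(adj.to_numpy()))) < 1e-12

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_tom_bounded_on_random_adjacency(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(pd.DataFrame(a)).to_numpy()
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()

    def test_permutation_equivariance(self, rng):
        cor = random_correlation(18, rng)
        adj = adjacency_from_correlation(cor, 2).to_numpy()
        perm = rng.permutation(18)
        tom = topological_overlap(pd.DataFrame(adj)).to_numpy()
        tom_p = topological_overlap(pd.DataFrame(adj[np.ix_(perm, perm)])).to_numpy()
        assert np.allclose(tom_p, tom[np.ix_(perm, perm)], atol=1e-12)


def block_tom(sizes, within=1.0, between=0.0):
    n = sum(sizes)
    tom = np.full((n, n), between)
    start = 0
    for s in sizes:
        tom[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(tom, 1.0)
    ids = [f"p{i}" for i in range(n)]
    return pd.DataFrame(tom, index=ids, columns=ids)


class TestDetectModules:
    def test_two_perfect_blocks(self):
        tom = block_tom([40, 40])
        modules = detect_modules(tom, min_module_size=30)
        assert dict(modules.sizes()) == {1: 40, 2: 40}
        assert (modules.labels != 0).all()
        lab = modules.labels.to_numpy()
        assert len(set(lab[:40])) == 1 and len(set(lab[40:])) == 1

    def test_homogeneous_tom_does_not_crash(self):
        tom = block_tom([60], within=0.5)
        modules = detect_modules(tom, min_module_size=30)
        assert modules.n_modules in (0, 1)

    def test_min_module_size_validation(self):
        tom = block_tom([40])
        with pytest.raises(ValueError, match="min_module_size"):
            detect_modules(tom, min_module_size=1)
        with pytest.raises(ValueError, match="fewer probes"):
            detect_modules(tom.iloc[:10, :10], min_module_size=30)

    def test_planted_module_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        from comethnet.residualize import residualize_matrix
        from comethnet.synthetic import SimulationConfig, simulate_study

        st = simulate_study(SimulationConfig(seed=3, module_correlation=0.7))
        res = residualize_matrix(st.pre_betas, st.sample_sheet, st.kinship, n_pcs=0)
        cor = pairwise_correlation(res)
        tom = topological_overlap(adjacency_from_correlation(cor, 3))
        modules = detect_modules(tom, min_module_size=30)
        ari = adjusted_rand_score(
            st.planted_modules.labels.to_numpy(), modules.labels.to_numpy()
        )
        assert ari >= 0.8

    def test_invariant_under_probe_reordering(self, rng):
        tom = block_tom([35, 33], within=0.8, between=0.05)
        perm = rng.permutation(len(tom))
        tom_p = tom.iloc[perm, perm]
        a = detect_modules(tom, min_module_size=30)
        b = detect_modules(tom_p, min_module_size=30)
        merged = pd.concat([a.labels.rename("a"), b.labels.rename("b")], axis=1)
        # same partition: the label pairing is a bijection
        groups = merged.groupby("a")["b"].nunique()
        assert (groups == 1).all()
        assert merged.groupby("b")["a"].nunique().eq(1).all()


class TestModuleAssignment:
    def test_labels_ordered_by_descending_size(self):
        labels = pd.Series([2] * 10 + [1] * 5 + [0] * 3, index=[f"p{i}" for i in range(18)])
        ma = ModuleAssignment(labels)
        assert dict(ma.sizes()) == {1: 10, 2: 5}
        assert ma.color(0) == "grey"
        assert ma.color(1) == "turquoise"

    def test_to_frame_schema(self, default_study):
        df = default_study.planted_modules.to_frame()
        assert list(df.columns) == ["probe_id", "module", "color"]


def test_soft_threshold_scan_monotone_mean_connectivity(rng):
    cor = random_correlation(40, rng)
    scan = soft_threshold_scan(cor, powers=[1, 2, 3, 4, 5])
    mk = scan["mean_connectivity"].to_numpy()
    assert (np.diff(mk) <= 1e-12).all()
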