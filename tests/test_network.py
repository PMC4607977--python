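"""Network construction: correlation, soft threshold, TOM, module detection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from coexval import (GRAY_LABEL, SyntheticSpec, TOMModuleDetector, WeightedNetwork,
                     correlation_matrix, detect_modules, make_modular_expression,
                     soft_threshold_adjacency, topological_overlap)


def brute_force_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())


class TestCorrelationMatrix:
    def test_duplicated_gene_has_unit_correlation(self):
        data = pd.DataFrame([[1.0, 2, 3, 5], [1.0, 2, 3, 5]], index=["a", "b"])
        cor = correlation_matrix(data)
        assert cor.loc["a", "b"] == pytest.approx(1.0)

    def test_negated_gene_has_minus_one(self):
        data = pd.DataFrame([[1.0, 2, 3, 5], [-1.0, -2, -3, -5]], index=["a", "b"])
        assert correlation_matrix(data).loc["a", "b"] == pytest.approx(-1.0)

    def test_toy_matrix_matches_direct_formula(self):
        rows = {"g1": [1.0, 2, 3], "g2": [1.0, 2, 4], "g3": [3.0, 1, 2]}
        cor = correlation_matrix(pd.DataFrame(rows).T)
        for a in rows:
            for b in rows:
                expected = 1.0 if a == b else brute_force_pearson(rows[a], rows[b])
                assert cor.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_zeroed_with_warning(self, caplog):
        data = pd.DataFrame([[1.0, 2, 3, 4], [5.0, 5, 5, 5]], index=["ok", "flat"])
        with caplog.at_level("WARNING"):
            cor = correlation_matrix(data)
        assert "flat" in caplog.text
        assert cor.loc["ok", "flat"] == 0.0
        assert cor.loc["flat", "flat"] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(pd.DataFrame([[1.0, 2], [3.0, 4]]))


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "r, beta, signed, expected",
        [(1.0, 6, False, 1.0), (-0.5, 2, False, 0.25), (-1.0, 3, True, 0.0),
         (0.5, 1, False, 0.5), (0.0, 4, True, 0.0625)],
    )
    def test_entrywise_map(self, r, beta, signed, expected):
        cor = np.array([[1.0, r], [r, 1.0]])
        net = soft_threshold_adjacency(cor, beta=beta, signed=signed)
        assert net.adjacency[0, 1] == pytest.approx(expected)
        assert net.adjacency[0, 0] == 0.0

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            soft_threshold_adjacency(np.eye(2), beta=0)

    def test_weighted_network_validates_entries(self):
        with pytest.raises(ValueError, match="symmetric"):
            WeightedNetwork(np.array([[0.0, 0.5], [0.1, 0.0]]), ["a", "b"])
        with pytest.raises(ValueError, match="diagonal"):
            WeightedNetwork(np.array([[0.5, 0.1], [0.1, 0.0]]), ["a", "b"])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            WeightedNetwork(np.array([[0.0, 1.5], [1.5, 0.0]]), ["a", "b"])


def tom_brute_force(a):
    """Direct triple-loop evaluation of the overlap formula."""
    n = a.shape[0]
    k = a.sum(axis=0)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTopologicalOverlap:
    def test_isolated_pair_has_full_overlap(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        tom = topological_overlap(WeightedNetwork(a, ["a", "b"]))
        assert tom[0, 1] == pytest.approx(1.0)

    def test_empty_network_has_zero_overlap(self):
        tom = topological_overlap(WeightedNetwork(np.zeros((4, 4)), list("abcd")))
        assert np.allclose(tom - np.eye(4), 0.0)

    @pytest.mark.parametrize("n,seed", [(4, 0), (6, 1), (8, 2)])
    def test_matches_triple_loop_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        net = WeightedNetwork(a, [f"g{i}" for i in range(n)])
        assert np.allclose(topological_overlap(net), tom_brute_force(a), atol=1e-12)

    def test_entries_bounded_and_symmetric(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 1, (12, 12))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(WeightedNetwork(a, [f"g{i}" for i in range(12)]))
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        assert np.allclose(tom, tom.T)


def block_dissimilarity(sizes, within=0.1, between=0.9, jitter=0.0, seed=0):
    n = sum(sizes)
    d = np.full((n, n), between)
    start = 0
    for s in sizes:
        d[start:start + s, start:start + s] = within
        start += s
    if jitter:
        rng = np.random.default_rng(seed)
        noise = rng.uniform(0, jitter, (n, n))
        d = d + (noise + noise.T) / 2
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


class TestDetectModules:
    def test_two_blocks_get_color_labels_by_size(self):
        d = block_dissimilarity([5, 3])
        part = detect_modules(d, [f"g{i}" for i in range(8)], min_size=3, cut_height=0.5)
        assert part.module_names == ["turquoise", "blue"]
        assert len(part.members("turquoise")) == 5
        assert len(part.members("blue")) == 3
        assert len(part.gray_genes) == 0

    def test_min_size_filter_relabels_small_clusters_gray(self):
        d = block_dissimilarity([5, 3])
        part = detect_modules(d, [f"g{i}" for i in range(8)], min_size=4, cut_height=0.5)
        assert part.module_names == ["turquoise"]
        assert len(part.gray_genes) == 3

    def test_cut_height_validated(self):
        d = block_dissimilarity([4, 4])
        with pytest.raises(ValueError, match="cut_height"):
            detect_modules(d, list(range(8)), cut_height=1.5)

    def test_gene_order_invariance_up_to_relabeling(self):
        d = block_dissimilarity([6, 5, 4], jitter=0.05, seed=3)
        ids = [f"g{i}" for i in range(15)]
        part = detect_modules(d, ids, min_size=3, cut_height=0.5)
        rng = np.random.default_rng(1)
        perm = rng.permutation(15)
        part2 = detect_modules(d[np.ix_(perm, perm)], [ids[i] for i in perm],
                               min_size=3, cut_height=0.5)
        lab1 = part.labels.sort_index()
        lab2 = part2.labels.sort_index()
        assert adjusted_rand_score(lab1.values, lab2.values) == pytest.approx(1.0)

    def test_increasing_min_size_never_adds_modules_or_shrinks_gray(self):
        d = block_dissimilarity([6, 4, 3], jitter=0.05, seed=8)
        ids = list(range(13))
        prev_modules, prev_gray = np.inf, -1
        for ms in (2, 3, 4, 5, 7):
            part = detect_modules(d, ids, min_size=ms, cut_height=0.5)
            assert part.n_modules <= prev_modules
            assert len(part.gray_genes) >= prev_gray
            prev_modules, prev_gray = part.n_modules, len(part.gray_genes)


class TestTOMModuleDetector:
    def test_recovers_planted_modules(self):
        aris = []
        for seed in range(10):
            spec = SyntheticSpec(n_samples=60, module_sizes=(30, 20, 15),
                                 module_strengths=(0.8, 0.8, 0.8), n_gray=50, seed=seed)
            data, truth = make_modular_expression(spec)
            labels = TOMModuleDetector().fit_predict(data)
            aris.append(adjusted_rand_score(truth.labels.values, labels))
        assert np.mean(aris) > 0.9

    def test_sklearn_estimator_contract(self, small_dataset):
        data, _ = small_dataset
        det = TOMModuleDetector(beta=4, min_size=4)
        params = det.get_params()
        assert params["beta"] == 4 and params["min_size"] == 4
        cloned = clone(det)
        assert cloned.get_params() == params
        det.fit(data)
        assert len(det.labels_) == data.shape[0]
        assert det.tom_.shape == (data.shape[0], data.shape[0])
        assert (det.partition_.labels.index == data.index).all()

    def test_missing_values_rejected(self):
        data = pd.DataFrame(np.ones((4, 6)))
        data.iloc[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            TOMModuleDetector().fit(data)
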