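import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from escompare.coexpr import (ModuleAssignment, all_eigengenes,
                              classify_temporal_pattern, detect_modules,
                              merge_modules, module_eigengene,
                              signed_adjacency, topological_overlap)
from escompare.io import ExpressionMatrix
from escompare.synthetic import PATTERN_TEMPLATES, gen_expression


def _expr_from(values, n_pre=None):
    n_genes, n_samples = values.shape
    n_pre = n_pre if n_pre is not None else n_samples // 2
    samples = [f"S{i}" for i in range(n_samples)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)],
                     columns=samples),
        pd.Series(np.arange(n_samples, dtype=float) + 1, index=samples),
        pd.Series([True] * n_pre + [False] * (n_samples - n_pre),
                  index=samples))


def naive_tom(a: np.ndarray) -> np.ndarray:
    """O(n^3) double-loop evaluation of the topological overlap formula."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestAdjacency:
    def test_signed_transform_endpoints(self):
        # perfectly correlated pair -> 1; anti-correlated -> 0
        t = np.linspace(0, 1, 10)
        vals = np.vstack([t, 2 * t + 1, -t])
        adj = signed_adjacency(_expr_from(vals), beta=15.0)
        assert adj.iloc[0, 1] == pytest.approx(1.0)
        assert adj.iloc[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_value(self):
        # orthogonal patterns: cor = 0 -> ((1+0)/2)^15
        vals = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        adj = signed_adjacency(_expr_from(vals), beta=15.0)
        assert adj.iloc[0, 1] == pytest.approx(0.5**15, rel=1e-9)

    def test_zero_variance_genes_removed(self):
        vals = np.vstack([np.linspace(0, 1, 6), np.ones(6)])
        adj = signed_adjacency(_expr_from(vals), beta=2.0)
        assert list(adj.index) == ["g0"]

    def test_invalid_beta(self, small_expr):
        with pytest.raises(ValueError, match="beta"):
            signed_adjacency(small_expr, beta=0.0)

    def test_biweight_close_to_pearson_on_clean_data(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((10, 40))
        em = _expr_from(vals)
        ap = signed_adjacency(em, beta=1.0, method="pearson")
        ab = signed_adjacency(em, beta=1.0, method="biweight")
        assert np.abs(ap.to_numpy() - ab.to_numpy()).max() < 0.1


class TestTOM:
    def test_two_gene_limits(self):
        full = topological_overlap(np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert full[0, 1] == pytest.approx(1.0)
        none = topological_overlap(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert none[0, 1] == pytest.approx(0.0)

    @pytest.mark.parametrize("n, seed", [(5, 0), (20, 1), (20, 2)])
    def test_matches_naive_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        np.testing.assert_allclose(topological_overlap(a), naive_tom(a),
                                   atol=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, (12, 12))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        perm = rng.permutation(12)
        t1 = topological_overlap(a)[np.ix_(perm, perm)]
        t2 = topological_overlap(a[np.ix_(perm, perm)])
        np.testing.assert_allclose(t1, t2, atol=1e-12)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(np.array([[1.0, 0.2], [0.5, 1.0]]))


class TestDetectModules:
    def test_recovers_planted_blocks(self):
        em, truth = gen_expression([40, 40, 40], list(PATTERN_TEMPLATES),
                                   n_prenatal=12, n_postnatal=12, snr=3.0,
                                   seed=0, n_background=60)
        tom = topological_overlap(signed_adjacency(em, beta=15.0))
        assign = detect_modules(tom, min_module_size=30)
        true_labels = [truth.module_membership[g] for g in assign.labels.index]
        assert adjusted_rand_score(true_labels, assign.labels.values) >= 0.8

    def test_small_blocks_unassigned(self):
        em, _ = gen_expression([40, 10], ["prenatal_rise_sustained",
                                          "prenatal_high_drop"],
                               n_prenatal=12, n_postnatal=12, snr=5.0,
                               seed=1)
        tom = topological_overlap(signed_adjacency(em, beta=15.0))
        assign = detect_modules(tom, min_module_size=30)
        assert assign.module_sizes == {1: 40}
        assert (assign.labels == 0).sum() == 10

    def test_labels_ordered_by_decreasing_size(self):
        em, _ = gen_expression([35, 60], ["prenatal_rise_sustained",
                                          "prenatal_high_drop"],
                               n_prenatal=12, n_postnatal=12, snr=5.0,
                               seed=2)
        tom = topological_overlap(signed_adjacency(em, beta=15.0))
        assign = detect_modules(tom, min_module_size=30)
        sizes = [assign.module_sizes[m] for m in assign.module_ids]
        assert sizes == sorted(sizes, reverse=True)


class TestEigengene:
    def test_identical_genes_perfect_representation(self):
        t = np.linspace(0, 1, 8)
        vals = np.vstack([t, t, t])
        em = _expr_from(vals)
        assign = ModuleAssignment(pd.Series([1, 1, 1], index=em.genes))
        eg = module_eigengene(em, assign, 1)
        z = (t - t.mean()) / t.std(ddof=1)
        assert abs(np.corrcoef(eg.scores, z)[0, 1]) == pytest.approx(1.0)
        assert eg.variance_explained == pytest.approx(1.0)

    def test_unit_norm_and_positive_orientation(self):
        em, _ = gen_expression([30], ["prenatal_rise_sustained"],
                               n_prenatal=10, n_postnatal=10, snr=3.0, seed=3)
        assign = ModuleAssignment(pd.Series(1, index=em.genes))
        eg = module_eigengene(em, assign, 1)
        assert np.linalg.norm(eg.scores) == pytest.approx(1.0)
        sub = em.values.to_numpy()
        z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, ddof=1, keepdims=True)
        assert np.corrcoef(eg.scores, z.mean(0))[0, 1] >= 0

    def test_global_sign_flip_is_undone_by_orientation(self):
        em, _ = gen_expression([30], ["prenatal_high_drop"],
                               n_prenatal=10, n_postnatal=10, snr=3.0, seed=4)
        flipped = ExpressionMatrix(-em.values, em.age_days, em.prenatal)
        assign = ModuleAssignment(pd.Series(1, index=em.genes))
        e1 = module_eigengene(em, assign, 1)
        e2 = module_eigengene(flipped, assign, 1)
        assert np.corrcoef(e1.scores, -e2.scores)[0, 1] == pytest.approx(1.0)

    def test_degenerate_module_rejected(self):
        vals = np.ones((3, 6))
        em = _expr_from(vals)
        assign = ModuleAssignment(pd.Series([1, 1, 1], index=em.genes))
        with pytest.raises(ValueError):
            module_eigengene(em, assign, 1)

    def test_too_small_module_rejected(self, small_expr):
        assign = ModuleAssignment(pd.Series([1, 0, 0, 0, 0, 0],
                                            index=small_expr.genes))
        with pytest.raises(ValueError, match=">= 2"):
            module_eigengene(small_expr, assign, 1)


class TestMerge:
    def _planted(self, sizes, patterns, seed, snr=5.0):
        em, _ = gen_expression(sizes, patterns, n_prenatal=12, n_postnatal=12,
                               snr=snr, seed=seed)
        labels = np.concatenate([[i + 1] * s for i, s in enumerate(sizes)])
        assign = ModuleAssignment(pd.Series(labels, index=em.genes))
        return em, assign, all_eigengenes(em, assign)

    def test_identical_pattern_modules_merge(self):
        em, assign, eigs = self._planted(
            [30, 30], ["prenatal_rise_sustained", "prenatal_rise_sustained"],
            seed=5)
        merged, _ = merge_modules(em, assign, eigs, merge_threshold=0.9)
        assert merged.module_ids == [1]
        assert merged.module_sizes[1] == 60

    def test_uncorrelated_modules_untouched(self):
        em, assign, eigs = self._planted(
            [30, 30], ["prenatal_rise_sustained", "prenatal_high_drop"],
            seed=6)
        merged, _ = merge_modules(em, assign, eigs, merge_threshold=0.9)
        assert len(merged.module_ids) == 2

    def test_three_way_merge_reaches_fixpoint(self):
        em, assign, eigs = self._planted(
            [30, 30, 30], ["low_prenatal_mid"] * 3, seed=7, snr=8.0)
        merged, eigs2 = merge_modules(em, assign, eigs, merge_threshold=0.9)
        assert merged.module_ids == [1]
        assert set(eigs2) == {1}


class TestTemporalPatterns:
    def _eig(self, pre, post):
        n_pre, n_post = len(pre), len(post)
        scores = np.array(pre + post, float)
        scores = scores / np.linalg.norm(scores)
        samples = [f"S{i}" for i in range(n_pre + n_post)]
        from escompare.coexpr import Eigengene
        eg = Eigengene(1, pd.Series(scores, index=samples), 1.0)
        ages = pd.Series(np.arange(n_pre + n_post, dtype=float), index=samples)
        prenatal = pd.Series([True] * n_pre + [False] * n_post, index=samples)
        return eg, ages, prenatal

    @pytest.mark.parametrize("pre, post, expected", [
        ([0, 1, 2, 3, 4, 5], [5, 5, 5, 5], "prenatal_rise_sustained"),
        ([5, 4, 3, 2, 1, 0], [0, 0, 0, 0], "prenatal_high_drop"),
        ([0, 0, 0, 0, 0, 0], [2, 2, 2, 2], "low_prenatal_mid"),
        ([0, 5, 0, 5, 0, 5], [2, 3, 2, 3], "unclassified"),
    ])
    def test_constructed_trajectories(self, pre, post, expected):
        eg, ages, prenatal = self._eig(pre, post)
        assert classify_temporal_pattern(eg, ages, prenatal) == expected

    def test_insufficient_samples_rejected(self):
        eg, ages, prenatal = self._eig([1, 2], [3, 4, 5])
        with pytest.raises(ValueError, match="prenatal"):
            classify_temporal_pattern(eg, ages, prenatal)

    def test_planted_patterns_recovered_end_to_end(self):
        em, truth = gen_expression([40, 40, 40], list(PATTERN_TEMPLATES),
                                   n_prenatal=12, n_postnatal=12, snr=3.0,
                                   seed=8, n_background=40)
        tom = topological_overlap(signed_adjacency(em, beta=15.0))
        assign = detect_modules(tom, min_module_size=30)
        eigs = all_eigengenes(em, assign)
        assign, eigs = merge_modules(em, assign, eigs)
        patterns = {classify_temporal_pattern(e, em.age_days, em.prenatal)
                    for e in eigs.values()}
        assert set(PATTERN_TEMPLATES) <= patterns
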