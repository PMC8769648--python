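import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import regpattern as rp
from regpattern.errors import EmptyResultError, ValidationError

from conftest import make_cells


def pearson_two_pass(x, y):
    """Independent brute-force two-pass Pearson correlation."""
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


class TestQcFilter:
    def _matrix(self, rows):
        return make_cells(np.asarray(rows, dtype=int), clusters=["c"] * len(rows))

    def test_umi_boundary_is_strict(self):
        # one cell at 599 total UMI (removed), one at 600 with ratio 1.25 and
        # enough detected genes (kept); gene filters relaxed for the fixture
        qc = rp.AnalysisConfig().qc
        qc.min_genes_per_cell = 2
        qc.min_cells_per_gene = 0
        qc.max_cell_fraction_per_gene = 1.0
        bad = [599] + [0] * 479
        good = [120] * 5 + [0] * 475
        cells = self._matrix([bad, good])
        # bad: 599 UMI over 1 gene (ratio fine) -> UMI rule; good: 600 UMI,
        # 5 genes -> ratio 120 and 600 UMI -> kept
        filtered, report = rp.qc_filter(cells, qc)
        assert filtered.n_cells == 1
        assert report.cells_low_umi == 1

    def test_gene_detection_boundary(self):
        rng = np.random.default_rng(0)
        n_cells = 1000
        counts = rng.poisson(2.0, size=(n_cells, 30)) + 1  # everything detected
        counts[:, 0] = 0
        counts[:981, 1] = 0  # gene 1 in 19 cells -> removed
        counts[:980, 2] = 0  # gene 2 in 20 cells -> kept
        qc = rp.AnalysisConfig().qc
        qc.min_umi = 0
        qc.min_ratio_umi_per_gene = 0
        qc.min_genes_per_cell = 0
        qc.max_cell_fraction_per_gene = 1.0
        cells = make_cells(counts, clusters=["c"] * n_cells)
        filtered, report = rp.qc_filter(cells, qc)
        assert "g1" not in filtered.gene_ids
        assert "g2" in filtered.gene_ids
        assert report.genes_few_cells == 2  # g0 (never detected) and g1

    def test_each_rule_counted_once(self):
        # 5 cells, exactly 2 violate exactly one rule each
        qc = rp.AnalysisConfig().qc
        qc.min_umi = 10
        qc.min_ratio_umi_per_gene = 2.0
        qc.min_genes_per_cell = 2
        qc.max_mito_fraction = 0.5
        qc.min_cells_per_gene = 0
        qc.max_cell_fraction_per_gene = 1.0
        genes = ["mt-a", "g1", "g2", "g3"]
        rows = [
            [0, 6, 6, 0],   # kept: 12 UMI, ratio 6, 2 genes, no mito
            [0, 5, 4, 0],   # removed: 9 UMI < 10
            [0, 10, 10, 10],  # kept: 30 UMI, ratio 10, 3 genes
            [9, 2, 2, 0],   # removed: mito fraction 9/13 > 0.5
            [0, 20, 20, 0],  # kept
        ]
        cells = make_cells(np.asarray(rows), clusters=["c"] * 5, genes=genes)
        filtered, report = rp.qc_filter(cells, qc)
        assert filtered.n_cells == 3
        assert report.cells_low_umi == 1
        assert report.cells_high_mito == 1

    def test_all_cells_removed_errors(self):
        cells = make_cells(np.ones((2, 3), dtype=int))
        with pytest.raises(EmptyResultError):
            rp.qc_filter(cells)  # default thresholds remove these tiny cells


class TestNormalize:
    def test_closed_form(self):
        cells = rp.normalize(make_cells([[10, 0]]), scale=10000)
        np.testing.assert_allclose(cells.normalized, [[np.log(10001), 0.0]])

    def test_scale_invariance_across_cells(self):
        # proportional counts normalize identically
        cells = rp.normalize(make_cells([[2, 4, 6], [1, 2, 3], [10, 20, 30]]))
        assert np.allclose(cells.normalized, cells.normalized[0])

    def test_matches_independent_log1p_cpm_oracle(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 50, size=(4, 3))
        cells = rp.normalize(make_cells(counts), scale=10000)
        for i in range(4):
            total = counts[i].sum()
            for j in range(3):
                expected = np.log(1 + 10000 * counts[i, j] / total)
                assert cells.normalized[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_total_cell_errors(self):
        with pytest.raises(ValidationError):
            rp.normalize(make_cells([[0, 0], [1, 2]]))


class TestVariableGenes:
    def _fixture(self, n_cells=200, n_genes=50, seed=0):
        # low-expression test genes plus a few high "housekeeping" genes that
        # carry the library size (and sit above the x_high mean cutoff)
        rng = np.random.default_rng(seed)
        counts = rng.poisson(0.5, size=(n_cells, n_genes))
        counts[:, 0] = 1  # identical in every cell: minimal dispersion
        # gene 1: similar mean, strongly inflated variance (rare large counts)
        counts[:, 1] = 0
        counts[rng.random(n_cells) < 0.1, 1] = 5
        housekeeping = rng.poisson(400, size=(n_cells, 5))
        counts = np.hstack([counts, housekeeping])
        return make_cells(counts, normalized=True)

    def test_constant_gene_excluded_variable_gene_selected(self):
        cells = self._fixture()
        hvg = rp.AnalysisConfig().hvg
        hvg.n_bins = 5
        selected = rp.select_variable_genes(cells, hvg)
        assert "g0" not in selected
        assert "g1" in selected

    def test_high_mean_cutoff_excludes(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(2.0, size=(60, 30))
        counts[:, 5] = rng.poisson(4000, size=60)  # back-transformed mean >> 8
        cells = make_cells(counts, normalized=True)
        hvg = rp.AnalysisConfig().hvg
        hvg.n_bins = 5
        assert "g5" not in rp.select_variable_genes(cells, hvg)

    def test_fewer_genes_than_bins_warns(self):
        cells = self._fixture(n_genes=20)
        with pytest.warns(UserWarning, match="bins"):
            rp.select_variable_genes(cells)


class TestClusterMeans:
    def test_singleton_cluster_equals_cell(self):
        cells = rp.normalize(make_cells([[5, 1], [2, 8]], clusters=["a", "b"]))
        means = rp.cluster_means(cells)
        np.testing.assert_allclose(means.means[0], cells.normalized[0])

    def test_hand_computed_two_clusters(self):
        cells = rp.normalize(
            make_cells([[1, 0], [3, 0], [0, 2], [0, 6]], clusters=["a", "a", "b", "b"])
        )
        means = rp.cluster_means(cells)
        expected_a = (cells.normalized[0] + cells.normalized[1]) / 2
        np.testing.assert_allclose(means.means[means.cluster_ids.index("a")], expected_a)

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 20, size=(10, 4))
        clusters = ["a"] * 5 + ["b"] * 5
        cells = rp.normalize(make_cells(counts, clusters=clusters))
        perm = rng.permutation(10)
        shuffled = rp.normalize(
            make_cells(counts[perm], clusters=[clusters[i] for i in perm])
        )
        np.testing.assert_allclose(
            rp.cluster_means(cells).means, rp.cluster_means(shuffled).means
        )

    def test_missing_gene_errors(self):
        cells = rp.normalize(make_cells([[1, 2], [3, 4]]))
        with pytest.raises(ValidationError, match="absent"):
            rp.cluster_means(cells, genes=["nope"])


class TestPartitionGenes:
    def test_basic_partition(self):
        cat = rp.GeneCatalog(category={"g1": "TF", "g2": "effector", "g3": "RBP"})
        parts = rp.partition_genes(cat, ["g1", "g2"])
        assert parts == {"TF": {"g1"}, "effector": {"g2"}, "RBP": set()}

    def test_union_subset_of_variable(self):
        cat = rp.GeneCatalog(
            category={"g1": "TF", "g2": "effector", "g3": "other", "g4": "RBP"}
        )
        parts = rp.partition_genes(cat, ["g1", "g2", "g3"])
        union = parts["TF"] | parts["effector"] | parts["RBP"]
        assert union <= {"g1", "g2", "g3"}

    def test_empty_tf_set_errors(self):
        cat = rp.GeneCatalog(category={"g1": "effector", "g2": "effector"})
        with pytest.raises(EmptyResultError):
            rp.partition_genes(cat, ["g1", "g2"])


class TestProfileDistance:
    def _means(self, rows, genes=3):
        return rp.ClusterMeanMatrix(
            means=np.asarray(rows, dtype=float),
            cluster_ids=[f"k{i}" for i in range(len(rows))],
            gene_ids=[f"g{j}" for j in range(genes)],
        )

    def test_hand_examples(self):
        d = rp.profile_distance(self._means([[1, 2, 3], [1, 2, 3]]))
        assert d.value("k0", "k1") == pytest.approx(0.0, abs=1e-12)
        d = rp.profile_distance(self._means([[1, 2, 3], [3, 2, 1]]))
        assert d.value("k0", "k1") == pytest.approx(1.0, abs=1e-12)
        d = rp.profile_distance(self._means([[1, 2, 3], [1, 3, 2]]))
        assert d.value("k0", "k1") == pytest.approx(0.25, abs=1e-12)

    def test_matches_brute_force_pearson_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            m = rng.uniform(0.1, 5.0, size=(5, 10))
            dist = rp.profile_distance(
                rp.ClusterMeanMatrix(
                    means=m,
                    cluster_ids=[f"k{i}" for i in range(5)],
                    gene_ids=[f"g{j}" for j in range(10)],
                )
            )
            for i in range(5):
                for j in range(i + 1, 5):
                    expected = (1 - pearson_two_pass(m[i], m[j])) / 2
                    assert abs(dist.d[i, j] - expected) < 1e-12

    def test_zero_variance_profile_names_cluster(self):
        with pytest.raises(ValidationError, match="k1"):
            rp.profile_distance(self._means([[1, 2, 3], [2, 2, 2]]))

    def test_pair_count_is_n_choose_2(self):
        n = 39
        rng = np.random.default_rng(5)
        m = rng.uniform(0.1, 3, size=(n, 10))
        dist = rp.profile_distance(
            rp.ClusterMeanMatrix(
                means=m,
                cluster_ids=[f"k{i:02d}" for i in range(n)],
                gene_ids=[f"g{j}" for j in range(10)],
            )
        )
        assert len(dist.d[np.triu_indices(n, k=1)]) == n * (n - 1) // 2 == 741

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_distance_invariants_hold_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0.05, 4.0, size=(4, 6)) + rng.normal(0, 0.5, size=(4, 6)).clip(min=0)
        dist = rp.profile_distance(
            rp.ClusterMeanMatrix(
                means=m,
                cluster_ids=list("abcd"),
                gene_ids=[f"g{j}" for j in range(6)],
            )
        )
        assert np.allclose(dist.d, dist.d.T)
        assert np.allclose(np.diag(dist.d), 0)
        assert dist.d.min() >= 0 and dist.d.max() <= 1


class TestSubsampledDistance:
    def test_fraction_one_equals_full(self, small_study):
        _, means, catalog = small_study
        genes = sorted(catalog.genes_in("TF"))
        full = rp.profile_distance(means, genes)
        sub = rp.subsampled_distance(means, genes, fraction=1.0, reps=7, seed=0)
        np.testing.assert_allclose(full.d, sub.d)

    def test_seed_determinism_and_variation(self, small_study):
        _, means, catalog = small_study
        genes = sorted(catalog.genes_in("effector"))
        a = rp.subsampled_distance(means, genes, 0.8, 5, seed=1)
        b = rp.subsampled_distance(means, genes, 0.8, 5, seed=1)
        c = rp.subsampled_distance(means, genes, 0.8, 5, seed=2)
        np.testing.assert_array_equal(a.d, b.d)
        assert not np.array_equal(a.d, c.d)
        tri = np.triu_indices_from(a.d, k=1)
        assert np.corrcoef(a.d[tri], c.d[tri])[0, 1] > 0.9

    def test_tracks_full_distance_on_large_gene_sets(self):
        # 1000-gene set, fraction 0.8, reps 20: elementwise correlation with
        # the full-gene distance stays above 0.95 across 10 seeds
        for seed in range(10):
            truth = rp.SyntheticTruth(
                n_clusters=8,
                genes_per_category={"TF": 1000, "effector": 0, "RBP": 0, "other": 0},
                planted_pairs=[(rp.PairKey("C1", "C2"), "divergent")],
                seed=seed,
            )
            means, catalog = rp.generate_cluster_means(truth)
            genes = sorted(catalog.genes_in("TF"))
            full = rp.profile_distance(means, genes)
            sub = rp.subsampled_distance(means, genes, 0.8, 20, seed=seed)
            tri = np.triu_indices_from(full.d, k=1)
            assert np.corrcoef(full.d[tri], sub.d[tri])[0, 1] > 0.95
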