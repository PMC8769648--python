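import itertools

import numpy as np
import pandas as pd
import pytest

import regpattern as rp
from regpattern.errors import ValidationError
from regpattern.markers import exact_rank_sum_p

from conftest import make_cells


def oracle_exact_p(x, y):
    """Independent enumeration of the rank-sum null: assign pooled values to
    groups in every possible way and compare rank sums (midranks by sorting)."""
    pooled = list(x) + list(y)
    n1, n = len(x), len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    w_obs = sum(ranks[:n1])
    le = ge = total = 0
    for combo in itertools.combinations(range(n), n1):
        w = sum(ranks[i] for i in combo)
        total += 1
        le += w <= w_obs + 1e-9
        ge += w >= w_obs - 1e-9
    return min(1.0, 2 * min(le, ge) / total)


class TestRankSumTest:
    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        cases = []
        for n1, n2 in [(3, 3), (4, 6), (5, 5), (8, 8), (3, 8)]:
            cases.append((rng.normal(size=n1), rng.normal(size=n2)))
            # tie-heavy case: integer-valued data
            cases.append((rng.integers(0, 3, n1).astype(float), rng.integers(0, 3, n2).astype(float)))
        for x, y in cases:
            assert exact_rank_sum_p(x, y) == pytest.approx(oracle_exact_p(x, y), abs=1e-10)

    def test_null_calibration_of_discoveries(self):
        # identical groups by construction: across 20 seeds the fraction of
        # genes reaching p_adj < 0.05 stays at or below 0.05
        frac = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            counts = rng.poisson(3.0, size=(60, 100)) + 1
            cells = make_cells(
                counts, clusters=["A"] * 30 + ["B"] * 30, normalized=True
            )
            res = rp.find_markers(cells, "A", "B", min_pct=0.0, min_diff_pct=0.0)
            frac.append(float((res["p_adj"] < 0.05).mean()) if len(res) else 0.0)
        assert np.mean(frac) <= 0.05

    def test_identical_groups_rarely_significant(self):
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            counts = rng.poisson(2.0, size=(40, 50)) + 1
            cells = make_cells(counts, clusters=["A"] * 20 + ["B"] * 20, normalized=True)
            res = rp.find_markers(cells, "A", "B", min_pct=0.0, min_diff_pct=0.0)
            if len(res) == 0 or (res["p_adj"] >= 0.05).all():
                ok += 1
        assert ok >= 9


class TestFindMarkers:
    def _planted_cells(self, seed=1):
        # gene 0: expressed in ~60% of A (mean 2) and ~5% of B
        rng = np.random.default_rng(seed)
        counts = rng.poisson(1.0, size=(40, 20))
        counts[:20, 0] = (rng.random(20) < 0.6) * rng.poisson(2.0, 20).clip(min=1)
        counts[20:, 0] = (rng.random(20) < 0.05) * 1
        counts[:, 1] += 1  # keep totals positive
        return make_cells(counts, clusters=["A"] * 20 + ["B"] * 20, normalized=True)

    def test_planted_difference_detected(self):
        cells = self._planted_cells()
        res = rp.find_markers(cells, "A", "B")
        row = res[res["gene_id"] == "g0"]
        assert len(row) == 1  # passed both filters and was tested
        assert row["p_adj"].iloc[0] < 0.05

    def test_min_diff_pct_filters_before_testing(self):
        counts = np.ones((40, 3), dtype=int)
        rng = np.random.default_rng(2)
        counts[:, 1] = rng.poisson(2.0, size=40)
        # gene 2: pct_a ~0.15, pct_b ~0.08 -> |diff| < 0.25, filtered out
        counts[:, 2] = 0
        counts[:3, 2] = 1   # 3/20 = 0.15 of A
        counts[20:22, 2] = 1  # 2/20 = 0.10 of B
        cells = make_cells(counts, clusters=["A"] * 20 + ["B"] * 20, normalized=True)
        res = rp.find_markers(cells, "A", "B")
        assert "g2" not in set(res["gene_id"])

    def test_bonferroni_over_post_filter_genes_only(self):
        cells = self._planted_cells()
        res = rp.find_markers(cells, "A", "B", min_pct=0.1, min_diff_pct=0.25)
        n_tested = len(res)
        np.testing.assert_allclose(
            res["p_adj"], np.minimum(1.0, res["p"] * n_tested), atol=1e-12
        )

    def test_small_group_errors(self):
        cells = make_cells(np.ones((4, 2), dtype=int), clusters=["A", "A", "B", "B"], normalized=True)
        with pytest.raises(ValidationError):
            rp.find_markers(cells, "A", "B")


class TestFindAllMarkers:
    def test_two_clusters_reduce_to_pairwise(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(2.0, size=(30, 15)) + 1
        counts[:15, 0] += 8
        cells = make_cells(counts, clusters=["A"] * 15 + ["B"] * 15, normalized=True)
        all_markers = rp.find_all_markers(cells, min_pct=0.0, min_diff_pct=0.0)
        direct = rp.find_markers(cells, "A", "B", min_pct=0.0, min_diff_pct=0.0, group_b_name="rest")
        lhs = all_markers["A"].sort_values("gene_id").reset_index(drop=True)
        rhs = direct.sort_values("gene_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(lhs, rhs)

    def test_planted_marker_ranks_first(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(1.0, size=(60, 25))
        counts[:, 3] += 1  # housekeeping gene keeps cell totals positive
        counts[:20, 7] = rng.poisson(10.0, size=20) + 1  # ~10x mean in cluster A
        cells = make_cells(counts, clusters=["A"] * 20 + ["B"] * 20 + ["C"] * 20, normalized=True)
        markers = rp.find_all_markers(cells, top_k=20)
        assert markers["A"].iloc[0]["gene_id"] == "g7"

    def test_top_k_bounds_rows(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(2.0, size=(40, 60)) + 1
        counts[:20, :30] += 4
        cells = make_cells(counts, clusters=["A"] * 20 + ["B"] * 20, normalized=True)
        markers = rp.find_all_markers(cells, min_pct=0.0, min_diff_pct=0.0, top_k=20)
        assert all(len(df) <= 20 for df in markers.values())


class TestRegionMarkers:
    def _cells(self, planted_types=4, seed=0):
        # 2 regions x 4 cell types, gene 0 planted high in region R1 for the
        # first `planted_types` cell types
        rng = np.random.default_rng(seed)
        n_per = 25
        regions, types, blocks = [], [], []
        for region in ("R1", "R2"):
            for ct in ("T1", "T2", "T3", "T4"):
                block = rng.poisson(1.0, size=(n_per, 30))
                block[:, 29] += 1  # housekeeping gene keeps totals positive
                if region == "R1" and int(ct[1]) <= planted_types:
                    block[:, 0] += 10
                blocks.append(block)
                regions += [region] * n_per
                types += [ct] * n_per
        counts = np.vstack(blocks)
        cells = make_cells(counts, clusters=types, normalized=True)
        return cells, np.array(regions, dtype=object), np.array(types, dtype=object)

    def test_gene_planted_in_all_types_is_region_marker(self):
        cells, regions, types = self._cells(planted_types=4)
        out = rp.region_specific_markers(cells, regions, types)
        assert "g0" in out["R1"]

    def test_gene_planted_in_three_of_four_types_is_not(self):
        cells, regions, types = self._cells(planted_types=3)
        out = rp.region_specific_markers(cells, regions, types)
        assert "g0" not in out["R1"]

    def test_null_yields_empty_sets(self):
        ok = 0
        for seed in range(10):
            cells, regions, types = self._cells(planted_types=0, seed=seed + 50)
            out = rp.region_specific_markers(cells, regions, types)
            if all(len(v) == 0 for v in out.values()):
                ok += 1
        assert ok >= 9

    def test_missing_stratum_requires_allow_partial(self):
        cells, regions, types = self._cells()
        types = types.copy()
        types[(regions == "R2") & (types == "T4")] = "T3"  # T4 absent from R2
        with pytest.raises(ValidationError):
            rp.region_specific_markers(cells, regions, types)
        with pytest.warns(UserWarning, match="skipped"):
            rp.region_specific_markers(cells, regions, types, allow_partial=True)


class TestAssignIdentity:
    def _cells(self, frac_expressing, umi_when_expressing):
        n = 100
        counts = np.ones((n, 3), dtype=int)  # gene 1,2 background
        counts[:, 0] = 0
        k = int(round(frac_expressing * n))
        counts[:k, 0] = umi_when_expressing
        return make_cells(counts, clusters=["c"] * n)

    def test_six_percent_expressing_assigned(self):
        out = rp.assign_identity(self._cells(0.06, 1), ["g0"])
        assert out["c"] is True

    def test_low_fraction_high_umi_assigned(self):
        out = rp.assign_identity(self._cells(0.04, 3), ["g0"])  # mean UMI 3 > 2
        assert out["c"] is True

    def test_both_clauses_fail_not_assigned(self):
        out = rp.assign_identity(self._cells(0.04, 1), ["g0"])
        assert out["c"] is False

    def test_boundaries_are_strict(self):
        assert rp.assign_identity(self._cells(0.05, 1), ["g0"])["c"] is False  # exactly 5%
        assert rp.assign_identity(self._cells(0.04, 2), ["g0"])["c"] is False  # exactly 2.0

    def test_empty_marker_set_errors(self):
        with pytest.raises(ValidationError):
            rp.assign_identity(self._cells(0.5, 2), [])


class TestRbpAnalysis:
    def _de(self, genes, p=0.001):
        return pd.DataFrame(
            {
                "gene_id": genes,
                "group_a": "x",
                "group_b": "y",
                "mean_log_diff": 1.0,
                "pct_a": 0.5,
                "pct_b": 0.1,
                "p": p,
                "p_adj": p,
            }
        )

    def _setup(self):
        catalog = rp.GeneCatalog(
            category={"r1": "RBP", "r2": "RBP", "r3": "RBP", "e1": "effector", "t1": "TF"}
        )
        assignment = rp.PatternAssignment(
            patterns={
                rp.PairKey("a", "b"): "divergent",
                rp.PairKey("c", "d"): "convergent",
                rp.PairKey("e", "f"): "divergent",
            },
            cluster_ids=list("abcdef"),
        )
        de = {
            rp.PairKey("a", "b"): self._de(["r1", "r2", "e1"]),
            rp.PairKey("c", "d"): self._de(["r2", "t1"]),
            rp.PairKey("e", "f"): self._de(["r3"]),
        }
        return catalog, assignment, de

    def test_pattern_specific_set_logic(self):
        catalog, assignment, de = self._setup()
        report = rp.pattern_specific_rbps(assignment, de, catalog)
        # r1 only in divergent pairs -> divergent-specific; r2 in both
        # convergent and divergent -> specific to neither
        assert report.pattern_specific["divergent"] == {"r1", "r3"}
        assert report.pattern_specific["convergent"] == set()
        assert "r2" not in set().union(*report.pattern_specific.values())

    def test_specific_sets_are_disjoint(self):
        catalog, assignment, de = self._setup()
        report = rp.pattern_specific_rbps(assignment, de, catalog)
        sets = list(report.pattern_specific.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])

    def test_missing_de_result_errors(self):
        catalog, assignment, de = self._setup()
        del de[rp.PairKey("e", "f")]
        with pytest.raises(ValidationError, match="without a DE result"):
            rp.pattern_specific_rbps(assignment, de, catalog)

    def test_reuse_fraction_counting(self):
        lists = {
            rp.PairKey("a", "b"): {"r1", "r2"},
            rp.PairKey("c", "d"): {"r1"},
        }
        out = rp.rbp_reuse_frequency(lists)
        assert out["fraction_reused"] == pytest.approx(0.5)
        disjoint = {rp.PairKey("a", "b"): {"r1"}, rp.PairKey("c", "d"): {"r2"}}
        assert rp.rbp_reuse_frequency(disjoint)["fraction_reused"] == 0.0

    def test_published_reuse_arithmetic(self):
        # 120 distinct RBPs of which 51 appear in >= 2 pairs -> 42.5%
        lists = {}
        for i in range(51):
            lists[rp.PairKey(f"a{i}", f"b{i}")] = {f"r{i}"}
            lists[rp.PairKey(f"c{i}", f"d{i}")] = {f"r{i}"}
        singles = {f"r{i}" for i in range(51, 120)}
        lists[rp.PairKey("x", "y")] = singles
        out = rp.rbp_reuse_frequency(lists)
        assert out["n_rbps_used"] == 120 and out["n_rbps_reused"] == 51
        assert out["fraction_reused"] == pytest.approx(0.425)


class TestTargetProportions:
    def _catalog(self):
        cats = {f"e{i}": "effector" for i in range(10)}
        cats.update({f"t{i}": "TF" for i in range(10)})
        cats.update({"r1": "RBP", "r2": "RBP", "r3": "RBP"})
        return rp.GeneCatalog(category=cats)

    def test_simple_proportion(self):
        rows = pd.DataFrame(
            {
                "rbp_gene_id": ["r1"] * 10,
                "target_gene_id": ["e0", "e1"] + [f"t{i}" for i in range(8)],
                "score": 0.9,
            }
        )
        out = rp.target_category_proportions(
            {"divergent": {"r1"}}, rp.RbpTargetTable(rows=rows), self._catalog()
        )
        assert out["divergent"]["effector"] == pytest.approx(0.20)

    def test_absent_rbps_flagged_undefined(self):
        rows = pd.DataFrame(
            {"rbp_gene_id": ["r1"], "target_gene_id": ["e0"], "score": 0.9}
        )
        with pytest.warns(UserWarning, match="absent"):
            out = rp.target_category_proportions(
                {"matched": {"r2"}}, rp.RbpTargetTable(rows=rows), self._catalog()
            )
        assert out["matched"] is None

    def test_published_comparison_direction(self):
        # effector-target proportions 5.0% / 3.8% / 7.6% for matched /
        # convergent / divergent: the comparison direction (divergent >
        # matched > convergent) is reproduced from constructed tables
        def rows_for(rbp, n_total, n_eff):
            targets = [f"e{i}" for i in range(n_eff)] + [
                f"t{i}" for i in range(n_total - n_eff)
            ]
            return pd.DataFrame(
                {
                    "rbp_gene_id": rbp,
                    "target_gene_id": targets,
                    "score": np.linspace(0.51, 0.99, n_total),
                }
            )

        cats = {f"e{i}": "effector" for i in range(100)}
        cats.update({f"t{i}": "TF" for i in range(1000)})
        cats.update({"r1": "RBP", "r2": "RBP", "r3": "RBP"})
        catalog = rp.GeneCatalog(category=cats)
        table = rp.RbpTargetTable(
            rows=pd.concat(
                [rows_for("r1", 1000, 50), rows_for("r2", 1000, 38), rows_for("r3", 1000, 76)]
            )
        )
        out = rp.target_category_proportions(
            {"matched": {"r1"}, "convergent": {"r2"}, "divergent": {"r3"}},
            table,
            catalog,
        )
        assert out["matched"]["effector"] == pytest.approx(0.050)
        assert out["convergent"]["effector"] == pytest.approx(0.038)
        assert out["divergent"]["effector"] == pytest.approx(0.076)
        assert out["divergent"]["effector"] > out["matched"]["effector"] > out["convergent"]["effector"]
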