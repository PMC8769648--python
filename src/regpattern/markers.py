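"""Differential expression with expression-fraction filters, identity rules,
and the pattern-specific RBP analysis.

Differential expression follows the standard droplet-data recipe: a gene is
testable between two groups only if it is detected (raw count > 0) in at
least ``min_pct`` of one group's cells AND the detection fractions differ by
at least ``min_diff_pct``; surviving genes are compared by a two-sided
Wilcoxon rank-sum test on the log-normalized layer with Bonferroni
correction over the genes actually tested. For tiny groups (both sides <= 8
cells) the exact rank-sum null distribution is enumerated; otherwise the
normal approximation with tie and continuity corrections is used.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .data_model import CellMatrix, GeneCatalog, PairKey, RbpTargetTable
from .errors import ValidationError
from .patterns import PATTERNS, PatternAssignment

DE_COLUMNS = ["gene_id", "group_a", "group_b", "mean_log_diff", "pct_a", "pct_b", "p", "p_adj"]

EXACT_MAX_GROUP = 8


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Wilcoxon rank-sum p-value by full enumeration.

    Handles ties through midranks. p = min(1, 2 * min(P(W <= w), P(W >= w)))
    where W is the rank sum of the first group under random assignment of the
    pooled values.
    """
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    total = 0
    le = ge = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def _resolve_group(cells: CellMatrix, group) -> np.ndarray:
    """Group spec -> boolean cell mask. Accepts a cluster label, a collection
    of labels, or a boolean mask."""
    if isinstance(group, str):
        return cells.cluster_labels == group
    group = np.asarray(group)
    if group.dtype == bool:
        if group.shape != (cells.n_cells,):
            raise ValidationError("boolean group mask has wrong length")
        return group
    labels = set(group.tolist())
    return np.array([lab in labels for lab in cells.cluster_labels])


def find_markers(
    cells: CellMatrix,
    group_a,
    group_b,
    min_pct: float = 0.1,
    min_diff_pct: float = 0.25,
    group_a_name: str | None = None,
    group_b_name: str | None = None,
) -> pd.DataFrame:
    """Differential expression between two cell groups.

    Returns one row per *tested* gene (those passing both detection filters),
    sorted by (p_adj ascending, |mean_log_diff| descending), with columns
    ``gene_id, group_a, group_b, mean_log_diff, pct_a, pct_b, p, p_adj``.
    ``mean_log_diff`` is the difference of group means on the normalized
    layer (group_a minus group_b). Bonferroni adjusts over the tested genes
    only.
    """
    if cells.normalized is None:
        raise ValidationError("normalized layer missing: call normalize() first")
    mask_a = _resolve_group(cells, group_a)
    mask_b = _resolve_group(cells, group_b)
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValidationError("each group needs at least 3 cells for the rank test")
    if np.any(mask_a & mask_b):
        raise ValidationError("groups overlap")
    name_a = group_a_name or (group_a if isinstance(group_a, str) else "group_a")
    name_b = group_b_name or (group_b if isinstance(group_b, str) else "group_b")

    counts_a, counts_b = cells.counts[mask_a], cells.counts[mask_b]
    pct_a = (counts_a > 0).mean(axis=0)
    pct_b = (counts_b > 0).mean(axis=0)
    testable = (np.maximum(pct_a, pct_b) >= min_pct) & (np.abs(pct_a - pct_b) >= min_diff_pct)
    idx = np.flatnonzero(testable)

    norm_a = cells.normalized[mask_a][:, idx]
    norm_b = cells.normalized[mask_b][:, idx]
    n1, n2 = norm_a.shape[0], norm_b.shape[0]
    if idx.size == 0:
        p = np.array([])
    elif n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP:
        p = np.array([exact_rank_sum_p(norm_a[:, g], norm_b[:, g]) for g in range(idx.size)])
    else:
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant genes -> sd 0 warnings
            res = mannwhitneyu(norm_a, norm_b, axis=0, alternative="two-sided", method="asymptotic")
        p = np.atleast_1d(np.nan_to_num(res.pvalue, nan=1.0))

    p_adj = np.minimum(1.0, p * idx.size)
    out = pd.DataFrame(
        {
            "gene_id": [cells.gene_ids[i] for i in idx],
            "group_a": name_a,
            "group_b": name_b,
            "mean_log_diff": norm_a.mean(axis=0) - norm_b.mean(axis=0) if idx.size else [],
            "pct_a": pct_a[idx],
            "pct_b": pct_b[idx],
            "p": p,
            "p_adj": p_adj,
        }
    )
    out["_absdiff"] = -out["mean_log_diff"].abs()
    out = out.sort_values(["p_adj", "_absdiff"], kind="stable").drop(columns="_absdiff")
    return out.reset_index(drop=True)


def find_all_markers(
    cells: CellMatrix,
    min_pct: float = 0.1,
    min_diff_pct: float = 0.25,
    top_k: int | None = None,
) -> dict[str, pd.DataFrame]:
    """One-vs-rest differential expression for every cluster.

    With ``top_k``, keeps at most k positively enriched genes per cluster
    (ranked by ascending p_adj, ties by descending mean_log_diff).
    """
    results: dict[str, pd.DataFrame] = {}
    for k in cells.cluster_ids():
        mask = cells.cluster_labels == k
        res = find_markers(
            cells, mask, ~mask, min_pct, min_diff_pct, group_a_name=k, group_b_name="rest"
        )
        if top_k is not None:
            res = res[res["mean_log_diff"] > 0].head(top_k).reset_index(drop=True)
        results[k] = res
    return results


def region_specific_markers(
    cells: CellMatrix,
    region_labels,
    celltype_labels,
    min_pct: float = 0.1,
    min_diff_pct: float = 0.25,
    alpha: float = 0.05,
    allow_partial: bool = False,
) -> dict[str, set[str]]:
    """Region markers shared by every cell type.

    Within each cell type, each region is tested one-vs-rest; a gene is a
    region-specific marker iff it is a significant (p_adj < alpha),
    positively enriched marker of that region in EVERY cell type (or every
    cell type present in the region, with ``allow_partial``).
    """
    region_labels = np.asarray(region_labels, dtype=object)
    celltype_labels = np.asarray(celltype_labels, dtype=object)
    if region_labels.shape != (cells.n_cells,) or celltype_labels.shape != (cells.n_cells,):
        raise ValidationError("label vectors must have one entry per cell")
    regions = sorted(set(region_labels.tolist()))
    celltypes = sorted(set(celltype_labels.tolist()))

    per_region: dict[str, set[str]] = {}
    for region in regions:
        marker_sets = []
        for ct in celltypes:
            ct_mask = celltype_labels == ct
            in_region = ct_mask & (region_labels == region)
            out_region = ct_mask & (region_labels != region)
            if in_region.sum() < 3 or out_region.sum() < 3:
                if allow_partial:
                    warnings.warn(
                        f"stratum (region={region}, cell type={ct}) too small; skipped",
                        stacklevel=2,
                    )
                    continue
                raise ValidationError(
                    f"cell type {ct!r} absent or too small in region {region!r}; "
                    "pass allow_partial=True to intersect over the remaining cell types"
                )
            res = find_markers(
                cells, in_region, out_region, min_pct, min_diff_pct,
                group_a_name=f"{region}", group_b_name="other-regions",
            )
            sig = res[(res["p_adj"] < alpha) & (res["mean_log_diff"] > 0)]
            marker_sets.append(set(sig["gene_id"]))
        per_region[region] = set.intersection(*marker_sets) if marker_sets else set()
    return per_region


def assign_identity(
    cells: CellMatrix,
    marker_genes,
    min_pct: float = 0.05,
    min_mean_umi: float = 2.0,
) -> dict[str, bool]:
    """Assign an identity to each cluster from a marker gene set.

    A cluster is assigned iff the fraction of its cells expressing any marker
    (raw count > 0) exceeds ``min_pct``, OR the mean marker UMI per
    marker-expressing cell exceeds ``min_mean_umi``. Both inequalities are
    strict ("over 5%", "over 2").
    """
    marker_genes = list(marker_genes)
    if not marker_genes:
        raise ValidationError("empty marker gene set")
    idx = cells.gene_index(marker_genes)
    out: dict[str, bool] = {}
    for k in cells.cluster_ids():
        sub = cells.counts[cells.cluster_labels == k][:, idx]
        expressing = sub.sum(axis=1) > 0
        frac = expressing.mean()
        mean_umi = sub[expressing].sum() / expressing.sum() if expressing.any() else 0.0
        out[k] = bool(frac > min_pct or mean_umi > min_mean_umi)
    return out


# --------------------------------------------------------------------------
# RBP analysis


@dataclass
class RbpPatternReport:
    """Pattern-specific RBPs, per-pair differential RBP lists, reuse counts."""

    pattern_specific: dict[str, set[str]]
    per_pair: dict[PairKey, set[str]]
    pattern_of_pair: dict[PairKey, str]
    reuse: dict[str, int] = field(default_factory=dict)

    def rbps_per_pair(self) -> dict[str, float | None]:
        """Mean number of differential RBPs per pair, by pattern."""
        out: dict[str, float | None] = {}
        for pat in PATTERNS:
            pairs = [p for p, v in self.pattern_of_pair.items() if v == pat]
            out[pat] = None if not pairs else float(np.mean([len(self.per_pair[p]) for p in pairs]))
        return out


def pattern_specific_rbps(
    assignment: PatternAssignment,
    de_results: dict[PairKey, pd.DataFrame],
    catalog: GeneCatalog,
    alpha: float = 0.05,
) -> RbpPatternReport:
    """Identify RBPs differential within pairs and exclusive to one pattern.

    A pair's differential RBPs are its significant DE genes (p_adj < alpha,
    after the detection filters) with catalog category RBP. An RBP is
    specific to pattern P iff it is differential in at least one pair of P
    and in no pair of any other pattern; the resulting sets are disjoint by
    construction.
    """
    rbp_genes = catalog.genes_in("RBP")
    missing = [p for p in assignment.patterns if p not in de_results]
    if missing:
        raise ValidationError(
            f"classified pairs without a DE result: {sorted(map(str, missing))[:5]}"
        )
    per_pair: dict[PairKey, set[str]] = {}
    for pair, pat in assignment.patterns.items():
        res = de_results[pair]
        sig = res[res["p_adj"] < alpha]
        per_pair[pair] = set(sig["gene_id"]) & rbp_genes

    used_by_pattern: dict[str, set[str]] = {pat: set() for pat in PATTERNS}
    for pair, pat in assignment.patterns.items():
        used_by_pattern[pat] |= per_pair[pair]
    specific = {
        pat: {
            r
            for r in used_by_pattern[pat]
            if all(r not in used_by_pattern[q] for q in PATTERNS if q != pat)
        }
        for pat in PATTERNS
    }
    reuse: dict[str, int] = {}
    for rbps in per_pair.values():
        for r in rbps:
            reuse[r] = reuse.get(r, 0) + 1
    return RbpPatternReport(
        pattern_specific=specific,
        per_pair=per_pair,
        pattern_of_pair=dict(assignment.patterns),
        reuse=reuse,
    )


def rbp_reuse_frequency(per_pair_rbps: dict[PairKey, set[str]]) -> dict:
    """Fraction of differential RBPs appearing in two or more pairs.

    Counting is joint over all pairs regardless of pattern.
    """
    counts: dict[str, int] = {}
    for rbps in per_pair_rbps.values():
        for r in rbps:
            counts[r] = counts.get(r, 0) + 1
    n_used = len(counts)
    n_reused = sum(1 for v in counts.values() if v >= 2)
    return {
        "n_rbps_used": n_used,
        "n_rbps_reused": n_reused,
        "fraction_reused": 0.0 if n_used == 0 else n_reused / n_used,
        "counts": counts,
    }


def target_category_proportions(
    rbp_sets_per_pattern: dict[str, set[str]],
    targets: RbpTargetTable,
    catalog: GeneCatalog,
) -> dict[str, dict[str, float] | None]:
    """Per-pattern proportions of target-gene categories among pooled
    binding-site rows of that pattern's RBPs.

    RBPs absent from the target table are excluded with a warning; a pattern
    whose RBPs have no rows at all gets ``None`` (undefined, not zero).
    """
    table_rbps = targets.rbps()
    out: dict[str, dict[str, float] | None] = {}
    for pat, rbps in rbp_sets_per_pattern.items():
        absent = set(rbps) - table_rbps
        if absent:
            warnings.warn(
                f"{len(absent)} {pat}-specific RBP(s) absent from the target table",
                stacklevel=2,
            )
        rows = targets.rows[targets.rows["rbp_gene_id"].isin(set(rbps) & table_rbps)]
        if rows.empty:
            out[pat] = None
            continue
        cats = rows["target_gene_id"].map(lambda g: catalog.category.get(g, "other"))
        out[pat] = (cats.value_counts() / len(rows)).to_dict()
    return out
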