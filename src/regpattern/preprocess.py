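"""QC, normalization, variable-gene selection, cluster profiles and distances.

The distance at the heart of the analysis is ``d(i, j) = (1 - r(i, j)) / 2``
where ``r`` is the Pearson correlation between two clusters' mean
log-normalized expression profiles over a chosen gene set (TF genes or
effector genes). It maps perfect correlation to 0 and perfect
anti-correlation to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import CellMatrix, ClusterMeanMatrix, GeneCatalog
from .errors import EmptyResultError, ValidationError


@dataclass
class QcReport:
    """Cells / genes removed per QC rule."""

    cells_low_umi: int = 0
    cells_low_ratio: int = 0
    cells_few_genes: int = 0
    cells_high_mito: int = 0
    genes_few_cells: int = 0
    genes_ubiquitous: int = 0
    n_cells_kept: int = 0
    n_genes_kept: int = 0


@dataclass
class PairwiseDistance:
    """Symmetric cluster x cluster distance matrix on the (1 - r)/2 scale."""

    d: np.ndarray
    cluster_ids: list[str]
    gene_set_tag: str = "custom"
    n_genes_used: int = 0

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.cluster_ids)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match cluster ids")
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("distances contain non-finite values")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix has a nonzero diagonal")
        if self.d.min() < -1e-12 or self.d.max() > 1 + 1e-12:
            raise ValidationError("distances must lie in [0, 1]")
        # clean up numerical fuzz so downstream rank logic sees exact values
        self.d = np.clip((self.d + self.d.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.d, 0.0)

    def value(self, a: str, b: str) -> float:
        i, j = self.cluster_ids.index(a), self.cluster_ids.index(b)
        return float(self.d[i, j])


def qc_filter(cells: CellMatrix, qc=None) -> tuple[CellMatrix, QcReport]:
    """Remove low-quality cells and uninformative genes.

    Cell rules (all strict inequalities): total UMI < ``min_umi``; UMI per
    detected gene < ``min_ratio_umi_per_gene``; detected genes <
    ``min_genes_per_cell``; mitochondrial fraction > ``max_mito_fraction``
    (mitochondrial genes identified by id prefix). Gene rules: detected in
    fewer than ``min_cells_per_gene`` cells or in more than
    ``max_cell_fraction_per_gene`` of all cells. Gene rules are evaluated on
    the surviving cells.
    """
    from .data_model import QcConfig

    qc = qc or QcConfig()
    counts = cells.counts
    report = QcReport()

    umi = counts.sum(axis=1)
    detected = (counts > 0).sum(axis=1)
    mito = np.array([g.startswith(qc.mito_prefix) for g in cells.gene_ids])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(detected > 0, umi / np.maximum(detected, 1), 0.0)
        mito_frac = np.where(umi > 0, counts[:, mito].sum(axis=1) / np.maximum(umi, 1), 0.0)

    low_umi = umi < qc.min_umi
    low_ratio = ratio < qc.min_ratio_umi_per_gene
    few_genes = detected < qc.min_genes_per_cell
    high_mito = mito_frac > qc.max_mito_fraction
    report.cells_low_umi = int(low_umi.sum())
    report.cells_low_ratio = int(low_ratio.sum())
    report.cells_few_genes = int(few_genes.sum())
    report.cells_high_mito = int(high_mito.sum())

    keep_cells = ~(low_umi | low_ratio | few_genes | high_mito)
    if not keep_cells.any():
        raise EmptyResultError("QC removed every cell")
    filtered = cells.subset_cells(keep_cells)

    cells_per_gene = (filtered.counts > 0).sum(axis=0)
    few = cells_per_gene < qc.min_cells_per_gene
    ubiquitous = cells_per_gene > qc.max_cell_fraction_per_gene * filtered.n_cells
    report.genes_few_cells = int(few.sum())
    report.genes_ubiquitous = int(ubiquitous.sum())
    keep_genes = ~(few | ubiquitous)
    if not keep_genes.any():
        raise EmptyResultError("QC removed every gene")
    filtered = filtered.subset_genes([g for g, k in zip(filtered.gene_ids, keep_genes) if k])

    report.n_cells_kept = filtered.n_cells
    report.n_genes_kept = filtered.n_genes
    return filtered, report


def normalize(cells: CellMatrix, scale: float = 10000.0) -> CellMatrix:
    """Attach the log-normalized layer: ln(1 + scale * count / cell_total)."""
    totals = cells.counts.sum(axis=1, keepdims=True).astype(float)
    if np.any(totals == 0):
        raise ValidationError("cells with zero total counts cannot be normalized")
    cells.normalized = np.log1p(scale * cells.counts / totals)
    return cells


def _require_normalized(cells: CellMatrix) -> np.ndarray:
    if cells.normalized is None:
        raise ValidationError("normalized layer missing: call normalize() first")
    return cells.normalized


def select_variable_genes(cells: CellMatrix, hvg=None) -> list[str]:
    """Dispersion-based highly-variable-gene selection.

    Per gene, the mean and dispersion are computed on the back-transformed
    scale (``expm1`` of the normalized layer): dispersion = log(variance /
    mean). Genes are binned by log1p(mean) into ``n_bins`` equal-count bins and
    the dispersion is robust-z-scored within each bin (median / MAD). Selected
    genes have back-transformed mean in (x_low, x_high) and dispersion z-score
    >= y_cutoff.
    """
    from .data_model import HvgConfig

    hvg = hvg or HvgConfig()
    expr = np.expm1(_require_normalized(cells))
    mean = expr.mean(axis=0)
    var = expr.var(axis=0, ddof=1) if cells.n_cells > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, np.log(np.maximum(var, 1e-300) / np.maximum(mean, 1e-300)), -np.inf)

    n_bins = hvg.n_bins
    n_genes = cells.n_genes
    if n_genes < n_bins:
        warnings.warn(
            f"fewer genes ({n_genes}) than bins ({n_bins}); reducing bin count",
            stacklevel=2,
        )
        n_bins = max(1, n_genes // 2)

    # equal-count bins over log1p(mean), as in dispersion-binning HVG selection
    order = np.argsort(np.log1p(mean), kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = np.floor(np.arange(n_genes) * n_bins / n_genes).astype(int)

    z = np.full(n_genes, -np.inf)
    for b in range(n_bins):
        members = np.flatnonzero(bin_of == b)
        disp = dispersion[members]
        finite = np.isfinite(disp)
        if not finite.any():
            continue
        med = np.median(disp[finite])
        mad = np.median(np.abs(disp[finite] - med))
        if mad == 0:
            z[members[finite]] = np.where(disp[finite] > med, np.inf, 0.0)
        else:
            z[members] = (disp - med) / (1.4826 * mad)

    selected = (mean > hvg.x_low) & (mean < hvg.x_high) & (z >= hvg.y_cutoff)
    return [g for g, s in zip(cells.gene_ids, selected) if s]


def cluster_means(cells: CellMatrix, genes=None) -> ClusterMeanMatrix:
    """Per-cluster arithmetic mean of log-normalized expression."""
    norm = _require_normalized(cells)
    if genes is not None:
        idx = cells.gene_index(genes)
        norm = norm[:, idx]
        gene_ids = list(genes)
    else:
        gene_ids = list(cells.gene_ids)
    cluster_ids = cells.cluster_ids()
    means = np.vstack(
        [norm[cells.cluster_labels == k].mean(axis=0) for k in cluster_ids]
    )
    return ClusterMeanMatrix(means=means, cluster_ids=cluster_ids, gene_ids=gene_ids)


def partition_genes(catalog: GeneCatalog, variable_genes) -> dict[str, set[str]]:
    """Intersect a variable-gene list with the TF / effector / RBP categories."""
    vset = set(variable_genes)
    unknown = vset - set(catalog.category)
    if unknown:
        raise ValidationError(f"variable genes missing from catalog: {sorted(unknown)[:10]}")
    parts = {cat: catalog.genes_in(cat) & vset for cat in ("TF", "effector", "RBP")}
    if not parts["TF"] or not parts["effector"]:
        raise EmptyResultError(
            "empty TF or effector gene set: downstream distances undefined"
        )
    return parts


def _pearson_rows(x: np.ndarray, cluster_ids) -> np.ndarray:
    """Pearson correlation between rows, erroring on zero-variance rows."""
    sd = x.std(axis=1, ddof=1)
    flat = [cluster_ids[i] for i in np.flatnonzero(sd == 0)]
    if flat:
        raise ValidationError(
            f"zero-variance profile(s) over this gene set: {flat} (correlation undefined)"
        )
    return np.corrcoef(x)


def profile_distance(
    means: ClusterMeanMatrix, genes=None, gene_set_tag: str = "custom"
) -> PairwiseDistance:
    """(1 - Pearson r)/2 between cluster mean profiles over a gene set."""
    if means.n_clusters < 2:
        raise ValidationError("need at least 2 clusters for a distance")
    sub = means if genes is None else means.subset_genes(sorted(genes))
    if len(sub.gene_ids) < 3:
        raise ValidationError("need at least 3 genes for a Pearson correlation")
    r = _pearson_rows(sub.means, sub.cluster_ids)
    d = (1.0 - r) / 2.0
    np.fill_diagonal(d, 0.0)
    return PairwiseDistance(
        d=d,
        cluster_ids=list(sub.cluster_ids),
        gene_set_tag=gene_set_tag,
        n_genes_used=len(sub.gene_ids),
    )


def subsampled_distance(
    means: ClusterMeanMatrix,
    genes,
    fraction: float = 0.8,
    reps: int = 20,
    seed: int = 0,
    gene_set_tag: str = "custom",
) -> PairwiseDistance:
    """Elementwise mean of (1 - r)/2 distances over random gene subsamples.

    Each rep draws ``floor(fraction * n_genes)`` genes without replacement;
    deterministic given ``seed``. With fraction = 1.0 this equals
    :func:`profile_distance` exactly.
    """
    genes = sorted(genes)
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must lie in (0, 1]")
    m = int(np.floor(fraction * len(genes)))
    if m < 3:
        raise ValidationError("subsample would keep fewer than 3 genes")
    if fraction == 1.0:
        return profile_distance(means, genes, gene_set_tag=gene_set_tag)
    rng = np.random.default_rng(seed)
    sub = means.subset_genes(genes)
    acc = np.zeros((sub.n_clusters, sub.n_clusters))
    for _ in range(reps):
        idx = rng.choice(len(genes), size=m, replace=False)
        r = _pearson_rows(sub.means[:, idx], sub.cluster_ids)
        acc += (1.0 - r) / 2.0
    d = acc / reps
    np.fill_diagonal(d, 0.0)
    return PairwiseDistance(
        d=d, cluster_ids=list(sub.cluster_ids), gene_set_tag=gene_set_tag, n_genes_used=m
    )
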