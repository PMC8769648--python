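"""NNLS cross-dataset cluster mapping, Jaccard cluster stability, and binary
combinatorial marking matrices.

NNLS decomposes each query cluster's marker-gene mean profile as a
non-negative mixture of reference cluster profiles (Lawson-Hanson active-set
solution); the coefficient magnitudes express cluster correspondence. Jaccard
stability re-clusters random 80% cell subsamples and scores each original
cluster by the maximum Jaccard index it achieves against any new cluster,
averaged over repetitions; clusters scoring below 0.6 are considered
unstable. Binary marking matrices record ON/OFF gene-by-cluster (expression
rule) or gene-by-morphology (labeling rule) calls for combinatorial-code
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .data_model import CellMatrix, ClusterMeanMatrix
from .errors import ConvergenceError, ValidationError


@dataclass
class NnlsResult:
    """Non-negative coefficients (query clusters x reference clusters)."""

    coefficients: pd.DataFrame
    residual_norm: pd.Series
    marker_genes: list[str]

    def best_match(self) -> dict[str, str]:
        """Reference cluster with the largest coefficient, per query."""
        return {q: self.coefficients.loc[q].idxmax() for q in self.coefficients.index}

    def row_normalized(self) -> pd.DataFrame:
        sums = self.coefficients.sum(axis=1)
        return self.coefficients.div(sums.where(sums > 0, 1.0), axis=0)


@dataclass
class BinaryMarkingMatrix:
    """Gene x (cluster | morphology subclass) ON/OFF matrix."""

    matrix: pd.DataFrame  # boolean
    rule_tag: str  # "expression" or "labeling"

    def __post_init__(self) -> None:
        if self.rule_tag not in ("expression", "labeling"):
            raise ValidationError(f"unknown rule_tag {self.rule_tag!r}")
        if not self.matrix.dtypes.map(lambda d: d == bool).all():
            raise ValidationError("marking matrix entries must be boolean")


@dataclass
class JaccardStability:
    """Per-cluster subsample-and-recluster stability."""

    mean: dict[str, float]
    median: dict[str, float]
    stable: dict[str, bool]
    reps: int
    fraction: float
    seed: int
    threshold: float


def nnls_solve(design: np.ndarray, response: np.ndarray) -> tuple[np.ndarray, float]:
    """argmin ||design @ x - response||^2 subject to x >= 0 (Lawson-Hanson)."""
    design = np.asarray(design, dtype=float)
    response = np.asarray(response, dtype=float)
    if design.ndim != 2 or design.shape[1] < 1:
        raise ValidationError("design must be 2-D with at least one column")
    if not (np.all(np.isfinite(design)) and np.all(np.isfinite(response))):
        raise ValidationError("NNLS inputs must be finite")
    try:
        x, rnorm = scipy.optimize.nnls(design, response)
    except RuntimeError as err:  # iteration budget exhausted
        raise ConvergenceError(f"NNLS did not converge: {err}") from err
    return x, float(rnorm)


def nnls_cluster_mapping(
    query: ClusterMeanMatrix,
    reference: ClusterMeanMatrix,
    reference_markers: dict[str, list[str]],
    k: int = 20,
) -> NnlsResult:
    """Decompose each query cluster against the reference cluster profiles.

    ``reference_markers`` gives each reference cluster's marker genes in rank
    order; the top ``k`` of each, intersected with the query's genes, are
    pooled into the decomposition panel. Each reference cluster must retain
    at least 3 markers after intersection.
    """
    query_genes = set(query.gene_ids)
    panel: list[str] = []
    for ref_cluster in reference.cluster_ids:
        markers = [g for g in reference_markers.get(ref_cluster, [])[:k] if g in query_genes]
        if len(markers) < 3:
            raise ValidationError(
                f"reference cluster {ref_cluster!r} keeps <3 of its top-{k} markers "
                "after intersecting with the query genes"
            )
        panel.extend(m for m in markers if m not in panel)
    if not panel:
        raise ValidationError("empty marker intersection")

    design = reference.subset_genes(panel).means.T  # genes x ref clusters
    q = query.subset_genes(panel).means  # query clusters x genes
    coef = np.zeros((query.n_clusters, reference.n_clusters))
    rnorm = np.zeros(query.n_clusters)
    for i in range(query.n_clusters):
        coef[i], rnorm[i] = nnls_solve(design, q[i])
    return NnlsResult(
        coefficients=pd.DataFrame(coef, index=query.cluster_ids, columns=reference.cluster_ids),
        residual_norm=pd.Series(rnorm, index=query.cluster_ids),
        marker_genes=panel,
    )


# --------------------------------------------------------------------------
# cluster stability


def jaccard_stability(
    cells: CellMatrix,
    clusterer,
    fraction: float = 0.8,
    reps: int = 20,
    seed: int = 0,
    threshold: float = 0.6,
) -> JaccardStability:
    """Subsample-and-recluster stability of the original clusters.

    Per rep: draw ``floor(fraction * n_cells)`` cells without replacement,
    re-cluster them with ``clusterer`` (any callable CellMatrix -> labels),
    and record for each original cluster the maximum Jaccard index between
    its subsampled members and any new cluster. A cluster is stable iff the
    mean over reps reaches the threshold (median also reported). Reps where
    an original cluster has no subsampled member are skipped for that
    cluster.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n_sub = int(np.floor(fraction * cells.n_cells))
    if n_sub < 1:
        raise ValidationError("subsample would be empty")
    original = cells.cluster_ids()
    scores: dict[str, list[float]] = {k: [] for k in original}

    for _ in range(reps):
        idx = rng.choice(cells.n_cells, size=n_sub, replace=False)
        sub = cells.subset_cells(idx)
        new_labels = np.asarray(clusterer(sub), dtype=object)
        if new_labels.shape != (n_sub,):
            raise ValidationError("clusterer must return one label per cell")
        if len(set(new_labels.tolist())) == 0:
            raise ValidationError("clusterer returned no clusters")
        new_groups = [new_labels == g for g in set(new_labels.tolist())]
        for k in original:
            members = sub.cluster_labels == k
            m = members.sum()
            if m == 0:
                continue
            best = max(
                float(np.sum(members & g)) / float(np.sum(members | g)) for g in new_groups
            )
            scores[k].append(best)

    mean = {k: float(np.mean(v)) if v else float("nan") for k, v in scores.items()}
    median = {k: float(np.median(v)) if v else float("nan") for k, v in scores.items()}
    stable = {k: bool(mean[k] >= threshold) for k in original}
    return JaccardStability(
        mean=mean, median=median, stable=stable, reps=reps, fraction=fraction,
        seed=seed, threshold=threshold,
    )


def make_kmeans_clusterer(n_clusters: int, n_pcs: int = 10, seed: int = 0):
    """Reference clusterer for stability checks: k-means on top principal
    components of the log-normalized matrix. A deliberately simple stand-in
    clustering procedure, not a product feature."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    def cluster(cells: CellMatrix) -> np.ndarray:
        from .preprocess import normalize

        data = cells.normalized
        if data is None:
            data = normalize(
                CellMatrix(
                    counts=cells.counts,
                    cell_ids=list(cells.cell_ids),
                    gene_ids=list(cells.gene_ids),
                    cluster_labels=cells.cluster_labels,
                )
            ).normalized
        comps = min(n_pcs, min(data.shape) - 1)
        pcs = PCA(n_components=comps, random_state=seed).fit_transform(data)
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(pcs)
        return km.labels_.astype(str)

    return cluster


# --------------------------------------------------------------------------
# binary combinatorial marking


def binary_marking_expression(
    cells: CellMatrix,
    genes,
    min_pct: float = 0.05,
    min_mean_umi: float = 2.0,
) -> BinaryMarkingMatrix:
    """Gene x cluster ON/OFF matrix from the expression rule.

    ON iff the fraction of the cluster's cells with raw count > 0 is >=
    ``min_pct``, OR the mean raw UMI over expressing cells is >=
    ``min_mean_umi``. Inclusive boundaries (the attainable-cutoff rule),
    unlike the strict identity-assignment rule.
    """
    genes = list(genes)
    idx = cells.gene_index(genes)
    clusters = cells.cluster_ids()
    data = {}
    for k in clusters:
        sub = cells.counts[cells.cluster_labels == k][:, idx]
        if sub.shape[0] == 0:
            raise ValidationError(f"cluster {k!r} is empty")
        expressing = sub > 0
        frac = expressing.mean(axis=0)
        with np.errstate(invalid="ignore"):
            mean_umi = np.where(
                expressing.any(axis=0),
                sub.sum(axis=0) / np.maximum(expressing.sum(axis=0), 1),
                0.0,
            )
        data[k] = (frac >= min_pct) | (mean_umi >= min_mean_umi)
    return BinaryMarkingMatrix(
        matrix=pd.DataFrame(data, index=genes).astype(bool), rule_tag="expression"
    )


def binary_marking_labeling(
    label_counts: pd.DataFrame,
    min_times: int = 4,
    min_fish: int = 4,
) -> BinaryMarkingMatrix:
    """Gene x morphology-subclass ON/OFF matrix from the labeling rule.

    ``label_counts`` has columns (gene, subclass, fish_id, count). ON iff the
    total labelings of (gene, subclass) are >= ``min_times`` AND come from >=
    ``min_fish`` distinct fish.
    """
    required = {"gene", "subclass", "fish_id", "count"}
    if not required.issubset(label_counts.columns):
        raise ValidationError(f"labeling table needs columns {sorted(required)}")
    if (label_counts["count"] < 0).any():
        raise ValidationError("labeling counts must be >= 0")
    pos = label_counts[label_counts["count"] > 0]
    totals = label_counts.groupby(["gene", "subclass"])["count"].sum()
    fish = pos.groupby(["gene", "subclass"])["fish_id"].nunique()
    genes = sorted(label_counts["gene"].unique())
    subclasses = sorted(label_counts["subclass"].unique())
    mat = pd.DataFrame(False, index=genes, columns=subclasses)
    for (g, s), tot in totals.items():
        n_fish = int(fish.get((g, s), 0))
        mat.loc[g, s] = bool(tot >= min_times and n_fish >= min_fish)
    return BinaryMarkingMatrix(matrix=mat.astype(bool), rule_tag="labeling")


def morphology_cluster_correspondence(
    tf_by_cluster: BinaryMarkingMatrix,
    tf_by_morph: BinaryMarkingMatrix,
    cutoff: float = 0.1,
) -> tuple[NnlsResult, pd.DataFrame]:
    """NNLS decomposition of each morphology column over the cluster columns.

    Returns the NNLS result (morphology subclasses as queries) and a boolean
    correspondence matrix: cluster corresponds to subclass iff its
    row-normalized coefficient exceeds ``cutoff``.
    """
    if list(tf_by_cluster.matrix.index) != list(tf_by_morph.matrix.index):
        raise ValidationError("the two marking matrices must share identical gene rows")
    design = tf_by_cluster.matrix.to_numpy(dtype=float)
    morph = tf_by_morph.matrix
    coef = np.zeros((morph.shape[1], design.shape[1]))
    rnorm = np.zeros(morph.shape[1])
    for i, col in enumerate(morph.columns):
        coef[i], rnorm[i] = nnls_solve(design, morph[col].to_numpy(dtype=float))
    result = NnlsResult(
        coefficients=pd.DataFrame(coef, index=list(morph.columns), columns=list(tf_by_cluster.matrix.columns)),
        residual_norm=pd.Series(rnorm, index=list(morph.columns)),
        marker_genes=list(tf_by_cluster.matrix.index),
    )
    correspondence = result.row_normalized() > cutoff
    return result, correspondence
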