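"""Core domain types and readers/writers for the external formats.

The package works on three in-memory containers:

``CellMatrix``
    cell x gene UMI counts with per-cell cluster labels and an optional
    log-normalized layer; the substrate for QC, differential expression,
    identity rules and stability analysis.
``GeneCatalog``
    gene -> regulatory category (TF / effector / RBP / other); drives the
    partitioning of expression profiles into the two regulatory views.
``ClusterMeanMatrix``
    cluster x gene mean log-normalized expression; the unit of all distance,
    tree and NNLS computations.

Matrices are accepted as Matrix Market sparse files (10x convention:
genes as rows, transposed on load) or dense CSV for small fixtures; tables
are TSV; trees are exported as newick; nested results as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

CATEGORIES = ("TF", "effector", "RBP", "other")


@dataclass(frozen=True)
class PairKey:
    """An unordered pair of cluster ids, stored in canonical sorted order."""

    a: str
    b: str

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValidationError(f"PairKey members must differ, got {self.a!r} twice")
        if self.a > self.b:
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    def __iter__(self):
        return iter((self.a, self.b))

    def __contains__(self, cluster_id: str) -> bool:
        return cluster_id == self.a or cluster_id == self.b

    def __str__(self) -> str:
        return f"{self.a}|{self.b}"

    @classmethod
    def parse(cls, text: str) -> "PairKey":
        a, b = text.split("|")
        return cls(a, b)


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for x in ids:
            (dups if x in seen else seen).add(x)
        raise ValidationError(f"duplicate {what}: {sorted(dups)[:5]}")
    return ids


@dataclass
class CellMatrix:
    """Cell x gene UMI counts with cluster labels and an optional normalized layer."""

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    cluster_labels: np.ndarray
    normalized: np.ndarray | None = None
    dataset_tag: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts contain non-finite values")
        if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
            raise ValidationError("counts must be non-negative integers")
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"cell axis mismatch: matrix has {n_cells} cells, "
                f"sidecar has {len(self.cell_ids)}"
            )
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"gene axis mismatch: matrix has {n_genes} genes, "
                f"sidecar has {len(self.gene_ids)}"
            )
        self.cluster_labels = np.asarray(self.cluster_labels, dtype=object)
        if self.cluster_labels.shape != (n_cells,):
            raise ValidationError("cluster_labels must have exactly one entry per cell")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)
            if self.normalized.shape != self.counts.shape:
                raise ValidationError("normalized layer must match counts shape")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def cluster_ids(self) -> list[str]:
        """Distinct cluster labels, sorted."""
        return sorted(set(self.cluster_labels.tolist()))

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:10]}")
        return np.array([pos[g] for g in genes], dtype=int)

    def subset_cells(self, mask: np.ndarray, tag: str | None = None) -> "CellMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return CellMatrix(
            counts=self.counts[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            cluster_labels=self.cluster_labels[idx],
            normalized=None if self.normalized is None else self.normalized[idx],
            dataset_tag=tag if tag is not None else self.dataset_tag,
        )

    def subset_genes(self, genes: Sequence[str]) -> "CellMatrix":
        idx = self.gene_index(genes)
        return CellMatrix(
            counts=self.counts[:, idx],
            cell_ids=list(self.cell_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
            cluster_labels=self.cluster_labels,
            normalized=None if self.normalized is None else self.normalized[:, idx],
            dataset_tag=self.dataset_tag,
        )


@dataclass
class GeneCatalog:
    """Gene -> regulatory category, with optional sub-annotations."""

    category: dict[str, str]
    effector_subcategory: dict[str, str] = field(default_factory=dict)
    rbp_function: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.category.items() if c not in CATEGORIES}
        if bad:
            raise ValidationError(f"unknown categories: {dict(list(bad.items())[:5])}")

    def genes_in(self, category: str) -> set[str]:
        if category not in CATEGORIES:
            raise ValidationError(f"unknown category {category!r}")
        return {g for g, c in self.category.items() if c == category}


@dataclass
class ClusterMeanMatrix:
    """Cluster x gene mean log-normalized expression."""

    means: np.ndarray
    cluster_ids: list[str]
    gene_ids: list[str]
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.means.ndim != 2:
            raise ValidationError("means must be 2-D (clusters x genes)")
        if not np.all(np.isfinite(self.means)):
            raise ValidationError("means contain non-finite values")
        if np.any(self.means < 0):
            raise ValidationError("means must be non-negative (log-normalized scale)")
        self.cluster_ids = _check_unique(self.cluster_ids, "cluster ids")
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        if self.means.shape != (len(self.cluster_ids), len(self.gene_ids)):
            raise FormatError("means shape does not match cluster/gene id lists")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise ValidationError(f"genes absent from cluster means: {missing[:10]}")
        return np.array([pos[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ClusterMeanMatrix":
        idx = self.gene_index(genes)
        return ClusterMeanMatrix(
            means=self.means[:, idx],
            cluster_ids=list(self.cluster_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
            meta=self.meta,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.means, index=self.cluster_ids, columns=self.gene_ids)


@dataclass
class RbpTargetTable:
    """Rows of (rbp_gene_id, target_gene_id, score). Score cutoffs are applied upstream."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"rbp_gene_id", "target_gene_id", "score"}
        if not required.issubset(self.rows.columns):
            raise FormatError(f"target table needs columns {sorted(required)}")
        if not np.all(np.isfinite(self.rows["score"].to_numpy(dtype=float))):
            raise ValidationError("target scores must be finite")
        dup = self.rows.duplicated(subset=["rbp_gene_id", "target_gene_id"])
        if dup.any():
            raise ValidationError("duplicate (rbp, target) pairs in target table")

    def rbps(self) -> set[str]:
        return set(self.rows["rbp_gene_id"].astype(str))


# --------------------------------------------------------------------------
# analysis configuration


@dataclass
class QcConfig:
    min_umi: int = 600
    min_ratio_umi_per_gene: float = 1.2
    min_cells_per_gene: int = 20
    max_cell_fraction_per_gene: float = 0.60
    min_genes_per_cell: int = 500
    max_mito_fraction: float = 0.05
    mito_prefix: str = "mt-"


@dataclass
class HvgConfig:
    n_bins: int = 300
    x_low: float = 0.0125
    x_high: float = 8.0
    y_cutoff: float = 0.5


@dataclass
class SimilarityConfig:
    q_low: float = 0.10
    q_high_top: float = 0.80
    mode: str = "conditional"  # or "global"

    def __post_init__(self) -> None:
        if not (0 < self.q_low <= 1 and 0 < self.q_high_top <= 1):
            raise ValidationError("similarity quantiles must lie in (0, 1]")
        if self.q_low > 1 - self.q_high_top + 1e-9:
            raise ValidationError(
                "similar and dissimilar zones overlap: need q_low <= 1 - q_high_top"
            )


@dataclass
class SubsampleConfig:
    fraction: float = 0.80
    reps: int = 20


@dataclass
class JaccardConfig:
    fraction: float = 0.80
    reps: int = 20
    stable_threshold: float = 0.6


@dataclass
class DeConfig:
    min_pct: float = 0.10
    min_diff_pct: float = 0.25
    alpha: float = 0.05


@dataclass
class IdentityConfig:
    min_pct_expressing: float = 0.05
    min_mean_umi_expressing: float = 2.0


@dataclass
class MorphologyRule:
    min_times: int = 4
    min_fish: int = 4


@dataclass
class AnalysisConfig:
    """All fixed constants of the analysis, with the published defaults."""

    qc: QcConfig = field(default_factory=QcConfig)
    hvg: HvgConfig = field(default_factory=HvgConfig)
    normalize_scale: float = 10000.0
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    subsample: SubsampleConfig = field(default_factory=SubsampleConfig)
    ward_cut_height: float = 0.42
    jaccard: JaccardConfig = field(default_factory=JaccardConfig)
    de: DeConfig = field(default_factory=DeConfig)
    identity: IdentityConfig = field(default_factory=IdentityConfig)
    nnls_top_k_markers: int = 20
    morphology_rule: MorphologyRule = field(default_factory=MorphologyRule)
    au_threshold: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in [
            ("subsample.fraction", self.subsample.fraction),
            ("jaccard.fraction", self.jaccard.fraction),
        ]:
            if not (0 < value <= 1):
                raise ValidationError(f"{name} must lie in (0, 1], got {value}")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AnalysisConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        raw = json.loads(text)
        return cls(
            qc=QcConfig(**raw.get("qc", {})),
            hvg=HvgConfig(**raw.get("hvg", {})),
            normalize_scale=raw.get("normalize_scale", 10000.0),
            similarity=SimilarityConfig(**raw.get("similarity", {})),
            subsample=SubsampleConfig(**raw.get("subsample", {})),
            ward_cut_height=raw.get("ward_cut_height", 0.42),
            jaccard=JaccardConfig(**raw.get("jaccard", {})),
            de=DeConfig(**raw.get("de", {})),
            identity=IdentityConfig(**raw.get("identity", {})),
            nnls_top_k_markers=raw.get("nnls_top_k_markers", 20),
            morphology_rule=MorphologyRule(**raw.get("morphology_rule", {})),
            au_threshold=raw.get("au_threshold", 0.9),
            seed=raw.get("seed", 0),
        )


# --------------------------------------------------------------------------
# readers


def read_cell_matrix(
    path_matrix: str | Path,
    path_genes: str | Path,
    path_cells: str | Path,
    orientation: str = "genes-rows",
    dataset_tag: str = "",
) -> CellMatrix:
    """Read a count matrix (.mtx or dense .csv) with gene/cell TSV sidecars.

    The cell sidecar must carry a ``cluster`` column holding the per-cell
    cluster label. ``orientation`` applies to Matrix Market input: the 10x
    convention stores genes as rows ("genes-rows", transposed on load);
    pass "cells-rows" for matrices already oriented cells x genes.
    """
    path_matrix = Path(path_matrix)
    genes = pd.read_csv(path_genes, sep="\t", dtype=str)
    cells = pd.read_csv(path_cells, sep="\t", dtype=str)
    if "gene_id" not in genes.columns:
        raise FormatError("gene sidecar needs a 'gene_id' column")
    if "cell_id" not in cells.columns or "cluster" not in cells.columns:
        raise FormatError("cell sidecar needs 'cell_id' and 'cluster' columns")

    if path_matrix.suffix == ".mtx":
        mat = scipy.io.mmread(path_matrix)
        mat = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        if orientation == "genes-rows":
            mat = mat.T
        elif orientation != "cells-rows":
            raise FormatError(f"unknown orientation {orientation!r}")
    else:
        mat = pd.read_csv(path_matrix, header=None).to_numpy()

    return CellMatrix(
        counts=np.asarray(mat),
        cell_ids=cells["cell_id"].tolist(),
        gene_ids=genes["gene_id"].tolist(),
        cluster_labels=cells["cluster"].to_numpy(dtype=object),
        dataset_tag=dataset_tag,
    )


def read_gene_catalog(path: str | Path) -> GeneCatalog:
    """Read a gene catalog TSV (columns: gene_id, category, optional sub-annotations).

    Unknown category strings are mapped to "other" with a warning; a gene listed
    twice with conflicting categories is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "category"}.issubset(df.columns):
        raise FormatError("catalog needs 'gene_id' and 'category' columns")
    category: dict[str, str] = {}
    for gene, cat in zip(df["gene_id"], df["category"]):
        if cat not in CATEGORIES:
            logger.warning("gene %s: unknown category %r mapped to 'other'", gene, cat)
            cat = "other"
        if gene in category and category[gene] != cat:
            raise ValidationError(
                f"gene {gene!r} listed with conflicting categories "
                f"{category[gene]!r} and {cat!r}"
            )
        category[gene] = cat
    sub = {}
    if "effector_subcategory" in df.columns:
        sub = {
            g: s
            for g, s in zip(df["gene_id"], df["effector_subcategory"])
            if isinstance(s, str) and s
        }
    rbp = {}
    if "rbp_function" in df.columns:
        rbp = {
            g: s
            for g, s in zip(df["gene_id"], df["rbp_function"])
            if isinstance(s, str) and s
        }
    return GeneCatalog(category=category, effector_subcategory=sub, rbp_function=rbp)


def read_rbp_targets(path: str | Path) -> RbpTargetTable:
    df = pd.read_csv(path, sep="\t", dtype={"rbp_gene_id": str, "target_gene_id": str})
    return RbpTargetTable(rows=df)


# --------------------------------------------------------------------------
# writers


def write_cell_matrix(cells: CellMatrix, out_dir: str | Path) -> None:
    """Write MTX (genes as rows, 10x convention) plus gene/cell TSV sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", scipy.sparse.coo_matrix(cells.counts.T))
    pd.DataFrame({"gene_id": cells.gene_ids}).to_csv(
        out / "genes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"cell_id": cells.cell_ids, "cluster": cells.cluster_labels}
    ).to_csv(out / "cells.tsv", sep="\t", index=False)


def write_results(obj, path: str | Path, format: str | None = None) -> None:
    """Write a result object to disk, dispatching on its type.

    Tables (DataFrames) become TSV with header; trees become newick with merge
    heights as branch lengths; objects with a ``to_json`` method (pattern
    assignments, configs) become JSON; mappings/sequences become JSON.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format is None:
        if isinstance(obj, pd.DataFrame):
            format = "tsv"
        elif hasattr(obj, "to_newick"):
            format = "newick"
        else:
            format = "json"
    if format == "tsv":
        obj.to_csv(path, sep="\t", index=isinstance(obj.index, pd.MultiIndex) or obj.index.name is not None)
    elif format == "newick":
        path.write_text(obj.to_newick() + "\n")
    elif format == "json":
        if hasattr(obj, "to_json"):
            path.write_text(obj.to_json())
        else:
            path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
    else:
        raise FormatError(f"unknown output format {format!r}")
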