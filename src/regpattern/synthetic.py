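"""Cluster-structured synthetic single-cell counts with planted pair patterns.

The generator emulates the statistical structure the pattern analysis
assumes: clusters of cells whose mean expression profiles over a
transcription-factor (TF) gene block and an effector gene block carry planted
correlations. A *matched* pair of clusters shares a latent profile over both
blocks; a *convergent* pair shares only the effector block; a *divergent*
pair shares only the TF block and additionally carries a fixed log-scale
offset on a designated subset of RBP genes, so divergent pairs have
recoverable differential RBP markers.

Latent construction: per gene block, every cluster's profile is

    z_k = sqrt(rho_bg) * b  +  sqrt(rho_sim - rho_bg) * s_pair  +  sqrt(1 - rho_sim) * e_k

with ``b`` a block-wide latent shared by all clusters, ``s_pair`` a latent
shared only by the two members of a planted pair on its correlated block(s),
and ``e_k`` cluster-private noise (the middle term is dropped, and the last
rescaled, for unplanted clusters). This yields pairwise latent correlations
of exactly ``rho_similar`` within planted pairs and ``rho_background``
otherwise. Profiles are mapped to the non-negative log-expression scale as
``softplus(mu_g + sigma * z_k)`` with per-gene baselines ``mu_g``; the
monotone transform attenuates the realized Pearson correlations slightly
below the latent targets.

Counts are negative binomial around each cluster's linear-scale profile,
scaled to a lognormal per-cell library size — the simplest observation model
matching UMI overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import CellMatrix, ClusterMeanMatrix, GeneCatalog, PairKey
from .errors import ValidationError
from .patterns import PATTERNS, PatternAssignment

DEFAULT_GENES_PER_CATEGORY = {"TF": 500, "effector": 500, "RBP": 100, "other": 100}


@dataclass
class SyntheticTruth:
    """Generator parameters plus the planted pair labels (the ground truth)."""

    n_clusters: int = 30
    genes_per_category: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENES_PER_CATEGORY)
    )
    planted_pairs: list[tuple[PairKey, str]] = field(default_factory=list)
    rho_similar: float = 0.95
    rho_background: float = 0.0
    cells_per_cluster: int = 200
    nb_dispersion: float = 2.0
    library_size_mean: float = 2000.0
    seed: int = 0
    # realism knobs (fixed study conditions, see docs/methods.md)
    gene_baseline_sigma: float = 0.5
    cluster_sigma: float = 1.2
    library_size_sigma: float = 0.3
    rbp_offset: float = 1.5
    n_rbp_diff: int = 10

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        if not (0 < self.rho_similar <= 1):
            raise ValidationError("rho_similar must lie in (0, 1]")
        if not (0 <= self.rho_background < self.rho_similar):
            raise ValidationError("need 0 <= rho_background < rho_similar")
        if 2 * len(self.planted_pairs) > self.n_clusters:
            raise ValidationError("more planted clusters than n_clusters")
        if self.rbp_offset < 1.0:
            raise ValidationError("divergent RBP offset must be >= 1.0 (log scale)")
        seen: set[str] = set()
        ids = set(self.cluster_ids())
        for pair, pattern in self.planted_pairs:
            if pattern not in PATTERNS:
                raise ValidationError(f"unknown planted pattern {pattern!r}")
            if pair.a in seen or pair.b in seen:
                raise ValidationError("planted pairs must be disjoint")
            if pair.a not in ids or pair.b not in ids:
                raise ValidationError(f"planted pair {pair} outside the cluster set")
            seen.update((pair.a, pair.b))

    def cluster_ids(self) -> list[str]:
        width = len(str(self.n_clusters))
        return [f"C{i + 1:0{width}d}" for i in range(self.n_clusters)]

    @classmethod
    def study(
        cls,
        seed: int = 0,
        n_clusters: int = 30,
        pairs_per_pattern: int = 3,
        **kwargs,
    ) -> "SyntheticTruth":
        """The standard study configuration: planted pairs of every pattern
        occupying the first clusters, in pattern order matched, convergent,
        divergent."""
        width = len(str(n_clusters))
        ids = [f"C{i + 1:0{width}d}" for i in range(n_clusters)]
        pairs = []
        k = 0
        for pattern in PATTERNS:
            for _ in range(pairs_per_pattern):
                pairs.append((PairKey(ids[k], ids[k + 1]), pattern))
                k += 2
        return cls(n_clusters=n_clusters, planted_pairs=pairs, seed=seed, **kwargs)


def _gene_ids(genes_per_category: dict[str, int]) -> tuple[list[str], dict[str, str]]:
    ids, category = [], {}
    for cat in ("TF", "effector", "RBP", "other"):
        n = genes_per_category.get(cat, 0)
        for i in range(n):
            g = f"{cat.lower()}_{i + 1:04d}"
            ids.append(g)
            category[g] = cat
    return ids, category


def _correlated_block(
    rng: np.random.Generator,
    n_clusters: int,
    n_genes: int,
    pair_rows: list[tuple[int, int]],
    rho_sim: float,
    rho_bg: float,
) -> np.ndarray:
    """Latent standard-normal block with the planted correlation structure."""
    b = rng.standard_normal(n_genes)
    e = rng.standard_normal((n_clusters, n_genes))
    z = np.sqrt(rho_bg) * b + np.sqrt(1.0 - rho_bg) * e
    for i, j in pair_rows:
        s = rng.standard_normal(n_genes)
        shared = np.sqrt(rho_bg) * b + np.sqrt(rho_sim - rho_bg) * s
        z[i] = shared + np.sqrt(1.0 - rho_sim) * e[i]
        z[j] = shared + np.sqrt(1.0 - rho_sim) * e[j]
    return z


def generate_cluster_means(truth: SyntheticTruth) -> tuple[ClusterMeanMatrix, GeneCatalog]:
    """Cluster x gene mean profiles (log-expression scale) with planted pairs.

    Pure function of ``truth`` (including its seed).
    """
    rng = np.random.default_rng(truth.seed)
    gene_ids, category = _gene_ids(truth.genes_per_category)
    catalog = GeneCatalog(category=category)
    cluster_ids = truth.cluster_ids()
    row = {c: i for i, c in enumerate(cluster_ids)}

    # which planted pairs are correlated on which block; the RBP and residual
    # blocks track terminal-feature (effector) similarity, so only divergent
    # pairs carry uncorrelated RBP profiles (plus their planted offsets)
    eff_like = [p for p, pat in truth.planted_pairs if pat in ("matched", "convergent")]
    corr_on = {
        "TF": [p for p, pat in truth.planted_pairs if pat in ("matched", "divergent")],
        "effector": eff_like,
        "RBP": eff_like,
        "other": eff_like,
    }

    blocks = []
    offsets = np.zeros((truth.n_clusters, len(gene_ids)))
    col0 = 0
    for cat in ("TF", "effector", "RBP", "other"):
        n_genes = truth.genes_per_category.get(cat, 0)
        if n_genes == 0:
            continue
        pair_rows = [(row[p.a], row[p.b]) for p in corr_on[cat]]
        z = _correlated_block(
            rng, truth.n_clusters, n_genes, pair_rows, truth.rho_similar, truth.rho_background
        )
        mu = rng.normal(0.0, truth.gene_baseline_sigma, size=n_genes)
        blocks.append(mu + truth.cluster_sigma * z)
        if cat == "RBP":
            divergent = [p for p, pat in truth.planted_pairs if pat == "divergent"]
            cursor = 0
            for p in divergent:
                take = min(truth.n_rbp_diff, n_genes)
                cols = [(cursor + t) % n_genes for t in range(take)]
                cursor += take
                for t, c in enumerate(cols):
                    # alternate the high side so neither cluster is globally brighter
                    up = p.a if t % 2 == 0 else p.b
                    offsets[row[up], col0 + c] += truth.rbp_offset
        col0 += n_genes

    log_expr = np.concatenate(blocks, axis=1) + offsets
    profiles = np.logaddexp(0.0, log_expr)  # softplus: smooth, positive
    means = ClusterMeanMatrix(means=profiles, cluster_ids=cluster_ids, gene_ids=gene_ids)
    return means, catalog


def divergent_rbp_genes(truth: SyntheticTruth) -> dict[PairKey, list[str]]:
    """The RBP genes carrying the planted offset for each divergent pair."""
    n_genes = truth.genes_per_category.get("RBP", 0)
    out: dict[PairKey, list[str]] = {}
    cursor = 0
    for p, pat in truth.planted_pairs:
        if pat != "divergent":
            continue
        take = min(truth.n_rbp_diff, n_genes)
        out[p] = [f"rbp_{(cursor + t) % n_genes + 1:04d}" for t in range(take)]
        cursor += take
    return out


def generate_counts(means: ClusterMeanMatrix, truth: SyntheticTruth) -> CellMatrix:
    """Negative-binomial UMI counts around the cluster profiles.

    Each cell draws a lognormal library size with mean
    ``library_size_mean``; its per-gene NB mean is the library size times the
    cluster's linear-scale profile (``expm1`` of the log-scale profile)
    normalized to proportions. ``nb_dispersion`` is the NB size parameter
    (variance = mu + mu^2 / size), so very large values approach Poisson.
    Deterministic given the truth's seed (a stream independent of the one used
    for the means).
    """
    if truth.nb_dispersion <= 0:
        raise ValidationError("nb_dispersion must be > 0")
    rng = np.random.default_rng([truth.seed, 1])
    cluster_ids = means.cluster_ids
    n_genes = len(means.gene_ids)
    intensity = np.expm1(means.means)
    props = intensity / intensity.sum(axis=1, keepdims=True)

    n_cells = truth.cells_per_cluster * len(cluster_ids)
    labels = np.repeat(cluster_ids, truth.cells_per_cluster)
    sigma = truth.library_size_sigma
    lib = rng.lognormal(
        mean=np.log(truth.library_size_mean) - sigma**2 / 2, sigma=sigma, size=n_cells
    )
    mu = lib[:, None] * np.repeat(props, truth.cells_per_cluster, axis=0)
    theta = truth.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(np.int64)

    cell_ids = [f"{lab}_cell{i % truth.cells_per_cluster + 1:04d}" for i, lab in enumerate(labels)]
    return CellMatrix(
        counts=counts,
        cell_ids=cell_ids,
        gene_ids=list(means.gene_ids),
        cluster_labels=np.asarray(labels, dtype=object),
        dataset_tag=f"synthetic(seed={truth.seed})",
    )


# --------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """Per-pattern precision/recall of planted-pair recovery."""

    precision: dict[str, float | None]
    recall: dict[str, float | None]
    overall_accuracy: float
    overall_precision: float | None
    n_planted: int
    n_recovered: int


def evaluate_recovery(predicted: PatternAssignment, truth: SyntheticTruth) -> RecoveryReport:
    """Score a pattern assignment against the planted truth.

    A planted pair counts as recovered iff the prediction assigns it the
    planted pattern. Precision counts every classified predicted pair against
    the planted set.
    """
    truth_ids = set(truth.cluster_ids())
    if not truth_ids.issubset(set(predicted.cluster_ids)):
        raise ValidationError(
            f"prediction does not cover the truth's clusters: "
            f"{sorted(truth_ids - set(predicted.cluster_ids))[:5]}"
        )
    planted = {pair: pat for pair, pat in truth.planted_pairs}
    precision: dict[str, float | None] = {}
    recall: dict[str, float | None] = {}
    for pat in PATTERNS:
        planted_p = {p for p, v in planted.items() if v == pat}
        predicted_p = predicted.pairs_with(pat)
        hits = len(planted_p & predicted_p)
        recall[pat] = None if not planted_p else hits / len(planted_p)
        precision[pat] = None if not predicted_p else hits / len(predicted_p)
    n_recovered = sum(
        1 for pair, pat in planted.items() if predicted.pattern_of(pair) == pat
    )
    n_classified = len(predicted.patterns)
    n_correct_classified = sum(
        1 for pair, pat in predicted.patterns.items() if planted.get(pair) == pat
    )
    return RecoveryReport(
        precision=precision,
        recall=recall,
        overall_accuracy=n_recovered / len(planted) if planted else 0.0,
        overall_precision=None if n_classified == 0 else n_correct_classified / n_classified,
        n_planted=len(planted),
        n_recovered=n_recovered,
    )
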