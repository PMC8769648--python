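"""Ward dendrograms, sister pairs, bootstrap clade support, tree discordance.

Agglomeration follows the classic Ward criterion applied directly to the
given dissimilarities (the "ward.D" Lance-Williams update on un-squared
inputs, as in R's hclust), not the squared-distance variant: the two differ
on non-Euclidean inputs such as the correlation distance used here.

Clade support is assessed by resampling genes with replacement, rebuilding
the tree, and counting how often each original clade reappears (bootstrap
proportion, BP). The multiscale variant resamples at a ladder of sample
sizes and extrapolates to the approximately-unbiased (AU) p-value via
Shimodaira's signed-distance / curvature fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm

from .data_model import ClusterMeanMatrix, PairKey
from .errors import ValidationError
from .preprocess import PairwiseDistance

PVCLUST_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


@dataclass
class Dendrogram:
    """Agglomerative tree: leaves plus an ordered list of merges.

    Node indexing follows the scipy convention: leaf ``i`` is node ``i``
    (``0 <= i < n``) and the ``k``-th merge creates internal node ``n + k``.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]
    gene_set_tag: str = "custom"

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValidationError(f"a tree on {n} leaves needs {n - 1} merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValidationError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def clades(self, include_root: bool = True) -> dict[int, frozenset[str]]:
        """Leaf set under each internal node, keyed by node index."""
        n = len(self.leaves)
        sets: dict[int, frozenset[str]] = {i: frozenset([x]) for i, x in enumerate(self.leaves)}
        for k, (a, b, _h) in enumerate(self.merges):
            sets[n + k] = sets[a] | sets[b]
        out = {i: s for i, s in sets.items() if i >= n}
        if not include_root and self.merges:
            out.pop(n + len(self.merges) - 1)
        return out

    def cherries(self) -> set[PairKey]:
        """Internal nodes whose two children are both leaves."""
        n = len(self.leaves)
        return {
            PairKey(self.leaves[a], self.leaves[b])
            for a, b, _h in self.merges
            if a < n and b < n
        }

    def node_height(self, node: int) -> float:
        n = len(self.leaves)
        return 0.0 if node < n else self.merges[node - n][2]

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        n = len(self.leaves)
        reps: dict[int, str] = {i: _quote(x) for i, x in enumerate(self.leaves)}
        for k, (a, b, h) in enumerate(self.merges):
            la = max(h - self.node_height(a), 0.0)
            lb = max(h - self.node_height(b), 0.0)
            reps[n + k] = f"({reps[a]}:{la:.10g},{reps[b]}:{lb:.10g})"
        return reps[n + len(self.merges) - 1] + ";"


def _quote(label: str) -> str:
    if any(c in label for c in "(),:; \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class SisterPairs:
    pairs: set[PairKey]
    source_tag: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.pairs:
            if p.a in seen or p.b in seen:
                raise ValidationError("sister pairs must be disjoint")
            seen.update((p.a, p.b))


@dataclass
class CladeSupport:
    """Per-clade bootstrap proportions and (optionally) AU p-values."""

    records: list[dict] = field(default_factory=list)
    n_boot: int = 0
    multiscale: bool = False

    def strongly_supported(self, au_threshold: float = 0.9) -> list[frozenset[str]]:
        """Clades whose AU p-value exceeds the threshold (strict)."""
        key = "au" if self.multiscale else "bp"
        return [r["clade"] for r in self.records if r[key] is not None and r[key] > au_threshold]

    def lookup(self, clade: frozenset[str]) -> dict | None:
        for r in self.records:
            if r["clade"] == clade:
                return r
        return None


# --------------------------------------------------------------------------
# ward.D agglomeration


def ward_tree(dist: PairwiseDistance, gene_set_tag: str | None = None) -> Dendrogram:
    """Agglomerate with the ward.D Lance-Williams update on the raw distances.

    Deterministic: among tied minimum distances the pair with the
    lexicographically smallest (representative-id, representative-id) wins,
    where a cluster's representative is its smallest leaf label.
    """
    ids = list(dist.cluster_ids)
    n = len(ids)
    if n < 2:
        raise ValidationError("need at least 2 clusters to build a tree")
    total = 2 * n - 1
    D = np.full((total, total), np.inf)
    D[:n, :n] = dist.d
    np.fill_diagonal(D, np.inf)
    size = np.ones(total, dtype=int)
    rep = list(ids) + [""] * (n - 1)  # representative = smallest leaf label
    active = np.zeros(total, dtype=bool)
    active[:n] = True
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        act = np.flatnonzero(active)
        sub = D[np.ix_(act, act)]
        h = sub.min()
        # tie-break: lexicographically smallest (rep_i, rep_j) pair
        ti, tj = np.nonzero(sub == h)
        cands = [(act[a], act[b]) for a, b in zip(ti, tj) if a < b]
        i, j = min(cands, key=lambda p: tuple(sorted((rep[p[0]], rep[p[1]]))))
        slot = n + step  # dendrogram node index of the new internal node
        ci, cj = (i, j) if rep[i] <= rep[j] else (j, i)
        merges.append((ci, cj, float(h)))

        # ward.D update against every other active cluster
        others = act[(act != i) & (act != j)]
        if others.size:
            t = size[i] + size[j] + size[others]
            newd = (
                (size[i] + size[others]) * D[i, others]
                + (size[j] + size[others]) * D[j, others]
                - size[others] * h
            ) / t
            D[slot, others] = newd
            D[others, slot] = newd
        active[[i, j]] = False
        active[slot] = True
        size[slot] = size[i] + size[j]
        rep[slot] = min(rep[i], rep[j])

    tag = gene_set_tag if gene_set_tag is not None else dist.gene_set_tag
    # ward.D heights may dip marginally under floating error; enforce monotone
    fixed, top = [], -np.inf
    for a, b, h in merges:
        top = max(top, h)
        fixed.append((a, b, top))
    return Dendrogram(leaves=ids, merges=fixed, gene_set_tag=tag)


def cut_tree(tree: Dendrogram, height: float) -> dict[str, int]:
    """Group labels after removing merges above the cut height.

    Groups are numbered 0, 1, ... in order of their smallest leaf label.
    """
    if height < 0:
        raise ValidationError("cut height must be >= 0")
    n = tree.n_leaves
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, h) in enumerate(tree.merges):
        if h <= height:
            node = n + k
            parent[find(a)] = find(node)
            parent[find(b)] = find(node)
    groups: dict[int, list[str]] = {}
    for i, leaf in enumerate(tree.leaves):
        groups.setdefault(find(i), []).append(leaf)
    ordered = sorted(groups.values(), key=lambda g: min(g))
    return {leaf: gi for gi, members in enumerate(ordered) for leaf in members}


def sister_pairs(tree: Dendrogram) -> SisterPairs:
    """The cherries of the tree: terminal sister-cluster pairs."""
    return SisterPairs(pairs=tree.cherries(), source_tag=tree.gene_set_tag)


# --------------------------------------------------------------------------
# bootstrap support


def _distance_on_genes(means: np.ndarray, idx: np.ndarray) -> np.ndarray:
    x = means[:, idx]
    sd = x.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[~np.isfinite(r)] = 0.0  # zero-variance resample rows: treat as uncorrelated
    if np.any(sd == 0):
        np.fill_diagonal(r, 1.0)
    d = np.clip((1.0 - r) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def bootstrap_support(
    means: ClusterMeanMatrix,
    genes,
    n_boot: int = 1000,
    seed: int = 0,
    multiscale: bool = False,
    gene_set_tag: str = "custom",
) -> CladeSupport:
    """Gene-resampling bootstrap proportions (and AU p-values) for tree clades.

    BP(node) is the fraction of trees built from gene resamples (with
    replacement) that contain the node's exact leaf set. With
    ``multiscale=True``, resampling is repeated at relative sample sizes
    r in {0.5, ..., 1.4} and AU = 1 - Phi(d - c) from the weighted
    least-squares fit z(r) = d*sqrt(r) + c/sqrt(r), z(r) = sqrt(r) *
    Phi^{-1}(1 - BP_r). Deterministic given the seed.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    genes = sorted(genes)
    sub = means.subset_genes(genes)
    n_genes = len(genes)
    base = ward_tree(
        PairwiseDistance(
            d=_distance_on_genes(sub.means, np.arange(n_genes)),
            cluster_ids=list(sub.cluster_ids),
            gene_set_tag=gene_set_tag,
            n_genes_used=n_genes,
        )
    )
    target_clades = list(base.clades(include_root=True).values())
    scales = PVCLUST_SCALES if multiscale else (1.0,)
    rng = np.random.default_rng(seed)

    bp_by_scale: dict[float, np.ndarray] = {}
    for r in scales:
        m = max(3, int(round(r * n_genes)))
        hits = np.zeros(len(target_clades))
        for _ in range(n_boot):
            idx = rng.integers(0, n_genes, size=m)
            d = _distance_on_genes(sub.means, idx)
            boot = ward_tree(
                PairwiseDistance(
                    d=d, cluster_ids=list(sub.cluster_ids), gene_set_tag=gene_set_tag
                )
            )
            got = set(boot.clades(include_root=True).values())
            hits += np.array([c in got for c in target_clades], dtype=float)
        bp_by_scale[r] = hits / n_boot

    records = []
    for ci, clade in enumerate(target_clades):
        bp1 = float(bp_by_scale[min(scales, key=lambda r: abs(r - 1.0))][ci])
        rec = {"clade": clade, "bp": bp1, "au": None, "degenerate": False}
        if multiscale:
            rec["au"], rec["degenerate"] = _au_fit(
                np.array([bp_by_scale[r][ci] for r in scales]), np.array(scales), n_boot
            )
        records.append(rec)
    return CladeSupport(records=records, n_boot=n_boot, multiscale=multiscale)


def _au_fit(bps: np.ndarray, scales: np.ndarray, n_boot: int) -> tuple[float, bool]:
    if np.all(bps >= 1.0):
        return 1.0, True
    if np.all(bps <= 0.0):
        return 0.0, True
    eps = 1.0 / (2.0 * n_boot)
    bp = np.clip(bps, eps, 1 - eps)
    z = np.sqrt(scales) * norm.ppf(1.0 - bp)
    # delta-method weights for the transformed proportions
    dens = norm.pdf(norm.ppf(1.0 - bp))
    var = scales * bp * (1.0 - bp) / (n_boot * dens**2)
    w = 1.0 / np.maximum(var, 1e-12)
    X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    WX = X * w[:, None]
    beta = np.linalg.solve(X.T @ WX, WX.T @ z)
    d_hat, c_hat = beta
    return float(1.0 - norm.cdf(d_hat - c_hat)), False


# --------------------------------------------------------------------------
# tree-to-tree discordance


@dataclass
class TreeComparison:
    distance: float
    matching_nodes: int
    matched_pairs: list[PairKey]
    metric: str


def _nonroot_clades(tree: Dendrogram) -> list[frozenset[str]]:
    return list(tree.clades(include_root=False).values())


def _bipartitions(tree: Dendrogram) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, canonicalized to the side without
    the smallest leaf."""
    all_leaves = frozenset(tree.leaves)
    anchor = min(tree.leaves)
    out = set()
    for clade in _nonroot_clades(tree):
        side = all_leaves - clade if anchor in clade else clade
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def _split_entropy(size_a: int, n: int) -> float:
    p = size_a / n
    q = 1.0 - p
    h = 0.0
    if p > 0:
        h -= p * np.log(p)
    if q > 0:
        h -= q * np.log(q)
    return h


def split_mutual_information(a: frozenset, b: frozenset, n: int) -> float:
    """Mutual information between two leaf bipartitions (natural log)."""
    n11 = len(a & b)
    n10 = len(a) - n11
    n01 = len(b) - n11
    n00 = n - n11 - n10 - n01
    mi = 0.0
    pa, pb = len(a) / n, len(b) / n
    for cnt, pr, pc in (
        (n11, pa, pb),
        (n10, pa, 1 - pb),
        (n01, 1 - pa, pb),
        (n00, 1 - pa, 1 - pb),
    ):
        if cnt > 0:
            p = cnt / n
            mi += p * np.log(p / (pr * pc))
    return max(mi, 0.0)


def tree_distance(t1: Dendrogram, t2: Dendrogram, metric: str = "cid") -> TreeComparison:
    """Topological discordance between two trees on the same leaf set.

    ``cid``: clustering-information distance — internal-node bipartitions of
    the two trees are matched one-to-one to maximize total shared (mutual)
    clustering information; distance = 1 - shared / mean(self-information).
    ``rf``: Robinson-Foulds on induced bipartitions, normalized by 2(n-3).

    Also reports matching nodes (internal nodes, root excluded, whose induced
    leaf sets are identical in both trees) and the cherries common to both.
    """
    s1, s2 = set(t1.leaves), set(t2.leaves)
    if s1 != s2:
        raise ValidationError(f"leaf sets differ: {sorted(s1 ^ s2)}")
    n = t1.n_leaves

    clades1, clades2 = _nonroot_clades(t1), _nonroot_clades(t2)
    matching = len(set(clades1) & set(clades2))
    matched_cherries = sorted(t1.cherries() & t2.cherries(), key=str)

    if metric == "rf":
        b1, b2 = _bipartitions(t1), _bipartitions(t2)
        denom = 2 * (n - 3)
        dist = 0.0 if denom <= 0 else min(1.0, len(b1 ^ b2) / denom)
    elif metric == "cid":
        if not clades1 and not clades2:
            dist = 0.0
        else:
            mi = np.zeros((len(clades1), len(clades2)))
            for i, a in enumerate(clades1):
                for j, b in enumerate(clades2):
                    mi[i, j] = split_mutual_information(a, b, n)
            k = max(mi.shape)
            padded = np.zeros((k, k))
            padded[: mi.shape[0], : mi.shape[1]] = mi
            rows, cols = linear_sum_assignment(-padded)
            shared = padded[rows, cols].sum()
            self1 = sum(_split_entropy(len(c), n) for c in clades1)
            self2 = sum(_split_entropy(len(c), n) for c in clades2)
            mean_self = 0.5 * (self1 + self2)
            dist = 1.0 if mean_self == 0 else float(np.clip(1.0 - shared / mean_self, 0.0, 1.0))
            if dist < 1e-12:  # identical topologies: snap floating fuzz to zero
                dist = 0.0
    else:
        raise ValidationError(f"unknown tree metric {metric!r}")

    return TreeComparison(
        distance=float(dist),
        matching_nodes=matching,
        matched_pairs=list(matched_cherries),
        metric=metric,
    )
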