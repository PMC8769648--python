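"""Population-level similarity calls and matched/convergent/divergent patterns.

A pair of clusters is judged twice, once on effector-gene profile distance
and once on TF profile distance:

* similar in both            -> **matched** (same terminal features, same TF program)
* similar in effector only   -> **convergent** (same terminal features from
  different TF programs)
* similar in TF only         -> **divergent** (same TF program, different
  terminal features)

"Similar" and "dissimilar" are population-level calls: a pair is similar when
its distance ranks within the lowest ``q_low`` fraction of a reference set of
distances, and dissimilar when it ranks inside the top ``q_high_top``
fraction. The default ("conditional") reference set for pair (i, j) is every
distance involving i or j, including d(i, j) itself; the "global" mode ranks
against all n(n-1)/2 distances. Ranks are ascending competition ranks with
ties sharing the minimum rank, so tied boundary distances are all included as
similar. Pairs falling between the two zones are "intermediate" and can never
support a pattern.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import PairKey
from .errors import ValidationError
from .hierarchy import SisterPairs
from .preprocess import PairwiseDistance, profile_distance, subsampled_distance

PATTERNS = ("matched", "convergent", "divergent")


@dataclass
class SimilarityCall:
    """Per-pair similar / dissimilar / intermediate call with rank provenance."""

    calls: dict[PairKey, str]
    ranks: dict[PairKey, tuple[int, int]]  # (competition rank, reference-set size)
    gene_set_tag: str = "custom"
    mode: str = "conditional"

    def pairs(self) -> set[PairKey]:
        return set(self.calls)


@dataclass
class PatternAssignment:
    """Pattern per unordered cluster pair, with provenance.

    ``patterns`` stores only classified pairs; any pair of ``cluster_ids`` not
    present is unclassified.
    """

    patterns: dict[PairKey, str]
    cluster_ids: list[str]
    provenance: str = "population"
    supporting: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {p: v for p, v in self.patterns.items() if v not in PATTERNS}
        if bad:
            raise ValidationError(f"unknown patterns: {bad}")
        universe = set(self.cluster_ids)
        for p in self.patterns:
            if p.a not in universe or p.b not in universe:
                raise ValidationError(f"pair {p} references unknown clusters")

    def pattern_of(self, pair: PairKey) -> str:
        return self.patterns.get(pair, "unclassified")

    def pairs_with(self, pattern: str) -> set[PairKey]:
        return {p for p, v in self.patterns.items() if v == pattern}

    def counts(self) -> dict[str, int]:
        return {pat: len(self.pairs_with(pat)) for pat in PATTERNS}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "provenance": self.provenance,
            "cluster_ids": list(self.cluster_ids),
            "patterns": {str(p): v for p, v in sorted(self.patterns.items(), key=lambda kv: str(kv[0]))},
            "supporting": self.supporting,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PatternAssignment":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        raw = json.loads(text)
        return cls(
            patterns={PairKey.parse(k): v for k, v in raw["patterns"].items()},
            cluster_ids=list(raw["cluster_ids"]),
            provenance=raw.get("provenance", "population"),
            supporting=raw.get("supporting", {}),
        )


# --------------------------------------------------------------------------


def _competition_rank(value: float, reference: np.ndarray) -> int:
    """Ascending competition rank (ties share the minimum rank); 1-based."""
    return 1 + int(np.sum(reference < value))


def similarity_calls(
    dist: PairwiseDistance,
    q_low: float = 0.10,
    q_high_top: float = 0.80,
    mode: str = "conditional",
    per_cluster_and: bool = False,
) -> SimilarityCall:
    """Call every cluster pair similar / dissimilar / intermediate.

    similar    iff rank(d) <= ceil(q_low * |S|)
    dissimilar iff rank(d) >  floor((1 - q_high_top) * |S|)  (and not similar)

    where S is the pair's reference distance set (see module docstring) and
    rank is the ascending competition rank of d(i, j) in S. With
    ``per_cluster_and=True`` (conditional mode only) the pair must satisfy the
    rank condition within each member cluster's own distance set separately.
    """
    if q_low > 1 - q_high_top + 1e-9:
        raise ValidationError("similar and dissimilar zones overlap")
    ids = dist.cluster_ids
    n = len(ids)
    if n < 4:
        raise ValidationError("need at least 4 clusters for population-level calls")

    tri = dist.d[np.triu_indices(n, k=1)]
    if np.allclose(tri, tri[0]):
        warnings.warn(
            "degenerate distance matrix: all pair distances tied; "
            "every pair will be called similar",
            stacklevel=2,
        )

    calls: dict[PairKey, str] = {}
    ranks: dict[PairKey, tuple[int, int]] = {}
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]

    if mode == "global":
        ref = np.array([dist.d[i, j] for i, j in all_pairs])
        size = len(ref)
        lo, hi = math.ceil(q_low * size), math.floor((1 - q_high_top) * size)
        for i, j in all_pairs:
            rank = _competition_rank(dist.d[i, j], ref)
            pair = PairKey(ids[i], ids[j])
            ranks[pair] = (rank, size)
            calls[pair] = "similar" if rank <= lo else ("dissimilar" if rank > hi else "intermediate")
    elif mode == "conditional":
        involving = {k: np.array([dist.d[a, b] for a, b in all_pairs if k in (a, b)]) for k in range(n)}
        for i, j in all_pairs:
            d_ij = dist.d[i, j]
            pair = PairKey(ids[i], ids[j])
            if per_cluster_and:
                size = n - 1
                lo, hi = math.ceil(q_low * size), math.floor((1 - q_high_top) * size)
                r_i = _competition_rank(d_ij, involving[i])
                r_j = _competition_rank(d_ij, involving[j])
                ranks[pair] = (max(r_i, r_j), size)
                if r_i <= lo and r_j <= lo:
                    calls[pair] = "similar"
                elif r_i > hi and r_j > hi:
                    calls[pair] = "dissimilar"
                else:
                    calls[pair] = "intermediate"
            else:
                # union of distances touching i or j; d(i,j) is a member of S.
                # The concatenation holds d(i,j) twice but the strict-minority
                # count is unaffected by the duplicate.
                ref = np.concatenate([involving[i], involving[j]])
                size = 2 * (n - 2) + 1
                lo, hi = math.ceil(q_low * size), math.floor((1 - q_high_top) * size)
                rank = 1 + int(np.sum(ref < d_ij))
                ranks[pair] = (rank, size)
                calls[pair] = (
                    "similar" if rank <= lo else ("dissimilar" if rank > hi else "intermediate")
                )
    else:
        raise ValidationError(f"unknown similarity mode {mode!r}")

    return SimilarityCall(calls=calls, ranks=ranks, gene_set_tag=dist.gene_set_tag, mode=mode)


def classify_patterns(
    eff_calls: SimilarityCall, tf_calls: SimilarityCall, cluster_ids=None
) -> PatternAssignment:
    """Combine effector-based and TF-based similarity calls into patterns.

    Any intermediate call on either side leaves the pair unclassified
    (conservative: an intermediate pair never supports a pattern).
    """
    if eff_calls.pairs() != tf_calls.pairs():
        missing = eff_calls.pairs() ^ tf_calls.pairs()
        raise ValidationError(f"call sets cover different pairs: {sorted(map(str, missing))[:5]}")
    if cluster_ids is None:
        cluster_ids = sorted({c for p in eff_calls.pairs() for c in p})
    patterns: dict[PairKey, str] = {}
    for pair in eff_calls.pairs():
        e, t = eff_calls.calls[pair], tf_calls.calls[pair]
        if e == "similar" and t == "similar":
            patterns[pair] = "matched"
        elif e == "similar" and t == "dissimilar":
            patterns[pair] = "convergent"
        elif e == "dissimilar" and t == "similar":
            patterns[pair] = "divergent"
    return PatternAssignment(
        patterns=patterns,
        cluster_ids=list(cluster_ids),
        provenance="population",
        supporting={
            "eff_mode": eff_calls.mode,
            "tf_mode": tf_calls.mode,
        },
    )


def sister_pattern_analysis(
    eff_sisters: SisterPairs, tf_sisters: SisterPairs, cluster_ids
) -> PatternAssignment:
    """Patterns from cherry membership: matched = cherry in both trees,
    convergent = effector-tree cherry only, divergent = TF-tree cherry only."""
    patterns: dict[PairKey, str] = {}
    for pair in eff_sisters.pairs | tf_sisters.pairs:
        in_eff, in_tf = pair in eff_sisters.pairs, pair in tf_sisters.pairs
        patterns[pair] = "matched" if (in_eff and in_tf) else ("convergent" if in_eff else "divergent")
    return PatternAssignment(
        patterns=patterns, cluster_ids=list(cluster_ids), provenance="sister"
    )


def intersect_patterns(
    population: PatternAssignment, sister: PatternAssignment
) -> PatternAssignment:
    """Keep a pair's pattern only when both strategies assign the same one."""
    if set(population.cluster_ids) != set(sister.cluster_ids):
        raise ValidationError("pattern assignments cover different cluster sets")
    patterns = {
        pair: pat
        for pair, pat in population.patterns.items()
        if sister.pattern_of(pair) == pat
    }
    return PatternAssignment(
        patterns=patterns,
        cluster_ids=list(population.cluster_ids),
        provenance="intersected",
        supporting={"population": population.counts(), "sister": sister.counts()},
    )


# --------------------------------------------------------------------------


@dataclass
class RobustnessReport:
    """Concordance between full-gene and gene-subsampled pattern calls."""

    concordance: dict[str, float | None]
    full: PatternAssignment
    subsampled: PatternAssignment
    fraction: float
    reps: int

    def all_concordant(self) -> bool:
        return all(v == 1.0 for v in self.concordance.values() if v is not None)


def _classify_from_distances(eff_dist, tf_dist, q_low, q_high_top, mode) -> PatternAssignment:
    eff = similarity_calls(eff_dist, q_low, q_high_top, mode)
    tf = similarity_calls(tf_dist, q_low, q_high_top, mode)
    return classify_patterns(eff, tf, cluster_ids=eff_dist.cluster_ids)


def robustness_check(
    means,
    effector_genes,
    tf_genes,
    fraction: float = 0.8,
    reps: int = 20,
    seed: int = 0,
    q_low: float = 0.10,
    q_high_top: float = 0.80,
    mode: str = "conditional",
    aggregate: str = "distances",
) -> RobustnessReport:
    """Re-derive patterns from 80%-gene subsamples and report concordance.

    ``aggregate="distances"`` (default) averages the subsampled distance
    matrices before calling patterns; ``aggregate="votes"`` classifies each
    rep separately and assigns a pattern only when it wins a strict majority
    of reps. Concordance for a pattern = fraction of the full run's pairs with
    that pattern that keep it in the subsampled run.
    """
    eff_full = profile_distance(means, effector_genes, gene_set_tag="effector")
    tf_full = profile_distance(means, tf_genes, gene_set_tag="TF")
    full = _classify_from_distances(eff_full, tf_full, q_low, q_high_top, mode)

    if aggregate == "distances":
        eff_sub = subsampled_distance(means, effector_genes, fraction, reps, seed, "effector")
        tf_sub = subsampled_distance(means, tf_genes, fraction, reps, seed + 1, "TF")
        sub = _classify_from_distances(eff_sub, tf_sub, q_low, q_high_top, mode)
    elif aggregate == "votes":
        votes: dict[PairKey, dict[str, int]] = {}
        for rep in range(reps):
            eff_r = subsampled_distance(means, effector_genes, fraction, 1, seed + 2 * rep, "effector")
            tf_r = subsampled_distance(means, tf_genes, fraction, 1, seed + 2 * rep + 1, "TF")
            rep_assign = _classify_from_distances(eff_r, tf_r, q_low, q_high_top, mode)
            for pair, pat in rep_assign.patterns.items():
                votes.setdefault(pair, {}).setdefault(pat, 0)
                votes[pair][pat] += 1
        patterns = {}
        for pair, tally in votes.items():
            pat, count = max(tally.items(), key=lambda kv: kv[1])
            if count > reps / 2:
                patterns[pair] = pat
        sub = PatternAssignment(
            patterns=patterns, cluster_ids=list(full.cluster_ids), provenance="population"
        )
    else:
        raise ValidationError(f"unknown aggregate {aggregate!r}")

    concordance: dict[str, float | None] = {}
    for pat in PATTERNS:
        full_pairs = full.pairs_with(pat)
        if not full_pairs:
            concordance[pat] = None
            continue
        kept = sum(1 for p in full_pairs if sub.pattern_of(p) == pat)
        concordance[pat] = kept / len(full_pairs)
    return RobustnessReport(
        concordance=concordance, full=full, subsampled=sub, fraction=fraction, reps=reps
    )
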