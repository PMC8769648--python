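#!/usr/bin/env python
"""Cross-dataset NNLS mapping, Jaccard cluster stability, binary marking.

Maps a resimulated (different observation noise) version of the study onto
the original cluster means by NNLS over top-20 markers, scores cluster
stability under 80% cell subsampling with the k-means reference clusterer,
and demonstrates the binary ON/OFF marking rules on a synthetic
gene-labeling table.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import regpattern as rp

SEED = 0
RESULTS = Path("results")


def main() -> None:
    # a compact version of the study keeps k-means reclustering quick
    truth = rp.SyntheticTruth.study(
        seed=SEED, n_clusters=8, pairs_per_pattern=1, cells_per_cluster=80,
        genes_per_category={"TF": 150, "effector": 150, "RBP": 40, "other": 40},
    )
    means_true, catalog = rp.generate_cluster_means(truth)
    cells = rp.normalize(rp.generate_counts(means_true, truth))
    means = rp.cluster_means(cells)

    # NNLS mapping of an independent count draw against the original clusters
    truth2 = rp.SyntheticTruth.study(
        seed=SEED + 1, n_clusters=8, pairs_per_pattern=1, cells_per_cluster=80,
        genes_per_category=dict(truth.genes_per_category),
    )
    query_cells = rp.normalize(rp.generate_counts(means_true, truth2))
    query_means = rp.cluster_means(query_cells)
    markers = {
        k: df["gene_id"].tolist()
        for k, df in rp.find_all_markers(cells, top_k=20).items()
    }
    mapping = rp.nnls_cluster_mapping(query_means, means, markers, k=20)
    correct = sum(1 for q, r in mapping.best_match().items() if q == r)
    print(f"NNLS mapping: {correct}/{len(means.cluster_ids)} clusters map to "
          f"their own counterpart (panel of {len(mapping.marker_genes)} markers)")

    stability = rp.jaccard_stability(
        cells, rp.make_kmeans_clusterer(8, n_pcs=10, seed=SEED),
        fraction=0.8, reps=10, seed=SEED,
    )
    n_stable = sum(stability.stable.values())
    print(f"Jaccard stability (k-means reference clusterer): "
          f"{n_stable}/{len(stability.stable)} clusters stable at the 0.6 cutoff; "
          f"mean index {np.mean(list(stability.mean.values())):.2f}")

    # binary marking: expression rule on TF genes, synthetic labeling table
    tf_genes = sorted(catalog.genes_in("TF"))[:6]
    by_cluster = rp.binary_marking_expression(cells, tf_genes)
    rng = np.random.default_rng(SEED)
    rows = []
    for g in tf_genes:
        for sub in ("I", "II", "III"):
            for fish in range(5):
                rows.append(
                    {"gene": g, "subclass": sub, "fish_id": f"f{fish}",
                     "count": int(rng.poisson(1.2))}
                )
    by_morph = rp.binary_marking_labeling(pd.DataFrame(rows))
    result, corr = rp.morphology_cluster_correspondence(
        rp.BinaryMarkingMatrix(matrix=by_cluster.matrix.loc[tf_genes], rule_tag="expression"),
        rp.BinaryMarkingMatrix(matrix=by_morph.matrix.loc[tf_genes], rule_tag="labeling"),
    )
    print(f"binary marking: {int(by_cluster.matrix.values.sum())} ON cells in the "
          f"TF x cluster matrix; {int(corr.values.sum())} cluster-morphology "
          f"correspondences above the 0.1 coefficient cutoff")

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "06_mapping_stability.json").write_text(
        json.dumps(
            {
                "nnls_self_mapping_correct": correct,
                "n_clusters": len(means.cluster_ids),
                "jaccard_mean": stability.mean,
                "jaccard_stable": stability.stable,
                "morphology_correspondences": int(corr.values.sum()),
            },
            indent=2,
        )
    )


if __name__ == "__main__":
    main()
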