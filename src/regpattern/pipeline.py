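"""End-to-end orchestration: counts -> QC -> profiles -> trees -> patterns -> RBPs.

``run_pipeline`` composes the full analysis from a single configuration and
seed: every stochastic stage draws its own seed derived from the top-level
seed and the stage name, so stages are independently reproducible and the
whole run is deterministic given (config, seed, inputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .data_model import AnalysisConfig, CellMatrix, GeneCatalog, RbpTargetTable, write_results
from .errors import RegpatternError
from .hierarchy import bootstrap_support, sister_pairs, tree_distance, ward_tree
from .markers import find_markers, pattern_specific_rbps, rbp_reuse_frequency, target_category_proportions
from .patterns import classify_patterns, intersect_patterns, robustness_check, similarity_calls, sister_pattern_analysis
from .preprocess import cluster_means, normalize, partition_genes, profile_distance, qc_filter, select_variable_genes, subsampled_distance

logger = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the top-level seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_hash: str
    version: str
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _hash_inputs(cells: CellMatrix, catalog: GeneCatalog) -> str:
    h = hashlib.sha256()
    h.update(cells.counts.tobytes())
    h.update("\n".join(cells.cell_ids).encode())
    h.update("\n".join(cells.gene_ids).encode())
    h.update("\n".join(map(str, cells.cluster_labels)).encode())
    h.update(json.dumps(sorted(catalog.category.items())).encode())
    return h.hexdigest()


def run_pipeline(
    config: AnalysisConfig,
    cells: CellMatrix,
    catalog: GeneCatalog,
    out_dir: str | Path | None = None,
    rbp_targets: RbpTargetTable | None = None,
    use_qc: bool = True,
    use_hvg: bool = True,
    n_boot: int = 0,
) -> tuple[dict, RunManifest]:
    """Run the dual-profile pattern analysis end to end.

    Stages: QC -> normalize -> variable genes -> cluster means -> gene
    partition -> full + subsampled distances -> ward trees (+ optional
    bootstrap support when ``n_boot`` > 0) -> sister pairs -> population
    similarity calls -> pattern classification -> intersection -> subsampling
    robustness -> per-pair differential expression -> RBP report. Results are
    returned as a dict and, when ``out_dir`` is given, written to disk.

    ``use_qc`` / ``use_hvg`` switch off cell-and-gene QC and variable-gene
    selection for inputs that are already filtered or where the gene panel is
    the analysis set itself.
    """
    manifest = RunManifest(
        config=json.loads(config.to_json()),
        seed=config.seed,
        input_hash=_hash_inputs(cells, catalog),
        version=__version__,
    )
    results: dict = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("stage: %s", name)
        manifest.stages.append(name)

    def emit(name: str, obj, fmt: str | None = None, suffix: str = "") -> None:
        if out is None:
            return
        path = out / f"{name}{suffix}"
        write_results(obj, path, fmt)
        manifest.outputs[name] = str(path)

    try:
        stage("qc")
        if use_qc:
            cells, qc_report = qc_filter(cells, config.qc)
            results["qc_report"] = qc_report
        stage("normalize")
        cells = normalize(cells, config.normalize_scale)

        stage("variable_genes")
        if use_hvg:
            variable = select_variable_genes(cells, config.hvg)
        else:
            variable = list(cells.gene_ids)
        results["variable_genes"] = variable

        stage("partition_genes")
        parts = partition_genes(catalog, variable)
        results["gene_partition"] = parts

        stage("cluster_means")
        means = cluster_means(cells)
        results["cluster_means"] = means

        stage("distances")
        eff_genes, tf_genes = sorted(parts["effector"]), sorted(parts["TF"])
        eff_dist = profile_distance(means, eff_genes, gene_set_tag="effector")
        tf_dist = profile_distance(means, tf_genes, gene_set_tag="TF")
        results["eff_dist"], results["tf_dist"] = eff_dist, tf_dist
        sub_seed = derive_seed(config.seed, "subsample")
        results["eff_dist_sub"] = subsampled_distance(
            means, eff_genes, config.subsample.fraction, config.subsample.reps, sub_seed, "effector"
        )
        results["tf_dist_sub"] = subsampled_distance(
            means, tf_genes, config.subsample.fraction, config.subsample.reps, sub_seed + 1, "TF"
        )

        stage("trees")
        eff_tree = ward_tree(eff_dist)
        tf_tree = ward_tree(tf_dist)
        results["eff_tree"], results["tf_tree"] = eff_tree, tf_tree
        results["tree_comparison"] = tree_distance(eff_tree, tf_tree, metric="cid")
        emit("eff_tree", eff_tree, "newick", ".nwk")
        emit("tf_tree", tf_tree, "newick", ".nwk")
        if n_boot > 0:
            stage("bootstrap")
            boot_seed = derive_seed(config.seed, "bootstrap")
            results["eff_support"] = bootstrap_support(
                means, eff_genes, n_boot=n_boot, seed=boot_seed, gene_set_tag="effector"
            )
            results["tf_support"] = bootstrap_support(
                means, tf_genes, n_boot=n_boot, seed=boot_seed + 1, gene_set_tag="TF"
            )

        stage("sister_pairs")
        eff_sisters, tf_sisters = sister_pairs(eff_tree), sister_pairs(tf_tree)
        results["eff_sisters"], results["tf_sisters"] = eff_sisters, tf_sisters
        sister_assign = sister_pattern_analysis(eff_sisters, tf_sisters, means.cluster_ids)
        results["sister_patterns"] = sister_assign

        stage("population_patterns")
        sim = config.similarity
        eff_calls = similarity_calls(eff_dist, sim.q_low, sim.q_high_top, sim.mode)
        tf_calls = similarity_calls(tf_dist, sim.q_low, sim.q_high_top, sim.mode)
        population = classify_patterns(eff_calls, tf_calls, cluster_ids=means.cluster_ids)
        results["population_patterns"] = population

        stage("intersection")
        intersected = intersect_patterns(population, sister_assign)
        results["intersected_patterns"] = intersected
        emit("population_patterns", population, "json", ".json")
        emit("sister_patterns", sister_assign, "json", ".json")
        emit("intersected_patterns", intersected, "json", ".json")

        stage("robustness")
        results["robustness"] = robustness_check(
            means, eff_genes, tf_genes,
            fraction=config.subsample.fraction, reps=config.subsample.reps,
            seed=derive_seed(config.seed, "robustness"),
            q_low=sim.q_low, q_high_top=sim.q_high_top, mode=sim.mode,
        )

        stage("pair_de")
        target_pairs = intersected.patterns if intersected.patterns else population.patterns
        de_results = {
            pair: find_markers(
                cells, pair.a, pair.b, config.de.min_pct, config.de.min_diff_pct
            )
            for pair in target_pairs
        }
        results["pair_de"] = de_results
        if out is not None:
            for pair, res in de_results.items():
                emit(f"de_{pair.a}_vs_{pair.b}", res, "tsv", ".tsv")

        stage("rbp_report")
        rbp_assignment = type(intersected)(
            patterns=dict(target_pairs),
            cluster_ids=list(intersected.cluster_ids),
            provenance=intersected.provenance if intersected.patterns else "population",
        )
        rbp_report = pattern_specific_rbps(rbp_assignment, de_results, catalog, config.de.alpha)
        results["rbp_report"] = rbp_report
        results["rbp_reuse"] = rbp_reuse_frequency(rbp_report.per_pair)
        if rbp_targets is not None:
            stage("rbp_targets")
            results["rbp_target_proportions"] = target_category_proportions(
                rbp_report.pattern_specific, rbp_targets, catalog
            )
    except RegpatternError as err:
        failed = manifest.stages[-1] if manifest.stages else "init"
        raise RegpatternError(
            f"pipeline aborted at stage {failed!r}: {err} "
            f"(completed: {manifest.stages[:-1]})"
        ) from err

    if out is not None:
        manifest.to_json(out / "manifest.json")
    return results, manifest
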