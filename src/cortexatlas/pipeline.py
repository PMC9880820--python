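"""End-to-end pipeline: merge -> normalize -> filter -> cluster -> signatures -> concordance.

Drives the whole analysis on a synthetic atlas (or pre-generated fixture
directory) with a single seed, writing every intermediate artifact plus a
machine-readable JSON report of counts, parameters and seeds so a run can
be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as _io
from .abundance import compute_ibaq, count_theoretical_peptides, tier_by_cumulative_mass
from .concordance import classify_all
from .consensus import consensus_cluster
from .isa import cluster_differential, isa_run, select_cluster_modules
from .itraq_merge import (
    batch_cv,
    compute_reference_ratios,
    median_normalize,
    merge_batches,
    variability_filter,
)
from .signatures import call_ba_signatures, derive_cutoff
from .synthetic_data import (
    AtlasConfig,
    feasible_category_plan,
    generate_proteome,
    generate_sequences,
    generate_transcriptome,
)
from .transcriptome import (
    call_gene_signatures,
    detection_filter,
    log2_counts,
    median_of_ratios,
    qc_filter,
    region_profile,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | Path = "atlas_run"
    atlas: AtlasConfig | None = None  # defaults to AtlasConfig(seed=seed)
    run_ibaq: bool = True
    run_transcriptome: bool = True
    min_log2_range: float = 1.0
    k_range: tuple[int, int] = (2, 10)
    n_resamples: int = 1000
    isa_n_seeds: int = 200
    isa_score_min: float = 0.7
    isa_coverage_min: float = 0.8
    ba_cutoff: float | None = None  # None -> derived from the data
    ba_max_regions: int = 2
    fc_threshold: float = 1.0
    magnitude_tolerance: float = 1.0
    mrna_noise_sd: float = 0.1


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages; return (and write) the run report."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas_cfg = config.atlas or AtlasConfig(seed=config.seed)
    report: dict = {
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k not in ("atlas", "out_dir")
        },
        "atlas_config": dataclasses.asdict(atlas_cfg),
        "stages": [],
    }

    # --- simulate
    tables, truth = generate_proteome(atlas_cfg)
    _io.write_truth_json(truth, out / "truth.json")
    report["stages"].append("simulate")

    # --- merge + normalize
    batch_tables = [
        compute_reference_ratios(
            t.intensities, t.channel_design, t.reference_region, t.batch_id, t.replicate_id
        )
        for t in tables
    ]
    merged = merge_batches(batch_tables)
    normalized = median_normalize(merged)
    _io.write_matrix_tsv(normalized.values, out / "normalized.tsv", index_name="protein_id")
    report["n_proteins_quantified"] = len(merged.protein_ids)
    report["median_cv_per_batch"] = batch_cv(batch_tables)
    report["stages"].append("merge")

    # --- variability filter
    var = variability_filter(normalized, config.min_log2_range)
    _io.write_matrix_tsv(var.retained.values, out / "variable.tsv", index_name="protein_id")
    report["n_variable_proteins"] = len(var.retained_ids)
    report["whisker_q3_iqr"] = var.whisker_q3_iqr
    report["stages"].append("variability_filter")

    # --- iBAQ tiers (on synthetic sequences + linear reference abundances)
    if config.run_ibaq:
        seqs = generate_sequences(
            atlas_cfg.n_proteins, seed=config.seed, protein_ids=list(truth.true_log2_matrix.index)
        )
        pep = pd.Series({p: count_theoretical_peptides(s) for p, s in seqs.items()})
        ref_ab = tables[0].intensities[
            [c for c, r in tables[0].channel_design.items() if r == atlas_cfg.reference_region][0]
        ].fillna(0.0)
        ibaq = compute_ibaq(ref_ab, pep)
        tiers = tier_by_cumulative_mass(ibaq.loc[ibaq["quantifiable"], "ibaq"])
        ibaq["tier"] = tiers.reindex(ibaq.index)
        ibaq.to_csv(out / "ibaq.tsv", sep="\t")
        report["tier_counts"] = tiers.value_counts().to_dict()
        report["stages"].append("ibaq")

    # --- consensus clustering (variable proteins)
    cons = consensus_cluster(
        var.retained,
        k_range=range(config.k_range[0], config.k_range[1] + 1),
        n_resamples=config.n_resamples,
        seed=config.seed + 1,
    )
    cons.assignment.rename("cluster").to_csv(out / "clusters.tsv", sep="\t")
    report["chosen_k"] = cons.chosen_k
    report["k_selection_warning"] = cons.k_warning
    report["mean_silhouette"] = cons.silhouette_mean[cons.chosen_k]
    report["delta_area"] = {str(k): v for k, v in cons.delta_area.items()}
    report["stages"].append("consensus_clustering")

    # --- ISA cluster signatures
    modules = isa_run(var.retained, n_seeds=config.isa_n_seeds, seed=config.seed + 2)
    cluster_sig = select_cluster_modules(
        modules,
        cons.assignment,
        coverage_min=config.isa_coverage_min,
        score_min=config.isa_score_min,
    )
    _write_signature_tsv(cluster_sig, out / "cluster_signatures.tsv", "cluster_id")
    report["n_isa_modules"] = len(modules)
    report["n_cluster_signature_proteins"] = len(cluster_sig.all_proteins)
    report["stages"].append("isa_signatures")

    # --- BA signatures
    spec = derive_cutoff(normalized)
    cutoff = config.ba_cutoff if config.ba_cutoff is not None else spec.derived_cutoff
    ba_sig = call_ba_signatures(normalized, cutoff=cutoff, max_regions=config.ba_max_regions)
    _write_signature_tsv(ba_sig, out / "ba_signatures.tsv", "region")
    report["cutoff_spec"] = dataclasses.asdict(spec)
    report["ba_cutoff_used"] = cutoff
    report["n_ba_signature_proteins"] = len(ba_sig.all_proteins)
    report["stages"].append("ba_signatures")

    # --- transcriptome + concordance
    if config.run_transcriptome:
        counts, meta, lengths = generate_transcriptome(
            truth,
            plan=feasible_category_plan(truth),
            seed=config.seed + 3,
            noise_sd=config.mrna_noise_sd,
        )
        qc = qc_filter(meta)
        kept_samples = list(qc.passing["sample_id"])
        detected = detection_filter(counts[kept_samples])
        sf, norm_counts = median_of_ratios(detected)
        log2m = log2_counts(norm_counts)
        profile = region_profile(log2m, qc.passing)
        _io.write_matrix_tsv(profile, out / "rna_region_log2.tsv", index_name="gene_id")
        gene_sig = call_gene_signatures(profile, cutoff=cutoff, max_regions=config.ba_max_regions)
        report["n_rna_samples_passing_qc"] = len(kept_samples)
        report["n_genes_detected"] = len(detected)
        report["n_ba_signature_genes"] = len(gene_sig.all_proteins)
        report["stages"].append("transcriptome")

        conc = classify_all(
            normalized,
            profile,
            fc_threshold=config.fc_threshold,
            magnitude_tolerance=config.magnitude_tolerance,
        )
        conc.pair_proportions.to_csv(out / "concordance_pairs.tsv", sep="\t")
        conc.mean_proportions.rename("proportion").to_csv(out / "concordance_mean.tsv", sep="\t")
        report["concordance_mean_proportions"] = conc.mean_proportions.to_dict()
        report["stages"].append("concordance")
    else:
        logger.info("transcriptome stage disabled; skipping concordance")
        report["skipped"] = ["transcriptome", "concordance"]

    report["runtime_s"] = round(time.time() - t0, 2)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _write_signature_tsv(sig, path: Path, key_name: str) -> None:
    rows = [
        {key_name: k, "protein_id": p}
        for k, members in sorted(sig.assignments.items(), key=lambda kv: str(kv[0]))
        for p in sorted(members)
    ]
    pd.DataFrame(rows, columns=[key_name, "protein_id"]).to_csv(path, sep="\t", index=False)
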