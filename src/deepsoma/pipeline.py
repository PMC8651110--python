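"""End-to-end orchestration: simulate, tabulate noise, filter, report.

This module glues the stages into the sequence a full analysis runs:
synthetic cohort -> per-sample germline calls and cohort germline mask ->
per-sample 192-cell noise models -> filter cascade -> spectrum-calibrated
binomial threshold -> consequence/enrichment/burden/clone-model reports.
The same function backs the `deepsoma run-all` subcommand and keeps all
randomness under one seed so repeated runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clonemodel, cohort as cohort_stats, enrich
from .calls import VariantCall, nonsynonymous, passing, select_consequence
from .config import PipelineConfig
from .filters import (
    apply_filters,
    attrition_table,
    calibrate_sensitivity,
    classify_consequence_summary,
    collect_germline_calls,
    germline_mask_from_calls,
    rethreshold_binomial,
    summary_frame,
)
from .io import write_annotations, write_report, write_variant_calls
from .noise import ContextNoiseModel, GermlineMask, tabulate_noise
from .panel import Panel, read_panel, write_panel_bed, write_subjects
from .simulate import Cohort, CohortCloneSpec, NoiseProfile, make_panel, simulate_cohort


@dataclass
class PipelineResult:
    cohort: Cohort
    noise_models: dict[str, ContextNoiseModel]
    cohort_germline: GermlineMask
    calibrated_alpha: float
    filtered_calls: list[VariantCall]
    pass_calls: list[VariantCall]
    burdens: pd.DataFrame
    enrichment_nonsyn: pd.DataFrame
    enrichment_syn: pd.DataFrame
    tables: dict[str, pd.DataFrame]


def _build_panel(config: PipelineConfig, seed: int) -> Panel:
    if config.panel_bed:
        return read_panel(config.panel_bed)
    return make_panel(
        config.panel_n_genes, config.mean_gene_length, seed=seed
    )


def run_pipeline(config: PipelineConfig | None = None, seed: int | None = None) -> PipelineResult:
    """Run the whole analysis on a simulated cohort; see module docstring."""
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed

    panel = _build_panel(config, seed)
    cohort = simulate_cohort(
        panel,
        config.n_cases,
        config.n_controls,
        depth_range=(config.depth_lo, config.depth_hi),
        clone_spec=CohortCloneSpec(
            burden_slope=config.burden_slope, vaf_min=config.vaf_min, vaf_max=config.vaf_max
        ),
        noise=NoiseProfile.with_cpg_ct(
            base_rate=config.noise_base_rate, multiplier=config.cpg_ct_multiplier
        ),
        seed=seed,
        cpg_fraction=config.cpg_fraction,
        pop_site_density=config.pop_site_density,
        candidate_min_alt=config.candidate_min_alt,
        expressed_fraction=config.expressed_fraction,
        include_germline_in_candidates=config.include_germline_in_candidates,
    )

    # germline calls drive both the cohort mask and the calibration spectrum
    germline_calls: list[VariantCall] = []
    noise_models: dict[str, ContextNoiseModel] = {}
    per_sample_masks = []
    for s in cohort.subjects:
        sc = cohort.site_counts[s.subject_id]
        g = collect_germline_calls(sc, s.subject_id, vaf_low=config.thresholds.germline_vaf_low)
        germline_calls.extend(g)
        per_sample_masks.append(germline_mask_from_calls(g))
    cohort_germline = GermlineMask.union(per_sample_masks)
    for s in cohort.subjects:
        noise_models[s.subject_id] = tabulate_noise(
            cohort.site_counts[s.subject_id], mask=cohort_germline, sample_id=s.subject_id
        )
    noise_arg: ContextNoiseModel | dict[str, ContextNoiseModel]
    if config.pooled_noise:
        noise_arg = ContextNoiseModel.pool(list(noise_models.values()))
    else:
        noise_arg = noise_models

    calls = cohort.all_candidates()
    apply_filters(
        calls,
        cohort.site_counts,
        noise_arg,
        cohort_germline=cohort_germline,
        expressed_genes=cohort.expressed_genes,
        thresholds=config.thresholds,
    )
    alpha = config.thresholds.binomial_alpha
    if config.calibrate:
        alpha = calibrate_sensitivity(calls, germline_calls, config.alpha_grid)
        rethreshold_binomial(calls, alpha, config.thresholds)
    pass_calls = passing(calls)

    nonsyn_expr = [c for c in nonsynonymous(pass_calls) if c.expressed_in_cd8]
    syn_expr = [
        c for c in select_consequence(pass_calls, "synonymous_SNV") if c.expressed_in_cd8
    ]
    burdens = cohort_stats.burden_table(pass_calls, cohort.subjects)
    enrichment_nonsyn = enrich.enrichment_table(nonsyn_expr, panel, cohort.subjects)
    enrichment_syn = enrich.enrichment_table(syn_expr, panel, cohort.subjects)

    stats_rows = [("calibrated_binomial_alpha", alpha)]
    try:
        stats_rows.append(
            ("p_group_nonsyn_expressed", cohort_stats.group_compare(burdens, "n_nonsyn_expressed"))
        )
        stats_rows.append(("p_group_syn", cohort_stats.group_compare(burdens, "n_syn_expressed")))
        stats_rows.append(("p_sex_nonsyn", cohort_stats.sex_compare(burdens, "n_nonsyn_expressed")))
    except ValueError:
        pass
    try:
        tau, p = cohort_stats.age_burden_association(burdens)
        stats_rows += [("age_burden_tau", tau), ("age_burden_p", p)]
    except ValueError:
        pass
    tau, p = cohort_stats.depth_count_association(burdens)
    stats_rows += [("depth_count_tau", tau), ("depth_count_p", p)]
    try:
        my, mo, p = cohort_stats.vaf_age_compare(burdens)
        stats_rows += [("vaf_mean_young", my), ("vaf_mean_old", mo), ("vaf_age_p", p)]
    except ValueError:
        pass

    mean_reads = (
        float(np.mean([c.alt_count for c in pass_calls])) if pass_calls else 19.3
    )
    params = clonemodel.CloneModelParams(
        median_depth=float(np.median([s.median_depth for s in cohort.subjects])),
        mean_variant_reads=mean_reads,
        genome_burden=clonemodel.genome_burden_at_age(
            float(np.mean([s.age for s in cohort.subjects]))
        ),
    )
    deriv = clonemodel.derivation(params)
    clone_rows = [(k, v["value"], v["exact"]) for k, v in deriv.items()]

    tables = {
        "attrition": attrition_table(calls).set_index("filter"),
        "consequence_summary": summary_frame(
            classify_consequence_summary(nonsyn_expr, cohort.subjects)
        ),
        "enrichment_nonsyn": enrichment_nonsyn.set_index("gene"),
        "enrichment_syn": enrichment_syn.set_index("gene"),
        "recurrent_variants": enrich.recurrent_variant_report(
            pass_calls, cohort.subjects
        ).set_index(["chrom", "pos"]) if len(pass_calls) else pd.DataFrame(),
        "burdens": burdens.assign(
            vafs=burdens["vafs"].map(lambda v: ";".join(f"{x:.6g}" for x in v))
        ).set_index("subject_id"),
        "cohort_stats": pd.DataFrame(stats_rows, columns=["statistic", "value"]).set_index(
            "statistic"
        ),
        "clone_model": pd.DataFrame(
            clone_rows, columns=["step", "value", "exact"]
        ).set_index("step"),
    }
    return PipelineResult(
        cohort=cohort,
        noise_models=noise_models,
        cohort_germline=cohort_germline,
        calibrated_alpha=alpha,
        filtered_calls=calls,
        pass_calls=pass_calls,
        burdens=burdens,
        enrichment_nonsyn=enrichment_nonsyn,
        enrichment_syn=enrichment_syn,
        tables=tables,
    )


def write_pipeline_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write every report, per-sample VCF/annotation/noise table and the panel."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_report(result.tables, out_dir)
    write_panel_bed(result.cohort.panel, out_dir / "panel.bed")
    write_subjects(result.cohort.subjects, out_dir / "subjects.tsv")
    with open(out_dir / "expressed_genes.txt", "w") as fh:
        for g in sorted(result.cohort.expressed_genes):
            fh.write(g + "\n")
    for s in result.cohort.subjects:
        sid = s.subject_id
        calls = [c for c in result.filtered_calls if c.subject_id == sid]
        if calls:
            write_variant_calls(calls, out_dir / f"calls_{sid}.vcf")
            write_annotations(calls, out_dir / f"annotations_{sid}.tsv")
        result.noise_models[sid].to_tsv(out_dir / f"noise_{sid}.tsv")
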