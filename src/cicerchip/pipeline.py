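"""End-to-end pipeline driver: simulate -> design -> qc -> map -> qtl.

Every stage reads and writes files under the output directory, so each can
also be run standalone from the CLI against externally supplied inputs.
The run log records seeds, per-stage counts and artifact checksums; reruns
with the same configuration are checksum-identical.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from . import __version__, io_files, report
from .array_design import apply_design_filters, score_hook
from .config import PipelineConfig
from .genotype_qc import (
    QcThresholds,
    classify_snp,
    compute_snp_metrics,
    filter_samples,
    qc_summary,
)
from .linkage_map import build_map, map_summary, select_parent_polymorphic
from .models import GeneticMap
from .qtl_icim import (
    call_qtls,
    categorize_qtls,
    code_genotypes,
    icim_scan,
    permutation_threshold,
    stepwise_select,
    interval_scan,
)
from .syndata import (
    Environment,
    QtlSpec,
    TrueMapSpec,
    add_monomorphic_markers,
    make_reference,
    simulate_cluster_signals,
    simulate_panel,
    simulate_phenotypes,
    simulate_ril,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _qc_thresholds(cfg: PipelineConfig) -> QcThresholds:
    q = cfg.qc
    return QcThresholds(
        dqc_min=q.dqc_min,
        sample_cr_min=q.sample_cr_min,
        snp_cr_min=q.snp_cr_min,
        fld_min=q.fld_min,
        hom_fld_min=q.hom_fld_min,
        het_so_min=q.het_so_min,
        het_so_otv_min=q.het_so_otv_min,
        hom_ro_1_min=q.hom_ro_1_min,
        hom_ro_2_min=q.hom_ro_2_min,
        minor_hom_min=q.minor_hom_min,
        var_x_max=q.var_x_max,
        var_y_max=q.var_y_max,
        inbred_penalty=q.inbred_penalty,
    )


def stage_simulate(cfg: PipelineConfig, out: str) -> dict:
    s = cfg.simulate
    genome = make_reference(
        seed=cfg.seed,
        n_chrom=s.n_chrom,
        chrom_length=s.chrom_length,
        gene_count=s.gene_count,
        ssr_count=s.ssr_count,
        gc_target=s.gc_target,
    )
    variants, truth = simulate_panel(
        genome,
        n_accessions=s.n_accessions,
        snp_rate=s.snp_rate,
        indel_rate=s.indel_rate,
        maf_alpha_beta=(s.maf_alpha, s.maf_beta),
        seed=cfg.seed + 1,
    )
    io_files.write_fasta(genome.chromosomes, os.path.join(out, "reference.fasta"))
    io_files.write_gff3(genome.genes, os.path.join(out, "genes.gff3"))
    io_files.write_vcf(
        variants,
        {c: len(seq) for c, seq in genome.chromosomes.items()},
        os.path.join(out, "panel.vcf"),
    )

    true_map = TrueMapSpec.regular(
        n_groups=s.n_chrom,
        markers_per_group=s.markers_per_group,
        spacing_cm=s.marker_spacing_cm,
    )
    calls = simulate_ril(
        true_map,
        n_ril=s.n_ril,
        residual_het_rate=s.residual_het_rate,
        missing_rate=s.missing_rate,
        seed=cfg.seed + 2,
    )
    qtl_spec = QtlSpec(
        traits=s.traits,
        sigma=s.sigma,
        environments=tuple(Environment(*e) for e in s.environments),
    )
    ril_cols = [c for c in calls.columns if c not in ("P1", "P2")]
    pheno = simulate_phenotypes(
        calls, qtl_spec, true_map, seed=cfg.seed + 3, sample_columns=ril_cols
    )
    calls_qc = add_monomorphic_markers(calls, s.n_monomorphic, seed=cfg.seed + 4)
    clusters, samples, otv_markers = simulate_cluster_signals(
        calls_qc[ril_cols],
        separation=s.cluster_separation,
        otv_fraction=s.otv_fraction,
        dqc_low_fraction=s.dqc_low_fraction,
        seed=cfg.seed + 5,
    )
    io_files.write_calls(calls_qc, os.path.join(out, "ril_calls.tsv"))
    io_files.write_phenotypes(pheno, os.path.join(out, "phenotypes.tsv"))
    io_files.write_clusters(clusters, os.path.join(out, "clusters.tsv"))
    io_files.write_sample_qc(samples, os.path.join(out, "sample_qc.tsv"))
    with open(os.path.join(out, "true_map.json"), "w") as fh:
        json.dump({g: m for g, m in true_map.groups.items()}, fh, indent=1)
    return {
        "n_variants": len(variants),
        "n_planted": len(truth.planted),
        "n_markers": calls_qc.shape[0],
        "n_ril": s.n_ril,
        "otv_markers": otv_markers,
    }


def stage_design(cfg: PipelineConfig, out: str) -> dict:
    genome = io_files.genome_from_files(
        os.path.join(out, "reference.fasta"), os.path.join(out, "genes.gff3")
    )
    variants = io_files.read_vcf(os.path.join(out, "panel.vcf"))
    d = cfg.design
    candidates, rep = apply_design_filters(
        variants,
        genome,
        genome.genes,
        thresholds={
            "maf_min": d.maf_min,
            "gc_min": d.gc_min,
            "gc_max": d.gc_max,
            "qual_min": d.qual_min,
        },
    )
    candidates = score_hook(candidates, threshold=d.score_min)
    rows = [
        (
            c.variant.chrom, c.variant.pos, c.window,
            report.round_half_up(c.gc_fraction, 4), c.region, c.effect or "",
            c.score,
        )
        for c in candidates
    ]
    pd.DataFrame(
        rows, columns=["chrom", "pos", "window", "gc", "region", "effect", "score"]
    ).to_csv(os.path.join(out, "probes.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "attrition.tsv"), "w") as fh:
        fh.write(report.render_attrition(rep))
    contigs = {c: len(seq) for c, seq in genome.chromosomes.items()}
    io_files.write_vcf(
        [c.variant for c in candidates], contigs,
        os.path.join(out, "survivors.vcf"),
    )
    return {"input": rep.input_count, "survivors": len(candidates),
            "removed": rep.removed}


def stage_qc(cfg: PipelineConfig, out: str) -> dict:
    calls = io_files.read_calls(os.path.join(out, "ril_calls.tsv"))
    clusters = io_files.read_clusters(os.path.join(out, "clusters.tsv"))
    samples = io_files.read_sample_qc(os.path.join(out, "sample_qc.tsv"))
    th = _qc_thresholds(cfg)
    retained, log = filter_samples(samples, dqc_min=th.dqc_min,
                                   cr_min=th.sample_cr_min)
    keep_cols = [s.sample_id for s in retained]
    ril_cols = [c for c in calls.columns if c in set(keep_cols)]

    rows = []
    categories = []
    for marker in calls.index:
        if str(marker) not in clusters:
            continue
        m = compute_snp_metrics(
            str(marker), list(calls.loc[marker, ril_cols]),
            clusters[str(marker)], th,
        )
        m.category = classify_snp(m, th)
        categories.append(m.category)
        rows.append(
            (m.snp_id, report.round_half_up(m.call_rate, 4), m.n_clusters,
             m.fld, m.hom_fld, m.het_so, m.hom_ro, m.minor_hom_count,
             int(m.otv_flag), m.category)
        )
    pd.DataFrame(
        rows,
        columns=["marker", "call_rate", "n_clusters", "fld", "hom_fld",
                 "het_so", "hom_ro", "minor_hom", "otv_flag", "category"],
    ).to_csv(os.path.join(out, "snp_metrics.tsv"), sep="\t", index=False)
    summary = qc_summary(categories)
    with open(os.path.join(out, "qc_summary.tsv"), "w") as fh:
        fh.write(report.render_category_table(summary))
    return {
        "samples_in": len(samples),
        "samples_removed_dqc": len(log["dqc"]),
        "samples_removed_cr": len(log["call_rate"]),
        "samples_retained": len(retained),
        "categories": summary["counts"],
    }


def stage_map(cfg: PipelineConfig, out: str) -> dict:
    calls = io_files.read_calls(os.path.join(out, "ril_calls.tsv"))
    progeny = select_parent_polymorphic(calls, "P1", "P2")
    m = cfg.map
    gmap, bin_map = build_map(
        progeny, rf_max=m.rf_max, lod_min=m.lod_min,
        min_group_size=m.min_group_size, seg_alpha=m.seg_alpha,
    )
    io_files.write_map(gmap, os.path.join(out, "genetic_map.tsv"))
    stats = map_summary(gmap)
    with open(os.path.join(out, "map_summary.tsv"), "w") as fh:
        fh.write(report.render_map_table(stats))
    pd.DataFrame(
        [(rep, ",".join(members)) for rep, members in bin_map.items()],
        columns=["representative", "members"],
    ).to_csv(os.path.join(out, "bin_map.tsv"), sep="\t", index=False)
    return {"groups": len(gmap.groups), "markers_mapped": gmap.total_markers,
            "total_cm": report.round_half_up(gmap.total_length_cm)}


def stage_qtl(cfg: PipelineConfig, out: str) -> dict:
    gmap = io_files.read_map(os.path.join(out, "genetic_map.tsv"))
    calls = io_files.read_calls(os.path.join(out, "ril_calls.tsv"))
    pheno = io_files.read_phenotypes(os.path.join(out, "phenotypes.tsv"))
    q = cfg.qtl
    mapped = [m for lg in gmap.groups for m in lg.markers]
    calls = calls.loc[mapped]

    all_results = []
    for (trait, env), sub in pheno.groupby(["trait", "environment"], sort=True):
        sub = sub.set_index("sample")
        samples = [s for s in calls.columns if s in sub.index]
        y = sub.loc[samples, "value"].to_numpy(dtype=float)
        sub_calls = calls[samples]
        loc = str(sub["location"].iloc[0])
        year = str(sub["year"].iloc[0])
        threshold = permutation_threshold(
            y, gmap, sub_calls, n_perm=q.n_perm, alpha=q.alpha,
            seed=cfg.seed + 7, p_in=q.p_in, p_out=q.p_out, step=q.step_cm,
        )
        profile = icim_scan(
            y, gmap, sub_calls, p_in=q.p_in, p_out=q.p_out, step=q.step_cm,
            trait=str(trait), location=loc, year=year,
        )
        results = call_qtls(profile, threshold, merge_cm=q.merge_cm,
                            support_drop=q.support_drop)
        all_results.extend(results)
    all_results = categorize_qtls(
        all_results, robust_pve=q.robust_pve, co_window_cm=q.co_window_cm
    )
    with open(os.path.join(out, "qtl_results.tsv"), "w") as fh:
        fh.write(report.render_qtl_table(all_results))
    return {
        "n_qtls": len(all_results),
        "n_robust": sum(r.robust for r in all_results),
        "n_stable": sum(r.stable for r in all_results),
        "n_consistent": sum(r.consistent for r in all_results),
    }


STAGES = [
    ("simulate", stage_simulate),
    ("design", stage_design),
    ("qc", stage_qc),
    ("map", stage_map),
    ("qtl", stage_qtl),
]


def run_pipeline(cfg: PipelineConfig, out_dir: str) -> dict:
    """Execute the enabled stages in order; halts naming a failing stage."""
    os.makedirs(out_dir, exist_ok=True)
    log: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    for name, fn in STAGES:
        if not getattr(cfg.stages, name):
            continue
        try:
            log["stages"][name] = fn(cfg, out_dir)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(name, exc) from exc
    checksums = {}
    for fname in sorted(os.listdir(out_dir)):
        fpath = os.path.join(out_dir, fname)
        if os.path.isfile(fpath) and fname != "run_log.json":
            checksums[fname] = io_files.file_checksum(fpath)
    log["checksums"] = checksums
    with open(os.path.join(out_dir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    return log
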