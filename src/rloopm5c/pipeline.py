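"""End-to-end pipeline: chain every stage over one config.

Stage order: spike-in calibration -> per-condition m5C calling -> dependence
and damage-induction classification -> RNaseH peak filtering -> overlap
enrichment vs the unmethylated background -> windowed GC stats, enrichment
grids, site grids and context profiles. Every filtering stage logs input
count, output count and the rule applied; the fully resolved config is
written beside the outputs. Outputs contain no timestamps, so identical
config + seed gives byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import calling, dependence, features, overlap
from .config import PipelineConfig, write_config
from .core import CONDITIONS, PipelineError, read_bed, read_counts, read_fasta, write_bed, write_table


@dataclass
class PipelineResult:
    """In-memory results of a full run; files are written by run_pipeline."""

    epsilon: calling.NonconversionEstimate
    calls: dict[str, pd.DataFrame]
    dependence_dmg: pd.DataFrame
    dependence_nodmg: pd.DataFrame
    damage_induction: pd.DataFrame
    class_summary: pd.DataFrame
    rnaseh_sensitive: list
    enrichment: pd.DataFrame
    windows: pd.DataFrame
    grids: dict[str, features.EnrichmentGrid]
    site_grids: dict[str, dict]
    context_top: features.ContextMatrix
    context_bottom: features.ContextMatrix
    log_lines: list[str] = field(default_factory=list)


_COUNT_KEYS = {
    "WT_nodmg": "counts_wt_nodmg",
    "WT_dmg": "counts_wt_dmg",
    "KO_nodmg": "counts_ko_nodmg",
    "KO_dmg": "counts_ko_dmg",
}


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Run every stage and write all declared outputs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed = {config.seed}"]

    def _log(msg: str) -> None:
        log.append(msg)

    # --- inputs ---
    for cond, key in _COUNT_KEYS.items():
        if not getattr(config, key):
            raise PipelineError(f"[inputs] missing count table for condition {cond} ({key})")
    for key in ("spikein_counts", "genome_fasta", "transcripts_bed",
                "drip_untreated_bed", "drip_rnaseh_bed"):
        if not getattr(config, key):
            raise PipelineError(f"[inputs] missing required input {key}")

    genome = read_fasta(config.genome_fasta)
    transcripts = read_bed(config.transcripts_bed)
    counts = {cond: read_counts(getattr(config, key)) for cond, key in _COUNT_KEYS.items()}
    spikein = read_counts(config.spikein_counts)
    peaks_untreated = read_bed(config.drip_untreated_bed)
    peaks_rnaseh = read_bed(config.drip_rnaseh_bed)
    _log(f"inputs: {len(transcripts)} transcripts, "
         f"{len(peaks_untreated)} untreated peaks, {len(peaks_rnaseh)} RNaseH peaks")

    # --- stage: spike-in calibration ---
    eps = calling.estimate_nonconversion(spikein)
    _log(f"spikein: epsilon = {eps.rate:.6g} "
         f"[{eps.ci_low:.6g}, {eps.ci_high:.6g}] from {eps.coverage} reads")

    # --- stage: m5C calling per condition ---
    calls: dict[str, pd.DataFrame] = {}
    for cond in CONDITIONS:
        c = calling.call_sites(counts[cond], eps.rate, alpha=config.alpha,
                               min_call_coverage=config.min_call_coverage)
        c = calling.flag_best(c, config.best_min_coverage, config.best_min_meth)
        calls[cond] = c
        n_called = int((c["status"] == "called").sum())
        _log(f"calling[{cond}]: {len(c)} sites in -> {n_called} called "
             f"(q < {config.alpha}, coverage >= {config.min_call_coverage}); "
             f"{int(c['best'].sum())} best (coverage > {config.best_min_coverage}, "
             f"meth > {config.best_min_meth})")
        write_table(c, out / f"calls_{cond}.tsv",
                    [f"m5C calls, condition {cond}; pos is 0-based"])

    # --- stage: dependence classification (within matching damage condition) ---
    dep_dmg = dependence.classify_dependence(calls["WT_dmg"], calls["KO_dmg"],
                                             config.fold_threshold,
                                             config.pseudocount_reads)
    dep_nodmg = dependence.classify_dependence(calls["WT_nodmg"], calls["KO_nodmg"],
                                               config.fold_threshold,
                                               config.pseudocount_reads)
    induction = dependence.classify_damage_induction(calls["WT_nodmg"], calls["WT_dmg"],
                                                     config.fold_threshold,
                                                     config.pseudocount_reads)
    dep_dmg = dep_dmg.merge(induction, on=dependence.SITE_KEYS, how="left")
    summary = pd.concat([
        dependence.summarize_site_classes(dep_dmg, condition="dmg"),
        dependence.summarize_site_classes(dep_nodmg, condition="nodmg"),
    ], ignore_index=True)
    for cond, dep in (("dmg", dep_dmg), ("nodmg", dep_nodmg)):
        n_dep = int((dep["label"] == dependence.LABEL_DEPENDENT).sum())
        _log(f"dependence[{cond}]: {len(dep)} WT-called sites -> {n_dep} dependent "
             f"(fold >= {config.fold_threshold}, pseudocount {config.pseudocount_reads})")
    write_table(dep_dmg, out / "dependence_dmg.tsv",
                ["WT vs KO dependence classification, +damage condition"])
    write_table(dep_nodmg, out / "dependence_nodmg.tsv",
                ["WT vs KO dependence classification, -damage condition"])
    write_table(summary, out / "class_summary.tsv", ["site class counts per condition"])

    # --- stage: RNaseH peak filtering ---
    sensitive = overlap.subtract_rnaseh(peaks_untreated, peaks_rnaseh,
                                        config.removal_overlap_frac)
    _log(f"rnaseh_filter: {len(peaks_untreated)} untreated peaks -> "
         f"{len(sensitive)} RNaseH-sensitive "
         f"(removed if overlap >= {config.removal_overlap_frac} of peak length)")
    write_bed(sensitive, out / "rnaseh_sensitive.bed")

    # --- stage: overlap enrichment ---
    background = calling.unmethylated_background(
        calls, eps.rate, min_coverage=config.best_min_coverage,
        meth_factor=config.background_meth_factor)
    if len(background) == 0:
        raise PipelineError("[overlap] empty unmethylated background set")
    _log(f"background: {len(background)} unmethylated C sites "
         f"(coverage > {config.best_min_coverage}, "
         f"meth <= {config.background_meth_factor} * epsilon, never called)")
    dep_sites = dep_dmg[dep_dmg["label"] == dependence.LABEL_DEPENDENT]
    indep_sites = dep_dmg[dep_dmg["label"] == dependence.LABEL_INDEPENDENT]
    site_sets: dict[str, pd.DataFrame] = {}
    if len(dep_sites):
        site_sets["dependent"] = dep_sites
        site_sets["best10_dependent"] = _top_fraction_dep(dep_sites, calls["WT_dmg"],
                                                          config.top_fraction)
    if len(indep_sites):
        site_sets["independent"] = indep_sites
        site_sets["best10_independent"] = _top_fraction_dep(indep_sites, calls["WT_dmg"],
                                                            config.top_fraction)
    enrich = overlap.overlap_by_class(site_sets, background, sensitive)
    for row in enrich.itertuples():
        _log(f"overlap[{row._1}]: {row.n_in_rloop}/{row.n_total} in R-loops vs "
             f"background {row.background_in}/{row.background_n}; "
             f"OR = {row.odds_ratio:.4g}, p = {row.p_value:.4g}")
    write_table(enrich, out / "overlap_enrichment.tsv",
                ["in-R-loop overlap enrichment vs unmethylated background"])

    # annotation TSV for every classified site
    annot = dep_dmg.copy()
    annot["in_rloop"] = overlap.annotate_sites_in_peaks(annot, sensitive)
    write_table(annot, out / "site_annotation_dmg.tsv",
                ["+damage dependence calls annotated with R-loop containment"])

    # --- stage: windowed GC stats and grids ---
    windows = features.windowed_gc_stats(genome, config.window_size, transcripts,
                                         sensitive, step=config.window_step)
    _log(f"windows: {len(windows)} windows of {config.window_size} bp; "
         f"{int(windows['in_rloop'].sum())} in R-loops; "
         f"{int(windows['gc_skew'].isna().sum())} undefined skew")
    write_table(windows, out / "window_stats.tsv",
                ["per-window GC skew (sense strand) and GC fraction"])
    grids = features.build_obs_exp_grid(windows, config.skew_bin_width,
                                        config.gc_bin_width)
    grid_frames = [g.to_frame() for g in grids.values()]
    write_table(pd.concat(grid_frames, ignore_index=True), out / "obs_exp_grid.tsv",
                ["observed (R-loop) vs expected (rest of genome) window counts per facet"])

    site_grids: dict[str, dict] = {}
    for name, sites in (("dependent", dep_sites), ("background", background)):
        if len(sites) == 0:
            continue
        counts_by_facet, excl = features.site_grid_distribution(
            sites, windows, config.window_size, config.skew_bin_width,
            config.gc_bin_width)
        site_grids[name] = {"counts": counts_by_facet, "excluded": excl}
        rows = []
        skew_edges = features._bin_edges(config.skew_bin_width, -1.0, 1.0)
        gc_edges = features._bin_edges(config.gc_bin_width, 0.0, 1.0)
        for facet, grid in counts_by_facet.items():
            for i in range(grid.shape[0]):
                for j in range(grid.shape[1]):
                    if grid[i, j]:
                        rows.append({"facet_strand": facet,
                                     "skew_bin_low": skew_edges[i],
                                     "gc_bin_low": gc_edges[j],
                                     "n_sites": int(grid[i, j])})
        write_table(pd.DataFrame(rows, columns=["facet_strand", "skew_bin_low",
                                                "gc_bin_low", "n_sites"]),
                    out / f"site_grid_{name}.tsv",
                    [f"{name} site counts per (skew, GC) cell; excluded = {excl}"])

    # --- stage: context profiles ---
    top_ctx, bottom_ctx = features.compare_top_bottom_contexts(
        calls["WT_dmg"], genome, config.flank_k, config.top_fraction)
    _log(f"context: top/bottom {top_ctx.n_sites}/{bottom_ctx.n_sites} + strand sites, "
         f"flank {config.flank_k}")
    write_table(top_ctx.to_frame(), out / "context_top.tsv",
                ["positional base frequencies, top-methylated + strand sites"])
    write_table(bottom_ctx.to_frame(), out / "context_bottom.tsv",
                ["positional base frequencies, bottom-methylated + strand sites"])

    write_config(config, out / "resolved_config.txt")
    with open(out / "run_log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")

    return PipelineResult(
        epsilon=eps, calls=calls, dependence_dmg=dep_dmg, dependence_nodmg=dep_nodmg,
        damage_induction=induction, class_summary=summary, rnaseh_sensitive=sensitive,
        enrichment=enrich, windows=windows, grids=grids, site_grids=site_grids,
        context_top=top_ctx, context_bottom=bottom_ctx, log_lines=log,
    )


def _top_fraction_dep(dep_sites: pd.DataFrame, wt_calls: pd.DataFrame,
                      fraction: float) -> pd.DataFrame:
    """Best-`fraction` subset of a dependence class, ranked like called sites."""
    merged = dep_sites[dependence.SITE_KEYS].merge(wt_calls, on=dependence.SITE_KEYS)
    return calling.rank_top_fraction(merged, fraction)
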