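"""End-to-end driver: normalize -> scan -> assign -> classify -> validate
-> cooperative -> diagnose -> summarize, plus report rendering.

Outputs (all TSV/JSON under the configured output directory):

* ``normalization_rep<k>.tsv`` -- per-array gain/offset and convergence
* ``peaks_rep1.tsv``           -- identified eQTL (one per probe, p <= 1e-6)
* ``best_rep2.tsv``            -- replicate 2's strongest marker per probe
* ``classified.tsv``           -- validated peaks with cis/trans mode
* ``validation.tsv``           -- per-probe validation category
* ``cooperative.tsv``          -- all ranks for probes with multiple eQTL
* ``diagnostics.json``         -- direction/FP estimates and power-law fit
* ``summary.tsv``              -- Table-1-style mode x p-bin counts
* ``manifest.json``            -- config snapshot, checksums, row counts
"""
from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import arraynorm, classify, fpdiag, io, kscan


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001 - re-raise with context
                raise StageError(name, e) from e
        return wrapper
    return deco


@_stage("load")
def _load(config: io.PipelineConfig):
    gmap = io.read_map(config.map_path)
    genotypes = io.read_genotypes(config.genotype_path)
    annot = io.read_annotation(config.annotation_path)
    reps = [io.read_expression(p) for p in config.expression_paths]
    return gmap, genotypes, annot, reps


@_stage("normalize")
def _normalize(reps, config):
    out = []
    models_tables = []
    for expr in reps:
        norm, models = arraynorm.normalize_arrays(
            expr, background_fraction=config.background_fraction)
        out.append(norm)
        models_tables.append(pd.DataFrame(
            {
                "array_id": [m.array_id for m in models],
                "gain": [m.gain for m in models],
                "offset": [m.offset for m in models],
                "n_iterations": [m.n_iterations for m in models],
                "converged": [m.converged for m in models],
            }
        ))
    return out, models_tables


@_stage("scan")
def _scan(norm_reps, genotypes, gmap, config):
    return [kscan.scan_matrix(expr, genotypes, gmap, config.min_group_size)
            for expr in norm_reps]


def run_pipeline(config: io.PipelineConfig) -> Path:
    """Execute the full analysis; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = io.RunManifest.start(config)

    gmap, genotypes, annot, reps = _load(config)
    manifest.stage_counts["markers"] = gmap.n_markers
    manifest.stage_counts["lines"] = genotypes.n_lines
    manifest.stage_counts["probes"] = reps[0].n_probes

    norm_reps, model_tables = _normalize(reps, config)
    for k, table in enumerate(model_tables, start=1):
        table.to_csv(outdir / f"normalization_rep{k}.tsv", sep="\t", index=False)

    scans = _scan(norm_reps, genotypes, gmap, config)

    # replicate 1: identified eQTL; replicate 2 (if present): best marker
    peaks1 = kscan.assign_peaks_table(
        scans[0], norm_reps[0], genotypes, config.identify_threshold)
    io.write_peaks(peaks1, outdir / "peaks_rep1.tsv")
    manifest.stage_counts["peaks_rep1"] = len(peaks1)

    if len(scans) >= 2:
        best2 = kscan.best_peaks_table(scans[1])
        io.write_peaks(best2, outdir / "best_rep2.tsv")
        report = classify.validate_replicates(
            peaks1, best2, p1=config.identify_threshold,
            p2=config.validate_threshold, window_cM=config.window_cM)
        validated = peaks1[peaks1["probe_id"].isin(report.validated_probes)]
    else:
        report = None
        validated = peaks1
    classified = classify.classify_peaks(validated, annot, config.window_cM)
    io.write_peaks(classified, outdir / "classified.tsv")
    manifest.stage_counts["validated"] = len(classified)
    if report is not None:
        report.table.to_csv(outdir / "validation.tsv", sep="\t", index=False)

    # cooperative search on validated probes (replicate 1 profiles)
    try:
        geno1 = genotypes.reindex_lines(norm_reps[0].line_ids)
        co_rows = []
        cmode = classified.set_index("probe_id")
        for _, row in classified.iterrows():
            pid = row["probe_id"]
            profile = scans[0].profile(pid)
            primary = kscan.EQTLPeak(
                probe_id=pid, marker_id=row["marker_id"],
                chromosome=row["chrom"], position_cM=row["cM"],
                D=row["D"], p=row["p"], direction=row["direction"],
                rank="primary")
            co_rows.append((pid, row["marker_id"], row["chrom"], row["cM"],
                            row["p"], row["direction"], "primary", row["mode"]))
            extras = classify.detect_cooperative(
                profile, primary, threshold=config.identify_threshold,
                exclusion_cM=config.window_cM,
                max_rank=config.cooperative_max_rank)
            expr_row = norm_reps[0].row(pid)
            for pk in extras:
                direction = kscan.allele_direction(expr_row, geno1, pk.marker_id)
                mode = classify.classify_mode(
                    pk.chromosome, pk.position_cM,
                    {"chromosome": cmode.loc[pid, "gene_chrom"],
                     "position_cM": cmode.loc[pid, "gene_cM"],
                     "unique_flag": True, "position_known": True},
                    config.window_cM)
                co_rows.append((pid, pk.marker_id, pk.chromosome,
                                pk.position_cM, pk.p, direction, pk.rank, mode))
        cooperative = pd.DataFrame(
            co_rows, columns=["probe_id", "marker_id", "chrom", "cM", "p",
                              "direction", "rank", "mode"])
        io.write_peaks(cooperative, outdir / "cooperative.tsv")
        manifest.stage_counts["cooperative_peaks"] = len(cooperative)
    except Exception as e:  # noqa: BLE001
        raise StageError("cooperative", e) from e

    # diagnostics
    try:
        diag: dict = {"identify_threshold": config.identify_threshold,
                      "validate_threshold": config.validate_threshold}
        cis_peaks = classified[classified["mode"] == classify.CIS]
        if len(cis_peaks):
            f, binom_p = fpdiag.mo17_higher_fraction(cis_peaks["direction"])
            diag["mo17_higher_fraction"] = f
            diag["direction_binom_p"] = binom_p
            diag["false_cis_fraction"] = fpdiag.estimate_false_positive_rate(f)
            strat = fpdiag.stratified_direction_analysis(cis_peaks)
            diag["stratified"] = strat.to_dict(orient="records")
        _, minp = scans[0].min_p_table()
        if minp.size >= 100:
            try:
                fit = fpdiag.fit_powerlaw_threshold(minp)
                diag["powerlaw"] = {
                    "exponent": fit.exponent,
                    "intercept": fit.intercept,
                    "fit_region": list(fit.fit_region),
                    "deviation_threshold": fit.deviation_threshold,
                    "goodness": fit.goodness,
                }
            except ValueError as e:
                diag["powerlaw"] = {"error": str(e)}
        with open(outdir / "diagnostics.json", "w") as fh:
            json.dump(diag, fh, indent=2)
            fh.write("\n")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("diagnose", e) from e

    # summary
    try:
        summary = classify.summarize_counts(classified, cooperative)
        bins = summary["bins"].reset_index().rename(columns={"index": "p_bin"})
        bins.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        if report is not None:
            vc = pd.DataFrame(
                {"category": list(report.counts),
                 "count": list(report.counts.values()),
                 "percent": [report.percentages[c] for c in report.counts]})
            vc.to_csv(outdir / "validation_summary.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("summarize", e) from e

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "manifest.json")
    return outdir


def render_report(outdir, plot: bool = False) -> Path:
    """Render human-readable summary tables from pipeline outputs.

    Writes ``report_table1.tsv`` (mode x p-bins), ``report_table2.tsv``
    (cooperative cross-tab), ``report_validation.tsv`` and ``scatter.tsv``
    (peak position vs gene position, the classic cis-diagonal layout), and
    optionally a scatter plot PNG.
    """
    outdir = Path(outdir)
    classified_path = outdir / "classified.tsv"
    if not classified_path.exists():
        raise FileNotFoundError(f"missing pipeline output {classified_path}")
    classified = io.read_peaks(classified_path)
    co_path = outdir / "cooperative.tsv"
    cooperative = io.read_peaks(co_path) if co_path.exists() else None
    summary = classify.summarize_counts(classified, cooperative)

    t1 = summary["bins"].reset_index().rename(columns={"index": "p_bin"})
    t1.loc["total"] = ["total", summary["n_cis"], summary["n_trans"]]
    t1.to_csv(outdir / "report_table1.tsv", sep="\t", index=False)

    if "cooperative" in summary:
        co = summary["cooperative"]
        rows = [("primary_cis", co["n_primary_cis"]),
                ("primary_trans", co["n_primary_trans"])]
        for (rank, pm, m), v in sorted(co["cells"].items()):
            rows.append((f"{rank}_{m}_given_primary_{pm}", v))
        rows.append(("total_verifiable_peaks", co["total_peaks"]))
        pd.DataFrame(rows, columns=["cell", "count"]).to_csv(
            outdir / "report_table2.tsv", sep="\t", index=False)

    vs_path = outdir / "validation_summary.tsv"
    if vs_path.exists():
        vs = pd.read_csv(vs_path, sep="\t")
        # recompute percentages from counts so the report is self-consistent
        counts = dict(zip(vs["category"], vs["count"]))
        pct = classify.validation_percentages(counts)
        vs["percent"] = [pct[c] for c in vs["category"]]
        vs.to_csv(outdir / "report_validation.tsv", sep="\t", index=False)

    assigned = classified[classified["mode"].isin((classify.CIS, classify.TRANS))]
    scatter = assigned[["probe_id", "chrom", "cM", "gene_chrom", "gene_cM",
                        "mode", "p"]]
    scatter.to_csv(outdir / "scatter.tsv", sep="\t", index=False)

    if plot and len(scatter):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        chroms = sorted(set(scatter["chrom"]) | set(scatter["gene_chrom"]),
                        key=str)
        offsets = {}
        off = 0.0
        for c in chroms:
            offsets[c] = off
            span = max(
                scatter.loc[scatter["chrom"] == c, "cM"].max(skipna=True)
                if (scatter["chrom"] == c).any() else 0,
                scatter.loc[scatter["gene_chrom"] == c, "gene_cM"].max(skipna=True)
                if (scatter["gene_chrom"] == c).any() else 0,
            )
            off += (span if np.isfinite(span) else 0) + 10
        x = [offsets[c] + p for c, p in zip(scatter["chrom"], scatter["cM"])]
        y = [offsets[c] + p
             for c, p in zip(scatter["gene_chrom"], scatter["gene_cM"])]
        strong = scatter["p"] <= 1e-15
        fig, ax = plt.subplots(figsize=(6, 6))
        ax.scatter(np.array(x)[~strong], np.array(y)[~strong], s=4, c="pink",
                   label="1e-15 < p <= 1e-6")
        ax.scatter(np.array(x)[strong], np.array(y)[strong], s=4, c="blue",
                   label="p <= 1e-15")
        ax.set_xlabel("eQTL peak position (concatenated cM)")
        ax.set_ylabel("gene position (concatenated cM)")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / "scatter.png", dpi=150)
        plt.close(fig)
    return outdir
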