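#!/usr/bin/env python
"""Validate eQTL across replicates, classify cis/trans, find cooperative loci.

Replicate-1 eQTL (p <= 1e-6) are validated against replicate 2 (p <= 1e-5,
same position within 10 cM), classified cis/trans by the 10 cM window, and
searched for secondary/tertiary peaks after masking each accepted peak's
region.  Writes classified/validation/cooperative tables and a Table-1-style
summary under results/classified/.
"""
from pathlib import Path

import pandas as pd

from eqtlscan import classify, io, kscan

SIM = Path("results/simulated")
NORM = Path("results/normalized")
SCAN = Path("results/scan")
OUT = Path("results/classified")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gmap = io.read_map(SIM / "map.tsv")
    genotypes = io.read_genotypes(SIM / "genotypes.tsv")
    annot = io.read_annotation(SIM / "annotation.tsv")
    peaks1 = io.read_peaks(SCAN / "peaks_rep1.tsv")
    best2 = io.read_peaks(SCAN / "best_rep2.tsv")

    report = classify.validate_replicates(peaks1, best2)
    report.table.to_csv(OUT / "validation.tsv", sep="\t", index=False)
    print("validation:", report.counts, "->",
          {k: f"{v}%" for k, v in report.percentages.items()})

    validated = peaks1[peaks1["probe_id"].isin(report.validated_probes)]
    classified = classify.classify_peaks(validated, annot)
    io.write_peaks(classified, OUT / "classified.tsv")

    # cooperative search needs the full replicate-1 profiles
    expr1 = io.read_expression(NORM / "normalized_rep1.tsv")
    scan1 = kscan.scan_matrix(expr1, genotypes, gmap)
    geno = genotypes.reindex_lines(expr1.line_ids)
    rows = []
    for _, row in classified.iterrows():
        pid = row["probe_id"]
        primary = kscan.EQTLPeak(
            probe_id=pid, marker_id=row["marker_id"], chromosome=row["chrom"],
            position_cM=row["cM"], D=row["D"], p=row["p"],
            direction=row["direction"], rank="primary")
        rows.append((pid, row["marker_id"], row["chrom"], row["cM"], row["p"],
                     row["direction"], "primary", row["mode"]))
        for pk in classify.detect_cooperative(scan1.profile(pid), primary):
            direction = kscan.allele_direction(expr1.row(pid), geno,
                                               pk.marker_id)
            mode = classify.classify_mode(
                pk.chromosome, pk.position_cM,
                {"chromosome": row["gene_chrom"],
                 "position_cM": row["gene_cM"],
                 "unique_flag": True, "position_known": True})
            rows.append((pid, pk.marker_id, pk.chromosome, pk.position_cM,
                         pk.p, direction, pk.rank, mode))
    cooperative = pd.DataFrame(
        rows, columns=["probe_id", "marker_id", "chrom", "cM", "p",
                       "direction", "rank", "mode"])
    io.write_peaks(cooperative, OUT / "cooperative.tsv")

    summary = classify.summarize_counts(classified, cooperative)
    summary["bins"].reset_index().rename(columns={"index": "p_bin"}).to_csv(
        OUT / "summary.tsv", sep="\t", index=False)
    print(f"classified: {summary['n_cis']} cis, {summary['n_trans']} trans "
          f"(strong tier: {summary['cis_strong_pct']}% of cis, "
          f"{summary['trans_strong_pct']}% of trans at p <= 1e-15)")
    if "cooperative" in summary:
        co = summary["cooperative"]
        print(f"cooperative: {co['n_multi_probes']} probes with >= 2 eQTL, "
              f"{co['total_peaks']} verifiable peaks; "
              f"{co['n_independent']} probes regulated independently")


if __name__ == "__main__":
    main()
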