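"""Cis/trans classification, replicate validation, cooperative eQTL search.

An eQTL is cis-acting when its peak marker lies within 10 cM of the measured
gene on the same chromosome (strictly less than the window; a distance of
exactly 10 cM, or any other chromosome, is trans).  Classification is only
attempted for probes whose genomic origin is unique and known.

Replicate validation follows the two-threshold scheme: eQTL identified in
replicate 1 at p <= 1e-6 are validated when replicate 2's strongest marker
for the same probe reaches p <= 1e-5 within the same 10 cM window on the
same chromosome.  Failures split into "not significant in replicate 2" and
"significant at an inconsistent position".

The cooperative search re-scans a probe after masking all markers within
10 cM of each accepted peak, accepting secondary and tertiary peaks at the
same identification threshold (at most three peaks per probe).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .kscan import EQTLPeak, ScanProfile, assign_peak

DEFAULT_WINDOW_CM = 10.0

CIS = "cis"
TRANS = "trans"
UNASSIGNABLE = "unassignable"

VALIDATED = "validated"
NON_SIGNIFICANT_REP2 = "non_significant_rep2"
INCONSISTENT_POSITION = "inconsistent_position"
ABSENT_REP1 = "absent_rep1"
CATEGORIES = (VALIDATED, NON_SIGNIFICANT_REP2, INCONSISTENT_POSITION, ABSENT_REP1)


def classify_mode(peak_chrom, peak_cM: float, annot_row,
                  window_cM: float = DEFAULT_WINDOW_CM) -> str:
    """cis if same chromosome and |peak - gene| < window; else trans.

    ``annot_row`` needs fields chromosome, position_cM, unique_flag,
    position_known; non-unique or position-unknown probes are unassignable.
    """
    if window_cM <= 0:
        raise ValueError("window_cM must be positive")
    if not (bool(annot_row["unique_flag"]) and bool(annot_row["position_known"])):
        return UNASSIGNABLE
    if annot_row["chromosome"] is None or not np.isfinite(annot_row["position_cM"]):
        return UNASSIGNABLE
    if peak_chrom != annot_row["chromosome"]:
        return TRANS
    return CIS if abs(peak_cM - annot_row["position_cM"]) < window_cM else TRANS


def classify_peaks(peaks: pd.DataFrame, annotation: pd.DataFrame,
                   window_cM: float = DEFAULT_WINDOW_CM) -> pd.DataFrame:
    """Add mode and gene-position columns to a peaks table."""
    annot = annotation.set_index("probe_id")
    out = peaks.copy()
    modes, gchrom, gcm = [], [], []
    for _, row in out.iterrows():
        pid = row["probe_id"]
        if pid not in annot.index:
            modes.append(UNASSIGNABLE)
            gchrom.append(None)
            gcm.append(np.nan)
            continue
        a = annot.loc[pid]
        modes.append(classify_mode(row["chrom"], row["cM"], a, window_cM))
        gchrom.append(a["chromosome"])
        gcm.append(a["position_cM"])
    out["mode"] = modes
    out["gene_chrom"] = gchrom
    out["gene_cM"] = gcm
    return out


@dataclass
class ValidationReport:
    """Per-probe validation categories for replicate-1 peaks, plus counts."""

    table: pd.DataFrame  # probe_id, category, rep1/rep2 peak details
    counts: dict
    percentages: dict

    @property
    def validated_probes(self) -> np.ndarray:
        t = self.table
        return t.loc[t["category"] == VALIDATED, "probe_id"].to_numpy()


def validation_percentages(counts: dict) -> dict:
    """Category percentages (1 decimal) of the replicate-1 peak total."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: round(100.0 * v / total, 1) for k, v in counts.items()}


def validate_replicates(peaks_rep1: pd.DataFrame, best_rep2: pd.DataFrame,
                        p1: float = 1e-6, p2: float = 1e-5,
                        window_cM: float = DEFAULT_WINDOW_CM) -> ValidationReport:
    """Categorize replicate-1 peaks by their reproducibility in replicate 2.

    ``peaks_rep1`` are the identified eQTL (p <= p1 enforced here);
    ``best_rep2`` holds each probe's strongest marker in replicate 2
    (columns probe_id, marker_id, chrom, cM, p), with no threshold applied.
    """
    rep2 = best_rep2.set_index("probe_id")
    rows = []
    for _, r1 in peaks_rep1.iterrows():
        if r1["p"] > p1:
            continue
        pid = r1["probe_id"]
        if pid not in rep2.index:
            rows.append((pid, ABSENT_REP1, r1["marker_id"], r1["chrom"],
                         r1["cM"], r1["p"], None, None, np.nan, np.nan))
            continue
        r2 = rep2.loc[pid]
        if r2["p"] > p2:
            cat = NON_SIGNIFICANT_REP2
        elif (r2["chrom"] == r1["chrom"]
              and abs(r2["cM"] - r1["cM"]) < window_cM):
            cat = VALIDATED
        else:
            cat = INCONSISTENT_POSITION
        rows.append((pid, cat, r1["marker_id"], r1["chrom"], r1["cM"], r1["p"],
                     r2["marker_id"], r2["chrom"], r2["cM"], r2["p"]))
    table = pd.DataFrame(
        rows,
        columns=["probe_id", "category", "rep1_marker", "rep1_chrom",
                 "rep1_cM", "rep1_p", "rep2_marker", "rep2_chrom", "rep2_cM",
                 "rep2_p"],
    )
    counts = {c: int((table["category"] == c).sum()) for c in CATEGORIES}
    return ValidationReport(table, counts, validation_percentages(counts))


def detect_cooperative(profile: ScanProfile, primary: EQTLPeak,
                       threshold: float = 1e-6,
                       exclusion_cM: float = DEFAULT_WINDOW_CM,
                       max_rank: int = 3) -> List[EQTLPeak]:
    """Secondary/tertiary peaks after masking each accepted peak's region.

    Iteratively masks all markers within ``exclusion_cM`` of every accepted
    peak (same chromosome), re-scans the remaining markers, and accepts the
    new minimum while it clears ``threshold``, up to ``max_rank`` peaks in
    total (primary included).  Returns the extra peaks in acceptance order.
    """
    rank_names = {2: "secondary", 3: "tertiary"}
    accepted = [primary]
    extras: List[EQTLPeak] = []
    mask = np.zeros(len(profile), dtype=bool)
    while len(accepted) < max_rank:
        for pk in accepted:
            mask |= (profile.chromosome == pk.chromosome) & (
                np.abs(profile.position_cM - pk.position_cM) <= exclusion_cM
            )
        nxt = assign_peak(profile, threshold, mask=mask)
        if nxt is None:
            break
        nxt.rank = rank_names[len(accepted) + 1]
        accepted.append(nxt)
        extras.append(nxt)
    return extras


# ---------------------------------------------------------------------------
# summaries (Table-1 / Table-2 style)


def strong_fraction(n_strong: int, n_total: int, digits: int = 0) -> float:
    """Percentage of peaks in the strong bin, rounded as printed."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_strong / n_total, digits)


def mode_partition(n_total: int, n_trans: int):
    """(n_cis, n_trans) from a total and its trans count."""
    if not 0 <= n_trans <= n_total:
        raise ValueError("n_trans must be between 0 and n_total")
    return n_total - n_trans, n_trans


def cooperative_table_total(counts: Iterable[int]) -> int:
    """Total verifiable peaks of a cooperative cross-tab (plain sum)."""
    return int(sum(counts))


def summarize_counts(classified: pd.DataFrame,
                     cooperative: Optional[pd.DataFrame] = None,
                     bin_edges=(0.0, 1e-15, 1e-6)) -> dict:
    """Cross-tabulate mode x p-value bins and cooperative ranks.

    ``classified`` needs columns mode and p (primary peaks);
    ``cooperative`` (optional) needs probe_id, mode, rank for all ranks.
    Unassignable probes are reported but excluded from mode statistics.
    Default bins are the strong tier (p <= 1e-15) and the moderate tier
    (1e-15 < p <= 1e-6).
    """
    edges = sorted(bin_edges)
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    assigned = classified[classified["mode"].isin((CIS, TRANS))]
    labels = []
    table = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        label = f"({lo:.0e}, {hi:.0e}]" if lo > 0 else f"<= {hi:.0e}"
        labels.append(label)
        sel = (assigned["p"] > lo) & (assigned["p"] <= hi)
        table[label] = {
            CIS: int((sel & (assigned["mode"] == CIS)).sum()),
            TRANS: int((sel & (assigned["mode"] == TRANS)).sum()),
        }
    bins_df = pd.DataFrame(table).T[[CIS, TRANS]]

    n_cis = int((assigned["mode"] == CIS).sum())
    n_trans = int((assigned["mode"] == TRANS).sum())
    strong_edge = edges[1] if len(edges) >= 3 else edges[0]
    out = {
        "bins": bins_df,
        "n_cis": n_cis,
        "n_trans": n_trans,
        "n_assigned": n_cis + n_trans,
        "n_unassignable": int((classified["mode"] == UNASSIGNABLE).sum()),
        "strong_edge": strong_edge,
        "cis_strong_pct": (
            strong_fraction(int(((assigned["mode"] == CIS)
                                 & (assigned["p"] <= strong_edge)).sum()), n_cis)
            if n_cis else np.nan
        ),
        "trans_strong_pct": (
            strong_fraction(int(((assigned["mode"] == TRANS)
                                 & (assigned["p"] <= strong_edge)).sum()), n_trans)
            if n_trans else np.nan
        ),
    }

    if cooperative is not None and len(cooperative):
        prim = cooperative[cooperative["rank"] == "primary"]
        multi = cooperative.groupby("probe_id").size()
        multi_probes = set(multi[multi >= 2].index)
        co = cooperative[cooperative["probe_id"].isin(multi_probes)]
        prim_mode = (co[co["rank"] == "primary"]
                     .set_index("probe_id")["mode"])
        cells = {}
        for rank in ("secondary", "tertiary"):
            sub = co[co["rank"] == rank]
            for _, row in sub.iterrows():
                pm = prim_mode.get(row["probe_id"], UNASSIGNABLE)
                cells[(rank, pm, row["mode"])] = cells.get(
                    (rank, pm, row["mode"]), 0) + 1
        out["cooperative"] = {
            "n_multi_probes": len(multi_probes),
            "n_primary_cis": int((co[co["rank"] == "primary"]["mode"] == CIS).sum()),
            "n_primary_trans": int((co[co["rank"] == "primary"]["mode"] == TRANS).sum()),
            "cells": cells,
            "total_peaks": int(len(co)),
            "n_independent": int((multi < 2).sum()),
        }
        _ = prim  # primary table retained for callers via `cooperative`
    return out
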