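"""Genome-wide Kolmogorov-Smirnov association scan.

For each probe, every usable marker splits the lines into B73- and
Mo17-allele classes; the two-sample KS test compares the intensity
distributions of the classes.  The scan assigns at most one eQTL per probe:
the marker with the most significant p-value, provided it clears the
identification threshold (1e-6 by default in the pipeline).

Small samples use the exact permutation null (via scipy); otherwise p comes
from the asymptotic Kolmogorov distribution evaluated at sqrt(en) * D with
effective sample size en = n1*n2/(n1+n2).  The statistic D is invariant
under any common strictly increasing transform of the intensities, so the
scan is insensitive to monotone per-array distortions; the allele-direction
call (class-mean comparison) is made on the normalized intensity scale.

A single-marker regression F-test is provided as an independent concordance
oracle (the classical regression approach to marker-trait association); it
is never used for eQTL calling.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import kolmogorov

from .containers import B73, MISSING, MO17, ExpressionMatrix, GeneticMap, GenotypeMatrix

EXACT_MAX_COMBINED_N = 16
DEFAULT_MIN_GROUP_SIZE = 10
P_FLOOR = 1e-300  # reporting floor for underflowing p-values

B73_HIGHER = "B73_higher"
MO17_HIGHER = "Mo17_higher"


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Max absolute ECDF difference over the pooled distinct values."""
    pooled = np.unique(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), pooled, side="right") / x.size
    fy = np.searchsorted(np.sort(y), pooled, side="right") / y.size
    return float(np.max(np.abs(fx - fy)))


def _exact_ks_pvalue(x: np.ndarray, y: np.ndarray, d_obs: float) -> float:
    """Exact permutation P(D* >= d_obs) by tie-aware lattice-path counting.

    Group labels are exchangeable within tied pooled values, so the null
    distribution depends only on how many x-labels fall in each tie group;
    a dynamic program over tie groups counts assignments whose running ECDF
    difference stays below d_obs at every valid evaluation point, i.e. at
    tie-group boundaries.
    """
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    _, group_sizes = np.unique(pooled, return_counts=True)
    eps = 1e-12
    # ways[i] = number of label assignments so far using i x-labels whose
    # partial paths never reached d_obs
    ways = {0: 1}
    total_so_far = 0
    for g in group_sizes:
        new_ways: dict = {}
        total_so_far += int(g)
        for i, cnt in ways.items():
            for a in range(0, int(g) + 1):
                ii = i + a
                if ii > n or (total_so_far - ii) > m:
                    continue
                d_here = abs(ii / n - (total_so_far - ii) / m)
                if d_here >= d_obs - eps:
                    continue  # this path attains D >= d_obs
                new_ways[ii] = new_ways.get(ii, 0) + cnt * math.comb(int(g), a)
        ways = new_ways
    below = ways.get(n, 0)
    return 1.0 - below / math.comb(n + m, n)


def ks_two_sample(x, y, method: str = "auto"):
    """Two-sample two-sided KS test: returns (D, p).

    ``method="auto"`` uses the exact permutation null when
    len(x)+len(y) <= 16, else the asymptotic Kolmogorov distribution with
    effective sample size n1*n2/(n1+n2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        method = "exact" if x.size + y.size <= EXACT_MAX_COMBINED_N else "asymptotic"
    d = _ks_statistic(x, y)
    if method == "exact":
        return d, float(_exact_ks_pvalue(x, y, d))
    if method == "asymptotic":
        en = x.size * y.size / (x.size + y.size)
        return d, float(min(1.0, kolmogorov(np.sqrt(en) * d)))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ScanProfile:
    """Per-marker KS results for one probe (unusable markers absent)."""

    probe_id: object
    marker_id: np.ndarray
    chromosome: np.ndarray
    position_cM: np.ndarray
    D: np.ndarray
    p: np.ndarray
    n_b73: np.ndarray
    n_mo17: np.ndarray
    skipped_markers: np.ndarray  # markers excluded by the group-size floor

    def __len__(self) -> int:
        return len(self.marker_id)


@dataclass
class EQTLPeak:
    """One assigned eQTL: the most significant marker of a probe's scan."""

    probe_id: object
    marker_id: object
    chromosome: object
    position_cM: float
    D: float
    p: float
    direction: Optional[str] = None
    rank: str = "primary"


@dataclass
class ScanResult:
    """Vectorized KS scan over all probes x usable markers."""

    probe_ids: np.ndarray
    marker_id: np.ndarray
    chromosome: np.ndarray
    position_cM: np.ndarray
    D: np.ndarray  # (n_probes, n_usable)
    p: np.ndarray  # (n_probes, n_usable)
    n_b73: np.ndarray
    n_mo17: np.ndarray
    skipped_markers: np.ndarray

    def profile(self, probe_id) -> ScanProfile:
        i = np.where(self.probe_ids == probe_id)[0]
        if i.size == 0:
            raise KeyError(f"probe {probe_id!r} not in scan")
        i = int(i[0])
        return ScanProfile(
            probe_id=probe_id,
            marker_id=self.marker_id,
            chromosome=self.chromosome,
            position_cM=self.position_cM,
            D=self.D[i],
            p=self.p[i],
            n_b73=self.n_b73,
            n_mo17=self.n_mo17,
            skipped_markers=self.skipped_markers,
        )

    def min_p_table(self):
        """Per probe: index and value of the minimum p (first in map order)."""
        idx = np.argmin(self.p, axis=1)
        return idx, self.p[np.arange(len(self.probe_ids)), idx]


def scan_matrix(expr: ExpressionMatrix, genotypes: GenotypeMatrix,
                gmap: GeneticMap,
                min_group_size: int = DEFAULT_MIN_GROUP_SIZE) -> ScanResult:
    """KS-scan every probe against every usable marker.

    Markers where either allele class has fewer than ``min_group_size``
    non-missing lines are skipped.  D is computed from the pooled ECDF
    difference evaluated at distinct intensity values (ties handled); the
    asymptotic Kolmogorov p uses en = n1*n2/(n1+n2) per marker.
    """
    if set(expr.line_ids) != set(genotypes.line_ids):
        raise ValueError("expression and genotype line identifiers differ")
    geno = genotypes.reindex_lines(expr.line_ids)
    if not np.array_equal(geno.marker_ids, gmap.marker_id):
        raise ValueError("genotype markers do not match the genetic map")

    codes = geno.codes  # (lines, markers)
    i1 = codes == B73
    i2 = codes == MO17
    n1 = i1.sum(axis=0)
    n2 = i2.sum(axis=0)
    usable = (np.minimum(n1, n2) >= min_group_size)
    if not usable.any():
        raise ValueError("no usable markers after group-size filtering")

    cols = np.where(usable)[0]
    I1 = i1[:, cols].astype(np.float64)
    I2 = i2[:, cols].astype(np.float64)
    inv1 = 1.0 / n1[cols]
    inv2 = 1.0 / n2[cols]

    n_probes = expr.n_probes
    D = np.empty((n_probes, cols.size))
    for pi in range(n_probes):
        e = expr.values[pi]
        order = np.argsort(e, kind="stable")
        v = e[order]
        valid = np.empty(v.size, dtype=bool)
        valid[:-1] = v[:-1] != v[1:]
        valid[-1] = True
        diff = np.cumsum(I1[order], axis=0) * inv1[None, :] \
            - np.cumsum(I2[order], axis=0) * inv2[None, :]
        D[pi] = np.abs(diff[valid]).max(axis=0)

    en = n1[cols] * n2[cols] / (n1[cols] + n2[cols])
    p = kolmogorov(np.sqrt(en)[None, :] * D)
    np.clip(p, P_FLOOR, 1.0, out=p)

    return ScanResult(
        probe_ids=expr.probe_ids.copy(),
        marker_id=gmap.marker_id[cols],
        chromosome=gmap.chromosome[cols],
        position_cM=gmap.position_cM[cols],
        D=D,
        p=p,
        n_b73=n1[cols],
        n_mo17=n2[cols],
        skipped_markers=gmap.marker_id[~usable],
    )


def scan_probe(expr_row: np.ndarray, genotypes: GenotypeMatrix,
               gmap: GeneticMap, min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
               probe_id="probe") -> ScanProfile:
    """Scan a single probe's intensities against all usable markers."""
    expr_row = np.asarray(expr_row, dtype=float)
    if expr_row.size != genotypes.n_lines:
        raise ValueError("expression row length does not match lines")
    expr = ExpressionMatrix(np.array([probe_id], dtype=object),
                            genotypes.line_ids.copy(), expr_row[None, :])
    return scan_matrix(expr, genotypes, gmap, min_group_size).profile(probe_id)


def assign_peak(profile: ScanProfile, threshold: float,
                mask: Optional[np.ndarray] = None,
                chrom_order: Optional[dict] = None) -> Optional[EQTLPeak]:
    """The probe's single most significant marker, if it clears ``threshold``.

    ``mask`` marks markers to exclude (used by the cooperative search).
    Ties on p break deterministically by (chromosome order, lowest cM,
    marker_id); chromosome order defaults to order of appearance in the map.
    """
    if len(profile) == 0:
        raise ValueError("empty scan profile")
    p = profile.p
    eligible = np.ones(len(profile), dtype=bool) if mask is None else ~mask
    if not eligible.any():
        return None
    pmin = p[eligible].min()
    if pmin > threshold:
        return None
    ties = np.where(eligible & (p == pmin))[0]
    if ties.size > 1:
        if chrom_order is None:
            chrom_order = {}
            for c in profile.chromosome:
                chrom_order.setdefault(c, len(chrom_order))
        key = sorted(
            ties,
            key=lambda j: (chrom_order[profile.chromosome[j]],
                           profile.position_cM[j], str(profile.marker_id[j])),
        )
        j = key[0]
    else:
        j = int(ties[0])
    return EQTLPeak(
        probe_id=profile.probe_id,
        marker_id=profile.marker_id[j],
        chromosome=profile.chromosome[j],
        position_cM=float(profile.position_cM[j]),
        D=float(profile.D[j]),
        p=float(profile.p[j]),
    )


def allele_direction(expr_row: np.ndarray, genotypes: GenotypeMatrix,
                     marker_id) -> str:
    """Which allele class has the higher mean normalized intensity."""
    expr_row = np.asarray(expr_row, dtype=float)
    j = genotypes.marker_index(marker_id)
    codes = genotypes.codes[:, j]
    b = expr_row[codes == B73]
    m = expr_row[codes == MO17]
    if b.size == 0 or m.size == 0:
        raise ValueError(f"marker {marker_id!r}: an allele class is empty")
    if b.mean() == m.mean():
        warnings.warn(
            f"marker {marker_id!r}: exact class-mean tie; calling B73_higher",
            stacklevel=2,
        )
        return B73_HIGHER
    return B73_HIGHER if b.mean() > m.mean() else MO17_HIGHER


def marker_regression_check(expr_row: np.ndarray, genotypes: GenotypeMatrix,
                            marker_id) -> float:
    """Single-marker regression F-test p-value (concordance oracle only).

    Regresses intensity on the 0/1 allele code at one marker; with a single
    regressor the slope t-test equals the F-test.  Degenerate cases (a class
    below 3 lines, or no genotype variance) raise.
    """
    expr_row = np.asarray(expr_row, dtype=float)
    j = genotypes.marker_index(marker_id)
    codes = genotypes.codes[:, j]
    keep = codes != MISSING
    x = codes[keep].astype(float)
    y = expr_row[keep]
    n_b = int((x == B73).sum())
    n_m = int((x == MO17).sum())
    if min(n_b, n_m) < 3:
        raise ValueError("both allele classes need at least 3 lines")
    if np.var(x) == 0:
        raise ValueError("degenerate genotype variance at marker")
    res = stats.linregress(x, y)
    p = res.pvalue
    if not np.isfinite(p):
        # perfect separation: zero residual variance -> p underflows
        resid = y - (res.intercept + res.slope * x)
        if np.allclose(resid, 0.0):
            return 0.0
        raise ValueError("regression p-value undefined")
    return float(p)


def assign_peaks_table(scan: ScanResult, expr: ExpressionMatrix,
                       genotypes: GenotypeMatrix, threshold: float):
    """Assign one peak per probe (threshold applied) with direction calls.

    Returns a pandas DataFrame with columns probe_id, marker_id, chrom, cM,
    D, p, direction, rank.
    """
    import pandas as pd

    geno = genotypes.reindex_lines(expr.line_ids)
    idx, pmin = scan.min_p_table()
    rows = []
    for i, (j, pv) in enumerate(zip(idx, pmin)):
        if pv > threshold:
            continue
        profile = ScanProfile(
            probe_id=scan.probe_ids[i], marker_id=scan.marker_id,
            chromosome=scan.chromosome, position_cM=scan.position_cM,
            D=scan.D[i], p=scan.p[i], n_b73=scan.n_b73, n_mo17=scan.n_mo17,
            skipped_markers=scan.skipped_markers,
        )
        peak = assign_peak(profile, threshold)
        peak.direction = allele_direction(expr.values[i], geno, peak.marker_id)
        rows.append(
            (peak.probe_id, peak.marker_id, peak.chromosome, peak.position_cM,
             peak.D, peak.p, peak.direction, peak.rank)
        )
    return pd.DataFrame(
        rows,
        columns=["probe_id", "marker_id", "chrom", "cM", "D", "p",
                 "direction", "rank"],
    )


def best_peaks_table(scan: ScanResult):
    """Per-probe minimum-p marker regardless of threshold (for validation)."""
    import pandas as pd

    idx, pmin = scan.min_p_table()
    return pd.DataFrame(
        {
            "probe_id": scan.probe_ids,
            "marker_id": scan.marker_id[idx],
            "chrom": scan.chromosome[idx],
            "cM": scan.position_cM[idx],
            "D": scan.D[np.arange(len(idx)), idx],
            "p": pmin,
        }
    )
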