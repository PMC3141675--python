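"""False-positive diagnostics for the eQTL scan.

Two diagnostics are implemented:

1. Allele-direction estimator of the false-cis fraction.  Probes are mostly
   designed from the B73 reference; sequence polymorphism under a probe
   suppresses hybridization of the Mo17 allele, so artifact-driven cis-eQTL
   are always B73-higher, while genuine cis regulation has no preferred
   direction.  If a fraction f of cis-eQTL is Mo17-higher, the model
   "true cis split 50/50 by direction, false cis always B73-higher" gives
   the false-positive fraction q = 1 - 2f.  The study's observed f = 0.324
   yields q = 0.352, i.e. about 35%.

2. Power-law threshold heuristic.  The cumulative count N(p) = #{p_i <= p}
   of per-probe minimum scan p-values is, for pure noise, a power law in p
   (exponent 1.0 for uniform p-values; genetic linkage between markers
   flattens it).  Fitting log10 N against log10 p over the noise region and
   locating where the data rise above the fit marks the p-value where real
   signal takes over -- a data-driven significance threshold.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .kscan import MO17_HIGHER

DEFAULT_FIT_REGION = (1e-4, 1.0)
DEFAULT_DEVIATION_DECADES = 0.3
DEFAULT_P_BINS = ((0.0, 1e-25), (1e-25, 1.0))


def mo17_higher_fraction(directions: Sequence[str]) -> Tuple[float, float]:
    """Fraction of cis-eQTL with higher Mo17-allele expression.

    Returns (f, binomial two-sided p-value against 0.5).
    """
    dirs = list(directions)
    if len(dirs) == 0:
        raise ValueError("no cis peaks supplied")
    k = sum(d == MO17_HIGHER for d in dirs)
    f = k / len(dirs)
    pval = stats.binomtest(k, len(dirs), 0.5).pvalue
    return f, float(pval)


def estimate_false_positive_rate(f: float) -> float:
    """False-cis fraction q = clamp(1 - 2f, 0, 1) from the direction model.

    Assumes genuine cis-eQTL are direction-symmetric and artifact cis-eQTL
    are always B73-higher.  f > 0.5 violates the model; returns 0 with a
    warning.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be a fraction in [0, 1]")
    if f > 0.5:
        warnings.warn(
            f"Mo17-higher fraction {f:.3f} > 0.5 violates the direction "
            "model; returning 0",
            stacklevel=2,
        )
        return 0.0
    return float(np.clip(1.0 - 2.0 * f, 0.0, 1.0))


def stratified_direction_analysis(cis_peaks: pd.DataFrame,
                                  p_bins: Sequence[Tuple[float, float]] = DEFAULT_P_BINS
                                  ) -> pd.DataFrame:
    """Direction fraction and FP estimate within disjoint p-value bins.

    ``cis_peaks`` needs columns p and direction.  Empty bins report NaN.
    """
    bins = [tuple(b) for b in p_bins]
    for (lo1, hi1) in bins:
        for (lo2, hi2) in bins:
            if (lo1, hi1) != (lo2, hi2) and lo1 < hi2 and lo2 < hi1:
                raise ValueError("p-value bins must be disjoint")
    rows = []
    for lo, hi in bins:
        sel = cis_peaks[(cis_peaks["p"] > lo) & (cis_peaks["p"] <= hi)]
        if len(sel) == 0:
            rows.append((lo, hi, 0, np.nan, np.nan, np.nan))
            continue
        f, pval = mo17_higher_fraction(sel["direction"])
        rows.append((lo, hi, len(sel), f, estimate_false_positive_rate(f), pval))
    return pd.DataFrame(
        rows, columns=["p_lo", "p_hi", "n", "mo17_higher_f", "fp_estimate",
                       "binom_p"],
    )


@dataclass
class PowerLawFit:
    """Power-law fit to the cumulative p-value count on a log-log scale."""

    exponent: float
    intercept: float  # of log10 N at log10 p = 0
    fit_region: Tuple[float, float]
    deviation_threshold: Optional[float]
    goodness: float  # R^2 over the fit region
    n_points: int


def fit_powerlaw_threshold(pvalues: Sequence[float],
                           fit_region: Tuple[float, float] = DEFAULT_FIT_REGION,
                           deviation_decades: float = DEFAULT_DEVIATION_DECADES,
                           min_fit_points: int = 50) -> PowerLawFit:
    """Fit log10 N(p) ~ log10 p over the noise region; find the signal tail.

    N(p) = #{p_i <= p} is evaluated at the sorted p-values.  The least
    squares fit runs over ``fit_region`` (default [1e-4, 1], the regime
    dominated by null probes).  ``deviation_threshold`` is the largest
    p-value below the fit region where the observed log10 N exceeds the
    fitted line by more than ``deviation_decades``; None when the data never
    depart (e.g. pure uniform noise).
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    if p.size < 100:
        raise ValueError("need at least 100 p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    n_cum = np.arange(1, p.size + 1, dtype=float)

    lo, hi = fit_region
    in_fit = (p >= lo) & (p <= hi)
    if in_fit.sum() < min_fit_points:
        raise ValueError(
            f"only {int(in_fit.sum())} p-values in fit region [{lo:g}, {hi:g}]"
        )
    x = np.log10(p[in_fit])
    y = np.log10(n_cum[in_fit])
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all p-values identical in fit region")
    res = stats.linregress(x, y)
    exponent, intercept = float(res.slope), float(res.intercept)
    goodness = float(res.rvalue ** 2)

    deviation = None
    below = p < lo
    if below.any():
        excess = np.log10(n_cum[below]) - (intercept + exponent * np.log10(p[below]))
        over = np.where(excess > deviation_decades)[0]
        if over.size:
            deviation = float(p[below][over[-1]])  # largest departing p
    return PowerLawFit(
        exponent=exponent,
        intercept=intercept,
        fit_region=(float(lo), float(hi)),
        deviation_threshold=deviation,
        goodness=goodness,
        n_points=int(in_fit.sum()),
    )
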