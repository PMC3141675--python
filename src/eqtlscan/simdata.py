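"""Synthetic intermated doubled-haploid populations and microarray expression.

The generator emulates the study design the scan is built for: a maize-style
B73 x Mo17 population taken through ten generations of random intermating and
then fixed as doubled-haploid (DH) lines (135 lines, 1,731 SNP markers by
default), profiled with single-color microarray intensities that carry
intensity-dependent noise and a background floor, with cis- and trans-acting
genetic effects planted on known probes.

Three probe-level artifact mechanisms seen on real arrays are reproduced:

* ``polymorphic`` -- sequence polymorphism under the probe suppresses
  hybridization of Mo17-allele transcripts, so Mo17-carrying lines lose signal
  regardless of true expression.  Downstream this masquerades as a strong
  B73-higher cis-eQTL.
* ``pav`` -- presence/absence variation: the gene is deleted from the Mo17
  genome, so Mo17-allele lines report background only (an on/off cis signal).
* ``crosshyb`` -- the probe also hybridizes a hidden paralog elsewhere in the
  genome; if the paralog is cis-regulated the probe shows an apparent
  trans-eQTL at the paralog's locus.

Meiosis is modeled as Poisson crossovers with no interference (Haldane's map
function).  At marker resolution this is realized exactly as independent
Bernoulli recombinations between adjacent markers with Haldane's r, which is
equivalent to sampling crossover points and taking parities.

Every draw is governed by ``SimConfig.seed``; the same config and seed give
bit-identical outputs.  A truth table records every planted effect and
artifact for parameter-recovery tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .containers import B73, MO17, MISSING, ExpressionMatrix, GeneticMap, GenotypeMatrix

MAP_RESOLUTION_CM = 0.01

TRUTH_COLUMNS = [
    "probe_id",
    "gene_chrom",
    "gene_cM",
    "locus_chrom",
    "locus_cM",
    "mode",
    "fold",
    "high_allele",
    "baseline",
    "artifact",
    "paralog_chrom",
    "paralog_cM",
    "paralog_fold",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults mirror the emulated study: 135 DH lines genotyped at 1,731 SNP
    markers on 10 chromosomes, derived from 10 generations of intermating.
    Intensities are single-color with additive + proportional Gaussian noise
    and a nonzero background; about 20% of probes measure background only.
    """

    n_lines: int = 135
    n_markers: int = 1731
    n_chromosomes: int = 10
    chrom_length_cM: Union[float, Sequence[float]] = 180.0
    n_intermating_generations: int = 10
    intermating_pop_size: int = 250
    n_probes: int = 2000
    n_cis_effects: int = 600
    n_trans_effects: int = 200
    effect_size_fold: Union[float, tuple] = (2.0, 9.0)
    baseline_intensity: float = 500.0
    baseline_log_sd: float = 0.6
    frac_background_probes: float = 0.2
    noise_sigma_mult: float = 0.2
    noise_sigma_add: float = 20.0
    background_level: float = 50.0
    array_gain_sd: float = 0.1
    array_offset_sd: float = 10.0
    frac_polymorphic_probes: float = 0.0
    polymorphic_attenuation: float = 0.1
    pav_region: Optional[tuple] = None  # (chromosome, lo_cM, hi_cM)
    n_crosshyb_probes: int = 0
    missing_genotype_rate: float = 0.01
    marker_placement: str = "even"  # "even" or "uniform"
    min_trans_distance_cM: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lines", "n_markers", "n_chromosomes", "n_probes",
                     "intermating_pop_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_intermating_generations < 0:
            raise ValueError("n_intermating_generations must be >= 0")
        for name in ("frac_background_probes", "frac_polymorphic_probes",
                     "missing_genotype_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sigma_add < 0 or self.noise_sigma_mult < 0:
            raise ValueError("noise scales must be nonnegative")
        if self.background_level < 0:
            raise ValueError("background_level must be nonnegative")
        if self.marker_placement not in ("even", "uniform"):
            raise ValueError("marker_placement must be 'even' or 'uniform'")
        lengths = self.chromosome_lengths()
        if any(l <= 0 for l in lengths):
            raise ValueError("chromosome lengths must be positive")

    def chromosome_lengths(self) -> list:
        if np.isscalar(self.chrom_length_cM):
            return [float(self.chrom_length_cM)] * self.n_chromosomes
        lengths = [float(x) for x in self.chrom_length_cM]
        if len(lengths) != self.n_chromosomes:
            raise ValueError(
                f"chrom_length_cM gives {len(lengths)} lengths for "
                f"{self.n_chromosomes} chromosomes"
            )
        return lengths

    def fold_range(self) -> tuple:
        if np.isscalar(self.effect_size_fold):
            f = float(self.effect_size_fold)
            if f <= 0:
                raise ValueError("effect_size_fold must be positive")
            return (f, f)
        lo, hi = (float(x) for x in self.effect_size_fold)
        if lo <= 0 or hi < lo:
            raise ValueError("effect_size_fold range must be positive and ordered")
        return (lo, hi)


# ---------------------------------------------------------------------------
# genetic map


def simulate_map(config: SimConfig) -> GeneticMap:
    """Place markers across chromosomes proportionally to their lengths.

    Placement is even (endpoints included) or uniform at random on a 0.01 cM
    grid, per ``config.marker_placement``.  Raises if a chromosome would need
    more markers than there are distinct grid positions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    lengths = np.asarray(config.chromosome_lengths())
    # largest-remainder allocation, at least proportional
    quota = config.n_markers * lengths / lengths.sum()
    alloc = np.floor(quota).astype(int)
    rem = config.n_markers - alloc.sum()
    if rem > 0:
        order = np.argsort(-(quota - alloc), kind="stable")
        alloc[order[:rem]] += 1

    marker_ids, chroms, positions = [], [], []
    for ci, (L, k) in enumerate(zip(lengths, alloc), start=1):
        if k == 0:
            continue
        n_grid = int(round(L / MAP_RESOLUTION_CM)) + 1
        if k > n_grid:
            raise ValueError(
                f"chromosome {ci}: {k} markers requested but only {n_grid} "
                f"distinct positions at {MAP_RESOLUTION_CM} cM resolution"
            )
        if config.marker_placement == "even":
            pos = np.linspace(0.0, L, k)
        else:
            pos = rng.choice(n_grid, size=k, replace=False) * MAP_RESOLUTION_CM
            pos.sort()
        pos = np.round(pos / MAP_RESOLUTION_CM) * MAP_RESOLUTION_CM
        # rounding of even placement can collide only if k > n_grid (excluded)
        pos = np.unique(pos)
        while len(pos) < k:  # defensive: refill any rounding collisions
            extra = rng.choice(n_grid, size=k - len(pos), replace=False)
            pos = np.unique(np.concatenate([pos, extra * MAP_RESOLUTION_CM]))
        chrom = f"chr{ci}"
        for j, p in enumerate(pos, start=1):
            marker_ids.append(f"m{ci}_{j:05d}")
            chroms.append(chrom)
            positions.append(float(p))
    return GeneticMap(np.array(marker_ids, dtype=object),
                      np.array(chroms, dtype=object),
                      np.array(positions))


# ---------------------------------------------------------------------------
# population


def _switch_probabilities(gmap: GeneticMap) -> np.ndarray:
    """Per-marker haplotype-switch probability for one meiosis.

    Within a chromosome the probability of switching parental haplotype
    between adjacent markers is Haldane's recombination fraction
    r = (1 - exp(-2d/100)) / 2 for map distance d cM.  The first marker of
    each chromosome switches with probability 1/2, which makes the starting
    haplotype of every chromosome an independent fair coin after the
    cumulative-parity construction.
    """
    n = gmap.n_markers
    p = np.empty(n)
    prev_chrom = None
    for j in range(n):
        if gmap.chromosome[j] != prev_chrom:
            p[j] = 0.5
            prev_chrom = gmap.chromosome[j]
        else:
            d = gmap.position_cM[j] - gmap.position_cM[j - 1]
            p[j] = 0.5 * (1.0 - math.exp(-2.0 * d / 100.0))
    return p


def _gametes(hapA: np.ndarray, hapB: np.ndarray, switch_p: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per row of (hapA, hapB): Poisson/Haldane meiosis."""
    switches = rng.random(hapA.shape) < switch_p
    chooser = np.cumsum(switches, axis=1) % 2  # 0 -> hapA, 1 -> hapB
    return np.where(chooser == 0, hapA, hapB)


def simulate_dh_population(gmap: GeneticMap, config: SimConfig) -> GenotypeMatrix:
    """Intermate B73 x Mo17 for g generations, then fix lines as DH.

    The F1 population (``intermating_pop_size`` individuals, all B73/Mo17
    heterozygotes) is randomly mated with replacement each generation; each
    offspring is the union of one gamete from each of two randomly chosen
    parents.  After ``n_intermating_generations`` rounds, one gamete is drawn
    per selected final-generation individual and doubled into a DH line, so
    every non-missing call is homozygous.  Missing calls are injected
    completely at random at ``missing_genotype_rate``.
    """
    if config.n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    n_mark = gmap.n_markers
    pop = config.intermating_pop_size
    switch_p = _switch_probabilities(gmap)

    # F1: every individual carries one full B73 and one full Mo17 haplotype
    hapA = np.zeros((pop, n_mark), dtype=np.int8)
    hapB = np.ones((pop, n_mark), dtype=np.int8)

    for _ in range(config.n_intermating_generations):
        mothers = rng.integers(pop, size=pop)
        fathers = rng.integers(pop, size=pop)
        eggs = _gametes(hapA[mothers], hapB[mothers], switch_p, rng)
        sperm = _gametes(hapA[fathers], hapB[fathers], switch_p, rng)
        hapA, hapB = eggs, sperm

    replace = config.n_lines > pop
    chosen = rng.choice(pop, size=config.n_lines, replace=replace)
    codes = _gametes(hapA[chosen], hapB[chosen], switch_p, rng)

    if config.missing_genotype_rate > 0:
        mask = rng.random(codes.shape) < config.missing_genotype_rate
        codes = codes.copy()
        codes[mask] = MISSING

    line_ids = np.array([f"DH{i:04d}" for i in range(1, config.n_lines + 1)],
                        dtype=object)
    return GenotypeMatrix(line_ids, gmap.marker_id.copy(), codes)


# ---------------------------------------------------------------------------
# truth table


def make_truth(gmap: GeneticMap, config: SimConfig) -> pd.DataFrame:
    """Plant effects and artifacts on probes; return the truth table.

    One row per (probe, effect); probes without effects get a single row with
    mode ``none``.  Artifact flags are mutually exclusive per probe and are
    planted on effect-free expressed probes, so the planted signal is purely
    the artifact mechanism.  Gene positions are uniform over the map; cis
    effects sit at the gene's own locus, trans effects at an unlinked locus
    (different chromosome, or >= ``min_trans_distance_cM`` away).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    lengths = np.asarray(config.chromosome_lengths())
    chrom_names = [f"chr{c}" for c in range(1, config.n_chromosomes + 1)]
    n = config.n_probes

    probe_ids = np.array([f"P{i:06d}" for i in range(1, n + 1)], dtype=object)
    gene_chrom_idx = rng.choice(len(lengths), size=n, p=lengths / lengths.sum())
    gene_cM = np.round(rng.random(n) * lengths[gene_chrom_idx], 2)
    gene_chrom = np.array([chrom_names[i] for i in gene_chrom_idx], dtype=object)

    n_bg = int(round(config.frac_background_probes * n))
    expressed = np.ones(n, dtype=bool)
    if n_bg:
        expressed[rng.choice(n, size=n_bg, replace=False)] = False
    baseline = np.where(
        expressed,
        config.baseline_intensity
        * np.exp(rng.normal(0.0, config.baseline_log_sd, size=n)),
        0.0,
    )

    n_eff = config.n_cis_effects + config.n_trans_effects
    candidates = np.where(expressed)[0]
    if n_eff > candidates.size:
        raise ValueError(
            f"{n_eff} effects requested but only {candidates.size} expressed probes"
        )
    eff_probes = rng.choice(candidates, size=n_eff, replace=False)
    cis_probes = eff_probes[: config.n_cis_effects]
    trans_probes = eff_probes[config.n_cis_effects:]

    lo, hi = config.fold_range()

    mode = np.full(n, "none", dtype=object)
    locus_chrom = np.full(n, None, dtype=object)
    locus_cM = np.full(n, np.nan)
    fold = np.ones(n)
    high = np.full(n, None, dtype=object)

    mode[cis_probes] = "cis"
    locus_chrom[cis_probes] = gene_chrom[cis_probes]
    locus_cM[cis_probes] = gene_cM[cis_probes]

    mode[trans_probes] = "trans"
    for i in trans_probes:
        while True:
            ci = rng.integers(len(lengths))
            pos = round(float(rng.random() * lengths[ci]), 2)
            if chrom_names[ci] != gene_chrom[i] or abs(pos - gene_cM[i]) >= (
                config.min_trans_distance_cM
            ):
                break
        locus_chrom[i] = chrom_names[ci]
        locus_cM[i] = pos

    fold[eff_probes] = rng.uniform(lo, hi, size=n_eff)
    high[eff_probes] = np.where(rng.random(n_eff) < 0.5, "B73", "Mo17")

    # artifacts: mutually exclusive, on effect-free probes whose gene is
    # clearly expressed -- hybridization loss, deletion on/off contrast and
    # paralog cross-talk all presuppose signal well above background
    artifact = np.full(n, "none", dtype=object)
    paralog_chrom = np.full(n, None, dtype=object)
    paralog_cM = np.full(n, np.nan)
    paralog_fold = np.full(n, np.nan)

    free = [i for i in np.where(expressed)[0]
            if mode[i] == "none" and baseline[i] >= 2.0 * config.background_level]
    rng.shuffle(free)
    free = list(free)

    n_poly = int(round(config.frac_polymorphic_probes * n))
    if n_poly > len(free):
        raise ValueError("not enough effect-free expressed probes for "
                         "polymorphic artifacts")
    for i in free[:n_poly]:
        artifact[i] = "polymorphic"
    free = free[n_poly:]

    if config.pav_region is not None:
        pchrom, lo_cM, hi_cM = config.pav_region
        for i in list(free):
            if (gene_chrom[i] == pchrom and lo_cM <= gene_cM[i] <= hi_cM):
                artifact[i] = "pav"
                free.remove(i)

    if config.n_crosshyb_probes > len(free):
        raise ValueError("not enough effect-free expressed probes for "
                         "cross-hybridization artifacts")
    for i in free[: config.n_crosshyb_probes]:
        artifact[i] = "crosshyb"
        while True:
            ci = rng.integers(len(lengths))
            if chrom_names[ci] != gene_chrom[i]:
                break
        paralog_chrom[i] = chrom_names[ci]
        paralog_cM[i] = round(float(rng.random() * lengths[ci]), 2)
        paralog_fold[i] = hi

    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_chrom": gene_chrom,
            "gene_cM": gene_cM,
            "locus_chrom": locus_chrom,
            "locus_cM": locus_cM,
            "mode": mode,
            "fold": fold,
            "high_allele": high,
            "baseline": baseline,
            "artifact": artifact,
            "paralog_chrom": paralog_chrom,
            "paralog_cM": paralog_cM,
            "paralog_fold": paralog_fold,
        }
    )


def probe_annotation(truth: pd.DataFrame) -> pd.DataFrame:
    """Probe annotation table derived from the truth table.

    All probes are flagged unique with known positions; note that
    cross-hybridizing probes are deliberately *still* flagged unique -- the
    hidden paralog is invisible to the sequence-level uniqueness check, which
    is exactly how the false-trans artifact arises.
    """
    return pd.DataFrame(
        {
            "probe_id": truth["probe_id"],
            "chromosome": truth["gene_chrom"],
            "position_cM": truth["gene_cM"],
            "unique_flag": True,
            "position_known": True,
        }
    ).drop_duplicates("probe_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# expression


def _high_allele_mask(genotypes: GenotypeMatrix, gmap: GeneticMap,
                      chrom, cM: float, high_allele: str) -> np.ndarray:
    """Boolean per line: carries the high allele at the nearest marker.

    Missing genotype calls at the causal marker count as low-allele carriers
    (they get no fold boost), a conservative convention.
    """
    j = gmap.nearest_marker(chrom, cM)
    code = B73 if high_allele == "B73" else MO17
    return genotypes.codes[:, j] == code


def _check_loci_in_range(truth: pd.DataFrame, gmap: GeneticMap) -> None:
    limits = {}
    for chrom in gmap.chromosomes:
        pos = gmap.position_cM[gmap.chromosome == chrom]
        limits[chrom] = (pos.min(), pos.max())
    for _, row in truth[truth["mode"] != "none"].iterrows():
        chrom = row["locus_chrom"]
        if chrom not in limits:
            raise ValueError(
                f"probe {row['probe_id']}: causal locus chromosome {chrom!r} "
                "absent from map"
            )


def simulate_expression(genotypes: GenotypeMatrix, gmap: GeneticMap,
                        truth: pd.DataFrame, config: SimConfig,
                        replicate_seed: int) -> ExpressionMatrix:
    """Single-color intensities for one biological replicate.

    Per line: intensity = background + baseline * prod(fold over causal loci
    whose allele is the high allele), perturbed by additive Gaussian noise
    (sd ``noise_sigma_add``), proportional Gaussian noise
    (sd ``noise_sigma_mult`` x intensity) and an optional per-array affine
    distortion (gain/offset), floored at zero.  Two calls with different
    ``replicate_seed`` share the truth (including baselines) but not noise.
    """
    if config.noise_sigma_add < 0 or config.noise_sigma_mult < 0:
        raise ValueError("noise scales must be nonnegative")
    _check_loci_in_range(truth, gmap)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 404, int(replicate_seed)])
    )
    probe_ids = truth["probe_id"].drop_duplicates().to_numpy(dtype=object)
    probe_pos = {p: i for i, p in enumerate(probe_ids)}
    n_probes, n_lines = len(probe_ids), genotypes.n_lines

    base = np.zeros(n_probes)
    for pid, grp in truth.groupby("probe_id", sort=False):
        base[probe_pos[pid]] = grp["baseline"].iloc[0]

    foldmat = np.ones((n_probes, n_lines))
    for _, row in truth[truth["mode"] != "none"].iterrows():
        mask = _high_allele_mask(genotypes, gmap, row["locus_chrom"],
                                 row["locus_cM"], row["high_allele"])
        foldmat[probe_pos[row["probe_id"]], mask] *= row["fold"]

    signal = config.background_level + base[:, None] * foldmat
    values = (
        signal
        + rng.normal(0.0, config.noise_sigma_add, size=signal.shape)
        + rng.normal(0.0, 1.0, size=signal.shape) * config.noise_sigma_mult * signal
    )
    if config.array_gain_sd > 0 or config.array_offset_sd > 0:
        gains = np.exp(rng.normal(0.0, config.array_gain_sd, size=n_lines))
        offsets = rng.normal(0.0, config.array_offset_sd, size=n_lines)
        values = values * gains[None, :] + offsets[None, :]
    np.maximum(values, 0.0, out=values)
    return ExpressionMatrix(probe_ids, genotypes.line_ids.copy(), values)


def inject_probe_artifacts(expr: ExpressionMatrix, genotypes: GenotypeMatrix,
                           gmap: GeneticMap, truth: pd.DataFrame,
                           config: SimConfig,
                           replicate_seed: int = 0) -> ExpressionMatrix:
    """Apply the planted probe artifacts to an expression matrix.

    polymorphic: Mo17-allele lines (at the probe's own locus) lose signal by
    ``polymorphic_attenuation``, independent of true expression.
    pav: Mo17-allele lines report background plus additive noise only.
    crosshyb: the probe's signal gains a hidden paralog's cis-regulated
    signal (B73-high by convention) driven by an unlinked locus.
    """
    out = expr.copy()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 505, int(replicate_seed)])
    )
    flagged = truth[truth["artifact"] != "none"].drop_duplicates("probe_id")
    for _, row in flagged.iterrows():
        if row["gene_chrom"] is None or not np.isfinite(row["gene_cM"]):
            raise ValueError(
                f"artifact probe {row['probe_id']} lacks a genomic position"
            )
        i = out.probe_index(row["probe_id"])
        kind = row["artifact"]
        if kind == "polymorphic":
            mo17 = _high_allele_mask(genotypes, gmap, row["gene_chrom"],
                                     row["gene_cM"], "Mo17")
            out.values[i, mo17] *= config.polymorphic_attenuation
        elif kind == "pav":
            mo17 = _high_allele_mask(genotypes, gmap, row["gene_chrom"],
                                     row["gene_cM"], "Mo17")
            noise = rng.normal(0.0, config.noise_sigma_add, size=mo17.sum())
            out.values[i, mo17] = np.maximum(config.background_level + noise, 0.0)
        elif kind == "crosshyb":
            high = _high_allele_mask(genotypes, gmap, row["paralog_chrom"],
                                     row["paralog_cM"], "B73")
            pf = row["paralog_fold"] if np.isfinite(row["paralog_fold"]) else 6.0
            par = config.baseline_intensity * np.where(high, pf, 1.0)
            par = par + rng.normal(0.0, 1.0, par.shape) * config.noise_sigma_mult * par
            out.values[i, :] = np.maximum(out.values[i, :] + par, 0.0)
        else:  # pragma: no cover - truth construction forbids this
            raise ValueError(f"unknown artifact kind {kind!r}")
    return out


# ---------------------------------------------------------------------------
# truth I/O


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the truth table as TSV (round-trips losslessly)."""
    truth.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str}, na_values=["NA"],
                     keep_default_na=False)
    for col in ("gene_chrom", "locus_chrom", "mode", "high_allele", "artifact",
                "paralog_chrom"):
        if col in df:
            df[col] = df[col].where(df[col].notna(), None).astype(object)
    return df


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class SimDataset:
    config: SimConfig
    gmap: GeneticMap
    genotypes: GenotypeMatrix
    truth: pd.DataFrame
    annotation: pd.DataFrame
    replicates: list = field(default_factory=list)


def simulate_dataset(config: SimConfig, n_replicates: int = 2) -> SimDataset:
    """Generate map, population, truth, annotation and replicate intensities."""
    gmap = simulate_map(config)
    genotypes = simulate_dh_population(gmap, config)
    truth = make_truth(gmap, config)
    annot = probe_annotation(truth)
    reps = []
    for k in range(1, n_replicates + 1):
        expr = simulate_expression(genotypes, gmap, truth, config, replicate_seed=k)
        expr = inject_probe_artifacts(expr, genotypes, gmap, truth, config,
                                      replicate_seed=k)
        reps.append(expr)
    return SimDataset(config, gmap, genotypes, truth, annot, reps)
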