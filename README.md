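# eqtlscan

Genome-wide expression QTL (eQTL) mapping for intermated doubled-haploid (DH)
populations, built around the analysis design used for maize B73 × Mo17
genetical-genomics studies: single-color microarray intensities per line are
normalized on the intensity scale, every probe is tested against every SNP
marker with the two-sample Kolmogorov–Smirnov test, one eQTL is assigned per
probe, and the resulting peaks are classified cis/trans, validated across
biological replicates, searched for cooperative secondary loci, and screened
for the false positives that incomplete parental genome sequences create.

## Who this is for

Quantitative geneticists and statistical-genomics developers who want a
tested, deterministic re-implementation of a classical marker-by-marker eQTL
scan — including the population simulator needed to validate it — rather than
an interval-mapping or mixed-model package.

## The method

For probe $g$ and marker $m$, lines are split by their fixed parental allele
($B$ = B73, $M$ = Mo17) and compared by the two-sample KS statistic

$$D_{gm} = \sup_x \left| \hat F_{g,B}(x) - \hat F_{g,M}(x) \right|,$$

with two-sided p-value from the exact permutation null for small groups and
otherwise from the asymptotic Kolmogorov distribution at effective sample
size $n_B n_M / (n_B + n_M)$. Each probe's single most significant marker is
its eQTL if $p \le 10^{-6}$; peaks within 10 cM of the measured gene on the
same chromosome are cis-acting, all others trans-acting. Replicate-1 eQTL
are validated when replicate 2's strongest marker reaches $p \le 10^{-5}$
within the same 10 cM window. Masking each accepted peak's ±10 cM region and
re-scanning yields secondary and tertiary (cooperative) eQTL, at most three
per probe.

Two false-positive diagnostics are included. Probes are designed from the
B73 reference, so probe-sequence polymorphism silences the Mo17 allele and
fakes a B73-higher cis-eQTL; with genuine cis effects direction-symmetric,
an observed Mo17-higher fraction $f$ among cis-eQTL implies a false-cis
fraction $q = 1 - 2f$. Separately, the cumulative count of per-probe minimum
p-values is fit with a power law over its noise region ($p \in [10^{-4},1]$;
exponent 1.0 for independent uniform p-values, flatter under marker linkage)
and the p-value where the data depart from the fit marks a data-driven
significance threshold.

The `simdata` module generates matched synthetic data: 135 DH lines from 10
generations of random intermating (Poisson-crossover meiosis, Haldane's map
function), 1,731 SNP markers by default, intensities with additive plus
proportional noise and a ~20% background floor, planted cis/trans effects
with 2–9 fold allele contrast, and the three artifact mechanisms
(probe-polymorphism hybridization loss, presence/absence variation,
cross-hybridizing hidden paralog) with a truth table for recovery tests.

## Worked example

The `analysis/` scripts run the whole chain on a simulated dataset
(1,200 probes × 135 lines × 500 markers, two replicates, all three artifact
mechanisms planted):

```
python analysis/01_simulate.py
python analysis/02_normalize.py
python analysis/03_scan.py
python analysis/04_classify_validate.py
python analysis/05_diagnose.py
python analysis/06_report.py
```

Selected output:

```
replicate 1: 479 probes with an eQTL at p <= 1e-6 (479 at p <= 1e-15)
validation: {'validated': 479, ...} -> {'validated': '100.0%', ...}
classified: 369 cis, 110 trans (strong tier: 100.0% of cis, 100.0% of trans at p <= 1e-15)
cis-eQTL: 369; Mo17-higher fraction f = 0.409 (binomial p vs 0.5: 5.73e-04)
estimated false-cis fraction 1 - 2f = 0.182; planted artifact fraction among cis calls = 0.187
power-law exponent over the noise region: 0.230 ... signal departs below p ~ 3.9e-06
```

Reading this: 479 of 1,200 probes get a primary eQTL in replicate 1 — the
400 planted effects plus the 79 artifact probes — and all of them reproduce
in replicate 2 under this noise model. Among the 369 cis calls the Mo17
allele is higher in only 40.9% of cases; the direction estimator turns that
deficit into an 18.2% false-cis fraction, matching the planted artifact
fraction of 18.7% within binomial error. The power-law diagnostic flags
signal taking over from noise near p ≈ 4×10⁻⁶, close to the classical 10⁻⁵
heuristic for this design, and its exponent 0.23 sits far below the
uniform-null value 1.0 because linked markers make the per-probe minimum
p-values strongly non-independent.

The same pipeline is scriptable end to end (`eqtlscan simulate|normalize|
scan|classify|diagnose|report|run`) with TSV inputs documented in
`eqtlscan.io`.

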