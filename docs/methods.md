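# Methods

## Population model

The simulator targets an intermated B73 × Mo17 doubled-haploid design: an
F1 population of `intermating_pop_size` individuals (default 250) is
randomly mated with replacement for `n_intermating_generations` rounds
(default 10); afterwards one gamete per selected final-generation individual
is doubled into a DH line, so every non-missing genotype call is homozygous
by construction. Missing calls are injected completely at random (default
1%), since no informative missingness mechanism is assumed.

Meiosis is modeled as Poisson crossovers with no interference. At marker
resolution this is realized exactly as independent Bernoulli haplotype
switches between adjacent markers with Haldane's recombination fraction
r = (1 − e^(−2d/100))/2 for map distance d cM — the parity of a Poisson
crossover count in disjoint intervals is independent across intervals, so
the two constructions have identical marker-level laws. This makes an
analytic check available: for two loci d cM apart, the expected recombinant
DH fraction after g intermating generations is 1/2 − (1 − 2r)(1 − r)^g / 2,
and the test suite verifies the simulator against both this closed form and
an independent brute-force gamete tracker that samples literal crossover
counts. Finite intermating populations add genetic drift on top of the
binomial sampling noise (per-marker allele-frequency SD ≈ 0.07 after 10
generations at population size 250); tests that isolate the absence of
systematic allele bias therefore use larger populations where drift is
negligible.

The effective intermating population size behind real intermated-DH panels
is not published; map expansion is matched qualitatively (recombinant
fraction strictly increasing in g), not to a specific reference map.

## Expression model

Single-color intensity for probe g in line l:

    I_gl = background + baseline_g × Π_k fold_k^{[line l carries the high allele at locus k]}
           + N(0, σ_add²) + N(0, (σ_mult · I)²),  floored at 0,

followed by an optional per-array affine distortion (log-normal gain,
Gaussian offset) representing scanner/labeling variation that normalization
is meant to remove. Defaults: baseline median 500 with log-SD 0.6,
background 50, σ_add = 20, σ_mult = 0.2 (a 20% proportional CV, typical for
intensity data), gain log-SD 0.1, offset SD 10. Twenty percent of probes
measure background only, matching the observation that roughly a fifth of
array intensities are background. Effect folds are drawn uniformly from
2–9 per planted effect, the range of allele contrasts this design resolves
comfortably; each effect's high allele is a fair coin, so genuine cis
effects are direction-symmetric — the property the false-positive estimator
relies on. Replicates share the truth table (including baselines) and
differ only in noise draws. Missing genotype calls at a causal marker
contribute no fold (conservative).

Artifacts are planted on effect-free probes whose baseline is at least
twice the background level: all three mechanisms presuppose a clearly
expressed gene (there is nothing to attenuate, delete, or cross-hybridize
otherwise). Probes with near-background baselines are dominated by residual
array effects shared across all weak probes, which is a realistic nuisance
but not the mechanism under test.

* polymorphic probe: Mo17-allele lines (at the probe's own locus) keep 10%
  of their intensity — strong enough to mimic the observed extreme false
  cis signals while staying above background;
* presence/absence variation: Mo17-allele lines are set to background plus
  additive noise (on/off);
* cross-hybridization: the probe's signal gains a hidden paralog's
  cis-regulated signal (B73-high, fold = the top of the fold range) driven
  by a locus on another chromosome, so the probe maps in apparent trans at
  the paralog's position while its sequence-level uniqueness flag remains
  true.

What the generator does not emulate: sequence-level probe/SNP structure,
epistasis, genotype×environment interaction, spatial array defects, and
dye effects (the design is single-color). Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
noise model, not robustness to every failure mode of real arrays.

## Normalization

Data stay on the intensity scale throughout so the intensity-dependent
noise structure remains available to significance estimation. Each array is
first shifted so the mean of its lowest 20% of intensities (the background
fraction, configurable) is zero. Arrays are then brought onto a common
scale by per-array affine transforms fit by weighted least squares against
the per-probe median pseudo-reference, with weights
1/(σ_add² + (σ_mult·I)²); the reference is recomputed and the fits iterated
until the largest relative gain change is below 1e-6 (at most 20
iterations; non-convergence is flagged on the models, not fatal). The
iteration is indeterminate in the common profile's scale and location:
left unpinned, regression dilution (noise in the fitted array) shrinks the
reference a little every round so the gains decay geometrically, and the
compensating rescale amplifies the offsets without bound. Each round
therefore pins the geometric-mean gain to 1 and the mean offset to 0,
which fixes the arbitrary affine gauge, keeps outputs on the input
intensity scale, and gives convergence in about half a dozen iterations at
default noise. Weight parameters default to σ_add estimated from the
background-quantile spread and σ_mult = 0.2 unless supplied. Corrected and
normalized intensities legitimately dip slightly below zero around the
background.

Affine fits need many probes whose expression is genotype-independent;
with only tens of probes, a handful of strongly differential probes can
drag per-array gains into correlation with genotype. Fixtures therefore
use several hundred probes, as any real array would provide.

## The scan

Every probe × marker pair is tested with the two-sample KS statistic on
the allele split (missing genotypes excluded marker-wise). Markers where
either allele class has fewer than 10 usable lines are skipped — without a
floor, tiny groups produce spurious D = 1 peaks. D is evaluated only at
distinct pooled intensity values, handling ties exactly. p-values: for
combined samples ≤ 16 an exact tie-aware lattice-path count of the
permutation null (the in-package implementation; scipy's exact mode
silently falls back to asymptotics for some small splits); otherwise the
asymptotic Kolmogorov distribution at effective sample size
n₁n₂/(n₁+n₂), which at this design's group sizes (~60/75) is slightly
conservative in the deep tail relative to the finite-n distribution.
Reported p-values are floored at 1e-300.

One eQTL per probe: the minimum-p marker, if it clears the identification
threshold (default 1e-6; the validation threshold defaults to 1e-5). Ties
break deterministically by chromosome order, then lowest cM, then marker
id. Allele direction is the comparison of class means on the normalized
intensity scale; an exact tie is called B73-higher with a warning. A
single-marker regression F-test is provided purely as a concordance oracle
and is never used for calling.

Because D is invariant under any common strictly increasing transform,
whether intensities or a monotone transform of them are scanned is
irrelevant to D; the intensity scale matters only for direction calls and
the noise model.

## Classification, validation, cooperative search

Cis means same chromosome and |peak − gene| strictly less than the 10 cM
window; exactly 10 cM (and any other chromosome) is trans, making the cis
window an open interval. Classification is attempted only for probes whose
genomic origin is unique and known; other probes are reported as
unassignable and excluded from mode statistics. Replicate validation uses
the same 10 cM window for "same position" — no tolerance is published, and
re-using the mechanism window is the least arbitrary choice. The
cooperative search masks all markers within 10 cM of every accepted peak
(both sides, closed interval), re-scans, and accepts new minima at the
unchanged 1e-6 threshold, stopping at three peaks per probe. Ranks need not
be monotone in significance between replicates, so only threshold
compliance is asserted for cooperative peaks.

## False-positive diagnostics

Direction estimator: with genuine cis effects direction-symmetric and
artifact cis always B73-higher, an observed Mo17-higher fraction f gives
the false-cis fraction q = clamp(1 − 2f, 0, 1). The functional form is a
reconstruction from this symmetry model (it reproduces the worked pair
f = 0.324 → q ≈ 0.35); f > 0.5 violates the model and returns 0 with a
warning. The estimate is also computed within p-value strata (default:
at or below 1e-25 versus above), since stronger eQTL are more
artifact-prone.

Power-law threshold: the cumulative count N(p) = #{pᵢ ≤ p} of per-probe
minimum p-values is fit as log₁₀N = a + b·log₁₀p over the noise region
(default p ∈ [1e-4, 1]); independent uniform p-values give b = 1,
marker linkage flattens the observed exponent well below 1. The deviation
threshold is the largest p below the fit region where observed log₁₀N
exceeds the fit by more than 0.3 decades (configurable); pure-noise inputs
have none. The pipeline's operating thresholds stay at 1e-6/1e-5
regardless of the fit — the fit is a diagnostic, not a controller.

## Problem sizes and determinism

Recovery suites run at 2,000 probes × 500 markers × 135 lines (and 1,000
probes for the planted-false-cis composition), sizes at which every
planted fold ≥ 2 is comfortably detectable and the whole chain runs in
seconds; the analysis drivers use 1,200 probes with all artifact
mechanisms active. All randomness flows from a single integer seed through
named seed sequences, so identical configurations reproduce bit-identical
outputs; the pipeline writes a manifest with input checksums and per-stage
row counts.

## Known limitations

* The asymptotic KS p-value is an approximation at n = 135; exact finite-n
  p-values are used only for tiny groups. Absolute p-values in the deep
  tail are conservative, which biases no comparison made here.
* The direction estimator assumes all false cis are B73-higher and true
  cis are exactly direction-symmetric; partial hybridization or biased
  regulatory divergence would violate it.
* The cooperative search is greedy and marginal: it masks regions, never
  fits multi-locus models, so linked causal pairs within 10 cM merge.
* Normalization assumes most probes are genotype-independent; arrays where
  a large fraction of probes are strongly differential violate the affine
  fit's premise.
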