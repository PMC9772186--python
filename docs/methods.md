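# Methods

This note documents the models and procedures implemented in `reefcore`, the
assumptions behind them, the defaults that matter, and what the synthetic
data generators do and do not emulate.

## Core densitometry

**Model.** A massive coral skeleton records one high/low density couplet per
year. The input is an evenly sampled 1D density profile ρ(z), z in mm from
the living surface; all intervals are half-open `[start, end)`.

**Band segmentation.** The dominant banding wavelength λ is estimated from
the Hann-windowed power spectrum of the detrended profile, restricted to
periods between 4 samples and half the core. A profile is rejected
("manual review required", mirroring the practice of excluding unreadable
cores) when the power within ±2 bins of the spectral peak holds less than
25% of the in-band total — white noise spreads its power and fails this,
while even strongly noisy banded profiles concentrate 60%+ there. The
profile is then smoothed with a moving average of width λ/4 and band
boundaries are taken at local minima with (a) minimum separation λ/2 and
(b) prominence ≥ 0.3 × the robust amplitude of the smoothed series (the
95th–5th percentile half-range). The prominence floor exists because pure
distance-constrained minima detection promotes noise micro-wiggles on the
flat parts of the annual cycle into spurious boundaries. Each minimum is
finally refined to the local minimum of a lightly smoothed (λ/16) profile
within ±λ/8, because a wide moving average biases trough positions sideways
when adjacent bands differ in width. Profile ends are accepted as
boundaries when the smoothed value there lies within 25% of the trough
level, so cores collected at a year boundary keep their topmost band;
otherwise partial top/bottom years are excluded (incomplete bands bias
extension downward).

**Year assignment.** The topmost complete band is the last complete
calendar year before the collection date; bands count backward from there.

**Growth metrics.** Per band: extension E = (bottom − top)/10 cm yr⁻¹, mean
density D over `[top, bottom)` in g cm⁻³, calcification C = D·E exactly
(g cm⁻² yr⁻¹). Window means default to 1999–2009 inclusive — between the
1998 and 2010 bleaching events — as unweighted means over the band-years
present.

**Stress bands.** A stress band is a maximal run of samples whose density
z-score, against the *whole-core* mean and SD (anomalous regions included —
no iterative re-estimation), strictly exceeds 2, subject to (a) run
thickness ≥ 1 mm and (b) at least one sample in the run whose
density-gradient-magnitude z-score (gradient via central differences,
one-sided at the ends) also exceeds 2. The "gradient" is the magnitude of
the first spatial derivative — the only quantity computable from a 1D
profile without further definition — and the gradient criterion is required
somewhere within the run rather than everywhere: a stress band is a
high-density region with sharp edges, and demanding pointwise conjunction
would make millimetre runs nearly impossible at 2 SD. A constant profile
returns no calls rather than a division error. Calls are attributed to the
calendar year of the band containing their midpoint; midpoints outside all
bands go to the nearest band with a warning. Raising either threshold can
only remove calls (tested property). Presence flags are tri-state: False
requires the core to actually cover the event year, otherwise the colony is
not assessable for that event.

## Thermal regime

**Inputs.** Regular 15–30 min logger series; temperatures outside a
configurable 20–36 °C plausibility band are rejected.

**Weekly climatology.** Mean per ISO calendar week; weeks under 50%
coverage are emitted as missing.

**Band-pass.** Butterworth, order 4, applied forward–backward
(`sosfiltfilt`) for zero phase; pass band 5–36 h by default. The long
cutoff follows the looser of the two conventions in circulation (removal of
variability slower than 36 h rather than 30 h) because the measured transfer
of the 30 h variant passes a 24 h sinusoid at only 94% amplitude — i.e. it
attenuates the very diurnal band the filter exists to isolate — while the
36 h variant passes it at 99.3% and still attenuates an annual sinusoid by
> 99.9%. Both cutoffs and the order are configurable. Gaps ≤ 3 h are
linearly interpolated on the cadence grid; longer gaps split the record
into segments filtered independently; segments shorter than 3× the long
cutoff are skipped with a warning (transients would dominate).

**Daily range.** max − min of the *filtered* series per calendar day; days
under 80% expected samples dropped. Adding a constant to the raw series
does not change it (tested). For a pure sinusoid of amplitude A the daily
range is 2A, which anchors the calibration tests.

**Warm tail.** Per calendar year with ≥ ~11 months of data, the 90th
percentile of raw temperature (linear interpolation between order
statistics), averaged across years per site (per-site-then-average;
pooling across sites first is the other defensible reading of an ambiguous
convention). Timestamps are treated as local standard time throughout; Palau
has no DST.

## Population structure

**Containers.** Genotypes are unordered diploid allele pairs over a
per-locus allele universe (fragment sizes for microsatellites, REF/ALT for
SNPs); homozygotes are doubled alleles; missing cells contribute nothing to
any likelihood or frequency sum (no imputation outside PCA).

**Microsatellite curation** (cells with > 2 called alleles), applied
per sample × locus:

1. with replicate runs, alleles seen in only one run are dropped;
2. in single-run cells, alleles with peak height below half the
   second-highest peak are dropped (the two tallest peaks always survive);
3. any cell still ambiguous keeps the two alleles most frequent in the
   whole dataset (rarest dropped — the choice least likely to bias toward
   isolated populations), with frequencies computed in a first pass over
   unambiguous cells only (two-pass scheme: dataset-wide frequencies must
   exist before ambiguous cells are resolved). Ties break by peak height,
   then smaller fragment size, for determinism.

Curation is idempotent (tested). Cells with no surviving allele become
missing and are logged.

**Missingness filters.** Loci with > 40% missing cells are removed first;
samples genotyped at fewer than 10 of the *remaining* loci are then
removed. Removed + retained always reconciles with the input (tested).

**Admixture model.** Each individual i has ancestry proportions q_i over K
source populations with per-locus allele frequencies p_k; each gene copy at
locus l is allele a with probability Σ_k q_ik p_kla. The log-likelihood is
maximized by EM (block-relaxation of Q and P), a deterministic-at-seed,
desk-scale replacement for MCMC-based clustering: same Q/P parameterization,
best of `n_restarts` random restarts by final log-likelihood, convergence
when the log-likelihood gain drops below `tol` (default 1e-3; parameter
recovery experiments use 1e-4 with `max_iter` 2000). The trace is
monotone non-decreasing (tested); non-convergence returns a flagged result.
Allele frequencies are floored at 1e-9 to keep the likelihood finite. A
simple BIC curve over K (`admixture_k_scan`) stands in for full best-K
machinery. Label switching is resolved by maximum-agreement bipartite
assignment (Hungarian algorithm) against a reference — the truth labels in
simulations, or the partner labeling in concordance calculations.

**Lineage assignment.** argmax_k Q_ik if it strictly exceeds 0.5, else
"admixed". Admixed individuals are excluded from lineage-based statistics
and from concordance numerators (counted separately).

**Nei's FST.** For each group pair, per polymorphic locus:
Hs = mean over the two groups of the sample-size-corrected gene diversity
(2n/(2n−1))(1 − Σ p²), and Ht = 1 − Σ p̄² + Hs/(4ñ) with p̄ the unweighted
mean of the two group frequency vectors and ñ their harmonic mean sample
size (Nei & Chesser-style corrections, so two samples from one population
give FST centered on zero; small negative estimates are possible and left
unclipped). Multi-locus FST = 1 − ΣHs/ΣHt over loci polymorphic in the
pooled pair; pairs with no polymorphic locus report 0; percentile CIs come
from bootstrap over loci (default 100 resamples, seeded). Exact numerical
identity with any particular legacy implementation is not claimed; the
estimator is pinned instead by a longhand oracle on small instances.

**PCA.** One-hot allele counts per locus-allele column; missing cells
mean-imputed per column; columns centered, scaled, zero-variance dropped;
SVD. Coordinates are reproducible up to sign.

## Trait statistics

One-way fixed-effects ANOVA (F, df = (k−1, N−k)); Tukey–Kramer HSD for
unequal n; k×2 Pearson chi-squared on stress-band presence with df = k−1,
Yates continuity correction applied to 2×2 tables by default (configurable,
and the uncorrected variant is a parameter away, since which convention a
given historical analysis used is often unknowable). Expected cells below 1
attach a warning; degenerate tables with no variation report X² = 0, p = 1.
Colonies whose cores do not reach an event year are excluded from that
year's prevalence denominator. No multiple-testing adjustment beyond Tukey
within each ANOVA. The full report battery covers: lineage ANOVAs + Tukey
for density/calcification/extension, lineage prevalence tests per event
year, lineage × habitat ANOVAs + Tukey for the lineages present in both
habitats, and per-lineage habitat prevalence tests.

Published-style supplementary tables (a per-core growth table and a
per-core × year strata table) are ingested through a declarative column
mapping, so the same battery can be pointed at deposited data files whose
headers differ from ours.

## Synthetic data

The generators define the study conditions for every test; none of the
paper's raw data ships with the package.

* **Cores.** Density = mean + annual sinusoid (one cycle per year, troughs
  at year boundaries, mapped through cumulative extension so band width
  tracks extension rate) + iid Gaussian noise. Defaults: mean 1.2 g cm⁻³,
  amplitude 0.15 g cm⁻³, spacing 0.1 mm, 1.0 cm yr⁻¹. A stress event adds a
  flat-topped tapered-cosine (Tukey window, taper fraction 0.5) anomaly of
  stated thickness (support width) whose peak is the stated multiple of the
  clean-profile SD √(A²/2 + σ²). The flat top reflects what a stress band
  is — a uniformly elevated-density layer with tapered edges — and keeps
  the above-threshold run close to the nominal thickness; a single-peaked
  bump of nominal amplitude 3 SD would exceed a 2 SD threshold over only
  ~⅓ of its support and make millimetre-scale detection of marginal events
  impossible by construction.
* **Loggers.** T(t) = site mean + seasonal sinusoid (365.25 d) + diurnal
  sinusoid (24 h) + iid noise + windowed offsets. The study-contrast
  defaults put the Rock Island analogue at 30.29 °C mean with 0.30 °C
  diurnal amplitude and the outer reef at 29.11 °C with 0.16 °C, which
  reproduce the observed orderings of mean, daily range and warm tail.
* **Genotypes.** Balding–Nichols: ancestral frequencies uniform(0.1, 0.9)
  (biallelic) or Dirichlet (multiallelic); per-population frequencies drawn
  with drift parameter calibrated to 2F/(1+F) so that the *realized
  pairwise* Nei's FST between populations equals the requested
  `divergence_F` (two populations with raw drift F′ have expected pairwise
  Nei's FST F′/(2−F′), so the raw parameterization would understate the
  requested divergence roughly twofold). Admixed individuals draw each gene
  copy from a population chosen by a Dirichlet(1) ancestry vector;
  missingness is uniform at random — the simplest null for filter testing.
* **Cohorts.** Each colony gets a lineage, a habitat (Bernoulli,
  configurable per lineage), genotypes from its lineage, and a core from
  its lineage's template with colony-level variation (SD 0.12 g cm⁻³ in
  mean density, 0.12 cm yr⁻¹ in extension — colonies of a lineage are not
  clones, and without this spread group contrasts would have unrealistically
  degenerate within-group variance) plus a 1998 stress event sampled at the
  lineage × habitat probability. The default stress probabilities for the
  four-lineage scenario are 0.68/0.22/0.17/0.25 (DB/LB/PI/RD).

**What the generators do not emulate:** sub-annual density structure,
bioerosion, partial mortality and unconformities in cores; weather-band
(synoptic) temperature variability, sensor drift and tidal signals in
loggers; linkage, null alleles, genotyping error and isolation-by-distance
in genotypes. Passing tests therefore demonstrate correctness of the
algorithms under clean, known-truth conditions — not robustness to every
pathology of field data; the segmentation rejection path and the filter
rules are the guard rails for those.

**Reproducibility.** One top-level seed threads to every sub-generator via
named substreams (`SeedSequence` with a per-stage spawn key); identical
spec + seed gives bitwise-identical outputs (tested).

## Problem sizes

The test suite and the acceptance script use desk-scale sizes chosen to
leave estimator behavior clearly resolved: 150 event + 150 clean cores for
injection recovery (12 years each at 0.1 mm spacing); 1,000 random profiles
for the detection-oracle equivalence; two-year half-hourly loggers;
admixture recovery at n = 50 per population and L = 300 biallelic loci for
K ∈ {2, 4} and pairwise FST ∈ {0.1, 0.3, 0.5} with 3 restarts; a
160-colony four-lineage cohort for the end-to-end statistics; 300–400
replicates for type-I calibration. The full suite runs in about a minute on
one CPU; the acceptance script in ~15 s.

## Known limitations

* Band segmentation assumes quasi-periodic banding; cores with strongly
  trending extension or density require the rejection path and manual
  review, as in practice.
* The admixture estimator is maximum likelihood without priors; at weak
  divergence its Q estimates are interior points of the simplex even for
  unadmixed individuals (the likelihood genuinely prefers them), so
  majority-rule assignment, not raw Q, is the unit of downstream analysis.
* Nei's FST here is a fixed, documented estimator; numbers from other
  packages can differ in bias correction and locus weighting.
* The chi-squared prevalence test is asymptotic; at the small per-group
  counts typical of core collections it is conservative, and warnings are
  attached when expected cells fall below 1.
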