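# Methods

This note documents the statistical machinery, the choices made where the
design was genuinely open, and what the synthetic world does and does not
establish.

## Transect geometry

Specimens are mapped to a one-dimensional transect by ordinary least squares
of latitude on longitude (literally that orientation; a longitude spread
below `min_lon_spread` raises an error advising an axis swap rather than
silently swapping). Coordinates are converted to a local planar frame by an
equirectangular projection about the mean latitude (1° latitude = 111.32 km,
1° longitude = 111.32·cos φ km). The transect spans < 1.5°, where this
approximation's error (checked against a haversine oracle in the tests) is
below 0.5% — far under collection-locality uncertainty. Because OLS of y on
x is invariant to axis rescaling of x and to uniform rescaling of the
residual axis, fitting in degrees or in km gives the same line.

The origin (distance 0) is the perpendicular foot of the most-northwest
specimen — the coastal end. It is a data-dependent anchor: refitting with a
different specimen set can shift all distances by a common offset, which
affects absolute centers but neither widths nor center *differences*.

Groupings: sectors are half-open thirds [0,45), [45,90), [90,135] km (closed
at the domain end) so real-valued distances partition totally; localities
are single-linkage clusters at 1 km (connected components of the ≤ 1 km
graph — "within 1 km of each other" is ambiguous for chains, and the
chaining convention is fixed and tested); periods are P1911 (≤ 1911), P1956
(1956–1986), P2010 (2007–2010, the collection years of the recent series).

## Phenotypes

**Body size.** PCA runs per sex on the correlation matrix: the six
characters are lengths of very different magnitudes (wing ~68 mm, bill
width ~7 mm), and standardization keeps the bill from vanishing. PC1 is
oriented so wing length loads positively (larger birds score higher). Only
PC1 enters cline fitting; remaining axes are computed and reported.

**Color.** Spectra are interpolated to a 1-nm grid of 300 points
(400–699 nm) and split into four segments of exactly 75 points. Equal point
counts are what make the identities exact: a flat spectrum has chroma
exactly 0 and a single-segment spectrum chroma exactly 1. With a 301-point
inclusive grid the quarters cannot be equal and both identities acquire
O(1/300) bias. Segment fractions Q1..Q4 (of total reflectance) give
LM = Q4 − Q2, MS = Q3 − Q1, chroma = √(LM² + MS²), hue = atan2(MS, LM)
(radians), brightness = mean reflectance. Chroma is invariant to spectrum
scaling; zero-contrast and zero-reflectance spectra return hue 0 with a
degeneracy flag. Replicate scans (`_rep` column suffix) are averaged on the
grid before metrics.

## Hill cline fitting

The four-parameter log-logistic `y = C + (D − C)/(1 + exp(B(log x − log E)))`
is fitted by least squares using **variable projection**: for fixed
(B, log E) the plateaus enter linearly and are solved by a closed-form 2×2
normal-equation solve, so the nonlinear search runs over two parameters
only (Levenberg–Marquardt, ftol/xtol/gtol 1e-10, ≤ 10 000 evaluations per
start). Multistart over B₀ ∈ {±1, ±5, ±20} with E₀ at the observation
nearest mid-range; best SSE wins, ties to the smallest |B|. This is ~7×
faster per fit than a 4-parameter search — the difference between minutes
and an hour for the bootstrap experiments — and recovers noiseless
generating parameters at machine precision.

Conventions and edge cases:

- (C, D, B) and (D, C, −B) describe the same curve; fits are canonicalized
  with C ≤ D (C the lower plateau), so increasing clines have B < 0.
- EDp = `E·(p/(100−p))^(1/|B|)`: the distance at which p% of the
  plateau-to-plateau response has been traversed, measured relative to the
  fitted asymptotes. Center = ED50 = E; width = ED90 − ED10, which
  → 0 as |B| → ∞ and diverges (reported as inf, never an overflow) as
  |B| → 0.
- log x is undefined at the coastal origin; the pipeline adds 0.1 km to all
  distances before fitting and subtracts it from reported centers/EDs. The
  `HillCline` estimator itself defaults to no offset so that synthetic data
  generated on strictly positive x are recovered exactly.
- A fit is non-converged when the optimizer fails or E leaves
  (0, 10 × transect length); constant responses and n < 8 raise typed
  errors.

The validation harness fits Hill curves to noiseless tanh-model allele
frequency clines p(x) = (1 + tanh(2(x − c)/w))/2 — the standard
population-genetic cline shape. The Hill family is symmetric in log x, not
x, so the fitted center carries a small model-mismatch bias; across
c ∈ [40, 95] km, w ∈ [10, 60] km it stays within 2% of the transect length
(worst case ~2.4 km), which is what licenses using Hill centers where
population-genetic cline software cannot be applied.

## Bootstrap and period comparisons

Case-resampling bootstrap at constant n, 1000 replicates by default;
replicate r draws from the independent substream `default_rng([seed, r])`,
so results are bit-reproducible and independent of execution order.
Replicates are retained only if the refit converged and the center lies in
0–140 km (small opportunistic samples often produce non-clinal resamples);
retention is never applied to width, but replicates whose width exceeds the
transect length are counted, and when they are the majority the width CI is
withheld from the summary (mirroring how wildly unstable width bootstraps
are reported, rather than quoted, for data-poor periods). Intervals are
95% percentile intervals; with n ≈ 80 and 10% noise their measured coverage
of the true center is 97% over 200 simulated datasets.

Periods are compared by one-way ANOVA and Tukey HSD (Tukey–Kramer for
unequal retention) *treating bootstrap replicates as observations*. This is
pseudo-replication: replicates within a period share one dataset, so these
P-values overstate evidence — under an identical-parameter null the
P1911-vs-P2010 Tukey test at α = 0.05 rejects in ~86% of runs (reps = 200),
close to the analytic rate P(|Z| > 2/√reps). Every report therefore labels
them "bootstrap-replicate ANOVA", and the movement summary also reports
CI-overlap flags, which behave nominally under the null. The comparison is
retained in this form because it is the inherited design, not because it is
a calibrated test.

## AMOVA

Molecular variance is decomposed at three levels (among sectors, among
localities within sectors, within localities) from a matrix of raw pairwise
nucleotide difference counts (pairwise deletion of gaps/N; no distance
correction — over ≤ 1% divergence corrections are noise). Variance
components use the standard unequal-sample-size coefficients and may be
negative; they are reported as computed. F_CT, F_SC, F_ST follow the usual
identities; F_SC is undefined (reported missing) when no sector has two
localities, and monomorphic data return missing F-statistics rather than
0/0. Significance uses the three conventional permutation schemes
(individuals across everything for F_ST; individuals among localities
within sectors for F_SC; whole localities among sectors for F_CT) with
P = (1 + #{perm ≥ obs})/(n_perm + 1), so P is never 0.

Permutation P-values are exactly valid but *discrete*: when few distinct
haplotypes exist, many permutations tie the observed statistic and the
P-value is conservative, not uniform. The calibration experiment therefore
uses a high-diversity unstructured world (16 haplotypes, 15 segregating
sites, dominant haplotype plus decaying tail; 8 individuals per locality),
where ties are negligible and the null P passes a KS uniformity test with
empirical size 0.050 at α = 0.05.

## Neutral diffusion

Expected width after T generations of dispersal with per-generation scale
σ: `w = σ·√(2πT)`. The proportionality constant differs between treatments
in the literature and published range endpoints cannot be uniquely
back-derived, so the constant (default √(2π) ≈ 2.51) is a parameter and is
echoed in every report. The envelope over σ ∈ [1, 20] km, generation time
1–2 y, age 6000 y runs from ~137 km to ~3900 km; fitted widths of tens of
km sit far below it, the tension-zone diagnosis.

## The synthetic world

Defaults state the study system's magnitudes: three periods with n = 40/60/65,
years 1894–1911 / 1956–1986 / 2007–2010; a ~135 km southeast-trending
transect; latent-size clines with centers 67.67/73.85/76.69 km and widths
41.75/21.97/33.12 km, plumage-mixing clines with centers 72.92/73.04/76.33 km
and widths 31.48/32.37/6.71 km (generator settings, not reproduced results);
uniform sampling mixed with a center-biased component (40/20/10% by period —
historical collecting concentrated near the zone); 62% males. Six morph
characters are affine in the latent size with wing and tail carrying the
signal, so correlation-PCA PC1 is an affine image of the latent cline — and
Hill centers/widths are invariant under affine response maps, so truth
transfers to PC1 exactly. Spectra mix a low-chroma yellowish template into a
high-chroma scarlet template; the red template is normalized to the yellow
template's total reflectance so segment fractions (hence approximately
chroma) are affine in the mixing fraction, keeping the chroma cline's center
within ~0.5 km of the mixing cline's. Haplotypes are drawn per sector from
frequency vectors: a sector-structured preset (positive true F_CT, the 1956
situation) and a homogeneous preset (true F_CT = 0, the 2010 situation);
2010-style alignments are 1008 bp and trimmed to a configured 210-bp window
for cross-period comparability.

What a green test establishes: the estimators recover the stated world's
truth at the stated noise. What it does not: the world has Gaussian
phenotype noise, straight-line geography, haplotypes in linkage-free
star-like configurations, and no measurement heteroscedasticity — real
museum series violate all of these, and only the bootstrap's behavior under
the real sampling unevenness speaks to that.

## Runtime scaling in the test suite

The statistical acceptance experiments run at 200 coverage datasets × 300
replicates, 50 movement runs × 200 replicates per period, and a 150-replicate
pipeline determinism check. Replicate counts below the 1000-replicate
production default affect only runtime: coverage depends on the percentile
interval (stable by 300 replicates), and the pseudo-replicated Tukey
comparison's power at a 9-km shift is astronomically high at any replicate
count.
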