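# Methods

This note documents the models implemented in `teanirs`, the synthetic data
they are exercised on, and the numerical conventions chosen where standard
practice leaves latitude. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic tea library

No public spectral library accompanies the study design this package
implements, so the `simulate` module generates one. The generator is
first-class, tested code; its defaults *are* the study conditions.

**Design.** 26 pure teas (7 black, 11 green, 8 red) plus binary blends of
the three type pairs, each blend built from one parent sample per
constituent with a dominant fraction drawn uniformly from
{0.50, 0.51, …, 0.99}, completing the library to 322 samples. An 80/20
random split yields the 257/65 calibration/validation sets (floor rule for
the calibration size). The published sample-count arithmetic is internally
inconsistent (16 vs 26 pure samples; subsets summing to 332); we follow the
per-class counts, 26 pures and a 322 total.

**Chemistry.** Pure-tea metal concentrations are drawn per class from
moment-matched gamma distributions (shape (μ/σ)², scale σ²/μ) with the
class means and SDs of the reference ICP-MS table: e.g. black tea
Al 2.04 ± 0.23 g/kg, red tea As 0.19 ± 0.09 mg/kg, green tea
Hg 0.01 ± 0.01 mg/kg, and exact zero where the table reports 0.00 ± 0.00
(Hg in black and red tea). A gamma rather than a zero-truncated normal is
used because several cells have μ within 1–3 σ of zero, where truncation
would bias the sample mean upward by far more than its standard error; the
gamma hits the printed mean and SD exactly on nonnegative support. Blend
concentrations are exactly linear: c_blend = f·c_A + (1−f)·c_B per metal.

**Spectra.** Each pure spectrum is a class baseline (black 0.70, red 0.60,
green 0.52 absorbance) plus 12 Gaussian absorption bands at 1220, 1330,
1400, 1440, 1670, 1740, 1885, 1950, 2150, 2170, 2280 and 2350 nm — the
water, C-H overtone, amide and phenolic-combination bands of tea — with
σ of 9–24 nm and peak amplitudes of roughly 0.1–1.1 absorbance. Three
features carry the class identity:

* per-band amplitude multipliers per class, deliberately **non-collinear**
  across the three types (black rich in the water and amide bands, green in
  the catechin-related C-H bands, red with its own profile), so that no tea
  type is expressible as a mixture of the other two — otherwise a
  "red blends" centroid would coincide with pure red and class-modelling
  would be structurally impossible, which contradicts the observed
  separability of real teas;
* per-band center shifts of a few nm per class (fermentation shifts band
  positions), which dominate the contrast that survives derivative
  pretreatments;
* mean absorbance ordered black > red > green at essentially every
  wavelength, with the largest red−green gap at the 1940–1950 nm water
  band.

Metal content enters the spectrum linearly through narrow (σ = 3 nm)
signature band pairs at Al 1282/1290, Pb 1164/1984, As 1264/1580,
Hg 1244/1252 and Cu 1310/1614 nm — the wavelengths where the calibration
β-coefficients of the reference analysis peak. This mimics the real
mechanism (metals are NIR-visible only through association with organic
complexes) and guarantees the calibration problem is well-posed. The
signature amplitudes (0.006 absorbance per g/kg Al, 0.35 per mg/kg Hg, …)
are set so that metal variation sits well above the noise floor but below
the between-class band contrast; larger values would make within-class
spectral variance metal-dominated and degrade class-modelling in a way real
teas do not show.

Per-sample effects: multiplicative scatter (slope SD 0.005), additive
offset (SD 0.01), band-amplitude jitter (0.5% relative, brand-to-brand
variability) and white measurement noise (SD 0.001 absorbance). Blend
spectra are convex combinations of their parents' *measured* spectra
(Beer–Lambert additivity) plus fresh measurement noise — so a 99% blend is
spectrally almost identical to its dominant parent, which is the
irreducible difficulty of the authentication task.

**What the generator does not emulate:** instrument drift, temperature and
repack effects, particle-size scattering physics, ternary blends, and the
idiosyncratic covariance of real commercial products. Passing tests
therefore demonstrate correctness of the algorithms and reasonable behaviour
under a faithful study geometry, not field performance on real teas.

## Pretreatments

Codes follow the four-digit convention `(d, g, s1, s2)`: derivative order,
gap in grid points, first and second running-average widths, optionally
prefixed by a scatter correction (SNV, MSC, Detrend, SNV-DT). Conventions
chosen where the public literature is ambiguous:

* the gap difference is a **forward** difference over `g` grid points,
  applied `d` times; widths and gaps count data points, not nm;
* processing order: scatter correction, then smoothing s1, then the
  derivative, then smoothing s2 (SNV-DT = SNV then detrend);
* edges consumed by the stencils are trimmed, never padded; the effective
  wavelength grid is returned with the data (`Detrend (2,4,4,1)` maps 700
  variables to 689);
* detrend fits and subtracts a degree-2 polynomial in wavelength;
* SNV uses the n−1 denominator; MSC regresses each spectrum on the
  calibration-set mean and stores that reference so validation data receive
  the identical transform.

## MPLS calibration

`MPLSRegression` implements PLS1 with the "modified" step: after each
factor (weight ∝ covariance of X-residuals with y-residuals, normalized;
scores; loadings; deflation), every X-residual column is divided by its
sample SD before the next factor. Prediction mirrors the recursion, and
since the map is affine the wavelength-domain coefficients β are recovered
exactly by propagating the identity matrix through it. With the scaling
disabled the implementation reduces to plain PLS1 (verified against a
NIPALS oracle), and with factors = rank it reproduces ordinary least
squares (±1e-6 on small full-rank problems).

**Outlier protocol** (`MetalCalibration`): PCA on the pretreated spectra
(10 components), global H distance GH = mean squared standardized score;
GH ≥ 3.0 removes a sample. Then at most two passes of {4-group
cross-validation → MPLS fit → removal of samples with standardized
prediction residual T = |y−ŷ|/SEC ≥ 2.5}, followed by a final
cross-validation and fit on the cleaned set. The T denominator is the SEC
of the current pass; both thresholds are inclusive; the run aborts if more
than half the samples would be removed. Cross-validation groups are a
seeded shuffle cut into contiguous blocks; the factor count (searched over
1–16, capped by the fold sizes) minimises SECV with ties toward fewer
factors.

**Statistics.** SEC = √(SSE/(N−k−1)); SECV = √(mean held-out squared
error); RSQ = 1 − SSE/SST; RPD = SD/SEC (the SD/SEC convention reproduces
the printed worked example 3.6119/0.625 = 5.78; an SD/SECV variant is a
one-line change but is not the default); estimated range = mean ± 3·SD with
the lower bound clamped at 0. External validation: bias = mean(ŷ−y),
SEP = √(Σ(ŷ−y)²/n), SEP(C) = √(Σ(ŷ−y−bias)²/(n−1)), RMSE ≡ SEP, RSQ is the
squared Pearson correlation, and a two-sided paired t-test compares ŷ with
y (p = 1 by convention when the differences have zero variance, flagged).
Negative predictions are not clamped.

## Discrimination

**Grouping.** Six groups (3 pure classes, fraction exactly 1.0, plus 3
">50% blend" classes) or twelve purity bins per tea type: >95%, 95–85%,
85–75%, 75–50% of the dominant tea, bins resolved on the integer
percentage with boundaries 95, 85 and 75 assigned to the upper-purity bin
label containing them (a pure sample falls in >95%). A 50/50 blend is
attributed to the first constituent in the fixed order black, green, red.

**SIMCA.** Spectra are normalized (per-spectrum SNV), autoscaled and
mean-centered on training statistics; each class gets a PCA model retaining
the components with eigenvalue > 1 (at least one, at most n−2), a residual
scale s₀² = RSS/((n−k−1)(p−k)) and an F-bound critical limit at α = 0.05.
Classification is by minimal standardized residual distance; samples
outside every class limit are returned as `"no class"` and count as
misclassifications in the summary percentages.

**OPLS-DA.** One-hot class encoding; orthogonal components (weights built
from the X-loading component orthogonal to the X–Y covariance basis) are
stripped before a 2-component PLS fit. Reported: R2X (X variance modelled
by orthogonal + predictive components), R2 (class-encoding variance
explained) and Q2 by 7-fold cross-validation of the whole filter+fit
pipeline. Q2 ≤ R2 is *not* enforced — cross-validated Q2 can legitimately
exceed R2 slightly on class-structured data.

**RMS-X residuals.** Spectra are pretreated (default `Detrend (2,4,4,1)`,
the code that also gives the best calibrations); each class stores its mean
pretreated spectrum and the mean/SD of its within-class RMS distribution,
rescaled by √((n+1)/(n−1)) because the RMS of a *new* sample to a mean
fitted on n training samples is systematically larger than the training
RMS. The decision rule first forms the candidate set of classes whose
decision limit accepts the sample (RMS ≤ mean + 2.5·SD of the class's
within-RMS distribution, the same 2.5 multiplier as the chemical outlier
criterion) and assigns the nearest candidate by raw RMS; a sample no class
accepts goes to the least atypical class. A plain argmin-RMS rule
(`rule="raw"`) is retained for reference; it systematically hands every
high-purity blend to the pure class, because the pure-class mean is closer
in absolute distance while the within-class statistics say the sample is an
outlier there. Exact ties go to the first class in model order, with a
warning.

## Pipeline

`anova_tukey` wraps one-way ANOVA and Tukey HSD (α = 0.05) and assembles a
compact letter display with an insert-and-absorb heuristic (two groups
share a letter iff no significant difference separates them within a
retained set). `exploratory_pca` autoscales the five-metal concentration
table and reports scores, loadings and variance fractions. The experiment
runners reproduce the report shapes end to end (five analyte rows with
calibration and validation statistics; 6 or 12 class rows with calibration
and validation sensitivity/specificity), embed the resolved configuration
for provenance, and are byte-deterministic given the configuration.

## Problem sizes and known limitations

All tests and the acceptance script run on the default 322-sample library
(700 wavelengths); a full five-metal calibration takes a few seconds and
the complete suite well under a minute, so no down-scaling is needed.
Sampling-based checks (concentration moments, noise monotonicity,
false-positive outlier rates) use 3–10 seeds or 10⁴ draws as stated in the
tests. Limitations worth keeping in mind: the spectral model is a
band-sum cartoon with additive mixing, so it cannot probe nonlinear
scattering effects; high-purity blends (≥97% of one tea) are inherently
confusable with the pure class under any spectral classifier, and the
remaining discrimination errors concentrate there and at the 50/50
composition boundary; and SIMCA on strongly overlapping blend classes is
weak by construction — the RMS-X method is the intended workhorse, matching
its documented advantage.
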