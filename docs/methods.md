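# Methods

This note documents the models, numerical choices and synthetic-data design
behind `ramanremodel`, in the spirit of a statistics package's model
documentation: what is assumed, what is configurable, and what the tests do
and do not demonstrate.

## Spectral model and preprocessing

A measured spectrum is modeled as

    y(ν̃) = Σᵢ βᵢ xᵢ(ν̃) + f(ν̃) + ε(ν̃),

where xᵢ are pure-component Raman spectra (collagen I, water, adipose) on a
common 1 cm⁻¹ grid over 900–1800 cm⁻¹, f is a smooth fluorescence
background, and ε is heteroscedastic detector noise. All cross-spectrum
arithmetic happens after linear interpolation to this grid.

**Axis calibration.** The pixel→wavelength map is a quadratic fit to lamp
emission lines (≥ degree+1 lines required). The excitation wavelength λ₀ is
solved in closed form from Raman-shift standards: since
ν̃ₖ = 10⁷/λ₀ − 10⁷/λₖ is linear in 1/λ₀, the least-squares minimizer is
10⁷/λ₀ = mean(ν̃ₖ + 10⁷/λₖ). Estimates outside 400–1100 nm are flagged
non-physical but returned. On noiseless standards the round-trip error is at
machine precision (the tests require < 0.01 nm).

**Response correction** divides by the measured/certified tungsten-lamp
ratio channel-wise; a non-positive measured lamp is an error naming the
offending channel. **Dark subtraction** is an optional constant or
recorded-frame subtraction applied before smoothing.

**Smoothing** is Savitzky–Golay (default window 11, order 3 — the
instrument's values are not universal, so both are configuration and are
recorded in the stage log). Endpoints use polynomial fits on the truncated
window; `window=1` is the identity.

**Fluorescence subtraction** is the iterative modified-polynomial method:
fit a degree-d polynomial (default d = 5), replace the working spectrum by
min(spectrum, fit), repeat until the fit's maximum relative change falls
below `tol` (default 1e-4) or `max_iter` (100) is reached; non-convergence
is flagged, not raised. The implementation shares one projection matrix
across spectra, so a full cohort is processed vectorized. The corrected
spectrum is not floored at zero. The polynomial converges to the envelope
*under* the Raman bands; on band-dense tissue spectra it therefore removes a
small amount of genuine signal along with the fluorescence — this envelope
bias matters for the unmixing residual scale (below).

**QC.** A spectrum is removed if its 1440 cm⁻¹ peak intensity is strictly
below 100 counts (low signal) or strictly above 1800 counts (dominant
adipose). "Peak intensity" is everywhere the maximum within ±8 cm⁻¹ of the
nominal center (robust to residual calibration jitter); the QC filter and the
feature table use the same lookup. Filtering is idempotent and an empty
surviving set is an explicit empty dataset, not an error.

## Features and their statistics

Peak ratios (1304/1265, 1265/1440, 1657/1440, 1003/1440) are computed per
spectrum on non-normalized intensities and only then averaged per mouse ×
day; group summaries are mean ± SEM over mice (biological replicates).
Normalization to the 1440 cm⁻¹ peak exists only for plotting; datasets so
normalized carry a flag and the statistics path refuses them.

## Non-negative unmixing

β = argmin‖Y − Xβ‖₂ s.t. β ≥ 0, solved by active-set NNLS (scipy). The
exclusion rule — summed residual strictly greater than 0.3 — is dimensionless
in its published form, so each spectrum is max-normalized before the
exclusion decision and raw-scale coefficients are recovered by multiplying
back; both scales are reported. "Summed residual" defaults to the sum of
absolute channel residuals (a signed sum would cancel; `signed` and
`squared` are available).

Two scale facts matter on this 901-channel grid. First, the reference
spectra entering X are passed through the same smoothing/baseline path as
the tissue spectra (at a tissue-like count level), which cancels most of the
shared envelope bias of the baseline step. Second, even so, realistic
baselines leave a smooth residual bias that dwarfs the 0.3 threshold: on the
default synthetic conditions, ordinary fits carry summed residuals around
8–11 while spectra containing a band-structured un-modeled component sit
above ~28. The published 0.3 therefore operates as intended only on
well-subtracted (near-noiseless) spectra, and that is the regime in which
the bookkeeping tests run it; the orchestrated pipeline's config defaults to
a threshold of 20 on this grid and convention, the operating point that
separates the two populations above. Both numbers are plain configuration
(`unmix.residual_threshold`).

Coefficients are non-negative by construction and asserted on every run; on
noisy fits the residual fluctuates above and below zero (checked to be
mean-zero within 2 standard errors).

## Longitudinal trajectory model

For a feature y (a ratio or an unmixing coefficient), individual spectra are
the observation unit:

    y = α + s(day)·γ + KO·δ + KO·s(day)·η + I_WT·θ₁ + I_KO·θ₂ + intensity·κ + ε

where s(day) is the 3-knot restricted cubic spline (linear term plus one
restricted cubic term; exactly linear beyond the boundary knots), knots
default to the 0.10/0.50/0.90 day quantiles, non-gravid animals are coded as
day 0 (configurable), I_WT and I_KO are per-genotype last-day indicators
(day 19 WT / day 20 KO) capturing the abrupt end-of-gestation change, and
intensity is the raw 1440 cm⁻¹ peak acting as a baseline offset so adipose
signal level does not masquerade as a gestational effect. Identity link and
Gaussian error are used; per-mouse averaging is *not* applied here because
the intensity covariate varies per spectrum (t-tests keep the per-mouse
unit).

Inference uses the cluster-robust sandwich with mice as clusters and the
G/(G−1) small-sample factor (cross-checked against statsmodels, which uses
an additional (N−1)/(N−K) factor). Wald chi-square ANOVA reports joint tests
for genotype, gestation, genotype×gestation, nonlinearity (cubic terms), and
each last-day indicator; singular sub-blocks are flagged untestable. No
multiplicity correction is applied across days or cells, and the outputs say
so.

Two design notes from simulation. (1) Cluster-robust chi-square tests
converge slowly in the number of clusters: at the cohort's own scale
(~50–100 mice) the interaction test over-rejects (8–10 %), reaching its
nominal 5 % only in a many-cluster regime; the calibration check therefore
simulates 50 mice per genotype×day cell (600 clusters), where the measured
size is ~4–6 % at 500 replicates. (2) The jump day is localized per genotype
by refitting with the indicator at each candidate day (coded day ≥ c) and
taking the largest robust |z|; on the default synthetic cohorts this
recovers day 19 (WT) vs day 20 (KO) in ≥ 95 % of runs, reproducing the
delayed-deviation phenotype.

## Biomechanics

Cycles are segmented from the displacement derivative (|v| > 0.02 mm/s marks
a ramp); stress = force / cross-sectional area (area is a measured input —
no geometric modeling of the ring-on-hooks configuration). Impulse stress is
the per-cycle maximum, equilibrium stress the mean over the final 30 s of
the hold (truncated with a warning for short holds). Both stress–opening
curves are fit to Stress = (A/B)[exp(x·B) − 1] by bounded nonlinear least
squares (A₀ = slope of the first two points, B₀ = 0.1 /mm, both parameters
≥ 0) with the B→0 limit evaluated as A·x via expm1, so perfectly linear data
degenerate gracefully to A = slope, B = 0. The linear region for the slope
and x-intercept is the largest suffix of points whose normalized second
difference stays below 0.15 (configurable).

Failure is the first instant at which stress falls by more than 50 % of the
running within-cycle maximum within 1 s while displacement is non-decreasing
(the threshold is ours — only the qualitative "sudden loss of stress"
definition is standard — and is exposed in config with a sensitivity test).
Records without such an event are censored, and total dilation then uses the
last achieved displacement; otherwise total dilation = initial dilation +
failure displacement. Force calibration is the exact two-point affine map
from the unloaded and 100 g (force = mass × g) records.

The hydration helper returns the study's printed formula wet/(wet+dry) *and*
the conventional (wet−dry)/wet side by side; they differ and neither is
silently corrected.

## Cross-modality correlation

Spearman rho (mid-rank ties, two-sided p via the t approximation) for each
of the four ratios plus the collagen coefficient against impulse/equilibrium
stiffness A, their x-intercepts, initial opening, total dilation and maximum
stress. Pairing is at the animal level using per-mouse means from the
terminal session; cells with fewer than 3 paired animals are flagged. The
matrix is written as CSV with rho, p and n per cell, plus a diverging
heatmap.

## Synthetic-data generator

The generator emulates the study's statistical structure, not its optics.

* **Components** are Gaussian/Lorentzian band tables at literature-typical
  positions (collagen: 938, 1003, 1245, 1265, 1304, 1450, 1657 cm⁻¹;
  adipose dominated by 1440 cm⁻¹; water a single broad 1640 cm⁻¹ band),
  unit-maximum normalized.
* **Cohort**: WT sampled NG/4/12/15/18/19, KO NG/4/12/15/19/20, 8 mice per
  group, 5–10 spectra per mouse. True mixing weights follow three-phase
  logistic trajectories (collagen declines from ~day 12, water and lipid
  signal rise) with an additive reversal of the lipid-vs-protein balance at
  day 19 (WT) / 20 (KO). Per-spectrum intensity scale is uniform 350–900
  counts with mouse- and spectrum-level lognormal factors; the baseline is a
  random concave-down quadratic of 150–600 counts; noise is Gaussian with
  σ = c·√intensity (shot-like), default c = 0.01 — the study reports no
  spectral variance, and the default is deliberately low so the published
  dimensionless residual rule operates in its intended regime on this grid
  (tests exercise larger noise explicitly where noise response is the
  property under test). Planted defects: ~4 % low-signal (target 20–90
  counts at 1440 cm⁻¹), ~4 % high-adipose (1900–2600), ~4 % bad-fit spectra
  carrying rogue bands at 1160/1525 cm⁻¹ absent from the library. Ground
  truth records every coefficient, baseline, noise scale and defect label.
* **Stress traces** follow the protocol exactly (4-min unloaded baseline,
  10 s ramps at 0.1 mm/s, 1 mm steps, 4-min holds); during holds stress
  relaxes exponentially (default τ = 20 s) from an impulse peak
  (1+overshoot)·eq(x) toward the equilibrium law eq(x) = (A/B)(e^{xB}−1),
  with multiplicative force noise and an optional planted failure that
  collapses stress and truncates the record.

Everything is driven by one explicit seed per call; equal seeds give
byte-identical outputs.

**What passing tests do not show.** The generator does not model probe
repositioning covariance, cosmic rays, detector etaloning, true biological
between-mouse variance structure, or tissue anisotropy in the mechanics; the
trajectory shapes are qualitative (three phases + term jump), so parameter
recovery here demonstrates correctness of the estimators under the stated
model, not field performance on real instruments.

## Problem sizes used in checks

The shipped checks run at desk scale, chosen as the smallest sizes at which
each property is statistically meaningful: 50 five-channel problems for the
grid-search oracle, ~340-spectrum cohorts for bookkeeping, 500 replicates ×
600 clusters for the null-size calibration, 100 cohort simulations for jump
localization, 100 traces for stiffness recovery. The demo pipeline runs 3
mice per group at 5 Hz trace sampling and completes in seconds; the full
default design (8 mice per group, 10 Hz) is configuration away.
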