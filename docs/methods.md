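# Methods

`leafspec` implements a complete leaf-level pipeline linking hyperspectral
reflectance (450–2500 nm) to the two determinants of photosynthetic
capacity — the maximum Rubisco carboxylation rate V_cmax and the maximum
electron-transport rate J_max — together with a synthetic dry-down study
generator that reproduces the statistical structure such field campaigns
assume. This note records the models, the tunable parameters that matter,
the numerical choices, and what the synthetic experiments do and do not
demonstrate.

## Gas exchange: the FvCB model and A/Ci fitting

Net CO₂ assimilation follows the Farquhar–von Caemmerer–Berry model of C3
photosynthesis:

    A = min(A_c, A_j) − R_d
    A_c = V_cmax (C_i − Γ*) / (C_i + K_m),   K_m = K_c (1 + O₂/K_o)
    A_j = J (C_i − Γ*) / (4 C_i + 8 Γ*)

with J the smaller root of θJ² − (αI + J_max)J + αI·J_max = 0. All
measurements are taken as made at 25 °C, so no temperature response is
implemented; kinetics default to the Bernacchi-family 25 °C constants used
by the standard `plantecophys` fitting tool (Γ* = 42.75 ppm, K_c = 404.9
ppm, K_o = 278.4 mbar, O₂ = 210 mbar), overridable via
`KineticConstants`. Light response uses θ = 0.85, α = 0.24 at PPFD
1800 µmol m⁻² s⁻¹; at saturating light J ≈ J_max, so estimates are
insensitive to α and θ. Triose-phosphate limitation is not modelled and
the highest-C_i points are retained.

Fitting minimises the sum of squared residuals over (V_cmax, J_max, R_d)
with bounded trust-region least squares from a four-point multi-start grid
(V_cmax ∈ {25, 50, 100, 200}, J_max = 2·V_cmax, R_d = 1); the best final
SSR wins. R_d is a free parameter bounded [0, 10]. Standard errors come
from the Jacobian at the optimum (σ² (JᵀJ)⁻¹ with σ² = SSR/(n−3)). Because
min(A_c, A_j) is only piecewise smooth, convergence is governed by step and
cost tolerances (1e-8) rather than the gradient test, which can be
unattainable exactly at a limitation crossover. Solutions within 0.1 % of
a bound are flagged, as is any fit whose points all fall in a single
limitation state; a fit that fails from every start returns an explicit
failure, never silent numbers. Per-point limitation labels take the
discrete minimum of the two rates, ties labelled Rubisco-limited.

Curve quality control (the printed rule plus our own declared checks):
initial A at ambient C_i must be ≥ 10 µmol m⁻² s⁻¹; at least 5 finite
points; and A must track C_i over the initial descending limb (Spearman
ρ ≥ 0.5), guarding against drift or stomatal closure during the down-ramp.
All violated rules are enumerated. Leaves failing QC are excluded from the
modelling table with a logged warning.

## Spectra and preprocessing

Spectra live on the strictly increasing 1-nm grid 350–2500 nm. QC masks
negative reflectance values; replicate averaging (nine replicates per leaf
by default) takes the per-wavelength mean over unmasked cells, and a cell
masked in every replicate is filled by linear interpolation from
neighbouring wavelengths, with a warning.

The chemometric chain before PLSR applies, in this exact order: standard
normal variate (per spectrum), Savitzky–Golay second derivative, autoscale
(divide each wavelength by the calibration-set sd), and mean-centre
(subtract the calibration-set mean). Spectra are subset to 450–2500 nm
before any transform. Two conventions are declared because no standard
fixes them: the sd denominator is n−1 everywhere, and the SG filter uses
window 15 nm with polynomial order 2 — a common chemometric default at
1-nm sampling; both are configurable. Scaling-then-centring in the literal
order listed composes to ordinary column autoscaling; we keep the literal
order and say so. SG edges are handled by evaluating the polynomial fitted
to the terminal window, so the output length equals the input length and
the filter is exact on quadratics everywhere. Calibration statistics are
estimated on training rows only and replayed on test rows; the fitted
chain serialises to JSON and replays bit-identically. Vegetation indices
are always computed on raw reflectance, never preprocessed values.

## PLSR, component selection, Selectivity Ratio

PLSR uses NIPALS with deflation. For a univariate response the weight of
each component is proportional to Xᵀy of the deflated predictors, so the
algorithm is direct and deterministic. The regression vector
b = W(PᵀW)⁻¹q reproduces component-wise prediction exactly (PᵀW is unit
upper triangular in NIPALS, so the nested coefficient path solves by back
substitution), and with as many components as the predictor rank NIPALS
reproduces minimum-norm least squares — both are tested against
independent oracles (pseudoinverse regression; scikit-learn's PLS).

The component count minimises cross-validated RMSEP over 1..10 candidates
(10-fold, seeded shuffle; ties toward fewer components). Inside component
selection, the column autoscaling/centring statistics are re-estimated
within each training fold, so selection is free of column-statistic
leakage; the row-wise SNV/derivative stages are sample-local and
fold-independent. The selection CV scheme and the maximum candidate count
are declared defaults — nothing in the analysis design fixes them.

Wavelength importance uses the Selectivity Ratio: predictors are projected
onto the normalised regression vector (target projection) and SR at each
wavelength is the ratio of variance explained by that single component to
residual variance, with the denominator floored at 1e-12 to keep
uninformative wavelengths finite. VIP is deliberately not implemented; SR
is the preferred diagnostic here.

## Vegetation indices

Nineteen published narrowband indices (chlorophyll, stress, water,
xanthophyll, greenness) are shipped as a versioned JSON registry and
evaluated at exact 1-nm grid wavelengths with no band averaging. Two
registry entries deliberately keep variant forms that circulate in
comparative studies rather than the original publications' formulas —
Vogelmann2 as a difference rather than the 1993 ratio, and SIPI in a
truncated two-band form — with the conventional SIPI available separately
as `SIPI_full` (excluded from the 19-index suite). Both discrepancies are
flagged in the registry notes so users know exactly which form they get. The broadband "MODIS-like"
NDVI averages raw reflectance over the nominal MODIS red (620–670 nm) and
NIR (841–876 nm) ranges by default; an alternate `fwhm` mode averages
between the half-height crossings of each band-restricted curve. The FWHM
construction is under-specified for band segments without a clear peak, so
the plain band mean is the default and the FWHM variant is provided
without further guessing. Index-versus-trait reporting is ordinary least
squares of trait on index with R², slope, intercept, p-value and n;
constant-valued indices are flagged degenerate and excluded from ranking.

## Validation designs

Three schemes of increasing rigour, each running the full leak-free
pipeline (preprocessing statistics and component count estimated inside
every training fold):

* **Leave-one-out**: n fits, n held-out predictions, pooled metrics;
  fully deterministic.
* **Repeated random splits** (default 80/20 × 100): per-repetition
  metrics summarised as mean, sd and median R².
* **Stress holdout**: the pair of consecutive sampling dates with the
  largest individual variation in predawn water potential (Ψ_pd) is held
  out; the model trains on the calm dates. The pair score is the mean of
  the two within-date variances — pooling the pair would conflate the
  seasonal Ψ_pd trend with between-tree spread, which is what
  "individual variation" means here. Ties resolve to the earlier pair.

The headline R² is the squared Pearson correlation between observed and
predicted — the convention consistent with observed-vs-predicted scatter
panels — with the 1 − SSE/SST "prediction R²" reported alongside, since
the two differ exactly when extrapolation is biased (the stress holdout
is the case in point). RMSE is the root mean squared prediction error in
trait units.

A note on the training-fraction sweep: mean held-out R² rises with the
training fraction, but the *sd* of per-repetition R² also rises, because
the held-out sample shrinks (the sampling variance of a squared
correlation on n points scales like 1/n). This estimator effect dominates
model instability at these sample sizes and is expected behaviour, not a
model defect.

## The synthetic study generator

The generator emulates a 12-tree, 7-weekly-date dry-down:

* **Traits.** Mean V_cmax declines along a logistic in time from 110 to
  55 µmol m⁻² s⁻¹ (the ~2-fold mid-season decline), normalised to hit
  both endpoints exactly; each tree adds a constant offset (sd 6). A
  stress dip subtracts 12 µmol m⁻² s⁻¹ per MPa of Ψ_pd depression below
  the well-watered baseline. J_max is 1.98 × V_cmax with 5 %
  multiplicative noise, plus a small extra stress sensitivity (15 % per
  MPa of depression): under within-population water stress J_max
  decouples from the chlorophyll-linked V_cmax signal, reflecting the
  differential drought sensitivity of RuBP regeneration. This term is
  what makes stress extrapolation degrade more for J_max than V_cmax —
  with strictly proportional coupling the two traits would degrade
  identically, which is not how the two parameters behave under stress.
* **Water status.** Ψ_pd starts at a −0.3 MPa well-watered baseline and
  dips by up to 0.9 MPa along a Gaussian-in-time pulse centred 0.4 dates
  after the configured stress-peak date (width 0.8 dates), baseline-
  subtracted so it is exactly zero on the first and last dates. Each
  tree's susceptibility is a lognormal factor (CV 0.35), so the
  population Ψ_pd variance is strictly maximal on the peak date with the
  following date second — which pins down the stress-holdout pair — on
  top of iid measurement noise (sd 0.05 MPa).
* **Gas exchange.** Each leaf gets the 13-step chamber protocol (400,
  300, 200, 100, 50, 0, 400, 400, 600, 800, 1200, 1600, 2000 ppm)
  forward-modelled with R_d = 1 and additive noise sd 0.5 µmol m⁻² s⁻¹.
* **Spectra.** Reflectance is an analytic green-leaf template, not a
  radiative-transfer model: chlorophyll absorption wells near 465 and
  668 nm whose depth grows linearly with V_cmax, a red-edge sigmoid whose
  inflection shifts from ~690 to ~720 nm with V_cmax, and water wells at
  1450 and 1940 nm whose depth grows as Ψ_pd becomes less negative
  (wetter leaf). Nine replicates per leaf with additive noise sd 0.005,
  clipped to [0, 1]. The Ψ_pd-coupled water wells are the stress-dependent
  spectral confound; `water_psi_gain = 0` disables it.

With all noise terms off, the trait→spectrum map is injective over the
simulated range and the chlorophyll simple ratio ρ750/ρ700 is strictly
increasing in V_cmax, so downstream recovery approaching R² = 1 is
attainable; the included tests verify both on a grid.

**What passing on synthetic data shows — and does not.** The generator
gives the pipeline a ground truth with the right qualitative structure:
temporal decline, stress-coupled water status, chlorophyll-linked visible/
red-edge variation, replicate and instrument noise. It does not emulate
leaf ontogeny, scattering or view-geometry effects, instrument wavelength-
dependent noise, or the full covariance structure of real leaf optical
properties; the index-versus-trait R² values it yields are accordingly
cleaner than field values, and their ordering (red-edge chlorophyll
indices strong, PRI/NDWI weak for V_cmax) is the meaningful output, not
their magnitudes. Passing here demonstrates correctness of the statistics
and leak-free validation machinery, not field-scale predictive skill.

## Degenerate inputs and numerical edges

Constant spectra are rejected by SNV (zero variance); wavelength columns
with zero variance after the row stages are dropped with a warning at
autoscaling. Zero denominators in index formulas yield NaN (an undefined
value), never an exception; a missing grid wavelength raises and names
the wavelength. Ties in the stress-pair score keep the earlier pair; ties
in RMSEP keep fewer components; ties between A_c and A_j label the point
Rubisco-limited. Validation repetitions whose test set would have fewer
than two samples are skipped with a warning. Seeds: every stochastic
routine takes either a config seed or an explicit `numpy` generator;
identical seeds give bit-identical studies.

## Problem sizes used by the shipped checks

The acceptance script and tests run the default study (12 × 7 = 84
leaves, 2051 modelling wavelengths), 200 Monte-Carlo A/Ci refits for bias
and SE coverage, 50 random 20 × 30 instances for the PLSR oracle, and 100
repetitions of the 80/20 split — sizes chosen so the full analysis,
including per-fold component selection inside leave-one-out, completes in
about a minute on one core while keeping the Monte-Carlo standard errors
small relative to the tolerances tested.
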