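# Methods

## Problem and model

Quantitative lung CT (emphysema scoring, COPD densitometry) compares
measured CT numbers against fixed HU thresholds, but the CT number of
the same material shifts with scanner, tube potential, dose and
reconstruction kernel.  `lungct` standardizes per-foam mean CT numbers
measured on the COPD gene2 phantom (air and water in silicone
cylinders, an acrylic rod, three reference foams of 64.2, 192.6 and
321.0 kg/m^3, and a surrounding lung-equivalent foam of 160.2 kg/m^3)
so that scans from different scanners and protocols land on a common
80 keV monochromatic scale.

Working in rescaled units `h = CT/1000 + 1` (air 0, water 1), the
method assumes a single-parameter linear relation between rescaled CT
number and electron density ratio ρe*:

    h / ρe* = α (1 − Z) + Z,        Z = Zeff*^n,

with `n = 3.21` (atomic exponent for sub-1000 kg/m^3 materials) and
`Zeff* = 0.871`.  α absorbs the scanner- and protocol-dependent
spectrum; `α80 = 0.946` is its value at the 80 keV reference energy.

The pipeline per scan:

1. **Internal calibration.**  Offsets of the two basis materials —
   air (δa, against −1000 HU) and the dense basis (δr1, against its
   nominal; foam 1 at −700 HU in the proposed mode, water at 0 HU in
   the legacy mode) — are interpolated linearly in electron density:
   `Δr = (δr1 − δa) ρf/ρr1 + δa`, and `h_cal = h_raw − Δr/1000`.
   Basis materials land exactly on their nominals; a pure global
   miscalibration is absorbed completely.
2. **Scanner parameter.**  Per-foam `α(r) = (h_cal/ρe* − Z)/(1 − Z)`
   for the reference foams; the scan's ᾱ is fitted over those foams
   plus the air point.
3. **Energy mapping.**  `ρe,t* = h(t)/[ᾱ(1−Z)+Z]`, then
   `h80 = ρe,t*[α80(1−Z)+Z]` and `CT80 = (h80 − 1)·1000`.

Standardized values are reported for the target (lung foam) and, for
reporting symmetry, for the reference foams themselves using the same
ᾱ they helped fit.

## Design choices

**ᾱ estimator.**  "Regression over the foams and air" is not a unique
estimator, because air's per-foam α is 0/0.  The default (`wls`) is
least squares on the line `h = ρe*·s` constrained through the origin —
the only formulation in which the air point participates meaningfully —
which reduces to the ρe*²-weighted mean of per-foam α;
an unweighted mean over foams is selectable (`alpha_mode="mean"`).  The
choice is recorded in the calibration metadata.

**Electron densities.**  The foams' true electron densities derive from
their elemental composition, which is not published per batch.  Default
ρe* is the mass-density ratio to water times a configurable composition
factor `za_factor` (default 1.0).  Internal calibration consumes only
the ratio ρf/ρr1, which is invariant to `za_factor`; the energy mapping
uses ρe* directly, so users with SRM-derived values should override the
material table via the YAML config.  The constant 0.956 (thoracic
soft-tissue ρe*) is stored for reference but consumed by no equation:
the target's electron density is always estimated from its own
measurement.

**Lung foam nominal.**  The material table carries −835 HU; some
SRM-derived text quotes −856 HU for the same foam.  The table value is
the default and is overridable in the config; only reporting (not the
calibration of other foams) is affected, since the lung foam is a
target, not a basis.

**δa convention.**  The air offset is defined against −1000 HU.  This
is forced by the air fixed point (`h_cal(air) = 0`) and by the
requirement that calibrated foams lie in [0, 1]; defining it against
0 HU is only meaningful for the legacy water basis, where the basis
offset is taken against water's nominal 0 HU.

**Degenerate scans.**  If any calibrated foam's `h_cal` leaves
[−0.05, 1.05] the scan is flagged (and excluded from group summaries by
default, with a per-group exclusion count); processing continues so the
flagged values remain inspectable.  An ᾱ-fit RMS residual above 0.01
(≈10 HU systematic misfit) logs a warning.  All arithmetic is double
precision; report tables round means/SDs to 2 decimals only at
formatting time.

**Truncation correction.**  Some vendors clip CT numbers below a floor
(−1000 or −1024 HU dialects), biasing the measured air mean upward.
The exact correction used in practice is vendor-specific and not
published; the implementation here is a labelled stand-in: clipping is
detected when the fraction of air-ROI voxels at the floor exceeds
`fraction_threshold` (default 0.05), and the mean is then re-estimated
by maximum likelihood under a left-censored Gaussian.  It is exact in
the no-clipping case (returns the plain mean, flag false) and recovers
a half-censored Gaussian's center to within sampling error.

**ROI convention.**  0-based (z, y, x) indices; closed cubes of side
`2·half_width + 1` (default 5×5×5) centered on config-supplied insert
centers.  No automatic phantom localization is attempted — manual
centers match physicist QA practice, and the method consumes only ROI
means.

## Synthetic generator

`simulate.forward_hu` inverts the attenuation model exactly:
`HU(m) = 1000(ρe*·[α_s(1−Z)+Z] − 1)`.  On top of the noiseless value,
`simulate_scan` adds

* a per-scan global miscalibration `b_s ~ N(0, sigma_cal²)`;
* ROI-mean noise `N(0, σ_p²)` with `σ_p = sigma0 · kernel_factor(recon)
  / sqrt(CTDI/1 mGy)` (photon statistics: SD grows at low dose, sharp
  kernels amplify it, iterative reconstruction suppresses it);
* water-only instability `N(0, sigma_water²)` (default 7 HU, the order
  of the spread seen in repeat water readings) emulating bubbles,
  precipitates and container effects.

Standard-normal draws are taken before scaling, so runs with the same
seed and different dose/kernel settings share a noise stream and the
noise magnitude scales exactly as configured.  The default protocol
grid crosses 9 (CTDI, kVp) cells — 1.0 mGy only with 80/100 kVp,
6.0 mGy only with 120 kVp — with 4 reconstruction labels; 8 synthetic
scanners give 288 scans per run (the grid structure of a real
multi-scanner campaign; actual campaign counts vary with per-site
availability).  Per-scan seeds are spawned deterministically from the
master seed.

Two noise regimes matter and the package ships both:

* **Class defaults** (`SimulationConfig()`: sigma0 2.5, sigma_cal 1.0):
  ROI noise dominates.  In this regime internal calibration *amplifies*
  spread — it injects the air and basis reading noise into every foam
  (variance factor ≈ 1.5 for the lung foam) — while the energy-mapping
  step claws some of it back because ᾱ is fitted from the same noisy
  foams and the ratio cancels correlated noise.
* **`campaign_config()`** (sigma0 1.0, sigma_cal 3.0): inter-scanner
  miscalibration dominates, the regime multi-scanner phantom campaigns
  actually show (repeat water readings alone span tens of HU) and the
  one the method is designed for.  Here the stage-wise SD ordering
  raw ≥ internal ≥ standardized holds in expectation, and the demo uses
  this preset.

Because the generator is exactly linear in ρe* through the origin,
internal calibration pins every foam onto the nominal line and the full
pipeline's output is *independent of α_s and b_s at zero noise* — this
is the collapse property the tests assert to < 1e−9 HU.  A corollary:
the pipeline ᾱ of a calibrated zero-noise synthetic scan is a constant
of the nominal table, so scanner-parameter *recovery* is verified at
the estimator level, on rescaled raw measurements with no
miscalibration, where `estimate_alpha_bar` inverts the forward model to
machine precision and is exactly unbiased under additive ROI noise.

What passing tests on this generator do **not** show about real data:
no beam hardening, scatter, kernel-dependent CT-number bias (kernels
only scale noise here), partial-volume effects at insert edges, or
deviations from the single-α linearity across the foam density range —
on real scanners those appear as a nonzero ᾱ-fit residual, which the
package reports per scan.

**Voxel rendering** uses a simplified geometry — circular inserts on a
ring inside an elliptical lung-foam body, air outside — rather than the
manufacturer's exact oval layout; the ROI pipeline never samples
outside insert interiors.  DICOM output encodes HU as signed 16-bit
with RescaleSlope 1/16 (an exact binary fraction): any HU value on the
1/16-HU grid round-trips bit-exactly, anything else is quantized with
error ≤ 1/32 HU.

## Numerical notes

* Internal-calibration stage values are computed as `HU − Δ` (not via
  the rescaled domain), so the zero-offset fixed point is bit-exact.
* `z_pow = Zeff*^n` is recomputed on construction, never hand-entered.
* Tie handling and quantiles in boxplot exports follow Tukey
  (1.5·IQR whiskers) with linear-interpolation quartiles.
* Group SDs use the n−1 denominator; singleton groups report SD 0 with
  a logged warning.
* Per-scan seeds derived from a master seed stay below 2^31.

## Problem sizes

Default study sizes were chosen so a full run (suite plus acceptance
script) represents the method faithfully at desk scale: 8 synthetic
scanners × 36 protocol cells (288 scans) for campaign-level summaries,
200 paired scans for the water-basis comparison, 20 seeds × 4 scanners
for the dose-monotonicity average, and 1000 replicates for the
ᾱ-unbiasedness check.

## Limitations

* The method standardizes ROI summary numbers, not voxels; voxel-wise
  application is a possible extension, deliberately out of scope.
* ᾱ80 is taken as the fixed constant 0.946; no spectral derivation.
* The truncation correction is a principled stand-in, not a
  reproduction of any vendor's filter.
* Electron densities default to mass-density proportionality; accuracy
  of the absolute 80 keV scale (not of the harmonization itself)
  depends on supplying measured ρe* values.
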