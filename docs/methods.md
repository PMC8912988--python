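# Methods

This note documents the models, conventions and numerical choices behind
the package, and what its synthetic validation does and does not show.

## EEM data model and conventions

An EEM is stored as an (emission × excitation) intensity grid on strictly
increasing wavelength axes, matching the on-disk dialect (excitation
header row, emission label column). The reference instrument grid runs
excitation 200–600 nm in 1 nm steps and emission 247.88–829.85 nm in
1.16 nm steps, so emission coordinates are generally not round numbers:
every peak coordinate is resolved to the nearest grid point, with the
lookup tolerance defaulting to one grid spacing of the relevant axis and
ties broken toward the lower wavelength (a documented, arbitrary
convention). Masked cells carry a boolean flag rather than NaN, and are
serialized as the token `NA`; numeric output uses ≥ 9 significant digits
(`%.10g`) so write/read round trips preserve values to I/O precision.

Negative absorbance inputs are clipped to zero with a logged warning —
instrument baselines commonly dip below zero — and absorbance at
arbitrary wavelengths is linearly interpolated, erroring outside the
measured range rather than extrapolating.

## Correction chain

Order: inner-filter correction of sample and blank → blank subtraction →
Rayleigh masking → crop → QSU normalization.

* **Inner-filter effect.** The absorbance (ABA) method: each cell is
  multiplied by `10^(L·(A(λ_ex)+A(λ_em))/2)` at pathlength `L` = 1 cm
  (10 mm cuvette). This is the standard one-pass correction for dilute
  samples; it assumes centered excitation/emission geometry and breaks
  down above roughly A ≈ 1.5, far beyond the A ≤ 0.05 regime simulated
  here.
* **Stage order.** IFE precedes blank subtraction because attenuation is
  sample-specific: subtracting a differently absorbing blank before
  de-attenuation would bias near-zero signals. Masking precedes cropping
  so ridge geometry is intact when flagged; QSU scaling is last (it
  commutes with IFE, which the suite checks to 1e-12).
* **Scatter.** First- and second-order Rayleigh ridges are masked at
  ±10 nm half-widths (configurable; the bands are conventions, not
  measurements). Raman scatter is not masked and Raman-unit
  normalization is out of scope.
* **Blank subtraction** keeps negative residuals (clipping would bias
  near-zero means upward); a flag is set when any cell drops below −5 %
  of the grid maximum.
* **QSU.** Intensities are divided by the raw response of a 1 µg L⁻¹
  quinine sulfate standard at excitation 347.5 nm / emission 450 nm,
  supplied either as a scalar or read off a measured standard EEM at the
  nearest grid cell. Double normalization is a unit error.

## Peak quantification

Peaks are emission cross-sections at a single excitation column averaged
over an emission band: T (275, 340), C (340, 420–470), C+ (400,
470–505); optional B (275, 305) and M (300, 370–420, the midpoint of the
conventional 290–310 nm excitation range). Point peaks (T, B) read the
single nearest emission pixel by default; a configurable half-width
widens them when an averaged window is preferred. Peak C uses the single
operative excitation 340 nm rather than the wider 320–365 nm literature
band. Masked pixels are excluded from band means; more than 50 % masked
is a quality error, not a silent NaN. Percent change between two times is
`100·(v(t₂)−v(t₁))/v(t₁)`, and a literally zero baseline is an error —
very large published percentages typically arise from near-zero
baselines, where the quantity is ill-conditioned.

## Growth coupling and per-cell fluorescence

Plate counts convert as `CFU ml⁻¹ = colonies · dilution / volume`;
zero-colony observations are carried as below detection and excluded
rather than treated as zero cells. Phase classification computes
piecewise slopes of log₁₀(CFU) between consecutive observations: the
initial run of slopes below 0.05 log₁₀ h⁻¹ is lag, the following run at
or above 0.05 is exponential, the remainder stationary. The thresholds
are conventions chosen to separate a flat phase from a typical
0.2–0.45 log₁₀ h⁻¹ exponential rate at the experiment's sampling
schedule; laboratory practice identifies these phases by inspection, and
the defaults reproduce the visual assignment on curves of this shape.
Intervals partition the observed range; lag or stationary may be
zero-length, and a curve with no growing interval is reported as a
single flagged lag phase.

Per-cell fluorescence is `f = QSU/(CFU ml⁻¹/10⁶)` (QSU per 10⁶ CFU),
with log₁₀ f as a derived field. The fraction table reports, per
condition, each peak's **time-course maximum** of the replicate-mean f
(the peak per-cell production the conditions support), their exact sum
`f_total`, and nearest-integer percent shares with ties rounded half-up;
an endpoint-time mode is available instead of the maximum. Replicate
spread is the sample SD (n−1 denominator). On the reference per-cell
table shipped in `examples/`, this rounding reproduces the published
integer shares in the four arithmetically consistent condition columns;
three printed cells elsewhere (50→49, 29→28, 18→19) differ by one from
half-up arithmetic on the printed addends — a rounding provenance that
cannot be recovered from the printed values, so they are documented, not
forced.

## Synthetic forward model

The generator is phenomenological: its purpose is to exercise every
pipeline stage with known truth, not to model pyoverdine chemistry or
carbon metabolism.

* **Fluorophores** are separable 2-D Gaussians (σ_ex 15 nm, σ_em 20 nm)
  centered on the three peak regions. Real AFOM spectra are broader and
  asymmetric; separability is the simplest shape sufficient to test
  peak-picking.
* **Amplitude kinetics** are flat at t = 0 baselines of 2.2 / 0.9 /
  0.6 QSU (T / C / C+), rise linearly from 4 h to 16 h, and plateau at
  each condition's 48 h endpoint level (e.g. SFW3: 51.8 / 162.7 /
  1215.8 QSU). Production beginning before the 6 h growth change-point
  encodes the observation that per-cell fluorescence peaks within the
  first 8 h, ahead of division.
* **Growth** is flat at the 10⁵ CFU ml⁻¹ inoculum for a 6 h lag, then
  exponential to a carrying capacity of 5×10⁶ (no DOC), 10⁷ (limited) or
  5×10⁷ CFU ml⁻¹ (excess DOC), reached at 12 h — rates of 0.28–0.45
  log₁₀ h⁻¹. Sampling follows the experimental schedule: hourly 0–8 h,
  then 12, 16, 20, 24, 36, 48 h (15 points). Observation noise is
  multiplicative lognormal with CV 2.3 %, the scale of triplicate-mean
  spiral-plate counts; single plate counts are noisier.
* **Optics.** The ideal QSU signal is scaled to raw counts by the QS
  reference intensity (1000), Gaussian scatter ridges (50 / 10 QSU, 6 nm
  width) are added along λ_em = λ_ex and λ_em = 2λ_ex, and the whole
  field — blank included, since the blank shares the sample matrix — is
  attenuated by `10^−(A(λ_ex)+A(λ_em))/2`. Absorbance is a 0.01 baseline
  plus bands tracking each fluorophore's excitation profile (2×10⁻⁵ per
  QSU of amplitude, total A ≲ 0.05). Detector noise is additive Gaussian,
  SD 0.05 QSU per pixel, mid-range for a dilute-standard EEM instrument
  at sub-second integration. A fresh, independently noisy blank
  accompanies every measurement, as in fresh-blank subtraction practice.
* **Replicates and seeds.** Three replicates per condition differ by a
  lognormal per-peak amplitude jitter (CV 5 %); every stream (jitter,
  growth noise, per-time EEM noise) derives from the master seed through
  fixed-offset seed sequences, so datasets are byte-identical under a
  fixed seed and every file is independently reproducible.
* **Problem sizes.** The multi-condition dataset uses a coarsened grid
  (5 nm excitation / 4.64 nm emission steps) — 270 sample EEMs of ~6,000
  cells each — which keeps every band with multiple pixels while making
  full-study regeneration a seconds-scale operation; single-EEM checks
  run on the full 401×502 instrument grid.

**What passing shows.** With noise off, preprocessing inverts the
forward model exactly (attenuation, scatter and scaling cancel
analytically), so the round-trip check validates the correction
algebra, not robustness to model misspecification. With noise on, the
six-condition study recovers per-peak fraction-table f values within
≈3 % of truth; this demonstrates the pipeline's statistical behaviour
under the stated noise model only. Real EEMs add Raman scatter,
asymmetric fluorophores, wavelength-dependent instrument response and
absorbance measurement error, none of which the generator emulates.

## Known limitations

* No PARAFAC decomposition, fluorescence regional integration, or
  humification/biological indices; peak-picking only.
* No transmittance-based inner-filter path and no dilution handling.
* Growth-phase thresholds are slope conventions; curves that diverge
  from clean three-phase shapes (diauxie, death phase) will not be
  partitioned meaningfully.
* The fraction table's "maximum f" aggregation and the endpoint mode are
  both provided because either is a defensible summary of per-cell
  production; results can differ materially when kinetics are
  non-monotone.
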