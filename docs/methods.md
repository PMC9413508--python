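# Methods

This note records the models behind each analysis stage, the choices made
where the design was genuinely open, and what the synthetic data do and do
not establish about real measurements.

## Inner-filter correction and peak tracking

Measured fluorescence is corrected multiplicatively,
F_c = F_m·exp((A1 + A2)/2), from the sample absorbance at the excitation and
emission wavelengths. The correction is applied only when both absorbances
accompany a titration point; otherwise the raw intensity is used and the run
record carries a "correction skipped" flag, because guessing absorbances is
worse than reporting that none were measured. Absorbance above 2 triggers a
warning: the parallel-beam approximation behind the formula degrades at high
optical density. When the correction uses the same absorbance pair at every
point it cancels exactly in F0/F, so quenching constants are unaffected by a
constant offset.

Emission maxima are located by taking the tallest interior local maximum
(plateau-aware: a flat-topped peak with strictly smaller values on both
sides counts; monotone or flat traces raise a no-peak error) and refining it
with a parabola through the argmax and its two neighbours. Ties between
equally tall maxima break toward the longer wavelength. On a noiseless
Gaussian band the refined position is accurate to well under 0.1 nm for grid
spacings up to 2 nm. Quenching fits read every titration point at the
*free-protein* peak wavelength, held fixed across the titration, because the
band itself redshifts as quencher binds and a per-spectrum peak readout would
mix the intensity change with the shift.

## Stern–Volmer analysis and mechanism classification

F0/F is regressed on [Q] by ordinary least squares with a free intercept.
The textbook form fixes the intercept at 1; leaving it free makes the fit
robust to normalization drift, and a fitted intercept more than 0.1 from 1 is
recorded as a diagnostic warning rather than an error. Kq = Ksv/τ0 with
τ0 = 1.0×10⁻⁸ s by default (the unquenched tryptophan lifetime of albumin);
both τ0 and the collisional ceiling 2.0×10¹⁰ L mol⁻¹ s⁻¹ are configurable.

Mechanism classification is a vote over three independent rules: the
temperature trend of Ksv (strictly decreasing → static, strictly increasing →
dynamic, otherwise inconclusive), the position of every Kq relative to the
ceiling, and — when lifetime data exist — whether the relative change of
τ_avg across the titration is below 5%. The 5% cutoff is a design choice: a
~1% disturbance is routinely treated as "unchanged" in this assay while a
genuinely collisional quencher shortens the lifetime in proportion to the
quench, so any value in the 2–10% band separates the regimes equally well on
clean data. The verdict is static or dynamic only when every evaluated rule
agrees; any conflict or inconclusive trend yields `combined_or_ambiguous`,
with all rule outcomes attached as evidence. A single temperature with no
lifetime data is insufficient evidence and raises.

## Binding constants and thermodynamics

The double-log isotherm log₁₀((F0−F)/F) = n·log₁₀[Q] + log₁₀Ka is fitted by
OLS over the points with [Q] > 0 (base-10 logs; the [Q] = 0 point defines F0
and is excluded). ln Ka vs 1/T gives ΔH = −R·slope and ΔS = R·intercept with
R = 8.314 J mol⁻¹ K⁻¹; the relation is treated as linear, i.e. heat-capacity
curvature is out of scope. Reported ΔG values follow ΔG = ΔH − TΔS exactly
(bit-for-bit from the stored ΔH, ΔS); −RT·ln Ka is also computed as a
cross-check diagnostic and typically agrees to better than 1%, the residual
being the scatter of individual Ka values about the Van 't Hoff line.

An important caveat the synthetic experiments quantify: Ka is the isotherm's
intercept at log₁₀[Q] = 0, i.e. extrapolated about five decades beyond a
micromolar titration window. Intensity noise therefore hits Ka far harder
than the quantities the regression estimates directly — at 1% multiplicative
noise the median relative error of log₁₀Ka and of n is ~4%, while Ka itself
on the linear scale scatters by tens of percent. Ka values from this assay
are order-of-magnitude statements unless the noise is well below 1%.

Force classification applies the sign rules in order: (ΔH<0, ΔS<0) → van der
Waals + hydrogen bonding; (ΔH>0, ΔS>0) → hydrophobic; ΔS>0 with ΔH negative
or below a small positive ceiling (+10 kJ/mol default) → electrostatic.
(ΔH>0, ΔS<0) lies outside the taxonomy and raises with diagnostics rather
than guessing.

## Lifetime fitting

Decay histograms are tail-fitted from the peak channel with
B + Σ Aᵢ·exp(−t/τᵢ), k ≤ 3, by weighted least squares (weights 1/max(count,1),
the Neyman form of Poisson weighting). The baseline B is fixed to the mean of
the pre-peak channels when the peak sits at least 5 channels into the record
and floats otherwise. The fitted window ends at the noise floor — the last
channel where the smoothed signal still exceeds baseline + max(1, 3√baseline).
Beyond that point channels carry no lifetime information, and including
thousands of empty channels deflates the reduced χ² until even a
single-exponential fit of three-component data "passes"; truncation restores
the statistic's textbook calibration (correctly specified fits give χ²_red ≈ 1).

Model order: among k = 1..3, the smallest k is selected whose reduced χ² is
below the acceptance threshold (1.3, configurable) *and* for which a
nested-model partial F-test (α = 10⁻³) shows no significant improvement from
k+1 components. The F-test matters because a bi-exponential can pass the χ²
gate on tri-exponential data at 10⁴ peak counts while biasing the
amplitude-weighted mean lifetime by ~3%; the variance-ratio test detects the
systematic residual improvement that the absolute χ² level cannot. If no
order passes the gate, the minimum-χ² order is returned with a `poor_fit`
flag. Optimization is multi-start (5 starts, log-spaced τ guesses over
[2·Δt, span/2], seeded lognormal jitter) trust-region least squares;
amplitudes are constrained non-negative and renormalized to fractions, and
τ_avg = Σ τᵢαᵢ is the amplitude-weighted mean throughout. No
instrument-response deconvolution is performed — appropriate for nanosecond
lifetimes measured with sub-100-ps channels, not for sub-channel components.

## Displacement and structure readouts

Displacement index I = 100·F2/F1 per marker concentration; a marker
"competes" when I at the top marker concentration has dropped more than 20
percentage points (configurable — the literature reports "remarkable" vs
"negligible" drops without a number, and observed contrasts of ~45 vs ~4
points make any threshold in the 10–35 band equivalent). The site assignment
is the site of the competing marker(s); a built-in registry maps warfarin
(WF-Na) to Sudlow site I and ibuprofen to site II and can be extended.

CD: MRE₂₂₂ = θ₂₂₂/(10·Cp·n·l) with n = 585 residues for human serum albumin
(required input for other proteins) and l in cm; helix % from the linear
calibration (−MRE₂₂₂ − 2340)/30300 × 100, clamped to [0, 100] with a flag
instead of erroring, since noisy low-signal spectra can land slightly outside
the calibration range. Synchronous-series and 3D-grid peaks reuse the
parabolic peak refinement. Excitation–emission matrices mask the first-order
(|em − ex| ≤ 12 nm) and second-order (|em − 2ex| ≤ 12 nm) Rayleigh ridges
before peak search; the tolerance is configurable and was chosen to cover the
ridge width of typical 5–10 nm slit widths. Labeled fluorophore peaks must be
local maxima whose whole 8-neighbourhood is outside the masked ridges — a
maximum hugging a mask edge is scattering spill-over. The maxima nearest 280
and 230 nm excitation become peak I (aromatic residues) and peak II (peptide
backbone); the ridge maxima themselves are reported separately.

## Synthetic data: what it emulates and what it does not

The generator produces titrations from F = F0/(1 + Ka(T)·[Q]^n) with Ka(T)
propagated through the Van 't Hoff relation, optional Gaussian emission bands
whose centers drift linearly over the titration, Poisson-sampled
multi-exponential decays, displacement series with or without competition,
and CD ellipticities that are exact inverses of the MRE/helix formulas.
Defaults mirror a typical albumin study: 2 µM protein, quencher 0–9 µM in 7
steps, T ∈ {298, 304, 310} K, Ka = 4.09×10⁵ M⁻¹ at 298 K with n = 1.14,
ΔH = −118.75 kJ/mol, a 337 nm emission peak redshifting 12 nm, a
tri-exponential decay with amplitude-weighted mean 5.4907 ns, and 53.94%
(free) / 51.98% (bound) helix content. ΔS is derived from (Ka_ref, T_ref, ΔH)
so the thermodynamic triple is exactly self-consistent (−291.06 J mol⁻¹ K⁻¹
with the defaults); supplying an inconsistent triple raises. Because the
generating isotherm has n ≠ 1, its classical Stern–Volmer slope is an
effective quantity; `GroundTruth.ksv_derived` defines it as the OLS slope of
the noiseless curve.

Noise models are multiplicative Gaussian for analog fluorescence and Poisson
for photon counting, matching the instruments' error physics. All generators
are bit-reproducible given (parameters, seed). What the synthetic data do
*not* contain: scatter/Raman bands, instrument response functions, baseline
drift, pipetting errors correlated across points, or photobleaching. Tests
passing on this data therefore establish correctness of the estimators and
their noise response under idealized conditions, not robustness to every
instrumental artifact.

## Numerical choices

- All OLS fits solve the two-column least-squares problem via `lstsq`;
  r² is 1 − SS_res/SS_tot, defined as 1 for an exactly flat exact fit.
- Concentrations are mol/L and temperatures kelvin internally; readers
  convert µM/mM and Celsius at the boundary.
- Helix clamping and the GroundTruth consistency check use 1e-9 tolerances;
  the amplitude-normalization tolerance for τ_avg is 1e-6.
- Degenerate inputs raise typed errors (`InvalidInputError`,
  `InsufficientDataError`, `NoPeakError`, `FitFailureError`,
  `UnclassifiableError`) rather than returning NaNs.

## Problem sizes

The test suite and acceptance script use the default study geometry: 7-point
titrations at 3 temperatures, 4096-channel decays at 0.05 ns/channel with
10⁴ peak counts (10⁵ when resolving the ~1% bound-vs-free lifetime
difference), 21×61 excitation–emission grids, and 20–50 seeded replicates
for the recovery statistics.
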