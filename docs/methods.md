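# Methods

This note records the models implemented in `protonfilm`, the conventions
and numerical choices behind them, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Net optical density and its uncertainty

A film piece is scanned before and after irradiation in transmission mode
(48-bit RGB, colour management off, 300 DPI → 25.4/300 ≈ 0.0847 mm pixel
pitch). Per colour channel,

    netOD = log10(I0 / I),

with `I0`, `I` the mean counts over a common region of interest. Because the
film piece's centre is the part free of cut-edge damage and lateral scanner
artifacts, the default ROI is the centred rectangle covering 50 % of each
dimension; this fraction is a package convention, not a measured constant,
and any explicit ROI can be supplied instead. ROI coordinates are 0-based
and half-open; ROIs must contain at least 16 pixels so that the sample
statistics are meaningful.

Two uncertainty formulas are shipped because the literature prints both:

* `standard` (default): σ_netOD = (1/ln 10)·√((σ_I0/I0)² + (σ_I/I)²), the
  first-order propagation of log10(I0/I). It tends to a finite noise floor
  as netOD → 0, which matches what a scanner actually does.
* `paper`: the same quantity multiplied by netOD. This variant appears in
  film-dosimetry papers; it vanishes at netOD = 0 and is therefore not the
  default. Neither form is endorsed beyond that; both are selectable
  (`sigma_form`).

σ_I0 and σ_I are by default the standard errors of the ROI means (pixel
SD/√n), because the mean is the estimator entering netOD; raw pixel SD is
available via `sigma_mode="pixel"` for workflows that want a per-pixel
noise figure.

A measurement in which the exposed film reads *brighter* than baseline by
more than 3σ is rejected as physically invalid; smaller negative netODs are
retained unclamped, since clamping them would bias low-dose statistics
upward.

Frames are stored as float64 in 16-bit count units. TIFF output rounds to
uint16 (a ~5·10⁻⁶ netOD quantisation at typical signal levels); in-memory
pipelines stay exact, which is what makes the noiseless round-trip tests
meaningful at the 10⁻⁶ level.

## Dose-response calibration

Per channel, the forward model is the rational saturating curve

    netOD(D) = a·D / (1 + b·Dⁿ),    a > 0, b ≥ 0, n > 0,

fitted by damped least squares (`scipy.optimize.least_squares`, TRF) with
multi-start: `a` starts at the secant slope through the two lowest doses,
and (b, n) start on the grid {0.01, 0.1, 0.5} × {0.7, 1.0, 1.5, 2.0}. The
exponent genuinely varies between film lots (≈0.66–2.11 across the shipped
presets), and single-start fits of this model are unreliable. The best
final SSE wins; ties break toward the smallest exponent. Inverse-variance
weighting is applied when netOD uncertainties are supplied (zero/absent
sigmas fall back to unweighted). Fit quality is reported as
R² = 1 − SS_res/SS_tot and RMSE; a fit with RMSE ≥ 10⁻³ on noiseless input
is considered failed.

The model has no closed-form inverse. Dose recovery fits the empirical
inverse

    D(netOD) = a′·netOD / (1 + b′·netODⁿ′),    b′ ≤ 0,

on 512 equally spaced doses over the fitted range, minimising *relative*
dose residuals. The negative denominator coefficient is essential: for
n = 1 the exact inverse is D = (x/a)/(1 − (b/a)x), i.e. exactly this family,
and for the shipped presets it reaches 0.06–0.4 % worst-case round-trip
error on near-linear channels. We also evaluated the additive form
D = a′·netOD + b′·netODⁿ′; its best achievable worst-case round-trip error
is ≈2.3 % even for the most linear preset (verified by direct minimax
optimisation), so it is not used. Strongly saturating channels (the EBT3
red channel above all) exceed the 2 % round-trip diagnostic with either
family; such fits carry a recorded warning naming the worst dose, and dose
conversion remains usable where the user accepts that figure. Dose
uncertainty is first-order: σ_D = |dD/dnetOD|·σ_netOD along the fitted
inverse.

Calibration transfers only within a film production batch. The three
shipped presets (EBT4 lots B1 and B2, EBT3 lot B4) carry per-channel
(a, b, n) and are the basis of the identifiability tests: noiseless data on
the standard dose ladder must refit every preset to within 0.1 % per
parameter.

The calibration dose ladder is 0.25-Gy steps to 1 Gy, 1-Gy steps to 10 Gy
and 2-Gy steps to 20 Gy — 18 points. Films for calibration are assumed
irradiated in the plateau region of the beam, where LET effects are absent;
applying a plateau calibration near a Bragg peak is precisely what exposes
quenching (below).

## Darkening kinetics

Post-irradiation polymerisation is modelled as a biexponential approach to
saturation,

    netOD(t) = netOD∞ − C1·e^(−t/T1) − C2·e^(−t/T2),

with a fast (hours) and a slow (tens of hours) component, canonicalised to
T1 ≤ T2. Biexponentials are ill-conditioned, so the fit multi-starts over
T1 ∈ {0.5, 2, 8} h × T2 ∈ {12, 24, 72} h with amplitude starts from the
endpoint deficits (the last sample estimates netOD∞; the t = 0 deficit is
split 60/40 between components). Fits with RMSE ≥ 10⁻³ are flagged
unaccepted rather than silently returned.

The protocol question — *when may the film be scanned?* — is answered
model-independently by the differential growth rate

    DGR(t) = 100 · (d netOD/dt) / netOD(48 h)   [%/h],

reported positive for growth. (The definition is sometimes printed with a
leading minus while the quoted rates are positive; positive-for-growth is
the convention here.) The derivative on the non-uniform scan-time grid uses
three-point Lagrange weights at interior points and one-sided two-point
stencils at the ends — exact for linear data everywhere and second-order on
uniform grids, which the tests verify against the analytic derivative. The
48-hour normaliser is the measured sample when the grid contains 48 h (the
standard grid does), otherwise linear interpolation in time. The film is
declared plateaued when the DGR falls below 0.05 %/h; for a fitted model the
crossing is unique (the analytic rate is strictly decreasing) and solved by
Brent's method, while for a raw series it is the first grid time from which
the numerical rate stays below threshold. Scan-delay correction multiplies
an early reading by netOD(48 h)/netOD(t_scan) from the fitted model.

Control-film correction of time series (a control scanned at each time
point) is exposed as an optional pre-step with no default, since whether
such corrections should be multiplicative or additive is
acquisition-dependent.

No numeric biexponential parameters are published for these films; the
generator's darkening truths are package fixtures chosen to reproduce the
qualitative record — ≈80 % of saturation immediately after exposure, ≈95 %
within the first two hours, plateau inside 24–48 h, red > green > blue
amplitudes — and they are stated as fixtures wherever they appear.

## Characterization statistics

All statistics operate on netOD and are invariant under a common rescaling.
Percent differences between two measured quantities are symmetric,
100·|x−y|/mean(x,y): reproducibility (two sessions' means per dose) and
batch variation (two batches' means at a common dose) use it. Energy
dependence is the maximum percent deviation of any energy group's mean from
the grand mean. Sensitivity deviation divides by the model prediction
instead — there the calibration curve, not a second measurement, is the
reference. Two doses are called resolvable when their netOD separation
exceeds k·√2·σ with k = 2 (≈95 % two-sided separation of two equal-variance
measurements); k is exposed. The noise-to-signal ratio of a calibration
dataset averages 100·σ/netOD per channel over non-zero doses. No hypothesis
tests or confidence intervals are attached beyond the k·σ rule.

Note that batch variation computed from netOD *measurements* at one dose
and the difference between two batches' fitted forward curves at that dose
are different quantities; measured lot-to-lot spreads include chemistry
differences the dose-response parameters alone do not carry.

## Profile comparison and quenching

Film and chamber profiles are compared on a common grid (linear
interpolation only — at the ~1 mm native step a spline would overshoot the
sharp peak). The pointwise statistic is 100·(film/chamber − 1); points
where the chamber dose is below 1 % of its maximum are masked, because
beyond the distal fall-off the gradient makes the ratio meaningless.
Lateral profiles are normalised to 100 % at the central axis before
penumbra analysis; level crossings (50/20/5 % by convention) are found by
outward search with linear interpolation, and deviation tables report film
minus chamber in percentage points (the relative form is also emitted).
Peak under-response is the mean relative difference over a ±1 mm window
around the chamber maximum; negative values mean the film under-reads —
LET quenching.

## Synthetic data: what it emulates, and what it does not

The generators invert the measurement chain. A calibration truth fixes
netOD(D); scanner frames are drawn as

    I = mean · (1 + f_ch·Z),   Z ~ N(0,1) i.i.d. per pixel and channel,

with the pre-frame at I0 = 42 000 counts (a typical flatbed transmission
level; arbitrary but fixed) and the post-frame attenuated by
10^(−netOD(D)). Default noise fractions (0.010, 0.016, 0.038 for R, G, B)
give the red < green < blue noise-to-signal ordering characteristic of
film scans. Pixels clip to [0, 65535]; clipping is recorded in frame
metadata and warned about when it exceeds 1 % of pixels. Every generator is
bit-reproducible under a fixed seed.

The beam stand-in is parametric, not physical: an entrance plateau with a
gentle linear rise times a distal cutoff, plus a skewed Gaussian peak with
separate proximal/distal widths (defaults: peak at 157 mm, ≈150 MeV-like;
peak-to-plateau 3.5). Film quenching is a multiplicative under-response
ramping linearly from zero at 15 mm proximal of the peak to `quench_max`
(default 0.18, consistent with the 13–20 % scale seen at clinical doses) at
and beyond it. The lateral field is a flat top with error-function
penumbrae (half-width 50 mm, σ = 3 mm), the film matching the chamber by
default. These are generator knobs for exercising the comparison
statistics — not claims about proton transport. Not emulated: Monte Carlo
or analytic (Bortfeld-type) depth-dose physics, scanner lateral-response
artifacts, film-cutting edge damage, Newton rings, orientation
polarisation. Consequently, passing pipeline tests demonstrates the
*analysis chain* is correct under the stated statistical structure; it does
not validate the physics of any real beam line or scanner.

## Problem sizes and numerics

Simulated frames default to 32×32 pixels (central ROI 16×16 = 256 pixels),
large enough for stable ROI statistics and small enough that full-pipeline
simulations of three batches over the 18-point ladder run in well under a
second. Replicate studies in the test suite use 100–200 seeded repeats for
the noisy-fit benchmarks and 5 films per group for the session/energy
statistics, matching the study design they emulate. Optimiser tolerances
are xtol = ftol = gtol ≈ 10⁻¹⁴–10⁻¹⁵ with generous evaluation budgets;
convergence failures raise with per-start diagnostics rather than
returning silently. Tie-breaks and degenerate limits are defined
explicitly: b = 0 reduces the forward model to a·D and the inverse to
netOD/a; constant kinetics series fit with zero amplitudes and plateau at
t = 0; an infinite plateau threshold returns 0 h.

## Known limitations

* The empirical inverse cannot represent strongly saturating channels to
  better than a few percent over the full 0.25–20 Gy range (worst: EBT3
  red, ≈9 %); such fits carry recorded warnings. Restricting the
  calibration range, or inverting the forward model numerically per
  reading, would be the next step if sub-percent inversion of those
  channels were required.
* Uncertainties are first-order (delta-method) throughout; at very low
  netOD the relative dose uncertainty is dominated by the scanner noise
  floor and should be read with the resolvability criterion, not alone.
* The kinetics truths and the beam stand-in are fixtures (see above), so
  agreement with them exercises correctness of the fitting and comparison
  code, not fidelity to any particular film lot or beam.
* Single-channel analysis only: multichannel dose reconstruction and LET
  correction factors are out of scope by design.
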