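# Methods

`lightplate` models a 24-well optogenetic illumination plate — 48
independently driven LEDs (a top and a bottom LED per well) — together
with the gene-expression responses of two well-characterized optogenetic
systems, so that light programs and their predicted expression outcomes
can be designed, encoded and analyzed entirely in silico.

## Hardware-code model and calibration

Each channel's output photon flux (μmol m⁻² s⁻¹) is modeled as exactly
bilinear in its two hardware codes:

    flux = max_flux · (dc / 63) · (gs / 4095)

where `gs` is the 12-bit PWM grayscale code and `dc` the 6-bit
dot-correction current scale. PWM duty cycle and current scaling are
nominally linear; whether real drivers are linear at very low dot
correction is unverified, so the bilinear form is an explicit
simplification. `predicted_flux` is nondecreasing in both codes, and
`command_for_flux` inverts it with round-half-even so a feasible flux is
reproduced within one grayscale step (calibrated max / 4095).

Calibration equalizes a same-spectrum LED population to a target (by
default the dimmest channel's maximum): the dot correction is the rounded
current fraction, clamped to [1, 63] so every channel stays addressable,
and a fractional grayscale scale (gcal ∈ (0, 1]) absorbs the quantization
residue. Channels whose dot correction rounds below the exact fraction
would need gcal > 1 and are clamped to 1, leaving a deficit of at most
0.5/dc ≈ 1%; across a population with 15% output CV the post-calibration
CV of predicted outputs is a few tenths of a percent. On-disk, the two
calibration files are 24 lines × 2 integer columns (top, bottom); gcal is
stored at 8-bit resolution (code/255), which adds at most 0.2% further
quantization. The file format's resolution is not published; 8 bits is an
assumption recorded here.

## Waveforms, programs, staggered start, randomization

Waveforms map time (minutes) to photon flux: constant, right-continuous
step, sine (`offset + amplitude·sin(2π(t − phase)/period)`, clamped at
zero because an LED cannot emit negative light; `phase` is a time shift
in minutes), hold-previous piecewise, and piecewise-linear (for reference
expression signals, where the slope between knots is meaningful).
Programs are frame sequences of 48 grayscale codes at a fixed timestep;
frame k encodes the waveform at t = k·timestep (left endpoint), and the
frame count is ceil(duration/timestep).

The staggered-start builder assigns each requested sample time t a start
offset `total − t`, running a precondition waveform (dark by default;
protocols that precondition with light override it) before the signal
begins. At harvest every well has experienced the signal for exactly its
sample time — the decoded on-duration in frames equals the sample time
exactly when the timestep divides the sample times. A well with sample
time 0 runs the precondition for the whole program; its signal would
begin exactly at harvest.

Well randomization permutes wells (top and bottom channels move
together — whether the original instrument permutes channels
independently is not published; paired wells are the physically plausible
choice) using numpy's PCG64 generator with the integer seed recorded in
the emitted map, so the permutation is reproducible across platforms.

## Binary program file

The `.lpf` layout is a clean-room design (the authentic firmware layout
lives in unpublished supplementary material): a 32-byte little-endian
header — magic `LPF1`, version, channel count (48), timestep in ms, frame
count, 12 reserved zero bytes — followed by frame-major u16 grayscale
codes in channel order 2·well + position. File size is exactly
32 + 96·n_frames bytes; codes above 4095 are rejected on read and write.

## Steady-state transfer functions

Both systems' steady states are four-parameter Hill curves

    y(I) = basal + (maximum − basal) · Iⁿ / (k_effⁿ + Iⁿ)

For the green/red bacterial two-component system, competing red light
shifts the half-maximal green intensity linearly,
k_eff = k_half + 0.11·I_red, with basal, maximum and n unchanged. The
reference parameterization is 5.3-fold dynamic range, n = 2.6,
k_half = 0.22 μmol m⁻² s⁻¹ (green doses 0–20.10). For the blue-light
yeast two-hybrid system: 5.6-fold range, n = 1.3, k_half = 10.74, valid
over 0.26–93.5 μmol m⁻² s⁻¹; above that range growth defects confound
the steady state, so the set-point map refuses extrapolation unless
asked. Absolute fluorescence scales are arbitrary calibrated units
(basal 1000 for the bacterial reporter, 100 for the yeast reporter);
every quantity of interest is a ratio, rate or intensity, so these
choices are neutral.

A recorded inconsistency in the source characterization: the forward
action-spectrum probe flux is stated as 0.40 μmol m⁻² s⁻¹ and described
as twice k_half, but 2 × 0.22 = 0.44. The printed 0.40 is used.

## Dynamic models

**Yeast (single stage).** A delay τ followed by first-order relaxation
toward the transfer-function set-point f(I_b):

    m(t) = m₀                                   t ≤ τ
    m(t) = f(I_b) + (m₀ − f(I_b)) e^(−α(t−τ))   t > τ

Reference values: τ = 75.13 min, post-delay half-time ln2/α = 222 min.

**Bacteria (two stages).** A delay followed by first-order
transcription-rate switching and first-order dilution:

    dp/dt = k_switch (p_ss(t) − p),   dG/dt = p − k_g G,
    p_ss(t) = k_g · Hill(green(t − τ), red(t − τ))

The governing equations of the original model are not reproduced in the
source text; this structure is a reconstruction that reproduces all three
published timescales (4.5 min delay, 11 min switching, division-limited
reporter dynamics). The "11 min transcription rate switching time" is
interpreted as the half-time ln2/k_switch (the convention in the source
lineage); `switching_time_is_half_time=False` switches to the
time-constant reading. The division time is not printed; 40 min
(k_g = ln2/40) is used as a typical value for this strain and medium and
only affects the shape of synthetic trajectories, not any recovered
target. Whether reporter maturation forms a separate stage is unknown;
the two-stage form is an explicit approximation.

From a preconditioned steady state the step response has the closed form

    G(τ+s) = h₁ + (h₀ − h₁)·[k_g/(k_g−k_s)(e^(−k_s s) − e^(−k_g s)) + e^(−k_g s)]

which is *symmetric under exchanging k_switch and k_g* — a single (or
jointly preconditioned) step experiment cannot label the two rates. Fits
therefore assign the faster rate to transcription switching
(`assume_switching_faster=True`), the physically expected ordering;
disable the flag to keep the raw solver output.

## Fitting

All fits are trust-region (`scipy.optimize.least_squares`, `trf`)
nonlinear least squares with positivity bounds, restarted from 5 seeded
log-normal perturbations of a data-driven initial guess (a few wider
fallback starts are tried if none converges). Standard errors come from
the linearized covariance s²(JᵀJ)⁻¹ with Student-t confidence intervals;
derived quantities (dynamic range, half-times) get delta-method errors.
Shared-parameter fits follow the published conventions: step-on and
step-off time courses share the delay and rate parameters (α for the
yeast system; τ and k_g — and k_switch — for the bacterial system) with
per-dataset levels; dose-response curves across red intensities share
basal, maximum and n with per-dataset k_half, and the red-competition
slope is the linear regression of fitted k_half on red intensity.

Degenerate data are rejected rather than silently fitted: Hill fits need
≥ 4 distinct intensities and flag k_half unreliable when the fitted span
is within the noise or k_half falls outside the sampled range; step fits
raise when almost no samples follow the fitted delay, when the fitted
relaxation is ≥ 5× slower than the observation window, or when the
fitted step amplitude is within 5 residual standard deviations — the
signatures of sampling that ended before the delay.

## Simulation

The two-stage cascade is linear, so simulation propagates the state with
exact exponential updates over substeps (default ≤ 0.25 min) on which the
delayed input is held at its midpoint value; waveform discontinuities,
shifted by the delay, are inserted as step boundaries, making the scheme
exact for piecewise-constant inputs. The delay is honored by evaluating
input waveforms at t − τ, including negative times (a step at t = 0
exposes its preconditioning level); an explicit input history can
override the pre-experiment levels. Every trajectory is recomputed at
half the substep and a relative discrepancy above `rtol` (10⁻⁶) raises a
resolution error. Tests cross-check the integrator against
`scipy.integrate.solve_ivp` and the closed-form step response.

## Function generation (feedforward inversion)

To drive expression along a reference r(t), the cascade is inverted in
exact discrete form: over one frame with a constant set-point the state
propagates by a known exponential map, so each frame's required set-point
is solved algebraically to land the output on the reference at the next
grid point, and the light command is the Hill inverse of that set-point,
issued one delay ahead (rounded to the nearest frame; the residual
sub-frame mismatch contributes an error of order r′·timestep/2). This is
the discrete counterpart of the continuous inversion
p_req = r′ + k_g r, p_ss,req = p_req + p_req′/k_switch, u = Hill⁻¹(p_ss,req/k_g),
which on a grid realizes the impulsive set-points at reference kinks
poorly; the discrete form is exact where the program does not saturate.
References must lie strictly inside (basal, maximum). Required
set-points outside the achievable band, or intensities outside the
commanded bounds, are clamped and reported; the recursion propagates the
realized state so later frames re-converge. Feeding the predicted
trajectory back as the reference reproduces the unsaturated program to
floating-point precision (under saturation the inverse is not unique).

## Action spectra

Forward spectra assign one wavelength per well at matched photon flux;
reverse spectra add a constant activating channel in every well and
report deactivation (reference response minus measured). Summaries are
min-max normalized and reported at measurement resolution: the peak is
the argmax wavelength and the half-maximum band is the contiguous run of
measured wavelengths above 0.5 containing the peak, with no
interpolation — the measured LEDs, not a continuous spectrum, are the
resolution. Whether published bands were computed after basal subtraction
is not stated; min-max normalization (which subtracts the minimum) is the
default, and normalizing by the maximum alone is available via the raw
table. All-equal responses yield a degenerate-spectrum warning and the
full range as the band.

## Synthetic data

Generators are pure functions of (parameters, seed). Measurement noise is
multiplicative log-normal with mean-1 factors (fluorescence is positive
and scatter scales with signal); the default CV is 5%, chosen to match
the visual scale of the published error bars. Dose responses use 24
intensities in triplicate (dark plus 23 log-spaced points for the green
system; 24 log-spaced over 0.26–93.5 for the blue system). Step time
courses are triplicate (published error bars are the SEM of three
experiments): the bacterial design uses 24 staggered sample times, dense
(2-min) early to resolve the minute-scale delay and sparse late; the
yeast design samples every 30 min over 0–900 min. The step levels are the
published ones (green 0 ↔ 17.88 with red 12.79 ↔ 0; blue 0 ↔ 88.8).
Entrainment programs are 12 h:12 h light/dark square trains (red
68.86, blue 244.76 μmol m⁻² s⁻¹) over three cycles with the dark period
starting at offsets {0, 4, 8, 12, 16, 20} h modulo the 24-h period.

Not modeled: day-to-day replicate effects (a single noise tier), flow
cytometry event-level noise, LED emission bandwidth, thermal drift, and
the growth defects above the validated blue-light range. Passing recovery
tests therefore show that the analysis pipeline is correct and unbiased
under the stated noise model at the published designs — not that real
measurements would be this clean.

## Replication studies and problem sizes

`lightplate.replication` re-runs each characterization analysis on
synthetic data and reports recovered medians: 200 replicate fits for the
dose-response and step-kinetics studies, 50 for the seven-dataset
red-competition joint fit; seed streams derive from a single base seed
via `numpy.random.SeedSequence`. Parameter recovery is judged on the
median across replicates because single noisy experiments identify the
minute-scale bacterial delay only weakly (its replicate distribution
spans roughly 1–8 min at 5% noise); 95% CI coverage of the generating
values exceeds 90% in the dose-response study.

## Known limitations

- The bilinear code→flux model and the 8-bit gcal file resolution are
  assumptions where the hardware documentation is not published.
- The two-stage bacterial model is a structural reconstruction; only its
  three timescales are constrained by published values.
- The rate-label ambiguity of preconditioned step responses is resolved
  by convention, not by data.
- Feedforward inversion is open-loop: model mismatch or saturation
  produces tracking error that nothing corrects; closed-loop control is
  out of scope.
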