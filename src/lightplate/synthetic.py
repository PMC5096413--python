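"""Seeded generators for every input the other modules consume.

These emulate the statistical structure of plate-based optogenetic
characterization experiments: Hill-shaped dose responses read out by flow
cytometry, delayed step-response time courses collected by staggered-start
sampling, LED populations with manufacturing output variability, and
light/dark entrainment programs. Noise is multiplicative log-normal
(fluorescence is positive and measurement scatter scales with signal),
with a 5% coefficient of variation by default.

The module also carries the reference parameterizations of the two
characterized systems (the green/red bacterial two-component system and
the blue-light yeast two-hybrid) used throughout the tests and the
acceptance analysis:

* bacterial transfer function: 5.3-fold dynamic range, n = 2.6,
  k_half = 0.22 umol m-2 s-1, shifted 0.11 per unit red;
* bacterial dynamics: 4.5 min delay, 11 min transcription-rate switching
  half-time, dilution set by a 40 min division time;
* yeast transfer function: 5.6-fold range, n = 1.3, k_half = 10.74,
  valid up to 93.5 umol m-2 s-1;
* yeast dynamics: 75.13 min delay, 222 min post-delay half-time.

Absolute fluorescence scales (basal levels) are arbitrary calibrated
units; all derived quantities of interest are ratios or rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .device import N_CHANNELS
from .errors import DomainError
from .kinetics import (
    LN2,
    CcaSDynamicModel,
    DelayedFirstOrderModel,
    HillTransferFunction,
    RedShift,
    ccas_step_response,
    hill_response,
    piecewise_solution,
)
from .programs import Piecewise, PiecewiseLinear

# --- reference parameterizations -------------------------------------------

#: Green-light transfer function of the bacterial two-component system.
CCAS_TRANSFER = HillTransferFunction(basal=1000.0, maximum=5300.0, k_half=0.22, n_hill=2.6)
#: Red-light competition on the half-maximal green intensity.
CCAS_RED_SHIFT = RedShift(0.11)
#: Green intensity range achievable by the green LED (umol m-2 s-1).
CCAS_GREEN_MAX = 20.10
#: Step-experiment levels: green 0 <-> 17.88, red 12.79 <-> 0.
CCAS_STEP_GREEN = 17.88
CCAS_STEP_RED = 12.79

#: Blue-light transfer function of the yeast two-hybrid system, valid on
#: the 0.26-93.5 umol m-2 s-1 range (growth defects confound higher doses).
CRY2_TRANSFER = HillTransferFunction(basal=100.0, maximum=560.0, k_half=10.74, n_hill=1.3)
CRY2_INTENSITY_MIN = 0.26
CRY2_INTENSITY_MAX = 93.5
#: Blue step level used in the kinetic experiments.
CRY2_STEP_BLUE = 88.8


def ccas_model(
    tau_delay: float = 4.5,
    switching_half_time: float = 11.0,
    division_time: float = 40.0,
    transfer: HillTransferFunction = CCAS_TRANSFER,
    red_shift: RedShift = CCAS_RED_SHIFT,
    switching_time_is_half_time: bool = True,
) -> CcaSDynamicModel:
    """Reference dynamic model of the bacterial system.

    ``switching_half_time`` is read as the half-time ln2/k_switch of the
    transcription-rate switching stage; set
    ``switching_time_is_half_time=False`` to read it as the time constant
    1/k_switch instead. The dilution rate is ln2/division_time.
    """
    ks = (LN2 / switching_half_time) if switching_time_is_half_time else (1.0 / switching_half_time)
    return CcaSDynamicModel(
        tau_delay=tau_delay,
        k_switch=ks,
        k_g=LN2 / division_time,
        transfer=transfer,
        red_shift=red_shift,
    )


def cry2_model(
    tau_delay: float = 75.13,
    half_time: float = 222.0,
    transfer: HillTransferFunction = CRY2_TRANSFER,
    m0: float | None = None,
) -> DelayedFirstOrderModel:
    """Reference dynamic model of the yeast system (m0 defaults to basal)."""
    return DelayedFirstOrderModel(
        tau_delay=tau_delay,
        alpha=LN2 / half_time,
        transfer=transfer,
        m0=transfer.basal if m0 is None else m0,
        max_intensity=CRY2_INTENSITY_MAX,
    )


# --- sampling designs --------------------------------------------------------

def ccas_dose_intensities(n: int = 24) -> np.ndarray:
    """Default green dose design: dark plus log-spaced up to the LED maximum."""
    return np.concatenate([[0.0], np.geomspace(0.01, CCAS_GREEN_MAX, n - 1)])


def cry2_dose_intensities(n: int = 24) -> np.ndarray:
    """Default blue dose design over the validated 0.26-93.5 range."""
    return np.geomspace(CRY2_INTENSITY_MIN, CRY2_INTENSITY_MAX, n)


def ccas_step_times() -> np.ndarray:
    """24-well staggered kinetic design: dense early (minute-scale delay),
    sparse late (division-time-scale settling)."""
    return np.array(
        [0, 2, 4, 6, 8, 10, 12, 15, 18, 21, 24, 28,
         32, 36, 40, 50, 60, 75, 90, 110, 130, 160, 200, 240],
        dtype=float,
    )


def cry2_step_times() -> np.ndarray:
    """Sampling every 30 min over 0-900 min (hour-scale yeast dynamics)."""
    return np.arange(0.0, 901.0, 30.0)


# --- noise -------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative log-normal measurement noise.

    ``cv`` is the fractional coefficient of variation; the noise factor has
    mean 1 (sigma^2/2 log-offset). cv = 0 reproduces the model exactly.
    """

    cv: float = 0.05
    distribution: str = "lognormal_multiplicative"
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise DomainError("cv must be >= 0")
        if self.distribution != "lognormal_multiplicative":
            raise DomainError(f"unknown noise distribution {self.distribution!r}")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0:
            return np.asarray(values, dtype=float).copy()
        sigma = math.sqrt(math.log(1.0 + self.cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=np.shape(values))
        return np.asarray(values, dtype=float) * factors


# --- generators --------------------------------------------------------------

def gen_dose_response(
    tf: HillTransferFunction,
    intensities,
    reps: int,
    noise: NoiseSpec,
    red_intensity: float = 0.0,
    shift: RedShift = RedShift(0.0),
) -> pd.DataFrame:
    """Noisy replicate dose-response table (columns intensity, replicate, value)."""
    if reps < 1:
        raise DomainError("reps must be >= 1")
    intensities = np.asarray(intensities, dtype=float)
    rng = np.random.default_rng(noise.seed)
    truth = hill_response(tf, intensities, red_intensity, shift)
    rows = []
    for rep in range(reps):
        vals = noise.apply(truth, rng)
        for I, v in zip(intensities, vals):
            rows.append({"intensity": I, "replicate": rep, "value": v})
    return pd.DataFrame(rows)


def gen_step_response(
    model: DelayedFirstOrderModel | CcaSDynamicModel,
    direction: str,
    t_grid,
    noise: NoiseSpec,
    reps: int = 3,
) -> pd.DataFrame:
    """Noisy step-response time course (columns time_min, replicate, value).

    For the yeast model, 'on' preconditioned dark and stepped to the
    reference blue level; 'off' the reverse. For the bacterial model, 'on'
    is green 0 -> 17.88 with simultaneous red 12.79 -> 0; 'off' the reverse.
    Defaults to triplicate time courses (experiments are run as three
    independent replicates whose SEM the error bars report).
    """
    if reps < 1:
        raise DomainError("reps must be >= 1")
    if direction not in ("on", "off"):
        raise DomainError("direction must be 'on' or 'off'")
    t = np.asarray(t_grid, dtype=float)
    if isinstance(model, DelayedFirstOrderModel):
        if direction == "on":
            m0, I = model.transfer.basal, CRY2_STEP_BLUE
        else:
            m0 = model.set_point(CRY2_STEP_BLUE)
            I = 0.0
        base = DelayedFirstOrderModel(
            model.tau_delay, model.alpha, model.transfer, m0, model.max_intensity
        )
        truth = piecewise_solution(base, I, t)
    elif isinstance(model, CcaSDynamicModel):
        if direction == "on":
            pre = (0.0, CCAS_STEP_RED)
            post = (CCAS_STEP_GREEN, 0.0)
        else:
            pre = (CCAS_STEP_GREEN, 0.0)
            post = (0.0, CCAS_STEP_RED)
        truth = ccas_step_response(model, t, pre[0], pre[1], post[0], post[1])
    else:
        raise DomainError(f"unsupported model type {type(model).__name__}")
    rng = np.random.default_rng(noise.seed)
    truth = np.atleast_1d(truth)
    frames = []
    for rep in range(reps):
        vals = noise.apply(truth, rng)
        frames.append(pd.DataFrame({"time_min": t, "replicate": rep, "value": vals}))
    return pd.concat(frames, ignore_index=True)


def gen_led_population(
    n: int, cv: float, seed: int, nominal_max_flux: float = CCAS_GREEN_MAX
) -> np.ndarray:
    """Simulated maximum outputs of ``n`` same-spectrum LEDs.

    Log-normal around the nominal flux with the given CV, emulating
    manufacturing variability across sockets.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if cv < 0:
        raise DomainError("cv must be >= 0")
    if cv == 0:
        return np.full(n, float(nominal_max_flux))
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return nominal_max_flux * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


# --- function-generation reference ------------------------------------------

def funcgen_reference(
    lo: float = 1500.0, hi: float = 3000.0
) -> tuple[PiecewiseLinear, float]:
    """Canonical tracking reference: linear ramp, hold, slow sine, ease-out.

    Returns (waveform, duration_min). Levels sit well inside the bacterial
    transfer function's output band, and slopes/curvatures are kept gentle
    enough that the required set-points stay within the achievable band
    (tracking speed is bounded by the dilution and switching rates).
    """
    mid = lo + 0.55 * (hi - lo)
    amp = hi - mid
    pts: list[tuple[float, float]] = [(0.0, lo), (150.0, hi), (240.0, hi)]
    for t in np.linspace(250.0, 600.0, 36):
        pts.append((float(t), float(mid + amp * math.cos(2 * math.pi * (t - 240.0) / 360.0))))
    pts += [(660.0, mid), (720.0, mid)]
    dedup = [pts[0]]
    for p in pts[1:]:
        if p[0] > dedup[-1][0]:
            dedup.append(p)
    return PiecewiseLinear(tuple(dedup)), 720.0


# --- entrainment programs ----------------------------------------------------

#: Default photon fluxes of the red (647 nm) and blue (467 nm) channels
#: used for circadian light/dark entrainment.
ENTRAINMENT_RED_FLUX = 68.86
ENTRAINMENT_BLUE_FLUX = 244.76


@dataclass(frozen=True)
class EntrainmentTrain:
    """One phase-shifted light/dark square train (both channels together)."""

    start_offset_h: float
    red: Piecewise
    blue: Piecewise
    duration_min: float


def _square_train(offset_h, light_h, dark_h, n_cycles, level) -> tuple[Piecewise, float]:
    period = light_h + dark_h
    offset = offset_h % period
    duration_h = n_cycles * period
    # light except during [offset + k*period, offset + k*period + dark_h)
    boundaries = []
    for k in range(-1, n_cycles + 1):
        dark_start = offset + k * period
        for b in (dark_start, dark_start + dark_h):
            if 0.0 < b < duration_h:
                boundaries.append(b)

    def state(t_h: float) -> float:
        phase = (t_h - offset) % period
        return 0.0 if phase < dark_h else level

    points = [(0.0, state(0.0))]
    for b in sorted(set(boundaries)):
        points.append((b * 60.0, state(b + 1e-9)))
    return Piecewise(tuple(points)), duration_h * 60.0


def gen_entrainment_program(
    cycle_hours: tuple[float, float] = (12.0, 12.0),
    n_cycles: int = 3,
    start_offsets_h=(0.0, 4.0, 8.0, 12.0, 16.0, 20.0),
    fluxes: tuple[float, float] = (ENTRAINMENT_RED_FLUX, ENTRAINMENT_BLUE_FLUX),
) -> list[EntrainmentTrain]:
    """Light/dark square-wave trains with phase-offset dark periods.

    For offset o the dark period occupies [o, o + dark) modulo the cycle
    period; offsets are taken modulo the period (offset 24 h == offset 0).
    Both channels (red, blue) switch together at their stated fluxes.
    """
    light_h, dark_h = cycle_hours
    if light_h <= 0 or dark_h <= 0:
        raise DomainError("cycle light/dark durations must be > 0")
    period = light_h + dark_h
    for o in start_offsets_h:
        if not 0 <= (o % period) < period:
            raise DomainError("offsets must be finite")
    red_flux, blue_flux = fluxes
    trains = []
    for o in start_offsets_h:
        red, dur = _square_train(o, light_h, dark_h, n_cycles, red_flux)
        blue, _ = _square_train(o, light_h, dark_h, n_cycles, blue_flux)
        trains.append(EntrainmentTrain(float(o), red, blue, dur))
    return trains
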