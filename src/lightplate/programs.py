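"""Symbolic light waveforms and their compilation to 48-channel programs.

A :class:`Waveform` is intensity (photon flux, umol m-2 s-1) versus time
(minutes). Programs are built in three modes mirroring how plate
experiments are designed:

* steady state — one constant flux per channel (dose-response layouts);
* dynamic — one waveform for all 24 top LEDs and one for all bottom LEDs;
* staggered start — each well's signal begins at ``total - sample_time``
  so that at harvest every well has experienced the signal for exactly its
  sample time, letting a whole kinetic time course be collected in a
  single simultaneous harvest.

Well positions can additionally be randomized by a seeded permutation to
decouple treatment from plate position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import device as dev
from .device import (
    CalibrationTable,
    DeviceConfig,
    GS_MAX,
    N_CHANNELS,
    N_WELLS,
    command_for_flux,
    decode_flux,
    well_name,
)
from .errors import CapacityError, DomainError


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------

class Waveform:
    """Base class: a nonnegative photon-flux signal of time in minutes."""

    def __call__(self, t: float) -> float:
        raise NotImplementedError

    def breakpoints(self, duration: float) -> list[float]:
        """Times in (0, duration) where the signal is discontinuous."""
        return []


@dataclass(frozen=True)
class Constant(Waveform):
    level: float

    def __post_init__(self):
        if self.level < 0:
            raise DomainError("level must be >= 0")

    def __call__(self, t: float) -> float:
        return self.level


@dataclass(frozen=True)
class Step(Waveform):
    """Right-continuous step: ``initial_level`` before ``step_time``,
    ``final_level`` at and after it."""

    initial_level: float
    final_level: float
    step_time: float

    def __post_init__(self):
        if self.initial_level < 0 or self.final_level < 0:
            raise DomainError("levels must be >= 0")

    def __call__(self, t: float) -> float:
        return self.final_level if t >= self.step_time else self.initial_level

    def breakpoints(self, duration: float) -> list[float]:
        return [self.step_time] if 0 < self.step_time < duration else []


@dataclass(frozen=True)
class Sine(Waveform):
    """offset + amplitude * sin(2*pi*(t - phase)/period), clamped at 0.

    ``phase`` is a time shift in minutes. Negative excursions clamp to zero
    flux (an LED cannot emit negative light) rather than raising.
    """

    amplitude: float
    period: float
    offset: float
    phase: float = 0.0

    def __post_init__(self):
        if self.period <= 0:
            raise DomainError("period must be > 0")

    def __call__(self, t: float) -> float:
        v = self.offset + self.amplitude * math.sin(2 * math.pi * (t - self.phase) / self.period)
        return max(0.0, v)


@dataclass(frozen=True)
class Piecewise(Waveform):
    """Hold-previous interpolation over (time, level) breakpoints.

    Breakpoint times must be strictly increasing and start at 0.
    """

    points: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if not self.points:
            raise DomainError("piecewise waveform needs at least one breakpoint")
        times = [p[0] for p in self.points]
        if times[0] != 0:
            raise DomainError("first breakpoint must be at time 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DomainError("breakpoint times must be strictly increasing")
        if any(p[1] < 0 for p in self.points):
            raise DomainError("levels must be >= 0")

    def __call__(self, t: float) -> float:
        level = self.points[0][1]
        for bt, lv in self.points:
            if bt <= t:
                level = lv
            else:
                break
        return level

    def breakpoints(self, duration: float) -> list[float]:
        return [bt for bt, _ in self.points if 0 < bt < duration]


@dataclass(frozen=True)
class PiecewiseLinear(Waveform):
    """Linear interpolation between (time, level) breakpoints; holds the
    last level afterwards. Used for reference expression waveforms, where
    the slope between knots is meaningful (light programs themselves use
    the hold-previous :class:`Piecewise`)."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.points) < 2:
            raise DomainError("piecewise-linear waveform needs >= 2 breakpoints")
        times = [p[0] for p in self.points]
        if times[0] != 0:
            raise DomainError("first breakpoint must be at time 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DomainError("breakpoint times must be strictly increasing")
        if any(p[1] < 0 for p in self.points):
            raise DomainError("levels must be >= 0")

    def __call__(self, t: float) -> float:
        times = [p[0] for p in self.points]
        levels = [p[1] for p in self.points]
        return float(np.interp(t, times, levels))

    def breakpoints(self, duration: float) -> list[float]:
        # kinks: interior knots where the slope changes
        return [bt for bt, _ in self.points[1:-1] if 0 < bt < duration]


@dataclass(frozen=True)
class Shifted(Waveform):
    """``base`` delayed by ``offset`` minutes; ``before`` applies earlier.

    Used by the staggered-start builder: before the shifted signal begins
    the well runs its preconditioning waveform.
    """

    base: Waveform
    offset: float
    before: Waveform = Constant(0.0)

    def __call__(self, t: float) -> float:
        if t < self.offset:
            return self.before(t)
        return self.base(t - self.offset)

    def breakpoints(self, duration: float) -> list[float]:
        pts = [self.offset] if 0 < self.offset < duration else []
        pts += [b for b in self.before.breakpoints(self.offset) if b < self.offset]
        if duration > self.offset:
            pts += [self.offset + b for b in self.base.breakpoints(duration - self.offset)]
        return sorted(p for p in pts if 0 < p < duration)


def eval_waveform(w: Waveform, t: float) -> float:
    """Evaluate a waveform at time ``t`` minutes (t >= 0)."""
    if t < 0:
        raise DomainError("time must be >= 0")
    return w(t)


# ---------------------------------------------------------------------------
# Programs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LightProgram:
    """Discretized program: frames of 48 grayscale codes at a fixed timestep."""

    timestep_ms: int
    frames: np.ndarray  # (n_frames, 48) uint16

    def __post_init__(self):
        f = np.asarray(self.frames, dtype=np.uint16)
        if f.ndim != 2 or f.shape[1] != N_CHANNELS:
            raise DomainError(f"frames must be (n, {N_CHANNELS}), got {f.shape}")
        if f.size and f.max() > GS_MAX:
            raise DomainError(f"grayscale code {int(f.max())} exceeds {GS_MAX}")
        if not (isinstance(self.timestep_ms, (int, np.integer)) and self.timestep_ms >= 1):
            raise DomainError("timestep_ms must be an integer >= 1")
        object.__setattr__(self, "frames", f)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def __eq__(self, other):
        return (
            isinstance(other, LightProgram)
            and self.timestep_ms == other.timestep_ms
            and self.frames.shape == other.frames.shape
            and bool(np.all(self.frames == other.frames))
        )


def _n_frames(duration_min: float, timestep_ms: int) -> int:
    return math.ceil(duration_min * 60_000 / timestep_ms)


def _frame_times_min(n: int, timestep_ms: int) -> np.ndarray:
    return np.arange(n) * (timestep_ms / 60_000)


def build_steady_state(
    grid: Sequence[float],
    duration: float,
    device: DeviceConfig,
    calib: CalibrationTable,
) -> LightProgram:
    """Constant program: one flux per channel (hardware order), every frame equal."""
    grid = np.asarray(grid, dtype=float)
    if grid.shape != (N_CHANNELS,):
        raise DomainError(f"grid must have {N_CHANNELS} fluxes, got {grid.shape}")
    codes = np.zeros(N_CHANNELS, dtype=np.uint16)
    for ch in device.by_index:
        codes[ch.channel_index] = command_for_flux(ch, calib, float(grid[ch.channel_index]))
    n = _n_frames(duration, device.timestep_ms)
    return LightProgram(device.timestep_ms, np.tile(codes, (n, 1)))


def build_dynamic(
    top: Waveform,
    bottom: Waveform,
    duration: float,
    device: DeviceConfig,
    calib: CalibrationTable,
) -> LightProgram:
    """All top LEDs run ``top``, all bottom LEDs run ``bottom``."""
    if duration <= 0:
        raise DomainError("duration must be > 0")
    per_well = {w: (top, bottom) for w in range(N_WELLS)}
    return build_per_well(per_well, duration, device, calib)


def build_per_well(
    waveforms: dict[int, tuple[Waveform, Waveform]],
    duration: float,
    device: DeviceConfig,
    calib: CalibrationTable,
) -> LightProgram:
    """General builder: per-well (top, bottom) waveform pairs; missing wells dark."""
    n = _n_frames(duration, device.timestep_ms)
    times = _frame_times_min(n, device.timestep_ms)
    frames = np.zeros((n, N_CHANNELS), dtype=np.uint16)
    for well, (top_w, bot_w) in waveforms.items():
        for pos, wave in (("top", top_w), ("bottom", bot_w)):
            ch = device.channel(well, pos)
            col = np.fromiter(
                (command_for_flux(ch, calib, eval_waveform(wave, float(t))) for t in times),
                dtype=np.uint16,
                count=n,
            )
            frames[:, ch.channel_index] = col
    return LightProgram(device.timestep_ms, frames)


# ---------------------------------------------------------------------------
# Staggered start
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaggeredSchedule:
    """Kinetic sampling design for a single simultaneous harvest.

    Each entry of ``sample_times`` (minutes) is assigned to one well; the
    well's signal starts at ``total_duration - sample_time`` so it has run
    for exactly the sample time at harvest. Before its start offset the
    well runs ``precondition_waveform`` (dark by default).
    """

    sample_times: tuple[float, ...]
    precondition_waveform: Waveform = Constant(0.0)

    def __post_init__(self):
        if len(self.sample_times) > N_WELLS:
            raise CapacityError(
                f"{len(self.sample_times)} sample times exceed {N_WELLS} wells"
            )
        if any(t < 0 for t in self.sample_times):
            raise DomainError("sample times must be >= 0")

    @property
    def total_duration(self) -> float:
        return max(self.sample_times)

    @property
    def start_offsets(self) -> tuple[float, ...]:
        total = self.total_duration
        return tuple(total - t for t in self.sample_times)


def build_staggered(
    signal: Waveform,
    schedule: StaggeredSchedule,
    device: DeviceConfig,
    calib: CalibrationTable,
    position: str = "bottom",
) -> LightProgram:
    """Compile a staggered-start kinetic program.

    Wells are assigned in order of ``schedule.sample_times``; the signal is
    run on ``position`` ('top'|'bottom'|'both'); unused wells stay dark.
    """
    if position not in ("top", "bottom", "both"):
        raise DomainError("position must be 'top', 'bottom' or 'both'")
    dark = Constant(0.0)
    per_well: dict[int, tuple[Waveform, Waveform]] = {}
    for well, offset in enumerate(schedule.start_offsets):
        shifted = Shifted(signal, offset, schedule.precondition_waveform)
        top_w = shifted if position in ("top", "both") else dark
        bot_w = shifted if position in ("bottom", "both") else dark
        per_well[well] = (top_w, bot_w)
    return build_per_well(per_well, schedule.total_duration, device, calib)


# ---------------------------------------------------------------------------
# Randomization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomizationMap:
    """Seeded bijection over wells: ``permutation[logical] = physical``."""

    seed: int
    permutation: tuple[int, ...]

    def __post_init__(self):
        if sorted(self.permutation) != list(range(N_WELLS)):
            raise DomainError("permutation must be a bijection over wells 0..23")

    @property
    def inverse(self) -> tuple[int, ...]:
        inv = [0] * N_WELLS
        for logical, physical in enumerate(self.permutation):
            inv[physical] = logical
        return tuple(inv)

    def to_frame(self, sample_times: Sequence[float] | None = None) -> pd.DataFrame:
        """User-readable randomization table (one row per physical well)."""
        rows = []
        for logical, physical in enumerate(self.permutation):
            st = (
                sample_times[logical]
                if sample_times is not None and logical < len(sample_times)
                else None
            )
            rows.append(
                {
                    "physical_well": well_name(physical),
                    "logical_well": well_name(logical),
                    "sample_time_min": st,
                    "seed": self.seed,
                }
            )
        rows.sort(key=lambda r: dev.well_index(r["physical_well"]))
        return pd.DataFrame(rows)


def _permutation_for_seed(seed: int) -> tuple[int, ...]:
    # PCG64 is the named, versioned generator recorded with the seed so the
    # permutation reproduces across platforms and numpy versions.
    rng = np.random.Generator(np.random.PCG64(seed))
    return tuple(int(x) for x in rng.permutation(N_WELLS))


def randomize_wells(program: LightProgram, seed: int) -> tuple[LightProgram, RandomizationMap]:
    """Permute wells (top+bottom channels move together) by a seeded bijection."""
    perm = _permutation_for_seed(seed)
    rmap = RandomizationMap(seed, perm)
    frames = np.empty_like(program.frames)
    for logical, physical in enumerate(perm):
        frames[:, 2 * physical] = program.frames[:, 2 * logical]
        frames[:, 2 * physical + 1] = program.frames[:, 2 * logical + 1]
    return LightProgram(program.timestep_ms, frames), rmap


def derandomize_program(program: LightProgram, rmap: RandomizationMap) -> LightProgram:
    """Undo :func:`randomize_wells` (logical-order program back)."""
    frames = np.empty_like(program.frames)
    for logical, physical in enumerate(rmap.permutation):
        frames[:, 2 * logical] = program.frames[:, 2 * physical]
        frames[:, 2 * logical + 1] = program.frames[:, 2 * physical + 1]
    return LightProgram(program.timestep_ms, frames)


def derandomize(measurements: pd.DataFrame, rmap: RandomizationMap) -> pd.DataFrame:
    """Reassign a measurement table keyed by physical well to logical wells.

    ``measurements`` must have a 'well' column of plate labels (A1..D6);
    the returned table is keyed by the logical well each physical well ran.
    """
    if "well" not in measurements.columns:
        raise KeyError("measurements must have a 'well' column")
    phys = [dev.well_index(w) for w in measurements["well"]]
    if sorted(set(phys)) != sorted(set(rmap.permutation)):
        raise KeyError("measurement wells do not match the randomization map")
    inv = rmap.inverse
    out = measurements.copy()
    out["well"] = [well_name(inv[p]) for p in phys]
    return out.sort_values("well", kind="stable").reset_index(drop=True)


def decode_program(
    program: LightProgram, device: DeviceConfig, calib: CalibrationTable
) -> np.ndarray:
    """Decode a program to predicted fluxes, shape (n_frames, 48)."""
    scale = np.empty(N_CHANNELS)
    for ch in device.by_index:
        scale[ch.channel_index] = decode_flux(ch, calib, GS_MAX) / GS_MAX
    return program.frames.astype(float) * scale
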