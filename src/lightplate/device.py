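"""Device geometry, hardware codes and LED output calibration.

The plate drives 48 LEDs: a top and a bottom LED in each of 24 wells
(rows A-D x columns 1-6, row-major). Each channel's instantaneous output
is set by a 12-bit pulse-width-modulation "grayscale" code (0-4095) and a
6-bit "dot correction" current-scaling code (0-63). Output photon flux is
modeled as bilinear in the two code fractions:

    flux = max_flux * (dc / 63) * (grayscale / 4095)

which is the nominal behaviour of PWM duty-cycle and current scaling; the
electro-optical transfer curve of real drivers may deviate at low codes.

Calibration equalizes a population of same-spectrum LEDs to a common
target (by default the dimmest channel's maximum) by choosing per-channel
dot-correction integers and a fractional grayscale scale ("gcal").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InfeasibleFluxError

N_WELLS = 24
N_CHANNELS = 48
GS_MAX = 4095
DC_MAX = 63

_ROWS = "ABCD"
_COLS = 6


def well_name(well_index: int) -> str:
    """Row-major well label: 0 -> 'A1', 5 -> 'A6', 6 -> 'B1', 23 -> 'D6'."""
    if not 0 <= well_index < N_WELLS:
        raise DomainError(f"well_index {well_index} outside 0..{N_WELLS - 1}")
    return f"{_ROWS[well_index // _COLS]}{well_index % _COLS + 1}"


def well_index(name: str) -> int:
    """Inverse of :func:`well_name` ('A1'..'D6' -> 0..23)."""
    name = name.strip().upper()
    try:
        row = _ROWS.index(name[0])
        col = int(name[1:]) - 1
    except (ValueError, IndexError):
        raise DomainError(f"malformed well name {name!r}") from None
    if not 0 <= col < _COLS:
        raise DomainError(f"malformed well name {name!r}")
    return row * _COLS + col


@dataclass(frozen=True)
class LEDChannel:
    """One LED socket.

    Parameters
    ----------
    well_index : int
        0-23, row-major A1..D6.
    position : str
        'top' or 'bottom'.
    wavelength_nm : float
        Peak emission wavelength.
    max_flux : float
        Photon flux in umol m-2 s-1 at grayscale 4095, dot correction 63.
    """

    well_index: int
    position: str
    wavelength_nm: float
    max_flux: float

    def __post_init__(self):
        if not 0 <= self.well_index < N_WELLS:
            raise DomainError(f"well_index {self.well_index} outside 0..23")
        if self.position not in ("top", "bottom"):
            raise DomainError(f"position must be 'top' or 'bottom', got {self.position!r}")
        if not self.wavelength_nm > 0:
            raise DomainError("wavelength_nm must be positive")
        if not self.max_flux > 0:
            raise DomainError("max_flux must be positive")

    @property
    def channel_index(self) -> int:
        """Hardware channel 0-47: 2*well + (0 if top else 1)."""
        return 2 * self.well_index + (0 if self.position == "top" else 1)


@dataclass(frozen=True)
class DeviceConfig:
    """Full 48-channel plate configuration with the frame timestep."""

    channels: tuple[LEDChannel, ...]
    timestep_ms: int = 1000

    def __post_init__(self):
        if len(self.channels) != N_CHANNELS:
            raise DomainError(f"need exactly {N_CHANNELS} channels, got {len(self.channels)}")
        seen = {(c.well_index, c.position) for c in self.channels}
        if len(seen) != N_CHANNELS:
            raise DomainError("every (well, position) pair must appear exactly once")
        if not (isinstance(self.timestep_ms, int) and self.timestep_ms >= 1):
            raise DomainError("timestep_ms must be an integer >= 1")

    def channel(self, well: int, position: str) -> LEDChannel:
        idx = 2 * well + (0 if position == "top" else 1)
        return self.by_index[idx]

    @property
    def by_index(self) -> tuple[LEDChannel, ...]:
        """Channels sorted by hardware channel index."""
        return tuple(sorted(self.channels, key=lambda c: c.channel_index))

    @classmethod
    def uniform(
        cls,
        top_wavelength_nm: float = 533.0,
        bottom_wavelength_nm: float = 533.0,
        top_max_flux: float = 20.10,
        bottom_max_flux: float = 20.10,
        timestep_ms: int = 1000,
    ) -> "DeviceConfig":
        """Plate outfitted with one LED type per position, same in every well."""
        chans = []
        for w in range(N_WELLS):
            chans.append(LEDChannel(w, "top", top_wavelength_nm, top_max_flux))
            chans.append(LEDChannel(w, "bottom", bottom_wavelength_nm, bottom_max_flux))
        return cls(tuple(chans), timestep_ms)


@dataclass(frozen=True)
class CalibrationTable:
    """Per-channel dot-correction integers and fractional grayscale scales.

    dc[i] in [1, 63]; gcal[i] in (0, 1]. Channel order is hardware order
    (2*well + position).
    """

    dc: tuple[int, ...]
    gcal: tuple[float, ...]

    def __post_init__(self):
        if len(self.dc) != N_CHANNELS or len(self.gcal) != N_CHANNELS:
            raise DomainError("dc and gcal must each have exactly 48 entries")
        for i, d in enumerate(self.dc):
            if not (1 <= d <= DC_MAX):
                raise DomainError(f"dc[{i}]={d} outside [1, {DC_MAX}]")
        for i, g in enumerate(self.gcal):
            if not (0.0 < g <= 1.0):
                raise DomainError(f"gcal[{i}]={g} outside (0, 1]")

    @classmethod
    def identity(cls) -> "CalibrationTable":
        return cls((DC_MAX,) * N_CHANNELS, (1.0,) * N_CHANNELS)

    def calibrated_max(self, channel: LEDChannel) -> float:
        """Maximum achievable flux at grayscale 4095 under this calibration."""
        i = channel.channel_index
        return channel.max_flux * (self.dc[i] / DC_MAX) * self.gcal[i]


def predicted_flux(channel: LEDChannel, grayscale: int, dc: int) -> float:
    """Model-predicted photon flux for raw hardware codes.

    Bilinear in the grayscale and dot-correction fractions:
    ``max_flux * (dc/63) * (grayscale/4095)``.
    """
    if not 0 <= grayscale <= GS_MAX:
        raise DomainError(f"grayscale {grayscale} outside [0, {GS_MAX}]")
    if not 0 <= dc <= DC_MAX:
        raise DomainError(f"dot correction {dc} outside [0, {DC_MAX}]")
    return channel.max_flux * (dc / DC_MAX) * (grayscale / GS_MAX)


def compute_calibration(
    measured_max_flux: Sequence[float],
    target_flux: float | None = None,
) -> CalibrationTable:
    """Equalize 48 LED outputs to a common target.

    For each channel the dot correction is the rounded (half-to-even) code
    closest to the required current fraction, and the grayscale scale mops
    up the quantization residue:

        dc_i   = clamp(round(63 * target / measured_i), 1, 63)
        gcal_i = clamp(target / (measured_i * dc_i / 63), 0+, 1)

    Parameters
    ----------
    measured_max_flux : sequence of 48 positive floats
        Measured output of each channel at full codes, hardware order.
    target_flux : float, optional
        Common post-calibration maximum. Defaults to the dimmest channel
        (min of the measurements), which every channel can reach.
    """
    m = np.asarray(measured_max_flux, dtype=float)
    if m.shape != (N_CHANNELS,):
        raise DomainError(f"need exactly {N_CHANNELS} measurements, got {m.shape}")
    if np.any(m <= 0):
        bad = np.nonzero(m <= 0)[0].tolist()
        raise DomainError(f"non-positive measured flux at channels {bad}")
    if target_flux is None:
        target_flux = float(m.min())
    if target_flux <= 0:
        raise DomainError("target_flux must be positive")
    if target_flux > m.min() * (1 + 1e-12):
        bad = np.nonzero(m < target_flux)[0].tolist()
        raise InfeasibleFluxError(
            f"target {target_flux} exceeds the maximum of channels {bad}"
        )
    # round-half-even via np.round, consistent with the rest of the package
    dc = np.clip(np.round(DC_MAX * target_flux / m).astype(int), 1, DC_MAX)
    gcal = target_flux / (m * dc / DC_MAX)
    gcal = np.clip(gcal, np.nextafter(0.0, 1.0), 1.0)
    return CalibrationTable(tuple(int(d) for d in dc), tuple(float(g) for g in gcal))


def command_for_flux(
    channel: LEDChannel, calib: CalibrationTable, desired_flux: float
) -> int:
    """Grayscale code whose predicted calibrated output is closest to ``desired_flux``.

    Round-trip guarantee: for feasible flux the decoded output is within one
    grayscale step (calibrated_max / 4095) of the request.
    """
    if desired_flux < 0:
        raise DomainError(f"desired_flux must be >= 0, got {desired_flux}")
    cmax = calib.calibrated_max(channel)
    if desired_flux > cmax * (1 + 1e-9):
        raise InfeasibleFluxError(
            f"requested {desired_flux:.6g} umol m-2 s-1 exceeds calibrated maximum "
            f"{cmax:.6g} for well {well_name(channel.well_index)} {channel.position}"
        )
    code = int(np.round(GS_MAX * desired_flux / cmax))
    return min(max(code, 0), GS_MAX)


def decode_flux(channel: LEDChannel, calib: CalibrationTable, grayscale: int) -> float:
    """Predicted flux of a grayscale code under a calibration (inverse of command)."""
    i = channel.channel_index
    return predicted_flux(channel, grayscale, calib.dc[i]) * calib.gcal[i]


def read_measured_intensity_csv(path) -> np.ndarray:
    """Read a measured-intensity table (columns well, position, flux).

    Returns the 48 fluxes in hardware channel order.
    """
    df = pd.read_csv(path)
    required = {"well", "position", "flux"}
    if not required.issubset(df.columns):
        raise DomainError(f"measured-intensity CSV needs columns {sorted(required)}")
    out = np.full(N_CHANNELS, np.nan)
    for _, row in df.iterrows():
        w = well_index(str(row["well"]))
        pos = str(row["position"]).strip().lower()
        if pos not in ("top", "bottom"):
            raise DomainError(f"position must be top/bottom, got {row['position']!r}")
        out[2 * w + (0 if pos == "top" else 1)] = float(row["flux"])
    if np.isnan(out).any():
        missing = np.nonzero(np.isnan(out))[0].tolist()
        raise DomainError(f"measured-intensity CSV missing channels {missing}")
    return out
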