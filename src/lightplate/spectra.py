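"""Action-spectrum experiment design and summarization.

A forward action spectrum (FAS) probes a photoreceptor's ground state:
each well carries an LED of a different wavelength, all emitting the same
photon flux, and the steady-state response is read per wavelength. A
reverse action spectrum (RAS) probes the activated state: every well is
additionally held active by a constant activating channel (the
antagonist's competitor), and the variable-wavelength LED measures
deactivation.

Summaries are reported at measurement resolution — the peak wavelength
and the contiguous half-maximum band — with no interpolation between the
measured LED wavelengths.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .device import (
    CalibrationTable,
    DeviceConfig,
    LEDChannel,
    N_CHANNELS,
    N_WELLS,
    well_name,
)
from .errors import CapacityError, DomainError, InfeasibleFluxError
from .programs import LightProgram, build_steady_state


@dataclass(frozen=True)
class ActionSpectrum:
    """Measured response versus LED wavelength.

    entries: (wavelength_nm, mean response, SEM) triples, unique wavelengths.
    mode: 'forward' (ground state) or 'reverse' (activated state; requires
    the antagonist (wavelength, flux) that held the system active).
    reference_response: for reverse mode, the response with no deactivating
    light; defaults to the maximum measured response when omitted.
    """

    entries: tuple[tuple[float, float, float], ...]
    mode: str = "forward"
    reference_flux: float = 0.0
    antagonist: tuple[float, float] | None = None
    reference_response: float | None = None

    def __post_init__(self):
        wl = [e[0] for e in self.entries]
        if len(set(wl)) != len(wl):
            raise DomainError("wavelengths must be unique")
        if any(e[1] < 0 for e in self.entries):
            raise DomainError("responses must be >= 0")
        if self.mode not in ("forward", "reverse"):
            raise DomainError("mode must be 'forward' or 'reverse'")
        if self.mode == "reverse" and self.antagonist is None:
            raise DomainError("reverse mode requires the antagonist (wavelength, flux)")

    @classmethod
    def from_table(cls, df: pd.DataFrame, mode="forward", reference_flux=0.0,
                   antagonist=None, reference_response=None) -> "ActionSpectrum":
        """Build from a tidy table with columns wavelength_nm, replicate, value."""
        need = {"wavelength_nm", "value"}
        if not need.issubset(df.columns):
            raise DomainError(f"spectrum table needs columns {sorted(need)}")
        g = df.groupby("wavelength_nm")["value"]
        mean = g.mean()
        sem = g.sem().fillna(0.0)
        entries = tuple(
            (float(w), float(mean[w]), float(sem[w])) for w in sorted(mean.index)
        )
        return cls(entries, mode, reference_flux, antagonist, reference_response)


def design_spectrum_program(
    leds: Sequence[LEDChannel],
    probe_flux: float,
    antagonist: tuple[LEDChannel, float] | None,
    device: DeviceConfig,
    calib: CalibrationTable,
    duration: float = 1.0,
) -> LightProgram:
    """One wavelength per well at matched photon flux.

    ``leds`` (<= 24, distinct wavelengths, distinct wells) are driven at
    ``probe_flux``. In reverse mode ``antagonist`` is an (LED template,
    flux) whose channel position is held constant in every well carrying a
    probe LED. All channels must belong to ``device``.
    """
    if len(leds) > N_WELLS:
        raise CapacityError(f"{len(leds)} LEDs exceed {N_WELLS} wells")
    wl = [c.wavelength_nm for c in leds]
    if len(set(wl)) != len(wl):
        raise DomainError("probe LEDs must have distinct wavelengths")
    wells = [c.well_index for c in leds]
    if len(set(wells)) != len(wells):
        raise DomainError("probe LEDs must occupy distinct wells")

    grid = np.zeros(N_CHANNELS)
    for c in leds:
        cmax = calib.calibrated_max(c)
        if probe_flux > cmax * (1 + 1e-9):
            raise InfeasibleFluxError(
                f"probe flux {probe_flux:.6g} exceeds the calibrated maximum "
                f"{cmax:.6g} of the {c.wavelength_nm:g} nm LED "
                f"(well {well_name(c.well_index)} {c.position})"
            )
        grid[c.channel_index] = probe_flux
    if antagonist is not None:
        ant_led, ant_flux = antagonist
        ant_pos = ant_led.position
        for c in leds:
            ch = device.channel(c.well_index, ant_pos)
            cmax = calib.calibrated_max(ch)
            if ant_flux > cmax * (1 + 1e-9):
                raise InfeasibleFluxError(
                    f"antagonist flux {ant_flux:.6g} exceeds calibrated maximum "
                    f"{cmax:.6g} in well {well_name(c.well_index)} {ant_pos}"
                )
            grid[ch.channel_index] = ant_flux
    return build_steady_state(grid, duration, device, calib)


@dataclass(frozen=True)
class SpectrumSummary:
    peak_wavelength: float
    half_max_band: tuple[float, float]
    normalized: pd.DataFrame  # wavelength_nm, response, normalized
    mode: str
    degenerate: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "peak_wavelength_nm": self.peak_wavelength,
                "half_max_band_nm": list(self.half_max_band),
                "degenerate": self.degenerate,
                "normalized": {
                    str(w): round(v, 6)
                    for w, v in zip(
                        self.normalized["wavelength_nm"], self.normalized["normalized"]
                    )
                },
            },
            indent=2,
        )


def summarize_spectrum(spec: ActionSpectrum) -> SpectrumSummary:
    """Peak wavelength and contiguous >50% half-maximum band.

    Responses are min-max normalized (peak -> 1, minimum -> 0), making the
    summary invariant to positive affine scaling. In reverse mode the
    summarized quantity is deactivation: reference response minus measured.
    The band is the contiguous run of measured wavelengths with normalized
    response > 0.5 that contains the peak; endpoints are members of the
    measured set (no interpolation).
    """
    if len(spec.entries) < 3:
        raise DomainError("need >= 3 wavelengths to summarize a spectrum")
    wl = np.array([e[0] for e in spec.entries])
    resp = np.array([e[1] for e in spec.entries])
    order = np.argsort(wl)
    wl, resp = wl[order], resp[order]
    mode_label = spec.mode
    if spec.mode == "reverse":
        ref = spec.reference_response if spec.reference_response is not None else resp.max()
        resp = np.maximum(ref - resp, 0.0)
        mode_label = "reverse (deactivation)"

    span = resp.max() - resp.min()
    if span <= 0:
        warnings.warn("degenerate spectrum: all responses equal", stacklevel=2)
        norm = np.ones_like(resp)
        df = pd.DataFrame({"wavelength_nm": wl, "response": resp, "normalized": norm})
        return SpectrumSummary(float(wl[0]), (float(wl[0]), float(wl[-1])), df,
                               mode_label, degenerate=True)

    norm = (resp - resp.min()) / span
    peak_i = int(np.argmax(norm))
    lo = peak_i
    while lo > 0 and norm[lo - 1] > 0.5:
        lo -= 1
    hi = peak_i
    while hi < len(wl) - 1 and norm[hi + 1] > 0.5:
        hi += 1
    df = pd.DataFrame({"wavelength_nm": wl, "response": resp, "normalized": norm})
    return SpectrumSummary(
        float(wl[peak_i]), (float(wl[lo]), float(wl[hi])), df, mode_label
    )
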