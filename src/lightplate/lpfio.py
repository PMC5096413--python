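"""Bit-exact readers/writers for the binary light-program file (.lpf)
and the two calibration text files the device loads from its SD card.

.lpf layout (little-endian):

    offset  size  field
    0       4     magic  b"LPF1"
    4       4     u32    format version (1)
    8       4     u32    number of channels (always 48)
    12      4     u32    timestep in ms (>= 1)
    16      4     u32    number of frames
    20      12    reserved, zero
    32      ...   frames: n_frames x 48 u16 grayscale codes, frame-major,
                  channel order 2*well + (0 top / 1 bottom)

Total size is exactly 32 + 96*n_frames bytes. Codes are stored as full
16-bit words whose top 4 bits must be zero (12-bit hardware resolution);
the reader range-checks every code.

Calibration text files: 24 lines x 2 whitespace-separated integer columns
(top, bottom). The dot-correction file holds codes 0-63; the grayscale-
calibration file holds codes 0-255 interpreted as gcal = code/255.
"""

from __future__ import annotations

import io
import struct
from pathlib import Path
from typing import BinaryIO

import numpy as np

from .device import CalibrationTable, DC_MAX, GS_MAX, N_CHANNELS, N_WELLS
from .errors import CalibrationFileError, DomainError, LPFParseError
from .programs import LightProgram

MAGIC = b"LPF1"
VERSION = 1
HEADER_SIZE = 32
FRAME_BYTES = 2 * N_CHANNELS
_HEADER_STRUCT = struct.Struct("<4sIIII12s")


def write_lpf(program: LightProgram, destination) -> None:
    """Serialize a program; ``destination`` is a path or binary file object."""
    frames = program.frames
    if frames.size and frames.max() > GS_MAX:
        idx = np.unravel_index(int(np.argmax(frames)), frames.shape)
        raise DomainError(
            f"grayscale {int(frames[idx])} > {GS_MAX} at frame {idx[0]}, channel {idx[1]}"
        )
    header = _HEADER_STRUCT.pack(
        MAGIC, VERSION, N_CHANNELS, program.timestep_ms, program.n_frames, b"\0" * 12
    )
    body = np.ascontiguousarray(frames, dtype="<u2").tobytes()
    if hasattr(destination, "write"):
        destination.write(header)
        destination.write(body)
    else:
        with open(destination, "wb") as fh:
            fh.write(header)
            fh.write(body)


def lpf_bytes(program: LightProgram) -> bytes:
    buf = io.BytesIO()
    write_lpf(program, buf)
    return buf.getvalue()


def read_lpf(source) -> LightProgram:
    """Parse a .lpf stream; exact inverse of :func:`write_lpf`."""
    if hasattr(source, "read"):
        data = source.read()
    else:
        data = Path(source).read_bytes()
    if len(data) < HEADER_SIZE:
        raise LPFParseError(
            f"truncated header: {len(data)} bytes < {HEADER_SIZE}", offset=len(data)
        )
    magic, version, n_channels, timestep_ms, n_frames, _reserved = _HEADER_STRUCT.unpack(
        data[:HEADER_SIZE]
    )
    if magic != MAGIC:
        raise LPFParseError(f"bad magic {magic!r}, expected {MAGIC!r}", offset=0)
    if version != VERSION:
        raise LPFParseError(f"unsupported version {version}", offset=4)
    if n_channels != N_CHANNELS:
        raise LPFParseError(f"n_channels {n_channels} != {N_CHANNELS}", offset=8)
    if timestep_ms < 1:
        raise LPFParseError(f"timestep_ms {timestep_ms} < 1", offset=12)
    expected = HEADER_SIZE + FRAME_BYTES * n_frames
    if len(data) != expected:
        raise LPFParseError(
            f"body size mismatch: file has {len(data)} bytes, header implies {expected}",
            offset=min(len(data), expected),
        )
    frames = np.frombuffer(data[HEADER_SIZE:], dtype="<u2").reshape(n_frames, N_CHANNELS)
    if frames.size and frames.max() > GS_MAX:
        flat = int(np.argmax(frames > GS_MAX))
        raise LPFParseError(
            f"grayscale code {int(frames.reshape(-1)[flat])} exceeds {GS_MAX}",
            offset=HEADER_SIZE + 2 * flat,
        )
    return LightProgram(int(timestep_ms), frames.copy())


# ---------------------------------------------------------------------------
# Calibration text files
# ---------------------------------------------------------------------------

GCAL_CODE_MAX = 255


def gcal_to_code(gcal: float) -> int:
    """Quantize a fractional grayscale scale to its 8-bit file code (1-255)."""
    return min(max(int(round(gcal * GCAL_CODE_MAX)), 1), GCAL_CODE_MAX)


def _write_pairs(values, path) -> None:
    lines = []
    for w in range(N_WELLS):
        top, bottom = values[2 * w], values[2 * w + 1]
        lines.append(f"{top}\t{bottom}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_pairs(path, lo: int, hi: int, what: str) -> list[int]:
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) != N_WELLS:
        raise CalibrationFileError(
            f"{what} file must have exactly {N_WELLS} lines, found {len(lines)}"
        )
    values = [0] * N_CHANNELS
    for i, ln in enumerate(lines):
        parts = ln.split()
        if len(parts) != 2:
            raise CalibrationFileError(
                f"{what} file needs 2 columns, found {len(parts)}", line=i + 1
            )
        for j, p in enumerate(parts):
            try:
                v = int(p)
            except ValueError:
                raise CalibrationFileError(
                    f"non-integer value {p!r} in {what} file", line=i + 1
                ) from None
            if not lo <= v <= hi:
                raise CalibrationFileError(
                    f"{what} value {v} outside [{lo}, {hi}]", line=i + 1
                )
            values[2 * i + j] = v
    return values


def write_calibration_files(calib: CalibrationTable, dc_path, gcal_path) -> None:
    """Write the dot-correction and grayscale-calibration text files.

    gcal fractions are quantized to 8-bit codes; a table read back from
    disk therefore carries gcal values that are exact multiples of 1/255.
    """
    _write_pairs(list(calib.dc), dc_path)
    _write_pairs([gcal_to_code(g) for g in calib.gcal], gcal_path)


def read_calibration_files(dc_path, gcal_path) -> CalibrationTable:
    dc = _read_pairs(dc_path, 0, DC_MAX, "dot-correction")
    codes = _read_pairs(gcal_path, 0, GCAL_CODE_MAX, "grayscale-calibration")
    # dc 0 / gcal 0 are representable in the file but disable the channel;
    # the in-memory table requires addressable channels.
    dc = [max(d, 1) for d in dc]
    gcal = [max(c, 1) / GCAL_CODE_MAX for c in codes]
    return CalibrationTable(tuple(dc), tuple(gcal))


def inspect_lpf(source) -> dict:
    """Header plus per-channel min/max/mean summary (for the CLI)."""
    prog = read_lpf(source)
    f = prog.frames.astype(float)
    return {
        "version": VERSION,
        "n_channels": N_CHANNELS,
        "timestep_ms": prog.timestep_ms,
        "n_frames": prog.n_frames,
        "duration_min": prog.n_frames * prog.timestep_ms / 60_000,
        "channel_min": f.min(axis=0).tolist() if prog.n_frames else [0.0] * N_CHANNELS,
        "channel_max": f.max(axis=0).tolist() if prog.n_frames else [0.0] * N_CHANNELS,
        "channel_mean": f.mean(axis=0).tolist() if prog.n_frames else [0.0] * N_CHANNELS,
    }
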