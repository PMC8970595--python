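"""Reading and writing of OMR1 high-speed fluorescence movie recordings.

The OMR1 container is a minimal lossless format for monochrome high-frame-rate
movies such as voltage-dye fluorescence recordings: a fixed 44-byte
little-endian header followed by the raw frame stream.

Layout (all little-endian)::

    bytes 0-3    ASCII magic "OMR1"
    uint32       format_version (= 1)
    uint32       width   (pixels)
    uint32       height  (pixels)
    float64      frame_rate (frames/second)
    uint32       bits_per_sample (1..16)
    uint64       n_frames
    float64      pixel_size (mm/pixel)

followed by ``n_frames * height * width`` uint16 samples in frame-major,
row-major order (origin top-left, 0-based indices).  Samples are stored in
16-bit containers regardless of ``bits_per_sample``; a 10-bit camera sample
simply occupies the low bits.
"""
from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MAGIC = b"OMR1"
HEADER_SIZE = 44
_HEADER = struct.Struct("<4sIIIdIQd")
assert _HEADER.size == HEADER_SIZE


class RecordingFormatError(ValueError):
    """File is not an OMR1 recording (bad magic or unsupported version)."""


class RecordingTruncationError(ValueError):
    """Payload is shorter than the header promises."""


class RecordingValidationError(ValueError):
    """Header/frame contents violate the type invariants."""


@dataclass(frozen=True)
class RecordingHeader:
    """Metadata of one movie recording.

    ``pixel_size`` defaults to 0.035 mm/px, the spatial calibration assumed
    for the packaged mouse scenario; conduction velocities in cm/s are
    meaningless without it.
    """

    width: int
    height: int
    frame_rate: float
    bits_per_sample: int = 10
    n_frames: int = 1
    pixel_size: float = 0.035
    format_version: int = 1

    def validate(self) -> None:
        if self.width < 1 or self.height < 1 or self.n_frames < 1:
            raise RecordingValidationError(
                f"width/height/n_frames must be >= 1, got "
                f"{self.width}x{self.height}x{self.n_frames}"
            )
        if not self.frame_rate > 0:
            raise RecordingValidationError(f"frame_rate must be > 0, got {self.frame_rate}")
        if not 1 <= self.bits_per_sample <= 16:
            raise RecordingValidationError(
                f"bits_per_sample must be in [1, 16], got {self.bits_per_sample}"
            )
        if not self.pixel_size > 0:
            raise RecordingValidationError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def max_sample(self) -> int:
        return (1 << self.bits_per_sample) - 1

    @property
    def frame_interval_ms(self) -> float:
        return 1000.0 / self.frame_rate

    @property
    def duration_ms(self) -> float:
        return self.n_frames * 1000.0 / self.frame_rate

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_frames, self.height, self.width)


@dataclass
class Recording:
    """A movie recording: header plus the (frame, row, col) intensity stack."""

    header: RecordingHeader
    frames: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)

    def validate(self) -> None:
        self.header.validate()
        if self.frames.shape != self.header.shape:
            raise RecordingValidationError(
                f"frame stack shape {self.frames.shape} does not match header "
                f"{self.header.shape}"
            )
        if not np.issubdtype(self.frames.dtype, np.integer):
            raise RecordingValidationError(f"samples must be integers, got {self.frames.dtype}")
        lo, hi = int(self.frames.min()), int(self.frames.max())
        if lo < 0 or hi > self.header.max_sample:
            raise RecordingValidationError(
                f"samples [{lo}, {hi}] exceed the {self.header.bits_per_sample}-bit "
                f"range [0, {self.header.max_sample}]"
            )

    @property
    def times_ms(self) -> np.ndarray:
        """Frame timestamps in ms (frame_index * 1000 / frame_rate)."""
        return np.arange(self.header.n_frames) * (1000.0 / self.header.frame_rate)


def write_recording(recording: Recording, destination: str | Path) -> None:
    """Write a validated recording to ``destination`` in OMR1 layout.

    The resulting file is exactly ``44 + 2 * n_frames * height * width``
    bytes long.
    """
    recording.validate()
    h = recording.header
    header_bytes = _HEADER.pack(
        MAGIC, h.format_version, h.width, h.height, h.frame_rate,
        h.bits_per_sample, h.n_frames, h.pixel_size,
    )
    payload = np.ascontiguousarray(recording.frames, dtype="<u2")
    with open(destination, "wb") as fh:
        fh.write(header_bytes)
        fh.write(payload.tobytes())


def read_recording(source: str | Path) -> Recording:
    """Read an OMR1 recording; typed errors for bad magic or short payload."""
    with open(source, "rb") as fh:
        header_bytes = fh.read(HEADER_SIZE)
        if len(header_bytes) < HEADER_SIZE:
            raise RecordingTruncationError(
                f"file too short for a {HEADER_SIZE}-byte OMR1 header "
                f"({len(header_bytes)} bytes)"
            )
        magic, version, width, height, frame_rate, bits, n_frames, pixel_size = (
            _HEADER.unpack(header_bytes)
        )
        if magic != MAGIC:
            raise RecordingFormatError(f"bad magic {magic!r}, expected {MAGIC!r}")
        if version != 1:
            raise RecordingFormatError(f"unsupported OMR1 version {version}")
        header = RecordingHeader(
            width=width, height=height, frame_rate=frame_rate,
            bits_per_sample=bits, n_frames=n_frames, pixel_size=pixel_size,
            format_version=version,
        )
        header.validate()
        expected = 2 * n_frames * height * width
        payload = fh.read(expected)
        if len(payload) < expected:
            raise RecordingTruncationError(
                f"payload truncated: expected {expected} bytes "
                f"({n_frames}x{height}x{width} uint16), got {len(payload)}"
            )
    frames = np.frombuffer(payload, dtype="<u2").reshape(header.shape)
    rec = Recording(header=header, frames=frames.astype(np.uint16))
    rec.validate()
    return rec


def export_traces(recording: Recording, pixels: list[tuple[int, int]]) -> pd.DataFrame:
    """Extract per-pixel time traces as a table.

    Returns one row per frame: first column ``time_ms`` =
    frame_index * 1000 / frame_rate, then one column ``px_r{row}c{col}``
    per requested pixel.
    """
    if not pixels:
        raise ValueError("pixel list must be non-empty")
    h = recording.header
    for r, c in pixels:
        if not (0 <= r < h.height and 0 <= c < h.width):
            raise ValueError(
                f"pixel ({r}, {c}) out of bounds for {h.height}x{h.width} frames"
            )
    data = {"time_ms": recording.times_ms}
    for r, c in pixels:
        data[f"px_r{r}c{c}"] = recording.frames[:, r, c]
    return pd.DataFrame(data)
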