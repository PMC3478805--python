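"""Core in-memory containers for the two acquisition streams.

A strain sensor record is a uniformly sampled 1-D series (200 Hz by default)
carrying capacitance in pF and/or calibrated elongation in mm.  A marker
record is a sequence of camera frames (114 Hz) with per-marker pixel
coordinates, a 16-bit sync word stamped by the sync box and two fiducial
bits that are permanently on in a healthy recording.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError

DEFAULT_STRAIN_RATE_HZ = 200.0
DEFAULT_FRAME_RATE_HZ = 114.0


@dataclass
class StrainSeries:
    """Uniformly sampled strain-sensor record.

    Attributes
    ----------
    t_s : ndarray
        Sample times in seconds, strictly increasing, nominally uniform.
    capacitance_pF : ndarray or None
        Raw quantized capacitance samples.
    elongation_mm : ndarray or None
        Calibrated elongation of the strainable section.
    rate_hz : float
        Nominal sample rate (200 Hz for the sensor hardware modeled here).
    """

    t_s: np.ndarray
    capacitance_pF: np.ndarray | None = None
    elongation_mm: np.ndarray | None = None
    rate_hz: float = DEFAULT_STRAIN_RATE_HZ

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        if self.capacitance_pF is not None:
            self.capacitance_pF = np.asarray(self.capacitance_pF, dtype=float)
        if self.elongation_mm is not None:
            self.elongation_mm = np.asarray(self.elongation_mm, dtype=float)
        if self.t_s.ndim != 1 or self.t_s.size < 2:
            raise ParseError("strain series needs at least two samples")
        if np.any(np.diff(self.t_s) <= 0):
            bad = int(np.argmax(np.diff(self.t_s) <= 0)) + 1
            raise ParseError(f"non-monotone time at row {bad}")
        for name in ("capacitance_pF", "elongation_mm"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != self.t_s.shape:
                raise ParseError(f"{name} length does not match t_s")

    @property
    def n(self) -> int:
        return int(self.t_s.size)

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    def inferred_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t_s)))


@dataclass
class MarkerFrameSeries:
    """Per-frame marker pixel coordinates plus the sync-box state.

    ``markers`` maps a marker id to an ``(n_frames, 2)`` array of (x, y)
    pixel coordinates; the pixel y axis points downward (image convention).
    ``sync_words`` holds the 16-bit gray-coded strain-sample numbers as
    plain integers; ``fiducial_ok`` is True where both always-on LEDs were
    recognized, i.e. the word for that frame can be trusted.
    """

    frame: np.ndarray
    t_s: np.ndarray
    markers: dict[str, np.ndarray] = field(default_factory=dict)
    sync_words: np.ndarray | None = None
    fiducial_ok: np.ndarray | None = None
    rate_hz: float = DEFAULT_FRAME_RATE_HZ

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.t_s = np.asarray(self.t_s, dtype=float)
        if self.frame.shape != self.t_s.shape:
            raise ParseError("frame and t_s length mismatch")
        n = self.t_s.size
        for mid, xy in self.markers.items():
            xy = np.asarray(xy, dtype=float)
            if xy.shape != (n, 2):
                raise ParseError(f"marker {mid!r}: expected shape ({n}, 2)")
            self.markers[mid] = xy
        if self.sync_words is not None:
            self.sync_words = np.asarray(self.sync_words, dtype=np.int64)
        if self.fiducial_ok is not None:
            self.fiducial_ok = np.asarray(self.fiducial_ok, dtype=bool)

    @property
    def n_frames(self) -> int:
        return int(self.t_s.size)

    def marker_xy(self, marker_id: str) -> np.ndarray:
        if marker_id not in self.markers:
            raise ParseError(f"marker {marker_id!r} not present")
        return self.markers[marker_id]
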