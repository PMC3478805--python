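"""Cross-device synchronization via gray-coded sample numbers.

The sync box displays the current strain-sample number on 16 LEDs in
binary-reflected gray code (so at most one LED flips per sample) plus two
always-on fiducial LEDs.  The camera records the box, each frame therefore
carries the index of the strain sample nearest its exposure.  Decoding the
words, unwrapping the 16-bit counter and interpolating against sample
indices puts marker-derived signals onto the 200 Hz strain timeline.

Bit order in the stored integer word is LSB-first: bit i of the word is the
state of LED i.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CannotSyncError
from .series import MarkerFrameSeries

__all__ = [
    "gray_encode",
    "gray_decode",
    "gray_encode_int",
    "gray_decode_int",
    "SyncMap",
    "decode_frames",
    "upsample_to_strain_timeline",
    "frame_time_to_sample",
]

WORD_BITS = 16


def gray_encode_int(n: int, width: int = WORD_BITS) -> int:
    """Binary-reflected gray code of ``n`` as an integer word."""
    if not 0 <= n < (1 << width):
        raise ValueError(f"n={n} outside [0, 2^{width})")
    return n ^ (n >> 1)


def gray_decode_int(g: int, width: int = WORD_BITS) -> int:
    """Inverse of :func:`gray_encode_int` (prefix-XOR)."""
    if not 0 <= g < (1 << width):
        raise ValueError(f"word={g} outside [0, 2^{width})")
    n = g
    shift = 1
    while shift < width:
        n ^= n >> shift
        shift <<= 1
    return n


def gray_encode(n: int, width: int = WORD_BITS) -> np.ndarray:
    """Gray code of ``n`` as a bit vector, LSB first."""
    g = gray_encode_int(n, width)
    return np.array([(g >> i) & 1 for i in range(width)], dtype=np.uint8)


def gray_decode(bits: np.ndarray) -> int:
    """Decode an LSB-first gray-code bit vector back to the integer."""
    bits = np.asarray(bits).astype(np.uint8)
    if bits.ndim != 1 or bits.size > WORD_BITS:
        raise ValueError(f"expected a bit vector of width <= {WORD_BITS}")
    g = int(sum(int(b) << i for i, b in enumerate(bits)))
    return gray_decode_int(g, width=bits.size)


@dataclass
class SyncMap:
    """Per-frame mapping onto the strain-sample index axis.

    ``frame_to_sample`` holds the unwrapped sample index for each frame
    (NaN where the decode was rejected); ``valid_mask`` flags trustworthy
    frames; ``offset_stats`` summarizes the residual between decoded
    indices and a uniform-rate model, in samples.
    """

    frame_to_sample: np.ndarray
    valid_mask: np.ndarray
    offset_stats: dict

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


def decode_frames(
    frames: MarkerFrameSeries,
    strain_rate_hz: float = 200.0,
    glitch_factor: float = 3.0,
) -> SyncMap:
    """Decode and unwrap the per-frame sync words.

    Frames whose fiducial bits are off are invalid.  Valid words are gray
    decoded and unwrapped modulo 2**16 by nearest continuation of the
    expected counter (the strain rate times the frame interval, ~1.754
    samples per frame at 200/114 Hz).  Isolated glitches — decoded indices
    jumping more than ``glitch_factor`` times the expected per-frame
    increment away from the continuation — are invalidated without
    disturbing their neighbors.
    """
    if frames.sync_words is None:
        raise CannotSyncError("marker series carries no sync words")
    n = frames.n_frames
    fiducial = (
        frames.fiducial_ok if frames.fiducial_ok is not None
        else np.ones(n, dtype=bool)
    )
    decoded = np.array(
        [gray_decode_int(int(w) & 0xFFFF) for w in frames.sync_words], dtype=float
    )
    t = frames.t_s
    mapped = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)

    inc_per_s = strain_rate_hz
    prev_idx: float | None = None
    prev_t: float | None = None
    modulus = 1 << WORD_BITS
    for i in range(n):
        if not fiducial[i]:
            continue
        if prev_idx is None:
            mapped[i] = decoded[i]
            valid[i] = True
            prev_idx, prev_t = decoded[i], t[i]
            continue
        expected = prev_idx + inc_per_s * (t[i] - prev_t)
        k = np.round((expected - decoded[i]) / modulus)
        unwrapped = decoded[i] + k * modulus
        step_budget = glitch_factor * max(inc_per_s * (t[i] - prev_t), 1.0)
        if abs(unwrapped - expected) > step_budget:
            continue  # glitch: leave frame invalid, keep the running estimate
        mapped[i] = unwrapped
        valid[i] = True
        prev_idx, prev_t = unwrapped, t[i]

    if valid.sum() < 2:
        raise CannotSyncError("fewer than 2 valid sync frames")

    vi = np.flatnonzero(valid)
    resid = mapped[vi] - (mapped[vi[0]] + inc_per_s * (t[vi] - t[vi[0]]))
    stats = {
        "n_valid": int(valid.sum()),
        "n_invalid": int(n - valid.sum()),
        "residual_mean_samples": float(np.mean(resid)),
        "residual_max_abs_samples": float(np.max(np.abs(resid))),
    }
    return SyncMap(frame_to_sample=mapped, valid_mask=valid, offset_stats=stats)


def upsample_to_strain_timeline(
    values: np.ndarray,
    syncmap: SyncMap,
    n_samples: int,
) -> np.ndarray:
    """Interpolate a per-frame signal onto the strain-sample grid.

    Piecewise-linear interpolation against the decoded sample indices;
    samples outside the span of valid frames are NaN (no extrapolation).
    Samples that coincide exactly with a frame's index reproduce that
    frame's value.
    """
    values = np.asarray(values, dtype=float)
    vi = np.flatnonzero(syncmap.valid_mask)
    if vi.size < 2:
        raise CannotSyncError("fewer than 2 valid sync frames")
    x = syncmap.frame_to_sample[vi]
    y = values[vi]
    target = np.arange(n_samples, dtype=float)
    out = np.interp(target, x, y)
    out[(target < x[0]) | (target > x[-1])] = np.nan
    if not np.any(~np.isnan(out)):
        raise CannotSyncError("no overlap between marker span and strain series")
    return out


def frame_time_to_sample(t: np.ndarray, frames: MarkerFrameSeries, syncmap: SyncMap) -> np.ndarray:
    """Map camera-side times to (fractional) strain-sample indices."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    vi = np.flatnonzero(syncmap.valid_mask)
    if vi.size < 2:
        raise CannotSyncError("fewer than 2 valid sync frames")
    return np.interp(t, frames.t_s[vi], syncmap.frame_to_sample[vi])
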