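"""Per-step gait-event detection.

Three flavours are provided:

* camera-side (reference) events from the navicular-height series — heel
  strike (HS) at the descent onset, lowest navicular height (NHL) at the
  within-step minimum, toe off (TO) at the post-minimum recovery;
* sensor-side events anchored on the reference: HS is the local elongation
  minimum inside a window of +/-10% of the step length around the
  reference HS, NHL is the maximal elongation inside the step;
* a standalone in-shoe mode needing no reference stream: HS at the bottom
  of the characteristic pre-rise strain drop, NHL at the step's elongation
  maximum.

Steps themselves are segmented from the signal's own periodicity
(autocorrelation period estimate, then peak picking), so no external
footswitch is required.  "Step length" in the +/-10% window rule is read as
step duration in samples.  Ties everywhere break to the earliest index so
results are deterministic.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import CannotSegmentError

__all__ = [
    "StepEvents",
    "smooth_series",
    "segment_steps",
    "detect_mvsa_events",
    "detect_pbs_hs",
    "detect_pbs_nhl",
    "detect_pbs_events",
    "detect_inshoe_events",
]

#: Steps whose NH range is below this are considered flat and skipped.
FLAT_STEP_RANGE_MM = 0.1


@dataclass
class StepEvents:
    """Per-step event sample indices on one stream's timeline.

    ``to_index`` is -1 where toe off is not defined for that mode (the
    sensor-side rules locate HS and NHL only).  ``step`` keeps the original
    step numbering so streams can be paired even when some steps were
    skipped on one side.
    """

    step: np.ndarray
    hs_index: np.ndarray
    nhl_index: np.ndarray
    to_index: np.ndarray
    step_bounds: list[tuple[int, int]]
    stream_id: str = ""
    mode: str = "reference"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.step = np.asarray(self.step, dtype=int)
        self.hs_index = np.asarray(self.hs_index, dtype=int)
        self.nhl_index = np.asarray(self.nhl_index, dtype=int)
        self.to_index = np.asarray(self.to_index, dtype=int)
        for k, (hs, nhl, to, (s, e)) in enumerate(
            zip(self.hs_index, self.nhl_index, self.to_index, self.step_bounds)
        ):
            if not (s <= hs < nhl <= e):
                raise ValueError(f"step {k}: event ordering violated")
            if to >= 0 and not (nhl < to <= e):
                raise ValueError(f"step {k}: toe off out of order")

    @property
    def n_steps(self) -> int:
        return int(self.step.size)


def smooth_series(x: np.ndarray, rate_hz: float, window_s: float = 0.035) -> np.ndarray:
    """Zero-phase boxcar smoothing with an odd window of ~``window_s``.

    Attenuates sample-level sensor quantization and marker jitter before
    event picking; 35 ms is short against the ~120 ms NH descent so the
    waveform shape is preserved.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(window_s * rate_hz))
    w = max(1, w | 1)  # odd
    if w == 1 or x.size < w:
        return x.copy()
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def _autocorr_period(x: np.ndarray, rate_hz: float,
                     min_period_s: float, max_period_s: float) -> int:
    n = x.size
    xc = x - x.mean()
    var = float(np.dot(xc, xc))
    if var < 1e-12 or np.std(x) < 1e-9:
        raise CannotSegmentError("signal is (near-)constant")
    ac = np.correlate(xc, xc, mode="full")[n - 1:]
    lo = max(2, int(min_period_s * rate_hz))
    hi = min(n // 2, int(max_period_s * rate_hz))
    if hi <= lo:
        raise CannotSegmentError("series too short to contain 2 gait cycles")
    lag = lo + int(np.argmax(ac[lo:hi]))
    if ac[lag] / ac[0] < 0.2:
        raise CannotSegmentError("no significant periodicity")
    return lag


def segment_steps(
    x: np.ndarray,
    rate_hz: float,
    min_period_s: float = 0.4,
    max_period_s: float = 2.5,
) -> list[tuple[int, int]]:
    """Segment a periodic gait signal into per-step windows.

    ``x`` must peak once per step (sensor elongation does; pass
    ``max(nh) - nh`` for a navicular-height series).  The stride period is
    estimated from the autocorrelation; peaks at least 0.7 periods apart
    are picked on a lightly smoothed copy, and step boundaries are placed
    midway between consecutive peaks (edge windows get the median
    half-gap), so each window holds one full HS-NHL-TO sequence.
    """
    x = np.asarray(x, dtype=float)
    lag = _autocorr_period(x, rate_hz, min_period_s, max_period_s)
    xs = smooth_series(x, rate_hz, window_s=0.05 * lag / rate_hz)
    prom = 0.3 * float(np.ptp(xs))
    peaks, _ = find_peaks(xs, distance=int(0.7 * lag), prominence=prom)
    if peaks.size < 2:
        raise CannotSegmentError("fewer than 2 step peaks found")
    mids = (peaks[:-1] + peaks[1:]) // 2
    half = int(np.median(np.diff(peaks)) // 2)
    starts = np.concatenate([[max(0, peaks[0] - half)], mids])
    ends = np.concatenate([mids, [min(x.size - 1, peaks[-1] + half)]])
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def detect_mvsa_events(
    nh_mm: np.ndarray,
    step_bounds: list[tuple[int, int]],
    stream_id: str = "mvsa",
) -> StepEvents:
    """Reference events from a navicular-height series.

    Per step: NHL is the NH minimum; HS is the last pre-NHL sample at the
    plateau (maximum) level, i.e. the descent onset; TO is the first
    post-NHL return to within 5% of the step's NH range of the HS level.
    Steps with an NH range under ~0.1 mm carry no gait information and are
    skipped with a warning.
    """
    nh = np.asarray(nh_mm, dtype=float)
    steps, hss, nhls, tos, bounds = [], [], [], [], []
    for k, (s, e) in enumerate(step_bounds):
        seg = nh[s:e + 1]
        rng = float(np.ptp(seg))
        if rng < FLAT_STEP_RANGE_MM:
            warnings.warn(f"step {k}: flat NH (range {rng:.3f} mm), skipped",
                          stacklevel=2)
            continue
        nhl = s + int(np.argmin(seg))
        if nhl <= s:
            warnings.warn(f"step {k}: minimum at window start, skipped", stacklevel=2)
            continue
        pre = nh[s:nhl]
        plateau = float(np.max(pre))
        at_plateau = np.flatnonzero(pre == plateau)
        hs = s + int(at_plateau[-1])
        h = 0.05 * rng
        post = nh[nhl:e + 1]
        above = np.flatnonzero(post >= nh[hs] - h)
        to = nhl + int(above[0]) if above.size else e
        if not hs < nhl < to:
            to = e
        if not hs < nhl < to:
            warnings.warn(f"step {k}: could not order events, skipped", stacklevel=2)
            continue
        steps.append(k); hss.append(hs); nhls.append(nhl); tos.append(to)
        bounds.append((s, e))
    return StepEvents(
        step=np.array(steps, dtype=int),
        hs_index=np.array(hss, dtype=int),
        nhl_index=np.array(nhls, dtype=int),
        to_index=np.array(tos, dtype=int),
        step_bounds=bounds,
        stream_id=stream_id,
        mode="reference",
    )


def detect_pbs_hs(
    elong_mm: np.ndarray, mvsa_hs: int, step_len: int
) -> int:
    """Sensor-side HS: elongation minimum within +/-10% of the step length
    around the reference HS; ties break to the earliest index.  A window
    extending past the series is clipped with a warning."""
    elong = np.asarray(elong_mm, dtype=float)
    w = max(1, int(round(0.1 * step_len)))
    lo, hi = mvsa_hs - w, mvsa_hs + w
    if lo < 0 or hi > elong.size - 1:
        warnings.warn("sensor HS window clipped to series bounds", stacklevel=2)
        lo, hi = max(0, lo), min(elong.size - 1, hi)
    return lo + int(np.argmin(elong[lo:hi + 1]))


def detect_pbs_nhl(elong_mm: np.ndarray, step_bounds: tuple[int, int]) -> int:
    """Sensor-side NHL: maximal elongation within the step window; earliest tie."""
    s, e = step_bounds
    elong = np.asarray(elong_mm, dtype=float)
    return s + int(np.argmax(elong[s:e + 1]))


def detect_pbs_events(
    elong_mm: np.ndarray,
    reference: StepEvents,
    stream_id: str = "pbs",
) -> StepEvents:
    """Sensor-side events for every step of a reference event set.

    Requires both streams on the same (synchronized) timeline.  Steps
    where the rules cannot be ordered (HS not before NHL) are skipped with
    a warning.
    """
    elong = np.asarray(elong_mm, dtype=float)
    steps, hss, nhls, tos, bounds = [], [], [], [], []
    for step, mhs, (s, e) in zip(
        reference.step, reference.hs_index, reference.step_bounds
    ):
        hs = detect_pbs_hs(elong, int(mhs), e - s + 1)
        nhl = detect_pbs_nhl(elong, (s, e))
        if not s <= hs < nhl <= e:
            warnings.warn(f"step {int(step)}: sensor events out of order, skipped",
                          stacklevel=2)
            continue
        steps.append(int(step)); hss.append(hs); nhls.append(nhl); tos.append(-1)
        bounds.append((s, e))
    return StepEvents(
        step=np.array(steps, dtype=int),
        hs_index=np.array(hss, dtype=int),
        nhl_index=np.array(nhls, dtype=int),
        to_index=np.array(tos, dtype=int),
        step_bounds=bounds,
        stream_id=stream_id,
        mode="anchored",
    )


def detect_inshoe_events(
    elong_mm: np.ndarray,
    rate_hz: float,
    stream_id: str = "pbs",
) -> StepEvents:
    """Standalone sensor-only events (no reference stream available).

    Steps come from :func:`segment_steps`; per step, NHL is the elongation
    maximum and HS the elongation minimum preceding it — the bottom of the
    characteristic strain drop just before the stance rise.  Flagged
    ``mode="standalone"`` because no reference system checks these events.
    """
    elong = np.asarray(elong_mm, dtype=float)
    step_bounds = segment_steps(elong, rate_hz)
    steps, hss, nhls, tos, bounds = [], [], [], [], []
    for k, (s, e) in enumerate(step_bounds):
        nhl = s + int(np.argmax(elong[s:e + 1]))
        if nhl <= s:
            warnings.warn(f"step {k}: peak at window start, skipped", stacklevel=2)
            continue
        hs = s + int(np.argmin(elong[s:nhl]))
        if not s <= hs < nhl:
            continue
        steps.append(k); hss.append(hs); nhls.append(nhl); tos.append(-1)
        bounds.append((s, e))
    return StepEvents(
        step=np.array(steps, dtype=int),
        hs_index=np.array(hss, dtype=int),
        nhl_index=np.array(nhls, dtype=int),
        to_index=np.array(tos, dtype=int),
        step_bounds=bounds,
        stream_id=stream_id,
        mode="standalone",
    )
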