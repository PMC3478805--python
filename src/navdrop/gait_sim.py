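"""Synthetic gait trials with known ground truth.

The simulator emulates the study conditions of a treadmill walking trial
recorded simultaneously by a capacitive strain sensor on the medial foot
(200 Hz, 0.13 pF quantization) and a single-camera marker system (114 Hz)
whose frames carry a 16-bit gray-coded strain-sample number from a sync box.

Every trial comes with a truth record — per-step heel-strike (HS), lowest
navicular height (NHL) and toe-off (TO) times plus the true navicular drop —
so each downstream stage can be tested against exact ground truth.

The navicular-height (NH) stride template is piecewise raised-cosine:
descent from the HS baseline to a per-step minimum at a fixed fraction of
stance, recovery to baseline at TO, and a shallow smooth dip during swing.
The swing dip reproduces the characteristic drop in sensor strain just
before the stance rise, which is the feature the sensor-side heel-strike
rules key on; its amplitude is a profile parameter.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidProfileError, OverStrainError
from .series import (
    DEFAULT_FRAME_RATE_HZ,
    DEFAULT_STRAIN_RATE_HZ,
    MarkerFrameSeries,
    StrainSeries,
)
from .sync import gray_encode_int

__all__ = [
    "GaitProfile",
    "SensorModel",
    "MarkerLayout",
    "SimulatedTrial",
    "simulate_nh_trajectory",
    "nh_to_elongation",
    "elongation_to_capacitance",
    "render_marker_frames",
    "generate_trial",
    "simulate_calibration_sweep",
]

#: Default metric scale of the camera image, mm per pixel.  At ~0.2 mm/px a
#: 25 cm foot spans ~1250 px, typical for a close-up gait camera.
MM_PER_PX = 0.2


@dataclass(frozen=True)
class GaitProfile:
    """Ground-truth description of one walking trial.

    Defaults describe a healthy adult at preferred treadmill speed
    (~5 km/h): one stride per leg roughly every 1.1 s, mean navicular drop
    5.0 mm with 0.8 mm stride-to-stride SD (healthy population mean is
    about 5.3 +/- 1.8 mm).
    """

    n_steps: int = 60
    cadence_hz: float = 0.9            # strides of the instrumented leg per second
    nd_mean_mm: float = 5.0
    nd_sd_mm: float = 0.8
    nh_baseline_mm: float = 45.0       # navicular height at heel strike
    stance_fraction: float = 0.62      # fraction of the stride spent in stance
    nhl_fraction_of_stance: float = 0.40
    swing_dip_mm: float = 1.0          # shallow NH dip during swing (strain pre-drop)
    noise_nh_mm: float = 0.0           # marker noise SD, expressed in mm
    noise_cap_pf: float = 0.0          # capacitance noise SD, pF
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise InvalidProfileError("n_steps must be >= 1")
        if self.cadence_hz <= 0:
            raise InvalidProfileError("cadence_hz must be positive")
        if not 0.0 < self.stance_fraction < 1.0:
            raise InvalidProfileError("stance_fraction must lie in (0, 1)")
        if not 0.0 < self.nhl_fraction_of_stance < 1.0:
            raise InvalidProfileError("nhl_fraction_of_stance must lie in (0, 1)")
        if self.nd_mean_mm < 0 or self.nd_sd_mm < 0:
            raise InvalidProfileError("navicular-drop parameters must be >= 0")
        if self.noise_nh_mm < 0 or self.noise_cap_pf < 0:
            raise InvalidProfileError("noise SDs must be >= 0")
        if self.swing_dip_mm < 0:
            raise InvalidProfileError("swing_dip_mm must be >= 0")

    @property
    def stride_s(self) -> float:
        return 1.0 / self.cadence_hz


@dataclass(frozen=True)
class SensorModel:
    """Capacitive strain sensor and its acquisition chain.

    The strainable film tolerates at most ``max_strain_frac`` of its rest
    length (50% for the material modeled here); the rest length default of
    40 mm makes a 20 mm calibration sweep reach exactly that limit.
    Capacitance is transduced linearly from elongation, quantized to
    0.13 pF, and sampled at 200 Hz.  ``geometry_gain`` maps a drop in
    navicular height to sensor elongation; ``crosstalk_mm`` is the amplitude
    of a smooth, stride-locked non-sagittal elongation component with
    stride-to-stride amplitude variation, emulating frontal-plane foot
    motion that the single-camera reference system cannot see.
    """

    rest_length_mm: float = 40.0
    max_strain_frac: float = 0.5
    slope_mm_per_pf: float = 0.5
    intercept_pf: float = 100.0
    quant_pf: float = 0.13
    sample_rate_hz: float = DEFAULT_STRAIN_RATE_HZ
    geometry_gain: float = 1.0
    crosstalk_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.rest_length_mm <= 0:
            raise InvalidProfileError("rest_length_mm must be positive")
        if self.quant_pf <= 0:
            raise InvalidProfileError("quant_pf must be positive")
        if not 0.0 < self.max_strain_frac <= 1.0:
            raise InvalidProfileError("max_strain_frac must lie in (0, 1]")
        if self.slope_mm_per_pf == 0:
            raise InvalidProfileError("slope_mm_per_pf must be nonzero")
        if self.sample_rate_hz <= 0:
            raise InvalidProfileError("sample_rate_hz must be positive")

    @property
    def max_elongation_mm(self) -> float:
        return self.max_strain_frac * self.rest_length_mm


@dataclass(frozen=True)
class MarkerLayout:
    """Camera-plane geometry of the rendered markers.

    Pixel y increases downward (image convention), so a drop in navicular
    height moves the navicular marker to larger y.  ``ref_a`` is the front
    foot marker, ``ref_b`` the calcaneus marker; both are treated as rigid
    on a treadmill-stationary foot outline.
    """

    ref_a_px: tuple[float, float] = (620.0, 400.0)
    ref_b_px: tuple[float, float] = (180.0, 400.0)
    nav_x_px: float = 330.0
    nav_y0_px: float = 310.0           # navicular pixel y when NH == nh_ref_mm
    nh_ref_mm: float = 45.0
    mm_per_px: float = MM_PER_PX
    ref_a_id: str = "A"
    ref_b_id: str = "B"
    nav_id: str = "NAV"


@dataclass
class SimulatedTrial:
    """A rendered trial: the two acquisition streams plus ground truth."""

    truth: pd.DataFrame                # step, t_hs_s, t_nhl_s, t_to_s, nd_true_mm
    strain: StrainSeries               # capacitance at 200 Hz
    markers: MarkerFrameSeries         # frames at 114 Hz with sync words
    nh_true_mm: np.ndarray             # noiseless NH on the strain timeline
    elongation_true_mm: np.ndarray     # noiseless elongation on the strain timeline
    profile: GaitProfile
    sensor: SensorModel
    layout: MarkerLayout


# ---------------------------------------------------------------------------
# NH trajectory


def _snap(t: float, rate_hz: float) -> float:
    return round(t * rate_hz) / rate_hz


def _stride_truth(profile: GaitProfile, rate_hz: float) -> pd.DataFrame:
    """Per-step event times (snapped to the sample grid) and true drops."""
    rng = np.random.default_rng(profile.seed)
    T = profile.stride_s
    stance = profile.stance_fraction * T
    lead = T - stance                       # one swing's worth of lead-in
    rows = []
    for k in range(profile.n_steps):
        d = rng.normal(profile.nd_mean_mm, profile.nd_sd_mm)
        d = max(0.0, d)
        t_hs = _snap(lead + k * T, rate_hz)
        t_nhl = _snap(lead + k * T + profile.nhl_fraction_of_stance * stance, rate_hz)
        t_to = _snap(lead + k * T + stance, rate_hz)
        rows.append((k, t_hs, t_nhl, t_to, d))
    return pd.DataFrame(rows, columns=["step", "t_hs_s", "t_nhl_s", "t_to_s", "nd_true_mm"])


def _raised_cosine(u: np.ndarray) -> np.ndarray:
    """0 -> 1 smoothly over u in [0, 1], zero slope at both ends."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))


def _eval_nh(t: np.ndarray, profile: GaitProfile, truth: pd.DataFrame) -> np.ndarray:
    """Evaluate the noiseless NH template at arbitrary times."""
    b = profile.nh_baseline_mm
    s_dip = profile.swing_dip_mm
    T = profile.stride_s
    nh = np.full(t.shape, b, dtype=float)

    hs = truth["t_hs_s"].to_numpy()
    nhl = truth["t_nhl_s"].to_numpy()
    to = truth["t_to_s"].to_numpy()
    d = truth["nd_true_mm"].to_numpy()

    # lead-in: tail of a virtual swing ending at the first heel strike
    swing_dur = T - (to[0] - hs[0])
    pre = t < hs[0]
    if np.any(pre) and swing_dur > 0:
        u = np.clip((t[pre] - (hs[0] - swing_dur)) / swing_dur, 0.0, 1.0)
        nh[pre] = b - s_dip * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))

    for k in range(len(hs)):
        # stance descent
        m = (t >= hs[k]) & (t < nhl[k])
        if np.any(m):
            u = (t[m] - hs[k]) / (nhl[k] - hs[k])
            nh[m] = b - d[k] * _raised_cosine(u)
        # stance recovery
        m = (t >= nhl[k]) & (t < to[k])
        if np.any(m):
            u = (t[m] - nhl[k]) / (to[k] - nhl[k])
            nh[m] = b - d[k] * (1.0 - _raised_cosine(u))
        # swing dip until the next heel strike (or a virtual one after the last TO)
        t_next = hs[k + 1] if k + 1 < len(hs) else to[k] + (T - (to[k] - hs[k]))
        m = (t >= to[k]) & (t < t_next)
        if np.any(m) and t_next > to[k]:
            u = (t[m] - to[k]) / (t_next - to[k])
            nh[m] = b - s_dip * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    return nh


def simulate_nh_trajectory(
    profile: GaitProfile, rate_hz: float = DEFAULT_STRAIN_RATE_HZ
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Sample the noiseless navicular-height trajectory.

    Returns ``(t_s, nh_mm, truth)`` where ``truth`` has one row per step
    with event times (snapped to the sample grid, so the sampled minimum of
    a noiseless step equals baseline minus the true drop exactly) and the
    true navicular drop drawn from Normal(nd_mean, nd_sd) truncated at 0.
    """
    if rate_hz <= 0 or rate_hz <= 2.0 * profile.cadence_hz:
        raise InvalidProfileError("rate_hz must exceed twice the cadence")
    truth = _stride_truth(profile, rate_hz)
    T = profile.stride_s
    tail = 0.2 * T
    duration = float(truth["t_to_s"].iloc[-1]) + (T - profile.stance_fraction * T) + tail
    n = int(np.floor(duration * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    nh = _eval_nh(t, profile, truth)
    return t, nh, truth


# ---------------------------------------------------------------------------
# Transduction


def nh_to_elongation(
    nh_mm: np.ndarray,
    sensor: SensorModel,
    baseline_mm: float,
    t_s: np.ndarray | None = None,
    truth: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Map navicular height to sensor elongation.

    ``elongation = geometry_gain * (baseline - NH) + crosstalk``.  The
    crosstalk term is a smooth half-period bump per stride (zero at each
    heel strike) whose amplitude varies from stride to stride around
    ``sensor.crosstalk_mm``; it needs ``t_s`` and the truth record to be
    phase-locked and is skipped when either is absent or the amplitude is 0.

    Raises :class:`OverStrainError` if the elongation anywhere exceeds the
    sensor's maximal safe strain.
    """
    nh_mm = np.asarray(nh_mm, dtype=float)
    elong = sensor.geometry_gain * (baseline_mm - nh_mm)
    if sensor.crosstalk_mm > 0 and t_s is not None and truth is not None:
        if rng is None:
            rng = np.random.default_rng()
        hs = truth["t_hs_s"].to_numpy()
        T = np.median(np.diff(hs)) if len(hs) > 1 else float(
            truth["t_to_s"].iloc[0] - truth["t_hs_s"].iloc[0]
        ) / 0.6
        bounds = np.append(hs, hs[-1] + T)
        for k in range(len(hs)):
            amp = max(0.0, rng.normal(sensor.crosstalk_mm, 0.5 * sensor.crosstalk_mm))
            m = (t_s >= bounds[k]) & (t_s < bounds[k + 1])
            if np.any(m):
                u = (t_s[m] - bounds[k]) / (bounds[k + 1] - bounds[k])
                elong[m] += amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    peak = float(np.max(elong)) if elong.size else 0.0
    if peak > sensor.max_elongation_mm + 1e-9:
        raise OverStrainError(
            f"elongation {peak:.2f} mm exceeds safe limit "
            f"{sensor.max_elongation_mm:.2f} mm ({sensor.max_strain_frac:.0%} of rest length)"
        )
    return elong


def elongation_to_capacitance(
    elong_mm: np.ndarray,
    sensor: SensorModel,
    noise_pf: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Transduce elongation to quantized capacitance samples.

    ``C = intercept + elongation / slope`` plus optional Gaussian noise,
    rounded to the nearest multiple of the quantization step (0.13 pF).
    """
    elong_mm = np.asarray(elong_mm, dtype=float)
    c = sensor.intercept_pf + elong_mm / sensor.slope_mm_per_pf
    if noise_pf > 0:
        if rng is None:
            rng = np.random.default_rng()
        c = c + rng.normal(0.0, noise_pf, size=c.shape)
    return np.round(c / sensor.quant_pf) * sensor.quant_pf


# ---------------------------------------------------------------------------
# Marker rendering


def render_marker_frames(
    t_s: np.ndarray,
    nh_mm: np.ndarray,
    layout: MarkerLayout | None = None,
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
    strain_rate_hz: float = DEFAULT_STRAIN_RATE_HZ,
    sync_origin: int = 0,
    noise_px: float = 0.0,
    rng: np.random.Generator | None = None,
) -> MarkerFrameSeries:
    """Render camera frames from an NH series.

    Each frame carries the three markers' pixel coordinates, the 16-bit
    gray code of the strain-sample index nearest the frame time (offset by
    ``sync_origin``, wrapping modulo 2**16) and both fiducial bits on.  NH
    is encoded on the pixel y axis: y increases as the navicular drops.
    """
    if layout is None:
        layout = MarkerLayout()
    t_s = np.asarray(t_s, dtype=float)
    nh_mm = np.asarray(nh_mm, dtype=float)
    n_frames = int(np.floor(t_s[-1] * frame_rate_hz)) + 1
    ft = np.arange(n_frames) / frame_rate_hz
    nh_f = np.interp(ft, t_s, nh_mm)
    if rng is None:
        rng = np.random.default_rng()

    def jitter(shape):
        return rng.normal(0.0, noise_px, size=shape) if noise_px > 0 else 0.0

    nav_y = layout.nav_y0_px + (layout.nh_ref_mm - nh_f) / layout.mm_per_px
    markers = {
        layout.ref_a_id: np.column_stack(
            [np.full(n_frames, layout.ref_a_px[0]) + jitter(n_frames),
             np.full(n_frames, layout.ref_a_px[1]) + jitter(n_frames)]
        ),
        layout.ref_b_id: np.column_stack(
            [np.full(n_frames, layout.ref_b_px[0]) + jitter(n_frames),
             np.full(n_frames, layout.ref_b_px[1]) + jitter(n_frames)]
        ),
        layout.nav_id: np.column_stack(
            [np.full(n_frames, layout.nav_x_px) + jitter(n_frames),
             nav_y + jitter(n_frames)]
        ),
    }
    sample_idx = np.round(ft * strain_rate_hz).astype(np.int64) + int(sync_origin)
    words = np.array([gray_encode_int(int(i) % 65536) for i in sample_idx], dtype=np.int64)
    return MarkerFrameSeries(
        frame=np.arange(n_frames),
        t_s=ft,
        markers=markers,
        sync_words=words,
        fiducial_ok=np.ones(n_frames, dtype=bool),
        rate_hz=frame_rate_hz,
    )


# ---------------------------------------------------------------------------
# Full trial


def generate_trial(
    profile: GaitProfile,
    sensor: SensorModel | None = None,
    layout: MarkerLayout | None = None,
) -> SimulatedTrial:
    """Simulate one trial end to end; deterministic given ``profile.seed``."""
    if sensor is None:
        sensor = SensorModel()
    if layout is None:
        layout = MarkerLayout(nh_ref_mm=profile.nh_baseline_mm)
    elif layout.nh_ref_mm != profile.nh_baseline_mm:
        layout = replace(layout, nh_ref_mm=profile.nh_baseline_mm)

    root = np.random.default_rng(profile.seed)
    seeds = root.integers(0, 2**31 - 1, size=3)

    t, nh, truth = simulate_nh_trajectory(profile, sensor.sample_rate_hz)
    elong = nh_to_elongation(
        nh, sensor, profile.nh_baseline_mm, t_s=t, truth=truth,
        rng=np.random.default_rng(int(seeds[0])),
    )
    cap = elongation_to_capacitance(
        elong, sensor, noise_pf=profile.noise_cap_pf,
        rng=np.random.default_rng(int(seeds[1])),
    )
    strain = StrainSeries(t_s=t, capacitance_pF=cap, rate_hz=sensor.sample_rate_hz)
    markers = render_marker_frames(
        t, nh, layout,
        strain_rate_hz=sensor.sample_rate_hz,
        noise_px=profile.noise_nh_mm / layout.mm_per_px,
        rng=np.random.default_rng(int(seeds[2])),
    )
    return SimulatedTrial(
        truth=truth, strain=strain, markers=markers,
        nh_true_mm=nh, elongation_true_mm=elong,
        profile=profile, sensor=sensor, layout=layout,
    )


def capacitance_to_frequency(
    c_pf: np.ndarray, k_hz_pf: float = 1.0e6, c_parasitic_pf: float = 10.0
) -> np.ndarray:
    """Generic timer-circuit model: ``f = k / (C + C_parasitic)``.

    The acquisition hardware converts capacitance to a timer frequency that
    the microcontroller counts; circuits of this family are inverse in the
    total (sensor plus parasitic) capacitance.  The default pipeline works
    on capacitance directly; this optional stage exists so timer-frequency
    records can be converted.  Units: pF in, Hz out.
    """
    c_pf = np.asarray(c_pf, dtype=float)
    return k_hz_pf / (c_pf + c_parasitic_pf)


def frequency_to_capacitance(
    f_hz: np.ndarray, k_hz_pf: float = 1.0e6, c_parasitic_pf: float = 10.0
) -> np.ndarray:
    """Inverse of :func:`capacitance_to_frequency`."""
    f_hz = np.asarray(f_hz, dtype=float)
    return k_hz_pf / f_hz - c_parasitic_pf


def simulate_calibration_sweep(
    sensor: SensorModel | None = None,
    step_mm: float = 0.5,
    max_mm: float = 20.0,
    noise_pf: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Bench calibration sweep: extend in steps of ``step_mm`` up to ``max_mm``.

    With the default 40 mm rest length, the default 20 mm maximum equals
    50% strain — the sensor's limit.  Returns a DataFrame with columns
    ``capacitance_pF`` and ``extension_mm``.
    """
    if sensor is None:
        sensor = SensorModel()
    ext = np.arange(0.0, max_mm + step_mm / 2, step_mm)
    if ext[-1] > sensor.max_elongation_mm + 1e-9:
        raise OverStrainError("sweep exceeds the sensor's maximal safe strain")
    cap = elongation_to_capacitance(ext, sensor, noise_pf=noise_pf, rng=rng)
    return pd.DataFrame({"capacitance_pF": cap, "extension_mm": ext})
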