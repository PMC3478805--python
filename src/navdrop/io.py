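"""File formats, run configuration and the end-to-end workflows.

All on-disk formats are plain text: CSV for sample/frame streams (column
names carry units — ``t_s``, ``capacitance_pF``, ``x_px`` — to keep unit
bugs loud) and JSON for calibration models, sync maps, truth records and
trial reports.  Every artifact written by a workflow embeds the seed and a
hash of the configuration that produced it.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gait_sim
from .calibration import CalibrationModel, apply_calibration, fit_calibration
from .errors import ParseError
from .events import (
    StepEvents,
    detect_inshoe_events,
    detect_mvsa_events,
    detect_pbs_events,
    segment_steps,
    smooth_series,
)
from .gait_sim import MM_PER_PX, GaitProfile, MarkerLayout, SensorModel, generate_trial
from .placement import to_local_frame
from .series import MarkerFrameSeries, StrainSeries
from .stats import (
    TrialReport,
    nd_from_mvsa,
    nd_from_pbs,
    paired_comparison,
    session_summary,
    test_retest,
)
from .sync import decode_frames, upsample_to_strain_timeline

__all__ = [
    "read_strain_csv", "write_strain_csv",
    "read_marker_csv", "write_marker_csv",
    "read_calibration_json", "write_calibration_json",
    "write_truth_json", "read_truth_json",
    "write_report_json",
    "RunConfig", "load_config", "run_workflow",
    "analyze_validate", "analyze_inshoe",
]

STRAIN_COLUMNS = ("t_s",)  # plus capacitance_pF and/or elongation_mm
MARKER_COLUMNS = ("frame", "t_s", "marker_id", "x_px", "y_px",
                  "sync_word_hex", "fiducial_ok")


# ---------------------------------------------------------------------------
# Strain CSV


def write_strain_csv(series: StrainSeries, path) -> None:
    cols = {"t_s": series.t_s}
    if series.capacitance_pF is not None:
        cols["capacitance_pF"] = series.capacitance_pF
    if series.elongation_mm is not None:
        cols["elongation_mm"] = series.elongation_mm
    pd.DataFrame(cols).to_csv(path, index=False)


def read_strain_csv(path, expected_rate_hz: float | None = 200.0,
                    rate_tol: float = 0.01) -> StrainSeries:
    """Read a strain record; validates monotone time and the sample rate.

    The rate inferred from the median time step must agree with
    ``expected_rate_hz`` to within ``rate_tol`` (1% by default); pass
    ``expected_rate_hz=None`` to skip the check.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "t_s" not in df.columns:
        raise ParseError(f"{path}: missing column t_s")
    if "capacitance_pF" not in df.columns and "elongation_mm" not in df.columns:
        raise ParseError(f"{path}: need capacitance_pF or elongation_mm column")
    t = df["t_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ParseError(f"{path}: non-monotone time at data row {int(bad[0]) + 2}")
    rate = 1.0 / float(np.median(np.diff(t)))
    if expected_rate_hz is not None and abs(rate - expected_rate_hz) > rate_tol * expected_rate_hz:
        raise ParseError(
            f"{path}: inferred rate {rate:.2f} Hz deviates more than "
            f"{rate_tol:.0%} from expected {expected_rate_hz:.0f} Hz"
        )
    return StrainSeries(
        t_s=t,
        capacitance_pF=df["capacitance_pF"].to_numpy(float) if "capacitance_pF" in df else None,
        elongation_mm=df["elongation_mm"].to_numpy(float) if "elongation_mm" in df else None,
        rate_hz=rate,
    )


# ---------------------------------------------------------------------------
# Marker CSV (long format: one row per marker per frame)


def write_marker_csv(series: MarkerFrameSeries, path) -> None:
    rows = []
    words = series.sync_words if series.sync_words is not None else np.zeros(series.n_frames, int)
    fid = series.fiducial_ok if series.fiducial_ok is not None else np.ones(series.n_frames, bool)
    for mid, xy in series.markers.items():
        rows.append(pd.DataFrame({
            "frame": series.frame,
            "t_s": series.t_s,
            "marker_id": mid,
            "x_px": xy[:, 0],
            "y_px": xy[:, 1],
            "sync_word_hex": [format(int(w), "04x") for w in words],
            "fiducial_ok": fid.astype(int),
        }))
    out = pd.concat(rows).sort_values(["frame", "marker_id"])
    out.to_csv(path, index=False)


def read_marker_csv(path, expected_rate_hz: float | None = 114.0,
                    rate_tol: float = 0.01) -> MarkerFrameSeries:
    df = pd.read_csv(path, dtype={"sync_word_hex": str},
                     float_precision="round_trip")
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df.duplicated(subset=["frame", "marker_id"]).any():
        dup = df[df.duplicated(subset=["frame", "marker_id"])].iloc[0]
        raise ParseError(
            f"{path}: duplicate (frame={int(dup['frame'])}, marker_id={dup['marker_id']!r})"
        )
    frames = np.sort(df["frame"].unique())
    per_frame = df.drop_duplicates(subset="frame").set_index("frame").loc[frames]
    t = per_frame["t_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ParseError(f"{path}: non-monotone frame times")
    rate = 1.0 / float(np.median(np.diff(t)))
    if expected_rate_hz is not None and abs(rate - expected_rate_hz) > rate_tol * expected_rate_hz:
        raise ParseError(
            f"{path}: inferred frame rate {rate:.2f} Hz deviates from "
            f"expected {expected_rate_hz:.0f} Hz"
        )
    markers: dict[str, np.ndarray] = {}
    for mid, g in df.groupby("marker_id"):
        g = g.set_index("frame").reindex(frames)
        markers[str(mid)] = g[["x_px", "y_px"]].to_numpy(dtype=float)
    words = np.array([int(w, 16) for w in per_frame["sync_word_hex"]], dtype=np.int64)
    return MarkerFrameSeries(
        frame=frames,
        t_s=t,
        markers=markers,
        sync_words=words,
        fiducial_ok=per_frame["fiducial_ok"].to_numpy(dtype=bool),
        rate_hz=rate,
    )


# ---------------------------------------------------------------------------
# JSON artifacts


def _dump_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_calibration_json(model: CalibrationModel, path, meta: dict | None = None) -> None:
    obj = model.to_dict()
    if meta:
        obj["meta"] = meta
    _dump_json(obj, path)


def read_calibration_json(path) -> CalibrationModel:
    obj = json.loads(Path(path).read_text())
    return CalibrationModel(
        slope_mm_per_pf=obj["slope_mm_per_pf"],
        intercept_mm=obj["intercept_mm"],
        r_squared=obj.get("r_squared"),
        n_points=obj["n_points"],
        label=obj.get("label", ""),
    )


def write_truth_json(truth: pd.DataFrame, path, meta: dict | None = None) -> None:
    obj = {"steps": truth.to_dict(orient="records")}
    if meta:
        obj["meta"] = meta
    _dump_json(obj, path)


def read_truth_json(path) -> pd.DataFrame:
    obj = json.loads(Path(path).read_text())
    df = pd.DataFrame(obj["steps"])
    order = [c for c in ("step", "t_hs_s", "t_nhl_s", "t_to_s", "nd_true_mm")
             if c in df.columns]
    return df[order + [c for c in df.columns if c not in order]]


def write_report_json(report: TrialReport, path) -> None:
    obj = report.to_dict()
    if obj["comparison"] is not None:
        obj["comparison"] = dict(obj["comparison"])
        scatter = obj["comparison"].pop("scatter", None)
        if scatter is not None:
            obj["comparison"]["scatter"] = scatter.to_dict(orient="records")
    _dump_json(obj, path)


def write_events_csv(events: StepEvents, path) -> None:
    pd.DataFrame({
        "step": events.step,
        "stream_id": events.stream_id,
        "hs_index": events.hs_index,
        "nhl_index": events.nhl_index,
        "to_index": events.to_index,
        "start": [s for s, _ in events.step_bounds],
        "end": [e for _, e in events.step_bounds],
        "mode": events.mode,
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Workflows


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    mode: str                               # simulate | validate | inshoe
    seed: int = 0
    paths: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    sensor: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "validate", "inshoe"):
            raise ParseError(f"unknown mode {self.mode!r}")
        required = {
            "simulate": ["out_dir"],
            "validate": ["strain_csv", "marker_csv", "calibration_json"],
            "inshoe": ["strain_csv", "calibration_json"],
        }[self.mode]
        missing = [k for k in required if k not in self.paths]
        if missing:
            raise ParseError(f"mode {self.mode!r} requires paths {missing}")

    def config_hash(self) -> str:
        # hash the scientific parameters only: where files live must not
        # change what identical runs produce
        blob = json.dumps(
            {"mode": self.mode, "seed": self.seed,
             "profile": self.profile, "sensor": self.sensor, "options": self.options},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"seed": self.seed, "config_hash": self.config_hash()}


def load_config(path) -> RunConfig:
    obj = json.loads(Path(path).read_text())
    return RunConfig(
        mode=obj.get("mode", "validate"),
        seed=int(obj.get("seed", 0)),
        paths=obj.get("paths", {}),
        profile=obj.get("profile", {}),
        sensor=obj.get("sensor", {}),
        options=obj.get("options", {}),
    )


def extract_nh_from_markers(
    markers: MarkerFrameSeries,
    ref_a: str = "A",
    ref_b: str = "B",
    nav: str = "NAV",
    mm_per_px: float = MM_PER_PX,
) -> np.ndarray:
    """Per-frame navicular height (up to an additive constant) in mm.

    Markers are expressed in the A/B local foot frame; with image y
    pointing down, height is the negated local y scaled to mm.  The
    constant offset is irrelevant: the navicular drop is a difference.
    """
    local = to_local_frame(
        {m: markers.marker_xy(m) for m in (nav, ref_a, ref_b)}, ref_a, ref_b
    )
    return -local[nav][:, 1] * mm_per_px


def analyze_validate(
    strain: StrainSeries,
    markers: MarkerFrameSeries,
    model: CalibrationModel,
    ref_a: str = "A",
    ref_b: str = "B",
    nav: str = "NAV",
    mm_per_px: float = MM_PER_PX,
    smooth_s: float = 0.035,
    meta: dict | None = None,
) -> TrialReport:
    """Bare-foot validation workflow: camera and sensor side by side.

    Calibrates the sensor record, decodes the sync words, upsamples the
    marker-derived navicular height onto the 200 Hz strain timeline,
    detects per-step events on both streams and pairs the per-step drops.
    """
    cal = apply_calibration(strain, model)
    elong = smooth_series(cal.elongation_mm, cal.rate_hz, smooth_s)
    syncmap = decode_frames(markers, strain_rate_hz=strain.rate_hz)
    nh_frame = extract_nh_from_markers(markers, ref_a, ref_b, nav, mm_per_px)
    nh_full = upsample_to_strain_timeline(nh_frame, syncmap, strain.n)
    valid = np.flatnonzero(~np.isnan(nh_full))
    i0, i1 = int(valid[0]), int(valid[-1])
    nh = smooth_series(nh_full[i0:i1 + 1], strain.rate_hz, smooth_s)
    el = elong[i0:i1 + 1]

    bounds = segment_steps(el, strain.rate_hz)
    mvsa_ev = detect_mvsa_events(nh, bounds)
    pbs_ev = detect_pbs_events(el, mvsa_ev)

    nd_m = nd_from_mvsa(nh, mvsa_ev).rename(columns={"nd_mm": "nd_mvsa_mm"})
    nd_p = nd_from_pbs(el, pbs_ev).rename(columns={"nd_mm": "nd_pbs_mm"})
    per_step = nd_m.merge(nd_p, on="step", how="inner")

    comparison = None
    if len(per_step) >= 3:
        comparison = paired_comparison(
            per_step["nd_mvsa_mm"].to_numpy(), per_step["nd_pbs_mm"].to_numpy()
        )
    return TrialReport(
        per_step=per_step,
        mvsa_summary=session_summary(per_step["nd_mvsa_mm"]),
        pbs_summary=session_summary(per_step["nd_pbs_mm"]),
        comparison=comparison,
        meta={"mode": "validate", "offset_samples": i0,
              "sync": syncmap.offset_stats, **(meta or {})},
    )


def analyze_inshoe(
    strain: StrainSeries,
    model: CalibrationModel,
    smooth_s: float = 0.035,
    meta: dict | None = None,
) -> TrialReport:
    """In-shoe workflow: sensor only, standalone event detection."""
    cal = apply_calibration(strain, model)
    elong = smooth_series(cal.elongation_mm, cal.rate_hz, smooth_s)
    ev = detect_inshoe_events(elong, strain.rate_hz)
    nd_p = nd_from_pbs(elong, ev).rename(columns={"nd_mm": "nd_pbs_mm"})
    return TrialReport(
        per_step=nd_p,
        mvsa_summary=None,
        pbs_summary=session_summary(nd_p["nd_pbs_mm"]),
        meta={"mode": "inshoe (standalone events)", **(meta or {})},
    )


def run_workflow(config: RunConfig) -> TrialReport | None:
    """Execute a configured workflow and write its artifacts.

    ``simulate`` renders a synthetic trial to CSV/JSON (returns None);
    ``validate`` and ``inshoe`` produce (and write, when an output path is
    configured) a :class:`TrialReport`.  Deterministic given the seed.
    """
    prov = config.provenance()
    if config.mode == "simulate":
        profile = GaitProfile(**{**config.profile, "seed": config.seed})
        sensor = SensorModel(**config.sensor)
        trial = generate_trial(profile, sensor)
        out = Path(config.paths["out_dir"])
        out.mkdir(parents=True, exist_ok=True)
        write_strain_csv(trial.strain, out / "strain.csv")
        write_marker_csv(trial.markers, out / "markers.csv")
        write_truth_json(trial.truth, out / "truth.json", meta=prov)
        sweep = gait_sim.simulate_calibration_sweep(sensor)
        write_calibration_json(
            fit_calibration(sweep, label="simulated bench sweep"),
            out / "calibration.json", meta=prov,
        )
        return None

    model = read_calibration_json(config.paths["calibration_json"])
    opts = config.options
    strain = read_strain_csv(config.paths["strain_csv"],
                             expected_rate_hz=opts.get("strain_rate_hz", 200.0))
    if config.mode == "validate":
        markers = read_marker_csv(config.paths["marker_csv"],
                                  expected_rate_hz=opts.get("frame_rate_hz", 114.0))
        report = analyze_validate(
            strain, markers, model,
            ref_a=opts.get("ref_a", "A"), ref_b=opts.get("ref_b", "B"),
            nav=opts.get("nav", "NAV"),
            mm_per_px=opts.get("mm_per_px", MM_PER_PX),
            smooth_s=opts.get("smooth_s", 0.035),
            meta=prov,
        )
        if "retest_strain_csv" in config.paths:
            strain2 = read_strain_csv(config.paths["retest_strain_csv"],
                                      expected_rate_hz=opts.get("strain_rate_hz", 200.0))
            markers2 = read_marker_csv(config.paths["retest_marker_csv"],
                                       expected_rate_hz=opts.get("frame_rate_hz", 114.0))
            report2 = analyze_validate(
                strain2, markers2, model,
                ref_a=opts.get("ref_a", "A"), ref_b=opts.get("ref_b", "B"),
                nav=opts.get("nav", "NAV"),
                mm_per_px=opts.get("mm_per_px", MM_PER_PX),
                smooth_s=opts.get("smooth_s", 0.035),
                meta=prov,
            )
            report.retest = {
                "mvsa": test_retest(report.per_step["nd_mvsa_mm"],
                                    report2.per_step["nd_mvsa_mm"]),
                "pbs": test_retest(report.per_step["nd_pbs_mm"],
                                   report2.per_step["nd_pbs_mm"]),
                "retest_summary": {
                    "mvsa": report2.mvsa_summary, "pbs": report2.pbs_summary,
                    "comparison": {k: v for k, v in (report2.comparison or {}).items()
                                   if k != "scatter"},
                },
            }
    else:
        report = analyze_inshoe(strain, model,
                                smooth_s=opts.get("smooth_s", 0.035), meta=prov)

    if "report_json" in config.paths:
        write_report_json(report, config.paths["report_json"])
    return report
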