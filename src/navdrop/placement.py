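"""Sensor-placement geometry from marker displacement clouds.

A local foot frame is defined per frame by two reference markers: the
calcaneus marker B maps to (0, 0) and the front-foot marker A to (|A-B|, 0)
— a rigid rotation plus translation, no scaling.  Expressing every other
marker in this frame removes whole-foot motion, leaving a per-marker
displacement point cloud over the trial.  The cloud's major axis (principal
eigenvector of the 2x2 coordinate covariance) summarizes the direction of
that marker's motion; a candidate upper attachment site whose major axis is
perpendicular to the sensor line contributes the least spurious strain.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AxisUndefinedError, DegenerateFrameError, ParseError
from .series import MarkerFrameSeries

__all__ = [
    "PointCloud",
    "to_local_frame",
    "displacement_cloud",
    "major_axis",
    "axis_angle_between",
    "score_attachment_pair",
    "rank_attachment_pairs",
]

#: Minimum major/minor eigenvalue ratio below which a cloud is treated as
#: isotropic and its major axis refused.
ISOTROPY_RATIO = 1.05


@dataclass
class PointCloud:
    """Displacement scatter of one marker in the local foot frame."""

    points: np.ndarray          # (n, 2)
    marker_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1 or self.points.shape[1] != 2:
            raise ParseError("point cloud must be a non-empty (n, 2) array")
        if not np.all(np.isfinite(self.points)):
            raise ParseError("point cloud contains non-finite coordinates")

    @property
    def n(self) -> int:
        return int(self.points.shape[0])


def to_local_frame(
    positions: dict[str, np.ndarray], ref_a: str, ref_b: str
) -> dict[str, np.ndarray]:
    """Rigidly transform marker positions into the A/B local frame.

    ``positions`` maps marker id to an (x, y) pixel position (or an (n, 2)
    stack).  B maps to the origin, A to (|A - B|, 0); the identical
    rotation+translation is applied to every marker, so all pairwise
    distances are preserved.
    """
    for rid in (ref_a, ref_b):
        if rid not in positions:
            raise ParseError(f"reference marker {rid!r} missing")
    a = np.asarray(positions[ref_a], dtype=float)
    b = np.asarray(positions[ref_b], dtype=float)
    v = a - b
    norm = np.linalg.norm(v, axis=-1)
    if np.any(norm < 1e-12):
        raise DegenerateFrameError("reference markers coincide")
    theta = np.arctan2(v[..., 1], v[..., 0])
    cos, sin = np.cos(theta), np.sin(theta)
    out: dict[str, np.ndarray] = {}
    for mid, p in positions.items():
        p = np.asarray(p, dtype=float)
        d = p - b
        out[mid] = np.stack(
            [cos * d[..., 0] + sin * d[..., 1],
             -sin * d[..., 0] + cos * d[..., 1]],
            axis=-1,
        )
    return out


def displacement_cloud(
    series: MarkerFrameSeries, marker: str, ref_a: str, ref_b: str
) -> PointCloud:
    """Local-frame displacement of one marker over a trial.

    Each frame's markers are transformed into that frame's A/B local frame;
    the marker's local coordinates, centered on their own centroid, form
    the cloud.
    """
    for mid in (marker, ref_a, ref_b):
        if mid not in series.markers:
            raise ParseError(f"marker {mid!r} not present in series")
    if series.n_frames < 2:
        raise ParseError("need at least 2 frames for a displacement cloud")
    local = to_local_frame(
        {mid: series.markers[mid] for mid in (marker, ref_a, ref_b)}, ref_a, ref_b
    )
    pts = local[marker]
    return PointCloud(points=pts - pts.mean(axis=0), marker_id=marker)


def major_axis(cloud: PointCloud) -> tuple[np.ndarray, float]:
    """Principal direction of a displacement cloud.

    Returns ``(unit_vector, angle_deg)`` with the angle measured from the
    local +x axis, folded into [0, 180).  Refuses near-isotropic clouds
    (eigenvalue ratio below :data:`ISOTROPY_RATIO`) rather than reporting a
    direction dominated by noise.
    """
    pts = cloud.points
    if pts.shape[0] < 2 or np.allclose(pts, pts[0]):
        raise AxisUndefinedError("need >= 2 distinct points")
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    lam_minor, lam_major = float(evals[0]), float(evals[1])
    if lam_major <= 0:
        raise AxisUndefinedError("degenerate cloud")
    if lam_minor > 0 and lam_major / lam_minor < ISOTROPY_RATIO:
        raise AxisUndefinedError(
            f"cloud is near-isotropic (eigenvalue ratio "
            f"{lam_major / lam_minor:.3f} < {ISOTROPY_RATIO})"
        )
    v = evecs[:, 1]
    angle = np.degrees(np.arctan2(v[1], v[0])) % 180.0
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        v = -v
    return v, float(angle)


def axis_angle_between(cloud_a: PointCloud, cloud_b: PointCloud) -> float:
    """Undirected angle in degrees, in [0, 180), between two major axes."""
    _, a = major_axis(cloud_a)
    _, b = major_axis(cloud_b)
    return float(abs(a - b) % 180.0)


def score_attachment_pair(
    upper: PointCloud, lower: PointCloud, sensor_line: np.ndarray
) -> float:
    """Alignment score of the upper attachment site's motion with the sensor.

    ``|cos(angle between the upper cloud's major axis and the sensor
    line)|`` — 0 means the upper site moves perpendicular to the sensor and
    contributes no spurious strain (ideal), 1 means fully aligned.  Lower
    is better.  The lower cloud's axis is validated (it must be defined)
    but does not enter the score: the lower site rides with the navicular
    by design.
    """
    axis, _ = major_axis(upper)
    major_axis(lower)
    line = np.asarray(sensor_line, dtype=float)
    norm = np.linalg.norm(line)
    if norm < 1e-12:
        raise ParseError("sensor line direction is zero")
    return float(abs(np.dot(axis, line / norm)))


def rank_attachment_pairs(
    pairs: list[tuple[PointCloud, PointCloud]], sensor_line: np.ndarray
) -> list[tuple[int, float]]:
    """Rank candidate (upper, lower) pairs, best (lowest score) first.

    Pairs whose axes are undefined are dropped with a warning.
    """
    scored: list[tuple[int, float]] = []
    for i, (upper, lower) in enumerate(pairs):
        try:
            scored.append((i, score_attachment_pair(upper, lower, sensor_line)))
        except AxisUndefinedError as exc:
            warnings.warn(f"pair {i}: {exc}", stacklevel=2)
    return sorted(scored, key=lambda t: t[1])
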