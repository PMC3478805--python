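"""Navicular-drop extraction and validation statistics.

The navicular drop (ND) of a step is the change in navicular height from
heel strike to the lowest navicular height: ``ND = NH(HS) - NH(NHL)`` on
the camera stream, and the calibrated elongation change
``elong(NHL) - elong(HS)`` on the sensor stream (the sensor's elongation in
mm is taken as the ND estimate directly).  Session summaries are means with
t-based 95% confidence intervals; agreement between the two streams is
quantified per step by the Pearson product-moment correlation (two-sided p
via the t transform) and the mean difference; test-retest change uses a
Welch two-sample t-test because the two sessions generally contain
different numbers of steps.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TrialReport",
    "nd_from_mvsa",
    "nd_from_pbs",
    "session_summary",
    "pearson_p_from_r",
    "paired_comparison",
    "test_retest",
]

from .events import StepEvents


@dataclass
class TrialReport:
    """Per-step ND pairs plus session-level validation statistics."""

    per_step: pd.DataFrame                  # step, nd_mvsa_mm, nd_pbs_mm
    mvsa_summary: dict | None
    pbs_summary: dict
    comparison: dict | None = None          # pearson r/p, mean difference + CI
    retest: dict | None = None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_step": self.per_step.to_dict(orient="records"),
            "mvsa_summary": self.mvsa_summary,
            "pbs_summary": self.pbs_summary,
            "comparison": self.comparison,
            "retest": self.retest,
            "meta": self.meta,
        }


def _nd_at_events(values: np.ndarray, events: StepEvents, sign: int) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    nds = sign * (values[events.nhl_index] - values[events.hs_index])
    return pd.DataFrame({"step": events.step, "nd_mm": nds})


def nd_from_mvsa(nh_mm: np.ndarray, events: StepEvents) -> pd.DataFrame:
    """Per-step ND from a navicular-height series: ``NH(HS) - NH(NHL)``."""
    return _nd_at_events(nh_mm, events, sign=-1)


def nd_from_pbs(elong_mm: np.ndarray, events: StepEvents) -> pd.DataFrame:
    """Per-step ND from calibrated elongation: ``elong(NHL) - elong(HS)``."""
    return _nd_at_events(elong_mm, events, sign=+1)


def session_summary(nds) -> dict:
    """Mean ND with a t-based 95% confidence interval.

    ``mean +/- t_{0.975, n-1} * SD / sqrt(n)``; requires n >= 2.
    """
    x = np.asarray(nds, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("session summary needs at least 2 steps")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    half = float(sps.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    return {"mean_mm": mean, "ci_low_mm": mean - half, "ci_high_mm": mean + half,
            "sd_mm": sd, "n": int(n)}


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson r via ``t = r*sqrt((n-2)/(1-r^2))``."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def paired_comparison(nd_mvsa, nd_pbs) -> dict:
    """Step-by-step agreement between the two streams.

    Returns the Pearson r with its two-sided p-value, the mean difference
    (camera minus sensor) with a t-based 95% CI, and a scatter table with
    the slope-1 reference line offset (the line drawn through ND scatter
    plots intercepts the y axis at the mean difference).
    """
    a = np.asarray(nd_mvsa, dtype=float)
    b = np.asarray(nd_pbs, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 paired steps")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance: Pearson r undefined")
    r = float(sps.pearsonr(a, b).statistic)
    p = pearson_p_from_r(r, n)
    diff = a - b
    dsum = session_summary(diff)
    return {
        "pearson_r": r,
        "p_value": p,
        "n": int(n),
        "mean_difference_mm": dsum["mean_mm"],
        "diff_ci_low_mm": dsum["ci_low_mm"],
        "diff_ci_high_mm": dsum["ci_high_mm"],
        "reference_line": {"slope": 1.0, "intercept_mm": dsum["mean_mm"]},
        "scatter": pd.DataFrame({"nd_pbs_mm": b, "nd_mvsa_mm": a}),
    }


def test_retest(session_a, session_b) -> dict:
    """Change in mean ND between two sessions with a Welch t-test p-value.

    The sessions generally hold different step counts, so an unpaired test
    is the only option; Welch's form drops the equal-variance assumption.
    Two identical degenerate (zero-variance) sessions return p = 1, a
    zero-variance shift returns p = 0; both paths are by-definition limits
    of the Welch statistic.
    """
    a = np.asarray(session_a, dtype=float)
    b = np.asarray(session_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each session needs at least 2 steps")
    change = float(np.mean(b) - np.mean(a))
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        p = 1.0 if change == 0 else 0.0
    else:
        p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    return {
        "mean_a_mm": float(np.mean(a)),
        "mean_b_mm": float(np.mean(b)),
        "change_mm": change,
        "p_value": p,
        "n_a": int(a.size),
        "n_b": int(b.size),
    }
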