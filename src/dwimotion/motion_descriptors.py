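"""Scan-level motion descriptors derived from eddy's outputs.

The headline measure is the *mean relative movement per imaging volume*
(mm/vol): the mean of the volume-to-volume RMS voxel displacement.
Normalizing by nominal scan time (n_volumes × TR) gives the *mean
relative movement per minute* (mm/min). Per-axis translation and
rotation rates are means of absolute volume-to-volume parameter
differences; rotations are reported in degrees.

The first volume is excluded from all relative means: it has no
predecessor, and counting its structural zero would deflate every rate
by 1/N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .eddy_io import AcquisitionMeta, MotionTrace, RMSSeries
from .errors import ValidationError

__all__ = ["MotionSummary", "summarize_scan", "skew_diagnostic", "cumulative_curves"]

#: Time step (minutes) of the common grid cumulative curves are pooled on.
CUMULATIVE_GRID_STEP_MIN = 0.1


@dataclass
class MotionSummary:
    """Motion descriptors for one scan.

    Per-axis vectors are ordered (L/R, P/A, I/S) — translations along,
    rotations about, those anatomical axes. ``cumulative_mm`` is the
    running sum of the relative RMS series (length n_volumes).
    """

    mean_rel_mm_per_vol: float
    median_rel_mm_per_vol: float
    mean_rel_mm_per_min: float
    trans_rate_per_vol: np.ndarray  # mm/vol
    trans_rate_per_min: np.ndarray  # mm/min
    rot_rate_per_vol: np.ndarray  # deg/vol
    rot_rate_per_min: np.ndarray  # deg/min
    cumulative_mm: np.ndarray
    tr_seconds: float

    @property
    def median_rel_mm_per_min(self) -> float:
        return self.median_rel_mm_per_vol * 60.0 / self.tr_seconds


def summarize_scan(rms: RMSSeries, trace: MotionTrace, meta: AcquisitionMeta) -> MotionSummary:
    """Compute the full descriptor set for one scan.

    ``rms`` and ``trace`` must both have ``meta.n_volumes`` volumes.
    Per-minute values are per-volume values × 60/TR.
    """
    n = meta.n_volumes
    if rms.n_volumes != n or trace.n_volumes != n:
        raise ValidationError(
            f"length mismatch: rms={rms.n_volumes}, trace={trace.n_volumes}, "
            f"meta.n_volumes={n}"
        )
    if n < 2:
        raise ValidationError("need at least 2 volumes to compute relative movement")

    per_min = 60.0 / meta.tr_seconds
    rel = rms.rel_rms[1:]  # first volume has no predecessor
    mean_vol = float(np.mean(rel))
    median_vol = float(np.median(rel))

    dtrans = np.abs(np.diff(trace.trans, axis=0))  # (n-1, 3), mm
    drot = np.abs(np.diff(trace.rot, axis=0))  # (n-1, 3), rad
    trans_rate = dtrans.mean(axis=0)
    rot_rate = np.degrees(drot.mean(axis=0))

    return MotionSummary(
        mean_rel_mm_per_vol=mean_vol,
        median_rel_mm_per_vol=median_vol,
        mean_rel_mm_per_min=mean_vol * per_min,
        trans_rate_per_vol=trans_rate,
        trans_rate_per_min=trans_rate * per_min,
        rot_rate_per_vol=rot_rate,
        rot_rate_per_min=rot_rate * per_min,
        cumulative_mm=np.cumsum(rms.rel_rms),
        tr_seconds=meta.tr_seconds,
    )


def skew_diagnostic(summaries: Sequence[MotionSummary]) -> tuple[float, float, bool]:
    """Cohort-level (mean of per-scan means, mean of per-scan medians,
    mean > median flag).

    The flag being true indicates right-skewed within-scan movement:
    frequent small movements punctuated by occasional large ones.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValidationError("skew_diagnostic needs at least one summary")
    mean_of_means = float(np.mean([s.mean_rel_mm_per_vol for s in summaries]))
    mean_of_medians = float(np.mean([s.median_rel_mm_per_vol for s in summaries]))
    return mean_of_means, mean_of_medians, mean_of_means > mean_of_medians


def cumulative_curves(
    summaries: Sequence[MotionSummary], span: float = 0.3
) -> tuple[list[tuple[np.ndarray, np.ndarray]], tuple[np.ndarray, np.ndarray]]:
    """Per-scan cumulative displacement curves plus a LOESS-averaged
    cohort time course.

    Each scan's cumulative series is resampled by linear interpolation
    onto a common 0.1-minute grid spanning [0, that scan's duration];
    the pooled (time, cumulative) points are smoothed with LOESS (local
    linear, tricube weights, fraction ``span``) and evaluated on the
    grid covered by all pooled points. Returns
    ``(per_scan, (grid_minutes, loess_curve))``; the averaged curve is
    clipped at 0.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValidationError("cumulative_curves needs at least one summary")
    per_scan: list[tuple[np.ndarray, np.ndarray]] = []
    pooled_t: list[np.ndarray] = []
    pooled_c: list[np.ndarray] = []
    for s in summaries:
        n = s.cumulative_mm.size
        t = np.arange(n) * s.tr_seconds / 60.0  # minutes since scan start
        duration = t[-1]
        grid = np.arange(0.0, duration + 1e-12, CUMULATIVE_GRID_STEP_MIN)
        resampled = np.interp(grid, t, s.cumulative_mm)
        per_scan.append((grid, resampled))
        pooled_t.append(grid)
        pooled_c.append(resampled)
    t_all = np.concatenate(pooled_t)
    c_all = np.concatenate(pooled_c)
    if t_all.size < 5:
        raise ValidationError("LOESS averaging needs at least 5 pooled points")
    out_grid = np.arange(0.0, t_all.max() + 1e-12, CUMULATIVE_GRID_STEP_MIN)
    smoothed = lowess(c_all, t_all, frac=span, it=0, xvals=out_grid)
    return per_scan, (out_grid, np.clip(smoothed, 0.0, None))
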