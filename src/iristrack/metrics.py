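"""Per-axis trajectory validation metrics and grouped comparison tables.

Given manually annotated (or synthetic ground-truth) iris centres and the
tracker output, the per-axis metrics are

    MAE  = (1/n) sum |a_i - m_i|                      [pixels]
    MPE  = (1/n) sum |a_i - m_i| / (a_i + eps) * 100  [percent]
    RMSE = sqrt((1/n) sum (a_i - m_i)^2)              [pixels]
    r    = Pearson correlation of a and m
    t    = r * sqrt((n - 2) / (1 - r^2)),  p = 2 * SF_t(|t|; df = n - 2)

where ``a`` is the ground truth, ``m`` the tracker output, and n counts the
frames valid in both sources.  Note MPE divides by the raw pixel coordinate,
so it is origin-dependent (it is defined relative to the ROI's top-left
corner); this convention is kept deliberately for comparability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .video_io import Trajectory

__all__ = [
    "AxisSeries",
    "AxisMetrics",
    "MetricsReport",
    "ConditionKey",
    "ConstantSeriesError",
    "mae",
    "mpe",
    "rmse",
    "pearson",
    "evaluate",
    "average_reports",
    "compare_groups",
]

DEFAULT_EPSILON = 1e-6

TASKS = ("vertical", "horizontal", "circular", "fixation")
CONDITIONS = ("finger", "no_finger")
SPEEDS = ("1s", "5s")
METHODS = ("CHT_ACM", "CHT_TM")


class ConstantSeriesError(ValueError):
    """Correlation is undefined for a constant series."""


@dataclass(frozen=True)
class AxisSeries:
    """Paired ground-truth and measured coordinates for one axis."""

    actual: np.ndarray
    measured: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.actual, dtype=np.float64)
        m = np.asarray(self.measured, dtype=np.float64)
        if a.shape != m.shape or a.ndim != 1:
            raise ValueError("actual and measured must be equal-length 1-D arrays")
        if a.size == 0:
            raise ValueError("series must contain at least one pair")
        object.__setattr__(self, "actual", a)
        object.__setattr__(self, "measured", m)

    @property
    def n(self) -> int:
        return int(self.actual.size)


@dataclass
class AxisMetrics:
    """All four metrics for one axis; Pearson fields are None when undefined."""

    mae: float
    mpe: float
    rmse: float
    pearson_r: Optional[float]
    t_stat: Optional[float]
    p_value: Optional[float]
    pearson_note: Optional[str] = None


@dataclass
class MetricsReport:
    """Per-axis metrics for one trajectory-vs-ground-truth pair."""

    x: AxisMetrics
    y: AxisMetrics
    n_valid: int
    n_invalid: int
    epsilon: float = DEFAULT_EPSILON


@dataclass(frozen=True)
class ConditionKey:
    """Grouping key for comparison tables (any field may be None = pooled)."""

    method: str
    condition: Optional[str] = None
    task: Optional[str] = None
    speed: Optional[str] = None
    subject: Optional[str] = None

    def __post_init__(self) -> None:
        checks = (
            (self.method, METHODS, "method"),
            (self.condition, CONDITIONS, "condition"),
            (self.task, TASKS, "task"),
            (self.speed, SPEEDS, "speed"),
        )
        for value, allowed, name in checks:
            if value is not None and value not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {value!r}")


def mae(s: AxisSeries) -> float:
    """Mean absolute error in pixels."""
    if s.n == 0:
        raise ValueError("empty series")
    return float(np.mean(np.abs(s.actual - s.measured)))


def mpe(s: AxisSeries, epsilon: float = DEFAULT_EPSILON) -> float:
    """Mean percentage error; epsilon guards division at coordinate zero."""
    if s.n == 0:
        raise ValueError("empty series")
    return float(
        np.mean(np.abs(s.actual - s.measured) / (s.actual + epsilon)) * 100.0
    )


def rmse(s: AxisSeries) -> float:
    """Root mean square error in pixels (always >= MAE)."""
    if s.n == 0:
        raise ValueError("empty series")
    return float(np.sqrt(np.mean((s.actual - s.measured) ** 2)))


def pearson(s: AxisSeries) -> tuple[float, float, float]:
    """Pearson r with its t statistic and two-tailed p value.

    ``t = r * sqrt((n-2) / (1-r^2))`` under a Student-t null with n - 2
    degrees of freedom.  Perfect correlation (|r| = 1 to machine precision)
    reports ``t = +/-inf, p = 0`` instead of dividing by zero.  A constant
    series raises :class:`ConstantSeriesError`.
    """
    if s.n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    a, m = s.actual, s.measured
    da, dm = a - a.mean(), m - m.mean()
    va, vm = float(np.sum(da * da)), float(np.sum(dm * dm))
    if va == 0.0 or vm == 0.0:
        raise ConstantSeriesError("correlation undefined for a constant series")
    r = float(np.sum(da * dm) / math.sqrt(va * vm))
    r = max(-1.0, min(1.0, r))
    df = s.n - 2
    if 1.0 - r * r <= 1e-15:
        return (r, math.copysign(math.inf, r), 0.0)
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return (r, t, min(p, 1.0))


def _axis_metrics(a: np.ndarray, m: np.ndarray, epsilon: float) -> AxisMetrics:
    s = AxisSeries(a, m)
    r = t = p = None
    note = None
    if s.n >= 3:
        try:
            r, t, p = pearson(s)
        except ConstantSeriesError:
            note = "constant series: correlation undefined"
    else:
        note = "fewer than 3 paired frames"
    return AxisMetrics(
        mae=mae(s), mpe=mpe(s, epsilon), rmse=rmse(s),
        pearson_r=r, t_stat=t, p_value=p, pearson_note=note,
    )


def evaluate(
    traj: Trajectory, truth: Trajectory, epsilon: float = DEFAULT_EPSILON
) -> MetricsReport:
    """Score a trajectory against ground truth on the co-valid frames.

    Frames are paired by frame index; a pair contributes only when both
    sources mark it valid (blink/failed frames are excluded pairwise).
    """
    pred = traj.centres()
    act = truth.centres()
    common = sorted(set(p.frame_index for p in traj) & set(p.frame_index for p in truth))
    paired = [i for i in common if i in pred and i in act]
    if not paired:
        raise ValueError("no co-valid frames to evaluate")
    ax = np.array([act[i][0] for i in paired])
    ay = np.array([act[i][1] for i in paired])
    mx = np.array([pred[i][0] for i in paired])
    my = np.array([pred[i][1] for i in paired])
    return MetricsReport(
        x=_axis_metrics(ax, mx, epsilon),
        y=_axis_metrics(ay, my, epsilon),
        n_valid=len(paired),
        n_invalid=len(common) - len(paired),
        epsilon=epsilon,
    )


def average_reports(reports: "list[MetricsReport]") -> dict:
    """Unweighted per-video mean of each error metric.

    Pooling every frame of every video into one series weights long videos
    more; averaging one report per video weights videos equally. Both
    aggregations are legitimate and can differ noticeably, so this helper
    offers the second one explicitly. Pearson fields are averaged over the
    reports where they are defined (None when undefined everywhere).
    """
    if not reports:
        raise ValueError("need at least one report")
    out: dict = {}
    for axis in ("x", "y"):
        ams = [getattr(rep, axis) for rep in reports]
        rs = [am.pearson_r for am in ams if am.pearson_r is not None]
        out[axis] = {
            "mae": float(np.mean([am.mae for am in ams])),
            "mpe": float(np.mean([am.mpe for am in ams])),
            "rmse": float(np.mean([am.rmse for am in ams])),
            "pearson_r": float(np.mean(rs)) if rs else None,
        }
    out["n_videos"] = len(reports)
    out["n_valid"] = int(sum(rep.n_valid for rep in reports))
    return out


_METRIC_COLS = ("MAE", "MPE", "RMSE", "PCC_r")
# lower is better for errors, higher for correlation
_BEST = {"MAE": "min", "MPE": "min", "RMSE": "min", "PCC_r": "max"}


def compare_groups(reports: Mapping[ConditionKey, MetricsReport]) -> pd.DataFrame:
    """Long-format comparison table with best-per-column flags.

    One row per (group, method, axis); columns MAE/MPE/RMSE/PCC_r plus
    PCC_p and n_valid.  Within each (method, axis) row family the best value
    of each metric across groups is flagged (lowest error, highest r) —
    flags stay False when the family has a single group.
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for key, rep in reports.items():
        for axis, am in (("x", rep.x), ("y", rep.y)):
            rows.append(
                {
                    "condition": key.condition,
                    "task": key.task,
                    "speed": key.speed,
                    "subject": key.subject,
                    "method": key.method,
                    "axis": axis,
                    "row": f"{axis}_{key.method}",
                    "MAE": am.mae,
                    "MPE": am.mpe,
                    "RMSE": am.rmse,
                    "PCC_r": am.pearson_r,
                    "PCC_p": am.p_value,
                    "n_valid": rep.n_valid,
                }
            )
    df = pd.DataFrame(rows)
    for col in _METRIC_COLS:
        df[f"best_{col}"] = False
    for _, idx in df.groupby(["method", "axis"]).groups.items():
        if len(idx) < 2:
            continue
        sub = df.loc[idx]
        for col in _METRIC_COLS:
            vals = sub[col].dropna()
            if vals.empty:
                continue
            target = vals.min() if _BEST[col] == "min" else vals.max()
            df.loc[sub.index[sub[col] == target], f"best_{col}"] = True
    return df
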