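"""The CHT_TM tracker: masked template matching plus darkest-region selection.

CHT_ACM runs only on the first frame, yielding an intact iris template; every
following frame is processed by sliding that template over the image,
scoring a masked similarity at every placement, keeping the placements near
the per-frame maximum, and choosing the one whose central circular region is
darkest.  The template is never updated.

Similarity defaults to masked zero-mean normalised cross-correlation (NCC):
only pixels under the template's central disc contribute, which stops an
eyelid-occluded iris from latching onto the lower half of the eye.  The raw
product-sum cross-correlation is available via ``MatchConfig.method``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve

from .detection import (
    DetectionConfig,
    IrisTemplate,
    NonIntactTemplateError,
    detect_iris_cht_acm,
    disc_mask,
    extract_template,
)
from .video_io import FrameRecord, Trajectory, TrajectoryPoint

__all__ = [
    "MatchCandidate",
    "MatchConfig",
    "TrackerConfig",
    "TrackingError",
    "match_similarity_map",
    "match_template",
    "select_darkest",
    "track_video_cht_tm",
    "track_video_cht_acm",
    "flag_invalid_frames",
    "Trajectory",
    "IrisTemplate",
]

# direct sliding-window correlation below this many multiply-adds, FFT above
_DIRECT_OP_LIMIT = 2_000_000


class TrackingError(RuntimeError):
    """Unrecoverable tracking failure (e.g. no template from the first frame)."""


@dataclass
class MatchCandidate:
    """One template placement: patch top-left, similarity, region darkness."""

    x: int
    y: int
    similarity: float
    region_mean: Optional[float] = None


@dataclass(frozen=True)
class MatchConfig:
    """Template-matching knobs."""

    use_mask: bool = True
    method: Literal["ncc", "ccorr"] = "ncc"
    sim_threshold: float = 0.98  # keep placements >= this fraction of the max
    sim_floor: float = 0.5  # absolute NCC floor below which a frame is invalid


@dataclass(frozen=True)
class TrackerConfig:
    """Detection + matching configuration for a whole tracking run."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    match: MatchConfig = field(default_factory=MatchConfig)


def _correlate(frame: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Valid-mode cross-correlation; direct for small problems, FFT otherwise."""
    oh = frame.shape[0] - kernel.shape[0] + 1
    ow = frame.shape[1] - kernel.shape[1] + 1
    ops = oh * ow * kernel.size
    if ops <= _DIRECT_OP_LIMIT:
        windows = sliding_window_view(frame, kernel.shape)
        return np.einsum("ijkl,kl->ij", windows, kernel)
    return fftconvolve(frame, kernel[::-1, ::-1], mode="valid")


def match_similarity_map(
    frame: np.ndarray, tmpl: IrisTemplate, use_mask: bool = True,
    method: Literal["ncc", "ccorr"] = "ncc",
) -> np.ndarray:
    """Similarity at every placement of the template over the frame.

    ``map[y, x]`` scores the placement with patch top-left at (x, y).  For
    NCC, zero-variance placements (or a zero-variance template) score 0.
    """
    f = np.asarray(frame, dtype=np.float64)
    t = np.asarray(tmpl.patch, dtype=np.float64)
    if t.shape[0] > f.shape[0] or t.shape[1] > f.shape[1]:
        raise ValueError(
            f"template {t.shape} does not fit inside frame {f.shape}"
        )
    m = tmpl.mask.astype(np.float64) if use_mask else np.ones_like(t)
    n = m.sum()
    if method == "ccorr":
        return _correlate(f, t * m)
    t_mean = (t * m).sum() / n
    t_prime = (t - t_mean) * m
    t_norm = np.sqrt((t_prime**2).sum())
    num = _correlate(f, t_prime)
    s1 = _correlate(f, m)
    s2 = _correlate(f * f, m)
    var = np.maximum(s2 - s1 * s1 / n, 0.0)
    denom = np.sqrt(var) * t_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 1e-9, num / np.where(denom > 0, denom, 1.0), 0.0)
    return sim


def _region_mean(frame: np.ndarray, tmpl: IrisTemplate, x: int, y: int) -> float:
    """Mean intensity of the circular region implied by a placement."""
    dx, dy = tmpl.centre_offset
    cx, cy = x + dx, y + dy
    m = disc_mask(frame.shape, cx, cy, tmpl.iris_radius)
    if not m.any():
        return float("inf")
    return float(np.asarray(frame, dtype=np.float64)[m].mean())


def match_template(
    frame: np.ndarray,
    tmpl: IrisTemplate,
    use_mask: bool = True,
    sim_threshold: float = 0.98,
    method: Literal["ncc", "ccorr"] = "ncc",
) -> list[MatchCandidate]:
    """Placements whose similarity reaches ``sim_threshold`` x the maximum.

    Sorted by similarity descending (ties by y then x, so the order is
    deterministic).  Returns an empty list in the degenerate zero-variance
    case, which flags the frame as unmatched.
    """
    sim = match_similarity_map(frame, tmpl, use_mask=use_mask, method=method)
    max_sim = float(sim.max())
    if max_sim <= 0:
        return []
    cut = sim_threshold * max_sim
    ys, xs = np.nonzero(sim >= cut)
    cands = [
        MatchCandidate(x=int(x), y=int(y), similarity=float(sim[y, x]))
        for y, x in zip(ys, xs)
    ]
    cands.sort(key=lambda c: (-c.similarity, c.y, c.x))
    for c in cands:
        c.region_mean = _region_mean(frame, tmpl, c.x, c.y)
    return cands


def select_darkest(
    frame: np.ndarray, candidates: Sequence[MatchCandidate], tmpl: IrisTemplate
) -> tuple[float, float]:
    """Iris centre of the candidate whose circular region is darkest.

    Ties break toward the higher similarity.  Raises ValueError on an empty
    candidate list (match failure; the frame should be marked invalid).
    """
    if not candidates:
        raise ValueError("no match candidates: frame cannot be resolved")
    for c in candidates:
        if c.region_mean is None:
            c.region_mean = _region_mean(frame, tmpl, c.x, c.y)
    best = min(candidates, key=lambda c: (c.region_mean, -c.similarity, c.y, c.x))
    dx, dy = tmpl.centre_offset
    return (best.x + dx, best.y + dy)


def _invalid_point(rec: FrameRecord, method: str) -> TrajectoryPoint:
    return TrajectoryPoint(
        frame_index=rec.index, time_s=rec.time_s, x=None, y=None,
        valid=False, method=method,
    )


def track_video_cht_tm(
    frames: Sequence[FrameRecord], cfg: Optional[TrackerConfig] = None
) -> Trajectory:
    """Track a frame sequence with CHT_TM.

    Frame 0 runs the full CHT_ACM chain and provides the iris template;
    every later frame is resolved by masked template matching followed by
    darkest-region selection.  Frames whose best similarity falls below the
    absolute floor are flagged invalid and skipped, never dropped.
    """
    cfg = cfg or TrackerConfig()
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    first = frames[0]
    det = detect_iris_cht_acm(first.image, cfg.detection) if first.valid else None
    if det is None:
        raise TrackingError(
            "CHT_ACM failed on the first frame: no iris template can be built"
        )
    try:
        tmpl = extract_template(
            first.image, (det.cx, det.cy), det.r, margin=cfg.detection.template_margin
        )
    except NonIntactTemplateError as exc:
        raise TrackingError(str(exc)) from exc

    points = [
        TrajectoryPoint(
            frame_index=first.index, time_s=first.time_s,
            x=float(det.cx), y=float(det.cy), valid=True, method="CHT_ACM",
        )
    ]
    mc = cfg.match
    for rec in frames[1:]:
        if not rec.valid:
            points.append(_invalid_point(rec, "CHT_TM"))
            continue
        cands = match_template(
            rec.image, tmpl, use_mask=mc.use_mask,
            sim_threshold=mc.sim_threshold, method=mc.method,
        )
        if not cands or (mc.method == "ncc" and cands[0].similarity < mc.sim_floor):
            points.append(_invalid_point(rec, "CHT_TM"))
            continue
        x, y = select_darkest(rec.image, cands, tmpl)
        points.append(
            TrajectoryPoint(
                frame_index=rec.index, time_s=rec.time_s, x=float(x), y=float(y),
                valid=True, method="CHT_TM", similarity=cands[0].similarity,
            )
        )
    return Trajectory(points, method="CHT_TM")


def track_video_cht_acm(
    frames: Sequence[FrameRecord], cfg: Optional[TrackerConfig] = None
) -> Trajectory:
    """Track a frame sequence by running the full CHT_ACM chain on every frame."""
    cfg = cfg or TrackerConfig()
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    points: list[TrajectoryPoint] = []
    for rec in frames:
        det = detect_iris_cht_acm(rec.image, cfg.detection) if rec.valid else None
        if det is None:
            points.append(_invalid_point(rec, "CHT_ACM"))
        else:
            points.append(
                TrajectoryPoint(
                    frame_index=rec.index, time_s=rec.time_s,
                    x=float(det.cx), y=float(det.cy), valid=True, method="CHT_ACM",
                )
            )
    return Trajectory(points, method="CHT_ACM")


def flag_invalid_frames(
    traj: Trajectory,
    frames: Optional[Sequence[FrameRecord]] = None,
    cfg: Optional[TrackerConfig] = None,
) -> Trajectory:
    """Re-apply the validity policy to a trajectory.

    A point is invalid if it failed detection (no centre), its source frame
    is flagged invalid, or its recorded best similarity sits below the
    absolute floor.  Valid-frame centres are left untouched, mirroring the
    manual exclusion of blink frames.
    """
    cfg = cfg or TrackerConfig()
    frame_valid = {f.index: f.valid for f in frames} if frames is not None else {}
    floor = cfg.match.sim_floor
    points = []
    for p in traj.points:
        ok = p.valid and p.x is not None
        if ok and frame_valid and not frame_valid.get(p.frame_index, True):
            ok = False
        if ok and p.similarity is not None and p.similarity < floor:
            ok = False
        if ok:
            points.append(p)
        else:
            points.append(
                TrajectoryPoint(
                    frame_index=p.frame_index, time_s=p.time_s, x=None, y=None,
                    valid=False, method=p.method, similarity=p.similarity,
                )
            )
    return Trajectory(points, method=traj.method)
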