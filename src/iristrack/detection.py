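"""Per-frame iris detection: the CHT_ACM pipeline.

The chain mirrors the visible-light iris detector it implements:

1. morphological cleanup of the grayscale eye crop,
2. an active contour (morphological Chan-Vese snake) that localises the dark
   iris region and yields a refined crop,
3. histogram binarisation of the refined crop,
4. a Circular Hough Transform (CHT) over the binarised crop producing circle
   candidates, and
5. the white-pixel selection rule: a candidate is accepted as the iris only
   if fewer than 60% of the pixels inside it are binarised white.

The CHT parameter names and defaults (min_dist 40, canny_high 180,
accumulator_threshold 10, radius range 15-50 px) follow the OpenCV
``HoughCircles`` convention: ``canny_high`` is the upper hysteresis threshold
of a 3x3 Sobel L1 gradient on the 0-255 intensity scale, and
``accumulator_threshold`` is a raw vote count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import circle_perimeter
from skimage.filters import apply_hysteresis_threshold
from skimage.measure import find_contours
from skimage.morphology import thin
from skimage.segmentation import disk_level_set, morphological_chan_vese
from skimage.transform import hough_circle

from .preprocess import BinaryFrame, MorphologyConfig, binarise, clean

__all__ = [
    "ChtParams",
    "CircleCandidate",
    "Contour",
    "AcmConfig",
    "DetectionConfig",
    "IrisTemplate",
    "IrisDetection",
    "SnakeCollapseError",
    "NonIntactTemplateError",
    "canny_edges",
    "hough_circles",
    "fit_snake",
    "white_fraction",
    "select_iris_circle",
    "detect_iris_cht_acm",
    "extract_template",
    "disc_mask",
]


class SnakeCollapseError(RuntimeError):
    """The active contour degenerated to an empty (or full-frame) region."""


class NonIntactTemplateError(ValueError):
    """The detected iris circle touches the frame border; no intact template."""


@dataclass(frozen=True)
class ChtParams:
    """Circular Hough Transform parameters (OpenCV HoughCircles convention)."""

    min_dist: float = 40.0
    canny_high: float = 180.0
    accumulator_threshold: float = 10.0
    min_radius: int = 15
    max_radius: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.min_radius < self.max_radius):
            raise ValueError("need 0 < min_radius < max_radius")
        if self.min_dist <= 0:
            raise ValueError("min_dist must be positive")


@dataclass
class CircleCandidate:
    """A circle hypothesis: centre, radius, accumulator votes, white fraction."""

    cx: float
    cy: float
    r: float
    votes: float
    white_fraction: Optional[float] = None


@dataclass
class Contour:
    """Closed snake contour: ordered (x, y) points plus convergence info."""

    points: np.ndarray  # (N, 2) float, columns x, y
    converged: bool
    iterations_used: int

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1), half-open, of the contour points."""
        xs, ys = self.points[:, 0], self.points[:, 1]
        return (
            int(math.floor(xs.min())),
            int(math.floor(ys.min())),
            int(math.ceil(xs.max())) + 1,
            int(math.ceil(ys.max())) + 1,
        )


@dataclass(frozen=True)
class AcmConfig:
    """Snake settings: morphological Chan-Vese with circular initialisation."""

    max_iter: int = 200
    tol: float = 0.1  # mean boundary displacement (px/iteration) to stop
    smoothing: int = 1
    chunk: int = 10  # iterations between convergence checks


@dataclass(frozen=True)
class DetectionConfig:
    """Everything the CHT_ACM chain needs."""

    cht: ChtParams = field(default_factory=ChtParams)
    morph: MorphologyConfig = field(default_factory=MorphologyConfig)
    acm: AcmConfig = field(default_factory=AcmConfig)
    white_threshold: float = 0.60
    crop_margin: int = 20
    template_margin: int = 0


@dataclass
class IrisTemplate:
    """First-frame iris patch with a central circular mask.

    ``centre_offset`` converts a template-matching placement (patch top-left)
    to an iris centre: ``centre = placement + centre_offset``.
    """

    patch: np.ndarray
    mask: np.ndarray
    iris_radius: int
    centre_offset: tuple[float, float]


@dataclass
class IrisDetection:
    """Accepted iris circle in ROI coordinates, plus the supporting evidence."""

    cx: float
    cy: float
    r: float
    contour: Optional[Contour]
    candidate: CircleCandidate


# ---------------------------------------------------------------------------
# edges + Hough accumulator
# ---------------------------------------------------------------------------

def canny_edges(img: np.ndarray, canny_high: float = 180.0) -> np.ndarray:
    """Thin edge map from a 3x3 Sobel L1 gradient with hysteresis.

    Thresholds live on the raw 0-255 gradient scale (lower = upper / 2);
    the edge mask is thinned to single-pixel width.
    """
    f = np.asarray(img, dtype=np.float64)
    gx = ndimage.sobel(f, axis=1, mode="nearest")
    gy = ndimage.sobel(f, axis=0, mode="nearest")
    mag = np.abs(gx) + np.abs(gy)
    strong = apply_hysteresis_threshold(mag, canny_high / 2.0, canny_high)
    return thin(strong)


def _perimeter_px(r: int) -> int:
    """Number of rasterised perimeter pixels of a radius-r circle."""
    return len(circle_perimeter(r + 1, r + 1, r)[0])


def hough_circles(img: np.ndarray, params: Optional[ChtParams] = None) -> list[CircleCandidate]:
    """Circle candidates from the CHT vote accumulator, best first.

    Votes accumulate in the 3-D (cx, cy, r) space from edge pixels; local
    maxima with at least ``accumulator_threshold`` raw votes become
    candidates, and accepted centres are kept at least ``min_dist`` apart
    (greedy suppression in vote order).  Returns an empty list when the
    image has no edges (e.g. a blank frame).
    """
    params = params or ChtParams()
    edges = canny_edges(img, params.canny_high)
    if not edges.any():
        return []
    radii = np.arange(params.min_radius, params.max_radius + 1)
    acc = hough_circle(edges, radii)  # normalised per-radius accumulator
    raw: list[tuple[float, int, int, int]] = []
    for plane, r in zip(acc, radii):
        votes = plane * _perimeter_px(int(r))
        local_max = ndimage.maximum_filter(votes, size=5, mode="constant")
        ys, xs = np.nonzero((votes >= local_max) & (votes >= params.accumulator_threshold))
        for y, x in zip(ys, xs):
            raw.append((float(votes[y, x]), int(x), int(y), int(r)))
    # deterministic order: votes desc, then y, x, r
    raw.sort(key=lambda c: (-c[0], c[2], c[1], c[3]))
    kept: list[CircleCandidate] = []
    md2 = params.min_dist ** 2
    for votes, x, y, r in raw:
        if all((x - k.cx) ** 2 + (y - k.cy) ** 2 >= md2 for k in kept):
            kept.append(CircleCandidate(cx=float(x), cy=float(y), r=float(r), votes=votes))
    return kept


# ---------------------------------------------------------------------------
# active contour
# ---------------------------------------------------------------------------

def fit_snake(
    img: np.ndarray,
    init_centre: tuple[float, float],
    init_radius: float,
    cfg: Optional[AcmConfig] = None,
) -> Contour:
    """Fit a region-based snake starting from a circular level set.

    Runs morphological Chan-Vese in chunks, stopping early once the mean
    per-iteration boundary displacement (changed pixels per boundary pixel
    per iteration) drops below ``cfg.tol``.  Raises
    :class:`SnakeCollapseError` if the region vanishes or floods the frame.
    """
    cfg = cfg or AcmConfig()
    f = np.asarray(img, dtype=np.float64)
    cx, cy = init_centre
    ls = disk_level_set(f.shape, center=(cy, cx), radius=init_radius).astype(np.int8)
    if ls.sum() == 0:
        raise SnakeCollapseError("initial circle lies outside the image")
    if f.min() == f.max():
        # no image force at all: keep the regularised initial circle
        contours = find_contours(ls.astype(float), 0.5)
        pts = np.column_stack([contours[0][:, 1], contours[0][:, 0]])
        return Contour(points=pts, converged=False, iterations_used=cfg.max_iter)
    iterations = 0
    converged = False
    while iterations < cfg.max_iter:
        n_iter = min(cfg.chunk, cfg.max_iter - iterations)
        new = morphological_chan_vese(
            f, num_iter=n_iter, init_level_set=ls, smoothing=cfg.smoothing
        ).astype(np.int8)
        iterations += n_iter
        changed = int(np.count_nonzero(new != ls))
        ls = new
        area = int(ls.sum())
        if area == 0 or area == ls.size:
            raise SnakeCollapseError(
                f"contour degenerated after {iterations} iterations (area={area})"
            )
        boundary = ls.astype(bool) & ~ndimage.binary_erosion(ls.astype(bool))
        perim = max(int(boundary.sum()), 1)
        if changed / (perim * n_iter) < cfg.tol:
            converged = True
            break
    contours = find_contours(ls.astype(float), 0.5)
    if not contours:
        raise SnakeCollapseError("no contour could be traced from the level set")
    # prefer the contour whose polygon contains the init centre, else longest
    best = max(contours, key=len)
    for c in contours:
        if (
            c[:, 0].min() <= cy <= c[:, 0].max()
            and c[:, 1].min() <= cx <= c[:, 1].max()
            and len(c) >= 3
        ):
            best = c if len(c) >= len(best) or c is best else best
    pts = np.column_stack([best[:, 1], best[:, 0]])  # (row, col) -> (x, y)
    return Contour(points=pts, converged=converged, iterations_used=iterations)


# ---------------------------------------------------------------------------
# white-pixel circle selection
# ---------------------------------------------------------------------------

def disc_mask(shape: tuple[int, int], cx: float, cy: float, r: float) -> np.ndarray:
    """Boolean mask of the discrete disc {(x-cx)^2 + (y-cy)^2 <= r^2}."""
    h, w = shape
    yy, xx = np.ogrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def white_fraction(binary: BinaryFrame, cand: CircleCandidate) -> float:
    """Fraction of binarised-white pixels inside the candidate circle."""
    m = disc_mask(binary.mask.shape, cand.cx, cand.cy, cand.r)
    n = int(m.sum())
    if n == 0:
        return 1.0
    return float(np.count_nonzero(binary.mask[m]) / n)


def select_iris_circle(
    candidates: Sequence[CircleCandidate],
    binary: BinaryFrame,
    white_threshold: float = 0.60,
) -> Optional[CircleCandidate]:
    """Accept the candidate whose interior is darkest in the binarised frame.

    A circle qualifies as the iris only if its white fraction is strictly
    below ``white_threshold`` (default 60%).  Among qualifying circles, ties
    break by lowest white fraction, then highest votes, then smallest centre
    y.  Returns None when no candidate qualifies (detection failure).
    """
    scored: list[CircleCandidate] = []
    for cand in candidates:
        wf = cand.white_fraction
        if wf is None:
            wf = white_fraction(binary, cand)
            cand.white_fraction = wf
        if wf < white_threshold:
            scored.append(cand)
    if not scored:
        return None
    return min(scored, key=lambda c: (c.white_fraction, -c.votes, c.cy, c.cx))


# ---------------------------------------------------------------------------
# full CHT_ACM chain
# ---------------------------------------------------------------------------

def detect_iris_cht_acm(
    frame: np.ndarray, cfg: Optional[DetectionConfig] = None
) -> Optional[IrisDetection]:
    """Detect the iris in one grayscale eye crop (snake -> binarise -> CHT).

    Returns None on detection failure (e.g. a blink frame); the caller marks
    the frame invalid rather than aborting the run.
    """
    cfg = cfg or DetectionConfig()
    img = np.asarray(frame)
    pre = clean(img, cfg.morph)

    # circular snake initialisation: best raw CHT candidate if available
    prior = hough_circles(pre, cfg.cht)
    if prior:
        init_centre = (prior[0].cx, prior[0].cy)
        init_radius = prior[0].r
    else:
        init_centre = (img.shape[1] / 2.0, img.shape[0] / 2.0)
        init_radius = 0.4 * min(img.shape)
    try:
        contour = fit_snake(pre, init_centre, init_radius, cfg.acm)
    except SnakeCollapseError:
        return None

    x0, y0, x1, y1 = contour.bounding_box()
    m = cfg.crop_margin
    x0 = max(0, x0 - m)
    y0 = max(0, y0 - m)
    x1 = min(img.shape[1], x1 + m)
    y1 = min(img.shape[0], y1 + m)
    if x1 - x0 < 2 or y1 - y0 < 2:
        return None
    crop = pre[y0:y1, x0:x1]

    binary = binarise(crop)
    if binary.degenerate:
        return None
    candidates = hough_circles(binary.mask, cfg.cht)
    for cand in candidates:
        cand.white_fraction = white_fraction(binary, cand)
    best = select_iris_circle(candidates, binary, cfg.white_threshold)
    if best is None:
        return None
    mapped = replace(best, cx=best.cx + x0, cy=best.cy + y0)
    return IrisDetection(
        cx=mapped.cx, cy=mapped.cy, r=mapped.r, contour=contour, candidate=mapped
    )


def extract_template(
    frame: np.ndarray,
    centre: tuple[float, float],
    radius: float,
    margin: int = 0,
) -> IrisTemplate:
    """Cut the square iris patch (side 2r + 2*margin) with a central disc mask.

    The circle must lie fully inside the frame — an intact iris — otherwise
    :class:`NonIntactTemplateError` is raised.
    """
    img = np.asarray(frame)
    cx, cy = int(round(centre[0])), int(round(centre[1]))
    r = int(round(radius))
    if r <= 0:
        raise ValueError("radius must be positive")
    half = r + margin
    x0, y0 = cx - half, cy - half
    x1, y1 = cx + half, cy + half
    h, w = img.shape[:2]
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise NonIntactTemplateError(
            f"circle (cx={cx}, cy={cy}, r={r}) + margin {margin} exceeds the "
            f"{w}x{h} frame; cannot build an intact template"
        )
    patch = img[y0:y1, x0:x1].copy()
    side = 2 * half
    mask = disc_mask((side, side), half, half, r)
    return IrisTemplate(
        patch=patch,
        mask=mask,
        iris_radius=r,
        centre_offset=(side / 2.0, side / 2.0),
    )
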