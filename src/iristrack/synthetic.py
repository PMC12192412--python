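"""Synthetic eye-video generator with exact ground truth.

Renders a stylised visible-light eye crop — light sclera, darker iris disc
with a still darker pupil, skin above and below the palpebral aperture,
partial eyelid occlusion, specular glints, eyelash strokes, blinks, and
additive sensor noise — moving along the four stimulus task trajectories
(vertical, horizontal, circular, fixation) at 1 s or 5 s duration.

Every stochastic element derives from ``SceneConfig.seed``, so identical
configurations render bit-identical videos.  The recorded ground truth is
the exact sub-pixel centre used to rasterise the iris disc.

The upper/lower lids translate vertically with the iris (gain
``lid_follow``), emulating how real lids ride on vertical gaze; without
this, a fixed aperture would implausibly swallow most of the iris at the
vertical-task extremes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IRIS_TONES",
    "SceneConfig",
    "TaskSpec",
    "make_trajectory",
    "render_eye_frame",
    "render_sequence",
    "generate_video",
]

#: Mean iris intensity by colour, darkest (easiest contrast) first.
IRIS_TONES = {"brown": 60, "green": 110, "gray": 140}


@dataclass(frozen=True)
class SceneConfig:
    """Appearance and noise parameters of the rendered eye."""

    width: int = 240
    height: int = 160
    fps: float = 30.0
    iris_radius: int = 30
    iris_tone: str = "brown"
    pupil_radius_frac: float = 0.4
    pupil_intensity: int = 25
    sclera_intensity: int = 220
    skin_intensity: int = 190
    coverage_top: float = 0.15
    coverage_bottom: float = 0.10
    lid_follow: float = 1.0
    aperture_halfwidth_frac: float = 0.45
    glint_count: int = 2
    glint_radius: int = 2
    glint_intensity: int = 250
    lash_count: int = 12
    lash_intensity: int = 50
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iris_tone not in IRIS_TONES:
            raise ValueError(f"iris_tone must be one of {sorted(IRIS_TONES)}")
        if not (0 <= self.coverage_top < 1 and 0 <= self.coverage_bottom < 1):
            raise ValueError("eyelid coverage fractions must lie in [0, 1)")
        if self.iris_radius <= 0:
            raise ValueError("iris_radius must be positive")

    @property
    def eye_centre(self) -> tuple[float, float]:
        return (self.width / 2.0, self.height / 2.0)


@dataclass(frozen=True)
class TaskSpec:
    """One stimulus task: trajectory shape, duration, amplitude, motion centre."""

    task: str = "horizontal"
    duration_s: float = 5.0
    amplitude: float = 25.0
    centre: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.task not in ("vertical", "horizontal", "circular", "fixation"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.duration_s <= 0 or self.amplitude < 0:
            raise ValueError("duration must be positive and amplitude >= 0")


def make_trajectory(
    spec: TaskSpec, fps: float, scene: Optional[SceneConfig] = None
) -> np.ndarray:
    """Per-frame iris centres, shape (N, 2) with N = round(duration * fps).

    Linear tasks ramp out and back once (triangular profile: the centre
    moves ``amplitude`` pixels away and returns to the start on the final
    frame).  The circular task runs exactly one revolution, so the first and
    last points coincide.  Fixation holds the motion centre.  If ``scene``
    is given, the trajectory is validated to keep the iris at least
    2 px inside the frame.
    """
    n = max(int(round(spec.duration_s * fps)), 1)
    if spec.centre is not None:
        cx, cy = spec.centre
    elif scene is not None:
        cx, cy = scene.eye_centre
    else:
        raise ValueError("TaskSpec.centre is unset and no scene was given")
    pts = np.tile(np.array([cx, cy], dtype=np.float64), (n, 1))
    if n > 1 and spec.task != "fixation":
        p = np.arange(n) / (n - 1)
        if spec.task in ("horizontal", "vertical"):
            d = spec.amplitude * (1.0 - np.abs(2.0 * p - 1.0))
            pts[:, 0 if spec.task == "horizontal" else 1] += d
        else:  # circular
            theta = 2.0 * np.pi * p
            pts[:, 0] += spec.amplitude * np.cos(theta)
            pts[:, 1] += spec.amplitude * np.sin(theta)
    if scene is not None:
        margin = scene.iris_radius + 2
        if (
            pts[:, 0].min() < margin
            or pts[:, 0].max() > scene.width - margin
            or pts[:, 1].min() < margin
            or pts[:, 1].max() > scene.height - margin
        ):
            raise ValueError(
                "trajectory amplitude pushes the iris out of the frame"
            )
    return pts


def _static_elements(cfg: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-video elements: glint offsets and lash geometry."""
    rng = np.random.default_rng(cfg.seed)
    ang = rng.uniform(0, 2 * np.pi, cfg.glint_count)
    dist = rng.uniform(0, 0.5 * cfg.iris_radius, cfg.glint_count)
    glints = np.column_stack([dist * np.cos(ang), dist * np.sin(ang)])
    x0, _ = cfg.eye_centre
    a = cfg.aperture_halfwidth_frac * cfg.width
    lash_x = rng.uniform(x0 - 0.7 * a, x0 + 0.7 * a, cfg.lash_count)
    lash_slant = rng.uniform(-0.6, 0.6, cfg.lash_count)  # dx per pixel up
    lash_len = rng.uniform(5, 11, cfg.lash_count)
    lashes = np.column_stack([lash_x, lash_slant, lash_len])
    return glints, lashes


def _aperture(cfg: SceneConfig, centre_y: float, shape: tuple[int, int]) -> tuple[np.ndarray, float]:
    """Boolean visible-eye region and the y of the upper lid at mid-eye."""
    h, w = shape
    x0, y0 = cfg.eye_centre
    r = cfg.iris_radius
    dy = (centre_y - y0) * cfg.lid_follow
    yt = y0 - r + cfg.coverage_top * 2 * r + dy
    yb = y0 + r - cfg.coverage_bottom * 2 * r + dy
    b = max((yb - yt) / 2.0, 1e-9)
    yc = (yt + yb) / 2.0
    a = cfg.aperture_halfwidth_frac * w
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    ap = (xx - x0) ** 2 / a**2 + (yy - yc) ** 2 / b**2 <= 1.0 + 1e-9
    return ap, yt


def render_eye_frame(
    cfg: SceneConfig,
    centre: tuple[float, float],
    blink: bool = False,
    frame_index: int = 0,
) -> np.ndarray:
    """Render one grayscale eye frame with the iris at ``centre``.

    ``frame_index`` seeds the per-frame noise stream; all structural
    randomness (glint placement, lash geometry) depends only on
    ``cfg.seed``, so the scene is static across frames.
    """
    h, w = cfg.height, cfg.width
    cx, cy = centre
    img = np.full((h, w), float(cfg.skin_intensity))
    if not blink:
        ap, yt = _aperture(cfg, cy, (h, w))
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        img[ap] = cfg.sclera_intensity
        r = cfg.iris_radius
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        iris = (d2 <= r * r) & ap
        img[iris] = IRIS_TONES[cfg.iris_tone]
        pupil = (d2 <= (cfg.pupil_radius_frac * r) ** 2) & ap
        img[pupil] = cfg.pupil_intensity
        glints, lashes = _static_elements(cfg)
        for gx, gy in glints:
            gm = ((xx - (cx + gx)) ** 2 + (yy - (cy + gy)) ** 2 <= cfg.glint_radius**2) & ap
            img[gm] = cfg.glint_intensity
        # lash strokes rising from the upper lid into the skin
        for lx, slant, length in lashes:
            for k in range(int(length)):
                py = int(round(yt - 1 - k))
                px = int(round(lx + slant * k))
                if 0 <= py < h and 0 <= px < w and not ap[py, px]:
                    img[py, px] = cfg.lash_intensity
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng([cfg.seed, 1 + frame_index])
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_sequence(
    cfg: SceneConfig,
    spec: TaskSpec,
    blink_frames: Iterable[int] = (),
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render a whole task video in memory.

    Returns the frame list and a ground-truth table with columns
    ``frame_index, x, y, blink`` aligned 1:1 with the frames.
    """
    centres = make_trajectory(spec, cfg.fps, scene=cfg)
    blink_set = set(int(b) for b in blink_frames)
    frames: list[np.ndarray] = []
    rows = []
    for i, (x, y) in enumerate(centres):
        blink = i in blink_set
        frames.append(render_eye_frame(cfg, (x, y), blink=blink, frame_index=i))
        rows.append({"frame_index": i, "x": x, "y": y, "blink": int(blink)})
    return frames, pd.DataFrame(rows)


def generate_video(
    cfg: SceneConfig,
    spec: TaskSpec,
    blink_frames: Iterable[int] = (),
    out_dir: str | Path = ".",
) -> tuple[Path, Path]:
    """Write per-frame PNGs, ``truth.csv`` and the echoed scene YAML.

    Returns ``(frames_dir, truth_csv)``.  The truth table indexes frames of
    the full-rate video, so sampling every k-th frame downstream pairs rows
    by ``frame_index``.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    frames_dir = out / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    frames, truth = render_sequence(cfg, spec, blink_frames)
    for i, img in enumerate(frames):
        iio.imwrite(frames_dir / f"frame_{i:06d}.png", img)
    truth_csv = out / "truth.csv"
    with open(truth_csv, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# seed={cfg.seed}\n")
        truth.to_csv(fh, index=False, lineterminator="\n")
    scene_yaml = out / "scene.yaml"
    payload = {"scene": dataclasses.asdict(cfg), "task": dataclasses.asdict(spec)}
    scene_yaml.write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")
    return frames_dir, truth_csv
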