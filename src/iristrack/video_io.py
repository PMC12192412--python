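"""Frame extraction, grayscale conversion, ROI cropping and trajectory CSV I/O.

All downstream coordinates are expressed relative to the top-left corner of
the cropped eye region of interest (ROI): origin ``(0, 0)``, x rightward,
y downward, 0-based.  Centres are stored as floats even when a detector
returns integer pixels, because manual ground truth is typically annotated
at half-pixel precision.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "RoiSpec",
    "FrameRecord",
    "TrajectoryPoint",
    "Trajectory",
    "sampled_indices",
    "to_grayscale",
    "extract_frames",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "read_truth_csv",
]

#: ITU-R BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Default frame-sampling interval: every 10th frame of a 30 fps recording,
#: i.e. an effective 3 Hz analysis rate.
DEFAULT_SAMPLING_INTERVAL = 10

_FRAME_EXTENSIONS = {".png", ".bmp", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class RoiSpec:
    """Fixed eye-region crop in source-frame pixels (top-left + size)."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI width and height must be positive")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI origin must be non-negative")

    def crop(self, image: np.ndarray) -> np.ndarray:
        """Crop ``image`` (2-D or 3-D) to this ROI; the crop must fit inside."""
        h, w = image.shape[:2]
        if self.x0 + self.width > w or self.y0 + self.height > h:
            raise ValueError(
                f"ROI {self} does not fit inside a {w}x{h} frame"
            )
        return image[self.y0 : self.y0 + self.height, self.x0 : self.x0 + self.width]

    @classmethod
    def parse(cls, text: str) -> "RoiSpec":
        """Parse ``"x0,y0,width,height"``."""
        parts = [int(p) for p in text.split(",")]
        if len(parts) != 4:
            raise ValueError("ROI spec must be 'x0,y0,width,height'")
        return cls(*parts)


@dataclass
class FrameRecord:
    """One sampled, cropped, grayscale frame of a sequence."""

    index: int
    time_s: float
    image: np.ndarray
    valid: bool = True


@dataclass(frozen=True)
class TrajectoryPoint:
    """Iris-centre estimate for one sampled frame (``x``/``y`` None if invalid)."""

    frame_index: int
    time_s: float
    x: Optional[float]
    y: Optional[float]
    valid: bool
    method: Optional[str] = None
    similarity: Optional[float] = None


@dataclass
class Trajectory:
    """Per-sampled-frame iris centres with validity flags."""

    points: list[TrajectoryPoint] = field(default_factory=list)
    method: Optional[str] = None

    def __post_init__(self) -> None:
        idx = [p.frame_index for p in self.points]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("trajectory frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[TrajectoryPoint]:
        return iter(self.points)

    @property
    def valid_points(self) -> list[TrajectoryPoint]:
        return [p for p in self.points if p.valid]

    def centres(self) -> dict[int, tuple[float, float]]:
        """Map frame index -> (x, y) over valid points."""
        return {p.frame_index: (p.x, p.y) for p in self.points if p.valid}


def sampled_indices(n_frames: int, interval: int) -> list[int]:
    """Frame indices retained when sampling every ``interval`` frames from 0.

    Count is ``floor((n_frames - 1) / interval) + 1`` for any non-empty video.
    """
    if interval < 1:
        raise ValueError("sampling interval must be >= 1")
    if n_frames <= 0:
        return []
    return list(range(0, n_frames, interval))


def to_grayscale(color_image: np.ndarray) -> np.ndarray:
    """Convert a 3-channel RGB raster in [0, 255] to grayscale (BT.601 luma)."""
    img = np.asarray(color_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected a 3-channel image, got shape {img.shape}")
    w = np.asarray(LUMA_WEIGHTS, dtype=np.float64)
    luma = img.astype(np.float64) @ w
    return np.clip(np.rint(luma), 0, 255).astype(np.uint8)


def _as_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img.astype(np.uint8, copy=False)
    if img.ndim == 3 and img.shape[2] >= 3:
        return to_grayscale(img[:, :, :3])
    if img.ndim == 3 and img.shape[2] == 1:
        return img[:, :, 0].astype(np.uint8, copy=False)
    raise ValueError(f"unsupported image shape {img.shape}")


def _iter_source_frames(path: Path) -> Iterator[np.ndarray]:
    """Yield raw frames from a frame directory or a video container."""
    import imageio.v3 as iio

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS
        )
        if not files:
            raise IOError(f"no image frames found in directory {path}")
        for f in files:
            yield iio.imread(f)
    elif path.is_file():
        try:
            for frame in iio.imiter(path):
                yield frame
        except Exception as exc:  # no decoding backend, corrupt file, ...
            raise IOError(f"cannot read video {path}: {exc}") from exc
    else:
        raise IOError(f"no such file or directory: {path}")


def extract_frames(
    video_path: str | Path,
    sampling_interval: int = DEFAULT_SAMPLING_INTERVAL,
    roi: Optional[RoiSpec] = None,
    fps: float = 30.0,
) -> list[FrameRecord]:
    """Read frames 0, k, 2k, ... from a video file or frame directory.

    Each retained frame is cropped to ``roi`` (if given) and converted to
    grayscale.  ``time_s = index / fps``.
    """
    if sampling_interval < 1:
        raise ValueError("sampling interval must be >= 1")
    path = Path(video_path)
    records: list[FrameRecord] = []
    for i, raw in enumerate(_iter_source_frames(path)):
        if i % sampling_interval != 0:
            continue
        img = np.asarray(raw)
        if roi is not None:
            img = roi.crop(img)
        records.append(
            FrameRecord(index=i, time_s=i / fps, image=_as_gray(img), valid=True)
        )
    return records


# ---------------------------------------------------------------------------
# trajectory CSV  (schema: frame_index,time_s,x,y,valid ; invalid rows have
# empty x and y fields; comma-separated, UTF-8, '.' decimal, LF endings)
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    return repr(float(v))


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    if len(traj) == 0:
        raise ValueError("refusing to write an empty trajectory")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["frame_index", "time_s", "x", "y", "valid"])
        for p in traj:
            if p.valid:
                w.writerow([p.frame_index, _fmt(p.time_s), _fmt(p.x), _fmt(p.y), 1])
            else:
                w.writerow([p.frame_index, _fmt(p.time_s), "", "", 0])


def read_trajectory_csv(path: str | Path) -> Trajectory:
    points: list[TrajectoryPoint] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            valid = bool(int(row["valid"]))
            points.append(
                TrajectoryPoint(
                    frame_index=int(row["frame_index"]),
                    time_s=float(row["time_s"]),
                    x=float(row["x"]) if valid else None,
                    y=float(row["y"]) if valid else None,
                    valid=valid,
                )
            )
    return Trajectory(points)


def read_truth_csv(path: str | Path, fps: float = 30.0) -> Trajectory:
    """Read a ground-truth CSV (``frame_index,x,y,blink``) as a Trajectory.

    Blink frames become invalid points, mirroring the manual invalidation of
    frames in which the subject was blinking.  Lines starting with ``#``
    (metadata such as the generator seed) are skipped.
    """
    points: list[TrajectoryPoint] = []
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(rows)
    for row in reader:
        blink = bool(int(row["blink"]))
        idx = int(row["frame_index"])
        points.append(
            TrajectoryPoint(
                frame_index=idx,
                time_s=idx / fps,
                x=None if blink else float(row["x"]),
                y=None if blink else float(row["y"]),
                valid=not blink,
            )
        )
    return Trajectory(points)
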