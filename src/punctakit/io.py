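"""Image, table and configuration I/O.

Conventions used throughout the package:

* Images are grayscale stacks with axis order ``(frame, row, column)``;
  row = y increasing downward, column = x increasing rightward.
* Pixel centers sit at integer coordinates, 0-based.
* Tables carry physical coordinates (µm) with pixel columns alongside, so
  the µm/pixel calibration is always explicit.
* CSV is the only tabular interchange format.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Type

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ValidationError

logger = logging.getLogger("punctakit")

__all__ = [
    "ImageStack",
    "CircleRoi",
    "PolygonRoi",
    "PolylineRoi",
    "RoiSet",
    "UnsupportedFormatError",
    "read_stack",
    "write_stack",
    "load_config",
    "save_config",
    "write_table",
    "read_table",
    "TRAJECTORY_COLUMNS",
    "MSD_COLUMNS",
    "SNR_COLUMNS",
    "FRAP_COLUMNS",
]


class UnsupportedFormatError(ValueError):
    """Raised when an input file is not a grayscale unsigned-integer TIFF."""


@dataclass
class ImageStack:
    """An ordered stack of 2D grayscale frames with physical calibration.

    Parameters
    ----------
    frames : ndarray, shape (T, rows, cols)
        Non-negative pixel intensities.
    pixel_size : float
        Lateral calibration in µm/pixel.
    frame_interval : float
        Time between frames in seconds.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float = 0.2

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None, ...]
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 2D or 3D, got ndim={self.frames.ndim}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_frames > 1 and self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive for multi-frame stacks")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame(self, i: int) -> np.ndarray:
        return self.frames[i]

    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame index × interval)."""
        return np.arange(self.n_frames) * self.frame_interval


# ---------------------------------------------------------------------------
# Regions of interest
# ---------------------------------------------------------------------------


@dataclass
class CircleRoi:
    """Circular region: center (x, y) and radius, in pixel units."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("circle radius must be positive")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        cx, cy = self.center
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.radius**2

    def to_dict(self) -> dict:
        return {"type": "circle", "center": list(self.center), "radius": self.radius}


@dataclass
class PolygonRoi:
    """Polygonal region: vertex list [(x, y), ...] in pixel units."""

    vertices: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        from skimage.draw import polygon2mask

        # polygon2mask expects (row, col) = (y, x) vertex order
        pts = np.array([(y, x) for x, y in self.vertices])
        return polygon2mask(shape, pts)

    def to_dict(self) -> dict:
        return {"type": "polygon", "vertices": [list(v) for v in self.vertices]}


@dataclass
class PolylineRoi:
    """Open polyline for intensity profiles: points [(x, y), ...] in pixels."""

    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("polyline needs at least 2 points")

    def to_dict(self) -> dict:
        return {"type": "polyline", "points": [list(p) for p in self.points]}


_ROI_TYPES = {"circle": CircleRoi, "polygon": PolygonRoi, "polyline": PolylineRoi}


@dataclass
class RoiSet:
    """Named collection of regions of interest."""

    rois: dict[str, CircleRoi | PolygonRoi | PolylineRoi] = field(default_factory=dict)

    def __getitem__(self, name: str):
        return self.rois[name]

    def __setitem__(self, name: str, roi) -> None:
        self.rois[name] = roi

    def __contains__(self, name: str) -> bool:
        return name in self.rois

    def names(self) -> list[str]:
        return sorted(self.rois)

    def save(self, path: str | Path) -> None:
        payload = {name: roi.to_dict() for name, roi in sorted(self.rois.items())}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RoiSet":
        payload = json.loads(Path(path).read_text())
        rois = {}
        for name, d in payload.items():
            kind = d.get("type")
            if kind == "circle":
                rois[name] = CircleRoi(tuple(d["center"]), d["radius"])
            elif kind == "polygon":
                rois[name] = PolygonRoi([tuple(v) for v in d["vertices"]])
            elif kind == "polyline":
                rois[name] = PolylineRoi([tuple(p) for p in d["points"]])
            else:
                raise ValueError(f"unknown ROI type {kind!r} for {name!r}")
        return cls(rois)


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------


def read_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float = 0.2,
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF into an :class:`ImageStack`.

    Calibration is attached from the arguments; a TIFF XResolution tag is
    honored when present but explicit arguments override it.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.photometric not in (
            tifffile.PHOTOMETRIC.MINISBLACK,
            tifffile.PHOTOMETRIC.MINISWHITE,
        ):
            raise UnsupportedFormatError(
                f"{path.name}: only grayscale TIFF supported, got photometric="
                f"{page.photometric.name}"
            )
        if page.dtype is None or page.dtype.kind != "u":
            raise UnsupportedFormatError(
                f"{path.name}: only 8/16-bit unsigned TIFF supported, got dtype="
                f"{page.dtype}"
            )
        data = tif.asarray()
        tag_pixel_size = None
        res = page.tags.get("XResolution")
        if res is not None:
            num, den = res.value
            if num:
                tag_pixel_size = den / num  # resolution = pixels per unit

    if data.ndim == 2:
        data = data[None, ...]
    if pixel_size is None:
        pixel_size = tag_pixel_size if tag_pixel_size else 0.1
    return ImageStack(data, pixel_size=pixel_size, frame_interval=frame_interval)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as a 16-bit multi-page TIFF.

    Intensities are rounded and clipped to [0, 65535].
    """
    data = np.clip(np.round(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
    )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

# Documented fixed headers per table kind.
TRAJECTORY_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um", "x_px", "y_px", "gap_flag"]
MSD_COLUMNS = ["lag_s", "msd_um2", "sem_um2", "n_pairs", "n_tracks"]
SNR_COLUMNS = ["punctum_id", "p_signal", "bg_mean", "bg_sd", "snr", "seed"]
FRAP_COLUMNS = ["frame", "t_s", "roi", "ref", "bg", "phase"]

_SORT_KEYS: dict[str, list[str]] = {
    "trajectory": ["track_id", "frame"],
    "msd": ["lag_s"],
    "snr": ["punctum_id"],
    "frap": ["frame"],
}


def write_table(df: pd.DataFrame, path: str | Path, kind: str | None = None) -> None:
    """Write a result table as CSV with a stable row order.

    ``kind`` selects the documented sort order (``trajectory``: track_id then
    frame; ``msd``: lag ascending; others by id/frame). Empty tables emit a
    header-only file with a warning.
    """
    if df.empty:
        warnings.warn(f"writing empty table to {path}", stacklevel=2)
    elif kind in _SORT_KEYS:
        keys = [k for k in _SORT_KEYS[kind] if k in df.columns]
        if keys:
            df = df.sort_values(keys, kind="mergesort")
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so full-precision floats survive the CSV boundary
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path, model: Type[BaseModel] | None = None):
    """Load and validate a JSON configuration file.

    Defaults are filled, unknown keys rejected, and the fully resolved
    configuration is logged. ``model`` defaults to the simulation
    configuration.
    """
    if model is None:
        from .synthetic import SimulationConfig

        model = SimulationConfig
    raw = json.loads(Path(path).read_text())
    try:
        cfg = model.model_validate(raw)
    except ValidationError as err:
        fields = "; ".join(
            f"{'.'.join(str(loc) for loc in e['loc'])}: {e['msg']}" for e in err.errors()
        )
        raise ValueError(f"invalid configuration {Path(path).name}: {fields}") from err
    logger.info("resolved config from %s: %s", path, cfg.model_dump_json())
    return cfg


def save_config(cfg: BaseModel, path: str | Path) -> None:
    Path(path).write_text(cfg.model_dump_json(indent=2))
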