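"""Signal-to-noise quantification of fluorescent puncta.

The SNR statistic is

    SNR = (max intensity within the spot region - mean background)
          / (SD of background)

with the background sampled as the union of several identically sized
circles placed at random inside the nucleus but outside every punctum.
The statistic is invariant under positive affine intensity transforms
(gain and offset cancel), which the tests assert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .io import CircleRoi, ImageStack, PolygonRoi, PolylineRoi

__all__ = ["SNRResult", "measure_snr", "line_profile", "ros_percent_change", "snr_cohort_summary"]


@dataclass
class SNRResult:
    """Per-punctum SNR with the background statistics behind it."""

    p_signal: float
    background_mean: float
    background_sd: float
    snr: float
    n_background_circles: int
    seed: int


def _region_mask(region, shape) -> np.ndarray:
    if isinstance(region, np.ndarray):
        return region.astype(bool)
    return region.mask(shape)


def measure_snr(
    image: np.ndarray | ImageStack,
    spot_region,
    nucleus_mask,
    spot_exclusion_masks: list | None = None,
    n_circles: int = 10,
    circle_radius: float = 3.0,
    seed: int = 0,
    max_attempts_per_circle: int = 1000,
) -> SNRResult:
    """Measure the SNR of one punctum.

    Background pixels are the union of ``n_circles`` non-overlapping
    circles of ``circle_radius`` px, rejection-sampled (seeded) fully
    inside the nucleus and outside every spot-exclusion mask. The signal
    is the raw maximum inside ``spot_region`` (no smoothing) minus the
    background mean, divided by the background SD.
    """
    if isinstance(image, ImageStack):
        image = image.frame(0)
    image = np.asarray(image, dtype=float)
    shape = image.shape
    spot_mask = _region_mask(spot_region, shape)
    if not spot_mask.any():
        raise ValueError("spot region contains no pixels")
    nucleus = _region_mask(nucleus_mask, shape)
    exclusion = np.zeros(shape, bool)
    for m in spot_exclusion_masks or []:
        exclusion |= _region_mask(m, shape)
    exclusion |= spot_mask

    # centers must keep the whole circle inside the nucleus and clear of
    # all exclusions: erode the allowed region by the circle radius
    r_int = max(1, int(np.ceil(circle_radius)))
    selem = CircleRoi((r_int, r_int), circle_radius).mask((2 * r_int + 1, 2 * r_int + 1))
    allowed = ndi.binary_erosion(nucleus & ~exclusion, structure=selem)
    allowed_idx = np.argwhere(allowed)
    if len(allowed_idx) == 0:
        raise ValueError(
            "no admissible background-circle centers; use fewer or smaller circles"
        )

    rng = np.random.default_rng(seed)
    centers: list[tuple[int, int]] = []
    attempts = 0
    cap = max_attempts_per_circle * n_circles
    while len(centers) < n_circles:
        if attempts >= cap:
            raise ValueError(
                f"could not place {n_circles} non-overlapping background circles "
                f"after {cap} attempts; use fewer or smaller circles"
            )
        attempts += 1
        r, c = allowed_idx[rng.integers(len(allowed_idx))]
        if all((r - r0) ** 2 + (c - c0) ** 2 > (2 * circle_radius) ** 2 for r0, c0 in centers):
            centers.append((int(r), int(c)))

    bg_mask = np.zeros(shape, bool)
    for r, c in centers:
        bg_mask |= CircleRoi((c, r), circle_radius).mask(shape)
    bg = image[bg_mask]
    bg_mean = float(bg.mean())
    bg_sd = float(bg.std(ddof=1))
    if bg_sd == 0:
        raise ValueError("background SD is zero (flat background); SNR undefined")
    p_signal = float(image[spot_mask].max()) - bg_mean
    return SNRResult(
        p_signal=p_signal,
        background_mean=bg_mean,
        background_sd=bg_sd,
        snr=p_signal / bg_sd,
        n_background_circles=n_circles,
        seed=seed,
    )


def snr_cohort_summary(results: list[SNRResult]) -> tuple[float, float]:
    """Aggregate per-punctum SNRs as (mean, SD) over puncta."""
    vals = np.array([r.snr for r in results])
    return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


def line_profile(
    images: dict[str, np.ndarray] | np.ndarray,
    polyline: PolylineRoi,
    normalize: bool = True,
) -> pd.DataFrame:
    """Sample intensity along a polyline at unit-pixel steps.

    Intensities are bilinearly interpolated; with ``normalize`` each
    channel is scaled to [0, 1] by its own maximum (a constant channel
    normalizes to 1 everywhere). Returns a table with ``distance_px`` and
    one column per channel.
    """
    if isinstance(images, np.ndarray):
        images = {"intensity": images}
    pts = np.asarray(polyline.points, float)  # (x, y)
    shape = next(iter(images.values())).shape
    for img in images.values():
        if img.shape != shape:
            raise ValueError("all channels must share the same shape")
    if (
        pts[:, 0].min() < 0
        or pts[:, 1].min() < 0
        or pts[:, 0].max() > shape[1] - 1
        or pts[:, 1].max() > shape[0] - 1
    ):
        raise ValueError("polyline extends outside the image")

    # sample positions spaced one pixel apart along the polyline
    seg = np.diff(pts, axis=0)
    seg_len = np.sqrt((seg**2).sum(axis=1))
    total = float(seg_len.sum())
    n_samples = max(2, int(np.floor(total)) + 1)
    dist = np.linspace(0.0, total, n_samples)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    xs = np.interp(dist, cum, pts[:, 0])
    ys = np.interp(dist, cum, pts[:, 1])

    out = {"distance_px": dist}
    for name, img in images.items():
        vals = ndi.map_coordinates(
            np.asarray(img, float), np.vstack([ys, xs]), order=1, mode="nearest"
        )
        if normalize:
            peak = vals.max()
            vals = vals / peak if peak > 0 else vals
        out[name] = vals
    return pd.DataFrame(out)


def ros_percent_change(series: np.ndarray) -> np.ndarray:
    """Per-frame percentage change of fluorescence relative to the first
    frame: ``100 (F_t - F_1) / F_1``; used as a photo-oxidative-stress
    readout in phototoxicity monitoring."""
    series = np.asarray(series, float)
    if series.size == 0:
        raise ValueError("empty intensity series")
    if series[0] <= 0:
        raise ValueError("first-frame intensity must be positive")
    return 100.0 * (series - series[0]) / series[0]
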