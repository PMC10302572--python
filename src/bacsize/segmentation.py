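"""Threshold-based segmentation of dark cells on a bright background.

The pipeline is deliberately classical: Gaussian smoothing, a global
Otsu threshold plus a signed, user-tunable *threshold offset* (in
intensity counts), connected components, area/intensity/border filters,
and a sub-pixel contour per component extracted by marching squares at
the effective threshold level.

The threshold offset is the package's handle on the mechanism by which
segmentation settings change measured cell size: cells are dark, the
foreground is *below* the threshold, and the offset is *added* to the
Otsu value — so a positive offset moves the detected boundary outward,
through the blurred edge and the bright halo, and enlarges every size
parameter.  A negative offset shrinks them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

__all__ = [
    "SegmentationConfig",
    "CellRegion",
    "SegmentationError",
    "otsu_threshold",
    "segment",
    "sweep_offsets",
]


class SegmentationError(ValueError):
    """Raised for invalid segmentation inputs or configuration."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable segmentation parameters.

    ``threshold_offset`` is in intensity counts, added to the Otsu value
    (positive offsets enlarge dark cells).  Area bounds are in µm² and
    applied to the pixel-count area of each component; the intensity
    filter bounds apply to a component's mean raw intensity.
    """

    threshold_offset: float = 0.0
    min_area_um2: float = 0.2
    max_area_um2: float = 25.0
    min_mean_intensity: float | None = None
    max_mean_intensity: float | None = None
    exclude_border: bool = True
    smoothing_sigma_px: float = 1.0

    def __post_init__(self) -> None:
        if not self.min_area_um2 < self.max_area_um2:
            raise SegmentationError("min_area_um2 must be < max_area_um2")
        if self.smoothing_sigma_px < 0:
            raise SegmentationError("smoothing_sigma_px must be >= 0")


@dataclass(frozen=True)
class CellRegion:
    """One segmented cell: pixel support plus a sub-pixel boundary polygon.

    ``mask`` is cropped to ``bbox`` = (row0, col0, row1, col1) in pixel
    coordinates; ``contour_um`` is a closed, simple polygon (n, 2) of
    (x, y) in µm, extracted at the effective threshold level.
    """

    label_id: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    contour_um: np.ndarray
    mean_intensity: float
    area_px: int
    pixel_size_um: float


def otsu_threshold(raster: np.ndarray, nbins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance (Otsu).

    Integer rasters are binned exactly at their integer values; float
    rasters are binned into ``nbins`` equal-width bins over their range.
    Ties are broken toward the lowest threshold.  A constant raster has
    no two classes to separate and raises :class:`SegmentationError`.
    """
    values = np.asarray(raster).ravel()
    if values.size == 0:
        raise SegmentationError("empty raster")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise SegmentationError("constant raster has no threshold")
    if np.issubdtype(values.dtype, np.integer):
        lo, hi = int(vmin), int(vmax)
        centers = np.arange(lo, hi + 1, dtype=float)
        counts = np.bincount((values - lo).astype(np.int64), minlength=hi - lo + 1)
    else:
        counts, edges = np.histogram(values, bins=nbins, range=(vmin, vmax))
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = counts.astype(np.int64)
    w = counts.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b, nan=-1.0, posinf=-1.0, neginf=-1.0)
    return float(centers[int(np.argmax(sigma_b))])


def _region_contour(
    smoothed: np.ndarray,
    labels: np.ndarray,
    label_id: int,
    bbox: tuple[int, int, int, int],
    level: float,
) -> np.ndarray | None:
    """Closed marching-squares contour of one labelled component, in px coords."""
    r0, c0, r1, c1 = bbox
    pad = 2
    rr0, cc0 = max(r0 - pad, 0), max(c0 - pad, 0)
    rr1, cc1 = min(r1 + pad, smoothed.shape[0]), min(c1 + pad, smoothed.shape[1])
    crop = smoothed[rr0:rr1, cc0:cc1].copy()
    other = (labels[rr0:rr1, cc0:cc1] != label_id) & (labels[rr0:rr1, cc0:cc1] > 0)
    # erase neighbouring cells from the crop so their iso-contours cannot bleed in
    crop[other] = level + abs(level) + 1.0
    contours = measure.find_contours(crop, level=level)
    best = None
    for cont in contours:
        if not np.allclose(cont[0], cont[-1]):
            continue  # open contour clipped by the crop edge
        if best is None or len(cont) > len(best):
            best = cont
    if best is None:
        return None
    best = best + np.array([rr0, cc0], dtype=float)
    return best[:-1]  # drop the repeated closing vertex


def segment(
    raster: np.ndarray,
    pixel_size_um: float,
    config: SegmentationConfig = SegmentationConfig(),
) -> list[CellRegion]:
    """Segment dark cells in a raster; returns one :class:`CellRegion` per cell.

    An image with no foreground returns an empty list — that is a valid
    result, not an error.  A missing/invalid pixel size is an error
    because every downstream size parameter depends on it.
    """
    if pixel_size_um is None or not pixel_size_um > 0:
        raise SegmentationError("pixel_size_um must be a positive number")
    img = np.asarray(raster, dtype=float)
    if img.ndim != 2:
        raise SegmentationError("raster must be 2-D grayscale")
    smoothed = (
        ndimage.gaussian_filter(img, config.smoothing_sigma_px, mode="nearest")
        if config.smoothing_sigma_px > 0
        else img
    )
    level = otsu_threshold(smoothed) + config.threshold_offset
    fg = smoothed < level
    labels, n_labels = ndimage.label(fg)
    if n_labels == 0:
        return []
    px_area = pixel_size_um**2
    min_px = config.min_area_um2 / px_area
    max_px = config.max_area_um2 / px_area
    regions: list[CellRegion] = []
    for prop in measure.regionprops(labels, intensity_image=img):
        if not (min_px <= prop.area <= max_px):
            continue
        if (
            config.min_mean_intensity is not None
            and prop.intensity_mean < config.min_mean_intensity
        ):
            continue
        if (
            config.max_mean_intensity is not None
            and prop.intensity_mean > config.max_mean_intensity
        ):
            continue
        r0, c0, r1, c1 = prop.bbox
        if config.exclude_border and (
            r0 == 0 or c0 == 0 or r1 == labels.shape[0] or c1 == labels.shape[1]
        ):
            continue
        contour_px = _region_contour(smoothed, labels, prop.label, prop.bbox, level)
        if contour_px is None or len(contour_px) < 8:
            continue
        contour_um = contour_px[:, ::-1] * pixel_size_um  # (row, col) -> (x, y)
        regions.append(
            CellRegion(
                label_id=int(prop.label),
                mask=prop.image.copy(),
                bbox=(r0, c0, r1, c1),
                contour_um=contour_um,
                mean_intensity=float(prop.intensity_mean),
                area_px=int(prop.area),
                pixel_size_um=pixel_size_um,
            )
        )
    return regions


def sweep_offsets(
    raster: np.ndarray,
    pixel_size_um: float,
    config: SegmentationConfig,
    offsets: list[float],
    width_definition: str = "fitted",
) -> pd.DataFrame:
    """Segment + measure the same raster at each threshold offset.

    Returns one row per offset with the population mean/SD of length,
    width, area and volume — the package-level analogue of re-running a
    segmentation tool under different auto-threshold settings on the
    same images.
    """
    from . import morphometry  # deferred: morphometry consumes CellRegion

    if len(offsets) < 1:
        raise SegmentationError("need at least one offset")
    rows = []
    for off in offsets:
        cfg = SegmentationConfig(
            threshold_offset=off,
            min_area_um2=config.min_area_um2,
            max_area_um2=config.max_area_um2,
            min_mean_intensity=config.min_mean_intensity,
            max_mean_intensity=config.max_mean_intensity,
            exclude_border=config.exclude_border,
            smoothing_sigma_px=config.smoothing_sigma_px,
        )
        regions = segment(raster, pixel_size_um, cfg)
        meas = [
            m
            for m in (
                morphometry.measure_cell(r, width_definition=width_definition, cell_id=i)
                for i, r in enumerate(regions)
            )
            if not m.degenerate
        ]
        if meas:
            s = morphometry.summarize_population(meas, condition=f"offset={off:g}")
            rows.append(
                {
                    "threshold_offset": off,
                    "n": s.n,
                    "length_mean": s.length_mean,
                    "length_sd": s.length_sd,
                    "width_mean": s.width_mean,
                    "width_sd": s.width_sd,
                    "area_mean": s.area_mean,
                    "area_sd": s.area_sd,
                    "volume_mean": s.volume_mean,
                    "volume_sd": s.volume_sd,
                }
            )
        else:
            rows.append(
                {
                    "threshold_offset": off,
                    "n": 0,
                    **{
                        f"{f}_{s}": np.nan
                        for f in ("length", "width", "area", "volume")
                        for s in ("mean", "sd")
                    },
                }
            )
    return pd.DataFrame(rows)
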