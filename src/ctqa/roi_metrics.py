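"""Circular-ROI statistics and the SNR / CNR image-quality ratios.

ROIs are circles in pixel coordinates; a pixel belongs to the ROI iff its
centre lies strictly inside the circle.  The standard deviation of the air
ROI serves as the image-noise estimate in both ratios:

    SNR = |mean(tissue)| / SD(air)          tissue = mean of liver & trachea means
    CNR = |mean(liver, trachea) - mean(air)| / SD(air)
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .image import CTImage

__all__ = [
    "CircularROI",
    "ROIStats",
    "roi_stats",
    "average_repeats",
    "snr",
    "cnr",
    "scan_roi_report",
    "load_rois",
]

DEFAULT_MIN_PIXELS = 5000
TISSUE_LABELS = ("trachea", "liver", "air")


@dataclass(frozen=True)
class CircularROI:
    center: tuple[float, float]  # (x, y) pixel coordinates
    radius: float  # pixels
    tissue_label: str = "air"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"ROI radius must be positive, got {self.radius}")

    def mask(self, image: CTImage) -> np.ndarray:
        """Boolean mask of pixels whose centres lie strictly inside the circle."""
        yy, xx = np.ogrid[: image.height, : image.width]
        cx, cy = self.center
        return (xx - cx) ** 2 + (yy - cy) ** 2 < self.radius**2


@dataclass
class ROIStats:
    mean_hu: float
    sd_hu: float  # population SD; represents image noise
    n_pixels: int
    tissue_label: str


def roi_stats(
    image: CTImage,
    roi: CircularROI,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> ROIStats:
    """Mean and population SD of HU over the pixels enclosed by a circle.

    Raises ``ValueError`` when the circle extends beyond the image or
    encloses fewer than ``min_pixels`` pixel centres.
    """
    cx, cy = roi.center
    r = roi.radius
    if cx - r < -0.5 or cy - r < -0.5 or cx + r > image.width - 0.5 or cy + r > image.height - 0.5:
        raise ValueError(
            f"ROI (center=({cx}, {cy}), radius={r}) extends beyond the "
            f"{image.width}x{image.height} image"
        )
    mask = roi.mask(image)
    n = int(mask.sum())
    if n < min_pixels:
        raise ValueError(
            f"ROI encloses {n} pixels, below the minimum allowed area of {min_pixels} pixels"
        )
    values = image.pixels[mask].astype(float)
    return ROIStats(
        mean_hu=float(values.mean()),
        sd_hu=float(values.std()),  # population SD (ddof=0)
        n_pixels=n,
        tissue_label=roi.tissue_label,
    )


def average_repeats(stats: Sequence[ROIStats]) -> ROIStats:
    """Average repeated ROI measurements of one tissue.

    Means and SDs are averaged arithmetically across repeats; pixel counts
    are summed for reporting.
    """
    if not stats:
        raise ValueError("need at least one ROI measurement")
    labels = {s.tissue_label for s in stats}
    if len(labels) > 1:
        raise ValueError(f"mixed tissue labels in repeats: {sorted(labels)}")
    return ROIStats(
        mean_hu=float(np.mean([s.mean_hu for s in stats])),
        sd_hu=float(np.mean([s.sd_hu for s in stats])),
        n_pixels=int(sum(s.n_pixels for s in stats)),
        tissue_label=stats[0].tissue_label,
    )


def snr(mean_tissue: float, sd_air: float) -> float:
    """Signal-to-noise ratio: |mean tissue HU| / air SD (magnitude convention)."""
    if sd_air <= 0:
        raise ZeroDivisionError("SNR undefined: air ROI standard deviation is zero")
    return abs(mean_tissue) / sd_air


def cnr(mean_liver: float, mean_trachea: float, mean_air: float, sd_air: float) -> float:
    """Contrast-to-noise ratio: |mean(liver, trachea) - mean air| / air SD."""
    if sd_air <= 0:
        raise ZeroDivisionError("CNR undefined: air ROI standard deviation is zero")
    return abs(0.5 * (mean_liver + mean_trachea) - mean_air) / sd_air


def scan_roi_report(
    image: CTImage,
    rois: Iterable[CircularROI],
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> dict:
    """Full ROI protocol for one scan: per-tissue averaged stats, SNR and CNR.

    Repeated ROIs sharing a tissue label are averaged; the trachea, liver
    and air labels must each be present at least once.
    """
    by_tissue: dict[str, list[ROIStats]] = {}
    for roi in rois:
        by_tissue.setdefault(roi.tissue_label, []).append(
            roi_stats(image, roi, min_pixels=min_pixels)
        )
    missing = [t for t in TISSUE_LABELS if t not in by_tissue]
    if missing:
        raise ValueError(f"missing ROI tissue labels: {missing}")
    averaged = {t: average_repeats(s) for t, s in by_tissue.items()}
    mean_tissue = 0.5 * (averaged["liver"].mean_hu + averaged["trachea"].mean_hu)
    sd_air = averaged["air"].sd_hu
    return {
        "stats": averaged,
        "mean_tissue_hu": mean_tissue,
        "snr": snr(mean_tissue, sd_air),
        "cnr": cnr(
            averaged["liver"].mean_hu,
            averaged["trachea"].mean_hu,
            averaged["air"].mean_hu,
            sd_air,
        ),
    }


def load_rois(path: str | os.PathLike) -> list[CircularROI]:
    """Read ROI definitions from CSV (x, y, radius, tissue) or JSON."""
    path = os.fspath(path)
    if path.endswith(".json"):
        with open(path) as fh:
            rows: Iterable[dict] = json.load(fh)
    else:
        rows = pd.read_csv(path).to_dict("records")
    return [
        CircularROI(
            center=(float(row["x"]), float(row["y"])),
            radius=float(row["radius"]),
            tissue_label=str(row.get("tissue", "air")),
        )
        for row in rows
    ]
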