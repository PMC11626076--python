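"""Rasterize measurement lines and extract HU line density profiles.

Coordinate convention: 0-based integer pixel indices with x = column and
y = row.  Distances are physical (mm), computed per-axis from the image's
pixel spacing, so downstream edge steepness comes out in HU/mm.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .image import CTImage

__all__ = [
    "ProfileLine",
    "LineProfile",
    "rasterize_line",
    "extract_profile",
    "load_grid",
    "save_grid",
]

LEVELS = ("apical", "mid", "basal")
SIDES = ("left", "right")
LOCATIONS = ("anterior", "lateral", "posterior")


@dataclass(frozen=True)
class ProfileLine:
    """A measurement line defined by integer pixel endpoints plus labels."""

    start: tuple[int, int]
    end: tuple[int, int]
    level: str = "mid"
    side: str = "left"
    location: str = "lateral"
    replicate: int = 0
    interface_id: int = 0

    def __post_init__(self) -> None:
        if tuple(self.start) == tuple(self.end):
            raise ValueError(f"degenerate line: start == end == {self.start}")

    @property
    def slice_index(self) -> int:
        """Stack slice this line belongs to, derived from its level label."""
        try:
            return LEVELS.index(self.level)
        except ValueError:
            return 0

    def check_bounds(self, image: CTImage) -> None:
        for name, (x, y) in (("start", self.start), ("end", self.end)):
            if not image.contains(x, y):
                raise ValueError(
                    f"line {name} point ({x}, {y}) lies outside the "
                    f"{image.width}x{image.height} image"
                )


@dataclass
class LineProfile:
    """Ordered (distance-from-start [mm], HU) samples along a rasterized line."""

    distances_mm: np.ndarray
    values_hu: np.ndarray
    source_line: ProfileLine | None = None
    pixels: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.distances_mm = np.asarray(self.distances_mm, dtype=float)
        self.values_hu = np.asarray(self.values_hu, dtype=float)
        if self.distances_mm.shape != self.values_hu.shape:
            raise ValueError("distances and values must have equal length")

    def __len__(self) -> int:
        return len(self.distances_mm)

    @property
    def span_mm(self) -> float:
        return float(self.distances_mm[-1] - self.distances_mm[0]) if len(self) else 0.0

    def reversed(self) -> "LineProfile":
        """Same HU samples in reverse order, distances re-anchored at 0."""
        d = self.distances_mm
        return LineProfile(
            distances_mm=d[-1] - d[::-1],
            values_hu=self.values_hu[::-1].copy(),
            source_line=self.source_line,
            pixels=list(reversed(self.pixels)),
        )


def rasterize_line(
    start: Sequence[int], end: Sequence[int]
) -> list[tuple[int, int]]:
    """All pixels on the 8-connected Bresenham raster from start to end.

    Endpoints are included; the result has ``max(|dx|, |dy|) + 1`` pixels and
    consecutive pixels differ by at most one in each coordinate.  Exact
    half-step ties are rounded toward the end point.  A degenerate
    ``start == end`` call returns the single pixel.
    """
    x0, y0 = int(start[0]), int(start[1])
    x1, y1 = int(end[0]), int(end[1])
    dx, dy = abs(x1 - x0), abs(y1 - y0)
    sx = 1 if x1 >= x0 else -1
    sy = 1 if y1 >= y0 else -1
    err = dx - dy
    x, y = x0, y0
    pixels: list[tuple[int, int]] = []
    while True:
        pixels.append((x, y))
        if x == x1 and y == y1:
            break
        e2 = 2 * err
        if e2 >= -dy:  # >= : half-step ties advance, i.e. round toward end
            err -= dy
            x += sx
        if e2 <= dx:
            err += dx
            y += sy
    return pixels


def extract_profile(image: CTImage, line: ProfileLine) -> LineProfile:
    """Sample HU values along a rasterized line with physical distances.

    For each Bresenham pixel the distance is the Euclidean norm of the
    physical (mm) offset of that pixel's centre from the start pixel's
    centre; no sub-pixel interpolation is performed.
    """
    line.check_bounds(image)
    pixels = rasterize_line(line.start, line.end)
    x0, y0 = line.start
    xs = np.array([p[0] for p in pixels])
    ys = np.array([p[1] for p in pixels])
    distances = np.hypot(
        (xs - x0) * image.spacing_x, (ys - y0) * image.spacing_y
    )
    values = image.pixels[ys, xs].astype(float)
    return LineProfile(
        distances_mm=distances, values_hu=values, source_line=line, pixels=pixels
    )


_GRID_COLUMNS = ["x_begin", "y_begin", "x_end", "y_end", "level", "side", "location", "replicate"]


def load_grid(path: str | os.PathLike) -> list[ProfileLine]:
    """Read a measurement grid from CSV or JSON.

    CSV columns: x_begin, y_begin, x_end, y_end, level, side, location,
    replicate (and optionally interface_id).  JSON is a list of objects with
    the same keys.
    """
    path = os.fspath(path)
    if path.endswith(".json"):
        with open(path) as fh:
            rows: Iterable[dict] = json.load(fh)
    else:
        rows = pd.read_csv(path).to_dict("records")
    lines = []
    for i, row in enumerate(rows):
        lines.append(
            ProfileLine(
                start=(int(row["x_begin"]), int(row["y_begin"])),
                end=(int(row["x_end"]), int(row["y_end"])),
                level=str(row.get("level", "mid")),
                side=str(row.get("side", "left")),
                location=str(row.get("location", "lateral")),
                replicate=int(row.get("replicate", 0)),
                interface_id=int(row.get("interface_id", i)),
            )
        )
    return lines


def save_grid(lines: Sequence[ProfileLine], path: str | os.PathLike) -> None:
    """Write a measurement grid to CSV (the dialect `load_grid` reads)."""
    records = [
        {
            "x_begin": ln.start[0],
            "y_begin": ln.start[1],
            "x_end": ln.end[0],
            "y_end": ln.end[1],
            "level": ln.level,
            "side": ln.side,
            "location": ln.location,
            "replicate": ln.replicate,
            "interface_id": ln.interface_id,
        }
        for ln in lines
    ]
    pd.DataFrame.from_records(records).to_csv(os.fspath(path), index=False)
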