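"""Closed-form spherocylinder geometry for rod-shaped bacteria.

A rod-shaped bacterium such as *E. coli* is modelled as a spherocylinder:
a cylinder of diameter ``W`` capped by two hemispheres, with pole-to-pole
length ``L``.  Its volume is

    V = (4/3) * pi * (W/2)**3 + pi * (W/2)**2 * (L - W)

and its 2-D projection is a stadium (a rectangle with semicircular caps)
of area

    A = W * (L - W) + pi * W**2 / 4.

Two entry points exist for volume: :func:`spherocylinder_volume` applied
per cell to its own ``(L, W)``, and :func:`volume_from_summary` applied to
population means.  They differ by a Jensen gap of a few percent on real
size distributions, so they are named distinctly and never conflated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "CellShape",
    "SizeVector",
    "spherocylinder_volume",
    "projected_area",
    "volume_from_summary",
    "stadium_contour",
]


class GeometryError(ValueError):
    """Raised for dimensions outside the spherocylinder domain (L >= W > 0)."""


def _validate_dims(length_um: float, width_um: float) -> None:
    if not (width_um > 0.0):
        raise GeometryError(f"width must be positive, got {width_um!r}")
    if not (length_um >= width_um):
        # L < W is not silently swapped: it usually signals a segmentation
        # failure upstream and must surface as an error.
        raise GeometryError(
            f"length ({length_um!r}) must be >= width ({width_um!r})"
        )


def spherocylinder_volume(length_um: float, width_um: float) -> float:
    """Volume (µm³) of a spherocylinder with total length L and diameter W."""
    _validate_dims(length_um, width_um)
    r = width_um / 2.0
    return (4.0 / 3.0) * math.pi * r**3 + math.pi * r * r * (length_um - width_um)


def projected_area(length_um: float, width_um: float) -> float:
    """Area (µm²) of the stadium-shaped 2-D footprint of a spherocylinder."""
    _validate_dims(length_um, width_um)
    return width_um * (length_um - width_um) + math.pi * width_um**2 / 4.0


@dataclass(frozen=True)
class CellShape:
    """Ground-truth pose and dimensions of a single spherocylindrical cell.

    ``orientation_rad`` is normalised into [0, pi); the long axis is
    undirected so angles differing by pi are the same pose.
    """

    length_um: float
    width_um: float
    center_xy: tuple[float, float] = (0.0, 0.0)
    orientation_rad: float = 0.0

    def __post_init__(self) -> None:
        _validate_dims(self.length_um, self.width_um)
        angle = self.orientation_rad % math.pi
        object.__setattr__(self, "orientation_rad", angle)

    @property
    def volume_um3(self) -> float:
        return spherocylinder_volume(self.length_um, self.width_um)

    @property
    def area_um2(self) -> float:
        return projected_area(self.length_um, self.width_um)

    def axis_endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Endpoints of the cylinder axis (the medial segment of length L-W)."""
        half = (self.length_um - self.width_um) / 2.0
        u = np.array([math.cos(self.orientation_rad), math.sin(self.orientation_rad)])
        c = np.asarray(self.center_xy, dtype=float)
        return c - half * u, c + half * u


@dataclass(frozen=True)
class SizeVector:
    """Population-level size summary: means with SDs and sample size."""

    length_um: float
    width_um: float
    area_um2: float = math.nan
    volume_um3: float = math.nan
    length_sd: float = 0.0
    width_sd: float = 0.0
    area_sd: float = 0.0
    volume_sd: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        _validate_dims(self.length_um, self.width_um)
        for sd in (self.length_sd, self.width_sd, self.area_sd, self.volume_sd):
            if sd < 0:
                raise GeometryError(f"SD must be non-negative, got {sd!r}")
        if self.n < 1:
            raise GeometryError(f"n must be >= 1, got {self.n!r}")


def volume_from_summary(size: SizeVector) -> float:
    """Spherocylinder volume evaluated at *population-mean* length and width.

    This is the volume of the mean cell, an approximation to the mean of
    per-cell volumes (the two differ by a Jensen gap of a few percent for
    typical bacterial size distributions).
    """
    return spherocylinder_volume(size.length_um, size.width_um)


def stadium_contour(
    length_um: float,
    width_um: float,
    n_vertices: int = 200,
    center_xy: tuple[float, float] = (0.0, 0.0),
    orientation_rad: float = 0.0,
) -> np.ndarray:
    """Closed polygon approximating the stadium outline of a spherocylinder.

    Returns an (n, 2) array of (x, y) µm coordinates, counter-clockwise,
    without a repeated closing vertex.  Used as an analytic reference
    contour by the morphometry layer and its tests.
    """
    _validate_dims(length_um, width_um)
    if n_vertices < 8:
        raise GeometryError("need at least 8 vertices for a stadium contour")
    r = width_um / 2.0
    half = (length_um - width_um) / 2.0
    n_cap = max(4, n_vertices // 4)
    n_side = max(2, (n_vertices - 2 * n_cap) // 2)
    # Right cap: angle from -pi/2 to +pi/2 around (+half, 0).
    t_right = np.linspace(-math.pi / 2, math.pi / 2, n_cap)
    right = np.column_stack([half + r * np.cos(t_right), r * np.sin(t_right)])
    top = np.column_stack(
        [np.linspace(half, -half, n_side + 2)[1:-1], np.full(n_side, r)]
    )
    t_left = np.linspace(math.pi / 2, 3 * math.pi / 2, n_cap)
    left = np.column_stack([-half + r * np.cos(t_left), r * np.sin(t_left)])
    bottom = np.column_stack(
        [np.linspace(-half, half, n_side + 2)[1:-1], np.full(n_side, -r)]
    )
    poly = np.vstack([right, top, left, bottom])
    c, s = math.cos(orientation_rad), math.sin(orientation_rad)
    rot = np.array([[c, -s], [s, c]])
    return poly @ rot.T + np.asarray(center_xy, dtype=float)
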