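"""Nanotube cylindrical geometry: axis/radius fitting and surface distances.

The (n,m) roll-up vector fixes a nanotube's radius,
r = a*sqrt(n^2 + n*m + m^2)/(2*pi) with graphene lattice constant
a = 2.461 A; for the (9,4) species this is ~4.52 A.  Distances of
analyte groups to the tube are expressed in cylindrical coordinates as
radial distance minus the tube radius, so a point on the wall scores 0
and points inside score negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CylinderModel",
    "chirality_radius",
    "fit_cylinder",
    "surface_distance",
    "GRAPHENE_LATTICE_A",
]

#: Graphene lattice constant in Angstrom.
GRAPHENE_LATTICE_A = 2.461


@dataclass(frozen=True)
class CylinderModel:
    """Axis point + unit direction + wall radius of a nanotube cylinder."""

    axis_point: np.ndarray
    axis_dir: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        p = np.asarray(self.axis_point, dtype=float).reshape(3)
        d = np.asarray(self.axis_dir, dtype=float).reshape(3)
        norm = np.linalg.norm(d)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("axis direction is the zero vector")
            d = d / norm
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        object.__setattr__(self, "axis_point", p)
        object.__setattr__(self, "axis_dir", d)


def chirality_radius(n: int, m: int, a: float = GRAPHENE_LATTICE_A) -> float:
    """Closed-form nanotube radius for roll-up vector (n, m), in Angstrom."""
    if n < 0 or m < 0 or (n == 0 and m == 0):
        raise ValueError(f"nonphysical chirality ({n}, {m})")
    return a * np.sqrt(n * n + n * m + m * m) / (2.0 * np.pi)


def fit_cylinder(swcnt_coords) -> CylinderModel:
    """Fit axis and radius of a nanotube from its (unwrapped) atom coordinates.

    The axis is the principal axis (largest-variance eigenvector of the
    coordinate covariance); the radius is the mean perpendicular distance
    of atoms to that axis.  A near-spherical point cloud (no dominant
    axis) is rejected.
    """
    coords = np.asarray(swcnt_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coordinates must be (n, 3)")
    if coords.shape[0] < 10:
        raise ValueError(f"need >= 10 atoms to fit a cylinder, got {coords.shape[0]}")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    # eigh sorts ascending: last eigenvector is the candidate axis
    if evals[-1] < 2.0 * evals[-2]:
        raise ValueError(
            "degenerate point cloud: no dominant principal axis "
            f"(eigenvalues {evals})"
        )
    axis = evecs[:, -1]
    perp = centered - np.outer(centered @ axis, axis)
    radius = float(np.linalg.norm(perp, axis=1).mean())
    if radius <= 0:
        raise ValueError("all atoms lie on the axis; radius undefined")
    return CylinderModel(axis_point=centroid, axis_dir=axis, radius=radius)


def surface_distance(point, cylinder: CylinderModel):
    """Signed distance of point(s) to the cylinder wall.

    d = (perpendicular distance to the axis) - radius.  Negative inside
    the wall radius.  Accepts a single point (3,) or an array (..., 3).
    """
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if not np.isfinite(pts).all():
        raise ValueError("point coordinates must be finite")
    rel = pts - cylinder.axis_point
    along = rel @ cylinder.axis_dir
    perp = rel - np.outer(along, cylinder.axis_dir)
    d = np.linalg.norm(perp, axis=-1) - cylinder.radius
    return float(d[0]) if single else d
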