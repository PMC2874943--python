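"""Symmetry-axis detection and feature-point handling.

The eye section is approximately mirror-symmetric about the optic axis,
and the 3D model is built by revolving the section profile about that
axis.  The axis is detected by principal component analysis of the
pooled contour points: the direction is the leading eigenvector of the
point covariance, and the line is anchored at the contour centroid.

Feature points are user-supplied picks (a click list): picks close to a
contour snap to the nearest contour vertex, picks further away are kept
verbatim as repair points for locally deformed tissue.  Picks near the
axis can be projected onto it, providing the on-axis pole points the
revolved surface needs to close without cracks.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contour import ContourPolyline, pool_points
from .errors import DegenerateInputError, InvalidArgumentError


@dataclass
class SymmetryAxis:
    """An in-plane line: anchor point plus unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if norm == 0:
            raise InvalidArgumentError("axis direction must be nonzero")
        self.direction = self.direction / norm

    @property
    def angle_deg(self) -> float:
        """Axis angle in degrees, folded into [0, 180)."""
        a = np.rad2deg(np.arctan2(self.direction[1], self.direction[0]))
        return float(a % 180.0)

    def to_dict(self) -> dict:
        return {"point": self.point.tolist(),
                "direction": self.direction.tolist(),
                "angle_deg": self.angle_deg}

    @classmethod
    def from_dict(cls, d: dict) -> "SymmetryAxis":
        return cls(np.asarray(d["point"], float),
                   np.asarray(d["direction"], float))


@dataclass
class Centroid:
    """Arithmetic mean of the pooled contour points."""

    x_c: float
    y_c: float
    n_contour: int

    @property
    def point(self) -> np.ndarray:
        return np.array([self.x_c, self.y_c])


@dataclass
class FeaturePointSet:
    """Ordered feature points with per-point on-axis flags."""

    points: np.ndarray
    on_axis_flags: np.ndarray = field(default=None)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.on_axis_flags is None:
            self.on_axis_flags = np.zeros(len(self.points), dtype=bool)
        self.on_axis_flags = np.asarray(self.on_axis_flags, dtype=bool)


def centroid(contours: list[ContourPolyline]) -> Centroid:
    """Centroid of all pooled contour points."""
    pts = pool_points(contours)
    if len(pts) < 3:
        raise InvalidArgumentError("centroid needs at least 3 pooled points")
    m = pts.mean(axis=0)
    return Centroid(float(m[0]), float(m[1]), len(pts))


def pca_symmetry_axis(contours: list[ContourPolyline],
                      isotropy_ratio: float = 0.99) -> SymmetryAxis:
    """Detect the symmetry axis by PCA of the pooled contour points.

    The direction is the unit eigenvector of the 2x2 covariance with the
    largest eigenvalue; the line passes through the centroid.  When the
    two eigenvalues are nearly equal (ratio above ``isotropy_ratio``)
    the principal direction is meaningless and a
    :class:`DegenerateInputError` is raised; supply an axis hint instead.
    """
    pts = pool_points(contours)
    if len(pts) < 3:
        raise InvalidArgumentError("axis detection needs >= 3 pooled points")
    c = pts.mean(axis=0)
    centred = pts - c
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    if evals[1] <= 0:
        raise DegenerateInputError("all contour points coincide")
    if evals[0] / evals[1] > isotropy_ratio:
        raise DegenerateInputError(
            "point set is near-isotropic; PCA axis is undefined — "
            "provide an explicit axis")
    direction = evecs[:, 1]
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction  # canonical half-plane
    return SymmetryAxis(point=c, direction=direction)


def snap_feature_points(clicks: np.ndarray, contour: ContourPolyline,
                        d_max: float = 5.0) -> FeaturePointSet:
    """Snap picked points to the contour within a distance threshold.

    Each pick whose nearest contour vertex lies within ``d_max`` pixels
    is replaced by that vertex; picks further away are kept verbatim
    (they patch local deformation of the tissue outline).  Input order
    is preserved.
    """
    if d_max <= 0:
        raise InvalidArgumentError("d_max must be positive")
    if len(contour) == 0:
        raise InvalidArgumentError("contour is empty")
    clicks = np.atleast_2d(np.asarray(clicks, dtype=float))
    out = clicks.copy()
    for i, p in enumerate(clicks):
        d2 = np.einsum("ij,ij->i", contour.points - p, contour.points - p)
        j = int(np.argmin(d2))
        if d2[j] <= d_max * d_max:
            out[i] = contour.points[j]
    return FeaturePointSet(out)


def project_onto_axis(p: np.ndarray, axis: SymmetryAxis) -> np.ndarray:
    """Perpendicular foot of a point on the axis line.

    Implemented in vector form, p' = a + ((p - a) . d) d, which agrees
    with the slope-intercept construction (intersecting the axis with
    the perpendicular through p) wherever the latter is defined, and
    stays total for vertical and horizontal axes.
    """
    p = np.asarray(p, dtype=float)
    rel = p - axis.point
    return axis.point + np.dot(rel, axis.direction) * axis.direction


def project_pole_candidates(features: FeaturePointSet, axis: SymmetryAxis,
                            band: float = 15.0) -> FeaturePointSet:
    """Project near-axis feature points onto the axis.

    Points within ``band`` pixels of the axis are replaced by their
    perpendicular foot and flagged on-axis; the revolved surface uses
    these as pole vertices so it closes without cracks.
    """
    pts = features.points.copy()
    flags = features.on_axis_flags.copy()
    n = np.array([-axis.direction[1], axis.direction[0]])
    for i, p in enumerate(pts):
        if abs(np.dot(p - axis.point, n)) <= band:
            pts[i] = project_onto_axis(p, axis)
            flags[i] = True
    return FeaturePointSet(pts, flags)
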