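"""Planar contour polylines.

A contour is an ordered sequence of 2D points in pixel coordinates,
(x, y) = (column, row).  Contours are the interchange currency of the
pipeline: segmentation emits them, axis detection pools them, and the
profile/revolution stages consume them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError


@dataclass
class ContourPolyline:
    """Ordered 2D point sequence, open or closed.

    Parameters
    ----------
    points : (n, 2) float array
        Vertex coordinates (x, y) in pixels.
    closed : bool
        Whether the last vertex connects back to the first.
    name : str, optional
        Tissue label, e.g. ``"outer_eyeball"`` or ``"lens"``.
    """

    points: np.ndarray
    closed: bool = True
    name: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidArgumentError("contour points must be an (n, 2) array")

    def __len__(self) -> int:
        return len(self.points)

    def perimeter(self) -> float:
        """Sum of consecutive chord lengths.

        For a closed contour whose last point differs from its first, the
        closing segment is included, so the value is the length of the
        full closed curve.
        """
        pts = self.points
        if len(pts) < 2:
            raise InvalidArgumentError("perimeter needs at least 2 points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        if self.closed and not np.allclose(pts[0], pts[-1]):
            seg += float(np.linalg.norm(pts[-1] - pts[0]))
        return float(seg)

    def resample(self, n: int) -> "ContourPolyline":
        """Resample to n points uniformly spaced by arc length.

        Grid-based contour extraction yields vertex density that varies
        with the local edge orientation; arc-length resampling removes
        that anisotropy (it would otherwise bias point-statistics such
        as the PCA symmetry axis).
        """
        if n < 2:
            raise InvalidArgumentError("resample needs n >= 2")
        pts = self.points
        if self.closed and not np.allclose(pts[0], pts[-1]):
            pts = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        if total == 0:
            raise InvalidArgumentError("contour has zero length")
        ss = (np.linspace(0.0, total, n, endpoint=False) if self.closed
              else np.linspace(0.0, total, n))
        x = np.interp(ss, s, pts[:, 0])
        y = np.interp(ss, s, pts[:, 1])
        return ContourPolyline(np.column_stack([x, y]), closed=self.closed,
                               name=self.name)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "closed": bool(self.closed),
            "points": self.points.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ContourPolyline":
        return cls(points=np.asarray(d["points"], dtype=float),
                   closed=bool(d.get("closed", True)),
                   name=d.get("name", ""))


def pool_points(contours: list[ContourPolyline]) -> np.ndarray:
    """Stack all contour vertices into a single (N, 2) array."""
    if not contours:
        raise InvalidArgumentError("no contours to pool")
    return np.vstack([c.points for c in contours])
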