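"""Surfaces of revolution and physical scaling.

A section profile (u, r) in the axis frame is revolved about the
symmetry axis into a triangulated surface.  Open pole-to-pole profiles
(r = 0 at both ends) become closed genus-0 surfaces with the poles
collapsed to single shared vertices — this is what prevents cracks
along the axis.  Closed annular profiles (iris) become torus-like
surfaces.

The mesh is built in pixel units and scaled to millimetres with a zoom
ratio R = d_perimeter / l_real, where d_perimeter is the equatorial
circumference of the segmented outer eyeball contour in pixels and
l_real the reference physical circumference (default 74.5 mm, the
normal equatorial circumference of an adult eye).
"""
from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import trimesh

from .contour import ContourPolyline
from .errors import InvalidArgumentError, InvalidStateError
from .symmetry import SymmetryAxis

DEFAULT_EYE_CIRCUMFERENCE_MM = 74.5


@dataclass
class RevolvedMesh:
    """Triangulated surface of revolution.

    ``axis_origin``/``axis_direction`` record the 3D revolution axis;
    ``units`` is ``"px"`` for meshes straight out of the image pipeline
    and ``"mm"`` after physical scaling.
    """

    vertices: np.ndarray       # (V, 3)
    faces: np.ndarray          # (F, 3) int
    units: str = "px"
    axis_origin: np.ndarray = None
    axis_direction: np.ndarray = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise InvalidArgumentError("face indices out of range")

    def as_trimesh(self) -> trimesh.Trimesh:
        """View as a :class:`trimesh.Trimesh` without vertex merging."""
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def edge_count(self) -> int:
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        return len(np.unique(e, axis=0))

    def euler_characteristic(self) -> int:
        return len(self.vertices) - self.edge_count() + len(self.faces)

    def total_area(self) -> float:
        return float(self.as_trimesh().area)


def _axis_basis(axis: SymmetryAxis):
    """Embed the 2D slice plane as the 3D (X, Y) plane.

    The 2D axis direction becomes d3 in-plane, the in-plane normal e1
    carries the theta = 0 ring (so that ring reproduces the input
    profile), and Z carries the out-of-plane component.
    """
    d = axis.direction
    origin = np.array([axis.point[0], axis.point[1], 0.0])
    d3 = np.array([d[0], d[1], 0.0])
    e1 = np.array([-d[1], d[0], 0.0])
    e2 = np.array([0.0, 0.0, 1.0])
    return origin, d3, e1, e2


def revolve_profile(profile_samples: np.ndarray, axis: SymmetryAxis,
                    n_theta: int = 64, closed: bool = False,
                    units: str = "px") -> RevolvedMesh:
    """Revolve (u, r) profile samples about the axis.

    Open profiles must start and end on the axis (r = 0) with strictly
    positive interior radii; the two poles become single vertices, so a
    profile of m samples yields (m - 2) * n_theta + 2 vertices.  Closed
    profiles yield one ring per sample and a toroidal surface.  Faces
    are wound consistently outward.
    """
    samples = np.asarray(profile_samples, dtype=float)
    if n_theta < 3:
        raise InvalidArgumentError("n_theta must be >= 3")
    if samples.ndim != 2 or samples.shape[1] != 2 or len(samples) < 3:
        raise InvalidArgumentError("need >= 3 (u, r) profile samples")
    origin, d3, e1, e2 = _axis_basis(axis)
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    ct, st = np.cos(theta), np.sin(theta)

    def ring(u, r):
        return origin + u * d3 + r * (np.outer(ct, e1) + np.outer(st, e2))

    if not closed:
        u, r = samples[:, 0], samples[:, 1]
        if abs(r[0]) > 1e-9 or abs(r[-1]) > 1e-9:
            raise InvalidArgumentError(
                "open profile must start and end on the axis (r = 0); "
                "without pole points the revolved surface has cracks")
        if np.any(r[1:-1] <= 0):
            raise InvalidArgumentError("interior profile radii must be > 0")
        m = len(samples)
        verts = [origin + u[0] * d3]
        for i in range(1, m - 1):
            verts.append(ring(u[i], r[i]))
        verts.append(origin + u[-1] * d3)
        vertices = np.vstack(verts)
        p0, p1 = 0, (m - 2) * n_theta + 1

        def rid(i, j):  # ring i (1..m-2), slot j
            return 1 + (i - 1) * n_theta + (j % n_theta)

        faces = []
        for j in range(n_theta):
            faces.append([p0, rid(1, j + 1), rid(1, j)])
        for i in range(1, m - 2):
            for j in range(n_theta):
                a, a1 = rid(i, j), rid(i, j + 1)
                b, b1 = rid(i + 1, j), rid(i + 1, j + 1)
                faces.append([a, b1, b])
                faces.append([a, a1, b1])
        for j in range(n_theta):
            faces.append([p1, rid(m - 2, j), rid(m - 2, j + 1)])
    else:
        if np.allclose(samples[0], samples[-1]):
            samples = samples[:-1]
        if np.any(samples[:, 1] <= 0):
            raise InvalidArgumentError(
                "closed profile radii must be strictly positive")
        # orient the loop clockwise in the (u, r) plane so the shared
        # quad pattern winds the toroidal surface outward
        uu, rr = samples[:, 0], samples[:, 1]
        loop_area = 0.5 * np.sum(uu * np.roll(rr, -1) - np.roll(uu, -1) * rr)
        if loop_area > 0:
            samples = samples[::-1]
        m = len(samples)
        vertices = np.vstack([ring(u, r) for u, r in samples])

        def vid(i, j):
            return (i % m) * n_theta + (j % n_theta)

        faces = []
        for i in range(m):
            for j in range(n_theta):
                a, a1 = vid(i, j), vid(i, j + 1)
                b, b1 = vid(i + 1, j), vid(i + 1, j + 1)
                faces.append([a, b1, b])
                faces.append([a, a1, b1])
    mesh = RevolvedMesh(vertices=np.asarray(vertices),
                        faces=np.asarray(faces, dtype=np.int64),
                        units=units, axis_origin=origin, axis_direction=d3)
    return mesh


def contour_perimeter(contour: ContourPolyline) -> float:
    """Perimeter of a contour polyline in pixels.

    Sum of consecutive chord lengths; the closing chord is included for
    contours flagged closed, since an equatorial circumference is a
    closed curve.
    """
    return contour.perimeter()


@dataclass
class ScaleInfo:
    """Pixel-to-millimetre zoom ratio derived from a circumference."""

    d_perimeter: float   # equatorial circumference, pixels
    l_real: float        # reference physical circumference, mm
    ratio: float         # pixel / mm

    @property
    def ratio_display(self) -> float:
        """Ratio rounded to 0.1 for reporting."""
        return round(self.ratio, 1)

    def to_dict(self) -> dict:
        return {"d_perimeter_px": self.d_perimeter, "l_real_mm": self.l_real,
                "ratio_px_per_mm": self.ratio,
                "ratio_display": self.ratio_display}


def zoom_ratio(d_perimeter: float,
               l_real: float = DEFAULT_EYE_CIRCUMFERENCE_MM) -> ScaleInfo:
    """Zoom ratio R = d_perimeter / l_real in pixel/mm."""
    if d_perimeter <= 0 or l_real <= 0:
        raise InvalidArgumentError("perimeter and reference must be positive")
    return ScaleInfo(d_perimeter=float(d_perimeter), l_real=float(l_real),
                     ratio=float(d_perimeter) / float(l_real))


def scale_mesh(mesh: RevolvedMesh, scale: ScaleInfo) -> RevolvedMesh:
    """Convert a pixel-unit mesh to millimetres by dividing by the ratio."""
    if mesh.units != "px":
        raise InvalidStateError("mesh is already in physical units")
    return replace(mesh, vertices=mesh.vertices / scale.ratio, units="mm",
                   faces=mesh.faces)


_FORMATS = {"obj", "stl", "ply"}


def write_mesh(mesh: RevolvedMesh, path: str, fmt: str | None = None) -> None:
    """Write the mesh as Wavefront OBJ, binary STL or ASCII PLY.

    OBJ preserves vertex order, so re-reading round-trips vertices.
    The format defaults to the file extension.
    """
    fmt = (fmt or str(path).rsplit(".", 1)[-1]).lower()
    if fmt not in _FORMATS:
        raise InvalidArgumentError(f"unknown mesh format {fmt!r}")
    tm = mesh.as_trimesh()
    if fmt == "ply":
        data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
    elif fmt == "stl":
        data = trimesh.exchange.stl.export_stl(tm)
    else:
        data = trimesh.exchange.obj.export_obj(tm).encode()
    with open(path, "wb") as fh:
        fh.write(data)


def read_mesh(path: str) -> RevolvedMesh:
    """Read a surface mesh back as a :class:`RevolvedMesh` (units unknown: px)."""
    tm = trimesh.load(path, process=False, force="mesh")
    return RevolvedMesh(vertices=np.asarray(tm.vertices, float),
                        faces=np.asarray(tm.faces, np.int64), units="px")
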