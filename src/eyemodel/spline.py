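"""Cubic-spline section profiles in the axis frame.

A section profile gives tissue radius r as a function of the axial
coordinate u (signed distance along the symmetry axis).  Open
pole-to-pole profiles (cornea/sclera outline, lens) are natural cubic
interpolating splines through the feature-point knots; the spline is
stored in second-derivative form: knot values r_i plus solved second
derivatives M_i, with the piecewise cubic on [u_i, u_{i+1}]

    S(u) = M_i (u_{i+1}-u)^3 / (6 h_i) + M_{i+1} (u-u_i)^3 / (6 h_i)
         + (r_i - M_i h_i^2/6) (u_{i+1}-u)/h_i
         + (r_{i+1} - M_{i+1} h_i^2/6) (u-u_i)/h_i .

C2 continuity at the interior knots yields a tridiagonal system in the
M_i; natural boundary conditions set M_0 = M_n = 0.

Annular tissues (the iris) do not touch the axis; their closed section
outlines are fitted parametrically by cumulative chord length with
periodic cubic splines in u and r separately.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import solve_banded

from .errors import InvalidArgumentError, OutOfRangeError
from .symmetry import SymmetryAxis


def to_axis_frame(points: np.ndarray, axis: SymmetryAxis) -> np.ndarray:
    """Map 2D image points into (u, r) axis-frame coordinates.

    u is the signed coordinate along ``axis.direction`` measured from
    ``axis.point``; r >= 0 is the perpendicular distance from the axis.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = pts - axis.point
    d = axis.direction
    u = rel @ d
    r = np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0])
    return np.column_stack([u, r])


def from_axis_frame(ur: np.ndarray, axis: SymmetryAxis) -> np.ndarray:
    """Map (u, r) back to image coordinates on the +r half-plane."""
    ur = np.atleast_2d(np.asarray(ur, dtype=float))
    d = axis.direction
    n = np.array([-d[1], d[0]])  # +r side: cross(d, n) convention
    return axis.point + np.outer(ur[:, 0], d) - np.outer(ur[:, 1], n)


def solve_natural_spline_m(u: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Second derivatives M_i of the natural cubic interpolating spline.

    Solves the C2-continuity tridiagonal system

        h_{i-1} M_{i-1} + 2 (h_{i-1}+h_i) M_i + h_i M_{i+1}
            = 6 [ (r_{i+1}-r_i)/h_i - (r_i-r_{i-1})/h_{i-1} ]

    with M_0 = M_n = 0, via a banded solver.
    """
    n = len(u)
    h = np.diff(u)
    M = np.zeros(n)
    if n == 3:
        rhs = 6.0 * ((r[2] - r[1]) / h[1] - (r[1] - r[0]) / h[0])
        M[1] = rhs / (2.0 * (h[0] + h[1]))
        return M
    m = n - 2  # interior unknowns
    ab = np.zeros((3, m))
    ab[0, 1:] = h[1:-1]                   # superdiagonal
    ab[1, :] = 2.0 * (h[:-1] + h[1:])     # diagonal
    ab[2, :-1] = h[1:-1]                  # subdiagonal
    slopes = np.diff(r) / h
    rhs = 6.0 * np.diff(slopes)
    M[1:-1] = solve_banded((1, 1), ab, rhs)
    return M


@dataclass
class SplineProfile:
    """Interpolating cubic spline r(u) through strictly increasing knots.

    For ``closed=True`` profiles the knots come from a closed section
    outline and evaluation goes through periodic parametric splines;
    ``M`` is then empty.
    """

    knots: np.ndarray            # (n, 2) columns (u, r)
    M: np.ndarray                # second derivatives at the knots
    closed: bool = False
    _param: object = field(default=None, repr=False)  # periodic splines

    @property
    def u(self) -> np.ndarray:
        return self.knots[:, 0]

    @property
    def r(self) -> np.ndarray:
        return self.knots[:, 1]

    @property
    def h(self) -> np.ndarray:
        return np.diff(self.u)

    def to_dict(self) -> dict:
        return {"closed": bool(self.closed),
                "knots": [{"u": float(a), "r": float(b)} for a, b in self.knots],
                "M": self.M.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "SplineProfile":
        knots = np.array([[k["u"], k["r"]] for k in d["knots"]], dtype=float)
        if d.get("closed", False):
            return fit_closed_profile(knots)
        return cls(knots=knots, M=np.asarray(d["M"], float), closed=False)


def fit_cubic_spline(knots: np.ndarray) -> SplineProfile:
    """Natural cubic spline through (u, r) knots with strictly increasing u."""
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 2 or knots.shape[1] != 2 or len(knots) < 3:
        raise InvalidArgumentError("need >= 3 (u, r) knots")
    u, r = knots[:, 0], knots[:, 1]
    if np.any(np.diff(u) <= 0):
        raise InvalidArgumentError("knot u values must be strictly increasing")
    M = solve_natural_spline_m(u, r)
    return SplineProfile(knots=knots, M=M, closed=False)


def fit_closed_profile(points: np.ndarray) -> SplineProfile:
    """Periodic parametric spline through a closed (u, r) outline.

    The outline is parameterised by cumulative chord length; u and r are
    each fitted with a periodic cubic spline in the parameter.  Used for
    annular tissues whose section outline never meets the axis.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise InvalidArgumentError("need >= 3 (u, r) outline points")
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    wrapped = np.vstack([pts, pts[:1]])
    t = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(wrapped, axis=0), axis=1))])
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError("closed outline has duplicate points")
    su = CubicSpline(t, wrapped[:, 0], bc_type="periodic")
    sr = CubicSpline(t, wrapped[:, 1], bc_type="periodic")
    return SplineProfile(knots=pts, M=np.zeros(0), closed=True,
                         _param=(t, su, sr))


def eval_spline(profile: SplineProfile, u) -> np.ndarray | float:
    """Evaluate an open profile at axial coordinate(s) u.

    No extrapolation: u outside the knot range raises
    :class:`OutOfRangeError`.
    """
    if profile.closed:
        raise InvalidArgumentError(
            "closed profiles are parametric; use sample_profile")
    uq = np.asarray(u, dtype=float)
    scalar = uq.ndim == 0
    uq = np.atleast_1d(uq)
    uk, rk, M = profile.u, profile.r, profile.M
    if uq.min() < uk[0] - 1e-12 or uq.max() > uk[-1] + 1e-12:
        raise OutOfRangeError(
            f"u outside the knot range [{uk[0]}, {uk[-1]}]")
    uq = np.clip(uq, uk[0], uk[-1])
    i = np.clip(np.searchsorted(uk, uq, side="right") - 1, 0, len(uk) - 2)
    h = uk[i + 1] - uk[i]
    a = uk[i + 1] - uq
    b = uq - uk[i]
    val = (M[i] * a ** 3 / (6 * h) + M[i + 1] * b ** 3 / (6 * h)
           + (rk[i] - M[i] * h ** 2 / 6) * a / h
           + (rk[i + 1] - M[i + 1] * h ** 2 / 6) * b / h)
    return float(val[0]) if scalar else val


def sample_profile(profile: SplineProfile, n: int) -> np.ndarray:
    """Sample n (u, r) points along the profile, endpoints included.

    Open profiles are sampled uniformly in u; closed profiles uniformly
    in the chord-length parameter (first point repeated at the end is
    omitted).
    """
    if n < 2:
        raise InvalidArgumentError("n must be >= 2")
    if profile.closed:
        t, su, sr = profile._param
        ts = np.linspace(0.0, t[-1], n, endpoint=False)
        return np.column_stack([su(ts), sr(ts)])
    us = np.linspace(profile.u[0], profile.u[-1], n)
    return np.column_stack([us, eval_spline(profile, us)])
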