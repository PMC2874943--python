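"""Synthetic eye-slice phantoms with analytic ground truth.

Histological slice photographs of an eye section show darker tissue
regions (sclera/cornea outline, biconvex lens, iris) on a light
background, approximately mirror-symmetric about the optic axis.  The
generators here emulate that layout with analytically known region
boundaries, so every downstream stage (segmentation, axis detection,
profile fitting, revolution) can be tested against exact truth.

All regions are built as functions of the axis-frame coordinates
(u, |v|), which makes the noise-free images mirror-symmetric about the
ground-truth axis by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contour import ContourPolyline
from .errors import InvalidArgumentError
from .symmetry import SymmetryAxis

# intensity conventions: light background, darker tissue
BACKGROUND = 0.9
EYEBALL_FILL = 0.55
IRIS_FILL = 0.35
LENS_FILL = 0.25


@dataclass
class SliceImage:
    """2D grayscale slice raster with optional physical pixel size.

    ``pixels`` holds intensities in [0, 1]; ``pixel_size`` is mm/pixel
    when known, else ``None``.
    """

    pixels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidArgumentError("slice image must be 2D")
        h, w = self.pixels.shape
        if h < 16 or w < 16:
            raise InvalidArgumentError("slice image must be at least 16x16")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise InvalidArgumentError("intensities must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class GroundTruth:
    """Exact contours and symmetry axis used to build a phantom."""

    contours: dict[str, ContourPolyline]
    axis: SymmetryAxis
    params: dict = field(default_factory=dict)


def _polar_ellipse(theta, a, b):
    """Polar radius of an origin-centred ellipse with semi-axes (a, b)."""
    return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


def _eyeball_radius(theta, scale):
    """Star-shaped eyeball boundary: ellipse plus anterior corneal bulge."""
    a = 0.38 * scale
    b = 0.33 * scale
    bump = 0.06 * scale * np.exp(-((theta / 0.5) ** 2))
    return _polar_ellipse(theta, a, b) + bump


def _lens_radius(theta, thickness, diameter):
    """Polar boundary of a biconvex lens (intersection of two circles).

    The lens is centred at the origin with its optic axis along theta=0;
    each face is an arc of a circle of radius R = (a^2 + h^2) / (2a)
    with a = thickness/2, h = diameter/2, centred at -/+ (R - a) on the
    axis.  The polar radius of the intersection is the minimum of the
    two circles' polar radii.
    """
    a = thickness / 2.0
    h = diameter / 2.0
    R = (a * a + h * h) / (2.0 * a)
    d = R - a
    ct = np.cos(theta)
    # circle centred at (+d, 0): rho = d cos t + sqrt(R^2 - d^2 sin^2 t)
    s = np.sqrt(R * R - (d * np.sin(theta)) ** 2)
    rho_front = d * ct + s
    rho_back = -d * ct + s
    return np.minimum(rho_front, rho_back)


def generate_eye_slice(width: int, height: int, axis_angle: float = 0.0,
                       noise_sigma: float = 0.0, seed: int = 0
                       ) -> tuple[SliceImage, GroundTruth]:
    """Generate an eye-slice phantom and its ground truth.

    Parameters
    ----------
    width, height : int
        Image size in pixels, each >= 64.
    axis_angle : float
        In-plane angle of the symmetry axis in degrees; the axis passes
        through the image centre.
    noise_sigma : float
        Standard deviation of additive Gaussian intensity noise,
        clipped to [0, 1] after addition.
    seed : int
        Seed for the noise field; same seed gives bit-identical output.

    Returns
    -------
    (SliceImage, GroundTruth)
        The noisy image and the exact noise-free contours/axis.
    """
    if width < 64 or height < 64:
        raise InvalidArgumentError("eye slice needs width, height >= 64")
    if noise_sigma < 0:
        raise InvalidArgumentError("noise_sigma must be >= 0")

    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    ang = np.deg2rad(axis_angle)
    d = np.array([np.cos(ang), np.sin(ang)])
    n = np.array([-d[1], d[0]])
    scale = min(width, height)

    xs, ys = np.meshgrid(np.arange(width), np.arange(height))
    u = (xs - cx) * d[0] + (ys - cy) * d[1]
    v = (xs - cx) * n[0] + (ys - cy) * n[1]
    rho = np.hypot(u, v)
    theta = np.arctan2(np.abs(v), u)  # even in v: mirror symmetry built in

    img = np.full((height, width), BACKGROUND)

    # eyeball (sclera + cornea bulge), anterior toward +u
    inside_eye = rho <= _eyeball_radius(theta, scale)
    img[inside_eye] = EYEBALL_FILL

    # biconvex lens centred on the axis, anterior of centre
    lens_u = 0.18 * scale
    lens_t = 0.12 * scale
    lens_d = 0.26 * scale
    ul = u - lens_u
    rho_l = np.hypot(ul, v)
    theta_l = np.arctan2(np.abs(v), ul)
    inside_lens = rho_l <= _lens_radius(theta_l, lens_t, lens_d)
    img[inside_lens] = LENS_FILL

    # iris: two elliptical lobes mirrored across the axis, resting just
    # anterior of the lens equator
    iris_u, iris_v = 0.21 * scale, 0.11 * scale
    iris_a, iris_b = 0.035 * scale, 0.055 * scale  # semi-axes along (u, v)
    for sgn in (+1.0, -1.0):
        inside = (((u - iris_u) / iris_a) ** 2
                  + ((v - sgn * iris_v) / iris_b) ** 2) <= 1.0
        img[inside] = IRIS_FILL

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0.0, noise_sigma, img.shape), 0.0, 1.0)

    # analytic ground-truth contours
    centre = np.array([cx, cy])

    def star_contour(radius_fn, origin_u, name, n_pts=720):
        t = np.linspace(-np.pi, np.pi, n_pts, endpoint=False)
        r = radius_fn(np.abs(t))
        pu = origin_u + r * np.cos(t)
        pv = r * np.sin(t)
        pts = centre + np.outer(pu, d) + np.outer(pv, n)
        return ContourPolyline(pts, closed=True, name=name)

    contours = {
        "outer_eyeball": star_contour(lambda t: _eyeball_radius(t, scale),
                                      0.0, "outer_eyeball"),
        "lens": star_contour(lambda t: _lens_radius(t, lens_t, lens_d),
                             lens_u, "lens"),
    }
    t = np.linspace(-np.pi, np.pi, 360, endpoint=False)
    for sgn, name in ((+1.0, "iris_upper"), (-1.0, "iris_lower")):
        pu = iris_u + iris_a * np.cos(t)
        pv = sgn * iris_v + iris_b * np.sin(t)
        pts = centre + np.outer(pu, d) + np.outer(pv, n)
        contours[name] = ContourPolyline(pts, closed=True, name=name)

    truth = GroundTruth(
        contours=contours,
        axis=SymmetryAxis(point=centre, direction=d),
        params={"width": width, "height": height, "axis_angle": axis_angle,
                "noise_sigma": noise_sigma, "seed": seed},
    )
    return SliceImage(img), truth


def generate_disk_image(width: int, height: int, center: tuple[float, float],
                        radius: float, fg: float = 0.2, bg: float = 0.9,
                        noise_sigma: float = 0.0, seed: int = 0,
                        n_contour: int = 360
                        ) -> tuple[SliceImage, ContourPolyline]:
    """Uniform disk on a uniform background; the segmentation oracle.

    Returns the image and the true circle sampled at ``n_contour``
    (>= 360) points.
    """
    cx, cy = center
    if radius >= min(width, height) / 2.0 - 2.0:
        raise InvalidArgumentError("disk radius too large for the frame")
    if (cx - radius < 2 or cy - radius < 2
            or cx + radius > width - 3 or cy + radius > height - 3):
        raise InvalidArgumentError("disk not fully inside the frame")
    n_contour = max(int(n_contour), 360)

    xs, ys = np.meshgrid(np.arange(width), np.arange(height))
    img = np.where((xs - cx) ** 2 + (ys - cy) ** 2 <= radius ** 2, fg, bg)
    img = img.astype(float)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0.0, noise_sigma, img.shape), 0.0, 1.0)

    t = np.linspace(0, 2 * np.pi, n_contour, endpoint=False)
    circle = np.column_stack([cx + radius * np.cos(t),
                              cy + radius * np.sin(t)])
    return SliceImage(img), ContourPolyline(circle, closed=True, name="disk")


def biconvex_profile(n_profile: int, thickness: float, diameter: float
                     ) -> np.ndarray:
    """Axis-frame samples (u, r) of a biconvex lens profile, pole to pole.

    ``u`` runs from -thickness/2 to +thickness/2; r follows the two
    spherical caps and is 0 at both poles.  An odd ``n_profile`` places
    a sample exactly on the equator so the full diameter is attained.
    """
    if n_profile < 3:
        raise InvalidArgumentError("n_profile must be >= 3")
    if thickness <= 0 or diameter <= 0:
        raise InvalidArgumentError("thickness and diameter must be positive")
    a = thickness / 2.0
    h = diameter / 2.0
    R = (a * a + h * h) / (2.0 * a)
    u = np.linspace(-a, a, n_profile)
    # front cap (u > 0): circle centred at u0 = a - R; back cap mirrored
    r = np.sqrt(np.maximum(R * R - (np.abs(u) + (R - a)) ** 2, 0.0))
    return np.column_stack([u, r])


def generate_biconvex_mesh(n_profile: int, n_theta: int,
                           thickness: float = 4.0, diameter: float = 10.0):
    """Closed watertight lens-shaped surface of revolution.

    A stand-in for a simplified crystalline-lens surface mesh: two
    spherical caps revolved about the optic axis, symmetric about the
    equatorial plane.  Vertex count is (n_profile - 2) * n_theta + 2
    (the two poles are shared vertices).
    """
    from .revolve import revolve_profile

    if n_theta < 3:
        raise InvalidArgumentError("n_theta must be >= 3")
    samples = biconvex_profile(n_profile, thickness, diameter)
    axis = SymmetryAxis(point=np.array([0.0, 0.0]),
                        direction=np.array([1.0, 0.0]))
    return revolve_profile(samples, axis, n_theta, closed=False, units="mm")
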