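# Methods

This note records the models implemented in `eyemodel`, the defaults
and why they were chosen, what the synthetic phantoms do and do not
emulate, and the numerical choices made where the procedure is
genuinely open.

## Level-set segmentation without reinitialization

The contour is the zero level of Φ (negative inside), evolved by the
explicit update

    Φ ← Φ + τ { μ [ΔΦ − div(∇Φ/|∇Φ|)]
              + λ δ_ε(Φ) div(g ∇Φ/|∇Φ|) + ν g δ_ε(Φ) }.

The μ-term penalises deviation of |∇Φ| from 1, so Φ stays close to a
signed distance function and the classical periodic reinitialization
step is unnecessary; this also permits a simple binary-step
initialisation (Φ = ∓c0 on either side of a user rectangle or mask,
c0 = 4 by default) and a comparatively large step length τ.

Parameters (defaults): μ = 0.04 (the explicit scheme requires
μτ < 0.25, enforced at construction), λ = 5 (edge-length weight),
ν = 3 (area weight; positive shrinks a contour initialised outside the
target, negative grows one initialised inside — a CLI flag), τ = 3 and
k = 200 iterations (a practical operating point for ~100 px of front
travel; the pipeline default raises k to 600 because its front starts
at the image border), ε = 1.5 px (Dirac half-width), σ = 1.5 px
(edge-indicator pre-smoothing).

**Edge indicator.** g = 1/(1 + |∇(G_σ∗I)|²) with the gradient taken on
the native 8-bit intensity scale (I·255). The functional balances
unit-strength length/area terms against image gradients in camera
units; on a [0, 1]-normalised image the squared-gradient term is ~5
orders of magnitude too small and the front coasts through every edge
(observed directly on the disk phantom). With 8-bit units a 0.7
contrast step smoothed at σ = 1.5 gives g ≈ 5e−4 at the edge, a hard
stop.

**Discretisation.** Central differences for ∇Φ, 5-point Laplacian,
div(g∇Φ/|∇Φ|) by differencing the normalised-gradient components
scaled by g; |∇Φ| floored at 1e−10 before division; replicate-edge
(zero normal derivative) boundary condition applied each iteration.
NaN/Inf during evolution raises an error naming the iteration.

**Contour extraction.** Marching squares with linear sub-pixel
interpolation along grid edges (`skimage.measure.find_contours`);
closed contours are oriented counter-clockwise. Extracted vertices are
exact roots of the bilinear interpolant, which downstream geometry
relies on.

## Symmetry axis and feature points

The axis direction is the leading unit eigenvector of the 2×2
covariance of the pooled contour points; the line is anchored at their
centroid. When the eigenvalue ratio exceeds 0.99 the point set is
treated as isotropic and an explicit axis hint is required — PCA
symmetry detection is undefined there. The detected direction is
canonicalised into the right half-plane; callers compare angles
modulo 180°.

Feature picking replaces an interactive GUI with click lists: a pick
within d_max (default 5 px, small against a ~1000 px eyeball) of the
contour snaps to the nearest contour vertex; farther picks are kept
verbatim as repair points for locally deformed tissue. Picks within
3·d_max of the axis are projected onto it (perpendicular foot) and
flagged as pole points. Projection is implemented in vector form,
p' = a + ((p−a)·d)d, which is algebraically equivalent to the
slope-intercept perpendicular-foot construction wherever that is
defined and remains total for vertical and horizontal axes.

A practical caveat found during development: marching-squares vertex
density varies with the local edge orientation relative to the pixel
grid, which biases point statistics. The pipeline therefore resamples
the segmented contour uniformly by arc length (720 points) before PCA;
without this the detected axis was ~3° off on an exactly symmetric
phantom.

## Spline profile

Open pole-to-pole profiles are natural cubic interpolating splines
r(u) in second-derivative form: the M_i solve the C²-continuity
tridiagonal system with M_0 = M_n = 0 (natural boundary — the simplest
closure; clamped variants can be compared externally) and each piece is
evaluated from the standard cubic in (u_{i+1}−u), (u−u_i). No
extrapolation outside the knot range. On-axis pole points are
mandatory first/last knots: without them the revolved surface has
cracks at the axis.

Annular tissues (iris) never touch the axis; their closed section
outlines are fitted parametrically by cumulative chord length, with
periodic cubic splines in u and r separately, and revolve to
torus-topology surfaces.

## Revolution and physical scaling

Profile samples (u, r) revolve about the axis with n_theta rings
(default 64; tests use up to 256). The slice plane embeds as the 3D
(X, Y) plane, the θ = 0 ring reproducing the input profile; poles
collapse to single shared vertices, so an open profile of m samples
yields (m−2)·n_theta + 2 vertices and a closed genus-0, watertight,
consistently outward-wound surface (V−E+F = 2); closed profiles yield
V−E+F = 0. Scaling divides vertices by the zoom ratio
R = d_perimeter/l_real, where d_perimeter is the closed perimeter of
the segmented equatorial contour (the closing chord is included — an
equatorial circumference is a closed curve, a deliberate divergence
from summing only consecutive chords of an open polyline) and l_real
defaults to 74.5 mm, the normal equatorial circumference of an adult
human eye. The reference worked example is 881.4 px / 74.5 mm =
11.8 px/mm (ratio displayed at 0.1 precision, kept at full precision
internally). Meshes export as Wavefront OBJ (vertex order preserved),
binary STL and ASCII PLY.

## Mass-spring deformation

One particle per mesh vertex (m_i = total_mass/V), one Hookean spring
per unique mesh edge with rest length equal to its initial length and
uniform stiffness k_s. Forces: g_ij = k_s(|p_j−p_i|−L⁰)·unit(p_j−p_i),
per-particle viscous damping −d_i v_i applied exactly as written (not
per-spring relative damping), plus external forces. Integration is
semi-implicit (symplectic) Euler — v then p — which is stable at larger
steps than explicit Euler and has exactly testable closed forms (a free
particle under constant force has v_n = n·dt·f/m exactly). `step`
enforces dt < 2√(min m_i/k_s); note the per-particle damping term
additionally requires dt < 2 m_i/d_i, which is why the pipeline runs
its demo on a simplified surface (30 profile samples × 24 rings,
~674 vertices) rather than the full 6274-vertex model — at demo
defaults (total_mass = 1 g, k_s = 100, d_i = 1, dt = 1e−3) the full
mesh's tiny per-particle mass makes the damping term unstable.
Pinned particles are bit-exact; simulation aborts with the step index
if any particle leaves 1e6× the initial bounding radius.

## Synthetic phantoms

The eye-slice phantom emulates a photographed central section: light
background (0.9), darker tissue fills (eyeball 0.55, iris 0.35, lens
0.25), an eyeball boundary that is an ellipse (semi-axes 0.38/0.33 of
the image size) plus a Gaussian anterior corneal bulge, a biconvex
lens (intersection of two circles, thickness 0.12, diameter 0.26 of
image size) on the axis, and two elliptical iris lobes overlying the
lens equator at ±0.11 of image size. All regions are functions of the
axis-frame coordinates (u, |v|), so noise-free images are exactly
mirror-symmetric about the ground-truth axis, which always passes
through the image centre (so truth is exactly representable). Noise is
additive Gaussian, clipped to [0, 1], from a seeded generator
(bit-identical per seed). Contrast levels are a stand-in — no
intensity statistics of real slice photographs were available to
calibrate against — and the phantom has no staining texture, slice
distortion or registration error; passing tests demonstrate correctness
of the geometry pipeline on well-contrasted, approximately symmetric
sections, not robustness to histological artefacts.

The iris lobes sit inboard deliberately: placing them near the eyeball
equator makes the pooled contour covariance nearly isotropic in the
worst case (and, beyond it, perpendicular-major), where PCA axis
detection degrades; the chosen proportions give a ~1.3 eigenvalue
ratio, comfortably anisotropic, and match the anatomy (the iris
overlies the lens, well inside the globe).

The disk phantom (uniform disk, analytic 360-gon contour) is the
segmentation oracle: recovery error is measured point-to-circle. The
biconvex lens mesh (two spherical caps, R = (a²+h²)/(2a)) is the
mass-spring demonstration body.

## Problem sizes

Default test and demonstration sizes: 128² disk images (200–500
iterations), 256² eye phantoms (600 iterations in the pipeline),
spheres at 101 profile samples × 200 rings, mass-spring systems of 2 to
~700 particles run for 2e3–4e4 steps. These sizes keep the full
validation suite under a minute while leaving every measured quantity
well inside its tolerance; all stages scale to larger inputs without
modification.

## Known limitations

- Single-slice, rotationally symmetric reconstruction only; asymmetric
  tissues need solid modelling downstream, and slice-to-slice
  registration/volume reconstruction is out of scope.
- The level-set front can leak through gaps weaker than the noise floor
  of the edge indicator; defaults assume clear tissue/background
  contrast.
- The mass-spring model is a surface (not volumetric) elasticity
  surrogate with no self-collision or contact; spring constants are
  illustrative, not fitted to tissue moduli.
- Volumetric/FEM meshing and material assignment are intentionally not
  provided; export OBJ/STL/PLY into an FEM tool instead.
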