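"""End-to-end model construction: slice image to deformable 3D eye model.

Stages: segment the outer eyeball contour with the level-set method,
detect the symmetry axis by PCA of the contour points, pick and snap
feature points (with the near-axis ones projected onto the axis as
poles), fit the natural cubic-spline profile r(u), revolve it into a
triangulated surface, scale pixels to millimetres via the equatorial
circumference, and run a mass-spring deformation demo on the result.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as emio
from .contour import ContourPolyline
from .errors import InvalidArgumentError
from .levelset import LevelSetParams, rect_mask, segment
from .masspring import build_system, simulate
from .revolve import (DEFAULT_EYE_CIRCUMFERENCE_MM, RevolvedMesh, ScaleInfo,
                      contour_perimeter, revolve_profile, scale_mesh,
                      write_mesh, zoom_ratio)
from .spline import fit_cubic_spline, sample_profile, to_axis_frame
from .symmetry import (SymmetryAxis, pca_symmetry_axis, project_onto_axis,
                       snap_feature_points)
from .synthetic import SliceImage, generate_eye_slice


def profile_knots_from_contour(contour: ContourPolyline, axis: SymmetryAxis,
                               n_knots: int = 21, d_max: float = 5.0
                               ) -> np.ndarray:
    """Derive spline knots (u, r) from a closed contour and its axis.

    Emulates interactive feature picking: picks are spread along one
    side of the contour, snapped to the nearest contour vertex, and the
    two extreme picks along the axis are replaced by their perpendicular
    feet on the axis (the pole points).  Returns strictly increasing
    (u, r) knots with r = 0 at both ends.
    """
    if n_knots < 5:
        raise InvalidArgumentError("need at least 5 knots")
    d = axis.direction
    n = np.array([-d[1], d[0]])
    rel = contour.points - axis.point
    u = rel @ d
    v = rel @ n
    side = v >= 0
    if side.sum() < n_knots:
        side = ~side
    pts = contour.points[side]
    us = u[side]
    order = np.argsort(us)
    pts, us = pts[order], us[order]

    # pole picks: extreme contour points along the axis, projected onto it
    lo = project_onto_axis(contour.points[np.argmin(u)], axis)
    hi = project_onto_axis(contour.points[np.argmax(u)], axis)

    # interior picks: one snapped contour point per axial bin
    edges = np.linspace(us[0], us[-1], n_knots - 1)
    picks = []
    for a, b in zip(edges[:-1], edges[1:]):
        m = (us >= a) & (us <= b)
        if m.any():
            picks.append(pts[m][len(pts[m]) // 2])
    picks = snap_feature_points(np.asarray(picks), contour, d_max=d_max).points

    ur_int = to_axis_frame(picks, axis)
    ur_lo = to_axis_frame(lo, axis)[0]
    ur_hi = to_axis_frame(hi, axis)[0]
    ur_int = ur_int[(ur_int[:, 0] > ur_lo[0] + 1.0)
                    & (ur_int[:, 0] < ur_hi[0] - 1.0)
                    & (ur_int[:, 1] > 0.5)]
    knots = np.vstack([[ur_lo[0], 0.0], ur_int, [ur_hi[0], 0.0]])
    keep = np.concatenate([[True], np.diff(knots[:, 0]) > 1e-9])
    return knots[keep]


@dataclass
class PipelineResult:
    """Artifacts and summary numbers of one end-to-end run."""

    image: SliceImage
    contour: ContourPolyline
    axis: SymmetryAxis
    knots: np.ndarray
    mesh_px: RevolvedMesh
    mesh_mm: RevolvedMesh
    scale: ScaleInfo
    trajectory: object
    summary: dict


def run_pipeline(out_dir: str | Path | None = None, seed: int = 0,
                 size: int = 256, axis_angle: float = 20.0,
                 noise_sigma: float = 0.01, iterations: int = 600,
                 n_knots: int = 21, n_profile_samples: int = 100,
                 n_theta: int = 64,
                 l_real: float = DEFAULT_EYE_CIRCUMFERENCE_MM,
                 sim_steps: int = 2000, sim_dt: float = 1e-3,
                 sim_profile_samples: int = 30, sim_n_theta: int = 24,
                 record_every: int = 100) -> PipelineResult:
    """Run the full construction pipeline on a synthetic eye slice.

    Writes (when ``out_dir`` is given) the slice image, segmented
    contours, axis, profile, scale info, the scaled eye mesh as OBJ and
    the deformation trajectory (per-frame OBJ plus an energy CSV).
    """
    image, truth = generate_eye_slice(size, size, axis_angle=axis_angle,
                                      noise_sigma=noise_sigma, seed=seed)

    # 1. segment the outer eyeball: shrink a border box onto the tissue
    params = LevelSetParams(iterations=iterations)
    mask = rect_mask(image.pixels.shape, 4, 4, size - 4, size - 4)
    contours = segment(image, mask, params)
    closed = [c for c in contours if c.closed and len(c) > 20]
    if not closed:
        raise InvalidArgumentError("segmentation found no closed contour")
    outer = max(closed, key=lambda c: c.perimeter())
    outer.name = "outer_eyeball"

    # 2. symmetry axis by PCA of the segmented contour points,
    #    resampled uniformly by arc length to undo grid anisotropy
    axis = pca_symmetry_axis([outer.resample(720)])

    # 3. feature knots and spline profile
    knots = profile_knots_from_contour(outer, axis, n_knots=n_knots)
    profile = fit_cubic_spline(knots)
    samples = sample_profile(profile, n_profile_samples)
    samples[1:-1, 1] = np.maximum(samples[1:-1, 1], 1e-3)  # guard overshoot

    # 4. revolve and scale to millimetres via the equatorial circumference
    mesh_px = revolve_profile(samples, axis, n_theta=n_theta, closed=False)
    scale = zoom_ratio(contour_perimeter(outer), l_real)
    mesh_mm = scale_mesh(mesh_px, scale)

    # 5. mass-spring deformation demo: the surface is simplified first
    #    (coarser revolution of the same spline profile), the equatorial
    #    ring is pinned, and the poles are pulled apart along the axis
    sim_samples = sample_profile(profile, sim_profile_samples)
    sim_samples[1:-1, 1] = np.maximum(sim_samples[1:-1, 1], 1e-3)
    sim_mesh = scale_mesh(
        revolve_profile(sim_samples, axis, n_theta=sim_n_theta,
                        closed=False), scale)
    system = build_system(sim_mesh, total_mass=1.0, stiffness=100.0,
                          damping=1.0)
    u_mid = 0.5 * (knots[0, 0] + knots[-1, 0])
    u_vert = ((sim_mesh.vertices - sim_mesh.axis_origin)
              @ sim_mesh.axis_direction)
    u_mid_mm = u_mid / scale.ratio
    ring = np.argsort(np.abs(u_vert - u_mid_mm))[:sim_n_theta]
    system.fixed[ring] = True
    system.velocities[system.fixed] = 0.0
    f = np.zeros_like(system.positions)
    pole_lo, pole_hi = 0, len(sim_mesh.vertices) - 1
    f[pole_lo] = -0.5 * sim_mesh.axis_direction
    f[pole_hi] = +0.5 * sim_mesh.axis_direction
    final, traj = simulate(system, n_steps=sim_steps, dt=sim_dt, f_ext=f,
                           record_every=record_every)

    extent0 = abs(u_vert[pole_hi] - u_vert[pole_lo])
    u_final = ((final.positions - sim_mesh.axis_origin)
               @ sim_mesh.axis_direction)
    extent1 = abs(u_final[pole_hi] - u_final[pole_lo])

    summary = {
        "axis_angle_deg": axis.angle_deg,
        "axis_angle_error_deg": _angle_error(axis, truth.axis),
        "perimeter_px": contour_perimeter(outer),
        "zoom_ratio_px_per_mm": scale.ratio_display,
        "n_vertices": len(mesh_mm.vertices),
        "n_faces": len(mesh_mm.faces),
        "euler_characteristic": mesh_mm.euler_characteristic(),
        "polar_extent_mm_initial": float(extent0),
        "polar_extent_mm_final": float(extent1),
        "final_kinetic_energy": final.kinetic_energy(),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        emio.write_image(image, out / "slice.png")
        emio.write_ground_truth(truth, out / "ground_truth.json")
        emio.write_contours([outer], out / "contours.json")
        emio.write_axis(axis, out / "axis.json")
        emio.write_profile(profile, out / "profile.json")
        write_mesh(mesh_mm, out / "eye_mm.obj")
        (out / "scale.json").write_text(json.dumps(scale.to_dict()))
        for i, frame in enumerate(traj.frames):
            m = RevolvedMesh(frame, sim_mesh.faces, units="mm")
            write_mesh(m, out / f"frame_{i:04d}.obj")
        disp = traj.max_displacement()
        rows = np.column_stack([traj.times, disp])
        np.savetxt(out / "trajectory.csv", rows, delimiter=",",
                   header="time_s,max_displacement_mm", comments="")

    return PipelineResult(image=image, contour=outer, axis=axis, knots=knots,
                          mesh_px=mesh_px, mesh_mm=mesh_mm, scale=scale,
                          trajectory=traj, summary=summary)


def _angle_error(a: SymmetryAxis, b: SymmetryAxis) -> float:
    """Unsigned angle between two axes in degrees, folded mod 180."""
    dot = abs(float(np.dot(a.direction, b.direction)))
    return float(np.rad2deg(np.arccos(np.clip(dot, -1.0, 1.0))))
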