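"""Mass-spring simulation of surface-mesh deformation.

Each mesh vertex is a particle; each unique mesh edge is a linear
(Hookean) spring with rest length equal to its initial length.  The
equation of motion per particle is Newton's second law with viscous
per-particle damping and an external force:

    m_i a_i = sum_j g_ij - d_i v_i + f_ext,i

where g_ij = k_s (|p_j - p_i| - L0_ij) * (p_j - p_i)/|p_j - p_i| is the
spring force from neighbour j.  Time integration is semi-implicit
(symplectic) Euler: v <- v + dt a, then p <- p + dt v; pinned particles
never move.  The explicit scheme is stable for
dt < 2 sqrt(min_i m_i / k_s).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DivergenceError, InvalidArgumentError, NumericFailureError
from .revolve import RevolvedMesh

_MIN_LENGTH = 1e-12


@dataclass
class MassSpringSystem:
    """Particle positions/velocities plus spring connectivity."""

    positions: np.ndarray        # (n, 3) mm
    velocities: np.ndarray       # (n, 3) mm/s
    masses: np.ndarray           # (n,) g
    damping: np.ndarray          # (n,) viscosity d_i
    springs: np.ndarray          # (s, 2) int endpoint indices
    rest_lengths: np.ndarray     # (s,)
    stiffness: float             # uniform k_s
    fixed: np.ndarray = field(default=None)    # (n,) bool
    f_ext: np.ndarray = field(default=None)    # (n, 3)

    def __post_init__(self):
        n = len(self.positions)
        self.positions = np.asarray(self.positions, float)
        self.velocities = np.asarray(self.velocities, float)
        self.masses = np.asarray(self.masses, float)
        self.damping = np.asarray(self.damping, float)
        self.springs = np.asarray(self.springs, np.int64)
        self.rest_lengths = np.asarray(self.rest_lengths, float)
        if self.fixed is None:
            self.fixed = np.zeros(n, dtype=bool)
        self.fixed = np.asarray(self.fixed, bool)
        if self.f_ext is None:
            self.f_ext = np.zeros((n, 3))
        self.f_ext = np.asarray(self.f_ext, float)
        if np.any(self.masses <= 0):
            raise InvalidArgumentError("particle masses must be positive")
        if len(self.springs) and np.any(
                self.springs[:, 0] == self.springs[:, 1]):
            raise InvalidArgumentError("spring endpoints must be distinct")
        if np.any(self.rest_lengths <= 0):
            raise InvalidArgumentError("rest lengths must be positive")
        self.velocities[self.fixed] = 0.0

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def copy(self) -> "MassSpringSystem":
        return MassSpringSystem(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            masses=self.masses.copy(), damping=self.damping.copy(),
            springs=self.springs.copy(),
            rest_lengths=self.rest_lengths.copy(),
            stiffness=self.stiffness, fixed=self.fixed.copy(),
            f_ext=self.f_ext.copy())

    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(
            self.masses * np.einsum("ij,ij->i", self.velocities,
                                    self.velocities)))

    def elastic_energy(self) -> float:
        i, j = self.springs.T
        length = np.linalg.norm(self.positions[j] - self.positions[i], axis=1)
        return float(0.5 * self.stiffness
                     * np.sum((length - self.rest_lengths) ** 2))

    def stable_dt(self) -> float:
        """Upper bound of the explicit-integration stable time step."""
        return 2.0 * np.sqrt(self.masses.min() / self.stiffness)


def unique_edges(faces: np.ndarray) -> np.ndarray:
    """Sorted unique undirected edges of a triangle face list."""
    e = np.sort(np.asarray(faces)[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2),
                axis=1)
    return np.unique(e, axis=0)


def build_system(mesh: RevolvedMesh, total_mass: float = 1.0,
                 stiffness: float = 100.0, damping: float = 1.0,
                 fixed: np.ndarray | list | None = None) -> MassSpringSystem:
    """Build a mass-spring system from a surface mesh.

    Mass is spread uniformly over vertices (m_i = total_mass / V); one
    spring per unique mesh edge, rest length equal to its initial
    length, uniform stiffness.  ``fixed`` lists pinned vertex indices.
    """
    if total_mass <= 0:
        raise InvalidArgumentError("total_mass must be positive")
    if stiffness <= 0:
        raise InvalidArgumentError("stiffness must be positive")
    springs = unique_edges(mesh.faces)
    p = np.asarray(mesh.vertices, float)
    rest = np.linalg.norm(p[springs[:, 1]] - p[springs[:, 0]], axis=1)
    if np.any(rest <= _MIN_LENGTH):
        raise InvalidArgumentError(
            "mesh contains coincident spring endpoints (zero rest length)")
    n = len(p)
    fixed_mask = np.zeros(n, dtype=bool)
    if fixed is not None:
        fixed_mask[np.asarray(list(fixed), dtype=np.int64)] = True
    return MassSpringSystem(
        positions=p.copy(), velocities=np.zeros((n, 3)),
        masses=np.full(n, total_mass / n), damping=np.full(n, float(damping)),
        springs=springs, rest_lengths=rest, stiffness=float(stiffness),
        fixed=fixed_mask)


def spring_forces(system: MassSpringSystem) -> np.ndarray:
    """Net Hookean spring force on each particle.

    g_ij = k_s (|p_j - p_i| - L0) * unit(p_j - p_i); forces are pairwise
    equal and opposite, so the internal forces sum to zero.
    """
    i, j = system.springs.T
    d = system.positions[j] - system.positions[i]
    length = np.linalg.norm(d, axis=1)
    if np.any(length <= _MIN_LENGTH):
        raise NumericFailureError("coincident spring endpoints in simulation")
    f = (system.stiffness * (length - system.rest_lengths) / length)[:, None] * d
    out = np.zeros_like(system.positions)
    np.add.at(out, i, f)
    np.add.at(out, j, -f)
    return out


def step(system: MassSpringSystem, dt: float,
         in_place: bool = False) -> MassSpringSystem:
    """One semi-implicit Euler step.

    a = (spring + damping + external) / m; v <- v + dt a; p <- p + dt v.
    Pinned particles are left bit-exact.  Raises on a violated stability
    bound.
    """
    if dt <= 0:
        raise InvalidArgumentError("dt must be positive")
    if dt >= system.stable_dt():
        raise InvalidArgumentError(
            f"dt={dt} violates stability bound {system.stable_dt():.3g}")
    s = system if in_place else system.copy()
    forces = spring_forces(s) - s.damping[:, None] * s.velocities + s.f_ext
    acc = forces / s.masses[:, None]
    free = ~s.fixed
    s.velocities[free] += dt * acc[free]
    s.positions[free] += dt * s.velocities[free]
    return s


@dataclass
class Trajectory:
    """Recorded frames of a simulation."""

    frames: list[np.ndarray]
    times: np.ndarray
    dt: float

    @property
    def final(self) -> np.ndarray:
        return self.frames[-1]

    def max_displacement(self) -> np.ndarray:
        """Per-frame max vertex displacement from the first frame."""
        p0 = self.frames[0]
        return np.array([np.max(np.linalg.norm(f - p0, axis=1))
                         for f in self.frames])


def simulate(system: MassSpringSystem, n_steps: int, dt: float,
             f_ext: np.ndarray | None = None,
             record_every: int = 1) -> tuple[MassSpringSystem, Trajectory]:
    """Run ``n_steps`` of semi-implicit Euler, recording every k-th frame.

    ``f_ext`` (n, 3) overrides the system's constant external forces.
    Raises :class:`DivergenceError` if any particle leaves a ball of
    1e6 times the initial bounding radius.
    """
    if n_steps < 1:
        raise InvalidArgumentError("n_steps must be >= 1")
    if record_every < 1:
        raise InvalidArgumentError("record_every must be >= 1")
    s = system.copy()
    if f_ext is not None:
        s.f_ext = np.asarray(f_ext, float)
    radius0 = float(np.linalg.norm(
        s.positions - s.positions.mean(axis=0), axis=1).max())
    bound = 1e6 * max(radius0, 1.0)
    frames = [s.positions.copy()]
    times = [0.0]
    for k in range(1, n_steps + 1):
        step(s, dt, in_place=True)
        if np.max(np.abs(s.positions)) > bound:
            raise DivergenceError(f"simulation diverged at step {k}", step=k)
        if k % record_every == 0 or k == n_steps:
            frames.append(s.positions.copy())
            times.append(k * dt)
    return s, Trajectory(frames=frames, times=np.asarray(times), dt=dt)
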