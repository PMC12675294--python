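"""Synthetic vessel surfaces and analytic warps for building and testing.

Parametric tube meshes (optionally with branch-stub protrusions) stand in
for patient anatomies: their cell areas and normals are known exactly by
construction, cohorts are generated by smooth random perturbations of a
base specification, and closed-form invertible warps provide ground-truth
deformations for registration-recovery experiments.  The fixtures are
aorta-like in scale (cm) but deliberately simple.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .cloud import SurfaceMesh

__all__ = [
    "BranchSpec",
    "VesselSpec",
    "AnalyticWarp",
    "make_tube",
    "make_cohort",
    "default_aorta_like_spec",
    "random_sinusoidal_warp",
]


@dataclass
class BranchSpec:
    """A branch stub realized as a smooth radial protrusion of the trunk."""

    s: float  # position along the centerline in [0.15, 0.85]
    angle: float  # circumferential position (radians)
    amplitude: float  # protrusion height (cm)
    width_s: float = 0.06  # longitudinal extent (arc-length fraction)
    width_angle: float = 0.5  # circumferential extent (radians)


@dataclass
class VesselSpec:
    """Tube around a spline centerline with a varying radius profile."""

    control_points: np.ndarray  # (n_ctrl, 3) centerline controls, cm
    radii: np.ndarray  # (n_ctrl,) radius at each control, cm
    branches: list[BranchSpec] = field(default_factory=list)
    n_circ: int = 24
    n_long: int = 40
    capped: bool = True  # open-ends variant reproduces inlet/outlet faces

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=np.float64)
        self.radii = np.asarray(self.radii, dtype=np.float64)
        if np.any(self.radii <= 0):
            raise ValueError("radius must be positive everywhere")


def default_aorta_like_spec(n_circ: int = 24, n_long: int = 40) -> VesselSpec:
    """A curved trunk (arch-like) with three upper branch stubs, cm units."""
    t = np.linspace(0.0, 1.0, 7)
    ctrl = np.column_stack(
        [
            2.8 * np.sin(np.pi * t),  # arch in the x-z plane
            0.5 * np.sin(2 * np.pi * t),  # mild out-of-plane bow
            10.0 * t - 5.0,
        ]
    )
    radii = 1.1 - 0.3 * t  # tapering trunk
    branches = [
        BranchSpec(s=0.30, angle=0.0, amplitude=0.9),
        BranchSpec(s=0.45, angle=0.4, amplitude=0.8),
        BranchSpec(s=0.60, angle=-0.4, amplitude=0.7),
    ]
    return VesselSpec(ctrl, radii, branches=branches, n_circ=n_circ, n_long=n_long)


# ---------------------------------------------------------------------------
# mesh construction


def _parallel_transport_frames(points: np.ndarray):
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    seed = np.array([0.0, 0.0, 1.0])
    if abs(seed @ tangents[0]) > 0.9:
        seed = np.array([1.0, 0.0, 0.0])
    normals = [seed - (seed @ tangents[0]) * tangents[0]]
    normals[0] /= np.linalg.norm(normals[0])
    for i in range(1, len(points)):
        n = normals[-1] - (normals[-1] @ tangents[i]) * tangents[i]
        normals.append(n / np.linalg.norm(n))
    normals = np.array(normals)
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals


def make_tube(spec: VesselSpec, seed: int | None = None) -> SurfaceMesh:
    """Closed triangulated tube (capped ends) around the centerline.

    Deterministic given the spec; raises if the centerline curvature is
    too tight for the radius (the surface would self-intersect).
    """
    s_ctrl = np.linspace(0.0, 1.0, len(spec.control_points))
    spline = CubicSpline(s_ctrl, spec.control_points, axis=0)
    radius = CubicSpline(s_ctrl, spec.radii)
    s = np.linspace(0.0, 1.0, spec.n_long + 1)
    C = spline(s)
    # self-intersection guard: radius must stay below the curvature radius
    d1, d2 = spline(s, 1), spline(s, 2)
    speed = np.linalg.norm(d1, axis=1)
    kappa = np.linalg.norm(np.cross(d1, d2), axis=1) / np.maximum(speed**3, 1e-12)
    r = radius(s)
    if np.any(r * kappa > 0.95):
        bad = int(np.argmax(r * kappa))
        raise ValueError(
            f"centerline self-intersects at s={s[bad]:.3f}: radius {r[bad]:.3f} "
            f"exceeds curvature radius {1/max(kappa[bad],1e-12):.3f}"
        )
    _, N, Bn = _parallel_transport_frames(C)

    theta = np.linspace(0.0, 2 * np.pi, spec.n_circ, endpoint=False)
    verts = []
    for i in range(spec.n_long + 1):
        ring_r = np.full(spec.n_circ, r[i])
        for b in spec.branches:
            dtheta = np.angle(np.exp(1j * (theta - b.angle)))
            bump = b.amplitude * np.exp(
                -((s[i] - b.s) ** 2) / (2 * b.width_s**2)
                - (dtheta**2) / (2 * b.width_angle**2)
            )
            ring_r = ring_r + bump
        ring = (
            C[i]
            + np.outer(np.cos(theta) * ring_r, N[i])
            + np.outer(np.sin(theta) * ring_r, Bn[i])
        )
        verts.append(ring)
    verts = np.concatenate(verts, axis=0)
    nc = spec.n_circ

    tris = []
    for i in range(spec.n_long):
        for j in range(nc):
            a = i * nc + j
            b = i * nc + (j + 1) % nc
            c = (i + 1) * nc + j
            d = (i + 1) * nc + (j + 1) % nc
            tris.append([a, b, d])
            tris.append([a, d, c])
    if spec.capped:
        c0 = len(verts)
        c1 = len(verts) + 1
        verts = np.concatenate([verts, C[[0]], C[[-1]]], axis=0)
        for j in range(nc):
            tris.append([c0, (j + 1) % nc, j])
            base = spec.n_long * nc
            tris.append([c1, base + j, base + (j + 1) % nc])
    tris = np.asarray(tris, dtype=np.int64)

    # enforce outward orientation via the signed volume
    vol = np.einsum(
        "ij,ij->i",
        verts[tris[:, 0]],
        np.cross(verts[tris[:, 1]], verts[tris[:, 2]]),
    ).sum() / 6.0
    if spec.capped and vol < 0:
        tris = tris[:, [0, 2, 1]]
    return SurfaceMesh(vertices=verts, triangles=tris, oriented=True)


def make_cohort(
    base_spec: VesselSpec, n: int, variation_scale: float = 0.1, seed: int = 0
) -> list[SurfaceMesh]:
    """n shapes from smooth random perturbations of the base specification.

    Control points, radius profile and branch amplitudes are scaled by
    independent Gaussian factors of relative size ``variation_scale``;
    every shape shares the base topology and resolution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    meshes = []
    r_ref = float(np.mean(base_spec.radii))
    for _ in range(n):
        ctrl = base_spec.control_points * (
            1.0 + variation_scale * rng.normal(size=(len(base_spec.control_points), 1))
        )
        radii = base_spec.radii * np.clip(
            1.0 + variation_scale * rng.normal(size=base_spec.radii.shape), 0.3, 2.0
        )
        branches = [
            replace(
                b,
                amplitude=b.amplitude
                * float(np.clip(1.0 + variation_scale * rng.normal(), 0.2, 2.0)),
                angle=b.angle + 0.5 * variation_scale * rng.normal(),
            )
            for b in base_spec.branches
        ]
        spec = replace(base_spec, control_points=ctrl, radii=radii, branches=branches)
        for _ in range(8):  # shrink radii until the curvature guard passes
            try:
                meshes.append(make_tube(spec))
                break
            except ValueError:
                spec = replace(spec, radii=spec.radii * 0.85)
        else:
            raise ValueError(
                "could not realize a perturbed spec; reduce variation_scale"
            )
    return meshes


# ---------------------------------------------------------------------------
# analytic warps


@dataclass
class AnalyticWarp:
    """Smooth sinusoidal displacement field, diffeomorphic by amplitude bound.

    u_d(x) = sum_m A_{m,d} sin(2 pi k_m . x + phi_{m,d}); the map
    x -> x + u(x) is a diffeomorphism when the displacement-gradient norm
    stays below 1, which is enforced at construction from the closed-form
    bound sum_m 2 pi |A_m| |k_m|.
    """

    amplitudes: np.ndarray  # (n_modes, 3)
    wavevectors: np.ndarray  # (n_modes, 3)
    phases: np.ndarray  # (n_modes, 3)

    def __post_init__(self):
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=np.float64))
        self.wavevectors = np.atleast_2d(np.asarray(self.wavevectors, dtype=np.float64))
        self.phases = np.atleast_2d(np.asarray(self.phases, dtype=np.float64))
        if self.gradient_bound() >= 1.0:
            raise ValueError(
                f"displacement gradient bound {self.gradient_bound():.3f} >= 1; "
                "the warp may not be invertible"
            )

    def gradient_bound(self) -> float:
        return float(
            sum(
                2 * np.pi * np.linalg.norm(A) * np.linalg.norm(k)
                for A, k in zip(self.amplitudes, self.wavevectors)
            )
        )

    def max_displacement(self) -> float:
        return float(np.linalg.norm(np.abs(self.amplitudes).sum(axis=0)))

    def displacement(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        u = np.zeros_like(x)
        for A, k, phi in zip(self.amplitudes, self.wavevectors, self.phases):
            u += A * np.sin(2 * np.pi * (x @ k)[:, None] + phi)
        return u

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) + self.displacement(points)

    def invert(self, points: np.ndarray, tol: float = 1e-12, max_iter: int = 500):
        """Solve y + u(y) = x by contraction iteration (Lip(u) < 1)."""
        x = np.asarray(points, dtype=np.float64)
        y = x.copy()
        for _ in range(max_iter):
            y_new = x - self.displacement(y)
            if np.max(np.abs(y_new - y)) < tol:
                return y_new
            y = y_new
        return y


def random_sinusoidal_warp(
    seed: int = 0, n_modes: int = 2, amplitude: float = 0.25
) -> AnalyticWarp:
    """A seeded low-frequency warp, scaled to a safe gradient bound."""
    rng = np.random.default_rng(seed)
    k = rng.uniform(-0.15, 0.15, size=(n_modes, 3))
    A = rng.normal(size=(n_modes, 3))
    A *= amplitude / np.abs(A).sum(axis=0).max()
    bound = sum(2 * np.pi * np.linalg.norm(a) * np.linalg.norm(kk) for a, kk in zip(A, k))
    if bound >= 0.9:
        A *= 0.85 / bound
    phases = rng.uniform(0, 2 * np.pi, size=(n_modes, 3))
    return AnalyticWarp(amplitudes=A, wavevectors=k, phases=phases)
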