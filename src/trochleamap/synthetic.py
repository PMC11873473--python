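"""Synthetic phantoms and simulated rater data with known ground truth.

Everything downstream (curvature, rendering, landmark angles, reliability
statistics) is testable without any imaging data: geometric primitives
carry closed-form principal curvatures, the trochlea phantom carries its
groove centerline, ridge crests and the construction angle, and the rater
simulator carries the implied true reliability of its tables.

The phantom follows the standard idealization of the distal femur as a
cylinder whose axis runs mediolaterally.  A Gaussian-profile concave
groove is carved into the anterior surface along a centerline that starts
at the distal notch and deflects laterally as it runs proximally;
Gaussian ridges are raised on either flank.  The profile is C² smooth so
quadric fitting is well-posed.  The phantom reproduces the qualitative
features the curvature maps must expose — a concave band flanked by
convex ridges — not realistic femoral anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .mesh import DEFAULT_CONDYLAR_WIDTH_MM, SurfaceMesh

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "RaterSimSpec",
    "make_primitive",
    "make_trochlea_phantom",
    "simulate_ratings",
]


# ---------------------------------------------------------------------------
# primitives with analytic curvature oracles
# ---------------------------------------------------------------------------

def _grid_faces(nu: int, nv: int, wrap_u: bool = False) -> np.ndarray:
    """Triangulate an (nu × nv) vertex grid, optionally closed in u."""
    faces = []
    nu_eff = nu if wrap_u else nu - 1
    for i in range(nu_eff):
        i2 = (i + 1) % nu
        for j in range(nv - 1):
            a = i * nv + j
            b = i2 * nv + j
            faces.append([a, b, b + 1])
            faces.append([a, b + 1, a + 1])
    return np.asarray(faces, dtype=np.int64)


def _cylinder(radius: float, height: float, spacing: float):
    n_ang = max(int(np.ceil(2 * np.pi * radius / spacing)), 8)
    n_len = max(int(np.ceil(height / spacing)) + 1, 2)
    theta = np.linspace(0, 2 * np.pi, n_ang, endpoint=False)
    x = np.linspace(-height / 2, height / 2, n_len)
    T, X = np.meshgrid(theta, x, indexing="ij")
    verts = np.column_stack([
        X.ravel(), radius * np.cos(T).ravel(), radius * np.sin(T).ravel()
    ])
    faces = _grid_faces(n_ang, n_len, wrap_u=True)
    normals = verts.copy()
    normals[:, 0] = 0.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    # cap fans
    side_n = len(verts)
    cap_faces = []
    cap_centers = []
    for sgn, x0 in ((-1.0, -height / 2), (1.0, height / 2)):
        center = side_n + len(cap_centers)
        cap_centers.append([x0, 0.0, 0.0])
        ring = np.arange(n_ang) * n_len + (0 if sgn < 0 else n_len - 1)
        for i in range(n_ang):
            a, b = ring[i], ring[(i + 1) % n_ang]
            tri = [center, a, b] if sgn > 0 else [center, b, a]
            cap_faces.append(tri)
    verts = np.vstack([verts, np.asarray(cap_centers)])
    normals = np.vstack([normals, [[-1, 0, 0], [1, 0, 0]]])
    faces = np.vstack([faces, np.asarray(cap_faces, np.int64)])
    k_max = np.full(len(verts), 1.0 / radius)
    k_min = np.zeros(len(verts))
    k_max[side_n:] = 0.0  # flat caps
    # oracle invalid near the rim where the crease breaks smoothness
    on_rim = np.abs(np.abs(verts[:, 0]) - height / 2) < 1e-9
    valid = ~on_rim
    valid[side_n:] = False
    return verts, faces, normals, k_max, k_min, valid


def _sphere(radius: float, spacing: float):
    import trimesh
    subdiv = max(int(np.ceil(np.log2(max(radius / spacing, 1.0)))) + 1, 2)
    tm = trimesh.creation.icosphere(subdivisions=min(subdiv, 6), radius=radius)
    verts = np.asarray(tm.vertices, float)
    normals = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    k = np.full(len(verts), 1.0 / radius)
    return (verts, np.asarray(tm.faces, np.int64), normals,
            k.copy(), k.copy(), np.ones(len(verts), bool))


def _monge_curvatures(hx, hy, hxx, hxy, hyy):
    """Principal curvatures of z=h(x,y) with the upward (+z-ish) normal,
    convex-positive convention (bending away from the normal positive)."""
    E = 1 + hx**2
    F = hx * hy
    G = 1 + hy**2
    w = np.sqrt(1 + hx**2 + hy**2)
    L, M, N = hxx / w, hxy / w, hyy / w
    det = E * G - F**2
    # S = -I^{-1} II, symmetrized eigenvalues via trace/determinant
    tr = -(G * L - 2 * F * M + E * N) / det
    dt = (L * N - M**2) / det
    disc = np.maximum(tr**2 / 4 - dt, 0.0)
    root = np.sqrt(disc)
    return tr / 2 + root, tr / 2 - root


def _saddle(size: float, c: float, spacing: float):
    n = max(int(np.ceil(size / spacing)) + 1, 8)
    x = np.linspace(-size / 2, size / 2, n)
    X, Y = np.meshgrid(x, x, indexing="ij")
    Z = (X**2 - Y**2) / (2 * c)
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    faces = _grid_faces(n, n, wrap_u=False)
    hx = X.ravel() / c
    hy = -Y.ravel() / c
    normals = np.column_stack([-hx, -hy, np.ones_like(hx)])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    k_max, k_min = _monge_curvatures(hx, hy, 1.0 / c, 0.0, -1.0 / c)
    valid = np.ones(len(verts), bool)
    return verts, faces, normals, k_max, k_min, valid


def make_primitive(kind: str, *, radius: float = 10.0, height: float = 50.0,
                   size: float = 40.0, c: float = 10.0,
                   spacing: float = 1.0):
    """Build a test primitive with a per-vertex analytic curvature oracle.

    Parameters
    ----------
    kind : {"cylinder", "sphere", "saddle"}
    radius, height : cylinder/sphere dimensions (mm)
    size, c : saddle patch extent and z = (x² − y²)/(2c) parameter (mm)
    spacing : target vertex spacing (mm); must allow a quadric fit

    Returns
    -------
    (SurfaceMesh, oracle) where oracle is a dict with arrays ``k_max``,
    ``k_min`` and a boolean ``valid`` mask excluding vertices (rims, caps)
    where the closed form does not apply.
    """
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    if kind == "cylinder":
        if radius <= 0 or height <= 0:
            raise ValidationError("cylinder needs positive radius and height")
        if spacing > min(radius, height) / 2:
            raise ValidationError("spacing too coarse for quadric fitting")
        out = _cylinder(radius, height, spacing)
    elif kind == "sphere":
        if radius <= 0:
            raise ValidationError("sphere needs positive radius")
        if spacing > radius:
            raise ValidationError("spacing too coarse for quadric fitting")
        out = _sphere(radius, spacing)
    elif kind == "saddle":
        if size <= 0 or c == 0:
            raise ValidationError("saddle needs positive size and nonzero c")
        if spacing > size / 4:
            raise ValidationError("spacing too coarse for quadric fitting")
        out = _saddle(size, c, spacing)
    else:
        raise ValidationError(f"unknown primitive kind: {kind!r}")
    verts, faces, normals, k_max, k_min, valid = out
    if len(verts) < 12:
        raise ValidationError("resolution too coarse for quadric fitting")
    mesh = SurfaceMesh(vertices=verts, faces=faces, normals=normals)
    oracle = {"k_max": k_max, "k_min": k_min, "valid": valid}
    return mesh, oracle


# ---------------------------------------------------------------------------
# trochlea phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry of the cylinder-based trochlea phantom (all lengths mm).

    The cylinder axis is x (mediolateral), anterior is +y, proximal +z.
    The groove starts at the distal notch (angular position
    ``theta_start``) centered at x=0 and deflects to
    ``groove_lateral_offset`` at its proximal end; lateral is −x (the
    lateral condyle sits at x = −width/2).
    """

    width: float = DEFAULT_CONDYLAR_WIDTH_MM
    cylinder_radius: float = 20.0
    groove_depth: float = 3.0
    groove_width: float = 12.0
    groove_lateral_offset: float = 0.0
    groove_proximal_extent: float = 0.6
    ridge_height: float = 1.5
    ridge_width: float = 5.0
    ridge_spacing: float = 11.0
    mesh_resolution: float = 1.0  # vertices per mm along each direction
    theta_start: float = np.pi / 3  # distal groove start, from distal apex

    def __post_init__(self) -> None:
        for name in ("width", "cylinder_radius", "groove_width",
                     "ridge_width", "ridge_spacing", "mesh_resolution"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.groove_depth < 0 or self.ridge_height < 0:
            raise ValidationError("depths/heights must be non-negative")
        if self.groove_depth >= self.cylinder_radius:
            raise ValidationError("groove deeper than cylinder radius")
        if self.groove_width >= self.width:
            raise ValidationError("groove wider than phantom")
        if not (0 < self.groove_proximal_extent <= 1):
            raise ValidationError("groove_proximal_extent must be in (0, 1]")


@dataclass
class PhantomTruth:
    """Analytic ground truth attached to a phantom mesh.

    Polylines are (n, 3) arrays in mesh coordinates (mm).  ``landmarks_3d``
    holds the 3D positions of the EPTG protocol points (condyles, notch
    apex, ridge ends); ``expected_eptg_deg`` is the construction angle of
    the groove deflection as seen in an anteroposterior projection,
    positive when the entry point lies lateral to the notch.
    """

    groove_centerline: np.ndarray
    medial_ridge_crest: np.ndarray
    lateral_ridge_crest: np.ndarray
    landmarks_3d: dict[str, np.ndarray]
    expected_eptg_deg: float


def _phantom_surface(spec: PhantomSpec, theta: np.ndarray, x: np.ndarray):
    """Radial displacement field r(theta, x) of the phantom surface."""
    theta_end = spec.theta_start + spec.groove_proximal_extent * (
        np.pi - spec.theta_start
    )
    span = theta_end - spec.theta_start
    T, X = np.meshgrid(theta, x, indexing="ij")
    t = np.clip((T - spec.theta_start) / span, 0.0, 1.0)
    # smoothstep window along the sweep, C² at both ends
    win = np.where(
        (T >= spec.theta_start) & (T <= theta_end),
        t**3 * (t * (t * 6 - 15) + 10), 0.0,
    )
    # lateral (−x) deflection of the centerline with proximal progression
    xc = -spec.groove_lateral_offset * t
    g = np.exp(-0.5 * ((X - xc) / (spec.groove_width / 2.355)) ** 2)
    rm = np.exp(-0.5 * ((X - xc - spec.ridge_spacing)
                        / (spec.ridge_width / 2.355)) ** 2)
    rl = np.exp(-0.5 * ((X - xc + spec.ridge_spacing)
                        / (spec.ridge_width / 2.355)) ** 2)
    dr = (-spec.groove_depth * g + spec.ridge_height * (rm + rl)) * win
    return spec.cylinder_radius + dr, theta_end


def make_trochlea_phantom(spec: PhantomSpec) -> tuple[SurfaceMesh, PhantomTruth]:
    """Build the grooved-cylinder phantom and its analytic ground truth.

    Returns the mesh together with the groove centerline, the two ridge
    crest polylines, the EPTG protocol landmark positions implied by the
    construction, and the expected EPTG angle.
    """
    spacing = 1.0 / spec.mesh_resolution
    n_ang = max(int(np.ceil(np.pi * spec.cylinder_radius / spacing)), 16)
    n_len = max(int(np.ceil(spec.width / spacing)) + 1, 8)
    # anterior half-shell: theta 0 (distal apex) → pi (proximal apex)
    theta = np.linspace(0.0, np.pi, n_ang)
    x = np.linspace(-spec.width / 2, spec.width / 2, n_len)
    R, theta_end = _phantom_surface(spec, theta, x)
    T, X = np.meshgrid(theta, x, indexing="ij")
    Y = R * np.sin(T)
    Z = -R * np.cos(T)
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    faces = _grid_faces(n_ang, n_len, wrap_u=False)

    # numerical outward normals from the parametric tangents
    dRdT, dRdX = np.gradient(R, theta, x)
    e_r = np.stack([np.zeros_like(T), np.sin(T), -np.cos(T)], axis=-1)
    e_t = np.stack([np.zeros_like(T), np.cos(T), np.sin(T)], axis=-1)
    tang_t = dRdT[..., None] * e_r + R[..., None] * e_t
    tang_x = np.zeros_like(tang_t)
    tang_x[..., 0] = 1.0
    tang_x += dRdX[..., None] * e_r
    normals = np.cross(tang_x, tang_t).reshape(-1, 3)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    # orient outward (away from the cylinder axis)
    flip = np.einsum("ij,ij->i", normals, e_r.reshape(-1, 3)) < 0
    normals[flip] *= -1
    mesh = SurfaceMesh(vertices=verts, faces=faces, normals=normals)

    # ground-truth polylines along the sweep
    tt = np.linspace(0.0, 1.0, 64)
    th = spec.theta_start + tt * (theta_end - spec.theta_start)
    xc = -spec.groove_lateral_offset * (tt**3 * (tt * (tt * 6 - 15) + 10))
    win = tt**3 * (tt * (tt * 6 - 15) + 10)
    r_groove = spec.cylinder_radius - spec.groove_depth * win
    def _polyline(xs, rs):
        return np.column_stack([xs, rs * np.sin(th), -rs * np.cos(th)])
    r_ridge = spec.cylinder_radius + spec.ridge_height * win
    groove = _polyline(xc, r_groove)
    medial = _polyline(xc + spec.ridge_spacing, r_ridge)
    lateral = _polyline(xc - spec.ridge_spacing, r_ridge)

    landmarks = {
        # condyles at the distal-anterior rims of the cylinder flanks
        "lateral_condyle": np.array(
            [-spec.width / 2, spec.cylinder_radius * np.sin(spec.theta_start),
             -spec.cylinder_radius * np.cos(spec.theta_start)]),
        "medial_condyle": np.array(
            [spec.width / 2, spec.cylinder_radius * np.sin(spec.theta_start),
             -spec.cylinder_radius * np.cos(spec.theta_start)]),
        "notch_apex": groove[0],
        "medial_ridge_end": medial[-1],
        "lateral_ridge_end": lateral[-1],
    }
    entry = 0.5 * (medial[-1] + lateral[-1])
    notch = groove[0]
    # AP projection: x is mediolateral, z proximal; the transcondylar line
    # is the x axis, so the reference line is vertical in the view
    dz = entry[2] - notch[2]
    dx = entry[0] - notch[0]
    lat_sign = np.sign(landmarks["lateral_condyle"][0] - landmarks["medial_condyle"][0])
    lateral_component = dx * lat_sign
    expected = float(np.degrees(np.arctan2(lateral_component, dz)))
    truth = PhantomTruth(
        groove_centerline=groove,
        medial_ridge_crest=medial,
        lateral_ridge_crest=lateral,
        landmarks_3d=landmarks,
        expected_eptg_deg=expected,
    )
    return mesh, truth


# ---------------------------------------------------------------------------
# simulated rater tables
# ---------------------------------------------------------------------------

@dataclass
class RaterSimSpec:
    """Variance-component model for repeated EPTG ratings (degrees).

    angle(knee, rater, condition, rep) = group mean + knee effect
    (Normal(0, subject_sd)) + rater bias + Normal(0, condition noise sd).
    Knees are split evenly between the patient and control groups.
    """

    n_subjects: int = 60
    subject_sd: float = 9.0
    rater_biases: tuple[float, ...] = (0.0, 0.0, 0.0)
    noise_sd_with_aid: float = 3.5
    noise_sd_without_aid: float = 7.0
    group_means: dict = field(
        default_factory=lambda: {"patient": 31.8, "control": 16.3}
    )
    n_repetitions: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.rater_biases) < 2:
            raise ValidationError("need at least 2 raters")
        if min(self.subject_sd, self.noise_sd_with_aid,
               self.noise_sd_without_aid) < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.n_subjects < 2:
            raise ValidationError("need at least 2 subjects")

    def _group_offsets(self) -> np.ndarray:
        n = self.n_subjects
        groups = np.where(np.arange(n) < n // 2, "patient", "control")
        return np.array([self.group_means[g] for g in groups], float)

    def implied_icc(self, aid: bool) -> float:
        """Closed-form ICC(A,1) implied by the variance components.

        Fixed effects enter as the ddof=1 sample variance of their
        realized offsets — rater biases through the column mean square
        and the patient/control group means through the row mean square —
        matching the expectations of the two-way ANOVA estimator.
        """
        sb2 = float(np.var(self.rater_biases, ddof=1))
        sg2 = float(np.var(self._group_offsets(), ddof=1))
        se2 = (self.noise_sd_with_aid if aid else self.noise_sd_without_aid) ** 2
        ss2 = self.subject_sd**2 + sg2
        return ss2 / (ss2 + sb2 + se2)


def simulate_ratings(spec: RaterSimSpec) -> pd.DataFrame:
    """Simulate a full measurement table (both aid conditions).

    Returns a DataFrame with columns knee_id, group, rater_id, aid,
    repetition, angle_deg.  Reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    groups = np.where(np.arange(n) < n // 2, "patient", "control")
    subject_effect = rng.normal(0.0, spec.subject_sd, size=n)
    base = spec._group_offsets() + subject_effect
    rows = []
    for rep in range(1, spec.n_repetitions + 1):
        for aid, sd in ((True, spec.noise_sd_with_aid),
                        (False, spec.noise_sd_without_aid)):
            noise = rng.normal(0.0, sd, size=(n, len(spec.rater_biases)))
            for j, bias in enumerate(spec.rater_biases):
                angles = base + bias + noise[:, j]
                for i in range(n):
                    rows.append({
                        "knee_id": f"K{i:03d}",
                        "group": groups[i],
                        "rater_id": f"R{j + 1}",
                        "aid": aid,
                        "repetition": rep,
                        "angle_deg": angles[i],
                    })
    return pd.DataFrame(rows)
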