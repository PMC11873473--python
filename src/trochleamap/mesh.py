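"""Surface meshes of the distal femur and multi-scale principal curvature.

The distal femur is, to first order, a cylinder whose axis runs
mediolaterally: at a large fitting scale the maximal principal curvature
wraps around the condyles and the minimal principal curvature runs along
the cylinder axis.  Small surface features (the trochlear ridges) only
appear when curvature is estimated over a small neighborhood, while the
trochlear groove — a wide concave channel — needs a large one.  Fitting
radii are therefore expressed as fractions of condylar width so that the
same two dimensionless factors transfer across differently sized knees:
0.05 of condylar width for the ridge map and 0.13 for the groove map
(3.9 mm and 10.1 mm on a 78.0 mm wide adult femur).

Sign convention: curvature of a convex region (condyles, ridges — the
surface bends away from the outward normal) is positive; a concave region
(the groove) is negative, with more negative meaning a deeper groove.

Curvature is estimated per vertex by collecting all vertices within a
Euclidean ball of the fitting radius, fitting a least-squares quadric
height field in the tangent frame of the vertex normal, and taking the
eigenvalues of the shape operator of the fitted patch at the origin.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import FormatError, ValidationError

__all__ = [
    "SurfaceMesh",
    "CurvatureField",
    "ScaleConfig",
    "load_mesh",
    "save_mesh",
    "estimate_condylar_width",
    "default_mediolateral_axis",
    "fitting_radius",
    "principal_curvatures",
    "RIDGE_FACTOR",
    "GROOVE_FACTOR",
    "DEFAULT_CONDYLAR_WIDTH_MM",
]

#: Fraction of condylar width for the small-scale (ridge) curvature map.
RIDGE_FACTOR = 0.05
#: Fraction of condylar width for the large-scale (groove) curvature map.
GROOVE_FACTOR = 0.13
#: Literature mean mediolateral condylar width of the adult distal femur (mm).
DEFAULT_CONDYLAR_WIDTH_MM = 78.0

_SUPPORTED_SUFFIXES = {".stl", ".ply", ".obj"}


@dataclass
class SurfaceMesh:
    """Triangle surface mesh in millimetres with outward unit vertex normals.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    normals : (n, 3) float array of outward unit normals
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.normals = np.asarray(self.normals, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError("faces must be an (m, 3) array")
        if len(self.faces) == 0:
            raise ValidationError("mesh has no faces")
        if not np.isfinite(self.vertices).all():
            raise ValidationError("mesh contains non-finite vertex coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValidationError("face indices out of range")
        if self.normals.shape != self.vertices.shape:
            raise ValidationError("normals must match vertices in shape")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValidationError("normals must be unit length within 1e-6")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def boundary_vertex_mask(self) -> np.ndarray:
        """Boolean mask of vertices lying on an open boundary edge."""
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        boundary_edges = uniq[counts == 1]
        mask = np.zeros(self.n_vertices, dtype=bool)
        mask[boundary_edges.ravel()] = True
        return mask

    def flipped(self) -> "SurfaceMesh":
        """Copy with all normals flipped (and winding reversed)."""
        return SurfaceMesh(
            vertices=self.vertices.copy(),
            faces=self.faces[:, ::-1].copy(),
            normals=-self.normals,
        )


@dataclass
class ScaleConfig:
    """Fitting-scale configuration for the two curvature maps.

    ridge_factor and groove_factor are dimensionless fractions of
    condylar_width (mm).
    """

    condylar_width: float = DEFAULT_CONDYLAR_WIDTH_MM
    ridge_factor: float = RIDGE_FACTOR
    groove_factor: float = GROOVE_FACTOR

    def __post_init__(self) -> None:
        if not (0.0 < self.ridge_factor < self.groove_factor < 1.0):
            raise ValidationError(
                "require 0 < ridge_factor < groove_factor < 1, got "
                f"{self.ridge_factor}, {self.groove_factor}"
            )
        if not self.condylar_width > 0:
            raise ValidationError("condylar_width must be positive")


@dataclass
class CurvatureField:
    """Per-vertex principal curvatures (1/mm) at a stated fitting radius.

    ``k_max >= k_min`` at every defined vertex; ``defined`` is False where
    the neighborhood was too small for a quadric fit, ``boundary`` flags
    vertices whose neighborhood was truncated by a mesh boundary (computed
    normally but suspect, e.g. at cut planes).
    """

    k_max: np.ndarray
    k_min: np.ndarray
    radius: float
    scale_factor: float | None = None
    defined: np.ndarray = field(default=None)  # type: ignore[assignment]
    boundary: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.k_max = np.asarray(self.k_max, dtype=float)
        self.k_min = np.asarray(self.k_min, dtype=float)
        if self.defined is None:
            self.defined = np.isfinite(self.k_max) & np.isfinite(self.k_min)
        if self.boundary is None:
            self.boundary = np.zeros(len(self.k_max), dtype=bool)
        if self.radius <= 0:
            raise ValidationError("fitting radius must be positive")
        d = self.defined
        if np.any(self.k_max[d] < self.k_min[d] - 1e-12):
            raise ValidationError("k_max < k_min at a defined vertex")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["vertex_id", "k_max", "k_min"])
            for i, (hi, lo) in enumerate(zip(self.k_max, self.k_min)):
                w.writerow([i, repr(float(hi)), repr(float(lo))])


def load_mesh(path: str | Path, units: str = "mm") -> SurfaceMesh:
    """Load an STL/PLY/OBJ triangle mesh and validate it.

    ``units`` is the length unit of the file ("mm" or "m"); coordinates are
    converted to millimetres.  Outward unit vertex normals are recomputed
    (area-weighted, oriented outward for watertight meshes).  Empty,
    non-finite or non-orientable meshes are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported mesh format: {path.suffix}")
    try:
        tm = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader failures
        raise FormatError(f"could not read {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValidationError(f"{path} contains no triangle faces")
    vertices = np.asarray(tm.vertices, dtype=float)
    if not np.isfinite(vertices).all():
        raise ValidationError(f"{path} contains non-finite vertex coordinates")
    if units == "m":
        vertices = vertices * 1000.0
    elif units != "mm":
        raise ValidationError(f"unknown unit tag: {units!r}")
    tm = trimesh.Trimesh(vertices=vertices, faces=tm.faces, process=False)
    tm.merge_vertices()  # STL stores vertices per facet
    tm.update_faces(tm.nondegenerate_faces())
    tm.remove_unreferenced_vertices()
    if len(tm.faces) == 0:
        raise ValidationError(f"{path} contains only degenerate faces")
    if not tm.is_winding_consistent:
        raise ValidationError(f"{path}: inconsistent face winding (non-orientable)")
    if tm.is_watertight:
        tm.fix_normals()  # outward orientation from signed volume
    normals = np.asarray(tm.vertex_normals, dtype=float)
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    return SurfaceMesh(
        vertices=np.asarray(tm.vertices, float),
        faces=np.asarray(tm.faces, np.int64),
        normals=normals,
    )


def save_mesh(mesh: SurfaceMesh, path: str | Path,
              vertex_scalars: dict[str, np.ndarray] | None = None,
              vertex_colors: np.ndarray | None = None) -> None:
    """Write a mesh to STL/PLY/OBJ.

    Per-vertex scalar fields (e.g. curvatures) are stored as PLY property
    columns; colors as standard PLY vertex colors.  Both are ignored for
    formats that cannot carry them.
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported mesh format: {path.suffix}")
    tm = mesh.as_trimesh()
    if vertex_colors is not None and path.suffix.lower() == ".ply":
        tm.visual.vertex_colors = (
            np.clip(np.asarray(vertex_colors, float), 0, 1) * 255
        ).astype(np.uint8)
    if vertex_scalars and path.suffix.lower() == ".ply":
        for name, values in vertex_scalars.items():
            tm.vertex_attributes[name] = np.asarray(values, dtype=np.float32)
    tm.export(str(path))


def default_mediolateral_axis(mesh: SurfaceMesh, up_axis=(0.0, 0.0, 1.0),
                              distal_fraction: float = 0.25) -> np.ndarray:
    """First principal axis of the distal slab of the mesh.

    The distal slab is the ``distal_fraction`` of the mesh's extent at the
    low end of ``up_axis`` (distal→proximal).  On a femur the widest spread
    of that slab runs mediolaterally across the condyles.
    """
    up = np.asarray(up_axis, float)
    up = up / np.linalg.norm(up)
    h = mesh.vertices @ up
    cut = h.min() + distal_fraction * (h.max() - h.min())
    slab = mesh.vertices[h <= cut]
    if len(slab) < 3:
        slab = mesh.vertices
    centered = slab - slab.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # deterministic sign: positive on the first nonzero component
    nz = np.flatnonzero(np.abs(axis) > 1e-12)
    if len(nz) and axis[nz[0]] < 0:
        axis = -axis
    return axis


def estimate_condylar_width(mesh: SurfaceMesh,
                            mediolateral_axis=None) -> float:
    """Mediolateral extent of the mesh: max − min of vertex projections.

    ``mediolateral_axis`` must be a unit 3-vector; if None, the default
    distal-slab principal axis is used.
    """
    if mediolateral_axis is None:
        axis = default_mediolateral_axis(mesh)
    else:
        axis = np.asarray(mediolateral_axis, float)
        n = np.linalg.norm(axis)
        if n < 1e-12:
            raise ValidationError("mediolateral axis must be nonzero")
        if abs(n - 1.0) > 1e-6:
            raise ValidationError("mediolateral axis must be unit length")
    proj = mesh.vertices @ axis
    return float(proj.max() - proj.min())


def fitting_radius(config: ScaleConfig, which: str) -> float:
    """Fitting radius in mm for the selected map: factor × condylar width.

    ``which`` is "ridge" (small-scale, maximal-curvature map) or "groove"
    (large-scale, minimal-curvature map).
    """
    if which == "ridge":
        return config.ridge_factor * config.condylar_width
    if which == "groove":
        return config.groove_factor * config.condylar_width
    raise ValidationError(f"which must be 'ridge' or 'groove', got {which!r}")


def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # pick the coordinate axis least aligned with the normal
    k = int(np.argmin(np.abs(normal)))
    e = np.zeros(3)
    e[k] = 1.0
    t1 = np.cross(normal, e)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return t1, t2


def principal_curvatures(mesh: SurfaceMesh, radius: float) -> CurvatureField:
    """Estimate per-vertex principal curvatures at a fitting radius (mm).

    For each vertex, all vertices within Euclidean distance ``radius`` are
    expressed in the tangent frame of the vertex normal and a quadric
    height field ``h = a u² + b u v + c v² + d u + e v`` is fitted by least
    squares.  The shape operator of the fitted patch at the origin (full
    Weingarten map, first-order terms included) gives the two principal
    curvatures, ordered ``k_max >= k_min`` and signed so that convex
    regions are positive and concave ones negative.

    Vertices with fewer than 6 in-ball neighbors are flagged undefined
    (NaN curvatures, ``defined`` False) rather than raising.
    """
    if radius <= 0:
        raise ValidationError("radius must be positive")
    verts = mesh.vertices
    tree = cKDTree(verts)
    neighborhoods = tree.query_ball_point(verts, r=radius, workers=-1)

    n = len(verts)
    k_max = np.full(n, np.nan)
    k_min = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)

    for i in range(n):
        idx = neighborhoods[i]
        if len(idx) < 6:
            continue
        normal = mesh.normals[i]
        t1, t2 = _tangent_basis(normal)
        rel = verts[idx] - verts[i]
        u = rel @ t1
        v = rel @ t2
        h = rel @ normal
        A = np.column_stack([u * u, u * v, v * v, u, v])
        coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        a, b, c, d, e = coef
        # first fundamental form of the Monge patch at the origin
        E = 1.0 + d * d
        F = d * e
        G = 1.0 + e * e
        w = np.sqrt(1.0 + d * d + e * e)
        L = 2.0 * a / w
        M = b / w
        N = 2.0 * c / w
        # shape operator S = I^{-1} II; height measured along the outward
        # normal, so convex patches curve downward: negate for the
        # convex-positive convention.
        det = E * G - F * F
        S = -np.array([[G * L - F * M, G * M - F * N],
                       [E * M - F * L, E * N - F * M]]) / det
        # S is similar to a symmetric matrix; eigenvalues are real
        tr = S[0, 0] + S[1, 1]
        dt = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
        disc = max(tr * tr / 4.0 - dt, 0.0)
        root = np.sqrt(disc)
        k1 = tr / 2.0 + root
        k2 = tr / 2.0 - root
        k_max[i] = k1
        k_min[i] = k2
        defined[i] = True

    # flag vertices whose ball is truncated by an open boundary
    bmask = mesh.boundary_vertex_mask()
    boundary = np.zeros(n, dtype=bool)
    if bmask.any():
        btree = cKDTree(verts[bmask])
        d, _ = btree.query(verts, k=1, distance_upper_bound=radius)
        boundary = np.isfinite(d)
    return CurvatureField(k_max=k_max, k_min=k_min, radius=float(radius),
                          defined=defined, boundary=boundary)
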