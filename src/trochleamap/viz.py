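"""Curvature colormapping and orthographic anteroposterior (AP) rendering.

Curvature maps are overlaid on the femur by mapping each vertex's
curvature linearly between two clamp values onto a cold→warm palette —
cold colors mark negative-to-low curvature (the concave groove on the
minimal-curvature map), warm colors mark high curvature (the ridges on
the maximal-curvature map).

Rendering is a deterministic software rasterizer: an orthographic,
z-buffered projection of Gouraud-shaded triangles, so output is
byte-reproducible across machines.  The in-plane image↔model transform is
recorded with every view, making 2D landmark clicks metrically
interpretable in millimetres.  ``make_triptych`` reproduces the standard
three-panel layout: plain model, small-scale maximal-curvature (ridge)
map, large-scale minimal-curvature (groove) map, all with identical
camera parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ValidationError
from .mesh import (CurvatureField, ScaleConfig, SurfaceMesh, fitting_radius,
                   principal_curvatures)

__all__ = [
    "ColorMap",
    "APView",
    "colorize",
    "render_ap_view",
    "make_triptych",
    "RIDGE_CLAMP",
    "GROOVE_CLAMP",
]

#: Default clamp range (1/mm) for the maximal-curvature (ridge) map.
RIDGE_CLAMP = (0.0, 0.5)
#: Default clamp range (1/mm) for the minimal-curvature (groove) map.
GROOVE_CLAMP = (-0.2, 0.05)

NEUTRAL_COLOR = (0.6, 0.6, 0.6)


def _default_palette(n: int = 256) -> np.ndarray:
    import matplotlib
    cmap = matplotlib.colormaps["turbo"]
    return np.asarray(cmap(np.linspace(0, 1, n)))[:, :3]


@dataclass
class ColorMap:
    """Linear cold→warm colormap over a clamped curvature range (1/mm)."""

    clamp_lo: float
    clamp_hi: float
    palette: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.clamp_lo < self.clamp_hi:
            raise ValidationError("require clamp_lo < clamp_hi")
        if self.palette is None:
            self.palette = _default_palette()
        self.palette = np.asarray(self.palette, float)
        if self.palette.ndim != 2 or self.palette.shape[1] != 3 \
                or len(self.palette) < 2:
            raise ValidationError("palette must be an (n>=2, 3) RGB array")

    def __call__(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, float)
        t = np.clip((v - self.clamp_lo) / (self.clamp_hi - self.clamp_lo),
                    0.0, 1.0)
        pos = t * (len(self.palette) - 1)
        i = np.floor(pos).astype(int)
        i = np.clip(i, 0, len(self.palette) - 2)
        frac = (pos - i)[:, None]
        return (1 - frac) * self.palette[i] + frac * self.palette[i + 1]


def colorize(field_: CurvatureField, which: str,
             cmap: ColorMap | None = None) -> np.ndarray:
    """Per-vertex RGB colors (floats in [0, 1]) for a curvature field.

    ``which`` selects "k_max" (ridge map) or "k_min" (groove map); the
    default clamp ranges suit cylinder-scale femoral anatomy.  Vertices
    with undefined curvature get a neutral gray.
    """
    if which == "k_max":
        values = field_.k_max
        cmap = cmap or ColorMap(*RIDGE_CLAMP)
    elif which == "k_min":
        values = field_.k_min
        cmap = cmap or ColorMap(*GROOVE_CLAMP)
    else:
        raise ValidationError("which must be 'k_max' or 'k_min'")
    colors = np.empty((len(values), 3))
    defined = field_.defined
    if defined.any():
        colors[defined] = cmap(values[defined])
    colors[~defined] = NEUTRAL_COLOR
    return colors


@dataclass
class APView:
    """An orthographic view with its invertible in-plane transform.

    ``view_axis`` points from the scene toward the viewer (+Y: looking at
    the femur from anterior), ``up_axis`` is the image's up direction in
    model space (+Z: distal→proximal).  ``origin`` is the 3D model point
    that maps to the pixel recorded in ``origin_px`` (x right, y down).
    """

    image: np.ndarray
    pixels_per_mm: float
    view_axis: np.ndarray
    up_axis: np.ndarray
    origin: np.ndarray
    origin_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.view_axis = np.asarray(self.view_axis, float)
        self.up_axis = np.asarray(self.up_axis, float)
        self.origin = np.asarray(self.origin, float)
        if abs(self.view_axis @ self.up_axis) > 1e-9:
            raise ValidationError("view_axis must be perpendicular to up_axis")
        if self.pixels_per_mm <= 0:
            raise ValidationError("pixels_per_mm must be positive")

    @property
    def right_axis(self) -> np.ndarray:
        return np.cross(self.up_axis, self.view_axis)

    def model_to_pixel(self, points: np.ndarray) -> np.ndarray:
        """Project 3D model points (mm) to (x, y) pixel coordinates."""
        p = np.atleast_2d(np.asarray(points, float)) - self.origin
        u = p @ self.right_axis
        v = p @ self.up_axis
        px = self.origin_px[0] + u * self.pixels_per_mm
        py = self.origin_px[1] - v * self.pixels_per_mm
        out = np.column_stack([px, py])
        return out[0] if np.asarray(points).ndim == 1 else out

    def pixel_to_model(self, pixels: np.ndarray) -> np.ndarray:
        """Map (x, y) pixels back to in-plane mm coordinates (right, up)."""
        q = np.atleast_2d(np.asarray(pixels, float))
        u = (q[:, 0] - self.origin_px[0]) / self.pixels_per_mm
        v = (self.origin_px[1] - q[:, 1]) / self.pixels_per_mm
        out = np.column_stack([u, v])
        return out[0] if np.asarray(pixels).ndim == 1 else out

    def save(self, path: str | Path) -> None:
        """Write the PNG plus a sidecar JSON with the camera parameters."""
        path = Path(path)
        img = (np.clip(self.image, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(img).save(path)
        meta = {
            "pixels_per_mm": self.pixels_per_mm,
            "view_axis": self.view_axis.tolist(),
            "up_axis": self.up_axis.tolist(),
            "origin": self.origin.tolist(),
            "origin_px": list(self.origin_px),
            "image_size": [int(self.image.shape[1]), int(self.image.shape[0])],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def render_ap_view(mesh: SurfaceMesh, colors: np.ndarray | None = None,
                   view_axis=(0.0, 1.0, 0.0), up_axis=(0.0, 0.0, 1.0),
                   pixels_per_mm: float = 2.0, margin_mm: float = 2.0,
                   background=(1.0, 1.0, 1.0)) -> APView:
    """Orthographic depth-buffered render of a vertex-colored mesh.

    Triangles facing away from the viewer are kept (the z-buffer resolves
    visibility); vertex colors are interpolated barycentrically.  With
    ``colors=None`` the mesh is shaded by a fixed headlight (plain view).
    """
    w = np.asarray(view_axis, float)
    u = np.asarray(up_axis, float)
    w = w / np.linalg.norm(w)
    u = u / np.linalg.norm(u)
    if abs(w @ u) > 1e-9:
        raise ValidationError("view_axis must be perpendicular to up_axis")
    r = np.cross(u, w)

    verts = mesh.vertices
    pu = verts @ r
    pv = verts @ u
    pw = verts @ w
    u_min, u_max = pu.min() - margin_mm, pu.max() + margin_mm
    v_min, v_max = pv.min() - margin_mm, pv.max() + margin_mm
    width = max(int(np.ceil((u_max - u_min) * pixels_per_mm)), 1)
    height = max(int(np.ceil((v_max - v_min) * pixels_per_mm)), 1)
    if width * height == 0:
        raise ValidationError("empty render")

    if colors is None:
        # headlight shading: lambert term against the view direction
        lam = np.clip(mesh.normals @ w, 0.0, 1.0)
        colors = np.outer(0.25 + 0.75 * lam, np.ones(3)) * \
            np.array([0.93, 0.90, 0.85])
    colors = np.asarray(colors, float)
    if colors.shape != (len(verts), 3):
        raise ValidationError("colors must be (n_vertices, 3)")

    px = (pu - u_min) * pixels_per_mm
    py = (v_max - pv) * pixels_per_mm
    img = np.empty((height, width, 3), float)
    img[:] = background
    zbuf = np.full((height, width), -np.inf)

    tri_px = px[mesh.faces]
    tri_py = py[mesh.faces]
    tri_z = pw[mesh.faces]
    tri_c = colors[mesh.faces]
    x0 = np.clip(np.floor(tri_px.min(axis=1)).astype(int), 0, width - 1)
    x1 = np.clip(np.ceil(tri_px.max(axis=1)).astype(int), 0, width - 1)
    y0 = np.clip(np.floor(tri_py.min(axis=1)).astype(int), 0, height - 1)
    y1 = np.clip(np.ceil(tri_py.max(axis=1)).astype(int), 0, height - 1)

    for t in range(len(mesh.faces)):
        ax, ay = tri_px[t, 0], tri_py[t, 0]
        bx, by = tri_px[t, 1], tri_py[t, 1]
        cx, cy = tri_px[t, 2], tri_py[t, 2]
        den = (by - cy) * (ax - cx) + (cx - bx) * (ay - cy)
        if abs(den) < 1e-12:
            continue
        xs = np.arange(x0[t], x1[t] + 1)
        ys = np.arange(y0[t], y1[t] + 1)
        if len(xs) == 0 or len(ys) == 0:
            continue
        X, Y = np.meshgrid(xs + 0.5, ys + 0.5)
        l1 = ((by - cy) * (X - cx) + (cx - bx) * (Y - cy)) / den
        l2 = ((cy - ay) * (X - cx) + (ax - cx) * (Y - cy)) / den
        l3 = 1.0 - l1 - l2
        inside = (l1 >= -1e-9) & (l2 >= -1e-9) & (l3 >= -1e-9)
        if not inside.any():
            continue
        z = l1 * tri_z[t, 0] + l2 * tri_z[t, 1] + l3 * tri_z[t, 2]
        sub = zbuf[y0[t]:y1[t] + 1, x0[t]:x1[t] + 1]
        win = inside & (z > sub)
        if not win.any():
            continue
        col = (l1[..., None] * tri_c[t, 0] + l2[..., None] * tri_c[t, 1]
               + l3[..., None] * tri_c[t, 2])
        sub[win] = z[win]
        img[y0[t]:y1[t] + 1, x0[t]:x1[t] + 1][win] = col[win]

    origin = u_min * r + v_max * u  # model point at pixel (0, 0)
    return APView(image=img, pixels_per_mm=pixels_per_mm, view_axis=w,
                  up_axis=u, origin=origin, origin_px=(0.0, 0.0))


def make_triptych(mesh: SurfaceMesh, config: ScaleConfig,
                  pixels_per_mm: float = 2.0,
                  ridge_field: CurvatureField | None = None,
                  groove_field: CurvatureField | None = None,
                  **camera) -> tuple[APView, APView, APView]:
    """Three AP views with identical cameras: plain, ridge map, groove map.

    The ridge panel shows maximal curvature at the small fitting radius
    (ridge_factor × condylar width), the groove panel minimal curvature at
    the large radius.  Precomputed fields may be passed to skip the
    curvature estimation.
    """
    if ridge_field is None:
        ridge_field = principal_curvatures(mesh, fitting_radius(config, "ridge"))
    if groove_field is None:
        groove_field = principal_curvatures(mesh, fitting_radius(config, "groove"))
    plain = render_ap_view(mesh, None, pixels_per_mm=pixels_per_mm, **camera)
    ridge = render_ap_view(mesh, colorize(ridge_field, "k_max"),
                           pixels_per_mm=pixels_per_mm, **camera)
    groove = render_ap_view(mesh, colorize(groove_field, "k_min"),
                            pixels_per_mm=pixels_per_mm, **camera)
    return plain, ridge, groove
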