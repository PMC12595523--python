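"""Deterministic flat-shading software rasterizer.

Renders triangle meshes with one unlit RGB color per object into an RGB
pixel buffer using a z-buffer — no lighting, no anti-aliasing, no GPU.
Determinism is the point: the same scene and camera always produce
byte-identical images, and with flat shading the set of distinct pixel
colors in a frame is exactly the set of object colors plus background,
which makes rendered output checkable in tests.

Two passes: translucent *underlay* meshes (anatomical context such as the
body outline) are depth-resolved among themselves and alpha-composited
over the background exactly once, then opaque meshes are drawn with their
own z-buffer on top.  Opaque neurons therefore always read on top of the
translucent body — the worm-anatomy behaviour wanted here (neurons visible
through the cuticle) — and every context pixel is one predictable blend,
never a stack of semi-transparent layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RasterMesh", "render_frame", "look_at", "perspective"]

_NEAR_EPS = 1e-6


@dataclass
class RasterMesh:
    """One renderable object: triangle soup + flat RGBA color."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray     # (m, 3) int
    color: tuple[float, float, float, float]
    opaque: bool = True


def look_at(eye, target, up) -> np.ndarray:
    """Right-handed world->view matrix (camera looks down -z)."""
    eye = np.asarray(eye, dtype=float)
    target = np.asarray(target, dtype=float)
    up = np.asarray(up, dtype=float)
    fwd = target - eye
    n = np.linalg.norm(fwd)
    if n == 0:
        raise ValueError("camera eye equals target")
    fwd = fwd / n
    right = np.cross(fwd, up)
    rn = np.linalg.norm(right)
    if rn < 1e-12:  # up parallel to view direction: pick any perpendicular
        up = np.array([0.0, 0.0, 1.0]) if abs(fwd[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        right = np.cross(fwd, up)
        rn = np.linalg.norm(right)
    right = right / rn
    true_up = np.cross(right, fwd)
    view = np.eye(4)
    view[0, :3], view[1, :3], view[2, :3] = right, true_up, -fwd
    view[:3, 3] = -view[:3, :3] @ eye
    return view


def perspective(fov_y_deg: float, aspect: float, near: float, far: float) -> np.ndarray:
    f = 1.0 / np.tan(np.radians(fov_y_deg) / 2.0)
    proj = np.zeros((4, 4))
    proj[0, 0] = f / aspect
    proj[1, 1] = f
    proj[2, 2] = (far + near) / (near - far)
    proj[2, 3] = 2 * far * near / (near - far)
    proj[3, 2] = -1.0
    return proj


def _clip_near(tri_clip: np.ndarray, near_w: float) -> list[np.ndarray]:
    """Sutherland-Hodgman clip of one clip-space triangle against w>near_w."""
    inside = tri_clip[:, 3] > near_w
    if inside.all():
        return [tri_clip]
    if not inside.any():
        return []
    poly = []
    for i in range(3):
        a, b = tri_clip[i], tri_clip[(i + 1) % 3]
        ain, bin_ = inside[i], inside[(i + 1) % 3]
        if ain:
            poly.append(a)
        if ain != bin_:
            t = (near_w - a[3]) / (b[3] - a[3])
            poly.append(a + t * (b - a))
    return [np.stack([poly[0], poly[k], poly[k + 1]])
            for k in range(1, len(poly) - 1)]


def _raster_triangle(px: np.ndarray, depth: np.ndarray, img: np.ndarray,
                     color: np.ndarray) -> None:
    """Fill one screen-space triangle (px: 3x3 of x,y,ndc-z) into img.

    Depth-tested replacement write; `color` may have as many channels as
    the target image (RGB for the main pass, RGBA for the underlay)."""
    h, w = depth.shape
    xs, ys = px[:, 0], px[:, 1]
    x0 = max(int(np.floor(xs.min())), 0)
    x1 = min(int(np.ceil(xs.max())), w - 1)
    y0 = max(int(np.floor(ys.min())), 0)
    y1 = min(int(np.ceil(ys.max())), h - 1)
    if x1 < x0 or y1 < y0:
        return
    gx, gy = np.meshgrid(np.arange(x0, x1 + 1) + 0.5, np.arange(y0, y1 + 1) + 0.5)
    d = np.empty((3,) + gx.shape)
    for i in range(3):
        ax, ay = xs[i], ys[i]
        bx, by = xs[(i + 1) % 3], ys[(i + 1) % 3]
        # edge function: cross((B-A), (P-A)); same convention as `area`
        d[i] = (bx - ax) * (gy - ay) - (by - ay) * (gx - ax)
    area = (xs[1] - xs[0]) * (ys[2] - ys[0]) - (ys[1] - ys[0]) * (xs[2] - xs[0])
    if area == 0:
        return
    cover = (d >= 0).all(axis=0) if area > 0 else (d <= 0).all(axis=0)
    if not cover.any():
        return
    # barycentric depth; ndc z is affine in screen space under perspective
    b0, b1, b2 = d[1] / area, d[2] / area, d[0] / area
    z = b0 * px[0, 2] + b1 * px[1, 2] + b2 * px[2, 2]
    sub_depth = depth[y0:y1 + 1, x0:x1 + 1]
    win = cover & (z < sub_depth)
    if not win.any():
        return
    sub_img = img[y0:y1 + 1, x0:x1 + 1]
    sub_img[win] = color
    sub_depth[win] = z[win]


def render_frame(
    meshes: list[RasterMesh],
    eye,
    target,
    up,
    fov_y_deg: float,
    resolution: tuple[int, int],
    background: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Render to an (h, w, 3) uint8 array.

    Translucent meshes (``opaque=False``) form an underlay: their nearest
    surface is composited over the background exactly once; opaque meshes
    are then z-buffered on top.  Colors are quantized to 8 bits only once,
    at the very end, so a flat surface is a single uint8 color.
    """
    w, h = int(resolution[0]), int(resolution[1])
    if w <= 0 or h <= 0:
        raise ValueError("resolution must be positive")
    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(background, dtype=float)
    depth = np.full((h, w), np.inf)

    view = look_at(eye, target, up)
    # near/far from scene depth range in view space
    eye = np.asarray(eye, dtype=float)
    dists = []
    for m in meshes:
        if len(m.vertices):
            v = np.c_[m.vertices, np.ones(len(m.vertices))] @ view.T
            dists.append(-v[:, 2])
    if not dists:
        return (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    allz = np.concatenate(dists)
    far = max(float(allz.max()) * 1.05, 1e-3)
    near = max(float(allz[allz > 0].min()) * 0.5 if (allz > 0).any() else far * 1e-4,
               far * 1e-5)
    proj = perspective(fov_y_deg, w / h, near, far)
    pv = proj @ view

    def draw(mesh: RasterMesh, target: np.ndarray, zbuf: np.ndarray,
             color: np.ndarray) -> None:
        if len(mesh.faces) == 0:
            return
        clip = np.c_[mesh.vertices, np.ones(len(mesh.vertices))] @ pv.T
        tris = clip[np.asarray(mesh.faces, dtype=np.int64)]
        for tri in tris:
            for piece in _clip_near(tri, near * _NEAR_EPS + 1e-9):
                ndc = piece[:, :3] / piece[:, 3:4]
                px = np.empty((3, 3))
                px[:, 0] = (ndc[:, 0] + 1.0) * 0.5 * w
                px[:, 1] = (1.0 - ndc[:, 1]) * 0.5 * h
                px[:, 2] = ndc[:, 2]
                _raster_triangle(px, zbuf, target, color)

    # underlay pass: translucent meshes rasterized with their own depth
    # buffer into an RGBA layer, so only the nearest context surface
    # counts; the layer is then composited over the background exactly once
    translucent = [m for m in meshes if not m.opaque]
    if translucent:
        layer = np.zeros((h, w, 4))
        layer_depth = np.full((h, w), np.inf)
        for m in translucent:
            draw(m, layer, layer_depth, np.asarray(m.color, dtype=float))
        a = layer[:, :, 3:4]
        img = a * layer[:, :, :3] + (1.0 - a) * img
    for m in meshes:
        if m.opaque:
            draw(m, img, depth, np.asarray(m.color[:3], dtype=float))
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
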