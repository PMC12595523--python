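"""Point/mesh proximity: exact distances and containment, pure numpy.

Used by neuron picking.  Distances are exact point-to-triangle distances
(region classification on barycentric coordinates, vectorized over all
triangles of a mesh for a batch of query points); containment uses
ray-crossing parity along a fixed direction with Möller–Trumbore
intersection tests.  No spatial index is built — mesh sizes here (soma
spheres, neurite tubes) are small enough that the dense computation wins.
"""

from __future__ import annotations

import numpy as np

__all__ = ["point_triangle_distances", "points_to_mesh_distance", "points_in_mesh"]


def point_triangle_distances(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Pairwise distances: (n_points, n_triangles).

    `triangles` is (m, 3, 3).  Implements the standard closest-point-on-
    triangle region test (Voronoi regions of vertices, edges, interior)
    on barycentric/edge parameters, fully vectorized.
    """
    p = np.asarray(points, dtype=float)[:, None, :]          # (n, 1, 3)
    a = np.asarray(triangles, dtype=float)[None, :, 0, :]    # (1, m, 3)
    b = np.asarray(triangles, dtype=float)[None, :, 1, :]
    c = np.asarray(triangles, dtype=float)[None, :, 2, :]
    ab, ac, ap = b - a, c - a, p - a

    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)
    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)
    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    denom_edge_ab = d1 - d3
    denom_edge_ac = d2 - d6
    denom_edge_bc = (d4 - d3) + (d5 - d6)

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(denom_edge_ab != 0, d1 / denom_edge_ab, 0.0)
        w_ac = np.where(denom_edge_ac != 0, d2 / denom_edge_ac, 0.0)
        w_bc = np.where(denom_edge_bc != 0, (d4 - d3) / denom_edge_bc, 0.0)
        denom = va + vb + vc
        v_in = np.where(denom != 0, vb / denom, 0.0)
        w_in = np.where(denom != 0, vc / denom, 0.0)

    # start from the interior projection, then overwrite edge regions,
    # then vertex regions (most specific last)
    closest = a + v_in[..., None] * ab + w_in[..., None] * ac
    m_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    closest = np.where(m_bc[..., None],
                       b + np.clip(w_bc, 0, 1)[..., None] * (c - b), closest)
    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest = np.where(m_ac[..., None],
                       a + np.clip(w_ac, 0, 1)[..., None] * ac, closest)
    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest = np.where(m_ab[..., None],
                       a + np.clip(v_ab, 0, 1)[..., None] * ab, closest)
    m_c = (d6 >= 0) & (d5 <= d6)
    closest = np.where(m_c[..., None], np.broadcast_to(c, closest.shape), closest)
    m_b = (d3 >= 0) & (d4 <= d3)
    closest = np.where(m_b[..., None], np.broadcast_to(b, closest.shape), closest)
    m_a = (d1 <= 0) & (d2 <= 0)
    closest = np.where(m_a[..., None], np.broadcast_to(a, closest.shape), closest)
    return np.linalg.norm(p - closest, axis=-1)


def points_to_mesh_distance(points: np.ndarray, mesh) -> np.ndarray:
    """Min distance from each point to a trimesh surface; (n,) array."""
    tris = np.asarray(mesh.triangles, dtype=float)
    points = np.atleast_2d(points)
    # chunk over points to bound memory on large meshes
    out = np.empty(len(points))
    step = max(1, int(2_000_000 / max(len(tris), 1)))
    for i in range(0, len(points), step):
        out[i:i + step] = point_triangle_distances(points[i:i + step], tris).min(axis=1)
    return out


# skewed, mutually non-parallel directions so no fixture-aligned plane or
# edge can fool all of them at once
_RAY_DIRECTIONS = (
    (0.5735393, 0.6179673, 0.5377623),
    (-0.2672612, 0.5345225, 0.8017837),
    (0.8111071, -0.3244428, 0.4866643),
)


def points_in_mesh(points: np.ndarray, mesh) -> np.ndarray:
    """Ray-parity containment test for (closed) meshes; (n,) bool array.

    Multi-body meshes (e.g. a soma sphere with an attached, mutually
    intersecting neurite tube) are split into connected components and a
    point counts as inside if it is inside any component — global parity
    over a self-intersecting union would misclassify the overlap region.
    Per component, rays are cast along three skewed fixed directions and
    crossings counted (Möller–Trumbore; odd = inside) with a majority
    vote, so a single ray grazing an edge cannot flip the answer.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    try:
        parts = mesh.split(only_watertight=False) if mesh.body_count > 1 \
            else [mesh]
    except Exception:
        parts = [mesh]
    inside = np.zeros(len(points), dtype=bool)
    for part in parts:
        votes = np.zeros(len(points), dtype=int)
        for d in _RAY_DIRECTIONS:
            votes += _ray_parity(points, part, d)
        inside |= votes >= 2
    return inside


def _ray_parity(points: np.ndarray, mesh, direction) -> np.ndarray:
    tris = np.asarray(mesh.triangles, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    v0 = tris[None, :, 0, :]
    e1 = tris[None, :, 1, :] - v0
    e2 = tris[None, :, 2, :] - v0
    pvec = np.cross(d, e2)
    det = np.sum(e1 * pvec, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(np.abs(det) > 1e-12, 1.0 / det, 0.0)
        tvec = points[:, None, :] - v0
        u = np.sum(tvec * pvec, axis=-1) * inv
        qvec = np.cross(tvec, e1)
        v = np.sum(qvec * d, axis=-1) * inv
        t = np.sum(e2 * qvec, axis=-1) * inv
    hit = (np.abs(det) > 1e-12) & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-10)
    return (hit.sum(axis=1) % 2).astype(int)
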