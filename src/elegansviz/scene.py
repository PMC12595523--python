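"""Colored 3D scenes: assembly, export, rendering, and neuron picking.

A :class:`Scene` binds an anatomy model to a color map derived from a
signature partition or a sender/receiver role map: colored neurons get
opaque flat materials, uncolored neurons a neutral grey, context anatomy a
translucent material.  Scenes can be exported to glTF 2.0, OBJ+MTL, or a
PLY directory with the per-object color quantized to 8 bits per channel,
rendered to PNG with the package's flat-shading rasterizer, and queried
with 3D points to identify the nearest neuron — the headless equivalent of
clicking a cell in a viewport.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
from PIL import Image

from . import geometry, mesh_io, raster
from .anatomy import AnatomyModel, ModelError
from .coexpression import (
    BACKGROUND_COLOR,
    CONTEXT_COLOR,
    NEUTRAL_COLOR,
    RGBA,
    ColorMap,
    SignaturePartition,
)

__all__ = [
    "CameraSpec",
    "Scene",
    "SceneError",
    "RenderUnavailableError",
    "build_scene",
    "camera_preset",
    "export_scene",
    "import_scene_colors",
    "validate_gltf",
    "render",
    "turntable",
    "pick_neuron",
    "pick_neurons",
    "quantize_rgba",
    "dequantize_rgba",
]

PRESETS = ("whole_worm", "head", "midbody", "tail", "custom")


class SceneError(ValueError):
    """Scene construction or export failure."""


class RenderUnavailableError(RuntimeError):
    """Raised when no renderer can run; scene export remains usable."""


@dataclass(frozen=True)
class CameraSpec:
    """Camera: preset tag, pose, vertical field of view, output size."""

    preset: str = "custom"
    eye: tuple[float, float, float] = (0.0, 0.0, 10.0)
    target: tuple[float, float, float] = (0.0, 0.0, 0.0)
    up: tuple[float, float, float] = (0.0, 1.0, 0.0)
    fov: float = 40.0
    resolution: tuple[int, int] = (640, 480)

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown camera preset {self.preset!r}")
        if tuple(self.eye) == tuple(self.target):
            raise ValueError("camera eye must differ from target")
        if self.resolution[0] <= 0 or self.resolution[1] <= 0:
            raise ValueError("resolution must be positive")
        if not 0 < self.fov < 180:
            raise ValueError("fov must be in (0, 180) degrees")


@dataclass
class Scene:
    """Renderable assembly: model + per-cell colors + camera."""

    model: AnatomyModel
    colormap: ColorMap
    cell_colors: dict[str, RGBA] = field(default_factory=dict)
    visible_cells: set[str] = field(default_factory=set)
    show_context: bool = True
    soma_radius: float = 1.0
    camera: CameraSpec | None = None
    # soma-sphere stand-ins for colored cells lacking a mesh
    stand_ins: dict[str, trimesh.Trimesh] = field(default_factory=dict)

    def mesh_of(self, cell: str) -> trimesh.Trimesh:
        if cell in self.model.neuron_meshes:
            return self.model.neuron_meshes[cell]
        if cell in self.stand_ins:
            return self.stand_ins[cell]
        raise KeyError(cell)

    def color_of(self, cell: str) -> RGBA:
        return self.cell_colors.get(cell, self.colormap.neutral_color)

    @property
    def visible_neurons(self) -> list[str]:
        return sorted(self.visible_cells)


def _soma_sphere(center: np.ndarray, radius: float) -> trimesh.Trimesh:
    sphere = trimesh.creation.icosphere(subdivisions=2, radius=radius)
    sphere.apply_translation(np.asarray(center, dtype=float))
    return sphere


def build_scene(
    model: AnatomyModel,
    colormap: ColorMap,
    partition_or_roles: SignaturePartition | dict[str, str] | None,
    *,
    include_uncolored: bool = True,
    soma_radius: float = 1.0,
    camera: CameraSpec | None = None,
) -> Scene:
    """Assemble a renderable scene from a partition or role map.

    Cells of each partition block receive the block's color; with a role
    map, cells are colored by role tag (the ``"none"`` role stays
    uncolored).  Uncolored neurons that have meshes are kept as neutral
    grey background anatomy when `include_uncolored` is set.  A colored
    cell with no mesh gets a soma-sphere stand-in of radius `soma_radius`
    at its soma position; a colored name absent from the roster altogether
    is an error.
    """
    roster_names = set(model.roster.cell_names)
    cell_colors: dict[str, RGBA] = {}
    if isinstance(partition_or_roles, SignaturePartition):
        for sig, cells in partition_or_roles.blocks.items():
            try:
                color = colormap.entries[sig]
            except KeyError:
                raise SceneError(
                    f"colormap lacks an entry for signature {sig.bitstring()}"
                ) from None
            for cell in cells:
                cell_colors[cell] = color
    elif partition_or_roles:
        for cell, role in partition_or_roles.items():
            if role == "none":
                continue
            if role not in colormap.entries:
                raise SceneError(f"colormap lacks an entry for role {role!r}")
            cell_colors[cell] = colormap.entries[role]

    unknown = set(cell_colors) - roster_names
    if unknown:
        raise SceneError(f"colored cells not in roster: {sorted(unknown)}")

    stand_ins: dict[str, trimesh.Trimesh] = {}
    for cell in sorted(cell_colors):
        if cell in model.neuron_meshes:
            continue
        pos = model.soma_positions.get(cell)
        if pos is None:
            rec = model.roster.cell(cell)
            pos = rec.soma_position
        if pos is None:
            raise SceneError(
                f"cell {cell} has neither a mesh nor a soma position"
            )
        stand_ins[cell] = _soma_sphere(np.asarray(pos, dtype=float), soma_radius)

    visible = set(cell_colors)
    if include_uncolored:
        visible |= set(model.neuron_meshes)
    return Scene(
        model=model,
        colormap=colormap,
        cell_colors=cell_colors,
        visible_cells=visible,
        soma_radius=soma_radius,
        camera=camera,
        stand_ins=stand_ins,
    )


# ---------------------------------------------------------------- cameras

def camera_preset(
    model: AnatomyModel | np.ndarray,
    preset: str = "whole_worm",
    resolution: tuple[int, int] = (640, 480),
    fov: float = 40.0,
) -> CameraSpec:
    """Build a camera from the model's bounding box.

    Presets are defined relative to the bounding box, not to anatomical
    axes (the model's coordinate frame is preserved as-is): the worm's
    long axis is taken to be the box's longest extent, ``head`` is the
    quarter of that axis containing the most neuron somas (in
    C. elegans most neurons cluster in the head ganglia), ``tail`` the
    opposite quarter, ``midbody`` the central quarter.  The eye sits along
    the box's thinnest axis so the worm is seen side-on.
    """
    if preset not in PRESETS or preset == "custom":
        raise ValueError(f"cannot derive a {preset!r} camera from the bounds")
    if isinstance(model, AnatomyModel):
        bounds = model.bounds
        somata = np.array(list(model.soma_positions.values())) \
            if model.soma_positions else np.empty((0, 3))
    else:
        bounds = np.asarray(model, dtype=float)
        somata = np.empty((0, 3))
    extent = bounds[1] - bounds[0]
    long_ax = int(np.argmax(extent))
    thin_ax = int(np.argmin(extent))
    if thin_ax == long_ax:
        thin_ax = (long_ax + 1) % 3
    up_ax = 3 - long_ax - thin_ax

    lo, hi = bounds[0][long_ax], bounds[1][long_ax]
    if preset == "whole_worm":
        window = (lo, hi)
    elif preset == "midbody":
        window = (lo + 0.375 * (hi - lo), lo + 0.625 * (hi - lo))
    else:
        low_end = (lo, lo + 0.25 * (hi - lo))
        high_end = (hi - 0.25 * (hi - lo), hi)
        if len(somata):
            n_low = int(((somata[:, long_ax] >= low_end[0])
                         & (somata[:, long_ax] <= low_end[1])).sum())
            n_high = int(((somata[:, long_ax] >= high_end[0])
                          & (somata[:, long_ax] <= high_end[1])).sum())
        else:
            n_low = n_high = 0
        head_window = high_end if n_high > n_low else low_end
        window = head_window if preset == "head" else (
            low_end if head_window == high_end else high_end)

    target = (bounds[0] + bounds[1]) / 2.0
    target[long_ax] = (window[0] + window[1]) / 2.0
    # fit the window diagonal in the vertical field of view
    span = np.array([window[1] - window[0], extent[up_ax]])
    radius = 0.6 * float(np.linalg.norm(span)) + 1e-6
    dist = radius / np.tan(np.radians(fov) / 2.0)
    eye = target.copy()
    eye[thin_ax] += dist + extent[thin_ax]
    up = np.zeros(3)
    up[up_ax] = 1.0
    return CameraSpec(
        preset=preset,
        eye=tuple(float(x) for x in eye),
        target=tuple(float(x) for x in target),
        up=tuple(float(x) for x in up),
        fov=fov,
        resolution=resolution,
    )


# ---------------------------------------------------------------- export

def quantize_rgba(color: RGBA) -> tuple[int, int, int, int]:
    """RGBA floats in [0,1] -> 8-bit channels (round-half-up)."""
    return tuple(int(round(float(c) * 255)) for c in color)


def dequantize_rgba(q: tuple[int, int, int, int]) -> RGBA:
    return tuple(round(c / 255.0, 8) for c in q)


def _scene_objects(scene: Scene) -> dict[str, tuple[trimesh.Trimesh, RGBA, bool]]:
    """name -> (mesh, color, opaque) for every exported/rendered object."""
    objects: dict[str, tuple[trimesh.Trimesh, RGBA, bool]] = {}
    for cell in sorted(scene.visible_cells):
        try:
            mesh = scene.mesh_of(cell)
        except KeyError:
            continue
        objects[cell] = (mesh, scene.color_of(cell), True)
    if scene.show_context:
        for name, mesh in sorted(scene.model.context_meshes.items()):
            objects[name] = (mesh, scene.colormap.context_color, False)
    return objects


def export_scene(scene: Scene, fmt: str, path: str | Path) -> Path:
    """Write the colored scene to disk.

    ``gltf`` — single-file glTF 2.0 with embedded buffers (or ``.glb``
    when the path says so), one PBR material per object with the object's
    color as 8-bit ``baseColorFactor``; ``obj`` — OBJ+MTL with one material
    per distinct color; ``ply`` — a directory of ASCII PLY files (PLY has
    no object names, so names live in the filenames) with uniform vertex
    colors.  Colors are quantized to 8 bits per channel; re-importing
    returns exactly the quantized colors.
    """
    path = Path(path)
    objects = _scene_objects(scene)
    if not objects:
        raise SceneError("nothing to export: scene has no visible meshes")
    if fmt == "gltf":
        tsc = trimesh.Scene()
        for name, (mesh, color, opaque) in objects.items():
            m = mesh.copy()
            q = quantize_rgba(color)
            material = trimesh.visual.material.PBRMaterial(
                name=f"color_{q[0]:02x}{q[1]:02x}{q[2]:02x}{q[3]:02x}",
                baseColorFactor=list(q),
                alphaMode=None if opaque and q[3] == 255 else "BLEND",
            )
            m.visual = trimesh.visual.TextureVisuals(material=material)
            tsc.add_geometry(m, node_name=name, geom_name=name)
        if path.suffix.lower() == ".glb":
            path.write_bytes(trimesh.exchange.gltf.export_glb(tsc))
        else:
            files = trimesh.exchange.gltf.export_gltf(tsc, embed_buffers=True)
            path.write_bytes(files["model.gltf"])
        return path
    if fmt == "obj":
        named = mesh_io.NamedMeshes()
        for name, (mesh, color, _opaque) in objects.items():
            named.meshes[name] = mesh
            named.colors[name] = dequantize_rgba(quantize_rgba(color))
        return mesh_io.write_obj(named, path)
    if fmt == "ply":
        path.mkdir(parents=True, exist_ok=True)
        for name, (mesh, color, _opaque) in objects.items():
            m = mesh.copy()
            q = quantize_rgba(color)
            m.visual = trimesh.visual.ColorVisuals(
                m, vertex_colors=np.tile(np.array(q, dtype=np.uint8),
                                         (len(m.vertices), 1)))
            m.export(path / f"{name}.ply", encoding="ascii")
        return path
    raise SceneError(f"unsupported export format {fmt!r}")


def import_scene_colors(path: str | Path) -> dict[str, RGBA]:
    """Read back an exported scene's object -> RGBA binding (quantized)."""
    path = Path(path)
    colors: dict[str, RGBA] = {}
    if path.is_dir():  # ply directory
        for p in sorted(path.glob("*.ply")):
            mesh = trimesh.load(p, process=False, force="mesh")
            q = tuple(int(c) for c in np.asarray(mesh.visual.vertex_colors[0]))
            colors[p.stem] = dequantize_rgba(q)
        return colors
    if path.suffix.lower() == ".obj":
        named = mesh_io.read_obj(path)
        for name in named.meshes:
            if name in named.colors:
                c = named.colors[name]
                colors[name] = dequantize_rgba(quantize_rgba(c))
        return colors
    if path.suffix.lower() in (".gltf", ".glb"):
        tsc = trimesh.load(path, process=False)
        geoms = tsc.geometry if isinstance(tsc, trimesh.Scene) else {path.stem: tsc}
        for name, mesh in geoms.items():
            factor = getattr(mesh.visual.material, "baseColorFactor", None)
            if factor is not None:
                arr = np.asarray(factor, dtype=float)
                if arr.max() <= 1.0 and arr.dtype.kind == "f":
                    arr = arr * 255.0
                colors[name] = dequantize_rgba(tuple(int(round(v)) for v in arr))
        return colors
    raise SceneError(f"cannot import scene colors from {path}")


def validate_gltf(path: str | Path) -> list[str]:
    """Structural glTF 2.0 validation; returns a list of problems (empty = ok).

    Checks the required asset version, presence and cross-consistency of
    the top-level arrays (scene/node/mesh/accessor/bufferView/buffer
    indices all in range, primitive attributes resolvable).
    """
    problems: list[str] = []
    raw = Path(path).read_bytes()
    if raw[:4] == b"glTF":  # binary container: JSON chunk starts at byte 20
        length = int.from_bytes(raw[12:16], "little")
        doc = json.loads(raw[20:20 + length].decode("utf-8"))
    else:
        doc = json.loads(raw.decode("utf-8"))
    asset = doc.get("asset")
    if not isinstance(asset, dict) or asset.get("version") != "2.0":
        problems.append("asset.version must be '2.0'")
    n = {k: len(doc.get(k, [])) for k in
         ("scenes", "nodes", "meshes", "accessors", "bufferViews",
          "buffers", "materials")}
    if "scene" in doc and not (0 <= doc["scene"] < n["scenes"]):
        problems.append("default scene index out of range")
    for i, sc in enumerate(doc.get("scenes", [])):
        for node in sc.get("nodes", []):
            if not (0 <= node < n["nodes"]):
                problems.append(f"scenes[{i}] references bad node {node}")
    for i, node in enumerate(doc.get("nodes", [])):
        if "mesh" in node and not (0 <= node["mesh"] < n["meshes"]):
            problems.append(f"nodes[{i}] references bad mesh")
        for child in node.get("children", []):
            if not (0 <= child < n["nodes"]):
                problems.append(f"nodes[{i}] references bad child {child}")
    for i, mesh in enumerate(doc.get("meshes", [])):
        for prim in mesh.get("primitives", []):
            if "POSITION" not in prim.get("attributes", {}):
                problems.append(f"meshes[{i}] primitive lacks POSITION")
            refs = list(prim.get("attributes", {}).values())
            refs += [prim[k] for k in ("indices",) if k in prim]
            for acc in refs:
                if not (0 <= acc < n["accessors"]):
                    problems.append(f"meshes[{i}] references bad accessor {acc}")
            if "material" in prim and not (0 <= prim["material"] < n["materials"]):
                problems.append(f"meshes[{i}] references bad material")
    for i, acc in enumerate(doc.get("accessors", [])):
        for key in ("componentType", "count", "type"):
            if key not in acc:
                problems.append(f"accessors[{i}] lacks {key}")
        if "bufferView" in acc and not (0 <= acc["bufferView"] < n["bufferViews"]):
            problems.append(f"accessors[{i}] references bad bufferView")
    for i, bv in enumerate(doc.get("bufferViews", [])):
        if not (0 <= bv.get("buffer", -1) < n["buffers"]):
            problems.append(f"bufferViews[{i}] references bad buffer")
        if "byteLength" not in bv:
            problems.append(f"bufferViews[{i}] lacks byteLength")
    for i, buf in enumerate(doc.get("buffers", [])):
        if "byteLength" not in buf:
            problems.append(f"buffers[{i}] lacks byteLength")
    return problems


# ---------------------------------------------------------------- render

def render(
    scene: Scene,
    spec: CameraSpec | None = None,
    out_path: str | Path | None = None,
) -> np.ndarray:
    """Flat-shaded render to an (h, w, 3) uint8 array (and optional PNG).

    Unlit flat shading, no anti-aliasing: every rendered pixel is exactly
    the background color, the context-over-background blend, or one of the
    object colors — and identical inputs give byte-identical images.
    """
    spec = spec or scene.camera
    if spec is None:
        spec = camera_preset(scene.model, "whole_worm")
    objects = _scene_objects(scene)
    meshes = [
        raster.RasterMesh(
            vertices=np.asarray(mesh.vertices, dtype=float),
            faces=np.asarray(mesh.faces, dtype=np.int64),
            color=dequantize_rgba(quantize_rgba(color)),
            opaque=opaque,
        )
        for _name, (mesh, color, opaque) in objects.items()
    ]
    img = raster.render_frame(
        meshes, spec.eye, spec.target, spec.up, spec.fov, spec.resolution,
        background=scene.colormap.background_color[:3],
    )
    if out_path is not None:
        Image.fromarray(img).save(Path(out_path), format="PNG")
    return img


def turntable(
    scene: Scene,
    n_frames: int,
    out_dir: str | Path,
    spec: CameraSpec | None = None,
) -> list[Path]:
    """Render `n_frames` PNGs orbiting the camera about its up axis.

    Frame 0 is the render at the starting camera; frame k rotates the eye
    by ``k * 360/n`` degrees around the target.  Video encoding is left to
    external tools (e.g. ffmpeg over the numbered frames).
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    spec = spec or scene.camera or camera_preset(scene.model, "whole_worm")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    eye = np.asarray(spec.eye, dtype=float)
    target = np.asarray(spec.target, dtype=float)
    up = np.asarray(spec.up, dtype=float)
    up = up / np.linalg.norm(up)
    paths = []
    for k in range(n_frames):
        angle = 2.0 * np.pi * k / n_frames
        rot = trimesh.transformations.rotation_matrix(angle, up, point=target)
        eye_k = (rot @ np.append(eye, 1.0))[:3]
        spec_k = replace(spec, preset="custom", eye=tuple(eye_k))
        p = out_dir / f"frame_{k:04d}.png"
        render(scene, spec_k, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------- picking

def pick_neurons(scene: Scene, points: np.ndarray) -> list[tuple[str, float]]:
    """Identify the nearest visible neuron for each 3D query point.

    For every point, the visible neuron whose mesh (or soma-sphere
    stand-in) has the smallest surface distance is returned; a point
    inside a mesh has distance 0.  Ties break lexicographically by cell
    name.  This is the headless form of clicking a neuron in a viewport.
    """
    cells = [c for c in scene.visible_neurons
             if c in scene.model.neuron_meshes or c in scene.stand_ins]
    if not cells:
        raise SceneError("no visible neurons to pick from")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    best_cell = np.full(len(points), "", dtype=object)
    best_dist = np.full(len(points), np.inf)
    for cell in cells:  # lexicographic order => first strict win keeps ties
        mesh = scene.mesh_of(cell)
        # bounding-sphere lower bound: a mesh whose bound cannot beat the
        # current best is skipped (ties would lose to the earlier name)
        center = mesh.bounds.mean(axis=0)
        radius = float(np.linalg.norm(mesh.bounds[1] - center))
        lower = np.linalg.norm(points - center, axis=1) - radius
        todo = lower < best_dist
        if not todo.any():
            continue
        sub = points[todo]
        dist = geometry.points_to_mesh_distance(sub, mesh)
        inside = geometry.points_in_mesh(sub, mesh)
        dist[inside] = 0.0
        idx = np.flatnonzero(todo)
        win = dist < best_dist[idx]
        best_dist[idx[win]] = dist[win]
        best_cell[idx[win]] = cell
    return [(str(c), float(d)) for c, d in zip(best_cell, best_dist)]


def pick_neuron(scene: Scene, point) -> tuple[str, float]:
    """Single-point form of :func:`pick_neurons`."""
    return pick_neurons(scene, np.asarray(point, dtype=float).reshape(1, 3))[0]
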