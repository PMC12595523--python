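"""Named-mesh Wavefront OBJ reading and writing.

Per-neuron anatomy and colored-scene export both need one property the
common OBJ toolchains treat as optional: the object name attached to each
mesh must survive a write/read round trip exactly, and so must the RGBA of
its material (MTL ``Kd`` + dissolve ``d``).  This module implements the
small OBJ dialect the package emits and consumes deterministically:

* ``o``/``g`` starts a named object (vertices are file-global, 1-based),
* ``v`` and triangular/polygonal ``f`` records (faces are fan-triangulated),
* one optional ``mtllib``/``usemtl`` material per object with ``Kd``/``d``.

Everything else (normals, texture coordinates, smoothing groups) is
ignored on read and never written.  glTF and PLY go through trimesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = ["NamedMeshes", "read_obj", "write_obj"]

_FMT = "%.8f"  # fixed float format => byte-identical output for equal input


@dataclass
class NamedMeshes:
    """Ordered name -> mesh mapping with optional per-object RGBA in [0,1]."""

    meshes: dict[str, trimesh.Trimesh] = field(default_factory=dict)
    colors: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)


def _parse_mtl(path: Path) -> dict[str, tuple[float, float, float, float]]:
    materials: dict[str, tuple[float, float, float, float]] = {}
    name = None
    kd = (0.8, 0.8, 0.8)
    alpha = 1.0

    def flush() -> None:
        if name is not None:
            materials[name] = (kd[0], kd[1], kd[2], alpha)

    if not path.is_file():
        return materials
    for raw in path.read_text(encoding="utf-8").splitlines():
        parts = raw.split()
        if not parts or parts[0].startswith("#"):
            continue
        if parts[0] == "newmtl":
            flush()
            name, kd, alpha = parts[1], (0.8, 0.8, 0.8), 1.0
        elif parts[0] == "Kd" and len(parts) >= 4:
            kd = (float(parts[1]), float(parts[2]), float(parts[3]))
        elif parts[0] == "d" and len(parts) >= 2:
            alpha = float(parts[1])
        elif parts[0] == "Tr" and len(parts) >= 2:  # inverted dissolve variant
            alpha = 1.0 - float(parts[1])
    flush()
    return materials


def read_obj(path: str | Path) -> NamedMeshes:
    """Read an OBJ file into named triangle meshes.

    Objects are delimited by ``o`` (or ``g``) records; content before the
    first delimiter is collected under the name ``"default"``.  Polygonal
    faces are fan-triangulated.  Negative (relative) vertex indices are
    supported.
    """
    path = Path(path)
    vertices: list[tuple[float, float, float]] = []
    # name -> (faces, material); order preserved
    objects: dict[str, list] = {}
    current = None
    materials: dict[str, tuple] = {}
    obj_material: dict[str, str] = {}

    def ensure(name: str) -> str:
        base, k = name, 1
        while name in objects:  # duplicate names stay distinct
            k += 1
            name = f"{base}_{k}"
        objects[name] = []
        return name

    for raw in path.read_text(encoding="utf-8").splitlines():
        parts = raw.split()
        if not parts or parts[0].startswith("#"):
            continue
        tag = parts[0]
        if tag == "mtllib" and len(parts) > 1:
            materials.update(_parse_mtl(path.parent / parts[1]))
        elif tag in ("o", "g"):
            current = ensure(parts[1] if len(parts) > 1 else "unnamed")
        elif tag == "v":
            vertices.append((float(parts[1]), float(parts[2]), float(parts[3])))
        elif tag == "usemtl" and len(parts) > 1:
            if current is None:
                current = ensure("default")
            obj_material[current] = parts[1]
        elif tag == "f":
            if current is None:
                current = ensure("default")
            idx = []
            for tok in parts[1:]:
                i = int(tok.split("/")[0])
                idx.append(i - 1 if i > 0 else len(vertices) + i)
            for k in range(1, len(idx) - 1):  # fan triangulation
                objects[current].append((idx[0], idx[k], idx[k + 1]))

    out = NamedMeshes()
    verts = np.asarray(vertices, dtype=float)
    for name, faces in objects.items():
        if not faces:
            continue
        faces_arr = np.asarray(faces, dtype=np.int64)
        used = np.unique(faces_arr)
        remap = np.full(len(verts), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        mesh = trimesh.Trimesh(
            vertices=verts[used], faces=remap[faces_arr], process=False
        )
        out.meshes[name] = mesh
        mat = obj_material.get(name)
        if mat in materials:
            out.colors[name] = materials[mat]
    return out


def write_obj(
    named: NamedMeshes,
    path: str | Path,
    *,
    mtl_name: str | None = None,
) -> Path:
    """Write named meshes (and their colors, if any) as OBJ+MTL.

    One MTL material is emitted per *distinct* RGBA; objects sharing a
    color share a material.  Output is byte-deterministic for equal input.
    """
    path = Path(path)
    lines: list[str] = []
    mtl_lines: list[str] = []
    mtl_path = None
    color_to_mat: dict[tuple, str] = {}
    if named.colors:
        mtl_path = path.with_suffix(".mtl") if mtl_name is None else path.parent / mtl_name
        lines.append(f"mtllib {mtl_path.name}")
        for color in named.colors.values():
            key = tuple(round(float(c), 8) for c in color)
            if key in color_to_mat:
                continue
            mat = f"mat{len(color_to_mat)}"
            color_to_mat[key] = mat
            mtl_lines.append(f"newmtl {mat}")
            mtl_lines.append("Kd " + " ".join(_FMT % c for c in key[:3]))
            mtl_lines.append("d " + _FMT % key[3])
            mtl_lines.append("")

    offset = 0
    for name, mesh in named.meshes.items():
        lines.append(f"o {name}")
        if name in named.colors:
            key = tuple(round(float(c), 8) for c in named.colors[name])
            lines.append(f"usemtl {color_to_mat[key]}")
        for v in np.asarray(mesh.vertices, dtype=float):
            lines.append("v " + " ".join(_FMT % x for x in v))
        for f in np.asarray(mesh.faces, dtype=np.int64):
            lines.append("f " + " ".join(str(i + 1 + offset) for i in f))
        offset += len(mesh.vertices)

    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    if mtl_path is not None:
        mtl_path.write_text("\n".join(mtl_lines) + "\n", encoding="utf-8")
    return path
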