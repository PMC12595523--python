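"""Canonical neuron nomenclature and 3D anatomy loading.

Single-cell RNA-seq datasets for the C. elegans nervous system report
expression per transcriptomic *neuron class* (AVK, RIM, VA, ...), while an
anatomical model names each individual *neuron cell* (AVKL, AVKR, VA3, ...).
This module owns the bridge between the two: a packaged roster of the 302
hermaphrodite neurons with their class assignment, class-label expansion
(including CeNGEN-style state-split labels such as ``AWC_ON`` that anatomy
cannot tell apart), and loading of a 3D model whose mesh names are matched
against the roster.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import trimesh

from . import mesh_io

__all__ = [
    "NeuronCell",
    "NeuronRoster",
    "AnatomyModel",
    "ClassExpansion",
    "RosterError",
    "ModelError",
    "load_roster",
    "expand_class",
    "load_model",
    "default_roster",
    "default_class_vocabulary",
]

HERMAPHRODITE_NEURON_COUNT = 302


class RosterError(ValueError):
    """Malformed roster data."""


class ModelError(ValueError):
    """A 3D model that cannot be bound to the roster."""


@dataclass(frozen=True)
class NeuronCell:
    """One anatomical neuron: name, scRNA-seq class, soma position, mesh."""

    cell_name: str
    class_name: str
    soma_position: tuple[float, float, float] | None = None
    mesh_ref: str | None = None


@dataclass(frozen=True)
class NeuronRoster:
    """The cell <-> class partition of a nervous system.

    ``class_index`` maps each class label to the ordered list of its member
    cell names; classes partition the roster (every cell in exactly one
    class).
    """

    cells: tuple[NeuronCell, ...]
    class_index: dict[str, list[str]] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        names = [c.cell_name for c in self.cells]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise RosterError(f"duplicate cell names: {dupes}")
        if any(not c.class_name for c in self.cells):
            raise RosterError("empty class name in roster")
        index: dict[str, list[str]] = {}
        for c in self.cells:
            index.setdefault(c.class_name, []).append(c.cell_name)
        object.__setattr__(self, "class_index", index)
        assert sum(len(v) for v in index.values()) == len(self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def cell_names(self) -> list[str]:
        return [c.cell_name for c in self.cells]

    def cell(self, name: str) -> NeuronCell:
        for c in self.cells:
            if c.cell_name == name:
                return c
        raise KeyError(name)

    def class_of(self, cell_name: str) -> str:
        return self.cell(cell_name).class_name


class ClassExpansion(NamedTuple):
    """Result of resolving a CSV column label to anatomical cells.

    ``flag`` is ``"exact"`` for a clean class or cell-name match,
    ``"state-ambiguous"`` when a state-split label (``AWC_ON``) fell back to
    its base class, and ``"unknown"`` when nothing resolved (empty list).
    """

    cells: list[str]
    flag: str


def load_roster(path: str | Path | None = None) -> NeuronRoster:
    """Load a roster CSV (``cell_name,class_name``).

    With no path, the packaged hermaphrodite roster (302 neurons, 118
    classes) is loaded; that default is validated against the 302-cell
    invariant.
    """
    if path is None:
        ref = resources.files("elegansviz.data") / "hermaphrodite_neurons.csv"
        with resources.as_file(ref) as p:
            roster = load_roster(p)
        if len(roster) != HERMAPHRODITE_NEURON_COUNT:
            raise RosterError(
                f"packaged roster has {len(roster)} cells, "
                f"expected {HERMAPHRODITE_NEURON_COUNT}"
            )
        return roster
    frame = pd.read_csv(path, dtype=str)
    required = {"cell_name", "class_name"}
    if not required.issubset(frame.columns):
        raise RosterError(f"roster file {path} lacks columns {sorted(required)}")
    if frame[list(required)].isna().any().any():
        raise RosterError(f"roster file {path} has missing entries")
    cells = tuple(
        NeuronCell(cell_name=row.cell_name, class_name=row.class_name)
        for row in frame.itertuples()
    )
    return NeuronRoster(cells=cells)


_DEFAULT_ROSTER: NeuronRoster | None = None


def default_roster() -> NeuronRoster:
    """The packaged hermaphrodite roster, loaded once per process."""
    global _DEFAULT_ROSTER
    if _DEFAULT_ROSTER is None:
        _DEFAULT_ROSTER = load_roster()
    return _DEFAULT_ROSTER


def default_class_vocabulary() -> set[str]:
    """Labels resolvable against the packaged roster: classes and cells."""
    roster = default_roster()
    vocab = set(roster.class_index)
    vocab.update(roster.cell_names)
    return vocab


_ZERO_PAD = re.compile(r"^([A-Z]+)0*(\d+)$")


def expand_class(roster: NeuronRoster, label: str) -> ClassExpansion:
    """Resolve a dataset column label to an ordered list of cell names.

    Total function: never raises.  Resolution order —

    1. exact class label (case-insensitive): its members, ``"exact"``;
    2. exact cell name, including zero-padded numbering as CeNGEN uses
       (``VB01`` -> ``VB1``): that one cell, ``"exact"``;
    3. state-split label ``BASE_SUFFIX`` whose base is a class (``AWC_ON``,
       ``RMD_DV``, ``VD_DD``): the base class members, ``"state-ambiguous"``
       (the anatomy cannot distinguish the states);
    4. otherwise ``([], "unknown")``.
    """
    token = str(label).strip().upper()
    if not token:
        return ClassExpansion([], "unknown")
    classes = {c.upper(): c for c in roster.class_index}
    if token in classes:
        return ClassExpansion(list(roster.class_index[classes[token]]), "exact")
    cells = {c.upper(): c for c in (cell.cell_name for cell in roster.cells)}
    m = _ZERO_PAD.match(token)
    depadded = f"{m.group(1)}{int(m.group(2))}" if m else token
    if depadded in cells:
        return ClassExpansion([cells[depadded]], "exact")
    base = token.split("_", 1)[0]
    if base in classes:
        return ClassExpansion(list(roster.class_index[classes[base]]), "state-ambiguous")
    return ClassExpansion([], "unknown")


@dataclass
class AnatomyModel:
    """Per-neuron meshes plus context anatomy in one coordinate frame.

    ``neuron_meshes`` keys are roster cell names; every other mesh in the
    source model lands in ``context_meshes`` (body outline, pharynx, ...)
    and is rendered translucently.  ``soma_positions`` holds the centroid
    (vertex mean of the largest connected component) per neuron mesh.
    """

    roster: NeuronRoster
    neuron_meshes: dict[str, trimesh.Trimesh] = field(default_factory=dict)
    context_meshes: dict[str, trimesh.Trimesh] = field(default_factory=dict)
    soma_positions: dict[str, np.ndarray] = field(default_factory=dict)
    frame: str = "model-native"

    def __post_init__(self) -> None:
        roster_names = set(self.roster.cell_names)
        unknown = set(self.neuron_meshes) - roster_names
        if unknown:
            raise ModelError(f"neuron meshes not in roster: {sorted(unknown)}")
        collisions = set(self.context_meshes) & roster_names
        if collisions:
            raise ModelError(f"context meshes collide with cell names: {sorted(collisions)}")
        for name, mesh in self.neuron_meshes.items():
            if name not in self.soma_positions:
                self.soma_positions[name] = soma_centroid(mesh)

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) min/max corner over all meshes."""
        pts = [m.vertices for m in self.neuron_meshes.values()]
        pts += [m.vertices for m in self.context_meshes.values()]
        if not pts:
            raise ModelError("empty model has no bounds")
        allv = np.vstack(pts)
        bounds = np.array([allv.min(axis=0), allv.max(axis=0)])
        if not np.isfinite(bounds).all():
            raise ModelError("non-finite model bounds")
        return bounds

    def soma_position(self, cell_name: str) -> np.ndarray:
        if cell_name in self.soma_positions:
            return self.soma_positions[cell_name]
        raise KeyError(f"no soma position for {cell_name}")


def soma_centroid(mesh: trimesh.Trimesh) -> np.ndarray:
    """Vertex mean of the mesh's largest connected component.

    For a neuron mesh the largest component is the soma+neurite body; for
    the synthetic fixtures it is the soma sphere itself, whose vertex mean
    equals the sphere center.
    """
    try:
        parts = mesh.split(only_watertight=False)
    except Exception:
        parts = []
    if len(parts) > 1:
        mesh = max(parts, key=lambda p: len(p.vertices))
    return np.asarray(mesh.vertices, dtype=float).mean(axis=0)


def _bind_names(
    mesh_names: Iterable[str],
    roster: NeuronRoster,
    name_pattern: str | None,
) -> dict[str, str]:
    """Match mesh names to roster cell names, case-insensitively.

    `name_pattern` is an optional regex removed from each mesh name before
    matching (model files often carry prefixes like ``WBneuron.AVKL``).
    """
    strip = re.compile(name_pattern) if name_pattern else None
    cells = {c.upper(): c for c in roster.cell_names}
    binding: dict[str, str] = {}
    for raw in mesh_names:
        name = strip.sub("", raw) if strip else raw
        cell = cells.get(name.strip().upper())
        if cell is not None and cell not in binding.values():
            binding[raw] = cell
    return binding


def load_model(
    path: str | Path,
    roster: NeuronRoster | None = None,
    *,
    name_pattern: str | None = None,
) -> AnatomyModel:
    """Load a 3D anatomy model and bind its named meshes to the roster.

    Accepts a single OBJ or glTF/GLB file with named objects, or a
    directory of one-mesh-per-file PLY (or OBJ) files named after cells.
    Mesh names matching roster cell names (case-insensitive, after
    optionally stripping `name_pattern`) become neuron meshes; everything
    else becomes a translucent context mesh.  The model's coordinate frame
    is preserved untouched.

    Raises :class:`ModelError` if no mesh name matches any roster cell —
    that signals a wrong model file rather than a naming dialect issue.
    """
    roster = roster if roster is not None else default_roster()
    path = Path(path)
    named: dict[str, trimesh.Trimesh] = {}
    if path.is_dir():
        for p in sorted(path.iterdir()):
            if p.suffix.lower() in (".ply", ".obj"):
                if p.suffix.lower() == ".obj":
                    for name, mesh in mesh_io.read_obj(p).meshes.items():
                        named[name if len(named) else p.stem] = mesh
                else:
                    mesh = trimesh.load(p, process=False, force="mesh")
                    named[p.stem] = mesh
        if not named:
            raise ModelError(f"no mesh files found in directory {path}")
    elif path.suffix.lower() == ".obj":
        named = mesh_io.read_obj(path).meshes
    elif path.suffix.lower() in (".gltf", ".glb"):
        scene = trimesh.load(path, process=False)
        if isinstance(scene, trimesh.Trimesh):
            named = {path.stem: scene}
        else:
            named = dict(scene.geometry)
    elif path.suffix.lower() == ".ply":
        named = {path.stem: trimesh.load(path, process=False, force="mesh")}
    else:
        raise ModelError(f"unsupported model format: {path.suffix!r}")
    if not named:
        raise ModelError(f"no geometry read from {path}")

    binding = _bind_names(named, roster, name_pattern)
    if not binding:
        raise ModelError(
            f"no mesh name in {path} matches any roster cell; "
            "wrong model file, or pass name_pattern to strip a prefix"
        )
    neuron_meshes = {cell: named[raw] for raw, cell in binding.items()}
    context_meshes = {
        raw: mesh for raw, mesh in named.items() if raw not in binding
    }
    return AnatomyModel(
        roster=roster,
        neuron_meshes=neuron_meshes,
        context_meshes=context_meshes,
    )
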