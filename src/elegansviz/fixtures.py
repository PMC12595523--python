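"""Synthetic worm models and expression tables with known structure.

Everything downstream — CSV loading, class expansion, signatures, scenes,
picking — is testable without downloading a real single-cell atlas or the
full anatomical model.  The generator builds a toy worm (soma spheres at
deterministic positions along a translucent body tube, left/right mirror
pairs for two-cell classes, optional neurite tubes) plus a matching
gene-by-class CSV.  Class names reuse real C. elegans class names (AVK,
RIM, RIC, ...) so the nomenclature code paths are exercised on the real
vocabulary, and every generator is byte-deterministic under its seed.

The emulation is structural only: expression values are i.i.d. draws, not
realistic single-cell count distributions, and the toy geometry has none
of the real model's neurite morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import mesh_io
from .anatomy import AnatomyModel, NeuronRoster, load_model, load_roster

__all__ = [
    "FixtureSpec",
    "LR_CLASSES",
    "SINGLE_CLASSES",
    "nested_design",
    "make_synthetic_model",
    "make_synthetic_expression",
    "make_fig1c_fixture",
]

# Real two-cell (L/R) neuron classes, in a fixed order, drawn on by the
# generator; all are present in the packaged roster.
LR_CLASSES: tuple[str, ...] = (
    "AVK", "RIM", "RIC", "ASK", "AWA", "AVA", "AIY", "RIB", "URX", "BAG",
    "ADL", "ASH", "AIB", "AIA", "AFD", "ASE", "AWB", "ASG", "ASI", "ASJ",
    "ADA", "ADE", "ADF", "AIM", "AIN", "AIZ", "ALM", "ALN", "AUA", "AVB",
)

# Real one-cell classes for cells_per_class=1 fixtures.
SINGLE_CLASSES: tuple[str, ...] = (
    "ALA", "AVG", "AVL", "AVM", "AQR", "DVA", "DVB", "DVC", "PDA", "PDB",
    "PQR", "PVM", "PVR", "PVT", "RID", "RIH", "RIR", "RIS",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic worm + expression dataset.

    ``expression_design`` maps gene -> set of expressing classes; when
    None, each (gene, class) is expressed Bernoulli(`sparsity`) under
    `seed`.  Geometry: somata of radius `soma_radius` spaced along a body
    tube of length `body_length` (model units ~ micrometres), mirror pairs
    offset left/right; `neurites` adds a thin tube from each soma to the
    body axis.  Same spec, same bytes out.
    """

    n_classes: int = 4
    cells_per_class: int = 2
    n_genes: int = 3
    expression_design: dict[str, frozenset[str]] | None = None
    sparsity: float = 0.3
    body_length: float = 50.0
    soma_radius: float = 1.0
    neurites: bool = True
    seed: int = 0
    gene_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.cells_per_class not in (1, 2):
            raise ValueError("cells_per_class must be 1 or 2")
        pool = LR_CLASSES if self.cells_per_class == 2 else SINGLE_CLASSES
        if self.n_classes > len(pool):
            raise ValueError(
                f"at most {len(pool)} classes with cells_per_class="
                f"{self.cells_per_class}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError("sparsity must be in [0, 1]")
        if self.gene_names and len(self.gene_names) != self.n_genes:
            raise ValueError("gene_names length must equal n_genes")
        if self.expression_design is not None:
            unknown = {
                c for cs in self.expression_design.values() for c in cs
            } - set(self.class_names)
            if unknown:
                raise ValueError(
                    f"expression design references unknown classes: "
                    f"{sorted(unknown)}")

    @property
    def class_names(self) -> tuple[str, ...]:
        pool = LR_CLASSES if self.cells_per_class == 2 else SINGLE_CLASSES
        return pool[: self.n_classes]

    @property
    def genes(self) -> tuple[str, ...]:
        if self.gene_names:
            return self.gene_names
        return tuple(f"g{i + 1}" for i in range(self.n_genes))

    @property
    def cell_names(self) -> tuple[str, ...]:
        cells: list[str] = []
        for cls in self.class_names:
            if self.cells_per_class == 2:
                cells += [cls + "L", cls + "R"]
            else:
                cells.append(cls)
        return tuple(cells)


def nested_design(spec: FixtureSpec) -> dict[str, frozenset[str]]:
    """The nested inclusion-chain design: gene i+1's classes ⊂ gene i's.

    With genes (g1, g2, g3) over classes (A, B, C, D) this is
    ``{g1: {A,B,C}, g2: {B,C}, g3: {C}}`` — the monoamine-pathway pattern
    (a transporter expressed broadly, synthesis enzymes in nested subsets)
    whose partition has exactly one block per gene.
    """
    classes = spec.class_names
    top = max(len(classes) - 1, 1) if len(classes) > 1 else 1
    design = {}
    for i, gene in enumerate(spec.genes):
        lo = min(i, top - 1)
        design[gene] = frozenset(classes[lo:top])
    return design


def _soma_positions(spec: FixtureSpec) -> dict[str, np.ndarray]:
    """Deterministic soma layout: classes spaced along x, pairs mirrored in z."""
    out: dict[str, np.ndarray] = {}
    n = spec.n_classes
    offset = 3.0 * spec.soma_radius
    for i, cls in enumerate(spec.class_names):
        x = spec.body_length * (i + 1) / (n + 1)
        if spec.cells_per_class == 2:
            out[cls + "L"] = np.array([x, 0.0, +offset])
            out[cls + "R"] = np.array([x, 0.0, -offset])
        else:
            out[cls] = np.array([x, 0.0, 0.0])
    return out


def _tube(p0: np.ndarray, p1: np.ndarray, radius: float,
          sections: int = 12) -> trimesh.Trimesh:
    """Closed cylinder from p0 to p1."""
    vec = p1 - p0
    length = float(np.linalg.norm(vec))
    cyl = trimesh.creation.cylinder(radius=radius, height=length,
                                    sections=sections)
    align = trimesh.geometry.align_vectors([0.0, 0.0, 1.0], vec / length)
    cyl.apply_transform(align)
    cyl.apply_translation((p0 + p1) / 2.0)
    return cyl


def make_synthetic_model(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the toy worm model (``model.obj``) and its roster CSV.

    Returns ``(model_path, roster_path)``.  Mesh object names equal cell
    names; the body tube is the one context mesh, named ``body``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    positions = _soma_positions(spec)

    named = mesh_io.NamedMeshes()
    body_r = 6.0 * spec.soma_radius
    named.meshes["body"] = _tube(
        np.array([0.0, 0.0, 0.0]),
        np.array([spec.body_length, 0.0, 0.0]),
        radius=body_r, sections=24,
    )
    for cell, pos in positions.items():
        soma = trimesh.creation.icosphere(subdivisions=2,
                                          radius=spec.soma_radius)
        soma.apply_translation(pos)
        if spec.neurites and abs(pos[2]) > 1e-12:
            neurite = _tube(pos, np.array([pos[0], pos[1], 0.0]),
                            radius=0.2 * spec.soma_radius, sections=8)
            soma = trimesh.util.concatenate([soma, neurite])
        named.meshes[cell] = soma
    model_path = mesh_io.write_obj(named, out_dir / "model.obj")

    roster_path = out_dir / "roster.csv"
    rows = [{"cell_name": cell,
             "class_name": cell[:-1] if spec.cells_per_class == 2 else cell}
            for cell in spec.cell_names]
    pd.DataFrame(rows).to_csv(roster_path, index=False)
    return model_path, roster_path


def make_synthetic_expression(
    spec: FixtureSpec, out_path: str | Path
) -> Path:
    """Write the genes x classes expression CSV for `spec`.

    An explicit design is reproduced exactly (expressed cells get a
    positive value drawn under the seed); otherwise each (gene, class) is
    expressed with probability `sparsity` and expressed entries get
    values uniform on [1, 10).
    """
    out_path = Path(out_path)
    rng = np.random.default_rng(spec.seed)
    genes, classes = spec.genes, spec.class_names
    mask = np.zeros((len(genes), len(classes)), dtype=bool)
    if spec.expression_design is not None:
        for i, g in enumerate(genes):
            for j, c in enumerate(classes):
                mask[i, j] = c in spec.expression_design.get(g, frozenset())
    else:
        mask = rng.random(mask.shape) < spec.sparsity
    values = np.where(mask, np.round(rng.uniform(1.0, 10.0, mask.shape), 4), 0.0)
    frame = pd.DataFrame(values, index=list(genes), columns=list(classes))
    frame.to_csv(out_path, index_label="gene")
    return out_path


def load_fixture(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[AnatomyModel, NeuronRoster, Path]:
    """Generate, write and reload a full fixture; returns (model, roster, csv)."""
    out_dir = Path(out_dir)
    model_path, roster_path = make_synthetic_model(spec, out_dir)
    csv_path = make_synthetic_expression(spec, out_dir / "expression.csv")
    roster = load_roster(roster_path)
    model = load_model(model_path, roster)
    return model, roster, csv_path


def make_fig1c_fixture(
    out_dir: str | Path,
    n_classes: int = 10,
    include_ligand_class_in_receptor: bool = False,
    seed: int = 0,
) -> tuple[Path, Path, Path]:
    """A broadcast-signaling fixture: one narrowly expressed neuropeptide
    gene and one widely expressed receptor gene.

    The ligand (named ``flp-1``) is confined to the two-cell class AVK;
    the receptor (``frpr-7``) is expressed in every other class (so in at
    least half of all classes), optionally in AVK too.  Returns
    ``(model_path, roster_path, expression_path)``; deterministic.
    """
    classes_with_avk_first = ("AVK",) + tuple(
        c for c in LR_CLASSES if c != "AVK")
    classes = classes_with_avk_first[:n_classes]
    receptor_classes = set(classes) if include_ligand_class_in_receptor \
        else set(classes) - {"AVK"}
    spec = FixtureSpec(
        n_classes=n_classes,
        cells_per_class=2,
        n_genes=2,
        gene_names=("flp-1", "frpr-7"),
        expression_design={
            "flp-1": frozenset({"AVK"}),
            "frpr-7": frozenset(receptor_classes),
        },
        seed=seed,
    )
    out_dir = Path(out_dir)
    model_path, roster_path = make_synthetic_model(spec, out_dir)
    csv_path = make_synthetic_expression(spec, out_dir / "expression.csv")
    return model_path, roster_path, csv_path
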