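"""Co-expression signatures, partitioning, colors, and signaling overlays.

The central abstraction: given an ordered list of query genes, every neuron
cell gets an *expression signature* — the boolean vector saying which of
the queried genes its class expresses.  Grouping cells by exact signature
yields a disjoint partition of the expressing nervous system; each block is
then bound to one RGBA color.  A ligand/receptor *signaling overlay* is the
two-gene special case read out as sender / receiver / both / none roles —
the scheme used to display, e.g., flp-1-expressing AVK neurons in dark red
against the widely distributed frpr-7 receptor field in light blue.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import NeuronRoster, default_roster, expand_class
from .expression import ExpressionTable, expressing_classes, lookup_gene

__all__ = [
    "ExpressionSignature",
    "SignaturePartition",
    "ColorMap",
    "RGBA",
    "compute_signatures",
    "partition_by_signature",
    "assign_colors",
    "signaling_overlay",
    "role_colormap",
    "export_partition_csv",
    "PALETTES",
    "ROLE_COLORS",
]

RGBA = tuple[float, float, float, float]

# Named palettes (RGBA in [0,1]).  "classic" follows the green -> blue ->
# orange progression used for nested monoamine-pathway queries
# (cat-1 alone green, +tdc-1 blue, +tbh-1 orange).
PALETTES: dict[str, tuple[RGBA, ...]] = {
    "classic": (
        (0.00, 0.80, 0.20, 1.0),  # green
        (0.10, 0.35, 0.95, 1.0),  # blue
        (1.00, 0.55, 0.00, 1.0),  # orange
        (0.85, 0.10, 0.50, 1.0),
        (0.55, 0.25, 0.85, 1.0),
        (0.95, 0.85, 0.10, 1.0),
        (0.00, 0.75, 0.75, 1.0),
        (0.60, 0.40, 0.10, 1.0),
    ),
    "bright": (
        (0.894, 0.102, 0.110, 1.0),
        (0.216, 0.494, 0.722, 1.0),
        (0.302, 0.686, 0.290, 1.0),
        (0.596, 0.306, 0.639, 1.0),
        (1.000, 0.498, 0.000, 1.0),
        (0.651, 0.337, 0.157, 1.0),
        (0.969, 0.506, 0.749, 1.0),
        (0.400, 0.761, 0.647, 1.0),
    ),
}

# Sender/receiver role scheme: neuropeptide senders dark red, receptor-
# bearing receivers light blue, cells doing both get their own distinct
# color (a blend would be ambiguous against light backgrounds).
ROLE_COLORS: dict[str, RGBA] = {
    "sender": (0.545, 0.000, 0.000, 1.0),    # dark red
    "receiver": (0.678, 0.847, 0.902, 1.0),  # light blue
    "both": (0.580, 0.000, 0.827, 1.0),      # violet
}

NEUTRAL_COLOR: RGBA = (0.55, 0.55, 0.55, 1.0)
BACKGROUND_COLOR: RGBA = (1.0, 1.0, 1.0, 1.0)
CONTEXT_COLOR: RGBA = (0.75, 0.75, 0.75, 0.15)


@dataclass(frozen=True)
class ExpressionSignature:
    """Which of the query genes a cell expresses; equality is bitwise."""

    query_genes: tuple[str, ...]
    bits: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != len(self.query_genes):
            raise ValueError("signature bit count must equal query gene count")
        object.__setattr__(self, "bits", tuple(bool(b) for b in self.bits))
        object.__setattr__(self, "query_genes", tuple(self.query_genes))

    @property
    def expressed_genes(self) -> tuple[str, ...]:
        return tuple(g for g, b in zip(self.query_genes, self.bits) if b)

    @property
    def popcount(self) -> int:
        return sum(self.bits)

    @property
    def any(self) -> bool:
        return any(self.bits)

    def as_int(self) -> int:
        """Bits as a binary number; the first query gene is the high bit."""
        value = 0
        for b in self.bits:
            value = (value << 1) | int(b)
        return value

    def bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)


@dataclass(frozen=True)
class SignaturePartition:
    """Disjoint grouping of cells by signature.

    ``blocks`` maps each non-empty signature (at least one gene expressed)
    to its cell set; cells expressing none of the query genes form the
    ``background``.
    """

    blocks: dict[ExpressionSignature, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sig, cells in self.blocks.items():
            if not sig.any:
                raise ValueError("all-false signature must not key a block")
            if not cells:
                raise ValueError("empty partition block")
            if seen & cells:
                raise ValueError("partition blocks overlap")
            seen |= cells
        if seen & self.background:
            raise ValueError("background overlaps a block")

    @property
    def expressing_cells(self) -> frozenset[str]:
        out: set[str] = set()
        for cells in self.blocks.values():
            out |= cells
        return frozenset(out)

    def block_of(self, cell: str) -> ExpressionSignature | None:
        for sig, cells in self.blocks.items():
            if cell in cells:
                return sig
        return None


@dataclass(frozen=True)
class ColorMap:
    """Signature (or role tag) -> RGBA binding for a scene."""

    entries: dict[ExpressionSignature | str, RGBA]
    background_color: RGBA = BACKGROUND_COLOR
    context_color: RGBA = CONTEXT_COLOR
    neutral_color: RGBA = NEUTRAL_COLOR

    def color_of(self, key: ExpressionSignature | str) -> RGBA:
        return self.entries[key]


def compute_signatures(
    table: ExpressionTable,
    genes: list[str],
    roster: NeuronRoster | None = None,
    min_value: float = 0.0,
) -> dict[str, ExpressionSignature]:
    """Per-cell expression signature over an ordered query gene list.

    Bit *i* of a cell's signature is true iff the cell belongs to a class
    (or state-split class label) whose expression of ``genes[i]`` exceeds
    `min_value`.  Cells whose class matches no table column get an
    all-false signature.  Iterating single-gene selections one at a time
    and intersecting by eye is exactly this computation done jointly.
    """
    if not genes:
        raise ValueError("at least one query gene is required")
    roster = roster if roster is not None else default_roster()
    canonical = tuple(lookup_gene(table, g) for g in genes)

    per_gene_cells: list[frozenset[str]] = []
    for gene in canonical:
        classes = expressing_classes(table, gene, min_value)
        cells: set[str] = set()
        for label in classes:
            cells.update(expand_class(roster, label).cells)
        per_gene_cells.append(frozenset(cells))

    return {
        cell.cell_name: ExpressionSignature(
            query_genes=canonical,
            bits=tuple(cell.cell_name in s for s in per_gene_cells),
        )
        for cell in roster.cells
    }


def partition_by_signature(
    signatures: dict[str, ExpressionSignature],
) -> SignaturePartition:
    """Group cells by exact signature; all-false cells form the background."""
    blocks: dict[ExpressionSignature, set[str]] = {}
    background: set[str] = set()
    for cell, sig in signatures.items():
        if sig.any:
            blocks.setdefault(sig, set()).add(cell)
        else:
            background.add(cell)
    return SignaturePartition(
        blocks={sig: frozenset(cells) for sig, cells in blocks.items()},
        background=frozenset(background),
    )


def _ordered_blocks(partition: SignaturePartition) -> list[ExpressionSignature]:
    # popcount then binary value: "more co-expression" gets later palette
    # colors, echoing a green -> blue -> orange nesting.
    return sorted(partition.blocks, key=lambda s: (s.popcount, s.as_int()))


def _extend_palette(base: tuple[RGBA, ...], n: int, seed: int) -> list[RGBA]:
    """Deterministically extend a palette to n distinct colors."""
    colors = list(base[:n])
    rng = np.random.default_rng(seed)
    golden = 0.6180339887498949
    h = float(rng.random())
    while len(colors) < n:
        h = (h + golden) % 1.0
        r, g, b = colorsys.hsv_to_rgb(h, 0.75, 0.95)
        cand = (round(r, 6), round(g, 6), round(b, 6), 1.0)
        if cand not in colors:
            colors.append(cand)
    return colors


def assign_colors(
    partition: SignaturePartition,
    palette: str | dict[ExpressionSignature, RGBA] = "classic",
    gene_order: tuple[str, ...] | None = None,
    seed: int = 0,
) -> ColorMap:
    """Bind each partition block to an RGBA color.

    An explicit ``signature -> color`` mapping wins and must cover every
    block (the error lists uncovered signatures).  Otherwise blocks are
    ordered by (popcount, signature-as-binary-number) and colors are drawn
    from the named palette, extended deterministically from `seed` if the
    palette runs out.  Same inputs, same ColorMap, always.
    """
    ordered = _ordered_blocks(partition)
    if isinstance(palette, dict):
        entries = {}
        missing = []
        for sig in ordered:
            normalized = {
                (k if isinstance(k, ExpressionSignature)
                 else ExpressionSignature(sig.query_genes, tuple(k))): v
                for k, v in palette.items()
            }
            if sig in normalized:
                entries[sig] = tuple(float(c) for c in normalized[sig])
            else:
                missing.append(sig.bitstring())
        if missing:
            raise KeyError(
                f"explicit color map misses signatures: {sorted(missing)}"
            )
        return ColorMap(entries=entries)
    if palette not in PALETTES:
        raise KeyError(f"unknown palette {palette!r}; have {sorted(PALETTES)}")
    colors = _extend_palette(PALETTES[palette], len(ordered), seed)
    return ColorMap(entries=dict(zip(ordered, colors)))


def signaling_overlay(
    table: ExpressionTable,
    ligand_gene: str,
    receptor_gene: str,
    roster: NeuronRoster | None = None,
    min_value: float = 0.0,
) -> dict[str, str]:
    """Sender/receiver roles for a ligand-receptor gene pair.

    sender = expresses the ligand only; receiver = the receptor only;
    both = both genes; none = neither.  Equivalent to the four signatures
    of :func:`compute_signatures` over ``[ligand, receptor]`` read out as
    role names.
    """
    roster = roster if roster is not None else default_roster()
    sigs = compute_signatures(table, [ligand_gene, receptor_gene], roster, min_value)
    role_of = {
        (True, False): "sender",
        (False, True): "receiver",
        (True, True): "both",
        (False, False): "none",
    }
    return {cell: role_of[sig.bits] for cell, sig in sigs.items()}


def role_colormap(colors: dict[str, RGBA] | None = None) -> ColorMap:
    """ColorMap over the sender/receiver/both role tags."""
    merged = dict(ROLE_COLORS)
    if colors:
        merged.update(colors)
    return ColorMap(entries=dict(merged))


def color_to_hex(color: RGBA) -> str:
    """8-bit-per-channel #RRGGBBAA (round-half-up quantization)."""
    return "#" + "".join(
        f"{int(round(float(c) * 255)):02x}" for c in color
    )


def export_partition_csv(
    partition: SignaturePartition,
    colormap: ColorMap,
    roster: NeuronRoster,
    path: str | Path,
    roles: dict[str, str] | None = None,
) -> Path:
    """Write the partition as a per-cell CSV.

    Columns: cell_name, class_name, signature_bits, color_hex, role.
    Background cells appear with an all-zero signature and no color.
    """
    rows = []
    for cell in roster.cells:
        sig = partition.block_of(cell.cell_name)
        role = (roles or {}).get(cell.cell_name, "")
        if sig is not None:
            key: ExpressionSignature | str = sig
            if role and role in colormap.entries:
                key = role
            rows.append({
                "cell_name": cell.cell_name,
                "class_name": cell.class_name,
                "signature_bits": sig.bitstring(),
                "color_hex": color_to_hex(colormap.entries[key])
                if key in colormap.entries else "",
                "role": role,
            })
        elif cell.cell_name in partition.background:
            nbits = len(next(iter(partition.blocks)).bits) if partition.blocks else 0
            rows.append({
                "cell_name": cell.cell_name,
                "class_name": cell.class_name,
                "signature_bits": "0" * nbits,
                "color_hex": "",
                "role": role,
            })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
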