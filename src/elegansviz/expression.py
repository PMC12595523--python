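"""Reading, validating and querying CeNGEN-style expression matrices.

The CeNGEN consortium distributes gene-by-neuron-class expression matrices
for the L4 hermaphrodite nervous system at several detection thresholds
(the widely used "threshold 2" and "threshold 4" tables).  Those tables are
already thresholded, so a strictly positive entry means "detected in that
neuron class".  This module loads any CSV structured that way — genes on
one axis, neuron-class labels on the other — into an :class:`ExpressionTable`
and answers the two queries everything downstream is built from: resolve a
gene name, and list the classes in which a gene is expressed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from .anatomy import default_class_vocabulary

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionTable",
    "ExpressionError",
    "GeneNotFoundError",
    "load_expression_csv",
    "write_expression_csv",
    "lookup_gene",
    "expressing_classes",
]


class ExpressionError(ValueError):
    """Raised when an expression CSV cannot be interpreted."""


class GeneNotFoundError(KeyError):
    """A queried gene is absent from the table.

    Carries up to five nearest gene symbols by Levenshtein distance in
    :attr:`suggestions`.
    """

    def __init__(self, query: str, suggestions: list[str]):
        self.query = query
        self.suggestions = list(suggestions)
        msg = f"gene {query!r} not found"
        if suggestions:
            msg += "; did you mean: " + ", ".join(suggestions)
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return self.args[0]


@dataclass(frozen=True)
class ExpressionTable:
    """A genes x neuron-classes matrix of non-negative expression values.

    Parameters
    ----------
    gene_ids
        Unique gene symbols (e.g. ``"flp-1"``); uniqueness holds after
        case-folding.
    class_names
        Column vocabulary: neuron-class labels (e.g. ``"AVK"``, ``"AWC_ON"``).
    values
        ``(len(gene_ids), len(class_names))`` float array, all entries >= 0.
        Missing cells in the source file are read as 0.
    threshold_label
        Free-text provenance tag, e.g. ``"threshold 2"`` or ``"synthetic"``.
    flagged_classes
        Column labels that did not resolve against the neuron-class
        vocabulary (typically non-neuronal cell types); kept, but marked.
    """

    gene_ids: tuple[str, ...]
    class_names: tuple[str, ...]
    values: np.ndarray
    threshold_label: str = "unlabeled"
    flagged_classes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.gene_ids), len(self.class_names)):
            raise ExpressionError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.class_names)} classes"
            )
        folded = [g.casefold() for g in self.gene_ids]
        if len(set(folded)) != len(folded):
            dupes = sorted({g for g in folded if folded.count(g) > 1})
            raise ExpressionError(f"duplicate gene identifiers (case-folded): {dupes}")
        if len(set(self.class_names)) != len(self.class_names):
            raise ExpressionError("duplicate class names")
        if values.size and (not np.isfinite(values).all() or (values < 0).any()):
            raise ExpressionError("expression values must be finite and >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def row(self, gene_id: str) -> np.ndarray:
        """Expression vector of `gene_id` over `class_names` (exact id)."""
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.class_names))


def _resolves(label: str, folded_vocab: set[str]) -> bool:
    """Does a header token name a known class or cell?

    Accepts exact labels, zero-padded cell numbering (``VB01``) and
    state-split class labels (``AWC_ON`` resolves via its base ``AWC``),
    mirroring :func:`elegansviz.anatomy.expand_class`.
    """
    token = str(label).strip().casefold()
    if token in folded_vocab:
        return True
    m = re.match(r"^([a-z]+)0*(\d+)$", token)
    if m and f"{m.group(1)}{int(m.group(2))}" in folded_vocab:
        return True
    return token.split("_", 1)[0] in folded_vocab


def _match_count(labels: list[str], vocabulary: set[str]) -> int:
    folded = {v.casefold() for v in vocabulary}
    return sum(1 for x in labels if _resolves(x, folded))


def load_expression_csv(
    path: str | Path,
    orientation: str = "auto",
    *,
    threshold_label: str | None = None,
    class_vocabulary: set[str] | None = None,
) -> ExpressionTable:
    """Load a CeNGEN-style expression CSV.

    The file is a standard comma-separated table (UTF-8, RFC-4180 dialect)
    with gene symbols on one axis and neuron-class labels on the other.

    Parameters
    ----------
    orientation
        ``"genes_as_rows"``, ``"genes_as_cols"``, or ``"auto"``.  Auto
        counts header tokens on each axis that match the neuron-class
        vocabulary and picks the axis with more matches, so a transposed
        file loads identically.
    threshold_label
        Provenance tag stored on the table; defaults to the file stem.
    class_vocabulary
        Class labels to resolve against; defaults to the packaged
        hermaphrodite roster's vocabulary (base classes plus common
        state-split labels such as ``AWC_ON``).

    Raises
    ------
    ExpressionError
        Unreadable file, duplicate genes, negative values, or neither axis
        matching any known class name (which signals a wrong file rather
        than a wrong orientation).
    """
    path = Path(path)
    if orientation not in ("auto", "genes_as_rows", "genes_as_cols"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        frame = pd.read_csv(path, index_col=0)
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ExpressionError(f"cannot read expression CSV {path}: {exc}") from exc
    if frame.index.has_duplicates:
        raise ExpressionError(f"duplicate row labels in {path}")
    if frame.isna().any().any():
        log.info("missing cells in %s read as 0", path)
        frame = frame.fillna(0.0)

    vocab = class_vocabulary if class_vocabulary is not None else default_class_vocabulary()
    cols = [str(c) for c in frame.columns]
    rows = [str(r) for r in frame.index]
    col_hits, row_hits = _match_count(cols, vocab), _match_count(rows, vocab)
    if orientation == "auto":
        if col_hits == 0 and row_hits == 0:
            raise ExpressionError(
                f"no header of {path} matches any known neuron class; "
                "this does not look like a neuron expression table"
            )
        orientation = "genes_as_rows" if col_hits >= row_hits else "genes_as_cols"
    if orientation == "genes_as_cols":
        frame = frame.T
        col_hits = row_hits
    if col_hits == 0:
        raise ExpressionError(
            f"no class header of {path} matches the neuron-class vocabulary"
        )

    class_names = tuple(str(c) for c in frame.columns)
    folded_vocab = {v.casefold() for v in vocab}
    flagged = frozenset(c for c in class_names if not _resolves(c, folded_vocab))
    if flagged:
        log.info("%d column(s) of %s do not match neuron classes: %s",
                 len(flagged), path, sorted(flagged))
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ExpressionError(f"non-numeric expression values in {path}: {exc}") from exc
    return ExpressionTable(
        gene_ids=tuple(str(g) for g in frame.index),
        class_names=class_names,
        values=values,
        threshold_label=threshold_label if threshold_label is not None else path.stem,
        flagged_classes=flagged,
    )


def write_expression_csv(table: ExpressionTable, path: str | Path) -> Path:
    """Write `table` back to CSV (genes as rows) in the dialect we read."""
    path = Path(path)
    table.to_frame().to_csv(path, index_label="gene")
    return path


def lookup_gene(table: ExpressionTable, query: str) -> str:
    """Resolve a gene name case-insensitively to its canonical symbol.

    An exact case-folded match wins.  On a miss a
    :class:`GeneNotFoundError` is raised carrying up to five nearest
    symbols by edit distance (ties broken alphabetically); an empty query
    gets no suggestions.
    """
    q = query.strip().casefold()
    if not q:
        raise GeneNotFoundError(query, [])
    for gene in table.gene_ids:
        if gene.casefold() == q:
            return gene
    ranked = sorted(
        table.gene_ids,
        key=lambda g: (edlib.align(q, g.casefold())["editDistance"], g.casefold()),
    )
    return_suggestions = ranked[:5]
    raise GeneNotFoundError(query, return_suggestions)


def expressing_classes(
    table: ExpressionTable, gene: str, min_value: float = 0.0
) -> set[str]:
    """Classes in which `gene` is expressed: entries strictly above `min_value`.

    The default ``min_value=0`` treats any nonzero entry of an
    already-thresholded table as "expressed".  An all-zero gene yields the
    empty set (a valid answer, not an error).
    """
    gene_id = lookup_gene(table, gene)
    if min_value < 0:
        raise ValueError("min_value must be >= 0")
    mask = table.row(gene_id) > min_value
    return {c for c, hit in zip(table.class_names, mask) if hit}
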