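"""Shared fixtures: synthetic worms and expression tables."""

from __future__ import annotations

import numpy as np
import pytest

import elegansviz as ev


@pytest.fixture(scope="session")
def nested_spec() -> ev.FixtureSpec:
    """3 genes over 4 two-cell classes in a nested inclusion chain."""
    base = ev.FixtureSpec(n_classes=4, cells_per_class=2, n_genes=3)
    return ev.FixtureSpec(
        n_classes=4, cells_per_class=2, n_genes=3,
        expression_design=ev.nested_design(base), seed=7,
    )


@pytest.fixture(scope="session")
def nested_fixture(nested_spec, tmp_path_factory):
    """(model, roster, table, partition) for the nested 3-gene design."""
    out = tmp_path_factory.mktemp("nested")
    model_path, roster_path = ev.make_synthetic_model(nested_spec, out)
    csv_path = ev.make_synthetic_expression(nested_spec, out / "expression.csv")
    roster = ev.load_roster(roster_path)
    model = ev.load_model(model_path, roster)
    table = ev.load_expression_csv(csv_path)
    sigs = ev.compute_signatures(table, list(nested_spec.genes), roster)
    partition = ev.partition_by_signature(sigs)
    return model, roster, table, partition


@pytest.fixture(scope="session")
def default_roster():
    return ev.default_roster()


def enumerate_partition(table, genes, roster, min_value=0.0):
    """Independent partition oracle: for each of the 2^G signatures,
    collect the matching cells by direct set arithmetic."""
    import itertools

    per_gene = []
    for g in genes:
        cells = set()
        for label in ev.expressing_classes(table, g, min_value):
            cells.update(ev.expand_class(roster, label).cells)
        per_gene.append(cells)
    universe = set(roster.cell_names)
    blocks = {}
    background = frozenset()
    for bits in itertools.product([False, True], repeat=len(genes)):
        members = set(universe)
        for b, cells in zip(bits, per_gene):
            members &= cells if b else (universe - cells)
        if not members:
            continue
        if any(bits):
            blocks[bits] = frozenset(members)
        else:
            background = frozenset(members)
    return blocks, background


def brute_force_point_triangle(point: np.ndarray, tri: np.ndarray) -> float:
    """Independent point-triangle distance: evaluate the 7 candidate
    closest points (unconstrained plane projection, 3 clamped edges,
    3 vertices) and take the minimum distance."""
    a, b, c = tri
    candidates = [a, b, c]
    for p0, p1 in ((a, b), (b, c), (c, a)):
        e = p1 - p0
        t = float(np.dot(point - p0, e) / np.dot(e, e))
        candidates.append(p0 + np.clip(t, 0.0, 1.0) * e)
    # plane projection, kept only if inside the triangle
    n = np.cross(b - a, c - a)
    nn = float(np.dot(n, n))
    if nn > 0:
        proj = point - (np.dot(point - a, n) / nn) * n
        area = np.linalg.norm(n)
        w0 = np.linalg.norm(np.cross(b - proj, c - proj)) / area
        w1 = np.linalg.norm(np.cross(c - proj, a - proj)) / area
        w2 = np.linalg.norm(np.cross(a - proj, b - proj)) / area
        if abs(w0 + w1 + w2 - 1.0) < 1e-9:
            candidates.append(proj)
    return min(float(np.linalg.norm(point - q)) for q in candidates)


def brute_force_nearest_cell(model, point: np.ndarray) -> tuple[str, float]:
    """Exhaustive nearest-mesh scan: min over every triangle of every
    neuron mesh, ties broken lexicographically by cell name."""
    best = (None, np.inf)
    for cell in sorted(model.neuron_meshes):
        tris = np.asarray(model.neuron_meshes[cell].triangles)
        d = min(brute_force_point_triangle(point, t) for t in tris)
        if d < best[1]:
            best = (cell, d)
    return best
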