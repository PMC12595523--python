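"""Signature computation, partitioning, color assignment, overlays."""

from __future__ import annotations

import numpy as np
import pytest

import elegansviz as ev
from elegansviz.coexpression import ExpressionSignature


def _table(genes, classes, design):
    """In-memory table from a gene -> expressing-class-set design."""
    values = np.array([[5.0 if c in design.get(g, set()) else 0.0
                        for c in classes] for g in genes])
    return ev.ExpressionTable(gene_ids=tuple(genes),
                              class_names=tuple(classes), values=values,
                              threshold_label="synthetic")


from conftest import enumerate_partition  # noqa: E402


@pytest.fixture(scope="module")
def roster():
    return ev.default_roster()


NESTED = {"g1": {"AVK", "RIM", "RIC"}, "g2": {"RIM", "RIC"}, "g3": {"RIC"}}
NESTED_CLASSES = ["AVK", "RIM", "RIC", "ASK"]


class TestSignatures:
    def test_full_coexpression_cell(self, roster):
        table = _table(["g1", "g2", "g3"], NESTED_CLASSES, NESTED)
        sigs = ev.compute_signatures(table, ["g1", "g2", "g3"], roster)
        assert sigs["RICL"].bits == (True, True, True)

    def test_single_gene_cell(self, roster):
        table = _table(["g1", "g2", "g3"], NESTED_CLASSES, NESTED)
        sigs = ev.compute_signatures(table, ["g1", "g2", "g3"], roster)
        assert sigs["AVKL"].bits == (True, False, False)

    def test_non_expressing_cell_all_false(self, roster):
        table = _table(["g1", "g2", "g3"], NESTED_CLASSES, NESTED)
        sigs = ev.compute_signatures(table, ["g1", "g2", "g3"], roster)
        assert sigs["ASKL"].bits == (False, False, False)
        part = ev.partition_by_signature(sigs)
        assert "ASKL" in part.background

    def test_state_split_column_reaches_both_cells(self, roster):
        table = _table(["g1"], ["AWC_ON"], {"g1": {"AWC_ON"}})
        sigs = ev.compute_signatures(table, ["g1"], roster)
        assert sigs["AWCL"].bits == (True,) and sigs["AWCR"].bits == (True,)

    def test_empty_gene_list_rejected(self, roster):
        table = _table(["g1"], ["AVK"], {"g1": {"AVK"}})
        with pytest.raises(ValueError):
            ev.compute_signatures(table, [], roster)

    def test_unknown_gene_raises_with_suggestions(self, roster):
        table = _table(["g1"], ["AVK"], {"g1": {"AVK"}})
        with pytest.raises(ev.GeneNotFoundError):
            ev.compute_signatures(table, ["g9"], roster)


class TestPartition:
    def test_nested_design_three_blocks(self, roster):
        table = _table(["g1", "g2", "g3"], NESTED_CLASSES, NESTED)
        part = ev.partition_by_signature(
            ev.compute_signatures(table, ["g1", "g2", "g3"], roster))
        got = {sig.bits: cells for sig, cells in part.blocks.items()}
        assert set(got) == {(True, False, False), (True, True, False),
                            (True, True, True)}
        assert got[(True, False, False)] == {"AVKL", "AVKR"}
        assert got[(True, True, True)] == {"RICL", "RICR"}

    def test_single_gene_single_block(self, roster):
        table = _table(["g1"], ["AVK"], {"g1": {"AVK"}})
        part = ev.partition_by_signature(
            ev.compute_signatures(table, ["g1"], roster))
        assert len(part.blocks) == 1

    def test_disjoint_genes_no_coexpression_block(self, roster):
        table = _table(["g1", "g2"], ["AVK", "RIM"],
                       {"g1": {"AVK"}, "g2": {"RIM"}})
        part = ev.partition_by_signature(
            ev.compute_signatures(table, ["g1", "g2"], roster))
        assert {s.bits for s in part.blocks} == {(True, False), (False, True)}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, roster, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(1, 6))
        classes = list(np.random.default_rng(seed + 100).choice(
            ev.fixtures.LR_CLASSES, size=int(rng.integers(2, 21)),
            replace=False))
        genes = [f"g{i}" for i in range(n_genes)]
        design = {g: {c for c in classes if rng.random() < 0.4}
                  for g in genes}
        table = _table(genes, classes, design)
        part = ev.partition_by_signature(
            ev.compute_signatures(table, genes, roster))
        oracle_blocks, oracle_bg = enumerate_partition(table, genes, roster)
        assert {s.bits: c for s, c in part.blocks.items()} == oracle_blocks
        assert part.background == oracle_bg

    @pytest.mark.parametrize("seed", range(5))
    def test_adding_a_gene_refines(self, roster, seed):
        rng = np.random.default_rng(seed)
        classes = list(ev.fixtures.LR_CLASSES[:10])
        genes = ["g1", "g2", "g3"]
        design = {g: {c for c in classes if rng.random() < 0.5} for g in genes}
        table = _table(genes, classes, design)
        small = ev.partition_by_signature(
            ev.compute_signatures(table, genes[:2], roster))
        big = ev.partition_by_signature(
            ev.compute_signatures(table, genes, roster))
        fine = list(big.blocks.values()) + [big.background]
        for cells in list(small.blocks.values()) + [small.background]:
            covered = [f & cells for f in fine if f & cells]
            assert frozenset().union(*covered) == cells
            for f in fine:  # each fine block entirely in or out
                assert (f & cells) in (frozenset(), f)


class TestColors:
    def _nested_partition(self, roster):
        table = _table(["g1", "g2", "g3"], NESTED_CLASSES, NESTED)
        return ev.partition_by_signature(
            ev.compute_signatures(table, ["g1", "g2", "g3"], roster))

    def test_explicit_green_blue_orange(self, roster):
        """Transporter-alone green, +first enzyme blue, +both orange."""
        part = self._nested_partition(roster)
        green, blue, orange = (0, .8, .2, 1), (.1, .35, .95, 1), (1, .55, 0, 1)
        cmap = ev.assign_colors(part, {
            (True, False, False): green,
            (True, True, False): blue,
            (True, True, True): orange,
        })
        by_bits = {s.bits: c for s, c in cmap.entries.items()}
        assert by_bits[(True, False, False)] == green
        assert by_bits[(True, True, False)] == blue
        assert by_bits[(True, True, True)] == orange

    def test_explicit_map_missing_block_lists_signatures(self, roster):
        part = self._nested_partition(roster)
        with pytest.raises(KeyError, match="111"):
            ev.assign_colors(part, {(True, False, False): (1, 0, 0, 1),
                                    (True, True, False): (0, 1, 0, 1)})

    def test_default_palette_order_is_popcount_then_binary(self, roster):
        part = self._nested_partition(roster)
        cmap = ev.assign_colors(part, "classic")
        by_bits = {s.bits: c for s, c in cmap.entries.items()}
        pal = ev.coexpression.PALETTES["classic"]
        assert by_bits[(True, False, False)] == pal[0]
        assert by_bits[(True, True, False)] == pal[1]
        assert by_bits[(True, True, True)] == pal[2]

    def test_determinism(self, roster):
        part = self._nested_partition(roster)
        a = ev.assign_colors(part, "bright", seed=3)
        b = ev.assign_colors(part, "bright", seed=3)
        assert a == b

    def test_injective_palette_gives_bijection(self, roster):
        rng = np.random.default_rng(1)
        classes = list(ev.fixtures.LR_CLASSES[:12])
        genes = [f"g{i}" for i in range(4)]
        design = {g: {c for c in classes if rng.random() < 0.5} for g in genes}
        table = _table(genes, classes, design)
        part = ev.partition_by_signature(
            ev.compute_signatures(table, genes, ev.default_roster()))
        cmap = ev.assign_colors(part, "classic", seed=0)
        assert len(set(cmap.entries.values())) == len(part.blocks)


class TestSignalingOverlay:
    def test_narrow_ligand_broad_receptor(self, roster):
        """Neuropeptide in AVK only; receptor widely expressed."""
        classes = list(ev.fixtures.LR_CLASSES[:8])
        design = {"flp-1": {"AVK"},
                  "frpr-7": set(classes) - {"AVK"}}
        table = _table(["flp-1", "frpr-7"], classes, design)
        roles = ev.signaling_overlay(table, "flp-1", "frpr-7", roster)
        senders = {c for c, r in roles.items() if r == "sender"}
        receivers = {c for c, r in roles.items() if r == "receiver"}
        assert senders == {"AVKL", "AVKR"}
        assert len(receivers) == 2 * 7
        assert not any(r == "both" for r in roles.values())

    def test_self_pair_is_both(self, roster):
        table = _table(["flp-1"], ["AVK"], {"flp-1": {"AVK"}})
        roles = ev.signaling_overlay(table, "flp-1", "flp-1", roster)
        assert roles["AVKL"] == "both"

    def test_non_expressing_cell_is_none(self, roster):
        table = _table(["flp-1", "frpr-7"], ["AVK", "RIM"],
                       {"flp-1": {"AVK"}, "frpr-7": {"RIM"}})
        roles = ev.signaling_overlay(table, "flp-1", "frpr-7", roster)
        assert roles["ASKL"] == "none"

    def test_equals_two_gene_signature_partition(self, roster):
        """Roles are exactly the four 2-gene signatures renamed."""
        rng = np.random.default_rng(5)
        classes = list(ev.fixtures.LR_CLASSES[:10])
        design = {"lig": {c for c in classes if rng.random() < 0.3},
                  "rec": {c for c in classes if rng.random() < 0.6}}
        table = _table(["lig", "rec"], classes, design)
        roles = ev.signaling_overlay(table, "lig", "rec", roster)
        sigs = ev.compute_signatures(table, ["lig", "rec"], roster)
        rename = {(True, False): "sender", (False, True): "receiver",
                  (True, True): "both", (False, False): "none"}
        assert roles == {c: rename[s.bits] for c, s in sigs.items()}


def test_export_partition_csv_columns(roster, tmp_path):
    table = _table(["g1", "g2", "g3"], NESTED_CLASSES, NESTED)
    part = ev.partition_by_signature(
        ev.compute_signatures(table, ["g1", "g2", "g3"], roster))
    cmap = ev.assign_colors(part)
    out = ev.export_partition_csv(part, cmap, roster, tmp_path / "p.csv")
    import pandas as pd
    frame = pd.read_csv(out)
    assert list(frame.columns) == ["cell_name", "class_name",
                                   "signature_bits", "color_hex", "role"]
    row = frame.set_index("cell_name").loc["RICL"]
    assert row.signature_bits == 111 or str(row.signature_bits) == "111"


def test_signature_invariants():
    sig = ExpressionSignature(("a", "b", "c"), (True, False, True))
    assert sig.popcount == 2 and sig.as_int() == 0b101
    with pytest.raises(ValueError):
        ExpressionSignature(("a",), (True, False))
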