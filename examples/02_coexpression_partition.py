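"""Partition neurons by which subset of three query genes they express.

Reproduces the nested monoamine-pathway pattern: a broadly expressed
gene (think cat-1/VMAT), a nested synthesis enzyme (tdc-1) and a further
nested one (tbh-1).  Cells expressing only the first gene are one block,
cells co-expressing the first two another, cells expressing all three a
third — colored green / blue / orange.
"""

import tempfile
from pathlib import Path

import elegansviz as ev

out = Path(tempfile.mkdtemp())
base = ev.FixtureSpec(n_classes=4, cells_per_class=2, n_genes=3)
spec = ev.FixtureSpec(n_classes=4, cells_per_class=2, n_genes=3,
                      expression_design=ev.nested_design(base))
csv_path = ev.make_synthetic_expression(spec, out / "expression.csv")

table = ev.load_expression_csv(csv_path)
roster = ev.default_roster()
signatures = ev.compute_signatures(table, ["g1", "g2", "g3"], roster)
partition = ev.partition_by_signature(signatures)

cmap = ev.assign_colors(partition, {
    (True, False, False): (0.0, 0.8, 0.2, 1.0),   # green: g1 only
    (True, True, False): (0.1, 0.35, 0.95, 1.0),  # blue: g1+g2
    (True, True, True): (1.0, 0.55, 0.0, 1.0),    # orange: all three
})

print(f"{len(partition.blocks)} co-expression blocks "
      f"({len(partition.expressing_cells)} cells express >=1 gene):")
for sig in sorted(partition.blocks, key=lambda s: (s.popcount, s.as_int())):
    cells = sorted(partition.blocks[sig])
    hexcol = ev.coexpression.color_to_hex(cmap.entries[sig])
    print(f"  genes {sig.expressed_genes} -> {cells}  color {hexcol}")
print("-> each block is the set of neurons sharing one exact expression "
      "signature over the query genes.")

csv = ev.export_partition_csv(partition, cmap, roster, out / "partition.csv")
print(f"per-cell table written to {csv}")
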