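"""Load a gene-by-neuron-class expression CSV and query a gene.

Builds a small synthetic dataset (real class names, toy values), then
resolves a gene name case-insensitively and lists the classes expressing
it — the starting point of every overlay.
"""

import tempfile
from pathlib import Path

import elegansviz as ev

out = Path(tempfile.mkdtemp())
spec = ev.FixtureSpec(n_classes=6, n_genes=4, sparsity=0.4, seed=11)
csv_path = ev.make_synthetic_expression(spec, out / "expression.csv")

table = ev.load_expression_csv(csv_path)
print(f"loaded {table.n_genes} genes x {table.n_classes} neuron classes "
      f"from {csv_path.name}")

gene = ev.lookup_gene(table, "G2")  # case-insensitive
classes = ev.expressing_classes(table, gene)
print(f"{gene} is expressed in {len(classes)} classes: {sorted(classes)}")
print("-> these are the transcriptomic classes whose neurons would light "
      "up for this gene.")

try:
    ev.lookup_gene(table, "g9")
except ev.GeneNotFoundError as err:
    print(f"unknown gene handled gracefully; suggestions: {err.suggestions}")
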