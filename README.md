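# elegansviz

Map single-cell RNA-seq expression onto the 3D anatomy of the
*Caenorhabditis elegans* nervous system — headlessly.

Transcriptomic atlases of the worm's nervous system report gene expression
per *neuron class* (AVK, RIM, VA, …), typically as a gene × class matrix
already thresholded for detection (the CeNGEN consortium's L4 matrices are
the canonical example).  Anatomical models name each individual *neuron
cell* (AVKL, AVKR, VA3, …).  `elegansviz` bridges the two for researchers
who want to see where expression sits in the animal rather than in a
heatmap: it loads any CeNGEN-style CSV, expands class labels to the 302
hermaphrodite neurons, partitions neurons by which subset of a query gene
set they express, binds each subset to a color, and renders or exports the
colored 3D scene.  It also supports ligand/receptor *sender–receiver*
overlays and point-based neuron identification (the headless analogue of
clicking a cell in a viewport).

## The core computation

For an ordered query gene list g₁…g_G and a thresholded expression matrix
E (genes × classes), each neuron cell *c* of class *k* gets a boolean
**expression signature**

    s(c) = ( 1[E(g₁, k) > t], …, 1[E(g_G, k) > t] )  ∈ {0,1}^G

with detection cutoff *t* (default 0: any positive entry of an
already-thresholded matrix counts as expressed).  Grouping cells by exact
signature yields a disjoint partition of the expressing nervous system —
one block per realized co-expression pattern, at most 2^G − 1 blocks —
while all-zero cells form the uncolored background.  Blocks are ordered by
(popcount, binary value) and bound deterministically to palette colors,
so "more co-expression" reads as hotter colors.  A ligand/receptor pair is
the G = 2 special case read out as roles: sender (ligand only), receiver
(receptor only), both, none.

## Worked example

```python
import elegansviz as ev

# synthetic stand-in for a real dataset + model (same formats, real
# class names); swap in your own CSV / OBJ / glTF paths to use real data
base = ev.FixtureSpec(n_classes=4, cells_per_class=2, n_genes=3)
spec = ev.FixtureSpec(n_classes=4, cells_per_class=2, n_genes=3,
                      expression_design=ev.nested_design(base))
model_path, roster_path = ev.make_synthetic_model(spec, "demo")
csv_path = ev.make_synthetic_expression(spec, "demo/expression.csv")

roster = ev.load_roster(roster_path)          # or ev.default_roster()
model = ev.load_model(model_path, roster)
table = ev.load_expression_csv(csv_path)

sigs = ev.compute_signatures(table, ["g1", "g2", "g3"], roster)
part = ev.partition_by_signature(sigs)
for sig in sorted(part.blocks, key=lambda s: (s.popcount, s.as_int())):
    print(sig.bitstring(), sorted(part.blocks[sig]))

scene = ev.build_scene(model, ev.assign_colors(part), part)
ev.render(scene, ev.camera_preset(model, "whole_worm", (320, 240)),
          "demo/worm.png")
ev.export_scene(scene, "gltf", "demo/worm.gltf")
print(ev.pick_neuron(scene, model.soma_positions["RICL"]))
```

prints

```
100 ['AVKL', 'AVKR']
110 ['RIML', 'RIMR']
111 ['RICL', 'RICR']
('RICL', 0.0)
```

Reading: the nested three-gene design puts the AVK pair in the
"first-gene-only" block (rendered green), RIM in the two-gene
co-expression block (blue), and RIC in the all-three block (orange);
picking at RICL's soma center identifies RICL at distance 0.  The PNG is
a flat-shaded render in which every pixel is exactly one block color, the
neutral neuron grey, the translucent body blend, or the background — so
rendered output is checkable, not just viewable.

The same workflow is available from the shell:

```
elegansviz simulate --out demo --design nested
elegansviz query g1 g2 g3 --expression demo/expression.csv --roster demo/roster.csv
elegansviz render g1 g2 g3 --expression demo/expression.csv \
    --roster demo/roster.csv --model demo/model.obj --out demo/worm.png
elegansviz pick --model demo/model.obj --roster demo/roster.csv --point 10,0,3
```

See `examples/` for one short script per capability.

## Scope

The package renders flat, unlit, anti-aliasing-free images by design —
that makes pixel content exactly predictable.  Presentation-quality lit
rendering, interactive viewports, video encoding (numbered PNG frames are
emitted instead), embryonic/male anatomies, statistical co-expression
testing, and inference of actual synaptic connectivity are out of scope.
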