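# Methods

## Data model

**Expression tables.**  Input is a genes × neuron-classes CSV (RFC-4180,
UTF-8, headers on both axes), the layout used by the CeNGEN consortium's
thresholded L4 matrices.  Values are non-negative reals; missing cells are
read as 0 (sparse exports commonly omit zeros) and logged once per file.
Gene identity is the symbol string, case-folded; duplicate symbols
differing only in case are rejected at load rather than disambiguated at
query time.  WormBase-ID cross-mapping is deliberately not attempted — the
datasets this targets key on symbols.  Orientation is auto-detected by
counting header tokens on each axis that resolve against the neuron-class
vocabulary and keeping the axis with more matches; a file in which
*neither* axis matches any class is rejected as a wrong file rather than
silently transposed.  Columns that fail to resolve (non-neuronal cell
types such as intestine or muscle) are retained but flagged, so one odd
column cannot abort a session.

**"Expressed" semantics.**  The CeNGEN-style matrices are already
thresholded upstream (their "threshold 2"/"threshold 4" variants), so the
default predicate is *strictly positive value*.  A single `min_value`
cutoff (strict `>`) is exposed for continuous tables and applies uniformly
to all query genes; per-gene thresholds were considered and deferred
because the thresholded-matrix contract makes them moot.  `expressing
classes` is monotone non-increasing in `min_value` by construction.

**Nomenclature.**  The hermaphrodite roster — 302 neurons in 118 classes
(class sizes 1–13) — is shipped as packaged CSV data rather than generated
from nomenclature rules at runtime: frozen data is auditable and
testable.  Class-label expansion is a *total* function returning a flag
instead of raising: exact class → members; exact cell name (including
CeNGEN's zero-padded numbering, `VB01` → `VB1`) → that cell; a state-split
label whose base is a class (`AWC_ON`, `RMD_DV`, `VD_DD`) → the base
class's members flagged `state-ambiguous`, because anatomy cannot
distinguish stochastically or positionally split transcriptomic states
and a fabricated left/right assignment would be worse than an honest
ambiguity; anything else → empty, flagged `unknown`.

**Anatomy.**  Models load from OBJ (named objects), glTF 2.0/GLB, or a
directory of per-cell PLY/OBJ files.  Mesh names are matched to roster
cells case-insensitively after an optional user regex strips dialect
prefixes (`WBneuron.AVKL`); unmatched meshes become translucent context
anatomy.  The model's coordinate frame is preserved untouched — camera
presets are defined from the bounding box, not from anatomical axes,
because mesh-file frames vary across model distributions.  Soma position
is the vertex mean of the mesh's largest connected component (for a
soma-plus-neurite mesh the soma sphere dominates the vertex count; for a
discretized sphere the vertex mean is the center).

## Signatures, partitioning, colors

Joint signature computation formalizes iterated single-gene selection:
bit *i* of a cell's signature is true iff its class (or a state-split
column resolving to it) expresses gene *i* above the cutoff.  Partitioning
groups cells by exact signature; the all-false signature never keys a
block — those cells are the background.  Two invariants anchor the tests:
equality with exhaustive enumeration over all 2^G signatures, and
refinement (adding a gene can only split blocks, never merge them).

Default colors are assigned by ordering blocks by (popcount, signature as
a binary number with the first query gene as the high bit) and walking the
palette, so deeper co-expression gets later, hotter colors; the ordering
is total, hence color maps are deterministic for a given palette, gene
order and seed.  When a palette runs out, additional colors are generated
by golden-ratio hue stepping from a seeded start, guaranteeing
distinctness from the existing list.  An explicit user map always wins and
must cover every block (the error names the uncovered bitstrings).  The
sender/receiver overlay gives "both" its own violet rather than a blend of
the dark-red/light-blue role colors — blends are ambiguous against light
backgrounds and would break the exact-pixel-set render contract.

## Rendering

No GPU or windowing stack is assumed: the renderer is a small software
rasterizer (look-at/perspective transform, Sutherland–Hodgman near-plane
clipping, half-space triangle fill, z-buffer) with **flat unlit shading
and no anti-aliasing**.  That trade is deliberate: identical scene and
camera give byte-identical PNGs, and the set of distinct pixel colors in
a frame is exactly {block colors} ∪ {neutral grey, context blend,
background}, which turns rendered images into testable artifacts.
NDC depth is affine in screen space under perspective, so depth is
interpolated linearly from the vertex values; colors are quantized to
8 bits exactly once, at the end of the frame.

Translucency is handled as an underlay: translucent context meshes are
depth-resolved among themselves and composited over the background
exactly once (nearest context surface wins), then opaque neurons are
z-buffered on top.  Neurons therefore always read through the body
outline — the behaviour wanted for worm anatomy — and a context pixel is
one predictable blend rather than a stack of semi-transparent layers.
Context opacity defaults to 0.15.  Turntable sequences are numbered PNG
frames (frame 0 is the start camera); video encoding is left to external
tools for codec reproducibility.

Camera presets derive from the bounding box: the worm's long axis is the
largest extent; `head` is the quarter of that axis containing the most
somata (most neurons cluster in the head ganglia), `tail` the opposite
quarter, `midbody` the central one; the eye sits along the thinnest axis
so the worm is viewed side-on, at the distance that fits the window in
the vertical field of view.

## Export and picking

Scene export writes one named object per visible cell with its RGBA
quantized to 8 bits per channel: glTF 2.0 (single file, embedded buffers,
one PBR material per object; `.glb` honored) via trimesh, OBJ+MTL with one
material per *distinct* color, or a directory of ASCII PLY files (PLY has
no object names, so names live in filenames) with uniform vertex colors.
Re-import returns exactly the quantized bindings.  The OBJ reader/writer
is implemented in-package for a small dialect (v/f/o/g, Kd/d materials)
because object names and material alpha must survive the round trip
bit-for-bit; glTF structural validity is checked by an in-package
validator covering the required asset version and all cross-references
among scenes, nodes, meshes, accessors, buffer views and buffers.

Picking is a 3D point query, not a GUI event: the nearest visible neuron
by exact point-to-triangle surface distance (vectorized closest-point
region classification), with distance 0 for points inside a mesh.
Containment uses ray-crossing parity along three skewed fixed directions
with majority vote (one grazing ray cannot flip the answer), evaluated
per connected component because a soma sphere with a mutually
intersecting neurite tube is a self-intersecting union where global
parity misclassifies the overlap.  Ties break lexicographically by cell
name.  A bounding-sphere lower bound prunes meshes that cannot beat the
current best; pruning preserves the tie-break because a pruned mesh could
at best tie, and ties lose to the earlier name.

## Synthetic data

The fixture generator emulates the two inputs structurally.  Geometry:
soma spheres (icosphere, radius 1 model unit) placed at evenly spaced
stations along a 50-unit body tube, left/right mirror pairs offset ±3
units for two-cell classes, optional thin neurite tubes to the midline;
class names are real C. elegans class names so nomenclature code paths
run on the real vocabulary.  Expression: either an explicit gene →
class-set design (reproduced exactly, with seeded positive values) or
i.i.d. Bernoulli(sparsity) occupancy with values uniform on [1, 10);
defaults are 4 classes × 2 cells, 3 genes, sparsity 0.3.  Two named
designs encode the motivating biology: the *nested* inclusion chain
(broad transporter ⊃ enzyme ⊃ enzyme, yielding exactly one block per
gene) and the *broadcast* design (ligand confined to AVK, receptor in all
other classes, giving 2 senders and 2 × (receptor classes − ligand
classes) receivers by set arithmetic).  Every generator is
byte-deterministic under its seed.

What the fixtures do *not* emulate: realistic single-cell count
distributions, correlated expression structure, real neurite morphology,
or the neuropil's spatial packing.  Passing tests therefore demonstrate
correctness of the mapping, partitioning, coloring, export and picking
machinery on the real nomenclature — not biological fidelity of any
particular rendering.

## Problem sizes and numerical choices

The verification suite uses 50 random fixtures (≤ 5 genes, ≤ 20 two-cell
classes) for the partition oracle, 1000 interior points over a 6-class
worm for picking, and small rasters (≈ 100×100 to 320×240) for render
checks; these sizes make the whole suite run in well under a minute while
exercising every 2^G signature case that matters.  Interior picking
points are sampled inside 0.95 × the discretized sphere's inradius, since
a point between the analytic sphere and its inscribed icosphere is
legitimately *outside* the mesh.  Degenerate rasterizer inputs (zero-area
triangles, triangles behind the eye) are dropped or near-clipped;
degenerate point-triangle configurations fall back to vertex/edge
candidates.  Edit-distance suggestions return the five nearest symbols,
ties alphabetical.

## Known limitations

Per-gene thresholds, male and embryonic rosters, lit rendering, and
screen-pixel (unprojected-ray) picking are not implemented; the state
split of AWC_ON/AWC_OFF is rendered on both anatomical cells by design;
OBJ import ignores normals and texture coordinates; very large meshes
would benefit from a spatial index that the dense proximity math here
does not build.
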