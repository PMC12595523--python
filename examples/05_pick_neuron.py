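"""Identify a neuron from a 3D point — headless 'clicking'.

Builds the toy worm, then asks which neuron is nearest a few query
points: one at a known soma center (distance 0), one off to the side.
"""

import tempfile
from pathlib import Path

import elegansviz as ev

out = Path(tempfile.mkdtemp())
spec = ev.FixtureSpec(n_classes=5, cells_per_class=2)
model_path, roster_path = ev.make_synthetic_model(spec, out)
roster = ev.load_roster(roster_path)
model = ev.load_model(model_path, roster)
scene = ev.build_scene(model, ev.ColorMap(entries={}), None)

center = model.soma_positions["RIML"]
cell, dist = ev.pick_neuron(scene, center)
print(f"point at RIML soma center -> {cell}, distance {dist}")

cell, dist = ev.pick_neuron(scene, center + [0.0, 2.5, 0.0])
print(f"point 2.5 units above it  -> {cell}, distance {dist:.3f}")
print("-> distance 0 means the point is inside the neuron's mesh; "
      "otherwise it is the distance to the nearest neuron surface.")
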