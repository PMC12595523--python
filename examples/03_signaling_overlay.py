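"""Sender/receiver overlay for a neuropeptide and its receptor.

The fixture mimics a broadcast network: a peptide gene confined to the
two AVK interneurons, and its receptor expressed in every other class.
Senders are colored dark red, receivers light blue.
"""

import tempfile
from collections import Counter
from pathlib import Path

import elegansviz as ev

out = Path(tempfile.mkdtemp())
_, roster_path, csv_path = ev.make_fig1c_fixture(out, n_classes=10)

roster = ev.load_roster(roster_path)
table = ev.load_expression_csv(csv_path)
roles = ev.signaling_overlay(table, "flp-1", "frpr-7", roster)

counts = Counter(roles.values())
senders = sorted(c for c, r in roles.items() if r == "sender")
print(f"senders ({counts['sender']}): {senders}")
print(f"receivers: {counts['receiver']} cells, both: {counts['both']}, "
      f"no role: {counts['none']}")
print("-> the two AVK cells broadcast the peptide; every receptor-positive "
      "cell elsewhere is a potential target.")

cmap = ev.role_colormap()
for role in ("sender", "receiver", "both"):
    print(f"  {role}: {ev.coexpression.color_to_hex(cmap.entries[role])}")
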