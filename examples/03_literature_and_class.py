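"""Literature Component and Class Component from offline tables.

LC starts at 1 and subtracts weighted fractions of the reported-compound
counts at species/genus/family rank; CC compares recurrent predicted
chemical classes against the literature class sets by set subtraction.
"""

import pandas as pd

from extractrank import LiteratureSummary, compute_cc, compute_lc, recurrent_classes
from extractrank.io_tables import FeatureTable

# --- LC: a barely studied species vs a heavily studied one -----------------
sparse = LiteratureSummary("x", rcs=2, rcg=8, rcf=100)
heavy = LiteratureSummary("y", rcs=1011, rcg=1353, rcf=6064)
print(f"LC, 2 species / 8 genus / 100 family reports:    {compute_lc(sparse):+.2f}")
print(f"LC, 1011 species / 1353 genus / 6064 reports:    {compute_lc(heavy):+.2f}")
print("(negative LC = reported counts far above the 20/100/500 maxima)")

from extractrank import LCParams

capped = LCParams(cap_fractions=True)
print(f"same counts with each fraction capped at 1:      {compute_lc(heavy, capped):+.2f}\n")

# --- CC: a recurrent confident class unreported in the literature ----------
ids = pd.Index(range(1, 6), name="feature_id")
feats = pd.DataFrame({"mz": [300.0] * 5, "rt": [1.0] * 5}, index=ids)
feats["iin_id"] = pd.array([pd.NA] * 5, dtype="Int64")
feats["adduct"] = None
table = FeatureTable(feats, pd.DataFrame({"ext": [10.0] * 5}, index=ids))
preds = pd.DataFrame(
    {
        "feature_id": ids,
        "npc_class": ["Agarofuran sesquiterpenoids"] * 5,
        "npc_probability": [0.95] * 5,
    }
)
classes = recurrent_classes(preds, table, "ext", min_class_confidence=0.8, min_recurrence=2)
literature = LiteratureSummary(
    "ext",
    species_classes=frozenset({"friedelane triterpenoids"}),
    genus_classes=frozenset({"friedelane triterpenoids"}),
)
cc = compute_cc(classes, literature)
print(f"recurrent classes in extract: {sorted(classes)}")
print(f"CCs={cc.ccs}  CCg={cc.ccg}  CC={cc.cc}")
print("CC = 1: the class is new to both the species and the genus.")
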