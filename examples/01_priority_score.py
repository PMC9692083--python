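"""Combine the four component scores into the Priority Score.

The Priority Score is the weighted sum PS = w_fc*FC + w_lc*LC + w_cc*CC +
w_sc*SC with all weights 1 by default.  Here we score three extracts from
known component values and rank them.
"""

import pandas as pd

from extractrank import compute_ps

components = pd.DataFrame(
    [
        {"filename": "roots_A", "FC": 0.36, "LC": 0.87, "CC": 1.0, "SC": 1},
        {"filename": "roots_B", "FC": 0.24, "LC": 0.78, "CC": 1.0, "SC": 1},
        {"filename": "seeds_C", "FC": 0.34, "LC": 0.66, "CC": 1.0, "SC": 1},
    ]
).set_index("filename")

ranked = compute_ps(components)
print(ranked[["FC", "LC", "CC", "SC", "PS", "rank"]])
print()
print(
    "PS near its maximum of 4 marks an extract that is feature-rich and\n"
    "unannotated (FC), barely studied (LC), shows an unreported chemical\n"
    "class (CC) and is spectrally dissimilar to the rest of the set (SC)."
)
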