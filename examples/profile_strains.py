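"""Merge GC- and HPLC-derived core lipid tables and compute GDGT/AR ratios.

The two instruments see complementary compound sets; archaeol (AR) is
measured by both and anchors the merge: each table is normalized to its AR
response, the union is taken, and the result is expressed in percent.
"""

import pandas as pd

from etherlipids import gdgt_ar_ratio, merge_core_datasets

gc = pd.DataFrame({
    "halophile": {"AR": 10.0, "MAR": 2.0},
    "methanogen": {"AR": 8.0, "MAR": 0.5},
})
hplc = pd.DataFrame({
    "halophile": {"AR": 5.0, "GDGT-0": 5.0},
    "methanogen": {"AR": 4.0, "GDGT-0": 14.0, "GDGT-1": 2.0},
})

merged = merge_core_datasets(gc, hplc)
print("percent of total ether lipids per strain:\n")
print(merged.round(2).to_string())
print()
for strain in merged.columns:
    print(f"GDGT/AR [{strain}] = {gdgt_ar_ratio(merged, strain):.2f}")

# A ratio above 1 marks a tetraether-dominated membrane (typical of the
# extremely halophilic methanogens); below 1, a diether-dominated one.
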