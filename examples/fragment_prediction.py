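"""Predict the diagnostic MS2 fragments of a PGPGP cardiolipin and interpret
an observed neutral loss.

Cardiolipins (two diether cores joined by a polar bridge) fragment by losing
a phytanyl chain, losing a whole core, and cleaving either side of each
phosphate into four half-ions.
"""

from etherlipids import enumerate_library, explain_loss, predict_fragments

lib = enumerate_library()
species = lib.by_id["PGPGP-AR,EXT-AR"]
print(f"{species.uid}: [M+H]+ = {species.mz('+H'):.4f}\n")

for f in predict_fragments(species, "+H"):
    print(f"  m/z {f.mz:9.4f}  (weight {f.weight:.1f})  {f.label}")

# Interpreting a measured delta: a sulfoglycolipid [M+NH4]+ at 1091.7936
# losing to 994.8116 is best explained as combined SO3 + NH3 departure.
hits = explain_loss(1091.7936, 994.8116, tolerance_da=5e-3)
label, theo, err = hits[0]
print(f"\nobserved loss 1091.7936 -> 994.8116 explained as: {label}"
      f" (theory {theo:.4f} Da, error {err * 1000:+.1f} mDa)")
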