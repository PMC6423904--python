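"""Build the default combinatorial lipid library and look at a few entries.

The library enumerates headgroup x core combinations (plus cardiolipins and
the empirical sulfoglycolipid series) with exact neutral formulas and the
three singly charged adduct masses used in positive-mode HILIC-ESI work.
"""

from etherlipids import enumerate_library

lib = enumerate_library()
print(f"{len(lib)} species in the default library\n")

for uid in ("PG-AR", "PG-EXT-AR", "trimethyl-APT-AR", "trimethyl-APT-Me-AR",
            "PGPGP-AR,EXT-AR", "SulfoGly1-AR"):
    sp = lib.by_id[uid]
    formula = sp.formula if sp.formula is not None else "(empirical mass)"
    print(f"{uid:24s} {str(formula):16s} M {sp.neutral_mass:10.4f}"
          f"  [M+H]+ {sp.mz('+H'):10.4f}  [M+NH4]+ {sp.mz('+NH4'):10.4f}")

# The [M+H]+ column is what a high-resolution instrument should measure for
# the protonated species (e.g. trimethyl-APT-AR at m/z 908.77); swapping an
# AR core for extended archaeol adds exactly one C5H10 unit (70.08 Da).
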