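"""Classify polyprenyl synthases by their FARM upstream residues.

The residues 11, 8 and 5 positions before the First Aspartate-Rich Motif
govern isoprenoid product length: small residues at -5 permit elongation to
C25 and beyond, bulky ones block it at C20 unless a small residue at -8
reopens the pocket.
"""

from etherlipids import SimulationConfig, classify_chain_length, find_farm
from etherlipids.simulate import plant_farm_sequence

for triplet in [("P", "L", "G"),   # long-chain synthase cluster
                ("I", "A", "F"),   # C25-capable short-chain (A. pernix-like)
                ("L", "I", "F")]:  # chain-limited short-chain synthase
    seq, _ = plant_farm_sequence(SimulationConfig(seed=1, triplet=triplet))
    motif = find_farm(seq)
    print(f"triplet {'/'.join(motif.triplet)}  motif {motif.motif} at "
          f"{motif.start:3d}  ->  {classify_chain_length(motif)}")

# Long-chain potential is what allows production of extended archaeol
# (the C20/C25 diether) rather than plain C20/C20 archaeol.
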