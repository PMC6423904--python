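"""Annotate a high-resolution MS2 spectrum against the library.

The peak list below is the four-headgroup-fragment pattern of the methylated
APT-Me archaeol: the intact phospho-headgroup ion, its water loss, the
dephosphorylated headgroup ion, and its water loss.
"""

import numpy as np

from etherlipids import Spectrum, annotate, enumerate_library

lib = enumerate_library()
spectrum = Spectrum(
    precursor_mz=922.7816,
    peaks=np.array([[288.1205, 100.0], [270.1100, 55.0],
                    [208.1544, 80.0], [190.1438, 40.0]]),
)

for a in annotate(spectrum, lib)[:3]:
    print(f"rank {a.rank}: {a.species_id:28s} {a.adduct}"
          f"  precursor error {a.precursor_error:+.2f} ppm"
          f"  score {a.score:.3f}  ({len(a.matched_fragments)} fragments)")

# Rank 1 is the trimethyl-APT-Me archaeol: its precursor matches within a
# few ppm and all four diagnostic headgroup ions are present. Lower-ranked
# candidates share the precursor mass but lack the headgroup fragments.
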