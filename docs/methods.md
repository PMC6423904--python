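# Methods

## Mass bookkeeping

All masses are monoisotopic sums of IUPAC atomic masses (≥ 6 decimals;
`etherlipids.chem.DEFAULT_MASSES`, overridable through an
`AtomicMassTable`). Singly charged positive adduct ions use
electron-corrected deltas: [M+H]+ adds the proton mass 1.007276 Da, [M+NH4]+
adds 18.033823 Da, [M+Na]+ adds 22.989218 Da. Measured Orbitrap values for
these lipids deviate from theory by 1–7 ppm, so either the H-atom or the
proton convention would match at a 10 ppm tolerance; the physically correct
proton convention is used throughout. Fragment ions that are intact cations
(the quaternary-ammonium APT headgroup fragments) are computed as the atom
sum minus one electron mass; protonated neutral substructures as neutral
mass plus the proton mass.

High-resolution comparisons are always relative (ppm); ion-trap values are
compared at 0.5 Da, matching the two instrument classes the pipeline
emulates (Orbitrap at 70k resolving power; linear ion trap).

## Species assembly

A species' neutral formula is the sum of its component formulas minus one
H2O per condensation bond. Headgroups are stored as free molecules
(glycerophosphate C3H9O6P for PG, phosphoglycerophosphate C3H10O9P2 for PGP,
and so on) attached by one bond. Permanently charged headgroups (the
N-methylated APT family, quaternary nitrogen) are bookkept as neutral
zwitterions so the ordinary [M+H]+ arithmetic reproduces measured protonated
masses (e.g. trimethyl-APT archaeol at m/z 908.77). Core modifications are
pure formula arithmetic: −H2 per unsaturation or cyclopentane ring or
macrocyclization, +O per hydroxyl, +C5H10 for the C20→C25 chain extension.
sn-2/sn-3 regiochemistry is carried as an annotation and never affects mass
— GC can separate these regioisomers, MS cannot.

Cardiolipin bridges are stored as net residue formulas added to the two core
formulas: C3H6O7P2 for the bisphosphatidylglycerol (BPG/PGP) bridge and
C6H13O12P3 for the PGPGP bridge, which carries one extra glycerophosphate
residue (C3H7O5P, 154.0031 Da exact; the familiar nominal "+154 Da").

The sulfoglycosyl headgroup series (composition C12H25NO13S, and its +SO3
homolog C12H25NO16S2) is stored as **empirical-mass species**: the covalent
attachment of that headgroup cannot be reconciled with the measured
precursor by any condensation bookkeeping (the reported internal losses are
mutually inconsistent at the mDa level), so these four entries are
calibrated to the measured [M+NH4]+ values (1091.7936 for the AR form,
1161.8720 for the EXT-AR form, each +79.9568 for the disulfo homolog) and
carry no assembled formula. Their fragment rules emit the exact SO3+NH3 and
hexose losses plus the theoretical protonated core and isoprenoid-glycerol
ions, which is what the measured spectra show.

## Fragmentation rules

Chain losses are modeled as alkene neutrals (C20H40, C25H50) with the ether
oxygen retained on the glycerol side — this reproduces the observed 280/350
Da deltas. Cardiolipins cleave on either side of each phosphate with both
charge-retention outcomes, giving four half-ions per mixed-core species: the
PG half (core + glycerophosphate residue) and the PGP half (core + the whole
phosphate–glycerol–phosphate bridge residue) for each core. Headgroup
residue losses from [M+NH4]+ precursors are combined with NH3 loss, so the
product is the same protonated ion an [M+H]+ precursor would give.

Diagnosticity weights default to 1.0 for headgroup-defining losses and
half-ions, 0.8 for whole-core losses, 0.5 for chain and glycerol-fragment
ions, 0.3 for NH3, 0.2 for water; they are tunable per call and the
neutral-loss vocabulary is exportable/reimportable as TSV. `explain_loss`
ranks vocabulary assignments by relative error; for every neutral-loss rule
the generating label is recovered at 1 mDa (rule symmetry). Substructure-ion
fragments have no unique complementary "loss" in general (their complement
depends on the precursor), so symmetry is asserted for neutral-loss rules.

## Annotation scoring and ranking

No scoring function exists in the source identifications (they were manual);
the composite score here is a design choice validated by round-trip
properties: `0.4 × max(0, 1 − |precursor error|/tolerance) + 0.6 × (matched
diagnostic weight / total diagnostic weight)`. Defaults: 10 ppm precursor
and 15 ppm fragment tolerance in high-resolution mode, 0.5 Da in trap mode.
All three adduct hypotheses are evaluated per spectrum.

Candidates sort by score, then fewer structural modifications, then species
id — fully deterministic and invariant to peak input order. Ranks use
**competition ranking**: exact score ties share a rank. This matters because
the library necessarily contains constitutional isomers with a single
elemental composition — a trimethyl-APT headgroup is isomeric with a
dimethyl-APT-Me headgroup, and macrocyclic archaeol is isomeric with
mono-unsaturated archaeol — whose precursor *and* fragment m/z sets are
identical. No mass-spectrometric evidence can separate such pairs
(chromatography does); reporting both at rank 1 is the honest statement, and
round-trip accuracy is measured as "the generating species is at rank 1".

## Profiling

Core lipid tables are pandas DataFrames (compounds × strains). The GC and
HPLC datasets are merged by normalizing each strain column to its archaeol
response, taking the union of compounds (AR counted once; the GC value wins
for any compound present in both) and rescaling to percent. This reproduces
the published merging procedure including its acknowledged caveats (equal AR
conservation across analyses, uniform GC response). Missing compounds are
absent cells in raw tables and count as zero in percent normalization;
ratios are returned at full precision, with rounding left to display code.

## Synthetic data

The spectrum generator jitters theoretical peaks uniformly within ±5 ppm
(high-resolution mode; ±0.15 Da in trap mode), drops each fragment with
probability 0.1, draws true intensities from the diagnosticity weights
scaled by lognormal noise (σ = 0.3), and adds a Poisson number of noise
peaks (expectation 0.2 × the number of true peaks) uniform in m/z below the
precursor with intensities under the 10th percentile of true peaks. The
uniform jitter bound mirrors a calibrated instrument's stated accuracy
window. What it does not emulate: isotope envelopes, chimeric precursor
isolation, retention-time structure and intensity response differences
between lipid classes — so passing round-trip tests demonstrates the
scoring separates the library's species under calibrated mass error, not
that real chromatographic interferences are handled.

The profile generator emulates one strain's paired measurements with a
Methanosarcinales-like default composition (45% AR, 15% OH-AR, 6% MAR, 16%
monoether hydrolysis artifacts, 18% GDGTs), lognormal area noise (σ = 0.1)
and instrument-specific scale factors; GDGTs appear only in the HPLC-like
table, mono/diethers only in the GC-like one, AR in both. The sequence
generator plants a DDxxD motif with a chosen (−11, −8, −5) triplet inside
an aspartate-free upstream flank (length ≥ 11, default 11–60 residues), so
no accidental motif can precede the planted one; downstream flanks use the
full alphabet. All generators are pure functions of (config, seed).

## FARM scanning choices

Both DDxxD and DDxxxxD are accepted as FARM variants; the most N-terminal
match wins, and at an equal start the shorter form is taken. Positions count
from the first aspartate: the residue immediately preceding it is −1, so
"the fifth residue before the motif" is index `start − 5` (stated explicitly
because the off-by-one is the classic failure here). The bulkiness partition
is small = {G, A, S, C}, bulky = {F, Y, W}; a bulky −5 with a small −8
(A/G/S) classifies as C25-capable-short, a bulky −5 otherwise as
short-chain-C20 — the latter deliberately includes non-bulky branched
residues at −8 (I, L), which known chain-limited synthases carry. Triplets
with a −5 residue in neither set are reported indeterminate rather than
guessed.

## Problem sizes and tolerances in the test suite

Round-trip experiments use 120 simulated spectra against the full
388-species default library (noise-free: 100% required; default jitter and
noise: ≥ 95%). Profile recovery uses 50 replicates at σ = 0.1 (mean within
2 percentage points). Motif recovery uses 1,000 planted sequences with
random triplets. Printed-mass checks use 10 ppm (high resolution) and 0.5
Da (trap). The whole suite runs in a few seconds on one CPU.

## Known limitations

* No isotope-pattern or intensity prediction; collision-energy dependence is
  not modeled.
* Negative-mode and multiply charged ions are out of scope (all target
  species are singly charged in positive mode).
* The sulfoglycosyl species are calibration entries: their headgroup
  connectivity is unresolved, so enumeration cannot extend them to new cores.
* Peak-area percentages compare classes within a run; they are not molar
  abundances (no response-factor correction across lipid classes).
* GC-resolvable sn-2/sn-3 regioisomer pairs collapse to one mass-degenerate
  library entry with an ambiguity tag.
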