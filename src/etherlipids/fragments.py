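"""Diagnostic MS2/MS3 fragment prediction for archaeal ether lipids.

Fragments are produced by two kinds of rules:

* **neutral-loss rules** subtract a departing neutral (water, ammonia, SO3,
  hexose, a phytanyl chain as the C20H40 alkene, a headgroup condensation
  residue, a whole diether core, ...) from the precursor ion;
* **substructure-ion rules** emit a charged substructure directly (protonated
  core ions, phytanyl-glycerol ions, the quaternary-ammonium headgroup
  fragments of the APT family, cardiolipin half-ions).

Chain losses are modeled as alkene neutrals (C20H40, 280.3130 Da; C25H50,
350.3913 Da) with the ether oxygen retained on the glycerol side.
Cardiolipin cleavage on either side of each phosphate yields both
charge-retention products per core: a PG half-ion and a PGP half-ion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .chem import (
    ADDUCTS,
    Formula,
    PROTON_MASS,
    monoisotopic_mass,
    parse_formula,
)
from .library import (
    BRIDGES,
    HEADGROUPS,
    CoreLipid,
    LipidSpecies,
    H2O,
)

__all__ = [
    "FragmentRule",
    "PredictedFragment",
    "predict_fragments",
    "explain_loss",
    "loss_vocabulary",
    "write_rule_table",
    "read_loss_vocabulary",
    "DEFAULT_WEIGHTS",
]

NH3 = parse_formula("NH3")
SO3 = parse_formula("SO3")
HEXOSE_LOSS = parse_formula("C6H10O5")     # glycosidic hexose as neutral loss
DIHEXOSE_LOSS = parse_formula("C12H20O10")
C20H40 = parse_formula("C20H40")
C25H50 = parse_formula("C25H50")
HPO3 = parse_formula("HPO3")

# Diagnosticity weights by rule family; headgroup-defining ions dominate the
# annotation score, water losses barely contribute.
DEFAULT_WEIGHTS: dict[str, float] = {
    "water": 0.2,
    "ammonia": 0.3,
    "headgroup": 1.0,
    "chain": 0.5,
    "core": 0.8,
    "glycerol": 0.5,
    "half_ion": 1.0,
}

_ADDUCT_ATOMS = {"+H": parse_formula("H"), "+NH4": parse_formula("NH4"),
                 "+Na": parse_formula("Na")}

_HEXOSE_HEADS = {"2Gly", "PG-Gly", "SulfoGly-1", "SulfoGly-2"}


@dataclass(frozen=True)
class FragmentRule:
    """One transformation: a neutral loss or a retained charged substructure."""

    label: str
    kind: str                 # "loss" | "protonated" | "cation"
    formula: Formula | None   # loss formula, or substructure formula
    ms_level: int = 2
    family: str = "headgroup"

    def weight(self, weights: Mapping[str, float]) -> float:
        return weights.get(self.family, 0.5)


@dataclass(frozen=True)
class PredictedFragment:
    mz: float
    label: str
    rule: FragmentRule
    parent_id: str
    ms_level: int
    weight: float


def _residue(head_name: str) -> Formula:
    """The condensed (bound) form of a headgroup: free molecule minus H2O."""
    return HEADGROUPS[head_name].formula - H2O


def _rules_for(species: LipidSpecies, adduct: str) -> list[FragmentRule]:
    rules: list[FragmentRule] = [
        FragmentRule("loss of H2O", "loss", H2O, 2, "water")]
    if adduct == "+NH4":
        rules.append(FragmentRule("loss of NH3", "loss", NH3, 2, "ammonia"))
    # combined with headgroup losses below when the charge carrier is NH4+
    nh4 = adduct == "+NH4"

    def loss(label, formula, level=2, family="headgroup"):
        if nh4:
            rules.append(FragmentRule(f"loss of NH3 + {label}", "loss",
                                      formula + NH3, level, family))
        else:
            rules.append(FragmentRule(f"loss of {label}", "loss", formula,
                                      level, family))

    heads = set(species.head_names)
    cores = species.cores

    # --- empirical sulfoglycosyl series --------------------------------
    if species.empirical:
        loss("SO3", SO3)
        loss("SO3 + hexose (C6H10O5)", SO3 + HEXOSE_LOSS)
        for core in cores:
            rules.append(FragmentRule(
                f"{core.label} core ion", "protonated", core.formula, 2, "core"))
        _glycerol_ions(rules, cores)
        return rules

    # --- cardiolipins ---------------------------------------------------
    if species.bridge is not None:
        for core in dict.fromkeys(cores):
            if core.has_c20_chain:
                loss("phytanyl chain (C20H40)", C20H40, family="chain")
            if core.has_c25_chain:
                loss(f"C25 chain (C25H50)", C25H50, family="chain")
            loss(f"{core.label} core ({core.formula})", core.formula,
                 family="core")
            # cleavage on either side of the central phosphate: the PG half
            # keeps one phosphoglycerol, the PGP half keeps the whole
            # phosphate-glycerol-phosphate bridge residue
            pg_half = core.formula + HEADGROUPS["PG"].formula - H2O
            pgp_half = core.formula + BRIDGES["BPG"].net_formula
            for half, frag in (("PG", pg_half), ("PGP", pgp_half)):
                rules.append(FragmentRule(
                    f"{half}-{core.label} half-ion", "protonated", frag, 2,
                    "half_ion"))
        _dedup_chain(rules)
        return rules

    # --- headgroup-bearing species -------------------------------------
    if "PGS" in heads:
        loss("SO3", SO3)
    if heads & _HEXOSE_HEADS:
        loss("hexose (C6H10O5)", HEXOSE_LOSS)
    if "2Gly" in heads:
        loss("dihexose (C12H20O10)", DIHEXOSE_LOSS)
    for h in species.head_names:
        if "APT" in h:
            hg = HEADGROUPS[h].formula
            rules.append(FragmentRule(
                f"{h} headgroup + phosphate ion", "protonated", hg, 2))
            rules.append(FragmentRule(
                f"{h} headgroup + phosphate - H2O ion", "protonated",
                hg - H2O, 2))
            rules.append(FragmentRule(
                f"{h} headgroup - phosphate ion", "protonated", hg - HPO3, 2))
            rules.append(FragmentRule(
                f"{h} headgroup - phosphate - H2O ion", "protonated",
                hg - HPO3 - H2O, 2))
    # loss of each headgroup residue -> core-containing ion
    for h in dict.fromkeys(species.head_names):
        level = 3 if heads & _HEXOSE_HEADS else 2
        loss(f"{h} residue ({_residue(h)})", _residue(h), level=level)
    core = cores[0]
    if core.cls != "GDGT":
        if core.has_c20_chain:
            loss("phytanyl chain (C20H40)", C20H40, family="chain")
        if core.has_c25_chain:
            loss("C25 chain (C25H50)", C25H50, family="chain")
        _glycerol_ions(rules, cores)
    _dedup_chain(rules)
    return rules


def _glycerol_ions(rules: list[FragmentRule], cores) -> None:
    """Isoprenoid-glycerol ions: one chain retained on the glycerol."""
    any_c20 = any(c.has_c20_chain for c in cores)
    any_c25 = any(c.has_c25_chain for c in cores)
    if any_c20:
        rules.append(FragmentRule(
            "phytanyl-glycerol ion (C23H49O3+)", "protonated",
            parse_formula("C23H48O3"), 3, "glycerol"))
    if any_c25:
        rules.append(FragmentRule(
            "C25-glycerol ion (C28H59O3+)", "protonated",
            parse_formula("C28H58O3"), 3, "glycerol"))


def _dedup_chain(rules: list[FragmentRule]) -> None:
    seen = set()
    out = []
    for r in rules:
        key = (r.label, r.kind)
        if key not in seen:
            seen.add(key)
            out.append(r)
    rules[:] = out


class FragmentationError(ValueError):
    pass


def predict_fragments(species: "LipidSpecies | CoreLipid", adduct: str = "+H",
                      max_ms_level: int = 3,
                      weights: Mapping[str, float] | None = None,
                      ) -> list[PredictedFragment]:
    """Predict diagnostic fragments of ``species`` ionized as ``adduct``.

    Bare :class:`CoreLipid` inputs get only water-loss and chain-related
    rules (no headgroup rules fire). The result is deduplicated by m/z,
    sorted ascending, and every fragment is traceable to its rule.
    """
    if adduct not in ADDUCTS:
        raise FragmentationError(f"unsupported adduct: {adduct!r}")
    weights = weights or DEFAULT_WEIGHTS
    if isinstance(species, CoreLipid):
        core = species
        species = LipidSpecies(core.label, core.label, (), (core,), None,
                               core.formula, core.formula.mass())
        rules = [FragmentRule("loss of H2O", "loss", H2O, 2, "water")]
        if core.has_c20_chain:
            rules.append(FragmentRule("loss of phytanyl chain (C20H40)",
                                      "loss", C20H40, 2, "chain"))
        if core.has_c25_chain:
            rules.append(FragmentRule("loss of C25 chain (C25H50)", "loss",
                                      C25H50, 2, "chain"))
        _glycerol_ions(rules, (core,))
    else:
        rules = _rules_for(species, adduct)

    precursor_mz = species.mz(adduct)
    precursor_atoms = None
    if species.formula is not None:
        precursor_atoms = species.formula + _ADDUCT_ATOMS[adduct]

    frags: list[PredictedFragment] = []
    for rule in rules:
        if rule.ms_level > max_ms_level:
            continue
        if rule.kind == "loss":
            if precursor_atoms is not None and not precursor_atoms.contains(rule.formula):
                continue  # loss not a sub-formula of this precursor
            fmz = precursor_mz - monoisotopic_mass(rule.formula)
        elif rule.kind == "protonated":
            fmz = monoisotopic_mass(rule.formula) + PROTON_MASS
        else:  # cation
            fmz = monoisotopic_mass(rule.formula) - 0.00054857990907
        if not (0 < fmz < precursor_mz):
            continue
        frags.append(PredictedFragment(fmz, rule.label, rule, species.uid,
                                       rule.ms_level, rule.weight(weights)))
    # dedup by rounded m/z, keep the highest-weight explanation
    best: dict[int, PredictedFragment] = {}
    for f in frags:
        key = round(f.mz * 1e5)
        if key not in best or f.weight > best[key].weight:
            best[key] = f
    return sorted(best.values(), key=lambda f: f.mz)


# ---------------------------------------------------------------------------
# Neutral-loss interpretation
# ---------------------------------------------------------------------------

def _base_vocabulary() -> dict[str, float]:
    vocab: dict[str, Formula] = {
        "loss of H2O": H2O,
        "loss of NH3": NH3,
        "loss of SO3": SO3,
        "loss of NH3 + SO3": SO3 + NH3,
        "loss of hexose (C6H10O5)": HEXOSE_LOSS,
        "loss of dihexose (C12H20O10)": DIHEXOSE_LOSS,
        "loss of SO3 + hexose (C6H10O5)": SO3 + HEXOSE_LOSS,
        "loss of NH3 + SO3 + hexose (C6H10O5)": SO3 + NH3 + HEXOSE_LOSS,
        "loss of phytanyl chain (C20H40)": C20H40,
        "loss of C25 chain (C25H50)": C25H50,
        "loss of CH2": parse_formula("CH2"),
        "loss of HPO3": HPO3,
    }
    for h, hg in HEADGROUPS.items():
        vocab[f"loss of {h} residue ({hg.formula - H2O})"] = hg.formula - H2O
        vocab[f"loss of NH3 + {h} residue ({hg.formula - H2O})"] = \
            hg.formula - H2O + NH3
    for cls in ("AR", "EXT-AR"):
        core = CoreLipid(cls)
        vocab[f"loss of {core.label} core ({core.formula})"] = core.formula
        vocab[f"loss of NH3 + {core.label} core ({core.formula})"] = \
            core.formula + NH3
    vocab["loss of NH3 + phytanyl chain (C20H40)"] = C20H40 + NH3
    vocab["loss of NH3 + C25 chain (C25H50)"] = C25H50 + NH3
    return {label: monoisotopic_mass(f) for label, f in vocab.items()}


_VOCAB = _base_vocabulary()


def loss_vocabulary() -> dict[str, float]:
    """The neutral-loss vocabulary (label -> exact mass, Da)."""
    return dict(_VOCAB)


def explain_loss(precursor_mz: float, fragment_mz: float, tolerance_da: float,
                 vocabulary: Mapping[str, float] | None = None,
                 ) -> list[tuple[str, float, float]]:
    """Rank candidate neutral-loss assignments for an observed mass delta.

    Returns ``(label, theoretical loss, signed error in Da)`` tuples sorted
    by increasing relative error. The observed loss is ``precursor -
    fragment``; precursor must exceed fragment.
    """
    if precursor_mz <= fragment_mz:
        raise ValueError(
            f"precursor ({precursor_mz}) must exceed fragment ({fragment_mz})")
    vocab = vocabulary if vocabulary is not None else _VOCAB
    observed = precursor_mz - fragment_mz
    hits = []
    for label, theo in vocab.items():
        delta = observed - theo
        if abs(delta) <= tolerance_da:
            hits.append((label, theo, delta))
    hits.sort(key=lambda t: abs(t[2]) / t[1])
    return hits


def write_rule_table(path) -> None:
    """Serialize the neutral-loss vocabulary as an editable TSV."""
    with open(path, "w") as fh:
        fh.write("label\tloss_mass\n")
        for label, mass in sorted(_VOCAB.items()):
            fh.write(f"{label}\t{mass:.6f}\n")


def read_loss_vocabulary(path) -> dict[str, float]:
    """Read an edited loss vocabulary TSV back (label -> mass)."""
    vocab = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("label"):
            raise ValueError(f"malformed rule table {path}: missing header")
        for line in fh:
            label, mass = line.rstrip("\n").split("\t")
            vocab[label] = float(mass)
    return vocab
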