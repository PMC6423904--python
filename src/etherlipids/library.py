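"""Combinatorial exact-mass library of archaeal ether lipids.

A lipid species is assembled from a diether/tetraether core (archaeol and its
variants, or a GDGT), one or two polar headgroups, or — for cardiolipins —
two cores joined by a polar bridge. Neutral formulas follow condensation
bookkeeping: the sum of the component formulas minus one H2O per bond formed.
Permanently charged headgroups (the N-methylated APT family, quaternary N)
are bookkept as neutral zwitterions so the ordinary [M+H]+ arithmetic applies.

Cores
-----
AR        sn-2,3-di-O-phytanyl glycerol (C43H88O3, two C20 chains)
EXT-AR    extended archaeol, one chain elongated to C25 (+C5H10)
OH-AR     hydroxy archaeol (+O)
MAR       macrocyclic archaeol, ring-closed chains (-H2)
GDGT      glycerol dialkyl glycerol tetraether (C86H172O6); GDGT-n carries
          n cyclopentane rings, each -H2
monoether C20/C25 alkyl glycerol monoethers (acid-hydrolysis artifacts)

Each unsaturation subtracts H2. sn-2/sn-3 regiochemistry is carried as an
annotation only; it never affects mass.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import yaml

from .chem import (
    ADDUCTS,
    Formula,
    FormulaError,
    format_formula,
    mz as adduct_mz,
    parse_formula,
)

__all__ = [
    "CoreLipid",
    "Headgroup",
    "Bridge",
    "LipidSpecies",
    "LipidLibrary",
    "LibraryConfig",
    "HEADGROUPS",
    "BRIDGES",
    "CORE_BASE_FORMULAS",
    "build_core",
    "assemble_species",
    "empirical_species",
    "enumerate_library",
    "default_config",
    "load_library_config",
]

H2 = parse_formula("H2")
H2O = parse_formula("H2O")
O1 = parse_formula("O")
CH2 = parse_formula("CH2")
C5H10 = parse_formula("C5H10")
SO3 = parse_formula("SO3")

CORE_BASE_FORMULAS: dict[str, Formula] = {
    "AR": parse_formula("C43H88O3"),
    "EXT-AR": parse_formula("C48H98O3"),
    "MAR": parse_formula("C43H86O3"),
    "GDGT": parse_formula("C86H172O6"),
    "monoether-C20": parse_formula("C23H48O3"),
    "monoether-C25": parse_formula("C28H58O3"),
}

# Classes whose formula may carry an extra hydroxyl (n_oh); tetraethers and
# monoethers do not.
_DIETHER_CLASSES = ("AR", "EXT-AR", "MAR")


class AssemblyError(ValueError):
    """Raised for incompatible or out-of-range component combinations."""


@dataclass(frozen=True)
class CoreLipid:
    """A core (headgroup-free) ether lipid with its structural modifications."""

    cls: str
    n_uns: int = 0
    n_oh: int = 0
    n_rings: int = 0
    regio: str | None = None  # "sn-2" | "sn-3" | None; annotation only

    @property
    def formula(self) -> Formula:
        f = CORE_BASE_FORMULAS[self.cls]
        if self.n_oh:
            f = f + O1 * self.n_oh
        n_h2 = self.n_uns + self.n_rings
        if n_h2:
            f = f - H2 * n_h2
        return f

    @property
    def label(self) -> str:
        parts = []
        if self.n_uns:
            parts.append(f"Uns{self.n_uns}")
        if self.n_oh:
            parts.append("OH")
        base = self.cls
        if self.cls == "GDGT":
            base = f"GDGT-{self.n_rings}"
        parts.append(base)
        return "-".join(parts)

    @property
    def has_c25_chain(self) -> bool:
        return self.cls in ("EXT-AR", "monoether-C25")

    @property
    def has_c20_chain(self) -> bool:
        return self.cls in ("AR", "EXT-AR", "MAR", "monoether-C20")


def build_core(cls: str, n_uns: int = 0, n_oh: int = 0, n_rings: int = 0,
               regio: str | None = None) -> CoreLipid:
    """Validate modification ranges and construct a :class:`CoreLipid`.

    ``cls`` "OH-AR" is accepted as shorthand for AR with one hydroxyl.
    """
    if cls == "OH-AR":
        cls, n_oh = "AR", max(1, n_oh)
    if cls not in CORE_BASE_FORMULAS:
        raise AssemblyError(f"unknown core class: {cls!r}")
    if not (0 <= n_uns <= 8):
        raise AssemblyError(f"n_uns out of range 0-8: {n_uns}")
    if n_oh not in (0, 1):
        raise AssemblyError(f"n_oh must be 0 or 1: {n_oh}")
    if n_oh and cls not in _DIETHER_CLASSES:
        raise AssemblyError(f"hydroxylation unsupported on {cls}")
    if n_rings and cls != "GDGT":
        raise AssemblyError(f"cyclopentane rings only on GDGT, not {cls}")
    if not (0 <= n_rings <= 8):
        raise AssemblyError(f"n_rings out of range 0-8: {n_rings}")
    return CoreLipid(cls, n_uns, n_oh, n_rings, regio)


@dataclass(frozen=True)
class Headgroup:
    """A polar headgroup as a free (uncondensed) molecule.

    ``formula`` includes the phosphate for phospho-headgroups; attachment to
    a core consumes ``n_bonds`` condensation bonds (one H2O each).
    """

    name: str
    formula: Formula
    n_bonds: int = 1
    zwitterionic: bool = False


def _hg(name: str, formula: str, zwit: bool = False) -> Headgroup:
    return Headgroup(name, parse_formula(formula), 1, zwit)


_APT_BASE = {  # n_N_methyl -> zwitterionic phospho-APT free-molecule formula
    1: "C6H16NO7P",
    2: "C7H18NO7P",
    3: "C8H20NO7P",
}

HEADGROUPS: dict[str, Headgroup] = {
    "PE": _hg("PE", "C2H8NO4P", zwit=True),
    "PG": _hg("PG", "C3H9O6P"),
    "PGP": _hg("PGP", "C3H10O9P2"),
    "PGP-Me": _hg("PGP-Me", "C4H12O9P2"),
    "PGS": _hg("PGS", "C3H9O9PS"),
    "PI": _hg("PI", "C6H13O9P"),
    "PS": _hg("PS", "C3H8NO6P", zwit=True),
    "2Gly": _hg("2Gly", "C12H22O11"),
    "PG-Gly": _hg("PG-Gly", "C9H19O11P"),
}
for _n, _name in ((1, "monomethyl"), (2, "dimethyl"), (3, "trimethyl")):
    f = parse_formula(_APT_BASE[_n])
    HEADGROUPS[f"{_name}-APT"] = Headgroup(f"{_name}-APT", f, 1, True)
    HEADGROUPS[f"{_name}-APT-Me"] = Headgroup(f"{_name}-APT-Me", f + CH2, 1, True)


@dataclass(frozen=True)
class Bridge:
    """A cardiolipin polar bridge, stored as the net residue formula.

    The net formula is what the bridge adds to the sum of the two core
    formulas after all condensations, so species = core_a + core_b + net.
    BPG is the bisphosphatidylglycerol (PGP) bridge; PGPGP carries one
    additional glycerophosphate residue (C3H7O5P, +154.0031 Da).
    """

    name: str
    net_formula: Formula


BRIDGES: dict[str, Bridge] = {
    "BPG": Bridge("BPG", parse_formula("C3H6O7P2")),
    "PGPGP": Bridge("PGPGP", parse_formula("C6H13O12P3")),
}


@dataclass(frozen=True)
class LipidSpecies:
    """One library entry: components, derived neutral formula and mass.

    ``empirical`` species (the sulfoglycosyl headgroup series whose covalent
    attachment could not be reconciled with the measured precursor) carry a
    calibrated neutral mass and no formula.
    """

    uid: str
    class_label: str
    head_names: tuple[str, ...]
    cores: tuple[CoreLipid, ...]
    bridge: str | None
    formula: Formula | None
    neutral_mass: float
    empirical: bool = False

    def mz(self, adduct: str) -> float:
        if adduct not in ADDUCTS:
            raise FormulaError(f"unsupported adduct: {adduct!r}")
        return self.neutral_mass + ADDUCTS[adduct].delta

    @property
    def n_modifications(self) -> int:
        """Structural modification count used for annotation tie-breaking."""
        return sum(c.n_uns + c.n_oh + c.n_rings for c in self.cores)


def assemble_species(heads: str | Sequence[str] | None,
                     cores: CoreLipid | Sequence[CoreLipid],
                     bridge: str | None = None) -> LipidSpecies:
    """Assemble a species from headgroup name(s), core(s) and optional bridge.

    Diethers take exactly one headgroup; GDGTs take one or two (bolaform);
    cardiolipin bridges take exactly two cores and no headgroup.
    """
    if isinstance(cores, CoreLipid):
        cores = (cores,)
    cores = tuple(cores)
    if heads is None:
        heads = ()
    elif isinstance(heads, str):
        heads = (heads,)
    heads = tuple(heads)

    if bridge is not None:
        if bridge not in BRIDGES:
            raise AssemblyError(f"unknown bridge: {bridge!r}")
        if len(cores) != 2:
            raise AssemblyError(f"bridge {bridge} requires exactly 2 cores, got {len(cores)}")
        if heads:
            raise AssemblyError("cardiolipin bridges do not take extra headgroups")
        formula = cores[0].formula + cores[1].formula + BRIDGES[bridge].net_formula
        label = f"{bridge}-{cores[0].label},{cores[1].label}"
        return LipidSpecies(label, label, (), cores, bridge, formula,
                            formula.mass())

    if len(cores) != 1:
        raise AssemblyError("non-cardiolipin species take exactly one core")
    core = cores[0]
    if core.cls == "GDGT":
        if not 1 <= len(heads) <= 2:
            raise AssemblyError("GDGT species take one or two headgroups")
    elif len(heads) != 1:
        raise AssemblyError(f"{core.cls} species take exactly one headgroup")

    formula = core.formula
    n_bonds = 0
    for h in heads:
        if h not in HEADGROUPS:
            raise AssemblyError(f"unknown headgroup: {h!r}")
        formula = formula + HEADGROUPS[h].formula
        n_bonds += HEADGROUPS[h].n_bonds
    formula = formula - H2O * n_bonds

    if core.cls == "GDGT" and len(heads) == 2:
        label = f"{heads[0]}-{core.label}-{heads[1]}"
    else:
        label = f"{heads[0]}-{core.label}"
    return LipidSpecies(label, label, heads, cores, None, formula, formula.mass())


def empirical_species(name: str, core: CoreLipid, head_name: str,
                      precursor_mz: float, adduct: str) -> LipidSpecies:
    """A calibration entry stored by its measured precursor m/z.

    Used for species whose headgroup composition is known only empirically:
    the neutral mass is back-computed from the printed adduct ion.
    """
    neutral = precursor_mz - ADDUCTS[adduct].delta
    return LipidSpecies(name, name, (head_name,), (core,), None, None,
                        neutral, empirical=True)


# Measured [M+NH4]+ precursors of the sulfoglycosyl series: headgroup
# composition C12H25NO13S (SulfoGly-1) or C12H25NO16S2 (SulfoGly-2, +SO3).
_SULFO_NH4 = {"SulfoGly1-AR": 1091.7936, "SulfoGly1-EXT-AR": 1161.8720}


def _sulfo_species() -> list[LipidSpecies]:
    out = []
    so3_mass = SO3.mass()
    for name, mz_nh4 in _SULFO_NH4.items():
        core = build_core("EXT-AR" if "EXT" in name else "AR")
        sp1 = empirical_species(name, core, "SulfoGly-1", mz_nh4, "+NH4")
        sp2 = replace(sp1, uid=name.replace("SulfoGly1", "SulfoGly2"),
                      class_label=name.replace("SulfoGly1", "SulfoGly2"),
                      head_names=("SulfoGly-2",),
                      neutral_mass=sp1.neutral_mass + so3_mass)
        out.extend([sp1, sp2])
    return out


# ---------------------------------------------------------------------------
# Library enumeration
# ---------------------------------------------------------------------------

@dataclass
class LibraryConfig:
    """What to enumerate: headgroups, core modification ranges, adducts."""

    heads: list[str] = field(default_factory=list)
    # core specs: (class, uns_range, oh, rings_range)
    cores: list[dict] = field(default_factory=list)
    adducts: list[str] = field(default_factory=lambda: ["+H", "+NH4", "+Na"])
    gdgt_species: list[tuple] = field(default_factory=list)  # (head1, n_rings, head2|None)
    cardiolipins: list[tuple] = field(default_factory=list)  # (bridge, clsA, clsB)
    include_empirical_sulfo: bool = False

    def is_empty(self) -> bool:
        return not (self.heads and self.cores) and not self.gdgt_species \
            and not self.cardiolipins and not self.include_empirical_sulfo


def default_config() -> LibraryConfig:
    """The default enumeration: the diether headgroup x core inventory of
    halo(alkali)philic euryarchaea, GDGT IPLs, BPG/PGPGP cardiolipins and
    the empirical sulfoglycosyl series."""
    heads = ["PE", "PG", "PGP", "PGP-Me", "PGS", "PI", "PS", "2Gly", "PG-Gly",
             "monomethyl-APT", "dimethyl-APT", "trimethyl-APT",
             "monomethyl-APT-Me", "dimethyl-APT-Me", "trimethyl-APT-Me"]
    cores = [
        {"class": "AR", "uns": (0, 8)},
        {"class": "EXT-AR", "uns": (0, 8)},
        {"class": "AR", "uns": (0, 5), "oh": 1},
        {"class": "MAR", "uns": (0, 0)},
    ]
    gdgts = [("2Gly", 0, None), ("PG", 0, "PG"), ("PG", 1, "PG"), ("PG", 0, "PE")]
    cls = [("BPG", "AR", "AR"), ("BPG", "AR", "EXT-AR"),
           ("PGPGP", "AR", "AR"), ("PGPGP", "AR", "EXT-AR"),
           ("PGPGP", "EXT-AR", "EXT-AR")]
    return LibraryConfig(heads=heads, cores=cores, gdgt_species=gdgts,
                         cardiolipins=cls, include_empirical_sulfo=True)


def load_library_config(path) -> LibraryConfig:
    """Read a LibraryConfig from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = LibraryConfig()
    cfg.heads = list(raw.get("heads", []))
    for c in raw.get("cores", []):
        spec = {"class": c["class"], "uns": tuple(c.get("uns", (0, 0)))}
        if c.get("oh"):
            spec["oh"] = 1
        cfg.cores.append(spec)
    if "adducts" in raw:
        cfg.adducts = list(raw["adducts"])
    for g in raw.get("gdgts", []):
        cfg.gdgt_species.append((g["head1"], int(g.get("rings", 0)), g.get("head2")))
    for c in raw.get("cardiolipins", []):
        cfg.cardiolipins.append((c["bridge"], c["core_a"], c["core_b"]))
    cfg.include_empirical_sulfo = bool(raw.get("empirical_sulfo", False))
    return cfg


class LipidLibrary:
    """An enumerated species list with a sorted, binary-searchable m/z index."""

    def __init__(self, species: Iterable[LipidSpecies], adducts: Sequence[str] = ("+H", "+NH4", "+Na")):
        self.species: list[LipidSpecies] = sorted(
            species, key=lambda s: (s.class_label, s.neutral_mass))
        self.adducts = list(adducts)
        seen: dict[str, int] = {}
        uniq = []
        for sp in self.species:
            if sp.uid in seen:
                seen[sp.uid] += 1
                sp = replace(sp, uid=f"{sp.uid}#{seen[sp.uid]}")
            else:
                seen[sp.uid] = 0
            uniq.append(sp)
        self.species = uniq
        self.by_id = {sp.uid: sp for sp in self.species}
        # flat (mz, species_index, adduct) index, sorted by mz
        entries = []
        for i, sp in enumerate(self.species):
            for a in self.adducts:
                entries.append((sp.mz(a), i, a))
        entries.sort(key=lambda t: t[0])
        self._index = entries
        self._index_mz = [t[0] for t in entries]

    def __len__(self):
        return len(self.species)

    def __iter__(self):
        return iter(self.species)

    def query_precursor(self, observed_mz: float, tol_ppm: float | None = None,
                        tol_da: float | None = None) -> list[tuple[LipidSpecies, str, float]]:
        """All (species, adduct, signed error) whose adduct m/z matches.

        Exactly one of ``tol_ppm`` / ``tol_da`` must be given; errors are
        returned in the same unit.
        """
        if (tol_ppm is None) == (tol_da is None):
            raise ValueError("give exactly one of tol_ppm / tol_da")
        half = observed_mz * tol_ppm * 1e-6 if tol_ppm is not None else tol_da
        lo = bisect.bisect_left(self._index_mz, observed_mz - half)
        hi = bisect.bisect_right(self._index_mz, observed_mz + half)
        out = []
        for theo, i, a in self._index[lo:hi]:
            err = ((observed_mz - theo) / theo * 1e6) if tol_ppm is not None \
                else (observed_mz - theo)
            out.append((self.species[i], a, err))
        return out

    # -- serialization ---------------------------------------------------
    _COLUMNS = ["id", "class", "heads", "cores", "n_uns", "bridge", "formula",
                "neutral_mass", "mz+H", "mz+NH4", "mz+Na", "empirical"]

    def _rows(self) -> list[dict]:
        rows = []
        for sp in self.species:
            rows.append({
                "id": sp.uid,
                "class": sp.class_label,
                "heads": ";".join(sp.head_names),
                "cores": ";".join(
                    f"{c.cls}:uns={c.n_uns}:oh={c.n_oh}:rings={c.n_rings}"
                    for c in sp.cores),
                "n_uns": sum(c.n_uns for c in sp.cores),
                "bridge": sp.bridge or "",
                "formula": format_formula(sp.formula) if sp.formula else "",
                "neutral_mass": f"{sp.neutral_mass:.6f}",
                "mz+H": f"{sp.mz('+H'):.6f}",
                "mz+NH4": f"{sp.mz('+NH4'):.6f}",
                "mz+Na": f"{sp.mz('+Na'):.6f}",
                "empirical": int(sp.empirical),
            })
        return rows

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self._COLUMNS) + "\n")
            for row in self._rows():
                fh.write("\t".join(str(row[c]) for c in self._COLUMNS) + "\n")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self._rows(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_tsv(cls, path) -> "LipidLibrary":
        species = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                cores = []
                for tok in row["cores"].split(";"):
                    if not tok:
                        continue
                    cc, *mods = tok.split(":")
                    kw = dict(m.split("=") for m in mods)
                    cores.append(CoreLipid(cc, int(kw["uns"]), int(kw["oh"]),
                                           int(kw["rings"])))
                formula = parse_formula(row["formula"]) if row["formula"] else None
                species.append(LipidSpecies(
                    row["id"], row["class"],
                    tuple(h for h in row["heads"].split(";") if h),
                    tuple(cores), row["bridge"] or None, formula,
                    float(row["neutral_mass"]), bool(int(row["empirical"]))))
        return cls(species)


def enumerate_library(config: LibraryConfig | None = None) -> LipidLibrary:
    """Enumerate all species allowed by ``config`` (default inventory if None).

    Ordering is deterministic (class label, then mass); duplicate
    (heads, core parameters, bridge) tuples are rejected.
    """
    if config is None:
        config = default_config()
    if config.is_empty():
        raise AssemblyError("empty library config")
    species: list[LipidSpecies] = []
    seen: set = set()

    def _add(sp: LipidSpecies, key):
        if key in seen:
            raise AssemblyError(f"duplicate species spec: {key}")
        seen.add(key)
        species.append(sp)

    for cspec in config.cores:
        lo, hi = cspec.get("uns", (0, 0))
        for n_uns in range(lo, hi + 1):
            core = build_core(cspec["class"], n_uns=n_uns, n_oh=cspec.get("oh", 0))
            for h in config.heads:
                _add(assemble_species(h, core), ((h,), core, None))
    for h1, n_rings, h2 in config.gdgt_species:
        core = build_core("GDGT", n_rings=n_rings)
        heads = (h1,) if h2 is None else (h1, h2)
        _add(assemble_species(heads, core), (heads, core, None))
    for bridge, cls_a, cls_b in config.cardiolipins:
        cores = (build_core(cls_a), build_core(cls_b))
        _add(assemble_species(None, cores, bridge=bridge), ((), cores, bridge))
    if config.include_empirical_sulfo:
        for sp in _sulfo_species():
            _add(sp, (sp.head_names, sp.cores, "empirical"))
    return LipidLibrary(species, adducts=config.adducts)
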