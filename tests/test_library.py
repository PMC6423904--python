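"""Combinatorial library assembly: cores, headgroups, cardiolipins, exports."""

import filecmp

import pytest

from etherlipids.chem import format_formula, monoisotopic_mass, parse_formula, ppm_error
from etherlipids.library import (
    AssemblyError,
    LibraryConfig,
    LipidLibrary,
    assemble_species,
    build_core,
    default_config,
    enumerate_library,
)


def ppm(observed, theoretical):
    return abs(ppm_error(observed, theoretical))


class TestBuildCore:
    def test_archaeol(self):
        assert format_formula(build_core("AR").formula) == "C43H88O3"

    def test_unsaturation_removes_h2(self):
        assert format_formula(build_core("AR", n_uns=1).formula) == "C43H86O3"

    def test_gdgt0_formula_and_mass(self):
        core = build_core("GDGT")
        assert format_formula(core.formula) == "C86H172O6"
        assert monoisotopic_mass(core.formula) + 1.007276 == pytest.approx(
            1302.32, abs=0.05)

    def test_oh_ar_shorthand(self):
        assert build_core("OH-AR").formula == parse_formula("C43H88O4")

    def test_macrocycle_is_minus_h2(self):
        assert build_core("MAR").formula == \
            build_core("AR").formula - parse_formula("H2")

    @pytest.mark.parametrize("kwargs", [
        {"cls": "GDGT", "n_oh": 1},          # hydroxyl unsupported on GDGT
        {"cls": "AR", "n_uns": 9},
        {"cls": "AR", "n_rings": 1},
        {"cls": "XX"},
    ])
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(AssemblyError):
            build_core(**kwargs)

    def test_regio_tag_never_affects_mass(self):
        a = build_core("EXT-AR", regio="sn-2")
        b = build_core("EXT-AR", regio="sn-3")
        assert a.formula == b.formula


class TestAssemble:
    def test_pg_archaeol(self):
        sp = assemble_species("PG", build_core("AR"))
        assert format_formula(sp.formula) == "C46H95O8P"
        assert sp.mz("+H") == pytest.approx(807.8, abs=0.5)

    def test_trimethyl_apt_archaeol_zwitterion(self):
        sp = assemble_species("trimethyl-APT", build_core("AR"))
        assert format_formula(sp.formula) == "C51H106NO9P"
        assert ppm(908.7666, sp.mz("+H")) < 10

    def test_pgpgp_ext_increment_is_70_da_nominal(self):
        iva = assemble_species(None, (build_core("AR"), build_core("AR")),
                               bridge="PGPGP")
        ivb = assemble_species(None, (build_core("AR"), build_core("EXT-AR")),
                               bridge="PGPGP")
        assert round(ivb.mz("+H") - iva.mz("+H")) == 70

    def test_bridge_requires_two_cores(self):
        with pytest.raises(AssemblyError):
            assemble_species(None, build_core("AR"), bridge="BPG")

    def test_gdgt_takes_two_headgroups(self):
        sp = assemble_species(("PG", "PE"), build_core("GDGT"))
        assert sp.class_label == "PG-GDGT-0-PE"
        # two condensations: component sum minus 2 waters
        expected = (build_core("GDGT").formula
                    + parse_formula("C3H9O6P") + parse_formula("C2H8NO4P")
                    - 2 * parse_formula("H2O"))
        assert sp.formula == expected


class TestEnumerate:
    def test_one_species_per_unsaturation(self):
        cfg = LibraryConfig(heads=["PG"], cores=[{"class": "AR", "uns": (0, 8)}])
        assert len(enumerate_library(cfg)) == 9

    def test_apt_product_count(self):
        heads = [f"{m}-APT" for m in ("monomethyl", "dimethyl", "trimethyl")]
        heads += [f"{m}-APT-Me" for m in ("monomethyl", "dimethyl", "trimethyl")]
        cfg = LibraryConfig(heads=heads, cores=[{"class": "AR", "uns": (0, 0)}])
        assert len(enumerate_library(cfg)) == 6

    def test_empty_config_rejected(self):
        with pytest.raises(AssemblyError):
            enumerate_library(LibraryConfig())

    def test_default_contains_sulfo_ext_ar_precursor(self, library):
        hits = library.query_precursor(1161.8720, tol_ppm=10)
        assert any(a == "+NH4" for _, a, _ in hits)

    def test_mass_ladder(self, library):
        """Each added unsaturation removes exactly one H2."""
        h2 = monoisotopic_mass(parse_formula("H2"))
        by_class = {}
        for sp in library:
            if sp.bridge or sp.empirical or sp.cores[0].cls == "GDGT":
                continue
            c = sp.cores[0]
            key = (sp.head_names, c.cls, c.n_oh)
            by_class.setdefault(key, {})[c.n_uns] = sp.neutral_mass
        assert by_class
        for ladder in by_class.values():
            for n in ladder:
                if n + 1 in ladder:
                    assert ladder[n] - ladder[n + 1] == pytest.approx(h2, abs=1e-9)

    def test_ext_increment(self, library):
        c5h10 = monoisotopic_mass(parse_formula("C5H10"))
        ar = library.by_id["PG-AR"].neutral_mass
        ext = library.by_id["PG-EXT-AR"].neutral_mass
        assert ext - ar == pytest.approx(c5h10, abs=1e-9)

    def test_sulfo_so3_increment(self, library):
        so3 = monoisotopic_mass(parse_formula("SO3"))
        for core in ("AR", "EXT-AR"):
            one = library.by_id[f"SulfoGly1-{core}"].neutral_mass
            two = library.by_id[f"SulfoGly2-{core}"].neutral_mass
            assert two - one == pytest.approx(so3, abs=1e-9)

    def test_enumeration_is_deterministic(self, tmp_path):
        for i in (1, 2):
            enumerate_library(default_config()).to_tsv(tmp_path / f"lib{i}.tsv")
            enumerate_library(default_config()).to_json(tmp_path / f"lib{i}.json")
        assert filecmp.cmp(tmp_path / "lib1.tsv", tmp_path / "lib2.tsv",
                           shallow=False)
        assert filecmp.cmp(tmp_path / "lib1.json", tmp_path / "lib2.json",
                           shallow=False)

    def test_tsv_round_trip(self, library, tmp_path):
        path = tmp_path / "lib.tsv"
        library.to_tsv(path)
        back = LipidLibrary.from_tsv(path)
        assert len(back) == len(library)
        for a, b in zip(library, back):
            assert a.uid == b.uid
            assert a.neutral_mass == pytest.approx(b.neutral_mass, abs=1e-5)
            assert a.formula == b.formula

    def test_precursor_query_units(self, library):
        target = library.by_id["PG-AR"].mz("+H")
        assert any(sp.uid == "PG-AR"
                   for sp, a, _ in library.query_precursor(target, tol_ppm=5))
        assert any(sp.uid == "PG-AR"
                   for sp, a, _ in library.query_precursor(target + 0.3, tol_da=0.5))
        with pytest.raises(ValueError):
            library.query_precursor(target)
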