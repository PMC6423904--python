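"""Fragment prediction rules and neutral-loss interpretation."""

import pytest

from etherlipids.chem import parse_formula
from etherlipids.fragments import (
    explain_loss,
    loss_vocabulary,
    predict_fragments,
    read_loss_vocabulary,
    write_rule_table,
)
from etherlipids.library import build_core

_ADDUCT_ATOMS = {"+H": parse_formula("H"), "+NH4": parse_formula("NH4"),
                 "+Na": parse_formula("Na")}


def mzs(frags):
    return [f.mz for f in frags]


def has_near(frags, target, tol):
    return any(abs(m - target) <= tol for m in mzs(frags))


class TestPredict:
    def test_pg_gly_ext_ar_pathway(self, library):
        """Hexose loss to the PG diether ion, then the bare core ion."""
        frags = predict_fragments(library.by_id["PG-Gly-EXT-AR"], "+H")
        assert has_near(frags, 877.8, 0.5)   # loss of hexose -> PG-EXT-AR ion
        assert has_near(frags, 723.7, 0.5)   # EXT-AR core ion

    def test_pgpgp_cardiolipin_chain_loss(self, library):
        frags = predict_fragments(library.by_id["PGPGP-AR,AR"], "+H")
        assert has_near(frags, 1396.0, 0.5)

    def test_cardiolipin_half_ions(self, library):
        """Cleavage either side of each phosphate: four half-ions."""
        frags = predict_fragments(library.by_id["PGPGP-AR,EXT-AR"], "+H")
        for target in (807.8, 869.7, 877.8, 939.7):
            assert has_near(frags, target, 0.5), target

    def test_bare_core_gets_no_headgroup_rules(self):
        frags = predict_fragments(build_core("AR"), "+H", max_ms_level=3)
        assert frags
        for f in frags:
            assert "headgroup" not in f.label and "residue" not in f.label
        assert has_near(frags, 635.7, 0.5)  # water loss from [AR+H]+

    def test_sulfo_series_printed_pathway(self, library):
        frags = predict_fragments(library.by_id["SulfoGly1-AR"], "+NH4")
        assert has_near(frags, 994.8116, 0.02)   # - (SO3 + NH3)
        assert has_near(frags, 832.7605, 0.02)   # - hexose as well
        assert has_near(frags, 653.6800, 0.01)   # AR core ion
        assert has_near(frags, 373.3675, 0.01)   # phytanyl-glycerol ion

    def test_fragments_sorted_dedup_below_precursor(self, library):
        for uid in ("PG-AR", "trimethyl-APT-AR", "PGPGP-AR,AR", "2Gly-GDGT-0"):
            sp = library.by_id[uid]
            frags = predict_fragments(sp, "+H")
            assert mzs(frags) == sorted(mzs(frags))
            assert len(set(round(m, 5) for m in mzs(frags))) == len(frags)
            assert all(0 < m < sp.mz("+H") for m in mzs(frags))

    def test_loss_formulas_are_subformulas_of_precursor(self, library):
        for sp in library:
            if sp.formula is None:
                continue
            for adduct in ("+H", "+NH4"):
                atoms = sp.formula + _ADDUCT_ATOMS[adduct]
                for f in predict_fragments(sp, adduct):
                    if f.rule.kind == "loss":
                        assert atoms.contains(f.rule.formula), (sp.uid, f.label)


class TestExplainLoss:
    def test_so3_plus_nh3(self):
        hits = explain_loss(1091.7936, 994.8116, 5e-3)
        assert hits
        top = hits[0][0]
        assert "SO3" in top and "NH3" in top

    def test_hexose(self):
        hits = explain_loss(994.8116, 832.7605, 5e-3)
        assert "hexose" in hits[0][0]

    def test_equal_masses_rejected(self):
        with pytest.raises(ValueError):
            explain_loss(500.0, 500.0, 1.0)

    def test_no_match_gives_empty_list(self):
        assert explain_loss(1000.0, 999.0, 1e-4) == []

    def test_rule_symmetry(self, library):
        """explain_loss recovers the generating rule for every neutral-loss
        fragment at 1 mDa; exactly isobaric vocabulary entries count as the
        same recovery."""
        for sp in list(library)[::7]:
            for f in predict_fragments(sp, "+H"):
                if f.rule.kind != "loss":
                    continue
                hits = explain_loss(sp.mz("+H"), f.mz, 1e-3)
                assert hits, (sp.uid, f.label)
                best = abs(hits[0][2])
                top_labels = {h[0] for h in hits if abs(h[2]) <= best + 1e-9}
                assert f.label in top_labels, (sp.uid, f.label, hits[:3])

    def test_rule_table_round_trip(self, tmp_path):
        path = tmp_path / "rules.tsv"
        write_rule_table(path)
        vocab = read_loss_vocabulary(path)
        orig = loss_vocabulary()
        assert set(vocab) == set(orig)
        for k in orig:
            assert vocab[k] == pytest.approx(orig[k], abs=1e-6)
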