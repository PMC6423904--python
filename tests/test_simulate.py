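"""Synthetic data generators: determinism, degenerate configs, recovery."""

import numpy as np
import pytest

from etherlipids.fragments import predict_fragments
from etherlipids.profiles import merge_core_datasets
from etherlipids.simulate import (
    DEFAULT_PROFILE_PROPORTIONS,
    SimulationConfig,
    plant_farm_sequence,
    simulate_spectra,
    simulate_spectrum,
    simulate_strain_profile,
)


class TestSpectra:
    def test_degenerate_config_reproduces_theory_exactly(self, library):
        sp = library.by_id["PG-AR"]
        cfg = SimulationConfig(seed=5, jitter_ppm=0.0, noise_fraction=0.0,
                               dropout=0.0)
        spec, truth = simulate_spectrum(sp, "+H", cfg)
        theo = sorted(f.mz for f in predict_fragments(sp, "+H"))
        assert spec.precursor_mz == sp.mz("+H")
        assert np.allclose(np.sort(spec.peaks[:, 0]), theo)
        assert truth["species_id"] == "PG-AR"

    def test_fixed_seed_reproducible(self, library):
        cfg = SimulationConfig(seed=9)
        a, _ = simulate_spectrum(library.by_id["PGS-AR"], "+H", cfg)
        b, _ = simulate_spectrum(library.by_id["PGS-AR"], "+H", cfg)
        assert np.array_equal(a.peaks, b.peaks)
        assert a.precursor_mz == b.precursor_mz

    def test_batch_simulation_samples_without_replacement(self, library):
        pairs = simulate_spectra(library, SimulationConfig(seed=1), n=25)
        assert len(pairs) == 25
        ids = [t["species_id"] for _, t in pairs]
        assert len(set(ids)) == 25

    def test_jitter_stays_within_bound(self, library):
        cfg = SimulationConfig(seed=2, jitter_ppm=5.0, dropout=0.0,
                               noise_fraction=0.0)
        sp = library.by_id["PG-AR"]
        spec, truth = simulate_spectrum(sp, "+H", cfg)
        err = abs(spec.precursor_mz - truth["theoretical_mz"]) \
            / truth["theoretical_mz"] * 1e6
        assert err <= 5.0


class TestProfiles:
    def test_zero_noise_recovers_truth_exactly(self):
        cfg = SimulationConfig(seed=0, profile_sigma=0.0)
        gc, hplc, truth = simulate_strain_profile(cfg)
        merged = merge_core_datasets(gc, hplc)["SIM1"]
        for compound, pct in truth.items():
            assert merged[compound] == pytest.approx(pct, abs=1e-9)

    def test_mean_recovery_under_noise(self):
        """Monte Carlo: mean recovered proportions within 2% at sigma=0.1."""
        cfg = SimulationConfig(profile_sigma=0.1)
        rng = np.random.default_rng(123)
        acc = []
        for _ in range(50):
            gc, hplc, truth = simulate_strain_profile(cfg, rng=rng)
            acc.append(merge_core_datasets(gc, hplc)["SIM1"])
        mean = sum(acc) / len(acc)
        for compound, pct in truth.items():
            assert abs(mean[compound] - pct) < 2.0, compound

    def test_ar_only_profile(self):
        cfg = SimulationConfig(seed=1, proportions={"AR": 1.0})
        gc, hplc, truth = simulate_strain_profile(cfg)
        assert list(gc.index) == ["AR"]
        assert truth["AR"] == 100.0

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            simulate_strain_profile(SimulationConfig(proportions={"AR": 0.5}))
        with pytest.raises(ValueError):
            simulate_strain_profile(SimulationConfig(
                proportions={"MAR": 1.0}))

    def test_default_proportions_are_a_distribution(self):
        assert sum(DEFAULT_PROFILE_PROPORTIONS.values()) == pytest.approx(1.0)


class TestPlantedSequences:
    def test_same_seed_same_sequence(self):
        cfg = SimulationConfig(seed=4, triplet=("I", "A", "F"))
        s1, t1 = plant_farm_sequence(cfg)
        s2, t2 = plant_farm_sequence(cfg)
        assert s1 == s2 and t1 == t2

    def test_two_seeds_differ_but_triplet_is_preserved(self):
        a, ta = plant_farm_sequence(SimulationConfig(seed=1))
        b, tb = plant_farm_sequence(SimulationConfig(seed=2))
        assert a != b
        assert ta["triplet"] == tb["triplet"] == ("P", "L", "G")

    def test_zero_flank_padded_to_eleven(self):
        cfg = SimulationConfig(seed=0, upstream_range=(0, 0))
        seq, truth = plant_farm_sequence(cfg)
        assert truth["motif_start"] == 11

    def test_upstream_flank_has_no_aspartate(self):
        seq, truth = plant_farm_sequence(SimulationConfig(seed=8))
        assert "D" not in seq[:truth["motif_start"]]
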