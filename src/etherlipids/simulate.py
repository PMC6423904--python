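"""Seeded synthetic test data: MS2 spectra, strain profiles, FARM sequences.

The spectrum generator emulates positive-mode HILIC-ESI spectra of intact
polar ether lipids: the precursor and its predicted diagnostic fragments are
jittered within an instrument-accuracy window, a fraction of fragments drops
out, and uniform noise peaks are added below the intensity floor of the true
peaks. The strain-profile generator emulates the paired GC-FID (mono/diether)
and HPLC-MS (AR + GDGT) core-lipid measurements that are merged via AR
normalization, with multiplicative lognormal area noise. The sequence
generator plants a FARM with a chosen upstream triplet inside flanks that are
guaranteed free of accidental upstream motifs.

All generators are pure functions of (config, seed): the same seed and
config reproduce byte-identical outputs. Ground truth is always returned
machine-readably next to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotate import Spectrum
from .fragments import predict_fragments
from .library import LipidLibrary, LipidSpecies

__all__ = [
    "SimulationConfig",
    "simulate_spectrum",
    "simulate_spectra",
    "simulate_strain_profile",
    "plant_farm_sequence",
    "DEFAULT_PROFILE_PROPORTIONS",
]

# A Methanosarcinales-like core lipid distribution: AR-dominated with
# hydroxy/macrocyclic archaeol, monoether hydrolysis artifacts and GDGTs.
DEFAULT_PROFILE_PROPORTIONS: dict[str, float] = {
    "AR": 0.45,
    "sn-2-C20-monoether": 0.04,
    "sn-3-C20-monoether": 0.12,
    "OH-AR": 0.15,
    "MAR": 0.06,
    "GDGT-0": 0.17,
    "GDGT-1": 0.01,
}

_GDGT_CLASSES = ("GDGT-0", "GDGT-1")
_AA_NO_D = "ACEFGHIKLMNPQRSTVWY"
_AA_ALL = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for all three generators; defaults are the study conditions.

    ``jitter_ppm`` bounds a uniform m/z perturbation (high-resolution mode);
    trap mode jitters uniformly within ``trap_jitter_da``. ``noise_fraction``
    sets the expected noise-peak count as a fraction of true peaks (Poisson).
    """

    seed: int = 0
    # spectra
    jitter_ppm: float = 5.0
    trap_jitter_da: float = 0.15
    noise_fraction: float = 0.2
    dropout: float = 0.1
    resolution: str = "high"
    intensity_sigma: float = 0.3
    # strain profiles
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROFILE_PROPORTIONS))
    profile_sigma: float = 0.1
    # planted FARM sequences
    triplet: tuple[str, str, str] = ("P", "L", "G")
    upstream_range: tuple[int, int] = (11, 60)
    downstream_range: tuple[int, int] = (30, 200)


def _jitter(rng: np.random.Generator, mz: np.ndarray,
            config: SimulationConfig) -> np.ndarray:
    if config.resolution == "trap":
        return mz + rng.uniform(-config.trap_jitter_da, config.trap_jitter_da,
                                size=mz.shape)
    return mz * (1.0 + rng.uniform(-config.jitter_ppm, config.jitter_ppm,
                                   size=mz.shape) * 1e-6)


def simulate_spectrum(species: LipidSpecies, adduct: str,
                      config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[Spectrum, dict]:
    """Simulate one MS2 spectrum of ``species``; returns (spectrum, truth).

    True fragment intensities are the rule diagnosticity weights scaled by
    lognormal noise; noise peaks are uniform in m/z below the precursor with
    intensities under the 10th percentile of the true peaks.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    preds = predict_fragments(species, adduct, max_ms_level=3)
    if not preds:
        raise ValueError(f"species {species.uid} has no predictable fragments")
    theo_mz = np.array([p.mz for p in preds])
    weights = np.array([p.weight for p in preds])

    keep = rng.random(len(preds)) >= config.dropout
    if not keep.any():
        keep[int(np.argmax(weights))] = True  # a spectrum needs >= 1 peak
    mz = _jitter(rng, theo_mz[keep], config)
    inten = weights[keep] * rng.lognormal(0.0, config.intensity_sigma,
                                          size=int(keep.sum())) * 1e4

    n_noise = int(rng.poisson(config.noise_fraction * len(preds)))
    if n_noise:
        floor = np.percentile(inten, 10)
        noise_mz = rng.uniform(50.0, species.mz(adduct) - 1.0, size=n_noise)
        noise_int = rng.uniform(0.0, floor, size=n_noise)
        mz = np.concatenate([mz, noise_mz])
        inten = np.concatenate([inten, noise_int])

    precursor = float(_jitter(rng, np.array([species.mz(adduct)]), config)[0])
    spec = Spectrum(precursor, np.column_stack([mz, inten]), ms_level=2,
                    resolution=config.resolution,
                    spectrum_id=f"sim:{species.uid}:{adduct}")
    truth = {"species_id": species.uid, "adduct": adduct,
             "theoretical_mz": species.mz(adduct)}
    return spec, truth


def simulate_spectra(library: LipidLibrary, config: SimulationConfig,
                     n: int | None = None, adduct: str = "+H",
                     ) -> list[tuple[Spectrum, dict]]:
    """Simulate spectra for ``n`` species sampled from the library (all if None).

    Empirical-mass species are included (their printed-mass fragment rules
    are predictable); species are sampled without replacement when n is
    smaller than the library.
    """
    rng = np.random.default_rng(config.seed)
    species = list(library)
    if n is not None and n < len(species):
        idx = rng.choice(len(species), size=n, replace=False)
        species = [species[i] for i in sorted(idx)]
    return [simulate_spectrum(sp, adduct, config, rng) for sp in species]


def simulate_strain_profile(config: SimulationConfig, strain: str = "SIM1",
                            rng: np.random.Generator | None = None,
                            ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate paired GC-like and HPLC-like raw area tables for one strain.

    Returns ``(gc_table, hplc_table, truth)`` where truth is the ground-truth
    percent composition. GDGTs appear only in the HPLC table, mono/diethers
    only in the GC table, and AR in both (the merge anchor).
    """
    props = config.proportions
    total = sum(props.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"proportions must sum to 1, got {total}")
    if props.get("AR", 0.0) <= 0:
        raise ValueError("AR proportion must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    def noisy(value: float) -> float:
        return value * rng.lognormal(0.0, config.profile_sigma)

    gc_scale, hplc_scale = 1_000.0, 250.0
    gc_rows, hplc_rows = {}, {}
    for compound, frac in props.items():
        if compound in _GDGT_CLASSES:
            hplc_rows[compound] = noisy(frac * hplc_scale)
        else:
            gc_rows[compound] = noisy(frac * gc_scale)
    hplc_rows["AR"] = noisy(props["AR"] * hplc_scale)

    gc = pd.DataFrame({strain: pd.Series(gc_rows)})
    hplc = pd.DataFrame({strain: pd.Series(hplc_rows)})
    truth = pd.Series(props, name=strain) * 100.0
    return gc, hplc, truth


def plant_farm_sequence(config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[str, dict]:
    """Generate a protein sequence with a planted FARM and known triplet.

    The upstream flank is drawn from the aspartate-free alphabet, so no
    accidental DDxxD/DDxxxxD can precede the planted motif; its length is at
    least 11 regardless of the configured range.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t11, t8, t5 = (t.upper() for t in config.triplet)
    for t in (t11, t8, t5):
        if t not in _AA_ALL:
            raise ValueError(f"invalid amino acid in triplet: {t!r}")
    lo, hi = config.upstream_range
    up_len = max(11, int(rng.integers(lo, hi + 1)))
    upstream = list(rng.choice(list(_AA_NO_D), size=up_len))
    upstream[-11], upstream[-8], upstream[-5] = t11, t8, t5
    motif = "DD" + "".join(rng.choice(list(_AA_NO_D), size=2)) + "D"
    lo, hi = config.downstream_range
    down_len = int(rng.integers(lo, hi + 1))
    downstream = "".join(rng.choice(list(_AA_ALL), size=down_len))
    seq = "".join(upstream) + motif + downstream
    truth = {"motif_start": up_len, "motif": motif,
             "triplet": (t11, t8, t5)}
    return seq, truth


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
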