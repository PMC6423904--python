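"""Spectrum annotation against the combinatorial lipid library.

A spectrum is matched by (1) finding every library species whose [M+H]+,
[M+NH4]+ or [M+Na]+ ion lies within the precursor tolerance and (2) scoring
how many of that candidate's predicted diagnostic fragments appear in the
peak list. The composite score is

    0.4 * precursor closeness  +  0.6 * weighted fraction of fragments matched

where precursor closeness is ``1 - |error| / tolerance`` (floored at 0) and
the fragment fraction is weighted by rule diagnosticity. Identification of
archaeal ether IPLs in practice rests on exactly these two signals —
accurate precursor mass plus class-defining neutral losses — so candidates
with the right mass but the wrong headgroup chemistry rank below ones whose
diagnostic losses are present.

Tolerances default to 10 ppm (precursor) / 15 ppm (fragments) for
high-resolution spectra and 0.5 Da for ion-trap spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragments import DEFAULT_WEIGHTS, predict_fragments
from .library import LipidLibrary, LipidSpecies

__all__ = [
    "Spectrum",
    "Annotation",
    "Tolerances",
    "annotate",
    "detect_homolog_delta",
    "HOMOLOG_DELTAS",
]


@dataclass
class Spectrum:
    """A peak list with precursor information.

    ``resolution`` is "high" (Orbitrap-like, ppm tolerances) or "trap"
    (linear ion trap, 0.5 Da tolerances). Peaks are stored sorted by m/z.
    """

    precursor_mz: float
    peaks: np.ndarray          # shape (n, 2): m/z, intensity
    ms_level: int = 2
    resolution: str = "high"
    spectrum_id: str = ""
    precursor_lineage: tuple[float, ...] = ()

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if peaks.size and (peaks[:, 1] < 0).any():
            raise ValueError("negative peak intensity")
        self.peaks = peaks[np.argsort(peaks[:, 0])] if peaks.size else peaks

    @property
    def mzs(self) -> np.ndarray:
        return self.peaks[:, 0] if self.peaks.size else np.empty(0)


@dataclass
class Tolerances:
    precursor_ppm: float = 10.0
    fragment_ppm: float = 15.0
    trap_da: float = 0.5


@dataclass
class Annotation:
    species_id: str
    adduct: str
    precursor_error: float       # ppm (high) or Da (trap)
    matched_fragments: dict[str, float] = field(default_factory=dict)
    score: float = 0.0
    rank: int = 0
    species: LipidSpecies | None = None


def _match_fragment(mzs: np.ndarray, target: float, tol_da: float) -> float | None:
    """Nearest observed peak within tolerance, or None."""
    if mzs.size == 0:
        return None
    i = int(np.searchsorted(mzs, target))
    best, best_d = None, tol_da
    for j in (i - 1, i):
        if 0 <= j < mzs.size:
            d = abs(mzs[j] - target)
            if d <= best_d:
                best, best_d = float(mzs[j]), d
    return best


def annotate(spectrum: Spectrum, library: LipidLibrary,
             tolerances: Tolerances | None = None,
             max_candidates: int | None = None) -> list[Annotation]:
    """Rank library species against ``spectrum``.

    All three adduct hypotheses are evaluated. Ties are broken by fewer
    structural modifications, then by species id, making the ranking
    deterministic and independent of peak input order.
    """
    tol = tolerances or Tolerances()
    trap = spectrum.resolution == "trap"
    if trap:
        cands = library.query_precursor(spectrum.precursor_mz, tol_da=tol.trap_da)
        prec_tol = tol.trap_da
    else:
        cands = library.query_precursor(spectrum.precursor_mz,
                                        tol_ppm=tol.precursor_ppm)
        prec_tol = tol.precursor_ppm

    mzs = spectrum.mzs
    annotations: list[Annotation] = []
    for species, adduct, err in cands:
        preds = predict_fragments(species, adduct, max_ms_level=3)
        matched: dict[str, float] = {}
        wsum = sum(p.weight for p in preds)
        wmatch = 0.0
        for p in preds:
            ftol = tol.trap_da if trap else p.mz * tol.fragment_ppm * 1e-6
            obs = _match_fragment(mzs, p.mz, ftol)
            if obs is not None:
                matched[p.label] = obs
                wmatch += p.weight
        frag_score = (wmatch / wsum) if wsum > 0 else 0.0
        prec_score = max(0.0, 1.0 - abs(err) / prec_tol)
        score = 0.4 * prec_score + 0.6 * frag_score
        annotations.append(Annotation(species.uid, adduct, err, matched,
                                      score, species=species))
    annotations.sort(key=lambda a: (-a.score,
                                    a.species.n_modifications if a.species else 0,
                                    a.species_id))
    # competition ranking: exact score ties share a rank. Constitutional
    # isomers with one elemental composition (e.g. a trimethyl-APT vs a
    # dimethyl-APT-Me species) produce identical precursor and fragment
    # masses and cannot be separated by MS; both are reported rank 1.
    for i, a in enumerate(annotations):
        if i and a.score == annotations[i - 1].score:
            a.rank = annotations[i - 1].rank
        else:
            a.rank = i + 1
    if max_candidates is not None:
        annotations = annotations[:max_candidates]
    return annotations


# Exact masses of the homolog/series mass differences the strain data show:
# CH2 (methylation homologs), SO3 (sulfation), C5H10 (C20 -> C25 chain
# extension), H2 (one unsaturation), O (hydroxylation).
HOMOLOG_DELTAS: dict[str, float] = {
    "CH2": 14.0156500641,
    "SO3": 79.9568148588,
    "C5H10": 70.0782503207,
    "H2": 2.0156500641,
    "O": 15.9949146196,
}


def detect_homolog_delta(precursor_a: float, precursor_b: float,
                         tolerance_da: float) -> str:
    """Name the homolog mass difference between two precursors, or "none".

    The label whose exact mass lies closest to ``|a - b|`` within the
    tolerance wins; a zero (or unmatched) difference yields "none".
    """
    if precursor_a <= 0 or precursor_b <= 0:
        raise ValueError("precursor m/z must be positive")
    delta = abs(precursor_a - precursor_b)
    best, best_d = "none", tolerance_da
    for label, mass in HOMOLOG_DELTAS.items():
        d = abs(delta - mass)
        if d <= best_d:
            best, best_d = label, d
    return best
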