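"""Format readers and writers: MGF, spectrum/annotation TSV, FASTA.

MGF parsing and writing go through pyteomics; the TSV spectrum dialect is a
flat long table (spectrum_id, precursor_mz, ms_level, resolution, mz,
intensity) convenient for spreadsheets and ad-hoc tooling. Charge is assumed
1+ when an MGF omits it (all species handled here are singly charged in
positive mode).
"""

from __future__ import annotations

import numpy as np
from pyteomics import mgf as _mgf

from .annotate import Annotation, Spectrum

__all__ = [
    "read_mgf",
    "write_mgf",
    "read_spectra_tsv",
    "write_spectra_tsv",
    "write_annotations_tsv",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_fasta",
]


def read_mgf(path, resolution: str = "high") -> list[Spectrum]:
    spectra = []
    with _mgf.read(str(path), use_index=False) as reader:
        for entry in reader:
            params = entry.get("params", {})
            pepmass = params.get("pepmass", (0.0,))
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list))
                              else pepmass)
            peaks = np.column_stack([entry["m/z array"],
                                     entry["intensity array"]]) \
                if len(entry["m/z array"]) else np.empty((0, 2))
            spectra.append(Spectrum(
                precursor_mz=precursor,
                peaks=peaks,
                ms_level=int(params.get("mslevel", 2)),
                resolution=resolution,
                spectrum_id=str(params.get("title", f"spectrum{len(spectra)}")),
            ))
    return spectra


def write_mgf(spectra: list[Spectrum], path) -> None:
    entries = []
    for s in spectra:
        entries.append({
            "m/z array": s.peaks[:, 0] if s.peaks.size else np.empty(0),
            "intensity array": s.peaks[:, 1] if s.peaks.size else np.empty(0),
            "params": {"title": s.spectrum_id, "pepmass": s.precursor_mz,
                       "charge": "1+", "mslevel": s.ms_level},
        })
    _mgf.write(entries, str(path), file_mode="w")


_SPEC_COLS = ["spectrum_id", "precursor_mz", "ms_level", "resolution",
              "mz", "intensity"]


def write_spectra_tsv(spectra: list[Spectrum], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SPEC_COLS) + "\n")
        for s in spectra:
            for mz, inten in s.peaks:
                fh.write(f"{s.spectrum_id}\t{s.precursor_mz:.6f}\t{s.ms_level}"
                         f"\t{s.resolution}\t{mz:.6f}\t{inten:.4f}\n")


def read_spectra_tsv(path) -> list[Spectrum]:
    groups: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SPEC_COLS:
            raise ValueError(f"malformed spectra TSV {path}: line 1: "
                             f"expected header {_SPEC_COLS}")
        for lineno, line in enumerate(fh, start=2):
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            try:
                g = groups.setdefault(vals["spectrum_id"], {
                    "precursor": float(vals["precursor_mz"]),
                    "ms_level": int(vals["ms_level"]),
                    "resolution": vals["resolution"], "peaks": []})
                g["peaks"].append((float(vals["mz"]), float(vals["intensity"])))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"malformed spectra TSV {path}: line {lineno}: {exc}")
    return [Spectrum(g["precursor"], np.array(g["peaks"]), g["ms_level"],
                     g["resolution"], sid) for sid, g in groups.items()]


_ANN_COLS = ["spectrum_id", "precursor_mz", "rank", "species_id", "adduct",
             "precursor_error", "score", "n_matched", "matched_fragments"]


def write_annotations_tsv(results: list[tuple[Spectrum, list[Annotation]]],
                          path, truth: dict[str, str] | None = None) -> None:
    """Write ranked annotations; with ``truth`` (spectrum_id -> species_id)
    an extra comparison column marks rank-1 hits."""
    cols = list(_ANN_COLS) + (["truth_species_id", "rank1_correct"]
                              if truth is not None else [])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for spec, anns in results:
            for a in anns:
                row = [spec.spectrum_id, f"{spec.precursor_mz:.6f}",
                       str(a.rank), a.species_id, a.adduct,
                       f"{a.precursor_error:.4f}", f"{a.score:.4f}",
                       str(len(a.matched_fragments)),
                       ";".join(sorted(a.matched_fragments))]
                if truth is not None:
                    t = truth.get(spec.spectrum_id, "")
                    row += [t, str(int(a.rank == 1 and a.species_id == t))]
                fh.write("\t".join(row) + "\n")


def write_truth_tsv(truths: list[dict], path) -> None:
    """Ground-truth sidecar for simulated data (one row per item)."""
    if not truths:
        with open(path, "w") as fh:
            fh.write("")
        return
    cols = list(truths[0])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truths:
            fh.write("\t".join(str(t[c]) for c in cols) + "\n")


def read_truth_tsv(path) -> list[dict]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
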