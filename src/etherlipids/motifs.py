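"""FARM-motif scanning and isoprenoid chain-length classification.

Polyprenyl synthases (prenyltransferases) elongate isoprenoid chains; the
residues 5, 8 and 11 positions upstream of the First Aspartate-Rich Motif
(FARM) govern the chain length of the product. A bulky residue at the fifth
position blocks elongation at C20; small residues there permit C25 and
beyond. When the fifth position is bulky, a small residue at the eighth
position can still open the pocket to C25 (the Aeropyrum pernix case).

Position convention: the residue immediately preceding the first aspartate
of the motif is position -1, so "the fifth amino acid before the FARM" is
``sequence[motif_start - 5]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "FarmMotif",
    "find_farm",
    "classify_chain_length",
    "scan_sequences",
    "scan_fasta",
    "NoMotifError",
    "UpstreamTooShortError",
]

# FARM variants: DDxxD and DDxxxxD; the more common short form is preferred
# when both match at the same position.
_FARM_PATTERNS = (re.compile(r"DD.{2}D"), re.compile(r"DD.{4}D"))

SMALL_RESIDUES = frozenset("GASC")   # permit elongation past C20
BULKY_RESIDUES = frozenset("FYW")    # block elongation at C20
_SMALL_AT_8 = frozenset("AGS")       # open the pocket to C25 despite bulky -5

_AA = set("ACDEFGHIKLMNPQRSTVWY")


class NoMotifError(ValueError):
    """The sequence contains no DDxxD / DDxxxxD motif."""


class UpstreamTooShortError(ValueError):
    """A motif was found but fewer than 11 residues precede it."""


@dataclass(frozen=True)
class FarmMotif:
    start: int              # 0-based index of the first aspartate
    motif: str
    triplet: tuple[str, str, str]  # residues at (-11, -8, -5)

    @property
    def residue_minus_11(self) -> str:
        return self.triplet[0]

    @property
    def residue_minus_8(self) -> str:
        return self.triplet[1]

    @property
    def residue_minus_5(self) -> str:
        return self.triplet[2]


def find_farm(sequence: str) -> FarmMotif:
    """Locate the most N-terminal FARM and extract the (-11, -8, -5) triplet.

    Raises :class:`NoMotifError` if no motif exists, and
    :class:`UpstreamTooShortError` if the first motif has fewer than 11
    upstream residues.
    """
    seq = sequence.strip().upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"non-standard amino acid codes: {sorted(bad)}")
    matches = [m for p in _FARM_PATTERNS if (m := p.search(seq))]
    if not matches:
        raise NoMotifError("no DDxxD or DDxxxxD motif found")
    # earliest start wins; at a tie the shorter (DDxxD) form
    m = min(matches, key=lambda m: (m.start(), m.end()))
    start = m.start()
    if start < 11:
        raise UpstreamTooShortError(
            f"motif at position {start} has fewer than 11 upstream residues")
    triplet = (seq[start - 11], seq[start - 8], seq[start - 5])
    return FarmMotif(start, m.group(0), triplet)


def classify_chain_length(motif: FarmMotif) -> str:
    """Classify isoprenoid chain-length potential from the FARM triplet.

    * small residue at -5 -> "long-chain" (elongation to C25 and beyond)
    * bulky residue at -5, small residue at -8 -> "C25-capable-short"
    * bulky residue at -5 otherwise -> "short-chain-C20"
    * anything else -> "indeterminate"
    """
    r5, r8 = motif.residue_minus_5, motif.residue_minus_8
    if r5 in SMALL_RESIDUES:
        return "long-chain"
    if r5 in BULKY_RESIDUES:
        if r8 in _SMALL_AT_8:
            return "C25-capable-short"
        return "short-chain-C20"
    return "indeterminate"


def scan_sequences(records: Iterable[tuple[str, str]]) -> Iterator[dict]:
    """Scan (id, sequence) pairs; one report row per record.

    Rows carry either the motif fields and classification or an ``error``
    string; records are processed independently.
    """
    for seq_id, seq in records:
        row = {"id": seq_id, "motif_start": "", "motif": "",
               "triplet": "", "classification": "", "error": ""}
        try:
            m = find_farm(str(seq))
            row.update(motif_start=m.start, motif=m.motif,
                       triplet="/".join(m.triplet),
                       classification=classify_chain_length(m))
        except (NoMotifError, UpstreamTooShortError, ValueError) as exc:
            row["error"] = str(exc)
        yield row


def scan_fasta(path) -> list[dict]:
    """Scan every record of a protein FASTA file."""
    return list(scan_sequences((rec.id, str(rec.seq))
                               for rec in SeqIO.parse(str(path), "fasta")))


def write_farm_report(rows: list[dict], path) -> None:
    cols = ["id", "motif_start", "motif", "triplet", "classification", "error"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
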