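"""Sequence input/output and alphabet normalization.

Every downstream stage consumes :class:`GenomeRecord` objects whose sequence
is stored in a single canonical alphabet (DNA letters, uppercase).  RNA input
(``U``) is converted on read; motif and structure reports re-render ``U`` at
the display layer so shift sites read like the RNA notation used in the
frameshifting literature (e.g. ``G_GAU_UUU``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "GenomeRecord",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "reverse_complement",
    "to_rna",
    "to_dna",
]

_VALID = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: IUPAC ambiguity codes (anything nucleotide-ish that is not ACGTU).
AMBIGUITY_CODES = set("RYSWKMBDHVN")


@dataclass
class GenomeRecord:
    """A named nucleotide sequence.

    ``seq`` is always uppercase DNA letters after construction; ``alphabet``
    records what was on disk (``"DNA"`` or ``"RNA"``) so writers can restore
    the original rendering if asked.
    """

    id: str
    seq: str
    description: str = ""
    alphabet: str = "DNA"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if "U" in self.seq:
            self.alphabet = "RNA"
            self.seq = self.seq.replace("U", "T")
        _validate(self.seq, self.id)

    def __len__(self) -> int:
        return len(self.seq)


def _validate(seq: str, rec_id: str, allow_n: bool = False) -> None:
    if not seq:
        raise ValueError(f"record {rec_id!r}: empty sequence")
    allowed = _VALID | ({"N"} if allow_n else set())
    for i, ch in enumerate(seq):
        if ch not in allowed:
            kind = "ambiguity code" if ch in AMBIGUITY_CODES else "non-nucleotide character"
            raise ValueError(
                f"record {rec_id!r}: {kind} {ch!r} at position {i + 1}"
            )


def _normalize(raw: str, rec_id: str, mask_ambiguity: bool) -> str:
    seq = raw.upper().replace("U", "T")
    if mask_ambiguity:
        seq = "".join("N" if ch in AMBIGUITY_CODES else ch for ch in seq)
        _validate(seq, rec_id, allow_n=True)
    else:
        _validate(seq, rec_id)
    return seq


def read_fasta(path: str | Path, mask_ambiguity: bool = False) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into normalized records, order preserved.

    Parameters
    ----------
    path:
        FASTA file path.
    mask_ambiguity:
        If true, IUPAC ambiguity codes are masked to ``N`` instead of being
        rejected.  Scans never match ``N``.
    """
    records = []
    for sr in SeqIO.parse(str(path), "fasta"):
        raw = str(sr.seq)
        alphabet = "RNA" if "U" in raw.upper() else "DNA"
        seq = _normalize(raw, sr.id, mask_ambiguity)
        rec = GenomeRecord.__new__(GenomeRecord)
        rec.id = sr.id
        rec.description = sr.description
        rec.seq = seq
        rec.alphabet = alphabet
        records.append(rec)
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_genbank(path: str | Path) -> GenomeRecord:
    """Read a single GenBank flat file; the record id is the ACCESSION field."""
    with open(path) as fh:
        text = fh.read()
    if "ORIGIN" not in text:
        raise ValueError(f"{path}: GenBank record has no ORIGIN block")
    sr = SeqIO.read(io.StringIO(text), "genbank")
    seq = _normalize(str(sr.seq), sr.id, mask_ambiguity=False)
    rec = GenomeRecord.__new__(GenomeRecord)
    rec.id = sr.id
    rec.description = sr.description
    rec.seq = seq
    rec.alphabet = "DNA"
    return rec


def reverse_complement(seq: str) -> str:
    """Standard reverse complement (DNA letters).  Involution on valid input."""
    s = seq.upper().replace("U", "T")
    _validate(s, "<seq>")
    return s.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """Render a canonical DNA-letter sequence with RNA letters (T -> U)."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")
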