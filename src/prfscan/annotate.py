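"""Polyprotein ORF and UTR annotation.

A flavivirus genome is a positive-sense RNA of ~10-11 kb carrying a single
long open reading frame flanked by untranslated regions.  Annotation here
means locating the longest AUG-initiated, stop-terminated ORF over the three
forward frames, delineating the 5' and 3' UTRs as the flanking remainders,
and translating the polyprotein with the standard genetic code.

Conventions (pinned once to avoid off-by-one drift):

* coordinates are 0-based, half-open internally; 1-based inclusive in GFF3;
* the ORF length counts start codon through stop codon inclusive, so
  ``utr5_len + orf_len + utr3_len == genome_len`` and the polyprotein has
  ``orf_len / 3 - 1`` residues;
* forward strand only by default (positive-sense genome).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import Seq

from .seq_io import GenomeRecord

__all__ = ["GenomeAnnotation", "NoOrfError", "translate", "find_longest_orf", "write_gff3"]

STOP_CODONS = {"TAA", "TAG", "TGA"}


class NoOrfError(ValueError):
    """Raised when a genome contains no AUG-initiated ORF with an in-frame stop."""


@dataclass
class GenomeAnnotation:
    genome_id: str
    genome_len: int
    orf_start: int  # 0-based, inclusive (the A of AUG)
    orf_end: int  # 0-based, exclusive (just past the stop codon)
    polyprotein: str  # amino acids, stop not included

    @property
    def utr5_len(self) -> int:
        return self.orf_start

    @property
    def orf_len(self) -> int:
        return self.orf_end - self.orf_start

    @property
    def utr3_len(self) -> int:
        return self.genome_len - self.orf_end

    @property
    def orf_codons(self) -> int:
        """Sense codons in the ORF (stop codon excluded)."""
        return self.orf_len // 3 - 1


def translate(seq: str, frame: int = 0) -> str:
    """Standard-code translation of complete codons from ``frame`` (0/1/2).

    Stops render as ``*``; a trailing partial codon is dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def find_longest_orf(rec: GenomeRecord) -> GenomeAnnotation:
    """Annotate the longest AUG..stop ORF over the three forward frames.

    Within a frame, each stop closes the span opened by the first upstream
    AUG; ties on length break toward the smaller start coordinate.
    """
    seq = rec.seq
    n = len(seq)
    best: tuple[int, int] | None = None  # (start, end) half-open incl. stop
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    cand = (start, i + 3)
                    if best is None or (cand[1] - cand[0], -cand[0]) > (
                        best[1] - best[0],
                        -best[0],
                    ):
                        best = cand
                    start = None
            elif codon == "ATG" and start is None:
                start = i
    if best is None:
        raise NoOrfError(f"genome {rec.id!r}: no AUG-initiated ORF with an in-frame stop")
    orf_start, orf_end = best
    protein = translate(seq[orf_start:orf_end])
    assert protein.endswith("*") and "*" not in protein[:-1]
    return GenomeAnnotation(
        genome_id=rec.id,
        genome_len=n,
        orf_start=orf_start,
        orf_end=orf_end,
        polyprotein=protein[:-1],
    )


def write_gff3(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write the annotation as GFF3 (1-based inclusive, strand ``+``)."""
    lines = ["##gff-version 3"]
    gid = ann.genome_id
    src = "prfscan"

    def row(ftype: str, start0: int, end0_excl: int) -> str:
        return f"{gid}\t{src}\t{ftype}\t{start0 + 1}\t{end0_excl}\t.\t+\t.\tID={ftype}_{gid}"

    if ann.utr5_len:
        lines.append(row("five_prime_UTR", 0, ann.orf_start))
    lines.append(row("CDS", ann.orf_start, ann.orf_end))
    if ann.utr3_len:
        lines.append(row("three_prime_UTR", ann.orf_end, ann.genome_len))
    Path(path).write_text("\n".join(lines) + "\n")
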