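"""-1 programmed ribosomal frameshift (-1 PRF) candidate site discovery.

A -1 PRF site is a slippery heptanucleotide ``X_XXY_YYZ`` followed, after a
5-9 nt spacer, by a stimulatory RNA structure.  The underscores mark codon
boundaries of the zero-frame ORF: the heptamer starts at the third position
of a codon, so its 2nd-7th nucleotides form two complete polyprotein codons
(``XXY`` and ``YYZ``).  The consensus requires three identical nucleotides
for ``XXX`` (with a small set of known exceptions such as ``GGA``),
``YYY`` in {AAA, UUU} and ``Z`` in {A, C, U}.

The -1 frame ORF length is counted from the first complete -1 frame codon
after the shift site — the codon whose first nucleotide is the heptamer's
last (``Z``), i.e. the first codon newly decoded after tandem-slippage
re-pairing — up to but excluding the first -1 frame stop.  The counting
origin is recorded in candidate metadata because conventions differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import GenomeAnnotation, STOP_CODONS
from .fold import FoldConfig, Hairpin, best_hairpin
from .seq_io import GenomeRecord, to_dna, to_rna

__all__ = [
    "PRFConfig",
    "SlipperySite",
    "PRFCandidate",
    "is_slippery",
    "scan_slippery",
    "minus1_orf_length",
    "build_candidates",
    "scan_genome",
]

#: The only exception the frameshifting consensus literature names outright
#: is GGA; GGU behaves analogously and is included by default.  The list is
#: configurable and never silently extended.
DEFAULT_XXX_EXCEPTIONS = frozenset({"GGA", "GGT"})

MINUS1_ORIGIN = "first -1 frame codon starting at the heptamer's last nt"


@dataclass
class PRFConfig:
    xxx_exceptions: frozenset = DEFAULT_XXX_EXCEPTIONS
    spacer_min: int = 5
    spacer_max: int = 9
    frame_filter: bool = True  # keep only codon-anchored (in-frame) heptamers
    fold: FoldConfig = field(default_factory=FoldConfig)


@dataclass
class SlipperySite:
    pos: int  # 0-based genome index of the heptamer start
    heptamer: str  # DNA letters internally
    xxx: str
    yyy: str
    z: str
    in_frame: bool = False
    via_exception: bool = False

    @property
    def display(self) -> str:
        """RNA rendering with codon-boundary underscores, e.g. G_GAU_UUU."""
        h = to_rna(self.heptamer)
        return f"{h[0]}_{h[1:4]}_{h[4:]}"


@dataclass
class PRFCandidate:
    site: SlipperySite
    spacer_len: int
    hairpin: Hairpin
    minus1_orf_codons: int
    minus1_truncated: bool = False
    minus1_origin: str = MINUS1_ORIGIN
    region_label: str | None = None


def is_slippery(heptamer: str, exceptions: frozenset | set = DEFAULT_XXX_EXCEPTIONS) -> SlipperySite | None:
    """Parse a 7-nt string against the slippery-site consensus.

    Accepts iff XXX is three identical nucleotides (or on the exception
    list), YYY is AAA or UUU, and Z is A, C or U.  Returns the parsed site
    or None on rejection.
    """
    h = to_dna(heptamer)
    if len(h) != 7:
        raise ValueError(f"heptamer must be exactly 7 nt, got {len(h)}")
    xxx, yyy, z = h[:3], h[3:6], h[6]
    identical = xxx[0] == xxx[1] == xxx[2]
    via_exception = not identical and to_dna(xxx) in {to_dna(e) for e in exceptions}
    if not (identical or via_exception):
        return None
    if yyy not in ("AAA", "TTT"):
        return None
    if z not in ("A", "C", "T"):
        return None
    return SlipperySite(pos=-1, heptamer=h, xxx=xxx, yyy=yyy, z=z, via_exception=via_exception)


def scan_slippery(
    rec: GenomeRecord, ann: GenomeAnnotation, config: PRFConfig | None = None
) -> list[SlipperySite]:
    """All consensus heptamers inside the ORF, frame-filtered by default.

    A site is in frame when the heptamer start sits at the third position of
    a polyprotein codon, so that ``X_XXY_YYZ`` underscores align with codon
    boundaries.
    """
    config = config or PRFConfig()
    sites: list[SlipperySite] = []
    seq = rec.seq
    # heptamer must lie fully inside the ORF
    for pos in range(ann.orf_start, ann.orf_end - 6):
        site = is_slippery(seq[pos : pos + 7], config.xxx_exceptions)
        if site is None:
            continue
        site.pos = pos
        site.in_frame = (pos - ann.orf_start) % 3 == 2
        if config.frame_filter and not site.in_frame:
            continue
        sites.append(site)
    return sites


def minus1_orf_length(rec: GenomeRecord, site: SlipperySite) -> tuple[int, bool]:
    """Sense-codon count of the -1 frame ORF downstream of a shift site.

    Counting starts at the codon whose first nucleotide is the heptamer's
    last nt (position ``pos + 6``, which lies in the -1 frame for a
    codon-anchored site) and stops before the first -1 frame stop codon.
    Returns ``(codons, truncated)`` where ``truncated`` is True when the
    genome ends before any stop is reached.
    """
    seq = rec.seq
    start = site.pos + 6
    count = 0
    i = start
    while i + 3 <= len(seq):
        if seq[i : i + 3] in STOP_CODONS:
            return count, False
        count += 1
        i += 3
    return count, True


def build_candidates(
    rec: GenomeRecord,
    ann: GenomeAnnotation,
    sites: list[SlipperySite],
    config: PRFConfig | None = None,
) -> list[PRFCandidate]:
    """Join scanned sites to their best downstream hairpin; filter on spacer.

    The fold window starts immediately after the heptamer; the spacer is the
    run of unpaired nucleotides between the heptamer end and the first
    paired base of the predicted hairpin.  Candidates whose spacer falls
    outside ``[spacer_min, spacer_max]`` (default 5-9 nt) are rejected, as
    are sites with no hairpin above the score threshold.
    """
    config = config or PRFConfig()
    out: list[PRFCandidate] = []
    for site in sorted(sites, key=lambda s: s.pos):
        wstart = site.pos + 7
        window = rec.seq[wstart : wstart + config.fold.window]
        if len(window) < 7:
            continue
        hp = best_hairpin(window, config.fold, region_start=wstart)
        if hp is None:
            continue
        spacer = hp.first_paired_index
        if not (config.spacer_min <= spacer <= config.spacer_max):
            continue
        codons, truncated = minus1_orf_length(rec, site)
        out.append(
            PRFCandidate(
                site=site,
                spacer_len=spacer,
                hairpin=hp,
                minus1_orf_codons=codons,
                minus1_truncated=truncated,
            )
        )
    return out


def scan_genome(
    rec: GenomeRecord, ann: GenomeAnnotation, config: PRFConfig | None = None
) -> list[PRFCandidate]:
    """Convenience: scan_slippery followed by build_candidates."""
    config = config or PRFConfig()
    return build_candidates(rec, ann, scan_slippery(rec, ann, config), config)
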