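"""Cross-species comparison of -1 PRF candidate sites.

Conservation of a shift site between related viruses — same genomic
neighbourhood, same or compatible heptamer, and compensatory substitutions
that preserve the predicted base-pairing — is the main desk evidence that a
predicted site is real rather than spurious.

The comparison anchors the two site regions at their heptamers (aligned
column-for-column), globally aligns the downstream spacer+hairpin stretch,
and classifies every stem pair of species A against the homologous
nucleotides of species B:

``identical``        both positions unchanged;
``compensatory``     both positions changed and B still forms a legal pair;
``half-substitution``one position changed, pairing retained;
``pairing-lost``     B's nucleotides no longer form a legal pair (or a gap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .annotate import GenomeAnnotation
from .fold import LEGAL_PAIRS, WC_PAIRS
from .prf import PRFCandidate
from .seq_io import GenomeRecord, to_rna

__all__ = ["ConserveConfig", "CompensatoryPair", "SiteAlignment", "align_sites", "classify_pairs", "compare_sites", "report_text"]


@dataclass
class ConserveConfig:
    #: accept wobble G:U as "pairing preserved" in species B (strict_wc=False)
    strict_wc: bool = False
    #: heptamer ORF codon offsets within this many codons count as the same location
    location_tolerance_codons: int = 50
    #: nucleotide alignment scores; gaps are expensive so that clustered
    #: substitutions in repeat-rich stems never outscore the gapless
    #: colinear alignment — gaps appear only for genuine indels
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = 10.0
    gap_extend: float = 2.0


@dataclass
class CompensatoryPair:
    pair_index: int
    a_nts: tuple  # (5', 3') nucleotides in species A
    b_nts: tuple  # homologous nucleotides in species B ('-' for gap)
    kind: str  # identical | compensatory | half-substitution | pairing-lost
    gap: bool = False


@dataclass
class SiteAlignment:
    a_id: str
    b_id: str
    a_aln: str  # gapped region sequences, heptamer columns first
    b_aln: str
    a_region_start: int  # genome coordinate of region start (= heptamer start)
    b_region_start: int
    location_conserved: bool
    length_warning: bool = False


def _region_extent(cand: PRFCandidate) -> int:
    """Length of heptamer + spacer + hairpin, from the heptamer start."""
    hp = cand.hairpin
    return hp.region_start + max(j for _, j in hp.pairs) + 1 - cand.site.pos


def align_sites(
    a: tuple[GenomeRecord, GenomeAnnotation, PRFCandidate],
    b: tuple[GenomeRecord, GenomeAnnotation, PRFCandidate],
    config: ConserveConfig | None = None,
) -> SiteAlignment:
    """Anchored alignment of two candidate site regions.

    The heptamers align column-wise by construction; the remainder of each
    region is aligned with a global nucleotide Needleman-Wunsch.  The
    ``location_conserved`` flag reports whether the heptamers sit at similar
    ORF codon offsets in the two genomes.
    """
    config = config or ConserveConfig()
    rec_a, ann_a, cand_a = a
    rec_b, ann_b, cand_b = b
    ext_a, ext_b = _region_extent(cand_a), _region_extent(cand_b)
    warn = max(ext_a, ext_b) > 3 * min(ext_a, ext_b)
    # both regions are cut at the common extent so that substitution-only
    # divergence aligns gaplessly; indels are still handled by the aligner
    ext = max(ext_a, ext_b)
    start_a, start_b = cand_a.site.pos, cand_b.site.pos
    reg_a = rec_a.seq[start_a : start_a + ext]
    reg_b = rec_b.seq[start_b : start_b + ext]

    tail_a, tail_b = reg_a[7:], reg_b[7:]
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = config.match
    aligner.mismatch_score = config.mismatch
    aligner.open_gap_score = -config.gap_open
    aligner.extend_gap_score = -config.gap_extend
    aln = aligner.align(tail_a, tail_b)[0]
    a_aln = reg_a[:7] + str(aln[0])
    b_aln = reg_b[:7] + str(aln[1])

    codon_a = (cand_a.site.pos - ann_a.orf_start) // 3
    codon_b = (cand_b.site.pos - ann_b.orf_start) // 3
    loc = abs(codon_a - codon_b) <= config.location_tolerance_codons
    return SiteAlignment(
        a_id=rec_a.id,
        b_id=rec_b.id,
        a_aln=a_aln,
        b_aln=b_aln,
        a_region_start=start_a,
        b_region_start=start_b,
        location_conserved=loc,
        length_warning=warn,
    )


def classify_pairs(
    cand_a: PRFCandidate,
    site_aln: SiteAlignment,
    config: ConserveConfig | None = None,
) -> list[CompensatoryPair]:
    """Classify every stem pair of species A against species B's homologs."""
    config = config or ConserveConfig()
    legal = WC_PAIRS if config.strict_wc else LEGAL_PAIRS

    # map region-local index in A -> homologous B nucleotide (or '-')
    b_at: dict[int, str] = {}
    ai = 0
    for ca, cb in zip(site_aln.a_aln, site_aln.b_aln):
        if ca != "-":
            b_at[ai] = cb
            ai += 1

    hp = cand_a.hairpin
    offset = hp.region_start - site_aln.a_region_start  # window -> region coords
    out: list[CompensatoryPair] = []
    for k, (i, j) in enumerate(hp.pairs):
        a5, a3 = hp.window[i], hp.window[j]
        b5 = b_at.get(offset + i, "-")
        b3 = b_at.get(offset + j, "-")
        if b5 == "-" or b3 == "-":
            kind, gap = "pairing-lost", True
        elif (b5, b3) not in legal:
            kind, gap = "pairing-lost", False
        elif a5 != b5 and a3 != b3:
            kind, gap = "compensatory", False
        elif a5 != b5 or a3 != b3:
            kind, gap = "half-substitution", False
        else:
            kind, gap = "identical", False
        out.append(CompensatoryPair(pair_index=k, a_nts=(a5, a3), b_nts=(b5, b3), kind=kind, gap=gap))
    return out


def compare_sites(a, b, config: ConserveConfig | None = None):
    """align_sites + classify_pairs in one call: (SiteAlignment, pair classes)."""
    config = config or ConserveConfig()
    site_aln = align_sites(a, b, config)
    classes = classify_pairs(a[2], site_aln, config)
    return site_aln, classes


def report_text(site_aln: SiteAlignment, classes: list[CompensatoryPair], cand_a: PRFCandidate) -> str:
    """Plain-text two-genome site report: aligned regions, structure line,
    per-pair substitution annotations."""
    hp = cand_a.hairpin
    offset = hp.region_start - site_aln.a_region_start
    struct = ["."] * len(site_aln.a_aln.replace("-", ""))
    for i, j in hp.pairs:
        struct[offset + i], struct[offset + j] = "(", ")"
    # re-gap the structure line to match the alignment
    gapped = []
    ai = 0
    for ca in site_aln.a_aln:
        if ca == "-":
            gapped.append("-")
        else:
            gapped.append(struct[ai])
            ai += 1
    lines = [
        f"# site comparison {site_aln.a_id} vs {site_aln.b_id}",
        f"# heptamer {to_rna(site_aln.a_aln[:7])} vs {to_rna(site_aln.b_aln[:7])}"
        f"  location_conserved={site_aln.location_conserved}",
        f"{site_aln.a_id:<12} {to_rna(site_aln.a_aln)}",
        f"{'structure':<12} {''.join(gapped)}",
        f"{site_aln.b_id:<12} {to_rna(site_aln.b_aln)}",
        "",
        "pair_index\ta_5p\ta_3p\tb_5p\tb_3p\tkind",
    ]
    for c in classes:
        lines.append(
            f"{c.pair_index}\t{to_rna(c.a_nts[0])}\t{to_rna(c.a_nts[1])}"
            f"\t{to_rna(c.b_nts[0]) if c.b_nts[0] != '-' else '-'}"
            f"\t{to_rna(c.b_nts[1]) if c.b_nts[1] != '-' else '-'}\t{c.kind}"
        )
    return "\n".join(lines) + "\n"
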