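"""Synthetic flavivirus-like genomes with planted, fully known ground truth.

Every pipeline stage can be tested offline against genomes whose 5'UTR/ORF/
3'UTR lengths, slippery heptamer, spacer, stem-loop and -1 frame stop are
planted by construction.  The generator emulates the genome architecture
the analysis assumes — one long AUG..stop ORF (thousands of codons, no
internal stop), flanking UTRs, a codon-anchored shift site, a 5-9 nt spacer
and a stable downstream hairpin — not realistic flavivirus base composition
or evolution.

To keep ground truth unique the generator re-scans its own emission and
(a) re-draws the 5'UTR if a spurious upstream start would lengthen the ORF,
(b) patches any chance in-frame compliant heptamer outside the planted
region (one nucleotide of its YYY is flipped, preserving the zero-frame
amino acid reading as a sense codon), and (c) verifies that annotation,
the slippery scan, the fold and the -1 ORF count all recover exactly the
planted values, re-drawing within a bounded retry budget otherwise.

A sister species can be derived with exactly ``n_compensatory`` paired
substitutions that preserve base-pairing (pair orientation flips, which
also preserve the pairing score), ``n_half`` single-side substitutions that
destroy pairing, and ``n_neutral_mut`` substitutions away from the site
region; every edit is recorded in a substitution ledger.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .annotate import STOP_CODONS, find_longest_orf
from .fold import FoldConfig, best_hairpin
from .prf import PRFConfig, is_slippery, minus1_orf_length, scan_genome, scan_slippery
from .seq_io import GenomeRecord

__all__ = [
    "PlantSiteSpec",
    "SisterSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_genome",
    "generate_sister",
    "generate_family",
    "InfeasibleSpecError",
]

NTS = "ACGT"
PAIR_LETTERS = {
    "GC": [("G", "C"), ("C", "G")],
    "AU": [("A", "T"), ("T", "A")],
    "GU": [("G", "T"), ("T", "G")],
}


class InfeasibleSpecError(ValueError):
    """The requested planted layout cannot be realized."""


@dataclass
class PlantSiteSpec:
    heptamer: str = "GGATTTT"  # G_GAU_UUU, the conserved dISF shift site
    codon_index: int = 1500  # ORF codon whose 3rd nt starts the heptamer
    spacer_len: int = 7
    #: outermost (stem base) pair first; 7 WC pairs, 4 G:C by default,
    #: mirroring a stable stem base
    stem_pairs: tuple = ("GC", "GC", "GC", "GC", "AU", "AU", "AU")
    loop_len: int = 4
    minus1_codons: int | None = 6  # -1 frame sense codons before the planted stop


@dataclass
class SisterSpec:
    n_compensatory: int = 3
    n_half: int = 0
    n_neutral_mut: int = 20


@dataclass
class SyntheticSpec:
    seed: int = 0
    utr5_len: int = 119
    orf_codons: int = 3450  # sense codons incl. the start; stop added automatically
    utr3_len: int = 376
    gc_content: float = 0.5
    plant_site: PlantSiteSpec | None = field(default_factory=PlantSiteSpec)
    sister: SisterSpec | None = None
    genome_id: str = "synth"
    max_attempts: int = 500


@dataclass
class GroundTruth:
    genome_id: str
    seed: int
    utr5_len: int
    orf_codons: int
    utr3_len: int
    orf_start: int
    orf_end: int
    site_pos: int | None = None
    heptamer: str | None = None
    spacer_len: int | None = None
    stem_pairs: list | None = None  # [(left_idx, right_idx, kind), ...] genome coords
    loop_len: int | None = None
    minus1_codons: int | None = None
    planted_base_run_wc: int | None = None
    planted_base_run_gc: int | None = None
    region_span: tuple | None = None  # genome cells written while planting
    substitutions: list = field(default_factory=list)  # sister ledger

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _random_nt(rng: random.Random, gc: float) -> str:
    r = rng.random()
    if r < gc / 2:
        return "G"
    if r < gc:
        return "C"
    return "A" if r < gc + (1 - gc) / 2 else "T"


def _random_sense_codon(rng: random.Random, gc: float) -> str:
    while True:
        c = "".join(_random_nt(rng, gc) for _ in range(3))
        if c not in STOP_CODONS:
            return c


def _utr5_is_clean(utr5: str) -> bool:
    """True when no upstream in-frame AUG could extend the planted ORF."""
    n = len(utr5)
    for p in range(n - 2):
        if (n - p) % 3 != 0:
            continue  # not in the ORF's frame
        if utr5[p : p + 3] != "ATG":
            continue
        stopped = any(
            utr5[q : q + 3] in STOP_CODONS for q in range(p + 3, n - 2, 3)
        )
        if not stopped:
            return False
    return True


def _codon_aligned_span(start: int, end: int, orf_start: int) -> tuple[int, int]:
    """Widen [start, end) to zero-frame codon boundaries."""
    s = start - (start - orf_start) % 3
    e = end + (-(end - orf_start)) % 3
    return s, e


def _plant_region(
    seq: list, spec: SyntheticSpec, rng: random.Random
) -> dict:
    """Overwrite the genome in place with the planted site; return truth info."""
    ps = spec.plant_site
    assert ps is not None
    site = is_slippery(ps.heptamer)
    if site is None:
        raise InfeasibleSpecError(f"planted heptamer {ps.heptamer!r} is not slippery")
    hept = site.heptamer
    orf_start = spec.utr5_len
    orf_end = orf_start + 3 * (spec.orf_codons + 1)
    pos = orf_start + 3 * ps.codon_index + 2
    P = len(ps.stem_pairs)
    if P < 1 or ps.loop_len < 3:
        raise InfeasibleSpecError("stem needs >=1 pair and loop >=3 nt")
    s0 = pos + 7 + ps.spacer_len
    r0 = s0 + P + ps.loop_len
    region_end = r0 + P
    q = pos + 6 + 3 * ps.minus1_codons if ps.minus1_codons is not None else None
    fold_cfg = FoldConfig()
    wstart = pos + 7
    span_end = max(region_end, (q + 3) if q is not None else 0, wstart + fold_cfg.window)
    span_start, span_end = _codon_aligned_span(pos - 2, span_end, orf_start)
    if span_start < orf_start + 3 or span_end > orf_end - 3:
        raise InfeasibleSpecError("planted site region does not fit inside the ORF")

    pair_cells = [(s0 + k, r0 + P - 1 - k, ps.stem_pairs[k]) for k in range(P)]
    wc_run = gc_run = 0
    for kind in ps.stem_pairs:
        if kind == "GU":
            break
        wc_run += 1
        if kind == "GC":
            gc_run += 1

    for _ in range(spec.max_attempts):
        cells: dict[int, str] = {pos + k: hept[k] for k in range(7)}
        ok = True
        if q is not None:
            for k, nt in enumerate("TAA"):
                if cells.get(q + k, nt) != nt:
                    raise InfeasibleSpecError("-1 frame stop collides with the heptamer")
                cells[q + k] = nt
        for idx, (li, ri, kind) in enumerate(pair_cells):
            if kind not in PAIR_LETTERS:
                raise InfeasibleSpecError(f"unknown pair kind {kind!r}")
            options = [
                o
                for o in PAIR_LETTERS[kind]
                if cells.get(li, o[0]) == o[0] and cells.get(ri, o[1]) == o[1]
            ]
            if idx == 0:
                # purine on the 5' side of the stem base so that no shifted
                # helix starting one nt earlier can tie the planted score
                options = [o for o in options if o[0] in "GA"] or options
            if not options:
                ok = False
                break
            l, r = rng.choice(options)
            cells[li], cells[ri] = l, r
        if not ok:
            raise InfeasibleSpecError("stem pair letters collide with fixed cells")
        # everything else inside the fold window is drawn from {A, C} only
        # (no G/U), so outside the planted stem essentially nothing can pair:
        # the planted hairpin is the provable score optimum of its window and
        # the measured spacer equals the planted spacer.  The last spacer
        # bases are C (C pairs only G, and the window has no free G).
        for i in range(wstart, s0):
            if i not in cells:
                cells[i] = "C" if i >= s0 - 3 else rng.choice("AC")
        for i in range(wstart, wstart + fold_cfg.window):
            if i not in cells:
                cells[i] = rng.choice("AC")
        for i in range(span_start, span_end):
            if i not in cells:
                cells[i] = _random_nt(rng, spec.gc_content)

        # zero-frame codons across the span must all be sense
        if any(
            "".join(cells[i + k] for k in range(3)) in STOP_CODONS
            for i in range(span_start, span_end, 3)
        ):
            continue
        # -1 frame: no stop before q, planted stop at q
        if q is not None:
            if any(
                "".join(cells[i + k] for k in range(3)) in STOP_CODONS
                for i in range(pos + 6, q, 3)
            ):
                continue
        # no second compliant codon-anchored heptamer inside the span
        window = "".join(cells[i] for i in range(span_start, span_end))
        spurious = False
        for i in range(span_start, span_end - 6):
            if i == pos or (i - orf_start) % 3 != 2:
                continue
            if is_slippery(window[i - span_start : i - span_start + 7]) is not None:
                spurious = True
                break
        if spurious:
            continue
        # the fold over the real window must recover the planted spacer and
        # at least the planted WC base run
        fold_window = "".join(cells[i] for i in range(wstart, wstart + fold_cfg.window))
        hp = best_hairpin(fold_window, fold_cfg)
        if hp is None or hp.first_paired_index != ps.spacer_len or hp.base_run_wc < wc_run:
            continue

        for i, nt in cells.items():
            seq[i] = nt
        return {
            "site_pos": pos,
            "heptamer": hept,
            "spacer_len": ps.spacer_len,
            "stem_pairs": [list(c) for c in pair_cells],
            "loop_len": ps.loop_len,
            "minus1_codons": ps.minus1_codons,
            "planted_base_run_wc": wc_run,
            "planted_base_run_gc": gc_run,
            "region_span": (span_start, span_end),
        }
    raise InfeasibleSpecError("could not realize planted region within the retry budget")


def _patch_spurious_heptamers(
    seq: list, orf_start: int, orf_end: int, protected: tuple | None, rng: random.Random
) -> bool:
    """Break chance in-frame compliant heptamers by flipping one YYY base.

    Returns False when a spurious heptamer overlaps the protected planted
    region (the caller must re-draw the genome).
    """
    rec_seq = "".join(seq)
    for _ in range(100):
        changed = False
        for p in range(orf_start + 2, orf_end - 6):
            if (p - orf_start) % 3 != 2:
                continue
            if is_slippery(rec_seq[p : p + 7]) is None:
                continue
            if protected:
                if p == protected[2]:
                    continue  # the planted site itself
                if protected[0] - 6 <= p < protected[1]:
                    # a chance compliant heptamer overlaps the planted span
                    # and cannot be patched without disturbing it
                    return False
            # flip the first Y (heptamer index 3, last base of codon XXY);
            # any other letter breaks YYY and XX_ codons ending in any base
            # stay sense for every legal XXX/exception prefix
            old = rec_seq[p + 3]
            seq[p + 3] = rng.choice([c for c in NTS if c != old])
            rec_seq = "".join(seq)
            changed = True
        if not changed:
            return True
    return False


def generate_genome(spec: SyntheticSpec) -> tuple[GenomeRecord, GroundTruth]:
    """Emit a genome realizing ``spec`` exactly, with its ground truth.

    Deterministic given the spec (including seed).  Raises
    :class:`InfeasibleSpecError` when the planted layout cannot fit.
    """
    rng = random.Random(spec.seed)
    orf_start = spec.utr5_len
    orf_len = 3 * (spec.orf_codons + 1)
    orf_end = orf_start + orf_len

    last_err: Exception | None = None
    for _ in range(spec.max_attempts):
        for _ in range(spec.max_attempts):
            utr5 = "".join(_random_nt(rng, spec.gc_content) for _ in range(spec.utr5_len))
            if _utr5_is_clean(utr5):
                break
        else:
            raise InfeasibleSpecError("could not draw a clean 5'UTR")
        codons = ["ATG"] + [
            _random_sense_codon(rng, spec.gc_content) for _ in range(spec.orf_codons - 1)
        ] + ["TAA"]
        utr3 = "".join(_random_nt(rng, spec.gc_content) for _ in range(spec.utr3_len))
        seq = list(utr5 + "".join(codons) + utr3)

        truth_site: dict = {}
        protected = None
        if spec.plant_site is not None:
            try:
                truth_site = _plant_region(seq, spec, rng)
            except InfeasibleSpecError as e:
                if "retry budget" in str(e):
                    last_err = e
                    continue
                raise
            protected = (
                truth_site["region_span"][0],
                truth_site["region_span"][1],
                truth_site["site_pos"],
            )
        if not _patch_spurious_heptamers(seq, orf_start, orf_end, protected, rng):
            continue

        rec = GenomeRecord(id=spec.genome_id, seq="".join(seq))
        truth = GroundTruth(
            genome_id=spec.genome_id,
            seed=spec.seed,
            utr5_len=spec.utr5_len,
            orf_codons=spec.orf_codons,
            utr3_len=spec.utr3_len,
            orf_start=orf_start,
            orf_end=orf_end,
            **truth_site,
        )
        if _verify(rec, truth, spec):
            return rec, truth
    raise last_err or InfeasibleSpecError("could not emit a verifiable genome")


def _verify(rec: GenomeRecord, truth: GroundTruth, spec: SyntheticSpec) -> bool:
    ann = find_longest_orf(rec)
    if (ann.orf_start, ann.orf_end) != (truth.orf_start, truth.orf_end):
        return False
    if spec.plant_site is None:
        return not scan_slippery(rec, ann)
    cfg = PRFConfig()
    cands = scan_genome(rec, ann, cfg)
    in_bounds = cfg.spacer_min <= truth.spacer_len <= cfg.spacer_max
    if not in_bounds:
        # a planted spacer violation must be rejected, not reported
        return not cands
    if len(cands) != 1:
        return False
    c = cands[0]
    if c.site.pos != truth.site_pos or c.spacer_len != truth.spacer_len:
        return False
    if truth.minus1_codons is not None and c.minus1_orf_codons != truth.minus1_codons:
        return False
    if c.hairpin.base_run_wc < truth.planted_base_run_wc:
        return False
    return True


def generate_sister(
    rec: GenomeRecord,
    truth: GroundTruth,
    sister: SisterSpec,
    seed: int | None = None,
    genome_id: str | None = None,
) -> tuple[GenomeRecord, GroundTruth]:
    """Derive a sister species with an exact, ledgered substitution budget.

    Compensatory edits flip the orientation of a planted stem pair (both
    nucleotides change, pairing and pairing score preserved); half edits
    change one side of a pair to a non-pairing base; neutral edits fall
    outside the planted region and keep the reading frame sense.
    """
    if truth.stem_pairs is None:
        raise ValueError("parent truth has no planted hairpin")
    base_seed = (truth.seed + 10007 if seed is None else seed) % 2**31
    n_pairs = len(truth.stem_pairs)
    if sister.n_compensatory + sister.n_half > n_pairs:
        raise InfeasibleSpecError(
            f"requested {sister.n_compensatory}+{sister.n_half} edited pairs "
            f"but the stem has only {n_pairs}"
        )
    last_err: Exception | None = None
    for attempt in range(50):
        rng = random.Random((base_seed + 9973 * attempt) % 2**31)
        try:
            seq, ledger = _edit_sister(rec, truth, sister, rng)
        except InfeasibleSpecError as e:
            last_err = e
            continue
        sister_rec = GenomeRecord(id=genome_id or f"{rec.id}_sister", seq="".join(seq))
        if _verify_sister(sister_rec, truth):
            break
    else:
        raise last_err or InfeasibleSpecError("could not emit a verifiable sister genome")

    # stem edits may rewrite the parent's planted -1 stop, so the sister's
    # -1 ORF length is re-measured rather than inherited
    m1_site = is_slippery(truth.heptamer)
    m1_site.pos = truth.site_pos
    sister_m1, _ = minus1_orf_length(sister_rec, m1_site)
    sister_truth = GroundTruth(
        genome_id=sister_rec.id,
        seed=truth.seed,
        utr5_len=truth.utr5_len,
        orf_codons=truth.orf_codons,
        utr3_len=truth.utr3_len,
        orf_start=truth.orf_start,
        orf_end=truth.orf_end,
        site_pos=truth.site_pos,
        heptamer=truth.heptamer,
        spacer_len=truth.spacer_len,
        stem_pairs=truth.stem_pairs,
        loop_len=truth.loop_len,
        minus1_codons=sister_m1,
        planted_base_run_wc=truth.planted_base_run_wc,
        planted_base_run_gc=truth.planted_base_run_gc,
        region_span=truth.region_span,
        substitutions=ledger,
    )
    return sister_rec, sister_truth


def _verify_sister(sister_rec: GenomeRecord, truth: GroundTruth) -> bool:
    """The sister must re-annotate and re-scan to the same planted site."""
    ann = find_longest_orf(sister_rec)
    if (ann.orf_start, ann.orf_end) != (truth.orf_start, truth.orf_end):
        return False
    cfg = PRFConfig()
    cands = scan_genome(sister_rec, ann, cfg)
    if not (cfg.spacer_min <= truth.spacer_len <= cfg.spacer_max):
        return not cands
    return (
        len(cands) == 1
        and cands[0].site.pos == truth.site_pos
        and cands[0].spacer_len == truth.spacer_len
    )


def _edit_sister(
    rec: GenomeRecord, truth: GroundTruth, sister: SisterSpec, rng: random.Random
) -> tuple[list, list]:
    n_pairs = len(truth.stem_pairs)
    seq = list(rec.seq)
    ledger: list[dict] = []
    # pairing-breaking edits go to the innermost pairs so the stem base --
    # and with it the measured spacer -- survives in the sister
    half_idx = list(range(n_pairs - 1, n_pairs - 1 - sister.n_half, -1))
    comp_idx = rng.sample([k for k in range(n_pairs) if k not in half_idx], sister.n_compensatory)

    def codon_sense_at(i: int) -> bool:
        c0 = i - (i - truth.orf_start) % 3
        return "".join(seq[c0 : c0 + 3]) not in STOP_CODONS

    for k in sorted(comp_idx):
        li, ri, kind = truth.stem_pairs[k]
        old = (seq[li], seq[ri])
        # prefer the orientation flip (same pair kind, score preserved), fall
        # back to any legal pair in which both sides change
        flips = [o for o in PAIR_LETTERS[kind] if o[0] != old[0] and o[1] != old[1]]
        others = [
            o
            for plist in PAIR_LETTERS.values()
            for o in plist
            if o[0] != old[0] and o[1] != old[1] and o not in flips
        ]
        done = False
        for new in flips + others:
            seq[li], seq[ri] = new
            if codon_sense_at(li) and codon_sense_at(ri):
                ledger.append(
                    {"kind": "compensatory", "pair_index": k, "positions": [li, ri],
                     "from": list(old), "to": list(new)}
                )
                done = True
                break
            seq[li], seq[ri] = old
        if not done:
            raise InfeasibleSpecError(f"no compensatory substitution possible at pair {k}")

    for k in sorted(half_idx):
        li, ri, kind = truth.stem_pairs[k]
        old = seq[ri]
        legal = {o[1] for o in PAIR_LETTERS["GC"] + PAIR_LETTERS["AU"] + PAIR_LETTERS["GU"]
                 if o[0] == seq[li]}
        done = False
        for new in rng.sample(NTS, 4):
            if new == old or new in legal:
                continue
            seq[ri] = new
            if codon_sense_at(ri):
                ledger.append(
                    {"kind": "half", "pair_index": k, "positions": [ri],
                     "from": [old], "to": [new]}
                )
                done = True
                break
            seq[ri] = old
        if not done:
            raise InfeasibleSpecError(f"no pairing-breaking substitution at pair {k}")

    span = truth.region_span or (truth.site_pos, truth.site_pos + 7)
    placed = 0
    guard = 0
    while placed < sister.n_neutral_mut and guard < 10000:
        guard += 1
        i = rng.randrange(len(seq))
        if span[0] - 8 <= i < span[1] + 8:
            continue
        old = seq[i]
        new = rng.choice([c for c in NTS if c != old])
        seq[i] = new
        in_orf = truth.orf_start + 3 <= i < truth.orf_end - 3
        if in_orf and not codon_sense_at(i):
            seq[i] = old
            continue
        # keep the planted site unique and the ORF boundaries intact
        window_lo = max(truth.orf_start + 2, i - 8)
        bad = False
        if in_orf:
            s = "".join(seq)
            for p in range(window_lo, min(i + 7, truth.orf_end - 6)):
                if (p - truth.orf_start) % 3 == 2 and p != truth.site_pos:
                    if is_slippery(s[p : p + 7]) is not None:
                        bad = True
                        break
        if not in_orf and i < truth.orf_start:
            bad = not _utr5_is_clean("".join(seq[: truth.orf_start]))
        if bad:
            seq[i] = old
            continue
        ledger.append({"kind": "neutral", "positions": [i], "from": [old], "to": [new]})
        placed += 1
    if placed < sister.n_neutral_mut:
        raise InfeasibleSpecError("could not place the requested neutral substitutions")

    return seq, ledger


def generate_family(spec: SyntheticSpec) -> tuple:
    """Genome plus (optionally) its sister: ((rec, truth), (sister, truth) | None)."""
    rec, truth = generate_genome(spec)
    if spec.sister is None:
        return (rec, truth), None
    return (rec, truth), generate_sister(rec, truth, spec.sister)
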