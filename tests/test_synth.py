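import pytest

from prfscan.annotate import find_longest_orf
from prfscan.prf import is_slippery, scan_genome
from prfscan.synth import (
    InfeasibleSpecError,
    PlantSiteSpec,
    SisterSpec,
    SyntheticSpec,
    generate_genome,
    generate_sister,
)


def test_genome_length_arithmetic():
    spec = SyntheticSpec(
        seed=0, utr5_len=100, orf_codons=3000, utr3_len=300,
        plant_site=PlantSiteSpec(codon_index=1500),
    )
    rec, truth = generate_genome(spec)
    assert len(rec) == 100 + 3 * 3001 + 300 == 9403


def test_same_seed_is_byte_identical():
    spec_kwargs = dict(seed=9, utr5_len=80, orf_codons=400, utr3_len=90)
    a, _ = generate_genome(SyntheticSpec(**spec_kwargs, plant_site=PlantSiteSpec(codon_index=200)))
    b, _ = generate_genome(SyntheticSpec(**spec_kwargs, plant_site=PlantSiteSpec(codon_index=200)))
    assert a.seq == b.seq


def test_different_seeds_differ():
    a, _ = generate_genome(SyntheticSpec(seed=1, utr5_len=80, orf_codons=400, utr3_len=90,
                                         plant_site=PlantSiteSpec(codon_index=200)))
    b, _ = generate_genome(SyntheticSpec(seed=2, utr5_len=80, orf_codons=400, utr3_len=90,
                                         plant_site=PlantSiteSpec(codon_index=200)))
    assert a.seq != b.seq


def test_planted_heptamer_is_codon_anchored(small_genome):
    rec, truth = small_genome
    assert (truth.site_pos - truth.orf_start) % 3 == 2
    assert is_slippery(rec.seq[truth.site_pos : truth.site_pos + 7]) is not None


def test_unplanted_genome_scans_clean():
    spec = SyntheticSpec(seed=13, utr5_len=90, orf_codons=500, utr3_len=100, plant_site=None)
    rec, truth = generate_genome(spec)
    ann = find_longest_orf(rec)
    assert (ann.utr5_len, ann.orf_codons, ann.utr3_len) == (90, 500, 100)
    from prfscan.prf import scan_slippery

    assert scan_slippery(rec, ann) == []


def test_infeasible_layout_raises():
    # site so close to the ORF end that the fold window cannot fit
    spec = SyntheticSpec(
        seed=0, utr5_len=60, orf_codons=300, utr3_len=60,
        plant_site=PlantSiteSpec(codon_index=295),
    )
    with pytest.raises(InfeasibleSpecError):
        generate_genome(spec)


def test_minus1_stop_collision_raises():
    # -1 stop demanded on top of a heptamer whose last nt is not T
    spec = SyntheticSpec(
        seed=0, utr5_len=60, orf_codons=300, utr3_len=60,
        plant_site=PlantSiteSpec(heptamer="AAAAAAA", codon_index=150, minus1_codons=0),
    )
    with pytest.raises(InfeasibleSpecError):
        generate_genome(spec)


def test_sister_all_zero_budget_is_identical(small_genome):
    rec, truth = small_genome
    sis, struth = generate_sister(rec, truth, SisterSpec(0, 0, 0))
    assert sis.seq == rec.seq
    assert struth.substitutions == []


def test_sister_ledger_counts_match_request(small_genome):
    rec, truth = small_genome
    sis, struth = generate_sister(rec, truth, SisterSpec(3, 2, 10))
    kinds = [s["kind"] for s in struth.substitutions]
    assert kinds.count("compensatory") == 3
    assert kinds.count("half") == 2
    assert kinds.count("neutral") == 10
    # every compensatory edit changed both sides to a still-legal pair
    from prfscan.fold import LEGAL_PAIRS

    for s in struth.substitutions:
        if s["kind"] == "compensatory":
            li, ri = s["positions"]
            assert (sis.seq[li], sis.seq[ri]) in LEGAL_PAIRS
            assert sis.seq[li] != rec.seq[li] and sis.seq[ri] != rec.seq[ri]
        if s["kind"] == "half":
            (ri,) = s["positions"]
            assert sis.seq[ri] != rec.seq[ri]


def test_sister_budget_exceeding_stem_raises(small_genome):
    rec, truth = small_genome
    with pytest.raises(InfeasibleSpecError):
        generate_sister(rec, truth, SisterSpec(n_compensatory=6, n_half=6, n_neutral_mut=0))


def test_full_pipeline_recovery_over_seeds():
    """UTR/ORF lengths, planted site position, spacer and stem base run are
    recovered exactly on every seeded genome."""
    for seed in range(12):
        spec = SyntheticSpec(seed=seed, utr5_len=110, orf_codons=700, utr3_len=180,
                             plant_site=PlantSiteSpec(codon_index=350))
        rec, truth = generate_genome(spec)
        ann = find_longest_orf(rec)
        assert (ann.utr5_len, ann.orf_codons, ann.utr3_len) == (110, 700, 180)
        (cand,) = scan_genome(rec, ann)
        assert cand.site.pos == truth.site_pos
        assert cand.spacer_len == truth.spacer_len
        assert cand.hairpin.base_run_wc >= truth.planted_base_run_wc
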