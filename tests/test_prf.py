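import pytest

from prfscan.annotate import find_longest_orf
from prfscan.prf import (
    PRFConfig,
    SlipperySite,
    build_candidates,
    is_slippery,
    minus1_orf_length,
    scan_genome,
    scan_slippery,
)
from prfscan.seq_io import GenomeRecord
from prfscan.synth import PlantSiteSpec, SyntheticSpec, generate_genome


@pytest.mark.parametrize(
    "heptamer,accept,via_exception",
    [
        ("GGAUUUU", True, True),  # the conserved dISF shift site
        ("UUUUUUU", True, False),
        ("UUUUUUA", True, False),
        ("AAAAAAC", True, False),
        ("GGGAAAA", True, False),
        ("UUUUUUG", False, None),  # Z must be A, C or U
        ("ACGUACG", False, None),
        ("AUGAAAU", False, None),  # XXX not identical, not an exception
        ("GGAGGGU", False, None),  # YYY must be AAA or UUU
    ],
)
def test_slippery_consensus_table(heptamer, accept, via_exception):
    site = is_slippery(heptamer)
    if accept:
        assert site is not None
        assert site.via_exception == via_exception
        assert site.heptamer == site.xxx + site.yyy + site.z
    else:
        assert site is None


def test_slippery_wrong_length_errors():
    with pytest.raises(ValueError, match="7 nt"):
        is_slippery("GGAUUU")


def test_display_renders_rna_with_codon_underscores():
    site = is_slippery("GGATTTT")
    assert site.display == "G_GAU_UUU"


def test_scan_finds_exactly_the_planted_site(small_genome):
    rec, truth = small_genome
    ann = find_longest_orf(rec)
    sites = scan_slippery(rec, ann)
    assert [s.pos for s in sites] == [truth.site_pos]
    assert sites[0].in_frame


def test_frame_filter_off_is_superset(small_genome):
    rec, truth = small_genome
    ann = find_longest_orf(rec)
    strict = {s.pos for s in scan_slippery(rec, ann)}
    loose = {s.pos for s in scan_slippery(rec, ann, PRFConfig(frame_filter=False))}
    assert strict <= loose


def test_poly_g_genome_has_no_sites():
    # needs a valid ORF but a YYY-free interior
    seq = "ATG" + "GGG" * 50 + "TAA"
    rec = GenomeRecord(id="g", seq=seq)
    ann = find_longest_orf(rec)
    assert scan_slippery(rec, ann) == []


def test_minus1_orf_length_manual_toy():
    # heptamer G_GAU_UUU at pos 4; the -1 frame starts at its last nt
    # (pos 10) and reads TCA ACC TAA -> 2 sense codons then stop
    seq = "ATGGGGATTTTCAACCTAAACCTAA"
    site = is_slippery("GGATTTT")
    site.pos = 4
    codons, truncated = minus1_orf_length(GenomeRecord(id="t", seq=seq), site)
    assert (codons, truncated) == (2, False)


def test_minus1_stop_immediately_after_shift():
    #  -1 frame codon at the heptamer's last nt is TAA at once
    seq = "CCGGATTTTAAG"
    site = is_slippery("GGATTTT")
    site.pos = 2
    codons, truncated = minus1_orf_length(GenomeRecord(id="t", seq=seq), site)
    assert (codons, truncated) == (0, False)


def test_minus1_runs_to_genome_end_sets_truncation_flag():
    seq = "CCGGATTTTCAACA"
    site = is_slippery("GGATTTT")
    site.pos = 2
    codons, truncated = minus1_orf_length(GenomeRecord(id="t", seq=seq), site)
    assert truncated and codons == 2


def test_planted_minus1_codon_count_recovered(small_genome):
    rec, truth = small_genome
    ann = find_longest_orf(rec)
    (cand,) = scan_genome(rec, ann)
    assert cand.minus1_orf_codons == truth.minus1_codons == 6


@pytest.mark.parametrize("spacer,kept", [(5, True), (7, True), (9, True), (4, False), (10, False)])
def test_spacer_bounds_drive_acceptance(spacer, kept):
    spec = SyntheticSpec(
        seed=77,
        utr5_len=90,
        orf_codons=500,
        utr3_len=120,
        plant_site=PlantSiteSpec(codon_index=250, spacer_len=spacer, minus1_codons=None),
    )
    rec, truth = generate_genome(spec)
    ann = find_longest_orf(rec)
    cands = scan_genome(rec, ann)
    if kept:
        assert [c.site.pos for c in cands] == [truth.site_pos]
        assert cands[0].spacer_len == spacer
    else:
        assert cands == []


def test_accepted_heptamers_revalidate(small_genome):
    rec, truth = small_genome
    ann = find_longest_orf(rec)
    for cand in scan_genome(rec, ann):
        assert is_slippery(cand.site.heptamer) is not None


def test_reverse_complement_scan_disjoint(small_genome):
    from prfscan.seq_io import reverse_complement

    rec, truth = small_genome
    ann = find_longest_orf(rec)
    fwd = {s.pos for s in scan_slippery(rec, ann, PRFConfig(frame_filter=False))}
    rc = GenomeRecord(id="rc", seq=reverse_complement(rec.seq))
    try:
        ann_rc = find_longest_orf(rc)
    except Exception:
        return
    n = len(rec.seq)
    rc_sites = {n - 7 - s.pos for s in scan_slippery(rc, ann_rc, PRFConfig(frame_filter=False))}
    # forward-strand sites are never re-reported from the reverse strand
    assert not (fwd & rc_sites) or all(
        rec.seq[p : p + 7] != reverse_complement(rec.seq)[n - 7 - p : n - p] for p in fwd & rc_sites
    )
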