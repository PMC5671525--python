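from collections import Counter

import pytest

from prfscan.annotate import find_longest_orf
from prfscan.conserve import (
    CompensatoryPair,
    ConserveConfig,
    align_sites,
    classify_pairs,
    compare_sites,
    report_text,
)
from prfscan.fold import Hairpin
from prfscan.prf import PRFCandidate, scan_genome
from prfscan.synth import SisterSpec, SyntheticSpec, generate_genome, generate_sister


def _family(seed=11, n_comp=3, n_half=2, n_neutral=15):
    spec = SyntheticSpec(
        seed=seed, sister=SisterSpec(n_compensatory=n_comp, n_half=n_half, n_neutral_mut=n_neutral)
    )
    rec, truth = generate_genome(spec)
    sis, struth = generate_sister(rec, truth, spec.sister)
    ann_a, ann_b = find_longest_orf(rec), find_longest_orf(sis)
    (ca,) = scan_genome(rec, ann_a)
    (cb,) = scan_genome(sis, ann_b)
    return (rec, ann_a, ca), (sis, ann_b, cb), struth


def test_self_comparison_is_all_identical(small_genome):
    rec, truth = small_genome
    ann = find_longest_orf(rec)
    (cand,) = scan_genome(rec, ann)
    aln, classes = compare_sites((rec, ann, cand), (rec, ann, cand))
    assert aln.location_conserved
    assert {c.kind for c in classes} == {"identical"}


def test_planted_substitution_budget_recovered_exactly():
    a, b, struth = _family()
    aln, classes = compare_sites(a, b)
    counts = Counter(c.kind for c in classes)
    assert counts["compensatory"] == 3
    assert counts["pairing-lost"] == 2
    assert counts["identical"] == len(classes) - 5
    assert aln.location_conserved


def test_compensatory_count_symmetric_when_structures_agree():
    a, b, _ = _family(seed=23, n_half=0, n_neutral=5)
    _, ab = compare_sites(a, b)
    _, ba = compare_sites(b, a)
    comp_ab = {c.pair_index for c in ab if c.kind == "compensatory"}
    comp_ba = {c.pair_index for c in ba if c.kind == "compensatory"}
    if [p for p in a[2].hairpin.pairs] == [p for p in b[2].hairpin.pairs]:
        assert comp_ab == comp_ba


@pytest.mark.parametrize(
    "a_pair,b_pair,expected",
    [
        (("G", "C"), ("C", "G"), "compensatory"),
        (("G", "C"), ("G", "C"), "identical"),
        (("G", "C"), ("G", "A"), "pairing-lost"),
        (("G", "C"), ("G", "T"), "half-substitution"),  # wobble retained
        (("A", "T"), ("T", "A"), "compensatory"),
    ],
)
def test_pair_classification_definitions(a_pair, b_pair, expected):
    # two 18-nt regions: 7-nt heptamer, 5-nt spacer, one stem pair at window
    # indices 5 and 10 of the hairpin window (positions 12 and 17)
    a_region = "GGATTTT" + "AACCA" + a_pair[0] + "AAAC" + a_pair[1]
    b_region = "GGATTTT" + "AACCA" + b_pair[0] + "AAAC" + b_pair[1]
    hp = Hairpin(region_start=7, window="AACCA" + a_pair[0] + "AAAC" + a_pair[1],
                 pairs=[(5, 10)], score=3.0)
    from prfscan.conserve import SiteAlignment

    site_aln = SiteAlignment(
        a_id="a", b_id="b", a_aln=a_region, b_aln=b_region,
        a_region_start=0, b_region_start=0, location_conserved=True,
    )
    cand = PRFCandidate(site=None, spacer_len=5, hairpin=hp, minus1_orf_codons=0)
    (res,) = classify_pairs(cand, site_aln)
    assert res.kind == expected


def test_strict_wc_mode_rejects_wobble():
    a_region = "GGATTTT" + "AACCA" + "G" + "AAAC" + "C"
    b_region = "GGATTTT" + "AACCA" + "G" + "AAAC" + "T"
    hp = Hairpin(region_start=7, window="AACCAGAAACC", pairs=[(5, 10)], score=3.0)
    from prfscan.conserve import SiteAlignment

    site_aln = SiteAlignment(
        a_id="a", b_id="b", a_aln=a_region, b_aln=b_region,
        a_region_start=0, b_region_start=0, location_conserved=True,
    )
    cand = PRFCandidate(site=None, spacer_len=5, hairpin=hp, minus1_orf_codons=0)
    (loose,) = classify_pairs(cand, site_aln, ConserveConfig(strict_wc=False))
    (strict,) = classify_pairs(cand, site_aln, ConserveConfig(strict_wc=True))
    assert loose.kind == "half-substitution"
    assert strict.kind == "pairing-lost"


def test_gap_in_paired_column_is_pairing_lost_with_flag():
    a_region = "GGATTTT" + "AACCA" + "G" + "AAAC" + "C"
    b_region = "GGATTTT" + "AACCA" + "G" + "AAAC" + "-"
    hp = Hairpin(region_start=7, window="AACCAGAAACC", pairs=[(5, 10)], score=3.0)
    from prfscan.conserve import SiteAlignment

    site_aln = SiteAlignment(
        a_id="a", b_id="b", a_aln=a_region, b_aln=b_region,
        a_region_start=0, b_region_start=0, location_conserved=True,
    )
    cand = PRFCandidate(site=None, spacer_len=5, hairpin=hp, minus1_orf_codons=0)
    (res,) = classify_pairs(cand, site_aln)
    assert res.kind == "pairing-lost" and res.gap


def test_location_flag_false_for_distant_sites():
    from prfscan.synth import PlantSiteSpec

    spec_a = SyntheticSpec(seed=2, plant_site=PlantSiteSpec(codon_index=500), genome_id="va")
    spec_b = SyntheticSpec(seed=3, plant_site=PlantSiteSpec(codon_index=2500), genome_id="vb")
    rec_a, _ = generate_genome(spec_a)
    rec_b, _ = generate_genome(spec_b)
    ann_a, ann_b = find_longest_orf(rec_a), find_longest_orf(rec_b)
    (ca,) = scan_genome(rec_a, ann_a)
    (cb,) = scan_genome(rec_b, ann_b)
    aln = align_sites((rec_a, ann_a, ca), (rec_b, ann_b, cb))
    assert not aln.location_conserved


def test_report_text_contains_structure_and_pairs():
    a, b, _ = _family(seed=31)
    aln, classes = compare_sites(a, b)
    text = report_text(aln, classes, a[2])
    assert "(" in text and ")" in text
    assert "compensatory" in text
    assert "U" in text and "T" not in text.split("\n")[2]  # RNA rendering
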