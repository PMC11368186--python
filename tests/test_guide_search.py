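"""The hit model, candidate sampling and selection filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multiguide.errors import ConfigurationError
from multiguide.guide_search import (
    GuideCandidate,
    MatchPolicy,
    ProximityPolicy,
    RepeatFilterPolicy,
    SeedIndex,
    draw_quotas,
    evaluate_guide,
    find_hits,
    has_simple_repeat,
    sample_candidates,
)
from multiguide.model import GenomeAssembly, Interval, RegionSet
from multiguide.synthesis import (
    brute_force_hits,
    make_genome,
    plant_sites,
    random_guide,
)


# -- policies ----------------------------------------------------------------


def test_match_policy_validates_block_lengths():
    with pytest.raises(ConfigurationError):
        MatchPolicy(seed_len=13)  # 13 + 8 != 20
    with pytest.raises(ConfigurationError):
        MatchPolicy(max_distal_mm=9)
    with pytest.raises(ConfigurationError):
        MatchPolicy(pam="NGQ")


def test_repeat_and_proximity_policy_bounds():
    with pytest.raises(ConfigurationError):
        RepeatFilterPolicy(min_units=1)
    with pytest.raises(ConfigurationError):
        ProximityPolicy(min_site_spacing=-1)


# -- simple repeats ----------------------------------------------------------


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("CTGAAAACTG", True),  # AAAA homopolymer
        ("CTACACACACGT", True),  # ACACACAC dinucleotide run
        ("GATTAATAGCCTAAACTGTC", False),  # a real multi-target guide
        ("GTGTGTGT", True),
        ("GTGTGT", False),  # only 3 units of GT
        ("ACGTACGTACGTACGTACGT", False),  # unit length 4 > max_unit_len
    ],
)
def test_simple_repeat_detection(seq, expected):
    assert has_simple_repeat(seq) is expected


def test_simple_repeat_rejects_invalid_input():
    with pytest.raises(ValueError):
        has_simple_repeat("")
    with pytest.raises(ValueError):
        has_simple_repeat("ACGNACGT")


def _oracle_simple_repeat(seq, max_unit_len, min_units):
    """Exhaustive substring oracle: any block of >= min_units tandem
    copies of any unit of length <= max_unit_len."""
    for u in range(1, max_unit_len + 1):
        for i in range(len(seq) - u * min_units + 1):
            unit = seq[i : i + u]
            if seq[i : i + u * min_units] == unit * min_units:
                return True
    return False


@settings(derandomize=True, max_examples=300)
@given(st.text(alphabet="ACGT", min_size=1, max_size=24))
def test_simple_repeat_matches_exhaustive_oracle(seq):
    policy = RepeatFilterPolicy()
    assert has_simple_repeat(seq, policy) == _oracle_simple_repeat(
        seq, policy.max_unit_len, policy.min_units
    )


# -- find_hits ---------------------------------------------------------------


def test_single_planted_site_found_exactly_once(small_synthetic, whole_genome_regions):
    rng = np.random.default_rng(5)
    guide = random_guide(rng)
    planted, truth = plant_sites(
        small_synthetic.assembly, guide, 1, whole_genome_regions, 2_000, seed=9
    )
    hits = find_hits(guide, planted)
    assert len(hits) == 1
    (h,) = hits
    assert (h.chromosome, h.start, h.strand) == truth.perfect_sites[0]
    assert h.distal_mismatches == 0


def test_mismatch_boundaries_of_the_seed_distal_model(planted_fixture):
    """3 perfect sites + decoys: the 2-distal-mismatch decoy is counted,
    the 3-distal-mismatch and seed-mismatch decoys are invisible."""
    planted, truth = planted_fixture
    hits = find_hits(truth.guide, planted)
    assert len(hits) == 4 + 1  # 4 perfect + one 2-mm decoy
    perfect = [(h.chromosome, h.start, h.strand) for h in hits if h.distal_mismatches == 0]
    assert sorted(perfect) == truth.perfect_sites
    near = [h for h in hits if h.distal_mismatches > 0]
    assert len(near) == 1 and near[0].distal_mismatches == 2


def test_find_hits_equals_brute_force_on_random_fixture():
    rng = np.random.default_rng(17)
    syn = make_genome({"c1": 15_000, "c2": 8_000}, 0.5, seed=17)
    regions = RegionSet(
        [Interval(c, 0, L) for c, L in syn.assembly.lengths.items()], "allowed"
    )
    guide = random_guide(rng)
    planted, _ = plant_sites(
        syn.assembly, guide, 3, regions, 1_000, [(0, 1), (0, 2), (2, 2)], seed=8
    )
    assert find_hits(guide, planted) == brute_force_hits(guide, planted)


def test_find_hits_without_pam_requirement_counts_bare_matches():
    rng = np.random.default_rng(21)
    guide = random_guide(rng)
    # one copy followed by a PAM, one copy followed by TTT (no PAM)
    filler = "".join(rng.choice(list("ACGT"), 200))
    seq = filler + guide + "AGG" + filler + guide + "TTT" + filler
    asm = GenomeAssembly({"c": seq})
    strict = MatchPolicy()
    lax = MatchPolicy(require_pam_at_hits=False)
    assert len(find_hits(guide, asm, strict)) == 1
    lax_hits = find_hits(guide, asm, lax)
    assert len(lax_hits) == 2
    assert sorted(h.pam_present for h in lax_hits) == [False, True]


def test_guides_with_n_are_rejected(small_synthetic):
    with pytest.raises(ValueError):
        find_hits("GN" + "ACGT" * 4 + "AC", small_synthetic.assembly)


def test_seed_index_mismatch_with_policy_is_an_error(small_synthetic):
    idx = SeedIndex(small_synthetic.assembly, 10)
    with pytest.raises(ValueError):
        find_hits("G" * 0 + "GACGTACGTACGTACGTACG", small_synthetic.assembly, MatchPolicy(), idx)


# -- evaluate_guide ----------------------------------------------------------


def _allowed_everywhere(asm):
    return RegionSet([Interval(c, 0, L) for c, L in asm.lengths.items()], "allowed")


def test_clean_guide_is_selected_with_its_multiplicity(small_synthetic, whole_genome_regions):
    rng = np.random.default_rng(31)
    guide = random_guide(rng)
    planted, truth = plant_sites(
        small_synthetic.assembly, guide, 4, whole_genome_regions, 12_000, seed=6
    )
    cand = GuideCandidate("g1", guide)
    hits = find_hits(guide, planted)
    rep = evaluate_guide(cand, hits, _allowed_everywhere(planted), list(planted.lengths))
    assert rep.status == "selected"
    assert rep.multiplicity == 4
    assert rep.rejection_reasons == []


def test_near_miss_hit_rejects_with_mismatched_hit(planted_fixture):
    planted, truth = planted_fixture
    cand = GuideCandidate("g1", truth.guide)
    hits = find_hits(truth.guide, planted)
    rep = evaluate_guide(
        cand, hits, _allowed_everywhere(planted), list(planted.lengths),
        ProximityPolicy(min_site_spacing=1_000),
    )
    assert rep.status == "rejected"
    assert "mismatched_hit" in rep.rejection_reasons
    assert rep.multiplicity == 4  # perfect hits still counted


def test_close_sites_reject_with_clustered_hits(small_synthetic, whole_genome_regions):
    rng = np.random.default_rng(41)
    guide = random_guide(rng)
    planted, _ = plant_sites(
        small_synthetic.assembly, guide, 2, whole_genome_regions, 500, seed=13
    )
    cand = GuideCandidate("g1", guide)
    hits = find_hits(guide, planted)
    starts = sorted(h.start for h in hits if h.chromosome == hits[0].chromosome)
    rep = evaluate_guide(cand, hits, _allowed_everywhere(planted), list(planted.lengths))
    if len(starts) == 2 and starts[1] - starts[0] < 10_000:
        assert "clustered_hits" in rep.rejection_reasons
    else:  # sites landed on different chromosomes: spacing filter passes
        assert "clustered_hits" not in rep.rejection_reasons


def test_off_region_and_off_chromosome_hits_reject(planted_fixture):
    planted, truth = planted_fixture
    cand = GuideCandidate("g1", truth.guide)
    hits = find_hits(truth.guide, planted)
    nowhere = RegionSet([Interval(list(planted.lengths)[0], 0, 10)], "allowed")
    rep = evaluate_guide(cand, hits, nowhere, ["not_a_chromosome"])
    assert "off_region_hit" in rep.rejection_reasons
    assert "off_chromosome_hit" in rep.rejection_reasons
    assert rep.status == "rejected"


def test_all_applicable_reasons_accumulate(planted_fixture):
    planted, truth = planted_fixture
    cand = GuideCandidate("g1", truth.guide)
    rep = evaluate_guide(cand, [], _allowed_everywhere(planted), list(planted.lengths))
    assert rep.rejection_reasons == ["no_hits"]
    assert rep.multiplicity == 0


# -- sampling ----------------------------------------------------------------


def test_zero_draws_yield_empty_collection(small_synthetic, whole_genome_regions):
    assert sample_candidates(small_synthetic.assembly, whole_genome_regions, 0, 1) == []


def test_empty_allowed_set_is_a_configuration_error(small_synthetic):
    with pytest.raises(ConfigurationError):
        sample_candidates(small_synthetic.assembly, RegionSet([], "allowed"), 5, 1)


def test_draw_quotas_match_direct_multinomial_oracle():
    """Fully-allowed 100 kb + 50 kb genome at n=3000: quotas equal the
    multinomial oracle at the same seed and sit in a 3-sigma envelope of
    the 2000/1000 expectation."""
    lengths = {"big": 100_000, "small": 50_000}
    quotas = draw_quotas(lengths, 3_000, np.random.default_rng(77))
    oracle = np.random.default_rng(77).multinomial(
        3_000, np.array([100_000, 50_000]) / 150_000
    )
    assert [quotas["big"], quotas["small"]] == list(oracle)
    for got, expect, p in [(quotas["big"], 2_000, 2 / 3), (quotas["small"], 1_000, 1 / 3)]:
        sigma = np.sqrt(3_000 * p * (1 - p))
        assert abs(got - expect) <= 3 * sigma


def test_candidates_satisfy_all_draw_constraints(small_synthetic, whole_genome_regions):
    asm = small_synthetic.assembly
    cands = sample_candidates(asm, whole_genome_regions, 300, seed=2)
    assert cands  # random 80 kb sequence offers plenty of G+NGG sites
    seqs = set()
    for c in cands:
        assert len(c.sequence) == 20
        assert c.sequence.startswith("G")
        assert "N" not in c.sequence
        assert not has_simple_repeat(c.sequence)
        seqs.add(c.sequence)
        src = c.source
        genomic = asm.chromosomes[src.chromosome][src.start : src.end]
        if src.strand == "+":
            assert genomic == c.sequence
            pam = asm.chromosomes[src.chromosome][src.end : src.end + 3]
        else:
            from multiguide._seq import revcomp

            assert revcomp(genomic) == c.sequence
            pam = revcomp(asm.chromosomes[src.chromosome][src.start - 3 : src.start])
        assert pam[1:] == "GG"
    assert len(seqs) == len(cands)  # duplicates collapsed


def test_sampling_is_deterministic_per_seed(small_synthetic, whole_genome_regions):
    a = sample_candidates(small_synthetic.assembly, whole_genome_regions, 150, seed=9)
    b = sample_candidates(small_synthetic.assembly, whole_genome_regions, 150, seed=9)
    c = sample_candidates(small_synthetic.assembly, whole_genome_regions, 150, seed=10)
    assert a == b
    assert [x.sequence for x in a] != [x.sequence for x in c]


# -- invariants --------------------------------------------------------------


def test_strand_symmetry_under_reverse_complement(planted_fixture):
    """Reverse-complementing every chromosome preserves total hit counts;
    strands swap and coordinates mirror."""
    from multiguide._seq import revcomp

    planted, truth = planted_fixture
    flipped = GenomeAssembly(
        {c: revcomp(s) for c, s in planted.chromosomes.items()}
    )
    fwd = find_hits(truth.guide, planted)
    rev = find_hits(truth.guide, flipped)
    assert len(fwd) == len(rev)
    glen = 20
    mirrored = sorted(
        (h.chromosome, planted.lengths[h.chromosome] - h.start - glen,
         "-" if h.strand == "+" else "+", h.distal_mismatches)
        for h in fwd
    )
    got = sorted(
        (h.chromosome, h.start, h.strand, h.distal_mismatches) for h in rev
    )
    assert got == mirrored


def test_hit_count_monotone_in_distal_mismatch_budget(planted_fixture):
    planted, truth = planted_fixture
    counts = []
    for mm in range(0, 9):
        policy = MatchPolicy(max_distal_mm=mm)
        counts.append(len(find_hits(truth.guide, planted, policy)))
    assert counts == sorted(counts)


def test_adding_near_decoy_flips_selection_and_far_decoy_does_not(
    small_synthetic, whole_genome_regions
):
    rng = np.random.default_rng(55)
    guide = random_guide(rng)
    asm = small_synthetic.assembly
    chroms = list(asm.lengths)
    planted, _ = plant_sites(asm, guide, 3, whole_genome_regions, 11_000, seed=60)
    base = evaluate_guide(
        GuideCandidate("g", guide), find_hits(guide, planted),
        _allowed_everywhere(planted), chroms,
    )
    assert base.status == "selected"
    with_near, _ = plant_sites(asm, guide, 3, whole_genome_regions, 11_000,
                               [(0, 2)], seed=60)
    rep = evaluate_guide(
        GuideCandidate("g", guide), find_hits(guide, with_near),
        _allowed_everywhere(with_near), chroms,
    )
    assert rep.status == "rejected" and "mismatched_hit" in rep.rejection_reasons
    with_far, _ = plant_sites(asm, guide, 3, whole_genome_regions, 11_000,
                              [(0, 3), (1, 0)], seed=60)
    rep2 = evaluate_guide(
        GuideCandidate("g", guide), find_hits(guide, with_far),
        _allowed_everywhere(with_far), chroms,
    )
    assert rep2.status == "selected"
    assert rep2.multiplicity == base.multiplicity
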