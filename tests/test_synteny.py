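"""Synteny decomposition, breakpoint classes, conformations, exact matches."""

import numpy as np
import pytest

from numtscope import simgenome as sg
from numtscope import synteny as sy
from numtscope._seq import random_seq, revcomp
from tests.conftest import breakpoint_recovery, make_genesis, truth_junctions


# ---------------------------------------------------------------------------
# decompose_synteny
# ---------------------------------------------------------------------------

def test_exact_slice_gives_single_identity_block(plain_genome):
    numt = plain_genome.sequence[4000:9000]
    blocks = sy.decompose_synteny(numt, plain_genome)
    assert len(blocks) == 1
    b = blocks[0]
    assert b.numt_interval == (0, 5000)
    assert b.organelle_interval == (4000, 9000)
    assert b.orientation == "+"


def test_wrapping_fragment_reported_with_unwrapped_interval(plain_genome):
    L = plain_genome.length
    numt = plain_genome.sequence[L - 2000:] + plain_genome.sequence[:3000]
    blocks = sy.decompose_synteny(numt, plain_genome)
    assert len(blocks) == 1
    b = blocks[0]
    assert b.organelle_interval == (L - 2000, L + 3000)
    assert b.wrapped(L)


def test_small_k_rejected_and_empty_on_no_anchors(plain_genome):
    with pytest.raises(ValueError):
        sy.decompose_synteny("ACGT" * 100, plain_genome, k=10)
    rng = np.random.default_rng(0)
    with pytest.warns(UserWarning):
        blocks = sy.decompose_synteny(random_seq(rng, 2000), plain_genome)
    assert blocks == []


def test_simulated_genesis_blocks_match_truth(study_sim, study_blocks):
    """Recovered blocks tile the numt in order and match truth source blocks
    with boundary error <= k."""
    truth = study_sim["truth"]
    blocks = study_blocks
    k = 31
    # tiling and order
    assert all(blocks[i].numt_interval[1] <= blocks[i + 1].numt_interval[0]
               for i in range(len(blocks) - 1))
    covered = sum(b.length() for b in blocks)
    assert covered >= 0.95 * len(study_sim["numt"])
    # every truth block boundary matched within k (repeat-conformation
    # junction boundaries are homology-ambiguous and checked by class below)
    truth_bounds = {b.numt_interval[0] for b in truth.source_blocks}
    conf_pos = {f.numt_pos for f in truth.fusion_points
                if f.klass == "repeat_conformation"}
    det_bounds = sorted({x for b in blocks for x in b.numt_interval})
    for tb in truth_bounds - conf_pos:
        assert min(abs(tb - d) for d in det_bounds) <= k


def test_strand_flip_reverses_blocks(study_sim, study_blocks):
    """Reverse-complementing the numt reverses block order and flips
    orientations; organelle intervals agree within junction ambiguity."""
    numt = study_sim["numt"]
    genome = study_sim["genome"]
    fwd = study_blocks
    rev = sy.decompose_synteny(revcomp(numt), genome)
    assert len(rev) == len(fwd)
    # blocks flanking a repeat-mediated junction are homology-ambiguous: the
    # flipped run may resolve the junction to the other repeat copy
    ambiguous = set()
    for bp in sy.classify_breakpoints(fwd, genome):
        if bp.klass == "repeat_mediated":
            ambiguous.update((bp.left_block, bp.right_block))
    tol = 31
    for i, (bf, br) in enumerate(zip(fwd, rev[::-1])):
        assert bf.orientation != br.orientation
        if i in ambiguous:
            continue
        assert abs(bf.numt_interval[0] - (len(numt) - br.numt_interval[1])) <= tol
        assert abs(bf.organelle_interval[0] - br.organelle_interval[0]) <= tol
        assert abs(bf.organelle_interval[1] - br.organelle_interval[1]) <= tol


# ---------------------------------------------------------------------------
# breakpoints
# ---------------------------------------------------------------------------

def test_single_block_has_no_breakpoints(plain_genome):
    numt = plain_genome.sequence[2000:12_000]
    blocks = sy.decompose_synteny(numt, plain_genome)
    assert sy.classify_breakpoints(blocks, plain_genome) == []


def test_overlapping_blocks_raise_structural_error(plain_genome):
    blocks = [sy.SyntenyBlock((0, 100), (0, 100), "+"),
              sy.SyntenyBlock((50, 150), (500, 600), "+")]
    with pytest.raises(sy.StructuralError):
        sy.classify_breakpoints(blocks, plain_genome)


def test_nhej_fusion_recovered_at_truth_position(plain_genome):
    """Fusing two non-adjacent fragments with no repeat at the junction gives
    one nhej breakpoint within tolerance of the truth position."""
    cfg = sg.SimConfig(genome_length=plain_genome.length, large_repeats=[],
                       small_repeats=[], seed=1, mutation_rate=0.001,
                       indel_rate=0.0)
    cfg.fragment_plan = [(1000, 6000, "+"), (12_000, 18_000, "+")]
    numt, truth = sg.simulate_numt_genesis(plain_genome, cfg)
    blocks = sy.decompose_synteny(numt, plain_genome)
    bps = sy.classify_breakpoints(blocks, plain_genome)
    assert len(bps) == 1
    assert bps[0].klass == "nhej"
    assert abs(bps[0].numt_position - truth.fusion_points[0].numt_pos) <= 31


def test_repeat_conformation_junction_classified_with_mediating_pair(study_sim,
                                                                     study_blocks):
    genome = study_sim["genome"]
    bps = sy.classify_breakpoints(study_blocks, genome)
    rep = [bp for bp in bps if bp.klass == "repeat_mediated"]
    assert len(rep) == 1
    assert rep[0].mediating_repeat == "R1"
    assert rep[0].mediating_copies == (1, 2)
    # position falls within the R1 copy homology (ambiguous by construction)
    truth_conf = next(f for f in study_sim["truth"].fusion_points
                      if f.klass == "repeat_conformation")
    r1 = genome.repeat("R1")
    assert rep[0].numt_position <= truth_conf.numt_pos
    assert truth_conf.numt_pos - rep[0].numt_position <= r1.length + 31


def test_breakpoint_recall_and_precision_on_five_simulations():
    """NHEJ junction recall/precision at boundary error <= k on a handful of
    random genesis configs (the full 20-simulation sweep runs with the
    acceptance properties)."""
    recall, precision, conf_rate = breakpoint_recovery(n_sims=5, seed0=100)
    assert recall >= 0.95 and precision >= 0.95
    assert conf_rate >= 0.8


# ---------------------------------------------------------------------------
# conformations
# ---------------------------------------------------------------------------

def _genome_with_pair(seed=2, L=30_000, rep=800):
    cfg = sg.SimConfig(genome_length=L, large_repeats=[(rep, 2)],
                       small_repeats=[], seed=seed)
    return sg.simulate_organelle_genome(cfg)


def test_parental_conformations_on_exact_copy():
    genome = _genome_with_pair()
    numt = genome.sequence  # full linear copy of the genome
    blocks = sy.decompose_synteny(numt, genome)
    conf = sy.detect_repeat_conformations(blocks, genome.repeat("R1"), genome)
    assert conf.present == {"A-B", "A'-B'"}


def test_all_four_conformations_detected_when_planted():
    genome = _genome_with_pair(seed=5)
    r1 = genome.repeat("R1")
    c1, c2 = r1.copy1, r1.copy2
    lo, hi = sorted([c1, c2])
    fl = 1000
    plan = [
        (c1[0] - fl, c1[1] + fl, "+"),   # A-B (parental, contains copy1)
        (c2[0] - fl, c2[1] + fl, "+"),   # A'-B' (parental)
        (c1[0] - fl, c1[1], "+"), (c2[1], c2[1] + fl, "+"),   # A-B'
        (c2[0] - fl, c2[1], "+"), (c1[1], c1[1] + fl, "+"),   # A'-B
    ]
    cfg = sg.SimConfig(genome_length=genome.length, large_repeats=[(800, 2)],
                       small_repeats=[], seed=5, mutation_rate=0.001,
                       indel_rate=0.0)
    cfg.fragment_plan = plan
    numt, truth = sg.simulate_numt_genesis(genome, cfg)
    blocks = sy.decompose_synteny(numt, genome)
    conf = sy.detect_repeat_conformations(blocks, r1, genome)
    assert conf.present == {"A-B", "A'-B'", "A-B'", "A'-B"}


def test_three_of_four_conformations(study_sim, study_blocks):
    """The study-structured genesis realizes the recombinant A-B' pairing;
    truth-derived conformations equal the detected set."""
    genome = study_sim["genome"]
    conf = sy.detect_repeat_conformations(study_blocks, genome.repeat("R1"), genome)
    assert "A-B'" in conf.present
    assert len(conf.present) <= 4
    # truth-side derivation: parental pairings from fragments containing a
    # copy, plus the planted recombinant junction
    r1 = genome.repeat("R1")
    expected = {"A-B'"}
    for s, e, orient in study_sim["config"].fragment_plan:
        for idx, (cs, ce) in enumerate(r1.copies(), start=1):
            for m in (0, genome.length):
                if s < cs + m and ce + m < e:
                    expected.add(("A-B", "A'-B'")[idx - 1])
    assert conf.present == expected


def test_unannotated_pair_raises():
    genome = _genome_with_pair()
    alien = sg.RepeatPair("Z", (0, 10), (100, 110))
    with pytest.raises(KeyError):
        sy.detect_repeat_conformations([], alien, genome)


# ---------------------------------------------------------------------------
# syntenic reference
# ---------------------------------------------------------------------------

def test_syntenic_reference_identity_and_revcomp(plain_genome):
    blocks = [sy.SyntenyBlock((0, 3000), (2000, 5000), "+"),
              sy.SyntenyBlock((3000, 4000), (10_000, 11_000), "-")]
    ref = sy.build_syntenic_reference(blocks, plain_genome)
    assert ref.sequence[:3000] == plain_genome.sequence[2000:5000]
    assert ref.sequence[3000:] == revcomp(plain_genome.sequence[10_000:11_000])
    assert len(ref.sequence) == 4000
    # offset round trip
    L = plain_genome.length
    pos, orient = ref.map_to_organelle(100, L)
    assert (pos, orient) == (2100, "+")
    pos, orient = ref.map_to_organelle(3000, L)
    assert (pos, orient) == (10_999, "-")
    assert plain_genome.sequence[pos] == revcomp(ref.sequence[3000])


def test_syntenic_reference_round_trip_on_variants(study_sim, study_blocks):
    """Variant positions mapped through the offset table land on the organelle
    base equal to the recorded organelle allele."""
    from numtscope import varspec as vs
    genome = study_sim["genome"]
    numt = study_sim["numt"]
    ref = sy.build_syntenic_reference(study_blocks, genome)
    # align numt portion of first block against its slice of the reference
    b = study_blocks[0]
    entry = ref.entries[0]
    sub_ref = ref.sequence[entry["out_start"]:entry["out_end"]]
    aln = vs.align_block(numt[b.numt_interval[0]:b.numt_interval[1]], sub_ref)
    for v in vs.call_variants(aln):
        if v.vtype != "snv":
            continue
        org_pos, orient = ref.map_to_organelle(entry["out_start"] + v.organelle_pos,
                                               genome.length)
        base = genome.sequence[org_pos]
        expect = v.ref_allele if orient == "+" else revcomp(v.ref_allele)
        assert base == expect


def test_empty_block_list_gives_empty_reference(plain_genome):
    ref = sy.build_syntenic_reference([], plain_genome)
    assert ref.sequence == "" and ref.entries == []


# ---------------------------------------------------------------------------
# identical regions
# ---------------------------------------------------------------------------

def test_no_long_match_between_random_sequences():
    rng = np.random.default_rng(3)
    a, b = random_seq(rng, 10_000), random_seq(rng, 10_000)
    assert sy.find_identical_regions(a, b, 7000) == []


def test_planted_repeat_found_exactly():
    rng = np.random.default_rng(4)
    bg = random_seq(rng, 30_000)
    unit = random_seq(rng, 8000)
    seq = bg[:5000] + unit + bg[5000:10_000] + unit + bg[10_000:]
    hits = sy.find_identical_regions(seq, seq, 7000)
    assert len(hits) == 1
    h = hits[0]
    assert h.a_interval == (5000, 13_000)
    assert h.b_interval == (18_000, 26_000)
    assert h.orientation == "+"


def test_internal_mismatch_splits_maximal_match():
    """One mismatch inside an 8-kb repeat: no single >=8 kb match; the two
    flanking maximal matches sum to 8 kb - 1."""
    rng = np.random.default_rng(6)
    bg = random_seq(rng, 26_000)
    unit = random_seq(rng, 8000)
    unit2 = list(unit)
    unit2[4000] = {"A": "C", "C": "G", "G": "T", "T": "A"}[unit2[4000]]
    seq = bg[:3000] + unit + bg[3000:6000] + "".join(unit2) + bg[6000:]
    assert sy.find_identical_regions(seq, seq, 7000) == []
    hits = sy.find_identical_regions(seq, seq, 3000)
    assert len(hits) == 2
    assert sum(h.length for h in hits) == 8000 - 1


def test_reverse_orientation_match_detected():
    rng = np.random.default_rng(8)
    a = random_seq(rng, 9000)
    b = random_seq(rng, 2000) + revcomp(a[1000:5000]) + random_seq(rng, 2000)
    hits = sy.find_identical_regions(a, b, 3500)
    assert len(hits) == 1
    assert hits[0].orientation == "-"
    assert hits[0].a_interval == (1000, 5000)
    assert hits[0].b_interval == (2000, 6000)
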