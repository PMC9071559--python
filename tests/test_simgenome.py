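"""Genesis simulator: determinism, spectrum realization, epochs, reads."""

import numpy as np
import pytest
from scipy import stats

from numtscope import simgenome as sg
from tests.conftest import make_genesis


# ---------------------------------------------------------------------------
# organelle genome
# ---------------------------------------------------------------------------

def test_genome_length_is_forced():
    cfg = sg.SimConfig(genome_length=10_000, large_repeats=[], small_repeats=[],
                       seed=7)
    genome = sg.simulate_organelle_genome(cfg)
    assert genome.length == 10_000


def test_default_config_plants_study_sized_repeats():
    genome = sg.simulate_organelle_genome(sg.SimConfig(seed=1))
    sizes = {rp.name: rp.length for rp in genome.repeat_pairs}
    assert sizes["R1"] == 6000 and sizes["R2"] == 4200
    assert sizes["C"] == 457 and sizes["Q"] == 206
    # copies are planted identical
    for rp in genome.repeat_pairs:
        assert (genome.sequence[rp.copy1[0]:rp.copy1[1]]
                == genome.sequence[rp.copy2[0]:rp.copy2[1]])


def test_gc_fraction_within_binomial_bounds():
    n = 100_000
    cfg = sg.SimConfig(genome_length=n, gc_fraction=0.45, large_repeats=[],
                       small_repeats=[], seed=5)
    genome = sg.simulate_organelle_genome(cfg)
    from numtscope._seq import gc_fraction
    sd = np.sqrt(0.45 * 0.55 / n)
    assert abs(gc_fraction(genome.sequence) - 0.45) < 3 * sd


def test_repeat_placement_error_names_the_pair():
    cfg = sg.SimConfig(genome_length=2000, large_repeats=[(450, 2), (450, 2)],
                       small_repeats=[(400, 2)], seed=0)
    with pytest.raises(sg.PlacementError):
        sg.simulate_organelle_genome(cfg)


def test_invalid_configs_rejected():
    with pytest.raises(sg.ConfigurationError):
        sg.SimConfig(genome_length=0).validate()
    with pytest.raises(sg.ConfigurationError):
        sg.SimConfig(large_repeats=[(100_000, 2)]).validate()
    with pytest.raises(sg.ConfigurationError):
        sg.SimConfig(spectrum_weights={c: 0.0 for c in sg.SPECTRUM_CATEGORIES}).validate()


# ---------------------------------------------------------------------------
# genesis
# ---------------------------------------------------------------------------

def test_zero_mutation_rate_gives_exact_fragment_concatenation():
    cfg = sg.SimConfig(genome_length=20_000, large_repeats=[], small_repeats=[],
                       seed=2, mutation_rate=0.0, indel_rate=0.0)
    genome = sg.simulate_organelle_genome(cfg)
    cfg.fragment_plan = [(1000, 5000, "+"), (19_000, 21_000, "+"), (8000, 9000, "-")]
    numt, truth = sg.simulate_numt_genesis(genome, cfg)
    from numtscope._seq import revcomp
    expect = (genome.sequence[1000:5000]
              + genome.sequence[19_000:] + genome.sequence[:1000]
              + revcomp(genome.sequence[8000:9000]))
    assert numt == expect
    assert truth.planted_variants == []
    assert [b.numt_interval for b in truth.source_blocks] == [
        (0, 4000), (4000, 6000), (6000, 7000)]


def test_determinism_byte_identical():
    g1, c1, n1, t1 = make_genesis(seed=13, indel_rate=1e-4)
    g2, c2, n2, t2 = make_genesis(seed=13, indel_rate=1e-4)
    assert g1.sequence == g2.sequence
    assert n1 == n2
    assert t1.to_json() == t2.to_json()
    sites = [(v.numt_pos, v.alt, v.ref) for v in t1.planted_variants]
    r1 = sg.simulate_reads(n1, g1, sites, sg.ReadConfig(n_reads=30, read_length=5000, seed=4))
    r2 = sg.simulate_reads(n2, g2, sites, sg.ReadConfig(n_reads=30, read_length=5000, seed=4))
    assert r1 == r2


def test_substitution_count_matches_poisson_expectation():
    cfg = sg.SimConfig(genome_length=200_000, large_repeats=[], small_repeats=[],
                       seed=3, mutation_rate=0.005, indel_rate=0.0)
    genome = sg.simulate_organelle_genome(cfg)
    cfg.fragment_plan = [(0, 200_000, "+")]
    _numt, truth = sg.simulate_numt_genesis(genome, cfg)
    expected = 0.005 * 200_000
    assert abs(len(truth.planted_variants) - expected) < 4 * np.sqrt(expected)


def test_at_bias_ratio_realized():
    """With the transition-dominated default weights (no context boost) the
    realized GC->AT : AT->GC ratio matches 6.7:1 within sampling error."""
    cfg = sg.SimConfig(genome_length=400_000, large_repeats=[], small_repeats=[],
                       seed=9, mutation_rate=0.025, indel_rate=0.0,
                       context_multipliers={"CpG": 1.0, "CHG": 1.0, "CHH": 1.0})
    genome = sg.simulate_organelle_genome(cfg)
    cfg.fragment_plan = [(0, 400_000, "+")]
    _numt, truth = sg.simulate_numt_genesis(genome, cfg)
    from numtscope.varspec import classify_spectrum
    n_gcat = n_atgc = 0
    for v in truth.planted_variants:
        cat, ts = classify_spectrum(v.ref, v.alt)
        if cat == "GC<>AT":
            n_gcat += 1
        elif cat == "AT<>GC":
            n_atgc += 1
    assert n_gcat + n_atgc >= 5000
    # binomial CI on the GC<>AT share of transitions
    share = n_gcat / (n_gcat + n_atgc)
    expect = 235 / 270
    sd = np.sqrt(expect * (1 - expect) / (n_gcat + n_atgc))
    assert abs(share - expect) < 4 * sd
    assert n_gcat / n_atgc == pytest.approx(6.7, rel=0.15)


def test_spectrum_chi2_goodness_of_fit():
    """Realized category counts fit the configured weights (chi-square GOF
    non-significant at alpha=0.001 with >=10,000 events; AT/GC site
    availability is accounted for by an even-composition genome)."""
    weights = dict(sg.DEFAULT_SPECTRUM_WEIGHTS)
    cfg = sg.SimConfig(genome_length=500_000, gc_fraction=0.5,
                       large_repeats=[], small_repeats=[], seed=17,
                       mutation_rate=0.025, indel_rate=0.0,
                       spectrum_weights=weights,
                       context_multipliers={"CpG": 1.0, "CHG": 1.0, "CHH": 1.0})
    genome = sg.simulate_organelle_genome(cfg)
    cfg.fragment_plan = [(0, 500_000, "+")]
    _numt, truth = sg.simulate_numt_genesis(genome, cfg)
    from numtscope.varspec import classify_spectrum
    from collections import Counter
    counts = Counter(classify_spectrum(v.ref, v.alt)[0]
                     for v in truth.planted_variants)
    n = sum(counts.values())
    assert n >= 10_000
    # category rates are normalised per available site class, so realized
    # proportions follow the configured weights directly
    w = np.array([weights[c] for c in sg.SPECTRUM_CATEGORIES])
    probs = w / w.sum()
    obs = np.array([counts.get(c, 0) for c in sg.SPECTRUM_CATEGORIES])
    chi2, p = stats.chisquare(obs, f_exp=probs * n)
    assert p > 0.001


def test_epoch_semantics_on_truth_and_sequence():
    """Pre-duplication variants appear at both homologous positions of the
    duplicated interval; post-duplication variants do not."""
    from tests.conftest import three_copy_genesis
    genome, cfg, numt, truth = three_copy_genesis(seed=23, mutation_rate=0.002,
                                                  post_dup=True)
    dup = truth.duplication
    D = dup.interval[1] - dup.interval[0]
    assert dup.second_copy == (dup.interval[1], dup.interval[1] + D)
    # every planted variant is realized in the sequence
    for v in truth.planted_variants:
        assert numt[v.numt_pos] == v.alt
    pre_in = [v for v in truth.planted_variants if v.epoch == "pre_duplication"
              and dup.interval[0] <= v.numt_pos < dup.interval[1]]
    assert pre_in, "expected pre-duplication variants inside the interval"
    pre_pos = {v.numt_pos for v in truth.planted_variants
               if v.epoch == "pre_duplication"}
    for v in pre_in:
        assert v.numt_pos + D in pre_pos
        assert numt[v.numt_pos + D] == v.alt
    post_in = [v for v in truth.planted_variants if v.epoch == "post_duplication"
               and dup.interval[0] <= v.numt_pos < dup.interval[1]]
    assert post_in
    for v in post_in:
        assert numt[v.numt_pos + D] != v.alt


def test_length_conservation_with_indels():
    cfg = sg.SimConfig(genome_length=30_000, large_repeats=[], small_repeats=[],
                       seed=29, mutation_rate=0.001, indel_rate=5e-4)
    genome = sg.simulate_organelle_genome(cfg)
    cfg.fragment_plan = [(2000, 12_000, "+"), (15_000, 25_000, "-")]
    numt, truth = sg.simulate_numt_genesis(genome, cfg)
    frag_total = 20_000
    delta = sum(e.length for e in truth.indel_events)
    assert truth.indel_events, "expected indel events at this rate"
    assert len(numt) == frag_total + delta
    # blocks still tile the final numt
    cur = 0
    for blk in truth.source_blocks:
        assert blk.numt_interval[0] == cur
        cur = blk.numt_interval[1]
    assert cur == len(numt)


def test_deletion_bias_realized():
    cfg = sg.SimConfig(genome_length=100_000, large_repeats=[], small_repeats=[],
                       seed=37, mutation_rate=0.0, indel_rate=2e-3,
                       deletion_bias=30 / 44)
    genome = sg.simulate_organelle_genome(cfg)
    cfg.fragment_plan = [(0, 100_000, "+")]
    _numt, truth = sg.simulate_numt_genesis(genome, cfg)
    dels = sum(1 for e in truth.indel_events if e.length < 0)
    n = len(truth.indel_events)
    assert n > 50
    sd = np.sqrt(n * (30 / 44) * (14 / 44))
    assert abs(dels - n * 30 / 44) < 4 * sd


def test_conversion_tract_copies_donor_into_acceptor():
    cfg = sg.SimConfig(genome_length=20_000, large_repeats=[], small_repeats=[],
                       seed=41, mutation_rate=0.01, indel_rate=0.0)
    genome = sg.simulate_organelle_genome(cfg)
    cfg.fragment_plan = [(0, 8000, "+"), (0, 8000, "+")]
    cfg.conversion_tracts = [sg.ConversionTract(1000, 9000, 500)]
    numt, truth = sg.simulate_numt_genesis(genome, cfg)
    assert numt[1000:1500] == numt[9000:9500]
    assert truth.conversion_events == cfg.conversion_tracts


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _sim_with_sites(seed=43):
    genome, cfg, numt, truth = make_genesis(seed=seed)
    sites = [(p, a, r) for p, _o, r, a in truth.final_variant_sites()]
    return genome, numt, sites


def test_error_free_numt_reads_carry_numt_alleles():
    genome, numt, sites = _sim_with_sites()
    rc = sg.ReadConfig(n_reads=60, read_length=8000, numt_fraction=1.0,
                       allele_error=0.0, seed=1)
    reads = sg.simulate_reads(numt, genome, sites, rc)
    site_map = dict((p, (na, oa)) for p, na, oa in sites)
    for r in reads.reads:
        assert r.source == "numt"
        for pos, allele in r.alleles.items():
            assert allele == site_map[pos][0]


def test_organelle_reads_unmethylated_when_rate_zero():
    genome, numt, sites = _sim_with_sites()
    rc = sg.ReadConfig(n_reads=40, read_length=6000, numt_fraction=0.0,
                       organelle_meth_rate=0.0, seed=2)
    reads = sg.simulate_reads(numt, genome, sites, rc)
    for r in reads.reads:
        assert r.source == "organelle"
        assert all(m == 0 for _p, _c, m in r.meth_calls)


def test_allele_error_rate_within_binomial_bounds():
    genome, numt, sites = _sim_with_sites()
    err = 0.05
    rc = sg.ReadConfig(n_reads=400, read_length=8000, numt_fraction=1.0,
                       allele_error=err, seed=3)
    reads = sg.simulate_reads(numt, genome, sites, rc)
    site_map = dict((p, (na, oa)) for p, na, oa in sites)
    n = disc = 0
    for r in reads.reads:
        for pos, allele in r.alleles.items():
            n += 1
            disc += allele != site_map[pos][0]
    assert n > 200
    sd = np.sqrt(n * err * (1 - err))
    assert abs(disc - n * err) < 4 * sd


def test_read_length_longer_than_source_rejected():
    genome, numt, sites = _sim_with_sites()
    with pytest.raises(sg.ConfigurationError):
        sg.simulate_reads(numt, genome, sites,
                          sg.ReadConfig(read_length=10**7))
    with pytest.raises(sg.ConfigurationError):
        sg.simulate_reads(numt, genome, [], sg.ReadConfig(read_length=100))
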