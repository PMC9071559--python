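"""Shared fixtures: seeded simulations reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from numtscope import simgenome as sg
from numtscope import synteny as sy


def make_genesis(seed: int, scale: float = 0.15, mutation_rate: float = 0.003,
                 indel_rate: float = 0.0):
    """Study-structured genesis at reduced scale with known truth."""
    cfg = sg.study_config(seed=seed, scale=scale, mutation_rate=mutation_rate,
                          indel_rate=indel_rate)
    genome = sg.simulate_organelle_genome(cfg)
    cfg = sg.study_fragment_plan(genome, cfg)
    numt, truth = sg.simulate_numt_genesis(genome, cfg)
    return genome, cfg, numt, truth


def three_copy_genesis(seed: int, mutation_rate: float, post_dup: bool,
                       genome_length: int = 40_000, seg: int = 15_000,
                       flank: int = 4_000, time_fraction: float = 0.5,
                       conversion: bool = False):
    """A genesis whose focal segment ends up in three numt copies.

    ``post_dup=True``: the segment is transferred twice and one occurrence is
    tandem-duplicated after ``time_fraction`` of the divergence time (two
    daughters share derived variants). ``post_dup=False``: three copies are
    transferred at insertion (star phylogeny). ``conversion`` overlays a
    2-kb gene-conversion tract between two copies of the star case.
    """
    cfg = sg.SimConfig(genome_length=genome_length, seed=seed,
                       large_repeats=[], small_repeats=[],
                       mutation_rate=mutation_rate, indel_rate=0.0)
    genome = sg.simulate_organelle_genome(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9]))
    s0 = int(rng.integers(0, genome_length - seg - 2 * flank - 200))
    seg_iv = (s0, s0 + seg)
    fa = (s0 + seg + 100, s0 + seg + 100 + flank)
    fb = (fa[1] + 100, fa[1] + 100 + flank)
    if post_dup:
        plan = [(fa[0], fa[1], "+"), (seg_iv[0], seg_iv[1], "+"),
                (fb[0], fb[1], "+"), (seg_iv[0], seg_iv[1], "+")]
        d_lo = flank + seg + flank
        cfg.fragment_plan = plan
        cfg.duplication = sg.Duplication((d_lo, d_lo + seg), time_fraction)
    else:
        plan = [(fa[0], fa[1], "+"), (seg_iv[0], seg_iv[1], "+"),
                (fb[0], fb[1], "+"), (seg_iv[0], seg_iv[1], "+"),
                (fa[0], fa[1], "-"), (seg_iv[0], seg_iv[1], "+")]
        cfg.fragment_plan = plan
        if conversion:
            # homologous 2-kb tract: copy 1 donates into copy 2
            c1 = flank + 1000
            c2 = flank + seg + flank + 1000
            cfg.conversion_tracts = [sg.ConversionTract(c1, c2, 2000)]
    numt, truth = sg.simulate_numt_genesis(genome, cfg)
    return genome, cfg, numt, truth


def truth_junctions(truth: sg.NumtTruth) -> list[tuple[int, str]]:
    """All expected junction positions: insertion fusions plus the tandem
    duplication breakpoint (which presents as an NHEJ-like organelle jump)."""
    out = [(f.numt_pos, f.klass) for f in truth.fusion_points]
    if truth.duplication is not None:
        out.append((truth.duplication.breakpoint, "nhej"))
    return sorted(out)


def breakpoint_recovery(n_sims: int = 20, seed0: int = 100, k: int = 31):
    """NHEJ-junction recall/precision and repeat-junction detection rate over
    study-structured genesis simulations (divergence 0.3%)."""
    tp = fn = fp = 0
    conf_found = 0
    for i in range(n_sims):
        genome, cfg, numt, truth = make_genesis(seed=seed0 + i,
                                                mutation_rate=0.003)
        blocks = sy.decompose_synteny(numt, genome)
        bps = sy.classify_breakpoints(blocks, genome)
        truth_nhej = [p for p, kl in truth_junctions(truth) if kl == "nhej"]
        det = [bp.numt_position for bp in bps if bp.klass != "repeat_mediated"]
        for t in truth_nhej:
            if det and min(abs(t - d) for d in det) <= k:
                tp += 1
            else:
                fn += 1
        for d in det:
            if not truth_nhej or min(abs(t - d) for t in truth_nhej) > k:
                fp += 1
        if any(bp.klass == "repeat_mediated" and bp.mediating_repeat == "R1"
               for bp in bps):
            conf_found += 1
    return tp / (tp + fn), tp / (tp + fp), conf_found / n_sims


@pytest.fixture(scope="session")
def study_sim():
    """One study-structured genesis shared by structural tests."""
    genome, cfg, numt, truth = make_genesis(seed=3)
    return {"genome": genome, "config": cfg, "numt": numt, "truth": truth}


@pytest.fixture(scope="session")
def study_blocks(study_sim):
    return sy.decompose_synteny(study_sim["numt"], study_sim["genome"])


@pytest.fixture(scope="session")
def plain_genome():
    """A repeat-free random organelle genome."""
    cfg = sg.SimConfig(genome_length=20_000, large_repeats=[], small_repeats=[],
                       seed=11)
    return sg.simulate_organelle_genome(cfg)
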