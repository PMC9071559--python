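"""Synthetic numt genesis with machine-readable ground truth.

Emulates the process by which a large numt arises: a circular organelle
genome carrying large and small repeat pairs; fusion of several organelle
fragments (non-homologous end joining and alternative repeat conformations);
nuclear mutation accumulation with a GC→AT transition bias elevated at
methylated cytosine contexts (CpG/CHG); an optional post-divergence tandem
duplication splitting mutational time into pre-/post-duplication epochs;
optional gene-conversion tracts; and long reads drawn from both the numt and
the organelle genome with distinct methylation states.

Every stochastic draw flows from a single seeded generator, so identical
configs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seq import A, C, G, T, decode, encode, random_seq, revcomp

# Strand-collapsed substitution categories, direction organelle -> numt.
SPECTRUM_CATEGORIES = ("GC<>AT", "AT<>GC", "GC<>TA", "AT<>CG", "GC<>CG", "AT<>TA")

# Relative rates emulating the observed numt divergence spectrum
# (transition-dominated, strong GC->AT excess).
DEFAULT_SPECTRUM_WEIGHTS = {
    "GC<>AT": 235.0,
    "AT<>GC": 35.0,
    "GC<>TA": 58.0,
    "AT<>CG": 30.0,
    "GC<>CG": 42.0,
    "AT<>TA": 25.0,
}

# C->T rate multipliers by cytosine context; 5mC deamination elevates CpG and
# CHG. 5.8 reproduces a ~74.5% CpG+CHG share of C->T events over a background
# in which ~1/3 of cytosines sit in CpG or CHG context.
DEFAULT_CONTEXT_MULTIPLIERS = {"CpG": 5.8, "CHG": 5.8, "CHH": 1.0}


class PlacementError(RuntimeError):
    """Repeat pair could not be placed without overlap."""


def _circ_overlap(a: tuple[int, int], b: tuple[int, int], L: int,
                  margin: int = 0) -> bool:
    """Overlap of circular intervals given as (start in [0,L), start+len)."""
    def segs(iv):
        s, e = iv[0] - margin, iv[1] + margin
        if e - s >= L:
            return [(0, L)]
        s %= L
        e = s + (iv[1] - iv[0]) + 2 * margin
        if e <= L:
            return [(s, e)]
        return [(s, L), (0, e - L)]
    return any(s1 < e2 and s2 < e1 for s1, e1 in segs(a) for s2, e2 in segs(b))


class ConfigurationError(ValueError):
    """Simulation configuration violates an invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatPair:
    """Two identical copies of a repeat on the (circular) organelle genome.

    Intervals are 0-based half-open in linear coordinates (no origin wrap).
    """

    name: str
    copy1: tuple[int, int]
    copy2: tuple[int, int]

    @property
    def length(self) -> int:
        return self.copy1[1] - self.copy1[0]

    def copies(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.copy1, self.copy2)

    def __post_init__(self):
        if (self.copy1[1] - self.copy1[0]) != (self.copy2[1] - self.copy2[0]):
            raise ConfigurationError(f"repeat {self.name}: copies differ in length")
        a, b = sorted([self.copy1, self.copy2])
        if a[1] > b[0]:
            raise ConfigurationError(f"repeat {self.name}: copies overlap")


@dataclass
class OrganelleGenome:
    """Circular organelle reference with annotated repeat pairs."""

    sequence: str
    repeat_pairs: list[RepeatPair] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Circular slice; ``end`` may exceed the length (wraps the origin)."""
        L = self.length
        if not 0 <= start < L:
            start %= L
            end = start + (end - start)
        if end - start > L:
            raise ValueError("slice longer than the genome")
        if end <= L:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[: end - L]

    def base(self, pos: int) -> str:
        return self.sequence[pos % self.length]

    def repeat(self, name: str) -> RepeatPair:
        for rp in self.repeat_pairs:
            if rp.name == name:
                return rp
        raise KeyError(f"repeat pair {name!r} not annotated on the genome")


@dataclass(frozen=True)
class Duplication:
    """Tandem duplication of ``interval`` on the fused numt; ``time_fraction``
    is the fraction of total mutational time elapsed before the duplication."""

    interval: tuple[int, int]
    time_fraction: float = 0.5


@dataclass(frozen=True)
class ConversionTract:
    """Non-reciprocal copy of ``length`` bases from ``donor_start`` to
    ``acceptor_start`` (both numt coordinates of homologous copies)."""

    donor_start: int
    acceptor_start: int
    length: int


@dataclass
class SimConfig:
    """Knobs of the genesis model.

    Defaults are the study conditions: a 368-kb circular organelle genome at
    GC 0.45 with two large repeat pairs (6.0 and 4.2 kb) and two small pairs
    (457 and 206 bp), a transition-dominated spectrum with 6.7:1 GC->AT bias,
    CpG/CHG-elevated C->T rates, ~0.067% substitution divergence, and a
    deletion-biased low indel rate.
    """

    genome_length: int = 368_000
    gc_fraction: float = 0.45
    large_repeats: list[tuple[int, int]] = field(
        default_factory=lambda: [(6000, 2), (4200, 2)])
    small_repeats: list[tuple[int, int]] = field(
        default_factory=lambda: [(457, 2), (206, 2)])
    seed: int = 0
    fragment_plan: list[tuple[int, int, str]] | None = None
    mutation_rate: float = 6.7e-4
    spectrum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM_WEIGHTS))
    context_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_MULTIPLIERS))
    duplication: Duplication | None = None
    conversion_tracts: list[ConversionTract] | None = None
    indel_rate: float = 7e-5  # ~44 indels over a 630-kb comparison
    deletion_bias: float = 30 / 44

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ConfigurationError("genome_length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ConfigurationError("gc_fraction must lie in [0,1]")
        for length, count in self.large_repeats + self.small_repeats:
            if length <= 0:
                raise ConfigurationError("repeat lengths must be positive")
            if count != 2:
                raise ConfigurationError("repeat pairs must have count 2")
            if length >= self.genome_length / 4:
                raise ConfigurationError(
                    f"repeat length {length} must be < genome_length/4")
        if self.mutation_rate < 0 or self.indel_rate < 0:
            raise ConfigurationError("rates must be nonnegative")
        if not 0.0 <= self.deletion_bias <= 1.0:
            raise ConfigurationError("deletion_bias must lie in [0,1]")
        ws = [self.spectrum_weights.get(c, 0.0) for c in SPECTRUM_CATEGORIES]
        if any(w < 0 for w in ws) or not any(w > 0 for w in ws):
            raise ConfigurationError(
                "spectrum_weights must be nonnegative and not all zero")
        if self.duplication is not None:
            if not 0.0 <= self.duplication.time_fraction <= 1.0:
                raise ConfigurationError("time_fraction must lie in [0,1]")


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass
class SourceBlock:
    numt_interval: tuple[int, int]
    organelle_interval: tuple[int, int]  # linear start, start+len (may exceed L: wraps)
    orientation: str  # '+' or '-'


@dataclass
class FusionPoint:
    numt_pos: int
    klass: str  # 'nhej' | 'repeat_conformation'
    mediating_repeat: str | None = None


@dataclass
class PlantedVariant:
    numt_pos: int
    organelle_pos: int
    ref: str  # ancestral (organelle-derived) base in numt forward frame
    alt: str
    epoch: str  # 'pre_duplication' | 'post_duplication'


@dataclass
class RealizedDuplication:
    interval: tuple[int, int]        # first daughter copy on the final numt
    second_copy: tuple[int, int]     # second daughter copy
    breakpoint: int                  # junction between the daughters
    time_fraction: float


@dataclass
class IndelEvent:
    numt_pos: int
    length: int   # positive = insertion, negative = deletion
    seq: str      # inserted or deleted bases


@dataclass
class NumtTruth:
    """Ground truth of a simulated genesis; coordinates are on the final numt."""

    source_blocks: list[SourceBlock] = field(default_factory=list)
    fusion_points: list[FusionPoint] = field(default_factory=list)
    planted_variants: list[PlantedVariant] = field(default_factory=list)
    duplication: RealizedDuplication | None = None
    conversion_events: list[ConversionTract] = field(default_factory=list)
    indel_events: list[IndelEvent] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @property
    def substitutions(self) -> list[PlantedVariant]:
        return self.planted_variants

    def final_variant_sites(self) -> list[tuple[int, int, str, str]]:
        """Net substitution per numt position after chaining repeat hits:
        ``(numt_pos, organelle_pos, ancestral_ref, final_alt)``, positions
        where the chain returned to the ancestral base dropped. Conversion
        tracts and indels are not reflected here."""
        by_pos: dict[int, tuple[int, str, str]] = {}
        for v in self.planted_variants:  # chronological within each epoch
            if v.numt_pos in by_pos:
                opos, ref0, _alt = by_pos[v.numt_pos]
                by_pos[v.numt_pos] = (opos, ref0, v.alt)
            else:
                by_pos[v.numt_pos] = (v.organelle_pos, v.ref, v.alt)
        return [(p, o, r, a) for p, (o, r, a) in sorted(by_pos.items()) if r != a]


# ---------------------------------------------------------------------------
# organelle genome simulation
# ---------------------------------------------------------------------------

def simulate_organelle_genome(config: SimConfig) -> OrganelleGenome:
    """Draw an i.i.d. circular genome and plant the configured repeat pairs.

    Each pair is two identical copies at uniformly chosen non-overlapping
    positions (no origin wrap); large pairs are named R1, R2, ..., small
    pairs C, Q, S3, ... . Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    seq = np.frombuffer(
        random_seq(rng, config.genome_length, config.gc_fraction).encode(), np.uint8
    ).copy()
    L = config.genome_length

    large_names = [f"R{i + 1}" for i in range(len(config.large_repeats))]
    small_names = (["C", "Q"] + [f"S{i + 1}" for i in range(2, len(config.small_repeats))])[
        : len(config.small_repeats)]
    specs = (
        [(n, length) for n, (length, _c) in zip(large_names, config.large_repeats)]
        + [(n, length) for n, (length, _c) in zip(small_names, config.small_repeats)]
    )
    placed: list[tuple[int, int]] = []
    pairs: list[RepeatPair] = []

    def overlaps(s: int, e: int) -> bool:
        return any(s < pe and ps < e for ps, pe in placed)

    for name, length in sorted(specs, key=lambda x: -x[1]):
        copies = []
        for _copy in range(2):
            for _try in range(2000):
                s = int(rng.integers(0, L - length))
                if not overlaps(s, s + length):
                    copies.append((s, s + length))
                    placed.append((s, s + length))
                    break
            else:
                raise PlacementError(
                    f"could not place repeat pair {name} (length {length})")
        c1, c2 = sorted(copies)
        seq[c2[0]:c2[1]] = seq[c1[0]:c1[1]]
        pairs.append(RepeatPair(name, c1, c2))

    order = {n: i for i, (n, _l) in enumerate(specs)}
    pairs.sort(key=lambda p: order[p.name])
    return OrganelleGenome(seq.tobytes().decode(), pairs)


# ---------------------------------------------------------------------------
# mutation machinery
# ---------------------------------------------------------------------------

# For each ref code, the three alt codes and their strand-collapsed categories.
_ALTS = {
    A: [(G, "AT<>GC"), (C, "AT<>CG"), (T, "AT<>TA")],
    T: [(C, "AT<>GC"), (G, "AT<>CG"), (A, "AT<>TA")],
    G: [(A, "GC<>AT"), (T, "GC<>TA"), (C, "GC<>CG")],
    C: [(T, "GC<>AT"), (A, "GC<>TA"), (G, "GC<>CG")],
}


def _context_codes(codes: np.ndarray) -> np.ndarray:
    """Cytosine-context code per site (0=CpG, 1=CHG, 2=CHH) on the strand where
    the site reads C; arbitrary (CHH) for non-C/G sites and sequence edges."""
    n = codes.shape[0]
    ctx = np.full(n, 2, dtype=np.uint8)
    nxt1 = np.roll(codes, -1)
    nxt2 = np.roll(codes, -2)
    prv1 = np.roll(codes, 1)
    prv2 = np.roll(codes, 2)
    cmask = codes == C
    gmask = codes == G
    ctx[cmask & (nxt1 == G)] = 0
    ctx[cmask & (nxt1 != G) & (nxt2 == G)] = 1
    ctx[gmask & (prv1 == C)] = 0
    ctx[gmask & (prv1 != C) & (prv2 == C)] = 1
    # np.roll makes the window circular; on the (linear) numt this only
    # affects the two terminal sites at each end, a negligible artifact.
    return ctx


def _mutate(codes: np.ndarray, rate: float, config: SimConfig,
            rng: np.random.Generator) -> list[tuple[int, int, int]]:
    """Apply one epoch of substitutions in place.

    ``spectrum_weights`` are relative *category* rates: the per-site weight of
    an alt is its category weight divided by the number of available sites of
    that strand class (GC or AT), so realized category proportions follow the
    configured weights regardless of base composition. The C->T / G->A
    direction is additionally multiplied by the context multiplier. Per-site
    probabilities are normalised so their mean equals ``rate``. Returns
    ``(pos, ref_code, alt_code)`` triples.
    """
    if rate <= 0 or codes.size == 0:
        return []
    w = np.array([config.spectrum_weights.get(c, 0.0) for c in SPECTRUM_CATEGORIES])
    wmap = dict(zip(SPECTRUM_CATEGORIES, w))
    ctx = _context_codes(codes)
    mult = np.array([config.context_multipliers.get(k, 1.0)
                     for k in ("CpG", "CHG", "CHH")])
    n_gc = int(((codes == C) | (codes == G)).sum())
    n_at = int(((codes == A) | (codes == T)).sum())
    class_n = {A: n_at, T: n_at, C: n_gc, G: n_gc}
    # per-site 3-alt weights
    alt_codes = np.zeros((codes.size, 3), dtype=np.uint8)
    alt_w = np.zeros((codes.size, 3))
    for ref_code, alts in _ALTS.items():
        mask = codes == ref_code
        if not mask.any() or class_n[ref_code] == 0:
            continue
        for k, (alt, cat) in enumerate(alts):
            alt_codes[mask, k] = alt
            aw = np.full(mask.sum(), wmap[cat] / class_n[ref_code])
            if cat == "GC<>AT":  # the C->T (equivalently G->A) direction
                aw = aw * mult[ctx[mask]]
            alt_w[mask, k] = aw
    total = alt_w.sum(axis=1)
    mean_w = total.mean()
    if mean_w <= 0:
        return []
    p = np.minimum(rate * total / mean_w, 0.75)
    hit = np.flatnonzero(rng.random(codes.size) < p)
    out = []
    if hit.size:
        cw = np.cumsum(alt_w[hit], axis=1)
        u = rng.random(hit.size) * cw[:, -1]
        pick = (u[:, None] >= cw).sum(axis=1)
        for pos, k in zip(hit, pick):
            ref = int(codes[pos])
            alt = int(alt_codes[pos, k])
            codes[pos] = alt
            out.append((int(pos), ref, alt))
    return out


# ---------------------------------------------------------------------------
# genesis
# ---------------------------------------------------------------------------

def _fragment_class(genome: OrganelleGenome, left_end: int, right_start: int,
                    tol: int = 2) -> tuple[str, str | None]:
    """Truth label for a fusion: repeat_conformation when the junction switches
    between homologous offsets of two copies of an annotated pair."""
    L = genome.length
    for rp in genome.repeat_pairs:
        for ci, cj in ((rp.copy1, rp.copy2), (rp.copy2, rp.copy1)):
            off_l = (left_end - ci[0]) % L
            off_r = (right_start - cj[0]) % L
            if off_l <= rp.length + tol and off_r <= rp.length + tol:
                if abs(off_l - off_r) <= tol:
                    return "repeat_conformation", rp.name
    return "nhej", None


def simulate_numt_genesis(genome: OrganelleGenome,
                          config: SimConfig) -> tuple[str, NumtTruth]:
    """Fuse the planned organelle fragments and evolve the insertion.

    Substitutions are drawn per ``spectrum_weights`` x ``context_multipliers``;
    if a duplication is configured, mutational time is split at
    ``time_fraction`` and pre-duplication variants inside the duplicated
    interval are carried into both daughter copies. Gene-conversion tracts and
    length-geometric indels (deletion-biased) are applied last.
    """
    config.validate()
    if not config.fragment_plan:
        raise ConfigurationError("fragment_plan is required for genesis")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    L = genome.length
    truth = NumtTruth()

    parts: list[np.ndarray] = []
    org_pos_parts: list[np.ndarray] = []
    cursor = 0
    frag_ends: list[int] = []
    frag_bounds: list[tuple[int, int]] = []  # organelle (left_end, right_start) per junction
    prev_end = None
    for start, end, orient in config.fragment_plan:
        length = (end - start) % L
        if length == 0 and end != start:
            length = L  # whole-circle fragment
        if length == 0:
            raise ConfigurationError("zero-length fragment in plan")
        sub = genome.slice(start % L, start % L + length)
        opos = (np.arange(start, start + length) % L).astype(np.int64)
        if orient == "-":
            sub = revcomp(sub)
            opos = opos[::-1]
        elif orient != "+":
            raise ConfigurationError(f"bad orientation {orient!r}")
        parts.append(encode(sub))
        org_pos_parts.append(opos)
        truth.source_blocks.append(SourceBlock(
            (cursor, cursor + length), (start % L, start % L + length), orient))
        # traversal entry/exit points on the organelle (+ frame)
        entry = (start % L) if orient == "+" else (end % L)
        if prev_end is not None:
            frag_bounds.append((prev_end, entry))
            frag_ends.append(cursor)
        prev_end = (end % L) if orient == "+" else (start % L)
        cursor += length

    codes = np.concatenate(parts)
    org_pos = np.concatenate(org_pos_parts)
    for pos, (le, rs) in zip(frag_ends, frag_bounds):
        klass, rp = _fragment_class(genome, le, rs)
        truth.fusion_points.append(FusionPoint(pos, klass, rp))

    dup = config.duplication
    t_pre = dup.time_fraction if dup is not None else 1.0

    # epoch 1: before any duplication
    events1 = _mutate(codes, config.mutation_rate * t_pre, config, rng)
    for pos, ref, alt in events1:
        truth.planted_variants.append(PlantedVariant(
            pos, int(org_pos[pos]), decode(np.array([ref], np.uint8)),
            decode(np.array([alt], np.uint8)), "pre_duplication"))

    if dup is not None:
        ds, de = dup.interval
        if not (0 <= ds < de <= codes.size):
            raise ConfigurationError("duplication interval outside the fused sequence")
        D = de - ds
        codes = np.concatenate([codes[:de], codes[ds:de], codes[de:]])
        org_pos = np.concatenate([org_pos[:de], org_pos[ds:de], org_pos[de:]])

        def shift(p: int) -> int:
            return p + D if p >= de else p

        # duplicate truth features inside [ds, de)
        new_blocks: list[SourceBlock] = []
        for blk in truth.source_blocks:
            s, e = blk.numt_interval
            for lo, hi, off in ((max(s, 0), min(e, ds), 0),
                                (max(s, ds), min(e, de), 0),
                                (max(s, ds), min(e, de), D),
                                (max(s, de), min(e, codes.size), D)):
                if hi <= lo:
                    continue
                os_, oe_ = blk.organelle_interval
                if blk.orientation == "+":
                    o0 = os_ + (lo - s)
                else:
                    o0 = os_ + (e - hi)
                new_blocks.append(SourceBlock(
                    (lo + off, hi + off), (o0, o0 + (hi - lo)), blk.orientation))
        new_blocks.sort(key=lambda b: b.numt_interval)
        truth.source_blocks = new_blocks

        new_fusions: list[FusionPoint] = []
        for fp in truth.fusion_points:
            if ds < fp.numt_pos < de:
                new_fusions.append(FusionPoint(fp.numt_pos, fp.klass, fp.mediating_repeat))
                new_fusions.append(FusionPoint(fp.numt_pos + D, fp.klass, fp.mediating_repeat))
            else:
                new_fusions.append(FusionPoint(shift(fp.numt_pos), fp.klass,
                                               fp.mediating_repeat))
        truth.fusion_points = sorted(new_fusions, key=lambda f: f.numt_pos)

        new_vars: list[PlantedVariant] = []
        for pv in truth.planted_variants:
            if ds <= pv.numt_pos < de:
                new_vars.append(pv)
                new_vars.append(PlantedVariant(pv.numt_pos + D, pv.organelle_pos,
                                               pv.ref, pv.alt, pv.epoch))
            else:
                new_vars.append(PlantedVariant(shift(pv.numt_pos), pv.organelle_pos,
                                               pv.ref, pv.alt, pv.epoch))
        truth.planted_variants = new_vars
        truth.duplication = RealizedDuplication((ds, de), (de, de + D), de,
                                                dup.time_fraction)

        # epoch 2: after the duplication, copies diverge independently
        events2 = _mutate(codes, config.mutation_rate * (1 - t_pre), config, rng)
        for pos, ref, alt in events2:
            truth.planted_variants.append(PlantedVariant(
                pos, int(org_pos[pos]), decode(np.array([ref], np.uint8)),
                decode(np.array([alt], np.uint8)), "post_duplication"))

    # gene conversion: copy-to-copy replacement of exact tracts
    for tract in (config.conversion_tracts or []):
        d0, a0, tl = tract.donor_start, tract.acceptor_start, tract.length
        if not (0 <= d0 and d0 + tl <= codes.size and 0 <= a0 and a0 + tl <= codes.size):
            raise ConfigurationError("conversion tract outside the numt")
        codes[a0:a0 + tl] = codes[d0:d0 + tl]
        truth.conversion_events.append(tract)

    # indels, placed away from block boundaries so truth blocks keep tiling
    if config.indel_rate > 0:
        boundaries = sorted({b for blk in truth.source_blocks for b in blk.numt_interval})
        sites = np.flatnonzero(rng.random(codes.size) < config.indel_rate)
        events: list[IndelEvent] = []
        for pos in sites:
            length = min(int(rng.geometric(0.5)), 20)
            if any(abs(int(pos) - b) <= length + 21 for b in boundaries):
                continue
            if rng.random() < config.deletion_bias:
                events.append(IndelEvent(int(pos), -length, ""))
            else:
                ins = random_seq(rng, length, config.gc_fraction)
                events.append(IndelEvent(int(pos), length, ins))
        codes, org_pos = _apply_indels(codes, org_pos, events, truth)

    # invariant check: blocks tile the numt without overlap
    cur = 0
    for blk in truth.source_blocks:
        if blk.numt_interval[0] != cur:
            raise AssertionError("truth blocks do not tile the numt")
        cur = blk.numt_interval[1]
    assert cur == codes.size

    return decode(codes), truth


def _apply_indels(codes: np.ndarray, org_pos: np.ndarray,
                  events: list[IndelEvent], truth: NumtTruth) -> tuple[np.ndarray, np.ndarray]:
    """Apply indel events (recorded at pre-indel coordinates) right-to-left and
    shift all truth coordinates onto the final numt frame."""
    events = sorted(events, key=lambda e: -e.numt_pos)
    removed: list[tuple[int, int]] = []  # pre-indel deleted intervals
    for ev in events:
        p = ev.numt_pos
        if ev.length < 0:
            d = -ev.length
            ev.seq = decode(codes[p:p + d])
            codes = np.concatenate([codes[:p], codes[p + d:]])
            org_pos = np.concatenate([org_pos[:p], org_pos[p + d:]])
            removed.append((p, p + d))
        else:
            ins = encode(ev.seq)
            codes = np.concatenate([codes[:p], ins, codes[p:]])
            org_pos = np.concatenate([org_pos[:p], np.full(ev.length, -1), org_pos[p:]])
    # coordinate map pre-indel -> final
    evs = sorted(events, key=lambda e: e.numt_pos)
    starts = np.array([e.numt_pos for e in evs])
    deltas = np.array([e.length for e in evs])
    cum = np.cumsum(deltas)

    def remap(p: int) -> int | None:
        for s, e in removed:
            if s <= p < e:
                return None
        k = int(np.searchsorted(starts, p, side="right"))
        # events at positions < p (deletions also consume [pos, pos+d))
        off = 0
        for i in range(k):
            off += int(deltas[i])
        return p + off

    truth.planted_variants = [
        dataclasses.replace(pv, numt_pos=np1)
        for pv in truth.planted_variants
        if (np1 := remap(pv.numt_pos)) is not None
    ]
    truth.fusion_points = [
        dataclasses.replace(fp, numt_pos=remap(fp.numt_pos)) for fp in truth.fusion_points
    ]
    new_blocks = []
    for blk in truth.source_blocks:
        s, e = blk.numt_interval
        s2 = remap(s)
        e2 = remap(e - 1)
        assert s2 is not None and e2 is not None  # boundaries were protected
        new_blocks.append(dataclasses.replace(blk, numt_interval=(s2, e2 + 1)))
    truth.source_blocks = new_blocks
    if truth.duplication is not None:
        d = truth.duplication
        truth.duplication = RealizedDuplication(
            (remap(d.interval[0]), remap(d.interval[1] - 1) + 1),
            (remap(d.second_copy[0]), remap(d.second_copy[1] - 1) + 1),
            remap(d.breakpoint - 1) + 1, d.time_fraction)
    truth.indel_events = evs
    return codes, org_pos


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class ReadConfig:
    """Long-read observation model (allele flips only; no quality scores)."""

    n_reads: int = 200
    read_length: int = 30_000
    numt_fraction: float = 0.5
    allele_error: float = 0.001
    meth_rates: dict[str, float] = field(
        default_factory=lambda: {"CpG": 0.9, "CHG": 0.7, "CHH": 0.1})
    organelle_meth_rate: float = 0.0
    max_meth_calls_per_read: int = 200
    emit_sequence: bool = False
    seq_error: float = 0.0
    seed: int = 0


@dataclass
class SimRead:
    read_id: str
    source: str  # 'numt' | 'organelle'
    start: int
    end: int
    alleles: dict[int, str]
    meth_calls: list[tuple[int, str, int]]
    sequence: str | None = None


@dataclass
class SimulatedReadSet:
    reads: list[SimRead]

    def by_source(self, source: str) -> list[SimRead]:
        return [r for r in self.reads if r.source == source]


_CTX_NAMES = ("CpG", "CHG", "CHH")


def simulate_reads(numt: str, genome: OrganelleGenome, diagnostic_sites,
                   read_config: ReadConfig | None = None) -> SimulatedReadSet:
    """Draw reads from both sources, observed in numt coordinates.

    Numt-source reads carry the numt allele at each covered diagnostic site
    (flipped to the organelle allele at the per-site error rate) and are
    methylated at the configured per-context rates; organelle-source reads
    carry organelle alleles and are (near-)unmethylated. Deterministic given
    the config seed.
    """
    cfg = read_config or ReadConfig()
    if not diagnostic_sites:
        raise ConfigurationError("diagnostic_sites must be nonempty")
    if cfg.read_length > len(numt) or cfg.read_length > genome.length:
        raise ConfigurationError("read length exceeds a source sequence length")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))

    sites = []
    for s in diagnostic_sites:
        if hasattr(s, "numt_pos"):
            sites.append((int(s.numt_pos), str(s.numt_allele), str(s.organelle_allele)))
        else:
            pos, na, oa = s
            sites.append((int(pos), str(na), str(oa)))
    sites.sort()
    sites = list({p: (p, na, oa) for p, na, oa in sites}.values())  # unique pos
    site_pos = np.array([p for p, _n, _o in sites])

    codes = encode(numt)
    from .varspec import classify_context  # context on the numt frame
    cmask = np.flatnonzero((codes == C) | (codes == G))

    reads: list[SimRead] = []
    for ridx in range(cfg.n_reads):
        source = "numt" if rng.random() < cfg.numt_fraction else "organelle"
        start = int(rng.integers(0, len(numt) - cfg.read_length + 1))
        end = start + cfg.read_length
        lo, hi = np.searchsorted(site_pos, [start, end])
        alleles: dict[int, str] = {}
        for pos, na, oa in sites[lo:hi]:
            true_allele = na if source == "numt" else oa
            wrong = oa if source == "numt" else na
            alleles[pos] = wrong if rng.random() < cfg.allele_error else true_allele
        # methylation calls at (a capped subsample of) cytosine positions
        clo, chi = np.searchsorted(cmask, [start, end])
        cpos = cmask[clo:chi]
        if cpos.size > cfg.max_meth_calls_per_read:
            cpos = np.sort(rng.choice(cpos, cfg.max_meth_calls_per_read, replace=False))
        meth_calls = []
        for pos in cpos:
            strand = "+" if codes[pos] == C else "-"
            ctx = classify_context(numt, int(pos), strand, circular=False)
            if ctx not in _CTX_NAMES:
                continue
            rate = cfg.meth_rates.get(ctx, 0.0) if source == "numt" else cfg.organelle_meth_rate
            meth_calls.append((int(pos), ctx, int(rng.random() < rate)))
        sequence = None
        if cfg.emit_sequence:
            arr = codes[start:end].copy()
            if source == "organelle":
                for pos, _na, oa in sites[lo:hi]:
                    arr[pos - start] = encode(oa)[0]
            if cfg.seq_error > 0:
                err = np.flatnonzero(rng.random(arr.size) < cfg.seq_error)
                for e in err:
                    arr[e] = (arr[e] + int(rng.integers(1, 4))) % 4
            sequence = decode(arr)
        reads.append(SimRead(f"read{ridx:05d}", source, start, end, alleles,
                             meth_calls, sequence))
    return SimulatedReadSet(reads)


# ---------------------------------------------------------------------------
# study-scale convenience builder
# ---------------------------------------------------------------------------

def study_config(seed: int = 0, scale: float = 1.0,
                 mutation_rate: float | None = None,
                 indel_rate: float | None = None) -> SimConfig:
    """A genesis config emulating the study conditions at a size ``scale``.

    ``scale=1.0`` gives the full 368-kb organelle genome; smaller scales
    shrink the genome and repeats proportionally (repeats floored at 60 bp)
    for fast exercises of the same structure.
    """
    s = scale
    cfg = SimConfig(
        genome_length=max(2000, int(368_000 * s)),
        large_repeats=[(max(60, int(6000 * s)), 2), (max(60, int(4200 * s)), 2)],
        small_repeats=[(max(40, int(457 * s)), 2), (max(30, int(206 * s)), 2)],
        seed=seed,
    )
    if mutation_rate is not None:
        cfg.mutation_rate = mutation_rate
    if indel_rate is not None:
        cfg.indel_rate = indel_rate
    return cfg


def study_fragment_plan(genome: OrganelleGenome, config: SimConfig,
                        rng: np.random.Generator | None = None) -> SimConfig:
    """Attach a genesis plan emulating the inferred insertion structure:
    several fragments fused by NHEJ, one duplicate organelle region (direct
    transfer of two copies), one alternative conformation through the first
    large repeat pair, and a post-divergence tandem duplication covering one
    copy of the duplicated region.

    Returns a copy of ``config`` with ``fragment_plan`` and ``duplication``
    set; deterministic given ``config.seed``.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    L = genome.length
    r1 = genome.repeat(genome.repeat_pairs[0].name)

    used: list[tuple[int, int]] = []  # organelle intervals already in the plan

    def mark(lo: int, hi: int) -> None:
        used.append((lo % L, lo % L + (hi - lo)))

    def disjoint(lo: int, hi: int, margin: int = 100) -> bool:
        a = (lo % L, lo % L + (hi - lo))
        return not any(_circ_overlap(a, b, L, margin) for b in used)

    def boundary_clear(pos: int, margin: int = 100) -> bool:
        # fragment ends inside a repeat copy would be anchorless; avoid them
        p = pos % L
        return not any(s - margin <= p <= e + margin
                       for rp in genome.repeat_pairs for s, e in rp.copies())

    flank = max(1400, L // 20)
    min_flank = 700  # keep conformation flanks above the default min_block
    # conformation fragment: enter at copy1's left flank, exit through copy2's
    # right flank (recombinant A-B' pairing); the left flank may wrap the origin
    for _ in range(1000):
        fl = int(rng.integers(min_flank, flank + 1))
        a0 = r1.copy1[0] - fl
        if boundary_clear(a0):
            break
    else:
        raise PlacementError("no clear left conformation flank")
    conf_left = (a0 % L, r1.copy1[1], "+")
    mark(a0, r1.copy1[1])
    for _ in range(1000):
        fr = int(rng.integers(min_flank, flank + 1))
        b1 = r1.copy2[1] + fr  # may wrap the origin
        if boundary_clear(b1 % L):
            break
    else:
        raise PlacementError("no clear right conformation flank")
    conf_right = (r1.copy2[1], b1, "+")
    mark(r1.copy2[1], b1)

    seg = max(800, L // 8)

    def pick_segment() -> tuple[int, int]:
        for _ in range(2000):
            s = int(rng.integers(0, L - seg))
            if (disjoint(s, s + seg) and boundary_clear(s)
                    and boundary_clear(s + seg)):
                mark(s, s + seg)
                return s, s + seg
        raise PlacementError("no clear fragment found")

    dup_frag = (*pick_segment(), "+")
    rev_frag = (*pick_segment(), "-")
    dup_frag = (dup_frag[0], dup_frag[1], "+")

    plan = [conf_left, conf_right, dup_frag, rev_frag, dup_frag]
    total = sum(((e - st) % L) for st, e, _o in plan)
    # tandem duplication spanning the second copy of dup_frag and some context
    cum = np.cumsum([0] + [((e - st) % L) for st, e, _o in plan])
    d_lo = int(cum[3])           # start of rev_frag
    d_hi = int(cum[5])           # end of second dup_frag copy
    out = dataclasses.replace(
        config,
        fragment_plan=plan,
        duplication=Duplication((d_lo, d_hi), time_fraction=0.5),
    )
    assert d_hi <= total
    return out


# ---------------------------------------------------------------------------
# writers (plain-text artifacts)
# ---------------------------------------------------------------------------

def write_fasta(path, name: str, seq: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def write_truth_json(path, truth: NumtTruth) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())


def write_blocks_bed(path, truth: NumtTruth, name: str = "numt") -> None:
    """Truth source blocks + fusion points as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, blk in enumerate(truth.source_blocks):
            s, e = blk.numt_interval
            fh.write(f"{name}\t{s}\t{e}\tblock{i}:"
                     f"{blk.organelle_interval[0]}-{blk.organelle_interval[1]}"
                     f"\t0\t{blk.orientation}\n")
        for fp in truth.fusion_points:
            fh.write(f"{name}\t{fp.numt_pos}\t{fp.numt_pos + 1}\tfusion:{fp.klass}\t0\t+\n")


def write_reads_tsv(path_obs, path_meth, readset: SimulatedReadSet) -> None:
    """Observations and methylation calls as flat TSV tables."""
    with open(path_obs, "w") as fh:
        fh.write("read_id\tsource\tstart\tend\tpos\tallele\n")
        for r in readset.reads:
            for pos in sorted(r.alleles):
                fh.write(f"{r.read_id}\t{r.source}\t{r.start}\t{r.end}\t{pos}\t{r.alleles[pos]}\n")
    with open(path_meth, "w") as fh:
        fh.write("read_id\tsource\tstart\tend\tpos\tcontext\tmethylated\n")
        for r in readset.reads:
            for pos, ctx, m in r.meth_calls:
                fh.write(f"{r.read_id}\t{r.source}\t{r.start}\t{r.end}\t{pos}\t{ctx}\t{m}\n")
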