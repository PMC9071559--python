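"""Synteny decomposition of a numt against a circular organelle genome.

Anchors are k-mers that occur exactly once in the organelle genome (both
strands considered); collinear anchor chains become syntenic blocks, whose
boundaries are refined by X-drop extension and junction-split scoring.
Adjacent block junctions are classified as repeat-mediated recombination
(the traversal switches between homologous offsets of two copies of an
annotated repeat pair) or NHEJ-like fusions of disjoint organelle regions.

All intervals are 0-based half-open. Organelle intervals are reported as
``(start, end)`` with ``start`` in ``[0, L)``; ``end`` may exceed ``L`` when
the block wraps the circular origin (``wrapped`` flag set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp
from .simgenome import OrganelleGenome, RepeatPair


class StructuralError(RuntimeError):
    """Overlapping or inconsistent blocks."""


@dataclass
class SyntenyBlock:
    """A maximal run of numt sequence collinear with one organelle region."""

    numt_interval: tuple[int, int]
    organelle_interval: tuple[int, int]
    orientation: str  # '+' | '-'
    anchor_count: int = 0
    identity_estimate: float = 1.0

    def wrapped(self, genome_length: int) -> bool:
        """True when the organelle interval crosses the circular origin."""
        return self.organelle_interval[1] > genome_length

    def length(self) -> int:
        return self.numt_interval[1] - self.numt_interval[0]

    def org_length(self) -> int:
        return self.organelle_interval[1] - self.organelle_interval[0]

    def traversal_end_org(self) -> int:
        """Organelle coordinate (+ frame) where the numt traversal of this
        block ends (exclusive side for '+', inclusive start side for '-')."""
        return self.organelle_interval[1] if self.orientation == "+" else self.organelle_interval[0]

    def traversal_start_org(self) -> int:
        return self.organelle_interval[0] if self.orientation == "+" else self.organelle_interval[1]


@dataclass
class Breakpoint:
    numt_position: int
    left_block: int
    right_block: int
    klass: str  # 'repeat_mediated' | 'nhej' | 'unknown'
    mediating_repeat: str | None = None
    mediating_copies: tuple[int, int] | None = None  # (left copy#, right copy#), 1-based


@dataclass
class ConformationSet:
    """Which of the four flank pairings across a repeat pair are realized.

    Copy 1 flanks are labelled A (upstream) and B (downstream); copy 2 flanks
    A' and B'. Parental pairings are A-B and A'-B'; recombinants A-B' and
    A'-B.
    """

    repeat_name: str
    present: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

def _unique_kmer_index(genome: OrganelleGenome, k: int):
    """Position and count of every k-mer on the forward strand of the circular
    genome. A numt k-mer anchors iff its total occurrence count over both
    strands is exactly one."""
    seq = genome.sequence
    L = len(seq)
    s2 = seq + seq[: k - 1]
    pos: dict[str, int] = {}
    cnt: dict[str, int] = {}
    for i in range(L):
        km = s2[i:i + k]
        c = cnt.get(km, 0)
        cnt[km] = c + 1
        if c == 0:
            pos[km] = i
    return pos, cnt


def _anchors(numt: str, genome: OrganelleGenome, k: int):
    """Yield ``(numt_pos, organelle_pos, strand)`` for unique-k-mer anchors.

    For '-' anchors ``organelle_pos`` is the forward-strand start of the
    matching organelle k-mer.
    """
    pos, cnt = _unique_kmer_index(genome, k)
    out = []
    for p in range(len(numt) - k + 1):
        km = numt[p:p + k]
        rkm = revcomp(km)
        n1 = cnt.get(km, 0)
        n2 = cnt.get(rkm, 0)
        if n1 == 1 and n2 == 0:
            out.append((p, pos[km], 1))
        elif n1 == 0 and n2 == 1:
            out.append((p, pos[rkm], -1))
    return out


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

class _Chain:
    __slots__ = ("strand", "first_p", "last_p", "first_g", "last_g", "count")

    def __init__(self, p, g, strand):
        self.strand = strand
        self.first_p = self.last_p = p
        self.first_g = self.last_g = g  # unwrapped organelle coords
        self.count = 1


def _chain_anchors(anchors, L: int, k: int, max_gap: int,
                   base_slack: int, drift_per_10kb: float):
    chains: list[_Chain] = []
    cur: _Chain | None = None
    for p, g, strand in anchors:
        if cur is not None and strand == cur.strand:
            gap = p - cur.last_p
            if 0 < gap <= max_gap:
                exp = cur.last_g + gap * strand
                m = round((exp - g) / L)
                cand = g + m * L
                slack = base_slack + drift_per_10kb * gap / 10_000.0
                if abs(cand - exp) <= slack:
                    cur.last_p = p
                    cur.last_g = cand
                    cur.count += 1
                    continue
        if cur is not None:
            chains.append(cur)
        cur = _Chain(p, g, strand)
    if cur is not None:
        chains.append(cur)
    return chains


def _extend(numt: str, genome: OrganelleGenome, p: int, g: int, strand: int,
            direction: int, limit: int, xdrop: int = 12,
            match: int = 1, mismatch: int = -3) -> int:
    """Greedy X-drop extension along a fixed diagonal.

    From numt position ``p`` (exclusive; first candidate is ``p + direction``)
    paired with unwrapped organelle coordinate ``g``, walk ``direction``
    (+1/-1) up to ``limit`` steps; returns the number of steps to the
    best-scoring prefix.
    """
    L = genome.length
    seq = genome.sequence
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    best = 0
    best_steps = 0
    score = 0
    steps = 0
    q = p
    og = g
    while steps < limit:
        q += direction
        og += direction * strand
        if q < 0 or q >= len(numt):
            break
        gb = seq[og % L]
        nb = numt[q]
        if strand == -1:
            gb = comp[gb]
        score += match if nb == gb else mismatch
        steps += 1
        if score > best:
            best = score
            best_steps = steps
        elif best - score > xdrop:
            break
    return best_steps


def decompose_synteny(numt: str, genome: OrganelleGenome, k: int = 31,
                      min_block: int = 500, max_gap: int = 20_000,
                      base_slack: int = 25, drift_per_10kb: float = 50.0) -> list[SyntenyBlock]:
    """Decompose the numt into syntenic blocks against the circular genome.

    Anchor chains with consistent diagonal (within an indel-drift slack of
    ``base_slack + drift_per_10kb`` per 10 kb) become blocks; boundaries are
    extended by X-drop along the block diagonal and adjacent-block overlaps
    are resolved at the best-scoring split. Returns blocks in numt order.
    """
    if k < 15:
        raise ValueError("k must be >= 15")
    if not numt or not genome.sequence:
        raise ValueError("empty sequence")
    anchors = _anchors(numt, genome, k)
    if not anchors:
        warnings.warn("no unique-k-mer anchors found; empty decomposition")
        return []
    chains = [c for c in _chain_anchors(anchors, genome.length, k, max_gap,
                                        base_slack, drift_per_10kb)
              if c.last_p + k - c.first_p >= min_block]
    if not chains:
        return []

    # anchored extents on the numt
    blocks: list[dict] = []
    for c in chains:
        blocks.append({
            "strand": c.strand,
            "n_start": c.first_p,
            "n_end": c.last_p + k,
            # unwrapped organelle coordinate paired with n_start
            "g_at_start": c.first_g if c.strand == 1 else c.first_g + k - 1,
            "count": c.count,
        })

    # X-drop extension into the gaps (and to the numt ends)
    for idx, b in enumerate(blocks):
        left_limit = b["n_start"] - (blocks[idx - 1]["n_start"] if idx > 0 else 0)
        if idx > 0:
            left_limit = b["n_start"] - blocks[idx - 1]["n_start"]
        else:
            left_limit = b["n_start"]
        ext_l = _extend(numt, genome, b["n_start"], b["g_at_start"], b["strand"],
                        -1, left_limit)
        b["n_start"] -= ext_l
        b["g_at_start"] -= ext_l * b["strand"]
        g_at_end = b["g_at_start"] + (b["n_end"] - 1 - b["n_start"]) * b["strand"]
        if idx + 1 < len(blocks):
            right_limit = blocks[idx + 1]["n_end"] - b["n_end"]
        else:
            right_limit = len(numt) - b["n_end"]
        ext_r = _extend(numt, genome, b["n_end"] - 1, g_at_end, b["strand"],
                        +1, right_limit)
        b["n_end"] += ext_r

    # resolve overlaps between neighbours at the best-scoring split
    seq = genome.sequence
    L = genome.length
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

    def diag_match(b: dict, q: int) -> int:
        og = b["g_at_start"] + (q - b["n_start"]) * b["strand"]
        gb = seq[og % L]
        if b["strand"] == -1:
            gb = comp[gb]
        return 1 if numt[q] == gb else 0

    for i in range(len(blocks) - 1):
        b1, b2 = blocks[i], blocks[i + 1]
        if b1["n_end"] <= b2["n_start"]:
            continue
        lo, hi = b2["n_start"], b1["n_end"]
        lo = max(lo, b1["n_start"])
        hi = min(hi, b2["n_end"])
        m1 = np.array([diag_match(b1, q) for q in range(lo, hi)])
        m2 = np.array([diag_match(b2, q) for q in range(lo, hi)])
        # split s: columns [lo, s) to b1, [s, hi) to b2
        pref1 = np.concatenate([[0], np.cumsum(m1)])
        suff2 = np.concatenate([np.cumsum(m2[::-1])[::-1], [0]])
        total = pref1 + suff2
        s = lo + int(np.argmax(total))  # ties -> lowest split
        b1["n_end"] = s
        b2["g_at_start"] += (s - b2["n_start"]) * b2["strand"]
        b2["n_start"] = s

    out: list[SyntenyBlock] = []
    for b in blocks:
        n0, n1 = b["n_start"], b["n_end"]
        if n1 - n0 <= 0:
            continue
        if b["strand"] == 1:
            g0 = b["g_at_start"]
            g1 = g0 + (n1 - n0)
        else:
            g1 = b["g_at_start"] + 1
            g0 = g1 - (n1 - n0)
        g0m = g0 % L
        out.append(SyntenyBlock(
            (n0, n1), (g0m, g0m + (g1 - g0)),
            "+" if b["strand"] == 1 else "-",
            anchor_count=b["count"],
            identity_estimate=min(1.0, b["count"] / max(1, n1 - n0 - k + 1)),
        ))
    return out


# ---------------------------------------------------------------------------
# breakpoints
# ---------------------------------------------------------------------------

def _circ_intervals_overlap(a: tuple[int, int], b: tuple[int, int], L: int,
                            slop: int = 0) -> bool:
    """Overlap of two circular intervals given as (start in [0,L), start+len)."""
    def segs(iv):
        s, e = iv[0] - slop, iv[1] + slop
        if e - s >= L:
            return [(0, L)]
        s %= L
        e = s + (iv[1] + slop - (iv[0] - slop))
        if e <= L:
            return [(s, e)]
        return [(s, L), (0, e - L)]
    for s1, e1 in segs(a):
        for s2, e2 in segs(b):
            if s1 < e2 and s2 < e1:
                return True
    return False


def _match_repeat_junction(genome: OrganelleGenome, left_end: int, right_start: int,
                           tolerance: int):
    """Repeat pair and copy indices mediating a junction, if any: the left
    traversal ends and the right traversal resumes at homologous offsets of
    two different copies of one annotated pair (within ``tolerance``)."""
    L = genome.length
    for rp in genome.repeat_pairs:
        for ci_idx, cj_idx in ((0, 1), (1, 0)):
            ci = rp.copies()[ci_idx]
            cj = rp.copies()[cj_idx]
            off_l = (left_end - ci[0]) % L
            off_r = (right_start - cj[0]) % L
            if off_l > rp.length + tolerance and off_l < L - tolerance:
                continue
            if off_r > rp.length + tolerance and off_r < L - tolerance:
                continue
            ol = off_l if off_l <= rp.length + tolerance else off_l - L
            orr = off_r if off_r <= rp.length + tolerance else off_r - L
            if abs(ol - orr) <= tolerance:
                return rp.name, (ci_idx + 1, cj_idx + 1)
    return None, None


def classify_breakpoints(blocks: list[SyntenyBlock], genome: OrganelleGenome,
                         tolerance: int = 50) -> list[Breakpoint]:
    """Classify each adjacent block junction.

    ``repeat_mediated``: the flanking blocks abut homologous offsets of two
    copies of one annotated repeat pair. ``nhej``: the organelle intervals are
    disjoint (beyond ``tolerance``). ``unknown`` otherwise (e.g. adjacent or
    overlapping organelle regions, or an orientation flip at a repeat).
    """
    for i in range(len(blocks) - 1):
        if blocks[i].numt_interval[1] > blocks[i + 1].numt_interval[0]:
            raise StructuralError(
                f"blocks {i} and {i + 1} overlap on the numt: "
                f"{blocks[i].numt_interval} vs {blocks[i + 1].numt_interval}")
    out: list[Breakpoint] = []
    L = genome.length
    for i in range(len(blocks) - 1):
        left, right = blocks[i], blocks[i + 1]
        pos = (left.numt_interval[1] + right.numt_interval[0]) // 2
        klass = "unknown"
        rp_name = copies = None
        if left.orientation == right.orientation:
            le = left.traversal_end_org() % L
            rs = right.traversal_start_org() % L
            rp_name, copies = _match_repeat_junction(genome, le, rs, tolerance)
        if rp_name is not None:
            klass = "repeat_mediated"
        elif not _circ_intervals_overlap(left.organelle_interval,
                                         right.organelle_interval, L,
                                         slop=tolerance):
            klass = "nhej"
        out.append(Breakpoint(pos, i, i + 1, klass, rp_name, copies))
    return out


# ---------------------------------------------------------------------------
# repeat conformations
# ---------------------------------------------------------------------------

def _contains_copy(block: SyntenyBlock, copy: tuple[int, int], L: int,
                   margin: int = 1) -> bool:
    s, e = block.organelle_interval
    cs, ce = copy
    for m in (0, 1):
        if s <= cs + m * L - margin and ce + m * L + margin <= e:
            return True
    return False


def detect_repeat_conformations(blocks: list[SyntenyBlock], repeat_pair: RepeatPair,
                                genome: OrganelleGenome,
                                tolerance: int = 50) -> ConformationSet:
    """Set of flank pairings observed across a repeat pair in the numt.

    A block whose organelle interval spans a copy with flanking sequence on
    both sides realizes that copy's parental pairing; a repeat-mediated
    breakpoint through the pair realizes the recombinant pairing of the
    entered copy's upstream flank with the exited copy's downstream flank.
    """
    if all(rp.name != repeat_pair.name for rp in genome.repeat_pairs):
        raise KeyError(f"repeat pair {repeat_pair.name!r} absent from genome annotation")
    L = genome.length
    a_label = {1: "A", 2: "A'"}
    b_label = {1: "B", 2: "B'"}
    conf = ConformationSet(repeat_pair.name)
    for block in blocks:
        for idx, copy in enumerate(repeat_pair.copies(), start=1):
            if _contains_copy(block, copy, L):
                conf.present.add(f"{a_label[idx]}-{b_label[idx]}")
    for bp in classify_breakpoints(blocks, genome, tolerance):
        if bp.klass != "repeat_mediated" or bp.mediating_repeat != repeat_pair.name:
            continue
        ci, cj = bp.mediating_copies
        orient = blocks[bp.left_block].orientation
        if orient == "+":
            conf.present.add(f"{a_label[ci]}-{b_label[cj]}")
        else:
            conf.present.add(f"{a_label[cj]}-{b_label[ci]}")
    return conf


# ---------------------------------------------------------------------------
# syntenic reference
# ---------------------------------------------------------------------------

@dataclass
class SyntenicReference:
    """Concatenation of organelle homologs in numt order, with a per-block
    offset table mapping output positions back to organelle coordinates."""

    sequence: str
    entries: list[dict]  # {out_start, out_end, org_start, org_end, orientation, block}

    def map_to_organelle(self, pos: int, L: int) -> tuple[int, str]:
        """Organelle coordinate (+ strand, in [0,L)) and block orientation for
        an output position."""
        for e in self.entries:
            if e["out_start"] <= pos < e["out_end"]:
                off = pos - e["out_start"]
                if e["orientation"] == "+":
                    return (e["org_start"] + off) % L, "+"
                return (e["org_end"] - 1 - off) % L, "-"
        raise IndexError(f"position {pos} outside the syntenic reference")


def build_syntenic_reference(blocks: list[SyntenyBlock],
                             genome: OrganelleGenome) -> SyntenicReference:
    """Concatenate each block's organelle homolog (reverse-complemented for
    '-' blocks) to match the synteny of the numt."""
    parts: list[str] = []
    entries: list[dict] = []
    out = 0
    for bi, b in enumerate(blocks):
        s, e = b.organelle_interval
        sub = genome.slice(s, e)
        if b.orientation == "-":
            sub = revcomp(sub)
        entries.append({"out_start": out, "out_end": out + len(sub),
                        "org_start": s, "org_end": e,
                        "orientation": b.orientation, "block": bi})
        parts.append(sub)
        out += len(sub)
    return SyntenicReference("".join(parts), entries)


# ---------------------------------------------------------------------------
# maximal exact matches
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IdenticalRegion:
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    length: int
    orientation: str  # '+' | '-' (b reverse-complemented)


def find_identical_regions(seq_a: str, seq_b: str, min_len: int) -> list[IdenticalRegion]:
    """Maximal exact matches of length >= ``min_len`` between two sequences,
    both orientations. Self-comparison (``seq_b is seq_a`` or equal strings)
    excludes the trivial full-length diagonal and reports each unordered pair
    once."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    self_cmp = seq_a is seq_b or seq_a == seq_b
    k = min(min_len, 32)
    stride = max(1, min_len - k + 1)
    results: set[tuple[int, int, int, str]] = set()

    for orient, sb in (("+", seq_b), ("-", revcomp(seq_b))):
        if self_cmp and orient == "-" and seq_b == revcomp(seq_b):
            continue
        index: dict[str, list[int]] = {}
        for j in range(len(sb) - k + 1):
            index.setdefault(sb[j:j + k], []).append(j)
        for i in range(0, len(seq_a) - k + 1, stride):
            km = seq_a[i:i + k]
            for j in index.get(km, ()):
                # maximal extension
                ai, bj = i, j
                while ai > 0 and bj > 0 and seq_a[ai - 1] == sb[bj - 1]:
                    ai -= 1
                    bj -= 1
                ae, be = i + k, j + k
                while ae < len(seq_a) and be < len(sb) and seq_a[ae] == sb[be]:
                    ae += 1
                    be += 1
                length = ae - ai
                if length < min_len:
                    continue
                if orient == "+":
                    b_iv = (bj, be)
                else:
                    b_iv = (len(seq_b) - be, len(seq_b) - bj)
                if self_cmp:
                    if orient == "+" and ai == b_iv[0]:
                        continue  # trivial diagonal
                    if b_iv[0] < ai or (b_iv[0] == ai and orient == "-" and b_iv[1] < ae):
                        continue  # canonical order: report (a before b) once
                results.add((ai, ae, b_iv[0], orient))

    out = []
    for ai, ae, bs, orient in sorted(results):
        out.append(IdenticalRegion((ai, ae), (bs, bs + (ae - ai)), ae - ai, orient))
    return out


# ---------------------------------------------------------------------------
# plain-text output
# ---------------------------------------------------------------------------

def write_blocks_paf(path, blocks: list[SyntenyBlock], numt_len: int,
                     genome: OrganelleGenome, numt_name: str = "numt",
                     org_name: str = "organelle") -> None:
    """PAF-like TSV (0-based half-open, organelle intervals may wrap)."""
    with open(path, "w") as fh:
        for b in blocks:
            s, e = b.organelle_interval
            fh.write("\t".join(str(x) for x in (
                numt_name, numt_len, b.numt_interval[0], b.numt_interval[1],
                b.orientation, org_name, genome.length, s % genome.length, e,
                b.anchor_count, b.length(), 255)) + "\n")


def write_breakpoints_bed(path, breakpoints: list[Breakpoint],
                          numt_name: str = "numt") -> None:
    with open(path, "w") as fh:
        for bp in breakpoints:
            name = bp.klass + (f":{bp.mediating_repeat}" if bp.mediating_repeat else "")
            fh.write(f"{numt_name}\t{bp.numt_position}\t{bp.numt_position + 1}\t{name}\t0\t+\n")
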