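"""Duplication-history inference from shared derived variants.

Organelle regions carried by three or more numt copies are grouped, each copy
is aligned to the organelle homolog and projected onto organelle columns
(reference-guided, no heuristic multiple alignment), pairwise divergences are
computed, and polymorphic columns are classified: a column where exactly two
copies share an allele absent from the organelle (and the remaining copy
matches it) is a shared derived variant — the signature of a duplication
after divergence began. A Monte-Carlo homoplasy null (independent mutations
on a star phylogeny at the observed per-copy rates) tests whether the
observed shared-pair count requires a post-insertion duplication, and the
consistent copy-pairing locates the tandem-duplication interval and its
central breakpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._align import align_block
from ._seq import decode, encode, revcomp
from .simgenome import OrganelleGenome
from .synteny import SyntenyBlock

_GAP = 4  # code for a gap/deleted column in a projected copy row


@dataclass
class RepeatCopyGroup:
    """One organelle region present as >= min_copies homologous numt copies."""

    organelle_interval: tuple[int, int]  # (start in [0,L), start+len)
    copies: list[tuple[int, int, str]]   # (numt start, numt end, orientation)


@dataclass
class CopyAlignment:
    """Copies projected onto organelle columns.

    ``alleles[c, j]`` is copy ``c``'s base code at organelle column ``j``
    (gap = 4); ``organelle_row`` holds the homolog codes; ``pos_maps[c, j]``
    is the numt coordinate of that base (-1 at gaps). Copy-specific
    insertions relative to the homolog are kept as side records.
    """

    group: RepeatCopyGroup
    alleles: np.ndarray
    organelle_row: np.ndarray
    pos_maps: np.ndarray
    insertions: list[tuple[int, int, str]] = field(default_factory=list)  # (copy, column, seq)

    @property
    def n_copies(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_columns(self) -> int:
        return self.alleles.shape[1]

    def copy_sequence(self, c: int) -> str:
        """Ungapped row ``c`` with its insertions restored (reconstructs the
        copy's numt substring in alignment orientation)."""
        ins = {}
        for ci, col, s in self.insertions:
            if ci == c:
                ins.setdefault(col, []).append(s)
        parts = []
        for j in range(self.n_columns + 1):
            for s in ins.get(j, ()):  # insertions before column j
                parts.append(s)
            if j < self.n_columns and self.alleles[c, j] != _GAP:
                parts.append(decode(self.alleles[c, j:j + 1]))
        return "".join(parts)


@dataclass
class SharedVariantPattern:
    column: int
    organelle_allele: str
    copy_alleles: tuple[str, ...]
    pattern_class: str  # 'singleton' | 'shared_pair' | 'all_derived' | 'other'
    pairing: tuple[int, int] | None = None  # copy indices sharing the derived allele
    numt_positions: dict[int, int] = field(default_factory=dict)


@dataclass
class DivergenceMatrix:
    labels: list[str]
    matrix: np.ndarray       # fraction of mismatching comparable columns
    comparable: np.ndarray   # count of comparable (both ungapped) columns
    n_columns: int

    def mean_copy_copy(self) -> float:
        n = len(self.labels) - 1  # last row is the organelle
        vals = [self.matrix[i, j] for i in range(n) for j in range(i + 1, n)]
        return float(np.mean(vals)) if vals else float("nan")

    def mean_copy_organelle(self) -> float:
        n = len(self.labels) - 1
        vals = [self.matrix[i, n] for i in range(n)]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass
class StarTestResult:
    observed_shared: int
    expected_shared: float
    p_value: float
    p_value_randomized: float
    verdict: str  # 'post_insertion_duplication' | 'star_phylogeny'
    n_sim: int


@dataclass
class DuplicationModel:
    duplicated_interval: tuple[int, int] | None
    central_breakpoint: int | None
    supporting_pattern_count: int
    conflicting_pattern_count: int
    verdict: str  # 'post_insertion_duplication' | 'star_phylogeny' | 'inconclusive'
    pairing: tuple[int, int] | None = None

    def to_dict(self) -> dict:
        return {
            "duplicated_interval": self.duplicated_interval,
            "central_breakpoint": self.central_breakpoint,
            "supporting_pattern_count": self.supporting_pattern_count,
            "conflicting_pattern_count": self.conflicting_pattern_count,
            "verdict": self.verdict,
            "pairing": self.pairing,
        }


# ---------------------------------------------------------------------------
# copy extraction
# ---------------------------------------------------------------------------

def extract_repeat_copies(blocks: list[SyntenyBlock], min_copies: int = 3,
                          min_len: int = 2000) -> list[RepeatCopyGroup]:
    """Organelle regions covered by >= ``min_copies`` blocks, intersected to
    the common core (length >= ``min_len``).

    Origin-wrapping block intervals are split at the origin for the sweep, so
    a multi-copy region that itself spans the origin is reported in two
    pieces.
    """
    if not blocks:
        return []
    L_guess = max(b.organelle_interval[1] for b in blocks)
    events: list[tuple[int, int]] = []
    pieces: list[tuple[int, int, SyntenyBlock]] = []
    for b in blocks:
        s, e = b.organelle_interval
        if e <= L_guess:
            pieces.append((s, e, b))
        else:  # wraps the origin: split for the linear sweep
            pieces.extend([(s, L_guess, b), (0, e - L_guess, b)])
    for s, e, _b in pieces:
        events.append((s, 1))
        events.append((e, -1))
    events.sort()
    groups: list[RepeatCopyGroup] = []
    depth = 0
    start = None
    bounds: list[tuple[int, int]] = []
    for pos, d in events:
        prev = depth
        depth += d
        if prev < min_copies <= depth:
            start = pos
        elif prev >= min_copies > depth and start is not None:
            bounds.append((start, pos))
            start = None
    for s, e in bounds:
        if e - s < min_len:
            continue
        copies = []
        for ps, pe, b in pieces:
            if ps <= s and e <= pe:
                bs, be = b.organelle_interval
                # unwrap the core into this block's frame
                s_u = s if s >= bs else s + L_guess
                e_u = s_u + (e - s)
                if b.orientation == "+":
                    ns = b.numt_interval[0] + (s_u - bs)
                else:
                    ns = b.numt_interval[0] + (be - e_u)
                copies.append((ns, ns + (e - s), b.orientation))
        if len(copies) >= min_copies:
            groups.append(RepeatCopyGroup((s, e), sorted(copies)))
    return groups


# ---------------------------------------------------------------------------
# reference-guided projection
# ---------------------------------------------------------------------------

def align_copies(group: RepeatCopyGroup, numt: str,
                 genome: OrganelleGenome) -> CopyAlignment:
    """Align every copy pairwise to the organelle homolog and project onto
    organelle columns; copy insertions are retained as side records."""
    s, e = group.organelle_interval
    homolog = genome.slice(s, e)
    Lc = len(homolog)
    n = len(group.copies)
    alleles = np.full((n, Lc), _GAP, dtype=np.uint8)
    pos_maps = np.full((n, Lc), -1, dtype=np.int64)
    insertions: list[tuple[int, int, str]] = []
    for c, (ns, ne, orient) in enumerate(group.copies):
        sub = numt[ns:ne]
        if orient == "-":
            sub = revcomp(sub)
        aln = align_block(sub, homolog)
        for op, i, j, nb, _rb in aln.columns():
            if op in "=X":
                alleles[c, j] = encode(nb)[0]
                # numt coordinate of this base
                pos_maps[c, j] = ns + i if orient == "+" else ne - 1 - i
            elif op == "I":
                insertions.append((c, j, nb))
    org_row = encode(homolog)
    return CopyAlignment(group, alleles, org_row, pos_maps, insertions)


def pairwise_divergence(aln: CopyAlignment) -> DivergenceMatrix:
    """Mismatch fraction over columns where both rows are ungapped, for all
    copy/copy and copy/organelle pairs."""
    rows = np.vstack([aln.alleles, aln.organelle_row[None, :]])
    n = rows.shape[0]
    mat = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            ok = (rows[i] != _GAP) & (rows[j] != _GAP)
            m = int(ok.sum())
            comp[i, j] = comp[j, i] = m
            if m == 0:
                mat[i, j] = mat[j, i] = float("nan")
                continue
            d = int(((rows[i] != rows[j]) & ok).sum()) / m
            mat[i, j] = mat[j, i] = d
    labels = [f"copy{c + 1}" for c in range(aln.n_copies)] + ["organelle"]
    return DivergenceMatrix(labels, mat, comp, aln.n_columns)


# ---------------------------------------------------------------------------
# shared-variant patterns
# ---------------------------------------------------------------------------

def detect_shared_variants(aln: CopyAlignment) -> list[SharedVariantPattern]:
    """Classify every polymorphic SNV column (gap columns are ignored).

    ``shared_pair``: exactly two copies share one allele different from the
    organelle and every other copy matches the organelle. ``singleton``: one
    copy differs. ``all_derived``: all copies share a non-organelle allele.
    Anything else is ``other``.
    """
    if aln.n_copies < 3:
        raise ValueError("shared-variant patterns require >= 3 copies")
    rows = aln.alleles
    org = aln.organelle_row
    ungapped = (rows != _GAP).all(axis=0) & (org != _GAP)
    poly = ungapped & (rows != org[None, :]).any(axis=0)
    out: list[SharedVariantPattern] = []
    for j in np.flatnonzero(poly):
        col = rows[:, j]
        o = org[j]
        derived = np.flatnonzero(col != o)
        alleles = tuple(decode(col[c:c + 1]) for c in range(col.size))
        if derived.size == 1:
            cls, pairing = "singleton", None
        elif derived.size == col.size and np.unique(col).size == 1:
            cls, pairing = "all_derived", None
        elif derived.size == 2 and col[derived[0]] == col[derived[1]]:
            cls, pairing = "shared_pair", (int(derived[0]), int(derived[1]))
        else:
            cls, pairing = "other", None
        positions = {int(c): int(aln.pos_maps[c, j]) for c in range(col.size)}
        out.append(SharedVariantPattern(int(j), decode(org[j:j + 1]), alleles,
                                        cls, pairing, positions))
    return out


# ---------------------------------------------------------------------------
# star-phylogeny homoplasy test
# ---------------------------------------------------------------------------

def expected_homoplasies(rates: np.ndarray, n_columns: int) -> float:
    """Closed-form expectation of shared-pair columns under independent
    mutation: sum over pairs of L * p_i * p_j * prod(1-p_k) / 3 (two hits at
    one column picking the same of 3 alts)."""
    n = rates.size
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            others = [1 - rates[k] for k in range(n) if k not in (i, j)]
            total += n_columns * rates[i] * rates[j] * float(np.prod(others)) / 3.0
    return total


def test_star_phylogeny(patterns: list[SharedVariantPattern],
                        divergence: DivergenceMatrix, n_sim: int = 10_000,
                        seed: int = 0) -> StarTestResult:
    """Monte-Carlo test of the star-phylogeny null.

    Null: each copy mutates independently of the others at its observed
    copy-vs-organelle rate, alt alleles uniform over the three alternatives.
    p is the fraction of simulated shared-pair counts >= the observed count
    (add-one corrected); a randomized (PIT) p-value is also reported for
    calibration checks on this discrete statistic. Verdict is
    ``post_insertion_duplication`` when p < 0.001.
    """
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives a low-precision Monte-Carlo p-value")
    n = len(divergence.labels) - 1
    if n < 3:
        raise ValueError("star test requires >= 3 copies")
    L = divergence.n_columns
    rates = np.array([divergence.matrix[i, n] for i in range(n)])
    rates = np.nan_to_num(rates, nan=0.0)
    observed = sum(1 for p in patterns if p.pattern_class == "shared_pair")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    counts = np.zeros(n_sim, dtype=np.int64)
    for s in range(n_sim):
        cols: list[np.ndarray] = []
        copy_ids: list[np.ndarray] = []
        for c in range(n):
            kc = rng.binomial(L, rates[c])
            if kc:
                cols.append(rng.integers(0, L, size=kc))
                copy_ids.append(np.full(kc, c))
        if not cols:
            continue
        col = np.concatenate(cols)
        cid = np.concatenate(copy_ids)
        alt = rng.integers(0, 3, size=col.size)
        order = np.argsort(col, kind="stable")
        col, cid, alt = col[order], cid[order], alt[order]
        uniq, start, cnt = np.unique(col, return_index=True, return_counts=True)
        shared = 0
        for st, ct in zip(start, cnt):
            if ct == 2 and cid[st] != cid[st + 1] and alt[st] == alt[st + 1]:
                shared += 1
        counts[s] = shared
    ge = int((counts >= observed).sum())
    gt = int((counts > observed).sum())
    p = (ge + 1) / (n_sim + 1)
    p_rand = (gt + rng.random() * (ge - gt)) / n_sim if n_sim else 1.0
    verdict = "post_insertion_duplication" if p < 0.001 else "star_phylogeny"
    return StarTestResult(observed, float(counts.mean()), float(min(p, 1.0)),
                          float(min(max(p_rand, 0.0), 1.0)), verdict, n_sim)


# ---------------------------------------------------------------------------
# tandem duplication inference
# ---------------------------------------------------------------------------

def infer_tandem_duplication(patterns: list[SharedVariantPattern],
                             blocks: list[SyntenyBlock],
                             min_support: int = 3,
                             min_span: int = 5000) -> DuplicationModel:
    """Locate a single tandem duplication from the consistent copy-pairing.

    The pairing with the most shared-pair patterns is the daughter pair;
    patterns pairing other copies are conflicting (possible gene conversion).
    Requires >= ``min_support`` consistent patterns spanning >= ``min_span``
    on the numt (a tight cluster is conversion-like, verdict inconclusive);
    with no shared patterns at all the verdict is inconclusive.
    """
    shared = [p for p in patterns if p.pattern_class == "shared_pair"]
    if not shared:
        return DuplicationModel(None, None, 0, 0, "inconclusive")
    tallies: dict[tuple[int, int], list[SharedVariantPattern]] = {}
    for p in shared:
        tallies.setdefault(p.pairing, []).append(p)
    pairing = max(tallies, key=lambda k: len(tallies[k]))
    supporting = tallies[pairing]
    n_sup = len(supporting)
    n_con = len(shared) - n_sup
    if n_sup < min_support:
        return DuplicationModel(None, None, n_sup, n_con, "star_phylogeny", pairing)
    # numt positions of the supporting patterns in the two daughter copies
    pos_lo, pos_hi = [], []
    for p in supporting:
        a, b = sorted(p.numt_positions[c] for c in pairing)
        pos_lo.append(a)
        pos_hi.append(b)
    span = max(max(pos_lo) - min(pos_lo), max(pos_hi) - min(pos_hi))
    if span < min_span:
        return DuplicationModel(None, None, n_sup, n_con, "inconclusive", pairing)
    lo = min(pos_lo)
    hi = max(pos_hi) + 1
    # extend to containing block boundaries
    for b in blocks:
        s, e = b.numt_interval
        if s <= lo < e:
            lo = s
        if s < hi <= e:
            hi = e
    # central breakpoint: block edge nearest the gap between the daughters
    mid = (max(pos_lo) + min(pos_hi)) // 2
    edges = sorted({x for b in blocks for x in b.numt_interval
                    if max(pos_lo) <= x <= min(pos_hi)})
    breakpoint = min(edges, key=lambda x: abs(x - mid)) if edges else mid
    return DuplicationModel((lo, hi), int(breakpoint), n_sup, n_con,
                            "post_insertion_duplication", pairing)


# ---------------------------------------------------------------------------
# plain-text output
# ---------------------------------------------------------------------------

def write_patterns_tsv(path, patterns: list[SharedVariantPattern]) -> None:
    with open(path, "w") as fh:
        fh.write("column\torganelle_allele\tcopy_alleles\tclass\tpairing\tnumt_positions\n")
        for p in patterns:
            pairing = "." if p.pairing is None else f"{p.pairing[0]},{p.pairing[1]}"
            pos = ";".join(f"{c}:{x}" for c, x in sorted(p.numt_positions.items()))
            fh.write(f"{p.column}\t{p.organelle_allele}\t{''.join(p.copy_alleles)}\t"
                     f"{p.pattern_class}\t{pairing}\t{pos}\n")


def write_divergence_tsv(path, div: DivergenceMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(div.labels) + "\n")
        for i, lab in enumerate(div.labels):
            row = "\t".join(f"{div.matrix[i, j]:.6f}" for j in range(len(div.labels)))
            fh.write(f"{lab}\t{row}\n")
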