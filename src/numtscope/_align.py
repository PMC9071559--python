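"""Banded global pairwise alignment (Gotoh affine-gap DP).

Built for near-identical (>=99%) sequence pairs where the optimal path stays
close to the main diagonal, so a narrow band suffices; the band is widened
automatically when the optimal path touches its edge.

Scoring convention: a gap of length L costs ``gap_open + L * gap_extend``
(i.e. the first gap character costs open+extend).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np

from ._seq import encode

NEG = np.int32(-(2**30))

# traceback pointer codes: state entered from M=0, X=1 (gap in b), Y=2 (gap in a)
_M, _X, _Y = 0, 1, 2


class BandExceededError(RuntimeError):
    """Optimal path touched the band edge; retry with a larger band."""


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1


@numba.njit(cache=False)
def _fill(a, b, dlo, W, match, mismatch, gap_open, gap_extend,
          M, X, Y, PM, PX, PY):  # pragma: no cover - exercised via wrapper
    n = a.shape[0]
    m = b.shape[0]
    oe = gap_open + gap_extend
    M[:] = NEG
    X[:] = NEG
    Y[:] = NEG
    # row 0
    for t in range(W):
        j = dlo + t
        if j < 0 or j > m:
            continue
        if j == 0:
            M[0, t] = 0
        else:
            Y[0, t] = oe + gap_extend * (j - 1)
            PY[0, t] = _Y if j > 1 else _M
    for i in range(1, n + 1):
        ai = a[i - 1]
        for t in range(W):
            j = i + dlo + t
            if j < 0 or j > m:
                continue
            # X: gap in b (consume a_i); predecessor at (i-1, j) -> t+1
            if j == 0:
                X[i, t] = oe + gap_extend * (i - 1)
                PX[i, t] = _X if i > 1 else _M
            elif t + 1 < W:
                vm = M[i - 1, t + 1]
                vx = X[i - 1, t + 1]
                vy = Y[i - 1, t + 1]
                best = vm + oe
                ptr = _M
                if vx + gap_extend > best:
                    best = vx + gap_extend
                    ptr = _X
                if vy + oe > best:
                    best = vy + oe
                    ptr = _Y
                if best > NEG // 2:
                    X[i, t] = best
                    PX[i, t] = ptr
            # Y: gap in a (consume b_j); predecessor at (i, j-1) -> t-1
            if j > 0 and t - 1 >= 0:
                vm = M[i, t - 1]
                vx = X[i, t - 1]
                vy = Y[i, t - 1]
                best = vm + oe
                ptr = _M
                if vy + gap_extend > best:
                    best = vy + gap_extend
                    ptr = _Y
                if vx + oe > best:
                    best = vx + oe
                    ptr = _X
                if best > NEG // 2:
                    Y[i, t] = best
                    PY[i, t] = ptr
            # M: diagonal; predecessor at (i-1, j-1) -> same t
            if j > 0:
                vm = M[i - 1, t]
                vx = X[i - 1, t]
                vy = Y[i - 1, t]
                best = vm
                ptr = _M
                if vx > best:
                    best = vx
                    ptr = _X
                if vy > best:
                    best = vy
                    ptr = _Y
                if best > NEG // 2:
                    s = match if ai == b[j - 1] else mismatch
                    M[i, t] = best + s
                    PM[i, t] = ptr


def _edge_bound_exceeds(M, X, Y, dlo, W, n, m, scoring, score) -> bool:
    """Sound certificate that no path through a band-edge cell can beat the
    in-band optimum.

    A path leaving through edge cell (i, j) can still match at most
    ``min(n-i, m-j)`` pairs and must pay at least one gap of the diagonal
    displacement back to the (n, m) corner. If that optimistic bound exceeds
    the found score, the band may be too narrow.
    """
    match = max(scoring.match, 0)
    for t, disp in ((0, (m - n) - dlo), (W - 1, (dlo + W - 1) - (m - n))):
        i = np.arange(n + 1)
        j = i + dlo + t
        ok = (j >= 0) & (j <= m)
        if not ok.any():
            continue
        i, j = i[ok], j[ok]
        best = np.maximum.reduce([M[i, t], X[i, t], Y[i, t]]).astype(np.int64)
        rem = np.minimum(n - i, m - j)
        ret_cost = 0 if disp <= 0 else -(scoring.gap_open + scoring.gap_extend * disp)
        bound = best + match * rem - ret_cost
        live = best > NEG // 2
        if live.any() and int(bound[live].max()) > score:
            return True
    return False


def banded_align(a: str, b: str, band: int,
                 scoring: Scoring = Scoring()) -> tuple[int, list[tuple[str, int]]]:
    """Optimal global alignment of ``a`` vs ``b`` restricted to diagonals
    ``j - i`` within ``band`` of the [0, m-n] corridor.

    Returns ``(score, cigar)`` where cigar is a run-length op list over
    ``=`` (match), ``X`` (mismatch), ``I`` (insertion: consumes a only) and
    ``D`` (deletion: consumes b only).

    Raises :class:`BandExceededError` when the optimal path touches the band
    edge and the band does not already cover the full DP matrix.
    """
    ca, cb = encode(a), encode(b)
    n, m = len(ca), len(cb)
    if band < 1:
        raise ValueError("band must be >= 1")
    if n == 0 or m == 0:
        cigar = []
        if m:
            cigar.append(("D", m))
        if n:
            cigar.append(("I", n))
        sc = 0
        if n + m:
            sc = scoring.gap_open + scoring.gap_extend * (n + m)
        return sc, cigar
    dlo = min(0, m - n) - band
    dhi = max(0, m - n) + band
    full = dlo <= -n and dhi >= m
    W = dhi - dlo + 1
    M = np.empty((n + 1, W), dtype=np.int32)
    X = np.empty((n + 1, W), dtype=np.int32)
    Y = np.empty((n + 1, W), dtype=np.int32)
    PM = np.zeros((n + 1, W), dtype=np.int8)
    PX = np.zeros((n + 1, W), dtype=np.int8)
    PY = np.zeros((n + 1, W), dtype=np.int8)
    _fill(ca, cb, dlo, W,
          np.int32(scoring.match), np.int32(scoring.mismatch),
          np.int32(scoring.gap_open), np.int32(scoring.gap_extend),
          M, X, Y, PM, PX, PY)
    t_end = m - n - dlo
    states = (M[n, t_end], X[n, t_end], Y[n, t_end])
    state = int(np.argmax(states))
    score = int(states[state])
    if score <= NEG // 2:
        raise BandExceededError("no path inside band")
    if not full and _edge_bound_exceeds(M, X, Y, dlo, W, n, m, scoring, score):
        raise BandExceededError("a path outside the band could score higher")
    # traceback
    ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        t = j - i - dlo
        if state == _M:
            ptr = PM[i, t]
            ops.append("=" if ca[i - 1] == cb[j - 1] else "X")
            i -= 1
            j -= 1
            state = int(ptr)
        elif state == _X:
            ptr = PX[i, t]
            ops.append("I")
            i -= 1
            state = int(ptr)
        else:
            ptr = PY[i, t]
            ops.append("D")
            j -= 1
            state = int(ptr)
    ops.reverse()
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return score, cigar


def global_align(a: str, b: str, scoring: Scoring = Scoring()) -> tuple[int, list[tuple[str, int]]]:
    """Unbanded (full-matrix) global alignment; convenience wrapper."""
    return banded_align(a, b, band=max(len(a), len(b), 1), scoring=scoring)


@dataclass
class BlockAlignment:
    """Global alignment of one numt block against its organelle homolog.

    ``cigar`` is run-length encoded over ``=XID``; ``numt_interval`` /
    ``reference_interval`` place the aligned substrings in their parents'
    coordinates (0-based half-open).
    """

    numt_seq: str
    ref_seq: str
    cigar: list[tuple[str, int]]
    score: int
    numt_interval: tuple[int, int] = (0, 0)
    reference_interval: tuple[int, int] = (0, 0)
    scoring: Scoring = field(default_factory=Scoring)

    def __post_init__(self):
        if self.numt_interval == (0, 0):
            self.numt_interval = (0, len(self.numt_seq))
        if self.reference_interval == (0, 0):
            self.reference_interval = (0, len(self.ref_seq))

    def columns(self):
        """Yield ``(op, numt_idx, ref_idx, numt_base, ref_base)`` per column.

        Indices are local (into ``numt_seq`` / ``ref_seq``); for I columns
        ``ref_idx`` is the index of the next reference base (gap columns carry
        ``None`` for the non-consumed base).
        """
        i = j = 0
        for op, run in self.cigar:
            for _ in range(run):
                if op in "=X":
                    yield op, i, j, self.numt_seq[i], self.ref_seq[j]
                    i += 1
                    j += 1
                elif op == "I":
                    yield op, i, j, self.numt_seq[i], None
                    i += 1
                else:
                    yield op, i, j, None, self.ref_seq[j]
                    j += 1

    def aligned_strings(self) -> tuple[str, str]:
        top, bot = [], []
        for op, _i, _j, nb, rb in self.columns():
            top.append(nb if nb is not None else "-")
            bot.append(rb if rb is not None else "-")
        return "".join(top), "".join(bot)

    @property
    def n_edits(self) -> int:
        return sum(run for op, run in self.cigar if op != "=")


def align_block(numt_sub: str, ref_sub: str, band: int | None = None,
                scoring: Scoring = Scoring(),
                numt_interval: tuple[int, int] | None = None,
                reference_interval: tuple[int, int] | None = None) -> BlockAlignment:
    """Align a numt substring to its organelle homolog, auto-widening the band.

    The starting band defaults to 32 and doubles whenever the in-band optimum
    is not certified optimal (see :func:`_edge_bound_exceeds`), up to full
    matrix coverage; the returned alignment is therefore the global optimum.
    """
    if band is None:
        band = 32
    limit = max(len(numt_sub), len(ref_sub), 1)
    band = min(band, limit)
    while True:
        try:
            score, cigar = banded_align(numt_sub, ref_sub, band, scoring)
            break
        except BandExceededError:
            if band >= limit:
                raise
            band = min(limit, band * 2)
    return BlockAlignment(
        numt_sub, ref_sub, cigar, score,
        numt_interval=numt_interval or (0, len(numt_sub)),
        reference_interval=reference_interval or (0, len(ref_sub)),
        scoring=scoring,
    )
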