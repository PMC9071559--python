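"""Variant calling and mutation-spectrum analysis for numt/organelle blocks.

Aligns homologous blocks (banded global alignment), calls SNVs with the
exclusion rules used for high-identity numt comparisons (indels,
multinucleotide variants, and short unalignable stretches adjacent to indels
are excluded), computes percent identity over the eligible columns, collapses
substitutions to the six strand-symmetric categories, assigns cytosine
contexts (CpG/CHG/CHH) on the organelle frame, and tests CpG+CHG enrichment
of C->T transitions with a 1-df goodness-of-fit chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._align import BandExceededError, BlockAlignment, Scoring, align_block, banded_align, global_align  # noqa: F401 (re-exported surface)
from ._seq import encode, revcomp

SPECTRUM_CATEGORIES = ("GC<>AT", "AT<>GC", "GC<>TA", "AT<>CG", "GC<>CG", "AT<>TA")

# direction organelle -> numt, strand-collapsed
_CATEGORY = {
    ("G", "A"): ("GC<>AT", True), ("C", "T"): ("GC<>AT", True),
    ("A", "G"): ("AT<>GC", True), ("T", "C"): ("AT<>GC", True),
    ("G", "T"): ("GC<>TA", False), ("C", "A"): ("GC<>TA", False),
    ("A", "C"): ("AT<>CG", False), ("T", "G"): ("AT<>CG", False),
    ("G", "C"): ("GC<>CG", False), ("C", "G"): ("GC<>CG", False),
    ("A", "T"): ("AT<>TA", False), ("T", "A"): ("AT<>TA", False),
}


class AlphabetError(ValueError):
    pass


class UndefinedIdentityError(ZeroDivisionError):
    """No eligible columns remain after exclusions."""


class ContextUndefinedError(ValueError):
    """Context requested at a non-cytosine position."""


@dataclass
class VariantRecord:
    """One called difference between the numt and the organelle reference.

    ``ref_allele`` is the organelle allele, ``alt_allele`` the numt allele
    (both on the aligned strand). ``excluded`` marks records that do not count
    toward SNV totals or percent identity, with ``reason`` in
    {mnv, indel, indel_adjacent, unalignable}.
    """

    numt_pos: int
    organelle_pos: int
    ref_allele: str
    alt_allele: str
    vtype: str  # 'snv' | 'mnv' | 'indel'
    excluded: bool = False
    reason: str | None = None
    spectrum_category: str | None = None
    transition: bool | None = None
    context: str = "n/a"

    def __post_init__(self):
        if self.vtype == "snv" and self.spectrum_category is None:
            cat, ts = classify_spectrum(self.ref_allele, self.alt_allele)
            self.spectrum_category = cat
            self.transition = ts


def classify_spectrum(ref_allele: str, alt_allele: str) -> tuple[str, bool]:
    """Strand-collapsed category and transition flag for an organelle->numt
    substitution."""
    key = (ref_allele.upper(), alt_allele.upper())
    if key[0] == key[1]:
        raise ValueError("ref and alt alleles are identical")
    if key not in _CATEGORY:
        raise AlphabetError(f"non-ACGT allele pair {key}")
    return _CATEGORY[key]


# ---------------------------------------------------------------------------
# variant calling
# ---------------------------------------------------------------------------

def _column_table(alignment: BlockAlignment):
    ops, ni, ri, nb, rb = [], [], [], [], []
    for op, i, j, n_base, r_base in alignment.columns():
        ops.append(op)
        ni.append(i)
        ri.append(j)
        nb.append(n_base)
        rb.append(r_base)
    return ops, ni, ri, nb, rb


def _excluded_column_mask(ops, nb, rb, adjacency_window: int) -> np.ndarray:
    """True for alignment columns excluded from the eligible set: gap columns,
    columns within ``adjacency_window`` of a gap column, N-containing columns,
    and multi-nucleotide (>=2 adjacent mismatch) columns."""
    ncols = len(ops)
    arr = np.zeros(ncols, dtype=bool)
    gap = np.array([op in "ID" for op in ops])
    arr |= gap
    if gap.any() and adjacency_window > 0:
        idx = np.flatnonzero(gap)
        for g in idx:
            lo = max(0, g - adjacency_window)
            hi = min(ncols, g + adjacency_window + 1)
            arr[lo:hi] = True
    for k in range(ncols):
        if (nb[k] == "N") or (rb[k] == "N"):
            arr[k] = True
    # MNV columns
    k = 0
    mism = [ops[k] == "X" and not ((nb[k] == "N") or (rb[k] == "N")) for k in range(ncols)]
    while k < ncols:
        if mism[k]:
            j = k
            while j < ncols and mism[j]:
                j += 1
            if j - k >= 2:
                arr[k:j] = True
            k = j
        else:
            k += 1
    return arr


def call_variants(alignment: BlockAlignment,
                  adjacency_window: int = 5) -> list[VariantRecord]:
    """Call SNV/MNV/indel records from a block alignment.

    Isolated mismatches become SNVs; runs of >=2 adjacent mismatch columns
    become one MNV (excluded); gap runs become indels (excluded); SNVs within
    ``adjacency_window`` columns of any gap column are excluded with reason
    ``indel_adjacent``. Columns containing N yield no records.
    """
    ops, ni, ri, nb, rb = _column_table(alignment)
    ncols = len(ops)
    n_off = alignment.numt_interval[0]
    r_off = alignment.reference_interval[0]
    gapcols = np.flatnonzero(np.array([op in "ID" for op in ops]))
    records: list[VariantRecord] = []

    def near_gap(k: int) -> bool:
        if gapcols.size == 0 or adjacency_window <= 0:
            return False
        i = np.searchsorted(gapcols, k)
        for cand in (i - 1, i):
            if 0 <= cand < gapcols.size and abs(int(gapcols[cand]) - k) <= adjacency_window:
                return True
        return False

    k = 0
    while k < ncols:
        op = ops[k]
        if op == "=":
            k += 1
            continue
        if op in "ID":
            j = k
            while j < ncols and ops[j] == op:
                j += 1
            if op == "D":
                ref = "".join(rb[k:j])
                alt = ""
            else:
                ref = ""
                alt = "".join(nb[k:j])
            records.append(VariantRecord(
                n_off + ni[k], r_off + ri[k], ref, alt, "indel",
                excluded=True, reason="indel"))
            k = j
            continue
        # mismatch run
        j = k
        while j < ncols and ops[j] == "X":
            j += 1
        has_n = any((nb[t] == "N") or (rb[t] == "N") for t in range(k, j))
        if has_n:
            k = j
            continue
        if j - k >= 2:
            records.append(VariantRecord(
                n_off + ni[k], r_off + ri[k],
                "".join(rb[k:j]), "".join(nb[k:j]), "mnv",
                excluded=True, reason="mnv"))
        else:
            rec = VariantRecord(n_off + ni[k], r_off + ri[k], rb[k], nb[k], "snv")
            if near_gap(k):
                rec.excluded = True
                rec.reason = "indel_adjacent"
            records.append(rec)
        k = j
    return records


def eligible_columns(alignment: BlockAlignment, adjacency_window: int = 5) -> int:
    """Aligned columns that count toward percent identity after exclusions."""
    ops, ni, ri, nb, rb = _column_table(alignment)
    excl = _excluded_column_mask(ops, nb, rb, adjacency_window)
    aligned = np.array([op in "=X" for op in ops])
    return int(np.count_nonzero(aligned & ~excl))


def percent_identity(variants: list[VariantRecord], aligned_length: int) -> float:
    """Identity over eligible columns: 1 - (non-excluded SNVs / eligible)."""
    if aligned_length <= 0:
        raise UndefinedIdentityError("no eligible columns")
    n_snv = sum(1 for v in variants if v.vtype == "snv" and not v.excluded)
    return 1.0 - n_snv / aligned_length


# ---------------------------------------------------------------------------
# spectrum table
# ---------------------------------------------------------------------------

@dataclass
class SpectrumTable:
    """Variant accounting in the layout of the published comparison table."""

    counts: dict[str, int] = field(default_factory=dict)
    snvs: int = 0
    transitions: int = 0
    transversions: int = 0
    mnvs: int = 0
    indels: int = 0
    numt_shorter: int = 0
    numt_longer: int = 0
    at_bias_ratio: float = float("nan")
    ratio_infinite: bool = False

    def to_dict(self) -> dict:
        d = {
            "total_snvs": self.snvs,
            "total_transitions": self.transitions,
            **{c: self.counts.get(c, 0) for c in ("GC<>AT", "AT<>GC")},
            "total_transversions": self.transversions,
            **{c: self.counts.get(c, 0) for c in ("GC<>TA", "AT<>CG", "GC<>CG", "AT<>TA")},
            "total_indels": self.indels,
            "numt_shorter": self.numt_shorter,
            "numt_longer": self.numt_longer,
            "mnvs_excluded": self.mnvs,
            "at_bias_ratio": None if self.ratio_infinite else self.at_bias_ratio,
        }
        return d

    def to_text(self) -> str:
        lines = ["Variant\tCount",
                 f"Total SNVs (Mitogenome<>numt)\t{self.snvs}",
                 f"Total transitions\t{self.transitions}",
                 f"  GC<>AT\t{self.counts.get('GC<>AT', 0)}",
                 f"  AT<>GC\t{self.counts.get('AT<>GC', 0)}",
                 f"Total transversions\t{self.transversions}",
                 f"  GC<>TA\t{self.counts.get('GC<>TA', 0)}",
                 f"  AT<>CG\t{self.counts.get('AT<>CG', 0)}",
                 f"  GC<>CG\t{self.counts.get('GC<>CG', 0)}",
                 f"  AT<>TA\t{self.counts.get('AT<>TA', 0)}",
                 f"Total indels\t{self.indels}",
                 f"  numt shorter\t{self.numt_shorter}",
                 f"  numt longer\t{self.numt_longer}",
                 ("AT-bias ratio (GC<>AT : AT<>GC transitions)\t"
                  + ("inf" if self.ratio_infinite else f"{self.at_bias_ratio:.2f}"))]
        return "\n".join(lines)


def spectrum_table(variants: list[VariantRecord]) -> SpectrumTable:
    """Tabulate non-excluded SNVs by category plus indel polarity totals."""
    tbl = SpectrumTable(counts={c: 0 for c in SPECTRUM_CATEGORIES})
    for v in variants:
        if v.vtype == "snv" and not v.excluded:
            tbl.counts[v.spectrum_category] += 1
            tbl.snvs += 1
            if v.transition:
                tbl.transitions += 1
            else:
                tbl.transversions += 1
        elif v.vtype == "mnv":
            tbl.mnvs += 1
        elif v.vtype == "indel":
            tbl.indels += 1
            if len(v.alt_allele) < len(v.ref_allele):
                tbl.numt_shorter += 1
            else:
                tbl.numt_longer += 1
    gcat = tbl.counts["GC<>AT"]
    atgc = tbl.counts["AT<>GC"]
    if atgc == 0:
        tbl.ratio_infinite = gcat > 0
        tbl.at_bias_ratio = float("inf") if gcat else float("nan")
    else:
        tbl.at_bias_ratio = gcat / atgc
    return tbl


# ---------------------------------------------------------------------------
# cytosine context
# ---------------------------------------------------------------------------

def classify_context(seq: str, pos: int, strand: str = "+",
                     circular: bool = True) -> str:
    """CpG / CHG / CHH context of the cytosine at ``(pos, strand)``.

    The next base downstream being G gives CpG; otherwise the next-next base
    being G gives CHG; otherwise CHH. ``circular`` wraps the window at the
    sequence ends; on linear sequences a truncated window returns 'unknown'.
    """
    L = len(seq)

    def at(i: int) -> str | None:
        if circular:
            return seq[i % L]
        if 0 <= i < L:
            return seq[i]
        return None

    if strand == "+":
        base, n1, n2 = at(pos), at(pos + 1), at(pos + 2)
    elif strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        base = comp.get(at(pos) or "N", "N")
        n1 = comp.get(at(pos - 1) or "", None) if at(pos - 1) else None
        n2 = comp.get(at(pos - 2) or "", None) if at(pos - 2) else None
    else:
        raise ValueError(f"bad strand {strand!r}")
    if base != "C":
        raise ContextUndefinedError(f"base at ({pos},{strand}) is {base}, not C")
    if n1 is None or n2 is None:
        return "unknown"
    if "N" in (n1, n2):
        return "unknown"
    if n1 == "G":
        return "CpG"
    if n2 == "G":
        return "CHG"
    return "CHH"


def variant_context(seq: str, pos: int, circular: bool = True) -> str:
    """Context at an organelle position on the strand where the base is C;
    'n/a' when the position is neither C nor G."""
    b = seq[pos % len(seq)] if circular else seq[pos]
    if b == "C":
        return classify_context(seq, pos, "+", circular)
    if b == "G":
        return classify_context(seq, pos, "-", circular)
    return "n/a"


def context_fractions(seq: str, circular: bool = True) -> dict[str, float]:
    """Fraction of all cytosines (both strands) in CpG / CHG / CHH context."""
    codes = encode(seq)
    from ._seq import C as _C, G as _G
    if circular:
        nxt1, nxt2 = np.roll(codes, -1), np.roll(codes, -2)
        prv1, prv2 = np.roll(codes, 1), np.roll(codes, 2)
    else:
        pad = np.full(2, 255, dtype=np.uint8)
        ext = np.concatenate([pad, codes, pad])
        nxt1, nxt2 = ext[3:3 + len(codes)], ext[4:4 + len(codes)]
        prv1, prv2 = ext[1:1 + len(codes)], ext[0:len(codes)]
    cmask = codes == _C
    gmask = codes == _G
    total = int(cmask.sum() + gmask.sum())
    if total == 0:
        raise ZeroDivisionError("sequence contains no cytosines")
    cpg = int((cmask & (nxt1 == _G)).sum() + (gmask & (prv1 == _C)).sum())
    chg = int((cmask & (nxt1 != _G) & (nxt2 == _G)).sum()
              + (gmask & (prv1 != _C) & (prv2 == _C)).sum())
    chh = total - cpg - chg
    return {"CpG": cpg / total, "CHG": chg / total, "CHH": chh / total}


def annotate_contexts(variants: list[VariantRecord], organelle_seq: str,
                      circular: bool = True) -> None:
    """Fill ``context`` in place for SNVs whose organelle allele is C or G,
    evaluated on the organelle sequence at the organelle position (the
    ancestral state defines the mutational context)."""
    for v in variants:
        if v.vtype != "snv":
            continue
        if v.ref_allele in ("C", "G"):
            v.context = variant_context(organelle_seq, v.organelle_pos, circular)
        else:
            v.context = "n/a"


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    observed_in: int
    observed_out: int
    expected_fraction: float
    chi2: float
    p_value: float
    small_expected: bool = False

    def to_dict(self) -> dict:
        return {
            "observed_in": self.observed_in,
            "observed_out": self.observed_out,
            "expected_fraction": self.expected_fraction,
            "chi2": self.chi2,
            "p_value": self.p_value,
            "small_expected": self.small_expected,
        }


def context_enrichment(observed_in: int, observed_out: int,
                       expected_fraction: float) -> EnrichmentResult:
    """1-df goodness-of-fit chi-square of an in/out split against an expected
    fraction (e.g. C->T SNVs in CpG+CHG context vs the genomic cytosine
    fraction)."""
    if observed_in < 0 or observed_out < 0:
        raise ValueError("counts must be nonnegative")
    n = observed_in + observed_out
    if n == 0:
        raise ValueError("total count must be positive")
    if not 0.0 < expected_fraction < 1.0:
        raise ValueError("expected_fraction must lie in (0,1)")
    e_in = n * expected_fraction
    e_out = n - e_in
    chi2 = (observed_in - e_in) ** 2 / e_in + (observed_out - e_out) ** 2 / e_out
    p = float(stats.chi2.sf(chi2, df=1))
    return EnrichmentResult(observed_in, observed_out, expected_fraction,
                            float(chi2), p, small_expected=min(e_in, e_out) < 1)


# ---------------------------------------------------------------------------
# plain-text output
# ---------------------------------------------------------------------------

def write_variants_vcf(path, variants: list[VariantRecord],
                       chrom: str = "numt") -> None:
    """Minimal single-sample-free VCF; POS is 1-based; INFO carries the
    organelle position, category, context and exclusion reason."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=OPOS,Number=1,Type=Integer,Description="Organelle position (1-based)">\n')
        fh.write('##INFO=<ID=VT,Number=1,Type=String,Description="Variant type">\n')
        fh.write('##INFO=<ID=CAT,Number=1,Type=String,Description="Spectrum category">\n')
        fh.write('##INFO=<ID=CTX,Number=1,Type=String,Description="Cytosine context">\n')
        fh.write('##INFO=<ID=EXCL,Number=1,Type=String,Description="Exclusion reason">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda x: x.numt_pos):
            info = [f"OPOS={v.organelle_pos + 1}", f"VT={v.vtype}"]
            if v.spectrum_category:
                info.append(f"CAT={v.spectrum_category}")
            if v.context != "n/a":
                info.append(f"CTX={v.context}")
            if v.excluded:
                info.append(f"EXCL={v.reason}")
            ref = v.ref_allele or "."
            alt = v.alt_allele or "."
            filt = "excluded" if v.excluded else "PASS"
            fh.write(f"{chrom}\t{v.numt_pos + 1}\t.\t{ref}\t{alt}\t.\t{filt}\t"
                     + ";".join(info) + "\n")


def write_variants_tsv(path, variants: list[VariantRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("numt_pos\torganelle_pos\tref\talt\tvtype\texcluded\treason\t"
                 "category\ttransition\tcontext\n")
        for v in sorted(variants, key=lambda x: x.numt_pos):
            fh.write("\t".join(str(x) for x in (
                v.numt_pos, v.organelle_pos, v.ref_allele or ".", v.alt_allele or ".",
                v.vtype, int(v.excluded), v.reason or ".",
                v.spectrum_category or ".", "." if v.transition is None else int(v.transition),
                v.context)) + "\n")
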