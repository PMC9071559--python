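"""Diagnostic-SNV read partitioning and windowed methylation profiles.

Non-excluded SNVs distinguishing the numt from the organelle genome are the
diagnostic sites; long reads are classified as numt- or organelle-derived
from the alleles they carry at covered sites, the read set is partitioned,
and per-context (CpG/CHG/CHH) methylation percentages are pooled over tiling
windows before and after organelle-read exclusion. Spanning reads anchored
by flanking diagnostic alleles provide a majority consensus to validate
numt regions that are identical to the organelle genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .varspec import VariantRecord

CONTEXTS = ("CpG", "CHG", "CHH")
ORIGINS = ("numt", "organelle", "ambiguous", "uninformative")


class ConsistencyError(ValueError):
    pass


class CoordinateError(ValueError):
    pass


class InsufficientCoverageError(RuntimeError):
    pass


@dataclass(frozen=True)
class DiagnosticSite:
    numt_pos: int
    organelle_pos: int
    numt_allele: str
    organelle_allele: str

    def __post_init__(self):
        if self.numt_allele == self.organelle_allele:
            raise ValueError("diagnostic site alleles must differ")


@dataclass
class ReadObservation:
    read_id: str
    interval: tuple[int, int]  # aligned interval, numt coordinates
    alleles: dict[int, str] = field(default_factory=dict)  # site pos -> observed base
    meth_calls: list[tuple[int, str, int]] = field(default_factory=list)
    sequence: str | None = None

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]


@dataclass
class ReadClassification:
    read_id: str
    numt_support: int
    organelle_support: int
    origin: str


@dataclass
class WindowProfile:
    window: tuple[int, int]
    context: str
    methylated_calls: int
    total_calls: int

    @property
    def percent(self) -> float | None:
        if self.total_calls == 0:
            return None
        return 100.0 * self.methylated_calls / self.total_calls

    @property
    def no_data(self) -> bool:
        return self.total_calls == 0


def observation_from_sim_read(read) -> ReadObservation:
    """Adapter from a simulator read to a generic observation."""
    return ReadObservation(read.read_id, (read.start, read.end),
                           dict(read.alleles), list(read.meth_calls),
                           read.sequence)


# ---------------------------------------------------------------------------
# diagnostic sites
# ---------------------------------------------------------------------------

def derive_diagnostic_sites(variants: list[VariantRecord]) -> list[DiagnosticSite]:
    """Non-excluded SNVs, sorted by numt position, deduplicated."""
    by_pos: dict[int, DiagnosticSite] = {}
    for v in variants:
        if v.vtype != "snv" or v.excluded:
            continue
        by_pos[v.numt_pos] = DiagnosticSite(v.numt_pos, v.organelle_pos,
                                            v.alt_allele, v.ref_allele)
    if not by_pos:
        warnings.warn("no usable SNVs: empty diagnostic site list")
    return [by_pos[p] for p in sorted(by_pos)]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_read(obs: ReadObservation, sites: list[DiagnosticSite],
                  min_sites: int = 2) -> ReadClassification:
    """Assign a read origin from its alleles at covered diagnostic sites.

    numt: >= ``min_sites`` numt alleles and zero organelle alleles (and
    symmetrically for organelle); ambiguous: at least one of each;
    uninformative otherwise. Alleles matching neither expectation (errors)
    support neither side; observations at positions absent from the site
    list (e.g. filtered upstream) are ignored.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    site_map = {s.numt_pos: s for s in sites}
    numt_sup = org_sup = 0
    for pos, allele in obs.alleles.items():
        site = site_map.get(pos)
        if site is None:
            continue
        if not (obs.start <= pos < obs.end):
            raise ConsistencyError(
                f"read {obs.read_id} observes allele outside its interval at {pos}")
        if allele == site.numt_allele:
            numt_sup += 1
        elif allele == site.organelle_allele:
            org_sup += 1
    if numt_sup >= 1 and org_sup >= 1:
        origin = "ambiguous"
    elif numt_sup >= min_sites:
        origin = "numt"
    elif org_sup >= min_sites:
        origin = "organelle"
    else:
        origin = "uninformative"
    return ReadClassification(obs.read_id, numt_sup, org_sup, origin)


def partition_reads(observations: list[ReadObservation],
                    sites: list[DiagnosticSite],
                    min_sites: int = 2) -> dict[str, set[str]]:
    """Partition read ids into four disjoint, exhaustive origin sets."""
    seen: dict[str, ReadObservation] = {}
    for obs in observations:
        if obs.read_id in seen:
            prev = seen[obs.read_id]
            if prev.interval != obs.interval or prev.alleles != obs.alleles:
                raise ConsistencyError(
                    f"duplicate read id {obs.read_id} with conflicting observations")
            continue
        seen[obs.read_id] = obs
    parts: dict[str, set[str]] = {o: set() for o in ORIGINS}
    for obs in seen.values():
        parts[classify_read(obs, sites, min_sites).origin].add(obs.read_id)
    return parts


# ---------------------------------------------------------------------------
# methylation profiles
# ---------------------------------------------------------------------------

def methylation_profile(calls, region_length: int, window: int,
                        contexts=CONTEXTS,
                        exclude_reads: set[str] | None = None) -> list[WindowProfile]:
    """Calls-weighted per-context methylation percent over tiling windows.

    ``calls``: iterable of ``(read_id, pos, context, methylated)`` or a
    DataFrame with those columns. The last window may be short; windows with
    zero calls are kept with ``percent`` None (flagged, not zero-filled).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if isinstance(calls, pd.DataFrame):
        df = calls[["read_id", "pos", "context", "methylated"]].copy()
    else:
        df = pd.DataFrame(list(calls),
                          columns=["read_id", "pos", "context", "methylated"])
    if len(df) and ((df["pos"] < 0) | (df["pos"] >= region_length)).any():
        bad = df.loc[(df["pos"] < 0) | (df["pos"] >= region_length), "pos"].iloc[0]
        raise CoordinateError(f"call position {bad} outside region [0,{region_length})")
    if exclude_reads:
        df = df[~df["read_id"].isin(exclude_reads)]
    n_windows = max(1, -(-region_length // window))
    profiles: list[WindowProfile] = []
    if len(df):
        df["win"] = df["pos"] // window
        grouped = df.groupby(["win", "context"])["methylated"].agg(["sum", "count"])
    else:
        grouped = None
    for w in range(n_windows):
        lo = w * window
        hi = min(region_length, lo + window)
        for ctx in contexts:
            if grouped is not None and (w, ctx) in grouped.index:
                row = grouped.loc[(w, ctx)]
                profiles.append(WindowProfile((lo, hi), ctx, int(row["sum"]),
                                              int(row["count"])))
            else:
                profiles.append(WindowProfile((lo, hi), ctx, 0, 0))
    return profiles


# ---------------------------------------------------------------------------
# anchored spanning-read consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    consensus: str
    matches_assembly: bool
    mismatch_positions: list[int]
    n_reads: int


def anchored_consensus(observations: list[ReadObservation],
                       interval: tuple[int, int],
                       sites: list[DiagnosticSite], assembly: str,
                       min_span_reads: int = 3) -> ConsensusResult:
    """Majority consensus of reads spanning ``interval`` that are anchored to
    the numt by a numt allele at >= 1 diagnostic site on each side.

    Used to validate regions of the assembly with no internal diagnostic
    variation (identical to the organelle or to another numt copy): the flag
    is True iff the consensus equals the assembly substring.
    """
    lo, hi = interval
    if not (0 <= lo < hi <= len(assembly)):
        raise CoordinateError("interval outside the assembly")
    spanning = []
    for obs in observations:
        if obs.sequence is None or obs.start > lo or obs.end < hi:
            continue
        left = right = False
        for pos, allele in obs.alleles.items():
            site = next((s for s in sites if s.numt_pos == pos), None)
            if site is None or allele != site.numt_allele:
                continue
            if obs.start <= pos < lo:
                left = True
            elif hi <= pos < obs.end:
                right = True
        if left and right:
            spanning.append(obs)
    if len(spanning) < min_span_reads:
        raise InsufficientCoverageError(
            f"only {len(spanning)} anchored spanning reads (need {min_span_reads})")
    cols = np.zeros((hi - lo, 4), dtype=np.int64)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for obs in spanning:
        seg = obs.sequence[lo - obs.start: hi - obs.start]
        for i, b in enumerate(seg):
            if b in base_idx:
                cols[i, base_idx[b]] += 1
    order = "ACGT"
    consensus = "".join(order[int(np.argmax(cols[i]))] for i in range(hi - lo))
    target = assembly[lo:hi]
    mismatches = [lo + i for i in range(hi - lo) if consensus[i] != target[i]]
    return ConsensusResult(consensus, not mismatches, mismatches, len(spanning))


# ---------------------------------------------------------------------------
# plain-text IO
# ---------------------------------------------------------------------------

def read_observations_tsv(path) -> list[ReadObservation]:
    """Observations TSV (read_id, start, end, pos, allele; extra columns
    ignored), one row per covered diagnostic site."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, ReadObservation] = {}
    for row in df.itertuples(index=False):
        obs = out.setdefault(row.read_id, ReadObservation(
            row.read_id, (int(row.start), int(row.end))))
        obs.alleles[int(row.pos)] = str(row.allele)
    return list(out.values())


def read_meth_tsv(path) -> pd.DataFrame:
    """Methylation calls TSV with columns read_id, pos, context, methylated."""
    df = pd.read_csv(path, sep="\t")
    return df[["read_id", "pos", "context", "methylated"]]


def write_partition(path, parts: dict[str, set[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\torigin\n")
        for origin in ORIGINS:
            for rid in sorted(parts.get(origin, ())):
                fh.write(f"{rid}\t{origin}\n")


def write_profiles_tsv(path, profiles: list[WindowProfile]) -> None:
    """Windowed percentages (calls-weighted pooling, stated in the header)."""
    with open(path, "w") as fh:
        fh.write("# methylation percent = 100 * methylated_calls / total_calls per window (calls-weighted)\n")
        fh.write("start\tend\tcontext\tmethylated\ttotal\tpercent\n")
        for p in profiles:
            pct = "NA" if p.percent is None else f"{p.percent:.3f}"
            fh.write(f"{p.window[0]}\t{p.window[1]}\t{p.context}\t"
                     f"{p.methylated_calls}\t{p.total_calls}\t{pct}\n")


def write_bedgraph(path, profiles: list[WindowProfile], context: str,
                   chrom: str = "numt") -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{context} methylation"\n')
        for p in profiles:
            if p.context == context and not p.no_data:
                fh.write(f"{chrom}\t{p.window[0]}\t{p.window[1]}\t{p.percent:.3f}\n")
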