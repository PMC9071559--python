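"""End-to-end orchestration: one config in, a structured report out.

Stages run in dependency order (synteny -> variants/spectrum/enrichment ->
duplication history -> read partitioning/methylation), each writing its
outputs before the next starts; the report aggregates the summary quantities
of the analysis. Reruns with identical config and inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from . import duphistory, readpart, simgenome, synteny, varspec

logger = logging.getLogger("numtscope")

# published summary values for the side-by-side reproduction table
REFERENCE_VALUES = {
    "percent_identity": 99.933,
    "total_snvs": 425,
    "total_transitions": 270,
    "total_indels": 44,
    "at_bias_ratio": 6.7,
    "ct_in_cpg_chg": 175,
    "ct_total": 235,
    "enrichment_chi2": 178.9,
    "shared_pair_variants": 34,
    "copy_copy_divergence_pct": 0.095,
    "copy_organelle_divergence_pct": 0.065,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class PipelineConfig:
    numt_fasta: str
    organelle_fasta: str
    outdir: str
    repeats_bed: str | None = None
    observations_tsv: str | None = None
    meth_tsv: str | None = None
    seed: int = 0
    k: int = 31
    min_block: int = 500
    tolerance: int = 50
    adjacency_window: int = 5
    min_copies: int = 3
    min_copy_len: int = 2000
    min_dup_span: int = 5000
    min_sites: int = 2
    min_read_length: int = 0
    nsim: int = 10_000
    windows: tuple[int, ...] = (50_000, 1_000)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["windows"] = tuple(data.get("windows", (50_000, 1_000)))
        return cls(**data)

    def validate(self) -> None:
        for attr in ("numt_fasta", "organelle_fasta"):
            if not Path(getattr(self, attr)).exists():
                raise FileNotFoundError(f"{attr}: {getattr(self, attr)}")
        for attr in ("repeats_bed", "observations_tsv", "meth_tsv"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        if self.k < 15 or self.min_block < 1 or self.min_sites < 1:
            raise ValueError("parameter out of documented range")


@dataclass
class AnalysisReport:
    numt_length: int = 0
    block_count: int = 0
    breakpoint_classes: dict[str, int] = field(default_factory=dict)
    conformations: dict[str, list[str]] = field(default_factory=dict)
    spectrum: dict = field(default_factory=dict)
    percent_identity: float | None = None
    eligible_columns: int = 0
    enrichment: dict | None = None
    cpg_chg_cytosine_fraction: float | None = None
    divergence_means: dict[str, float] = field(default_factory=dict)
    shared_variant_count: int = 0
    duplication: dict | None = None
    partition_sizes: dict[str, int] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))

    def to_text(self) -> str:
        lines = [
            "numtscope analysis report",
            f"numt length:            {self.numt_length}",
            f"synteny blocks:         {self.block_count}",
            f"breakpoints:            {self.breakpoint_classes}",
            f"conformations:          {self.conformations}",
            f"eligible columns:       {self.eligible_columns}",
        ]
        if self.percent_identity is not None:
            lines.append(f"percent identity:       {100 * self.percent_identity:.3f}%")
        lines.append(f"spectrum:               {self.spectrum}")
        if self.enrichment:
            lines.append(f"CpG+CHG enrichment:     chi2={self.enrichment['chi2']:.1f} "
                         f"p={self.enrichment['p_value']:.3g}")
        lines += [
            f"divergence means:       {self.divergence_means}",
            f"shared-pair variants:   {self.shared_variant_count}",
            f"duplication:            {self.duplication}",
            f"read partition:         {self.partition_sizes}",
        ]
        return "\n".join(lines)


def _read_single_fasta(path) -> str:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise ValueError(f"no FASTA records in {path}")
    return str(recs[0].seq).upper()


def read_repeats_bed(path) -> list[simgenome.RepeatPair]:
    """Repeat pairs from BED: two rows per pair sharing the name field."""
    rows: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            rows.setdefault(f[3].strip(), []).append((int(f[1]), int(f[2])))
    pairs = []
    for name, ivs in rows.items():
        if len(ivs) != 2:
            raise ValueError(f"repeat {name}: expected 2 BED rows, got {len(ivs)}")
        c1, c2 = sorted(ivs)
        pairs.append(simgenome.RepeatPair(name, c1, c2))
    return pairs


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full(config: PipelineConfig) -> AnalysisReport:
    """Run every stage on the configured inputs and write all artifacts.

    On a stage failure the error is re-raised as :class:`StageError` naming
    the stage, and a FAILED marker file is left in the output directory
    alongside any partial outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = AnalysisReport()
    stage = "setup"
    try:
        numt = _read_single_fasta(config.numt_fasta)
        org_seq = _read_single_fasta(config.organelle_fasta)
        pairs = read_repeats_bed(config.repeats_bed) if config.repeats_bed else []
        genome = simgenome.OrganelleGenome(org_seq, pairs)
        report.numt_length = len(numt)
        report.provenance = {
            "numt_fasta": {"path": str(config.numt_fasta), "sha256": _sha256(config.numt_fasta)},
            "organelle_fasta": {"path": str(config.organelle_fasta),
                                "sha256": _sha256(config.organelle_fasta)},
            "seed": config.seed,
        }

        stage = "synteny"
        logger.info("stage=%s numt=%dbp organelle=%dbp", stage, len(numt), genome.length)
        blocks = synteny.decompose_synteny(numt, genome, k=config.k,
                                           min_block=config.min_block)
        breakpoints = synteny.classify_breakpoints(blocks, genome, config.tolerance)
        synteny.write_blocks_paf(outdir / "blocks.paf", blocks, len(numt), genome)
        synteny.write_breakpoints_bed(outdir / "breakpoints.bed", breakpoints)
        report.block_count = len(blocks)
        for bp in breakpoints:
            report.breakpoint_classes[bp.klass] = report.breakpoint_classes.get(bp.klass, 0) + 1
        confs = {}
        for rp in genome.repeat_pairs:
            cs = synteny.detect_repeat_conformations(blocks, rp, genome, config.tolerance)
            confs[rp.name] = sorted(cs.present)
        (outdir / "conformations.json").write_text(json.dumps(confs, indent=1))
        report.conformations = confs

        stage = "variants"
        logger.info("stage=%s blocks=%d", stage, len(blocks))
        variants: list[varspec.VariantRecord] = []
        eligible = 0
        for b in blocks:
            s, e = b.organelle_interval
            ref_sub = genome.slice(s, e)
            if b.orientation == "-":
                from ._seq import revcomp
                ref_sub = revcomp(ref_sub)
            aln = varspec.align_block(numt[b.numt_interval[0]:b.numt_interval[1]],
                                      ref_sub, numt_interval=b.numt_interval)
            block_vars = varspec.call_variants(aln, config.adjacency_window)
            # map reference-local coordinates back to organelle (+) coords
            for v in block_vars:
                local = v.organelle_pos
                if b.orientation == "+":
                    v.organelle_pos = (s + local) % genome.length
                else:
                    v.organelle_pos = (e - 1 - local) % genome.length
            eligible += varspec.eligible_columns(aln, config.adjacency_window)
            variants.extend(block_vars)
        varspec.annotate_contexts(variants, genome.sequence)
        varspec.write_variants_vcf(outdir / "variants.vcf", variants)
        varspec.write_variants_tsv(outdir / "variants.tsv", variants)
        tbl = varspec.spectrum_table(variants)
        (outdir / "spectrum.json").write_text(json.dumps(tbl.to_dict(), indent=1))
        (outdir / "spectrum.txt").write_text(
            tbl.to_text() + f"\n# adjacency window: {config.adjacency_window} columns\n")
        report.spectrum = tbl.to_dict()
        report.eligible_columns = eligible
        if eligible:
            report.percent_identity = varspec.percent_identity(variants, eligible)

        stage = "enrichment"
        fr = varspec.context_fractions(genome.sequence)
        report.cpg_chg_cytosine_fraction = fr["CpG"] + fr["CHG"]
        ct = [v for v in variants
              if v.vtype == "snv" and not v.excluded and v.spectrum_category == "GC<>AT"
              and v.context in ("CpG", "CHG", "CHH")]
        n_in = sum(1 for v in ct if v.context in ("CpG", "CHG"))
        n_out = len(ct) - n_in
        if ct:
            enr = varspec.context_enrichment(n_in, n_out, fr["CpG"] + fr["CHG"])
            report.enrichment = enr.to_dict()
            (outdir / "enrichment.json").write_text(json.dumps(enr.to_dict(), indent=1))

        stage = "duphistory"
        groups = duphistory.extract_repeat_copies(blocks, config.min_copies,
                                                  config.min_copy_len)
        logger.info("stage=%s groups=%d", stage, len(groups))
        all_patterns = []
        cc, co = [], []
        dup_model = duphistory.DuplicationModel(None, None, 0, 0, "inconclusive")
        for gi, group in enumerate(groups):
            aln = duphistory.align_copies(group, numt, genome)
            div = duphistory.pairwise_divergence(aln)
            duphistory.write_divergence_tsv(outdir / f"divergence_group{gi}.tsv", div)
            cc.append(div.mean_copy_copy())
            co.append(div.mean_copy_organelle())
            patterns = duphistory.detect_shared_variants(aln)
            all_patterns.extend(patterns)
            duphistory.write_patterns_tsv(outdir / f"patterns_group{gi}.tsv", patterns)
        shared = [p for p in all_patterns if p.pattern_class == "shared_pair"]
        report.shared_variant_count = len(shared)
        if groups:
            import numpy as np
            report.divergence_means = {
                "copy_copy": float(np.nanmean(cc)) if cc else float("nan"),
                "copy_organelle": float(np.nanmean(co)) if co else float("nan"),
            }
            dup_model = duphistory.infer_tandem_duplication(
                all_patterns, blocks, min_span=config.min_dup_span)
        report.duplication = dup_model.to_dict()
        (outdir / "duplication.json").write_text(json.dumps(dup_model.to_dict(), indent=1))

        stage = "readpart"
        if config.observations_tsv:
            obs = readpart.read_observations_tsv(config.observations_tsv)
            if config.min_read_length:
                obs = [o for o in obs if o.end - o.start >= config.min_read_length]
            sites = readpart.derive_diagnostic_sites(variants)
            parts = readpart.partition_reads(obs, sites, config.min_sites)
            readpart.write_partition(outdir / "partition.tsv", parts)
            report.partition_sizes = {k: len(v) for k, v in parts.items()}
            if config.meth_tsv:
                calls = readpart.read_meth_tsv(config.meth_tsv)
                exclude = parts["organelle"] | parts["ambiguous"]
                for w in config.windows:
                    pre = readpart.methylation_profile(calls, len(numt), w)
                    post = readpart.methylation_profile(calls, len(numt), w,
                                                        exclude_reads=exclude)
                    readpart.write_profiles_tsv(outdir / f"meth_{w}_all.tsv", pre)
                    readpart.write_profiles_tsv(outdir / f"meth_{w}_numt.tsv", post)

        stage = "report"
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "report.txt").write_text(report.to_text() + "\n")
        return report
    except Exception as err:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {err}\n")
        raise StageError(stage, err) from err


# ---------------------------------------------------------------------------
# accession-driven reproduction (optional; needs network unless paths given)
# ---------------------------------------------------------------------------

_EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
           "?db=nuccore&id={acc}&rettype=fasta&retmode=text")


def _fetch_fasta(accession: str, dest: Path) -> Path:
    import urllib.request
    url = _EFETCH.format(acc=accession)
    try:
        with urllib.request.urlopen(url, timeout=120) as resp:
            dest.write_bytes(resp.read())
    except Exception as err:
        raise RuntimeError(
            f"could not fetch {accession} from NCBI ({err}); download the "
            f"FASTA manually and pass it as a local path") from err
    return dest


def reproduce_paper(outdir, numt_fasta=None, organelle_fasta=None,
                    numt_accession: str = "ON220560",
                    organelle_accession: str = "NC_037304.1",
                    **config_kwargs) -> AnalysisReport:
    """Run the full analysis on the published numt/mitogenome pair and print
    a side-by-side table against the published summary values.

    Local FASTA paths take precedence; otherwise the accessions are fetched
    from NCBI (network required). Never needed by the offline test suite.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if numt_fasta is None:
        numt_fasta = _fetch_fasta(numt_accession, outdir / f"{numt_accession}.fasta")
    if organelle_fasta is None:
        organelle_fasta = _fetch_fasta(organelle_accession,
                                       outdir / f"{organelle_accession}.fasta")
    cfg = PipelineConfig(str(numt_fasta), str(organelle_fasta),
                         str(outdir / "analysis"), **config_kwargs)
    report = run_full(cfg)
    rows = [
        ("percent identity (%)",
         None if report.percent_identity is None else 100 * report.percent_identity,
         REFERENCE_VALUES["percent_identity"]),
        ("total SNVs", report.spectrum.get("total_snvs"), REFERENCE_VALUES["total_snvs"]),
        ("transitions", report.spectrum.get("total_transitions"),
         REFERENCE_VALUES["total_transitions"]),
        ("indels", report.spectrum.get("total_indels"), REFERENCE_VALUES["total_indels"]),
        ("AT-bias ratio", report.spectrum.get("at_bias_ratio"),
         REFERENCE_VALUES["at_bias_ratio"]),
        ("CpG+CHG C->T / total C->T",
         None if not report.enrichment else
         f"{report.enrichment['observed_in']}/{report.enrichment['observed_in'] + report.enrichment['observed_out']}",
         f"{REFERENCE_VALUES['ct_in_cpg_chg']}/{REFERENCE_VALUES['ct_total']}"),
        ("enrichment chi2", None if not report.enrichment else report.enrichment["chi2"],
         REFERENCE_VALUES["enrichment_chi2"]),
        ("shared-pair variants", report.shared_variant_count,
         REFERENCE_VALUES["shared_pair_variants"]),
        ("copy-copy divergence (%)",
         100 * report.divergence_means.get("copy_copy", float("nan")),
         REFERENCE_VALUES["copy_copy_divergence_pct"]),
        ("copy-organelle divergence (%)",
         100 * report.divergence_means.get("copy_organelle", float("nan")),
         REFERENCE_VALUES["copy_organelle_divergence_pct"]),
    ]
    width = max(len(r[0]) for r in rows)
    lines = [f"{'quantity'.ljust(width)}  {'this run':>12}  {'published':>12}"]
    for name, got, ref in rows:
        g = "NA" if got is None else (f"{got:.4g}" if isinstance(got, float) else str(got))
        lines.append(f"{name.ljust(width)}  {g:>12}  {str(ref):>12}")
    table = "\n".join(lines)
    print(table)
    (outdir / "comparison.txt").write_text(table + "\n")
    return report
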