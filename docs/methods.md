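# Methods

This note documents the models and procedures behind numtscope, the
parameters that matter, the numerical choices, and what the simulation-based
tests do and do not establish about real data.

## The analysis problem

A numt is a nuclear copy of organelle DNA. A large, recent numt is nearly
identical to its source mitogenome, so its structure and history must be
read out of three weak signals: (i) where collinearity with the organelle
genome breaks (insertion-time fusions, repeat-mediated rearrangements, later
duplications), (ii) the spectrum and sequence context of the few hundred
substitutions that have accumulated, and (iii) the sharing pattern of
derived alleles among repeated copies within the numt. numtscope implements
each step so the whole chain is testable against simulated ground truth.

## Synteny decomposition

Anchors are k-mers (default k = 31) that occur exactly once in the circular
organelle genome counting both strands. Anchors found in the numt are
chained greedily: an anchor extends the current chain when it has the same
strand, lies within `max_gap` (default 20 kb) on the numt, and its unwrapped
organelle coordinate deviates from the chain diagonal by at most
`base_slack + 50 bp per 10 kb` (defaults 25 bp + drift), which tolerates the
indel drift expected at ≤0.5% divergence. Chains spanning ≥ `min_block`
(default 500 bp — below the small repeat sizes, so small-repeat-mediated
events remain visible) become blocks.

Repeat interiors are anchorless (their k-mers are not unique), so block
boundaries inside repeats are resolved by flank information: each block is
extended along its diagonal by greedy X-drop scoring (+1 match, −3 mismatch,
drop 12), and where neighbouring extensions overlap, the junction is placed
at the split maximizing the number of matching columns on each side (ties
take the lowest coordinate). Within an identical repeat both diagonals match
every column, so the split — and hence the junction coordinate of a
repeat-mediated breakpoint — is ambiguous by homology, a property of the
data rather than of the algorithm. Tests therefore score NHEJ junction
positions (error ≤ k in practice; observed ≤3 bp) but score repeat-mediated
junctions by class and mediating pair.

A junction is **repeat_mediated** when the left block's traversal ends and
the right block's traversal resumes at homologous offsets (within
`tolerance`, default 50 bp) of two different copies of one annotated repeat
pair; **nhej** when the flanking organelle intervals are disjoint beyond the
tolerance; **unknown** otherwise. The 50-bp tolerance is a package choice —
there is no published quantitative criterion for "at a repeat" — and is
stated in outputs.

Conformations across a repeat pair are labelled by flank pairing: copy 1's
flanks are A (upstream) and B (downstream), copy 2's are A′/B′. A block that
spans a copy with flanking sequence on both sides realizes the parental
pairing; a repeat-mediated junction realizes the recombinant pairing of the
entered copy's upstream flank with the exited copy's downstream flank
(swapped for '−' traversals).

## Alignment and variant calling

Blocks are aligned to their organelle homolog with a banded three-state
Gotoh DP: match +1, mismatch −2, gap open −4, gap extend −1 (a gap of length
L costs 4 + L). These defaults are chosen to behave like a global aligner at
≥99% identity and are not tuned to any particular published matrix. The band
covers diagonals within `band` of the corridor between (0,0) and (n,m).
After filling, a certificate bounds the score of any path through a
band-edge cell (its score, plus one match per remaining diagonal step, minus
one gap back to the end corner); if the bound beats the in-band optimum the
band doubles, up to full coverage — so the returned alignment is the global
optimum, verified in tests against an independent exhaustive aligner.

Variant calling mirrors the exclusion rules used for high-identity numt
comparisons: isolated mismatch columns are SNVs; runs of ≥2 adjacent
mismatch columns are one multi-nucleotide variant (excluded); gap runs are
indels (excluded); SNVs within `adjacency_window` (default 5) columns of any
gap column are excluded as `indel_adjacent` — the window size is a package
choice for the published-but-unquantified "short unalignable sequences
adjacent to indel regions", exposed as a flag and stated in the identity
report. Columns containing N are excluded and never become variants.
Percent identity is 1 − (non-excluded SNVs / eligible columns), where
eligible columns exclude gap columns, the adjacency windows around them, MNV
columns and N columns.

Substitutions are collapsed to six strand-symmetric categories in the
organelle→numt direction. Cytosine context is evaluated on the organelle
sequence at the organelle position, on the strand where the organelle allele
is C (the ancestral state defines the mutational context): next base G →
CpG, else next-next base G → CHG, else CHH, with circular wrap. Context
enrichment is a 1-df goodness-of-fit χ² of the CpG+CHG / CHH split of C→T
SNVs against the genomic fraction of cytosines in CpG or CHG context, with a
small-expected-count flag below 1.

MNVs are excluded from SNV totals and reported separately; whether published
SNV totals count MNV bases individually is not determinable from the text,
and the alternative convention would add the MNV column counts to the
totals.

## Duplication history

Organelle regions covered by ≥ `min_copies` (default 3) blocks of length ≥
`min_copy_len` are intersected to their common core. Each copy is aligned
pairwise to the organelle homolog and projected onto organelle columns —
reference-guided rather than a heuristic multiple alignment, which is
lossless for copies ≥99% identical except at copy-specific insertions, kept
as side records. Pairwise divergence is mismatches over columns where both
rows are ungapped. Polymorphic SNV columns (gap columns ignored) are
classified: `shared_pair` means exactly two copies share an allele absent
from the organelle while the rest match it.

The star-phylogeny test asks whether the observed shared-pair count could be
homoplasy. The null simulates each copy mutating independently at its
observed copy-vs-organelle rate, alt alleles uniform over the three
alternatives (a deliberate simplification; a transition-biased alt choice
would raise the null expectation by at most 3×, which does not matter at the
observed orders of magnitude — expectation ≪ 1 vs tens observed). The
Monte-Carlo p-value is add-one corrected (so `n_sim ≥ 1999` is needed to
resolve p < 0.001, the verdict threshold); a randomized (probability
integral transform) p-value is also reported because the statistic is a
small discrete count, whose conservative p-values are super-uniform by
construction — the calibration test checks uniformity of the randomized
version. Closed-form expectation `Σ_pairs L·p_i·p_j·Π(1−p_k)/3` cross-checks
the simulation.

Tandem-duplication inference takes the copy-pairing supported by the most
shared-pair patterns as the daughter pair; patterns pairing other copies are
conflicting (candidate gene conversion). A duplication verdict additionally
requires ≥ `min_support` (3) consistent patterns spanning ≥ `min_dup_span`
(default 5 kb at full scale; scaled configs should scale it), because a
tight cluster of shared alleles is the signature of a localized conversion
tract, not a duplication — such cases return `inconclusive`. The duplicated
interval is the span of consistent patterns extended to block boundaries;
the central breakpoint is the block edge nearest the midpoint between the
daughters. Only single tandem duplications are searched; nested or multiple
events return `inconclusive` with diagnostics. Shared variants cannot fully
distinguish pervasive gene conversion from duplication; the model reports
supporting and conflicting counts and never claims to resolve that.

## Read partitioning and methylation

Diagnostic sites are the non-excluded SNVs. A read's support is the number
of covered sites carrying each allele; origin is `numt` if numt-support ≥
`min_sites` (default 2) with zero organelle alleles, symmetrically
`organelle`, `ambiguous` if both alleles are seen (excluded from both
partitions), else `uninformative`. The published pipeline's "duplicate IDs
(>2)" filter is ambiguous between ≥2 and ≥3; `min_sites` makes the
strictness a visible tunable rather than a hidden constant. Raising
`min_sites` can only move reads toward `uninformative` (tested property).

Window profiles pool calls (calls-weighted, not read-averaged — stated in
output headers) per context over tiling windows; empty windows are flagged,
not zero-filled. Excluding organelle-derived reads cannot lower a window's
percentage when the excluded reads are unmethylated, and raises it in
contaminated windows — the deconvolution property the tests check.

The anchored consensus takes reads spanning an interval that carry the numt
allele at ≥1 diagnostic site on each side, and majority-votes each column
against the assembly; disagreement flags candidate "overwritten" assembly
sequence. Read length filtering (e.g. >30 kb) is the caller's concern; a
`--min-read-length` convenience filter is provided, default off.

## The simulator

The generator's defaults are the study conditions: a 368-kb circular
i.i.d. genome at GC 0.45 (no gene structure — none of the analyses use
annotation), two large repeat pairs of 6.0 and 4.2 kb (R1, R2) and two small
pairs of 457 and 206 bp (C, Q) planted as identical copies; substitution
rate 6.7 × 10⁻⁴ per site; category weights proportional to the published
spectrum counts (235/35/58/30/42/25), applied per available site class so
realized proportions match the weights regardless of composition; CpG/CHG
C→T multipliers 5.8 (reproducing a ~74.5% CpG+CHG share of C→T over a ~1/3
background); indel rate 7 × 10⁻⁵ with geometric lengths (p=0.5, capped at
20 bp — no published indel length model) and deletion bias 30/44. The
circular origin is handled by letting fragment intervals wrap; internally
the genome is linear. A single seed drives every draw; identical configs
give byte-identical outputs.

Genesis fuses a fragment plan (the published question of one multimeric
molecule vs several fragments is left open: the plan expresses either),
records truth blocks/fusions, splits mutational time at the duplication's
`time_fraction` (epoch semantics: pre-duplication variants are carried into
both daughters), applies conversion tracts as exact copy-to-copy
replacements, and finally applies indels placed away from block boundaries
so the truth tiling survives coordinate shifting. Reads are labelled with
their true source; numt reads carry numt alleles at diagnostic sites except
at a per-site flip rate and are methylated at per-context rates (defaults
0.9/0.7/0.1 for CpG/CHG/CHH, typical of pericentromeric plant chromatin);
organelle reads are unmethylated. No quality scores, no FASTQ, no error
model beyond the per-site flip.

What the simulator does **not** emulate: real mitogenome base composition
and repeat-internal divergence, assembly errors, mapping bias, nanopore
methylation-caller noise, and population-level variation. Passing recovery
tests therefore establishes the correctness of the algorithms under the
stated generative model, not the accuracy of any particular published value
on real data; the accession-driven `reproduce` path exists for that and is
optional (network).

## Problem sizes in tests and the acceptance script

Structural and recovery tests run at 10–20% of the study scale (genomes of
40–55 kb, numts of 35–55 kb, divergence 0.1–0.3%) with 5–40 replicates per
property, and the full-scale defaults are exercised for genome generation
itself; these sizes were chosen so the whole suite runs in well under a
minute of simulation time while every property is measured at sampling
errors far below its threshold. The acceptance script reports each metric's
problem size (`n`) alongside its value.

## Known limitations

* Breakpoint coordinates inside identical repeats are reported at the
  lowest-coordinate tie, with the ambiguity documented rather than resolved.
* The duplication search considers one tandem event; the real history may
  stack conversion on duplication, which the verdict logic surfaces as
  conflicting patterns instead of resolving.
* `extract_repeat_copies` splits origin-wrapping multi-copy regions at the
  origin for its linear sweep.
* The banded aligner targets ≥99% identity pairs; it is exact everywhere
  (certificate + widening) but not performance-tuned for divergent pairs.
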