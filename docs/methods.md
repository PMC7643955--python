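# Methods

This note documents the statistical models, numerical choices and open
design decisions behind `oomics`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted from memory.

## Differential methylation

**Pooling.** Single-cell whole-genome bisulfite data is extremely sparse
(one or two reads per cytosine per cell at typical coverage), so no
per-site, per-cell test is attempted. Cells of a stage are pooled by
summing methylated and total counts per (chromosome, position, strand).
Pooling is associative and order-independent, which the tests assert;
methylation level of a region is always the coverage-weighted mean
Σm/Σn, never a mean of per-site fractions. Strands are counted
independently for all contexts, including CpG: collapsing symmetric CpG
pairs would treat one context differently from CHG/CHH and complicate
sparse-data bookkeeping for no statistical gain at these coverages.

**Windows.** Each chromosome is tiled with 3 000 bp windows stepped every
600 bp, starting at 0. If the last regular window ends short of the
chromosome end, one terminal window [L − 3000, L) is appended so every
base is covered; chromosomes shorter than one window get a single
truncated window [0, L). Window width, step, coverage floor and
significance cutoffs are all arguments of `call_dmrs` and of the
`call-dmrs` CLI command.

**Per-window test.** The two pooled groups form a 2×2 table of
(methylated, unmethylated) counts. The window is testable when both
groups have pooled coverage ≥ 10 (default); untestable windows are
excluded from the multiple-testing universe rather than counted as
failures. The p-value is a two-sided Fisher exact test using the
*doubling rule* — twice the smaller conditional hypergeometric tail,
capped at 1 — which the tests verify against full enumeration of the
hypergeometric distribution on small tables. The doubling rule was chosen
over the minimum-likelihood two-sided rule because it is monotone in the
tails and trivially vectorizable; both are valid conventions. BH
correction runs across all testable windows of one context and contrast.
Windows pass at q ≤ 0.05 and |Δ| ≥ 0.1 (Δ = level_B − level_A).

**Merging.** Passing windows of the same context and direction that
*strictly* overlap are merged; abutting half-open intervals ([a,b), [b,c))
stay separate. A merged DMR reports levels recomputed over the merged
interval, the smallest constituent q, and the window count. Because
windows that only partially overlap a true differential region can still
pass the Δ threshold, called DMRs extend up to roughly two-thirds of a
window beyond the true boundary on each side; the merged-interval Δ is
correspondingly diluted relative to the core effect. Direction is labeled
relative to the later maturation stage: `hyper` means more methylated in
the mature group (group B).

**Conversion efficiency.** Lambda phage spike-in DNA is unmethylated, so
efficiency = 1 − Σm/Σn over all spike-in cytosines; the QC predicate
flags libraries at or below 0.98. Zero spike-in coverage is an error, not
an efficiency of 1.

## Genomic classification

Coordinates are 0-based half-open internally; the GTF-like annotation is
1-based inclusive on disk and converted at the I/O boundary. Promoters
are strand-aware: [t − 2000, t + 500) around a + TSS and the mirrored
[t − 499, t + 2001) around a − TSS, clipped to the chromosome.

Two views of a region are exposed deliberately. `is_distal` implements
the study's literal definition — overlapping no promoter, exon or UTR —
under which intronic regions qualify as distal. `classify_feature`
assigns one label by priority (promoter > 5′UTR > 3′UTR > exon > intron >
distal) for feature-breakdown summaries. The tests assert their
consistency (`is_distal` ⇔ label ∈ {intron, distal} with no
promoter/exon/UTR overlap) and validate both against per-base brute-force
oracles.

Region-to-gene assignment for distal regions uses the nearest TSS to the
region midpoint within 100 kb (ties to the smaller gene id). This is a
transparent desk-scale substitute for database-backed basal-plus-extension
tools; it is exact, auditable and has one parameter.

Overlap fractions count a region as hit at ≥ 1 bp of overlap and are
invariant under merging of the track. Statistics that could be counted
per DMR or per gene (a DMR overlapping several genes) are reported per
gene and per pair separately rather than conflated.

## Expression

TPM and FPKM are computed from counts and union-of-exon gene lengths;
isoforms are not modeled. Merged-stage FPKM sums counts across a stage's
cells first, which equals FPKM of the summed matrix exactly (asserted).
"Expressed" means FPKM ≥ 1, inclusive; stage-specific means expressed in
exactly one stage.

The differential test is a self-contained negative-binomial Wald test:

* size factors by median-of-ratios (each cell's median ratio to per-gene
  geometric means over everywhere-nonzero genes, falling back to totals
  when fewer than 10 such genes exist). Total-count scaling is *not* used
  because a large block of same-direction differential genes drags it and
  shifts every null gene — the classic composition artifact, visible in
  early development contrasts where thousands of genes change;
* one method-of-moments dispersion α shared across genes (median of
  per-gene (s² − μ)/μ² over informative genes, clipped to [1e−8, 10]);
* log2 fold change log2((μ_B + ½)/(μ_A + ½)) with pseudo-mean ½ to avoid
  infinities — deterministic and shrinkage-free;
* delta-method standard error Var(μ̂)/(μ + ½)² per group with
  Var(count) = μ + αμ², normal Wald p, BH across genes with nonzero
  counts in at least one group;
* a gene is differential at q ≤ 0.05 and |log2FC| ≥ 1 ("fold change ≥ 2"
  read as the NB mean ratio).

The caller is exactly antisymmetric under swapping groups and returns
all-zero effects for duplicated groups. Measured operating
characteristics on simulation: type-I fraction ≤ 0.05 on null contrasts,
≥ 90% power at planted |log2FC| = 3 with 8 cells per group, and a planted
log2FC of 2 estimated within ±0.5 at 24 cells per group.

PCA ranks genes by mean expression, keeps the top 1000 (or all, if
fewer), transforms log2(x+1), centers, and uses a full SVD; explained
variance ratios are non-increasing by construction.

## Integration

PWMs are position probability matrices over A,C,G,T with uniform 0.25
background by default; scores are log-odds in bits; non-ACGT bases score
−∞. Both strands are scanned at every offset; the default hit threshold
is 0.8 × the maximum attainable score of that PWM, which for a
consensus-style matrix (probability ~1 per column) effectively demands a
near-exact match while remaining PWM-relative and deterministic. The
study's motif evidence mixed ChIP-derived sites and motif scans without
stating a threshold; both "any DMR" and "distal DMR only" motif flags are
reported so either reading is available.

TF triangulation is a conjunction: expressed (FPKM ≥ 1 in MI or MII) ∧
present in the user-supplied DNMT3B binding-partner list ∧ ≥ 1 motif hit
inside a DMR. TFs without a PWM get an unknown motif flag and cannot
triangulate. The set is intersection-monotone in all inputs (asserted).
Target-direction tallies count a target gene when some gene-body DMR
contains a hit of the TF's motif, and as hypermethylated when at least
one such motif-bearing DMR is hyper.

Gene-set over-representation is the one-sided hypergeometric tail
P(X ≥ overlap) with BH across sets, after intersecting query and sets
with the supplied universe. It replaces web-service enrichment with
user-supplied gene-set files, removing any database-version dependency.

## The simulator

The generator emulates the statistical structure the analysis assumes,
with all parameters in `SimConfig`:

* **Genome**: 2 chromosomes × 500 kb of uniform random sequence. Each
  chromosome has a gene compartment (proximal 45%) holding non-overlapping
  genes (50 genes of 3–7 kb, 2–4 exons with intron-heavy slack, UTRs
  carved from the terminal exons) and a distal repeat-rich "desert".
  Long LINE1-like elements (3.5–6 kb) are placed with a 6 kb mutual gap —
  30% overlapping gene bodies, the rest intergenic and ≥ 4.5 kb from any
  gene so that regions called around them stay clear of promoters;
  shorter SINE/LTR elements fill the repeat track to 25% of the genome.
  An accessibility track covers 30%. The compartment structure is a
  coarse imitation of real gene-dense versus LINE-dense isochores and is
  what lets a desk-scale genome produce a majority-distal DMR set, as a
  full-size genome does.
* **Methylome**: cytosine contexts are read off both strands with
  Bismark semantics (CpG = C,G; CHG = C,H,G; CHH otherwise). Site means:
  0.70 at CpG in every stage; 0.03 (GV, MI) and 0.06 (MII) at non-CpG
  sites, so the genome-wide non-CpG level doubles on maturation. Thirty
  3 kb hyper-DMRs (70% CHH, 30% CHG; 90% inside long repeats) add +0.30
  to their context's MII mean, clamped at 1 with a warning. Per cell,
  coverage is Poisson(2.0) per site and methylated counts are
  Binomial(coverage, site mean); 7 cells per stage. An optional per-cell
  logit-normal jitter (`cell_level_sd`, default 0) exists because
  cell-to-cell methylation variance is not pinned down by published
  summaries; the default is the smallest model that exercises the caller.
  Lambda spike-ins: 2 000 sites, Poisson(20) coverage, true conversion
  failure 0.005. The planted TF's 8-mer consensus is embedded in 80% of
  planted DMRs *before* contexts are enumerated (the call finalizes the
  genome in place).
* **Transcriptome**: baseline gene means are log-normal (meanlog 4,
  sdlog 1); GV and MI share means exactly, so that contrast is null by
  construction. Genes overlapping planted DMRs (and expressed above a
  floor of 5) become upregulated targets with log2FC ~ U(1.5, 3) —
  the mechanism behind the positive gene-body association — and the
  remaining planted genes (30 total) get signed effects, 75% negative,
  matching the strong downregulation bias of maturation. Counts are NB
  with shared dispersion 0.1 and log-normal library-size factors
  (sdlog 0.3). The planted TF is the highest-baseline unperturbed gene.
* **Determinism**: all randomness flows from `SimConfig.seed` through
  separate `SeedSequence` streams for annotation, methylome and
  transcriptome; identical seeds give byte-identical tables, which the
  CLI manifest checksums verify end to end.

**What the simulator does not model** — and hence what passing tests do
not demonstrate about real data: read-level artifacts (mapping bias,
incomplete conversion correlated along reads), imprinted or
allele-specific methylation, CpG islands and methylation autocorrelation
beyond the planted blocks, isoform structure, zero-inflation or dropout
beyond NB sampling, batch effects, and inter-individual variation.
Recovery and error-rate results certify the *algorithms* under the
declared generative model, not the biology of any particular dataset.

## Problem sizes and numerical conventions

The default simulation (1 Mb genome, ~500 k cytosines on both strands,
21 methylomes, 21 transcriptomes over 50 genes) was chosen so the entire
test suite and the acceptance script each run in a couple of minutes on
one CPU, while every stage of the pipeline still has non-trivial work.
Other conventions: q-values of 0 are written as BED score 1000
(−10·log10 q capped); "no data" methylation levels are `None`, never 0;
empty region lists make overlap fractions an error rather than a silent
0; DMR direction must match the sign of Δ, enforced at construction;
ties in nearest-gene assignment break to the lexicographically smaller
gene id.

## Known limitations

The exact statistical test and cutoffs behind the original DMR lists were
published separately and are not restated in the source study; the
defaults here (Fisher doubling rule, coverage ≥ 10, q ≤ 0.05, |Δ| ≥ 0.1)
are declared substitutes, configurable at every entry point. Headline
counts that depend on raw sequencing libraries (absolute expressed-gene
and differential-gene totals) are outside desk scale and are not
reproduced; the pipeline instead demonstrates the same structure —
a null GV/MI contrast, MII-specific effects, repeat-dominated non-CpG
DMRs, and motif-bearing hypermethylated gene bodies on upregulated
targets — with measured error control on known truth.
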