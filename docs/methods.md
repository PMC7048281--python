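# Methods

## The isomiR model

A mature miRNA is excised from its hairpin precursor by DROSHA/DICER
cleavage; imprecise or alternative cleavage yields isomiRs whose 5' and/or 3'
ends are shifted relative to the canonical (annotated) sequence, and single
internal substitutions ("polymorphic" isomiRs) arise from SNPs, editing or
sequencing error. Rather than aligning reads to a genome, the pipeline
materializes the isomiR sequence space explicitly and assigns reads to it by
exact/near-exact lookup. For each mature located at `[start, end)` in its
hairpin, every offset pair (e5, e3) with −max_trim ≤ e ≤ +max_add is realized
as `hairpin[start−e5 : end+e3]`; variants shorter than `min_len` are pruned
at build time (shorter reads are discarded during preprocessing, so such
variants can never match anything and pruning changes no result). For a
22-nt mature with full flanks and the default grid this yields 79 variants:
the 10×10 grid minus the 21 cells with e5+e3 ≤ −7.

End **additions are hairpin-templated by default**: a mapping reference needs
concrete bases, and the flanking precursor sequence is the only principled
source (this is exactly the alternative-cleavage interpretation of isomiR
extensions). Whether real 3' tails are templated is dataset-dependent, so an
optional `nontemplated_AU` mode generates all A/U mono- to tri-nucleotide 3'
tails instead; it is off by default and 5' additions are not generated in
that mode (tailing is a 3'-end phenomenon).

Sequences are held internally in the DNA alphabet (U→T on input) so FASTQ
reads and FASTA references compare directly; coordinates are 0-based
half-open throughout. Identical variant sequences arising from different
(miRNA, e5, e3) origins collapse into a single record carrying every parent
annotation; its counts roll up to the lexicographically smallest parent id,
and the annotation tables flag such features as ambiguous.

## Preprocessing

A 50-cycle read is insert + 3' adapter (+ more adapter when the construct is
short). The trimmer is deliberately simple and deterministic, not a
re-implementation of any particular trimming tool: (1) scan for the
adapter's first 10 nt anywhere in the read, allowing up to
`max_adapter_mismatch` (default 1) substitutions — adapter bases are
sequenced like any others and carry errors, and an exact-seed rule would
misclassify ~1% of reads as adapterless at an error rate of 10⁻³; (2)
otherwise look for a 3'-terminal overlap of ≥ `min_overlap` (default 6)
bases with ≤ 1 mismatch. The leftmost qualifying position wins. Reads with
no detectable adapter are *No Adaptor*; inserts < 16 nt are *Short*.

Contaminant screening asks whether the insert occurs as an ungapped window
of any rRNA/tRNA/snRNA/snoRNA reference sequence with ≤ 1 mismatch — the
same stringency as miRNA mapping. The class priority order
rRNA > tRNA > snRNA > snoRNA is fixed purely for determinism; the classes
are all excluded from mapping, so the order affects only the species
breakdown, never which reads survive. Base qualities are carried through but
never interpreted (no quality threshold is part of the procedure).

## Read assignment

Matching is **ungapped and length-preserving** (substitutions only): a read
of length L can only match variants of length L, at Hamming distance 0 or 1.
Indels are representable only through the enumerated trim/extension
variants, which is what the explicit reference is for. The index stores, per
variant sequence, its L "deletion-at-position-i" keys; two equal-length
sequences at distance 1 share exactly one such key, so the distance-1 lookup
is exhaustive without scanning the reference.

"Best" assignment means best-stratum-only: if any exact hit exists the
1-mismatch stratum is never consulted. Within the 1-mismatch stratum a
multi-candidate tie breaks deterministically by (a) smallest |e5|+|e3| over
the candidate's parent annotations — prefer the least-modified isoform —
then (b) smallest variant id. Determinism is preferred over the
pseudo-random multiread behavior of conventional aligners because it makes
every count reproducible and testable; ambiguous reads may therefore be
distributed differently than an aligner would.

Counts accumulate per (variant, mismatch-descriptor) key — effectively per
unique read sequence — so an exact read and a substituted read of the same
variant are separate features, which is what lets downstream analyses see
polymorphic isomiRs.

## Differential expression

Size factors are median-of-ratios: s_j = median over features with a
positive geometric mean of k_ij / (∏_j k_ij)^(1/m). Factors are defined up
to the geometric-mean reference, so only factor ratios are meaningful; the
implementation agrees with the canonical estimator (cross-checked against an
independent implementation in the test suite) and a single sample gets
factor 1 by convention.

Per feature, a negative-binomial GLM with log link, a two-level group design
and offset log s_j is fitted; the per-feature dispersion is a
method-of-moments estimate from the pooled within-group variance of
normalized counts, floored at 10⁻⁸, with **no** shrinkage toward a
mean–dispersion trend. The group coefficient's two-sided Wald p-value is
BH-adjusted across all tested features. This is intentionally a simplified
NB-Wald procedure: Cox–Reid dispersion estimation, fold-change shrinkage,
independent filtering and outlier replacement found in full DE packages are
not replicated, and the procedure is validated by its simulation properties
(type-I error under the full filter ≤ 1% at 2000 null features, ~100%
sensitivity with median log2FC estimate within ±0.3 of a planted 2.0),
not by matching another package's numbers.

Numerical edge cases: all-zero features are excluded from testing and
reported with missing p; when either group has fewer than two replicates
every feature gets a descriptive fold change (pseudo-count 0.5) and missing
p; when one group is entirely zero the log-link MLE diverges, so a 0.5
continuity correction is added to the counts for that fit only; a fit that
fails or returns a degenerate standard error falls back to the descriptive
fold change with missing p.

Significance uses the inclusive filter padj ≤ 0.05 AND |log2FC| ≥ 1 AND
baseMean ≥ 50, with baseMean computed over the samples of the comparison at
hand. The default contrast manifest covers every group-vs-group comparison
and, within each group, every later time point against the pre-feeding
reference time point.

In the pipeline driver, isomiR-level matrices are pre-filtered to features
with ≥ `min_total_count` (default 10) reads in the comparison before
testing. Sequencing errors generate a long tail of singleton keys that can
never approach the baseMean ≥ 50 threshold; removing them is the analog of
independent filtering and keeps the BH denominator meaningful. Note also
that with very few features (e.g. a canonical matrix over a handful of
miRNAs) median-of-ratios normalization loses its anchor when a large
fraction of features is truly changing; the compositional caveat is inherent
to count normalization, and the packaged fixtures keep planted features a
minority.

## Profiling

Counts are transformed as log2(k/s + 1) — a plain variance-stabilizing
approximation of a regularized log transform, adequate because the
clustering/PCA conclusions drawn from it are qualitative. PCA uses the
top-k-variance features (default k = 500; ties broken by feature id),
centered but not scaled, via SVD, with each component's sign fixed so its
largest-magnitude loading is positive. Clustering uses Euclidean distances
on the same transformed matrix with Ward linkage in the Ward.D2 variant
(scipy's `ward`), stated in the output metadata. The abundance/up-regulation
overlap ranks features by mean normalized count within the reference group
(ties by id), intersects the top-n set (default 100) with each time point's
up-regulated set, and also reports the share of the reference group's reads
that the top-n set carries.

## Pathway enrichment

The query set is the union of target genes over all significant miRNAs, so a
gene targeted by many miRNAs counts once — the gene-level collapse that
prevents single promiscuous miRNAs from inflating pathway statistics. The
universe is the intersection of genes present in the target map and genes
present in any pathway; this choice is a contract of this package (no single
convention is standard). Each pathway is scored with the upper-tail
hypergeometric probability of an overlap at least as large as observed,
BH-adjusted across pathways. Target maps are 2–3-column TSVs with an
optional evidence filter (e.g. keep only "strong" pairs) and an optional
miRNA homolog translation table (identity by default); pathways are GMT.

## The synthetic-study generator

The simulator emulates the structure of a colostrum-feeding transfer
experiment so that every stage has a ground truth:

- **Design**: groups × time points × replicates; defaults follow the study
  layout — two compartments, time points 0 h, 1 h, 3 h, 6 h, 9–12 h, 3
  replicates, 10⁵ reads per sample, 50-nt reads.
- **Reference**: random hairpins (70–90 nt) each embedding one mature
  (20–23 nt) with ≥ 3 nt of flank so all templated additions exist;
  contaminants (60–120 nt) are rejection-sampled so no window lies within
  Hamming distance 1 of any enumerated variant, making read provenance
  unambiguous by construction.
- **Abundances**: one fixed simplex over the variant space shared by all
  samples — per-miRNA abundance log-normal (σ = 1.5), ~70% of each miRNA's
  mass on its canonical variant and the rest split by a sparse Dirichlet
  (concentration 0.05), mimicking the canonical-dominated skew of real
  isomiR profiles. Planted log2 fold changes multiply the proportions of
  chosen features in chosen group/time cells before renormalization.
- **Counts and reads**: per-sample counts are gamma-Poisson
  (NB, dispersion 0.1 by default) around depth × proportion; biological
  replicate variability therefore enters through NB dispersion only, not
  through per-sample redraws of the simplex. Reads are insert + adapter
  (repeated, truncated to 50 nt) with independent per-base substitution
  errors at rate 10⁻³ by default. Contaminant (10%), short-insert (2%) and
  adapterless (2%) reads are injected with Poisson-distributed totals;
  adapterless reads are rejection-sampled so the trimmer genuinely finds no
  adapter.
- **Determinism**: all randomness flows from one seed through named
  SeedSequence streams; a fixed seed reproduces byte-identical FASTQ files
  (gzip mtime pinned to 0).

What the simulator does **not** model: quality-score structure, ligation and
GC bias, PCR duplicates, indel sequencing errors (the matcher is
substitution-only, so indel errors would only inflate the unmapped class),
cross-mapping between genuinely homologous miRNA family members, and
biological variance beyond NB dispersion. Passing tests on synthetic data
therefore demonstrate the correctness of the bookkeeping, the matcher, and
the statistical procedures under a known generative model — not performance
on real libraries with those artifacts.

## Problem sizes and runtime

The packaged end-to-end fixture uses 20 miRNAs (~1500 variants), 2 groups ×
3 time points × 3 replicates at 5×10⁴ reads per sample and completes in
about 40 s on one CPU; validation simulations use 10⁵-read libraries for
quantification checks, 2000-feature null and 150-feature planted designs
(3 vs 3) for the DE operating characteristics, and a 2×10⁵-depth,
dispersion-0.02 count-level design for overlap recovery, where the planted
effect (log2FC = 3 on twelve of the reference group's top-abundance
features) is large enough that recovery is limited by bookkeeping rather
than NB power (power itself is characterized separately). These sizes were
chosen as the smallest at which the measured properties are stable across
seeds.
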