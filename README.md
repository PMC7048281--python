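# isomirseq

A small RNA-seq analysis pipeline for studying **isomiRs** — the 5'/3'
end-variants and single-substitution ("polymorphic") variants of mature
miRNAs — built around the question of whether miRNA cargo from colostrum
extracellular vesicles (EVs) is transferred into the circulation of newborn
calves after their first feeding. It is aimed at transcriptomics
practitioners who want an isomiR-resolved, fully reproducible alternative to
genome alignment for short (50-cycle, single-end) miRNA libraries, and it
ships a complete synthetic-study simulator so every stage can be exercised
and validated without any external data.

## What the pipeline does

1. **Reference enumeration** — from a mature+hairpin miRNA FASTA pair, every
   isomiR sequence is realized explicitly: all end-offset pairs
   (e5, e3) ∈ [−6, +3]², where negative offsets trim and positive offsets add
   hairpin-templated nucleotides, pruned below 16 nt. Identical sequences
   from different origins collapse into one variant carrying all parents.
2. **Preprocessing** — 3' adapter trimming (10-nt seed scan with ≤1 mismatch,
   then a ≥6-nt 3'-terminal overlap), a <16 nt length filter, and
   rRNA/tRNA/snRNA/snoRNA contaminant removal (substring containment with ≤1
   mismatch). Every raw read receives exactly one class label:
   *No Adaptor, Short, rRNA, tRNA, snRNA, snoRNA, isomiR/miRNA, Unmapped*.
3. **Quantification** — ungapped, length-preserving assignment of each insert
   to a variant at Hamming distance 0 or 1 (exact hits always win; ties break
   by smallest |e5|+|e3|, then variant id). Counting keys carry the mismatch
   descriptor, so every unique read sequence has its own key:
   `syn-miR-007|-2|+1|m10G>C` means "variant of syn-miR-007 with 2 nt trimmed
   at the 5' end and 1 nt added at the 3' end, read carries G→C at position
   10". Keys roll up to canonical miRNA counts by parent.
4. **Differential expression** — median-of-ratios size factors
   s_j = median_i(k_ij / (∏_j k_ij)^(1/m)), a per-feature negative-binomial
   GLM with log link and offset log s_j, method-of-moments dispersion, a
   two-sided Wald test and Benjamini–Hochberg FDR. A feature is significant
   when padj ≤ 0.05, |log2FC| ≥ 1 and baseMean ≥ 50 (all inclusive).
5. **Profiling** — RNA-species distribution per library, Ward.D2 hierarchical
   clustering and top-500-variance PCA of log2(normalized+1) counts, and the
   overlap between a reference group's top-100 most abundant isomiRs and the
   up-regulated isomiRs at each postprandial time point.
6. **Enrichment** — hypergeometric pathway over-representation on the
   *union* of target genes of all significant miRNAs (gene-level collapse, so
   one miRNA with many targets in a pathway cannot inflate the statistic).

## Worked example

Run the packaged synthetic study — 2 compartments (colostrum EV, calf EV) ×
3 time points (0 h, 1 h, 6 h) × 3 replicates at 50,000 reads each, with a
time-increasing effect planted on 8 miRNAs in the calf-EV group:

```bash
isomirseq run-all --config configs/synthetic_run.yaml --out runs/demo
```

which prints

```
done: 18 samples, 1513 variants; outputs in runs/demo
```

and writes, among other tables, `runs/demo/diffexp/comparison_manifest.tsv`:

```
contrast                 level      n_features_tested  n_significant  n_up  n_down
colostrum_EV_vs_calf_EV  canonical  20                 2              0     2
calf_EV_1h_vs_0h         canonical  20                 3              2     1
calf_EV_6h_vs_0h         canonical  20                 8              8     0
colostrum_EV_1h_vs_0h    canonical  20                 0              0     0
colostrum_EV_6h_vs_0h    canonical  20                 0              0     0
...
```

Reading this: all 8 planted miRNAs are recovered as up-regulated in calf EVs
at 6 h, the weaker 1 h effect is partially recovered, and the unperturbed
colostrum-EV time course produces no false positives.
`stats/species_distribution.tsv` shows each library partitioned into read
classes (≈86% isomiR/miRNA-mapped, ≈10% contaminants, ≈2% each No-Adaptor
and Short under the fixture's generating fractions), and
`profiling/abundance_overlap.tsv` reports how many of the colostrum-EV
top-100 isomiRs reappear among the postprandially up-regulated isomiRs.

Individual stages are available both as library functions
(`isomirseq.enumerate_isomir_space`, `isomirseq.nb_differential`, ...) and as
subcommands (`simulate`, `build-ref`, `preprocess`, `quantify`, `diffexp`,
`profile`, `enrich`). Pointing a config's `inputs:` section at real FASTQ
files, miRBase-style FASTAs and a sample sheet runs the same analysis on
real data.

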