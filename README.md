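# terramotif

Quantification of telomeric repeat-containing RNA (TERRA) in RNA-seq
reads, and nonparametric testing of TERRA motif abundance across
longitudinal exposure categories.

TERRA is transcribed from subtelomeres through the telomeric tract and
consists largely of tandem 5'-UUAGGG-3' repeats, with frequent variant
repeat units interspersed among the perfect runs. Because TERRA has no
single genomic locus that standard quantification pipelines handle well,
its abundance can instead be estimated directly from read content: the
fraction of k-mers belonging to the telomeric repeat family. `terramotif`
implements that estimator for anyone studying TERRA dynamics in cohort
RNA-seq data — e.g. blood transcriptomes sampled before, during and after
an environmental exposure — together with a synthetic-cohort generator
that makes every stage verifiable against ground truth.

## Method

For each sample the pipeline:

1. **Filters** reads containing the canonical motif (DNA `TTAGGG`),
   accounting for reverse complementarity (`CCCTAA`), and orients retained
   reads to the G-rich strand.
2. **Counts** all 5-, 6- and 7-mers of the retained reads under
   *circular-shift equivalence*: the sliding windows of a tandem repeat
   cycle through every rotation of its unit, so k-mers identical up to
   rotation form one class, named by its lexicographically smallest
   rotation (AGGGTT for TTAGGG). Baseline counts of raw k-mers over all
   reads are kept for QC and as an optional denominator.
3. **Normalizes** each class count by the total count of all k-mers of the
   same k: `a(m, s) = c(m, s) / Σ_{|m'|=|m|} c(m', s)`.
4. **Ranks** motif classes by the Pearson correlation r of their abundance
   profile across all samples to the canonical motif's profile, and selects
   the top n (default 10, including the canonical motif itself) — highly
   correlated variants act as proxies for TERRA detection.
5. **Tests** each selected motif with two-sided Mann–Whitney U tests,
   either a focal category against the combined remaining categories
   (e.g. `space_effect` vs `ground`+`recovery`) or all unordered pairs of
   groups (e.g. per timepoint), pooling every resulting p-value into a
   single Benjamini–Hochberg FDR adjustment. Exact null enumeration is
   used for small tie-free comparisons (n_a + n_b ≤ 12), the tie-corrected
   normal approximation with continuity correction otherwise.
6. **Reports** z-scored normalized abundances of the selected motifs,
   per-motif triangular matrices of adjusted p-values (pairwise designs),
   and TSV tables for every intermediate.

## Worked example

Simulate a 12-sample cohort (4 ground, 4 space_effect, 4 recovery;
5,000 reads per sample; TERRA-derived read fraction 1.5% in the
space-effect category vs 0.5% elsewhere; variant units TGAGGG at 5% and
TCAGGG at 3% of repeat units) and run the full analysis:

```sh
cat > cohort.yaml <<'EOF'
seed: 7
reads_per_sample: 5000
read_length: 100
error_rate: 0.005
categories:
  ground: {n_samples: 4, terra_fraction: 0.005}
  space_effect: {n_samples: 4, terra_fraction: 0.015}
  recovery: {n_samples: 4, terra_fraction: 0.005}
variant_model:
  canonical_unit: TTAGGG
  variants: {TGAGGG: 0.05, TCAGGG: 0.03}
EOF

terramotif simulate --config cohort.yaml --out cohort
terramotif run --manifest cohort/manifest.tsv --out results
```

`results/comparisons.tsv` begins:

```
motif_rna  k  group_a       group_b          n_a  n_b  U             p_raw         q_adjusted    method
AGGGUU     6  space_effect  ground+recovery  4    8    3.200000e+01  4.040404e-03  4.489338e-03  exact
AGGUU      5  space_effect  ground+recovery  4    8    3.200000e+01  4.040404e-03  4.489338e-03  exact
AGGGGUU    7  space_effect  ground+recovery  4    8    3.200000e+01  4.040404e-03  4.489338e-03  exact
```

U = 32 = n_a·n_b means every space-effect sample exceeds every non-space
sample in the motif's normalized abundance; p = 2/495 is the exact
two-sided enumeration p, and q is its pooled BH adjustment — the elevated
TERRA fraction seeded in the space-effect category is recovered as a
significant enrichment of the canonical motif class (AGGGUU, the rotation
class of UUAGGG) and its co-varying variants. `results/correlations.tsv`
shows the correlation ranking behind the selection:

```
motif_rna  k  r             selected
AGGGUU     6  1.000000e+00  1
AGGUU      5  9.998979e-01  1
AGGGGUU    7  9.998812e-01  1
...
AGGGGUG    7  9.311392e-01  1
```

Classes derived purely from the canonical repeat correlate at r ≈ 1;
classes carrying the seeded variant units follow at r ≈ 0.93. The run
also writes the abundance matrix, z-scores, selected-motif list,
per-sample count tables, a log with per-sample read and window totals,
and a machine-readable run summary. `terramotif count` and
`terramotif analyze` expose the same stages separately and compose
bit-for-bit with `terramotif run`.

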