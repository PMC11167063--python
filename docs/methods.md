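# Methods

## Model and procedure

`terramotif` estimates the abundance of telomeric repeat-containing RNA
(TERRA) in a sequencing sample from read content alone. The underlying
model is that TERRA-derived reads are tandem arrays of the canonical
repeat unit (RNA 5'-UUAGGG-3', DNA G-strand `TTAGGG`) interrupted by
variant repeat units, sequenced from either strand, and mixed with a
large background of non-telomeric reads. No alignment is involved; all
inference is on k-mer composition.

All internal computation is in DNA space: RNA `U` is mapped to `T` at
ingest, and motif reporting maps back to RNA (`T` → `U`), since telomeric
motifs are conventionally written as RNA.

### Rotation-equivalence counting

The sliding windows of a tandem repeat cycle through every rotation of
its unit, so counting raw k-mers would split one repeat signal across k
strings. K-mers are therefore pooled into circular-shift equivalence
classes, each represented by its lexicographically smallest rotation —
computed by brute-force minimum over the k rotations, which for k ≤ 7 is
both trivial to verify and fast once memoized into a per-k lookup table
over all 4^k codes. An optional `collapse_strands` mode additionally
minimizes over the rotations of the reverse complement, merging G-strand
and C-strand classes; the chosen representative is still rotation-minimal,
so idempotence holds in both modes.

Counting itself is vectorized: reads are joined with `N` separators,
bases are 2-bit encoded, window codes accumulated by shifted adds, and
windows containing `N` (including the separators, hence windows spanning
read boundaries) are masked out. Windows step by 1; reads shorter than k
contribute nothing. Per-k window totals are retained as normalization
denominators.

Two scopes are computed per sample. The *baseline* scope counts raw
(non-canonicalized) k-mers over all reads, mirroring a plain k-mer
counter; it serves as QC and as an optional normalization denominator.
The *filtered* scope counts rotation classes over the reads retained by
the motif filter, after orienting each read to the G-rich strand
(reads matching only via the reverse complement are reverse-complemented
whole; forward matches take priority). Orientation plus rotation-only
canonicalization is the default because motifs are reported in their
G-strand RNA form; strand collapse remains available where strand of
origin is not meaningful.

### Normalization, correlation ranking, z-scores

The abundance of class m in sample s is `count(m, s) / totals(|m|, s)`,
so abundances of one k sum to 1 per sample under the filtered
denominator (asserted to ±1e-9 in the tests). The denominator scope is
configurable (`filtered` default, `baseline` optional) because "total
count of all k-mers in the dataset" admits either reading; the choice is
an explicit key in the run configuration.

Motif variants are ranked by Pearson r between their abundance profile
and the canonical motif's profile across *all* samples of a run jointly,
and the top n (default 10, always including the canonical motif first)
are selected for testing and display. Classes of k ∈ {5,6,7} are pooled
into one ranking; counts of shorter k-mers are partially contributed to
by longer k-mers (UUAGG within UUAGGG), which is reported as a caveat,
not corrected for. Zero-variance profiles have undefined r, are marked
NaN, and are never selected; ties are broken lexicographically on the
canonical DNA string, so selection is invariant to input order.

Z-scores are computed per motif row across all samples with the sample
standard deviation (ddof = 1); rows that are exactly constant (or have
zero SD) map to all zeros rather than NaN, keeping downstream tables and
heatmaps well-defined.

### Group testing

Two designs cover the longitudinal cohort layouts the package targets:
`two_category` (a focal exposure category vs the combined remaining
categories, e.g. space_effect vs ground+recovery) and `pairwise_groups`
(every unordered pair of groups, grouped by timepoint or category). Each
selected motif is tested with a two-sided Mann–Whitney U test; U counts
pairs with x > y plus half the tied pairs. With combined sample size
≤ 12 and no ties the exact null distribution is used (cohorts this small
make exactness matter — the smallest achievable two-sided p for 6 vs 6
is 2/924); otherwise the tie-corrected normal approximation with
continuity correction. If every value in both groups is identical the
test is uninformative and p = 1 by convention, with a logged warning.
Groups of size 1 are allowed but warned about, since the test is then
driven entirely by replicate timepoints.

All p-values emitted by a run form a single Benjamini–Hochberg step-up
family (sort ascending, p·m/rank, running minimum from the largest rank,
cap at 1); q-values are reported alongside raw p-values, and pairwise
designs additionally write per-motif triangular matrices of q-values.
Sidedness, exact-vs-approximate switching and tie handling are
documented defaults, not claims about any particular prior analysis.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with ground truth for every sample:

- **TERRA reads** are pure repeat tracts: units drawn i.i.d. (canonical
  with probability 1 − Σv, else a variant unit by its probability v),
  concatenated from a uniformly random phase offset, truncated to the
  read length, mutated by per-base substitutions, and
  reverse-complemented with probability `strand_flip_prob` (default 0.5).
  Variant units of length 5–7 are allowed; non-6 units deliberately
  exercise cross-k leakage.
- **Background reads** are i.i.d. bases with P(G) = P(C) = gc/2 (default
  gc 0.5); an optional rejection mode guarantees motif-free reads for
  degenerate-path testing. Substitution error is not applied to
  background reads: a uniform substitution process on i.i.d. bases is
  distributionally absorbed into the base model, so applying it would
  only spend runtime.
- **Samples** draw each of `reads_per_sample` reads as TERRA-derived
  with their category's `terra_fraction`. One root seed spawns one child
  seed per sample (by sample index), so cohorts are byte-reproducible
  (gzip containers are written with mtime 0) and samples independent.

Defaults encode the package's reference study conditions: 6 ground vs 6
space_effect samples, 20,000 reads of length 100, TERRA read fractions
0.005 vs 0.015 (a 3× in-flight contrast), variants TGAGGG at 5% and
TCAGGG at 3% of units, substitution error 0.005. Background reads of
length 100 at gc 0.5 contain the motif by chance in ~4.5% of cases
(either strand), so the filtered set realistically mixes true repeat
reads with motif-bearing background — the normalization denominator is
not artificially pure.

What the generator does *not* emulate: transcriptome structure and
expression covariance, subtelomeric flanks on TERRA reads (an option
exists but is off, as the pipeline operates on repeat content only),
indels, quality-score structure, coverage/poly(A) bias, UMIs and
barcodes, and between-subject biological variability beyond binomial
sampling. Passing tests therefore demonstrate correctness of the
counting, normalization and inference machinery and calibration under
the stated model — not robustness to alignment artifacts or library
chemistry.

## Validation results and a known limitation

With the reference conditions, the canonical motif class reaches
BH-adjusted q < 0.05 in 50/50 simulated cohorts, and under null cohorts
(equal TERRA fractions) its raw p < 0.05 in ~3.5–4.5% of 200 runs,
matching the nominal rate (the exact test's largest achievable level
below 0.05 is 0.0498). The selected top-10 correlations for
variant-bearing classes fall around r ≈ 0.93–0.99.

A structural property of pooled-k ranking is worth knowing: a pure
canonical tract itself produces seven rotation classes across k ∈
{5,6,7} (AGGGT/AGGTT/GGGTT at k=5, AGGGTT at k=6,
AAGGGTT/AGGGGTT/AGGGTTT at k=7), all correlating at r ≈ 1. With n = 10
this leaves about three slots for variant-derived classes, and each
variant unit spawns its own k=5/k=7 junction classes competing with its
6-mer class; low-rate variant units therefore often rank just outside
the top 10 (the 3%-rate TCAGGG class typically lands at rank 12–16).
Choosing a larger n, or ranking within k = 6 only, surfaces such
variants reliably; both are configuration options, and the default n
remains 10.

## Numerical and interface choices

- All analysis tables are TSV with fixed float formatting (scientific
  notation, 6 significant digits), making repeated runs byte-identical.
- Matrix rows are ordered by (k, canonical string) and columns by
  manifest order; every ranking has a deterministic tie-break.
- Degenerate inputs fail loudly and early with stage-tagged errors: a
  cohort whose filtered counts lack the canonical motif class aborts at
  the correlation stage naming that stage; manifest schema problems,
  unknown categories, duplicate sample ids and missing read files are
  rejected at load time.
- Parse errors from sequence files name the file, format and offending
  record index (record-level, not line-level, localization).
- Reads are treated independently (paired-end mates are two reads); no
  quality trimming or adapter handling is performed — preprocessing is
  assumed upstream.

## Problem sizes used in the test suite

Unit and property tests run on small fixtures generated in memory.
The simulation-based checks use: 500 random sequences (lengths 10–200,
2% N) for counting-oracle agreement; exhaustive 6-mer and sampled
5-/7-mer checks of the rotation algebra; 200 random small-group splits
against full permutation enumeration and 1,000 random vectors against a
literal BH oracle; 50 reference-condition cohorts for power and variant
recovery; and 200 null cohorts for type-I calibration. These sizes keep
the full suite in the minutes range on one CPU while leaving the
binomial uncertainty of the calibration checks well inside their
acceptance bands.
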