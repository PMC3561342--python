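# Methods

This note documents the statistical model behind each stage, every decided
default with its rationale, what the synthetic generator does and does not
emulate, and the numerical choices that affect results. Nothing here claims
an empirical result the code does not compute.

## Expression model

Expression is quantified as **RPKM**: reads per kilobase of coding sequence
per million mapped reads, `rpkm = reads / (cds_kb * mapped_millions)`. A
gene's expression is the **sum over its isoforms**. Inputs are genes ×
samples matrices of non-negative reals with per-sample group labels
(`normal` / `cancer`); all downstream statistics treat the matrix as given
and make no distributional assumption beyond non-negativity.

## Background threshold

- **Positive set**: a sample's positive gene expression values. Zeros are
  excluded — a gene with no reads carries no evidence about where the
  noise floor sits.
- **Negative set**: expression density over intergenic regions.
- At candidate cutoff *t*: `FP = #{negative > t}`, `TN = #{negative <= t}`,
  `FN = #{positive <= t}`, `TP = #{positive > t}`. "Expressed" is strictly
  greater than the threshold, consistent with the FP definition.
- **Candidates** are the sorted unique observed values plus 0 (not a fixed
  grid): exact and scale-invariant.
- **Selection**: argmin |FPR − FNR| — the balanced-error crossing — with
  ties going to the smaller threshold. Ties are compared in integer
  arithmetic (`|FP·N_pos − FN·N_neg|`) because exactly equal rational gaps
  can differ in floating point, which would break the tie rule
  nondeterministically.
- **Unification**: median of per-sample thresholds (mean of the middle two
  for even counts).

## Housekeeping catalog

A gene is HK for a group when its expression exceeds the background
threshold in **every** sample of the group (`min_breadth_fraction = 1.0`;
the parameter exists to relax ubiquity, threshold count = ceil(fraction ×
group size)). Set algebra on the normal and cancer HK sets yields four
mutually exclusive base classes (shared, normal_unique, cancer_associated,
non_HK) and two derived supersets (normal_HK = shared ∪ normal_unique,
cancer_HK = shared ∪ cancer_associated). Accounting percentages are
integers rounded **half-up** (`round_half_up`), the convention used
throughout report tables; Python's built-in banker's rounding would round
e.g. 46.5 down.

## Tri-level thresholds (1-D weighted k-medians)

- Points are (value, multiplicity) pairs over a sample's expressed values.
- **Transform**: distances are computed on `log2(x + n)` with transform
  factor `n = 1` by default. The log compresses the right tail so the
  high-expression cluster does not absorb everything; the +1 keeps the
  transform defined toward zero. A `distance_space="raw"` flag computes
  distances on the original scale instead, since either convention is
  defensible; results in this package default to the transformed space.
- **Centroid**: the weighted median of the member values — an actual data
  value (the "middle gene"), lower-middle on even total weight.
- **Assignment**: nearest centroid; equidistant points go to the lower
  cluster, so clusters are contiguous intervals.
- **Initialisation**: deterministic weighted quantiles at (2j+1)/(2k);
  `max_restarts` adds seeded random restarts keeping the best objective.
  k-medians is a local optimiser: on adversarial instances the
  deterministic start alone reaches the global optimum ~96 % of the time,
  with 20 restarts ~98-99 % (measured against the exact oracle below).
- **Empty-cluster repair**: reseed at the point farthest from its nearest
  surviving centroid.
- **Thresholds**: on the original RPKM scale, low = midpoint of (max LEG,
  min MEG), high = midpoint of (max MEG, min HEG).
- **Unification**: componentwise medians over the **normal** samples only —
  the normal panel acts as the control standard and the cancer group's
  thresholds would otherwise shift the rank alphabet used to compare the
  two conditions.
- **Exact oracle**: `dp_optimal_objective` computes the true minimum
  weighted-L1 objective over all contiguous k-partitions by dynamic
  programming (O(k·n²) with prefix sums). It shares no code with the
  iterative algorithm and anchors the optimality tests.

## Rank-based variation (CV)

Expression CV on raw values grows with expression level; measuring
variation on tri-level **ranks** (1 = low, 2 = moderate, 3 = high, cells at
or below background masked) removes that scale effect. Per gene,
`CV = sigma / mu` with the **population** standard deviation (divide by N —
the gene's samples are the whole population of interest, not a sample from
a larger one); fewer than two usable ranks leaves CV undefined. Status
classes: constant `[0, q1]`, moderately variable `(q1, q3]`, variable
`(q3, ∞)`, where q1/q3 are the quartiles (linear interpolation between
order statistics) of the normal-group HK CV distribution. CV = 0 counts as
constant so every gene receives a status, including the case q1 = 0 that
arises when more than a quarter of genes never change rank. Reference
human-data quartiles (0.14 / 0.26) are available as defaults. Transitions
between the normal and cancer statuses of shared HK genes are tallied in a
3 × 3 matrix whose row sums equal the per-status totals in normal.

## MDAD statistics

For each gene, with max/min taken over **strictly positive** entries per
group: `MD = log2(max_n/min_n) − log2(max_c/min_c)` (span-width difference;
negative = wider in cancer) and `AD = ½(log2 max_n + log2 min_n) − ½(log2
max_c + log2 min_c)` (mid-level difference; negative = higher in cancer).
Raw ratios `maxR = max_n/max_c`, `minR = min_n/min_c` use 0 / ∞ for genes
on in only one condition; genes silent everywhere are dropped. Accumulation
tables report the percentage of genes with ratio ≤ 1 at two decimals
(half-up).

**Wilcoxon signed-rank** against a zero-median null, two-sided: exact zero
differences dropped, ties share average ranks. For n ≤ 20 the p-value is
exact — the sign-flip distribution of W⁺ is built by convolution over the
2×-scaled (integer) ranks, equivalent to enumerating all 2ⁿ sign
assignments. Above 20, a normal approximation with tie-corrected variance
(−Σ(t³−t)/48) and 0.5 continuity correction. Z always carries the sign of
(W⁺ − n(n+1)/4). α = 0.05 for the reject flag.

## Profile clustering

Spearman correlation between sample expression profiles (average ranks on
ties); distance 1 − ρ; agglomerative clustering with average linkage
(complete/single available). Sample ids are sorted lexicographically before
clustering so scipy's internal tie-breaking cannot make output depend on
input column order. Trees export to Newick; `cut_k` reads out a k-cluster
partition and, given labels, purity (fraction of samples agreeing with
their cluster's majority label). Constant profiles have undefined
correlations and are rejected with the offending sample named.

## Structure bias

Features come from the **representative transcript — the one with the
longest CDS** — giving a single consistent structure per locus: gene span,
CDS length, exon count, minimal-intron count (≤ 125 bp), large-intron count
(≥ 50 kb), GC fraction. The intron cutoffs are configurable; the defaults
follow common usage in the gene-architecture literature. Each HK class is
compared against its complement with a two-sided Mann-Whitney rank-sum test
per feature (a distribution-shift question, hence a rank test); the
direction flag is the sign of the median difference when p < α, 0
otherwise. A class covering all genes reports zero shift (p = 1) by
definition. Under a null with no class/structure association the rejection
rate is controlled at the nominal level (checked by label permutation).

## Synthetic generator

The generator produces annotation, a two-group expression matrix and an
intergenic negative set with planted truth. Independent seeded substreams
(`default_rng([stage, seed])`) make each stage reproducible in isolation:
drawing more intergenic values never changes the expression matrix.

What it emulates: a 12 normal + 9 cancer study design; four gene classes in
fixed fractions realised as per-sample on/off masks (a class's required
silence gets at least one silent sample); three log-normal expression modes
with a per-gene, per-group mode and planted variation status realised as a
rank template whose CV lands in the status's band; multiplicative per-cell
noise; optional cancer up-regulation (`2^fc` applied to a Bernoulli subset
of shared + cancer-associated genes); silent cells as exact zeros (90 %) or
faint intergenic-level draws, matching how real RPKM noise behaves (an
option `force_zero` exists for exact-recovery tests); annotation with
log-normal exon/intron lengths (heavy tail yields both minimal and large
introns), GC ~ N(0.46, 0.07) with an AT-shift planted in cancer-associated
genes, and an optional intron-length factor for planting large-gene
depletion.

Default calibration and why:

| parameter | default | rationale |
|---|---|---|
| level modes (RPKM) | 0.5 / 6 / 60, ln-sd 0.25 / 0.35 / 0.30 | adjacent modes ~3.5 ln-sd apart so the tri-level boundaries fall in the density gaps |
| level weights | 0.25 / 0.62 / 0.13 | moderate-heavy mix typical of bulk expression histograms |
| intergenic density | lognormal(ln 0.03, 0.7) | ~1.5 decades below the low mode: the FPR/FNR crossing lands near 0.14 RPKM, well clear of both |
| silent_zero_fraction | 0.9 | most silent cells are true zeros; the rest emulate stray reads |
| dropout_rate | 0.4 | silent-sample fraction for classes that require off samples |
| variation_sd | 0.12 (ln) | cell noise small vs rank steps so planted statuses survive |
| cancer_upregulation_log2fc / fraction | 1.0 / 0.7 | a detectable but not universal planted shift |
| at_rich_shift | 0.05 | planted GC depression in cancer-associated genes |

What it does **not** emulate: read-level sampling noise (values are drawn
at the RPKM level directly), isoform deconvolution, between-tissue
biological heterogeneity within the normal group, batch effects, or any
real genome's gene structure. Conclusions about real data require real
data; the generator exists to verify that the pipeline recovers what was
planted.

## Numerical choices

- Report rounding is **half-up** everywhere (`round_half_up`, decimal
  based): integer percents for accounting, two decimals for accumulation
  tables.
- TSV expression output uses `repr(float)` — the shortest lossless
  representation — so write/read round-trips are exact.
- Background tie-breaking uses integer cross-multiplication (above).
- k-medians objectives compare with absolute slack 1e-12; the DP oracle is
  exact up to float summation.
- The exact Wilcoxon enumeration scales ranks by 2 so half-integer tied
  ranks become integers; the convolution is over at most n(n+1) cells.

## Known limitations

- k-medians with restarts is not guaranteed optimal; measured agreement
  with the exact DP optimum is ~98 % on adversarial random instances
  (100 % on well-separated expression-like mixtures). The DP oracle is
  available when a guarantee is needed (small instances).
- The published per-tissue threshold table used in worked examples contains
  one internally inconsistent row (Kidney: parts sum to 13,569 against a
  printed total of 13,695); consistency checks exclude it and document it.
- `spearman_matrix` is dense over samples; it targets sample-level
  clustering (tens of columns), not gene-level clustering.
- The Wilcoxon exact path is O(n² · max_rank) via convolution; above n = 20
  the normal approximation is used (observed |exact − approx| ≤ 0.011 at
  n = 15).
- Five-type classification ignores expression level — a gene scraping past
  the background in every sample and a highly expressed gene are equally HK
  by definition.
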