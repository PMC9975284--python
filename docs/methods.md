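# Methods

## Normalization model

Expression tables from independent studies arrive as counts, TPM, or
array intensities. Counts are converted to TPM
(`rate_f = counts_f / length_f`, scaled so each column sums to 10^6).
Quantile normalization is never applied automatically: it is a per-study
flag, with a diagnostic (a 90th/10th percentile ratio of column sums
above ~2 suggests enabling it). When a gene is represented by several
features, the feature with the highest SD of log2 values is kept (ties
break to the lexicographically smallest feature id) — selection only,
values are never modified.

Linear-scale inputs get `log2(x + 1)`; data already in log space pass
through (per-study `units` flag). The pseudocount and the log handling
of array data are configuration-exposed because different platforms
warrant different choices.

The central transform is **SD-from-median units**: per gene, within each
study × cancer-type stratum, `x' = (x − median) / SD`. The center is the
median (robust to outlying tumors); the spread is the conventional
sample SD about the mean (ddof = 1) — the phrase "standard deviations
from the median" fixes the center but not the spread estimator, and the
conventional SD is the choice made here (configurable in principle,
ddof=1 throughout the package). The transform is a fixed point: applying
it twice equals applying it once. Strata of one sample cannot be
standardized and yield all-missing output with a warning; genes with
fewer than two observations or zero spread map to 0. Genes absent from a
study are missing values, propagated; all downstream correlations and
t-tests use pairwise-complete observations.

Paired metastasis–primary profiles use a different normalization: the
metastasis log2 profile is centered on its paired primary (the primary's
own differential is exactly zero by construction), then per study and
gene divided by the SD across the centered metastasis *and* primary
profiles — the primaries contribute all-zero columns, which is read
literally and shrinks the SD by a deterministic factor (for m pairs the
padded vector has 2m entries). Zero SD maps to 0.

The lymphoma-contamination filter for xenograft studies removes a sample
when the B-cell marker gene (CD19 by convention) sits at ≥3 SD-from-median
units, or when a B-cell signature score — the mean of the signature
genes' values, re-standardized to SD-from-median across the dataset — 
does. A mean of gene values was chosen as the signature combination;
other combinations (medians, weighted sums) would be defensible.

## Subtype discovery

Consensus clustering follows the Monti resampling scheme. Clustering
genes are a uniform random draw (seeded) of n genes among those observed
in at least `min_presence` samples. The sample–sample dissimilarity is
`1 − r` with pairwise-complete Pearson r; pairs sharing fewer than 30
genes get maximal distance 1 with a warning. Because the pairwise
distance does not depend on which other samples are subsampled, the full
distance matrix is computed once and each replicate subsamples it — an
exact optimization that makes 1,000 replicates cheap.

Per replicate, ⌈fraction · n⌉ samples are drawn without replacement and
Ward-clustered; consensus(i, j) is the co-clustering count over the
co-subsampling count (0 for pairs never co-drawn). Defaults: 1,000
replicates at fraction 0.8 (the referenced consensus-clustering
package's conventions); tests and the acceptance script use 15–100
replicates, which this data regime saturates. Ward linkage is scipy's
`ward` on the condensed dissimilarity, i.e. the Ward.D2 convention
treating dissimilarities as Euclidean distances — stated explicitly
because implementations differ. The final per-K assignment cuts an
average-linkage tree of `1 − consensus` at K (matching the reference
package's final-linkage default).

K selection is deliberately not automated. The CDF/Δ-area diagnostic
(area under the empirical CDF of off-diagonal consensus entries, and its
relative increase per K) is reported; the workflow supports working at a
larger K and explicitly merging minor clusters (`--k-work 7 --keep
1,2,3,4` style), because deciding which clusters are robust requires
metadata judgment (e.g. representation across data sources) the code
cannot make.

Minor-cluster reclassification is one-shot: a top-gene model is built
once from the kept clusters' current members, and each minor-cluster
sample moves to the kept subtype whose binary centroid it correlates
with best. No iteration; kept samples never move.

**Top-gene selection.** For every gene and subtype, the Welch t of
subtype-vs-rest is computed; a gene is *eligible* only for the subtype
where its t is maximal (making the lists disjoint by construction), and
each subtype's list is its eligible genes by descending t, ties broken
by gene id, truncated at `n_top` (default 200, giving e.g. a 4 × 200 =
800-gene classifier). The binary centroid matrix sets M[g, k] = 1 iff
gene g is in subtype k's list.

## Classification

A profile in SD units is restricted to the model genes it carries
(pairwise-complete; a floor of 30 shared genes, configurable, below
which classification refuses) and assigned to the centroid column with
the highest Pearson correlation. Assignment is invariant to positive
affine transforms of the profile. Correlation ties break to the lowest
subtype index and are flagged; ties have measure zero on real data.

The signed scheme (for externally supplied {−1,0,1} centroid files, e.g.
a 10-subtype pan-cancer classifier) additionally tests the best
correlation once — two-sided, via `t = r·√((n−2)/(1−r²))` with n−2 df — 
and assigns a nondescript fallback label when p ≥ α (default 0.05). No
multiplicity correction over the K candidate centroids is applied,
matching the single-threshold description of the procedure.

Plurality concordance counts a multi-tumor patient as concordant only
when one subtype *strictly* outnumbers every other among their tumors;
tied modes are non-concordant. Paired concordance reports the
met-vs-primary agreement fraction and, per subtype, the 2×2 overlap
(met = k × primary = k) with a one-sided Fisher exact p.

## Copy number and enrichment

Ploidy correction rescales each sample so its median gene copy value is
2 (`v' = 2v / median`); it is idempotent and applied only to datasets
whose source did not already correct for ploidy (per-dataset flag).
Calls threshold the corrected, possibly non-integer values without
rounding: loss < 2 ≤ neutral < 3 ≤ gain ≤ 5 < amplification. A uniformly
tetraploid genome therefore calls all-neutral after correction — whole-
genome duplication is not a burden of gains. The CNA burden index is the
per-sample SD (ddof = 1) of copy values across genes, reported raw and
centered to SD-from-median units across each dataset's samples.

All 2×2 enrichment tests (copy-gain by subtype, mutation by subtype,
gene-set overlap, annotation terms) are one-sided in the enrichment
direction and share one method switch: Fisher's exact test when any
expected cell is below 5 or the total below 200, otherwise a chi-square
whose two-sided p is halved when the doubly-positive cell exceeds its
expectation (and reflected otherwise). The one-sided chi-square
convention (signed-statistic halving) is stated because conventions
vary.

## Expression and drug associations

Differential expression is the Welch (unequal-variance) t per gene,
subtype vs rest; "t test" alone underdetermines the variant and Welch is
the safer default (a pooled variant would be a one-line change). The
"highest in subtype" flag requires the subtype's mean (on SD-unit
values) to exceed every other subtype's mean. Paired differentials are
the one-sample t of per-pair deltas against zero, equivalent to the
paired t-test; all-zero delta rows report t undefined with p = 1, and
constant non-zero rows report exact separation (p = 0, flagged).

Gene sets are built at nominal per-gene p < 0.01; Storey q-values
(π₀ estimated at λ = 0.5, monotone-smoothed) are reported as a
multiplicity diagnostic but never used for selection — the multiple
criteria stacked on top (orthogonal-family overlap at p < 10⁻⁶,
consistency across dataset families) control false positives instead.
The orthogonal overlap matrix crosses subtype-vs-rest sets with
paired-differential sets over the shared gene universe; the consensus
set unions the diagonal intersections that pass the overlap cutoff.

TF-target screening requires, for a TF and subtype, target-set overlap
p < 10⁻⁶ in *every* supplied dataset family plus the TF's own expression
association at p < 0.05 with a consistent direction in every family.
Reference signature scoring is the Pearson correlation of a profile with
a centered reference differential profile over shared genes (≥30).

Drug association merges ln IC50 tables cellwise (mean where both
present), then runs Welch t per (drug, subtype) of subtype lines vs the
rest; "sensitive" means lower mean ln IC50 in the subtype. Drugs with
fewer than 3 measured lines on either side are flagged and skipped.

## Synthetic data: what it emulates and what it does not

The generator plants exactly the structure the pipeline assumes: K
disjoint modules of genes shifted by `effect_size_delta` (in units of
the log2 noise SD, default 1.5 over 150-gene modules) in their subtype's
samples; per-gene study and tissue location shifts (SD 1.0 and 0.5);
i.i.d. Gaussian log2 noise (σ = 1) exponentiated to a TPM-like positive
scale; 5% of genes dropped per study (independent draws, absent rows
rather than NaN, to exercise gene-universe logic); 20% of patients
contributing 2–5 tumors sharing a subtype (intra-patient switch rate
default 0), to exercise plurality statistics; paired cohorts whose
metastasis keeps the primary's subtype with probability 1 − switch_rate;
copy tables with ploidy drawn from {2: 0.8, 3: 0.1, 4: 0.1}, a 5%
baseline gain rate and an odds multiplier (default 8) for module genes
in their subtype; mutation panels of 102 genes with 5× planted rate
ratios; and ln IC50 = drug baseline + N(0, 1) − 1.0 for planted
sensitive (drug, subtype) pairs, 150 lines per subtype. Defaults were
chosen once as a realistic regime for this kind of compendium (hundreds
of samples per study, ~1–2 SD subtype effects spread over hundreds of
genes, high but imperfect gain odds) and are not tuned per test.

Reproducibility: one integer seed; every generator draws from a named
child seed (CRC32 of the generator name spawned from the master seed),
so outputs are bit-identical per seed and independent of call order.

Deliberately **not** modeled: RNA-seq count overdispersion and
gene-length bias, real CNA segment/arm structure, tumor purity, subtype
proportions varying by cancer type, and correlated noise between genes
outside the planted modules. Passing tests therefore demonstrate that
the pipeline's logic is correct and recovers structure of the assumed
form — not that real compendia satisfy those assumptions.

## Numerical choices and degenerate inputs

- SD is ddof = 1 everywhere; medians are the standard midpoint median.
- Quantile normalization with missing cells falls back to per-column
  quantile interpolation onto the mean quantile curve (101-point grid);
  complete matrices use the exact per-rank-means construction with tied
  input values averaged within a column.
- Pearson correlations against constant vectors are undefined and
  treated as −∞ for argmax purposes (never win a label).
- Problem sizes in the tests and acceptance script (400-sample
  compendia, 60 consensus replicates, 600–2,400 association tests) were
  chosen as the smallest sizes at which the planted effects are
  comfortably identifiable under the generator's defaults.

## Known limitations

- K selection and the choice of clusters to merge are manual by design.
- The signed 10-subtype classifier is consumed from a user-supplied
  file; the package never retrains it.
- No repository download clients (expression archives, drug-screen
  databases): all inputs are local tables.
- Chi-square one-sidedness uses the signed-statistic convention; at
  small counts the Fisher branch of the switch always applies.
- The q-value estimator is the simple λ = 0.5 plug-in, adequate as a
  diagnostic but cruder than spline-based π₀ estimation.
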