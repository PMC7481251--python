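# Methods

This note documents the models and procedures implemented in `txsig`, the
parameters that matter, the numerical conventions, and what the synthetic
data do and do not establish.

## Quantification

Reads are assigned to transcripts fractionally: a read compatible with one
transcript contributes 1; a read compatible with *n* transcripts contributes
1/*n* to each. The total assigned count therefore equals the number of valid
reads exactly (records with an empty candidate list are rejected and
counted). Counts stay fractional through all downstream steps — no rounding.

TPM for transcript *i* with count c_i and length l_i (nt) is
(c_i/l_i) / Σ_j(c_j/l_j) × 10⁶; columns sum to 10⁶ by construction (relative
tolerance 1e-6 is enforced on tagged matrices). CPM omits the length
normalization. Gene-level values sum the gene's transcripts, which preserves
column sums because genes partition transcripts. All-zero samples would make
these ratios undefined; they are returned as zero columns with a degenerate
flag rather than NaNs, so a pipeline can report rather than crash.

**Expression filter.** A gene is kept when it has ≥ 1 unit (CPM or TPM;
threshold and unit are parameters) in at least as many samples as the
smallest (muscle, condition) group, counted matrix-wide. The filter is
idempotent. Both CPM- and TPM-based filtering are supported because count
pipelines conventionally filter on CPM while abundance pipelines filter on
TPM; which one feeds which stage is a configuration choice.

**Fold changes.** logFC = log₂((mean_A + 1)/(mean_B + 1)) on
library-normalized (CPM/TPM) group means. This is deliberately the simplest
estimator with the right shape: every downstream stage (ranking, clustering,
pairwise fits) consumes only a per-gene logFC vector, so a generalized
linear model fit from a dedicated differential-expression package can be
substituted without touching anything else. The pseudocount of 1 unit is
mandatory because the filter only guarantees non-zero expression in
min-group-size samples; log base 2 keeps fold-change interpretation
standard. Swapping the contrast negates the vector exactly.

## Gene–PC alignment

Input is the filtered log₂(TPM+1) matrix X (n genes x m samples, n ≫ m).

1. **Double-centering.** G = X − row means − column means + grand mean.
   Every row and column of G sums to zero (tolerance 1e-10 scaled by matrix
   magnitude). Sequential column-then-row subtraction yields the same
   matrix; the closed form is used and the equivalence is tested. Purely
   additive structure (gene baselines, sample depth offsets) is annihilated.
2. **Thin SVD.** G = U D Vᵀ with singular values descending. λ_j = d_j²/Σd_i²
   equals the eigenvalue fraction of the sample covariance C = GᵀG/(n−1);
   the test suite checks the SVD route against an explicit eigendecomposition
   of C. SVD signs are fixed by making the largest-|entry| coordinate of each
   V column positive (ties → earliest sample), so outputs are stable across
   BLAS implementations. Only the thin factorization is ever materialized.
3. **Projections.** P = G V = U D. Row k of P holds gene k's coordinates in
   PC space; Σ_j P_kj² = ‖g_k‖².
4. **z-scores.** Projections are standardized with the sample standard
   deviation (n−1). The population is configurable:
   - `pooled` (default): one mean/sd over the entire P matrix. This is the
     reading under which the 26-gene toy behaves as documented — with only
     6 planted outliers among 26 genes, a per-PC z-score is mathematically
     capped at √(25/6) ≈ 2.04 and can never clear 1.96 robustly, whereas
     pooling across PCs (whose lower-order columns carry only noise-scale
     projections) restores the expected calibration.
   - `per_pc`: mean/sd across genes within each PC. More natural when many
     samples give many comparable-scale PCs; exposed for that use.
   A zero sd yields z = 0 with a warning instead of NaNs.
5. **Cosines.** cos θ_kj = P_kj/‖g_k‖, the cosine between the centered gene
   vector and PC j — identical to the Pearson correlation between the gene's
   centered profile and the PC's sample coordinates. Σ_j cos²_kj = 1 for any
   gene with nonzero norm; zero-norm genes get cos = 0 with a warning.
6. **Alignment call.** Gene k is aligned with PC j iff |z_kj| ≥ 1.96 and
   |cos_kj| ≥ 0.4 (both thresholds are parameters). The signed sets (up:
   both positive; down: both negative) together with the full gene universe
   feed the integration stages.

The PC carrying a condition contrast (e.g. aging) is located by the largest
two-sample t-statistic of the V coordinates between the two condition
groups, not by its index — in multi-tissue designs the top PCs are tissue
identity and the contrast of interest appears further down the spectrum.

## Signature integration

**Signed overlap.** For signatures A and B restricted to their shared
universe (size N): concordant-up compares A.up with B.up, concordant-down
the down sets, and discordant pools |A.up ∩ B.down| + |A.down ∩ B.up|.
Expected counts are |A||B|/N (summed over the two pooled pairs for
discordant); fold = observed/expected. P-values are two-tailed
hypergeometric (twice the smaller tail, capped at 1), exact for the
concordant categories and checked against explicit summation to 1e-12. The
pooled discordant count has no simple exact null because the two overlaps
are dependent; its p-value convolves the two exact marginal PMFs
(independence approximation), which is accurate when the sets are small
relative to the universe. Empty sets give fold 0 with p = 1 and a flag.

**Clustering.** Agglomerative clustering of per-gene fold-change profiles
with Euclidean distance and average linkage (linkage is configurable), tree
cut to exactly k clusters; k defaults to 10. Rows are sorted by gene id
before linkage so results are independent of input order, and cluster
labels are reassigned by decreasing size (ties by smallest member id).

**Pre-ranked GSEA.** Genes are sorted by the ranking statistic descending,
ties broken lexicographically by gene id so results are platform-stable. The
running sum gains |s|^w / Σ_hits |s|^w at set members (w = 1 by default) and
loses 1/(N−K) at non-members; ES is the extremum of larger magnitude (exact
against a full running-sum enumeration in tests). The null redraws the K
member positions uniformly without replacement — the gene-label permutation
appropriate to pre-ranked input — with 1,000 permutations by default and a
mandatory seed. NES divides ES by the mean |null ES| of the same sign; the
FDR is the standard ratio of same-sign null-NES tail fraction to same-sign
observed-NES tail fraction, with null NES pooled across sets when several
sets are screened together (for a single set this reduces to the normalized
null tail). Leading edge counts members at or before the extremum for
positive ES, and at or after it for negative ES. Significance is reported
at FDR < 0.01. With w = 0 the score is invariant under monotone transforms
of the statistic, which is tested.

**Reversal screen.** Each signature cluster is run through pre-ranked GSEA
against a chosen contrast ranking (typically drug vs untreated aged).
Negative enrichment of an aging-up cluster at FDR < 0.01 is the reversal
readout.

## Pairwise fits

For paired logFC vectors (x, y) over the genes surviving the filter in both
data sets, the summary line is the direction of highest variance: the
leading eigenvector of the 2x2 covariance matrix, through the centroid
(total least squares). For v_xy ≠ 0 the slope equals the closed form
(v_yy − v_xx + √((v_yy − v_xx)² + 4v_xy²)) / (2v_xy), tested against the
eigen solution. Swapping axes maps s → 1/s while Pearson r is unchanged; an
exactly vertical leading direction is reported as an infinite slope with a
flag, and zero variance in both coordinates is an error. The OLS slope is
computed alongside for comparison (TLS is the primary fit because it treats
both fold-change vectors as noisy). The density grid is a plain equal-width
2-D histogram spanning the data range; counts partition the genes.

## Synthetic data

The generators emulate the latent structure the analysis assumes; they are
first-class, tested code with their ground truth always returned.

**Multi-muscle model.** log₂ expression = gene baseline N(8, 2²) +
muscle-identity offset N(0, 0.5²) drawn once per gene x muscle + planted
aging term + N(0, noise_sd²) per cell, exponentiated and rescaled per sample
to 10⁶ (TPM); a counts mode draws Poisson at a configurable library size
(default 2e7). The planted term is direction(±1) × effect_size ×
muscle_scaling[m] in the aged condition; the aged+drug condition carries
(1 + reversal_coefficient[m]) times it, so r = −1 erases the aging shift,
r = 0 leaves it, r = +1 doubles it. Defaults mirror the emulated study
design: 4 muscles x 3 conditions x 6 samples, 2,000 genes, 50 up + 50 down
planted, effect 1.0 log₂, noise 0.3. The unstated spread parameters were
chosen once so that muscle identity dominates the top PCs (as in real
multi-tissue data) while planted aging cosines remain resolvable: baseline
sd 2.0 is a typical log₂-TPM spread, and muscle-offset sd 0.5 puts
tissue-identity variance well above the planted axis without drowning the
per-gene cosine. Under these conditions the alignment rule recovers planted
genes with sensitivity ≥ 0.9 at false-positive rate ≤ 0.05 across seeds
(computed by the test suite and the acceptance script, not asserted here).

**Toy example.** 26 genes x 3 samples: 20 null genes share a per-gene
location across samples; 3 + 3 genes are shifted ±effect_size in sample 3
only; all cells get N(0, noise_sd²) noise. Defaults: effect 2.0, noise 0.25,
seed 7. The underlying distribution is under-specified in the emulating
design (a per-gene t-test condition is not evaluable with one value per
gene per sample), so the generator plants mean shifts and exposes
effect/noise such that the intended significance pattern — all six planted
genes, and no null gene, pass the alignment rule on PC1 — holds by
construction at the defaults; noise 0.25 keeps that pattern in ≈99% of
seeds while leaving λ₁ ≈ 0.9 rather than exactly 1.

**Pseudoalignments.** One record per read; with probability multimap_rate a
read lists its true transcript plus 1–2 decoys. Unique-mapping input makes
weighted counting lossless, which is the test anchor for the 1/n rule.

**What the simulations do not emulate:** read-level sequences, GC/length
bias, batch effects, overdispersed biological replicates beyond log-normal
noise, and correlated gene modules other than the planted signature.
Passing recovery tests therefore demonstrates the statistics behave as
designed under their own assumptions, not performance on real libraries.

## Numerical conventions and edge cases

- Determinism: every stochastic routine takes an explicit seed and refuses
  to run without one (pipeline validation); identical config + seed
  reproduces byte-identical TSV outputs and manifest checksums.
- Ties: gene-id lexicographic order breaks ranking ties (GSEA), cluster
  relabeling ties, and SVD sign ties (earliest sample index).
- Degenerate inputs are flagged, not silently dropped: all-zero samples,
  zero-norm gene rows (cos/z set to 0 with warnings), empty overlap sets
  (p = 1 with a flag), constant projections (z = 0 with a warning).
- Serialization uses 17 significant digits so TSV round-trips are exact to
  double precision; the run manifest records a config hash and per-output
  SHA-256 checksums and is written atomically.

## Problem sizes

The test suite and acceptance script run the simulation at its default
2,000-gene scale for recovery and reversal checks, 500 genes for the
100-replicate null calibration, 300 trials x 500 permutations for GSEA
type-I calibration, and a strided full enumeration (universe ≤ 60) for
hypergeometric exactness. These sizes were chosen as the smallest that make
the Monte-Carlo bounds meaningful.

## Known limitations

- The simplified logFC estimator ignores dispersion and library-composition
  effects; it is a ranking device, not a differential-expression test.
- The discordant-overlap p-value is an independence approximation (see
  above); concordant categories are exact.
- The pooled z-score couples a gene's significance on one PC to the whole
  spectrum; with many samples and many comparable PCs, `per_pc` may be
  preferable, and the choice is surfaced rather than hidden.
- GSEA uses gene-label permutation only; sample-permutation nulls (which
  preserve gene–gene correlation) are out of scope for pre-ranked input.
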