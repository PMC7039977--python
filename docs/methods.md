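# Methods

This note documents the models behind `paleostruct`, the defaults that
matter, what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Observation model

The package's input layer is per-sample, per-SNP allele read counts (or
genotype calls already derived from them) at a fixed capture panel.
Pseudo-haploid calling samples one read uniformly at each covered site
(`P(alt call) = d_alt / (d_ref + d_alt)`) and records a homozygous call;
zero depth is missing. A pseudo-haploid sample therefore contributes exactly
one allele to any group frequency: `k` counts one allele per PH sample and
two per diploid sample. This one-allele rule is what keeps PH sampling noise
from inflating apparent drift in f-statistics and FST.

Site/sample filtering couples two thresholds: samples below 60% site
coverage are *retained* in the output but excluded from the missingness
census, and SNPs missing in more than 90% of census samples are removed.
The census-only reading (rather than dropping poor samples outright) lets
low-coverage individuals through for reporting without letting them distort
site selection; the boundary is strict (`missing fraction > site_missing_max`
removes, so a threshold of 1.0 removes nothing). The MAF boundary is
inclusive: MAF exactly equal to the threshold is kept. LD pruning follows
the plink `--indep-pairwise 200 25 0.4` convention and deterministically
removes the *later* SNP of an offending pair.

## Block jackknife

All ratio-of-sums statistics get standard errors from the weighted
delete-one-block jackknife (Busing, Meijer & van der Leeden 1999) over
contiguous blocks of 1000 markers (`blen`), with the final block per
chromosome allowed to be short and blocks never spanning chromosomes.
Block weights are the per-statistic *used*-site counts, so complete-case
site selection and unequal final blocks are handled uniformly. When a
delete-one-block denominator vanishes (possible only on tiny or degenerate
panels), the point estimate is still returned with SE = NaN rather than an
error.

## f-statistics

Per-site formulas are listed in the README. Two details:

- **Outgroup-f3** uses a synthetic outgroup fixed at the ancestral allele
  with n = 10⁶, which makes the finite-sample correction `h_c/n_c` vanish
  and reduces the statistic to `mean(a·b)` (shared drift). Because that
  outgroup is monomorphic, the heterozygosity-normalized f3 variant is
  undefined there; requesting it raises an error directing to the
  unnormalized mode.
- **Negative admixture-f3** requires the admixed target's own drift to be
  smaller than `α(1−α)·f2(A,B)`; the test scenarios are chosen with deeply
  diverged sources so the signal is identifiable.

FST offers both the Hudson and the Patterson (f2-based) ratio-of-sums
estimators; both need n ≥ 2 per group per site, and first-degree relatives
should be excluded from groups (via `group_frequencies(..., exclude=...)`)
before tallying.

## Rank-constrained admixture models

`build_f4_matrix` computes `A[i][j] = f4(target, sᵢ; r₀, rⱼ)` on the common
site set of all left and right groups, together with the jackknife
covariance Q of the flattened entries and the per-block leave-one-out
matrices. `fit_qpadm` minimizes the GLS quadratic form over rank-(k−1)
matrices by alternating exact GLS updates of the two factors (started at
the truncated SVD, relative tolerance 1e-10, ≤1000 iterations); weights are
the left null vector of the fitted matrix normalized to sum 1, reported
unconstrained with a feasibility flag. Weight SEs come from refitting on
each delete-one-block replicate. Q is ridge-regularized
(ε·trace(Q)/dim, ε = 1e-7) when ill-conditioned. For k = 1 the rank-0
model tests A ≈ 0 (continuity). df = |R| − k follows from the
(rows−rank)(cols−rank) convention with rows = k, cols = |R|−1,
rank = k−1.

**χ² approximation quality.** The LRT p-value treats Q as known, but Q is
itself estimated from g jackknife blocks; with few blocks the statistic is
inflated by roughly the Hotelling factor (g−1)/(g−df−2). Measured on the
benchmark graph: E[LRT/df] ≈ 1.15 at g = 50 and ≈ 1.07–1.11 at g = 100,
independent of SNP count. Calibration experiments therefore use ≥100k SNPs
(g = 100 at blen = 1000), where the 0.05-level rejection rate sits near
nominal (measured 0.035–0.09 across scenarios). Users testing models on
small panels should expect mildly anti-conservative p-values — a property
shared with the reference implementation, which uses the same
approximation. No multiple-testing correction is applied in model scans;
scan tests share data and are highly correlated, and only p < 10⁻³ is
flagged as strong evidence against a model.

## PCA projection and shrinkage

Reference PCA normalizes each SNP to `(g − μ)/√(p(1−p))` with `p = μ/2`
(Patterson normalization; the constant 2 cancels), imputes residual missing
calls to the mean, excludes monomorphic and rare (MAF < 0.05) sites, and
takes the top-K singular vectors with a deterministic sign convention
(largest-|loading| entry positive). Sparse samples are projected by least
squares on the loading rows at their non-missing SNPs; PH 0/2 calls are
projected as-is since their expectation (2p) matches the diploid mean.

Out-of-sample projections in high dimensions are contracted toward the
origin. The correction factor τ_k is estimated empirically: hold out a
fraction of the reference panel, refit, project the held-out individuals,
and take the pooled regression slope of their projections on their
in-sample scores in the full model (refit axes sign-aligned via loading
overlap). The matched-pairs slope was chosen over a ratio of score spreads
because it is insensitive to the population composition of the holdout;
with the spread ratio the 10%-variance-match target is unattainable when
eigenvalues are nearly degenerate. Corrected scores are raw/τ_k, with τ
clipped to (0, 1] and a warning if the pre-clip estimate exceeds 1.05.

τ → 1 only as n·f grows (n = reference size, f = per-SNP between-group
variance fraction); adding SNPs at fixed n does not remove shrinkage. At
typical reference sizes (hundreds of samples) top-PC τ is ~0.9 and higher
PCs shrink more.

## Sample QC decision rules

- **Sexing**: R_x and R_y are per-site mean X and Y depths over the
  autosomal mean. Theoretical values are (1, 0) for XX and (0.5, 0.5) for
  XY; the decision margins (XY: R_y ≥ 0.3 ∧ R_x ≤ 0.8; XX: R_y ≤ 0.1 ∧
  R_x ≥ 0.8; otherwise undetermined, and always undetermined below 1000
  autosomal sites) are deliberately wide so low-coverage noise lands in
  "undetermined" rather than flipping a call.
- **Relatedness**: the normalized pairwise-mismatch statistic r divides a
  pair's PH mismatch rate by the cohort median rate. Under Hardy–Weinberg
  the expectations are 0.5 (same individual/twins), 0.75 (first degree)
  and 1.0 (unrelated), so class boundaries sit at the midpoints 0.625 and
  0.875; a pair is indeterminate when overlap < 5000 SNPs or its 2-SE
  interval spans a boundary. The cohort-median baseline assumes most pairs
  are unrelated; for cohorts dominated by relatives supply a baseline
  cohort explicitly.
- **Y haplogroups**: walk from the root into the child whose marker group
  has the most derived reads (≥1 required), stopping conservatively at
  ties (flagged `ambiguous_at_*`) and flagging off-path nodes with more
  than 10% derived among covered markers (`conflict_*`).

## Synthetic data: what it emulates, what it does not

The generator is frequency-level Balding–Nichols drift on an admixture
graph: a drift edge with parameter F draws the child frequency from
`Beta(p(1−F)/F, (1−p)(1−F)/F)` (mean p, variance F·p(1−p)); admixed nodes
mix parents as `α·p_A + (1−α)·p_B` exactly before their own drift; root
frequencies are uniform on [0.05, 0.95] (capture panels are ascertained
polymorphic). On top sit binomial genotypes, Poisson depth, a scalar
per-read error ε, sex-dependent X/Y coverage (with a 0.5% Y mismapping
rate for XX), Y-marker reads along a haplogroup path, and
duplicate/parent–offspring/unrelated pairs.

It does **not** emulate: linkage between neighboring SNPs (sites are
exchangeable, so block-jackknife calibration tests verify the machinery,
not LD robustness), position-dependent damage profiles (only the scalar
ε), reference bias, contamination mixtures, or ascertainment beyond the
bounded root law. A green recovery test therefore establishes estimator
correctness under the stated model, not robustness to those artifacts.

The benchmark graph (`pipeline.default_graph`) places the two sources on
deeply split lineages with eight right populations attached at different
depths — two adjacent to the source lineages, three mid-depth, three near
the root — which is the minimal layout under which admixture weights are
identifiable from the left×right f4 matrix. A variant (`ghost_graph`)
gives the target a 20% contribution from a population cladal with one
right, the canonical misspecification that the rank test must reject.
Default observation parameters (20 individuals per group, 1× coverage,
ε = 0.005, 50k–100k SNPs) mirror a mid-sized capture study.

## Known limitations

- qpAdm p-values are anti-conservative on panels with fewer than ~100
  jackknife blocks (see above).
- The merge step matches sites by (chromosome, position) and drops
  allele-incompatible (including strand-ambiguous mismatching) sites
  rather than attempting strand flips.
- The relatedness classifier covers degrees ≤1 only; second-degree
  relatives will usually land in "unrelated" or "indeterminate".
- EIGENSTRAT files carry no ploidy metadata; on read, a sample is inferred
  pseudo-haploid iff it carries no heterozygous call.
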