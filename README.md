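# paleostruct

Population-structure inference from capture-based ancient-DNA genotypes.

Ancient-DNA studies of population history typically work from low-coverage
sequencing reads captured at a fixed SNP panel (~1.2M sites). At that
coverage, diploid genotypes cannot be called reliably, so the field works
with *pseudo-haploid* genotypes — at each covered SNP one read is sampled at
random and the sample is declared homozygous for that read's allele — and
with estimators that are robust to this observation model. `paleostruct`
implements that analysis stack as a tested, reusable Python library:

- **I/O and panel management** — EIGENSTRAT (.geno/.snp/.ind) and VCF
  readers/writers, panel merging with allele harmonization, site/sample
  missingness filters, MAF filtering, sliding-window LD pruning, and
  contiguous marker blocks for the jackknife.
- **Sample QC** — pseudo-haploid calling from allele read counts; genetic
  sexing from X/Y/autosome coverage ratios; first-degree-relative screening
  by normalized pairwise mismatch (READ-style); Y-haplogroup assignment by
  walking a marker tree on derived/ancestral read counts.
- **f-statistics** — Patterson f3 (with the outgroup-f3 device of an
  ancestral-allele outgroup fixed at n = 10⁶), f4 and D, and FST (Hudson and
  Patterson ratio-of-sums estimators), all with weighted block-jackknife
  standard errors (default 1000 markers per block).
- **PCA projection** — Patterson-normalized PCA on modern reference
  genotypes, least-squares projection of sparse ancient samples onto the
  fixed axes, and an empirical per-PC correction for high-dimensional
  projection shrinkage.
- **qpAdm-style admixture modeling** — rank-constrained fitting of the
  left×right f4 matrix: admixture weights from the left null space,
  jackknife weight SEs, a χ² likelihood-ratio rejection test
  (df = |R| − k), and combinatorial 1–5-source model scans.
- **Synthetic data** — a Balding–Nichols admixture-graph generator
  (frequency-level drift, binomial genotypes, Poisson read depth, per-read
  error, sex-chromosome coverage, Y-marker reads, related pairs) so the
  whole pipeline is testable end to end without external downloads.

## The statistics in brief

For group allele frequencies `a, b, c, d` with sample sizes `n_•` and
heterozygosity `h = p(1−p)·n/(n−1)`, per-site values are combined as ratios
of sums over the usable sites:

```
f3(C; A, B)  = mean[ (c−a)(c−b) − h_c/n_c ]
f4(A,B;C,D)  = mean[ (a−b)(c−d) ]
D(A,B;C,D)   = Σ(a−b)(c−d) / Σ(a+b−2ab)(c+d−2cd)
FST (Hudson) = Σ[(p₁−p₂)² − p₁q₁/(n₁−1) − p₂q₂/(n₂−1)] / Σ[p₁q₂ + p₂q₁]
```

Pseudo-haploid samples contribute **one** allele each to `(k, n)` so their
sampling noise does not masquerade as genetic drift. Standard errors come
from the weighted delete-one-block jackknife (Busing et al. 1999) over
contiguous marker blocks that never span a chromosome.

A k-source admixture model for a target T implies that the k×(|R|−1) matrix
`A[i][j] = f4(T, sᵢ; r₀, rⱼ)` over right populations R has rank k−1, with
the mixture weights `w` (Σw = 1) spanning its left null space. The fit
minimizes `(vec(A)−vec(Â))ᵀ Q⁻¹ (vec(A)−vec(Â))` over rank-(k−1) matrices
(Q = block-jackknife covariance); the minimum is the LRT statistic,
asymptotically χ² with df = |R| − k.

## Worked example

Simulate capture-style data (15 populations, 50,000 SNPs, 25 pseudo-haploid
individuals per group at 2× coverage) from the built-in benchmark graph, in
which `Target` is a 30% / 70% mixture of `SrcA` and `SrcB`:

```bash
python -c "from paleostruct.pipeline import default_graph; default_graph().to_yaml('bench.yaml')"
paleostruct simulate --graph bench.yaml --n-snps 50000 --n-ind 25 \
    --coverage 2.0 --seed 7 --out demo
paleostruct qpadm fit demo --target Target --sources SrcA,SrcB \
    --rights Outgroup,R0,R1,R2,R3,R4,R5,R6,R7 --blen 1000
paleostruct stat f3 demo --target Target --a SrcA --b SrcB --blen 1000
paleostruct stat fst demo --a SrcA --b SrcB --estimator hudson --blen 1000
```

prints

```
target Target: SrcA=0.295±0.013, SrcB=0.705±0.013
LRT 1.50 df 7 p 0.982 feasible=True rejected=False
f3(Target; SrcA, SrcB) = -0.00128363 SE 0.000102 Z -12.59 (50000 SNPs)
FST[hudson](SrcA, SrcB) = 0.0287258 SE 0.000483
```

Reading these: the estimated admixture weight 0.295 ± 0.013 recovers the
simulated 0.30; p = 0.98 means the two-source model is not rejected; the
strongly negative admixture-f3 (Z = −12.6) independently confirms that
`Target` is a mixture of populations related to the two sources; and the
source populations are differentiated at FST ≈ 0.029.

The same flow is available as a library (`paleostruct.simulate`,
`paleostruct.qc`, `paleostruct.fstats`, `paleostruct.qpadm`,
`paleostruct.pca`) and as one call, `paleostruct run --config run.yaml`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end synthetic analysis from scratch —
generating admixture-graph data under the given seed, pseudo-haploid
calling, filtering, outgroup-f3, FST, and the rank-constrained admixture
fit — and writes the results JSON to `--out`.

## Scope

Read alignment, damage rescaling, contamination estimation, mtDNA
haplogrouping and the ADMIXTURE model itself are out of scope: the package
consumes post-alignment allele read counts or genotype calls. See
`docs/methods.md` for the models, defaults and known limitations.
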