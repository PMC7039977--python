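"""Patterson f-statistics, D, and FST with weighted block-jackknife errors.

All estimators operate on per-group, per-SNP allele counts (k alt alleles
out of n observed).  Pseudo-haploid samples contribute exactly one allele
each; diploid samples two.  Per-site values are combined as ratios of sums
over the sites where every participating group is observed, and standard
errors come from the weighted delete-one-block jackknife (blocks of
contiguous markers, default 1000 per block, never spanning chromosomes).

Per-site formulas (group frequencies a, b, c, d with sample sizes n_*,
heterozygosity term h = p (1 - p) n / (n - 1)):

    f3(C; A, B)  num = (c - a)(c - b) - h_c / n_c        den = 1 (or h_c)
    f4(A,B;C,D)  num = (a - b)(c - d)                    den = 1
    D(A,B;C,D)   num = (a - b)(c - d)
                 den = (a + b - 2ab)(c + d - 2cd)
    FST hudson   num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
                 den = p1(1-p2) + p2(1-p1)
    FST patterson num = (p1-p2)^2 - h1/n1 - h2/n2        den = num + h1 + h2

The f3 bias correction h_c / n_c removes the finite-sample inflation from
estimating the "apex" population C; a synthetic outgroup fixed at the
ancestral allele with n = 10^6 makes the correction vanish, reducing
outgroup-f3 to the mean of a*b (shared drift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, BlockPartition, GenotypeMatrix
from .jackknife import JackknifeEstimate, jackknife_ratio


@dataclass
class GroupFrequencies:
    """Per-group alt-allele counts: k (alt alleles) and n (total observed)."""

    groups: list[str]
    k: np.ndarray   # groups x snps, float64
    n: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=np.float64)
        self.n = np.asarray(self.n, dtype=np.float64)
        if self.k.shape != self.n.shape or self.k.shape[0] != len(self.groups):
            raise ValueError("k/n shape mismatch with groups")
        if np.any(self.k > self.n) or np.any(self.k < 0):
            raise ValueError("require 0 <= k <= n")
        self._index = {g: i for i, g in enumerate(self.groups)}

    def row(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        if group not in self._index:
            raise KeyError(f"unknown group label {group!r}")
        i = self._index[group]
        return self.k[i], self.n[i]

    def freq(self, group: str) -> np.ndarray:
        k, n = self.row(group)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, k / np.maximum(n, 1), np.nan)

    @property
    def n_snps(self) -> int:
        return self.k.shape[1]

    def add_group(self, label: str, k: np.ndarray, n: np.ndarray
                  ) -> "GroupFrequencies":
        return GroupFrequencies(self.groups + [label],
                                np.vstack([self.k, k[None, :]]),
                                np.vstack([self.n, n[None, :]]))


@dataclass
class FStatResult:
    """A statistic's estimate with jackknife SE and block bookkeeping."""

    statistic: str
    labels: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_snps: int
    n_blocks: int


def _wrap(name: str, labels: tuple[str, ...], est: JackknifeEstimate) -> FStatResult:
    return FStatResult(name, labels, est.estimate, est.se, est.z,
                       est.n_snps, est.n_blocks)


def group_frequencies(geno: GenotypeMatrix, groups: dict[str, str] | None = None,
                      exclude: set[str] | None = None) -> GroupFrequencies:
    """Tally per-group allele counts from a genotype matrix.

    ``groups`` maps sample_id -> group label (defaults to the matrix's
    ``group_label`` column).  Diploid samples contribute two alleles per
    non-missing call, pseudo-haploid samples one — the one-allele rule that
    prevents pseudo-haploid sampling noise from masquerading as drift.
    ``exclude`` drops samples (e.g. first-degree relatives) before tallying.
    """
    ids = geno.samples["sample_id"]
    if groups is None:
        groups = dict(zip(ids, geno.samples["group_label"]))
    unknown = set(groups) - set(ids)
    if unknown:
        raise KeyError(f"group map references unknown samples: {sorted(unknown)}")
    exclude = exclude or set()

    labels = sorted(set(groups.values()))
    label_of = np.array([groups.get(s, None) for s in ids], dtype=object)
    ph = geno.ploidy_mask
    obs = ~geno.missing_mask
    calls = np.where(obs, geno.calls, 0).astype(np.float64)

    K = np.zeros((len(labels), geno.n_snps))
    N = np.zeros_like(K)
    for gi, lab in enumerate(labels):
        in_group = (label_of == lab) & ~np.isin(ids, list(exclude))
        if not in_group.any():
            raise ValueError(f"group {lab!r} is empty")
        for si in np.flatnonzero(in_group):
            w = 1.0 if ph[si] else 2.0
            K[gi] += np.where(ph[si], calls[si] / 2.0, calls[si]) * obs[si]
            N[gi] += w * obs[si]
    return GroupFrequencies(labels, K, N)


def fixed_outgroup(variants: pd.DataFrame, n_fixed: int = 10 ** 6,
                   label: str = "Ancestral") -> tuple[str, np.ndarray, np.ndarray]:
    """Synthetic outgroup fixed for the ancestral allele with huge n.

    Setting n = 10^6 makes the finite-sample heterozygosity correction
    h / n vanish in outgroup-f3.  Sites with unknown ancestral allele
    (not matching ref or alt) get n = 0 and are excluded downstream.
    Returns (label, k, n) suitable for :meth:`GroupFrequencies.add_group`.
    """
    anc = variants["allele_ancestral"].to_numpy()
    ref = variants["allele_ref"].to_numpy()
    alt = variants["allele_alt"].to_numpy()
    k = np.where(anc == alt, float(n_fixed), 0.0)
    n = np.where((anc == ref) | (anc == alt), float(n_fixed), 0.0)
    return label, k, n


def _hzty(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """h = p(1-p) n/(n-1); NaN where n < 2."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(n > 1, p * (1 - p) * n / np.maximum(n - 1, 1), np.nan)


def f3(freqs: GroupFrequencies, target: str, a: str, b: str,
       blocks: BlockPartition, normalize: bool = False) -> FStatResult:
    """f3(target; A, B) with the target's finite-sample correction.

    Negative f3 with |Z| > 3 is evidence that ``target`` is admixed
    between populations related to A and B; with a distant outgroup as
    ``target``, f3 measures the shared drift of A and B (outgroup-f3).
    ``normalize`` divides by the target's heterozygosity sum (errors out
    for a monomorphic target such as the fixed ancestral outgroup).
    """
    kc, nc = freqs.row(target)
    ka, na = freqs.row(a)
    kb, nb = freqs.row(b)
    usable = (na >= 1) & (nb >= 1) & (nc >= 2)
    with np.errstate(invalid="ignore"):
        pa, pb, pc = ka / np.maximum(na, 1), kb / np.maximum(nb, 1), kc / np.maximum(nc, 1)
    hc = _hzty(pc, nc)
    num = np.where(usable, (pc - pa) * (pc - pb) - hc / np.maximum(nc, 2), np.nan)
    if normalize:
        den = np.where(usable, hc, np.nan)
        if np.nansum(den) == 0:
            raise ValueError(
                "normalized f3 undefined: target heterozygosity sum is zero "
                "(monomorphic outgroup) — run unnormalized")
    else:
        den = np.ones_like(num)
    est = jackknife_ratio(num, den, blocks.block_index, blocks.g)
    return _wrap("f3", (target, a, b), est)


def f4_or_d(freqs: GroupFrequencies, a: str, b: str, c: str, d: str,
            blocks: BlockPartition, mode: str = "f4") -> FStatResult:
    """f4(A, B; C, D) or the normalized D statistic.

    Both test treeness of the unrooted tree ((A,B),(C,D)): expectation 0
    without gene flow.  D divides by the per-site ABBA+BABA normalizer
    (a + b - 2ab)(c + d - 2cd).
    """
    if mode not in ("f4", "D"):
        raise ValueError("mode must be 'f4' or 'D'")
    rows = [freqs.row(x) for x in (a, b, c, d)]
    usable = np.all([n >= 1 for _, n in rows], axis=0)
    pa, pb, pc, pd_ = (np.where(n > 0, k / np.maximum(n, 1), np.nan)
                       for k, n in rows)
    num = np.where(usable, (pa - pb) * (pc - pd_), np.nan)
    if mode == "D":
        den = np.where(usable, (pa + pb - 2 * pa * pb) * (pc + pd_ - 2 * pc * pd_),
                       np.nan)
        if np.nansum(den) == 0:
            raise ValueError("D statistic undefined: zero denominator sum")
    else:
        den = np.ones_like(num)
    est = jackknife_ratio(num, den, blocks.block_index, blocks.g)
    return _wrap(mode, (a, b, c, d), est)


def fst(freqs: GroupFrequencies, a: str, b: str, blocks: BlockPartition,
        estimator: str = "hudson") -> FStatResult:
    """Pairwise FST by Hudson's or Patterson's ratio-of-sums estimator.

    Both numerators subtract the within-population sampling variance, so
    two samples from the same population give an estimate near 0, and both
    require n >= 2 per group per site.  First-degree relatives should be
    removed from each group before tallying counts (see
    :func:`group_frequencies`'s ``exclude``).
    """
    if estimator not in ("hudson", "patterson"):
        raise ValueError("estimator must be 'hudson' or 'patterson'")
    k1, n1 = freqs.row(a)
    k2, n2 = freqs.row(b)
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = k1 / np.maximum(n1, 1)
        p2 = k2 / np.maximum(n2, 1)
        if estimator == "hudson":
            num = ((p1 - p2) ** 2
                   - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
                   - p2 * (1 - p2) / np.maximum(n2 - 1, 1))
            den = p1 * (1 - p2) + p2 * (1 - p1)
        else:
            h1, h2 = _hzty(p1, n1), _hzty(p2, n2)
            num = (p1 - p2) ** 2 - h1 / np.maximum(n1, 2) - h2 / np.maximum(n2, 2)
            den = num + h1 + h2
    num = np.where(usable, num, np.nan)
    den = np.where(usable, den, np.nan)
    if np.nansum(den) == 0:
        raise ValueError("FST undefined: zero denominator sum")
    est = jackknife_ratio(num, den, blocks.block_index, blocks.g)
    return _wrap(f"fst_{estimator}", (a, b), est)


def outgroup_f3_matrix(freqs: GroupFrequencies, groups: list[str],
                       outgroup: str, blocks: BlockPartition) -> pd.DataFrame:
    """Symmetric matrix of f3(outgroup; g_i, g_j) for all pairs.

    Higher values mean more drift shared since divergence from the
    outgroup.  The diagonal is left NaN.  Returns a long-format frame via
    ``.attrs['results']`` plus the square estimate matrix.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    mat = pd.DataFrame(np.nan, index=groups, columns=groups)
    results = []
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            res = f3(freqs, outgroup, gi, gj, blocks)
            mat.loc[gi, gj] = mat.loc[gj, gi] = res.estimate
            results.append(res)
    mat.attrs["results"] = results
    return mat
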