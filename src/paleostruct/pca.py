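"""Patterson-normalized PCA, least-squares projection, shrinkage correction.

The reference PCA is computed on (near-)complete modern genotypes: each
SNP column is mean-centered and divided by the square root of its
heterozygosity, sqrt(p (1 - p)) with p = mu / 2 (the Patterson
normalization; the constant factor 2 cancels in every comparison).  Sparse
ancient samples are then projected onto the fixed axes by least squares
over their non-missing SNPs.

Out-of-sample projections in high dimensions are systematically contracted
toward the origin ("shrinkage"): with many more SNPs than samples, sample
eigenvalues overestimate population eigenvalues and the fitted axes
overfit the reference panel, so a projected individual's score on PC k is
biased toward 0 by a factor tau_k < 1.  We estimate tau_k empirically by
repeatedly holding out reference individuals, refitting the PCA, and
regressing their out-of-sample projections on their in-sample scores;
corrected scores are raw / tau_k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, maf_filter

logger = logging.getLogger(__name__)


@dataclass
class PCAModel:
    """Fitted reference PCA: per-SNP moments, loadings, eigenvalues, tau."""

    snp_ids: np.ndarray
    mu: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray       # SNPs x K, orthonormal columns
    eigenvalues: np.ndarray    # length K, non-increasing
    scores: pd.DataFrame       # in-sample reference scores
    tau: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


@dataclass
class ProjectedScores:
    """Raw and (optionally) shrinkage-corrected scores per sample."""

    raw: pd.DataFrame
    corrected: pd.DataFrame | None
    n_snps_used: pd.Series
    unreliable: pd.Series


def _normalized_matrix(geno: GenotypeMatrix, mask: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Impute-to-mean, center and scale the masked genotype matrix."""
    calls = geno.calls[:, mask].astype(np.float64)
    miss = calls == MISSING
    calls[miss] = np.nan
    mu = np.nanmean(calls, axis=0)
    p = mu / 2.0
    scale = np.sqrt(p * (1.0 - p))
    calls = np.where(miss, mu[None, :], calls)
    X = (calls - mu[None, :]) / scale[None, :]
    return X, mu, scale


def _fix_signs(loadings: np.ndarray, scores: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Resolve PC sign indeterminacy: largest-|loading| entry positive."""
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return loadings, scores


def fit_reference_pca(geno_modern: GenotypeMatrix, k: int,
                      maf_min: float = 0.05) -> PCAModel:
    """Fit a K-component PCA on modern reference genotypes.

    Rare variants (MAF < ``maf_min``) and monomorphic SNPs are excluded;
    residual missing calls are imputed to the SNP mean before
    normalization.  Eigenvalues are the singular values squared over
    (n - 1), returned non-increasing.
    """
    mask = maf_filter(geno_modern, maf_min)
    n = geno_modern.n_samples
    if k > min(n - 1, int(mask.sum())):
        raise ValueError(f"K={k} exceeds the rank bound "
                         f"min(n_samples - 1, n_snps) = {min(n - 1, int(mask.sum()))}")
    X, mu, scale = _normalized_matrix(geno_modern, mask)
    poly = scale > 0
    X, mu, scale = X[:, poly], mu[poly], scale[poly]
    snp_ids = geno_modern.variants["snp_id"].to_numpy()[mask][poly]

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = Vt[:k].T
    scores = U[:, :k] * S[:k]
    loadings, scores = _fix_signs(loadings, scores)
    eigenvalues = S[:k] ** 2 / (n - 1)
    score_df = pd.DataFrame(scores, index=geno_modern.samples["sample_id"],
                            columns=[f"PC{i + 1}" for i in range(k)])
    return PCAModel(snp_ids, mu, scale, loadings, eigenvalues, score_df)


def project_samples(model: PCAModel, geno: GenotypeMatrix,
                    min_snps: int = 5000) -> ProjectedScores:
    """Least-squares projection of (possibly sparse) samples onto fixed axes.

    Per sample, the normalized genotype vector restricted to its
    non-missing SNPs shared with the model is regressed on the
    corresponding rows of the loading matrix; with complete data and
    orthonormal loadings this reduces to the inner-product score.
    Pseudo-haploid 0/2 calls are projected as-is — their expectation 2p
    matches the diploid mean, the extra sampling noise is absorbed by the
    least squares.  Samples sharing fewer than ``min_snps`` SNPs are
    flagged unreliable.  Applies the model's tau if present.
    """
    pos = {s: i for i, s in enumerate(model.snp_ids)}
    cols = np.array([pos.get(s, -1) for s in geno.variants["snp_id"]])
    in_model = cols >= 0
    raw = np.full((geno.n_samples, model.k), np.nan)
    used = np.zeros(geno.n_samples, dtype=int)
    for i in range(geno.n_samples):
        obs = in_model & (geno.calls[i] != MISSING)
        idx = cols[obs]
        used[i] = len(idx)
        if len(idx) == 0:
            continue
        x = (geno.calls[i, obs].astype(np.float64) - model.mu[idx]) / model.scale[idx]
        beta, *_ = np.linalg.lstsq(model.loadings[idx], x, rcond=None)
        raw[i] = beta
    ids = geno.samples["sample_id"]
    raw_df = pd.DataFrame(raw, index=ids,
                          columns=[f"PC{i + 1}" for i in range(model.k)])
    corrected = raw_df / model.tau if model.tau is not None else None
    return ProjectedScores(raw=raw_df, corrected=corrected,
                           n_snps_used=pd.Series(used, index=ids),
                           unreliable=pd.Series(used < min_snps, index=ids))


def estimate_shrinkage(model: PCAModel, geno_modern: GenotypeMatrix,
                       holdout_fraction: float = 0.1, seed: int = 0,
                       n_repeats: int = 4, maf_min: float = 0.05) -> np.ndarray:
    """Estimate per-PC shrinkage factors tau_k by a holdout experiment.

    Each repeat holds out a random ``holdout_fraction`` of the reference
    individuals, refits the PCA on the remainder, and projects the held-out
    individuals onto the refit axes.  tau_k is the pooled regression slope
    of the held-out projections on the same individuals' in-sample scores
    in ``model`` — a matched-pairs estimator that, unlike a ratio of score
    spreads, is insensitive to the population composition of the holdout.
    Refit axes are sign-aligned to the model's via their loading overlap.
    The estimate is clipped to (0, 1]; a pre-clip value >= 1.05 triggers a
    warning (shrinkage should not expand scores — K may be too small or
    the panel large enough that shrinkage is negligible).
    """
    rng = np.random.default_rng(seed)
    n = geno_modern.n_samples
    n_hold = max(1, int(round(holdout_fraction * n)))
    if n - n_hold <= model.k:
        raise ValueError("too few reference samples to hold any out")
    pos = {s: i for i, s in enumerate(model.snp_ids)}
    num = np.zeros(model.k)
    den = np.zeros(model.k)
    for rep in range(n_repeats):
        held = rng.choice(n, size=n_hold, replace=False)
        keep = np.setdiff1d(np.arange(n), held)
        sub_model = fit_reference_pca(geno_modern.take_samples(keep),
                                      model.k, maf_min=maf_min)
        proj = project_samples(sub_model, geno_modern.take_samples(held),
                               min_snps=0).raw.to_numpy()
        ref = model.scores.to_numpy()[held]
        shared = [(pos[s], j) for j, s in enumerate(sub_model.snp_ids)
                  if s in pos]
        fi, si = (np.array(x) for x in zip(*shared))
        dots = np.einsum("ij,ij->j", model.loadings[fi], sub_model.loadings[si])
        proj = proj * np.sign(dots)
        num += (proj * ref).sum(axis=0)
        den += (ref * ref).sum(axis=0)
    tau = num / den
    if np.any(tau >= 1.05):
        logger.warning("shrinkage estimate >= 1.05 on PC(s) %s before clipping",
                       np.flatnonzero(tau >= 1.05) + 1)
    return np.clip(tau, np.finfo(float).tiny, 1.0)


def apply_correction(scores: ProjectedScores, tau: np.ndarray) -> ProjectedScores:
    """Divide raw scores by tau element-wise per PC."""
    corrected = scores.raw / tau
    return ProjectedScores(raw=scores.raw, corrected=corrected,
                           n_snps_used=scores.n_snps_used,
                           unreliable=scores.unreliable)


def save_model(model: PCAModel, directory: str) -> None:
    """Persist a model as a directory of TSVs (snps, loadings, eigenvalues,
    scores, and tau when estimated)."""
    import os
    os.makedirs(directory, exist_ok=True)
    pcs = [f"PC{i + 1}" for i in range(model.k)]
    snps = pd.DataFrame({"snp_id": model.snp_ids, "mu": model.mu,
                         "scale": model.scale})
    pd.concat([snps, pd.DataFrame(model.loadings, columns=pcs)], axis=1) \
        .to_csv(os.path.join(directory, "loadings.tsv"), sep="\t", index=False)
    pd.DataFrame({"pc": pcs, "eigenvalue": model.eigenvalues,
                  "tau": model.tau if model.tau is not None else np.nan}) \
        .to_csv(os.path.join(directory, "eigenvalues.tsv"), sep="\t", index=False)
    model.scores.to_csv(os.path.join(directory, "scores.tsv"), sep="\t")


def load_model(directory: str) -> PCAModel:
    import os
    load = pd.read_csv(os.path.join(directory, "loadings.tsv"), sep="\t")
    eig = pd.read_csv(os.path.join(directory, "eigenvalues.tsv"), sep="\t")
    scores = pd.read_csv(os.path.join(directory, "scores.tsv"), sep="\t",
                         index_col=0)
    pcs = eig["pc"].tolist()
    tau = eig["tau"].to_numpy()
    return PCAModel(snp_ids=load["snp_id"].to_numpy(),
                    mu=load["mu"].to_numpy(), scale=load["scale"].to_numpy(),
                    loadings=load[pcs].to_numpy(),
                    eigenvalues=eig["eigenvalue"].to_numpy(), scores=scores,
                    tau=None if np.all(np.isnan(tau)) else tau)
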