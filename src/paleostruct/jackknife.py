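"""Weighted delete-one-block jackknife for ratio-of-sums statistics.

Nearby SNPs are correlated through linkage, so naive per-site variance
estimates are anti-conservative.  The standard remedy in allele-sharing
statistics is the block jackknife: delete one contiguous block of markers
at a time, recompute the statistic, and combine the leave-one-out values.
Because the final block on each chromosome may be short, blocks carry
unequal weights m_j; we use the weighted jackknife of Busing, Meijer &
van der Leeden (1999), which reduces to Tukey's formula for equal blocks.

For a statistic theta computed on all M markers and leave-one-out values
theta_{-j} with block weights m_j (sum M, g blocks, h_j = M / m_j):

    theta_J = g * theta - sum_j (1 - m_j / M) * theta_{-j}
    tau_j   = h_j * theta - (h_j - 1) * theta_{-j}
    var     = (1 / g) * sum_j (tau_j - theta_J)^2 / (h_j - 1)

All statistics in this package are ratios of per-site sums, so the
leave-one-out values are obtained exactly from per-block partial sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class JackknifeEstimate:
    """Point estimate with jackknife standard error."""

    estimate: float
    se: float
    n_blocks: int
    n_snps: int
    #: leave-one-out estimates, one per contributing block
    loo: np.ndarray

    @property
    def z(self) -> float:
        return self.estimate / self.se if self.se > 0 else np.nan


def block_sums(values: np.ndarray, block_index: np.ndarray, g: int) -> np.ndarray:
    """Per-block sums of ``values`` (NaN treated as 0 / unused)."""
    v = np.where(np.isnan(values), 0.0, values)
    return np.bincount(block_index, weights=v, minlength=g)


def jackknife_from_loo(theta: float | np.ndarray, loo: np.ndarray,
                       weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted jackknife mean and variance from leave-one-out estimates.

    ``loo`` has shape (g, ...) and ``weights`` the per-block marker counts.
    Returns (theta_J, var), each with the trailing shape of ``theta``.
    """
    weights = np.asarray(weights, dtype=np.float64)
    g = len(weights)
    if g < 2:
        raise ValueError("jackknife needs at least 2 blocks")
    M = weights.sum()
    h = M / weights
    theta = np.asarray(theta, dtype=np.float64)
    loo = np.asarray(loo, dtype=np.float64)
    w = (1.0 - weights / M)
    theta_j = g * theta - np.tensordot(w, loo, axes=(0, 0))
    tau = h[:, None] * theta.reshape(1, -1) - (h - 1.0)[:, None] * loo.reshape(g, -1)
    dev = tau - theta_j.reshape(1, -1)
    var = (dev ** 2 / (h - 1.0)[:, None]).sum(axis=0) / g
    return theta_j.reshape(theta.shape), var.reshape(theta.shape)


def jackknife_ratio(num: np.ndarray, den: np.ndarray,
                    block_index: np.ndarray, g: int,
                    weights: np.ndarray | None = None) -> JackknifeEstimate:
    """Jackknife a ratio-of-sums statistic sum(num)/sum(den) over blocks.

    ``num`` and ``den`` are per-site arrays; sites with NaN numerator are
    unused (their denominator is ignored too).  Blocks without any used
    site drop out of the jackknife.  ``weights`` defaults to the per-block
    used-site counts, matching the convention of f-statistic toolkits.
    """
    used = ~np.isnan(num)
    if den is None:
        den = np.ones_like(num)
    num = np.where(used, num, np.nan)
    den = np.where(used, den, np.nan)

    ns = block_sums(num, block_index, g)
    ds = block_sums(den, block_index, g)
    counts = np.bincount(block_index, weights=used.astype(float), minlength=g)

    active = counts > 0
    if active.sum() < 2:
        raise ValueError("fewer than 2 jackknife blocks contain used sites")
    ns, ds, counts = ns[active], ds[active], counts[active]

    N, D = ns.sum(), ds.sum()
    if D == 0:
        raise ValueError("zero denominator sum in ratio statistic")
    theta = N / D
    with np.errstate(divide="ignore", invalid="ignore"):
        loo = (N - ns) / (D - ds)
    if np.any(~np.isfinite(loo)):
        # a leave-one-block-out denominator vanished: the point estimate is
        # fine but its jackknife SE is undefined (tiny or degenerate panels)
        se = float("nan")
    else:
        w = counts if weights is None else np.asarray(weights, float)[active]
        _, var = jackknife_from_loo(np.array([theta]), loo[:, None], w)
        se = float(np.sqrt(var[0]))
    return JackknifeEstimate(estimate=float(theta), se=se,
                             n_blocks=int(active.sum()),
                             n_snps=int(used.sum()), loo=loo)


def jackknife_cov(theta: np.ndarray, loo: np.ndarray,
                  weights: np.ndarray) -> np.ndarray:
    """Weighted jackknife covariance of a vector statistic.

    ``theta`` has shape (d,), ``loo`` shape (g, d).  Uses the same
    pseudo-value construction as :func:`jackknife_from_loo` with outer
    products in place of squares; the result is symmetric PSD up to
    floating-point error.
    """
    weights = np.asarray(weights, dtype=np.float64)
    g = len(weights)
    M = weights.sum()
    h = M / weights
    w = 1.0 - weights / M
    theta_j = g * theta - w @ loo
    tau = h[:, None] * theta[None, :] - (h - 1.0)[:, None] * loo
    dev = tau - theta_j[None, :]
    cov = (dev.T * (1.0 / (h - 1.0))) @ dev / g
    return 0.5 * (cov + cov.T)
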