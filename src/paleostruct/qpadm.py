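"""Rank-constrained admixture modeling of the left x right f4 matrix (qpAdm).

A target population modeled as a k-way mixture of sources s_1..s_k implies
that the k x (|R| - 1) matrix

    A[i][j] = f4(target, s_i; r_0, r_j)

has rank k - 1, with the admixture weights w (sum 1) spanning its left
null space: f4 is linear in each argument, so target = sum_i w_i s_i gives
sum_i w_i A[i][j] = 0 for every right pair.  The fit minimizes the
generalized quadratic form

    (vec(A) - vec(A_hat))' Q^{-1} (vec(A) - vec(A_hat))

over rank-(k-1) matrices A_hat, where Q is the block-jackknife covariance
of the f4 entries.  The minimized form is the LRT statistic against the
saturated (full-rank) model, asymptotically chi^2 with
df = (rows - rank)(cols - rank) = |R| - k.  Small p-values reject the
proposed admixture scenario; because scans share data across many highly
correlated tests, only p < 1e-3 is treated as strong evidence against a
model.  Weights are reported unconstrained with a feasibility flag (they
may exit [0, 1]); their SEs come from refitting on each delete-one-block
f4 replicate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import BlockPartition
from .fstats import GroupFrequencies
from .jackknife import jackknife_cov, jackknife_from_loo


@dataclass
class F4Matrix:
    """Left x right f4 matrix with jackknife covariance and block replicates."""

    target: str
    sources: list[str]
    rights: list[str]
    A: np.ndarray             # k x (|R| - 1)
    Q: np.ndarray             # covariance of vec(A), row-major
    loo: np.ndarray           # g x k x (|R| - 1) delete-one-block matrices
    block_weights: np.ndarray
    n_snps: int

    @property
    def k(self) -> int:
        return len(self.sources)

    @property
    def df(self) -> int:
        return len(self.rights) - self.k


def build_f4_matrix(freqs: GroupFrequencies, lefts: list[str],
                    rights: list[str], blocks: BlockPartition) -> F4Matrix:
    """Compute A[i][j] = f4(target, s_i; r_0, r_j) on the common site set.

    ``lefts`` is (target, source_1, ..., source_k).  Sites are used only
    where every left and right group has at least one observed allele, so
    all entries share one site set.  Q and the delete-one-block replicate
    matrices come from the weighted block jackknife of the flattened
    entries.
    """
    if len(lefts) < 2:
        raise ValueError("need a target plus at least one source")
    overlap = set(lefts) & set(rights)
    if overlap:
        raise ValueError(f"labels in both lefts and rights: {sorted(overlap)}")
    target, sources = lefts[0], list(lefts[1:])
    k = len(sources)
    if len(rights) < k + 2:
        raise ValueError(
            f"need at least {k + 2} rights for df >= 1 with {k} sources "
            f"(df = |R| - k), got {len(rights)}")

    labels = [target] + sources + list(rights)
    ks, ns = zip(*(freqs.row(x) for x in labels))
    ks, ns = np.array(ks), np.array(ns)
    usable = np.all(ns >= 1, axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(ns > 0, ks / np.maximum(ns, 1), np.nan)
    pt = p[0]
    ps = p[1:1 + k]
    pr = p[1 + k:]

    m = len(rights) - 1
    # per-site numerators for all entries: (t - s_i)(r0 - r_j)
    left_diff = pt[None, :] - ps                      # k x S
    right_diff = pr[0][None, :] - pr[1:]              # m x S
    num = left_diff[:, None, :] * right_diff[None, :, :]   # k x m x S
    num = np.where(usable[None, None, :], num, np.nan)

    flat = num.reshape(k * m, -1)
    used = usable
    counts = np.bincount(blocks.block_index, weights=used.astype(float),
                         minlength=blocks.g)
    sums = np.vstack([
        np.bincount(blocks.block_index,
                    weights=np.where(used, flat[e], 0.0),
                    minlength=blocks.g)
        for e in range(k * m)
    ])                                                # (k*m) x g
    active = counts > 0
    if active.sum() < 2:
        raise ValueError("fewer than 2 jackknife blocks contain usable sites")
    counts = counts[active]
    sums = sums[:, active]

    total = sums.sum(axis=1)
    n_used = counts.sum()
    theta = total / n_used
    loo_flat = (total[:, None] - sums) / (n_used - counts)[None, :]   # (k*m) x g
    Q = jackknife_cov(theta, loo_flat.T, counts)
    A = theta.reshape(k, m)
    loo = loo_flat.T.reshape(-1, k, m)
    return F4Matrix(target, sources, list(rights), A, Q, loo,
                    counts, int(n_used))


@dataclass
class QpAdmResult:
    target: str
    sources: list[str]
    weights: np.ndarray
    weight_se: np.ndarray
    lrt: float
    df: int
    p_value: float
    feasible: bool
    rank: int
    n_snps: int
    rejected: bool = False

    def __post_init__(self) -> None:
        self.rejected = self.p_value < 1e-3


def _regularize(Q: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Ridge-regularize an ill-conditioned covariance."""
    d = Q.shape[0]
    ridge = eps * np.trace(Q) / d
    Qr = Q + ridge * np.eye(d)
    if np.linalg.cond(Qr) > 1e12:
        Qr = Q + max(ridge, 1e-12) * 1e3 * np.eye(d)
    return Qr


def _quad_form(resid: np.ndarray, Qinv: np.ndarray) -> float:
    return float(resid @ Qinv @ resid)


def _fit_rank(A: np.ndarray, Qinv: np.ndarray, rank: int,
              tol: float = 1e-10, max_iter: int = 1000) -> tuple[np.ndarray, float]:
    """GLS rank-``rank`` approximation A_hat = U V' by alternating minimization.

    Starts from the truncated SVD and alternates generalized least squares
    for U given V and V given U (each step exact), until the objective's
    relative change drops below ``tol``.
    """
    k, m = A.shape
    d = A.flatten()
    if rank == 0:
        return np.zeros_like(A), _quad_form(d, Qinv)
    Us, Ss, Vts = np.linalg.svd(A, full_matrices=False)
    U = Us[:, :rank] * Ss[:rank]
    V = Vts[:rank].T

    def gls(X: np.ndarray) -> np.ndarray:
        XtW = X.T @ Qinv
        return np.linalg.solve(XtW @ X, XtW @ d)

    obj = np.inf
    for _ in range(max_iter):
        # U step: vec_rows(U V') = kron(I_k, V) @ vec_rows(U)
        Xu = np.kron(np.eye(k), V)
        u = gls(Xu)
        U = u.reshape(k, rank)
        # V step: vec_rows(U V') = kron(U, I_m) @ vec_cols(V)
        Xv = np.kron(U, np.eye(m))
        v = gls(Xv)
        V = v.reshape(rank, m).T
        resid = d - (U @ V.T).flatten()
        new_obj = _quad_form(resid, Qinv)
        if obj - new_obj <= tol * max(abs(obj), 1.0) and np.isfinite(obj):
            obj = new_obj
            break
        obj = new_obj
    return U @ V.T, obj


def _null_weights(A_hat: np.ndarray) -> np.ndarray:
    """Left null vector of the fitted matrix, normalized to sum 1."""
    U, S, Vt = np.linalg.svd(A_hat)
    w = U[:, -1]
    s = w.sum()
    if abs(s) < 1e-12:
        raise np.linalg.LinAlgError("null-space weights sum to ~0")
    return w / s


def fit_qpadm(m: F4Matrix) -> QpAdmResult:
    """Fit the rank-(k-1) admixture model to an f4 matrix.

    Returns mixture weights (sum exactly 1, possibly outside [0, 1] with
    ``feasible=False``), jackknife weight SEs, the LRT statistic and its
    chi^2 upper-tail p-value on df = |R| - k.  For k = 1 the rank-0 model
    tests A ~ 0 (continuity of the target with the single source) and the
    weight is trivially [1].
    """
    k = m.k
    df = m.df
    Qr = _regularize(m.Q)
    try:
        Qinv = np.linalg.inv(Qr)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "f4 covariance is singular even after regularization") from exc

    rank = k - 1
    A_hat, lrt = _fit_rank(m.A, Qinv, rank)
    if k == 1:
        weights = np.array([1.0])
        w_se = np.array([0.0])
        feasible = True
    else:
        weights = _null_weights(A_hat)
        loo_w = np.empty((len(m.block_weights), k))
        for b in range(len(m.block_weights)):
            Ab_hat, _ = _fit_rank(m.loo[b], Qinv, rank)
            loo_w[b] = _null_weights(Ab_hat)
        _, var = jackknife_from_loo(weights, loo_w, m.block_weights)
        w_se = np.sqrt(var)
        feasible = bool(np.all((weights >= 0) & (weights <= 1)))
    p = float(stats.chi2.sf(lrt, df))
    return QpAdmResult(m.target, m.sources, weights, w_se, float(lrt), df, p,
                       feasible, rank, m.n_snps)


def model_scan(freqs: GroupFrequencies, target: str, candidates: list[str],
               rights: list[str], blocks: BlockPartition,
               k_range: range = range(1, 6)) -> pd.DataFrame:
    """Fit every k-source combination of ``candidates`` for each k.

    Returns a table sorted by p descending within k, with a ``rejected``
    column marking models at p < 1e-3 and a ``feasible`` column for
    weights inside [0, 1].  No multiple-testing correction is applied; the
    tests share data and are highly correlated.
    """
    rows = []
    for k in k_range:
        if k > len(candidates):
            break
        for sources in itertools.combinations(candidates, k):
            fm = build_f4_matrix(freqs, [target, *sources], rights, blocks)
            res = fit_qpadm(fm)
            rows.append({
                "k": k,
                "sources": ",".join(sources),
                "weights": ",".join(f"{w:.4f}" for w in res.weights),
                "weight_se": ",".join(f"{s:.4f}" for s in res.weight_se),
                "lrt": res.lrt,
                "df": res.df,
                "p": res.p_value,
                "feasible": res.feasible,
                "rejected": res.rejected,
            })
    table = pd.DataFrame(rows)
    return (table.sort_values(["k", "p"], ascending=[True, False])
                 .reset_index(drop=True))
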