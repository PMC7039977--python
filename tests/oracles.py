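"""Naive per-site reference implementations used as independent oracles.

Everything here is written with explicit Python loops over sites and plain
float arithmetic, deliberately sharing no code with the package's
vectorized estimators.
"""

from __future__ import annotations

import math


def _freq(k, n):
    return k / n if n > 0 else None


def naive_f3(kc, nc, ka, na, kb, nb):
    """Ratio-of-sums f3(C; A, B) with C's finite-sample correction."""
    num_sum, n_used = 0.0, 0
    for i in range(len(kc)):
        if na[i] >= 1 and nb[i] >= 1 and nc[i] >= 2:
            a = ka[i] / na[i]
            b = kb[i] / nb[i]
            c = kc[i] / nc[i]
            h_c = c * (1 - c) * nc[i] / (nc[i] - 1)
            num_sum += (c - a) * (c - b) - h_c / nc[i]
            n_used += 1
    return num_sum / n_used, n_used


def naive_f4(ka, na, kb, nb, kc, nc, kd, nd, mode="f4"):
    """Mean of (a-b)(c-d), or the D-statistic ratio."""
    num_sum, den_sum, n_used = 0.0, 0.0, 0
    for i in range(len(ka)):
        if min(na[i], nb[i], nc[i], nd[i]) >= 1:
            a, b = ka[i] / na[i], kb[i] / nb[i]
            c, d = kc[i] / nc[i], kd[i] / nd[i]
            num_sum += (a - b) * (c - d)
            den_sum += (a + b - 2 * a * b) * (c + d - 2 * c * d)
            n_used += 1
    if mode == "f4":
        return num_sum / n_used, n_used
    return num_sum / den_sum, n_used


def naive_fst(k1, n1, k2, n2, estimator="hudson"):
    """Ratio-of-sums Hudson or Patterson FST."""
    num_sum, den_sum, n_used = 0.0, 0.0, 0
    for i in range(len(k1)):
        if n1[i] >= 2 and n2[i] >= 2:
            p1, p2 = k1[i] / n1[i], k2[i] / n2[i]
            if estimator == "hudson":
                num = ((p1 - p2) ** 2
                       - p1 * (1 - p1) / (n1[i] - 1)
                       - p2 * (1 - p2) / (n2[i] - 1))
                den = p1 * (1 - p2) + p2 * (1 - p1)
            else:
                h1 = p1 * (1 - p1) * n1[i] / (n1[i] - 1)
                h2 = p2 * (1 - p2) * n2[i] / (n2[i] - 1)
                num = (p1 - p2) ** 2 - h1 / n1[i] - h2 / n2[i]
                den = num + h1 + h2
            num_sum += num
            den_sum += den
            n_used += 1
    return num_sum / den_sum, n_used


def naive_truth_fst_hudson(p1, p2):
    """Hudson FST computed directly from true allele frequencies
    (infinite sample size: no finite-sample correction terms)."""
    num = sum((a - b) ** 2 for a, b in zip(p1, p2))
    den = sum(a * (1 - b) + b * (1 - a) for a, b in zip(p1, p2))
    return num / den
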