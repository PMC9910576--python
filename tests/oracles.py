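"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementation: template
matrices are materialized explicitly and all pairwise Chebyshev distances
are computed by numpy broadcasting.
"""

from __future__ import annotations

import numpy as np


def _template_matrix(x: np.ndarray, length: int, d: int, n_vec: int) -> np.ndarray:
    return np.stack([[x[i + k * d] for k in range(length)] for i in range(n_vec)])


def sample_entropy_oracle(x: np.ndarray, m: int = 2, r: float | None = None, d: int = 1) -> float:
    """O(N^2) sample entropy from explicit pairwise distance matrices."""
    x = np.asarray(x, float)
    if r is None:
        r = 0.2 * x.std()
    n_vec = len(x) - m * d
    Tm = _template_matrix(x, m, d, n_vec)
    Tm1 = _template_matrix(x, m + 1, d, n_vec)
    Dm = np.abs(Tm[:, None, :] - Tm[None, :, :]).max(axis=2)
    Dm1 = np.abs(Tm1[:, None, :] - Tm1[None, :, :]).max(axis=2)
    off = ~np.eye(n_vec, dtype=bool)
    c_m = int((Dm[off] <= r).sum())
    c_m1 = int((Dm1[off] <= r).sum())
    if c_m == 0 or c_m1 == 0:
        return float("nan")
    return -np.log(c_m1 / c_m)


def fuzzy_entropy_oracle(
    x: np.ndarray, m: int = 2, r: float = 0.2, n: float = 1.0, d: int = 1
) -> float:
    """O(N^2) fuzzy entropy: baseline-removed templates, exp similarity."""
    x = np.asarray(x, float)
    n_vec = len(x) - m * d
    phis = []
    for length in (m, m + 1):
        T = _template_matrix(x, length, d, n_vec)
        T = T - T.mean(axis=1, keepdims=True)
        D = np.abs(T[:, None, :] - T[None, :, :]).max(axis=2)
        theta = np.exp(-(D**n) / r)
        off = ~np.eye(n_vec, dtype=bool)
        phis.append(theta[off].sum() / (n_vec * (n_vec - 1)))
    return -np.log(phis[1] / phis[0])


def shannon_entropy_oracle(x: np.ndarray, n_bins: int, log_base: float = 2.0) -> float:
    """Direct -sum P log P over an explicitly constructed histogram."""
    x = np.asarray(x, float)
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    h = 0.0
    for lo, hi, last in zip(edges[:-1], edges[1:], [False] * (n_bins - 1) + [True]):
        c = np.sum((x >= lo) & (x < hi)) if not last else np.sum((x >= lo) & (x <= hi))
        if c:
            p = c / len(x)
            h -= p * np.log(p) / np.log(log_base)
    return h


def fdr_bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg from the step-up definition, O(n^2)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        adj[i] = running_min
    return adj


def partial_corr_precision_oracle(x, y, confounds) -> float:
    """Partial correlation from the inverse covariance (precision) matrix."""
    Z = np.column_stack([x, y, confounds])
    P = np.linalg.inv(np.cov(Z, rowvar=False))
    return -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
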