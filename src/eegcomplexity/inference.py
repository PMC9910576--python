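"""Association screening: partial correlations, FDR, cluster permutation.

Feature-score relations are assessed with partial Pearson correlations
controlling for nuisance covariates (age, number of removed epochs; sex
for mixed-sex cohorts).  Multiplicity is handled by Benjamini-Hochberg FDR
for channel-wise and microstate families, and by a cluster-size
permutation test on the channels x scales MSE grid (clusters of
same-signed suprathreshold cells connected through montage neighborhood or
consecutive scales).

Also houses the a priori power utility for the two-sided test of zero
Pearson correlation (noncentral-t method).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import InvalidParameterError


# ---------------------------------------------------------------------------
# confound regression

def regress_out(values: np.ndarray, confounds: np.ndarray | None) -> np.ndarray:
    """Column-wise OLS residuals against [1, confounds], then z-standardized.

    Zero-variance residual columns (features that are exact linear
    functions of the confounds) raise, as standardization is undefined.
    """
    X = np.asarray(values, dtype=float)
    one_d = X.ndim == 1
    if one_d:
        X = X[:, None]
    n = X.shape[0]
    if confounds is None or np.size(confounds) == 0:
        resid = X - X.mean(axis=0)
    else:
        C = np.asarray(confounds, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if n <= C.shape[1] + 2:
            raise InvalidParameterError("too few observations for confound regression")
        D = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise InvalidParameterError("rank-deficient confound matrix")
        beta, *_ = np.linalg.lstsq(D, X, rcond=None)
        resid = X - D @ beta
    sd = resid.std(axis=0)
    # exact linear functions of the confounds leave only rounding noise
    if np.any(sd <= 1e-10 * np.maximum(X.std(axis=0), 1e-300)):
        raise InvalidParameterError("zero-variance residuals; cannot standardize")
    out = (resid - resid.mean(axis=0)) / sd
    return out[:, 0] if one_d else out


def partial_pearson(
    x: np.ndarray, y: np.ndarray, confounds: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation and two-sided p (t distribution).

    Degrees of freedom are n - 2 - n_confounds.  With no confounds this is
    the plain Pearson correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    n_conf = 0 if confounds is None or np.size(confounds) == 0 else (
        np.atleast_2d(np.asarray(confounds)).shape[1]
        if np.asarray(confounds).ndim > 1 else 1
    )
    if n <= n_conf + 3:
        raise InvalidParameterError("too few observations")
    rx = regress_out(x, confounds)
    ry = regress_out(y, confounds)
    r = float(np.clip((rx @ ry) / n, -1.0, 1.0))  # both are z-scored (ddof 0)
    df = n - 2 - n_conf
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def fdr_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# MSE cluster-size permutation test

@dataclass
class ClusterPermutationResult:
    """Observed suprathreshold clusters against a max-cluster-size null."""

    r_matrix: np.ndarray = field(repr=False)       # (channels, scales)
    p_matrix: np.ndarray = field(repr=False)
    significant_mask: np.ndarray = field(repr=False)
    clusters: list[tuple[np.ndarray, int]]          # (flat cell indices, sign)
    cluster_sizes: list[int]
    min_significant_size: int | None
    null_max_sizes: np.ndarray = field(repr=False)
    n_permutations: int


def _grid_clusters(
    mask: np.ndarray, signs: np.ndarray, adjacency: np.ndarray
) -> list[np.ndarray]:
    """Connected components of same-signed suprathreshold cells.

    Cells (c, s) and (c', s') are linked iff same scale and neighboring
    channels, or same channel and consecutive scales.
    """
    n_ch, n_sc = mask.shape
    flat = np.flatnonzero(mask.ravel())
    if len(flat) == 0:
        return []
    index = {cell: i for i, cell in enumerate(flat)}
    visited = np.zeros(len(flat), dtype=bool)
    clusters = []
    sign_flat = signs.ravel()
    for start in range(len(flat)):
        if visited[start]:
            continue
        stack = [flat[start]]
        visited[start] = True
        comp = []
        while stack:
            cell = stack.pop()
            comp.append(cell)
            c, s = divmod(cell, n_sc)
            sgn = sign_flat[cell]
            neighbors = []
            if s > 0:
                neighbors.append(cell - 1)
            if s < n_sc - 1:
                neighbors.append(cell + 1)
            neighbors.extend(c2 * n_sc + s for c2 in np.flatnonzero(adjacency[c]))
            for nb in neighbors:
                j = index.get(nb)
                if j is not None and not visited[j] and sign_flat[nb] == sgn:
                    visited[j] = True
                    stack.append(nb)
        clusters.append(np.array(sorted(comp)))
    return clusters


def _mse_partial_grid(
    mse_stack: np.ndarray, scores: np.ndarray, confounds: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized partial r and p of every (channel, scale) cell vs score."""
    n, n_ch, n_sc = mse_stack.shape
    X = regress_out(mse_stack.reshape(n, n_ch * n_sc), confounds)
    y = regress_out(scores, confounds)
    r = np.clip((X.T @ y) / n, -1.0, 1.0)
    n_conf = 0 if confounds is None or np.size(confounds) == 0 else (
        np.atleast_2d(np.asarray(confounds)).shape[1]
        if np.asarray(confounds).ndim > 1 else 1
    )
    df = n - 2 - n_conf
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return r.reshape(n_ch, n_sc), p.reshape(n_ch, n_sc)


def mse_cluster_permutation(
    mse_stack: np.ndarray,
    scores: np.ndarray,
    adjacency: np.ndarray,
    confounds: np.ndarray | None = None,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ClusterPermutationResult:
    """Cluster-size permutation test on the channel x scale MSE grid.

    The null distribution of the maximal cluster size is built by
    re-running the screening with permuted scores; the minimal significant
    size is the smallest s with P(max null cluster >= s) < alpha.
    """
    mse_stack = np.asarray(mse_stack, float)
    n, n_ch, n_sc = mse_stack.shape
    r, p = _mse_partial_grid(mse_stack, scores, confounds)
    mask = p < alpha
    signs = np.sign(r).astype(int)
    clusters = _grid_clusters(mask, signs, adjacency)
    sizes = [len(c) for c in clusters]

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        ys = rng.permutation(scores)
        rp, pp = _mse_partial_grid(mse_stack, ys, confounds)
        cl = _grid_clusters(pp < alpha, np.sign(rp).astype(int), adjacency)
        null_max[b] = max((len(c) for c in cl), default=0)

    min_sig: int | None = None
    if sizes:
        for s in range(1, max(max(sizes), null_max.max()) + 2):
            if np.mean(null_max >= s) < alpha:
                min_sig = s
                break
    sig_mask = np.zeros((n_ch, n_sc), dtype=bool)
    if min_sig is not None:
        for c in clusters:
            if len(c) >= min_sig:
                sig_mask.ravel()[c] = True
    return ClusterPermutationResult(
        r_matrix=r,
        p_matrix=p,
        significant_mask=sig_mask,
        clusters=[(c, int(signs.ravel()[c[0]])) for c in clusters],
        cluster_sizes=sizes,
        min_significant_size=min_sig,
        null_max_sizes=null_max,
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# a priori power

def correlation_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided test of zero correlation at sample size n.

    Uses the classical bias-corrected Fisher-z method (Cohen, 1988; the
    formula behind ``pwr.r.test`` and G*Power's correlation module): the
    critical sample correlation is derived from the central t distribution
    with df = n-2, and the probability of exceeding it under the
    alternative is evaluated on the arctanh scale with the small-sample
    mean correction r / (2(n-1)).
    """
    if n < 4:
        return 0.0
    df = n - 2
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    r_crit = np.sqrt(tcrit**2 / (tcrit**2 + df))
    zr = np.arctanh(r) + r / (2.0 * (n - 1))
    zc = np.arctanh(r_crit)
    s = np.sqrt(n - 3)
    return float(stats.norm.cdf((zr - zc) * s) + stats.norm.cdf((-zr - zc) * s))


def power_min_n(
    r: float, power: float = 0.80, alpha: float = 0.05, n_max: int = 1_000_000
) -> int:
    """Smallest n at which the zero-correlation test reaches target power."""
    if not 0 < r < 1 or not 0 < power < 1:
        raise InvalidParameterError("r and power must lie in (0, 1)")
    lo, hi = 4, 8
    while correlation_power(r, hi, alpha) < power:
        hi *= 2
        if hi > n_max:
            raise InvalidParameterError(f"no n <= {n_max} reaches power {power}")
    while lo < hi:
        mid = (lo + hi) // 2
        if correlation_power(r, mid, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    return lo
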