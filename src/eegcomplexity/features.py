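"""Per-subject complexity feature vectors and their factor structure.

The canonical configuration (28 channels, 20 MSE scales, 5 microstates)
yields exactly 709 named features per subject:

    22   GFP entropies (Shannon + Fuzzy + 20-scale MSE of the GFP)
    56   channel-wise Shannon + Fuzzy entropy
    560  channel x scale MSE
    1    number of GFP peaks
    20   coverage / lifespan / frequency / lifespan-at-peaks x 5 states
    25   transition probabilities
    25   transition probabilities at GFP peaks

For prediction, the 560 MSE values are collapsed into 32 aggregates (8
spatial clusters x 4 five-scale bins) to curb multicollinearity, and the
candidate pool is those 32 + channel and GFP Shannon/Fuzzy entropies + the
71 microstate measures (161 candidates).

The covariance structure of the features is summarized by exploratory
factor analysis: factor count from parallel analysis, unweighted-least-
squares (principal-axis / MINRES) extraction, promax rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entropy import EntropyProfile
from .microstates import MicrostateMeasures
from .montage import CHANNELS_28, CLUSTERS_8
from .preprocess import InvalidParameterError

#: MSE scale bins used for aggregation (inclusive scale ranges).
SCALE_BINS: tuple[tuple[int, int], ...] = ((1, 5), (6, 10), (11, 15), (16, 20))


# ---------------------------------------------------------------------------
# feature naming and assembly

def feature_names(
    channels: tuple[str, ...] = CHANNELS_28,
    n_scales: int = 20,
    k: int = 5,
) -> list[str]:
    """Deterministic canonical ordering of the full feature vector."""
    names = ["shannon.GFP", "fuzzy.GFP"]
    names += [f"mse.GFP.s{t:02d}" for t in range(1, n_scales + 1)]
    names += [f"shannon.{ch}" for ch in channels]
    names += [f"fuzzy.{ch}" for ch in channels]
    for ch in channels:
        names += [f"mse.{ch}.s{t:02d}" for t in range(1, n_scales + 1)]
    names.append("n_gfp_peaks")
    for measure in ("coverage", "lifespan", "frequency", "lifespan_peaks"):
        names += [f"{measure}.{j}" for j in range(k)]
    names += [f"trans.{i}.{j}" for i in range(k) for j in range(k)]
    names += [f"transpeaks.{i}.{j}" for i in range(k) for j in range(k)]
    return names


def expected_feature_count(n_channels: int = 28, n_scales: int = 20, k: int = 5) -> int:
    """Closed form: 2 + S + 2C + C*S + 1 + 4k + 2k^2 (= 709 canonically)."""
    return 2 + n_scales + 2 * n_channels + n_channels * n_scales + 1 + 4 * k + 2 * k * k


def assemble_features(
    profile: EntropyProfile, ms: MicrostateMeasures,
    channels: tuple[str, ...] = CHANNELS_28,
) -> pd.Series:
    """The named per-subject complexity feature vector (709 canonical)."""
    n_scales = len(profile.params.scales)
    k = len(ms.coverage)
    values = [profile.gfp_shannon, profile.gfp_fuzzy, *profile.gfp_mse]
    values += list(profile.shannon)
    values += list(profile.fuzzy)
    values += list(profile.mse.ravel())
    values.append(float(ms.n_gfp_peaks))
    values += list(ms.coverage) + list(ms.lifespan) + list(ms.frequency)
    values += list(ms.lifespan_at_peaks)
    values += list(ms.transitions.ravel()) + list(ms.transitions_at_peaks.ravel())
    names = feature_names(channels, n_scales, k)
    if len(values) != len(names):
        raise InvalidParameterError(
            f"feature count mismatch: {len(values)} values vs {len(names)} names"
        )
    return pd.Series(values, index=names, dtype=float)


# ---------------------------------------------------------------------------
# MSE aggregation and the prediction-candidate pool

def aggregate_mse(
    profile: EntropyProfile,
    clusters: dict[str, tuple[str, ...]] | None = None,
    channels: tuple[str, ...] = CHANNELS_28,
    scale_bins: tuple[tuple[int, int], ...] = SCALE_BINS,
) -> pd.Series:
    """Cluster x scale-bin MSE means: 8 x 4 = 32 aggregated values.

    Averages first over the cluster's channels, then over each scale bin;
    NaN scale cells are skipped (bin mean over available values).
    """
    clusters = CLUSTERS_8 if clusters is None else clusters
    ch_index = {c: i for i, c in enumerate(channels)}
    scales = np.asarray(profile.params.scales)
    out = {}
    for cname, chans in clusters.items():
        rows = [ch_index[c] for c in chans]
        cluster_mse = profile.mse[rows].mean(axis=0)
        for lo, hi in scale_bins:
            sel = (scales >= lo) & (scales <= hi)
            vals = cluster_mse[sel]
            out[f"mse_agg.{cname}.s{lo:02d}-{hi:02d}"] = (
                float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else np.nan
            )
    return pd.Series(out, dtype=float)


def candidate_features(
    profile: EntropyProfile, ms: MicrostateMeasures,
    channels: tuple[str, ...] = CHANNELS_28,
    include_gfp_mse: bool = False,
) -> pd.Series:
    """The reduced prediction-candidate pool (161 canonical).

    32 aggregated MSE + 28 channel Shannon + 28 channel Fuzzy + GFP
    Shannon + GFP Fuzzy + 71 microstate measures.  GFP MSE excluded by
    default (toggle via ``include_gfp_mse``).
    """
    full = assemble_features(profile, ms, channels)
    parts = [aggregate_mse(profile, channels=channels)]
    parts.append(full[[f"shannon.{c}" for c in channels]])
    parts.append(full[[f"fuzzy.{c}" for c in channels]])
    parts.append(full[["shannon.GFP", "fuzzy.GFP"]])
    if include_gfp_mse:
        parts.append(full[[n for n in full.index if n.startswith("mse.GFP.")]])
    k = len(ms.coverage)
    ms_names = ["n_gfp_peaks"]
    for measure in ("coverage", "lifespan", "frequency", "lifespan_peaks"):
        ms_names += [f"{measure}.{j}" for j in range(k)]
    ms_names += [f"trans.{i}.{j}" for i in range(k) for j in range(k)]
    ms_names += [f"transpeaks.{i}.{j}" for i in range(k) for j in range(k)]
    parts.append(full[ms_names])
    return pd.concat(parts)


def build_subject_table(
    features: list[pd.Series],
    subjects: pd.DataFrame,
) -> pd.DataFrame:
    """Combine per-subject feature vectors with scores and covariates.

    Subjects whose feature vector contains missing values (undefined
    entropy sentinels) are dropped, with the reason recorded in the
    returned frame's ``attrs["dropped"]``.
    """
    if len(features) != len(subjects):
        raise InvalidParameterError("feature list and subject table length mismatch")
    X = pd.DataFrame([f for f in features])
    X.index = subjects.index
    merged = pd.concat([subjects.reset_index(drop=True), X.reset_index(drop=True)], axis=1)
    bad = merged.isna().any(axis=1)
    dropped = [
        (str(merged.loc[i, "subject_id"]) if "subject_id" in merged else str(i),
         list(merged.columns[merged.loc[i].isna()])[:5])
        for i in merged.index[bad]
    ]
    out = merged.loc[~bad].reset_index(drop=True)
    out.attrs["dropped"] = dropped
    return out


# ---------------------------------------------------------------------------
# factor analysis

def parallel_analysis(
    table: pd.DataFrame | np.ndarray,
    n_random: int = 100,
    seed: int | None = None,
    quantile: float | None = 0.95,
) -> int:
    """Factor count: observed correlation eigenvalues above the random ones.

    Compares the eigenvalues of the observed correlation matrix with the
    eigenvalue spectrum of ``n_random`` standard-normal datasets of the
    same shape, retaining leading eigenvalues up to the first one not
    exceeding the reference curve.  The reference is the per-rank
    ``quantile`` of the random eigenvalues (default 0.95, the conservative
    criterion with near-zero null retention); ``quantile=None`` uses the
    per-rank mean (Horn's original rule).
    """
    X = np.asarray(table, dtype=float)
    n, p = X.shape
    if n <= 3:
        raise InvalidParameterError("need more than 3 observations")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise InvalidParameterError("zero-variance column; correlation undefined")
    R = np.corrcoef(X, rowvar=False)
    obs = np.sort(np.linalg.eigvalsh(R))[::-1]
    rng = np.random.default_rng(seed)
    rand = np.empty((n_random, p))
    for b in range(n_random):
        Z = rng.standard_normal((n, p))
        rand[b] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    ref = rand.mean(axis=0) if quantile is None else np.quantile(rand, quantile, axis=0)
    below = obs <= ref
    return int(np.argmax(below)) if below.any() else p


@dataclass
class FactorSolution:
    """Rotated EFA solution with explained-variance bookkeeping."""

    loadings: np.ndarray = field(repr=False)      # (p, q) promax pattern
    variance_explained: np.ndarray                # per-factor fractions (unrotated)
    cumulative_variance: np.ndarray
    factor_correlations: np.ndarray = field(repr=False)  # (q, q) after promax
    communalities: np.ndarray = field(repr=False)
    heywood: bool
    n_iter: int


def _varimax(L: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    p, q = L.shape
    R = np.eye(q)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        var = s.sum()
        if var_old != 0 and (var - var_old) / var < tol:
            break
        var_old = var
    return L @ R, R


def _promax(L: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Promax: varimax target raised to `power`, oblique procrustes fit."""
    V, _ = _varimax(L)
    target = np.sign(V) * np.abs(V) ** power
    # least-squares transformation V @ T ~ target
    T, *_ = np.linalg.lstsq(V, target, rcond=None)
    # normalize so factor variances are 1 under the oblique transformation
    d = np.sqrt(np.diag(np.linalg.inv(T.T @ T)))
    T = T * d
    pattern = V @ T
    phi = np.linalg.inv(T.T @ T)
    return pattern, phi


def efa_minres_promax(
    table: pd.DataFrame | np.ndarray,
    n_factors: int,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> FactorSolution:
    """Unweighted-least-squares factor extraction with promax rotation.

    Communalities are iterated principal-axis style (diagonal of R replaced
    by current communalities, loadings from the top eigenpairs) until the
    residuals stabilize -- the classical minimum-residual fit.  Heywood
    cases (communalities reaching 1) are reported, not silently clipped.
    """
    X = np.asarray(table, dtype=float)
    n, p = X.shape
    if not 1 <= n_factors < p:
        raise InvalidParameterError(f"n_factors={n_factors} out of range for p={p}")
    R = np.corrcoef(X, rowvar=False)
    if np.any(~np.isfinite(R)):
        raise InvalidParameterError("degenerate correlation matrix")

    # initial communalities: squared multiple correlations where invertible
    try:
        Rinv = np.linalg.inv(R)
        h2 = np.clip(1.0 - 1.0 / np.diag(Rinv), 0.0, 0.995)
    except np.linalg.LinAlgError:
        A = np.abs(R - np.eye(p))
        h2 = A.max(axis=1)

    heywood = False
    L = None
    for it in range(1, max_iter + 1):
        Rh = R.copy()
        np.fill_diagonal(Rh, h2)
        vals, vecs = np.linalg.eigh(Rh)
        idx = np.argsort(vals)[::-1][:n_factors]
        lam = vals[idx]
        lam_clipped = np.maximum(lam, 0.0)
        L = vecs[:, idx] * np.sqrt(lam_clipped)
        new_h2 = (L**2).sum(axis=1)
        if np.any(new_h2 >= 1.0):
            heywood = True
            new_h2 = np.minimum(new_h2, 0.999)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            break
        h2 = new_h2

    ev = np.sort(np.maximum((L**2).sum(axis=0), 0.0))[::-1]
    var_frac = ev / p
    pattern, phi = _promax(L)
    # sign convention: dominant loading positive per factor
    signs = np.sign(pattern[np.abs(pattern).argmax(axis=0), np.arange(pattern.shape[1])])
    signs[signs == 0] = 1.0
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)
    return FactorSolution(
        loadings=pattern,
        variance_explained=var_frac,
        cumulative_variance=np.cumsum(var_frac),
        factor_correlations=phi,
        communalities=h2,
        heywood=heywood,
        n_iter=it,
    )


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-congruence matrix between two loading matrices."""
    An = A / np.linalg.norm(A, axis=0, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=0, keepdims=True)
    return An.T @ Bn
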