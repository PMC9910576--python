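"""Multimodal prediction of ability scores from complexity features.

The model follows the connectome-predictive-modeling recipe adapted to
complexity features: candidate features are confound-residualized and
z-standardized, those correlating with the (residualized) score at
p < 0.05 are split by correlation sign into a positive set X+ and a
negative set X-, and the prediction for a subject is

    yhat = beta0 + beta1 * (mean(X+) - mean(X-)),  beta0 = 0, beta1 = 1.

In the typical configuration -- negatively correlated features having
negative means for high scorers -- this equals the absolute-value form
|mean(X+)| + |mean(X-)| of the combination rule; the literal
absolute-value variant is available via ``signed=False`` but is
non-monotone in the features (both extremes of a feature mean map to
large predictions) and therefore cannot produce positive prediction
correlations.  An empty selection predicts the constant 0
and scores a correlation of 0 -- the "zero convention" that produces the
characteristic null-distribution spike at zero.

Internal validity uses 10-fold cross-validation with stratified folds
(sort scores, deal round-robin); significance comes from permutation
nulls: the mean CV correlation over many stratified divisions is compared
with CV correlations obtained on permuted scores.  External application
freezes the full-sample selection and normalization and evaluates on an
independent cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import InvalidParameterError


@dataclass
class PredictionModel:
    """Frozen feature selection plus training normalization parameters."""

    feature_names: list[str]
    pos_mask: np.ndarray = field(repr=False)   # boolean over candidates
    neg_mask: np.ndarray = field(repr=False)
    confound_beta: np.ndarray = field(repr=False)  # (n_conf+1, n_features)
    score_beta: np.ndarray = field(repr=False)     # (n_conf+1,)
    feat_mean: np.ndarray = field(repr=False)
    feat_sd: np.ndarray = field(repr=False)
    score_mean: float = 0.0
    score_sd: float = 1.0
    threshold: float = 0.05
    beta0: float = 0.0
    beta1: float = 1.0
    signed: bool = True

    def __post_init__(self) -> None:
        if np.any(self.pos_mask & self.neg_mask):
            raise InvalidParameterError("positive and negative masks overlap")
        if not 0 < self.threshold < 1:
            raise InvalidParameterError("threshold must lie in (0, 1)")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "pos_features": [n for n, m in zip(self.feature_names, self.pos_mask) if m],
            "neg_features": [n for n, m in zip(self.feature_names, self.neg_mask) if m],
            "pos_mask": self.pos_mask.astype(int).tolist(),
            "neg_mask": self.neg_mask.astype(int).tolist(),
            "confound_beta": self.confound_beta.tolist(),
            "score_beta": np.asarray(self.score_beta).tolist(),
            "feat_mean": self.feat_mean.tolist(),
            "feat_sd": self.feat_sd.tolist(),
            "score_mean": self.score_mean,
            "score_sd": self.score_sd,
            "threshold": self.threshold,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "signed": self.signed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PredictionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            pos_mask=np.array(d["pos_mask"], dtype=bool),
            neg_mask=np.array(d["neg_mask"], dtype=bool),
            confound_beta=np.array(d["confound_beta"]),
            score_beta=np.array(d["score_beta"]),
            feat_mean=np.array(d["feat_mean"]),
            feat_sd=np.array(d["feat_sd"]),
            score_mean=d["score_mean"],
            score_sd=d["score_sd"],
            threshold=d["threshold"],
            beta0=d["beta0"],
            beta1=d["beta1"],
            signed=d["signed"],
        )


# ---------------------------------------------------------------------------
# numpy core (tables in, arrays out; kept lean for permutation loops)

def _design(confounds: np.ndarray | None, n: int) -> np.ndarray:
    if confounds is None or np.size(confounds) == 0:
        return np.ones((n, 1))
    C = np.asarray(confounds, float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(n), C])


def _fit_residualizer(X: np.ndarray, D: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    return beta


def select_features(
    Xz: np.ndarray, yz: np.ndarray, threshold: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Masks of candidates correlating with the score at p < threshold.

    Inputs must already be confound-residualized and z-standardized
    (population SD).  Selection splits by the sign of r.  Empty masks are
    allowed.
    """
    n = len(yz)
    r = np.clip((Xz.T @ yz) / n, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    sig = p < threshold
    return sig & (r > 0), sig & (r < 0)


def cpm_score(
    Xz: np.ndarray,
    pos_mask: np.ndarray,
    neg_mask: np.ndarray,
    beta0: float = 0.0,
    beta1: float = 1.0,
    signed: bool = True,
) -> np.ndarray:
    """Per-subject prediction from z-normalized features and frozen masks.

    ``yhat = beta0 + beta1 (mean X+ - mean X-)`` (signed network-strength
    convention, default) or ``beta0 + beta1 (|mean X+| + |mean X-|)`` with
    ``signed=False``.  An empty mask contributes 0.
    """
    n = Xz.shape[0]
    pos = Xz[:, pos_mask].mean(axis=1) if pos_mask.any() else np.zeros(n)
    neg = Xz[:, neg_mask].mean(axis=1) if neg_mask.any() else np.zeros(n)
    combined = (pos - neg) if signed else (np.abs(pos) + np.abs(neg))
    return beta0 + beta1 * combined


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, defined as 0 when either input is constant (zero convention)."""
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment equalizing score distributions: sort, deal round-robin.

    Subjects are ordered by score (random tie-breaking); each consecutive
    block of k subjects is dealt to the k folds in random order, so every
    fold spans the whole score range while divisions vary with the seed.
    """
    n = len(y)
    if n < 2 * k:
        raise InvalidParameterError(f"need n >= 2k (n={n}, k={k})")
    order = np.lexsort((rng.random(n), y))
    folds = np.empty(n, dtype=int)
    for start in range(0, n, k):
        block = order[start : start + k]
        folds[block] = rng.permutation(k)[: len(block)]
    return folds


def crossval_predict(
    X: np.ndarray,
    y: np.ndarray,
    confounds: np.ndarray | None,
    k: int = 10,
    threshold: float = 0.05,
    signed: bool = True,
    seed: int | np.random.Generator | None = None,
    folds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One stratified k-fold CV run.

    Per fold, confound regression, z-normalization parameters, and feature
    selection are fitted on the training part only and applied to the held
    out fold; folds with empty selections predict 0.  Returns
    ``(yhat, y_residualized, r)`` with r the Pearson correlation between
    predicted and observed (residualized) scores over all subjects.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(y)
    if np.std(y) == 0:
        raise InvalidParameterError("constant scores")
    if folds is None:
        folds = stratified_folds(y, k, rng)
    yhat = np.zeros(n)
    yres = np.zeros(n)
    for f in range(k):
        test = folds == f
        train = ~test
        if np.std(y[train]) == 0:
            raise InvalidParameterError("degenerate fold: constant training scores")
        D_tr = _design(confounds[train] if confounds is not None else None, train.sum())
        D_te = _design(confounds[test] if confounds is not None else None, test.sum())
        bX = _fit_residualizer(X[train], D_tr)
        by = _fit_residualizer(y[train, None], D_tr)[:, 0]
        rX_tr = X[train] - D_tr @ bX
        ry_tr = y[train] - D_tr @ by
        mu, sd = rX_tr.mean(axis=0), rX_tr.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        ymu, ysd = ry_tr.mean(), ry_tr.std()
        Xz_tr = (rX_tr - mu) / sd_safe
        yz_tr = (ry_tr - ymu) / ysd
        pos, neg = select_features(Xz_tr, yz_tr, threshold)
        Xz_te = ((X[test] - D_te @ bX) - mu) / sd_safe
        yhat[test] = cpm_score(Xz_te, pos, neg, signed=signed)
        yres[test] = ((y[test] - D_te @ by) - ymu) / ysd
    return yhat, yres, _safe_pearson(yhat, yres)


@dataclass
class PermutationResult:
    """Observed statistic against a permutation null."""

    observed: float
    null_distribution: np.ndarray = field(repr=False)
    p_value: float
    significant: bool
    n_divisions: int
    n_permutations: int


def permutation_test_internal(
    X: np.ndarray,
    y: np.ndarray,
    confounds: np.ndarray | None,
    k: int = 10,
    threshold: float = 0.05,
    n_divisions: int = 100,
    n_perm: int = 1000,
    signed: bool = True,
    seed: int | None = None,
) -> PermutationResult:
    """Mean CV correlation over stratified divisions vs a permutation null.

    The observed statistic averages ``n_divisions`` CV runs with different
    stratified divisions of the true scores; each null entry is one full
    CV run on permuted scores (empty selections score exactly 0).
    p = (1 + #{null >= observed}) / (1 + n_perm); significance additionally
    requires the observed mean to exceed the null 95th percentile.
    """
    rng = np.random.default_rng(seed)
    obs = np.array([
        crossval_predict(X, y, confounds, k, threshold, signed, rng)[2]
        for _ in range(n_divisions)
    ])
    observed = float(obs.mean())
    null = np.array([
        crossval_predict(X, rng.permutation(y), confounds, k, threshold, signed, rng)[2]
        for _ in range(n_perm)
    ])
    p = float((1 + np.sum(null >= observed)) / (1 + n_perm))
    return PermutationResult(
        observed=observed,
        null_distribution=null,
        p_value=p,
        significant=bool(observed > np.quantile(null, 0.95)),
        n_divisions=n_divisions,
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# full-sample model and external application

def fit_full_model(
    table: pd.DataFrame,
    feature_cols: list[str],
    score_col: str = "score",
    confound_cols: list[str] | None = None,
    threshold: float = 0.05,
    signed: bool = True,
) -> PredictionModel:
    """Select features on the whole sample and freeze everything needed
    to apply the model elsewhere (masks, confound betas, z-parameters)."""
    X = table[feature_cols].to_numpy(float)
    y = table[score_col].to_numpy(float)
    C = table[confound_cols].to_numpy(float) if confound_cols else None
    D = _design(C, len(y))
    bX = _fit_residualizer(X, D)
    by = _fit_residualizer(y[:, None], D)[:, 0]
    rX = X - D @ bX
    ry = y - D @ by
    mu, sd = rX.mean(axis=0), rX.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    pos, neg = select_features((rX - mu) / sd_safe, (ry - ry.mean()) / ry.std(), threshold)
    return PredictionModel(
        feature_names=list(feature_cols),
        pos_mask=pos,
        neg_mask=neg,
        confound_beta=bX,
        score_beta=by,
        feat_mean=mu,
        feat_sd=sd_safe,
        score_mean=float(ry.mean()),
        score_sd=float(ry.std()),
        threshold=threshold,
        signed=signed,
    )


def apply_model(model: PredictionModel, Xz: np.ndarray) -> np.ndarray:
    """Predictions from already-normalized features under frozen masks."""
    return cpm_score(Xz, model.pos_mask, model.neg_mask, model.beta0, model.beta1, model.signed)


def predict_external(
    model: PredictionModel,
    table: pd.DataFrame,
    feature_cols: list[str] | None = None,
    score_col: str = "score",
    confound_cols: list[str] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[np.ndarray, float, float]:
    """Apply a frozen model to an independent cohort.

    External features and scores are confound-residualized *within* the
    external sample (its own covariate structure, e.g. including sex), then
    features are z-scaled with the frozen training parameters and passed
    through the frozen masks.  Returns ``(yhat, r, p)`` with p from
    permuting the external scores under the same frozen model.
    """
    feature_cols = feature_cols or model.feature_names
    if list(feature_cols) != list(model.feature_names):
        raise InvalidParameterError("feature set does not match the frozen model")
    missing = [c for c in feature_cols if c not in table.columns]
    if missing:
        raise InvalidParameterError(f"external table lacks features: {missing[:5]}")
    X = table[feature_cols].to_numpy(float)
    y = table[score_col].to_numpy(float)
    C = table[confound_cols].to_numpy(float) if confound_cols else None
    D = _design(C, len(y))
    rX = X - D @ _fit_residualizer(X, D)
    ry = y - D @ _fit_residualizer(y[:, None], D)[:, 0]
    Xz = (rX - model.feat_mean) / model.feat_sd
    yz = (ry - ry.mean()) / ry.std() if ry.std() > 0 else ry
    yhat = apply_model(model, Xz)
    r = _safe_pearson(yhat, yz)
    rng = np.random.default_rng(seed)
    null = np.array([_safe_pearson(yhat, rng.permutation(yz)) for _ in range(n_perm)])
    p = float((1 + np.sum(null >= r)) / (1 + n_perm))
    return yhat, r, p
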