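"""Shannon, Fuzzy, and multiscale (sample) entropy of EEG signals.

All three families quantify the unpredictability of a voltage time series:

* Shannon entropy of the amplitude distribution,
  ``H = -sum_i P_i log P_i`` over a fixed-width histogram;
* Fuzzy entropy, ``-ln(phi(m+1)/phi(m))`` where ``phi(l)`` is the average
  exponential similarity ``exp(-Delta^n / r)`` between baseline-removed
  length-``l`` template vectors (Chebyshev distance ``Delta``);
* sample entropy, the same scaffold with raw (non-baseline-removed)
  templates and a hard similarity threshold ``Delta <= r`` with
  ``r = 0.2 x SD``; evaluated on coarse-grained series for scales
  tau = 1..20 it yields the multiscale entropy (MSE) profile.

Template vectors are taken with delay ``d`` and BOTH template lengths use
the same ``N - m*d`` vectors, so phi(m) and phi(m+1) average over identical
index sets:

    phi(l) = 1/((N-md)(N-md-1)) * sum_{i} sum_{j != i} theta_ij(l)

Standard deviations are population SDs (ddof=0) throughout.

Everything is computed per channel and on the global field power (GFP),
the per-sample SD of the average-referenced signal across electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .preprocess import EpochedRecording, InvalidParameterError, Recording

#: Sentinel for entropies that are undefined (no template matches).
UNDEFINED = float("nan")


@dataclass(frozen=True)
class EntropyParams:
    """Parameters shared by the entropy family.

    ``m`` is the template (embedding) length, ``r_fuzzy`` the absolute fuzzy
    tolerance applied to unit-variance signals, ``r_factor`` the sample-
    entropy tolerance as a multiple of the signal SD, ``fuzzy_exponent``
    the fuzziness power ``n``, and ``delay`` the embedding delay ``d``.
    ``r_mode`` selects whether the sample-entropy tolerance is recomputed
    from each coarse-grained series (``"per_scale"``) or fixed from the
    scale-1 signal (``"global"``).
    """

    m: int = 2
    r_fuzzy: float = 0.2
    r_factor: float = 0.2
    fuzzy_exponent: float = 1.0
    delay: int = 1
    scales: tuple[int, ...] = tuple(range(1, 21))
    n_bins: int = 100
    log_base: float = 2.0
    r_mode: str = "per_scale"

    def __post_init__(self) -> None:
        if self.m < 1 or self.delay < 1:
            raise InvalidParameterError("m and delay must be >= 1")
        if self.r_fuzzy <= 0 or self.r_factor <= 0:
            raise InvalidParameterError("tolerances must be positive")
        if self.scales[0] != 1 or any(np.diff(self.scales) != 1):
            raise InvalidParameterError("scales must be consecutive starting at 1")
        if self.r_mode not in ("per_scale", "global"):
            raise InvalidParameterError(f"unknown r_mode {self.r_mode!r}")


@dataclass
class GFPSeries:
    """Global field power with its strict local maxima."""

    values: np.ndarray
    peak_indices: np.ndarray
    fs: float


@dataclass
class EntropyProfile:
    """Per-subject entropy summary: channels x measures (+ GFP variants)."""

    shannon: np.ndarray            # (n_channels,)
    fuzzy: np.ndarray              # (n_channels,)
    mse: np.ndarray                # (n_channels, n_scales)
    gfp_shannon: float
    gfp_fuzzy: float
    gfp_mse: np.ndarray            # (n_scales,)
    params: EntropyParams
    gfp_series: GFPSeries = field(repr=False)


# ---------------------------------------------------------------------------
# GFP

def gfp(rec: Recording) -> GFPSeries:
    """Per-sample population SD across channels, with strict local maxima."""
    if rec.data.shape[0] < 2:
        raise InvalidParameterError("GFP needs at least 2 channels")
    values = rec.data.std(axis=0)
    interior = values[1:-1]
    peaks = np.flatnonzero((interior > values[:-2]) & (interior > values[2:])) + 1
    return GFPSeries(values=values, peak_indices=peaks, fs=rec.fs)


# ---------------------------------------------------------------------------
# Shannon entropy

def shannon_entropy(x: np.ndarray, n_bins: int = 100, log_base: float = 2.0) -> float:
    """Histogram-based Shannon entropy over equal-width amplitude bins."""
    x = np.asarray(x, dtype=float)
    if x.size < n_bins:
        raise InvalidParameterError(f"need >= {n_bins} samples, got {x.size}")
    if x.min() == x.max():
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p)).sum() / np.log(log_base))


# ---------------------------------------------------------------------------
# sample / fuzzy entropy kernels

@njit(cache=True, fastmath=True)
def _sample_pair_counts(x: np.ndarray, m: int, d: int, r: float) -> tuple[int, int]:
    """Unordered pairs with Chebyshev distance <= r at lengths m and m+1."""
    n_vec = x.shape[0] - m * d
    c_m = 0
    c_m1 = 0
    for i in range(n_vec):
        for j in range(i + 1, n_vec):
            dmax = 0.0
            for k in range(m):
                diff = abs(x[i + k * d] - x[j + k * d])
                if diff > dmax:
                    dmax = diff
            if dmax <= r:
                c_m += 1
                diff = abs(x[i + m * d] - x[j + m * d])
                if diff <= r:  # Delta_{m+1} = max(dmax, diff) <= r
                    c_m1 += 1
    return c_m, c_m1


@njit(cache=True, fastmath=True)
def _fuzzy_pair_sums(
    x: np.ndarray, m: int, d: int, r: float, nexp: float
) -> tuple[float, float]:
    """Summed exponential similarities of baseline-removed template pairs."""
    n_vec = x.shape[0] - m * d
    mean_m = np.empty(n_vec)
    mean_m1 = np.empty(n_vec)
    for i in range(n_vec):
        s = 0.0
        for k in range(m):
            s += x[i + k * d]
        mean_m[i] = s / m
        mean_m1[i] = (s + x[i + m * d]) / (m + 1)
    s_m = 0.0
    s_m1 = 0.0
    for i in range(n_vec):
        for j in range(i + 1, n_vec):
            dm = 0.0
            dm1 = 0.0
            for k in range(m):
                diff = abs((x[i + k * d] - mean_m[i]) - (x[j + k * d] - mean_m[j]))
                if diff > dm:
                    dm = diff
                diff1 = abs((x[i + k * d] - mean_m1[i]) - (x[j + k * d] - mean_m1[j]))
                if diff1 > dm1:
                    dm1 = diff1
            diff1 = abs((x[i + m * d] - mean_m1[i]) - (x[j + m * d] - mean_m1[j]))
            if diff1 > dm1:
                dm1 = diff1
            s_m += np.exp(-(dm ** nexp) / r)
            s_m1 += np.exp(-(dm1 ** nexp) / r)
    return s_m, s_m1


def _check_length(x: np.ndarray, m: int, d: int) -> None:
    if x.size <= m * d + 1:
        raise InvalidParameterError(
            f"signal length {x.size} too short for m={m}, d={d}"
        )


def fuzzy_entropy(
    x: np.ndarray,
    m: int = 2,
    r: float = 0.2,
    n: float = 1.0,
    d: int = 1,
) -> float:
    """Fuzzy entropy ``-ln(phi(m+1)/phi(m))`` with exponential similarity.

    ``r`` is an absolute tolerance; callers computing channel entropies
    normalize the signal to unit variance first (see ``entropy_profile``).
    Baseline removal makes the value invariant to additive offsets.
    """
    x = np.ascontiguousarray(x, dtype=float)
    _check_length(x, m, d)
    s_m, s_m1 = _fuzzy_pair_sums(x, m, d, r, n)
    n_vec = x.size - m * d
    denom = n_vec * (n_vec - 1) / 2
    return float(-np.log((s_m1 / denom) / (s_m / denom)))


def sample_entropy(
    x: np.ndarray,
    m: int = 2,
    r: float | None = None,
    d: int = 1,
) -> float:
    """Sample entropy with hard threshold ``r`` (default 0.2 x SD of ``x``).

    Returns NaN when no template pair matches at length m+1 (the
    conditional probability is undefined); downstream code treats NaN as
    an explicit missing value.
    """
    x = np.ascontiguousarray(x, dtype=float)
    _check_length(x, m, d)
    if r is None:
        sd = x.std()
        if sd == 0:  # constant signal: phi(m) = phi(m+1) = 1
            return 0.0
        r = 0.2 * sd
    c_m, c_m1 = _sample_pair_counts(x, m, d, r)
    if c_m == 0 or c_m1 == 0:
        return UNDEFINED
    return float(-np.log(c_m1 / c_m))


# ---------------------------------------------------------------------------
# multiscale entropy

def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping block means of length ``tau``; remainder discarded."""
    if tau < 1:
        raise InvalidParameterError("tau must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.size < tau:
        raise InvalidParameterError(f"signal length {x.size} < tau={tau}")
    n_out = x.size // tau
    return x[: n_out * tau].reshape(n_out, tau).mean(axis=1)


def multiscale_entropy(x: np.ndarray, params: EntropyParams = EntropyParams()) -> np.ndarray:
    """Sample entropy of coarse-grained series for each scale in ``params``."""
    x = np.asarray(x, dtype=float)
    max_tau = params.scales[-1]
    if x.size // max_tau < 10 * (params.m + 1):
        raise InvalidParameterError(
            f"length {x.size} too short for scale {max_tau} "
            f"(need >= {10 * (params.m + 1) * max_tau})"
        )
    r_global = params.r_factor * x.std()
    out = np.empty(len(params.scales))
    for i, tau in enumerate(params.scales):
        cg = coarse_grain(x, tau)
        r = params.r_factor * cg.std() if params.r_mode == "per_scale" else r_global
        if r == 0:
            out[i] = 0.0
            continue
        out[i] = sample_entropy(cg, m=params.m, r=r, d=params.delay)
    return out


# ---------------------------------------------------------------------------
# per-subject profile

def entropy_profile(ep: EpochedRecording, params: EntropyParams = EntropyParams()) -> EntropyProfile:
    """All entropy measures of one subject, per channel and on the GFP.

    Retained epochs are concatenated per channel so that coarse scales see
    a series long enough for stable estimates; fuzzy entropy is computed on
    the unit-variance (z-scored) signal with the absolute tolerance
    ``r_fuzzy``, Shannon and sample entropy on the raw signal.
    """
    if ep.n_epochs < 1:
        raise InvalidParameterError("no retained epochs")
    data = ep.concatenated()
    n_ch = data.shape[0]
    n_scales = len(params.scales)

    shannon = np.empty(n_ch)
    fuzzy = np.empty(n_ch)
    mse = np.empty((n_ch, n_scales))
    for c in range(n_ch):
        x = data[c]
        shannon[c] = shannon_entropy(x, params.n_bins, params.log_base)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else x - x.mean()
        fuzzy[c] = fuzzy_entropy(
            z, m=params.m, r=params.r_fuzzy, n=params.fuzzy_exponent, d=params.delay
        )
        mse[c] = multiscale_entropy(x, params)

    series = gfp(Recording(data=data, fs=ep.fs, layout=ep.layout, reference="average"))
    g = series.values
    gsd = g.std()
    gz = (g - g.mean()) / gsd if gsd > 0 else g - g.mean()
    return EntropyProfile(
        shannon=shannon,
        fuzzy=fuzzy,
        mse=mse,
        gfp_shannon=shannon_entropy(g, params.n_bins, params.log_base),
        gfp_fuzzy=fuzzy_entropy(
            gz, m=params.m, r=params.r_fuzzy, n=params.fuzzy_exponent, d=params.delay
        ),
        gfp_mse=multiscale_entropy(g, params),
        params=params,
        gfp_series=series,
    )
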