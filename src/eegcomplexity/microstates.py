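"""EEG microstate segmentation, backfitting, and sequence statistics.

Microstates are quasi-stable scalp topographies dominating the signal for
tens of milliseconds.  The segmentation is two-level: scalp maps at GFP
peaks are clustered per subject with a polarity-invariant (modified)
k-means into k=5 individual template maps; the pooled individual maps are
then clustered again into k group maps.  Group maps are backfitted to each
subject's continuous signal (each sample labeled by the map with the
highest absolute spatial correlation), and six statistics are derived from
the label sequence: coverage, lifespan, frequency, lifespan at GFP peaks,
number of GFP peaks, and (peak-)transition probability matrices.

Polarity is ignored throughout (assignment by squared/absolute spatial
correlation), the established convention for spontaneous EEG topographies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .entropy import gfp
from .preprocess import InvalidParameterError, Recording


@dataclass
class MicrostateMaps:
    """Template maps with their fit quality.

    ``maps`` is ``(k, n_channels)``; each map is zero-mean across channels
    and unit norm.  ``gev`` is the GFP-squared-weighted fraction of
    variance the maps explain in the data they were fitted to.
    """

    maps: np.ndarray = field(repr=False)
    gev: float
    level: str = "individual"  # "individual" | "group"

    @property
    def k(self) -> int:
        return self.maps.shape[0]


@dataclass
class MicrostateSequence:
    """Per-sample microstate labels plus the GFP-peak-restricted labels."""

    labels: np.ndarray
    peak_labels: np.ndarray
    peak_indices: np.ndarray
    fs: float
    k: int


@dataclass
class MicrostateMeasures:
    """The six sequence statistics of one subject.

    ``lifespan`` entries are NaN for states that never occur; their
    transition rows are uniform and coverage is 0.
    """

    coverage: np.ndarray
    lifespan: np.ndarray            # ms
    frequency: np.ndarray           # run counts
    lifespan_at_peaks: np.ndarray   # mean consecutive-peak run length
    n_gfp_peaks: int
    transitions: np.ndarray         # (k, k) row-stochastic
    transitions_at_peaks: np.ndarray
    n_samples: int
    fs: float


# ---------------------------------------------------------------------------
# helpers

def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Zero-mean across channels, unit norm, per map."""
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return maps / norms


def _spatial_corr(samples: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels, (n_samples, k).

    Rows of both inputs are centered; zero-variance samples yield 0.
    """
    s = samples - samples.mean(axis=1, keepdims=True)
    sn = np.linalg.norm(s, axis=1, keepdims=True)
    zero = sn[:, 0] == 0
    sn[zero] = 1.0
    m = _normalize_maps(maps)
    corr = (s / sn) @ m.T
    corr[zero] = 0.0
    return corr


def _gev(samples: np.ndarray, maps: np.ndarray, labels: np.ndarray) -> float:
    """GFP^2-weighted squared correlation of each sample with its map."""
    gfp2 = samples.std(axis=1) ** 2
    total = gfp2.sum()
    if total == 0:
        return 0.0
    corr = _spatial_corr(samples, maps)
    sel = corr[np.arange(len(labels)), labels]
    return float((gfp2 * sel**2).sum() / total)


# ---------------------------------------------------------------------------
# modified k-means

def modified_kmeans(
    maps_at_peaks: np.ndarray,
    k: int = 5,
    n_init: int = 1000,
    max_iter: int = 500,
    seed: int | None = None,
) -> MicrostateMaps:
    """Polarity-invariant k-means over scalp maps, best of ``n_init`` restarts.

    Assignment maximizes squared spatial correlation; each template is
    updated to the first principal component of its assigned maps.  The
    restart with the highest GEV wins.  With k=1 the single template is the
    dominant eigenvector of the whole sample.
    """
    samples = np.asarray(maps_at_peaks, dtype=float)
    if samples.ndim != 2:
        raise InvalidParameterError("maps_at_peaks must be (n_samples, n_channels)")
    n, n_ch = samples.shape
    if k > n_ch:
        raise InvalidParameterError(f"k={k} exceeds channel count {n_ch}")
    if k < 1 or n < k:
        raise InvalidParameterError(f"need >= k={k} input maps, got {n}")

    rng = np.random.default_rng(seed)
    centered = samples - samples.mean(axis=1, keepdims=True)
    gfp2 = samples.std(axis=1) ** 2
    w_total = gfp2.sum()

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, n_init)):
        init = rng.choice(n, size=k, replace=False)
        templates = _normalize_maps(samples[init])
        labels = np.full(n, -1)
        for _sweep in range(max_iter):
            corr = _spatial_corr(centered, templates)
            new_labels = np.argmax(corr**2, axis=1)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                members = centered[labels == j]
                if len(members) == 0:
                    # re-seed an empty cluster with the worst-fit map
                    fit = np.max(corr**2, axis=1)
                    templates[j] = _normalize_maps(
                        centered[np.argmin(fit)][None, :]
                    )[0]
                    continue
                cov = members.T @ members
                vals, vecs = np.linalg.eigh(cov)
                templates[j] = _normalize_maps(vecs[:, -1][None, :])[0]
        sel = corr[np.arange(n), labels] ** 2
        gev = float((gfp2 * sel).sum() / w_total) if w_total > 0 else 0.0
        if best is None or gev > best[0]:
            best = (gev, templates.copy(), labels.copy())

    gev, templates, labels = best
    # deterministic ordering: descending share of assigned GFP^2 weight
    shares = np.array([gfp2[labels == j].sum() for j in range(k)])
    order = np.argsort(-shares, kind="stable")
    return MicrostateMaps(maps=templates[order], gev=gev, level="individual")


def peak_maps(rec: Recording) -> np.ndarray:
    """Scalp maps at GFP peaks, ``(n_peaks, n_channels)``."""
    series = gfp(rec)
    return rec.data[:, series.peak_indices].T


def fit_individual_then_group(
    subject_peak_maps: list[np.ndarray],
    k: int = 5,
    n_init: int = 1000,
    seed: int | None = None,
) -> tuple[list[MicrostateMaps], MicrostateMaps]:
    """Two-level clustering: per-subject maps, then a group-level solution.

    Stage 1 clusters each subject's GFP-peak maps; stage 2 clusters the
    pooled ``n_subjects * k`` individual template maps into k group maps.
    """
    if len(subject_peak_maps) < 2:
        raise InvalidParameterError("need >= 2 subjects")
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(len(subject_peak_maps) + 1)
    individual = [
        modified_kmeans(pm, k=k, n_init=n_init, seed=sseed.generate_state(1)[0])
        for pm, sseed in zip(subject_peak_maps, subject_seeds[:-1])
    ]
    pooled = np.vstack([m.maps for m in individual])
    group = modified_kmeans(
        pooled, k=k, n_init=n_init, seed=subject_seeds[-1].generate_state(1)[0]
    )
    group.level = "group"
    return individual, group


# ---------------------------------------------------------------------------
# backfitting and measures

def backfit(rec: Recording, group: MicrostateMaps) -> MicrostateSequence:
    """Label every sample with its best-matching map (polarity-invariant).

    Zero-variance samples inherit the previous label (state 0 at t=0).
    Ties break toward the lowest map index via argmax.
    """
    if rec.data.shape[0] != group.maps.shape[1]:
        raise InvalidParameterError("channel count mismatch between data and maps")
    samples = rec.data.T
    corr = _spatial_corr(samples, group.maps)
    labels = np.argmax(np.abs(corr), axis=1)
    zero_var = samples.std(axis=1) == 0
    if zero_var.any():
        labels = labels.copy()
        for t in np.flatnonzero(zero_var):
            labels[t] = labels[t - 1] if t > 0 else 0
    series = gfp(rec)
    return MicrostateSequence(
        labels=labels,
        peak_labels=labels[series.peak_indices],
        peak_indices=series.peak_indices,
        fs=rec.fs,
        k=group.k,
    )


def _run_lengths(labels: np.ndarray, k: int) -> list[list[int]]:
    """Lengths of maximal constant runs, grouped by state."""
    runs: list[list[int]] = [[] for _ in range(k)]
    if len(labels) == 0:
        return runs
    boundaries = np.flatnonzero(np.diff(labels) != 0)
    starts = np.r_[0, boundaries + 1]
    ends = np.r_[boundaries + 1, len(labels)]
    for s, e in zip(starts, ends):
        runs[labels[s]].append(e - s)
    return runs


def _transition_matrix(labels: np.ndarray, k: int) -> np.ndarray:
    """Row-stochastic transition counts (self-transitions included).

    States with no outgoing transition get a uniform row.
    """
    counts = np.zeros((k, k))
    if len(labels) > 1:
        np.add.at(counts, (labels[:-1], labels[1:]), 1)
    row_sums = counts.sum(axis=1, keepdims=True)
    out = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), 1.0 / k)
    return out


def microstate_measures(seq: MicrostateSequence) -> MicrostateMeasures:
    """Coverage, lifespan, frequency, peak lifespan, peak count, transitions."""
    if len(seq.labels) == 0:
        raise InvalidParameterError("empty label sequence")
    k = seq.k
    n = len(seq.labels)
    coverage = np.bincount(seq.labels, minlength=k) / n

    runs = _run_lengths(seq.labels, k)
    lifespan = np.array(
        [np.mean(r) * 1000.0 / seq.fs if r else np.nan for r in runs]
    )
    frequency = np.array([len(r) for r in runs], dtype=float)

    peak_runs = _run_lengths(seq.peak_labels, k)
    lifespan_at_peaks = np.array([np.mean(r) if r else np.nan for r in peak_runs])

    return MicrostateMeasures(
        coverage=coverage,
        lifespan=lifespan,
        frequency=frequency,
        lifespan_at_peaks=lifespan_at_peaks,
        n_gfp_peaks=len(seq.peak_labels),
        transitions=_transition_matrix(seq.labels, k),
        transitions_at_peaks=_transition_matrix(seq.peak_labels, k),
        n_samples=n,
        fs=seq.fs,
    )


# ---------------------------------------------------------------------------
# post hoc variability metrics

def map_similarity(maps: MicrostateMaps | np.ndarray) -> float:
    """Mean absolute pairwise Pearson correlation between a subject's maps."""
    m = maps.maps if isinstance(maps, MicrostateMaps) else np.asarray(maps, float)
    k = m.shape[0]
    if k < 2:
        raise InvalidParameterError("need k >= 2 maps")
    mn = _normalize_maps(m)
    corr = mn @ mn.T
    iu = np.triu_indices(k, 1)
    return float(np.abs(corr[iu]).mean())


def explained_variance(rec: Recording, maps: MicrostateMaps) -> float:
    """GEV over ALL samples under the backfit labeling (not just peaks)."""
    seq = backfit(rec, maps)
    return _gev(rec.data.T, maps.maps, seq.labels)
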