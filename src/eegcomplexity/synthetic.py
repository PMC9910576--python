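"""Synthetic resting-state EEG cohorts with known ground truth.

Each subject's recording is built from three ingredients:

* a Markov chain over k quasi-stable scalp topographies (microstates) with
  geometric dwell times (mean ~60 ms), emulating spontaneous microstate
  dynamics;
* an alpha-band-dominant activation waveform (unit-RMS mixture of 8-12 Hz
  band-limited noise and a 1/f broadband component) multiplying the active
  template, reproducing the eyes-closed alpha-dominant spectrum;
* 1/f background noise whose spectral exponent varies across subjects,
  composed of a spatially smooth component confined to the spatial modes
  complementary to the template span (background activity outside the
  microstate subspace, mimicking volume-conducted inter-channel
  correlation) plus a smaller channel-independent sensor-noise part.

Cognitive ability scores are planted through the *generative* parameters
(spectral exponent, dwell time, alpha power): score = sum_i rho_i * z_i +
sqrt(1 - sum rho_i^2) * eps with z_i the population-standardized parameter,
so the population correlation between each named parameter and the score
equals its target exactly.  Feature-score correlations downstream then
arise mechanistically rather than by construction.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .montage import ChannelLayout, default_layout
from .preprocess import InvalidParameterError, Recording

#: Generative parameters that can carry a planted score effect, with their
#: population mean and SD (used for exact standardization when planting).
PARAM_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "spectral_exponent": (1.5, 0.2),   # 1/f slope of the channel noise
    "dwell_mean": (60.0, 8.0),         # mean microstate dwell time, ms
    "alpha_power": (0.7, 0.08),        # relative 8-12 Hz power of activation
}

#: RAPM-like score scale used for cohort tables (sum-score convention).
SCORE_MEAN, SCORE_SD = 26.9, 4.48


@dataclass(frozen=True)
class SimulationParams:
    """Cohort-level simulation settings.

    ``effect_spec`` maps generative-parameter names to target population
    correlations with the score; targets must satisfy sum(rho^2) < 1.
    ``noise_scale`` is the per-channel noise SD as a multiple of the
    per-channel signal RMS (``amplitude``).
    """

    n_subjects: int = 30
    fs: float = 250.0
    duration: float = 280.0
    k_states: int = 5
    dwell_mean: float = 60.0                  # ms (population mean)
    transition_matrix: np.ndarray | None = None
    noise_scale: float = 0.5
    amplitude: float = 5e-6                   # average per-channel signal RMS, volts
    effect_spec: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.fs <= 0 or self.duration <= 0:
            raise InvalidParameterError("invalid cohort dimensions")
        if self.dwell_mean <= 0:
            raise InvalidParameterError("dwell_mean must be > 0")
        if self.k_states < 2:
            raise InvalidParameterError("need k_states >= 2")
        if self.transition_matrix is not None:
            tm = np.asarray(self.transition_matrix, float)
            if tm.shape != (self.k_states, self.k_states):
                raise InvalidParameterError("transition_matrix must be k x k")
            if np.any(np.abs(tm.sum(axis=1) - 1) > 1e-12) or np.any(tm < 0):
                raise InvalidParameterError("transition_matrix rows must sum to 1")
        unknown = set(self.effect_spec) - set(PARAM_DISTRIBUTIONS)
        if unknown:
            raise InvalidParameterError(f"unknown generative parameters: {unknown}")
        rhos = np.array(list(self.effect_spec.values()), float)
        if np.any(np.abs(rhos) >= 1) or rhos @ rhos >= 1:
            raise InvalidParameterError("unattainable joint correlation targets")


@dataclass
class GroundTruth:
    """What was actually planted in one subject's recording."""

    state_sequence: np.ndarray
    templates: np.ndarray = field(repr=False)
    subject_params: dict[str, float] = field(default_factory=dict)


@dataclass
class Cohort:
    """Simulated recordings plus the subject table and all ground truth."""

    recordings: list[Recording]
    table: pd.DataFrame
    ground_truths: list[GroundTruth]
    templates: np.ndarray = field(repr=False)
    layout: ChannelLayout = None


# ---------------------------------------------------------------------------
# templates

def make_templates(
    layout: ChannelLayout,
    k: int,
    seed: int | None = None,
    max_pairwise_r: float = 0.7,
) -> np.ndarray:
    """k smooth, mutually distinguishable scalp maps, zero-mean and unit-norm.

    Maps are random low-order spherical-harmonic combinations of electrode
    position plus a small seeded perturbation; candidates too similar to an
    accepted map (|spatial r| >= ``max_pairwise_r``) are rejected, which
    guarantees distinguishability while keeping realistic spatial
    autocorrelation.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if k > len(layout):
        raise InvalidParameterError(f"k={k} exceeds channel count {len(layout)}")
    rng = np.random.default_rng(seed)
    x, y, z = layout.positions.T
    basis = np.column_stack([x, y, z, x * y, x * z, y * z, x * x - y * y, 3 * z * z - 1])
    maps: list[np.ndarray] = []
    attempts = 0
    while len(maps) < k:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("template rejection sampling did not converge")
        v = basis @ rng.standard_normal(basis.shape[1])
        v = v + 0.15 * rng.standard_normal(len(layout))
        v -= v.mean()
        v /= np.linalg.norm(v)
        if all(abs(v @ m) < max_pairwise_r for m in maps):
            maps.append(v)
    return np.array(maps)


# ---------------------------------------------------------------------------
# single subject

def _markov_sequence(
    n: int, k: int, p_stay: float, rng: np.random.Generator,
    transition_matrix: np.ndarray | None = None,
) -> np.ndarray:
    if transition_matrix is None:
        off = (1.0 - p_stay) / (k - 1)
        tm = np.full((k, k), off)
        np.fill_diagonal(tm, p_stay)
    else:
        tm = transition_matrix
    cum = np.cumsum(tm, axis=1)
    u = rng.random(n)
    seq = np.empty(n, dtype=np.int64)
    seq[0] = rng.integers(k)
    for t in range(1, n):
        seq[t] = np.searchsorted(cum[seq[t - 1]], u[t], side="right")
    return np.minimum(seq, k - 1)


def _one_over_f_noise(
    n: int, fs: float, beta: float, rng: np.random.Generator,
    band: tuple[float, float] = (1.0, 40.0),
) -> np.ndarray:
    """Unit-RMS Gaussian noise with PSD proportional to 1/f^beta inside `band`."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    inside = (freqs >= band[0]) & (freqs <= band[1])
    amp[inside] = freqs[inside] ** (-beta / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _background_noise(
    templates: np.ndarray,
    layout: ChannelLayout,
    n: int,
    fs: float,
    beta: float,
    rng: np.random.Generator,
    sensor_mix: float = 0.4,
    smooth_scale: float = 0.7,
) -> np.ndarray:
    """Unit-SD-per-channel 1/f background with realistic spatial structure.

    The dominant component is spatially smooth (Gaussian kernel of width
    ``smooth_scale`` on the unit-sphere chord distance) but projected onto
    the orthogonal complement of the template span -- background activity
    in the spatial modes not occupied by the microstates.  A
    channel-independent component (weight ``sensor_mix``) models sensor
    noise.  The smooth part gives neighboring channels the high mutual
    correlations real volume-conducted EEG shows.
    """
    n_ch = len(layout)
    pos = layout.positions
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    G = np.exp(-(dist**2) / (2.0 * smooth_scale**2))
    Q, _ = np.linalg.qr(templates.T)
    proj = np.eye(n_ch) - Q @ Q.T

    pink = np.vstack([_one_over_f_noise(n, fs, beta, rng) for _ in range(n_ch)])
    smooth = proj @ (G @ pink)
    smooth /= smooth.std(axis=1, keepdims=True)
    sensor = np.vstack([_one_over_f_noise(n, fs, beta, rng) for _ in range(n_ch)])
    noise = np.sqrt(1.0 - sensor_mix**2) * smooth + sensor_mix * sensor
    return noise / noise.std(axis=1, keepdims=True)


def _alpha_activation(
    n: int, fs: float, alpha_power: float, beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS activation: alpha-band noise plus a broadband 1/f floor."""
    b, a = sps.butter(4, [8.0 / (fs / 2), 12.0 / (fs / 2)], btype="bandpass")
    alpha = sps.filtfilt(b, a, rng.standard_normal(n))
    alpha /= alpha.std()
    broad = _one_over_f_noise(n, fs, beta, rng)
    act = np.sqrt(alpha_power) * alpha + np.sqrt(1.0 - alpha_power) * broad
    return act / act.std()


def draw_subject_params(
    params: SimulationParams, subject_index: int, seed: int | None = None
) -> dict[str, float]:
    """Deterministic per-subject generative parameter draw.

    ``seed`` overrides the cohort-derived stream entirely, so two calls
    with the same explicit seed draw identical parameters regardless of
    the subject index.
    """
    if seed is None:
        ss = np.random.SeedSequence([int(params.seed), 1000 + int(subject_index)])
    else:
        ss = np.random.SeedSequence([int(seed), 1000])
    rng = np.random.default_rng(ss)
    out = {}
    for name, (mu, sd) in PARAM_DISTRIBUTIONS.items():
        val = float(rng.normal(mu, sd))
        # keep physically sensible ranges without distorting the distribution
        if name == "alpha_power":
            val = float(np.clip(val, 0.05, 0.95))
        elif name == "dwell_mean":
            val = max(val, 10.0)
        elif name == "spectral_exponent":
            val = max(val, 0.1)
        out[name] = val
    return out


def simulate_subject(
    params: SimulationParams,
    templates: np.ndarray,
    subject_index: int,
    layout: ChannelLayout | None = None,
    seed: int | None = None,
) -> tuple[Recording, GroundTruth]:
    """One subject's recording: Markov-switched templates + 1/f channel noise.

    ``seed`` overrides the deterministic per-subject seed derived from
    ``params.seed`` and ``subject_index``.
    """
    layout = layout if layout is not None else default_layout()
    k, n_ch = templates.shape
    if n_ch != len(layout):
        raise InvalidParameterError("templates do not match layout")
    n = int(round(params.duration * params.fs))
    sp = draw_subject_params(params, subject_index, seed=seed)
    if seed is None:
        ss = np.random.SeedSequence([int(params.seed), 2000 + int(subject_index)])
    else:
        ss = np.random.SeedSequence([int(seed), 2000])
    rng = np.random.default_rng(ss)

    dwell_samples = sp["dwell_mean"] * params.fs / 1000.0
    p_stay = max(0.0, 1.0 - 1.0 / dwell_samples)
    seq = _markov_sequence(n, k, p_stay, rng, params.transition_matrix)
    act = _alpha_activation(n, params.fs, sp["alpha_power"], sp["spectral_exponent"], rng)

    # scale so the RMS over channels and time of the template signal equals
    # `amplitude` (templates are unit-norm, mean squared channel weight 1/n_ch)
    signal = templates[seq].T * act * (params.amplitude * np.sqrt(n_ch))
    noise = _background_noise(
        templates, layout, n, params.fs, sp["spectral_exponent"], rng
    ) * (params.noise_scale * params.amplitude)
    rec = Recording(data=signal + noise, fs=params.fs, layout=layout, reference="average")
    gt = GroundTruth(state_sequence=seq, templates=templates, subject_params=sp)
    return rec, gt


# ---------------------------------------------------------------------------
# cohort

def _planted_scores(
    subject_params: list[dict[str, float]],
    effect_spec: dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Standardized scores correlated with the named generative parameters."""
    n = len(subject_params)
    signal = np.zeros(n)
    rho_sq = 0.0
    for name, rho in effect_spec.items():
        mu, sd = PARAM_DISTRIBUTIONS[name]
        z = (np.array([sp[name] for sp in subject_params]) - mu) / sd
        signal += rho * z
        rho_sq += rho**2
    return signal + np.sqrt(1.0 - rho_sq) * rng.standard_normal(n)


def simulate_subject_table(params: SimulationParams) -> pd.DataFrame:
    """The cohort's subject table alone (no recordings simulated).

    Scores, covariates and generative parameters are drawn exactly as in
    ``simulate_cohort``; useful for checking the effect-planting
    calibration at sample sizes where simulating recordings is wasteful.
    """
    sps_list = [
        draw_subject_params(params, i) for i in range(params.n_subjects)
    ]
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 3000]))
    score_z = _planted_scores(sps_list, params.effect_spec, rng)
    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(params.n_subjects)],
            "score": SCORE_MEAN + SCORE_SD * score_z,
            "age": rng.integers(18, 36, params.n_subjects),
            "sex": rng.integers(0, 2, params.n_subjects),
            "seed": params.seed,
        }
    )
    for name in PARAM_DISTRIBUTIONS:
        table[name] = [sp[name] for sp in sps_list]
    return table


def simulate_cohort(params: SimulationParams) -> Cohort:
    """Simulate all subjects plus the subject table (scores, age, sex)."""
    layout = default_layout()
    templates = make_templates(layout, params.k_states, seed=params.seed)
    recordings, gts = [], []
    for i in range(params.n_subjects):
        rec, gt = simulate_subject(params, templates, i, layout=layout)
        recordings.append(rec)
        gts.append(gt)
    return Cohort(
        recordings=recordings, table=simulate_subject_table(params),
        ground_truths=gts, templates=templates, layout=layout,
    )


def simulate_feature_cohort(
    n_subjects: int,
    effect_spec: dict[str, float] | None = None,
    n_candidates: int = 161,
    n_informative: int = 24,
    loading: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Candidate-feature table with the same effect-planting semantics.

    A fast stand-in for the full EEG pipeline when validating the
    prediction machinery statistically: informative features load (with
    ``+-loading``, alternating sign, mirroring the coexistence of
    positively and negatively score-related measures) on the same
    standardized latent generative parameters that drive the score;
    remaining candidates are pure noise.  The high default loading
    reflects how strongly redundant EEG complexity features track their
    generative parameters at ~260 s of data.  Columns: ``feat_000..`` +
    ``score`` + confounds (``age``, ``sex``, ``n_removed_epochs``).
    """
    effect_spec = effect_spec or {}
    rhos = np.array(list(effect_spec.values()), float)
    if np.any(np.abs(rhos) >= 1) or (rhos @ rhos if len(rhos) else 0) >= 1:
        raise InvalidParameterError("unattainable joint correlation targets")
    rng = np.random.default_rng(seed)
    n_latents = max(len(effect_spec), 1)
    latents = rng.standard_normal((n_latents, n_subjects))

    X = rng.standard_normal((n_candidates, n_subjects))
    if effect_spec:
        for f in range(min(n_informative, n_candidates)):
            lat = latents[f % n_latents]
            sign = 1.0 if f % 2 == 0 else -1.0
            X[f] = sign * loading * lat + np.sqrt(1 - loading**2) * rng.standard_normal(
                n_subjects
            )

    score = np.zeros(n_subjects)
    for i, rho in enumerate(rhos):
        score += rho * latents[i]
    score += np.sqrt(1.0 - (rhos @ rhos if len(rhos) else 0.0)) * rng.standard_normal(n_subjects)

    df = pd.DataFrame(X.T, columns=[f"feat_{i:03d}" for i in range(n_candidates)])
    df["score"] = SCORE_MEAN + SCORE_SD * score
    df["age"] = rng.integers(18, 36, n_subjects)
    df["sex"] = rng.integers(0, 2, n_subjects)
    df["n_removed_epochs"] = rng.poisson(3.0, n_subjects)
    return df


# ---------------------------------------------------------------------------
# BrainVision export

def write_brainvision(rec: Recording, basepath: str | Path) -> Path:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg, IEEE float32, uV).

    Returns the header path.  Readable by any BrainVision-aware tool.
    """
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    n_ch = rec.data.shape[0]
    sampling_interval_us = 1e6 / rec.fs
    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={sampling_interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, label in enumerate(rec.layout.labels, start=1):
        header.append(f"Ch{i}={label},,1,µV")
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    marker = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    vmrk.write_text("\n".join(marker) + "\n", encoding="utf-8")

    uv = (rec.data * 1e6).astype("<f4")  # volts -> microvolts, multiplexed
    uv.T.tofile(eeg)
    return vhdr


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write every recording as BrainVision plus ``subjects.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, rec in zip(cohort.table["subject_id"], cohort.recordings):
        write_brainvision(rec, outdir / sid)
    cohort.table.to_csv(outdir / "subjects.csv", index=False)
    return outdir
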