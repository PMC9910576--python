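import itertools

import numpy as np
import pytest

from eegcomplexity import (
    MicrostateMaps,
    Recording,
    average_reference,
    backfit,
    explained_variance,
    fit_individual_then_group,
    make_templates,
    map_similarity,
    microstate_measures,
    modified_kmeans,
    peak_maps,
    simulate_subject,
)
from eegcomplexity.microstates import MicrostateSequence, _normalize_maps


def _orthogonal_maps(k: int, n_ch: int = 28, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_ch, n_ch))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    return _normalize_maps(q.T[:k])


def _match(estimated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Best |r| of each true map among the estimated maps (greedy-free)."""
    corr = np.abs(_normalize_maps(estimated) @ _normalize_maps(truth).T)
    best = np.zeros(len(truth))
    cost = -corr
    from scipy.optimize import linear_sum_assignment

    ri, ci = linear_sum_assignment(cost)
    best[ci] = corr[ri, ci]
    return best


class TestModifiedKmeans:
    def test_noiseless_fixed_point_recovers_inputs(self):
        truth = _orthogonal_maps(4)
        samples = np.repeat(truth, 50, axis=0) * 2e-6
        fit = modified_kmeans(samples, k=4, n_init=20, seed=0)
        assert fit.gev == pytest.approx(1.0)
        assert (_match(fit.maps, truth) > 0.999).all()

    def test_polarity_invariance(self):
        truth = _orthogonal_maps(3, seed=1)
        samples = np.repeat(truth, 30, axis=0)
        flips = np.random.default_rng(0).choice([-1.0, 1.0], size=len(samples))
        a = modified_kmeans(samples, k=3, n_init=10, seed=5)
        b = modified_kmeans(samples * flips[:, None], k=3, n_init=10, seed=5)
        assert (np.abs(_normalize_maps(a.maps) @ _normalize_maps(b.maps).T).max(axis=1)
                > 0.999).all()

    def test_matches_exhaustive_labeling_oracle(self):
        """Best-of-all-labelings oracle on a tiny planted problem."""
        rng = np.random.default_rng(3)
        truth = _orthogonal_maps(3, seed=3)
        labels_true = np.repeat(np.arange(3), 3)[:8]
        samples = truth[labels_true] + 0.05 * rng.standard_normal((8, 28))
        samples = _normalize_maps(samples)

        def gev_of(labels):
            g = 0.0
            w = samples.std(axis=1) ** 2
            for j in set(labels):
                members = samples[np.array(labels) == j]
                cov = members.T @ members
                _, vecs = np.linalg.eigh(cov)
                t = vecs[:, -1]
                t = t - t.mean()
                t /= np.linalg.norm(t)
                sel = np.array(labels) == j
                c = (samples[sel] - samples[sel].mean(1, keepdims=True)) @ t
                c /= np.linalg.norm(samples[sel] - samples[sel].mean(1, keepdims=True), axis=1)
                g += (w[sel] * c**2).sum()
            return g / w.sum()

        best_labels, best_gev = None, -1.0
        for labels in itertools.product(range(3), repeat=8):
            if len(set(labels)) < 3:
                continue
            g = gev_of(labels)
            if g > best_gev:
                best_gev, best_labels = g, labels
        fit = modified_kmeans(samples, k=3, n_init=50, seed=0)
        assert fit.gev == pytest.approx(best_gev, abs=1e-9)

    def test_k_exceeding_channels_rejected(self):
        with pytest.raises(Exception):
            modified_kmeans(np.random.default_rng(0).standard_normal((40, 28)), k=29)

    def test_seeded_determinism(self):
        samples = np.random.default_rng(0).standard_normal((60, 28))
        a = modified_kmeans(samples, k=4, n_init=5, seed=9)
        b = modified_kmeans(samples, k=4, n_init=5, seed=9)
        np.testing.assert_array_equal(a.maps, b.maps)
        assert a.gev == b.gev


class TestTwoLevelFit:
    def test_group_maps_recover_shared_templates(self, layout, templates, short_params):
        peak_sets = []
        for i in range(4):
            rec, _ = simulate_subject(short_params, templates, i, layout=layout)
            peak_sets.append(peak_maps(average_reference(rec)))
        individual, group = fit_individual_then_group(peak_sets, k=5, n_init=20, seed=0)
        assert group.level == "group"
        assert len(individual) == 4
        assert (_match(group.maps, templates) > 0.9).all()

    def test_single_subject_rejected(self):
        with pytest.raises(Exception):
            fit_individual_then_group([np.zeros((10, 28))], k=2)


class TestBackfit:
    def test_exact_and_flipped_map_assignment(self, layout):
        truth = _orthogonal_maps(4, seed=2)
        data = np.stack([truth[2], -truth[2], truth[0]]).T
        group = MicrostateMaps(maps=truth, gev=1.0, level="group")
        seq = backfit(Recording(data=data, fs=250.0, layout=layout), group)
        assert list(seq.labels) == [2, 2, 0]

    def test_zero_variance_sample_inherits_previous_label(self, layout):
        truth = _orthogonal_maps(3, seed=4)
        data = np.stack([truth[1], np.zeros(28), truth[2]]).T
        group = MicrostateMaps(maps=truth, gev=1.0, level="group")
        seq = backfit(Recording(data=data, fs=250.0, layout=layout), group)
        assert list(seq.labels) == [1, 1, 2]

    def test_planted_sequence_recovered(self, subject, templates, layout):
        rec, gt = subject
        group = MicrostateMaps(maps=templates, gev=1.0, level="group")
        seq = backfit(average_reference(rec), group)
        assert (seq.labels == gt.state_sequence).mean() > 0.9

    def test_channel_mismatch_rejected(self, layout):
        group = MicrostateMaps(maps=_orthogonal_maps(3)[:, :10], gev=1.0)
        with pytest.raises(Exception):
            backfit(Recording(data=np.zeros((28, 5)), fs=250.0, layout=layout), group)


class TestMeasures:
    def test_hand_enumerated_six_sample_sequence(self):
        seq = MicrostateSequence(
            labels=np.array([0, 0, 1, 1, 1, 0]),
            peak_labels=np.array([0, 1, 0]),
            peak_indices=np.array([0, 3, 5]),
            fs=250.0, k=2,
        )
        m = microstate_measures(seq)
        assert m.coverage[0] == pytest.approx(0.5)
        # runs of state 0: lengths 2 and 1 -> mean 1.5 samples = 6 ms at 250 Hz
        assert m.lifespan[0] == pytest.approx(1.5 * 1000 / 250)
        assert m.frequency[0] == 2
        # pairs: 00, 01, 11, 11, 10 -> row 0: [1/2, 1/2], row 1: [2/3, 1/3]
        np.testing.assert_allclose(m.transitions[0], [0.5, 0.5])
        np.testing.assert_allclose(m.transitions[1], [1 / 3, 2 / 3])

    def test_constant_sequence(self):
        seq = MicrostateSequence(
            labels=np.full(100, 2), peak_labels=np.full(10, 2),
            peak_indices=np.arange(10) * 10, fs=250.0, k=5,
        )
        m = microstate_measures(seq)
        assert m.coverage[2] == 1.0
        assert m.transitions[2, 2] == 1.0
        assert m.frequency[2] == 1  # first run counts even with no predecessor
        # states that never occur: NaN lifespan, uniform transition row
        assert np.isnan(m.lifespan[0])
        np.testing.assert_allclose(m.transitions[0], 0.2)

    def test_coverage_partitions_and_rows_stochastic(self, measures):
        assert measures.coverage.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(measures.transitions.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(measures.transitions_at_peaks.sum(axis=1), 1.0, atol=1e-9)


class TestPostHoc:
    def test_identical_maps_have_similarity_one(self):
        m = np.tile(_orthogonal_maps(1), (4, 1))
        assert map_similarity(m) == pytest.approx(1.0)

    def test_orthogonal_maps_have_similarity_zero(self):
        assert map_similarity(_orthogonal_maps(5)) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_three_map_mean(self):
        a = _orthogonal_maps(2, seed=6)
        m0, m1 = a
        m2 = _normalize_maps(((m0 + m1) / np.sqrt(2))[None])[0]
        maps = np.stack([m0, m1, m2])
        c = np.abs(_normalize_maps(maps) @ _normalize_maps(maps).T)
        expected = (c[0, 1] + c[0, 2] + c[1, 2]) / 3
        assert map_similarity(maps) == pytest.approx(expected, abs=1e-12)

    def test_explained_variance_bounds(self, layout):
        truth = _orthogonal_maps(4, seed=7)
        labels = np.random.default_rng(0).integers(0, 4, 500)
        act = np.random.default_rng(1).standard_normal(500)
        rec = Recording(data=(truth[labels].T * act), fs=250.0, layout=layout)
        group = MicrostateMaps(maps=truth, gev=1.0, level="group")
        assert explained_variance(rec, group) == pytest.approx(1.0)
        # maps orthogonal to the data subspace explain nothing
        other = MicrostateMaps(maps=_orthogonal_maps(8, seed=7)[4:], gev=1.0)
        assert explained_variance(rec, other) == pytest.approx(0.0, abs=1e-9)


def test_end_to_end_polarity_invariance(subject, templates, layout):
    """Flipping the sign of every sample leaves labels and measures unchanged."""
    rec, _ = subject
    ref = average_reference(rec)
    flipped = Recording(data=-ref.data, fs=ref.fs, layout=layout, reference="average")
    group = MicrostateMaps(maps=templates, gev=1.0, level="group")
    a = microstate_measures(backfit(ref, group))
    b = microstate_measures(backfit(flipped, group))
    np.testing.assert_array_equal(a.coverage, b.coverage)
    np.testing.assert_array_equal(a.transitions, b.transitions)
    np.testing.assert_array_equal(a.lifespan, b.lifespan)
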