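import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegcomplexity import (
    EntropyParams,
    InvalidParameterError,
    Recording,
    coarse_grain,
    entropy_profile,
    fuzzy_entropy,
    gfp,
    multiscale_entropy,
    sample_entropy,
    shannon_entropy,
)
from .oracles import fuzzy_entropy_oracle, sample_entropy_oracle, shannon_entropy_oracle


class TestGFP:
    def test_identical_channels_give_zero(self, layout):
        rec = Recording(data=np.ones((28, 100)), fs=250.0, layout=layout)
        assert gfp(rec).values.max() == 0.0

    def test_two_antisymmetric_channels(self, layout):
        a = np.linspace(-1, 1, 50)
        from eegcomplexity.montage import ChannelLayout

        lay2 = ChannelLayout(labels=layout.labels[:2], positions=layout.positions[:2])
        rec = Recording(data=np.vstack([a, -a]), fs=250.0, layout=lay2)
        # population SD of {+a, -a} is |a|
        np.testing.assert_allclose(gfp(rec).values, np.abs(a))

    def test_monotone_gfp_has_no_peaks(self, layout):
        data = np.vstack([np.linspace(0, 1, 100), -np.linspace(0, 1, 100)])
        from eegcomplexity.montage import ChannelLayout

        lay2 = ChannelLayout(labels=layout.labels[:2], positions=layout.positions[:2])
        assert len(gfp(Recording(data=data, fs=250.0, layout=lay2)).peak_indices) == 0

    def test_single_channel_rejected(self, layout):
        from eegcomplexity.montage import ChannelLayout

        lay1 = ChannelLayout(labels=layout.labels[:1], positions=layout.positions[:1])
        with pytest.raises(InvalidParameterError):
            gfp(Recording(data=np.zeros((1, 100)), fs=250.0, layout=lay1))


class TestShannon:
    def test_constant_signal_is_zero(self):
        assert shannon_entropy(np.full(500, 3.7)) == 0.0

    def test_uniform_64_bin_cycle_is_six_bits(self):
        # cycle through the 64 bin centers equally often
        centers = (np.arange(64) + 0.5) / 64
        x = np.tile(centers, 10)
        assert shannon_entropy(x, n_bins=64, log_base=2) == pytest.approx(6.0)

    def test_matches_hand_histogram_on_uniform_noise(self):
        x = np.random.default_rng(42).uniform(size=1000)
        assert shannon_entropy(x, n_bins=10) == pytest.approx(
            shannon_entropy_oracle(x, n_bins=10), abs=1e-12
        )

    def test_never_exceeds_log_bin_count(self):
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(400)
            assert shannon_entropy(x, n_bins=32) <= 5.0 + 1e-12


class TestFuzzy:
    def test_constant_signal_is_zero(self):
        assert fuzzy_entropy(np.full(60, 2.0)) == pytest.approx(0.0)

    def test_offset_invariance(self):
        x = np.random.default_rng(0).standard_normal(200)
        assert fuzzy_entropy(x + 123.4) == pytest.approx(fuzzy_entropy(x), abs=1e-10)

    def test_small_pattern_matches_bruteforce(self):
        x = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1.0])
        assert fuzzy_entropy(x, m=2, r=0.2, n=1) == pytest.approx(
            fuzzy_entropy_oracle(x, m=2, r=0.2, n=1), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_noise(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(int(rng.integers(50, 300)))
        assert fuzzy_entropy(x) == pytest.approx(fuzzy_entropy_oracle(x), abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidParameterError):
            fuzzy_entropy(np.array([1.0, 2.0, 3.0]), m=2)


class TestSample:
    def test_constant_signal_is_zero(self):
        assert sample_entropy(np.full(60, -1.5)) == 0.0

    def test_monotone_ramp_undefined(self):
        x = np.arange(50, dtype=float)  # step 1 > r = 0.2*SD scaled below
        assert np.isnan(sample_entropy(x, m=1, r=0.5))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_noise(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.standard_normal(500)
        assert sample_entropy(x, m=2) == pytest.approx(
            sample_entropy_oracle(x, m=2), abs=1e-12
        )

    def test_affine_invariance(self):
        # r scales with the SD, so a*x + b leaves the value unchanged
        x = np.random.default_rng(7).standard_normal(300)
        assert sample_entropy(3.5 * x - 2.0) == pytest.approx(sample_entropy(x), abs=1e-12)


class TestCoarseGrain:
    def test_scale_one_is_identity(self):
        x = np.random.default_rng(0).standard_normal(100)
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_block_average_drops_remainder(self):
        np.testing.assert_array_equal(coarse_grain(np.array([1.0, 2, 3, 4, 5]), 2), [1.5, 3.5])

    def test_scale_20_spans_80_ms_at_250_hz(self):
        fs = 250.0
        assert 20 / fs == pytest.approx(0.080)  # one coarse point = 80 ms
        x = np.arange(int(fs))
        assert len(coarse_grain(x, 20)) == int(fs) // 20


class TestMultiscale:
    def test_scale_1_equals_plain_sample_entropy(self):
        x = np.random.default_rng(3).standard_normal(800)
        mse = multiscale_entropy(x)
        assert mse[0] == sample_entropy(x, m=2)

    def test_seeded_determinism(self):
        x = np.random.default_rng(4).standard_normal(700)
        np.testing.assert_array_equal(multiscale_entropy(x), multiscale_entropy(x))

    def test_too_short_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            multiscale_entropy(np.random.default_rng(0).standard_normal(100))


class TestProfile:
    def test_shapes_and_finiteness(self, profile):
        assert profile.mse.shape == (28, 20)
        assert profile.shannon.shape == (28,)
        assert profile.fuzzy.shape == (28,)
        assert profile.gfp_mse.shape == (20,)
        assert np.isfinite(profile.mse).all()
        assert np.isfinite(profile.gfp_mse).all()

    def test_duplicated_channel_gives_identical_rows(self, epoched):
        ep2 = type(epoched)(
            epochs=epoched.epochs.copy(), fs=epoched.fs, layout=epoched.layout,
            epoch_length=epoched.epoch_length,
            n_removed=epoched.n_removed, n_total=epoched.n_total,
        )
        ep2.epochs[:, 1, :] = ep2.epochs[:, 0, :]
        prof = entropy_profile(ep2)
        np.testing.assert_array_equal(prof.mse[0], prof.mse[1])
        assert prof.shannon[0] == prof.shannon[1]
        assert prof.fuzzy[0] == prof.fuzzy[1]

    def test_profile_composes_from_single_operations(self, epoched, profile):
        """The profile equals manual per-operation calls on the same data."""
        params = EntropyParams()
        x = epoched.concatenated()[4]
        assert profile.shannon[4] == shannon_entropy(x, params.n_bins, params.log_base)
        z = (x - x.mean()) / x.std()
        assert profile.fuzzy[4] == fuzzy_entropy(z, m=params.m, r=params.r_fuzzy)
        np.testing.assert_array_equal(profile.mse[4], multiscale_entropy(x, params))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_fuzzy_offset_invariance_property(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(80)
    c = float(rng.uniform(-100, 100))
    assert fuzzy_entropy(x + c) == pytest.approx(fuzzy_entropy(x), abs=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_shannon_bounded_by_log_bins_property(seed):
    x = np.random.default_rng(seed).standard_normal(200)
    assert shannon_entropy(x, n_bins=16) <= 4.0 + 1e-12
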