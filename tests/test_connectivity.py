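import numpy as np
import pytest
from scipy import signal as sps

from megspeech.connectivity import (
    aec,
    connectivity_density,
    correlation_density,
    correlation_range,
    mean_correlation,
    strong_pair_count,
    strong_sensor_count,
    trial_correlation,
)
from megspeech.core_io import CANONICAL_BANDS, BandSpec, ValidationError
from megspeech.synth import bandlimited_source

from conftest import make_epochs

BETA = CANONICAL_BANDS[3]


def matrix3(r01, r02, r12):
    m = np.eye(3)
    m[0, 1] = m[1, 0] = r01
    m[0, 2] = m[2, 0] = r02
    m[1, 2] = m[2, 1] = r12
    return m


class TestTrialCorrelation:
    def test_duplicate_and_negated_channels(self, rng):
        x = rng.standard_normal(200)
        es = make_epochs(np.stack([x, x, -x])[None, :, :])
        corr = trial_correlation(es)[0]
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_three_sample_pair(self):
        es = make_epochs(np.array([[[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]]]))
        assert trial_correlation(es)[0][0, 1] == pytest.approx(0.5)

    def test_zero_variance_channel_marked_undefined(self, rng):
        data = rng.standard_normal((1, 3, 50))
        data[0, 1] = 2.0
        corr = trial_correlation(make_epochs(data))
        assert np.isnan(corr[0, 0, 1]) and not np.isnan(corr[0, 0, 2])

    def test_averaging_is_arithmetic_on_r(self, rng):
        es = make_epochs(rng.standard_normal((6, 4, 100)))
        np.testing.assert_allclose(
            mean_correlation(es).values, trial_correlation(es).mean(axis=0)
        )

    def test_invariant_to_positive_channel_rescaling(self, rng):
        data = rng.standard_normal((3, 4, 120))
        scales = np.array([0.2, 3.0, 17.0, 1e-3])[None, :, None]
        c1 = trial_correlation(make_epochs(data))
        c2 = trial_correlation(make_epochs(data * scales))
        np.testing.assert_allclose(c1, c2, atol=1e-10)


class TestDensitySummaries:
    def test_correlation_density_examples(self):
        assert correlation_density(np.eye(4)) == 0.0
        assert correlation_density(np.ones((4, 4))) == 1.0
        assert correlation_density(matrix3(0.5, -0.5, 0.2)) == pytest.approx(0.4)

    def test_strong_pair_count_strict_threshold(self):
        m = matrix3(0.5, -0.5, 0.2)
        assert strong_pair_count(np.eye(3)) == 0
        assert strong_pair_count(m, thresh=0.5) == 0
        assert strong_pair_count(m, thresh=0.4) == 2

    def test_strong_sensor_count(self):
        m = matrix3(0.6, 0.0, 0.0)
        assert strong_sensor_count(m, thresh=0.5) == 2

    def test_connectivity_density_signed_mean(self):
        assert connectivity_density(matrix3(0.2, 0.2, 0.2)) == pytest.approx(0.2)
        assert connectivity_density(matrix3(0.1, 0.3, 0.5)) == pytest.approx(0.3)

    def test_all_undefined_matrix_rejected(self):
        m = np.full((3, 3), np.nan)
        with pytest.raises(ValidationError, match="undefined"):
            connectivity_density(m)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValidationError):
            correlation_density(np.ones((1, 1)))


class TestCorrelationRange:
    def test_uniform_distribution_quantiles(self, rng):
        values = rng.uniform(-0.5, 0.5, size=10**5)
        lo, hi = correlation_range(values, coverage=0.95, n_boot=200, seed=0)
        assert lo == pytest.approx(-0.475, abs=0.01)
        assert hi == pytest.approx(0.475, abs=0.01)

    def test_degenerate_values(self):
        import pytest as _pytest

        lo, hi = correlation_range(np.full(50, 0.3), seed=1)
        assert lo == _pytest.approx(0.3) and hi == _pytest.approx(0.3)

    def test_full_coverage_rejected(self, rng):
        with pytest.raises(ValidationError, match="coverage"):
            correlation_range(rng.normal(size=100), coverage=1.0)

    def test_seed_determinism(self, rng):
        values = rng.normal(size=500)
        assert correlation_range(values, seed=7) == correlation_range(values, seed=7)


def naive_aec(data, fs, band, trim_s=0.1):
    """Reference AEC: explicit per-channel loop of filter -> analytic-signal
    magnitude -> textbook Pearson formula, averaged across trials."""
    sos = sps.butter(4, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")
    trim = int(round(trim_s * fs))
    n_trials, n_ch, _ = data.shape
    out = np.zeros((n_ch, n_ch))
    for t in range(n_trials):
        envs = []
        for c in range(n_ch):
            filtered = sps.sosfiltfilt(sos, data[t, c])
            env = np.abs(sps.hilbert(filtered))[trim:-trim]
            envs.append(env)
        m = np.eye(n_ch)
        for i in range(n_ch):
            for j in range(i + 1, n_ch):
                a, b = envs[i] - np.mean(envs[i]), envs[j] - np.mean(envs[j])
                r = np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2))
                m[i, j] = m[j, i] = r
        out += m
    return out / n_trials


class TestAec:
    def test_duplicated_channel_has_unit_aec(self, rng):
        x = rng.standard_normal(1000)
        es = make_epochs(np.stack([x, x])[None], fs=1000.0)
        cm = aec(es, BETA)
        assert cm.values[0, 1] == pytest.approx(1.0)

    def test_matches_naive_reference_loop(self, rng):
        # 4 channels, 200 samples at 250 Hz (beta band fits)
        data = rng.standard_normal((3, 4, 200))
        es = make_epochs(data, fs=250.0)
        for mode in ("single-trial-averaged",):
            cm = aec(es, BETA, mode=mode)
            ref = naive_aec(data, 250.0, BETA)
            np.testing.assert_allclose(cm.values, ref, atol=1e-8)

    def test_concatenated_mode_equals_reference_on_joined_trials(self, rng):
        # reference: filter each trial, join end-to-end, then envelope + Pearson
        data = rng.standard_normal((3, 4, 200))
        es = make_epochs(data, fs=250.0)
        cm = aec(es, BETA, mode="concatenated")
        sos = sps.butter(4, [BETA.lo, BETA.hi], btype="bandpass", fs=250.0, output="sos")
        trim = int(round(0.1 * 250.0))
        envs = []
        for c in range(4):
            joined = np.concatenate([sps.sosfiltfilt(sos, data[t, c]) for t in range(3)])
            envs.append(np.abs(sps.hilbert(joined))[trim:-trim])
        ref = np.eye(4)
        for i in range(4):
            for j in range(i + 1, 4):
                a, b = envs[i] - np.mean(envs[i]), envs[j] - np.mean(envs[j])
                ref[i, j] = ref[j, i] = np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2))
        np.testing.assert_allclose(cm.values, ref, atol=1e-8)

    def test_independent_channels_have_near_zero_mean_aec(self):
        trials = np.stack(
            [
                np.stack(
                    [
                        bandlimited_source(BETA, 1000, 1000.0, seed=2 * t),
                        bandlimited_source(BETA, 1000, 1000.0, seed=2 * t + 1),
                    ]
                )
                for t in range(60)
            ]
        )
        cm = aec(make_epochs(trials, fs=1000.0), BETA)
        vals = [cm.values[0, 1]]
        se = np.std(
            [np.corrcoef(trials[t, 0], trials[t, 1])[0, 1] for t in range(60)]
        ) / np.sqrt(60)
        assert abs(np.mean(vals)) <= max(3 * se, 0.05)

    def test_shared_source_coupling_is_monotone_in_rho(self):
        for seed in range(20):
            rng_local = np.random.default_rng(seed)
            values = {}
            trials = {0.3: [], 0.6: []}
            for _ in range(20):
                shared = bandlimited_source(BETA, 2000, 1000.0, seed=rng_local.integers(2**31))
                p1 = bandlimited_source(BETA, 2000, 1000.0, seed=rng_local.integers(2**31))
                p2 = bandlimited_source(BETA, 2000, 1000.0, seed=rng_local.integers(2**31))
                for rho in trials:
                    w = np.sqrt(1 - rho**2)
                    trials[rho].append(np.stack([w * p1 + rho * shared, w * p2 + rho * shared]))
            for rho, stack in trials.items():
                cm = aec(make_epochs(np.stack(stack), fs=1000.0), BETA)
                values[rho] = cm.values[0, 1]
            assert values[0.6] > values[0.3]

    def test_invariant_to_positive_rescaling(self, rng):
        data = rng.standard_normal((2, 3, 1000))
        scales = np.array([0.1, 5.0, 42.0])[None, :, None]
        c1 = aec(make_epochs(data, fs=1000.0), BETA).values
        c2 = aec(make_epochs(data * scales, fs=1000.0), BETA).values
        np.testing.assert_allclose(c1, c2, atol=1e-10)

    def test_edge_trim_removes_filter_transient_bias(self, rng):
        """The zero-phase filter transients decay toward the trial edges,
        giving every channel a common envelope edge profile that biases the
        untrimmed AEC upward; the 100 ms trim removes it.  Independent
        channels therefore show near-zero trimmed AEC but a clearly positive
        untrimmed one on 2.5 s trials."""
        data = rng.standard_normal((60, 3, 2500))
        es = make_epochs(data, fs=1000.0)
        with_trim = aec(es, BETA, edge_trim_s=0.1).values
        without = aec(es, BETA, edge_trim_s=0.0).values
        iu = np.triu_indices(3, k=1)
        assert abs(with_trim[iu].mean()) < 0.02
        assert without[iu].mean() > with_trim[iu].mean()

    def test_trial_shorter_than_two_band_periods_rejected(self, rng):
        es = make_epochs(rng.standard_normal((1, 2, 100)), fs=1000.0)
        delta = CANONICAL_BANDS[0]
        with pytest.raises(ValidationError, match="periods"):
            aec(es, delta)
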