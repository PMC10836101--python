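"""Chirp time-frequency features: Morlet transform, ITPC, single-trial power."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fxseeg as fx
from fxseeg.chirp import n_cycles_for

from conftest import SEED, phase_cube


def sinusoid_trials(freq=40.0, amplitude=1.0, n_trials=3, sfreq=500.0, dur=2.0, phases=None):
    t = np.arange(int(dur * sfreq)) / sfreq
    if phases is None:
        phases = np.zeros(n_trials)
    return np.stack([amplitude * np.cos(2 * np.pi * freq * t + p) for p in phases])


class TestClusterAverage:
    def make_rec(self, data):
        return fx.EpochedRecording(data, 500.0, [f"c{i}" for i in range(data.shape[0])], task="chirp", tmin=-0.1)

    def test_single_channel_identity(self, rng):
        data = rng.normal(size=(3, 2, 100))
        rec = self.make_rec(data)
        np.testing.assert_array_equal(fx.cluster_average(rec, ["c1"]), data[1])

    def test_opposite_channels_cancel(self, rng):
        x = rng.normal(size=(1, 2, 100))
        rec = self.make_rec(np.concatenate([x, -x]))
        assert np.allclose(fx.cluster_average(rec, ["c0", "c1"]), 0.0)

    def test_order_invariance_and_empty_error(self, rng):
        rec = self.make_rec(rng.normal(size=(3, 2, 50)))
        a = fx.cluster_average(rec, ["c0", "c2"])
        b = fx.cluster_average(rec, ["c2", "c0"])
        np.testing.assert_allclose(a, b)
        with pytest.raises(ValueError, match="empty"):
            fx.cluster_average(rec, [])


class TestMorletTransform:
    def test_cycle_rule_linear_1_to_30(self):
        freqs = np.arange(2.0, 101.0)
        cyc = n_cycles_for(freqs)
        assert cyc[0] == 1.0 and cyc[-1] == 30.0
        mid = n_cycles_for(np.array([(2.0 + 100.0) / 2]), 2.0, 100.0)
        assert np.isclose(mid[0], 15.5)

    def test_ridge_at_stimulus_frequency(self):
        cube = fx.morlet_transform(sinusoid_trials(40.0), 500.0)
        power = (np.abs(cube.coeffs) ** 2).mean(axis=0)
        power = np.where(cube.valid, power, 0.0)
        t_mid = np.abs(cube.times - 1.0) < 0.2
        ridge = cube.freqs[np.argmax(power[:, t_mid].mean(axis=1))]
        assert ridge == 40.0
        # ridge flat over interior valid times
        row = power[cube.freqs == 40.0, :][0]
        interior = cube.valid[list(cube.freqs).index(40.0)] & (np.abs(cube.times - 1.0) < 0.6)
        assert row[interior].std() / row[interior].mean() < 1e-3

    def test_power_scales_with_amplitude_squared(self):
        c1 = fx.morlet_transform(sinusoid_trials(40.0, 1.0), 500.0)
        c2 = fx.morlet_transform(sinusoid_trials(40.0, 2.0), 500.0)
        i = list(c1.freqs).index(40.0)
        sel = c1.valid[i]
        ratio = (np.abs(c2.coeffs[0, i, sel]) ** 2) / (np.abs(c1.coeffs[0, i, sel]) ** 2)
        np.testing.assert_allclose(ratio, 4.0, atol=1e-6)

    def test_short_trial_rejected_naming_frequency(self):
        sig = np.zeros((1, 50))  # 0.1 s at 500 Hz
        with pytest.raises(ValueError, match="2 Hz"):
            fx.morlet_transform(sig, 500.0)

    def test_decimation_keeps_every_kth_sample(self):
        full = fx.morlet_transform(sinusoid_trials(40.0), 500.0, decim=1)
        dec = fx.morlet_transform(sinusoid_trials(40.0), 500.0, decim=10)
        np.testing.assert_allclose(dec.coeffs, full.coeffs[:, :, ::10])


class TestITPC:
    def test_identical_trials_give_one(self):
        cube = phase_cube(np.full(8, 0.7))
        np.testing.assert_allclose(fx.itpc(cube), 1.0)

    def test_antipodal_trials_cancel(self):
        cube = phase_cube([0.3, 0.3 + np.pi])
        np.testing.assert_allclose(fx.itpc(cube), 0.0, atol=1e-12)

    @pytest.mark.parametrize("n", [25, 100, 400])
    def test_uniform_phases_match_closed_form(self, n):
        """E|resultant| of N uniform phases is sqrt(pi)/(2 sqrt(N))."""
        rng = np.random.default_rng(SEED + n)
        reps = 4000 // n + 20
        vals = []
        for _ in range(reps):
            cube = phase_cube(rng.uniform(-np.pi, np.pi, n), n_freqs=6, n_times=10)
            # all TF points share the trial phases, so take the scalar value
            vals.append(fx.itpc(cube)[0, 0])
        expected = np.sqrt(np.pi) / (2 * np.sqrt(n))
        se = np.sqrt((1 - np.pi / 4) / n / len(vals))
        assert abs(np.mean(vals) - expected) < 4 * se

    def test_amplitude_scaling_invariance(self, rng):
        phases = rng.uniform(-np.pi, np.pi, 12)
        a = fx.itpc(phase_cube(phases))
        b = fx.itpc(phase_cube(phases, amplitudes=rng.uniform(0.1, 10.0, 12)))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_needs_two_trials(self):
        with pytest.raises(ValueError, match="2 trials"):
            fx.itpc(phase_cube([0.0]))

    def test_monotone_decreasing_in_jitter(self):
        """ROI ITPC falls strictly as wrapped-normal phase jitter grows."""
        from scipy.stats import spearmanr

        jitters = [0.0, 0.5, 1.0, 1.6, 2.4]
        vals = []
        for sd in jitters:
            p = fx.ChirpSimParams(
                n_trials=40, n_channels=2, sfreq=500, phase_jitter_sd=sd,
                noise_amplitude=0.2, alpha_amplitude=0.5, seed=SEED, ch_names=["a", "b"],
            )
            rec = fx.simulate_chirp_trials(p)
            vec = fx.chirp_feature_vector(rec, cluster=["a", "b"], decim=5)
            vals.append(vec["Low Gamma ITPC"])
        rho = spearmanr(jitters, vals).statistic
        assert np.isclose(rho, -1.0)
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestSingleTrialPower:
    def test_log_power_doubles_by_six_db(self):
        c1 = fx.morlet_transform(sinusoid_trials(40.0, 1.0), 500.0)
        c2 = fx.morlet_transform(sinusoid_trials(40.0, 2.0), 500.0)
        p1, p2 = fx.single_trial_power(c1), fx.single_trial_power(c2)
        i = list(c1.freqs).index(40.0)
        sel = c1.valid[i]
        np.testing.assert_allclose((p2 - p1)[i, sel], 10 * np.log10(4.0), atol=1e-9)

    def test_constant_oscillation_baseline_corrects_to_zero(self):
        sig = sinusoid_trials(10.0, 1.0, n_trials=2, dur=3.0)
        cube = fx.morlet_transform(sig, 500.0, tmin=-1.0)
        logp = fx.single_trial_power(cube, baseline=(-0.8, -0.2))
        i = list(cube.freqs).index(10.0)
        sel = cube.valid[i] & (cube.times > 0.2) & (cube.times < 1.5)
        # residual ripple from negative-frequency leakage of the short
        # low-frequency wavelet stays well below 0.01 dB
        np.testing.assert_allclose(logp[i, sel], 0.0, atol=1e-2)

    def test_baseline_overlapping_stimulus_rejected(self):
        cube = fx.morlet_transform(sinusoid_trials(10.0, dur=3.0), 500.0, tmin=-1.0)
        with pytest.raises(ValueError, match="baseline"):
            fx.single_trial_power(cube, baseline=(-0.5, 0.5))

    def test_phase_randomization_leaves_stp_changes_itpc(self, rng):
        """STP is phase-blind; ITPC collapses under phase randomization."""
        phases = np.zeros(30)
        locked = phase_cube(phases)
        scrambled = phase_cube(rng.uniform(-np.pi, np.pi, 30))
        np.testing.assert_allclose(
            fx.single_trial_power(locked), fx.single_trial_power(scrambled), atol=1e-9
        )
        assert fx.itpc(locked)[0, 0] == 1.0
        assert fx.itpc(scrambled)[0, 0] < 0.5


@pytest.fixture(scope="module")
def locked_features():
    p = fx.ChirpSimParams(
        n_trials=30, n_channels=3, sfreq=500, phase_jitter_sd=0.0,
        noise_amplitude=0.0, alpha_amplitude=1.0, alpha_desync=0.5,
        seed=SEED, ch_names=["a", "b", "c"],
    )
    rec = fx.simulate_chirp_trials(p)
    return fx.chirp_feature_vector(rec, cluster=["a", "b", "c"], decim=5)


class TestExtractChirpVariables:

    def test_exactly_seven_named_variables(self, locked_features):
        assert list(locked_features.index) == [
            "Gamma Power", "Theta Power", "Alpha Power", "Low Gamma ITPC",
            "High Gamma ITPC", "Stimulus Onset ITPC", "Stimulus Offset ITPC",
        ]

    def test_zero_jitter_gives_unit_chirp_itpc(self, locked_features):
        assert locked_features["Low Gamma ITPC"] > 1 - 1e-6
        assert locked_features["High Gamma ITPC"] > 1 - 1e-6

    def test_alpha_desynchronization_is_negative_evoked_power(self, locked_features):
        assert locked_features["Alpha Power"] < 0

    def test_itpc_values_in_unit_interval(self, locked_features):
        for name in locked_features.index:
            if name.endswith("ITPC"):
                assert 0.0 <= locked_features[name] <= 1.0

    def test_all_noise_itpc_below_null_bound(self):
        """Without any stimulus response, ITPC stays below 3x the null level."""
        n = 60
        p = fx.ChirpSimParams(
            n_trials=n, n_channels=2, sfreq=500, response_amplitude=0.0,
            onset_amplitude=0.0, offset_amplitude=0.0, alpha_amplitude=0.0,
            noise_amplitude=1.0, seed=SEED, ch_names=["a", "b"],
        )
        vec = fx.chirp_feature_vector(fx.simulate_chirp_trials(p), cluster=["a", "b"], decim=5)
        bound = 3 * np.sqrt(np.pi) / (2 * np.sqrt(n))
        for name in ("Low Gamma ITPC", "High Gamma ITPC", "Stimulus Onset ITPC", "Stimulus Offset ITPC"):
            assert vec[name] < bound

    def test_zero_response_gamma_stp_at_noise_floor(self):
        common = dict(n_trials=25, n_channels=2, sfreq=500, onset_amplitude=0.0,
                      offset_amplitude=0.0, alpha_amplitude=0.0, noise_amplitude=1.0,
                      ch_names=["a", "b"])
        silent = fx.ChirpSimParams(response_amplitude=0.0, seed=SEED, **common)
        silent2 = fx.ChirpSimParams(response_amplitude=0.0, seed=SEED + 9, **common)
        a = fx.chirp_feature_vector(fx.simulate_chirp_trials(silent), cluster=["a", "b"], decim=5)
        b = fx.chirp_feature_vector(fx.simulate_chirp_trials(silent2), cluster=["a", "b"], decim=5)
        assert abs(a["Gamma Power"] - b["Gamma Power"]) < 0.5  # dB

    def test_empty_roi_rejected(self):
        cube = fx.morlet_transform(sinusoid_trials(40.0, n_trials=3), 500.0)
        bad = (fx.TFROI("Nothing There", 4, 8, 90.0, 95.0, measure="itpc"),)
        with pytest.raises(ValueError, match="no valid"):
            fx.extract_chirp_variables(cube, bad)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=12), st.integers(min_value=0, max_value=10_000))
def test_itpc_always_in_unit_interval(n_trials, seed):
    rng = np.random.default_rng(seed)
    cube = phase_cube(rng.uniform(-np.pi, np.pi, n_trials), n_freqs=3, n_times=4,
                      amplitudes=rng.uniform(0.5, 2.0, n_trials))
    m = fx.itpc(cube)
    assert np.all(m >= 0.0) and np.all(m <= 1.0 + 1e-12)
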