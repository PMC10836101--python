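"""Generator ground truth: determinism, moment recovery, round trips."""

import numpy as np
import pandas as pd
import pytest

import fxseeg as fx
from fxseeg.presets import GroupStats

from conftest import SEED


@pytest.fixture(scope="module")
def paf_stats():
    return GroupStats.from_dict(
        {"Posterior PAF": {"FXS": (8.17, 0.52), "CON": (8.57, 0.29)}},
        {"FXS": 70, "CON": 71},
        {"Posterior PAF": (6.0, 14.0)},
    )


class TestFeatureTable:
    def test_same_seed_bit_identical(self, paf_stats):
        a = fx.simulate_feature_table(paf_stats, n_per_group={"FXS": 50, "CON": 50}, seed=SEED)
        b = fx.simulate_feature_table(paf_stats, n_per_group={"FXS": 50, "CON": 50}, seed=SEED)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, paf_stats):
        a = fx.simulate_feature_table(paf_stats, n_per_group={"FXS": 50, "CON": 50}, seed=SEED)
        b = fx.simulate_feature_table(paf_stats, n_per_group={"FXS": 50, "CON": 50}, seed=SEED + 1)
        assert not np.allclose(a["Posterior PAF"], b["Posterior PAF"])

    def test_group_means_within_three_se(self, paf_stats):
        n = 5000
        t = fx.simulate_feature_table(paf_stats, n_per_group={"FXS": n, "CON": n}, seed=SEED)
        for grp, mean, sd in (("FXS", 8.17, 0.52), ("CON", 8.57, 0.29)):
            got = t.loc[t.group == grp, "Posterior PAF"].mean()
            assert abs(got - mean) < 3 * sd / np.sqrt(n)

    def test_zero_sd_gives_constant_rows(self):
        stats = GroupStats.from_dict(
            {"v": {"FXS": (1.5, 0.0), "CON": (0.5, 0.0)}}, {"FXS": 5, "CON": 5}
        )
        t = fx.simulate_feature_table(stats, n_per_group={"FXS": 5, "CON": 5}, seed=SEED)
        assert (t.loc[t.group == "FXS", "v"] == 1.5).all()
        assert (t.loc[t.group == "CON", "v"] == 0.5).all()

    def test_missing_pair_error_names_pair(self, paf_stats):
        with pytest.raises(KeyError, match="Posterior PAF.*MYSTERY"):
            fx.simulate_feature_table(paf_stats, n_per_group={"FXS": 5, "MYSTERY": 5}, seed=SEED)

    def test_negative_n_rejected(self, paf_stats):
        with pytest.raises(ValueError, match="negative"):
            fx.simulate_feature_table(paf_stats, n_per_group={"FXS": -1, "CON": 5}, seed=SEED)

    def test_bounded_variables_stay_in_bounds(self):
        t = fx.simulate_feature_table(fx.chirp_stats(), n_per_group={"FXS": 2000, "CON": 2000}, seed=SEED)
        for col in [c for c in t.columns if c.endswith("ITPC")]:
            assert t[col].between(0.0, 1.0).all()

    def test_relative_theta_alpha_paf_effect_directions(self):
        """FXS shows higher relative theta, lower high-alpha, slower posterior PAF."""
        t = fx.simulate_feature_table(
            fx.resting_stats(), composition=fx.default_composition("rest"), seed=SEED
        )
        fxs = t[t.group == "FXS"]
        con = t[t.group == "CON"]
        assert fxs["Relative|Frontal Theta"].mean() > con["Relative|Frontal Theta"].mean()
        assert fxs["Relative|Whole Head Alpha 2"].mean() < con["Relative|Whole Head Alpha 2"].mean()
        assert fxs["PAF|Posterior"].mean() < con["PAF|Posterior"].mean()

    def test_default_composition_counts(self):
        rest = fx.simulate_feature_table(
            fx.resting_stats(), composition=fx.default_composition("rest"), seed=SEED
        )
        assert len(rest) == 141
        assert (rest.group == "FXS").sum() == 70
        assert ((rest.group == "FXS") & (rest.sex == "M") & rest.mosaic).sum() == 12
        chirp = fx.simulate_feature_table(
            fx.chirp_stats(), composition=fx.default_composition("chirp"), seed=SEED
        )
        assert len(chirp) == 114
        assert ((chirp.group == "FXS") & (chirp.sex == "M")).sum() == 37


class TestSampleMatched:
    @pytest.mark.parametrize(
        "mean,sd,lo,hi",
        [
            (0.04, 0.03, 0.0, 1.0),   # ITPC-like, near the lower bound
            (0.18, 0.19, 0.0, np.inf),  # absolute-power-like, CV > 1
            (0.30, 0.06, 0.0, 1.0),   # comfortably interior
            (8.17, 0.52, 6.0, 14.0),  # PAF-like, both bounds finite
        ],
    )
    def test_moments_recovered(self, rng, mean, sd, lo, hi):
        x = fx.sample_matched(rng, mean, sd, lo, hi, 200_000)
        assert x.min() >= lo and x.max() <= hi
        assert abs(x.mean() - mean) < 4 * sd / np.sqrt(len(x))
        assert abs(x.std(ddof=1) - sd) < 0.02 * sd

    def test_mean_outside_bounds_rejected(self, rng):
        with pytest.raises(ValueError):
            fx.sample_matched(rng, -0.1, 0.05, 0.0, 1.0, 10)


class TestRestingSimulator:
    def test_alpha_peak_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="alpha peak"):
            fx.simulate_resting_eeg(fx.RestingSimParams(alpha_peak=5.0))

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            fx.simulate_resting_eeg(fx.RestingSimParams(sfreq=60.0, alpha_peak=10.0, duration=4))

    def test_epoch_geometry_and_determinism(self):
        p = fx.RestingSimParams(n_channels=3, duration=10, sfreq=250, seed=SEED)
        rec = fx.simulate_resting_eeg(p)
        assert rec.data.shape == (3, 5, 500)
        rec2 = fx.simulate_resting_eeg(p)
        np.testing.assert_array_equal(rec.data, rec2.data)
        p3 = fx.RestingSimParams(n_channels=3, duration=10, sfreq=250, seed=SEED + 1)
        assert not np.array_equal(rec.data, fx.simulate_resting_eeg(p3).data)

    def test_theta_amplitude_monotone_in_relative_theta(self, four_channel_regions):
        """Doubling the theta oscillator strictly raises extracted theta share."""
        vals = []
        for amp in (0.5, 1.0, 2.0):
            p = fx.RestingSimParams(
                n_channels=4, duration=40, sfreq=500, seed=SEED,
                oscillators={"theta": (6.0, amp)}, alpha_amplitude=1.0,
                pink_amplitude=2.0, noise_amplitude=0.5,
            )
            vec = fx.resting_feature_vector(fx.simulate_resting_eeg(p), four_channel_regions)
            vals.append(vec["Relative|Whole Head Theta"])
        assert vals[0] < vals[1] < vals[2]

    def test_pure_one_over_f_power_decreases_with_frequency(self, four_channel_regions):
        """With no oscillators, absolute band power falls across band centers."""
        p = fx.RestingSimParams(
            n_channels=4, duration=120, sfreq=500, seed=SEED,
            oscillators={}, alpha_amplitude=0.0, pink_amplitude=5.0, noise_amplitude=0.0,
        )
        spec = fx.amplitude_spectrum(fx.simulate_resting_eeg(p), four_channel_regions)
        bp = fx.band_power(spec, mode="absolute").loc["whole-head"]
        per_bin = [
            bp[b.label] / ((b.high - b.low) * 2)  # per-bin average within band
            for b in fx.DEFAULT_BANDS
        ]
        assert all(a > b for a, b in zip(per_bin, per_bin[1:]))


class TestChirpSimulator:
    def test_negative_padding_rejected(self):
        with pytest.raises(ValueError, match="trial window"):
            fx.simulate_chirp_trials(fx.ChirpSimParams(post_stimulus=-0.1))

    def test_zero_jitter_zero_noise_trials_identical(self):
        p = fx.ChirpSimParams(
            n_trials=5, n_channels=2, sfreq=500, phase_jitter_sd=0.0,
            noise_amplitude=0.0, alpha_amplitude=0.0, seed=SEED, ch_names=["a", "b"],
        )
        rec = fx.simulate_chirp_trials(p)
        for k in range(1, 5):
            np.testing.assert_allclose(rec.data[:, k], rec.data[:, 0])

    def test_determinism(self):
        p = fx.ChirpSimParams(n_trials=4, n_channels=2, sfreq=500, seed=SEED, ch_names=["a", "b"])
        a = fx.simulate_chirp_trials(p).data
        b = fx.simulate_chirp_trials(p).data
        np.testing.assert_array_equal(a, b)

    def test_jitter_for_itpc_inverse(self):
        assert fx.jitter_for_itpc(1.0) == 0.0
        sd = fx.jitter_for_itpc(0.14)
        assert np.isclose(np.exp(-sd**2 / 2), 0.14)
        with pytest.raises(ValueError):
            fx.jitter_for_itpc(0.0)
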