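"""Synthetic ERD trial generator: signal model, determinism, label symmetry."""

import numpy as np
import pytest

import capsmi as cm
from capsmi.synth import LABELS, load_trialset, save_trialset


def _trial(cfg, label, seed=0):
    return cm.synthesize_trial(cfg, label, np.random.default_rng(seed))


class TestSignalModel:
    def test_zero_depth_makes_labels_indistinguishable(self):
        cfg = cm.SynthConfig(erd_depth=0.0)
        left = _trial(cfg, "left", seed=3)
        right = _trial(cfg, "right", seed=3)
        np.testing.assert_array_equal(left.data, right.data)

    def test_same_seed_is_bit_identical(self, strong_cfg):
        a = _trial(strong_cfg, "left", seed=9)
        b = _trial(strong_cfg, "left", seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_contralateral_mu_amplitude_scaled_by_depth(self):
        # noiseless right-hand trial: C3 mu amplitude inside the ERD window
        # must equal (1 - d) * mu_amp = 0.2
        cfg = cm.SynthConfig(erd_depth=0.8, noise_sd=0.0, beta_amp=0.0)
        trial = _trial(cfg, "right", seed=5)
        window = (cfg.cue_time + 0.5, cfg.cue_time + 2.5)
        power = cm.band_power(trial, channel=0, band=(8, 12), window=window)
        # mean square of A*sin = A^2/2
        assert power == pytest.approx(0.5 * 0.2**2, rel=0.05)
        # ipsilateral channel is untouched
        full = cm.band_power(trial, channel=2, band=(8, 12), window=window)
        assert full == pytest.approx(0.5, rel=0.05)

    def test_label_swaps_attenuated_hemisphere(self):
        cfg = cm.SynthConfig(erd_depth=0.8, noise_sd=0.0)
        window = (cfg.cue_time + 0.5, cfg.cue_time + 2.5)
        left = _trial(cfg, "left", seed=1)
        right = _trial(cfg, "right", seed=1)
        # left hand -> C4 low, C3 high; right hand mirrored
        assert cm.band_power(left, 2, (8, 12), window) < cm.band_power(left, 0, (8, 12), window)
        assert cm.band_power(right, 0, (8, 12), window) < cm.band_power(right, 2, (8, 12), window)

    def test_cz_statistics_are_label_independent(self, strong_cfg):
        window = (strong_cfg.cue_time + 0.5, strong_cfg.cue_time + 2.5)
        powers = {label: [] for label in LABELS}
        trials = cm.synthesize_dataset(strong_cfg, n_per_class=50, seed=7)
        for t in trials:
            powers[t.label].append(cm.band_power(t, 1, (8, 12), window))
        means = {k: np.mean(v) for k, v in powers.items()}
        pooled_sd = np.sqrt(np.var(powers["left"]) / 50 + np.var(powers["right"]) / 50)
        assert abs(means["left"] - means["right"]) < 4 * pooled_sd

    def test_mu_power_monotone_in_depth(self):
        window = (3.5, 5.5)
        powers = []
        for d in (0.0, 0.25, 0.5, 0.75, 1.0):
            cfg = cm.SynthConfig(erd_depth=d, noise_sd=0.0)
            powers.append(cm.band_power(_trial(cfg, "right", seed=2), 0, (8, 12), window))
        assert all(a > b for a, b in zip(powers, powers[1:]))

    def test_contra_to_ipsi_power_ratio_matches_squared_gain(self):
        cfg = cm.SynthConfig(erd_depth=0.6, noise_sd=0.0)
        trial = _trial(cfg, "right", seed=4)
        window = (cfg.cue_time + 0.5, cfg.cue_time + 2.5)
        ratio = cm.band_power(trial, 0, (8, 12), window) / cm.band_power(trial, 2, (8, 12), window)
        assert ratio == pytest.approx((1 - 0.6) ** 2, rel=0.05)


class TestDatasetGeneration:
    def test_balanced_counts(self, strong_cfg):
        ts = cm.synthesize_dataset(strong_cfg, n_per_class=10, seed=0)
        assert len(ts) == 20
        assert sum(t.label == "left" for t in ts) == 10

    def test_seed_determinism_and_divergence(self, strong_cfg):
        a = cm.synthesize_dataset(strong_cfg, 3, seed=5)
        b = cm.synthesize_dataset(strong_cfg, 3, seed=5)
        c = cm.synthesize_dataset(strong_cfg, 3, seed=6)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.data, tb.data)
        assert any(not np.array_equal(ta.data, tc.data) for ta, tc in zip(a, c))

    @pytest.mark.parametrize("bad", [0, -1])
    def test_rejects_empty_classes(self, strong_cfg, bad):
        with pytest.raises(ValueError):
            cm.synthesize_dataset(strong_cfg, n_per_class=bad)

    def test_invalid_label_rejected(self, strong_cfg):
        with pytest.raises(ValueError, match="label"):
            cm.synthesize_trial(strong_cfg, "foot", np.random.default_rng(0))

    @pytest.mark.parametrize("kwargs", [
        {"erd_depth": 1.5}, {"erd_depth": -0.1}, {"sampling_rate": 0.0},
        {"erd_window": (2.0, 1.0)}, {"cue_time": 7.0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cm.SynthConfig(**kwargs)


class TestBandPowerOracle:
    def test_zero_signal_zero_power(self):
        t = cm.LabeledTrial(np.zeros((3, 2000)), "left", 750, 250.0)
        assert cm.band_power(t, 0, (8, 12), (0, 8)) == 0.0

    def test_unit_sinusoid_mean_square(self):
        fs, n = 250.0, 2000
        x = np.sin(2 * np.pi * 10 * np.arange(n) / fs)
        t = cm.LabeledTrial(np.tile(x, (3, 1)), "left", 750, fs)
        assert cm.band_power(t, 0, (8, 12), (0, 8)) == pytest.approx(0.5, rel=0.10)

    def test_out_of_band_component_ignored(self):
        fs, n = 250.0, 2000
        tt = np.arange(n) / fs
        base = np.sin(2 * np.pi * 10 * tt)
        mixed = base + np.sin(2 * np.pi * 45 * tt)
        p0 = cm.band_power(cm.LabeledTrial(np.tile(base, (3, 1)), "left", 750, fs), 0, (8, 12), (0, 8))
        p1 = cm.band_power(cm.LabeledTrial(np.tile(mixed, (3, 1)), "left", 750, fs), 0, (8, 12), (0, 8))
        assert p1 == pytest.approx(p0, rel=0.05)

    def test_invalid_band_or_window(self):
        t = cm.LabeledTrial(np.zeros((3, 2000)), "left", 750, 250.0)
        with pytest.raises(ValueError):
            cm.band_power(t, 0, (0, 12), (0, 8))
        with pytest.raises(ValueError):
            cm.band_power(t, 0, (8, 12), (5, 5))


class TestHdf5RoundTrip:
    def test_roundtrip_preserves_everything(self, small_trialset, tmp_path):
        path = str(tmp_path / "trials.h5")
        save_trialset(small_trialset, path)
        loaded = load_trialset(path)
        assert loaded.labels == small_trialset.labels
        for a, b in zip(loaded, small_trialset):
            np.testing.assert_array_equal(a.data, b.data)
            assert a.cue_index == b.cue_index
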