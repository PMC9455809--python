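import numpy as np
import pandas as pd
import pytest

from segbeat import FEATURE_NAMES, beat_feature_frame, extract_features, \
    mi_rank, select_top
from segbeat.features import (N_HERMITE, dwt_features, hermite_basis,
                              hermite_features, local_normalize, rr_features,
                              segment_stats)
from segbeat.io import BeatWindow

from conftest import metronome_peaks


class TestRRFeatures:
    def test_metronomic_record(self):
        out = rr_features(metronome_peaks(40), 20)
        assert out["rr"] == out["pre_rr"] == out["post_rr"] == 120
        assert out["pre_rr_over_rr"] == out["post_rr_over_rr"] == 1.0
        assert out["t_rr"] == 0.0

    def test_t_statistic_against_bruteforce(self):
        # 31 intervals of 100 samples, then one of 150
        peaks = np.concatenate([[0], np.cumsum([100] * 31 + [150])])
        i = len(peaks) - 1
        out = rr_features(peaks, i)
        window = np.array([100.0] * 31 + [150.0])  # independent reference
        expected = (150.0 - window.mean()) / (window.std(ddof=1) / np.sqrt(32))
        assert out["t_rr"] == pytest.approx(expected)
        assert out["rr"] == 150.0

    def test_first_beat_uses_record_median(self):
        peaks = np.array([0, 100, 200, 320])
        out = rr_features(peaks, 0)
        med = np.median(np.diff(peaks))
        assert out["rr"] == med
        assert out["pre_rr"] == med
        assert out["post_rr"] == 100.0
        assert out["pre_rr_over_rr"] == pytest.approx(1.0)

    def test_single_beat_rejected(self):
        with pytest.raises(ValueError):
            rr_features(np.array([100]), 0)


class TestLocalNormalize:
    def test_constant_series_becomes_ones(self):
        np.testing.assert_allclose(local_normalize(np.full(10, 3.3)), 1.0)

    def test_hand_computed_example(self):
        out = local_normalize(np.array([1.0, 1, 1, 2]), window=4)
        assert out[-1] == pytest.approx(2 / 1.25)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.random(50) + 0.5
        np.testing.assert_allclose(local_normalize(2 * x), local_normalize(x))

    def test_zero_mean_maps_to_zero(self):
        assert local_normalize(np.zeros(5))[3] == 0.0


class TestSegmentStats:
    def test_zero_window_gives_zeros(self):
        out = segment_stats(np.zeros(75))
        assert all(v == 0.0 for v in out.values())

    def test_gaussian_parts_have_null_moments(self):
        rng = np.random.default_rng(2)
        out = segment_stats(rng.normal(size=7500))
        se_skew, se_kurt = np.sqrt(6 / 1500), np.sqrt(24 / 1500)
        for i in range(1, 6):
            assert abs(out[f"skew_{i}"]) < 3 * se_skew
            assert abs(out[f"kurt_{i}"]) < 3 * se_kurt

    def test_symmetric_part_has_zero_skewness(self):
        # a linear ramp has a symmetric (uniform) value distribution
        x = np.tile(np.arange(15.0), 5)
        out = segment_stats(x)
        assert out["skew_1"] == pytest.approx(0.0, abs=1e-12)


class TestDwt:
    def test_zero_signal_gives_24_zeros(self):
        out = dwt_features(np.zeros(75))
        assert len(out) == 24
        assert all(v == 0.0 for v in out.values())

    def test_linearity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=75)
        a = np.array(list(dwt_features(x).values()))
        b = np.array(list(dwt_features(2.5 * x).values()))
        np.testing.assert_allclose(b, 2.5 * a)

    def test_constant_signal_has_vanishing_details(self):
        # 75-sample db2 level-3: 12 approximation + 12 detail coefficients
        out = dwt_features(np.full(75, 4.0))
        vec = list(out.values())
        approx, detail = np.array(vec[:12]), np.array(vec[12:24])
        assert np.max(np.abs(detail)) < 1e-8 * 4.0
        assert np.max(np.abs(approx)) > 1.0


class TestHermite:
    def test_recovers_pure_basis_function(self):
        basis = hermite_basis(75, 37, 150.0, sigma_ms=20.0)
        beat = BeatWindow(basis[:, 0].copy(), 37, 150.0)
        out = hermite_features(beat)
        assert out["hbf_1"] == pytest.approx(1.0, abs=1e-9)
        assert all(abs(out[f"hbf_{i}"]) < 1e-6 for i in range(2, 15))

    def test_reconstruction_error_monotone_in_order(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=75)
        basis = hermite_basis(75, 37, 150.0, sigma_ms=20.0, n_basis=N_HERMITE)
        sses = []
        for k in range(1, N_HERMITE + 1):
            coef, _, _, _ = np.linalg.lstsq(basis[:, :k], x, rcond=None)
            sses.append(np.sum((x - basis[:, :k] @ coef) ** 2))
        assert all(a >= b - 1e-9 for a, b in zip(sses, sses[1:]))

    def test_zero_beat_gives_zero_coefficients(self):
        out = hermite_features(BeatWindow(np.zeros(75), 37, 150.0))
        assert all(v == 0.0 for v in out.values())


class TestFeatureFrame:
    def test_79_named_finite_features(self, working_rate_record):
        rec, _ = working_rate_record
        frame = extract_features(rec)
        assert list(frame.columns[:79]) == FEATURE_NAMES
        assert len(FEATURE_NAMES) == 79
        assert np.isfinite(frame[FEATURE_NAMES].to_numpy()).all()
        assert len(frame) == rec.n_beats

    def test_extraction_is_deterministic(self, noisy_record_pair):
        rec, _ = noisy_record_pair
        a = beat_feature_frame(rec)
        b = beat_feature_frame(rec)
        pd.testing.assert_frame_equal(a, b)

    def test_finite_at_high_noise(self):
        from segbeat import SynthConfig, generate_record
        cfg = SynthConfig(seed=8, noise_sd=0.5,
                          rhythm_blocks=(("NSR", 30.0),))
        rec, _ = generate_record(cfg, "loud")
        frame = beat_feature_frame(rec)
        assert np.isfinite(frame[FEATURE_NAMES].to_numpy()).all()


class TestMutualInformation:
    def test_label_copy_ranks_first_near_entropy(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 3, size=2000)
        X = pd.DataFrame({
            "copy_of_label": y.astype(float),
            "noise_a": rng.normal(size=2000),
            "noise_b": rng.normal(size=2000),
        })
        ranked = mi_rank(X, y, seed=0)
        assert ranked[0][0] == "copy_of_label"
        p = np.bincount(y) / len(y)
        entropy = -np.sum(p * np.log(p))
        assert ranked[0][1] == pytest.approx(entropy, rel=0.10)

    def test_independent_noise_scores_near_zero(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, size=2000)
        X = pd.DataFrame({"noise": rng.normal(size=2000)})
        ranked = mi_rank(X, y, seed=0)
        assert ranked[0][1] < 0.05

    def test_duplicated_columns_get_equal_scores(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, size=500)
        x = y + rng.normal(scale=0.5, size=500)
        X = pd.DataFrame({"a": x, "b": x.copy()})
        ranked = dict(mi_rank(X, y, seed=3))
        assert ranked["a"] == pytest.approx(ranked["b"])

    def test_single_class_rejected(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError):
            mi_rank(X, np.zeros(10), seed=0)

    def test_select_top_counts(self):
        ranked = [(f"f{i}", 1.0 / (i + 1)) for i in range(79)]
        assert select_top(ranked, 6) == [f"f{i}" for i in range(6)]
        assert select_top(ranked, 0) == []
        assert len(select_top(ranked, 79)) == 79
        with pytest.raises(ValueError):
            select_top(ranked, 80)
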