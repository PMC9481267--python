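"""FFT/AR feature definitions, the generic bank, and table construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plantarpress import BankConfig, CohortConfig, extract_feature_bank
from plantarpress.cohort import SubjectProfile
from plantarpress.features import (
    DegenerateSeriesError,
    FeatureError,
    LABEL_COLUMN,
    ar_coefficients,
    build_feature_table,
    feature_columns,
    fft_angle,
    fft_coefficient,
    parse_feature_name,
    render_feature_name,
)
from plantarpress.preprocessing import SubjectSignalSet
from plantarpress.zones import ZONES


def dft_direct(x, k):
    """O(n^2) evaluation of A_k = sum_m x_m exp(-2 pi i m k / n)."""
    n = len(x)
    m = np.arange(n)
    return complex(np.sum(x * np.exp(-2j * np.pi * m * k / n)))


class TestFFT:
    def test_cosine_closed_form(self):
        n = 32
        x = np.cos(2 * np.pi * 3 * np.arange(n) / n)
        a3 = fft_coefficient(x, 3)
        assert a3.real == pytest.approx(n / 2, abs=1e-9)
        assert a3.imag == pytest.approx(0.0, abs=1e-9)
        assert fft_angle(a3) == pytest.approx(0.0, abs=1e-9)

    def test_sine_angle_minus_half_pi(self):
        n = 32
        x = np.sin(2 * np.pi * 3 * np.arange(n) / n)
        assert fft_angle(fft_coefficient(x, 3)) == pytest.approx(-np.pi / 2,
                                                                 abs=1e-9)

    def test_constant_series(self):
        x = np.full(16, 2.5)
        assert fft_coefficient(x, 0) == pytest.approx(16 * 2.5)
        for k in (1, 5, 15):
            assert abs(fft_coefficient(x, k)) == pytest.approx(0.0, abs=1e-9)
            assert fft_angle(fft_coefficient(x, k)) == 0.0

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(2, 65))
            x = rng.normal(0, 1, n)
            k = int(rng.integers(0, n))
            a = fft_coefficient(x, k)
            b = dft_direct(x, k)
            assert abs(a - b) <= 1e-9 * max(abs(b), 1.0)

    def test_out_of_range_k_raises(self):
        with pytest.raises(FeatureError):
            fft_coefficient(np.ones(8), 8)
        with pytest.raises(FeatureError):
            fft_coefficient(np.ones(8), -1)


class TestAR:
    def test_ar1_parameter_recovery(self):
        for seed in (0, 1):
            rng = np.random.default_rng(seed)
            n = 5000
            x = np.zeros(n)
            for t in range(1, n):
                x[t] = 0.6 * x[t - 1] + rng.normal()
            phi = ar_coefficients(x, max_lag=10)
            assert phi[1] == pytest.approx(0.6, abs=0.05)
            assert np.all(np.abs(phi[2:]) < 0.05)
            assert phi[0] == pytest.approx(0.0, abs=0.05)

    def test_white_noise_null(self):
        x = np.random.default_rng(5).normal(0, 1, 5000)
        phi = ar_coefficients(x, max_lag=10)
        assert np.all(np.abs(phi[1:]) < 0.05)

    def test_matches_statsmodels_autoreg(self):
        from statsmodels.tsa.ar_model import AutoReg

        x = np.random.default_rng(2).normal(0, 1, 400).cumsum()
        phi = ar_coefficients(x, max_lag=4)
        sm_params = AutoReg(x, lags=4, trend="c").fit().params
        np.testing.assert_allclose(phi, sm_params, rtol=1e-6, atol=1e-8)

    def test_degenerate_series_raise(self):
        with pytest.raises(DegenerateSeriesError):
            ar_coefficients(np.ones(100), max_lag=10)
        with pytest.raises(DegenerateSeriesError):
            ar_coefficients(np.arange(5.0), max_lag=10)


class TestBank:
    def test_hand_computed_values(self):
        out = extract_feature_bank([1.0, 2.0, 3.0], BankConfig(fft_max_k=0,
                                                               ar_max_lag=1,
                                                               acf_lags=1))
        assert out["abs_energy"] == 14.0
        assert out["maximum"] == 3.0
        assert out["minimum"] == 1.0
        assert out["mean"] == 2.0

    def test_linear_trend_exact_line(self):
        out = extract_feature_bank([0.0, 1.0, 2.0, 3.0], BankConfig())
        assert out["linear_trend_slope"] == pytest.approx(1.0)
        assert out["linear_trend_intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_signal(self):
        out = extract_feature_bank(np.zeros(30), BankConfig())
        assert out["maximum"] == 0.0
        assert out["abs_energy"] == 0.0
        assert out["fft_angle_3"] == 0.0  # zero coefficient -> angle 0
        assert np.isnan(out["skewness"])
        assert np.isnan(out["ar_coeff_1_maxlag_10"])

    def test_local_maxima_count(self):
        x = np.array([0.0, 2.0, 1.0, 3.0, 1.0, 1.0])
        out = extract_feature_bank(x, BankConfig())
        assert out["count_local_maxima"] == 2.0

    def test_autocorrelation_matches_direct_formula(self):
        x = np.random.default_rng(6).normal(0, 1, 80)
        out = extract_feature_bank(x, BankConfig())
        mu, var, n = x.mean(), x.var(), x.size
        for lag in (1, 4, 10):
            direct = ((x[:-lag] - mu) * (x[lag:] - mu)).sum() / ((n - lag) * var)
            assert out[f"autocorr_lag_{lag}"] == pytest.approx(direct)

    def test_bank_size_matches_config(self):
        cfg = BankConfig()
        n = 70
        ids = cfg.feature_ids(n)
        out = extract_feature_bank(np.random.default_rng(0).normal(0, 1, n), cfg)
        assert list(out) == ids
        assert len(ids) == 7 + 2 + 10 + 2 * min(cfg.fft_max_k, n - 1) + 2 + 11 + 1

    def test_too_short_signal_raises(self):
        with pytest.raises(FeatureError):
            extract_feature_bank([1.0], BankConfig())


class TestFeatureNaming:
    @given(st.sampled_from(ZONES + ("whole_foot", "person")),
           st.sampled_from(("peak_pressure", "mean_pressure", "mean_force",
                            "vertical_force", "characteristic")),
           st.sampled_from(("barefoot", "shod", "na")),
           st.sampled_from(("maximum", "fft_angle_21",
                            "ar_coeff_7_maxlag_10", "abs_energy")))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_round_trip(self, zone, measurement, footwear, fid):
        name = render_feature_name(zone, measurement, footwear, fid)
        assert parse_feature_name(name) == (zone, measurement, footwear, fid)

    def test_invalid_tokens_raise(self):
        with pytest.raises(FeatureError):
            render_feature_name("elbow", "peak_pressure", "shod", "maximum")
        with pytest.raises(FeatureError):
            parse_feature_name("too|few|parts")


class TestFeatureTable:
    @staticmethod
    def _profile(sid, injured=False):
        return SubjectProfile(sid, "female", 170.0, 65.0, 41.0, injured)

    def _signal_sets(self, sids, n=24, wiggle=0.0):
        rng = np.random.default_rng(0)
        base = {
            (zone, meas, fw): np.abs(rng.normal(1, 0.3, n))
            for zone in ZONES
            for meas in ("peak_pressure", "mean_pressure", "mean_force")
            for fw in ("barefoot", "shod")
        }
        for fw in ("barefoot", "shod"):
            base[("whole_foot", "vertical_force", fw)] = np.abs(rng.normal(1, 0.3, n))
        return {
            sid: SubjectSignalSet(sid, {k: v + i * wiggle
                                        for k, v in base.items()})
            for i, sid in enumerate(sids)
        }

    def test_column_count_from_bank_config(self):
        bank = BankConfig(fft_max_k=5, acf_lags=3, ar_max_lag=2)
        sids = ["A", "B"]
        table = build_feature_table(self._signal_sets(sids, n=24),
                                    [self._profile(s) for s in sids], bank)
        per_signal = len(bank.feature_ids(24))
        assert table.shape == (2, 62 * per_signal + 5 + 1)  # + label

    def test_identical_subjects_identical_rows(self):
        sids = ["A", "B"]
        table = build_feature_table(self._signal_sets(sids, wiggle=0.0),
                                    [self._profile(s) for s in sids],
                                    BankConfig(fft_max_k=3))
        feats = feature_columns(table)
        np.testing.assert_array_equal(table.loc["A", feats].to_numpy(float),
                                      table.loc["B", feats].to_numpy(float))

    def test_construction_deterministic(self):
        sids = ["A", "B", "C"]
        profs = [self._profile(s, injured=(s == "C")) for s in sids]
        t1 = build_feature_table(self._signal_sets(sids, wiggle=0.1), profs,
                                 BankConfig(fft_max_k=3))
        t2 = build_feature_table(self._signal_sets(sids, wiggle=0.1), profs,
                                 BankConfig(fft_max_k=3))
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_zone_raises(self):
        sids = ["A", "B"]
        sets = self._signal_sets(sids)
        del sets["B"].signals[("midfoot", "mean_force", "shod")]
        with pytest.raises(FeatureError, match="inventory"):
            build_feature_table(sets, [self._profile(s) for s in sids],
                                BankConfig(fft_max_k=3))

    def test_person_characteristics_and_label(self):
        sids = ["A", "B"]
        profs = [self._profile("A"), self._profile("B", injured=True)]
        table = build_feature_table(self._signal_sets(sids, wiggle=0.1),
                                    profs, BankConfig(fft_max_k=3))
        assert table.loc["B", LABEL_COLUMN] == 1
        assert table.loc["A", "person|characteristic|na|height"] == 170.0
        assert table.loc["A", "person|characteristic|na|sex"] == 0.0
        assert table.loc["A", "person|characteristic|na|bmi"] == pytest.approx(
            65.0 / 1.70 ** 2)
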