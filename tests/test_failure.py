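"""Failure-detection tests: MAD thresholds, AUROC, regression, screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mskseg.failure import (
    K_FAILED,
    K_INACCURATE,
    MAD_SCALE,
    FailureModel,
    detect_auroc,
    fit_dc_uncertainty_regression,
    fit_failure_model,
    mad_threshold,
    screen_unlabeled,
    uncertainty_threshold_from_regression,
)

WORKED_DCS = [0.90, 0.92, 0.94, 0.96, 0.98]  # median 0.94, MAD 0.02


def brute_force_auroc(u, d, thr):
    """O(n^2) pairwise AUROC oracle with 0.5 tie credit."""
    u, d = np.asarray(u, float), np.asarray(d, float)
    pos = np.where(d < thr)[0]
    neg = np.where(d >= thr)[0]
    if len(pos) == 0 or len(neg) == 0:
        return None
    s = 0.0
    for i in pos:
        for j in neg:
            s += 1.0 if u[i] > u[j] else (0.5 if u[i] == u[j] else 0.0)
    return s / (len(pos) * len(neg))


class TestMadThreshold:
    def test_worked_example_k2(self):
        # 0.94 + 1.4826 * (-2) * 0.02 = 0.880696
        assert mad_threshold(WORKED_DCS, K_INACCURATE) == pytest.approx(0.880696, abs=1e-9)

    def test_worked_example_k3(self):
        # 0.94 + 1.4826 * (-3) * 0.02 = 0.851044
        assert mad_threshold(WORKED_DCS, K_FAILED) == pytest.approx(0.851044, abs=1e-9)

    def test_scale_constant(self):
        assert MAD_SCALE == 1.4826

    def test_needs_three_values(self):
        with pytest.raises(ValueError):
            mad_threshold([0.9, 0.8], -2)

    def test_rejects_out_of_range_dice(self):
        with pytest.raises(ValueError):
            mad_threshold([0.9, 1.1, 0.8], -2)


class TestAuroc:
    def test_perfect_separation(self):
        u = [0.9, 0.8, 0.1, 0.2]
        d = [0.3, 0.4, 0.95, 0.9]  # high uncertainty <-> low Dice
        assert detect_auroc(u, d, 0.5) == 1.0

    def test_inverted_detector(self):
        u = [0.1, 0.2, 0.9, 0.8]
        d = [0.3, 0.4, 0.95, 0.9]
        assert detect_auroc(u, d, 0.5) == 0.0

    def test_all_tied_gives_half(self):
        assert detect_auroc([0.5, 0.5, 0.5, 0.5], [0.2, 0.3, 0.9, 0.95], 0.5) == 0.5

    def test_single_class_undefined(self):
        assert detect_auroc([0.1, 0.2], [0.9, 0.95], 0.5) is None

    def test_nan_uncertainties_excluded(self):
        u = [0.9, np.nan, 0.1]
        d = [0.3, 0.4, 0.9]
        assert detect_auroc(u, d, 0.5) == 1.0

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            u = np.round(rng.random(n), 1)  # coarse values force ties
            d = rng.random(n)
            thr = float(rng.uniform(0.2, 0.8))
            expected = brute_force_auroc(u, d, thr)
            got = detect_auroc(u, d, thr)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.random(12)
        d = rng.random(12)
        a = detect_auroc(u, d, 0.5)
        b = detect_auroc(np.exp(3 * u), d, 0.5)
        if a is None:
            assert b is None
        else:
            assert b == pytest.approx(a, abs=1e-12)


class TestRegression:
    def test_hand_line(self):
        reg = fit_dc_uncertainty_regression([1.0, 2.0, 3.0], [0.9, 0.8, 0.7])
        assert reg["a"] == pytest.approx(1.0, abs=1e-12)
        assert reg["b"] == pytest.approx(-0.1, abs=1e-12)
        assert reg["pearson_rho"] == pytest.approx(-1.0, abs=1e-12)
        assert reg["n"] == 3

    def test_constant_uncertainty_rejected(self):
        with pytest.raises(ValueError):
            fit_dc_uncertainty_regression([0.5, 0.5, 0.5], [0.9, 0.8, 0.7])

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            fit_dc_uncertainty_regression([1.0, 2.0], [0.9, 0.8])

    def test_threshold_inversion(self):
        reg = {"a": 1.0, "b": -0.1}
        # u* = (0.7 - 1.0) / -0.1 = 3.0
        assert uncertainty_threshold_from_regression(reg, 0.7) == pytest.approx(3.0)

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            uncertainty_threshold_from_regression({"a": 0.0, "b": 0.1}, 0.7)

    def test_lower_dc_threshold_gives_higher_cutoff(self):
        reg = {"a": 1.0, "b": -0.1}
        assert uncertainty_threshold_from_regression(reg, 0.6) > uncertainty_threshold_from_regression(reg, 0.8)


class TestFailureModelFit:
    def _records(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        u = rng.uniform(0.01, 0.2, n)
        d = np.clip(1.0 - 3.0 * u + rng.normal(0, 0.02, n), 0, 1)
        return u, d

    def test_formula_fidelity(self):
        """Stored thresholds reproduce the defining formulas bit-for-bit."""
        u, d = self._records()
        fm = fit_failure_model(u, d)
        med = float(np.median(d))
        mad = float(np.median(np.abs(d - med)))
        assert fm.dc_threshold_k2 == med + MAD_SCALE * K_INACCURATE * mad
        assert fm.dc_threshold_k3 == med + MAD_SCALE * K_FAILED * mad
        assert fm.uncertainty_threshold_k2 == (fm.dc_threshold_k2 - fm.regression_intercept) / fm.regression_slope
        assert fm.uncertainty_threshold_k3 == (fm.dc_threshold_k3 - fm.regression_intercept) / fm.regression_slope
        assert fm.uncertainty_threshold_k3 > fm.uncertainty_threshold_k2  # k=-3 is the stricter outlier

    def test_json_roundtrip(self, tmp_path):
        u, d = self._records(seed=1)
        fm = fit_failure_model(u, d, structure_id=2)
        fm.to_json(tmp_path / "fm.json")
        loaded = FailureModel.from_json(tmp_path / "fm.json")
        assert loaded == fm

    def test_degenerate_mad_warns(self):
        u = np.linspace(0.01, 0.1, 10)
        d = np.full(10, 0.9)
        d[-1] = 0.2  # highest-uncertainty case fails: slope negative, MAD still 0
        with pytest.warns(UserWarning):
            fit_failure_model(u, d)


class TestScreening:
    def _model(self):
        return FailureModel(
            structure_id="all_structures_average",
            dc_median=0.94, dc_mad=0.02,
            dc_threshold_k2=0.880696, dc_threshold_k3=0.851044,
            regression_intercept=1.0, regression_slope=-0.1, pearson_rho=-0.9,
            uncertainty_threshold_k2=1.19304, uncertainty_threshold_k3=1.48956,
            auroc_k2=1.0, auroc_k3=1.0, n=40,
        )

    def test_flag_bands(self):
        fm = self._model()
        report = screen_unlabeled(
            {
                "ok-case": {1: 0.5, 2: 0.6},
                "inaccurate-case": {1: 1.3, 2: 1.3},
                "failed-case": {1: 2.0, 2: 2.0},
            },
            fm,
        )
        flags = {r["case"]: r["flag"] for r in report}
        assert flags == {"ok-case": "ok", "inaccurate-case": "inaccurate", "failed-case": "failed"}

    def test_missing_structure_fails_outright(self):
        fm = self._model()
        report = screen_unlabeled({"case": {1: 0.1, 2: float("nan")}}, fm)
        assert report[0]["flag"] == "failed"
        assert "missing" in report[0]["reason"]

    def test_mean_uncertainty_reported(self):
        fm = self._model()
        report = screen_unlabeled({"case": {1: 0.2, 2: 0.4}}, fm)
        assert report[0]["mean_uncertainty"] == pytest.approx(0.3)
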