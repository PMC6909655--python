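"""Iso-DO2i bands, weighted quadratic fits and flow recommendations."""

import numpy as np
import pandas as pd
import pytest

from gdperf import physiology
from gdperf.iso_do2 import (
    DEFAULT_LEVELS, IsoBand, closed_form_curve, extract_band, fit_quadratic,
    recommend_flow,
)


def band_frame(level, hb_lo=8.0, hb_hi=12.0, n=200):
    """Noise-free rows lying exactly on the closed-form iso surface."""
    hb = np.linspace(hb_lo, hb_hi, n)
    ci = physiology.required_ci(level, hb, 1.0, 0.0)
    do2i = physiology.do2i_from_ci(ci, hb, 1.0, 0.0)
    return pd.DataFrame({"ci": ci, "hb": hb, "do2i": do2i})


class TestExtractBand:
    def test_noise_free_rows_captured_with_weight_one(self):
        df = band_frame(330.0)
        band = extract_band(df, 330.0, 10.0)
        assert len(band) == len(df)
        np.testing.assert_allclose(band.weights, 1.0, atol=1e-10)

    def test_zero_tolerance_degenerate_kernel(self):
        df = pd.DataFrame({"ci": [2.0, 2.1, 2.2], "hb": [10, 10.5, 11],
                           "do2i": [330.0, 331.0, 330.0]})
        band = extract_band(df, 330.0, 0.0)
        assert len(band) == 2 and (band.weights == 1.0).all()

    def test_membership_matches_brute_force_scan(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame({"ci": rng.uniform(1, 3, 2000),
                           "hb": rng.uniform(7, 13, 2000)})
        df["do2i"] = physiology.do2i_from_ci(
            df["ci"].to_numpy(), df["hb"].to_numpy(), 1.0, 0.0)
        band = extract_band(df, 330.0, 5.0)
        oracle = df.loc[(df["do2i"] - 330.0).abs() <= 5.0]
        assert set(zip(band.data["ci"], band.data["hb"])) == set(
            zip(oracle["ci"], oracle["hb"]))
        np.testing.assert_allclose(
            band.weights, 1 - (band.data["do2i"] - 330).abs() / 5.0)

    def test_empty_band_signals_insufficient_data(self):
        df = band_frame(280.0)
        with pytest.raises(ValueError, match="insufficient data"):
            extract_band(df, 1000.0, 5.0)


class TestFitQuadratic:
    @pytest.mark.parametrize("level", DEFAULT_LEVELS)
    def test_closed_form_oracle(self, level):
        """Fitted curve within 0.05 L/min/m2 of the generating hyperbola."""
        band = extract_band(band_frame(level), level, 10.0)
        fit = fit_quadratic(band)
        hb = np.linspace(fit.hb_min, fit.hb_max, 500)
        curve = closed_form_curve(level)
        assert np.max(np.abs(fit(hb) - curve(hb))) < 0.05

    def test_straight_line_band_has_negligible_curvature(self):
        hb = np.linspace(8, 12, 50)
        df = pd.DataFrame({"ci": 3.0 - 0.1 * hb, "hb": hb, "do2i": 330.0})
        fit = fit_quadratic(extract_band(df, 330.0, 10.0))
        assert fit.coefficients[2] == pytest.approx(0.0, abs=1e-8)
        assert fit.coefficients[1] == pytest.approx(-0.1, abs=1e-8)

    def test_duplicated_rows_with_halved_weights_give_identical_fit(self):
        df = band_frame(330.0, n=40)
        base = extract_band(df, 330.0, 10.0)
        # perturb ci so the fit is not exact and weights actually matter
        rng = np.random.default_rng(3)
        data = base.data.copy()
        data["ci"] = data["ci"] + rng.normal(0, 0.05, len(data))
        band = IsoBand(330.0, 10.0, data, base.weights)
        doubled = IsoBand(330.0, 10.0,
                          pd.concat([data, data], ignore_index=True),
                          np.concatenate([band.weights / 2, band.weights / 2]))
        c1 = fit_quadratic(band).coefficients
        c2 = fit_quadratic(doubled).coefficients
        np.testing.assert_allclose(c1, c2, rtol=1e-9)

    def test_agrees_with_statsmodels_wls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        hb = rng.uniform(8, 12, 300)
        ci = 6 - 0.6 * hb + 0.02 * hb**2 + rng.normal(0, 0.05, 300)
        w = rng.uniform(0.1, 1.0, 300)
        band = IsoBand(330.0, 10.0,
                       pd.DataFrame({"ci": ci, "hb": hb, "do2i": 330.0}), w)
        ours = fit_quadratic(band).coefficients
        X = sm.add_constant(np.column_stack([hb, hb**2]))
        theirs = sm.WLS(ci, X, weights=w).fit().params
        np.testing.assert_allclose(ours, theirs, rtol=1e-8)

    def test_too_few_distinct_hb_rejected(self):
        df = pd.DataFrame({"ci": np.linspace(2, 2.5, 6),
                           "hb": [9, 9, 10, 10, 11, 11], "do2i": 330.0})
        with pytest.raises(ValueError, match="distinct Hb"):
            fit_quadratic(extract_band(df, 330.0, 10.0))

    def test_evaluation_outside_domain_rejected(self):
        fit = fit_quadratic(extract_band(band_frame(330.0), 330.0, 10.0))
        with pytest.raises(ValueError, match="domain"):
            fit(15.0)
        fit(15.0, extrapolate=True)  # explicit override is allowed

    def test_round_trips_through_dict(self):
        from gdperf.iso_do2 import QuadraticFit

        fit = fit_quadratic(extract_band(band_frame(280.0), 280.0, 10.0))
        again = QuadraticFit.from_dict(fit.to_dict())
        assert again == fit


class TestClosedFormCurve:
    def test_discussion_value(self):
        assert closed_form_curve(280.0)(8.0) == pytest.approx(2.574, abs=5e-4)

    def test_scales_linearly_with_level(self):
        hb = np.linspace(7, 13, 20)
        np.testing.assert_allclose(closed_form_curve(560.0)(hb),
                                   2 * closed_form_curve(280.0)(hb))

    def test_decreasing_convex_vanishing(self):
        curve = closed_form_curve(330.0)
        hb = np.linspace(6, 14, 100)
        ci = curve(hb)
        assert (np.diff(ci) < 0).all()
        assert (np.diff(ci, 2) > 0).all()
        assert curve(1e9) == pytest.approx(0.0, abs=1e-6)


class TestRecommendFlow:
    def test_discussion_worked_example(self):
        rec = recommend_flow(hb=8.0, bsa=1.95, level=280.0)
        assert rec.ci_rounded == 2.6
        assert rec.flow == pytest.approx(rec.ci * 1.95)

    def test_initial_study_flow_satisfies_target_at_hb_10(self):
        rec = recommend_flow(hb=10.0, bsa=1.95, level=280.0)
        assert rec.ci == pytest.approx(2.06, abs=0.005)
        assert 2.2 >= rec.ci  # the study's initial CI 2.2 meets the target

    def test_zero_level_needs_zero_flow(self):
        rec = recommend_flow(hb=10.0, bsa=1.95, level=0.0)
        assert rec.ci == 0.0 and rec.flow == 0.0

    def test_full_precision_retained_internally(self):
        rec = recommend_flow(hb=8.0, bsa=1.95, level=280.0)
        assert rec.ci != rec.ci_rounded
        assert rec.ci == pytest.approx(280.0 / (10 * 1.36 * 8.0), rel=1e-12)
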