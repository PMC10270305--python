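"""Perturbation detection and the 40-feature extraction."""

import numpy as np
import pytest

from resilmilk.data_io import LactationSeries
from resilmilk.lactation_models import ModelFit, expected_residuals, fit_expected_curve
from resilmilk.perturbation_features import (
    CATEGORY_SIZES,
    FEATURE_CATALOG,
    FEATURE_NAMES,
    detect_perturbations,
    expected_residual_features,
    extract_all,
    perturbation_features,
    resilience_indicators,
    wood_residual_features,
)
from resilmilk.synthetic_data import (
    SimConfig,
    simulate_lactation,
    truth_feature_oracle,
)

from conftest import make_quartic_series


def make_fit(dims, observed, expected, kind="expected"):
    dims = np.asarray(dims)
    observed = np.asarray(observed, dtype=float)
    expected = np.broadcast_to(np.asarray(expected, dtype=float), observed.shape)
    return ModelFit(kind=kind, dims=dims, observed=observed, predicted=expected.copy())


def constant_fit_with_dip(level=30.0, dip_value=21.0, dip_start=100, dip_end=109):
    dims = np.arange(11, 341)
    observed = np.full(dims.size, level)
    observed[(dims >= dip_start) & (dims <= dip_end)] = dip_value
    return make_fit(dims, observed, level)


class TestDetectPerturbations:
    def test_no_negative_residuals_no_perturbations(self):
        fit = make_fit(np.arange(11, 341), np.full(330, 30.0), 30.0)
        assert detect_perturbations(fit) == []

    def test_constructed_ten_day_dip(self):
        fit = constant_fit_with_dip(30.0, 21.0)
        perts = detect_perturbations(fit)
        assert len(perts) == 1
        p = perts[0]
        assert (p.start_dim, p.end_dim) == (100, 109)
        assert p.milk_loss == pytest.approx(90.0, abs=1e-9)
        assert p.deepest_deficit == pytest.approx(9.0, abs=1e-12)
        assert p.deepest_dim == 100  # ties broken to the earliest day
        # 21/30 = 0.70 reaches the 85% floor but not strictly below 70%
        assert p.severity == "minor"
        assert p.dev_days + p.rec_days == p.duration

    def test_deeper_dip_is_major(self):
        perts = detect_perturbations(constant_fit_with_dip(30.0, 20.0))
        assert len(perts) == 1 and perts[0].severity == "major"

    def test_four_day_run_too_short(self):
        perts = detect_perturbations(constant_fit_with_dip(30.0, 20.0, 100, 103))
        assert perts == []

    def test_shallow_run_is_not_a_perturbation(self):
        # 27/30 = 0.90 never crosses the 85% floor: routine variability
        fit = constant_fit_with_dip(30.0, 27.0)
        assert detect_perturbations(fit) == []
        # ... but it still counts as a >=5-day negative run
        assert expected_residual_features(fit)["ExpNeg_5d"] == 1.0

    def test_missing_day_breaks_run(self):
        dims = np.concatenate([np.arange(11, 105), np.arange(106, 341)])
        observed = np.full(dims.size, 30.0)
        observed[(dims >= 98) & (dims <= 112)] = 20.0  # dim 105 missing
        perts = detect_perturbations(make_fit(dims, observed, 30.0))
        assert [(p.start_dim, p.end_dim) for p in perts] == [(98, 104), (106, 112)]


class TestWoodResidualFeatures:
    def test_alternating_residuals(self):
        dims = np.arange(1, 31)
        resid = np.resize([1.0, -1.0], 30)
        fit = make_fit(dims, 20.0 + resid, 20.0, kind="wood")
        feats = wood_residual_features(fit)
        assert feats["WoodResMeanAbs"] == 1.0
        assert feats["WoodResSkew"] == pytest.approx(0.0, abs=1e-12)
        assert feats["WoodResMaxAbs"] == 1.0
        assert feats["WoodResRMSE"] == 1.0

    def test_zero_residuals(self):
        fit = make_fit(np.arange(1, 31), np.full(30, 20.0), 20.0, kind="wood")
        feats = wood_residual_features(fit)
        assert feats["WoodResVar"] == 0.0 and feats["WoodResRMSE"] == 0.0

    def test_lag1_autocorrelation_matches_direct_formula(self):
        rng = np.random.default_rng(42)
        r = rng.normal(0, 1, 200)
        for t in range(1, 200):
            r[t] = 0.5 * r[t - 1] + r[t]
        fit = make_fit(np.arange(1, 201), 20.0 + r, 20.0, kind="wood")
        got = wood_residual_features(fit)["WoodResAClag1"]
        rc = r - r.mean()
        want = np.sum(rc[:-1] * rc[1:]) / np.sum(rc**2)
        assert got == pytest.approx(want, rel=1e-12)


class TestExpectedResidualFeatures:
    def test_zero_residuals(self):
        fit = make_fit(np.arange(11, 341), np.full(330, 25.0), 25.0)
        feats = expected_residual_features(fit)
        assert feats["ExpPercNegative"] == 0.0
        assert feats["ExpNeg_5d"] == 0.0
        assert feats["ExpAutoCorr"] == 0.0

    def test_sign_changes(self):
        resid = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
        fit = make_fit(np.arange(11, 16), 25.0 + resid, 25.0)
        assert expected_residual_features(fit)["ExpAutoCorr"] == 4.0

    def test_constructed_dip_percentages(self):
        fit = constant_fit_with_dip(30.0, 21.0)
        feats = expected_residual_features(fit)
        assert feats["ExpPercLower85"] == pytest.approx(10 / 330 * 100, rel=1e-12)
        assert feats["ExpPercNegative"] == pytest.approx(10 / 330 * 100, rel=1e-12)
        assert feats["ExpPercLower70"] == 0.0
        assert feats["ExpMaxNegRes"] == -9.0
        assert feats["ExpNeg_5d"] == 1.0


class TestPerturbationFeatures:
    def test_empty_list_all_zero(self):
        feats = perturbation_features([])
        assert set(feats) == {n for n, c, *_ in FEATURE_CATALOG if c == 5}
        assert all(v == 0.0 for v in feats.values())

    def test_single_major_episode(self):
        perts = detect_perturbations(constant_fit_with_dip(30.0, 20.0))
        feats = perturbation_features(perts)
        assert feats["PertNoTotal"] == 1.0
        assert feats["PertNoMajor"] == 1.0
        assert feats["PertTotalLoss"] == pytest.approx(100.0, abs=1e-9)
        assert feats["PertDeepest"] == pytest.approx(10.0, abs=1e-12)
        assert feats["PertMajDaysDev"] == 1.0
        assert feats["PertMajDaysRec"] == 9.0

    def test_minor_means(self):
        from resilmilk.perturbation_features import Perturbation

        perts = [
            Perturbation(10, 16, 12, "minor", 5.0, 2.0),  # dev 3
            Perturbation(30, 36, 34, "minor", 7.0, 3.0),  # dev 5
        ]
        feats = perturbation_features(perts)
        assert feats["PertMinDaysDev"] == 4.0
        assert feats["PertMinMilkLoss"] == 12.0
        assert feats["PertNoMinor"] == 2.0

    def test_count_and_loss_partitions(self, small_population):
        # PertNoTotal = minor + major; losses add up; ExpNeg_5d >= PertNoTotal
        for series in small_population.series[:20]:
            feats = extract_all(series).values
            assert feats["PertNoTotal"] == feats["PertNoMinor"] + feats["PertNoMajor"]
            assert feats["PertTotalLoss"] == pytest.approx(
                feats["PertMinMilkLoss"] + feats["PertMajMilkLoss"], abs=1e-9
            )
            assert feats["ExpNeg_5d"] >= feats["PertNoTotal"]


class TestResilienceIndicators:
    def test_lnvar_identity(self):
        n = 330
        r = np.resize([1.0, -1.0], n)
        r *= np.e / np.sqrt(np.var(r, ddof=1))  # sample variance exactly e^2
        fit = make_fit(np.arange(11, 11 + n), 25.0 + r, 25.0)
        feats = resilience_indicators(fit)
        assert feats["LnVar"] == pytest.approx(2.0, abs=1e-12)

    def test_zero_variance_raises(self):
        fit = make_fit(np.arange(11, 341), np.full(330, 25.0), 25.0)
        with pytest.raises(ValueError, match="degenerate"):
            resilience_indicators(fit)

    def test_white_noise_autocorrelation_near_zero(self):
        rng = np.random.default_rng(1)
        r = rng.normal(0, 1, 330)
        fit = make_fit(np.arange(11, 341), 25.0 + r, 25.0)
        assert abs(resilience_indicators(fit)["ExpAClag1"]) < 0.15

    def test_ar1_autocorrelation_recovery(self):
        rng = np.random.default_rng(2)
        n, rho = 330, 0.6
        r = np.empty(n)
        r[0] = rng.normal(0, 1)
        for t in range(1, n):
            r[t] = rho * r[t - 1] + rng.normal(0, np.sqrt(1 - rho**2))
        fit = make_fit(np.arange(11, 11 + n), 25.0 + r, 25.0)
        assert resilience_indicators(fit)["ExpAClag1"] == pytest.approx(rho, abs=0.1)

    def test_gap_pairs_excluded(self):
        # identical residual values; removing a day removes exactly the two
        # pairs that straddle it from the numerator
        rng = np.random.default_rng(3)
        r = rng.normal(0, 1, 100)
        dims = np.arange(11, 111)
        full = resilience_indicators(make_fit(dims, 25.0 + r, 25.0))["ExpAClag1"]
        keep = dims != 50
        gapped = resilience_indicators(make_fit(dims[keep], 25.0 + r[keep], 25.0))[
            "ExpAClag1"
        ]
        assert gapped != pytest.approx(full, abs=1e-12)

    def test_lnvar_increases_with_noise(self):
        cfg = SimConfig(seed=5, pert_rate=0.0, missing_rate=0.0)
        vals = []
        for sigma in (0.5, 1.0, 2.0):
            rng = np.random.default_rng(99)  # matched noise draws
            series, _ = simulate_lactation(
                cfg, "c", "h", (25.0, 0.2, 0.003), rng, noise_sigma=sigma
            )
            curve = fit_expected_curve(series)
            fit = expected_residuals(series, curve)
            vals.append(resilience_indicators(fit)["LnVar"])
        assert vals[0] < vals[1] < vals[2]


class TestExtractAll:
    def test_forty_features_in_six_categories(self, small_population):
        fv = extract_all(small_population.series[0])
        assert len(fv.values) == 40
        sizes = {}
        for name, cat, *_ in FEATURE_CATALOG:
            sizes[cat] = sizes.get(cat, 0) + 1
        assert sizes == CATEGORY_SIZES == {1: 6, 2: 6, 3: 4, 4: 11, 5: 11, 6: 2}

    def test_established_feature_names_present(self):
        required = {
            "ExpAClag1", "ExpPercNegative", "ExpPercLower85", "ExpNeg_5d",
            "PertNoMinor", "PertNoTotal", "PertMinDaysRec", "PertMinDaysDev",
            "PertMajMilkLoss", "PertMinMilkLoss", "PertTotalLoss", "PertDeepest",
        }
        assert required <= set(FEATURE_NAMES)

    def test_determinism(self, small_population):
        s = small_population.series[3]
        v1 = extract_all(s).values
        v2 = extract_all(s).values
        assert v1 == v2

    def test_scale_equivariance(self):
        series = make_quartic_series(dims=np.arange(1, 336))
        dmy = series.dmy.copy()
        dmy[110:125] *= 0.6  # one deep dip
        base = LactationSeries("s", series.dims, dmy)
        doubled = LactationSeries("s", series.dims, 2.0 * dmy)
        f1, f2 = extract_all(base).values, extract_all(doubled).values
        for kg_feature in ("WoodPeakYield", "WoodCumYield305", "ExpPeakYield",
                           "PertTotalLoss", "PertDeepest", "ExpRMSE"):
            assert f2[kg_feature] == pytest.approx(2.0 * f1[kg_feature], rel=1e-6)
        for invariant_feature in ("PertNoTotal", "PertNoMajor", "ExpPercLower85",
                                  "ExpNeg_5d", "ExpPeakDIM"):
            assert f2[invariant_feature] == pytest.approx(f1[invariant_feature], abs=1e-9)
        # variance scales by 4 => LnVar shifts by ln 4
        assert f2["LnVar"] == pytest.approx(f1["LnVar"] + np.log(4.0), abs=1e-6)


class TestInjectionRecovery:
    def test_zero_noise_dips_recovered_exactly(self):
        # quartic-representable base: the quantile fit recovers the true
        # curve, so every injected episode must come back exactly
        cfg = SimConfig(seed=17, noise_sigma=0.0, pert_rate=2.0,
                        missing_rate=0.0, base_curve="quartic")
        rng = np.random.default_rng(17)
        n_checked = 0
        for i in range(15):
            series, truth = simulate_lactation(cfg, f"c{i}", "h", (25.0, 0.2, 0.003), rng)
            curve = fit_expected_curve(series)
            perts = detect_perturbations(expected_residuals(series, curve))
            expected_perts = [p for p in truth.perturbations if p.detectable]
            assert len(perts) == len(expected_perts)
            for got, want in zip(perts, expected_perts):
                assert (got.start_dim, got.end_dim) == (want.start_dim, want.end_dim)
                assert got.deepest_dim == want.deepest_dim
                assert got.severity == want.severity
                assert got.milk_loss == pytest.approx(want.loss_kg, abs=1e-6)
            n_checked += len(expected_perts)
        assert n_checked >= 10  # the scenario actually exercised recovery

    def test_category5_features_match_truth_oracle(self):
        cfg = SimConfig(seed=23, noise_sigma=0.0, pert_rate=2.0,
                        missing_rate=0.0, base_curve="quartic")
        rng = np.random.default_rng(23)
        for i in range(10):
            series, truth = simulate_lactation(cfg, f"c{i}", "h", (24.0, 0.21, 0.0031), rng)
            got = extract_all(series).values
            want = truth_feature_oracle(truth)
            for name, value in want.items():
                assert got[name] == pytest.approx(value, abs=1e-6), name
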