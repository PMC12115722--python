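"""Karickhoff partitioning, DF/AF factors and their regression models."""
import numpy as np
import pandas as pd
import pytest

from ednarisk import (
    TABLE6_DF_MODEL,
    TABLE8_AF_MODEL,
    apply_calibration,
    distribution_factor,
    fit_factor_regression,
    fold_change_range,
    generate_factor_data,
    karickhoff_koc,
    predict_af,
    predict_df,
)
from ednarisk.calibration import soil_water_kd


def test_karickhoff_loglinear():
    assert karickhoff_koc(0.21) == pytest.approx(1.0)
    # BaP literature log Kow 6.04 -> Koc = 10^5.83
    assert karickhoff_koc(6.04) == pytest.approx(10**5.83, rel=1e-12)


def test_karickhoff_proportional():
    assert karickhoff_koc(3.0, variant="proportional") == pytest.approx(411.0)


def test_karickhoff_warns_outside_plausible_range():
    with pytest.warns(UserWarning):
        karickhoff_koc(9.5)


def test_kd_combines_koc_and_organic_carbon():
    # foc = 5/100 * 0.58 = 0.029
    assert soil_water_kd(0.21, som=5.0) == pytest.approx(0.029)
    with pytest.raises(ValueError):
        soil_water_kd(3.0, som=0.0)


def test_distribution_factor_is_a_ratio():
    assert distribution_factor(2.0, 2.0) == 1.0
    # first calibrated/raw endpoint pair of the reference tables
    assert distribution_factor(0.06367, 0.2005) == pytest.approx(3.149, abs=5e-4)
    assert distribution_factor(1.0, 4.0) == 2 * distribution_factor(1.0, 2.0)
    with pytest.raises(ValueError):
        distribution_factor(0.0, 1.0)


def test_df_model_evaluation():
    assert predict_df(TABLE6_DF_MODEL, som=7.0, pahs=10.0) == pytest.approx(2.374, abs=1e-12)
    assert predict_df(TABLE6_DF_MODEL, som=0.0, pahs=0.0) == pytest.approx(9.968)
    # root of the model along the SOM axis
    assert predict_df(TABLE6_DF_MODEL, som=9.968 / 1.132, pahs=0.0) == pytest.approx(0.0, abs=1e-9)


def test_af_model_evaluation():
    assert predict_af(TABLE8_AF_MODEL, som=5.0, ph=8.0, ec=1000.0) == pytest.approx(
        242.518 * 5 + 1256.029 * np.log10(8.0) + 0.024 * 1000 - 1415.447, abs=1e-9
    )
    assert predict_af(TABLE8_AF_MODEL, som=5.0, ph=8.0, ec=1000.0) == pytest.approx(955.44, abs=0.05)
    base = predict_af(TABLE8_AF_MODEL, som=5.0, ph=8.0, ec=1000.0)
    assert predict_af(TABLE8_AF_MODEL, som=5.0, ph=8.0, ec=1100.0) - base == pytest.approx(2.4)
    with pytest.raises(ValueError, match="pH"):
        predict_af(TABLE8_AF_MODEL, som=5.0, ph=0.0, ec=1000.0)


def test_zero_coefficient_model_is_identity_factor():
    from ednarisk.calibration import FactorRegressionModel

    unit = FactorRegressionModel("AF", (("som", 0.0), ("lg_ph", 0.0), ("ec", 0.0)), 1.0)
    assert predict_af(unit, som=9.0, ph=8.5, ec=2000.0) == 1.0


def test_factor_regression_recovers_generating_model():
    table = generate_factor_data(TABLE6_DF_MODEL, n=32, noise_sd=0.0, seed=23)
    fitted = fit_factor_regression(table["DF"], table, terms=["som", "pahs"])
    coefs = dict(fitted.terms)
    assert coefs["som"] == pytest.approx(-1.132, abs=1e-8)
    assert coefs["pahs"] == pytest.approx(0.033, abs=1e-8)
    assert fitted.intercept == pytest.approx(9.968, abs=1e-8)
    assert fitted.r2 == pytest.approx(1.0, abs=1e-10)


def test_af_regression_recovers_generating_model():
    table = generate_factor_data(TABLE8_AF_MODEL, n=32, noise_sd=0.0, seed=29)
    fitted = fit_factor_regression(
        table["AF"], table, terms=["som", "lg_ph", "ec"], response="AF"
    )
    coefs = dict(fitted.terms)
    assert coefs["som"] == pytest.approx(242.518, abs=1e-8)
    assert coefs["lg_ph"] == pytest.approx(1256.029, abs=1e-8)
    assert coefs["ec"] == pytest.approx(0.024, abs=1e-8)
    assert fitted.intercept == pytest.approx(-1415.447, abs=1e-7)


def test_pure_noise_response_has_low_r2():
    low = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        table = generate_factor_data(TABLE6_DF_MODEL, n=32, noise_sd=0.0, seed=seed)
        fitted = fit_factor_regression(
            rng.normal(0, 1, 32), table, terms=["som", "pahs"]
        )
        low += fitted.r2 < 0.3
    assert low >= 17  # expected for 2 predictors at n = 32 in >= 90% of replicates


def test_identity_regression():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 10, 20)
    fitted = fit_factor_regression(x, pd.DataFrame({"x": x}))
    assert dict(fitted.terms)["x"] == pytest.approx(1.0, abs=1e-10)
    assert fitted.intercept == pytest.approx(0.0, abs=1e-9)
    assert fitted.r2 == pytest.approx(1.0)


def test_collinear_terms_raise():
    rng = np.random.default_rng(4)
    x = rng.uniform(0, 10, 20)
    frame = pd.DataFrame({"a": x, "b": 2 * x})
    with pytest.raises(ValueError, match="collinear"):
        fit_factor_regression(x, frame)


def test_apply_calibration_roundtrip_and_metadata():
    values = np.array([1.0, 2.0, 3.0])
    cal = apply_calibration(values, 2.0, stage="DF")
    np.testing.assert_allclose(cal.values, [2.0, 4.0, 6.0])
    assert cal.stage == "DF"
    back = apply_calibration(cal.values, 1 / 2.0)
    np.testing.assert_allclose(back.values, values, atol=1e-12)
    unit = apply_calibration(values, np.ones(3))
    np.testing.assert_allclose(unit.values, values)
    with pytest.raises(ValueError, match="mismatch"):
        apply_calibration(values, np.ones(2))
    with pytest.raises(ValueError):
        apply_calibration(values, np.array([1.0, -1.0, 1.0]))


def test_factors_are_dimensionless():
    rng = np.random.default_rng(8)
    before = rng.uniform(0.1, 10, 17)
    after = before * rng.uniform(2, 8, 17)
    base = fold_change_range(before, after)
    scaled = fold_change_range(1000 * before, 1000 * after)
    assert scaled.min_ratio == pytest.approx(base.min_ratio, rel=1e-12)
    assert scaled.max_ratio == pytest.approx(base.max_ratio, rel=1e-12)


def test_fold_change_ranges_of_reference_tables(table5, table7):
    ident = fold_change_range(table5["ec50_before_mg_kg"], table5["ec50_before_mg_kg"])
    assert (ident.min_ratio, ident.max_ratio) == (1.0, 1.0)
    dist = fold_change_range(table5["ec50_before_mg_kg"], table5["ec50_after_mg_kg"])
    # printed lower bound 2.17 verifies (10.52/4.853); the printed upper
    # bound 7.10 does not: recomputation gives 7.495 (1.580/0.2108)
    assert dist.min_ratio == pytest.approx(2.17, abs=0.005)
    assert dist.max_ratio == pytest.approx(7.495, abs=0.001)
    assert table5["species"][dist.argmin] == "Lysobacter_maris"
    aging = fold_change_range(table5["ec50_before_mg_kg"], table7["ec50_after_mg_kg"])
    assert aging.min_ratio == pytest.approx(3.07209, abs=5e-6)
    assert aging.max_ratio == pytest.approx(14.1436, abs=5e-5)
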