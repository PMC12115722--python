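"""Distribution-factor (DF) and aging-factor (AF) calibration of toxicity data.

PAHs in aged soils are partly sequestered by sorption to organic matter
(distribution/partitioning) and by aging, so toxicity endpoints measured
against nominal concentrations understate the tolerable level.  The
calibration is operationalised as dimensionless per-sample factors:

- DF = calibrated concentration / original concentration, where the
  partitioning side uses the Karickhoff Koc-from-Kow relation and
  Kd = Koc · foc (foc = SOM/100 × 0.58 by the van Bemmelen convention);
- AF = equivalent toxicity after an aging period / original value.

Both factors can also be predicted from soil covariates via fitted linear
models; the published reference models are shipped as
:data:`TABLE6_DF_MODEL` and :data:`TABLE8_AF_MODEL`.  Note the reference
AF model returns values in the hundreds on survey-scale inputs although
observed EC50 fold changes are 3.07-14.14; the discrepancy is inherent to
the printed model and is flagged, not corrected, here.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "karickhoff_koc",
    "soil_water_kd",
    "distribution_factor",
    "FactorRegressionModel",
    "TABLE6_DF_MODEL",
    "TABLE8_AF_MODEL",
    "fit_factor_regression",
    "predict_df",
    "predict_af",
    "apply_calibration",
    "CalibratedSeries",
    "fold_change_range",
    "FoldChangeRange",
]

#: van Bemmelen factor: carbon fraction of soil organic matter.
SOM_CARBON_FRACTION = 0.58


def karickhoff_koc(log_kow: float, variant: str = "loglinear") -> float:
    """Organic-carbon partition coefficient Koc (L/kg) from log Kow.

    loglinear: log10 Koc = log10 Kow - 0.21;  proportional: Koc = 0.411 Kow.
    Values of log Kow outside [0, 8] only warn (PAH log Kow spans ~3.3-7).
    """
    if not 0 <= log_kow <= 8:
        warnings.warn(f"log Kow = {log_kow} outside the plausible range [0, 8]")
    if variant == "loglinear":
        return float(10.0 ** (log_kow - 0.21))
    if variant == "proportional":
        return float(0.411 * 10.0**log_kow)
    raise ValueError(f"unknown Karickhoff variant {variant!r}")


def soil_water_kd(
    log_kow: float,
    som: float,
    carbon_fraction: float = SOM_CARBON_FRACTION,
    variant: str = "loglinear",
) -> float:
    """Soil-water distribution coefficient Kd = Koc · foc (L/kg).

    foc = som/100 × carbon_fraction; som in percent of dry mass.
    """
    foc = som / 100.0 * carbon_fraction
    if not 0 < foc < 1:
        raise ValueError(f"organic-carbon fraction {foc} outside (0, 1)")
    return karickhoff_koc(log_kow, variant) * foc


def distribution_factor(original_conc, calibrated_conc):
    """DF = calibrated / original; both strictly positive (vectorised)."""
    orig = np.asarray(original_conc, dtype=float)
    cal = np.asarray(calibrated_conc, dtype=float)
    if (orig <= 0).any() or (cal <= 0).any():
        raise ValueError("concentrations must be > 0 to form a ratio")
    out = cal / orig
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FactorRegressionModel:
    """A linear factor model: response = intercept + Σ coef·predictor."""

    response: str  # "DF" or "AF"
    terms: tuple[tuple[str, float], ...]
    intercept: float
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.r2 is not None and not 0 <= self.r2 <= 1:
            raise ValueError("R^2 must lie in [0, 1]")

    def predict(self, **covariates: float) -> float:
        value = self.intercept
        for name, coef in self.terms:
            if name not in covariates:
                raise ValueError(f"missing predictor {name!r} for {self.response} model")
            value += coef * float(covariates[name])
        return float(value)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "terms": {name: coef for name, coef in self.terms},
            "intercept": self.intercept,
            "r2": self.r2,
        }


#: Published distribution-factor model: DF = -1.132 SOM + 0.033 PAHs + 9.968 (R^2 0.438).
TABLE6_DF_MODEL = FactorRegressionModel(
    "DF", (("som", -1.132), ("pahs", 0.033)), 9.968, 0.438
)

#: Published aging-factor model:
#: AF = 242.518 SOM + 1256.029 lg(pH) + 0.024 EC - 1415.447 (R^2 0.995).
TABLE8_AF_MODEL = FactorRegressionModel(
    "AF", (("som", 242.518), ("lg_ph", 1256.029), ("ec", 0.024)), -1415.447, 0.995
)


def fit_factor_regression(
    factors,
    predictors: pd.DataFrame,
    terms: list[str] | None = None,
    response: str = "DF",
) -> FactorRegressionModel:
    """OLS fit of per-sample factors on soil covariates (with intercept).

    ``terms`` selects a predictor subset of ``predictors``' columns.  Rank
    deficiency raises, naming the collinear terms.
    """
    y = np.asarray(factors, dtype=float)
    terms = list(terms) if terms is not None else list(predictors.columns)
    X = predictors[terms].astype(float)
    if len(y) <= len(terms) + 1:
        raise ValueError(f"need more than {len(terms) + 1} observations, got {len(y)}")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(f"rank-deficient design; collinear terms among {terms}")
    res = sm.OLS(y, design).fit()
    coefs = tuple((name, float(res.params[name])) for name in terms)
    return FactorRegressionModel(
        response=response,
        terms=coefs,
        intercept=float(res.params["const"]),
        r2=float(min(max(res.rsquared, 0.0), 1.0)),
    )


def predict_df(model: FactorRegressionModel, som: float, pahs: float) -> float:
    """Evaluate a DF model at SOM (%) and ΣPAHs (mg/kg)."""
    if model.response != "DF":
        raise ValueError(f"model response is {model.response!r}, expected 'DF'")
    return model.predict(som=som, pahs=pahs)


def predict_af(model: FactorRegressionModel, som: float, ph: float, ec: float) -> float:
    """Evaluate an AF model at SOM (%), pH and EC (µS/cm); uses lg(pH)."""
    if model.response != "AF":
        raise ValueError(f"model response is {model.response!r}, expected 'AF'")
    if ph <= 0:
        raise ValueError("pH must be > 0 to take its logarithm")
    return model.predict(som=som, lg_ph=np.log10(ph), ec=ec)


@dataclass(frozen=True)
class CalibratedSeries:
    """Calibrated values plus a record of which factor stage produced them."""

    values: np.ndarray
    stage: str


def apply_calibration(values, factors, stage: str = "DF") -> CalibratedSeries:
    """Element-wise multiplication of toxicity data by per-observation factors."""
    v = np.asarray(values, dtype=float)
    f = np.asarray(factors, dtype=float)
    if f.ndim == 0:
        f = np.full_like(v, float(f))
    if v.shape != f.shape:
        raise ValueError(f"length mismatch: {v.shape} values vs {f.shape} factors")
    if (f <= 0).any():
        raise ValueError("calibration factors must be > 0")
    return CalibratedSeries(values=v * f, stage=stage)


@dataclass(frozen=True)
class FoldChangeRange:
    min_ratio: float
    max_ratio: float
    argmin: int
    argmax: int


def fold_change_range(before, after) -> FoldChangeRange:
    """Extremes of element-wise after/before ratios, with their indices."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("before/after vectors must have equal length")
    if (b <= 0).any() or (a <= 0).any():
        raise ValueError("fold changes require strictly positive values")
    ratios = a / b
    return FoldChangeRange(
        min_ratio=float(ratios.min()),
        max_ratio=float(ratios.max()),
        argmin=int(ratios.argmin()),
        argmax=int(ratios.argmax()),
    )
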