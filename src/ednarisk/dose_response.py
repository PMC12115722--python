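"""Logistic dose-response fitting and ECx extraction.

The response model is the three-parameter logistic

    y = y0 / (1 + exp(b * (x - m)))

with y the *relative index* in percent (the control, CK, defines 100%),
x the natural log of the total toxicity concentration (mg/kg), and
m = ln(EC50): at x = m the response is half its asymptote y0.  ECx for
other effect levels follows from the model's symmetry,
ECx = exp(m + ln(x/(100-x)) / b).

Fitting follows the statsmodels model/results split::

    res = DoseResponse(x, y).fit()
    res.ec50, res.params, res.summary()
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datatypes import CommunityProfile

__all__ = [
    "relative_index",
    "DoseResponse",
    "DoseResponseResults",
    "fit_dose_response",
    "batch_ec50",
]


def relative_index(response, ck_response: float) -> np.ndarray:
    """Scale responses to percent of the control (CK = 100%)."""
    if ck_response <= 0:
        raise ValueError(f"CK response must be > 0, got {ck_response}")
    return 100.0 * np.asarray(response, dtype=float) / float(ck_response)


def _logistic(x: np.ndarray, y0: float, b: float, m: float) -> np.ndarray:
    return y0 / (1.0 + np.exp(np.clip(b * (x - m), -700, 700)))


class DoseResponse:
    """Logistic dose-response model of a relative index against ln concentration.

    Parameters
    ----------
    x : array
        Natural log of concentration (ln mg/kg).
    y : array
        Relative index in percent (>= 0); the CK level corresponds to 100.
    x_level : float
        Effect level in percent for the reported ECx (default 50).
    """

    def __init__(self, x, y, x_level: float = 50.0):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if len(self.x) < 4:
            raise ValueError(f"need at least 4 points to fit, got {len(self.x)}")
        if (self.y < 0).any():
            raise ValueError("relative index values must be >= 0")
        if np.ptp(self.y) == 0:
            raise ValueError("degenerate response: all y equal")
        if not 0 < x_level < 100:
            raise ValueError("x_level must be in (0, 100)")
        self.x_level = float(x_level)

    def _starts(self) -> list[np.ndarray]:
        m0 = float(np.median(self.x))
        starts = []
        for y0 in (100.0, float(self.y.max())):
            for b in (0.5, -0.5, 2.0, -2.0):
                starts.append(np.array([y0, b, m0]))
        return starts

    def fit(self) -> "DoseResponseResults":
        """Multi-start Levenberg-Marquardt least squares on (y0, b, m)."""
        best = None
        for start in self._starts():
            try:
                sol = least_squares(
                    lambda th: _logistic(self.x, *th) - self.y,
                    start,
                    method="lm",
                    xtol=1e-12,
                    ftol=1e-12,
                    max_nfev=2000,
                )
            except Exception:
                continue
            if not np.isfinite(sol.fun).all():
                continue
            rss = float(sol.fun @ sol.fun)
            if best is None or rss < best[0]:
                best = (rss, sol)
        if best is None:
            return DoseResponseResults(self, np.full(3, np.nan), np.inf, False)
        rss, sol = best
        converged = bool(sol.success) and np.isfinite(sol.x).all()
        return DoseResponseResults(self, sol.x, rss, converged)


@dataclass
class DoseResponseResults:
    """Fitted (y0, b, m) with derived ECx and diagnostics."""

    model: DoseResponse
    params: np.ndarray = field(repr=False)
    rss: float = np.nan
    converged: bool = False

    @property
    def y0(self) -> float:
        return float(self.params[0])

    @property
    def b(self) -> float:
        return float(self.params[1])

    @property
    def m(self) -> float:
        """Natural log of the EC50 (the curve's inflection point)."""
        return float(self.params[2])

    @property
    def ec50(self) -> float:
        m = self.m
        return float("inf") if m > 700 else float(np.exp(m))

    @property
    def ecx(self) -> float:
        """ECx at the model's effect level (equals ec50 for x_level = 50)."""
        lvl = self.model.x_level
        if lvl == 50.0:
            return self.ec50
        return float(np.exp(self.m + np.log(lvl / (100.0 - lvl)) / self.b))

    def predict(self, x) -> np.ndarray:
        return _logistic(np.asarray(x, dtype=float), *self.params)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": [self.y0, self.b, self.m, self.ec50, self.model.x_level,
                          self.rss, self.converged],
            },
            index=["y0 (%)", "b", "m = ln EC50", "EC50 (mg/kg)", "x_level (%)",
                   "rss", "converged"],
        )


def fit_dose_response(x, y, x_level: float = 50.0) -> DoseResponseResults:
    """Functional wrapper: ``DoseResponse(x, y, x_level).fit()``."""
    return DoseResponse(x, y, x_level=x_level).fit()


def batch_ec50(
    profile: CommunityProfile,
    toxicity,
    taxa: list[str] | None = None,
    ck_sample: str | None = None,
    x_level: float = 50.0,
) -> list[tuple[str, DoseResponseResults | None]]:
    """Per-taxon dose-response fits of relative abundance against ln toxicity.

    ``toxicity`` is the per-sample total toxicity (mg/kg, aligned with
    ``profile.samples``); the control CK is the sample with the lowest
    toxicity unless ``ck_sample`` designates one explicitly.  Samples with
    non-positive toxicity are dropped before taking logs (they can only
    serve as CK).  Taxa whose fit fails are reported with ``None`` or a
    non-converged result, never silently dropped.
    """
    tox = np.asarray(toxicity, dtype=float)
    if len(tox) != len(profile.samples):
        raise ValueError("toxicity vector does not match profile samples")
    if ck_sample is None:
        if not np.isfinite(tox).any():
            raise ValueError("no CK sample identifiable; designate ck_sample explicitly")
        ck_idx = int(np.nanargmin(tox))
    else:
        if ck_sample not in profile.samples:
            raise ValueError(f"CK sample {ck_sample!r} not in profile")
        ck_idx = profile.samples.index(ck_sample)
    keep = tox > 0
    x = np.log(tox[keep])
    results: list[tuple[str, DoseResponseResults | None]] = []
    for taxon in taxa if taxa is not None else profile.taxa:
        row = profile.abundance.loc[taxon].to_numpy(dtype=float)
        ck_abund = row[ck_idx]
        if ck_abund <= 0:
            results.append((taxon, None))
            continue
        y = relative_index(row[keep], ck_abund)
        try:
            fit = DoseResponse(x, y, x_level=x_level).fit()
        except ValueError:
            results.append((taxon, None))
            continue
        results.append((taxon, fit))
    return results


def batch_to_frame(results: list[tuple[str, DoseResponseResults | None]]) -> pd.DataFrame:
    """CSV-ready table: taxon, y0, b, m, ec50, rss, converged."""
    rows = []
    for taxon, fit in results:
        if fit is None:
            rows.append({"taxon": taxon, "y0": np.nan, "b": np.nan, "m": np.nan,
                         "ec50": np.nan, "rss": np.nan, "converged": False})
        else:
            rows.append({"taxon": taxon, "y0": fit.y0, "b": fit.b, "m": fit.m,
                         "ec50": fit.ec50, "rss": fit.rss, "converged": fit.converged})
    return pd.DataFrame(rows)
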