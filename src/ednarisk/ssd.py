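"""Species sensitivity distributions (SSD) and hazardous concentrations.

An SSD is a cumulative distribution fitted to ranked per-species toxicity
endpoints (EC50s).  Location-scale models (normal, logistic) are fitted on
log10-transformed concentrations — i.e. log-normal and log-logistic SSDs,
the universal ecotoxicology convention — while the Burr III model works on
the concentration scale directly.  The hazardous concentration HCq is the
fitted model's q-quantile back-transformed to mg/kg; HC5 (q = 0.05) is the
protective threshold for 95% of species.

Two fitting objectives are available:

- ``method="ls"`` (default): nonlinear least squares of the model CDF
  against rank-based plotting positions.
- ``method="mle"``: maximum likelihood (normal: sample mean/SD with
  ddof=1 of log10 EC50; logistic: numerical ML).  RMSE is evaluated
  against the plotting positions in both cases, so RMSE-based model
  selection is available regardless of objective.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.special import expit, logit

__all__ = [
    "plotting_positions",
    "SSD",
    "SSDResults",
    "fit_ssd",
    "select_model",
    "hc_burr3",
    "MODEL_ORDER",
]

MODEL_ORDER = ("normal", "logistic", "burr3")


def plotting_positions(n: int, scheme: str = "weibull") -> np.ndarray:
    """Rank-based empirical cumulative probabilities for n sorted endpoints.

    weibull: i/(n+1); hazen: (i - 0.5)/n, for i = 1..n.
    """
    if n < 2:
        raise ValueError(f"need at least 2 species, got {n}")
    i = np.arange(1, n + 1, dtype=float)
    if scheme == "weibull":
        return i / (n + 1)
    if scheme == "hazen":
        return (i - 0.5) / n
    raise ValueError(f"unknown plotting-position scheme: {scheme!r}")


def hc_burr3(b: float, k: float, c: float, q: float) -> float:
    """Burr III quantile: HCq = b * (q^(-1/k) - 1)^(-1/c).

    The Burr III CDF is F(x) = (1 + (x/b)^-c)^-k; this inverts it at q.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if min(b, k, c) <= 0:
        raise ValueError("Burr III parameters must be > 0")
    return float(b * (q ** (-1.0 / k) - 1.0) ** (-1.0 / c))


class SSD:
    """SSD model over a vector of positive toxicity endpoints (mg/kg)."""

    def __init__(
        self,
        ec50s,
        dist: str = "normal",
        scheme: str = "weibull",
        min_n: int = 5,
    ):
        x = np.asarray(ec50s, dtype=float)
        if (x <= 0).any() or not np.isfinite(x).all():
            raise ValueError("all toxicity endpoints must be positive and finite")
        if len(x) < min_n:
            raise ValueError(
                f"need at least {min_n} endpoints for SSD fitting, got {len(x)}"
            )
        if dist not in MODEL_ORDER:
            raise ValueError(f"unknown SSD model {dist!r}; choose from {MODEL_ORDER}")
        self.ec50s = np.sort(x)
        self.dist = dist
        self.scheme = scheme
        self.positions = plotting_positions(len(x), scheme)

    # CDF on the concentration scale, parameterised per model
    def _cdf(self, conc: np.ndarray, params: np.ndarray) -> np.ndarray:
        z = np.log10(conc)
        if self.dist == "normal":
            mu, sigma = params
            return stats.norm.cdf(z, mu, sigma)
        if self.dist == "logistic":
            alpha, s = params
            return expit((z - alpha) / s)
        b, k, c = params
        return (1.0 + (conc / b) ** (-c)) ** (-k)

    def _quantile(self, q: float, params: np.ndarray) -> float:
        if self.dist == "normal":
            mu, sigma = params
            return float(10 ** (mu + sigma * stats.norm.ppf(q)))
        if self.dist == "logistic":
            alpha, s = params
            return float(10 ** (alpha + s * logit(q)))
        return hc_burr3(*params, q)

    def _start(self) -> np.ndarray:
        z = np.log10(self.ec50s)
        if self.dist == "normal":
            return np.array([z.mean(), max(z.std(), 1e-6)])
        if self.dist == "logistic":
            return np.array([np.median(z), max(z.std() * np.sqrt(3) / np.pi, 1e-6)])
        return np.array([np.median(self.ec50s), 1.0, 1.0])

    def fit(self, method: str = "ls") -> "SSDResults":
        """Fit the CDF; see the module docstring for the two objectives."""
        z = np.log10(self.ec50s)
        if method == "mle":
            if self.dist == "normal":
                params = np.array([z.mean(), z.std(ddof=1)])
            elif self.dist == "logistic":
                # fit in standardized coordinates for exact scale equivariance
                zbar, zsd = z.mean(), z.std()
                zsd = zsd if zsd > 0 else 1.0
                alpha_u, s_u = stats.logistic.fit((z - zbar) / zsd)
                params = np.array([zbar + zsd * alpha_u, zsd * s_u])
            else:
                raise NotImplementedError("MLE is not implemented for the Burr III model")
        elif method == "ls":
            if self.dist in ("normal", "logistic"):
                # fit in standardized log10 coordinates: concentration
                # rescaling then leaves the optimization problem identical,
                # making HCq scale-equivariant by construction
                zbar, zsd = z.mean(), z.std()
                zsd = zsd if zsd > 0 else 1.0
                u = (z - zbar) / zsd
                base = stats.norm if self.dist == "normal" else stats.logistic
                start = self._start()
                th0 = np.array([(start[0] - zbar) / zsd, np.log(start[1] / zsd)])
                residual = lambda th: base.cdf(u, th[0], np.exp(th[1])) - self.positions

                def jac(th):
                    s = np.exp(th[1])
                    w = (u - th[0]) / s
                    dens = base.pdf(w)
                    # columns: d/d loc, d/d log(scale)
                    return np.column_stack([-dens / s, -dens * w])

                sol = least_squares(residual, th0, jac=jac,
                                    xtol=1e-15, ftol=1e-15, gtol=1e-15)
                # Gauss-Newton polish to the exact stationary point J'r = 0;
                # the optimizer's stopping rules leave ~1e-9 of gradient
                th = sol.x
                for _ in range(100):
                    J = jac(th)
                    step = np.linalg.lstsq(J, -residual(th), rcond=None)[0]
                    th = th + step
                    if np.abs(step).max() < 1e-14:
                        break
                params = np.array([zbar + zsd * th[0], zsd * np.exp(th[1])])
            else:
                # Burr III: positivity enforced via log-reparameterisation
                pack = lambda th: np.exp(th)
                th0 = np.log(self._start())
                residual = lambda th: self._cdf(self.ec50s, pack(th)) - self.positions
                sol = least_squares(residual, th0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
                sol = least_squares(residual, sol.x, xtol=1e-15, ftol=1e-15, gtol=1e-15)
                params = pack(sol.x)
        else:
            raise ValueError(f"unknown fitting method {method!r}")
        resid = self._cdf(self.ec50s, params) - self.positions
        rmse = float(np.sqrt(np.mean(resid**2)))
        return SSDResults(self, params, rmse, method)


@dataclass
class SSDResults:
    """Fitted SSD with its RMSE (probability scale) and HCq accessors."""

    model: SSD
    params: np.ndarray = field(repr=False)
    rmse: float = np.nan
    method: str = "ls"

    @property
    def dist(self) -> str:
        return self.model.dist

    @property
    def n_species(self) -> int:
        return len(self.model.ec50s)

    @property
    def plotting_positions(self) -> np.ndarray:
        return self.model.positions

    def hcq(self, q: float) -> float:
        """Hazardous concentration affecting a fraction q of species (mg/kg)."""
        if not 0 < q < 1:
            raise ValueError("q must be in (0, 1)")
        return self.model._quantile(q, self.params)

    @property
    def hc5(self) -> float:
        return self.hcq(0.05)

    @property
    def median(self) -> float:
        return self.hcq(0.5)

    def cdf(self, conc) -> np.ndarray:
        return self.model._cdf(np.asarray(conc, dtype=float), self.params)

    def param_dict(self) -> dict[str, float]:
        names = {
            "normal": ("mu", "sigma"),
            "logistic": ("alpha", "s"),
            "burr3": ("b", "k", "c"),
        }[self.dist]
        return dict(zip(names, map(float, self.params)))

    def curve_frame(self) -> pd.DataFrame:
        """(rank, log10 EC50, plotting position, fitted CDF) for plotting."""
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.n_species + 1),
                "log10_ec50": np.log10(self.model.ec50s),
                "plotting_position": self.plotting_positions,
                "fitted_cdf": self.cdf(self.model.ec50s),
            }
        )

    def summary(self) -> pd.DataFrame:
        rows = dict(self.param_dict())
        rows.update({"rmse": self.rmse, "hc5": self.hc5, "n_species": self.n_species,
                     "model": self.dist, "method": self.method})
        return pd.DataFrame({"value": list(rows.values())}, index=list(rows.keys()))


def fit_ssd(
    ec50s,
    model: str = "normal",
    scheme: str = "weibull",
    method: str = "ls",
    min_n: int = 5,
) -> SSDResults:
    """Functional wrapper: ``SSD(ec50s, model, scheme).fit(method)``."""
    return SSD(ec50s, dist=model, scheme=scheme, min_n=min_n).fit(method=method)


def select_model(fits: list[SSDResults]) -> SSDResults:
    """Minimum-RMSE model; ties broken by model order (normal, logistic, burr3)."""
    if not fits:
        raise ValueError("no fitted models to select from")
    return min(fits, key=lambda f: (f.rmse, MODEL_ORDER.index(f.dist)))
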