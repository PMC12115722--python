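"""Synthetic soil surveys and communities with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
~32-sample oilfield survey whose covariates span the published ranges
(pH 7.9-8.9, EC 700-4800 µS/cm, SOM 3.7-11.7%, TPH up to 588 mg/kg,
ΣTEQ_BaP ~0.003-1.1 mg/kg), and a few-hundred-taxon community in which a
planted subset of taxa responds to ln ΣTEQ through the same logistic
dose-response the estimator fits, with EC50s drawn from a log10-normal
species sensitivity distribution.  Half the responders are planted with a
decreasing response (sensitive), half increasing (tolerant).  Noise is
multiplicative lognormal and columns are renormalised afterwards, so the
planted curves are mildly distorted by compositionality, as real
relative-abundance data would be.

All randomness flows from the single integer seed of the spec.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import EPA16, CommunityProfile, SoilSample, TefTable
from .teq import teq_series

__all__ = ["SyntheticSpec", "generate_samples", "generate_community", "generate_factor_data"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Stated world of the generator; defaults mirror the published survey."""

    n_samples: int = 32
    n_taxa: int = 200
    n_responders: int = 17
    ssd_mu: float = -1.0  # log10 mg/kg: planted EC50s centred near 0.1
    ssd_sigma: float = 0.5
    noise_sd: float = 0.1  # sd of log abundance noise (~10% relative)
    teq_range: tuple[float, float] = (0.003, 1.1)
    # mean congener mass weights by ring class: petroleum PAH profiles are
    # dominated by 2-3-ring congeners, with 4-ring intermediate and 5-6-ring
    # minor (weights 8/4/1 over the EPA16 order)
    congener_weights: tuple[float, ...] = (8.0,) * 6 + (4.0,) * 4 + (1.0,) * 6
    ranges: dict = field(
        default_factory=lambda: {
            "ph": (7.9, 8.9),
            "ec": (700.0, 4800.0),
            "som": (3.7, 11.7),
            "tph": (0.0, 588.0),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders > self.n_taxa:
            raise ValueError("n_responders cannot exceed n_taxa")
        for name, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"range for {name!r} is not ordered: {(lo, hi)}")
        if self.teq_range[0] <= 0 or self.teq_range[0] > self.teq_range[1]:
            raise ValueError("teq_range must be positive and ordered")
        if len(self.congener_weights) != 16 or min(self.congener_weights) <= 0:
            raise ValueError("congener_weights must be 16 positive values")


def _uniform(rng, lo, hi, n):
    return np.full(n, lo) if lo == hi else rng.uniform(lo, hi, n)


def _log_uniform(rng, lo, hi, n):
    if lo == hi:
        return np.full(n, lo)
    lo_eff = lo if lo > 0 else hi * 1e-3  # log scale needs a positive floor
    return np.exp(rng.uniform(np.log(lo_eff), np.log(hi), n))


def generate_samples(spec: SyntheticSpec, tefs: TefTable | None = None) -> list[SoilSample]:
    """Draw a covariate table plus 16-congener PAH vectors.

    pH and SOM are uniform, EC and TPH log-uniform within the configured
    ranges.  Per-sample ΣTEQ targets are drawn log-uniformly over
    ``teq_range`` and distributed over congeners with lognormally jittered
    mixture weights, so Σ c_i·TEF_i reproduces the target exactly.
    """
    tefs = tefs or TefTable.default()
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_samples
    ph = _uniform(rng, *spec.ranges["ph"], n)
    som = _uniform(rng, *spec.ranges["som"], n)
    ec = _log_uniform(rng, *spec.ranges["ec"], n)
    tph = _log_uniform(rng, *spec.ranges["tph"], n)
    teq_target = _log_uniform(rng, *spec.teq_range, n)
    tef_vec = tefs.vector
    base_weights = np.asarray(spec.congener_weights, dtype=float)
    samples = []
    for i in range(n):
        weights = base_weights * rng.lognormal(mean=0.0, sigma=1.0, size=len(EPA16))
        conc = teq_target[i] * weights / float(weights @ tef_vec)
        samples.append(
            SoilSample(
                sample_id=f"S{i + 1:03d}",
                ph=float(ph[i]),
                ec=float(ec[i]),
                som=float(som[i]),
                tph=float(tph[i]),
                pah=dict(zip(EPA16, conc.tolist())),
            )
        )
    return samples


def generate_community(
    spec: SyntheticSpec,
    samples: list[SoilSample],
    tefs: TefTable | None = None,
) -> tuple[CommunityProfile, pd.DataFrame]:
    """Community matrix with planted logistic responders and its ground truth.

    Responder i follows w_i / (1 + exp(b_i (x - ln EC50_i))) in x = ln ΣTEQ,
    with EC50_i ~ 10^Normal(ssd_mu, ssd_sigma) and alternating slope sign
    (b > 0 decreasing = sensitive, b < 0 increasing = tolerant).
    Non-responders have stressor-independent means.  Lognormal noise of
    scale ``noise_sd`` is injected before column renormalisation.

    Returns the profile and a ground-truth table with each taxon's
    responder flag, true EC50, slope b and slope sign.
    """
    if not samples:
        raise ValueError("samples must be non-empty")
    rng = np.random.default_rng([spec.seed, 1])
    teq = np.array([t.teq_bap for t in teq_series(samples, tefs)])
    x = np.log(teq)
    taxa = [f"taxon_{i + 1:04d}" for i in range(spec.n_taxa)]
    responder = np.zeros(spec.n_taxa, dtype=bool)
    responder[: spec.n_responders] = True
    ec50 = np.full(spec.n_taxa, np.nan)
    slope = np.full(spec.n_taxa, np.nan)
    ec50[responder] = 10 ** rng.normal(spec.ssd_mu, spec.ssd_sigma, spec.n_responders)
    signs = np.where(np.arange(spec.n_responders) % 2 == 0, 1.0, -1.0)
    slope[responder] = signs * rng.uniform(1.0, 3.0, spec.n_responders)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_taxa)
    mat = np.empty((spec.n_taxa, len(samples)))
    for i in range(spec.n_taxa):
        if responder[i]:
            mat[i] = base[i] / (1.0 + np.exp(slope[i] * (x - np.log(ec50[i]))))
        else:
            mat[i] = base[i]
    mat *= rng.lognormal(mean=0.0, sigma=spec.noise_sd, size=mat.shape)
    mat /= mat.sum(axis=0, keepdims=True)
    profile = CommunityProfile(
        pd.DataFrame(mat, index=taxa, columns=[s.sample_id for s in samples])
    )
    truth = pd.DataFrame(
        {
            "taxon": taxa,
            "responder": responder,
            "ec50": ec50,
            "b": slope,
            "slope_sign": np.sign(-slope),  # abundance slope vs stressor
        }
    )
    return profile, truth


def generate_factor_data(
    model,
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Covariate table plus a factor response generated from a linear model.

    Covariates are drawn within the survey ranges (SOM 3.7-11.7%,
    pH 7.9-8.9, EC 700-4800 µS/cm, ΣPAHs 0.68-135 mg/kg; lg_ph derived).
    The response column is ``model.predict(...) + Normal(0, noise_sd)``.
    """
    if n <= len(model.terms) + 1:
        raise ValueError("n must exceed the number of terms + 1")
    rng = np.random.default_rng([seed, 2])
    table = pd.DataFrame(
        {
            "som": rng.uniform(3.7, 11.7, n),
            "ph": rng.uniform(7.9, 8.9, n),
            "ec": np.exp(rng.uniform(np.log(700.0), np.log(4800.0), n)),
            "pahs": np.exp(rng.uniform(np.log(0.68), np.log(135.0), n)),
        }
    )
    table["lg_ph"] = np.log10(table["ph"])
    response = np.array(
        [model.predict(**{name: row[name] for name, _ in model.terms})
         for _, row in table.iterrows()]
    )
    table[model.response] = response + rng.normal(0.0, noise_sd, n)
    return table
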