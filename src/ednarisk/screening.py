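"""Sensitive/tolerant species screening and key-stressor identification.

Each taxon's relative abundance is regressed on a stressor level by
ordinary least squares.  A taxon is called *tolerant* when the slope is
positive and significant at ``alpha`` (default 0.1, two-sided t-test on
the slope), *sensitive* when the slope is negative and significant, and
*unclassified* otherwise.  No multiple-testing correction is applied by
default, matching the per-taxon screening convention; Benjamini-Hochberg
is available as an opt-in.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import AlignmentError, CommunityProfile, SoilSample
from .teq import TeqResult

__all__ = [
    "RegressionResult",
    "SpeciesCall",
    "fit_simple_regression",
    "screen_species",
    "identify_key_stressors",
    "DegenerateDesignError",
    "InsufficientDataError",
]


class DegenerateDesignError(ValueError):
    """The stressor vector is constant; the OLS slope is undefined."""


class InsufficientDataError(ValueError):
    """Fewer than three paired observations."""


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class SpeciesCall:
    taxon: str
    stressor: str
    call: str  # sensitive | tolerant | unclassified
    regression: RegressionResult | None


def fit_simple_regression(x, y) -> RegressionResult:
    """OLS line of y on x; p from the two-sided t-test on the slope.

    A flat response (constant y) is reported as slope 0, r = 0, p = 1 by
    convention rather than as an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("stressor vector is constant")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, n)
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=n,
    )


def screen_species(
    profile: CommunityProfile,
    stressor,
    alpha: float = 0.1,
    stressor_name: str = "stressor",
    min_present: int = 3,
    bh_correct: bool = False,
) -> list[SpeciesCall]:
    """Classify every taxon of a community as sensitive/tolerant/unclassified.

    ``stressor`` is a per-sample vector: a mapping/Series keyed by sample id
    or a plain sequence aligned with ``profile.samples``.  Taxa present
    (abundance > 0) in fewer than ``min_present`` samples are auto-unclassified.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if isinstance(stressor, (dict, pd.Series)):
        s = pd.Series(stressor)
        missing = [sid for sid in profile.samples if sid not in s.index]
        if missing:
            raise AlignmentError(f"stressor values missing for samples: {missing}")
        x = s.loc[profile.samples].to_numpy(dtype=float)
    else:
        x = np.asarray(stressor, dtype=float)
        if len(x) != len(profile.samples):
            raise AlignmentError(
                f"stressor length {len(x)} != {len(profile.samples)} samples"
            )
    calls: list[SpeciesCall] = []
    fits: list[RegressionResult | None] = []
    for taxon in profile.taxa:
        y = profile.abundance.loc[taxon].to_numpy(dtype=float)
        if int((y > 0).sum()) < min_present:
            fits.append(None)
            continue
        fits.append(fit_simple_regression(x, y))
    pvals = np.array([f.p_value if f is not None else np.nan for f in fits])
    if bh_correct:
        finite = np.isfinite(pvals)
        adjusted = pvals.copy()
        if finite.any():
            adjusted[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
        pvals = adjusted
    for taxon, fit, p in zip(profile.taxa, fits, pvals):
        if fit is None:
            call = "unclassified"
        elif p < alpha and fit.slope > 0:
            call = "tolerant"
        elif p < alpha and fit.slope < 0:
            call = "sensitive"
        else:
            call = "unclassified"
        calls.append(SpeciesCall(taxon, stressor_name, call, fit))
    return calls


def calls_to_frame(calls: list[SpeciesCall]) -> pd.DataFrame:
    """Tabular view of screening calls (taxon, stressor, slope, r, p, call)."""
    return pd.DataFrame(
        {
            "taxon": [c.taxon for c in calls],
            "stressor": [c.stressor for c in calls],
            "slope": [c.regression.slope if c.regression else np.nan for c in calls],
            "r": [c.regression.r if c.regression else np.nan for c in calls],
            "p": [c.regression.p_value if c.regression else np.nan for c in calls],
            "call": [c.call for c in calls],
        }
    )


def identify_key_stressors(
    samples: list[SoilSample],
    teq: list[TeqResult],
    otu_counts,
    alpha: float = 0.05,
) -> list[tuple[str, RegressionResult]]:
    """Regress community richness on each candidate stressor.

    Candidates are pH, EC, SOM, TPH and ΣTEQ_BaP; stressors significant at
    ``alpha`` are returned sorted by p-value.  Samples with missing values
    for a given stressor are excluded pairwise.
    """
    if len(teq) != len(samples):
        raise AlignmentError("teq list does not match samples")
    y = np.asarray(otu_counts, dtype=float)
    if len(y) != len(samples):
        raise AlignmentError("otu_counts does not match samples")
    candidates = {
        "pH": np.array([s.ph for s in samples], dtype=float),
        "EC": np.array([s.ec for s in samples], dtype=float),
        "SOM": np.array([s.som for s in samples], dtype=float),
        "TPH": np.array([np.nan if s.tph is None else s.tph for s in samples]),
        "TEQ": np.array([t.teq_bap for t in teq], dtype=float),
    }
    hits = []
    for name, x in candidates.items():
        try:
            fit = fit_simple_regression(x, y)
        except (DegenerateDesignError, InsufficientDataError):
            continue  # constant or mostly-missing stressor: nothing to test
        if fit.p_value < alpha:
            hits.append((name, fit))
    hits.sort(key=lambda item: item[1].p_value)
    return hits
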