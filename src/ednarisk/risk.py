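"""Risk quotients, ecological risk levels, and comparison pollution indices.

The risk quotient divides a soil concentration (here ΣTEQ_BaP) by a
negligible-concentration standard (NCs) and a maximum-permissible standard
(MPCs): RQ_NCs = c/C_QV(NCs), RQ_MPCs = c/C_QV(MPCs).  The pair maps to an
ordinal risk level via a two-condition decision table; the region where
both quotients are below 1 is assigned an explicit level 0 ("negligible").

The comparison indices are the single-factor pollution index
PI = c/standard, the geoaccumulation index Igeo = log2(c/(k·background)),
and the Nemerow integrated index NIPI = sqrt((mean(PI)^2 + max(PI)^2)/2),
each with configurable grading breakpoints.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .teq import TeqResult

__all__ = [
    "risk_quotients",
    "classify_risk",
    "pollution_index",
    "igeo",
    "nipi",
    "RiskStandards",
    "RiskResult",
    "assess_samples",
    "results_to_frame",
]


def risk_quotients(ci, cqv_ncs: float, cqv_mpcs: float):
    """(RQ_NCs, RQ_MPCs) for a concentration or vector of concentrations.

    For 16-congener assessments, per-congener quotients are simply summed
    (RQ_Σ16 = Σ_i RQ_i), which this vectorised form supports directly.
    """
    if cqv_ncs <= 0 or cqv_mpcs <= 0:
        raise ValueError("risk standards must be > 0")
    if cqv_ncs >= cqv_mpcs:
        raise ValueError("C_QV(NCs) must be below C_QV(MPCs)")
    c = np.asarray(ci, dtype=float)
    if (c < 0).any():
        raise ValueError("concentrations must be >= 0")
    rq_ncs = c / cqv_ncs
    rq_mpcs = c / cqv_mpcs
    if rq_ncs.ndim == 0:
        return float(rq_ncs), float(rq_mpcs)
    return rq_ncs, rq_mpcs


def classify_risk(rq_ncs: float, rq_mpcs: float) -> int:
    """Two-condition decision table mapping (RQ_NCs, RQ_MPCs) to a level 0-4.

    level 1: RQ_NCs in [1, 800) and RQ_MPCs < 1
    level 2: RQ_NCs >= 800     and RQ_MPCs < 1
    level 3: RQ_NCs < 800      and RQ_MPCs >= 1
    level 4: RQ_NCs >= 800     and RQ_MPCs >= 1
    level 0: both quotients below 1 (negligible; explicit extension of the
    published table, which leaves this region undefined).  Boundaries are
    taken literally: a quotient exactly 1 falls in the ">= 1" rows.
    """
    if rq_ncs < 0 or rq_mpcs < 0:
        raise ValueError("risk quotients must be >= 0")
    if rq_mpcs >= 1:
        return 4 if rq_ncs >= 800 else 3
    if rq_ncs >= 800:
        return 2
    if rq_ncs >= 1:
        return 1
    return 0


#: Default PI grading: <=1 clean/slight, (1,2] light, (2,3] moderate, >3 heavy.
PI_BREAKPOINTS: tuple[tuple[float, int], ...] = ((1.0, 2), (2.0, 3), (3.0, 4))
PI_TOP_GRADE = 5

#: Default Igeo grading: standard 7 classes, <=0 unpolluted ... >5 extreme.
IGEO_BREAKPOINTS: tuple[tuple[float, int], ...] = (
    (0.0, 0), (1.0, 1), (2.0, 2), (3.0, 3), (4.0, 4), (5.0, 5),
)
IGEO_TOP_GRADE = 6

#: Default NIPI grading: <=0.7 safe ... >3 heavy (grades 1-5).
NIPI_BREAKPOINTS: tuple[tuple[float, int], ...] = ((0.7, 1), (1.0, 2), (2.0, 3), (3.0, 4))
NIPI_TOP_GRADE = 5


def _grade(value: float, breakpoints, top_grade: int) -> int:
    for limit, grade in breakpoints:
        if value <= limit:
            return grade
    return top_grade


def pollution_index(
    ci: float,
    standard: float,
    breakpoints=PI_BREAKPOINTS,
    top_grade: int = PI_TOP_GRADE,
) -> tuple[float, int]:
    """Single-factor pollution index PI = ci/standard with its ordinal grade."""
    if standard <= 0:
        raise ValueError("standard must be > 0")
    if ci < 0:
        raise ValueError("concentration must be >= 0")
    pi = ci / standard
    return float(pi), _grade(pi, breakpoints, top_grade)


def igeo(
    ci: float,
    background: float,
    k: float = 1.5,
    breakpoints=IGEO_BREAKPOINTS,
    top_grade: int = IGEO_TOP_GRADE,
) -> tuple[float, int]:
    """Geoaccumulation index log2(ci/(k·background)) with its grade.

    k absorbs natural background fluctuation (default 1.5).
    """
    if ci <= 0 or background <= 0 or k <= 0:
        raise ValueError("ci, background and k must be > 0")
    value = float(np.log2(ci / (k * background)))
    return value, _grade(value, breakpoints, top_grade)


def nipi(
    pis,
    breakpoints=NIPI_BREAKPOINTS,
    top_grade: int = NIPI_TOP_GRADE,
) -> tuple[float, int]:
    """Nemerow integrated index sqrt((mean^2 + max^2)/2) over single-factor PIs."""
    p = np.asarray(pis, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one pollution index")
    if (p < 0).any():
        raise ValueError("pollution indices must be >= 0")
    value = float(np.sqrt((p.mean() ** 2 + p.max() ** 2) / 2.0))
    return value, _grade(value, breakpoints, top_grade)


@dataclass(frozen=True)
class RiskStandards:
    """Assessment configuration: standards, background and breakpoints."""

    cqv_ncs: float = 0.0028  # mg/kg, negligible-concentration standard
    cqv_mpcs: float = 0.1956  # mg/kg; typically the pipeline's calibrated HC5
    background: float | None = None  # mg/kg, Igeo background (no default)
    k: float = 1.5
    pi_standard: float | None = None  # defaults to cqv_mpcs

    def __post_init__(self) -> None:
        if self.cqv_ncs <= 0 or self.cqv_mpcs <= 0:
            raise ValueError("risk standards must be > 0")
        if self.cqv_ncs >= self.cqv_mpcs:
            raise ValueError("C_QV(NCs) must be below C_QV(MPCs)")


@dataclass(frozen=True)
class RiskResult:
    sample_id: str
    teq: float
    rq_ncs: float
    rq_mpcs: float
    level: int
    pi: float | None = None
    pi_grade: int | None = None
    igeo: float | None = None
    igeo_grade: int | None = None
    nipi: float | None = None
    nipi_grade: int | None = None
    warnings: tuple[str, ...] = field(default_factory=tuple)


def assess_samples(
    teq_results: list[TeqResult],
    standards: RiskStandards,
) -> list[RiskResult]:
    """Per-sample risk assessment from ΣTEQ_BaP values.

    PI uses ``pi_standard`` (default: the MPCs standard).  Igeo is computed
    only when a background value is configured.  NIPI integrates the
    per-congener PIs when congener contributions are present, and otherwise
    degenerates to the single ΣTEQ PI (mean = max).
    """
    out = []
    pi_standard = standards.pi_standard or standards.cqv_mpcs
    for res in teq_results:
        notes: list[str] = []
        rq_n, rq_m = risk_quotients(res.teq_bap, standards.cqv_ncs, standards.cqv_mpcs)
        level = classify_risk(rq_n, rq_m)
        if res.teq_bap == 0:
            notes.append("zero TEQ: level 0 by construction")
        pi, pi_grade = pollution_index(res.teq_bap, pi_standard)
        if res.per_congener is not None and any(v > 0 for v in res.per_congener.values()):
            congener_pis = [v / pi_standard for v in res.per_congener.values()]
            nipi_val, nipi_grade = nipi(congener_pis)
        else:
            nipi_val, nipi_grade = nipi([pi])
        if standards.background is not None and res.teq_bap > 0:
            igeo_val, igeo_grade = igeo(res.teq_bap, standards.background, standards.k)
        else:
            igeo_val = igeo_grade = None
            if standards.background is None:
                notes.append("no background configured: Igeo skipped")
        out.append(
            RiskResult(
                sample_id=res.sample_id,
                teq=res.teq_bap,
                rq_ncs=rq_n,
                rq_mpcs=rq_m,
                level=level,
                pi=pi,
                pi_grade=pi_grade,
                igeo=igeo_val,
                igeo_grade=igeo_grade,
                nipi=nipi_val,
                nipi_grade=nipi_grade,
                warnings=tuple(notes),
            )
        )
    return out


def results_to_frame(results: list[RiskResult]) -> pd.DataFrame:
    """CSV-ready per-sample risk table."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "teq_bap": [r.teq for r in results],
            "rq_ncs": [r.rq_ncs for r in results],
            "rq_mpcs": [r.rq_mpcs for r in results],
            "level": [r.level for r in results],
            "pi": [r.pi for r in results],
            "pi_grade": [r.pi_grade for r in results],
            "igeo": [r.igeo for r in results],
            "igeo_grade": [r.igeo_grade for r in results],
            "nipi": [r.nipi for r in results],
            "nipi_grade": [r.nipi_grade for r in results],
        }
    )
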