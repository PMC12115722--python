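"""BaP toxic-equivalent (TEQ) conversion of 16-congener PAH vectors.

The total toxicity of a PAH mixture is expressed as benzo[a]pyrene
equivalents, ΣTEQ_BaP = Σ_i c_i · TEF_i, a strictly additive weighting of
congener concentrations by their potency relative to BaP (TEF_BaP = 1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import EPA16, SoilSample, TefTable

__all__ = ["TeqResult", "compute_teq", "teq_series"]


@dataclass(frozen=True)
class TeqResult:
    """ΣTEQ_BaP of one sample with its per-congener contributions (mg/kg).

    ``as_reported`` marks results carried over from a published ΣTEQ column
    because congener-level data were unavailable for the sample.
    """

    sample_id: str
    teq_bap: float
    per_congener: dict[str, float] | None = None
    as_reported: bool = False

    def __post_init__(self) -> None:
        if self.teq_bap < 0:
            raise ValueError(f"{self.sample_id}: negative TEQ")
        if self.per_congener is not None:
            total = float(sum(self.per_congener.values()))
            if abs(total - self.teq_bap) > 1e-9 * max(1.0, abs(total)):
                raise ValueError(f"{self.sample_id}: contributions do not sum to TEQ")


def compute_teq(sample: SoilSample, tefs: TefTable | None = None) -> TeqResult:
    """ΣTEQ_BaP = Σ_i c_i·TEF_i for one sample with a complete PAH vector."""
    tefs = tefs or TefTable.default()
    conc = sample.pah_vector
    contributions = conc * tefs.vector  # raises SchemaError on missing congener
    return TeqResult(
        sample_id=sample.sample_id,
        teq_bap=float(contributions.sum()),
        per_congener=dict(zip(EPA16, contributions.tolist())),
    )


def teq_series(
    samples: list[SoilSample],
    tefs: TefTable | None = None,
    allow_reported: bool = True,
) -> list[TeqResult]:
    """Order-preserving TEQ conversion of a sample list.

    Samples without congener-level data fall back to their reported ΣTEQ
    column (flagged ``as_reported``) when ``allow_reported`` is true;
    otherwise the missing data raise with the sample id.
    """
    tefs = tefs or TefTable.default()
    results = []
    for sample in samples:
        if sample.pah is not None:
            results.append(compute_teq(sample, tefs))
        elif allow_reported and sample.reported_teq is not None:
            results.append(
                TeqResult(sample.sample_id, float(sample.reported_teq), as_reported=True)
            )
        else:
            raise ValueError(
                f"{sample.sample_id}: no congener-level PAH data and no reported TEQ"
            )
    return results


def teq_vector(results: list[TeqResult]) -> np.ndarray:
    """Convenience: ΣTEQ_BaP values of a result list as an array (mg/kg)."""
    return np.array([r.teq_bap for r in results], dtype=float)
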