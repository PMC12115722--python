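"""Packaged reference tables from the oilfield case study.

Four tables transcribed digit-for-digit from the published field study of
aged petroleum-contaminated soils around the Shengli Oilfield:

- ``table2``: physicochemical survey of the 32 soil samples (pH, EC, SOM,
  TPH, ΣPAHs, ΣTEQ_BaP).
- ``table5``: 17 species EC50 values (mg/kg ΣTEQ_BaP) before/after the
  distribution (partitioning) calibration.
- ``table7``: the same 17 species before/after the aging calibration
  ("before" equals table5's "after").
- ``table9``: per-sample risk quotients and risk/pollution-index grades.

The NIPI grade column of ``table9`` is uniform (grade 5): the source table
prints it only for the first row and states in text that the Nemerow index
classified all 32 soils as heavily polluted.
"""
from __future__ import annotations

import importlib.resources

import pandas as pd

__all__ = ["load_fixture", "FIXTURES"]

FIXTURES = ("table2", "table5", "table7", "table9")


def load_fixture(name: str) -> pd.DataFrame:
    """Return one of the packaged reference tables as a typed DataFrame."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    path = importlib.resources.files("ednarisk.fixtures") / f"{name}.tsv"
    df = pd.read_csv(path, sep="\t")
    return df
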