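"""Core domain types: soil samples, community profiles and TEF tables.

The pipeline's unit conventions are fixed here once: concentrations in
mg/kg dry soil, electrical conductivity in µS/cm, soil organic matter as a
percentage of dry mass, and relative abundances as fractions in [0, 1]
(percent only at presentation time).
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EPA16",
    "canonical_congener",
    "SoilSample",
    "CommunityProfile",
    "TefTable",
    "SchemaError",
    "AlignmentError",
]

#: The 16 EPA priority PAH congeners, in ring-number order.
EPA16: tuple[str, ...] = (
    "naphthalene",
    "acenaphthylene",
    "acenaphthene",
    "fluorene",
    "phenanthrene",
    "anthracene",
    "fluoranthene",
    "pyrene",
    "benz[a]anthracene",
    "chrysene",
    "benzo[b]fluoranthene",
    "benzo[k]fluoranthene",
    "benzo[a]pyrene",
    "indeno[1,2,3-cd]pyrene",
    "dibenz[a,h]anthracene",
    "benzo[ghi]perylene",
)

_SHORT = (
    "nap", "acy", "ace", "flu", "phe", "ant", "flt", "pyr",
    "baa", "chr", "bbf", "bkf", "bap", "icdp", "daha", "bghip",
)


def _squash(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


_ALIASES: dict[str, str] = {}
for _full, _short in zip(EPA16, _SHORT):
    _ALIASES[_squash(_full)] = _full
    _ALIASES[_short] = _full
# spelling variants seen in the wild
for _variant, _full in {
    "benzoaanthracene": "benz[a]anthracene",
    "benzaanthracene": "benz[a]anthracene",
    "dibenzahanthracene": "dibenz[a,h]anthracene",
    "dibenzoahanthracene": "dibenz[a,h]anthracene",
    "indeno123cdpyrene": "indeno[1,2,3-cd]pyrene",
    "indenopyrene": "indeno[1,2,3-cd]pyrene",
    "benzoghiperylene": "benzo[ghi]perylene",
    "fluoranthrene": "fluoranthene",
    "fla": "fluoranthene",
    "inp": "indeno[1,2,3-cd]pyrene",
    "dba": "dibenz[a,h]anthracene",
    "bpe": "benzo[ghi]perylene",
}.items():
    _ALIASES[_squash(_variant)] = _full


class SchemaError(ValueError):
    """A required column or congener is missing, or a value is malformed."""


class AlignmentError(ValueError):
    """Sample identifiers of two joined tables do not match."""


def canonical_congener(name: str) -> str:
    """Map a congener name or common abbreviation to its canonical EPA name.

    Raises :class:`SchemaError` for unrecognised names.
    """
    key = _squash(name)
    if key not in _ALIASES:
        raise SchemaError(f"unknown PAH congener name: {name!r}")
    return _ALIASES[key]


@dataclass
class SoilSample:
    """One site's physicochemical state plus its 16-congener PAH vector.

    ``pah`` may be ``None`` when only aggregate columns (``pah_sum``,
    ``reported_teq``) were published for the site; downstream stages then
    run on the reported totals, flagged "as-reported".  Congeners missing
    from an otherwise complete vector are stored as explicit zeros with
    their names recorded in ``pah_imputed``.
    """

    sample_id: str
    ph: float
    ec: float  # µS/cm
    som: float  # % of dry mass
    tph: float | None = None  # mg/kg; optional (one site reports 0, some none)
    pah: dict[str, float] | None = None  # mg/kg per congener
    aged_years: float | None = None
    pah_sum: float | None = None  # reported ΣPAHs, mg/kg
    reported_teq: float | None = None  # reported ΣTEQ_BaP, mg/kg
    pah_imputed: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.ec < 0:
            raise ValueError(f"{self.sample_id}: EC must be >= 0, got {self.ec}")
        if not 0.0 <= self.som <= 100.0:
            raise ValueError(f"{self.sample_id}: SOM must be in [0, 100] %, got {self.som}")
        if self.tph is not None and self.tph < 0:
            raise ValueError(f"{self.sample_id}: TPH must be >= 0, got {self.tph}")
        if self.pah is not None:
            pah = {}
            imputed = set(self.pah_imputed)
            for name, value in self.pah.items():
                cname = canonical_congener(name)
                if value < 0:
                    raise ValueError(f"{self.sample_id}: negative concentration for {cname}")
                pah[cname] = float(value)
            for cname in EPA16:
                if cname not in pah:
                    pah[cname] = 0.0
                    imputed.add(cname)
            self.pah = {c: pah[c] for c in EPA16}
            self.pah_imputed = frozenset(imputed)

    @property
    def pah_vector(self) -> np.ndarray:
        """Congener concentrations as a length-16 array in :data:`EPA16` order."""
        if self.pah is None:
            raise ValueError(f"{self.sample_id}: no congener-level PAH data")
        return np.array([self.pah[c] for c in EPA16], dtype=float)


class CommunityProfile:
    """Taxa x samples relative-abundance matrix (the eDNA receptor data).

    Stores abundances as fractions.  Use :meth:`from_counts` to build from a
    raw count matrix (columns are normalised to sum to one).
    """

    def __init__(self, abundance: pd.DataFrame, normalized: bool = True):
        if abundance.index.has_duplicates:
            dupes = abundance.index[abundance.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicated taxon labels: {dupes}")
        if (abundance.to_numpy() < 0).any():
            raise SchemaError("negative abundance entries")
        self._df = abundance.astype(float)
        self.normalized = normalized
        if normalized:
            colsums = self._df.sum(axis=0).to_numpy()
            if len(self._df.columns) and not np.allclose(colsums, 1.0, atol=1e-6):
                raise SchemaError("declared normalized but column sums deviate from 1")

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "CommunityProfile":
        colsums = counts.sum(axis=0)
        if (colsums <= 0).any():
            raise SchemaError("cannot normalise a column with non-positive sum")
        return cls(counts / colsums, normalized=True)

    @property
    def taxa(self) -> list[str]:
        return list(self._df.index)

    @property
    def samples(self) -> list[str]:
        return list(self._df.columns)

    @property
    def abundance(self) -> pd.DataFrame:
        return self._df

    def align(self, sample_ids: Iterable[str]) -> "CommunityProfile":
        """Restrict/reorder columns to ``sample_ids``; error on mismatch."""
        wanted = list(sample_ids)
        missing = [s for s in wanted if s not in self._df.columns]
        if missing:
            raise AlignmentError(f"samples absent from community profile: {missing}")
        return CommunityProfile(self._df[wanted], normalized=self.normalized)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CommunityProfile) and self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"CommunityProfile({len(self.taxa)} taxa x {len(self.samples)} samples)"


@dataclass(frozen=True)
class TefTable:
    """Toxic equivalency factors relative to benzo[a]pyrene (TEF_BaP = 1)."""

    tefs: Mapping[str, float]

    def __post_init__(self) -> None:
        canon = {canonical_congener(k): float(v) for k, v in self.tefs.items()}
        if any(v <= 0 for v in canon.values()):
            raise ValueError("all TEF values must be > 0")
        if canon.get("benzo[a]pyrene") != 1.0:
            raise ValueError("TEF of benzo[a]pyrene must be exactly 1")
        object.__setattr__(self, "tefs", canon)

    def __getitem__(self, congener: str) -> float:
        cname = canonical_congener(congener)
        if cname not in self.tefs:
            raise SchemaError(f"congener missing from TEF table: {cname}")
        return self.tefs[cname]

    def __contains__(self, congener: str) -> bool:
        return canonical_congener(congener) in self.tefs

    @property
    def vector(self) -> np.ndarray:
        return np.array([self[c] for c in EPA16], dtype=float)

    @classmethod
    def default(cls) -> "TefTable":
        """The packaged Nisbet & LaGoy-style TEF table (ΣTEF = 2.437)."""
        return cls.from_csv(
            importlib.resources.files("ednarisk.fixtures") / "tef_nisbet_lagoy.csv"
        )

    @classmethod
    def from_csv(cls, path) -> "TefTable":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "congener" not in cols or "tef" not in cols:
            raise SchemaError("TEF CSV must have 'congener' and 'tef' columns")
        return cls(dict(zip(df[cols["congener"]], df[cols["tef"]])))
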