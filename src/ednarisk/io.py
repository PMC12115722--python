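"""Readers and writers for soil-sample tables and abundance matrices.

Sample tables are CSV/TSV with a header; column names are matched
case-insensitively against a small alias map so tables exported from
different tools load without renaming.  Abundance matrices are TSV
(taxa rows x sample columns) or BIOM v1 JSON.  Count matrices are
auto-detected (any column sum > 1.5) and normalised to fractions.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    EPA16,
    AlignmentError,
    CommunityProfile,
    SchemaError,
    SoilSample,
    canonical_congener,
    _squash,
)

__all__ = [
    "read_sample_table",
    "write_sample_table",
    "read_abundance",
    "write_abundance",
    "ParseError",
]


class ParseError(ValueError):
    """A cell could not be parsed as a number; names the row and column."""


_COLUMN_ALIASES = {
    "sample_id": {"sample", "sampleid", "sample_id", "site", "id"},
    "ph": {"ph"},
    "ec": {"ec", "ecuscm", "ec_us_cm", "conductivity", "electricalconductivity"},
    "som": {"som", "sompct", "som_pct", "organicmatter", "soilorganicmatter"},
    "tph": {"tph", "tphmgkg", "tph_mg_kg", "tphmgg"},
    "pah_sum": {"pahs", "pahsum", "pah_sum", "pah_sum_mg_kg", "pahsmgkg", "sigmapahs"},
    "reported_teq": {"teq", "teqbap", "teq_bap", "teq_bap_mg_kg", "teqbapmgkg",
                     "sigmateqbap", "teqsum", "teq_sum_mg_kg"},
    "aged_years": {"agedyears", "aged_years", "aging", "agingyears", "age"},
}


def _resolve_columns(columns: list[str]) -> tuple[dict[str, str], dict[str, str]]:
    """Split a header into (field -> column, congener -> column) maps."""
    fields: dict[str, str] = {}
    congeners: dict[str, str] = {}
    for col in columns:
        key = _squash(col)
        matched = False
        for fieldname, aliases in _COLUMN_ALIASES.items():
            if key in {_squash(a) for a in aliases}:
                fields[fieldname] = col
                matched = True
                break
        if matched:
            continue
        try:
            congeners[canonical_congener(col)] = col
        except SchemaError:
            pass  # unknown extra column; ignored
    return fields, congeners


def _cell(df_row, colname: str, row_idx: int, required: bool = False) -> float | None:
    raw = df_row[colname]
    if pd.isna(raw) or (isinstance(raw, str) and not raw.strip()):
        if required:
            raise ParseError(f"row {row_idx}: empty required cell in column {colname!r}")
        return None
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ParseError(
            f"row {row_idx}: cannot parse {raw!r} in column {colname!r} as a number"
        ) from None


def read_sample_table(path, dialect: str | None = None) -> list[SoilSample]:
    """Read a soil-sample table (CSV or TSV) into :class:`SoilSample` records.

    ``dialect`` is the delimiter; by default it is inferred from the file
    extension (``.tsv`` -> tab, otherwise comma).  Rows are returned in file
    order.  Numeric parsing is locale-independent (dot decimal separator).
    """
    path = Path(path)
    sep = dialect or ("\t" if path.suffix.lower() in {".tsv", ".tab"} else ",")
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    fields, congeners = _resolve_columns(list(df.columns))
    for mandatory in ("sample_id", "ph", "ec", "som"):
        if mandatory not in fields:
            raise SchemaError(f"missing mandatory column: {mandatory}")
    samples = []
    for i, (_, row) in enumerate(df.iterrows()):
        pah = None
        imputed: frozenset[str] = frozenset()
        if congeners:
            pah = {}
            for cname, col in congeners.items():
                value = _cell(row, col, i)
                pah[cname] = 0.0 if value is None else value
                if value is None:
                    imputed = imputed | {cname}
        samples.append(
            SoilSample(
                sample_id=str(row[fields["sample_id"]]),
                ph=_cell(row, fields["ph"], i, required=True),
                ec=_cell(row, fields["ec"], i, required=True),
                som=_cell(row, fields["som"], i, required=True),
                tph=_cell(row, fields["tph"], i) if "tph" in fields else None,
                pah=pah,
                aged_years=_cell(row, fields["aged_years"], i) if "aged_years" in fields else None,
                pah_sum=_cell(row, fields["pah_sum"], i) if "pah_sum" in fields else None,
                reported_teq=_cell(row, fields["reported_teq"], i) if "reported_teq" in fields else None,
                pah_imputed=imputed,
            )
        )
    return samples


def write_sample_table(samples: list[SoilSample], path, dialect: str | None = None) -> None:
    """Write samples back to CSV/TSV; inverse of :func:`read_sample_table`."""
    path = Path(path)
    sep = dialect or ("\t" if path.suffix.lower() in {".tsv", ".tab"} else ",")
    rows = []
    any_pah = any(s.pah is not None for s in samples)
    for s in samples:
        row: dict[str, object] = {
            "sample_id": s.sample_id, "ph": s.ph, "ec": s.ec, "som": s.som,
            "tph": s.tph, "pah_sum": s.pah_sum, "teq_bap": s.reported_teq,
            "aged_years": s.aged_years,
        }
        if any_pah:
            for c in EPA16:
                row[c] = None if s.pah is None else s.pah[c]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_abundance(path, format: str | None = None) -> CommunityProfile:
    """Read an abundance matrix from TSV or BIOM v1 (JSON).

    TSV layout: first column = taxon labels, remaining columns = samples.
    Counts are detected when any column sums above 1.5 and are normalised
    to per-sample fractions.
    """
    path = Path(path)
    fmt = format or ("biom" if path.suffix.lower() == ".biom" else "tsv")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    elif fmt == "biom":
        df = _read_biom_json(path)
    else:
        raise ValueError(f"unknown abundance format: {format!r}")
    if (df.to_numpy() < 0).any():
        raise SchemaError("negative entries in abundance matrix")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicated taxon labels: {dupes}")
    if len(df.columns) and (df.sum(axis=0) > 1.5).any():
        return CommunityProfile.from_counts(df)
    return CommunityProfile(df, normalized=True)


def _read_biom_json(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    return pd.DataFrame(mat, index=taxa, columns=samples)


def write_abundance(profile: CommunityProfile, path, format: str | None = None) -> None:
    """Write an abundance matrix as TSV or BIOM v1 dense JSON."""
    path = Path(path)
    fmt = format or ("biom" if path.suffix.lower() == ".biom" else "tsv")
    if fmt == "tsv":
        profile.abundance.rename_axis("taxon").to_csv(path, sep="\t")
    elif fmt == "biom":
        df = profile.abundance
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "ednarisk",
            "matrix_type": "dense",
            "matrix_element_type": "float",
            "shape": [len(df.index), len(df.columns)],
            "rows": [{"id": t, "metadata": None} for t in df.index],
            "columns": [{"id": s, "metadata": None} for s in df.columns],
            "data": df.to_numpy().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown abundance format: {format!r}")
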