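"""Occurrence tables, covariate extraction and labelled feature tables.

This module turns raw inputs — per-species occurrence tables (CSV or XLSX)
and gridded weather layers — into the :class:`FeatureTable` the classifier
consumes: one row per usable collection event with the weather values of
its collection year at its grid cell, plus a binary class label
(``invasive`` vs ``native``).

Conventions
-----------
* Point-to-cell mapping is nearest-cell containment on half-open cells; no
  interpolation.  Points outside the extent or on nodata cells are excluded
  and counted, never imputed.
* Duplicate records (same species/cell/year) are retained.
* Class labels come from a species-role map ``{species_id: "invasive" |
  "native"}``; the invasive species is always the positive class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import ClimateStack, GridError

logger = logging.getLogger(__name__)

INVASIVE, NATIVE = "invasive", "native"
_META_COLUMNS = ("species", "year", "x", "y", "label")


class FormatError(ValueError):
    """Malformed input table (missing column, non-numeric covariate, ...)."""


@dataclass(frozen=True)
class OccurrenceRecord:
    """One collection event: species, calendar year, planar coordinates."""

    species_id: str
    year: int
    x: float
    y: float
    date: str | None = None

    def __post_init__(self) -> None:
        if not (1000 <= int(self.year) <= 9999):
            raise ValueError(f"year {self.year!r} is not a 4-digit calendar year")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("coordinates must be finite")


@dataclass
class FeatureTable:
    """Occurrence rows joined to covariates plus a binary class label.

    ``data`` columns: species, year, x, y, label, then one column per
    variable in ``variables`` (the declared covariate order).
    """

    data: pd.DataFrame
    variables: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in (*_META_COLUMNS, *self.variables)
                   if c not in self.data.columns]
        if missing:
            raise FormatError(f"feature table missing columns: {missing}")
        bad = set(self.data["label"].unique()) - {INVASIVE, NATIVE}
        if bad:
            raise FormatError(f"labels must be binary invasive/native, got {bad}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        """Covariate matrix in declared variable order."""
        return self.data[self.variables].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Binary labels, 1 = invasive (positive class), 0 = native."""
        return (self.data["label"] == INVASIVE).to_numpy(dtype=int)

    def subset(self, mask) -> "FeatureTable":
        return FeatureTable(self.data.loc[mask].reset_index(drop=True),
                            list(self.variables))

    def class_counts(self) -> dict[str, int]:
        return self.data["label"].value_counts().to_dict()

    def species_counts(self) -> dict[str, int]:
        return self.data["species"].value_counts().to_dict()


# ---------------------------------------------------------------------------
# Occurrence ingestion


def read_occurrences(path: str | Path,
                     species_role_map: Mapping[str, str] | None = None,
                     species_id: str | None = None) -> list[OccurrenceRecord]:
    """Read one occurrence table (CSV or XLSX) into records.

    Rows with unparseable year or coordinates are dropped and the count is
    logged.  The species may come from a ``species`` column or, as with the
    one-file-per-species database exports, from ``species_id``.  When a role
    map is given, species absent from it are dropped (logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "species" not in df.columns:
        if species_id is None:
            raise FormatError("missing required column 'species' "
                              "(and no species_id given)")
        df["species"] = species_id
    for col in ("year", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if df.empty:
        logger.warning("%s: empty occurrence table", path)
        return []

    records: list[OccurrenceRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        try:
            year = int(row.year)
            x, y = float(row.x), float(row.y)
            rec = OccurrenceRecord(str(row.species), year, x, y,
                                   date=getattr(row, "date", None))
        except (TypeError, ValueError):
            dropped += 1
            continue
        if species_role_map is not None and rec.species_id not in species_role_map:
            dropped += 1
            continue
        records.append(rec)
    if dropped:
        logger.info("%s: dropped %d unusable rows (kept %d)",
                    path, dropped, len(records))
    return records


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Covariate extraction


def attach_features(records: Sequence[OccurrenceRecord],
                    stacks_by_year: Mapping[int, ClimateStack],
                    variables: Sequence[str],
                    species_role_map: Mapping[str, str]) -> FeatureTable:
    """Join each record to its collection-year weather values.

    Each point takes the value of the grid cell containing it, from the
    stack of its own collection year.  Points outside the extent or on a
    nodata cell of any requested layer are excluded; exclusions are logged.
    """
    missing_years = sorted({r.year for r in records} - set(stacks_by_year))
    if missing_years:
        raise GridError(f"no climate stack for years {missing_years}")
    for stack in stacks_by_year.values():
        absent = [v for v in variables if v not in stack.layers]
        if absent:
            raise GridError(f"stack {stack.label} lacks variables {absent}")

    rows: list[dict] = []
    outside = nodata = 0
    for rec in records:
        role = species_role_map.get(rec.species_id)
        if role not in (INVASIVE, NATIVE):
            raise FormatError(f"species {rec.species_id!r} has no role "
                              f"(invasive/native) in the role map")
        stack = stacks_by_year[rec.year]
        if not stack.geometry.contains(rec.x, rec.y):
            outside += 1
            continue
        values = [stack.value_at(v, rec.x, rec.y) for v in variables]
        if not all(np.isfinite(values)):
            nodata += 1
            continue
        row = {"species": rec.species_id, "year": rec.year,
               "x": rec.x, "y": rec.y, "label": role}
        row.update(zip(variables, values))
        rows.append(row)
    if outside or nodata:
        logger.info("attach_features: excluded %d points outside extent, "
                    "%d on nodata cells", outside, nodata)
    columns = [*_META_COLUMNS, *variables]
    data = pd.DataFrame(rows, columns=columns)
    table = FeatureTable(data, list(variables))
    table.n_excluded_outside = outside  # type: ignore[attr-defined]
    table.n_excluded_nodata = nodata  # type: ignore[attr-defined]
    return table


# ---------------------------------------------------------------------------
# Feature-table round trip


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table.data.to_excel(path, index=False)
    else:
        table.data.to_csv(path, index=False)


def read_feature_table(path: str | Path,
                       variables: Sequence[str] | None = None) -> FeatureTable:
    """Read a pre-joined feature table; validates covariates are numeric.

    When ``variables`` is omitted, every non-metadata column is taken as a
    covariate, in file order.
    """
    path = Path(path)
    df = _read_table(path)
    df.columns = [str(c).strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    rename = {lower[m]: m for m in _META_COLUMNS if m in lower}
    df = df.rename(columns=rename)
    if variables is None:
        variables = [c for c in df.columns if c not in _META_COLUMNS]
    else:
        missing = [v for v in variables if v not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing variable columns {missing}")
    for var in variables:
        numeric = pd.to_numeric(df[var], errors="coerce")
        bad = numeric.isna() & df[var].notna()
        if bad.any():
            raise FormatError(
                f"{path}: non-numeric value in column {var!r} at row "
                f"{int(bad.idxmax())}")
        df[var] = numeric
    df["year"] = df["year"].astype(int)
    return FeatureTable(df.reset_index(drop=True), list(variables))


def concat_tables(tables: Iterable[FeatureTable]) -> FeatureTable:
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to concatenate")
    variables = tables[0].variables
    for t in tables[1:]:
        if t.variables != variables:
            raise FormatError("cannot concatenate tables with different "
                              "variable lists")
    data = pd.concat([t.data for t in tables], ignore_index=True)
    return FeatureTable(data, list(variables))
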