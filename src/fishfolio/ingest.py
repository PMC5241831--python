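"""Reading, deflating, filtering and reshaping community landings records.

Landings data are long-format delimited text emulating the Alaska Commercial
Fisheries Entry Commission (CFEC) community earnings files: one row per
community x year x fishery observation, where a fishery is a taxon harvested
at a location with a particular gear.  Records carry pounds landed and nominal
ex-vessel revenue (the price paid to fishers at the dock, in dollars of the
landing year).

The canonical in-memory container is a :class:`pandas.DataFrame` with the
columns in :data:`CANONICAL_FIELDS`; all downstream modules consume that
frame.  Panels (entity x year matrices fed to the dynamic factor analysis)
are held in the small :class:`Panel` dataclass.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical column names of a landings record.
CANONICAL_FIELDS = (
    "community",
    "year",
    "taxon",
    "location",
    "gear",
    "pounds",
    "revenue_nominal",
)

_NUMERIC_FIELDS = ("year", "pounds", "revenue_nominal")

#: Default CPI base year: revenues are deflated to dollars of this year.
DEFAULT_BASE_YEAR = 2013


class SchemaError(ValueError):
    """A required column is missing or cannot be mapped."""


class ValidationError(ValueError):
    """A parsed row violates a record invariant."""


@dataclasses.dataclass
class Panel:
    """Dense entity x year matrix of revenue or catch.

    Attributes
    ----------
    entity_ids : list of str
        Row labels (community names or ``taxon|location`` stock labels).
    years : numpy.ndarray
        Contiguous integer years, one per column.
    values : numpy.ndarray
        Matrix of shape ``(len(entity_ids), len(years))``.
    kind : str
        Either ``"revenue"`` or ``"catch"``.
    """

    entity_ids: list
    years: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entity_ids), len(self.years)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.years)} years"
            )
        if len(self.years) > 1 and not np.all(np.diff(self.years) == 1):
            raise ValueError("panel years must be contiguous")

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.entity_ids, name="entity"), columns=self.years
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str) -> "Panel":
        df = pd.read_csv(path, index_col=0)
        return cls(
            entity_ids=list(df.index),
            years=np.array([int(c) for c in df.columns]),
            values=df.to_numpy(dtype=float),
            kind=kind,
        )


def stock_label(taxon: str, location: str) -> str:
    """Stock identity used throughout: taxon x location, gear aggregated."""
    return f"{taxon}|{location}"


def load_landings(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read long-format landings records from delimited text.

    Parameters
    ----------
    path : str or Path
        CSV or TSV file (delimiter chosen by extension) with a header row.
    schema : mapping, optional
        Maps canonical field names (:data:`CANONICAL_FIELDS`) to the column
        names used in the file.  Unmapped fields must appear under their
        canonical names.

    Returns
    -------
    pandas.DataFrame
        Records with canonical columns, duplicates on the
        (community, year, taxon, location, gear) key summed so the key is
        unique after ingest.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        If a row has negative pounds or revenue, or a non-numeric value;
        the message cites the offending file line (header is line 1).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    rename = {v: k for k, v in (schema or {}).items()}
    raw = raw.rename(columns=rename)

    missing = [f for f in CANONICAL_FIELDS if f not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = raw[list(CANONICAL_FIELDS)].copy()
    for field in _NUMERIC_FIELDS:
        parsed = pd.to_numeric(df[field], errors="coerce")
        bad = parsed.isna() & df[field].notna() | df[field].isna()
        if bad.any():
            lines = [str(i + 2) for i in df.index[bad][:10]]
            raise ValidationError(
                f"non-numeric or missing {field!r} at file line(s): {', '.join(lines)}"
            )
        df[field] = parsed
    df["year"] = df["year"].astype(int)

    for field in ("pounds", "revenue_nominal"):
        neg = df[field] < 0
        if neg.any():
            lines = [str(i + 2) for i in df.index[neg][:10]]
            raise ValidationError(
                f"negative {field!r} at file line(s): {', '.join(lines)}"
            )

    key = ["community", "year", "taxon", "location", "gear"]
    df = df.groupby(key, as_index=False)[["pounds", "revenue_nominal"]].sum()
    return df


def load_cpi(path) -> pd.Series:
    """Read an annual CPI table (columns ``year``, ``cpi``) into a Series."""
    df = pd.read_csv(path)
    if not {"year", "cpi"}.issubset(df.columns):
        raise SchemaError("CPI table must have 'year' and 'cpi' columns")
    if df["year"].duplicated().any():
        raise ValidationError("CPI table has duplicate years")
    if (df["cpi"] <= 0).any():
        raise ValidationError("CPI values must be positive")
    return pd.Series(df["cpi"].to_numpy(float), index=df["year"].astype(int).to_numpy())


def deflate(
    records: pd.DataFrame, cpi: pd.Series, base_year: int = DEFAULT_BASE_YEAR
) -> pd.DataFrame:
    """Add a ``revenue_real`` column: nominal revenue in base-year dollars.

    ``revenue_real = revenue_nominal * cpi[base_year] / cpi[year]``.
    """
    if base_year not in cpi.index:
        raise ValidationError(f"CPI table does not cover base year {base_year}")
    years = records["year"].unique()
    uncovered = sorted(set(years) - set(cpi.index))
    if uncovered:
        raise ValidationError(f"CPI table does not cover year(s): {uncovered}")
    out = records.copy()
    factor = cpi.loc[base_year] / cpi.reindex(out["year"]).to_numpy()
    out["revenue_real"] = out["revenue_nominal"].to_numpy() * factor
    return out


def filter_communities(
    records: pd.DataFrame,
    start: int = 1980,
    end: int = 1999,
    value: str = "revenue_real",
) -> list:
    """Communities with positive total revenue in *every* year of [start, end].

    This is the completeness filter applied before the revenue DFA and the
    regime-response comparisons: a community missing from the records in any
    window year, or with zero summed revenue in one, is dropped.
    """
    if start > end:
        raise ValueError("start must be <= end")
    if records.empty:
        return []
    window = records[(records["year"] >= start) & (records["year"] <= end)]
    totals = window.groupby(["community", "year"])[value].sum().unstack("year")
    n_years = end - start + 1
    totals = totals.reindex(columns=range(start, end + 1))
    keep = totals.notna().all(axis=1) & (totals > 0).fillna(False).all(axis=1)
    assert totals.shape[1] == n_years
    return sorted(totals.index[keep])


def filter_stocks(
    records: pd.DataFrame,
    max_zero_years: int = 3,
    start: int | None = None,
    end: int | None = None,
) -> list:
    """Stocks (taxon x location, gear summed) with few zero-catch years.

    A stock is kept iff the number of years in [start, end] with zero (or
    absent) summed pounds is at most ``max_zero_years``.  The window defaults
    to the full span of the records.
    """
    if records.empty:
        return []
    if start is None:
        start = int(records["year"].min())
    if end is None:
        end = int(records["year"].max())
    window = records[(records["year"] >= start) & (records["year"] <= end)]
    pounds = (
        window.groupby(["taxon", "location", "year"])["pounds"].sum().unstack("year")
    )
    pounds = pounds.reindex(columns=range(start, end + 1))
    zero_years = ((pounds.isna()) | (pounds == 0)).sum(axis=1)
    kept = zero_years[zero_years <= max_zero_years].index
    return sorted(stock_label(t, l) for t, l in kept)


def build_panel(
    records: pd.DataFrame,
    entity: str,
    value: str,
    years: Sequence[int],
    entity_ids: Sequence[str] | None = None,
    exclude_taxa: Sequence[str] | None = None,
) -> Panel:
    """Reshape long records into a dense entity x year matrix.

    Parameters
    ----------
    entity : {"community", "stock"}
        Row identity; stocks are taxon|location with gear aggregated.
    value : {"revenue_real", "pounds"}
        Cell contents.
    years : sequence of int
        Contiguous years forming the columns.
    entity_ids : sequence, optional
        Restrict (and order) rows; defaults to all entities present, sorted.
    exclude_taxa : sequence, optional
        Taxa dropped before aggregation (e.g. the sablefish/halibut
        sensitivity run, whose management switched to transferable quotas).

    Notes
    -----
    Absent cells are filled with zero — legitimate only for catch panels of
    pre-filtered stocks.  A revenue panel containing a zero cell indicates a
    violated community filter and is fatal.
    """
    years = np.asarray(list(years), dtype=int)
    df = records[records["year"].isin(years)]
    if exclude_taxa:
        df = df[~df["taxon"].isin(set(exclude_taxa))]
    if entity == "community":
        labels = df["community"]
    elif entity == "stock":
        labels = df["taxon"].str.cat(df["location"], sep="|")
    else:
        raise ValueError(f"unknown entity kind {entity!r}")
    if value not in ("revenue_real", "pounds"):
        raise ValueError(f"unknown value kind {value!r}")

    wide = (
        df.assign(_entity=labels)
        .groupby(["_entity", "year"])[value]
        .sum()
        .unstack("year")
        .reindex(columns=years)
    )
    if entity_ids is None:
        entity_ids = sorted(wide.index)
    wide = wide.reindex(index=entity_ids).fillna(0.0)

    kind = "revenue" if value == "revenue_real" else "catch"
    if kind == "revenue" and (wide.to_numpy() <= 0).any():
        bad = wide.index[(wide <= 0).any(axis=1)].tolist()[:5]
        raise ValidationError(
            f"revenue panel has non-positive cells for kept communities: {bad} "
            "(community filter violated)"
        )
    return Panel(entity_ids=list(entity_ids), years=years, values=wide.to_numpy(float), kind=kind)
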