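"""Readers, writers and in-memory containers for vegetation-plot tables.

The universal input is a long-format observation table (one row per
species-in-plot record: plot id, taxon name, optional vegetation layer,
percent cover) plus a header table (one row per plot: coordinates and an
optional EUNIS level-3 habitat code).  Column names vary between database
exports, so both readers take a :class:`Dialect` mapping with an EVA-like
default.
"""

from __future__ import annotations

import csv
import math
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "Observation",
    "PlotHeader",
    "PlotTable",
    "NameRecord",
    "Dialect",
    "HeaderDialect",
    "ParseError",
    "read_observations",
    "read_headers",
    "read_name_records",
    "write_table",
    "write_headers",
]

#: ranks a name-standardization record may carry
NAME_RANKS = ("species", "subspecies", "genus", "hybrid", "unmatched")


@dataclass(frozen=True)
class Observation:
    """One species record in one plot."""

    plot_id: str
    taxon_name: str
    cover_pct: float
    layer: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.taxon_name:
            raise ValueError("taxon_name must be non-empty")
        if not math.isfinite(self.cover_pct):
            raise ValueError(f"cover_pct must be finite, got {self.cover_pct!r}")


@dataclass(frozen=True)
class PlotHeader:
    """Per-plot metadata: coordinates and optional EUNIS level-3 label."""

    plot_id: str
    longitude: float
    latitude: float
    habitat_code: Optional[str] = None

    def __post_init__(self) -> None:
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")


@dataclass(frozen=True)
class NameRecord:
    """Outcome of taxon-name standardization for one input name.

    ``rank == "unmatched"`` iff no accepted binomial exists.  Subspecies
    records carry their *parent* binomial (lumping target).
    """

    input_name: str
    accepted_binomial: Optional[str]
    rank: str

    def __post_init__(self) -> None:
        if self.rank not in NAME_RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if (self.rank == "unmatched") != (self.accepted_binomial is None):
            if self.rank == "genus" and self.accepted_binomial is None:
                return  # genus-only names legitimately have no binomial
            raise ValueError("rank=unmatched iff accepted_binomial absent")


@dataclass(frozen=True)
class ParseError:
    """A row that failed type coercion, kept for reporting (never silent)."""

    row: int
    message: str


_OBS_COLUMNS = ["plot_id", "taxon_name", "layer", "cover_pct"]


class PlotTable:
    """Ordered collection of :class:`Observation`, indexed by plot id.

    Thin wrapper over a pandas DataFrame with the canonical columns
    ``plot_id, taxon_name, layer, cover_pct``; row order is preserved by
    every loader and curation step (within a plot, order is meaningful:
    it reflects the source record).
    """

    def __init__(self, df: Optional[pd.DataFrame] = None,
                 parse_errors: Sequence[ParseError] = ()) -> None:
        if df is None:
            df = pd.DataFrame(columns=_OBS_COLUMNS)
        missing = [c for c in _OBS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing canonical columns: {missing}")
        self.df = df[_OBS_COLUMNS].reset_index(drop=True)
        self.parse_errors = list(parse_errors)

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_observations(cls, obs: Iterable[Observation]) -> "PlotTable":
        rows = [(o.plot_id, o.taxon_name, o.layer, o.cover_pct) for o in obs]
        return cls(pd.DataFrame(rows, columns=_OBS_COLUMNS))

    # -- container protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Observation]:
        for row in self.df.itertuples(index=False):
            yield Observation(row.plot_id, row.taxon_name, row.cover_pct, row.layer)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlotTable):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def plot_ids(self) -> list[str]:
        """Distinct plot ids in first-appearance order."""
        return list(dict.fromkeys(self.df["plot_id"]))

    @property
    def n_plots(self) -> int:
        return self.df["plot_id"].nunique()

    @property
    def species(self) -> list[str]:
        """Distinct taxon names, sorted."""
        return sorted(self.df["taxon_name"].unique())

    def plot(self, plot_id: str) -> pd.DataFrame:
        """All observations of one plot, source order preserved."""
        return self.df[self.df["plot_id"] == plot_id]

    def groupby_plot(self):
        return self.df.groupby("plot_id", sort=False)

    def subset(self, plot_ids: Iterable[str]) -> "PlotTable":
        keep = set(plot_ids)
        return PlotTable(self.df[self.df["plot_id"].isin(keep)])


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping for observation tables (EVA-like default)."""

    plot_id: str = "PlotObservationID"
    taxon_name: str = "Matched concept"
    layer: str = "Layer"
    cover_pct: str = "Cover %"


@dataclass(frozen=True)
class HeaderDialect:
    """Column-name mapping for plot header tables."""

    plot_id: str = "PlotObservationID"
    longitude: str = "Longitude"
    latitude: str = "Latitude"
    habitat_code: str = "Expert System"


def _sniff_delimiter(path: Path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    suffix = path.suffix.lower()
    if suffix == ".tsv":
        return "\t"
    if suffix == ".csv":
        return ","
    with open(path, "r", encoding="utf-8", newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def _require_columns(df: pd.DataFrame, wanted: Mapping[str, str], path) -> None:
    missing = [src for src in wanted.values() if src and src not in df.columns]
    if missing:
        raise KeyError(
            f"{path}: missing column(s) {missing}; available: {list(df.columns)}"
        )


def read_observations(path, dialect: Dialect = Dialect(),
                      delimiter: Optional[str] = None) -> PlotTable:
    """Load a long-format observation table.

    Rows whose cover fails numeric coercion are excluded from the table but
    recorded in ``table.parse_errors`` — never dropped silently.  The layer
    column is optional (set ``dialect.layer`` to ``""`` to skip it).
    """
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                      encoding="utf-8")
    wanted = {"plot_id": dialect.plot_id, "taxon_name": dialect.taxon_name,
              "cover_pct": dialect.cover_pct}
    _require_columns(raw, wanted, path)
    has_layer = bool(dialect.layer) and dialect.layer in raw.columns

    errors: list[ParseError] = []
    rows = []
    for i, row in enumerate(raw.itertuples(index=False)):
        rec = dict(zip(raw.columns, row))
        name = unicodedata.normalize("NFC", rec[dialect.taxon_name]).strip()
        if not name:
            errors.append(ParseError(i, "empty taxon name"))
            continue
        try:
            cover = float(rec[dialect.cover_pct])
        except ValueError:
            errors.append(ParseError(
                i, f"unparseable cover {rec[dialect.cover_pct]!r}"))
            continue
        if not math.isfinite(cover):
            errors.append(ParseError(i, f"non-finite cover {cover!r}"))
            continue
        layer = rec[dialect.layer] if has_layer else None
        rows.append((str(rec[dialect.plot_id]), name, layer or None, cover))
    df = pd.DataFrame(rows, columns=_OBS_COLUMNS)
    return PlotTable(df, parse_errors=errors)


def read_headers(path, dialect: HeaderDialect = HeaderDialect(),
                 delimiter: Optional[str] = None) -> list[PlotHeader]:
    """Load a plot header table; one header per plot id.

    Duplicate plot ids raise; rows with out-of-range coordinates are
    collected as row-level errors and reported in one exception at the end
    (a malformed header table is a hard error, unlike a few bad observation
    rows).  Missing habitat cells yield unlabelled plots.
    """
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                      encoding="utf-8")
    wanted = {"plot_id": dialect.plot_id, "longitude": dialect.longitude,
              "latitude": dialect.latitude}
    _require_columns(raw, wanted, path)
    has_hab = dialect.habitat_code in raw.columns

    headers: list[PlotHeader] = []
    errors: list[ParseError] = []
    seen: set[str] = set()
    for i, rec in enumerate(raw.to_dict("records")):
        pid = str(rec[dialect.plot_id])
        if pid in seen:
            raise ValueError(f"{path}: duplicate plot_id {pid!r}")
        seen.add(pid)
        try:
            lon = float(rec[dialect.longitude])
            lat = float(rec[dialect.latitude])
        except ValueError as exc:
            errors.append(ParseError(i, f"bad coordinate: {exc}"))
            continue
        hab = rec.get(dialect.habitat_code, "").strip() if has_hab else ""
        try:
            headers.append(PlotHeader(pid, lon, lat, hab or None))
        except ValueError as exc:
            errors.append(ParseError(i, str(exc)))
    if errors:
        msgs = "; ".join(f"row {e.row}: {e.message}" for e in errors)
        raise ValueError(f"{path}: invalid header rows — {msgs}")
    return headers


def read_name_records(path, delimiter: Optional[str] = None) -> list[NameRecord]:
    """Load a taxon synonym table (columns input_name, accepted_binomial, rank)."""
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                      encoding="utf-8")
    _require_columns(raw, {"input_name": "input_name", "rank": "rank",
                           "accepted_binomial": "accepted_binomial"}, path)
    records = []
    for rec in raw.to_dict("records"):
        accepted = rec["accepted_binomial"].strip() or None
        records.append(NameRecord(rec["input_name"].strip(), accepted,
                                  rec["rank"].strip()))
    return records


def write_table(table: PlotTable, path, dialect: Dialect = Dialect(),
                delimiter: Optional[str] = None) -> None:
    """Write an observation table; round-trips through :func:`read_observations`."""
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter) if path.suffix else (delimiter or "\t")
    out = table.df.rename(columns={
        "plot_id": dialect.plot_id, "taxon_name": dialect.taxon_name,
        "layer": dialect.layer, "cover_pct": dialect.cover_pct})
    out.to_csv(path, sep=sep, index=False, encoding="utf-8")


def write_headers(headers: Sequence[PlotHeader], path,
                  dialect: HeaderDialect = HeaderDialect(),
                  delimiter: Optional[str] = None) -> None:
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter) if path.suffix else (delimiter or "\t")
    df = pd.DataFrame(
        [(h.plot_id, h.longitude, h.latitude, h.habitat_code or "")
         for h in headers],
        columns=[dialect.plot_id, dialect.longitude, dialect.latitude,
                 dialect.habitat_code])
    df.to_csv(path, sep=sep, index=False, encoding="utf-8")
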