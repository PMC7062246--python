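"""Occurrence ingestion, filtering, and de-duplication.

Cleaning rules: record type restricted to observation/specimen, event
year >= a floor (default 1980), coordinate uncertainty <= a ceiling
(default 30 m, boundary inclusive), removal of records at known
administrative centroids, and per-grid-cell thinning so no two retained
records share a snapped analysis cell.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

RECORD_TYPES = ("observation", "specimen", "other")

#: Default mapping from our field names to DarwinCore-flavoured columns.
DEFAULT_COLUMN_MAP = {
    "species_name": "scientificName",
    "x": "x",
    "y": "y",
    "event_date": "eventDate",
    "record_type": "basisOfRecord",
    "coordinate_uncertainty_m": "coordinateUncertaintyInMeters",
    "source": "source",
}

#: Optional extra column (target-guild background tables carry it).
LIFEFORM_FIELD = "lifeform"


class SchemaError(ValueError):
    """A mapped column is absent from the input table."""


@dataclass
class OccurrenceRecord:
    species_name: str
    x: float
    y: float
    event_date: Optional[date] = None
    record_type: str = "other"
    coordinate_uncertainty_m: Optional[float] = None
    source: str = ""
    lifeform: Optional[str] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("coordinates must be finite")
        if (
            self.coordinate_uncertainty_m is not None
            and self.coordinate_uncertainty_m < 0
        ):
            raise ValueError("coordinate uncertainty must be non-negative")


@dataclass
class OccurrenceSet:
    """Ordered occurrence records plus a per-filter removal log."""

    records: list[OccurrenceRecord]
    crs_id: str = "synthetic-planar"
    filter_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array."""
        return np.array([[r.x, r.y] for r in self.records], dtype=float).reshape(
            -1, 2
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self.records]
        df = pd.DataFrame(
            rows,
            columns=[
                "species_name",
                "x",
                "y",
                "event_date",
                "record_type",
                "coordinate_uncertainty_m",
                "source",
                "lifeform",
            ],
        )
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_filter_log(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.filter_log, fh, indent=2, sort_keys=True)


def _parse_date(value) -> Optional[date]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, date):
        return value
    text = str(value).strip()
    if not text:
        return None
    parsed = pd.to_datetime(text, errors="coerce")
    if pd.isna(parsed):
        return None
    return parsed.date()


def _parse_uncertainty(value) -> Optional[float]:
    if value is None:
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    if math.isnan(out) or out < 0:
        return None
    return out


def _normalize_type(value) -> str:
    text = str(value).strip().lower() if value is not None else ""
    if text in ("observation", "humanobservation", "machineobservation"):
        return "observation"
    if text in ("specimen", "preservedspecimen", "livingspecimen"):
        return "specimen"
    return "other"


def load_occurrences(
    path,
    column_map: Optional[dict[str, str]] = None,
    crs_id: str = "synthetic-planar",
    sep: str = ",",
) -> OccurrenceSet:
    """Load a delimited occurrence table into an :class:`OccurrenceSet`.

    Unparseable dates and uncertainties become null; no rows are dropped
    here.  A mapped column missing from the file raises
    :class:`SchemaError` naming it.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype=str)
    # accept either the mapped (DarwinCore-style) or the native field name
    for fieldname in list(cmap):
        if cmap[fieldname] not in df.columns and fieldname in df.columns:
            cmap[fieldname] = fieldname
    for fieldname in ("species_name", "x", "y"):
        if cmap[fieldname] not in df.columns:
            raise SchemaError(
                f"required column {cmap[fieldname]!r} (mapped to {fieldname}) "
                f"is missing from {path}"
            )
    records = []
    for _, row in df.iterrows():
        get = lambda f: row.get(cmap.get(f, f))  # noqa: E731
        records.append(
            OccurrenceRecord(
                species_name=str(get("species_name")),
                x=float(get("x")),
                y=float(get("y")),
                event_date=_parse_date(get("event_date")),
                record_type=_normalize_type(get("record_type")),
                coordinate_uncertainty_m=_parse_uncertainty(
                    get("coordinate_uncertainty_m")
                ),
                source=str(get("source")) if get("source") is not None else "",
                lifeform=(
                    str(row[cmap.get(LIFEFORM_FIELD, LIFEFORM_FIELD)])
                    if cmap.get(LIFEFORM_FIELD, LIFEFORM_FIELD) in df.columns
                    else None
                ),
            )
        )
    return OccurrenceSet(records, crs_id=crs_id, filter_log={})


def filter_occurrences(
    s: OccurrenceSet,
    min_year: int = 1980,
    max_uncertainty_m: float = 30.0,
    allowed_types: Iterable[str] = ("observation", "specimen"),
    keep_null_uncertainty: bool = False,
    keep_null_date: bool = False,
) -> OccurrenceSet:
    """Apply the type / date / uncertainty filters.

    The retained set is independent of the order the three rules are
    applied; removal counts are attributed to the first failing rule in
    the order type, date, uncertainty.  Null uncertainty (and null date)
    fail their rule unless the corresponding ``keep_null_*`` switch is
    on.
    """
    allowed = set(allowed_types)
    log = dict(s.filter_log)
    retained: list[OccurrenceRecord] = []
    counts = {"record_type": 0, "event_date": 0, "coordinate_uncertainty": 0}
    for rec in s.records:
        if rec.record_type not in allowed:
            counts["record_type"] += 1
            continue
        if rec.event_date is None:
            if not keep_null_date:
                counts["event_date"] += 1
                continue
        elif rec.event_date.year < min_year:
            counts["event_date"] += 1
            continue
        unc = rec.coordinate_uncertainty_m
        if unc is None:
            if not keep_null_uncertainty:
                counts["coordinate_uncertainty"] += 1
                continue
        elif unc > max_uncertainty_m:
            counts["coordinate_uncertainty"] += 1
            continue
        retained.append(rec)
    for key, n in counts.items():
        log[key] = log.get(key, 0) + n
    return OccurrenceSet(retained, crs_id=s.crs_id, filter_log=log)


def deduplicate_and_flag(
    s: OccurrenceSet,
    centroid_points: Sequence[tuple[float, float]] = (),
    centroid_tol_m: float = 100.0,
    snap_cell_m: float = 90.0,
) -> OccurrenceSet:
    """Remove centroid-coincident records, then thin to one per grid cell.

    A record within ``centroid_tol_m`` of any listed centroid is removed.
    Remaining records are snapped to a ``snap_cell_m`` grid
    (``floor(coord / snap_cell_m)``); within a cell the first-encountered
    record wins.
    """
    log = dict(s.filter_log)
    centroids = np.asarray(centroid_points, dtype=float).reshape(-1, 2)
    retained: list[OccurrenceRecord] = []
    n_centroid = 0
    n_dup = 0
    seen: set[tuple[int, int]] = set()
    for rec in s.records:
        if len(centroids):
            d = np.hypot(centroids[:, 0] - rec.x, centroids[:, 1] - rec.y)
            if float(d.min()) <= centroid_tol_m:
                n_centroid += 1
                continue
        key = (
            int(math.floor(rec.x / snap_cell_m)),
            int(math.floor(rec.y / snap_cell_m)),
        )
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        retained.append(rec)
    log["centroid"] = log.get("centroid", 0) + n_centroid
    log["duplicate_cell"] = log.get("duplicate_cell", 0) + n_dup
    return OccurrenceSet(retained, crs_id=s.crs_id, filter_log=log)
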