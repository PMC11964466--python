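"""Readers and writers for site tables, raw-material tables and GeoJSON.

All tables are delimited text with a header; geometries travel as GeoJSON
FeatureCollections. Coordinates are metres in the study's equal-area
projection throughout — GeoJSON files written here are *not* WGS84.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .records import ATTRIBUTION_FLAGS, SiteRecord

SITE_COLUMNS = ("id", "x", "y", "region", "attributions", "evidence")
RAWMAT_COLUMNS = (
    "assemblage_id",
    "site_id",
    "source_x",
    "source_y",
    "share_percent",
    "attributions",
    "single_piece",
)


class FormatError(ValueError):
    """The file does not match the expected table schema."""


class RecordError(ValueError):
    """One or more records are malformed; ids are listed in the message."""


@dataclass
class ReadReport:
    """What happened while reading a site table."""

    n_read: int = 0
    rejected_outside_window: list[str] = field(default_factory=list)
    n_duplicate_coordinates: int = 0

    @property
    def n_accepted(self) -> int:
        return self.n_read - len(self.rejected_outside_window)


def _check_columns(df: pd.DataFrame, required: Sequence[str], path: Any) -> None:
    cols = list(df.columns)
    missing = [c for c in required if c not in cols]
    dupes = {c for c in cols if cols.count(c) > 1}
    if missing or dupes:
        raise FormatError(
            f"{path}: missing columns {missing or 'none'}, duplicate columns {sorted(dupes) or 'none'}"
        )


def read_sites(
    path: str | Path, window: BaseGeometry | None = None, sep: str = ","
) -> tuple[list[SiteRecord], ReadReport]:
    """Read a site table, validating every record.

    Records outside ``window`` are rejected and listed in the report — never
    silently dropped. Exact duplicate coordinates are retained (geometry
    stages deduplicate) but counted in the report.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    _check_columns(df, SITE_COLUMNS, path)

    records: list[SiteRecord] = []
    report = ReadReport(n_read=len(df))
    bad: list[str] = []
    from shapely import prepare
    from shapely.geometry import Point

    if window is not None:
        prepare(window)
    for row in df.itertuples(index=False):
        rid = str(row.id)
        try:
            x, y = float(row.x), float(row.y)
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError
        except ValueError:
            bad.append(rid)
            continue
        attrs = frozenset(a for a in str(row.attributions).split(";") if a)
        try:
            rec = SiteRecord(
                id=rid, x=x, y=y, region=str(row.region),
                attributions=attrs, evidence=str(row.evidence) or "excavation",
            )
        except ValueError as e:
            bad.append(f"{rid} ({e})")
            continue
        if window is not None and not window.covers(Point(x, y)):
            report.rejected_outside_window.append(rid)
            continue
        records.append(rec)
    if bad:
        raise RecordError(f"{path}: malformed records: {', '.join(bad)}")

    seen: set[tuple[float, float]] = set()
    for r in records:
        if (r.x, r.y) in seen:
            report.n_duplicate_coordinates += 1
        seen.add((r.x, r.y))
    return records, report


def sites_to_frame(records: Iterable[SiteRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.id, "x": r.x, "y": r.y, "region": r.region,
            "attributions": ";".join(sorted(r.attributions, key=ATTRIBUTION_FLAGS.index)),
            "evidence": r.evidence,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(SITE_COLUMNS))


def write_sites(records: Iterable[SiteRecord], path: str | Path) -> None:
    sites_to_frame(records).to_csv(path, index=False)


def read_raw_materials(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a raw-material source table (one row per assemblage × source)."""
    df = pd.read_csv(path, sep=sep, dtype={"assemblage_id": str, "site_id": str})
    _check_columns(df, RAWMAT_COLUMNS, path)
    df["share_percent"] = df["share_percent"].astype(float)
    if ((df["share_percent"] <= 0) | (df["share_percent"] > 100)).any():
        bad = df.loc[(df["share_percent"] <= 0) | (df["share_percent"] > 100), "assemblage_id"]
        raise RecordError(f"{path}: share_percent outside (0, 100] for {sorted(set(bad))}")
    df["single_piece"] = df["single_piece"].astype(bool)
    return df


def write_geojson(
    geoms: Iterable[tuple[BaseGeometry, dict[str, Any]]] | Iterable[BaseGeometry],
    path: str | Path,
) -> None:
    """Write geometries (optionally with a properties dict each) as GeoJSON."""
    features = []
    for i, item in enumerate(geoms):
        geom, props = item if isinstance(item, tuple) else (item, {})
        if geom.is_empty:
            pass
        elif not geom.is_valid:
            raise ValueError(f"feature {props.get('id', i)}: invalid geometry")
        features.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_geojson(path: str | Path) -> list[tuple[BaseGeometry, dict[str, Any]]]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        (shape(f["geometry"]), f.get("properties") or {})
        for f in payload["features"]
    ]
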