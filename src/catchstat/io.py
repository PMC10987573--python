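"""Reading, writing and joining community-level tables and region boundaries.

A *community table* holds one row per geographic region (e.g. one of
Chicago's 77 community areas) with a string region id and a mix of numeric
(rates, percentages) and categorical columns.  Boundaries arrive as a
GeoJSON FeatureCollection of WGS84 polygons keyed by the same ids.  All
downstream analysis assumes the invariants enforced here: unique non-empty
ids, explicit NaN missing markers, and no other non-finite sentinels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

#: cell contents (case-insensitive, after stripping) treated as missing on read
MISSING_MARKERS = {"", "na", "nan"}


class CommunityTableError(ValueError):
    """Raised when a table violates the community-table data contract."""


@dataclass
class CommunityTable:
    """Region-indexed variable table, the unit of all analysis.

    Parameters
    ----------
    data : pandas.DataFrame
        Indexed by region id (string). Numeric columns are float dtype with
        NaN marking missing values; everything else is categorical.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index.astype(str).str.strip()
        if (idx == "").any():
            raise CommunityTableError("empty region id")
        dup = idx[idx.duplicated()].unique().tolist()
        if dup:
            raise CommunityTableError(f"duplicate region ids: {dup}")
        self.data = self.data.copy()
        self.data.index = idx
        self.data.index.name = "region_id"
        for col in self.numeric_vars:
            vals = self.data[col].to_numpy(dtype=float)
            if np.isinf(vals).any():
                raise CommunityTableError(f"non-finite values in column {col!r}")

    @property
    def region_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def numeric_vars(self) -> list[str]:
        return [c for c in self.data.columns
                if pd.api.types.is_numeric_dtype(self.data[c])]

    @property
    def categorical_vars(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.numeric_vars]

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, region_ids) -> "CommunityTable":
        """Rows for the given ids, in table order."""
        keep = [r for r in self.region_ids if r in set(region_ids)]
        return CommunityTable(self.data.loc[keep])


@dataclass
class BoundarySet:
    """Region geometries (WGS84 lon/lat polygons), keyed by region id."""

    geometries: dict[str, BaseGeometry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, geom in self.geometries.items():
            if geom is None or geom.is_empty:
                raise CommunityTableError(f"empty geometry for region {rid!r}")
            if geom.geom_type not in ("Polygon", "MultiPolygon"):
                raise CommunityTableError(
                    f"region {rid!r}: geometry type {geom.geom_type} is not polygonal")

    @property
    def region_ids(self) -> list[str]:
        return list(self.geometries)

    def __len__(self) -> int:
        return len(self.geometries)


@dataclass
class JoinReport:
    """Ids present on only one side of a table/boundary join."""

    table_only: list[str]
    boundaries_only: list[str]

    def log_lines(self) -> list[str]:
        lines = []
        for rid in self.table_only:
            lines.append(f"region {rid} present in table only")
        for rid in self.boundaries_only:
            lines.append(f"region {rid} present in boundaries only")
        return lines


def _parse_column(raw: pd.Series) -> pd.Series:
    """Classify a raw string column as numeric or categorical.

    Recognized missing markers become NaN.  A column is numeric when at
    least half of its non-missing cells parse as numbers; unparseable cells
    in a numeric column become missing.
    """
    def _to_float(cell):
        try:
            return float(cell)  # correctly-rounded parse, unlike to_numeric
        except (TypeError, ValueError):
            return np.nan

    stripped = raw.astype("string").str.strip()
    is_missing = stripped.isna() | stripped.str.lower().isin(MISSING_MARKERS)
    parsed = stripped.mask(is_missing).map(_to_float, na_action="ignore")
    parsed = pd.to_numeric(parsed, errors="coerce")
    n_nonmissing = int((~is_missing).sum())
    if n_nonmissing == 0:
        return parsed.astype(float)
    n_parsed = int(parsed.notna().sum())
    if n_parsed * 2 >= n_nonmissing and n_parsed > 0:
        return parsed.astype(float)
    return stripped.mask(is_missing).astype(object)


def read_community_csv(path, id_column: str) -> CommunityTable:
    """Read a community table from a headered CSV file.

    Region ids are stripped of surrounding whitespace; blank/"NA"/"NaN"
    cells (case-insensitive) become missing; numeric columns are parsed as
    floats with unparseable cells turned missing.

    Raises
    ------
    CommunityTableError
        If ``id_column`` is absent or region ids are duplicated/empty.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if id_column not in raw.columns:
        raise CommunityTableError(
            f"id column {id_column!r} not found in {path} "
            f"(columns: {list(raw.columns)})")
    ids = raw[id_column].astype(str).str.strip()
    cols = {c: _parse_column(raw[c]) for c in raw.columns if c != id_column}
    df = pd.DataFrame(cols)
    df.index = ids
    return CommunityTable(df)


def write_community_csv(table: CommunityTable, path) -> None:
    """Write a community table back to CSV (missing values as empty cells)."""
    out = table.data.copy()
    out.to_csv(path, na_rep="")


def read_boundaries(path, id_property: str) -> BoundarySet:
    """Read region boundaries from a GeoJSON FeatureCollection.

    Every feature must carry ``id_property`` in its properties and a
    non-null Polygon or MultiPolygon geometry; the CRS is assumed WGS84.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise CommunityTableError(f"{path}: not a GeoJSON FeatureCollection")
    geoms: dict[str, BaseGeometry] = {}
    for i, feature in enumerate(doc.get("features", [])):
        props = feature.get("properties") or {}
        if id_property not in props or props[id_property] in (None, ""):
            raise CommunityTableError(
                f"feature {i}: missing id property {id_property!r}")
        rid = str(props[id_property]).strip()
        if feature.get("geometry") is None:
            raise CommunityTableError(f"feature {i} (region {rid!r}): null geometry")
        geom = shape(feature["geometry"])
        if rid in geoms:
            raise CommunityTableError(f"duplicate region id in boundaries: {rid!r}")
        geoms[rid] = geom
    return BoundarySet(geoms)


def write_boundaries(boundaries: BoundarySet, path) -> None:
    """Write a BoundarySet as a GeoJSON FeatureCollection."""
    features = []
    for rid, geom in boundaries.geometries.items():
        features.append({
            "type": "Feature",
            "properties": {"region_id": rid},
            "geometry": geom.__geo_interface__,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def join_table_boundaries(
    table: CommunityTable, boundaries: BoundarySet
) -> tuple[pd.DataFrame, dict[str, BaseGeometry], JoinReport]:
    """Inner-join a table with boundaries on region id.

    Returns the joined rows (table order preserved), the matching
    geometries, and a report of ids present on only one side.

    Raises
    ------
    CommunityTableError
        If the id sets are disjoint.
    """
    table_ids = set(table.region_ids)
    boundary_ids = set(boundaries.region_ids)
    common = table_ids & boundary_ids
    if not common:
        raise CommunityTableError("table and boundaries share no region ids")
    report = JoinReport(
        table_only=sorted(table_ids - boundary_ids),
        boundaries_only=sorted(boundary_ids - table_ids),
    )
    for line in report.log_lines():
        logger.info(line)
    keep = [r for r in table.region_ids if r in common]
    joined = table.data.loc[keep]
    geoms = {r: boundaries.geometries[r] for r in keep}
    return joined, geoms, report
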