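"""Occurrence and range-map preparation.

Covers the pre-analysis steps: spatial thinning of occurrence records to one
per grid cell, extraction of the native portion of an expert range map,
conversion of an alien range polygon into an administrative-region checklist,
and biogeographical classification of each record as native, alien (with its
region), or discarded.

Vector data are GeoJSON (read via shapely); occurrences and checklists are
CSV. Records carry no more provenance than (lon, lat, status, region_id).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .env_grid import GridSpec, cell_id

__all__ = [
    "ARCMIN_2_5",
    "OccurrenceRecord",
    "OccurrenceSet",
    "RegionSet",
    "RangeMap",
    "thin_records",
    "filter_native_range",
    "rangemap_to_checklist",
    "classify_records",
    "read_occurrences_csv",
    "read_geojson_features",
    "read_regions_geojson",
    "read_rangemap_geojson",
    "read_checklist_csv",
]

#: 2.5 arc-minutes in degrees — the default thinning-grid resolution,
#: matching typical bioclimatic layer resolution.
ARCMIN_2_5 = 2.5 / 60.0

NATIVE = "native"
ALIEN = "alien"
DISCARDED = "discarded"


@dataclass
class OccurrenceRecord:
    lon: float
    lat: float
    status: str | None = None
    region_id: str | None = None


@dataclass
class OccurrenceSet:
    """Thinned, status-tagged occurrence records for one species."""

    species: str
    records: list[OccurrenceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def coords(self) -> np.ndarray:
        return np.asarray([(r.lon, r.lat) for r in self.records], dtype=float).reshape(
            len(self.records), 2
        )

    def kept(self) -> "OccurrenceSet":
        return OccurrenceSet(
            self.species, [r for r in self.records if r.status != DISCARDED]
        )

    def by_status(self, status: str) -> "OccurrenceSet":
        return OccurrenceSet(self.species, [r for r in self.records if r.status == status])

    def by_region(self) -> dict[str, "OccurrenceSet"]:
        out: dict[str, OccurrenceSet] = {}
        for r in self.records:
            if r.status == ALIEN and r.region_id is not None:
                out.setdefault(r.region_id, OccurrenceSet(self.species)).records.append(r)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "decimalLongitude": [r.lon for r in self.records],
                "decimalLatitude": [r.lat for r in self.records],
                "status": [r.status for r in self.records],
                "region_id": [r.region_id for r in self.records],
            }
        )


@dataclass
class RegionSet:
    """Administrative regions keyed by a unique region_id."""

    regions: dict[str, BaseGeometry]

    def __post_init__(self) -> None:
        repaired = {}
        for rid, geom in self.regions.items():
            if not geom.is_valid:
                geom = shapely.make_valid(geom)
                if not geom.is_valid or geom.is_empty:
                    raise ValueError(f"region {rid!r}: unrepairable geometry")
            repaired[rid] = geom
        self.regions = repaired

    def __len__(self) -> int:
        return len(self.regions)

    def subset(self, region_ids: list[str]) -> "RegionSet":
        return RegionSet({rid: self.regions[rid] for rid in region_ids})


@dataclass
class RangeMap:
    """Expert range map: polygons tagged with a biogeographical status."""

    features: list[tuple[BaseGeometry, str]]

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("range map must contain at least one feature")


def thin_records(
    records: np.ndarray | list[tuple[float, float]],
    grid: GridSpec = GridSpec(ARCMIN_2_5),
    rng_seed: int | np.random.Generator = 0,
    species: str = "species",
) -> OccurrenceSet:
    """Keep one record per occupied grid cell, chosen uniformly at random.

    Thinning at the environmental layers' resolution removes duplicate
    records in the same raster cell, which would otherwise pseudo-replicate
    identical environmental values. The retained record within each cell is
    drawn uniformly under the seed, so upstream sort order cannot leak into
    the result. Idempotent on already-thinned data.
    """
    pts = np.asarray(records, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("no records to thin")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    cells: dict[tuple[int, int], list[int]] = {}
    for i, (lon, lat) in enumerate(pts):
        cells.setdefault(cell_id(lon, lat, grid), []).append(i)
    keep = sorted(
        int(rng.choice(idx)) if len(idx) > 1 else idx[0] for idx in cells.values()
    )
    return OccurrenceSet(
        species, [OccurrenceRecord(lon=pts[i, 0], lat=pts[i, 1]) for i in keep]
    )


def filter_native_range(
    range_map: RangeMap, excluded_statuses: tuple[str, ...] = ("Introduced", "Unknown")
) -> BaseGeometry:
    """Union of range-map features representing the native distribution.

    Features whose biogeographical status is 'Introduced' or 'Unknown' are
    removed; everything else counts as native. The result may be empty,
    signalling that no usable native range exists.
    """
    kept = [geom for geom, status in range_map.features if status not in excluded_statuses]
    if not kept:
        return shapely.Polygon()
    return unary_union(kept)


def rangemap_to_checklist(
    alien_polygons: BaseGeometry,
    admin_regions: RegionSet,
    min_overlap_fraction: float = 0.0,
) -> list[str]:
    """Convert an alien range polygon into a checklist of region ids.

    A region is listed when its intersection with the alien range, as a
    fraction of the region's own area, is at least ``min_overlap_fraction``
    (default 0: any non-degenerate intersection counts). Output is sorted by
    region_id for determinism.
    """
    if alien_polygons.is_empty or not admin_regions.regions:
        raise ValueError("alien polygons and admin regions must be non-empty")
    if not alien_polygons.is_valid:
        alien_polygons = shapely.make_valid(alien_polygons)
        if not alien_polygons.is_valid:
            raise ValueError("unrepairable alien range geometry")
    out = []
    for rid, geom in admin_regions.regions.items():
        inter = geom.intersection(alien_polygons)
        if inter.is_empty or inter.area == 0:
            continue
        if geom.area > 0 and inter.area / geom.area >= min_overlap_fraction:
            out.append(rid)
    return sorted(out)


def classify_records(
    occ: OccurrenceSet,
    native_polygons: BaseGeometry,
    alien_regions: RegionSet,
) -> OccurrenceSet:
    """Tag each thinned record as native, alien (with region) or discarded.

    A record inside the native polygons is native; native takes precedence
    over any alien region it may also fall in. A record inside one or more
    checklist regions (and outside the native range) is alien, assigned to
    the lexicographically smallest containing region_id. Anything else is
    discarded. Containment is boundary-inclusive.
    """
    out = []
    region_items = sorted(alien_regions.regions.items())
    for r in occ.records:
        rec = OccurrenceRecord(lon=r.lon, lat=r.lat)
        if not native_polygons.is_empty and shapely.intersects_xy(
            native_polygons, r.lon, r.lat
        ):
            rec.status = NATIVE
        else:
            rec.status = DISCARDED
            for rid, geom in region_items:
                if shapely.intersects_xy(geom, r.lon, r.lat):
                    rec.status = ALIEN
                    rec.region_id = rid
                    break
        out.append(rec)
    return OccurrenceSet(occ.species, out)


# ---------------------------------------------------------------------------
# External formats

_LON_ALIASES = ("decimallongitude", "longitude", "lon", "x")
_LAT_ALIASES = ("decimallatitude", "latitude", "lat", "y")


def read_occurrences_csv(path: str | Path, species: str | None = None) -> pd.DataFrame:
    """Read an occurrence CSV; Darwin-Core column names accepted as aliases.

    Returns a DataFrame with columns species, decimalLongitude,
    decimalLatitude, filtered to one species when requested.
    """
    df = pd.read_csv(path)
    lower = {c.lower(): c for c in df.columns}
    lon_col = next((lower[a] for a in _LON_ALIASES if a in lower), None)
    lat_col = next((lower[a] for a in _LAT_ALIASES if a in lower), None)
    if lon_col is None or lat_col is None:
        raise ValueError(f"could not find longitude/latitude columns in {path}")
    sp_col = lower.get("species")
    out = pd.DataFrame(
        {
            "species": df[sp_col] if sp_col else "species",
            "decimalLongitude": df[lon_col].astype(float),
            "decimalLatitude": df[lat_col].astype(float),
        }
    )
    if species is not None:
        out = out[out["species"] == species].reset_index(drop=True)
    return out


def read_geojson_features(path: str | Path) -> list[tuple[BaseGeometry, dict]]:
    gj = json.loads(Path(path).read_text())
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    return [(shapely_shape(f["geometry"]), f.get("properties") or {}) for f in feats]


def read_regions_geojson(path: str | Path, id_field: str = "region_id") -> RegionSet:
    regions: dict[str, BaseGeometry] = {}
    for geom, props in read_geojson_features(path):
        rid = str(props[id_field])
        regions[rid] = (
            geom if rid not in regions else unary_union([regions[rid], geom])
        )
    return RegionSet(regions)


def read_rangemap_geojson(path: str | Path, status_field: str = "legend") -> RangeMap:
    return RangeMap(
        [
            (geom, str(props.get(status_field, "Native")))
            for geom, props in read_geojson_features(path)
        ]
    )


def read_checklist_csv(path: str | Path, species: str | None = None) -> list[str]:
    df = pd.read_csv(path, dtype=str)
    if species is not None and "species" in df.columns:
        df = df[df["species"] == species]
    return sorted(df["region_id"].astype(str).unique())
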