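"""Domain types, coordinate-system contract, and layer/table I/O.

All geometric computation in this package happens in a single projected,
metre-based coordinate reference system (in Great Britain this is typically
the British National Grid, EPSG:27700).  Buffer radii are metric lengths, so
layers stored in geographic (degree) coordinates are rejected outright rather
than reprojected silently.

Vector layers are read and written as GeoJSON ``FeatureCollection`` files
carrying a legacy top-level ``crs`` member that names the projected CRS.
Point/weight tables and exposure tables travel as UTF-8 CSV.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import shapely
from shapely.geometry import Point, Polygon, MultiPolygon, shape, mapping
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class PostbufferError(Exception):
    """Base class for all package errors."""


class CoordinateContractError(PostbufferError):
    """A layer violates the projected-metres coordinate contract."""


class SchemaError(PostbufferError):
    """A required attribute/field is missing or malformed."""


class ParameterError(PostbufferError):
    """An operation was called with out-of-domain parameters."""


class GeometryError(PostbufferError):
    """A geometry is invalid beyond repair, or a consistency check failed."""


# ---------------------------------------------------------------------------
# Class catalogue defaults
# ---------------------------------------------------------------------------

#: The 17 broad habitat classes of the national habitat map used as the
#: default land-cover vocabulary, plus the two coastal classes appended when
#: the composite is assembled.
DEFAULT_HABITAT_CLASSES: tuple[str, ...] = (
    "acid, calcareous or neutral grassland",
    "arable and horticulture",
    "bare ground",
    "bare sand",
    "bog",
    "bracken",
    "broadleaved, mixed and yew woodland",
    "built-up areas and gardens",
    "coastal saltmarsh",
    "coastal sand dunes",
    "coniferous woodland",
    "dwarf shrub heath",
    "fen, marsh and swamp",
    "improved grassland",
    "scrub",
    "unclassified",
    "water",
)

ESTUARIES_LABEL = "estuaries"
SEA_LABEL = "sea"
EXCLUSION_LABEL = "out-of-country"
#: Label assigned to any frame area covered by no input layer.  Distinct from
#: the "unclassified" habitat, which is a map class in its own right.
RESIDUAL_LABEL = "residual"

DEFAULT_CLASS_CATALOGUE: tuple[str, ...] = DEFAULT_HABITAT_CLASSES + (
    ESTUARIES_LABEL,
    SEA_LABEL,
)

#: Cross-class overlap tolerance, as a fraction of the smaller feature area.
OVERLAP_REL_TOL = 1e-6
#: Features below this absolute area (m^2) are discarded as slivers.
SLIVER_AREA_M2 = 1e-4


# ---------------------------------------------------------------------------
# Coordinate contract
# ---------------------------------------------------------------------------

_GEOGRAPHIC_CRS_TOKENS = (
    "epsg:4326",
    "crs84",
    "wgs84",
    "wgs 84",
    "longlat",
    "epsg:4258",  # ETRS89 geographic
)


def _crs_is_geographic(crs: str) -> bool:
    name = crs.strip().lower().replace("urn:ogc:def:crs:", "").replace("::", ":")
    return any(tok in name for tok in _GEOGRAPHIC_CRS_TOKENS)


def check_projected_metres(
    crs: str | None, bounds: tuple[float, float, float, float] | None, layer_name: str
) -> None:
    """Enforce the projected-metres contract for one layer.

    A declared geographic CRS is rejected.  When no CRS is declared, a bounds
    heuristic rejects coordinates that fit inside the longitude/latitude
    envelope (almost certainly degrees, never metric site coordinates for the
    landscapes this package handles).
    """
    if crs is not None:
        if _crs_is_geographic(crs):
            raise CoordinateContractError(
                f"layer {layer_name!r} declares geographic CRS {crs!r}; "
                "a projected metre-based CRS is required"
            )
        return
    if bounds is not None:
        minx, miny, maxx, maxy = bounds
        if -180.0 <= minx <= maxx <= 180.0 and -90.0 <= miny <= maxy <= 90.0:
            raise CoordinateContractError(
                f"layer {layer_name!r} has no declared CRS and coordinates that "
                "look like lon/lat degrees; a projected metre-based CRS is required"
            )


def check_shared_crs(*named_layers: tuple[str, str | None]) -> str | None:
    """Check that all declared CRS names agree; returns the common name."""
    declared = {crs for _, crs in named_layers if crs is not None}
    if len(declared) > 1:
        detail = ", ".join(f"{n}={c!r}" for n, c in named_layers)
        raise CoordinateContractError(f"layers use mismatched CRSs: {detail}")
    return next(iter(declared), None)


# ---------------------------------------------------------------------------
# Geometry repair
# ---------------------------------------------------------------------------


def repair_geometry(geom: BaseGeometry, context: str = "") -> BaseGeometry:
    """Repair an invalid polygonal geometry by zero-width buffering.

    Geometries still invalid after repair are rejected; non-polygonal debris
    produced by the repair is dropped.
    """
    if geom.is_valid:
        return geom
    repaired = geom.buffer(0)
    if not repaired.is_valid:
        raise GeometryError(f"geometry {context or '?'} is invalid beyond repair")
    logger.info("repaired invalid geometry %s via zero-width buffer", context or "?")
    return repaired


def _as_polygonal(geom: BaseGeometry) -> BaseGeometry:
    if isinstance(geom, (Polygon, MultiPolygon)):
        return geom
    # GeometryCollection from a repair: keep the polygonal parts only.
    parts = [g for g in getattr(geom, "geoms", []) if isinstance(g, (Polygon, MultiPolygon))]
    if not parts:
        raise GeometryError("geometry has no polygonal component")
    return shapely.unary_union(parts)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class LandCoverFeature:
    geometry: BaseGeometry
    class_label: str


@dataclass
class LandCoverLayer:
    """Classed polygon features in one projected metre-based CRS."""

    features: list[LandCoverFeature]
    class_catalogue: list[str]
    crs: str | None = None

    @classmethod
    def from_features(
        cls,
        features: Iterable[tuple[BaseGeometry, str]],
        crs: str | None = None,
        class_catalogue: Sequence[str] | None = None,
    ) -> "LandCoverLayer":
        feats = [LandCoverFeature(g, c) for g, c in features]
        if class_catalogue is None:
            catalogue: list[str] = []
            for f in feats:
                if f.class_label not in catalogue:
                    catalogue.append(f.class_label)
        else:
            catalogue = list(class_catalogue)
        layer = cls(feats, catalogue, crs)
        layer.validate()
        return layer

    def validate(self) -> None:
        seen = set(self.class_catalogue)
        for i, f in enumerate(self.features):
            if not f.geometry.is_valid:
                f.geometry = repair_geometry(f.geometry, f"feature[{i}]")
            if f.geometry.area < 0:  # pragma: no cover - shapely areas are >= 0
                raise GeometryError(f"feature[{i}] has negative area")
            if f.class_label not in seen:
                raise SchemaError(
                    f"feature[{i}] class {f.class_label!r} not in class_catalogue"
                )
        if self.features:
            check_projected_metres(self.crs, self.bounds(), "land-cover layer")

    def bounds(self) -> tuple[float, float, float, float] | None:
        if not self.features:
            return None
        return shapely.unary_union([f.geometry for f in self.features]).bounds

    def union(self) -> BaseGeometry:
        if not self.features:
            return Polygon()
        return shapely.unary_union([f.geometry for f in self.features])

    def class_areas(self) -> dict[str, float]:
        areas = {c: 0.0 for c in self.class_catalogue}
        for f in self.features:
            areas[f.class_label] += f.geometry.area
        return areas


@dataclass
class LandCoverComposite:
    """A non-overlapping classed tiling of a study frame.

    ``residual_label`` names the class assigned to frame area covered by no
    feature; the residual geometry is derived, never stored.
    """

    layer: LandCoverLayer
    frame: BaseGeometry
    residual_label: str = RESIDUAL_LABEL

    _tree: STRtree | None = field(default=None, repr=False, compare=False)
    _geoms: list[BaseGeometry] | None = field(default=None, repr=False, compare=False)

    @property
    def class_catalogue(self) -> list[str]:
        cat = list(self.layer.class_catalogue)
        if self.residual_label not in cat:
            cat.append(self.residual_label)
        return cat

    def residual_geometry(self) -> BaseGeometry:
        return self.frame.difference(self.layer.union())

    def feature_tree(self) -> tuple[STRtree, list[BaseGeometry]]:
        if self._tree is None:
            self._geoms = [f.geometry for f in self.layer.features]
            self._tree = STRtree(self._geoms)
        return self._tree, self._geoms  # type: ignore[return-value]

    def query_features(self, geom: BaseGeometry) -> list[LandCoverFeature]:
        tree, _ = self.feature_tree()
        idx = tree.query(geom)
        return [self.layer.features[i] for i in sorted(idx)]

    def class_areas(self, include_residual: bool = True) -> dict[str, float]:
        areas = self.layer.class_areas()
        if include_residual:
            areas[self.residual_label] = self.residual_geometry().area
        return areas

    def validate(self) -> None:
        """Check the non-overlap and exact-tiling invariants."""
        feats = self.layer.features
        tree, _ = self.feature_tree()
        for i, f in enumerate(feats):
            for j in tree.query(f.geometry):
                j = int(j)
                if j <= i:
                    continue
                other = feats[j]
                if other.class_label == f.class_label:
                    continue
                inter = f.geometry.intersection(other.geometry).area
                smaller = min(f.geometry.area, other.geometry.area)
                if smaller > 0 and inter > OVERLAP_REL_TOL * smaller:
                    raise GeometryError(
                        f"features {i} ({f.class_label!r}) and {j} "
                        f"({other.class_label!r}) overlap by {inter:.6g} m^2"
                    )
        covered = shapely.unary_union([self.layer.union(), self.residual_geometry()])
        mismatch = covered.symmetric_difference(self.frame).area
        if mismatch > OVERLAP_REL_TOL * self.frame.area:
            raise GeometryError(
                f"composite does not tile its frame (symmetric difference "
                f"{mismatch:.6g} m^2)"
            )


@dataclass
class PostcodeRecord:
    """A postcode point with a domestic-delivery weight and unit membership."""

    postcode_id: str
    location: Point
    delivery_count: int
    unit_id: str

    def __post_init__(self) -> None:
        if self.delivery_count < 0:
            raise SchemaError(
                f"postcode {self.postcode_id!r}: delivery_count must be >= 0"
            )


@dataclass
class StatUnit:
    """A statistical-geography polygon (e.g. an LSOA)."""

    unit_id: str
    boundary: BaseGeometry
    urban_rural: str = "urban"
    region: str = "unassigned"
    area_km2: float | None = None

    def __post_init__(self) -> None:
        self.boundary = repair_geometry(self.boundary, f"unit {self.unit_id!r}")
        geometric = self.boundary.area / 1e6
        if self.area_km2 is None:
            self.area_km2 = geometric
        elif geometric > 0 and abs(self.area_km2 - geometric) > 1e-3 * geometric:
            raise SchemaError(
                f"unit {self.unit_id!r}: declared area {self.area_km2} km^2 "
                f"disagrees with geometry ({geometric:.6g} km^2) beyond 0.1%"
            )


def check_unique_unit_ids(units: Sequence[StatUnit]) -> None:
    seen: set[str] = set()
    for u in units:
        if u.unit_id in seen:
            raise SchemaError(f"duplicate unit_id {u.unit_id!r}")
        seen.add(u.unit_id)


@dataclass
class ExposureTable:
    """Per-unit, per-class percentage covers for one method.

    ``rows`` maps unit_id -> {class_label -> percentage in [0, 100]}; every
    non-missing row sums to 100 (the residual class absorbs gaps).
    ``total_weight`` is populated by the proposed (buffer-weighted) method
    only.
    """

    method: str  # "proposed" | "typical"
    rows: dict[str, dict[str, float]]
    class_catalogue: list[str]
    total_weight: dict[str, int] = field(default_factory=dict)
    missing_units: set[str] = field(default_factory=set)

    def validate(self, atol: float = 1e-6) -> None:
        if self.method not in ("proposed", "typical"):
            raise SchemaError(f"unknown method {self.method!r}")
        for uid, row in self.rows.items():
            total = 0.0
            for c, v in row.items():
                if c not in self.class_catalogue:
                    raise SchemaError(f"row {uid!r}: class {c!r} not in catalogue")
                if not (-atol <= v <= 100 + atol):
                    raise SchemaError(f"row {uid!r}: percentage {v} out of [0, 100]")
                total += v
            if abs(total - 100.0) > atol:
                raise SchemaError(f"row {uid!r} sums to {total!r}, expected 100")

    def unit_ids(self) -> list[str]:
        return sorted(set(self.rows) | self.missing_units)


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

_SUPPORTED_SUFFIXES = (".geojson", ".json")


def _read_feature_collection(path: Path) -> tuple[list[dict], str | None]:
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise SchemaError(
            f"unsupported vector format {path.suffix!r} for {path.name}; "
            "this toolkit reads GeoJSON"
        )
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except OSError as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path} is not valid GeoJSON: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path} is not a GeoJSON FeatureCollection")
    crs = None
    if isinstance(doc.get("crs"), dict):
        crs = doc["crs"].get("properties", {}).get("name")
    return doc.get("features", []), crs


def _write_feature_collection(
    path: Path, features: list[dict], crs: str | None
) -> None:
    doc: dict = {"type": "FeatureCollection", "features": features}
    if crs is not None:
        doc["crs"] = {"type": "name", "properties": {"name": crs}}
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, ensure_ascii=False)
        fh.write("\n")


def read_land_cover(path: str | Path, class_field: str = "class") -> LandCoverLayer:
    """Read a classed polygon layer from GeoJSON."""
    path = Path(path)
    raw, crs = _read_feature_collection(path)
    feats: list[tuple[BaseGeometry, str]] = []
    n_repaired = 0
    for i, f in enumerate(raw):
        props = f.get("properties") or {}
        if class_field not in props:
            raise SchemaError(
                f"{path.name} feature {i}: missing class attribute {class_field!r}"
            )
        geom = shape(f["geometry"])
        if not geom.is_valid:
            geom = repair_geometry(geom, f"{path.name}[{i}]")
            n_repaired += 1
        feats.append((_as_polygonal(geom), str(props[class_field])))
    if n_repaired:
        logger.info("%s: repaired %d invalid geometries", path.name, n_repaired)
    layer = LandCoverLayer.from_features(feats, crs=crs)
    check_projected_metres(crs, layer.bounds(), path.name)
    return layer


def write_land_cover(
    layer: LandCoverLayer, path: str | Path, class_field: str = "class"
) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(f.geometry),
            "properties": {class_field: f.class_label},
        }
        for f in layer.features
    ]
    _write_feature_collection(Path(path), feats, layer.crs)


def read_stat_units(
    path: str | Path,
    id_field: str = "unit_id",
    urban_rural_field: str = "urban_rural",
    region_field: str = "region",
) -> list[StatUnit]:
    """Read statistical-unit polygons from GeoJSON."""
    path = Path(path)
    raw, crs = _read_feature_collection(path)
    units: list[StatUnit] = []
    for i, f in enumerate(raw):
        props = f.get("properties") or {}
        if id_field not in props:
            raise SchemaError(f"{path.name} feature {i}: missing {id_field!r}")
        geom = _as_polygonal(repair_geometry(shape(f["geometry"]), f"{path.name}[{i}]"))
        check_projected_metres(crs, geom.bounds, path.name)
        units.append(
            StatUnit(
                unit_id=str(props[id_field]),
                boundary=geom,
                urban_rural=str(props.get(urban_rural_field, "urban")),
                region=str(props.get(region_field, "unassigned")),
                area_km2=props.get("area_km2"),
            )
        )
    check_unique_unit_ids(units)
    return units


def write_stat_units(units: Sequence[StatUnit], path: str | Path, crs: str | None = None) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(u.boundary),
            "properties": {
                "unit_id": u.unit_id,
                "urban_rural": u.urban_rural,
                "region": u.region,
                "area_km2": u.area_km2,
            },
        }
        for u in units
    ]
    _write_feature_collection(Path(path), feats, crs)


def read_postcodes(
    path: str | Path,
    weight_field: str = "delivery_count",
    unit_field: str = "unit_id",
    id_field: str = "postcode_id",
) -> list[PostcodeRecord]:
    """Read postcode points from CSV (postcode_id,x,y,delivery_count,unit_id)
    or from a GeoJSON point layer."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        records = []
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            cols = reader.fieldnames or []
            for needed in (id_field, "x", "y", weight_field, unit_field):
                if needed not in cols:
                    raise SchemaError(f"{path.name}: missing column {needed!r}")
            for row in reader:
                records.append(
                    PostcodeRecord(
                        postcode_id=row[id_field],
                        location=Point(float(row["x"]), float(row["y"])),
                        delivery_count=int(row[weight_field]),
                        unit_id=row[unit_field],
                    )
                )
        if records:
            xs = [r.location.x for r in records]
            ys = [r.location.y for r in records]
            check_projected_metres(
                None, (min(xs), min(ys), max(xs), max(ys)), path.name
            )
        return records
    raw, crs = _read_feature_collection(path)
    records = []
    for i, f in enumerate(raw):
        props = f.get("properties") or {}
        for needed in (id_field, weight_field, unit_field):
            if needed not in props:
                raise SchemaError(f"{path.name} feature {i}: missing {needed!r}")
        geom = shape(f["geometry"])
        if not isinstance(geom, Point):
            raise SchemaError(f"{path.name} feature {i}: expected Point geometry")
        check_projected_metres(crs, geom.bounds, path.name)
        records.append(
            PostcodeRecord(
                postcode_id=str(props[id_field]),
                location=geom,
                delivery_count=int(props[weight_field]),
                unit_id=str(props[unit_field]),
            )
        )
    return records


def write_postcodes_csv(records: Sequence[PostcodeRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["postcode_id", "x", "y", "delivery_count", "unit_id"])
        for r in records:
            writer.writerow(
                [r.postcode_id, repr(r.location.x), repr(r.location.y),
                 r.delivery_count, r.unit_id]
            )


def read_vector_layer(
    path: str | Path, kind: str, class_field: str = "class", **fields
):
    """Dispatching reader: ``kind`` is one of 'landcover', 'units', 'postcodes'."""
    if kind == "landcover":
        return read_land_cover(path, class_field=class_field)
    if kind == "units":
        return read_stat_units(path, **fields)
    if kind == "postcodes":
        return read_postcodes(path, **fields)
    raise ParameterError(f"unknown layer kind {kind!r}")


# ---------------------------------------------------------------------------
# Exposure table CSV
# ---------------------------------------------------------------------------


def write_exposure_csv(table: ExposureTable, path: str | Path) -> None:
    """Write one row per unit, one column per catalogue class, 6-decimal
    percentages; missing units get empty cells and a 'missing' flag."""
    table.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    classes = list(table.class_catalogue)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["unit_id", "missing", "total_weight", *classes])
        for uid in table.unit_ids():
            if uid in table.missing_units:
                writer.writerow([uid, "1", "", *[""] * len(classes)])
                continue
            row = table.rows[uid]
            weight = table.total_weight.get(uid, "")
            writer.writerow(
                [uid, "0", weight, *[f"{row.get(c, 0.0):.6f}" for c in classes]]
            )


def read_exposure_csv(path: str | Path, method: str) -> ExposureTable:
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:3] != ["unit_id", "missing", "total_weight"]:
            raise SchemaError(f"{path.name}: unexpected exposure-CSV header")
        classes = header[3:]
        rows: dict[str, dict[str, float]] = {}
        weights: dict[str, int] = {}
        missing: set[str] = set()
        for rec in reader:
            uid = rec[0]
            if rec[1] == "1":
                missing.add(uid)
                continue
            if rec[2] != "":
                weights[uid] = int(rec[2])
            rows[uid] = {c: float(v) for c, v in zip(classes, rec[3:])}
    table = ExposureTable(method, rows, classes, weights, missing)
    table.validate(atol=1e-4)  # 6-decimal serialization rounding
    return table
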