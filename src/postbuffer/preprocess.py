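"""Build the non-overlapping land-cover composite.

The study frame is tiled by merging, in precedence order, the habitat map,
the estuaries layer, the out-of-country exclusion layer, and a derived sea
layer.  Later layers are clipped by everything already placed ("merged and
clipped to ensure no overlap"), and any remaining gap is kept as an explicit
residual class so the per-area accounting always closes to 100%.

The sea layer follows the source workflow: buffer the merged land outward by
500 m and subtract the land, leaving a coastal annulus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import shapely
from shapely.geometry import Polygon, MultiPolygon
from shapely.geometry.base import BaseGeometry

from .geodata import (
    EXCLUSION_LABEL,
    SEA_LABEL,
    SLIVER_AREA_M2,
    CoordinateContractError,
    GeometryError,
    LandCoverComposite,
    LandCoverFeature,
    LandCoverLayer,
    ParameterError,
    check_shared_crs,
    repair_geometry,
)

logger = logging.getLogger(__name__)


@dataclass
class ExclusionLayer:
    """Area removed from every denominator (e.g. land beyond the national
    border that a residential buffer can reach)."""

    polygons: BaseGeometry = field(default_factory=MultiPolygon)
    label: str = EXCLUSION_LABEL
    crs: str | None = None

    def __post_init__(self) -> None:
        self.polygons = repair_geometry(self.polygons, f"exclusion {self.label!r}")

    def is_empty(self) -> bool:
        return self.polygons.is_empty

    def as_layer(self) -> LandCoverLayer:
        feats = [] if self.is_empty() else [(self.polygons, self.label)]
        return LandCoverLayer.from_features(feats, crs=self.crs,
                                            class_catalogue=[self.label])


def merge_with_precedence(
    base: LandCoverLayer, additions: list[LandCoverLayer]
) -> LandCoverLayer:
    """Merge layers with strict precedence: base wins everywhere, each
    addition is clipped by the union of base and all earlier additions."""
    check_shared_crs(
        ("base", base.crs), *[(f"addition[{i}]", a.crs) for i, a in enumerate(additions)]
    )
    catalogue = list(base.class_catalogue)
    features = list(base.features)
    occupied = base.union()
    n_slivers = 0
    for layer in additions:
        clipped: list[LandCoverFeature] = []
        for f in layer.features:
            geom = f.geometry.difference(occupied)
            if geom.is_empty:
                continue
            if geom.area < SLIVER_AREA_M2:
                n_slivers += 1
                continue
            clipped.append(LandCoverFeature(geom, f.class_label))
        for c in layer.class_catalogue:
            if c not in catalogue:
                catalogue.append(c)
        features.extend(clipped)
        if clipped or layer.features:
            occupied = shapely.unary_union([occupied, layer.union()])
    if n_slivers:
        logger.info("merge_with_precedence: discarded %d slivers", n_slivers)
    crs = base.crs or next((a.crs for a in additions if a.crs), None)
    return LandCoverLayer(features, catalogue, crs)


def build_sea_layer(
    land: LandCoverLayer, buffer_m: float = 500.0, quad_segs: int = 64
) -> LandCoverLayer:
    """Derive a single-class sea layer as the outward buffer of the merged
    land minus the land itself (a coastal annulus of width ``buffer_m``)."""
    if not land.features:
        raise ParameterError("build_sea_layer: land layer is empty")
    if buffer_m < 0:
        raise ParameterError("build_sea_layer: buffer must be >= 0")
    land_union = land.union()
    if buffer_m == 0:
        return LandCoverLayer.from_features([], crs=land.crs,
                                            class_catalogue=[SEA_LABEL])
    sea = land_union.buffer(buffer_m, quad_segs=quad_segs).difference(land_union)
    return LandCoverLayer.from_features([(sea, SEA_LABEL)], crs=land.crs)


def assemble_composite(
    habitats: LandCoverLayer,
    estuaries: LandCoverLayer | None = None,
    exclusion: ExclusionLayer | None = None,
    sea: LandCoverLayer | None = None,
    frame: BaseGeometry | None = None,
    residual_label: str | None = None,
) -> LandCoverComposite:
    """Assemble the composite with precedence habitats > estuaries >
    exclusion > sea, clip to the frame, and validate the tiling invariants.

    When ``frame`` is omitted it defaults to the union of everything placed,
    so the residual class starts empty.
    """
    additions = []
    if estuaries is not None:
        additions.append(estuaries)
    if exclusion is not None and not exclusion.is_empty():
        additions.append(exclusion.as_layer())
    if sea is not None:
        additions.append(sea)
    merged = merge_with_precedence(habitats, additions)

    if frame is None:
        frame = merged.union()
    frame = repair_geometry(frame, "frame")

    clipped: list[LandCoverFeature] = []
    for f in merged.features:
        geom = f.geometry.intersection(frame)
        if geom.is_empty or geom.area < SLIVER_AREA_M2:
            continue
        clipped.append(LandCoverFeature(geom, f.class_label))
    layer = LandCoverLayer(clipped, merged.class_catalogue, merged.crs)

    kwargs = {} if residual_label is None else {"residual_label": residual_label}
    composite = LandCoverComposite(layer=layer, frame=frame, **kwargs)
    try:
        composite.validate()
    except GeometryError as exc:
        raise GeometryError(f"assembled composite is inconsistent: {exc}") from exc
    return composite
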