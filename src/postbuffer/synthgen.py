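"""Synthetic landscapes, units, and postcodes with known ground truth.

These generators emulate the shape of the real study inputs — a classed
habitat tiling, gridded statistical units whose areas span the urban→rural
size gradient, and clustered postcode points with right-skewed domestic
delivery counts (median 12, mean 17 dwellings per postcode) — so every other
module is testable without licensed national datasets.

The module also provides the Monte-Carlo area oracle (uniform rejection
sampling with binomial standard errors) used to cross-check exact polygon
overlay, and analytic stripe-cover truth from the circular-segment closed
form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, box
from shapely.geometry.base import BaseGeometry

from .geodata import (
    LandCoverComposite,
    LandCoverLayer,
    ParameterError,
    PostcodeRecord,
    StatUnit,
)
from .exposure import BufferCover, halfplane_cover_fraction
from .preprocess import ExclusionLayer, assemble_composite

logger = logging.getLogger(__name__)

#: CRS name stamped on generated layers (projected, metres).
SYNTH_CRS = "EPSG:27700"


@dataclass
class SyntheticScene:
    """A complete synthetic study area, reproducible from seed + parameters.

    ``truth`` carries analytic per-buffer covers where the landscape admits a
    closed form (striped landscapes, buffers fully inside the frame)."""

    composite: LandCoverComposite
    units: list[StatUnit]
    postcodes: list[PostcodeRecord]
    exclusion: ExclusionLayer = field(default_factory=ExclusionLayer)
    truth: dict[str, BufferCover] = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# Landscapes
# ---------------------------------------------------------------------------


def _frame_polygon(frame) -> Polygon:
    if isinstance(frame, BaseGeometry):
        return frame
    minx, miny, maxx, maxy = frame
    return box(minx, miny, maxx, maxy)


def striped_landscape(
    frame,
    stripe_width: float,
    classes: list[str],
    offset: float = 0.0,
) -> LandCoverComposite:
    """Vertical stripes cycling through ``classes``, tiling the frame exactly.

    ``offset`` shifts stripe boundaries rightward (mod stripe_width), letting
    tests place a buffer at a known distance from a class boundary.
    """
    if stripe_width <= 0:
        raise ParameterError("stripe_width must be > 0")
    if not classes:
        raise ParameterError("need at least one class")
    poly = _frame_polygon(frame)
    minx, miny, maxx, maxy = poly.bounds
    # stripe k spans [minx + shift + k*width, +width) with class classes[k % n]
    shift = offset % stripe_width
    k = 0 if shift == 0 else -1
    x = minx + shift + k * stripe_width
    feats: list[tuple[BaseGeometry, str]] = []
    while x < maxx:
        stripe = box(x, miny, x + stripe_width, maxy).intersection(poly)
        if not stripe.is_empty and stripe.area > 0:
            feats.append((stripe, classes[k % len(classes)]))
        x += stripe_width
        k += 1
    layer = LandCoverLayer.from_features(
        feats, crs=SYNTH_CRS, class_catalogue=list(dict.fromkeys(classes))
    )
    composite = LandCoverComposite(layer=layer, frame=poly)
    composite.validate()
    return composite


def stripe_cover_truth(
    center_x: float,
    radius: float,
    stripe_width: float,
    classes: list[str],
    frame_minx: float,
    offset: float = 0.0,
) -> dict[str, float]:
    """Analytic fractional cover of a disc on a striped landscape, by summing
    circular-segment areas between successive stripe boundaries.

    Valid when the disc lies wholly inside the frame vertically and
    horizontally (no frame clipping).
    """
    start = frame_minx + (offset % stripe_width)
    # index of stripe containing the leftmost point of the disc
    first = math.floor((center_x - radius - start) / stripe_width)
    covers: dict[str, float] = {}
    k = first
    while True:
        left = start + k * stripe_width
        right = left + stripe_width
        if left >= center_x + radius:
            break
        # fraction of disc with x >= left minus fraction with x >= right
        frac = halfplane_cover_fraction(left - center_x, radius) - \
            halfplane_cover_fraction(right - center_x, radius)
        if frac > 0:
            label = classes[k % len(classes)]
            covers[label] = covers.get(label, 0.0) + frac
        k += 1
    return covers


def variable_unit_grid(
    frame,
    small_cell: float,
    growth: float,
    n_bands: int,
    urban_area_km2: float = 1.0,
) -> list[StatUnit]:
    """Bands of square units whose cell size grows geometrically band to
    band, emulating the urban→rural size gradient of small statistical
    geographies (areas grow by growth² per band).

    Units with area below ``urban_area_km2`` are flagged urban; regions split
    the frame into West/East halves by centroid.
    """
    if growth <= 1:
        raise ParameterError("growth must be > 1")
    if n_bands < 1 or small_cell <= 0:
        raise ParameterError("need n_bands >= 1 and small_cell > 0")
    poly = _frame_polygon(frame)
    minx, miny, maxx, maxy = poly.bounds
    band_w = (maxx - minx) / n_bands
    midx = (minx + maxx) / 2
    units: list[StatUnit] = []
    for b in range(n_bands):
        cell = small_cell * growth**b
        bx0, bx1 = minx + b * band_w, minx + (b + 1) * band_w
        ncols = max(1, math.ceil((bx1 - bx0) / cell))
        nrows = max(1, math.ceil((maxy - miny) / cell))
        for r in range(nrows):
            for c in range(ncols):
                g = box(
                    bx0 + c * cell,
                    miny + r * cell,
                    min(bx0 + (c + 1) * cell, bx1),
                    min(miny + (r + 1) * cell, maxy),
                )
                g = g.intersection(poly)
                if g.is_empty or g.area <= 0:
                    continue
                area_km2 = g.area / 1e6
                units.append(
                    StatUnit(
                        unit_id=f"b{b}r{r:03d}c{c:03d}",
                        boundary=g,
                        urban_rural="urban" if area_km2 < urban_area_km2 else "rural",
                        region="West" if g.centroid.x < midx else "East",
                    )
                )
    return units


# ---------------------------------------------------------------------------
# Postcodes and delivery counts
# ---------------------------------------------------------------------------


def delivery_count_law(
    n: int, rng: np.random.Generator, median: float = 12.0, mean: float = 17.0
) -> np.ndarray:
    """Right-skewed integer delivery counts: a rounded lognormal calibrated so
    the continuous law has exactly the target median and mean.

    For LN(mu, sigma): median = exp(mu) and mean = exp(mu + sigma²/2), so
    mu = ln(median), sigma = sqrt(2·ln(mean/median)).
    """
    if mean <= median:
        raise ParameterError("right-skew calibration needs mean > median")
    mu = math.log(median)
    sigma = math.sqrt(2.0 * math.log(mean / median))
    draws = rng.lognormal(mu, sigma, size=n)
    return np.maximum(np.rint(draws).astype(int), 0)


def _uniform_points_in(geom: BaseGeometry, n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform points inside a polygon by rejection from its bounding box."""
    minx, miny, maxx, maxy = geom.bounds
    pts = np.empty((0, 2))
    shapely.prepare(geom)
    while pts.shape[0] < n:
        m = max(64, int((n - pts.shape[0]) * 2.5))
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(geom, xs, ys)
        pts = np.vstack([pts, np.column_stack([xs[keep], ys[keep]])])
    return pts[:n]


def clustered_postcodes(
    units: list[StatUnit],
    density_per_km2: float,
    seed: int,
    weight_median: float = 12.0,
    weight_mean: float = 17.0,
) -> list[PostcodeRecord]:
    """Postcode points uniform within each unit, count ~ Poisson(density·area)
    with a minimum of one per unit; delivery counts from the calibrated
    right-skewed law.  Fully reproducible from the seed."""
    if density_per_km2 <= 0:
        raise ParameterError("density must be > 0")
    rng = np.random.default_rng(seed)
    records: list[PostcodeRecord] = []
    for u in sorted(units, key=lambda u: u.unit_id):
        n = max(1, int(rng.poisson(density_per_km2 * u.area_km2)))
        pts = _uniform_points_in(u.boundary, n, rng)
        weights = delivery_count_law(n, rng, weight_median, weight_mean)
        for i in range(n):
            records.append(
                PostcodeRecord(
                    postcode_id=f"{u.unit_id}_p{i:04d}",
                    location=Point(pts[i, 0], pts[i, 1]),
                    delivery_count=int(weights[i]),
                    unit_id=u.unit_id,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Monte-Carlo cover oracle
# ---------------------------------------------------------------------------


@dataclass
class MonteCarloCover:
    """Point-sampling estimate of fractional class cover inside a buffer,
    with per-class binomial standard errors."""

    covers: dict[str, float]
    se: dict[str, float]
    n_effective: int
    usable: bool = True


def montecarlo_cover(
    buffer: BaseGeometry,
    composite: LandCoverComposite,
    exclusion: ExclusionLayer | None,
    n_points: int,
    seed: int,
) -> MonteCarloCover:
    """Estimate buffer cover by uniform rejection sampling: points falling in
    the exclusion layer leave the denominator; unclaimed points count as the
    residual class."""
    if n_points < 1000:
        raise ParameterError("montecarlo_cover: n_points must be >= 1000")
    rng = np.random.default_rng(seed)
    pts = _uniform_points_in(buffer, n_points, rng)
    xs, ys = pts[:, 0], pts[:, 1]

    keep = np.ones(n_points, dtype=bool)
    if exclusion is not None and not exclusion.is_empty():
        shapely.prepare(exclusion.polygons)
        keep = ~shapely.contains_xy(exclusion.polygons, xs, ys)
    m = int(keep.sum())
    if m == 0:
        return MonteCarloCover({}, {}, 0, usable=False)
    xs, ys = xs[keep], ys[keep]

    labels = np.full(m, -1, dtype=int)
    catalogue = composite.class_catalogue
    label_idx = {c: i for i, c in enumerate(catalogue)}
    for feat in composite.query_features(buffer):
        unassigned = labels < 0
        if not unassigned.any():
            break
        shapely.prepare(feat.geometry)
        inside = shapely.contains_xy(feat.geometry, xs[unassigned], ys[unassigned])
        idx = np.flatnonzero(unassigned)[inside]
        labels[idx] = label_idx[feat.class_label]
    labels[labels < 0] = label_idx[composite.residual_label]

    covers, se = {}, {}
    for c, i in label_idx.items():
        p = float(np.mean(labels == i))
        covers[c] = p
        se[c] = math.sqrt(p * (1.0 - p) / m)
    return MonteCarloCover(covers, se, m, usable=True)


# ---------------------------------------------------------------------------
# Scene presets
# ---------------------------------------------------------------------------


def scene_stripes(
    seed: int = 0,
    frame_km: float = 4.0,
    stripe_width_m: float = 400.0,
    classes: tuple[str, ...] = ("improved grassland", "built-up areas and gardens",
                                "broadleaved, mixed and yew woodland"),
    unit_cell_m: float = 1000.0,
    density_per_km2: float = 8.0,
    buffer_radius_m: float = 300.0,
) -> SyntheticScene:
    """Striped landscape on a square frame with a uniform unit grid; analytic
    truth recorded for every postcode whose buffer avoids the frame edge."""
    size = frame_km * 1000.0
    frame = (0.0, 0.0, size, size)
    composite = striped_landscape(frame, stripe_width_m, list(classes))
    units = variable_unit_grid(frame, unit_cell_m, growth=1.0001, n_bands=1)
    postcodes = clustered_postcodes(units, density_per_km2, seed)
    truth: dict[str, BufferCover] = {}
    r = buffer_radius_m
    for rec in postcodes:
        x, y = rec.location.x, rec.location.y
        if r <= x <= size - r and r <= y <= size - r:
            covers = stripe_cover_truth(x, r, stripe_width_m, list(classes), 0.0)
            truth[rec.postcode_id] = BufferCover(
                rec.postcode_id, math.pi * r * r, covers, usable=True
            )
    return SyntheticScene(composite, units, postcodes, ExclusionLayer(),
                          truth, seed)


def scene_urban_rural(
    seed: int = 0,
    frame_km: float = 8.0,
    small_cell_m: float = 400.0,
    growth: float = 3.0,
    n_bands: int = 3,
    stripe_width_m: float = 700.0,
    density_per_km2: float = 6.0,
    exclusion_strip_km: float = 0.5,
) -> SyntheticScene:
    """Urban→rural gradient: unit areas grow geometrically across bands, a
    striped multi-class landscape underneath, and an out-of-country exclusion
    strip along the western edge (so border buffers lose denominator area)."""
    size = frame_km * 1000.0
    strip = exclusion_strip_km * 1000.0
    frame = (0.0, 0.0, size, size)
    composite = striped_landscape(
        frame,
        stripe_width_m,
        ["improved grassland", "built-up areas and gardens",
         "arable and horticulture", "water"],
        offset=137.0,
    )
    units = variable_unit_grid(
        (strip, 0.0, size, size), small_cell_m, growth, n_bands
    )
    postcodes = clustered_postcodes(units, density_per_km2, seed)
    exclusion = ExclusionLayer(box(0.0, 0.0, strip, size), crs=SYNTH_CRS)
    return SyntheticScene(composite, units, postcodes, exclusion, {}, seed)


def random_scene(
    seed: int,
    frame_km: float = 2.0,
    n_classes_range: tuple[int, int] = (2, 5),
) -> tuple[SyntheticScene, BaseGeometry]:
    """A randomized striped scene plus one random 300 m buffer inside the
    frame, for oracle-vs-exact sweeps."""
    rng = np.random.default_rng(seed)
    size = frame_km * 1000.0
    n_classes = int(rng.integers(*n_classes_range, endpoint=True))
    classes = [f"class_{chr(ord('a') + i)}" for i in range(n_classes)]
    width = float(rng.uniform(120.0, 900.0))
    offset = float(rng.uniform(0.0, width))
    composite = striped_landscape((0, 0, size, size), width, classes, offset)
    units = [StatUnit("u0", box(0, 0, size, size))]
    x = float(rng.uniform(350.0, size - 350.0))
    y = float(rng.uniform(350.0, size - 350.0))
    pc = PostcodeRecord("p0", Point(x, y), 10, "u0")
    scene = SyntheticScene(composite, units, [pc], ExclusionLayer(), {}, seed)
    from .exposure import buffer_point

    return scene, buffer_point(Point(x, y), 300.0)
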