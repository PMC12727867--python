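"""Study domain construction, spherical areas, biome assignment, summaries.

The study domain is the union of tropical biome polygons plus a buffer (100 km
by default) to absorb transition zones; buffer distance means kilometers at
all latitudes, so buffering happens in a local sinusoidal projection rather
than in raw degrees.  Areas are computed on a sphere of authalic radius
6371 km.  Per-biome summaries mirror the classic table layout: counts,
percentage shares, densities per 1e5 km2, and the citation:sampling ratio.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .litdb import LiteratureTable, allocate_citations
from .raster import RasterGrid

__all__ = [
    "EARTH_RADIUS_KM",
    "EXTRA_TROPICAL",
    "BiomeUnit",
    "BiomeLayer",
    "StudyDomain",
    "ClipReport",
    "build_domain",
    "compute_area",
    "assign_locations",
    "biome_areas",
    "biome_summary",
    "grid_density",
    "read_biome_layer",
    "write_biome_layer",
    "round_half_away",
]

EARTH_RADIUS_KM = 6371.0
#: Label for the buffer zone outside the core tropical biomes.
EXTRA_TROPICAL = "Extra-tropical other"


@dataclass
class BiomeUnit:
    ecoregion: str
    biome: str
    geometry: BaseGeometry


@dataclass
class BiomeLayer:
    """Ordered collection of (ecoregion, biome, polygon) units, WGS-84 lon/lat."""

    units: list[BiomeUnit]

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("biome layer is empty")
        repaired = []
        for u in self.units:
            if not u.biome:
                raise ValueError("biome_name must be non-empty")
            geom = u.geometry
            if not geom.is_valid:
                geom = shapely.make_valid(geom)
                if not geom.is_valid or geom.is_empty:
                    raise ValueError(
                        f"unit {u.ecoregion!r}: geometry invalid and not repairable"
                    )
            repaired.append(BiomeUnit(u.ecoregion, u.biome, geom))
        self.units = repaired

    @property
    def biomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for u in self.units:
            seen.setdefault(u.biome, None)
        return list(seen)


@dataclass
class StudyDomain:
    core: BaseGeometry
    buffered: BaseGeometry
    buffer_km: float
    total_area_km2: float

    @property
    def extra_tropical(self) -> BaseGeometry:
        return self.buffered.difference(self.core)


class ClipReport(NamedTuple):
    n_input: int
    n_kept: int
    n_dropped: int


# ---------------------------------------------------------------------------
# geodesy
# ---------------------------------------------------------------------------

def _sinusoidal_forward(lon0: float, radius_km: float):
    def fwd(coords: np.ndarray) -> np.ndarray:
        lam = np.deg2rad(coords[:, 0] - lon0)
        phi = np.deg2rad(coords[:, 1])
        return np.column_stack(
            [radius_km * lam * np.cos(phi), radius_km * phi]
        )

    return fwd


def _sinusoidal_inverse(lon0: float, radius_km: float):
    def inv(coords: np.ndarray) -> np.ndarray:
        phi = coords[:, 1] / radius_km
        cos = np.cos(phi)
        cos = np.where(np.abs(cos) < 1e-12, 1e-12, cos)
        lam = coords[:, 0] / (radius_km * cos)
        return np.column_stack([lon0 + np.rad2deg(lam), np.rad2deg(phi)])

    return inv


def _ring_area_sr(coords: np.ndarray) -> float:
    """Unsigned area (steradians) of a ring given in lon/lat degrees.

    Shoelace in the cylindrical equal-area plane (lambda, sin phi); exact for
    edges that run along meridians or parallels, convergent for densified
    diagonal edges.
    """
    lam = np.deg2rad(coords[:, 0])
    sinphi = np.sin(np.deg2rad(coords[:, 1]))
    dlam = np.diff(lam)
    return abs(float(np.sum(dlam * (sinphi[:-1] + sinphi[1:]) / 2.0)))


def compute_area(
    geometry: BaseGeometry,
    radius_km: float = EARTH_RADIUS_KM,
    max_segment_deg: float = 0.1,
) -> float:
    """Spherical area of a geographic polygon, in km2.

    Edges are densified to ``max_segment_deg`` before applying an equal-area
    shoelace; holes are subtracted, multi-part geometries are additive.
    """
    if geometry is None or geometry.is_empty:
        warnings.warn("empty geometry has zero area", stacklevel=2)
        return 0.0
    geometry = shapely.segmentize(geometry, max_segment_deg)
    total = 0.0
    polys = getattr(geometry, "geoms", [geometry])
    for poly in polys:
        if poly.is_empty or poly.geom_type not in ("Polygon",):
            continue
        total += _ring_area_sr(np.asarray(poly.exterior.coords))
        for hole in poly.interiors:
            total -= _ring_area_sr(np.asarray(hole.coords))
    return total * radius_km**2


def _geodesic_buffer(
    geom: BaseGeometry, buffer_km: float, radius_km: float = EARTH_RADIUS_KM
) -> BaseGeometry:
    """Buffer a geographic polygon by a distance in kilometers.

    Projects into a sinusoidal projection centered on the geometry (locally
    length-preserving at tropical latitudes), buffers in km, and projects
    back.
    """
    lon0 = geom.centroid.x
    dense = shapely.segmentize(geom, 0.25)
    fwd = shapely.transform(dense, _sinusoidal_forward(lon0, radius_km))
    buffered = fwd.buffer(buffer_km, quad_segs=16)
    back = shapely.transform(
        shapely.segmentize(buffered, 25.0), _sinusoidal_inverse(lon0, radius_km)
    )
    return shapely.make_valid(back)


def build_domain(
    biomes: BiomeLayer,
    buffer_km: float = 100.0,
    radius_km: float = EARTH_RADIUS_KM,
) -> StudyDomain:
    """Union the tropical biomes and dilate by ``buffer_km`` kilometers."""
    core = shapely.make_valid(unary_union([u.geometry for u in biomes.units]))
    if core.is_empty:
        raise ValueError("biome layer unions to an empty geometry")
    if buffer_km < 0:
        raise ValueError("buffer_km must be >= 0")
    if buffer_km == 0:
        buffered = core
    else:
        buffered = shapely.make_valid(
            unary_union([core, _geodesic_buffer(core, buffer_km, radius_km)])
        )
    return StudyDomain(
        core=core,
        buffered=buffered,
        buffer_km=buffer_km,
        total_area_km2=compute_area(buffered, radius_km),
    )


# ---------------------------------------------------------------------------
# assignment & summaries
# ---------------------------------------------------------------------------

def assign_locations(
    table: LiteratureTable,
    biomes: BiomeLayer,
    domain: StudyDomain,
    reallocate: bool = True,
) -> tuple[LiteratureTable, ClipReport]:
    """Label each location with its ecoregion/biome and clip to the domain.

    Points inside a biome unit take that unit's labels (earliest unit in
    layer order wins ties; boundary points count as inside).  Points in the
    buffer but outside every unit are labeled extra-tropical.  Points outside
    the buffered domain are dropped and counted in the clip report; articles
    left without locations are dropped and citations re-allocated.
    """
    loc = table.locations
    pts = [Point(xy) for xy in zip(loc["longitude"], loc["latitude"])]
    tree = STRtree([u.geometry for u in biomes.units])
    for u in biomes.units:
        shapely.prepare(u.geometry)

    eco = np.full(len(pts), None, dtype=object)
    bio = np.full(len(pts), None, dtype=object)
    kept = np.zeros(len(pts), dtype=bool)
    shapely.prepare(domain.buffered)
    for i, pt in enumerate(pts):
        candidates = sorted(tree.query(pt))
        unit_idx = next(
            (j for j in candidates if biomes.units[j].geometry.covers(pt)), None
        )
        if unit_idx is not None:
            eco[i] = biomes.units[unit_idx].ecoregion
            bio[i] = biomes.units[unit_idx].biome
            kept[i] = True
        elif domain.buffered.covers(pt):
            eco[i] = EXTRA_TROPICAL
            bio[i] = EXTRA_TROPICAL
            kept[i] = True

    locations = loc[kept].reset_index(drop=True).copy()
    locations["ecoregion"] = eco[kept]
    locations["biome"] = bio[kept]
    remaining = locations["article_id"].value_counts()
    articles = table.articles[
        table.articles["article_id"].isin(remaining.index)
    ].reset_index(drop=True)
    articles = articles.assign(
        n_locations=articles["article_id"].map(remaining).astype(int)
    )
    if len(locations) == 0:
        warnings.warn("no locations fall inside the study domain", stacklevel=2)
    out = LiteratureTable(locations, articles, table.provenance)
    if len(locations) and (reallocate or not table.is_allocated):
        out = allocate_citations(out)
    report = ClipReport(len(loc), int(kept.sum()), int((~kept).sum()))
    return out, report


def biome_areas(
    biomes: BiomeLayer,
    domain: StudyDomain,
    radius_km: float = EARTH_RADIUS_KM,
) -> dict[str, float]:
    """Dissolved spherical area per biome plus the extra-tropical buffer, km2."""
    areas: dict[str, float] = {}
    for biome in biomes.biomes:
        geom = unary_union(
            [u.geometry for u in biomes.units if u.biome == biome]
        )
        areas[biome] = compute_area(geom, radius_km)
    extra = domain.extra_tropical
    areas[EXTRA_TROPICAL] = compute_area(extra, radius_km) if not extra.is_empty else 0.0
    return areas


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for printed tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def biome_summary(
    table: LiteratureTable, areas: Mapping[str, float]
) -> pd.DataFrame:
    """Per-biome counts, shares, densities per 1e5 km2, citation:sampling ratio.

    Percentages are computed before rounding; the ratio column is
    pct_citations / pct_locations displayed at 1 decimal (half away from
    zero).  Requires every biome present in the table to have an area.
    """
    loc = table.locations
    if "biome" not in loc.columns:
        raise ValueError("locations must be labeled with biomes (assign_locations)")
    missing = set(loc["biome"]) - set(areas)
    if missing:
        raise ValueError(f"biomes present in table but missing areas: {missing}")

    grouped = loc.groupby("biome")
    n_loc = grouped.size()
    cit = grouped["allocated_citations"].sum()
    order = [b for b in areas if b in n_loc.index or areas[b] > 0]
    total_area = float(sum(areas[b] for b in order))
    total_loc = float(n_loc.sum())
    total_cit = float(cit.sum())

    rows = []
    for b in order:
        nl = float(n_loc.get(b, 0))
        nc = float(cit.get(b, 0.0))
        pct_loc = 100.0 * nl / total_loc if total_loc else 0.0
        pct_cit = 100.0 * nc / total_cit if total_cit else 0.0
        rows.append(
            {
                "biome": b,
                "area_km2": areas[b],
                "pct_area": 100.0 * areas[b] / total_area if total_area else 0.0,
                "n_locations": int(nl),
                "pct_locations": pct_loc,
                "loc_density": nl / (areas[b] / 1e5) if areas[b] > 0 else np.nan,
                "citations": nc,
                "pct_citations": pct_cit,
                "cit_density": nc / (areas[b] / 1e5) if areas[b] > 0 else np.nan,
                "ratio": round_half_away(pct_cit / pct_loc, 1) if pct_loc else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("biome")


def grid_density(
    table: LiteratureTable,
    domain: StudyDomain,
    cell_deg: float = 3.0,
    weight: str = "locations",
    radius_km: float = EARTH_RADIUS_KM,
) -> tuple[RasterGrid, RasterGrid]:
    """Coarse per-cell density of locations or citations over domain land.

    Returns ``(density, counts)`` grids on a lon/lat lattice of ``cell_deg``
    cells snapped to multiples of ``cell_deg``.  Density is the cell's weight
    sum divided by the domain land area falling in the cell (per 1e5 km2);
    cells without domain land are nodata.  Pre-division weight totals are
    conserved.
    """
    if not (360.0 / cell_deg).is_integer():
        raise ValueError("cell_deg must divide 360")
    if weight not in ("locations", "citations"):
        raise ValueError("weight must be 'locations' or 'citations'")
    minx, miny, maxx, maxy = domain.buffered.bounds
    x0 = math.floor(minx / cell_deg) * cell_deg
    y1 = math.ceil(maxy / cell_deg) * cell_deg
    x1 = math.ceil(maxx / cell_deg) * cell_deg
    y0 = math.floor(miny / cell_deg) * cell_deg
    nx = int(round((x1 - x0) / cell_deg))
    ny = int(round((y1 - y0) / cell_deg))

    counts = np.zeros((ny, nx))
    loc = table.locations
    w = (
        np.ones(len(loc))
        if weight == "locations"
        else loc["allocated_citations"].to_numpy(dtype=float)
    )
    col = np.floor((loc["longitude"].to_numpy() - x0) / cell_deg).astype(int)
    row = np.floor((y1 - loc["latitude"].to_numpy()) / cell_deg).astype(int)
    col = np.clip(col, 0, nx - 1)
    row = np.clip(row, 0, ny - 1)
    np.add.at(counts, (row, col), w)

    land = np.full((ny, nx), np.nan)
    shapely.prepare(domain.buffered)
    for r in range(ny):
        for c in range(nx):
            cell = shapely.box(
                x0 + c * cell_deg, y1 - (r + 1) * cell_deg,
                x0 + (c + 1) * cell_deg, y1 - r * cell_deg,
            )
            if not domain.buffered.intersects(cell):
                continue
            area = compute_area(
                domain.buffered.intersection(cell), radius_km, max_segment_deg=0.25
            )
            if area > 0:
                land[r, c] = area
    with np.errstate(invalid="ignore", divide="ignore"):
        density = counts / (land / 1e5)
    grid_kw = dict(x0=x0, y0=y1, dx=cell_deg, dy=cell_deg)
    return (
        RasterGrid(density, name=f"{weight}_density", units="per 1e5 km2", **grid_kw),
        RasterGrid(counts, name=f"{weight}_count", units="count", **grid_kw),
    )


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

def read_biome_layer(
    path, eco_field: str = "ECO_NAME", biome_field: str = "BIOME_NAME"
) -> BiomeLayer:
    """Read biome/ecoregion polygons from a GeoJSON FeatureCollection."""
    doc = json.loads(Path(path).read_text())
    units = []
    for feat in doc["features"]:
        props = feat.get("properties", {})
        units.append(
            BiomeUnit(
                ecoregion=str(props.get(eco_field, "")),
                biome=str(props.get(biome_field, "")),
                geometry=shape(feat["geometry"]),
            )
        )
    return BiomeLayer(units)


def write_biome_layer(
    layer: BiomeLayer, path,
    eco_field: str = "ECO_NAME", biome_field: str = "BIOME_NAME",
) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {eco_field: u.ecoregion, biome_field: u.biome},
            "geometry": mapping(u.geometry),
        }
        for u in layer.units
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
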