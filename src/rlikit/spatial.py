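"""Equal-area grid aggregation: richness maps and dominant-driver maps.

Species ranges (polygons in geographic coordinates, or pre-computed
species-cell pairs) are binned onto a square grid in a Behrmann
world cylindrical equal-area projection, so every cell covers the same
ground area.  Two presets match common map resolutions: 865 km² cells for
richness maps and 7,775 km² cells for driver maps.

Per-cell products:

* richness and its 10-quantile class (class 1 = sparsest decile of
  occupied cells, class 10 = richest);
* the dominant primary driver of status deteriorations among the cell's
  species, with a tie flag when exactly two drivers are joint-dominant
  (maps show an intermediate colour) and a star flag when the dominant
  attribution is undetermined or numerous (or three or more drivers tie).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .backcast import ChangeDirection, ChangeRecord, DriverGroup

__all__ = [
    "GridSpec",
    "GridIncidence",
    "CellDriver",
    "build_incidence",
    "incidence_from_pairs",
    "incidence_from_geojson",
    "richness_quantiles",
    "dominant_driver",
]

# Authalic Earth radius (km): preserves total area under the projection.
_EARTH_RADIUS_KM = 6371.0072
_BEHRMANN_STD_PARALLEL = math.radians(30.0)


def _project(lon: float, lat: float) -> tuple[float, float]:
    """Behrmann equal-area projection, km east/north of (0, 0)."""
    k = math.cos(_BEHRMANN_STD_PARALLEL)
    x = _EARTH_RADIUS_KM * math.radians(lon) * k
    y = _EARTH_RADIUS_KM * math.sin(math.radians(lat)) / k
    return x, y


@dataclass(frozen=True)
class GridSpec:
    """Square equal-area grid definition.

    ``cell_area`` is in km²; presets 865 and 7,775 correspond to the two
    published map resolutions. The grid origin sits at the projection of
    (lon 0, lat 0); cell ids are ``(col, row)`` index pairs.
    """

    cell_area: float = 865.0

    def __post_init__(self) -> None:
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")

    @property
    def cell_size(self) -> float:
        return math.sqrt(self.cell_area)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        x, y = _project(lon, lat)
        s = self.cell_size
        return (math.floor(x / s), math.floor(y / s))

    def cell_centroid_lonlat(self, cell: tuple[int, int]) -> tuple[float, float]:
        s = self.cell_size
        x = (cell[0] + 0.5) * s
        y = (cell[1] + 0.5) * s
        k = math.cos(_BEHRMANN_STD_PARALLEL)
        lon = math.degrees(x / (_EARTH_RADIUS_KM * k))
        lat = math.degrees(math.asin(max(-1.0, min(1.0, y * k / _EARTH_RADIUS_KM))))
        return lon, lat


@dataclass
class GridIncidence:
    """Species-by-cell occurrence with derived per-cell summaries."""

    grid: GridSpec
    cells: dict = field(default_factory=dict)  # cell_id -> set[str]
    n_skipped_features: int = 0

    def add(self, species_id: str, cell_id) -> None:
        self.cells.setdefault(cell_id, set()).add(species_id)

    def richness(self) -> dict:
        return {cell: len(s) for cell, s in self.cells.items()}

    def species_cells(self, species_id: str) -> set:
        return {cell for cell, s in self.cells.items() if species_id in s}


def incidence_from_pairs(
    pairs: Iterable[tuple[str, object]], grid: Optional[GridSpec] = None
) -> GridIncidence:
    """Ingest (species_id, cell_id) pairs; duplicates collapse."""
    inc = GridIncidence(grid=grid or GridSpec())
    for species_id, cell_id in pairs:
        inc.add(species_id, cell_id)
    return inc


def incidence_from_geojson(
    geojson: Union[str, dict],
    grid: GridSpec,
    species_property: str = "species_id",
    presence_filter: bool = True,
) -> GridIncidence:
    """Rasterize a GeoJSON FeatureCollection of range polygons.

    Each feature's polygon is projected to the equal-area plane and every
    grid cell it intersects records the species.  With
    ``presence_filter``, features carrying explicit ``presence`` or
    ``origin`` attributes are kept only when extant (presence 1-3) and
    native/reintroduced (origin 1-2); features without the attributes
    always count.  Invalid geometries are skipped with a warning and
    counted in ``n_skipped_features``.
    """
    from shapely.geometry import box, shape
    from shapely.ops import transform
    from shapely.validation import explain_validity

    if isinstance(geojson, str):
        geojson = json.loads(geojson)
    inc = GridIncidence(grid=grid)
    s = grid.cell_size
    for feature in geojson.get("features", []):
        props = feature.get("properties") or {}
        species_id = props.get(species_property)
        if species_id is None:
            warnings.warn("feature without species id skipped", stacklevel=2)
            inc.n_skipped_features += 1
            continue
        if presence_filter:
            presence = props.get("presence")
            origin = props.get("origin")
            if presence is not None and presence not in (1, 2, 3):
                continue
            if origin is not None and origin not in (1, 2):
                continue
        try:
            geom = shape(feature["geometry"])
            if not geom.is_valid:
                raise ValueError(explain_validity(geom))
        except Exception as exc:  # malformed geometry: skip, count, report
            warnings.warn(f"invalid geometry for {species_id}: {exc}", stacklevel=2)
            inc.n_skipped_features += 1
            continue
        proj = transform(lambda xs, ys: _project_arrays(xs, ys), geom)
        minx, miny, maxx, maxy = proj.bounds
        c0, c1 = math.floor(minx / s), math.floor(maxx / s)
        r0, r1 = math.floor(miny / s), math.floor(maxy / s)
        for col in range(c0, c1 + 1):
            for row in range(r0, r1 + 1):
                cell = box(col * s, row * s, (col + 1) * s, (row + 1) * s)
                if proj.intersects(cell) and not proj.touches(cell):
                    inc.add(str(species_id), (col, row))
    return inc


def _project_arrays(xs, ys):
    import numpy as np

    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    k = math.cos(_BEHRMANN_STD_PARALLEL)
    return (
        _EARTH_RADIUS_KM * np.radians(xs) * k,
        _EARTH_RADIUS_KM * np.sin(np.radians(ys)) / k,
    )


def build_incidence(
    source: Union[Iterable[tuple[str, object]], dict, str],
    grid: Optional[GridSpec] = None,
) -> GridIncidence:
    """Build incidence from either species-cell pairs or GeoJSON ranges."""
    if isinstance(source, (dict, str)):
        if grid is None:
            raise ValueError("polygon mode requires an explicit GridSpec")
        return incidence_from_geojson(source, grid)
    return incidence_from_pairs(source, grid)


def richness_quantiles(incidence: GridIncidence, k: int = 10) -> dict:
    """Class occupied cells 1..k by richness quantiles.

    Boundaries are the i/k quantiles of the occupied-cell richness
    distribution; a cell's class is 1 plus the number of boundaries
    strictly below its richness, so ties share a class and a value sitting
    exactly on a boundary takes the lower class.  With fewer distinct
    richness values than k some classes are empty (merged); a warning
    reports it.
    """
    import numpy as np

    rich = incidence.richness()
    if not rich:
        raise ValueError("no occupied cells")
    values = np.array(sorted(rich.values()), dtype=float)
    cuts = np.quantile(values, [i / k for i in range(1, k)])
    classes = {cell: 1 + int(np.sum(cuts < r)) for cell, r in rich.items()}
    if len(set(rich.values())) < k:
        warnings.warn("quantile classes merged (few distinct richness values)", stacklevel=2)
    return classes


@dataclass(frozen=True)
class CellDriver:
    drivers: tuple[DriverGroup, ...]
    tie_flag: bool
    star_flag: bool
    n_species: int


def dominant_driver(
    incidence: GridIncidence,
    changes: Sequence[ChangeRecord],
    interval: tuple[int, int],
) -> dict:
    """Per-cell dominant primary driver of deteriorations in one interval.

    The cell's label is the driver group attributed to the most
    deteriorated species present in the cell.  A two-way tie keeps both
    labels with ``tie_flag`` (intermediate colour); three or more tied
    drivers, or a dominant attribution of undetermined/numerous, set
    ``star_flag``.  Cells with no deteriorated species are absent from the
    result.
    """
    driver_of: dict[str, DriverGroup] = {}
    for c in changes:
        if (
            c.genuine
            and c.interval == interval
            and c.direction is ChangeDirection.DETERIORATION
        ):
            driver_of[c.species_id] = c.driver_group or DriverGroup.UNDETERMINED

    out: dict = {}
    for cell, species in sorted(incidence.cells.items(), key=lambda kv: str(kv[0])):
        tallies: dict[DriverGroup, int] = {}
        n = 0
        for sp in species:
            d = driver_of.get(sp)
            if d is None:
                continue
            tallies[d] = tallies.get(d, 0) + 1
            n += 1
        if not tallies:
            continue
        top = max(tallies.values())
        winners = tuple(sorted((d for d, v in tallies.items() if v == top), key=lambda d: d.value))
        tie = len(winners) == 2
        star = len(winners) > 2 or any(
            w in (DriverGroup.UNDETERMINED, DriverGroup.NUMEROUS) for w in winners
        )
        out[cell] = CellDriver(drivers=winners, tie_flag=tie, star_flag=star, n_species=n)
    return out
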