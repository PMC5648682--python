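"""Breeding-territory modelling by Dirichlet (Voronoi) tessellation.

Occupied nest boxes of one breeding season are tessellated into territory
tiles; per-tile diameters give the annual mean territory diameter and its
normal-theory 95% CI.  The upper CI limit is the dispersed/nondispersed
threshold: an individual that moved a distance equal to or longer than the
threshold is classified as dispersed.  Distances can also be expressed in
territory units (distance / mean territory diameter) for cross-site
comparisons.

Unbounded outer Voronoi cells are clipped to a study region; by default the
convex hull of all boxes buffered outward by half the median nearest-
neighbour spacing.  Tile diameter is, by default, the diameter of the circle
of equal area (2*sqrt(area/pi)), which is robust to sliver vertices of
clipped cells; the maximum vertex-to-vertex distance is available as an
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import MultiPoint, Polygon

__all__ = [
    "TessellationError",
    "TerritoryModel",
    "default_clip_region",
    "tessellate_territories",
    "diameter_stats",
    "classify_dispersal",
    "to_territory_units",
    "territory_models_by_year",
]

DISPERSED = "dispersed"
NONDISPERSED = "nondispersed"


class TessellationError(ValueError):
    """Raised when a valid tessellation cannot be built."""


@dataclass
class TerritoryModel:
    """Per-year Voronoi territory model of the occupied boxes."""

    site: str
    year: int | None
    tiles: dict  # box_id -> shapely Polygon (clipped)
    diameters_m: np.ndarray
    mean_diameter_m: float
    se_diameter_m: float
    ci95_upper_m: float


def default_clip_region(boxes: pd.DataFrame) -> Polygon:
    """Habitat-aware clip region built from the nest-box pattern itself.

    Boxes are grouped into spatial clusters (single-linkage components at
    2.5x the median nearest-neighbour spacing); each cluster contributes its
    convex hull buffered by half the median spacing, and the clip region is
    the union.  On a continuous layout this reduces to one buffered hull; on
    a fragmented layout it excludes the open matrix between patches, where
    no territory can lie.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial import cKDTree
    from shapely.ops import unary_union

    from raydisp.synthetic import nearest_neighbour_distances

    xy = boxes[["x_m", "y_m"]].to_numpy(float)
    nn = nearest_neighbour_distances(boxes)
    buffer = 0.5 * float(np.median(nn)) if len(nn) else 1.0
    if len(xy) < 3:
        return MultiPoint(xy).buffer(buffer)
    link = 2.5 * float(np.median(nn))
    pairs = cKDTree(xy).query_pairs(link, output_type="ndarray")
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
        shape=(len(xy), len(xy)),
    )
    n_comp, labels = connected_components(adj, directed=False)
    parts = []
    for c in range(n_comp):
        pts = MultiPoint(xy[labels == c])
        parts.append(pts.convex_hull.buffer(buffer))
    return unary_union(parts)


def tessellate_territories(
    occupied: pd.DataFrame,
    clip_region: Polygon,
    site: str = "SITE",
    year: int | None = None,
    diameter_method: str = "equal_area",
) -> TerritoryModel:
    """Tessellate the occupied boxes into clipped territory tiles.

    ``occupied`` needs columns box_id, x_m, y_m; at least three non-collinear
    boxes are required.  Outer cells are intersected with ``clip_region`` so
    that the tiles partition the clip region.
    """
    xy = occupied[["x_m", "y_m"]].to_numpy(float)
    if len(xy) < 3:
        raise TessellationError(
            f"need >= 3 occupied boxes to tessellate, got {len(xy)}"
        )
    centred = xy - xy.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-8 * max(1.0, np.abs(centred).max())) < 2:
        raise TessellationError("occupied boxes are collinear; tessellation undefined")
    if diameter_method not in ("equal_area", "max_vertex"):
        raise ValueError(f"unknown diameter_method {diameter_method!r}")

    # Ghost points far outside the clip region bound every real cell, so each
    # region can be read off scipy's Voronoi diagram as a finite polygon.
    minx, miny, maxx, maxy = clip_region.bounds
    cx, cy = (minx + maxx) / 2.0, (miny + maxy) / 2.0
    radius = 100.0 * max(maxx - minx, maxy - miny, 1.0)
    theta = np.linspace(0.0, 2.0 * np.pi, 16, endpoint=False)
    ghosts = np.c_[cx + radius * np.cos(theta), cy + radius * np.sin(theta)]
    vor = Voronoi(np.vstack([xy, ghosts]))

    tiles: dict[str, Polygon] = {}
    diams = []
    for i, box_id in enumerate(occupied["box_id"]):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:  # pragma: no cover - ghosts prevent this
            raise TessellationError(f"unbounded cell for box {box_id!r}")
        poly = Polygon(vor.vertices[region]).intersection(clip_region)
        if poly.is_empty:
            raise TessellationError(f"tile for box {box_id!r} outside clip region")
        tiles[box_id] = poly
        if diameter_method == "equal_area":
            diams.append(2.0 * np.sqrt(poly.area / np.pi))
        else:
            from shapely import get_coordinates

            verts = get_coordinates(poly)
            d2 = ((verts[:, None, :] - verts[None, :, :]) ** 2).sum(-1)
            diams.append(float(np.sqrt(d2.max())))

    diams = np.asarray(diams, dtype=float)
    mean, se, upper = diameter_stats(diams)
    return TerritoryModel(site, year, tiles, diams, mean, se, upper)


def diameter_stats(diameters) -> tuple[float, float, float]:
    """Mean, standard error and upper 95% CI limit (mean + 1.96*se)."""
    d = np.asarray(diameters, dtype=float)
    if d.size < 2:
        raise ValueError("need >= 2 territory diameters for a standard error")
    mean = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(d.size))
    return mean, se, mean + 1.96 * se


def classify_dispersal(distance_m: float, threshold_m: float) -> str:
    """'dispersed' iff the distance equals or exceeds the threshold."""
    if distance_m < 0:
        raise ValueError("distance_m must be >= 0")
    return DISPERSED if distance_m >= threshold_m else NONDISPERSED


def to_territory_units(distance_m: float, mean_diameter_m: float) -> float:
    """Distance expressed in territory units, rounded to two decimals."""
    if not mean_diameter_m > 0:
        raise ValueError("mean_diameter_m must be > 0")
    return round(distance_m / mean_diameter_m, 2)


def territory_models_by_year(
    captures: pd.DataFrame,
    boxes: pd.DataFrame,
    clip_region: Polygon | None = None,
    site: str | None = None,
    diameter_method: str = "equal_area",
) -> dict[int, TerritoryModel]:
    """One territory model per year from the boxes holding breeding adults.

    Years whose occupation pattern cannot be tessellated (fewer than three
    non-collinear occupied boxes) are skipped.
    """
    if clip_region is None:
        clip_region = default_clip_region(boxes)
    if site is None:
        site = str(boxes["site"].iloc[0]) if "site" in boxes else "SITE"
    coords = boxes.set_index("box_id")[["x_m", "y_m"]]
    models: dict[int, TerritoryModel] = {}
    adults = captures[captures["stage"] == "adult"]
    for year, grp in adults.groupby("year"):
        occ = (
            grp[["box_id"]].drop_duplicates().join(coords, on="box_id")
            .rename(columns={"x_m": "x_m", "y_m": "y_m"})
        )
        try:
            models[int(year)] = tessellate_territories(
                occ, clip_region, site=site, year=int(year),
                diameter_method=diameter_method,
            )
        except TessellationError:
            continue
    return models
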