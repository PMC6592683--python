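"""Voronoï-tessellation-based nanodomain detection from pooled localizations.

The plane is partitioned into one Voronoï polygon per localization; the
inverse of neighbourhood polygon area is a local density estimator.  The
first-rank density of localization *i* averages over its Voronoï neighbours:

    δ_i = (1 + |N_i|) / (A_i + Σ_{j∈N_i} A_j)

Objects (e.g. the cell outline) are connected components of localizations
whose density exceeds a multiple of the global average; nanodomains are
connected components *within* an object whose density exceeds
``density_factor`` (default 2) times the object's mean density and that hold
at least ``min_detections`` (default 50) localizations.  Domain diameter is
estimated by principal component analysis of member coordinates and the area
from the merged member-polygon outline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Voronoi
from shapely.geometry import Polygon
from shapely.ops import unary_union

#: recorded in output metadata: diameter = 2·√2·√(λ1+λ2) over the PCA
#: eigenvalues λ of the member coordinates — equals the true diameter for a
#: uniformly filled disc and 4σ for an isotropic Gaussian cluster.
PCA_DIAMETER_CONVENTION = "2*sqrt(2)*sqrt(lambda1+lambda2)"


@dataclass
class TessellationMap:
    points: np.ndarray  # (n, 2) μm
    areas: np.ndarray  # polygon area per localization; 0 where unbounded
    unbounded: np.ndarray  # bool mask
    density: np.ndarray  # first-rank density δ, μm⁻²; 0 where unbounded
    avg_density: float  # bounded localizations per unit field area
    neighbors: list  # adjacency lists (Voronoï ridge sharing)
    cell_polygons: list = field(repr=False, default=None)
    field_area: float = 0.0


def tessellate(points: np.ndarray, rank: int = 1, field=None) -> TessellationMap:
    """Voronoï tessellation with first-rank neighbour-averaged densities.

    ``field`` is the acquisition field of view — a shapely polygon, a
    ``(minx, miny, maxx, maxy)`` tuple, or None (convex hull of the points).
    The global average density is the number of bounded localizations per
    unit field area; a cell footprint inside a larger (emptier) field
    therefore sits well above the average, which is what lets object
    segmentation recover the whole footprint.  ``rank=0`` gives the bare
    inverse-polygon-area density instead of the neighbour-averaged one.
    Duplicate points are perturbed by ≤1e-9 μm with a warning; fewer than 4
    non-collinear points are rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = pts.shape[0]
    if n < 4:
        raise ValueError("tessellation needs at least 4 points")
    spans = pts.max(axis=0) - pts.min(axis=0)
    _, s, _ = np.linalg.svd(pts - pts.mean(axis=0), full_matrices=False)
    if s[-1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("all points are collinear")
    _, first_idx, counts = np.unique(pts, axis=0, return_index=True, return_counts=True)
    if np.any(counts > 1):
        warnings.warn(f"{int((counts > 1).sum())} duplicate point(s) perturbed by <=1e-9 um")
        rng = np.random.default_rng(0)
        dup_mask = np.ones(n, dtype=bool)
        dup_mask[first_idx] = False
        pts = pts.copy()
        pts[dup_mask] += rng.uniform(-1e-9, 1e-9, size=(int(dup_mask.sum()), 2))

    if field is None:
        from shapely.geometry import MultiPoint

        field_poly = MultiPoint(pts).convex_hull
    elif isinstance(field, (tuple, list)):
        minx, miny, maxx, maxy = field
        field_poly = Polygon([(minx, miny), (maxx, miny), (maxx, maxy), (minx, maxy)])
    else:
        field_poly = field

    vor = Voronoi(pts)
    areas = np.zeros(n)
    unbounded_mask = np.zeros(n, dtype=bool)
    polys: list = [None] * n
    for i in range(n):
        reg = vor.regions[vor.point_region[i]]
        if len(reg) == 0 or -1 in reg:
            # infinite cell: convex-hull boundary point
            unbounded_mask[i] = True
            continue
        poly = Polygon(vor.vertices[reg])
        if not poly.is_valid or poly.area <= 0:
            unbounded_mask[i] = True
            continue
        clipped = poly.intersection(field_poly)  # bound cells by the field of view
        if clipped.is_empty or clipped.area <= 0:
            unbounded_mask[i] = True
            continue
        areas[i] = clipped.area
        polys[i] = clipped

    neighbors: list[list[int]] = [[] for _ in range(n)]
    for a, b in vor.ridge_points:
        neighbors[a].append(int(b))
        neighbors[b].append(int(a))

    density = np.zeros(n)
    bounded = ~unbounded_mask
    if rank == 0:
        density[bounded] = 1.0 / areas[bounded]
    else:
        for i in np.nonzero(bounded)[0]:
            nb = [j for j in neighbors[i] if bounded[j]]
            density[i] = (1 + len(nb)) / (areas[i] + areas[nb].sum())
    field_area = float(field_poly.area)
    avg = float(bounded.sum() / field_area) if field_area > 0 else 0.0
    return TessellationMap(
        points=pts,
        areas=areas,
        unbounded=unbounded_mask,
        density=density,
        avg_density=avg,
        neighbors=neighbors,
        cell_polygons=polys,
        field_area=field_area,
    )


def _components(selected: np.ndarray, neighbors: list) -> list[np.ndarray]:
    """Connected components (Voronoï adjacency) of the selected localizations."""
    idx = np.nonzero(selected)[0]
    if idx.size == 0:
        return []
    pos = -np.ones(len(selected), dtype=np.int64)
    pos[idx] = np.arange(idx.size)
    rows, cols = [], []
    for i in idx:
        for j in neighbors[i]:
            if selected[j]:
                rows.append(pos[i])
                cols.append(pos[j])
    adj = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(idx.size, idx.size)
    )
    n_comp, lab = connected_components(adj, directed=False)
    return [idx[lab == c] for c in range(n_comp)]


@dataclass
class SegmentedObject:
    members: np.ndarray  # localization indices
    outline: object  # shapely (Multi)Polygon
    area: float
    mean_density: float  # detections per μm² of outline area


def segment_objects(
    tmap: TessellationMap, object_factor: float = 1.0, min_members: int = 10
) -> list[SegmentedObject]:
    """Density-thresholded connected components forming contiguous objects.

    Localizations with δ ≥ ``object_factor`` × global average density are
    merged by Voronoï adjacency into component cores; each core is then
    closed with its directly adjacent below-threshold cells, so the object
    is the full contiguous footprint (a cell's rim localizations have
    genuinely lower local density but belong to the contour).  Components
    under ``min_members`` members are discarded.  The outline is the union
    of the member Voronoï polygons; the object's mean density is its member
    count per outline area.
    """
    sel = (tmap.density >= object_factor * tmap.avg_density) & ~tmap.unbounded
    cores = _components(sel, tmap.neighbors)
    cores.sort(key=lambda c: (-c.size, c.min() if c.size else 0))
    claimed = sel.copy()  # cells already belonging to some object
    objs = []
    for core in cores:
        ext = {
            j
            for i in core
            for j in tmap.neighbors[i]
            if not claimed[j] and not tmap.unbounded[j]
        }
        claimed[list(ext)] = True
        members = np.sort(np.concatenate([core, np.fromiter(ext, dtype=np.int64, count=len(ext))]))
        if members.size < min_members:
            continue
        outline = unary_union([tmap.cell_polygons[i] for i in members])
        area = float(outline.area)
        objs.append(
            SegmentedObject(
                members=members,
                outline=outline,
                area=area,
                mean_density=members.size / area if area > 0 else 0.0,
            )
        )
    objs.sort(key=lambda o: -o.members.size)
    return objs


@dataclass
class Nanodomain:
    members: np.ndarray
    centroid: np.ndarray  # μm
    diameter_nm: float
    area_um2: float
    mean_density: float
    host_object: int = -1
    host_roi: object = None
    diameter_convention: str = PCA_DIAMETER_CONVENTION


def nanodomain_geometry(
    coords: np.ndarray, cell_polygons: list | None = None, clip_to=None
) -> tuple[float, float]:
    """(diameter nm, area μm²) of a set of member localizations.

    Diameter: PCA — 2·√2·√(λ1+λ2) over the eigenvalues of the coordinate
    covariance, converted to nm (calibrated so a uniformly filled disc
    returns its true diameter).  Area: union of the member Voronoï polygons
    (clipped to the host object when given); falls back to the convex hull
    when polygons are unavailable.  Collinear members yield area 0.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("nanodomain geometry needs at least 3 members")
    cov = np.cov(coords.T)
    lam = np.linalg.eigvalsh(cov)
    diameter_nm = 2.0 * np.sqrt(2.0) * np.sqrt(max(lam.sum(), 0.0)) * 1000.0
    if cell_polygons is not None:
        union = unary_union([p for p in cell_polygons if p is not None])
        if clip_to is not None:
            union = union.intersection(clip_to)
        area = float(union.area)
    else:
        from shapely.geometry import MultiPoint

        area = float(MultiPoint(coords).convex_hull.area)
    return float(diameter_nm), area


def detect_nanodomains(
    tmap: TessellationMap,
    obj: SegmentedObject,
    min_detections: int = 50,
    density_factor: float = 2.0,
    object_index: int = -1,
) -> list[Nanodomain]:
    """High-density clusters within one segmented object.

    Member localizations with δ ≥ ``density_factor`` × the object's mean
    density are merged by Voronoï adjacency; components smaller than
    ``min_detections`` are rejected.  Each surviving domain's defining
    thresholds are re-checked post hoc before it is returned.
    """
    sel = np.zeros(len(tmap.density), dtype=bool)
    sel[obj.members] = True
    sel &= tmap.density >= density_factor * obj.mean_density
    sel &= ~tmap.unbounded
    domains = []
    for comp in _components(sel, tmap.neighbors):
        if comp.size < min_detections:
            continue
        coords = tmap.points[comp]
        diameter, area = nanodomain_geometry(
            coords, cell_polygons=[tmap.cell_polygons[i] for i in comp], clip_to=obj.outline
        )
        mean_density = float(tmap.density[comp].mean())
        dom = Nanodomain(
            members=comp,
            centroid=coords.mean(axis=0),
            diameter_nm=diameter,
            area_um2=area,
            mean_density=mean_density,
            host_object=object_index,
        )
        # post-hoc re-check of the defining thresholds (never assumed)
        if dom.members.size < min_detections:
            raise RuntimeError("nanodomain violates the minimum-detection rule")
        if dom.mean_density < density_factor * obj.mean_density:
            raise RuntimeError("nanodomain violates the density-factor rule")
        domains.append(dom)
    domains.sort(key=lambda d: (d.centroid[0], d.centroid[1]))
    return domains


def find_nanodomains(
    points: np.ndarray,
    object_factor: float = 1.0,
    min_detections: int = 50,
    density_factor: float = 2.0,
    rank: int = 1,
    field=None,
) -> tuple[TessellationMap, list[SegmentedObject], list[Nanodomain]]:
    """Full tessellation → object segmentation → nanodomain detection chain."""
    tmap = tessellate(points, rank=rank, field=field)
    objects = segment_objects(tmap, object_factor=object_factor)
    domains = []
    for oi, obj in enumerate(objects):
        domains.extend(
            detect_nanodomains(
                tmap,
                obj,
                min_detections=min_detections,
                density_factor=density_factor,
                object_index=oi,
            )
        )
    return tmap, objects, domains


def nanodomains_per_roi(domains: list, rois: list) -> pd.DataFrame:
    """Per-ROI nanodomain counts (zero-inclusive) by centroid containment.

    ``rois`` is a list of objects with ``roi_id`` and shapely ``polygon``
    attributes (see the compartments module).  A centroid lying on a shared
    boundary is tie-broken to the lowest roi_id; centroids in no ROI are
    tallied in the ``unassigned`` row.
    """
    import shapely

    counts = {r.roi_id: 0 for r in rois}
    unassigned = 0
    ordered = sorted(rois, key=lambda r: str(r.roi_id))
    for dom in domains:
        x, y = dom.centroid
        hit = None
        for r in ordered:
            if shapely.intersects_xy(r.polygon, x, y):  # boundary-inclusive
                hit = r.roi_id
                break
        if hit is None:
            unassigned += 1
        else:
            counts[hit] += 1
            dom.host_roi = hit
    rows = [{"roi_id": rid, "n_nanodomains": c} for rid, c in counts.items()]
    rows.append({"roi_id": "unassigned", "n_nanodomains": unassigned})
    return pd.DataFrame(rows)
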