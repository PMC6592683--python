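"""Dendrite geometry for the synthetic generator: shaft, spines, nanodomains.

A :class:`CompartmentLayout` holds one shaft polygon, zero or more spine
polygons (head + neck, attached to the shaft edge), and a set of circular
trapping nanodomains, each wholly inside exactly one compartment.  Layouts
stand in for the manually drawn regions of interest a microscopist would
supply; units are micrometres throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union


@dataclass(frozen=True)
class NanodomainDisc:
    """A circular trapping zone: centre (μm), radius (μm), host compartment id."""

    x: float
    y: float
    radius: float
    host_roi: str


@dataclass
class CompartmentLayout:
    shaft: Polygon
    spines: dict = field(default_factory=dict)  # spine_id -> Polygon
    nanodomains: list = field(default_factory=list)  # list[NanodomainDisc]

    def __post_init__(self):
        if not self.shaft.is_valid or not self.shaft.is_simple:
            raise ValueError("shaft polygon is not simple")
        for sid, poly in self.spines.items():
            if not poly.is_valid or not poly.is_simple:
                raise ValueError(f"spine {sid!r} polygon is not simple")
        for nd in self.nanodomains:
            host = self.compartment(nd.host_roi)
            if not host.contains(Point(nd.x, nd.y).buffer(nd.radius, quad_segs=16)):
                raise ValueError(
                    f"nanodomain at ({nd.x:.3f}, {nd.y:.3f}) not inside {nd.host_roi!r}"
                )

    def compartment(self, roi_id: str) -> Polygon:
        if roi_id == "shaft":
            return self.shaft
        return self.spines[roi_id]

    @property
    def compartment_ids(self) -> list[str]:
        return ["shaft"] + list(self.spines)

    def domains_in(self, roi_id: str) -> list[NanodomainDisc]:
        return [nd for nd in self.nanodomains if nd.host_roi == roi_id]

    # ---- serialization (ROI JSON schema shared with the compartments module) ----

    def to_json(self, path: str | Path, cell_id: str = "cell0") -> None:
        rois = [
            {
                "roi_id": "shaft",
                "label": "shaft",
                "vertices_um": [[float(x), float(y)] for x, y in self.shaft.exterior.coords[:-1]],
            }
        ]
        for sid, poly in self.spines.items():
            rois.append(
                {
                    "roi_id": sid,
                    "label": "spine",
                    "paired_shaft_id": "shaft",
                    "vertices_um": [[float(x), float(y)] for x, y in poly.exterior.coords[:-1]],
                }
            )
        payload = {
            "cell_id": cell_id,
            "rois": rois,
            "nanodomains": [
                {"x": nd.x, "y": nd.y, "radius": nd.radius, "host_roi": nd.host_roi}
                for nd in self.nanodomains
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CompartmentLayout":
        payload = json.loads(Path(path).read_text())
        shaft = None
        spines = {}
        for roi in payload["rois"]:
            poly = Polygon(roi["vertices_um"])
            if roi["label"] == "shaft":
                shaft = poly
            else:
                spines[roi["roi_id"]] = poly
        if shaft is None:
            raise ValueError(f"{path}: layout has no shaft polygon")
        domains = [
            NanodomainDisc(d["x"], d["y"], d["radius"], d["host_roi"])
            for d in payload.get("nanodomains", [])
        ]
        return cls(shaft=shaft, spines=spines, nanodomains=domains)


class LayoutError(ValueError):
    """Spines could not be placed without overlap at the requested density."""


def build_default_layout(
    n_spines: int,
    seed: int = 0,
    shaft_length: float = 10.0,
    shaft_width: float = 1.5,
    spine_head_diameter: float = 0.5,
    neck_length: float = 0.3,
    neck_width: float = 0.15,
    nanodomain_diameter: float = 0.17,
    nanodomains_per_spine: int = 1,
    shaft_nanodomain_density: float = 0.2,
) -> CompartmentLayout:
    """Build a rectangular shaft with ``n_spines`` mushroom spines on its sides.

    Spine heads (~0.5 μm diameter) sit on short necks protruding alternately
    from the top and bottom shaft edge.  One nanodomain disc of the configured
    diameter is placed per spine head (centre), and discs are scattered
    sparsely through the shaft at ``shaft_nanodomain_density`` per μm².
    Deterministic for a fixed seed.
    """
    if n_spines < 0:
        raise ValueError("n_spines must be >= 0")
    rng = np.random.default_rng(seed)
    shaft = Polygon(
        [(0.0, 0.0), (shaft_length, 0.0), (shaft_length, shaft_width), (0.0, shaft_width)]
    )
    head_r = spine_head_diameter / 2.0
    # minimum x spacing so heads cannot touch
    per_side = int(np.ceil(n_spines / 2))
    if n_spines and shaft_length / per_side < spine_head_diameter + 0.2:
        raise LayoutError(
            f"cannot place {n_spines} spines on a {shaft_length} um shaft without overlap"
        )
    spines: dict[str, Polygon] = {}
    for i in range(n_spines):
        side = 1 if i % 2 == 0 else -1  # top / bottom
        k = i // 2
        x = (k + 0.5) * shaft_length / per_side + rng.uniform(-0.05, 0.05)
        y0 = shaft_width if side == 1 else 0.0
        # head centre pulled back slightly so head and neck overlap into one polygon
        head_c = y0 + side * (neck_length + 0.85 * head_r)
        neck = Polygon(
            [
                (x - neck_width / 2, y0),
                (x + neck_width / 2, y0),
                (x + neck_width / 2, y0 + side * neck_length),
                (x - neck_width / 2, y0 + side * neck_length),
            ]
        )
        head = Point(x, head_c).buffer(head_r, quad_segs=16)
        spine = unary_union([neck, head])
        if isinstance(spine, Polygon):
            spines[f"spine{i:02d}"] = Polygon(spine.exterior)
        else:  # pragma: no cover - union of touching parts is always a polygon
            raise LayoutError("spine construction produced a non-polygon")
    domains: list[NanodomainDisc] = []
    nd_r = nanodomain_diameter / 2.0
    for sid, poly in spines.items():
        # place at the head centre (guaranteed inside); extra discs jittered
        cx, cy = poly.centroid.x, poly.centroid.y
        head_centre = max(
            poly.exterior.coords, key=lambda c: abs(c[1] - shaft_width / 2)
        )  # furthest vertex from shaft gives the head pole
        hx, hy = head_centre
        hy = hy - np.sign(hy - shaft_width / 2) * head_r  # back off one radius
        for j in range(nanodomains_per_spine):
            for _ in range(200):
                jitter = rng.uniform(-head_r / 3, head_r / 3, 2) if j else (0.0, 0.0)
                cand = Point(hx + jitter[0], hy + jitter[1])
                if poly.contains(cand.buffer(nd_r, quad_segs=16)):
                    domains.append(NanodomainDisc(cand.x, cand.y, nd_r, sid))
                    break
            else:
                raise LayoutError(f"could not place nanodomain inside {sid}")
    n_shaft_dom = int(round(shaft.area * shaft_nanodomain_density))
    placed = 0
    attempts = 0
    while placed < n_shaft_dom and attempts < 10000:
        attempts += 1
        x = rng.uniform(nd_r, shaft_length - nd_r)
        y = rng.uniform(nd_r, shaft_width - nd_r)
        domains.append(NanodomainDisc(x, y, nd_r, "shaft"))
        placed += 1
    return CompartmentLayout(shaft=shaft, spines=spines, nanodomains=domains)


def box_layout(width: float = 20.0, height: float = 20.0) -> CompartmentLayout:
    """A plain rectangular region with no spines and no nanodomains.

    Used for statistics-only fixtures where boundary effects should be
    negligible and the displacement distribution should match the pure
    mixture model exactly.
    """
    return CompartmentLayout(
        shaft=Polygon([(0, 0), (width, 0), (width, height), (0, height)]),
        spines={},
        nanodomains=[],
    )


def sample_points_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a polygon by rejection sampling in its bounding box."""
    import shapely

    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(4 * (n - got), 16)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        ok = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        take = cand[ok][: n - got]
        out[got : got + take.shape[0]] = take
        got += take.shape[0]
    return out
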