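"""Spine/shaft region-of-interest handling and compartment-resolved mobility.

ROIs are 2D polygons labelled ``spine``, ``shaft`` or ``excluded`` (the last
marks manually discarded segments, e.g. spines projecting out of the imaging
plane).  A trajectory is assigned to the ROI containing the majority of its
localizations; tracks touching an excluded ROI are dropped and
boundary-straddling tracks without a majority stay unassigned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .trajectories import (
    DEFAULT_DT,
    Trajectory,
    effective_diffusion,
    summarize_cell,
)

VALID_LABELS = ("spine", "shaft", "excluded")


@dataclass
class CompartmentROI:
    roi_id: object
    label: str
    polygon: Polygon
    cell_id: object = None
    paired_shaft_id: object = None

    def __post_init__(self):
        if self.label not in VALID_LABELS:
            raise ValueError(f"roi {self.roi_id!r}: unknown label {self.label!r}")
        if not self.polygon.is_valid or not self.polygon.is_simple:
            raise ValueError(f"roi {self.roi_id!r}: polygon is not simple")
        # normalize to positive (counter-clockwise) orientation
        self.polygon = shapely.geometry.polygon.orient(self.polygon, sign=1.0)


def load_rois(path: str | Path) -> list[CompartmentROI]:
    """Load and validate an ROI JSON file.

    Schema: ``{cell_id, rois: [{roi_id, label, paired_shaft_id?, vertices_um}]}``.
    Malformed polygons, unknown labels, duplicate ids, and spine pairings that
    reference a non-shaft ROI are all rejected with the offending roi_id.
    """
    payload = json.loads(Path(path).read_text())
    cell_id = payload.get("cell_id")
    rois = []
    seen = set()
    for spec in payload["rois"]:
        rid = spec["roi_id"]
        if rid in seen:
            raise ValueError(f"duplicate roi_id {rid!r}")
        seen.add(rid)
        rois.append(
            CompartmentROI(
                roi_id=rid,
                label=spec["label"],
                polygon=Polygon(spec["vertices_um"]),
                cell_id=cell_id,
                paired_shaft_id=spec.get("paired_shaft_id"),
            )
        )
    by_id = {r.roi_id: r for r in rois}
    for r in rois:
        if r.paired_shaft_id is not None:
            target = by_id.get(r.paired_shaft_id)
            if target is None:
                raise ValueError(
                    f"roi {r.roi_id!r}: paired_shaft_id {r.paired_shaft_id!r} not found"
                )
            if target.label != "shaft":
                raise ValueError(
                    f"roi {r.roi_id!r}: paired_shaft_id {r.paired_shaft_id!r} "
                    f"is a {target.label}, not a shaft"
                )
    return rois


@dataclass
class RoiAssignment:
    track_id: object
    roi_id: object  # None when unassigned/excluded
    fraction_inside: float
    status: str  # assigned | excluded | unassigned


def assign_trajectories(
    trajectories: list[Trajectory],
    rois: list[CompartmentROI],
    majority: float = 0.5,
) -> list[RoiAssignment]:
    """Majority-of-localizations assignment of tracks to ROIs.

    A track is assigned to the ROI holding the largest fraction of its points
    when that fraction reaches ``majority`` and is unique; ties and
    sub-majority tracks stay unassigned.  Any overlap with an ``excluded``
    ROI excludes the track outright.  The result is invariant under ROI list
    reordering (ties resolve to unassigned, not to list order).
    """
    active = [r for r in rois if r.label != "excluded"]
    excluded = [r for r in rois if r.label == "excluded"]
    out = []
    for t in trajectories:
        x, y = t.xy[:, 0], t.xy[:, 1]
        if any(shapely.intersects_xy(r.polygon, x, y).any() for r in excluded):
            out.append(RoiAssignment(t.track_id, None, 0.0, "excluded"))
            continue
        fracs = np.array(
            [shapely.intersects_xy(r.polygon, x, y).mean() for r in active]
        )
        if fracs.size == 0:
            out.append(RoiAssignment(t.track_id, None, 0.0, "unassigned"))
            continue
        best = float(fracs.max())
        if best >= majority and (fracs == best).sum() == 1:
            rid = active[int(fracs.argmax())].roi_id
            out.append(RoiAssignment(t.track_id, rid, best, "assigned"))
        else:
            out.append(RoiAssignment(t.track_id, None, best, "unassigned"))
    return out


def assignments_table(assignments: list[RoiAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "track_id": a.track_id,
                "roi_id": a.roi_id,
                "fraction_inside": a.fraction_inside,
                "status": a.status,
            }
            for a in assignments
        ]
    )


def compartment_report(
    assignments: list[RoiAssignment],
    trajectories: list[Trajectory],
    rois: list[CompartmentROI],
    dt: float = DEFAULT_DT,
    min_track_frames: int = 8,
    min_trajectories_cell: int = 1000,
    min_trajectories_roi: int = 50,
) -> dict:
    """Compartment-resolved mobility tables.

    Returns a dict with:

    ``per_compartment`` — one row per (cell, label): mean-MSD AUC, immobile
    fraction, trajectory count (empty-flagged compartments carry NaN);
    ``per_roi`` — one row per ROI: D_eff with the ``min_trajectories_roi``
    floor (NaN when under-populated);
    ``paired`` — spine rows joined to their paired shaft's D_eff.
    """
    by_track = {t.track_id: t for t in trajectories}
    members: dict = {r.roi_id: [] for r in rois}
    for a in assignments:
        if a.status == "assigned" and a.track_id in by_track:
            members[a.roi_id].append(by_track[a.track_id])
    label_of = {r.roi_id: r.label for r in rois}
    cell_of = {r.roi_id: r.cell_id for r in rois}

    comp_rows = []
    cells = sorted({r.cell_id for r in rois}, key=str)
    for cell in cells:
        for label in ("spine", "shaft"):
            tracks = [
                t
                for rid, ts in members.items()
                if label_of[rid] == label and cell_of[rid] == cell
                for t in ts
            ]
            summary = (
                summarize_cell(
                    tracks,
                    dt=dt,
                    min_track_frames=min_track_frames,
                    min_trajectories=min_trajectories_cell,
                )
                if tracks
                else None
            )
            comp_rows.append(
                {
                    "cell_id": cell,
                    "compartment": label,
                    "n_trajectories": 0 if summary is None else summary.n_trajectories,
                    "auc": np.nan if summary is None else summary.auc,
                    "immobile_fraction": np.nan
                    if summary is None
                    else summary.immobile_fraction,
                    "empty": summary is None,
                    "below_min_trajectories": True
                    if summary is None
                    else summary.below_min_trajectories,
                }
            )

    roi_rows = []
    for r in rois:
        if r.label == "excluded":
            continue
        fit = effective_diffusion(
            members[r.roi_id], dt=dt, min_trajectories=min_trajectories_roi
        )
        roi_rows.append(
            {
                "cell_id": r.cell_id,
                "roi_id": r.roi_id,
                "label": r.label,
                "n_trajectories": len(members[r.roi_id]),
                "d_eff": np.nan if fit is None else fit.D,
            }
        )
    per_roi = pd.DataFrame(roi_rows)

    paired_rows = []
    if not per_roi.empty:
        deff = dict(zip(per_roi["roi_id"], per_roi["d_eff"]))
        for r in rois:
            if r.label == "spine" and r.paired_shaft_id is not None:
                paired_rows.append(
                    {
                        "cell_id": r.cell_id,
                        "spine_id": r.roi_id,
                        "shaft_id": r.paired_shaft_id,
                        "spine_d_eff": deff.get(r.roi_id, np.nan),
                        "shaft_d_eff": deff.get(r.paired_shaft_id, np.nan),
                    }
                )
    return {
        "per_compartment": pd.DataFrame(comp_rows),
        "per_roi": per_roi,
        "paired": pd.DataFrame(
            paired_rows,
            columns=["cell_id", "spine_id", "shaft_id", "spine_d_eff", "shaft_d_eff"],
        ),
    }
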