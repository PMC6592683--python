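"""ROI loading/validation, trajectory assignment, compartment report."""

import json

import numpy as np
import pytest
from shapely.geometry import Polygon

from sptnano.compartments import (
    CompartmentROI,
    assign_trajectories,
    compartment_report,
    load_rois,
)
from sptnano.geometry import build_default_layout
from sptnano.synthetic import SimulationConfig, simulate_cell
from sptnano.trajectories import Trajectory, summarize_cell
from conftest import make_brownian_track


def write_roi_file(tmp_path, rois, cell_id="c"):
    p = tmp_path / "rois.json"
    p.write_text(json.dumps({"cell_id": cell_id, "rois": rois}))
    return p


SQUARE = [[0, 0], [2, 0], [2, 2], [0, 2]]


class TestLoadRois:
    def test_round_trip_labels(self, tmp_path):
        p = write_roi_file(
            tmp_path,
            [
                {"roi_id": "shaft", "label": "shaft", "vertices_um": SQUARE},
                {"roi_id": "s1", "label": "spine", "vertices_um": [[3, 0], [4, 0], [4, 1], [3, 1]]},
                {"roi_id": "s2", "label": "spine", "vertices_um": [[5, 0], [6, 0], [6, 1], [5, 1]]},
            ],
        )
        rois = load_rois(p)
        assert [r.label for r in rois] == ["shaft", "spine", "spine"]

    def test_self_intersecting_polygon_rejected_by_id(self, tmp_path):
        bowtie = [[0, 0], [1, 1], [1, 0], [0, 1]]
        p = write_roi_file(tmp_path, [{"roi_id": "bad", "label": "spine", "vertices_um": bowtie}])
        with pytest.raises(ValueError, match="bad"):
            load_rois(p)

    def test_unknown_label_rejected(self, tmp_path):
        p = write_roi_file(tmp_path, [{"roi_id": "x", "label": "axon", "vertices_um": SQUARE}])
        with pytest.raises(ValueError, match="label"):
            load_rois(p)

    def test_duplicate_roi_id_rejected(self, tmp_path):
        p = write_roi_file(
            tmp_path,
            [
                {"roi_id": "x", "label": "shaft", "vertices_um": SQUARE},
                {"roi_id": "x", "label": "spine", "vertices_um": [[3, 0], [4, 0], [4, 1]]},
            ],
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_rois(p)

    def test_spine_paired_to_spine_rejected(self, tmp_path):
        p = write_roi_file(
            tmp_path,
            [
                {"roi_id": "a", "label": "spine", "vertices_um": SQUARE},
                {
                    "roi_id": "b",
                    "label": "spine",
                    "paired_shaft_id": "a",
                    "vertices_um": [[3, 0], [4, 0], [4, 1], [3, 1]],
                },
            ],
        )
        with pytest.raises(ValueError, match="not a shaft"):
            load_rois(p)


class TestAssignTrajectories:
    def _rois(self):
        return [
            CompartmentROI("shaft", "shaft", Polygon([(0, 0), (10, 0), (10, 2), (0, 2)])),
            CompartmentROI("sp", "spine", Polygon([(4, 2), (6, 2), (6, 4), (4, 4)])),
        ]

    def test_track_fully_inside_spine(self):
        xy = np.column_stack([np.full(5, 5.0), np.full(5, 3.0)]) + np.arange(5)[:, None] * 0.01
        t = Trajectory(0, "c", np.arange(5), xy)
        (a,) = assign_trajectories([t], self._rois())
        assert (a.status, a.roi_id, a.fraction_inside) == ("assigned", "sp", 1.0)

    def test_minority_overlap_unassigned(self):
        # 3 of 10 points inside the spine, the rest outside every ROI
        ys = np.array([5.0] * 7 + [3.0] * 3)
        t = Trajectory(0, "c", np.arange(10), np.column_stack([np.full(10, 5.0), ys]))
        (a,) = assign_trajectories([t], self._rois())
        assert a.status == "unassigned"
        assert a.fraction_inside == pytest.approx(0.3)

    def test_excluded_roi_wins(self):
        rois = self._rois() + [
            CompartmentROI("bad", "excluded", Polygon([(4.5, 2.5), (5.5, 2.5), (5.5, 3.5), (4.5, 3.5)]))
        ]
        xy = np.column_stack([np.full(3, 5.0), np.full(3, 3.0)]) + np.arange(3)[:, None] * 0.01
        t = Trajectory(0, "c", np.arange(3), xy)
        (a,) = assign_trajectories([t], rois)
        assert a.status == "excluded"

    def test_invariant_under_roi_reorder(self, rng):
        rois = self._rois()
        tracks = [make_brownian_track(rng, D=0.05, n=10, track_id=i, start=(5, 2)) for i in range(40)]
        a1 = assign_trajectories(tracks, rois)
        a2 = assign_trajectories(tracks, rois[::-1])
        assert [(a.roi_id, a.status) for a in a1] == [(a.roi_id, a.status) for a in a2]

    def test_no_track_assigned_twice(self, rng):
        tracks = [make_brownian_track(rng, D=0.05, n=10, track_id=i, start=(5, 1)) for i in range(30)]
        assigns = assign_trajectories(tracks, self._rois())
        assert len({a.track_id for a in assigns}) == len(assigns)

    def test_ground_truth_agreement_on_simulated_cell(self):
        layout = build_default_layout(3, seed=31)
        cfg = SimulationConfig(
            geometry=layout, n_molecules=500, spine_fraction=0.5, seed=31
        )
        res = simulate_cell(cfg, cell_id="c")
        rois = [
            CompartmentROI("shaft", "shaft", layout.shaft, cell_id="c"),
            *[
                CompartmentROI(sid, "spine", poly, cell_id="c", paired_shaft_id="shaft")
                for sid, poly in layout.spines.items()
            ],
        ]
        assigns = assign_trajectories(res.trajectories, rois)
        gt = res.ground_truth.set_index("track_id")["compartment_id"]
        assigned = [a for a in assigns if a.status == "assigned"]
        agree = np.mean([gt[a.track_id] == a.roi_id for a in assigned])
        assert len(assigned) / len(assigns) > 0.9
        assert agree >= 0.95


class TestCompartmentReport:
    def _setup(self, seed=41, spine_occ=(0.45, 0.45, 0.1)):
        layout = build_default_layout(2, seed=seed)
        cfg = SimulationConfig(
            geometry=layout,
            n_molecules=600,
            spine_fraction=0.4,
            spine_occupancy=spine_occ,
            state_occupancy=(0.1, 0.2, 0.7),
            seed=seed,
        )
        res = simulate_cell(cfg, cell_id="c")
        rois = [
            CompartmentROI("shaft", "shaft", layout.shaft, cell_id="c"),
            *[
                CompartmentROI(sid, "spine", poly, cell_id="c", paired_shaft_id="shaft")
                for sid, poly in layout.spines.items()
            ],
        ]
        assigns = assign_trajectories(res.trajectories, rois)
        return res, rois, assigns

    def test_all_tracks_in_shaft_flags_empty_spines(self, rng):
        rois = [
            CompartmentROI("shaft", "shaft", Polygon([(0, 0), (10, 0), (10, 2), (0, 2)]), cell_id="c"),
            CompartmentROI("sp", "spine", Polygon([(4, 3), (6, 3), (6, 5), (4, 5)]), cell_id="c"),
        ]
        tracks = [make_brownian_track(rng, D=0.02, n=12, track_id=i, start=(5, 1)) for i in range(60)]
        assigns = assign_trajectories(tracks, rois)
        rep = compartment_report(assigns, tracks, rois, min_trajectories_cell=10)
        per = rep["per_compartment"].set_index("compartment")
        assert bool(per.loc["spine", "empty"])
        assert per.loc["shaft", "n_trajectories"] > 0

    def test_spine_mobility_lower_than_shaft(self):
        res, rois, assigns = self._setup()
        rep = compartment_report(assigns, res.trajectories, rois, min_trajectories_cell=50)
        per = rep["per_compartment"].set_index("compartment")
        assert per.loc["spine", "immobile_fraction"] > per.loc["shaft", "immobile_fraction"]
        roi_tab = rep["per_roi"].dropna(subset=["d_eff"])
        spine_d = roi_tab.loc[roi_tab["label"] == "spine", "d_eff"]
        shaft_d = roi_tab.loc[roi_tab["label"] == "shaft", "d_eff"]
        assert spine_d.mean() < shaft_d.mean()

    def test_report_consistent_with_direct_recomputation(self):
        """The compartment rows must equal per-module metrics recomputed on
        exactly that compartment's tracks (consistency oracle)."""
        res, rois, assigns = self._setup(seed=43)
        rep = compartment_report(assigns, res.trajectories, rois, min_trajectories_cell=50)
        by_track = {t.track_id: t for t in res.trajectories}
        label_of = {r.roi_id: r.label for r in rois}
        spine_tracks = [
            by_track[a.track_id]
            for a in assigns
            if a.status == "assigned" and label_of[a.roi_id] == "spine"
        ]
        direct = summarize_cell(spine_tracks, min_trajectories=50)
        per = rep["per_compartment"].set_index("compartment")
        assert per.loc["spine", "auc"] == pytest.approx(direct.auc, rel=1e-12)
        assert per.loc["spine", "immobile_fraction"] == pytest.approx(
            direct.immobile_fraction, abs=1e-12
        )

    def test_paired_rows_present(self):
        res, rois, assigns = self._setup(seed=44)
        rep = compartment_report(assigns, res.trajectories, rois, min_trajectories_cell=50)
        assert len(rep["paired"]) == 2
        assert set(rep["paired"]["shaft_id"]) == {"shaft"}
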