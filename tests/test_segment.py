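import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adipovol import (
    MOUSE_GEOMETRY,
    EditScript,
    PipelineConfig,
    apply_edit_script,
    assign_depots,
    compute_adipose_threshold,
    generate_phantom,
    label_objects,
    local_threshold,
    quantify_volumes,
    reinsert_cut_voxels,
    segment_subject,
)
from conftest import make_tiny_mouse_spec
from oracles import bfs_partition, labels_to_partition, loop_local_threshold


def _contour_for(values):
    """A fat slice + contour whose contour intensities are exactly `values`."""
    values = np.asarray(values, dtype=float)
    fat = np.zeros((1, values.size))
    fat[0] = values
    contour = np.array([[0, i] for i in range(values.size)])
    return fat, contour


class TestAdiposeThreshold:
    def test_contour_branch(self):
        # mean 200, sd 50 -> tc = 150 above bg 80
        vals = np.array([150.0, 250.0])  # mean 200, sample sd ~70.7
        fat, contour = _contour_for(vals)
        thr = compute_adipose_threshold(fat, contour, bg=80.0)
        sd = vals.std(ddof=1)
        assert not thr.fallback_used
        assert thr.tc == pytest.approx(200 - sd)

    def test_fallback_branch(self):
        # candidate mean - sd below bg: tc = bg + 0.1 sd
        vals = np.array([60.0, 140.0])  # mean 100, sd ~56.6 -> candidate ~43
        fat, contour = _contour_for(vals)
        thr = compute_adipose_threshold(fat, contour, bg=90.0)
        sd = vals.std(ddof=1)
        assert thr.fallback_used
        assert thr.tc == pytest.approx(90.0 + 0.1 * sd)

    def test_boundary_equality_keeps_contour_value(self):
        vals = np.array([50.0, 150.0])
        sd = vals.std(ddof=1)
        candidate = 100.0 - sd
        fat, contour = _contour_for(vals)
        thr = compute_adipose_threshold(fat, contour, bg=candidate)
        assert not thr.fallback_used
        assert thr.tc == pytest.approx(candidate)

    def test_empty_contour(self):
        with pytest.raises(ValueError, match="no contour"):
            compute_adipose_threshold(np.zeros((2, 2)), np.empty((0, 2), dtype=int), 1.0)

    def test_dichotomy_random(self, rng):
        # exactly one of the two formulas holds, matching the flag
        for _ in range(500):
            vals = rng.uniform(0, 100, rng.integers(2, 12))
            bg = float(rng.uniform(0, 120))
            mean, sd = vals.mean(), vals.std(ddof=1)
            thr = compute_adipose_threshold(*_contour_for(vals), bg=bg)
            if mean - sd >= bg:
                assert not thr.fallback_used and thr.tc == pytest.approx(mean - sd)
            else:
                assert thr.fallback_used and thr.tc == pytest.approx(bg + 0.1 * sd)


class TestLocalThreshold:
    def test_constant_image_all_zero(self):
        assert local_threshold(np.full((9, 9), 7.0), 3, 3, 0.5).sum() == 0

    def test_single_bright_voxel(self):
        img = np.zeros((9, 9))
        img[4, 4] = 100.0
        mask = local_threshold(img, 3, 3, 10.0)
        # centre: local mean 100/9, 100 > 100/9 + 10; neighbours are 0
        assert mask[4, 4] == 1
        assert mask.sum() == 1

    @pytest.mark.parametrize("window", [3, 15])
    def test_matches_loop_oracle(self, rng, window):
        for _ in range(5):
            img = rng.uniform(0, 100, (32, 32))
            for offset in (0.05, 5.0, 50.0):
                got = local_threshold(img, window, window, offset)
                assert np.array_equal(got, loop_local_threshold(img, window, window, offset))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="window must be odd"):
            local_threshold(np.zeros((5, 5)), 4, 3, 1.0)

    def test_monotone_in_offset(self, rng):
        img = rng.uniform(0, 100, (24, 24))
        prev = local_threshold(img, 5, 5, 1.0)
        for offset in (2.0, 5.0, 20.0):
            cur = local_threshold(img, 5, 5, offset)
            assert np.all(cur <= prev)
            prev = cur


class TestLabelObjects:
    def test_diagonal_connectivity(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[1, 1] = mask[2, 2] = 1
        assert label_objects(mask, 4).max() == 2
        assert label_objects(mask, 8).max() == 1

    def test_empty_mask(self):
        assert label_objects(np.zeros((5, 5), dtype=np.uint8)).max() == 0

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_bfs_oracle(self, rng, connectivity):
        for _ in range(20):
            mask = (rng.random((32, 32)) < 0.4).astype(np.uint8)
            labels = label_objects(mask, connectivity)
            assert labels_to_partition(labels) == bfs_partition(mask, connectivity)

    def test_raster_first_encounter_order(self):
        mask = np.zeros((4, 6), dtype=np.uint8)
        mask[0, 4] = 1          # first in raster order
        mask[2, 0:2] = 1        # second
        mask[3, 5] = 1          # third
        labels = label_objects(mask, 4)
        assert labels[0, 4] == 1 and labels[2, 0] == 2 and labels[3, 5] == 3


class TestEditScript:
    def test_round_trip(self, tmp_path):
        script = EditScript(
            removals=[(0, 1, 2)],
            cut_voxels=[(0, 3, 4), (1, 5, 6)],
            additions=[(1, 7, 8)],
            depot_seeds=[(0, 2, 2, 1), (1, 9, 9, 2)],
        )
        path = tmp_path / "edits.csv"
        script.to_file(path)
        back = EditScript.from_file(path)
        assert back == script

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            EditScript(removals=[(0, 1, 1)], cut_voxels=[(0, 1, 1)])

    def test_corrupt_record(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("kind,slice,row,col,depot\nseed,0,1,not_a_number,SAT\n")
        with pytest.raises(ValueError, match="line 2"):
            EditScript.from_file(path)

    def test_empty_script_identity(self, rng):
        mask = (rng.random((2, 8, 8)) < 0.5).astype(np.uint8)
        out, cuts = apply_edit_script(mask, EditScript())
        assert np.array_equal(out, mask) and cuts == []

    def test_out_of_bounds(self):
        with pytest.raises(ValueError, match="edit out of range"):
            apply_edit_script(np.zeros((1, 4, 4), dtype=np.uint8), EditScript(removals=[(0, 9, 0)]))

    def test_cut_splits_dumbbell(self):
        mask = np.zeros((1, 3, 7), dtype=np.uint8)
        mask[0, 0:3, 0:3] = 1
        mask[0, 0:3, 4:7] = 1
        mask[0, 1, 3] = 1  # the neck
        assert label_objects(mask[0], 4).max() == 1
        out, cuts = apply_edit_script(mask, EditScript(cut_voxels=[(0, 1, 3)]))
        assert label_objects(out[0], 4).max() == 2
        assert cuts == [(0, 1, 3)]

    def test_addition_makes_new_object(self):
        mask = np.zeros((1, 5, 5), dtype=np.uint8)
        mask[0, 0, 0] = 1
        out, _ = apply_edit_script(mask, EditScript(additions=[(0, 4, 4)]))
        assert label_objects(out[0], 4).max() == 2


class TestAssignDepots:
    def test_unseeded_objects_stay_zero(self):
        labels = np.zeros((3, 9), dtype=int)
        labels[1, 0:2] = 1
        labels[1, 4:6] = 2
        labels[1, 7:9] = 3
        depots = assign_depots(labels, [(1, 0, 1), (1, 7, 2)])
        assert np.all(depots[labels == 1] == 1)
        assert np.all(depots[labels == 2] == 0)
        assert np.all(depots[labels == 3] == 2)

    def test_seed_on_background(self):
        with pytest.raises(ValueError, match="seed misses object"):
            assign_depots(np.zeros((3, 3), dtype=int), [(1, 1, 1)])

    def test_conflicting_seeds(self):
        labels = np.ones((2, 2), dtype=int)
        with pytest.raises(ValueError, match="conflicting assignment"):
            assign_depots(labels, [(0, 0, 1), (1, 1, 2)])

    def test_single_object_sat(self):
        labels = np.ones((3, 3), dtype=int)
        assert np.all(assign_depots(labels, [(1, 1, 1)]) == 1)


class TestReinsertCutVoxels:
    def test_majority_and_tie(self):
        depots = np.zeros((3, 3), dtype=np.uint8)
        depots[0, :] = 1       # SAT row
        depots[2, 0] = 2       # one VAT neighbour
        out = reinsert_cut_voxels(depots, [(1, 1)])
        assert out[1, 1] == 1  # 3 SAT vs 1 VAT

        depots = np.zeros((3, 3), dtype=np.uint8)
        depots[0, 0] = depots[0, 1] = 1
        depots[2, 0] = depots[2, 1] = 2
        out = reinsert_cut_voxels(depots, [(1, 1)])
        assert out[1, 1] == 1  # 2 vs 2 tie -> SAT

    def test_vat_majority(self):
        depots = np.zeros((3, 3), dtype=np.uint8)
        depots[0, 0] = 1
        depots[2, 0] = depots[2, 1] = depots[2, 2] = 2
        assert reinsert_cut_voxels(depots, [(1, 1)])[1, 1] == 2

    def test_isolated_defaults_sat(self):
        assert reinsert_cut_voxels(np.zeros((3, 3), dtype=np.uint8), [(1, 1)])[1, 1] == 1

    def test_frozen_map_semantics(self):
        # two adjacent cut voxels must not see each other's reinserted value
        depots = np.zeros((3, 4), dtype=np.uint8)
        depots[0, :] = 2
        out = reinsert_cut_voxels(depots, [(1, 1), (1, 2)])
        assert out[1, 1] == 2 and out[1, 2] == 2


class TestQuantifyVolumes:
    def test_mouse_geometry_arithmetic(self):
        depots = np.zeros((10, 10, 10), dtype=np.uint8)
        depots.ravel()[:1000] = 1
        report = quantify_volumes(depots, MOUSE_GEOMETRY)
        assert report.sat_voxels == 1000
        assert report.sat_cm3 == pytest.approx(0.024336, abs=1e-12)
        assert report.tat_voxels == report.sat_voxels + report.vat_voxels

    def test_empty_map(self):
        report = quantify_volumes(np.zeros((2, 4, 4), dtype=np.uint8), MOUSE_GEOMETRY)
        assert report.sat_cm3 == report.vat_cm3 == report.tat_cm3 == 0

    @given(n_sat=st.integers(0, 50), n_vat=st.integers(0, 50))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_volume_linearity(self, n_sat, n_vat):
        depots = np.zeros((1, 20, 20), dtype=np.uint8)
        flat = depots.ravel()
        flat[:n_sat] = 1
        flat[n_sat:n_sat + n_vat] = 2
        single = quantify_volumes(depots, MOUSE_GEOMETRY)
        double = quantify_volumes(np.concatenate([depots, depots]), MOUSE_GEOMETRY)
        assert double.sat_cm3 == pytest.approx(2 * single.sat_cm3)
        assert double.vat_cm3 == pytest.approx(2 * single.vat_cm3)


class TestSegmentSubject:
    def test_deterministic_rerun(self, tiny_phantom, tiny_config):
        scan, truth = tiny_phantom
        a = segment_subject(scan, tiny_config, truth.edits)
        b = segment_subject(scan, tiny_config, truth.edits)
        assert np.array_equal(a.depot_map, b.depot_map)
        assert a.provenance.equals(b.provenance)

    def test_recovers_truth_at_zero_noise(self, tiny_phantom, tiny_config):
        scan, truth = tiny_phantom
        res = segment_subject(scan, tiny_config, truth.edits)
        assert np.array_equal(res.depot_map, truth.depot_map)

    def test_zero_fat_phantom_empty(self):
        spec = make_tiny_mouse_spec(seed=8, sat_thickness=0.0, n_vat_blobs=0,
                                    background_noise_sd=100.0)
        scan, truth = generate_phantom(spec)
        assert truth.depot_map.sum() == 0
        res = segment_subject(scan, PipelineConfig.for_species("mouse", seed=8), truth.edits)
        assert res.depot_map.sum() == 0
        assert res.report.tat_cm3 == 0

    def test_provenance_columns(self, tiny_phantom, tiny_config):
        scan, truth = tiny_phantom
        res = segment_subject(scan, tiny_config, truth.edits)
        assert list(res.provenance["slice"]) == list(range(scan.fat.n_slices))
        for col in ("bg_mean", "bg_sd", "bg", "contour_mean", "contour_sd",
                    "tc", "fallback_used", "n_objects", "seed"):
            assert col in res.provenance.columns
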