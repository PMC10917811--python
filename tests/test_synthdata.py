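"""Generator contracts: response curves, exact rendering oracles, determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from nuctrans import (
    OpticsSpec,
    ResponseModel,
    SceneSpec,
    dose_series_layout,
    generate_field,
    generate_plate,
    simulate_plate,
    time_series_layout,
    true_ratio_from_dose,
    true_ratio_from_time,
)


class TestDoseResponseCurve:
    def test_vehicle_returns_baseline(self, dose_model):
        assert true_ratio_from_dose(dose_model, 0.0) == dose_model.r0

    def test_half_maximal_at_ec50(self, dose_model):
        # r0 (1 + (f_max - 1)/2) = 0.5 * 2.5 with defaults
        assert true_ratio_from_dose(dose_model, 3.0) == pytest.approx(1.25)

    def test_saturation_limit(self, dose_model):
        sat = dose_model.r0 * dose_model.f_max * dose_model.partial_efficacy
        at_100x = true_ratio_from_dose(dose_model, 100 * dose_model.ec50)
        assert abs(at_100x - sat) / sat < 0.01

    def test_partial_efficacy_lowers_plateau(self):
        partial = ResponseModel(partial_efficacy=0.5)
        full = ResponseModel()
        assert true_ratio_from_dose(partial, 1e4) < true_ratio_from_dose(full, 1e4)

    def test_negative_concentration_rejected(self, dose_model):
        with pytest.raises(ValueError):
            true_ratio_from_dose(dose_model, -1.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        concs=st.lists(
            st.floats(0, 1e4, allow_nan=False, allow_infinity=False),
            min_size=2,
            max_size=10,
        ),
        hill=st.floats(0.2, 4.0),
        pe=st.floats(0.25, 1.0),
    )
    def test_monotone_in_concentration(self, concs, hill, pe):
        model = ResponseModel(hill=hill, partial_efficacy=pe)
        ratios = true_ratio_from_dose(model, np.sort(np.asarray(concs)))
        assert np.all(np.diff(ratios) >= -1e-12)


class TestTimeCourse:
    def test_time_zero_returns_baseline(self):
        model = ResponseModel(kind="time")
        assert true_ratio_from_time(model, 0.0) == model.r0

    def test_one_time_constant(self):
        model = ResponseModel(kind="time")
        expected = 0.5 * (1 + 3 * (1 - np.exp(-1.0)))
        assert true_ratio_from_time(model, model.tau) == pytest.approx(expected)
        assert expected == pytest.approx(1.448, abs=5e-4)

    def test_two_hours_is_near_fourfold(self):
        # the assay's read-out saturates to ~4x baseline by 2 h
        model = ResponseModel(kind="time")
        fold = true_ratio_from_time(model, 120.0) / model.r0
        assert fold == pytest.approx(3.79, abs=5e-3)

    def test_monotone_in_time(self):
        model = ResponseModel(kind="time")
        t = np.linspace(0, 300, 50)
        assert np.all(np.diff(true_ratio_from_time(model, t)) >= 0)

    def test_kind_mismatch_rejected(self, dose_model):
        with pytest.raises(ValueError):
            true_ratio_from_time(dose_model, 10.0)
        with pytest.raises(ValueError):
            true_ratio_from_dose(ResponseModel(kind="time"), 1.0)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"nucleus_radius_median": 0},
            {"cell_radius_factor": 1.0},
            {"n_cells_mean": -1},
        ],
    )
    def test_scene_invariants(self, kwargs):
        with pytest.raises(ValueError):
            SceneSpec(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"r0": 0},
            {"f_max": 0.5},
            {"ec50": 0},
            {"partial_efficacy": 0},
            {"partial_efficacy": 1.5},
            {"partial_efficacy": 0.1},  # plateau would drop below baseline
            {"kind": "banana"},
        ],
    )
    def test_response_invariants(self, kwargs):
        with pytest.raises(ValueError):
            ResponseModel(**kwargs)


class TestGenerateField:
    def test_empty_field(self, ideal_optics):
        scene = SceneSpec(
            field_shape=(64, 64), n_cells_mean=0, n_cells_poisson=False
        )
        field, gt = generate_field(scene, ideal_optics, 1.0, 0)
        assert len(gt) == 0
        assert np.all(field.channel("gfp") == 0)
        assert np.all(field.channel("nuclear_marker") == 0)

    def test_noiseless_construction_is_ratio_exact(self, ideal_optics):
        """With no blur/noise, GT disk masks reproduce the ratio exactly."""
        scene = SceneSpec(
            field_shape=(256, 256),
            n_cells_mean=5,
            n_cells_poisson=False,
            min_center_distance=60,
        )
        field, gt = generate_field(scene, ideal_optics, 2.0, 3)
        gfp = field.channel("gfp")
        rr, cc = np.mgrid[0 : gfp.shape[0], 0 : gfp.shape[1]]
        for row in gt.itertuples():
            d2 = (rr - row.row) ** 2 + (cc - row.col) ** 2
            nuc = d2 <= row.nucleus_radius**2
            ann = (d2 <= row.cell_radius**2) & ~nuc
            assert gfp[nuc].mean() / gfp[ann].mean() == pytest.approx(2.0, rel=1e-12)
            # conservation: total GFP over the cell body equals the drawn total
            assert gfp[nuc | ann].sum() == pytest.approx(row.gfp_total, rel=1e-9)

    def test_varying_ratio_redistributes_but_conserves_total(self, ideal_optics):
        scene = SceneSpec(
            field_shape=(128, 128), n_cells_mean=1, n_cells_poisson=False
        )
        totals = []
        for ratio in (0.5, 2.0, 4.0):
            field, gt = generate_field(scene, ideal_optics, ratio, 7)
            totals.append(field.channel("gfp").sum())
        assert np.ptp(totals) / totals[0] < 1e-9

    def test_requested_count_and_reconstruction(self, ideal_optics):
        """50 spaced cells -> 50 ground-truth rows -> 50 labeled components."""
        scene = SceneSpec(
            field_shape=(1080, 1280),
            n_cells_mean=50,
            n_cells_poisson=False,
            nucleus_radius_sigma_log=0.0,
            min_center_distance=30,
        )
        field, gt = generate_field(scene, ideal_optics, 1.0, 11)
        assert len(gt) == 50
        recon = np.zeros(scene.field_shape, dtype=bool)
        rr, cc = np.mgrid[0 : 1080, 0 : 1280]
        for row in gt.itertuples():
            recon |= (rr - row.row) ** 2 + (cc - row.col) ** 2 <= row.nucleus_radius**2
        _, n = ndimage.label(recon)
        assert n == 50

    def test_placement_respects_min_distance(self, ideal_optics):
        scene = SceneSpec(
            field_shape=(320, 384), n_cells_mean=25, min_center_distance=30
        )
        _, gt = generate_field(scene, ideal_optics, 1.0, 5)
        pts = gt[["row", "col"]].to_numpy()
        for i in range(len(pts)):
            d = np.hypot(*(pts[i] - np.delete(pts, i, axis=0)).T)
            assert np.all(d >= 30)

    def test_overcrowded_request_places_fewer_and_records(self, ideal_optics):
        scene = SceneSpec(
            field_shape=(96, 96),
            n_cells_mean=200,
            n_cells_poisson=False,
            min_center_distance=24,
            max_place_attempts=20,
        )
        field, gt = generate_field(scene, ideal_optics, 1.0, 1)
        assert field.metadata["n_cells_requested"] == 200
        assert field.metadata["n_cells_placed"] == len(gt) < 200

    def test_noisy_images_are_integers_within_bit_depth(
        self, small_scene, default_optics
    ):
        field, _ = generate_field(small_scene, default_optics, 2.0, 2)
        for img in field.channels.values():
            assert np.all(img == np.rint(img))
            assert img.min() >= 0 and img.max() <= 65535
        assert set(field.metadata["saturation_fraction"]) == {
            "nuclear_marker",
            "gfp",
        }

    def test_determinism(self, small_scene, default_optics):
        f1, g1 = generate_field(small_scene, default_optics, 2.0, 42)
        f2, g2 = generate_field(small_scene, default_optics, 2.0, 42)
        for ch in f1.channels:
            np.testing.assert_array_equal(f1.channels[ch], f2.channels[ch])
        pd.testing.assert_frame_equal(g1, g2)

    def test_invalid_ratio_rejected(self, small_scene, default_optics):
        with pytest.raises(ValueError):
            generate_field(small_scene, default_optics, 0.0, 0)


class TestGeneratePlate:
    def test_minimal_plate_on_disk(self, tmp_path, ideal_optics):
        layout = dose_series_layout([], wells_per_dose=1, fields_per_well=1)
        scene = SceneSpec(field_shape=(96, 96), n_cells_mean=3, n_cells_poisson=False)
        generate_plate(layout, scene, ideal_optics, ResponseModel(), 0, tmp_path)
        tiffs = sorted(p.name for p in tmp_path.glob("*.tif"))
        assert len(tiffs) == 2  # one per channel for the single field
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "ground_truth.csv").exists()

    def test_same_seed_byte_identical(self, tmp_path, default_optics):
        layout = dose_series_layout([3.0], wells_per_dose=1, fields_per_well=1)
        scene = SceneSpec(field_shape=(96, 96), n_cells_mean=4)
        for sub in ("a", "b"):
            generate_plate(
                layout, scene, default_optics, ResponseModel(), 9, tmp_path / sub
            )
        for p in sorted((tmp_path / "a").iterdir()):
            assert p.read_bytes() == (tmp_path / "b" / p.name).read_bytes()

    def test_treated_over_vehicle_true_ratio_fold(self, default_optics):
        """4 vehicle + 4 saturating-dose wells: true-ratio fold is ~4x."""
        layout = dose_series_layout([100.0], wells_per_dose=4, fields_per_well=2)
        scene = SceneSpec(field_shape=(256, 320), n_cells_mean=12)
        sim = simulate_plate(layout, scene, default_optics, ResponseModel(), 5)
        gt = sim.ground_truth.merge(
            pd.DataFrame(
                [
                    {"well": w.well, "is_vehicle": w.is_vehicle}
                    for w in layout.wells
                ]
            ),
            on="well",
        )
        fold = (
            gt.loc[~gt.is_vehicle, "true_ratio"].mean()
            / gt.loc[gt.is_vehicle, "true_ratio"].mean()
        )
        assert 3.5 <= fold <= 4.1

    def test_kind_mismatch_raises(self, ideal_optics):
        layout = time_series_layout([60.0], wells_per_timepoint=1, fields_per_well=1)
        scene = SceneSpec(field_shape=(96, 96), n_cells_mean=2)
        with pytest.raises(ValueError, match="dose"):
            simulate_plate(layout, scene, ideal_optics, ResponseModel(kind="dose"), 0)
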