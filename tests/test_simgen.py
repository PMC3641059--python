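"""Tests of the synthetic-microscopy generator against its ground truth."""

import dataclasses

import numpy as np
import pytest

from pictools import (
    EXOCYST_PREYS,
    FrapSimConfig,
    ScreenSimConfig,
    SimFieldConfig,
    simulate_field,
    simulate_frap_trace,
    simulate_screen,
)
from pictools.imgproc import detect_patches, local_threshold, subtract_background


def merged_anchor_count(coords, merge_dist):
    """Count planted anchors after merging coordinates closer than
    ``merge_dist`` (single-linkage), the resolvable-spot oracle."""
    coords = list(coords)
    parent = list(range(len(coords)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            d = np.hypot(coords[i][0] - coords[j][0], coords[i][1] - coords[j][1])
            if d < merge_dist:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(len(coords))})


class TestSimulateField:
    def test_zero_prey_expression_green_is_background(self, small_field_config):
        cfg = dataclasses.replace(small_field_config, prey_expression=0.0)
        fld, _ = simulate_field(cfg, "plusRAP", interactor=True)
        assert abs(fld.green.mean() - cfg.background_level) < 2.0
        mask = local_threshold(subtract_background(fld.green, 40))
        assert detect_patches(mask).total_area == 0

    def test_null_recruitment_matches_vehicle_bitwise(self, small_field_config):
        cfg = dataclasses.replace(small_field_config, recruitment_efficiency=0.0)
        plus, _ = simulate_field(cfg, "plusRAP", interactor=True)
        minus, _ = simulate_field(cfg, "minusRAP", interactor=True)
        assert np.array_equal(plus.green, minus.green)
        assert np.array_equal(plus.red, minus.red)

    def test_determinism_bit_identical(self, small_field_config):
        a, _ = simulate_field(small_field_config, "plusRAP", True)
        b, _ = simulate_field(small_field_config, "plusRAP", True)
        assert np.array_equal(a.red, b.red)
        assert np.array_equal(a.green, b.green)

    def test_anchor_count_recovered_from_red_channel(self):
        cfg = SimFieldConfig(anchors_per_cell=5.0, n_cells=10, seed=42)
        fld, truth = simulate_field(cfg, "minusRAP", False)
        mask = local_threshold(subtract_background(fld.red, 115))
        n_detected = len(detect_patches(mask))
        n_expected = merged_anchor_count(
            truth.anchor_coordinates, 2 * cfg.psf_sigma_px
        )
        assert abs(n_detected - n_expected) <= 0.1 * n_expected

    def test_truth_recovery_noise_free(self):
        """With noise off and bright anchors, segmentation finds >=95% of
        planted sites."""
        cfg = SimFieldConfig(anchors_per_cell=4.0, n_cells=8, seed=7)
        fld, truth = simulate_field(cfg, "minusRAP", False, apply_noise=False)
        mask = local_threshold(fld.red)
        found = sum(1 for r, c in truth.anchor_coordinates if mask.mask[r, c])
        assert found >= 0.95 * len(truth.anchor_coordinates)

    def test_photon_conservation_under_recruitment(self, small_field_config):
        """Recruitment relocates green signal, it does not create it."""
        totals = []
        for eff in (0.0, 0.3, 0.6, 1.0):
            cfg = dataclasses.replace(
                small_field_config, recruitment_efficiency=eff, prey_native_puncta=2
            )
            fld, _ = simulate_field(cfg, "plusRAP", True, apply_noise=False)
            totals.append((fld.green - cfg.background_level).sum() / cfg.gain)
        assert np.allclose(totals, totals[0], rtol=1e-3)

    def test_anchors_lie_on_cell_perimeter(self, small_field_config):
        _, truth = simulate_field(small_field_config, "minusRAP", False)
        mean_r, sd_r = small_field_config.cell_radius_px
        for ar, ac in truth.anchor_coordinates:
            d = min(
                np.hypot(ar - cr, ac - cc) for cr, cc in truth.cell_centers
            )
            assert d <= mean_r + 4 * sd_r + 1.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"recruitment_efficiency": 1.5},
            {"anchor_amplitude": -1.0},
            {"field_shape": (32, 128)},
            {"psf_sigma_px": float("nan")},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimFieldConfig(**kwargs)

    def test_unknown_condition_rejected(self, small_field_config):
        with pytest.raises(ValueError, match="condition"):
            simulate_field(small_field_config, "noRAP", False)


class TestSimulateScreen:
    def test_field_counting(self):
        cfg = ScreenSimConfig(
            n_strains=3,
            interactor_ids=("Sec3",),
            fields_per_condition=9,
            field_config=SimFieldConfig(field_shape=(64, 64), n_cells=1),
        )
        fields = list(simulate_screen(cfg))
        assert len(fields) == 54

    def test_default_layout_matches_screen_design(self):
        cfg = ScreenSimConfig()
        labels = cfg.strain_labels()
        assert cfg.n_strains == 227 and len(labels) == 227
        assert cfg.fields_per_condition == 9
        assert set(cfg.interactor_ids) == set(EXOCYST_PREYS)
        assert len(cfg.interactor_ids) == 6

    def test_master_seed_determinism(self):
        cfg = ScreenSimConfig(
            n_strains=2,
            interactor_ids=("Sec3",),
            fields_per_condition=2,
            field_config=SimFieldConfig(field_shape=(64, 64), n_cells=1),
            master_seed=5,
        )
        first = [f.green.copy() for _, _, _, f, _ in simulate_screen(cfg)]
        second = [f.green.copy() for _, _, _, f, _ in simulate_screen(cfg)]
        for a, b in zip(first, second):
            assert np.array_equal(a, b)

    def test_only_interactors_recruited(self):
        cfg = ScreenSimConfig(
            n_strains=2,
            interactor_ids=("Sec3",),
            fields_per_condition=2,
            field_config=SimFieldConfig(field_shape=(64, 64), n_cells=1),
        )
        for strain, condition, _, _, truth in simulate_screen(cfg):
            assert truth.is_interactor == (strain == "Sec3")

    def test_duplicate_strains_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ScreenSimConfig(n_strains=2, interactor_ids=("Sec3", "Sec3"))

    def test_override_for_unknown_strain_rejected(self):
        with pytest.raises(ValueError, match="overrides"):
            ScreenSimConfig(
                n_strains=2,
                interactor_ids=("Sec3",),
                overrides={"nobody": {"n_cells": 2}},
            )


class TestSimulateFrapTrace:
    def test_no_exchange_gives_flat_postbleach(self):
        cfg = FrapSimConfig(k_off=0.0, noise_sd=0.0, acquisition_bleach_rate=0.0)
        trace = simulate_frap_trace(cfg)
        post = trace.spot_intensity[cfg.bleach_frame :]
        assert np.allclose(post, post[0])
        assert post[0] < trace.spot_intensity[0]

    def test_no_bleach_is_plateau_times_envelope(self):
        cfg = FrapSimConfig(bleach_depth=0.0, noise_sd=0.0, acquisition_bleach_rate=0.002)
        trace = simulate_frap_trace(cfg)
        expected = (
            cfg.spot_amplitude * np.exp(-0.002 * trace.times) + cfg.background_offset
        )
        assert np.allclose(trace.spot_intensity, expected)

    def test_closed_form_at_one_time_constant(self):
        # k_off = 0.02/s: 50 s after the bleach the mobile pool has
        # recovered 1 - e^-1 of its bleached share
        cfg = FrapSimConfig(
            k_off=0.02,
            immobile_fraction=0.0,
            bleach_depth=0.8,
            acquisition_bleach_rate=0.0,
            noise_sd=0.0,
            frame_interval=2.0,
            bleach_frame=5,
        )
        trace = simulate_frap_trace(cfg)
        idx = cfg.bleach_frame + 25  # +50 s at 2 s/frame
        rel = (trace.spot_intensity[idx] - cfg.background_offset) / cfg.spot_amplitude
        assert rel == pytest.approx(1.0 - 0.8 * np.exp(-1.0), abs=1e-12)

    def test_closed_form_general_parameters(self):
        cfg = FrapSimConfig(
            k_off=0.05, immobile_fraction=0.3, bleach_depth=0.9,
            acquisition_bleach_rate=0.0, noise_sd=0.0, frame_interval=1.0,
            bleach_frame=4, n_frames=100,
        )
        trace = simulate_frap_trace(cfg)
        t = 30.0
        idx = int(cfg.bleach_frame + t)
        rel = (trace.spot_intensity[idx] - cfg.background_offset) / cfg.spot_amplitude
        expected = 1.0 - 0.9 * (0.3 + 0.7 * np.exp(-0.05 * t))
        assert rel == pytest.approx(expected, abs=1e-12)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="n_frames"):
            FrapSimConfig(n_frames=6, bleach_frame=5)

    def test_determinism(self):
        cfg = FrapSimConfig(seed=9)
        a = simulate_frap_trace(cfg)
        b = simulate_frap_trace(cfg)
        assert np.array_equal(a.spot_intensity, b.spot_intensity)
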