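"""Ground-truth generators: traces, rendered stacks, plates, erosion model."""

import numpy as np
import pytest
from dataclasses import replace

from conftest import iou
from microclot import (
    ConfigurationError,
    ErosionModelParams,
    InvalidInputError,
    KineticsTruth,
    RenderConfig,
    erosion_dissolution_time,
    extract_trace,
    fit_4pl,
    render_stack,
    simulate_plate,
    simulate_trace,
    volume_sweep,
)

HOURLY = np.arange(0.0, 169.0)


class TestSimulateTrace:
    def test_midpoint_of_noiseless_trace(self, control_truth):
        trace = simulate_trace(control_truth, HOURLY)
        assert trace.api_percent[72] == pytest.approx((40.0 + 105.0) / 2)

    def test_non_degrading_trace_is_flat_at_baseline(self):
        truth = KineticsTruth(40, 4, 72, 105, degrading=False)
        trace = simulate_trace(truth, HOURLY)
        assert np.all(trace.api_percent == 40.0)

    def test_noise_magnitude_matches_requested_sigma(self, control_truth):
        noisy = simulate_trace(control_truth, HOURLY, noise_sigma=2.0, seed=5)
        clean = control_truth.curve(HOURLY)
        resid_sd = np.std(noisy.api_percent - clean, ddof=1)
        assert 1.5 <= resid_sd <= 2.5

    def test_non_increasing_times_rejected(self, control_truth):
        with pytest.raises(InvalidInputError):
            simulate_trace(control_truth, [0.0, 2.0, 2.0, 3.0])

    def test_truth_invariants_enforced(self):
        with pytest.raises(InvalidInputError):
            KineticsTruth(40, -1, 72, 105)
        with pytest.raises(InvalidInputError):
            KineticsTruth(40, 4, 72, 30)  # d < a while degrading


class TestRenderStack:
    def test_roundtrip_statistic_matches_trace_model(self, control_truth, small_cfg):
        stack, gt = render_stack(control_truth, small_cfg)
        trace = extract_trace(stack, gt.mask)
        expected = control_truth.curve(trace.times_h)
        assert np.max(np.abs(trace.api_percent - expected) / expected) < 0.01

    def test_non_degrading_stack_keeps_disc_visible(self, small_cfg):
        truth = KineticsTruth(40, 4, 72, 105, degrading=False)
        stack, gt = render_stack(truth, small_cfg)
        assert np.array_equal(stack.frames[0], stack.frames[-1])
        final = stack.frames[-1]
        assert final[gt.mask].mean() < 0.5 * final[~gt.mask].mean()

    def test_vignette_pushes_final_statistic_above_100(self, small_cfg):
        truth = KineticsTruth(40, 4, 48, 100.0)
        stack, gt = render_stack(truth, replace(small_cfg, vignette_gain=0.1))
        trace = extract_trace(stack, gt.mask)
        assert trace.api_percent[-1] > 100.0

    def test_vignette_is_zero_in_frame_1(self, control_truth, small_cfg):
        plain, _ = render_stack(control_truth, small_cfg)
        vign, _ = render_stack(control_truth, replace(small_cfg, vignette_gain=0.2))
        assert np.array_equal(plain.frames[0], vign.frames[0])
        assert not np.array_equal(plain.frames[-1], vign.frames[-1])

    def test_bit_identical_under_fixed_seed(self, control_truth, small_cfg):
        cfg = replace(small_cfg, noise_sigma=250.0, speck_count=5)
        s1, _ = render_stack(control_truth, cfg)
        s2, _ = render_stack(control_truth, cfg)
        assert np.array_equal(s1.frames, s2.frames)

    def test_disc_outside_image_rejected(self):
        with pytest.raises(InvalidInputError):
            RenderConfig(image_size=(100, 100), clot_radius=60)

    def test_ground_truth_mask_is_the_rendered_disc(self, control_truth, small_cfg):
        stack, gt = render_stack(control_truth, small_cfg)
        dark = stack.frames[0] < 0.7 * small_cfg.background_level
        assert iou(dark, gt.mask) == pytest.approx(1.0)


class TestSimulatePlate:
    def test_condition_ordering_recovered_through_pipeline(self, small_cfg):
        conditions = {
            "control": KineticsTruth(40, 4, 72, 105),
            "inhibitor": KineticsTruth(40, 4, 120, 105),
        }
        stacks, truths, platemap = simulate_plate(
            conditions, n_replicates=4, cfg=small_cfg, seed=21, jitter_frac=0.05)
        fitted = {}
        for wid, stack in stacks.items():
            trace = extract_trace(stack, truths[wid].mask)
            fitted[wid] = fit_4pl(trace).c
        by_cond = platemap.groupby("condition")["well_id"].apply(list)
        mean_c = {cond: np.mean([fitted[w] for w in wells])
                  for cond, wells in by_cond.items()}
        assert mean_c["control"] < mean_c["inhibitor"]

    def test_zero_jitter_zero_noise_wells_are_identical(self, small_cfg):
        conditions = {"only": KineticsTruth(40, 4, 72, 105)}
        stacks, truths, _ = simulate_plate(conditions, n_replicates=4,
                                           cfg=small_cfg, seed=3, jitter_frac=0.0)
        cs = [fit_4pl(extract_trace(s, truths[w].mask)).c
              for w, s in stacks.items()]
        assert np.ptp(cs) / np.mean(cs) < 1e-6

    def test_fixed_seed_reproduces_stacks_bit_for_bit(self, small_cfg):
        conditions = {"a": KineticsTruth(40, 4, 72, 105)}
        cfg = replace(small_cfg, noise_sigma=200.0)
        s1, _, _ = simulate_plate(conditions, 2, cfg, seed=9)
        s2, _, _ = simulate_plate(conditions, 2, cfg, seed=9)
        for wid in s1:
            assert np.array_equal(s1[wid].frames, s2[wid].frames)

    def test_missing_condition_entry_is_a_configuration_error(self, small_cfg):
        with pytest.raises(ConfigurationError):
            simulate_plate({"bad": None}, 2, small_cfg, seed=1)
        with pytest.raises(InvalidInputError):
            simulate_plate({"a": KineticsTruth(40, 4, 72, 105)}, 1, small_cfg, seed=1)


class TestErosionModel:
    def test_alpha_zero_matches_cube_root_closed_form(self):
        params = ErosionModelParams(volume_uL=1.0, k_surf=0.033, alpha=0.0)
        t = erosion_dissolution_time(params, horizon_h=1000.0)
        closed = 3.0 * (1.0 - 0.01 ** (1 / 3)) / 0.033
        assert abs(t - closed) / closed < 0.01

    def test_vanishing_rate_is_censored(self):
        params = ErosionModelParams(volume_uL=1.0, k_surf=1e-9)
        assert erosion_dissolution_time(params, horizon_h=168.0) == np.inf

    def test_times_increase_and_accelerate_with_volume(self):
        df = volume_sweep([0.5, 1, 2, 4, 8], ErosionModelParams(), horizon_h=2000.0)
        t = df["dissolution_time_h"].to_numpy()
        assert not df["censored"].any()
        assert np.all(np.diff(t) > 0)
        assert np.all(np.diff(t, 2) > 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidInputError):
            ErosionModelParams(volume_uL=-1.0)
        with pytest.raises(InvalidInputError):
            ErosionModelParams(k_surf=0.0)
        with pytest.raises(InvalidInputError):
            erosion_dissolution_time(ErosionModelParams(), horizon_h=0.0)


class TestPipelineRoundTrip:
    @pytest.mark.parametrize("c_true", [24.0, 72.0, 120.0])
    @pytest.mark.parametrize("b_true", [2.0, 4.0, 8.0])
    def test_noiseless_render_recovers_truth(self, c_true, b_true, small_cfg):
        from microclot import generate_mask

        truth = KineticsTruth(40.0, b_true, c_true, 105.0)
        stack, gt = render_stack(truth, small_cfg)
        mask = generate_mask(stack.frames[0])
        fit = fit_4pl(extract_trace(stack, mask))
        assert abs(fit.c - c_true) / c_true < 0.02
        assert abs(fit.d - 105.0) / 105.0 < 0.02
        assert abs(fit.a - 40.0) < 2.0
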