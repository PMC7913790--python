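"""Inverse-solver correctness: exact recovery, degeneracy handling, units."""

import numpy as np
import pytest

from conftest import TRUE_D, TRUE_U, multi_blob_stack
from iffmap.estimation import (
    EstimationOptions,
    assemble_pixel_system,
    estimate_transport,
    to_physical_units,
    to_pixel_frame_units,
    velocity_magnitude,
)
from iffmap.image_io import subtract_background
from iffmap.synthetic import PhantomSpec, make_phantom, simulate_stack
from iffmap.types import (
    STATUS_DEGENERATE,
    ConcentrationStack,
    RegionMask,
    TransportField,
)


def _stack_from_frames(frames, times=None):
    frames = np.asarray(frames, dtype=float)
    if times is None:
        times = np.arange(len(frames), dtype=float)
    return ConcentrationStack(frames=frames, frame_times=times, pixel_spacing=1.0,
                              pre_contrast_count=0)


class TestAssemblePixelSystem:
    def test_flat_frames_are_degenerate(self):
        stack = _stack_from_frames([np.full((5, 5), 2.0)] * 4)
        system = assemble_pixel_system(stack, (2, 2))
        assert system.status == "degenerate"
        np.testing.assert_array_equal(system.response, 0.0)
        np.testing.assert_array_equal(system.design, 0.0)

    def test_hand_computed_stencil_coefficients(self):
        """Center-pixel row coefficients equal the hand-evaluated stencils."""
        phi0 = np.array([[0.0, 1.0, 2.0], [1.0, 3.0, 2.0], [2.0, 2.0, 4.0]])
        frames = [phi0, phi0 + 1.0, phi0 + 1.5, phi0 + 1.75]
        system = assemble_pixel_system(_stack_from_frames(frames), (1, 1))
        # L = 1 + 2 + 1 + 2 - 4*3 = -6 ; Gx = (2-1)/2 ; Gy = (2-1)/2
        np.testing.assert_allclose(system.design[0], [-6.0, -0.5, -0.5])
        np.testing.assert_allclose(system.response, [1.0, 0.5, 0.25])

    def test_matched_forward_rows_satisfied_by_true_parameters(self, matched_stack):
        """One FTCS step per interval: the true (D, ux, uy) zero the residual."""
        stack = subtract_background(matched_stack)
        theta = np.array([TRUE_D, TRUE_U[0], TRUE_U[1]])
        for pixel in [(20, 20), (32, 32), (40, 25)]:
            system = assemble_pixel_system(stack, pixel)
            residual = system.design @ theta - system.response
            assert np.max(np.abs(residual)) < 1e-10

    def test_border_pixel_rejected(self):
        stack = _stack_from_frames([np.random.default_rng(0).random((5, 5))] * 4)
        with pytest.raises(IndexError, match="border"):
            assemble_pixel_system(stack, (0, 2))

    def test_solution_matches_estimate_transport(self, matched_stack):
        stack = subtract_background(matched_stack)
        field = estimate_transport(stack)
        system = assemble_pixel_system(stack, (30, 30))
        sol = system.solve()
        assert field.valid_mask[30, 30]
        np.testing.assert_allclose(
            sol,
            [field.diffusion[30, 30], field.velocity_x[30, 30], field.velocity_y[30, 30]],
            rtol=1e-8,
        )


class TestEstimateTransport:
    def test_exact_recovery_on_matched_stack(self, matched_stack):
        """Noiseless matched discretization recovers D, ux, uy to 1e-6 everywhere valid."""
        field = estimate_transport(subtract_background(matched_stack))
        ok = field.valid_mask
        assert ok.sum() > 1000
        assert np.nanmax(np.abs(field.diffusion[ok] - TRUE_D) / TRUE_D) < 1e-6
        assert np.nanmax(np.abs(field.velocity_x[ok] - TRUE_U[0]) / abs(TRUE_U[0])) < 1e-6
        assert np.nanmax(np.abs(field.velocity_y[ok] - TRUE_U[1]) / abs(TRUE_U[1])) < 1e-6

    def test_pure_diffusion_recovers_zero_velocity(self):
        spec = PhantomSpec(grid_shape=(64, 64), kind="uniform", diffusion=0.2,
                           velocity=(0.0, 0.0))
        field_true, init = make_phantom(spec)
        stack = simulate_stack(field_true, init, [0, 1, 2, 3, 4], pre_contrast_count=1,
                               scheme="gradient", dt_micro=1.0)
        est = estimate_transport(subtract_background(stack))
        ok = est.valid_mask
        assert np.nanmedian(velocity_magnitude(est)[ok]) < 1e-6
        assert np.nanmax(np.abs(est.diffusion[ok] - 0.2) / 0.2) < 1e-6

    def test_spatially_varying_field_recovered_at_matched_discretization(self):
        """Per-pixel solves recover a piecewise tumor/parenchyma transport field."""
        spec = PhantomSpec(
            grid_shape=(64, 64), kind="tumor_ring",
            inner_speed=0.05, outer_speed=0.15,
            inner_diffusion=0.1, outer_diffusion=0.2,
            blobs=[(26, 26, 6, 1.0), (38, 38, 5, 0.8)],
        )
        truth, init = make_phantom(spec)
        stack = simulate_stack(truth, init, [0, 1, 2, 3, 4], pre_contrast_count=1,
                               scheme="gradient", dt_micro=1.0)
        est = estimate_transport(subtract_background(stack))
        ok = est.valid_mask
        assert ok.sum() > 500
        for est_map, true_map in [
            (est.diffusion, truth.diffusion),
            (est.velocity_x, truth.velocity_x),
            (est.velocity_y, truth.velocity_y),
        ]:
            err = np.abs(est_map[ok] - true_map[ok])
            assert np.nanmax(err) < 1e-6

    def test_flat_regions_are_invalid_not_zero_velocity(self):
        """A flat background patch yields invalid pixels, never |u| = 0 estimates."""
        frames = np.zeros((4, 32, 32))
        blob = np.zeros((32, 32))
        blob[8:16, 8:16] = np.random.default_rng(1).random((8, 8)) + 1.0
        for k in range(4):
            frames[k] = blob * (1 + 0.2 * k)
        stack = _stack_from_frames(frames)
        field = estimate_transport(stack)
        flat = np.zeros((32, 32), dtype=bool)
        flat[20:30, 20:30] = True
        assert not field.valid_mask[flat].any()
        assert np.all(field.status[flat] == STATUS_DEGENERATE)
        assert np.all(np.isnan(field.diffusion[flat]))

    def test_noise_degrades_errors_monotonically(self, blob_roi):
        """Median per-pixel |error| grows with noise sigma for both D and |u|."""
        true_u = float(np.hypot(*TRUE_U))
        med_u, med_d = [], []
        for sigma_frac in [0.0, 0.005, 0.01, 0.02, 0.05]:
            eu, ed = [], []
            for seed in range(30):
                stack = multi_blob_stack(16, sigma_frac, seed)
                est = estimate_transport(subtract_background(stack), blob_roi)
                ok = est.valid_mask
                eu.append(np.nanmedian(np.abs(velocity_magnitude(est)[ok] - true_u)))
                ed.append(np.nanmedian(np.abs(est.diffusion[ok] - TRUE_D)))
            med_u.append(np.median(eu))
            med_d.append(np.median(ed))
        assert np.all(np.diff(med_u) > 0)
        assert np.all(np.diff(med_d) > 0)

    def test_mismatched_discretization_recovery_within_frozen_bounds(self, blob_roi):
        """Fine-micro-step data inverted with the frame-level stencil: D within 15%."""
        stack = multi_blob_stack(8, 0.0, 0, diffusion=0.08, velocity=(0.1, 0.15))
        # regenerate with the conservative micro-stepped scheme (mismatched)
        spec = PhantomSpec(grid_shape=(64, 64), kind="uniform", diffusion=0.08,
                           velocity=(0.1, 0.15),
                           blobs=[(26, 26, 4, 1.0), (38, 28, 5, 0.8),
                                  (28, 40, 3.5, 0.9), (40, 40, 4.5, 0.7)])
        truth, init = make_phantom(spec)
        times = [float(t) for t in range(9)]
        stack = simulate_stack(truth, init, times, pre_contrast_count=1,
                               scheme="conservative", cfl_factor=0.1)
        est = estimate_transport(subtract_background(stack), blob_roi)
        ok = est.valid_mask
        d_med = np.nanmedian(est.diffusion[ok])
        u_med = np.nanmedian(velocity_magnitude(est)[ok])
        assert abs(d_med - 0.08) / 0.08 < 0.15
        assert abs(u_med - np.hypot(0.1, 0.15)) / np.hypot(0.1, 0.15) < 0.05

    def test_negative_d_policy_clip_flags_but_keeps_pixel(self):
        rng = np.random.default_rng(4)
        frames = rng.random((5, 16, 16)) + 0.5  # incoherent -> some negative D fits
        stack = _stack_from_frames(frames)
        clipped = estimate_transport(stack, options=EstimationOptions(negative_d_policy="clip"))
        rejected = estimate_transport(stack, options=EstimationOptions(negative_d_policy="reject"))
        ok = clipped.valid_mask
        assert np.nanmin(clipped.diffusion[ok]) >= 0.0
        assert rejected.valid_mask.sum() <= clipped.valid_mask.sum()

    def test_too_few_intervals_rejected(self):
        stack = _stack_from_frames(np.random.default_rng(0).random((3, 8, 8)))
        with pytest.raises(ValueError, match="underdetermined"):
            estimate_transport(stack)

    def test_empty_mask_rejected(self, matched_stack):
        stack = subtract_background(matched_stack)
        with pytest.raises(ValueError, match="empty"):
            estimate_transport(stack, RegionMask(np.zeros((64, 64), dtype=bool)))


class TestUnits:
    def _field(self, D=1.0, ux=2.0, uy=0.0):
        shape = (4, 4)
        return TransportField(
            diffusion=np.full(shape, D),
            velocity_x=np.full(shape, ux),
            velocity_y=np.full(shape, uy),
            valid_mask=np.ones(shape, dtype=bool),
            pixel_spacing=1.0,
            units="pixel-frame",
            frame_interval_s=1.0,
        )

    def test_identity_conversion(self):
        phys = to_physical_units(self._field(D=1.0), 1.0, 1.0)
        assert phys.units == "physical"
        np.testing.assert_array_equal(phys.diffusion, 1.0)

    def test_velocity_scaling(self):
        phys = to_physical_units(self._field(ux=2.0), 0.5, 10.0)
        np.testing.assert_allclose(phys.velocity_x, 0.1)

    def test_round_trip_exact(self):
        field = self._field(D=0.37, ux=1.2, uy=-0.4)
        back = to_pixel_frame_units(to_physical_units(field, 0.93, 17.0), 0.93, 17.0)
        np.testing.assert_allclose(back.diffusion, field.diffusion, rtol=1e-12)
        np.testing.assert_allclose(back.velocity_x, field.velocity_x, rtol=1e-12)
        np.testing.assert_allclose(back.velocity_y, field.velocity_y, rtol=1e-12)

    def test_magnitude_commutes_with_conversion(self):
        field = self._field(D=0.1, ux=0.3, uy=-0.4)
        phys = to_physical_units(field, 0.8, 4.0)
        np.testing.assert_allclose(
            velocity_magnitude(phys), velocity_magnitude(field) * (0.8 / 4.0)
        )


class TestVelocityMagnitude:
    def test_three_four_five(self):
        field = TransportField(
            diffusion=np.zeros((2, 2)),
            velocity_x=np.full((2, 2), 3.0),
            velocity_y=np.full((2, 2), 4.0),
            valid_mask=np.ones((2, 2), dtype=bool),
        )
        np.testing.assert_array_equal(velocity_magnitude(field), 5.0)

    def test_zero_and_nan_propagation(self):
        field = TransportField(
            diffusion=np.zeros((2, 2)),
            velocity_x=np.array([[0.0, np.nan], [1.0, 0.0]]),
            velocity_y=np.array([[0.0, np.nan], [0.0, 0.0]]),
            valid_mask=np.array([[True, False], [True, True]]),
        )
        mag = velocity_magnitude(field)
        assert mag[0, 0] == 0.0
        assert np.isnan(mag[0, 1])

    def test_rotated_field_gives_rotated_magnitude_map(self):
        rng = np.random.default_rng(3)
        ux = rng.normal(size=(12, 12))
        uy = rng.normal(size=(12, 12))
        field = TransportField(
            diffusion=np.zeros((12, 12)), velocity_x=ux, velocity_y=uy,
            valid_mask=np.ones((12, 12), dtype=bool),
        )
        # rotate grid 90 deg CCW in storage and the vectors with it
        rot = TransportField(
            diffusion=np.zeros((12, 12)),
            velocity_x=np.rot90(uy),
            velocity_y=np.rot90(-ux),
            valid_mask=np.ones((12, 12), dtype=bool),
        )
        np.testing.assert_allclose(
            velocity_magnitude(rot), np.rot90(velocity_magnitude(field))
        )
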