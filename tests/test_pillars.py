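import warnings

import numpy as np
import pytest

from mechanoinvade.phantoms import PillarPhantomSpec, generate_pillar_sequence
from mechanoinvade.pillars import (
    PillarSpec,
    compute_spring_constant,
    correct_drift,
    detect_pillars,
    forces_and_summary,
    track_pillars,
)


class TestSpringConstant:
    def test_pdms_pillar_matches_printed_value(self):
        """2 MPa, 5 µm x 1 µm pillar: k agrees with the published 2.35 nN/µm
        to the printed precision."""
        k = compute_spring_constant(2e6, 5.0, 1.0)
        assert abs(k - 2.35) < 0.01

    def test_fourth_power_diameter_scaling(self):
        assert compute_spring_constant(2e6, 5.0, 2.0) == pytest.approx(
            16 * compute_spring_constant(2e6, 5.0, 1.0)
        )
        assert compute_spring_constant(2e6, 5.0, 2.0) == pytest.approx(37.70, abs=0.01)

    def test_inverse_cubic_height_scaling(self):
        assert compute_spring_constant(2e6, 10.0, 1.0) == pytest.approx(
            compute_spring_constant(2e6, 5.0, 1.0) / 8
        )
        assert compute_spring_constant(2e6, 10.0, 1.0) == pytest.approx(0.2945, abs=0.001)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_spring_constant(-1.0, 5.0, 1.0)
        with pytest.raises(ValueError):
            compute_spring_constant(2e6, 0.0, 1.0)

    def test_pillar_spec_checks_consistency(self):
        assert PillarSpec().spring_constant_nN_per_um == pytest.approx(2.3562, abs=1e-3)
        with pytest.raises(ValueError, match="beam formula"):
            PillarSpec(spring_constant_nN_per_um=5.0)


def lattice_order_match(detected_xy, true_xy):
    """Permutation mapping each detected position to its nearest truth."""
    return np.array(
        [int(np.argmin(np.linalg.norm(true_xy - p, axis=1))) for p in detected_xy]
    )


class TestDetectPillars:
    def test_full_lattice_detected_subpixel(self):
        spec = PillarPhantomSpec(n_rows=8, n_cols=8, n_frames=1, seed=2)
        frames, _ = generate_pillar_sequence(spec)
        xy = detect_pillars(frames[0], spec.pitch_um, spec.pixel_size_um)
        assert len(xy) == 64
        truth = spec.rest_positions_um()
        perm = lattice_order_match(xy, truth)
        assert len(set(perm)) == 64
        err_px = np.abs(xy - truth[perm]) / spec.pixel_size_um
        assert err_px.max() < 0.5

    def test_blank_frame_errors(self):
        with pytest.raises(ValueError, match="pillars"):
            detect_pillars(np.zeros((64, 64)), 2.0, 0.16)

    def test_missing_pillar_warns_incomplete(self):
        spec = PillarPhantomSpec(n_rows=4, n_cols=4, n_frames=1, noise_sd=0.0)
        frames, _ = generate_pillar_sequence(spec)
        # erase one interior pillar
        pos = spec.rest_positions_um()[5] / spec.pixel_size_um
        r, c = int(round(pos[1])), int(round(pos[0]))
        frames[0][r - 8 : r + 8, c - 8 : c + 8] = 0.0
        with pytest.warns(UserWarning, match="incomplete"):
            xy = detect_pillars(frames[0], spec.pitch_um, spec.pixel_size_um)
        assert len(xy) == 15


def tracked_phantom(disp=None, drift=None, n=16, T=12, seed=8):
    rows = int(np.sqrt(n))
    spec = PillarPhantomSpec(
        n_rows=rows, n_cols=rows, n_frames=T, displacements_um=disp, drift_um=drift, seed=seed
    )
    frames, truth = generate_pillar_sequence(spec)
    rest = detect_pillars(frames[0], spec.pitch_um, spec.pixel_size_um)
    tracks = track_pillars(frames, rest, spec.pixel_size_um, spec.pitch_um)
    perm = lattice_order_match(rest, spec.rest_positions_um())
    return spec, tracks, truth[perm]


class TestTrackPillars:
    def test_static_lattice_below_noise_floor(self):
        _, tracks, _ = tracked_phantom()
        disp_nm = 1000 * np.linalg.norm(tracks.displacements_um, axis=-1)
        assert disp_nm.max() < 20.0

    def test_step_displacement_recovered(self):
        n, T = 16, 12
        disp = np.zeros((n, T, 2))
        disp[5, 6:, 0] = 0.3
        _, tracks, truth = tracked_phantom(disp=disp)
        err_nm = 1000 * np.linalg.norm(tracks.displacements_um - truth, axis=-1)
        assert err_nm.max() < 20.0

    def test_ramp_to_max_displacement_recovered(self):
        n, T = 16, 12
        disp = np.zeros((n, T, 2))
        disp[10, :, 1] = np.linspace(0, 0.425, T)
        _, tracks, truth = tracked_phantom(disp=disp)
        final = np.linalg.norm(tracks.displacements_um[:, -1, :], axis=-1)
        assert abs(final.max() - 0.425) * 1000 < 20.0


class TestCorrectDrift:
    def test_pure_drift_removed(self):
        T = 12
        drift = np.cumsum(np.full((T, 2), 0.01), axis=0)
        drift[0] = 0
        _, tracks, _ = tracked_phantom(drift=drift)
        corrected = correct_drift(tracks, tracks.pillar_ids[:6])
        resid_nm = 1000 * np.linalg.norm(corrected.displacements_um, axis=-1)
        assert resid_nm.max() < 20.0

    def test_loaded_pillar_preserved_under_drift(self):
        n, T = 16, 12
        disp = np.zeros((n, T, 2))
        disp[7, :, 0] = np.linspace(0, 0.3, T)
        drift = np.outer(np.linspace(0, 0.15, T), [1.0, -0.5])
        _, tracks, truth = tracked_phantom(disp=disp, drift=drift)
        loaded = int(np.argmax(np.linalg.norm(truth, axis=-1).max(axis=1)))
        refs = np.array([i for i in range(n) if i != loaded])[:6]
        corrected = correct_drift(tracks, refs)
        err_nm = 1000 * np.linalg.norm(
            corrected.displacements_um[loaded] - truth[loaded], axis=-1
        )
        assert err_nm.max() < 20.0

    def test_empty_reference_set_errors(self):
        _, tracks, _ = tracked_phantom()
        with pytest.raises(ValueError, match="empty"):
            correct_drift(tracks, np.array([], dtype=int))

    def test_contaminated_reference_warns(self):
        n, T = 16, 12
        disp = np.zeros((n, T, 2))
        disp[3, :, 0] = np.linspace(0, 0.4, T)
        _, tracks, _ = tracked_phantom(disp=disp)
        with pytest.warns(UserWarning, match="reference"):
            correct_drift(tracks, tracks.pillar_ids)


class TestForcesAndSummary:
    def test_zero_displacement_zero_force(self):
        _, tracks, _ = tracked_phantom()
        summary = forces_and_summary(tracks, 2.3562)
        assert summary.peak_force_nN.max() < 0.05  # noise floor only

    def test_displacement_times_stiffness_near_one_nanonewton(self):
        n, T = 16, 12
        disp = np.zeros((n, T, 2))
        disp[5, 1:, 0] = 0.425  # zero-force rest at frame 1, then loaded
        spec, tracks, truth = tracked_phantom(disp=disp)
        summary = forces_and_summary(tracks, 2.35)
        assert summary.peak_force_nN.max() == pytest.approx(1.0, abs=0.06)

    def test_aggregate_is_mean_of_peaks(self):
        _, tracks, _ = tracked_phantom()
        # synthetic: fabricate two pillars with known peaks
        from mechanoinvade.pillars import PillarTrackSet

        centers = np.zeros((2, 3, 2))
        centers[0, :, 0] = [0.0, 0.2, 0.4]
        centers[1, :, 0] = [0.0, 1.0, 1.2]
        ts = PillarTrackSet(
            pillar_ids=np.array([0, 1]),
            rest_positions_um=np.zeros((2, 2)),
            centers_um=centers,
            drift_um=np.zeros((3, 2)),
        )
        summary = forces_and_summary(ts, 2.5)
        np.testing.assert_allclose(summary.peak_force_nN, [1.0, 3.0])
        assert summary.cell_aggregate_nN == pytest.approx(2.0)

    def test_peak_invariant_under_frame_reordering(self):
        n, T = 16, 12
        rng = np.random.default_rng(0)
        disp = rng.uniform(-0.3, 0.3, size=(n, T, 2))
        spec, tracks, _ = tracked_phantom(disp=disp)
        base = forces_and_summary(tracks, 2.3562).peak_force_nN
        from mechanoinvade.pillars import PillarTrackSet

        order = rng.permutation(tracks.centers_um.shape[1])
        shuffled = PillarTrackSet(
            pillar_ids=tracks.pillar_ids,
            rest_positions_um=tracks.rest_positions_um,
            centers_um=tracks.centers_um[:, order, :],
            drift_um=tracks.drift_um[order],
        )
        np.testing.assert_allclose(
            forces_and_summary(shuffled, 2.3562).peak_force_nN, base
        )

    def test_force_linear_in_stiffness(self):
        _, tracks, _ = tracked_phantom()
        f1 = forces_and_summary(tracks, 1.0).peak_force_nN
        f2 = forces_and_summary(tracks, 3.0).peak_force_nN
        np.testing.assert_allclose(f2, 3 * f1, rtol=1e-12)

    def test_nonpositive_stiffness_rejected(self):
        _, tracks, _ = tracked_phantom()
        with pytest.raises(ValueError):
            forces_and_summary(tracks, 0.0)
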