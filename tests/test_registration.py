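"""Chromatic/drift estimation, nucleus segmentation, foci fitting, corrections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromtrace.registration import (
    RegistrationError,
    RigidTransform3D,
    apply_corrections,
    estimate_chromatic_transform,
    estimate_drift,
    fit_foci,
    fit_foci_zstack,
    segment_nuclei,
)
from chromtrace.synthetic_data import SimulationConfig, render_zstack, simulate_conformations, simulate_imaging


def xyz_frame(points):
    return pd.DataFrame(np.atleast_2d(points), columns=["x_nm", "y_nm", "z_nm"])


def scattered_beads(n, seed, spread=20_000.0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0, spread, size=(n, 3))


class TestChromatic:
    def test_constant_offset_recovered_exactly(self):
        beads = scattered_beads(15, 0)
        offset = np.array([60.0, 40.0, 0.0])
        t = estimate_chromatic_transform(xyz_frame(beads + offset), xyz_frame(beads))
        assert np.allclose(t.translation, -offset)
        assert t.rms == pytest.approx(0.0, abs=1e-9)

    def test_identical_channels_identity(self):
        beads = scattered_beads(10, 1)
        t = estimate_chromatic_transform(xyz_frame(beads), xyz_frame(beads))
        assert np.allclose(t.translation, 0.0)
        assert t.rms == 0.0

    def test_affine_recovery(self):
        rng = np.random.default_rng(2)
        beads = scattered_beads(10, 3, spread=5000.0)
        M = np.eye(3) + rng.normal(scale=1e-3, size=(3, 3))
        tvec = np.array([50.0, -30.0, 10.0])
        moved = beads @ M.T + tvec
        # moving -> reference: estimate should invert the planted map
        t = estimate_chromatic_transform(xyz_frame(beads), xyz_frame(moved), mode="affine")
        rec = t.apply(beads)
        assert np.allclose(rec, moved, rtol=1e-6, atol=1e-6)

    def test_too_few_matches_is_error(self):
        with pytest.raises(RegistrationError, match="at least"):
            estimate_chromatic_transform(xyz_frame(np.zeros((0, 3))), xyz_frame(np.zeros((0, 3))))


class TestDrift:
    def test_noiseless_drift_exact(self):
        beads = scattered_beads(20, 4)
        drift = np.array([100.0, -50.0, 20.0])
        t = estimate_drift(xyz_frame(beads + drift), xyz_frame(beads))
        assert np.allclose(t.translation, drift)

    def test_self_reference_zero(self):
        beads = scattered_beads(20, 5)
        t = estimate_drift(xyz_frame(beads), xyz_frame(beads))
        assert np.allclose(t.translation, 0.0)

    def test_zero_matches_error(self):
        a = scattered_beads(5, 6)
        with pytest.raises(RegistrationError):
            estimate_drift(xyz_frame(a + 1e7), xyz_frame(a))

    def test_jittered_estimate_within_standard_error(self):
        # sigma=10 nm on 20 beads: per-axis error should stay below 3*sigma/sqrt(20)
        beads = scattered_beads(20, 7)
        drift = np.array([120.0, 80.0, -40.0])
        rng = np.random.default_rng(8)
        obs = beads + drift + rng.normal(scale=10.0, size=beads.shape)
        t = estimate_drift(xyz_frame(obs), xyz_frame(beads))
        assert np.all(np.abs(t.translation - drift) <= 3 * 10.0 / np.sqrt(20))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.tuples(*[st.floats(-1e5, 1e5) for _ in range(3)]))
    def test_translation_equivariance(self, shift):
        beads = scattered_beads(12, 9)
        drift = np.array([75.0, -25.0, 5.0])
        v = np.array(shift)
        t0 = estimate_drift(xyz_frame(beads + drift), xyz_frame(beads))
        t1 = estimate_drift(xyz_frame(beads + drift + v), xyz_frame(beads + v))
        assert np.allclose(t0.translation, t1.translation, atol=1e-6)

    def test_robust_trim_discards_outlier(self):
        beads = scattered_beads(10, 10)
        drift = np.array([10.0, 0.0, 0.0])
        obs = beads + drift
        obs[0] += 400.0  # one corrupted bead
        plain = estimate_drift(xyz_frame(obs), xyz_frame(beads))
        robust = estimate_drift(xyz_frame(obs), xyz_frame(beads), robust=True)
        err_plain = np.abs(plain.translation - drift).max()
        err_robust = np.abs(robust.translation - drift).max()
        assert err_robust < err_plain


class TestNucleusSegmentation:
    @staticmethod
    def _blob_image(centers, radius=6, shape=(64, 64)):
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        img = np.zeros(shape)
        for cy, cx in centers:
            img += 100.0 * (((yy - cy) ** 2 + (xx - cx) ** 2) <= radius**2)
        return img

    def test_two_blobs_two_nuclei(self):
        masks = segment_nuclei(self._blob_image([(16, 16), (48, 48)]), min_volume=10)
        assert len(masks) == 2

    def test_blank_image_no_nuclei(self):
        masks = segment_nuclei(np.zeros((32, 32)), min_volume=10)
        assert len(masks) == 0

    def test_disk_centers_and_radius_recovered(self):
        masks = segment_nuclei(self._blob_image([(20, 40)], radius=8), min_volume=10)
        row = masks.iloc[0]
        assert row.cx == pytest.approx(40, abs=1)
        assert row.cy == pytest.approx(20, abs=1)
        assert row.radius == pytest.approx(8, rel=0.15)

    def test_vector_mode_pass_through(self):
        table = pd.DataFrame({"nucleus_id": [0], "cx": [1.0], "cy": [2.0], "cz": [3.0], "radius": [5.0]})
        assert segment_nuclei(nuclei_table=table).equals(table)


class TestFociFitting:
    def test_noiseless_render_fit_within_a_tenth_voxel(self):
        truth = np.array([[3456.0, 2592.0, 1500.0]])
        img = render_zstack(truth, intensities=5e4, background=5.0, shot_noise=False)
        out = fit_foci_zstack(img, intensity_threshold=50.0)
        assert len(out) == 1
        row = out.iloc[0]
        assert abs(row.x_nm - truth[0, 0]) <= 0.1 * 108
        assert abs(row.y_nm - truth[0, 1]) <= 0.1 * 108
        assert abs(row.z_nm - truth[0, 2]) <= 0.1 * 200

    def test_fit_accuracy_at_snr20(self):
        rng = np.random.default_rng(13)
        truth = np.array([[3456.0, 2592.0, 1500.0]])
        img = render_zstack(truth, intensities=2e5, background=100.0, shot_noise=True, rng=rng)
        out = fit_foci_zstack(img, intensity_threshold=300.0)
        row = out.iloc[0]
        assert abs(row.x_nm - truth[0, 0]) <= 0.15 * 108
        assert abs(row.y_nm - truth[0, 1]) <= 0.15 * 108

    def _foci_table(self, points, intensity=1000.0):
        df = xyz_frame(points)
        df["intensity"] = intensity
        df["round"] = 0
        df["channel"] = "647"
        return df

    def test_focus_outside_masks_excluded(self):
        masks = pd.DataFrame({"nucleus_id": [0], "cx": [0.0], "cy": [0.0], "cz": [0.0], "radius": [1000.0]})
        foci = self._foci_table([[0, 0, 0], [50_000, 0, 0]])
        accepted, pool, qc = fit_foci(foci, masks, intensity_threshold=0.0, containment_margin=0.0)
        assert len(accepted) == 1 and qc["n_outside"] == 1

    def test_subthreshold_goes_to_pool(self):
        masks = pd.DataFrame({"nucleus_id": [0], "cx": [0.0], "cy": [0.0], "cz": [0.0], "radius": [1000.0]})
        foci = pd.concat(
            [self._foci_table([[0, 0, 0]], 1000.0), self._foci_table([[10, 0, 0]], 100.0)],
            ignore_index=True,
        )
        accepted, pool, qc = fit_foci(foci, masks, intensity_threshold=400.0)
        assert len(accepted) == 1 and len(pool) == 1
        assert qc["n_accepted"] == 1 and qc["n_subthreshold"] == 1


class TestCorrections:
    def _experiment(self, toy_panel, seed=14, **over):
        base = dict(sigma_xy=0.0, sigma_z=0.0, p_det=1.0, false_positive_rate=0.0)
        base.update(over)
        cfg = SimulationConfig(seed=seed, n_traces=4, n_loci=toy_panel.n_segments, **base)
        ens = simulate_conformations(cfg, toy_panel)
        return ens, simulate_imaging(ens, toy_panel, cfg)

    def test_round_trip_recovers_ground_truth_exactly(self, toy_panel):
        ens, exp = self._experiment(toy_panel)
        chromatic = estimate_chromatic_transform(
            exp.chromatic_beads[exp.chromatic_beads["channel"] == "560"],
            exp.chromatic_beads[exp.chromatic_beads["channel"] == "647"],
        )
        ref = exp.fiducials[exp.fiducials["round"] == 0]
        drifts = {
            int(r): estimate_drift(exp.fiducials[exp.fiducials["round"] == r], ref)
            for r in exp.fiducials["round"].unique()
        }
        reg = apply_corrections(exp.foci, chromatic, drifts)
        truth = ens.traces[reg["truth_trace"], reg["truth_locus"]]
        assert np.allclose(reg[["x_nm", "y_nm", "z_nm"]].to_numpy(), truth, atol=1e-9)

    def test_estimated_drifts_equal_planted(self, toy_panel):
        _, exp = self._experiment(toy_panel, seed=15)
        ref = exp.fiducials[exp.fiducials["round"] == 0]
        for r, planted in exp.drifts.items():
            est = estimate_drift(exp.fiducials[exp.fiducials["round"] == r], ref)
            assert np.allclose(est.translation, planted, atol=1e-9)

    def test_transform_inverse_composition(self):
        t = RigidTransform3D(translation=np.array([10.0, -5.0, 3.0]))
        pts = scattered_beads(7, 16)
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)
        rng = np.random.default_rng(17)
        ta = RigidTransform3D(
            translation=np.array([3.0, 4.0, 5.0]),
            matrix=np.eye(3) + rng.normal(scale=0.01, size=(3, 3)),
        )
        assert np.allclose(ta.inverse().apply(ta.apply(pts)), pts, atol=1e-9)

    def test_registration_preserves_rows_and_labels(self, toy_panel):
        _, exp = self._experiment(toy_panel, seed=18, false_positive_rate=2.0)
        drifts = {r: RigidTransform3D(translation=v) for r, v in exp.drifts.items()}
        reg = apply_corrections(exp.foci, None, drifts)
        assert len(reg) == len(exp.foci)
        assert (reg["intensity"] == exp.foci["intensity"]).all()
        assert (reg["round"] == exp.foci["round"]).all()
        assert (reg["channel"] == exp.foci["channel"]).all()

    def test_missing_round_transform_is_error(self, toy_panel):
        _, exp = self._experiment(toy_panel, seed=19)
        with pytest.raises(RegistrationError, match="rounds"):
            apply_corrections(exp.foci, None, {0: np.zeros(3)})

    def test_correction_reduces_fiducial_rms_under_noise(self, toy_panel):
        cfg = SimulationConfig(seed=20, n_traces=3, n_loci=toy_panel.n_segments,
                               sigma_xy=10.0, sigma_z=20.0)
        ens = simulate_conformations(cfg, toy_panel)
        exp = simulate_imaging(ens, toy_panel, cfg)
        f = exp.fiducials
        ref = f[f["round"] == 0].set_index("fiducial_id")[["x_nm", "y_nm", "z_nm"]]
        pre, post = [], []
        for r in sorted(f["round"].unique())[1:]:
            cur = f[f["round"] == r].set_index("fiducial_id")[["x_nm", "y_nm", "z_nm"]]
            est = estimate_drift(cur, ref)
            pre.append(np.sqrt(((cur - ref) ** 2).sum(axis=1).mean()))
            post.append(np.sqrt(((cur - est.translation - ref) ** 2).sum(axis=1).mean()))
        assert np.mean(post) <= np.mean(pre)
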