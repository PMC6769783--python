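"""Morphometry: volume, LAC, bead calibration, shape tensor, FA, 2D area."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sxtmorph import (
    LabelVolume,
    area_2d,
    calibrate_beads,
    fractional_anisotropy,
    organelle_lac,
    organelle_volume,
    quantify_cell,
    shape_eigenvalues,
)
from sxtmorph.recon import ReconVolume
from sxtmorph.phantom import make_cell_phantom, PhantomConfig

from conftest import rasterize_ellipsoid


class TestVolume:
    def test_printed_pixel_size_arithmetic(self):
        # 1000 voxels at the 11.8 nm working pixel size
        assert organelle_volume(1000, 11.8) == pytest.approx(1000 * 11.8**3)
        assert organelle_volume(1, 1.0) == 1.0

    def test_sphere_volume_within_rasterization_error(self):
        mask = rasterize_ellipsoid(32, (10, 10, 10))
        vol = organelle_volume(int(mask.sum()), 1.0)
        assert vol == pytest.approx(4 / 3 * np.pi * 10**3, rel=0.05)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            organelle_volume(0, 11.8)

    def test_additive_over_disjoint_merges(self):
        assert organelle_volume(700, 11.8) + organelle_volume(300, 11.8) == (
            organelle_volume(1000, 11.8)
        )


class TestLac:
    def test_uniform_region(self):
        vol = np.full((8, 8, 8), 0.45, dtype=np.float32)
        mask = np.zeros_like(vol, dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        mean, sd = organelle_lac(ReconVolume(vol, 10.0), mask)
        assert mean == pytest.approx(0.45)
        assert sd == pytest.approx(0.0, abs=1e-7)

    def test_two_voxel_mask(self):
        vol = np.zeros((4, 4, 4))
        vol[0, 0, 0], vol[0, 0, 1] = 0.4, 0.5
        mask = np.zeros_like(vol, dtype=bool)
        mask[0, 0, :2] = True
        mean, sd = organelle_lac(ReconVolume(vol, 10.0), mask)
        assert mean == pytest.approx(0.45)
        assert sd == pytest.approx(0.05)

    def test_empty_mask_rejected(self):
        vol = np.zeros((4, 4, 4))
        with pytest.raises(ValueError):
            organelle_lac(ReconVolume(vol, 10.0), np.zeros_like(vol, dtype=bool))


class TestBeadCalibration:
    @staticmethod
    def _bead_scene():
        vol = np.full((24, 24, 24), 0.2, dtype=np.float32)
        labels = np.zeros_like(vol, dtype=np.int32)
        bead = rasterize_ellipsoid(24, (4, 4, 4))
        vol[bead] = 8.0
        labels[bead] = 1
        organelle = np.zeros_like(bead)
        organelle[2:6, 2:6, 2:6] = True
        vol[organelle] = 0.45
        labels[organelle] = 2
        return vol, labels, organelle

    def test_identity_case(self):
        vol, labels, _ = self._bead_scene()
        beads = LabelVolume(labels=(labels == 1).astype(np.int32), kind="groundtruth",
                            voxel_size=40.0, bead_ids=(1,))
        cal = calibrate_beads(ReconVolume(vol, 40.0), beads, nominal_bead_lac=8.0)
        assert cal.scale == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("gain", [0.5, 2.0, 10.0])
    def test_normalized_lac_invariant_under_global_gain(self, gain):
        """Bead calibration exists to cancel per-tomogram gain variation."""
        vol, labels, organelle = self._bead_scene()
        beads = LabelVolume(labels=(labels == 1).astype(np.int32), kind="groundtruth",
                            voxel_size=40.0, bead_ids=(1,))
        cal_1 = calibrate_beads(ReconVolume(vol, 40.0), beads, 8.0)
        cal_g = calibrate_beads(ReconVolume(vol * gain, 40.0), beads, 8.0)
        lac_1, _ = organelle_lac(ReconVolume(vol, 40.0), organelle)
        lac_g, _ = organelle_lac(ReconVolume(vol * gain, 40.0), organelle)
        assert cal_g.scale == pytest.approx(cal_1.scale / gain, rel=1e-6)
        assert cal_g.normalize(lac_g) == pytest.approx(cal_1.normalize(lac_1), abs=1e-6)

    def test_no_beads_rejected(self):
        vol = np.full((8, 8, 8), 0.2, dtype=np.float32)
        beads = LabelVolume(labels=np.zeros_like(vol, dtype=np.int32),
                            kind="groundtruth", voxel_size=40.0)
        with pytest.raises(ValueError):
            calibrate_beads(ReconVolume(vol, 40.0), beads, 8.0)


class TestShapeTensor:
    def test_ball_is_isotropic(self):
        mask = rasterize_ellipsoid(32, (10, 10, 10))
        eig = shape_eigenvalues(mask, 1.0)
        assert eig.l1 / eig.l3 == pytest.approx(1.0, rel=0.02)

    def test_elongated_ellipsoid_eigenvalue_ratios(self):
        """Continuous ellipsoid covariance is diag(a², b², c²)/5."""
        mask = rasterize_ellipsoid(96, (40, 10, 10))
        eig = shape_eigenvalues(mask, 1.0)
        assert eig.l1 / eig.l2 == pytest.approx(16.0, rel=0.02)
        assert eig.l2 / eig.l3 == pytest.approx(1.0, rel=0.02)
        assert eig.l1 == pytest.approx(40**2 / 5.0, rel=0.02)

    def test_rotation_invariance(self):
        theta = np.deg2rad(30.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0.0],
             [np.sin(theta), np.cos(theta), 0.0],
             [0.0, 0.0, 1.0]]
        )
        e0 = shape_eigenvalues(rasterize_ellipsoid(112, (40, 12, 12)), 1.0)
        e1 = shape_eigenvalues(rasterize_ellipsoid(112, (40, 12, 12), rot), 1.0)
        for a, b in zip(e0.as_tuple(), e1.as_tuple()):
            assert a == pytest.approx(b, rel=0.02)

    def test_degenerate_mask_flagged_not_raised(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2, 2, 2:6] = True  # collinear voxels
        eig = shape_eigenvalues(mask, 1.0)
        assert eig.degenerate
        assert eig.l3 == 0.0


class TestFractionalAnisotropy:
    def test_isotropic_is_zero(self):
        assert fractional_anisotropy(1.0, 1.0, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_fully_directional_is_hundred(self):
        assert fractional_anisotropy(1.0, 0.0, 0.0) == pytest.approx(100.0, abs=1e-9)

    def test_prolate_case_closed_form(self):
        # independent evaluation of the closed form at (2, 1, 1):
        # 100·sqrt(1.5·(4/9 + 1/9 + 1/9) / 6) = 100/sqrt(6)
        assert fractional_anisotropy(2.0, 1.0, 1.0) == pytest.approx(40.82, abs=0.005)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fractional_anisotropy(0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            fractional_anisotropy(-1.0, 1.0, 1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.floats(0.0, 1e6), st.floats(0.0, 1e6), st.floats(0.0, 1e6)
        ).filter(lambda t: sum(t) > 1e-9),
        st.floats(1e-6, 1e6),
    )
    def test_scale_and_permutation_invariance(self, lam, c):
        base = fractional_anisotropy(*lam)
        assert 0.0 <= base <= 100.0
        assert fractional_anisotropy(*(c * v for v in lam)) == pytest.approx(
            base, abs=1e-7
        )
        assert fractional_anisotropy(lam[2], lam[0], lam[1]) == pytest.approx(
            base, abs=1e-10
        )

    def test_monotone_in_axis_ratio_of_rasterized_ellipsoids(self):
        ratios = [1.0, 1.5, 2.0, 3.0, 4.0, 6.0]
        fas = []
        for q in ratios:
            b = 8.0
            mask = rasterize_ellipsoid(int(2 * q * b) + 16, (q * b, b, b))
            fas.append(fractional_anisotropy(*shape_eigenvalues(mask, 1.0).as_tuple()))
        assert all(x < y for x, y in zip(fas, fas[1:]))


class TestArea2d:
    def test_pixel_count_arithmetic(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10, :10] = True  # 100 pixels at 10 nm
        assert area_2d(mask, 10.0) == pytest.approx(10000.0)

    def test_disc_area_matches_pi_r_squared(self):
        c = (32 - 1) / 2.0
        zz, yy = np.meshgrid(np.arange(32) - c, np.arange(32) - c, indexing="ij")
        mask = zz**2 + yy**2 <= 15**2
        assert area_2d(mask, 1.0) == pytest.approx(np.pi * 15**2, rel=0.05)

    def test_empty_slice_rejected(self):
        with pytest.raises(ValueError):
            area_2d(np.zeros((8, 8), dtype=bool), 10.0)


@pytest.fixture(scope="module")
def labelled_phantom():
    cfg = PhantomConfig(grid_shape=(48, 48, 48), voxel_size=40.0,
                        n_mitochondria=5, n_beads=2, seed=21)
    return make_cell_phantom(cfg)


class TestQuantifyCell:
    def test_truth_labels_reproduce_truth_table(self, labelled_phantom):
        """Identity pipeline: metrics on ground-truth LAC match the generator."""
        ph = labelled_phantom
        recon = ReconVolume(ph.lac_volume, ph.voxel_size)
        labels = LabelVolume(ph.label_volume, kind="groundtruth",
                             voxel_size=ph.voxel_size,
                             bead_ids=tuple(ph.bead_labels))
        table = quantify_cell(recon, labels, exclude_labels=(1,))
        truth = ph.truth_table.set_index("label")
        assert len(table) == len(ph.mito_labels)
        for _, row in table.iterrows():
            t = truth.loc[row["organelle_id"]]
            assert t["kind"] == "mitochondrion"
            assert row["voxel_count"] == t["voxel_count"]
            assert row["volume_nm3"] == pytest.approx(
                t["voxel_count"] * ph.voxel_size**3
            )
            assert row["lac_mean"] == pytest.approx(t["lac"], rel=1e-6)
            assert row["lac_sd"] == pytest.approx(0.0, abs=1e-6)

    def test_bead_labels_never_in_organelle_table(self, labelled_phantom):
        ph = labelled_phantom
        recon = ReconVolume(ph.lac_volume, ph.voxel_size)
        labels = LabelVolume(ph.label_volume, kind="groundtruth",
                             voxel_size=ph.voxel_size,
                             bead_ids=tuple(ph.bead_labels))
        table = quantify_cell(recon, labels, exclude_labels=(1,))
        assert not set(table["organelle_id"]) & set(ph.bead_labels)
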