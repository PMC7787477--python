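"""Multi-reference global registration: solver oracles, gauge invariants,
affine recovery, and rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, optimize

import aoreg
from aoreg import globalreg
from aoreg.globalreg import (
    AffineTransform,
    GlobalBScanCoords,
    MultiRefDisplacements,
    pairwise_cost,
)
from aoreg.volume import Volume

from conftest import zero_motion


def make_mrd(rows, n_y=16, n_volumes=3, references=(0,)):
    table = pd.DataFrame(rows, columns=["T", "R", "i", "j", "dx", "dy", "dz", "ncc"])
    return MultiRefDisplacements(
        table=table,
        n_y=n_y,
        n_volumes=n_volumes,
        references=list(references),
        registrable={},
        video_of=np.zeros(n_volumes, dtype=int),
        fraction_registered=1.0,
    )


class TestReferenceMotion:
    def test_zero_displacements_give_zero_motion(self):
        rows = [(t, 0, i, i, 0.0, 0.0, 0.0, 1.0) for t in range(3) for i in range(16)]
        mot = globalreg.reference_motion(make_mrd(rows), 0, smooth_window=0, center_targets=False)
        assert np.allclose(mot.a, 0) and np.allclose(mot.b, 0) and np.allclose(mot.c, 0)

    def test_opposite_contributions_cancel(self):
        rows = [
            (1, 0, 5, 5, 2.0, 0.0, -1.0, 1.0),
            (2, 0, 5, 5, -2.0, 0.0, 1.0, 1.0),
        ]
        mot = globalreg.reference_motion(make_mrd(rows), 0, smooth_window=0, center_targets=False)
        assert np.allclose(mot.a[5], 0.0)

    def test_matches_groupby_mean_oracle(self, rng):
        rows = []
        for t in range(1, 4):
            for i in range(16):
                j = int(np.clip(i + rng.integers(-2, 3), 0, 15))
                dx, dy, dz = rng.normal(0, 2, 3)
                rows.append((t, 0, i, j, dx, dy, dz, 0.9))
        mrd = make_mrd(rows)
        mot = globalreg.reference_motion(mrd, 0, smooth_window=0, center_targets=False)
        df = mrd.table
        oracle = df.groupby("j")[["dx", "dy", "dz"]].mean()
        for j, row in oracle.iterrows():
            assert np.allclose(mot.a[int(j)], row.to_numpy())
        assert np.allclose(mot.b.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(mot.a, mot.b + mot.c)

    def test_unmatched_rows_interpolated_and_flagged(self):
        rows = [(1, 0, i, i, float(i), 0.0, 0.0, 1.0) for i in (2, 6)]
        mot = globalreg.reference_motion(make_mrd(rows), 0, smooth_window=0, center_targets=False)
        assert mot.interpolated[3] and mot.interpolated[4]
        assert mot.a[4, 0] == pytest.approx(4.0)  # linear between 2 and 6


class TestComputeP:
    def test_zero_displacement_reduces_to_scanner_term(self):
        rows = [(1, 0, i, i, 0.0, 0.0, 0.0, 1.0) for i in range(16)]
        mrd = make_mrd(rows)
        mot = {0: globalreg.reference_motion(mrd, 0, smooth_window=0, center_targets=False)}
        p = globalreg.compute_p(mrd, mot)
        i_c = 7.5
        assert np.allclose(p["px"], 0)
        assert np.allclose(p["py"], p["i"] - i_c)
        assert np.allclose(p["pz"], 0)

    def test_elementwise_oracle(self, rng):
        rows = []
        for t in range(1, 3):
            for i in range(16):
                rows.append((t, 0, i, i, *rng.normal(0, 1, 3), 0.9))
        mrd = make_mrd(rows)
        mot = {0: globalreg.reference_motion(mrd, 0, smooth_window=0, center_targets=False)}
        p = globalreg.compute_p(mrd, mot)
        for _, row in p.iterrows():
            a = mot[0].a[int(row["j"])]
            assert row["px"] == pytest.approx(row["dx"] - a[0])
            assert row["py"] == pytest.approx(row["dy"] - a[1] + row["i"] - 7.5)
            assert row["pz"] == pytest.approx(row["dz"] - a[2])


def _ptable(rows):
    return pd.DataFrame(rows, columns=["T", "R", "i", "px", "py", "pz"])


class TestSolveOffsets:
    def test_identical_p_gives_zero_offsets(self):
        rows = []
        for r in range(3):
            for i in range(10):
                rows.append((1, r, i, float(i), 2.0, -1.0))
        eps, ncomp = globalreg.solve_reference_offsets(_ptable(rows), [0, 1, 2])
        assert ncomp == 1
        for r in range(3):
            assert np.allclose(eps[r], 0.0, atol=1e-9)

    def test_two_node_closed_form(self):
        k = 3.7
        rows = []
        for i in range(10):
            rows.append((1, 0, i, float(i), 0.0, 0.0))
            rows.append((1, 1, i, float(i) - k, 0.0, 0.0))
        eps, _ = globalreg.solve_reference_offsets(_ptable(rows), [0, 1])
        assert eps[0][0] == 0.0  # gauge
        assert eps[1][0] == pytest.approx(k)

    def test_matches_numerical_minimizer(self, rng):
        """Closed-form epsilon equals an independent numerical minimization
        of the pairwise quadratic cost on 3 references."""
        rows = []
        for r in range(3):
            for t in range(1, 4):
                for i in rng.choice(12, size=8, replace=False):
                    rows.append((t, r, int(i), *rng.normal(0, 3, 3)))
        ptab = _ptable(rows)
        eps, _ = globalreg.solve_reference_offsets(ptab, [0, 1, 2])
        for axis in range(3):
            def cost(v):
                trial = {0: np.zeros(3), 1: np.zeros(3), 2: np.zeros(3)}
                trial[1][axis], trial[2][axis] = v
                return pairwise_cost(ptab, trial, axis)

            res = optimize.minimize(cost, [0.0, 0.0], method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-12})
            assert eps[1][axis] == pytest.approx(res.x[0], abs=1e-3)
            assert eps[2][axis] == pytest.approx(res.x[1], abs=1e-3)

    def test_gauge_invariance_of_tau(self, rng):
        """Adding a constant to all p of a non-gauge reference shifts its
        epsilon by the negative constant and leaves tau unchanged."""
        rows = []
        for r in range(2):
            for t in range(1, 3):
                for i in range(12):
                    rows.append((t, r, i, *rng.normal(0, 2, 3)))
        ptab = _ptable(rows)
        eps0, _ = globalreg.solve_reference_offsets(ptab, [0, 1])
        tau0 = globalreg.global_bscan_coords(ptab, eps0, 3, 12)
        shifted = ptab.copy()
        const = np.array([5.0, -2.0, 1.0])
        mask = shifted["R"] == 1
        for c, col in zip(const, ("px", "py", "pz")):
            shifted.loc[mask, col] += c
        eps1, _ = globalreg.solve_reference_offsets(shifted, [0, 1])
        tau1 = globalreg.global_bscan_coords(shifted, eps1, 3, 12)
        assert np.allclose(eps1[1], eps0[1] - const, atol=1e-9)
        sel = tau0.defined
        assert np.allclose(tau0.tau[sel], tau1.tau[sel], atol=1e-9)

    def test_disconnected_components_flagged(self):
        rows = []
        for i in range(8):
            rows.append((1, 0, i, 1.0, 0.0, 0.0))
            rows.append((1, 1, i, 2.0, 0.0, 0.0))
            rows.append((2, 2, i, 5.0, 0.0, 0.0))  # no shared B-scans with 0/1
        eps, ncomp = globalreg.solve_reference_offsets(_ptable(rows), [0, 1, 2])
        assert ncomp == 2


class TestGlobalCoords:
    def test_motion_free_target_gets_centered_scanner_positions(self):
        rows = [(1, 0, i, i, 0.0, 0.0, 0.0, 1.0) for i in range(16)]
        mrd = make_mrd(rows, n_volumes=2)
        coords = globalreg.solve_global(mrd)
        sel = coords.defined[1]
        assert sel.all()
        expect = np.stack(
            [np.zeros(16), np.arange(16) - 7.5, np.zeros(16)], axis=1
        )
        assert np.allclose(coords.tau[1], expect, atol=1e-9)

    def test_tau_has_zero_mean(self, rng):
        rows = []
        for t in range(1, 4):
            for i in range(16):
                rows.append((t, 0, i, i, *rng.normal(0, 2, 3), 0.9))
        coords = globalreg.solve_global(make_mrd(rows, n_volumes=4))
        sel = coords.defined
        assert np.allclose(coords.tau[sel].mean(axis=0), 0.0, atol=1e-6)


class TestAffine:
    def _mosaic(self):
        ph = aoreg.build_phantom((160.0, 160.0, 90.0), 6.0, seed=2, mosaic_jitter=0.6)
        return ph.reflectance[:, 26:34, :].mean(axis=1)[20:120, 20:120]

    def test_identical_subsets_give_identity(self):
        img = self._mosaic()
        out = globalreg.estimate_affine({0: img, 1: img.copy()}, 0)
        assert out[1].converged
        assert abs(out[1].rotation_deg) < 0.05
        assert abs(out[1].scale - 1.0) < 1e-3

    def test_recovers_one_degree_rotation(self):
        img = self._mosaic()
        rot = ndimage.rotate(img, 1.0, reshape=False, order=3)
        out = globalreg.estimate_affine({0: img, 1: rot}, 0)
        assert out[1].converged
        assert abs(abs(out[1].rotation_deg) - 1.0) < 0.1

    def test_recovers_two_percent_scale(self):
        img = self._mosaic()
        c = (np.array(img.shape) - 1) / 2
        yy, xx = np.indices(img.shape)
        coords = np.stack([(yy - c[0]) / 1.02 + c[0], (xx - c[1]) / 1.02 + c[1]])
        scaled = ndimage.map_coordinates(img, coords, order=3)
        out = globalreg.estimate_affine({0: img, 1: scaled}, 0)
        assert out[1].converged
        scale = out[1].scale
        err = min(abs(scale - 1.02), abs(scale - 1 / 1.02))
        assert err < 0.005

    def test_affine_matrix_invariants(self):
        aff = AffineTransform.identity()
        assert aff.rotation_deg == 0.0 and aff.scale == 1.0
        m4 = aff.as_4x4()
        assert np.array_equal(m4, np.eye(4))
        with pytest.raises(ValueError):
            AffineTransform(matrix=np.diag([-1.0, 1.0, 1.0]))


def fake_coords(n_volumes, n_y, tau=None):
    if tau is None:
        tau = np.zeros((n_volumes, n_y, 3))
        tau[:, :, 1] = np.arange(n_y) - (n_y - 1) / 2
    return GlobalBScanCoords(
        tau=tau,
        defined=np.ones((n_volumes, n_y), dtype=bool),
        eps={0: np.zeros(3)},
        o_mean=np.zeros(3),
    )


class TestALineCoords:
    def test_identity_affine_gives_tau_plus_raster(self, still_volume):
        coords = fake_coords(1, still_volume.n_y)
        affs = {0: AffineTransform.identity()}
        out = globalreg.aline_global_coords(coords, affs, [still_volume])
        alpha = np.arange(still_volume.n_x) - (still_volume.n_x - 1) / 2
        for i in (0, 10, 20):
            assert np.allclose(out.chi[0, i, :, 0], alpha)
            assert np.allclose(out.chi[0, i, :, 1], coords.tau[0, i, 1])
            assert np.allclose(out.chi[0, i, :, 2], 0.0)

    def test_pure_translation_offsets_all_alines(self, still_volume):
        m = np.eye(3)
        m[0, 2], m[1, 2] = 4.0, -3.0
        coords = fake_coords(1, still_volume.n_y)
        base = globalreg.aline_global_coords(
            coords, {0: AffineTransform.identity()}, [still_volume]
        )
        moved = globalreg.aline_global_coords(
            coords, {0: AffineTransform(matrix=m)}, [still_volume]
        )
        sel = base.defined[0]
        assert np.allclose(moved.chi[0, sel, :, 0] - base.chi[0, sel, :, 0], 4.0)
        assert np.allclose(moved.chi[0, sel, :, 1] - base.chi[0, sel, :, 1], -3.0)
        assert np.allclose(moved.chi[0, sel, :, 2], base.chi[0, sel, :, 2])

    def test_matrix_vector_oracle(self, still_volume, rng):
        theta = np.deg2rad(1.5)
        m = np.eye(3)
        m[:2, :2] = 1.01 * np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        m[0, 2], m[1, 2] = 0.7, -0.2
        coords = fake_coords(1, still_volume.n_y, tau=rng.normal(0, 3, (1, still_volume.n_y, 3)))
        out = globalreg.aline_global_coords(
            coords, {0: AffineTransform(matrix=m)}, [still_volume]
        )
        alpha = np.arange(still_volume.n_x) - (still_volume.n_x - 1) / 2
        i, a = 7, 13
        sigma = np.array([alpha[a], 0.0, 1.0])
        expect_xy = (m @ sigma)[:2] + coords.tau[0, i, :2]
        assert np.allclose(out.chi[0, i, a, :2], expect_xy)
        assert out.chi[0, i, a, 2] == pytest.approx(coords.tau[0, i, 2])

    def test_failed_affine_marks_volume_undefined(self, still_volume):
        coords = fake_coords(1, still_volume.n_y)
        affs = {0: AffineTransform(matrix=np.eye(3), converged=False)}
        out = globalreg.aline_global_coords(coords, affs, [still_volume])
        assert not out.defined.any()


class TestRenderGlobal:
    def test_identity_render_reproduces_volume(self, still_volume):
        coords = fake_coords(1, still_volume.n_y)
        aline = globalreg.aline_global_coords(
            coords, {0: AffineTransform.identity()}, [still_volume]
        )
        rendered, count = globalreg.render_global([still_volume], aline)
        assert rendered.shape == still_volume.shape
        assert np.allclose(rendered.intensity, still_volume.intensity, atol=1e-5)
        assert np.all(count == 1)

    def test_count_map_conserves_placed_alines(self, still_volume):
        coords = fake_coords(1, still_volume.n_y)
        aline = globalreg.aline_global_coords(
            coords, {0: AffineTransform.identity()}, [still_volume]
        )
        _, count = globalreg.render_global([still_volume], aline)
        assert count.sum() == still_volume.n_y * still_volume.n_x

    def test_offset_volumes_extend_canvas_and_overlap_counts(self, still_volume):
        """Two laterally offset copies enlarge the field of view; the count
        map is 2 in the overlap and 1 in the flanks."""
        offset = 20.0
        tau = np.zeros((2, still_volume.n_y, 3))
        tau[:, :, 1] = np.arange(still_volume.n_y) - (still_volume.n_y - 1) / 2
        tau[1, :, 0] = offset
        coords = GlobalBScanCoords(
            tau=tau,
            defined=np.ones((2, still_volume.n_y), dtype=bool),
            eps={0: np.zeros(3)},
            o_mean=np.zeros(3),
        )
        aline = globalreg.aline_global_coords(
            coords, {0: AffineTransform.identity()}, [still_volume, still_volume]
        )
        rendered, count = globalreg.render_global([still_volume, still_volume], aline)
        assert rendered.intensity.shape[2] == still_volume.n_x + offset
        assert np.all(count[:, int(offset) : still_volume.n_x] == 2)
        assert np.all(count[:, : int(offset)] == 1)
        assert np.all(count[:, still_volume.n_x :] == 1)


class TestMultiReference:
    def test_identical_target_fully_registrable(self, still_volume):
        v0 = still_volume
        v1 = still_volume.with_intensity(still_volume.intensity.copy())
        v1.video, v1.index = 0, 1
        mrd = globalreg.multi_reference_register(
            [v0, v1], references=[0], sampling=aoreg.CoarseSampling(s=8, d=4),
            auto_add=False,
        )
        assert mrd.fraction_registered == 1.0
        assert mrd.registrable[(1, 0)]

    def test_disjoint_patches_need_multiple_references(self, phantom, scan):
        """Volumes of non-overlapping retinal patches only all register
        when each patch contributes a reference."""
        quiet = aoreg.simulate_motion(0.1, zero_motion(), scan.bscan_rate)
        far = 70.0  # much larger than the field of view
        a1, _ = aoreg.acquire_volume(phantom, quiet, scan, origin_um=(5, 5))
        a2, _ = aoreg.acquire_volume(phantom, quiet, scan, origin_um=(5, 5), seed=1,
                                     noise_sd=0.02, speckle_contrast=0.2)
        b1, _ = aoreg.acquire_volume(phantom, quiet, scan, origin_um=(5 + far, 5 + far))
        b2, _ = aoreg.acquire_volume(phantom, quiet, scan, origin_um=(5 + far, 5 + far),
                                     seed=2, noise_sd=0.02, speckle_contrast=0.2)
        vols = [a1, a2, b1, b2]
        for k, v in enumerate(vols):
            v.video, v.index = k // 2, k % 2
        single = globalreg.multi_reference_register(
            vols, references=[0], sampling=aoreg.CoarseSampling(s=8, d=4),
            auto_add=False,
        )
        assert single.fraction_registered <= 0.5
        multi = globalreg.multi_reference_register(
            vols, references=[0, 2], sampling=aoreg.CoarseSampling(s=8, d=4),
            auto_add=False,
        )
        assert multi.fraction_registered == 1.0

    def test_auto_add_stops_at_target_fraction(self, phantom, scan):
        quiet = aoreg.simulate_motion(0.1, zero_motion(), scan.bscan_rate)
        vols = []
        for k in range(4):
            v, _ = aoreg.acquire_volume(
                phantom, quiet, scan, origin_um=(10, 10), seed=k,
                noise_sd=0.02, speckle_contrast=0.2,
            )
            v.video, v.index = k // 2, k % 2
            vols.append(v)
        mrd = globalreg.multi_reference_register(
            vols, references=[0], sampling=aoreg.CoarseSampling(s=8, d=4),
            auto_add=True, target_frac=0.8,
        )
        assert mrd.fraction_registered >= 0.8
        assert len(mrd.references) == 1  # already satisfied, nothing added
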