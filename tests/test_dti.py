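"""Tensor fitting, FA computation, skeletonization, feature stacking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import label as cc_label
from scipy.stats import special_ortho_group

import dticlass as dc
from dticlass.dti import fa_from_eigenvalues


def _fa_invariant_oracle(tensor):
    """FA from tensor invariants, no eigen-decomposition:
    FA^2 = 3/2 * (||D||_F^2 - 3*mean^2) / ||D||_F^2."""
    frob2 = float((tensor**2).sum())
    if frob2 == 0:
        return 0.0
    mean = np.trace(tensor) / 3.0
    return float(np.sqrt(1.5 * (frob2 - 3 * mean**2) / frob2))


class TestFitTensor:
    def test_noiseless_fit_inverts_generation(self, straight_tube_phantom):
        _, dwi, truth, _ = straight_tube_phantom
        fit = dc.fit_tensor(dwi)
        assert fit.mask.all()
        assert np.abs(fit.tensors - truth.tensors).max() < 1e-8

    def test_constant_signal_gives_zero_tensor(self, gtab):
        data = np.full((3, 3, 3, gtab.n_volumes), 50.0)
        dwi = dc.DWIVolume(data=data, affine=np.eye(4), gradients=gtab)
        fit = dc.fit_tensor(dwi)
        assert np.abs(fit.tensors).max() < 1e-12

    def test_weighted_fit_also_inverts_noiseless(self, straight_tube_phantom):
        _, dwi, truth, _ = straight_tube_phantom
        fit = dc.fit_tensor(dwi, weighted=True)
        assert np.abs(fit.tensors - truth.tensors).max() < 1e-7

    def test_collinear_design_rejected(self):
        vecs = np.zeros((8, 3))
        vecs[1:, 0] = 1.0
        # bypass GradientTable's own validation to reach the fit check
        gt = dc.default_gradient_table()
        gt.bvecs = vecs
        gt.bvals = np.array([0.0] + [1000.0] * 7)
        data = np.full((2, 2, 2, 8), 10.0)
        dwi = dc.DWIVolume.__new__(dc.DWIVolume)
        dwi.data, dwi.affine, dwi.gradients = data, np.eye(4), gt
        with pytest.raises(ValueError, match="collinear|rank"):
            dc.fit_tensor(dwi)

    def test_rician_noise_error_bounded(self, gtab):
        # Monte-Carlo: with sigma = 0.02*S0 the median componentwise
        # error stays below the sigma-scaled bound (sigma/S0)/b
        errs = []
        for rep in range(30):
            spec = dc.PhantomSpec(
                shape=(6, 6, 6), voxel_size=(2, 2, 2),
                tubes=[dc.Tube(start=(0, 6, 6), direction=(1, 0, 0),
                               length=12, radius=4)],
                noise_sigma=2.0, seed=rep)
            dwi, truth, _ = dc.gen_dwi_phantom(spec, gtab)
            fit = dc.fit_tensor(dwi)
            errs.append(np.abs(fit.tensors - truth.tensors).ravel())
        bound = (2.0 / 100.0) / 1000.0  # (sigma/S0)/b in mm^2/s
        assert np.median(np.concatenate(errs)) < bound


class TestComputeFA:
    def test_isotropic_fa_zero(self):
        assert fa_from_eigenvalues(np.array([2e-3, 2e-3, 2e-3])) == 0.0

    def test_single_direction_limit_fa_one(self):
        assert fa_from_eigenvalues(np.array([1.0, 0.0, 0.0])) == pytest.approx(1.0)

    def test_zero_tensor_fa_zero(self):
        assert fa_from_eigenvalues(np.zeros(3)) == 0.0

    def test_fa_matches_invariant_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            A = rng.normal(size=(3, 3))
            spd = A @ A.T + 1e-3 * np.eye(3)
            tf = dc.TensorField(tensors=spd[None, None, None],
                                mask=np.ones((1, 1, 1), bool))
            fa = dc.compute_fa(tf).fa[0, 0, 0]
            assert fa == pytest.approx(_fa_invariant_oracle(spd), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_fa_rotation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        spd = A @ A.T + 1e-3 * np.eye(3)
        R = special_ortho_group.rvs(3, random_state=rng)
        rotated = R @ spd @ R.T
        rotated = (rotated + rotated.T) / 2
        assert _tensor_fa(spd) == pytest.approx(_tensor_fa(rotated),
                                                abs=1e-10)

    def test_principal_direction_in_tube(self, straight_tube_fa,
                                         straight_tube_phantom):
        _, _, _, labels = straight_tube_phantom
        dirs = straight_tube_fa.directions[labels > 0]
        assert np.abs(np.abs(dirs[:, 0]) - 1.0).max() < 1e-6


def _tensor_fa(t):
    tf = dc.TensorField(tensors=t[None, None, None],
                        mask=np.ones((1, 1, 1), bool))
    return float(dc.compute_fa(tf).fa[0, 0, 0])


class TestSkeleton:
    def test_tube_skeleton_is_centerline(self, straight_tube_fa):
        sk = dc.build_mean_fa_skeleton([straight_tube_fa], fa_threshold=0.2)
        # one voxel per x-slice, exactly on the tube axis (y=z=6)
        assert sk.n_voxels == 30
        assert (sk.order[:, 1] == 6).all() and (sk.order[:, 2] == 6).all()

    def test_skeleton_subset_of_suprathreshold(self, straight_tube_fa):
        sk = dc.build_mean_fa_skeleton([straight_tube_fa], fa_threshold=0.2)
        assert (straight_tube_fa.fa[sk.mask] >= 0.2).all()

    def test_threshold_above_max_errors(self, straight_tube_fa):
        with pytest.raises(ValueError, match="lower the threshold"):
            dc.build_mean_fa_skeleton([straight_tube_fa], fa_threshold=0.99)

    def test_two_tubes_two_components(self, gtab):
        spec = dc.PhantomSpec(
            shape=(30, 16, 16), voxel_size=(2, 2, 2),
            tubes=[dc.Tube(start=(0, 8, 8), direction=(1, 0, 0), length=60,
                           radius=4, anisotropy_falloff=0.6),
                   dc.Tube(start=(0, 24, 24), direction=(1, 0, 0), length=60,
                           radius=4, anisotropy_falloff=0.6)],
            seed=2)
        dwi, _, _ = dc.gen_dwi_phantom(spec, gtab)
        fa = dc.compute_fa(dc.fit_tensor(dwi))
        sk = dc.build_mean_fa_skeleton([fa])
        ncomp = cc_label(sk.mask, structure=np.ones((3, 3, 3)))[1]
        assert ncomp == 2

    def test_deterministic(self, straight_tube_fa):
        a = dc.build_mean_fa_skeleton([straight_tube_fa])
        b = dc.build_mean_fa_skeleton([straight_tube_fa])
        assert (a.mask == b.mask).all()
        assert (a.order == b.order).all()

    def test_grid_mismatch_rejected(self, straight_tube_fa, uniform_field):
        with pytest.raises(ValueError, match="grid"):
            dc.build_mean_fa_skeleton([straight_tube_fa, uniform_field])


class TestSkeletonFeatures:
    def test_vector_length_and_order(self, straight_tube_fa):
        sk = dc.build_mean_fa_skeleton([straight_tube_fa])
        vec = dc.extract_skeleton_features(straight_tube_fa, sk)
        assert vec.shape == (sk.n_voxels,)

    def test_constant_fa_gives_constant_vector(self, straight_tube_fa):
        sk = dc.build_mean_fa_skeleton([straight_tube_fa])
        flat = dc.FAVolume(fa=np.full(straight_tube_fa.shape, 0.5),
                           directions=straight_tube_fa.directions,
                           mask=straight_tube_fa.mask,
                           affine=straight_tube_fa.affine)
        vec = dc.extract_skeleton_features(flat, sk)
        assert (vec == 0.5).all()

    def test_swapping_voxels_swaps_entries(self, straight_tube_fa):
        sk = dc.build_mean_fa_skeleton([straight_tube_fa])
        # subject with distinct FA at every voxel (ramp in [0.2, 0.8])
        shape = straight_tube_fa.shape
        ramp = np.linspace(0.2, 0.8, np.prod(shape)).reshape(shape)
        a, b = tuple(sk.order[3]), tuple(sk.order[7])
        fa2 = ramp.copy()
        fa2[a], fa2[b] = fa2[b], fa2[a]
        base = dc.FAVolume(fa=ramp, directions=straight_tube_fa.directions,
                           mask=straight_tube_fa.mask,
                           affine=straight_tube_fa.affine)
        swapped = dc.FAVolume(fa=fa2, directions=straight_tube_fa.directions,
                              mask=straight_tube_fa.mask,
                              affine=straight_tube_fa.affine)
        v1 = dc.extract_skeleton_features(base, sk)
        v2 = dc.extract_skeleton_features(swapped, sk)
        diff = np.nonzero(v1 != v2)[0]
        assert set(diff.tolist()) == {3, 7}
        assert v1[3] == v2[7] and v1[7] == v2[3]

    def test_grid_mismatch_rejected(self, straight_tube_fa, uniform_field):
        sk = dc.build_mean_fa_skeleton([straight_tube_fa])
        with pytest.raises(ValueError, match="grid"):
            dc.extract_skeleton_features(uniform_field, sk)


class TestStackFeatureMatrix:
    def test_zero_column_dropped_and_logged(self):
        vecs = [np.array([1.0, 0.0, 2.0]), np.array([3.0, 0.0, 4.0])]
        table, dropped = dc.stack_feature_matrix(vecs, [1, 0])
        assert table.X.shape == (2, 2)
        assert dropped.tolist() == [1]

    def test_no_zero_columns_identity(self):
        vecs = [np.array([1.0, 2.0]), np.array([3.0, 4.0])]
        table, dropped = dc.stack_feature_matrix(vecs, [1, 0])
        assert (table.X == np.array([[1, 2], [3, 4]])).all()
        assert dropped.size == 0

    def test_row_count_preserved(self):
        rng = np.random.default_rng(0)
        vecs = [rng.normal(size=5) for _ in range(97)]
        table, _ = dc.stack_feature_matrix(
            vecs, [1] * 30 + [0] * 67)
        assert table.n_subjects == 97

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            dc.stack_feature_matrix([np.ones(3), np.ones(4)], [1, 0])
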