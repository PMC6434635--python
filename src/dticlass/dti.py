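"""Voxel-wise diffusion tensor fitting, FA maps, and mean-FA skeleton
features.

The diffusion tensor D is estimated per voxel by log-linear least squares
on the monoexponential signal model ln S = ln S0 - b g^T D g.  Fractional
anisotropy is the standard eigenvalue statistic

    FA = sqrt(3/2) * sqrt(sum (lam_i - mean)^2) / sqrt(sum lam_i^2)

which is 0 for isotropic diffusion and 1 in the single-direction limit.
The group skeleton is the ridge of the mean-FA map: supra-threshold voxels
that are strict local maxima of mean FA along the grid axis most
orthogonal to the local mean principal direction (a simplified
perpendicular non-maximum suppression).  Subjects here are generated
pre-aligned on one grid, so per-subject skeleton features are direct
lookups of the subject's FA at the skeleton voxels in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import CohortTable
from .synthetic import GradientTable

__all__ = [
    "DWIVolume",
    "TensorField",
    "FAVolume",
    "SkeletonMask",
    "fit_tensor",
    "compute_fa",
    "build_mean_fa_skeleton",
    "extract_skeleton_features",
    "stack_feature_matrix",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class DWIVolume:
    """4-D diffusion-weighted signal with its gradient table and affine."""

    data: np.ndarray  # (x, y, z, n_volumes)
    affine: np.ndarray
    gradients: GradientTable

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-D (x, y, z, volume)")
        if self.data.shape[3] != self.gradients.n_volumes:
            raise ValueError(
                f"{self.data.shape[3]} volumes but gradient table has "
                f"{self.gradients.n_volumes} entries"
            )
        if (self.data < 0).any():
            raise ValueError("DWI signals must be nonnegative")

    @property
    def shape(self):
        return self.data.shape[:3]

    def to_nifti(self, path, bval_path=None, bvec_path=None) -> None:
        nib.save(nib.Nifti1Image(self.data, self.affine), str(path))
        if bval_path is not None:
            self.gradients.to_files(bval_path, bvec_path)

    @classmethod
    def from_nifti(cls, path, bval_path, bvec_path) -> "DWIVolume":
        img = nib.load(str(path))
        gt = GradientTable.from_files(bval_path, bvec_path)
        return cls(data=np.asarray(img.dataobj, dtype=float),
                   affine=img.affine, gradients=gt)


@dataclass
class TensorField:
    """Per-voxel symmetric 3x3 diffusion tensors (mm^2/s) + validity mask."""

    tensors: np.ndarray  # (x, y, z, 3, 3)
    mask: np.ndarray  # bool, valid voxels
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must be (..., 3, 3)")
        if self.mask.shape != self.tensors.shape[:-2]:
            raise ValueError("mask shape must match the tensor grid")
        # symmetrize-or-reject: tolerate fp asymmetry only
        asym = np.abs(self.tensors - np.swapaxes(self.tensors, -1, -2))
        if asym.max() > 1e-9:
            raise ValueError("tensors must be symmetric")

    @property
    def shape(self):
        return self.tensors.shape[:-2]


@dataclass
class FAVolume:
    """Per-voxel FA scalar and unit principal eigenvector."""

    fa: np.ndarray  # (x, y, z)
    directions: np.ndarray  # (x, y, z, 3), unit where mask
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.fa = np.asarray(self.fa, dtype=float)
        valid_fa = self.fa[self.mask]
        if valid_fa.size and (valid_fa.min() < -1e-12
                              or valid_fa.max() > 1 + 1e-12):
            raise ValueError("FA must lie in [0, 1] on valid voxels")

    @property
    def shape(self):
        return self.fa.shape

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.fa, self.affine), str(path))


@dataclass
class SkeletonMask:
    """Boolean skeleton volume plus the fixed feature ordering.

    ``order`` lists the skeleton voxels by sorted C-order linear index;
    feature j of every subject is the FA value at ``order[j]``.
    """

    mask: np.ndarray
    order: np.ndarray  # (n_voxels, 3) int indices, sorted by linear index

    @property
    def n_voxels(self) -> int:
        return self.order.shape[0]

    def order_to_tsv(self, path) -> None:
        pd.DataFrame(self.order, columns=["i", "j", "k"]).to_csv(
            path, sep="\t", index=False
        )


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def _design_matrix(gt: GradientTable) -> np.ndarray:
    """Rows [1, -b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz]
    for unknowns [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
    b = gt.bvals
    gx, gy, gz = gt.bvecs.T
    return np.column_stack([
        np.ones_like(b),
        -b * gx * gx, -b * gy * gy, -b * gz * gz,
        -2 * b * gx * gy, -2 * b * gx * gz, -2 * b * gy * gz,
    ])


def fit_tensor(dwi: DWIVolume, weighted: bool = False) -> TensorField:
    """Log-linear least-squares tensor fit at every voxel.

    With ``weighted=True`` each measurement is weighted by its observed
    signal (the usual WLS correction for the log transform's
    heteroscedasticity); the default is the plain OLS fit.  Voxels whose
    mean b=0 signal is nonpositive are masked invalid.
    """
    gt = dwi.gradients
    B = _design_matrix(gt)
    if np.linalg.matrix_rank(B) < 7:
        raise ValueError(
            "rank-deficient design: gradient directions are collinear; "
            "need >= 6 non-collinear nonzero-b directions plus b=0"
        )
    shape = dwi.shape
    s = dwi.data.reshape(-1, gt.n_volumes)
    b0 = s[:, gt.bvals == 0].mean(axis=1)
    valid = b0 > 0
    logs = np.log(np.clip(s, 1e-12, None))

    if weighted:
        coef = np.empty((s.shape[0], 7))
        coef[~valid] = 0.0
        for i in np.nonzero(valid)[0]:
            w = s[i]
            coef[i] = np.linalg.lstsq(B * w[:, None], logs[i] * w,
                                      rcond=None)[0]
    else:
        coef, *_ = np.linalg.lstsq(B, logs.T, rcond=None)
        coef = coef.T
        coef[~valid] = 0.0

    dxx, dyy, dzz, dxy, dxz, dyz = coef[:, 1:7].T
    tensors = np.zeros((s.shape[0], 3, 3))
    tensors[:, 0, 0] = dxx
    tensors[:, 1, 1] = dyy
    tensors[:, 2, 2] = dzz
    tensors[:, 0, 1] = tensors[:, 1, 0] = dxy
    tensors[:, 0, 2] = tensors[:, 2, 0] = dxz
    tensors[:, 1, 2] = tensors[:, 2, 1] = dyz
    return TensorField(
        tensors=tensors.reshape(shape + (3, 3)),
        mask=valid.reshape(shape),
        affine=dwi.affine,
    )


def fa_from_eigenvalues(lam: np.ndarray) -> np.ndarray:
    """FA from eigenvalue triples (..., 3); zero tensor -> FA 0."""
    lam = np.asarray(lam, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = ((lam - mean) ** 2).sum(axis=-1)
    den = (lam**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(num / den)
    return np.where(den > 0, np.clip(np.nan_to_num(fa), 0.0, 1.0), 0.0)


def compute_fa(tf: TensorField) -> FAVolume:
    """Eigen-decompose the tensor field: FA map + principal directions."""
    flat = tf.tensors.reshape(-1, 3, 3)
    lam, vec = np.linalg.eigh(flat)  # ascending eigenvalues
    fa = fa_from_eigenvalues(lam)
    principal = vec[:, :, 2]  # eigenvector of the largest eigenvalue
    norms = np.linalg.norm(principal, axis=1, keepdims=True)
    principal = principal / np.where(norms > 0, norms, 1.0)
    shape = tf.shape
    return FAVolume(
        fa=fa.reshape(shape),
        directions=principal.reshape(shape + (3,)),
        mask=tf.mask.copy(),
        affine=tf.affine,
    )


def _mean_principal_directions(fa_volumes) -> np.ndarray:
    """Average direction field via the mean dyadic tensor (sign-free)."""
    shape = fa_volumes[0].shape
    dyad = np.zeros(shape + (3, 3))
    for fv in fa_volumes:
        d = fv.directions
        dyad += d[..., :, None] * d[..., None, :]
    dyad /= len(fa_volumes)
    _, vec = np.linalg.eigh(dyad.reshape(-1, 3, 3))
    return vec[:, :, 2].reshape(shape + (3,))


def build_mean_fa_skeleton(fa_volumes, fa_threshold: float = 0.2
                           ) -> SkeletonMask:
    """Extract the 1-voxel-thick ridge of the group mean-FA map.

    A voxel joins the skeleton when its mean FA is at least
    ``fa_threshold`` and is a strict local maximum of mean FA along the
    grid axes perpendicular to the local mean principal direction (the
    two axes other than the fiber's dominant axis — a simplified
    perpendicular non-maximum suppression that thins a tube to its
    centerline ridge).  On plateaus (exactly equal neighbors along a
    suppression axis) only the voxel with the lowest C-order linear
    index of the plateau survives, so the result is deterministic.
    """
    if not fa_volumes:
        raise ValueError("need at least one FA volume")
    shape = fa_volumes[0].shape
    affine = fa_volumes[0].affine
    for fv in fa_volumes[1:]:
        if fv.shape != shape or not np.allclose(fv.affine, affine):
            raise ValueError("all FA volumes must share grid and affine")

    mean_fa = np.mean([fv.fa for fv in fa_volumes], axis=0)
    if mean_fa.max() < fa_threshold:
        raise ValueError(
            f"no voxel reaches mean FA {fa_threshold}; the maximum is "
            f"{mean_fa.max():.3f} — lower the threshold"
        )
    directions = _mean_principal_directions(fa_volumes)

    # the fiber's dominant grid axis per voxel; the two remaining axes
    # are (most) orthogonal to the fiber and carry the suppression
    fiber_axis = np.argmax(np.abs(directions), axis=-1)

    supra = mean_fa >= fa_threshold
    skeleton = supra.copy()
    lin_index = np.arange(mean_fa.size).reshape(shape)
    for axis in range(3):
        cand = supra & (fiber_axis != axis)
        if not cand.any():
            continue
        lo = _shift(mean_fa, axis, +1)  # value at index-1 neighbor
        hi = _shift(mean_fa, axis, -1)  # value at index+1 neighbor
        strict = (mean_fa > lo) & (mean_fa > hi)
        plateau = cand & ~strict & ~(mean_fa < lo) & ~(mean_fa < hi)
        keep = cand & strict
        if plateau.any():
            keep |= _plateau_minima(mean_fa, plateau, axis, lin_index)
        # voxels subject to suppression on this axis must survive it
        skeleton &= ~cand | keep
    order = np.argwhere(skeleton)
    lin = np.ravel_multi_index(order.T, shape)
    order = order[np.argsort(lin)]
    return SkeletonMask(mask=skeleton, order=order)


def _shift(arr: np.ndarray, axis: int, offset: int) -> np.ndarray:
    """Neighbor values along ``axis``; out-of-bounds treated as -inf."""
    out = np.full_like(arr, -np.inf)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    if offset > 0:
        src[axis] = slice(None, -offset)
        dst[axis] = slice(offset, None)
    else:
        src[axis] = slice(-offset, None)
        dst[axis] = slice(None, offset)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _plateau_minima(mean_fa, plateau, axis, lin_index) -> np.ndarray:
    """Resolve equal-FA plateaus along ``axis``: keep only the voxel with
    the lowest linear index of each run whose flanking values are lower."""
    out = np.zeros_like(plateau)
    o_moved = np.moveaxis(out, axis, -1)  # view: writes propagate
    moved = np.moveaxis(mean_fa, axis, -1)
    p_moved = np.moveaxis(plateau, axis, -1)
    l_moved = np.moveaxis(lin_index, axis, -1)
    n = moved.shape[-1]
    for idx in np.argwhere(p_moved.any(axis=-1)):
        key = tuple(idx)
        v = moved[key]
        p = p_moved[key]
        lin = l_moved[key]
        i = 0
        while i < n:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if p[i:j + 1].any():
                left_ok = i == 0 or v[i - 1] < v[i]
                right_ok = j == n - 1 or v[j + 1] < v[i]
                if left_ok and right_ok:
                    k = i + int(np.argmin(lin[i:j + 1]))
                    o_moved[key + (k,)] = True
            i = j + 1
    return out


def extract_skeleton_features(fa: FAVolume, mask: SkeletonMask) -> np.ndarray:
    """Subject FA values at the skeleton voxels in the mask's fixed order."""
    if fa.shape != mask.mask.shape:
        raise ValueError(
            f"grid mismatch: FA {fa.shape} vs skeleton {mask.mask.shape}"
        )
    return fa.fa[tuple(mask.order.T)]


def stack_feature_matrix(vectors, labels, subject_ids=None,
                         feature_ids=None):
    """Stack per-subject feature vectors into a CohortTable, dropping
    columns that are zero for every subject.

    Returns
    -------
    table : CohortTable
    dropped : ndarray of int
        Original column indices removed as all-zero (the drop log).
    """
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent feature vector lengths: {lengths}")
    X = np.vstack([np.asarray(v, dtype=float) for v in vectors])
    nonzero = ~(X == 0).all(axis=0)
    dropped = np.nonzero(~nonzero)[0]
    if feature_ids is not None:
        feature_ids = [f for f, keep in zip(feature_ids, nonzero) if keep]
    else:
        feature_ids = [f"f{j:06d}" for j in np.nonzero(nonzero)[0]]
    table = CohortTable(
        X=X[:, nonzero],
        y=np.asarray(labels, dtype=int),
        subject_ids=list(subject_ids) if subject_ids else [],
        feature_ids=feature_ids,
    )
    return table, dropped
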