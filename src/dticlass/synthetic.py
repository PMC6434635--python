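"""Seeded synthetic data: DWI phantoms, parcellations, and two-group cohorts.

Every downstream stage of the pipeline (tensor fitting, skeletonization,
tractography, connectome construction, nested cross-validated
classification) is exercised on data from this module, so each generator
carries its ground truth alongside the signal: phantoms return the
generating tensor field and bundle labels, cohorts return the informative
feature/edge index sets through their specs.

Signal model: the noiseless diffusion-weighted signal at a voxel with
tensor D (mm^2/s) under gradient direction g and b-value b (s/mm^2) is

    S = S0 * exp(-b * g^T D g)

with optional Rician noise on the magnitude.  Default acquisition: 25
non-collinear directions at b = 1000 s/mm^2 plus one b = 0 volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cohort import CohortTable

__all__ = [
    "GradientTable",
    "Tube",
    "PhantomSpec",
    "CohortSpec",
    "default_gradient_table",
    "gen_dwi_phantom",
    "gen_parcellation",
    "gen_feature_cohort",
    "gen_connectome_cohort",
]


# --------------------------------------------------------------------------
# gradient table
# --------------------------------------------------------------------------

@dataclass
class GradientTable:
    """b-values (s/mm^2) and unit gradient directions, one per volume."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3); rows for b=0 volumes may be zero

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must be (n, 3) matching bvals length")
        if not (self.bvals == 0).any():
            raise ValueError("gradient table needs at least one b=0 volume")
        dwi = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dwi], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("nonzero-b gradient vectors must be unit-norm")
        if self._n_noncollinear() < 6:
            raise ValueError(
                "need at least 6 non-collinear nonzero-b directions"
            )

    def _n_noncollinear(self) -> int:
        """Count pairwise non-collinear (up to sign) nonzero-b directions."""
        vs = self.bvecs[self.bvals > 0]
        kept: list[np.ndarray] = []
        for v in vs:
            if all(abs(abs(v @ u) - 1.0) > 1e-8 for u in kept):
                kept.append(v)
        return len(kept)

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    def to_files(self, bval_path, bvec_path) -> None:
        """Write FSL-style bvals (one row) and bvecs (three rows)."""
        np.savetxt(bval_path, self.bvals[None, :], fmt="%g")
        np.savetxt(bvec_path, self.bvecs.T, fmt="%.8f")

    @classmethod
    def from_files(cls, bval_path, bvec_path) -> "GradientTable":
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3:
            bvecs = bvecs.T
        return cls(bvals=bvals, bvecs=bvecs)


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n well-spread unit vectors on a hemisphere (deterministic)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = (i + 0.5) / n  # upper hemisphere only -> pairwise non-collinear
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def default_gradient_table(n_directions: int = 25,
                           b_value: float = 1000.0) -> GradientTable:
    """One b=0 volume plus ``n_directions`` non-collinear directions."""
    vecs = _fibonacci_hemisphere(n_directions)
    bvals = np.concatenate([[0.0], np.full(n_directions, b_value)])
    bvecs = np.vstack([np.zeros(3), vecs])
    return GradientTable(bvals=bvals, bvecs=bvecs)


# --------------------------------------------------------------------------
# DWI phantom
# --------------------------------------------------------------------------

@dataclass
class Tube:
    """A tubular fiber bundle: straight segment or circular arc.

    Straight: centerline from ``start`` along unit ``direction`` for
    ``length`` mm.  Curved: arc of ``arc_radius`` mm around ``center`` in
    the plane spanned by orthonormal ``u``/``v`` axes, over
    ``angle_range`` radians.  The tensor inside the tube is prolate with
    principal axis along the local centerline tangent.
    """

    kind: str = "straight"  # "straight" | "curved"
    start: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    length: float = 10.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    u_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    v_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    arc_radius: float = 10.0
    angle_range: tuple[float, float] = (0.0, np.pi / 2)
    radius: float = 2.0  # tube radius, mm
    axial_diffusivity: float = 1.7e-3  # mm^2/s
    radial_diffusivity: float = 0.3e-3
    # fraction of the axial-radial gap lost at the tube wall; > 0 makes
    # FA peak at the centerline and decay quadratically outward
    anisotropy_falloff: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "curved"):
            raise ValueError(f"unknown tube kind {self.kind!r}")
        if self.axial_diffusivity < 0 or self.radial_diffusivity < 0:
            raise ValueError(
                "tube diffusivities must be nonnegative (negative "
                "eigenvalues would make the tensor non-physical)"
            )
        if self.axial_diffusivity < self.radial_diffusivity:
            raise ValueError("axial diffusivity must be >= radial")
        if not 0.0 <= self.anisotropy_falloff <= 1.0:
            raise ValueError("anisotropy_falloff must be in [0, 1]")

    def distance_and_tangent(self, pts: np.ndarray):
        """Distance from points (n,3) mm to the centerline, and tangents."""
        if self.kind == "straight":
            d = np.asarray(self.direction, float)
            d = d / np.linalg.norm(d)
            rel = pts - np.asarray(self.start, float)
            t = np.clip(rel @ d, 0.0, self.length)
            closest = np.asarray(self.start, float) + t[:, None] * d
            dist = np.linalg.norm(pts - closest, axis=1)
            tang = np.broadcast_to(d, pts.shape)
            return dist, tang
        # curved: project onto the arc plane, clamp the angle to the range
        c = np.asarray(self.center, float)
        u = np.asarray(self.u_axis, float)
        u = u / np.linalg.norm(u)
        v = np.asarray(self.v_axis, float)
        v = v - (v @ u) * u
        v = v / np.linalg.norm(v)
        w = np.cross(u, v)
        rel = pts - c
        a = np.arctan2(rel @ v, rel @ u)
        lo, hi = self.angle_range
        a = np.clip(a, lo, hi)
        on_arc = (c + self.arc_radius
                  * (np.cos(a)[:, None] * u + np.sin(a)[:, None] * v))
        dist = np.linalg.norm(pts - on_arc, axis=1)
        tang = -np.sin(a)[:, None] * u + np.cos(a)[:, None] * v
        # keep out-of-plane distance too (already in euclidean dist)
        del w
        return dist, tang


@dataclass
class PhantomSpec:
    """Geometry, diffusivities and noise for a synthetic DWI volume."""

    shape: tuple[int, int, int] = (24, 16, 16)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)  # mm
    tubes: list[Tube] = field(default_factory=list)
    background_diffusivity: float = 0.8e-3  # isotropic, mm^2/s
    s0: float = 100.0
    noise_sigma: float = 0.0  # Rician sigma in signal units; 0 = noiseless
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_diffusivity < 0:
            raise ValueError("background diffusivity must be nonnegative")
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape must be positive")
        lo = np.zeros(3)
        hi = np.asarray(self.shape, float) * np.asarray(self.voxel_size)
        for tube in self.tubes:
            for p in _tube_extreme_points(tube):
                if ((p < lo - 1e-9).any() or (p > hi + 1e-9).any()):
                    raise ValueError(
                        f"tube centerline leaves the grid at {p}"
                    )

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff


def _tube_extreme_points(tube: Tube) -> list[np.ndarray]:
    if tube.kind == "straight":
        d = np.asarray(tube.direction, float)
        d = d / np.linalg.norm(d)
        s = np.asarray(tube.start, float)
        return [s, s + tube.length * d]
    c = np.asarray(tube.center, float)
    u = np.asarray(tube.u_axis, float)
    v = np.asarray(tube.v_axis, float)
    angles = np.linspace(*tube.angle_range, 16)
    return [c + tube.arc_radius * (np.cos(a) * u + np.sin(a) * v)
            for a in angles]


def _voxel_centers_mm(shape, affine) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def gen_dwi_phantom(spec: PhantomSpec, gt: GradientTable):
    """Simulate a DWI volume from tube phantoms.

    Returns
    -------
    dwi : DWIVolume
        4-D signal array with the gradient table and affine attached.
    tensors : TensorField
        The ground-truth generating tensor at every voxel.
    labels : ndarray of int, shape ``spec.shape``
        0 = background, i = inside tube i (first tube wins on overlap).
    """
    from .dti import DWIVolume, TensorField  # local import: avoid cycle

    shape = tuple(spec.shape)
    affine = spec.affine
    pts = _voxel_centers_mm(shape, affine)
    n_vox = pts.shape[0]

    # background: isotropic tensors
    tensors = np.zeros((n_vox, 3, 3))
    tensors[:, 0, 0] = tensors[:, 1, 1] = tensors[:, 2, 2] = (
        spec.background_diffusivity
    )
    labels = np.zeros(n_vox, dtype=int)
    for i, tube in enumerate(spec.tubes, start=1):
        dist, tang = tube.distance_and_tangent(pts)
        inside = (dist <= tube.radius) & (labels == 0)
        if not inside.any():
            continue
        t = tang[inside]
        t = t / np.linalg.norm(t, axis=1, keepdims=True)
        lam_r = tube.radial_diffusivity
        gap = tube.axial_diffusivity - lam_r
        if tube.anisotropy_falloff > 0:
            frac = (dist[inside] / tube.radius) ** 2
            gap = gap * (1.0 - tube.anisotropy_falloff * frac)
        else:
            gap = np.full(inside.sum(), gap)
        outer = t[:, :, None] * t[:, None, :]
        eye = np.eye(3)
        tensors[inside] = lam_r * eye + gap[:, None, None] * outer
        labels[inside] = i

    # S = S0 exp(-b g^T D g), vectorized over voxels and volumes
    g = gt.bvecs  # (m, 3)
    quad = np.einsum("mi,vij,mj->vm", g, tensors, g)
    signals = spec.s0 * np.exp(-gt.bvals[None, :] * quad)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        n1 = rng.normal(0.0, spec.noise_sigma, signals.shape)
        n2 = rng.normal(0.0, spec.noise_sigma, signals.shape)
        signals = np.sqrt((signals + n1) ** 2 + n2**2)

    data = signals.reshape(shape + (gt.n_volumes,))
    dwi = DWIVolume(data=data, affine=affine, gradients=gt)
    tf = TensorField(
        tensors=tensors.reshape(shape + (3, 3)),
        mask=np.ones(shape, dtype=bool),
        affine=affine,
    )
    return dwi, tf, labels.reshape(shape)


# --------------------------------------------------------------------------
# parcellation
# --------------------------------------------------------------------------

def gen_parcellation(shape, n_regions: int = 116, seed: int = 0,
                     mask: np.ndarray | None = None):
    """Seeded Voronoi tessellation of the grid into ``n_regions`` labels.

    Any space-filling labeling satisfies the parcellation contract; a
    Voronoi tessellation of randomly placed seed voxels gives compact,
    roughly equal-sized regions reminiscent of an anatomical atlas.
    Labels are 1..n_regions; voxels outside ``mask`` (if given) are 0.
    """
    from .connectome import ParcellationVolume

    shape = tuple(shape)
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    in_idx = np.argwhere(mask)
    if n_regions > in_idx.shape[0]:
        raise ValueError(
            f"n_regions={n_regions} exceeds the {in_idx.shape[0]} "
            "in-mask voxels"
        )
    rng = np.random.default_rng(seed)
    centers = in_idx[rng.choice(in_idx.shape[0], n_regions, replace=False)]
    tree = cKDTree(centers.astype(float))
    _, nearest = tree.query(in_idx.astype(float))
    labels = np.zeros(shape, dtype=int)
    labels[tuple(in_idx.T)] = nearest + 1
    return ParcellationVolume(labels=labels, affine=np.eye(4),
                              n_regions=n_regions)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Two-group cohort with a sparse set of shifted features.

    ``effect`` is the standardized mean difference applied to patients on
    the ``informative`` features (or designated connectome edges).
    Defaults mirror the study's largest patient group against controls
    (30 patients vs 67 controls).
    """

    n_patients: int = 30
    n_controls: int = 67
    n_features: int = 200
    informative: tuple[int, ...] = tuple(range(20))
    effect: float = 0.0
    baseline_mean: float = 0.5
    baseline_sd: float = 0.1
    seed: int = 0
    # connectome-cohort parameters
    n_regions: int = 116
    edge_mean: float = 20.0
    nb_dispersion: float = 8.0  # negative-binomial size parameter

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        bad = [i for i in self.informative
               if not 0 <= i < self.n_features]
        if bad:
            raise ValueError(
                f"informative indices {bad} outside [0, {self.n_features})"
            )
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls


def gen_feature_cohort(spec: CohortSpec) -> CohortTable:
    """Gaussian feature cohort: patients shifted by effect*sd on the
    informative features, controls at baseline.  Patients occupy the
    first ``n_patients`` rows (label 1)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    X = rng.normal(spec.baseline_mean, spec.baseline_sd,
                   size=(n, spec.n_features))
    y = np.concatenate([np.ones(spec.n_patients, int),
                        np.zeros(spec.n_controls, int)])
    if spec.effect != 0.0 and spec.informative:
        shift = spec.effect * spec.baseline_sd
        X[:spec.n_patients, list(spec.informative)] -= shift
    ids = ([f"patient-{i:03d}" for i in range(spec.n_patients)]
           + [f"control-{i:03d}" for i in range(spec.n_controls)])
    return CohortTable(X=X, y=y, subject_ids=ids)


def gen_connectome_cohort(spec: CohortSpec,
                          informative_edges=None):
    """Streamline-count connectome cohort.

    Counts are negative-binomial (over-dispersed, as streamline counts
    are); patients have their means reduced by ``effect`` standard
    deviations on the designated edges, clipped at zero.  Edges are
    indexed into the upper-triangular feature vector (row-major v<u).

    Returns
    -------
    matrices : list of ConnectivityMatrix
        One per subject, patients first.
    y : ndarray of int
    informative_edges : ndarray of int
        Upper-triangular indices of the affected edges.
    """
    from .connectome import ConnectivityMatrix

    rng = np.random.default_rng(spec.seed)
    r = spec.n_regions
    n_edges = r * (r - 1) // 2
    if informative_edges is None:
        informative_edges = np.asarray(spec.informative, dtype=int)
    else:
        informative_edges = np.asarray(informative_edges, dtype=int)
    if informative_edges.size and informative_edges.max() >= n_edges:
        raise ValueError("informative edge index out of range")

    mu0 = np.full(n_edges, float(spec.edge_mean))
    theta = spec.nb_dispersion
    sd0 = np.sqrt(mu0 + mu0**2 / theta)
    mu_pat = mu0.copy()
    if spec.effect != 0.0 and informative_edges.size:
        shifted = mu0[informative_edges] - spec.effect * sd0[informative_edges]
        if (shifted < 0).any():
            warnings.warn(
                "effect size drives some edge means negative; clipping at 0",
                stacklevel=2,
            )
            shifted = np.clip(shifted, 0.0, None)
        mu_pat[informative_edges] = shifted

    iu = np.triu_indices(r, k=1)
    matrices = []
    y = np.concatenate([np.ones(spec.n_patients, int),
                        np.zeros(spec.n_controls, int)])
    for label in y:
        mu = mu_pat if label == 1 else mu0
        # NB(mean mu, size theta): p = theta / (theta + mu)
        with np.errstate(divide="ignore"):
            p = theta / (theta + mu)
        counts = np.where(
            mu > 0, rng.negative_binomial(theta, np.clip(p, 1e-12, 1.0)), 0
        )
        m = np.zeros((r, r), dtype=int)
        m[iu] = counts
        m = m + m.T
        matrices.append(ConnectivityMatrix(counts=m, n_regions=r))
    return matrices, y, informative_edges
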