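"""Structural connectome construction from streamlines and a parcellation.

Nodes are parcellation regions (ROIs); the edge e = (v, u) between two
regions carries weight w(e) = the number of streamlines whose two
endpoints fall in ROI(v) and ROI(u).  The result is a symmetric R x R
count matrix with zero diagonal; its upper triangle (row-major over
v < u, R(R-1)/2 entries — 6670 for the 116-region AAL parcellation) is
the per-subject feature vector for classification.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ParcellationVolume",
    "ConnectivityMatrix",
    "assign_streamlines",
    "build_connectivity_matrix",
    "upper_triangular_features",
    "matrix_from_features",
]


@dataclass
class ParcellationVolume:
    """Integer label volume: 0 = background, 1..R = regions."""

    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    n_regions: int = 0
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("parcellation labels must be integers")
        if self.n_regions == 0:
            self.n_regions = int(self.labels.max())
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() > self.n_regions:
            raise ValueError("labels must lie in {0..n_regions}")
        expected = np.arange(1, self.n_regions + 1)
        if not np.isin(expected, present).all():
            missing = expected[~np.isin(expected, present)]
            raise ValueError(f"empty region labels: {missing.tolist()}")
        if not self.region_names:
            self.region_names = [f"region_{i:03d}"
                                 for i in range(1, self.n_regions + 1)]

    def label_at_mm(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest-voxel label lookup for world-coordinate points."""
        inv = np.linalg.inv(self.affine)
        pv = points_mm @ inv[:3, :3].T + inv[:3, 3]
        vox = np.round(pv).astype(int)
        shape = np.asarray(self.labels.shape)
        inside = ((vox >= 0) & (vox < shape)).all(axis=1)
        out = np.zeros(points_mm.shape[0], dtype=int)
        v = vox[inside]
        out[inside] = self.labels[v[:, 0], v[:, 1], v[:, 2]]
        return out

    def to_nifti(self, path, names_tsv=None) -> None:
        nib.save(nib.Nifti1Image(self.labels.astype(np.int32), self.affine),
                 str(path))
        if names_tsv is not None:
            pd.DataFrame({
                "label": np.arange(1, self.n_regions + 1),
                "name": self.region_names,
            }).to_csv(names_tsv, sep="\t", index=False)


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative integer streamline-count matrix."""

    counts: np.ndarray
    n_regions: int = 0
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("entries must be integer counts")
            self.counts = np.round(self.counts).astype(int)
        if (self.counts < 0).any():
            raise ValueError("streamline counts must be nonnegative")
        if not (self.counts == self.counts.T).all():
            raise ValueError("connectivity matrix must be symmetric")
        if np.diagonal(self.counts).any():
            raise ValueError("diagonal must be zero (self-edges removed)")
        if self.n_regions == 0:
            self.n_regions = self.counts.shape[0]
        elif self.n_regions != self.counts.shape[0]:
            raise ValueError("n_regions does not match matrix size")
        if not self.region_names:
            self.region_names = [f"region_{i:03d}"
                                 for i in range(1, self.n_regions + 1)]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.counts, index=self.region_names,
                     columns=self.region_names).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df.to_numpy(), region_names=[str(c) for c in df.columns])


def assign_streamlines(streamlines, parc: ParcellationVolume):
    """Map streamlines to region-pair edges by their endpoints.

    A streamline contributes one count to the undirected edge {v, u} when
    its first and last points fall in two distinct nonzero labels; an
    endpoint in background or both endpoints in one region contribute
    nothing.

    Returns
    -------
    edges : collections.Counter
        Multiset of frozenset-free sorted tuples (v, u) with v < u,
        1-based region labels.
    n_unassigned : int
        Streamlines that produced no edge.
    """
    if not streamlines:
        return Counter(), 0
    endpoints = np.array([[s.points[0], s.points[-1]] for s in streamlines])
    lab_a = parc.label_at_mm(endpoints[:, 0])
    lab_b = parc.label_at_mm(endpoints[:, 1])
    good = (lab_a > 0) & (lab_b > 0) & (lab_a != lab_b)
    lo = np.minimum(lab_a[good], lab_b[good])
    hi = np.maximum(lab_a[good], lab_b[good])
    edges = Counter(zip(lo.tolist(), hi.tolist()))
    return edges, int((~good).sum())


def build_connectivity_matrix(edges, n_regions: int,
                              region_names=None) -> ConnectivityMatrix:
    """Tally an edge multiset into a symmetric count matrix.

    ``edges`` is any iterable of (v, u) 1-based label pairs, or a
    Counter/dict mapping pairs to multiplicities.
    """
    m = np.zeros((n_regions, n_regions), dtype=int)
    items = edges.items() if hasattr(edges, "items") else (
        (e, 1) for e in edges
    )
    for (v, u), k in items:
        if not (1 <= v <= n_regions and 1 <= u <= n_regions):
            raise ValueError(
                f"edge ({v}, {u}) outside the 1..{n_regions} label range"
            )
        if v == u:
            raise ValueError(f"self-edge ({v}, {u}) is not allowed")
        m[v - 1, u - 1] += k
        m[u - 1, v - 1] += k
    return ConnectivityMatrix(counts=m, n_regions=n_regions,
                              region_names=list(region_names or []))


def upper_triangular_features(matrix: ConnectivityMatrix) -> np.ndarray:
    """Vectorize the strict upper triangle, row-major over v < u.

    For R regions the vector has R(R-1)/2 entries (6670 when R = 116);
    entry order is (1,2), (1,3), ..., (1,R), (2,3), ... so each feature
    index maps back to a named region pair.
    """
    c = matrix.counts
    if not (c == c.T).all():
        raise ValueError("matrix must be symmetric")
    iu = np.triu_indices(matrix.n_regions, k=1)
    return c[iu]


def matrix_from_features(vec: np.ndarray, n_regions: int) -> ConnectivityMatrix:
    """Inverse of :func:`upper_triangular_features`."""
    vec = np.asarray(vec)
    expected = n_regions * (n_regions - 1) // 2
    if vec.size != expected:
        raise ValueError(f"expected {expected} features for R={n_regions}")
    m = np.zeros((n_regions, n_regions), dtype=vec.dtype)
    iu = np.triu_indices(n_regions, k=1)
    m[iu] = vec
    m = m + m.T
    return ConnectivityMatrix(counts=m, n_regions=n_regions)


def edge_feature_names(region_names) -> list[str]:
    """Feature names for the upper-triangular vector, '<v>--<u>'."""
    r = len(region_names)
    return [f"{region_names[v]}--{region_names[u]}"
            for v in range(r) for u in range(v + 1, r)]
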