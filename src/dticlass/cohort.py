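"""Subjects-by-features table with binary group labels.

The common currency of both feature streams (FA-skeleton vectors and
connectome edge-weight vectors): a dense matrix of subjects x features,
a binary label per subject (patient = 1, control = 0), and stable subject
and feature identifiers.  Serialized as TSV with ``subject_id`` and
``group`` as the first two columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortTable"]


@dataclass
class CohortTable:
    """Matrix of subjects x features plus binary group labels.

    Parameters
    ----------
    X : ndarray, shape (n_subjects, n_features)
        Feature matrix, one row per subject.
    y : ndarray of int, shape (n_subjects,)
        Binary labels: patient = 1, control = 0.
    subject_ids : list of str
        One identifier per row; generated as ``sub-0001`` ... if omitted.
    feature_ids : list of str
        One identifier per column; generated as ``f000000`` ... if omitted.
    """

    X: np.ndarray
    y: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x features)")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must equal the number of rows of X")
        if not np.isin(self.y, [0, 1]).all():
            raise ValueError("labels must be binary: patient=1, control=0")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:04d}" for i in range(self.X.shape[0])]
        if not self.feature_ids:
            self.feature_ids = [f"f{j:06d}" for j in range(self.X.shape[1])]
        if len(self.subject_ids) != self.X.shape[0]:
            raise ValueError("subject_ids length mismatch")
        if len(self.feature_ids) != self.X.shape[1]:
            raise ValueError("feature_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_ids)
        df.insert(0, "group", self.y)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CohortTable":
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "subject_id" or df.columns[1] != "group":
            raise ValueError(
                "cohort TSV must start with columns 'subject_id', 'group'"
            )
        return cls(
            X=df.iloc[:, 2:].to_numpy(dtype=float),
            y=df["group"].to_numpy(dtype=int),
            subject_ids=[str(s) for s in df["subject_id"]],
            feature_ids=[str(c) for c in df.columns[2:]],
        )
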