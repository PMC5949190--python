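"""Labeled ROI feature tables.

A :class:`FeatureDataset` is the package's in-memory container for a
two-class classification problem: an ``l x N`` numeric feature matrix and
a +/-1 label vector, where +1 marks the positive class (pulmonary nodule)
and -1 the negative class (non-nodule false positive).

On disk the table is a plain CSV with a header row, one feature column
per dimension and a final ``label`` column containing -1 or +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureDataset"]


@dataclass
class FeatureDataset:
    """Feature matrix X (l x N), labels y in {-1, +1}, optional row ids."""

    X: np.ndarray
    y: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y).astype(int).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} labels"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if not np.all(np.isin(self.y, (-1, 1))):
            bad = sorted(set(self.y) - {-1, 1})
            raise ValueError(f"labels must be -1 or +1, found {bad}")
        if self.ids is not None:
            self.ids = np.asarray(self.ids)
            if self.ids.shape[0] != self.y.shape[0]:
                raise ValueError("ids length does not match number of rows")

    def __len__(self) -> int:
        return self.y.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.y == -1))

    def has_both_classes(self) -> bool:
        return self.n_positive > 0 and self.n_negative > 0

    def subset(self, indices) -> "FeatureDataset":
        indices = np.asarray(indices)
        ids = self.ids[indices] if self.ids is not None else None
        return FeatureDataset(self.X[indices], self.y[indices], ids)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"f{j}" for j in range(self.n_features)]
        df = pd.DataFrame(self.X, columns=cols)
        df["label"] = self.y
        if self.ids is not None:
            df.insert(0, "id", self.ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureDataset":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError(f"{path}: feature table needs a 'label' column")
        y = df["label"].to_numpy()
        ids = df["id"].to_numpy() if "id" in df.columns else None
        feat_cols = [c for c in df.columns if c not in ("label", "id")]
        if not feat_cols:
            raise ValueError(f"{path}: no feature columns found")
        return cls(df[feat_cols].to_numpy(dtype=float), y, ids)
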