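"""The tabular dataset container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TabularDataset"]


@dataclass
class TabularDataset:
    """A numeric sample-by-feature matrix with categorical class labels.

    Attributes
    ----------
    X : ndarray of shape (n_samples, n_features)
        Feature values.
    y : ndarray of shape (n_samples,)
        Integer class codes (0..n_classes-1).
    feature_names : list of str
        One name per column of ``X``.
    label_name : str
        Name of the label column (for round-tripping to CSV).
    class_names : list
        Original label values, indexed by class code.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list = field(default_factory=list)
    label_name: str = "label"
    class_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if len(self.y) != self.X.shape[0]:
            raise ValueError(
                f"label length {len(self.y)} != sample count {self.X.shape[0]}"
            )
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match feature count")
        if not self.class_names:
            self.class_names = sorted(set(np.unique(self.y).tolist()))

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.y))

    def class_counts(self) -> dict:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def select_features(self, indices) -> "TabularDataset":
        """A new dataset restricted to the given feature columns (in order)."""
        indices = list(indices)
        return TabularDataset(
            X=self.X[:, indices],
            y=self.y.copy(),
            feature_names=[self.feature_names[i] for i in indices],
            label_name=self.label_name,
            class_names=list(self.class_names),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, TabularDataset):
            return NotImplemented
        return (
            np.array_equal(self.X, other.X)
            and np.array_equal(self.y, other.y)
            and self.feature_names == other.feature_names
            and self.label_name == other.label_name
        )
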