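"""Preprocessing: sparse-feature removal and random oversampling.

Gene-expression matrices routinely carry features that are zero in most
samples; these contribute noise to association estimates and are dropped
before ranking. Cohorts are often imbalanced (e.g. 371 tumor vs 160 normal
samples); random oversampling duplicates minority-class rows with
replacement until every class matches the majority count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .data import TabularDataset

__all__ = [
    "PreprocessConfig",
    "SparseFeatureFilter",
    "RandomOverSampler",
    "filter_sparse_features",
    "random_oversample",
]


@dataclass(frozen=True)
class PreprocessConfig:
    max_zero_fraction: float = 0.5
    oversample: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_zero_fraction <= 1.0:
            raise ValueError("max_zero_fraction must be in [0, 1]")


class SparseFeatureFilter(SelectorMixin, BaseEstimator):
    """Drop features whose fraction of exact zeros exceeds a threshold.

    A feature is kept iff ``(# zeros) / n_samples <= max_zero_fraction``.

    Attributes
    ----------
    zero_fraction_ : ndarray of shape (n_features,)
        Observed zero fraction per feature.
    support_ : boolean ndarray of shape (n_features,)
        True for kept features.
    """

    def __init__(self, max_zero_fraction: float = 0.5):
        self.max_zero_fraction = max_zero_fraction

    def fit(self, X, y=None):
        if not 0.0 <= self.max_zero_fraction <= 1.0:
            raise ValueError("max_zero_fraction must be in [0, 1]")
        X = validate_data(self, X)
        self.zero_fraction_ = (X == 0).mean(axis=0)
        self.support_ = self.zero_fraction_ <= self.max_zero_fraction
        if not self.support_.any():
            raise ValueError(
                "every feature exceeds the zero-fraction threshold "
                f"{self.max_zero_fraction}; raise max_zero_fraction"
            )
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_


class RandomOverSampler(BaseEstimator):
    """Balance class counts by duplicating minority rows with replacement.

    Every original row is retained; each appended row is an exact copy of an
    original row of a not-yet-majority class, drawn with replacement from a
    seeded generator. After resampling every class count equals the majority
    count.
    """

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("oversampling requires at least 2 classes")
        rng = np.random.default_rng(self.random_state)
        target = counts.max()
        picks_all = []
        for cls, cnt in zip(classes, counts):
            if cnt == target:
                continue
            pool = np.flatnonzero(y == cls)
            picks_all.append(rng.choice(pool, size=target - cnt, replace=True))
        # originals first, then the duplicated minority rows
        self.sample_indices_ = np.concatenate([np.arange(len(y))] + picks_all)
        return X[self.sample_indices_], y[self.sample_indices_]


def filter_sparse_features(dataset: TabularDataset, config: PreprocessConfig | None = None):
    """Remove zero-heavy features from a dataset.

    Returns the filtered dataset and the list of removed feature names (for
    the audit log). Zero fractions are computed on the rows as given, so the
    result is unaffected by any later oversampling.
    """
    config = config or PreprocessConfig()
    zero_frac = (dataset.X == 0).mean(axis=0)
    keep = zero_frac <= config.max_zero_fraction
    if not keep.any():
        raise ValueError(
            "every feature exceeds the zero-fraction threshold "
            f"{config.max_zero_fraction}; raise max_zero_fraction"
        )
    removed = [n for n, k in zip(dataset.feature_names, keep) if not k]
    return dataset.select_features(np.flatnonzero(keep)), removed


def random_oversample(dataset: TabularDataset, seed: int = 0) -> TabularDataset:
    """Oversample minority classes until all class counts are equal.

    Already-balanced datasets are returned row-identical (a copy).
    """
    sampler = RandomOverSampler(random_state=seed)
    X, y = sampler.fit_resample(dataset.X, dataset.y)
    return TabularDataset(
        X=X,
        y=y,
        feature_names=list(dataset.feature_names),
        label_name=dataset.label_name,
        class_names=list(dataset.class_names),
    )
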