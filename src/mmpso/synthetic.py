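"""Seeded generators for datasets with known ground truth.

These generators stand in for real benchmark and expression data in tests:
planted class-informative features among redundant and pure-noise features,
configurable class imbalance mimicking tumor/normal cohorts, and functional
(x, y) pairs for exercising the dependence measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import TabularDataset

__all__ = ["PlantSpec", "make_planted_dataset", "make_functional_pair", "make_imbalanced"]


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for a planted-signal classification dataset.

    ``class_sep`` is the between-class mean shift of informative features in
    units of their (unit) noise SD; ``imbalance_ratio`` is the minority /
    majority class-size ratio (1 = balanced).
    """

    n_samples: int = 200
    n_informative: int = 3
    n_redundant: int = 0
    n_noise: int = 27
    class_sep: float = 3.0
    imbalance_ratio: float = 1.0
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_classes) < 1:
            raise ValueError("n_samples and n_classes must be >= 1")
        if min(self.n_informative, self.n_redundant, self.n_noise) < 0:
            raise ValueError("feature counts must be >= 0")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant features require at least one informative feature")
        if not 0 < self.imbalance_ratio <= 1:
            raise ValueError("imbalance_ratio must be in (0, 1]")


def _class_sizes(n: int, k: int, ratio: float) -> np.ndarray:
    """Class sizes: one majority class, k-1 minority classes at the ratio."""
    if k == 1:
        return np.array([n])
    # majority size m solves m + (k-1)*round(ratio*m) ~= n
    m = int(round(n / (1 + (k - 1) * ratio)))
    sizes = np.full(k, int(round(ratio * m)))
    sizes[0] = n - sizes[1:].sum()
    if (sizes < 1).any():
        raise ValueError("imbalance_ratio yields an empty class")
    return sizes


def make_planted_dataset(spec: PlantSpec):
    """Generate a dataset with known informative/redundant/noise features.

    Informative features are class-conditional unit-variance Gaussians whose
    class means are spaced ``class_sep`` apart. Redundant features are noisy
    strictly monotone transforms (cubic link, SD-0.1 noise) of randomly
    chosen informative features. Noise features are independent standard
    Gaussians. Feature columns are laid out informative, redundant, noise.

    Returns
    -------
    dataset : TabularDataset
    truth : dict with keys ``informative``, ``redundant``, ``noise``
        Disjoint index lists partitioning the feature axis.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _class_sizes(spec.n_samples, spec.n_classes, spec.imbalance_ratio)
    y = np.repeat(np.arange(spec.n_classes), sizes)

    p = spec.n_informative + spec.n_redundant + spec.n_noise
    X = np.empty((spec.n_samples, p))
    for f in range(spec.n_informative):
        means = spec.class_sep * np.arange(spec.n_classes)
        X[:, f] = means[y] + rng.standard_normal(spec.n_samples)
    sources = rng.integers(0, spec.n_informative, size=spec.n_redundant)
    for r, src in enumerate(sources):
        base = X[:, src]
        X[:, spec.n_informative + r] = (
            base + 0.05 * base**3 + 0.1 * rng.standard_normal(spec.n_samples)
        )
    lo = spec.n_informative + spec.n_redundant
    X[:, lo:] = rng.standard_normal((spec.n_samples, spec.n_noise))

    names = (
        [f"inf{i}" for i in range(spec.n_informative)]
        + [f"red{i}" for i in range(spec.n_redundant)]
        + [f"noise{i}" for i in range(spec.n_noise)]
    )
    truth = {
        "informative": list(range(spec.n_informative)),
        "redundant": list(range(spec.n_informative, lo)),
        "noise": list(range(lo, p)),
    }
    dataset = TabularDataset(X=X, y=y, feature_names=names)
    return dataset, truth


_KINDS = ("linear", "quadratic", "sine", "checkerboard", "independent")


def make_functional_pair(kind: str, n: int, noise_sd: float = 0.0, seed: int = 0):
    """A seeded (x, y) pair with a known functional (or null) relationship.

    ``y = f(x) + N(0, noise_sd)`` for functional kinds with x uniform on
    [0, 1]; ``independent`` draws both coordinates independently;
    ``checkerboard`` samples from alternating cells of a 4x4 grid.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown kind {kind!r}; choose from {_KINDS}")
    if n < 8:
        raise ValueError("n must be >= 8")
    rng = np.random.default_rng(seed)
    x = rng.random(n)
    if kind == "linear":
        y = 2.0 * x - 0.5
    elif kind == "quadratic":
        y = 4.0 * (x - 0.5) ** 2
    elif kind == "sine":
        y = np.sin(2.0 * np.pi * x)
    elif kind == "checkerboard":
        cx = rng.integers(0, 4, size=n)
        cy = (cx + 2 * rng.integers(0, 2, size=n)) % 4
        x = (cx + rng.random(n)) / 4.0
        y = (cy + rng.random(n)) / 4.0
        return x, y
    else:  # independent
        y = rng.random(n)
        return x, y
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(n)
    return x, y


def make_imbalanced(spec: PlantSpec) -> TabularDataset:
    """Planted dataset with exact imbalanced class counts (truth discarded)."""
    dataset, _ = make_planted_dataset(spec)
    return dataset
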