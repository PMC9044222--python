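"""Particle-swarm wrapper search over feature subsets.

Particles move in the continuous unit hypercube [0, 1]^d, one dimension per
candidate feature; a position decodes to the subset of dimensions strictly
above ``decode_threshold``. The cost of a subset combines a k-nearest-
neighbor cross-validated error estimate with a subset-size penalty:

    cost = alpha * V_error + beta * N_selected / N_all,   alpha + beta = 1.

Velocities follow the classic inertia-weight update
``v' = omega*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)`` with per-dimension
uniform r1, r2, elementwise velocity clamping to [-v_max, v_max] and position
clamping to [0, 1]. One stratified fold assignment is fixed per run so the
fitness is a deterministic function of position; the whole search is
reproducible from (seed, config, data).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_is_fitted, validate_data

from .data import TabularDataset

__all__ = [
    "SwarmConfig",
    "FitnessConfig",
    "Particle",
    "SwarmState",
    "SelectionResult",
    "PSOSubsetSelector",
    "decode_subset",
    "knn_error",
    "fitness_cost",
    "update_velocity",
    "update_position",
    "run_pso",
]


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters (defaults follow the reference configuration:
    100 particles, 50 iterations, c1 = c2 = 2, inertia 0.9)."""

    population: int = 100
    iterations: int = 50
    c1: float = 2.0
    c2: float = 2.0
    omega: float = 0.9
    v_max: float = 4.0
    seed: int = 0
    decode_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.population < 1 or self.iterations < 1:
            raise ValueError("population and iterations must be >= 1")
        if self.omega < 0 or self.v_max <= 0:
            raise ValueError("omega must be >= 0 and v_max > 0")
        if not 0.0 < self.decode_threshold < 1.0:
            raise ValueError("decode_threshold must be in (0, 1)")


@dataclass(frozen=True)
class FitnessConfig:
    """Cost-function weights and the KNN error-estimation protocol.

    ``alpha`` weights the CV error, ``beta`` the relative subset size; they
    must sum to 1. ``n_all`` is the size of the search space (defaults to the
    dimensionality of the data handed to the search).
    """

    alpha: float = 0.95
    beta: float = 0.05
    knn_k: int = 5
    folds: int = 5
    n_all: int | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError(f"alpha + beta must equal 1, got {self.alpha + self.beta}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_cost: float


@dataclass
class SwarmState:
    particles: list
    gbest_position: np.ndarray
    gbest_cost: float
    trace: list
    rng_state: dict


@dataclass
class SelectionResult:
    """Outcome of one PSO run: the decoded global best and its cost parts."""

    selected: list
    cost: float
    error_component: float
    trace: list
    swarm_config: dict
    fitness_config: dict
    selected_names: list = field(default_factory=list)


def decode_subset(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Indices of dimensions strictly above the threshold."""
    position = np.asarray(position)
    if not np.isfinite(position).all():
        raise ValueError("position entries must be finite")
    return np.flatnonzero(position > threshold)


def make_fold_assignment(y: np.ndarray, folds: int, seed: int) -> list:
    """One stratified (train, test) index partition, fixed for a PSO run."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**32))
    return list(skf.split(np.zeros((len(y), 1)), y))


def knn_error(dataset: TabularDataset, subset, config: FitnessConfig, fold_assignment) -> float:
    """Mean misclassification rate of a KNN classifier over fixed CV folds.

    Features are min-max scaled (scaler fit on each training fold); distances
    are Euclidean; votes are majority with scikit-learn's lowest-class-index
    tie resolution. Deterministic given the fold assignment.
    """
    subset = np.asarray(list(subset), dtype=np.intp)
    if subset.size == 0:
        raise ValueError("subset must be non-empty; empty subsets are costed by the caller")
    X = dataset.X[:, subset]
    y = dataset.y
    errors = []
    for train, test in fold_assignment:
        if len(train) < config.knn_k:
            raise ValueError(
                f"training fold of size {len(train)} is smaller than knn_k={config.knn_k}"
            )
        scaler = MinMaxScaler().fit(X[train])
        knn = KNeighborsClassifier(n_neighbors=config.knn_k)
        knn.fit(scaler.transform(X[train]), y[train])
        pred = knn.predict(scaler.transform(X[test]))
        errors.append(np.mean(pred != y[test]))
    return float(np.mean(errors))


def fitness_cost(position, dataset: TabularDataset, config: FitnessConfig,
                 fold_assignment, threshold: float = 0.5,
                 _cache: dict | None = None) -> tuple[float, float]:
    """Cost of a particle position: ``alpha*V_error + beta*size/n_all``.

    An empty decoded subset is assigned V_error = 1.0 (worst case), so it
    costs exactly alpha. Returns ``(cost, v_error)``.
    """
    subset = decode_subset(position, threshold)
    n_all = config.n_all if config.n_all is not None else len(np.asarray(position))
    key = subset.tobytes() if _cache is not None else None
    if key is not None and key in _cache:
        v_error = _cache[key]
    else:
        v_error = 1.0 if subset.size == 0 else knn_error(dataset, subset, config, fold_assignment)
        if key is not None:
            _cache[key] = v_error
    return config.alpha * v_error + config.beta * subset.size / n_all, v_error


def update_velocity(particle: Particle, gbest_position: np.ndarray,
                    config: SwarmConfig, rng: np.random.Generator) -> np.ndarray:
    """Inertia-weight velocity update with fresh per-dimension r1, r2."""
    d = len(particle.position)
    r1 = rng.random(d)
    r2 = rng.random(d)
    v = (
        config.omega * particle.velocity
        + config.c1 * r1 * (particle.pbest_position - particle.position)
        + config.c2 * r2 * (gbest_position - particle.position)
    )
    return np.clip(v, -config.v_max, config.v_max)


def update_position(particle: Particle, new_velocity: np.ndarray) -> np.ndarray:
    """Additive position update, clamped to the unit hypercube."""
    return np.clip(particle.position + new_velocity, 0.0, 1.0)


def run_pso(dataset: TabularDataset, swarm_config: SwarmConfig | None = None,
            fitness_config: FitnessConfig | None = None) -> SelectionResult:
    """Minimize the subset cost over the dataset's features by PSO.

    The dataset is typically the top-K restriction produced by the ranking
    stage; returned indices refer to its columns. Raises before any iteration
    when the dataset cannot support stratified KNN error estimation.
    """
    swarm_config = swarm_config or SwarmConfig()
    fitness_config = fitness_config or FitnessConfig()
    y = dataset.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("PSO search needs at least 2 classes")
    if counts.min() < fitness_config.folds:
        raise ValueError(
            f"smallest class ({counts.min()} samples) cannot be stratified into "
            f"{fitness_config.folds} folds"
        )
    d = dataset.n_features
    if fitness_config.n_all is None:
        fitness_config = FitnessConfig(**{**asdict(fitness_config), "n_all": d})

    rng = np.random.default_rng(swarm_config.seed)
    folds = make_fold_assignment(y, fitness_config.folds, swarm_config.seed)
    cache: dict = {}
    thr = swarm_config.decode_threshold

    positions = rng.random((swarm_config.population, d))
    velocities = rng.uniform(-1.0, 1.0, (swarm_config.population, d))
    particles = []
    gbest_position, gbest_cost, gbest_error = None, np.inf, 1.0
    for i in range(swarm_config.population):
        cost, err = fitness_cost(positions[i], dataset, fitness_config, folds, thr, cache)
        particles.append(Particle(positions[i], velocities[i], positions[i].copy(), cost))
        if cost < gbest_cost:
            gbest_position, gbest_cost, gbest_error = positions[i].copy(), cost, err

    trace = []
    for _ in range(swarm_config.iterations):
        for part in particles:
            v = update_velocity(part, gbest_position, swarm_config, rng)
            part.velocity = v
            part.position = update_position(part, v)
            cost, err = fitness_cost(part.position, dataset, fitness_config, folds, thr, cache)
            if cost < part.pbest_cost:
                part.pbest_cost = cost
                part.pbest_position = part.position.copy()
            if cost < gbest_cost:
                gbest_position, gbest_cost, gbest_error = part.position.copy(), cost, err
        trace.append(gbest_cost)

    selected = decode_subset(gbest_position, thr)
    return SelectionResult(
        selected=selected.tolist(),
        cost=float(gbest_cost),
        error_component=float(gbest_error),
        trace=[float(c) for c in trace],
        swarm_config=asdict(swarm_config),
        fitness_config=asdict(fitness_config),
        selected_names=[dataset.feature_names[i] for i in selected],
    )


class PSOSubsetSelector(SelectorMixin, BaseEstimator):
    """PSO feature-subset selector (scikit-learn estimator over run_pso).

    ``fit(X, y)`` searches subsets of X's columns minimizing the KNN-error
    plus size-penalty cost; ``transform`` keeps the winning subset.

    Attributes
    ----------
    result_ : SelectionResult — full outcome including the cost trace.
    support_ : boolean mask of selected features.
    """

    def __init__(self, population: int = 100, iterations: int = 50, c1: float = 2.0,
                 c2: float = 2.0, omega: float = 0.9, v_max: float = 4.0,
                 decode_threshold: float = 0.5, alpha: float = 0.95, beta: float = 0.05,
                 knn_k: int = 5, cv: int = 5, random_state: int = 0):
        self.population = population
        self.iterations = iterations
        self.c1 = c1
        self.c2 = c2
        self.omega = omega
        self.v_max = v_max
        self.decode_threshold = decode_threshold
        self.alpha = alpha
        self.beta = beta
        self.knn_k = knn_k
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        dataset = TabularDataset(X=X, y=y)
        result = run_pso(
            dataset,
            SwarmConfig(
                population=self.population, iterations=self.iterations, c1=self.c1,
                c2=self.c2, omega=self.omega, v_max=self.v_max,
                seed=self.random_state, decode_threshold=self.decode_threshold,
            ),
            FitnessConfig(alpha=self.alpha, beta=self.beta, knn_k=self.knn_k,
                          folds=self.cv),
        )
        self.result_ = result
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[result.selected] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
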