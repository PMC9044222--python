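"""The end-to-end hybrid selection pipeline.

Stages: sparse-feature filtering and optional class balancing, mRMR-MIQ
ranking of the surviving features with MIC, PSO wrapper search over the
top-K ranked features, and SVM cross-validation of the final subset. The
:class:`MMPSOSelector` estimator exposes the whole chain as a scikit-learn
feature selector; :func:`run_pipeline` additionally produces an audit
manifest with every stage's configuration, seed and output.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .data import TabularDataset
from .evaluate import cv_accuracy
from .preprocess import PreprocessConfig, filter_sparse_features, random_oversample
from .ranking import MRMRRanker, rank_features
from .swarm import FitnessConfig, SwarmConfig, run_pso

__all__ = ["MMPSOSelector", "RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    """Audit record of one pipeline run; sufficient to reproduce it."""

    config: dict
    seeds: dict
    input_shape: tuple
    removed_features: list
    ranking: dict
    selection: dict
    evaluation: dict
    selected_features: list
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def to_dict(self) -> dict:
        return asdict(self)


class MMPSOSelector(SelectorMixin, BaseEstimator):
    """Hybrid filter-wrapper feature selector.

    Ranks features by greedy mRMR with MIC relevance/redundancy, then
    searches subsets of the top ``k`` ranked features with a particle swarm
    minimizing KNN error plus a subset-size penalty. Optional preprocessing
    (zero-heavy feature removal, random oversampling of minority classes)
    happens inside ``fit`` on the training data only; ``transform`` merely
    selects columns, so the estimator composes with sklearn pipelines.

    Parameters mirror the stage estimators; ``random_state`` seeds both the
    oversampler and the swarm.
    """

    def __init__(self, k: int = 100, max_zero_fraction: float = 1.0,
                 oversample: bool = False, measure: str = "mic",
                 b_exponent: float = 0.6, clump_factor: int = 15,
                 population: int = 100, iterations: int = 50, c1: float = 2.0,
                 c2: float = 2.0, omega: float = 0.9, v_max: float = 4.0,
                 decode_threshold: float = 0.5, alpha: float = 0.95,
                 beta: float = 0.05, knn_k: int = 5, cv: int = 5,
                 random_state: int = 0):
        self.k = k
        self.max_zero_fraction = max_zero_fraction
        self.oversample = oversample
        self.measure = measure
        self.b_exponent = b_exponent
        self.clump_factor = clump_factor
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

        filtered, removed = filter_sparse_features(
            dataset, PreprocessConfig(max_zero_fraction=self.max_zero_fraction)
        )
        kept = [i for i, n in enumerate(dataset.feature_names)
                if n in set(filtered.feature_names)]
        self.removed_features_ = removed

        work = random_oversample(filtered, seed=self.random_state) if self.oversample \
            else filtered

        ranking = rank_features(
            work, K=min(self.k, work.n_features), measure=self.measure,
            config=self._association_config(),
        )
        self.ranking_ = ranking

        top = work.select_features(ranking.order)
        result = run_pso(
            top,
            SwarmConfig(population=self.population, iterations=self.iterations,
                        c1=self.c1, c2=self.c2, omega=self.omega, v_max=self.v_max,
                        seed=self.random_state,
                        decode_threshold=self.decode_threshold),
            FitnessConfig(alpha=self.alpha, beta=self.beta, knn_k=self.knn_k,
                          folds=self.cv),
        )
        # map: top-K index -> filtered index -> original index
        original = [kept[ranking.order[i]] for i in result.selected]
        self.selection_result_ = result
        self.selected_indices_ = sorted(original)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.selected_indices_] = True
        return self

    def _association_config(self):
        from .association import AssociationConfig

        return AssociationConfig(
            b_exponent=self.b_exponent, clump_factor=self.clump_factor
        )

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_


def run_pipeline(dataset: TabularDataset, k: int = 100, max_zero_fraction: float = 1.0,
                 oversample: bool = False, measure: str = "mic",
                 swarm_config: SwarmConfig | None = None,
                 fitness_config: FitnessConfig | None = None,
                 eval_folds: int = 10, seed: int = 0,
                 input_checksum: str | None = None) -> RunManifest:
    """Run preprocess -> rank -> select -> evaluate and emit the manifest.

    ``k`` caps the ranked handoff; datasets with p <= k pass every feature to
    the wrapper. The evaluation stage scores the final subset with
    ``eval_folds``-fold SVM accuracy on the same (possibly balanced) data the
    search used, and records which variant was scored.
    """
    swarm_config = swarm_config or SwarmConfig(seed=seed)
    fitness_config = fitness_config or FitnessConfig()

    filtered, removed = filter_sparse_features(
        dataset, PreprocessConfig(max_zero_fraction=max_zero_fraction)
    )
    work = random_oversample(filtered, seed=seed) if oversample else filtered

    # p <= k simply passes every feature to the wrapper; not worth a warning
    ranking = rank_features(work, K=min(k, work.n_features), measure=measure)
    top = work.select_features(ranking.order)
    selection = run_pso(top, swarm_config, fitness_config)
    selected_filtered = [ranking.order[i] for i in selection.selected]
    selected_names = [work.feature_names[i] for i in selected_filtered]

    report = cv_accuracy(work, selected_filtered, folds=eval_folds, seed=seed)

    return RunManifest(
        config={
            "k": k,
            "max_zero_fraction": max_zero_fraction,
            "oversample": oversample,
            "measure": measure,
            "swarm": asdict(swarm_config),
            "fitness": selection.fitness_config,
            "eval_folds": eval_folds,
            "evaluated_on": "oversampled" if oversample else "original",
            "input_checksum": input_checksum,
        },
        seeds={"pipeline": seed, "swarm": swarm_config.seed},
        input_shape=(dataset.n_samples, dataset.n_features),
        removed_features=removed,
        ranking={
            "order": ranking.order,
            "feature_names": ranking.feature_names,
            "scores": ranking.scores,
            "relevance": ranking.relevance,
            "redundancy": ranking.redundancy,
            "K": ranking.K,
            "capped": ranking.capped,
        },
        selection={
            "selected": selection.selected,
            "selected_names": selection.selected_names,
            "cost": selection.cost,
            "error_component": selection.error_component,
            "trace": selection.trace,
        },
        evaluation={
            "accuracy": report.accuracy,
            "per_fold": report.per_fold,
            "folds": report.folds,
            "classifier": report.classifier,
        },
        selected_features=selected_names,
    )
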