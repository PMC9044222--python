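"""mRMR feature ranking under the MIQ (quotient) criterion.

Relevance V of a feature set is the mean feature-label association and
redundancy W the mean pairwise feature-feature association (self-terms
included in the literal set-level form). The greedy ranking picks the most
label-relevant feature first, then repeatedly the candidate maximizing the
incremental quotient

    assoc(y; candidate) / mean_{s in selected} assoc(candidate; s)

with an epsilon floor on the denominator. The association measure is MIC by
default; plug-in discrete mutual information is available as a baseline for
pre-discretized data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .association import AssociationConfig, association_to_label, mic, mutual_info_discrete
from .data import TabularDataset

__all__ = [
    "RankingResult",
    "MRMRRanker",
    "relevance",
    "redundancy",
    "incremental_miq_score",
    "rank_features",
]

#: denominator floor; the quotient criterion is undefined at exactly zero
#: redundancy, so non-redundant candidates get a large finite score instead
EPS_REDUNDANCY = 1e-12


def _assoc_factory(measure: str, config: AssociationConfig):
    """(feature, feature) and (feature, label) association callables."""
    if measure == "mic":

        def ff(a, b):
            return mic(a, b, config)

        def fl(a, y):
            return association_to_label(a, y, config)

    elif measure == "mi":

        def ff(a, b):
            return mutual_info_discrete(a, b, config.log_base)

        fl = ff
    else:
        raise ValueError(f"measure must be 'mic' or 'mi', got {measure!r}")
    return ff, fl


@dataclass
class RankingResult:
    """Greedy mRMR ranking: feature order plus the per-step criterion parts.

    ``scores[r]``, ``relevance[r]`` and ``redundancy[r]`` are the MIQ score,
    label association V and candidate-vs-selected mean redundancy W of the
    feature at rank r *at the moment it was selected* (first pick has W=0 and
    score=V).
    """

    order: list
    scores: list
    relevance: list
    redundancy: list
    K: int
    measure: str
    capped: bool = False
    feature_names: list = field(default_factory=list)


def relevance(candidates, dataset: TabularDataset, measure: str = "mic",
              config: AssociationConfig | None = None) -> float:
    """Set-level relevance: mean label association over the candidate set."""
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    _, fl = _assoc_factory(measure, config or AssociationConfig())
    return float(np.mean([fl(dataset.X[:, i], dataset.y) for i in candidates]))


def redundancy(candidates, dataset: TabularDataset, measure: str = "mic",
               config: AssociationConfig | None = None) -> float:
    """Set-level redundancy: mean association over all ordered pairs.

    Includes the i=j self-terms, so a singleton set under MIC scores 1.
    """
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    ff, _ = _assoc_factory(measure, config or AssociationConfig())
    total = 0.0
    for i in candidates:
        for j in candidates:
            total += ff(dataset.X[:, i], dataset.X[:, j])
    return total / len(candidates) ** 2


def incremental_miq_score(candidate: int, selected, dataset: TabularDataset,
                          measure: str = "mic",
                          config: AssociationConfig | None = None) -> float:
    """Greedy MIQ step score for one candidate against the selected set."""
    config = config or AssociationConfig()
    ff, fl = _assoc_factory(measure, config)
    v = fl(dataset.X[:, candidate], dataset.y)
    selected = list(selected)
    if not selected:
        return v
    w = float(np.mean([ff(dataset.X[:, candidate], dataset.X[:, s]) for s in selected]))
    return v / max(w, EPS_REDUNDANCY)


class MRMRRanker(SelectorMixin, BaseEstimator):
    """Greedy mRMR-MIQ feature ranker (scikit-learn selector).

    Ranks features by forward selection under the quotient criterion and
    selects the top ``k``; ``transform`` keeps those columns. Feature-feature
    associations are computed lazily (each newly ranked feature is compared
    against the remaining candidates once), so ranking min(k, p) features
    costs O(min(k, p) * p) association evaluations.

    Parameters
    ----------
    k : int
        Number of features to rank/keep; silently capped at p (the capped
        state is exposed as ``capped_``).
    measure : {"mic", "mi"}
        Association measure. ``mi`` treats values as categorical codes and is
        only meaningful on pre-discretized data.
    b_exponent, clump_factor, mode : MIC estimator settings
        See :class:`~mmpso.association.AssociationConfig`.

    Attributes
    ----------
    ranking_ : list of int — feature indices, best first.
    scores_, relevance_, redundancy_ : per-rank criterion parts.
    support_ : boolean mask of the selected (top-k) features.
    """

    def __init__(self, k: int = 100, measure: str = "mic", b_exponent: float = 0.6,
                 clump_factor: int = 15, mode: str = "approx"):
        self.k = k
        self.measure = measure
        self.b_exponent = b_exponent
        self.clump_factor = clump_factor
        self.mode = mode

    def fit(self, X, y):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        X, y = validate_data(self, X, y)
        config = AssociationConfig(
            b_exponent=self.b_exponent, clump_factor=self.clump_factor, mode=self.mode
        )
        ff, fl = _assoc_factory(self.measure, config)
        p = X.shape[1]
        k = min(self.k, p)
        self.capped_ = k < self.k
        if self.capped_:
            warnings.warn(
                f"k={self.k} exceeds feature count {p}; ranking all features",
                stacklevel=2,
            )

        label_assoc = np.array([fl(X[:, i], y) for i in range(p)])
        selected: list[int] = []
        scores, rels, reds = [], [], []
        # running sum of assoc(candidate, s) over selected s, per candidate
        red_sum = np.zeros(p)
        remaining = np.ones(p, dtype=bool)
        for step in range(k):
            if step == 0:
                crit = np.where(remaining, label_assoc, -np.inf)
                w_cur = np.zeros(p)
            else:
                w_cur = red_sum / step
                crit = np.where(
                    remaining, label_assoc / np.maximum(w_cur, EPS_REDUNDANCY), -np.inf
                )
            pick = int(np.argmax(crit))  # ties resolve to the lowest index
            selected.append(pick)
            scores.append(float(crit[pick]))
            rels.append(float(label_assoc[pick]))
            reds.append(float(w_cur[pick]))
            remaining[pick] = False
            if step < k - 1:
                for c in np.flatnonzero(remaining):
                    red_sum[c] += ff(X[:, c], X[:, pick])

        self.ranking_ = selected
        self.scores_ = scores
        self.relevance_ = rels
        self.redundancy_ = reds
        self.label_association_ = label_assoc
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[selected] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    def to_result(self, feature_names=None) -> RankingResult:
        check_is_fitted(self)
        return RankingResult(
            order=list(self.ranking_),
            scores=list(self.scores_),
            relevance=list(self.relevance_),
            redundancy=list(self.redundancy_),
            K=self.k,
            measure=self.measure,
            capped=self.capped_,
            feature_names=(
                [feature_names[i] for i in self.ranking_] if feature_names else []
            ),
        )


def rank_features(dataset: TabularDataset, K: int = 100, measure: str = "mic",
                  config: AssociationConfig | None = None) -> RankingResult:
    """Greedy mRMR-MIQ ranking of a dataset's features (thin wrapper)."""
    config = config or AssociationConfig()
    ranker = MRMRRanker(
        k=K,
        measure=measure,
        b_exponent=config.b_exponent,
        clump_factor=config.clump_factor,
        mode=config.mode,
    )
    ranker.fit(dataset.X, dataset.y)
    return ranker.to_result(dataset.feature_names)
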