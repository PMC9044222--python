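"""Final-subset validation: SVM cross-validation accuracy, logistic biomarker
panels, and ROC/AUC.

``cv_accuracy`` scores a feature subset by stratified k-fold accuracy of an
RBF-kernel soft-margin SVM on min-max-scaled features — the harness used to
compare selection methods. ``fit_panel`` fits a maximum-likelihood logistic
model to a biomarker subset; the fitted :class:`PanelModel` realizes the
panel probability

    PP = 1 / (1 + exp(-(constant + sum_i coefficient_i * expression_i)))

used to score samples, whose discrimination is summarized by the area under
the ROC curve (Mann-Whitney convention, ties half-credited).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .data import TabularDataset

__all__ = [
    "EvaluationReport",
    "PanelModel",
    "cv_accuracy",
    "fit_panel",
    "panel_probability",
    "roc_auc",
]


@dataclass
class EvaluationReport:
    """Cross-validated accuracy of one classifier on one feature subset."""

    accuracy: float  # percent, mean of per_fold
    per_fold: list
    folds: int
    classifier: dict
    subset: list
    seed: int

    def __post_init__(self) -> None:
        assert abs(self.accuracy - float(np.mean(self.per_fold))) < 1e-9


@dataclass
class PanelModel:
    """Intercept + per-feature coefficients of a logistic biomarker panel."""

    constant: float
    coefficients: list
    feature_names: list
    std_errors: list = field(default_factory=list)
    wald: list = field(default_factory=list)
    p_values: list = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("coefficients and feature_names must align")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names in panel")

    def table(self) -> pd.DataFrame:
        """Coefficient table: Variable, Coefficient, Std. Error, Wald, P value."""
        rows = list(zip(self.feature_names, self.coefficients, self.std_errors,
                        self.wald, self.p_values))
        rows.append(("Constant", self.constant, np.nan, np.nan, np.nan))
        df = pd.DataFrame(
            rows, columns=["Variable", "Coefficient", "Std. Error", "Wald", "P value"]
        )
        return df

    def to_dict(self) -> dict:
        return asdict(self)


def cv_accuracy(dataset: TabularDataset, subset, folds: int = 10, seed: int = 0,
                C: float = 1.0, gamma="auto") -> EvaluationReport:
    """Stratified k-fold SVM accuracy (percent) on a feature subset.

    The classifier is an RBF-kernel SVC (default C=1, gamma=1/d, one-vs-one
    for multi-class) on min-max-scaled features; the scaler is fit on each
    training fold. The fold assignment is seeded and recorded in the report.
    """
    subset = sorted(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    X = dataset.X[:, subset]
    y = dataset.y
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2 or counts.min() < folds:
        raise ValueError(
            f"labels cannot be stratified into {folds} folds (min class size {counts.min()})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**32))
    model = make_pipeline(MinMaxScaler(), SVC(C=C, kernel="rbf", gamma=gamma))
    per_fold = cross_val_score(model, X, y, cv=skf, scoring="accuracy")
    per_fold = [float(a) * 100.0 for a in per_fold]
    return EvaluationReport(
        accuracy=float(np.mean(per_fold)),
        per_fold=per_fold,
        folds=folds,
        classifier={"kind": "svm-rbf", "C": C, "gamma": str(gamma)},
        subset=list(subset),
        seed=seed,
    )


def fit_panel(dataset: TabularDataset, subset=None, tol: float = 1e-8,
              maxiter: int = 100) -> PanelModel:
    """Maximum-likelihood logistic fit of the label on a biomarker subset.

    Newton/IRLS optimization; reports coefficients, standard errors, Wald
    chi-square statistics and p-values. ``subset=None`` or empty fits the
    intercept-only model. Perfect separation is flagged via ``converged``
    rather than raised.
    """
    y = dataset.y
    if len(np.unique(y)) != 2:
        raise ValueError("panel fitting requires binary labels")
    y01 = (y == np.unique(y)[1]).astype(float)
    subset = sorted(subset) if subset else []
    names = [dataset.feature_names[i] for i in subset]
    X = sm.add_constant(dataset.X[:, subset], has_constant="add")

    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y01, X).fit(method="newton", tol=tol, maxiter=maxiter, disp=0)
        except Exception as exc:  # perfect separation raises in some versions
            raise ValueError(f"logistic fit failed: {exc}") from None
        if any("separation" in str(w.message).lower() or "converge" in str(w.message).lower()
               for w in caught):
            converged = False
    if not fit.mle_retvals.get("converged", True):
        converged = False

    params = np.asarray(fit.params)
    bse = np.asarray(fit.bse)
    wald = (params / bse) ** 2
    pvals = np.asarray(fit.pvalues)
    return PanelModel(
        constant=float(params[0]),
        coefficients=params[1:].tolist(),
        feature_names=names,
        std_errors=bse[1:].tolist(),
        wald=wald[1:].tolist(),
        p_values=pvals[1:].tolist(),
        converged=converged,
    )


def panel_probability(model: PanelModel, expression) -> np.ndarray | float:
    """Panel probability of one sample (1-D) or many (2-D, samples x features).

    Sigmoid of ``constant + sum_i coefficient_i * expression_i``; strictly
    increasing in every feature with a positive coefficient and decreasing
    where negative.
    """
    expr = np.asarray(expression, dtype=float)
    k = len(model.coefficients)
    if expr.ndim == 1:
        if len(expr) != k:
            raise ValueError(
                f"expression has {len(expr)} values but the panel has {k} features "
                f"({model.feature_names})"
            )
        z = model.constant + float(np.dot(model.coefficients, expr))
        return float(expit(z))
    if expr.shape[1] != k:
        raise ValueError(
            f"expression has {expr.shape[1]} columns but the panel has {k} features"
        )
    z = model.constant + expr @ np.asarray(model.coefficients)
    return expit(z)


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC and ROC curve points for binary labels.

    AUC follows the Mann-Whitney convention: the probability that a positive
    sample outscores a negative one, with ties counted half. Returns the
    (fpr, tpr, threshold) sweep as a DataFrame.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"ROC needs exactly 2 classes, got {len(classes)}")
    y01 = (labels == classes[1]).astype(int)
    if np.ptp(scores) == 0:
        # constant scores: no threshold separates anything; AUC is chance
        curve = pd.DataFrame({"fpr": [0.0, 1.0], "tpr": [0.0, 1.0],
                              "threshold": [np.inf, scores[0]]})
        return 0.5, curve
    auc = float(roc_auc_score(y01, scores))
    fpr, tpr, thr = roc_curve(y01, scores)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
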