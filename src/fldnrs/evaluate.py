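"""Cross-validated classifier accuracy of a selected gene subset.

Stratified k-fold cross-validation on the matrix restricted to the
subset, with a linear-kernel SVM as the primary classifier (the standard
choice for high-dimensional, small-sample expression data) and k-NN,
decision-tree and naive-Bayes comparators. Leave-one-out is available for
very small cohorts via ``folds="loo"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, LeaveOneOut, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataset import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = ["EvaluationReport", "cross_validate", "CLASSIFIERS"]


def _make_classifier(name: str, seed: int):
    name = name.lower()
    if name == "svm":
        return SVC(kernel="linear", C=1.0)
    if name == "svm-rbf":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "nb":
        return GaussianNB()
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


CLASSIFIERS = ("svm", "svm-rbf", "knn", "tree", "nb")


@dataclass(frozen=True)
class EvaluationReport:
    subset: tuple
    classifier: str
    folds: int
    stratified: bool
    seed: int
    fold_accuracies: tuple
    mean_accuracy: float

    @property
    def subset_size(self) -> int:
        return len(self.subset)

    def to_dict(self) -> dict:
        return {
            "subset": list(self.subset),
            "m": self.subset_size,
            "classifier": self.classifier,
            "cv": {"folds": self.folds, "stratified": self.stratified,
                   "seed": self.seed},
            "fold_accuracies": list(self.fold_accuracies),
            "mean_accuracy": self.mean_accuracy,
        }


def cross_validate(ds: ExpressionDataset, subset, classifier: str = "svm",
                   folds=10, seed: int = 0) -> EvaluationReport:
    """Stratified k-fold accuracy of ``classifier`` on the gene subset.

    The fold partition is reproducible from ``seed``. If the smallest
    class has fewer members than ``folds``, the fold count is reduced to
    that size with a warning rather than failing.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("gene subset must be nonempty")
    X = ds.matrix[:, ds.positions(subset)]
    y = np.asarray(ds.labels)

    if folds == "loo":
        cv = LeaveOneOut()
        n_folds, stratified = ds.n_samples, False
    else:
        folds = int(folds)
        if folds < 2:
            raise ValueError("folds must be >= 2")
        smallest = int(np.bincount(np.unique(y, return_inverse=True)[1]).min())
        if smallest < folds:
            warnings.warn(
                f"smallest class has {smallest} samples; reducing folds "
                f"from {folds} to {smallest}", stacklevel=2)
            folds = smallest
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        n_folds, stratified = folds, True

    clf = _make_classifier(classifier, seed)
    scores = cross_val_score(clf, X, y, cv=cv, scoring="accuracy")
    return EvaluationReport(tuple(subset), classifier, n_folds, stratified,
                            seed, tuple(float(s) for s in scores),
                            float(scores.mean()))
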