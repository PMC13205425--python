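"""Wrapper fitness: descriptor -> features -> stratified CV linear SVM error.

A candidate Gabor bank is scored by extracting its mu/sigma features for every
training sample, running a stratified K-fold cross-validation with a linear
SVM (C = 1 by default), and returning one minus the mean held-out accuracy.
Folds are built once per run (from ``fold_seed``) and reused for every
candidate so that all candidates are compared on identical partitions.

Feature standardisation (z-scoring fitted on the training folds only) is on by
default: raw Gabor means reach hundreds while other components sit near zero,
and a fixed-C linear SVM is scale-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import de
from .gabor import GaborBank, extract_feature_vector
from .preprocess import LabeledSample

__all__ = [
    "CVConfig",
    "FitnessRecord",
    "build_feature_table",
    "feature_matrix",
    "make_stratified_folds",
    "evaluate_error",
    "fit_final_svm",
    "make_fitness",
]


@dataclass(frozen=True)
class CVConfig:
    folds: int = 5
    svm_c: float = 1.0
    kernel: str = "linear"
    standardize: bool = True
    fold_seed: int = 0


@dataclass(frozen=True)
class FitnessRecord:
    """Cross-validated error E = 1 - mean(per-fold accuracy)."""

    error: float
    fold_accuracies: tuple[float, ...]


def build_feature_table(samples: Sequence[LabeledSample], bank: GaborBank) -> pd.DataFrame:
    """One row per sample: id, mu1, sigma1, ..., muNf, sigmaNf, label."""
    if len(samples) == 0:
        raise ValueError("no samples")
    labels = {s.label for s in samples}
    if len(labels) < 2:
        raise ValueError(f"single-class input (labels {sorted(labels)}); CV is undefined")
    columns = ["id"]
    for j in range(len(bank)):
        columns += [f"mu{j + 1}", f"sigma{j + 1}"]
    columns.append("label")
    rows = []
    for s in samples:
        feats = extract_feature_vector(s.image, bank)
        rows.append([s.id, *feats.tolist(), s.label])
    return pd.DataFrame(rows, columns=columns)


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature table into (X, y)."""
    feat_cols = [c for c in table.columns if c not in ("id", "label")]
    return table[feat_cols].to_numpy(dtype=float), table["label"].to_numpy(dtype=int)


def make_stratified_folds(labels: Sequence[int], folds: int, fold_seed: int) -> list[np.ndarray]:
    """Partition indices into K class-proportional test folds (deterministic
    under ``fold_seed``)."""
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small} has {counts.min()} members, fewer than {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
    return [test_idx for _, test_idx in skf.split(np.zeros((y.size, 1)), y)]


def _make_svm(cv: CVConfig) -> SVC:
    return SVC(kernel=cv.kernel, C=cv.svm_c)


def evaluate_error(table: pd.DataFrame, cv: CVConfig,
                   folds: list[np.ndarray] | None = None) -> FitnessRecord:
    """Stratified K-fold CV error of a linear SVM on the feature table.

    Standardisation statistics, when enabled, are fitted on the training folds
    only — the held-out fold never leaks into the fit.
    """
    X, y = feature_matrix(table)
    if folds is None:
        folds = make_stratified_folds(y, cv.folds, cv.fold_seed)
    accuracies = []
    for k, test_idx in enumerate(folds):
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        y_train = y[train_mask]
        if np.unique(y_train).size < 2:
            raise ValueError(f"fold {k}: training split contains a single class")
        X_train, X_test = X[train_mask], X[test_idx]
        if cv.standardize:
            scaler = StandardScaler().fit(X_train)
            X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
        model = _make_svm(cv).fit(X_train, y_train)
        accuracies.append(float((model.predict(X_test) == y[test_idx]).mean()))
    return FitnessRecord(error=1.0 - float(np.mean(accuracies)),
                         fold_accuracies=tuple(accuracies))


def fit_final_svm(train_table: pd.DataFrame, test_table: pd.DataFrame,
                  cv: CVConfig) -> tuple[np.ndarray, np.ndarray]:
    """Single fit on the full training table, predictions on the held-out
    table (no cross-validation): returns (y_true, y_pred) for the test rows."""
    X_train, y_train = feature_matrix(train_table)
    X_test, y_test = feature_matrix(test_table)
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError(
            f"feature length mismatch: train {X_train.shape[1]}, test {X_test.shape[1]}"
        )
    if cv.standardize:
        scaler = StandardScaler().fit(X_train)
        X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
    model = _make_svm(cv).fit(X_train, y_train)
    return y_test, model.predict(X_test)


def make_fitness(samples: Sequence[LabeledSample], cv: CVConfig) -> Callable[[np.ndarray], float]:
    """Build the DE objective: decision vector -> decoded bank -> CV error.

    The stratified folds are computed once from ``cv.fold_seed`` and reused
    for every candidate, removing partition noise from candidate comparisons.
    """
    labels = [s.label for s in samples]
    folds = make_stratified_folds(labels, cv.folds, cv.fold_seed)

    def fitness(vector: np.ndarray) -> float:
        bank = de.decode(vector)
        table = build_feature_table(samples, bank)
        return evaluate_error(table, cv, folds=folds).error

    return fitness
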