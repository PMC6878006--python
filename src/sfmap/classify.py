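"""Class-weighted RBF-kernel SVM over marker fractionation profiles.

Training data are the curated marker proteins; features are the combined
20-dimensional (two-replicate) relative-abundance profiles. Class weights
are inversely proportional to class frequencies (normalized to mean 1) to
counter the strong imbalance between, e.g., the soluble class and the
ribosomal subunits. Hyperparameters (C, gamma) are chosen by repeated
stratified 80/20 partitioning with k-fold inner grid scoring; the winning
pair maximizes mean inner macro-F1 with ties broken toward the smallest C,
then the smallest gamma (preferring smoother decision surfaces). The
confidence score of each protein is the Platt-scaled (pairwise-coupled)
probability of its winning class, so scores live on [0, 1] and per-class
scores sum to one.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .errors import ConfigurationError
from .ingest import profile_matrix
from .markers import MarkerSet

logger = logging.getLogger(__name__)

DEFAULT_GRID = tuple(float(2.0**k) for k in range(-4, 5))  # 2^-4 .. 2^4


@dataclass(frozen=True)
class ClassifierSpec:
    cost_grid: Sequence[float] = DEFAULT_GRID
    gamma_grid: Sequence[float] = DEFAULT_GRID
    class_weights: Mapping[str, float] | None = None  # None → computed from data
    cv_outer_rounds: int = 100
    cv_inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cost_grid or not self.gamma_grid:
            raise ConfigurationError("hyperparameter grids must be nonempty")
        if any(c <= 0 for c in self.cost_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ConfigurationError("cost and gamma values must be positive")
        if self.class_weights is not None and any(
            w <= 0 for w in self.class_weights.values()
        ):
            raise ConfigurationError("class weights must be strictly positive")
        if self.cv_outer_rounds < 1 or self.cv_inner_folds < 2:
            raise ConfigurationError("cv_outer_rounds >= 1 and cv_inner_folds >= 2")


@dataclass
class TrainedClassifier:
    model: SVC
    classes: tuple[str, ...]
    cost: float
    gamma: float
    class_weights: dict[str, float]
    cv_macro_f1: float
    training_hash: str

    def summary(self) -> dict:
        return {
            "cost": self.cost,
            "gamma": self.gamma,
            "class_weights": self.class_weights,
            "cv_macro_f1": self.cv_macro_f1,
            "classes": list(self.classes),
            "training_hash": self.training_hash,
        }


def compute_class_weights(labels: Sequence[str]) -> dict[str, float]:
    """Weights inversely proportional to class frequencies, mean-normalized to 1."""
    labels = list(labels)
    if not labels:
        raise ConfigurationError("empty training set")
    counts = pd.Series(labels).value_counts()
    if (counts == 0).any():
        raise ConfigurationError("empty class in training labels")
    inv = 1.0 / counts
    weights = inv / inv.mean()
    return {str(c): float(w) for c, w in weights.items()}


def _make_svc(cost: float, gamma: float, weights: Mapping[str, float],
              probability: bool, seed: int) -> SVC:
    kwargs = dict(
        C=cost, gamma=gamma, kernel="rbf", class_weight=dict(weights),
        random_state=seed, cache_size=100,
    )
    if probability:
        # Pairwise-coupled Platt scaling: the confidence score is the winning
        # class's probability, so the built-in SVC calibration is the model,
        # not an optional extra. Recent sklearn deprecates the flag in favour
        # of one-vs-rest CalibratedClassifierCV, which has different coupling
        # semantics; silence the migration warning at the fit site.
        kwargs["probability"] = True
    return SVC(**kwargs)


def _fit(clf: SVC, X: np.ndarray, y: np.ndarray) -> SVC:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        return clf.fit(X, y)


def tune_and_train(
    profiles: pd.DataFrame, markers: MarkerSet, spec: ClassifierSpec
) -> TrainedClassifier:
    """Grid-search (C, gamma) on marker profiles and refit on all markers.

    Each outer round splits the markers 80/20 (stratified); every grid pair
    is scored by stratified k-fold macro-F1 within the 80% block, and the
    round's inner winner is evaluated on the held-out 20% to estimate
    generalization. The final pair maximizes mean inner macro-F1 across
    rounds (ties → smallest C, then smallest gamma).
    """
    marker_ids = [p for p in profiles.index if p in markers]
    y = np.array([markers.entries[p] for p in marker_ids])
    X = profile_matrix(profiles.loc[marker_ids])

    class_counts = pd.Series(y).value_counts()
    if len(class_counts) < 2:
        raise ConfigurationError("training requires at least 2 classes")
    if (class_counts < 2).any():
        small = class_counts[class_counts < 2].index.tolist()
        raise ConfigurationError(
            f"class(es) with a single member (stratification impossible): {small}"
        )

    weights = (
        dict(spec.class_weights)
        if spec.class_weights is not None
        else compute_class_weights(y)
    )
    pairs = [(c, g) for c in spec.cost_grid for g in spec.gamma_grid]
    inner_folds = int(min(spec.cv_inner_folds, class_counts.min()))
    inner_folds = max(inner_folds, 2)

    round_seeds = np.random.SeedSequence(spec.seed).generate_state(spec.cv_outer_rounds)
    round_seeds = [int(s % (2**31 - 1)) for s in round_seeds]

    inner_sums = np.zeros(len(pairs))
    outer_f1: list[float] = []
    for r, rseed in enumerate(round_seeds):
        idx_tr, idx_te = train_test_split(
            np.arange(len(y)), test_size=0.2, stratify=y, random_state=rseed
        )
        Xtr, ytr = X[idx_tr], y[idx_tr]
        if len(pairs) == 1:
            round_scores = np.array([1.0])
        else:
            skf = StratifiedKFold(inner_folds, shuffle=True, random_state=rseed)
            folds = list(skf.split(Xtr, ytr))
            round_scores = np.empty(len(pairs))
            for j, (c, g) in enumerate(pairs):
                fold_f1 = []
                for f_tr, f_te in folds:
                    clf = _make_svc(c, g, weights, probability=False, seed=rseed)
                    _fit(clf, Xtr[f_tr], ytr[f_tr])
                    fold_f1.append(
                        f1_score(ytr[f_te], clf.predict(Xtr[f_te]),
                                 average="macro", zero_division=0)
                    )
                round_scores[j] = float(np.mean(fold_f1))
        inner_sums += round_scores
        best_j = _argmax_with_ties(round_scores, pairs)
        clf = _make_svc(*pairs[best_j], weights, probability=False, seed=rseed)
        _fit(clf, Xtr, ytr)
        outer_f1.append(
            f1_score(y[idx_te], clf.predict(X[idx_te]), average="macro",
                     zero_division=0)
        )

    chosen = pairs[_argmax_with_ties(inner_sums, pairs)]
    cv_macro_f1 = float(np.mean(outer_f1))
    logger.info(
        "chosen (C, gamma) = %s; CV macro-F1 = %.3f over %d rounds",
        chosen, cv_macro_f1, spec.cv_outer_rounds,
    )

    model = _make_svc(*chosen, weights, probability=True, seed=spec.seed)
    _fit(model, X, y)
    digest = hashlib.sha256()
    digest.update(np.ascontiguousarray(X).tobytes())
    digest.update(json.dumps(sorted(marker_ids)).encode())
    return TrainedClassifier(
        model=model,
        classes=tuple(model.classes_),
        cost=float(chosen[0]),
        gamma=float(chosen[1]),
        class_weights={str(k): float(v) for k, v in weights.items()},
        cv_macro_f1=cv_macro_f1,
        training_hash=digest.hexdigest()[:16],
    )


def _argmax_with_ties(scores: np.ndarray, pairs: list[tuple[float, float]]) -> int:
    """Best score; ties resolved toward the smallest cost, then smallest gamma."""
    best = np.max(scores)
    tied = [j for j, s in enumerate(scores) if s >= best - 1e-12]
    return min(tied, key=lambda j: (pairs[j][0], pairs[j][1]))


def score_all(trained: TrainedClassifier, profiles: pd.DataFrame) -> pd.DataFrame:
    """Score every protein (markers included) with the trained model.

    Returns columns: predicted_class, score, and score_<class> for each
    class. predicted_class is the argmax of the Platt probabilities, so the
    invariant score == max(per-class scores) holds exactly.
    """
    X = profile_matrix(profiles)
    if X.shape[1] != trained.model.shape_fit_[1]:
        raise ConfigurationError(
            f"profile dimension {X.shape[1]} does not match the trained model"
        )
    proba = trained.model.predict_proba(X)
    order = np.argsort(trained.model.classes_)  # already sorted, kept explicit
    classes = trained.model.classes_[order]
    proba = proba[:, order]
    winners = np.argmax(proba, axis=1)
    out = pd.DataFrame(index=profiles.index.copy())
    out["predicted_class"] = classes[winners]
    out["score"] = proba[np.arange(len(out)), winners]
    for j, cls in enumerate(classes):
        out[f"score_{cls}"] = proba[:, j]
    return out
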