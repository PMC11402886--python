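"""Classifier training for six-stage maturation classification.

Pipeline per dataset: stratified 70/30 split, feature selection by random
forest impurity importance on the training portion, then hyperparameter
search (random search with inner stratified cross-validation) over six
model families: logistic regression, multi-layer perceptron, random
forest, k-nearest neighbours, support vector machine, and gradient
boosting.  Scale-sensitive estimators are standardized inside the fitted
pipeline so nothing is learned from test data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint
from sklearn.base import clone
from sklearn.ensemble import (
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import ParameterSampler, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datamodel import LabeledDataset, STAGES

FAMILIES = ("LogReg", "MLP", "RForest", "KNeighbors", "SVM", "GraBoost")

#: families that are scale-invariant and skip standardization
_TREE_FAMILIES = {"RForest", "GraBoost"}


def search_space(family: str) -> dict:
    """Default random-search distributions per model family (editable)."""
    spaces = {
        "LogReg": {"C": loguniform(1e-2, 1e3)},
        "MLP": {
            "hidden_layer_sizes": [(16,), (32,), (64,), (128,), (32, 16),
                                   (64, 32)],
            "alpha": loguniform(1e-5, 1e-2),
            "learning_rate_init": loguniform(3e-4, 3e-2),
        },
        "RForest": {
            "n_estimators": randint(50, 201),
            "max_depth": [None, 4, 6, 8, 12, 16],
        },
        "KNeighbors": {
            "n_neighbors": randint(3, 26),
            "weights": ["uniform", "distance"],
        },
        "SVM": {
            "kernel": ["rbf", "linear"],
            "C": loguniform(1e-2, 1e2),
            "gamma": loguniform(1e-4, 1e1),
        },
        "GraBoost": {
            "max_iter": randint(30, 121),
            "learning_rate": loguniform(0.03, 0.3),
            "max_depth": [None, 2, 3, 4, 6],
        },
    }
    if family not in spaces:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    return spaces[family]


def _make_estimator(family: str, params: dict, seed: int):
    if family == "LogReg":
        est = LogisticRegression(max_iter=2000, **params)
    elif family == "MLP":
        est = MLPClassifier(max_iter=300, early_stopping=True,
                            n_iter_no_change=10, random_state=seed, **params)
    elif family == "RForest":
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    elif family == "KNeighbors":
        est = KNeighborsClassifier(**params)
    elif family == "SVM":
        est = SVC(random_state=seed, **params)
    elif family == "GraBoost":
        est = HistGradientBoostingClassifier(
            random_state=seed, early_stopping=True, validation_fraction=0.15,
            n_iter_no_change=10, **params)
    else:
        raise ValueError(f"unknown family {family!r}")
    if family in _TREE_FAMILIES:
        return Pipeline([("clf", est)])
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


# ------------------------------------------------------------------ split

@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split plan (70/30 by stage by default)."""

    train_frac: float = 0.70
    seed: int = 0


def stratified_split(dataset: LabeledDataset, spec: SplitSpec = SplitSpec(),
                     ) -> tuple[LabeledDataset, LabeledDataset]:
    """Deterministic per-stage split preserving stage proportions.

    Within each stage the train share is the largest-remainder rounding of
    ``train_frac``; a stage with a single subject goes to train with a
    warning.
    """
    rng = np.random.default_rng(spec.seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for stage in STAGES:
        ids = np.array(sorted(dataset.y.index[dataset.y == stage]))
        if len(ids) == 0:
            continue
        if len(ids) == 1:
            warnings.warn(f"stage {stage} has a single subject; placed in "
                          f"train", stacklevel=2)
            train_ids.extend(ids)
            continue
        n_train = int(round(spec.train_frac * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    return dataset.subset(sorted(train_ids)), dataset.subset(sorted(test_ids))


# -------------------------------------------------------------- selection

@dataclass
class SelectionReport:
    """Impurity-importance feature selection result."""

    importances: pd.Series
    selected: list[str]
    threshold: float
    rule: str

    def __post_init__(self) -> None:
        if not set(self.selected) <= set(self.importances.index):
            raise ValueError("selected features outside candidate set")


def select_features(train: LabeledDataset, n_trees: int = 300,
                    threshold_rule: str = "mean", top_k: int | None = None,
                    seed: int = 0) -> SelectionReport:
    """Retain the most impactful features by random-forest importance.

    Fits an impurity-importance forest on the training split only and keeps
    features whose importance reaches the mean importance (default) or the
    ``top_k`` highest.  Age and sex compete as ordinary candidates.
    """
    if train.X.shape[1] < 2:
        raise ValueError("need at least two candidate features")
    if train.y.nunique() < 2:
        raise ValueError("training labels are constant")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1)
    forest.fit(train.X.to_numpy(), train.y.to_numpy())
    imp = pd.Series(forest.feature_importances_, index=train.X.columns)
    if threshold_rule == "mean":
        threshold = float(imp.mean())
        selected = list(imp.index[imp >= threshold])
    elif threshold_rule == "top_k":
        if not top_k or top_k < 1:
            raise ValueError("top_k rule needs a positive top_k")
        threshold = float(imp.sort_values(ascending=False).iloc[
            min(top_k, len(imp)) - 1])
        selected = list(imp.sort_values(ascending=False).index[:top_k])
    else:
        raise ValueError("threshold_rule must be 'mean' or 'top_k'")
    return SelectionReport(importances=imp, selected=selected,
                           threshold=threshold, rule=threshold_rule)


# --------------------------------------------------------------- training

@dataclass
class TrainedModel:
    """A tuned, refitted classifier bound to its provenance and features."""

    provenance: str
    family: str
    features: list[str]
    pipeline: Pipeline
    params: dict
    cv_accuracy: float
    train_ids: list[str]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise ValueError(f"holdout lacks features {missing}")
        return self.pipeline.predict(X[self.features].to_numpy())


@dataclass
class ModelReport:
    """Test-set performance of one family on one dataset."""

    family: str
    provenance: str
    params: dict
    cv_accuracy: float
    test_accuracy: float
    confusion: pd.DataFrame
    n_features: int
    model: TrainedModel | None = field(default=None, repr=False)
    tie: bool = False


def tune_and_train(train: LabeledDataset, family: str,
                   features: list[str] | None = None,
                   search_budget: int = 50, cv_folds: int = 5,
                   seed: int = 0, space: dict | None = None) -> TrainedModel:
    """Random hyperparameter search with inner stratified CV, then refit.

    Samples ``search_budget`` configurations from the family's search
    space, scores each by mean CV accuracy on the training split, and
    refits the best configuration on the full training split.  Ties keep
    the earliest sampled configuration, so a fixed seed fixes the outcome.
    """
    if search_budget < 1:
        raise ValueError("search budget must be >= 1")
    if features is None:
        features = list(train.X.columns)
    X = train.X[features].to_numpy()
    y = train.y.to_numpy()
    class_counts = np.bincount(y)
    n_splits = max(2, min(cv_folds, int(class_counts[class_counts > 0].min())))
    if space is None:
        space = search_space(family)
        if family == "KNeighbors":
            # neighbours cannot exceed the training-fold size
            n_fit = int(len(y) * (n_splits - 1) / n_splits)
            space = dict(space,
                         n_neighbors=randint(3, max(4, min(26, n_fit + 1))))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small grids may undersample
        configs = list(ParameterSampler(space, n_iter=search_budget,
                                        random_state=seed))
    folds = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        split_idx = list(folds.split(X, y))

    best_score, best_params = -np.inf, None
    for params in configs:
        pipe = _make_estimator(family, params, seed)
        scores = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                for tr, va in split_idx:
                    m = clone(pipe)
                    m.fit(X[tr], y[tr])
                    scores.append(accuracy_score(y[va], m.predict(X[va])))
            except ValueError:
                continue  # config invalid at this sample size (e.g. k > n)
        score = float(np.mean(scores))
        if score > best_score:
            best_score, best_params = score, params
    if best_params is None:
        raise ValueError(f"{family}: no sampled configuration could be "
                         f"fitted on {len(y)} training subjects")
    final = _make_estimator(family, best_params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    return TrainedModel(
        provenance=train.provenance, family=family, features=list(features),
        pipeline=final, params=best_params, cv_accuracy=best_score,
        train_ids=list(train.X.index),
    )


def evaluate(model: TrainedModel, test: LabeledDataset) -> ModelReport:
    """Accuracy and 6x6 confusion table on a disjoint test set."""
    if len(test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(test.X)
    acc = float(accuracy_score(test.y.to_numpy(), pred))
    conf = pd.DataFrame(
        confusion_matrix(test.y.to_numpy(), pred, labels=list(STAGES)),
        index=[f"true_CS{s}" for s in STAGES],
        columns=[f"pred_CS{s}" for s in STAGES],
    )
    return ModelReport(
        family=model.family, provenance=model.provenance, params=model.params,
        cv_accuracy=model.cv_accuracy, test_accuracy=acc, confusion=conf,
        n_features=len(model.features), model=model,
    )


def pick_top_model(reports: list[ModelReport]) -> ModelReport:
    """Highest test accuracy; ties resolved by fewer features, then the
    fixed family order, and flagged on the winning report."""
    if not reports:
        raise ValueError("no reports to rank")

    def key(r: ModelReport):
        return (-r.test_accuracy, r.n_features, FAMILIES.index(r.family))

    ranked = sorted(reports, key=key)
    best = ranked[0]
    best.tie = len(reports) > 1 and any(
        r is not best and r.test_accuracy == best.test_accuracy
        for r in reports)
    return best


def train_dataset(dataset: LabeledDataset, families=FAMILIES,
                  search_budget: int = 50, cv_folds: int = 5, seed: int = 0,
                  n_trees: int = 300,
                  ) -> tuple[ModelReport, list[ModelReport], SelectionReport]:
    """Full per-dataset modelling stage: split, select, tune, evaluate, rank."""
    train, test = stratified_split(dataset, SplitSpec(seed=seed))
    selection = select_features(train, n_trees=n_trees, seed=seed)
    reports = []
    for family in families:
        model = tune_and_train(train, family, features=selection.selected,
                               search_budget=search_budget,
                               cv_folds=cv_folds, seed=seed)
        reports.append(evaluate(model, test))
    return pick_top_model(reports), reports, selection
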