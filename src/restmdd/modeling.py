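"""Subject-wise splitting, mutual-information reduction, and the six-model
classification harness.

The cohort feature table is split subject-wise with exact class
stratification (100 train / 40 test for the default 140-subject cohort).
Features are ranked on the training rows only by mutual information with the
diagnosis (k-nearest-neighbour estimator for continuous-discrete pairs) and
optionally reduced to the top 100. Six model families — decision tree, SVM,
random forest, k-nearest neighbours, gradient-boosted trees, and Gaussian
naive Bayes — are tuned by grid search with stratified 10-fold
cross-validated accuracy and evaluated on the held-out subjects with
accuracy, binary F1 (MDD positive), and confusion matrices.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_classif
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier, GradientBoostingClassifier

from .cohort import GROUP_MDD

MODEL_FAMILIES = ("DT", "SVM", "RF", "KNN", "GBOOST", "NB")


class LeakageError(RuntimeError):
    """Raised when test subjects reach a fitting operation."""


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint subject-wise train/test partition."""

    train_ids: tuple
    test_ids: tuple
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test subject sets overlap")


def stratified_subject_split(table: pd.DataFrame, test_size: int = 40,
                             seed: int = 0) -> SplitSpec:
    """Random subject-wise partition with exact class-proportional allocation.

    Per-class test counts follow largest-remainder rounding of
    ``test_size * n_class / n_total``, so a balanced 140-subject cohort with
    ``test_size=40`` always yields 20 MDD + 20 healthy test subjects.
    """
    if test_size <= 0:
        raise ValueError("test_size must be positive")
    n = len(table)
    if test_size >= n:
        raise ValueError(f"test_size={test_size} must be < n_subjects={n}")
    groups = table["group"]
    classes = sorted(groups.unique())
    if len(classes) < 2:
        raise ValueError("both diagnosis classes must be present")
    # Largest-remainder allocation of test slots to classes.
    quotas = {c: test_size * (groups == c).sum() / n for c in classes}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    short = test_size - sum(counts.values())
    for c in sorted(classes, key=lambda c: quotas[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    rng = np.random.default_rng(seed)
    test_ids: list = []
    for c in classes:
        ids = np.asarray(table.index[groups == c])
        rng.shuffle(ids)
        test_ids.extend(ids[:counts[c]])
    test_set = set(test_ids)
    train_ids = [i for i in table.index if i not in test_set]
    return SplitSpec(tuple(train_ids), tuple(sorted(test_ids, key=test_ids.index)),
                     seed=seed)


def _xy(table: pd.DataFrame, feature_names=None):
    names = [c for c in table.columns if c != "group"] if feature_names is None \
        else list(feature_names)
    X = table[names].to_numpy(dtype=float)
    y = (table["group"] == GROUP_MDD).to_numpy(dtype=int)
    return X, y, names


def mi_rank_features(train_table: pd.DataFrame, seed: int = 0,
                     n_neighbors: int = 3,
                     split: SplitSpec | None = None) -> pd.DataFrame:
    """Rank features by mutual information with the diagnosis label.

    Uses the k-nearest-neighbour estimator for continuous-discrete pairs
    (k=3). When a :class:`SplitSpec` is supplied, the table is audited: any
    test subject present raises :class:`LeakageError`. Ties in the estimate
    are broken by feature index, so the ranking is deterministic under the
    seed. Returns a DataFrame with columns ``feature`` and ``mi`` in
    descending order.
    """
    if split is not None:
        leaked = set(train_table.index) & set(split.test_ids)
        if leaked:
            raise LeakageError(
                f"table passed to mi_rank_features contains "
                f"{len(leaked)} test subjects (e.g. {sorted(leaked)[:3]})")
    X, y, names = _xy(train_table)
    scores = mutual_info_classif(X, y, n_neighbors=n_neighbors,
                                 random_state=seed)
    order = np.argsort(-scores, kind="stable")
    return pd.DataFrame({"feature": [names[i] for i in order],
                         "mi": scores[order]})


def select_top_k(ranking: pd.DataFrame, k: int) -> list:
    """First ``k`` ranked feature names, order preserved."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds the {len(ranking)} ranked features")
    return list(ranking["feature"].iloc[:k])


def default_model_grids(gboost_backend: str = "xgboost") -> dict:
    """Estimator factories and hyperparameter grids for the six families.

    Grids are built around each family's typical operating point for
    tabular EEG features (e.g. shallow decision trees, RBF/linear SVMs,
    50-200 tree forests, boosted trees with learning rate 0.1-0.5, depth
    3-7 and split regularisation gamma 0-3). Scale-sensitive families (SVM,
    KNN) are wrapped with a standardizer fitted inside each CV fold; tree
    models and naive Bayes consume raw features.
    """
    def dt(seed):
        return DecisionTreeClassifier(random_state=seed)

    def svm(seed):
        return Pipeline([("scale", StandardScaler()),
                         ("clf", SVC(random_state=seed))])

    def rf(seed):
        return RandomForestClassifier(random_state=seed, n_jobs=1)

    def knn(seed):
        return Pipeline([("scale", StandardScaler()),
                         ("clf", KNeighborsClassifier())])

    if gboost_backend == "xgboost":
        from xgboost import XGBClassifier

        def gboost(seed):
            # 32 histogram bins lose nothing at ~100 training subjects and
            # keep the 54-point grid search fast on one core.
            return XGBClassifier(random_state=seed, n_jobs=1,
                                 tree_method="hist", max_bin=32,
                                 eval_metric="logloss")

        gboost_grid = {"learning_rate": [0.1, 0.3, 0.5],
                       "max_depth": [3, 5, 7],
                       "n_estimators": [50, 100],
                       "gamma": [0, 1, 3]}
    elif gboost_backend == "sklearn":
        def gboost(seed):
            return GradientBoostingClassifier(random_state=seed)

        gboost_grid = {"learning_rate": [0.1, 0.3, 0.5],
                       "max_depth": [3, 5, 7],
                       "n_estimators": [50, 100]}
    else:
        raise ValueError(f"unknown gboost backend {gboost_backend!r}")

    def nb(seed):
        return GaussianNB()

    return {
        "DT": (dt, {"criterion": ["gini"], "splitter": ["best", "random"],
                    "max_depth": [2, 3, 5, 10],
                    "min_samples_leaf": [1], "min_samples_split": [2]}),
        "SVM": (svm, {"clf__kernel": ["rbf", "linear"],
                      "clf__C": [0.1, 1.0, 10.0], "clf__gamma": ["scale"]}),
        "RF": (rf, {"n_estimators": [50, 100, 200], "criterion": ["gini"],
                    "min_samples_split": [10], "min_samples_leaf": [2]}),
        "KNN": (knn, {"clf__n_neighbors": [3, 5, 7, 11],
                      "clf__weights": ["uniform"], "clf__leaf_size": [30]}),
        "GBOOST": (gboost, gboost_grid),
        "NB": (nb, {}),
    }


def compact_model_grids(gboost_backend: str = "xgboost") -> dict:
    """Single-point grids at each family's typical best operating point.

    A desk-scale alternative to :func:`default_model_grids` for smoke runs
    where full tuning is not the question.
    """
    full = default_model_grids(gboost_backend)
    compact = {}
    best = {
        "DT": {"criterion": ["gini"], "splitter": ["random"], "max_depth": [2],
               "min_samples_leaf": [1], "min_samples_split": [2]},
        "SVM": {"clf__kernel": ["rbf"], "clf__C": [1.0], "clf__gamma": ["scale"]},
        "RF": {"n_estimators": [50], "criterion": ["gini"],
               "min_samples_split": [10], "min_samples_leaf": [2]},
        "KNN": {"clf__n_neighbors": [5], "clf__weights": ["uniform"],
                "clf__leaf_size": [30]},
        "GBOOST": {"learning_rate": [0.5], "n_estimators": [50],
                   "max_depth": [5], "gamma": [3]},
        "NB": {},
    }
    if gboost_backend == "sklearn":
        best["GBOOST"] = {k: v for k, v in best["GBOOST"].items() if k != "gamma"}
    for fam, (factory, _) in full.items():
        compact[fam] = (factory, best[fam])
    return compact


@dataclass
class TrainedModel:
    family: str
    best_params: dict
    cv_accuracy: float
    estimator: object
    feature_names: list


def grid_search_cv(family: str, train_table: pd.DataFrame,
                   feature_names=None, grid=None, folds: int = 10,
                   seed: int = 0, grids: dict | None = None) -> TrainedModel:
    """Tune one family by stratified k-fold CV accuracy and refit on the
    full training set. Ties between grid points go to the first in grid
    order."""
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    grids = grids or default_model_grids()
    factory, default_grid = grids[family]
    grid = grid if grid is not None else default_grid
    X, y, names = _xy(train_table, feature_names)
    minority = min(np.bincount(y))
    if folds > minority:
        raise ValueError(
            f"folds={folds} exceeds the minority-class count {minority}")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    est = factory(seed)
    if grid:
        search = GridSearchCV(est, grid, scoring="accuracy", cv=cv, n_jobs=1,
                              refit=True)
        search.fit(X, y)
        best_params = search.best_params_
        cv_acc = float(search.best_score_)
        fitted = search.best_estimator_
    else:
        from sklearn.model_selection import cross_val_score
        cv_acc = float(np.mean(cross_val_score(est, X, y, scoring="accuracy",
                                               cv=cv, n_jobs=1)))
        fitted = est.fit(X, y)
        best_params = {}
    return TrainedModel(family=family, best_params=dict(best_params),
                        cv_accuracy=cv_acc, estimator=fitted,
                        feature_names=names)


@dataclass
class CellResult:
    """Evaluation of one (family, feature set) cell on the test subjects."""

    family: str
    feature_set: str  # "full" or "reduced"
    tn: int
    fp: int
    fn: int
    tp: int
    accuracy: float
    f1: float
    cv_accuracy: float
    best_params: dict
    n_features: int

    def confusion(self) -> np.ndarray:
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def evaluate(model: TrainedModel, test_table: pd.DataFrame,
             feature_set: str = "full",
             split: SplitSpec | None = None) -> CellResult:
    """Confusion matrix, accuracy and binary F1 with MDD as positive class."""
    if split is not None:
        leaked = set(test_table.index) & set(split.train_ids)
        if leaked:
            raise LeakageError("test table contains training subjects")
    missing = [f for f in model.feature_names if f not in test_table.columns]
    if missing:
        raise ValueError(f"test table lacks feature columns: {missing[:3]}...")
    X, y, _ = _xy(test_table, model.feature_names)
    pred = np.asarray(model.estimator.predict(X), dtype=int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    acc = (tp + tn) / len(y)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return CellResult(family=model.family, feature_set=feature_set,
                      tn=tn, fp=fp, fn=fn, tp=tp,
                      accuracy=float(acc), f1=float(f1),
                      cv_accuracy=model.cv_accuracy,
                      best_params=model.best_params,
                      n_features=len(model.feature_names))


@dataclass
class EvaluationReport:
    """All (family x feature-set) results for one experiment."""

    cells: list = field(default_factory=list)
    split: SplitSpec | None = None
    ranking: pd.DataFrame | None = None
    selected_features: list = field(default_factory=list)
    errors: dict = field(default_factory=dict)
    seed: int = 0

    def cell(self, family: str, feature_set: str) -> CellResult:
        for c in self.cells:
            if c.family == family and c.feature_set == feature_set:
                return c
        raise KeyError((family, feature_set))

    def best(self) -> CellResult:
        return max(self.cells, key=lambda c: c.accuracy)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "train_ids": list(self.split.train_ids) if self.split else [],
            "test_ids": list(self.split.test_ids) if self.split else [],
            "selected_features": list(self.selected_features),
            "errors": {k: str(v) for k, v in self.errors.items()},
            "cells": [
                {"family": c.family, "feature_set": c.feature_set,
                 "confusion": {"tn": c.tn, "fp": c.fp, "fn": c.fn, "tp": c.tp},
                 "accuracy": round(c.accuracy, 2), "f1": round(c.f1, 2),
                 "accuracy_exact": c.accuracy, "f1_exact": c.f1,
                 "cv_accuracy": c.cv_accuracy,
                 "best_params": c.best_params, "n_features": c.n_features}
                for c in self.cells
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary_table(self) -> pd.DataFrame:
        """Accuracy/F1 per family for both feature sets, 2-decimal style."""
        rows = {}
        for c in self.cells:
            row = rows.setdefault(c.family, {})
            tag = "all" if c.feature_set == "full" else "selected"
            row[f"accuracy_{tag}"] = round(c.accuracy, 2)
            row[f"f1_{tag}"] = round(c.f1, 2)
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "model"
        return df.reindex([f for f in MODEL_FAMILIES if f in df.index])

    def plot_confusions(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fams = [f for f in MODEL_FAMILIES
                if any(c.family == f for c in self.cells)]
        sets = sorted({c.feature_set for c in self.cells})
        fig, axes = plt.subplots(len(sets), len(fams),
                                 figsize=(2.2 * len(fams), 2.4 * len(sets)),
                                 squeeze=False)
        for i, fs in enumerate(sets):
            for j, fam in enumerate(fams):
                ax = axes[i][j]
                try:
                    c = self.cell(fam, fs)
                except KeyError:
                    ax.axis("off")
                    continue
                m = c.confusion()
                ax.imshow(m, cmap="Blues", vmin=0)
                for (r, cc), v in np.ndenumerate(m):
                    ax.text(cc, r, str(v), ha="center", va="center")
                ax.set_title(f"{fam} ({fs})", fontsize=9)
                ax.set_xticks([0, 1], ["H", "MDD"], fontsize=7)
                ax.set_yticks([0, 1], ["H", "MDD"], fontsize=7)
                if j == 0:
                    ax.set_ylabel("true", fontsize=8)
                if i == len(sets) - 1:
                    ax.set_xlabel("predicted", fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)


def run_experiment(table: pd.DataFrame, seed: int = 0, k: int = 100,
                   test_size: int = 40, folds: int = 10,
                   grids: dict | None = None,
                   families=MODEL_FAMILIES) -> EvaluationReport:
    """Split, rank, tune and evaluate all families on both feature sets.

    Hyperparameters are tuned separately for the full and the reduced
    feature set. A failure in one (family, feature set) cell is recorded in
    ``report.errors`` without aborting the others.
    """
    split = stratified_subject_split(table, test_size=test_size, seed=seed)
    train = table.loc[list(split.train_ids)]
    test = table.loc[list(split.test_ids)]
    ranking = mi_rank_features(train, seed=seed, split=split)
    n_feat = len(ranking)
    selected = select_top_k(ranking, min(k, n_feat))
    report = EvaluationReport(split=split, ranking=ranking,
                              selected_features=selected, seed=seed)
    feature_sets = {"full": None, "reduced": selected}
    for family in families:
        for fs_name, feats in feature_sets.items():
            try:
                model = grid_search_cv(family, train, feature_names=feats,
                                       folds=folds, seed=seed, grids=grids)
                report.cells.append(
                    evaluate(model, test, feature_set=fs_name, split=split))
            except Exception as exc:  # per-cell isolation
                report.errors[f"{family}/{fs_name}"] = exc
    return report
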