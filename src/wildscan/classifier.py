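"""Binary-relevance random forests over stacked heterogeneous features.

The three feature blocks S1 (band statistics), S2 (bag-of-segments
histograms) and S3 (template correlations) are column-stacked into one
matrix S = [S1|S2|S3].  The multi-label target is a binary matrix whose
first column marks recordings void of animal vocalisations ("noise") and
whose remaining columns are acoustic classes (calls and songs of the same
species count as distinct classes).

An initial 80-tree forest provides out-of-bag permutation importances
used to select features once, shared across labels; the final model is
one 250-tree forest per label (one-vs-all, the binary-relevance
formulation), replicated over 10 random seeds, and predictions are the
arithmetic mean of the per-seed class probabilities.  Evaluation is
rank-based per-label ROC AUC.  A gradient-boosting detector trained on
the same features but only the noise column separates recordings with
animal vocalisations from purely abiotic ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import classification_report, roc_auc_score
from sklearn.model_selection import GridSearchCV

__all__ = [
    "ForestParams",
    "StackedFeatures",
    "MultiLabelForest",
    "make_label_matrix",
    "stack_features",
    "select_features_oob",
    "train",
    "predict",
    "evaluate_auc",
    "tune_forest",
    "train_void_detector",
    "void_detector_report",
]


@dataclass(frozen=True)
class ForestParams:
    """Final-forest hyperparameters (grid-search-tuned defaults)."""

    n_trees: int = 250
    criterion: str = "entropy"
    min_samples_split: int = 4
    min_samples_leaf: int = 3


@dataclass
class StackedFeatures:
    """Feature matrix with per-column provenance tags (block:name)."""

    values: np.ndarray
    tags: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.tags):
            raise ValueError("values/tags shape mismatch")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def block_of(self, column: int) -> str:
        return self.tags[column].split(":", 1)[0]

    def subset(self, columns: np.ndarray) -> "StackedFeatures":
        return StackedFeatures(
            self.values[:, columns], [self.tags[c] for c in columns]
        )


def make_label_matrix(
    annotations: dict[str, list[str]], class_names: list[str]
) -> pd.DataFrame:
    """Binary recordings x (noise + classes) matrix from per-recording tags.

    The leading "noise" column is 1 iff a recording carries no class at
    all; a noise recording therefore has an all-zero class row.
    """
    rows = {}
    for rec_id, present in annotations.items():
        unknown = set(present) - set(class_names)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)} for {rec_id}")
        row = [1 if not present else 0] + [
            1 if name in present else 0 for name in class_names
        ]
        rows[rec_id] = row
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["noise"] + list(class_names)
    ).sort_index()


def stack_features(*blocks: StackedFeatures) -> StackedFeatures:
    """Column-stack feature blocks, keeping provenance tags."""
    if not blocks:
        raise ValueError("no blocks to stack")
    n_rows = {b.values.shape[0] for b in blocks}
    if len(n_rows) != 1:
        raise ValueError(f"row counts differ across blocks: {sorted(n_rows)}")
    return StackedFeatures(
        np.hstack([b.values for b in blocks]),
        [t for b in blocks for t in b.tags],
    )


def _tree_bootstrap_oob(tree, n_samples: int) -> np.ndarray:
    """Indices left out of one tree's bootstrap sample.

    Reconstructs the forest's bootstrap draw from the tree's integer seed
    (same RNG recipe scikit-learn uses internally).
    """
    rng = np.random.RandomState(tree.random_state)
    sampled = rng.randint(0, n_samples, n_samples)
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return np.nonzero(mask)[0]


def oob_permutation_importance(
    forest: RandomForestClassifier, X: np.ndarray, Y: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Breiman-style OOB permutation importance, one value per feature.

    For each tree, accuracy on its out-of-bag samples is compared with the
    accuracy after permuting one feature among those samples; the
    importance is the mean accuracy drop over trees.  Features a tree
    never splits on are skipped for that tree (their drop is exactly 0).
    """
    rng = np.random.default_rng(seed)
    n_samples, n_features = X.shape
    Y2 = Y if Y.ndim == 2 else Y[:, None]
    importances = np.zeros(n_features)
    for tree in forest.estimators_:
        oob = _tree_bootstrap_oob(tree, n_samples)
        if oob.size == 0:
            continue
        X_oob = X[oob]
        pred = np.asarray(tree.predict(X_oob)).reshape(len(oob), -1)
        base_acc = float((pred == Y2[oob]).mean())
        used = np.unique(tree.tree_.feature)
        for j in used[used >= 0]:
            X_perm = X_oob.copy()
            X_perm[:, j] = X_perm[rng.permutation(len(oob)), j]
            pred_j = np.asarray(tree.predict(X_perm)).reshape(len(oob), -1)
            importances[j] += base_acc - float((pred_j == Y2[oob]).mean())
    return importances / len(forest.estimators_)


def select_features_oob(
    S: StackedFeatures,
    Y: pd.DataFrame | np.ndarray,
    n_trees: int = 80,
    threshold: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Indices of features whose OOB permutation importance exceeds threshold.

    One multi-output forest serves all labels, so the selection is done
    once and shared; spurious features (e.g. correlations against noise
    ROIs) carry no descriptive power and are discarded here.
    """
    Ym = np.asarray(Y)
    # exhaustive split search: trees then only ever use genuinely useful
    # features, so spurious columns score an importance of exactly zero
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="entropy",
        max_features=None,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(S.values, Ym)
    imp = oob_permutation_importance(forest, S.values, Ym, seed=seed)
    selected = np.nonzero(imp > threshold)[0]
    if selected.size == 0:
        raise ValueError(
            "feature selection removed every feature; lower the threshold"
        )
    return selected


@dataclass
class MultiLabelForest:
    """Per-label forests replicated over seeds, plus the shared selection."""

    label_names: list[str]
    seeds: list[int]
    params: ForestParams
    selected: np.ndarray
    forests: dict = field(default_factory=dict)  # label -> list of fitted forests
    constant: dict = field(default_factory=dict)  # label -> prevalence
    n_features_in: int = 0


def train(
    S: StackedFeatures,
    Y: pd.DataFrame,
    params: ForestParams | None = None,
    seeds: list[int] | None = None,
    selected: np.ndarray | None = None,
) -> MultiLabelForest:
    """Fit one binary one-vs-all forest per label per seed.

    Labels with fewer than 2 positive or 2 negative examples cannot grow a
    meaningful forest and fall back to constant-prevalence predictors.
    """
    params = params or ForestParams()
    seeds = list(seeds) if seeds is not None else list(range(10))
    if Y.shape[1] == 0:
        raise ValueError("empty label set")
    if selected is None:
        selected = np.arange(S.n_features)
    X = S.values[:, selected]
    model = MultiLabelForest(
        label_names=list(Y.columns),
        seeds=seeds,
        params=params,
        selected=np.asarray(selected),
        n_features_in=S.n_features,
    )
    for name in Y.columns:
        y = Y[name].to_numpy()
        if y.sum() < 2 or (1 - y).sum() < 2:
            model.constant[name] = float(y.mean())
            continue
        model.forests[name] = [
            RandomForestClassifier(
                n_estimators=params.n_trees,
                criterion=params.criterion,
                min_samples_split=params.min_samples_split,
                min_samples_leaf=params.min_samples_leaf,
                random_state=s,
                n_jobs=1,
            ).fit(X, y)
            for s in seeds
        ]
    return model


def predict(
    model: MultiLabelForest, T: StackedFeatures, *, include_noise: bool = False
) -> pd.DataFrame:
    """Seed-averaged per-label probabilities for new recordings.

    The noise column is dropped from the returned matrix by default (the
    0 class is deleted at recognition time); pass ``include_noise=True``
    to keep it.
    """
    if T.n_features != model.n_features_in:
        raise ValueError(
            f"feature count {T.n_features} != training count {model.n_features_in}"
        )
    X = T.values[:, model.selected]
    cols = {}
    for name in model.label_names:
        if name in model.constant:
            cols[name] = np.full(X.shape[0], model.constant[name])
        else:
            probs = [
                f.predict_proba(X)[:, list(f.classes_).index(1)]
                for f in model.forests[name]
            ]
            cols[name] = np.mean(probs, axis=0)
    out = pd.DataFrame(cols)
    if not include_noise and out.columns[0] == "noise":
        out = out.drop(columns="noise")
    return out


def evaluate_auc(
    pred: pd.DataFrame, truth: pd.DataFrame
) -> tuple[dict[str, float], float]:
    """Per-label ROC AUC and their macro average.

    Labels with a single class in the truth are not evaluable and are
    skipped (reported as NaN).
    """
    per_label: dict[str, float] = {}
    for name in pred.columns:
        y = truth[name].to_numpy()
        if y.min() == y.max():
            per_label[name] = float("nan")
            continue
        per_label[name] = float(roc_auc_score(y, pred[name].to_numpy()))
    evaluable = [v for v in per_label.values() if v == v]
    if not evaluable:
        raise ValueError("no evaluable label: every label is single-class")
    return per_label, float(np.mean(evaluable))


def tune_forest(
    X: np.ndarray,
    y: np.ndarray,
    param_grid: dict | None = None,
    cv: int = 10,
    seed: int = 0,
) -> dict:
    """Grid-search a binary forest with seeded k-fold CV; returns best params.

    Provided for completeness — the package defaults are already the
    tuned values (250 trees, entropy, min_samples_split=4,
    min_samples_leaf=3).
    """
    param_grid = param_grid or {
        "min_samples_split": [2, 4, 8],
        "min_samples_leaf": [1, 3, 5],
    }
    search = GridSearchCV(
        RandomForestClassifier(
            n_estimators=250, criterion="entropy", random_state=seed
        ),
        param_grid,
        cv=min(cv, int(np.bincount(y).min())),
        scoring="roc_auc",
    )
    search.fit(X, y)
    return search.best_params_


def train_void_detector(
    S: StackedFeatures, Y: pd.DataFrame, seed: int = 0, *, use_boosting: bool = True
):
    """Binary detector: animal vocalisation present vs abiotic-only.

    Uses the same stacked features as species classification but only the
    noise column of the labels; the positive class is "animal present"
    (the negation of the noise flag).  Gradient boosting by default, with
    a random-forest fallback.
    """
    y = 1 - Y["noise"].to_numpy()
    if y.min() == y.max():
        raise ValueError("void detector needs both classes in training data")
    if use_boosting:
        clf = GradientBoostingClassifier(random_state=seed)
    else:
        clf = RandomForestClassifier(
            n_estimators=250, criterion="entropy", random_state=seed
        )
    return clf.fit(S.values, y)


def void_detector_report(detector, S: StackedFeatures, Y: pd.DataFrame) -> dict:
    """precision / recall / f-score / support per class on held-out data."""
    y = 1 - Y["noise"].to_numpy()
    pred = detector.predict(S.values)
    return classification_report(
        y,
        pred,
        labels=[1, 0],
        target_names=["animal_vocalization", "abiotic_sounds"],
        output_dict=True,
        zero_division=0,
    )
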