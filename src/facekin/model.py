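"""AdaBoost-over-Random-Forest classification under Monte Carlo CV.

The classifier is a discrete (SAMME) AdaBoost ensemble,
``G(x) = sign(sum_m alpha_m G_m(x))``, whose weak learners ``G_m`` are
small Random Forests (5 stumps, log2 feature subsampling by default).
Evaluation uses leave-group-out / Monte Carlo cross-validation: repeated
stratified 70/30 train-test partitions, with the below-Q1 feature
references, missing-cell imputation, interaction generation and feature
selection all re-fit on the training rows of each split — no test-row
information ever reaches the fit (the mutation tests assert this).

Per split five metrics are computed (F1, specificity, sensitivity,
balanced accuracy = (sensitivity + specificity)/2, ROC-AUC) and summarised
as mean/SD/max/min across splits; ROC curves are vertically averaged on a
fixed 101-point FPR grid.  Permutation feature importance is the mean F1
drop after within-column permutation of held-out rows, summed across
splits.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from .features import FeatureTable, impute_with_medians
from .io import ARMS, CohortLabels, IntegrityError
from .selection import (
    SelectionConfig,
    apply_recipe,
    select_features,
    selection_recipe,
)

METRICS = ("f1", "specificity", "sensitivity", "balanced_accuracy", "roc_auc")

FPR_GRID = np.linspace(0.0, 1.0, 101)


class FitError(RuntimeError):
    """The ensemble could not be fit on the given training data."""


@dataclasses.dataclass
class EnsembleConfig:
    """AdaBoost-over-Random-Forest hyperparameters.

    Defaults follow the reference configuration: 900 boosting estimators
    with learning rate 2 (unusually large, but kept as the documented
    default), each weak learner a 5-tree depth-1 Random Forest with log2
    feature subsampling.
    """

    n_estimators: int = 900
    learning_rate: float = 2.0
    rf_trees: int = 5
    rf_max_depth: int = 1
    rf_max_features: str | int | float = "log2"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_estimators, self.rf_trees, self.rf_max_depth) < 1:
            raise ValueError("all counts must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclasses.dataclass
class FittedEnsemble:
    """A fitted boosted ensemble with its training-split feature state.

    ``model.estimators_`` are the weak learners G_m and
    ``model.estimator_weights_`` the boosting weights alpha_m.  The stored
    recipe/references let held-out rows be transformed exactly as the
    training rows were.
    """

    model: AdaBoostClassifier
    recipe: Mapping[str, Mapping[str, str]]
    feature_names: tuple[str, ...]
    ear_q1: float = np.nan
    mar_q1: float = np.nan
    medians: pd.Series | None = None

    @property
    def weak_learners(self) -> list:
        return list(self.model.estimators_)

    @property
    def weights(self) -> np.ndarray:
        w = np.asarray(self.model.estimator_weights_[: len(self.model.estimators_)])
        return w


def _as_binary(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "biu":
        return y.astype(int)
    return (y == ARMS).astype(int)


def fit_adaboost_rf(
    train_table: pd.DataFrame,
    labels: Sequence,
    config: EnsembleConfig | None = None,
) -> FittedEnsemble:
    """Fit the AdaBoost ensemble on an already-selected training matrix.

    Uses the discrete SAMME reweighting (training weights multiplied by
    exp(+alpha) on misclassified and exp(-alpha) on correctly classified
    samples).  Deterministic given the seed.
    """
    config = config or EnsembleConfig()
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit")
    X = train_table.to_numpy(dtype=float)
    if len(np.unique(X, axis=0)) == 1:
        raise FitError("all training rows are identical; nothing to learn")
    base = RandomForestClassifier(
        n_estimators=config.rf_trees,
        max_depth=config.rf_max_depth,
        max_features=config.rf_max_features,
    )
    model = AdaBoostClassifier(
        estimator=base,
        n_estimators=config.n_estimators,
        learning_rate=config.learning_rate,
        random_state=config.seed,
    )
    model.fit(X, y)
    names = tuple(train_table.columns)
    return FittedEnsemble(
        model=model, recipe=selection_recipe(names), feature_names=names
    )


def _base_frame(ensemble: FittedEnsemble, table) -> pd.DataFrame:
    """Base-feature matrix of ``table`` under the ensemble's stored
    references and training medians."""
    if isinstance(table, FeatureTable):
        if table.raw is not None and np.isfinite(ensemble.ear_q1):
            base = table.raw.table_with_reference(ensemble.ear_q1, ensemble.mar_q1)
            base = base.loc[table.data.index]
        else:
            base = table.data
    else:
        base = table
    if ensemble.medians is not None:
        base, _ = impute_with_medians(base, ensemble.medians)
    return base


def predict_scores(ensemble: FittedEnsemble, table) -> np.ndarray:
    """Per-participant probability-like score in [0, 1] for the ARMS class.

    ``table`` may be a :class:`FeatureTable`, a base-feature DataFrame or
    an already-transformed matrix with the model's feature columns.
    """
    if isinstance(table, pd.DataFrame) and list(table.columns) == list(
        ensemble.feature_names
    ):
        X = table
    else:
        try:
            X = apply_recipe(_base_frame(ensemble, table), ensemble.recipe)
        except KeyError as exc:
            raise IntegrityError(f"cannot resolve model features: {exc}") from exc
    return ensemble.model.predict_proba(X.to_numpy(dtype=float))[:, 1]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def compute_metrics(
    true_labels: Sequence, scores: Sequence[float], threshold: float = 0.5
) -> dict[str, float]:
    """The five evaluation metrics; positive class = ARMS.

    AUC uses the trapezoidal rank method; balanced accuracy is exactly
    (sensitivity + specificity)/2.  With single-class truth the AUC is NaN
    and the metrics with empty denominators are NaN.
    """
    y = _as_binary(true_labels)
    s = np.asarray(scores, dtype=float)
    pred = (s > threshold).astype(int)
    tp = int(np.sum((y == 1) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    prec = tp / (tp + fp) if (tp + fp) else np.nan
    if np.isnan(sens) or np.isnan(prec) or (prec + sens) == 0:
        f1 = 0.0 if (tp + fn) else np.nan
    else:
        f1 = 2 * prec * sens / (prec + sens)
    auc = roc_auc_score(y, s) if len(np.unique(y)) == 2 else np.nan
    return {
        "f1": f1,
        "specificity": spec,
        "sensitivity": sens,
        "balanced_accuracy": (sens + spec) / 2.0,
        "roc_auc": float(auc) if not np.isnan(auc) else np.nan,
    }


def mean_roc_curve(
    per_split_curves: Sequence[tuple[np.ndarray, np.ndarray]],
    grid: np.ndarray = FPR_GRID,
) -> pd.DataFrame:
    """Vertical averaging of ROC curves on a fixed FPR grid.

    Returns columns fpr, mean_tpr, sd_tpr; the mean curve passes through
    (0, 0) and (1, 1).
    """
    if len(per_split_curves) == 0:
        raise ValueError("need at least one curve")
    tprs = []
    for fpr, tpr in per_split_curves:
        interp = np.interp(grid, fpr, tpr)
        interp[0] = 0.0
        interp[-1] = 1.0
        tprs.append(interp)
    stack = np.vstack(tprs)
    return pd.DataFrame(
        {"fpr": grid, "mean_tpr": stack.mean(axis=0), "sd_tpr": stack.std(axis=0)}
    )


# ---------------------------------------------------------------------------
# permutation feature importance
# ---------------------------------------------------------------------------


def permutation_importance(
    ensemble: FittedEnsemble,
    test_table,
    labels: Sequence,
    n_repeats: int = 100,
    seed: int = 0,
    threshold: float = 0.5,
) -> pd.Series:
    """Mean F1 drop after within-column permutation of held-out rows.

    Computed per model feature (products included); deterministic given
    the seed.  Across CV splits these per-split importances are summed.
    """
    if isinstance(test_table, pd.DataFrame) and list(test_table.columns) == list(
        ensemble.feature_names
    ):
        X = test_table.copy()
    else:
        X = apply_recipe(_base_frame(ensemble, test_table), ensemble.recipe)
    y = _as_binary(labels)
    if len(X) < 2:
        raise ValueError("need at least 2 test rows")
    rng = np.random.default_rng(seed)
    base_f1 = compute_metrics(y, predict_scores(ensemble, X), threshold)["f1"]
    drops = pd.Series(0.0, index=list(ensemble.feature_names))
    for name in ensemble.feature_names:
        saved = X[name].to_numpy().copy()
        total = 0.0
        for _ in range(n_repeats):
            X[name] = rng.permutation(saved)
            perm_f1 = compute_metrics(y, predict_scores(ensemble, X), threshold)["f1"]
            total += base_f1 - perm_f1
        X[name] = saved
        drops[name] = total / n_repeats
    return drops


# ---------------------------------------------------------------------------
# Monte Carlo cross-validation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MetricsSummary:
    """Mean/SD/max/min of the five metrics over splits + averaged ROC."""

    summary: pd.DataFrame  # index: metric, columns: mean, sd, max, min
    per_split: pd.DataFrame  # one row per split
    roc: pd.DataFrame  # fpr, mean_tpr, sd_tpr
    importance: pd.Series | None = None  # summed F1 drops per feature
    selected_features: list[list[str]] | None = None

    def __post_init__(self) -> None:
        s = self.summary
        if not ((s["max"] + 1e-12 >= s["mean"]) & (s["mean"] >= s["min"] - 1e-12)).all():
            raise ValueError("metric summary must satisfy max >= mean >= min")


def _split_seed(master_seed: int, split: int, salt: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), int(split), int(salt)])


def stratified_split(
    groups: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class floor(train_frac * n_class) training sample; returns
    boolean masks (train, test)."""
    train = np.zeros(len(groups), dtype=bool)
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        n_train = int(np.floor(train_frac * len(idx)))
        if n_train < 1 or n_train >= len(idx):
            raise ValueError(f"class '{g}' too small to stratify at {train_frac}")
        train[rng.permutation(idx)[:n_train]] = True
    return train, ~train


def monte_carlo_cv(
    table: FeatureTable,
    labels: CohortLabels | Sequence,
    n_splits: int = 100,
    train_frac: float = 0.7,
    selection_config: SelectionConfig | None = None,
    ensemble_config: EnsembleConfig | None = None,
    seed: int = 0,
    *,
    selection_mode: str = "per-split",
    compute_importance: bool = False,
    importance_repeats: int = 10,
    threshold: float = 0.5,
) -> MetricsSummary:
    """Repeated stratified 70/30 evaluation of the full modelling chain.

    For every split the below-Q1 references, imputation medians,
    interaction/selection stage and the AdaBoost fit are all recomputed on
    the training rows only.  ``selection_mode='global'`` instead selects
    once on the full table before splitting (a deliberately leaky variant
    kept for comparison).  Deterministic given the master seed.
    """
    selection_config = selection_config or SelectionConfig()
    ensemble_config = ensemble_config or EnsembleConfig()
    ids = table.participant_ids
    groups = labels.groups(ids) if isinstance(labels, CohortLabels) else np.asarray(labels)
    if min(np.bincount(_as_binary(groups))) < 2:
        raise ValueError("need at least 2 participants per class")

    global_selection: list[str] | None = None
    if selection_mode == "global":
        cfg = dataclasses.replace(selection_config, seed=seed)
        global_selection = select_features(table.data, groups, cfg)
    elif selection_mode != "per-split":
        raise ValueError("selection_mode must be 'per-split' or 'global'")

    rows = []
    curves = []
    importance_sum: pd.Series | None = None
    selected_sets: list[list[str]] = []
    for split in range(n_splits):
        rng = np.random.default_rng(_split_seed(seed, split))
        train, test = stratified_split(groups, train_frac, rng)
        train_ids = [i for i, m in zip(ids, train) if m]

        if table.raw is not None:
            ear_q1, mar_q1 = table.raw.pooled_q1(train_ids)
            base = table.raw.table_with_reference(ear_q1, mar_q1).loc[ids]
        else:
            ear_q1 = mar_q1 = np.nan
            base = table.data
        base_train, medians = impute_with_medians(base[train])
        base_test, _ = impute_with_medians(base[test], medians)

        if global_selection is not None:
            selected = global_selection
        else:
            cfg = dataclasses.replace(
                selection_config, seed=int(rng.integers(2**31))
            )
            selected = select_features(base_train, groups[train], cfg)
        selected_sets.append(list(selected))
        recipe = selection_recipe(selected)
        X_train = apply_recipe(base_train, recipe)
        X_test = apply_recipe(base_test, recipe)

        ens_cfg = dataclasses.replace(ensemble_config, seed=int(rng.integers(2**31)))
        ensemble = fit_adaboost_rf(X_train, groups[train], ens_cfg)
        ensemble.ear_q1, ensemble.mar_q1 = ear_q1, mar_q1
        ensemble.medians = medians

        scores = predict_scores(ensemble, X_test)
        y_test = _as_binary(groups[test])
        rows.append(compute_metrics(y_test, scores, threshold))
        if len(np.unique(y_test)) == 2:
            fpr, tpr, _ = roc_curve(y_test, scores)
            curves.append((fpr, tpr))
        if compute_importance:
            imp = permutation_importance(
                ensemble,
                X_test,
                y_test,
                n_repeats=importance_repeats,
                seed=int(rng.integers(2**31)),
                threshold=threshold,
            )
            importance_sum = (
                imp if importance_sum is None else importance_sum.add(imp, fill_value=0.0)
            )

    per_split = pd.DataFrame(rows)
    per_split.index.name = "split"
    summary = pd.DataFrame(
        {
            "mean": per_split.mean(),
            "sd": per_split.std(ddof=1),
            "max": per_split.max(),
            "min": per_split.min(),
        }
    ).loc[list(METRICS)]
    if importance_sum is not None:
        importance_sum = importance_sum.sort_values(ascending=False)
    return MetricsSummary(
        summary=summary,
        per_split=per_split,
        roc=mean_roc_curve(curves),
        importance=importance_sum,
        selected_features=selected_sets,
    )
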