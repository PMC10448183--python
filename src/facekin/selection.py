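"""Pairwise feature interactions and gradient-boosting feature selection.

The working feature set is chosen in three stages, always on training rows
only:

1. rank the base features with a gradient-boosted tree ensemble
   (LightGBM) and keep the top *m*;
2. append the m(m-1)/2 pairwise products of the survivors, named
   ``"{a} * {b}"``;
3. re-rank the combined set and keep the top *k* names.

Base features may survive without entering any product.  Importance is the
booster's "gain" (average information gain of the splits using the
feature) or "split" (number of splits using it); ties are broken by column
order so selection is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier

from .io import ARMS


@dataclasses.dataclass
class SelectionConfig:
    """Settings of the two ranking passes and the interaction stage."""

    stage1_top_m: int = 40
    final_top_k: int = 30
    importance_type: str = "gain"  # or "split"
    booster_rounds: int = 100
    booster_learning_rate: float = 0.1
    seed: int = 0
    #: optional bootstrap stability filter: minimum fraction of bootstrap
    #: reselections a feature needs to be kept (None = off)
    stability_fraction: float | None = None
    n_bootstrap: int = 20

    def __post_init__(self) -> None:
        max_k = self.stage1_top_m + self.stage1_top_m * (self.stage1_top_m - 1) // 2
        if not 1 <= self.final_top_k <= max_k:
            raise ValueError("final_top_k must lie in [1, m + m(m-1)/2]")
        if self.importance_type not in ("gain", "split"):
            raise ValueError("importance_type must be 'gain' or 'split'")


def _as_binary(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "biu":
        y = y.astype(int)
    else:
        y = (y == ARMS).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for selection")
    return y


def generate_interactions(
    table: pd.DataFrame, candidate_names: Sequence[str]
) -> pd.DataFrame:
    """Append the elementwise product of every unordered pair of candidates.

    Product columns are named ``"{a} * {b}"``; original columns are kept.
    """
    missing = [c for c in candidate_names if c not in table.columns]
    if missing:
        raise KeyError(f"candidate feature(s) not in table: {missing}")
    products = {
        f"{a} * {b}": table[a].to_numpy() * table[b].to_numpy()
        for a, b in itertools.combinations(candidate_names, 2)
    }
    if not products:
        return table.copy()
    return pd.concat([table, pd.DataFrame(products, index=table.index)], axis=1)


def gbm_rank_features(
    table: pd.DataFrame, labels: Sequence, config: SelectionConfig | None = None
) -> list[tuple[str, float]]:
    """Rank features by gradient-boosting importance, descending.

    Ties are broken by column order, so the ranking is a pure function of
    (rows, labels, config, seed).
    """
    config = config or SelectionConfig()
    y = _as_binary(labels)
    clf = LGBMClassifier(
        n_estimators=config.booster_rounds,
        learning_rate=config.booster_learning_rate,
        num_leaves=7,
        min_child_samples=5,
        random_state=config.seed,
        deterministic=True,
        force_col_wise=True,
        n_jobs=1,
        verbosity=-1,
    )
    clf.fit(table.to_numpy(), y, feature_name=[f"f{i}" for i in range(table.shape[1])])
    imp = clf.booster_.feature_importance(importance_type=config.importance_type)
    imp = np.asarray(imp, dtype=float)
    order = np.lexsort((np.arange(len(imp)), -imp))  # stable: importance, then position
    return [(table.columns[i], float(imp[i])) for i in order]


def select_features(
    train_table: pd.DataFrame,
    labels: Sequence,
    config: SelectionConfig | None = None,
) -> list[str]:
    """Three-stage interaction/selection procedure (training rows only)."""
    config = config or SelectionConfig()
    ranked = gbm_rank_features(train_table, labels, config)
    top_m = [name for name, _ in ranked[: config.stage1_top_m]]
    widened = generate_interactions(train_table[top_m], top_m)
    reranked = gbm_rank_features(widened, labels, config)
    selected = [name for name, _ in reranked[: config.final_top_k]]
    if config.stability_fraction:
        selected = _stability_filter(widened, labels, selected, config)
    return selected


def _stability_filter(
    widened: pd.DataFrame,
    labels: Sequence,
    selected: list[str],
    config: SelectionConfig,
) -> list[str]:
    """Drop features reselected in fewer than ``stability_fraction`` of
    bootstrap resamples of the training split (out-of-bootstrap style)."""
    y = _as_binary(labels)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    counts = {name: 0 for name in selected}
    done = 0
    for _ in range(config.n_bootstrap):
        idx = rng.integers(0, len(widened), size=len(widened))
        if len(np.unique(y[idx])) < 2:
            continue
        boot_cfg = dataclasses.replace(
            config, stability_fraction=None, seed=int(rng.integers(2**31))
        )
        ranked = gbm_rank_features(widened.iloc[idx], y[idx], boot_cfg)
        keep = {name for name, _ in ranked[: config.final_top_k]}
        for name in selected:
            counts[name] += name in keep
        done += 1
    if done == 0:
        return selected
    kept = [n for n in selected if counts[n] / done >= config.stability_fraction]
    return kept or selected


# ---------------------------------------------------------------------------
# selection recipe (re-creating selected columns on new rows)
# ---------------------------------------------------------------------------


def selection_recipe(selected: Sequence[str]) -> dict[str, Mapping[str, str]]:
    """JSON-serialisable recipe mapping each selected name to its
    construction (base column or product of two base columns)."""
    recipe: dict[str, Mapping[str, str]] = {}
    for name in selected:
        if " * " in name:
            a, b = name.split(" * ", 1)
            recipe[name] = {"kind": "product", "a": a, "b": b}
        else:
            recipe[name] = {"kind": "base", "column": name}
    return recipe


def apply_recipe(
    table: pd.DataFrame, recipe: Mapping[str, Mapping[str, str]]
) -> pd.DataFrame:
    """Materialise the selected columns on any table of base features."""
    cols: dict[str, np.ndarray] = {}
    for name, spec in recipe.items():
        if spec["kind"] == "base":
            if spec["column"] not in table.columns:
                raise KeyError(f"base feature '{spec['column']}' not in table")
            cols[name] = table[spec["column"]].to_numpy()
        else:
            for key in ("a", "b"):
                if spec[key] not in table.columns:
                    raise KeyError(f"base feature '{spec[key]}' not in table")
            cols[name] = table[spec["a"]].to_numpy() * table[spec["b"]].to_numpy()
    return pd.DataFrame(cols, index=table.index)
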