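"""End-to-end orchestration: extract -> cross-validate -> validity report.

A single :class:`RunConfig` (loadable from YAML) drives the whole chain
with one master seed that fans out deterministically to every stochastic
stage, so a recorded config reproduces a run bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .features import FeatureManifest, build_feature_table, default_manifest
from .io import CohortLabels, LandmarkTrajectory, read_labels_csv, read_landmark_csv
from .model import EnsembleConfig, MetricsSummary, monte_carlo_cv
from .selection import SelectionConfig
from .simulate import CohortSpec, generate_cohort
from .validity import convergent_validity_table

logger = logging.getLogger("facekin")


@dataclasses.dataclass
class RunConfig:
    """Everything one full analysis run needs."""

    cohort_dir: str | None = None  # directory of landmark CSVs + labels.csv
    simulate: CohortSpec | None = None  # generate instead of reading
    manifest_path: str | None = None  # default 649-feature manifest if unset
    out_dir: str | None = None
    selection: SelectionConfig = dataclasses.field(default_factory=SelectionConfig)
    ensemble: EnsembleConfig = dataclasses.field(default_factory=EnsembleConfig)
    n_splits: int = 100
    train_frac: float = 0.7
    seed: int = 0
    selection_mode: str = "per-split"
    compute_importance: bool = True
    importance_repeats: int = 5
    validity_items: tuple[str, ...] = ("N2", "N3")
    fps: float = 10.0
    image_size: tuple[int, int] | None = (640, 480)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = CohortSpec(**raw["simulate"])
        if "selection" in raw:
            raw["selection"] = SelectionConfig(**raw["selection"])
        if "ensemble" in raw:
            raw["ensemble"] = EnsembleConfig(**raw["ensemble"])
        if "image_size" in raw and raw["image_size"] is not None:
            raw["image_size"] = tuple(raw["image_size"])
        if "validity_items" in raw:
            raw["validity_items"] = tuple(raw["validity_items"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_cohort(
    cohort_dir: str | Path, fps: float = 10.0, image_size=None
) -> tuple[list[LandmarkTrajectory], CohortLabels]:
    """Read every per-participant landmark CSV plus labels.csv."""
    cohort_dir = Path(cohort_dir)
    labels = read_labels_csv(cohort_dir / "labels.csv")
    trajectories = []
    for pid in labels.participant_ids:
        trajectories.append(
            read_landmark_csv(
                cohort_dir / f"{pid}.csv",
                fps=fps,
                participant_id=pid,
                image_size=image_size,
            )
        )
    return trajectories, labels


def _stage(name: str, start: float) -> None:
    logger.info("%-18s %.1fs", name, time.perf_counter() - start)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full chain and (optionally) write the report bundle.

    Returns a dict with the feature table, metrics summary, per-split
    metrics, averaged ROC, summed permutation importance, the
    convergent-validity table and a provenance record.
    """
    t0 = time.perf_counter()
    if config.simulate is not None:
        trajectories, labels = generate_cohort(config.simulate)
    elif config.cohort_dir:
        trajectories, labels = load_cohort(
            config.cohort_dir, fps=config.fps, image_size=config.image_size
        )
    else:
        raise ValueError("config needs either 'simulate' or 'cohort_dir'")
    _stage("cohort", t0)

    manifest = (
        FeatureManifest.load_csv(config.manifest_path)
        if config.manifest_path
        else default_manifest()
    )
    t1 = time.perf_counter()
    table = build_feature_table(trajectories, labels, manifest)
    _stage("features", t1)

    t2 = time.perf_counter()
    result: MetricsSummary = monte_carlo_cv(
        table,
        labels,
        n_splits=config.n_splits,
        train_frac=config.train_frac,
        selection_config=config.selection,
        ensemble_config=config.ensemble,
        seed=config.seed,
        selection_mode=config.selection_mode,
        compute_importance=config.compute_importance,
        importance_repeats=config.importance_repeats,
    )
    _stage("cross-validation", t2)

    t3 = time.perf_counter()
    items = [i for i in config.validity_items if i in labels.table.columns]
    if result.importance is not None and len(result.importance):
        top = result.importance.index[: min(10, len(result.importance))]
        model_features = [f for f in top]
    else:
        model_features = manifest.names[:10]
    base_or_product = pd.DataFrame(index=table.data.index)
    for name in model_features:
        if " * " in name:
            a, b = name.split(" * ", 1)
            base_or_product[name] = table.data[a] * table.data[b]
        else:
            base_or_product[name] = table.data[name]
    validity = (
        convergent_validity_table(
            base_or_product, labels.table[items], items=items
        )
        if items
        else pd.DataFrame()
    )
    _stage("validity", t3)

    provenance = {
        "facekin_version": __version__,
        "config": config.to_dict(),
        "n_participants": len(table.participant_ids),
        "n_features": len(manifest),
        "seed": config.seed,
    }
    outputs = {
        "table": table,
        "selected_features": result.selected_features,
        "summary": result.summary,
        "per_split": result.per_split,
        "roc": result.roc,
        "importance": result.importance,
        "validity": validity,
        "provenance": provenance,
    }
    if config.out_dir:
        write_report(outputs, config.out_dir)
    return outputs


def write_report(outputs: dict[str, Any], out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs["summary"].rename_axis("metric").to_csv(out_dir / "metrics_summary.csv")
    outputs["per_split"].to_csv(out_dir / "metrics_per_split.csv")
    outputs["roc"].to_csv(out_dir / "roc_mean.csv", index=False)
    if outputs.get("importance") is not None:
        outputs["importance"].rename("summed_f1_drop").rename_axis("feature").to_csv(
            out_dir / "importance.csv"
        )
    if outputs.get("validity") is not None and len(outputs["validity"]):
        outputs["validity"].to_csv(out_dir / "validity.csv", index=False)
    if outputs.get("selected_features"):
        from .selection import selection_recipe

        recipes = [selection_recipe(s) for s in outputs["selected_features"]]
        with open(out_dir / "selected_features.json", "w") as fh:
            json.dump(recipes, fh, indent=2)
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(outputs["provenance"], fh, indent=2, default=str)
    return out_dir


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
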