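"""End-to-end orchestration of the FGS score-prediction experiments.

``run_phase2`` reproduces the experimental grid of the score-prediction
phase on any dataset of annotations plus multi-rater score tables: binary
classification under the AND/OR label aggregations, regression of the total
score under mean/max/min, and per-AU ordinal classification under
mode/max/min — each across the six descriptor subsets (all 35, RFE-selected,
Boruta-selected, and the whiskers / head-position / both exclusions for the
binary and regression families).  Feature selection runs on the training
split only.  ``score_annotation`` applies a trained bundle to one face and
returns every intermediate quantity (descriptor vector, per-AU scores, total
score, painful flag) so predictions stay explainable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .descriptors import (DescriptorRegistry, build_default_registry,
                          evaluate_registry, subset_registry)
from .models import (DEFAULT_GRID, FGSBinaryClassifier, FGSOrdinalClassifier,
                     FGSRegressor, HyperGrid, auroc, boruta_shap_select, mse,
                     rfe_select, shuffled_split)
from .schema import AUS, FaceAnnotation, LandmarkSchema, build_default_schema
from .scoring import PAIN_THRESHOLD_MODEL, aggregate_labels

__all__ = [
    "TaskSpec",
    "PipelineConfig",
    "ScoreBundle",
    "run_phase2",
    "train_bundle",
    "score_annotation",
]

BINARY_RULES = ("AND", "OR")
REGRESSION_RULES = ("mean", "maximum", "minimum")
ORDINAL_RULES = ("mode", "maximum", "minimum")
FEATURE_SUBSETS = ("all", "rfe", "boruta", "wWhiskers", "wHP", "wWHP")

_EXCLUSIONS = {
    "wWhiskers": ("whiskers_change",),
    "wHP": ("head_position",),
    "wWHP": ("whiskers_change", "head_position"),
}


@dataclass(frozen=True)
class TaskSpec:
    """One prediction task: what is predicted and how labels are built."""

    task: str  # binary | regression | ordinal
    aggregation: str
    threshold: float | None = None  # binary only
    au: str | None = None  # ordinal only

    def __post_init__(self):
        if self.task == "binary":
            if self.threshold is None:
                raise ValueError("binary task needs a threshold")
            if self.aggregation.upper() not in BINARY_RULES:
                raise ValueError(f"bad binary rule {self.aggregation!r}")
        elif self.task == "regression":
            if self.aggregation.lower() not in REGRESSION_RULES:
                raise ValueError(f"bad regression rule {self.aggregation!r}")
        elif self.task == "ordinal":
            if self.au not in AUS:
                raise ValueError("ordinal task needs a valid action unit")
            if self.aggregation.lower() not in ORDINAL_RULES:
                raise ValueError(f"bad ordinal rule {self.aggregation!r}")
        else:
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class PipelineConfig:
    schema: LandmarkSchema = field(default_factory=build_default_schema)
    registry: DescriptorRegistry = field(default_factory=build_default_registry)
    grid: HyperGrid = DEFAULT_GRID
    threshold: float = PAIN_THRESHOLD_MODEL
    test_size: int | float = 100
    seed: int = 0
    feature_subsets: tuple = FEATURE_SUBSETS
    boruta_trials: int = 20


def _feature_table(registry, annotations) -> pd.DataFrame:
    rows = [evaluate_registry(registry, a) for a in annotations]
    df = pd.DataFrame(rows)
    df.index = [a.image_id for a in annotations]
    return df


def _subset_columns(name, registry, X_train, y_train, task, cfg):
    """Column names of feature subset *name* (selection on training data)."""
    if name == "all":
        return list(X_train.columns)
    if name in _EXCLUSIONS:
        sub = subset_registry(registry, _EXCLUSIONS[name])
        return sub.ids
    if name == "rfe":
        idx = rfe_select(X_train.values, y_train, task=task, seed=cfg.seed)
        return [X_train.columns[i] for i in idx]
    if name == "boruta":
        idx = boruta_shap_select(X_train.values, y_train, task=task,
                                 n_trials=cfg.boruta_trials, seed=cfg.seed)
        if not idx:  # degenerate: nothing passes — keep everything
            return list(X_train.columns)
        return [X_train.columns[i] for i in idx]
    raise ValueError(f"unknown feature subset {name!r}")


def _fit_eval(task, cols, Xtr, ytr, Xte, yte, cfg):
    est = {"binary": FGSBinaryClassifier, "regression": FGSRegressor,
           "ordinal": FGSOrdinalClassifier}[task](
        grid=cfg.grid, random_state=cfg.seed)
    est.fit(Xtr[cols].values, ytr)
    pred = est.predict(Xte[cols].values)
    if task == "binary":
        return {"accuracy_pct": 100.0 * float(np.mean(pred == yte)),
                "auroc": auroc(est.decision_scores(Xte[cols].values), yte),
                "n_features": len(cols)}
    return {"mse": mse(pred, yte), "n_features": len(cols)}


def run_phase2(annotations, rater_score_sets, config: PipelineConfig | None = None,
               families=("binary", "regression", "ordinal"), out_dir=None):
    """Run the full experimental grid; returns {family: DataFrame}.

    Images without labels for a given task are dropped (their count is
    recorded in the reproducibility record when ``out_dir`` is given).
    """
    cfg = config or PipelineConfig()
    X = _feature_table(cfg.registry, annotations)
    tr_idx, te_idx = shuffled_split(len(X), cfg.test_size, cfg.seed)
    reports: dict = {}
    dropped: dict = {}

    def split_for(labels: dict):
        ids = X.index
        mask = np.array([i in labels for i in ids])
        dropped_n = int((~mask).sum())
        keep_tr = [i for i in tr_idx if mask[i]]
        keep_te = [i for i in te_idx if mask[i]]
        y = np.array([labels[ids[i]] for i in keep_tr + keep_te])
        return (X.iloc[keep_tr], y[:len(keep_tr)],
                X.iloc[keep_te], y[len(keep_tr):], dropped_n)

    if "binary" in families:
        rows = {}
        for rule in BINARY_RULES:
            labels = aggregate_labels(rater_score_sets, "binary", rule,
                                      threshold=cfg.threshold)
            Xtr, ytr, Xte, yte, dropped[f"binary/{rule}"] = split_for(labels)
            for name in cfg.feature_subsets:
                cols = _subset_columns(name, cfg.registry, Xtr, ytr, "binary", cfg)
                cell = _fit_eval("binary", cols, Xtr, ytr, Xte, yte, cfg)
                rows.setdefault(name, {})
                for k, v in cell.items():
                    rows[name][f"{rule}_{k}"] = v
        reports["binary"] = pd.DataFrame(rows).T

    if "regression" in families:
        rows = {}
        for rule in REGRESSION_RULES:
            labels = aggregate_labels(rater_score_sets, "regression", rule)
            Xtr, ytr, Xte, yte, dropped[f"regression/{rule}"] = split_for(labels)
            for name in cfg.feature_subsets:
                cols = _subset_columns(name, cfg.registry, Xtr, ytr,
                                       "regression", cfg)
                cell = _fit_eval("regression", cols, Xtr, ytr, Xte, yte, cfg)
                rows.setdefault(name, {})
                for k, v in cell.items():
                    rows[name][f"{rule}_{k}"] = v
        reports["regression"] = pd.DataFrame(rows).T

    if "ordinal" in families:
        rows = {}
        for rule in ORDINAL_RULES:
            for au in AUS:
                labels = aggregate_labels(rater_score_sets, "ordinal", rule, au=au)
                Xtr, ytr, Xte, yte, dropped[f"ordinal/{rule}/{au}"] = \
                    split_for(labels)
                cell = _fit_eval("ordinal", list(X.columns), Xtr, ytr,
                                 Xte, yte, cfg)
                rows.setdefault(au, {})
                rows[au][f"{rule}_mse"] = cell["mse"]
        reports["ordinal"] = pd.DataFrame(rows).T

    if out_dir is not None:
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for family, df in reports.items():
            df.to_csv(out / f"report_{family}.csv")
        record = {
            "package_version": _pkg_version, "seed": cfg.seed,
            "test_size": cfg.test_size, "threshold": cfg.threshold,
            "n_images": len(X), "dropped": dropped,
            "feature_subsets": list(cfg.feature_subsets),
            "registry_hash": _registry_hash(cfg.registry),
            "schema_hash": _schema_hash(cfg.schema),
        }
        (out / "run_record.json").write_text(json.dumps(record, indent=2))
    return reports


# ---------------------------------------------------------------------------
# Trained-model bundle and single-face scoring
# ---------------------------------------------------------------------------

def _registry_hash(reg) -> str:
    blob = repr([(d.id, d.au, d.kind, d.triples, d.numerator, d.denominator)
                 for d in reg]).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _schema_hash(schema) -> str:
    blob = repr(sorted(schema.au_of.items())).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ScoreBundle:
    """Everything needed to score one annotated face."""

    schema: LandmarkSchema
    registry: DescriptorRegistry
    binary_model: FGSBinaryClassifier
    regression_model: FGSRegressor
    ordinal_models: dict  # au -> FGSOrdinalClassifier
    threshold: float
    registry_hash: str = ""
    schema_hash: str = ""

    def __post_init__(self):
        if not self.registry_hash:
            self.registry_hash = _registry_hash(self.registry)
        if not self.schema_hash:
            self.schema_hash = _schema_hash(self.schema)


def train_bundle(annotations, rater_score_sets,
                 config: PipelineConfig | None = None,
                 binary_rule: str = "AND", regression_rule: str = "mean",
                 ordinal_rule: str = "mode") -> ScoreBundle:
    """Fit the binary, regression and per-AU ordinal models on a dataset."""
    cfg = config or PipelineConfig()
    X = _feature_table(cfg.registry, annotations)

    def aligned(labels):
        ids = [i for i in X.index if i in labels]
        return X.loc[ids].values, np.array([labels[i] for i in ids])

    Xb, yb = aligned(aggregate_labels(rater_score_sets, "binary", binary_rule,
                                      threshold=cfg.threshold))
    binary = FGSBinaryClassifier(grid=cfg.grid, random_state=cfg.seed).fit(Xb, yb)
    Xr, yr = aligned(aggregate_labels(rater_score_sets, "regression",
                                      regression_rule))
    regression = FGSRegressor(grid=cfg.grid, random_state=cfg.seed).fit(Xr, yr)
    ordinal = {}
    for au in AUS:
        Xo, yo = aligned(aggregate_labels(rater_score_sets, "ordinal",
                                          ordinal_rule, au=au))
        ordinal[au] = FGSOrdinalClassifier(
            grid=cfg.grid, random_state=cfg.seed).fit(Xo, yo)
    return ScoreBundle(cfg.schema, cfg.registry, binary, regression, ordinal,
                       cfg.threshold)


def score_annotation(ann: FaceAnnotation, bundle: ScoreBundle,
                     expected_registry_hash: str | None = None) -> dict:
    """Score one face; returns every intermediate quantity.

    The result carries the 35-value descriptor vector, per-AU ordinal
    predictions, the regressed total score, the binary painful flag and the
    positive-class probability, so any unexpected score can be traced back
    to the geometry that produced it.
    """
    if expected_registry_hash is not None \
            and expected_registry_hash != bundle.registry_hash:
        raise ValueError("registry hash mismatch: bundle was trained with a "
                         "different descriptor registry")
    feats = evaluate_registry(bundle.registry, ann)
    x = np.array([list(feats.values())])
    prob = float(bundle.binary_model.predict_proba(x)[0, 1])
    flag = bool(bundle.binary_model.predict(x)[0])
    total = float(np.clip(bundle.regression_model.predict(x)[0], 0.0, 1.0))
    per_au = {au: int(m.predict(x)[0]) for au, m in bundle.ordinal_models.items()}
    return {
        "image_id": ann.image_id,
        "descriptors": feats,
        "total_fgs_pred": total,
        "au_scores_pred": per_au,
        "painful": flag,
        "painful_probability": prob,
        "threshold": bundle.threshold,
    }
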