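"""Per-type gradient-boosted-tree classifiers with an abstaining call policy.

One XGBoost binary classifier is trained per CNV type (loss / gain) on the
overlap-count feature vectors, with pathogenic as the positive class.  Class
imbalance is handled by weighting positives with
``scale_pos_weight = sqrt(n_benign / n_pathogenic)`` — the square root keeps
the reweighting gentler than full inverse-frequency weighting, which matters
because the output probabilities are consumed directly by the call policy.

The policy turns a pathogenicity probability into a three-way call: with
threshold ``p_ct``, probabilities >= p_ct are called pathogenic, <= 1 - p_ct
benign, and everything in between is abstained as uncertain significance.
Supported presets are 0.5 (no abstention), 0.95 (default) and 0.99.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import accuracy_score, matthews_corrcoef

from .annotation import AnnotationSchema, CnvType, ValidationError
from .dataset import LabeledDataset

__all__ = [
    "BoostedTreeConfig",
    "TrainedClassifier",
    "ClassificationPolicy",
    "THRESHOLD_PRESETS",
    "compute_scale_pos_weight",
    "train_classifier",
    "grid_search",
    "predict_proba",
    "classify",
    "classify_many",
]

THRESHOLD_PRESETS = (0.5, 0.95, 0.99)

CALL_BENIGN = "benign"
CALL_UNCERTAIN = "uncertain"
CALL_PATHOGENIC = "pathogenic"


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class BoostedTreeConfig:
    """Hyperparameters of one boosted-tree training run.

    Defaults are the selected configuration for both CNV types: moderately
    deep trees (max_depth 8), full-row subsampling, 80% column subsampling
    per tree, a split penalty gamma of 1 and a light L2 penalty of 0.1, run
    for up to 100 boosting rounds with early stopping after 15 rounds without
    validation improvement.
    """

    max_depth: int = 8
    eta: float = 0.3
    gamma: float = 1.0
    subsample: float = 1.0
    reg_lambda: float = 0.1
    colsample_bytree: float = 0.8
    scale_pos_weight: float | None = None  # derived from class counts if None
    n_rounds: int = 100
    early_stopping_rounds: int = 15

    def xgb_params(self, seed: int) -> dict:
        return {
            "objective": "binary:logistic",
            "eval_metric": "logloss",
            "max_depth": self.max_depth,
            "eta": self.eta,
            "gamma": self.gamma,
            "subsample": self.subsample,
            "lambda": self.reg_lambda,
            "colsample_bytree": self.colsample_bytree,
            "scale_pos_weight": self.scale_pos_weight,
            "seed": seed,
            "nthread": 1,
        }


@dataclass(frozen=True)
class ClassificationPolicy:
    """Probability-threshold policy producing benign/uncertain/pathogenic calls."""

    p_ct: float = 0.95

    def __post_init__(self) -> None:
        if not (0.5 <= self.p_ct <= 1.0):
            raise ValidationError(f"p_ct must lie in [0.5, 1], got {self.p_ct}")


def compute_scale_pos_weight(n_benign: int, n_pathogenic: int) -> float:
    """sqrt(n_benign / n_pathogenic) — positive-class weight for training."""
    if n_benign <= 0 or n_pathogenic <= 0:
        raise ConfigurationError(
            "both classes must be present to compute scale_pos_weight "
            f"(got benign={n_benign}, pathogenic={n_pathogenic})"
        )
    return math.sqrt(n_benign / n_pathogenic)


def _schema_hash(schema: AnnotationSchema) -> str:
    payload = f"{schema.cnv_type.value}|" + "|".join(schema.attribute_names)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TrainedClassifier:
    """A fitted boosted-tree ensemble bound to one CNV type and schema."""

    cnv_type: CnvType
    schema: AnnotationSchema
    config: BoostedTreeConfig
    booster: xgb.Booster
    best_iteration: int
    training_counts: tuple[int, int]  # (n_benign, n_pathogenic)
    seed: int

    def _check_schema(self, X: pd.DataFrame) -> None:
        if list(X.columns) != list(self.schema.attribute_names):
            raise ValidationError(
                f"feature columns do not match the {self.cnv_type.value} model "
                "schema"
            )

    def _dmatrix(self, X: pd.DataFrame) -> xgb.DMatrix:
        return xgb.DMatrix(X, feature_names=list(self.schema.attribute_names))

    @property
    def _iter_range(self) -> tuple[int, int]:
        return (0, self.best_iteration + 1)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Pathogenicity probability per row, in input order."""
        self._check_schema(X)
        return self.booster.predict(self._dmatrix(X), iteration_range=self._iter_range)

    def predict_margin(self, X: pd.DataFrame) -> np.ndarray:
        """Raw ensemble margin (log-odds scale) per row."""
        self._check_schema(X)
        return self.booster.predict(
            self._dmatrix(X), output_margin=True, iteration_range=self._iter_range
        )

    def predict_contributions(self, X: pd.DataFrame) -> np.ndarray:
        """Exact tree-path Shapley contributions; last column is the base value."""
        self._check_schema(X)
        return self.booster.predict(
            self._dmatrix(X), pred_contribs=True, iteration_range=self._iter_range
        )

    def save(self, directory: str | Path) -> None:
        """Persist as {model.ubj, metadata.json}; loading verifies the schema hash."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(str(directory / "model.ubj"))
        meta = {
            "cnv_type": self.cnv_type.value,
            "attribute_names": list(self.schema.attribute_names),
            "schema_hash": _schema_hash(self.schema),
            "config": asdict(self.config),
            "best_iteration": self.best_iteration,
            "training_counts": list(self.training_counts),
            "seed": self.seed,
        }
        (directory / "metadata.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedClassifier":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        schema = AnnotationSchema(
            cnv_type=CnvType(meta["cnv_type"]),
            attribute_names=tuple(meta["attribute_names"]),
        )
        if _schema_hash(schema) != meta["schema_hash"]:
            raise ValidationError("model metadata schema hash mismatch")
        booster = xgb.Booster()
        booster.load_model(str(directory / "model.ubj"))
        return cls(
            cnv_type=schema.cnv_type,
            schema=schema,
            config=BoostedTreeConfig(**meta["config"]),
            booster=booster,
            best_iteration=meta["best_iteration"],
            training_counts=tuple(meta["training_counts"]),
            seed=meta["seed"],
        )


def train_classifier(
    train: LabeledDataset,
    val: LabeledDataset,
    config: BoostedTreeConfig | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit a boosted-tree ensemble with early stopping on validation log-loss.

    ``scale_pos_weight`` is derived from the training class counts unless the
    config overrides it.  Training is reproducible for a fixed seed (single
    threaded histogram construction).
    """
    if train.cnv_type != val.cnv_type:
        raise ValidationError("train and validation sets have different CNV types")
    if list(train.X.columns) != list(val.X.columns):
        raise ValidationError("train and validation feature schemas differ")
    config = config or BoostedTreeConfig()
    n_benign, n_pathogenic = train.class_counts
    if n_benign == 0 or n_pathogenic == 0:
        raise ValidationError("training set must contain both classes")
    if config.scale_pos_weight is None:
        config = replace(
            config, scale_pos_weight=compute_scale_pos_weight(n_benign, n_pathogenic)
        )
    feature_names = list(train.schema.attribute_names)
    dtrain = xgb.DMatrix(train.X, label=train.y, feature_names=feature_names)
    dval = xgb.DMatrix(val.X, label=val.y, feature_names=feature_names)
    booster = xgb.train(
        config.xgb_params(seed),
        dtrain,
        num_boost_round=config.n_rounds,
        evals=[(dval, "validation")],
        early_stopping_rounds=config.early_stopping_rounds,
        verbose_eval=False,
    )
    best_iteration = getattr(booster, "best_iteration", None)
    if best_iteration is None:
        best_iteration = config.n_rounds - 1
    return TrainedClassifier(
        cnv_type=train.cnv_type,
        schema=train.schema,
        config=config,
        booster=booster,
        best_iteration=int(best_iteration),
        training_counts=(n_benign, n_pathogenic),
        seed=seed,
    )


def grid_search(
    train: LabeledDataset,
    val: LabeledDataset,
    grid: Sequence[BoostedTreeConfig],
    seed: int = 0,
) -> tuple[TrainedClassifier, pd.DataFrame]:
    """Train every config and rank by validation Matthews correlation.

    Ties are broken by higher validation accuracy, then lower max_depth, then
    grid order.  Returns the best classifier and the full ranking table.
    """
    if len(grid) == 0:
        raise ValidationError("hyperparameter grid must not be empty")
    rows = []
    fitted: list[TrainedClassifier] = []
    for i, config in enumerate(grid):
        clf = train_classifier(train, val, config, seed=seed)
        proba = clf.predict_proba(val.X)
        pred = (proba >= 0.5).astype(int)
        mcc = matthews_corrcoef(val.y, pred) if len(np.unique(pred)) > 0 else 0.0
        acc = accuracy_score(val.y, pred)
        fitted.append(clf)
        rows.append(
            {
                "grid_index": i,
                "validation_mcc": float(mcc),
                "validation_accuracy": float(acc),
                "max_depth": config.max_depth,
                "eta": config.eta,
                "n_rounds": config.n_rounds,
                "best_iteration": clf.best_iteration,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        by=["validation_mcc", "validation_accuracy", "max_depth", "grid_index"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    best = fitted[int(table.iloc[0]["grid_index"])]
    return best, table


def predict_proba(clf: TrainedClassifier, X: pd.DataFrame) -> np.ndarray:
    return clf.predict_proba(X)


def classify(p: float, policy: ClassificationPolicy = ClassificationPolicy()) -> str:
    """Three-way call for one probability under the threshold policy.

    pathogenic iff p >= p_ct; benign iff p <= 1 - p_ct; otherwise uncertain.
    Both boundaries are inclusive, so at p_ct = 0.5 only p exactly 0.5 could
    satisfy both rules and the pathogenic rule wins.
    """
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"probability must lie in [0, 1], got {p}")
    if p >= policy.p_ct:
        return CALL_PATHOGENIC
    if p <= 1.0 - policy.p_ct:
        return CALL_BENIGN
    return CALL_UNCERTAIN


def classify_many(
    probabilities: Sequence[float] | np.ndarray,
    policy: ClassificationPolicy = ClassificationPolicy(),
) -> np.ndarray:
    """Vectorized three-way calls, order preserved."""
    p = np.asarray(probabilities, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValidationError("probabilities must lie in [0, 1]")
    calls = np.full(p.shape, CALL_UNCERTAIN, dtype=object)
    calls[p >= policy.p_ct] = CALL_PATHOGENIC
    calls[(p <= 1.0 - policy.p_ct) & (p < policy.p_ct)] = CALL_BENIGN
    return calls
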