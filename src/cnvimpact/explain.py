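"""Additive per-attribute explanation of individual predictions.

Each prediction is decomposed into exact tree-path Shapley contributions: a
base value (the expectation of the ensemble margin over the training
distribution, as encoded by the tree cover statistics) plus one signed value
per attribute, summing to the raw log-odds margin of the prediction.  The
decomposition is exact and additive on the log-odds scale; the probability
scale shown to end users is a display transform of the endpoints only, since
the sigmoid is nonlinear and probability-scale "contributions" are at best
proportional approximations.

Averaging absolute contributions over a dataset gives a global importance
ranking of the annotation attributes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ._treeshap import TreeEnsembleF64
from .annotation import ValidationError
from .model import TrainedClassifier

__all__ = [
    "AttributionReport",
    "explain_prediction",
    "explain_many",
    "global_importance",
    "export_waterfall",
]


def _exact_ensemble(clf: TrainedClassifier) -> TreeEnsembleF64:
    """Float64 view of the fitted ensemble, cached on the classifier."""
    cached = getattr(clf, "_exact_ensemble_cache", None)
    if cached is None:
        cached = TreeEnsembleF64(
            clf.booster,
            list(clf.schema.attribute_names),
            n_trees=clf.best_iteration + 1,
        )
        clf._exact_ensemble_cache = cached
    return cached


@dataclass
class AttributionReport:
    """Additive attribution of one prediction.

    base_value + sum(contributions) == output_value on the log-odds scale.
    """

    attribute_names: tuple[str, ...]
    feature_values: np.ndarray
    base_value: float
    contributions: np.ndarray
    output_value: float
    scale: str = "log_odds"

    def __post_init__(self) -> None:
        self.contributions = np.asarray(self.contributions, dtype=float)
        self.feature_values = np.asarray(self.feature_values)
        if len(self.contributions) != len(self.attribute_names):
            raise ValidationError("one contribution per attribute required")

    @property
    def output_probability(self) -> float:
        """Endpoint of the attribution mapped to the probability scale."""
        if self.scale == "probability":
            return self.output_value
        return float(expit(self.output_value))

    @property
    def base_probability(self) -> float:
        if self.scale == "probability":
            return self.base_value
        return float(expit(self.base_value))

    def to_probability_scale(self) -> "AttributionReport":
        """Display transform: endpoints through the sigmoid, contributions
        rescaled proportionally so the additive identity still holds.

        Only the log-odds report is exact; use this for plotting.
        """
        if self.scale == "probability":
            return self
        base_p = float(expit(self.base_value))
        out_p = float(expit(self.output_value))
        span = self.output_value - self.base_value
        factor = (out_p - base_p) / span if span != 0 else 0.0
        return AttributionReport(
            attribute_names=self.attribute_names,
            feature_values=self.feature_values,
            base_value=base_p,
            contributions=self.contributions * factor,
            output_value=out_p,
            scale="probability",
        )


def explain_prediction(
    clf: TrainedClassifier, features: pd.DataFrame | pd.Series
) -> AttributionReport:
    """Exact tree-path Shapley attribution for a single feature vector.

    Computed in double precision over the parsed tree dump so the additive
    identity holds to numerical round-off; the booster's single-precision
    contribution predictor is only used for batch importance scans.
    """
    if isinstance(features, pd.Series):
        features = features.to_frame().T
    if len(features) != 1:
        raise ValidationError("explain_prediction expects exactly one row")
    if list(features.columns) != list(clf.schema.attribute_names):
        raise ValidationError("feature columns do not match the model schema")
    ensemble = _exact_ensemble(clf)
    x = features.iloc[0].to_numpy(dtype=float)
    contributions = ensemble.shap_values(x)
    base = ensemble.expected_margin()
    return AttributionReport(
        attribute_names=tuple(clf.schema.attribute_names),
        feature_values=features.iloc[0].to_numpy(),
        base_value=base,
        contributions=contributions,
        # the margin is recomputed by an independent float64 tree walk; the
        # additive identity base + sum(contributions) == margin is a property
        # of the attribution, not a definition
        output_value=ensemble.margin(x),
    )


def explain_many(clf: TrainedClassifier, X: pd.DataFrame) -> np.ndarray:
    """Contribution matrix (n_rows, n_attributes); base column stripped."""
    return clf.predict_contributions(X)[:, :-1]


def global_importance(clf: TrainedClassifier, X: pd.DataFrame) -> pd.DataFrame:
    """Mean absolute contribution per attribute, descending.

    Attributes the ensemble never splits on receive exactly zero.
    """
    if len(X) == 0:
        raise ValidationError("global importance requires a non-empty dataset")
    contrib = explain_many(clf, X)
    mean_abs = np.abs(contrib).mean(axis=0)
    out = pd.DataFrame(
        {
            "attribute": list(clf.schema.attribute_names),
            "mean_abs_contribution": mean_abs,
        }
    )
    return out.sort_values(
        by=["mean_abs_contribution", "attribute"],
        ascending=[False, True],
        kind="mergesort",
    ).reset_index(drop=True)


def export_waterfall(report: AttributionReport, top_k: int = 10) -> pd.DataFrame:
    """Plot-ready waterfall rows: strongest attributes first, rest collapsed.

    Rows carry (attribute, feature value, contribution, cumulative) with
    cumulative starting from the base value; attributes beyond ``top_k`` are
    merged into a single "other" row so the final cumulative value equals the
    output value exactly.
    """
    if top_k < 1:
        raise ValidationError(f"top_k must be >= 1, got {top_k}")
    order = np.argsort(-np.abs(report.contributions), kind="mergesort")
    head = order[:top_k]
    tail = order[top_k:]
    rows = []
    cumulative = report.base_value
    for i in head:
        cumulative += report.contributions[i]
        rows.append(
            {
                "attribute": report.attribute_names[i],
                "value": report.feature_values[i],
                "contribution": float(report.contributions[i]),
                "cumulative": float(cumulative),
            }
        )
    if len(tail) > 0:
        other = float(report.contributions[tail].sum())
        cumulative += other
        rows.append(
            {
                "attribute": "other",
                "value": None,
                "contribution": other,
                "cumulative": float(cumulative),
            }
        )
    return pd.DataFrame(rows)
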