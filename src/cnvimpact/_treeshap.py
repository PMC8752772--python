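"""Double-precision path-dependent Shapley values for boosted-tree ensembles.

Implements the polynomial-time tree-traversal algorithm for Shapley additive
attributions of tree ensembles (the "tree path dependent" feature
perturbation: conditional expectations follow the training cover recorded at
each split).  The booster's own contribution predictor implements the same
algorithm in single precision; this module re-derives it in float64 so the
additive identity  base + sum(phi) == margin  holds to ~1e-12, which matters
when contributions are consumed programmatically rather than plotted.

The ensemble is parsed once from the booster's JSON dump; the raw margin and
the expectation are recomputed here in float64 as well, so all three
quantities live on one numeric scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import xgboost as xgb

__all__ = ["TreeEnsembleF64"]


@dataclass
class _Tree:
    # flat arrays indexed by node id; children == -1 marks a leaf
    left: np.ndarray
    right: np.ndarray
    missing: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray
    cover: np.ndarray


def _flatten(node: dict, feature_index: dict[str, int], nodes: dict[int, dict]) -> None:
    nodes[node["nodeid"]] = node
    for child in node.get("children", ()):
        _flatten(child, feature_index, nodes)


def _parse_tree(root: dict, feature_index: dict[str, int]) -> _Tree:
    nodes: dict[int, dict] = {}
    _flatten(root, feature_index, nodes)
    n = max(nodes) + 1
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    missing = np.full(n, -1, dtype=np.int64)
    feature = np.full(n, -1, dtype=np.int64)
    threshold = np.zeros(n, dtype=np.float64)
    value = np.zeros(n, dtype=np.float64)
    cover = np.zeros(n, dtype=np.float64)
    for nid, node in nodes.items():
        cover[nid] = node["cover"]
        if "leaf" in node:
            value[nid] = node["leaf"]
        else:
            split = node["split"]
            if split in feature_index:
                feature[nid] = feature_index[split]
            else:  # "f12"-style fallback when no feature names were attached
                feature[nid] = int(split.lstrip("f"))
            threshold[nid] = node["split_condition"]
            left[nid] = node["yes"]
            right[nid] = node["no"]
            missing[nid] = node["missing"]
    return _Tree(left, right, missing, feature, threshold, value, cover)


class TreeEnsembleF64:
    """Float64 view of a fitted XGBoost binary-logistic ensemble."""

    def __init__(
        self,
        booster: xgb.Booster,
        feature_names: list[str],
        n_trees: int | None = None,
    ):
        feature_index = {name: i for i, name in enumerate(feature_names)}
        dumps = booster.get_dump(dump_format="json", with_stats=True)
        if n_trees is not None:
            dumps = dumps[:n_trees]
        self.trees = [_parse_tree(json.loads(d), feature_index) for d in dumps]
        self.n_features = len(feature_names)
        config = json.loads(booster.save_config())
        base_score = float(
            config["learner"]["learner_model_param"]["base_score"]
        )
        # binary:logistic stores the global bias as a probability
        self.intercept = math.log(base_score / (1.0 - base_score))

    # -- margins ----------------------------------------------------------
    def _leaf_value(self, tree: _Tree, x: np.ndarray) -> float:
        j = 0
        while tree.left[j] != -1:
            xv = x[tree.feature[j]]
            if np.isnan(xv):
                j = tree.missing[j]
            elif xv < tree.threshold[j]:
                j = tree.left[j]
            else:
                j = tree.right[j]
        return float(tree.value[j])

    def margin(self, x: np.ndarray) -> float:
        """Raw log-odds margin of one instance, accumulated in float64."""
        x = np.asarray(x, dtype=np.float64)
        return self.intercept + sum(self._leaf_value(t, x) for t in self.trees)

    def _expected_tree_value(self, tree: _Tree, j: int = 0) -> float:
        if tree.left[j] == -1:
            return float(tree.value[j])
        lo, hi = tree.left[j], tree.right[j]
        return (
            tree.cover[lo] * self._expected_tree_value(tree, lo)
            + tree.cover[hi] * self._expected_tree_value(tree, hi)
        ) / tree.cover[j]

    def expected_margin(self) -> float:
        """Cover-weighted expectation of the margin — the base value."""
        return self.intercept + sum(self._expected_tree_value(t) for t in self.trees)

    # -- Shapley attribution ----------------------------------------------
    def shap_values(self, x: np.ndarray) -> np.ndarray:
        """phi per feature; expected_margin() + phi.sum() == margin(x)."""
        x = np.asarray(x, dtype=np.float64)
        phi = np.zeros(self.n_features, dtype=np.float64)
        for tree in self.trees:
            self._tree_shap(tree, x, phi)
        return phi

    def shap_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return np.stack([self.shap_values(row) for row in X])

    def _tree_shap(self, tree: _Tree, x: np.ndarray, phi: np.ndarray) -> None:
        # path elements: feature d, zero fraction z, one fraction o, weight w
        self._recurse(tree, x, phi, 0, [], 1.0, 1.0, -1)

    @staticmethod
    def _extend(
        m: list[list[float]], pz: float, po: float, pi: int
    ) -> list[list[float]]:
        l = len(m)
        m = [e.copy() for e in m]
        m.append([pi, pz, po, 1.0 if l == 0 else 0.0])
        for i in range(l - 1, -1, -1):
            m[i + 1][3] += po * m[i][3] * (i + 1) / (l + 1)
            m[i][3] = pz * m[i][3] * (l - i) / (l + 1)
        return m

    @staticmethod
    def _unwind(m: list[list[float]], i: int) -> list[list[float]]:
        l = len(m) - 1
        o, z = m[i][2], m[i][1]
        n = m[l][3]
        out = [e.copy() for e in m[:l]]
        for j in range(l - 1, -1, -1):
            if o != 0.0:
                t = out[j][3]
                out[j][3] = n * (l + 1) / ((j + 1) * o)
                n = t - out[j][3] * z * (l - j) / (l + 1)
            else:
                out[j][3] = out[j][3] * (l + 1) / (z * (l - j))
        for j in range(i, l):
            out[j][0], out[j][1], out[j][2] = m[j + 1][0], m[j + 1][1], m[j + 1][2]
        return out

    @classmethod
    def _unwound_sum(cls, m: list[list[float]], i: int) -> float:
        # total weight of the path with element i removed, without mutating m
        return sum(e[3] for e in cls._unwind(m, i))

    def _recurse(
        self,
        tree: _Tree,
        x: np.ndarray,
        phi: np.ndarray,
        j: int,
        m: list[list[float]],
        pz: float,
        po: float,
        pi: int,
    ) -> None:
        m = self._extend(m, pz, po, pi)
        if tree.left[j] == -1:
            v = float(tree.value[j])
            for i in range(1, len(m)):
                w = self._unwound_sum(m, i)
                phi[int(m[i][0])] += w * (m[i][2] - m[i][1]) * v
            return
        d = int(tree.feature[j])
        xv = x[d]
        if np.isnan(xv):
            hot = int(tree.missing[j])
        elif xv < tree.threshold[j]:
            hot = int(tree.left[j])
        else:
            hot = int(tree.right[j])
        cold = int(tree.right[j]) if hot == int(tree.left[j]) else int(tree.left[j])
        iz, io = 1.0, 1.0
        k = next((idx for idx in range(1, len(m)) if int(m[idx][0]) == d), None)
        if k is not None:
            iz, io = m[k][1], m[k][2]
            m = self._unwind(m, k)
        r_j = float(tree.cover[j])
        self._recurse(
            tree, x, phi, hot, m, iz * float(tree.cover[hot]) / r_j, io, d
        )
        self._recurse(
            tree, x, phi, cold, m, iz * float(tree.cover[cold]) / r_j, 0.0, d
        )
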