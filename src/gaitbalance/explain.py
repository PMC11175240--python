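"""Consistency and explainability analysis.

* :func:`ks_compare` — per-feature two-sample Kolmogorov-Smirnov tests
  between the real and generated feature distributions (the fidelity check
  for the generative balancers).
* :func:`shap_attributions` — exact Shapley-value attributions of the
  random forest's minority-class probability.  The coalition value of a
  feature subset is the path-dependent tree expectation: splits on
  conditioned features follow the observation, other splits average the
  children weighted by their training cover.  All 2^M subsets are enumerated
  (M is small after feature selection), so the efficiency (local accuracy)
  and dummy axioms hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from .prep import feature_columns


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov consistency
# ---------------------------------------------------------------------------


@dataclass
class KSResult:
    """Per-feature two-sample KS statistics against the significance level."""

    table: pd.DataFrame          # feature, ks, p, significant
    alpha: float = 0.05

    @property
    def n_consistent(self) -> int:
        return int((~self.table["significant"]).sum())


def ks_compare(real: pd.DataFrame, synthetic: pd.DataFrame,
               features: list[str] | None = None, alpha: float = 0.05,
               method: str = "asymp") -> KSResult:
    """Two-sample KS test per feature (sup CDF difference).

    ``method`` is passed to scipy (``"asymp"`` default, ``"exact"`` for the
    small-sample distribution).  Features with p < alpha are flagged as
    significantly different.
    """
    feats = features or [f for f in feature_columns(real)
                         if f in synthetic.columns]
    if not feats:
        raise ValueError("no common features to compare")
    rows = []
    for f in feats:
        a = real[f].dropna().to_numpy(dtype=float)
        b = synthetic[f].dropna().to_numpy(dtype=float)
        if len(a) < 5 or len(b) < 5:
            raise ValueError(f"feature {f}: need >= 5 values in both samples")
        res = stats.ks_2samp(a, b, method=method)
        rows.append({"feature": f, "ks": float(res.statistic),
                     "p": float(res.pvalue),
                     "significant": bool(res.pvalue < alpha)})
    return KSResult(table=pd.DataFrame(rows), alpha=alpha)


# ---------------------------------------------------------------------------
# exact Shapley attributions for tree ensembles
# ---------------------------------------------------------------------------


@dataclass
class ShapSummary:
    """Per-observation, per-feature Shapley attributions of one model output."""

    values: np.ndarray           # (n_obs, n_features), signed
    base_value: float            # expected model output (empty coalition)
    feature_values: pd.DataFrame
    features: list[str]

    @property
    def mean_abs(self) -> pd.Series:
        return pd.Series(np.abs(self.values).mean(axis=0),
                         index=self.features).sort_values(ascending=False)

    @property
    def ranking(self) -> list[str]:
        return list(self.mean_abs.index)

    def predictions(self) -> np.ndarray:
        """Reconstructed model outputs: base + sum of attributions (efficiency)."""
        return self.base_value + self.values.sum(axis=1)

    def long_frame(self) -> pd.DataFrame:
        """Long format (observation, feature, value, feature_value) for plotting."""
        n, p = self.values.shape
        return pd.DataFrame({
            "observation": np.repeat(np.arange(n), p),
            "feature": np.tile(self.features, n),
            "value": self.values.ravel(),
            "feature_value": self.feature_values.to_numpy().ravel(),
        })


def _tree_subset_values(tree, X: np.ndarray, pos_idx: int,
                        masks: np.ndarray) -> np.ndarray:
    """v(S) for every subset S and observation under one fitted tree.

    Returns an (n_obs, 2^M) array: splits on features in S follow the
    observation; other splits take the cover-weighted average of the two
    children.  ``masks[f]`` is the boolean subset-membership vector of
    feature f over the 2^M subsets.
    """
    t = tree.tree_
    n_obs = X.shape[0]

    def node_value(node: int) -> np.ndarray:
        v = t.value[node][0]
        s = v.sum()
        return np.full(1, v[pos_idx] / s if s else 0.0)

    def rec(node: int) -> np.ndarray:
        if t.children_left[node] == -1:
            return np.broadcast_to(node_value(node),
                                   (n_obs, masks.shape[1])).copy()
        f = t.feature[node]
        left = rec(t.children_left[node])
        right = rec(t.children_right[node])
        wl = t.weighted_n_node_samples[t.children_left[node]]
        wr = t.weighted_n_node_samples[t.children_right[node]]
        out = (wl * left + wr * right) / (wl + wr)
        go_left = X[:, f] <= t.threshold[node]
        sel = np.where(go_left[:, None], left, right)
        out[:, masks[f]] = sel[:, masks[f]]
        return out

    return rec(0)


def shap_attributions(rf, df: pd.DataFrame, features: list[str] | None = None,
                      positive_class: int = 1,
                      max_features: int = 14) -> ShapSummary:
    """Exact Shapley attributions of the forest's positive-class probability.

    Enumerates all feature subsets (feasible for the post-selection feature
    counts this pipeline produces; refuses beyond ``max_features``).  The
    attributions of each tree are averaged, matching ``predict_proba``.
    """
    feats = features or feature_columns(df)
    if len(feats) > max_features:
        raise ValueError(f"exact enumeration limited to {max_features} features")
    if list(getattr(rf, "feature_names_in_", feats)) != list(feats) and \
            getattr(rf, "n_features_in_", len(feats)) != len(feats):
        raise ValueError("model feature schema does not match the table")
    X = df[feats].to_numpy(dtype=float)
    M = len(feats)
    n_sub = 1 << M
    subsets = np.arange(n_sub)
    masks = np.array([(subsets >> f) & 1 for f in range(M)], dtype=bool)
    sizes = np.array([bin(s).count("1") for s in subsets])
    weights = np.array([factorial(s) * factorial(M - 1 - s) / factorial(M)
                        for s in range(M)])

    pos_idx = list(rf.classes_).index(positive_class)
    V = np.zeros((X.shape[0], n_sub))
    for est in rf.estimators_:
        V += _tree_subset_values(est, X, pos_idx, masks)
    V /= len(rf.estimators_)

    phi = np.zeros((X.shape[0], M))
    for f in range(M):
        without = subsets[~masks[f]]
        w = weights[sizes[without]]
        phi[:, f] = ((V[:, without | (1 << f)] - V[:, without]) * w).sum(axis=1)

    return ShapSummary(values=phi, base_value=float(V[0, 0]),
                       feature_values=df[feats].reset_index(drop=True),
                       features=list(feats))


def shap_sampling(rf, df: pd.DataFrame, features: list[str] | None = None,
                  n_permutations: int = 128, positive_class: int = 1,
                  seed: int = 0) -> ShapSummary:
    """Permutation-sampling Shapley approximation (model-agnostic fallback).

    Marginalises absent features over the empirical background (the rows of
    ``df`` themselves); useful beyond the exact enumeration limit.
    """
    rng = np.random.default_rng(seed)
    feats = features or feature_columns(df)
    X = df[feats].to_numpy(dtype=float)
    n, M = X.shape
    pos_idx = list(rf.classes_).index(positive_class)

    def f(mat):
        return rf.predict_proba(mat)[:, pos_idx]

    base = float(f(X).mean())
    phi = np.zeros((n, M))
    for _ in range(n_permutations):
        order = rng.permutation(M)
        bg = X[rng.integers(n, size=n)]
        cur = bg.copy()
        prev = f(cur)
        for j in order:
            cur[:, j] = X[:, j]
            new = f(cur)
            phi[:, j] += new - prev
            prev = new
    phi /= n_permutations
    return ShapSummary(values=phi, base_value=base,
                       feature_values=df[feats].reset_index(drop=True),
                       features=list(feats))


# ---------------------------------------------------------------------------
# combined report
# ---------------------------------------------------------------------------


def consistency_report(real: pd.DataFrame, synthetic: pd.DataFrame,
                       rf=None, explain_df: pd.DataFrame | None = None,
                       alpha: float = 0.05) -> dict:
    """KS fidelity table plus (optionally) the SHAP importance ranking.

    Returns a dict with the KS table (one row per feature), the count of
    consistent features, and — when a fitted forest is supplied — the mean
    absolute Shapley attribution per feature and the plotting-ready long
    frame.
    """
    ks = ks_compare(real, synthetic, alpha=alpha)
    out = {
        "ks_table": ks.table,
        "n_features": len(ks.table),
        "n_consistent": ks.n_consistent,
    }
    if rf is not None:
        summary = shap_attributions(rf, explain_df if explain_df is not None else real)
        out["shap_mean_abs"] = summary.mean_abs
        out["shap_ranking"] = summary.ranking
        out["shap_long"] = summary.long_frame()
    return out
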