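"""Preprocessing and feature selection for the labelled gait feature table.

Pipeline stages, in the order the study applies them:

1. IQR outlier replacement (values beyond 1.5 x IQR fences -> feature median);
2. Yeo-Johnson power transform (maximum-likelihood lambda per feature);
3. standardisation to zero mean / unit SD;
4. collinearity filtering at |r| > 0.5 with domain keep-preferences;
5. random-forest importance ranking against a uniform-random *noise* feature,
   averaged over stratified CV folds — features no more important than noise
   are excluded;
6. univariate group comparison (independent-samples t-test, Cohen's d).

Only :func:`rf_select_features` and :func:`group_compare` read the class
label; the cleaning transforms are label-blind by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import PowerTransformer

NON_FEATURE_COLUMNS = ("subject_id", "class", "provenance", "strategy")


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Numeric feature columns (everything but identifiers / labels / flags)."""
    return [c for c in df.columns
            if c not in NON_FEATURE_COLUMNS
            and pd.api.types.is_numeric_dtype(df[c])]


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------


def replace_outliers_iqr(df: pd.DataFrame, fence: float = 1.5,
                         per_class: bool = False, max_passes: int = 1):
    """Replace IQR outliers with the feature median.

    Values outside [Q1 - fence*IQR, Q3 + fence*IQR] are replaced by the
    feature's median.  Fences and medians are computed over the whole column
    by default (``per_class=True`` computes them within each class).  A
    single pass can leave new borderline outliers because replacement
    tightens the fences; ``max_passes`` > 1 (or ``None``) repeats the pass
    until a fixed point, which makes the operation idempotent.

    Returns ``(cleaned df, counts per class, boolean replacement mask)``.
    """
    out, counts, mask = df, None, None
    passes = 0
    while max_passes is None or passes < max_passes:
        out, new_counts, new_mask = _replace_outliers_once(out, fence, per_class)
        counts = new_counts if counts is None else \
            {k: counts.get(k, 0) + v for k, v in new_counts.items()}
        mask = new_mask if mask is None else (mask | new_mask)
        passes += 1
        if sum(new_counts.values()) == 0:
            break
    return out, counts, mask


def _replace_outliers_once(df: pd.DataFrame, fence: float, per_class: bool):
    out = df.copy()
    feats = feature_columns(df)
    mask = pd.DataFrame(False, index=df.index, columns=feats)

    def _clean(block: pd.DataFrame, rows: pd.Index):
        for f in feats:
            col = block[f]
            q1, q3 = col.quantile([0.25, 0.75])
            iqr = q3 - q1
            if iqr == 0:
                warnings.warn(f"feature {f} has zero IQR; no replacements")
                continue
            bad = (col < q1 - fence * iqr) | (col > q3 + fence * iqr)
            out.loc[rows[bad.to_numpy()], f] = col.median()
            mask.loc[rows[bad.to_numpy()], f] = True

    if per_class and "class" in df.columns:
        for label, block in df.groupby("class"):
            _clean(block, block.index)
    else:
        _clean(df, df.index)

    if "class" in df.columns:
        counts = {label: int(mask.loc[df["class"] == label].to_numpy().sum())
                  for label in df["class"].unique()}
    else:
        counts = {"all": int(mask.to_numpy().sum())}
    return out, counts, mask


def power_transform(df: pd.DataFrame):
    """Yeo-Johnson power transform per feature (maximum-likelihood lambda).

    Monotone per feature, so rank order is preserved.  Returns the
    transformed table and the fitted transformer (with ``lambdas_``).
    """
    feats = feature_columns(df)
    pt = PowerTransformer(method="yeo-johnson", standardize=False)
    out = df.copy()
    out[feats] = pt.fit_transform(df[feats].to_numpy())
    return out, pt


@dataclass
class Standardizer:
    """Per-feature mean/SD (n-1) with an exact inverse transform."""

    features: list[str]
    means: np.ndarray
    sds: np.ndarray

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out[self.features] = (df[self.features].to_numpy() - self.means) / self.sds
        return out

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out[self.features] = df[self.features].to_numpy() * self.sds + self.means
        return out


def standardize(df: pd.DataFrame, features: list[str] | None = None):
    """Standardise features to mean 0 / SD 1 (sample SD, n-1).

    Returns ``(standardised df, Standardizer)``; the Standardizer can be
    fitted on training folds and applied to held-out rows.
    """
    feats = features or feature_columns(df)
    X = df[feats].to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        zero = [f for f, s in zip(feats, sds) if s == 0]
        raise ValueError(f"zero-variance feature(s): {zero}")
    scaler = Standardizer(feats, means, sds)
    return scaler.transform(df), scaler


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------


def collinearity_filter(df: pd.DataFrame, threshold: float = 0.5,
                        keep_preferences: tuple = ()):
    """Drop one member of each feature pair with |r| above the threshold.

    While any pair exceeds the threshold, the most-correlated pair is
    resolved: a feature named in ``keep_preferences`` (domain expertise,
    e.g. keep stance phase over swing/support phases) survives; otherwise the
    member with the larger mean |r| to the remaining features is dropped.

    Returns ``(retained feature list, list of (dropped, kept, r) records)``.
    """
    feats = feature_columns(df)
    if len(feats) < 2:
        return feats, []
    corr = df[feats].corr().to_numpy()
    active = list(range(len(feats)))
    dropped = []
    while True:
        sub = np.abs(corr[np.ix_(active, active)])
        np.fill_diagonal(sub, 0.0)
        if sub.size == 0 or sub.max() <= threshold:
            break
        a, b = np.unravel_index(np.argmax(sub), sub.shape)
        fa, fb = feats[active[a]], feats[active[b]]
        r = corr[active[a], active[b]]
        pa, pb = fa in keep_preferences, fb in keep_preferences
        if pa and not pb:
            drop = b
        elif pb and not pa:
            drop = a
        else:
            drop = a if sub[a].mean() >= sub[b].mean() else b
        dropped.append((feats[active[drop]],
                        fb if drop == a else fa, float(r)))
        del active[drop]
    return [feats[i] for i in active], dropped


@dataclass
class SelectionReport:
    """Outcome of RF importance selection against the noise baseline."""

    importances: dict            # feature -> mean importance (incl. "noise")
    noise_importance: float
    retained: list[str]
    excluded: list[str]
    ranking: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.ranking:
            self.ranking = sorted(self.importances,
                                  key=self.importances.get, reverse=True)


def rf_select_features(df: pd.DataFrame, n_noise: int = 1, cv_folds: int = 4,
                       seed: int = 0, n_estimators: int = 200) -> SelectionReport:
    """Random-forest feature selection against a random *noise* baseline.

    A uniform-random column with no predictive value is appended; impurity
    importances are averaged across stratified CV folds (forest refitted on
    each training split); features whose mean importance does not exceed the
    noise feature's are excluded.
    """
    if "class" not in df.columns or df["class"].nunique() < 2:
        raise ValueError("need a two-class labelled table")
    feats = feature_columns(df)
    rng = np.random.default_rng(seed)
    X = df[feats].to_numpy(dtype=float)
    noise_names = [f"noise{i}" if i else "noise" for i in range(n_noise)]
    X = np.column_stack([X, rng.uniform(0.0, 1.0, (len(df), n_noise))])
    names = feats + noise_names
    y = (df["class"] == df["class"].unique()[0]).to_numpy(int)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    imp = np.zeros(len(names))
    for tr, _ in skf.split(X, y):
        rf = RandomForestClassifier(n_estimators=n_estimators,
                                    random_state=seed)
        rf.fit(X[tr], y[tr])
        imp += rf.feature_importances_
    imp /= cv_folds

    importances = dict(zip(names, imp.tolist()))
    noise_imp = max(importances[n] for n in noise_names)
    retained = [f for f in feats if importances[f] > noise_imp]
    excluded = [f for f in feats if f not in retained] + noise_names
    return SelectionReport(importances=importances, noise_importance=noise_imp,
                           retained=retained, excluded=excluded)


# ---------------------------------------------------------------------------
# univariate comparison
# ---------------------------------------------------------------------------


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled SD (n-1 weights)."""
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled variance: Cohen's d undefined")
    return float((np.mean(a) - np.mean(b)) / pooled)


def group_compare(df: pd.DataFrame, equal_var: bool = True) -> pd.DataFrame:
    """Per-feature independent-samples t-test and Cohen's d between classes.

    Returns a frame with columns ``feature, t, p, cohens_d`` (minority minus
    majority orientation follows the first class label encountered).
    """
    labels = df["class"].unique()
    if len(labels) != 2:
        raise ValueError("group_compare requires exactly two classes")
    ga = df[df["class"] == labels[0]]
    gb = df[df["class"] == labels[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each class needs n >= 2")
    rows = []
    for f in feature_columns(df):
        a = ga[f].to_numpy(dtype=float)
        b = gb[f].to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append({"feature": f, "t": float(t), "p": float(p),
                     "cohens_d": cohens_d(a, b)})
    return pd.DataFrame(rows)
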