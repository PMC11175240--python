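"""Random-forest evaluation of the balancing strategies.

Stratified k=4 cross-validation, Gaussian-process Bayesian hyperparameter
optimisation over the study's ranges (trees 50-500, depth 2-20, min split
2-10, min leaf 1-10), and the classification metrics (accuracy, per-class
precision/recall/F1, log loss, ROC AUC) computed from first principles.

Two augmentation scopes are supported: the default balances the training
folds only and evaluates on real held-out rows (leakage-free); ``pooled_augmentation``
balances the full table before splitting, mirroring the original protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern
from sklearn.model_selection import StratifiedKFold

from .balance import BalanceConfig, balance
from .prep import feature_columns
from .simdata import MINORITY_LABEL


@dataclass
class HyperSpace:
    """Random-forest hyperparameter bounds (inclusive integer ranges)."""

    n_trees: tuple[int, int] = (50, 500)
    max_depth: tuple[int, int] = (2, 20)
    min_samples_split: tuple[int, int] = (2, 10)
    min_samples_leaf: tuple[int, int] = (1, 10)

    @property
    def names(self):
        return ("n_trees", "max_depth", "min_samples_split", "min_samples_leaf")

    def bounds(self) -> list[tuple[int, int]]:
        return [getattr(self, n) for n in self.names]

    def contains(self, params: dict) -> bool:
        return all(lo <= params[n] <= hi
                   for n, (lo, hi) in zip(self.names, self.bounds()))


@dataclass
class RFParams:
    """Concrete random-forest configuration (Gini impurity throughout)."""

    n_trees: int = 100
    max_depth: int | None = None
    min_samples_split: int = 2
    min_samples_leaf: int = 1

    def build(self, seed: int = 0) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees, max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            criterion="gini", random_state=seed,
        )


# ---------------------------------------------------------------------------
# folds and metrics
# ---------------------------------------------------------------------------


def stratified_folds(df: pd.DataFrame, k: int = 4, seed: int = 0) -> np.ndarray:
    """Fold label per row from a shuffled stratified k-fold split.

    Rows are folded in a canonical order (sorted by ``subject_id`` when
    present), so the assignment is invariant to the row order of the table.
    """
    y = df["class"].to_numpy()
    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        raise ValueError(f"every class needs at least k={k} members")
    if "subject_id" in df.columns:
        order = np.argsort(df["subject_id"].to_numpy(), kind="stable")
    else:
        order = np.arange(len(df))
    folds = np.empty(len(df), dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for f, (_, test) in enumerate(skf.split(np.zeros(len(df)), y[order])):
        folds[order[test]] = f
    return folds


def confusion_counts(y_true, y_pred, positive) -> dict:
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    return {
        "TP": int(np.sum((yt == positive) & (yp == positive))),
        "TN": int(np.sum((yt != positive) & (yp != positive))),
        "FP": int(np.sum((yt != positive) & (yp == positive))),
        "FN": int(np.sum((yt == positive) & (yp != positive))),
    }


def metrics_from_confusion(c: dict) -> dict:
    """Accuracy / precision / recall / F1 from TP, TN, FP, FN counts."""
    n = c["TP"] + c["TN"] + c["FP"] + c["FN"]
    acc = (c["TP"] + c["TN"]) / n if n else np.nan
    prec = c["TP"] / (c["TP"] + c["FP"]) if c["TP"] + c["FP"] else np.nan
    rec = c["TP"] / (c["TP"] + c["FN"]) if c["TP"] + c["FN"] else np.nan
    f1 = (2 * prec * rec / (prec + rec)
          if np.isfinite(prec) and np.isfinite(rec) and (prec + rec) > 0 else np.nan)
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def log_loss_score(y_true, p_pos, eps: float = 1e-15) -> float:
    """Binary cross-entropy between 0/1 labels and positive-class probabilities."""
    y = np.asarray(y_true, dtype=float)
    p = np.clip(np.asarray(p_pos, dtype=float), eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def roc_auc(y_true, scores) -> float:
    """ROC AUC by the rank statistic (ties get average ranks).

    Equivalent to the concordant-pair probability with ties counted as 1/2.
    """
    y = np.asarray(y_true, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC AUC undefined with a single class")
    r = rankdata(scores)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# Bayesian hyperparameter optimisation
# ---------------------------------------------------------------------------


def _cv_accuracy(X, y, params: RFParams, k: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        rf = params.build(seed=seed)
        rf.fit(X[tr], y[tr])
        accs.append(float(np.mean(rf.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def bayes_opt_rf(df: pd.DataFrame, space: HyperSpace | None = None,
                 n_iter: int = 25, n_initial: int = 5, cv: int = 4,
                 seed: int = 0):
    """Gaussian-process Bayesian optimisation of the RF hyperparameters.

    A Matern-5/2 GP models mean stratified-CV accuracy over the normalised
    hyperparameter cube; the next point maximises expected improvement over
    random candidates.  Returns ``(best RFParams, trace DataFrame)``.
    """
    if n_iter < 5:
        raise ValueError("n_iter must be >= 5")
    space = space or HyperSpace()
    rng = np.random.default_rng(seed)
    feats = feature_columns(df)
    X = df[feats].to_numpy(dtype=float)
    y = (df["class"].to_numpy() == MINORITY_LABEL).astype(int)
    bounds = np.array(space.bounds(), dtype=float)

    def decode(u: np.ndarray) -> RFParams:
        vals = np.round(bounds[:, 0] + u * (bounds[:, 1] - bounds[:, 0])).astype(int)
        return RFParams(*[int(v) for v in vals])

    U, scores, trace = [], [], []
    for it in range(n_iter):
        if it < n_initial:
            u = rng.random(len(bounds))
        else:
            kernel = ConstantKernel(1.0) * Matern(length_scale=0.3, nu=2.5)
            gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-4,
                                          normalize_y=True, random_state=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(np.array(U), np.array(scores))
            cand = rng.random((256, len(bounds)))
            mu, sd = gp.predict(cand, return_std=True)
            best = max(scores)
            sd = np.maximum(sd, 1e-9)
            z = (mu - best) / sd
            ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
            u = cand[int(np.argmax(ei))]
        params = decode(u)
        score = _cv_accuracy(X, y, params, cv, seed)
        U.append(u)
        scores.append(score)
        trace.append({**{n: getattr(params, n if n != "n_trees" else "n_trees")
                         for n in space.names}, "cv_accuracy": score})
    best_idx = int(np.argmax(scores))
    return decode(U[best_idx]), pd.DataFrame(trace)


# ---------------------------------------------------------------------------
# strategy evaluation
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-fold and aggregated classification metrics for one configuration."""

    per_fold: pd.DataFrame
    summary: dict                 # metric -> (mean, sd)
    per_class: dict               # label -> {precision/recall/f1: (mean, sd)}
    strategy: str = "none"
    target_total: int | None = None

    def mean(self, metric: str) -> float:
        return self.summary[metric][0]


def _aggregate(per_fold: pd.DataFrame, cols) -> dict:
    out = {}
    for c in cols:
        vals = per_fold[c].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        out[c] = ((float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
                  if len(vals) else (np.nan, np.nan))
    return out


def evaluate_strategy(df: pd.DataFrame, balance_config: BalanceConfig,
                      rf_params: RFParams | None = None, seed: int = 0,
                      k: int = 4, pooled_augmentation: bool = False,
                      positive: str = MINORITY_LABEL) -> MetricsReport:
    """Stratified k-fold evaluation of one balancing strategy.

    Default scope balances each training split only and scores on the real
    held-out rows; ``pooled_augmentation=True`` balances the full table before
    splitting (synthetic rows then appear in test folds).  Undefined metrics
    on a fold (e.g. an empty test class) are recorded as NaN, not dropped.
    """
    rf_params = rf_params or RFParams()
    labels = sorted(df["class"].unique())
    negative = [l for l in labels if l != positive][0]

    if pooled_augmentation:
        work = balance(df, replace(balance_config, seed=balance_config.seed)).frame
        folds = stratified_folds(work, k=k, seed=seed)
    else:
        work = df
        folds = stratified_folds(work, k=k, seed=seed)

    feats = feature_columns(df)
    rows = []
    for f in range(k):
        train = work[folds != f]
        if "subject_id" in train.columns:  # canonical order: row-order invariance
            train = train.sort_values("subject_id")
        train = train.reset_index(drop=True)
        test = work[folds == f]
        if not pooled_augmentation and balance_config.strategy != "none":
            cfg = replace(balance_config,
                          seed=balance_config.seed * 1000 + f)
            bal = balance(train, cfg)
            train = bal.frame
        rf = rf_params.build(seed=seed)
        rf.fit(train[feats].to_numpy(), (train["class"] == positive).astype(int))
        y_true = (test["class"] == positive).to_numpy(int)
        p_pos = rf.predict_proba(test[feats].to_numpy())[:, list(rf.classes_).index(1)]
        y_pred = (p_pos >= 0.5).astype(int)

        cpos = confusion_counts(y_true, y_pred, 1)
        m = metrics_from_confusion(cpos)
        cneg = confusion_counts(1 - y_true, 1 - y_pred, 1)
        mneg = metrics_from_confusion(cneg)
        try:
            auc = roc_auc(y_true, p_pos)
        except ValueError:
            warnings.warn(f"fold {f}: single-class test fold, AUC undefined")
            auc = np.nan
        rows.append({
            "fold": f, "accuracy": m["accuracy"], "recall": m["recall"],
            "precision": m["precision"], "f1": m["f1"],
            "log_loss": log_loss_score(y_true, p_pos), "roc_auc": auc,
            f"precision_{positive}": m["precision"], f"recall_{positive}": m["recall"],
            f"f1_{positive}": m["f1"],
            f"precision_{negative}": mneg["precision"],
            f"recall_{negative}": mneg["recall"], f"f1_{negative}": mneg["f1"],
            **cpos,
        })
    per_fold = pd.DataFrame(rows)
    overall = _aggregate(per_fold,
                         ["accuracy", "recall", "precision", "f1",
                          "log_loss", "roc_auc"])
    per_class = {
        lab: _aggregate(per_fold, [f"precision_{lab}", f"recall_{lab}", f"f1_{lab}"])
        for lab in labels
    }
    return MetricsReport(per_fold=per_fold, summary=overall,
                         per_class=per_class,
                         strategy=balance_config.strategy,
                         target_total=balance_config.target_total)


def benchmark_all(df: pd.DataFrame, strategies=("none", "undersample",
                                                "oversample", "smote",
                                                "gan", "ctgan"),
                  sizes=(200, 1000), seeds=(0, 1, 2),
                  rf_params: RFParams | None = None,
                  net_config=None, pooled_augmentation: bool = False,
                  k: int = 4) -> pd.DataFrame:
    """Run every (strategy, size, seed) cell and return a long-format report.

    ``none`` and ``undersample`` ignore the size axis (run once per seed).
    Cells that fail are reported with an ``error`` note instead of aborting
    the whole benchmark.
    """
    from .balance import GanConfig

    if len(strategies) < 2:
        raise ValueError("benchmark needs at least two strategies to compare")
    net_config = net_config or GanConfig()
    records = []
    for strategy in strategies:
        strat_sizes = [None] if strategy in ("none", "undersample") else sizes
        for size in strat_sizes:
            for seed in seeds:
                cfg = BalanceConfig(strategy=strategy,
                                    target_total=size or 200,
                                    net_config=net_config, seed=seed)
                base = {"strategy": strategy, "N": size, "seed": seed}
                try:
                    rep = evaluate_strategy(df, cfg, rf_params=rf_params,
                                            seed=seed, k=k,
                                            pooled_augmentation=pooled_augmentation)
                except Exception as exc:  # propagate per cell
                    records.append({**base, "error": str(exc)})
                    continue
                row = {**base, "error": None}
                for metric, (mean, sd) in rep.summary.items():
                    row[metric] = mean
                    row[f"{metric}_sd"] = sd
                for lab, mm in rep.per_class.items():
                    for key, (mean, sd) in mm.items():
                        row[key] = mean
                        row[f"{key}_sd"] = sd
                records.append(row)
    return pd.DataFrame(records)


def summarize_benchmark(report: pd.DataFrame) -> pd.DataFrame:
    """Mean over seeds per (strategy, N) in the shape of the study's tables."""
    ok = report[report["error"].isna()] if "error" in report else report
    num = ok.select_dtypes("number").columns.difference(["seed", "N"])
    return (ok.groupby(["strategy", "N"], dropna=False)[list(num)]
            .mean().reset_index())
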