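"""End-to-end orchestration: simulate -> prep -> select -> balance ->
benchmark -> explain -> power, from a single validated config with global
seeding and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from . import __version__, balance as balance_mod, explain, model, power, prep, simdata
from ._seeding import derive_seed

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "runs/default",
    "pooled_augmentation": False,
    "simulate": {"n_minority": 30, "n_majority": 100, "outlier_rate": 0.0},
    "prep": {"iqr_fence": 1.5, "collinearity_threshold": 0.5,
             "keep_preferences": ["stance_phase", "HR_AP", "sLLE_AP"]},
    "balance": {"k_neighbors": 4, "epochs": 500, "noise_dim": 32,
                "batch_size": 16, "learning_rate": 2e-4, "adam_beta1": 0.5},
    "benchmark": {"strategies": ["none", "undersample", "oversample",
                                 "smote", "gan", "ctgan"],
                  "sizes": [200, 1000], "n_seeds": 3, "cv_folds": 4,
                  "rf_trees": 100},
    "explain": {"alpha": 0.05, "ctgan_epochs": 500},
    "power": {"delta": 0.51, "alpha": 0.05, "power": 0.95},
}


def validate_config(config: dict) -> list[str]:
    """Schema-check a run config; returns a list of error messages (empty = ok)."""
    errors = []
    ref = DEFAULT_CONFIG
    for key in config:
        if key not in ref:
            errors.append(f"unknown config section or key: {key!r}")
    for section in ("simulate", "prep", "balance", "benchmark", "explain", "power"):
        sub = config.get(section, {})
        if not isinstance(sub, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        for key in sub:
            if key not in ref[section]:
                errors.append(f"{section}: unknown key {key!r}")
    b = {**ref["balance"], **config.get("balance", {})}
    if b["k_neighbors"] < 1:
        errors.append("balance: k_neighbors must be >= 1")
    sim = {**ref["simulate"], **config.get("simulate", {})}
    if b["k_neighbors"] >= sim["n_minority"]:
        errors.append("balance: k_neighbors must be below the minority size")
    for strat in {**ref["benchmark"], **config.get("benchmark", {})}["strategies"]:
        if strat not in balance_mod.STRATEGIES:
            errors.append(f"benchmark: unknown strategy {strat!r}")
    if not isinstance(config.get("seed", 0), int):
        errors.append("seed must be an integer")
    return errors


def load_config(path) -> dict:
    return json.loads(Path(path).read_text())


def _merged(config: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in config.items():
        if isinstance(v, dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: dict | None = None) -> dict:
    """Execute the full study on simulated data; returns the run manifest.

    Stage seeds derive deterministically from the global seed and the stage
    name, so re-running the same config reproduces every artifact.
    """
    cfg = _merged(config or {})
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    manifest = {"version": __version__, "seed": seed, "config": cfg,
                "stages": {}, "artifacts": {}}

    def stage(name):
        manifest["stages"][name] = {"seed": derive_seed(seed, name)}
        return manifest["stages"][name]

    def save(df: pd.DataFrame, name: str):
        path = out_dir / name
        df.to_csv(path, index=False)
        manifest["artifacts"][name] = _sha256(path)
        return path

    # --- simulate -----------------------------------------------------
    st = stage("simulate")
    t0 = time.perf_counter()
    table = simdata.simulate_cohort(seed=st["seed"], **{
        k: v for k, v in cfg["simulate"].items()})
    save(table, "features_raw.csv")
    st["seconds"] = round(time.perf_counter() - t0, 3)

    # --- prep ---------------------------------------------------------
    st = stage("prep")
    t0 = time.perf_counter()
    cleaned, n_out, _ = prep.replace_outliers_iqr(table, fence=cfg["prep"]["iqr_fence"])
    transformed, _ = prep.power_transform(cleaned)
    standardized, _ = prep.standardize(transformed)
    retained, dropped = prep.collinearity_filter(
        standardized, threshold=cfg["prep"]["collinearity_threshold"],
        keep_preferences=tuple(cfg["prep"]["keep_preferences"]))
    sel = prep.rf_select_features(
        standardized[["subject_id", "class"] + retained], seed=st["seed"])
    selected = standardized[["subject_id", "class"] + sel.retained]
    stats = prep.group_compare(selected)
    save(selected, "features_selected.csv")
    save(stats, "group_compare.csv")
    st.update({"outliers_replaced": n_out, "dropped_collinear": dropped,
               "retained": sel.retained,
               "seconds": round(time.perf_counter() - t0, 3)})

    # --- benchmark ----------------------------------------------------
    st = stage("benchmark")
    t0 = time.perf_counter()
    bcfg = cfg["balance"]
    net = balance_mod.GanConfig(
        noise_dim=bcfg["noise_dim"], epochs=bcfg["epochs"],
        batch_size=bcfg["batch_size"], learning_rate=bcfg["learning_rate"],
        adam_beta1=bcfg["adam_beta1"])
    bench = model.benchmark_all(
        selected, strategies=tuple(cfg["benchmark"]["strategies"]),
        sizes=tuple(cfg["benchmark"]["sizes"]),
        seeds=tuple(derive_seed(seed, "benchmark", i)
                    for i in range(cfg["benchmark"]["n_seeds"])),
        rf_params=model.RFParams(n_trees=cfg["benchmark"]["rf_trees"]),
        net_config=net, pooled_augmentation=cfg["pooled_augmentation"],
        k=cfg["benchmark"]["cv_folds"])
    save(bench, "benchmark.csv")
    save(model.summarize_benchmark(bench), "benchmark_summary.csv")
    st["seconds"] = round(time.perf_counter() - t0, 3)

    # --- explain ------------------------------------------------------
    st = stage("explain")
    t0 = time.perf_counter()
    ccfg = balance_mod.BalanceConfig(
        strategy="ctgan", target_total=200, seed=st["seed"],
        net_config=balance_mod.GanConfig(epochs=cfg["explain"]["ctgan_epochs"]))
    bal = balance_mod.balance(selected, ccfg)
    minority = simdata.MINORITY_LABEL
    real_min = selected[selected["class"] == minority]
    synth_min = bal.synthetic_frame()
    synth_min = synth_min[synth_min["class"] == minority]
    rf = model.RFParams(n_trees=cfg["benchmark"]["rf_trees"]).build(seed=st["seed"])
    feats = prep.feature_columns(selected)
    rf.fit(bal.frame[feats].to_numpy(),
           (bal.frame["class"] == minority).astype(int))
    report = explain.consistency_report(
        real_min, synth_min if len(synth_min) else bal.frame,
        rf=rf, explain_df=selected, alpha=cfg["explain"]["alpha"])
    save(report["ks_table"], "ks_consistency.csv")
    save(report["shap_long"], "shap_values.csv")
    st.update({"n_consistent": report["n_consistent"],
               "n_features": report["n_features"],
               "shap_ranking": report["shap_ranking"],
               "seconds": round(time.perf_counter() - t0, 3)})

    # --- power --------------------------------------------------------
    st = stage("power")
    t0 = time.perf_counter()
    n_req = power.required_n_per_group(power.PowerSpec(
        delta=cfg["power"]["delta"], alpha=cfg["power"]["alpha"],
        power=cfg["power"]["power"]))
    st.update({"required_n_per_group": n_req,
               "seconds": round(time.perf_counter() - t0, 3)})

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
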