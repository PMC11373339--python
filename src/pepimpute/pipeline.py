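"""End-to-end benchmark driver.

Runs one shared mask plan, every requested imputation method on the same
training view, and the full evaluation stack, producing a machine-readable
report.  One MaskPlan per run is mandatory — the paired Wilcoxon
comparison requires all methods to see the identical test set — and the
plan is serialized alongside the report for audit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from .baselines import run_imputer
from .datamodel import (
    DataError,
    MaskPlan,
    PeptideDataset,
    log_standardize,
    make_masked_split,
)
from .graph import build_peptide_graph, graph_stats
from .model import ModelConfig, impute, train

GNN_METHOD = "pepermint"

__all__ = [
    "GNN_METHOD",
    "desk_model_config",
    "run_methods",
    "run_benchmark",
    "write_report",
    "plan_to_json",
    "plan_from_json",
]


def desk_model_config(seed: int = 0, **overrides) -> ModelConfig:
    """Compact training configuration for the synthetic presets.

    Fits the `medium` preset in roughly two minutes on one CPU core while
    preserving the full architecture; used by the documented benchmark
    runs.  Full-size defaults live in :class:`ModelConfig`.
    """
    params = dict(
        attention_heads=8,
        epoch_size=150,
        max_epochs=12,
        patience=3,
        learning_rate=1e-3,
        round2_learning_rate=1e-3,
        weight_decay=1e-2,
        dropout=0.2,
        seed=seed,
    )
    params.update(overrides)
    return ModelConfig(**params)


def plan_to_json(plan: MaskPlan) -> dict:
    return {
        "mechanism": plan.mechanism,
        "test_idx": plan.test_idx.tolist(),
        "val_idx": plan.val_idx.tolist(),
        "truth": {f"{i},{j}": v for (i, j), v in sorted(plan.truth.items())},
    }


def plan_from_json(d: dict) -> MaskPlan:
    truth = {tuple(int(x) for x in k.split(",")): float(v) for k, v in d["truth"].items()}
    return MaskPlan(np.array(d["test_idx"]), np.array(d["val_idx"]), truth, d["mechanism"])


def run_methods(
    ds: PeptideDataset,
    plan: MaskPlan,
    methods,
    embeddings: np.ndarray | None = None,
    model_cfg: ModelConfig | None = None,
    seed: int = 0,
    baseline_params: dict | None = None,
):
    """Impute with every method on the identical training view.

    Returns ``(std, state, outputs)`` where ``outputs[name]`` is a dict
    with the completed standardized matrix (``pred_std``), and for the GNN
    method also ``sigma`` and training info.
    """
    baseline_params = baseline_params or {}
    std, state = log_standardize(ds)
    train_view = plan.apply(std)
    outputs: dict = {}
    for name in methods:
        if name.lower() == GNN_METHOD:
            if embeddings is None:
                raise DataError("the GNN method needs a sequence-embedding matrix")
            cfg = model_cfg or ModelConfig(seed=seed)
            graph = build_peptide_graph(ds)
            model, info = train(std, plan, embeddings, graph, cfg)
            result = impute(model, train_view, state, embeddings)
            outputs[GNN_METHOD] = {
                "pred_std": result.mu,
                "sigma": result.sigma,
                "result": result,
                "train_info": {
                    "best_val_mse_round1": info["best_val_mse_round1"],
                    "best_val_round2": info["best_val_round2"],
                    "epochs_round1": len(info["round1_val_mse"]) - 1,
                    "epochs_round2": len(info["round2_val_history"]) - 1,
                },
            }
        else:
            completed = run_imputer(name, train_view, seed=seed, **baseline_params.get(name, {}))
            outputs[name] = {"pred_std": completed, "sigma": None}
    return std, state, outputs


def run_benchmark(
    ds: PeptideDataset,
    methods,
    plan: MaskPlan | None = None,
    embeddings: np.ndarray | None = None,
    model_cfg: ModelConfig | None = None,
    seed: int = 0,
    test_frac: float = 0.10,
    val_frac: float = 0.10,
    baseline_params: dict | None = None,
    bins=(0.0, 0.25, 0.5, 0.75, 1.0),
    bootstrap_reps: int = 1000,
    alpha: float = 0.05,
    fdr_mark: float = 0.05,
    de_labels: np.ndarray | None = None,
    sigma_thresholds=(0.2, 0.5, 1.0),
) -> dict:
    """Full benchmark: one mask plan, all methods, all evaluation surfaces.

    Returns a JSON-serializable report dict; DE surfaces are included when
    the dataset carries two sample groups and `de_labels` is given.
    """
    if len(methods) < 2:
        raise DataError("benchmark needs >= 2 methods")
    if plan is None:
        plan = make_masked_split(ds, test_frac=test_frac, val_frac=val_frac, seed=seed)
    std, state, outputs = run_methods(
        ds, plan, methods, embeddings=embeddings, model_cfg=model_cfg, seed=seed, baseline_params=baseline_params
    )
    train_view = plan.apply(std)
    pep_missing = ds.peptide_missing_fractions()

    tables: dict = {}
    report: dict = {
        "seed": seed,
        "mechanism": plan.mechanism,
        "n_peptides": ds.n_peptides,
        "n_samples": ds.n_samples,
        "n_test_positions": int(len(plan.test_idx)),
        "graph": graph_stats(build_peptide_graph(ds)),
        "methods": {},
        "plan": plan_to_json(plan),
    }
    for name, out in outputs.items():
        table = ev.build_error_table(
            name, out["pred_std"], plan, ds.peptide_ids, ds.sample_ids, pep_missing, sigma=out["sigma"]
        )
        tables[name] = table
        sw = ev.samplewise_rmse(table)
        entry = {
            "samplewise_rmse": {k: float(v) for k, v in sw.items()},
            "rmse": ev.dataset_rmse(table),
            "mae": ev.dataset_mae(table),
            "rmse_ci95": list(ev.bootstrap_ci(sw.to_numpy(), reps=bootstrap_reps, seed=seed)),
            "stratified_rmse": {
                r["bin"]: r["rmse"] for _, r in ev.stratified_rmse(table, bins).iterrows()
            },
        }
        if out["sigma"] is not None:
            qr = ev.uncertainty_quantile_rmse(table)
            entry["uncertainty_quantile_rmse"] = {str(r["quantile"]): r["rmse"] for _, r in qr.iterrows()}
            from scipy.stats import spearmanr

            entry["sigma_error_spearman"] = float(spearmanr(table["sigma"], table["abs_error"]).statistic)
        if "train_info" in out:
            entry["train_info"] = out["train_info"]
        report["methods"][name] = entry

    pmat, wins = ev.pairwise_wilcoxon_matrix(tables, alpha=alpha)
    report["wilcoxon_p"] = {a: {b: float(pmat.loc[a, b]) for b in pmat.columns} for a in pmat.index}
    report["win_counts"] = {k: float(v) for k, v in wins.items()}

    groups = None
    if ds.sample_groups is not None:
        groups = np.array([ds.sample_groups[s] for s in ds.sample_ids])
    if groups is not None and de_labels is not None and len(set(groups.tolist())) == 2:
        de_report: dict = {}
        unimputed = ev.de_from_matrix(train_view, groups, de_labels, fdr_mark=fdr_mark)
        de_report["no_imputation"] = {"auc": unimputed.auc, "n_excluded": unimputed.n_excluded}
        for name, out in outputs.items():
            completed_std = np.where(np.isfinite(train_view), train_view, out["pred_std"])
            de = ev.de_from_matrix(completed_std, groups, de_labels, fdr_mark=fdr_mark)
            de_report[name] = {"auc": de.auc, "fdr_point": list(de.fdr_point)}
            if out["sigma"] is not None:
                filtered = {}
                for thr in sigma_thresholds:
                    fde = ev.uncertainty_filtered_de(
                        completed_std, ~np.isfinite(train_view), out["sigma"], groups, de_labels, thr, fdr_mark=fdr_mark
                    )
                    filtered[str(thr)] = {"auc": fde.auc, "n_excluded": fde.n_excluded}
                de_report[name]["uncertainty_filtered"] = filtered
        report["differential_expression"] = de_report

    report["error_tables"] = {name: t.drop(columns=["method"]).to_dict("list") for name, t in tables.items()}
    return report


def write_report(report: dict, outdir):
    """Serialize the report: report.json, plan.json, and TSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = report.pop("error_tables", {})
    plan = report.get("plan")
    with open(outdir / "plan.json", "w") as fh:
        json.dump(plan, fh, sort_keys=True, indent=1)
    slim = {k: v for k, v in report.items() if k != "plan"}
    with open(outdir / "report.json", "w") as fh:
        json.dump(slim, fh, sort_keys=True, indent=1)
    for name, cols in tables.items():
        pd.DataFrame(cols).to_csv(outdir / f"errors_{name}.tsv", sep="\t", index=False)
    rows = []
    for name, entry in report["methods"].items():
        for sample, value in entry["samplewise_rmse"].items():
            rows.append({"method": name, "sample_id": sample, "rmse": value})
    pd.DataFrame(rows).to_csv(outdir / "samplewise_rmse.tsv", sep="\t", index=False)
    report["error_tables"] = tables
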