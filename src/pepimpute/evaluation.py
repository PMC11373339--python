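"""Evaluation surfaces for imputation benchmarks.

Three complementary views of imputation quality:

* abundance error — sample-wise RMSE (with bootstrap CIs), dataset MAE,
  and RMSE stratified by each peptide's missingness fraction;
* pairwise significance — one-sided paired Wilcoxon signed-rank tests on
  absolute errors between every ordered pair of methods, Bonferroni
  corrected, aggregated into tournament win counts (a significant win
  scores 1, an insignificant comparison 0.5 to each side);
* differential expression — Welch's t-test per peptide between two
  condition groups, Benjamini-Hochberg correction, and ROC / PR curves
  against known DE labels, with the operating point at the 5% FDR cutoff
  marked.

Uncertainty diagnostics relate the model's predicted sigma to the actual
error (quantile-RMSE curves) and drive uncertainty-filtered DE, where
imputed values above a sigma cutoff are reverted to missing.

All error tables are tidy pandas DataFrames with one row per
(method, test position).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics
from statsmodels.stats.multitest import multipletests

from .datamodel import DataError, MaskPlan

logger = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "build_error_table",
    "samplewise_rmse",
    "dataset_rmse",
    "dataset_mae",
    "bootstrap_ci",
    "pairwise_wilcoxon_matrix",
    "stratified_rmse",
    "welch_de",
    "roc_pr",
    "uncertainty_quantile_rmse",
    "uncertainty_filtered_de",
]


@dataclass
class DEResult:
    """Per-peptide DE scores plus ROC/PR summaries."""

    table: pd.DataFrame  # columns: t, df, p, q, label, tested
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    pr_precision: np.ndarray
    pr_recall: np.ndarray
    fdr_point: tuple  # (FPR, TPR) of the q <= 0.05 rule
    n_excluded: int = 0
    sigma_threshold: float | None = None


# ---------------------------------------------------------------------------
# Error tables and abundance metrics


def build_error_table(
    method: str,
    pred_std: np.ndarray,
    plan: MaskPlan,
    peptide_ids,
    sample_ids,
    peptide_missing_frac: np.ndarray,
    sigma: np.ndarray | None = None,
) -> pd.DataFrame:
    """One row per test position: prediction, truth, absolute error,
    the peptide's missingness fraction, and predicted sigma if available."""
    rows = []
    for i, j in plan.test_idx:
        truth = plan.truth[(i, j)]
        pred = float(pred_std[i, j])
        rows.append(
            {
                "method": method,
                "peptide_id": peptide_ids[i],
                "sample_id": sample_ids[j],
                "row": int(i),
                "col": int(j),
                "pred": pred,
                "truth": truth,
                "abs_error": abs(pred - truth),
                "missing_frac": float(peptide_missing_frac[i]),
                "sigma": float(sigma[i, j]) if sigma is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _require_rows(errors: pd.DataFrame):
    if len(errors) == 0:
        raise DataError("empty error table")


def samplewise_rmse(errors: pd.DataFrame) -> pd.Series:
    """RMSE per sample over that sample's test positions."""
    _require_rows(errors)
    out = errors.groupby("sample_id", sort=True)["abs_error"].apply(
        lambda e: float(np.sqrt(np.mean(np.square(e))))
    )
    out.name = "rmse"
    return out


def dataset_rmse(errors: pd.DataFrame) -> float:
    _require_rows(errors)
    return float(np.sqrt(np.mean(np.square(errors["abs_error"]))))


def dataset_mae(errors: pd.DataFrame) -> float:
    """Mean absolute error over all test positions."""
    _require_rows(errors)
    return float(np.mean(errors["abs_error"]))


def bootstrap_ci(values, level: float = 0.95, reps: int = 1000, seed: int = 0, statistic=np.mean) -> tuple:
    """Nonparametric percentile bootstrap interval for `statistic`."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DataError("bootstrap needs >= 2 values")
    rng = np.random.default_rng(seed)
    stats_ = np.array(
        [statistic(values[rng.integers(0, values.size, size=values.size)]) for _ in range(reps)]
    )
    alpha = (1.0 - level) / 2
    return float(np.quantile(stats_, alpha)), float(np.quantile(stats_, 1 - alpha))


def stratified_rmse(errors: pd.DataFrame, bins) -> pd.DataFrame:
    """RMSE per missingness-fraction bin (bins = edges partitioning [0, 1];
    each bin is [lo, hi) except the last, which includes 1).  Rows: one per
    (method, bin); empty bins are omitted with a warning."""
    _require_rows(errors)
    edges = np.asarray(bins, dtype=float)
    if edges[0] != 0.0 or edges[-1] != 1.0 or np.any(np.diff(edges) <= 0):
        raise DataError("bins must be increasing edges from 0 to 1")
    idx = np.clip(np.searchsorted(edges, errors["missing_frac"], side="right") - 1, 0, len(edges) - 2)
    labels = [f"[{edges[i]:g},{edges[i+1]:g})" for i in range(len(edges) - 1)]
    work = errors.assign(bin=[labels[i] for i in idx])
    present = set(work["bin"])
    for lab in labels:
        if lab not in present:
            warnings.warn(f"missingness bin {lab} is empty; omitted")
    out = (
        work.groupby(["method", "bin"], sort=False)["abs_error"]
        .apply(lambda e: float(np.sqrt(np.mean(np.square(e)))))
        .rename("rmse")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# Pairwise significance


def pairwise_wilcoxon_matrix(tables: dict, alpha: float = 0.05) -> tuple:
    """One-sided paired Wilcoxon signed-rank tests between all method pairs.

    ``tables`` maps method name -> error table; all tables must cover the
    identical test-position set.  Entry (A, B) of the returned matrix is
    the Bonferroni-corrected p-value for H1: |errors_A| < |errors_B|
    (family = all k(k-1) ordered pairs).  Win counts follow the tournament
    rule: +1 to the significant winner of a pair, +0.5 to each side when
    neither direction is significant.
    """
    names = list(tables)
    if len(names) < 2:
        raise DataError("need >= 2 methods to compare")
    key_cols = ["row", "col"]
    ref = tables[names[0]].sort_values(key_cols).reset_index(drop=True)
    aligned = {}
    for name in names:
        t = tables[name].sort_values(key_cols).reset_index(drop=True)
        if len(t) != len(ref) or not (t[key_cols].values == ref[key_cols].values).all():
            raise DataError(f"method {name!r} evaluated on a different test set")
        aligned[name] = t["abs_error"].to_numpy()
    k = len(names)
    n_tests = k * (k - 1)
    pmat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for a, b in itertools.permutations(names, 2):
        d = aligned[a] - aligned[b]
        if np.all(d == 0):
            logger.info("all paired differences zero for (%s, %s); p = 1", a, b)
            p = 1.0
        else:
            p = float(stats.wilcoxon(d, alternative="less", zero_method="wilcox").pvalue)
        pmat.loc[a, b] = min(1.0, p * n_tests)
    wins = pd.Series(0.0, index=names)
    for a, b in itertools.combinations(names, 2):
        if pmat.loc[a, b] < alpha:
            wins[a] += 1.0
        elif pmat.loc[b, a] < alpha:
            wins[b] += 1.0
        else:
            wins[a] += 0.5
            wins[b] += 0.5
    return pmat, wins


# ---------------------------------------------------------------------------
# Differential expression


def welch_de(matrix: np.ndarray, groups) -> pd.DataFrame:
    """Welch's t-test per peptide row between the two condition groups.

    ``groups`` is a label per sample column with exactly two levels.
    Peptides with fewer than two observed values in either group are
    excluded from testing (``tested=False``, p/q = NaN).  BH adjustment is
    computed across tested peptides.
    """
    matrix = np.asarray(matrix, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    if len(levels) != 2:
        raise DataError(f"need exactly 2 conditions, got {levels}")
    ga = groups == levels[0]
    gb = groups == levels[1]
    n = matrix.shape[0]
    t = np.full(n, np.nan)
    df = np.full(n, np.nan)
    p = np.full(n, np.nan)
    tested = np.zeros(n, dtype=bool)
    for i in range(n):
        xa = matrix[i, ga]
        xb = matrix[i, gb]
        xa = xa[np.isfinite(xa)]
        xb = xb[np.isfinite(xb)]
        if xa.size < 2 or xb.size < 2:
            continue
        tested[i] = True
        va, vb = xa.var(ddof=1), xb.var(ddof=1)
        na, nb = xa.size, xb.size
        se2 = va / na + vb / nb
        if se2 == 0:
            t[i], df[i], p[i] = 0.0, na + nb - 2.0, 1.0
            continue
        t[i] = (xa.mean() - xb.mean()) / np.sqrt(se2)
        df[i] = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p[i] = 2.0 * stats.t.sf(abs(t[i]), df[i])
    q = np.full(n, np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    if (~tested).any():
        logger.info("welch_de: %d peptides excluded (fewer than 2 values per group)", int((~tested).sum()))
    return pd.DataFrame({"t": t, "df": df, "p": p, "q": q, "tested": tested})


def roc_pr(labels, qvalues, fdr_mark: float = 0.05) -> DEResult:
    """ROC and PR curves for DE detection from q-values (smaller = more
    significant), plus the operating point of the q <= `fdr_mark` rule."""
    labels = np.asarray(labels, dtype=bool)
    q = np.asarray(qvalues, dtype=float)
    if labels.all() or not labels.any():
        raise DataError("both DE classes must be present")
    score = -q
    fpr, tpr, _ = skmetrics.roc_curve(labels, score)
    auc = float(skmetrics.auc(fpr, tpr))
    precision, recall, _ = skmetrics.precision_recall_curve(labels, score)
    called = q <= fdr_mark
    tp = int(np.sum(called & labels))
    fp = int(np.sum(called & ~labels))
    point = (fp / max(1, int(np.sum(~labels))), tp / max(1, int(np.sum(labels))))
    table = pd.DataFrame({"q": q, "label": labels})
    return DEResult(
        table=table,
        roc_fpr=fpr,
        roc_tpr=tpr,
        auc=auc,
        pr_precision=precision,
        pr_recall=recall,
        fdr_point=point,
    )


def de_from_matrix(matrix: np.ndarray, groups, labels, fdr_mark: float = 0.05, untested_score: float | None = None) -> DEResult:
    """Welch + BH + ROC in one step.

    Peptides that cannot be tested are excluded from the ROC population
    (counted in ``n_excluded``); passing ``untested_score`` instead assigns
    them that q-value so they stay in the population.
    """
    de = welch_de(matrix, groups)
    labels = np.asarray(labels, dtype=bool)
    tested = de["tested"].to_numpy()
    q = de["q"].to_numpy().copy()
    if untested_score is None:
        keep = tested
        n_excluded = int((~tested).sum())
    else:
        q[~tested] = untested_score
        keep = np.ones(len(q), dtype=bool)
        n_excluded = 0
    result = roc_pr(labels[keep], q[keep], fdr_mark=fdr_mark)
    result.n_excluded = n_excluded
    result.table = de.assign(label=labels)
    return result


# ---------------------------------------------------------------------------
# Uncertainty diagnostics


def uncertainty_quantile_rmse(errors: pd.DataFrame, quantiles=(0.25, 0.5, 0.75, 1.0)) -> pd.DataFrame:
    """RMSE over the lowest-sigma fraction of test positions, per quantile."""
    _require_rows(errors)
    if errors["sigma"].isna().any():
        raise DataError("predicted sigma required for every test position")
    work = errors.sort_values("sigma", kind="stable").reset_index(drop=True)
    rows = []
    for qt in quantiles:
        count = max(1, int(np.ceil(qt * len(work))))
        sub = work.iloc[:count]
        rows.append({"quantile": qt, "n": count, "rmse": float(np.sqrt(np.mean(np.square(sub["abs_error"]))))})
    return pd.DataFrame(rows)


def uncertainty_filtered_de(
    completed_std: np.ndarray,
    imputed_mask: np.ndarray,
    sigma: np.ndarray,
    groups,
    labels,
    threshold: float,
    fdr_mark: float = 0.05,
    untested_score: float | None = None,
) -> DEResult:
    """DE detection after reverting unreliable imputations.

    Imputed entries with predicted sigma above `threshold` are set back to
    missing before the Welch/BH/ROC pipeline runs.  Peptides that then
    fail the two-per-group rule are excluded from scoring (counted).
    """
    if not threshold > 0:
        raise DataError("threshold must be > 0")
    matrix = np.asarray(completed_std, dtype=float).copy()
    revert = np.asarray(imputed_mask, dtype=bool) & (np.asarray(sigma, dtype=float) > threshold)
    matrix[revert] = np.nan
    result = de_from_matrix(matrix, groups, labels, fdr_mark=fdr_mark, untested_score=untested_score)
    result.sigma_threshold = float(threshold)
    return result
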