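"""Agreement and error statistics for the HR/EE estimators.

RMSE, MAE, R2 and MAPE between predictions and ground truth; Bland-Altman
mean error and 95% limits of agreement (ME +/- 1.96 SD of the differences,
sample SD); and the paired one-tailed t-test comparing the attention model
against its no-attention ablation subject by subject.

Sign convention: differences are estimated minus actual, so a positive mean
error means over-estimation. MAPE is stored as a fraction and scaled to
percent only for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class RegressionMetrics:
    rmse: float
    mae: float
    r2: float
    mape: float | None  # None when any y_true is zero
    n: int


@dataclass
class BlandAltmanResult:
    mean_error: float
    sd: float
    lower_loa: float
    upper_loa: float
    ci_multiplier: float = 1.96


@dataclass
class AblationComparison:
    """Per-subject metric pairs and one-tailed paired t-tests per metric.

    p-values test the alternative "with attention is better" (lower RMSE/MAE,
    higher R2).
    """

    subjects: list[str]
    with_attention: dict[str, np.ndarray]  # metric -> per-subject values
    without_attention: dict[str, np.ndarray]
    t_statistics: dict[str, float]
    p_values: dict[str, float]


def regression_metrics(y_true, y_pred) -> RegressionMetrics:
    """RMSE, MAE, R2 and MAPE of predictions against ground truth."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    n = len(y_true)
    if n < 2:
        raise ValueError("need at least 2 samples")
    err = y_true - y_pred
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant y_true: R2 undefined")
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    if np.any(y_true == 0):
        warnings.warn("y_true contains zeros; MAPE undefined", stacklevel=2)
        mape = None
    else:
        mape = float(np.mean(np.abs(err / y_true)))
    return RegressionMetrics(rmse=rmse, mae=mae, r2=r2, mape=mape, n=n)


def bland_altman(y_true, y_pred) -> BlandAltmanResult:
    """Mean error and 95% limits of agreement of (estimated - actual)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or len(y_true) < 2:
        raise ValueError("need two equal-length arrays of length >= 2")
    d = y_pred - y_true
    me = float(d.mean())
    sd = float(d.std(ddof=1))  # sample SD, standard Bland-Altman practice
    return BlandAltmanResult(
        mean_error=me,
        sd=sd,
        lower_loa=me - 1.96 * sd,
        upper_loa=me + 1.96 * sd,
    )


def _one_tailed_paired_p(with_vals: np.ndarray, without_vals: np.ndarray,
                         better: str) -> tuple[float, float]:
    """Paired t-test that 'with' is better; returns (t, p).

    ``better`` is "lower" for error metrics, "higher" for R2. Zero-variance
    differences are guarded: all-zero -> (0, 0.5); constant nonzero -> p 0 or
    1 by sign.
    """
    d = with_vals - without_vals
    if np.allclose(d.std(ddof=1) if len(d) > 1 else 0.0, 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 0.5
        favourable = d.mean() < 0 if better == "lower" else d.mean() > 0
        return (-np.inf if d.mean() < 0 else np.inf), (0.0 if favourable else 1.0)
    alternative = "less" if better == "lower" else "greater"
    t, p = sps.ttest_rel(with_vals, without_vals, alternative=alternative)
    return float(t), float(p)


def compare_ablation(
    fold_results_with, fold_results_without
) -> AblationComparison:
    """Subject-paired comparison of the attention and no-attention arms."""
    subj_with = [f.test_subject for f in fold_results_with]
    subj_without = [f.test_subject for f in fold_results_without]
    if sorted(subj_with) != sorted(subj_without):
        raise ValueError("both arms must cover the same subjects")
    order = {s: i for i, s in enumerate(subj_with)}
    fold_results_without = sorted(fold_results_without,
                                  key=lambda f: order[f.test_subject])
    metrics_with: dict[str, list] = {"rmse": [], "mae": [], "r2": []}
    metrics_without: dict[str, list] = {"rmse": [], "mae": [], "r2": []}
    for fw, fo in zip(fold_results_with, fold_results_without):
        mw = regression_metrics(fw.y_true, fw.y_pred)
        mo = regression_metrics(fo.y_true, fo.y_pred)
        for key in metrics_with:
            metrics_with[key].append(getattr(mw, key))
            metrics_without[key].append(getattr(mo, key))
    t_stats, p_vals = {}, {}
    for key, better in (("rmse", "lower"), ("mae", "lower"), ("r2", "higher")):
        w = np.array(metrics_with[key])
        o = np.array(metrics_without[key])
        t_stats[key], p_vals[key] = _one_tailed_paired_p(w, o, better)
    return AblationComparison(
        subjects=subj_with,
        with_attention={k: np.array(v) for k, v in metrics_with.items()},
        without_attention={k: np.array(v) for k, v in metrics_without.items()},
        t_statistics=t_stats,
        p_values=p_vals,
    )


def summarize_folds(fold_results) -> dict[str, tuple[float, float]]:
    """Mean +/- sd of RMSE/MAE/R2 across subjects (the usual reporting style)."""
    per = {"rmse": [], "mae": [], "r2": []}
    for f in fold_results:
        m = regression_metrics(f.y_true, f.y_pred)
        for k in per:
            per[k].append(getattr(m, k))
    return {k: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
            for k, v in per.items()}


def export_traces(fold_results, best_worst_by: str = "rmse",
                  out_dir=None) -> dict[str, dict]:
    """Best- and worst-subject prediction/reference series by a chosen metric.

    Returns {"best": {...}, "worst": {...}} with aligned REF/EST arrays; when
    ``out_dir`` is given, also writes one CSV per case.
    """
    if not fold_results:
        raise ValueError("no fold results")
    scored = []
    for f in fold_results:
        m = regression_metrics(f.y_true, f.y_pred)
        scored.append((getattr(m, best_worst_by), f))
    ascending = best_worst_by != "r2"  # errors: low is good; R2: high is good
    scored.sort(key=lambda sf: sf[0], reverse=not ascending)
    cases = {"best": scored[0][1], "worst": scored[-1][1]}
    out = {}
    for name, f in cases.items():
        out[name] = {
            "subject": f.test_subject,
            "ref": np.asarray(f.y_true),
            "est": np.asarray(f.y_pred),
        }
        if out_dir is not None:
            import pandas as pd
            from pathlib import Path

            pd.DataFrame({"ref": f.y_true, "est": f.y_pred}).to_csv(
                Path(out_dir) / f"trace_{name}_{f.test_subject}.csv", index=False
            )
    return out
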