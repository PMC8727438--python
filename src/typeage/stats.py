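"""Model performance metrics and brain-age-gap group comparisons.

Performance is summarised by RMSE, Breiman's pseudo R² (1 − MSE/Var, the
forest-community analogue of R², with a population-variance denominator) and
the median absolute error.  Group contrasts use rank-based tests: a paired
Wilcoxon signed-rank test between the two models' absolute errors, and
Wilcoxon rank-sum tests comparing raw and absolute prediction errors between
screen-positive and screen-negative subjects, with Holm–Bonferroni control
over that two-test family.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EvaluationReport:
    model_id: str
    partition: str
    rmse: float
    pseudo_r2: float
    median_abs_error: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroupComparison:
    comparison_id: str
    statistic_name: str          # "rank_sum_W" or "signed_rank_V"
    statistic: float
    p_raw: float
    p_adjusted: float
    group_medians: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _paired(pred, actual) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise ValueError("pred and actual must be 1-D arrays of equal length")
    if p.size == 0:
        raise ValueError("empty prediction vectors")
    return p, a


def rmse(pred, actual) -> float:
    """Root mean squared prediction error (years)."""
    p, a = _paired(pred, actual)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def pseudo_r_squared(pred, actual) -> float:
    """Breiman's pseudo R²: 1 − MSE / Var(actual) (n-denominator variance)."""
    p, a = _paired(pred, actual)
    var = float(np.var(a))
    if var == 0.0:
        raise ValueError("actual values have zero variance; pseudo R² undefined")
    return float(1.0 - np.mean((p - a) ** 2) / var)


def median_absolute_error(pred, actual) -> float:
    """Median of |pred − actual| (years)."""
    p, a = _paired(pred, actual)
    return float(np.median(np.abs(p - a)))


def evaluate(predictions: pd.DataFrame) -> EvaluationReport:
    """Evaluation report for one model's prediction records."""
    return EvaluationReport(
        model_id=str(predictions["model_id"].iloc[0]),
        partition=str(predictions["partition"].iloc[0]),
        rmse=rmse(predictions["age_pred"], predictions["age_true"]),
        pseudo_r2=pseudo_r_squared(predictions["age_pred"], predictions["age_true"]),
        median_abs_error=median_absolute_error(predictions["age_pred"], predictions["age_true"]),
    )


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm's step-down adjusted p-values, returned in input order.

    Sorted ascending, each raw p is multiplied by (k − rank + 1); a running
    maximum enforces monotonicity and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="holm")
    return adjusted


def _rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum; returns (W, p).

    W is the Mann–Whitney U of the first sample (the statistic R reports).
    The exact null is used for combined n ≤ 50 without ties, otherwise the
    normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 50 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_models_paired(abs_errors_m1, abs_errors_m2) -> GroupComparison:
    """Paired two-sided Wilcoxon signed-rank test between two models' absolute errors.

    The statistic V is the sum of ranks of positive (model 1 − model 2)
    differences, as R reports it; zero differences are dropped.  All-zero
    differences leave no test to run and raise.
    """
    a1 = np.asarray(abs_errors_m1, dtype=float)
    a2 = np.asarray(abs_errors_m2, dtype=float)
    if a1.shape != a2.shape:
        raise ValueError("paired error vectors must have equal length")
    d = a1 - a2
    if np.all(d == 0):
        raise ValueError("degenerate paired test: all differences are zero")
    two_sided = sps.wilcoxon(a1, a2, zero_method="wilcox", alternative="two-sided")
    greater = sps.wilcoxon(a1, a2, zero_method="wilcox", alternative="greater")
    return GroupComparison(
        comparison_id="model1_vs_model2_abs_error",
        statistic_name="signed_rank_V",
        statistic=float(greater.statistic),   # V = sum of positive ranks
        p_raw=float(two_sided.pvalue),
        p_adjusted=float(two_sided.pvalue),   # reported unadjusted (single test)
        group_medians={"model1": float(np.median(a1)), "model2": float(np.median(a2))},
    )


def compare_groups_by_mdq(predictions: pd.DataFrame) -> list[GroupComparison]:
    """Screen-positive vs screen-negative comparisons of prediction errors.

    Runs two-sided rank-sum tests on the raw errors and on the absolute
    errors (screen-negative group first, so W is the negatives' U), and
    applies Holm–Bonferroni across this two-test family.
    """
    flags = predictions["mdq_positive"].astype(bool)
    neg = predictions.loc[~flags]
    pos = predictions.loc[flags]
    for name, grp in (("mdq_negative", neg), ("mdq_positive", pos)):
        if len(grp) == 0:
            raise ValueError(f"group {name} is empty; cannot compare")
    results = []
    raw_p = []
    for err_col in ("raw_error", "abs_error"):
        w, p = _rank_sum(neg[err_col], pos[err_col])
        raw_p.append(p)
        results.append(GroupComparison(
            comparison_id=f"mdq_{err_col}",
            statistic_name="rank_sum_W",
            statistic=w, p_raw=p, p_adjusted=np.nan,
            group_medians={
                "mdq_negative": float(neg[err_col].median()),
                "mdq_positive": float(pos[err_col].median()),
            },
        ))
    adjusted = holm_bonferroni(raw_p)
    results = [
        GroupComparison(
            comparison_id=r.comparison_id, statistic_name=r.statistic_name,
            statistic=r.statistic, p_raw=r.p_raw, p_adjusted=float(adj),
            group_medians=r.group_medians,
        )
        for r, adj in zip(results, adjusted)
    ]
    return results
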