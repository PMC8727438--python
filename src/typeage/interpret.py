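"""Model interpretation: OOB permutation importance and Accumulated Local Effects.

Importance follows the classic forest convention: for each tree, each
observation is evaluated only where it is out of bag; a feature's importance
is the mean increase in OOB mean squared error after permuting that
feature's values among the tree's OOB observations, averaged over trees and
permutation repeats.

ALE curves/surfaces are computed natively against an arbitrary
``predict_fn(DataFrame) -> array`` so that closed-form predictors can serve
as oracles.  Bins are quantile (equal-count) based with duplicate edges
collapsed.  First-order curves accumulate per-bin mean finite differences
and are centered so the count-weighted mean of the interpolated effect over
the data is zero.  Second-order surfaces accumulate per-cell mean second
differences; additive row/column structure is then removed by a
count-weighted double-centering projection, which leaves a pure interaction
surface whose count-weighted row and column means vanish.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np
import pandas as pd


# --------------------------------------------------------------------------
# permutation importance
# --------------------------------------------------------------------------

def _inbag_indices(forest, n_samples: int) -> list[np.ndarray]:
    """Per-tree in-bag sample indices of a fitted bootstrap forest."""
    if not getattr(forest, "bootstrap", False):
        raise ValueError("forest was not trained with bootstrap; no OOB structure")
    try:
        return [np.asarray(s) for s in forest.estimators_samples_]
    except AttributeError:  # older sklearn
        from sklearn.ensemble._forest import _generate_sample_indices
        return [
            _generate_sample_indices(tree.random_state, n_samples, n_samples)
            for tree in forest.estimators_
        ]


def permutation_importance(bundle, seed: int = 0, n_permutations: int = 5,
                           rng=None) -> pd.DataFrame:
    """Out-of-bag permutation importance of a fitted :class:`AgeModelBundle`.

    Returns a table with ``feature``, ``delta_mse`` (mean OOB MSE increase,
    years²) and ``rank`` (1 = most important).  ``rng`` may be supplied
    instead of ``seed``; it only needs a ``permutation(n)`` method.
    """
    X, y = bundle.oob_X, bundle.oob_y
    if X is None or y is None:
        raise ValueError("bundle lacks the retained training matrix needed for OOB importance")
    forest = bundle.forest
    n, p = X.shape
    inbag = _inbag_indices(forest, n)
    if rng is None:
        rng = np.random.default_rng(seed)

    deltas = np.zeros((len(forest.estimators_), p))
    n_used = np.zeros(len(forest.estimators_), dtype=bool)
    for t, (tree, bag) in enumerate(zip(forest.estimators_, inbag)):
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[bag] = False
        idx = np.nonzero(oob_mask)[0]
        m = idx.size
        if m < 2:
            continue
        n_used[t] = True
        X_oob = X[idx]
        y_oob = y[idx]
        base_mse = float(np.mean((tree.predict(X_oob) - y_oob) ** 2))
        # one predict call per tree: stack (feature × repeat) permuted copies
        blocks = []
        for _ in range(n_permutations):
            perm = rng.permutation(m)
            for j in range(p):
                Xp = X_oob.copy()
                Xp[:, j] = X_oob[perm, j]
                blocks.append(Xp)
        preds = tree.predict(np.vstack(blocks)).reshape(n_permutations, p, m)
        mse = np.mean((preds - y_oob[None, None, :]) ** 2, axis=2)  # (reps, p)
        deltas[t] = mse.mean(axis=0) - base_mse
    if not n_used.any():
        raise ValueError("no tree had enough OOB observations")
    delta_mse = deltas[n_used].mean(axis=0)
    out = pd.DataFrame({"feature": bundle.feature_names, "delta_mse": delta_mse})
    out["rank"] = out["delta_mse"].rank(ascending=False, method="first").astype(int)
    return out.sort_values("rank").reset_index(drop=True)


# --------------------------------------------------------------------------
# accumulated local effects
# --------------------------------------------------------------------------

@dataclass
class ALECurve:
    """First-order ALE: effect (years) at bin edges plus per-bin counts."""

    feature: str
    edges: np.ndarray          # length K+1, strictly increasing
    effect: np.ndarray         # length K+1, centered
    counts: np.ndarray         # length K, sums to n

    def interpolate(self, x) -> np.ndarray:
        """Piecewise-linear effect evaluated at data values."""
        return np.interp(np.asarray(x, dtype=float), self.edges, self.effect)


@dataclass
class ALESurface:
    """Second-order ALE: per-cell interaction effect (years), doubly centered."""

    features: tuple[str, str]
    edges1: np.ndarray
    edges2: np.ndarray
    effect: np.ndarray         # shape (K1, K2)
    counts: np.ndarray         # shape (K1, K2)


def _quantile_edges(x: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(qs)
    if edges.size < 2:
        raise ValueError("feature is constant; no local effect estimable")
    return edges


def _bin_index(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin k for x in (edges[k], edges[k+1]]; the minimum maps to bin 0."""
    return np.clip(np.searchsorted(edges, x, side="left") - 1, 0, edges.size - 2)


def ale_first_order(predict_fn, data: pd.DataFrame, feature: str,
                    n_bins: int = 20) -> ALECurve:
    """First-order ALE curve of one feature.

    Per bin, the mean of ``f(upper edge) − f(lower edge)`` over the
    observations falling in the bin is accumulated along the edges; the curve
    is then centered so its interpolated, count-weighted mean over the data
    is zero.  Fewer than ``n_bins`` distinct quantiles reduce the bin count.
    """
    x = data[feature].to_numpy(dtype=float)
    edges = _quantile_edges(x, n_bins)
    K = edges.size - 1
    bins = _bin_index(x, edges)

    lo = data.copy()
    hi = data.copy()
    lo[feature] = edges[bins]
    hi[feature] = edges[bins + 1]
    diffs = np.asarray(predict_fn(hi), dtype=float) - np.asarray(predict_fn(lo), dtype=float)

    counts = np.bincount(bins, minlength=K)
    sums = np.bincount(bins, weights=diffs, minlength=K)
    means = np.divide(sums, counts, out=np.zeros(K), where=counts > 0)
    effect = np.concatenate([[0.0], np.cumsum(means)])
    effect = effect - np.mean(np.interp(x, edges, effect))
    return ALECurve(feature=feature, edges=edges, effect=effect, counts=counts)


def _fill_empty_cells(M: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Replace empty-cell means with the value of the nearest occupied cell."""
    out = M.copy()
    empty = counts == 0
    if not empty.any():
        return out
    occ = np.argwhere(~empty)
    if occ.size == 0:
        raise ValueError("no occupied cells")
    for j, k in np.argwhere(empty):
        d = np.abs(occ[:, 0] - j) + np.abs(occ[:, 1] - k)
        nearest = occ[np.argmin(d)]
        out[j, k] = M[nearest[0], nearest[1]]
    return out


def _remove_additive(W: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Project out count-weighted additive row/column structure exactly.

    Solves the weighted least-squares fit W ≈ a_j + b_k over occupied cells
    and subtracts it everywhere; the residual's count-weighted row and column
    means are zero by the normal equations.
    """
    K1, K2 = W.shape
    jj, kk = np.nonzero(counts > 0)
    if jj.size == 0:
        return W - W.mean()
    w = np.sqrt(counts[jj, kk].astype(float))
    design = np.zeros((jj.size, K1 + K2))
    design[np.arange(jj.size), jj] = 1.0
    design[np.arange(jj.size), K1 + kk] = 1.0
    coef, *_ = np.linalg.lstsq(design * w[:, None], W[jj, kk] * w, rcond=None)
    return W - coef[:K1, None] - coef[None, K1:]


def ale_second_order(predict_fn, data: pd.DataFrame, feature_pair: tuple[str, str],
                     n_bins: int = 10) -> ALESurface:
    """Second-order ALE surface for a pair of features.

    Per-cell mean second differences are accumulated over the 2-D grid
    (empty cells borrowing the nearest occupied cell's local effect), each
    cell takes the four-corner average of the accumulated surface, and the
    count-weighted additive row/column structure is projected out, leaving
    the pure interaction.
    """
    f1, f2 = feature_pair
    x1 = data[f1].to_numpy(dtype=float)
    x2 = data[f2].to_numpy(dtype=float)
    e1 = _quantile_edges(x1, n_bins)
    e2 = _quantile_edges(x2, n_bins)
    K1, K2 = e1.size - 1, e2.size - 1
    b1 = _bin_index(x1, e1)
    b2 = _bin_index(x2, e2)

    corners = []
    for v1, v2 in ((e1[b1 + 1], e2[b2 + 1]), (e1[b1], e2[b2 + 1]),
                   (e1[b1 + 1], e2[b2]), (e1[b1], e2[b2])):
        d = data.copy()
        d[f1] = v1
        d[f2] = v2
        corners.append(np.asarray(predict_fn(d), dtype=float))
    second_diff = corners[0] - corners[1] - corners[2] + corners[3]

    flat = b1 * K2 + b2
    counts = np.bincount(flat, minlength=K1 * K2).reshape(K1, K2)
    sums = np.bincount(flat, weights=second_diff, minlength=K1 * K2).reshape(K1, K2)
    M = np.divide(sums, counts, out=np.zeros((K1, K2)), where=counts > 0)
    M = _fill_empty_cells(M, counts)

    S = np.zeros((K1 + 1, K2 + 1))
    S[1:, 1:] = np.cumsum(np.cumsum(M, axis=0), axis=1)
    W = (S[1:, 1:] + S[:-1, 1:] + S[1:, :-1] + S[:-1, :-1]) / 4.0
    W = _remove_additive(W, counts)
    return ALESurface(features=(f1, f2), edges1=e1, edges2=e2, effect=W, counts=counts)


def forest_predict_fn(bundle):
    """Adapt an :class:`AgeModelBundle` to the ALE ``predict_fn`` interface."""
    from .model import _design_matrix, _impute

    def predict(df: pd.DataFrame) -> np.ndarray:
        X = _design_matrix(df, bundle.feature_names)
        return bundle.forest.predict(_impute(X, bundle.imputation_values.to_numpy()))

    return predict


# --------------------------------------------------------------------------
# report rendering
# --------------------------------------------------------------------------

def render_reports(out_dir, importance: pd.DataFrame | None = None,
                   curves=(), surfaces=(), predictions: pd.DataFrame | None = None,
                   comparisons=(), evaluations=(), tuning_traces: dict | None = None
                   ) -> list[Path]:
    """Write figures and a machine-readable JSON summary to ``out_dir``.

    Emits (when the corresponding input is given): an importance bar chart,
    one line plot per ALE curve, one heat map per ALE surface, raw/absolute
    error boxplots by screen status, tuning-curve plots, and
    ``summary.json`` collecting evaluations, comparisons and importance in
    one deterministic document.  Returns the written paths.
    """
    from matplotlib.figure import Figure

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(fig: Figure, name: str):
        path = out_dir / name
        fig.savefig(path, dpi=120, bbox_inches="tight")
        written.append(path)

    if importance is not None and len(importance):
        imp = importance.sort_values("delta_mse")
        fig = Figure(figsize=(7, max(3, 0.25 * len(imp))))
        ax = fig.subplots()
        ax.barh(imp["feature"], imp["delta_mse"], color="#4878d0")
        ax.set_xlabel("increase in OOB MSE (years$^2$)")
        ax.set_title("Permutation feature importance")
        save(fig, "importance.png")

    for curve in curves:
        fig = Figure(figsize=(5, 4))
        ax = fig.subplots()
        ax.plot(curve.edges, curve.effect, marker=".", color="#333")
        ax.axhline(0.0, lw=0.5, color="grey")
        ax.set_xlabel(curve.feature)
        ax.set_ylabel("ALE (years)")
        save(fig, f"ale_{curve.feature}.png")

    for surf in surfaces:
        fig = Figure(figsize=(5.5, 4.5))
        ax = fig.subplots()
        pc = ax.pcolormesh(surf.edges2, surf.edges1, surf.effect, shading="flat",
                           cmap="RdBu_r")
        fig.colorbar(pc, ax=ax, label="second-order ALE (years)")
        ax.set_xlabel(surf.features[1])
        ax.set_ylabel(surf.features[0])
        save(fig, f"ale2_{surf.features[0]}__{surf.features[1]}.png")

    if predictions is not None and len(predictions):
        fig = Figure(figsize=(8, 4))
        axes = fig.subplots(1, 2)
        flags = predictions["mdq_positive"].astype(bool)
        for ax, col, label in zip(axes, ("raw_error", "abs_error"),
                                  ("raw prediction error (years)", "absolute error (years)")):
            ax.boxplot([predictions.loc[~flags, col], predictions.loc[flags, col]],
                       tick_labels=["screen −", "screen +"])
            ax.set_ylabel(label)
        fig.suptitle("Prediction error by bipolar-screen status")
        save(fig, "error_by_mdq.png")

    if tuning_traces:
        fig = Figure(figsize=(5 * len(tuning_traces), 4))
        axes = np.atleast_1d(fig.subplots(1, len(tuning_traces)))
        for ax, (model_id, trace) in zip(axes, tuning_traces.items()):
            if trace is None or trace["cv_rmse"].isna().all():
                continue
            ax.plot(trace["mtry"], trace["cv_rmse"], marker="o")
            ax.set_xlabel("mtry")
            ax.set_ylabel("CV RMSE (years)")
            ax.set_title(model_id)
        save(fig, "tuning.png")

    summary = {
        "evaluation": [e.to_dict() for e in evaluations],
        "group_comparisons": [c.to_dict() for c in comparisons],
        "importance": (importance.to_dict(orient="records")
                       if importance is not None else []),
        "ale_features": [c.feature for c in curves],
        "ale_interactions": [list(s.features) for s in surfaces],
    }
    path = out_dir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(path)
    return written
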