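"""Random-forest age regression: split, mtry tuning, fitting, prediction.

Two stepwise models are supported: Model 1 uses the 30 typing features only;
Model 2 adds the gender indicator and the bipolar-screen status.  The
``mtry`` hyperparameter (features considered per split) is tuned by grid
search under repeated k-fold cross-validation, minimising RMSE; the fitted
bundle stores the tuning trace, the training-median imputation values and
the out-of-bag machinery needed for permutation importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold

from .features import MODEL1_PREDICTORS, MODEL2_PREDICTORS

MODEL_PREDICTORS = {
    "model1_typing_only": MODEL1_PREDICTORS,
    "model2_plus_gender_mdq": MODEL2_PREDICTORS,
}

#: min_samples_leaf mirrors the regression default terminal-node size of the
#: classic R forest implementation
_NODESIZE = 5


@dataclass(frozen=True)
class TuneConfig:
    """Grid-search / cross-validation configuration."""

    mtry_grid: tuple[int, ...] = tuple(range(1, 31))
    cv_folds: int = 10
    cv_repeats: int = 3
    n_trees: int = 500
    split_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if len(self.mtry_grid) == 0:
            raise ValueError("mtry_grid must be non-empty")
        if any(m < 1 for m in self.mtry_grid):
            raise ValueError("mtry values must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")


@dataclass
class AgeModelBundle:
    """A fitted age model plus everything needed to reuse and interrogate it."""

    model_id: str
    forest: RandomForestRegressor
    chosen_mtry: int
    tuning_trace: pd.DataFrame            # columns: mtry, cv_rmse
    feature_names: list[str]
    imputation_values: pd.Series          # training medians per feature
    training_subject_ids: list[str]
    oob_X: np.ndarray = field(repr=False, default=None)
    oob_y: np.ndarray = field(repr=False, default=None)


def split_train_validation(subject_ids, split_fraction: float = 0.75,
                           seed: int = 0) -> tuple[list[str], list[str]]:
    """Seeded simple random 75:25 split into training and validation ids.

    The training set gets ``ceil(split_fraction * n)`` subjects; e.g. 344
    subjects split 258/86.
    """
    ids = list(subject_ids)
    n = len(ids)
    if n < 4:
        raise ValueError("need at least 4 subjects to split")
    if not (0.0 < split_fraction < 1.0):
        raise ValueError("split_fraction must be in (0, 1)")
    n_train = int(np.ceil(split_fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [ids[i] for i in sorted(perm[:n_train])]
    valid = [ids[i] for i in sorted(perm[n_train:])]
    return train, valid


def _design_matrix(features: pd.DataFrame, names: list[str]) -> np.ndarray:
    missing = [c for c in names if c not in features.columns]
    if missing:
        raise KeyError(f"feature table is missing predictor column(s) {missing}")
    return features.loc[:, names].astype(float).to_numpy()


def _impute(X: np.ndarray, medians: np.ndarray) -> np.ndarray:
    out = X.copy()
    nan = np.isnan(out)
    if nan.any():
        out[nan] = np.take(medians, np.nonzero(nan)[1])
    return out


def tune_mtry(train_features: pd.DataFrame, train_ages, config: TuneConfig,
              model_id: str = "model1_typing_only") -> tuple[int, pd.DataFrame]:
    """Grid-search mtry by repeated k-fold CV, minimising mean fold RMSE.

    Fold RMSEs are averaged (not pooled) over folds × repeats.  Grid values
    exceeding the predictor count are skipped with a warning; ties in the
    trace resolve to the smallest mtry.  Imputation medians are recomputed
    from each fold's training part to avoid leakage.
    """
    import warnings

    names = MODEL_PREDICTORS[model_id]
    X = _design_matrix(train_features, names)
    y = np.asarray(train_ages, dtype=float)
    p = X.shape[1]
    grid = []
    for m in config.mtry_grid:
        if m > p:
            warnings.warn(f"mtry={m} exceeds the {p} available predictors; skipped")
        else:
            grid.append(int(m))
    if not grid:
        raise ValueError("no usable mtry values in the grid")

    cv = RepeatedKFold(n_splits=config.cv_folds, n_repeats=config.cv_repeats,
                       random_state=config.seed % (2**31))
    folds = list(cv.split(X))
    trace = []
    for m in grid:
        fold_rmse = []
        for k, (tr, te) in enumerate(folds):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                med = np.nanmedian(X[tr], axis=0)
            med = np.where(np.isnan(med), 0.0, med)  # fold-local all-missing column
            rf = RandomForestRegressor(
                n_estimators=config.n_trees, max_features=m,
                min_samples_leaf=_NODESIZE, bootstrap=True, n_jobs=1,
                random_state=(config.seed * 1000 + k) % (2**31),
            )
            rf.fit(_impute(X[tr], med), y[tr])
            pred = rf.predict(_impute(X[te], med))
            fold_rmse.append(float(np.sqrt(np.mean((pred - y[te]) ** 2))))
        trace.append({"mtry": m, "cv_rmse": float(np.mean(fold_rmse))})
    trace = pd.DataFrame(trace)
    chosen = int(trace.loc[trace["cv_rmse"].idxmin(), "mtry"])  # idxmin → first/smallest on ties
    return chosen, trace


def fit_age_model(train_features: pd.DataFrame, train_ages, model_id: str,
                  chosen_mtry: int, config: TuneConfig,
                  tuning_trace: pd.DataFrame | None = None) -> AgeModelBundle:
    """Fit the final forest with the chosen mtry on the full training set.

    Missing feature values are imputed with training medians (stored in the
    bundle for reuse at prediction time); a feature that is missing for every
    training subject is an error.
    """
    names = MODEL_PREDICTORS[model_id]
    X = _design_matrix(train_features, names)
    y = np.asarray(train_ages, dtype=float)
    if np.isnan(y).any():
        raise ValueError("training ages must not be missing")
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        bad = [names[j] for j in np.nonzero(all_missing)[0]]
        raise ValueError(f"feature(s) entirely missing in training data: {bad}")
    medians = np.nanmedian(X, axis=0)
    Xi = _impute(X, medians)
    rf = RandomForestRegressor(
        n_estimators=config.n_trees, max_features=int(chosen_mtry),
        min_samples_leaf=_NODESIZE, bootstrap=True, oob_score=True, n_jobs=1,
        random_state=config.seed % (2**31),
    )
    rf.fit(Xi, y)
    if tuning_trace is None:
        tuning_trace = pd.DataFrame({"mtry": [int(chosen_mtry)], "cv_rmse": [np.nan]})
    ids = (train_features["subject_id"].astype(str).tolist()
           if "subject_id" in train_features.columns else [str(i) for i in range(len(y))])
    return AgeModelBundle(
        model_id=model_id, forest=rf, chosen_mtry=int(chosen_mtry),
        tuning_trace=tuning_trace, feature_names=list(names),
        imputation_values=pd.Series(medians, index=names),
        training_subject_ids=ids, oob_X=Xi, oob_y=y,
    )


def train_age_model(train_features: pd.DataFrame, model_id: str,
                    config: TuneConfig, tune: bool = True,
                    fixed_mtry: int | None = None) -> AgeModelBundle:
    """Convenience wrapper: (optionally) tune mtry, then fit.

    ``tune=False`` with ``fixed_mtry`` skips the grid search — useful for
    replicate studies where the tuning curve is not of interest.
    """
    y = train_features["age"]
    if tune:
        chosen, trace = tune_mtry(train_features, y, config, model_id)
    else:
        if fixed_mtry is None:
            raise ValueError("fixed_mtry is required when tune=False")
        chosen, trace = int(fixed_mtry), None
    return fit_age_model(train_features, y, model_id, chosen, config, trace)


def predict_age(bundle: AgeModelBundle, features: pd.DataFrame,
                partition: str = "validation") -> pd.DataFrame:
    """Per-subject prediction records for a feature table.

    Missing values are imputed with the bundle's stored training medians.
    ``raw_error`` is predicted minus true age (positive = predicted older);
    ``abs_error`` its magnitude.
    """
    X = _design_matrix(features, bundle.feature_names)
    Xi = _impute(X, bundle.imputation_values.to_numpy())
    pred = bundle.forest.predict(Xi)
    out = pd.DataFrame({
        "subject_id": features["subject_id"].astype(str).to_numpy(),
        "age_true": features["age"].astype(float).to_numpy(),
        "age_pred": pred,
    })
    out["raw_error"] = out["age_pred"] - out["age_true"]
    out["abs_error"] = out["raw_error"].abs()
    out["mdq_positive"] = features["mdq_positive"].to_numpy()
    out["partition"] = partition
    out["model_id"] = bundle.model_id
    return out
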