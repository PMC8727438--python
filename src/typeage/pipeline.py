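"""End-to-end orchestration: simulate → featurize → train → evaluate → interpret.

One master seed deterministically derives an independent seed per stage via
``numpy.random.SeedSequence([master_seed, stage_index])``, so each stage can
be re-run in isolation and two runs with the same master seed produce
byte-identical JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .features import SampleEntropyParams, compute_feature_table, filter_participants
from .model import TuneConfig, predict_age, split_train_validation, train_age_model
from .simulate import CohortParams, generate_cohort
from .stats import compare_groups_by_mdq, compare_models_paired, evaluate
from .interpret import (ale_first_order, ale_second_order, forest_predict_fn,
                        permutation_importance, render_reports)

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "split", "model1", "model2", "interpret")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([int(master_seed), idx]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, with one master seed."""

    cohort: CohortParams = field(default_factory=CohortParams)
    tune: TuneConfig = field(default_factory=TuneConfig)
    entropy: SampleEntropyParams = field(default_factory=SampleEntropyParams)
    alpha: float = 0.05
    min_weeks: float = 12.0
    apply_inclusion_filter: bool = True
    tune_mtry: bool = True
    fixed_mtry: int = 10
    n_ale_curves: int = 4
    master_seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        cohort = CohortParams(**{k: tuple(v) if k == "age_range" else v
                                 for k, v in raw.pop("cohort", {}).items()})
        tune_d = raw.pop("tune", {})
        if "mtry_grid" in tune_d:
            tune_d["mtry_grid"] = tuple(int(m) for m in tune_d["mtry_grid"])
        tune = TuneConfig(**tune_d)
        entropy = SampleEntropyParams(**raw.pop("entropy", {}))
        return cls(cohort=cohort, tune=tune, entropy=entropy, **raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["age_range"] = list(d["cohort"]["age_range"])
        d["tune"]["mtry_grid"] = list(d["tune"]["mtry_grid"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, out_dir,
                 events: pd.DataFrame | None = None,
                 metadata: pd.DataFrame | None = None,
                 write_figures: bool = True) -> dict:
    """Run the full analysis and write its artifacts under ``out_dir``.

    When ``events``/``metadata`` are not supplied, a synthetic cohort is
    generated from ``config.cohort`` (stage-seeded from the master seed).
    Writes features.csv, tuning traces, predictions.csv, evaluation.json,
    group_comparison.json, figures/ and a manifest, and returns the in-memory
    results dictionary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"master_seed": config.master_seed, "stage_seeds": {}, "inputs": {}}

    # -- stage: data ---------------------------------------------------------
    if events is None or metadata is None:
        seed = stage_seed(config.master_seed, "simulate")
        manifest["stage_seeds"]["simulate"] = seed
        cohort = dataclasses.replace(config.cohort, seed=seed)
        metadata, events, profiles = generate_cohort(cohort)
        tio.write_event_log(events, out_dir / "events.csv")
        tio.write_metadata(metadata, out_dir / "metadata.csv")
        profiles.to_csv(out_dir / "truth.csv", index=False, float_format="%.12g")
    for name in ("events.csv", "metadata.csv"):
        p = out_dir / name
        if p.exists():
            manifest["inputs"][name] = _sha256(p)

    # -- stage: inclusion filter + features ---------------------------------
    if config.apply_inclusion_filter:
        included, report = filter_participants(events, config.min_weeks)
        report.to_csv(out_dir / "inclusion_report.csv", index=False, float_format="%.12g")
        events = events[events["subject_id"].isin(included)]
        logger.info("inclusion filter kept %d/%d subjects", len(included), len(report))
    features = compute_feature_table(events, metadata, config.entropy)
    tio.write_feature_table(features, out_dir / "features.csv")

    # -- stage: split + models ----------------------------------------------
    split_rs = stage_seed(config.master_seed, "split")
    manifest["stage_seeds"]["split"] = split_rs
    train_ids, valid_ids = split_train_validation(
        features["subject_id"], config.tune.split_fraction, split_rs)
    train_df = features[features["subject_id"].isin(train_ids)].reset_index(drop=True)
    valid_df = features[features["subject_id"].isin(valid_ids)].reset_index(drop=True)

    bundles, predictions, evaluations, traces = {}, [], [], {}
    for model_id in ("model1_typing_only", "model2_plus_gender_mdq"):
        seed = stage_seed(config.master_seed, "model1" if model_id.startswith("model1") else "model2")
        manifest["stage_seeds"][model_id] = seed
        tcfg = dataclasses.replace(config.tune, seed=seed)
        bundle = train_age_model(train_df, model_id, tcfg,
                                 tune=config.tune_mtry, fixed_mtry=config.fixed_mtry)
        bundles[model_id] = bundle
        if bundle.tuning_trace is not None:
            bundle.tuning_trace.to_csv(out_dir / f"tuning_trace_{model_id}.csv", index=False)
            traces[model_id] = bundle.tuning_trace
        predictions.append(predict_age(bundle, train_df, partition="train"))
        predictions.append(predict_age(bundle, valid_df, partition="validation"))
    predictions = pd.concat(predictions, ignore_index=True)
    predictions.to_csv(out_dir / "predictions.csv", index=False, float_format="%.12g")

    # -- stage: evaluation ---------------------------------------------------
    for (model_id, partition), grp in predictions.groupby(["model_id", "partition"]):
        evaluations.append(evaluate(grp))
    val = predictions[predictions["partition"] == "validation"]
    v1 = val[val["model_id"] == "model1_typing_only"].set_index("subject_id")
    v2 = val[val["model_id"] == "model2_plus_gender_mdq"].set_index("subject_id")
    common = v1.index.intersection(v2.index)
    try:
        model_cmp = compare_models_paired(
            v1.loc[common, "abs_error"], v2.loc[common, "abs_error"]).to_dict()
    except ValueError as exc:
        model_cmp = {"error": str(exc)}
    evaluation_doc = {
        "models": {e.model_id: {} for e in evaluations},
        "model_comparison_abs_error": model_cmp,
        "chosen_mtry": {mid: b.chosen_mtry for mid, b in bundles.items()},
        "n_train": len(train_df),
        "n_validation": len(valid_df),
    }
    for e in evaluations:
        evaluation_doc["models"].setdefault(e.model_id, {})[e.partition] = {
            "rmse": e.rmse, "pseudo_r2": e.pseudo_r2, "median_abs_error": e.median_abs_error,
        }
    _write_json(evaluation_doc, out_dir / "evaluation.json")

    # -- stage: MDQ group comparison (Model 2, validation) --------------------
    val2 = val[val["model_id"] == "model2_plus_gender_mdq"]
    comparisons = compare_groups_by_mdq(val2)
    comparison_doc = {
        "alpha": config.alpha,
        "comparisons": [c.to_dict() for c in comparisons],
        "n_by_group": {
            "mdq_negative": int((~val2["mdq_positive"].astype(bool)).sum()),
            "mdq_positive": int(val2["mdq_positive"].astype(bool).sum()),
        },
    }
    _write_json(comparison_doc, out_dir / "group_comparison.json")

    # -- stage: interpretation (Model 2) --------------------------------------
    seed = stage_seed(config.master_seed, "interpret")
    manifest["stage_seeds"]["interpret"] = seed
    bundle2 = bundles["model2_plus_gender_mdq"]
    importance = permutation_importance(bundle2, seed=seed)
    importance.to_csv(out_dir / "importance.csv", index=False, float_format="%.12g")
    curves, surfaces = [], []
    if write_figures:
        fn = forest_predict_fn(bundle2)
        # ALE is computed on the imputed training design the forest saw
        ale_df = pd.DataFrame(bundle2.oob_X, columns=bundle2.feature_names)
        top = [f for f in importance["feature"]
               if ale_df[f].nunique() > 2][:config.n_ale_curves]
        for feat in top:
            curves.append(ale_first_order(fn, ale_df, feat))
        for pair in (("Median_interkey_time_mean", "Mean_session_length"),
                     ("Mean_backspace_rate", "Sample_entropy_backspace_rate")):
            if ale_df[pair[0]].nunique() > 3 and ale_df[pair[1]].nunique() > 3:
                surfaces.append(ale_second_order(fn, ale_df, pair, n_bins=10))
        render_reports(out_dir / "figures", importance=importance, curves=curves,
                       surfaces=surfaces, predictions=val2, comparisons=comparisons,
                       evaluations=evaluations, tuning_traces=traces)

    manifest["config"] = config.to_dict()
    try:
        from importlib.metadata import version
        manifest["typeage_version"] = version("typeage")
    except Exception:
        manifest["typeage_version"] = "unknown"
    _write_json(manifest, out_dir / "manifest.json")

    return {
        "features": features, "predictions": predictions, "bundles": bundles,
        "evaluation": evaluation_doc, "group_comparison": comparison_doc,
        "importance": importance, "curves": curves, "surfaces": surfaces,
        "train_ids": train_ids, "valid_ids": valid_ids,
    }
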