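"""Readers, writers and validation for keystroke event logs and subject metadata.

The on-disk formats are deliberately plain:

* ``events.csv`` / ``events.jsonl`` — one record per keypress with columns/keys
  ``subject_id``, ``timestamp`` (seconds since epoch) and ``event_type``
  (``alphanumeric``, ``backspace``, ``autocorrect`` or ``other``).
* ``metadata.csv`` — ``subject_id``, ``birth_year``, ``gender``,
  ``mdq_score``, ``self_report_dx``.

In memory both are pandas DataFrames.  Ingestion never drops rows silently:
counts of rejected rows and remapped event types are recorded in
``DataFrame.attrs`` and logged.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the four recognised keypress categories
EVENT_TYPES = ("alphanumeric", "backspace", "autocorrect", "other")

#: MDQ symptom-score threshold for a positive bipolar-disorder screen
MDQ_CUT = 7

#: plausible adult age window used to validate birth years
AGE_RANGE = (18, 120)

# timestamps larger than this are assumed to be milliseconds since epoch
_MS_MAGNITUDE = 1e11

EVENT_COLUMNS = ["subject_id", "timestamp", "event_type"]
METADATA_COLUMNS = ["subject_id", "birth_year", "gender", "mdq_score", "self_report_dx"]


class SchemaError(ValueError):
    """Raised when an input file is missing required columns or keys."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_event_log(path, format: str | None = None) -> pd.DataFrame:
    """Read a keystroke event log from CSV or JSONL.

    Returns a DataFrame with columns ``subject_id`` (str), ``timestamp``
    (float seconds) and ``event_type`` (one of :data:`EVENT_TYPES`), sorted by
    ``(subject_id, timestamp)`` with a stable sort so equal timestamps keep
    file order.  Unknown event-type strings are mapped to ``other``;
    ``attrs["n_unknown_event_type"]`` counts them.  Millisecond timestamps are
    detected by magnitude and converted to seconds.

    Parameters
    ----------
    path
        Input file.
    format
        ``"csv"`` or ``"jsonl"``; inferred from the suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix in {".jsonl", ".ndjson"} else "csv"
    if format == "csv":
        df = pd.read_csv(path, dtype={"subject_id": str})
    elif format == "jsonl":
        records = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}:{i}: invalid JSON: {exc}") from exc
        df = pd.DataFrame.from_records(records)
        if df.empty:
            df = pd.DataFrame(columns=EVENT_COLUMNS)
        df["subject_id"] = df.get("subject_id", pd.Series(dtype=str)).astype(str)
    else:
        raise ValueError(f"unknown event-log format {format!r}")

    _check_columns(df, EVENT_COLUMNS, path)
    df = df.loc[:, EVENT_COLUMNS].copy()

    ts = pd.to_numeric(df["timestamp"], errors="coerce")
    bad = ts.isna() | ~np.isfinite(ts) | (ts < 0)
    n_rejected = int(bad.sum())
    if n_rejected:
        lines = (df.index[bad] + 2).tolist()[:20]  # +2: header + 1-based
        logger.warning(
            "%s: rejected %d row(s) with unparseable/negative timestamps (lines %s%s)",
            path, n_rejected, lines, "…" if n_rejected > 20 else "",
        )
    df = df.loc[~bad].copy()
    ts = ts.loc[~bad].astype(float)
    # magnitude heuristic: epoch-milliseconds are ~1.6e12, epoch-seconds ~1.6e9
    if len(ts) and ts.abs().max() > _MS_MAGNITUDE:
        logger.info("%s: timestamps look like milliseconds; converting to seconds", path)
        ts = ts / 1000.0
    df["timestamp"] = ts

    known = df["event_type"].isin(EVENT_TYPES)
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.warning("%s: %d event(s) with unknown event_type mapped to 'other'", path, n_unknown)
        df.loc[~known, "event_type"] = "other"

    df = df.sort_values(["subject_id", "timestamp"], kind="stable").reset_index(drop=True)
    df.attrs["n_rejected"] = n_rejected
    df.attrs["n_unknown_event_type"] = n_unknown
    return df


def write_event_log(events: pd.DataFrame, path, format: str | None = None) -> None:
    """Write an event log to CSV or JSONL (inverse of :func:`read_event_log`)."""
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix in {".jsonl", ".ndjson"} else "csv"
    out = events.loc[:, EVENT_COLUMNS]
    if format == "csv":
        out.to_csv(path, index=False, float_format="%.12g")
    elif format == "jsonl":
        with open(path, "w") as fh:
            for rec in out.itertuples(index=False):
                fh.write(json.dumps({
                    "subject_id": rec.subject_id,
                    "timestamp": rec.timestamp,
                    "event_type": rec.event_type,
                }) + "\n")
    else:
        raise ValueError(f"unknown event-log format {format!r}")


def read_metadata(path, reference_year: int | None = None) -> pd.DataFrame:
    """Read the subject metadata table and derive screen status and age.

    ``mdq_positive`` is ``True`` iff ``mdq_score >= 7`` (the instrument's
    standard cut score), ``False`` below it and missing (``NA``) when the
    score is absent; ``unscreenable`` flags the latter.  ``age`` is
    ``reference_year - birth_year`` and must fall in [18, 120]; records
    outside that window are rejected with a warning
    (``attrs["n_rejected"]`` counts them).

    Parameters
    ----------
    path
        CSV with columns ``subject_id``, ``birth_year`` and optionally
        ``gender``, ``mdq_score``, ``self_report_dx``.
    reference_year
        Year against which age is computed.  Required here; pipelines default
        it to the latest event year in the accompanying log.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    _check_columns(df, ["subject_id", "birth_year"], path)
    dupes = df["subject_id"][df["subject_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate subject_id(s): {sorted(dupes)[:10]}")

    for col, default in (("gender", "missing"), ("mdq_score", np.nan), ("self_report_dx", "not_provided")):
        if col not in df.columns:
            df[col] = default
    df["gender"] = df["gender"].fillna("missing")
    df["self_report_dx"] = df["self_report_dx"].fillna("not_provided")

    score = pd.to_numeric(df["mdq_score"], errors="coerce")
    bad_score = score.notna() & ((score < 0) | (score > 13))
    if bad_score.any():
        raise ValueError(f"{path}: mdq_score outside [0, 13] for {df.loc[bad_score, 'subject_id'].tolist()}")
    df["mdq_score"] = score
    df["mdq_positive"] = pd.array(
        [bool(s >= MDQ_CUT) if not np.isnan(s) else None for s in score], dtype="boolean"
    )
    df["unscreenable"] = score.isna()
    df["gender_not_male"] = np.where(
        df["gender"].eq("missing"), np.nan, (df["gender"] != "male").astype(float)
    )

    if reference_year is None:
        raise ValueError("reference_year is required to compute age from birth_year")
    age = reference_year - pd.to_numeric(df["birth_year"], errors="coerce")
    ok = age.between(AGE_RANGE[0], AGE_RANGE[1])
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning(
            "%s: rejected %d record(s) with age outside %s: %s",
            path, n_rejected, AGE_RANGE, df.loc[~ok, "subject_id"].tolist()[:10],
        )
    df = df.loc[ok].copy()
    df["age"] = age.loc[ok].astype(float)
    df = df.reset_index(drop=True)
    df.attrs["n_rejected"] = n_rejected
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    """Write the raw metadata columns back to CSV."""
    meta.loc[:, METADATA_COLUMNS].to_csv(path, index=False)


def write_feature_table(features: pd.DataFrame, path) -> None:
    """Write a subject feature table to CSV.

    One row per subject: ``subject_id``, the 30 typing features in canonical
    order, then ``gender_not_male``, ``mdq_positive`` and ``age``.  Values
    round-trip through :func:`read_feature_table` to 12 significant digits;
    missing values become empty cells.
    """
    from .features import FEATURE_NAMES  # local import to avoid a cycle

    if len(features) == 0:
        raise ValueError("refusing to write an empty feature table")
    cols = ["subject_id"] + FEATURE_NAMES + ["gender_not_male", "mdq_positive", "age"]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise SchemaError(f"feature table is missing column(s) {missing}")
    out = features.loc[:, cols].copy()
    out["mdq_positive"] = out["mdq_positive"].astype(float)  # NA-safe 0/1
    out.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    from .features import FEATURE_NAMES

    df = pd.read_csv(path, dtype={"subject_id": str})
    _check_columns(df, ["subject_id"] + FEATURE_NAMES + ["gender_not_male", "mdq_positive", "age"], path)
    return df
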