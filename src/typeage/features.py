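"""Per-session typing metrics and subject-level feature summaries.

Each typing session yields six metrics: keypress count, mean and median
interkey time, autocorrect rate, backspace rate and session length.  Each
subject's chronological series of session metrics is then summarised by its
mean, median, sample standard deviation and (unscaled) median absolute
deviation, plus the sample entropy of the series — 5 summaries × 6 metrics =
30 typing features.

Sample entropy is computed with the conventional template-matching estimator
SampEn(m, r, tau) = −ln(A/B), where B counts pairs of length-m templates
within Chebyshev distance r of each other (self-matches excluded) and A the
same for length-(m+1) templates; r is tied to the series' standard deviation
(r = r_factor · sd), which makes the estimate invariant under affine
rescaling of the series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .sessions import DEFAULT_GAP_THRESHOLD, tokenize_all

#: per-session metric columns, in canonical order
SERIES_COLUMNS = ["n_keypresses", "ikt_mean", "ikt_median",
                  "autocorrect_rate", "backspace_rate", "duration"]

#: the 30 typing features in canonical order: four summaries per metric
#: (mean, median, sd, MAD) followed by the six sample entropies
FEATURE_NAMES = [
    "Mean_keypresses_per_session",
    "Median_keypresses_per_session",
    "Standard_deviation_keypress_per_session",
    "Median_absolute_deviation_keypress_per_session",
    "Mean_interkey_time_mean",
    "Median_interkey_time_mean",
    "Standard_deviation_interkey_time_mean",
    "Median_absolute_deviation_interkey_time_mean",
    "Mean_interkey_time_median",
    "Median_interkey_time_median",
    "Standard_deviation_interkey_time_median",
    "Median_absolute_deviation_interkey_time_median",
    "Mean_autocorrect_rate",
    "Median_autocorrect_rate",
    "Standard_deviation_autocorrect_rate",
    "Median_absolute_deviation_autocorrect_rate",
    "Mean_backspace_rate",
    "Median_backspace_rate",
    "Standard_deviation_backspace_rate",
    "Median_absolute_deviation_backspace_rate",
    "Mean_session_length",
    "Median_session_length",
    "Standard_deviation_session_length",
    "Median_absolute_deviation_session_length",
    "Sample_entropy_keypress",
    "Sample_entropy_interkey_time_mean",
    "Sample_entropy_interkey_time_median",
    "Sample_entropy_autocorrect_rate",
    "Sample_entropy_backspace_rate",
    "Sample_entropy_session_length",
]

# metric -> its four summary-feature names (in FEATURE_NAMES order) + entropy name
_SUMMARY_BLOCKS = {
    "n_keypresses": FEATURE_NAMES[0:4],
    "ikt_mean": FEATURE_NAMES[4:8],
    "ikt_median": FEATURE_NAMES[8:12],
    "autocorrect_rate": FEATURE_NAMES[12:16],
    "backspace_rate": FEATURE_NAMES[16:20],
    "duration": FEATURE_NAMES[20:24],
}
_ENTROPY_NAMES = {
    "n_keypresses": "Sample_entropy_keypress",
    "ikt_mean": "Sample_entropy_interkey_time_mean",
    "ikt_median": "Sample_entropy_interkey_time_median",
    "autocorrect_rate": "Sample_entropy_autocorrect_rate",
    "backspace_rate": "Sample_entropy_backspace_rate",
    "duration": "Sample_entropy_session_length",
}

#: predictor sets for the two stepwise models
MODEL1_PREDICTORS = list(FEATURE_NAMES)
MODEL2_PREDICTORS = list(FEATURE_NAMES) + ["gender_not_male", "mdq_positive"]


@dataclass(frozen=True)
class SampleEntropyParams:
    """Parameters of the sample-entropy estimator.

    m : embedding (template) length.
    r_factor : tolerance as a multiple of the series standard deviation.
    tau : subsampling stride used when building templates.
    min_len : series shorter than this yield a missing value rather than a
        noisy estimate.
    """

    m: int = 2
    r_factor: float = 0.2
    tau: int = 1
    min_len: int = 10

    def __post_init__(self):
        if self.m < 1 or self.tau < 1:
            raise ValueError("m and tau must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")


def mad(values) -> float:
    """Unscaled median absolute deviation, median(|x − median(x)|).

    Note this deliberately omits the 1.4826 normal-consistency factor some
    libraries apply by default.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad of empty sequence")
    return float(np.median(np.abs(x - np.median(x))))


def _embed(x: np.ndarray, length: int, tau: int, n_templates: int) -> np.ndarray:
    """First ``n_templates`` delay-embedding vectors of the given length."""
    idx = np.arange(n_templates)[:, None] + tau * np.arange(length)[None, :]
    return x[idx]


def sample_entropy(series, params: SampleEntropyParams = SampleEntropyParams()) -> float:
    """SampEn(m, r, tau) of a numeric series; NaN when undefined.

    Returns NaN when the series is shorter than ``params.min_len`` or when
    either template count is zero (so the estimate stays finite).  Non-finite
    input values are an error.  Template pairs match when their Chebyshev
    distance is ≤ r = r_factor · sd(series) (population sd); self-matches are
    excluded.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size and not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    n = x.size
    if n < params.min_len:
        return float("nan")
    m, tau = params.m, params.tau
    n_templates = n - m * tau  # both template lengths use this count
    if n_templates < 2:
        return float("nan")
    r = params.r_factor * float(np.std(x))
    emb_m = _embed(x, m, tau, n_templates)
    emb_m1 = _embed(x, m + 1, tau, n_templates)
    b = int(np.sum(pdist(emb_m, "chebyshev") <= r))
    a = int(np.sum(pdist(emb_m1, "chebyshev") <= r))
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def session_metrics(session_events: pd.DataFrame) -> pd.Series:
    """Metrics of a single session (one subject's events of one session).

    Interkey times are the successive timestamp differences within the
    session; they are missing for single-keypress sessions.  Rates are the
    fraction of the session's keypresses of the given type.
    """
    if len(session_events) == 0:
        raise ValueError("session is empty")
    ts = session_events["timestamp"].to_numpy(dtype=float)
    types = session_events["event_type"]
    n = len(ts)
    gaps = np.diff(ts)
    return pd.Series({
        "n_keypresses": float(n),
        "ikt_mean": float(np.mean(gaps)) if n >= 2 else np.nan,
        "ikt_median": float(np.median(gaps)) if n >= 2 else np.nan,
        "autocorrect_rate": float((types == "autocorrect").sum()) / n,
        "backspace_rate": float((types == "backspace").sum()) / n,
        "duration": float(ts[-1] - ts[0]),
        "start_time": float(ts[0]),
    })


def session_metrics_table(tokenized: pd.DataFrame) -> pd.DataFrame:
    """Per-session metrics for a tokenized (multi-subject) event log.

    Vectorised equivalent of applying :func:`session_metrics` to every
    session.  Returns one row per (subject_id, session), chronologically
    ordered within subject.
    """
    if len(tokenized) == 0:
        return pd.DataFrame(columns=["subject_id", "session"] + SERIES_COLUMNS + ["start_time"])
    df = tokenized
    key = ["subject_id", "session"]
    # within-session interkey gaps: timestamp diffs where the session id repeats
    ts = df["timestamp"].to_numpy(dtype=float)
    gaps = pd.Series(np.concatenate([[np.nan], np.diff(ts)]), index=df.index)
    same = (df["session"].shift() == df["session"]) & (df["subject_id"].shift() == df["subject_id"])
    gaps[~same] = np.nan

    g = df.groupby(key, sort=True)
    out = g.agg(
        n_keypresses=("timestamp", "size"),
        start_time=("timestamp", "first"),
        end_time=("timestamp", "last"),
    )
    out["duration"] = out["end_time"] - out["start_time"]
    bs = df["event_type"].eq("backspace").groupby([df["subject_id"], df["session"]]).sum()
    ac = df["event_type"].eq("autocorrect").groupby([df["subject_id"], df["session"]]).sum()
    out["backspace_rate"] = bs / out["n_keypresses"]
    out["autocorrect_rate"] = ac / out["n_keypresses"]
    gg = gaps.groupby([df["subject_id"], df["session"]])
    out["ikt_mean"] = gg.mean()
    out["ikt_median"] = gg.median()
    out["n_keypresses"] = out["n_keypresses"].astype(float)
    out = out.reset_index()
    return out[["subject_id", "session"] + SERIES_COLUMNS + ["start_time"]]


def _summaries(series: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, median, sample sd, MAD) of a series with missing values dropped."""
    x = series[~np.isnan(series)]
    if x.size == 0:
        return (np.nan, np.nan, np.nan, np.nan)
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else np.nan
    return (float(np.mean(x)), float(np.median(x)), sd, mad(x))


def subject_features(metrics: pd.DataFrame,
                     entropy_params: SampleEntropyParams = SampleEntropyParams()) -> pd.Series:
    """The 30 typing features of one subject.

    ``metrics`` is the subject's per-session metric table in chronological
    order (as from :func:`session_metrics_table`).  Sample entropy is
    computed on the chronologically ordered series; sessions where a metric
    is undefined (single-keypress sessions for interkey times) are dropped
    from that metric's series.
    """
    if len(metrics) == 0:
        raise ValueError("subject has no sessions")
    values: dict[str, float] = {}
    for col in SERIES_COLUMNS:
        series = metrics[col].to_numpy(dtype=float)
        clean = series[~np.isnan(series)]
        mean, median, sd, mad_ = _summaries(series)
        names = _SUMMARY_BLOCKS[col]
        values[names[0]] = mean
        values[names[1]] = median
        values[names[2]] = sd
        values[names[3]] = mad_
        values[_ENTROPY_NAMES[col]] = sample_entropy(clean, entropy_params)
    return pd.Series(values).reindex(FEATURE_NAMES)


def filter_participants(events: pd.DataFrame, min_weeks: float = 12.0
                        ) -> tuple[list[str], pd.DataFrame]:
    """Apply the data-sufficiency inclusion rule.

    A subject is included when their total keypress count is at least
    ``min_weeks`` weeks' worth of typical typing, where "typical" is the
    cohort median of per-subject daily keypress rates:

        threshold = min_weeks × 7 × median_subjects(total / observed_days)

    ``observed_days`` is the number of distinct UTC days with at least one
    event.  Returns the included subject ids and a per-subject report with
    each total, the threshold and the inclusion flag.
    """
    if len(events) == 0:
        raise ValueError("empty cohort: no events to filter")
    per = events.groupby("subject_id").agg(
        total_keypresses=("timestamp", "size"),
        observed_days=("timestamp", lambda t: int(np.unique(np.floor(t / 86400.0)).size)),
    )
    per["daily_rate"] = per["total_keypresses"] / per["observed_days"]
    cohort_median_daily = float(per["daily_rate"].median())
    threshold = min_weeks * 7.0 * cohort_median_daily
    per["threshold"] = threshold
    per["included"] = per["total_keypresses"] >= threshold
    report = per.reset_index()
    included = report.loc[report["included"], "subject_id"].tolist()
    return included, report


def compute_feature_table(events: pd.DataFrame, metadata: pd.DataFrame,
                          entropy_params: SampleEntropyParams = SampleEntropyParams(),
                          gap_threshold: float = DEFAULT_GAP_THRESHOLD) -> pd.DataFrame:
    """End-to-end featurisation: events + metadata → subject feature table.

    Tokenizes each subject's stream, computes per-session metrics, summarises
    them into the 30 typing features, and joins ``gender_not_male``,
    ``mdq_positive`` and ``age`` from the metadata.  Subjects without events
    or without metadata are dropped.
    """
    tok = tokenize_all(events, gap_threshold)
    metrics = session_metrics_table(tok)
    rows = []
    for sid, grp in metrics.groupby("subject_id", sort=True):
        feats = subject_features(grp.sort_values(["session"]), entropy_params)
        feats["subject_id"] = sid
        rows.append(feats)
    if not rows:
        raise ValueError("no subjects with events")
    table = pd.DataFrame(rows)
    meta_cols = metadata.loc[:, ["subject_id", "gender_not_male", "mdq_positive", "age"]]
    table = table.merge(meta_cols, on="subject_id", how="inner")
    return table[["subject_id"] + FEATURE_NAMES + ["gender_not_male", "mdq_positive", "age"]]
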