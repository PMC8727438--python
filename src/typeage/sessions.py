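"""Tokenize keystroke streams into typing sessions.

A *session* is a maximal run of consecutive keypresses in which every gap
between neighbouring events is strictly less than the gap threshold
(5 seconds by default).  A gap of exactly the threshold therefore starts a
new session, and identical timestamps always join.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: gap (seconds) at or above which two consecutive keypresses belong to
#: different sessions
DEFAULT_GAP_THRESHOLD = 5.0


def session_ids(timestamps: np.ndarray, gap_threshold: float = DEFAULT_GAP_THRESHOLD) -> np.ndarray:
    """Assign a 0-based session index to each of one subject's timestamps.

    ``timestamps`` must be sorted non-decreasingly; passing unsorted input is
    a contract violation and raises rather than silently re-sorting.
    """
    if gap_threshold <= 0:
        raise ValueError("gap_threshold must be positive")
    ts = np.asarray(timestamps, dtype=float)
    if ts.ndim != 1:
        raise ValueError("timestamps must be one-dimensional")
    if ts.size == 0:
        return np.zeros(0, dtype=np.int64)
    gaps = np.diff(ts)
    if (gaps < 0).any():
        raise ValueError("timestamps must be sorted non-decreasingly before tokenization")
    return np.concatenate([[0], np.cumsum(gaps >= gap_threshold)]).astype(np.int64)


def tokenize_sessions(events: pd.DataFrame, gap_threshold: float = DEFAULT_GAP_THRESHOLD) -> pd.DataFrame:
    """Split one subject's time-ordered events into sessions.

    Returns a copy of ``events`` with an added integer ``session`` column
    (0-based, ordered by time).  Every event belongs to exactly one session;
    the partition is the unique maximal-run partition under the strict-<
    joining rule.
    """
    if "subject_id" in events.columns and events["subject_id"].nunique() > 1:
        raise ValueError("tokenize_sessions expects events of a single subject; "
                         "use tokenize_all for multi-subject logs")
    out = events.copy()
    out["session"] = session_ids(out["timestamp"].to_numpy(), gap_threshold)
    return out


def tokenize_all(events: pd.DataFrame, gap_threshold: float = DEFAULT_GAP_THRESHOLD) -> pd.DataFrame:
    """Tokenize a multi-subject event log (sorted by subject then time)."""
    if len(events) == 0:
        out = events.copy()
        out["session"] = np.zeros(0, dtype=np.int64)
        return out
    parts = []
    for _, grp in events.groupby("subject_id", sort=False):
        parts.append(tokenize_sessions(grp, gap_threshold))
    return pd.concat(parts, ignore_index=True)


def session_bounds(session_timestamps) -> tuple[float, float, float]:
    """Return ``(start_time, end_time, duration)`` of one session's timestamps.

    Duration is last minus first timestamp; a single-keypress session has
    duration 0.  Empty input is an error.
    """
    ts = np.asarray(session_timestamps, dtype=float)
    if ts.size == 0:
        raise ValueError("session is empty")
    start, end = float(ts[0]), float(ts[-1])
    return start, end, end - start
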