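"""Synthetic keystroke cohorts with a controllable brain-age offset.

The generator emulates the statistical structure the downstream analysis
assumes: each subject types in short sessions whose starts follow a daily
Poisson process; interkey times are lognormal with a location that increases
linearly in the subject's *effective typing age*; session length grows with
age; and the session-to-session backspace/autocorrect rates follow an AR(1)
process whose autocorrelation increases with age, so the backspace-rate
series of older subjects is smoother (lower sample entropy) than that of
younger ones.  Note that simply shrinking the variance of the rate series
would not move sample entropy at all — the estimator's tolerance is tied to
the series' own standard deviation — so the age–entropy association is
driven by serial correlation, not scale.

A positive screen on the bipolar-disorder questionnaire can carry an
additive offset δ (``brainage_offset_years``) to the effective typing age,
the minimal mechanism for a "types older than their years" group: with
δ > 0, screen-positive subjects type like people δ years older while their
chronological age is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sessions import DEFAULT_GAP_THRESHOLD

#: 2021-01-01 UTC; synthetic event times are laid out from here so the
#: "latest event year" reference-year convention resolves to 2021
EPOCH = 1609459200.0
REFERENCE_YEAR = 2021

_SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class CohortParams:
    """Generator configuration.

    Defaults describe a cohort like the one the analysis is designed for:
    344 subjects, two thirds screening positive, 12 weeks (84 days) of
    observation, and an activity level landing near a median of ~10,000 total
    keypresses per subject, with a heavy-tailed (lognormal) spread of
    per-subject activity.
    """

    n_subjects: int = 344
    prop_mdq_positive: float = 227 / 344
    age_range: tuple[float, float] = (18.0, 88.0)
    n_days: int = 84
    sessions_per_day_rate: float = 4.0     # Poisson mean of session starts/day
    ikt_base: float = 0.25                 # mean interkey time (s) at age 18
    ikt_age_slope: float = 0.003           # s of interkey time per year of age
    session_len_base: float = 8.0          # mean session duration (s) at age 18
    session_len_age_slope: float = 0.08    # s of session duration per year
    backspace_rate_base: float = 0.12
    autocorrect_rate_base: float = 0.05
    entropy_age_effect: float = 0.8        # AR(1) coefficient of the rate series at max age
    rate_noise_sd: float = 0.5             # log-scale sd of session rate fluctuations
    brainage_offset_years: float = 0.0     # δ added to effective typing age of positives
    noise_sd_subject: float = 0.15         # log-scale sd of subject speed multipliers
    noise_sd_session: float = 0.10         # log-scale sd of session/keypress fluctuations
    activity_dispersion: float = 0.6       # log-scale sd of subject activity multipliers
    gap_threshold: float = DEFAULT_GAP_THRESHOLD
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not (0.0 <= self.prop_mdq_positive <= 1.0):
            raise ValueError("prop_mdq_positive must be in [0, 1]")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be a non-empty (min, max) interval")
        for name in ("backspace_rate_base", "autocorrect_rate_base"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 <= self.entropy_age_effect <= 1.0):
            raise ValueError("entropy_age_effect must be in [0, 1]")
        for name in ("sessions_per_day_rate", "noise_sd_subject", "noise_sd_session",
                     "activity_dispersion", "rate_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")


def strong_signal_params(n_subjects: int, seed: int, *,
                         brainage_offset_years: float = 0.0,
                         age_range: tuple[float, float] = (18.0, 80.0),
                         n_days: int = 14) -> CohortParams:
    """A compact, strong-age-signal configuration for validation studies.

    Steeper interkey-time and session-length slopes and lower subject noise
    than the realistic defaults, with a shorter observation window, so that
    signal-recovery experiments run quickly and the age signal dominates
    sampling noise.
    """
    return CohortParams(
        n_subjects=n_subjects,
        age_range=age_range,
        n_days=n_days,
        sessions_per_day_rate=4.0,
        ikt_age_slope=0.008,
        session_len_age_slope=0.30,
        noise_sd_subject=0.05,
        noise_sd_session=0.08,
        activity_dispersion=0.2,
        brainage_offset_years=brainage_offset_years,
        seed=seed,
    )


def _subject_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0])


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series with marginal sd ``sd``."""
    z = rng.standard_normal(n)
    if n == 0:
        return z
    out = np.empty(n)
    out[0] = z[0]
    innov = np.sqrt(1.0 - rho ** 2)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + innov * z[t]
    return sd * out


def generate_subject_events(profile: pd.Series, params: CohortParams) -> pd.DataFrame:
    """Generate one subject's keystroke events from their profile row.

    By construction all within-session gaps are < ``params.gap_threshold``
    and all between-session gaps are ≥ it, so re-tokenizing the output
    recovers the generator's session boundaries exactly.  The intended
    session count is stored in ``attrs["n_sessions"]``.
    """
    rng = np.random.default_rng(int(profile["stream_seed"]))
    eff_age = float(profile["effective_typing_age"])
    lo, hi = params.age_range
    frac = np.clip((eff_age - lo) / (hi - lo), 0.0, 1.5)

    activity = float(profile.get("activity_mult", 1.0))
    n_per_day = rng.poisson(params.sessions_per_day_rate * activity, size=params.n_days)
    starts = []
    for day, k in enumerate(n_per_day):
        if k:
            offs = np.sort(rng.uniform(0.0, _SECONDS_PER_DAY, size=k))
            starts.append(EPOCH + day * _SECONDS_PER_DAY + offs)
    if not starts:
        out = pd.DataFrame({"subject_id": pd.Series(dtype=str),
                            "timestamp": pd.Series(dtype=float),
                            "event_type": pd.Series(dtype=str)})
        out.attrs["n_sessions"] = 0
        return out
    starts = np.concatenate(starts)
    n_sessions = starts.size

    # subject-level speed and rate levels
    ikt_subj = (params.ikt_base + params.ikt_age_slope * (eff_age - lo)) \
        * float(np.exp(params.noise_sd_subject * rng.standard_normal()))
    dur_subj = max(1.0, params.session_len_base + params.session_len_age_slope * (eff_age - lo))

    # session-to-session structure: lognormal speed/duration wobble, AR(1) rates
    sess_speed = np.exp(params.noise_sd_session * rng.standard_normal(n_sessions))
    sess_dur = dur_subj * np.exp(params.noise_sd_session * rng.standard_normal(n_sessions))
    rho = params.entropy_age_effect * frac
    rho = min(rho, 0.95)
    p_back = np.clip(params.backspace_rate_base
                     * np.exp(_ar1(rng, n_sessions, rho, params.rate_noise_sd)), 0.0, 0.6)
    p_auto = np.clip(params.autocorrect_rate_base
                     * np.exp(_ar1(rng, n_sessions, rho, params.rate_noise_sd)), 0.0, 0.3)

    ts_parts, type_parts = [], []
    prev_end = -np.inf
    margin = params.gap_threshold
    max_ikt = 0.98 * params.gap_threshold
    for s in range(n_sessions):
        mean_ikt = ikt_subj * sess_speed[s]
        # session length emerges from a geometric keypress count with mean
        # matching the target duration at this subject's typing speed
        mu_extra = max(sess_dur[s] / mean_ikt, 1e-9)
        n_kp = 1 + int(rng.geometric(1.0 / (1.0 + mu_extra)) - 1)
        start = max(float(starts[s]), prev_end + margin)
        if n_kp > 1:
            ikts = mean_ikt * np.exp(params.noise_sd_session * rng.standard_normal(n_kp - 1))
            ikts = np.clip(ikts, 1e-4, max_ikt)
            ts = start + np.concatenate([[0.0], np.cumsum(ikts)])
        else:
            ts = np.array([start])
        prev_end = float(ts[-1])
        u = rng.random(n_kp)
        types = np.where(u < p_back[s], "backspace",
                         np.where(u < p_back[s] + p_auto[s], "autocorrect", "alphanumeric"))
        ts_parts.append(ts)
        type_parts.append(types)

    out = pd.DataFrame({
        "subject_id": str(profile["subject_id"]),
        "timestamp": np.concatenate(ts_parts),
        "event_type": np.concatenate(type_parts),
    })
    out.attrs["n_sessions"] = int(n_sessions)
    return out


def generate_cohort(params: CohortParams) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (metadata, events, profiles) for a full synthetic cohort.

    Deterministic given ``params.seed``.  Metadata has the columns of the
    on-disk subject table plus the derived ``age``, ``mdq_positive`` and
    ``gender_not_male``; profiles record each subject's ground truth
    (true and effective typing age, per-subject stream seed, intended
    session count).
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    n = params.n_subjects
    lo, hi = params.age_range

    ids = [f"S{i:04d}" for i in range(n)]
    ages = np.floor(rng.uniform(lo, hi + 1.0, size=n)).clip(lo, hi)
    positive = rng.random(n) < params.prop_mdq_positive
    # MDQ symptom scores consistent with screen status (cut score 7)
    score_pos = np.clip(np.round(rng.normal(12.0, 1.5, size=n)), 7, 13)
    score_neg = np.clip(np.round(rng.normal(4.0, 2.0, size=n)), 0, 6)
    mdq_score = np.where(positive, score_pos, score_neg).astype(int)
    not_male = rng.random(n) < np.where(positive, 0.75, 0.60)
    dx_probs = np.where(positive[:, None],
                        np.array([[0.51, 0.13, 0.36]]),
                        np.array([[0.21, 0.56, 0.23]]))
    dx_u = rng.random(n)
    dx = np.select(
        [dx_u < dx_probs[:, 0], dx_u < dx_probs[:, 0] + dx_probs[:, 1]],
        ["yes", "no"], default="not_provided",
    )
    activity = np.exp(params.activity_dispersion * rng.standard_normal(n))
    activity /= np.exp(0.5 * params.activity_dispersion ** 2)  # mean ≈ 1

    eff_age = ages + params.brainage_offset_years * positive.astype(float)
    profiles = pd.DataFrame({
        "subject_id": ids,
        "true_age": ages.astype(float),
        "effective_typing_age": eff_age.astype(float),
        "gender": np.where(not_male, "not_male", "male"),
        "mdq_positive": positive,
        "mdq_score": mdq_score,
        "activity_mult": activity,
        "stream_seed": [_subject_seed(params.seed, i + 1) for i in range(n)],
    })

    events_parts, n_sessions = [], []
    for _, prof in profiles.iterrows():
        ev = generate_subject_events(prof, params)
        n_sessions.append(ev.attrs["n_sessions"])
        if len(ev):
            events_parts.append(ev)
    profiles["n_sessions"] = n_sessions
    if events_parts:
        events = pd.concat(events_parts, ignore_index=True)
    else:
        events = pd.DataFrame({"subject_id": pd.Series(dtype=str),
                               "timestamp": pd.Series(dtype=float),
                               "event_type": pd.Series(dtype=str)})
    events = events.sort_values(["subject_id", "timestamp"], kind="stable").reset_index(drop=True)

    metadata = pd.DataFrame({
        "subject_id": ids,
        "birth_year": (REFERENCE_YEAR - ages).astype(int),
        "gender": profiles["gender"],
        "mdq_score": mdq_score,
        "self_report_dx": dx,
        "age": ages.astype(float),
        "mdq_positive": pd.array(positive, dtype="boolean"),
        "gender_not_male": not_male.astype(float),
        "unscreenable": False,
    })
    return metadata, events, profiles


def with_seed(params: CohortParams, seed: int) -> CohortParams:
    """Copy of ``params`` with a different seed (replicate helper)."""
    return replace(params, seed=seed)
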