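import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from typeage.features import (FEATURE_NAMES, MODEL2_PREDICTORS, SampleEntropyParams,
                              compute_feature_table, filter_participants, mad,
                              sample_entropy, session_metrics, session_metrics_table,
                              subject_features)
from typeage.sessions import tokenize_all

from _oracles import brute_mad, brute_sampen, brute_summaries
from conftest import make_events


class TestSessionMetrics:
    def test_arithmetic(self):
        m = session_metrics(make_events([0.0, 0.2, 0.4]))
        assert m["n_keypresses"] == 3
        assert m["ikt_mean"] == pytest.approx(0.2)
        assert m["ikt_median"] == pytest.approx(0.2)
        assert m["autocorrect_rate"] == 0.0 and m["backspace_rate"] == 0.0
        assert m["duration"] == pytest.approx(0.4)

    def test_rates_count_all_keypress_types(self):
        m = session_metrics(make_events(
            [0.0, 0.1, 0.2, 0.3],
            ["alphanumeric", "backspace", "autocorrect", "alphanumeric"]))
        assert m["backspace_rate"] == 0.25
        assert m["autocorrect_rate"] == 0.25

    def test_single_event_session(self):
        m = session_metrics(make_events([5.0], ["backspace"]))
        assert m["n_keypresses"] == 1
        assert np.isnan(m["ikt_mean"]) and np.isnan(m["ikt_median"])
        assert m["backspace_rate"] == 1.0
        assert m["duration"] == 0.0

    def test_vectorised_table_matches_per_session(self, rng):
        ts = np.cumsum(rng.exponential(2.0, size=200))
        types = rng.choice(["alphanumeric", "backspace", "autocorrect", "other"], 200)
        tok = tokenize_all(make_events(ts, types))
        table = session_metrics_table(tok).set_index("session")
        for s, grp in tok.groupby("session"):
            expected = session_metrics(grp)
            for col in ("n_keypresses", "ikt_mean", "ikt_median",
                        "autocorrect_rate", "backspace_rate", "duration"):
                got = table.loc[s, col]
                if np.isnan(expected[col]):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected[col], rel=1e-12)


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.full(20, 3.7)) == 0.0

    def test_short_series_is_missing(self):
        assert np.isnan(sample_entropy([1.0, 2.0, 3.0]))

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            sample_entropy(np.r_[np.ones(19), np.nan])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(10, 80))
            x = rng.normal(size=n)
            expected = brute_sampen(x)
            got = sample_entropy(x)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-10)

    def test_oracle_agreement_with_tau_and_m(self, rng):
        params = SampleEntropyParams(m=3, r_factor=0.15, tau=2, min_len=12)
        for _ in range(10):
            x = rng.normal(size=40)
            expected = brute_sampen(x, m=3, r_factor=0.15, tau=2, min_len=12)
            got = sample_entropy(x, params)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-10)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(10, 60), st.floats(0.1, 100.0), st.floats(-50.0, 50.0),
           st.integers(0, 2**31 - 1))
    def test_scale_invariance(self, n, a, b, seed):
        x = np.random.default_rng(seed).normal(size=n)
        base = sample_entropy(x)
        scaled = sample_entropy(a * x + b)
        if np.isnan(base):
            assert np.isnan(scaled)
        else:
            assert scaled == pytest.approx(base, rel=1e-9)


class TestMad:
    def test_examples(self):
        assert mad([1, 1, 1]) == 0.0
        assert mad([1, 2, 3, 4, 5]) == 1.0

    def test_unscaled_no_consistency_factor(self):
        # a normal-consistency implementation would return 1.4826…
        assert mad([0.0, 1.0, 2.0]) == 1.0

    def test_matches_definition(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(1, 40)))
            assert mad(x) == pytest.approx(brute_mad(x), rel=1e-12)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            mad([])


def _metrics_frame(rng, n_sessions, subject="s1"):
    return pd.DataFrame({
        "subject_id": subject,
        "session": np.arange(n_sessions),
        "n_keypresses": rng.integers(1, 50, n_sessions).astype(float),
        "ikt_mean": np.where(rng.random(n_sessions) < 0.1, np.nan,
                             rng.exponential(0.3, n_sessions)),
        "ikt_median": rng.exponential(0.25, n_sessions),
        "autocorrect_rate": rng.uniform(0, 0.2, n_sessions),
        "backspace_rate": rng.uniform(0, 0.4, n_sessions),
        "duration": rng.exponential(10.0, n_sessions),
        "start_time": np.sort(rng.uniform(0, 1e6, n_sessions)),
    })


class TestSubjectFeatures:
    def test_identical_sessions_have_zero_dispersion(self):
        m = _metrics_frame(np.random.default_rng(0), 2)
        m.iloc[1, 2:] = m.iloc[0, 2:]
        feats = subject_features(m)
        for name in FEATURE_NAMES:
            if "deviation" in name.lower() or name.startswith("Standard"):
                assert feats[name] == 0.0 or np.isnan(feats[name])
            if name.startswith("Sample_entropy"):
                assert np.isnan(feats[name])  # series shorter than min_len

    def test_symmetric_series_mean_equals_median(self):
        m = _metrics_frame(np.random.default_rng(1), 5)
        m["duration"] = [1.0, 2.0, 3.0, 4.0, 5.0]
        feats = subject_features(m)
        assert feats["Mean_session_length"] == feats["Median_session_length"] == 3.0

    def test_straight_line_recomputation(self, rng):
        m = _metrics_frame(rng, 100)
        feats = subject_features(m)
        blocks = {
            "n_keypresses": ("Mean_keypresses_per_session", "Median_keypresses_per_session",
                             "Standard_deviation_keypress_per_session",
                             "Median_absolute_deviation_keypress_per_session",
                             "Sample_entropy_keypress"),
            "ikt_mean": ("Mean_interkey_time_mean", "Median_interkey_time_mean",
                         "Standard_deviation_interkey_time_mean",
                         "Median_absolute_deviation_interkey_time_mean",
                         "Sample_entropy_interkey_time_mean"),
            "duration": ("Mean_session_length", "Median_session_length",
                         "Standard_deviation_session_length",
                         "Median_absolute_deviation_session_length",
                         "Sample_entropy_session_length"),
        }
        for col, names in blocks.items():
            series = m[col].to_numpy()
            mean, med, sd, mad_ = brute_summaries(series)
            clean = series[~np.isnan(series)]
            ent = brute_sampen(clean)
            for name, expected in zip(names, (mean, med, sd, mad_, ent)):
                if np.isnan(expected):
                    assert np.isnan(feats[name])
                else:
                    assert feats[name] == pytest.approx(expected, abs=1e-10)

    def test_feature_count_and_model2_width(self, small_features):
        assert len(FEATURE_NAMES) == 30
        assert len(MODEL2_PREDICTORS) == 32
        assert list(small_features.columns[1:31]) == FEATURE_NAMES

    def test_session_order_matters_only_for_entropy(self, rng):
        m = _metrics_frame(rng, 60)
        shuffled = m.sample(frac=1.0, random_state=3).reset_index(drop=True)
        f1, f2 = subject_features(m), subject_features(shuffled)
        for name in FEATURE_NAMES:
            if name.startswith("Sample_entropy"):
                continue
            np.testing.assert_allclose(f1[name], f2[name], rtol=1e-12, equal_nan=True)
        # entropy is order-sensitive: at least one entropy feature must move
        ent = [n for n in FEATURE_NAMES if n.startswith("Sample_entropy")]
        assert any(abs(f1[n] - f2[n]) > 1e-12
                   for n in ent if np.isfinite(f1[n]) and np.isfinite(f2[n]))

    def test_rate_and_dispersion_ranges(self, small_features):
        for name in FEATURE_NAMES:
            v = small_features[name].dropna()
            if "rate" in name and not name.startswith("Sample"):
                assert ((v >= 0) & (v <= 1)).all()
            if "deviation" in name.lower() or name.startswith(("Standard", "Sample")):
                assert (v >= 0).all()


class TestInclusionFilter:
    def _uniform_cohort(self, n_subjects, per_day, days):
        frames = []
        for i in range(n_subjects):
            ts = np.concatenate([d * 86400.0 + np.linspace(0, 3600, per_day)
                                 for d in range(days)])
            frames.append(make_events(ts, subject=f"s{i}"))
        return pd.concat(frames, ignore_index=True)

    def test_identical_activity_all_included_at_boundary(self):
        events = self._uniform_cohort(5, per_day=10, days=84)
        included, report = filter_participants(events, min_weeks=12)
        assert len(included) == 5  # total == threshold exactly → included

    def test_low_activity_subject_excluded(self):
        events = self._uniform_cohort(4, per_day=10, days=84)
        events = pd.concat([events, make_events([0.0, 1.0], subject="lazy")],
                           ignore_index=True)
        included, report = filter_participants(events, min_weeks=12)
        assert "lazy" not in included
        assert set(included) == {"s0", "s1", "s2", "s3"}

    def test_planted_halves_match_hand_computation(self):
        high = self._uniform_cohort(3, per_day=20, days=84)
        low = self._uniform_cohort(3, per_day=4, days=84)
        low["subject_id"] = low["subject_id"].map(lambda s: s + "_low")
        events = pd.concat([high, low], ignore_index=True)
        included, report = filter_participants(events, min_weeks=12)
        # cohort median daily = (20+4)/2 = 12 → threshold = 84·12 = 1008
        assert report["threshold"].iloc[0] == pytest.approx(84 * 12.0)
        assert set(included) == {"s0", "s1", "s2"}  # 1680 ≥ 1008, 336 < 1008

    def test_empty_cohort_is_error(self):
        with pytest.raises(ValueError):
            filter_participants(make_events([]), min_weeks=12)


def test_compute_feature_table_shape(small_cohort, small_features):
    assert list(small_features.columns) == (
        ["subject_id"] + FEATURE_NAMES + ["gender_not_male", "mdq_positive", "age"])
    assert len(small_features) == small_cohort["params"].n_subjects
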