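"""Co-contraction index, fiducial features and the feature table.

The window CCI is checked against an independent brute-force coding of
the per-sample ratio-times-sum definition and its windowed sum.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgait.core import CCI_PAIRS, MUSCLES, NormalizedEnvelope, TemporospatialRecord, GaitEventSet
from emgait.features import (
    build_feature_table,
    cci_timeseries,
    cci_window,
    feature_columns,
    fiducial_features,
    limb_features,
    temporospatial_features,
    window_bounds,
)


def _env(values, muscle="TA", boundary=60):
    return NormalizedEnvelope(np.asarray(values, dtype=float), boundary, muscle)


def brute_force_cci(a: np.ndarray, b: np.ndarray, t1: int, t2: int) -> float:
    """Independent oracle: literal loop over the ratio-times-sum definition,
    then the arithmetic mean over the inclusive window."""
    total = 0.0
    for t in range(t1, t2 + 1):
        low, high = (a[t], b[t]) if a[t] <= b[t] else (b[t], a[t])
        total += 0.0 if high == 0 else (low / high) * (low + high)
    return total / (t2 - t1 + 1)


class TestCCITimeseries:
    def test_equal_envelopes(self):
        c = 0.4
        series = cci_timeseries(_env(c * np.ones(101)), _env(c * np.ones(101), "G"))
        assert np.allclose(series.values, 2 * c)

    def test_zero_antagonist(self):
        series = cci_timeseries(_env(np.ones(101)), _env(np.zeros(101), "G"))
        assert np.allclose(series.values, 0.0)

    def test_direct_substitution(self):
        series = cci_timeseries(_env(0.5 * np.ones(101)), _env(1.0 * np.ones(101), "G"))
        assert np.allclose(series.values, 0.75)

    def test_symmetry_exact(self, rng):
        a = _env(rng.uniform(0, 1, 101))
        b = _env(rng.uniform(0, 1, 101), "G")
        assert np.array_equal(cci_timeseries(a, b).values, cci_timeseries(b, a).values)

    def test_bound(self, rng):
        a, b = rng.uniform(0, 1, 101), rng.uniform(0, 1, 101)
        values = cci_timeseries(_env(a), _env(b, "G")).values
        assert np.all(values >= 0)
        assert np.all(values <= a + b + 1e-12)
        assert np.all(values <= 2.0 + 1e-12)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_homogeneous_degree_one(self, scale):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 1, 101), rng.uniform(0, 1, 101)
        base = cci_timeseries(_env(a), _env(b, "G")).values
        scaled = cci_timeseries(_env(scale * a), _env(scale * b, "G")).values
        assert np.allclose(scaled, scale * base, rtol=1e-10)


class TestCCIWindow:
    def test_constant_series(self):
        series = cci_timeseries(_env(0.3 * np.ones(101)), _env(0.3 * np.ones(101), "G"))
        assert cci_window(series, 0, 100) == pytest.approx(0.6)
        assert cci_window(series, 10, 40) == pytest.approx(0.6)

    def test_zero_series(self):
        series = cci_timeseries(_env(np.zeros(101)), _env(np.zeros(101), "G"))
        assert cci_window(series, 0, 100) == 0.0

    def test_arithmetic_sequence(self):
        # equal envelopes t/200 make CCI(t) = t/100
        ramp = np.arange(101) / 200.0
        series = cci_timeseries(_env(ramp), _env(ramp, "G"))
        assert cci_window(series, 0, 100) == pytest.approx(0.5)

    def test_span_divisor_variant(self):
        ramp = np.arange(101) / 200.0
        series = cci_timeseries(_env(ramp), _env(ramp, "G"))
        assert cci_window(series, 0, 100, divisor="span") == pytest.approx(50.5 / 100)

    def test_oracle_equivalence_1000_pairs(self, rng):
        boundaries = rng.integers(20, 81, size=1000)
        for i in range(1000):
            a = rng.uniform(0, 1, 101)
            b = rng.uniform(0, 1, 101)
            series = cci_timeseries(_env(a), _env(b, "G"))
            sb = int(boundaries[i])
            for t1, t2 in ((0, 100), (0, sb), (sb, 100)):
                assert cci_window(series, t1, t2) == pytest.approx(
                    brute_force_cci(a, b, t1, t2), abs=1e-10
                )


class TestFiducial:
    def test_constant_full_window(self):
        out = fiducial_features(np.ones(101), 0, 100)
        assert out == {
            "A": 1.0, "MAX": 1.0, "MIN": 1.0, "T_MAX": 0.0, "T_MIN": 0.0, "AUC": 100.0,
        }

    def test_single_peak_in_swing(self):
        values = np.zeros(101)
        values[75] = 1.0
        out = fiducial_features(values, 60, 100)
        assert out["T_MAX"] == 75.0
        assert out["MAX"] == 1.0

    def test_linear_ramp(self):
        out = fiducial_features(np.linspace(0, 1, 101), 0, 100)
        assert out["A"] == pytest.approx(0.5)
        assert out["T_MIN"] == 0.0
        assert out["T_MAX"] == 100.0
        assert out["AUC"] == pytest.approx(50.0)

    def test_first_occurrence_tiebreak(self):
        values = np.zeros(101)
        values[[10, 20]] = 1.0
        out = fiducial_features(values, 0, 100)
        assert out["T_MAX"] == 10.0
        assert out["T_MIN"] == 0.0

    def test_degenerate_window(self):
        with pytest.raises(ValueError, match="degenerate"):
            fiducial_features(np.ones(101), 50, 50)


class TestWindows:
    def test_bounds(self):
        assert window_bounds("", 60) == (0, 100)
        assert window_bounds("ST", 60) == (0, 60)
        assert window_bounds("SW", 60) == (60, 100)

    def test_unknown_window(self):
        with pytest.raises(ValueError, match="unknown window"):
            window_bounds("XX", 60)


class TestTemporospatial:
    def _events(self, durations):
        hs = np.concatenate([[0.0], np.cumsum(durations)])
        to = hs[:-1] + 0.6 * np.asarray(durations)
        return GaitEventSet(hs, to)

    def test_cadence_from_duration(self):
        ts = temporospatial_features(self._events([1.0]), 1.2, 0.6)
        assert ts.cadence == pytest.approx(120.0)

    def test_speed_ratio(self):
        ts = temporospatial_features(self._events([1.2]), 1.2, 0.6)
        assert ts.speed == pytest.approx(1.0)

    def test_cadence_constancy(self):
        ts = temporospatial_features(self._events([1.0, 1.0, 1.0]), 1.2, 0.6)
        assert ts.cadence == pytest.approx(120.0)

    def test_single_event_rejected(self):
        with pytest.raises(Exception):
            temporospatial_features(GaitEventSet(np.array([0.0]), np.array([])), 1.2, 0.6)


def _limb_envelopes(rng, boundary=60):
    out = {}
    for m in MUSCLES:
        v = rng.uniform(0, 1, 101)
        v[rng.integers(0, 101)] = 1.0  # normalized waveforms peak at 1
        out[m] = NormalizedEnvelope(v, boundary, m)
    return out


class TestFeatureTable:
    def test_expected_columns(self):
        cols = feature_columns()
        for name in ("G_SW_A", "CCI_TA-G_SW_A", "MH_ST_MIN", "CCI_RF-G_ST_MIN", "speed"):
            assert name in cols
        # 4 muscles x 3 windows x 6 stats + 4 pairs x 3 windows x 6 stats + 4 TS
        assert len(cols) == 4 * 3 * 6 + 4 * 3 * 6 + 4

    def test_two_limb_cohort(self, small_cohort_table):
        assert len(small_cohort_table) == 8  # 4 subjects x 2 limbs
        assert set(feature_columns()) <= set(small_cohort_table.columns)
        assert not small_cohort_table[feature_columns()].isna().any().any()

    def test_latencies_in_range(self, small_cohort_table):
        t_cols = [c for c in small_cohort_table.columns if "_T_" in c]
        assert t_cols
        vals = small_cohort_table[t_cols].to_numpy()
        assert np.all((vals >= 0) & (vals <= 100))

    def test_muscle_order_invariance(self, rng):
        envs = _limb_envelopes(rng)
        ts = TemporospatialRecord(1.0, 0.6, 1.2, 110.0)
        forward = limb_features(envs, ts)
        reversed_envs = {m: envs[m] for m in reversed(MUSCLES)}
        assert limb_features(reversed_envs, ts) == forward

    def test_missing_muscle_skipped(self, rng, caplog):
        from emgait.core import LimbRecord, PROMRecord

        envs = _limb_envelopes(rng)
        del envs["G"]
        rec = LimbRecord(
            subject_id="S0",
            limb="left",
            envelopes=envs,
            temporospatial=TemporospatialRecord(1.0, 0.6, 1.2, 110.0),
            prom=PROMRecord(np.zeros(24, dtype=int), 0.0),
        )
        with caplog.at_level("WARNING"):
            table = build_feature_table([rec])
        assert len(table) == 0
        assert "G" in caplog.text


class TestSeveritySensitivity:
    def test_cci_ta_g_monotone_in_groups(self, default_cohort_table):
        """Group-mean swing TA-G co-contraction rises mild -> moderate -> severe."""
        from emgait.prom import categorize_womac_total

        table = default_cohort_table
        labels = table["womac_total"].map(categorize_womac_total)
        means = [
            table.loc[labels == g, "CCI_TA-G_SW_A"].mean()
            for g in ("mild", "moderate", "severe")
        ]
        assert means[0] < means[1] < means[2]
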