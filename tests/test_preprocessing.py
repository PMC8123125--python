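import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amperofit import AmperogramTrace, FilterConfig, TraceRejection, alpha_from_p, clean_trace, ema_filter
from amperofit.preprocessing import EmaStream, alpha_report_value


def trace_from(values, dt=1.0):
    values = np.asarray(values, dtype=float)
    return AmperogramTrace(times=np.arange(len(values)) * dt, currents=values, dt=dt)


class TestEmaFilter:
    def test_alpha_one_is_identity(self, rng):
        tr = trace_from(rng.normal(10, 2, 50))
        out = ema_filter(tr, FilterConfig(alpha=1.0))
        np.testing.assert_array_equal(out.currents, tr.currents)

    def test_constant_input_is_fixed_point(self):
        tr = trace_from(np.full(30, 7.5))
        out = ema_filter(tr, FilterConfig(alpha=0.3))
        np.testing.assert_allclose(out.currents, 7.5)

    def test_hand_evaluated_recurrence(self):
        out = ema_filter(
            trace_from([0.0, 1.0, 1.0]),
            FilterConfig(alpha=0.5, initial_value=0.0),
        )
        np.testing.assert_allclose(out.currents, [0.0, 0.5, 0.75])

    def test_invalid_alpha(self):
        for alpha in (0.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                FilterConfig(alpha=alpha)

    @given(
        values=st.lists(st.floats(-100, 100), min_size=2, max_size=40),
        alpha=st.floats(0.01, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_output_within_input_range(self, values, alpha):
        tr = trace_from(values)
        out = ema_filter(tr, FilterConfig(alpha=alpha))
        assert np.min(tr.currents) - 1e-9 <= np.min(out.currents)
        assert np.max(out.currents) <= np.max(tr.currents) + 1e-9

    def test_stream_matches_batch(self, rng):
        tr = trace_from(rng.normal(5, 1, 80))
        cfg = FilterConfig(alpha=0.22)
        stream = EmaStream(cfg)
        streamed = np.array([stream.update(v) for v in tr.currents])
        np.testing.assert_array_equal(streamed, ema_filter(tr, cfg).currents)


class TestAlphaSchedule:
    # the printed sweep table: p -> smoothing constant, at printed precision
    PRINTED = {2: 0.6667, 4: 0.4, 6: 0.285, 8: 0.22, 10: 0.182, 12: 0.154,
               14: 0.133, 16: 0.118, 18: 0.105, 20: 0.095}

    def test_formula(self):
        assert alpha_from_p(8) == pytest.approx(2.0 / 9.0)
        assert alpha_from_p(2) == pytest.approx(0.6667, abs=5e-5)
        assert alpha_from_p(1) == 1.0

    def test_reproduces_printed_sweep_values(self):
        # one printed value (p=6: 0.285) is a truncation of 0.2857, so the
        # check is agreement within one unit in the last printed digit
        for p, printed in self.PRINTED.items():
            decimals = len(str(printed).split(".")[1])
            assert abs(alpha_from_p(p) - printed) <= 10 ** -decimals

    def test_monotone_in_p(self):
        alphas = [alpha_from_p(p) for p in range(1, 30)]
        assert all(a > b for a, b in zip(alphas, alphas[1:]))

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            alpha_from_p(0)

    def test_report_rounding(self):
        assert alpha_report_value(8, 2) == 0.22


class TestSmoothingTradeoff:
    def test_smoothing_monotone_in_alpha(self, rng):
        """Variance of filtered first differences shrinks as alpha does."""
        tr = trace_from(10 + rng.normal(0, 1, 400))
        variances = []
        for p in range(2, 21, 2):
            out = ema_filter(tr, FilterConfig(alpha=alpha_from_p(p)))
            variances.append(np.var(np.diff(out.currents)))
        assert all(a >= b for a, b in zip(variances, variances[1:]))

    def test_step_lag_monotone_in_alpha(self):
        """Smaller alpha reaches 63% of a unit step later (or as late)."""
        step = trace_from(np.concatenate([np.zeros(1), np.ones(120)]))
        lags = []
        for p in range(2, 21, 2):
            out = ema_filter(step, FilterConfig(alpha=alpha_from_p(p)))
            lags.append(int(np.argmax(out.currents >= 0.632)))
        assert all(a <= b for a, b in zip(lags, lags[1:]))


class TestCleanTrace:
    def test_accepts_well_formed(self):
        t = np.arange(100.0)
        out = clean_trace(t, 10 + np.sin(t))
        assert isinstance(out, AmperogramTrace)
        assert len(out) == 100

    def test_missing_value(self):
        y = np.ones(20)
        y[7] = np.nan
        out = clean_trace(np.arange(20.0), y)
        assert isinstance(out, TraceRejection) and out.reason == "non_finite_values"

    def test_signal_loss_run_of_zeros(self):
        y = np.ones(50)
        y[20:25] = 0.0
        out = clean_trace(np.arange(50.0), y)
        assert isinstance(out, TraceRejection) and out.reason == "signal_loss"
        # short dropouts below gap_max are tolerated
        y = np.ones(50)
        y[20:22] = 0.0
        assert isinstance(clean_trace(np.arange(50.0), y), AmperogramTrace)

    def test_non_uniform_sampling(self):
        t = np.arange(30.0)
        t[10] += 0.5
        out = clean_trace(t, np.ones(30))
        assert isinstance(out, TraceRejection) and out.reason == "non_uniform_sampling"

    def test_too_short(self):
        out = clean_trace(np.array([0.0]), np.array([1.0]))
        assert isinstance(out, TraceRejection) and out.reason == "too_short"
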