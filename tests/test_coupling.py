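"""Normalized cross-correlation, peak extraction, per-trial coupling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fearlfp import (
    CouplingResult,
    peak_coupling,
    session_coupling_average,
    trial_coupling,
    xcorr_coeff,
)


def brute_xcorr_coeff(x, y, max_lag):
    """Independent O(N*L) oracle for the raw-moment normalized cross-correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    denom = np.sqrt(np.dot(x, x) * np.dot(y, y))
    out = []
    for m in range(-max_lag, max_lag + 1):
        if m >= 0:
            s = sum(x[k + m] * y[k] for k in range(n - m))
        else:
            s = sum(y[k - m] * x[k] for k in range(n + m))
        out.append(s / denom)
    return np.array(out)


def test_hand_computed_example():
    res = xcorr_coeff([1, 2, 3, 4], [4, 3, 2, 1], max_lag=3)
    np.testing.assert_allclose(
        res.coefficients, brute_xcorr_coeff([1, 2, 3, 4], [4, 3, 2, 1], 3), atol=1e-12
    )


def test_identical_and_negated_signals(rng):
    x = rng.standard_normal(256)
    peak, lag = peak_coupling(xcorr_coeff(x, x, 64, 1000.0))
    assert peak == pytest.approx(1.0, abs=1e-12)
    assert lag == 0.0
    res = xcorr_coeff(x, -x, 64, 1000.0)
    assert res.coefficients[64] == pytest.approx(-1.0, abs=1e-12)


finite_arrays = hnp.arrays(
    np.float64,
    st.integers(8, 64),
    elements=st.floats(-1e3, 1e3, allow_nan=False, width=32),
)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(finite_arrays, finite_arrays, st.integers(1, 7))
def test_bounded_and_antisymmetric(x, y, max_lag):
    """|coefficients| <= 1 and Rxy(m) from (x,y) equals Ryx(-m) from (y,x)."""
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    assume(np.dot(x, x) > 0 and np.dot(y, y) > 0)
    res_xy = xcorr_coeff(x, y, max_lag)
    res_yx = xcorr_coeff(y, x, max_lag)
    assert np.all(np.abs(res_xy.coefficients) <= 1 + 1e-12)
    np.testing.assert_allclose(
        res_xy.coefficients, res_yx.coefficients[::-1], atol=1e-12
    )


def test_fft_equals_brute_force(rng):
    for _ in range(10):
        n = int(rng.integers(16, 300))
        L = int(rng.integers(1, n))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        np.testing.assert_allclose(
            xcorr_coeff(x, y, L).coefficients,
            brute_xcorr_coeff(x, y, L),
            rtol=1e-10,
            atol=1e-12,
        )


def test_errors():
    with pytest.raises(ValueError, match="length mismatch"):
        xcorr_coeff([1.0, 2.0], [1.0], 1)
    with pytest.raises(ValueError, match="max_lag"):
        xcorr_coeff([1.0, 2.0], [1.0, 2.0], 5)
    with pytest.raises(ValueError, match="zero-energy"):
        xcorr_coeff([0.0, 0.0], [1.0, 2.0], 1)


class TestPeak:
    @staticmethod
    def _result(coeffs, fs=1000.0):
        L = (len(coeffs) - 1) // 2
        return CouplingResult(
            lags=np.arange(-L, L + 1),
            coefficients=np.asarray(coeffs, float),
            sampling_rate_hz=fs,
        )

    def test_unique_maximum(self):
        peak, lag = peak_coupling(self._result([0.1, 0.2, 0.3, 0.2, 0.52]))
        assert (peak, lag) == (0.52, 2.0)

    def test_symmetric_tie_prefers_negative_lag(self):
        # equal maxima at lags -10 and +10 samples -> -10 ms at 1 kHz
        coeffs = np.zeros(21)
        coeffs[0] = coeffs[20] = 0.5
        peak, lag = peak_coupling(self._result(coeffs))
        assert (peak, lag) == (0.5, -10.0)

    def test_absolute_mode_keeps_sign(self):
        peak, lag = peak_coupling(self._result([-0.9, 0.1, 0.5]), mode="absolute")
        assert (peak, lag) == (-0.9, -1.0)
        peak_signed, _ = peak_coupling(self._result([-0.9, 0.1, 0.5]))
        assert peak_signed == 0.5

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            peak_coupling(self._result([0.1, 0.2, 0.1]), mode="rms")


class TestTrialCoupling:
    fs = 500.0

    def _events(self, onsets):
        return pd.DataFrame(
            {
                "session": "S",
                "trial_index": np.arange(1, len(onsets) + 1),
                "stimulus": "CS_PLUS",
                "onset_s": onsets,
            }
        )

    def test_identical_channels_peak_one_at_zero(self, rng):
        x = rng.standard_normal(int(60 * self.fs))
        out = trial_coupling(x, x, self._events([20.0, 40.0]), self.fs, max_lag=100)
        assert len(out) == 2
        for r in out:
            assert r.peak_coeff == pytest.approx(1.0, abs=1e-12)
            assert r.peak_lag_ms == 0.0
            assert r.trial_index in (1, 2)

    def test_envelope_mode_runs(self, rng):
        x = rng.standard_normal(int(40 * self.fs))
        y = rng.standard_normal(int(40 * self.fs))
        out = trial_coupling(
            x, y, self._events([20.0]), self.fs, max_lag=50, amplitude_mode="envelope"
        )
        assert abs(out[0].peak_coeff) <= 1 + 1e-12

    def test_window_outside_recording_raises(self, rng):
        x = rng.standard_normal(int(20 * self.fs))
        with pytest.raises(ValueError, match="outside"):
            trial_coupling(x, x, self._events([10.0]), self.fs, max_lag=10)


def test_zero_coupling_indistinguishable_from_shuffled_null():
    """With no injected coupling, the mean observed peak does not exceed the
    95th percentile of a trial-shuffled null (200 shuffles)."""
    from fearlfp import FilterSpec, THETA, apply_zero_phase, design_bandpass
    from fearlfp.power import window_indices
    from fearlfp.simulate import CS_MINUS, CS_PLUS, simulate_sessions
    from conftest import make_config, make_plan

    plan = make_plan((("S", "A", 20, 0, False),))
    config = make_config(
        plan,
        seed=99,
        band_components=(("theta", 60.0),),
        cs_gain_table={
            (r, "S", s, "theta"): 1.0 for r in ("PL", "IL") for s in (CS_PLUS, CS_MINUS)
        },
        coupling_table={("S", CS_PLUS): 0.0, ("S", CS_MINUS): 0.0},
    )
    signals, events, _, _ = simulate_sessions(config, plan)
    fs = config.sampling_rate_hz
    fir = design_bandpass(THETA, FilterSpec(), fs)
    windows = {}
    for region in ("PL", "IL"):
        filt = apply_zero_phase(signals["S"][region].astype(np.float64), fir)
        windows[region] = [
            filt[slice(*window_indices(r.onset_s, r.onset_s + 15.0, fs))]
            for r in events.itertuples()
        ]

    def mean_peak(pairing):
        peaks = [
            peak_coupling(xcorr_coeff(windows["PL"][i], windows["IL"][j], 250, fs))[0]
            for i, j in pairing
        ]
        return np.mean(peaks)

    n = len(events)
    observed = mean_peak(list(zip(range(n), range(n))))
    rng = np.random.default_rng(5)
    null = [mean_peak(list(enumerate(rng.permutation(n)))) for _ in range(200)]
    assert observed <= np.percentile(null, 95)


def test_session_average_by_hand():
    df = pd.DataFrame(
        {
            "session": ["A", "A", "B", "B", "B"],
            "stimulus": "CS_PLUS",
            "trial_index": [1, 2, 1, 2, 3],
            "peak_coeff": [0.5, 0.5, 0.2, 0.4, 0.6],
        }
    )
    out = session_coupling_average(df).set_index("session")
    assert out.loc["A", "mean"] == 0.5
    assert out.loc["A", "sem"] == 0.0
    assert out.loc["B", "mean"] == pytest.approx(0.4)
    assert out.loc["B", "sem"] == pytest.approx(0.2 / np.sqrt(3), abs=1e-4)
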