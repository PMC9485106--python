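"""Synthetic dataset generator: noise shaping, oscillations, protocol structure."""

import numpy as np
import pandas as pd
import pytest

from fearlfp import (
    DEFAULT_PLAN,
    THETA,
    GroundTruth,
    generate_band_oscillation,
    generate_freezing,
    generate_pink_noise,
)
from fearlfp.simulate import CS_MINUS, CS_PLUS, simulate_sessions
from conftest import make_config, make_plan


class TestPinkNoise:
    def test_white_limit_rms(self):
        x = generate_pink_noise(10000, exponent=0.0, rms=1.0, seed=1)
        assert np.sqrt(np.mean(x**2)) == pytest.approx(1.0, rel=0.05)

    def test_spectral_slope_near_minus_one(self):
        """Periodogram log-log slope of 1/f noise, fit with an independent DFT."""
        fs, n = 1000.0, 2**14
        x = generate_pink_noise(n, exponent=1.0, rms=1.0, seed=2)
        freqs = np.fft.rfftfreq(n, 1 / fs)
        power = np.abs(np.fft.rfft(x)) ** 2
        sel = (freqs >= 1.0) & (freqs <= 100.0)
        slope = np.polyfit(np.log10(freqs[sel]), np.log10(power[sel]), 1)[0]
        assert -1.3 <= slope <= -0.7

    def test_determinism_and_errors(self):
        a = generate_pink_noise(5000, 1.0, 2.0, seed=9)
        b = generate_pink_noise(5000, 1.0, 2.0, seed=9)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            generate_pink_noise(0, 1.0, 1.0, seed=1)
        with pytest.raises(ValueError):
            generate_pink_noise(100, 1.0, -1.0, seed=1)


class TestBandOscillation:
    def test_power_confined_to_band(self):
        fs, n = 1000.0, 16384
        x = generate_band_oscillation(THETA, n, fs, amplitude=1.0, seed=3)
        freqs = np.fft.rfftfreq(n, 1 / fs)
        power = np.abs(np.fft.rfft(x)) ** 2
        in_band = power[(freqs >= THETA.f_lo) & (freqs <= THETA.f_hi)].sum()
        assert in_band / power.sum() >= 0.90

    def test_zero_amplitude(self):
        assert np.all(generate_band_oscillation(THETA, 1000, 500.0, 0.0, seed=1) == 0)

    def test_seeds_differ_rms_matches(self):
        a = generate_band_oscillation(THETA, 8192, 500.0, 1.0, seed=1)
        b = generate_band_oscillation(THETA, 8192, 500.0, 1.0, seed=2)
        assert not np.array_equal(a, b)
        target = 1.0 / np.sqrt(2.0)
        for x in (a, b):
            assert np.sqrt(np.mean(x**2)) == pytest.approx(target, rel=0.05)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            generate_band_oscillation(THETA, 1000, 15.0, 1.0, seed=1)


class TestProtocolStructure:
    """Event-level structure of the full default simulated protocol."""

    def test_default_plan_trial_counts(self, default_world):
        _, _, events, _ = default_world
        counts = events.groupby("stimulus").size()
        assert counts[CS_PLUS] == 38
        assert counts[CS_MINUS] == 38
        per_session = events.groupby(["session", "stimulus"]).size().unstack()
        expected = {"Hab": 5, "ACQ": 5, "EXT1": 12, "EXT2": 12, "EXT_recall": 2, "Renewal": 2}
        for session, n in expected.items():
            assert per_session.loc[session, CS_PLUS] == n
            assert per_session.loc[session, CS_MINUS] == n

    def test_itis_within_range_and_baselines(self, default_world):
        config, _, events, _ = default_world
        for _, grp in events.groupby("session"):
            onsets = grp["onset_s"].to_numpy()
            itis = np.diff(onsets) - DEFAULT_PLAN.cs_duration_s
            assert np.all(itis >= config.iti_range_s[0])
            assert np.all(itis <= config.iti_range_s[1])
            assert onsets[0] >= 15.0

    def test_pseudorandom_order_constraint(self, default_world):
        """No more than 3 consecutive same-type stimuli within a session."""
        _, _, events, _ = default_world
        for _, grp in events.groupby("session"):
            stims = grp.sort_values("onset_s")["stimulus"].to_list()
            run = 1
            for a, b in zip(stims, stims[1:]):
                run = run + 1 if a == b else 1
                assert run <= 3

    def test_us_paired_only_in_acquisition_cs_plus(self, default_world):
        _, _, events, _ = default_world
        with_us = events[events["us_onset_s"] != ""]
        assert set(with_us["session"]) == {"ACQ"}
        assert set(with_us["stimulus"]) == {CS_PLUS}
        # US at the offset of the last pip: 19 pips / 1.5 Hz + 0.5 s
        delay = with_us["us_onset_s"].astype(float) - with_us["onset_s"]
        assert np.allclose(delay, 19 / 1.5 + 0.5, atol=1e-6)


def test_full_coupling_no_noise_components_identical():
    """Coupling 1 at lag 0 with no noise: IL theta equals PL theta in CS windows."""
    plan = make_plan((("Hab", "A", 2, 1, False),))
    config = make_config(
        plan,
        noise_rms_uV=0.0,
        band_components=(("theta", 60.0),),
        cs_gain_table={
            (r, "Hab", s, "theta"): 1.0
            for r in ("PL", "IL")
            for s in (CS_PLUS, CS_MINUS)
        },
        coupling_table={("Hab", CS_PLUS): 1.0, ("Hab", CS_MINUS): 1.0},
        coupling_lag_ms=0.0,
    )
    signals, events, _, extras = simulate_sessions(config, plan, return_components=True)
    comp = extras["components"]["Hab"]
    fs = config.sampling_rate_hz
    for row in events.itertuples():
        # interior of the CS window, past the on/off amplitude ramps
        i0 = int((row.onset_s + 0.5) * fs)
        i1 = int((row.onset_s + 29.5) * fs)
        np.testing.assert_array_equal(
            comp["PL_theta"][i0:i1], comp["IL_theta"][i0:i1]
        )


def test_simulation_determinism(tiny_config, tiny_plan):
    s1, e1, g1, _ = simulate_sessions(tiny_config, tiny_plan)
    s2, e2, g2, _ = simulate_sessions(tiny_config, tiny_plan)
    pd.testing.assert_frame_equal(e1, e2)
    pd.testing.assert_frame_equal(g1.trials, g2.trials)
    for session in s1:
        for region in s1[session]:
            np.testing.assert_array_equal(s1[session][region], s2[session][region])


def test_gain_table_validation(tiny_plan):
    with pytest.raises(ValueError, match="does not match"):
        config = make_config(tiny_plan)
        bad = dict(config.cs_gain_table)
        bad[("PL", "NoSuchSession", CS_PLUS, "theta")] = 2.0
        simulate_sessions(
            make_config(tiny_plan, cs_gain_table=bad), tiny_plan
        )
    with pytest.raises(ValueError, match="coupling coefficient"):
        make_config(tiny_plan, coupling_table={("Hab", CS_PLUS): 1.5})


class TestFreezing:
    @staticmethod
    def _gt(gain_by_session):
        rows = []
        for session, gain in gain_by_session.items():
            for stim in (CS_PLUS, CS_MINUS):
                for ti in range(1, 6):
                    rows.append(
                        {
                            "session": session,
                            "stimulus": stim,
                            "trial_index": ti,
                            "gain_PL_theta": gain if stim == CS_PLUS else 1.0,
                        }
                    )
        return GroundTruth(
            trials=pd.DataFrame(rows), coupling=pd.DataFrame(), seed=0
        )

    def test_no_fear_state_low_baseline(self):
        out = generate_freezing(self._gt({"Hab": 1.0}), seed=4)
        assert out["freezing_pct"].between(0, 100).all()
        assert out["freezing_pct"].mean() < 20.0

    def test_acquisition_exceeds_habituation_in_expectation(self):
        gt = self._gt({"Hab": 1.0, "ACQ": 1.6})
        diffs = []
        for seed in range(100):
            out = generate_freezing(gt, seed=seed)
            by = out[out.stimulus == CS_PLUS].groupby("session")["freezing_pct"].mean()
            diffs.append(by["ACQ"] - by["Hab"])
        assert np.mean(diffs) > 0

    def test_determinism(self):
        gt = self._gt({"Hab": 1.0})
        pd.testing.assert_frame_equal(
            generate_freezing(gt, seed=11), generate_freezing(gt, seed=11)
        )
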