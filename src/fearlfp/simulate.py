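"""Synthetic two-region LFP datasets for the 5-day discriminative fear protocol.

The generator emulates the statistical structure the analysis assumes:

* a 1/f^beta pink-noise background per region,
* band-limited stochastic oscillations in theta (4-10 Hz), slow gamma
  (30-55 Hz) and fast gamma (55-100 Hz), realized as brick-wall
  band-filtered Gaussian noise (stationary, with analytically known power),
* multiplicative CS-evoked amplitude gains per (region, session, stimulus,
  band), applied with 200 ms raised-cosine ramps at CS on/offset,
* a shared, lag-shifted theta component controlling PL-IL coupling: inside
  a CS window with coupling coefficient c, the IL theta component is
  c * (lag-shifted unit-variance PL theta) + sqrt(1-c^2) * independent theta,
  so the theoretical peak correlation of the components equals c.

Every draw goes through one seeded generator, so a fixed (config, plan,
seed) triple yields a byte-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len

from .filters import CANONICAL_BANDS, BandDefinition

__all__ = [
    "SessionSpec",
    "SessionPlan",
    "SimulationConfig",
    "GroundTruth",
    "DEFAULT_PLAN",
    "CS_PLUS",
    "CS_MINUS",
    "REGIONS",
    "default_gain_table",
    "default_coupling_table",
    "generate_pink_noise",
    "generate_band_oscillation",
    "simulate_sessions",
    "simulate_dafc_dataset",
    "generate_freezing",
]

CS_PLUS = "CS_PLUS"
CS_MINUS = "CS_MINUS"
REGIONS = ("PL", "IL")

_BANDS: dict[str, BandDefinition] = {b.name: b for b in CANONICAL_BANDS}

# CS-evoked envelope ramp at on/offset; avoids spectral splatter from a
# step change in amplitude.
RAMP_S = 0.2


@dataclass(frozen=True)
class SessionSpec:
    name: str
    context: str
    n_cs_plus: int
    n_cs_minus: int
    us_paired: bool = False


@dataclass(frozen=True)
class SessionPlan:
    """Trial structure of the behavioral protocol.

    The default matches the 5-day discriminative auditory fear conditioning
    design: habituation (5 CS+/5 CS-, context A), acquisition (5/5, CS+
    paired with the foot-shock US, context A), two extinction days (12/12,
    context B), extinction recall (2/2, context B) and renewal (2/2,
    context A).  Each CS lasts 30 s and consists of 20 pips of 500 ms at
    1.5 Hz.
    """

    sessions: tuple[SessionSpec, ...]
    cs_duration_s: float = 30.0
    pip_rate_hz: float = 1.5
    pip_duration_ms: float = 500.0
    n_pips: int = 20
    lead_in_s: float = 180.0  # free context exploration before the first trial
    tail_s: float = 10.0

    def __post_init__(self) -> None:
        if self.n_pips / self.pip_rate_hz > self.cs_duration_s:
            raise ValueError("pip train does not fit inside cs_duration_s")
        if self.lead_in_s < 0 or self.tail_s < 0:
            raise ValueError("lead_in_s and tail_s must be non-negative")

    def session_names(self) -> list[str]:
        return [s.name for s in self.sessions]


DEFAULT_PLAN = SessionPlan(
    sessions=(
        SessionSpec("Hab", "A", 5, 5),
        SessionSpec("ACQ", "A", 5, 5, us_paired=True),
        SessionSpec("EXT1", "B", 12, 12),
        SessionSpec("EXT2", "B", 12, 12),
        SessionSpec("EXT_recall", "B", 2, 2),
        SessionSpec("Renewal", "A", 2, 2),
    )
)


def default_gain_table(plan: SessionPlan = DEFAULT_PLAN) -> dict:
    """CS-evoked amplitude gains emulating the observed state pattern.

    PL theta rises in high-fear states (acquisition, renewal) and dips in
    late extinction; IL theta rises in late extinction and drops in
    renewal.  Gamma bands and all CS- responses are unchanged (gain 1).
    Keys are (region, session, stimulus, band) -> amplitude gain.
    """
    table = {
        (r, s.name, stim, b): 1.0
        for r in REGIONS
        for s in plan.sessions
        for stim in (CS_PLUS, CS_MINUS)
        for b in _BANDS
    }
    # ACQ and Renewal share one "high fear" gain: both are reported elevated
    # but no ordering between them is claimed.
    overrides = {
        ("PL", "ACQ", CS_PLUS, "theta"): 1.5,
        ("PL", "EXT2", CS_PLUS, "theta"): 0.8,
        ("PL", "Renewal", CS_PLUS, "theta"): 1.5,
        ("IL", "EXT2", CS_PLUS, "theta"): 1.5,
        ("IL", "Renewal", CS_PLUS, "theta"): 0.7,
    }
    for k, v in overrides.items():
        if k in table:
            table[k] = v
    return table


def default_coupling_table(plan: SessionPlan = DEFAULT_PLAN) -> dict:
    """Theta coupling coefficients per (session, stimulus).

    CS+ coupling is high throughout fear and extinction learning and its
    recall, and drops in renewal (the representative recorded peaks are
    0.520 in extinction recall vs 0.323 in renewal); CS- coupling stays at
    the habituation level.
    """
    high = {"ACQ", "EXT1", "EXT2", "EXT_recall"}
    table = {}
    for s in plan.sessions:
        if s.name in high:
            c_plus = 0.52
        elif s.name == "Renewal":
            c_plus = 0.32
        else:
            c_plus = 0.25
        table[(s.name, CS_PLUS)] = c_plus
        table[(s.name, CS_MINUS)] = 0.25
    return table


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of the synthetic world.

    Amplitudes are in microvolts; ``band_components`` gives the sinusoid-
    equivalent center amplitude per band (the component's RMS is
    amplitude/sqrt(2)).  ``cs_gain_table`` maps (region, session, stimulus,
    band) to a multiplicative amplitude gain active during that CS window;
    ``coupling_table`` maps (session, stimulus) to the fraction of the IL
    theta component shared (lag-shifted) with PL.
    """

    sampling_rate_hz: float = 1000.0
    noise_exponent: float = 1.0
    noise_rms_uV: float = 15.0
    band_components: tuple[tuple[str, float], ...] = (
        ("theta", 60.0),
        ("slow_gamma", 25.0),
        ("fast_gamma", 15.0),
    )
    cs_gain_table: dict = field(default_factory=default_gain_table)
    coupling_table: dict = field(default_factory=default_coupling_table)
    coupling_lag_ms: float = 10.0
    mains_hz: float = 0.0  # optional 50 Hz contamination amplitude is mains_amp_uV
    mains_amp_uV: float = 0.0
    iti_range_s: tuple[float, float] = (90.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.noise_rms_uV < 0:
            raise ValueError("noise_rms_uV must be non-negative")
        lo, hi = self.iti_range_s
        if not lo <= hi:
            raise ValueError("iti_range_s must satisfy low <= high")
        for key, g in self.cs_gain_table.items():
            if g < 0:
                raise ValueError(f"gain for {key} must be >= 0")
        for key, c in self.coupling_table.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coupling coefficient for {key} must be in [0, 1]")

    def validate_against(self, plan: SessionPlan) -> None:
        names = set(plan.session_names())
        bands = {b for b, _ in self.band_components}
        for region, session, stim, band in self.cs_gain_table:
            if region not in REGIONS or session not in names or band not in bands:
                raise ValueError(
                    f"cs_gain_table key ({region}, {session}, {stim}, {band}) does not "
                    "match the session plan / regions / band components"
                )
        for session, _stim in self.coupling_table:
            if session not in names:
                raise ValueError(
                    f"coupling_table references unknown session {session!r}"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Injected per-trial gains and per-session coupling, for recovery checks."""

    trials: pd.DataFrame  # session, stimulus, trial_index, onset_s, per-band gains
    coupling: pd.DataFrame  # session, stimulus, coefficient, lag_ms
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "trials": self.trials.to_dict(orient="records"),
            "coupling": self.coupling.to_dict(orient="records"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            trials=pd.DataFrame(d["trials"]),
            coupling=pd.DataFrame(d["coupling"]),
            seed=int(d["seed"]),
        )


# ---------------------------------------------------------------------------
# elementary generators


def generate_pink_noise(
    n_samples: int,
    exponent: float,
    rms: float,
    seed: int | np.random.Generator,
    dtype=np.float64,
) -> np.ndarray:
    """1/f^exponent Gaussian noise, shaped in the frequency domain.

    The spectrum is drawn as complex Gaussian coefficients scaled by
    f^(-exponent/2) (DC removed) and inverted; the result is rescaled to
    the requested sample RMS exactly.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if rms <= 0:
        raise ValueError("rms must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # synthesize at an FFT-friendly length and truncate; the process is
    # stationary, so the truncated segment has the same spectral shape
    n_fft = next_fast_len(n_samples, real=True)
    n_freq = n_fft // 2 + 1
    rdtype = np.float32 if dtype == np.float32 else np.float64
    draws = rng.standard_normal(2 * n_freq, dtype=rdtype)
    spec = draws[:n_freq] + 1j * draws[n_freq:]
    f = np.arange(1, n_freq, dtype=rdtype)
    envelope = np.zeros(n_freq, dtype=rdtype)
    if exponent == 1.0:
        envelope[1:] = 1.0 / np.sqrt(f)
    else:
        envelope[1:] = f ** (-exponent / 2.0)
    x = np.fft.irfft(spec * envelope, n=n_fft)[:n_samples]
    x *= rms / np.sqrt(np.mean(np.square(x, dtype=np.float64)))
    return x.astype(dtype, copy=False)


def _unit_band_noise(
    n_samples: int,
    fs: float,
    f_lo: float,
    f_hi: float,
    rng: np.random.Generator,
    dtype=np.float64,
) -> np.ndarray:
    """Unit-RMS Gaussian noise confined to [f_lo, f_hi] (brick-wall in frequency).

    Only the in-band DFT coefficients are drawn (the rest are zero), so the
    cost per signal is one inverse real FFT plus a few thousand Gaussian
    draws.
    """
    n_fft = next_fast_len(n_samples, real=True)
    n_freq = n_fft // 2 + 1
    # bin k sits at frequency k * fs / n_fft
    k_lo = int(np.ceil(f_lo * n_fft / fs))
    k_hi = min(int(np.floor(f_hi * n_fft / fs)), n_freq - 1)
    if k_hi < k_lo:
        raise ValueError(f"band [{f_lo}, {f_hi}] Hz contains no DFT bins at n={n_samples}")
    rdtype = np.float32 if dtype == np.float32 else np.float64
    n_band = k_hi - k_lo + 1
    draws = rng.standard_normal(2 * n_band, dtype=rdtype)
    spec = np.zeros(n_freq, dtype=np.complex64 if dtype == np.float32 else np.complex128)
    spec[k_lo : k_hi + 1] = draws[:n_band] + 1j * draws[n_band:]
    x = np.fft.irfft(spec, n=n_fft)[:n_samples]
    norm = np.sqrt(np.mean(np.square(x, dtype=np.float64)))
    if norm == 0:
        raise ValueError(f"band [{f_lo}, {f_hi}] Hz contains no DFT bins at n={n_samples}")
    return (x / norm).astype(dtype, copy=False)


def generate_band_oscillation(
    band: BandDefinition,
    n_samples: int,
    sampling_rate_hz: float,
    amplitude: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Narrowband stochastic oscillation with RMS = amplitude / sqrt(2).

    Realized as brick-wall band-filtered Gaussian noise, so all of its
    power lies inside [f_lo, f_hi].  ``amplitude`` is the equivalent
    sinusoid amplitude (a pure tone of that amplitude has the same RMS).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    band.validate_for(sampling_rate_hz)
    if amplitude == 0:
        return np.zeros(n_samples)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = _unit_band_noise(n_samples, sampling_rate_hz, band.f_lo, band.f_hi, rng)
    return u * (amplitude / np.sqrt(2.0))


# ---------------------------------------------------------------------------
# session assembly


def _constrained_order(
    n_plus: int, n_minus: int, rng: np.random.Generator, max_run: int = 3
) -> list[str]:
    """Pseudorandom CS+/CS- order with at most ``max_run`` consecutive repeats."""
    labels = [CS_PLUS] * n_plus + [CS_MINUS] * n_minus
    if n_plus == 0 or n_minus == 0:
        return labels
    for _ in range(1000):
        order = list(rng.permutation(labels))
        run, ok = 1, True
        for a, b in zip(order, order[1:]):
            run = run + 1 if a == b else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return order
    raise RuntimeError("could not satisfy the pseudorandom order constraint")


def _gain_envelope(
    n: int, fs: float, windows: list[tuple[float, float, float]]
) -> np.ndarray:
    """Multiplicative envelope: 1 outside CS windows, ramped to each gain inside.

    ``windows`` holds (onset_s, duration_s, gain) triples.  The transition
    from 1 to the gain uses a raised-cosine ramp of RAMP_S seconds inside
    the window at both ends.
    """
    env = np.ones(n, dtype=np.float32)
    for onset, dur, gain in windows:
        if gain == 1.0:
            continue
        i0 = int(np.floor(onset * fs))
        i1 = min(int(np.floor((onset + dur) * fs)), n)
        w = _window_profile(i1 - i0, fs)
        env[i0:i1] = 1.0 + (float(gain) - 1.0) * w
    return env


def _window_profile(n_win: int, fs: float) -> np.ndarray:
    """0->1->0 raised-cosine-edged profile across one CS window."""
    n_ramp = min(int(round(RAMP_S * fs)), n_win // 2)
    w = np.ones(n_win, dtype=np.float32)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp, dtype=np.float32) / n_ramp))
        w[:n_ramp] = ramp
        w[-n_ramp:] = ramp[::-1]
    return w


def _coupling_profile(
    n: int, fs: float, windows: list[tuple[float, float, float]]
) -> np.ndarray:
    """Per-sample coupling coefficient c(t): 0 outside CS windows, ramped inside."""
    c = np.zeros(n, dtype=np.float32)
    for onset, dur, coeff in windows:
        if coeff == 0.0:
            continue
        i0 = int(np.floor(onset * fs))
        i1 = min(int(np.floor((onset + dur) * fs)), n)
        c[i0:i1] = float(coeff) * _window_profile(i1 - i0, fs)
    return c


def _session_events(
    spec: SessionSpec, plan: SessionPlan, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    order = _constrained_order(spec.n_cs_plus, spec.n_cs_minus, rng)
    lo, hi = config.iti_range_s
    t = plan.lead_in_s
    counters = {CS_PLUS: 0, CS_MINUS: 0}
    rows = []
    for stim in order:
        t += rng.uniform(lo, hi)
        counters[stim] += 1
        us = ""
        if spec.us_paired and stim == CS_PLUS:
            us_onset = t + (plan.n_pips - 1) / plan.pip_rate_hz + plan.pip_duration_ms / 1e3
            us = f"{us_onset:.6f}"
        rows.append(
            {
                "session": spec.name,
                "trial_index": counters[stim],
                "stimulus": stim,
                "onset_s": round(t, 6),
                "us_onset_s": us,
            }
        )
        t += plan.cs_duration_s
    return pd.DataFrame(rows)


def _build_session(
    spec: SessionSpec,
    plan: SessionPlan,
    config: SimulationConfig,
    rng: np.random.Generator,
    return_components: bool = False,
) -> tuple[dict[str, np.ndarray], pd.DataFrame, dict]:
    """Simulate one session: region signals, event table, ground-truth extras."""
    fs = config.sampling_rate_hz
    events = _session_events(spec, plan, config, rng)
    duration_s = (
        events["onset_s"].iloc[-1] + plan.cs_duration_s + plan.tail_s
        if len(events)
        else plan.lead_in_s + plan.tail_s
    )
    n = int(np.ceil(duration_s * fs))
    amplitudes = dict(config.band_components)
    lag = int(round(config.coupling_lag_ms * fs / 1000.0))

    cs_windows = {
        stim: [
            (row.onset_s, plan.cs_duration_s)
            for row in events.itertuples()
            if row.stimulus == stim
        ]
        for stim in (CS_PLUS, CS_MINUS)
    }

    def gain_windows(region: str, band: str) -> list[tuple[float, float, float]]:
        out = []
        for stim, wins in cs_windows.items():
            g = config.cs_gain_table.get((region, spec.name, stim, band), 1.0)
            out.extend((onset, dur, g) for onset, dur in wins)
        return out

    signals: dict[str, np.ndarray] = {}
    components: dict[str, np.ndarray] = {}

    # Theta: shared lag-shifted component drives the IL inside CS windows.
    theta = _BANDS["theta"]
    u_pl = _unit_band_noise(n, fs, theta.f_lo, theta.f_hi, rng, dtype=np.float32)
    u_ind = _unit_band_noise(n, fs, theta.f_lo, theta.f_hi, rng, dtype=np.float32)
    c_wins = [
        (onset, dur, config.coupling_table.get((spec.name, stim), 0.0))
        for stim, wins in cs_windows.items()
        for onset, dur in wins
    ]
    c_t = _coupling_profile(n, fs, c_wins)
    # a positive configured lag is recovered as a positive peak lag downstream
    u_shared = np.roll(u_pl, -lag)
    u_il = c_t * u_shared + np.sqrt(1.0 - c_t**2) * u_ind
    theta_amp = float(amplitudes.get("theta", 0.0)) / float(np.sqrt(2.0))
    base_components = {"PL": {"theta": theta_amp * u_pl}, "IL": {"theta": theta_amp * u_il}}

    # Gamma bands: independent between regions.
    for band_name in amplitudes:
        if band_name == "theta":
            continue
        b = _BANDS[band_name]
        amp = float(amplitudes[band_name]) / float(np.sqrt(2.0))
        for region in REGIONS:
            base_components[region][band_name] = amp * _unit_band_noise(
                n, fs, b.f_lo, b.f_hi, rng, dtype=np.float32
            )

    for region in REGIONS:
        x = np.zeros(n, dtype=np.float32)
        for band_name, comp in base_components[region].items():
            enveloped = comp * _gain_envelope(n, fs, gain_windows(region, band_name))
            x += enveloped
            if return_components:
                components[f"{region}_{band_name}"] = enveloped
        if config.noise_rms_uV > 0:
            x += generate_pink_noise(
                n, config.noise_exponent, config.noise_rms_uV, rng, dtype=np.float32
            )
        if config.mains_amp_uV > 0 and config.mains_hz > 0:
            x += (
                config.mains_amp_uV
                * np.sin(2 * np.pi * config.mains_hz * np.arange(n) / fs)
            ).astype(np.float32)
        signals[region] = x

    extras = {"components": components} if return_components else {}
    return signals, events, extras


def simulate_sessions(
    config: SimulationConfig,
    plan: SessionPlan = DEFAULT_PLAN,
    return_components: bool = False,
) -> tuple[dict[str, dict[str, np.ndarray]], pd.DataFrame, GroundTruth, dict]:
    """Simulate all sessions in memory.

    Returns ``(signals, events, ground_truth, extras)`` where ``signals``
    maps session name -> region -> float32 samples and ``events`` is the
    concatenated event table.  ``extras['components']`` (when requested)
    holds the noiseless per-band components for oracle checks.
    """
    config.validate_against(plan)
    rng = np.random.default_rng(config.seed)
    all_signals: dict[str, dict[str, np.ndarray]] = {}
    all_events = []
    extras: dict = {"components": {}} if return_components else {}
    gt_trials = []
    gt_coupling = []
    for spec in plan.sessions:
        signals, events, ex = _build_session(spec, plan, config, rng, return_components)
        all_signals[spec.name] = signals
        all_events.append(events)
        if return_components:
            extras["components"][spec.name] = ex["components"]
        for row in events.itertuples():
            rec = {
                "session": spec.name,
                "stimulus": row.stimulus,
                "trial_index": int(row.trial_index),
                "onset_s": float(row.onset_s),
            }
            for region in REGIONS:
                for band, _a in config.band_components:
                    rec[f"gain_{region}_{band}"] = config.cs_gain_table.get(
                        (region, spec.name, row.stimulus, band), 1.0
                    )
            gt_trials.append(rec)
        for stim in (CS_PLUS, CS_MINUS):
            gt_coupling.append(
                {
                    "session": spec.name,
                    "stimulus": stim,
                    "coefficient": config.coupling_table.get((spec.name, stim), 0.0),
                    "lag_ms": config.coupling_lag_ms,
                }
            )
    events_df = pd.concat(all_events, ignore_index=True)
    gt = GroundTruth(
        trials=pd.DataFrame(gt_trials),
        coupling=pd.DataFrame(gt_coupling),
        seed=config.seed,
    )
    return all_signals, events_df, gt, extras


def simulate_dafc_dataset(
    config: SimulationConfig, plan: SessionPlan = DEFAULT_PLAN, out_dir=None
):
    """Simulate the full protocol and write the dataset directory.

    Returns ``(out_dir, GroundTruth)``.  See :mod:`fearlfp.dataio` for the
    on-disk layout.  With ``out_dir=None`` nothing is written and the
    in-memory dataset is returned instead (``signals, events, gt``).
    """
    signals, events, gt, _ = simulate_sessions(config, plan)
    if out_dir is None:
        return signals, events, gt
    from .dataio import write_dataset

    write_dataset(
        out_dir, signals, events, config.sampling_rate_hz, plan.cs_duration_s, gt
    )
    return out_dir, gt


def generate_freezing(
    ground_truth: GroundTruth,
    plan: SessionPlan = DEFAULT_PLAN,
    seed: int = 0,
    baseline_pct: float = 10.0,
    slope_pct: float = 55.0,
    noise_sd_pct: float = 5.0,
) -> pd.DataFrame:
    """Synthetic per-trial freezing percentages for demo tables.

    Freezing is a monotone noisy function of the injected PL theta gain:
    baseline + slope * (gain - 1) + Gaussian noise, clipped to [0, 100].
    This is presentation plumbing only (the real behavior was scored by a
    human observer); it carries no information beyond the gain table.
    """
    rng = np.random.default_rng(seed)
    trials = ground_truth.trials
    if not {"session", "stimulus", "trial_index"}.issubset(trials.columns):
        raise ValueError("ground truth does not cover trial identities")
    gains = trials.get("gain_PL_theta", pd.Series(1.0, index=trials.index))
    freezing = (
        baseline_pct
        + slope_pct * (gains.to_numpy(dtype=float) - 1.0)
        + rng.normal(0.0, noise_sd_pct, size=len(trials))
    )
    out = trials[["session", "stimulus", "trial_index"]].copy()
    out["freezing_pct"] = np.clip(freezing, 0.0, 100.0)
    return out
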