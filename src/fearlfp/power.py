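"""CS-evoked normalized LFP power.

Power spectral densities of the 15-s CS window and the 15-s pre-CS baseline
are estimated by Welch's method: the window is split into 16 equal
non-overlapping segments (remainder samples dropped), each segment is
mean-subtracted, Hann-windowed, and the averaged periodogram is scaled as
power per Hz.  The evoked-power ratio for a band is the summed PSD of the
band-filtered CS window divided by the summed PSD of the band-filtered
pre-CS window; it is dimensionless and invariant to the recording's scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .filters import FIRFilter

__all__ = [
    "PSDResult",
    "DEFAULT_BLOCKS",
    "welch_psd",
    "evoked_power_ratio",
    "window_indices",
    "block_average",
]

# Trial indices (1-based, per stimulus) quantified in each session of the
# default 5-day protocol: all habituation trials, the last 3 acquisition
# trials (fear learning), the first 3 of extinction day 3 (fear expression),
# the last 3 of extinction day 4 (extinction learning), and both trials of
# extinction recall and renewal.
DEFAULT_BLOCKS: dict[str, tuple[int, ...]] = {
    "Hab": (1, 2, 3, 4, 5),
    "ACQ": (3, 4, 5),
    "EXT1": (1, 2, 3),
    "EXT2": (10, 11, 12),
    "EXT_recall": (1, 2),
    "Renewal": (1, 2),
}


@dataclass(frozen=True)
class PSDResult:
    frequencies: np.ndarray
    density: np.ndarray
    n_segments: int
    window: str = "hann"
    overlap: float = 0.0

    @property
    def total_power(self) -> float:
        """Integral of the density over the frequency grid (variance estimate)."""
        return float(np.trapezoid(self.density, self.frequencies))


def welch_psd(segment: np.ndarray, sampling_rate_hz: float, n_segments: int = 16) -> PSDResult:
    """Welch PSD over ``n_segments`` equal non-overlapping Hann-windowed pieces.

    Segment length is ``len(segment) // n_segments``; trailing remainder
    samples are dropped.  Each piece is mean-subtracted before windowing.
    Density scaling normalizes by the window power so that Parseval holds
    for white noise.
    """
    segment = np.asarray(segment)
    if segment.ndim != 1:
        raise ValueError("welch_psd expects a 1-D segment")
    if len(segment) < n_segments:
        raise ValueError(
            f"segment of {len(segment)} samples is shorter than n_segments={n_segments}"
        )
    nperseg = len(segment) // n_segments
    freqs, density = _sig.welch(
        segment,
        fs=sampling_rate_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=0,
        detrend="constant",
        scaling="density",
    )
    return PSDResult(frequencies=freqs, density=density, n_segments=n_segments)


def window_indices(t0_s: float, t1_s: float, sampling_rate_hz: float) -> tuple[int, int]:
    """Half-open sample range for the time window [t0, t1) in seconds."""
    return int(np.floor(t0_s * sampling_rate_hz)), int(np.floor(t1_s * sampling_rate_hz))


def evoked_power_ratio(
    filtered: np.ndarray,
    onset_s: float,
    sampling_rate_hz: float,
    window_s: float = 15.0,
    n_segments: int = 16,
) -> float:
    """Summed PSD of [onset, onset+window) over summed PSD of [onset-window, onset).

    ``filtered`` is the band-filtered session signal; the ratio is computed
    on its Welch PSDs, summing over all frequency bins (the band filter has
    already confined the power).
    """
    fs = float(sampling_rate_hz)
    i_pre0, i_on = window_indices(onset_s - window_s, onset_s, fs)
    i_cs1 = window_indices(onset_s, onset_s + window_s, fs)[1]
    if i_pre0 < 0:
        raise ValueError(
            f"insufficient baseline: onset at {onset_s} s needs {window_s} s before it"
        )
    if i_cs1 > len(filtered):
        raise ValueError(
            f"insufficient signal after onset at {onset_s} s: need {window_s} s"
        )
    psd_pre = welch_psd(filtered[i_pre0:i_on], fs, n_segments)
    psd_cs = welch_psd(filtered[i_on:i_cs1], fs, n_segments)
    denom = psd_pre.density.sum()
    if denom == 0:
        raise ValueError("pre-CS window has zero power; ratio undefined")
    return float(psd_cs.density.sum() / denom)


def band_filtered_ratio(
    raw: np.ndarray,
    fir: FIRFilter,
    onset_s: float,
    window_s: float = 15.0,
    n_segments: int = 16,
) -> float:
    """Convenience: band-filter a whole session signal, then take the evoked ratio."""
    from .filters import apply_zero_phase

    return evoked_power_ratio(
        apply_zero_phase(raw, fir), onset_s, fir.sampling_rate_hz, window_s, n_segments
    )


def block_average(
    results: pd.DataFrame,
    blocks: dict[str, tuple[int, ...]] | None = None,
    value: str = "ratio",
    group_cols: tuple[str, ...] = ("session", "region", "band", "stimulus"),
) -> pd.DataFrame:
    """Mean +/- SEM of ``value`` over each session's quantification block.

    ``results`` holds one row per analyzable trial with ``session``,
    ``trial_index``, ``stimulus`` and the value column.  ``blocks`` maps
    session name to the 1-based trial indices used for quantification
    (identical for CS+ and CS-); sessions absent from the map use all
    trials.  Blocks left empty by artifact exclusions produce a row with
    n=0 and NaN mean, with a warning.
    """
    if blocks is None:
        blocks = DEFAULT_BLOCKS
    rows = []
    key_cols = [c for c in group_cols if c in results.columns]
    for keys, grp in results.groupby(key_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        rec = dict(zip(key_cols, keys))
        session = rec.get("session")
        sel = grp
        if session in blocks:
            sel = grp[grp["trial_index"].isin(blocks[session])]
        vals = sel[value].to_numpy(dtype=float)
        n = len(vals)
        if n == 0:
            warnings.warn(
                f"block for {rec} is empty after exclusions; emitting NaN row",
                stacklevel=2,
            )
            rec.update(n=0, mean=np.nan, sem=np.nan)
        else:
            rec.update(
                n=n,
                mean=float(vals.mean()),
                sem=float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            )
        rows.append(rec)
    return pd.DataFrame(rows, columns=[*key_cols, "n", "mean", "sem"])
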