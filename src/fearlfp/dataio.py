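"""Dataset directory format and result tables.

A dataset is a plain directory:

``dataset.json``
    sampling rate, channel list with region tags, session list, units.
``signals/<session>__<region>.f32``
    raw little-endian 32-bit float samples, one file per channel.
``events.tsv``
    columns session, trial_index (1-based within session and stimulus),
    stimulus (CS_PLUS|CS_MINUS), onset_s, us_onset_s (empty if none).
``ground_truth.json``
    optional injected gains/coupling for recovery checks.

Validation is strict: any structural violation raises with the offending
file or row named; nothing is silently coerced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import REGIONS, GroundTruth

__all__ = [
    "Recording",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "write_results",
    "validate_events",
]

EVENT_COLUMNS = ["session", "trial_index", "stimulus", "onset_s", "us_onset_s"]


class DatasetError(ValueError):
    """Structural problem in a dataset directory, with file/row provenance."""


@dataclass(frozen=True)
class Recording:
    """One session's multi-channel continuous signal.

    Sample index 0 is session time 0.0 s; time windows are half-open
    [t0, t1) in seconds, converted to samples by floor(t * fs).
    """

    session_name: str
    sampling_rate_hz: float
    channels: dict[str, np.ndarray]  # region -> samples (microvolts)

    def __post_init__(self) -> None:
        lengths = {r: len(x) for r, x in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise DatasetError(
                f"session {self.session_name!r}: channel length mismatch {lengths}"
            )
        if self.sampling_rate_hz <= 0:
            raise DatasetError(f"session {self.session_name!r}: non-positive sampling rate")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


def validate_events(
    events: pd.DataFrame,
    recordings: dict[str, Recording] | None = None,
    baseline_s: float = 15.0,
    cs_duration_s: float = 30.0,
    source: str = "events.tsv",
) -> None:
    """Check event-table invariants, naming the offending row on failure.

    Onsets must be strictly increasing within a session, each with at least
    ``baseline_s`` seconds before it and ``cs_duration_s`` after it inside
    the recording, and trial indices must run contiguously from 1 per
    (session, stimulus).
    """
    missing = [c for c in EVENT_COLUMNS[:4] if c not in events.columns]
    if missing:
        raise DatasetError(f"{source}: missing columns {missing}")
    for session, grp in events.groupby("session", sort=False):
        onsets = grp["onset_s"].to_numpy(dtype=float)
        if np.any(np.diff(onsets) <= 0):
            i = int(np.flatnonzero(np.diff(onsets) <= 0)[0]) + 1
            raise DatasetError(
                f"{source}: session {session!r} row {grp.index[i]}: onsets not "
                "strictly increasing"
            )
        dur = recordings[session].duration_s if recordings and session in recordings else None
        for idx, onset in zip(grp.index, onsets):
            if onset < baseline_s:
                raise DatasetError(
                    f"{source}: row {idx} (session {session!r}): onset {onset} s has "
                    f"less than {baseline_s} s of baseline"
                )
            if dur is not None and onset + cs_duration_s > dur + 1e-9:
                raise DatasetError(
                    f"{source}: row {idx} (session {session!r}): onset {onset} s "
                    f"extends past the recording ({dur:.3f} s)"
                )
        for stim, sgrp in grp.groupby("stimulus", sort=False):
            idxs = sgrp["trial_index"].to_numpy(dtype=int)
            if not np.array_equal(idxs, np.arange(1, len(idxs) + 1)):
                raise DatasetError(
                    f"{source}: session {session!r} stimulus {stim!r}: trial_index "
                    f"not contiguous from 1 (got {idxs.tolist()})"
                )


def _signal_path(root: Path, session: str, region: str) -> Path:
    return root / "signals" / f"{session}__{region}.f32"


def write_dataset(
    out_dir,
    signals: dict[str, dict[str, np.ndarray]],
    events: pd.DataFrame,
    sampling_rate_hz: float,
    cs_duration_s: float = 30.0,
    ground_truth: GroundTruth | None = None,
) -> Path:
    """Write signals, events and metadata in the dataset layout."""
    root = Path(out_dir)
    (root / "signals").mkdir(parents=True, exist_ok=True)
    sessions = []
    for session, regions in signals.items():
        for region, x in regions.items():
            np.asarray(x, dtype="<f4").tofile(_signal_path(root, session, region))
        n = len(next(iter(regions.values())))
        sessions.append(
            {
                "name": session,
                "n_samples": int(n),
                "duration_s": n / sampling_rate_hz,
            }
        )
    meta = {
        "sampling_rate_hz": sampling_rate_hz,
        "units": "uV",
        "channels": [{"name": f"LFP_{r}", "region": r} for r in REGIONS],
        "sessions": sessions,
        "cs_duration_s": cs_duration_s,
    }
    (root / "dataset.json").write_text(json.dumps(meta, indent=2) + "\n")
    events.to_csv(root / "events.tsv", sep="\t", index=False, float_format="%.6f")
    if ground_truth is not None:
        (root / "ground_truth.json").write_text(
            json.dumps(ground_truth.to_dict(), indent=2, sort_keys=True) + "\n"
        )
    return root


def read_dataset(
    dataset_dir,
) -> tuple[dict[str, Recording], pd.DataFrame, dict]:
    """Read and validate a dataset directory.

    Returns ``(recordings, events, metadata)``; ``metadata`` includes the
    parsed ``ground_truth`` when present.  Raises :class:`DatasetError`
    naming the offending file or row on any structural violation.
    """
    root = Path(dataset_dir)
    meta_path = root / "dataset.json"
    if not meta_path.exists():
        raise DatasetError(f"missing file: {meta_path}")
    meta = json.loads(meta_path.read_text())
    fs = float(meta["sampling_rate_hz"])
    regions = [c["region"] for c in meta["channels"]]
    recordings: dict[str, Recording] = {}
    for sess in meta["sessions"]:
        name, n_expected = sess["name"], int(sess["n_samples"])
        channels = {}
        for region in regions:
            path = _signal_path(root, name, region)
            if not path.exists():
                raise DatasetError(f"missing file: {path}")
            x = np.fromfile(path, dtype="<f4")
            if len(x) != n_expected:
                raise DatasetError(
                    f"{path}: expected {n_expected} samples, found {len(x)}"
                )
            channels[region] = x
        recordings[name] = Recording(
            session_name=name, sampling_rate_hz=fs, channels=channels
        )
    events_path = root / "events.tsv"
    if not events_path.exists():
        raise DatasetError(f"missing file: {events_path}")
    events = pd.read_csv(
        events_path, sep="\t", dtype={"us_onset_s": str}, keep_default_na=False
    )
    unknown = set(events["session"]) - set(recordings)
    if unknown:
        raise DatasetError(f"{events_path}: unknown sessions {sorted(unknown)}")
    validate_events(
        events,
        recordings,
        cs_duration_s=float(meta.get("cs_duration_s", 30.0)),
        source=str(events_path),
    )
    gt_path = root / "ground_truth.json"
    if gt_path.exists():
        meta["ground_truth"] = GroundTruth.from_dict(json.loads(gt_path.read_text()))
    return recordings, events, meta


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write result tables as UTF-8 CSVs with a header row and '.' decimals.

    ``tables`` maps a base name (``evoked_power``, ``coupling``,
    ``session_summary``) to its DataFrame.  An empty mapping is a no-op
    with a warning.
    """
    import warnings

    if not tables:
        warnings.warn("no result tables to write", stacklevel=2)
        return []
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = root / f"{name}.csv"
        df.to_csv(path, index=False, encoding="utf-8")
        written.append(path)
    return written
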