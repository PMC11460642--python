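"""Read/write session recordings as CSV time series + JSON sidecar.

A session on disk is a pair ``<stem>.csv`` / ``<stem>.json``:

* CSV: columns ``time_s, EDA, ECG, TRIGGER, RESPONSE``, one row per sample,
  floats at 6 significant digits, comma-separated, UTF-8.
* Sidecar JSON: ``fs_hz``, ``channels``, ``session`` (the stimulus plan),
  optional ``truth`` (simulator ground truth) and ``meta`` provenance.

Sample times are reconstructed from the sampling rate on read; the stored
time column is only cross-checked (to half a sample period) against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import SessionPlan
from .synth import CHANNEL_ROLES, GroundTruth, SignalSet

__all__ = ["SessionRecord", "SessionFormatError", "write_session", "read_session"]


class SessionFormatError(ValueError):
    """Malformed or inconsistent session files."""


@dataclass
class SessionRecord:
    signals: SignalSet
    meta: dict = field(default_factory=dict)

    @property
    def participant(self) -> str:
        return str(self.meta.get("participant", "unknown"))


def _validate(record: SessionRecord) -> None:
    sig = record.signals
    if set(sig.channels) != set(CHANNEL_ROLES):
        raise SessionFormatError(
            f"channel roles must be exactly {CHANNEL_ROLES}"
        )
    if sig.fs_hz <= 0:
        raise SessionFormatError("fs_hz must be positive")
    lengths = {len(v) for v in sig.channels.values()}
    if len(lengths) != 1:
        raise SessionFormatError(f"channel length mismatch: {sorted(lengths)}")


def write_session(record: SessionRecord, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>.csv`` + ``<path>.json``; returns the two paths."""
    _validate(record)
    stem = Path(path).with_suffix("")
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")

    sig = record.signals
    df = pd.DataFrame({"time_s": sig.time()})
    for role in CHANNEL_ROLES:
        df[role] = sig.channels[role]
    df.to_csv(csv_path, index=False, float_format="%.6g")

    sidecar = {
        "fs_hz": sig.fs_hz,
        "channels": list(CHANNEL_ROLES),
        "session": sig.session.to_dict(),
        "meta": record.meta,
    }
    if sig.truth is not None:
        sidecar["truth"] = sig.truth.to_dict()
    json_path.write_text(json.dumps(sidecar))
    return csv_path, json_path


def read_session(path: str | Path) -> SessionRecord:
    """Load and validate a CSV + sidecar pair written by :func:`write_session`."""
    stem = Path(path).with_suffix("")
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")
    if not csv_path.exists() or not json_path.exists():
        raise FileNotFoundError(f"missing session pair {stem}.csv/.json")

    sidecar = json.loads(json_path.read_text())
    fs = float(sidecar["fs_hz"])
    if fs <= 0:
        raise SessionFormatError("fs_hz must be positive")
    roles = sidecar.get("channels", [])
    if set(roles) != set(CHANNEL_ROLES):
        raise SessionFormatError(f"unknown channel roles {roles}")

    try:
        df = pd.read_csv(csv_path)
    except Exception as exc:  # malformed CSV
        raise SessionFormatError(f"unreadable CSV {csv_path}: {exc}") from exc
    missing = [c for c in ("time_s", *CHANNEL_ROLES) if c not in df.columns]
    if missing:
        raise SessionFormatError(f"CSV missing columns {missing}")
    if df.isna().any().any():
        raise SessionFormatError("CSV contains missing values (truncated file?)")

    n = len(df)
    expected_t = np.arange(n) / fs
    if np.max(np.abs(df["time_s"].to_numpy() - expected_t)) > 0.5 / fs:
        raise SessionFormatError("time column inconsistent with sampling rate")

    plan = SessionPlan.from_dict(sidecar["session"])
    truth = GroundTruth.from_dict(sidecar["truth"]) if "truth" in sidecar else None
    signals = SignalSet(
        fs_hz=fs,
        channels={role: df[role].to_numpy(dtype=float) for role in CHANNEL_ROLES},
        session=plan,
        truth=truth,
    )
    return SessionRecord(signals=signals, meta=sidecar.get("meta", {}))
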