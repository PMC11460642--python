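"""R-peak detection, inter-beat-interval cleaning and time-domain HRV.

The detector is a Pan-Tompkins-style chain: band-pass (5-15 Hz) ->
differentiate -> square -> 150 ms moving-window integration -> adaptive
signal/noise threshold with a 200 ms refractory period, followed by
refinement of each detection to the local raw-signal maximum within
+/-50 ms.

Cleaning drops intervals outside the physiological 300-2000 ms range or
deviating more than 25% from the running median of five; successive-
difference statistics (rMSSD, pNNx) are computed only across retained
*adjacent* interval pairs, so a rejected interval never contributes a
spurious difference.

Metrics follow the standard time-domain definitions: BPM = 60000/mean(IBI),
SDNN the sample standard deviation (n-1), rMSSD the root mean square of
successive differences, and pNNx the percentage of successive differences
strictly exceeding x ms (x = 10, 30, 50), with the number of successive
differences as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

from .protocol import Block

__all__ = [
    "IBISeries",
    "HRVMetrics",
    "InsufficientDataError",
    "detect_r_peaks",
    "clean_ibis",
    "hrv_time_domain",
    "session_hrv",
]

IBI_MIN_MS = 300.0
IBI_MAX_MS = 2000.0


class InsufficientDataError(ValueError):
    """Not enough beats/intervals to compute the requested quantity."""


@dataclass(frozen=True)
class HRVMetrics:
    bpm: float
    sdnn_ms: float
    rmssd_ms: float
    pnn10: float
    pnn30: float
    pnn50: float
    n_beats: int

    def to_dict(self) -> dict:
        return {
            "bpm": self.bpm,
            "sdnn_ms": self.sdnn_ms,
            "rmssd_ms": self.rmssd_ms,
            "pnn10": self.pnn10,
            "pnn30": self.pnn30,
            "pnn50": self.pnn50,
            "n_beats": self.n_beats,
        }


@dataclass(frozen=True)
class IBISeries:
    """Retained inter-beat intervals with provenance.

    ``indices`` are positions of each retained interval in the raw
    first-difference sequence; two retained intervals are *adjacent* (and so
    contribute a successive difference) only when their raw indices are
    consecutive.
    """

    ibis_ms: np.ndarray
    first_beat_times_s: np.ndarray
    indices: np.ndarray
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.ibis_ms)

    @classmethod
    def from_ibis(cls, ibis_ms) -> "IBISeries":
        ibis = np.asarray(ibis_ms, dtype=float)
        starts = np.concatenate([[0.0], np.cumsum(ibis[:-1]) / 1000.0])
        return cls(ibis_ms=ibis, first_beat_times_s=starts,
                   indices=np.arange(len(ibis)), n_rejected=0)

    def successive_diffs(self) -> np.ndarray:
        """Differences between retained intervals that were raw-adjacent."""
        if len(self.ibis_ms) < 2:
            return np.empty(0)
        adjacent = np.diff(self.indices) == 1
        return np.diff(self.ibis_ms)[adjacent]

    def subset(self, mask: np.ndarray) -> "IBISeries":
        return IBISeries(
            ibis_ms=self.ibis_ms[mask],
            first_beat_times_s=self.first_beat_times_s[mask],
            indices=self.indices[mask],
            n_rejected=self.n_rejected,
        )


def detect_r_peaks(ecg, fs_hz: float) -> np.ndarray:
    """Detect R-peak times (s) in a raw ECG trace."""
    ecg = np.asarray(ecg, dtype=float)
    if fs_hz < 100:
        raise ValueError("sampling rate below 100 Hz is insufficient for QRS detection")
    if len(ecg) < 2 * fs_hz:
        raise ValueError("need at least 2 s of signal")

    b, a = butter(2, [5.0, 15.0], btype="band", fs=fs_hz)
    filtered = filtfilt(b, a, ecg)
    squared = np.gradient(filtered) ** 2
    win = max(1, int(round(0.150 * fs_hz)))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs_hz))
    candidates, _ = find_peaks(integrated, distance=refractory)
    if candidates.size == 0:
        return np.empty(0)

    # adaptive signal/noise running estimates (Pan-Tompkins style)
    head = integrated[: int(2 * fs_hz)]
    spki = 0.25 * float(np.max(head))
    npki = 0.5 * float(np.mean(head))
    accepted = []
    for p in candidates:
        v = integrated[p]
        threshold = npki + 0.25 * (spki - npki)
        if v > threshold:
            accepted.append(p)
            spki = 0.125 * v + 0.875 * spki
        else:
            npki = 0.125 * v + 0.875 * npki
    if not accepted:
        return np.empty(0)

    # refine to the raw-signal local maximum within +/-50 ms
    half = int(round(0.050 * fs_hz))
    refined = []
    for p in accepted:
        lo, hi = max(0, p - half), min(len(ecg), p + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    # enforce refractory after refinement (keep the larger raw peak)
    keep = []
    for r in refined:
        if keep and r - keep[-1] < refractory:
            if ecg[r] > ecg[keep[-1]]:
                keep[-1] = r
        else:
            keep.append(r)
    return np.asarray(keep) / fs_hz


def clean_ibis(beat_times_s) -> IBISeries:
    """Build a cleaned IBI series from detected beat times.

    Rejects intervals outside [300, 2000] ms or deviating more than 25% from
    the centered running median of five.
    """
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    if len(beat_times_s) < 3:
        raise InsufficientDataError("need at least 3 beats")
    raw = np.diff(beat_times_s) * 1000.0

    runmed = (
        pd.Series(raw).rolling(5, center=True, min_periods=1).median().to_numpy()
    )
    in_range = (raw >= IBI_MIN_MS) & (raw <= IBI_MAX_MS)
    near_med = np.abs(raw - runmed) <= 0.25 * runmed
    keep = in_range & near_med

    if keep.sum() < 2:
        raise InsufficientDataError("fewer than 2 intervals retained after cleaning")
    return IBISeries(
        ibis_ms=raw[keep],
        first_beat_times_s=beat_times_s[:-1][keep],
        indices=np.flatnonzero(keep),
        n_rejected=int((~keep).sum()),
    )


def hrv_time_domain(series: IBISeries) -> HRVMetrics:
    """Compute BPM, SDNN, rMSSD and pNN10/30/50 for one IBI series."""
    ibis = series.ibis_ms
    if len(ibis) < 3:
        raise InsufficientDataError("need at least 3 intervals")
    diffs = series.successive_diffs()
    if diffs.size == 0:
        raise InsufficientDataError("no adjacent interval pairs retained")

    abs_d = np.abs(diffs)
    return HRVMetrics(
        bpm=60000.0 / float(np.mean(ibis)),
        sdnn_ms=float(np.std(ibis, ddof=1)),
        rmssd_ms=float(np.sqrt(np.mean(diffs**2))),
        pnn10=100.0 * float(np.mean(abs_d > 10.0)),
        pnn30=100.0 * float(np.mean(abs_d > 30.0)),
        pnn50=100.0 * float(np.mean(abs_d > 50.0)),
        n_beats=len(ibis) + 1,
    )


def session_hrv(beat_times_s, windows) -> dict[Block, HRVMetrics]:
    """Per-block metrics: an interval belongs to the block containing its
    first beat; windows are (block, start_s, end_s)."""
    series = clean_ibis(beat_times_s)
    out: dict[Block, HRVMetrics] = {}
    for block, start, end in windows:
        mask = (series.first_beat_times_s >= start) & (series.first_beat_times_s < end)
        out[block] = hrv_time_domain(series.subset(mask))
    return out
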