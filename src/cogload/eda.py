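"""Electrodermal analysis: tonic skin conductance level and phasic SCRs.

SCL is the arithmetic mean of the conductance trace over a block window
(phasic activity included).  Stimulus-locked SCRs are scored with a simple
trough-to-peak rule: within 1-5 s after a stimulus onset, the maximum rise
above the window-start value counts as a response when it reaches 0.05 uS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import Block, SessionPlan

__all__ = ["SCLSummary", "mean_scl", "detect_scrs", "session_eda"]

#: Minimum rise (uS) to call an SCR.
SCR_MIN_AMP_US = 0.05
#: Post-stimulus latency window (s) searched for a response.
SCR_WINDOW_S = (1.0, 5.0)


@dataclass(frozen=True)
class SCLSummary:
    block: Block
    mean_scl_us: float
    n_scrs: int
    mean_scr_amp_us: float

    def to_dict(self) -> dict:
        return {
            "block": self.block.value,
            "mean_scl_us": self.mean_scl_us,
            "n_scrs": self.n_scrs,
            "mean_scr_amp_us": self.mean_scr_amp_us,
        }


def mean_scl(eda, fs_hz: float, window: tuple[float, float]) -> float:
    """Mean conductance over [start, end), seconds."""
    eda = np.asarray(eda, dtype=float)
    start, end = window
    i0, i1 = int(np.floor(start * fs_hz)), int(np.floor(end * fs_hz))
    i0, i1 = max(i0, 0), min(i1, len(eda))
    if i1 <= i0:
        raise ValueError(f"empty SCL window [{start}, {end})")
    return float(np.mean(eda[i0:i1]))


def detect_scrs(
    eda,
    fs_hz: float,
    stimulus_onsets,
    min_amp_us: float = SCR_MIN_AMP_US,
    window_s: tuple[float, float] = SCR_WINDOW_S,
) -> list[tuple[float, float, int]]:
    """Score at most one SCR per stimulus.

    Returns (peak_time_s, amplitude_us, stimulus_index) for every stimulus
    whose 1-5 s post-onset window contains a rise >= ``min_amp_us`` above
    the window-start value.
    """
    eda = np.asarray(eda, dtype=float)
    lo, hi = window_s
    out = []
    for k, onset in enumerate(stimulus_onsets):
        i0 = int(round((onset + lo) * fs_hz))
        i1 = int(round((onset + hi) * fs_hz))
        i0, i1 = max(i0, 0), min(i1, len(eda))
        if i1 - i0 < 2:
            continue
        seg = eda[i0:i1] - eda[i0]
        peak = int(np.argmax(seg))
        amp = float(seg[peak])
        if amp >= min_amp_us:
            out.append(((i0 + peak) / fs_hz, amp, k))
    return out


def session_eda(eda, fs_hz: float, plan: SessionPlan) -> dict[Block, SCLSummary]:
    """Per-block SCL mean and stimulus-locked SCR counts for one session."""
    out: dict[Block, SCLSummary] = {}
    stim = plan.absolute_onsets()
    for block, start, end in plan.windows():
        onsets = [t for b, _i, t, _tg in stim if b is block]
        scrs = detect_scrs(eda, fs_hz, onsets)
        amps = [a for _t, a, _k in scrs]
        out[block] = SCLSummary(
            block=block,
            mean_scl_us=mean_scl(eda, fs_hz, (start, end)),
            n_scrs=len(scrs),
            mean_scr_amp_us=float(np.mean(amps)) if amps else 0.0,
        )
    return out
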