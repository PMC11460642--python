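"""Button-channel decoding, stimulus-response matching and RT summaries.

The button box encodes presses as bipolar square pulses on one analog
channel: Button-1 (simple/target responses) at -1 V, Button-2 (non-target
responses) at +1 V.  Presses are detected at the pulse onset with a
+/-0.5 V threshold and a 50 ms debounce.

Matching assigns to each stimulus the first press falling in the
(onset + 100 ms, onset + 2000 ms] window -- earlier presses are treated as
anticipations and ignored, later ones as lapses.  A press is consumed by at
most one stimulus and every stimulus yields exactly one record (possibly a
miss).  Six RT categories are reported: S, SV, Ct, Cn, CVt, CVn (cognitive
blocks split by target / non-target).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import Block, SessionPlan

__all__ = [
    "RTRecord",
    "RT_CATEGORIES",
    "decode_buttons",
    "match_responses",
    "rt_summary",
    "stimulus_class",
    "rt_category",
]

RT_MIN_MS = 100.0
RT_MAX_MS = 2000.0
DEBOUNCE_S = 0.050

RT_CATEGORIES = ("S", "SV", "Ct", "Cn", "CVt", "CVn")


@dataclass(frozen=True)
class RTRecord:
    block: Block
    stimulus_index: int
    stimulus_class: str  # simple | target | nontarget
    button_id: int | None
    rt_ms: float | None
    correct: bool
    missed: bool


def stimulus_class(block: Block, is_target: bool) -> str:
    if block in (Block.S, Block.SV):
        return "simple"
    return "target" if is_target else "nontarget"


def rt_category(block: Block, stim_class: str) -> str:
    """Map (block, class) to one of the six RT report categories."""
    if stim_class == "simple":
        return block.value
    suffix = "t" if stim_class == "target" else "n"
    return block.value + suffix


def decode_buttons(response, fs_hz: float, threshold_v: float = 0.5,
                   debounce_s: float = DEBOUNCE_S) -> list[tuple[float, int]]:
    """Detect press onsets on the bipolar button channel.

    Returns time-sorted (time_s, button_id): the leading edge of a -1 V
    pulse is Button-1, of a +1 V pulse Button-2.
    """
    x = np.asarray(response, dtype=float)
    active = np.abs(x) > threshold_v
    onsets = np.flatnonzero(active & ~np.concatenate([[False], active[:-1]]))
    presses: list[tuple[float, int]] = []
    last_t = -np.inf
    for i in onsets:
        t = i / fs_hz
        if t - last_t < debounce_s:
            continue
        presses.append((t, 1 if x[i] < 0 else 2))
        last_t = t
    return presses


def match_responses(plan: SessionPlan, presses) -> list[RTRecord]:
    """Assign presses to stimuli and score correctness.

    Correct iff Button-1 on simple/target stimuli or Button-2 on non-target
    stimuli.  Presses within 100 ms of onset are anticipations and are not
    assigned; each press is consumed by at most one stimulus.
    """
    presses = sorted(presses)
    used = np.zeros(len(presses), dtype=bool)
    times = np.array([p[0] for p in presses]) if presses else np.empty(0)

    records: list[RTRecord] = []
    for block, idx, onset, is_target in plan.absolute_onsets():
        cls = stimulus_class(block, is_target)
        lo, hi = onset + RT_MIN_MS / 1000.0, onset + RT_MAX_MS / 1000.0
        chosen = None
        j = int(np.searchsorted(times, lo, side="right"))
        while j < len(presses) and times[j] <= hi:
            if not used[j]:
                chosen = j
                break
            j += 1
        if chosen is None:
            records.append(RTRecord(block, idx, cls, None, None, False, True))
            continue
        used[chosen] = True
        t_press, button = presses[chosen]
        rt_ms = (t_press - onset) * 1000.0
        correct = (button == 1) if cls in ("simple", "target") else (button == 2)
        records.append(RTRecord(block, idx, cls, button, rt_ms, correct, False))
    return records


def rt_summary(records, correct_only: bool = True) -> pd.DataFrame:
    """Median and IQR of RT per category over one participant's records.

    Categories with no usable responses are absent from the result (not
    reported as zero).
    """
    rows = []
    for r in records:
        if r.missed or r.rt_ms is None:
            continue
        if correct_only and not r.correct:
            continue
        rows.append({"category": rt_category(r.block, r.stimulus_class),
                     "rt_ms": r.rt_ms})
    if not rows:
        return pd.DataFrame(columns=["category", "median_rt_ms", "iqr_rt_ms", "n"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby("category")["rt_ms"]
        .agg(
            median_rt_ms="median",
            iqr_rt_ms=lambda x: float(np.percentile(x, 75) - np.percentile(x, 25)),
            n="count",
        )
        .reindex([c for c in RT_CATEGORIES if c in df["category"].unique()])
        .reset_index()
    )
    return out
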