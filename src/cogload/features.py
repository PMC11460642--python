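"""Per-participant feature tables, baseline-normalized percent changes and
vagal-tone group splits.

For each participant the five blocks yield one row each of SCL, HRV and RT
features; every physiological metric in a task block is then expressed as
100*(task - baseline)/baseline, the normalization used throughout the
statistical layer.  Reaction times have no baseline block and are analyzed
as raw medians.  Participants are split into low/high vagal-tone groups at
the cohort mean or median of baseline rMSSD (ties go to "low").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import Block, TASK_BLOCKS
from .eda import session_eda
from .hrv import detect_r_peaks, session_hrv
from .responses import decode_buttons, match_responses, rt_summary, rt_category
from .signal_io import SessionRecord

__all__ = [
    "GroupLabel",
    "UndefinedBaselineError",
    "IncompleteParticipantError",
    "DegenerateSplitError",
    "PCT_METRICS",
    "percent_change",
    "split_by_rmssd",
    "analyze_session",
    "build_feature_tables",
]

#: Metrics normalized to percent change vs. baseline.
PCT_METRICS = (
    "mean_scl_us",
    "bpm",
    "sdnn_ms",
    "rmssd_ms",
    "pnn10",
    "pnn30",
    "pnn50",
)
_PCT_NAMES = {
    "mean_scl_us": "pct_scl",
    "bpm": "pct_bpm",
    "sdnn_ms": "pct_sdnn",
    "rmssd_ms": "pct_rmssd",
    "pnn10": "pct_pnn10",
    "pnn30": "pct_pnn30",
    "pnn50": "pct_pnn50",
}


class UndefinedBaselineError(ValueError):
    """Baseline value is zero (or numerically so); percent change undefined."""


class IncompleteParticipantError(ValueError):
    """A participant is missing one or more of the five blocks."""


class DegenerateSplitError(ValueError):
    """All baseline rMSSD values identical; no two groups exist."""


@dataclass(frozen=True)
class GroupLabel:
    participant: str
    group: str  # "low" | "high"
    method: str  # "mean" | "median"
    threshold_ms: float


def percent_change(task_value: float, baseline_value: float) -> float:
    """100 * (task - baseline) / baseline."""
    if abs(baseline_value) < 1e-12:
        raise UndefinedBaselineError("baseline value is zero")
    return 100.0 * (task_value - baseline_value) / baseline_value


def split_by_rmssd(baseline_rmssd: dict, method: str = "median") -> list[GroupLabel]:
    """Label each participant low/high by cohort mean or median baseline
    rMSSD; values at the threshold go to "low"."""
    if method not in ("mean", "median"):
        raise ValueError(f"unknown split method {method!r}")
    if len(baseline_rmssd) < 2:
        raise ValueError("need at least 2 participants to split")
    values = np.array(list(baseline_rmssd.values()), dtype=float)
    if np.all(values == values[0]):
        raise DegenerateSplitError("all baseline rMSSD values identical")
    threshold = float(np.mean(values) if method == "mean" else np.median(values))
    return [
        GroupLabel(
            participant=str(p),
            group="high" if v > threshold else "low",
            method=method,
            threshold_ms=threshold,
        )
        for p, v in baseline_rmssd.items()
    ]


def analyze_session(record: SessionRecord) -> dict:
    """Run the full analysis chain on one session.

    Returns ``{"blocks": DataFrame, "rt_records": DataFrame,
    "rt_summary": DataFrame}``: per-block SCL/HRV/RT features plus the
    per-stimulus response table and the six-category RT summary.
    """
    sig = record.signals
    plan = sig.session
    fs = sig.fs_hz
    participant = record.participant

    beats = detect_r_peaks(sig.channels["ECG"], fs)
    hrv_by_block = session_hrv(beats, plan.windows())
    eda_by_block = session_eda(sig.channels["EDA"], fs, plan)
    presses = decode_buttons(sig.channels["RESPONSE"], fs)
    records = match_responses(plan, presses)

    rt_rows = [
        {
            "participant": participant,
            "block": r.block.value,
            "stimulus_index": r.stimulus_index,
            "class": r.stimulus_class,
            "button": r.button_id,
            "rt_ms": r.rt_ms,
            "correct": r.correct,
            "missed": r.missed,
        }
        for r in records
    ]
    rt_records = pd.DataFrame(rt_rows)

    block_rows = []
    for block, _start, _end in plan.windows():
        hrv = hrv_by_block[block]
        scl = eda_by_block[block]
        rts = [
            r.rt_ms for r in records
            if r.block is block and not r.missed and r.correct
        ]
        block_rows.append(
            {
                "participant": participant,
                "block": block.value,
                "mean_scl_us": scl.mean_scl_us,
                "n_scrs": scl.n_scrs,
                "mean_scr_amp_us": scl.mean_scr_amp_us,
                **hrv.to_dict(),
                "median_rt_ms": float(np.median(rts)) if rts else np.nan,
            }
        )
    summary = rt_summary(records)
    summary.insert(0, "participant", participant)
    return {
        "blocks": pd.DataFrame(block_rows),
        "rt_records": rt_records,
        "rt_summary": summary,
    }


def build_feature_tables(
    per_participant_blocks: list[pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack per-participant block features and derive the percent-change
    table (one row per participant x task).

    Raises :class:`IncompleteParticipantError` if any participant lacks one
    of the five blocks.
    """
    features = pd.concat(per_participant_blocks, ignore_index=True)
    expected = {Block.BASELINE.value, *(b.value for b in TASK_BLOCKS)}
    for p, grp in features.groupby("participant"):
        missing = expected - set(grp["block"])
        if missing:
            raise IncompleteParticipantError(
                f"participant {p} missing blocks {sorted(missing)}"
            )

    pct_rows = []
    for p, grp in features.groupby("participant"):
        grp = grp.set_index("block")
        base = grp.loc[Block.BASELINE.value]
        for task in TASK_BLOCKS:
            row = {"participant": p, "task": task.value}
            for metric in PCT_METRICS:
                row[_PCT_NAMES[metric]] = percent_change(
                    float(grp.loc[task.value, metric]), float(base[metric])
                )
            row["median_rt_ms"] = float(grp.loc[task.value, "median_rt_ms"])
            pct_rows.append(row)
    pct = pd.DataFrame(pct_rows)
    return features, pct
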