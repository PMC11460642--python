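"""Visual task battery: block definitions and stimulus scheduling.

The battery consists of a 2-minute resting baseline followed by four
2-minute visual task blocks of increasing cognitive load:

* **S** (simple) -- 30 red stimuli, fixed 2 s inter-stimulus gap.
* **SV** (simple vigilance) -- 30 red stimuli, gaps drawn uniformly on 2-5 s.
* **C** (cognitive) -- 30 five-colour stimuli, 6 red targets among 24
  non-targets, fixed 2 s gap.
* **CV** (cognitive vigilance) -- as C with random 2-5 s gaps.

Every stimulus is shown for 0.5 s.  The inter-stimulus interval is
interpreted as the *offset-to-onset* gap (stimulus disappears, gap elapses,
next stimulus appears), so consecutive onsets in fixed mode are 2.5 s apart.
Blocks whose random gap draws overrun the nominal 120 s window are extended
to the last stimulus offset; fixed-mode blocks are padded with stimulus-free
time up to 120 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Block",
    "TASK_BLOCKS",
    "TARGET_COLOR",
    "NONTARGET_COLORS",
    "TaskConfig",
    "StimulusEvent",
    "TaskSchedule",
    "SessionPlan",
    "SchedulingOverflowError",
    "build_task_config",
    "generate_schedule",
    "generate_session",
    "derive_seed",
]


class Block(str, Enum):
    """The five session blocks, in presentation order."""

    BASELINE = "BASELINE"
    S = "S"
    SV = "SV"
    C = "C"
    CV = "CV"


#: Task blocks in fixed presentation order (baseline excluded).
TASK_BLOCKS: tuple[Block, ...] = (Block.S, Block.SV, Block.C, Block.CV)

TARGET_COLOR = "red"
NONTARGET_COLORS: tuple[str, ...] = ("black", "green", "yellow", "blue")

#: Nominal block length in seconds.
BLOCK_DURATION_S = 120.0
#: Stimulus exposure in seconds (all tasks).
EXPOSURE_S = 0.5


class SchedulingOverflowError(RuntimeError):
    """Raised when the requested stimuli cannot fit in the block window."""


@dataclass(frozen=True)
class TaskConfig:
    task_id: Block
    exposure_s: float
    n_stimuli: int
    n_target: int
    n_nontarget: int
    isi_mode: str  # "fixed" | "random"
    isi_fixed_s: float
    isi_min_s: float
    isi_max_s: float
    block_duration_s: float
    palette: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_target + self.n_nontarget != self.n_stimuli:
            raise ValueError("n_target + n_nontarget must equal n_stimuli")
        if self.isi_mode not in ("fixed", "random"):
            raise ValueError(f"unknown isi_mode {self.isi_mode!r}")


@dataclass(frozen=True)
class StimulusEvent:
    index: int
    onset_s: float
    color: str
    is_target: bool

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "onset_s": self.onset_s,
            "color": self.color,
            "is_target": self.is_target,
        }


@dataclass(frozen=True)
class TaskSchedule:
    """A realized stimulus sequence for one block."""

    config: TaskConfig
    events: tuple[StimulusEvent, ...]
    seed: int
    #: Effective block duration; >= config.block_duration_s when a random
    #: draw sequence overran the nominal window.
    duration_s: float

    def onsets(self) -> np.ndarray:
        return np.array([e.onset_s for e in self.events], dtype=float)

    def to_dict(self) -> dict:
        return {
            "task_id": self.config.task_id.value,
            "seed": self.seed,
            "exposure_s": self.config.exposure_s,
            "duration_s": self.duration_s,
            "events": [e.to_dict() for e in self.events],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSchedule":
        config = build_task_config(Block(d["task_id"]))
        events = tuple(
            StimulusEvent(e["index"], e["onset_s"], e["color"], e["is_target"])
            for e in d["events"]
        )
        return cls(config=config, events=events, seed=d["seed"], duration_s=d["duration_s"])


@dataclass(frozen=True)
class SessionPlan:
    """Five consecutive block schedules: BASELINE, S, SV, C, CV."""

    blocks: tuple[TaskSchedule, ...]
    seed: int

    def __post_init__(self) -> None:
        order = tuple(b.config.task_id for b in self.blocks)
        expected = (Block.BASELINE,) + TASK_BLOCKS
        if order != expected:
            raise ValueError(f"blocks must be in order {expected}, got {order}")

    @property
    def block_starts(self) -> np.ndarray:
        """Absolute session start time of each block, seconds."""
        durs = [b.duration_s for b in self.blocks]
        return np.concatenate([[0.0], np.cumsum(durs)[:-1]])

    @property
    def total_duration_s(self) -> float:
        return float(sum(b.duration_s for b in self.blocks))

    def windows(self) -> list[tuple[Block, float, float]]:
        """(block, start_s, end_s) for every block, session-absolute."""
        starts = self.block_starts
        return [
            (sched.config.task_id, float(t0), float(t0 + sched.duration_s))
            for sched, t0 in zip(self.blocks, starts)
        ]

    def absolute_onsets(self) -> list[tuple[Block, int, float, bool]]:
        """(block, stimulus index, session-absolute onset, is_target) for all stimuli."""
        out = []
        for sched, t0 in zip(self.blocks, self.block_starts):
            for ev in sched.events:
                out.append((sched.config.task_id, ev.index, float(t0 + ev.onset_s), ev.is_target))
        return out

    def to_dict(self) -> dict:
        return {"seed": self.seed, "blocks": [b.to_dict() for b in self.blocks]}

    @classmethod
    def from_dict(cls, d: dict) -> "SessionPlan":
        return cls(
            blocks=tuple(TaskSchedule.from_dict(b) for b in d["blocks"]),
            seed=d["seed"],
        )


_TASK_TABLE = {
    Block.BASELINE: dict(n_stimuli=0, n_target=0, n_nontarget=0, isi_mode="fixed"),
    Block.S: dict(n_stimuli=30, n_target=30, n_nontarget=0, isi_mode="fixed"),
    Block.SV: dict(n_stimuli=30, n_target=30, n_nontarget=0, isi_mode="random"),
    Block.C: dict(n_stimuli=30, n_target=6, n_nontarget=24, isi_mode="fixed"),
    Block.CV: dict(n_stimuli=30, n_target=6, n_nontarget=24, isi_mode="random"),
}


def build_task_config(task_id: Block | str) -> TaskConfig:
    """Return the battery parameterization for one block.

    Simple blocks show only the red target; cognitive blocks mix 6 red
    targets with 24 non-targets over a five-colour palette.  The baseline
    is a stimulus-free 120 s resting block.
    """
    try:
        task_id = Block(task_id)
    except ValueError:
        raise ValueError(f"unknown task_id {task_id!r}") from None
    row = _TASK_TABLE[task_id]
    palette = (
        (TARGET_COLOR,)
        if row["n_nontarget"] == 0 and row["n_stimuli"] > 0
        else (TARGET_COLOR, *NONTARGET_COLORS)
    )
    if task_id is Block.BASELINE:
        palette = ()
    return TaskConfig(
        task_id=task_id,
        exposure_s=EXPOSURE_S if row["n_stimuli"] else 0.0,
        n_stimuli=row["n_stimuli"],
        n_target=row["n_target"],
        n_nontarget=row["n_nontarget"],
        isi_mode=row["isi_mode"],
        isi_fixed_s=2.0,
        isi_min_s=2.0,
        isi_max_s=5.0,
        block_duration_s=BLOCK_DURATION_S,
        palette=palette,
    )


def generate_schedule(config: TaskConfig, seed: int) -> TaskSchedule:
    """Draw one stimulus schedule for a block.

    The first stimulus appears after one inter-stimulus gap; subsequent
    onsets follow offset-to-onset gaps (fixed 2 s or uniform 2-5 s).  In
    cognitive blocks the 6 target slots are a uniform draw without
    replacement from the 30 positions and non-target colours cycle
    round-robin through black/green/yellow/blue.
    """
    rng = np.random.default_rng(seed)
    n = config.n_stimuli
    if n == 0:
        return TaskSchedule(config=config, events=(), seed=seed,
                            duration_s=config.block_duration_s)

    if config.isi_mode == "fixed":
        gaps = np.full(n, config.isi_fixed_s)
    else:
        gaps = rng.uniform(config.isi_min_s, config.isi_max_s, size=n)
    onsets = np.cumsum(gaps) + config.exposure_s * np.arange(n)
    last_offset = onsets[-1] + config.exposure_s

    duration = config.block_duration_s
    if last_offset > duration:
        if config.isi_mode == "fixed":
            raise SchedulingOverflowError(
                f"{n} stimuli at fixed gap {config.isi_fixed_s}s do not fit in "
                f"{duration}s"
            )
        duration = float(last_offset)

    is_target = np.zeros(n, dtype=bool)
    colors = [TARGET_COLOR] * n
    if config.n_nontarget == 0:
        is_target[:] = True
    else:
        target_slots = rng.choice(n, size=config.n_target, replace=False)
        is_target[target_slots] = True
        k = 0
        for i in range(n):
            if not is_target[i]:
                colors[i] = NONTARGET_COLORS[k % len(NONTARGET_COLORS)]
                k += 1

    events = tuple(
        StimulusEvent(index=i, onset_s=float(onsets[i]), color=colors[i],
                      is_target=bool(is_target[i]))
        for i in range(n)
    )
    return TaskSchedule(config=config, events=events, seed=seed, duration_s=duration)


def derive_seed(seed: int, *key: int) -> int:
    """Deterministic counter-based sub-seed derivation (always < 2**31)."""
    ss = np.random.SeedSequence([int(seed), *map(int, key)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_session(seed: int) -> SessionPlan:
    """Build a five-block session plan with per-block derived sub-seeds."""
    blocks = []
    for i, block in enumerate((Block.BASELINE,) + TASK_BLOCKS):
        sub = derive_seed(seed, i)
        blocks.append(generate_schedule(build_task_config(block), sub))
    return SessionPlan(blocks=tuple(blocks), seed=seed)
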