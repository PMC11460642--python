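"""Synthetic participant: four-channel physiological session generator.

Generates EDA, ECG, stimulus-trigger and button-response channels on a
common clock for a full five-block session, with parameterized autonomic
structure:

* **Heart rhythm** -- inter-beat intervals are a constant mean plus one slow
  sinusoid (SDNN driver) plus white Gaussian jitter (rMSSD driver), the
  jitter scaled per block so tasks modulate vagally mediated variability.
* **Electrodermal activity** -- a tonic skin conductance level per block
  (tasks elevated relative to baseline, linear 5 s cross-fades) plus
  stimulus-locked phasic responses with a Bateman (double-exponential)
  kernel.
* **Behaviour** -- log-normal reaction times per block and stimulus class,
  with misses; responses are rendered as bipolar button pulses (-1 V for
  Button-1 target/simple presses, +1 V for Button-2 non-target presses).

A :class:`GroundTruth` record of beats, phasic events and responses is kept
so recovery by the analysis chain can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .protocol import (
    Block,
    TASK_BLOCKS,
    SessionPlan,
    derive_seed,
    generate_session,
)

__all__ = [
    "ANSProfile",
    "GroundTruth",
    "SignalSet",
    "ResponseTruth",
    "default_profile",
    "simulate_ibi_series",
    "render_ecg",
    "render_eda",
    "render_responses",
    "simulate_session",
    "bateman_kernel",
]

CHANNEL_ROLES = ("EDA", "ECG", "TRIGGER", "RESPONSE")

#: Bateman kernel time constants (s): rise and decay of a phasic SCR.
SCR_TAU_RISE_S = 0.75
SCR_TAU_DECAY_S = 2.0

QRS_WIDTH_S = 0.080
TRIGGER_PULSE_S = 0.050
RESPONSE_PULSE_S = 0.100


def _default_jitter_factors() -> dict[Block, float]:
    # rMSSD scales with the white-jitter SD: non-vigilance tasks raise it
    # slightly, vigilance tasks depress it, mirroring the qualitative task
    # pattern the battery is meant to elicit.
    return {
        Block.BASELINE: 1.00,
        Block.S: 1.12,
        Block.SV: 0.94,
        Block.C: 1.10,
        Block.CV: 0.96,
    }


def _default_scl_factors() -> dict[Block, float]:
    # Tonic SCL multipliers: every task above baseline, fixed-interval tasks
    # above their vigilance counterparts.
    return {
        Block.BASELINE: 1.00,
        Block.S: 2.22,
        Block.SV: 1.82,
        Block.C: 2.37,
        Block.CV: 1.75,
    }


def _default_rt_params() -> dict[tuple[Block, str], tuple[float, float]]:
    # (mu, sigma) of log reaction time in ms; exp(mu) is the median.
    # Medians ordered simple < simple-vigilance < cognitive, targets slowest.
    med = {
        (Block.S, "simple"): 544.0,
        (Block.SV, "simple"): 569.0,
        (Block.C, "target"): 737.0,
        (Block.C, "nontarget"): 709.0,
        (Block.CV, "target"): 754.0,
        (Block.CV, "nontarget"): 735.0,
    }
    return {k: (math.log(v), 0.1) for k, v in med.items()}


@dataclass
class ANSProfile:
    """Autonomic parameter set for one synthetic participant."""

    mean_ibi_ms: float = 800.0
    jitter_sd_ms: float = 30.0
    slow_amp_ms: float = 20.0
    slow_freq_hz: float = 0.1
    ibi_jitter_factor_by_block: dict = field(default_factory=_default_jitter_factors)
    scl_base_us: float = 2.0
    scl_factor_by_block: dict = field(default_factory=_default_scl_factors)
    scr_amp_us: float = 0.3
    scr_prob: float = 0.5
    scr_latency_s: float = 2.0
    rt_lognorm_params: dict = field(default_factory=_default_rt_params)
    miss_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 300.0 <= self.mean_ibi_ms <= 2000.0:
            raise ValueError("mean_ibi_ms must lie in [300, 2000] ms")
        for p, name in ((self.scr_prob, "scr_prob"), (self.miss_prob, "miss_prob")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for m in self.ibi_jitter_factor_by_block.values():
            if m <= 0:
                raise ValueError("jitter factors must be positive")
        for m in self.scl_factor_by_block.values():
            if m <= 0:
                raise ValueError("SCL factors must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ibi_jitter_factor_by_block"] = {
            k.value: v for k, v in self.ibi_jitter_factor_by_block.items()
        }
        d["scl_factor_by_block"] = {
            k.value: v for k, v in self.scl_factor_by_block.items()
        }
        d["rt_lognorm_params"] = {
            f"{b.value}:{cls}": list(v) for (b, cls), v in self.rt_lognorm_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ANSProfile":
        d = dict(d)
        d["ibi_jitter_factor_by_block"] = {
            Block(k): v for k, v in d["ibi_jitter_factor_by_block"].items()
        }
        d["scl_factor_by_block"] = {
            Block(k): v for k, v in d["scl_factor_by_block"].items()
        }
        rt = {}
        for k, v in d["rt_lognorm_params"].items():
            b, stim_cls = k.split(":")
            rt[(Block(b), stim_cls)] = tuple(v)
        d["rt_lognorm_params"] = rt
        return cls(**d)


def default_profile(seed: int = 0, **overrides) -> ANSProfile:
    """The study-condition profile: task-modulated SCL, HRV and RT."""
    return ANSProfile(seed=seed, **overrides)


@dataclass
class ResponseTruth:
    block: Block
    stimulus_index: int
    rt_ms: float
    button_id: int
    truncated: bool = False

    def to_dict(self) -> dict:
        return {
            "block": self.block.value,
            "stimulus_index": self.stimulus_index,
            "rt_ms": self.rt_ms,
            "button_id": self.button_id,
            "truncated": self.truncated,
        }


@dataclass
class GroundTruth:
    """What the simulator actually injected, for recovery scoring."""

    beat_times_s: np.ndarray
    scr_events: list  # (onset_s, amplitude_us)
    responses: list  # ResponseTruth

    def to_dict(self) -> dict:
        return {
            "beat_times_s": [float(t) for t in self.beat_times_s],
            "scr_events": [[float(t), float(a)] for t, a in self.scr_events],
            "responses": [r.to_dict() for r in self.responses],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        return cls(
            beat_times_s=np.asarray(d["beat_times_s"], dtype=float),
            scr_events=[(t, a) for t, a in d["scr_events"]],
            responses=[
                ResponseTruth(
                    block=Block(r["block"]),
                    stimulus_index=r["stimulus_index"],
                    rt_ms=r["rt_ms"],
                    button_id=r["button_id"],
                    truncated=r["truncated"],
                )
                for r in d["responses"]
            ],
        )


@dataclass
class SignalSet:
    """Synchronized four-channel session recording."""

    fs_hz: float
    channels: dict[str, np.ndarray]
    session: SessionPlan
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        roles = set(self.channels)
        if roles != set(CHANNEL_ROLES):
            raise ValueError(f"channels must be exactly {CHANNEL_ROLES}, got {sorted(roles)}")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"channels differ in length: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return len(self.channels["ECG"])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


def simulate_ibi_series(
    profile: ANSProfile,
    block: Block,
    duration_s: float,
    seed: int,
    t0_s: float = 0.0,
) -> np.ndarray:
    """Draw inter-beat intervals (ms) covering at least ``duration_s``.

    IBI_i = mean + slow_amp * sin(2*pi*f*t_i) + e_i with e_i white Gaussian
    of SD jitter_sd_ms * block factor; t_i is the (session-absolute) time at
    which interval i starts.  All intervals are clipped to [300, 2000] ms.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    sd = profile.jitter_sd_ms * profile.ibi_jitter_factor_by_block.get(block, 1.0)

    ibis: list[float] = []
    t = t0_s
    # vectorized draws in chunks; the sinusoid needs running time, so we
    # iterate but draw noise in blocks
    target_end = t0_s + duration_s
    chunk = max(16, int(duration_s / (profile.mean_ibi_ms / 1000.0)) + 8)
    while t < target_end:
        noise = rng.normal(0.0, sd, size=chunk) if sd > 0 else np.zeros(chunk)
        for e in noise:
            ibi = (
                profile.mean_ibi_ms
                + profile.slow_amp_ms * math.sin(2 * math.pi * profile.slow_freq_hz * t)
                + e
            )
            ibi = min(max(ibi, 300.0), 2000.0)
            ibis.append(ibi)
            t += ibi / 1000.0
            if t >= target_end:
                break
    return np.asarray(ibis)


def render_ecg(
    beat_times_s: Sequence[float],
    fs_hz: float,
    noise_sd: float = 0.0,
    duration_s: float | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Synthesize an ECG trace: a triangular QRS template at each beat.

    The template is 80 ms wide with unit amplitude; the R-wave apex falls on
    the sample nearest the beat time.  Additive white Gaussian noise with SD
    ``noise_sd`` models acquisition noise.
    """
    if fs_hz < 100:
        raise ValueError("sampling rate below 100 Hz cannot resolve QRS timing")
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    if beat_times_s.size and np.any(np.diff(beat_times_s) <= 0):
        raise ValueError("beat times must be strictly increasing")
    if duration_s is None:
        duration_s = float(beat_times_s[-1] + 1.0) if beat_times_s.size else 1.0
    n = int(round(duration_s * fs_hz))

    half = int(round(QRS_WIDTH_S / 2 * fs_hz))
    # triangular template, apex 1.0 at centre
    tpl = 1.0 - np.abs(np.arange(-half, half + 1)) / half if half > 0 else np.array([1.0])

    ecg = np.zeros(n)
    for bt in beat_times_s:
        c = int(round(bt * fs_hz))
        lo, hi = c - half, c + half + 1
        tlo = max(lo, 0) - lo
        thi = len(tpl) - (hi - min(hi, n))
        if max(lo, 0) < min(hi, n):
            seg = ecg[max(lo, 0):min(hi, n)]
            np.maximum(seg, tpl[tlo:thi], out=seg)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ecg = ecg + rng.normal(0.0, noise_sd, size=n)
    return ecg


def bateman_kernel(t: np.ndarray, amp_us: float) -> np.ndarray:
    """Phasic SCR kernel a*(exp(-t/tau_d) - exp(-t/tau_r)), peak == amp_us."""
    tr, td = SCR_TAU_RISE_S, SCR_TAU_DECAY_S
    t_peak = math.log(td / tr) * tr * td / (td - tr)
    peak = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = (np.exp(-t[pos] / td) - np.exp(-t[pos] / tr)) * (amp_us / peak)
    return out


def _tonic_scl(plan: SessionPlan, profile: ANSProfile, n: int, fs_hz: float) -> np.ndarray:
    """Piecewise-constant tonic level with a linear 5 s cross-fade after
    each block boundary."""
    t = np.arange(n) / fs_hz
    levels = [
        profile.scl_base_us * profile.scl_factor_by_block.get(w[0], 1.0)
        for w in plan.windows()
    ]
    tonic = np.full(n, levels[0])
    fade = 5.0
    for (block, start, _end), lev in zip(plan.windows()[1:], levels[1:]):
        prev = tonic[np.searchsorted(t, start) - 1] if start > 0 else levels[0]
        seg = t >= start
        tonic[seg] = lev
        ramp = (t >= start) & (t < start + fade)
        tonic[ramp] = prev + (lev - prev) * (t[ramp] - start) / fade
    return tonic


def render_eda(
    plan: SessionPlan,
    profile: ANSProfile,
    fs_hz: float,
    seed: int,
    duration_s: float | None = None,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Render the EDA channel: tonic block levels plus stimulus-locked SCRs.

    Each stimulus independently elicits a phasic response with probability
    ``scr_prob``; the Bateman kernel starts ``scr_latency_s`` after onset and
    its peak equals ``scr_amp_us``.  Returns the trace and the injected
    (onset_s, amplitude_us) events.
    """
    if duration_s is None:
        duration_s = plan.total_duration_s
    n = int(round(duration_s * fs_hz))
    rng = np.random.default_rng(seed)

    eda = _tonic_scl(plan, profile, n, fs_hz)
    events: list[tuple[float, float]] = []
    t = np.arange(n) / fs_hz
    for _block, _idx, onset, _tgt in plan.absolute_onsets():
        if rng.random() >= profile.scr_prob:
            continue
        start = onset + profile.scr_latency_s
        events.append((start, profile.scr_amp_us))
        i0 = int(round(start * fs_hz))
        if i0 >= n:
            continue
        # kernel support truncated at 10 decay constants
        i1 = min(n, i0 + int(10 * SCR_TAU_DECAY_S * fs_hz))
        eda[i0:i1] += bateman_kernel(t[i0:i1] - start, profile.scr_amp_us)
    return eda, events


def _stim_class(block: Block, is_target: bool) -> str:
    if block in (Block.S, Block.SV):
        return "simple"
    return "target" if is_target else "nontarget"


def render_responses(
    plan: SessionPlan,
    profile: ANSProfile,
    fs_hz: float,
    seed: int,
    duration_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray, list[ResponseTruth]]:
    """Render the trigger and bipolar button channels.

    TRIGGER carries a unit 50 ms pulse at every stimulus onset.  RESPONSE
    carries a 100 ms pulse at onset + RT for each non-missed stimulus:
    amplitude -1 V for Button-1 (simple/target) and +1 V for Button-2
    (non-target).  Draws that would overrun the next stimulus onset are
    truncated and flagged in the truth record.
    """
    if duration_s is None:
        duration_s = plan.total_duration_s
    n = int(round(duration_s * fs_hz))
    rng = np.random.default_rng(seed)

    trigger = np.zeros(n)
    response = np.zeros(n)
    truths: list[ResponseTruth] = []

    stim = plan.absolute_onsets()
    trig_len = int(round(TRIGGER_PULSE_S * fs_hz))
    resp_len = int(round(RESPONSE_PULSE_S * fs_hz))
    for i, (block, idx, onset, is_target) in enumerate(stim):
        i0 = int(round(onset * fs_hz))
        trigger[i0:min(i0 + trig_len, n)] = 1.0

        if rng.random() < profile.miss_prob:
            continue
        cls = _stim_class(block, is_target)
        mu, sigma = profile.rt_lognorm_params[(block, cls)]
        rt_ms = float(rng.lognormal(mu, sigma))
        truncated = False
        if i + 1 < len(stim) and stim[i + 1][0] is block:
            next_onset = stim[i + 1][2]
            max_rt = (next_onset - onset) * 1000.0 - 1000.0 / fs_hz
            if rt_ms > max_rt:
                rt_ms, truncated = max_rt, True
        button = 1 if cls in ("simple", "target") else 2
        amp = -1.0 if button == 1 else 1.0
        j0 = int(round((onset + rt_ms / 1000.0) * fs_hz))
        if j0 < n:
            response[j0:min(j0 + resp_len, n)] = amp
        truths.append(ResponseTruth(block, idx, rt_ms, button, truncated))
    return trigger, response, truths


def simulate_session(
    profile: ANSProfile,
    fs_hz: float = 500.0,
    seed: int | None = None,
    plan: SessionPlan | None = None,
    ecg_noise_sd: float = 0.1,
) -> SignalSet:
    """Assemble a full four-channel session for one synthetic participant.

    The heart rhythm is continuous across blocks: intervals are drawn block
    by block (each with its own jitter factor) from a single running clock.
    Deterministic for a given seed.
    """
    if seed is None:
        seed = profile.seed
    if plan is None:
        plan = generate_session(derive_seed(seed, 0))

    total = plan.total_duration_s
    n = int(round(total * fs_hz))

    # continuous beat train across blocks; the cursor stays on the last
    # placed beat so the interval spanning a boundary is re-drawn by the
    # next block rather than leaving a gap
    beats: list[float] = []
    t = 0.0
    for k, (block, start, end) in enumerate(plan.windows()):
        ibis = simulate_ibi_series(profile, block, end - t, derive_seed(seed, 1, k), t0_s=t)
        for ibi in ibis:
            if t + ibi / 1000.0 >= end:
                break
            t += ibi / 1000.0
            beats.append(t)
    beat_times = np.asarray(beats)

    ecg = render_ecg(beat_times, fs_hz, noise_sd=ecg_noise_sd,
                     duration_s=total, seed=derive_seed(seed, 2))
    eda, scr_events = render_eda(plan, profile, fs_hz, derive_seed(seed, 3),
                                 duration_s=total)
    trigger, response, resp_truth = render_responses(
        plan, profile, fs_hz, derive_seed(seed, 4), duration_s=total
    )

    truth = GroundTruth(beat_times_s=beat_times, scr_events=scr_events,
                        responses=resp_truth)
    return SignalSet(
        fs_hz=fs_hz,
        channels={"EDA": eda, "ECG": ecg, "TRIGGER": trigger, "RESPONSE": response},
        session=plan,
        truth=truth,
    )
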