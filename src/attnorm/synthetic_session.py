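"""Synthetic passive-viewing sessions: trials, spike trains, pupil traces.

The generative process mirrors the task and the winner-take-all account of
covert attention.  On every trial the animal attends one cue at a time:
with two cues it attends the higher-value cue; a brief visual perturbation
of the lower-value cue captures attention for the rest of the cue period
with probability

    a = d / (1 + exp(c * |dV_norm|)),

where ``|dV_norm|`` is the value difference normalized by the largest
reward (8 drops).  The generator's latent drive is value itself, while the
fitting stage works with measured single-cue responses; keeping the two
independent makes parameter-recovery tests honest.

Spike trains are inhomogeneous Poisson.  The firing-rate function is
piecewise constant on a 10 ms grid: baseline before cue onset plus visual
latency, then baseline plus a tuning-signed drive of the currently attended
cue's value under a transient-then-sustained envelope, rectified at zero.
Pupil traces are sampled at 500 Hz: a baseline plus a slow cue-locked
kernel whose amplitude grows with the attended (higher) cue's value, plus
Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from attnorm.attention_model import attention_weight
from attnorm.task_core import (
    CUE_DURATION_MS,
    DELAY_DURATION_MS,
    FIXATION_DURATION_MS,
    PerturbationEvent,
    Condition,
    Cue,
    Trial,
    assign_reward,
    condition_lookup,
    conditions_from_frame,
    conditions_to_frame,
    enumerate_block_conditions,
    generate_block_order,
    trials_to_frame,
)

__all__ = [
    "GroundTruthNeuron",
    "AttentionTrace",
    "PupilGroundTruth",
    "SessionConfig",
    "SessionData",
    "draw_attention_trace",
    "simulate_spike_train",
    "simulate_pupil_trace",
    "simulate_session",
    "default_neuron_population",
]

#: Piecewise-constant rate grid (ms relative to cue onset).
GRID_STEP_MS = 10
GRID_START_MS = -2000
GRID_END_MS = 1200
MAX_VALUE = 8  # drops; normalizes the latent value drive

TUNING_CLASSES = ("positive", "negative", "untuned", "non-visual")


class ConfigError(ValueError):
    """Raised for invalid simulation configuration fields."""


@dataclass
class GroundTruthNeuron:
    """Simulator parameters of one neuron.

    The sustained drive of a visual neuron attending a cue of value V is
    ``visual_offset + value_gain * V/8`` (positive tuning) or
    ``visual_offset + value_gain * (1 - V/8)`` (negative tuning); untuned
    neurons carry only the value-independent visual offset and non-visual
    neurons none.  ``b, c, d`` parameterize the attention process exactly as
    in the normalization model; ``b`` is an additive offset in normalized
    units (0 in the pure winner-take-all process).
    """

    neuron_id: str
    tuning: str = "positive"
    baseline_rate: float = 10.0  # spikes/s
    value_gain: float = 20.0  # spikes/s from lowest- to highest-value cue
    visual_offset: float = 5.0  # value-independent visual drive, spikes/s
    visual_latency_ms: float = 150.0
    ramp_ms: float = 50.0
    transient_scale: float = 1.5
    transient_duration_ms: float = 200.0
    b: float = 0.0
    c: float = 8.0
    d: float = 1.0
    attention_shift_latency_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.tuning not in TUNING_CLASSES:
            raise ValueError(f"unknown tuning class {self.tuning!r}")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if not 0.0 <= self.c <= 100.0:
            raise ValueError(f"c out of [0, 100]: {self.c}")
        if not 0.0 <= self.d <= 2.0:
            raise ValueError(f"d out of [0, 2]: {self.d}")

    def drive(self, value: float) -> float:
        """Sustained attended-value drive (spikes/s) above baseline."""
        v = value / MAX_VALUE
        if self.tuning == "positive":
            return self.visual_offset + self.value_gain * v
        if self.tuning == "negative":
            return self.visual_offset + self.value_gain * (1.0 - v)
        if self.tuning == "untuned":
            return self.visual_offset
        return 0.0


@dataclass
class AttentionTrace:
    """Per-trial attention timeline over the cue period [0, 1000) ms.

    ``segments`` is a list of ``(t_start_ms, t_end_ms, side)`` intervals
    partitioning the cue period; ``values`` maps each displayed side to its
    cue value; ``shifted`` records whether the perturbation captured
    attention on this trial.
    """

    segments: list[tuple[float, float, str]]
    values: dict[str, float]
    shifted: bool = False

    def attended_value(self, t_ms: float) -> float:
        """Value of the attended cue at time ``t_ms`` (clamped to the cue period)."""
        t = min(max(t_ms, self.segments[0][0]), self.segments[-1][1] - 1e-9)
        for t0, t1, side in self.segments:
            if t0 <= t < t1:
                return self.values[side]
        raise RuntimeError("segments do not cover the cue period")


@dataclass
class PupilGroundTruth:
    """Generative parameters of the pupil trace (arbitrary tracker units)."""

    baseline: float = 1000.0
    drift_per_s: float = 0.0
    amplitude_per_drop: float = 5.0
    ramp_ms: float = float(CUE_DURATION_MS)  # kernel rise time from cue onset
    noise_sd: float = 2.0
    sampling_rate_hz: float = 500.0


def draw_attention_trace(
    condition: Condition,
    c: float,
    d: float,
    rng: np.random.Generator,
    *,
    shift_latency_ms: float = 100.0,
    perturbation: PerturbationEvent = PerturbationEvent(),
    cue_duration_ms: float = float(CUE_DURATION_MS),
) -> AttentionTrace:
    """Draw the winner-take-all attention timeline for one trial.

    Single cue: that cue is attended throughout.  Double cue: the
    higher-value cue is attended (ties broken uniformly).  A perturbation of
    the already-attended higher-value cue changes nothing; a perturbation of
    the lower-value cue (or of either cue of an equal-value pair) captures
    attention with probability ``a = d/(1+exp(c*|dV_norm|))``, in which case
    attention switches at perturbation onset + shift latency and stays.
    """
    values = {}
    if condition.left_cue is not None:
        values["left"] = float(condition.left_cue.value)
    if condition.right_cue is not None:
        values["right"] = float(condition.right_cue.value)

    if condition.is_single:
        side = next(iter(values))
        return AttentionTrace([(0.0, cue_duration_ms, side)], values)

    vl_, vr_ = values["left"], values["right"]
    if vl_ > vr_:
        attended = "left"
    elif vr_ > vl_:
        attended = "right"
    else:
        attended = "left" if rng.random() < 0.5 else "right"

    target = condition.perturbed_target
    shift = False
    if target in ("lower", "equal") and condition.perturbed_side != attended:
        dv_norm = abs(vl_ - vr_) / MAX_VALUE
        a = float(attention_weight(dv_norm, c, d))
        shift = rng.random() < a
    if not shift:
        return AttentionTrace([(0.0, cue_duration_ms, attended)], values)
    t_switch = perturbation.onset_ms + shift_latency_ms
    return AttentionTrace(
        [
            (0.0, t_switch, attended),
            (t_switch, cue_duration_ms, condition.perturbed_side),
        ],
        values,
        shifted=True,
    )


# ---------------------------------------------------------------------------
# Firing-rate construction


def rate_grid() -> tuple[np.ndarray, np.ndarray]:
    """Bin edges and centers (ms relative to cue onset) of the rate grid."""
    edges = np.arange(GRID_START_MS, GRID_END_MS + GRID_STEP_MS, GRID_STEP_MS, dtype=float)
    centers = edges[:-1] + GRID_STEP_MS / 2.0
    return edges, centers


def _envelope(centers: np.ndarray, neuron: GroundTruthNeuron) -> np.ndarray:
    """Transient-then-sustained response envelope evaluated at bin centers."""
    lat = neuron.visual_latency_ms
    ramp_end = lat + neuron.ramp_ms
    tr_end = ramp_end + neuron.transient_duration_ms
    drive_end = CUE_DURATION_MS + lat
    e = np.zeros_like(centers)
    in_ramp = (centers >= lat) & (centers < ramp_end)
    e[in_ramp] = neuron.transient_scale * (centers[in_ramp] - lat) / neuron.ramp_ms
    e[(centers >= ramp_end) & (centers < tr_end)] = neuron.transient_scale
    e[(centers >= tr_end) & (centers < drive_end)] = 1.0
    return e


def rate_function(
    neuron: GroundTruthNeuron, attention: AttentionTrace
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant firing rate (spikes/s) on the grid for one trial."""
    edges, centers = rate_grid()
    attended = np.array([attention.attended_value(t) for t in centers])
    drive = np.array([neuron.drive(v) for v in attended])
    rate = neuron.baseline_rate + _envelope(centers, neuron) * drive
    return edges, np.maximum(rate, 0.0)


def simulate_spike_train(
    neuron: GroundTruthNeuron,
    trial: Trial,
    attention: AttentionTrace,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample one inhomogeneous-Poisson spike train (ms relative to cue onset)."""
    edges, rate = rate_function(neuron, attention)
    widths_s = np.diff(edges) / 1000.0
    if np.any(widths_s < 0):
        raise ValueError("negative bin duration")
    counts = rng.poisson(rate * widths_s)
    spikes = np.repeat(edges[:-1], counts) + rng.random(counts.sum()) * GRID_STEP_MS
    return np.sort(spikes)


def simulate_pupil_trace(
    trial: Trial,
    attended_value: float,
    gt: PupilGroundTruth,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one pupil trace; times are ms relative to fixation onset.

    The trace covers fixation, cue and delay.  The value kernel is zero
    before cue onset, rises linearly over ``ramp_ms`` and then holds, so the
    mean over the 1 s after cue offset equals exactly
    ``amplitude_per_drop * attended_value`` above baseline (plus noise).
    """
    step_ms = 1000.0 / gt.sampling_rate_hz
    total = FIXATION_DURATION_MS + CUE_DURATION_MS + DELAY_DURATION_MS
    t = np.arange(0.0, total, step_ms)
    kernel = np.clip((t - FIXATION_DURATION_MS) / gt.ramp_ms, 0.0, 1.0)
    trace = (
        gt.baseline
        + gt.drift_per_s * t / 1000.0
        + gt.amplitude_per_drop * attended_value * kernel
    )
    if gt.noise_sd > 0:
        trace = trace + rng.normal(0.0, gt.noise_sd, size=t.size)
    return t, trace


# ---------------------------------------------------------------------------
# Whole-session simulation


@dataclass
class SessionConfig:
    """Configuration of one simulated session."""

    n_blocks: int = 9
    neurons: list[GroundTruthNeuron] = field(default_factory=list)
    cue_values: tuple[int, ...] = (0, 1, 2, 4, 8)
    incomplete_rate: float = 0.0
    inter_trial_ms: float = 1000.0
    pupil: PupilGroundTruth = field(default_factory=PupilGroundTruth)
    include_pupil: bool = True
    include_spikes: bool = True

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")
        if not 0.0 <= self.incomplete_rate < 1.0:
            raise ConfigError("incomplete_rate must be in [0, 1)")
        if not self.cue_values:
            raise ConfigError("cue_values must be nonempty")
        seen = set()
        for n in self.neurons:
            if n.neuron_id in seen:
                raise ConfigError(f"duplicate neuron_id {n.neuron_id!r}")
            seen.add(n.neuron_id)


@dataclass
class SessionData:
    """In-memory bundle of one simulated session."""

    conditions: pd.DataFrame
    trials: pd.DataFrame
    spikes: pd.DataFrame
    pupil: pd.DataFrame
    neurons: pd.DataFrame

    def save(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("conditions", "trials", "spikes", "pupil", "neurons"):
            df = getattr(self, name)
            fname = "neurons_truth.csv" if name == "neurons" else f"{name}.csv"
            path = outdir / fname
            df.to_csv(path, index=False)
            paths[name] = path
        return paths

    @classmethod
    def load(cls, indir: str | Path) -> "SessionData":
        indir = Path(indir)
        def _read(fname, **kw):
            p = indir / fname
            return pd.read_csv(p, **kw) if p.exists() else pd.DataFrame()
        return cls(
            conditions=_read("conditions.csv", keep_default_na=False),
            trials=_read("trials.csv", keep_default_na=False, na_values=[""]),
            spikes=_read("spikes.csv"),
            pupil=_read("pupil.csv"),
            neurons=_read("neurons_truth.csv"),
        )

    def condition_objects(self) -> list[Condition]:
        return conditions_from_frame(self.conditions)


def default_neuron_population(
    rng: np.random.Generator | int,
    n_positive: int = 2,
    n_negative: int = 2,
    n_untuned: int = 1,
    n_nonvisual: int = 1,
    *,
    value_gain_range: tuple[float, float] = (12.0, 28.0),
    baseline_range: tuple[float, float] = (5.0, 15.0),
    c_range: tuple[float, float] = (2.0, 20.0),
    d_range: tuple[float, float] = (0.5, 1.8),
) -> list[GroundTruthNeuron]:
    """Draw a mixed population of ground-truth neurons with realistic rates."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    neurons = []
    classes = (
        ["positive"] * n_positive
        + ["negative"] * n_negative
        + ["untuned"] * n_untuned
        + ["non-visual"] * n_nonvisual
    )
    for i, tuning in enumerate(classes):
        neurons.append(
            GroundTruthNeuron(
                neuron_id=f"n{i:03d}_{tuning.replace('-', '')}",
                tuning=tuning,
                baseline_rate=float(rng.uniform(*baseline_range)),
                value_gain=float(rng.uniform(*value_gain_range))
                if tuning in ("positive", "negative")
                else 0.0,
                visual_offset=5.0 if tuning != "non-visual" else 0.0,
                c=float(rng.uniform(*c_range)),
                d=float(rng.uniform(*d_range)),
            )
        )
    return neurons


def _simulate_trials(
    config: SessionConfig, conditions: Sequence[Condition], rng: np.random.Generator
) -> list[Trial]:
    lookup = condition_lookup(conditions)
    trials: list[Trial] = []
    clock = 0.0
    trial_id = 0

    def _new_trial(cid: str, block: int, completed: bool) -> Trial:
        nonlocal clock, trial_id
        t = Trial(
            trial_id=trial_id,
            block_index=block,
            condition_id=cid,
            completed=completed,
            t_fixation_on_ms=clock,
            t_cue_on_ms=clock + FIXATION_DURATION_MS,
            t_cue_off_ms=clock + FIXATION_DURATION_MS + CUE_DURATION_MS,
            t_reward_ms=clock
            + FIXATION_DURATION_MS
            + CUE_DURATION_MS
            + DELAY_DURATION_MS,
        )
        if completed:
            side, drops = assign_reward(lookup[cid], rng)
            t.rewarded_side, t.reward_drops = side, drops
        trial_id += 1
        clock = t.t_reward_ms + config.inter_trial_ms
        return t

    for block in range(config.n_blocks):
        for cid in generate_block_order(conditions, rng):
            # a fixation break aborts the trial; the condition is repeated
            while config.incomplete_rate > 0 and rng.random() < config.incomplete_rate:
                trials.append(_new_trial(cid, block, completed=False))
            trials.append(_new_trial(cid, block, completed=True))
    return trials


def simulate_neuron_bin_counts(
    neuron: GroundTruthNeuron,
    trial_conditions: Sequence[Condition],
    rng: np.random.Generator,
    *,
    attention_mode: str = "winner_take_all",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-trial spike counts on the rate grid for one neuron.

    Draws the attention trace per trial from the neuron's (c, d), groups
    trials by the resulting attended-value timeline, and samples Poisson
    counts per 10 ms bin.  Returns ``(edges, counts, shifted)`` with counts
    of shape (n_trials, n_bins), distributionally identical to binning the
    spike trains of :func:`simulate_spike_train`.

    ``attention_mode='equal_average'`` replaces the winner-take-all process
    with an unselective one: the drive of a double-cue trial follows the
    mean of the two values and the perturbation has no effect.  This
    contrast generator exists to show the analyses can tell the two coding
    schemes apart.
    """
    if attention_mode not in ("winner_take_all", "equal_average"):
        raise ValueError(f"unknown attention_mode {attention_mode!r}")
    edges, centers = rate_grid()
    env = _envelope(centers, neuron)
    n_trials = len(trial_conditions)
    counts = np.zeros((n_trials, centers.size), dtype=np.int64)
    shifted = np.zeros(n_trials, dtype=bool)

    # key: attended value before/after the shift time (equal if no shift)
    groups: dict[tuple[float, float], list[int]] = {}
    t_switch = PerturbationEvent().onset_ms + neuron.attention_shift_latency_ms
    for i, cond in enumerate(trial_conditions):
        if attention_mode == "equal_average":
            if cond.is_single:
                v = float(cond.single_cue.value)
            else:
                v = (cond.left_cue.value + cond.right_cue.value) / 2.0
            groups.setdefault((v, v), []).append(i)
            continue
        trace = draw_attention_trace(
            cond, neuron.c, neuron.d, rng,
            shift_latency_ms=neuron.attention_shift_latency_ms,
        )
        shifted[i] = trace.shifted
        v0 = trace.attended_value(0.0)
        v1 = trace.attended_value(CUE_DURATION_MS - 1e-6)
        groups.setdefault((v0, v1), []).append(i)

    widths_s = np.diff(edges) / 1000.0
    in_cue = (centers >= 0) & (centers < CUE_DURATION_MS)
    post_cue = centers >= CUE_DURATION_MS
    for (v0, v1), idx in groups.items():
        attended = np.where(in_cue & (centers < t_switch), v0, v1)
        attended = np.where(post_cue, v1, attended)
        drive = np.array([neuron.drive(v) for v in attended])
        rate = np.maximum(neuron.baseline_rate + env * drive, 0.0)
        lam = np.broadcast_to(rate * widths_s, (len(idx), centers.size))
        counts[idx, :] = rng.poisson(lam)
    return edges, counts, shifted


def counts_to_spikes(
    edges: np.ndarray,
    counts: np.ndarray,
    trial_ids: Sequence[int],
    neuron_id: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Expand a per-bin count matrix into a long spikes table (t in ms)."""
    per_trial = counts.sum(axis=1)
    t_rows = np.repeat(np.asarray(trial_ids), per_trial)
    flat = counts.ravel()
    lows = np.tile(edges[:-1], counts.shape[0])
    t_ms = np.repeat(lows, flat) + rng.random(int(flat.sum())) * GRID_STEP_MS
    return pd.DataFrame(
        {"neuron_id": neuron_id, "trial_id": t_rows, "t_ms": t_ms}
    )


def simulate_session(
    config: SessionConfig, rng_seed: int | np.random.Generator
) -> SessionData:
    """Simulate a full session and return the tabular bundle.

    Fully reproducible from the seed.  Each neuron's attention process uses
    its own (c, d); set them equal across neurons to emulate a single
    animal-level process.  The pupil trace follows the higher-value cue.
    """
    config.validate()
    rng = (
        np.random.default_rng(rng_seed)
        if isinstance(rng_seed, (int, np.integer))
        else rng_seed
    )
    cues = tuple(Cue(f"v{v}", v) for v in config.cue_values)
    conditions = enumerate_block_conditions(cues)
    lookup = condition_lookup(conditions)

    trials = _simulate_trials(config, conditions, rng)
    trials_df = trials_to_frame(trials)
    completed = [t for t in trials if t.completed]
    completed_conds = [lookup[t.condition_id] for t in completed]
    completed_ids = [t.trial_id for t in completed]

    spike_frames = []
    truth_rows = []
    for neuron in config.neurons:
        truth_rows.append(asdict(neuron))
        if not config.include_spikes:
            continue
        edges, counts, shifted_mask = simulate_neuron_bin_counts(
            neuron, completed_conds, rng
        )
        spike_frames.append(
            counts_to_spikes(edges, counts, completed_ids, neuron.neuron_id, rng)
        )
    spikes_df = (
        pd.concat(spike_frames, ignore_index=True)
        if spike_frames
        else pd.DataFrame(columns=["neuron_id", "trial_id", "t_ms"])
    )

    pupil_rows = []
    if config.include_pupil:
        for t, cond in zip(completed, completed_conds):
            v = float(cond.higher_value)
            tt, trace = simulate_pupil_trace(t, v, config.pupil, rng)
            pupil_rows.append(
                pd.DataFrame(
                    {"trial_id": t.trial_id, "t_ms": tt, "pupil_size": trace}
                )
            )
    pupil_df = (
        pd.concat(pupil_rows, ignore_index=True)
        if pupil_rows
        else pd.DataFrame(columns=["trial_id", "t_ms", "pupil_size"])
    )

    return SessionData(
        conditions=conditions_to_frame(conditions),
        trials=trials_df,
        spikes=spikes_df,
        pupil=pupil_df,
        neurons=pd.DataFrame(truth_rows),
    )
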