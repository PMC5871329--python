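"""Quantification of perturbation-driven attentional modulation.

Perturbed double-cue trials are split into two groups: rotations of the
higher-value cue and rotations of the lower-value cue.  A sliding-window
PSTH contrast between the groups (two-tailed t-test per bin, BH-FDR for
display) locates when modulation emerges; a neuron counts as modulated if
the uncorrected pointwise test stays below 0.05 over a contiguous window of
at least 200 ms between perturbation onset and cue offset (200-1000 ms
after cue onset).  Modulated neurons get a modulation window, Z-scored
group responses, a modulation index MI = (FRh - FRl)/(FRh + FRl), and a
consistency label recording whether the perturbed-condition response moved
toward the perturbed cue's single-cue response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from attnorm.task_core import Condition, condition_lookup
from attnorm.neuron_screening import (
    BASELINE_WINDOW,
    MODEL_WINDOW,
    windowed_rates,
)

__all__ = [
    "Psth",
    "ModulationResult",
    "compute_psth",
    "pointwise_rotation_test",
    "benjamini_hochberg",
    "find_modulation_window",
    "modulation_index",
    "zscore_modulation",
    "classify_consistency",
    "first_block_control",
    "compare_rotation_conditions",
    "rotation_groups",
]

PSTH_WINDOW_MS = 50.0
PSTH_STEP_MS = 10.0
PSTH_RANGE_MS = (-200.0, 1000.0)
MODULATION_SEARCH_MS = (200.0, 1000.0)  # perturbation onset to cue offset
MIN_MODULATION_MS = 200.0
UNIFORM_WINDOW_MS = (450.0, 750.0)
ALPHA = 0.05


@dataclass
class Psth:
    """Sliding-window PSTH of one trial group."""

    neuron_id: str
    group: str
    bin_centers: np.ndarray  # ms relative to cue onset
    rates: np.ndarray  # normalized, baseline-subtracted
    window_ms: float = PSTH_WINDOW_MS
    step_ms: float = PSTH_STEP_MS
    baseline: float = 0.0  # spikes/s subtracted before normalization


@dataclass
class ModulationResult:
    neuron_id: str
    modulated: bool
    window: Optional[tuple[float, float]]  # [start, end] ms or None
    z_high: float
    z_low: float
    mi: float
    consistency: str  # consistent | inconsistent | n/a


class UndefinedMIError(ValueError):
    pass


def _spike_matrix(
    spikes: pd.DataFrame, trial_ids: Sequence[int], neuron_id: str
) -> dict[int, np.ndarray]:
    sel = spikes[spikes["neuron_id"] == neuron_id]
    grouped = {tid: g["t_ms"].to_numpy() for tid, g in sel.groupby("trial_id")}
    return {tid: grouped.get(tid, np.empty(0)) for tid in trial_ids}


def trialwise_bin_rates(
    spikes: pd.DataFrame,
    trial_ids: Sequence[int],
    neuron_id: str,
    *,
    window_ms: float = PSTH_WINDOW_MS,
    step_ms: float = PSTH_STEP_MS,
    t_range: tuple[float, float] = PSTH_RANGE_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial x bin matrix of sliding-window rates (spikes/s).

    Bin centers step by ``step_ms`` over ``t_range``; each bin counts spikes
    in the 50 ms window centered on it.
    """
    centers = np.arange(t_range[0], t_range[1] + step_ms / 2, step_ms)
    by_trial = _spike_matrix(spikes, trial_ids, neuron_id)
    half = window_ms / 2.0
    mat = np.empty((len(trial_ids), centers.size))
    for i, tid in enumerate(trial_ids):
        t = by_trial[tid]
        lo = np.searchsorted(t, centers - half, side="left")
        hi = np.searchsorted(t, centers + half, side="left")
        mat[i] = (hi - lo) / (window_ms / 1000.0)
    return centers, mat


def compute_psth(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    neuron_id: str,
    group_trial_ids: Sequence[int],
    group: str = "",
    *,
    step_ms: float = PSTH_STEP_MS,
    baseline: Optional[float] = None,
    peak_norm: Optional[float] = None,
) -> Psth:
    """Sliding-window PSTH averaged over the trials of one condition group.

    The 200 ms pre-cue mean rate is subtracted as baseline; if
    ``peak_norm`` is given (the neuron's peak preferred-condition response)
    the curve is divided by it.
    """
    if len(group_trial_ids) == 0:
        raise ValueError("empty trial group")
    centers, mat = trialwise_bin_rates(
        spikes, group_trial_ids, neuron_id, step_ms=step_ms
    )
    mean = mat.mean(axis=0)
    if baseline is None:
        baseline = float(
            windowed_rates(spikes, group_trial_ids, BASELINE_WINDOW, neuron_id).mean()
        )
    mean = mean - baseline
    if peak_norm is not None:
        if peak_norm == 0:
            raise ValueError("peak_norm must be nonzero")
        mean = mean / peak_norm
    return Psth(neuron_id, group, centers, mean, baseline=baseline)


def pointwise_rotation_test(
    rates_high: np.ndarray, rates_low: np.ndarray
) -> np.ndarray:
    """Two-tailed t-test per bin on trial-wise windowed rates.

    Inputs are trial x bin matrices of the higher-rotated and lower-rotated
    groups.  Bins where both groups have zero variance and equal means get
    p = 1 (degenerate, no evidence either way).
    """
    if rates_high.shape[0] == 0 or rates_low.shape[0] == 0:
        raise ValueError("both groups must be nonempty")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(rates_high, rates_low, axis=0)
    p = np.asarray(p)
    degenerate = ~np.isfinite(p)
    p[degenerate] = 1.0
    return p


def benjamini_hochberg(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Step-up Benjamini-Hochberg rejection mask at FDR level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def find_modulation_window(
    bin_centers: np.ndarray,
    pvalues: np.ndarray,
    *,
    alpha: float = ALPHA,
    search: tuple[float, float] = MODULATION_SEARCH_MS,
    min_length_ms: float = MIN_MODULATION_MS,
    step_ms: float = PSTH_STEP_MS,
) -> Optional[tuple[float, float]]:
    """Longest contiguous run of sub-alpha bins spanning >= 200 ms.

    Restricted to bin centers inside [200, 1000] ms.  A run of k bins at
    step s covers k*s ms.  Ties in length resolve to the earliest run.
    Returns (start, end) in ms of the run's bin-center extent, or None.
    """
    centers = np.asarray(bin_centers)
    p = np.asarray(pvalues)
    mask = (centers >= search[0]) & (centers <= search[1])
    centers, p = centers[mask], p[mask]
    sig = p < alpha
    best = None
    i = 0
    n = sig.size
    while i < n:
        if sig[i]:
            j = i
            while j + 1 < n and sig[j + 1]:
                j += 1
            length = (j - i + 1) * step_ms
            if length >= min_length_ms and (best is None or length > best[0]):
                best = (length, centers[i], centers[j])
            i = j + 1
        else:
            i += 1
    if best is None:
        return None
    return float(best[1]), float(best[2])


def modulation_index(fr_high: float, fr_low: float) -> float:
    """MI = (FRh - FRl) / (FRh + FRl); requires a positive denominator."""
    denom = fr_high + fr_low
    if denom == 0:
        raise UndefinedMIError("FRh + FRl = 0")
    return (fr_high - fr_low) / denom


def zscore_modulation(
    rates_high: np.ndarray, rates_low: np.ndarray
) -> tuple[float, float]:
    """Z-scored group means against the pooled trial-rate distribution.

    Trial-wise rates of both rotation groups in the (modulation) window are
    pooled; each group mean is standardized by the pooled mean and SD.
    """
    pooled = np.concatenate([rates_high, rates_low])
    sd = pooled.std(ddof=1)
    if sd == 0:
        raise ValueError("zero pooled SD; z-scores undefined")
    mu = pooled.mean()
    return float((rates_high.mean() - mu) / sd), float((rates_low.mean() - mu) / sd)


def rotation_groups(
    trials: pd.DataFrame, conditions: Sequence[Condition]
) -> dict[str, np.ndarray]:
    """Trial ids of completed perturbed trials split by rotated-cue identity.

    Returns keys 'higher', 'lower', 'equal' (same-value pairs), and
    'none' (completed unperturbed double-cue trials).
    """
    lookup = condition_lookup(conditions)
    out: dict[str, list[int]] = {"higher": [], "lower": [], "equal": [], "none": []}
    for row in trials[trials["completed"].astype(bool)].itertuples(index=False):
        cond = lookup[row.condition_id]
        if not cond.is_double:
            continue
        out[cond.perturbed_target if cond.is_perturbed else "none"].append(
            row.trial_id
        )
    return {k: np.asarray(v) for k, v in out.items()}


def analyze_modulation(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    conditions: Sequence[Condition],
    neuron_id: str,
    *,
    include_equal_in_low: bool = False,
) -> ModulationResult:
    """Full per-neuron modulation analysis.

    Finds the modulation window from the pointwise higher-vs-lower rotation
    contrast, then computes Z-scores and MI in that window (or in the
    200-1000 ms window for unmodulated neurons), and classifies consistency
    against the single-cue responses.
    """
    groups = rotation_groups(trials, conditions)
    high_ids, low_ids = groups["higher"], groups["lower"]
    if include_equal_in_low:
        low_ids = np.concatenate([low_ids, groups["equal"]])
    centers, mat_high = trialwise_bin_rates(spikes, high_ids, neuron_id)
    _, mat_low = trialwise_bin_rates(spikes, low_ids, neuron_id)
    p = pointwise_rotation_test(mat_high, mat_low)
    window = find_modulation_window(centers, p)
    modulated = window is not None
    zwin = window if modulated else MODULATION_SEARCH_MS
    rh = windowed_rates(spikes, high_ids, zwin, neuron_id).to_numpy()
    rl = windowed_rates(spikes, low_ids, zwin, neuron_id).to_numpy()
    z_high, z_low = zscore_modulation(rh, rl)
    mi = modulation_index(float(rh.mean()), float(rl.mean()))
    consistency = (
        classify_consistency(spikes, trials, conditions, neuron_id, zwin)
        if modulated
        else "n/a"
    )
    return ModulationResult(neuron_id, modulated, window, z_high, z_low, mi, consistency)


def classify_consistency(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    conditions: Sequence[Condition],
    neuron_id: str,
    window: tuple[float, float],
) -> str:
    """Did lower-cue rotations pull responses toward the lower cue's single-cue level?

    For every value pair, the lower-cue-perturbed response should sit closer
    to the perturbed (lower-value) cue's single-cue response than the
    unperturbed double-cue response does.  Aggregated over pairs by the mean
    signed movement; 'consistent' if the net movement is toward the
    single-cue level.
    """
    lookup = condition_lookup(conditions)
    tr = trials[trials["completed"].astype(bool)]
    rates = windowed_rates(spikes, tr["trial_id"].to_numpy(), window, neuron_id)
    df = pd.DataFrame(
        {"condition_id": tr["condition_id"].to_numpy(), "rate": rates.to_numpy()}
    )
    means = df.groupby("condition_id")["rate"].mean()

    single_by_value: dict[int, list[float]] = {}
    for cid, m in means.items():
        cond = lookup[cid]
        if cond.is_single:
            single_by_value.setdefault(cond.single_cue.value, []).append(m)
    single_mean = {v: float(np.mean(ms)) for v, ms in single_by_value.items()}

    movements = []
    for cid, m in means.items():
        cond = lookup[cid]
        if cond.perturbed_target != "lower":
            continue
        unpert_id = Condition(cond.left_cue, cond.right_cue).condition_id
        if unpert_id not in means.index:
            continue
        target = single_mean.get(cond.lower_value)
        if target is None:
            continue
        baseline_dist = abs(means[unpert_id] - target)
        pert_dist = abs(m - target)
        movements.append(baseline_dist - pert_dist)
    if not movements:
        return "n/a"
    return "consistent" if float(np.mean(movements)) > 0 else "inconsistent"


def first_block_control(
    trials: pd.DataFrame,
    conditions: Sequence[Condition],
    rng: np.random.Generator | int,
    n: int = 50,
) -> pd.DataFrame:
    """Early-trials control: first ``n`` completed trials per block, balanced.

    Keeps the first ``n`` completed trials of every block, then randomly
    removes trials within each cue-combination stratum so the perturbed and
    unperturbed double-cue trial counts match.  Reproducible via seed.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    lookup = condition_lookup(conditions)
    kept = (
        trials[trials["completed"].astype(bool)]
        .sort_values("trial_id")
        .groupby("block_index", group_keys=False)
        .head(n)
    )

    def _pair_key(cid: str):
        cond = lookup[cid]
        if not cond.is_double:
            return None
        return (cond.left_cue.value, cond.right_cue.value)

    keys = kept["condition_id"].map(_pair_key)
    perturbed = kept["condition_id"].map(lambda c: lookup[c].is_perturbed)
    keep_ids: list[int] = list(kept.loc[keys.isna(), "trial_id"])
    for key in keys.dropna().unique():
        sel = kept[keys == key]
        pert = sel.loc[perturbed.loc[sel.index], "trial_id"].to_numpy()
        unpert = sel.loc[~perturbed.loc[sel.index], "trial_id"].to_numpy()
        m = min(len(pert), len(unpert))
        keep_ids.extend(rng.choice(pert, size=m, replace=False))
        keep_ids.extend(rng.choice(unpert, size=m, replace=False))
    return trials[trials["trial_id"].isin(keep_ids)].sort_values("trial_id")


def compare_rotation_conditions(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    conditions: Sequence[Condition],
    neuron_id: str,
    *,
    window: tuple[float, float] = MODEL_WINDOW,
) -> dict:
    """Mean contrasts between rotation groups and the no-perturbation group.

    Returns, for the given window, the trial means of the higher-rotated,
    lower-rotated, and unperturbed double-cue groups, plus two-tailed
    t-tests of higher vs lower and higher vs no perturbation.  Under
    winner-take-all coding the higher-vs-lower contrast is significant
    while higher-rotated vs unperturbed is null.
    """
    groups = rotation_groups(trials, conditions)
    out = {}
    samples = {}
    for key in ("higher", "lower", "none"):
        r = windowed_rates(spikes, groups[key], window, neuron_id).to_numpy()
        samples[key] = r
        out[f"mean_{key}"] = float(r.mean()) if r.size else float("nan")
    t_hl, p_hl = stats.ttest_ind(samples["higher"], samples["lower"])
    t_hn, p_hn = stats.ttest_ind(samples["higher"], samples["none"])
    out.update(
        diff_high_low=out["mean_higher"] - out["mean_lower"],
        p_high_low=float(p_hl),
        diff_high_none=out["mean_higher"] - out["mean_none"],
        p_high_none=float(p_hn),
    )
    return out
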