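"""Screening of simulated neurons for visual responsiveness and value tuning.

Mirrors the screening cascade applied to recorded units: a neuron is
visually responsive if its firing rate differs between the fixation period
and the cue period; a visually responsive neuron is value selective if its
150-550 ms responses differ across the five single-cue reward levels
(one-way ANOVA, alpha = 0.05); value-selective neurons are assigned
positive or negative tuning by the sign of the slope of firing rate on
value (FR = b0 + b1 * V).  Responses are then baseline-subtracted and
normalized to the preferred single-cue response (8 drops for positive
tuning, 0 drops for negative) so neurons can be averaged on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from attnorm.task_core import Condition, condition_lookup

__all__ = [
    "ScreeningResult",
    "windowed_rate",
    "windowed_rates",
    "test_visual_responsiveness",
    "test_value_selectivity",
    "classify_tuning",
    "normalize_responses",
    "analyze_double_cue",
    "screen_neuron",
    "screen_population",
]

ALPHA = 0.05
VALUE_WINDOW = (150.0, 550.0)  # ms after cue onset, value-selectivity window
CUE_WINDOW = (0.0, 1000.0)
FIXATION_WINDOW = (-2000.0, 0.0)
BASELINE_WINDOW = (-200.0, 0.0)
MODEL_WINDOW = (200.0, 1000.0)  # perturbation onset to cue offset
NORMALIZATION_EPS = 0.1  # spikes/s; smaller divisors are degenerate


class InsufficientDataError(ValueError):
    pass


class GroupingError(ValueError):
    pass


class DegenerateNormalizationError(ValueError):
    """Preferred-response minus baseline too small to normalize by."""


@dataclass
class ScreeningResult:
    neuron_id: str
    visually_responsive: bool
    visual_p: float
    value_selective: Optional[bool] = None
    selectivity_p: Optional[float] = None
    tuning: str = "none"  # positive | negative | none
    slope: Optional[float] = None
    slope_p: Optional[float] = None
    preferred_value: Optional[int] = None


def windowed_rate(spike_times_ms: np.ndarray, window: tuple[float, float]) -> float:
    """Firing rate (spikes/s) in the half-open window [start, end) ms."""
    start, end = window
    if end <= start:
        raise ValueError(f"empty or inverted window {window}")
    t = np.asarray(spike_times_ms)
    n = int(np.count_nonzero((t >= start) & (t < end)))
    return n / ((end - start) / 1000.0)


def windowed_rates(
    spikes: pd.DataFrame,
    trial_ids: Sequence[int],
    window: tuple[float, float],
    neuron_id: Optional[str] = None,
) -> pd.Series:
    """Trial-wise rates (spikes/s) in a window, indexed by trial_id.

    Trials without spikes in the window get rate 0.  ``spikes`` is the long
    table (neuron_id, trial_id, t_ms); times are ms relative to cue onset.
    """
    start, end = window
    if end <= start:
        raise ValueError(f"empty or inverted window {window}")
    sel = spikes
    if neuron_id is not None:
        sel = sel[sel["neuron_id"] == neuron_id]
    sel = sel[(sel["t_ms"] >= start) & (sel["t_ms"] < end)]
    counts = sel.groupby("trial_id").size()
    rates = counts.reindex(trial_ids, fill_value=0) / ((end - start) / 1000.0)
    rates.name = "rate"
    return rates.astype(float)


def _completed(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["completed"].astype(bool)]


def _single_cue_table(
    trials: pd.DataFrame, conditions: Sequence[Condition]
) -> pd.DataFrame:
    """Completed single-cue trials with a 'value' column (sides pooled)."""
    lookup = condition_lookup(conditions)
    t = _completed(trials)
    rows = []
    for row in t.itertuples(index=False):
        cond = lookup[row.condition_id]
        if cond.is_single:
            rows.append({"trial_id": row.trial_id, "value": cond.single_cue.value})
    return pd.DataFrame(rows, columns=["trial_id", "value"])


def test_visual_responsiveness(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    neuron_id: str,
    *,
    paired: bool = True,
    welch: bool = False,
) -> tuple[bool, float]:
    """Compare fixation-period and cue-period rates across completed trials.

    Paired two-tailed t-test by default (both windows come from the same
    trials); set ``paired=False`` for an independent-samples test and
    ``welch=True`` for unequal variances in that case.
    """
    tr = _completed(trials)
    if len(tr) < 2:
        raise InsufficientDataError("need >= 2 completed trials")
    ids = tr["trial_id"].to_numpy()
    pre = windowed_rates(spikes, ids, FIXATION_WINDOW, neuron_id).to_numpy()
    cue = windowed_rates(spikes, ids, CUE_WINDOW, neuron_id).to_numpy()
    if paired:
        diff = cue - pre
        if np.allclose(diff, diff[0]):
            # zero-variance differences: degenerate, not evidence of a response
            return False, 1.0
        t, p = stats.ttest_rel(cue, pre)
    else:
        t, p = stats.ttest_ind(cue, pre, equal_var=not welch)
    return bool(p < ALPHA), float(p)


def test_value_selectivity(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    conditions: Sequence[Condition],
    neuron_id: str,
) -> tuple[bool, float]:
    """One-way ANOVA of 150-550 ms rates across single-cue reward levels."""
    singles = _single_cue_table(trials, conditions)
    values = sorted({c.single_cue.value for c in conditions if c.is_single})
    present = set(singles["value"].unique())
    missing = [v for v in values if v not in present]
    if missing:
        raise GroupingError(f"no completed single-cue trials for values {missing}")
    rates = windowed_rates(
        spikes, singles["trial_id"].to_numpy(), VALUE_WINDOW, neuron_id
    )
    groups = [
        rates.loc[singles.loc[singles["value"] == v, "trial_id"]].to_numpy()
        for v in values
    ]
    if np.ptp(np.concatenate(groups)) == 0:
        # all rates identical: no variance anywhere, trivially non-selective
        return False, 1.0
    f, p = stats.f_oneway(*groups)
    return bool(p < ALPHA), float(p)


def classify_tuning(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    conditions: Sequence[Condition],
    neuron_id: str,
) -> tuple[str, float, float]:
    """OLS of single-cue 150-550 ms rates on value; sign of the slope tunes.

    Returns ``(tuning, slope, p)`` with tuning 'positive' or 'negative'.
    """
    singles = _single_cue_table(trials, conditions)
    rates = windowed_rates(
        spikes, singles["trial_id"].to_numpy(), VALUE_WINDOW, neuron_id
    )
    res = stats.linregress(singles["value"].to_numpy(), rates.to_numpy())
    tuning = "positive" if res.slope >= 0 else "negative"
    return tuning, float(res.slope), float(res.pvalue)


def screen_neuron(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    conditions: Sequence[Condition],
    neuron_id: str,
) -> ScreeningResult:
    """Run the full screening cascade on one neuron."""
    responsive, p_vis = test_visual_responsiveness(spikes, trials, neuron_id)
    result = ScreeningResult(neuron_id, responsive, p_vis)
    if not responsive:
        return result
    selective, p_sel = test_value_selectivity(spikes, trials, conditions, neuron_id)
    result.value_selective, result.selectivity_p = selective, p_sel
    if not selective:
        return result
    tuning, slope, p_slope = classify_tuning(spikes, trials, conditions, neuron_id)
    result.tuning, result.slope, result.slope_p = tuning, slope, p_slope
    values = sorted({c.single_cue.value for c in conditions if c.is_single})
    result.preferred_value = max(values) if tuning == "positive" else min(values)
    return result


def screen_population(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    conditions: Sequence[Condition],
    neuron_ids: Sequence[str],
) -> pd.DataFrame:
    """Screen every neuron; one row per neuron (``screening.csv`` schema)."""
    rows = []
    for nid in neuron_ids:
        r = screen_neuron(spikes, trials, conditions, nid)
        rows.append(
            {
                "neuron_id": r.neuron_id,
                "visually_responsive": r.visually_responsive,
                "visual_p": r.visual_p,
                "value_selective": r.value_selective,
                "selectivity_p": r.selectivity_p,
                "tuning": r.tuning,
                "slope": r.slope,
                "slope_p": r.slope_p,
                "preferred_value": r.preferred_value,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Normalization and double-cue analyses


def normalization_factors(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    conditions: Sequence[Condition],
    neuron_id: str,
    preferred_value: int,
    *,
    window: tuple[float, float] = MODEL_WINDOW,
    eps: float = NORMALIZATION_EPS,
) -> tuple[float, float]:
    """Baseline (200 ms pre-cue mean) and normalization divisor for a neuron.

    The divisor is the preferred single-cue mean minus baseline in the given
    window; magnitudes below ``eps`` raise DegenerateNormalizationError.
    """
    lookup = condition_lookup(conditions)
    tr = _completed(trials)
    ids = tr["trial_id"].to_numpy()
    baseline = float(windowed_rates(spikes, ids, BASELINE_WINDOW, neuron_id).mean())
    pref_ids = [
        row.trial_id
        for row in tr.itertuples(index=False)
        if lookup[row.condition_id].is_single
        and lookup[row.condition_id].single_cue.value == preferred_value
    ]
    pref_mean = float(windowed_rates(spikes, pref_ids, window, neuron_id).mean())
    divisor = pref_mean - baseline
    if abs(divisor) < eps:
        raise DegenerateNormalizationError(
            f"{neuron_id}: |preferred - baseline| = {abs(divisor):.3g} < {eps}"
        )
    return baseline, divisor


def normalize_responses(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    conditions: Sequence[Condition],
    neuron_id: str,
    preferred_value: int,
    *,
    window: tuple[float, float] = MODEL_WINDOW,
    eps: float = NORMALIZATION_EPS,
) -> pd.DataFrame:
    """Per-condition normalized mean responses of one neuron.

    Normalized response = (condition mean - baseline) / (preferred
    single-cue mean - baseline), so the preferred condition maps to exactly
    1 and baseline-level activity to 0.  Returns the
    ``normalized_responses.csv`` schema plus a trial-wise column is *not*
    included here; see :func:`normalized_trial_rates` for trial-level data.
    """
    baseline, divisor = normalization_factors(
        spikes, trials, conditions, neuron_id, preferred_value,
        window=window, eps=eps,
    )
    tr = _completed(trials)
    rates = windowed_rates(spikes, tr["trial_id"].to_numpy(), window, neuron_id)
    df = pd.DataFrame(
        {"condition_id": tr["condition_id"].to_numpy(), "rate": rates.to_numpy()}
    )
    agg = df.groupby("condition_id")["rate"].agg(["mean", "count"]).reset_index()
    agg["normalized_mean"] = (agg["mean"] - baseline) / divisor
    agg.insert(0, "neuron_id", neuron_id)
    return agg.rename(columns={"count": "n_trials"})[
        ["neuron_id", "condition_id", "normalized_mean", "n_trials"]
    ]


def normalized_trial_rates(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    conditions: Sequence[Condition],
    neuron_id: str,
    preferred_value: int,
    *,
    window: tuple[float, float] = MODEL_WINDOW,
    eps: float = NORMALIZATION_EPS,
) -> pd.DataFrame:
    """Trial-wise normalized rates (columns trial_id, condition_id, rate_norm)."""
    baseline, divisor = normalization_factors(
        spikes, trials, conditions, neuron_id, preferred_value,
        window=window, eps=eps,
    )
    tr = _completed(trials)
    rates = windowed_rates(spikes, tr["trial_id"].to_numpy(), window, neuron_id)
    return pd.DataFrame(
        {
            "trial_id": tr["trial_id"].to_numpy(),
            "condition_id": tr["condition_id"].to_numpy(),
            "rate_norm": (rates.to_numpy() - baseline) / divisor,
        }
    )


def analyze_double_cue(
    trial_rates: pd.DataFrame,
    conditions: Sequence[Condition],
) -> dict:
    """Winner-take-all signature tests on single- vs double-cue responses.

    ``trial_rates`` has columns condition_id, rate_norm (trial-wise,
    possibly pooled over neurons).  Double-cue (unperturbed) trials are
    grouped by the higher of the two values and compared with single-cue
    trials by a two-way ANOVA (factors: value, cue count); separately, the
    double-cue responses are regressed jointly on the higher and the lower
    value.  Under winner-take-all coding only the higher value should carry
    a significant coefficient and the cue-count factor should be null.
    """
    lookup = condition_lookup(conditions)
    rows = []
    for row in trial_rates.itertuples(index=False):
        cond = lookup[row.condition_id]
        if cond.is_perturbed:
            continue
        rows.append(
            {
                "rate_norm": row.rate_norm,
                "value": cond.higher_value,
                "lower": cond.lower_value if cond.is_double else np.nan,
                "n_cues": 2 if cond.is_double else 1,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty or df["n_cues"].nunique() < 2:
        raise GroupingError("need both single- and double-cue unperturbed trials")
    cells = df.groupby(["value", "n_cues"]).size()
    values = df["value"].unique()
    for v in values:
        for k in (1, 2):
            if (v, k) not in cells.index:
                raise GroupingError(f"empty cell value={v}, n_cues={k}")

    model = ols("rate_norm ~ C(value) + C(n_cues)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    dd = df[df["n_cues"] == 2]
    X = sm.add_constant(dd[["value", "lower"]].rename(columns={"value": "higher"}))
    reg = sm.OLS(dd["rate_norm"], X).fit()

    return {
        "anova": anova,
        "anova_p_value": float(anova.loc["C(value)", "PR(>F)"]),
        "anova_p_cue_count": float(anova.loc["C(n_cues)", "PR(>F)"]),
        "higher_coef": float(reg.params["higher"]),
        "higher_p": float(reg.pvalues["higher"]),
        "lower_coef": float(reg.params["lower"]),
        "lower_p": float(reg.pvalues["lower"]),
        "group_means": df.groupby(["n_cues", "value"])["rate_norm"].mean(),
    }
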