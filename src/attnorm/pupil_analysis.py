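"""Pupillometric readout of reward expectation.

Pupil size tracks the value of the attended cue: the baseline is the mean
pupil size 400-900 ms after fixation acquisition, and the response is the
baseline-subtracted mean in the 1 s after cue offset.  Responses in the
single-cue conditions are regressed on reward size (PS = b0 + b1 * V); a
two-way ANOVA (factors: reward size, number of cues, double-cue trials
grouped by the higher value) with Tukey post-hocs tests whether adding a
second, lower-value cue changes the pupil response — under winner-take-all
attention it should not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from attnorm.task_core import Condition, condition_lookup

__all__ = [
    "PupilResponse",
    "PupilRegressionResult",
    "extract_pupil_response",
    "extract_all_responses",
    "regress_pupil_on_value",
    "compare_single_vs_double",
]

BASELINE_WINDOW_MS = (400.0, 900.0)  # after fixation acquisition
RESPONSE_DURATION_MS = 1000.0  # after cue offset


class CoverageError(ValueError):
    """A required pupil window has no samples."""


@dataclass
class PupilResponse:
    trial_id: int
    baseline: float
    response: float  # baseline-subtracted


@dataclass
class PupilRegressionResult:
    b0: float
    b1: float
    p_b0: float
    p_b1: float
    n_trials: int


def extract_pupil_response(
    t_ms: np.ndarray,
    pupil: np.ndarray,
    trial_id: int,
    t_cue_off_rel_fix_ms: float,
) -> PupilResponse:
    """Windowed baseline and baseline-subtracted post-cue-offset response.

    ``t_ms`` is relative to fixation acquisition; ``t_cue_off_rel_fix_ms``
    locates the cue offset on the same axis.
    """
    t = np.asarray(t_ms, dtype=float)
    y = np.asarray(pupil, dtype=float)
    base_mask = (t >= BASELINE_WINDOW_MS[0]) & (t < BASELINE_WINDOW_MS[1])
    resp_mask = (t >= t_cue_off_rel_fix_ms) & (
        t < t_cue_off_rel_fix_ms + RESPONSE_DURATION_MS
    )
    if not base_mask.any():
        raise CoverageError(f"trial {trial_id}: no samples in baseline window")
    if not resp_mask.any():
        raise CoverageError(f"trial {trial_id}: no samples in response window")
    baseline = float(y[base_mask].mean())
    return PupilResponse(trial_id, baseline, float(y[resp_mask].mean() - baseline))


def extract_all_responses(
    pupil: pd.DataFrame, trials: pd.DataFrame
) -> pd.DataFrame:
    """Per-trial pupil responses (``pupil_responses.csv`` schema).

    ``pupil`` is the long table (trial_id, t_ms, pupil_size) with t_ms
    relative to fixation onset; incomplete trials are skipped.
    """
    offsets = (
        trials.set_index("trial_id")
        .eval("t_cue_off_ms - t_fixation_on_ms")
        .to_dict()
    )
    completed = set(
        trials.loc[trials["completed"].astype(bool), "trial_id"].tolist()
    )
    rows = []
    for tid, g in pupil.groupby("trial_id"):
        if tid not in completed:
            continue
        r = extract_pupil_response(
            g["t_ms"].to_numpy(), g["pupil_size"].to_numpy(), tid, offsets[tid]
        )
        rows.append({"trial_id": tid, "baseline": r.baseline, "response": r.response})
    return pd.DataFrame(rows)


def _with_condition_values(
    responses: pd.DataFrame, trials: pd.DataFrame, conditions: Sequence[Condition]
) -> pd.DataFrame:
    lookup = condition_lookup(conditions)
    cid = trials.set_index("trial_id")["condition_id"]
    df = responses.copy()
    df["condition_id"] = df["trial_id"].map(cid)
    conds = df["condition_id"].map(lookup.get)
    df["is_single"] = [c.is_single for c in conds]
    df["is_perturbed"] = [c.is_perturbed for c in conds]
    df["value"] = [c.higher_value for c in conds]
    return df


def regress_pupil_on_value(
    responses: pd.DataFrame,
    trials: pd.DataFrame,
    conditions: Sequence[Condition],
) -> PupilRegressionResult:
    """OLS of single-cue pupil responses on reward size (drops)."""
    df = _with_condition_values(responses, trials, conditions)
    df = df[df["is_single"]]
    if df["value"].nunique() < 2:
        raise ValueError("need >= 2 distinct reward values for the regression")
    X = sm.add_constant(df["value"].astype(float))
    fit = sm.OLS(df["response"].astype(float), X).fit()
    return PupilRegressionResult(
        b0=float(fit.params["const"]),
        b1=float(fit.params["value"]),
        p_b0=float(fit.pvalues["const"]),
        p_b1=float(fit.pvalues["value"]),
        n_trials=int(len(df)),
    )


def compare_single_vs_double(
    responses: pd.DataFrame,
    trials: pd.DataFrame,
    conditions: Sequence[Condition],
) -> dict:
    """Two-way ANOVA (reward size x cue count) with Tukey post-hocs.

    Unperturbed double-cue trials are grouped by the higher of the two
    values.  Post-hoc Tukey comparisons run over value levels within each
    cue-count stratum.
    """
    df = _with_condition_values(responses, trials, conditions)
    df = df[~df["is_perturbed"]].copy()
    df["n_cues"] = np.where(df["is_single"], 1, 2)
    cells = df.groupby(["value", "n_cues"]).size()
    for v in sorted(df["value"].unique()):
        for k in (1, 2):
            if (v, k) not in cells.index:
                raise ValueError(f"empty cell: value={v}, n_cues={k}")
    model = ols("response ~ C(value) + C(n_cues)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    posthoc = {}
    for k, sub in df.groupby("n_cues"):
        tk = pairwise_tukeyhsd(sub["response"], sub["value"])
        posthoc[int(k)] = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    return {
        "anova": anova,
        "p_value_factor": float(anova.loc["C(value)", "PR(>F)"]),
        "p_cue_count_factor": float(anova.loc["C(n_cues)", "PR(>F)"]),
        "tukey_by_cue_count": posthoc,
        "n_trials": int(len(df)),
    }
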