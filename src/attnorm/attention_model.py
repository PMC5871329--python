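"""Normalization model of attention shift and its reduced variants.

The response of a value-coding neuron to a pair of cues is modeled as a
weighted average of its responses to each cue presented alone,

    R = (1 - a) * Rh + a * Rl + b,

where ``Rh`` and ``Rl`` are the (normalized) single-cue responses to the
higher- and lower-value cue and ``0 <= a <= 1`` describes how attention is
distributed between the two cues.  When the visual perturbation is applied
to the lower-value cue, the attention shift toward it is a sigmoid function
of the response difference,

    a = d / (1 + exp(c * |Rh - Rl|)),    0 <= c <= 100,  0 <= d <= 2,

so the full model has three free parameters (b, c, d).  Two reduced models
keep ``a`` constant in the value difference: Model 1 shares one ``a`` across
all neurons of a tuning group (with a per-neuron offset b), Model 2 fits
``a`` per neuron.  Models are fitted by least squares on one half of the
trials and evaluated (RSS, R-squared, AICc) on the held-out half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc, ttest_rel

__all__ = [
    "FullModelParams",
    "FitEvaluation",
    "attention_weight",
    "predict_full",
    "predict_model1",
    "predict_model2",
    "split_half",
    "fit_full",
    "fit_model2",
    "fit_model1",
    "evaluate_fit",
    "compare_models",
]

C_BOUNDS = (0.0, 100.0)
D_BOUNDS = (0.0, 2.0)
B_BOUNDS = (-2.0, 2.0)  # offset in normalized response units


@dataclass(frozen=True)
class FullModelParams:
    """Parameters of the full sigmoid-weight model."""

    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not C_BOUNDS[0] <= self.c <= C_BOUNDS[1]:
            raise ValueError(f"c out of bounds {C_BOUNDS}: {self.c}")
        if not D_BOUNDS[0] <= self.d <= D_BOUNDS[1]:
            raise ValueError(f"d out of bounds {D_BOUNDS}: {self.d}")


def attention_weight(delta, c: float, d: float):
    """Attention weight on the lower-value cue after a perturbation of it.

    ``a = d / (1 + exp(c * |delta|))`` clipped into [0, 1]; ``delta`` is the
    difference between the higher and lower single-cue responses (or, in the
    generative process, the normalized value difference).
    """
    a = d / (1.0 + np.exp(c * np.abs(np.asarray(delta, dtype=float))))
    return np.clip(a, 0.0, 1.0)


def predict_full(rh, rl, params: FullModelParams, perturbed_target: str = "lower"):
    """Predicted double-cue response under the full model.

    For lower-cue perturbations the weight follows the sigmoid of |Rh - Rl|;
    for higher-cue perturbations the perturbation does not displace attention
    from the already-attended cue, so a = 0 and R = Rh + b.
    """
    rh = np.asarray(rh, dtype=float)
    rl = np.asarray(rl, dtype=float)
    if perturbed_target == "lower":
        a = attention_weight(rh - rl, params.c, params.d)
    elif perturbed_target == "higher":
        a = np.zeros_like(rh)
    else:
        raise ValueError(f"perturbed_target must be lower|higher: {perturbed_target}")
    return (1.0 - a) * rh + a * rl + params.b


def _predict_constant_a(rh, rl, a: float, b: float):
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"a out of [0, 1]: {a}")
    rh = np.asarray(rh, dtype=float)
    rl = np.asarray(rl, dtype=float)
    return (1.0 - a) * rh + a * rl + b


def predict_model1(rh, rl, a_shared: float, b: float):
    """Reduced model: one attention weight shared across all neurons."""
    return _predict_constant_a(rh, rl, a_shared, b)


def predict_model2(rh, rl, a_neuron: float, b: float):
    """Reduced model: constant attention weight, fitted per neuron."""
    return _predict_constant_a(rh, rl, a_neuron, b)


# ---------------------------------------------------------------------------
# Split-half cross-validation


def split_half(
    trials: pd.DataFrame, rng: np.random.Generator | int
) -> pd.Series:
    """Randomly split completed trials into halves, stratified by condition.

    Returns a Series indexed like ``trials`` with values 'train'/'test'.
    Each condition contributes trials to both halves (odd counts put the
    extra trial in train; a single-trial condition goes to train with a
    warning).  Reproducible given the seed.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    labels = pd.Series("train", index=trials.index, dtype=object)
    for cond, idx in trials.groupby("condition_id").groups.items():
        idx = np.asarray(idx)
        perm = rng.permutation(len(idx))
        n_test = len(idx) // 2
        if len(idx) < 2:
            warnings.warn(
                f"condition {cond} has a single trial; assigned to train",
                stacklevel=2,
            )
        labels.loc[idx[perm[:n_test]]] = "test"
    return labels


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FullFitResult:
    params: FullModelParams
    rss: float
    identifiable: bool = True


def fit_full(
    rh: np.ndarray,
    rl: np.ndarray,
    r_obs: np.ndarray,
    *,
    rh_anchor: Optional[np.ndarray] = None,
    r_obs_anchor: Optional[np.ndarray] = None,
    n_starts: int = 16,
    rng: Optional[np.random.Generator | int] = None,
) -> FullFitResult:
    """Least-squares fit of (b, c, d) to lower-cue-perturbed condition means.

    The objective is non-convex in c, so a bounded trust-region fit is run
    from Latin-hypercube starting points and the best solution kept; among
    solutions with (numerically) tied RSS the smallest-d one is returned,
    since (c, d) trade off along a ridge when the data show little or no
    shift and parsimony favors the least-shift explanation.  If all
    |Rh - Rl| coincide the sigmoid steepness c is unidentifiable and the
    result carries ``identifiable=False``.

    ``rh_anchor``/``r_obs_anchor`` optionally add condition means whose
    model prediction is ``Rh + b`` regardless of (c, d) — higher-cue-
    perturbed or unperturbed double-cue conditions — which pin the offset b
    without informing the sigmoid.
    """
    rh = np.asarray(rh, dtype=float)
    rl = np.asarray(rl, dtype=float)
    r_obs = np.asarray(r_obs, dtype=float)
    if rh.shape != rl.shape or rh.shape != r_obs.shape:
        raise ValueError("rh, rl, r_obs must have identical shapes")
    if (rh_anchor is None) != (r_obs_anchor is None):
        raise ValueError("rh_anchor and r_obs_anchor must be given together")
    deltas = np.round(np.abs(rh - rl), 12)
    identifiable = np.unique(deltas).size > 1
    rh_a = np.asarray(rh_anchor, dtype=float) if rh_anchor is not None else np.empty(0)
    y_a = (
        np.asarray(r_obs_anchor, dtype=float)
        if r_obs_anchor is not None
        else np.empty(0)
    )

    def residuals(theta):
        b, c, d = theta
        a = attention_weight(rh - rl, c, d)
        res = (1.0 - a) * rh + a * rl + b - r_obs
        if rh_a.size:
            res = np.concatenate([res, rh_a + b - y_a])
        return res

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sampler = qmc.LatinHypercube(d=3, seed=rng)
    lo = np.array([B_BOUNDS[0], C_BOUNDS[0], D_BOUNDS[0]])
    hi = np.array([B_BOUNDS[1], C_BOUNDS[1], D_BOUNDS[1]])
    # bias starting c toward the identifiable low range, where the sigmoid
    # actually varies over |Rh - Rl| of order one
    starts = qmc.scale(sampler.random(n_starts), lo, [hi[0], 30.0, hi[2]])
    # deterministic coarse-grid starts guard against basins the random
    # starts miss (grid-then-polish); b starts at the mean residual of the
    # pure winner-take-all prediction
    b0 = float(np.clip(np.mean(r_obs - rh), lo[0], hi[0]))
    coarse = [
        (b0, c0, d0)
        for c0 in (0.0, 2.0, 6.0, 15.0, 40.0, 90.0)
        for d0 in (0.1, 0.7, 1.3, 1.9)
    ]
    starts = np.vstack([starts, coarse])
    solutions = []
    for x0 in starts:
        sol = optimize.least_squares(
            residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12
        )
        solutions.append((float(np.sum(sol.fun**2)), sol.x))
    best_rss = min(s[0] for s in solutions)
    tied = [x for r, x in solutions if r <= best_rss * (1 + 1e-9) + 1e-12]
    b, c, d = min(tied, key=lambda x: x[2])
    rss = float(np.sum(residuals((b, c, d)) ** 2))
    return FullFitResult(FullModelParams(float(b), float(c), float(d)), rss, identifiable)


def fit_model2(rh, rl, r_obs) -> tuple[float, float, float]:
    """Per-neuron constant-weight fit; returns ``(a, b, rss)``.

    With b profiled out the problem is a 1-D convex quadratic in a, so the
    box-constrained optimum is the unconstrained optimum clamped to [0, 1].
    """
    rh = np.asarray(rh, dtype=float)
    rl = np.asarray(rl, dtype=float)
    y = np.asarray(r_obs, dtype=float) - rh
    x = rl - rh
    xc = x - x.mean()
    yc = y - y.mean()
    denom = float(np.sum(xc**2))
    a = float(np.sum(xc * yc) / denom) if denom > 0 else 0.0
    a = min(max(a, 0.0), 1.0)
    b = float(np.mean(y - a * x))
    rss = float(np.sum((y - a * x - b) ** 2))
    return a, b, rss


def fit_model1(
    groups: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
) -> tuple[float, list[float], float]:
    """Group-level constant-weight fit: one shared a, per-neuron offsets b.

    ``groups`` lists ``(rh, rl, r_obs)`` per neuron.  Given a, each b_i has
    the closed form mean residual, so the profiled objective is again convex
    quadratic in a and solved in closed form (clamped to [0, 1]).
    """
    num = 0.0
    den = 0.0
    xs, ys = [], []
    for rh, rl, r_obs in groups:
        rh = np.asarray(rh, dtype=float)
        x = np.asarray(rl, dtype=float) - rh
        y = np.asarray(r_obs, dtype=float) - rh
        xc = x - x.mean()
        yc = y - y.mean()
        num += float(np.sum(xc * yc))
        den += float(np.sum(xc**2))
        xs.append(x)
        ys.append(y)
    a = min(max(num / den, 0.0), 1.0) if den > 0 else 0.0
    bs = [float(np.mean(y - a * x)) for x, y in zip(xs, ys)]
    rss = float(
        sum(np.sum((y - a * x - b) ** 2) for x, y, b in zip(xs, ys, bs))
    )
    return a, bs, rss


# ---------------------------------------------------------------------------
# Evaluation and comparison


@dataclass
class FitEvaluation:
    rss: float
    r2: float
    aicc: float
    n: int
    k: float
    aicc_defined: bool = True


def evaluate_fit(r_obs_test, r_pred, k: float) -> FitEvaluation:
    """Out-of-sample RSS, R-squared, and small-sample-corrected AIC.

    ``R^2 = 1 - RSS/TSS`` with TSS about the test mean (may be negative out
    of sample) and ``AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)`` with n the
    number of test condition means and k the parameter count attributed to
    the neuron.  AICc is undefined (NaN, flagged) when n <= k + 1.
    """
    y = np.asarray(r_obs_test, dtype=float)
    yhat = np.asarray(r_pred, dtype=float)
    if y.size == 0:
        raise ValueError("empty test set")
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -np.inf)
    n = y.size
    if n <= k + 1:
        return FitEvaluation(rss, r2, float("nan"), n, k, aicc_defined=False)
    aicc = n * np.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    return FitEvaluation(rss, r2, float(aicc), n, k)


def compare_models(fits: pd.DataFrame) -> dict:
    """Compare models fitted to the same neurons on identical splits.

    ``fits`` must have columns neuron_id, model, test_rss, test_r2,
    test_aicc, split_seed.  Returns winner counts (lowest AICc), per-model
    mean R-squared/AICc, and paired two-tailed t-tests of the full model
    against each reduced model on AICc and R-squared.
    """
    required = {"neuron_id", "model", "test_rss", "test_r2", "test_aicc", "split_seed"}
    missing = required - set(fits.columns)
    if missing:
        raise ValueError(f"fits table missing columns: {sorted(missing)}")
    seeds = fits.pivot_table(
        index="neuron_id", columns="model", values="split_seed", aggfunc="first"
    )
    if seeds.nunique(axis=1).max() > 1:
        raise ValueError("models were evaluated on mismatched splits")
    aicc = fits.pivot(index="neuron_id", columns="model", values="test_aicc")
    r2 = fits.pivot(index="neuron_id", columns="model", values="test_r2")
    if aicc.isna().any().any():
        raise ValueError("every neuron must be fitted under all models")
    winners = aicc.idxmin(axis=1).value_counts().to_dict()
    result = {
        "n_neurons": int(aicc.shape[0]),
        "winner_counts_aicc": {m: int(winners.get(m, 0)) for m in aicc.columns},
        "mean_r2": r2.mean().to_dict(),
        "mean_aicc": aicc.mean().to_dict(),
        "paired_tests": {},
    }
    for other in aicc.columns:
        if other == "full":
            continue
        entry = {
            "mean_delta_aicc": float((aicc["full"] - aicc[other]).mean()),
            "mean_delta_r2": float((r2["full"] - r2[other]).mean()),
        }
        if aicc.shape[0] >= 2:
            t_a, p_a = ttest_rel(aicc["full"], aicc[other])
            t_r, p_r = ttest_rel(r2["full"], r2[other])
            entry.update(
                aicc_t=float(t_a), aicc_p=float(p_a),
                r2_t=float(t_r), r2_p=float(p_r),
            )
        result["paired_tests"][f"full_vs_{other}"] = entry
    return result
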