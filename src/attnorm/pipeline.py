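"""End-to-end orchestration: simulate -> screen -> perturb -> fit -> report.

Each stage reads and writes tidy CSV files in a run directory and appends a
manifest entry (config hash, file checksums) so that a rerun with the same
configuration is verifiably identical for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

import attnorm
from attnorm import attention_model as am
from attnorm import neuron_screening as ns
from attnorm import perturbation_analysis as pa
from attnorm import pupil_analysis as pu
from attnorm.synthetic_session import (
    SessionConfig,
    SessionData,
    default_neuron_population,
    simulate_session,
)
from attnorm.task_core import Condition, condition_lookup

__all__ = [
    "RunConfig",
    "DependencyError",
    "FormatError",
    "run_stage",
    "run_all",
    "make_fixture",
    "build_condition_means",
    "fit_neuron_models",
    "fit_population_models",
]

STAGES = ("simulate", "screen", "perturb", "fit", "report")

SPIKES_COLUMNS = ("neuron_id", "trial_id", "t_ms")
TRIALS_COLUMNS = (
    "trial_id",
    "block_index",
    "condition_id",
    "completed",
    "rewarded_side",
    "reward_drops",
    "t_fixation_on_ms",
    "t_cue_on_ms",
    "t_cue_off_ms",
    "t_reward_ms",
)


class ConfigError(ValueError):
    pass


class DependencyError(FileNotFoundError):
    pass


class FormatError(ValueError):
    pass


@dataclass
class RunConfig:
    """Run-level configuration; every seed used downstream is recorded here."""

    seed_simulate: int = 1
    seed_split: int = 2
    seed_balance: int = 3
    n_blocks: int = 9
    n_positive: int = 2
    n_negative: int = 2
    n_untuned: int = 1
    n_nonvisual: int = 1
    incomplete_rate: float = 0.0
    include_pupil: bool = True
    outdir: str = "run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        for key in raw:
            if key not in known:
                raise ConfigError(f"unknown config field: {key!r}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ConfigError("invalid config field n_blocks: must be >= 1")
        if not 0.0 <= self.incomplete_rate < 1.0:
            raise ConfigError("invalid config field incomplete_rate: must be in [0, 1)")
        for name in ("n_positive", "n_negative", "n_untuned", "n_nonvisual"):
            if getattr(self, name) < 0:
                raise ConfigError(f"invalid config field {name}: must be >= 0")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def session_config(self) -> SessionConfig:
        neurons = default_neuron_population(
            np.random.default_rng(self.seed_simulate + 1),
            self.n_positive,
            self.n_negative,
            self.n_untuned,
            self.n_nonvisual,
        )
        return SessionConfig(
            n_blocks=self.n_blocks,
            neurons=neurons,
            incomplete_rate=self.incomplete_rate,
            include_pupil=self.include_pupil,
        )


# ---------------------------------------------------------------------------
# Manifest


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _append_manifest(outdir: Path, stage: str, config: RunConfig, files: Sequence[Path]) -> None:
    manifest_path = outdir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {"stages": {}}
    )
    manifest["config_hash"] = config.hash()
    manifest["package_version"] = attnorm.__version__
    manifest["stages"][stage] = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": {p.name: _checksum(p) for p in files},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))


def _require(path: Path) -> Path:
    if not path.exists():
        raise DependencyError(f"missing upstream file: {path}")
    return path


def _check_columns(df: pd.DataFrame, required: Sequence[str], name: str) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{name}: missing column {col!r}")


# ---------------------------------------------------------------------------
# Condition means and model fitting


def pair_bucket(cond: Condition) -> tuple:
    """Grouping key for condition means: single value or (vh, vl) pair bucket.

    Same-value perturbed pairs land in the lower-perturbed bucket (the
    model treats them with weight a = d/2; their prediction is Rh + b
    regardless since Rh = Rl).
    """
    if cond.is_single:
        return ("single", cond.single_cue.value)
    pair = (cond.higher_value, cond.lower_value)
    if not cond.is_perturbed:
        return ("unpert", pair)
    target = cond.perturbed_target
    return ("lower_pert" if target in ("lower", "equal") else "higher_pert", pair)


def build_condition_means(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    conditions: Sequence[Condition],
    neuron_id: str,
    preferred_value: int,
    split_seed: int,
    *,
    window: tuple[float, float] = ns.MODEL_WINDOW,
) -> pd.DataFrame:
    """Per-value-pair normalized condition means, split into train/test halves.

    Sides are pooled: a pair is identified by (higher value, lower value).
    Normalization factors (baseline, preferred-response divisor) come from
    all completed trials; the split stratifies trials by condition.  Columns:
    neuron_id, vh, vl, split, rh, rl (single-cue means), r_lower_pert,
    r_higher_pert, r_unpert and their trial counts.  Same-value pairs carry
    their perturbed conditions under r_lower_pert.
    """
    lookup = condition_lookup(conditions)
    trial_rates = ns.normalized_trial_rates(
        spikes, trials, conditions, neuron_id, preferred_value, window=window
    )
    completed = trials[trials["completed"].astype(bool)].reset_index(drop=True)
    labels = am.split_half(completed, split_seed)
    split_of = dict(zip(completed["trial_id"], labels))
    trial_rates["split"] = trial_rates["trial_id"].map(split_of)
    trial_rates["bucket"] = trial_rates["condition_id"].map(
        lambda cid: pair_bucket(lookup[cid])
    )
    values = sorted({c.single_cue.value for c in conditions if c.is_single})
    pairs = [(vh, vl) for vh in values for vl in values if vh >= vl]

    rows = []
    for split in ("train", "test"):
        sub = trial_rates[trial_rates["split"] == split]
        means = sub.groupby("bucket")["rate_norm"].agg(["mean", "count"])

        def _get(bucket):
            if bucket in means.index:
                m = means.loc[[bucket]]
                return float(m["mean"].iloc[0]), int(m["count"].iloc[0])
            return float("nan"), 0

        single = {v: _get(("single", v)) for v in values}
        for vh, vl in pairs:
            low, n_low = _get(("lower_pert", (vh, vl)))
            high, n_high = _get(("higher_pert", (vh, vl)))
            unp, n_unp = _get(("unpert", (vh, vl)))
            rows.append(
                {
                    "neuron_id": neuron_id,
                    "vh": vh,
                    "vl": vl,
                    "split": split,
                    "rh": single[vh][0],
                    "rl": single[vl][0],
                    "r_lower_pert": low,
                    "n_lower_pert": n_low,
                    "r_higher_pert": high,
                    "n_higher_pert": n_high,
                    "r_unpert": unp,
                    "n_unpert": n_unp,
                }
            )
    return pd.DataFrame(rows)


def _fit_arrays(cm: pd.DataFrame, split: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sub = cm[
        (cm["split"] == split)
        & np.isfinite(cm["rh"])
        & np.isfinite(cm["rl"])
        & np.isfinite(cm["r_lower_pert"])
    ]
    return (
        sub["rh"].to_numpy(),
        sub["rl"].to_numpy(),
        sub["r_lower_pert"].to_numpy(),
    )


def fit_neuron_models(
    cm: pd.DataFrame,
    split_seed: int,
    rng: Optional[np.random.Generator | int] = None,
) -> list[dict]:
    """Fit the full and per-neuron constant-weight models for one neuron.

    Fits on the train half of the lower-cue-perturbed condition means and
    evaluates on the test half (predictions built from the test-half
    single-cue responses).  Returns ``model_fits.csv`` rows for the full
    model and Model 2; Model 1 requires the group fit
    (:func:`fit_population_models`).
    """
    rh_tr, rl_tr, y_tr = _fit_arrays(cm, "train")
    rh_te, rl_te, y_te = _fit_arrays(cm, "test")
    if y_tr.size < 4 or y_te.size < 1:
        raise ValueError("insufficient condition means for fitting")
    neuron_id = cm["neuron_id"].iloc[0]
    rows = []

    full = am.fit_full(rh_tr, rl_tr, y_tr, rng=rng)
    pred = am.predict_full(rh_te, rl_te, full.params)
    ev = am.evaluate_fit(y_te, pred, k=3)
    rows.append(
        {
            "neuron_id": neuron_id,
            "model": "full",
            "b": full.params.b,
            "c": full.params.c,
            "d": full.params.d,
            "a": float("nan"),
            "test_rss": ev.rss,
            "test_r2": ev.r2,
            "test_aicc": ev.aicc,
            "split_seed": split_seed,
            "identifiability_flag": not full.identifiable,
        }
    )

    a2, b2, _ = am.fit_model2(rh_tr, rl_tr, y_tr)
    pred2 = am.predict_model2(rh_te, rl_te, a2, b2)
    ev2 = am.evaluate_fit(y_te, pred2, k=2)
    rows.append(
        {
            "neuron_id": neuron_id,
            "model": "model2",
            "b": b2,
            "c": float("nan"),
            "d": float("nan"),
            "a": a2,
            "test_rss": ev2.rss,
            "test_r2": ev2.r2,
            "test_aicc": ev2.aicc,
            "split_seed": split_seed,
            "identifiability_flag": False,
        }
    )
    return rows


def fit_population_models(
    cond_means: dict[str, pd.DataFrame],
    split_seed: int,
    rng: Optional[np.random.Generator | int] = None,
) -> pd.DataFrame:
    """Fit full, Model 2 (per neuron), and Model 1 (shared weight) jointly.

    ``cond_means`` maps neuron_id -> output of :func:`build_condition_means`
    computed on the same split seed.  Model 1's AICc attributes
    k = 1 + 1/G parameters to each neuron (its own b plus an equal share of
    the group weight a).
    """
    rows: list[dict] = []
    groups_train = []
    per_neuron_test = {}
    for nid, cm in cond_means.items():
        rows.extend(fit_neuron_models(cm, split_seed, rng=rng))
        groups_train.append(_fit_arrays(cm, "train"))
        per_neuron_test[nid] = _fit_arrays(cm, "test")

    a1, bs, _ = am.fit_model1(groups_train)
    G = len(cond_means)
    k1 = 1.0 + 1.0 / G
    for (nid, (rh_te, rl_te, y_te)), b1 in zip(per_neuron_test.items(), bs):
        pred = am.predict_model1(rh_te, rl_te, a1, b1)
        ev = am.evaluate_fit(y_te, pred, k=k1)
        rows.append(
            {
                "neuron_id": nid,
                "model": "model1",
                "b": b1,
                "c": float("nan"),
                "d": float("nan"),
                "a": a1,
                "test_rss": ev.rss,
                "test_r2": ev.r2,
                "test_aicc": ev.aicc,
                "split_seed": split_seed,
                "identifiability_flag": False,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stages


def _stage_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    session = simulate_session(config.session_config(), config.seed_simulate)
    paths = session.save(outdir / "session")
    return list(paths.values())


def _load_session(outdir: Path) -> SessionData:
    for fname in ("trials.csv", "spikes.csv", "conditions.csv"):
        _require(outdir / "session" / fname)
    session = SessionData.load(outdir / "session")
    _check_columns(session.spikes, SPIKES_COLUMNS, "spikes.csv")
    _check_columns(session.trials, TRIALS_COLUMNS, "trials.csv")
    return session


def _stage_screen(config: RunConfig, outdir: Path) -> list[Path]:
    session = _load_session(outdir)
    conditions = session.condition_objects()
    neuron_ids = list(session.neurons["neuron_id"])
    screening = ns.screen_population(
        session.spikes, session.trials, conditions, neuron_ids
    )
    screening_path = outdir / "screening.csv"
    screening.to_csv(screening_path, index=False)

    norm_frames = []
    excluded = []
    for row in screening.itertuples(index=False):
        if row.tuning not in ("positive", "negative"):
            continue
        try:
            norm_frames.append(
                ns.normalize_responses(
                    session.spikes,
                    session.trials,
                    conditions,
                    row.neuron_id,
                    int(row.preferred_value),
                )
            )
        except ns.DegenerateNormalizationError as exc:
            excluded.append(str(exc))
    norm = (
        pd.concat(norm_frames, ignore_index=True)
        if norm_frames
        else pd.DataFrame(columns=["neuron_id", "condition_id", "normalized_mean", "n_trials"])
    )
    norm_path = outdir / "normalized_responses.csv"
    norm.to_csv(norm_path, index=False)
    log = {
        "n_neurons": len(neuron_ids),
        "n_visually_responsive": int(screening["visually_responsive"].sum()),
        "n_value_selective": int(screening["value_selective"].eq(True).sum()),
        "n_positive": int((screening["tuning"] == "positive").sum()),
        "n_negative": int((screening["tuning"] == "negative").sum()),
        "normalization_excluded": excluded,
    }
    log_path = outdir / "screen_log.json"
    log_path.write_text(json.dumps(log, indent=2))
    return [screening_path, norm_path, log_path]


def _stage_perturb(config: RunConfig, outdir: Path) -> list[Path]:
    session = _load_session(outdir)
    conditions = session.condition_objects()
    screening = pd.read_csv(_require(outdir / "screening.csv"))
    rows = []
    psth_frames = []
    for srow in screening.itertuples(index=False):
        if srow.tuning not in ("positive", "negative"):
            continue
        res = pa.analyze_modulation(
            session.spikes, session.trials, conditions, srow.neuron_id
        )
        rows.append(
            {
                "neuron_id": res.neuron_id,
                "modulated": res.modulated,
                "window_start_ms": res.window[0] if res.window else float("nan"),
                "window_end_ms": res.window[1] if res.window else float("nan"),
                "z_high": res.z_high,
                "z_low": res.z_low,
                "MI": res.mi,
                "consistency": res.consistency,
            }
        )
        groups = pa.rotation_groups(session.trials, conditions)
        for gname in ("higher", "lower"):
            psth = pa.compute_psth(
                session.spikes, session.trials, srow.neuron_id, groups[gname], gname
            )
            psth_frames.append(
                pd.DataFrame(
                    {
                        "neuron_id": srow.neuron_id,
                        "group": gname,
                        "bin_ms": psth.bin_centers,
                        "rate_norm": psth.rates,
                    }
                )
            )
    mod_path = outdir / "modulation.csv"
    pd.DataFrame(
        rows,
        columns=[
            "neuron_id", "modulated", "window_start_ms", "window_end_ms",
            "z_high", "z_low", "MI", "consistency",
        ],
    ).to_csv(mod_path, index=False)
    psth_path = outdir / "psth.csv"
    (
        pd.concat(psth_frames, ignore_index=True)
        if psth_frames
        else pd.DataFrame(columns=["neuron_id", "group", "bin_ms", "rate_norm"])
    ).to_csv(psth_path, index=False)
    return [mod_path, psth_path]


def _stage_fit(config: RunConfig, outdir: Path) -> list[Path]:
    session = _load_session(outdir)
    conditions = session.condition_objects()
    screening = pd.read_csv(_require(outdir / "screening.csv"))
    modulation = pd.read_csv(_require(outdir / "modulation.csv"))
    mod_ok = set(
        modulation.loc[
            modulation["modulated"] & (modulation["consistency"] == "consistent"),
            "neuron_id",
        ]
    )
    cond_means = {}
    for srow in screening.itertuples(index=False):
        if srow.tuning not in ("positive", "negative") or srow.neuron_id not in mod_ok:
            continue
        cond_means[srow.neuron_id] = build_condition_means(
            session.spikes,
            session.trials,
            conditions,
            srow.neuron_id,
            int(srow.preferred_value),
            config.seed_split,
        )
    fits_path = outdir / "model_fits.csv"
    comparison_path = outdir / "model_comparison.json"
    if cond_means:
        fits = fit_population_models(
            cond_means, config.seed_split, rng=config.seed_split
        )
        fits.to_csv(fits_path, index=False)
        comparison = am.compare_models(fits)
        comparison.pop("anova", None)
        comparison_path.write_text(
            json.dumps({k: v for k, v in comparison.items()}, indent=2, default=str)
        )
    else:
        pd.DataFrame(
            columns=[
                "neuron_id", "model", "b", "c", "d", "a",
                "test_rss", "test_r2", "test_aicc", "split_seed",
                "identifiability_flag",
            ]
        ).to_csv(fits_path, index=False)
        comparison_path.write_text(json.dumps({"n_neurons": 0}, indent=2))
    return [fits_path, comparison_path]


def _stage_report(config: RunConfig, outdir: Path) -> list[Path]:
    screening = pd.read_csv(_require(outdir / "screening.csv"))
    modulation = pd.read_csv(_require(outdir / "modulation.csv"))
    session = _load_session(outdir)
    conditions = session.condition_objects()

    report: dict = {
        "counts": {
            "total": int(len(screening)),
            "visually_responsive": int(screening["visually_responsive"].sum()),
            "value_selective": int(screening["value_selective"].eq(True).sum()),
            "positive": int((screening["tuning"] == "positive").sum()),
            "negative": int((screening["tuning"] == "negative").sum()),
            "modulated": int(modulation["modulated"].sum()),
            "consistent": int((modulation["consistency"] == "consistent").sum()),
        },
        "modulation_index": {
            "mean_MI": float(modulation["MI"].mean()) if len(modulation) else None,
        },
    }
    if config.include_pupil and len(session.pupil):
        responses = pu.extract_all_responses(session.pupil, session.trials)
        reg = pu.regress_pupil_on_value(responses, session.trials, conditions)
        report["pupil_regression"] = {
            "b0": reg.b0, "b1": reg.b1, "p_b1": reg.p_b1, "n": reg.n_trials
        }
    comparison_path = outdir / "model_comparison.json"
    if comparison_path.exists():
        report["model_comparison"] = json.loads(comparison_path.read_text())

    json_path = outdir / "report.json"
    json_path.write_text(json.dumps(report, indent=2, default=str))
    md_path = outdir / "report.md"
    lines = ["# Run report", "", "## Screening counts", ""]
    for k, v in report["counts"].items():
        lines.append(f"- {k}: {v}")
    if "pupil_regression" in report:
        pr = report["pupil_regression"]
        lines += [
            "",
            "## Pupil regression (response = b0 + b1 * drops)",
            "",
            f"- b1 = {pr['b1']:.4g} (p = {pr['p_b1']:.3g}, n = {pr['n']})",
        ]
    md_path.write_text("\n".join(lines) + "\n")
    return [json_path, md_path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "screen": _stage_screen,
    "perturb": _stage_perturb,
    "fit": _stage_fit,
    "report": _stage_report,
}


_STAGE_OUTPUTS = {
    "simulate": (
        "session/conditions.csv", "session/trials.csv", "session/spikes.csv",
        "session/pupil.csv", "session/neurons_truth.csv",
    ),
    "screen": ("screening.csv", "normalized_responses.csv", "screen_log.json"),
    "perturb": ("modulation.csv", "psth.csv"),
    "fit": ("model_fits.csv", "model_comparison.json"),
    "report": ("report.json", "report.md"),
}


def run_stage(stage: str, config: RunConfig) -> list[Path]:
    """Execute one pipeline stage; partial outputs are removed on failure."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        files = _STAGE_FUNCS[stage](config, outdir)
    except Exception:
        for rel in _STAGE_OUTPUTS[stage]:
            (outdir / rel).unlink(missing_ok=True)
        raise
    _append_manifest(outdir, stage, config, files)
    return files


def run_all(config: RunConfig) -> dict[str, list[Path]]:
    return {stage: run_stage(stage, config) for stage in STAGES}


def make_fixture(size: str = "tiny", outdir: Optional[str | Path] = None) -> SessionData:
    """Deterministic miniature session bundle for tests.

    ``tiny``: 2 blocks, 6 neurons (2 positive, 2 negative, 1 untuned,
    1 non-visual), fixed seed; ``default``: 9 blocks, same population.
    """
    if size not in ("tiny", "default"):
        raise ValueError("size must be 'tiny' or 'default'")
    n_blocks = 2 if size == "tiny" else 9
    neurons = default_neuron_population(np.random.default_rng(20240501))
    cfg = SessionConfig(n_blocks=n_blocks, neurons=neurons)
    session = simulate_session(cfg, 20240502)
    if outdir is not None:
        session.save(outdir)
    return session
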