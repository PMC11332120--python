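"""Orchestration: simulate/ingest -> code -> exclude -> classify -> model -> stats.

One call (:func:`run_main_analysis`) reproduces the whole analysis as plain
CSV/JSON stage outputs in an output directory, so any stage can be re-run in
isolation, plus a run manifest (config snapshot, seed, package version, stage
timings, output paths).  Outputs are deterministic given (input, seed, config);
the manifest's wall-clock timings are the only non-deterministic field.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import behavior_stats as bs
from . import cims_model as cm
from .dataset_io import (
    main_stimuli,
    main_schedule,
    read_trials,
    replication_schedule,
    replication_stimuli,
    write_trials,
)
from .response_coding import code_trials
from .synthetic_cohort import CohortConfig, generate_cohort

__all__ = ["RunConfig", "RunManifest", "StageError", "run_main_analysis", "load_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    input_csv: str | None = None  # load this table instead of simulating
    column_map: Mapping[str, str] | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    control_accuracy_threshold: float = 0.80
    perceiver_threshold: float = 0.5
    run_glmm: bool = True
    trajectory_low_threshold: float = 10.0


@dataclass
class RunManifest:
    seed: int
    config: dict
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _config_snapshot(config: RunConfig) -> dict:
    def clean(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Mapping):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return clean(config)


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump_json(payload: Any, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))


def longterm_series(trials: pd.DataFrame, aud_stimulus_id: str) -> pd.DataFrame:
    """Per-participant %FIR time series (months since final exposure).

    The 24-h post-test contributes t = 0; each long-term test contributes its
    ``months_since_exposure``.  Only participants with at least one long-term
    test appear.
    """
    sub = trials[trials["stimulus_id"] == aud_stimulus_id]
    post = sub[sub["phase"] == "posttest_24h"].copy()
    post["months"] = 0.0
    lt = sub[sub["phase"] == "longterm"].copy()
    lt["months"] = lt["months_since_exposure"].astype(float)
    have_lt = set(lt["participant_id"].unique())
    both = pd.concat([post[post["participant_id"].isin(have_lt)], lt])
    rows = (
        both.groupby(["participant_id", "months"])["coded_category"]
        .apply(lambda s: 100.0 * float((s == "Fusion").mean()))
        .rename("fir_pct")
        .reset_index()
    )
    return rows


def run_main_analysis(config: RunConfig, out_dir) -> RunManifest:
    """Run the full pipeline; write stage outputs under ``out_dir``.

    Stages: ingest (simulate or load), code, exclude, classify, descriptives,
    mixed model (optional), model predictions + evaluation, long-term decay and
    trajectory grouping, manifest.  Any stage failure raises :class:`StageError`
    naming the stage; outputs of completed stages remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, config=_config_snapshot(config), version=__version__)
    stimuli = main_stimuli()
    target_id = config.cohort.model.target_stimulus
    aud_id = next(s.stimulus_id for s in stimuli.values() if s.parent_id == target_id)
    state: dict[str, Any] = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as err:
                manifest.save(out / "manifest.json")
                raise StageError(name, err) from err
            manifest.stage_seconds[name] = time.perf_counter() - t0

        return wrap

    @stage("ingest")
    def _ingest():
        if config.input_csv is not None:
            trials = read_trials(config.input_csv, config.column_map)
            truth = None
        else:
            trials, truth = generate_cohort(config.cohort, seed=config.seed)
        write_trials(trials, out / "trials.csv")
        manifest.outputs["trials"] = "trials.csv"
        if truth is not None:
            truth.to_csv(out / "truth.csv", index=False)
            manifest.outputs["truth"] = "truth.csv"
        state["trials"] = trials

    @stage("code")
    def _code():
        coded = code_trials(state["trials"], stimuli)
        write_trials(coded, out / "coded.csv")
        manifest.outputs["coded"] = "coded.csv"
        state["coded"] = coded

    @stage("exclude")
    def _exclude():
        from .dataset_io import exclude_low_performers

        kept, report = exclude_low_performers(
            state["coded"], stimuli, config.control_accuracy_threshold
        )
        report.to_csv(out / "exclusions.csv", index=False)
        manifest.outputs["exclusions"] = "exclusions.csv"
        state["coded"] = state["coded"][state["coded"]["participant_id"].isin(kept)]

    @stage("classify")
    def _classify():
        classes = bs.classify_perceivers(state["coded"], target_id, config.perceiver_threshold)
        classes.to_csv(out / "perceiver_classes.csv", index=False)
        manifest.outputs["perceiver_classes"] = "perceiver_classes.csv"
        state["classes"] = classes

    @stage("descriptives")
    def _descriptives():
        coded = state["coded"].merge(
            state["classes"][["participant_id", "perceiver_class"]], on="participant_id"
        )
        desc = bs.descriptives(coded, group_by=("phase", "perceiver_class", "stimulus_id"))
        desc.to_csv(out / "descriptives.csv", index=False)
        manifest.outputs["descriptives"] = "descriptives.csv"

    @stage("mixed_model")
    def _glmm():
        if not config.run_glmm:
            return
        counts = bs.fusion_counts_prepost(state["coded"], aud_id, state["classes"])
        fit = bs.fit_fusion_glmm(counts)
        _dump_json(
            {
                "effects": {k: dataclasses.asdict(v) for k, v in fit.effects.items()},
                "posthoc": {k: dataclasses.asdict(v) for k, v in fit.posthoc.items()},
                "singular": fit.singular,
                "converged": fit.converged,
            },
            out / "glmm.json",
        )
        manifest.outputs["glmm"] = "glmm.json"

    @stage("model")
    def _model():
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        pred = cm.predict_cohort(
            state["coded"], stimuli, config.cohort.model, simulate=True, rng=rng
        )
        pred.to_csv(out / "predictions.csv", index=False)
        manifest.outputs["predictions"] = "predictions.csv"
        day1 = np.rint(pred["day1_fusion_fraction"] * 5).astype(int)
        try:
            summary = bs.evaluate_model(
                pred["predicted_fir"],
                pred["observed_fir"],
                day1_counts=day1,
                rng=np.random.default_rng(np.random.SeedSequence([config.seed, 2])),
            )
            payload = dataclasses.asdict(summary)
        except ValueError as err:
            payload = {"flag": f"not_evaluable: {err}"}
        _dump_json(payload, out / "model_evaluation.json")
        manifest.outputs["model_evaluation"] = "model_evaluation.json"

    @stage("longterm")
    def _longterm():
        series = longterm_series(state["coded"], aud_id)
        if series.empty:
            _dump_json({"flag": "no_longterm_tests"}, out / "decay_fits.json")
            manifest.outputs["decay_fits"] = "decay_fits.json"
            return
        groups = bs.group_trajectories(series, low_threshold=config.trajectory_low_threshold)
        groups.to_csv(out / "trajectories.csv", index=False)
        manifest.outputs["trajectories"] = "trajectories.csv"
        fits = {}
        for traj, sub in groups.groupby("trajectory"):
            members = sub["participant_id"]
            mean_series = (
                series[series["participant_id"].isin(members)]
                .groupby("months")["fir_pct"]
                .mean()
                .reset_index()
            )
            if len(mean_series) >= 3:
                fit = bs.fit_decay(mean_series["months"], mean_series["fir_pct"])
                fits[traj] = dataclasses.asdict(fit)
                fits[traj]["n_participants"] = int(members.nunique())
        _dump_json(fits, out / "decay_fits.json")
        manifest.outputs["decay_fits"] = "decay_fits.json"

    manifest.save(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# config files


def _cohort_from_dict(d: Mapping[str, Any]) -> CohortConfig:
    d = dict(d)
    model = cm.ModelConfig(**d.pop("model", {}))
    schedule_name = d.pop("schedule", "main")
    schedule = {"main": main_schedule, "replication": replication_schedule}[schedule_name]()
    if "p_common_high" in d:
        d["p_common_high"] = tuple(d["p_common_high"])
    if "p_common_low" in d:
        d["p_common_low"] = tuple(d["p_common_low"])
    return CohortConfig(model=model, schedule=schedule, **d)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration; all defaults are overridable.

    Top-level keys mirror :class:`RunConfig`; ``cohort`` mirrors
    :class:`CohortConfig` (with ``schedule: main|replication``) and
    ``cohort.model`` mirrors :class:`ModelConfig`.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    cohort = _cohort_from_dict(data.pop("cohort", {}))
    return RunConfig(cohort=cohort, **data)
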