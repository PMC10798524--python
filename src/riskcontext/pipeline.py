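"""Configuration and staged pipeline binding the analysis together.

Stages: ``generate`` (task schedules), ``simulate`` (choices + SCR
traces), ``score`` (SCR scoring), ``fit`` (feature table + model suite),
``power`` (simulation-based power), ``report`` (plain-text summary).
Every stochastic stage derives its random stream from the global seed,
the stage name, and the subject id, so stages rerun reproducibly in
isolation; a manifest records the config hash and artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as rcio
from .cohort import (
    PopulationConfig,
    ScrGenParams,
    SubjectParams,
    sample_subject_params,
    simulate_choices,
    synthesize_scr_trace,
)
from .features import NormalizationScheme, build_cohort_features
from .power import simulate_power
from .scr import score_subject
from .suite import attach_scr, run_behavior_suite, run_scr_suite
from .task import TaskConfig, generate_choice_set

__all__ = ["RunConfig", "load_config", "run_pipeline", "STAGES"]

log = logging.getLogger("riskcontext")

STAGES = ("generate", "simulate", "score", "fit", "power", "report")


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 12
    miss_rate: float = 0.005
    write_traces: bool = True
    n_trace_subjects: int | None = None  # default: all subjects
    coef_sds: dict = field(default_factory=dict)
    mean_overrides: dict = field(default_factory=dict)
    scr_overrides: dict = field(default_factory=dict)
    re_sd_riskygain: float = 2.5
    re_sd_safe: float = 2.5
    re_corr: float = -0.3
    re_sd_intercept: float = 0.3

    def population(self) -> PopulationConfig:
        scr = ScrGenParams(**self.scr_overrides)
        mean = SubjectParams(scr=scr, **self.mean_overrides)
        return PopulationConfig(
            mean=mean,
            coef_sds=dict(self.coef_sds),
            re_sd_riskygain=self.re_sd_riskygain,
            re_sd_safe=self.re_sd_safe,
            re_corr=self.re_corr,
            re_sd_intercept=self.re_sd_intercept,
        )


@dataclass(frozen=True)
class ScrConfig:
    cutoff_hz: float = 25.0
    n_coefficients: int = 16
    window_samples: int = 3
    window: tuple[float, float] = (0.5, 4.5)
    floor: float = 0.02
    responder_fraction: float = 0.25


@dataclass(frozen=True)
class EngineConfig:
    include_random_in_offset: bool = True
    model3c_offset: str = "1"


@dataclass(frozen=True)
class PowerConfig:
    model: str = "2"
    term: str = "prev_outcome"
    alpha: float = 0.05
    n_sims: int = 100
    n_subjects: int = 62


@dataclass(frozen=True)
class RunConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    scr: ScrConfig = field(default_factory=ScrConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    power: PowerConfig = field(default_factory=PowerConfig)
    money_scale: float | None = None
    earnings_scale: float | None = None
    seed: int = 0
    outdir: str = "riskcontext_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build(cls, block: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise PipelineError(f"unknown keys in config block {name!r}: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in block.items()
    }
    return cls(**kwargs)


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; missing blocks take their defaults."""
    raw: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update(overrides or {})
    return RunConfig(
        task=_build(TaskConfig, raw.get("task", {}), "task"),
        cohort=_build(CohortConfig, raw.get("cohort", {}), "cohort"),
        scr=_build(ScrConfig, raw.get("scr", {}), "scr"),
        engine=_build(EngineConfig, raw.get("engine", {}), "engine"),
        power=_build(PowerConfig, raw.get("power", {}), "power"),
        money_scale=raw.get("money_scale"),
        earnings_scale=raw.get("earnings_scale"),
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "riskcontext_out")),
    )


_STAGE_KEY = {name: i for i, name in enumerate(STAGES)}


def stage_rng(seed: int, stage: str, subject: int | None = None) -> np.random.Generator:
    key = (_STAGE_KEY[stage],) if subject is None else (_STAGE_KEY[stage], subject)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _path(cfg: RunConfig, name: str) -> str:
    return os.path.join(cfg.outdir, name)


def _require(cfg: RunConfig, name: str, producer: str) -> str:
    p = _path(cfg, name)
    if not os.path.exists(p):
        raise PipelineError(
            f"missing input {p!r}; run the {producer!r} stage first"
        )
    return p


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order; returns the manifest dict."""
    cfg = config
    os.makedirs(cfg.outdir, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    artifacts: list[str] = []
    for stage in ordered:
        log.info("stage %s", stage)
        artifacts.extend(_RUNNERS[stage](cfg))
    manifest = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "stages": ordered,
        "artifacts": sorted(set(artifacts)),
        "config": cfg.to_dict(),
    }
    with open(_path(cfg, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _norm(cfg: RunConfig, choice_sets: dict) -> NormalizationScheme:
    if cfg.money_scale and cfg.earnings_scale:
        return NormalizationScheme(cfg.money_scale, cfg.earnings_scale)
    auto = NormalizationScheme.from_choice_sets(choice_sets.values())
    return NormalizationScheme(
        cfg.money_scale or auto.money_scale,
        cfg.earnings_scale or auto.earnings_scale,
    )


def _stage_generate(cfg: RunConfig) -> list[str]:
    sets = {
        s: generate_choice_set(cfg.task, seed=stage_rng(cfg.seed, "generate", s))
        for s in range(cfg.cohort.n_subjects)
    }
    rcio.write_trials(_path(cfg, "trials.csv"), sets)
    return ["trials.csv"]


def _stage_simulate(cfg: RunConfig) -> list[str]:
    sets = rcio.read_trials(_require(cfg, "trials.csv", "generate"))
    norm = _norm(cfg, sets)
    pop = cfg.cohort.population()
    records: dict = {}
    artifacts = ["behavior.csv"]
    trace_subjects = (
        sorted(sets)
        if cfg.cohort.n_trace_subjects is None
        else sorted(sets)[: cfg.cohort.n_trace_subjects]
    )
    for s in sorted(sets):
        rng = stage_rng(cfg.seed, "simulate", s)
        params = sample_subject_params(pop, seed=rng)
        records[s] = simulate_choices(
            sets[s], params, norm, seed=rng, miss_rate=cfg.cohort.miss_rate
        )
        if cfg.cohort.write_traces and s in trace_subjects:
            trace = synthesize_scr_trace(records[s], sets[s], params, norm, seed=rng)
            tp, ep = f"traces/trace_s{s}.csv", f"traces/events_s{s}.csv"
            rcio.write_trace(_path(cfg, tp), _path(cfg, ep), trace)
            artifacts += [tp, ep]
    rcio.write_behavior(_path(cfg, "behavior.csv"), records)
    return artifacts


def _stage_score(cfg: RunConfig) -> list[str]:
    tdir = _path(cfg, "traces")
    if not os.path.isdir(tdir):
        raise PipelineError(
            f"missing input {tdir!r}; run the 'simulate' stage with "
            "write_traces enabled first"
        )
    parts = []
    for fn in sorted(os.listdir(tdir)):
        if not fn.startswith("trace_s"):
            continue
        s = int(fn[len("trace_s"):-len(".csv")])
        trace = rcio.read_trace(
            os.path.join(tdir, fn), os.path.join(tdir, f"events_s{s}.csv")
        )
        for phase in ("outcome", "decision"):
            t = score_subject(
                trace,
                phase=phase,
                cutoff_hz=cfg.scr.cutoff_hz,
                n_coefficients=cfg.scr.n_coefficients,
                window_samples=cfg.scr.window_samples,
                window=cfg.scr.window if phase == "outcome" else None,
                floor=cfg.scr.floor,
                min_fraction=cfg.scr.responder_fraction,
            )
            t.insert(0, "subject", s)
            parts.append(t)
    if not parts:
        raise PipelineError(f"no trace files found under {tdir!r}")
    rcio.write_table(_path(cfg, "scored_scr.csv"), pd.concat(parts, ignore_index=True))
    return ["scored_scr.csv"]


def _stage_fit(cfg: RunConfig) -> list[str]:
    sets = rcio.read_trials(_require(cfg, "trials.csv", "generate"))
    records = rcio.read_behavior(_require(cfg, "behavior.csv", "simulate"))
    norm = _norm(cfg, sets)
    feats = build_cohort_features(sets, records, norm)
    scored_path = _path(cfg, "scored_scr.csv")
    have_scr = os.path.exists(scored_path)
    if have_scr:
        scored = rcio.read_table(scored_path)
        feats = attach_scr(
            feats,
            scored[scored["phase"] == "outcome"],
            scored[scored["phase"] == "decision"],
        )
    rcio.write_table(_path(cfg, "features.csv"), feats)
    report = run_behavior_suite(
        feats,
        include_random=cfg.engine.include_random_in_offset,
        model3c_offset=cfg.engine.model3c_offset,
    )
    results = report.results_table()
    artifacts = ["features.csv", "results.csv"]
    if report.aic_table is not None:
        rcio.write_table(_path(cfg, "aic.csv"), report.aic_table)
        artifacts.append("aic.csv")
    if have_scr:
        scr_report = run_scr_suite(
            feats,
            include_random=cfg.engine.include_random_in_offset,
            m1_fit=report.fits["1"],
        )
        scr_results = scr_report.results_table()
        results = pd.concat(
            [results, scr_results[scr_results["model"] != "1"]],
            ignore_index=True,
        )
    rcio.write_table(_path(cfg, "results.csv"), results)
    return artifacts


def _stage_power(cfg: RunConfig) -> list[str]:
    res = simulate_power(
        term=cfg.power.term,
        model=cfg.power.model,
        n_subjects=cfg.power.n_subjects,
        task=cfg.task,
        population=cfg.cohort.population(),
        alpha=cfg.power.alpha,
        n_sims=cfg.power.n_sims,
        seed=cfg.seed,
    )
    df = pd.DataFrame(
        [{
            "model": res.model, "term": res.term, "alpha": res.alpha,
            "n_sims": res.n_sims, "n_rejections": res.n_rejections,
            "power": res.power, "ci_lo": res.ci[0], "ci_hi": res.ci[1],
            "formatted": res.format(),
        }]
    )
    rcio.write_table(_path(cfg, "power.csv"), df)
    return ["power.csv"]


def _stage_report(cfg: RunConfig) -> list[str]:
    results = rcio.read_table(_require(cfg, "results.csv", "fit"))
    lines = ["Model suite summary", "===================", ""]
    for mid, grp in results.groupby("model", sort=False):
        lines.append(f"model {mid} (AIC = {grp['aic'].iloc[0]:.1f}, n = {int(grp['n'].iloc[0])})")
        for _, r in grp.iterrows():
            lines.append(
                f"  {r['term']:<28} β = {r['estimate']:+.3f} ({r['se']:.3f})"
                f"  p = {r['p']:.3g}"
            )
        lines.append("")
    ppath = _path(cfg, "power.csv")
    if os.path.exists(ppath):
        p = rcio.read_table(ppath).iloc[0]
        lines.append(
            f"power: model {p['model']} term {p['term']}: {p['formatted']}"
        )
    out = _path(cfg, "report.txt")
    with open(out, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    return ["report.txt"]


_RUNNERS = {
    "generate": _stage_generate,
    "simulate": _stage_simulate,
    "score": _stage_score,
    "fit": _stage_fit,
    "power": _stage_power,
    "report": _stage_report,
}
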