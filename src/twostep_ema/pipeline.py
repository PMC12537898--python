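"""End-to-end orchestration: simulate, fit, score, generate EMA, analyze.

A pipeline run is fully determined by its configuration and global seed.
Each stage writes a CSV/JSON artifact; a manifest records the seed, a hash
of the canonical configuration, and the artifact list. Stage failures abort
with the stage name in the diagnostic.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .task import TaskConfig, write_trials
from .hybrid import (GeneratingDistribution, PARAM_NAMES, decompose_rpes,
                     fit_subject, simulate_agent)
from .stay import build_stay_table, fit_stay_glmm, summary_text
from .ema import EMAGenConfig, restructure, simulate_cohort, summarize
from .moderation import (ModerationSpec, fit_glmm_drinking, fit_moderation,
                         icc, report_json, select_random_structure)

logger = logging.getLogger("twostep_ema.pipeline")

SCHEMA_VERSION = 1

ARTIFACTS = (
    "trials.csv",
    "fitted_params.csv",
    "rpes.csv",
    "mb_scores.csv",
    "ema_ratings.csv",
    "ema_reports.csv",
    "ema_daily.csv",
    "moderation_report.json",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Master configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "run"
    n_subjects: int = 67
    task: TaskConfig = field(default_factory=TaskConfig)
    n_restarts: int = 10
    ema: EMAGenConfig = field(default_factory=EMAGenConfig)
    analysis: ModerationSpec = field(default_factory=ModerationSpec)
    select_structure: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = {k: raw[k] for k in ("seed", "out_dir", "n_subjects",
                                      "n_restarts", "select_structure") if k in raw}
        if "task" in raw:
            kwargs["task"] = TaskConfig(**raw["task"])
        if "ema" in raw:
            ema = dict(raw["ema"])
            if "p_stationary" in ema:
                ema["p_stationary"] = tuple(ema["p_stationary"])
            if "omega_beta" in ema:
                ema["omega_beta"] = tuple(ema["omega_beta"])
            kwargs["ema"] = EMAGenConfig(**ema)
        if "analysis" in raw:
            a = dict(raw["analysis"])
            for key in ("traits", "covariates"):
                if key in a:
                    a[key] = tuple(a[key])
            kwargs["analysis"] = ModerationSpec(**a)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # the hash identifies the scientific config
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return out
        return wrapper
    return deco


@_stage("simulate-task")
def _simulate_task(config: RunConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    gen = GeneratingDistribution()
    frames, truth = [], []
    for i in range(config.n_subjects):
        params = gen.sample(rng)
        frames.append(simulate_agent(params, config.task, rng, subject=i))
        truth.append(dict(subject=i, **params.to_dict()))
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truth)


@_stage("fit-hybrid")
def _fit_hybrid(config: RunConfig, trials: pd.DataFrame, rng) -> pd.DataFrame:
    rows = []
    for subject, grp in trials.groupby("subject", sort=False):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_subject(grp, n_restarts=config.n_restarts, rng=rng,
                              p_common=config.task.p_common)
        if not fit.converged:
            logger.warning("subject %r: no converged restart", subject)
        rows.append(dict(subject=subject, **fit.params.to_dict(),
                         nll=fit.nll, converged=fit.converged,
                         hessian_ok=fit.hessian_ok))
    return pd.DataFrame(rows)


@_stage("decompose-rpes")
def _rpes(config: RunConfig, trials, fits: pd.DataFrame) -> pd.DataFrame:
    from .hybrid import HybridParams

    frames = []
    for subject, grp in trials.groupby("subject", sort=False):
        row = fits.set_index("subject").loc[subject]
        params = HybridParams(**{k: float(row[k]) for k in PARAM_NAMES})
        frames.append(decompose_rpes(params, grp, config.task.p_common))
    return pd.concat(frames, ignore_index=True)


@_stage("mb-score")
def _mb_score(trials: pd.DataFrame):
    table = build_stay_table(trials)
    return fit_stay_glmm(table)


@_stage("simulate-ema")
def _simulate_ema(config: RunConfig, rng):
    return simulate_cohort(config.ema, rng)


@_stage("restructure")
def _restructure(ratings, reports, window: int):
    return restructure(ratings, reports, window=window)


@_stage("analyze")
def _analyze(config: RunConfig, daily, traits) -> dict:
    report: dict = {"schema_version": SCHEMA_VERSION}
    unconditional = icc(daily)
    report["icc"] = dict(icc=unconditional.icc, defined=unconditional.defined,
                         var_between=unconditional.var_between,
                         var_within=unconditional.var_within)
    spec = config.analysis
    if config.select_structure:
        sel = select_random_structure(daily, traits, spec)
        report["structure_selection"] = dict(
            chosen=sel.chosen, notes=sel.notes,
            table=sel.table.replace({np.nan: None}).to_dict(orient="records"),
        )
        spec = ModerationSpec(dependent=spec.dependent, traits=spec.traits,
                              covariates=spec.covariates,
                              random_structure=sel.chosen)
    # degenerate cohorts (very few subjects, missing categories) yield
    # warnings in the report rather than aborting the run
    for name, fitter in (("lmm", fit_moderation), ("glmm", fit_glmm_drinking)):
        try:
            report[name] = report_json(fitter(daily, traits, spec))
        except Exception as exc:
            logger.warning("%s model degenerate: %s", name, exc)
            report[name] = dict(error=str(exc))
    report["ema_summary"] = summarize(daily, traits).to_dict()
    return report


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the artifact directory.

    Deterministic given the configuration: all randomness flows from one
    seeded generator. Writes the artifacts listed in ``ARTIFACTS`` plus
    ``manifest.json`` and ``run.log``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("twostep_ema")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("run seed=%d config_hash=%s", config.seed, config.hash())
        rng = np.random.default_rng(config.seed)

        trials, truth = _simulate_task(config, rng)
        write_trials(trials, out / "trials.csv")
        fits = _fit_hybrid(config, trials, rng)
        fits.to_csv(out / "fitted_params.csv", index=False)
        rpes = _rpes(config, trials, fits)
        rpes.to_csv(out / "rpes.csv", index=False)
        stay_fit = _mb_score(trials)
        stay_fit.mb_scores.to_csv(out / "mb_scores.csv", index=False)
        (out / "stay_model.txt").write_text(summary_text(stay_fit))

        traits, ratings, reports = _simulate_ema(config, rng)
        ratings.to_csv(out / "ema_ratings.csv", index=False)
        reports.to_csv(out / "ema_reports.csv", index=False)
        daily = _restructure(ratings, reports, config.ema.window)
        daily.to_csv(out / "ema_daily.csv", index=False)

        report = _analyze(config, daily, traits)
        (out / "moderation_report.json").write_text(json.dumps(report, indent=1))

        manifest = dict(
            schema_version=SCHEMA_VERSION,
            package_version=__version__,
            seed=config.seed,
            config_hash=config.hash(),
            created=datetime.datetime.now().isoformat(timespec="seconds"),
            artifacts=list(ARTIFACTS),
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        logger.info("run complete: %s", out)
        return out
    finally:
        root.removeHandler(handler)
        handler.close()
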