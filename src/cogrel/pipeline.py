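"""End-to-end orchestration: simulate or load, fit, compare, report.

``run_pipeline`` composes the analysis stages in their natural order:
model-agnostic measures -> per-session hierarchical fits -> model
comparison -> joint correlated fit -> reliability tables -> posterior
predictive forecasting. Every output CSV/JSON carries the configuration
hash, and a run with the same config and seed reproduces its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agnostic, comparison, io, prediction, reliability, synth
from .fitting import (ModelSpec, SamplerSettings, check_convergence,
                      fit_joint_correlated, fit_per_session)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("cogrel")


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    tasks: tuple = ("bandit", "gamble")
    simulate: bool = True
    n_subjects: int = 50
    bandit_csv: str | None = None
    gamble_csv: str | None = None
    profile: str = "test"             # "smoke" | "test" | "full"
    seed: int = 0
    out_dir: str = "cogrel_run"
    compare_variants: bool = False
    stages: tuple = ("agnostic", "fit", "joint", "reliability", "predict")
    T: int = 200
    walk_sd: float = 0.03
    walk_bounds: tuple = (0.2, 0.8)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls(**json.load(fh))

    def hash(self) -> str:
        fields = asdict(self)
        fields.pop("out_dir")  # where results land does not change what they are
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def sampler_settings(self) -> SamplerSettings:
        if self.profile == "full":
            return SamplerSettings()
        if self.profile == "smoke":
            return SamplerSettings(chains=2, warmup=250, draws=250)
        return SamplerSettings.test_profile()


def _model_for(task: str) -> ModelSpec:
    return ModelSpec.bandit_winning() if task == "bandit" else ModelSpec.gamble_winning()


def _stamp(df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = cfg.hash()
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; write the report bundle; return it."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    bundle: dict = {"config": asdict(config), "config_hash": config.hash()}
    settings = config.sampler_settings()

    # ----- data
    if config.simulate:
        study = synth.simulate_study(
            bandit_spec=(synth.default_bandit_population(config.n_subjects)
                         if "bandit" in config.tasks else None),
            gamble_spec=(synth.default_gamble_population(config.n_subjects)
                         if "gamble" in config.tasks else None),
            T=config.T, walk_sd=config.walk_sd,
            walk_bounds=tuple(config.walk_bounds), seed=config.seed)
        data = {"bandit": study.bandit, "gamble": study.gamble}
        io.write_csv(_stamp(study.truth, config), out / "truth.csv")
        bundle["truth"] = study.truth
    else:
        data = {}
        if config.bandit_csv:
            data["bandit"] = io.read_bandit_csv(config.bandit_csv)
        if config.gamble_csv:
            data["gamble"] = io.read_gamble_csv(config.gamble_csv)
    for task in config.tasks:
        if task in data and len(data[task]):
            io.write_csv(_stamp(data[task], config), out / f"{task}.csv")

    timings = {}
    for task in config.tasks:
        if task not in data or not len(data[task]):
            continue
        df = data[task]
        model = _model_for(task)

        if "agnostic" in config.stages:
            t0 = time.time()
            tab = (agnostic.stay_table(df) if task == "bandit"
                   else agnostic.gamble_rate_table(df))
            bundle[f"{task}_agnostic"] = tab
            io.write_csv(_stamp(tab, config), out / f"{task}_agnostic.csv")
            timings[f"{task}_agnostic"] = time.time() - t0

        posts = {}
        if "fit" in config.stages:
            t0 = time.time()
            for session in (1, 2):
                posts[session] = fit_per_session(model, df, session=session,
                                                 settings=settings,
                                                 seed=config.seed + session)
                conv = check_convergence(posts[session])
                conv.table.to_csv(out / f"{task}_s{session}_convergence.csv",
                                  index=False)
                if not conv.ok:
                    log.warning("%s session %d: Rhat flags %s", task, session,
                                conv.rhat_flags)
            bundle[f"{task}_posteriors"] = posts
            est = pd.concat([p.subject_means for p in posts.values()])
            io.write_csv(_stamp(est.reset_index(), config),
                         out / f"{task}_subject_estimates.csv")
            timings[f"{task}_fit"] = time.time() - t0

        if config.compare_variants and posts:
            t0 = time.time()
            variants = _comparison_variants(task)
            pw = []
            for m in variants:
                p = (posts[1] if m == model else
                     fit_per_session(m, df, session=1, settings=settings,
                                     seed=config.seed + 1))
                pw.append(comparison.pointwise_loglik(p, df))
            cmp_tab = comparison.looic_compare(pw)
            bundle[f"{task}_comparison"] = cmp_tab
            io.write_csv(_stamp(cmp_tab, config), out / f"{task}_comparison.csv")
            timings[f"{task}_compare"] = time.time() - t0

        if "joint" in config.stages:
            t0 = time.time()
            joint = fit_joint_correlated(model, df, settings=settings,
                                         seed=config.seed + 7)
            bundle[f"{task}_joint"] = joint
            io.write_csv(_stamp(joint.reliability, config),
                         out / f"{task}_joint_reliability.csv")
            timings[f"{task}_joint"] = time.time() - t0

        if "reliability" in config.stages:
            t0 = time.time()
            measures = _paired_measures(task, bundle, df, posts)
            rep = reliability.reliability_report(measures)
            bundle[f"{task}_reliability"] = rep
            io.write_csv(_stamp(rep, config), out / f"{task}_reliability.csv")
            timings[f"{task}_reliability"] = time.time() - t0

        if "predict" in config.stages and posts:
            t0 = time.time()
            rep = prediction.prediction_battery(posts[1], df, session=2)
            bundle[f"{task}_prediction"] = rep
            io.write_csv(_stamp(rep.table, config), out / f"{task}_prediction.csv")
            with open(out / f"{task}_prediction_tests.json", "w") as fh:
                json.dump({"tests": rep.tests, "chance": rep.chance,
                           "config_hash": config.hash()}, fh, indent=2)
            timings[f"{task}_predict"] = time.time() - t0

    meta = {"config": asdict(config), "config_hash": config.hash(),
            "timings_s": {k: round(v, 2) for k, v in timings.items()},
            "total_s": round(time.time() - t_start, 2)}
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    bundle["meta"] = meta
    return bundle


def _comparison_variants(task: str):
    if task == "bandit":
        return [ModelSpec.bandit_winning(),
                ModelSpec(task="bandit", shared_learning_rate=True, lapse=False)]
    return [ModelSpec.gamble_winning(), ModelSpec(task="gamble", fix_rho=True)]


def _paired_measures(task, bundle, df, posts) -> dict:
    """Assemble PairedMeasures for agnostic and model-based quantities."""
    measures = {}
    tab = bundle.get(f"{task}_agnostic")
    if tab is not None:
        cols = ([c for c in tab.columns if c.startswith("p_stay")]
                if task == "bandit" else ["p_gamble_mixed", "p_gamble_gain"])
        wide = tab.pivot(index="subject", columns="session", values=cols)
        for c in cols:
            try:
                measures[c] = reliability.PairedMeasures(
                    wide[(c, 1)].to_numpy(), wide[(c, 2)].to_numpy(), name=c)
            except ValueError:
                pass
    if posts:
        e1 = posts[1].subject_means.droplevel("session")
        e2 = posts[2].subject_means.droplevel("session")
        common = e1.index.intersection(e2.index)
        for c in e1.columns:
            measures[c] = reliability.PairedMeasures(
                e1.loc[common, c].to_numpy(), e2.loc[common, c].to_numpy(), name=c)
    return measures
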