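"""End-to-end experiment orchestration from a single configuration.

A configuration (dict or YAML file) names the stages and their parameters;
``run_experiment`` executes them in dependency order (schedule -> agent ->
model fits -> population -> spike counts -> encoding classification ->
decoding -> RSA), propagates seeds deterministically to every stage, writes
intermediates, and assembles a report whose every number is traceable to a
stage output.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding as dec
from . import rsa as rsa_mod
from .encoding import classify_value_neuron
from .glm import zscore_epochs
from .population import DEFAULT_POP_SPEC, generate_population
from .rl import RLParams, fit_rl, simulate_agent
from .spikes import generate_spike_counts, session_values
from .task import ConfigurationError, generate_schedule

log = logging.getLogger("viewchoice.workbench")

_STAGES = ("schedule", "agent", "rl_fit", "population", "spikes",
           "classification", "decoding", "rsa")

_REQUIRED = {
    "schedule": ("task_variant", "n_trials"),
    "agent": ("alpha", "beta"),
    "population": ("n_neurons",),
    "spikes": ("rate_source",),
}


@dataclass
class ExperimentConfig:
    stages: dict
    seed: int = 0
    outdir: str | None = None
    name: str = "experiment"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f)
        return cls(stages=raw.get("stages", {}), seed=int(raw.get("seed", 0)),
                   outdir=raw.get("outdir"), name=raw.get("name", "experiment"))

    def validate(self) -> None:
        for name in self.stages:
            if name not in _STAGES:
                raise ConfigurationError(f"unknown stage {name!r}")
        for name, req in _REQUIRED.items():
            if name in self.stages:
                missing = [k for k in req if k not in self.stages[name]]
                if missing:
                    raise ConfigurationError(
                        f"stage {name!r} missing parameters: {missing}")

    def stage(self, name: str, default: dict | None = None) -> dict:
        return dict(self.stages.get(name, default or {}))


def standard_config(seed: int = 0, n_neurons: int = 233,
                    n_trials: int = 150) -> ExperimentConfig:
    """Bundled default: one main-task session with the full type mixture."""
    return ExperimentConfig(
        name="standard",
        seed=seed,
        stages={
            "schedule": {"task_variant": "main", "n_trials": n_trials},
            "agent": {"variant": "reversal", "alpha": 0.3, "beta": 3.0,
                      "mag_weight": 1.0},
            "rl_fit": {"variant": "reversal", "n_restarts": 10},
            "population": {"n_neurons": n_neurons, "spec": dict(DEFAULT_POP_SPEC)},
            "spikes": {"rate_source": "parametric"},
            "classification": {"alpha": 0.05},
            "decoding": {"grouping": "view_choice", "method": "svm",
                         "min_trials": 5, "n_matchings": 20, "n_shuffles": 100},
            "rsa": {"n_perm": 1000},
        },
    )


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "summary.json", "w") as f:
            json.dump({"summary": self.summary, "provenance": self.provenance,
                       "failures": self.failures}, f, indent=2, default=str)


def summarize_classification(counts: dict[str, int] | list[tuple[str, int]],
                             total: int, mode: str = "round") -> pd.DataFrame:
    """Category counts -> percentage table.

    ``mode="round"`` gives nearest-integer percentages; ``mode="truncate1"``
    truncates (floors) to one decimal, for comparability with one-decimal
    reports.  total = 0 is an error.
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    if mode not in ("round", "truncate1"):
        raise ValueError(f"unknown mode {mode!r}")
    items = counts.items() if isinstance(counts, dict) else counts
    rows = []
    for name, cnt in items:
        if cnt > total:
            raise ValueError(f"count for {name!r} exceeds total")
        pct = 100.0 * cnt / total
        if mode == "round":
            pct_out: float | int = int(round(pct))
        else:
            pct_out = math.floor(pct * 10.0) / 10.0
        rows.append({"category": name, "count": cnt, "total": total,
                     "percent": pct_out})
    return pd.DataFrame(rows)


def _sub_seed(seed: int, stage: str) -> int:
    import zlib

    return int(np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
               .generate_state(1)[0] % (2 ** 31))


def run_experiment(config: ExperimentConfig,
                   outdir: str | None = None) -> ExperimentReport:
    """Execute all configured stages; idempotent under identical config+seed."""
    config.validate()
    report = ExperimentReport(config=config)
    t_start = time.time()

    def done(stage: str, seed: int, **extra):
        report.provenance[stage] = {"seed": seed,
                                    "elapsed_s": round(time.time() - t_start, 3),
                                    **extra}
        log.info("stage %s done (seed=%d)", stage, seed)

    # schedule + agent
    s_cfg = config.stage("schedule", {"task_variant": "main", "n_trials": 150})
    seed = _sub_seed(config.seed, "schedule")
    schedule = generate_schedule(s_cfg["task_variant"], int(s_cfg["n_trials"]), seed)
    done("schedule", seed, n_trials=schedule.n_trials, n_blocks=schedule.n_blocks)

    a_cfg = config.stage("agent", {"alpha": 0.3, "beta": 3.0})
    params = RLParams(variant=a_cfg.get("variant", "reversal"),
                      alpha=float(a_cfg["alpha"]), beta=float(a_cfg["beta"]),
                      mag_weight=float(a_cfg.get("mag_weight", 0.0)))
    seed = _sub_seed(config.seed, "agent")
    behavior = simulate_agent(schedule, params, seed)
    report.tables["trial_log"] = behavior.trials
    done("agent", seed, n_trials=behavior.n_trials)

    if "rl_fit" in config.stages:
        f_cfg = config.stage("rl_fit")
        seed = _sub_seed(config.seed, "rl_fit")
        try:
            fit = fit_rl(behavior, f_cfg.get("variant", "reversal"),
                         n_restarts=int(f_cfg.get("n_restarts", 10)), seed=seed)
            report.summary["rl_fit"] = {
                "alpha": fit.params.alpha, "beta": fit.params.beta,
                "neg_loglik": fit.neg_loglik, "aic": fit.aic, "bic": fit.bic,
            }
            done("rl_fit", seed)
        except Exception as e:  # stage failure -> partial report
            report.failures["rl_fit"] = repr(e)

    values = session_values(behavior)
    report.tables["session_values"] = values

    p_cfg = config.stage("population", {"n_neurons": 120})
    seed = _sub_seed(config.seed, "population")
    population = generate_population(p_cfg.get("spec"), int(p_cfg["n_neurons"]), seed)
    done("population", seed, n_neurons=len(population))

    sp_cfg = config.stage("spikes", {"rate_source": "parametric"})
    seed = _sub_seed(config.seed, "spikes")
    recording = generate_spike_counts(population, behavior,
                                      rate_source=sp_cfg["rate_source"],
                                      seed=seed, values=values)
    done("spikes", seed, clipped=recording.clipped_rate_bins)

    if "classification" in config.stages:
        c_cfg = config.stage("classification")
        rows = []
        va = values["value_A"].to_numpy()
        vb = values["value_B"].to_numpy()
        for i, neuron in enumerate(population):
            resp = recording.epochs["cue1"][i].astype(float)
            cls = classify_value_neuron(resp, va, vb,
                                        alpha=float(c_cfg.get("alpha", 0.05)))
            rows.append({"neuron_id": neuron.neuron_id,
                         "planted_type": neuron.functional_type,
                         "category": cls.category, "angle_deg": cls.angle_deg,
                         "gate_p": cls.gate_p})
        cls_table = pd.DataFrame(rows)
        report.tables["value_classification"] = cls_table
        counts = cls_table["category"].value_counts().to_dict()
        report.tables["classification_percentages"] = summarize_classification(
            counts, total=len(population))
        report.summary["classification_counts"] = counts
        done("classification", _sub_seed(config.seed, "classification"))

    zs = zscore_epochs(recording)
    if "decoding" in config.stages:
        d_cfg = config.stage("decoding")
        seed = _sub_seed(config.seed, "decoding")
        try:
            grouping = d_cfg.get("grouping", "view_choice")
            labels = behavior.trials[grouping].to_numpy()
            pop = dec.build_pseudopopulation(
                zs.data["cue2"], labels,
                neuron_ids=zs.neuron_ids,
                min_trials=int(d_cfg.get("min_trials", 5)), seed=seed)
            res = dec.decode(pop, method=d_cfg.get("method", "svm"),
                             n_matchings=int(d_cfg.get("n_matchings", 20)),
                             seed=seed, n_shuffles=int(d_cfg.get("n_shuffles", 100)))
            report.summary["decoding"] = {
                "grouping": grouping, "accuracy": res.mean_accuracy,
                "sd": res.sd_accuracy, "shuffle_p": res.shuffle_p,
            }
            done("decoding", seed)
        except Exception as e:
            report.failures["decoding"] = repr(e)

    if "rsa" in config.stages:
        r_cfg = config.stage("rsa")
        seed = _sub_seed(config.seed, "rsa")
        try:
            viewed_obj = np.where(behavior.trials["first_object"] == "A", "A", "B")
            level = rsa_mod.value_quartile_labels(values["v_first"].to_numpy())
            labels = pd.DataFrame({"object": viewed_obj, "value_level": level})
            cm, rsam = rsa_mod.condition_rsa(zs.data["cue1"], labels)
            templates = rsa_mod.build_templates(
                cm.conditions, which=["identity", "object", "view_value",
                                      "object_value"])
            reg = rsa_mod.rsa_regression(cm, templates,
                                         n_perm=int(r_cfg.get("n_perm", 1000)),
                                         alpha=float(r_cfg.get("alpha", 0.001)),
                                         seed=seed)
            report.tables["rsa_matrix"] = pd.DataFrame(
                rsam.values, columns=[str(i) for i in range(rsam.values.shape[0])])
            report.summary["rsa"] = {
                nm: {"coef": float(reg.coef[j]), "t": float(reg.t[j]),
                     "partial_r2": float(reg.partial_r2[j]),
                     "perm_p": float(reg.perm_p[nm]),
                     "significant": bool(reg.significant[nm])}
                for j, nm in enumerate(reg.names)
            }
            done("rsa", seed)
        except Exception as e:
            report.failures["rsa"] = repr(e)

    if outdir or config.outdir:
        report.save(outdir or config.outdir)
    return report
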