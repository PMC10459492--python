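"""End-to-end identification runs: simulate -> features -> stack -> metrics
-> statistics -> report.

One independent stack is trained per participant on its six training
signals (leave-one-signal-out cross-validation inside), then evaluated on
the held-out seventh signal at each requested horizon, for the stack and
for every base learner individually. The per-participant VAF table feeds
the Friedman/Nemenyi comparison. A single global seed is fanned out
deterministically to every stochastic component, so a config plus seed
reproduces every artifact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (FeatureSpec, build_design, build_design_set,
                       read_trials, split_sessions)
from .learners import default_specs, fast_specs
from .metrics import (friedman_test, make_metrics_table, nemenyi_test,
                      residual_whiteness, rmse, summarize, vaf)
from .optimize import JadeConfig
from .rules import MetaConfig
from .stacking import fit_stack, predict_one_step, predict_recursive, save_bundle
from .synth import MultisineSpec, make_benchmark

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "compare_models",
            "write_report", "load_config"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (exactly one data source)."""

    n_participants: int = 2
    input_file: str | None = None           # delimited trials; overrides synthesis
    seconds: float = 5.0
    n_signals: int = 7
    target_vaf_range: tuple[float, float] | None = (92.0, 96.0)
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    grids: str = "default"                  # "default" or "fast"
    tuner: str = "jade"                     # "jade", "de" or "grid"
    jade_pop: int = 10
    jade_generations: int = 10
    horizons: tuple = (1, 3)
    seed: int = 0
    outdir: str | None = None
    save_bundles: bool = False

    def __post_init__(self) -> None:
        if not set(self.horizons) <= set(range(1, 11)):
            raise ValueError("horizons must be within 1..10")

    def specs(self):
        if self.grids == "default":
            return default_specs()
        if self.grids == "fast":
            return fast_specs()
        raise ValueError(f"unknown grid preset {self.grids!r}")


@dataclass
class RunReport:
    metrics: pd.DataFrame          # participant, model, horizon, vaf, rmse
    tuned: pd.DataFrame            # per-participant tuned hyperparameters
    whiteness: pd.DataFrame        # per-participant KS statistic and p (h=1)
    stats: dict = field(default_factory=dict)
    predictions: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _stack_label(tuner: str) -> str:
    return {"jade": "JADE-STACK", "de": "DE-STACK", "grid": "GRID-STACK"}[tuner]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full identification protocol for every participant."""
    if config.input_file:
        trials = read_trials(config.input_file)
    else:
        ms = MultisineSpec(seconds=config.seconds, n_signals=config.n_signals)
        bench = make_benchmark(config.n_participants, ms, seed=config.seed,
                               target_vaf_range=config.target_vaf_range)
        trials = [t for p in bench for t in p.trials]
    splits = split_sessions(trials, n_signals=config.n_signals)

    specs = config.specs()
    label = _stack_label(config.tuner)
    root = np.random.SeedSequence(config.seed)
    part_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                  for s in root.spawn(len(splits))]

    records, tuned_rows, white_rows, pred_frames = [], [], [], []
    for split, pseed in zip(splits, part_seeds):
        logger.info("participant %s: fitting stack", split.participant)
        design = build_design_set(split.train, config.feature_spec)
        model = fit_stack(
            design, specs, template=MetaConfig(), tuner=config.tuner,
            jade_config=JadeConfig(pop_size=config.jade_pop,
                                   generations=config.jade_generations,
                                   seed=pseed),
            seed=pseed,
        )
        tuned_rows.append(
            {"participant": split.participant, "committees": model.committees,
             "neighbors": model.neighbors, "cv_vaf": model.cv_vaf,
             **{f"{n}_params": str(model.layer0[n].params)
                for n in model.learner_names}}
        )
        test_design = build_design(split.test, config.feature_spec)
        X_test = test_design.X.to_numpy(dtype=float)

        for h in sorted(config.horizons):
            res = (predict_one_step(model, test_design) if h == 1
                   else predict_recursive(model, split.test, h))
            records.append((split.participant, label, h,
                            vaf(test_design.y, res.yhat),
                            rmse(test_design.y, res.yhat)))
            pred_frames.append(res.to_frame(test_design.y))
            if h == 1:
                K, p = residual_whiteness(res.residuals)
                white_rows.append({"participant": split.participant,
                                   "K": K, "pvalue": p})
            # base learners, recursive through the same lag-feedback scheme
            for name in model.learner_names:
                single = _single_learner_view(model, name)
                res_b = (predict_one_step(single, test_design) if h == 1
                         else predict_recursive(single, split.test, h))
                records.append((split.participant, name, h,
                                vaf(test_design.y, res_b.yhat),
                                rmse(test_design.y, res_b.yhat)))
        if config.save_bundles and config.outdir:
            save_bundle(model, Path(config.outdir) / f"participant_{split.participant}")

    report = RunReport(
        metrics=make_metrics_table(records),
        tuned=pd.DataFrame(tuned_rows),
        whiteness=pd.DataFrame(white_rows),
        predictions=pd.concat(pred_frames, ignore_index=True),
        manifest={"seed": config.seed, "tuner": config.tuner,
                  "grids": config.grids, "horizons": list(config.horizons),
                  "n_participants": len(splits),
                  "stack_label": label},
    )
    if len(splits) >= 2:
        report.stats = compare_models(report)
    else:
        logger.info("single participant: skipping the model comparison stage")
    if config.outdir:
        write_report(report, config.outdir)
    return report


class _SingleLearnerMeta:
    """Identity meta over one layer-0 column (for per-learner evaluation)."""

    def __init__(self, col: int):
        self.col = col

    def predict(self, Z):
        return np.asarray(Z)[:, self.col]


def _single_learner_view(model, name: str):
    """A StackModel whose meta passes through one base learner unchanged."""
    from copy import copy

    view = copy(model)
    view.meta = _SingleLearnerMeta(model.learner_names.index(name))
    return view


def compare_models(report: RunReport, alpha: float = 0.05) -> dict:
    """Friedman omnibus per horizon on per-participant VAF, with the
    Nemenyi post hoc when the omnibus rejects."""
    out = {}
    for h in sorted(report.metrics["horizon"].unique()):
        wide = report.metrics[report.metrics["horizon"] == h].pivot(
            index="participant", columns="model", values="vaf")
        if wide.shape[1] < 3 or wide.shape[0] < 2:
            raise ValueError("model comparison needs >= 3 models and >= 2 participants")
        fr = friedman_test(wide, better="higher")
        entry = {"friedman": fr, "alpha": alpha, "nemenyi": None}
        if fr.pvalue < alpha:
            entry["nemenyi"] = nemenyi_test(wide, alpha=alpha, better="higher")
        out[int(h)] = entry
    return out


def write_report(report: RunReport, outdir) -> None:
    """Write delimited-text artifacts; every table is recomputable from the
    stored predictions."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.metrics.to_csv(out / "metrics.csv", index=False)
    report.tuned.to_csv(out / "tuned_hyperparameters.csv", index=False)
    report.whiteness.to_csv(out / "residual_whiteness.csv", index=False)
    if report.predictions is not None:
        report.predictions.to_csv(out / "predictions.csv", index=False)

    lines = []
    for h, entry in report.stats.items():
        fr = entry["friedman"]
        lines.append(f"horizon {h}: Friedman FD={fr.statistic:.4f} df={fr.df} "
                     f"p={fr.pvalue:.3g}")
        if entry["nemenyi"] is not None:
            ne = entry["nemenyi"]
            lines.append(f"  Nemenyi CD={ne.cd:.4f}")
            for m, r in ne.mean_ranks.sort_values().items():
                lines.append(f"    {m}: mean rank {r:.2f}")
    (out / "statistics.txt").write_text("\n".join(lines) + "\n")

    summary_rows = []
    for h in sorted(report.metrics["horizon"].unique()):
        for m in report.metrics["model"].unique():
            mean_v, std_v = summarize(report.metrics, m, h, "vaf")
            mean_r, std_r = summarize(report.metrics, m, h, "rmse")
            summary_rows.append({"horizon": h, "model": m, "vaf_mean": mean_v,
                                 "vaf_std": std_v, "rmse_mean": mean_r,
                                 "rmse_std": std_r})
    pd.DataFrame(summary_rows).to_csv(out / "summary.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(report.manifest, indent=2) + "\n")


def load_config(path) -> RunConfig:
    """Flat key=value text configuration."""
    kwargs: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key in {"n_participants", "n_signals", "jade_pop", "jade_generations", "seed"}:
            kwargs[key] = int(value)
        elif key in {"seconds"}:
            kwargs[key] = float(value)
        elif key == "horizons":
            kwargs[key] = tuple(int(v) for v in value.split(","))
        elif key == "target_vaf_range":
            kwargs[key] = (None if value.lower() == "none"
                           else tuple(float(v) for v in value.split(",")))
        elif key == "save_bundles":
            kwargs[key] = value.lower() in {"1", "true", "yes"}
        elif key in {"input_file", "grids", "tuner", "outdir"}:
            kwargs[key] = value
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    return RunConfig(**kwargs)
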