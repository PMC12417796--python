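"""Repetition harness for the in-silico transfer-learning studies.

A *study* re-runs the whole framework several times (default ten), each
repetition starting from a fresh set of three noisy batch experiments drawn
from the ground-truth target model at random initial conditions.  Per
repetition the harness records the discovered model, whether its structure
matches the ground truth, the fitting MAPE on the training batches and the
prediction MAPE on a shared set of held-out noise-free ground-truth batches;
aggregates (success rate, MAPE mean/s.d.) are recomputed from the rows.

Seeding is hierarchical (numpy SeedSequence spawning), so adding
repetitions never perturbs earlier ones and a study replays bit-identically
from its master seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import PipelineConfig, multi_pass, run_pass
from .casestudy import Y0_RANGES, low_prior_model, source_model, target_model
from .design import DesignSpec, mbdoe_loop
from .models import KineticModel, dumps_model, structural_match
from .simulate import ExperimentDataset, generate_dataset, mape, simulate

__all__ = ["StudyConfig", "RepetitionResult", "StudyReport", "run_study",
           "holdout_dataset", "prediction_mape"]

_SCENARIO_SOURCES = {
    "high_prior": source_model,
    "low_prior": low_prior_model,
    "self_transfer": target_model,
}


@dataclass
class StudyConfig:
    """What to run and at which scale."""

    scenario: str = "high_prior"     # high_prior | low_prior | self_transfer
    repetitions: int = 10
    n_initial_experiments: int = 3
    passes: str = "multi"            # single | multi
    mbdoe_budget: int = 0            # 0 disables the design loop
    holdout_batches: int = 20
    master_seed: int = 0
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIO_SOURCES:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.passes not in ("single", "multi"):
            raise ValueError("passes must be 'single' or 'multi'")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class RepetitionResult:
    repetition: int
    seed: int
    matched: bool
    fit_mape: float
    prediction_mape: float
    n_passes: int
    model_text: str
    mbdoe_prediction_mapes: list[float] = field(default_factory=list)
    failure: str | None = None


@dataclass
class StudyReport:
    config_summary: dict
    rows: list[RepetitionResult]

    @property
    def success_rate(self) -> float:
        ok = [r for r in self.rows if r.failure is None]
        return sum(r.matched for r in ok) / len(self.rows)

    def aggregates(self) -> dict:
        ok = [r for r in self.rows if r.failure is None]
        pm = np.array([r.prediction_mape for r in ok])
        fm = np.array([r.fit_mape for r in ok])
        agg = {
            "repetitions": len(self.rows),
            "completed": len(ok),
            "success_rate": self.success_rate,
            "prediction_mape_mean": float(pm.mean()) if ok else None,
            "prediction_mape_sd": float(pm.std()) if ok else None,
            "fit_mape_mean": float(fm.mean()) if ok else None,
        }
        if ok and ok[0].mbdoe_prediction_mapes:
            length = max(len(r.mbdoe_prediction_mapes) for r in ok)
            per_iter = []
            for i in range(length):
                vals = [r.mbdoe_prediction_mapes[min(i, len(r.mbdoe_prediction_mapes) - 1)]
                        for r in ok]
                per_iter.append(float(np.mean(vals)))
            agg["mbdoe_prediction_mape_per_iteration"] = per_iter
        return agg

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])

    def save(self, path: str | Path) -> None:
        payload = {"config": self.config_summary,
                   "aggregates": self.aggregates(),
                   "rows": [asdict(r) for r in self.rows]}
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def holdout_dataset(n_batches: int, seed: int) -> ExperimentDataset:
    """Noise-free ground-truth batches for prediction scoring."""
    return generate_dataset(target_model(), n_batches, Y0_RANGES,
                            noise_sd=0.0, seed=seed)


#: MAPE assigned to a held-out batch the model cannot integrate (a finite
#: failure ceiling keeps aggregates well-defined)
FAILED_BATCH_MAPE = 1000.0


def prediction_mape(model: KineticModel,
                    holdout: ExperimentDataset) -> float:
    """Mean over held-out batches of the per-batch MAPE; a batch whose
    simulation fails (or goes non-finite) counts as FAILED_BATCH_MAPE."""
    per_batch = []
    for e in holdout.experiments:
        try:
            pred = simulate(model, e.y0, e.sample_times)
            value = mape(pred, e.observations)
            if not np.isfinite(value):
                value = FAILED_BATCH_MAPE
        except Exception:
            value = FAILED_BATCH_MAPE
        per_batch.append(min(value, FAILED_BATCH_MAPE))
    return float(np.mean(per_batch))


def run_study(config: StudyConfig | None = None) -> StudyReport:
    """Run the configured scenario across all repetitions."""
    config = config or StudyConfig()
    truth = target_model()
    source = _SCENARIO_SOURCES[config.scenario]()
    root = np.random.SeedSequence(config.master_seed)
    holdout_seed, *rep_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                                for s in root.spawn(config.repetitions + 1)]
    holdout = holdout_dataset(config.holdout_batches, holdout_seed)

    rows: list[RepetitionResult] = []
    for r, rep_seed in enumerate(rep_seeds, start=1):
        dataset = generate_dataset(truth, config.n_initial_experiments,
                                   seed=rep_seed)
        try:
            row = _run_repetition(r, rep_seed, source, truth, dataset,
                                  holdout, config)
        except Exception as exc:  # repetition-level failure, study continues
            row = RepetitionResult(r, rep_seed, False, FAILED_BATCH_MAPE,
                                   FAILED_BATCH_MAPE, 0, "", failure=repr(exc))
        rows.append(row)
    summary = {"scenario": config.scenario, "passes": config.passes,
               "repetitions": config.repetitions,
               "n_initial_experiments": config.n_initial_experiments,
               "mbdoe_budget": config.mbdoe_budget,
               "master_seed": config.master_seed}
    return StudyReport(summary, rows)


def _run_repetition(r: int, rep_seed: int, source: KineticModel,
                    truth: KineticModel, dataset: ExperimentDataset,
                    holdout: ExperimentDataset,
                    config: StudyConfig) -> RepetitionResult:
    from dataclasses import replace as dc_replace

    pipeline = dc_replace(config.pipeline,
                          training=dc_replace(config.pipeline.training,
                                              seed=rep_seed),
                          sr=dc_replace(config.pipeline.sr, seed=rep_seed))
    mbdoe_mapes: list[float] = []
    if config.mbdoe_budget > 0:
        state = mbdoe_loop(source, dataset, truth, config.mbdoe_budget,
                           pipeline, DesignSpec(), seed=rep_seed,
                           evaluation=holdout)
        model = state.final_model
        n_passes = len(state.iterations)
        fit_mape_val = state.iterations[-1].fit_mape
        mbdoe_mapes = [it.prediction_mape for it in state.iterations
                       if it.prediction_mape is not None]
    elif config.passes == "single":
        rec = run_pass(source, dataset, pipeline)
        model, n_passes, fit_mape_val = rec.model, 1, rec.fit_mape
    else:
        model, records = multi_pass(source, dataset, pipeline)
        n_passes, fit_mape_val = len(records), records[-1].fit_mape

    diff = structural_match(model, truth)
    return RepetitionResult(
        repetition=r, seed=rep_seed, matched=diff.matched,
        fit_mape=fit_mape_val,
        prediction_mape=prediction_mape(model, holdout),
        n_passes=n_passes, model_text=dumps_model(model),
        mbdoe_prediction_mapes=mbdoe_mapes)
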