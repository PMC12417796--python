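"""Forward simulation and synthetic batch-experiment generation.

Reference integration uses adaptive RK45 (rtol 1e-8 / atol 1e-10) through
scipy; a fixed-step mode mirrors the integrator used inside hybrid training.
Synthetic datasets emulate the in-silico study design: batches run for 144 h,
states sampled every 14 h (t = 0, 14, ..., 140), observations carry 5 %
multiplicative Gaussian noise and are clipped at zero, and initial conditions
are drawn uniformly from the stated design box.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import sympy as sp
from scipy.integrate import solve_ivp

from . import casestudy
from .models import KineticModel

__all__ = ["Experiment", "ExperimentDataset", "SimulationError", "simulate",
           "default_sample_times", "generate_dataset", "mape",
           "compile_rhs", "dataset_to_csv", "dataset_from_csv"]


class SimulationError(RuntimeError):
    """Integration produced a non-finite state; message names the time reached."""


def compile_rhs(model: KineticModel):
    """Lambdify a model's right-hand side as ``f(t, y) -> dy/dt``.

    Shared rates are inlined symbolically once, so each call is a single
    vectorized numpy evaluation.
    """
    syms = [sp.Symbol(s) for s in model.state_names]
    eqs = model.sympy_equations(inline_rates=True, substitute_params=True)
    funcs = [sp.lambdify(syms, eqs[s], modules="numpy") for s in model.state_names]

    def rhs(t, y):
        with np.errstate(all="ignore"):
            return np.array([f(*y) for f in funcs], dtype=float)

    return rhs


def simulate(model: KineticModel, y0: Sequence[float], t_grid: Sequence[float],
             mode: str = "reference", rtol: float = 1e-8, atol: float = 1e-10,
             fixed_steps: int = 1440) -> np.ndarray:
    """Integrate ``model`` from ``y0`` and return states at each ``t_grid`` time.

    ``mode="reference"`` uses adaptive RK45; ``mode="fixed"`` uses classic
    RK4 with ``fixed_steps`` uniform steps (the training-style integrator).
    """
    y0 = np.asarray(y0, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if y0.shape != (len(model.state_names),):
        raise ValueError("y0 dimension mismatch")
    if np.any(y0 < 0):
        raise ValueError("initial state must be nonnegative")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    rhs = compile_rhs(model)

    if mode == "fixed":
        t0, t1 = float(t_grid[0]), float(t_grid[-1])
        h = (t1 - t0) / fixed_steps
        ts = [t0]
        ys = [y0]
        y = y0.copy()
        t = t0
        for _ in range(fixed_steps):
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            if not np.all(np.isfinite(y)):
                raise SimulationError(f"non-finite state at t = {t:.3f} h")
            ts.append(t)
            ys.append(y.copy())
        dense = np.array(ys)
        # linear interpolation of the fixed grid onto the requested times
        out = np.empty((len(t_grid), len(y0)))
        for i in range(len(y0)):
            out[:, i] = np.interp(t_grid, ts, dense[:, i])
        return out

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, method="RK45",
                    t_eval=t_grid, rtol=rtol, atol=atol)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        reached = sol.t[-1] if sol.t.size else t_grid[0]
        raise SimulationError(f"integration failed near t = {reached:.3f} h: {sol.message}")
    return sol.y.T


@dataclass
class Experiment:
    """One batch: known initial condition, sample times, noisy observations."""

    y0: np.ndarray
    sample_times: np.ndarray
    observations: np.ndarray  # shape (ni, n_states)

    def __post_init__(self) -> None:
        self.y0 = np.asarray(self.y0, dtype=float)
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.observations = np.asarray(self.observations, dtype=float)
        if self.sample_times[0] != 0 or np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample_times must start at 0 and strictly increase")
        if self.observations.shape[0] != self.sample_times.shape[0]:
            raise ValueError("observation rows must match sample times")


@dataclass
class ExperimentDataset:
    """Collection of batch experiments with provenance metadata."""

    state_names: tuple[str, ...]
    experiments: list[Experiment]
    noise_sd_fraction: float = 0.0
    seed: int | None = None

    @property
    def ne(self) -> int:
        return len(self.experiments)

    @property
    def ni(self) -> int:
        return len(self.experiments[0].sample_times)

    def state_maxima(self, floor: float = 1e-6) -> np.ndarray:
        """Per-state maximum observation over the dataset (normalization scale)."""
        stacked = np.concatenate([e.observations for e in self.experiments], axis=0)
        return np.maximum(stacked.max(axis=0), floor)

    def extended(self, experiment: Experiment) -> "ExperimentDataset":
        return ExperimentDataset(self.state_names,
                                 list(self.experiments) + [experiment],
                                 self.noise_sd_fraction, self.seed)


def default_sample_times(horizon: float = casestudy.HORIZON_H,
                         interval: float = casestudy.SAMPLE_INTERVAL_H) -> np.ndarray:
    """Sampling grid t = 0, interval, ... up to (and excluding past) the horizon."""
    n = int(np.floor(horizon / interval))
    return np.arange(n + 1) * interval


def generate_dataset(model: KineticModel, n_experiments: int,
                     y0_ranges: Mapping[str, tuple[float, float]] | None = None,
                     horizon: float = casestudy.HORIZON_H,
                     interval: float = casestudy.SAMPLE_INTERVAL_H,
                     noise_sd: float = casestudy.NOISE_SD,
                     seed: int | np.random.Generator = 0) -> ExperimentDataset:
    """Draw initial conditions, simulate the model, and add observation noise.

    observation = truth × (1 + ε), ε ~ N(0, noise_sd²), clipped at zero.
    Bit-reproducible for a given integer seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    y0_ranges = dict(y0_ranges or casestudy.Y0_RANGES)
    for name in model.state_names:
        lo, hi = y0_ranges[name]
        if hi < lo:
            raise ValueError(f"empty y0 range for {name}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = default_sample_times(horizon, interval)
    experiments = []
    for _ in range(n_experiments):
        y0 = np.array([rng.uniform(*y0_ranges[s]) for s in model.state_names])
        truth = simulate(model, y0, times)
        eps = rng.normal(0.0, noise_sd, size=truth.shape) if noise_sd > 0 else 0.0
        obs = np.clip(truth * (1.0 + eps), 0.0, None)
        experiments.append(Experiment(y0, times, obs))
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    return ExperimentDataset(model.state_names, experiments, noise_sd, seed_val)


def mape(predicted: np.ndarray, observed: np.ndarray,
         floor: np.ndarray | float | None = None) -> float:
    """Mean absolute percentage error (%) with a floored denominator.

    The default floor is 1 % of each state's maximum over ``observed`` so
    that early-batch near-zero product concentrations cannot dominate.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("shape mismatch")
    if np.all(observed == 0):
        raise ValueError("all-zero observations")
    if floor is None:
        floor = 0.01 * np.abs(observed).max(axis=tuple(range(observed.ndim - 1)))
        floor = np.maximum(floor, 1e-12)
    denom = np.maximum(np.abs(observed), floor)
    return float(100.0 * np.mean(np.abs(predicted - observed) / denom))


# -- CSV / JSON I/O --------------------------------------------------------


def dataset_to_csv(dataset: ExperimentDataset, csv_path: str | Path,
                   meta: dict | None = None) -> None:
    rows = []
    for e_id, exp in enumerate(dataset.experiments):
        for t, obs in zip(exp.sample_times, exp.observations):
            rows.append({"experiment_id": e_id, "time_h": t,
                         **{s: v for s, v in zip(dataset.state_names, obs)}})
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    meta_out = {"state_names": list(dataset.state_names),
                "noise_sd_fraction": dataset.noise_sd_fraction,
                "seed": dataset.seed,
                "y0": [list(map(float, e.y0)) for e in dataset.experiments]}
    if meta:
        meta_out.update(meta)
    Path(csv_path).with_suffix(".json").write_text(json.dumps(meta_out, indent=2))


def dataset_from_csv(csv_path: str | Path) -> ExperimentDataset:
    df = pd.read_csv(csv_path)
    meta_path = Path(csv_path).with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    state_names = tuple(meta.get("state_names")
                        or [c for c in df.columns if c not in ("experiment_id", "time_h")])
    experiments = []
    for e_id, grp in df.groupby("experiment_id"):
        grp = grp.sort_values("time_h")
        times = grp["time_h"].to_numpy()
        obs = grp[list(state_names)].to_numpy()
        y0_list = meta.get("y0")
        y0 = np.array(y0_list[int(e_id)]) if y0_list else obs[0]
        experiments.append(Experiment(y0, times, obs))
    return ExperimentDataset(state_names, experiments,
                             meta.get("noise_sd_fraction", 0.0), meta.get("seed"))
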