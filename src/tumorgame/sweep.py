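"""Payoff-sweep experiments: growth velocity and roughness velocity grids.

For every combination of the proliferative-proliferative inhibition magnitude
``alpha_pp`` and the invasive-invasive enhancement ``beta_ii``, a number of
independent trials are simulated and two velocities are fit per trial by OLS
after the burn-in window: the front growth velocity ``v`` (slope of the mean
front radius over time) and the roughness velocity ``v_r`` (slope of the
global surface roughness R(t)).  Trials that touch the lattice edge before
``t_max`` are fit on the available window and flagged ``halted_early``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dynamics import run_simulation
from .metrics import MetricError, fit_slope, records_to_frame
from .world import PayoffMatrix, SimulationConfig

__all__ = ["SweepSpec", "trial_seed", "run_trial", "run_sweep", "aggregate_sweep"]

_RESULT_COLUMNS = ["alpha_pp", "beta_ii", "trial", "seed", "v", "v_r", "halted_early"]


@dataclasses.dataclass(frozen=True)
class SweepSpec:
    """Grid of payoff magnitudes to simulate, plus the shared base config."""

    alpha_pp_values: tuple[float, ...]
    beta_ii_values: tuple[float, ...]
    n_trials: int = 10
    base_config: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not self.alpha_pp_values or not self.beta_ii_values:
            raise ValueError("sweep value lists must be non-empty")
        if any(a < 0 for a in self.alpha_pp_values) or any(
            b < 0 for b in self.beta_ii_values
        ):
            raise ValueError("alpha_pp and beta_ii are magnitudes and must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def trial_seed(base_seed: int, i_alpha: int, i_beta: int, trial: int) -> int:
    """Deterministic, collision-free per-trial seed below 2**31.

    Derived through a seed sequence keyed on the base seed and the grid-point
    and trial indices, so no two (grid point, trial) pairs share a stream.
    """
    ss = np.random.SeedSequence([int(base_seed), int(i_alpha), int(i_beta), int(trial)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_trial(config: SimulationConfig) -> tuple[float, float, bool]:
    """One simulation -> (v, v_r, halted_early); NaN when a fit is impossible."""
    result = run_simulation(config)
    frame = records_to_frame(result.records)
    try:
        v = fit_slope(frame["t"], frame["mean_front_radius"], config.burn_in)
    except MetricError:
        v = float("nan")
    try:
        v_r = fit_slope(frame["t"], frame["roughness"], config.burn_in)
    except MetricError:
        v_r = float("nan")
    return v, v_r, result.halted_early


def run_sweep(
    spec: SweepSpec,
    out_csv: str | Path | None = None,
    resume: bool = True,
    progress: Callable[[str], None] | None = None,
) -> pd.DataFrame:
    """Run every (alpha_pp, beta_ii, trial) combination of the sweep.

    With ``out_csv`` the result table is written incrementally after each
    trial, and ``resume`` skips (grid point, trial) rows already present in
    that file — an interrupted sweep restarted with the same spec converges
    to the same table as an uninterrupted one.
    """
    done: set[tuple[float, float, int]] = set()
    rows: list[dict] = []
    if out_csv is not None and resume and Path(out_csv).exists():
        previous = pd.read_csv(out_csv)
        for rec in previous.to_dict("records"):
            done.add((float(rec["alpha_pp"]), float(rec["beta_ii"]), int(rec["trial"])))
            rows.append(rec)
    for ia, alpha in enumerate(spec.alpha_pp_values):
        for ib, beta in enumerate(spec.beta_ii_values):
            payoff = PayoffMatrix.from_magnitudes(
                alpha_pp=alpha,
                beta_ii=beta,
                alpha_pi=spec.base_config.payoff.a_pi,
                beta_ip=spec.base_config.payoff.b_ip,
            )
            for trial in range(spec.n_trials):
                key = (float(alpha), float(beta), trial)
                if key in done:
                    continue
                seed = trial_seed(spec.base_config.seed, ia, ib, trial)
                config = spec.base_config.replace(payoff=payoff, seed=seed)
                v, v_r, halted = run_trial(config)
                rows.append(
                    {
                        "alpha_pp": float(alpha),
                        "beta_ii": float(beta),
                        "trial": trial,
                        "seed": seed,
                        "v": v,
                        "v_r": v_r,
                        "halted_early": halted,
                    }
                )
                if out_csv is not None:
                    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(
                        out_csv, index=False
                    )
                if progress is not None:
                    progress(
                        f"alpha_pp={alpha:g} beta_ii={beta:g} trial={trial} "
                        f"v={v:.3f} v_r={v_r:.3f}"
                    )
    frame = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    frame = frame.sort_values(["alpha_pp", "beta_ii", "trial"]).reset_index(drop=True)
    return frame


def aggregate_sweep(results: pd.DataFrame) -> pd.DataFrame:
    """Per-grid-point trial means <v> and <v_r> (NaN-fits excluded)."""
    return (
        results.groupby(["alpha_pp", "beta_ii"], as_index=False)
        .agg(v_mean=("v", "mean"), v_r_mean=("v_r", "mean"), n_trials=("trial", "count"))
    )
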