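"""Experiment grids: scenarios x extrinsic mortalities x replicates.

The reference design crosses the five mutational-architecture scenarios
with extrinsic hazards 0.0 and 0.2, 20 replicates per cell, at
N = 1000 colonies and T = 10^6 steps (the ``full`` preset).  The ``desk``
preset (N = 100, T = 5 x 10^4, 5 replicates) preserves the qualitative
selection regime — colony turnover much faster than the simulation
horizon — at minutes-per-replicate runtime for interactive work.

Replicate seeds are derived from the master seed through a cell-addressed
splitting rule (scenario, h_ext, rho, delay, bias, replicate index), so
per-cell results do not depend on grid execution order.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .architecture import SCENARIOS, ConfigurationError
from .simulation import Parameters, ReplicateResult, run, write_outputs

logger = logging.getLogger("casteage")

__all__ = [
    "PRESETS",
    "ExperimentGrid",
    "cell_seed",
    "run_grid",
    "aggregate",
    "compare_castes",
    "curves_frame",
    "plot_survival_curves",
]

#: Scale presets: (n_colonies, t_steps, replicates).
PRESETS = {
    "full": {"n_colonies": 1000, "t_steps": 1_000_000, "replicates": 20},
    "desk": {"n_colonies": 100, "t_steps": 50_000, "replicates": 5},
}


@dataclass
class ExperimentGrid:
    """A factorial design over scenarios and parameter values."""

    scenarios: tuple = SCENARIOS
    h_ext_values: tuple = (0.0, 0.2)
    rho_values: tuple = (-0.8,)
    delay_values: tuple = (5,)
    bias_values: tuple = (-0.2,)
    replicates: int = 5
    preset: str = "desk"
    base_params: Parameters | None = None

    def __post_init__(self) -> None:
        if not self.scenarios or not self.h_ext_values:
            raise ConfigurationError("grid must name at least one scenario and h_ext")
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ConfigurationError(f"unknown scenarios: {sorted(unknown)}")
        if self.preset not in PRESETS:
            raise ConfigurationError(f"unknown preset {self.preset!r}")
        if self.replicates < 1:
            raise ConfigurationError("need at least one replicate")

    def cells(self):
        return list(itertools.product(self.scenarios, self.h_ext_values,
                                      self.rho_values, self.delay_values,
                                      self.bias_values))

    def cell_params(self, scenario, h_ext, rho, delay, bias) -> Parameters:
        preset = PRESETS[self.preset]
        base = self.base_params.to_dict() if self.base_params else {}
        base.update(n_colonies=preset["n_colonies"], t_steps=preset["t_steps"],
                    scenario=scenario, h_ext=h_ext, rho=rho, delay=delay, b=bias)
        return Parameters.from_dict(base)


def cell_seed(master_seed: int, scenario: str, h_ext: float, rho: float,
              delay: int, bias: float, replicate: int) -> np.random.SeedSequence:
    """Deterministic, cell-addressed seed derivation (order-independent)."""
    ints = [
        int(master_seed),
        SCENARIOS.index(scenario),
        int(round(h_ext * 10_000)),
        int(round((rho + 2.0) * 10_000)),   # shift: SeedSequence wants non-negatives
        int(delay),
        int(round((bias + 100.0) * 10_000)),
        int(replicate),
    ]
    return np.random.SeedSequence(ints)


def run_grid(grid: ExperimentGrid, master_seed: int,
             outdir: Path | None = None,
             replicate_hook=None) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run every cell x replicate; return (raw, aggregate, provenance).

    ``raw`` holds one summary row per replicate x caste; ``aggregate``
    per-cell medians and ranges (order statistics over replicates).
    Extinct replicates are recorded in the provenance, not fatal.
    """
    rows = []
    extinctions = []
    for scenario, h_ext, rho, delay, bias in grid.cells():
        params = grid.cell_params(scenario, h_ext, rho, delay, bias)
        for rep in range(grid.replicates):
            seed = cell_seed(master_seed, scenario, h_ext, rho, delay, bias, rep)
            result = run(params, seed)
            if replicate_hook is not None:
                replicate_hook(result, rep)
            if result.extinct or result.summary is None:
                extinctions.append({"scenario": scenario, "h_ext": h_ext,
                                    "rho": rho, "delay": delay, "bias": bias,
                                    "replicate": rep,
                                    "step": result.extinct_step})
                logger.info("cell (%s, h_ext=%s) replicate %d extinct",
                            scenario, h_ext, rep)
                continue
            summ = result.summary.copy()
            summ["replicate"] = rep
            summ["rho"] = rho
            summ["delay"] = delay
            summ["bias"] = bias
            summ["equilibrium"] = result.equilibrium
            rows.append(summ)
            if outdir is not None:
                cell_dir = (Path(outdir) / f"{scenario}_h{h_ext}" / f"rep{rep}")
                write_outputs(result, cell_dir)
    raw = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    agg = aggregate(raw)
    provenance = {
        "master_seed": int(master_seed),
        "preset": grid.preset,
        "replicates": grid.replicates,
        "cells": [list(c) for c in grid.cells()],
        "extinctions": extinctions,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        raw.to_csv(outdir / "aggregate_raw.csv", index=False)
        agg.to_csv(outdir / "aggregate.csv", index=False)
        if not raw.empty:
            k = int(grid.cell_params(*grid.cells()[0]).k)
            curves_frame(raw, k=k).to_csv(outdir / "curves.csv", index=False)
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return raw, agg, provenance


def curves_frame(raw: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Long-format mean trait curves: one row per cell x replicate x caste
    x age, with ``mean_survival`` and ``mean_fecundity`` columns."""
    if raw.empty:
        return pd.DataFrame()
    keys = [c for c in _CELL_KEYS if c in raw.columns] + ["replicate"]
    rows = []
    for _, r in raw.iterrows():
        for age in range(1, k + 1):
            rows.append({**{c: r[c] for c in keys}, "age": age,
                         "mean_survival": r[f"surv_a{age}"],
                         "mean_fecundity": r[f"fec_a{age}"]})
    return pd.DataFrame(rows)


_CELL_KEYS = ["scenario", "h_ext", "rho", "delay", "bias", "caste"]
_METRICS = ["life_expectancy", "lifetime_fecundity",
            "lifespan_proportion", "fecundity_proportion"]


def aggregate(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-cell median, min and max over replicates for each metric."""
    if raw.empty:
        return pd.DataFrame()
    agg = raw.groupby(_CELL_KEYS)[_METRICS].agg(["median", "min", "max"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


def compare_castes(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-cell queen-worker life-expectancy divergence.

    Returns the queen minus worker median difference, the queen/worker
    ratio of medians, and the count of replicates in which the queen
    outlives the worker.
    """
    if raw.empty:
        return pd.DataFrame()
    keys = [c for c in _CELL_KEYS if c != "caste"]
    wide = raw.pivot_table(index=keys + ["replicate"], columns="caste",
                           values="life_expectancy")
    if "queen" not in wide or "worker" not in wide:
        raise ConfigurationError("both castes are required per cell")
    if wide[["queen", "worker"]].isna().any().any():
        raise ConfigurationError("both castes are required per cell")
    rows = []
    for key, grp in wide.groupby(level=keys):
        q_med = float(grp["queen"].median())
        w_med = float(grp["worker"].median())
        rows.append(dict(zip(keys, key)) | {
            "queen_minus_worker": q_med - w_med,
            "queen_worker_ratio": q_med / w_med if w_med else np.inf,
            "n_replicates": len(grp),
            "n_queen_longer": int((grp["queen"] > grp["worker"]).sum()),
        })
    return pd.DataFrame(rows)


def plot_survival_curves(raw: pd.DataFrame, path, k: int = 20) -> None:
    """Quick-look plot: per-scenario median intrinsic survival curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    surv_cols = [f"surv_a{a}" for a in range(1, k + 1)]
    scenarios = sorted(raw["scenario"].unique())
    fig, axes = plt.subplots(1, len(scenarios), figsize=(3 * len(scenarios), 3),
                             sharey=True, squeeze=False)
    ages = np.arange(1, k + 1)
    for ax, scen in zip(axes[0], scenarios):
        sub = raw[raw["scenario"] == scen]
        for caste, color in (("queen", "tab:purple"), ("worker", "tab:orange")):
            curves = sub[sub["caste"] == caste][surv_cols].to_numpy()
            if curves.size:
                ax.plot(ages, np.median(curves, axis=0), color=color, label=caste)
        ax.set_title(scen)
        ax.set_xlabel("age class")
    axes[0][0].set_ylabel("intrinsic survival")
    axes[0][0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
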