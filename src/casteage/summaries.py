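"""Outcome measures computed from a population.

Evolved lifespan is the area under the discrete survivorship curve built
from the population-mean intrinsic survival probabilities,

    LE = sum_{a=1..k} prod_{j<=a} s_j,

so a curve of all ones gives exactly ``k`` (extrinsic mortality is not
part of this measure).  Lifetime fecundity is the plain sum of the
population-mean age-specific fecundities, unweighted by survivorship,
with maximum ``k * m``.  Both are transformed to proportions of their
maxima for downstream statistics (e.g. beta regression, which this
package deliberately does not reimplement).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .architecture import CASTES, ConfigurationError

__all__ = [
    "EmptyPopulationError",
    "population_mean_traits",
    "life_expectancy",
    "lifetime_fecundity",
    "proportion_transform",
    "summarize_population",
]


class EmptyPopulationError(RuntimeError):
    """No living individuals available to average over."""


def population_mean_traits(population, caste: str) -> tuple[np.ndarray, np.ndarray]:
    """Population-mean expressed trait curves for one caste.

    Queen-caste means average over living queens' genomes, worker-caste
    means over living workers' genomes; in both cases the genome is
    expressed for that caste and the expressed (not realized) curves are
    averaged arithmetically per age class.
    """
    if caste not in CASTES:
        raise ConfigurationError(f"unknown caste {caste!r}")
    layout = population.layout
    m = population.params.m
    if caste == "queen":
        alive = population.q_alive
        if not alive.any():
            raise EmptyPopulationError("no living queens")
        sums = population.q_geno[alive].sum(axis=1)
    else:
        if population.w_sums.shape[0] == 0:
            raise EmptyPopulationError("no living workers")
        sums = population.w_sums
    surv = expit(sums[:, layout.block_slice(caste, "survival")]).mean(axis=0)
    fec = (m * expit(sums[:, layout.block_slice(caste, "fecundity")])).mean(axis=0)
    return surv, fec


def life_expectancy(mean_survival: np.ndarray) -> float:
    """Area under the discrete survivorship curve; maximum ``k``."""
    s = np.asarray(mean_survival, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("survival probabilities must lie in [0, 1]")
    return float(np.cumprod(s).sum())


def lifetime_fecundity(mean_fecundity: np.ndarray) -> float:
    """Sum of age-specific fecundities (no survivorship weighting)."""
    return float(np.asarray(mean_fecundity, dtype=float).sum())


def proportion_transform(life_exp: float, lifetime_fec: float,
                         k: int, m: float) -> tuple[float, float]:
    """Scale lifespan by ``k`` and lifetime fecundity by ``k * m``."""
    if k <= 0 or m <= 0:
        raise ConfigurationError("k and m must be positive")
    return life_exp / k, lifetime_fec / (k * m)


def summarize_population(population, replicate: int | None = None) -> pd.DataFrame:
    """One summary row per caste for a population's current state.

    Columns: replicate, scenario, h_ext, caste, life_expectancy,
    lifetime_fecundity, lifespan_proportion, fecundity_proportion, and the
    per-age mean curves as ``surv_a*`` / ``fec_a*`` columns.
    """
    p = population.params
    rows = []
    for caste in CASTES:
        surv, fec = population_mean_traits(population, caste)
        le = life_expectancy(surv)
        lf = lifetime_fecundity(fec)
        ple, plf = proportion_transform(le, lf, p.k, p.m)
        row = {
            "replicate": replicate,
            "scenario": p.scenario,
            "h_ext": p.h_ext,
            "caste": caste,
            "life_expectancy": le,
            "lifetime_fecundity": lf,
            "lifespan_proportion": ple,
            "fecundity_proportion": plf,
        }
        row.update({f"surv_a{a+1}": surv[a] for a in range(p.k)})
        row.update({f"fec_a{a+1}": fec[a] for a in range(p.k)})
        rows.append(row)
    return pd.DataFrame(rows)
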