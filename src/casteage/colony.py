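"""Per-colony, per-time-step economics.

A queen splits her time between foraging (fraction ``z``) and egg laying
(``1 - z``).  Colony resources are ``R = z + w`` with ``w`` foraging
workers (queens and workers forage equally well); eggs laid are
``E = f_a (1 - z)`` with ``f_a`` the queen's age-specific fecundity.  Per-
egg survival rises with resources per egg as ``g(x) = x / (1 + x)``, so
the expected offspring number is ``F = E R / (E + R)``.  The queen's
foraging fraction maximizes ``F``: setting ``dF/dz = 0`` gives
``E = sqrt(f_a) R`` and hence ``z = max(0, 1 - (1+w)/(1+sqrt(f_a)))``,
clamped at zero once the worker force covers the colony's resource
needs.  Realized offspring are Poisson-distributed around ``F``.

Foraging exposes an individual to the age-independent extrinsic hazard
``h_ext`` for the fraction of time it forages: the death probability is
``d_ext = 1 - (1 - h_ext)**z``.  Workers always forage (``z = 1``), so
their extrinsic death probability is ``h_ext``; a queen with enough
workers stays in the nest (``z = 0``) and is fully shielded.  Survival of
a step is a single Bernoulli draw with parameter ``s_a(C) * (1 - d_ext)``.

All functions accept scalars or numpy arrays (elementwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ColonyStepOutcome",
    "foraging_time",
    "resources",
    "eggs_laid",
    "expected_offspring",
    "realize_offspring",
    "foraging_death_prob",
    "survive_step",
    "colony_step_outcome",
]


def foraging_time(f_a, w):
    """Optimal queen foraging fraction ``max(0, 1 - (1+w)/(1+sqrt(f_a)))``."""
    f_a = np.asarray(f_a, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(f_a < 0) or np.any(w < 0):
        raise ValueError("fecundity and worker count must be non-negative")
    z = np.maximum(0.0, 1.0 - (1.0 + w) / (1.0 + np.sqrt(f_a)))
    return z if z.ndim else float(z)


def resources(z, w):
    """Colony resources in worker-equivalents: ``R = z + w``."""
    r = np.asarray(z, dtype=float) + np.asarray(w, dtype=float)
    return r if r.ndim else float(r)


def eggs_laid(f_a, z):
    """Eggs laid per step: ``E = f_a * (1 - z)`` (a real-valued intensity)."""
    e = np.asarray(f_a, dtype=float) * (1.0 - np.asarray(z, dtype=float))
    return e if e.ndim else float(e)


def expected_offspring(E, R):
    """Expected offspring ``F = E R / (E + R)``; 0 when both inputs are 0."""
    E = np.asarray(E, dtype=float)
    R = np.asarray(R, dtype=float)
    tot = E + R
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(tot > 0, E * R / np.where(tot > 0, tot, 1.0), 0.0)
    return F if F.ndim else float(F)


def realize_offspring(F_mean, rng: np.random.Generator):
    """Realized offspring count: Poisson with mean ``F_mean``."""
    return rng.poisson(F_mean)


def foraging_death_prob(h_ext, z):
    """Extrinsic death probability ``d_ext = 1 - (1 - h_ext)**z``."""
    d = 1.0 - (1.0 - np.asarray(h_ext, dtype=float)) ** np.asarray(z, dtype=float)
    return d if d.ndim else float(d)


def survive_step(intrinsic_s, d_ext, rng: np.random.Generator):
    """Bernoulli survival with parameter ``s_a(C) * (1 - d_ext)``."""
    p = np.asarray(intrinsic_s, dtype=float) * (1.0 - np.asarray(d_ext, dtype=float))
    draw = rng.random(p.shape) < p
    return draw if p.ndim else bool(draw)


@dataclass
class ColonyStepOutcome:
    """All per-step quantities for one colony's reproduction phase."""

    z: float
    R: float
    E: float
    F_mean: float
    n_offspring: int
    n_males: int
    d_ext_queen: float


def colony_step_outcome(f_a: float, w: int, h_ext: float,
                        rng: np.random.Generator) -> ColonyStepOutcome:
    """Run one colony's reproduction economics for a step.

    One haploid (male) egg accompanies every realized diploid offspring,
    so ``n_males == n_offspring``.
    """
    z = foraging_time(f_a, w)
    R = resources(z, w)
    E = eggs_laid(f_a, z)
    F = expected_offspring(E, R)
    n = int(realize_offspring(F, rng))
    d = foraging_death_prob(h_ext, z)
    return ColonyStepOutcome(z=z, R=R, E=E, F_mean=F, n_offspring=n,
                             n_males=n, d_ext_queen=d)
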