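"""Genomes and their expression into caste-specific life-history traits.

An individual's regulatory state is a vector of ``4k`` unbounded real
genetic values (queen survival, queen fecundity, worker survival, worker
fecundity — ``k`` age classes each).  Diploids carry two such haploid
networks; the two allelic values at a locus interact additively, and the
sum is pushed through a logistic map to give an age-specific survival
probability in ``[0, 1]`` or a fecundity in ``[0, m]``:

    s_a(C) = logistic(x_a + y_a)          f_a(C) = m * logistic(x_a + y_a)

Gametes are by default whole-network copies of one parental haplotype
(the network is transmitted as a unit); a free-recombination mode that
draws each locus independently is available for sensitivity checks.
Each transmitted network mutates with probability ``mu``: at most one
mutation event, a single multivariate-normal draw perturbing all ``4k``
coordinates at once according to the mutational architecture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .architecture import (
    CASTES,
    ConfigurationError,
    MutationArchitecture,
    TraitIndexLayout,
    sample_mutation,
)

__all__ = [
    "HaploidNetwork",
    "DiploidGenome",
    "ExpressedTraits",
    "express",
    "make_gamete",
    "mutate",
    "founder_genome",
    "gametes_batch",
    "mutate_batch",
]


@dataclass
class HaploidNetwork:
    """One gamete's regulatory state: 4k real genetic values."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size % 4:
            raise ConfigurationError("haploid network must be a flat vector of length 4k")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("genetic values must be finite")

    @property
    def k(self) -> int:
        return self.values.size // 4

    @property
    def layout(self) -> TraitIndexLayout:
        return TraitIndexLayout(self.k)


@dataclass
class DiploidGenome:
    """Two haploid networks sharing one layout."""

    copy_a: HaploidNetwork
    copy_b: HaploidNetwork

    def __post_init__(self) -> None:
        if self.copy_a.k != self.copy_b.k:
            raise ConfigurationError(
                f"genome copies disagree on k: {self.copy_a.k} vs {self.copy_b.k}"
            )

    @property
    def k(self) -> int:
        return self.copy_a.k

    def allelic_sums(self) -> np.ndarray:
        return self.copy_a.values + self.copy_b.values


@dataclass
class ExpressedTraits:
    """Caste-specific expressed phenotype: k survival probabilities, k fecundities."""

    survival: np.ndarray
    fecundity: np.ndarray


def express(genome: DiploidGenome, caste: str, m: float = 5.0) -> ExpressedTraits:
    """Express a diploid genome for one caste.

    Reads only that caste's survival and fecundity blocks; the other
    caste's loci never influence the result.
    """
    if caste not in CASTES:
        raise ConfigurationError(f"unknown caste {caste!r}")
    layout = genome.copy_a.layout
    sums = genome.allelic_sums()
    surv = expit(sums[layout.block_slice(caste, "survival")])
    fec = m * expit(sums[layout.block_slice(caste, "fecundity")])
    return ExpressedTraits(survival=surv, fecundity=fec)


def make_gamete(genome: DiploidGenome, rng: np.random.Generator,
                recombination: bool = False) -> HaploidNetwork:
    """Form one gamete: a copy of one haplotype, or per-locus draws."""
    stacked = np.stack([genome.copy_a.values, genome.copy_b.values])
    out = gametes_batch(stacked[None, :, :], rng, recombination=recombination)
    return HaploidNetwork(out[0])


def mutate(gamete: HaploidNetwork, mu: float, architecture: MutationArchitecture,
           rng: np.random.Generator) -> HaploidNetwork:
    """With probability ``mu``, add one sampled mutational effect vector."""
    if not 0.0 <= mu <= 1.0:
        raise ConfigurationError(f"mu must lie in [0, 1], got {mu}")
    if rng.random() < mu:
        return HaploidNetwork(gamete.values + sample_mutation(architecture, rng))
    return HaploidNetwork(gamete.values.copy())


def founder_genome(k: int, init_value: float = 0.0) -> DiploidGenome:
    """Homozygous founder: every locus on both copies equals ``init_value``."""
    if not np.isfinite(init_value):
        raise ConfigurationError("init_value must be finite")
    vals = np.full(4 * k, float(init_value))
    return DiploidGenome(HaploidNetwork(vals.copy()), HaploidNetwork(vals.copy()))


# ---------------------------------------------------------------------------
# Vectorized kernels (used by the population engine; the object API above
# wraps these so both code paths share one implementation).
# ---------------------------------------------------------------------------

def gametes_batch(genomes: np.ndarray, rng: np.random.Generator,
                  recombination: bool = False,
                  rows: np.ndarray | None = None) -> np.ndarray:
    """Form one gamete per diploid genome.

    ``genomes`` has shape ``(n, 2, 4k)``.  Default: uniformly pick one
    whole haplotype per genome.  Free recombination: pick the haplotype
    independently at every locus.  ``rows`` selects source genomes (with
    repetition allowed) without materialising an intermediate copy.
    """
    if genomes.ndim != 3 or genomes.shape[1] != 2:
        raise ConfigurationError("genomes must have shape (n, 2, 4k)")
    L = genomes.shape[2]
    if rows is None:
        rows = np.arange(genomes.shape[0])
    n = rows.size
    if recombination:
        pick = rng.integers(0, 2, size=(n, L))
        return genomes[rows[:, None], pick, np.arange(L)[None, :]]
    pick = rng.integers(0, 2, size=n)
    return genomes[rows, pick, :]


def mutate_batch(gametes: np.ndarray, mu: float,
                 architecture: MutationArchitecture,
                 rng: np.random.Generator) -> np.ndarray:
    """Independently mutate each transmitted network with probability ``mu``.

    Mutates in place and returns the array.  Each mutated network gets
    exactly one MVN effect vector added to all its coordinates.
    """
    n = gametes.shape[0]
    if n == 0 or mu == 0.0:
        return gametes
    hit = rng.random(n) < mu
    nhit = int(hit.sum())
    if nhit:
        gametes[hit] += sample_mutation(architecture, rng, size=nhit)
    return gametes
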