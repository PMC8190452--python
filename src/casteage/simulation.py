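"""Population-level simulation: N colony slots through T discrete steps.

The population holds a fixed number of colony slots.  Each colony is
monogynous: one singly mated queen (with her stored mate's haploid
network), a worker roster, and two egg pools (eggs develop for one step
before hatching).  Every time step executes, in order:

1.  **Reproduce** — each living queen allocates time via the colony
    economics, lays diploid eggs (maternal gamete x stored sperm; every
    transmitted network passes through the mutation operator) and one
    haploid (male) egg per realized diploid offspring.  Males mature and
    die within the step; they exist only as a mating pool.
2.  **Survive/age** — workers face their intrinsic age-specific survival
    times the full extrinsic hazard (they always forage); the queen faces
    hers times the foraging exposure implied by the ``z`` she used this
    step.  Individuals at the maximum age die.  Survivors age one class.
3.  **Requeen** — each empty slot draws a source colony with probability
    proportional to its hatching-egg count (eggs laid by a queen who died
    this step still count: they are in the nest and a daughter queen can
    hatch from them), withdraws one egg as the new queen (age 1), and
    mates her with a male drawn uniformly from this step's population-wide
    male pool.  If no hatching eggs exist anywhere, the current-step egg
    cohort is used as a fallback (logged).
4.  **Collapse** — a colony whose queen died loses all remaining members:
    its workers die (step 2) and its leftover brood is destroyed, whether
    or not an unrelated new queen takes over the empty slot.
5.  **Hatch** — remaining hatching eggs become age-1 workers in their
    natal colonies; this step's eggs become the next step's hatching pool.

Simulations start from identical singly mated founding queens with no
workers; a founding queen must forage herself (``w = 0`` gives ``z > 0``),
so she is exposed to the extrinsic hazard until workers shield her.

The engine is vectorized struct-of-arrays numpy: queens live in fixed
per-slot arrays, workers in an append-only store with a live-row index
that is compacted periodically (workers never reproduce, so their genomes
are kept as diploid allelic sums).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import summaries as sm
from .architecture import (
    SCENARIOS,
    ConfigurationError,
    MutationArchitecture,
    TraitIndexLayout,
)
from .genome import gametes_batch, mutate_batch

logger = logging.getLogger("casteage")

__all__ = [
    "Parameters",
    "Extinction",
    "MatingFailure",
    "PopulationState",
    "ReplicateResult",
    "requeen",
    "step",
    "run",
    "write_outputs",
]


@dataclass
class Parameters:
    """Full simulation parameter set.

    Defaults are the reference study conditions: 1000 colonies, 10^6
    steps, 20 age classes, mutation rate 0.005, mutation bias -0.2 with
    sd 0.4, partial correlation -0.8, effect delay 5, maximum fecundity 5.
    ``init_value`` sets every founder genetic value; the default 1.0
    starts the population at survival expit(2) ~ 0.88 and fecundity
    ~ 4.40 per age class — an intermediate ancestral phenotype that is
    demographically robust even under extrinsic hazard 0.2, yet whose
    survivorship declines steeply enough with age that the force of
    selection falls with age: early-age survival can be lifted by
    selection while rarely-reached old ages decay under biased mutation.
    """

    n_colonies: int = 1000
    t_steps: int = 1_000_000
    k: int = 20
    h_ext: float = 0.0
    mu: float = 0.005
    b: float = -0.2
    sigma: float = 0.4
    rho: float = -0.8
    delay: int = 5
    m: float = 5.0
    scenario: str = "baseline"
    init_value: float = 1.0
    recombination: bool = False
    checkpoint_interval: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_colonies < 2:
            raise ConfigurationError("need at least 2 colonies")
        if self.t_steps < 1:
            raise ConfigurationError("t_steps must be >= 1")
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.k <= self.delay:
            raise ConfigurationError(
                f"k must exceed delay (k={self.k}, delay={self.delay})")
        if not 0.0 <= self.mu <= 1.0:
            raise ConfigurationError("mu must lie in [0, 1]")
        if not 0.0 <= self.h_ext < 1.0:
            raise ConfigurationError("h_ext must lie in [0, 1)")
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")
        if self.m <= 0:
            raise ConfigurationError("m must be > 0")
        if not np.isfinite(self.init_value):
            raise ConfigurationError("init_value must be finite")

    @property
    def effective_checkpoint_interval(self) -> int:
        if self.checkpoint_interval is not None:
            return max(1, int(self.checkpoint_interval))
        return max(1, self.t_steps // 200)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Parameters":
        return cls(**d)


class Extinction(RuntimeError):
    """The population went globally extinct (no queens, no eggs)."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"population extinct at step {step}")


class MatingFailure(Extinction):
    """A new queen had to mate but the male pool was empty."""

    def __init__(self, step: int):
        super().__init__(step, f"no males available for mating at step {step}")


class _WorkerStore:
    """Append-only worker arrays with a live-row index.

    Rows are appended when eggs hatch and dropped from ``live`` when
    workers die; the backing arrays are compacted when dead rows dominate,
    keeping per-step cost proportional to births and deaths rather than
    to the standing worker population's genome size.
    """

    def __init__(self, L: int, k: int, capacity: int = 1024):
        self.L, self.k = L, k
        self.col = np.empty(capacity, dtype=np.int64)
        self.age = np.empty(capacity, dtype=np.int64)
        self.sums = np.empty((capacity, L))
        self.surv = np.empty((capacity, k))
        self.n = 0
        self.live = np.empty(0, dtype=np.int64)

    @property
    def size(self) -> int:
        return self.live.size

    def _grow(self, need: int) -> None:
        cap = self.col.size
        new_cap = max(2 * cap, self.n + need)
        for name in ("col", "age", "sums", "surv"):
            old = getattr(self, name)
            new = np.empty((new_cap,) + old.shape[1:], dtype=old.dtype)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)

    def append(self, cols: np.ndarray, sums: np.ndarray, surv: np.ndarray) -> None:
        n_new = cols.size
        if self.n + n_new > self.col.size:
            self._grow(n_new)
        sl = slice(self.n, self.n + n_new)
        self.col[sl] = cols
        self.age[sl] = 1
        self.sums[sl] = sums
        self.surv[sl] = surv
        self.live = np.concatenate([self.live, np.arange(self.n, self.n + n_new)])
        self.n += n_new

    def compact(self) -> None:
        if self.n <= max(1024, 3 * self.size):
            return
        m = self.size
        for name in ("col", "age", "sums", "surv"):
            arr = getattr(self, name)
            arr[:m] = arr[self.live]
        self.n = m
        self.live = np.arange(m, dtype=np.int64)


@dataclass
class PopulationState:
    """Struct-of-arrays state of the whole population.

    Queens live in fixed slot arrays (``q_*``, one entry per colony
    slot); workers and eggs in flat arrays carrying their colony id.
    Worker genomes are stored as diploid allelic sums (expression and
    summaries only ever need the sum; workers never transmit genes).
    """

    params: Parameters
    architecture: MutationArchitecture
    rng: np.random.Generator
    time: int = 0
    # queens (per colony slot)
    q_alive: np.ndarray = field(repr=False, default=None)
    q_age: np.ndarray = field(repr=False, default=None)
    q_geno: np.ndarray = field(repr=False, default=None)   # (N, 2, 4k)
    q_sperm: np.ndarray = field(repr=False, default=None)  # (N, 4k)
    # workers
    workers: _WorkerStore = field(repr=False, default=None)
    # egg pools (flat, diploid genomes)
    hatch_col: np.ndarray = field(repr=False, default=None)
    hatch_geno: np.ndarray = field(repr=False, default=None)  # (K, 2, 4k)
    cur_col: np.ndarray = field(repr=False, default=None)
    cur_geno: np.ndarray = field(repr=False, default=None)
    # per-step male pool (counts per source colony)
    male_count: np.ndarray = field(repr=False, default=None)
    # bookkeeping
    fallback_requeenings: int = 0
    events: list = field(default_factory=list, repr=False)

    @property
    def layout(self) -> TraitIndexLayout:
        return self.architecture.layout

    # live-worker views (copies) for summaries, dumps and tests
    @property
    def w_col(self) -> np.ndarray:
        return self.workers.col[self.workers.live].copy()

    @property
    def w_age(self) -> np.ndarray:
        return self.workers.age[self.workers.live].copy()

    @property
    def w_sums(self) -> np.ndarray:
        return self.workers.sums[self.workers.live].copy()

    @classmethod
    def initialize(cls, params: Parameters, rng: np.random.Generator,
                   founder_genomes: np.ndarray | None = None,
                   founder_sperm: np.ndarray | None = None) -> "PopulationState":
        """Found the population: N identical singly mated age-1 queens.

        ``founder_genomes`` (N, 2, 4k) and ``founder_sperm`` (N, 4k) let
        tests inject distinguishable founder haplotypes; by default every
        genetic value is ``params.init_value``.
        """
        arch = MutationArchitecture(scenario=params.scenario, k=params.k,
                                    rho=params.rho, delay=params.delay,
                                    b=params.b, sigma=params.sigma)
        if arch.repair.fired:
            logger.info(
                "PD repair fired for scenario %s (iterations=%d, frobenius=%.4g)",
                params.scenario, arch.repair.iterations,
                arch.repair.frobenius_distance,
            )
        N, L = params.n_colonies, 4 * params.k
        if founder_genomes is None:
            founder_genomes = np.full((N, 2, L), float(params.init_value))
        else:
            founder_genomes = np.array(founder_genomes, dtype=float)
        if founder_sperm is None:
            founder_sperm = np.full((N, L), float(params.init_value))
        else:
            founder_sperm = np.array(founder_sperm, dtype=float)
        if founder_genomes.shape != (N, 2, L) or founder_sperm.shape != (N, L):
            raise ConfigurationError("founder arrays have the wrong shape")
        return cls(
            params=params, architecture=arch, rng=rng, time=0,
            q_alive=np.ones(N, dtype=bool),
            q_age=np.ones(N, dtype=np.int64),
            q_geno=founder_genomes,
            q_sperm=founder_sperm,
            workers=_WorkerStore(L, params.k),
            hatch_col=np.empty(0, dtype=np.int64),
            hatch_geno=np.empty((0, 2, L)),
            cur_col=np.empty(0, dtype=np.int64),
            cur_geno=np.empty((0, 2, L)),
            male_count=np.zeros(N, dtype=np.int64),
        )

    def worker_counts(self) -> np.ndarray:
        ws = self.workers
        return np.bincount(ws.col[ws.live], minlength=self.params.n_colonies)

    def n_queens(self) -> int:
        return int(self.q_alive.sum())

    def total_eggs(self) -> int:
        return int(self.hatch_col.size + self.cur_col.size)


def _queen_trait_sums(pop: PopulationState, trait: str,
                      slots: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Allelic sums of queens' caste-specific trait at the given ages."""
    idx = pop.layout.block_start("queen", trait) + ages - 1
    return pop.q_geno[slots, 0, idx] + pop.q_geno[slots, 1, idx]


def requeen(pop: PopulationState) -> int:
    """Fill empty colony slots from the hatching-egg pool.

    Each empty slot draws a source colony with probability proportional
    to its current egg count (weights shrink as eggs are withdrawn), takes
    one uniform random egg from it as the new queen, and mates her with a
    male sampled uniformly from this step's population-wide pool.
    Hatching eggs of colonies widowed this step remain valid sources: a
    daughter queen can hatch from them even though the colony dissolves.
    Falls back to the current-step egg cohort when no hatching egg exists
    anywhere.  Returns the number of slots filled.

    Raises :class:`MatingFailure` when a queen must mate but the male
    pool is empty.
    """
    p = pop.params
    rng = pop.rng
    empty = np.flatnonzero(~pop.q_alive)
    if empty.size == 0:
        return 0
    pool_col, pool_geno, from_fallback = pop.hatch_col, pop.hatch_geno, False
    if pool_col.size == 0 and pop.cur_col.size:
        pool_col, pool_geno, from_fallback = pop.cur_col, pop.cur_geno, True
        pop.fallback_requeenings += 1
        logger.debug("step %d: requeening from current-step eggs", pop.time)
    n_fill = min(empty.size, pool_col.size)
    if n_fill:
        total_males = int(pop.male_count.sum())
        if total_males == 0:
            raise MatingFailure(pop.time)
        # Mates: uniform over this step's population-wide male pool.
        # Males were fathered by this step's (possibly now dead) queens,
        # whose genomes are still in place — sample and build all sperm
        # before any slot is overwritten.  Each male is a (possibly
        # mutated) maternal gamete; the per-egg paternal transmission
        # applies the mutation operator separately.
        male_cum = np.cumsum(pop.male_count)
        mcs = np.searchsorted(male_cum, rng.random(n_fill) * total_males,
                              side="right")
        sperm = gametes_batch(pop.q_geno, rng,
                              recombination=p.recombination, rows=mcs)
        sperm = mutate_batch(sperm, p.mu, pop.architecture, rng)
        # Sequential egg withdrawal — draw a source colony with
        # probability proportional to its remaining egg count, then a
        # uniform egg within it — is distributionally identical to
        # drawing eggs uniformly WITHOUT replacement from the pooled
        # cohort: P(egg e next) = (c_e/total) * (1/c_e) = 1/total.
        chosen = rng.choice(pool_col.size, size=n_fill, replace=False)
        slots = empty[:n_fill]
        pop.q_alive[slots] = True
        pop.q_age[slots] = 1
        pop.q_geno[slots] = pool_geno[chosen]
        pop.q_sperm[slots] = sperm
        keep = np.ones(pool_col.size, dtype=bool)
        keep[chosen] = False
        if from_fallback:
            pop.cur_col = pool_col[keep]
            pop.cur_geno = pool_geno[keep]
        else:
            pop.hatch_col = pool_col[keep]
            pop.hatch_geno = pool_geno[keep]
    return int(n_fill)


def step(pop: PopulationState) -> PopulationState:
    """Advance the population one time step (in place).

    Raises :class:`Extinction` when no queen and no egg remains anywhere,
    and :class:`MatingFailure` when a new queen cannot find a male.
    """
    p = pop.params
    rng = pop.rng
    arch = pop.architecture
    N, k, L = p.n_colonies, p.k, 4 * p.k
    one_minus_h = 1.0 - p.h_ext

    # --- 1. reproduction -------------------------------------------------
    alive = np.flatnonzero(pop.q_alive)
    queen_z = np.zeros(N)
    pop.male_count = np.zeros(N, dtype=np.int64)
    if alive.size:
        ages = pop.q_age[alive]
        f_a = p.m * expit(_queen_trait_sums(pop, "fecundity", alive, ages))
        w = pop.worker_counts()[alive]
        z = np.maximum(0.0, 1.0 - (1.0 + w) / (1.0 + f_a))
        E = f_a * (1.0 - z)
        R = z + w
        tot = E + R
        F = np.where(tot > 0, E * R / np.where(tot > 0, tot, 1.0), 0.0)
        n_off = rng.poisson(F)
        queen_z[alive] = z
        pop.male_count[alive] = n_off

        egg_col = np.repeat(alive, n_off)
        if egg_col.size:
            maternal = gametes_batch(pop.q_geno, rng,
                                     recombination=p.recombination,
                                     rows=egg_col)
            maternal = mutate_batch(maternal, p.mu, arch, rng)
            paternal = pop.q_sperm[egg_col].copy()
            paternal = mutate_batch(paternal, p.mu, arch, rng)
            pop.cur_geno = np.empty((egg_col.size, 2, L))
            pop.cur_geno[:, 0] = maternal
            pop.cur_geno[:, 1] = paternal
            pop.cur_col = egg_col
        else:
            pop.cur_col = np.empty(0, dtype=np.int64)
            pop.cur_geno = np.empty((0, 2, L))

    # --- 2. survival and ageing ------------------------------------------
    if alive.size:
        s_int = expit(_queen_trait_sums(pop, "survival", alive, pop.q_age[alive]))
        d_ext = 1.0 - one_minus_h ** queen_z[alive]
        surv = (rng.random(alive.size) < s_int * (1.0 - d_ext)) \
            & (pop.q_age[alive] < k)
        pop.q_alive[alive] = surv
        pop.q_age[alive[surv]] += 1

    ws = pop.workers
    if ws.size:
        live = ws.live
        w_ages = ws.age[live]
        s_w = ws.surv[live, w_ages - 1]
        # Bernoulli survival x max-age death x colony collapse (a queenless
        # colony loses its workers; remaining brood is destroyed below)
        keep = (rng.random(live.size) < s_w * one_minus_h) & (w_ages < k) \
            & pop.q_alive[ws.col[live]]
        ws.live = live[keep]
        ws.age[ws.live] += 1
        ws.compact()

    widowed = ~pop.q_alive  # slots whose colony dissolved this step

    # --- 3. requeening -----------------------------------------------------
    requeen(pop)

    # --- 4. collapse: leftover brood of dissolved colonies dies ------------
    if pop.hatch_col.size:
        keep = ~widowed[pop.hatch_col]
        if not keep.all():
            pop.hatch_col = pop.hatch_col[keep]
            pop.hatch_geno = pop.hatch_geno[keep]
    if pop.cur_col.size:
        keep = ~widowed[pop.cur_col]
        if not keep.all():
            pop.cur_col = pop.cur_col[keep]
            pop.cur_geno = pop.cur_geno[keep]

    # --- 5. hatch ----------------------------------------------------------
    if pop.hatch_col.size:
        sums = pop.hatch_geno.sum(axis=1)
        surv = expit(sums[:, pop.layout.block_slice("worker", "survival")])
        pop.workers.append(pop.hatch_col, sums, surv)
    pop.hatch_col = pop.cur_col
    pop.hatch_geno = pop.cur_geno
    pop.cur_col = np.empty(0, dtype=np.int64)
    pop.cur_geno = np.empty((0, 2, L))

    pop.time += 1
    if not pop.q_alive.any() and pop.hatch_col.size == 0:
        raise Extinction(pop.time)
    return pop


@dataclass
class ReplicateResult:
    """Outcome of one replicate run."""

    params: Parameters
    seed: object
    extinct: bool
    extinct_step: int | None
    population: PopulationState
    summary: pd.DataFrame | None
    timeseries: pd.DataFrame
    equilibrium: bool | None
    repair_fired: bool
    fallback_requeenings: int


def _checkpoint_row(pop: PopulationState) -> dict:
    row = {"step": pop.time}
    k = pop.params.k
    for caste in ("queen", "worker"):
        try:
            surv, fec = sm.population_mean_traits(pop, caste)
            row[f"{caste}_life_expectancy"] = sm.life_expectancy(surv)
            row[f"{caste}_lifetime_fecundity"] = sm.lifetime_fecundity(fec)
            for a in range(k):
                row[f"{caste}_surv_a{a + 1}"] = surv[a]
                row[f"{caste}_fec_a{a + 1}"] = fec[a]
        except sm.EmptyPopulationError:
            row[f"{caste}_life_expectancy"] = np.nan
            row[f"{caste}_lifetime_fecundity"] = np.nan
    return row


def _equilibrium_flag(timeseries: pd.DataFrame, t_steps: int) -> bool | None:
    """Mean life expectancies changed by <2% over the final 10% of steps."""
    if timeseries.empty:
        return None
    tail = timeseries[timeseries["step"] >= 0.9 * t_steps]
    if len(tail) < 2:
        return None
    ok = True
    for caste in ("queen", "worker"):
        vals = tail[f"{caste}_life_expectancy"].to_numpy()
        if np.any(np.isnan(vals)):
            return None
        ref = max(abs(vals[0]), 1e-9)
        ok &= abs(vals[-1] - vals[0]) / ref < 0.02
    return bool(ok)


def run(params: Parameters, seed) -> ReplicateResult:
    """Run one replicate for ``params.t_steps`` steps (or until extinction).

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.
    """
    rng = np.random.default_rng(seed)
    pop = PopulationState.initialize(params, rng)
    interval = params.effective_checkpoint_interval
    checkpoints = []
    extinct, extinct_step = False, None
    for _ in range(params.t_steps):
        try:
            step(pop)
        except Extinction as exc:
            extinct, extinct_step = True, exc.step
            logger.info("replicate extinct at step %d (%s)", exc.step, exc)
            break
        if pop.time % interval == 0 or pop.time == params.t_steps:
            checkpoints.append(_checkpoint_row(pop))
            if pop.time % (10 * interval) == 0:
                logger.info("step %d/%d: %d queens, %d workers, %d eggs",
                            pop.time, params.t_steps, pop.n_queens(),
                            pop.workers.size, pop.total_eggs())
    timeseries = pd.DataFrame(checkpoints)
    summary = None
    if not extinct:
        try:
            summary = sm.summarize_population(pop)
        except sm.EmptyPopulationError:
            summary = None
    equilibrium = _equilibrium_flag(timeseries, params.t_steps) \
        if not extinct else None
    return ReplicateResult(
        params=params, seed=seed, extinct=extinct, extinct_step=extinct_step,
        population=pop, summary=summary, timeseries=timeseries,
        equilibrium=equilibrium,
        repair_fired=pop.architecture.repair.fired,
        fallback_requeenings=pop.fallback_requeenings,
    )


def final_genomes_frame(pop: PopulationState) -> pd.DataFrame:
    """Per-individual diploid allelic sums with flat-index labels."""
    labels = pop.layout.labels()
    alive = np.flatnonzero(pop.q_alive)
    q_sums = pop.q_geno[alive].sum(axis=1)
    w_col, w_age, w_sums = pop.w_col, pop.w_age, pop.w_sums
    meta = pd.DataFrame({
        "caste": ["queen"] * alive.size + ["worker"] * w_col.size,
        "colony": np.concatenate([alive, w_col]),
        "age": np.concatenate([pop.q_age[alive], w_age]),
    })
    vals = pd.DataFrame(np.concatenate([q_sums, w_sums], axis=0)
                        if alive.size or w_col.size
                        else np.empty((0, pop.layout.n)), columns=labels)
    return pd.concat([meta, vals], axis=1)


def write_outputs(result: ReplicateResult, outdir) -> None:
    """Write params.json, timeseries.csv, final_genomes.csv, summary.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "params": result.params.to_dict(),
        "seed": repr(result.seed),
        "extinct": result.extinct,
        "extinct_step": result.extinct_step,
        "equilibrium": result.equilibrium,
        "repair_fired": result.repair_fired,
        "fallback_requeenings": result.fallback_requeenings,
    }
    (outdir / "params.json").write_text(json.dumps(meta, indent=2))
    result.timeseries.to_csv(outdir / "timeseries.csv", index=False)
    final_genomes_frame(result.population).to_csv(
        outdir / "final_genomes.csv", index=False)
    if result.summary is not None:
        result.summary.to_csv(outdir / "summary.csv", index=False)
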