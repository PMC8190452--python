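# Methods

`casteage` simulates the evolution of caste-specific ageing in advanced
eusocial insects. A fixed set of `N` colony slots holds monogynous,
haplodiploid colonies — one singly mated queen plus sterile workers — and
advances through discrete time steps. Age- and caste-specific intrinsic
survival probabilities and fecundities are genetically encoded, and evolve
through biased, correlated mutations, selection among colony lineages, and
drift.

## Genotype and expression

Each haploid "gene regulatory network" is a vector of `4k` unbounded real
values: queen survival, queen fecundity, worker survival and worker
fecundity, with `k` age classes each (`k = 20` by default). Diploids carry
two such vectors. The two allelic values at a locus add, and the sum is
mapped through a logistic function:

    s_a(C) = logistic(x_a),        f_a(C) = m * logistic(y_a),

giving survival probabilities in `[0, 1]` and fecundities in `[0, m]`
(`m = 5`). Workers never reproduce, so worker fecundity is expressed but
demographically inert — a deliberate feature, since it provides an
internal selectively neutral control block.

Allelic interaction is the *sum* rather than the mean; the two differ only
by a factor-of-two rescaling of genetic values.

## Colony economics

With `w` workers and a queen of age-specific fecundity `f_a`, the queen
spends a fraction `z` of her time foraging and `1 - z` laying:

    R = z + w                 (resources; queens and workers forage equally)
    E = f_a (1 - z)           (eggs laid)
    F = E R / (E + R)         (expected offspring; per-egg survival g(x) =
                               x/(1+x) with x = R/E)

`z` is chosen to maximize `F`: solving `dF/dz = 0` gives `E = sqrt(f_a) R`
and hence

    z* = max(0, 1 - (1 + w) / (1 + sqrt(f_a))).

A founding queen (`w = 0`) always forages (`z > 0`) — semiclaustral
founding — and is exposed to extrinsic hazard until her worker force
covers the colony's resource needs (`w >= sqrt(f_a)` gives `z = 0`).
The realized offspring number is Poisson with mean `F`. One haploid (male)
egg accompanies every realized diploid offspring; males mature and die
within the step and serve purely as gene carriers in the mating pool.

Extrinsic mortality is an age-independent hazard `h_ext` applied only
while foraging: `d_ext = 1 - (1 - h_ext)^z`. Workers always forage
(`z = 1`, so `d_ext = h_ext`); a fully provisioned queen is shielded
(`z = 0`, `d_ext = 0`). Survival of a step is one Bernoulli draw with
parameter `s_a(C) (1 - d_ext)`, and individuals at the maximum age `k`
die regardless.

## Mutational architecture

Transmitted networks mutate with probability `mu = 0.005`; a mutation is a
single draw from a `4k`-dimensional multivariate normal with mean `b =
-0.2` in every coordinate (most mutations are harmful) and covariance
`Sigma` derived from a scenario-specific partial-correlation matrix `P`
(`sigma = 0.4` per coordinate):

- **baseline** — no pleiotropy: `P = I`, `Sigma = sigma^2 I`.
- **WCWT** — within-caste within-trait: each trait at age `a` couples to
  the same trait at age `a + delay` (delay 5), for queen survival, queen
  fecundity and worker survival.
- **WCBT** — queen fecundity at `a` couples to queen survival at
  `a + delay`.
- **BCWT** — queen survival couples to worker survival at the same age.
- **BCBT** — queen fecundity couples to worker survival at the same age.

Couplings take the value `rho = -0.8`; sterile workers exempt the
worker-fecundity block from all couplings. Delayed couplings are absent
for the last `delay` age classes (the partner age would exceed `k`), and
every inserted entry is mirrored so `P` stays symmetric.

`P` is converted to a covariance through the Gaussian-graphical-model
identity between partial correlations and the precision matrix: build
`Omega` with unit diagonal and off-diagonal `-P_ij`, invert, rescale the
inverse to unit diagonal, scale by `sigma^2`. For the chain-structured
scenarios (WCWT, WCBT) a partial correlation of -0.8 between successive
chain neighbours is infeasible — `Omega` is indefinite — so `Omega` is
first projected to the positive-definite cone (Higham-style alternating
projections: eigenvalue clipping at `1e-8`, diagonal restoration, at most
100 iterations). The repair preserves the sign structure of the couplings
but saturates the realized chain correlations at ±1; whether the repair
fired, and the Frobenius distance it moved, are recorded in the run
metadata (`RepairInfo`) so users can see when realized correlations
deviate from the nominal value. The baseline and the same-age between-
caste scenarios (BCWT, BCBT) are exactly representable (pairwise 2x2
precision blocks), need no repair, and reproduce `rho` exactly as the
marginal correlation.

## Life history and colony turnover

Each step executes: (1) reproduction — maternal gamete (a whole parental
haplotype by default; free recombination behind a flag) times stored
sperm, all transmissions passing through the mutation operator; (2)
survival and ageing; (3) requeening — every empty slot draws a source
colony with probability proportional to its hatching-egg count, withdraws
one egg as the new queen (age 1), and mates her with a male drawn
uniformly from this step's population-wide male pool; (4) collapse — a
colony whose queen died loses its workers and any remaining brood, whether
or not the slot was refilled by an unrelated new queen; (5) hatching —
surviving eggs laid in the previous step become age-1 workers.

Two boundary rules matter in small populations. First, hatching eggs of a
colony whose queen died *this* step remain valid requeening sources (a
daughter queen can hatch from them even though the colony dissolves);
destroying them first makes synchronized queen death — all founders
reaching the maximum age together — an artificial extinction. Second,
when no hatching egg exists anywhere, requeening falls back to the
current-step egg cohort (logged). Sampling a source colony proportionally
to egg counts and then a uniform egg within it is distributionally
identical to drawing eggs uniformly without replacement from the pooled
cohort; the engine uses the pooled form.

Global extinction (no queen and no egg anywhere) and mating failure (a
new queen with an empty male pool) abort a replicate cleanly and are
recorded, not raised through batch runs.

## Initial conditions

The founding population consists of `N` identical singly mated age-1
queens; castes start with identical trait values. The default founder
genetic value is 1.0 per allele (survival `logistic(2) ~ 0.88`, fecundity
`~ 4.40`), chosen on two mechanistic grounds:

- *Demographic viability.* A founding queen must, over her expected
  tenure, produce more than one egg that reaches the hatching pool, under
  both `h_ext = 0` and `h_ext = 0.2`. Founder survival 0.73 or below
  (init 0.5/0.75) fails this at `h_ext = 0.2` — populations of perpetual
  foundresses collapse; survival 0.88 gives a founding reproduction ratio
  comfortably above 1 in both hazard conditions.
- *Room for senescence.* If founder survival is too high (e.g. 0.98), old
  age classes are common, the force of selection barely declines with
  age, and no senescence can evolve on any feasible timescale — the
  population sits at mutation-selection balance. At 0.88 per step,
  survivorship to the last age class is below 10%, so selection weakens
  with age as the theory requires.

## Outcome measures

At any point, population-mean expressed trait curves are computed per
caste (queen means over living queens' genomes, worker means over living
workers'). Evolved lifespan is the area under the discrete survivorship
curve of the *mean* survival probabilities,

    LE = sum_{a=1..k} prod_{j<=a} s_j        (maximum k; intrinsic only),

and lifetime fecundity is the unweighted sum of mean age-specific
fecundities (maximum `k m`). Both are also exported as proportions of
their maxima — the stats-ready scale for beta regression, which this
package intentionally leaves to standard statistical software.

A quasi-equilibrium flag reports whether both castes' life expectancies
changed by less than 2% across the final 10% of steps (an
operationalization of "mean trait values no longer change"; reported, not
enforced).

## Scale presets and problem sizes

The reference study conditions are `N = 1000` colonies, `T = 10^6` steps,
20 replicates per cell (`full` preset). The `desk` preset (`N = 100`,
`T = 5 x 10^4`, 5 replicates) runs a cell in under a minute on one core.

Scale changes what can be observed. Caste divergence driven by
caste-specific extrinsic mortality (`h_ext = 0.2`) expresses within a few
thousand colony generations and is reliably visible at desk scale.
Divergence in the *absence* of extrinsic mortality is mutation-limited
and drift-mediated at these parameter values: it emerges as a stochastic
breakaway whose waiting time at `N = 100` is comparable to or exceeds the
desk horizon, so an individual desk replicate may still sit in the
founder regime when it ends — the desk-scale hazard-free comparison
measures the sign of a small fluctuating difference as often as a genuine
divergence. The same logic affects scenario contrasts: cells that have
not yet left the founder regime compare as "less eroded" regardless of
their mutational architecture. Larger populations supply proportionally
more mutations and break away sooner; the full preset's `N = 1000`,
`T = 10^6` puts every replicate far past the transition. The test suite
and the acceptance script run the evolution experiments at desk scale
(with the scenario contrasts evaluated in the hazard-0.2 cells, where
desk-scale dynamics actually leave the founder state) and report what
that scale supports; quantitative expectations belong to the full
preset.

## Numerical choices

- Positive-definiteness repair: eigenvalue clip at `1e-8`, 100-iteration
  cap, explicit failure (never silent).
- Mutation sampling uses a cached Cholesky factor of `Sigma`; a `1e-12`
  diagonal jitter is added only if the factorization fails outright.
- All randomness flows through one `numpy.random.Generator` per
  replicate. Replicate seeds derive from the master seed by a
  cell-addressed `SeedSequence` rule (scenario, hazard, rho, delay, bias,
  replicate index), so grid results are independent of execution order.
- Colony egg-count-weighted requeening is implemented as uniform
  sampling without replacement from the pooled egg cohort (provably
  equivalent; see above).
- Worker genomes are stored as diploid allelic sums: expression,
  summaries and dumps only ever need the sum, and workers never transmit
  genes. Queens and eggs keep both haplotypes.

## Known limitations

- The realized mutational correlations under WCWT/WCBT saturate at ±1
  after the positive-definiteness repair; the nominal -0.8 partial
  correlation is not representable on those chain structures. A side
  effect is that within-block effects on a chain largely cancel in the
  block's sum, which weakens net selection against (and net erosion by)
  those mutations and so changes the pace at which the WCWT scenario
  leaves the founder regime.
- Lifespan summaries use the curve-of-means convention (survivorship of
  the population-mean survival curve), not the mean of per-individual
  life expectancies.
- No polygyny, polyandry, worker reproduction, colony fission, spatial
  structure, or resource stochasticity; workers all forage (`z = 1`)
  with no task polymorphism.
- Desk-scale runs are far from the reference quasi-equilibrium for
  hazard-free conditions (see above); quantitative trait values at desk
  scale should not be compared against full-scale results.
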