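# casteage

Individual-based simulation of the evolution of caste-specific ageing in
eusocial insects under antagonistic pleiotropy.

## The problem

Queens of ants, bees, wasps and termites can outlive their workers by
orders of magnitude, although both castes develop from near-identical
genomes. The textbook explanation — workers forage and fight, so they
face higher extrinsic mortality, so selection against late-acting
deleterious mutations is weaker in workers — had never been backed by a
formal model. `casteage` implements such a model: a fixed-size population
of monogynous, haplodiploid colonies in which age- and caste-specific
intrinsic survival probabilities `s_a(C)` and fecundities `f_a(Q)` are
genetically encoded and evolve under biased, correlated mutations,
selection among colony lineages, and drift. It is aimed at evolutionary
biologists studying senescence, social evolution, and mutation-selection
dynamics in structured populations.

## The model in brief

Each individual carries two copies of a regulatory network: a vector of
`4k` real values (2 castes x 2 traits x `k = 20` age classes). Allelic
values add and map through a logistic to survival probabilities in
`[0, 1]` and fecundities in `[0, m]`, `m = 5`. Per colony and time step,
with `w` workers and queen fecundity `f_a`:

    R = z + w,   E = f_a (1 - z),   F = E R / (E + R),
    z = max(0, 1 - (1 + w) / (1 + sqrt(f_a)))   (maximizes F),

with realized offspring Poisson(`F`), one short-lived male per diploid
egg, and foraging-only extrinsic hazard `d_ext = 1 - (1 - h_ext)^z`
(workers always forage; provisioned queens are shielded). Queenless
colonies collapse and their slots are refilled by daughter queens drawn
from colonies in proportion to their egg counts, mated to a random male.

Transmitted networks mutate with probability `mu = 0.005`: one draw from
a `4k`-dimensional normal with mean `-0.2` everywhere (biased downward)
and a covariance built from a scenario-specific partial-correlation
matrix (couplings `rho = -0.8`): within-caste within-trait (WCWT),
within-caste between-trait (WCBT), between-caste within-trait (BCWT),
between-caste between-trait (BCBT), or none (baseline). Sterile workers'
fecundity block never carries couplings. See `docs/methods.md` for the
full construction, including the positive-definiteness repair.

## Worked example

```python
import casteage as ca

params = ca.Parameters(n_colonies=100, t_steps=50_000,
                       scenario="baseline", h_ext=0.2)
result = ca.run(params, seed=1)
print(result.summary[["caste", "life_expectancy", "lifetime_fecundity",
                      "lifespan_proportion"]].to_string(index=False))
```

prints (seed 1, about half a minute):

```
 caste  life_expectancy  lifetime_fecundity  lifespan_proportion
 queen         5.874599           59.695061             0.293730
worker         2.180280           64.313013             0.109014
```

Queens evolved a life expectancy of 5.9 of the maximum 20 age classes
while their workers — genetically identical at the start — dropped to
2.2: with foraging hazard 0.2, selection cannot maintain worker survival
at ages few workers reach, and the downward mutation bias erodes it,
while the shielded queen, whose death costs the whole colony, keeps her
survival high. `lifespan_proportion` is the same number scaled by the
maximum lifespan (the stats-ready scale). Without extrinsic hazard
(`h_ext=0`) the same divergence arises as a slower, drift-mediated
transition; see `docs/methods.md` on time scales.

Command-line equivalents:

```
casteage run --seed 1 --steps 50000 --out out/        # single replicate
casteage batch --preset desk --seed 1 --out batch/    # scenario grid
```

`batch` writes `aggregate.csv` (per-cell medians and ranges),
`divergence.csv` (queen-worker contrasts) and per-replicate outputs
(`params.json`, `timeseries.csv`, `final_genomes.csv`, `summary.csv`).

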