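# ddaffinity

Bayesian species-site unified **dark-diversity-affinity (DDA)** models for
binary metacommunity matrices.

Dark diversity is the unobservable part of a local community: species in the
regional species pool that find a site ecologically suitable yet are absent
from it. `ddaffinity` is for community ecologists and parasitologists who
want to know *whether* that absence is driven by the species or by the site,
and *which* traits and site attributes drive it — for example, flea or
gamasid-mite assemblages on small mammals, where "sites" can be regions (a
component metacommunity: one host species surveyed across regions) or host
species (a compound metacommunity: many hosts within one region).

## The model

The inputs are a binary species × site presence-absence matrix `prab`, a
species trait table, and a site attribute table.  A cellwise suitability
`suit ∈ [0, 1]` is first estimated from pairwise co-occurrence alone: for
each species pair, the observed co-occurrence count is standardized against
its hypergeometric mean and variance under random placement, and a species'
raw score at a site is the mean standardized effect size against the species
present there (monotonically rescaled into [0, 1]).

Each cell's dark-diversity affinity combines a species-side and a site-side
tendency, each a logit-linear model:

    logit(dda_sp)   = a_sp   + Σ_k b_sp,k   · T_k      (species traits)
    logit(dda_site) = a_site + Σ_k b_site,k · E_k      (site attributes)
    logit(DDA)      = [logit(dda_sp) + logit(dda_site)] / 2

so the DDA odds are the geometric mean of the two component odds, and all
three metrics live in (0, 1) with 0.5 the neutral threshold (above 0.5: the
species tends to be absent from suitable sites / the site tends to lack
suitable species).  The observed cell is Bernoulli with presence likelihood

    logit(p) = logit((1 − DDA) · suit) + δ,
    δ        = logit(mean(prab)) − logit(0.5 · mean(suit)),

where δ balances p to the observed prevalence.  Quantitative predictors are
standardized to mean 0 and SD 0.5; categorical predictors enter as one
indicator per level, identified by shrinkage priors.  Coefficients get
normal priors (mean 0; SD 0.5 for intercepts, 2.5 for slopes) and are
sampled by seeded adaptive Metropolis MCMC — 3 chains × 333 retained draws
(999 posterior samples), burn-in 4000 / thinning 12 by default, escalated up
to 25000 / 75 until every Gelman–Rubin R-hat ≤ 1.1.

## Worked example

```python
from ddaffinity import (AnalysisConfig, DDAModel, ScenarioConfig,
                        simulate_metacommunity)

# a synthetic metacommunity with one known trait effect (+2) and one known
# site-attribute effect (-2); real data would come from load_metacommunity()
cfg = ScenarioConfig(n_species=40, n_sites=30, n_quant_traits=2,
                     n_quant_attrs=1, b_sp=(2.0, 0.0), b_site=(-2.0,))
matrix, traits, sites, suit, truth = simulate_metacommunity(cfg, seed=7)

model = DDAModel(matrix, traits, sites, suitability=suit,
                 config=AnalysisConfig(burn_in=2000, thinning=6))
res = model.fit(seed=42)
print(res.summary())
```

```
Species-site unified dark-diversity-affinity model
==========================================================
species: 40   sites: 30   cells: 1200
delta: 0.0066   prevalence: 0.2558
draws: 999 (3 chains x 333)   burn-in: 2000   thinning: 6
max R-hat: 1.0035   converged: True   seed: 42
----------------------------------------------------------
                  mean   lower   upper  significant
a_sp           -0.0609 -0.7818  0.7232        False
a_site         -0.0463 -0.7915  0.6615        False
b_sp:sp_q1      2.2379  1.4138  3.1142         True
b_sp:sp_q2     -0.0839 -0.9220  0.6585        False
b_site:site_q1 -2.0009 -2.9960 -1.0991         True
----------------------------------------------------------
priors: N(0.0, 0.5^2) on a, N(0.0, 2.5^2) on b; CI level 0.95
```

Both injected effects are recovered with the correct sign and a 95%
credible interval excluding 0; the null coefficients are not flagged.
Splitting cells into absent (`prab = 0`) and present (`prab = 1`) subsets:

```python
print(res.compare_subsets().table)
```

```
          median_absent  median_present     H   p_value
quantity
p                0.2105          0.3345 139.3 3.871e-32
suit             0.4541          0.6295 100.1 1.413e-23
DDA              0.5186          0.4325 42.14 8.486e-11
dda_sp           0.5553          0.4027 24.02 9.526e-07
dda_site         0.5605          0.3959 17.63 2.687e-05
```

Absent cells have higher dark-diversity affinity and lower suitability and
presence likelihood than present cells (tie-corrected Kruskal–Wallis H with
its χ² p-value).  `res.species_affinity()` and `res.site_affinity()` label
each entity `dark-affine` (95% CI above 0.5), `presence-affine` (below), or
`unresolved`.

The same pipeline is scriptable from the shell:

```sh
ddaffinity simulate --scenario scenario.yaml --seed 7 --out data/
ddaffinity suitability --matrix data/matrix.csv --out suit.csv
ddaffinity fit --matrix data/matrix.csv --traits data/traits.csv \
    --sites data/sites.csv --seed 42 --out results/
ddaffinity recover --scenario scenario.yaml --replicates 10 --seed 3 --out rec/
```

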