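# flocknet

Co-occurrence network analysis of avian mixed-species flocks: who flocks
with whom, whether that structure exceeds chance, how robust it is, and
how it changes along environmental gradients.

Mixed-species flocks are foraging aggregations of two or more bird
species. Field surveys record them under the *gambit of the group*: every
species seen in a flock is assumed to associate with every other member,
so a site's data are a binary flock-by-species matrix. `flocknet` turns
such matrices into weighted species networks and answers the questions an
avian community ecologist asks of them:

1. **How strong is each association?** The simple ratio index
   `SRI(a,b) = x / (y_a + y_b + x)` — the probability two species are
   together given either was seen (`x` joint flocks, `y_a`, `y_b`
   exclusive flocks).
2. **Is the network structured at all?** The coefficient of variation of
   the edge weights, tested against a constrained permutation null: a
   Markov chain of checkerboard swaps on the raw observation matrix that
   preserves every species' flocking frequency and every flock's
   richness. The default kernel is a Metropolized swap whose stationary
   distribution is *exactly* uniform on the fixed-margin matrix class.
3. **How connected and cohesive is it?** Normalized average degree,
   connectance, weighted modularity Q (deterministic greedy
   agglomerative optimization) and weighted global clustering — each also
   scored against the 2.5/97.5 percentile null envelope.
4. **Are the detected modules trustworthy?** Bootstrap community
   assortativity (r_com): flocks are resampled, networks re-partitioned,
   and the concentration of pairwise co-membership within the original
   modules measured; sites with r_com ≤ 0.4 are excluded from the robust
   modularity regression.
5. **What drives the structure?** Per-site metrics regressed on
   elevation, absolute latitude, forest cover and human footprint with
   response-appropriate families (Gamma for richness and CV, Gaussian for
   modularity and log-connectance, Beta for degree and clustering),
   collinearity screening (correlations, VIFs) and an
   elevation × latitude interaction retained only when significant.

A synthetic-data module generates flock matrices with controllable
incidence heterogeneity and latent module structure (affinity α; α = 1 is
an exact open-membership null, large α yields clear flock subtypes), plus
multi-site datasets whose covariates drive the generator through known
links — so every stage of the pipeline is validated against ground truth
without any field data. See `docs/methods.md` for the model details and
design rationale.

## Worked example

```python
import flocknet as fn

# a strongly structured synthetic site: 2 latent modules, affinity 8
cfg = fn.SyntheticConfig(n_species=15, n_flocks=40, affinity=8.0,
                         n_modules=2, seed=7)
fm = fn.generate_site(cfg)

res = fn.assess_network(fm, n_perm=500, seed=1)   # null-model assessment
m = res.observed
print(f"CV = {m.cv:.3f}, p = {res.cv_pvalue:.4f}")
print(f"connectance = {m.connectance:.3f}, Q = {m.modularity_q:.3f} "
      f"({m.partition.n_communities} modules)")
print(res.envelope_verdicts)
print(f"r_com = {fn.rcom(fm, n_boot=100, seed=2).r_com:.3f}")
```

prints

```
CV = 0.502, p = 0.0000
connectance = 0.990, Q = 0.131 (2 modules)
{'avg_degree_norm': 'within', 'connectance': 'within',
 'modularity_q': 'higher', 'clustering': 'within'}
r_com = 0.785
```

The CV p-value is the fraction of 500 permuted matrices whose network CV
exceeds the observed one: here none do, so the site has significantly
more preferred/avoided associations than expected given species'
flocking frequencies. Modularity sits above its 97.5th null percentile
(`'higher'`) — the two generated flock subtypes are real, detected, and
robust to resampling (r_com 0.79 > 0.4).

## The analysis

Numbered drivers under `analysis/` run the full study on synthetic data
and write tables under `results/`:

```sh
python analysis/01_simulate_study.py     # 40 sites along the gradient
python analysis/02_networks_and_nulls.py # networks, null tests, r_com
python analysis/03_gradient_models.py    # regressions on 3 subsets
python analysis/04_method_validation.py  # calibration / power / uniformity
```

A typical run reports ~30 % of sites with significant social structure,
and a negative per-SD elevation coefficient for modularity
(β = −0.024, p = 0.002 on all sites; β = −0.035 on the ≥ 20-flock
subset) — the generator's planted "flocks lose their subtypes upslope"
signal, recovered end to end. The same steps are available as a CLI
(`flocknet simulate|validate|network|metrics|nulltest|rcom|regress|run`)
for use on real per-site CSVs (long format: `flock_id,species_id`).

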