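# Methods

## The model of the data

The observation unit is a *mixed-species flock*: one sighting of an
aggregation of two or more bird species moving and foraging together.
Under the gambit of the group, all species recorded in the same flock are
taken to be associating, so a site's data reduce to a binary
flock-by-species incidence matrix (rows = independently surveyed flocks,
columns = species). Sites enter the analysis only with at least 10
surveyed flocks; a stricter ≥ 20-flock subset is used as a sensitivity
check. Flocks that end up with fewer than two species after filtering are
dropped, as are species observed in no retained flock (network nodes are
observed species only).

## Association networks and the structure test

Association strength between species *a* and *b* is the simple ratio
index,

    SRI(a, b) = x / (y_a + y_b + x),

with *x* the number of flocks containing both, and *y_a*, *y_b* the
flocks containing exactly one of them. Because each flock records presence
only, no "both present but not associated" category exists and the
denominator has exactly these three terms. The SRI estimates the
probability that the pair is together given that at least one was seen.

Overall structure is summarized by the network coefficient of variation
(CV): the standard deviation of the edge weights over their mean. The dyad
set includes **all** unordered pairs of observed species, structural zeros
included — conditioning on the realized edge set would discard exactly the
preferred/avoided signal the test looks for — and the sample (n − 1)
standard deviation is used. Both choices are arguments of `network_cv`
because the CV definition alone does not force them.

The null hypothesis is that species assort into flocks at random given
each species' flocking frequency (column sums) and each flock's richness
(row sums). The null is simulated by a serial data-stream permutation: a
Markov chain on the incidence matrix whose move flips a 2×2 checkerboard
submatrix, i.e. swaps two species between two flocks in which they do not
co-occur, preserving all margins. The default chain records 3 500 states
with no burn-in, and the one-tailed p-value is the fraction of null CVs
strictly larger than the observed CV (no +1 correction; a `(k+1)/(n+1)`
variant is available). The four structural metrics are evaluated on the
same chain and compared to their empirical 2.5th/97.5th null percentiles
(verdicts `lower`/`within`/`higher`).

### Choice of the chain kernel

Three kernels are implemented; the default is the only one that combines
exact uniformity with usable mixing:

- **metropolis (default)** — choose a checkerboard uniformly, flip it, and
  accept with probability min(1, c_A/c_B), where c_A and c_B count the
  checkerboards available before and after the flip. Detailed balance
  makes the uniform distribution over the fixed-margin class exactly
  stationary, and nearly every recorded state is a fresh swap.
- **lazy** — propose one uniform flock-pair × species-pair per step and
  flip only if it is a checkerboard. Symmetric, hence exactly uniform, but
  on realistic matrices ~90 % of proposals are rejected; short chains then
  barely move, repeated states tie with the observed CV, and the
  strictly-greater counting rule turns those ties into anticonservative
  p-values.
- **retry** — re-propose until a checkerboard is found (the common field
  implementation). One swap per state, but the stationary distribution is
  proportional to the per-matrix checkerboard count, which is not constant
  (on the 4×4 all-margins-2 class it ranges at least 12–16), so the
  sampled null is only approximately uniform.

With the default kernel the CV test is calibrated: on open-membership
synthetic sites the 5 %-level rejection rate sits inside the exact
binomial band (see `tests/test_acceptance.py` and
`scripts/acceptance.py`).

## Network metrics

- **Normalized average degree**: mean over nodes of degree/(n − 1),
  degrees counted on nonzero-weight edges.
- **Connectance**: realized links over n(n − 1)/2 possible links.
  Under these literal definitions the two quantities are algebraically
  identical (mean degree/(n − 1) = 2L/n(n − 1)); published analyses
  sometimes report different ranges for them, which requires a different
  possible-links denominator (e.g. n²) or weighted degrees, so the
  denominator is exposed as an argument but the identity is the default
  behaviour and is asserted in the tests.
- **Weighted modularity Q** of the partition found by a deterministic
  greedy agglomerative (CNM-style) optimization: start from singleton
  communities, repeatedly merge the connected pair with the largest
  ΔQ = w_ab/W − s_a s_b/2W², breaking ties toward the lexicographically
  smallest community pair, and return the partition maximizing Q along the
  merge path. Communities in different components are never merged (their
  ΔQ is strictly negative), so disconnected networks keep at least one
  community per component. On all reference graphs of ≤ 7 nodes the greedy
  optimum equals the exhaustive-partition maximum.
- **Weighted global clustering**: generalized transitivity where a triplet
  centred on node *j* is an ordered pair of distinct neighbours of *j*,
  its value is the arithmetic mean of the two edges at *j* (geometric mean
  available), and it is closed iff the neighbours are connected; the
  coefficient is total closed value / total value. Undefined (no triplets)
  is reported as missing, never coerced to 0.

## Robustness of detected modules (r_com)

Flocks (the sampling unit) are resampled with replacement `n_boot = 100`
times; each replicate's SRI network is re-partitioned and every species
pair is scored by the fraction of replicates, among those containing both,
in which they share a community. r_com is the categorical assortativity of
the full-data partition labels on this co-membership-weighted graph:
with mixing proportions e_gh and marginals a_g,
r_com = (Σ e_gg − Σ a_g²)/(1 − Σ a_g²), self-pairs excluded. Pairs never
co-present contribute zero weight (logged). A single-community reference
makes the formula 0/0; it is reported as 1.0 with a `degenerate` flag and
such sites are never retained by the r_com > 0.4 (strict) filter used for
the robust-modularity regression subset.

100 bootstrap replicates stabilize co-membership frequencies to roughly
±0.05; the default is a compromise between that precision and the cost of
re-partitioning every replicate.

## Gradient regressions

Each analysed site contributes one row: network metrics as responses;
elevation (m a.s.l.), absolute latitude (decimal degrees), forest cover
(%) and the human-footprint score as predictors. Families follow each
response's support: Gamma GLM with log link for mean richness per flock
and CV (continuous, positive; the log link is used because the canonical
inverse link risks non-convergence on small positive responses), Gaussian
GLM for modularity and for log-transformed connectance (bounded but
heavily right-skewed), and Beta regression (logit mean link, constant
precision) for average degree and clustering, which live in (0, 1).
Responses touching 0 or 1 are compressed by the Smithson–Verkuilen
transform y′ = (y(n − 1) + 0.5)/n before a Beta fit, with a logged
warning.

Predictors are z-scored before fitting, so coefficients are per-SD
effects; signs and significance, not raw magnitudes, are the reported
surface. An elevation × |latitude| interaction is fitted first and
retained iff its Wald p < 0.05. Collinearity is screened by pairwise
Pearson correlations (|r| ≥ 0.5 flagged) and variance inflation factors
VIF_j = 1/(1 − R²_j). Subsets: all analysed sites, sites with ≥ 20
flocks, and (modularity only) sites with r_com > 0.4.

The retain-if-significant interaction rule is a selection step; repeated
null simulations show it inflates the main-effect false-positive rate
slightly above nominal (pooled ≈ 6 % at a 5 % level), which is inherited
from the procedure itself, not from the implementation.

## Synthetic data generator

`generate_site` emulates the statistical structure the analysis assumes:

- **Heterogeneous incidence**: species base weights w_i ~ LogNormal(0, σ)
  with σ = `incidence_spread` (default 0.5, giving roughly a 5–10-fold
  spread between common and rare species, in line with the skewed
  participation typical of flock surveys).
- **Flock sizes**: Poisson(λ) truncated to ≥ 2 and capped at the species
  pool (default λ = 5, a realistic mean flock richness for Andean sites).
- **Module structure**: species are assigned to `n_modules` balanced,
  contiguous modules (default 2, the canopy/understory contrast). Each
  flock draws a founder ∝ w to set a module tilt and then draws its whole
  species set by *conditional Poisson sampling* — the maximum-entropy law
  on fixed-size subsets with P(S) ∝ Π_{i∈S} w_i·α^[module_i = founder's],
  sampled exactly via elementary symmetric polynomials.

Conditional Poisson sampling, rather than drawing members one at a time
in proportion to weight, is what makes α = 1 a *clean* null: the
probability of the incidence matrix then factorizes over its row and
column sums, so conditional on the margins every matrix is equally likely
and the swap test's null hypothesis is exactly true. Sequential weighted
draws lack this sufficiency property and generate small spurious
structure under heterogeneous weights (measured as a 2–4× inflation of
the CV test's type-I error). At α = 1 the tilt vanishes entirely; as
α → ∞ flocks become single-module whenever their size permits.

Affinity must rise well above 1 before detectable structure appears: mean
greedy Q and mean r_com are flat between α = 1 and α = 2 and climb
steeply through α = 4 to α = 8. Tests of the monotone response therefore
contrast α ∈ {1, 4, 8}.

The multi-site layer samples covariates uniformly on Andean-scale ranges
(elevation 400–4 000 m, latitude 41° S–10° N, forest cover 5–95 %,
human footprint 0–30, 10–60 flocks per site) and maps them through linear
links on range-standardized covariates to (α, species pool, flock-size
mean). Defaults encode the expected field gradient — α declining with
elevation (log α slope −0.8 per half-range), richness declining with
elevation and latitude (−5 and −4 species per half-range), flock size
declining slightly upslope — at moderate effect sizes; `GradientSpec.null()`
zeroes every slope for calibration studies.

What the generator does **not** emulate: territory geometry and spatial
autocorrelation among flocks, temporal/seasonal turnover, observer
detection bias, and taxonomic structure in participation. Passing tests
therefore show that the pipeline recovers the truth when sampling is
exchangeable within sites and sites are independent — not that field data
satisfy those assumptions.

## Numerical and design notes

- All randomness flows through `numpy.random.Generator`; the pipeline
  derives per-site seeds from a master seed and the site's position, so
  results are a pure function of (inputs, config, seed) and independent of
  execution order.
- Greedy-merge ties are broken lexicographically; Q bookkeeping is
  incremental with a final exact recomputation of Q for the returned
  partition.
- p-values use strictly-greater counting over the full permutation count;
  missing null draws (degenerate or tripletless null networks) stay in the
  denominator, which can only make the test conservative.
- Envelope percentiles use linearly interpolated empirical quantiles.
- Edge-list output keeps full float precision (`%.17g`; reading uses
  round-trip parsing), so write/read round trips are bit-exact.
- Problem sizes in the test-suite simulations (100 calibration sites at
  500 permutations, 50 power sites, 200 small null-regression replicates)
  were chosen so each statistical check has conventional power while the
  whole suite stays interactive-fast.

## Known limitations

- The greedy optimizer is a heuristic; on larger or pathological graphs
  its Q can fall below the true maximum (always detected as ≤ in tests,
  equality asserted only on the small reference graphs).
- The r_com formulation operationalizes the bootstrap-assortativity idea
  with a weighted co-membership graph; other published variants weight
  pairs differently, so absolute r_com values are comparable within this
  package, not across implementations.
- Beta regressions use constant precision; a covariate-dependent
  precision model is out of scope.
- The CV permutation test shares one chain across all metrics per site; a
  fresh chain per metric is available via repeated calls but is not the
  default.
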