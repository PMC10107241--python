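"""Constrained permutation null models for flock co-occurrence matrices.

The null hypothesis is that species assort into flocks at random given how
often each species flocks (column sums) and how species-rich each flock is
(row sums).  Randomization therefore permutes the *raw observation matrix*
(a data-stream permutation), not the derived network: each step flips a
randomly chosen 2x2 checkerboard submatrix ([[1,0],[0,1]] <-> [[0,1],[1,0]]),
which swaps two species between two flocks in which they do not co-occur
and leaves every row and column sum unchanged.

Three proposal kernels are available.  The default, ``"metropolis"``,
picks a checkerboard uniformly at random and accepts the flip with
probability min(1, c_A / c_B), where c_A and c_B count the checkerboards
available before and after; this performs (nearly) one swap per recorded
state *and* has an exactly uniform stationary distribution over the
reachable fixed-margin matrices.  ``"lazy"`` draws one uniform flock pair
x species pair per step and flips iff it forms a checkerboard (symmetric,
hence exactly uniform, but most proposals are rejected so mixing per
recorded state is slow).  ``"retry"`` re-draws until a checkerboard is
found and always flips, matching the common field implementation; because
the checkerboard count varies across matrices, that chain's stationary
distribution is proportional to it and only approximately uniform.

Observed metrics are scored against the chain: a one-tailed p-value for the
edge-weight CV (the structure test) and a two-sided 2.5/97.5 percentile
envelope for the four structural metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .metrics import (ALL_METRICS, MetricSet, UndefinedMetricError,
                      compute_all_metrics, connectance, greedy_modularity,
                      normalized_average_degree, weighted_global_clustering)
from .network import (DegenerateNetworkError, FlockMatrix, build_network,
                      network_cv)

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 3500


@dataclass(frozen=True)
class NullEnsemble:
    """Per-metric null distributions from one permutation chain."""

    site_id: str
    n_perm: int
    null_values: dict[str, np.ndarray]  # NaN marks an undefined draw
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        for k, v in self.null_values.items():
            if len(v) != self.n_perm:
                raise ValueError(f"null list for {k} has wrong length")

    def missing_counts(self) -> dict[str, int]:
        return {k: int(np.isnan(v).sum()) for k, v in self.null_values.items()}


@dataclass(frozen=True)
class SignificanceResult:
    """Observed metrics with their null-model verdicts for one site."""

    site_id: str
    observed: MetricSet
    cv_pvalue: float
    cv_significant: bool
    envelope_verdicts: dict[str, str]
    n_perm: int
    seed: int | None = None
    missing_counts: dict[str, int] = field(default_factory=dict)


def checkerboard_swap(m: np.ndarray, rng: np.random.Generator,
                      max_tries: int | None = None) -> tuple[np.ndarray, bool]:
    """Apply one uniformly chosen checkerboard swap to a copy of ``m``.

    Proposes uniform (flock pair, species pair) cells until a checkerboard
    is found or ``max_tries`` (default ``10 * n_rows * n_cols``) proposals
    fail, in which case the matrix is returned unchanged with a False flag.
    The swap is self-inverse and preserves all row and column sums.
    """
    m = np.asarray(m)
    nr, nc = m.shape
    if nr < 2 or nc < 2:
        raise ValueError("need at least a 2x2 matrix")
    if max_tries is None:
        max_tries = 10 * nr * nc
    out = m.copy()
    for _ in range(max_tries):
        if _propose_flip(out, rng):
            return out, True
    return out, False


def _propose_flip(m: np.ndarray, rng: np.random.Generator) -> bool:
    """One uniform proposal; flip in place iff it is a checkerboard."""
    nr, nc = m.shape
    r1 = rng.integers(nr)
    r2 = rng.integers(nr - 1)
    if r2 >= r1:
        r2 += 1
    c1 = rng.integers(nc)
    c2 = rng.integers(nc - 1)
    if c2 >= c1:
        c2 += 1
    a, b, c, d = m[r1, c1], m[r1, c2], m[r2, c1], m[r2, c2]
    if a == d and b == c and a != b:
        m[r1, c1] = b
        m[r1, c2] = a
        m[r2, c1] = d
        m[r2, c2] = c
        return True
    return False


def count_checkerboards(m: np.ndarray) -> int:
    """Number of 2x2 checkerboard submatrices (flock pair x species pair)."""
    m = np.asarray(m, dtype=np.int64)
    d = m @ (1 - m).T  # d[i, j] = species in flock i but not flock j
    return int((d * d.T).sum()) // 2


def _metropolis_step(m: np.ndarray, c_now: int, rng: np.random.Generator,
                     max_tries: int) -> int:
    """One exactly-uniform swap step in place; returns the new checkerboard count.

    A checkerboard is chosen uniformly (rejection sampling over cell
    pairs); the flip is then accepted with probability min(1, c_A/c_B),
    which makes the uniform distribution over the fixed-margin class
    stationary by detailed balance.
    """
    saved = None
    for _ in range(max_tries):
        nr, nc = m.shape
        r1 = rng.integers(nr)
        r2 = rng.integers(nr - 1)
        if r2 >= r1:
            r2 += 1
        c1 = rng.integers(nc)
        c2 = rng.integers(nc - 1)
        if c2 >= c1:
            c2 += 1
        a, b = m[r1, c1], m[r1, c2]
        c, d = m[r2, c1], m[r2, c2]
        if a == d and b == c and a != b:
            saved = (r1, r2, c1, c2, a, b, c, d)
            break
    if saved is None:
        return c_now  # no checkerboard found; matrix unchanged
    r1, r2, c1, c2, a, b, c, d = saved
    m[r1, c1], m[r1, c2] = b, a
    m[r2, c1], m[r2, c2] = d, c
    c_new = count_checkerboards(m)
    if c_new > c_now and rng.random() >= c_now / c_new:
        m[r1, c1], m[r1, c2] = a, b  # reject: revert
        m[r2, c1], m[r2, c2] = c, d
        return c_now
    return c_new


def permutation_chain(fm: FlockMatrix, n_perm: int = DEFAULT_N_PERM,
                      rng: np.random.Generator | None = None,
                      burn_in: int = 0,
                      proposal: str = "metropolis") -> Iterator[np.ndarray]:
    """Serial checkerboard-swap chain started at the observed matrix.

    Yields ``n_perm`` successive states (after discarding ``burn_in``;
    default 0, the canonical design records every state).  See the module
    docstring for the three proposal kernels; ``"metropolis"`` (default)
    combines one swap per step with an exactly uniform stationary
    distribution.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    if proposal not in {"metropolis", "lazy", "retry"}:
        raise ValueError(f"unknown proposal kernel {proposal!r}")
    if rng is None:
        rng = np.random.default_rng()
    state = fm.incidence.astype(np.int8).copy()
    max_tries = 10 * state.shape[0] * state.shape[1]
    c_now = count_checkerboards(state) if proposal == "metropolis" else 0
    n_fail = 0
    for step in range(burn_in + n_perm):
        if proposal == "lazy":
            _propose_flip(state, rng)
        elif proposal == "metropolis":
            c_now = _metropolis_step(state, c_now, rng, max_tries)
        else:
            state, swapped = checkerboard_swap(state, rng)
            if not swapped:
                n_fail += 1
        if step >= burn_in:
            yield state.copy()
    if n_fail:
        logger.warning("%s: %d chain step(s) found no checkerboard",
                       fm.site_id, n_fail)


def null_metric_distribution(fm: FlockMatrix, metrics: list[str] | tuple[str, ...],
                             n_perm: int = DEFAULT_N_PERM,
                             rng: np.random.Generator | None = None,
                             seed: int | None = None,
                             proposal: str = "metropolis") -> NullEnsemble:
    """Evaluate the requested metrics on every state of one swap chain.

    All metrics share a single chain (one network build per state).  A
    metric undefined on some null network (degenerate or tripletless) is
    recorded as NaN and excluded from downstream quantiles; if more than
    half the draws of a metric are missing an unreliable-null warning is
    logged.
    """
    metrics = list(metrics)
    unknown = set(metrics) - set(ALL_METRICS)
    if unknown:
        raise ValueError(f"unknown metric(s) {sorted(unknown)}")
    if rng is None:
        rng = np.random.default_rng(seed)
    values = {k: np.full(n_perm, np.nan) for k in metrics}
    for i, state in enumerate(permutation_chain(fm, n_perm, rng,
                                                proposal=proposal)):
        net = build_network(FlockMatrix(
            site_id=fm.site_id, species_ids=fm.species_ids,
            flock_ids=fm.flock_ids, incidence=state))
        for k in metrics:
            try:
                if k == "cv":
                    values[k][i] = network_cv(net)
                elif k == "avg_degree_norm":
                    values[k][i] = normalized_average_degree(net)
                elif k == "connectance":
                    values[k][i] = connectance(net)
                elif k == "modularity_q":
                    values[k][i] = greedy_modularity(net)[1]
                elif k == "clustering":
                    values[k][i] = weighted_global_clustering(net)
            except (DegenerateNetworkError, UndefinedMetricError):
                pass  # stays NaN
    ensemble = NullEnsemble(site_id=fm.site_id, n_perm=n_perm,
                            null_values=values, seed=seed)
    for k, miss in ensemble.missing_counts().items():
        if miss > n_perm / 2:
            logger.warning("%s: unreliable null for %s (%d/%d missing)",
                           fm.site_id, k, miss, n_perm)
    return ensemble


def upper_tail_pvalue(observed: float, nulls: np.ndarray | list[float]) -> float:
    """One-tailed p-value: fraction of null draws strictly above ``observed``.

    Ties do not count as exceedances and no +1 continuity correction is
    applied; NaN draws are dropped from the numerator but the denominator
    stays the full number of permutations, so missing nulls can only make
    the test conservative.
    """
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    exceed = np.nansum(nulls > observed)
    return float(exceed / nulls.size)


def envelope_verdict(observed: float, nulls: np.ndarray | list[float]) -> str:
    """Two-sided null-envelope classification: lower / within / higher.

    Compares the observed value against the empirical 2.5th and 97.5th
    percentiles of the (non-missing) null draws, linear interpolation.
    """
    nulls = np.asarray(nulls, dtype=float)
    nulls = nulls[~np.isnan(nulls)]
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    lo, hi = np.quantile(nulls, [0.025, 0.975])
    if observed > hi:
        return "higher"
    if observed < lo:
        return "lower"
    return "within"


def assess_network(fm: FlockMatrix, n_perm: int = DEFAULT_N_PERM,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None,
                   alpha: float = 0.05,
                   proposal: str = "metropolis") -> SignificanceResult:
    """Full null-model assessment of one site.

    Computes the observed metrics, runs one permutation chain for all five,
    derives the one-tailed CV p-value (significant social structure iff
    p < ``alpha``) and the percentile-envelope verdict for each of the four
    structural metrics.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = compute_all_metrics(fm)
    ensemble = null_metric_distribution(fm, list(ALL_METRICS), n_perm=n_perm,
                                        rng=rng, seed=seed, proposal=proposal)
    p = upper_tail_pvalue(observed.cv, ensemble.null_values["cv"])
    verdicts = {}
    for k in ("avg_degree_norm", "connectance", "modularity_q", "clustering"):
        obs = observed.values()[k]
        nulls = ensemble.null_values[k]
        if obs is None or np.isnan(nulls).all():
            verdicts[k] = "undefined"
        else:
            verdicts[k] = envelope_verdict(obs, nulls)
    return SignificanceResult(
        site_id=fm.site_id, observed=observed, cv_pvalue=p,
        cv_significant=p < alpha, envelope_verdicts=verdicts,
        n_perm=n_perm, seed=seed, missing_counts=ensemble.missing_counts())
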