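"""Bootstrap confidence in detected community structure (r_com).

Detected modules in an association network are only as trustworthy as the
sampling behind them.  Here the observation unit — the flock — is
resampled with replacement, the SRI network and its greedy-modularity
partition are rebuilt for every replicate, and the pairwise co-membership
frequency of every species pair is tabulated.  The community assortativity
coefficient r_com then measures how concentrated that co-membership weight
is within the communities of the reference (full-data) partition: r_com
near 1 means replicates keep recovering the same modules; values near 0
mean module assignment is not robust to resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .metrics import MetricSet, Partition, greedy_modularity
from .network import DegenerateNetworkError, FlockMatrix, build_network

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 100
RCOM_THRESHOLD = 0.4


@dataclass(frozen=True)
class RcomResult:
    site_id: str
    r_com: float
    n_boot: int
    comembership: np.ndarray = field(repr=False)
    reference_partition: Partition = field(repr=False)
    degenerate: bool = False  # single-community reference, r_com by convention

    def __post_init__(self) -> None:
        c = np.asarray(self.comembership, dtype=float)
        if not np.allclose(c, c.T):
            raise ValueError("comembership must be symmetric")
        if (c < 0).any() or (c > 1).any():
            raise ValueError("comembership entries must lie in [0, 1]")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("comembership diagonal must be 1")
        if not -1.0 - 1e-9 <= self.r_com <= 1.0 + 1e-9:
            raise ValueError("r_com must lie in [-1, 1]")


def bootstrap_comembership(fm: FlockMatrix, n_boot: int = DEFAULT_N_BOOT,
                           rng: np.random.Generator | None = None,
                           seed: int | None = None) -> np.ndarray:
    """Pairwise community co-membership frequencies over flock bootstraps.

    Each replicate resamples ``n_flocks`` flocks with replacement, drops
    species absent from the replicate, rebuilds the SRI network and runs
    greedy modularity.  Entry (i, j) is the fraction of replicates, among
    those where both species occur, in which they share a community.  Pairs
    never jointly present across all replicates are scored 0 (no evidence
    of co-membership), with a logged count.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = fm.n_species
    together = np.zeros((n, n))
    both_present = np.zeros((n, n))
    for _ in range(n_boot):
        rows = rng.integers(fm.n_flocks, size=fm.n_flocks)
        m = fm.incidence[rows]
        present = np.nonzero(m.sum(axis=0) > 0)[0]
        if present.size < 2:
            continue
        sub = FlockMatrix(
            site_id=fm.site_id,
            species_ids=tuple(fm.species_ids[i] for i in present),
            flock_ids=tuple(f"b{i}" for i in range(len(rows))),
            incidence=m[:, present])
        try:
            part, _ = greedy_modularity(build_network(sub))
        except DegenerateNetworkError:
            continue
        labels = np.asarray(part.labels)
        same = labels[:, None] == labels[None, :]
        ix = np.ix_(present, present)
        both_present[ix] += 1
        together[ix] += same
    never = (both_present == 0)
    np.fill_diagonal(never, False)
    if never.any():
        logger.info("%s: %d species pair(s) never co-present across %d replicates",
                    fm.site_id, int(never.sum()) // 2, n_boot)
    with np.errstate(invalid="ignore"):
        co = np.where(both_present > 0, together / np.maximum(both_present, 1), 0.0)
    np.fill_diagonal(co, 1.0)
    return co


def community_assortativity(reference: Partition,
                            comembership: np.ndarray) -> tuple[float, bool]:
    """Categorical assortativity of reference labels on the co-membership graph.

    With mixing proportions ``e_gh`` = co-membership weight between
    communities g and h over the total weight (self-pairs excluded) and
    marginals ``a_g = sum_h e_gh``,

        r_com = (sum_g e_gg - sum_g a_g^2) / (1 - sum_g a_g^2).

    A single-community reference makes the formula 0/0; by convention it is
    reported as 1.0 with a degenerate flag so the caller can avoid treating
    structureless sites as robust.
    """
    c = np.asarray(comembership, dtype=float)
    n = len(reference.species_ids)
    if c.shape != (n, n):
        raise ValueError("comembership does not cover the reference node set")
    if reference.n_communities == 1:
        return 1.0, True
    labels = np.asarray(reference.labels)
    k = reference.n_communities
    # ordered pairs, diagonal excluded; symmetric so e is symmetric
    w = c.copy()
    np.fill_diagonal(w, 0.0)
    total = w.sum()
    if total == 0:
        return 0.0, False  # no co-membership signal anywhere
    e = np.zeros((k, k))
    for g in range(k):
        for h in range(k):
            e[g, h] = w[np.ix_(labels == g, labels == h)].sum()
    e /= total
    a = e.sum(axis=1)
    trace = np.trace(e)
    denom = 1.0 - float(a @ a)
    if denom == 0:
        return 1.0, True
    return float((trace - a @ a) / denom), False


def rcom(fm: FlockMatrix, n_boot: int = DEFAULT_N_BOOT,
         rng: np.random.Generator | None = None,
         seed: int | None = None) -> RcomResult:
    """Full r_com computation for one site."""
    part, _ = greedy_modularity(build_network(fm))
    co = bootstrap_comembership(fm, n_boot=n_boot, rng=rng, seed=seed)
    r, degenerate = community_assortativity(part, co)
    return RcomResult(site_id=fm.site_id, r_com=r, n_boot=n_boot,
                      comembership=co, reference_partition=part,
                      degenerate=degenerate)


def rcom_filter(results: list[tuple[MetricSet, RcomResult]],
                threshold: float = RCOM_THRESHOLD) -> list[str]:
    """Sites whose community structure is robust: r_com strictly > threshold.

    Degenerate single-community sites are never retained, whatever their
    conventional r_com value.
    """
    if not -1 < threshold < 1:
        raise ValueError("threshold must lie in (-1, 1)")
    return [m.site_id for m, r in results
            if r.r_com > threshold and not r.degenerate]
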