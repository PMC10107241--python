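"""Network-level connectivity and cohesion metrics.

Connectivity is summarized by the normalized average degree (mean node
degree divided by n-1) and connectance (realized fraction of possible
links); both operate on the binarized edge set (weight > 0).  Cohesion is
summarized by weighted Newman modularity Q, optimized with a deterministic
greedy agglomerative (CNM-style) merge, and by the generalized weighted
global clustering coefficient (triplet value = arithmetic mean of the two
edges anchored at the centre).

Note that under these literal definitions the normalized average degree and
connectance are the same number (mean degree / (n-1) = 2L / n(n-1));
published ranges sometimes differ because other denominators (e.g. n^2) or
weighted degrees are in circulation, so the possible-links denominator is
exposed as an argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .network import (AssociationNetwork, DegenerateNetworkError, FlockMatrix,
                      build_network, network_cv)

STRUCTURE_METRICS = ("avg_degree_norm", "connectance", "modularity_q", "clustering")
ALL_METRICS = ("cv",) + STRUCTURE_METRICS


class UndefinedMetricError(ValueError):
    """Metric has no defined value on this network (e.g. no triplets)."""


@dataclass(frozen=True)
class Partition:
    """Assignment of species to communities, labels 0..k-1, none empty."""

    species_ids: tuple[str, ...]
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.species_ids) != len(self.labels):
            raise ValueError("labels must cover all species")
        ks = sorted(set(self.labels))
        if ks != list(range(len(ks))):
            raise ValueError("labels must be consecutive integers from 0")
        object.__setattr__(self, "species_ids", tuple(self.species_ids))
        object.__setattr__(self, "labels", tuple(int(x) for x in self.labels))

    @property
    def n_communities(self) -> int:
        return len(set(self.labels))

    def as_sets(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for s, c in zip(self.species_ids, self.labels):
            out.setdefault(c, set()).add(s)
        return [out[k] for k in sorted(out)]


@dataclass(frozen=True)
class MetricSet:
    """One site's richness summaries plus the four structural metrics."""

    site_id: str
    n_species: int
    n_flocks: int
    mean_richness_per_flock: float
    cv: float
    avg_degree_norm: float
    connectance: float
    modularity_q: float
    partition: Partition = field(repr=False)
    clustering: float | None  # None when the network has no triplets

    def values(self) -> dict[str, float | None]:
        return {
            "cv": self.cv,
            "avg_degree_norm": self.avg_degree_norm,
            "connectance": self.connectance,
            "modularity_q": self.modularity_q,
            "clustering": self.clustering,
        }


def normalized_average_degree(net: AssociationNetwork) -> float:
    """Mean over nodes of degree/(n-1), degrees counted on nonzero edges."""
    n = net.n_species
    if n < 2:
        raise ValueError("need at least two species")
    deg = (net.weights > 0).sum(axis=1)
    return float(deg.mean() / (n - 1))


def connectance(net: AssociationNetwork, denominator: str = "pairs") -> float:
    """Realized links over possible links.

    ``denominator="pairs"`` uses n(n-1)/2 (all unordered species pairs, the
    literal definition); ``"squared"`` uses n^2, a convention seen in some
    bipartite-web software and kept for comparability.
    """
    n = net.n_species
    if n < 2:
        raise ValueError("need at least two species")
    links = int((net.weights > 0).sum()) // 2
    if denominator == "pairs":
        possible = n * (n - 1) / 2
    elif denominator == "squared":
        possible = n * n
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return float(links / possible)


def modularity_q(net: AssociationNetwork, part: Partition) -> float:
    """Weighted Newman modularity of a given partition.

    Q = sum_c ( w_c / W  -  (s_c / 2W)^2 ) with W the total edge weight,
    w_c the weight inside community c and s_c the summed node strength of c.
    """
    if tuple(part.species_ids) != tuple(net.species_ids):
        raise ValueError("partition does not cover this network's species")
    w = net.weights
    total = w.sum() / 2.0
    if total == 0:
        raise DegenerateNetworkError("modularity undefined: no edges")
    labels = np.asarray(part.labels)
    strength = w.sum(axis=1)
    q = 0.0
    for c in range(part.n_communities):
        mask = labels == c
        w_c = w[np.ix_(mask, mask)].sum() / 2.0
        s_c = strength[mask].sum()
        q += w_c / total - (s_c / (2 * total)) ** 2
    return float(q)


def greedy_modularity(net: AssociationNetwork) -> tuple[Partition, float]:
    """Greedy agglomerative (CNM-style) weighted modularity optimization.

    Starts from singleton communities and repeatedly merges the connected
    pair with the largest modularity gain, breaking ties toward the
    lexicographically smallest community-index pair; the partition with the
    highest Q along the merge path is returned.  Deterministic by
    construction.  Components are never merged with each other (a zero
    between-weight merge strictly lowers Q), so disconnected networks yield
    at least one community per component.
    """
    w = net.weights
    n = net.n_species
    total2 = w.sum()  # 2W
    if total2 == 0:
        raise DegenerateNetworkError("greedy modularity needs a nonzero edge")

    # community state: between-weight matrix, per-community strength
    between = w.copy()
    strength = w.sum(axis=1).astype(float)
    members: list[list[int] | None] = [[i] for i in range(n)]
    alive = np.ones(n, dtype=bool)
    labels = np.arange(n)

    q_now = -float(np.sum((strength / total2) ** 2))  # all-singletons Q
    best_q = q_now
    best_labels = labels.copy()

    while alive.sum() > 1:
        idx = np.nonzero(alive)[0]
        sub = between[np.ix_(idx, idx)]
        gains = 2.0 * sub / total2 - 2.0 * np.outer(
            strength[idx], strength[idx]) / total2**2
        gains[sub <= 0] = -np.inf  # never merge disconnected communities
        flat = int(np.argmax(gains))  # row-major first max = smallest (a, b) pair
        ai, bi = divmod(flat, len(idx))
        if not np.isfinite(gains[ai, bi]):
            break  # only mutually disconnected communities remain
        a, b = sorted((int(idx[ai]), int(idx[bi])))
        labels[np.asarray(members[b])] = a  # type: ignore[arg-type]
        members[a] = members[a] + members[b]  # type: ignore[operator]
        members[b] = None
        strength[a] += strength[b]
        between[a, :] += between[b, :]
        between[:, a] += between[:, b]
        between[a, a] = 0.0
        between[b, :] = 0.0
        between[:, b] = 0.0
        alive[b] = False
        q_now += float(gains[ai, bi])
        if q_now > best_q + 1e-12:
            best_q = q_now
            best_labels = labels.copy()

    part = _relabel(net.species_ids, best_labels)
    return part, modularity_q(net, part)


def _relabel(species_ids: Iterable[str], raw: np.ndarray) -> Partition:
    seen: dict[int, int] = {}
    labels = []
    for x in raw:
        labels.append(seen.setdefault(int(x), len(seen)))
    return Partition(species_ids=tuple(species_ids), labels=tuple(labels))


def weighted_global_clustering(net: AssociationNetwork,
                               triplet_value: str = "arithmetic") -> float:
    """Generalized (weighted) global clustering coefficient.

    A triplet centred on node j is an ordered pair of distinct neighbours of
    j; its value is the arithmetic (default) or geometric mean of the two
    edges anchored at j, and it is closed iff the two neighbours are
    themselves connected.  Returns total closed value / total value.
    """
    w = net.weights
    b = (w > 0).astype(float)
    if triplet_value == "arithmetic":
        # ordered-pair totals: sum_j sum_{i != k in N(j)} (w_ji + w_jk)/2
        deg = b.sum(axis=1)
        s = w.sum(axis=1)
        denom = ((deg - 1) * s).sum()
        common = b @ b  # [i, j] = shared neighbours of i and j
        closed = (w * common).sum()
    elif triplet_value == "geometric":
        sw = np.sqrt(w)
        denom = (sw.sum(axis=1)) ** 2 - (w).sum(axis=1)  # per-centre ordered sum
        denom = denom.sum()
        common = b @ b
        closed = 0.0
        n = net.n_species
        for j in range(n):
            nb = np.nonzero(b[j])[0]
            for ii in nb:
                for kk in nb:
                    if ii != kk and b[ii, kk]:
                        closed += np.sqrt(w[j, ii] * w[j, kk])
    else:
        raise ValueError(f"unknown triplet_value {triplet_value!r}")
    if denom <= 0:
        raise UndefinedMetricError("no open or closed triplets in network")
    return float(closed / denom)


def compute_all_metrics(fm: FlockMatrix) -> MetricSet:
    """Build the SRI network once and evaluate every site-level metric.

    A clustering coefficient undefined for the network (no triplets) is
    reported as ``None`` rather than coerced to zero.
    """
    net = build_network(fm)
    part, q = greedy_modularity(net)
    try:
        clust = weighted_global_clustering(net)
    except UndefinedMetricError:
        clust = None
    return MetricSet(
        site_id=fm.site_id,
        n_species=fm.n_species,
        n_flocks=fm.n_flocks,
        mean_richness_per_flock=float(fm.richness_per_flock().mean()),
        cv=network_cv(net),
        avg_degree_norm=normalized_average_degree(net),
        connectance=connectance(net),
        modularity_q=q,
        partition=part,
        clustering=clust,
    )
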