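"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each quantity by direct enumeration
(per-dyad counting, all set partitions, all triplets) so they share no code
with the implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from flocknet import AssociationNetwork, FlockMatrix


@pytest.fixture
def toy_fm() -> FlockMatrix:
    """Three flocks: F1={A,B}, F2={A,B,C}, F3={A,C}."""
    return FlockMatrix("toy", ("A", "B", "C"), ("F1", "F2", "F3"),
                       np.array([[1, 1, 0], [1, 1, 1], [1, 0, 1]]))


@pytest.fixture
def two_triangles() -> AssociationNetwork:
    """Two disjoint unit-weight triangles on six species."""
    w = np.zeros((6, 6))
    for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        w[i, j] = w[j, i] = 1.0
    return AssociationNetwork("tri2", tuple("abcdef"), w)


def net_from_weights(w: np.ndarray, site_id: str = "w") -> AssociationNetwork:
    w = np.asarray(w, dtype=float)
    return AssociationNetwork(site_id, tuple(f"s{i}" for i in range(len(w))), w)


def random_flock_matrix(rng: np.random.Generator, n_flocks: int = 12,
                        n_species: int = 8) -> FlockMatrix:
    """Random valid incidence matrix: each flock 2..n_species members."""
    m = np.zeros((n_flocks, n_species), dtype=np.int8)
    for f in range(n_flocks):
        size = int(rng.integers(2, n_species + 1))
        m[f, rng.choice(n_species, size=size, replace=False)] = 1
    keep = m.sum(axis=0) > 0
    m = m[:, keep]
    return FlockMatrix("rand", tuple(f"sp{i}" for i in np.nonzero(keep)[0]),
                       tuple(f"F{f}" for f in range(n_flocks)), m)


def sri_matrix_oracle(incidence: np.ndarray) -> np.ndarray:
    """Brute-force SRI: enumerate every flock for every dyad."""
    n = incidence.shape[1]
    w = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            x = ya = yb = 0
            for row in incidence:
                if row[a] and row[b]:
                    x += 1
                elif row[a]:
                    ya += 1
                elif row[b]:
                    yb += 1
            if x + ya + yb > 0:
                w[a, b] = w[b, a] = x / (x + ya + yb)
    return w


def set_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    labels = [0] * n

    def rec(i: int, k: int):
        if i == n:
            yield tuple(labels)
            return
        for c in range(k + 1):
            labels[i] = c
            yield from rec(i + 1, max(k, c + 1))

    yield from rec(0, 0)


def modularity_oracle(w: np.ndarray, labels) -> float:
    """Direct evaluation of weighted Newman Q for one partition."""
    labels = np.asarray(labels)
    total = w.sum() / 2
    q = 0.0
    for c in set(labels.tolist()):
        mask = labels == c
        w_c = w[np.ix_(mask, mask)].sum() / 2
        s_c = w[mask].sum()
        q += w_c / total - (s_c / (2 * total)) ** 2
    return q


def max_modularity_oracle(w: np.ndarray) -> float:
    """Exhaustive maximum of Q over every partition (feasible for n <= 7)."""
    return max(modularity_oracle(w, lab) for lab in set_partitions(len(w)))


def clustering_oracle(w: np.ndarray) -> float:
    """Brute-force generalized clustering: enumerate all ordered triplets."""
    n = len(w)
    closed = total = 0.0
    for j in range(n):
        for i in range(n):
            for k in range(n):
                if i == k or i == j or k == j:
                    continue
                if w[j, i] > 0 and w[j, k] > 0:
                    value = (w[j, i] + w[j, k]) / 2
                    total += value
                    if w[i, k] > 0:
                        closed += value
    if total == 0:
        raise ValueError("no triplets")
    return closed / total


def checkerboard_count_oracle(m: np.ndarray) -> int:
    """Count 2x2 checkerboards by scanning every row pair x column pair."""
    nr, nc = m.shape
    count = 0
    for r1 in range(nr):
        for r2 in range(r1 + 1, nr):
            for c1 in range(nc):
                for c2 in range(c1 + 1, nc):
                    sub = m[np.ix_((r1, r2), (c1, c2))]
                    if sub[0, 0] == sub[1, 1] and sub[0, 1] == sub[1, 0] \
                            and sub[0, 0] != sub[0, 1]:
                        count += 1
    return count
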