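"""Weighted species co-occurrence networks from flock observations.

Each surveyed flock is scored under the gambit of the group: every species
recorded in the same flock is assumed to be associating with every other
member. Association strength between two species is the simple ratio index
(SRI), the probability that the pair is observed together given that at
least one of them was observed:

    SRI(a, b) = x / (y_a + y_b + x)

where ``x`` counts flocks containing both species, ``y_a`` flocks with *a*
but not *b*, and ``y_b`` flocks with *b* but not *a*.  Because every flock
records species presence only (no "both present but not associating" state
exists under per-flock sampling), the denominator has exactly these three
terms.

The dispersion of the resulting edge weights — the network coefficient of
variation (CV) — is the headline measure of social structure: high CV means
some partners are strongly preferred or avoided, low CV means associations
are even and open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateNetworkError(ValueError):
    """Raised when a network carries no co-occurrence signal at all."""


class UndefinedDyadError(ValueError):
    """Raised for an SRI query on a dyad never observed in any flock."""


@dataclass(frozen=True)
class FlockMatrix:
    """Binary flock-by-species incidence matrix for one site.

    Rows are independently surveyed flocks, columns species; entry 1 iff the
    species was recorded in that flock.  Invariants: every flock contains at
    least two species, every retained species was seen at least once,
    entries are 0/1, and identifiers are unique.
    """

    site_id: str
    species_ids: tuple[str, ...]
    flock_ids: tuple[str, ...]
    incidence: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.incidence)
        if m.ndim != 2:
            raise ValueError("incidence must be a 2-D matrix")
        if m.shape != (len(self.flock_ids), len(self.species_ids)):
            raise ValueError(
                f"incidence shape {m.shape} does not match "
                f"{len(self.flock_ids)} flocks x {len(self.species_ids)} species"
            )
        if not np.isin(m, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("species_ids must be unique")
        if len(set(self.flock_ids)) != len(self.flock_ids):
            raise ValueError("flock_ids must be unique")
        if m.size and (m.sum(axis=1) < 2).any():
            raise ValueError("every flock must contain at least two species")
        if m.size and (m.sum(axis=0) < 1).any():
            raise ValueError("every retained species must occur in some flock")
        object.__setattr__(self, "incidence", m.astype(np.int8))
        object.__setattr__(self, "species_ids", tuple(self.species_ids))
        object.__setattr__(self, "flock_ids", tuple(self.flock_ids))

    @property
    def n_flocks(self) -> int:
        return len(self.flock_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def richness_per_flock(self) -> np.ndarray:
        """Number of species in each flock (row sums)."""
        return self.incidence.sum(axis=1)

    def species_incidence(self) -> np.ndarray:
        """Number of flocks each species joined (column sums)."""
        return self.incidence.sum(axis=0)


@dataclass(frozen=True)
class AssociationNetwork:
    """Symmetric SRI-weighted species network for one site."""

    site_id: str
    species_ids: tuple[str, ...]
    weights: np.ndarray = field(repr=False)
    n_flocks: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.species_ids)
        if w.shape != (n, n):
            raise ValueError(f"weights must be {n}x{n}")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.diag(w).any():
            raise ValueError("diagonal must be zero")
        if (w < 0).any() or (w > 1).any():
            raise ValueError("SRI weights must lie in [0, 1]")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "species_ids", tuple(self.species_ids))

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def dyad_weights(self) -> np.ndarray:
        """Edge weights of all unordered species pairs (zeros included)."""
        iu = np.triu_indices(self.n_species, k=1)
        return self.weights[iu]


def sri(x: int, ya: int, yb: int) -> float:
    """Simple ratio index for one dyad from its flock counts.

    Parameters are the joint count ``x`` and the exclusive counts ``ya``,
    ``yb``.  All must be non-negative and at least one positive (a dyad in
    which neither species was ever observed has no defined association).
    """
    if x < 0 or ya < 0 or yb < 0:
        raise ValueError("counts must be non-negative")
    total = x + ya + yb
    if total == 0:
        raise UndefinedDyadError("dyad never observed in any flock")
    return x / total


def build_network(fm: FlockMatrix) -> AssociationNetwork:
    """Build the full SRI network for a site.

    Joint counts for every pair come from the cross-product of the incidence
    matrix; exclusive counts follow from the per-species incidences, so
    ``SRI_ab = x_ab / (n_a + n_b - x_ab)``.  Nodes are all observed species;
    never-co-occurring pairs get an explicit weight of zero.
    """
    m = fm.incidence.astype(np.int64)
    joint = m.T @ m                      # x_ab on off-diagonal
    n_per_species = np.diag(joint)      # flocks per species
    denom = n_per_species[:, None] + n_per_species[None, :] - joint
    with np.errstate(invalid="ignore"):
        w = np.where(denom > 0, joint / np.where(denom > 0, denom, 1), 0.0)
    np.fill_diagonal(w, 0.0)
    return AssociationNetwork(
        site_id=fm.site_id,
        species_ids=fm.species_ids,
        weights=w,
        n_flocks=fm.n_flocks,
    )


def edge_weight_cv(values: np.ndarray, ddof: int = 1) -> float:
    """CV of a dyad-weight vector: sample sd (default) over the mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DegenerateNetworkError("CV needs at least two dyads")
    mean = values.mean()
    if mean == 0:
        raise DegenerateNetworkError("no co-occurrences: CV undefined")
    return float(values.std(ddof=ddof) / mean)


def network_cv(net: AssociationNetwork, ddof: int = 1,
               include_zero_dyads: bool = True) -> float:
    """Coefficient of variation of the edge weights.

    The dyad set is, by default, *all* unordered pairs of observed species —
    structural zeros included — and the standard deviation is the sample
    (``ddof=1``) convention.  Both choices are exposed because neither is
    forced by the CV definition itself; excluding zero dyads conditions on
    the realized edge set and weakens the structure test.
    """
    w = net.dyad_weights()
    if not include_zero_dyads:
        w = w[w > 0]
    return edge_weight_cv(w, ddof=ddof)
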