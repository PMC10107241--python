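"""Reading, validating and writing flock observations, covariates and networks.

Canonical on-disk form for observations is the *long* table (one row per
species-in-flock record, columns ``flock_id, species_id``), matching how
field notebooks and public deposits are organized; a *wide* 0/1
flock-by-species table is accepted for convenience and yields an identical
:class:`~flocknet.network.FlockMatrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import AssociationNetwork, FlockMatrix

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("site_id", "elevation", "latitude",
                     "forest_cover", "human_footprint")


class ParseError(ValueError):
    """Malformed observation or covariate file."""


class EmptySiteError(ValueError):
    """Site has no valid flocks left after filtering."""


@dataclass(frozen=True)
class SiteCovariates:
    """Per-site environmental predictors.

    ``latitude`` is signed decimal degrees (models use its absolute value);
    ``elevation`` metres a.s.l.; ``forest_cover`` percent in [0, 100];
    ``human_footprint`` a unitless anthropogenic-pressure score >= 0.
    """

    site_id: str
    elevation: float
    latitude: float
    forest_cover: float
    human_footprint: float
    n_flocks: int

    def __post_init__(self) -> None:
        if not 0 <= self.forest_cover <= 100:
            raise ValueError(
                f"{self.site_id}: forest_cover {self.forest_cover} outside [0, 100]")
        if self.elevation < 0:
            raise ValueError(f"{self.site_id}: negative elevation")
        if self.human_footprint < 0:
            raise ValueError(f"{self.site_id}: negative human footprint")
        if self.n_flocks < 1:
            raise ValueError(f"{self.site_id}: n_flocks must be positive")


@dataclass(frozen=True)
class ValidationReport:
    site_id: str
    passed: bool
    min_flocks_rule: int
    issues: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.passed and self.issues:
            raise ValueError("a passed report cannot carry issues")


def _matrix_from_long(df: pd.DataFrame, site_id: str) -> FlockMatrix:
    flock_ids = list(dict.fromkeys(df["flock_id"]))
    species_ids = list(dict.fromkeys(df["species_id"]))
    m = np.zeros((len(flock_ids), len(species_ids)), dtype=np.int8)
    fidx = {f: i for i, f in enumerate(flock_ids)}
    sidx = {s: j for j, s in enumerate(species_ids)}
    for f, s in zip(df["flock_id"], df["species_id"]):
        m[fidx[f], sidx[s]] = 1
    return _filtered_matrix(site_id, flock_ids, species_ids, m)


def _filtered_matrix(site_id, flock_ids, species_ids, m) -> FlockMatrix:
    """Apply the inclusion filters: flocks need >=2 species, species >=1 flock."""
    keep_flocks = m.sum(axis=1) >= 2
    dropped = [f for f, k in zip(flock_ids, keep_flocks) if not k]
    if dropped:
        logger.warning("%s: dropped %d flock(s) with <2 species: %s",
                       site_id, len(dropped), dropped)
        m = m[keep_flocks]
        flock_ids = [f for f, k in zip(flock_ids, keep_flocks) if k]
    keep_species = m.sum(axis=0) >= 1 if m.size else np.zeros(len(species_ids), bool)
    gone = [s for s, k in zip(species_ids, keep_species) if not k]
    if gone:
        logger.warning("%s: dropped %d never-observed species: %s",
                       site_id, len(gone), gone)
        m = m[:, keep_species]
        species_ids = [s for s, k in zip(species_ids, keep_species) if k]
    if m.size == 0 or len(flock_ids) == 0:
        raise EmptySiteError(f"{site_id}: no valid flocks after filtering")
    return FlockMatrix(site_id=site_id, species_ids=tuple(species_ids),
                       flock_ids=tuple(flock_ids), incidence=m)


def read_flock_matrix(path: str | Path, dialect: str = "long",
                      site_id: str | None = None) -> FlockMatrix:
    """Read a site's flock composition table.

    ``dialect="long"`` expects columns ``flock_id, species_id``;
    ``dialect="wide"`` expects ``flock_id`` plus one 0/1 column per species.
    Single-species flocks and never-observed species are dropped with a
    logged warning; a file empty after filtering raises
    :class:`EmptySiteError`.
    """
    path = Path(path)
    sid = site_id if site_id is not None else path.stem
    try:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # pandas raises many flavours for bad files
        raise ParseError(f"{path}: cannot parse ({exc})") from exc
    if dialect == "long":
        missing = {"flock_id", "species_id"} - set(df.columns)
        if missing:
            raise ParseError(f"{path}: long dialect missing columns {sorted(missing)}")
        if df.duplicated(["flock_id", "species_id"]).any():
            dup = df[df.duplicated(["flock_id", "species_id"])].index[0]
            logger.warning("%s: duplicate record at data line %d ignored", sid, dup + 2)
            df = df.drop_duplicates(["flock_id", "species_id"])
        return _matrix_from_long(df, sid)
    if dialect == "wide":
        if "flock_id" not in df.columns:
            raise ParseError(f"{path}: wide dialect missing flock_id column")
        species = [c for c in df.columns if c != "flock_id"]
        if not species:
            raise ParseError(f"{path}: wide dialect has no species columns")
        try:
            m = df[species].astype(float).to_numpy()
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric presence value ({exc})") from exc
        if not np.isin(m, (0, 1)).all():
            bad = int(np.argwhere(~np.isin(m, (0, 1)))[0, 0])
            raise ParseError(f"{path}: non-binary entry at data line {bad + 2}")
        return _filtered_matrix(sid, list(df["flock_id"]), species, m.astype(np.int8))
    raise ValueError(f"unknown dialect {dialect!r}")


def read_site_covariates(path: str | Path) -> list[SiteCovariates]:
    """Read the per-site covariate table (CSV/TSV with a header row).

    Required columns: ``site_id, elevation, latitude, forest_cover,
    human_footprint``; ``n_flocks`` is used when present, else defaults must
    be supplied downstream by joining against the observation files.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(COVARIATE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing covariate column(s) {sorted(missing)}")
    if df.empty:
        logger.warning("%s: empty covariate table", path)
        return []
    records = []
    for _, row in df.iterrows():
        records.append(SiteCovariates(
            site_id=str(row["site_id"]),
            elevation=float(row["elevation"]),
            latitude=float(row["latitude"]),
            forest_cover=float(row["forest_cover"]),
            human_footprint=float(row["human_footprint"]),
            n_flocks=int(row["n_flocks"]) if "n_flocks" in df.columns else 1,
        ))
    return records


def validate_site(fm: FlockMatrix, min_flocks: int = 10) -> ValidationReport:
    """Check a site against the inclusion rule of >= ``min_flocks`` flocks.

    The bound is inclusive: a site with exactly ``min_flocks`` surveyed
    flocks passes.  Failures are reported, never raised, so batch runs can
    tabulate exclusions.
    """
    if min_flocks < 1:
        raise ValueError("min_flocks must be >= 1")
    issues = []
    if fm.n_flocks < min_flocks:
        issues.append(f"n_flocks {fm.n_flocks} < {min_flocks}")
    if fm.incidence.size and (fm.richness_per_flock() < 2).any():
        issues.append("flock with <2 species present")
    return ValidationReport(site_id=fm.site_id, passed=not issues,
                            min_flocks_rule=min_flocks, issues=tuple(issues))


def write_network(net: AssociationNetwork, path: str | Path,
                  format: str = "edgelist") -> None:
    """Write a network as an edge-list CSV or GraphML.

    Zero-weight dyads are omitted from the edge list (they are structural,
    recoverable from the node set); node identity is preserved in GraphML so
    isolated species survive a round trip there.
    """
    path = Path(path)
    iu, ju = np.triu_indices(net.n_species, k=1)
    mask = net.weights[iu, ju] > 0
    if format == "edgelist":
        df = pd.DataFrame({
            "source": [net.species_ids[i] for i in iu[mask]],
            "target": [net.species_ids[j] for j in ju[mask]],
            "weight": net.weights[iu[mask], ju[mask]],
        })
        df.to_csv(path, index=False, float_format="%.17g")
    elif format == "graphml":
        g = to_networkx(net)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network(path: str | Path, species_ids=None,
                 site_id: str | None = None) -> AssociationNetwork:
    """Read an edge-list CSV back into an :class:`AssociationNetwork`.

    ``species_ids`` restores the full node set (isolated species are not
    present in an edge list); by default nodes are the species appearing on
    edges, in order of first appearance.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"source", "target", "weight"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: edge list missing columns {sorted(missing)}")
    if species_ids is None:
        species_ids = list(dict.fromkeys(
            [*df["source"].astype(str), *df["target"].astype(str)]))
    sidx = {s: i for i, s in enumerate(species_ids)}
    n = len(species_ids)
    w = np.zeros((n, n))
    for s, t, wt in zip(df["source"].astype(str), df["target"].astype(str),
                        df["weight"].astype(float)):
        w[sidx[s], sidx[t]] = wt
        w[sidx[t], sidx[s]] = wt
    return AssociationNetwork(site_id=site_id or path.stem,
                              species_ids=tuple(species_ids), weights=w)


def to_networkx(net: AssociationNetwork) -> nx.Graph:
    """Undirected weighted networkx graph (zero-weight dyads excluded)."""
    g = nx.Graph(site_id=net.site_id)
    g.add_nodes_from(net.species_ids)
    iu, ju = np.triu_indices(net.n_species, k=1)
    for i, j in zip(iu, ju):
        if net.weights[i, j] > 0:
            g.add_edge(net.species_ids[i], net.species_ids[j],
                       weight=float(net.weights[i, j]))
    return g
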