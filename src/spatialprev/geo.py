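"""Area geography: centroid tables, adjacency graphs and derived spatial structure.

The spatial support shared by the hierarchical model and the scan statistic is
a set of areas (counties, districts, ...) each carrying a point centroid in
decimal degrees and a symmetric neighbourhood relation.  Centroids come in as
a small CSV (``id,lon,lat``); adjacency as a GAL-dialect neighbour list, the
de-facto interchange format for spatial weights.  From an :class:`AreaMap`
the module derives the intrinsic CAR structure matrix ``Q`` (graph Laplacian)
and the great-circle distance matrix used to grow circular scan windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "AreaMap",
    "StructureMatrix",
    "read_area_map",
    "structure_matrix",
    "distance_matrix",
    "EARTH_RADIUS_KM",
]


@dataclass(frozen=True)
class AreaMap:
    """Ordered set of areas with centroids and a symmetric adjacency relation.

    Parameters
    ----------
    area_ids
        Unique, opaque area identifiers.  Their order fixes the dense index
        used by every matrix the package derives.
    centroids
        ``(n_areas, 2)`` array of (longitude, latitude) in decimal degrees.
    neighbors
        Mapping ``area_id -> frozenset of neighbouring area_ids``.  Must be
        symmetric and free of self-loops; islands (empty sets) are allowed.
    """

    area_ids: tuple[str, ...]
    centroids: np.ndarray
    neighbors: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        ids = self.area_ids
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate area ids")
        cent = np.asarray(self.centroids, dtype=float)
        if cent.shape != (len(ids), 2):
            raise ValueError(f"centroids must be (n_areas, 2), got {cent.shape}")
        if not np.all(np.isfinite(cent)):
            raise ValueError("centroids must be finite")
        object.__setattr__(self, "centroids", cent)
        known = set(ids)
        for a in ids:
            for b in self.neighbors.get(a, frozenset()):
                if b not in known:
                    raise ValueError(f"unknown neighbor id {b!r} for area {a!r}")
                if b == a:
                    raise ValueError(f"self-neighbor for area {a!r}")
                if a not in self.neighbors.get(b, frozenset()):
                    raise ValueError(f"asymmetric adjacency: {a!r} ~ {b!r}")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.area_ids)}

    def adjacency_matrix(self) -> np.ndarray:
        """Dense 0/1 adjacency in file order."""
        idx = self.index
        A = np.zeros((self.n_areas, self.n_areas))
        for a, nbrs in self.neighbors.items():
            i = idx[a]
            for b in nbrs:
                A[i, idx[b]] = 1.0
        return A

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edge list as dense index pairs (i < j)."""
        idx = self.index
        out = []
        for a, nbrs in self.neighbors.items():
            i = idx[a]
            for b in nbrs:
                j = idx[b]
                if i < j:
                    out.append((i, j))
        return sorted(out)

    def component_labels(self) -> tuple[int, np.ndarray]:
        """Connected components of the adjacency graph: ``(k, labels)``."""
        A = csr_matrix(self.adjacency_matrix())
        k, labels = connected_components(A, directed=False)
        return int(k), labels


@dataclass(frozen=True)
class StructureMatrix:
    """Intrinsic CAR (ICAR) precision structure of an area graph.

    ``Q`` is the graph Laplacian: degree on the diagonal, −1 for each
    neighbour pair.  Row sums are zero, so ``Q`` is positive semidefinite
    with rank ``n_areas − n_components``.
    """

    Q: np.ndarray
    n_components: int
    component_labels: np.ndarray = field(repr=False)


def structure_matrix(area_map: AreaMap) -> StructureMatrix:
    """Build the ICAR structure matrix ``Q`` and count graph components."""
    A = area_map.adjacency_matrix()
    Q = np.diag(A.sum(axis=1)) - A
    k, labels = area_map.component_labels()
    return StructureMatrix(Q=Q, n_components=k, component_labels=labels)


def distance_matrix(area_map: AreaMap) -> np.ndarray:
    """Pairwise great-circle (haversine) distances between centroids, in km."""
    lon = np.radians(area_map.centroids[:, 0])
    lat = np.radians(area_map.centroids[:, 1])
    dlon = lon[None, :] - lon[:, None]
    dlat = lat[None, :] - lat[:, None]
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    h = np.clip(h, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    np.fill_diagonal(d, 0.0)
    return d


def _read_gal(path) -> dict[str, set[str]]:
    """Parse a GAL-dialect neighbour list into a (possibly asymmetric) dict.

    The first line carries the area count (either alone or as the second
    token of a four-token header); thereafter tokens come in groups of
    ``id  n_neighbors  neighbor_1 ... neighbor_n``.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty adjacency file {path}")
    header = lines[0].split()
    if len(header) >= 2:
        count = int(header[1])
    else:
        count = int(header[0])
    tokens = [tok for ln in lines[1:] for tok in ln.split()]
    neighbors: dict[str, set[str]] = {}
    pos = 0
    while pos < len(tokens):
        area = tokens[pos]
        try:
            n_nbr = int(tokens[pos + 1])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"malformed GAL record near token {pos} ({area!r})") from exc
        nbrs = tokens[pos + 2 : pos + 2 + n_nbr]
        if len(nbrs) != n_nbr:
            raise ValueError(f"truncated neighbor list for area {area!r}")
        if area in neighbors:
            raise ValueError(f"duplicate area id {area!r} in adjacency file")
        neighbors[area] = set(nbrs)
        pos += 2 + n_nbr
    if count != len(neighbors):
        warnings.warn(
            f"GAL header declares {count} areas but file lists {len(neighbors)}",
            stacklevel=3,
        )
    return neighbors


def read_area_map(centroid_path, adjacency_path) -> AreaMap:
    """Read and validate an :class:`AreaMap` from a centroid CSV + GAL file.

    The centroid file must be delimited text with header ``id,lon,lat``.
    One-directional adjacency entries are symmetrized with a warning;
    neighbour ids absent from the centroid table are rejected.
    """
    tab = pd.read_csv(centroid_path, dtype={"id": str})
    missing = {"id", "lon", "lat"} - set(tab.columns)
    if missing:
        raise ValueError(f"centroid table missing columns {sorted(missing)}")
    ids = tab["id"].tolist()
    if len(ids) != len(set(ids)):
        dup = tab["id"][tab["id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate area id {dup!r} in centroid table")
    known = set(ids)

    raw = _read_gal(adjacency_path)
    for area, nbrs in raw.items():
        if area not in known:
            raise ValueError(f"adjacency file names unknown area {area!r}")
        for b in nbrs:
            if b not in known:
                raise ValueError(f"adjacency for area {area!r} names unknown area {b!r}")
            if b == area:
                raise ValueError(f"self-neighbor for area {area!r}")
    # symmetrize
    sym = {a: set(raw.get(a, set())) for a in ids}
    fixed = False
    for a in ids:
        for b in sym[a]:
            if a not in sym[b]:
                sym[b].add(a)
                fixed = True
    if fixed:
        warnings.warn("one-directional adjacency entries symmetrized", stacklevel=2)

    return AreaMap(
        area_ids=tuple(ids),
        centroids=tab[["lon", "lat"]].to_numpy(dtype=float),
        neighbors={a: frozenset(sym[a]) for a in ids},
    )
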