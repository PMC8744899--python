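"""Areal neighbourhood structure and the intrinsic CAR (ICAR) precision algebra.

An :class:`AreaGraph` stores the contiguity structure of a set of areas
(counties).  The ICAR prior for a vector of area effects ``w`` penalises
squared differences between neighbours:

    log p(w | s2)  =  -(rank/2) * log(2*pi*s2)  -  (1/(2*s2)) * w' Q w,

where ``Q = D - W`` is the graph Laplacian (degree matrix minus adjacency),
``rank = n_areas - n_components`` is the rank of ``Q``, and the density is
proper only on the contrast space orthogonal to the per-component constant
vectors — hence the sum-to-zero identification used throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "AreaGraph",
    "IcarStructure",
    "read_adjacency",
    "build_icar_structure",
    "icar_log_density",
    "kenya_counties",
]


@dataclass(frozen=True)
class AreaGraph:
    """Symmetric areal adjacency: ordered labels plus undirected edges.

    Edges are stored as index pairs ``(i, j)`` with ``i < j``; duplicates are
    collapsed and self-loops rejected at construction.
    """

    area_ids: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    degree: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        n = len(self.area_ids)
        if len(set(self.area_ids)) != n:
            raise ValueError("duplicate area labels")
        seen = set()
        deg = np.zeros(n, dtype=int)
        canonical = []
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-edge on area {self.area_ids[i]!r}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge index out of range: ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            canonical.append(key)
            deg[i] += 1
            deg[j] += 1
        object.__setattr__(self, "edges", tuple(sorted(canonical)))
        object.__setattr__(self, "degree", deg)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, label: str) -> int:
        try:
            return self.area_ids.index(label)
        except ValueError:
            raise KeyError(f"unknown area label {label!r}") from None

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_label_pairs(
        cls, pairs: Iterable[tuple[str, str]], area_ids: Sequence[str] | None = None
    ) -> "AreaGraph":
        """Build a graph from (label, label) pairs.

        Label order is fixed by ``area_ids`` when given, else by first
        appearance in the pair stream.
        """
        pairs = list(pairs)
        if area_ids is None:
            order: dict[str, int] = {}
            for a, b in pairs:
                for lab in (a, b):
                    if lab not in order:
                        order[lab] = len(order)
            area_ids = list(order)
        index = {lab: k for k, lab in enumerate(area_ids)}
        edges = []
        for a, b in pairs:
            if a not in index:
                raise KeyError(f"unknown area label {a!r}")
            if b not in index:
                raise KeyError(f"unknown area label {b!r}")
            edges.append((index[a], index[b]))
        return cls(tuple(area_ids), tuple(edges))


@dataclass(frozen=True)
class IcarStructure:
    """Unscaled ICAR precision ``Q = D - W`` with its rank bookkeeping."""

    precision_unscaled: np.ndarray
    n_components: int
    rank: int
    edges: tuple[tuple[int, int], ...]

    @property
    def n_areas(self) -> int:
        return self.precision_unscaled.shape[0]


def _parse_edge_list(lines: list[str]) -> AreaGraph:
    pairs = []
    for ln, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise ValueError(f"line {ln}: expected two labels, got {len(tokens)}")
        pairs.append((tokens[0], tokens[1]))
    return AreaGraph.from_label_pairs(pairs)


def _parse_gal(lines: list[str]) -> AreaGraph:
    # GAL: header line whose last integer is the area count, then per area a
    # "label n_neighbours" line followed by a line listing the neighbours.
    content = [ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    header = content[0].split()
    n_declared = int(header[-1]) if len(header) == 1 else int(header[1])
    area_ids: list[str] = []
    neigh: dict[str, list[str]] = {}
    pos = 1
    for _ in range(n_declared):
        if pos >= len(content):
            raise ValueError(f"truncated GAL file: expected {n_declared} areas")
        parts = content[pos].split()
        pos += 1
        if len(parts) != 2:
            raise ValueError(f"malformed GAL area line: {content[pos - 1]!r}")
        label, deg = parts[0], int(parts[1])
        nbrs: list[str] = []
        if deg > 0:  # degree-0 areas carry no neighbour line
            if pos >= len(content):
                raise ValueError(f"area {label!r}: neighbour line missing")
            nbrs = content[pos].split()
            pos += 1
            if len(nbrs) != deg:
                raise ValueError(
                    f"area {label!r}: declared {deg} neighbours, listed {len(nbrs)}"
                )
        area_ids.append(label)
        neigh[label] = nbrs
    known = set(area_ids)
    for a, nbrs in neigh.items():
        for b in nbrs:
            if b not in known:
                raise ValueError(f"area {a!r} lists unknown neighbour {b!r}")
            if a not in neigh[b]:
                raise ValueError(f"asymmetric adjacency: {a!r} lists {b!r} but not vice versa")
    pairs = [(a, b) for a in area_ids for b in neigh[a] if a < b]
    # areas with degree 0 must still appear
    return AreaGraph.from_label_pairs(pairs, area_ids=area_ids)


def read_adjacency(source: str | Path) -> AreaGraph:
    """Read an areal adjacency from an edge-list or GAL text file.

    The dialect is sniffed from the first non-comment line: a GAL file opens
    with a header of integers (the last being the area count); an edge list
    has two labels per line with ``#`` comments.
    """
    path = Path(source)
    lines = path.read_text().splitlines()
    stripped = [ln.split("#", 1)[0].strip() for ln in lines]
    first = next((ln for ln in stripped if ln), None)
    if first is None:
        raise ValueError(f"{path}: empty adjacency file")
    tokens = first.split()
    is_gal = all(t.lstrip("-").isdigit() for t in tokens)
    return _parse_gal(lines) if is_gal else _parse_edge_list(lines)


def build_icar_structure(graph: AreaGraph) -> IcarStructure:
    """Assemble ``Q = D - W`` and report its rank via the component count.

    Isolated areas draw a warning: their frailty is informed only through the
    sum-to-zero constraint, not by any neighbour.
    """
    n = graph.n_areas
    if n < 2:
        raise ValueError("ICAR structure needs at least 2 areas")
    if (graph.degree == 0).any():
        isolated = [graph.area_ids[i] for i in np.flatnonzero(graph.degree == 0)]
        warnings.warn(
            f"isolated area(s) {isolated}: frailty identified only through "
            "the sum-to-zero constraint",
            stacklevel=2,
        )
    q = np.diag(graph.degree.astype(float))
    for i, j in graph.edges:
        q[i, j] -= 1.0
        q[j, i] -= 1.0
    n_components = nx.number_connected_components(graph.to_networkx())
    return IcarStructure(
        precision_unscaled=q,
        n_components=n_components,
        rank=n - n_components,
        edges=graph.edges,
    )


def icar_quadratic_form(frailties: np.ndarray, structure: IcarStructure) -> float:
    """``w' Q w``, equivalently the sum over edges of squared differences."""
    w = np.asarray(frailties, dtype=float)
    return float(w @ structure.precision_unscaled @ w)


def icar_log_density(
    frailties: np.ndarray, variance: float, structure: IcarStructure
) -> float:
    """Log density of the ICAR prior on the contrast space.

    Uses ``rank = n_areas - n_components`` in the normalising exponent so the
    frailty-variance posterior is proper under the sum-to-zero constraint.
    """
    if variance <= 0:
        raise ValueError(f"variance must be positive, got {variance}")
    w = np.asarray(frailties, dtype=float)
    if w.shape != (structure.n_areas,):
        raise ValueError(
            f"frailty vector length {w.shape} does not match {structure.n_areas} areas"
        )
    quad = icar_quadratic_form(w, structure)
    rank = structure.rank
    return -0.5 * rank * np.log(2.0 * np.pi * variance) - quad / (2.0 * variance)


def kenya_counties() -> AreaGraph:
    """Packaged 47-county Kenya-like contiguity graph.

    The adjacency approximates first-order (rook-style) contiguity of the 47
    Kenyan counties; it is hand-assembled from a small-scale map, not derived
    from official shapefiles, and is intended for simulation and testing.
    Users analysing real data should supply their own adjacency file.
    """
    ref = resources.files("arealsurv.data").joinpath("kenya_counties_approx.txt")
    return _parse_edge_list(ref.read_text().splitlines())
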