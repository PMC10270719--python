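"""Vietoris–Rips persistent homology over GF(2) with representative cycles.

Given a symmetric distance matrix on n points (brain regions), this module
builds the Vietoris–Rips filtration up to dimension 2 and computes persistent
homology in dimensions 0 (connected components) and 1 (loops) with
coefficients in the two-element field.  The death column of each finite
H1 bar is retained as a representative cycle: an even-degree edge set that
contains the bar's birth edge and bounds the hole whose lifetime the bar
records.

The reduction is the standard left-to-right column algorithm on the GF(2)
boundary matrix.  Columns are stored as Python integers used as bitmasks
(bit k = row k), so column addition is a single XOR and the pivot is
``bit_length() - 1``.  Simplices are totally ordered by
(filtration value, dimension, lexicographic vertex tuple); this fixed
tie-break makes pairings and representatives deterministic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Simplex",
    "Filtration",
    "Bar",
    "ReductionState",
    "build_filtration",
    "reduce_filtration",
    "representative_cycle",
    "tighten_cycle",
    "betti_curve",
]


@dataclass(frozen=True)
class Simplex:
    """A simplex of the filtration: sorted vertex tuple plus entry value.

    The Vietoris–Rips rule fixes the value: 0 for vertices, the pairwise
    distance for edges, and the longest edge for triangles.
    """

    vertices: tuple[int, ...]
    value: float

    @property
    def dim(self) -> int:
        return len(self.vertices) - 1

    def sort_key(self) -> tuple[float, int, tuple[int, ...]]:
        return (self.value, self.dim, self.vertices)


@dataclass
class Filtration:
    """Ordered simplices of a Vietoris–Rips complex (faces-first)."""

    simplices: list[Simplex]
    n_vertices: int

    def __len__(self) -> int:
        return len(self.simplices)


@dataclass
class Bar:
    """One persistence interval.

    ``death`` is ``math.inf`` for essential classes (features that survive
    the whole filtration, e.g. the one component left once everything is
    connected).  ``representative`` is only set for finite dimension-1 bars:
    the vertex indices of the GF(2) cycle stored in the reduced death
    column.
    """

    dim: int
    birth: float
    death: float
    birth_simplex: Simplex
    death_simplex: Simplex | None = None
    representative: tuple[int, ...] | None = None
    representative_edges: tuple[tuple[int, int], ...] | None = None

    @property
    def essential(self) -> bool:
        return math.isinf(self.death)

    @property
    def longitude(self) -> float:
        """Persistence (death − birth); the robustness measure of a loop."""
        return self.death - self.birth


@dataclass
class ReductionState:
    """Reduction bookkeeping needed to (re)extract representative cycles."""

    edges: list[Simplex] = field(default_factory=list)
    edge_index: dict[tuple[int, int], int] = field(default_factory=dict)
    # reduced (nonzero) triangle columns as edge-index bitmasks, keyed by the
    # edge index they killed
    death_columns: dict[int, int] = field(default_factory=dict)


def _validate_distance_values(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {d.shape}")
    if d.shape[0] < 1:
        raise ValueError("empty distance matrix")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.array_equal(d, d.T):
        raise ValueError("distance matrix is not exactly symmetric")
    if np.any(np.diag(d) != 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    return d


def build_filtration(
    d: np.ndarray,
    max_dim: int = 2,
    eps_max: float = math.inf,
) -> Filtration:
    """Build the Vietoris–Rips filtration of a distance matrix.

    Includes every simplex of dimension ≤ ``max_dim`` whose entry value is
    ≤ ``eps_max``, ordered by (value, dimension, lexicographic vertices).
    Triangles enter at the value of their longest edge.
    """
    d = _validate_distance_values(d)
    if max_dim not in (0, 1, 2):
        raise ValueError("max_dim must be 0, 1 or 2")
    n = d.shape[0]

    simplices: list[Simplex] = [Simplex((i,), 0.0) for i in range(n)]
    if max_dim >= 1:
        for i, j in itertools.combinations(range(n), 2):
            v = float(d[i, j])
            if v <= eps_max:
                simplices.append(Simplex((i, j), v))
    if max_dim >= 2:
        for i, j, k in itertools.combinations(range(n), 3):
            v = float(max(d[i, j], d[i, k], d[j, k]))
            if v <= eps_max:
                simplices.append(Simplex((i, j, k), v))

    simplices.sort(key=Simplex.sort_key)
    return Filtration(simplices=simplices, n_vertices=n)


def _split_by_dim(filtration: Filtration) -> tuple[list[Simplex], list[Simplex], list[Simplex]]:
    by_dim: tuple[list[Simplex], list[Simplex], list[Simplex]] = ([], [], [])
    prev_key: tuple[float, int, tuple[int, ...]] | None = None
    for s in filtration.simplices:
        key = s.sort_key()
        if prev_key is not None and key < prev_key:
            raise ValueError("filtration order violated (not sorted)")
        prev_key = key
        by_dim[s.dim].append(s)
    return by_dim


def reduce_filtration(
    filtration: Filtration,
    keep_zero_bars: bool = False,
) -> tuple[list[Bar], ReductionState]:
    """Compute the persistence barcode by GF(2) boundary-matrix reduction.

    Each column is reduced by adding earlier columns with the same pivot
    (lowest nonzero row) until it is empty or its pivot is unclaimed; a
    surviving pivot pairs the row simplex's birth with this column's value.
    Because the boundary matrix is block-diagonal by dimension, dimensions
    are reduced independently; the global simplex order fixes row and
    column order within each block.

    Returns the bars (dimension 0 and 1) plus the reduction state holding
    the reduced death columns used for representative cycles.  Bars with
    zero longitude are dropped unless ``keep_zero_bars`` — barcodes show
    only visible bars, but Betti-number bookkeeping needs all of them.
    """
    vertices, edges, triangles = _split_by_dim(filtration)
    n = filtration.n_vertices
    if len(vertices) != n:
        raise ValueError("filtration must contain every vertex")

    state = ReductionState(edges=edges)
    state.edge_index = {e.vertices: idx for idx, e in enumerate(edges)}

    bars: list[Bar] = []

    # --- dimension 0: reduce edge columns over vertex rows -----------------
    # vertex rows are ordered by index (all vertices share value 0)
    pivot_v: dict[int, int] = {}  # vertex row -> reduced column mask
    h1_creator_edges: list[int] = []  # edge indices whose column vanished
    for eidx, e in enumerate(edges):
        i, j = e.vertices
        col = (1 << i) | (1 << j)
        while col:
            low = col.bit_length() - 1
            other = pivot_v.get(low)
            if other is None:
                pivot_v[low] = col
                bars.append(Bar(dim=0, birth=0.0, death=e.value,
                                birth_simplex=vertices[low], death_simplex=e))
                break
            col ^= other
        else:
            h1_creator_edges.append(eidx)
    for v in range(n):
        if v not in pivot_v:
            bars.append(Bar(dim=0, birth=0.0, death=math.inf,
                            birth_simplex=vertices[v]))

    # --- dimension 1: reduce triangle columns over edge rows ---------------
    pivot_e: dict[int, int] = {}  # edge row -> triangle position in `triangles`
    cols_t: dict[int, int] = {}  # triangle position -> reduced column mask
    eindex = state.edge_index
    for tpos, t in enumerate(triangles):
        i, j, k = t.vertices
        col = (1 << eindex[(i, j)]) | (1 << eindex[(i, k)]) | (1 << eindex[(j, k)])
        while col:
            low = col.bit_length() - 1
            other = pivot_e.get(low)
            if other is None:
                pivot_e[low] = tpos
                cols_t[tpos] = col
                state.death_columns[low] = col
                birth_edge = edges[low]
                bar = Bar(dim=1, birth=birth_edge.value, death=t.value,
                          birth_simplex=birth_edge, death_simplex=t)
                _attach_representative(bar, col, state)
                bars.append(bar)
                break
            col ^= cols_t[other]
        # a vanished triangle column would create an H2 class: out of scope

    killed = set(pivot_e)
    for eidx in h1_creator_edges:
        if eidx not in killed:
            e = edges[eidx]
            bars.append(Bar(dim=1, birth=e.value, death=math.inf, birth_simplex=e))

    if not keep_zero_bars:
        bars = [b for b in bars if b.essential or b.death > b.birth]
    bars.sort(key=lambda b: (b.dim, b.birth, b.death,
                             b.birth_simplex.vertices))
    return bars, state


def _mask_to_edges(mask: int, state: ReductionState) -> tuple[tuple[int, int], ...]:
    out = []
    while mask:
        low = mask.bit_length() - 1
        out.append(state.edges[low].vertices)
        mask ^= 1 << low
    return tuple(sorted(out))


def _attach_representative(bar: Bar, col_mask: int, state: ReductionState) -> None:
    edges = _mask_to_edges(col_mask, state)
    bar.representative_edges = edges
    bar.representative = tuple(sorted({v for e in edges for v in e}))


def representative_cycle(bar: Bar, state: ReductionState) -> tuple[int, ...]:
    """Vertex indices of the GF(2) cycle witnessing a finite H1 bar.

    The cycle is the reduced column of the bar's death triangle: it contains
    the birth edge and every vertex it touches has even degree.  It is a
    valid representative of the dying class but not guaranteed to be the
    shortest one (see :func:`tighten_cycle`).
    """
    if bar.dim != 1:
        raise ValueError("representative cycles exist only for dimension-1 bars")
    if bar.essential:
        raise ValueError("essential bars have no death column to represent them")
    if bar.representative is not None:
        return bar.representative
    eidx = state.edge_index[bar.birth_simplex.vertices]
    col = state.death_columns[eidx]
    _attach_representative(bar, col, state)
    assert bar.representative is not None
    return bar.representative


def tighten_cycle(
    bar: Bar,
    d: np.ndarray,
    state: ReductionState,
) -> tuple[tuple[int, int], ...]:
    """Greedily shorten a representative cycle by adding triangle boundaries.

    Adds (XOR) the boundary of any triangle already present strictly before
    the bar's death whenever doing so reduces the edge count; repeats to a
    fixed point.  The result stays homologous to the original class just
    before its death.  Off by default in the pipeline — the un-tightened
    death-column cycle is the documented convention.
    """
    if bar.representative_edges is None:
        representative_cycle(bar, state)
    assert bar.representative_edges is not None
    eindex = state.edge_index
    mask = 0
    for e in bar.representative_edges:
        mask |= 1 << eindex[e]

    n = int(np.asarray(d).shape[0])
    tri_masks = []
    for i, j, k in itertools.combinations(range(n), 3):
        v = max(d[i, j], d[i, k], d[j, k])
        if v < bar.death:
            tri_masks.append((1 << eindex[(i, j)]) | (1 << eindex[(i, k)])
                             | (1 << eindex[(j, k)]))

    improved = True
    while improved:
        improved = False
        size = mask.bit_count()
        for tm in tri_masks:
            cand = mask ^ tm
            if cand.bit_count() < size:
                mask = cand
                size = cand.bit_count()
                improved = True
    return _mask_to_edges(mask, state)


def betti_curve(bars: Iterable[Bar], dim: int, eps: float) -> int:
    """Betti number at scale ``eps``: bars alive on [birth, death).

    Pass bars computed with ``keep_zero_bars=True`` for exact counts; a
    zero-longitude bar never satisfies birth ≤ eps < death, so retained
    zero bars are harmless but discarded positive bars would undercount.
    """
    return sum(1 for b in bars
               if b.dim == dim and b.birth <= eps < b.death)
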