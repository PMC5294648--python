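"""Graph filtration over distance matrices: Betti-0 curves, barcodes,
single-linkage (minimax-path) matrices, projected ultrametrics, dendrograms.

Conventions
-----------
* An edge exists at filtration value ``eps`` iff its distance ``d <= eps``
  (closed threshold).  A distance of exactly 1 is the non-edge sentinel and
  is never processed; the filtration domain is ``[0, 1)``.
* Bipartite matrices span ``n1 + n2`` nodes (rows first, then columns);
  symmetric matrices span ``p`` nodes.  Nodes never merged by any edge stay
  isolated, and never-connected pairs are censored at 1.
* Equal edge weights are processed in a fixed row-major order.  Ties cannot
  change component counts or first-connection values, only which merge is
  bookkept first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Union

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_network import BipartiteDistanceMatrix, SymmetricDistanceMatrix

__all__ = [
    "FiltrationEvent",
    "Filtration",
    "BettiCurve",
    "Barcode",
    "SingleLinkageMatrix",
    "ProjectedUltrametric",
    "MergeTree",
    "filtrate",
    "partition_betti_curve",
    "barcode",
    "single_linkage_matrix",
    "projected_ultrametric",
    "dendrogram",
]

_CENSOR = 1.0

DistanceInput = Union[BipartiteDistanceMatrix, SymmetricDistanceMatrix]


@dataclass(frozen=True)
class FiltrationEvent:
    """One component merge during the filtration.

    ``member_nodes`` lists every node of the merged component as
    ``(partition_tag, node_index)`` pairs; ``component_a`` / ``component_b``
    hold the two pre-merge memberships (global node ids).
    """

    epsilon: float
    merged_components: tuple[int, int]
    member_nodes: tuple[tuple[str, int], ...]
    component_a: tuple[int, ...]
    component_b: tuple[int, ...]


@dataclass
class Filtration:
    """The ordered merge-event list plus the node universe it refers to.

    Iterable over its events; global node ids run over rows first, then
    columns (bipartite) or over the single node set (symmetric).
    """

    events: list
    node_partition: tuple[str, ...]
    node_labels: tuple[str, ...]
    partitions: tuple[str, ...]

    def __iter__(self) -> Iterator[FiltrationEvent]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def n_nodes(self) -> int:
        return len(self.node_partition)

    def partition_size(self, partition: str) -> int:
        if partition == "all":
            return self.n_nodes
        n = sum(1 for t in self.node_partition if t == partition)
        if n == 0:
            raise ValueError(f"unknown partition {partition!r}")
        return n

    def partition_nodes(self, partition: str) -> np.ndarray:
        if partition == "all":
            return np.arange(self.n_nodes)
        idx = np.array([i for i, t in enumerate(self.node_partition) if t == partition], dtype=int)
        if idx.size == 0:
            raise ValueError(f"unknown partition {partition!r}")
        return idx


# ---------------------------------------------------------------------------
# edge extraction + union-find
# ---------------------------------------------------------------------------

def _bipartite_edge_lists(D: np.ndarray):
    """(eps, a, b) triples for entries < 1, ascending, row-major tie order."""
    n1 = D.shape[0]
    ii, jj = np.nonzero(D < _CENSOR)  # row-major order
    w = D[ii, jj]
    order = np.argsort(w, kind="stable")
    return w[order].tolist(), ii[order].tolist(), (jj[order] + n1).tolist()


def _symmetric_edge_lists(D: np.ndarray):
    iu, ju = np.triu_indices_from(D, k=1)
    keep = D[iu, ju] < _CENSOR
    iu, ju, w = iu[keep], ju[keep], D[iu, ju][keep]
    order = np.argsort(w, kind="stable")
    return w[order].tolist(), iu[order].tolist(), ju[order].tolist()


class _UnionFind:
    __slots__ = ("parent", "members")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.members = [[i] for i in range(n)]

    def find(self, a: int) -> int:
        parent = self.parent
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a


def _distance_payload(D: DistanceInput):
    """Normalize either matrix type to (edge lists, node partitions, labels)."""
    if isinstance(D, BipartiteDistanceMatrix):
        w, aa, bb = _bipartite_edge_lists(D.values)
        part = (D.row_partition,) * len(D.row_labels) + (D.col_partition,) * len(D.col_labels)
        labels = D.row_labels + D.col_labels
        partitions = (D.row_partition, D.col_partition)
    elif isinstance(D, SymmetricDistanceMatrix):
        w, aa, bb = _symmetric_edge_lists(D.values)
        part = ("all",) * len(D.labels)
        labels = D.labels
        partitions = ("all",)
    else:
        raise TypeError(f"unsupported distance matrix type {type(D).__name__}")
    return w, aa, bb, part, labels, partitions


def filtrate(D: DistanceInput) -> Filtration:
    """Run the graph filtration and record every component merge.

    Unique edge weights below 1 are processed in ascending order through a
    disjoint-set union over the node universe; each merge is recorded with
    its filtration value and the two component memberships.
    """
    w, aa, bb, part, labels, partitions = _distance_payload(D)
    n = len(part)
    uf = _UnionFind(n)
    events: list[FiltrationEvent] = []
    for eps, a, b in zip(w, aa, bb):
        ra, rb = uf.find(a), uf.find(b)
        if ra == rb:
            continue
        mem_a = tuple(uf.members[ra])
        mem_b = tuple(uf.members[rb])
        merged = mem_a + mem_b
        events.append(
            FiltrationEvent(
                epsilon=float(eps),
                merged_components=(ra, rb),
                member_nodes=tuple((part[i], i) for i in merged),
                component_a=mem_a,
                component_b=mem_b,
            )
        )
        # union by size
        if len(uf.members[ra]) < len(uf.members[rb]):
            ra, rb = rb, ra
        uf.parent[rb] = ra
        uf.members[ra].extend(uf.members[rb])
        uf.members[rb] = []
    return Filtration(events=events, node_partition=part, node_labels=labels,
                      partitions=partitions)


# ---------------------------------------------------------------------------
# fast array-level paths (used by the permutation engines; algorithmically
# identical to the event-based route above, checked by tests)
# ---------------------------------------------------------------------------

def _merge_eps_bipartite(D: np.ndarray):
    """Per-partition merge epsilons of a bipartite distance matrix.

    Returns (row_eps, col_eps): the sorted filtration values at which two
    components each holding at least one row (resp. column) node merge.
    The row-partition Betti-0 curve is ``n1 - #{row_eps <= eps}``.
    """
    n1, n2 = D.shape
    w, aa, bb = _bipartite_edge_lists(D)
    parent = list(range(n1 + n2))
    nrow = [1] * n1 + [0] * n2
    ncol = [0] * n1 + [1] * n2
    row_eps: list[float] = []
    col_eps: list[float] = []
    for eps, a, b in zip(w, aa, bb):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        while parent[b] != b:
            parent[b] = parent[parent[b]]
            b = parent[b]
        if a == b:
            continue
        if nrow[a] and nrow[b]:
            row_eps.append(eps)
        if ncol[a] and ncol[b]:
            col_eps.append(eps)
        parent[b] = a
        nrow[a] += nrow[b]
        ncol[a] += ncol[b]
    return np.asarray(row_eps), np.asarray(col_eps)


def _connection_times(w, aa, bb, n: int) -> np.ndarray:
    """Full n x n matrix of first-connection filtration values.

    Entry (i, j) is the smallest eps at which i and j share a component;
    1 when never connected below 1; diagonal 0."""
    times = np.full((n, n), _CENSOR)
    np.fill_diagonal(times, 0.0)
    parent = list(range(n))
    members = [[i] for i in range(n)]
    for eps, a, b in zip(w, aa, bb):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        while parent[b] != b:
            parent[b] = parent[parent[b]]
            b = parent[b]
        if a == b:
            continue
        ma, mb = members[a], members[b]
        times[np.ix_(ma, mb)] = eps
        times[np.ix_(mb, ma)] = eps
        if len(ma) < len(mb):
            a, b = b, a
            ma, mb = mb, ma
        parent[b] = a
        ma.extend(mb)
        members[b] = []
    return times


def _connection_times_bipartite(D: np.ndarray) -> np.ndarray:
    n1, n2 = D.shape
    w, aa, bb = _bipartite_edge_lists(D)
    return _connection_times(w, aa, bb, n1 + n2)


def _slm_bipartite(D: np.ndarray) -> np.ndarray:
    """Cross-block single-linkage matrix (rows x columns) of a bipartite D.

    Tracks row-side and column-side component members separately so only
    cross pairs are ever assigned; small components are filled with plain
    loops (fancy indexing costs more than it saves on tiny graphs).
    """
    n1, n2 = D.shape
    w, aa, bb = _bipartite_edge_lists(D)
    times = np.full((n1, n2), _CENSOR)
    parent = list(range(n1 + n2))
    rows = [[i] if i < n1 else [] for i in range(n1 + n2)]
    cols = [[] if i < n1 else [i - n1] for i in range(n1 + n2)]
    for eps, a, b in zip(w, aa, bb):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        while parent[b] != b:
            parent[b] = parent[parent[b]]
            b = parent[b]
        if a == b:
            continue
        ra, ca, rb, cb = rows[a], cols[a], rows[b], cols[b]
        for block_rows, block_cols in ((ra, cb), (rb, ca)):
            if len(block_rows) * len(block_cols) > 256:
                times[np.asarray(block_rows)[:, None], block_cols] = eps
            else:
                for i in block_rows:
                    ti = times[i]
                    for j in block_cols:
                        ti[j] = eps
        parent[b] = a
        ra.extend(rb)
        ca.extend(cb)
        rows[b] = cols[b] = []
    return times


# ---------------------------------------------------------------------------
# topological summaries
# ---------------------------------------------------------------------------

@dataclass
class BettiCurve:
    """Right-continuous step function of connected-component counts
    restricted to one node partition.

    ``breakpoints`` are the (sorted, possibly repeated) merge epsilons that
    each decrement the count by one; the curve starts at ``size``.
    """

    partition: str
    size: int
    breakpoints: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.sort(np.asarray(self.breakpoints, dtype=float))
        if len(self.breakpoints) > max(self.size - 1, 0):
            raise ValueError("more merges than partition size allows")

    def value(self, eps):
        """Component count at threshold(s) ``eps`` (edges with d <= eps)."""
        return self.size - np.searchsorted(self.breakpoints, eps, side="right")

    @property
    def counts(self) -> np.ndarray:
        """Count after each breakpoint."""
        return self.size - np.arange(1, len(self.breakpoints) + 1)

    @property
    def final_count(self) -> int:
        return self.size - len(self.breakpoints)


@dataclass
class Barcode:
    """Birth-death intervals of the partition-projected components.

    Every node is born at 0; a bar dies at each merge epsilon of the
    partition's Betti curve; survivors are censored at death = 1.
    Exactly ``size`` bars for a ``size``-node partition.
    """

    partition: str
    size: int
    deaths: np.ndarray

    def __post_init__(self) -> None:
        self.deaths = np.sort(np.asarray(self.deaths, dtype=float))
        if len(self.deaths) != self.size:
            raise ValueError("barcode must have exactly one bar per partition node")

    @property
    def bars(self) -> list[tuple[float, float]]:
        return [(0.0, float(d)) for d in self.deaths]

    def betti(self, eps):
        """Component count recovered from the bars: deaths strictly above
        ``eps`` (censored bars at 1 always count below the censor value)."""
        return self.size - np.searchsorted(self.deaths, eps, side="right")


@dataclass
class SingleLinkageMatrix:
    """First-connection filtration value for every (row node, column node)
    pair -- the minimax (bottleneck) path distance over the graph; 1 for
    never-connected pairs."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.row_labels = tuple(self.row_labels)
        self.col_labels = tuple(self.col_labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("values shape does not match labels")


@dataclass
class ProjectedUltrametric:
    """First-connection value between same-partition node pairs; an exact
    ultrametric (zero diagonal, symmetric, max-inequality)."""

    partition: str
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.labels)
        if self.values.shape != (p, p):
            raise ValueError("values shape does not match labels")


def _events_connection_times(filt: Filtration) -> np.ndarray:
    times = np.full((filt.n_nodes, filt.n_nodes), _CENSOR)
    np.fill_diagonal(times, 0.0)
    for ev in filt.events:
        a = list(ev.component_a)
        b = list(ev.component_b)
        times[np.ix_(a, b)] = ev.epsilon
        times[np.ix_(b, a)] = ev.epsilon
    return times


def partition_betti_curve(filt: Filtration, partition: str) -> BettiCurve:
    """Betti-0 curve of the components projected onto one node partition.

    A component of the full graph counts toward the partition iff it
    contains at least one node of that partition; the curve starts at the
    partition size and drops by one at every merge joining two such
    components.
    """
    size = filt.partition_size(partition)
    part = filt.node_partition
    eps = []
    for ev in filt.events:
        in_a = partition == "all" or any(part[i] == partition for i in ev.component_a)
        in_b = partition == "all" or any(part[i] == partition for i in ev.component_b)
        if in_a and in_b:
            eps.append(ev.epsilon)
    return BettiCurve(partition=partition, size=size, breakpoints=np.asarray(eps))


def barcode(filt: Filtration, partition: str) -> Barcode:
    """Barcode of the partition-projected components (births all at 0,
    deaths at the Betti-curve breakpoints, survivors censored at 1)."""
    curve = partition_betti_curve(filt, partition)
    n_censored = curve.size - len(curve.breakpoints)
    deaths = np.concatenate([curve.breakpoints, np.full(n_censored, _CENSOR)])
    return Barcode(partition=partition, size=curve.size, deaths=deaths)


def single_linkage_matrix(filt: Filtration, D: DistanceInput) -> SingleLinkageMatrix:
    """Single-linkage matrix from the filtration of ``D``.

    For a bipartite input the result is the (row ROI, column ROI) block; for
    a symmetric input it is the full matrix with zero diagonal.
    """
    times = _events_connection_times(filt)
    if isinstance(D, BipartiteDistanceMatrix):
        n1 = len(D.row_labels)
        if filt.n_nodes != n1 + len(D.col_labels):
            raise ValueError("filtration does not match distance matrix")
        return SingleLinkageMatrix(D.row_labels, D.col_labels, times[:n1, n1:])
    if isinstance(D, SymmetricDistanceMatrix):
        if filt.n_nodes != len(D.labels):
            raise ValueError("filtration does not match distance matrix")
        return SingleLinkageMatrix(D.labels, D.labels, times)
    raise TypeError(f"unsupported distance matrix type {type(D).__name__}")


def projected_ultrametric(filt: Filtration, partition: str) -> ProjectedUltrametric:
    """First-connection values among the nodes of one partition."""
    idx = filt.partition_nodes(partition)
    times = _events_connection_times(filt)
    labels = tuple(filt.node_labels[i] for i in idx)
    return ProjectedUltrametric(partition=partition, labels=labels,
                                values=times[np.ix_(idx, idx)])


@dataclass
class MergeTree:
    """Single-linkage merge tree with fixed leaf order along the axis."""

    labels: tuple[str, ...]
    linkage: np.ndarray
    leaf_order: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def _check_ultrametric(U: np.ndarray, atol: float = 1e-9) -> None:
    if not np.allclose(U, U.T, atol=atol):
        raise ValueError("dendrogram: matrix is not symmetric")
    if np.abs(np.diag(U)).max(initial=0.0) > atol:
        raise ValueError("dendrogram: diagonal must be zero")
    for j in range(U.shape[0]):
        bound = np.maximum.outer(U[:, j], U[j, :])
        if (U > bound + atol).any():
            raise ValueError("dendrogram: input violates the ultrametric inequality")


def dendrogram(ultra: ProjectedUltrametric) -> MergeTree:
    """Single-linkage merge tree whose cophenetic matrix equals the input
    ultrametric exactly.  Raises on non-ultrametric input."""
    U = np.asarray(ultra.values, dtype=float)
    if U.shape == (1, 1):
        return MergeTree(labels=ultra.labels, linkage=np.empty((0, 4)),
                         leaf_order=np.array([0]))
    _check_ultrametric(U)
    Z = hierarchy.linkage(squareform(U, checks=False), method="single")
    return MergeTree(labels=ultra.labels, linkage=Z,
                     leaf_order=hierarchy.leaves_list(Z))
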