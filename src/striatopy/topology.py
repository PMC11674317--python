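"""Directed-clique statistics of the striatal connectome.

The network is abstracted to a directed graph: one typed vertex per neuron
and at most one directed edge per ordered neuron pair (synapse multiplicity
kept as an edge weight). A directed n-clique is an ordered tuple of n+1
distinct vertices (v0, …, vn) with an edge vi→vj for every i < j — a
feedforward motif whose first element is presynaptic to all others (the
source) and whose last is postsynaptic to all others (the sink). Counting
follows the directed-flag-complex convention (ordered tuples), the same
convention as the flagser family of tools; with reciprocally connected
pairs inside a clique several orderings of the same vertex set are counted
separately. A strict set-based variant (each admissible vertex set counted
once) is available for sensitivity analysis.

To avoid boundary artifacts, cliques can be restricted to those
intersecting a small central *kernel* of neurons; the kernel plus all its
pre- and postsynaptic partners form the *core* on which the counting runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import SynapseTable, NeuronInstance, erode_synapses

__all__ = [
    "DirectedGraph",
    "CliqueCountVector",
    "KernelCoreSelection",
    "digraph_from_synapses",
    "count_directed_cliques",
    "enumerate_directed_cliques",
    "brute_force_cliques",
    "select_kernel_core",
    "classify_cliques",
    "synapse_count_histogram",
    "erosion_curves",
    "COMPOSITION_CLASSES",
]

INTERNEURON_TYPES = frozenset({"FS", "ChIN", "LTS"})
COMPOSITION_CLASSES = ("all_dSPN", "all_iSPN", "contains_interneuron",
                       "mixed_dSPN_iSPN")


class DirectedGraph:
    """Simple directed graph: typed vertices, weighted edges, no self-loops.

    Vertices are arbitrary integer ids; adjacency is kept as sorted
    out-neighbor arrays over a dense internal index for fast sorted-array
    intersection during clique enumeration.
    """

    def __init__(self, vertex_ids: Sequence[int],
                 vertex_types: Mapping[int, str] | None,
                 edges: Iterable[tuple[int, int, int]]):
        self.vertex_ids = np.asarray(sorted(set(int(v) for v in vertex_ids)),
                                     dtype=np.int64)
        self._index = {int(v): k for k, v in enumerate(self.vertex_ids)}
        self.vertex_types = dict(vertex_types or {})
        n = len(self.vertex_ids)
        adj: list[list[int]] = [[] for _ in range(n)]
        self._weights: dict[tuple[int, int], int] = {}
        for u, v, w in edges:
            if u == v:
                raise ValueError(f"self-loop on vertex {u}")
            iu, iv = self._index[int(u)], self._index[int(v)]
            key = (iu, iv)
            if key in self._weights:
                raise ValueError(f"duplicate edge {u}->{v}")
            self._weights[key] = int(w)
            adj[iu].append(iv)
        self.out = [np.asarray(sorted(a), dtype=np.int64) for a in adj]

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    @property
    def n_edges(self) -> int:
        return len(self._weights)

    def has_edge(self, u: int, v: int) -> bool:
        return (self._index[int(u)], self._index[int(v)]) in self._weights

    def weight(self, u: int, v: int) -> int:
        return self._weights[(self._index[int(u)], self._index[int(v)])]

    def edge_list(self) -> list[tuple[int, int, int]]:
        return [(int(self.vertex_ids[iu]), int(self.vertex_ids[iv]), w)
                for (iu, iv), w in self._weights.items()]

    def type_of(self, v: int) -> str:
        return self.vertex_types.get(int(v), "unknown")

    def subgraph(self, vertices: Iterable[int]) -> "DirectedGraph":
        vs = set(int(v) for v in vertices)
        edges = [(u, v, w) for u, v, w in self.edge_list()
                 if u in vs and v in vs]
        types = {v: self.vertex_types[v] for v in vs
                 if v in self.vertex_types}
        return DirectedGraph(vs, types, edges)


def digraph_from_synapses(table: SynapseTable,
                          instances: Sequence[NeuronInstance] | None = None,
                          include_isolated: bool = False) -> DirectedGraph:
    """Collapse a synapse table to a directed graph.

    Edge (u, v) iff at least one synapse u→v; the weight is the synapse
    count. Reciprocally connected pairs yield two edges. With `instances`
    given and include_isolated=True every modeled neuron becomes a vertex
    even if unconnected.
    """
    df = table.df
    if len(df) and (df.pre_id == df.post_id).any():
        raise ValueError("self-synapse rows are not allowed")
    grouped = df.groupby(["pre_id", "post_id"], sort=True).size()
    edges = [(int(u), int(v), int(w)) for (u, v), w in grouped.items()]
    if instances is not None:
        types = {i.id: i.cell_type for i in instances
                 if i.cell_type != "other"}
        if include_isolated:
            vids = list(types)
        else:
            vids = sorted(set(df.pre_id) | set(df.post_id))
        types = {v: types[v] for v in vids if v in types}
    else:
        vids = sorted(set(df.pre_id) | set(df.post_id))
        types = {}
        for col_id, col_t in (("pre_id", "pre_type"), ("post_id", "post_type")):
            if col_t in df.columns:
                types.update(dict(zip(df[col_id].astype(int), df[col_t])))
    return DirectedGraph(vids, types, edges)


@dataclass
class CliqueCountVector:
    """counts[n] = number of directed n-cliques (n+1 neurons each)."""

    counts: np.ndarray
    max_dimension: int

    @property
    def top_dimension(self) -> int:
        """Highest dimension with a nonzero count (-1 if empty)."""
        nz = np.flatnonzero(self.counts)
        return int(nz[-1]) if len(nz) else -1

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts,
                         index=pd.RangeIndex(len(self.counts),
                                             name="dimension"),
                         name="count")


def _bit_adjacency(graph: DirectedGraph) -> list[int]:
    """Out-neighborhoods as integer bitsets over the dense vertex index."""
    out = [0] * graph.n_vertices
    for (iu, iv) in graph._weights:
        out[iu] |= 1 << iv
    return out


def _trim(counts: list[int]) -> np.ndarray:
    arr = np.asarray(counts, dtype=np.int64)
    nz = np.flatnonzero(arr)
    return arr[:nz[-1] + 1] if len(nz) else arr[:1]


def count_directed_cliques(graph: DirectedGraph,
                           kernel: Iterable[int] | None = None,
                           max_dim: int = 13,
                           convention: str = "tuple") -> CliqueCountVector:
    """Exact directed-clique counts per dimension, optionally kernel-filtered.

    A clique is counted iff its vertex set intersects the kernel (any
    position). convention='tuple' counts ordered tuples (directed flag
    complex, primary); convention='set' counts each admissible vertex set
    once (strict reading of the unique-source/sink definition; differs only
    when reciprocal edges occur inside cliques).
    """
    if convention == "set":
        return _count_set_convention(graph, kernel, max_dim)
    if convention != "tuple":
        raise ValueError(f"unknown convention {convention!r}")
    n = graph.n_vertices
    kbits = None
    if kernel is not None:
        kbits = 0
        for v in kernel:
            kbits |= 1 << graph._index[int(v)]
    counts = [0] * (max_dim + 1)
    counts[0] = n if kbits is None else int(kbits.bit_count())
    out = _bit_adjacency(graph)
    unfiltered = kbits is None

    def extend(cand: int, depth: int, has_kernel: bool) -> None:
        deeper = depth < max_dim
        c = cand
        while c:
            lsb = c & -c
            c ^= lsb
            u = lsb.bit_length() - 1
            hk = has_kernel or bool(kbits is not None and kbits & lsb)
            if unfiltered or hk:
                counts[depth] += 1
            if not deeper:
                continue
            nxt = cand & out[u]
            if not nxt:
                continue
            if not unfiltered and not hk and not (nxt & kbits):
                continue
            extend(nxt, depth + 1, hk)

    for v0 in range(n):
        cand = out[v0]
        if not cand:
            continue
        hk0 = bool(kbits is not None and (kbits >> v0) & 1)
        if not unfiltered and not hk0 and not (cand & kbits):
            continue
        extend(cand, 1, hk0)
    counts = _trim(counts)
    return CliqueCountVector(counts, max_dimension=len(counts) - 1)


def enumerate_directed_cliques(graph: DirectedGraph,
                               kernel: Iterable[int] | None = None,
                               max_dim: int = 13,
                               min_dim: int = 0):
    """Yield directed cliques as ordered tuples of vertex ids (source first).

    Same tuple convention and kernel filter as count_directed_cliques.
    """
    n = graph.n_vertices
    kbits = None
    if kernel is not None:
        kbits = 0
        for v in kernel:
            kbits |= 1 << graph._index[int(v)]
    out = _bit_adjacency(graph)
    ids = graph.vertex_ids

    def extend(prefix: list[int], cand: int, has_kernel: bool):
        if len(prefix) - 1 >= max_dim:
            return
        c = cand
        while c:
            lsb = c & -c
            c ^= lsb
            u = lsb.bit_length() - 1
            hk = has_kernel or bool(kbits is not None and kbits & lsb)
            tup = prefix + [u]
            if (kbits is None or hk) and len(tup) - 1 >= min_dim:
                yield tuple(int(ids[i]) for i in tup)
            nxt = cand & out[u]
            if not nxt:
                continue
            if kbits is not None and not hk and not (nxt & kbits):
                continue
            yield from extend(tup, nxt, hk)

    for v0 in range(n):
        hk0 = bool(kbits is not None and (kbits >> v0) & 1)
        if (kbits is None or hk0) and min_dim == 0:
            yield (int(ids[v0]),)
        if not out[v0]:
            continue
        if kbits is not None and not hk0 and not (out[v0] & kbits):
            continue
        yield from extend([v0], out[v0], hk0)


def _count_set_convention(graph, kernel, max_dim) -> CliqueCountVector:
    if graph.n_vertices > 2000:
        raise ValueError("set convention is limited to small graphs")
    seen: list[set] = [set() for _ in range(max_dim + 1)]
    for tup in enumerate_directed_cliques(graph, kernel, max_dim):
        seen[len(tup) - 1].add(frozenset(tup))
    counts = _trim([len(s) for s in seen])
    return CliqueCountVector(counts, max_dimension=len(counts) - 1)


def brute_force_cliques(graph: DirectedGraph,
                        max_dim: int | None = None
                        ) -> tuple[CliqueCountVector, list[tuple[int, ...]]]:
    """Independent oracle: exhaustive ordered-tuple enumeration.

    Checks every permutation of every vertex subset against the edge set;
    guarded to ≤ 15 vertices. Returns the count vector and the clique list.
    """
    n = graph.n_vertices
    if n > 15:
        raise ValueError("brute force is guarded to graphs with <= 15 vertices")
    ids = [int(v) for v in graph.vertex_ids]
    edge = {(u, v) for u, v, _ in graph.edge_list()}
    top = max_dim if max_dim is not None else n - 1
    counts = [0] * (top + 1)
    cliques: list[tuple[int, ...]] = []
    for v in ids:
        counts[0] += 1
        cliques.append((v,))
    for size in range(2, top + 2):
        for subset in itertools.combinations(ids, size):
            # quick reject: every pair must be connected in some direction
            if any((a, b) not in edge and (b, a) not in edge
                   for a, b in itertools.combinations(subset, 2)):
                continue
            for perm in itertools.permutations(subset):
                if all((perm[i], perm[j]) in edge
                       for i in range(size) for j in range(i + 1, size)):
                    counts[size - 1] += 1
                    cliques.append(perm)
    counts = _trim(counts)
    return CliqueCountVector(counts, len(counts) - 1), cliques


# ---------------------------------------------------------------------------
# Kernel / core selection
# ---------------------------------------------------------------------------

@dataclass
class KernelCoreSelection:
    kernel: set[int]
    core: set[int]

    def __post_init__(self):
        if not self.kernel <= self.core:
            raise ValueError("kernel must be a subset of the core")


def select_kernel_core(instances: Sequence[NeuronInstance],
                       graph: DirectedGraph,
                       k: int = 8,
                       composition: Mapping[str, int] | None = None,
                       center: np.ndarray | None = None
                       ) -> KernelCoreSelection:
    """Kernel = the nearest-to-center neurons per requested composition
    (default 4 dSPN + 4 iSPN, ties broken by lower id); core = kernel plus
    every pre- and postsynaptic partner of a kernel neuron."""
    composition = dict(composition or {"dSPN": k // 2, "iSPN": k - k // 2})
    if sum(composition.values()) != k:
        raise ValueError("composition must sum to k")
    pos = np.array([i.position for i in instances])
    if center is None:
        center = 0.5 * (pos.min(axis=0) + pos.max(axis=0))
    kernel: set[int] = set()
    in_graph = set(int(v) for v in graph.vertex_ids)
    for ctype, need in composition.items():
        cands = [i for i in instances
                 if i.cell_type == ctype and i.id in in_graph]
        if len(cands) < need:
            raise ValueError(
                f"not enough {ctype} neurons for the kernel "
                f"({len(cands)} < {need})")
        cands.sort(key=lambda i: (np.linalg.norm(i.position - center), i.id))
        kernel.update(i.id for i in cands[:need])
    core = set(kernel)
    for u, v, _ in graph.edge_list():
        if u in kernel:
            core.add(v)
        if v in kernel:
            core.add(u)
    return KernelCoreSelection(kernel=kernel, core=core)


# ---------------------------------------------------------------------------
# Composition and synapse-weight breakdowns
# ---------------------------------------------------------------------------

def classify_composition(types: Sequence[str]) -> str:
    """Exhaustive, mutually exclusive composition class of one clique."""
    ts = set(types)
    unknown = ts - {"dSPN", "iSPN"} - INTERNEURON_TYPES
    if unknown:
        raise ValueError(f"unknown cell types {sorted(unknown)}")
    if ts & INTERNEURON_TYPES:
        return "contains_interneuron"
    if ts == {"dSPN"}:
        return "all_dSPN"
    if ts == {"iSPN"}:
        return "all_iSPN"
    return "mixed_dSPN_iSPN"


def classify_cliques(cliques: Iterable[tuple[int, ...]],
                     types: Mapping[int, str]) -> pd.DataFrame:
    """Count cliques per (dimension, composition class); exhaustive partition."""
    counts: dict[tuple[int, str], int] = {}
    for tup in cliques:
        dim = len(tup) - 1
        cls = classify_composition([types[v] for v in tup])
        counts[(dim, cls)] = counts.get((dim, cls), 0) + 1
    rows = [(d, c, n) for (d, c), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["dimension", "composition", "count"])


def synapse_count_histogram(cliques: Iterable[tuple[int, ...]],
                            graph: DirectedGraph,
                            dimension: int) -> pd.Series:
    """Histogram of per-clique synapse totals at one dimension.

    A clique's synapse total sums the multiplicities of every edge present
    between its vertices, in both directions where reciprocal edges exist.
    """
    totals: dict[int, int] = {}
    for tup in cliques:
        if len(tup) - 1 != dimension:
            continue
        tot = 0
        for a, b in itertools.permutations(tup, 2):
            if graph.has_edge(a, b):
                tot += graph.weight(a, b)
        totals[tot] = totals.get(tot, 0) + 1
    ser = pd.Series(totals, name="n_cliques").sort_index()
    ser.index.name = "total_synapses"
    return ser


# ---------------------------------------------------------------------------
# Erosion experiment
# ---------------------------------------------------------------------------

def erosion_curves(table: SynapseTable,
                   instances: Sequence[NeuronInstance],
                   fractions: Sequence[float],
                   scope: str = "all",
                   reps: int = 3,
                   seed: int = 0,
                   max_dim: int = 13) -> pd.DataFrame:
    """Mean clique counts per dimension after random synapse removal.

    For each removal fraction and repetition: erode, rebuild the graph,
    count. Returns a tidy frame (fraction, dimension, mean_count); totals
    are non-increasing in the fraction in expectation.
    """
    rows = []
    for frac in fractions:
        acc: dict[int, float] = {}
        for rep in range(reps):
            eroded = erode_synapses(table, frac, scope=scope,
                                    seed=seed + 97 * rep + int(frac * 1e6))
            g = digraph_from_synapses(eroded, instances,
                                      include_isolated=True)
            cc = count_directed_cliques(g, max_dim=max_dim)
            for d, c in enumerate(cc.counts):
                acc[d] = acc.get(d, 0.0) + c / reps
        for d in sorted(acc):
            rows.append((frac, d, acc[d]))
    return pd.DataFrame(rows, columns=["fraction", "dimension", "mean_count"])
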