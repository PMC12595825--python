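"""Weighted median-joining networks for multistate STR haplotypes.

A median-joining network generalises the minimum spanning network by adding
inferred intermediate haplotypes (median vectors, the multistate analogue
of Steiner points): for connected triplets of nodes the component-wise
median of the three allele vectors is a candidate ancestor whose inclusion
can shorten the network. Loci are weighted 1-10 inversely to their
variance, so fast-mutating loci contribute less to edge lengths.

Maximum-parsimony (MP) pruning afterwards deletes median nodes that are not
needed by any minimum-total-cost subgraph spanning the observed haplotypes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .io import AnalysisView, MISSING_INT, ViewMode

__all__ = [
    "LocusWeights",
    "MJGraph",
    "compute_weights",
    "median_joining",
    "mp_prune",
    "export_graph",
]


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


@dataclass
class LocusWeights:
    """Integer locus weights in [1, 10], inversely proportional to variance."""

    weights: dict[str, int]
    variances: dict[str, float]

    def __post_init__(self) -> None:
        for loc, w in self.weights.items():
            if not 1 <= w <= 10:
                raise ValueError(f"weight {w} for {loc} outside [1, 10]")

    def vector(self, loci: Sequence[str]) -> np.ndarray:
        return np.asarray([self.weights[l] for l in loci], dtype=np.int64)


def compute_weights(view: AnalysisView, clamp: tuple[int, int] = (1, 10)) -> LocusWeights:
    """Locus weights from allelic variances.

    ``w_l = round(1 + 9 * (1/v_l - 1/v_max) / (1/v_min - 1/v_max))`` over
    loci with positive variance, so the least variable locus gets 10 and
    the most variable gets 1. Zero-variance loci get the maximum weight;
    if all variances are equal every locus gets the midpoint weight 5.
    """
    lo, hi = clamp
    mid = (lo + hi) // 2
    variances: dict[str, float] = {}
    distinct = {tuple(row) for row in view.matrix.tolist()}
    if len(distinct) < 2:
        raise ValueError("need >= 2 distinct haplotypes to compute weights")
    for j, loc in enumerate(view.effective_loci):
        col = view.matrix[:, j]
        obs = col[col != MISSING_INT].astype(float)
        variances[loc] = float(np.var(obs)) if obs.size else 0.0
    positive = {l: v for l, v in variances.items() if v > 0}
    weights: dict[str, int] = {}
    if positive:
        inv = {l: 1.0 / v for l, v in positive.items()}
        imax, imin = max(inv.values()), min(inv.values())
        for l, iv in inv.items():
            if imax == imin:
                weights[l] = mid
            else:
                w = lo + (hi - lo) * (iv - imin) / (imax - imin)
                weights[l] = min(hi, max(lo, _round_half_away(w)))
    for l, v in variances.items():
        if v == 0:
            weights[l] = hi
    return LocusWeights(weights=weights, variances=variances)


@dataclass
class MJGraph:
    """Median-joining network: observed + median haplotype nodes.

    Nodes are integer allele tuples; attributes live in ``graph`` (a
    networkx Graph): ``kind`` (OBSERVED/MEDIAN), ``multiplicity``,
    ``populations`` (label → count). Edge attributes: ``steps`` (locus →
    absolute step count over mutated loci) and ``length`` (weighted).
    """

    graph: nx.Graph
    loci: tuple[str, ...]
    weights: LocusWeights
    epsilon: int = 0

    @property
    def observed(self) -> list[tuple]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "OBSERVED"]

    @property
    def medians(self) -> list[tuple]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "MEDIAN"]

    def total_cost(self) -> float:
        return sum(d["length"] for _, _, d in self.graph.edges(data=True))

    def mst_cost(self) -> float:
        """Cost of a minimum spanning tree over the current node set."""
        nodes = sorted(self.graph.nodes)
        w = self.weights.vector(self.loci)
        return _mst_cost(nodes, w)


def _wdist_matrix(nodes: Sequence[tuple], w: np.ndarray) -> np.ndarray:
    X = np.asarray(nodes, dtype=np.int64)
    return np.abs(X[:, None, :] - X[None, :, :]).dot(w).astype(float)


def _mst_cost(nodes: Sequence[tuple], w: np.ndarray) -> float:
    if len(nodes) < 2:
        return 0.0
    D = _wdist_matrix(nodes, w)
    return float(minimum_spanning_tree(D).sum())


def _msn_edges(nodes: Sequence[tuple], w: np.ndarray, epsilon: int) -> list[tuple[int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    An edge (u, v) is feasible iff its weighted distance is within epsilon
    of the minimax path weight between u and v (the largest edge on their
    MST path); at epsilon = 0 this is exactly the union of all MSTs.
    """
    n = len(nodes)
    if n < 2:
        return []
    D = _wdist_matrix(nodes, w)
    mst = minimum_spanning_tree(D).toarray()
    T = nx.Graph()
    T.add_nodes_from(range(n))
    for i, j in zip(*np.nonzero(mst)):
        T.add_edge(int(i), int(j), weight=float(mst[i, j]))
    # minimax path weights via per-source DFS over the tree
    lam = np.zeros((n, n))
    for s in range(n):
        stack = [(s, 0.0)]
        seen = {s}
        while stack:
            u, mx = stack.pop()
            for v in T.neighbors(u):
                if v not in seen:
                    seen.add(v)
                    m2 = max(mx, T[u][v]["weight"])
                    lam[s, v] = m2
                    stack.append((v, m2))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] <= lam[i, j] + epsilon:
                edges.append((i, j))
    return edges


def _component_median(a: tuple, b: tuple, c: tuple) -> tuple:
    return tuple(sorted(t)[1] for t in zip(a, b, c))


def median_joining(
    view: AnalysisView,
    weights: Optional[LocusWeights] = None,
    epsilon: int = 0,
) -> MJGraph:
    """Build the weighted median-joining network for a NETWORK-view dataset.

    Samples with a missing allele at any retained locus are excluded with a
    warning. The algorithm alternates (1) the epsilon-relaxed minimum
    spanning network over the current node set with (2) addition of
    component-wise median vectors of connected triplets whenever their
    inclusion strictly lowers the minimum-spanning cost, until no candidate
    improves. The final graph contains every link of every minimum spanning
    tree over the final node set (epsilon = 0 case).
    """
    if view.mode not in (ViewMode.NETWORK, ViewMode.RHO):
        warnings.warn("median_joining expects a NETWORK view")
    keep = ~(view.matrix == MISSING_INT).any(axis=1)
    if not keep.all():
        dropped = [view.sample_ids[i] for i in np.nonzero(~keep)[0]]
        warnings.warn(f"excluding {len(dropped)} sample(s) with missing alleles: {dropped}")
    rows = view.matrix[keep]
    if rows.shape[0] == 0:
        raise ValueError("no complete haplotypes to build a network from")
    sample_pops = [p for p, k in zip(view.populations, keep) if k]
    if weights is None:
        weights = compute_weights(view)
    w = weights.vector(view.effective_loci)

    mult: dict[tuple, int] = {}
    pops: dict[tuple, dict[str, int]] = {}
    for row, pop in zip(rows.tolist(), sample_pops):
        key = tuple(row)
        mult[key] = mult.get(key, 0) + 1
        pops.setdefault(key, {})[pop] = pops.setdefault(key, {}).get(pop, 0) + 1

    observed = sorted(mult)
    nodes = list(observed)
    # iterative median addition: one best candidate per round, strict
    # integer cost decrease guarantees termination
    while True:
        edges = _msn_edges(nodes, w, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        base = _mst_cost(nodes, w)
        node_set = set(nodes)
        candidates = set()
        for i, j in edges:
            for k in adj[i] | adj[j]:
                if k in (i, j):
                    continue
                m = _component_median(nodes[i], nodes[j], nodes[k])
                if m not in node_set:
                    candidates.add(m)
        best: Optional[tuple] = None
        best_cost = base
        for m in sorted(candidates):
            c = _mst_cost(nodes + [m], w)
            if c < best_cost - 1e-9:
                best, best_cost = m, c
        if best is None:
            break
        nodes.append(best)
        nodes.sort()

    g = _build_graph(nodes, set(observed), mult, pops, view.effective_loci, weights, epsilon)
    return g


def _build_graph(
    nodes: Sequence[tuple],
    observed: set,
    mult: Mapping[tuple, int],
    pops: Mapping[tuple, Mapping[str, int]],
    loci: Sequence[str],
    weights: LocusWeights,
    epsilon: int,
) -> MJGraph:
    w = weights.vector(loci)
    g = nx.Graph()
    for v in nodes:
        is_obs = v in observed
        g.add_node(
            v,
            kind="OBSERVED" if is_obs else "MEDIAN",
            multiplicity=mult.get(v, 0),
            populations=dict(pops.get(v, {})),
        )
    for i, j in _msn_edges(list(nodes), w, epsilon):
        u, v = nodes[i], nodes[j]
        steps = {loc: abs(a - b) for loc, a, b in zip(loci, u, v) if a != b}
        length = float(sum(weights.weights[loc] * s for loc, s in steps.items()))
        if length == 0:
            raise AssertionError("zero-length edge between distinct nodes")
        g.add_edge(u, v, steps=steps, length=length)
    return MJGraph(graph=g, loci=tuple(loci), weights=weights, epsilon=epsilon)


def mp_prune(g: MJGraph, exact_cutoff: int = 12) -> MJGraph:
    """Maximum-parsimony pruning of median nodes.

    Keeps only medians that appear in some inclusion-minimal median subset
    achieving the minimum spanning cost over the observed haplotypes
    (exact subset enumeration up to ``exact_cutoff`` medians, greedy
    elimination beyond). The rebuilt network spans all observed nodes and
    its cost never increases; the operation is idempotent.
    """
    observed = sorted(g.observed)
    medians = sorted(g.medians)
    w = g.weights.vector(g.loci)
    if not medians:
        return g
    if len(medians) <= exact_cutoff:
        costs: dict[frozenset, float] = {}
        for r in range(len(medians) + 1):
            for sub in itertools.combinations(medians, r):
                costs[frozenset(sub)] = _mst_cost(observed + list(sub), w)
        best = min(costs.values())
        winners = [s for s, c in costs.items() if c <= best + 1e-9]
        minimal = [
            s for s in winners if not any(t < s for t in winners)
        ]
        keep = sorted(set().union(*minimal)) if minimal else []
    else:
        keep = list(medians)
        improved = True
        while improved:
            improved = False
            base = _mst_cost(observed + keep, w)
            for m in sorted(keep):
                trial = [x for x in keep if x != m]
                if _mst_cost(observed + trial, w) <= base + 1e-9:
                    keep = trial
                    improved = True
                    break
    nodes = sorted(observed + list(keep))
    mult = {v: g.graph.nodes[v]["multiplicity"] for v in observed}
    pops = {v: g.graph.nodes[v]["populations"] for v in observed}
    return _build_graph(nodes, set(observed), mult, pops, g.loci, g.weights, g.epsilon)


def export_graph(g: MJGraph, path: str | Path, format: str = "graphml") -> None:
    """Write the network as GraphML (default) or DOT.

    Node attributes: type, haplotype vector, multiplicity, population
    composition. Edge attributes: mutated loci with step counts, weighted
    length.
    """
    path = Path(path)
    out = nx.Graph()
    ids = {v: f"n{i}" for i, v in enumerate(sorted(g.graph.nodes))}
    for v, d in g.graph.nodes(data=True):
        out.add_node(
            ids[v],
            vector=",".join(map(str, v)),
            kind=d["kind"],
            multiplicity=int(d["multiplicity"]),
            populations=";".join(f"{p}:{c}" for p, c in sorted(d["populations"].items())),
        )
    for u, v, d in g.graph.edges(data=True):
        out.add_edge(
            ids[u],
            ids[v],
            steps=";".join(f"{loc}:{s}" for loc, s in sorted(d["steps"].items())),
            length=float(d["length"]),
        )
    if format == "graphml":
        nx.write_graphml(out, path)
    elif format == "dot":
        lines = ["graph mjnet {"]
        for n, d in out.nodes(data=True):
            shape = "circle" if d["kind"] == "OBSERVED" else "point"
            lines.append(f'  {n} [label="{d["vector"]}" shape={shape}];')
        for u, v, d in out.edges(data=True):
            lines.append(f'  {u} -- {v} [label="{d["steps"]}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
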