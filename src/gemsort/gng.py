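"""Streaming graph-network clustering (growing neural gas).

Nodes live in feature space and move toward incoming spikes; edges connect
the two nodes nearest each spike and age out when unused.  Connected
components of the node graph are the clusters, so cluster structure can
grow, split and drift while spikes stream through -- no spike is retained
after it is classified.

The adaptation step follows the canonical growing-neural-gas recipe: the
nearest node W1 absorbs the squared distance into its error, W1 moves by
``e_s1`` and its edge neighbours by ``e_nbr`` toward the spike, the edge
W1-W2 is refreshed, W1's other edges age, over-aged edges (and then
edgeless nodes) are deleted, and every ``lam``-th spike a node is inserted
halfway between the highest-error node and its highest-error neighbour.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .core import SortResult
from .features import FeatureVector


@dataclass
class GngParams:
    """Graph hyperparameters; defaults are the values used for the
    16-channel benchmark (node budget ~12 per channel)."""

    max_nodes: int = 192
    edge_prune_age: int = 8
    n_init: int = 2
    e_s1: float = 0.8
    e_nbr: float = 0.001
    alpha: float = 0.5
    beta: float = 0.01
    lam: int = 10
    node_stale_age: int | None = 400  # delete nodes unused this many steps
    edge_gate_factor: float | None = 3.0  # no new edge when d2 > factor x typical d1
    reject_distance: float | None = None  # off by default: no outlier class

    def __post_init__(self) -> None:
        if not (0.0 < self.e_nbr < self.e_s1 < 1.0):
            raise ValueError("moving rates must satisfy 0 < e_nbr < e_s1 < 1")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.beta < 1.0):
            raise ValueError("alpha and beta must lie in (0, 1)")
        if self.lam < 1:
            raise ValueError("lam must be >= 1")
        if self.max_nodes < self.n_init:
            raise ValueError("max_nodes must be >= n_init")
        if self.edge_prune_age < 0:
            raise ValueError("edge_prune_age must be >= 0")


class Graph:
    """Mutable growing-neural-gas state: node positions, errors, aged edges.

    Node ids are creation-ordered and never reused.  Separately from the
    structural connected components, every node carries a persistent
    cluster *label*: labels are inherited when nodes are inserted, minted
    afresh when a cluster fissions, re-homogenised per side whenever a
    component splits, and never rewritten when components merge.  Spikes
    are named by these labels, so cluster identity survives node turnover
    and transient bridges between clusters.
    """

    def __init__(self, params: GngParams | None = None):
        self.params = params or GngParams()
        self.positions: dict[int, np.ndarray] = {}
        self.errors: dict[int, float] = {}
        self.adjacency: dict[int, dict[int, int]] = {}  # id -> {nbr: age}
        self.labels: dict[int, int] = {}  # persistent cluster label per node
        self.last_active: dict[int, int] = {}  # step at which node was last W1
        self._next_id = 0
        self._next_label = 0
        self._steps = 0
        self._d1_scale: float | None = None  # running robust scale of d1

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def node_ids(self) -> list[int]:
        return sorted(self.positions)

    @property
    def edges(self) -> list[tuple[int, int, int]]:
        """(a, b, age) triples with a < b."""
        return [
            (a, b, age)
            for a, nbrs in self.adjacency.items()
            for b, age in nbrs.items()
            if a < b
        ]

    def add_node(self, position: np.ndarray, error: float = 0.0, label: int | None = None) -> int:
        if self.n_nodes >= self.params.max_nodes:
            raise RuntimeError("node budget exhausted")
        nid = self._next_id
        self._next_id += 1
        self.positions[nid] = np.asarray(position, dtype=float).copy()
        self.errors[nid] = error
        self.adjacency[nid] = {}
        if label is None:
            label = self._next_label
            self._next_label += 1
        self.labels[nid] = label
        self.last_active[nid] = self._steps
        return nid

    def _remove_node(self, nid: int) -> None:
        for nbr in list(self.adjacency[nid]):
            del self.adjacency[nbr][nid]
        del self.adjacency[nid]
        del self.positions[nid]
        del self.errors[nid]
        del self.labels[nid]
        del self.last_active[nid]

    def _set_edge(self, a: int, b: int, age: int = 0) -> None:
        self.adjacency[a][b] = age
        self.adjacency[b][a] = age

    def _remove_edge(self, a: int, b: int) -> None:
        del self.adjacency[a][b]
        del self.adjacency[b][a]

    def _members_of(self, nid: int) -> set[int]:
        seen = {nid}
        queue = deque([nid])
        while queue:
            cur = queue.popleft()
            for nbr in self.adjacency[cur]:
                if nbr not in seen:
                    seen.add(nbr)
                    queue.append(nbr)
        return seen

    def component_of(self, nid: int) -> int:
        """Structural component id (= smallest node id) containing ``nid``."""
        return min(self._members_of(nid))

    def label_of(self, nid: int) -> int:
        """Persistent cluster label of the component containing ``nid``.

        Labels are carried by nodes: inherited at insertion, minted afresh
        only when a cluster genuinely fissions, homogenised per side at
        every split, and never rewritten on a merge.  The component answers
        with the label of the majority of its nodes (ties to the smaller
        label), so a transient bridge renames nothing permanently.
        """
        return self._majority_label(self._members_of(nid))

    def _majority_label(self, members: set[int]) -> int:
        counts: dict[int, int] = {}
        for m in members:
            counts[self.labels[m]] = counts.get(self.labels[m], 0) + 1
        return min(counts, key=lambda lab: (-counts[lab], lab))

    def _split_check(self, a: int, b: int) -> None:
        """Restore label uniformity after removing edge a-b disconnects a
        component.

        Each side is homogenised to its own majority label, so two clusters
        that were joined by a transient bridge recover their original names
        when it dissolves.  If both sides carry the same majority (a true
        fission of one cluster), the smaller side is minted a fresh label.
        This keeps every component label-uniform and no two disconnected
        components ever share a name."""
        if a not in self.positions or b not in self.positions:
            return
        side_a = self._members_of(a)
        if b in side_a:
            return  # still connected
        side_b = self._members_of(b)
        maj_a = self._majority_label(side_a)
        maj_b = self._majority_label(side_b)
        if maj_a == maj_b:
            smaller, keep = (
                (side_b, side_a) if len(side_b) <= len(side_a) else (side_a, side_b)
            )
            fresh = self._next_label
            self._next_label += 1
            for m in smaller:
                self.labels[m] = fresh
            for m in keep:
                self.labels[m] = maj_a
        else:
            for m in side_a:
                self.labels[m] = maj_a
            for m in side_b:
                self.labels[m] = maj_b


def nearest_two(graph: Graph, x: np.ndarray) -> tuple[int, int, float, float]:
    """Ids and distances of the two nodes nearest ``x`` (ties to lower id)."""
    if graph.n_nodes < 2:
        raise ValueError("graph needs at least two nodes")
    ids = graph.node_ids
    pos = np.stack([graph.positions[i] for i in ids])
    d = np.linalg.norm(pos - np.asarray(x, dtype=float), axis=1)
    order = np.argsort(d, kind="stable")  # ids sorted ascending => ties to lower id
    i1, i2 = int(order[0]), int(order[1])
    return ids[i1], ids[i2], float(d[i1]), float(d[i2])


def adapt(graph: Graph, x: np.ndarray) -> int:
    """One streaming step; returns the cluster id assigned to ``x``.

    Requires an initialised graph (>= 2 nodes); see module docstring for
    the step sequence.
    """
    p = graph.params
    x = np.asarray(x, dtype=float)
    w1, w2, d1, d2 = nearest_two(graph, x)

    # track the typical nearest-node distance (outlier-clipped EMA); an
    # incoming spike much farther than this is an outlier (noise event or
    # overlapping-spike distortion): it is still classified, but it must
    # neither drag a node out of its cluster nor wire clusters together
    if graph._d1_scale is None:
        graph._d1_scale = d1 if d1 > 0 else None
    else:
        graph._d1_scale += 0.01 * (min(d1, 3.0 * graph._d1_scale) - graph._d1_scale)
    gate = (
        None
        if p.edge_gate_factor is None or graph._d1_scale is None
        else p.edge_gate_factor * graph._d1_scale
    )
    if gate is not None and d1 > gate:
        if p.reject_distance is not None and d1 > p.reject_distance:
            return -1
        return _local_label(graph, x, w1, d1)

    graph.errors[w1] += d1 * d1
    graph.positions[w1] += p.e_s1 * (x - graph.positions[w1])
    for nbr in graph.adjacency[w1]:
        graph.positions[nbr] += p.e_nbr * (x - graph.positions[nbr])

    # refresh the W1-W2 edge, age W1's other edges, prune the over-aged
    if gate is None or d2 <= gate:
        graph._set_edge(w1, w2, 0)
    for nbr in list(graph.adjacency[w1]):
        if nbr != w2:
            age = graph.adjacency[w1][nbr] + 1
            if age > p.edge_prune_age:
                graph._remove_edge(w1, nbr)
                if not graph.adjacency[nbr]:
                    graph._remove_node(nbr)
                else:
                    graph._split_check(w1, nbr)
            else:
                graph._set_edge(w1, nbr, age)

    graph.last_active[w1] = graph._steps
    graph._steps += 1
    if graph._steps % p.lam == 0:
        if p.node_stale_age is not None:
            _prune_stale_nodes(graph)
        if graph.n_nodes < p.max_nodes:
            _insert_node(graph)
            for nid in graph.errors:
                graph.errors[nid] *= 1.0 - p.beta

    if p.reject_distance is not None and d1 > p.reject_distance:
        return -1
    return _local_label(graph, x, w1, d1)


def _local_label(graph: Graph, x: np.ndarray, w1: int, d1: float) -> int:
    """Cluster label for a spike: majority label among the nodes of W1's
    component lying near the spike (within twice its nearest-node
    distance).

    While a transient bridge joins two clusters into one component, the
    nodes near the spike are the ones of its own cluster, so both sides
    keep their names for the duration of the bridge; a lone mislabelled
    immigrant node is likewise outvoted by its neighbourhood.
    """
    members = graph._members_of(w1)
    radius = 2.0 * d1 + 1e-12
    local = [m for m in members if np.linalg.norm(graph.positions[m] - x) <= radius]
    if not local:
        local = [w1]
    counts: dict[int, int] = {}
    for m in local:
        counts[graph.labels[m]] = counts.get(graph.labels[m], 0) + 1
    return min(counts, key=lambda lab: (-counts[lab], lab))


def _prune_stale_nodes(graph: Graph) -> None:
    """Delete nodes that have not won a spike for ``node_stale_age`` steps.

    Spikes stop arriving in a region of feature space either because the
    underlying cluster drifted away or because the node was parked between
    clusters (e.g. on an outlier) and never serves real data; such nodes
    would otherwise keep stale edges alive indefinitely, since edge ages
    only advance on the winning node's edges.
    """
    stale = [
        nid
        for nid, last in graph.last_active.items()
        if graph._steps - last > graph.params.node_stale_age
    ]
    if len(stale) >= graph.n_nodes - 1:
        # never empty the graph below the two nodes adaptation requires
        stale = sorted(stale, key=lambda nid: graph.last_active[nid])[
            : max(0, graph.n_nodes - 2)
        ]
    for nid in stale:
        nbrs = list(graph.adjacency[nid])
        graph._remove_node(nid)
        # removing a cut vertex can split its component
        for a in nbrs:
            if a not in graph.positions:
                continue
            for b in nbrs:
                if b > a and b in graph.positions:
                    graph._split_check(a, b)


def _insert_node(graph: Graph) -> None:
    """Insert a node halfway between the worst node and its worst neighbour.

    Only neighbours carrying the worst node's own cluster label qualify: a
    node is inserted to refine the interior of a cluster, and a midpoint
    across a transient bridge between two clusters would plant a
    foreign-labelled node inside one of them.
    """
    q = min(graph.errors, key=lambda nid: (-graph.errors[nid], nid))
    nbrs = [n for n in graph.adjacency[q] if graph.labels[n] == graph.labels[q]]
    if not nbrs:
        nbrs = list(graph.adjacency[q])  # lone bridgehead: canonical choice
    if not nbrs:
        return
    f = min(nbrs, key=lambda nid: (-graph.errors[nid], nid))
    graph.errors[q] *= graph.params.alpha
    graph.errors[f] *= graph.params.alpha
    new = graph.add_node(
        (graph.positions[q] + graph.positions[f]) / 2.0,
        error=graph.errors[q],
        label=graph.labels[q],
    )
    graph._remove_edge(q, f)
    graph._set_edge(q, new, 0)
    graph._set_edge(f, new, 0)


def cluster_components(graph: Graph) -> dict[int, int]:
    """Map node id -> cluster id (smallest node id of its component)."""
    labels: dict[int, int] = {}
    for nid in graph.node_ids:
        if nid in labels:
            continue
        seen = {nid}
        queue = deque([nid])
        while queue:
            cur = queue.popleft()
            for nbr in graph.adjacency[cur]:
                if nbr not in seen:
                    seen.add(nbr)
                    queue.append(nbr)
        label = min(seen)
        for member in seen:
            labels[member] = label
    return labels


def sort_stream(
    features: Iterable[FeatureVector],
    params: GngParams | None = None,
    graph: Graph | None = None,
) -> SortResult:
    """Classify a time-ordered feature stream in a single pass.

    The first ``n_init`` distinct feature vectors seed the graph; every
    subsequent spike triggers one :func:`adapt` step.  Each spike is
    emitted as (peak time, cluster id, channel) the moment it is processed
    and is not retained afterwards.
    """
    params = params or GngParams()
    graph = graph or Graph(params)
    times: list[int] = []
    labels: list[int] = []
    channels: list[int] = []
    for fv in features:
        x = fv.vector
        if graph.n_nodes < params.n_init:
            if any(np.array_equal(x, pos) for pos in graph.positions.values()):
                # duplicate of an init vector: classify to its node
                label = graph.label_of(
                    next(i for i, pos in graph.positions.items() if np.array_equal(x, pos))
                )
            else:
                label = graph.label_of(graph.add_node(x))
        else:
            label = adapt(graph, x)
        times.append(fv.spike.peak_sample if fv.spike is not None else len(times))
        channels.append(fv.spike.channel if fv.spike is not None else -1)
        labels.append(label)
    return SortResult(
        np.asarray(times, dtype=int),
        np.asarray(labels, dtype=int),
        np.asarray(channels, dtype=int),
        params={"gng": params.__dict__.copy()},
    )
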