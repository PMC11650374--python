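"""Layered DAGs linking groups of observations.

The groups being clustered are the nodes of a known directed acyclic graph;
edges point from a "parent" group to the groups derived from it.  All model
recursions in this package are layer-wise: the (possibly hidden) root sits at
layer 0 and every edge must connect consecutive layers (a *graded* DAG).
This module builds and validates such DAGs and answers the structural queries
the model needs: layers, generation-``g`` ancestors, and Markov blankets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "GroupDAG",
    "CycleError",
    "GradednessError",
    "MultiRootError",
    "build_dag",
    "augment_hidden_root",
    "ancestors",
    "markov_blanket",
]


class CycleError(ValueError):
    """The edge set contains a directed cycle."""


class GradednessError(ValueError):
    """An edge skips a layer: parent and child are not in consecutive layers."""


class MultiRootError(ValueError):
    """More than one root and hidden-root augmentation was disabled."""


@dataclass(frozen=True)
class GroupDAG:
    """A validated, graded DAG over groups.

    Attributes
    ----------
    node_ids : tuple of int
        All node labels in canonical (layer, id) order.
    edges : tuple of (int, int)
        Directed (parent, child) pairs.
    observed : dict
        Node -> bool; a hidden root carries no data.
    layer : dict
        Node -> layer index (longest directed path from the root).
    layers : tuple of tuple
        ``layers[k]`` lists the nodes of layer k, sorted by id.
    root : int
        The unique layer-0 node.
    K : int
        Number of non-root layers.
    p : int
        Number of non-root nodes (``sum(len(layers[k]) for k >= 1)``).
    """

    node_ids: tuple
    edges: tuple
    observed: dict
    layer: dict
    layers: tuple
    root: int
    K: int
    p: int
    _parents: dict = field(repr=False, default_factory=dict)
    _children: dict = field(repr=False, default_factory=dict)

    def parents(self, node) -> tuple:
        return self._parents[node]

    def children(self, node) -> tuple:
        return self._children[node]

    @property
    def observed_nodes(self) -> tuple:
        return tuple(j for j in self.node_ids if self.observed[j])

    @property
    def non_root_nodes(self) -> tuple:
        """Nodes of layers 1..K in canonical order."""
        return tuple(j for j in self.node_ids if j != self.root)

    def topological_order(self) -> tuple:
        return self.node_ids  # canonical order is (layer, id), hence topological


def _layers_from_edges(nodes, parents):
    """Longest-path depth from the roots; roots get layer 0."""
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for child, pars in parents.items():
        g.add_edges_from((u, child) for u in pars)
    if not nx.is_directed_acyclic_graph(g):
        raise CycleError("the edge set contains a directed cycle")
    layer = {}
    for v in nx.topological_sort(g):
        pars = parents.get(v, ())
        layer[v] = 0 if not pars else 1 + max(layer[u] for u in pars)
    return layer


def build_dag(
    edges: Iterable[Sequence[int]],
    observed: Mapping[int, bool] | None = None,
    validate: bool = True,
    auto_augment: bool = True,
) -> GroupDAG:
    """Build a :class:`GroupDAG` from an edge list.

    Parameters
    ----------
    edges
        Iterable of ``(parent, child)`` integer pairs.
    observed
        Optional node -> bool map.  Nodes appearing only here (no incident
        edges) are included as isolated nodes; nodes not listed default to
        observed.
    validate
        If True (default), reject cycles and non-graded edge sets.
    auto_augment
        If True (default), a multi-root input is augmented with a single
        hidden common parent of all roots; if False, raise
        :class:`MultiRootError` instead.
    """
    edges = tuple((int(u), int(v)) for u, v in edges)
    nodes = set()
    for u, v in edges:
        nodes.add(u)
        nodes.add(v)
    obs = {int(j): bool(f) for j, f in (observed or {}).items()}
    nodes.update(obs)
    if not nodes:
        raise ValueError("empty DAG: declare at least one node")
    for u, v in edges:
        if u == v:
            raise CycleError(f"self-loop at node {u}")

    parents: dict = {j: [] for j in nodes}
    for u, v in edges:
        parents[v].append(u)

    layer = _layers_from_edges(nodes, parents)
    roots = sorted(j for j in nodes if not parents[j])
    if len(roots) > 1:
        if not auto_augment:
            raise MultiRootError(f"multiple roots {roots} and auto_augment=False")
        hidden = 0 if 0 not in nodes else min(nodes) - 1
        edges = edges + tuple((hidden, r) for r in roots)
        nodes.add(hidden)
        obs[hidden] = False
        parents = {j: [] for j in nodes}
        for u, v in edges:
            parents[v].append(u)
        layer = _layers_from_edges(nodes, parents)
        roots = [hidden]

    root = roots[0]
    if validate:
        for u, v in edges:
            if layer[v] != layer[u] + 1:
                raise GradednessError(
                    f"edge ({u}, {v}) skips a layer: layer({u})={layer[u]}, "
                    f"layer({v})={layer[v]}; the layer-wise recursions require "
                    "every parent of a layer-k node to sit in layer k-1"
                )

    observed_map = {j: obs.get(j, True) for j in nodes}
    order = sorted(nodes, key=lambda j: (layer[j], j))
    K = max(layer.values())
    children: dict = {j: [] for j in nodes}
    for u, v in edges:
        children[u].append(v)
    layers = tuple(
        tuple(sorted(j for j in nodes if layer[j] == k)) for k in range(K + 1)
    )
    return GroupDAG(
        node_ids=tuple(order),
        edges=edges,
        observed=observed_map,
        layer=dict(layer),
        layers=layers,
        root=root,
        K=K,
        p=len(nodes) - 1,
        _parents={j: tuple(sorted(parents[j])) for j in nodes},
        _children={j: tuple(sorted(children[j])) for j in nodes},
    )


def augment_hidden_root(dag: GroupDAG) -> GroupDAG:
    """Return a single-root DAG, adding a hidden common parent if needed.

    A multi-root DAG is converted by adding one hidden node as parent of
    every original root; this only adds the hidden parent to the original
    roots' Markov blankets and leaves all other blankets unchanged.  A DAG
    that already has a unique root is returned unchanged.
    """
    roots = [j for j in dag.node_ids if not dag.parents(j)]
    if len(roots) == 1:
        return dag
    return build_dag(dag.edges, dag.observed, auto_augment=True)


def ancestors(dag: GroupDAG, node: int, generation: int) -> set:
    """Generation-``g`` ancestors: nodes reached by reversing exactly g edges.

    In a graded DAG these are precisely the ancestors of ``node`` sitting
    ``generation`` layers above it.
    """
    if node not in dag.layer:
        raise KeyError(f"unknown node {node}")
    k = dag.layer[node]
    if not 1 <= generation <= k:
        raise ValueError(
            f"generation must be in [1, layer({node})={k}], got {generation}"
        )
    frontier = {node}
    for _ in range(generation):
        frontier = {u for v in frontier for u in dag.parents(v)}
    return frontier


def markov_blanket(dag: GroupDAG, node: int) -> set:
    """Parents, children, and co-parents of children, excluding the node."""
    if node not in dag.layer:
        raise KeyError(f"unknown node {node}")
    blanket = set(dag.parents(node)) | set(dag.children(node))
    for child in dag.children(node):
        blanket.update(dag.parents(child))
    blanket.discard(node)
    return blanket
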