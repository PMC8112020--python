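"""Prefix graphs: Aho-Corasick rollouts of a splice graph over phasing paths.

Matching phasing paths against candidate transcripts is a multi-pattern
matching problem: the alphabet is the set of splice-graph vertices, the
patterns are the phasing paths, and each transcript (S-T path) is a text.
The Aho-Corasick automaton over the patterns — with transitions restricted
to splice-graph successors — induces two graphs:

* the **prefix graph**: automaton states are vertices, transitions are
  edges; a phasing path p is recognized at the vertex set AS(p) = {v : p is
  a suffix of the state label t(v)};
* the **compact prefix graph**: vertices are the singleton paths plus the
  strict prefixes of phasing paths; each transition becomes a *labeled*
  edge, and recognition moves to edges: AS(p) = {e : p is a suffix of the
  edge label t(e)}.

S-T paths of the splice graph correspond one-to-one to [S]-[T] paths of
either rollout, and a transcript contains p iff its lifted path meets AS(p)
exactly once.  Flows on these graphs therefore carry every path abundance
c_p as a linear functional of the edge weights — the representation the
inference optimizes over.

State labels that can never be realized while reading an S-T path (their
occurrences are always absorbed into longer states) are pruned; they could
only ever carry zero flow.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .phasing import PhasingSet
from .splice_graph import GraphError, GraphPath, SpliceGraph

__all__ = [
    "ACAutomaton",
    "PGEdge",
    "PrefixGraph",
    "CompactPrefixGraph",
    "build_automaton",
    "build_prefix_graph",
    "build_compact_prefix_graph",
    "lift_path",
    "project_path",
    "longest_suffix_in",
]


def longest_suffix_in(word: Sequence[int], keys) -> GraphPath:
    """Longest suffix of ``word`` (possibly empty) contained in ``keys``."""
    w = tuple(word)
    for i in range(len(w)):
        if w[i:] in keys:
            return w[i:]
    return ()


# ---------------------------------------------------------------------------
# Aho-Corasick automaton


@dataclass
class ACState:
    id: int
    key: GraphPath  # the splice-graph path this state matches
    depth: int
    fail: int = 0  # longest proper suffix state


@dataclass
class ACAutomaton:
    """Aho-Corasick automaton over phasing-path patterns.

    States are the prefix closure of the pattern set (phasing paths plus
    all singletons, including [S] and [T]); goto edges form the trie; the
    full transition ``step(state, y)`` follows failure links and is defined
    for any vertex y that is a splice-graph successor of the state's last
    vertex.
    """

    graph: SpliceGraph
    states: list[ACState]
    key_to_id: dict[GraphPath, int]
    goto: dict[tuple[int, int], int]  # trie edges (state, symbol) -> state
    patterns: set[GraphPath]
    _delta: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def root(self) -> int:
        return 0

    def state_key(self, sid: int) -> GraphPath:
        return self.states[sid].key

    def step(self, sid: int, symbol: int) -> int:
        """delta(state, symbol): longest suffix of key+symbol among states."""
        key = (sid, symbol)
        if key in self._delta:
            return self._delta[key]
        s = sid
        while True:
            if (s, symbol) in self.goto:
                t = self.goto[(s, symbol)]
                break
            if s == self.root:
                t = self.root
                break
            s = self.states[s].fail
        self._delta[key] = t
        return t


def build_automaton(g: SpliceGraph, P: PhasingSet | Iterable[GraphPath]) -> ACAutomaton:
    """Build the restricted Aho-Corasick automaton for phasing set P.

    The pattern set is P plus every singleton path, including [S] and [T]
    (so that the rollouts have a well-defined source and sink).
    """
    paths = list(P.paths) if isinstance(P, PhasingSet) else [tuple(p) for p in P]
    for p in paths:
        q = g.validate_path(p)
        if any(g.vertex(v).kind != "exon" for v in q):
            raise GraphError(f"phasing path {q} must contain exons only")
    patterns = set(map(tuple, paths))
    patterns.update((v.id,) for v in g.vertices)

    states = [ACState(id=0, key=(), depth=0)]
    key_to_id: dict[GraphPath, int] = {(): 0}
    goto: dict[tuple[int, int], int] = {}
    for pat in sorted(patterns):
        sid = 0
        for depth, sym in enumerate(pat, start=1):
            nxt = goto.get((sid, sym))
            if nxt is None:
                nxt = len(states)
                states.append(ACState(id=nxt, key=pat[:depth], depth=depth))
                key_to_id[pat[:depth]] = nxt
                goto[(sid, sym)] = nxt
            sid = nxt

    # failure links, BFS by depth
    queue: deque[int] = deque()
    for (sid, sym), child in goto.items():
        if sid == 0:
            states[child].fail = 0
            queue.append(child)
    visited = set(queue)
    while queue:
        sid = queue.popleft()
        for sym in set(k[1] for k in goto if k[0] == sid):
            child = goto[(sid, sym)]
            f = states[sid].fail
            while f != 0 and (f, sym) not in goto:
                f = states[f].fail
            states[child].fail = goto.get((f, sym), 0)
            if child not in visited:
                visited.add(child)
                queue.append(child)

    return ACAutomaton(
        graph=g, states=states, key_to_id=key_to_id, goto=goto, patterns=patterns
    )


# ---------------------------------------------------------------------------
# rollout graphs


@dataclass(frozen=True)
class PGEdge:
    """An edge of a (compact) prefix graph.

    ``label`` is the full splice path read by the transition (key of the
    origin plus the new symbol); ``symbol`` is its last vertex.
    """

    id: int
    src: int
    dst: int
    label: GraphPath

    @property
    def symbol(self) -> int:
        return self.label[-1]


class _Rollout:
    """Shared structure of prefix and compact prefix graphs."""

    kind = "abstract"

    def __init__(
        self,
        splice_graph: SpliceGraph,
        vertex_keys: list[GraphPath],
        edges: list[PGEdge],
        phasing_paths: list[GraphPath],
    ) -> None:
        self.splice_graph = splice_graph
        self.vertex_keys = vertex_keys
        self.key_to_vertex = {k: i for i, k in enumerate(vertex_keys)}
        self.edges = edges
        self.out_edges: list[list[int]] = [[] for _ in vertex_keys]
        self.in_edges: list[list[int]] = [[] for _ in vertex_keys]
        self._out_by_symbol: list[dict[int, int]] = [{} for _ in vertex_keys]
        for e in edges:
            self.out_edges[e.src].append(e.id)
            self.in_edges[e.dst].append(e.id)
            if e.symbol in self._out_by_symbol[e.src]:
                raise GraphError(
                    f"vertex {vertex_keys[e.src]} has two out-edges reading "
                    f"{e.symbol}"
                )
            self._out_by_symbol[e.src][e.symbol] = e.id
        self.source = self.key_to_vertex[(splice_graph.source,)]
        self.sink = self.key_to_vertex[(splice_graph.sink,)]
        self.phasing_paths = [tuple(p) for p in phasing_paths]
        self._topo = self._topological_order()
        self._recognition: dict[GraphPath, np.ndarray] = {}

    # -- structure ---------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertex_keys)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def _topological_order(self) -> list[int]:
        indeg = [len(self.in_edges[v]) for v in range(self.n_vertices)]
        order = []
        ready = sorted(v for v in range(self.n_vertices) if indeg[v] == 0)
        queue = deque(ready)
        while queue:
            v = queue.popleft()
            order.append(v)
            for eid in self.out_edges[v]:
                w = self.edges[eid].dst
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        if len(order) != self.n_vertices:
            raise GraphError(f"{self.kind} graph is not a DAG")
        return order

    def topological_order(self) -> list[int]:
        return list(self._topo)

    def step_edge(self, vertex: int, symbol: int) -> int:
        """The unique out-edge of ``vertex`` reading ``symbol``."""
        try:
            return self._out_by_symbol[vertex][symbol]
        except KeyError:
            raise GraphError(
                f"no transition from {self.vertex_keys[vertex]} on {symbol}"
            ) from None

    # -- recognition -------------------------------------------------------
    def recognition_edges(self, p: GraphPath) -> np.ndarray:
        """Edge ids whose traversal recognizes phasing path p (AS(p), as
        edges).  c_p is the total flow through these edges."""
        p = tuple(p)
        if p not in self._recognition:
            if p not in set(self.phasing_paths):
                raise KeyError(
                    f"path {p} is not in the phasing set of this {self.kind} "
                    "graph; its abundance is not representable"
                )
            self._recognition[p] = self._compute_recognition(p)
        return self._recognition[p]

    def _compute_recognition(self, p: GraphPath) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def size_metrics(self) -> tuple[int, int]:
        return self.n_vertices, self.n_edges


def _suffix_of(p: GraphPath, q: GraphPath) -> bool:
    return len(p) <= len(q) and q[len(q) - len(p) :] == p


class PrefixGraph(_Rollout):
    """State-vertex rollout: automaton states as vertices, recognition at
    vertices.  ``recognition_edges`` exposes AS(p) through incoming edges so
    that all abundances are linear in the edge weights."""

    kind = "prefix"

    def recognition_vertices(self, p: GraphPath) -> list[int]:
        p = tuple(p)
        return [v for v, key in enumerate(self.vertex_keys) if _suffix_of(p, key)]

    def _compute_recognition(self, p: GraphPath) -> np.ndarray:
        eids: list[int] = []
        for v in self.recognition_vertices(p):
            eids.extend(self.in_edges[v])
        return np.asarray(sorted(eids), dtype=int)


class CompactPrefixGraph(_Rollout):
    """Edge-labeled rollout: vertices are singletons plus strict prefixes of
    phasing paths; recognition happens on labeled edges."""

    kind = "compact"

    def _compute_recognition(self, p: GraphPath) -> np.ndarray:
        p = tuple(p)
        return np.asarray(
            sorted(e.id for e in self.edges if _suffix_of(p, e.label)), dtype=int
        )


def _prune_and_build(
    cls,
    g: SpliceGraph,
    keys: list[GraphPath],
    raw_edges: list[tuple[GraphPath, GraphPath, GraphPath]],  # (src, dst, label)
    phasing_paths: list[GraphPath],
):
    """Keep only vertices reachable from [S]; renumber by (depth, key)."""
    adj: dict[GraphPath, list[tuple[GraphPath, GraphPath]]] = {k: [] for k in keys}
    for src, dst, label in raw_edges:
        adj[src].append((dst, label))
    reachable = {(g.source,)}
    queue = deque([(g.source,)])
    while queue:
        k = queue.popleft()
        for dst, _ in adj[k]:
            if dst not in reachable:
                reachable.add(dst)
                queue.append(dst)
    kept = sorted(reachable, key=lambda k: (len(k), k))
    key_index = {k: i for i, k in enumerate(kept)}
    edges = []
    for src, dst, label in raw_edges:
        if src in reachable:  # dst then reachable by construction
            edges.append(
                PGEdge(id=len(edges), src=key_index[src], dst=key_index[dst], label=label)
            )
    return cls(g, kept, edges, phasing_paths)


def build_prefix_graph(aut: ACAutomaton) -> PrefixGraph:
    """Prefix graph from the automaton: states (minus the empty state) are
    vertices, restricted transitions are edges."""
    g = aut.graph
    keys = [s.key for s in aut.states if s.key]
    raw_edges = []
    for s in aut.states:
        if not s.key:
            continue
        last = s.key[-1]
        for y in g.successors(last):
            t = aut.step(s.id, y)
            tkey = aut.state_key(t)
            if not tkey:  # cannot happen: every singleton is a pattern
                raise GraphError("automaton transition fell back to the root")
            raw_edges.append((s.key, tkey, s.key + (y,)))
    phasing = [p for p in aut.patterns if all(g.vertex(v).kind == "exon" for v in p)]
    return _prune_and_build(PrefixGraph, g, keys, raw_edges, phasing)


def build_compact_prefix_graph(
    g: SpliceGraph, P: PhasingSet | Iterable[GraphPath]
) -> CompactPrefixGraph:
    """Compact prefix graph built directly from the phasing set.

    Vertices: every singleton path plus every strict prefix of a phasing
    path.  From vertex p reading successor y, one edge labeled ``p + (y,)``
    leads to the longest suffix of the label in the vertex set.
    """
    paths = list(P.paths) if isinstance(P, PhasingSet) else [tuple(p) for p in P]
    for p in paths:
        q = g.validate_path(p)
        if any(g.vertex(v).kind != "exon" for v in q):
            raise GraphError(f"phasing path {q} must contain exons only")
    keys = {(v.id,) for v in g.vertices}
    for p in paths:
        for cut in range(1, len(p)):
            keys.add(tuple(p[:cut]))
    key_set = set(keys)
    raw_edges = []
    for k in keys:
        last = k[-1]
        for y in g.successors(last):
            label = k + (y,)
            dst = longest_suffix_in(label, key_set)
            if not dst:
                raise GraphError("no suffix vertex found (singletons missing?)")
            raw_edges.append((k, dst, label))
    return _prune_and_build(
        CompactPrefixGraph, g, sorted(keys), raw_edges, [tuple(p) for p in paths]
    )


# ---------------------------------------------------------------------------
# the path bijection


def lift_path(pg: _Rollout, st_path: Sequence[int]) -> list[int]:
    """Lift a splice-graph S-T path to its unique [S]-[T] edge sequence."""
    p = pg.splice_graph.validate_path(st_path)
    if not pg.splice_graph.is_st_path(p):
        raise GraphError(f"{p} is not an S-T path")
    v = pg.source
    eids = []
    for y in p[1:]:
        eid = pg.step_edge(v, y)
        eids.append(eid)
        v = pg.edges[eid].dst
    if v != pg.sink:  # pragma: no cover - guaranteed by construction
        raise GraphError("lifted path did not terminate at [T]")
    return eids


def project_path(pg: _Rollout, pg_path: Sequence[int]) -> GraphPath:
    """Project an [S]-[T] edge sequence back to the splice-graph S-T path."""
    eids = list(pg_path)
    if not eids:
        raise GraphError("empty rollout path")
    edges = [pg.edges[e] for e in eids]
    if edges[0].src != pg.source or edges[-1].dst != pg.sink:
        raise GraphError("rollout path must run from [S] to [T]")
    for a, b in zip(edges, edges[1:]):
        if a.dst != b.src:
            raise GraphError("rollout path is not contiguous")
    st = (pg.splice_graph.source,) + tuple(e.symbol for e in edges)
    return pg.splice_graph.validate_path(st)
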