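"""Splice graphs: DAGs of (partial) exons with a virtual source S and sink T.

A splice graph encodes the alternative-splicing structure of a single gene.
Vertices are disjoint exons (or sub-exons); edges are splice junctions or
adjacencies; ``S`` and ``T`` are virtual transcript start/termination
vertices.  Each annotated transcript corresponds to a unique S-T path, and
under the incomplete-reference assumption *every* S-T path is a potential
transcript.

Paths are represented throughout the package as tuples of integer vertex
ids.  ``S`` always has id 0; exons are numbered 1..n in transcription order;
``T`` has id n+1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "GraphError",
    "CycleError",
    "PathCountOverflow",
    "Vertex",
    "SpliceGraph",
    "QuantifiedTranscriptSet",
    "build_splice_graph",
    "splice_graph_from_lengths",
    "transcript_to_path",
    "enumerate_st_paths",
    "count_st_paths",
    "is_subpath",
]

GraphPath = tuple[int, ...]


class GraphError(ValueError):
    """Invalid splice-graph structure or path."""


class CycleError(GraphError):
    """The supplied junctions imply a cycle."""


class PathCountOverflow(GraphError):
    """More S-T paths than the caller-supplied enumeration limit."""


@dataclass(frozen=True)
class Vertex:
    """A splice-graph vertex: the virtual S/T or an exon.

    Coordinates, when present, are 0-based half-open in genome space.
    ``length`` is the exonic length in bases (0 for S and T); synthetic
    graphs may carry a length without genomic coordinates.
    """

    id: int
    kind: str  # "S", "T" or "exon"
    length: int = 0
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.kind not in ("S", "T", "exon"):
            raise GraphError(f"unknown vertex kind {self.kind!r}")
        if self.kind == "exon":
            if self.start is not None and self.end is not None:
                if not self.start < self.end:
                    raise GraphError(
                        f"exon {self.id}: degenerate interval "
                        f"[{self.start}, {self.end})"
                    )
                if self.length != self.end - self.start:
                    raise GraphError(f"exon {self.id}: length/coordinate mismatch")
            if self.length < 1:
                raise GraphError(f"exon {self.id}: nonpositive length")


@dataclass
class SpliceGraph:
    """A DAG over exon vertices with virtual source S and sink T."""

    gene_id: str
    _vertices: dict[int, Vertex]
    nxg: nx.DiGraph
    source: int
    sink: int
    _topo: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.nxg):
            edge = next(iter(nx.find_cycle(self.nxg)))
            raise CycleError(f"splice graph contains a cycle; back edge {edge}")
        if self.nxg.in_degree(self.source) != 0:
            raise GraphError("S must have in-degree 0")
        if self.nxg.out_degree(self.sink) != 0:
            raise GraphError("T must have out-degree 0")
        # every non-S/T vertex must lie on at least one S-T path
        reach = nx.descendants(self.nxg, self.source) | {self.source}
        coreach = nx.ancestors(self.nxg, self.sink) | {self.sink}
        stranded = set(self.nxg.nodes) - (reach & coreach)
        if stranded:
            raise GraphError(
                f"vertices not on any S-T path: {sorted(stranded)}"
            )
        self._topo = list(nx.lexicographical_topological_sort(self.nxg))

    # -- basic accessors ---------------------------------------------------
    @property
    def vertices(self) -> list[Vertex]:
        """Vertices in (lexicographic) topological order."""
        return [self._vertices[v] for v in self._topo]

    @property
    def edges(self) -> set[tuple[int, int]]:
        return set(self.nxg.edges)

    @property
    def exon_ids(self) -> list[int]:
        return [v.id for v in self.vertices if v.kind == "exon"]

    def vertex(self, vid: int) -> Vertex:
        return self._vertices[vid]

    def length(self, vid: int) -> int:
        return self._vertices[vid].length

    def successors(self, vid: int) -> list[int]:
        return sorted(self.nxg.successors(vid))

    def predecessors(self, vid: int) -> list[int]:
        return sorted(self.nxg.predecessors(vid))

    def topological_order(self) -> list[int]:
        return list(self._topo)

    def has_edge(self, u: int, v: int) -> bool:
        return self.nxg.has_edge(u, v)

    # -- path helpers ------------------------------------------------------
    def validate_path(self, vertices: Sequence[int]) -> GraphPath:
        """Check that ``vertices`` is a nonempty path of this graph."""
        path = tuple(int(v) for v in vertices)
        if not path:
            raise GraphError("empty path")
        for v in path:
            if v not in self._vertices:
                raise GraphError(f"unknown vertex {v}")
        for u, v in itertools.pairwise(path):
            if not self.nxg.has_edge(u, v):
                raise GraphError(f"missing edge ({u}, {v})")
        return path

    def is_st_path(self, path: Sequence[int]) -> bool:
        p = tuple(path)
        return len(p) >= 2 and p[0] == self.source and p[-1] == self.sink

    def path_length(self, path: Sequence[int]) -> int:
        """Total exonic length of a path (S/T contribute 0)."""
        return sum(self._vertices[v].length for v in path)

    def exon_containing(self, pos: int) -> int:
        """Exon id whose genomic interval contains 0-based position ``pos``."""
        for v in self.vertices:
            if v.kind == "exon" and v.start is not None and v.start <= pos < v.end:
                return v.id
        raise GraphError(f"no exon contains genomic position {pos}")


def is_subpath(path: Sequence[int], sub: Sequence[int]) -> bool:
    """True when ``sub`` occurs as a contiguous run of vertices in ``path``."""
    p, s = tuple(path), tuple(sub)
    if not s or len(s) > len(p):
        return False
    return any(p[i : i + len(s)] == s for i in range(len(p) - len(s) + 1))


@dataclass
class QuantifiedTranscriptSet:
    """Transcripts (S-T paths) with abundances c_i and exonic lengths l_i."""

    transcripts: list[GraphPath]
    abundances: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=int)
        if not (len(self.transcripts) == len(self.abundances) == len(self.lengths)):
            raise GraphError("transcripts/abundances/lengths length mismatch")
        if np.any(self.abundances < 0):
            raise GraphError("abundances must be nonnegative")
        if np.any(self.lengths <= 0):
            raise GraphError("transcript lengths must be positive")

    @classmethod
    def from_graph(
        cls,
        g: SpliceGraph,
        transcripts: Iterable[Sequence[int]],
        abundances: Iterable[float],
    ) -> "QuantifiedTranscriptSet":
        paths = [g.validate_path(t) for t in transcripts]
        for p in paths:
            if not g.is_st_path(p):
                raise GraphError(f"transcript {p} is not an S-T path")
        lengths = [g.path_length(p) for p in paths]
        return cls(paths, np.asarray(list(abundances), dtype=float), np.asarray(lengths))

    @property
    def total_abundance(self) -> float:
        return float(self.abundances.sum())


# ---------------------------------------------------------------------------
# construction


def _make_exon_vertices(
    exons: Sequence[tuple], lengths_only: bool = False
) -> dict[int, Vertex]:
    vertices: dict[int, Vertex] = {}
    for i, ex in enumerate(exons, start=1):
        if lengths_only:
            vertices[i] = Vertex(id=i, kind="exon", length=int(ex))
        else:
            chrom, start, end, strand = ex
            vertices[i] = Vertex(
                id=i,
                kind="exon",
                length=int(end) - int(start),
                chrom=chrom,
                start=int(start),
                end=int(end),
                strand=strand,
            )
    return vertices


def _assemble(
    gene_id: str,
    exon_vertices: dict[int, Vertex],
    junctions: Iterable[tuple[int, int]],
    transcripts: list[list[int]] | None,
) -> SpliceGraph:
    n = len(exon_vertices)
    source, sink = 0, n + 1
    vertices = dict(exon_vertices)
    vertices[source] = Vertex(id=source, kind="S")
    vertices[sink] = Vertex(id=sink, kind="T")

    g = nx.DiGraph()
    g.add_nodes_from(vertices)
    for u, v in junctions:
        if u not in exon_vertices or v not in exon_vertices:
            raise GraphError(f"junction ({u}, {v}) references a missing exon")
        if u == v:
            raise CycleError(f"self-loop junction ({u}, {v})")
        g.add_edge(int(u), int(v))

    if not nx.is_directed_acyclic_graph(g):
        edge = next(iter(nx.find_cycle(g)))
        raise CycleError(f"junctions imply a cycle; back edge {edge}")

    if transcripts:
        # annotated transcript ends: S-edges to each first exon, T-edges from
        # each last exon; chain interior must already be junction-connected.
        for chain in transcripts:
            if not chain:
                raise GraphError("empty transcript chain")
            for u, v in itertools.pairwise(chain):
                if not g.has_edge(u, v):
                    raise GraphError(
                        f"transcript chain uses missing junction ({u}, {v})"
                    )
            g.add_edge(source, chain[0])
            g.add_edge(chain[-1], sink)
    else:
        # junction-only input: permissive closure
        for v in exon_vertices:
            if g.in_degree(v) == 0:
                g.add_edge(source, v)
        for v in exon_vertices:
            if g.out_degree(v) == 0 and v != source:
                g.add_edge(v, sink)

    return SpliceGraph(gene_id=gene_id, _vertices=vertices, nxg=g, source=source, sink=sink)


def build_splice_graph(
    exons: Sequence[tuple[str, int, int, str]],
    junctions: Iterable[tuple[int, int]],
    gene_id: str = "gene",
    transcripts: list[list[int]] | None = None,
) -> SpliceGraph:
    """Build a splice graph from genomic exons and junctions.

    Parameters
    ----------
    exons
        ``(chrom, start, end, strand)`` per exon, 0-based half-open, in
        transcription order (minus-strand genes must be pre-reversed; the
        GTF reader does this).  Exon ids are assigned 1..n in this order.
    junctions
        Pairs of 1-based exon ids ``(u, v)`` meaning u precedes v in some
        transcript.
    transcripts
        Optional annotated exon-id chains.  When given, S-edges go to each
        chain's first exon and T-edges from each last exon; otherwise S
        connects to all in-degree-0 exons and T from all out-degree-0 exons.
    """
    return _assemble(gene_id, _make_exon_vertices(exons), junctions, transcripts)


def splice_graph_from_lengths(
    lengths: Sequence[int],
    junctions: Iterable[tuple[int, int]],
    gene_id: str = "gene",
    transcripts: list[list[int]] | None = None,
) -> SpliceGraph:
    """Build a coordinate-free splice graph from exon lengths (synthetic data)."""
    return _assemble(
        gene_id, _make_exon_vertices(lengths, lengths_only=True), junctions, transcripts
    )


def transcript_to_path(g: SpliceGraph, exon_chain: Sequence[int]) -> GraphPath:
    """Map an exon chain to its unique S-T path ``(S, chain..., T)``."""
    if not exon_chain:
        raise GraphError("empty exon chain")
    return g.validate_path((g.source, *exon_chain, g.sink))


def count_st_paths(g: SpliceGraph) -> int:
    """Number of S-T paths, by dynamic programming over the topological order."""
    counts = {v: 0 for v in g.nxg.nodes}
    counts[g.sink] = 1
    for v in reversed(g.topological_order()):
        if v != g.sink:
            counts[v] = sum(counts[w] for w in g.nxg.successors(v))
    return counts[g.source]


def enumerate_st_paths(g: SpliceGraph, limit: int = 10_000) -> list[GraphPath]:
    """All S-T paths in lexicographic order, guarded by ``limit``.

    Raises :class:`PathCountOverflow` when the DP path count exceeds the
    limit, so callers never start an exponential enumeration by accident.
    """
    if limit < 1:
        raise GraphError("limit must be >= 1")
    total = count_st_paths(g)
    if total > limit:
        raise PathCountOverflow(
            f"{total} S-T paths exceed enumeration limit {limit}"
        )
    out: list[GraphPath] = []
    stack: list[int] = [g.source]

    def dfs(v: int) -> None:
        if v == g.sink:
            out.append(tuple(stack))
            return
        for w in g.successors(v):
            stack.append(w)
            dfs(w)
            stack.pop()

    dfs(g.source)
    return out
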