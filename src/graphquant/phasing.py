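"""Phasing paths: splice-graph paths witnessed by sequenced fragments.

A fragment whose alignment touches several exons is evidence that those
exons co-occur in one transcript; the touched exon chain is the fragment's
*phasing path*.  Singleton paths (one exon) are phasing paths too, so every
fragment maps to at least one.  The set ``P`` of phasing paths with positive
effective length, together with per-path fragment counts, is the sufficient
statistic the whole inference runs on.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .effective_length import AffinityModel, FragLenDist, NoBiasAffinity, path_eff_len
from .splice_graph import GraphError, GraphPath, SpliceGraph

__all__ = [
    "PhasingError",
    "FragmentMapping",
    "FragmentRecord",
    "PhasingSet",
    "fragment_to_path",
    "enumerate_phasing_paths",
    "build_phasing_set",
    "default_trim_threshold",
    "trim_phasing_set",
]


class PhasingError(ValueError):
    """Fragment cannot be expressed as a phasing path."""


@dataclass(frozen=True)
class FragmentMapping:
    """One candidate placement of a fragment on a phasing path."""

    path: GraphPath
    start_offset: int  # 0-based offset of the fragment start within path[0]
    frag_len: int
    affinity: float  # A(f|p), >= 0
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.frag_len < 1:
            raise PhasingError("fragment_length must be >= 1")
        if self.affinity < 0:
            raise PhasingError("affinity must be nonnegative")


@dataclass
class FragmentRecord:
    """A fragment with one or more candidate path mappings M(f)."""

    fragment_id: str
    mappings: list[FragmentMapping]

    def __post_init__(self) -> None:
        if not self.mappings:
            raise PhasingError(f"fragment {self.fragment_id} has no mappings")


@dataclass
class PhasingSet:
    """The set P of phasing paths with counts and effective lengths.

    ``counts`` are expected fragment counts per path (fractional under
    multimapping); ``eff_lengths`` are the l_hat_p values used in the
    likelihood normalization.
    """

    graph: SpliceGraph
    paths: list[GraphPath]
    counts: np.ndarray
    eff_lengths: np.ndarray
    index: dict[GraphPath, int] = field(default_factory=dict)
    D: FragLenDist | None = None  # the distribution P was built under, if any

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.eff_lengths = np.asarray(self.eff_lengths, dtype=float)
        if not (len(self.paths) == len(self.counts) == len(self.eff_lengths)):
            raise PhasingError("paths/counts/eff_lengths length mismatch")
        if len(set(self.paths)) != len(self.paths):
            raise PhasingError("duplicate phasing paths")
        if np.any(self.counts < 0):
            raise PhasingError("counts must be nonnegative")
        if not self.index:
            self.index = {p: i for i, p in enumerate(self.paths)}

    def __len__(self) -> int:
        return len(self.paths)

    def __contains__(self, p) -> bool:
        return tuple(p) in self.index

    def count(self, p: GraphPath) -> float:
        return float(self.counts[self.index[tuple(p)]])

    def lhat(self, p: GraphPath) -> float:
        return float(self.eff_lengths[self.index[tuple(p)]])

    @property
    def total_count(self) -> float:
        return float(self.counts.sum())

    def normalization(self, c: np.ndarray) -> float:
        """sum_p c_p * l_hat_p for abundances aligned with ``paths``."""
        return float(np.dot(np.asarray(c, dtype=float), self.eff_lengths))

    def with_counts(self, counts: np.ndarray) -> "PhasingSet":
        return replace(self, counts=np.asarray(counts, dtype=float))


# ---------------------------------------------------------------------------
# fragment -> path


def _exon_chains(
    g: SpliceGraph, u: int, v: int, max_paths: int = 64, cutoff: int = 24
) -> list[GraphPath]:
    """All exon chains from u to v (inclusive) in the splice graph."""
    if u == v:
        return [(u,)]
    sub = g.nxg.subgraph(g.exon_ids)
    chains = []
    for path in nx.all_simple_paths(sub, u, v, cutoff=cutoff):
        chains.append(tuple(path))
        if len(chains) > max_paths:
            raise PhasingError(f"too many exon chains between {u} and {v}")
    return chains


def _block_to_exons(g: SpliceGraph, start: int, end: int) -> list[int]:
    """Exons overlapped by an aligned block, validated for full coverage."""
    hit = [
        v
        for v in g.vertices
        if v.kind == "exon"
        and v.start is not None
        and v.start < end
        and start < v.end
    ]
    if not hit:
        raise PhasingError(f"block [{start}, {end}) overlaps no exon")
    hit.sort(key=lambda v: v.start)
    if start < hit[0].start or end > hit[-1].end:
        raise PhasingError(f"block [{start}, {end}) extends outside exons")
    for a, b in itertools.pairwise(hit):
        if a.end != b.start and not g.has_edge(a.id, b.id):
            raise PhasingError(
                f"block [{start}, {end}) spans unconnected exons {a.id}, {b.id}"
            )
        if b.start > a.end and a.end != a.end:  # pragma: no cover - defensive
            raise PhasingError("gap inside an aligned block")
    # interior exons must be fully covered by the block
    for v in hit[1:-1]:
        if not (start <= v.start and v.end <= end):
            raise PhasingError(f"block [{start}, {end}) skips into exon {v.id}")
    return [v.id for v in hit]


def fragment_to_path(
    g: SpliceGraph,
    blocks: list[tuple[int, int]],
    D: FragLenDist | None = None,
) -> list[FragmentMapping]:
    """Map aligned genomic blocks to candidate phasing-path placements.

    Blocks are 0-based half-open genomic intervals in transcription order
    (e.g. the two mate alignments of a paired-end fragment).  Exons spanned
    only by the inner gap are included when they form the unique chain
    between the mate anchors; when several chains are length-consistent,
    one mapping per chain is emitted (within-gene multimapping).

    Affinities are D(fragment_length) when ``D`` is given, else 1.0.
    """
    if not blocks:
        raise PhasingError("no aligned blocks")
    blocks = sorted((int(s), int(e)) for s, e in blocks)
    for s, e in blocks:
        if not s < e:
            raise PhasingError(f"degenerate block [{s}, {e})")
    block_exons = [_block_to_exons(g, s, e) for s, e in blocks]

    # chain the blocks together through the splice graph
    candidate_chains: list[GraphPath] = [tuple(block_exons[0])]
    for prev_blk, next_blk in itertools.pairwise(range(len(blocks))):
        u = block_exons[prev_blk][-1]
        v = block_exons[next_blk][0]
        tails = block_exons[next_blk][1:]
        new_chains = []
        for chain in candidate_chains:
            if u == v:
                bridges = [(u,)]
            else:
                bridges = _exon_chains(g, u, v)
            for bridge in bridges:
                if bridge[0] != chain[-1]:
                    continue
                merged = chain + bridge[1:] + tuple(tails)
                new_chains.append(merged)
        candidate_chains = new_chains
    if not candidate_chains:
        raise PhasingError("blocks touch exons with no connecting path")

    first_exon_start = {v.id: v.start for v in g.vertices if v.kind == "exon"}
    mappings = []
    for chain in candidate_chains:
        try:
            chain = g.validate_path(chain)
        except GraphError:
            continue
        start_offset = blocks[0][0] - first_exon_start[chain[0]]
        # distance along the chain from fragment start to fragment end
        chain_len = g.path_length(chain)
        tail = g.vertex(chain[-1]).end - blocks[-1][1]
        frag_len = chain_len - start_offset - tail
        if frag_len < 1:
            continue
        affinity = float(D.d(frag_len)) if D is not None else 1.0
        if D is not None and affinity == 0.0:
            continue  # length-inconsistent chain
        mappings.append(
            FragmentMapping(
                path=chain,
                start_offset=start_offset,
                frag_len=frag_len,
                affinity=affinity,
                gene_id=g.gene_id,
            )
        )
    if not mappings:
        raise PhasingError("no length-consistent chain for fragment blocks")
    return mappings


# ---------------------------------------------------------------------------
# the set P


def enumerate_phasing_paths(g: SpliceGraph, D: FragLenDist) -> list[GraphPath]:
    """All exon paths that could be spanned by a fragment drawn from D.

    Includes every singleton.  A multi-exon path needs a fragment of at
    least ``interior + 2`` bases, so the DFS prunes once the interior
    exceeds ``max_len - 2``.
    """
    M = D.max_len
    out: list[GraphPath] = []
    exons = g.exon_ids
    for x in exons:
        out.append((x,))

    def extend(path: list[int], interior: int) -> None:
        last = path[-1]
        for y in g.successors(last):
            if g.vertex(y).kind != "exon":
                continue
            cand = path + [y]
            # interior of cand = interior of path + length of old last exon
            new_interior = interior + (g.length(last) if len(path) > 1 else 0)
            if len(cand) >= 2 and new_interior + 2 <= M:
                out.append(tuple(cand))
                extend(cand, new_interior)

    for x in exons:
        extend([x], 0)
    return out


def build_phasing_set(
    g: SpliceGraph,
    D: FragLenDist,
    fragments: list[FragmentRecord] | None = None,
    affinity: AffinityModel | None = None,
) -> PhasingSet:
    """Assemble P: all paths with positive effective length, plus singletons.

    Counts aggregate fragment mappings: a uniquely mapped fragment adds 1 to
    its path; a multimapped fragment is split across its candidate paths
    proportionally to affinity (the EM later refines this split).
    """
    aff = affinity or NoBiasAffinity(D)
    paths = []
    lhat = []
    for p in enumerate_phasing_paths(g, D):
        lp = path_eff_len(g, p, aff)
        if lp > 0 or len(p) == 1:
            paths.append(p)
            lhat.append(lp)
    index = {p: i for i, p in enumerate(paths)}
    counts = np.zeros(len(paths))
    for frag in fragments or []:
        total_aff = sum(m.affinity for m in frag.mappings)
        for m in frag.mappings:
            p = tuple(m.path)
            if p not in index:
                warnings.warn(
                    f"fragment {frag.fragment_id} maps to path {p} with zero "
                    "effective length under D; adding it to P"
                )
                index[p] = len(paths)
                paths.append(p)
                lhat.append(path_eff_len(g, p, aff))
                counts = np.append(counts, 0.0)
            share = m.affinity / total_aff if total_aff > 0 else 1 / len(frag.mappings)
            counts[index[p]] += share
    return PhasingSet(
        graph=g,
        paths=paths,
        counts=counts,
        eff_lengths=np.asarray(lhat, dtype=float),
        index=index,
        D=D,
    )


def default_trim_threshold(D: FragLenDist, q: float = 0.995) -> float:
    """Trim threshold: the l_hat contributed by a single fragment length at
    the q-th percentile of D (the long-tail regime the trimming targets)."""
    return float(D.d(D.percentile(q)))


def trim_phasing_set(P: PhasingSet, min_eff_len: float | None = None) -> PhasingSet:
    """Drop multi-exon paths with no mapped fragments and tiny l_hat.

    Singletons and paths carrying fragments are never removed, and no
    renormalization is applied: the likelihood simply omits the dropped
    normalization mass, whose contribution is argued to be negligible.
    """
    if min_eff_len is None:
        if P.D is None:
            raise PhasingError(
                "trim_phasing_set needs an explicit min_eff_len when the "
                "phasing set does not carry its fragment-length distribution"
            )
        min_eff_len = default_trim_threshold(P.D)
    keep = [
        i
        for i, p in enumerate(P.paths)
        if len(p) == 1 or P.counts[i] > 0 or P.eff_lengths[i] >= min_eff_len
    ]
    return PhasingSet(
        graph=P.graph,
        paths=[P.paths[i] for i in keep],
        counts=P.counts[keep],
        eff_lengths=P.eff_lengths[keep],
        D=P.D,
    )
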