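"""Flow algebra on (compact) prefix graphs.

A flow assigns a nonnegative weight to every edge of a rollout graph such
that inflow equals outflow at every internal vertex.  Transcript sets map
onto flows by lifting each transcript's S-T path; flows map back by
decomposition into weighted [S]-[T] paths.  Both directions preserve every
phasing-path abundance c_p, which is the edge-sum over the recognition set
AS(p) — this is what makes the flow a faithful, compact reparameterization
of transcript abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .prefix_graph import CompactPrefixGraph, PrefixGraph, lift_path, project_path
from .splice_graph import GraphError, GraphPath, QuantifiedTranscriptSet

__all__ = [
    "FlowError",
    "Flow",
    "transcripts_to_flow",
    "path_abundance",
    "decompose_flow",
    "compute_psi",
    "psi_bounds",
    "balance_matrix",
    "minimal_sufficiency_nullspace",
]

Rollout = PrefixGraph | CompactPrefixGraph

# relative / absolute tolerance for flow-balance residuals
BALANCE_RTOL = 1e-9
BALANCE_ATOL = 1e-15


class FlowError(ValueError):
    """Imbalanced or otherwise invalid flow."""


@dataclass
class Flow:
    """Nonnegative edge weights on a rollout graph satisfying balance."""

    graph: Rollout
    edge_weights: np.ndarray
    validate: bool = True
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edge_weights = np.asarray(self.edge_weights, dtype=float)
        if len(self.edge_weights) != self.graph.n_edges:
            raise FlowError("one weight per edge required")
        if np.any(self.edge_weights < 0):
            raise FlowError("edge weights must be nonnegative")
        if self.validate:
            res = self.balance_residual()
            tol = BALANCE_RTOL * max(self.total(), 1e-300) + BALANCE_ATOL
            if res > tol:
                raise FlowError(f"flow imbalance {res:g} exceeds tolerance {tol:g}")

    def total(self) -> float:
        """Total flow shipped from [S] to [T]."""
        return float(self.edge_weights[self.graph.out_edges[self.graph.source]].sum())

    def vertex_throughput(self, v: int) -> float:
        eids = (
            self.graph.out_edges[v] if v == self.graph.source else self.graph.in_edges[v]
        )
        return float(self.edge_weights[eids].sum())

    def balance_residual(self) -> float:
        res = 0.0
        for v in range(self.graph.n_vertices):
            if v in (self.graph.source, self.graph.sink):
                continue
            inflow = self.edge_weights[self.graph.in_edges[v]].sum()
            outflow = self.edge_weights[self.graph.out_edges[v]].sum()
            res = max(res, abs(inflow - outflow))
        return res


def transcripts_to_flow(pg: Rollout, qts: QuantifiedTranscriptSet) -> Flow:
    """Route each transcript's abundance along its lifted [S]-[T] path."""
    w = np.zeros(pg.n_edges)
    for path, c in zip(qts.transcripts, qts.abundances):
        for eid in lift_path(pg, path):
            w[eid] += c
    return Flow(graph=pg, edge_weights=w)


def path_abundance(flow: Flow, p: GraphPath) -> float:
    """c_p: total flow through the recognition set AS(p)."""
    try:
        eids = flow.graph.recognition_edges(p)
    except KeyError as exc:
        raise FlowError(str(exc)) from None
    return float(flow.edge_weights[eids].sum())


def decompose_flow(flow: Flow, merge: bool = True) -> QuantifiedTranscriptSet:
    """Greedy widest-path decomposition into weighted transcripts.

    Repeatedly extracts the [S]-[T] path with the largest bottleneck weight
    (ties broken lexicographically by edge id), which zeroes at least one
    edge per round, so at most |E| paths are produced.  Residual flow below
    ``1e-12 *`` total is clipped.
    """
    pg = flow.graph
    res = flow.balance_residual()
    total = flow.total()
    if res > BALANCE_RTOL * max(total, 1e-300) + BALANCE_ATOL:
        raise FlowError(f"cannot decompose imbalanced flow (residual {res:g})")
    residual = flow.edge_weights.copy()
    clip = 1e-12 * max(total, 1e-300)
    paths: list[tuple[GraphPath, float]] = []
    topo = pg.topological_order()
    for _ in range(pg.n_edges + 1):
        if residual[pg.out_edges[pg.source]].sum() <= clip:
            break
        # widest-path DP over the topological order
        width = np.full(pg.n_vertices, -1.0)
        back = np.full(pg.n_vertices, -1, dtype=int)
        width[pg.source] = np.inf
        for v in topo:
            if width[v] < 0:
                continue
            for eid in pg.out_edges[v]:
                if residual[eid] <= clip:
                    continue
                w = min(width[v], residual[eid])
                dst = pg.edges[eid].dst
                if w > width[dst]:
                    width[dst] = w
                    back[dst] = eid
        if width[pg.sink] <= 0:
            break
        eids = []
        v = pg.sink
        while v != pg.source:
            eid = back[v]
            eids.append(eid)
            v = pg.edges[eid].src
        eids.reverse()
        w = float(width[pg.sink])
        residual[eids] -= w
        paths.append((project_path(pg, eids), w))
    g = pg.splice_graph
    if merge:
        agg: dict[GraphPath, float] = {}
        for p, w in paths:
            agg[p] = agg.get(p, 0.0) + w
        paths = sorted(agg.items())
    transcripts = [p for p, _ in paths]
    weights = [w for _, w in paths]
    lengths = [g.path_length(p) for p in transcripts]
    return QuantifiedTranscriptSet(transcripts, np.asarray(weights), np.asarray(lengths))


# ---------------------------------------------------------------------------
# PSI


def _psi_from_qts(
    qts: QuantifiedTranscriptSet, e_first: int, e_mid: int, e_last: int
) -> float:
    num = den = 0.0
    for path, c in zip(qts.transcripts, qts.abundances):
        s = set(path)
        if e_first in s and e_last in s:
            den += c
            if e_mid in s:
                num += c
    if den <= 0:
        warnings.warn(
            f"PSI({e_first},{e_mid},{e_last}) undefined: no flanking abundance"
        )
        return float("nan")
    return num / den


def compute_psi(
    source: QuantifiedTranscriptSet | Flow,
    e_first: int,
    e_mid: int,
    e_last: int,
    graph=None,
) -> float:
    """Percent spliced in for an exon triple.

    Abundance of transcripts containing all three exons divided by the
    abundance of those containing the two flanking exons.  A ``Flow`` is
    first decomposed with the canonical greedy decomposition; note that
    when the relevant phasing paths are not in P, different decompositions
    of the same flow can yield different PSI (see :func:`psi_bounds`).
    """
    if isinstance(source, Flow):
        graph = source.graph.splice_graph
        qts = decompose_flow(source)
    else:
        qts = source
    if graph is not None:
        for e in (e_first, e_mid, e_last):
            if e not in graph._vertices or graph.vertex(e).kind != "exon":
                raise GraphError(f"exon {e} not in splice graph")
    return _psi_from_qts(qts, e_first, e_mid, e_last)


def psi_bounds(
    flow: Flow, e_first: int, e_mid: int, e_last: int
) -> tuple[float, float]:
    """Min/max PSI over all decompositions of ``flow``.

    Works on a flag-expanded copy of the rollout graph (8 copies of each
    vertex tracking which of the three exons have been visited) and solves
    two linear programs via the Charnes-Cooper transform of the PSI ratio.
    """
    pg = flow.graph
    nv, ne = pg.n_vertices, pg.n_edges
    if len({e_first, e_mid, e_last}) != 3:
        raise GraphError("PSI exon triple must be distinct")
    markbit = {e_first: 1, e_mid: 2, e_last: 4}

    def vmark(v: int) -> int:
        """Mark bit contributed by entering rollout vertex v (its symbol)."""
        return markbit.get(pg.vertex_keys[v][-1], 0)

    # variables: y[e, fl] = flow on edge e whose walk has seen mark set `fl`
    # at the edge's source state (marks of all splice vertices entered so
    # far, including the source vertex's own symbol); plus the
    # Charnes-Cooper scale tau.
    nvar = ne * 8 + 1
    idx = lambda e, fl: e * 8 + fl

    A_eq = []
    b_eq = []
    # edge-sum consistency: sum_flags y[e, fl] = f_e * tau
    for e in range(ne):
        row = np.zeros(nvar)
        row[[idx(e, fl) for fl in range(8)]] = 1.0
        row[-1] = -flow.edge_weights[e]
        A_eq.append(row)
        b_eq.append(0.0)
    # balance at every internal expanded state (v, fl)
    for v in range(nv):
        if v in (pg.source, pg.sink):
            continue
        mv = vmark(v)
        for fl in range(8):
            if fl & mv != mv:
                continue  # state flags always include the vertex's own mark
            row = np.zeros(nvar)
            preds = {fl} if mv == 0 else {fl, fl ^ mv}
            for eid in pg.in_edges[v]:
                for fl0 in preds:
                    row[idx(eid, fl0)] += 1.0
            for eid in pg.out_edges[v]:
                row[idx(eid, fl)] -= 1.0
            A_eq.append(row)
            b_eq.append(0.0)
    # walks start at [S] with no marks seen
    forbid = np.zeros(nvar, dtype=bool)
    for eid in pg.out_edges[pg.source]:
        for fl in range(1, 8):
            forbid[idx(eid, fl)] = True
    # an out-edge copy must carry its source vertex's mark
    for e in range(ne):
        mv = vmark(pg.edges[e].src)
        for fl in range(8):
            if fl & mv != mv:
                forbid[idx(e, fl)] = True
    # Charnes-Cooper: denominator (flanking-pair abundance) scaled to 1
    den_row = np.zeros(nvar)
    num = np.zeros(nvar)
    for eid in pg.in_edges[pg.sink]:
        for fl in range(8):
            if fl & 0b101 == 0b101:
                den_row[idx(eid, fl)] = 1.0
            if fl & 0b111 == 0b111:
                num[idx(eid, fl)] = 1.0
    A_eq.append(den_row)
    b_eq.append(1.0)

    bounds = [(0.0, 0.0) if forbid[i] else (0.0, None) for i in range(nvar)]
    bounds[-1] = (0.0, None)
    out = []
    for sign in (+1, -1):
        r = linprog(
            sign * num,
            A_eq=np.asarray(A_eq),
            b_eq=np.asarray(b_eq),
            bounds=bounds,
            method="highs",
        )
        if not r.success:
            warnings.warn(f"PSI bound LP failed: {r.message}")
            out.append(float("nan"))
        else:
            out.append(sign * r.fun)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# minimal sufficiency


def balance_matrix(pg: Rollout) -> np.ndarray:
    """Signed incidence rows (one per internal vertex) over edge weights."""
    rows = []
    for v in range(pg.n_vertices):
        if v in (pg.source, pg.sink):
            continue
        row = np.zeros(pg.n_edges)
        row[pg.in_edges[v]] += 1.0
        row[pg.out_edges[v]] -= 1.0
        rows.append(row)
    return np.asarray(rows) if rows else np.zeros((0, pg.n_edges))


def minimal_sufficiency_nullspace(pg: Rollout) -> int:
    """Dimension of {flows with all c_p = 0 and balance}: 0 iff the linear
    map flow -> {c_p} is injective on balanced flows."""
    rows = [balance_matrix(pg)]
    for p in pg.phasing_paths:
        row = np.zeros(pg.n_edges)
        row[pg.recognition_edges(p)] = 1.0
        rows.append(row[None, :])
    M = np.vstack(rows)
    return pg.n_edges - int(np.linalg.matrix_rank(M))
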