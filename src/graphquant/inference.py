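"""Inference: maximum-likelihood prefix-graph flows by EM.

The single-gene problem is the concave program

    max  sum_p w_p log c_p
    s.t. c_p = sum_{e in AS(p)} f_e          (recognition)
         flow balance at internal vertices
         sum_p c_p l_hat_p = mass,  f >= 0

where ``w_p`` are (expected) fragment counts per phasing path.  Because
every balanced flow is a nonnegative combination of [S]-[T] paths, and each
such path pi contributes exactly ``1(p subset pi)`` to c_p and
``sum_{e in pi} h_e`` to the normalization (h_e aggregates the effective
lengths recognized at e), the program is solved by column generation: run
the classical quantification EM restricted to a working set of [S]-[T]
paths, then search the rollout DAG for the best-ratio path

    max_pi  (sum_e gamma_e) / (sum_e h_e),   gamma_e = sum_{p: e in AS(p)} w_p / c_p

via Dinkelbach iterations of a longest-path DP.  The KKT condition of the
full program is exactly ``max ratio <= |F| / mass``; when it holds (to
tolerance) the restricted optimum is the global optimum.  No enumeration of
all S-T paths ever happens: every quantity is an edge sum on the rollout.

Multimapped fragments (within or across genes) are handled by an outer EM:
a global E-step computes responsibilities z_{f,p} = c_p A(f|p) / sum, and a
gene-level M-step re-solves each gene's flow with counts sum_f z_{f,p} and
normalization mass s_g/|F|, which also yields the gene abundances
c_g = s_g/|F|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .effective_length import FragLenDist
from .flow import Flow
from .phasing import FragmentRecord, PhasingSet
from .prefix_graph import (
    CompactPrefixGraph,
    PrefixGraph,
    build_automaton,
    build_compact_prefix_graph,
    build_prefix_graph,
)
from .splice_graph import GraphPath, SpliceGraph

__all__ = [
    "InferenceError",
    "EMConfig",
    "Gene",
    "EMState",
    "loglik",
    "solve_single_gene",
    "e_step",
    "m_step",
    "run_em",
]


class InferenceError(RuntimeError):
    """Solver failure or invalid inference input."""


@dataclass
class EMConfig:
    """Tunable knobs of the EM driver and the per-gene flow solver."""

    tol: float = 1e-9  # relative loglik change for outer EM convergence
    max_iter: int = 1000  # outer EM iterations
    inner_tol: float = 1e-13  # restricted-EM relative loglik tolerance
    inner_max_iter: int = 200_000
    kkt_tol: float = 1e-9  # KKT violation per unit fragment count
    max_columns: int = 2000
    graph_type: str = "compact"  # or "prefix"
    monotone_tol: float = 1e-9


@dataclass
class Gene:
    """A gene's splice graph, phasing set and rollout, ready for inference."""

    gene_id: str
    graph: SpliceGraph
    phasing: PhasingSet
    rollout: PrefixGraph | CompactPrefixGraph
    # per-edge aggregated effective length: h_e = sum_{p: e in AS(p)} l_hat_p
    h: np.ndarray = field(default=None, repr=False)
    # recognition edge ids per phasing-path index
    recognition: list[np.ndarray] = field(default=None, repr=False)

    @classmethod
    def build(
        cls, graph: SpliceGraph, phasing: PhasingSet, graph_type: str = "compact"
    ) -> "Gene":
        if graph_type == "compact":
            pg = build_compact_prefix_graph(graph, phasing)
        elif graph_type == "prefix":
            pg = build_prefix_graph(build_automaton(graph, phasing))
        else:
            raise InferenceError(f"unknown graph_type {graph_type!r}")
        rec = [pg.recognition_edges(p) for p in phasing.paths]
        h = np.zeros(pg.n_edges)
        for eids, lp in zip(rec, phasing.eff_lengths):
            h[eids] += lp
        return cls(
            gene_id=graph.gene_id, graph=graph, phasing=phasing, rollout=pg,
            h=h, recognition=rec,
        )

    def path_index(self, p: GraphPath) -> int:
        return self.phasing.index[tuple(p)]


def loglik(
    counts: dict[GraphPath, float] | np.ndarray,
    c: dict[GraphPath, float] | np.ndarray,
    lhat: dict[GraphPath, float] | np.ndarray,
) -> float:
    """sum_p w_p log c_p - (sum_p w_p) log(sum_p c_p l_hat_p).

    Dict inputs are aligned by path key; array inputs positionally.
    """
    if isinstance(counts, dict):
        keys = list(c.keys()) if isinstance(c, dict) else list(counts.keys())
        w = np.array([counts.get(k, 0.0) for k in keys])
        cv = np.array([c[k] for k in keys]) if isinstance(c, dict) else np.asarray(c)
        lv = np.array([lhat[k] for k in keys]) if isinstance(lhat, dict) else np.asarray(lhat)
    else:
        w, cv, lv = map(np.asarray, (counts, c, lhat))
    norm = float(np.dot(cv, lv))
    if norm <= 0:
        raise InferenceError("normalization sum c_p * l_hat_p must be positive")
    active = w > 0
    if np.any(cv[active] <= 0):
        return float("-inf")  # counted path with zero abundance
    return float(np.dot(w[active], np.log(cv[active])) - w.sum() * math.log(norm))


# ---------------------------------------------------------------------------
# single-gene flow solver (column-generation EM)


def _fallback_path_through(gene: Gene, eid: int) -> tuple[int, ...]:
    """Any [S]-[T] edge path through edge ``eid`` (greedy extension)."""
    pg = gene.rollout
    chain = [eid]
    v = pg.edges[eid].src
    while v != pg.source:
        e = pg.in_edges[v][0]
        chain.insert(0, e)
        v = pg.edges[e].src
    v = pg.edges[eid].dst
    while v != pg.sink:
        e = pg.out_edges[v][0]
        chain.append(e)
        v = pg.edges[e].dst
    return tuple(chain)


def _best_linear_path(pg, score: np.ndarray) -> tuple[float, tuple[int, ...]]:
    """[S]-[T] path maximizing the edge-score sum (topological DP,
    deterministic tie-break by edge id)."""
    best = np.full(pg.n_vertices, -np.inf)
    back = np.full(pg.n_vertices, -1, dtype=int)
    best[pg.source] = 0.0
    for v in pg.topological_order():
        if not np.isfinite(best[v]):
            continue
        for eid in pg.out_edges[v]:
            w = best[v] + score[eid]
            dst = pg.edges[eid].dst
            if w > best[dst]:
                best[dst] = w
                back[dst] = eid
    eids = []
    v = pg.sink
    while v != pg.source:
        eid = back[v]
        eids.append(eid)
        v = pg.edges[eid].src
    eids.reverse()
    return float(best[pg.sink]), tuple(eids)


def _best_ratio_path(
    pg, gamma: np.ndarray, h: np.ndarray, lam0: float, max_rounds: int = 50
) -> tuple[float, tuple[int, ...]]:
    """max_pi (sum gamma_e) / (sum h_e) by Dinkelbach iteration.

    Paths with zero h-sum carry zero gamma-sum as well (an edge recognizing
    a counted path also aggregates its positive effective length), so the
    ratio is well defined on every relevant path.
    """
    lam = lam0
    best_ratio, best_path = -np.inf, ()
    for _ in range(max_rounds):
        _, eids = _best_linear_path(pg, gamma - lam * h)
        gsum = float(gamma[list(eids)].sum())
        hsum = float(h[list(eids)].sum())
        if hsum <= 0:
            break
        ratio = gsum / hsum
        if ratio > best_ratio:
            best_ratio, best_path = ratio, eids
        if ratio <= lam * (1 + 1e-14):
            break  # Dinkelbach fixed point: lam is the maximum ratio
        lam = ratio
    return best_ratio, best_path


def _restricted_em(
    A: np.ndarray,  # (n_paths, n_cols) 0/1 compatibility
    w: np.ndarray,  # counts per phasing path
    lcol: np.ndarray,  # effective length per column
    mass: float,
    u0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float]:
    """Quantification EM over a fixed set of columns ([S]-[T] paths)."""
    W = w.sum()
    u = u0.copy()
    active = w > 0
    Aw = A[active]
    wv = w[active]
    prev = -np.inf
    for _ in range(max_iter):
        cp = Aw @ u
        if np.any(cp <= 0):
            raise InferenceError("counted phasing path lost all support")
        ll = float(wv @ np.log(cp) - W * math.log(mass))
        if ll - prev <= tol * (1.0 + abs(ll)) and prev > -np.inf:
            prev = ll
            break
        prev = ll
        n = u * (Aw.T @ (wv / cp))
        u = n / W * mass / lcol
    cp = Aw @ u
    ll = float(wv @ np.log(cp) - W * math.log(mass))
    return u, ll


def solve_single_gene(
    gene: Gene,
    counts: dict[GraphPath, float] | np.ndarray,
    lhat: dict[GraphPath, float] | np.ndarray | None = None,
    mass: float = 1.0,
    config: EMConfig | None = None,
) -> Flow:
    """Maximum-likelihood flow for one gene at fixed per-path counts.

    ``counts`` maps phasing paths to (expected) fragment counts; ``lhat``
    defaults to the phasing set's effective lengths.  ``mass`` is the
    right-hand side of the normalization sum_p c_p l_hat_p = mass (1 for a
    single gene, s_g/|F| inside the gene-level M-step).

    Returns a :class:`~graphquant.flow.Flow` whose ``diagnostics`` carry the
    achieved objective, the KKT residual and the column count.
    """
    cfg = config or EMConfig()
    pg = gene.rollout
    P = gene.phasing
    if mass <= 0:
        raise InferenceError("mass must be positive")
    if isinstance(counts, dict):
        w = np.zeros(len(P))
        for p, wp in counts.items():
            if tuple(p) not in P.index:
                raise InferenceError(f"counted path {p} not in the phasing set")
            w[P.index[tuple(p)]] = wp
    else:
        w = np.asarray(counts, dtype=float)
    if lhat is None:
        lv = P.eff_lengths
    elif isinstance(lhat, dict):
        lv = np.array([lhat[p] for p in P.paths])
    else:
        lv = np.asarray(lhat, dtype=float)
    if np.any(w[lv <= 0] > 0):
        bad = P.paths[int(np.nonzero(w * (lv <= 0))[0][0])]
        raise InferenceError(
            f"path {bad} has fragments but zero effective length"
        )
    W = float(w.sum())
    h = gene.h if lhat is None else _aggregate_h(gene, lv)

    if W == 0.0:
        f = _uniform_flow(pg)
        s = float(np.dot(h, f))
        if s <= 0:
            raise InferenceError("normalization infeasible: all h_e are zero")
        return Flow(graph=pg, edge_weights=f * (mass / s),
                    diagnostics={"objective": 0.0, "kkt_residual": 0.0, "n_columns": 0})

    # -- initial working set: one [S]-[T] path through each counted path
    columns: list[tuple[int, ...]] = []
    seen = set()
    for i in np.nonzero(w > 0)[0]:
        eids = gene.recognition[i]
        if len(eids) == 0:
            raise InferenceError(
                f"counted path {P.paths[i]} has an empty recognition set"
            )
        col = _fallback_path_through(gene, int(eids[0]))
        if col not in seen:
            seen.add(col)
            columns.append(col)

    def col_stats(cols):
        A = np.zeros((len(P), len(cols)))
        lcol = np.zeros(len(cols))
        for j, col in enumerate(cols):
            members = set(col)
            lcol[j] = h[list(col)].sum()
            for i, eids in enumerate(gene.recognition):
                hits = sum(1 for e in eids if e in members)
                A[i, j] = 1.0 if hits else 0.0
        return A, lcol

    A, lcol = col_stats(columns)
    u = mass / (len(columns) * lcol)
    obj = -np.inf
    kkt = np.inf
    for outer in range(cfg.max_columns):
        u, obj = _restricted_em(
            A, w, lcol, mass, u, cfg.inner_tol, cfg.inner_max_iter
        )
        cp = A @ u
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio_w = np.where(cp > 0, w / cp, 0.0)
        gamma = np.zeros(pg.n_edges)
        for i, eids in enumerate(gene.recognition):
            if ratio_w[i] > 0:
                gamma[eids] += ratio_w[i]
        lam = W / mass
        best_ratio, best_path = _best_ratio_path(pg, gamma, h, lam)
        kkt = max(0.0, mass * best_ratio - W)  # bound on the remaining gap
        if kkt <= cfg.kkt_tol * max(W, 1.0) or not best_path:
            break
        if best_path in seen:
            break  # numerically stalled; KKT residual is reported below
        seen.add(best_path)
        columns.append(best_path)
        A, lcol = col_stats(columns)
        u = np.append(u * (1 - 1e-9), 1e-9 * mass / lcol[-1])
    else:  # pragma: no cover
        raise InferenceError("column generation failed to converge")

    f = np.zeros(pg.n_edges)
    for j, col in enumerate(columns):
        f[list(col)] += u[j]
    return Flow(
        graph=pg,
        edge_weights=f,
        diagnostics={
            "objective": obj,
            "kkt_residual": kkt,
            "n_columns": len(columns),
        },
    )


def _aggregate_h(gene: Gene, lv: np.ndarray) -> np.ndarray:
    h = np.zeros(gene.rollout.n_edges)
    for eids, lp in zip(gene.recognition, lv):
        h[eids] += lp
    return h


def _uniform_flow(pg) -> np.ndarray:
    """Deterministic balanced flow: unit mass split equally at each vertex."""
    f = np.zeros(pg.n_edges)
    mass_at = np.zeros(pg.n_vertices)
    mass_at[pg.source] = 1.0
    for v in pg.topological_order():
        outs = pg.out_edges[v]
        if not outs or mass_at[v] == 0:
            continue
        share = mass_at[v] / len(outs)
        for eid in outs:
            f[eid] += share
            mass_at[pg.edges[eid].dst] += share
    return f


# ---------------------------------------------------------------------------
# multi-gene EM


@dataclass
class EMState:
    """Converged (or in-progress) EM quantities.

    ``c`` holds absolute path abundances per gene (summing against the
    effective lengths to c_g); ``c_rel`` the within-gene relative versions
    with sum_p c*_p l_hat_p = 1; ``z`` the last responsibilities, grouped by
    identical mapping signature.
    """

    genes: list[Gene]
    c: dict[str, np.ndarray]
    c_gene: dict[str, float]
    s_gene: dict[str, float]
    flows: dict[str, Flow]
    loglik_trace: list[float]
    z_groups: list[tuple[list[str], list[tuple[str, int]], np.ndarray]]
    n_fragments: int

    @property
    def c_rel(self) -> dict[str, np.ndarray]:
        return {
            gid: (c / self.c_gene[gid] if self.c_gene[gid] > 0 else c * 0.0)
            for gid, c in self.c.items()
        }

    def abundance(self, gene_id: str, p: GraphPath) -> float:
        gene = next(g for g in self.genes if g.gene_id == gene_id)
        return float(self.c[gene_id][gene.path_index(p)])

    def responsibilities(self) -> dict[tuple[str, str, GraphPath], float]:
        """Expanded z_{f,p} keyed by (fragment_id, gene_id, path)."""
        genes_by_id = {g.gene_id: g for g in self.genes}
        out = {}
        for frag_ids, keys, z in self.z_groups:
            for fid in frag_ids:
                for (gid, pi), zz in zip(keys, z):
                    out[(fid, gid, genes_by_id[gid].phasing.paths[pi])] = float(zz)
        return out


def _group_fragments(
    genes: list[Gene], fragments: list[FragmentRecord]
) -> list[tuple[list[str], list[tuple[str, int]], np.ndarray]]:
    """Group fragments by identical (gene, path, affinity) mapping signature."""
    by_id = {g.gene_id: g for g in genes}
    default_gid = genes[0].gene_id if len(genes) == 1 else None
    groups: dict[tuple, list[str]] = {}
    metas: dict[tuple, tuple[list[tuple[str, int]], np.ndarray]] = {}
    for frag in fragments:
        keys = []
        affs = []
        for m in frag.mappings:
            gid = m.gene_id or default_gid
            if gid is None or gid not in by_id:
                raise InferenceError(
                    f"fragment {frag.fragment_id}: unknown gene {m.gene_id!r}"
                )
            gene = by_id[gid]
            p = tuple(m.path)
            if p not in gene.phasing.index:
                raise InferenceError(
                    f"fragment {frag.fragment_id}: path {p} not in phasing set "
                    f"of gene {gid}"
                )
            keys.append((gid, gene.phasing.index[p]))
            affs.append(m.affinity)
        sig = tuple(sorted(zip(keys, affs)))
        if sig not in metas:
            skeys = [k for k, _ in sig]
            saffs = np.array([a for _, a in sig])
            metas[sig] = (skeys, saffs)
            groups[sig] = []
        groups[sig].append(frag.fragment_id)
    return [
        (groups[sig], metas[sig][0], metas[sig][1]) for sig in groups
    ]


def e_step(
    c: dict[str, np.ndarray],
    genes: list[Gene],
    fragments: list[FragmentRecord],
) -> dict[str, list[tuple[str, GraphPath, float]]]:
    """Per-fragment responsibilities z_{f,p}.

    z_{f,p} = c_p A(f|p) / sum_{p' in M(f)} c_{p'} A(f|p'); normalized over
    each fragment's candidate mappings.  Returns, per fragment id, a list of
    (gene_id, path, z).
    """
    by_id = {g.gene_id: g for g in genes}
    default_gid = genes[0].gene_id if len(genes) == 1 else None
    out: dict[str, list[tuple[str, GraphPath, float]]] = {}
    for frag in fragments:
        weights = []
        keys = []
        for m in frag.mappings:
            gid = m.gene_id or default_gid
            gene = by_id[gid]
            pi = gene.phasing.index[tuple(m.path)]
            keys.append((gid, tuple(m.path)))
            weights.append(c[gid][pi] * m.affinity)
        total = float(sum(weights))
        if total <= 0:
            raise InferenceError(
                f"fragment {frag.fragment_id}: zero total affinity-weighted "
                "abundance over its mappings"
            )
        out[frag.fragment_id] = [
            (gid, p, wgt / total) for (gid, p), wgt in zip(keys, weights)
        ]
    return out


def m_step(
    genes: list[Gene],
    counts: dict[str, np.ndarray],
    n_fragments: int,
    config: EMConfig | None = None,
) -> tuple[dict[str, Flow], dict[str, float]]:
    """Gene-level M-step: independent per-gene solves with mass s_g/|F|.

    Genes with s_g = 0 get the zero flow.  Gene abundances are
    c_g = s_g / |F|.
    """
    cfg = config or EMConfig()
    flows: dict[str, Flow] = {}
    c_gene: dict[str, float] = {}
    for gene in genes:
        w = np.asarray(counts[gene.gene_id], dtype=float)
        s_g = float(w.sum())
        c_gene[gene.gene_id] = s_g / n_fragments
        if s_g == 0:
            flows[gene.gene_id] = Flow(
                graph=gene.rollout, edge_weights=np.zeros(gene.rollout.n_edges)
            )
            continue
        flows[gene.gene_id] = solve_single_gene(
            gene, w, mass=s_g / n_fragments, config=cfg
        )
    return flows, c_gene


def _abundances_from_flow(gene: Gene, flow: Flow) -> np.ndarray:
    return np.array(
        [flow.edge_weights[eids].sum() for eids in gene.recognition]
    )


def _initial_abundances(genes: list[Gene]) -> dict[str, np.ndarray]:
    """Uniform routing flow per gene, scaled so each gene carries equal mass."""
    out = {}
    for gene in genes:
        f = _uniform_flow(gene.rollout)
        s = float(np.dot(gene.h, f))
        if s <= 0:
            raise InferenceError(
                f"gene {gene.gene_id}: no phasing path has positive "
                "effective length"
            )
        f *= 1.0 / (len(genes) * s)
        out[gene.gene_id] = np.array(
            [f[eids].sum() for eids in gene.recognition]
        )
    return out


def run_em(
    genes: list[Gene] | Gene,
    fragments: list[FragmentRecord],
    config: EMConfig | None = None,
) -> EMState:
    """Alternate global E-steps and gene-level M-steps to convergence.

    The log-likelihood trace is monotone non-decreasing (up to
    ``config.monotone_tol``); a violation beyond tolerance signals a solver
    failure and raises :class:`InferenceError`.
    """
    if isinstance(genes, Gene):
        genes = [genes]
    cfg = config or EMConfig()
    if not fragments:
        raise InferenceError("at least one fragment required")
    nF = len(fragments)
    groups = _group_fragments(genes, fragments)
    c = _initial_abundances(genes)

    def full_loglik(c_abs: dict[str, np.ndarray]) -> float:
        norm = sum(
            float(np.dot(c_abs[g.gene_id], g.phasing.eff_lengths)) for g in genes
        )
        if norm <= 0:
            raise InferenceError("zero normalization")
        ll = -nF * math.log(norm)
        for frag_ids, keys, affs in groups:
            val = sum(
                c_abs[gid][pi] * a for (gid, pi), a in zip(keys, affs)
            )
            if val <= 0:
                return float("-inf")
            ll += len(frag_ids) * math.log(val)
        return ll

    trace: list[float] = []
    flows: dict[str, Flow] = {}
    c_gene = {g.gene_id: 1.0 / len(genes) for g in genes}
    counts_arr: dict[str, np.ndarray] = {}
    for it in range(cfg.max_iter):
        ll = full_loglik(c)
        if trace:
            if ll < trace[-1] - cfg.monotone_tol * (1.0 + abs(trace[-1])):
                raise InferenceError(
                    f"non-monotone EM step at iteration {it}: "
                    f"{trace[-1]:.12g} -> {ll:.12g}"
                )
            converged = abs(ll - trace[-1]) <= cfg.tol * (1.0 + abs(ll))
        else:
            converged = False
        trace.append(ll)
        if converged:
            break
        # E-step (grouped)
        counts_arr = {g.gene_id: np.zeros(len(g.phasing)) for g in genes}
        for frag_ids, keys, affs in groups:
            weights = np.array([c[gid][pi] for gid, pi in keys]) * affs
            denom = weights.sum()
            if denom <= 0:
                raise InferenceError(
                    f"fragment {frag_ids[0]}: zero denominator in E-step"
                )
            z = weights / denom * len(frag_ids)
            for (gid, pi), zz in zip(keys, z):
                counts_arr[gid][pi] += zz
        # M-step
        flows, c_gene = m_step(genes, counts_arr, nF, cfg)
        c = {
            g.gene_id: _abundances_from_flow(g, flows[g.gene_id]) for g in genes
        }
    s_gene = {gid: cg * nF for gid, cg in c_gene.items()}
    # final responsibilities at the converged abundances
    z_groups = []
    for frag_ids, keys, affs in groups:
        weights = np.array([c[gid][pi] for gid, pi in keys]) * affs
        z = weights / weights.sum()
        z_groups.append((frag_ids, keys, z))
    return EMState(
        genes=genes,
        c=c,
        c_gene=c_gene,
        s_gene=s_gene,
        flows=flows,
        loglik_trace=trace,
        z_groups=z_groups,
        n_fragments=nF,
    )
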