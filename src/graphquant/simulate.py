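"""Synthetic data: random splice graphs, fragment sampling, and the
transcript-enumeration oracle.

The generator draws a random forward DAG of exons, a ground-truth
quantified transcript set, and fragments from the standard generative
model: a transcript is sampled proportional to abundance times effective
length, then a window (j, k) with weight D(k-j+1).  Fragments are reported
as phasing-path records; optional within-gene multimapping duplicates a
fragment's mapping onto every alternative exon chain consistent with its
anchor exons and the fragment-length distribution.

``oracle_quantify`` runs the classical quantification EM over an explicitly
enumerated transcript set — the independent reference that flow-based
inference is checked against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .effective_length import FragLenDist, transcript_eff_len
from .phasing import FragmentMapping, FragmentRecord, PhasingSet
from .prefix_graph import build_automaton, build_compact_prefix_graph, build_prefix_graph
from .splice_graph import (
    GraphPath,
    QuantifiedTranscriptSet,
    SpliceGraph,
    count_st_paths,
    enumerate_st_paths,
    is_subpath,
    splice_graph_from_lengths,
)

__all__ = [
    "SimConfig",
    "make_fld",
    "random_splice_graph",
    "random_transcripts",
    "simulate_fragments",
    "random_instance",
    "oracle_quantify",
    "prefix_graph_size_metrics",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror a typical short-read paired-end experiment: fragment
    lengths roughly normal around 350 bp (sd 70, truncated to [50, 600])
    and sub-exon lengths from a few tens to a few hundred bases.  All
    randomness flows through ``numpy.random.default_rng(seed)``.
    """

    n_internal_vertices: int = 6
    edge_density: float = 0.4
    n_transcripts: int = 4
    abundance_dirichlet_alpha: float = 1.0
    exon_length_range: tuple[int, int] = (50, 300)
    fld_spec: tuple = ("normal", 350.0, 70.0, 50, 600)
    n_fragments: int = 1000
    multimap_rate: float = 0.0
    max_out_degree: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_internal_vertices < 1 or self.n_transcripts < 1:
            raise ValueError("vertex and transcript counts must be positive")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must be in [0, 1]")
        if not 0.0 <= self.multimap_rate <= 1.0:
            raise ValueError("multimap_rate must be in [0, 1]")
        lo, hi = self.exon_length_range
        if not 1 <= lo <= hi:
            raise ValueError("bad exon_length_range")


def make_fld(cfg: SimConfig) -> FragLenDist:
    spec = cfg.fld_spec
    if isinstance(spec, dict):
        return FragLenDist.from_pmf(spec)
    kind = spec[0]
    if kind == "normal":
        _, mean, sd, lo, hi = spec
        return FragLenDist.discretized_normal(mean, sd, int(lo), int(hi))
    raise ValueError(f"unknown fld_spec {spec!r}")


def random_splice_graph(cfg: SimConfig, rng: np.random.Generator | None = None) -> SpliceGraph:
    """Random forward DAG of exons with the permissive S/T closure.

    Edges run only from lower to higher exon index, so a topological order
    exists by construction; S connects to every in-degree-0 exon and T from
    every out-degree-0 exon, which puts every exon on an S-T path.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_internal_vertices
    lo, hi = cfg.exon_length_range
    lengths = rng.integers(lo, hi + 1, size=n).tolist()
    junctions: list[tuple[int, int]] = []
    if cfg.max_out_degree is None:
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                if rng.random() < cfg.edge_density:
                    junctions.append((i, j))
    else:
        # degree-capped construction: every exon j > 1 gets a parent among
        # the earlier exons with spare capacity, so only exon 1 starts and
        # S keeps out-degree 1; extra forward edges fill remaining capacity.
        k = cfg.max_out_degree
        out_deg = [0] * (n + 1)
        edge_set = set()
        for j in range(2, n + 1):
            parents = [i for i in range(1, j) if out_deg[i] < k]
            i = int(parents[rng.integers(len(parents))]) if parents else j - 1
            edge_set.add((i, j))
            out_deg[i] += 1
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                if out_deg[i] >= k:
                    break
                if (i, j) not in edge_set and rng.random() < cfg.edge_density:
                    edge_set.add((i, j))
                    out_deg[i] += 1
        junctions = sorted(edge_set)
    g = splice_graph_from_lengths(lengths, junctions, gene_id=f"sim{cfg.seed}")
    if cfg.max_out_degree is not None and any(
        len(g.successors(v.id)) > cfg.max_out_degree for v in g.vertices
    ):  # pragma: no cover - construction guarantees the cap
        raise ValueError("max_out_degree violated after S/T closure")
    return g


def random_transcripts(
    g: SpliceGraph,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    enumeration_limit: int = 4096,
) -> QuantifiedTranscriptSet:
    """Ground-truth transcript set: distinct random S-T paths with
    Dirichlet-distributed abundances."""
    rng = rng or np.random.default_rng(cfg.seed)
    total = count_st_paths(g)
    if total <= enumeration_limit:
        paths = enumerate_st_paths(g, enumeration_limit)
        k = min(cfg.n_transcripts, len(paths))
        chosen = [paths[i] for i in rng.choice(len(paths), size=k, replace=False)]
    else:  # random walks, deduplicated
        chosen_set = set()
        while len(chosen_set) < cfg.n_transcripts:
            v = g.source
            path = [v]
            while v != g.sink:
                succ = g.successors(v)
                v = int(succ[rng.integers(len(succ))])
                path.append(v)
            chosen_set.add(tuple(path))
        chosen = sorted(chosen_set)
    alpha = np.full(len(chosen), cfg.abundance_dirichlet_alpha)
    abundances = rng.dirichlet(alpha)
    return QuantifiedTranscriptSet.from_graph(g, chosen, abundances)


# ---------------------------------------------------------------------------
# fragment sampling


def _window_to_phasing(
    g: SpliceGraph, transcript: GraphPath, j: int, k: int
) -> tuple[GraphPath, int]:
    """Map a 1-based window (j, k) on the transcript sequence to its
    phasing path and 0-based offset within the first exon."""
    exons = [v for v in transcript if g.vertex(v).kind == "exon"]
    bounds = np.cumsum([0] + [g.length(v) for v in exons])
    first = int(np.searchsorted(bounds, j - 1, side="right")) - 1
    last = int(np.searchsorted(bounds, k - 1, side="right")) - 1
    path = tuple(exons[first : last + 1])
    return path, int(j - 1 - bounds[first])


def _alternative_chains(
    g: SpliceGraph, u: int, v: int, max_paths: int = 32
) -> list[GraphPath]:
    sub = g.nxg.subgraph(g.exon_ids)
    out = []
    for p in nx.all_simple_paths(sub, u, v, cutoff=16):
        out.append(tuple(p))
        if len(out) >= max_paths:
            break
    return out


def simulate_fragments(
    g: SpliceGraph,
    qts: QuantifiedTranscriptSet,
    D: FragLenDist,
    n: int,
    rng: np.random.Generator | int = 0,
    multimap_rate: float = 0.0,
    id_prefix: str = "f",
) -> list[FragmentRecord]:
    """Draw n fragments from the generative model.

    Transcripts are sampled proportional to c_i * l_hat_i, fragment lengths
    proportional to D(t) (l_i + 1 - t), start positions uniformly.  With
    probability ``multimap_rate`` a fragment also reports every alternative
    exon chain between its anchor exons whose implied length has positive
    probability under D (paired-end gap ambiguity).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if len(qts.transcripts) == 0:
        raise ValueError("empty transcript set")
    lhat = np.array([transcript_eff_len(D, int(l)) for l in qts.lengths])
    probs = qts.abundances * lhat
    if probs.sum() <= 0:
        raise ValueError("no transcript can generate fragments under D")
    probs = probs / probs.sum()

    # per-transcript fragment-length distributions ∝ D(t) (l+1-t)
    tlen_dists = []
    for l in qts.lengths:
        hi = min(int(l), len(D.pmf) - 1)
        t = np.arange(1, hi + 1)
        wt = D.pmf[1 : hi + 1] * (l + 1 - t)
        s = wt.sum()
        tlen_dists.append((t, wt / s if s > 0 else wt))

    draws = rng.choice(len(qts.transcripts), size=n, p=probs)
    records = []
    for fi, ti in enumerate(draws):
        t_vals, t_probs = tlen_dists[ti]
        t = int(rng.choice(t_vals, p=t_probs))
        l = int(qts.lengths[ti])
        j = int(rng.integers(1, l + 1 - t + 1))
        k = j + t - 1
        path, offset = _window_to_phasing(g, qts.transcripts[ti], j, k)
        mappings = [
            FragmentMapping(
                path=path,
                start_offset=offset,
                frag_len=t,
                affinity=float(D.d(t)),
                gene_id=g.gene_id,
            )
        ]
        if multimap_rate > 0 and len(path) >= 2 and rng.random() < multimap_rate:
            first_len = g.length(path[0])
            a = first_len - offset  # bases in the first exon
            b = k - j + 1 - a - sum(g.length(v) for v in path[1:-1])
            for chain in _alternative_chains(g, path[0], path[-1]):
                if chain == path:
                    continue
                t_alt = a + sum(g.length(v) for v in chain[1:-1]) + b
                aff = float(D.d(t_alt)) if t_alt >= 2 else 0.0
                if aff > 0:
                    mappings.append(
                        FragmentMapping(
                            path=chain,
                            start_offset=offset,
                            frag_len=t_alt,
                            affinity=aff,
                            gene_id=g.gene_id,
                        )
                    )
        records.append(FragmentRecord(fragment_id=f"{id_prefix}{fi}", mappings=mappings))
    return records


def random_instance(
    cfg: SimConfig,
) -> tuple[SpliceGraph, QuantifiedTranscriptSet, FragLenDist, list[FragmentRecord]]:
    """Convenience bundle: graph, truth, FLD and fragments from one seed."""
    rng = np.random.default_rng(cfg.seed)
    g = random_splice_graph(cfg, rng)
    qts = random_transcripts(g, cfg, rng)
    D = make_fld(cfg)
    frags = simulate_fragments(
        g, qts, D, cfg.n_fragments, rng, multimap_rate=cfg.multimap_rate
    )
    return g, qts, D, frags


# ---------------------------------------------------------------------------
# transcript-enumeration oracle


def oracle_quantify(
    g: SpliceGraph,
    st_paths: list[GraphPath],
    fragments: list[FragmentRecord],
    D: FragLenDist,
    tol: float = 1e-13,
    max_iter: int = 200_000,
) -> tuple[QuantifiedTranscriptSet, float]:
    """Classical quantification EM over an enumerated transcript set.

    Maximizes  sum_f log(sum_i c_i B_{f,i}) - |F| log(sum_i c_i l_hat_i)
    with B_{f,i} = sum_{p in M(f), p subset T_i} A(f|p), normalized to
    sum_i c_i l_hat_i = 1.  Returns the quantified set and the maximum
    log-likelihood (same scale as the flow-side EM).
    """
    paths = [g.validate_path(p) for p in st_paths]
    lhat = np.array([transcript_eff_len(D, g.path_length(p)) for p in paths])
    if np.any(lhat <= 0):
        raise ValueError("transcript with zero effective length under D")

    # group fragments by mapping signature
    groups: dict[tuple, int] = {}
    for frag in fragments:
        sig = tuple(sorted((tuple(m.path), m.affinity) for m in frag.mappings))
        groups[sig] = groups.get(sig, 0) + 1
    sigs = list(groups)
    wts = np.array([groups[s] for s in sigs], dtype=float)
    B = np.zeros((len(sigs), len(paths)))
    for r, sig in enumerate(sigs):
        for p, aff in sig:
            for i, t in enumerate(paths):
                if is_subpath(t, p):
                    B[r, i] += aff
        if not np.any(B[r] > 0):
            raise ValueError(f"fragment signature {sig} compatible with no transcript")

    nF = wts.sum()
    c = (1.0 / lhat) / len(paths)
    c /= np.dot(c, lhat)
    prev = -np.inf
    ll = prev
    for _ in range(max_iter):
        like = B @ c
        ll = float(wts @ np.log(like))
        if ll - prev <= tol * (1.0 + abs(ll)) and prev > -np.inf:
            break
        prev = ll
        nhat = c * (B.T @ (wts / like))
        c = nhat / nF / lhat
        c /= np.dot(c, lhat)  # guard drift
    qts = QuantifiedTranscriptSet(
        paths, c, np.array([g.path_length(p) for p in paths])
    )
    return qts, ll


def prefix_graph_size_metrics(
    g: SpliceGraph, P: PhasingSet
) -> dict[str, tuple[int, int]]:
    """(n_vertices, n_edges) of both rollouts for a phasing set."""
    pg = build_prefix_graph(build_automaton(g, P))
    cpg = build_compact_prefix_graph(g, P)
    return {"prefix": pg.size_metrics(), "compact": cpg.size_metrics()}
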