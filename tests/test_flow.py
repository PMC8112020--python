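"""Flow mapping, abundance preservation, decomposition and PSI."""

import numpy as np
import pytest

from graphquant import (
    FlowError,
    QuantifiedTranscriptSet,
    build_automaton,
    build_compact_prefix_graph,
    build_prefix_graph,
    compute_psi,
    decompose_flow,
    minimal_sufficiency_nullspace,
    path_abundance,
    psi_bounds,
    splice_graph_from_lengths,
    transcripts_to_flow,
)
from graphquant.flow import Flow
from graphquant.simulate import SimConfig, random_transcripts
from graphquant.splice_graph import enumerate_st_paths, is_subpath

from conftest import small_random_setup


def _rollouts(g, P):
    paths = P.paths if hasattr(P, "paths") else P
    return (
        build_prefix_graph(build_automaton(g, paths)),
        build_compact_prefix_graph(g, paths),
    )


def _random_qts(g, seed, k=3):
    rng = np.random.default_rng(seed)
    cfg = SimConfig(n_transcripts=k, seed=seed)
    return random_transcripts(g, cfg, rng)


# ---------------------------------------------------------------------------
# transcripts_to_flow


def test_single_transcript_flow(chain_graph, point_fld):
    from graphquant import build_phasing_set

    P = build_phasing_set(chain_graph, point_fld)
    for pg in _rollouts(chain_graph, P):
        qts = QuantifiedTranscriptSet.from_graph(chain_graph, [(0, 1, 2, 3)], [5.0])
        fl = transcripts_to_flow(pg, qts)
        assert np.allclose(fl.edge_weights, 5.0)


def test_shared_prefix_flows_add(diamond_chord_graph, point_fld):
    from graphquant import build_phasing_set

    g = diamond_chord_graph
    P = build_phasing_set(g, point_fld)
    for pg in _rollouts(g, P):
        qts = QuantifiedTranscriptSet.from_graph(
            g, [(0, 1, 2, 3, 4), (0, 1, 3, 4)], [2.0, 3.0]
        )
        fl = transcripts_to_flow(pg, qts)
        # the S->e1 edge is shared
        first = [e for e in pg.edges if e.src == pg.source]
        assert len(first) == 1
        assert fl.edge_weights[first[0].id] == pytest.approx(5.0)
        assert fl.balance_residual() < 1e-12


@pytest.mark.parametrize("seed", range(10))
def test_flow_balance_on_random_transcript_sets(seed):
    g, D, P = small_random_setup(seed)
    qts = _random_qts(g, seed)
    for pg in _rollouts(g, P):
        fl = transcripts_to_flow(pg, qts)
        assert fl.balance_residual() < 1e-12 * max(1.0, fl.total())


# ---------------------------------------------------------------------------
# path_abundance


def test_path_abundance_matches_containment_sum():
    checked = 0
    for seed in range(12):
        g, D, P = small_random_setup(seed, n_hi=7)
        qts = _random_qts(g, seed)
        for pg in _rollouts(g, P):
            fl = transcripts_to_flow(pg, qts)
            for p in P.paths:
                want = sum(
                    c
                    for t, c in zip(qts.transcripts, qts.abundances)
                    if is_subpath(t, p)
                )
                assert path_abundance(fl, p) == pytest.approx(want, abs=1e-12)
                checked += 1
    assert checked >= 300


def test_path_abundance_rejects_unknown_path(chain_graph, point_fld):
    from graphquant import build_phasing_set

    P = build_phasing_set(chain_graph, point_fld)
    pg = _rollouts(chain_graph, P)[1]
    qts = QuantifiedTranscriptSet.from_graph(chain_graph, [(0, 1, 2, 3)], [1.0])
    fl = transcripts_to_flow(pg, qts)
    with pytest.raises(FlowError):
        path_abundance(fl, (2, 1))


# ---------------------------------------------------------------------------
# decomposition


def test_decompose_diamond(diamond_graph, point_fld):
    from graphquant import build_phasing_set

    g = diamond_graph
    P = build_phasing_set(g, point_fld)
    for pg in _rollouts(g, P):
        qts = QuantifiedTranscriptSet.from_graph(g, [(0, 1, 3), (0, 2, 3)], [2.0, 3.0])
        dec = decompose_flow(transcripts_to_flow(pg, qts))
        got = dict(zip(dec.transcripts, dec.abundances))
        assert got[(0, 1, 3)] == pytest.approx(2.0)
        assert got[(0, 2, 3)] == pytest.approx(3.0)


@pytest.mark.parametrize("seed", range(10))
def test_decomposition_round_trip(seed):
    """transcripts_to_flow(decompose(flow)) reproduces the flow edge-wise."""
    g, D, P = small_random_setup(seed)
    qts = _random_qts(g, seed, k=4)
    for pg in _rollouts(g, P):
        fl = transcripts_to_flow(pg, qts)
        dec = decompose_flow(fl)
        assert len(dec.transcripts) <= pg.n_edges
        fl2 = transcripts_to_flow(pg, dec)
        assert np.allclose(fl.edge_weights, fl2.edge_weights, atol=1e-9 * max(1.0, fl.total()))


@pytest.mark.parametrize("seed", range(8))
def test_abundance_preserved_through_round_trip(seed):
    """c_p identical before mapping, after mapping, after decomposition."""
    g, D, P = small_random_setup(seed, n_hi=7)
    qts = _random_qts(g, seed)
    for pg in _rollouts(g, P):
        fl = transcripts_to_flow(pg, qts)
        dec = decompose_flow(fl)
        for p in P.paths:
            direct = sum(
                c for t, c in zip(qts.transcripts, qts.abundances) if is_subpath(t, p)
            )
            after = sum(
                c for t, c in zip(dec.transcripts, dec.abundances) if is_subpath(t, p)
            )
            assert path_abundance(fl, p) == pytest.approx(direct, abs=1e-9)
            assert after == pytest.approx(direct, abs=1e-9)


def test_decompose_rejects_imbalance(chain_graph, point_fld):
    from graphquant import build_phasing_set

    P = build_phasing_set(chain_graph, point_fld)
    pg = _rollouts(chain_graph, P)[0]
    w = np.zeros(pg.n_edges)
    w[0] = 1.0  # mass appears at [S] but vanishes midway
    fl = Flow(graph=pg, edge_weights=w, validate=False)
    with pytest.raises(FlowError):
        decompose_flow(fl)


# ---------------------------------------------------------------------------
# PSI


def _psi_qts():
    g = splice_graph_from_lengths([5, 4, 6], [(1, 2), (1, 3), (2, 3)])
    qts = QuantifiedTranscriptSet.from_graph(
        g, [(0, 1, 2, 3, 4), (0, 1, 3, 4)], [3.0, 1.0]
    )
    return g, qts


def test_psi_worked_example():
    g, qts = _psi_qts()
    assert compute_psi(qts, 1, 2, 3, graph=g) == pytest.approx(0.75)


def test_psi_all_inclusive_is_one():
    g, qts = _psi_qts()
    qts.abundances = np.array([3.0, 0.0])
    assert compute_psi(qts, 1, 2, 3, graph=g) == pytest.approx(1.0)


def test_psi_undefined_is_nan():
    g, qts = _psi_qts()
    qts.abundances = np.array([0.0, 0.0])
    with pytest.warns(UserWarning):
        assert np.isnan(compute_psi(qts, 1, 2, 3, graph=g))


def test_psi_from_flow_matches_qts_when_phasing_identifies():
    """PSI is decomposition-invariant when the discriminating paths are in P."""
    g, qts = _psi_qts()
    D = None
    from graphquant import FragLenDist, build_phasing_set

    D = FragLenDist.discretized_normal(8, 3, 2, 30)
    P = build_phasing_set(g, D)
    assert (1, 2) in P and (2, 3) in P and (1, 3) in P
    for pg in _rollouts(g, P):
        fl = transcripts_to_flow(pg, qts)
        assert compute_psi(fl, 1, 2, 3) == pytest.approx(0.75)


def test_psi_bounds_bracket_canonical_value():
    g, qts = _psi_qts()
    from graphquant import FragLenDist, build_phasing_set

    D = FragLenDist.discretized_normal(8, 3, 2, 30)
    P = build_phasing_set(g, D)
    pg = _rollouts(g, P)[1]
    fl = transcripts_to_flow(pg, qts)
    lo, hi = psi_bounds(fl, 1, 2, 3)
    val = compute_psi(fl, 1, 2, 3)
    assert lo - 1e-7 <= val <= hi + 1e-7
    # phasing paths identify the flow here, so the bounds collapse
    assert hi - lo < 1e-6


# ---------------------------------------------------------------------------
# minimal sufficiency


def _prefix_closed_phasing(g, D):
    from graphquant import build_phasing_set
    from graphquant.effective_length import path_eff_len
    from graphquant.phasing import PhasingSet

    P = build_phasing_set(g, D)
    keys = set(P.paths)
    for p in P.paths:
        for cut in range(1, len(p)):
            keys.add(p[:cut])
    paths = sorted(keys, key=lambda p: (len(p), p))
    lh = np.array([path_eff_len(g, p, D) for p in paths])
    return PhasingSet(
        graph=g, paths=paths, counts=np.zeros(len(paths)), eff_lengths=lh, D=D
    )


def test_minimal_sufficiency_on_conforming_fixtures():
    """Prefix-closed P + out-degree <= 2: flow -> {c_p} is injective."""
    from graphquant import make_fld
    from graphquant.simulate import SimConfig, random_splice_graph

    n_ok = 0
    seed = 0
    while n_ok < 25 and seed < 300:
        seed += 1
        cfg = SimConfig(
            n_internal_vertices=int(np.random.default_rng(seed).integers(2, 7)),
            edge_density=0.3,
            exon_length_range=(20, 80),
            fld_spec=("normal", 90.0, 30.0, 10, 200),
            max_out_degree=2,
            seed=seed,
        )
        try:
            g = random_splice_graph(cfg)
        except ValueError:
            continue
        D = make_fld(cfg)
        P = _prefix_closed_phasing(g, D)
        cpg = build_compact_prefix_graph(g, P)
        assert minimal_sufficiency_nullspace(cpg) == 0, seed
        n_ok += 1
    assert n_ok == 25
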