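"""EM inference: likelihood, single-gene solver, E/M steps, full driver."""

import math

import numpy as np
import pytest

from graphquant import (
    EMConfig,
    FragLenDist,
    FragmentMapping,
    FragmentRecord,
    Gene,
    InferenceError,
    build_phasing_set,
    e_step,
    loglik,
    m_step,
    run_em,
    solve_single_gene,
    splice_graph_from_lengths,
)
from graphquant.flow import path_abundance
from graphquant.simulate import (
    SimConfig,
    oracle_quantify,
    random_instance,
)
from graphquant.splice_graph import count_st_paths, enumerate_st_paths


def _uniq(path, frag_len=2, gene_id=None, n=1, prefix="f"):
    return [
        FragmentRecord(
            f"{prefix}{i}",
            [
                FragmentMapping(
                    path=path, start_offset=0, frag_len=frag_len, affinity=1.0,
                    gene_id=gene_id,
                )
            ],
        )
        for i in range(n)
    ]


def _diamond_gene(gene_id="diamond"):
    g = splice_graph_from_lengths([4, 4], [], gene_id=gene_id)
    D = FragLenDist.from_pmf({2: 1.0})
    P = build_phasing_set(g, D)
    return g, D, Gene.build(g, P)


# ---------------------------------------------------------------------------
# loglik


def test_loglik_normalized_point_mass():
    assert loglik({(1,): 7.0}, {(1,): 1.0}, {(1,): 1.0}) == pytest.approx(0.0)


def test_loglik_symmetric_optimum():
    c = {(1,): 0.5, (2,): 0.5}
    val = loglik({(1,): 1.0, (2,): 1.0}, c, {(1,): 1.0, (2,): 1.0})
    assert val == pytest.approx(2 * math.log(0.5))


def test_loglik_zero_abundance_counted_path():
    assert loglik({(1,): 1.0}, {(1,): 0.0, (2,): 1.0}, {(1,): 1.0, (2,): 1.0}) == -np.inf


def test_loglik_concavity_along_random_chords():
    rng = np.random.default_rng(0)
    w = rng.integers(1, 20, size=5).astype(float)
    lh = rng.uniform(0.5, 4.0, size=5)
    for _ in range(50):
        x, y = rng.uniform(0.05, 1.0, size=(2, 5))
        lam = rng.uniform()
        z = lam * x + (1 - lam) * y
        fz = loglik(w, z, lh)
        assert fz >= lam * loglik(w, x, lh) + (1 - lam) * loglik(w, y, lh) - 1e-9


# ---------------------------------------------------------------------------
# solve_single_gene


def test_single_path_gene_routes_all_flow(chain_graph, point_fld):
    P = build_phasing_set(chain_graph, point_fld)
    gene = Gene.build(chain_graph, P)
    fl = solve_single_gene(gene, {(1,): 10.0}, mass=1.0)
    # a chain has one S-T path: every edge carries the same flow
    assert np.allclose(fl.edge_weights, fl.edge_weights[0])
    assert gene.phasing.normalization(
        [path_abundance(fl, p) for p in P.paths]
    ) == pytest.approx(1.0, rel=1e-9)


def test_diamond_branch_ratio():
    """Counts (10, 30) on the two branch singletons, equal l_hat -> 1:3."""
    g, D, gene = _diamond_gene()
    fl = solve_single_gene(gene, {(1,): 10.0, (2,): 30.0}, mass=1.0)
    c1 = path_abundance(fl, (1,))
    c2 = path_abundance(fl, (2,))
    assert c2 / c1 == pytest.approx(3.0, rel=1e-6)
    assert fl.diagnostics["kkt_residual"] <= 1e-9 * 40
    # two-variable closed form: c = w / (W * l_hat)
    lh = gene.phasing.lhat((1,))
    assert c1 == pytest.approx(10 / (40 * lh), rel=1e-6)


def test_solver_objective_matches_enumeration_oracle():
    for seed in (3, 5, 9):
        cfg = SimConfig(
            n_internal_vertices=5,
            edge_density=0.5,
            n_transcripts=3,
            n_fragments=500,
            exon_length_range=(30, 120),
            fld_spec=("normal", 150.0, 40.0, 20, 300),
            seed=seed,
        )
        g, qts, D, frags = random_instance(cfg)
        P = build_phasing_set(g, D, frags)
        gene = Gene.build(g, P)
        fl = solve_single_gene(gene, P.counts, mass=1.0)
        _, ll_oracle = oracle_quantify(g, enumerate_st_paths(g, 64), frags, D)
        # the solver objective omits the constant per-fragment affinity terms
        aff_const = sum(np.log(f.mappings[0].affinity) for f in frags)
        assert fl.diagnostics["objective"] == pytest.approx(
            ll_oracle - aff_const, rel=1e-6
        ), seed


def test_counted_path_needs_positive_eff_len(chain_graph, point_fld):
    P = build_phasing_set(chain_graph, point_fld)
    gene = Gene.build(chain_graph, P)
    w = np.zeros(len(P))
    w[P.index[(1, 2)]] = 1.0
    lh = P.eff_lengths.copy()
    lh[P.index[(1, 2)]] = 0.0
    with pytest.raises(InferenceError):
        solve_single_gene(gene, w, lhat=lh, mass=1.0)


# ---------------------------------------------------------------------------
# E-step


def test_e_step_unique_mapping_is_one():
    g, D, gene = _diamond_gene()
    c = {gene.gene_id: np.ones(len(gene.phasing))}
    frag = _uniq((1,), gene_id=gene.gene_id)[0]
    z = e_step(c, [gene], [frag])
    assert z[frag.fragment_id] == [(gene.gene_id, (1,), 1.0)]


def test_e_step_ratio_and_symmetry():
    g, D, gene = _diamond_gene()
    i1, i2 = gene.phasing.index[(1,)], gene.phasing.index[(2,)]
    c = np.zeros(len(gene.phasing))
    c[i1], c[i2] = 1.0, 3.0
    frag = FragmentRecord(
        "m",
        [
            FragmentMapping(path=(1,), start_offset=0, frag_len=2, affinity=1.0),
            FragmentMapping(path=(2,), start_offset=0, frag_len=2, affinity=1.0),
        ],
    )
    z = e_step({gene.gene_id: c}, [gene], [frag])["m"]
    assert dict(((g_, p), v) for g_, p, v in z) == pytest.approx(
        {(gene.gene_id, (1,)): 0.25, (gene.gene_id, (2,)): 0.75}
    )
    # symmetric abundances, equal affinities -> 1/k each
    c[i1] = c[i2] = 1.0
    z = e_step({gene.gene_id: c}, [gene], [frag])["m"]
    assert all(v == pytest.approx(0.5) for _, _, v in z)


def test_e_step_zero_denominator_names_fragment():
    g, D, gene = _diamond_gene()
    c = {gene.gene_id: np.zeros(len(gene.phasing))}
    frag = _uniq((1,), gene_id=gene.gene_id, prefix="dead")[0]
    with pytest.raises(InferenceError, match="dead0"):
        e_step(c, [gene], [frag])


# ---------------------------------------------------------------------------
# M-step


def test_gene_abundance_proportional_to_read_count():
    _, _, gene_a = _diamond_gene("gA")
    _, _, gene_b = _diamond_gene("gB")
    counts = {
        "gA": np.array([20.0, 10.0, 0.0])[: len(gene_a.phasing)],
        "gB": np.array([50.0, 20.0, 0.0])[: len(gene_b.phasing)],
    }
    # make totals 30 and 70
    counts["gA"] = np.zeros(len(gene_a.phasing))
    counts["gA"][gene_a.phasing.index[(1,)]] = 30.0
    counts["gB"] = np.zeros(len(gene_b.phasing))
    counts["gB"][gene_b.phasing.index[(2,)]] = 70.0
    flows, c_gene = m_step([gene_a, gene_b], counts, n_fragments=100)
    assert c_gene == pytest.approx({"gA": 0.3, "gB": 0.7})
    # per-gene normalization mass equals s_g / |F|
    for gene, cg in ((gene_a, 0.3), (gene_b, 0.7)):
        c = [path_abundance(flows[gene.gene_id], p) for p in gene.phasing.paths]
        assert gene.phasing.normalization(c) == pytest.approx(cg, rel=1e-9)


def test_zero_count_gene_gets_zero_flow():
    _, _, gene_a = _diamond_gene("gA")
    _, _, gene_b = _diamond_gene("gB")
    counts = {
        "gA": np.zeros(len(gene_a.phasing)),
        "gB": np.zeros(len(gene_b.phasing)),
    }
    counts["gB"][0] = 10.0
    flows, c_gene = m_step([gene_a, gene_b], counts, n_fragments=10)
    assert c_gene["gA"] == 0.0
    assert np.all(flows["gA"].edge_weights == 0)


# ---------------------------------------------------------------------------
# run_em


def test_run_em_unique_mappings_converges_immediately():
    g, D, gene = _diamond_gene()
    frags = _uniq((1,), n=3) + _uniq((2,), n=1, prefix="g")
    state = run_em(gene, frags)
    # E-step is the identity without multimapping: one M-step suffices
    assert len(state.loglik_trace) <= 3
    assert state.c_gene[gene.gene_id] == pytest.approx(1.0)


def test_run_em_symmetric_multimapping_stays_symmetric():
    g, D, gene = _diamond_gene()
    frag = FragmentRecord(
        "m",
        [
            FragmentMapping(path=(1,), start_offset=0, frag_len=2, affinity=1.0),
            FragmentMapping(path=(2,), start_offset=0, frag_len=2, affinity=1.0),
        ],
    )
    state = run_em(gene, [frag])
    c1 = state.abundance(gene.gene_id, (1,))
    c2 = state.abundance(gene.gene_id, (2,))
    assert c1 == pytest.approx(c2, rel=1e-9)


def test_run_em_trace_monotone_and_normalized():
    cfg = SimConfig(
        n_internal_vertices=6,
        edge_density=0.5,
        n_transcripts=4,
        n_fragments=1500,
        exon_length_range=(30, 120),
        fld_spec=("normal", 150.0, 40.0, 20, 300),
        multimap_rate=0.4,
        seed=11,
    )
    g, qts, D, frags = random_instance(cfg)
    P = build_phasing_set(g, D, frags)
    gene = Gene.build(g, P)
    state = run_em(gene, frags)
    trace = state.loglik_trace
    assert len(trace) >= 2
    for a, b in zip(trace, trace[1:]):
        assert b >= a - 1e-9 * (1.0 + abs(a))
    assert sum(state.c_gene.values()) == pytest.approx(1.0)
    # per-fragment responsibilities normalize
    for _, _, z in state.z_groups:
        assert z.sum() == pytest.approx(1.0)


def test_decoupled_m_step_matches_joint_solve():
    """Two genes solved independently equal a joint enumeration solve."""
    cfg_a = SimConfig(
        n_internal_vertices=4, edge_density=0.6, n_transcripts=2,
        n_fragments=400, exon_length_range=(30, 100),
        fld_spec=("normal", 120.0, 30.0, 20, 240), seed=21,
    )
    cfg_b = SimConfig(
        n_internal_vertices=3, edge_density=0.6, n_transcripts=2,
        n_fragments=600, exon_length_range=(30, 100),
        fld_spec=("normal", 120.0, 30.0, 20, 240), seed=22,
    )
    g_a, qts_a, D, frags_a = random_instance(cfg_a)
    g_b, qts_b, _, frags_b = random_instance(cfg_b)
    # make gene ids distinct and merge the two fragment pools
    frags = []
    for i, f in enumerate(frags_a + frags_b):
        frags.append(FragmentRecord(f"j{i}", f.mappings))
    P_a = build_phasing_set(g_a, D, frags_a)
    P_b = build_phasing_set(g_b, D, frags_b)
    genes = [Gene.build(g_a, P_a), Gene.build(g_b, P_b)]
    state = run_em(genes, frags)

    # joint oracle: one EM over the union of enumerated transcripts
    import graphquant.simulate as sim

    paths_a = enumerate_st_paths(g_a, 64)
    paths_b = enumerate_st_paths(g_b, 64)
    # emulate the joint solve by evaluating the combined likelihood
    from graphquant.effective_length import transcript_eff_len
    from graphquant.splice_graph import is_subpath

    def joint_oracle():
        paths = [("a", p) for p in paths_a] + [("b", p) for p in paths_b]
        graphs = {"a": g_a, "b": g_b}
        lhat = np.array(
            [transcript_eff_len(D, graphs[s].path_length(p)) for s, p in paths]
        )
        sigs = {}
        for f in frags:
            key = tuple(sorted((m.gene_id, tuple(m.path), m.affinity) for m in f.mappings))
            sigs[key] = sigs.get(key, 0) + 1
        B = np.zeros((len(sigs), len(paths)))
        tags = {g_a.gene_id: "a", g_b.gene_id: "b"}
        for r, key in enumerate(sigs):
            for gid, p, aff in key:
                for i, (s, t) in enumerate(paths):
                    if s == tags[gid] and is_subpath(t, p):
                        B[r, i] += aff
        w = np.array(list(sigs.values()), dtype=float)
        c = np.ones(len(paths)) / lhat
        c /= c @ lhat
        prev = -np.inf
        for _ in range(100_000):
            like = B @ c
            ll = float(w @ np.log(like))
            if ll - prev <= 1e-13 * (1 + abs(ll)) and prev > -np.inf:
                break
            prev = ll
            c = c * (B.T @ (w / like)) / w.sum() / lhat
            c /= c @ lhat
        return ll

    ll_joint = joint_oracle()
    assert state.loglik_trace[-1] == pytest.approx(ll_joint, rel=1e-6)


def test_run_em_matches_oracle_end_to_end():
    for seed in (31, 32):
        cfg = SimConfig(
            n_internal_vertices=6, edge_density=0.5, n_transcripts=4,
            n_fragments=2000, exon_length_range=(30, 120),
            fld_spec=("normal", 150.0, 40.0, 20, 300),
            multimap_rate=0.3, seed=seed,
        )
        g, qts, D, frags = random_instance(cfg)
        if count_st_paths(g) > 64:
            continue
        P = build_phasing_set(g, D, frags)
        state = run_em(Gene.build(g, P), frags)
        _, ll_oracle = oracle_quantify(g, enumerate_st_paths(g, 64), frags, D)
        assert state.loglik_trace[-1] == pytest.approx(ll_oracle, rel=1e-6)


def test_run_em_requires_fragments():
    g, D, gene = _diamond_gene()
    with pytest.raises(InferenceError):
        run_em(gene, [])
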