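"""Shared fixtures: tiny hand-built graphs and random-instance helpers."""

import numpy as np
import pytest

from graphquant import (
    FragLenDist,
    build_phasing_set,
    splice_graph_from_lengths,
)
from graphquant.simulate import SimConfig, make_fld, random_splice_graph


@pytest.fixture
def chain_graph():
    """S -> a -> b -> T with exon lengths 5 and 3 (ids 1 and 2)."""
    return splice_graph_from_lengths([5, 3], [(1, 2)], gene_id="chain")


@pytest.fixture
def diamond_graph():
    """S -> {a, b} -> T: two parallel single-exon transcripts."""
    return splice_graph_from_lengths([4, 6], [], gene_id="diamond")


@pytest.fixture
def diamond_chord_graph():
    """e1 -> e2 -> e3 with chord e1 -> e3 (junction-only S/T closure)."""
    return splice_graph_from_lengths(
        [5, 4, 6], [(1, 2), (1, 3), (2, 3)], gene_id="chord"
    )


@pytest.fixture
def point_fld():
    """All fragments have length exactly 2."""
    return FragLenDist.from_pmf({2: 1.0})


def small_random_setup(seed, n_lo=2, n_hi=9, fld=("normal", 90.0, 30.0, 10, 200)):
    """A random splice graph + FLD + phasing set, sized for exhaustive checks."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        n_internal_vertices=int(rng.integers(n_lo, n_hi)),
        edge_density=float(rng.uniform(0.2, 0.9)),
        exon_length_range=(20, 80),
        fld_spec=fld,
        seed=seed,
    )
    g = random_splice_graph(cfg, rng)
    D = make_fld(cfg)
    P = build_phasing_set(g, D)
    return g, D, P
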