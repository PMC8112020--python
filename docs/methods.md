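# Methods

## The model

`graphquant` performs *graph quantification*: instead of estimating the
abundances of a fixed list of transcripts, it treats every source-to-sink
(S-T) path of a gene's splice graph as a potential transcript and infers
the abundance structure that the sequencing data can actually determine.

The starting point is the standard generative model of RNA-seq
quantification.  With transcripts T_i of length l_i and abundances c_i, a
fragment is generated by sampling a transcript with probability
proportional to c_i·l̂_i and then a window (j, k) inside it with weight
A(j, k) — equal to D(k−j+1), the fragment-length probability, in the
unbiased case.  The transcript *effective length* is the total window
weight l̂_i = Σ_{j≤k} D(k−j+1) = Σ_t D(t)(l_i+1−t); the package exposes
both this window-sum form and the classical (Σ_{t≤l} D(t))·(l+1−μ) form and
tests their identity.

Every fragment's alignment spans a chain of exons — its *phasing path*
(singleton chains included).  Grouping the likelihood by phasing path
rather than by transcript yields a reparameterization in terms of **path
abundances** c_p = Σ_{i: p ⊂ T_i} c_i and **path effective lengths** l̂_p
(the total affinity of windows spanning exactly p):

    L(c) ∝ Π_f  c_{p(f)} / ( Σ_{p∈𝒫} c_p l̂_p ),

with c_{p(f)} replaced by Σ_{p∈M(f)} c_p·A(f|p) for multimapped fragments.
The set 𝒫 contains every path with l̂_p > 0 (plus all singletons).  The
maximum of this objective equals the maximum of the transcript-space
objective over all compatible transcripts — the equivalence the test suite
and the acceptance script verify numerically on hundreds of random
instances.

## Prefix graphs

The c_p are not free parameters: they must be consistent with *some*
nonnegative transcript mixture.  The package encodes that feasible set as
network flows on an Aho-Corasick rollout of the splice graph.  Matching
phasing paths in a transcript is multi-pattern matching (alphabet = splice
graph vertices, patterns = 𝒫, text = the transcript), and the Aho-Corasick
automaton — with transitions restricted to splice-graph successors — turns
into two graphs:

* **prefix graph**: automaton states are vertices, transitions edges;
  p is recognized at the vertices whose state label ends with p;
* **compact prefix graph**: vertices are the singletons plus the strict
  prefixes of 𝒫; transitions become *labeled* edges and recognition moves
  to edges: AS(p) = {e : p is a suffix of the edge label t(e)}.

S-T paths correspond one-to-one to [S]-[T] paths in either rollout, and a
lifted transcript meets AS(p) exactly once iff it contains p.  Hence a
flow f carries every path abundance as the linear sum c_p = Σ_{AS(p)} f,
and flow decomposition maps any balanced flow back to a quantified
transcript set with the same c_p.

Two construction details differ deliberately from the most literal reading
of the definitions:

* Recognition on compact-graph edges uses the direction "p is a suffix of
  t(e)".  The compact walk state is provably the longest suffix of the
  read text present in the vertex set, which makes this rule exact; the
  package enforces it operationally through an exhaustive recognition
  invariant test (`|lift(τ) ∩ AS(p)| = 1(p ⊂ τ)` over all S-T paths of
  small graphs), which is the authoritative contract.
* Vertices unreachable from [S] (state labels whose occurrences are always
  absorbed into longer states) are pruned from both rollouts.  They can
  never carry flow; pruning keeps the invariant that every vertex lies on
  an [S]-[T] path.

When 𝒫 is prefix-closed and every splice-graph vertex has out-degree ≤ 2,
the linear map from balanced compact-graph flows to {c_p} is injective
(*minimal sufficiency*); the package checks this by a rank computation on
the stacked recognition/balance matrix.  Note that the 𝒫 produced by
`build_phasing_set` is prefix-closed by construction, because a prefix of
a realizable path is realizable by a shorter fragment.

## Inference

The single-gene problem is the concave program

    max Σ_p w_p log c_p   s.t.  c_p = Σ_{AS(p)} f_e,  flow balance,
                                f ≥ 0,  Σ_p c_p l̂_p = mass.

Because every balanced flow is a nonnegative combination of [S]-[T] paths
π, and each π contributes 1(p⊂π) to c_p and Σ_{e∈π} h_e to the
normalization (h_e aggregates the l̂_p recognized at e), the program is
solved by **column generation**:

1. keep a working set of [S]-[T] paths (initially one path through each
   counted phasing path's recognition set);
2. run the classical quantification EM restricted to those columns to
   convergence (relative log-likelihood change < 1e-13);
3. search the rollout for the best-ratio path
   max_π (Σ_{e∈π} γ_e)/(Σ_{e∈π} h_e), γ_e = Σ_{p: e∈AS(p)} w_p/c_p,
   by Dinkelbach iterations of a longest-path DP over the topological
   order (ties broken by edge id, so runs are deterministic);
4. the KKT condition of the full program is exactly
   max-ratio ≤ (Σ_p w_p)/mass; if violated, add the path as a new column
   and repeat.  The residual `mass·max-ratio − W` bounds the remaining
   objective gap; the solver stops at 1e-9·W.

All quantities in steps 2-4 are edge sums on the rollout; the set of all
S-T paths is never enumerated.  The working set is typically a handful of
columns — at most a few dozen on the random instances exercised here.

Multimapped fragments are handled by the outer EM: a global E-step
z_{f,p} = c_p A(f|p)/Σ_{p'∈M(f)} c_{p'}A(f|p'), then a gene-level M-step
that solves each gene independently with counts Σ_f z_{f,p} and
normalization mass s_g/|F|, which also fixes the gene abundances
c_g = s_g/|F| (so Σ_g c_g = 1).  Because the M-step solves each gene to
its global optimum, the log-likelihood trace is monotone; a violation
beyond 1e-9 (relative) raises an error rather than being silently
accepted.  Fragments with identical mapping signatures are grouped, so the
E-step cost scales with the number of distinct signatures, not |F|.

Initialization is deterministic (equal-split routing flow per gene, scaled
to the normalization), so identical inputs give identical outputs without
seeds.  Convergence: relative log-likelihood change < 1e-9 or 1000
iterations (both configurable).  Zero-count paths stay in the
normalization term; their abundances may legitimately reach 0.

The `loglik` value reported by the solver and EM driver omits the
per-fragment constant Σ_f log A(f|p(f)) for uniquely mapped fragments; the
multimapping objective keeps all affinity terms inside the per-fragment
logs.  Comparisons against the enumeration oracle use identical
conventions on both sides.

## Effective lengths and bias

Path effective lengths are computed in closed form in the unbiased model:
for a singleton of length L, l̂ = Σ_t D(t)(L+1−t); for a multi-exon path
with terminal exon lengths L₁, L_m and interior length M₀,
l̂ = Σ_{a≤L₁, b≤L_m} D(a+M₀+b).  Both are independent of the embedding
transcript, which the tests assert on graphs with two distinct embeddings.

The positional-bias affinity averages a per-transcript bias
B_i(j,k) = D(k−j+1)·β_i(bin of the window midpoint) over the reference
transcripts containing the path, weighted by reference abundances —
with β piecewise-constant over five relative-position bins.  The package
supports both the consistent mode (the same affinity in effective lengths
and fragment likelihoods) and a "two affinities" shortcut (unbiased l̂,
biased likelihoods); exactness of the equivalence requires the consistent
mode, and the defaults use it.  GC- or sequence-motif bias models are out
of scope; the affinity interface is the hook for them.

Trimming 𝒫 removes multi-exon paths with no mapped fragments and
l̂_p below a threshold (default: the pmf value at the 99.5th percentile of
D, targeting paths realizable only through the distribution's long tail).
Trimmed mass is *not* re-added to the normalization; the induced
underestimate is negligible exactly because the removed paths have tiny
l̂_p and no support.  Trimming is off in every equivalence test, since the
equivalence is exact only for the untrimmed 𝒫.

## Synthetic data

The generator draws forward DAGs over exons (edges only from lower to
higher index, so a topological order exists by construction; S feeds every
in-degree-0 exon and T drains every out-degree-0 exon), ground-truth
transcripts as distinct random S-T paths with Dirichlet(α=1) abundances,
and fragments exactly from the generative model above.  Defaults mirror a
typical paired-end short-read library: fragment lengths discretized
normal(350, 70) truncated to [50, 600], sub-exon lengths uniform on
[50, 300] — sub-exons of a few tens to a few hundred bases are the regime
in which fragments span several exons and phasing matters.  When an
out-degree cap is requested (for identifiability fixtures), the generator
switches to a degree-capped construction in which every exon beyond the
first receives a parent with spare capacity, so S keeps out-degree 1.

Within-gene multimapping is injected structurally: a fragment whose
anchors admit several connecting exon chains reports one mapping per
chain whose implied length has positive probability under D.  No
sequence-level read simulation, error model, or cross-gene sequence
homology is emulated — so passing tests demonstrate correctness of the
model, the graph algebra and the optimizer under the model's own
assumptions, not robustness to alignment artifacts, positional bias
mis-specification, or annotation errors in real data.

The transcript-enumeration oracle (`oracle_quantify`) is an independent
implementation of the classical quantification EM over an explicitly
enumerated transcript set; it shares no code path with the flow solver and
serves as the reference in every equivalence check.

## Numerical choices

* Flow balance tolerance: relative 1e-9 (absolute 1e-15); decomposition
  clips residuals below 1e-12 of the total and uses greedy widest paths
  (deterministic tie-breaks), producing at most |E| components.
* PSI from a flow uses the canonical greedy decomposition.  Different
  decompositions of the same flow can yield different PSI when the
  discriminating phasing paths are not in 𝒫; `psi_bounds` quantifies that
  non-identifiability exactly with two small LPs (Charnes-Cooper transform
  over a flag-expanded rollout).  PSI with zero flanking abundance is NaN
  with a warning.
* Rank computations (minimal sufficiency) use `numpy.linalg.matrix_rank`
  with its default SVD threshold; instances are small and far from
  borderline.
* The restricted EM and the oracle EM stop on relative log-likelihood
  change < 1e-13; the outer EM on < 1e-9.

## Problem sizes

The validation harness (`tests/test_acceptance.py`,
`scripts/acceptance.py`) exercises: 200 random genes with ≤ 8 internal
exons, ≤ 64 S-T paths and 10³–10⁴ fragments for the equivalence check;
1000 random (D, l) pairs for the effective-length identity; 100 fixtures
each for the round-trip, bijection and minimal-sufficiency checks; a
two-gene multimapping instance for the EM mechanics; three identifiable
fixtures with 10⁵ fragments for parameter recovery; and 50 fixtures for
the size trends.  These sizes give tight, reproducible checks in a few
minutes on one core; all randomness flows through a single seeded
generator.

## Known limitations

* Exon chains are assumed disjoint; overlapping annotation must be split
  into sub-exons upstream (no automatic splitting).
* Fragment ingestion expects phasing-path records or aligned block
  coordinates; BAM/SAM parsing is out of scope (`fragment_to_path`
  documents the expected block extraction).
* The rollout size grows with the length of phasing paths; for
  transcript-length reads the prefix graph approaches the full transcript
  enumeration and loses its advantage.
* Flow non-identifiability is intrinsic: many transcript mixtures induce
  the same flow.  Everything reported at the path-abundance level is
  exact; transcript-level outputs (decompositions, PSI from flows) are one
  canonical representative, with bounds available where it matters.
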