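"""Fragment-length distributions, affinities and effective lengths.

The generative model samples a transcript proportional to abundance times
*effective length* and then a fragment window (j, k) with weight given by an
*affinity* A_p(j, k) — D(k-j+1) in the unbiased case.  The transcript
effective length is the total window weight

    l_hat_i = sum_{1<=j<=k<=l_i} D(k-j+1) = sum_t D(t) (l_i + 1 - t),

which coincides (up to the factor ``sum_{t<=l} D(t)``) with the classical
``l - mu`` form.  The *path* effective length generalizes this to splice
graph paths: the total affinity of windows whose exon span is exactly the
path.  Both quantities drive the normalization term of the likelihood.

Window coordinates (j, k) are 1-based inclusive on the concatenated exon
sequence of the path (or transcript) under consideration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .splice_graph import GraphError, GraphPath, SpliceGraph, is_subpath

__all__ = [
    "FragLenDist",
    "empirical_fld",
    "transcript_eff_len",
    "classical_transcript_eff_len",
    "path_eff_len",
    "AffinityModel",
    "NoBiasAffinity",
    "PositionalBiasAffinity",
    "ReferenceBias",
    "positional_affinity",
]


@dataclass
class FragLenDist:
    """Discrete fragment-length distribution D(l) on 1..max_len."""

    pmf: np.ndarray  # pmf[t] = D(t); pmf[0] unused (0.0)

    def __post_init__(self) -> None:
        self.pmf = np.asarray(self.pmf, dtype=float)
        if self.pmf.ndim != 1 or len(self.pmf) < 2:
            raise ValueError("pmf must be a 1-d array indexed by length")
        if np.any(self.pmf < 0):
            raise ValueError("pmf has negative entries")
        self.pmf = self.pmf.copy()
        self.pmf[0] = 0.0
        total = self.pmf.sum()
        if total <= 0:
            raise ValueError("pmf sums to zero")
        if abs(total - 1.0) > 1e-12:
            self.pmf /= total

    @classmethod
    def from_pmf(cls, d: dict[int, float]) -> "FragLenDist":
        m = max(d)
        pmf = np.zeros(m + 1)
        for length, prob in d.items():
            if length < 1:
                raise ValueError("fragment lengths must be >= 1")
            pmf[length] = prob
        return cls(pmf)

    @classmethod
    def discretized_normal(
        cls, mean: float, sd: float, lo: int, hi: int
    ) -> "FragLenDist":
        """Normal(mean, sd) discretized on integers and truncated to [lo, hi]."""
        if not (1 <= lo <= hi):
            raise ValueError("need 1 <= lo <= hi")
        t = np.arange(lo, hi + 1)
        w = stats.norm.cdf(t + 0.5, mean, sd) - stats.norm.cdf(t - 0.5, mean, sd)
        pmf = np.zeros(hi + 1)
        pmf[lo : hi + 1] = w
        return cls(pmf)

    # -- queries -----------------------------------------------------------
    @property
    def max_len(self) -> int:
        return int(np.max(np.nonzero(self.pmf)[0]))

    def d(self, length: int | np.ndarray) -> float | np.ndarray:
        """D(length); zero outside the support."""
        arr = np.asarray(length)
        out = np.where(
            (arr >= 1) & (arr < len(self.pmf)), self.pmf[np.clip(arr, 0, len(self.pmf) - 1)], 0.0
        )
        return float(out) if np.isscalar(length) else out

    def cdf(self, length: int) -> float:
        length = min(int(length), len(self.pmf) - 1)
        return float(self.pmf[: length + 1].sum()) if length >= 1 else 0.0

    def mean(self) -> float:
        t = np.arange(len(self.pmf))
        return float((t * self.pmf).sum())

    def truncated_mean(self, l: int) -> float:
        """Mean of D restricted to lengths <= l."""
        hi = min(int(l), len(self.pmf) - 1)
        mass = self.pmf[: hi + 1].sum()
        if mass == 0:
            return 0.0
        t = np.arange(hi + 1)
        return float((t * self.pmf[: hi + 1]).sum() / mass)

    def percentile(self, q: float) -> int:
        """Smallest length with CDF >= q."""
        c = np.cumsum(self.pmf)
        return int(np.searchsorted(c, q * c[-1]))

    def to_dict(self) -> dict[int, float]:
        return {int(t): float(p) for t, p in enumerate(self.pmf) if p > 0}


def empirical_fld(
    lengths: Sequence[int], smoothing: float | None = None
) -> FragLenDist:
    """Normalized histogram of observed fragment lengths.

    ``smoothing`` is an optional Gaussian kernel bandwidth (in bases).
    """
    arr = np.asarray(lengths, dtype=int)
    if arr.size == 0:
        raise ValueError("no fragment lengths supplied")
    if np.any(arr < 1):
        raise ValueError("fragment lengths must be >= 1")
    m = int(arr.max())
    pmf = np.bincount(arr, minlength=m + 1).astype(float)
    pmf[0] = 0.0
    if smoothing is not None and smoothing > 0:
        halfwidth = int(np.ceil(4 * smoothing))
        x = np.arange(-halfwidth, halfwidth + 1)
        kernel = np.exp(-0.5 * (x / smoothing) ** 2)
        kernel /= kernel.sum()
        # mass smoothed below length 1 is dropped; the constructor renormalizes
        pmf = np.convolve(pmf, kernel, mode="full")[halfwidth:]
        pmf[0] = 0.0
    return FragLenDist(pmf)


# ---------------------------------------------------------------------------
# effective lengths


def transcript_eff_len(D: FragLenDist, l: int) -> float:
    """Window-sum effective length: sum_t D(t) (l + 1 - t) for t <= l."""
    if l < 1:
        raise ValueError("transcript length must be >= 1")
    hi = min(int(l), len(D.pmf) - 1)
    t = np.arange(1, hi + 1)
    return float((D.pmf[1 : hi + 1] * (l + 1 - t)).sum())


def classical_transcript_eff_len(D: FragLenDist, l: int) -> float:
    """Classical form ``(sum_{t<=l} D(t)) * (l + 1 - truncated_mean)``."""
    if l < 1:
        raise ValueError("transcript length must be >= 1")
    return D.cdf(l) * (l + 1 - D.truncated_mean(l))


class AffinityModel:
    """Unnormalized fragment-generation likelihood A_p(j, k).

    ``evaluate`` takes a splice-graph path and 1-based inclusive window
    coordinates on the path's concatenated exon sequence.
    """

    mode = "abstract"

    def evaluate(self, p: GraphPath, j: int, k: int) -> float:  # pragma: no cover
        raise NotImplementedError

    def evaluate_many(
        self, p: GraphPath, j: np.ndarray, k: np.ndarray
    ) -> np.ndarray:
        return np.array([self.evaluate(p, jj, kk) for jj, kk in zip(j, k)])


@dataclass
class NoBiasAffinity(AffinityModel):
    """A_p(j, k) = D(k - j + 1): fragment likelihood from length only."""

    D: FragLenDist
    mode: str = field(default="no_bias", init=False)

    def evaluate(self, p: GraphPath, j: int, k: int) -> float:
        return float(self.D.d(k - j + 1))

    def evaluate_many(self, p: GraphPath, j: np.ndarray, k: np.ndarray) -> np.ndarray:
        return self.D.d(np.asarray(k) - np.asarray(j) + 1)


@dataclass
class ReferenceBias:
    """Positional bias learned over a reference transcriptome.

    Per-transcript bias ``B_i(j, k)`` is D(k-j+1) multiplied by a
    piecewise-constant factor over ``n_bins`` relative-position bins of the
    fragment midpoint, weighted across reference transcripts by their
    abundances ``r_hat``.
    """

    graph: SpliceGraph
    transcripts: list[GraphPath]  # exon chains (no S/T)
    r_hat: np.ndarray
    D: FragLenDist
    bin_weights: np.ndarray  # shape (n_transcripts, n_bins)

    def __post_init__(self) -> None:
        self.r_hat = np.asarray(self.r_hat, dtype=float)
        self.bin_weights = np.asarray(self.bin_weights, dtype=float)
        if np.any(self.r_hat < 0):
            raise ValueError("reference abundances must be nonnegative")
        if self.bin_weights.shape[0] != len(self.transcripts):
            raise ValueError("bin_weights rows must match transcripts")
        self._lengths = [self.graph.path_length(t) for t in self.transcripts]

    @property
    def n_bins(self) -> int:
        return self.bin_weights.shape[1]

    def bias(self, i: int, j: int, k: int) -> float:
        """B_i(j, k) on transcript coordinates (1-based inclusive)."""
        li = self._lengths[i]
        mid = 0.5 * (j + k)
        b = min(int(self.n_bins * (mid - 0.5) / li), self.n_bins - 1)
        return float(self.D.d(k - j + 1) * self.bin_weights[i, b])


def _locate_subpath(chain: Sequence[int], p: Sequence[int]) -> int | None:
    """Start index of contiguous occurrence of p in chain, else None."""
    p = tuple(p)
    chain = tuple(chain)
    for i in range(len(chain) - len(p) + 1):
        if chain[i : i + len(p)] == p:
            return i
    return None


def positional_affinity(bias: ReferenceBias, p: GraphPath, j: int, k: int) -> float:
    """Abundance-weighted positional bias A_p(j, k).

    Averages ``B_i`` at the translated coordinates (j', k') over every
    reference transcript containing ``p``, weighted by reference abundance.
    """
    num = 0.0
    den = 0.0
    found = False
    for i, chain in enumerate(bias.transcripts):
        at = _locate_subpath(chain, p)
        if at is None:
            continue
        found = True
        offset = sum(bias.graph.length(v) for v in chain[:at])
        num += bias.r_hat[i] * bias.bias(i, j + offset, k + offset)
        den += bias.r_hat[i]
    if not found or den == 0:
        raise ValueError(
            f"no reference transcript with positive abundance contains {p}; "
            "fall back to the no_bias affinity model"
        )
    return num / den


@dataclass
class PositionalBiasAffinity(AffinityModel):
    """Affinity model backed by :func:`positional_affinity`."""

    bias: ReferenceBias
    mode: str = field(default="positional", init=False)

    def evaluate(self, p: GraphPath, j: int, k: int) -> float:
        return positional_affinity(self.bias, p, j, k)


def path_eff_len(
    g: SpliceGraph, p: GraphPath, aff: AffinityModel | FragLenDist
) -> float:
    """Path effective length l_hat_p: total affinity of windows spanning exactly p.

    A window (j, k) on an embedding transcript spans exactly ``p`` when its
    first base falls in p's first exon, its last base in p's last exon, and
    it covers every interior exon.  The result is independent of the chosen
    embedding in the no-bias model; coordinates are path-local, so the same
    holds for any affinity defined on path coordinates.
    """
    if isinstance(aff, FragLenDist):
        aff = NoBiasAffinity(aff)
    p = g.validate_path(p)
    if any(g.vertex(v).kind != "exon" for v in p):
        raise GraphError(f"phasing path {p} must contain exons only")
    lens = [g.length(v) for v in p]
    if len(p) == 1:
        L = lens[0]
        if isinstance(aff, NoBiasAffinity):  # closed form
            return transcript_eff_len(aff.D, L)
        j, k = np.triu_indices(L)
        return float(aff.evaluate_many(p, j + 1, k + 1).sum())
    first, mid, last = lens[0], sum(lens[1:-1]), lens[-1]
    # window: a bases into the first exon, b bases into the last exon
    a = np.repeat(np.arange(1, first + 1), last)
    b = np.tile(np.arange(1, last + 1), first)
    j = first - a + 1
    k = first + mid + b
    return float(aff.evaluate_many(p, j, k).sum())
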