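"""Intersection matrix and per-entry cumulative probabilities.

The intersection matrix ``I`` holds, for every pair of time bins, the number
of neurons active in both bins, ``I_ij = |S_i n S_j|``.  Under the null
hypothesis of independent (marginally Poisson) spike trains with known rate
profiles, ``I_ij`` is a Poisson-binomial sum of per-neuron Bernoulli
indicators with success probabilities

    p_ij^(k) = (1 - exp(-lambda_i^(k) Delta)) * (1 - exp(-lambda_j^(k) Delta)).

Each observed count is mapped to its cumulative probability
``P_ij = Pr(I < I_ij)`` (strict inequality, so that ``1 - P_ij`` is a valid
p-value), either exactly via iterative convolution of the Bernoulli pmfs or
through the Le Cam Poisson approximation with rate ``sum_k p_ij^(k)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rates import RateProfiles
from .spikedata import BinnedSpikes

__all__ = [
    "IntersectionMatrix",
    "ProbabilityMatrix",
    "intersection_matrix",
    "pair_probability",
    "poisson_binomial_pmf",
    "lecam_pmf",
    "probability_matrix",
]

EXACT_MAX_NEURONS = 30  # 'auto' switches to Le Cam above this


@dataclass
class IntersectionMatrix:
    """Bin-by-bin overlap counts.

    In symmetric mode (both axes from the same data segment) the matrix is
    symmetric and its main diagonal is the population histogram; only the
    strict upper triangle carries non-redundant information.
    """

    counts: np.ndarray
    mode: str  # 'symmetric' | 'cross'

    def __post_init__(self):
        self.counts = np.asarray(self.counts, int)
        if self.mode not in ("symmetric", "cross"):
            raise ValueError("mode must be 'symmetric' or 'cross'")

    @property
    def shape(self):
        return self.counts.shape


@dataclass
class ProbabilityMatrix:
    """Cumulative probabilities ``P_ij = Pr(I < I_ij)`` in [0, 1).

    In symmetric mode only the strict upper triangle is populated (the rest
    is zero).  ``lecam_rate`` holds the per-entry Poisson rate when the Le Cam
    approximation was used.
    """

    probs: np.ndarray
    method: str  # 'exact' | 'lecam'
    mode: str
    lecam_rate: np.ndarray | None = None

    @property
    def shape(self):
        return self.probs.shape


def intersection_matrix(
    binned_x: BinnedSpikes, binned_y: BinnedSpikes | None = None
) -> IntersectionMatrix:
    """Exact set-intersection counts between all bin pairs.

    With one argument the matrix is symmetric (``I_ii`` = population
    histogram); with two arguments (e.g. two segments of a recording, same
    neurons) a rectangular cross matrix is produced.
    """
    occ_x = binned_x.occupancy
    if binned_y is None:
        counts = occ_x.astype(np.int32).T @ occ_x.astype(np.int32)
        return IntersectionMatrix(counts=counts, mode="symmetric")
    if binned_y.n_neurons != binned_x.n_neurons:
        raise ValueError("both axes must hold the same neuron set")
    counts = occ_x.astype(np.int32).T @ binned_y.occupancy.astype(np.int32)
    return IntersectionMatrix(counts=counts, mode="cross")


def firing_probabilities(rates: np.ndarray, bin_width: float) -> np.ndarray:
    """Per-neuron, per-bin probability of >= 1 spike: ``1 - exp(-lambda Delta)``."""
    rates = np.asarray(rates, float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    return -np.expm1(-rates * bin_width)


def pair_probability(rate_i, rate_j, bin_width: float):
    """Bernoulli parameter of one neuron being active in both bins."""
    return firing_probabilities(rate_i, bin_width) * firing_probabilities(
        rate_j, bin_width
    )


def poisson_binomial_pmf(p) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_k) variables.

    Computed by iterative convolution in O(N^2); identical to the subset-sum
    definition (which has 2^N terms) for any N.
    """
    p = np.asarray(p, float).ravel()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("Bernoulli parameters must lie in [0, 1]")
    pmf = np.array([1.0])
    for pk in p:
        pmf = np.convolve(pmf, [1.0 - pk, pk])
    return pmf


def lecam_pmf(lam: float, support) -> np.ndarray:
    """Poisson pmf with rate ``lam`` over the integer ``support``."""
    if lam < 0:
        raise ValueError("rate must be non-negative")
    return stats.poisson.pmf(np.asarray(support, int), lam)


def _upper_triangle_mask(shape, mode):
    if mode == "symmetric":
        return np.triu(np.ones(shape, bool), k=1)
    return np.ones(shape, bool)


def probability_matrix(
    imat: IntersectionMatrix,
    rates: RateProfiles,
    method: str = "auto",
) -> ProbabilityMatrix:
    """Map intersection counts to cumulative probabilities under the null.

    ``method='auto'`` uses the exact Poisson-binomial evaluation for up to
    30 neurons and the Le Cam Poisson approximation beyond.  In symmetric
    mode only the strict upper triangle is evaluated.
    """
    counts = imat.counts
    if imat.mode == "symmetric":
        b1 = b2 = rates.bins.n_bins
    else:
        b1, b2 = counts.shape
    if counts.shape != (b1, b2):
        raise ValueError("intersection matrix and rate profiles disagree on bins")
    n = rates.n_neurons
    if method == "auto":
        method = "exact" if n <= EXACT_MAX_NEURONS else "lecam"
    q = firing_probabilities(rates.rates, rates.bins.bin_width)  # N x B
    valid = _upper_triangle_mask(counts.shape, imat.mode)
    probs = np.zeros_like(counts, dtype=float)
    lam = None
    if method == "lecam":
        lam = q.T @ q  # lam_ij = sum_k p_i^(k) p_j^(k)
        with np.errstate(divide="ignore"):
            probs[valid] = stats.poisson.cdf(counts[valid] - 1, lam[valid])
    elif method == "exact":
        rows, cols = np.nonzero(valid)
        for i, j in zip(rows, cols):
            pvec = q[:, i] * q[:, j]
            pmf = poisson_binomial_pmf(pvec)
            c = counts[i, j]
            probs[i, j] = float(pmf[:c].sum()) if c > 0 else 0.0
        probs[valid] = np.clip(probs[valid], 0.0, 1.0 - 1e-15)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ProbabilityMatrix(probs=probs, method=method, mode=imat.mode, lecam_rate=lam)
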