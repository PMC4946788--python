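"""Joint significance of the largest kernel neighbors of each matrix entry.

A repeated SSE shows up as several jointly large entries of the probability
matrix aligned along a diagonal.  For each entry ``(i, j)`` a rectangular
kernel of length ``l_K`` and width ``w_K`` oriented along the 45-degree
direction selects a neighborhood of up to

    n = l_K * w_K - floor(w_K/2) * (floor(w_K/2) + 1)

positions; the ``d`` largest probability values among the neighbors are
tested jointly through the survival function of the top-``d`` order
statistics of ``n`` iid uniforms,

    Fbar(x_1..x_d) = n! * sum_{i_1=d}^{n} sum_{i_2=d-1}^{i_1} ...
                     prod_k (x*_{k+1} - x*_k)^{i_k - i_{k+1}} / (i_k - i_{k+1})!

with every value capped at ``p_max`` so that a single extreme entry cannot
carry the test by itself.  The joint probability matrix is
``J_ij = 1 - Fbar``.

The nested sum is evaluated in log space, vectorized over matrix entries: for
fixed ``(n, d)`` all admissible exponent tuples are tabulated once and the
per-entry terms are obtained by a single matrix product with the logs of the
consecutive differences of the sorted, capped values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations_with_replacement

import numpy as np
from scipy.special import gammaln

from .matrix import ProbabilityMatrix

__all__ = [
    "KernelSpec",
    "JointProbabilityMatrix",
    "diagonal_neighborhood",
    "joint_survival",
    "joint_probability_matrix",
]

_LOG_ZERO = -1.0e300  # stand-in for log(0); multiplied by exponent 0 it vanishes


@dataclass(frozen=True)
class KernelSpec:
    """Diagonal rectangular kernel and order-statistic test parameters.

    ``length`` (l_K) and ``width`` (w_K) must be odd so the kernel is
    symmetric around the tested entry; ``n_largest`` (d) neighbors are tested
    jointly; probabilities are capped at ``p_max``.
    """

    length: int = 5
    width: int = 5
    n_largest: int = 5
    p_max: float = 0.999

    def __post_init__(self):
        if self.length < 1 or self.length % 2 == 0:
            raise ValueError("kernel length must be odd and >= 1")
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError("kernel width must be odd and >= 1")
        if not 1 <= self.n_largest <= self.n_total:
            raise ValueError("n_largest must lie in [1, n_total]")
        if not 0.0 < self.p_max < 1.0:
            raise ValueError("p_max must lie in (0, 1)")

    @property
    def n_total(self) -> int:
        """Interior neighborhood size: l_K*w_K - floor(w_K/2)(floor(w_K/2)+1)."""
        h = self.width // 2
        return self.length * self.width - h * (h + 1)


@dataclass
class JointProbabilityMatrix:
    """Joint cumulative probabilities ``J_ij`` in [0, 1].

    ``evaluated`` marks the entries at which the order-statistic test was
    actually computed (the pipeline may restrict evaluation to candidate
    entries; everywhere else ``J`` is left at 0).
    """

    probs: np.ndarray
    kernel: KernelSpec
    evaluated: np.ndarray | None = None


def _kernel_offsets(kernel: KernelSpec):
    """Lattice offsets (dr, dc) of the rotated rectangle, including (0, 0).

    For each diagonal offset ``c`` in ``-w//2..w//2`` the segment holds
    ``l_K - |c|`` consecutive positions on the diagonal shifted by ``c``,
    centered on the projection of the tested entry (rounding half down).
    """
    offsets = []
    half_w = kernel.width // 2
    for c in range(-half_w, half_w + 1):
        seg = kernel.length - abs(c)
        center = -c / 2.0  # along-diagonal projection of (i, j), in row units
        start = math.floor(center - (seg - 1) / 2.0 + 0.5)
        for s in range(seg):
            dr = start + s
            offsets.append((dr, dr + c))
    return offsets


def diagonal_neighborhood(i, j, kernel: KernelSpec, shape, mode="symmetric"):
    """Kernel-covered positions around (i, j), clipped to the valid region.

    Returns the list of in-matrix positions (including ``(i, j)`` itself);
    in symmetric mode positions on or below the main diagonal are removed.
    For an interior entry the count equals ``kernel.n_total``.
    """
    b1, b2 = shape
    if not (0 <= i < b1 and 0 <= j < b2):
        raise ValueError("entry outside the matrix")
    if mode == "symmetric" and i >= j:
        raise ValueError("symmetric mode tests only the strict upper triangle")
    out = []
    for dr, dc in _kernel_offsets(kernel):
        r, c = i + dr, j + dc
        if not (0 <= r < b1 and 0 <= c < b2):
            continue
        if mode == "symmetric" and r >= c:
            continue
        out.append((r, c))
    return out


@lru_cache(maxsize=256)
def _term_table(n: int, d: int):
    """Exponent tuples and constant log-terms of the nested sum for (n, d).

    Rows enumerate admissible non-increasing index tuples ``i_1 >= ... >= i_d``
    with ``i_k >= d - k + 1`` and ``i_1 <= n``; columns hold the exponents
    ``e_k = i_k - i_{k+1}`` (``i_0 = n``, ``i_{d+1} = 0``) applied to the
    consecutive differences of the sorted values.
    """
    if d < 1 or d > n:
        raise ValueError("need 1 <= d <= n")
    rows = []
    for asc in combinations_with_replacement(range(1, n + 1), d):
        # asc is non-decreasing: asc[m-1] = i_{d+1-m}; constraint i_k >= d-k+1
        if all(a >= m for m, a in enumerate(asc, start=1)):
            i_seq = asc[::-1]  # i_1 >= i_2 >= ... >= i_d
            e = [n - i_seq[0]]
            e.extend(i_seq[k] - i_seq[k + 1] for k in range(d - 1))
            e.append(i_seq[-1])
            rows.append(e)
    expo = np.asarray(rows, float)  # T x (d+1)
    const = gammaln(n + 1) - gammaln(expo + 1.0).sum(axis=1)
    return expo, const


def _survival_batch(x_sorted: np.ndarray, n: int, chunk: int = 512) -> np.ndarray:
    """Fbar for a batch of sorted value vectors (E x d), common sample size n."""
    x = np.asarray(x_sorted, float)
    if x.ndim == 1:
        x = x[None, :]
    d = x.shape[1]
    bounded = np.concatenate(
        [np.zeros((x.shape[0], 1)), x, np.ones((x.shape[0], 1))], axis=1
    )
    diffs = np.diff(bounded, axis=1)  # E x (d+1), all >= 0
    if np.any(diffs < -1e-12):
        raise ValueError("values must be sorted ascending in [0, 1]")
    diffs = np.clip(diffs, 0.0, None)
    expo, const = _term_table(n, d)
    with np.errstate(divide="ignore"):
        logd = np.where(diffs > 0.0, np.log(np.maximum(diffs, 1e-320)), _LOG_ZERO)
    out = np.empty(x.shape[0])
    for lo in range(0, x.shape[0], chunk):
        hi = min(lo + chunk, x.shape[0])
        logterms = logd[lo:hi] @ expo.T + const  # E' x T
        out[lo:hi] = np.exp(logterms).sum(axis=1)
    return np.clip(out, 0.0, 1.0)


def joint_survival(x, n: int, p_max: float | None = None) -> float:
    """Upper-tail probability that the d largest of n iid uniforms jointly
    exceed the ascending values ``x`` (each capped at ``p_max`` if given)."""
    x = np.asarray(x, float).ravel()
    if np.any(np.diff(x) < 0):
        raise ValueError("x must be sorted ascending")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x values must lie in [0, 1]")
    if x.size > n:
        raise ValueError("need d <= n")
    if p_max is not None:
        x = np.minimum(x, p_max)
    return float(_survival_batch(x[None, :], n)[0])


def _neighbor_index_table(shape, kernel: KernelSpec, mode: str):
    """Per-entry neighbor gather table over the valid region.

    Returns (entries (E,2), flat neighbor indices (E, n_off) with B1*B2 as the
    padding slot, counts (E,)).  The tested entry itself is part of its
    neighborhood: the kernel covers it, and the count formula n = lK*wK - ...
    includes it.
    """
    b1, b2 = shape
    offsets = _kernel_offsets(kernel)
    if mode == "symmetric":
        rows, cols = np.triu_indices(b1, k=1)
    else:
        rows, cols = np.indices((b1, b2)).reshape(2, -1)
    e = rows.size
    idx = np.full((e, len(offsets)), b1 * b2, dtype=np.int64)
    for m, (dr, dc) in enumerate(offsets):
        r = rows + dr
        c = cols + dc
        ok = (r >= 0) & (r < b1) & (c >= 0) & (c < b2)
        if mode == "symmetric":
            ok &= r < c
        idx[ok, m] = r[ok] * b2 + c[ok]
    counts = (idx < b1 * b2).sum(axis=1)
    return np.column_stack([rows, cols]), idx, counts


_NEIGHBOR_CACHE: dict = {}


def _neighbors_for(shape, kernel, mode):
    key = (shape, kernel.length, kernel.width, mode)
    if key not in _NEIGHBOR_CACHE:
        if len(_NEIGHBOR_CACHE) > 8:
            _NEIGHBOR_CACHE.clear()
        _NEIGHBOR_CACHE[key] = _neighbor_index_table(shape, kernel, mode)
    return _NEIGHBOR_CACHE[key]


def top_d_neighbors(pmat: ProbabilityMatrix, kernel: KernelSpec):
    """For every valid entry: its d largest neighbor values and sample size.

    Returns (entries (E,2), top values (E,d) ascending with leading zero
    padding when fewer than d covered positions exist, counts (E,)).
    """
    probs = pmat.probs
    entries, idx, counts = _neighbors_for(probs.shape, kernel, pmat.mode)
    flat = np.append(probs.ravel(), 0.0)  # padding slot holds 0
    vals = flat[idx]
    d = kernel.n_largest
    top = np.partition(vals, vals.shape[1] - d, axis=1)[:, -d:]
    top.sort(axis=1)
    return entries, top, counts


def joint_probability_matrix(
    pmat: ProbabilityMatrix,
    kernel: KernelSpec,
    entries=None,
) -> JointProbabilityMatrix:
    """Order-statistic joint significance of each entry's largest neighbors.

    For every entry the ``d`` largest probabilities among the kernel-covered
    positions (the entry itself included, values capped at ``p_max``) enter
    the joint survival function with ``n`` equal to the actual neighborhood
    size; ``J = 1 - Fbar``.

    ``entries`` restricts evaluation to the given (i, j) positions (an
    (E, 2) array); elsewhere ``J`` stays 0.  Because the detection mask also
    requires ``P > alpha_1``, restricting to those candidates leaves all
    downstream results unchanged.
    """
    probs = pmat.probs
    all_entries, top, counts = top_d_neighbors(pmat, kernel)
    if entries is not None:
        entries = np.asarray(entries, int).reshape(-1, 2)
        b2 = probs.shape[1]
        want = np.zeros(probs.shape[0] * b2 + 1, bool)
        want[entries[:, 0] * b2 + entries[:, 1]] = True
        sel = want[all_entries[:, 0] * b2 + all_entries[:, 1]]
        all_entries, top, counts = all_entries[sel], top[sel], counts[sel]

    d = kernel.n_largest
    top = np.minimum(top, kernel.p_max)
    jmat = np.zeros_like(probs, dtype=float)
    evaluated = np.zeros_like(probs, dtype=bool)
    for m in np.unique(counts):
        sel = counts == m
        rows = all_entries[sel]
        if m == 0:
            continue
        d_eff = min(d, int(m))
        fbar = _survival_batch(top[sel][:, -d_eff:], int(m))
        jmat[rows[:, 0], rows[:, 1]] = 1.0 - fbar
        evaluated[rows[:, 0], rows[:, 1]] = True
    return JointProbabilityMatrix(probs=jmat, kernel=kernel, evaluated=evaluated)
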