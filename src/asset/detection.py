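"""Dual-threshold masking, anisotropic clustering and SSE reconstruction.

Entries passing both the individual test (``P_ij > alpha_1``) and the joint
test (``J_ij > alpha_2``) form the binary mask ``M``.  Masked entries are
grouped into diagonal structures (DS) with DBSCAN under an elliptical
distance that stretches the anti-diagonal direction by a factor ``rho``:

    d_rho(a, b) = [1 + (rho - 1) |sin(theta - pi/4)|] * sqrt((di^2 + dj^2)/2)

so that steps along a diagonal cost 1 per bin while anti-diagonal steps cost
``rho``.  Each cluster is a DS; the corresponding repeated SSE is read off as
the per-entry intersection of the neuron sets active in the two bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .joint import JointProbabilityMatrix, KernelSpec, joint_probability_matrix
from .matrix import IntersectionMatrix, ProbabilityMatrix, intersection_matrix, probability_matrix
from .rates import RateProfiles, kernel_rate, true_rates
from .spikedata import BinnedSpikes, SpikeTrainSet, bin_spike_trains

__all__ = [
    "MaskParams",
    "ClusterParams",
    "DiagonalStructure",
    "SSE",
    "mask_matrix",
    "elliptical_distance",
    "dbscan_diagonal",
    "extract_sses",
    "run_asset",
    "AssetResult",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MaskParams:
    """Significance thresholds of the two tests (``alpha1 < alpha2``)."""

    alpha1: float = 0.99
    alpha2: float = 0.99999

    def __post_init__(self):
        if not 0.0 < self.alpha1 < self.alpha2 < 1.0:
            raise ValueError("need 0 < alpha1 < alpha2 < 1")


@dataclass(frozen=True)
class ClusterParams:
    """Elliptical-DBSCAN parameters.

    ``stretch`` (rho) penalizes anti-diagonal displacements; ``eps`` is the
    DBSCAN neighborhood radius (in bins along the diagonal); ``min_size``
    (l_0) is the minimum number of entries forming a DS.
    """

    stretch: float = 5.0
    eps: float = 3.5
    min_size: int = 3

    def __post_init__(self):
        if self.stretch < 1:
            raise ValueError("stretch must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")

    def check_against_kernel(self, kernel: KernelSpec) -> None:
        """Warn when the clustering ellipse is not contained in the kernel."""
        if int(self.eps) > kernel.length:
            logger.warning(
                "eps=%.3g exceeds the kernel length %d; the clustering "
                "ellipse should be contained within the kernel",
                self.eps, kernel.length,
            )
        short_axis = 2.0 * self.eps / self.stretch
        if short_axis > kernel.width:
            logger.warning(
                "ellipse short axis %.3g exceeds the kernel width %d",
                short_axis, kernel.width,
            )


@dataclass
class DiagonalStructure:
    """One cluster of matrix entries (a candidate repeated SSE)."""

    label: int
    entries: list  # [(i, j), ...] sorted by row

    def __post_init__(self):
        self.entries = sorted((int(i), int(j)) for i, j in self.entries)

    @property
    def size(self) -> int:
        return len(self.entries)

    @property
    def length(self) -> int:
        """Span along the diagonal (bins), l_DS."""
        rows = [i for i, _ in self.entries]
        return max(rows) - min(rows) + 1

    @property
    def wiggliness(self) -> int:
        """Number of adjacent off-diagonals spanned, w_DS."""
        lags = [j - i for i, j in self.entries]
        return max(lags) - min(lags) + 1

    def entry_set(self) -> frozenset:
        return frozenset(self.entries)


@dataclass
class SSE:
    """Reconstructed repeated sequence of synchronous events.

    One event per DS entry: ``(bin_i, bin_j, neurons)`` where ``neurons`` is
    the set of neurons active in both bins, ordered by ``bin_i``.
    """

    events: list  # [(i, j, frozenset), ...]

    @property
    def n_events(self) -> int:
        return len(self.events)

    def neuron_sets(self) -> list:
        return [ev[2] for ev in self.events]


def mask_matrix(
    pmat: ProbabilityMatrix,
    jmat: JointProbabilityMatrix,
    params: MaskParams = MaskParams(),
) -> np.ndarray:
    """Binary mask: 1 where ``P > alpha1`` and ``J > alpha2``.

    In symmetric mode the main diagonal and lower triangle are forced to 0.
    """
    p, j = pmat.probs, jmat.probs
    if p.shape != j.shape:
        raise ValueError("P and J must share a shape")
    mask = (p > params.alpha1) & (j > params.alpha2)
    if pmat.mode == "symmetric":
        mask &= np.triu(np.ones_like(mask), k=1)
    return mask


def elliptical_distance(a, b, stretch: float = 5.0) -> float:
    """Anisotropic distance between two matrix positions.

    Diagonal steps: ``d((i,j),(i+k,j+k)) = k`` for any stretch; anti-diagonal
    steps: ``d((i,j),(i+k,j-k)) = stretch*k``.
    """
    di = float(b[0] - a[0])
    dj = float(b[1] - a[1])
    if di == 0.0 and dj == 0.0:
        return 0.0
    theta = np.arctan(dj / di) if di != 0.0 else np.pi / 2.0
    factor = 1.0 + (stretch - 1.0) * abs(np.sin(theta - np.pi / 4.0))
    return factor * np.sqrt((di * di + dj * dj) / 2.0)


def _pairwise_elliptical(points: np.ndarray, stretch: float) -> np.ndarray:
    di = points[:, 0][None, :] - points[:, 0][:, None]
    dj = points[:, 1][None, :] - points[:, 1][:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(di != 0, np.arctan(dj / np.where(di == 0, 1, di)), np.pi / 2)
    factor = 1.0 + (stretch - 1.0) * np.abs(np.sin(theta - np.pi / 4.0))
    dist = factor * np.sqrt((di**2 + dj**2) / 2.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def dbscan_diagonal(mask: np.ndarray, params: ClusterParams = ClusterParams()):
    """Cluster mask entries into diagonal structures with elliptical DBSCAN.

    Returns ``(structures, labels)``: a list of :class:`DiagonalStructure`
    (labels 1, 2, ...) and a matrix of per-entry labels (0 = not masked,
    -1 = masked but isolated noise, k >= 1 = cluster id).  Entries are
    processed in row-major order, making the output deterministic.
    """
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, int)
    pts = np.argwhere(mask)  # row-major order
    if pts.shape[0] == 0:
        return [], labels
    dist = _pairwise_elliptical(pts.astype(float), params.stretch)
    db = DBSCAN(eps=params.eps, min_samples=params.min_size, metric="precomputed")
    raw = db.fit_predict(dist)
    structures = []
    next_label = 1
    for lab in np.unique(raw):
        sel = raw == lab
        if lab == -1 or sel.sum() < params.min_size:
            labels[pts[sel, 0], pts[sel, 1]] = -1
            continue
        entries = [tuple(p) for p in pts[sel]]
        structures.append(DiagonalStructure(label=next_label, entries=entries))
        labels[pts[sel, 0], pts[sel, 1]] = next_label
        next_label += 1
    return structures, labels


def extract_sses(structures, binned: BinnedSpikes):
    """Reconstruct each DS's repeated SSE from the binned data.

    The neuron set of the event at entry ``(i, j)`` is ``S_i n S_j``.
    """
    sses = []
    for ds in structures:
        events = []
        for i, j in ds.entries:
            neurons = frozenset(
                np.flatnonzero(binned.occupancy[:, i] & binned.occupancy[:, j]).tolist()
            )
            events.append((i, j, neurons))
        events.sort(key=lambda ev: (ev[0], ev[1]))
        sses.append(SSE(events=events))
    return sses


@dataclass
class AssetResult:
    """All pipeline stages of one analysis run."""

    binned: BinnedSpikes
    imat: IntersectionMatrix
    pmat: ProbabilityMatrix
    jmat: JointProbabilityMatrix
    mask: np.ndarray
    labels: np.ndarray
    structures: list
    sses: list


def run_asset(
    spikes: SpikeTrainSet,
    rates: RateProfiles | None = None,
    bin_width: float = 0.005,
    kernel: KernelSpec = KernelSpec(),
    mask_params: MaskParams = MaskParams(),
    cluster_params: ClusterParams = ClusterParams(),
    prob_method: str = "auto",
    rate_method: str = "boxcar",
    rate_width: float = 0.200,
    joint_entries: str = "candidates",
) -> AssetResult:
    """Full analysis pipeline: bin -> I -> P -> J -> M -> clusters -> SSEs.

    If ``rates`` is None they are estimated from the analyzed data itself
    with a fixed-width kernel (``rate_method``/``rate_width``).  With
    ``joint_entries='candidates'`` the joint test is evaluated only where
    ``P > alpha_1`` (the mask requires both conditions, so results are
    identical to ``'all'``).
    """
    cluster_params.check_against_kernel(kernel)
    binned = bin_spike_trains(spikes, bin_width)
    if rates is None:
        rates = kernel_rate([spikes], binned.config, shape=rate_method, width=rate_width)
    elif isinstance(rates, np.ndarray):
        rates = true_rates(rates, binned.config)
    imat = intersection_matrix(binned)
    pmat = probability_matrix(imat, rates, method=prob_method)
    if joint_entries == "candidates":
        cand = np.argwhere(pmat.probs > mask_params.alpha1)
        jmat = joint_probability_matrix(pmat, kernel, entries=cand)
    elif joint_entries == "all":
        jmat = joint_probability_matrix(pmat, kernel)
    else:
        raise ValueError("joint_entries must be 'candidates' or 'all'")
    mask = mask_matrix(pmat, jmat, mask_params)
    structures, labels = dbscan_diagonal(mask, cluster_params)
    sses = extract_sses(structures, binned)
    return AssetResult(
        binned=binned, imat=imat, pmat=pmat, jmat=jmat,
        mask=mask, labels=labels, structures=structures, sses=sses,
    )
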