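"""Scikit-learn-style estimator wrapping the full detection pipeline.

:class:`ASSET` is a clustering-shaped estimator: ``fit`` takes parallel spike
trains, runs binning, the two significance tests and the elliptical DBSCAN
clustering, and exposes every pipeline stage as a fitted attribute.  It
composes with sklearn tooling (``get_params`` / ``set_params`` / ``clone``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .detection import ClusterParams, MaskParams, run_asset
from .joint import KernelSpec
from .rates import RateProfiles
from .spikedata import SpikeTrainSet

__all__ = ["ASSET"]


class ASSET(BaseEstimator):
    """Detector of repeated sequences of synchronous events (SSEs).

    Parameters
    ----------
    bin_width : float
        Synchrony bin width Delta in seconds (default 5 ms).
    kernel_length, kernel_width, n_largest, p_max
        Diagonal-kernel parameters of the joint test (l_K, w_K, d, cap).
    alpha1, alpha2
        Significance thresholds of the individual and joint tests.
    stretch, eps, min_size
        Elliptical-DBSCAN clustering parameters (rho, epsilon, l_0).
    rate_method, rate_width
        Single-train kernel rate estimator used when ``fit`` receives no
        rate profiles ('boxcar' or 'gaussian'; full width in seconds).
    prob_method
        'exact', 'lecam' or 'auto' evaluation of the null distribution.
    joint_entries
        'candidates' evaluates the joint test only where P > alpha1 (same
        detections, much faster) or 'all'.

    Attributes
    ----------
    binned_ : BinnedSpikes
    intersection_ : ndarray of int, (B, B)
    probability_ : ndarray, (B, B)
    joint_ : ndarray, (B, B)
    mask_ : ndarray of bool, (B, B)
    labels_ : ndarray of int, (B, B)
        0 = background, -1 = masked noise, k >= 1 = cluster id.
    structures_ : list of DiagonalStructure
    sses_ : list of SSE

    Examples
    --------
    >>> from asset.simulate import generate_model, inject_sse, SSESpec
    >>> data, truth = inject_sse(generate_model(0, seed=0), SSESpec(), seed=1)
    >>> det = ASSET().fit(data)
    >>> len(det.sses_)
    1
    """

    def __init__(
        self,
        bin_width: float = 0.005,
        kernel_length: int = 5,
        kernel_width: int = 5,
        n_largest: int = 5,
        p_max: float = 0.999,
        alpha1: float = 0.99,
        alpha2: float = 0.99999,
        stretch: float = 5.0,
        eps: float = 3.5,
        min_size: int = 3,
        rate_method: str = "boxcar",
        rate_width: float = 0.200,
        prob_method: str = "auto",
        joint_entries: str = "candidates",
    ):
        self.bin_width = bin_width
        self.kernel_length = kernel_length
        self.kernel_width = kernel_width
        self.n_largest = n_largest
        self.p_max = p_max
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.stretch = stretch
        self.eps = eps
        self.min_size = min_size
        self.rate_method = rate_method
        self.rate_width = rate_width
        self.prob_method = prob_method
        self.joint_entries = joint_entries

    def fit(self, X, y=None, rates: RateProfiles | np.ndarray | None = None):
        """Run the full pipeline on parallel spike trains.

        ``X`` is a :class:`SpikeTrainSet` or a list of per-neuron spike-time
        arrays (then the window defaults to [0, max spike time]).  ``rates``
        optionally supplies known N x B rate profiles in Hz; otherwise rates
        are estimated from ``X`` by fixed-width kernel convolution.
        """
        spikes = self._as_spikes(X)
        result = run_asset(
            spikes,
            rates=rates,
            bin_width=self.bin_width,
            kernel=KernelSpec(
                length=self.kernel_length, width=self.kernel_width,
                n_largest=self.n_largest, p_max=self.p_max,
            ),
            mask_params=MaskParams(alpha1=self.alpha1, alpha2=self.alpha2),
            cluster_params=ClusterParams(
                stretch=self.stretch, eps=self.eps, min_size=self.min_size
            ),
            prob_method=self.prob_method,
            rate_method=self.rate_method,
            rate_width=self.rate_width,
            joint_entries=self.joint_entries,
        )
        self.result_ = result
        self.binned_ = result.binned
        self.intersection_ = result.imat.counts
        self.probability_ = result.pmat.probs
        self.joint_ = result.jmat.probs
        self.mask_ = result.mask
        self.labels_ = result.labels
        self.structures_ = result.structures
        self.sses_ = result.sses
        return self

    def fit_predict(self, X, y=None, **fit_kwargs) -> np.ndarray:
        """Fit and return the B x B cluster-label matrix."""
        return self.fit(X, y, **fit_kwargs).labels_

    @staticmethod
    def _as_spikes(X) -> SpikeTrainSet:
        if isinstance(X, SpikeTrainSet):
            return X
        trains = [np.asarray(t, float) for t in X]
        t_stop = max((t.max() for t in trains if t.size), default=1.0) + 1e-9
        return SpikeTrainSet(trains=trains, t_start=0.0, t_stop=t_stop)
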