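"""Monte-Carlo joint-significance estimation under bin shuffling.

When fine-temporal correlations (population or group synchrony) should be
part of the null hypothesis, the analytic joint test can be replaced by a
Monte-Carlo estimate: the binned data's columns are permuted (preserving each
bin's synchronous pattern, destroying temporal order), the probability matrix
is recomputed for each surrogate with the ORIGINAL rate profiles, and a
kernel-filtered statistic

    F_ij = 1 - prod_k (1 - P^(k)_ij)    over the d largest neighbors

is ranked against its surrogate distribution:

    Jtilde_ij = (1/S) * #{s : Ftilde_s;ij <= F_ij}.

Entries with ``Jtilde > alpha2`` are significant under the shuffled null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .joint import KernelSpec, top_d_neighbors
from .matrix import ProbabilityMatrix, intersection_matrix, probability_matrix
from .rates import RateProfiles
from .spikedata import BinnedSpikes

__all__ = [
    "SurrogateConfig",
    "shuffle_bins",
    "filtered_probability_matrix",
    "surrogate_joint_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurrogateConfig:
    """Number of bin-shuffling surrogates and master seed."""

    n_surrogates: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if self.n_surrogates < 1:
            raise ValueError("need at least one surrogate")


def shuffle_bins(binned: BinnedSpikes, permutation=None, seed=None) -> BinnedSpikes:
    """Permute the time bins of the occupancy table (all neurons together).

    Within-bin synchronous patterns are preserved; temporal order is not.
    """
    if permutation is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        permutation = rng.permutation(binned.n_bins)
    else:
        permutation = np.asarray(permutation, int)
        if sorted(permutation.tolist()) != list(range(binned.n_bins)):
            raise ValueError("permutation must reorder all bins")
    return BinnedSpikes(occupancy=binned.occupancy[:, permutation], config=binned.config)


def filtered_probability_matrix(pmat: ProbabilityMatrix, kernel: KernelSpec) -> np.ndarray:
    """Product-combined top-d neighbor statistic ``F_ij = 1 - prod(1 - P^(k))``.

    Uncapped: the rank comparison against surrogates applies the same
    statistic to both sides.
    """
    entries, top, _counts = top_d_neighbors(pmat, kernel)
    fvals = 1.0 - np.prod(1.0 - top, axis=1)
    f = np.zeros(pmat.probs.shape)
    f[entries[:, 0], entries[:, 1]] = fvals
    return f


def surrogate_joint_matrix(
    binned: BinnedSpikes,
    rates: RateProfiles,
    kernel: KernelSpec = KernelSpec(),
    config: SurrogateConfig = SurrogateConfig(),
    prob_method: str = "lecam",
    alpha2: float = 0.99999,
) -> np.ndarray:
    """Monte-Carlo joint probability matrix under the bin-shuffled null.

    For each surrogate one uniform permutation is applied to both matrix
    axes; the original (unshuffled) rate profiles enter every probability
    matrix.  Values lie on the grid {0, 1/S, ..., 1}.  Per-surrogate seeds
    are derived from the master seed by counter, so results do not depend on
    execution order.
    """
    s = config.n_surrogates
    if 1.0 / s > 1.0 - alpha2:
        logger.warning(
            "with %d surrogates the significance threshold alpha2=%g is "
            "unreachable (finest achievable tail is 1/S)", s, alpha2,
        )
    pmat = probability_matrix(intersection_matrix(binned), rates, method=prob_method)
    f_obs = filtered_probability_matrix(pmat, kernel)
    ge_count = np.zeros(f_obs.shape)
    children = np.random.SeedSequence(config.seed).spawn(s)
    for i in range(s):
        surr = shuffle_bins(binned, seed=np.random.default_rng(children[i]))
        p_s = probability_matrix(intersection_matrix(surr), rates, method=prob_method)
        f_s = filtered_probability_matrix(p_s, kernel)
        ge_count += f_s <= f_obs
    jtilde = ge_count / s
    if pmat.mode == "symmetric":
        jtilde *= np.triu(np.ones_like(jtilde, bool), k=1)
    return jtilde
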