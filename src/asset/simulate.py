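"""Stochastic generators of parallel spike-train test data.

Ten background models of increasing difficulty for a rate-based null
hypothesis, numbered 0-9:

====  =========================================================================
id    construction
====  =========================================================================
0     independent Poisson, stationary 15 Hz
1     independent Poisson, coherent rate jump 10 -> 60 Hz on (600, 700) ms
2     independent Poisson, heterogeneous stationary rates 5..25 Hz
3     gamma-renewal ISIs (shape 5), stationary 15 Hz
4     gamma-renewal ISIs (shape 5) with the model-1 rate jump
5     gamma-renewal ISIs (shape 5) with the model-2 heterogeneous rates
6     20 groups of 5 Poisson neurons; each group a 5-ms rate jump 14 -> 100 Hz,
      staggered by 5 ms per group, repeated at 50 ms and 500 ms
7     compound Poisson population synchrony, A(1)=0.938, A(5)=0.062, 15 Hz
8     multiple single-interaction processes: 7 disjoint groups of 5 neurons,
      each with synchronous spikes in 2 random bins, total rate 15 Hz
9     independent Poisson, heterogeneous 5..15 Hz baselines + coherent
      +50 Hz jump on (600, 700) ms
====  =========================================================================

On top of any background, :func:`inject_sse` adds a repeated sequence of
synchronous events (SSE): ``l_SSE`` events of ``xi_SSE`` neurons each, placed
in consecutive bins and repeated at two (or more) occurrence times, with
optional per-event bin shifts encoding holes and wiggliness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .spikedata import BinConfig, SpikeTrainSet

__all__ = [
    "PiecewiseRate",
    "ModelSpec",
    "SSESpec",
    "poisson_process",
    "gamma_renewal",
    "compound_poisson",
    "multiple_sip",
    "rate_jump_propagation",
    "generate_model",
    "true_rate_profiles",
    "inject_sse",
]

GAMMA_SHAPE = 5.0  # ISI shape factor of models 3-5


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PiecewiseRate:
    """Piecewise-constant firing-rate profile on [edges[0], edges[-1]].

    ``values[m]`` is the rate in Hz on ``[edges[m], edges[m+1])``.
    """

    edges: tuple
    values: tuple

    def __post_init__(self):
        if len(self.edges) != len(self.values) + 1:
            raise ValueError("need len(edges) == len(values) + 1")
        if any(v < 0 for v in self.values):
            raise ValueError("rates must be non-negative")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")

    @classmethod
    def constant(cls, rate: float, t_stop: float, t_start: float = 0.0):
        return cls(edges=(t_start, t_stop), values=(rate,))

    @classmethod
    def with_jumps(cls, base: float, jumps, t_stop: float, t_start: float = 0.0):
        """Constant baseline plus additive jumps ``[(t1, t2, extra), ...]``."""
        points = {t_start, t_stop}
        for t1, t2, _ in jumps:
            points.update((t1, t2))
        edges = sorted(p for p in points if t_start <= p <= t_stop)
        values = []
        for a, b in zip(edges[:-1], edges[1:]):
            mid = 0.5 * (a + b)
            rate = base + sum(extra for t1, t2, extra in jumps if t1 <= mid < t2)
            values.append(rate)
        return cls(edges=tuple(edges), values=tuple(values))

    @property
    def t_start(self) -> float:
        return self.edges[0]

    @property
    def t_stop(self) -> float:
        return self.edges[-1]

    def __call__(self, t):
        t = np.asarray(t, float)
        idx = np.clip(np.searchsorted(self.edges, t, side="right") - 1, 0, len(self.values) - 1)
        return np.asarray(self.values)[idx]

    def cumulative_at_edges(self) -> np.ndarray:
        widths = np.diff(self.edges)
        return np.concatenate([[0.0], np.cumsum(widths * np.asarray(self.values))])

    def integral(self) -> float:
        return float(self.cumulative_at_edges()[-1])


def _as_profile(rate, t_stop: float, t_start: float = 0.0) -> PiecewiseRate:
    if isinstance(rate, PiecewiseRate):
        return rate
    return PiecewiseRate.constant(float(rate), t_stop, t_start)


def poisson_process(rate, t_stop: float = 1.0, seed=None, t_start: float = 0.0) -> np.ndarray:
    """One inhomogeneous-Poisson spike train with a piecewise-constant profile.

    ``rate`` may be a scalar (Hz) or a :class:`PiecewiseRate`.  The expected
    spike count equals the integral of the profile.
    """
    profile = _as_profile(rate, t_stop, t_start)
    rng = _rng(seed)
    times = []
    for a, b, lam in zip(profile.edges[:-1], profile.edges[1:], profile.values):
        count = rng.poisson(lam * (b - a))
        if count:
            times.append(rng.uniform(a, b, size=count))
    if not times:
        return np.array([])
    return np.sort(np.concatenate(times))


def gamma_renewal(
    shape: float,
    mean_isi: float,
    t_stop: float = 1.0,
    seed=None,
    t_start: float = 0.0,
    equilibrium: bool = True,
) -> np.ndarray:
    """Stationary gamma-renewal spike train with ISI ~ Gamma(shape, mean_isi).

    With ``equilibrium=True`` the first interval is drawn from the residual
    (length-biased) distribution, so the count rate is ``1/mean_isi`` from
    ``t_start`` onwards; the ISI coefficient of variation is ``1/sqrt(shape)``.
    """
    if shape < 1:
        raise ValueError("shape must be >= 1")
    if mean_isi <= 0:
        raise ValueError("mean_isi must be positive")
    rng = _rng(seed)
    theta = mean_isi / shape  # scale
    duration = t_stop - t_start
    times = []
    if equilibrium:
        # residual life: U * L with L length-biased, i.e. Gamma(shape+1, theta)
        t = rng.uniform() * rng.gamma(shape + 1.0, theta)
    else:
        t = rng.gamma(shape, theta)
    # draw ISIs in blocks until past the window
    while t < duration:
        times.append(t)
        block = rng.gamma(shape, theta, size=max(16, int(2 * duration / mean_isi)))
        cum = t + np.cumsum(block)
        inside = cum[cum < duration]
        times.extend(inside.tolist())
        t = cum[-1]
    return t_start + np.asarray(times, float)


def inhomogeneous_gamma(rate, shape: float, t_stop: float = 1.0, seed=None,
                        t_start: float = 0.0) -> np.ndarray:
    """Non-stationary gamma process via operational-time rescaling.

    A unit-rate equilibrium gamma renewal process is generated in operational
    time ``s = Lambda(t)`` (the cumulative rate) and mapped back through the
    piecewise-linear inverse of ``Lambda``; the instantaneous rate is then
    ``rate(t)`` while ISIs keep gamma regularity.
    """
    profile = _as_profile(rate, t_stop, t_start)
    total = profile.integral()
    if total <= 0:
        return np.array([])
    op_times = gamma_renewal(shape, 1.0, t_stop=total, seed=seed, equilibrium=True)
    cum = profile.cumulative_at_edges()
    return np.interp(op_times, cum, np.asarray(profile.edges))


def compound_poisson(
    n_neurons: int,
    amplitude: dict,
    rate: float = 15.0,
    t_stop: float = 1.0,
    seed=None,
    mother_rate: float | None = None,
) -> SpikeTrainSet:
    """Compound Poisson process: population synchrony via a mother process.

    A mother Poisson process of rate ``lambda_m = N * rate / E[xi]`` emits
    events; each event draws a size ``xi`` from the amplitude distribution
    ``A(.)`` and copies a spike into ``xi`` distinct, uniformly chosen neurons.
    Marginal matching makes every neuron's total rate equal ``rate``.
    ``mother_rate`` overrides the marginal-matching constant.
    """
    sizes = np.asarray(sorted(amplitude), dtype=int)
    probs = np.asarray([amplitude[s] for s in sizes], float)
    if np.any(sizes < 1) or np.any(sizes > n_neurons):
        raise ValueError("amplitude support must lie in {1..N}")
    if not math.isclose(probs.sum(), 1.0, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError("amplitude distribution must sum to 1")
    rng = _rng(seed)
    mean_size = float((sizes * probs).sum())
    lam_m = mother_rate if mother_rate is not None else n_neurons * rate / mean_size
    n_events = rng.poisson(lam_m * t_stop)
    event_times = rng.uniform(0.0, t_stop, size=n_events)
    event_sizes = rng.choice(sizes, size=n_events, p=probs)
    trains = [[] for _ in range(n_neurons)]
    for t, xi in zip(event_times, event_sizes):
        for k in rng.choice(n_neurons, size=int(xi), replace=False):
            trains[k].append(t)
    return SpikeTrainSet(
        trains=[np.sort(np.asarray(tr)) for tr in trains], t_start=0.0, t_stop=t_stop
    )


def multiple_sip(
    n_neurons: int = 100,
    n_groups: int = 7,
    group_size: int = 5,
    events_per_group: int = 2,
    rate: float = 15.0,
    t_stop: float = 1.0,
    bin_width: float = 0.005,
    seed=None,
    groups=None,
) -> SpikeTrainSet:
    """Multiple single-interaction processes (intra-group synchrony).

    ``n_groups`` disjoint groups each receive exactly-synchronous spikes in
    ``events_per_group`` random bins (independent across groups); independent
    Poisson background tops every neuron's total rate up to ``rate``.
    """
    rng = _rng(seed)
    if groups is None:
        # groups occupy the TOP neuron ids, leaving the low ids (the
        # conventional home of an injected SSE) independent
        first = n_neurons - n_groups * group_size
        if first < 0:
            raise ValueError("groups do not fit into the neuron count")
        groups = [
            tuple(range(first + g * group_size, first + (g + 1) * group_size))
            for g in range(n_groups)
        ]
    flat = [k for g in groups for k in g]
    if len(set(flat)) != len(flat):
        raise ValueError("groups must be pairwise disjoint")
    if len(flat) > n_neurons or (flat and max(flat) >= n_neurons):
        raise ValueError("groups exceed the neuron count")
    bg_rate_member = rate - events_per_group / t_stop
    if bg_rate_member < 0:
        raise ValueError("events_per_group too large for the requested total rate")
    member = np.zeros(n_neurons, bool)
    member[flat] = True
    trains = [
        poisson_process(bg_rate_member if member[k] else rate, t_stop, rng)
        for k in range(n_neurons)
    ]
    n_bins = int(math.floor(t_stop / bin_width + 1e-9))
    for g in groups:
        bins = rng.choice(n_bins, size=events_per_group, replace=False)
        for b in bins:
            t = (b + 0.5) * bin_width
            for k in g:
                trains[k] = np.sort(np.append(trains[k], t))
    return SpikeTrainSet(trains=trains, t_start=0.0, t_stop=t_stop)


def rate_jump_propagation(
    n_neurons: int = 100,
    group_size: int = 5,
    base_rate: float = 14.0,
    jump_rate: float = 100.0,
    jump_duration: float = 0.005,
    t1: float = 0.050,
    t2: float = 0.500,
    t_stop: float = 1.0,
    seed=None,
) -> SpikeTrainSet:
    """Staggered rate-jump ("rate propagation") model.

    Group ``l`` (0-based, ``group_size`` neurons each) jumps from
    ``base_rate`` to ``jump_rate`` for ``jump_duration`` starting at
    ``t1 + l*jump_duration`` and again at ``t2 + l*jump_duration``.
    """
    rng = _rng(seed)
    n_groups = n_neurons // group_size
    last = t2 + n_groups * jump_duration
    if last > t_stop:
        raise ValueError("jump schedule does not fit in the observation window")
    trains = []
    for k in range(n_neurons):
        profile = _model6_profile(k, group_size, base_rate, jump_rate,
                                  jump_duration, t1, t2, t_stop)
        trains.append(poisson_process(profile, t_stop, rng))
    return SpikeTrainSet(trains=trains, t_start=0.0, t_stop=t_stop)


def _model6_profile(k, group_size, base, jump, dur, t1, t2, t_stop):
    l = k // group_size
    extra = jump - base
    jumps = [
        (t1 + l * dur, t1 + (l + 1) * dur, extra),
        (t2 + l * dur, t2 + (l + 1) * dur, extra),
    ]
    return PiecewiseRate.with_jumps(base, jumps, t_stop)


@dataclass
class ModelSpec:
    """Declarative description of one background model realization."""

    model_id: int
    n_neurons: int = 100
    t_stop: float = 1.0
    seed: int | None = None
    # model-specific overrides
    rate: float = 15.0
    jump_window: tuple = (0.600, 0.700)
    jump_rate: float = 50.0           # additive jump of models 1/4/9
    gamma_shape: float = GAMMA_SHAPE
    amplitude: dict = field(default_factory=lambda: {1: 0.938, 5: 0.062})
    mother_rate: float | None = None
    bin_width: float = 0.005

    def __post_init__(self):
        if self.model_id not in range(10):
            raise ValueError(f"unknown model id {self.model_id}")
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.gamma_shape < 1:
            raise ValueError("gamma shape must be >= 1")


def _model_profile(spec: ModelSpec, k: int) -> PiecewiseRate:
    """True generative rate profile of neuron ``k`` under ``spec``."""
    m, N, T = spec.model_id, spec.n_neurons, spec.t_stop
    t1, t2 = spec.jump_window
    if m in (0, 3, 7, 8):
        return PiecewiseRate.constant(spec.rate, T)
    if m in (1, 4):
        return PiecewiseRate.with_jumps(spec.rate - 5.0, [(t1, t2, spec.jump_rate)], T)
    if m in (2, 5):
        return PiecewiseRate.constant(5.0 + 20.0 * k / (N - 1), T)
    if m == 6:
        return _model6_profile(k, 5, 14.0, 100.0, 0.005, 0.050, 0.500, T)
    if m == 9:
        return PiecewiseRate.with_jumps(
            5.0 + 10.0 * k / (N - 1), [(t1, t2, spec.jump_rate)], T
        )
    raise ValueError(m)


def generate_model(spec: ModelSpec | int, seed=None, **kwargs) -> SpikeTrainSet:
    """Simulate one realization of a background model.

    ``spec`` may be a :class:`ModelSpec` or a bare model id (0-9) with keyword
    overrides.  Identical seeds give identical output.
    """
    if not isinstance(spec, ModelSpec):
        spec = ModelSpec(model_id=int(spec), **kwargs)
    rng = _rng(seed if seed is not None else spec.seed)
    m = spec.model_id
    if m == 7:
        return compound_poisson(
            spec.n_neurons, spec.amplitude, spec.rate, spec.t_stop, rng,
            mother_rate=spec.mother_rate,
        )
    if m == 8:
        return multiple_sip(
            spec.n_neurons, rate=spec.rate, t_stop=spec.t_stop,
            bin_width=spec.bin_width, seed=rng,
        )
    trains = []
    for k in range(spec.n_neurons):
        profile = _model_profile(spec, k)
        if m in (3, 4, 5):
            trains.append(
                inhomogeneous_gamma(profile, spec.gamma_shape, spec.t_stop, rng)
            )
        else:
            trains.append(poisson_process(profile, spec.t_stop, rng))
    return SpikeTrainSet(trains=trains, t_start=0.0, t_stop=spec.t_stop)


def true_rate_profiles(spec: ModelSpec | int, bins: BinConfig, **kwargs) -> np.ndarray:
    """N x B table of the generative rates (Hz) evaluated at bin centers."""
    if not isinstance(spec, ModelSpec):
        spec = ModelSpec(model_id=int(spec), **kwargs)
    centers = bins.centers()
    return np.vstack(
        [_model_profile(spec, k)(centers) for k in range(spec.n_neurons)]
    )


@dataclass
class SSESpec:
    """A repeated sequence of synchronous events to inject.

    ``n_events`` (l_SSE) events of ``event_size`` (xi_SSE) neurons each; the
    member groups default to consecutive disjoint id blocks ``0..4, 5..9, ...``.
    ``offsets[r, e]`` adds extra bin shifts to event ``e`` of repetition ``r``
    (cumulative shifts create holes; unequal shifts across repetitions create
    wiggliness).
    """

    n_events: int = 7
    event_size: int = 5
    groups: list | None = None
    spacing: int = 1
    n_repetitions: int = 2
    offsets: np.ndarray | None = None

    def __post_init__(self):
        if self.spacing < 1:
            raise ValueError("spacing must be >= 1 bin")
        if self.groups is None:
            self.groups = [
                tuple(range(e * self.event_size, (e + 1) * self.event_size))
                for e in range(self.n_events)
            ]
        if len(self.groups) != self.n_events:
            raise ValueError("need one neuron group per event")
        flat = [k for g in self.groups for k in g]
        if len(set(flat)) != len(flat):
            raise ValueError("event groups must be pairwise disjoint")
        if self.offsets is None:
            self.offsets = np.zeros((self.n_repetitions, self.n_events), int)
        else:
            self.offsets = np.asarray(self.offsets, int)
            if self.offsets.shape != (self.n_repetitions, self.n_events):
                raise ValueError("offsets must have shape (n_repetitions, n_events)")
            if np.any(np.diff(self.offsets, axis=1) < 0):
                raise ValueError("offsets must be non-decreasing along events")

    @property
    def max_neuron(self) -> int:
        return max(k for g in self.groups for k in g)

    def span(self, rep: int) -> int:
        """Number of bins covered by repetition ``rep``."""
        return (self.n_events - 1) * self.spacing + int(self.offsets[rep, -1]) + 1

    def event_bins(self, rep: int, start: int) -> np.ndarray:
        return start + np.arange(self.n_events) * self.spacing + self.offsets[rep]


def inject_sse(
    spikes: SpikeTrainSet,
    sse: SSESpec,
    bin_width: float = 0.005,
    starts=None,
    seed=None,
    min_separation: int = 5,
):
    """Add a repeated SSE to background spikes.

    One spike per member neuron is ADDED at the center of each target bin
    (collisions with background spikes are absorbed later by binary binning).
    Occurrence start bins are drawn uniformly over admissible positions with at
    least ``min_separation`` empty bins between repetitions, or can be given
    explicitly.

    Returns
    -------
    (SpikeTrainSet, truth)
        ``truth`` is a list with one ground-truth diagonal structure per
        ordered pair of repetitions; each structure is a list of ``(i, j)``
        bin-pair entries (i < j).
    """
    rng = _rng(seed)
    if sse.max_neuron >= spikes.n_neurons:
        raise ValueError("SSE neuron ids exceed the data's neuron count")
    n_bins = int(math.floor(spikes.duration / bin_width + 1e-9))
    spans = [sse.span(r) for r in range(sse.n_repetitions)]
    if starts is None:
        starts = _draw_starts(rng, n_bins, spans, min_separation)
    else:
        starts = sorted(int(s) for s in starts)
        if len(starts) != sse.n_repetitions:
            raise ValueError("need one start bin per repetition")
        for (s1, sp1), s2 in zip(zip(starts[:-1], spans[:-1]), starts[1:]):
            if s2 < s1 + sp1:
                raise ValueError("repetition windows overlap")
        if starts[-1] + spans[-1] > n_bins:
            raise ValueError("repetition window exceeds the binned interval")

    trains = [t.copy() for t in spikes.trains]
    for r, start in enumerate(starts):
        for e, b in enumerate(sse.event_bins(r, start)):
            t = spikes.t_start + (b + 0.5) * bin_width
            for k in sse.groups[e]:
                trains[k] = np.sort(np.append(trains[k], t))
    out = SpikeTrainSet(trains=trains, t_start=spikes.t_start, t_stop=spikes.t_stop)

    truth = []
    for r in range(sse.n_repetitions):
        for s in range(r + 1, sse.n_repetitions):
            bins_r = sse.event_bins(r, starts[r])
            bins_s = sse.event_bins(s, starts[s])
            truth.append([(int(i), int(j)) for i, j in zip(bins_r, bins_s)])
    return out, truth


def _draw_starts(rng, n_bins, spans, min_separation, max_tries=1000):
    n_reps = len(spans)
    for _ in range(max_tries):
        starts = sorted(
            int(rng.integers(0, n_bins - sp + 1)) for sp in [max(spans)] * n_reps
        )
        ok = all(
            starts[r + 1] >= starts[r] + spans[r] + min_separation
            for r in range(n_reps - 1)
        )
        if ok and starts[-1] + spans[-1] <= n_bins:
            return starts
    raise RuntimeError("could not place non-overlapping SSE repetitions")
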