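"""Performance benchmarking: TP/FP classification and simulation studies.

A found diagonal structure is a true positive (TP) with respect to a known
ground-truth DS iff it contains at least 50% of the truth's entries AND at
least 50% of its own entries belong to the truth; otherwise (or when no SSE
was injected) it is a false positive (FP).  The studies below replicate the
validation protocol of the method on the stochastic background models:
per-model benchmarks with and without an injected SSE, a rate-estimation
trial-count study, and a full-factorial sweep over neuron count, SSE length
and event size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import ClusterParams, KernelSpec, MaskParams, run_asset
from .rates import RateProfiles, kernel_rate, optimized_kernel_rate, psth, true_rates
from .simulate import ModelSpec, SSESpec, generate_model, inject_sse, true_rate_profiles
from .spikedata import bin_spike_trains

__all__ = [
    "classify_detection",
    "PerformanceResult",
    "benchmark",
    "sweep",
    "trial_count_study",
]


def classify_detection(found, truth) -> str:
    """Classify one found DS against a ground-truth entry set.

    ``found`` may be a DiagonalStructure or an iterable of (i, j) entries.
    Empty truth makes every found DS an FP.
    """
    found_set = found.entry_set() if hasattr(found, "entry_set") else frozenset(
        (int(i), int(j)) for i, j in found
    )
    truth_set = frozenset((int(i), int(j)) for i, j in truth)
    if not truth_set or not found_set:
        return "FP"
    overlap = len(found_set & truth_set)
    if 2 * overlap >= len(truth_set) and 2 * overlap >= len(found_set):
        return "TP"
    return "FP"


@dataclass
class PerformanceResult:
    """Aggregated detection tallies over repeated simulations."""

    condition: dict
    n_runs: int
    tp_counts: list = field(default_factory=list)
    fp_counts: list = field(default_factory=list)
    fp_disjoint_counts: list = field(default_factory=list)
    tp_event_fractions: list = field(default_factory=list)

    @property
    def tp_rate(self) -> float:
        return float(np.mean(self.tp_counts)) if self.tp_counts else 0.0

    @property
    def fp_rate(self) -> float:
        return float(np.mean(self.fp_counts)) if self.fp_counts else 0.0

    @property
    def fp_disjoint_rate(self) -> float:
        return float(np.mean(self.fp_disjoint_counts)) if self.fp_disjoint_counts else 0.0

    @property
    def tp_event_fraction(self) -> float:
        vals = [v for v in self.tp_event_fractions if v is not None]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def tp_rate_sd(self) -> float:
        return float(np.std(self.tp_counts)) if self.tp_counts else 0.0

    @property
    def fp_rate_sd(self) -> float:
        return float(np.std(self.fp_counts)) if self.fp_counts else 0.0

    def as_dict(self) -> dict:
        return {
            **self.condition,
            "n_runs": self.n_runs,
            "tp_rate": self.tp_rate,
            "fp_rate": self.fp_rate,
            "fp_disjoint_rate": self.fp_disjoint_rate,
            "tp_event_fraction": self.tp_event_fraction,
            "tp_rate_sd": self.tp_rate_sd,
            "fp_rate_sd": self.fp_rate_sd,
        }


def _tally(result, truth_entries, perf: PerformanceResult) -> None:
    truth_set = frozenset(
        (int(i), int(j)) for ds in truth_entries for (i, j) in ds
    )
    tp = fp = fp_disjoint = 0
    fractions = []
    for ds in result.structures:
        verdicts = [classify_detection(ds, t) for t in truth_entries] or ["FP"]
        if "TP" in verdicts:
            tp += 1
        else:
            fp += 1
            if truth_set and not (ds.entry_set() & truth_set):
                fp_disjoint += 1
            elif not truth_set:
                fp_disjoint += 1
        if truth_set:
            fractions.append(len(ds.entry_set() & truth_set) / len(ds.entry_set()))
    perf.tp_counts.append(tp)
    perf.fp_counts.append(fp)
    perf.fp_disjoint_counts.append(fp_disjoint)
    if truth_set and fractions:
        perf.tp_event_fractions.append(float(np.mean(fractions)))
    else:
        perf.tp_event_fractions.append(None)


def _make_rates(rate_source, analyzed, model_spec, bins, rate_width=0.200):
    if rate_source == "true":
        return true_rates(true_rate_profiles(model_spec, bins), bins)
    if rate_source == "kernel":
        return kernel_rate([analyzed], bins, shape="boxcar", width=rate_width)
    raise ValueError(f"unknown rate source {rate_source!r}")


def benchmark(
    model: int | ModelSpec = 0,
    inject: bool = True,
    n_runs: int = 20,
    rate_source: str = "kernel",
    seed: int | None = 0,
    sse: SSESpec | None = None,
    bin_width: float = 0.005,
    kernel: KernelSpec = KernelSpec(),
    mask_params: MaskParams = MaskParams(),
    cluster_params: ClusterParams = ClusterParams(),
    rate_width: float = 0.200,
) -> PerformanceResult:
    """Repeatedly simulate one background model and tally TP/FP detections.

    Each run: generate the background, optionally inject the repeated SSE at
    two random non-overlapping times, obtain rate profiles from
    ``rate_source`` ('kernel' = single-train 200 ms boxcar, 'true' =
    generative profiles), run the full pipeline, classify every found DS
    with the 50% rules.
    """
    spec = model if isinstance(model, ModelSpec) else ModelSpec(model_id=int(model))
    if sse is None:
        sse = SSESpec()
    perf = PerformanceResult(
        condition={"model": spec.model_id, "inject": inject, "rate_source": rate_source},
        n_runs=n_runs,
    )
    children = np.random.SeedSequence(seed).spawn(n_runs)
    for r in range(n_runs):
        rng = np.random.default_rng(children[r])
        background = generate_model(spec, seed=rng)
        if inject:
            analyzed, truth = inject_sse(
                background, sse, bin_width=bin_width, seed=rng,
                min_separation=kernel.length,
            )
        else:
            analyzed, truth = background, []
        binned_cfg = bin_spike_trains(analyzed, bin_width).config
        rates = _make_rates(rate_source, analyzed, spec, binned_cfg, rate_width)
        result = run_asset(
            analyzed, rates=rates, bin_width=bin_width, kernel=kernel,
            mask_params=mask_params, cluster_params=cluster_params,
            prob_method="lecam",
        )
        _tally(result, truth, perf)
    return perf


def trial_count_study(
    model: int = 4,
    estimators=("psth-10", "kernel-200", "kernel-opt"),
    trial_counts=(1, 2, 3, 5, 10),
    n_runs: int = 20,
    seed: int | None = 0,
    sse: SSESpec | None = None,
    bin_width: float = 0.005,
    in_sample: bool = True,
    **pipeline_kwargs,
) -> list:
    """Cross-trial rate estimation study (non-stationary background).

    For each estimator and trial count R: simulate R trials, estimate each
    neuron's rate profile from them, inject the SSE into the analyzed
    realization (the first trial when ``in_sample``, a fresh one otherwise)
    and run the pipeline.  Estimator names: ``psth-<ms>``, ``kernel-<ms>``
    (boxcar), ``kernel-opt``.
    """
    spec = ModelSpec(model_id=int(model))
    if sse is None:
        sse = SSESpec()
    kernel = pipeline_kwargs.pop("kernel", KernelSpec())
    results = []
    for est in estimators:
        for n_trials in trial_counts:
            perf = PerformanceResult(
                condition={"model": spec.model_id, "estimator": est, "n_trials": n_trials},
                n_runs=n_runs,
            )
            children = np.random.SeedSequence(seed).spawn(n_runs)
            for r in range(n_runs):
                rng = np.random.default_rng(children[r])
                trials = [generate_model(spec, seed=rng) for _ in range(n_trials)]
                base = trials[0] if in_sample else generate_model(spec, seed=rng)
                analyzed, truth = inject_sse(
                    base, sse, bin_width=bin_width, seed=rng,
                    min_separation=kernel.length,
                )
                bins = bin_spike_trains(analyzed, bin_width).config
                rates = _estimate(est, trials, bins)
                result = run_asset(
                    analyzed, rates=rates, bin_width=bin_width, kernel=kernel,
                    prob_method="lecam", **pipeline_kwargs,
                )
                _tally(result, truth, perf)
            results.append(perf)
    return results


def _estimate(name: str, trials, bins) -> RateProfiles:
    if name == "kernel-opt":
        return optimized_kernel_rate(trials, bins)
    kind, _, width_ms = name.partition("-")
    width = float(width_ms) / 1000.0
    if kind == "psth":
        return psth(trials, width, bins)
    if kind == "kernel":
        return kernel_rate(trials, bins, shape="boxcar", width=width)
    raise ValueError(f"unknown estimator {name!r}")


def sweep(
    n_neurons=(50, 100, 200),
    sse_lengths=(3, 5, 7),
    event_sizes=(2, 3, 5),
    n_runs: int = 20,
    seed: int | None = 0,
    rate_source: str = "kernel",
    **benchmark_kwargs,
) -> list:
    """Full-factorial detection-power sweep on the stationary background.

    Varies the total neuron count N, the number of events per SSE (l_SSE)
    and the neurons per event (xi_SSE); each cell runs :func:`benchmark`
    with an injected SSE on model-0 background.
    """
    cells = [
        (int(n), int(l_sse), int(xi))
        for n in n_neurons for l_sse in sse_lengths for xi in event_sizes
    ]
    cell_seeds = np.random.SeedSequence(seed).generate_state(len(cells)) % (2**31)
    results = []
    for (n, l_sse, xi), cell_seed in zip(cells, cell_seeds):
        spec = ModelSpec(model_id=0, n_neurons=n)
        sse = SSESpec(n_events=l_sse, event_size=xi)
        perf = benchmark(
            model=spec, inject=True, n_runs=n_runs, rate_source=rate_source,
            seed=int(cell_seed), sse=sse, **benchmark_kwargs,
        )
        perf.condition.update({"n_neurons": n, "l_sse": l_sse, "xi_sse": xi})
        results.append(perf)
    return results
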