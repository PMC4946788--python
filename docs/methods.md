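# Methods

## The detection model

The pipeline tests, for every pair of time bins `(b_i, b_j)`, whether the
overlap of active neurons is larger than chance, and whether such excess
overlap occurs *jointly* along a diagonal of the bin-pair matrix — the
signature of a repeated temporal sequence of synchronous events (SSE).

Assumptions of the null hypothesis:

* spike trains are mutually independent given their rate profiles;
* each train is (locally) Poisson, so the probability that neuron `k` is
  active in bin `b_i` is `1 − exp(−λ_i^(k) Δ)`;
* rate profiles are known or estimated well enough that residual structure
  in time is small on the scale of a bin.

Violations act in known directions: *underestimated* rates (smoothed rate
jumps) inflate significance and hence false positives; more regular-than-
Poisson inter-spike intervals raise the per-bin occupancy probability above
the Poisson value at a given rate (for gamma ISIs with shape 5 at 60 Hz and
5 ms bins, 0.299 vs 0.259) and likewise push toward false positives. The
validation harness quantifies both effects.

Entry-wise significance uses `P_ij = Pr(I < I_ij)` with a **strict**
inequality, so `1 − P_ij` is a valid (conservative, because discrete)
p-value; `P_ij = 0` whenever `I_ij = 0`. The exact Poisson-binomial pmf is
computed by iterative convolution in `O(N²)` (mathematically identical to
the `2^N` subset sum); above 30 neurons the default switches to the Le Cam
Poisson approximation with rate `Σ_k p_ij^(k)` — the sum of the Bernoulli
*success probabilities*, the only reading consistent with Le Cam's theorem.
Its total-variation error is bounded by `Σ_k (p_ij^(k))²` and the
integrated absolute error stays below 0.04 for the bin probabilities
arising at tens of Hz and 5 ms bins.

## The joint test

The kernel is realized on the lattice as per-diagonal segments: for each
diagonal offset `c ∈ {−⌊w_K/2⌋, …, ⌊w_K/2⌋}` the `l_K − |c|` consecutive
entries on that diagonal centered on the projection of `(i, j)` (rounding
half-down). Summing segment lengths reproduces the closed-form count
`n = l_K w_K − ⌊w_K/2⌋(⌊w_K/2⌋ + 1)`; this is the unique symmetric shape
with that count. Positions outside the matrix and — in symmetric mode — on
or below the main diagonal are dropped, and `n` becomes the actual count.

The tested entry itself is part of its neighborhood and eligible for the
`d`-largest selection (the kernel covers it and the count formula includes
it). Ties among equal values are broken by row-major position order. All
selected values are capped at `p_max = 0.999` before entering the joint
survival function, so one extreme isolated entry cannot reach significance
by itself while jointly large neighbors can.

The survival function of the top-`d` order statistics of `n` iid uniforms
is evaluated as the exact nested sum over non-increasing index tuples.
Numerics: exponent tuples and their log-factorial constants are tabulated
once per `(n, d)` (cached); per-entry terms are a single matrix product of
the logs of consecutive differences of the sorted values against the
exponent table, exponentiated and summed (all terms are non-negative, so no
cancellation occurs); `0^0 = 1` is honored by replacing `log 0` with a
finite sentinel that vanishes under a zero exponent; results are clipped to
`[0, 1]`. Entries are processed in chunks of 512 to bound memory. The
implementation is verified against the `1 − x^n` closed form (`d = 1`), an
exact two-sample formula, and seeded Monte-Carlo order-statistic oracles.

Because the mask requires both `P_ij > α₁` and `J_ij > α₂`, the pipeline by
default evaluates `J` only at entries already passing the first test
(`joint_entries="candidates"`); detections are provably identical to full
evaluation (asserted in the test suite) at a fraction of the cost. Full
evaluation remains available.

## Clustering

Masked entries are clustered with DBSCAN (scikit-learn, precomputed
distances) under the elliptical metric

    d_ρ(a, b) = [1 + (ρ − 1)|sin(θ − π/4)|] · sqrt((Δi² + Δj²)/2),

with `θ = arctan(Δj/Δi)` (`θ = π/2` for vertical displacements). Diagonal
steps cost exactly their bin count (`d = k` for `(i+k, j+k)`, any `ρ`),
anti-diagonal steps cost `ρk`, and `ε = 3.5` therefore bridges up to
`⌊ε⌋ − 1 = 2` empty bins between collinear entries. A plausible alternative
normalization (dropping the `1/√2`) would disconnect adjacent diagonals at
the default `ε` and fragment dense regions into per-diagonal chains; the
implemented form is the one consistent with the closed-form step costs and
the two-hole bridging rule above. `min_size = 3` acts both as DBSCAN's
core-point threshold (the point itself counts) and as a final minimum
cluster cardinality; points are processed in row-major order, making labels
deterministic. At configuration time a warning is emitted when the
`ε`-ellipse is not contained in the joint-test kernel.

Each cluster's SSE is reconstructed as `S_i ∩ S_j` per entry, ordered by
`i`; on background-free data this recovers exactly the injected groups, on
noisy data a superset when background spikes coincide.

## Rate estimation

* **PSTH**: trial-summed counts in coarse bins (≥ the analysis bin) divided
  by `R · width`, resampled piecewise-constant onto analysis bins.
* **Fixed kernel**: boxcar (default width 200 ms, the single-train
  validation setting) or Gaussian truncated at ±2.7σ (`w* = 5.4σ`). Each
  spike's kernel mass inside the observation window is renormalized to one:
  without this, rates near the window edges are systematically
  underestimated, which directly inflates downstream significance. The
  integral of the estimate then equals the per-trial spike count (asserted).
* **Optimized bandwidth**: Gaussian kernel on the spikes pooled over
  trials; σ minimizes the unbiased least-squares cross-validation cost on a
  25-point log grid spanning `[2Δ, T/2]`, per neuron. Fewer than 2 spikes
  fall back to a flat `count/(R·T)` profile. On the non-stationary
  gamma-ISI background with 3 trials the selected σ is typically 30–50 ms.

Rates are evaluated at bin centers; the per-bin probability uses that value
rather than an integral (exact for the piecewise-constant generative
profiles, which are bin-aligned).

## Synthetic data

The generators emulate controlled departures from the null: coherent and
staggered rate jumps, across-neuron rate heterogeneity, gamma-renewal ISI
regularity (equilibrium start — the first interval is drawn from the
length-biased residual distribution so the count rate is stationary from
`t = 0`; non-stationary variants warp an equilibrium unit-rate process
through the cumulative rate), compound-Poisson population synchrony (mother
rate fixed by marginal matching, `λ_m = Nλ/E[ξ]`, reproducing the stated
per-neuron rate and a pairwise binned correlation of ≈ 0.01; the mother
rate is overridable), and multiple single-interaction groups (synchronous
spikes in two random bins per group plus background topping each member up
to the nominal total rate). SIP groups default to the *top* neuron ids so
that they stay disjoint from an injected SSE's conventional groups; a
collision would create genuine repeated synchrony across the two structures
and is available explicitly via the `groups` argument.

Injected SSEs add one spike per member neuron at the center of each target
bin (any within-bin position is equivalent after binary binning; collisions
with background spikes are absorbed by clipping). Events occupy consecutive
bins by default; per-repetition, per-event bin shifts encode holes and
wiggliness. Occurrence times are drawn uniformly with at least `l_K` bins
between repetitions so that two occurrences never fall inside one kernel
window. The injection returns the exact ground-truth entry list, one
diagonal structure per repetition pair.

What the generators do **not** emulate: network-driven correlations beyond
the stated constructions, cross-trial non-stationarity and latency jitter,
refractoriness, and electrode artifacts. Passing benchmarks on these models
therefore demonstrates statistical calibration and power under the stated
departures, not robustness to every feature of recorded data.

## Surrogate (Monte-Carlo) null

Bin shuffling permutes occupancy columns (one permutation per surrogate,
applied to both matrix axes), preserving within-bin synchrony while
destroying temporal order; probability matrices are recomputed with the
*original* rate profiles. The kernel-filtered statistic uses the product
formula over the `d` largest neighbors without capping — the rank
comparison applies the same statistic to both the observed and surrogate
matrices, so a cap would cancel. Ties count as non-exceeding, per the
estimator's definition. Per-surrogate seeds are spawned from the master
seed, so results are independent of execution order. A warning is issued
when `1/S` exceeds `1 − α₂` (threshold unreachable).

## Benchmarking scales

The validation harness uses 20 realizations per condition (50 for the
staggered rate-jump model) with 100 neurons on a 1 s window at 5 ms bins —
sizes at which binomial/Poisson error bars remain informative (SE ≈ 0.05 on
a TP proportion) while a full sweep completes in minutes on one core. The
trial-count study estimates rates from `R` freshly simulated trials and
analyzes the first of them with the SSE injected (rates partially
in-sample; an out-of-sample flag exists).

## Known limitations

* The joint test is exact under independence of the neighbor values;
  entries sharing a bin index are weakly dependent, making the test
  slightly conservative in dense regions.
* Minimum-size clusters (3 entries) can arise from triple chance
  coincidences; backgrounds with population synchrony (compound-Poisson
  events in ~30% of bins) produce such clusters at a measurable rate
  (~0.5/run at the default thresholds) even though each entry only
  marginally exceeds `α₁`.
* Any smoothing rate estimator underestimates instantaneous rate steps at
  their edges; combined with gamma-regular ISIs this leaves residual false
  positives inside coherent jump windows that more trials reduce but do not
  eliminate.
* Exact Poisson-binomial evaluation loops over bin pairs and is intended
  for ≤ 30 neurons or small matrices; the Le Cam path is fully vectorized.
* The nested-sum evaluation is exponential-ish in `(n, d)`; the validation
  guard assumes `n ≲ 50`, `d ≲ 10`.
* Spike-dithering surrogates and n-dimensional (triplet) intersection
  extensions are out of scope; bin shuffling is the only surrogate null.
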