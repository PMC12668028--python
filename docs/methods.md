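# Methods

## The integrate-and-fire avalanche model

Non-leaky integrate-and-fire units sit at random positions in a cube of
side L = (N/0.016)^(1/3) (constant density). Each neuron draws an
out-degree k from P(k) ∝ k⁻² on [2, 20] (N ≤ 100; [2, 100] above) and
wires to k distinct targets with probability ∝ e^(−r/5) in the Euclidean
distance r; 20% of neurons are inhibitory; initial strengths g ∈
[0.4, 0.6] uniform. When vᵢ ≥ v_c = 1, neuron i fires: every target j
receives ±vᵢuᵢg_ij (− for inhibitory senders), vᵢ resets to 0, the
resource pool uᵢ shrinks by the factor 1 − δu (δu = 0.05), and i is
refractory for one timestep. All supra-threshold non-refractory neurons
of a timestep fire synchronously; inputs are summed before the next
threshold test. A refractory neuron accumulates input but cannot fire.

Avalanches are separated in time scale from the drive: a quiescent
timestep adds δv = 0.1 to one uniformly random neuron; once any
potential crosses threshold, the drive is suspended until all potentials
drop below threshold again. At each avalanche end every pool recovers,
uᵢ → min(1, uᵢ + δu_rec). The recovery increment δu_rec is the single
control parameter: starving the synapses (small δu_rec) produces small,
short avalanches; over-recovery produces system-spanning bursts.

**Long-term plasticity.** During an avalanche each used synapse is
potentiated by δg = β·|Δv| (β = 0.04, applied to inhibitory synapses
identically); at the avalanche end all synapses are depressed by the
mean increment per synapse, with g clipped to [10⁻⁵, 1]. Pre-training
applies this rule for 10⁴ avalanches or until a strength first reaches
g_min = 10⁻⁵. Because the very first avalanche from the cold start
(v = 0, u = 1, slow drive charging the whole network) is a giant
transient whose depression step would erase the strength distribution in
one move, pre-training first settles the network for 500 avalanches with
plasticity off; measurement runs likewise discard a warm-up stretch
(≥ 1000 avalanches) so that u has reached its stationary distribution.

**Calibration.** The critical point δu_rec^crit(N) is located by
scanning a geometric grid, classifying each candidate's avalanche
statistics (below), and taking the geometric middle of the critical
plateau. The shipped table (N = 20…100: 3.8, 5.1, 4.2, 4.2, 3.2 ×10⁻³)
was derived from three network realizations per size; off-critical
states use 0.1× and 10× these values. The critical point carries
realization-to-realization scatter from the quenched topology disorder,
so analyses that condition on a dynamical state first verify a
realization's classification.

## Avalanche-state classification

The discriminating statistic is the cutoff of the size distribution
relative to system size, summarized by the 99th percentile q99:
subcritical when q99 < N/2 (decay well before the system scale),
supercritical when q99 > 2.5N or when the log-binned density (bin ratio
2^(1/4)) shows a valley-to-peak rise > e^0.8 across ≥ 50-event bins
beyond N/2 (the bump of system-spanning avalanches), critical otherwise.
A discrete power-law vs geometric likelihood ratio (MLE on S ≥ 2,
Hurwitz-zeta normalization) is reported as evidence but is deliberately
not decisive: on short-cutoff data the two tail models are nearly
indistinguishable, and at N ≤ 40 the geometric wins regardless of state.
Classification needs ≥ 10³ avalanches; quantile-based statistics make it
insensitive to catalog length above that.

## Raster statistics

Events are binned into windows of Δt_b = 5 timesteps (model) or 25 ms
(recordings); σᵢ(k) = +1 iff channel i fired at least once in bin k;
trailing partial bins are dropped. Moments ⟨σᵢ⟩, ⟨σᵢσⱼ⟩, covariances
Cᵢⱼ and the synchrony distribution P(K) carry standard errors from up to
100 contiguous blocks of bins (blocked rather than i.i.d. resampling, to
respect temporal correlation). Firing rates are rᵢ = (⟨σᵢ⟩+1)/(2Δt_b);
their total n_a scales sublinearly with N (allometric exponent η < 1 in
all three dynamical states; log–log least squares with bootstrap over
replicates). Three-point correlations are the centered triple moments
Tᵢⱼₖ, computed per channel i by one rank-reduced matrix product (O(N²·
bins) per i).

## K-pairwise maximum-entropy model

H(σ) = −Σ hᵢσᵢ − ½Σ_{i≠j} Jᵢⱼσᵢσⱼ − Σ_K V_K δ(K, K′(σ)), with K′ the
number of up-spins. V₀ = 0 fixes the gauge freedom left by the
normalization of P(K). Remaining redundancy between V_K and uniform
shifts of h is left to the learning dynamics.

**Sampling.** Single-spin-flip Metropolis with cached local fields:
an attempt costs O(1), an accepted flip O(N). Burn-in 150N attempts.
Means, P(K) and energy/magnetization accumulate every attempt; pair
moments accumulate once per sweep of N attempts for N > 16 (O(N)
amortized; every attempt for small N). Exact enumeration of all 2^N
states (N ≤ 20, chunked, log-sum-exp stabilized) provides the oracle
for every sampled quantity.

**Inverse problem.** Boltzmann-machine learning with θ(n) = θ₀n^(−α),
couplings at rate θ/2, V_K at rate θ switched to θ/P(K)_data after the
warm-up iteration; h initialized at the data means, J = V = 0; one
persistent chain re-burned each iteration. Only V_K with P(K)_data
above 10⁻⁵ (≥ 10⁶ bins) or 10⁻⁴ (shorter recordings) are learned.
Parameters are averaged over the final 20% of iterations
(Robbins–Monro tail averaging), which removes the O(θ·noise) jitter of
the last stochastic update; with the reduced schedule below this
recovers all moments of a known N=10 model within one standard error.
Learning aborts if any parameter exceeds 10³ in magnitude.

Near the sampling threshold the learned V_K are noisy and systematically
inflated: with rate θ/P(K) a K bin holding only tens of events (data
side) and a handful per iteration (model side) receives enormous,
noise-driven updates. Analyses of V structure therefore distinguish
well-sampled K (P(K) ≥ 10⁻²) from threshold-adjacent K.

## Thermodynamics

P(σ, T) ∝ e^(−H(σ)/T) rescales all parameters by 1/T; T = 1 is the
data-fitted model. C_v = Var(H)/T² and χ = Var(M)/T per chain, with
errors across independent chains; H is always the T = 1 Hamiltonian.
The default grid is 60 geometric points on [0.01, 3] plus a 21-point
linear insert on [0.8, 1.6] where the maxima live; maxima are refined
by a local 5-point quadratic fit, and edge maxima are flagged.

Below a temperature T* the sampler is no longer ergodic: random-start
chains freeze into different metastable valleys, so C_v and χ acquire
order-of-magnitude chain-to-chain scatter while reference chains started
from the all-silent state stay frozen near zero — the low-T divergence
is a sampling artifact, not an equilibrium property. T* is the largest
grid temperature below which random-start and silent-start curves
disagree by > 3 combined standard errors on two consecutive grid points,
compared on log scale (on linear scale the artifact inflates the error
bars as fast as the gap, and the z-score saturates below threshold).
Scaling analyses therefore use maxima restricted to T above the glassy
region (T ≥ 0.75 at the sizes used here).

Finite-size scaling of max C_v and max χ is log–log least squares over
per-size replicate means, with the exponent error bootstrapped over
replicates (10³ resamples).

## Reduced study conditions used by the test suite

Full-scale conditions (10⁷ bins, 2×10⁵ BM iterations × 3×10⁵ attempts,
N up to 100, five replicates) are cluster-scale. The shipped tests run:
recordings of 5×10⁵ bins; BM schedules θ₀ = 0.3, α = 0.5, 3.5×10³
iterations × 4–6×10⁴ attempts; fits at N = 20 and 40 with three
replicates; oracle comparisons at N = 6–12. The acceptance script uses
four N=100 replicates of 1.2×10⁵ bins each.

What these conditions demonstrate: oracle-exact sampling and
thermodynamics; parameter recovery; the sub/critical/supercritical
dynamical taxonomy and its monotone dependence on δu_rec; the silent-bin
probability of the critical model; the critical-fit V_K shape (negative
dip at low K/N, positive mid-range); interior C_v/χ maxima above T = 1
that grow from N = 20 to N = 40; and a finite glassy onset T* < 1 for
critical and supercritical fits but not for independent-spin or small
oracle models.

What they do not: the asymptotic finite-size exponents (the N = 20 to
40 growth of the maxima is positive but still below its large-N slope,
which develops toward N = 100, beyond the suite's budget), the
deep-subcritical regime in which V_K
vanish entirely (at 0.1× the calibrated critical point our subcritical
rasters retain a genuine synchrony tail that demands nonzero V_K — a
pairwise-only fit misses its P(K) by orders of magnitude), and
~10-fold per-step firing-rate contrasts between adjacent states (our
calibration yields ≈3× and ≈6× per step, ≈18× end to end), and
supercritical high-K synchrony potentials at N = 40, whose recordings
have no sampled P(K) support beyond K/N ≈ 0.6.

The synthetic generator emulates spike rasters, not recordings: no
electrode noise, no LFP deconvolution, no per-channel detection
thresholds, and silent-bin probabilities in the model band (~0.6) rather
than the much sparser experimental band (~0.9). Conclusions about real
multi-electrode data require the ingestion path (`ingest_recording`)
plus the caveats above.

## Numerical choices and degenerate inputs

Weighted sampling without replacement of synaptic targets uses the
exponential-keys trick; out-degrees exceeding N−1 are truncated with a
warning. Empty event lists bin to valid all-silent rasters; an empty
avalanche catalog, a zero-bin raster, and fits from fewer than 10⁴ bins
are errors. Model files round-trip bit-exactly (repr-serialized
floats). Metropolis chains, simulator streams and per-stage pipeline
seeds all derive from single master seeds via independent substreams;
reruns are bit-reproducible on a fixed software stack.
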