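# Methods

This note records the model as implemented, the numerical conventions the
results depend on, and the choices made where the design was genuinely
open. Symbols follow the package's parameter tables
(`NeuronParams`, `PlasticityParams`, `SimParams`).

## Network and neuron model

A single conductance-based leaky integrate-and-fire neuron receives
`N = 1000` plastic excitatory inputs and 200 inhibitory inputs of fixed
unit weight, all Poisson. Membrane dynamics:

    C_m dv/dt = (v_rest − v)/R_m + g_exc (E_exc − v) + g_inh (E_inh − v)

with C_m = 200 pF, R_m = 100 MΩ (leak 10 nS), v_th = −54 mV,
v_rest = −70 mV, E_exc = 0 mV, E_inh = −70 mV. On a threshold crossing the
neuron spikes and resets to rest; there is no refractory period beyond the
reset.

Synaptic conductances are alpha functions with τ_exc = τ_inh = 5 ms.
A spike through synapse j adds a transient
`g(s) = ĝ · w_j · (s/τ) · e^(−s/τ)` that peaks at `ĝ · w_j / e` at
`s = τ` (ĝ_exc = 0.15 nS, ĝ_inh = 0.25 nS, inhibitory weight fixed at 1).
The kernel is realized exactly by a two-variable linear system `(h, g)`
advanced with its matrix exponential each step; only the membrane equation
uses forward Euler (Δt = 0.5 ms). **Normalization choice**: the amplitude
convention is the standard simulator idiom in which a spike adds the
impulse `ĝ·w` to the auxiliary variable (peak conductance `ĝ·w/e`), rather
than a peak-normalized kernel. The two conventions differ only in an
overall conductance scale (a factor e ≈ 2.72); a sensitivity comparison of
the two on the default receptive-field protocols showed the adopted
convention reproduces the expected spineness operating point (mean spine
μ ≈ 0.10–0.11) with the cleaner symmetric outcome for equal-correlation
input blocks, and it matches how
conductance-amplitude parameters are conventionally interpreted in common
simulators.

## Plasticity

All six rules share trace-based, all-to-all pair STDP. Traces obey
`τ_STDP dz/dt = −z` with τ_STDP = 20 ms and are incremented **by 1** on
each spike — not by 1/τ_STDP. With λ = 0.006, a 1/τ increment would make
single pre/post pairings jump weights by ~0.3 and destroy learning; the
unit increment matches the exponential pair kernel with unit amplitude and
standard simulator practice.

Event ordering inside one integration bin:

1. decay all traces;
2. presynaptic spikes: depression `w_i ← w_i − λ α f₋(w_i) z_post`
   (using z_post from before any same-bin postsynaptic spike), then
   `z_pre,i += 1`, then conductance injection at the updated weight;
3. membrane update and spike detection;
4. on a postsynaptic spike: potentiation `w_i ← w_i + λ f₊(w_i) z_pre,i`
   for every synapse (a same-bin pre→post pairing counts as causal), then
   `z_post += 1`;
5. spineness relaxation (FS rule).

Weights are hard-clipped to [0, 1] after every update. Depression uses
`|w − w₀⁻|^μ` on both sides of the lower soft bound w₀⁻ = 0.5;
potentiation uses `(w₀⁺ − w)^μ` with w₀⁺ = 1.

The spineness map `τ_μ dμᵢ/dt = −(μᵢ − (wᵢ + a)/q)` is advanced with its
exact exponential relaxation each step, holding w at its current value
(exact between plasticity events), and **clipped at zero**: with the
default targets (μ_filo = 0.01 at w = 0.1, μ_spine = 0.1 at w = 0.75) the
solved constants are a ≈ −0.0278, q ≈ 7.222, so the fixed point a/q at
w = 0 is negative, and a negative exponent would invert the soft-bound
geometry. The fixed point is read as (w + a)/q, the form consistent with
the defining two-point solve for (a, q). Initial conditions: w = 0.3
(avoids quiescence), μ = 0 (all synapses start filopodial).

## Correlated input generator

The generator draws a Bernoulli(r·Δt) reference train and lets neuron i
copy reference bins with mixing weight c_i:
`P(spike | ref) = rΔt + c_i(1 − rΔt)`, `P(spike | no ref) = rΔt(1 − c_i)`.
Marginal rates equal r exactly for every c_i, and bin-level correlations
are exactly `corr(X_i, X_j) = c_i c_j` at zero lag and zero elsewhere
(rank-1 family). Bins are half-open `[t, t + Δt)`, 0-based; the spike time
of bin k is kΔt. The structure is held fixed within a protocol phase and
switched instantaneously at phase boundaries; rasters are drawn in 1 s
blocks, which is statistically equivalent to any other regeneration
granularity because the reference construction is memoryless across bins.

Structures: von Mises (evenly spaced neuron angles on [0, 2π), density
rescaled so Σc_i = c_tot, κ = 8 by default), squared pulse (N_tot = 200
contiguous neurons at c_tot/N_tot, placement configurable and
permutation-irrelevant), and Gaussian samples (clip negatives at zero
first, then rescale to c_tot).

## Mean-field theory and its oracle

For a linear Poisson readout (rate `(1/N) Σ w_i S_i(t − ε)`, delay ε of
one bin) the ensemble drift is

    dw_i/dt = (λ τ r²/N) [ −Δf(w_i) Σⱼ wⱼ + f₊(w_i) Σⱼ wⱼ C⁺ᵢⱼ ]

with Δf ≡ f₋ − f₊ (α folded into f₋). **Sign convention**: with α > 1,
competition corresponds to Δf > 0 entering with the minus sign; factor
tables that print the competition column as f₊ − f₋ are sign-flipped
relative to this definition and are not followed.

**Self-term**: off-diagonal `C⁺ᵢⱼ = c_i c_j/(τ r)`, but the self-term kept
in the j-sum is `C⁺ᵢᵢ = 1/(τ r)` — a Poisson train's normalized
autocorrelation carries a δ(Δt)/r peak regardless of c_i, so every synapse
cooperates fully with itself. At N = 1000 the distinction is invisible
(O(1/N)); on the 10-synapse validation system it is essential — with the
rank-1 value c_i²/(τr) the simulated drift exceeds the prediction by a
bias of λ f₊ w_i r/N per synapse, comparable to the drift itself.

The stochastic validation ensemble (`simulate_linear_poisson`) runs many
independent realizations from the same initial weights at λ/10, with a
0.2 s warm-up during which traces and the postsynaptic process run but
weights are frozen, so measurement starts from stationary traces. The
measurement window is kept short (1.5 s) because the drift itself moves w
and bends the trajectory (an O(λ·T) bias, steepest for mlt/mlt whose
factors vary fastest in w); Δt = 0.1 ms keeps discretization biases at the
few-per-mil level (each trace-pairing term carries O(Δt/τ) corrections).

## Protocols and metrics

* **RF formation**: one phase, 200 s at r_pre = 30 Hz (inhibition 10 Hz
  throughout). Synapses are labeled spines when their mean weight over the
  final 10 s is at or above w₀⁻, filopodia otherwise. The graded-
  representation score is the Pearson correlation between spine efficacies
  and their c_i (spine-only by default; an all-synapse variant is
  available via the metrics module).
* **Discrimination index**: plasticity frozen (the protocol measures the
  formed RF, not further learning; configurable), r_pre = 10 Hz, the
  preferred pattern measured for 100 s and each rotation for 1 s;
  DI(θ) = (y_pref − y_θ)/(y_pref + y_θ), averaged over a configurable
  subsample of 16 evenly spaced rotations (unbiased under rotation,
  desk-scale runtime). Angles where both rates vanish are excluded with a
  warning.
* **Consolidation**: pattern A for 200 s, then pattern B (A rotated by π)
  for 400 s. The A-alone reference RF is the same run's state at the end
  of phase A (identical protocol prefix); the B-alone reference is a
  separate run. Memory presence is cosine overlap ≥ 0.5 against each
  reference; regimes: both present → partial overwriting, only B → total,
  only A → none, neither → unformed (the fourth class covers grids where
  no RF forms at all).
* **Sweeps** iterate an (α, c_tot) grid over seeds and tabulate r, DI, or
  regimes; per-cell failures are recorded and the sweep continues.

## Problem sizes in the test suite

The automated suite runs the full 1000-input network at the default
200 s for the spineness and two-stage-competition checks (two seeds each),
and scales the consolidation grid to 100 s of pattern A plus 200 s of
pattern B per cell (3×3 grid in α ∈ [1.05, 1.35] × c_tot ∈ [60, 120], two
seeds, μ_spine ∈ {0.1, 0.3}, plus the additive control). Formation is
essentially complete within the first 100 s at these parameters, so the
scaled protocol preserves the regime structure; the α and c_tot ranges
were chosen, as in the full-scale sweeps, so that a receptive field always
forms from the homogeneous initial state while both protected and
overwriting outcomes occur within the grid.

## Determinism

Every entry point is reproducible from (configuration, seed). Random
streams derive from `SeedSequence([seed, crc32(label)])`, with distinct
labels for input generation, initial conditions, and protocol stages;
records embed the generating configuration and are bit-stable through
HDF5 round trips.

## Known limitations

* The mean-field expression assumes the linear Poisson readout; for the
  LIF network it is qualitative (the LIF's coincidence detection
  strengthens cooperation beyond the linear prediction), which is the
  expected and documented behaviour of this approximation.
* Only the rank-1 correlation family is generated (no arbitrary
  cross-correlation matrices, no backward pre-after-post correlations).
* No triplet STDP, inhibitory plasticity, stochastic release,
  multi-compartment structure, or AMPA/NMDA channel separation.
* Exact subthreshold integration (exponential integrators) is not
  implemented; the forward-Euler membrane error is first order in Δt and
  validated by a halving test.
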