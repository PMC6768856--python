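# Methods

## Model

`fluctmem` simulates a recurrent firing-rate network of N neurons whose
state vector **x** (synaptic input) evolves as

    dx/dt = -x + W φ(x) + b(t)

with recurrent weights W (entry W_ij: synapse from neuron j to neuron i),
a pointwise nonlinearity φ and an external input **b**. Time is measured
in units of the neural time constant; integration is explicit Euler with
step dt = 0.1 (configurable for convergence tests). The weights co-evolve
with activity on a slower timescale,

    dW/dt = η (Δ_L + Δ_F),      η = 0.01,

where Δ_L is the learning operator and Δ_F collects the processes that
endanger stored memories: white activity-independent synaptic noise
ξ_ij ~ N(0, 1/N), drawn freshly for every weight update and independently
across synapses, plus one of three homeostatic mechanisms:

* **dissipation** Δ_F = ξ − βW with β = 0.1: every weight decays; all
  spectral structure decays at rate ηβ = 10⁻³ regardless of coding.
* **rate control** Δ_F = ξ + [(φ₀ − φ(x)) φ(x)ᵀ] ∘ W (Hadamard product):
  multiplicative scaling of each synapse by a factor depending on the
  postsynaptic rate error and the presynaptic rate; targets φ₀ are drawn
  once per run from U[−1, 1].
* **decorrelation** Δ_F = ξ + I − φ_post(x) φ_pre(x)ᵀ with
  φ_pre = φ(x), φ_post = φ(x − x̄), where x̄ is a slow average of x
  (timescale τ_x = 20): an anti-Hebbian term that suppresses whichever
  mode currently dominates activity, balanced against a uniform
  diagonal growth term.

### Memory coding

A memory is a low-rank perturbation of W built from a pattern pair
(u, v), entries ~ N(0, 1/N). The symmetric perturbation uuᵀ adds a real
outlier eigenvalue (a fixed-point memory, as in the Hopfield picture);
the anti-symmetric perturbation ρ(uvᵀ − vuᵀ) adds a conjugate pair ±iρ
whose invariant plane span{u, v} carries a limit-cycle attractor. In
continuous time the limit cycle requires an additional symmetric
in-plane term γ(uuᵀ + vvᵀ) with γ > 1; with γ = 0 the origin is globally
stable and the orbit exists only for the discretized (Euler dt = 0.1 or
synchronous-map) dynamics. Multiple memories combine as W = U D Uᵀ with
interleaved pattern columns and 2×2 rotation blocks.

### Learning rule

Averaging an exponential spike-timing kernel (amplitudes a_P > 0,
a_D < 0, timescales τ_P, τ_D) over a rate description gives

    Δ_L = a_P φ y_Pᵀ + a_D y_D φᵀ,

where y_P, y_D are first-order low-pass filters of φ(x) with timescales
τ_P, τ_D (τ = 50 in the anti-symmetric case). Note the sign convention:
depression enters with its negative amplitude, so that for τ_P = τ_D and
a_D = −a_P the operator is purely anti-symmetric,
Δ_L = a_P (φ yᵀ − y φᵀ), and can only write to the anti-symmetric
(imaginary-coded) part of W. η multiplies the sum (Δ_L + Δ_F) once, in
the weight update, never inside the terms.

## Key parameter choices

| parameter | default | why |
|---|---|---|
| N | 128 (64 in scaled-down experiments) | published network size; experiments scale down to keep runs in seconds–minutes |
| dt | 0.1 | published integration step |
| η | 0.01 | published plasticity rate |
| τ (STDP filter) | 50 | published filter timescale |
| τ_x (decorrelation) | 20 | published slow-average timescale |
| β | 0.1 | published dissipation rate |
| ξ variance | 1/N per step | published noise scale; a √dt (diffusion) convention is available via `noise_convention` |
| OU stimulus timescale | 0.01 | published value; far below dt, so the planar drive is effectively white across steps (asserted by test) |
| stimulus amplitude A | 10 | matches the published retrieval-pulse scale c_u = 10; the stimulus amplitude itself is not published |
| STDP gain a_P | 30 (learning experiments) | not published; calibrated once so a 100-time-unit stimulus at η = 0.01 writes an imaginary outlier clearly outside the spectral bulk |
| retrieval cue | amplitude 10 along u for 2 time constants | published |
| γ (retrieval) | 1.5 | a value > 1, required for a persistent orbit in continuous time |
| erosion embedding | outlier at 3× the spectral-bulk radius | clearly resolvable without destabilizing the run |

## Nonlinearity and the stationarity of homeostasis

The default φ is tanh. The homeostatic experiments use the
rectified-linear φ(z) = max(−5, z) instead, for a structural reason that
the package documents as its own finding:

* With tanh, the decorrelation rule has no stationary state. The +I term
  injects trace at rate ηN while the anti-Hebbian term, bounded by
  |tanh| ≤ 1, can at most balance it when every neuron is both saturated
  and perpetually transitioning. The network instead falls into a static
  saturated state where x̄ → x, φ_post → 0 and the rule switches off
  entirely, after which the spectrum drifts without bound.
* With the unbounded rectified-linear φ (the "negative threshold"
  variant), strongly driven modes produce unbounded anti-Hebbian
  feedback, so every unstable mode is hammered back below the edge as
  soon as it activates. The network settles into a stationary
  edge-of-instability recycling state (verified stable for ≥ 5000 time
  units at N = 64) with ongoing moderate activity.

In that stationary state the differential erosion emerges cleanly: a
real-coded outlier destabilizes the origin, is expressed in activity and
is actively suppressed within tens of time units, while an
imaginary-coded pair leaves the origin stable (Jacobian eigenvalues
−1 ± iρ), is never expressed, and erodes only through slow noise
diffusion — half-life ratios ≫ 10.

The multiplicative rate-control rule deserves a caveat that the erosion
suite makes explicit (one acceptance test is expected to fail, and is
left failing deliberately). Because the rule multiplies W entrywise, its
average effect on a coherent zero-mean Gaussian mode is proportional to
odd moments of the pattern entries, which vanish: the erosion of uuᵀ it
produces is O(1/N) at best. At the same time, entries with persistently
favorable rate-error sign grow exponentially under sustained saturated
activity, so every active regime eventually diverges, and every
quiescent regime (x = 0 is an exact fixed point of the activity
equation) leaves both memory codings untouched. We therefore demonstrate
differential erosion with the decorrelation rule, and report the
rate-control variant faithfully as implemented.

## Learning experiments

Learning runs start from W = 0 (compact, constant pre-learning spectrum)
with a quiescent network and use the rate-control rule as the
homeostatic background: its quiescent state is exactly inert, so the
anti-symmetric STDP term only integrates stimulus-driven activity and
the learned eigenplane matches the stimulated plane with normalized
overlap > 0.9. Under the decorrelation background the diagonal growth
term makes every mode marginal by t ≈ 1/η = 100 and the resulting
churning activity writes broadband anti-symmetric structure through the
high-gain STDP term, burying the stimulated plane; the two backgrounds
give the same qualitative learning result, and the package defaults to
the clean one.

The learned rotation direction is a spontaneously broken symmetry: for
an uncorrelated planar drive the expected wedge ⟨φ_u y_v − φ_v y_u⟩
vanishes, and the memory grows by self-amplification of an initial
fluctuation (any nascent in-plane rotation skews the lagged activity
correlations in its own favor). Strength therefore grows monotonically
with stimulation duration, with a seed-dependent sign of the rotation —
the spectral readout |Im λ| is sign-blind.

## Retrieval and the reduced model

With frozen connectivity, W = ρ(uvᵀ − vuᵀ) + γ(uuᵀ + vvᵀ), trajectories
from inside and outside converge to one closed orbit in the overlap
coordinates p_u = uᵀx/√N, p_v = vᵀx/√N; with M embedded planes a brief
cue along u⁽¹⁾ retrieves plane 1 (r₁ dominating every other r_k). The
2-D reduction for a step-like nonlinearity,
ṗ_u = −p_u + ρ q_v (+γ q_u), ṗ_v = −p_v − ρ q_u (+γ q_v) with
q_v = arctan(p_v/|p_u|) and the symmetric completion
q_u = arctan(p_u/|p_v|), reproduces the orbit topology, its ρ- and
γ-dependence and its loss at γ = 0, dt → 0. Its amplitude, however, is
systematically ~40–55% larger than the full model's: the arctan
approximation overestimates the in-plane drive relative to the exact
Gaussian average for a hard sign nonlinearity, q = √(2/π) p/r. Both q
forms are implemented (`q_form="arctan" | "gaussian"`); the Gaussian
form agrees with the full model within 10% and serves as the package's
quantitative cross-check, while the arctan form is retained as the
documented reduction. The corresponding acceptance test asserts the 10%
agreement for the arctan form and is expected to fail; it is left in
place as an honest record.

## Capacity

Capacity runs use the synchronous discrete-time map x' = sign(Wx) with
γ = 0 and binary ±1/√N planar patterns. Binary patterns matter: they
make each memory's four cycle phases (u, −v, −u, v) exact states of the
sign map, giving Hopfield-like error correction; with Gaussian patterns
the map renormalizes the state globally, crosstalk overlaps condense,
and measured capacity collapses. A retrieval trial cues one plane
(pattern + 10% Gaussian noise) and succeeds if the time-averaged target
overlap over the trailing half of 60 steps exceeds 0.7 of its
single-memory value; the identical protocol is applied to the symmetric
Hopfield baseline. The critical load (success rate crossing 1/2,
linearly interpolated) is reported as 2M/N for the planar model — two
pattern vectors per memory — and M/N for Hopfield. Measured values:
2M/N ≈ 0.28–0.31, roughly constant over N ∈ {128, 256, 512} and above
the Hopfield baseline's ≈ 0.18–0.24.

## Lifecycle and contribution accounting

The lifecycle run (N = 128, decorrelation rule, horizon 4000) learns two
planes (100-time-unit OU stimuli), retains them under ongoing noise and
homeostasis, then applies retrieval pulses to each plane and to a novel
plane. Readouts: the plane overlaps r₁, r₂, r₃ (retrieval produces a
transient, selective, oscillatory excursion on the cued plane only), and
the contribution accounting — temporal averages of (1/N²) Σ|Δ_ij| for
the activity-dependent terms (Δ_L + homeostatic) versus the spontaneous
noise ξ. The noise average equals the half-normal mean √(2/(πN))
analytically; the activity-dependent average lands within a factor of
three of it under the default protocol, i.e. directed and spontaneous
plasticity are of similar magnitude throughout the memory's life.

## What the synthetic conditions do and do not show

All inputs are generated internally (random connectivity, Gaussian or
binary patterns, OU stimuli); there is no external data. The generator
reproduces the published study conditions where stated (N, dt, η, τ, β,
noise scale, cue shape) and otherwise uses fixed, documented choices
(initial W, stimulus amplitude, STDP gain, embedding amplitude,
protocol timings). Passing tests therefore demonstrate the internal
consistency and the claimed dynamical mechanisms of the model — not that
biological synapses follow these rules. Notable idealizations: no
activity noise in the state equation (the only stochasticity is
synaptic); instantaneous rates rather than spikes (the STDP rule is the
rate-averaged reduction of a spike-timing kernel); Gaussian patterns
with exact orthonormalization only where analytic spectra are asserted.

## Numerical details

* Explicit Euler throughout; the per-step weight noise is included in
  Δ_F like any other term (`per_step`), matching the published numerics;
  a `sqrt_dt` diffusion convention is available.
* Eigenvalue trajectories are matched between snapshots by a
  minimum-cost assignment (Hungarian algorithm) with cost
  |Δλ|/s + (1 − |⟨v, v'⟩|), s the median nearest-neighbour spacing of
  the previous spectrum; value-only matching provably swaps crossing
  conjugate pairs, and a constructed crossing family is part of the
  test suite.
* Plane overlaps orthonormalize each spanning pair, then report
  √(r_u² + r_v²); the normalized variant divides by √2 so identical
  planes score 1. Degenerate (collinear or zero) spanning vectors raise
  a dedicated error.
* Half-lives are measured on the memory-matched spectral amplitude
  (eigenvector-matched real part, or |Im| of the best-overlap pair),
  baseline-subtracted against the pre-embedding level, with linear
  interpolation between snapshots; runs that never cross half are
  reported as not-decayed and enter ratios at the observation horizon
  (a lower bound).
* The sign nonlinearity maps 0 to 0; discrete-time retrieval protocols
  break ties upward explicitly so no unit goes permanently silent.
* Erosion embeds at t = 2500 of a 5000-time-unit horizon and re-draws
  the (otherwise fully decayed) activity state at the embedding event,
  so the stability of the perturbed connectivity is actually probed.
* Problem sizes in tests and the acceptance script are scaled down
  (N = 64 for erosion/learning, N = 128 lifecycle, N ≤ 512 retrieval
  and capacity); the mechanisms are size-robust and the published sizes
  are reachable by raising N in the config.

## Known limitations

* The rate-control rule reproduces neither stationary homeostasis nor
  real-memory erosion as printed (see above); its operator-level algebra
  is fully tested, and the erosion experiment reports what actually
  happens (quiescence or divergence, depending on regime).
* The arctan reduced model is a qualitative oracle only; quantitative
  cross-checks use the Gaussian mean-field form.
* Capacity is measured for binary planar patterns; Gaussian-pattern
  capacity in the discrete map is far lower and not proportional to N.
* With tanh, long decorrelation runs drift (no stationary state); keep
  horizons ≲ 1000 or use the rectified-linear φ.
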