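# Methods

This note documents the model implemented by `eqprop`, the numerical
choices behind it, what the synthetic data generator does and does not
emulate, and the known limitations.

## Model and objective

The network is a continuous-valued rate model with symmetric synapses. The
full unit vector `u` splits into clamped inputs `x` and the free state
`s = {h, y}` (hidden and output units). The internal energy

    E(u) = ½ Σ_i u_i² − ½ Σ_{i≠j} W_ij ρ(u_i) ρ(u_j) − Σ_i b_i ρ(u_i)

combines a leak term pulling every potential toward its resting value 0, a
Hebbian pairwise term over connected unit pairs, and a bias term. The
pairwise sum is implemented over unordered masked pairs, which is
equivalent to the ½-weighted double sum over ordered pairs. The quadratic
cost `C = ½‖y − d‖²` acts as an external potential on the outputs, and the
total energy `F = E + βC` weights it by the clamping factor β, which may
take either sign.

The training objective for one example is `J(θ) = C(s⁰_θ)`: the cost at the
free fixed point, itself an implicit function of the parameters
θ = (W, b). The contrastive estimator

    Δθ = −(1/β) (∂F/∂θ |_{u^β} − ∂F/∂θ |_{u⁰})

approaches −∂J/∂θ as β → 0. For this energy, ∂E/∂W_ij = −ρ(u_i)ρ(u_j) on a
tied pair and ∂E/∂b_i = −ρ(u_i), so the update reduces to a difference of
local co-activities at the two fixed points. The estimator is written
against `∂F/∂θ` via a `cost_param_gradient` hook (identically zero for the
quadratic cost), so both algebraically equivalent forms — the total-energy
difference and the free-point-cost-corrected form — are available and are
exact duplicates whenever the cost carries no explicit parameter
dependence. The bias update uses the same two-point form as the weights;
it is forced by differentiating E even though only the weight rule is
usually quoted.

## Dynamics and fixed points

The free state follows synchronous discretized gradient descent on F with
step ε and a clip to [0, 1]:

    s ← max(0, min(1, s − ε ∂F/∂s)),
    ∂F/∂s_i = s_i − ρ′(s_i)(Σ_j W_ij ρ(u_j) + b_i) + β(y_i − d_i)·[i output]

The clip matters with the hard sigmoid: since ρ′ vanishes outside [0, 1],
an unclipped unit that left the box would never re-enter it. Two stopping
rules are supported. Fixed iteration counts are the training default (the
benchmark presets use 20/100/500 free-phase iterations for 1/2/3 hidden
layers and ε = 0.5); the second-phase default is N/ε iterations for N
non-input layers — the time a perturbation needs to propagate from the
outputs back through the network — because full convergence of the nudged
phase is not required, only the initiation of the movement. Tolerance mode
(max-norm state change below a threshold, with an iteration cap) is used
wherever true fixed points are needed, since gradient-estimate quality is
limited by the precision with which fixed points are located.

Numerical choices:

- **ρ′ at the hard-sigmoid kinks** is defined as 1 on the *closed* interval
  [0, 1], so a unit sitting exactly on a boundary remains responsive to its
  drive and the clipped dynamics can pull it back inside.
- **Clipping is optional** (`RelaxationConfig(clip=False)`). With the
  smooth logistic activation the stationary points of F can have small
  negative coordinates; the gradient-validation suites therefore run the
  unclipped dynamics, whose fixed points satisfy ∂F/∂s = 0 exactly in the
  reals. The leak term guarantees boundedness either way. Training always
  uses the clipped rule.
- **Prediction** is argmax over output-unit values at the free fixed
  point; exact ties break toward the lowest class index.
- **Oracle relaxation** uses tolerance 1e−13 with a 200,000-step cap and
  ε = 0.5; at these sizes convergence takes a few hundred steps.

## Exact-gradient oracles

Two independent oracles validate the estimator on seeded random layered
instances (3–8 units per layer, so brute force runs in seconds), both with
the logistic activation:

- **Finite differences**: centered differences of J with δ = 1e−5,
  re-relaxing the network for every perturbed parameter (warm-started from
  the unperturbed fixed point). A symmetric pair (W_ij, W_ji) is one
  parameter and is perturbed jointly.
- **Implicit solve**: at the free fixed point, solve
  (∂²E/∂s²) λ = ∂C/∂s and return ∂C/∂θ − λᵀ ∂²E/∂s∂θ. The free-state
  Hessian is assembled analytically (off-diagonal −ρ′(s_i) W_ik ρ′(s_k),
  diagonal 1 − ρ″(s_i)·drive_i) and must be positive definite and
  well-conditioned; units pinned at a box boundary are detected and
  reported before the solve, since the implicit function theorem needs an
  interior fixed point.

The two oracles agree to ~1e−7 relative; the two-sided (±β-averaged)
contrastive estimate at β = 1e−3 matches them to ~1e−6, with the one-sided
error scaling as O(β) and the two-sided error as O(β²).

A related check confirms that weak clamping is always beneficial: over
seeded instances the cost at the fully converged nudged fixed point
(β = 0.01) never exceeds the cost at the free fixed point, with equality
exactly when the free prediction is already perfect.

## STDP bridge

At the rate level, the plasticity rule `dW_ij/dt ∝ ρ(u_i) dρ(u_j)/dt`,
symmetrized for tied weights into `d(ρ(u_i)ρ(u_j))/dt`, integrates along
the second-phase path into the contrastive endpoint update. Two
discretizations are provided: the telescoping sum of increments of
ρ(u_i)ρ(u_j), which reproduces the endpoint difference exactly (to float
round-off) by construction, and the left-endpoint product-rule sum
ρ_i Δρ_j + ρ_j Δρ_i, which mirrors the biological reading and converges to
the telescoping value at first order in ε (the per-step defect is the
second-order term Δρ_i Δρ_j). No spike trains are simulated; the module
works at the same rate-model level as the theory.

## Training loop

Minibatch SGD with the following conventions:

- **Averaging**: gradient estimates are averaged (not summed) over the
  minibatch, so learning rates are batch-size independent. Default batch
  size 20.
- **Per-layer learning rates** α_k apply to the k-th inter-layer weight
  block and the biases of its downstream layer. The theory requires a
  single rate; in practice per-layer rates are needed, plausibly because
  fixed points are only located to finite precision. The loop reports
  ‖ΔW_k‖/‖W_k‖ per layer per epoch as a diagnostic so this can be studied;
  no automatic adaptation is attempted.
- **Random β sign**: when enabled, the sign of β is drawn once per
  minibatch. The 1/β factor keeps updates of either sign consistent, and
  averaging over signs equals the two-sided symmetric estimate in
  expectation. This acts as a regularizer.
- **Persistent particles**: each training example's free-unit state at the
  end of its free phase is cached (keyed by dataset row index) and used to
  warm-start its next free phase, cutting relaxation cost across epochs.
  Only the free state is stored; the nudged state is discarded. Validation
  is always stateless (fresh zero starts).
- **Initialization**: fan-based uniform weights per inter-layer block
  (limit √(6/(fan_in + fan_out))), mirrored exactly across the diagonal;
  zero biases.
- **Exact symmetry**: updates mirror the upper triangle of the gradient
  estimate, so `W == W.T` holds bitwise after arbitrarily long training,
  and masked-off entries stay exactly zero.
- **Reproducibility**: epoch-level randomness derives from a generator
  seeded by (seed, epoch), so resuming from a checkpoint (which stores
  parameters, history and particles) reproduces the original run
  bit-identically.
- Optional L2 weight shrinkage is available (default off).

## Synthetic data

`make_clusters` draws class centers uniformly in [0.2, 0.8]^n and adds
Gaussian noise (default spread 0.05) clipped to the unit hypercube,
producing well-separated, approximately isotropic classes. The default
study task is 3 classes × 10 features with 600 training and 200 validation
examples — small enough that the full suite runs in seconds, large enough
that minibatch SGD behaves normally. The generator emulates the *format* of
an image-classification task (bounded features, one-hot targets, train/valid
split) but none of its difficulty: no class overlap, no manifold structure,
no label noise. Passing tests therefore demonstrate the correctness of the
algorithm and its implementation, not competitive benchmark accuracy. The
full benchmark replication (MNIST via local IDX files, architectures
784-500-10 and deeper, multi-hour runs) is supported through the shipped
configs but is not exercised by the test suite.

`make_fixture_network` builds the seeded random layered instances used for
gradient checking: layered connectivity only (no skip-layer, no lateral
connections), fan-based uniform weights, a random clamped input in [0, 1]
and a random one-hot target.

## Problem sizes used by the checks

Gradient validation uses 5-8-3 networks (64 tied weights + 16 biases), 20
instances for the oracle-equivalence check and 100 for the nudged-cost
check; energy-descent checks record 400-step trajectories at ε = 0.1; the
training checks use the 10-20-3 synthetic task for 50 epochs (1,500
updates). These sizes keep every check to seconds while exercising all code
paths; the estimator's limit behaviour is size-independent.

## Known limitations

- The hard sigmoid violates the smoothness assumptions of the gradient
  theory at its kinks; gradient validation therefore uses the logistic
  activation, while training uses the hard sigmoid. No attempt is made to
  analyze the hard-sigmoid case beyond the boundary-detection guard.
- Only fixed-iteration and max-norm-tolerance stopping are provided; there
  is no principled rule for choosing free-phase durations, which grow
  quickly with depth.
- Asynchronous update orders, continuous-time ODE integration, stochastic
  (Langevin) dynamics, alternative costs (softmax/cross-entropy), scaled
  energies, and momentum/adaptive optimizers are out of scope.
- The implicit-solve oracle requires an interior, well-conditioned free
  fixed point and fails loudly otherwise; it is a validation tool, not a
  training path.
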