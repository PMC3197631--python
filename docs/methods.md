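# Methods

## The model

`mtmoe` implements a three-level continuous-time recurrent neural network
(CTRNN) that learns to imitate, and then spontaneously recombine, stochastic
sequences of behaviour primitives observed as multivariate visuo-proprioceptive
time series.

Every unit is a leaky integrator discretized with unit step size,

    u_{t+1} = (1 - 1/tau) u_t + (1/tau) * (W f(u_t) + inputs + b),

with `f = tanh`.  The time constant `tau` sets the level's speed:

- **Lower level** (`tau_low`, default 2): a bank of expert RNNs.  Each
  expert receives the input delayed by the feedback delay `d` (default 1
  step) and predicts the next visuo-proprioceptive frame through a tanh
  output layer.  Experts come to encode reusable sensorimotor patterns.
- **Middle level** (`tau_mid`, default 10): part of the gating network.  It
  receives the current input, the previous gate opening, and the higher
  level's activity; a linear readout of its tanh activations, normalized by
  a softmax, is the gate opening `g_t` — a probability vector over experts.
- **Higher level** (`tau_high`, default 100; swept over {10, 30, 100} in the
  timescale experiments): recurrently coupled to the middle level only; no
  direct sensory input.  Its slow dynamics come to encode the sequencing of
  primitives.

The model output is the gate-weighted mean of the expert predictions.  The
underlying probabilistic model is a mixture of isotropic Gaussians (shared
scale `sigma`), so the weighted mean is the mixture expectation; we generate
with the expectation rather than sampling a winner so that motor imagery is
deterministic, which the Lyapunov analysis requires.

Two generation modes: **closed loop** ("motor imagery") feeds each
prediction back as the next input; **open loop** conditions on externally
supplied observations and emits one-step-ahead predictions.

Wiring choices the architecture leaves open were resolved as follows: the
gate readout is a linear map from middle-level tanh activations; the gate
feedback and the raw input enter the middle level additively; the gate at
t < 0 is the uniform vector; internal states are never clipped (a NaN
raises).  Mid and high levels update synchronously (both read the pre-step
activations of the other).

## Two-phase MAP training

**Phase 1 (experts).**  The gate schedule is treated as unknown: per-step
free variables `v_t` parameterize gate estimates `ghat_t = softmax(v_t)`.
The objective is the log of likelihood times prior,

    sum_t log sum_i ghat_{i,t} N(x_{t+1}; y^i_{t+1}, sigma^2 I)
      - sum_t ||v_{t+1} - v_t||^2 / (2 ς^2),

maximized over expert weights, `v`, `sigma`, and per-sequence expert initial
states.  The Brownian prior (scale `ς`, default 1) suppresses needless gate
switching.  Gradients are exact reverse-mode BPTT through the leak term and
the delay buffer, verified against central finite differences to < 1e-4
relative error on every block.  Expert runs are teacher-forced (true inputs
at every step).

**Phase 2 (gating network).**  With `ghat` frozen as targets, the gating
network (middle + higher weights and their per-sequence initial states) is
trained to minimize `KL(ghat || g)` under teacher forcing: the gate-feedback
term into the middle level uses `ghat_{t-1}` rather than the network's own
output.  The multinomial normalization constant is parameter-independent
and dropped.  An adaptive learning-rate scheme accelerates this phase: each
candidate momentum step is evaluated; if the KL ratio (candidate/current)
exceeds 1 the step is rejected and the rate is halved (up to 10 retries);
an accepted, clearly improving step (ratio < 0.999) grows the rate by 1.2.
Accepted steps therefore never increase the divergence.

**Optimizer.**  Both phases use full-batch gradient ascent with momentum
(default 0.9).  The nominal learning rate (default 0.02) is rescaled per
parameter block by the number of data terms its gradient sums over —
weights and `sigma` by 1/(total steps × output dimension), initial states
by 1/dimension, the per-step gate variables not at all.  This keeps step
sizes size-invariant without starving the per-step variables, which a single
global 1/(T·D) factor does.  The scaled gradient's global norm is clipped at
1.0; without clipping the joint descent on weights and `sigma` is unstable
once `sigma` becomes small.  `sigma` starts at 0.3 and is floored at 1e-3.
Phase 1 keeps the best-seen parameters; a convergence window (relative
improvement < 1e-6 over 50 epochs) only engages after a warmup
(`min_epochs`), since early plateaus before the recurrent dynamics pick up
the task are common.

Because the likelihood is a mixture, training is multi-modal: a single
recurrent expert can absorb several regimes through its internal state
(symmetric non-specialized optimum) or the experts can specialize.  Where an
experiment depends on specialization, the standard mixture protocol is used:
several random restarts, keeping the run with the highest objective — the
specialized solutions have a decisively higher likelihood.

**Initialization.**  Weights and biases are uniform on
(-1/sqrt(N), +1/sqrt(N)) with N the destination layer's unit count; initial
states uniform on (-1, 1); `v` zero (uniform gate estimate).

## Synthetic tutoring data

The generator emulates a tutored object-moving task: an object rests at one
of three positions (L at vision x = -0.6, C at 0, R at +0.6, in normalized
coordinates); each primitive reaches, grasps, carries the object to another
position drawn from a configurable row-stochastic transition matrix with
zero diagonal (no self-moves), releases, and returns to a home posture.
Proprioception (default 8 channels) interpolates through fixed keyframe
postures — yaw tracking the target, lift, elbow, hand aperture — with
cosine easing, so velocities are continuous at keyframes; all segments
start and end exactly at the home posture, making primitives concatenable.
Vision (2 channels) holds the object position, moving during the carry
phase with a small vertical bump.  Each primitive takes `primitive_duration`
steps (default 40), giving all primitives a common period — the source of
the periodic autocorrelation structure in the trained data.  Optional
i.i.d. Gaussian observation noise is added and clipped to [-1, 1].

What the generator does **not** emulate: physical dynamics, grasp mechanics
and failures, camera imaging, variable primitive durations, or sensory
delays beyond the fixed feedback delay.  Tests passing on this data show
that the learning machinery and the dynamical phenomena work as specified
on smooth, repeatable, position-discriminating trajectories; they do not
certify performance on real robot recordings.

## Analyses

**Maximum Lyapunov exponent.**  Two-trajectory Benettin estimate in closed
loop: a reference and a perturbed run evolve together; every
`renorm_interval` (10) steps the log expansion of the separation is
recorded and the perturbed state is pulled back to distance `eps` (1e-8,
measured over all internal units) along the current separation direction.
For a subnetwork exponent the full coupled dynamics are simulated but the
separation is measured on that subnetwork's state components only; a
positive subnetwork exponent therefore implies a positive entire-network
exponent, which the suite asserts.  The estimate is averaged over random
initial states.  The two-trajectory method was chosen over tangent-space
integration because the softmax gate makes hand-derived Jacobians easy to
get subtly wrong; a tangent-dynamics oracle for a 1-unit chaotic fixture
cross-checks the estimator in the tests.

**Symbolization.**  The horizontal vision channel is binned by the
midpoints between object positions; a bin must persist `min_dwell` steps
(a quarter primitive) to emit its symbol, and repeats collapse.  n-block
novelty is the number of distinct length-n substrings over the number of
admissible ones, `3 * 2^(n-1)` (no immediate repeats).  Transition
probabilities are maximum-likelihood bigram frequencies with unobserved
rows flagged as NaN.

**Lesion.**  Removing the higher level zeroes its projection onto the
middle level and freezes its state at zero.  The comparison reports
single-primitive regeneration RMSE and 5-block novelty of long imagery,
before and after.

**Fixed-point detection.**  Imagery runs `horizon` steps; the higher level
has reached a fixed point when its per-step change stays below `tol`
(1e-5) throughout the final 10% of the horizon.

**Noise robustness (proxy).**  The physical success-rate experiment is out
of scope; as a desk-scale proxy, open-loop prediction runs on
noise-perturbed teaching observations, and a primitive counts as valid when
the predicted vision ends the primitive with a full dwell in a single
position bin.

## Study conditions (problem sizes)

All experiments run on synthetic data at desk scale; sizes were fixed once
as follows (command-line runs additionally record their configuration in a
run manifest).

- Model: 4 experts × 10 units, 12 middle, 6 higher units; D = 8 + 2;
  `tau = (2, 10, tau_high)`; feedback delay 1.
- Regeneration fixture: 2 sequences × 6 transitions × 40 steps; 2000
  Phase-1 and 800 Phase-2 epochs, best of 3 restarts by MAP objective.
- Timescale/lesion/fixed-point ensembles: 3 sequences × 12 transitions
  (2 transitions for the short-training condition), 1500 + 800 epochs,
  10 seeded runs per condition; Lyapunov estimates use 6 samples × 2500
  steps after a 200-step transient.
- Probability-reconstruction run: transition matrix with P(C→L) = 0.7,
  P(C→R) = 0.3 (other rows uniform); 3 sequences × 12 transitions;
  imagery of 2000 primitive transitions.

## Known limitations

- Mixture training is restart-dependent; the package reports and selects by
  the MAP objective but does not guarantee specialization for arbitrary
  data.
- Training is teacher-forced throughout, so closed-loop (imagery)
  regeneration is limited by expert drift under self-feedback: one-step
  prediction errors of a few percent compound over tens of steps and the
  imagery can fall into the majority transition even when the gate schedule
  itself is reproduced almost exactly.  In the physical setting this model
  family targets, environmental feedback re-anchors the state; imagery has
  no such anchor.
- Trained imagery at these data volumes sits near the edge of chaos:
  long-run attractors are mostly (quasi-)periodic, so Lyapunov exponents
  cluster within about 1e-3 nats/step of zero — the same order as the
  estimator's sampling error — and reconstructed transition statistics come
  out more deterministic than the tutoring distribution.  Substantially
  larger teaching sets are needed for developed chaos.
- The Benettin estimate with a finite horizon has sampling error of order
  1e-3 nats/step; exponents within that band of zero are effectively
  "neutral".
- The CSV/HDF5 formats store full double precision but the CSV writer
  rounds to 12 significant digits; round trips through CSV are lossless to
  that precision only.
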