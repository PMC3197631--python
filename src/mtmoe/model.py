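"""Forward dynamics of the hierarchical multiple-timescale mixture of RNN experts.

The model is a three-level continuous-time recurrent neural network (CTRNN).
The lower level is a set of expert RNNs with a small time constant, each
specializing in a reusable sensorimotor pattern.  The middle and higher levels
form the gating network: the middle level (moderate time constant) reads the
visuo-proprioceptive input and the previous gate opening, emits the gate via a
softmax readout, and exchanges activity with the higher level (large time
constant), which has no direct sensory input.  The combined output is the
gate-weighted mean of the expert predictions.

Two generation modes are supported: closed loop ("motor imagery"), where the
model's own prediction is fed back as the next input, and open loop, where
externally supplied observations drive the network and the model emits
one-step-ahead predictions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels

Array = np.ndarray


class ConfigurationError(ValueError):
    """Inconsistent shapes, time constants, or model wiring."""


class InvalidStateError(FloatingPointError):
    """Non-finite values encountered in the network state."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimescaleProfile:
    """CTRNN time constants for the three levels.

    ``tau_low`` governs the expert units, ``tau_mid`` the middle level and
    ``tau_high`` the higher level, in units of integration steps.  The Euler
    step size is fixed at 1, so the leak factor ``1 - 1/tau`` lies in
    ``[0, 1)`` whenever ``tau >= 1``.
    """

    tau_low: float = 2.0
    tau_mid: float = 10.0
    tau_high: float = 100.0
    step_size: float = 1.0

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ConfigurationError("step_size must be positive")
        taus = (self.tau_low, self.tau_mid, self.tau_high)
        if not (self.tau_low <= self.tau_mid <= self.tau_high):
            raise ConfigurationError("require tau_low <= tau_mid <= tau_high")
        if any(t < self.step_size for t in taus):
            raise ConfigurationError("all time constants must be >= step_size")


@dataclass
class ExpertParams:
    """Weights of one expert RNN (lower level)."""

    recurrent_weights: Array  # (N, N)
    input_weights: Array      # (N, D)
    output_weights: Array     # (D, N)
    recurrent_bias: Array     # (N,)
    output_bias: Array        # (D,)

    @property
    def n_units(self) -> int:
        return self.recurrent_weights.shape[0]

    def validate(self, D: int) -> None:
        N = self.n_units
        shapes = {
            "recurrent_weights": (self.recurrent_weights.shape, (N, N)),
            "input_weights": (self.input_weights.shape, (N, D)),
            "output_weights": (self.output_weights.shape, (D, N)),
            "recurrent_bias": (self.recurrent_bias.shape, (N,)),
            "output_bias": (self.output_bias.shape, (D,)),
        }
        for name, (got, want) in shapes.items():
            if got != want:
                raise ConfigurationError(f"expert {name}: shape {got}, expected {want}")


@dataclass
class GatingParams:
    """Weights of the gating network (middle + higher levels).

    The higher level has no input weights: sensory input reaches the middle
    level only, and the middle level relays it upward through
    ``high_from_mid``.
    """

    mid_recurrent: Array         # (M, M)
    mid_from_high: Array         # (M, H)
    mid_input_weights: Array     # (M, D)
    mid_gatefeedback_weights: Array  # (M, E)
    mid_bias: Array              # (M,)
    high_recurrent: Array        # (H, H)
    high_from_mid: Array         # (H, M)
    high_bias: Array             # (H,)
    gate_readout: Array          # (E, M)

    @property
    def n_mid(self) -> int:
        return self.mid_recurrent.shape[0]

    @property
    def n_high(self) -> int:
        return self.high_recurrent.shape[0]

    @property
    def n_experts(self) -> int:
        return self.gate_readout.shape[0]

    def validate(self, D: int, n_experts: int) -> None:
        M, H = self.n_mid, self.n_high
        shapes = {
            "mid_recurrent": (self.mid_recurrent.shape, (M, M)),
            "mid_from_high": (self.mid_from_high.shape, (M, H)),
            "mid_input_weights": (self.mid_input_weights.shape, (M, D)),
            "mid_gatefeedback_weights": (self.mid_gatefeedback_weights.shape, (M, n_experts)),
            "mid_bias": (self.mid_bias.shape, (M,)),
            "high_recurrent": (self.high_recurrent.shape, (H, H)),
            "high_from_mid": (self.high_from_mid.shape, (H, M)),
            "high_bias": (self.high_bias.shape, (H,)),
            "gate_readout": (self.gate_readout.shape, (n_experts, M)),
        }
        for name, (got, want) in shapes.items():
            if got != want:
                raise ConfigurationError(f"gating {name}: shape {got}, expected {want}")


@dataclass
class ModelParams:
    """Complete parameter set of the hierarchical model."""

    experts: list[ExpertParams]
    gating: GatingParams
    timescales: TimescaleProfile = field(default_factory=TimescaleProfile)
    feedback_delay: int = 1
    io_dims: tuple[int, int] = (8, 2)  # (proprio_dim, vision_dim)
    lesioned: bool = False

    @property
    def n_experts(self) -> int:
        return len(self.experts)

    @property
    def n_dim(self) -> int:
        return self.io_dims[0] + self.io_dims[1]

    def validate(self) -> None:
        if self.n_experts < 1:
            raise ConfigurationError("need at least one expert")
        if self.feedback_delay < 0:
            raise ConfigurationError("feedback_delay must be >= 0")
        D = self.n_dim
        n_units = self.experts[0].n_units
        for e in self.experts:
            e.validate(D)
            if e.n_units != n_units:
                raise ConfigurationError("all experts must have the same unit count")
        self.gating.validate(D, self.n_experts)


@dataclass(frozen=True)
class ModelConfig:
    """Structural sizes used to build a model (see :func:`mtmoe.learning.init_params`)."""

    n_experts: int = 4
    n_units: int = 10
    n_mid: int = 12
    n_high: int = 6
    proprio_dim: int = 8
    vision_dim: int = 2
    timescales: TimescaleProfile = field(default_factory=TimescaleProfile)
    feedback_delay: int = 1

    @property
    def n_dim(self) -> int:
        return self.proprio_dim + self.vision_dim


# ---------------------------------------------------------------------------
# State and trajectories
# ---------------------------------------------------------------------------


@dataclass
class NetworkState:
    """Instantaneous state of the whole network.

    ``input_buffer`` holds the last ``feedback_delay + 1`` inputs (most recent
    last); experts read the entry ``feedback_delay`` steps back.
    """

    expert_states: Array  # (E, N)
    mid_state: Array      # (M,)
    high_state: Array     # (H,)
    gate: Array           # (E,)
    input_buffer: Array   # (d+1, D)

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.expert_states.copy(), self.mid_state.copy(),
            self.high_state.copy(), self.gate.copy(), self.input_buffer.copy(),
        )

    @staticmethod
    def initial(m: "ModelParams",
                expert_states: Optional[Array] = None,
                mid_state: Optional[Array] = None,
                high_state: Optional[Array] = None,
                x0: Optional[Array] = None) -> "NetworkState":
        """Build a state at t=0: given (or zero) internal states, uniform gate,
        input buffer pre-filled with ``x0`` (or zeros)."""
        E, N = m.n_experts, m.experts[0].n_units
        M, H, D = m.gating.n_mid, m.gating.n_high, m.n_dim
        u = np.zeros((E, N)) if expert_states is None else np.asarray(expert_states, float).reshape(E, N).copy()
        mid = np.zeros(M) if mid_state is None else np.asarray(mid_state, float).reshape(M).copy()
        high = np.zeros(H) if high_state is None else np.asarray(high_state, float).reshape(H).copy()
        if m.lesioned:
            high = np.zeros(H)
        gate = np.full(E, 1.0 / E)
        x0 = np.zeros(D) if x0 is None else np.asarray(x0, float).reshape(D)
        buf = np.tile(x0, (m.feedback_delay + 1, 1))
        return NetworkState(u, mid, high, gate, buf)


@dataclass
class Trajectory:
    """A visuo-proprioceptive sequence (proprioception then vision columns)."""

    values: Array                 # (T, D)
    proprio_dim: int
    labels: Optional[list[str]] = None  # per-step symbol in {L, C, R} or ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ConfigurationError("trajectory values must be a (T, D) array with T >= 1")
        if self.labels is not None and len(self.labels) != len(self.values):
            raise ConfigurationError("labels length must match trajectory length")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_dim(self) -> int:
        return self.values.shape[1]

    @property
    def proprio(self) -> Array:
        return self.values[:, : self.proprio_dim]

    @property
    def vision(self) -> Array:
        return self.values[:, self.proprio_dim:]


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def ctrnn_update(u: Array, drive: Array, tau: float, step_size: float = 1.0) -> Array:
    """One leaky-integrator Euler step: ``(1 - 1/tau) u + (1/tau) drive``.

    ``drive`` is the fully assembled synaptic input ``W f(u) + (inputs) + b``.
    """
    if tau < step_size:
        raise ConfigurationError("tau must be >= step_size")
    u = np.asarray(u, float)
    drive = np.asarray(drive, float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(drive))):
        raise InvalidStateError("non-finite state or drive in ctrnn_update")
    a = step_size / tau
    return (1.0 - a) * u + a * drive


def expert_step(p: ExpertParams, u: Array, x_delayed: Array,
                tau_low: float) -> tuple[Array, Array]:
    """Advance one expert by one step and emit its prediction.

    The drive is ``W_rec tanh(u) + W_in x_delayed + b``; the output is
    ``tanh(W_out tanh(u') + b_out)``.
    """
    u = np.asarray(u, float)
    x_delayed = np.asarray(x_delayed, float)
    if u.shape != (p.n_units,) or x_delayed.shape != (p.input_weights.shape[1],):
        raise ConfigurationError("expert_step: dimension mismatch")
    drive = p.recurrent_weights @ np.tanh(u) + p.input_weights @ x_delayed + p.recurrent_bias
    u_new = ctrnn_update(u, drive, tau_low)
    y = np.tanh(p.output_weights @ np.tanh(u_new) + p.output_bias)
    return u_new, y


def gate_softmax(pre_activations: Array) -> Array:
    """Numerically stable softmax over expert pre-activations."""
    z = np.asarray(pre_activations, float)
    if z.size == 0:
        raise ConfigurationError("gate_softmax: empty pre-activation vector")
    if not np.all(np.isfinite(z)):
        raise InvalidStateError("non-finite gate pre-activations")
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def gating_step(p: GatingParams, mid: Array, high: Array, x: Array,
                g_prev: Array, timescales: TimescaleProfile,
                lesioned: bool = False) -> tuple[Array, Array, Array]:
    """Advance the gating network (middle + higher levels) one step.

    Both levels update synchronously from the pre-step activations; the gate
    is read out from the updated middle level.  Under a higher-level lesion
    the higher state is held at zero.
    """
    mid = np.asarray(mid, float)
    high = np.asarray(high, float)
    x = np.asarray(x, float)
    g_prev = np.asarray(g_prev, float)
    if mid.shape != (p.n_mid,) or high.shape != (p.n_high,) or g_prev.shape != (p.n_experts,):
        raise ConfigurationError("gating_step: dimension mismatch")
    tm, th = np.tanh(mid), np.tanh(high)
    mid_drive = (p.mid_recurrent @ tm + p.mid_from_high @ th
                 + p.mid_input_weights @ x + p.mid_gatefeedback_weights @ g_prev
                 + p.mid_bias)
    mid_new = ctrnn_update(mid, mid_drive, timescales.tau_mid, timescales.step_size)
    if lesioned:
        high_new = np.zeros_like(high)
    else:
        high_drive = p.high_recurrent @ th + p.high_from_mid @ tm + p.high_bias
        high_new = ctrnn_update(high, high_drive, timescales.tau_high, timescales.step_size)
    g = gate_softmax(p.gate_readout @ np.tanh(mid_new))
    return mid_new, high_new, g


def combine_outputs(g: Array, expert_outputs: Sequence[Array]) -> Array:
    """Gate-weighted mean of expert outputs (the mixture expectation)."""
    g = np.asarray(g, float)
    ys = np.asarray(expert_outputs, float)
    if ys.shape[0] != g.shape[0]:
        raise ConfigurationError("combine_outputs: gate/outputs length mismatch")
    return g @ ys


def model_step(m: ModelParams, s: NetworkState, x: Array) -> tuple[NetworkState, Array]:
    """Advance the whole model one step on input ``x`` and return the
    prediction for the next visuo-proprioception.

    In open loop ``x`` is the true observation; in closed loop it is the
    previous prediction.  Experts read the input from ``feedback_delay``
    steps back through the input buffer.
    """
    x = np.asarray(x, float)
    if x.shape != (m.n_dim,):
        raise ConfigurationError("model_step: input dimension mismatch")
    if not np.all(np.isfinite(x)):
        raise InvalidStateError("non-finite model input")
    buf = np.vstack([s.input_buffer[1:], x[None]]) if len(s.input_buffer) > 1 else x[None].copy()
    x_delayed = buf[0]
    ts = m.timescales
    new_u = np.empty_like(s.expert_states)
    outputs = np.empty((m.n_experts, m.n_dim))
    for i, p in enumerate(m.experts):
        new_u[i], outputs[i] = expert_step(p, s.expert_states[i], x_delayed, ts.tau_low)
    mid, high, g = gating_step(m.gating, s.mid_state, s.high_state, x, s.gate,
                               ts, lesioned=m.lesioned)
    yhat = combine_outputs(g, outputs)
    return NetworkState(new_u, mid, high, g, buf), yhat


# ---------------------------------------------------------------------------
# Fast stacked runner (used by generation and analysis loops)
# ---------------------------------------------------------------------------


class StackedModel:
    """Experts stacked along a leading axis for fast step loops.

    Numerically identical to composing :func:`model_step`; kept internal to
    the generation helpers, which are verified against the reference path.
    """

    def __init__(self, m: ModelParams):
        m.validate()
        self.m = m
        self.Wr = np.stack([e.recurrent_weights for e in m.experts])
        self.Win = np.stack([e.input_weights for e in m.experts])
        self.br = np.stack([e.recurrent_bias for e in m.experts])
        self.Wout = np.stack([e.output_weights for e in m.experts])
        self.bout = np.stack([e.output_bias for e in m.experts])
        g = m.gating
        self.A, self.B, self.U = g.mid_recurrent, g.mid_from_high, g.mid_input_weights
        self.G, self.bm = g.mid_gatefeedback_weights, g.mid_bias
        self.Eh, self.Fh, self.bh = g.high_recurrent, g.high_from_mid, g.high_bias
        self.C = g.gate_readout
        ts = m.timescales
        self.al = ts.step_size / ts.tau_low
        self.am = ts.step_size / ts.tau_mid
        self.ah = ts.step_size / ts.tau_high
        self.lesioned = m.lesioned

    def step(self, s: NetworkState, x: Array) -> tuple[NetworkState, Array]:
        buf = s.input_buffer
        if len(buf) > 1:
            buf = np.vstack([buf[1:], x[None]])
        else:
            buf = x[None].copy()
        xd = buf[0]
        r = np.tanh(s.expert_states)
        drive = np.matmul(self.Wr, r[..., None])[..., 0] + self.Win @ xd + self.br
        u = (1.0 - self.al) * s.expert_states + self.al * drive
        y = np.tanh(np.matmul(self.Wout, np.tanh(u)[..., None])[..., 0] + self.bout)
        tm, th = np.tanh(s.mid_state), np.tanh(s.high_state)
        mid = (1.0 - self.am) * s.mid_state + self.am * (
            self.A @ tm + self.B @ th + self.U @ x + self.G @ s.gate + self.bm)
        if self.lesioned:
            high = np.zeros_like(s.high_state)
        else:
            high = (1.0 - self.ah) * s.high_state + self.ah * (
                self.Eh @ th + self.Fh @ tm + self.bh)
        z = self.C @ np.tanh(mid)
        z = z - z.max()
        e = np.exp(z)
        g = e / e.sum()
        yhat = g @ y
        return NetworkState(u, mid, high, g, buf), yhat


def _kernel_args(m: ModelParams) -> tuple:
    sm = StackedModel(m)
    c = np.ascontiguousarray
    return (c(sm.Wr), c(sm.Win), c(sm.br), c(sm.Wout), c(sm.bout),
            c(sm.A), c(sm.B), c(sm.U), c(sm.G), c(sm.bm),
            c(sm.Eh), c(sm.Fh), c(sm.bh), c(sm.C),
            sm.al, sm.am, sm.ah, m.lesioned)


def _state_args(s: NetworkState) -> tuple:
    c = np.ascontiguousarray
    return (c(s.expert_states), c(s.mid_state), c(s.high_state),
            c(s.gate), c(s.input_buffer))


def _run(m: ModelParams, s0: NetworkState, X: Array, closed: bool):
    Y, HI = _kernels.run_scan(*_kernel_args(m), *_state_args(s0),
                              np.ascontiguousarray(X), closed)
    return Y, HI


def generate_closed_loop(m: ModelParams, s0: NetworkState, T: int,
                         x0: Optional[Array] = None) -> Trajectory:
    """Generate a length-``T`` motor-imagery trajectory.

    The prediction at each step is fed back as the next input.  The first
    input is ``x0`` if given, otherwise the most recent entry of the initial
    state's input buffer.  Deterministic in ``(m, s0, T, x0)``.
    """
    if T < 1:
        raise ConfigurationError("T must be >= 1")
    x = s0.input_buffer[-1] if x0 is None else np.asarray(x0, float)
    X = np.zeros((T, m.n_dim))
    X[0] = x
    Y, _ = _run(m, s0, X, True)
    if not np.all(np.isfinite(Y)):
        raise InvalidStateError("non-finite prediction during closed-loop run")
    return Trajectory(Y, m.io_dims[0])


def generate_open_loop(m: ModelParams, s0: NetworkState,
                       observations: Trajectory) -> Trajectory:
    """One-step-ahead predictions conditioned on true observations."""
    T = len(observations)
    if T < 1:
        raise ConfigurationError("observations must have length >= 1")
    Y, _ = _run(m, s0, observations.values, False)
    return Trajectory(Y, m.io_dims[0])


def lesion_higher(m: ModelParams) -> ModelParams:
    """Remove the higher level: zero its projection to the middle level and
    freeze its state at zero.  Idempotent; other parameters unchanged."""
    lm = copy.deepcopy(m)
    lm.gating.mid_from_high = np.zeros_like(lm.gating.mid_from_high)
    lm.lesioned = True
    return lm
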