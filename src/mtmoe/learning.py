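"""Two-phase maximum-a-posteriori training of the mixture of RNN experts.

Phase 1 fits the lower level: expert weights, per-sequence expert initial
states, the per-step gate-opening variables ``v`` (whose row-softmax is the
gate estimate ``ghat``) and the shared output noise scale ``sigma`` are
jointly optimized by gradient ascent on the log of

    likelihood  = prod_t  sum_i ghat_{i,t} N(y_t; y^i_t, sigma^2 I)
    prior       = Brownian-motion smoothness prior on v

with exact gradients obtained by backpropagation through time through the
leaky-integrator dynamics.  Phase 2 then trains the gating network (middle
and higher levels plus their initial states) to reproduce the optimized gate
schedule, by minimizing the Kullback-Leibler divergence KL(ghat || g) with
teacher forcing (the gate feedback into the middle level uses ``ghat``), and
with an adaptive learning-rate acceleration that rejects steps that would
increase the divergence.

Both phases use plain full-batch gradient ascent with a momentum term; the
nominal learning rate is divided by (total training steps x output
dimension) so that step sizes are insensitive to problem size.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import _kernels
from .model import (
    Array,
    ConfigurationError,
    ExpertParams,
    GatingParams,
    ModelConfig,
    ModelParams,
    Trajectory,
)

_LOG2PI = np.log(2.0 * np.pi)


class DivergenceError(RuntimeError):
    """Training objective became non-finite; carries the loss trace so far."""

    def __init__(self, message: str, trace: Optional[list] = None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# Training-set containers
# ---------------------------------------------------------------------------


@dataclass
class GateVariableSequence:
    """Free gate variables ``v`` for one sequence; ``ghat = softmax(v)`` rowwise.

    ``v`` has one row per predicted step (sequence length minus one)."""

    v: Array  # (S, E)

    @property
    def ghat(self) -> Array:
        z = self.v - self.v.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


@dataclass
class NoiseModel:
    """Shared isotropic output noise standard deviation."""

    sigma: float = 0.3
    learnable: bool = True
    min_sigma: float = 1e-3

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")


@dataclass
class TrainingSet:
    """Teaching sequences plus the per-sequence learnable state.

    Each sequence carries its own expert initial states, gating initial
    states and gate-variable sequence; the noise model is shared."""

    sequences: list[Trajectory]
    expert_init: list[Array]   # (E, N) per sequence
    mid_init: list[Array]      # (M,) per sequence
    high_init: list[Array]     # (H,) per sequence
    gate_vars: list[GateVariableSequence]
    noise: NoiseModel = field(default_factory=NoiseModel)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def total_steps(self) -> int:
        return sum(len(s) - 1 for s in self.sequences)


@dataclass
class OptimizerConfig:
    """Gradient-ascent settings shared by both phases.

    ``learning_rate`` is the nominal per-quantity rate; gradients of blocks
    that sum over the whole data set (weights, sigma) are divided by the
    number of summed terms so that step sizes are insensitive to problem
    size, while per-step quantities (the gate variables) keep their natural
    scale.  ``clip_norm`` bounds the global norm of the scaled gradient.
    The adaptive block applies to Phase 2 only."""

    learning_rate: float = 0.02
    momentum: float = 0.9
    rate_up: float = 1.2
    rate_down: float = 0.5
    accept_threshold: float = 1.0
    improve_threshold: float = 0.999
    max_retries: int = 10
    prior_scale: float = 1.0
    max_epochs: int = 5000
    tolerance: float = 1e-6
    tolerance_window: int = 50
    min_epochs: int = 500
    clip_norm: Optional[float] = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.rate_down < 1.0):
            raise ConfigurationError("rate_down must be in (0, 1)")
        if self.rate_up <= 1.0:
            raise ConfigurationError("rate_up must be > 1")
        if self.max_retries < 1:
            raise ConfigurationError("max_retries must be >= 1")
        if not (0.0 <= self.momentum < 1.0):
            raise ConfigurationError("momentum must be in [0, 1)")
        if self.prior_scale <= 0:
            raise ConfigurationError("prior_scale must be positive")


# ---------------------------------------------------------------------------
# Parameter stacking helpers (trainer-internal flat representation)
# ---------------------------------------------------------------------------


def _stack_expert_params(m: ModelParams) -> dict:
    return {
        "Wr": np.stack([e.recurrent_weights for e in m.experts]),
        "Win": np.stack([e.input_weights for e in m.experts]),
        "br": np.stack([e.recurrent_bias for e in m.experts]),
        "Wout": np.stack([e.output_weights for e in m.experts]),
        "bout": np.stack([e.output_bias for e in m.experts]),
    }


def _unstack_expert_params(m: ModelParams, P: dict) -> None:
    for i, e in enumerate(m.experts):
        e.recurrent_weights = P["Wr"][i].copy()
        e.input_weights = P["Win"][i].copy()
        e.output_weights = P["Wout"][i].copy()
        e.recurrent_bias = P["br"][i].copy()
        e.output_bias = P["bout"][i].copy()


def _gating_param_dict(g: GatingParams) -> dict:
    return {
        "A": g.mid_recurrent, "B": g.mid_from_high, "U": g.mid_input_weights,
        "G": g.mid_gatefeedback_weights, "bm": g.mid_bias,
        "Eh": g.high_recurrent, "Fh": g.high_from_mid, "bh": g.high_bias,
        "C": g.gate_readout,
    }


def _set_gating_params(g: GatingParams, P: dict) -> None:
    g.mid_recurrent = P["A"].copy()
    g.mid_from_high = P["B"].copy()
    g.mid_input_weights = P["U"].copy()
    g.mid_gatefeedback_weights = P["G"].copy()
    g.mid_bias = P["bm"].copy()
    g.high_recurrent = P["Eh"].copy()
    g.high_from_mid = P["Fh"].copy()
    g.high_bias = P["bh"].copy()
    g.gate_readout = P["C"].copy()


def _tree_map(f: Callable, *trees):
    t0 = trees[0]
    if isinstance(t0, dict):
        return {k: _tree_map(f, *[t[k] for t in trees]) for k in t0}
    if isinstance(t0, list):
        return [_tree_map(f, *items) for items in zip(*trees)]
    return f(*trees)


def _tree_copy(tree):
    return _tree_map(lambda a: np.array(a, dtype=float, copy=True), tree)


# ---------------------------------------------------------------------------
# Phase 1: likelihood, prior, and gradients
# ---------------------------------------------------------------------------


def _delayed_inputs(X: Array, d: int) -> Array:
    """Input seen by the experts at each predicted step: X[max(t - d, 0)].

    The input buffer is pre-filled with the first observation, so early steps
    see x_0."""
    S = X.shape[0] - 1
    idx = np.maximum(np.arange(S) - d, 0)
    return X[idx]


def _expert_forward(P: dict, X: Array, u0: Array, d: int, al: float):
    """Teacher-forced forward pass of all experts over one sequence.

    Returns internal states ``u`` (S+1, E, N), their tanh, the expert outputs
    ``y`` (S, E, D) and the delayed input matrix."""
    Xd = _delayed_inputs(X, d)
    inX = np.einsum("end,td->ten", P["Win"], Xd) + P["br"]
    u = _kernels.expert_scan(np.ascontiguousarray(P["Wr"]),
                             np.ascontiguousarray(u0),
                             np.ascontiguousarray(inX), al)
    th = np.tanh(u)
    z = np.einsum("edn,ten->ted", P["Wout"], th[1:]) + P["bout"]
    y = np.tanh(z)
    return u, th, y, Xd


def _mixture_terms(y: Array, Y: Array, v: Array, sigma: float):
    """Per-step mixture log-likelihood and responsibilities.

    ``y`` (S, E, D) expert outputs, ``Y`` (S, D) targets, ``v`` (S, E) gate
    variables.  Returns (loglik, responsibilities h, ghat, squared errors)."""
    D = Y.shape[1]
    e = y - Y[:, None, :]
    sq = np.einsum("ted,ted->te", e, e)
    logN = -sq / (2.0 * sigma ** 2) - 0.5 * D * (_LOG2PI + 2.0 * np.log(sigma))
    lg = v - v.max(axis=1, keepdims=True)
    lg = lg - np.log(np.exp(lg).sum(axis=1, keepdims=True))
    a = lg + logN
    amax = a.max(axis=1, keepdims=True)
    lse = amax[:, 0] + np.log(np.exp(a - amax).sum(axis=1))
    h = np.exp(a - lse[:, None])
    return float(lse.sum()), h, np.exp(lg), sq


def mixture_loglik(y_obs: Array, expert_outputs: Sequence[Array], gate: Array,
                   noise: NoiseModel) -> float:
    """log of the gate-weighted mixture of isotropic Gaussians at ``y_obs``."""
    if noise.sigma <= 0:
        raise ConfigurationError("sigma must be positive")
    y_obs = np.asarray(y_obs, float)
    ys = np.asarray(expert_outputs, float)
    g = np.asarray(gate, float)
    D = y_obs.shape[0]
    sq = ((ys - y_obs) ** 2).sum(axis=1)
    logN = -sq / (2.0 * noise.sigma ** 2) - 0.5 * D * (_LOG2PI + 2.0 * np.log(noise.sigma))
    a = np.log(np.maximum(g, 1e-300)) + logN
    amax = a.max()
    return float(amax + np.log(np.exp(a - amax).sum()))


def sequence_loglik(ts: TrainingSet, m: ModelParams, seq_index: int = 0) -> float:
    """Teacher-forced mixture log-likelihood of one training sequence."""
    P = _stack_expert_params(m)
    X = ts.sequences[seq_index].values
    al = m.timescales.step_size / m.timescales.tau_low
    _, _, y, _ = _expert_forward(P, X, ts.expert_init[seq_index], m.feedback_delay, al)
    ll, _, _, _ = _mixture_terms(y, X[1:], ts.gate_vars[seq_index].v, ts.noise.sigma)
    return ll


def brownian_log_prior(v: GateVariableSequence | Array, scale: float) -> float:
    """Log-density (up to a constant) of the Brownian smoothness prior on v."""
    if scale <= 0:
        raise ConfigurationError("prior scale must be positive")
    arr = v.v if isinstance(v, GateVariableSequence) else np.asarray(v, float)
    dv = np.diff(arr, axis=0)
    return float(-np.sum(dv * dv) / (2.0 * scale ** 2))


def _brownian_prior_grad(v: Array, scale: float) -> Array:
    g = np.zeros_like(v)
    dv = np.diff(v, axis=0) / scale ** 2
    g[:-1] += dv
    g[1:] -= dv
    return g


def phase1_objective(ts: TrainingSet, m: ModelParams, prior_scale: float = 1.0) -> float:
    """Sum of sequence log-likelihoods plus the Brownian log-prior on v."""
    total = 0.0
    for s in range(ts.n_sequences):
        total += sequence_loglik(ts, m, s)
        total += brownian_log_prior(ts.gate_vars[s], prior_scale)
    return total


def _expert_backward(P: dict, u: Array, th: Array, y: Array, Xd: Array,
                     dLdy: Array, al: float):
    """Reverse-mode pass for one sequence; returns weight grads and dL/du0."""
    S = y.shape[0]
    dz = dLdy * (1.0 - y * y)
    gWout = np.einsum("ted,ten->edn", dz, th[1:])
    gbout = dz.sum(axis=0)
    dq = np.einsum("edn,ted->ten", P["Wout"], dz)
    du_out = dq * (1.0 - th[1:] ** 2)
    lam_store, du0 = _kernels.expert_backscan(
        np.ascontiguousarray(P["Wr"]), np.ascontiguousarray(du_out),
        np.ascontiguousarray(th), al)
    lam_all = al * lam_store[1:]
    gWr = np.einsum("ten,tem->enm", lam_all, th[:-1])
    gWin = np.einsum("ten,td->end", lam_all, Xd)
    gbr = lam_all.sum(axis=0)
    return {"Wr": gWr, "Win": gWin, "br": gbr, "Wout": gWout, "bout": gbout}, du0


def phase1_gradients(ts: TrainingSet, m: ModelParams, prior_scale: float = 1.0):
    """Objective and exact gradients of Phase 1 for every parameter block.

    Returns ``(objective, grads)`` where ``grads`` holds stacked expert-weight
    gradients plus ``sigma`` (scalar), ``v`` and ``u0`` (per-sequence lists).
    All gradients are ascent directions on the log-posterior.
    """
    m.validate()
    P = _stack_expert_params(m)
    al = m.timescales.step_size / m.timescales.tau_low
    sigma = ts.noise.sigma
    D = m.n_dim
    obj = 0.0
    gP = {k: np.zeros_like(a) for k, a in P.items()}
    g_sigma = 0.0
    g_v: list[Array] = []
    g_u0: list[Array] = []
    for s in range(ts.n_sequences):
        X = ts.sequences[s].values
        v = ts.gate_vars[s].v
        u, th, y, Xd = _expert_forward(P, X, ts.expert_init[s], m.feedback_delay, al)
        ll, h, gh, sq = _mixture_terms(y, X[1:], v, sigma)
        obj += ll + brownian_log_prior(v, prior_scale)
        if not np.isfinite(obj):
            raise DivergenceError(f"non-finite objective in sequence {s}")
        dLdy = h[:, :, None] * (X[1:, None, :] - y) / sigma ** 2
        gs, du0 = _expert_backward(P, u, th, y, Xd, dLdy, al)
        for k in gP:
            gP[k] += gs[k]
        g_sigma += float(np.sum(h * (sq / sigma ** 3 - D / sigma)))
        g_v.append((h - gh) + _brownian_prior_grad(v, prior_scale))
        g_u0.append(du0)
    grads = dict(gP)
    grads["sigma"] = np.asarray(g_sigma)
    grads["v"] = g_v
    grads["u0"] = g_u0
    return obj, grads


# ---------------------------------------------------------------------------
# Phase 2: gating-network objective (negative KL) and gradients
# ---------------------------------------------------------------------------


def _gate_feedback_targets(gh: Array, n_experts: int) -> Array:
    """Teacher-forced gate feedback: uniform at the first step (the gate is
    undefined before t=0), then the optimized gate estimates."""
    S = gh.shape[0]
    F = np.empty_like(gh)
    F[0] = 1.0 / n_experts
    if S > 1:
        F[1:] = gh[:-1]
    return F


def _gating_forward(G: dict, X: Array, gh: Array, mid0: Array, high0: Array,
                    am: float, ah: float):
    """Teacher-forced forward pass of the gating network over one sequence."""
    S = X.shape[0] - 1
    E = gh.shape[1]
    F = _gate_feedback_targets(gh, E)
    inmid = X[:-1] @ G["U"].T + F @ G["G"].T + G["bm"]
    mid, high = _kernels.gating_scan(
        np.ascontiguousarray(G["A"]), np.ascontiguousarray(G["B"]),
        np.ascontiguousarray(G["Eh"]), np.ascontiguousarray(G["Fh"]),
        np.ascontiguousarray(G["bh"]), np.ascontiguousarray(inmid),
        np.ascontiguousarray(mid0), np.ascontiguousarray(high0), am, ah)
    tmids = np.tanh(mid)
    thighs = np.tanh(high)
    pre = tmids[1:] @ G["C"].T
    logg = pre - pre.max(axis=1, keepdims=True)
    logg = logg - np.log(np.exp(logg).sum(axis=1, keepdims=True))
    return mid, high, tmids, thighs, logg, F


def _kl_rows(gh: Array, logg: Array) -> float:
    """Total KL(ghat || g) over a sequence; 0 ln 0 := 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        lh = np.where(gh > 0, np.log(np.maximum(gh, 1e-300)), 0.0)
    return float(np.sum(gh * (lh - logg)))


def phase2_objective(ts: TrainingSet, m: ModelParams) -> float:
    """Negative total KL(ghat || g) under teacher forcing (maximum 0)."""
    G = _gating_param_dict(m.gating)
    am = m.timescales.step_size / m.timescales.tau_mid
    ah = m.timescales.step_size / m.timescales.tau_high
    total = 0.0
    for s in range(ts.n_sequences):
        gh = ts.gate_vars[s].ghat
        _check_prob_rows(gh)
        _, _, _, _, logg, _ = _gating_forward(
            G, ts.sequences[s].values, gh, ts.mid_init[s], ts.high_init[s], am, ah)
        total -= _kl_rows(gh, logg)
    return total


def _check_prob_rows(gh: Array) -> None:
    if np.any(gh < -1e-12) or np.any(np.abs(gh.sum(axis=1) - 1.0) > 1e-8):
        raise ConfigurationError("gate targets must be probability rows")


def phase2_gradients(ts: TrainingSet, m: ModelParams,
                     freeze_initial_states: bool = False):
    """Objective (negative KL) and its gradients for the gating parameters.

    Gradients are ascent directions; per-sequence initial-state gradients are
    returned unless frozen."""
    G = _gating_param_dict(m.gating)
    am = m.timescales.step_size / m.timescales.tau_mid
    ah = m.timescales.step_size / m.timescales.tau_high
    gG = {k: np.zeros_like(a) for k, a in G.items()}
    g_mid0: list[Array] = []
    g_high0: list[Array] = []
    obj = 0.0
    A, B, Eh, Fh, C = G["A"], G["B"], G["Eh"], G["Fh"], G["C"]
    for s in range(ts.n_sequences):
        gh = ts.gate_vars[s].ghat
        _check_prob_rows(gh)
        X = ts.sequences[s].values
        S = X.shape[0] - 1
        mid, high, tmids, thighs, logg, F = _gating_forward(
            G, X, gh, ts.mid_init[s], ts.high_init[s], am, ah)
        obj -= _kl_rows(gh, logg)
        g = np.exp(logg)
        dpre = gh - g  # d obj / d pre-activation
        gG["C"] += np.einsum("te,tm->em", dpre, tmids[1:])
        dmid_out = (1.0 - tmids[1:] ** 2) * (dpre @ C)
        Lm, Lh, du_mid0, du_high0 = _kernels.gating_backscan(
            np.ascontiguousarray(A), np.ascontiguousarray(B),
            np.ascontiguousarray(Eh), np.ascontiguousarray(Fh),
            np.ascontiguousarray(dmid_out), np.ascontiguousarray(tmids),
            np.ascontiguousarray(thighs), am, ah)
        wm = am * Lm[1:]
        wh = ah * Lh[1:]
        gG["A"] += np.einsum("tm,tn->mn", wm, tmids[:-1])
        gG["B"] += np.einsum("tm,th->mh", wm, thighs[:-1])
        gG["U"] += np.einsum("tm,td->md", wm, X[:-1])
        gG["G"] += np.einsum("tm,te->me", wm, F)
        gG["bm"] += wm.sum(axis=0)
        gG["Eh"] += np.einsum("th,tk->hk", wh, thighs[:-1])
        gG["Fh"] += np.einsum("th,tm->hm", wh, tmids[:-1])
        gG["bh"] += wh.sum(axis=0)
        g_mid0.append(du_mid0)
        g_high0.append(du_high0)
    grads = dict(gG)
    if not freeze_initial_states:
        grads["mid0"] = g_mid0
        grads["high0"] = g_high0
    return obj, grads


# ---------------------------------------------------------------------------
# Optimizer: momentum and the adaptive-rate acceleration
# ---------------------------------------------------------------------------


def momentum_update(theta, grad, prev_delta, learning_rate: float, momentum: float):
    """Gradient-ascent momentum step: ``delta' = a*grad + eta*prev``;
    ``theta' = theta + delta'``.  Operates on matching trees of arrays."""
    delta = _tree_map(lambda g, p: learning_rate * g + momentum * p, grad, prev_delta)
    theta_new = _tree_map(lambda t, d: t + d, theta, delta)
    return theta_new, delta


@dataclass
class AdaptiveStepResult:
    params: dict
    delta: dict
    alpha: float
    accepted: bool
    kl_before: float
    kl_after: float
    retries: int


def adaptive_rate_step(params: dict, grads: dict, prev_delta: dict, alpha: float,
                       kl_fn: Callable[[dict], float],
                       cfg: OptimizerConfig) -> AdaptiveStepResult:
    """One accelerated Phase-2 step.

    A candidate momentum update is evaluated through ``kl_fn``; the ratio
    ``r = KL(candidate) / KL(current)`` decides acceptance.  If ``r`` exceeds
    the acceptance threshold the learning rate shrinks and the candidate is
    recomputed (up to ``max_retries``); on acceptance the rate grows when the
    step clearly improved.  Accepted steps therefore never increase the KL
    when the acceptance threshold is at most 1.
    """
    kl_before = kl_fn(params)
    tiny = 1e-15
    for attempt in range(cfg.max_retries):
        cand, delta = momentum_update(params, grads, prev_delta, alpha, cfg.momentum)
        kl_after = kl_fn(cand)
        if not np.isfinite(kl_after):
            r = np.inf
        elif kl_before > tiny:
            r = kl_after / kl_before
        else:
            r = 0.0 if kl_after <= kl_before + tiny else np.inf
        if r > cfg.accept_threshold:
            alpha *= cfg.rate_down
            continue
        if r < cfg.improve_threshold:
            alpha *= cfg.rate_up
        return AdaptiveStepResult(cand, delta, alpha, True, kl_before, kl_after, attempt)
    warnings.warn("adaptive_rate_step: max_retries exhausted; step skipped")
    zero = _tree_map(np.zeros_like, prev_delta)
    return AdaptiveStepResult(params, zero, alpha, False, kl_before, kl_before,
                              cfg.max_retries)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def init_params(cfg: ModelConfig, rng: np.random.Generator) -> ModelParams:
    """Random model parameters: every weight and bias drawn uniformly from
    ``(-1/sqrt(N), 1/sqrt(N))`` with ``N`` the destination layer's unit count."""
    D = cfg.n_dim

    def u(bound, *shape):
        return rng.uniform(-bound, bound, size=shape)

    bN = 1.0 / np.sqrt(cfg.n_units)
    bD = 1.0 / np.sqrt(D)
    experts = [
        ExpertParams(
            recurrent_weights=u(bN, cfg.n_units, cfg.n_units),
            input_weights=u(bN, cfg.n_units, D),
            output_weights=u(bD, D, cfg.n_units),
            recurrent_bias=u(bN, cfg.n_units),
            output_bias=u(bD, D),
        )
        for _ in range(cfg.n_experts)
    ]
    bM = 1.0 / np.sqrt(cfg.n_mid)
    bH = 1.0 / np.sqrt(cfg.n_high)
    bE = 1.0 / np.sqrt(cfg.n_experts)
    gating = GatingParams(
        mid_recurrent=u(bM, cfg.n_mid, cfg.n_mid),
        mid_from_high=u(bM, cfg.n_mid, cfg.n_high),
        mid_input_weights=u(bM, cfg.n_mid, D),
        mid_gatefeedback_weights=u(bM, cfg.n_mid, cfg.n_experts),
        mid_bias=u(bM, cfg.n_mid),
        high_recurrent=u(bH, cfg.n_high, cfg.n_high),
        high_from_mid=u(bH, cfg.n_high, cfg.n_mid),
        high_bias=u(bH, cfg.n_high),
        gate_readout=u(bE, cfg.n_experts, cfg.n_mid),
    )
    m = ModelParams(experts=experts, gating=gating, timescales=cfg.timescales,
                    feedback_delay=cfg.feedback_delay,
                    io_dims=(cfg.proprio_dim, cfg.vision_dim))
    m.validate()
    return m


def init_training_set(m: ModelParams, trajectories: Sequence[Trajectory],
                      rng: np.random.Generator, sigma0: float = 0.3) -> TrainingSet:
    """Per-sequence initial states uniform in (-1, 1); gate variables zero
    (uniform gate estimate); sigma at its starting value."""
    E, N = m.n_experts, m.experts[0].n_units
    M, H = m.gating.n_mid, m.gating.n_high
    seqs = list(trajectories)
    for tr in seqs:
        if tr.n_dim != m.n_dim:
            raise ConfigurationError("trajectory dimension does not match model")
        if len(tr) < 2:
            raise ConfigurationError("training sequences need length >= 2")
    return TrainingSet(
        sequences=seqs,
        expert_init=[rng.uniform(-1, 1, size=(E, N)) for _ in seqs],
        mid_init=[rng.uniform(-1, 1, size=M) for _ in seqs],
        high_init=[rng.uniform(-1, 1, size=H) for _ in seqs],
        gate_vars=[GateVariableSequence(np.zeros((len(tr) - 1, E))) for tr in seqs],
        noise=NoiseModel(sigma=sigma0),
    )


# ---------------------------------------------------------------------------
# Training drivers
# ---------------------------------------------------------------------------


@dataclass
class Phase1Result:
    model: ModelParams
    training_set: TrainingSet
    trace: list  # (epoch, objective, alpha)


@dataclass
class Phase2Result:
    model: ModelParams
    training_set: TrainingSet
    trace: list  # (epoch, kl, alpha)


def _tree_sq_norm(tree) -> float:
    total = 0.0

    def acc(a):
        nonlocal total
        total += float(np.sum(np.asarray(a) ** 2))
        return a

    _tree_map(acc, tree)
    return total


def _scale_and_clip(grads: dict, scales: dict, clip_norm: Optional[float]) -> dict:
    """Per-block gradient scaling (size invariance) plus global norm clipping."""
    g = {k: _tree_map(lambda a, s=scales[k]: a * s, v) for k, v in grads.items()}
    if clip_norm is not None:
        norm = np.sqrt(_tree_sq_norm(g))
        if norm > clip_norm:
            g = _tree_map(lambda a: a * (clip_norm / norm), g)
    return g


def _converged(history: list[float], window: int, tol: float,
               min_epochs: int = 0) -> bool:
    # the window test only engages after a warmup: early plateaus are common
    # before the recurrent dynamics pick up the task
    if len(history) <= max(window, min_epochs):
        return False
    prev = history[-window - 1]
    cur = history[-1]
    scale = max(abs(prev), abs(cur), 1.0)
    return (cur - prev) / scale < tol


def train_phase1(ts: TrainingSet, m: ModelParams, cfg: OptimizerConfig,
                 rng: Optional[np.random.Generator] = None) -> Phase1Result:
    """Phase 1: fit experts, gate variables, noise scale and expert initial
    states by momentum gradient ascent on the log-posterior.

    Returns the best-seen parameters and the per-epoch objective trace.
    ``rng`` is accepted for interface symmetry; the optimization itself is
    deterministic given the initialized training set.
    """
    m = copy.deepcopy(m)
    ts = copy.deepcopy(ts)
    theta = _stack_expert_params(m)
    theta["sigma"] = np.asarray(float(ts.noise.sigma))
    theta["v"] = [gv.v for gv in ts.gate_vars]
    theta["u0"] = list(ts.expert_init)
    prev_delta = _tree_map(np.zeros_like, theta)
    n_summed = ts.total_steps * m.n_dim
    # weights and sigma accumulate over every step and output dimension; the
    # gate variables are per-step; initial states act per sequence
    scales = {"Wr": 1.0 / n_summed, "Win": 1.0 / n_summed, "br": 1.0 / n_summed,
              "Wout": 1.0 / n_summed, "bout": 1.0 / n_summed,
              "sigma": 1.0 / n_summed, "v": 1.0, "u0": 1.0 / m.n_dim}
    alpha = cfg.learning_rate
    trace: list = []
    best_obj = -np.inf
    best_theta = None
    history: list[float] = []

    def write_back(th):
        _unstack_expert_params(m, {k: th[k] for k in ("Wr", "Win", "br", "Wout", "bout")})
        ts.noise.sigma = float(th["sigma"])
        for s in range(ts.n_sequences):
            ts.gate_vars[s].v = th["v"][s].copy()
            ts.expert_init[s] = th["u0"][s].copy()

    for epoch in range(cfg.max_epochs):
        write_back(theta)
        try:
            obj, grads = phase1_gradients(ts, m, cfg.prior_scale)
        except DivergenceError as err:
            err.trace = trace
            raise
        if not np.isfinite(obj):
            raise DivergenceError("phase 1 objective diverged", trace)
        trace.append((epoch, obj, alpha))
        history.append(obj)
        if obj > best_obj:
            best_obj = obj
            best_theta = _tree_copy(theta)
        if _converged(history, cfg.tolerance_window, cfg.tolerance, cfg.min_epochs):
            break
        grads = _scale_and_clip(grads, scales, cfg.clip_norm)
        theta, prev_delta = momentum_update(theta, grads, prev_delta, alpha, cfg.momentum)
        theta["sigma"] = np.asarray(max(float(theta["sigma"]), ts.noise.min_sigma))

    write_back(best_theta if best_theta is not None else theta)
    return Phase1Result(m, ts, trace)


def train_phase2(ts: TrainingSet, m: ModelParams, cfg: OptimizerConfig,
                 freeze_initial_states: bool = False) -> Phase2Result:
    """Phase 2: fit the gating network to the Phase-1 gate schedule.

    Minimizes KL(ghat || g) with teacher forcing, using the adaptive
    learning-rate acceleration; the KL over accepted steps is non-increasing.
    Gating initial states are optimized unless frozen.
    """
    m = copy.deepcopy(m)
    ts = copy.deepcopy(ts)
    am = m.timescales.step_size / m.timescales.tau_mid
    ah = m.timescales.step_size / m.timescales.tau_high
    targets = [gv.ghat for gv in ts.gate_vars]
    for gh in targets:
        _check_prob_rows(gh)
    Xs = [tr.values for tr in ts.sequences]

    def kl_fn(theta: dict) -> float:
        total = 0.0
        for s in range(ts.n_sequences):
            mid0 = theta["mid0"][s] if "mid0" in theta else ts.mid_init[s]
            high0 = theta["high0"][s] if "high0" in theta else ts.high_init[s]
            _, _, _, _, logg, _ = _gating_forward(theta, Xs[s], targets[s],
                                                  mid0, high0, am, ah)
            total += _kl_rows(targets[s], logg)
        return total

    def write_back(theta: dict) -> None:
        _set_gating_params(m.gating, theta)
        if "mid0" in theta:
            for s in range(ts.n_sequences):
                ts.mid_init[s] = theta["mid0"][s].copy()
                ts.high_init[s] = theta["high0"][s].copy()

    theta = _gating_param_dict(m.gating)
    theta = {k: np.array(a, copy=True) for k, a in theta.items()}
    if not freeze_initial_states:
        theta["mid0"] = [a.copy() for a in ts.mid_init]
        theta["high0"] = [a.copy() for a in ts.high_init]
    prev_delta = _tree_map(np.zeros_like, theta)
    scales = {k: 1.0 / ts.total_steps for k in
              ("A", "B", "U", "G", "bm", "Eh", "Fh", "bh", "C")}
    scales["mid0"] = scales["high0"] = 1.0
    alpha = cfg.learning_rate
    trace: list = []
    history: list[float] = []
    for epoch in range(cfg.max_epochs):
        write_back(theta)
        obj, grads = phase2_gradients(ts, m, freeze_initial_states)
        if not np.isfinite(obj):
            raise DivergenceError("phase 2 objective diverged", trace)
        grads = _scale_and_clip(
            grads, {k: scales[k] for k in grads}, cfg.clip_norm)
        step = adaptive_rate_step(theta, grads, prev_delta, alpha, kl_fn, cfg)
        theta, prev_delta, alpha = step.params, step.delta, step.alpha
        trace.append((epoch, step.kl_after, alpha))
        history.append(-step.kl_after)
        if step.kl_after <= 1e-12:
            break
        if _converged(history, cfg.tolerance_window, cfg.tolerance, cfg.min_epochs):
            break
        if alpha < 1e-18:
            break
    write_back(theta)
    return Phase2Result(m, ts, trace)


@dataclass
class TwoPhaseResult:
    model: ModelParams
    training_set: TrainingSet
    phase1: Phase1Result
    phase2: Phase2Result


def train_two_phase(trajectories: Sequence[Trajectory], model_cfg: ModelConfig,
                    rng: np.random.Generator,
                    phase1_cfg: Optional[OptimizerConfig] = None,
                    phase2_cfg: Optional[OptimizerConfig] = None,
                    sigma0: float = 0.3,
                    freeze_initial_states: bool = False) -> TwoPhaseResult:
    """Initialize a model and run the full two-phase training procedure."""
    phase1_cfg = phase1_cfg or OptimizerConfig()
    phase2_cfg = phase2_cfg or OptimizerConfig()
    m = init_params(model_cfg, rng)
    ts = init_training_set(m, trajectories, rng, sigma0=sigma0)
    r1 = train_phase1(ts, m, phase1_cfg, rng)
    r2 = train_phase2(r1.training_set, r1.model, phase2_cfg,
                      freeze_initial_states=freeze_initial_states)
    return TwoPhaseResult(r2.model, r2.training_set, r1, r2)
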