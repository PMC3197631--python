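"""Dynamical and symbolic analyses of trained models.

Covers: maximum Lyapunov exponents of the whole network or of a subnetwork
(two-trajectory Benettin estimate in motor-imagery mode), autocorrelation,
symbolization of vision trajectories into L/C/R position strings, n-block
novelty ratios, maximum-likelihood transition-probability reconstruction,
regeneration fidelity against a teaching sequence, higher-level fixed-point
detection, and an open-loop noise-robustness proxy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .model import (
    Array,
    ConfigurationError,
    ModelParams,
    NetworkState,
    Trajectory,
    _kernel_args,
    _state_args,
    generate_closed_loop,
)
from .synth import SYMBOLS, LabeledSequence, TaskConfig

# ---------------------------------------------------------------------------
# Maximum Lyapunov exponent
# ---------------------------------------------------------------------------


@dataclass
class LyapunovConfig:
    """Benettin-estimate settings.

    The separation between a reference and a perturbed closed-loop run is
    renormalized to ``perturbation_size`` every ``renorm_interval`` steps;
    log expansion factors are measured on the selected subnetwork's state
    components only and averaged per step after the transient."""

    n_samples: int = 20
    horizon: int = 5000
    transient: int = 200
    perturbation_size: float = 1e-8
    renorm_interval: int = 10
    subnetwork: str = "entire"  # entire | middle | higher | expert_<i>

    def __post_init__(self) -> None:
        if self.perturbation_size <= 0:
            raise ConfigurationError("perturbation_size must be positive")
        if self.horizon <= self.transient:
            raise ConfigurationError("horizon must exceed transient")
        if self.renorm_interval < 1:
            raise ConfigurationError("renorm_interval must be >= 1")


def _random_state(m: ModelParams, rng: np.random.Generator) -> NetworkState:
    E, N = m.n_experts, m.experts[0].n_units
    s = NetworkState.initial(
        m,
        expert_states=rng.uniform(-1, 1, (E, N)),
        mid_state=rng.uniform(-1, 1, m.gating.n_mid),
        high_state=rng.uniform(-1, 1, m.gating.n_high),
        x0=rng.uniform(-1, 1, m.n_dim),
    )
    return s


def _perturb(m: ModelParams, s: NetworkState, eps: float,
             rng: np.random.Generator) -> NetworkState:
    p = s.copy()
    dU = rng.normal(size=p.expert_states.shape)
    dm = rng.normal(size=p.mid_state.shape)
    dh = rng.normal(size=p.high_state.shape)
    norm = np.sqrt((dU ** 2).sum() + (dm ** 2).sum() + (dh ** 2).sum())
    scale = eps / norm
    p.expert_states = p.expert_states + dU * scale
    p.mid_state = p.mid_state + dm * scale
    if not m.lesioned:
        p.high_state = p.high_state + dh * scale
    return p


_SEL_CODES = {"entire": _kernels.SEL_ENTIRE, "middle": _kernels.SEL_MIDDLE,
              "higher": _kernels.SEL_HIGHER}


def _sel_code(sel: str) -> tuple[int, int]:
    if sel in _SEL_CODES:
        return _SEL_CODES[sel], 0
    if sel.startswith("expert_"):
        return _kernels.SEL_EXPERT, int(sel.split("_", 1)[1])
    raise ConfigurationError(f"unknown subnetwork selector: {sel}")


def _lyapunov_sample(m: ModelParams, ka: tuple, cfg: LyapunovConfig,
                     rng: np.random.Generator) -> float:
    eps = cfg.perturbation_size
    ref = _random_state(m, rng)
    pert = _perturb(m, ref, eps, rng)
    sel, sel_e = _sel_code(cfg.subnetwork)
    x = np.ascontiguousarray(ref.input_buffer[-1])
    log_sum, n_steps = _kernels.benettin_scan(
        *ka, *_state_args(ref), x.copy(), *_state_args(pert), x.copy(),
        cfg.horizon, cfg.transient, cfg.renorm_interval, eps, sel, sel_e)
    if n_steps <= 0:
        return np.nan  # separation underflow; caller resamples
    return log_sum / n_steps


def max_lyapunov(m: ModelParams, cfg: LyapunovConfig,
                 rng: np.random.Generator) -> tuple[float, Array]:
    """Mean maximum Lyapunov exponent over random initial states, plus the
    per-sample estimates (nats per step)."""
    if m.lesioned and cfg.subnetwork == "higher":
        raise ConfigurationError("higher subnetwork is frozen in a lesioned model")
    ka = _kernel_args(m)
    samples = []
    attempts = 0
    while len(samples) < cfg.n_samples:
        attempts += 1
        if attempts > 5 * cfg.n_samples:
            raise RuntimeError("Lyapunov sampling kept underflowing; "
                               "increase perturbation_size")
        lam = _lyapunov_sample(m, ka, cfg, rng)
        if np.isfinite(lam):
            samples.append(lam)
    samples = np.array(samples)
    return float(samples.mean()), samples


# ---------------------------------------------------------------------------
# Autocorrelation
# ---------------------------------------------------------------------------


def autocorrelation(series: Array, max_lag: int) -> Array:
    """Normalized autocorrelation per unit up to ``max_lag``.

    ``series`` is (T,) or (T, U); the result is (max_lag + 1,) or
    (max_lag + 1, U) with value 1 at lag 0.  Constant series return 1 at all
    lags by convention."""
    x = np.asarray(series, float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    T = x.shape[0]
    if T <= max_lag + 1:
        raise ConfigurationError("series too short for requested max_lag")
    xc = x - x.mean(axis=0)
    denom = (xc * xc).mean(axis=0)
    scale = np.abs(x).max(axis=0) ** 2 + 1e-300
    constant = denom < 1e-24 * scale
    out = np.empty((max_lag + 1, x.shape[1]))
    for k in range(max_lag + 1):
        # lag-adjusted (unbiased) normalization so a pure periodic signal
        # scores 1 at its period regardless of series length
        num = (xc[: T - k] * xc[k:]).sum(axis=0) / (T - k)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[k] = np.where(constant, 1.0, num / np.where(constant, 1.0, denom))
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# Symbolization and block statistics
# ---------------------------------------------------------------------------


@dataclass
class SymbolizerConfig:
    """Threshold bins on the horizontal vision channel.

    Values below the first threshold read L, between the thresholds C, above
    R; a bin must persist ``min_dwell`` steps to emit a symbol, and repeats
    are collapsed."""

    thresholds: tuple[float, float] = (-0.3, 0.3)
    min_dwell: int = 10

    def __post_init__(self) -> None:
        if not self.thresholds[0] < self.thresholds[1]:
            raise ConfigurationError("thresholds must be increasing")
        if self.min_dwell < 1:
            raise ConfigurationError("min_dwell must be >= 1")

    @staticmethod
    def for_task(task: TaskConfig) -> "SymbolizerConfig":
        """Midpoint thresholds between the task's object positions; dwell of
        a quarter primitive."""
        xs = sorted(float(task.positions[s][0]) for s in SYMBOLS)
        return SymbolizerConfig(
            thresholds=((xs[0] + xs[1]) / 2, (xs[1] + xs[2]) / 2),
            min_dwell=max(1, task.primitive_duration // 4),
        )


def _bins(vis_x: Array, cfg: SymbolizerConfig) -> Array:
    return np.digitize(vis_x, cfg.thresholds)  # 0=L, 1=C, 2=R


def symbolize(traj: Trajectory, cfg: SymbolizerConfig) -> str:
    """Collapse a trajectory's horizontal vision channel into a position
    symbol string; dwells shorter than ``min_dwell`` are ignored."""
    if traj.vision.shape[1] < 1:
        raise ConfigurationError("trajectory has no vision channels")
    b = _bins(traj.vision[:, 0], cfg)
    out: list[str] = []
    run_val, run_len = b[0], 1
    for v in b[1:]:
        if v == run_val:
            run_len += 1
        else:
            if run_len >= cfg.min_dwell:
                sym = SYMBOLS[run_val]
                if not out or out[-1] != sym:
                    out.append(sym)
            run_val, run_len = v, 1
    if run_len >= cfg.min_dwell:
        sym = SYMBOLS[run_val]
        if not out or out[-1] != sym:
            out.append(sym)
    return "".join(out)


def nblock_novelty(symbols: str, n: int) -> float:
    """Distinct observed n-blocks over all admissible n-blocks.

    Admissible blocks are length-n strings over {L, C, R} without immediate
    repeats: ``3 * 2**(n-1)`` of them."""
    if n < 1:
        raise ConfigurationError("block length must be >= 1")
    if len(symbols) < n:
        raise ConfigurationError("symbol string shorter than block length")
    blocks = {symbols[i:i + n] for i in range(len(symbols) - n + 1)}
    total = 3 * 2 ** (n - 1)
    return len(blocks) / total


def transition_probability_estimate(symbols: str) -> tuple[Array, Array]:
    """Maximum-likelihood bigram transition matrix over (L, C, R).

    Returns ``(probs, counts)``; rows with no observations are NaN in
    ``probs``.  The diagonal is zero by construction (repeats never occur in
    collapsed symbol strings)."""
    if len(symbols) < 2:
        raise ConfigurationError("need at least two symbols")
    counts = np.zeros((3, 3))
    idx = {s: i for i, s in enumerate(SYMBOLS)}
    for a, b in zip(symbols, symbols[1:]):
        counts[idx[a], idx[b]] += 1
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row > 0, counts / np.where(row > 0, row, 1.0), np.nan)
    return probs, counts


# ---------------------------------------------------------------------------
# Model-level analyses
# ---------------------------------------------------------------------------


def regeneration_fidelity(m: ModelParams, s0: NetworkState,
                          teaching: LabeledSequence, cfg: SymbolizerConfig,
                          horizon: Optional[int] = None) -> int:
    """Number of teaching primitive transitions reproduced from the start.

    Generates closed-loop imagery from ``s0``, symbolizes it and counts the
    length (in transitions) of the common prefix with the teaching symbols."""
    T = horizon if horizon is not None else len(teaching.trajectory)
    gen = generate_closed_loop(m, s0, T, x0=teaching.trajectory.values[0])
    got = symbolize(gen, cfg)
    want = teaching.symbol_string
    k = 0
    for a, b in zip(got, want):
        if a != b:
            break
        k += 1
    return max(0, k - 1)


def detect_fixed_point(m: ModelParams, s0: NetworkState, horizon: int,
                       tol: float = 1e-5) -> tuple[bool, Optional[int]]:
    """Whether the higher-level state settles to a fixed point.

    Runs closed-loop imagery and checks that the per-step change of the
    higher-level state stays below ``tol`` throughout the final 10% of the
    horizon.  Also returns the first step after which the change never again
    exceeds ``tol`` (None if it always does)."""
    X = np.zeros((horizon, m.n_dim))
    X[0] = s0.input_buffer[-1]
    _, HI = _kernels.run_scan(*_kernel_args(m), *_state_args(s0), X, True)
    highs = np.vstack([s0.high_state[None], HI])
    deltas = np.abs(np.diff(highs, axis=0)).max(axis=1)
    tail = max(1, horizon // 10)
    if not np.all(deltas[-tail:] < tol):
        return False, None
    above = np.nonzero(deltas >= tol)[0]
    return True, int(above[-1] + 1) if above.size else 0


def noise_robustness(m: ModelParams, s0: NetworkState, teaching: LabeledSequence,
                     task: TaskConfig, noise_sd: float, n_trials: int,
                     rng: np.random.Generator,
                     sym_cfg: Optional[SymbolizerConfig] = None) -> float:
    """Open-loop proxy for behavioural robustness under sensory noise.

    Observations are the teaching trajectory plus Gaussian noise; a primitive
    counts as valid when the model's predicted vision ends the primitive with
    a full dwell in a single legal position bin.  Returns the valid fraction
    over all primitives and trials."""
    from .model import generate_open_loop

    sym_cfg = sym_cfg or SymbolizerConfig.for_task(task)
    dur = task.primitive_duration
    base = teaching.trajectory.values
    n_prims = len(base) // dur
    if n_prims == 0:
        raise ConfigurationError("teaching trajectory shorter than one primitive")
    valid = 0
    total = 0
    for _ in range(n_trials):
        obs = base + rng.normal(0.0, noise_sd, size=base.shape) if noise_sd > 0 else base
        obs = np.clip(obs, -1.0, 1.0)
        pred = generate_open_loop(m, s0.copy(), Trajectory(obs, task.proprio_dim))
        vis = pred.vision[:, 0]
        for k in range(n_prims):
            tail = vis[(k + 1) * dur - sym_cfg.min_dwell:(k + 1) * dur]
            b = _bins(tail, sym_cfg)
            total += 1
            if np.all(b == b[0]):
                valid += 1
    return valid / total


@dataclass
class LesionComparison:
    rmse_intact: float
    rmse_lesioned: float
    novelty_intact: float
    novelty_lesioned: float


def lesion_comparison(m: ModelParams, s0: NetworkState, teaching: LabeledSequence,
                      task: TaskConfig, block_length: int = 5,
                      imagery_steps: int = 4000,
                      sym_cfg: Optional[SymbolizerConfig] = None) -> LesionComparison:
    """Quantify a higher-level lesion along both axes of interest:
    single-primitive regeneration error (RMSE over the first primitive of
    closed-loop imagery vs. the teaching data) and n-block novelty of long
    imagery."""
    from .model import lesion_higher

    sym_cfg = sym_cfg or SymbolizerConfig.for_task(task)
    dur = task.primitive_duration
    ref = teaching.trajectory.values[:dur]

    def measure(model: ModelParams) -> tuple[float, float]:
        st = s0.copy()
        if model.lesioned:
            st.high_state = np.zeros_like(st.high_state)
        gen = generate_closed_loop(model, st, imagery_steps,
                                   x0=teaching.trajectory.values[0])
        rmse = float(np.sqrt(np.mean((gen.values[:dur] - ref) ** 2)))
        syms = symbolize(gen, sym_cfg)
        nov = nblock_novelty(syms, block_length) if len(syms) >= block_length else 0.0
        return rmse, nov

    r_i, n_i = measure(m)
    r_l, n_l = measure(lesion_higher(m))
    return LesionComparison(r_i, r_l, n_i, n_l)
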