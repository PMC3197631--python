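"""Synthetic visuo-proprioceptive teaching data.

Emulates a tutored object-moving task: an object sits at one of three
workbench positions (L, C, R); each behaviour primitive reaches for it,
grasps it, carries it to another position chosen at random from a
configurable transition matrix (no self-moves), releases it and returns to a
home posture.  Proprioception is a set of plausible joint-angle channels
rendered by cosine interpolation through fixed keyframe postures; vision is
the 2-D object position.  All values live in [-1, 1].

The generator is not a physics simulation: postures are smooth, repeatable
and position-discriminating, which is all the prediction-learning model
observes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import Array, ConfigurationError, Trajectory

SYMBOLS = ("L", "C", "R")
_SYM_INDEX = {s: i for i, s in enumerate(SYMBOLS)}


def default_positions() -> dict[str, Array]:
    """Object positions in normalized vision coordinates."""
    return {
        "L": np.array([-0.6, 0.0]),
        "C": np.array([0.0, 0.0]),
        "R": np.array([0.6, 0.0]),
    }


def uniform_transitions() -> Array:
    """Uniform choice among the two admissible destinations (no self-moves)."""
    P = np.full((3, 3), 0.5)
    np.fill_diagonal(P, 0.0)
    return P


@dataclass
class TaskConfig:
    """Tutoring-process description.

    ``transition_probs`` rows/columns are ordered (L, C, R); rows must be
    stochastic with a zero diagonal.  ``primitive_duration`` is the number of
    time steps each grasp-move-release-return primitive occupies."""

    positions: dict[str, Array] = field(default_factory=default_positions)
    transition_probs: Array = field(default_factory=uniform_transitions)
    primitive_duration: int = 40
    proprio_dim: int = 8
    noise_sd: float = 0.0
    n_transitions: int = 6
    start_symbol: str = "C"

    def __post_init__(self) -> None:
        self.transition_probs = np.asarray(self.transition_probs, float)
        P = self.transition_probs
        if P.shape != (3, 3):
            raise ConfigurationError("transition_probs must be 3x3")
        if np.any(np.abs(np.diag(P)) > 1e-12):
            raise ConfigurationError("self-transitions are not allowed (diagonal must be 0)")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigurationError("transition_probs rows must sum to 1")
        if self.primitive_duration < 4:
            raise ConfigurationError("primitive_duration must be >= 4")
        if self.proprio_dim < 2:
            raise ConfigurationError("need at least 2 proprioceptive channels")
        if self.start_symbol not in SYMBOLS:
            raise ConfigurationError("start_symbol must be one of L, C, R")

    @property
    def n_dim(self) -> int:
        return self.proprio_dim + 2

    @property
    def home_posture(self) -> Array:
        return _posture(self.proprio_dim, 0.0, grip=-0.5, lift=-0.4)


@dataclass
class LabeledSequence:
    """A rendered trajectory plus the object-position symbols at primitive
    boundaries (consecutive symbols always differ)."""

    trajectory: Trajectory
    symbol_string: str


def _posture(P: int, px: float, grip: float, lift: float) -> Array:
    """Deterministic joint-angle vector for a hand position/grip/lift pose.

    Channels cycle through: yaw tracking the horizontal target, pitch
    tracking lift, elbow flexion, and hand aperture; extra channels repeat
    the cycle with sign flips so every posture is unique and bounded."""
    base = [0.9 * px, lift, 0.4 * abs(px) - 0.3, grip]
    out = np.empty(P)
    for j in range(P):
        k = j % 4
        sign = 1.0 if (j // 4) % 2 == 0 else -1.0
        out[j] = sign * base[k]
    return out


def _keyframes(cfg: TaskConfig, frm: str, to: str):
    """(time fraction, posture, vision) keyframes of one primitive."""
    pos = cfg.positions
    fx, tx = float(pos[frm][0]), float(pos[to][0])
    P = cfg.proprio_dim
    home = cfg.home_posture
    return [
        (0.00, home, pos[frm]),
        (0.15, _posture(P, fx, grip=-0.5, lift=0.2), pos[frm]),
        (0.30, _posture(P, fx, grip=0.5, lift=0.2), pos[frm]),
        (0.60, _posture(P, tx, grip=0.5, lift=0.4), pos[to]),
        (0.75, _posture(P, tx, grip=-0.5, lift=0.2), pos[to]),
        (1.00, home, pos[to]),
    ]


def _smoothstep(s: Array) -> Array:
    return 0.5 * (1.0 - np.cos(np.pi * s))


def render_primitive(cfg: TaskConfig, from_sym: str, to_sym: str) -> Array:
    """Render one primitive as a (primitive_duration, P+2) array.

    Proprioception passes through the keyframe postures with cosine easing;
    the vision channels move from the source to the destination position
    during the carry phase (with a small vertical lift bump) and are constant
    otherwise.  The segment starts and ends exactly at the home posture so
    primitives concatenate without discontinuities.
    """
    if from_sym == to_sym:
        raise ConfigurationError("primitives never keep the object in place")
    if from_sym not in cfg.positions or to_sym not in cfg.positions:
        raise ConfigurationError("missing keyframes for requested positions")
    frames = _keyframes(cfg, from_sym, to_sym)
    dur = cfg.primitive_duration
    t = np.arange(dur) / (dur - 1)
    out = np.empty((dur, cfg.n_dim))
    times = np.array([f[0] for f in frames])
    seg = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(frames) - 2)
    t0 = times[seg]
    t1 = times[seg + 1]
    s = _smoothstep((t - t0) / (t1 - t0))
    post = np.array([f[1] for f in frames])
    vis = np.array([f[2] for f in frames])
    out[:, : cfg.proprio_dim] = (1 - s)[:, None] * post[seg] + s[:, None] * post[seg + 1]
    out[:, cfg.proprio_dim:] = (1 - s)[:, None] * vis[seg] + s[:, None] * vis[seg + 1]
    # vertical lift bump while the object is carried (keyframes 2 -> 3)
    carry = seg == 2
    out[carry, cfg.proprio_dim + 1] += 0.3 * np.sin(np.pi * s[carry])
    out[-1, : cfg.proprio_dim] = frames[-1][1]
    out[-1, cfg.proprio_dim:] = frames[-1][2]
    return out


def sample_symbol_sequence(cfg: TaskConfig, n_transitions: int,
                           rng: np.random.Generator,
                           start: Optional[str] = None) -> str:
    """Markov sample of object positions: start symbol plus ``n_transitions``
    moves; consecutive symbols never repeat."""
    if n_transitions < 1:
        raise ConfigurationError("need at least one transition")
    cur = start if start is not None else cfg.start_symbol
    if cur not in SYMBOLS:
        raise ConfigurationError("invalid start symbol")
    out = [cur]
    for _ in range(n_transitions):
        probs = cfg.transition_probs[_SYM_INDEX[cur]]
        cur = SYMBOLS[rng.choice(3, p=probs)]
        out.append(cur)
    return "".join(out)


def render_symbol_sequence(cfg: TaskConfig, symbols: str) -> Trajectory:
    """Concatenate rendered primitives for a symbol string, with per-step
    labels giving the nearest object position."""
    if len(symbols) < 2:
        raise ConfigurationError("need at least two symbols to render")
    parts = [render_primitive(cfg, a, b) for a, b in zip(symbols, symbols[1:])]
    values = np.vstack(parts)
    labels = _nearest_labels(cfg, values[:, cfg.proprio_dim])
    return Trajectory(values, cfg.proprio_dim, labels=labels)


def _nearest_labels(cfg: TaskConfig, vis_x: Array) -> list[str]:
    centers = np.array([float(cfg.positions[s][0]) for s in SYMBOLS])
    idx = np.argmin(np.abs(vis_x[:, None] - centers[None, :]), axis=1)
    return [SYMBOLS[i] for i in idx]


def generate_teaching_set(cfg: TaskConfig, n_sequences: int,
                          rng: np.random.Generator) -> list[LabeledSequence]:
    """Sample and render ``n_sequences`` teaching sequences of
    ``cfg.n_transitions`` primitives each, adding i.i.d. Gaussian observation
    noise (``cfg.noise_sd``) clipped to [-1, 1]."""
    out = []
    for _ in range(n_sequences):
        symbols = sample_symbol_sequence(cfg, cfg.n_transitions, rng)
        traj = render_symbol_sequence(cfg, symbols)
        if cfg.noise_sd > 0:
            noisy = traj.values + rng.normal(0.0, cfg.noise_sd, size=traj.values.shape)
            traj = Trajectory(np.clip(noisy, -1.0, 1.0), cfg.proprio_dim,
                              labels=traj.labels)
        out.append(LabeledSequence(traj, symbols))
    return out
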