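"""The laterally-inhibitory 1-D periodic neural field.

Local excitation / distal inhibition on a ring of ``N`` nodes covering 10 mm
of SCi tissue.  The internal state ``u`` follows leaky Euler dynamics driven
by the sum of external inputs and the internal (lateral) contribution
``W @ a``; the output activity ``a`` is a sigmoid of ``u``.  A saccade is
triggered the first time any non-central node's output activity reaches the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import FieldParams


def node_positions(params: FieldParams) -> np.ndarray:
    """Positions x_i (mm) of the field nodes.

    Node ``i`` (1-based) sits at ``x_i = i * dx - 5`` so that node 50 is the
    fixation point (x=0) and nodes 25 / 75 are the canonical stimulus sites
    at x = -2.5 / +2.5 mm.
    """
    i = np.arange(1, params.n_nodes + 1, dtype=float)
    return i * params.dx - params.circumference / 2.0


def mirror_permutation(params: FieldParams) -> np.ndarray:
    """Index permutation mapping each node to the node at the mirrored
    position (x -> -x) on the torus."""
    n = params.n_nodes
    return (n - 2 - np.arange(n)) % n


def toroidal_distance(x: np.ndarray, mu: float, circumference: float) -> np.ndarray:
    """Minimal distance on the ring between positions ``x`` and ``mu``."""
    d = np.abs(np.asarray(x, dtype=float) - mu)
    return np.minimum(d, circumference - d)


def gaussian_profile(mu: float, params: FieldParams) -> np.ndarray:
    """Gaussian spatial profile k^mu of an input, peak ``input_amp`` at mu.

    Distances are measured on the torus so a profile centred near one edge
    wraps around to the other.  ``mu`` outside [-5, 5) is wrapped.
    """
    x = node_positions(params)
    half = params.circumference / 2.0
    mu = (float(mu) + half) % params.circumference - half
    d = toroidal_distance(x, mu, params.circumference)
    return params.input_amp * np.exp(-(d ** 2) / (2.0 * params.input_gamma ** 2))


@dataclass(frozen=True)
class LateralWeightMatrix:
    """Circulant-symmetric lateral interaction matrix W (Gaussian, shifted
    down by ``shift_fraction * max(G)`` and scaled by dx)."""

    w: np.ndarray

    def __post_init__(self) -> None:
        if self.w.ndim != 2 or self.w.shape[0] != self.w.shape[1]:
            raise ValueError("weight matrix must be square")


def build_weight_matrix(params: FieldParams) -> LateralWeightMatrix:
    """Construct the laterally-inhibitory weight matrix.

    ``G[i, j] = sf * exp(-(d_ij)^2 / (2 sigma^2))`` with ``d_ij`` the toroidal
    distance ``min(|i-j|, N-|i-j|) * dx`` in mm; ``W = (G - m) * dx`` with
    ``m = shift_fraction * max(G)``.  Proximal entries are excitatory
    (positive), distal entries inhibitory (negative).
    """
    n = params.n_nodes
    idx = np.arange(n)
    k = np.abs(idx[:, None] - idx[None, :])
    d = np.minimum(k, n - k) * params.dx
    g = params.lateral_scale * np.exp(-(d ** 2) / (2.0 * params.lateral_sigma ** 2))
    m = params.shift_fraction * g.max()
    return LateralWeightMatrix((g - m) * params.dx)


def output_activity(u: np.ndarray, params: FieldParams) -> np.ndarray:
    """Sigmoidal output nonlinearity a = 1 / (1 + exp(-beta * u))."""
    return 1.0 / (1.0 + np.exp(-params.beta * np.asarray(u, dtype=float)))


@dataclass
class FieldState:
    """Internal state ``u`` and output activity ``a`` at time ``t`` (ms,
    relative to stimulus onset)."""

    t: float
    u: np.ndarray
    a: np.ndarray

    @classmethod
    def resting(cls, t: float, params: FieldParams) -> "FieldState":
        u = np.full(params.n_nodes, params.resting_potential, dtype=float)
        return cls(t=t, u=u, a=output_activity(u, params))


@dataclass(frozen=True)
class SaccadeEvent:
    """A threshold crossing at a non-central node."""

    node: int
    x: float
    direction: str  # "left" | "right"
    srt: float      # ms from stimulus onset


def step_field(state: FieldState, c_ext: np.ndarray, w: LateralWeightMatrix,
               params: FieldParams) -> FieldState:
    """One Euler step of the field dynamics.

    The internal contribution is computed from the *current* activity, then
    ``u(t+dt) = (1 - dt/tau) u(t) + dt/tau (c_ext + c_int)`` and ``a`` is
    recomputed from the new ``u``.
    """
    c_int = w.w @ state.a
    coef = 1.0 - params.dt / params.tau
    u_new = coef * state.u + (params.dt / params.tau) * (np.asarray(c_ext, float) + c_int)
    if not np.all(np.isfinite(u_new)):
        raise FloatingPointError("non-finite internal state; configuration error")
    return FieldState(t=state.t + params.dt, u=u_new,
                      a=output_activity(u_new, params))


def eligible_nodes(params: FieldParams) -> np.ndarray:
    """Boolean mask of nodes outside the central fixation exclusion zone."""
    return np.abs(node_positions(params)) > params.fixation_exclusion_radius


def detect_saccade(state: FieldState, params: FieldParams) -> Optional[SaccadeEvent]:
    """Return the saccade event if any non-central node's activity has
    reached threshold, else None.

    Winner: the eligible node with maximal activity; ties broken by smallest
    |x|, then leftmost.
    """
    x = node_positions(params)
    elig = np.abs(x) > params.fixation_exclusion_radius
    a = state.a[elig]
    if a.size == 0 or a.max() < params.threshold:
        return None
    node = winner_node(state.a, x, elig)
    return SaccadeEvent(node=node, x=float(x[node]),
                        direction="right" if x[node] > 0 else "left",
                        srt=float(state.t))


def winner_node(a: np.ndarray, x: np.ndarray, elig: np.ndarray) -> int:
    """Winning node among eligible nodes: maximal activity, then smallest
    |x|, then leftmost."""
    idx = np.flatnonzero(elig)
    a_e = a[idx]
    cand = idx[a_e == a_e.max()]
    absx = np.abs(x[cand])
    cand = cand[absx == absx.min()]
    return int(cand[np.argmin(x[cand])])


__all__ = [
    "node_positions", "mirror_permutation", "toroidal_distance",
    "gaussian_profile", "LateralWeightMatrix", "build_weight_matrix",
    "output_activity", "FieldState", "SaccadeEvent", "step_field",
    "eligible_nodes", "detect_saccade", "winner_node",
]
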