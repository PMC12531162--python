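"""Discrete-time dynamics of anticipated change.

In the spirit of fuzzy cognitive maps, an initial perturbation a(0) is
applied to the Self-Now state and propagated through the weight matrix:

    s(t+1) = f_th( s(t) + a(t) )
    a(t)   = W^T ds(t) e^(-lambda t)      for t >= 1
    ds(t)  = s(t) - s(t-1)

f_th clips every component to [-1, 1] (the rating bounds), and the
exponential factor damps the influence of older changes at rate
``lambda``.  For lambda > 0 the geometric decay guarantees convergence to
a fixed point; the run stops once the largest state change drops below a
tolerance, or at a step cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "threshold",
    "perturbation_vector",
    "simulate",
    "differential_trajectory",
]


def threshold(x: np.ndarray) -> np.ndarray:
    """Clip componentwise to the normalized rating bounds [-1, 1]."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite activation")
    return np.clip(x, -1.0, 1.0)


def perturbation_vector(n: int, target: int, magnitude: float) -> np.ndarray:
    """Initial activation a(0) hitting a single construct.

    Models a targeted intervention: ``magnitude`` at index ``target``,
    zero elsewhere.  ``|magnitude| <= 2`` (the widest possible swing on
    the normalized scale).
    """
    if not 0 <= target < n:
        raise IndexError(f"construct index {target} out of range for n={n}")
    if abs(magnitude) > 2:
        raise ValueError("perturbation magnitude cannot exceed 2")
    a0 = np.zeros(n)
    a0[target] = magnitude
    return a0


@dataclass
class SimulationConfig:
    """Simulation parameters.

    lam — decay rate in [0, 1] (0.1 is the typical choice); a0 — initial
    activation vector; max_steps — step cap; tol — convergence tolerance
    on max |ds(t)|.
    """

    a0: np.ndarray
    lam: float = 0.1
    max_steps: int = 50
    tol: float = 1e-6

    def __post_init__(self) -> None:
        self.a0 = np.asarray(self.a0, dtype=float)
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass
class Trajectory:
    """Recorded run: states s(0..T), activations a(0..T-1), deltas ds(1..T).

    ``converged_at`` is the first step t with max |ds(t)| < tol, or None
    if the run hit the step cap first.
    """

    states: np.ndarray  # (T+1, n)
    activations: np.ndarray  # (T, n)
    deltas: np.ndarray  # (T, n)
    converged_at: int | None
    labels: list[str] | None = None

    @property
    def n_steps(self) -> int:
        return self.states.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        """Long-format record: one row per (step, construct)."""
        T1, n = self.states.shape
        names = self.labels if self.labels is not None else list(range(n))
        rows = []
        for t in range(T1):
            for i in range(n):
                rows.append(
                    {
                        "step": t,
                        "construct": names[i],
                        "state": self.states[t, i],
                        "delta": self.deltas[t - 1, i] if t >= 1 else np.nan,
                        "activation": self.activations[t, i] if t < self.activations.shape[0] else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def simulate(W: np.ndarray, s0: np.ndarray, cfg: SimulationConfig) -> Trajectory:
    """Propagate the perturbation ``cfg.a0`` from state ``s0`` through W.

    a(0) is applied as given (decay starts at t = 1).  Deltas are taken
    between post-clipping states, so every recorded state respects the
    rating bounds exactly.
    """
    W = np.asarray(W, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    n = s0.size
    if W.shape != (n, n):
        raise ValueError(f"W shape {W.shape} does not match state length {n}")
    if cfg.a0.size != n:
        raise ValueError("a0 length does not match state length")
    if np.any(np.abs(s0) > 1.0):
        raise ValueError("initial state outside [-1, 1]")

    states = [s0]
    activations = [cfg.a0]
    deltas = []
    converged_at = None
    WT = W.T
    for t in range(1, cfg.max_steps + 1):
        s_next = threshold(states[-1] + activations[-1])
        delta = s_next - states[-1]
        states.append(s_next)
        deltas.append(delta)
        if np.max(np.abs(delta)) < cfg.tol:
            converged_at = t
            break
        if t < cfg.max_steps:
            activations.append(WT @ delta * np.exp(-cfg.lam * t))
    return Trajectory(
        states=np.asarray(states),
        activations=np.asarray(activations),
        deltas=np.asarray(deltas),
        converged_at=converged_at,
    )


def differential_trajectory(traj: Trajectory) -> np.ndarray:
    """Series s(t) - s(0): each construct's cumulative departure from its
    initial position (the quantity plotted in change-trajectory figures)."""
    if traj.states.shape[0] == 0:
        raise ValueError("empty trajectory")
    return traj.states - traj.states[0]
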