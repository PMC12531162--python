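"""Synthetic grid generation.

Three generators cover testing and demonstration needs without any
external data: uniformly random raw grids, continuous normalized grids
built from a prescribed weight matrix via the forward model
``M[j, i] = s_j + w[i, j] (h_i - s_i)`` (so weight recovery is exact),
and a fixed 5-construct demonstration grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import (
    Construct,
    NormalizedGrid,
    RatingScale,
    RawWimpGrid,
    hypothetical_direction,
)

__all__ = ["SynthSpec", "random_grid", "grid_from_weights", "example_grid", "InfeasibleWeightError"]


class InfeasibleWeightError(ValueError):
    """A prescribed weight would push a hypothetical rating outside [-1, 1]."""


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a random grid draw.

    density is the probability that an off-diagonal hypothetical cell
    departs from the Self-Now rating (density 0 yields a zero weight
    matrix downstream).  Same spec, same grid: generation is a pure
    function of the seed.
    """

    n: int = 5
    scale: RatingScale = field(default_factory=lambda: RatingScale(1, 7))
    density: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 constructs")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")


def random_grid(spec: SynthSpec) -> RawWimpGrid:
    """Draw a valid random raw grid.

    Self-Now and Ideal ratings are uniform over the scale integers; each
    off-diagonal hypothetical cell keeps the Self-Now rating with
    probability 1 - density, otherwise it is redrawn uniformly.
    """
    rng = np.random.default_rng(spec.seed)
    n, lo, hi = spec.n, spec.scale.r_min, spec.scale.r_max
    self_now = rng.integers(lo, hi + 1, size=n)
    ideal = rng.integers(lo, hi + 1, size=n)
    hyp = np.tile(self_now[:, None], (1, n))
    change = rng.random((n, n)) < spec.density
    np.fill_diagonal(change, False)
    hyp[change] = rng.integers(lo, hi + 1, size=int(change.sum()))
    constructs = tuple(Construct(f"left{i+1}", f"right{i+1}") for i in range(n))
    return RawWimpGrid(scale=spec.scale, constructs=constructs, hyp=hyp, ideal=ideal)


def grid_from_weights(
    W: np.ndarray,
    s: np.ndarray,
    d: np.ndarray,
    scale: RatingScale | None = None,
    constructs: tuple[Construct, ...] | None = None,
) -> NormalizedGrid:
    """Build the normalized grid whose weight matrix is exactly W.

    The forward model fills ``M[j, i] = s_j + W[i, j] (h_i - s_i)`` with h
    derived from (s, d); recomputing weights from the result returns W to
    machine precision.  The grid is continuous (no integer quantization).
    Raises :class:`InfeasibleWeightError` naming the first offending cell
    if any entry of M would leave [-1, 1].
    """
    W = np.asarray(W, dtype=float)
    s = np.asarray(s, dtype=float)
    d = np.asarray(d, dtype=float)
    n = s.size
    if W.shape != (n, n):
        raise ValueError("W shape does not match s")
    h = hypothetical_direction(s, d)
    M = s[:, None] + (W * (h - s)[:, None]).T
    np.fill_diagonal(M, s)
    bad = np.argwhere(np.abs(M) > 1.0 + 1e-12)
    if bad.size:
        j, i = bad[0]
        raise InfeasibleWeightError(
            f"weight W[{i},{j}]={W[i, j]} drives M[{j},{i}]={M[j, i]:.4f} outside [-1, 1]"
        )
    M = np.clip(M, -1.0, 1.0)
    if scale is None:
        scale = RatingScale(1, 7)
    if constructs is None:
        constructs = tuple(Construct(f"left{i+1}", f"right{i+1}") for i in range(n))
    return NormalizedGrid(scale=scale, constructs=constructs, s=s, d=d, h=h, M=M)


def example_grid() -> RawWimpGrid:
    """A fixed 5-construct demonstration grid (synthetic ratings).

    The person rates themselves healthy (and wants to be), undecided
    between sporty and not sporty, lazy and anxious against their ideal,
    and busy with no clear preference between free and busy.  The
    anticipated implications include a mutually reinforcing
    Healthy <-> Sporty loop, Busy -> Anxious, Anxious -> Lazy, and a
    Hardworker -> Busy -> Anxious ripple, so every node and edge category
    and a nontrivial simulation are exercised by one small grid.
    """
    scale = RatingScale(1, 7)
    constructs = (
        Construct("Sick", "Healthy"),
        Construct("No sporty", "Sporty"),
        Construct("Lazy", "Hardworker"),
        Construct("Calm", "Anxious"),
        Construct("Free", "Busy"),
    )
    # columns = hypothetical scenarios (totally Sick, totally Sporty,
    # totally Hardworker, totally Calm, totally Free); diagonal = Self-Now
    hyp = np.array(
        [
            [6, 7, 6, 6, 6],
            [2, 4, 4, 4, 4],
            [2, 2, 2, 4, 2],
            [6, 6, 7, 6, 3],
            [5, 5, 7, 5, 5],
        ]
    )
    ideal = np.array([7, 7, 6, 2, 4])
    return RawWimpGrid(scale=scale, constructs=constructs, hyp=hyp, ideal=ideal)
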