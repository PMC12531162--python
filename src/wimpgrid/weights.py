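"""Inter-construct weight matrices.

The weight ``w[i, j]`` is the anticipated change in construct *j* per unit
of hypothetical change in construct *i*:

    w_ij = (m_ji - s_j) / (h_i - s_i)

The numerator is the shift the person anticipates for construct *j* under
scenario *i*; the denominator is the (maximal) shift imposed on construct
*i* itself.  Since ``|m_ji - s_j| <= 2`` and ``|h_i - s_i| >= 1`` always,
``|w_ij| <= 2``, and the diagonal is exactly 0 because the diagonal of M
stores the Self-Now.

For ideal-frame analyses the matrix is conjugated by a +/-1 orientation
vector so that the positive direction of every construct points toward its
ideal pole (``W* = diag(o) W diag(o)``).
"""

from __future__ import annotations

import numpy as np

from .grid import ZERO_TOL, NormalizedGrid

__all__ = [
    "compute_weights",
    "ceiling_floor_flags",
    "orientation_vector",
    "orient_to_ideal",
    "ideal_oriented_weights",
]


def compute_weights(g: NormalizedGrid) -> np.ndarray:
    """Weight matrix W of a normalized grid; ``W[i, j]`` = sensitivity of
    construct *j* to the hypothetical change of construct *i*."""
    denom = g.h - g.s
    # |h_i - s_i| >= 1 for any valid grid; a violation means corrupt input
    assert np.all(np.abs(denom) >= 1.0 - 1e-9), "degenerate hypothetical shift"
    W = (g.M.T - g.s[None, :]) / denom[:, None]
    W[W == 0] = 0.0  # collapse negative zeros for clean export
    np.fill_diagonal(W, 0.0)
    return W


def ceiling_floor_flags(g: NormalizedGrid, limit: float = 0.9) -> np.ndarray:
    """Boolean matrix flagging cells whose weight may be attenuated by a
    ceiling/floor effect: the target construct's Self-Now already sits near
    a scale extreme (``|s_j| > limit``), so little observable room remains.

    No correction is applied — the flags are a per-cell diagnostic only.
    """
    flags = np.zeros((g.n, g.n), dtype=bool)
    flags[:, np.abs(g.s) > limit] = True
    np.fill_diagonal(flags, False)
    return flags


def orientation_vector(s: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Per-construct orientation o in {-1, +1}: the ideal pole where defined,
    else the self pole (dilemmatic constructs), else the right pole."""
    s = np.asarray(s, dtype=float)
    d = np.asarray(d, dtype=float)
    return np.where(
        np.abs(d) > ZERO_TOL,
        np.sign(d),
        np.where(np.abs(s) > ZERO_TOL, np.sign(s), 1.0),
    )


def orient_to_ideal(W: np.ndarray, o: np.ndarray) -> np.ndarray:
    """Conjugate W into the ideal frame: ``W*[i, j] = o_i o_j W[i, j]``.

    Involutive: applying the same orientation twice restores W.  After
    alignment a positive ``W*[i, j]`` reads "moving i toward its ideal
    pole moves j toward its ideal pole".
    """
    W = np.asarray(W, dtype=float)
    o = np.asarray(o, dtype=float)
    if W.shape != (o.size, o.size):
        raise ValueError(f"shape mismatch: W {W.shape} vs o length {o.size}")
    return o[:, None] * W * o[None, :]


def ideal_oriented_weights(g: NormalizedGrid) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: (W*, o) for a normalized grid."""
    o = orientation_vector(g.s, g.d)
    return orient_to_ideal(compute_weights(g), o), o
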