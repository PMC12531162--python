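"""Core data model for Weighted Implication Grids.

A WimpGrid records, for ``n`` bipolar personal constructs, how a person
rates every construct under each of ``n`` hypothetical self-transformations
(one per construct), plus the current self (*Self-Now*, stored on the
diagonal of the hypothetical matrix) and the desired self (*Ideal-Self*).
Raw integer ratings on an arbitrary scale ``[r_min, r_max]`` are mapped
affinely onto the normalized interval ``[-1, 1]``, where -1 means full
identification with the left pole of a construct and +1 with the right
pole.  All downstream analysis (weights, networks, dynamics) operates on
this normalized space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Absolute tolerance below which a normalized score is treated as the
#: scale midpoint.  Integer ratings on even-span scales hit 0 exactly;
#: the tolerance only matters for continuous forward-model grids.
ZERO_TOL = 1e-12

__all__ = [
    "ZERO_TOL",
    "RatingScale",
    "Construct",
    "RawWimpGrid",
    "NormalizedGrid",
    "Violation",
    "GridValidationError",
    "normalize_score",
    "denormalize_score",
    "hypothetical_direction",
    "validate_grid",
    "normalize_grid",
]


class GridValidationError(ValueError):
    """Raised when an operation requires a valid grid but validation fails.

    Carries the full violation report in :attr:`violations`.
    """

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        lines = "; ".join(str(v) for v in violations)
        super().__init__(f"invalid grid: {lines}")


@dataclass(frozen=True)
class RatingScale:
    """Integer rating scale ``[r_min, r_max]`` used during the interview.

    Common choices are [1, 7], [1, 9] and [1, 3].  The midpoint of an
    even-span scale (e.g. 4 on [1, 7]) normalizes to exactly 0.
    """

    r_min: int
    r_max: int

    def __post_init__(self) -> None:
        if self.r_min >= self.r_max:
            raise ValueError(f"r_min must be < r_max, got [{self.r_min}, {self.r_max}]")

    @property
    def span(self) -> int:
        return self.r_max - self.r_min

    @property
    def midpoint(self) -> float:
        return (self.r_min + self.r_max) / 2


@dataclass(frozen=True)
class Construct:
    """A bipolar meaning dimension, e.g. ``Calm`` vs ``Anxious``.

    The left pole corresponds to -1 on the normalized scale and the right
    pole to +1.
    """

    left_pole: str
    right_pole: str

    def __post_init__(self) -> None:
        if not self.left_pole or not self.right_pole:
            raise ValueError("pole labels must be non-empty")
        if self.left_pole == self.right_pole:
            raise ValueError(f"poles must differ, got {self.left_pole!r} twice")

    @property
    def label(self) -> str:
        return f"{self.left_pole}-{self.right_pole}"


@dataclass
class RawWimpGrid:
    """A completed grid as filled in the interview, on the raw scale.

    Parameters
    ----------
    scale
        The integer rating scale.
    constructs
        Ordered constructs; their order fixes row and scenario order.
    hyp
        ``n x n`` integer matrix; entry ``hyp[j, i]`` is the rating of
        construct *j* under the hypothetical transformation of construct
        *i*.  The diagonal ``hyp[i, i]`` stores the Self-Now rating of
        construct *i* (the scenario target itself is never written into
        the matrix — it is modelled as a projection to the extreme pole).
    ideal
        Length-``n`` integer vector of Ideal-Self ratings.
    """

    scale: RatingScale
    constructs: tuple[Construct, ...]
    hyp: np.ndarray
    ideal: np.ndarray

    def __post_init__(self) -> None:
        self.constructs = tuple(self.constructs)
        self.hyp = np.asarray(self.hyp)
        self.ideal = np.asarray(self.ideal)

    @property
    def n(self) -> int:
        return len(self.constructs)

    @property
    def self_now(self) -> np.ndarray:
        """Raw Self-Now ratings (the diagonal of ``hyp``)."""
        return np.diagonal(self.hyp).copy()

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.constructs]


@dataclass
class NormalizedGrid:
    """The grid mapped into the normalized psychological space [-1, 1]^n.

    Attributes
    ----------
    s : Self-Now vector.
    d : Ideal-Self vector.
    h : hypothetical-direction vector in {-1, +1}^n; scenario *i* pushes
        construct *i* to the pole ``h[i]``.
    M : ``n x n`` matrix; ``M[j, i]`` is the normalized state of construct
        *j* under scenario *i*; ``diag(M) == s``.
    """

    scale: RatingScale
    constructs: tuple[Construct, ...]
    s: np.ndarray
    d: np.ndarray
    h: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        self.constructs = tuple(self.constructs)
        for name in ("s", "d", "h", "M"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def n(self) -> int:
        return len(self.constructs)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.constructs]


def normalize_score(r, scale: RatingScale):
    """Map a raw rating ``r`` onto [-1, 1]: ``x = 2 (r - r_min)/(r_max - r_min) - 1``.

    Accepts scalars or arrays.  Out-of-range values raise ``ValueError``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < scale.r_min) or np.any(r > scale.r_max):
        raise ValueError(
            f"rating outside scale [{scale.r_min}, {scale.r_max}]"
        )
    x = 2.0 * (r - scale.r_min) / scale.span - 1.0
    return x if x.ndim else float(x)


def denormalize_score(x, scale: RatingScale):
    """Inverse of :func:`normalize_score`; returns a raw-scale value.

    The result is continuous (not rounded to an integer rating).
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0):
        raise ValueError("normalized value outside [-1, 1]")
    r = (x + 1.0) / 2.0 * scale.span + scale.r_min
    return r if r.ndim else float(r)


def hypothetical_direction(s: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Direction h in {-1, +1}^n of each maximally contrasting hypothetical self.

    Per component: the opposite pole of the current self; if the self sits
    at the midpoint, the ideal's pole; if both are at the midpoint, the
    right pole by convention.
    """
    s = np.asarray(s, dtype=float)
    d = np.asarray(d, dtype=float)
    if s.shape != d.shape:
        raise ValueError("s and d must have the same shape")
    h = np.where(
        np.abs(s) > ZERO_TOL,
        -np.sign(s),
        np.where(np.abs(d) > ZERO_TOL, np.sign(d), 1.0),
    )
    return h


@dataclass(frozen=True)
class Violation:
    """One validation failure: a rule id, a human-readable message and,
    where applicable, the (row, column) location in the grid."""

    rule: str
    message: str
    location: tuple | None = None

    def __str__(self) -> str:
        loc = f" at {self.location}" if self.location is not None else ""
        return f"[{self.rule}]{loc} {self.message}"


def validate_grid(g: RawWimpGrid) -> list[Violation]:
    """Check every structural invariant of a raw grid.

    Returns the complete list of violations (empty iff the grid is valid);
    it never stops at the first problem.
    """
    out: list[Violation] = []
    n = g.n
    if n < 2:
        out.append(Violation("too_few_constructs", f"need n >= 2 constructs, got {n}"))
    if g.hyp.shape != (n, n):
        out.append(
            Violation("shape", f"hypothetical matrix must be {n}x{n}, got {g.hyp.shape}")
        )
        return out  # positional checks below are meaningless on a misshaped grid
    if g.ideal.shape != (n,):
        out.append(Violation("shape", f"ideal vector must have length {n}, got {g.ideal.shape}"))
        return out

    lo, hi = g.scale.r_min, g.scale.r_max
    for j in range(n):
        for i in range(n):
            v = g.hyp[j, i]
            if not float(v).is_integer():
                out.append(
                    Violation("non_integer", f"hyp rating {v!r} is not an integer", (j, i))
                )
            elif not lo <= v <= hi:
                out.append(
                    Violation(
                        "out_of_range",
                        f"hyp rating {v} outside scale [{lo}, {hi}]",
                        (j, i),
                    )
                )
    for j in range(n):
        v = g.ideal[j]
        if not float(v).is_integer():
            out.append(Violation("non_integer", f"ideal rating {v!r} is not an integer", (j,)))
        elif not lo <= v <= hi:
            out.append(
                Violation("out_of_range", f"ideal rating {v} outside scale [{lo}, {hi}]", (j,))
            )
    return out


def normalize_grid(g: RawWimpGrid) -> NormalizedGrid:
    """Derive the normalized model (s, d, h, M) from a valid raw grid.

    Raises :class:`GridValidationError` with the full report if the grid
    is invalid.
    """
    report = validate_grid(g)
    if report:
        raise GridValidationError(report)
    M = normalize_score(g.hyp, g.scale)
    s = np.diagonal(M).copy()
    d = normalize_score(g.ideal, g.scale)
    h = hypothetical_direction(s, d)
    return NormalizedGrid(scale=g.scale, constructs=g.constructs, s=s, d=d, h=h, M=M)
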