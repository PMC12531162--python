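"""Change-to-ideal analysis on the ideal-oriented weight matrix W*.

Once every construct's positive direction points toward its ideal pole,
each ordered pair (i, j) with a nonzero forward weight falls into one of
six classes: the impact of an ideal-ward change of *i* on *j* is positive
or negative, and the return edge provides no, positive (amplifying) or
negative (self-regulating) feedback.  Aggregating over all targets gives
the per-construct Impact/Feedback index:

    I_i = sum_j W*[i, j]          anticipated system-wide consequence
    F_i = sum_j W*[i, j] W*[j, i] anticipated loop return

F sums loop products, so it is invariant under any global pole
re-orientation.  A negative I with positive F flags a costly,
self-entrenching change — the signature of an implicative dilemma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import NormalizedGrid
from .network import DISCREPANT, classify_node

__all__ = [
    "ImplicationPairClass",
    "classify_implication_pair",
    "pair_typology",
    "if_index",
    "discrepant_constructs",
]


@dataclass(frozen=True)
class ImplicationPairClass:
    """Typology of an ordered construct pair in the ideal frame."""

    impact_sign: str  # "positive" | "negative"
    feedback: str  # "none" | "positive" | "negative"

    def __str__(self) -> str:
        fb = "without feedback" if self.feedback == "none" else f"with {self.feedback} feedback"
        return f"{self.impact_sign} impact {fb}"


def classify_implication_pair(wstar_ij: float, wstar_ji: float) -> ImplicationPairClass | None:
    """Classify the ordered pair (i, j) from its two oriented weights.

    Returns ``None`` when the forward weight is zero (no implication to
    classify).  Feedback is the sign of the loop product
    ``wstar_ij * wstar_ji``: positive loops amplify the change, negative
    loops push back against it.
    """
    if wstar_ij == 0:
        return None
    impact = "positive" if wstar_ij > 0 else "negative"
    if wstar_ji == 0:
        feedback = "none"
    else:
        feedback = "positive" if wstar_ij * wstar_ji > 0 else "negative"
    return ImplicationPairClass(impact, feedback)


def pair_typology(
    Wstar: np.ndarray,
    labels: list[str] | None = None,
    sources: list[int] | None = None,
) -> pd.DataFrame:
    """Classify every ordered pair with a nonzero forward weight.

    ``sources`` optionally restricts rows to implications originating in
    the given constructs (e.g. the discrepant ones, the clinically loaded
    case).  Columns: source, target, w_forward, w_back, impact, feedback.
    """
    Wstar = np.asarray(Wstar, dtype=float)
    n = Wstar.shape[0]
    names = labels if labels is not None else list(range(n))
    rows = []
    src_set = set(range(n)) if sources is None else set(sources)
    for i in range(n):
        if i not in src_set:
            continue
        for j in range(n):
            if i == j:
                continue
            cls = classify_implication_pair(Wstar[i, j], Wstar[j, i])
            if cls is None:
                continue
            rows.append(
                {
                    "source": names[i],
                    "target": names[j],
                    "w_forward": Wstar[i, j],
                    "w_back": Wstar[j, i],
                    "impact": cls.impact_sign,
                    "feedback": cls.feedback,
                }
            )
    return pd.DataFrame(rows, columns=["source", "target", "w_forward", "w_back", "impact", "feedback"])


def if_index(Wstar: np.ndarray, labels: list[str] | None = None) -> pd.DataFrame:
    """Per-construct Impact (row sums of W*) and Feedback (loop-product sums)."""
    Wstar = np.asarray(Wstar, dtype=float)
    if Wstar.ndim != 2 or Wstar.shape[0] != Wstar.shape[1]:
        raise ValueError("Wstar must be square")
    I = Wstar.sum(axis=1)
    F = (Wstar * Wstar.T).sum(axis=1)
    idx = labels if labels is not None else list(range(Wstar.shape[0]))
    return pd.DataFrame({"impact": I, "feedback": F}, index=idx)


def discrepant_constructs(g: NormalizedGrid) -> list[int]:
    """Indices of constructs whose self and ideal sit on opposite poles."""
    return [i for i in range(g.n) if classify_node(g.s[i], g.d[i]) == DISCREPANT]
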