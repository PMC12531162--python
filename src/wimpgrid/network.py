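"""Directed construct network: typology, centrality and layouts.

The weight matrix is read as a weighted adjacency matrix of a digraph
whose nodes are constructs.  Nodes are classified by the alignment of
Self-Now and Ideal-Self (congruent / discrepant / dilemmatic /
undefined_self), edges by whether the implied movement of source and
target runs in the same perceived direction (direct) or opposite
(inverse).  Centrality comes in two flavours: weighted in/out degree and
the Presence-Balance index, a 45-degree rotation of the degree plane that
separates overall connectivity (P) from the superordinate-vs-subordinate
tendency (B).
"""

from __future__ import annotations

import random

import networkx as nx
import numpy as np
import pandas as pd

from .grid import ZERO_TOL, NormalizedGrid

__all__ = [
    "CONGRUENT",
    "DISCREPANT",
    "DILEMMATIC",
    "UNDEFINED_SELF",
    "NODE_CATEGORIES",
    "classify_node",
    "classify_edge",
    "build_digraph",
    "weighted_degrees",
    "pb_index",
    "layout",
    "PB_FACTOR_DEFAULT",
]

CONGRUENT = "congruent"
DISCREPANT = "discrepant"
DILEMMATIC = "dilemmatic"
UNDEFINED_SELF = "undefined_self"
NODE_CATEGORIES = (CONGRUENT, DISCREPANT, DILEMMATIC, UNDEFINED_SELF)

#: Default Presence-Balance rotation factor: 1/sqrt(2) makes the degree ->
#: (P, B) map an exact orthonormal 45-degree rotation.
PB_FACTOR_DEFAULT = 1.0 / np.sqrt(2.0)


def classify_node(s_i: float, d_i: float) -> str:
    """Category of a construct from its Self-Now and Ideal-Self scores.

    undefined_self: self at the midpoint (no clear self-definition);
    dilemmatic: ideal at the midpoint (ambivalence about what is desirable);
    congruent: self and ideal on the same pole; discrepant: opposite poles.
    """
    if abs(s_i) <= ZERO_TOL:
        return UNDEFINED_SELF
    if abs(d_i) <= ZERO_TOL:
        return DILEMMATIC
    return CONGRUENT if np.sign(s_i) == np.sign(d_i) else DISCREPANT


def _display_sign(s: float) -> float:
    # display orientation: the pole the self occupies; right pole when undefined
    return np.sign(s) if abs(s) > ZERO_TOL else 1.0


def classify_edge(w_ij: float, s_i: float, s_j: float) -> str:
    """``direct`` if moving toward the displayed pole of *i* increases the
    displayed pole of *j*, else ``inverse``.

    The displayed pole of a construct is the pole its Self-Now occupies
    (right pole if the self is undefined), so the classification is a
    sign conjugation of the raw weight.
    """
    if w_ij == 0:
        raise ValueError("a zero weight is not an edge")
    return "direct" if _display_sign(s_i) * _display_sign(s_j) * w_ij > 0 else "inverse"


def build_digraph(g: NormalizedGrid, W: np.ndarray, epsilon: float = 0.0) -> nx.DiGraph:
    """Directed graph with one node per construct and an edge (i -> j) for
    every weight with ``|W[i, j]| > epsilon``.

    Node attributes: left_pole, right_pole, self_now, ideal, category,
    size (= |s_i|, the degree of self-definition).  Edge attributes:
    weight, relation (direct/inverse).
    """
    W = np.asarray(W, dtype=float)
    if W.shape != (g.n, g.n):
        raise ValueError(f"weight matrix shape {W.shape} does not match grid n={g.n}")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    G = nx.DiGraph()
    for i, c in enumerate(g.constructs):
        G.add_node(
            i,
            label=c.label,
            left_pole=c.left_pole,
            right_pole=c.right_pole,
            self_now=float(g.s[i]),
            ideal=float(g.d[i]),
            category=classify_node(g.s[i], g.d[i]),
            size=float(abs(g.s[i])),
        )
    for i in range(g.n):
        for j in range(g.n):
            if i != j and abs(W[i, j]) > epsilon:
                G.add_edge(
                    i,
                    j,
                    weight=float(W[i, j]),
                    relation=classify_edge(W[i, j], g.s[i], g.s[j]),
                )
    return G


def weighted_degrees(
    W: np.ndarray, mode: str = "absolute", labels: list[str] | None = None
) -> pd.DataFrame:
    """Weighted in/out degrees per construct.

    mode="absolute" (default) sums |w| so degrees read as degree of
    involvement and stay non-negative; mode="signed" sums the raw weights.
    Returns a DataFrame with columns k_in, k_out, k (= k_in + k_out).
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if mode == "absolute":
        A = np.abs(W)
    elif mode == "signed":
        A = W
    else:
        raise ValueError(f"unknown degree mode {mode!r}")
    k_out = A.sum(axis=1)
    k_in = A.sum(axis=0)
    idx = labels if labels is not None else list(range(W.shape[0]))
    return pd.DataFrame({"k_in": k_in, "k_out": k_out, "k": k_in + k_out}, index=idx)


def pb_index(degrees: pd.DataFrame, factor: float = PB_FACTOR_DEFAULT) -> pd.DataFrame:
    """Presence-Balance index: rotate the (k_in, k_out) plane by 45 degrees.

        P = c (k_in + k_out)      overall implication connectivity
        B = c (k_out - k_in)      >0 superordinate, <0 subordinate

    With the default c = 1/sqrt(2) the rotation is orthonormal
    (P^2 + B^2 = k_in^2 + k_out^2); pass ``factor=0.52`` to reproduce
    outputs computed with that constant instead.
    """
    if factor <= 0:
        raise ValueError("rotation factor must be > 0")
    P = factor * (degrees["k_in"] + degrees["k_out"])
    B = factor * (degrees["k_out"] - degrees["k_in"])
    return pd.DataFrame({"presence": P, "balance": B}, index=degrees.index)


def layout(G: nx.DiGraph, method: str = "graphopt", seed: int = 0) -> pd.DataFrame:
    """2-D node coordinates by one of three classic arrangements.

    reingold_tilford — tree-like hierarchy, most influential constructs on
    top; graphopt — force-directed, clusters highly connected constructs;
    mds — classical scaling of the Euclidean distances between rows of the
    symmetrized absolute weight matrix, so similar implication profiles
    land close together.  Stochastic methods are made deterministic by
    ``seed``.  Returns a DataFrame (index = node ids, columns x, y).
    """
    if G.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty graph")
    nodes = list(G.nodes)
    if method in ("reingold_tilford", "graphopt"):
        import igraph as ig

        index = {v: k for k, v in enumerate(nodes)}
        edges = [(index[u], index[v]) for u, v in G.edges]
        h = ig.Graph(n=len(nodes), edges=edges, directed=True)
        random.seed(seed)
        if method == "reingold_tilford":
            coords = h.layout_reingold_tilford(mode="all").coords
        else:
            coords = h.layout_graphopt(niter=500).coords
        xy = np.asarray(coords, dtype=float)
    elif method == "mds":
        xy = _mds_coords(G, nodes)
    else:
        raise ValueError(f"unknown layout method {method!r}")
    return pd.DataFrame(xy, index=nodes, columns=["x", "y"])


def _mds_coords(G: nx.DiGraph, nodes: list) -> np.ndarray:
    from skbio.stats.ordination import pcoa

    n = len(nodes)
    if n == 1:
        return np.zeros((1, 2))
    W = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    S = (np.abs(W) + np.abs(W).T) / 2.0
    diff = S[:, None, :] - S[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    with np.errstate(invalid="ignore"):
        res = pcoa(D, number_of_dimensions=2)
    xy = res.samples.values[:, :2]
    if xy.shape[1] < 2:  # degenerate spectra can yield a single axis
        xy = np.column_stack([xy, np.zeros(n)])
    return xy
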