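# wimpgrid

Analysis of **Weighted Implication Grids (WimpGrids)** — a constructivist
assessment instrument in which a person rates, for each of their personal
constructs, how a maximally contrasting hypothetical change in one
construct would shift all the others.  The package turns a completed grid
into a weighted directed network of constructs and provides the standard
analyses on it: centrality, change-to-ideal implication typologies, and
discrete-time simulations of anticipated psychological change.  It is
aimed at researchers and clinicians working with personal construct
methods who want a scriptable, reproducible alternative to manual
grid scoring.

## The model

A grid over `n` bipolar constructs is rated on an integer scale
`[r_min, r_max]` and mapped onto the normalized space `[-1, 1]^n` by
`x = 2 (r - r_min)/(r_max - r_min) - 1`.  Four objects summarise the
interview: the Self-Now vector `s` (diagonal of the hypothetical matrix),
the Ideal-Self vector `d`, the hypothetical-direction vector
`h ∈ {-1, +1}^n` (the pole opposite the current self; the ideal's pole, or
the right pole, when the self is undefined), and the hypothetical-selves
matrix `M` with `M[j, i]` = state of construct *j* under the scenario that
pushes construct *i* to `h_i`.

Assuming proportionality between imposed and induced change, the weight
matrix is

```
w_ij = (m_ji - s_j) / (h_i - s_i)
```

— the anticipated shift of construct *j* per unit hypothetical shift of
construct *i* (`|w_ij| ≤ 2`, diagonal 0).  On top of `W` the package
computes:

* **Construct digraph** — nodes classified congruent / discrepant /
  dilemmatic / undefined-self from `(s_i, d_i)`; edges direct or inverse;
  node size `|s_i|`; Reingold–Tilford, graphopt and classical-MDS layouts;
  GraphML/DOT export.
* **Centrality** — weighted in/out degrees and the Presence–Balance index
  `P = c (k⁻ + k⁺)`, `B = c (k⁺ - k⁻)` with `c = 1/√2` (an orthonormal
  45° rotation of the degree plane).
* **Change-to-ideal analysis** — on the ideal-oriented matrix
  `W* = diag(o) W diag(o)`: the six-way pair typology
  (positive/negative impact × no/positive/negative feedback) and the
  Impact/Feedback index `I_i = Σ_j w*_ij`, `F_i = Σ_j w*_ij w*_ji`.
* **Dynamics** — fuzzy-cognitive-map style propagation
  `s(t+1) = f_th(s(t) + a(t))`, `a(t) = Wᵀ Δs(t) e^{-λt}`, with clipping
  to `[-1, 1]` and decay `λ` (default 0.1), run to a fixed point.

## Worked example

The bundled 5-construct demonstration grid (synthetic ratings) describes a
person who is healthy and wants to be, undecided about being sporty, lazy
and anxious against their ideal, and busy with no clear ideal:

```
$ wimpgrid synth --example --out grid.csv
$ wimpgrid weights grid.csv --out-dir out
$ cat out/W.csv
,Sick-Healthy,No sporty-Sporty,Lazy-Hardworker,Calm-Anxious,Free-Busy
Sick-Healthy,0,0.4,0,0,0
No sporty-Sporty,0.333333333333,0,0,0,0
Lazy-Hardworker,0,0,0,0.2,0.4
Calm-Anxious,0,0,-0.4,0,0
Free-Busy,0,0,0,0.75,0
```

Row *i*, column *j* is `w_ij`: a full hypothetical swing toward Sick is
expected to drag Sporty down with sensitivity 0.4, and vice versa with
0.33 — a mutually reinforcing Healthy↔Sporty loop.  The pair typology
confirms it, and flags the conflict around the ideal of becoming a
hard worker:

```
$ wimpgrid ideal grid.csv --out-dir out
$ cat out/pairs.csv
source,target,w_forward,w_back,impact,feedback
Sick-Healthy,No sporty-Sporty,0.4,0.333333333333,positive,positive
No sporty-Sporty,Sick-Healthy,0.333333333333,0.4,positive,positive
Lazy-Hardworker,Calm-Anxious,-0.2,0.4,negative,negative
Lazy-Hardworker,Free-Busy,0.4,0,positive,none
Calm-Anxious,Lazy-Hardworker,0.4,-0.2,positive,negative
Free-Busy,Calm-Anxious,-0.75,0,negative,none
```

In the ideal frame, moving toward Hardworker is expected to *increase*
anxiety (forward weight -0.2 toward the Calm ideal: a negative impact).
Simulating a 0.5 push toward Hardworker propagates exactly that:

```
$ wimpgrid simulate grid.csv --construct 2 --magnitude 0.5 --out out/traj.csv
INFO wimpgrid: simulation converged at step 12; wrote out/traj.csv
```

Busy rises from 0.33 to ~0.50 and Anxious from 0.67 to ~0.85 before the
decay settles the system — the anticipated emotional cost of working
harder.  Centrality (`wimpgrid centrality`) shows Calm-Anxious with the
highest Presence (0.95) and the most negative Balance (-0.39): the most
involved and most *recipient* construct in this system.

The same operations are available as a library (`wimpgrid.normalize_grid`,
`compute_weights`, `build_digraph`, `pb_index`, `if_index`, `simulate`, …)
returning numpy arrays and pandas DataFrames.

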