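# Methods

## The grid and its normalization

A completed WimpGrid over `n` bipolar constructs holds an `n × n` integer
matrix `hyp` (row *j*, column *i* = rating of construct *j* under the
hypothetical transformation of construct *i*; diagonal = Self-Now), an
Ideal-Self vector, and an integer scale `[r_min, r_max]`.  Ratings are
mapped affinely onto `[-1, 1]`; the left pole of a construct is -1, the
right pole +1.  Raw ratings must be integers in range (anything else is
rejected with a full violation report rather than coerced); all analysis
happens on the continuous normalized scale.  Odd-span scales such as
[1, 8] are accepted — they simply have no rating that normalizes to 0, so
the midpoint-dependent rules below are vacuous for them.

The hypothetical direction of construct *i* is the pole opposite its
Self-Now; if the self sits at the midpoint, the ideal's pole; if both do,
the right pole by convention.  This guarantees `|h_i - s_i| ≥ 1`, so the
weight quotient below never divides by zero.

A normalized score is treated as "at the midpoint" when its magnitude is
below 1e-12.  Integer ratings on even-span scales produce exact zeros, so
the tolerance only matters for continuous forward-model grids.

## Weights

`w_ij = (m_ji - s_j)/(h_i - s_i)` is the induced shift of construct *j*
per unit imposed shift of construct *i*.  The convention is fixed as:
rows of `M` are rated constructs, columns are scenarios, and `W[i, j]`
reads "sensitivity of *j* to a change of *i*".  `|w_ij| ≤ 2` always and
the diagonal is identically zero.

When the target construct's Self-Now is already near a scale extreme, the
observable shift is compressed (a ceiling/floor effect) and the weight
may understate the anticipated influence.  No nonlinear correction is
applied; `ceiling_floor_flags` marks cells with `|s_j| > 0.9` as a
diagnostic so downstream users can treat those weights with caution.
Weights are not thresholded or shrunk at derivation time; sparsification
happens only at graph construction (edge threshold ε, default 0).

For ideal-frame analyses the matrix is conjugated by the orientation
vector `o` (`o_i` = sign of the ideal; sign of the self for dilemmatic
constructs; +1 when both are undefined): `W* = diag(o) W diag(o)`.  The
conjugation is an involution, and after it a positive `w*_ij` means
"moving *i* toward its ideal pole moves *j* toward its ideal pole".
Dilemmatic constructs are included in ideal-frame analyses under the
self-pole fallback rather than excluded; the fallback mirrors the
tie-breaking of the hypothetical-direction rule, keeping every orientation
well defined.

## Network, degrees, Presence–Balance

`W` is read as a weighted adjacency matrix.  Node categories follow the
(s, d) sign pattern, with an undefined self taking precedence over an
undefined ideal.  Edge categories use display orientations
`σ_k = sign(s_k)` (right pole if the self is undefined): an edge is
*direct* when `σ_i σ_j w_ij > 0`, i.e. when movement toward the displayed
pole of the source increases the displayed pole of the target.

Weighted degrees default to absolute-value sums: degree is read as degree
of involvement, which keeps it non-negative and keeps the
Presence–Balance plane inside its feasible wedge `P ≥ |B|`.  The literal
signed sums remain available as `mode="signed"` for users who want raw
net influence.

The Presence–Balance index rotates `(k⁻, k⁺)` by 45°.  The rotation
factor defaults to `1/√2 ≈ 0.70711`, the unique value making the map
orthonormal (`P² + B² = (k⁻)² + (k⁺)²`); `pb_factor = 0.52` is accepted
for compatibility with outputs computed using that constant, at the cost
of norm preservation.

Layouts are delegated: Reingold–Tilford and graphopt to python-igraph
(python-igraph draws from Python's `random`, so seeding that module makes
both deterministic), and the similarity arrangement to classical
multidimensional scaling via scikit-bio's PCoA.  The MDS dissimilarity is
a package convention: the Euclidean distance between rows of the
symmetrized absolute weight matrix `(|W| + |W|ᵀ)/2`, so constructs with
identical implication profiles coincide exactly.  SMACOF-style MDS was
deliberately avoided because it is stochastic and need not collapse
zero-distance pairs.

## Change-to-ideal typology and the IF index

Each ordered pair with a nonzero forward weight in `W*` falls into one of
six classes: impact = sign of `w*_ij`, feedback = none / positive /
negative by the sign of the loop product `w*_ij w*_ji`.  Defining
feedback through the loop product (positive = amplifying) makes a
double-negative loop *positive* feedback — a costly change that the
system then entrenches — and is consistent with the aggregate index
`F_i = Σ_j w*_ij w*_ji`, which sums exactly those loop products.  `F` is
invariant under any global pole re-orientation.  The typology is computed
for all ordered pairs and can be filtered to pairs whose source is a
discrepant construct (the clinically loaded case); both views are
exposed.  The typology is defined on the ideal-oriented frame only.

## Dynamics

Discrete-time propagation with decay and clipping:

```
s(t+1) = f_th(s(t) + a(t))          f_th = clip to [-1, 1]
a(t)   = Wᵀ Δs(t) e^{-λt}           t ≥ 1
Δs(t)  = s(t) - s(t-1)
```

`a(0)` is the external perturbation and is applied as given (decay starts
at t = 1).  Deltas are taken between post-clipping states, so every
recorded state respects the bounds exactly.  λ defaults to 0.1.  Since
`‖Δs(t+1)‖ ≤ ‖W‖∞ e^{-λt} ‖Δs(t)‖` and clipping only shrinks updates,
any λ > 0 forces convergence; the stopping rule — absent from the method's
original description, hence a package convention — is
`max|Δs(t)| < tol` (default 1e-6) with a step cap (default 50), recording
`converged_at`.  The simulator accepts either the raw-frame `W` (default,
the frame the update rule is stated in) or the ideal-oriented `W*`; the
CLI makes the choice explicit via `--frame`.  Multi-construct
simultaneous perturbations are supported, although single-construct
perturbations are the typical use.

## Synthetic grids

`random_grid` draws Self-Now and Ideal ratings uniformly over the scale
integers and lets each off-diagonal hypothetical cell depart from the
Self-Now with probability `density` (default 0.5, a moderately connected
system; density 0 yields a zero weight matrix).  Generation is a pure
function of the seed.  `grid_from_weights` is the exact forward model
`M[j, i] = s_j + w_ij (h_i - s_i)`: it emits continuous normalized grids
(no integer quantization) so that weight recovery is exact to machine
precision, and rejects prescribed weights that would push any cell
outside `[-1, 1]`, naming the offending cell.

These generators emulate the *structure* of real grids — valid ranges,
the diagonal convention, configurable implication density — but not the
psychology: real grids have correlated, clustered implications, ceiling
effects and respondent noise, none of which the uniform model reproduces.
Passing tests therefore certify the algebra and the software contracts,
not any empirical property of human construct systems.

`example_grid()` is a hand-written 5-construct grid with explicitly
synthetic ratings, designed so that one small grid exercises every node
category (congruent, two discrepant, dilemmatic, undefined-self), both
edge relations, a mutually reinforcing loop, and a three-construct ripple
(Hardworker → Busy → Anxious) that makes simulations non-trivial.

## File formats and numerics

The grid-csv / grid-json dialects are defined by this package (the
instrument itself specifies a visual template, not a file format): CSV
rows are constructs with columns `left_pole, right_pole, H1..Hn, ideal`
and a `# scale: r_min r_max` header line, mirroring the template's
row/column semantics; JSON carries the same fields.  Integer grids
round-trip bit-exactly.  Analysis outputs are CSV with 12 significant
digits; construct order is preserved everywhere, never sorted.

## Verification scale

The test-suite and acceptance batteries use 100–1000 replicates per
property (200 forward-model roundtrips at n = 3–12, 500 random grids for
structural invariants, 1000 clipping runs, etc.), sizes at which every
battery completes in seconds while still sweeping the relevant dimension
ranges.

## Known limitations

Weights are point estimates from a single interview — no repeated-measure
estimation or confidence intervals.  Ceiling/floor attenuation is flagged
but not corrected.  The dynamics are deterministic and linear between
clips; no stochastic or continuous-time variants.  Legacy
repertory-grid / implication-grid file formats are not imported, and the
dialect here is independent of any other tool's on-disk format.
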