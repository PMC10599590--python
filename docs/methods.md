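# Methods

## Model and notation

`eescreen` treats a model as a map from `k` inputs `X_1..X_k` to `q` outputs
`Y_1..Y_q`. Each input has a type (real, integer, boolean), bounds
`[min_i, max_i]` in its own units, and a unit-space counterpart
`x_i = (X_i − min_i)/(max_i − min_i)` restricted to the grid
`{j/(p_i − 1) : j = 0..p_i − 1}` of `p_i` levels. Inputs are assumed
independent and uniform on their ranges; non-uniform marginals are supported
through a per-input inverse-CDF hook (levels stay equi-spaced in unit space
and the hook maps them to actual values — the working notion of input
variability is then the hook's image of the unit interval, not the plain
range). The sensitivity notion throughout is *contribution of the input's
variability to output variance*, with the finite range as the default
measure of input variability.

An elementary effect is the finite difference
`EE_ij = (Y_j(to) − Y_j(from)) / Δ_i` between two design points differing
only in input `i`, with the **signed** actual step `Δ_i` in the denominator,
so the effect has units `[Y_j]/[X_i]` and the sign of a derivative
regardless of step direction.

## Designs

Two block shapes provide `k + 1` points serving `k` effects each:

* *winding stairs* — a walk changing exactly one coordinate per step. The
  fixed-step variant starts on the restricted grid `{0, …, 1 − |δ_i|}`,
  steps up or down with equal probability, and randomizes step order only
  among inputs sharing `(p_i, |δ_i|)` (permuting across level groups would
  move a coordinate onto another input's grid).
* *radial* — a star around a base point; perturbed point `i` replaces
  coordinate `i`.

Quasi-random variants draw one `(r + q) × 2k` matrix from a Sobol or R_d
stream; the left half supplies base points `A_i`, the right half
perturbation vectors, with block `i` pairing `A_i` with `B_{i+q}`. The shift
`q` (default 4) decorrelates base and perturbation; drawing two separate
k-dimensional streams is deliberately not offered, as successive QR points
are dependent and pairing them that way produces non-converging estimates.
If a free coordinate of a perturbation row coincides with its base
counterpart (a zero step), the whole stream row is discarded and regenerated
from further along the stream, with a retry cap of `100·r`; the scan resumes
at the affected block so a replaced row that later serves as a base is
re-checked.

Discrete (integer/boolean) coordinates are always *pinned* to the level grid
(`x = 1 → 1`, else `⌊p x⌋/(p − 1)`) and stepped by the fixed `|δ_i|` in a
direction keeping the point inside the cube; when both directions are
admissible the sign of `b_i − a_i` is reused (falling back to `+`), so the
decision still derives from the QR stream. `pinned=True` extends this
treatment to all inputs, giving the large-step fixed-grid strategies.
The fixed step defaults to `p/(2(p − 1))` (exact for even `p`, where it
equalizes level-sampling probabilities); for odd `p` that optimum is not a
grid multiple and the nearest admissible value below it, `⌊p/2⌋/(p − 1)`, is
used with a warning — it keeps perturbed points interior.

Optimized-trajectory selection maximizes the spread `D`, the sum over
ordered block pairs of squared inter-block distances (each unordered pair
counted twice, matching the printed definition the scaled spread assumes);
a block's distance to itself is zero by object identity. The greedy selector
(EOT) grows a set from each of the `M` pool blocks by repeatedly adding the
unused block with the largest spread gain, excluding blocks already selected
(duplicates add no information) and breaking ties toward the lowest pool
index; the exact selector enumerates all `C(M, r)` subsets under a
configurable cap. Random winding start points are sampled uniformly on the
restricted grid; QR/LHS starts for the pool are not implemented, as pooling
dominates any start-point refinement.

## Measures and classification

Per `(input, output)`: mean `μ`, standard deviation `σ` (denominator
`r − 1`, requiring `r ≥ 2`), mean of absolute effects `μ*` and median of
absolute effects `χ` (even `r`: midpoint of the central pair). The
normalized indices scale an aggregate by `c_x_i` (default: the range) and
divide by the sum over inputs, so `S_μ*`, `S_χ` and the exploratory `S_σ`
are dimensionless, invariant to output rescaling, and sum to one per output.
An all-zero denominator raises rather than silently returning 0/0. The two
rankings (`S_μ*`/`S_χ` vs `S_σ`) are deliberately not reconciled into one
score; `μ*/σ` ratios are available only as raw values.

Wu's classification sorts one output's indices ascending and takes the
largest prefix with cumulative mass strictly below `h/100` as unimportant
(the inequality is strict-then-inclusive exactly as printed, so a tie at
`h/100` ends the prefix); the importance threshold is
`μ̂₀ + n_σ σ̂₀` over that prefix (default `n_σ = 3`). With a single
unimportant input `σ̂₀` is undefined and set to 0 with a warning; with an
empty prefix the threshold is undefined and no input is labelled important.

Legacy dimensionless-model measures (per-trajectory normalized `τ`, its
output-average `β`, and the normalization of raw `μ*`) sum effects with
different units across inputs; they are gated behind a `dimensionless` flag
and refuse dimensional spaces by default.

## Diagnostics

The wrap-around L2 discrepancy uses its closed form; the scaled versions
divide the spread by the number of terms in its definition times the scale
of a squared block distance, `C(r,2)·k·((k+1)⁴ + (k+1)²)`, and the
discrepancy by `(k + 1)` times the expected squared discrepancy of a uniform
sample of the same size, `((3/2)^k − (4/3)^k)/N`. The spread normalization's
printed form is typographically ambiguous in its source; the raw `D` is
always reported alongside so any alternative normalization is recoverable,
and only orderings at fixed `(k, r)` are treated as meaningful.

## Sobol totals and benchmarking

Total-order indices are estimated with the Jansen form: squared differences
between base and single-coordinate-perturbed outputs, divided by `2r` times
a variance estimate using only base and fully-perturbed points (including
perturbed points would bias it). For winding samples the squared differences
come from consecutive walk steps and the walk's endpoints serve as base and
fully-perturbed points; for radial samples the fully-perturbed points are
`r` extra evaluations.

Reference ("ground-truth") indices per built-in function: the K-function by
an exact variance decomposition (the model is linear in each coordinate, so
conditional variances reduce to moments of products of uniforms, summed in
closed form); the G*-function by the standard product-function formula
`S_Ti = V_i Π_{j≠i}(1 + V_j) / (Π_j (1 + V_j) − 1)` with
`V_i = α_i²/((1 + 2α_i)(1 + a_i)²)`; f6 by 1-D adaptive quadrature of its
additive terms (the constant sixth term contributes exactly zero); and
Penman–Monteith by a scrambled-QMC Jansen oracle (default base sample 2¹⁷,
three seeds, warning if replicates disagree by more than 0.005). The
K-reference agrees with an independent QMC oracle to < 0.005; the
G*-reference is cross-checked against a pick-freeze Monte-Carlo estimate,
as the Jansen oracle converges slowly on G*'s spiky factors.

Replicate protocols: QR strategies give replicate `i` the stream segment
starting after `i·r` elements (the `q` extra perturbation rows of adjacent
replicates overlap, keeping the printed base-point segment boundaries); the
G* benchmark reuses the stream but resamples the offsets `η_i` per replicate
with recorded seeds (its total indices are η-independent). Rankings are
scored with Kendall τ-a and the Pearson correlation of Savage scores
`s_j = Σ_{i≥j} 1/i`; both require tie-free ranks, and ties in estimated
indices (possible at tiny `r`) are broken by input order and flagged in the
report.

## Synthetic inputs and what the tests show

The built-in test functions are the package's synthetic-data source; no
external data is needed. They span additive (f6), mildly nonlinear (K),
strongly nonlinear/interacting (G*) and dimensional/heterogeneous-range
(Penman–Monteith, with the canonical published ranges, all eight constants
screened as inputs) behavior. They do not emulate simulation noise,
model failures, correlated inputs, or non-uniform marginals — conclusions
about real models with those features require care beyond what passing
tests establish. Benchmark sizes in the test suite are scaled down from the
full study (e.g. 10–50 replicates, `r ≤ 100`, pools of 200, strategy-ordering
checks at `r = 20`); the package's own choice of default sizes keeps every
qualitative ordering reproduced while each check runs in seconds.

## Numerical choices

* Sobol streams are unscrambled by default (bit-reproducible replicate
  segments); the all-zeros leading point is skipped. A scramble seed is
  available where decorrelated replicates are wanted (the oracle uses it).
* The generalized golden ratio root is bracketed by `brentq` on (1, 2] and
  polished with Newton steps; the attainable residual floor grows with the
  derivative `(k+1)φ^k`, about 1e-12 near `k = 150`.
* R_d offset `α₀ = 1/2`.
* Affine unit transforms round-trip to 1e-12 relative; inverse-CDF hooks are
  inverted by 80-step bisection.
* CSV exchange writes full-repr floats and reads with round-trip float
  parsing, so design/outputs files reproduce coordinates bit-exactly.
* Model failures abort effect computation with the offending block and row;
  partial effect tables are never produced.

## Known limitations

* No alternative pool-based samplers (modified OT, sampling-for-uniformity,
  cluster sampling) and no star/centered-L2 discrepancies.
* Output-direction normalizations beyond a constant are not provided.
* The brute-force OT selector is exponential in `C(M, r)` and refuses past
  its cap; EOT is the practical path.
* First-order Sobol indices are out of scope; only total-order indices are
  estimated.
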