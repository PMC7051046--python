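# Methods

Design and numerical notes for `ratebound`. These record the choices that
are not obvious from the code and the reasoning behind them.

## 1. The bound

Let X take values `x_1, …, x_K ≥ 0`, each with probability `1/K`, and let
`μ = E(X)`. Then `Σ x_i = Kμ`, so for each i, `x_i ≤ Kμ` and hence
`x_i² ≤ Kμ·x_i`. Summing, `E(X²) ≤ Kμ²`, giving `Var(X) ≤ (K−1)μ²` and
`CV ≤ √(K−1)`. The same argument with `x_i^n ≤ (Kμ)^{n−1} x_i` gives
`E(Xⁿ) ≤ K^{n−1}μⁿ`. Equality holds exactly at the degenerate point
`(0, …, 0, Kμ)`.

Because the bound is an elementary consequence of equal weights, it binds
*every* equiprobable rate model — most importantly the discrete gamma —
regardless of the underlying continuous family. `max_variance_equiprobable`
re-derives it numerically (multi-start SLSQP over the simplex) purely as an
oracle for the test suite; the objective is convex, so the maximum is at a
vertex, which is what the optimizer finds.

`is_at_bound` tests `CV ≥ (1 − tol)·√(K−1)` with a relative tolerance
(default `1e-3`). A tolerance is required: a fitted shape parameter stops
at the bottom of its search range, not at α = 0, so the fitted CV is near
but not exactly on the ceiling. We verified, before writing any fitting
code, that with the shape floor at `1e-3` the discretized CV equals
`√(K−1)` to machine precision for K ≤ 10 — so the default tolerance
registers saturation whenever the optimizer pins the shape at its floor,
and the two defaults are mutually consistent rather than independently
tunable knobs.

## 2. Discretizing the gamma

`discretize_gamma` uses the standard equiprobable interval-mean
construction: category i of K is the conditional mean of the unit-mean
gamma on its quantile interval, computed from the regularized incomplete
gamma function with shape α+1 (the cumulative first-moment identity), then
the category rates are renormalized so the weighted mean is *exactly* 1.
The renormalization matters: every bound statement holds the mean fixed,
and downstream identifiability assumes unit-mean rate distributions. An
interval-median variant is provided for comparison.

Reported CVs are always computed **from the discretized distribution
itself**, never by plugging the fitted α into the continuous formula
`1/√α`. The distinction is the whole point: the continuous plug-in CV is
unbounded, while the discretized CV — the thing the likelihood actually
used — cannot exceed `√(K−1)`. The plug-in value is still available as
`gamma_plugin_cv`, deliberately under a separate name.

On the saturated plateau (α at or below ~0.01 for small K) the discretized
CV equals `√(K−1)` exactly in floating point, so CV as a function of α is
*weakly*, not strictly, monotone; tests assert accordingly.

## 3. The dual-rate codon model

State space: the 61 sense codons of the universal code. For codon pairs
differing at one nucleotide position,

```
q(x→y) = class_rate × exchangeability(a→b) × π_position(b)
```

(HKY exchangeabilities with ratio κ, F3x4 position-specific target
frequencies), where `class_rate` is the site's synonymous rate for
synonymous changes and its nonsynonymous rate times a global ω-like
`nonsyn_scale` for nonsynonymous ones. The model is time-reversible with
stationary distribution proportional to the product of position
frequencies. The synonymous and nonsynonymous generator parts are jointly
normalized so the neutral generator (both rates 1, scale 1) has expected
rate 1; branch lengths are expected substitutions per codon on that scale.

Each site carries an independent (synonymous, nonsynonymous) rate pair, so
the site likelihood is a mixture over the `K_syn × K_nonsyn` product of the
two discrete distributions. Identifiability is resolved by convention:
both rate distributions have unit mean; a single fitted `branch_scale`
multiplies all input branch lengths (absorbing the overall time scale); and
`nonsyn_scale` carries the mean nonsynonymous/synonymous ratio.

## 4. Likelihood engine

Felsenstein pruning, vectorized over joint categories × site patterns:

- site patterns are deduplicated once per (alignment, tree) pair;
- all joint-category generators are built in one stacked array and
  eigendecomposed together: reversibility makes `diag(√π) Q diag(1/√π)`
  symmetric, so a single batched `eigh` gives every transition matrix as
  two matmuls. This is both faster and numerically cleaner than `expm`;
- per-edge transition matrices are formed with a reused scratch buffer (an
  explicit loop over edges measurably outperforms one giant broadcast
  matmul at this size);
- leaf messages take a gather fast path when a row has no ambiguity;
- partial likelihoods are renormalized at every 8th internal node (and the
  root), trading the per-node max/divide against underflow protection —
  cheap insurance that only costs on large trees, which are the ones that
  need it.

Correctness is anchored to independent oracles in the test suite:
`scipy.linalg.expm` plus explicit enumeration of internal-node states on
small trees (identical to 1e-10 relative), re-rooting invariance, the
rate×c / branch÷c confounding identity, and closed-form two-taxon and
zero-branch cases.

## 5. Fitting

All parameters are optimized on log (rates, scales, κ, α) or
logit/stick-breaking (GDD weights) scales with L-BFGS-B under box bounds;
finite-difference steps are `3e-5` (sized against the ~1e-8 relative noise
of the likelihood), and gradient/function tolerances are sized for the
quantities we report (CVs to ~1e-3), not machine precision.

**Discrete gamma.** One shape parameter per rate class, α ∈ [1e-3, 100].
The profile likelihood in a class's α can hold two basins: an *interior*
basin and a *bound-saturated* basin in which the likelihood is flat in α
(every α below some threshold yields the same discretization to machine
precision, the extremal point). A single local search can land in either
basin and silently misreport saturation. After the first pass we therefore
run one targeted **regime-flip restart**: any class whose fitted
discretized CV is within tolerance of `√(K−1)` is restarted from an
interior shape (α = 0.25), and any class between 80% and 100% of the
ceiling is restarted from a saturating shape (α = 0.02); the better optimum
wins. Classes far below the ceiling skip the probe — the flip cannot
matter there, and skipping it keeps the experiment fast.

**GDD.** Per class, K free rates and K free weights with the first of each
fixed as reference (K−1 log-rate offsets + K−1 weight logits), rates
renormalized to unit weighted mean inside the transform, so the unit-mean
constraint is exact by construction rather than penalized. The surface is
multimodal and full of flat ridges, so the strategy is: one **informed
start** packed from a discrete-gamma (pre)fit's exact fitted
discretizations — which also guarantees the nesting property
`llf_GDD ≥ llf_DG` up to optimizer tolerance — plus seeded random
restarts run as short probes (8 iterations); the best probe is polished to
convergence only if it lands within 2 logL of the informed optimum. If the
optimizer exhausts its budget crawling a ridge, a short continuation is
run; if it gains < 0.05 logL the fit is declared a converged plateau (the
message records this). Weights that collapse below `1e-6` are flagged as
degenerate and pruned in `effective_distributions()` — a GDD using fewer
support points than allotted is a finding, not an error.

**Saturation flags** (`at_bound_syn` / `at_bound_nonsyn`) are defined only
for equiprobable fits; they are `None` for GDD, whose free weights make
`√(K−1)` inapplicable.

## 6. The experiment pipeline

For each alignment, the discrete-gamma ladder is fitted in increasing K
with warm starts, κ is estimated once (first converged fit) and then held
fixed across the ladder — it is a stable nuisance whose re-estimation per
cell roughly doubles runtime without moving any CV — and GDD fits start
from the last discrete-gamma fit. Failures are recorded per cell and
reported as attrition, never silently dropped; summary fractions are over
converged fits. The summary recomputes saturation from the stored CV
columns, so a written per-fit CSV is self-contained and re-summarizable at
any tolerance.

The default bias demonstration simulates 20 alignments of 8 taxa × 300
codons with synonymous rates gamma(α=1) and nonsynonymous rates gamma(α=0.2)
(true CV `√5 ≈ 2.236`). The nonsynonymous law is the stressor; the
synonymous law (not dictated by the scientific question) was fixed at α=1
— moderate, realistic variation safely below the K=3 ceiling — *before*
any fitting, so saturation statistics are driven by the nonsynonymous
class. Observed with the default seed: K=3 discrete-gamma CV estimates
mean 1.37 (45% of replicates at the `√2` ceiling), monotonically relaxing
with K, versus a K=4 GDD mean of 2.10.

## 7. Known limitations

- The best discrete-gamma log-likelihood is **not** monotone in K:
  different K impose different fixed quantile grids on the same
  one-parameter family, so the families are not nested and refinement
  arguments do not apply. We verified this empirically (multi-start fits
  where K=4 beats both K=5 and K=10 on the same data). GDD families *are*
  nested across K (a zero-weight category embeds K in K+1).
- The α search floor (`1e-3`) is a modeling convention: everything below
  it is likelihood-equivalent at double precision for K ≤ 10, so the floor
  is an equivalence-class representative, and "α at floor" should be read
  as "saturated", not as a point estimate.
- Branch lengths are taken from the input tree up to the single fitted
  `branch_scale`; per-branch re-estimation is out of scope.
- F3x4 frequencies use a +1 pseudocount so all 61 sense codons have
  positive stationary probability (required for a valid reversible
  generator); with very short alignments this shrinks frequencies toward
  uniform.
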