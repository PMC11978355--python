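# Methods

## Model

Counts `y_i` given predictors `x_i ∈ R^p` are assumed conditionally Poisson
with mean `θ(x_i) = exp(m(x_i))` (canonical log link, equidispersion:
conditional variance equals the conditional mean; `dispersion_check` reports
the sample variance-to-mean ratio so users can screen this assumption). The
log-mean surface `m` is unknown and assumed smooth. At an evaluation point
`x0` it is approximated by its first-order Taylor expansion, giving the
centered design row `(1, x_i1 − x0_1, …, x_ip − x0_p)` and a parameter vector
`β(x0) = (β0, β11, …, β1p)` of length p + 1. A single intercept is used:
per-predictor intercepts are not identifiable because only their sum enters
the linear predictor, and the curvature matrix of the estimating equations
has exactly one intercept column.

Estimation at `x0` maximizes the kernel-weighted Poisson log-likelihood
`ℓ(β; x0) = Σ_i w_i [y_i η_i − exp(η_i) − ln(y_i!)]` with product-kernel
weights `w_i = Π_j K_hj(x_ij − x0_j)`. The weights enter the score
`g = Xcᵀ W (y − μ)` *and* the curvature `−H = Xcᵀ diag(w μ) Xc`; omitting
them from the curvature would make Newton–Raphson solve a different set of
equations than the weighted score it is paired with. `ln(y!)` is computed via
the log-gamma function so counts in the hundreds do not overflow.

A "fitted model" is the collection of local fits anchored at the n
observation points, each carrying its coefficient vector, Fisher information
(`−H`, stored for diagnostics; no Wald inference is offered), convergence
diagnostics, and a validity window `x0_j ± h_j` inside which the first-order
approximation is considered applicable. Evaluating a stored fit outside its
window warns rather than errors: extrapolating a published local model by a
unit offset is a legitimate, if approximate, use.

## Kernels and weights

Gaussian (default) and Epanechnikov kernels are provided. The Gaussian
default keeps every weight strictly positive, so the local likelihood is well
defined at any evaluation point; Epanechnikov gives compactly supported
weights and can empty a neighbourhood at small h, which surfaces as a
degenerate-neighbourhood error. The scaled kernel uses the density convention
`K_h(t) = K(t/h)/h`. The 1/h factor cancels from the score equations —
estimates are invariant to it — but it fixes the scale on which MLCV values
are reported. Weights are never renormalized: only their ratios matter for
estimation.

## Fitting

Newton–Raphson: `β ← β + (−H)⁻¹ g`, stopping when the L2 norm of the accepted
step is ≤ ε (default 1e−6; max_iter 100 — the stopping rule is standard, the
constants are this package's choices). The linear system is solved, never
inverted, after adding a relative ridge `1e−10 · tr(−H)/(p+1)` to the
diagonal; this leaves the converged solution untouched (the fixed point is
defined by g = 0) while making rank-deficient directions — e.g. a predictor
constant within the effective neighbourhood — harmless: their score
components are zero and their coefficients simply stay put.

Initialization follows the OLS-of-raw-counts-on-raw-predictors recipe,
re-expressed in centered coordinates (centered intercept = raw fitted value
at x0; slopes unchanged). Because that fit lives on the count scale, its
linear predictor can sit far above the log-scale optimum when counts are
large (a fitted count of 110 puts η at 110, where exp(η) is astronomically
large and plain Newton needs ~100 damped iterations to descend). The
initializer therefore evaluates both the OLS candidate and a log-mean
fallback `(ln max(ȳ_w, 1), 0, …, 0)` (ȳ_w the kernel-weighted mean response)
and starts from whichever has the higher local log-likelihood; the fallback
also covers rank-deficient raw designs. A step-halving safeguard (up to 30
halvings, on by default; `safeguard=False` recovers the plain update)
rejects steps that overflow `exp(η)` or decrease the likelihood, so the
likelihood is non-decreasing across accepted iterations.

Degenerate neighbourhoods are detected in two ways: all weights exactly zero
(compact kernel, empty window) errors at design construction; a nearly
single-point neighbourhood (`Σw < 10⁻² · max w · n`) errors before fitting.
In per-observation batch fitting such failures are collected as flagged
entries, not raised, so one isolated point cannot abort a whole table of
fits.

The global baseline is the same Newton–Raphson run on the uncentered design
with unit weights — definitionally a Poisson GLM, and verified in the tests
against an independent IRLS implementation to 1e−8.

## Bandwidth selection

`MLCV(h) = Σ_i [m̂₋ᵢ(x_i) y_i − exp(m̂₋ᵢ(x_i)) − ln y_i!]` where `m̂₋ᵢ(x_i)`
is the centered intercept of the local fit at `x0 = x_i` computed with row i
deleted — the only value the local parameterization defines at x0 itself.
The deletion is literal (the row is removed and the model refitted); the test
suite checks this against an independently coded loop. The bandwidth
maximizing MLCV over a user-supplied grid is selected; no plug-in or
continuous optimization is offered.

Failed leave-one-out fits are dropped from the sum with a recorded count
rather than aborting — compact kernels at small h routinely isolate points —
and a grid point with more than 20% failures is marked invalid. The selected
vector attains the maximum among valid points with the fewest failures
(sums over different numbers of terms are not comparable), ties breaking to
the first grid point in order, which makes selection deterministic.

Two scan modes: `joint` evaluates an explicit list of bandwidth vectors;
`per_predictor` (default) scans each coordinate's 1-D grid in turn, holding
the others at their current best, starting from the middle of each grid, in
a single pass — the presentation used in per-predictor bandwidth tables.
Whether such tables are produced jointly or marginally is typically unstated;
both are provided.

## Prediction

Two strategies. `refit` (default, statistically correct for arbitrary query
points) fits a fresh local model at each query. `nearest_fit` evaluates the
stored fit whose anchor is nearest in bandwidth-scaled Euclidean distance,
mirroring the use of per-district stored models; the two coincide exactly at
training points. Predictions are positive reals; rounding to integer counts
is opt-in (`round_mode="nearest"`), never silent.

## Synthetic data

The generator draws predictors uniformly (or by right-skewed scaled-Beta
draws) on configured ranges, forms a known log-mean — log-linear, quadratic,
or sinusoidal — and samples Poisson counts; the true mean surface is returned
for recovery tests. A cap on the implied mean (default 10⁴) guards against
overflow from pathological scenarios.

The `stunting_like` scenario emulates the small-area count setting the method
targets: n = 39 units, counts with mean ≈ 110 and standard deviation well
above the mean *marginally* (driven by a steep log-linear surface over
right-skewed predictors, not by conditional overdispersion), predictor means
near 4.1 and 7.3 on ranges 0–21.4 and 0.75–30. The packaged fixture is one
seed-fixed draw from this scenario (seed 20230052, chosen so the realized
summaries track those targets), checksum-verified on load. What the fixture
does **not** emulate: spatial correlation between districts, measurement
error in the percentage covariates, and any true nonlinearity of the real
surface — so tests passing on it demonstrate correctness of the estimator
machinery, not substantive conclusions about real stunting data, which are
confidential and not shipped.

Simulation sizes used in the test suite (n = 39–2000, 50 replicates for
recovery studies, n = 10⁵ for moment checks) are the package's chosen desk
scale: large enough for the asymptotic statements being checked, small
enough to keep the suite fast.

## Numerical choices and edge cases

- `exp(η)` is declared overflowed above η = 700 and signalled as divergence
  (−∞ log-likelihood), which the safeguard then backs away from.
- Convergence is declared on step size; the max-norm of the score at the
  final iterate is recorded (`score_norm`) as a post-hoc quality check.
- CSV output uses `%.17g` formatting and CSV input uses round-trip float
  parsing, so write→read is bit-lossless and reruns are byte-identical.
- All simulation randomness flows through one `numpy` `default_rng(seed)`;
  a scenario plus its seed fully determines the dataset.

## Known limitations

- No quasi-Poisson or negative-binomial variant: conditional equidispersion
  is assumed, only diagnosed.
- No standard-error/Wald inference from the stored Fisher information.
- Grid-only bandwidth search; MLCV is not optimized continuously.
- `refit` prediction is O(n) Newton solves per query point; for large query
  batches `nearest_fit` trades statistical exactness for speed.
- Local fits at boundary points lean on one-sided neighbourhoods; the local
  linear form mitigates but does not remove boundary bias.
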