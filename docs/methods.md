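# Methods

## Model and estimator

For an ordered ROI pair (source *i*, target *j*) the target series is
modeled as the output of a causal, linear, time-invariant system with finite
memory, driven by the source:

    x̂_{j|i}[n] = Σ_{m=0}^{N_h-1} h_{j|i}[m] x_i[n-m],   n = 0..N_x-1,

with x_i[n] = 0 for n < 0 (zero initial conditions). N_h counts filter taps,
so N_h = 1 uses only the current source sample. Both series are demeaned
before fitting (`center=True`), which makes the N_h = 1 case reduce exactly
to standard Pearson correlation — sign-clipped under the nonnegativity
constraint, absolute-valued without it.

Coefficients minimize the residual sum of squares J over the full sample
range. Zero-padding (rather than discarding the first N_h − 1 residuals)
keeps J comparable across candidate orders on an identical sample set;
for N_h ≪ N_x the two conventions differ negligibly.

* Unconstrained: minimum-norm least squares (`numpy.linalg.lstsq`).
* Constrained (h ≥ 0): Lawson–Hanson NNLS (`scipy.optimize.nnls`), which
  satisfies the KKT conditions exactly; tests verify them at 1e-8 against
  an exhaustive active-set enumeration oracle.

The p-correlation ρ_{j|i} is the Pearson correlation of the target with its
prediction. A consequence worth stating: at the NNLS optimum the residual
is orthogonal to every active lag column, so cov(x_j, x̂) = ‖x̂‖²/(N_x−1) > 0
whenever the prediction is nonzero — **constrained p-correlation is never
negative**. When NNLS returns the all-zero filter (a legitimately optimal
answer for negatively related pairs) the prediction is constant, the
correlation is undefined, and ρ is reported as 0 with a degenerate flag;
downstream thresholding expects finite values. Diagonal entries are never
computed and are stored as 0.

## Order selection

The filter length is chosen by evaluating every N_h in {1, …, max_taps} and
minimizing

    AIC(N_h) = N_x log(2π J / (N_x − N_h)) + N_x + N_h,

with the standard small-sample (AICc) correction
2 N_h (N_h + 1)/(N_x − N_h − 1) added when N_x/N_h < 40. The switching rule
follows the published criterion; the correction term itself follows the
established AICc convention (Hurvich–Tsai/Cavanaugh) because the printed
small-sample branch in the source material is typographically corrupted —
this is a documented design choice, not a transcription. Ties break toward
the shorter filter; a perfect fit (J = 0) is treated as AIC = −∞ so the
smallest perfect-fit order wins. A seconds-denominated search window D is
converted to taps by max(1, floor(D/TR)); sub-TR increments would only
duplicate tap counts.

Selection properties tested: J is non-increasing in N_h; constrained J ≥
unconstrained J; the selected order is invariant to positive rescaling of
the source; on data with a true two-sample delay the selected order never
falls below the true lag and exceeds it with roughly the classical
P(χ²₁ > 2) ≈ 0.16 overfitting probability per extra tap.

## Thresholding, averaging, accuracy

Three idempotent matrix operators are applied in a fixed order:

1. clip: negative entries → 0 (nonnegative-interaction prior);
2. percentile: keep the top ceil(s/100 · N²) of all N² stored entries
   (zero diagonal included — that is how s is denominated), nearest-rank
   from above, ties at the cutoff kept; an off-diagonal-only universe is
   available behind `include_diagonal=False` for sensitivity checks;
3. unidirectional: for each pair zero the smaller of the two directed
   weights (ties keep both).

With ground truth available, s = 100 · COI / N², where the COI count is
twice the number of unordered ROI pairs carrying at least one true directed
connection (the absent reverse direction of a one-way edge is still a
connection of interest). The ratio is returned exact, never rounded.

Directionality accuracy is A = Σ 1{a_{j|i}>0} 1{d_{j|i}>0} / Σ 1{a_{j|i}>0}:
the fraction of true directed connections detected as strictly positive
after thresholding. Subject matrices can be averaged elementwise, and a
seeded split-half utility regresses cohort-2 mean positive strengths on
cohort-1's (dropping coordinates where both are zero) to quantify
robustness.

## The common-driver simulator

The validation generator is the three-ROI stationary AR(1) network in which
ROI 1 drives ROIs 2 and 3 while 2 and 3 never interact:

    x1[n+1] = a1 x1[n]              + b1 w1[n]
    x2[n+1] = a2 x2[n] + a21 x1[n]  + b2 w2[n]
    x3[n+1] = a3 x3[n] + a31 x1[n]  + b3 w3[n]

with i.i.d. N(0,1) innovations. Defaults are the study conditions:
a1 = a2 = a3 = 0.8 (equal intrinsic memory), b1 = b2 = b3 = 0.2 (equal
intrinsic noise power), N_x = 1000 samples, 50 subjects, TR = 1 (one model
step per sample), and four driving regimes
(a21, a31) ∈ {(0,0), (0.1,0.1), (0.4,0.4), (0.4,0.1)} — none, weak, strong,
asymmetric strong. The regime list resolves an ambiguity in the source
numbering by calling the asymmetric regime Case 4 throughout.

Initialization is exact: x[0] ~ N(0, P) where P solves the discrete
Lyapunov equation P = A P Aᵀ + B Bᵀ (scipy's direct solver; the contract is
the equation residual, and tests cross-check a fixed-point iteration oracle
and the scalar closed form b²/(1−a²) = 1/9). Per-subject generators derive
from a (base_seed, subject_index) seed sequence: bit-identical re-runs,
independent subjects. A generalized `simulate_linear_network` accepts any
stable state matrix for test fixtures.

What the generator emulates — lag-1 directed coupling, shared-driver
confounding, stationarity — is what the estimator claims to exploit. What
it does not emulate: hemodynamic convolution and its variable latency,
scanner/thermal noise, non-Gaussian or nonstationary dynamics, measurement
TR ≫ neural timescales. Passing tests therefore demonstrate correct
directed-network recovery for stationary linear lagged dynamics, not
performance on real BOLD data.

The steady state makes the confound concrete: under strong symmetric
driving the 2–3 correlation (0.669) exceeds the true 1–2/1–3 correlations
(0.511), so plain correlation ranks the spurious pair first, while the
3-tap population p-correlation ranks the 2–3 pair lowest (0.679 vs 0.709).
Both facts are verified empirically at N_x = 5000.

## Numerical choices and degenerate inputs

* Percentile cutoffs use nearest-rank (no interpolation) for determinism.
* Covariances in pair diagnostics use the n−1 normalization and the same
  zero-padding as the fit, so the identity R_{j|i} = Σ_m R_{j,i}[m] h[m]
  holds to 1e-10 relative tolerance.
* Constant columns are permitted on load but flagged; their correlations
  are reported as 0 rather than NaN.
* TSV floats are written with 17 significant digits for lossless
  round-trips; matrix orientation (target rows, source columns) is recorded
  in a header comment.
* Ordered pairs are mutually independent; any evaluation order produces
  identical matrices.

## Problem sizes

The packaged experiments use 50 subjects × 1000 samples × 3 ROIs with at
most 3 filter taps per regime (seconds per case on one core), and
N_x = 5000 with a handful of subjects for steady-state convergence and
ranking checks. These are the study conditions, chosen to match the
simulation design the estimator was validated on.

## Known limitations

* Single-source prediction only; multi-source (multivariate) prediction and
  MVAR/SEM hybrids are out of scope.
* BIC-based order selection is a hook point only, not implemented.
* No group/individual decomposition of the impulse response; subjects are
  processed independently and combined only by averaging.
* The unconstrained variant can reward sign-flipped predictions (|ρ|-like
  behavior at one tap), which makes it slightly less reliable than the
  constrained variant on all-positive networks — visible in the weak-driving
  regime, where an occasional subject in ~1/3 of 50-subject cohorts misses
  one connection.
* With ~2 effective taps the AIC's known small overfitting probability is
  harmless here, but on short series (N_x/N_h < 40) the AICc branch becomes
  load-bearing and has not been stress-tested beyond unit level.
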