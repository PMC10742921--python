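# Methods

This note records the model the package implements, the numerical
choices made where the procedure is genuinely open, the defaults and
their rationale, and what the simulator does and does not emulate.

## Model and assumptions

An N × I observed matrix `X` (persons × items, arbitrary missing cells)
is modelled as `X = RC + ε` with `R` (N × D) and `C` (D × I) of common
rank D. The assumptions that give the method its measurement
properties:

- every item loads on the *same* D dimensions and on no others (a
  "common space" — the multidimensional analogue of the Rasch
  unidimensionality requirement);
- each row and column has a characteristic noise scale (cellwise noise
  is the product of a row and a column factor);
- D is correctly specified. Specific objectivity — invariance of person
  measures to the item subset — holds exactly at zero noise and
  degrades smoothly with noise and with misspecified D (especially
  D too large).

Estimation is alternating least squares on non-missing cells only. Each
iteration: solve every person row against `C` by OLS, orthonormalize `R`
by QR (the triangular factor is re-absorbed by the following
column solve), then solve every item column against `R`. There is no
regularization penalty anywhere; the QR step plus explicit
dimensionality selection plays that role.

## Numerical choices

**Convergence.** RMS change of the estimates over observed cells
< 1e-6 (default) with a cap of 50 iterations (200 in the end-to-end
calibrator); both configurable. Oracle-style tests tighten the
tolerance to 1e-9..1e-12.

**Initialization and restarts.** `C` is drawn standard normal from the
given seed. Structured (blocked) missing patterns give the alternation
genuine local minima — on a noise-free rank-6 200 × 100 matrix with 25%
blocked missingness roughly 40% of random starts stall at a nonzero
residual plateau. `n_starts` runs several seeded starts and keeps the
one with the lowest observed-cell RMS; the dimensionality search
likewise scores each candidate D over several seeds and keeps the best.

**Degenerate solves.** A rank-deficient least-squares system gets the
minimum-norm solution and a logged condition number, never a ridge
term. Rows or columns with ≤ D observed cells are dropped from
calibration with a warning rather than aborting the run. The standalone
`solve_coordinates` accepts exactly-determined systems; calibration and
scoring enforce stricter overdetermined floors (> D for calibration
rows/columns, 2D by default for scoring).

**Anchoring.** Fixed `C` columns (equating) pin the coordinate frame,
so the QR step is skipped when column anchors are present — it would
rotate `R` out of the frame the anchors live in — and the first person
solve uses the anchored columns only. A fixed `R` dimension (age) is
unit-normalized; free dimensions are orthonormalized against it.

## Column metrics: the pseudo-logit scale

Least squares needs one unbounded, approximately linear metric across
columns. The plausible-value maps (the general framework prescribes
their existence but not their constants; these are this package's
choices, selected to be symmetric, finite and order-preserving):

| kind        | map                                   | inverse returns |
|-------------|---------------------------------------|-----------------|
| dichotomous | 0 → logit(0.25), 1 → logit(0.75)      | probability     |
| polytomous  | k of K → logit((k + 0.5)/K)           | expected category |
| interval    | column z-score                        | raw value       |
| ratio       | z-score of natural log (hard zero floor motivates the log) | raw value |

Standardization parameters are fitted at calibration, stored with the
item bank, and replayed exactly when scoring new persons.
Probabilities are clamped to [1e-6, 1 − 1e-6] before any logit. Timing
columns are not sign-flipped; the factorization handles negative
loadings natively.

Note a structural consequence of per-column centering: on complete data
the z-score removes any constant (difficulty) dimension and one rank is
absorbed, so a generator dimension that is constant across persons is
invisible to the factorization of complete data (with blocked
missingness the per-form means differ and the dimension partially
re-enters).

## Dimensionality selection

For each candidate d: *accuracy* hides a seeded 10% of observed cells
(large enough for a stable correlation, small enough to keep every
row/column solvable; cells are only hidden while > d observations
remain in their row and column), refits, and correlates hidden values
with their estimates. *Stability* calibrates `R` from alternating item
halves; because independent runs differ by an arbitrary rotation of the
space, the second solution is aligned to the first by orthogonal
Procrustes before correlating (the alternative — a shared anchored C —
was rejected because it understates independent-calibration
variance). *Objectivity* is the root product, with negative inputs
clamped to zero (a negative correlation carries no evidence of
reproducible structure and the root of a negative product is
undefined). Defaults: d in 1..10, 5 seeds per d, best seed kept; exact
ties go to the smallest d. The end-to-end calibrator runs the search on
the age-residualized matrix, so the selected d counts the non-age
dimensions only.

## Error model

Three error levels: raw residuals `Res = X − E`; the **expected
absolute residual** `EAR`, the characteristic residual scale per cell;
and the **standard error** `SE`, the expected distance between the
estimate and the unobservable true value.

`EAR` comes from decomposing squared residuals. Squares are floored at
1e-12, logged (the log turns the multiplicative row × column noise
model into an additive one, which is why the decomposition uses two
dimensions), fit by ALS, exponentiated, and mapped back per column by a
degree-1 polynomial fit against the raw squares; the square root is the
EAR. Two guards: the degree-1 fit can dip below zero, so fitted squares
are floored at 1% of the column's observed mean square (EAR never drops
below 10% of the column RMS residual — a bare epsilon floor turned a
handful of cells into astronomical misfits); and exact-fit data, where
the log matrix is constant and the 2-dim ALS degenerates, falls back to
an additive row/column-mean model, flooring EAR at √1e-12.

The cell standard error uses the (r − d)(c − d) denominator,

    SE = 2 · EAR · √d / ((r − d)(c − d))^(1/4),

where r, c count *observed* cells (so missingness folds into the
error automatically) — this is the variant whose divergence at r = d or
c = d matches the argument that an exactly-reproducing decomposition
has unbounded uncertainty. The (r − 1)(c − 1) variant is available as
`formula="legacy"`; the one-facet reduction `ear/√(n−1)` is provided
separately. A known bias pattern is inherited from the formula itself:
error is mildly over-estimated at small noise and under-estimated at
very large noise (the test suite asserts the direction, not a
magnitude). The formula is only calibrated when D is correctly
specified.

`ESE` applies the same pipeline to the SE matrix (infinite cells
excluded from the fit, refilled from coordinates), yielding portable
2-dimensional error coordinates per person and item; the bank stores
the item-side EAR/SE coordinates and polyfit coefficients, which is
what lets a scorer standardize a new person's residuals without the
calibration data.

Cell misfit is `Res/EAR`; person and item outfit are RMS misfit;
interpretability threshold 2.0 (configurable).

## Age anchoring and equating

Age-anchored calibration: (1) standardized (centered, unit-norm)
log-age becomes `R[:, 0]` — the raw scale is absorbed by `C[0]`, and
the log roughly equalizes age effects across the 7–82 range; (2) each
column's age loading is solved directly, leaving residuals orthogonal
to the age vector; (3) ALS on the residuals at the residual
dimensionality; (4) the residual dimensions are appended to the age
dimension; (5) a final refinement re-solves `C` then `R` with the age
coordinate re-estimated freely. Step 5 is *iterated* to the ALS
tolerance rather than run as a single pass: the single pass leaves
O(1/√N) age contamination from step 3's rank-d_residual fit of a
matrix whose observed-cell rank is d_residual + 1, visibly violating
the zero-noise oracle; iterated sweeps (each ending with the person
solve, so person coordinates are always computed last) converge to the
exact solution. Person coordinates from step 5 are deliberately not
orthonormal — they are the best least-squares fit given `C`.

Equating anchors the banked `C` vectors of common items, solves the new
form's `R` in one pass from those anchors alone, then the new items'
`C`; the link is accepted when common-item misfit stays below
threshold. At least 2D common items are required by default (the
identification minimum is D + 1; the margin guards against noise).
Equating is transitive at zero noise. Item drift reports per-item,
per-dimension and pooled coordinate correlations between group
calibrations, with optional Procrustes alignment for independently
calibrated groups.

## Construct scoring

Construct coordinates are the OLS regression of pseudo-logit ratings on
`R` (the rating column is *not* part of the factorized matrix — this
keeps the reporting scale an honest prediction of the rating and makes
calibration-versus-rescoring agreement exact). The semi-true rescale
restores the variance that least-squares estimation shrinks away:
`g = sqrt(1 + RMSE²/var(estimates))` applied about the mean, with
`RMSE² = mean(se²)`. The affine map to the reporting scale anchors the
calibration sample's 1st/99th percentiles at 10/90 — robust to tail
outliers while keeping scores inside [0, 100] without hard clipping —
and is persisted in the bank. Cut scores default to 45/50/55 with
half-open intervals ([50, 55) is Moderate).

Scoring a new person: match responses to bank items (unknown ids are
skipped with a warning; the default floor is 2D matched items), replay
the banked pseudo-logit parameters, solve `R_n` from the banked item
coordinates, dot with the construct coordinates, rescale. The person's
EAR per response comes from solving their 2-dim error coordinates
against the banked item error coordinates; item-level standard errors
use the SE formula with r = number of matched items and c = banked
observation counts; the construct-measure standard error propagates
them through the least-squares covariance,

    Var(w · R_n) = wᵀ P diag(se²) Pᵀ w,   P = (A Aᵀ)⁻¹ A,

and is multiplied by the combined scale slope (affine slope × semi-true
factor). No age input is needed: the age dimension is inferred from the
responses through the banked coordinates.

## The simulator

`simulate_dataset` draws `R_true`, `C_true` standard normal, noise
sd = noise_base × row × column lognormal multipliers, and deletes cells
randomly or in three staggered contiguous item windows ("forms").
`simulate_instrument` adds the screening-study structure: ages
log-uniform on [7, 82] with standardized log-age installed as dimension
0; a constant difficulty dimension 1; forms assigned by age group
(children < 10, teens 10–15, adults ≥ 16), each covering 75% of items
so the blocked missingness is 25%; 40% of columns dichotomized at their
median, 40% converted to lognormal "timing" columns whose loadings are
negatively related to a paired dichotomous item; and a 0–10 rating
discretized from a noisy projection of `R_true` weighted mostly on the
substantive dimensions (weight 0.3 on age, 0 on difficulty).

Defaults — 300 persons × 120 items, D = 6 (age + 5), 25% blocked
missing, noise_base 1.0, row/column noise spreads 0.3 (lognormal σ),
11 rating categories — mirror the study's structure at desk scale.
noise_base 1.0 against a per-cell signal sd of √D ≈ 2.4 puts roughly
15% of cell variance in noise: enough that error modelling and
dimensionality selection are non-trivial, well short of the regime
where the objectivity peak disappears. Tests that need known-truth
oracles scale down to 120–250 persons and 60–100 items so the full
suite runs in well under a minute.

What the simulator does **not** emulate: real clinical item content;
rater panels or rating drift; non-Gaussian noise; items violating the
common space (every simulated item loads on all D dimensions, so the
"analysis of fit, remove misfitting items" workflow is exercised only
through the statistics, not through genuinely aberrant items); and
realistic timing distributions beyond a lognormal transform. Passing
tests therefore show the machinery is correct *under the model's own
assumptions*, not that any particular real instrument fits the model.

## Known limitations

- Age-aligned blocked missingness makes the log-age and constant
  difficulty dimensions nearly collinear within each form; the problem
  stays identifiable through the form overlaps but is ill-conditioned,
  and machine-precision recovery can need thousands of alternations.
  Zero-noise oracle checks therefore use random missingness; at
  realistic noise levels the effect is irrelevant (the conditioning
  error is far below the noise floor).
- Dichotomization caps the recoverable latent correlation per binary
  column at E|z| = √(2/π) ≈ 0.80; latent-recovery bounds are asserted
  on continuous columns.
- The SE formula has no proof; its empirical calibration (median
  |E − T|/SE near 1, positive rank correlation with the true error) is
  what the tests assert, and it degrades when D is misspecified.
- One construct per bank is exercised end-to-end; the bank schema
  allows several, but multi-construct reporting is not built out.
- No 3-facet (person × item × rater) generalization.
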