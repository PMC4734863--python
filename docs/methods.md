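# Methods

## Model

A test-day milk record of cow *p*, taken in herd-test-date class *i* at
*t* days in milk (DIM), is modeled as

y = HTD_i + Σₙ₌₁..k_b bₙ·ageⁿ + Σₙ₌₁..k_c cₙ·tⁿ
  + Σₙ₌₀..ka−1 α_{pn} φₙ(t) + Σₙ₌₀..kpe−1 γ_{pn} φₙ(t) + e .

* **HTD** — the (herd, test date) contemporary group, fixed. HTD incidence
  carries the global level; there is no separate intercept, so the fixed
  block is full rank without dropping a level.
* **Fixed regressions** — powers 1..k of age at calving and of DIM (both
  default k = 3, configurable 0..5). Covariates are mapped to [−1, 1]
  before powering (age by its observed range, DIM by the model window);
  raising raw days to cubes produces condition numbers around 10¹⁴, so the
  literal raw-power variant exists only behind `raw_fixed_powers`.
* **Random regressions** — per-animal additive coefficient vectors α with
  Cov(α) = A ⊗ K_a over the full pedigree, and per-cow permanent-
  environment vectors γ with I ⊗ K_pe. φₙ is the orthonormalized Legendre
  polynomial √((2n+1)/2)·Pₙ(x) on x = 2(t−5)/300 − 1; "order k" always
  means k coefficients (degrees 0..k−1), so ka = 1 is an intercept-only
  animal effect. A plain (non-normalized) basis is available by flag.
* **Residuals** — independent, with a separate variance per ten 30-day DIM
  classes (5–35, 36–65, …, 276–305; the first class absorbs the odd day).

Each parity × milking-frequency group is analyzed as an independent
single-trait dataset; HTD classes are defined within the group.

## Data edits

Records outside DIM 5–305 or outside 1–70 kg are dropped; then all records
of cows whose age at first calving is outside 20–36 months; then all
records of cows left with fewer than 4 or more than 10 records in their
parity × frequency group. Removals are attributed to the first rule
violated, in that order, so the edit report is deterministic; the
record-level filters deliberately run before the count rule so that the
count applies to usable records. The edit is idempotent.

## Pedigree

A is built by the tabular method (kept dense; it is the oracle and the
simulation kernel), A⁻¹ by Henderson's rules from Mendelian-sampling
variances dᵢ, with parental inbreeding included by default (½ − ¼(F_s+F_d)
etc.); `use_inbreeding=False` gives the classical 1, ¾, ½ pattern, since
the original analysis does not state its choice. Σ log dᵢ supplies log|A|
for the likelihood. Unknown parents are "0" in files; parents referenced
but never defined become founders with a warning.

## REML

With G = blockdiag(A ⊗ K_a, I ⊗ K_pe) and R the diagonal class-variance
matrix, the restricted log-likelihood is evaluated through the
mixed-model equations: −2l = log|R| + log|G| + log|C| + y'Py + (n−p)·log 2π,
where C is the MME coefficient matrix and y'Py = y'R⁻¹y − θ̂'W'R⁻¹y. The
(n−p)·log 2π constant is kept so l matches the textbook dense formula
exactly (the tests do exactly that comparison).

**Factorization.** The permanent-environment equations are block-diagonal
per cow (kpe × kpe blocks), so they are absorbed: the solver factorizes
the dense Schur complement over [fixed | additive] and reconstructs every
inverse-matrix piece the estimators need — the additive block C_aa, the
per-cow PE diagonal blocks, and per-record quadratic forms w'Cw — at a
cost dominated by one Cholesky of a (p + ka·q) matrix per iteration. A
full sparse assembly of the MME is retained for oracle tests and export.

**Updates.** Free parameters are vech(K_a), vech(K_pe) and the ten σ²ₑ.

* EM: K_a ← (1/q)·Σ_{uv} A⁻¹_{uv}(α̂_u α̂_v' + C_aa[u,v]), analogously for
  K_pe with identity weights, and σ²_c ← (ê'ê + Σ w'Cw)/n_c per class.
  Exact EM, hence monotone in l (asserted to 10⁻⁹ relative per step).
* AI: analytic gradients −½(tr(P V̇) − y'P V̇ P y) via the same inverse
  pieces, and the average-information matrix ½ F'PF from the working
  vectors F_k = V̇_k Py. A candidate θ + AI⁻¹g that leaves the PD cone is
  *projected back* by eigenvalue clipping (floor 10⁻⁶ of the spectral
  radius) rather than discarded — near-singular K̂_pe is a real occurrence,
  and projection lets the iteration move along the boundary instead of
  stalling. Fractions 1, ¼, 1/20 of the step are tried; a candidate is
  accepted only if l does not decrease, otherwise the iteration falls back
  to an EM step. The default method (`ai-em`, after 2 EM burn-in steps)
  therefore produces a monotone likelihood path with near-quadratic
  terminal convergence (typically 9–30 iterations at ~3,000 records).
* Convergence: largest relative parameter change < tol (default 10⁻⁶);
  l alone flattens before the components settle. Non-convergence is a
  reported state, not an exception.
* Initialization: K_a = K_pe = 0.2·Var(y)·I on the coefficient scale,
  σ²ₑ = 0.6·Var(y) in every class; optional seeded relative jitter.

Cross-checks: on a paternal half-sib intercept-only instance the animal
model is an exact reparameterization of a sire + cow random-intercept
model, and the estimates agree with lme4 to five decimals; on general
small instances, Nelder-Mead polishing of the restricted likelihood from
either our solution or the truth returns our estimate, and the analytic
gradient matches central differences.

## Model selection

BIC = −2l + K·log n with n the record count of the analyzed group. Two
parameter counts: `true_count` = ka(ka+1)/2 + kpe(kpe+1)/2 + 10 (the free
parameters actually estimated; package default) and `paper_compat` =
10 + 3(ka+kpe), the rule that reproduces every printed count in the
published selection grids; it does not count the free elements of
unstructured K and is flagged nonstandard. The published BIC values are
likewise consistent only with base-10 logs, so base 10 is the reporting
default and natural log is a flag. Grid rows are ordered by (ka, kpe);
non-converged fits stay in the table, flagged, and are excluded from the
argmin; ties break toward smaller K, then smaller ka.

## Trajectories

σ²(t) = φ(t)'K φ(t); h²(t) = σ²ₐ/(σ²ₐ+σ²ₚₑ+σ²ₑ(class t)); repeatability
adds σ²ₚₑ to the numerator. Between-day phenotypic covariance is additive
plus permanent-environment covariance only — residuals are independent
across test days, the standard test-day assumption. Per-bin tables are
evaluated at bin midpoints 20, 50, …, 290 (whether the published per-bin
values are midpoint evaluations or bin averages is unstated; midpoint is
the cleaner convention). Whole-lactation summaries are unweighted means of
the daily values over DIM 5–305 and are labeled "daily-mean"; published
"overall" values computed by an unstated method are not comparable and are
never asserted against.

## Synthetic herd-books

The generator emulates the structure of the motivating study's data
(which were never deposited): herds with monthly test calendars (30 ± 3 d
jitter), cows calving uniformly over the year and tested at a random
subset of 4–10 eligible visits (so all ten DIM classes stay populated),
two parities and a 3X/4X split, ages at first calving uniform on 20–36
months. Yields are generated exactly under the fitted model: herd-test-
date effects N(0, 2²) kg, a parity-specific cubic in standardized DIM over
a base level (32/36 kg) scaled by 1.12 for 4X (inside the published
8–12 % frequency-response range), a linear age term, additive coefficients
sampled by pedigree-ordered Mendelian recursion (exactly A ⊗ K_a), PE
coefficients i.i.d. MVN, and class-heteroskedastic residuals. Defaults:
K_a = [[10, −1], [−1, 2]], K_pe = [[18, −2], [−2, 4]], σ²ₑ declining 14→8
kg² across classes — mid-lactation h² ≈ 0.21, inside the published 0.2–0.3
mid-lactation band (calibration is ours, not a published value). Pedigrees
are paternal half-sib families with unknown dams (unrelated dams carry no
additional information; a flag emits explicit founder dams). One integer
seed determines the output byte for byte.

What the generator does *not* emulate: culling and selection bias,
seasonality, parity-correlated repeated cows, multi-generation pedigrees,
or non-Gaussian residuals. Passing tests therefore demonstrate correctness
of the estimator under the model's own assumptions, not robustness to the
ways real milk-recording data violate them.

## The replicated study

20 replicates of 500 cows in 25 half-sib families (~19 daughters/sire,
matching the published pedigree's ratio) across 5 herds, ~6 records/cow
(~3,000 records), truth of order ka = kpe = 2. Each replicate is edited,
fitted at (2,2) and (1,1) (tol 10⁻⁵, ≤60 iterations), and summarized by
Monte-Carlo z-scores (replicate mean vs truth over SE of the mean) and the
BIC comparison. At the study seed, all 16 free parameters recover within
|z| < 1 and BIC prefers the generating order in 20/20 replicates. A
caveat worth knowing: with only 25 sire families the additive intercept
variance has a strongly right-skewed sampling distribution (MC sd ≈ 4.5 on
a truth of 10), so the 3-SE band on 20 replicates, while correct on
average, can fail for unlucky replicate sets; 60-replicate runs confirm
the estimator is unbiased. The problem sizes here (500 cows, 20
replicates) are the package's chosen desk-scale study conditions.

## Numerical notes and limitations

* Singular fixed blocks are reported with the offending column when the
  Cholesky pivot identifies one (e.g. a confounded regression power).
* A residual class with zero records keeps its current σ²ₑ during EM.
* `kpe = 0` (no PE term) is allowed for free-standing fits — with A = I
  and a single class this is the classical repeatability model and matches
  closed-form ANOVA REML; the BIC grid enforces 1 ≤ kpe ≤ ka ≤ 5.
* Multi-trait (joint-parity) models, maternal effects, dominance, genomic
  relationships, splines/parametric lactation curves, 305-d projections
  and eigenfunction decompositions are out of scope.
* The dense tabular A limits pedigrees to desk scale (≲ 10⁴ animals);
  the MME path itself is sparse apart from the Schur complement.
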