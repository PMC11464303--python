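# Methods

This note records the models implemented in `climacop`, the defaults and
why, the numerical choices made where the underlying method descriptions
were ambiguous, and what the synthetic-data tests do and do not establish.

## Data model and cleansing

A questionnaire table holds one row per respondent: an id, categorical
demographic attributes, integer 1–5 Likert responses per criterion, and
optionally a numeric target column. Criteria map to factors (e.g. safety
communication, management, attitude, awareness) and factors carry a
benefit/cost direction that all their criteria inherit; the default
configuration marks safety awareness as the sole cost factor.

Cleansing removes rows, never imputes. Five rules are supported, applied
per row in a fixed canonical order (duplicates, missing, out-of-range,
straight-line, reverse-item inconsistency) with each removed row attributed
to the first rule that fires, making report counts deterministic. Choices
that required judgment:

- **Duplicate** means identical full response vector *and* identical
  attributes, id excluded. The first occurrence is retained.
- **Straight-line** (a "violated the survey rules" pattern) is zero
  variance across all items; **reverse-item inconsistency** is
  `|a + b − 6| > 3` on user-configured reverse-keyed pairs. Both are opt-in
  because they need study-specific knowledge (which items are
  reverse-keyed; whether constant responding is plausible).
- Min-max normalization maps a constant column to all zeros (avoiding 0/0)
  with a warning.

## Criterion weighting

**BP / Garson.** A single-hidden-layer feed-forward network with logistic
sigmoid on both hidden and output layers, hidden size
`⌊√(m+n)⌋ + a` (default `a = 2`, giving 7 hidden neurons for 27 inputs and
1 output). Inputs and target are min-max normalized to [0, 1]. The
objective is the per-sample mean of ½(y − ŷ)², minimized by L-BFGS with the
analytic gradient on a seeded 70/30 train/test split; training stops at the
error tolerance (default 1e−6) or the iteration cap (default 500). Any
deterministic gradient-based optimizer satisfies the contract; L-BFGS was
chosen for robustness without tuning a learning rate. If the tolerance is
not reached the model is returned with `converged=False` and a warning —
importances remain meaningful. Garson importance normalizes
|input→hidden × hidden→output| products per hidden neuron; it is invariant
to positive rescaling of the output weights, and hidden neurons with
all-zero products are skipped.

Garson importance from a *single* trained network is noticeably unstable
across weight initializations. The canonical route `bp_weights` therefore
averages the importance over 5 independent seeded restarts; in the planted
top-3-recovery setting below this raises recovery from 17/20 to 20/20
seeds. The single-net path (`train_bp` + `garson_importance`) remains
public for inspection of individual fits.

**RF / oob permutation.** A bagged forest of `K` regression trees (default
500, `min_samples_leaf` 5, `max_features` 1/3). Bootstrap sampling and
out-of-bag bookkeeping are done in-package so that, per tree, the oob
squared error `e₁` can be compared with the error `e₂` after permuting one
criterion among that tree's oob rows; the raw importance is
`Σ(e₂ − e₁)/K`. For the weight vector, negatives are clamped to zero and
the vector normalized. Under a pure-noise target this clamped
normalization is inherently unstable (almost all raw importances are
slightly negative and the few positive fluctuations absorb all mass), so
null behavior should be judged on the raw scale via `rf_raw_importance`,
which also reports the mean oob error for reference; the null test asserts
raw importances below 5% of the oob error.

**Fusion by maximizing deviations.** With per-criterion deviation sums
`D_j = Σ_i (r_ij − r̄_j)²` over the (normalized) sample matrix, the
deviation objective `Z = α(D·u) + β(D·v)` restricted to the positive unit
circle is maximized in closed form at `α = A/√(A²+B²)`, `β = B/√(A²+B²)`
(`A = D·u`, `B = D·v`), i.e. the Lagrangian stationary point. Printed
derivations of this scheme circulate in at least two mutually inconsistent
forms (one of which does not satisfy α² + β² = 1); the constrained
maximizer is implemented and verified in tests against a dense grid search
over the quarter circle to 1e−6. The fused weights use the sum-one
rescaling `ω = α′u + β′v`.

## Cloud model

A cloud `(Ex, En, He)` represents a group's answers on one criterion: `Ex`
the central tendency, `En` the spread/fuzziness, `He` the instability of
that spread (both as standard deviations). Droplets are drawn by the
double-normal process `Enn ~ N(En, He²)`, `x ~ N(Ex, Enn²)`; non-positive
`Enn` draws are replaced by their absolute value (standard practice), and
`He = 0` short-circuits to `Enn = En` exactly so degenerate clouds realize
exactly.

The backward transformation (MBCT-SR) draws `d` groups of `c` samples with
replacement, computes unbiased within-group variances `t_l²`, and sets

    En² = ½·√(4(ET²)² − 2·DT²),   He² = ET² − En²

with `ET² = mean(t_l²)`, `DT² = var(t_l²)`. This rendering is
self-consistent: homogeneous group variances (`DT² = 0`) give `En² = ET²`
and `He = 0`, and `En² ≤ ET²` always, so `He² ≥ 0` whenever the radicand
is nonnegative. A negative radicand (heavy-tailed `t_l²`) is clamped to
`En = 0`, `He² = ET²` with a warning. Defaults `c = min(30, m/5)` (floor 2)
and `d = 200` balance resampling noise against cost; both are exposed in
`BackwardCloudConfig` since the transformation's sensitivity to them is a
property of the data, not a universal constant.

Droplets are deliberately **not** clipped to the Likert range: realized
cell means sit inside [1, 5] naturally and clipping would bias them.

## CM-COPRAS

The cloud decision matrix (groups × criteria grid of clouds) is realized
by averaging `n_droplets` forward droplets per cell (default 2,000, the
scale at which the realization standard error on typical survey clouds is
~0.014 Likert points). Each cell uses an RNG substream keyed by (master
seed, group index, criterion index), so adding a criterion or group never
perturbs other cells. Realized values are column-sum normalized
(`d_ij = r_ij/Σ_i r_ij`), weighted (`d̂_ij = ω_j d_ij`), and ranked:

    P_i = Σ_{benefit} d̂_ij,   R_i = Σ_{cost} d̂_ij,
    Q_i = P_i + ΣR / (R_i · Σ(1/R)),   U_i = Q_i / Q_max.

The two printed forms of `Q` (with and without `R_min`) are algebraically
identical (`R_min` cancels); tests confirm agreement to 1e−12. With no cost
criteria the correction term has an empty sum and `Q = P`. A zero `R_i`
alongside cost criteria is an error (the harmonic term is undefined). Ties
in `Q` are broken by input group order with a logged notice.

## Cloud-TOPSIS comparators

Variant 1 treats each weighted cloud `(ωEx, ωEn, ωHe)` as a 3-D point; per
criterion the ideal is (max ωEx, min ωEn, min ωHe) and the negative ideal
the reverse; `d⁺/d⁻` are Euclidean distances over all criteria. Variant 2
weights the cloud as `(ωEx, (ωEn)², (ωHe)²)` — implemented literally as
described, with `squared_entropies=False` available since the squaring may
be a transcription artifact — and accumulates a composite cloud distance:
an expectation-offset term scaled by the span of the two clouds' 3·En
envelopes plus one-minus-min/max ratio terms on En and He, mixed by
`λ = (⅓, ⅓, ⅓)` by default (the λ's must sum to 1). Ratio terms with both
operands zero contribute 0, keeping the distance total on degenerate
clouds.

Closeness is reported as `d⁻/(d⁺+d⁻)` (larger = better), because published
rankings with this family order alternatives by descending score; the
literal `d⁺/(d⁺+d⁻)` form is available via `orientation="literal"`. Ideal
construction ignores benefit/cost direction by default (as the method is
usually printed); `apply_direction=True` with a criteria spec swaps the
Ex max/min for cost criteria. When every alternative coincides (d⁺ = d⁻ =
0) closeness is defined as 0.5.

## Synthetic data generator

The generator emulates the target survey population: 27 items in four
factors sized 10/7/5/5; 5-point Likert answers from a latent
`base mean (4.2) + per-category factor shifts + N(0, 0.7)` rounded and
clipped to {1..5}; six demographic attributes whose gender/age/education
proportions follow the published sample statistics (renormalized, since
printed percentages carry rounding); planted age and education effects
reproducing the published ordering direction; default contamination rates
(2% duplicates, 2.5% missing, 1.5% out-of-range, 1.5% straight-lining,
~7.5% total) matching the scale of a real survey's cleansing loss.
Contaminated rows are appended after the clean block with recorded
indices, so cleansing tests are exact. The composite target is
`y = Σ w*_j x_j + N(0, σ)` min-max normalized, with `w*` known.

What passing tests show — and don't. Rounding/clipping shrinks planted
mean shifts (tolerances account for this); real surveys have
item-response-theory response styles, missing-not-at-random patterns, and
correlated item errors that the generator does not emulate. Recovery
results on synthetic data establish the pipeline's correctness, not the
measurement validity of any particular questionnaire.

## Problem sizes in the test suite

Statistical properties run at sizes chosen for sound error bounds: weight
recovery uses 12 criteria with three dominant true weights (0.30, 0.22,
0.15), n = 2,000, SNR 10, 20 seeds, forest size 120; full-pipeline ordering
recovery uses 8 criteria, 3 groups of 300 with ±0.3 per-factor shifts, 20
seeds; dominance/agreement checks use 100 seeded trials at 2,000 droplets.
Group-mean recovery tests use response sd 0.3 so the 0.05 tolerance is a
≈3.7σ bound.

## Known limitations

- The BP error contract is on the optimizer's objective, not on reaching a
  global optimum; pathological targets may return `converged=False`.
- Garson importance ignores interaction structure; the RF route partially
  compensates, and the fusion inherits both estimators' biases.
- MBCT-SR assumes approximately normal within-group responses; strongly
  skewed or bimodal Likert distributions inflate He.
- COPRAS significance magnitudes depend on the number of alternatives
  (column normalization); only orderings and utility degrees are
  comparable across analyses.
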