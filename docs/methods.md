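# Methods

## Item models and the generator

Thirteen item models produce number-series items by substituting numeric
values into fixed rules. Five cognitive operators underlie them:
apprehension of succession (AOS), identification of parallel sequences
(PS), object cluster formation (CF), non-progressive coefficient patterns
(NPCP) and complex progressive coefficient patterns (PCP). Each model's
operator involvement is a row of the five-column Q-matrix in
`ansig.qmatrix`; models 12 and 13 intentionally share a profile, so the
eleven fielded models (3–13) realise 8 of the 32 possible binary profiles
(all thirteen realise 10).

Length and blank conventions follow the published exemplars: model 1 shows
five elements with one blank; model 2 is two clusters of three; models 3,
6, 7 and 8 are six elements with one blank; model 9 is seven; models 4, 5,
10, 11 and 13 are interleaved or patterned layouts of 8–11 elements with
two blanks. Model 12 supports both printed layouts of its S1 S2 S2 pattern
— nine elements with the final paired-subsequence elements blanked
(default) or ten elements with the last subsequence-1 element blanked last
— via `GeneratorConfig(model12_layout=...)`. Blanks always occupy the final
positions of the displayed sequence.

Default parameter ranges keep magnitudes small (starting values mostly in
1–10, coefficients 2–9, additive constants 1/10/100 for succession chains,
group anchors up to 300); an overall magnitude cap of 10,000 rejects any
draw with larger elements, because visually enormous numbers make items
look hard for reasons unrelated to the intended operators. Division chains
are generated by reversing a multiplication chain so every quotient is an
integer. Degeneracy guards require distinct cluster values, distinct
parallel subsequences and non-zero progressive increments. Rejection
sampling retries up to `max_retries` (500) before failing.

Seeding: a bank draw derives one `numpy` generator per item from
`default_rng([root_seed, model_id, attempt])`, so any item can be
regenerated in isolation and banks are reproducible item-by-item.

## Rule inference (solving)

The solver for each model knows the model's structural layout (single
chain, interleave, pairs, S1 S2 S2 pattern) and infers the numeric rule
from the stem with exact rational arithmetic. Chain extrapolation prefers
the lowest-order rule family consistent with *all* stem elements:

1. constant difference;
2. constant ratio;
3. arithmetically progressive differences (constant second difference);
4. multiplicatively progressive differences (constant difference ratio).

Family 4 is algebraically identical to the composite add-then-multiply step
x ← (x + a)·b — for any sequence whose differences have constant ratio b,
setting a = x₂/b − x₁ satisfies the composite relation at every position
and yields the same extrapolation — so the two descriptions are one family
and cannot disagree. Stems that fit no family raise an "unsolvable" error;
stems too short to pin down a rule (e.g. a single element of a cluster)
raise an ambiguity error rather than guessing.

## Rasch calibration

Conditional maximum likelihood removes the person parameters by
conditioning on raw scores. Elementary symmetric functions of the item
easiness values are evaluated with the summation (difference-free)
polynomial recurrence, which is numerically safe for ~50 items; first
derivatives use forward–backward prefix/suffix polynomial products and the
information matrix uses the conditional score covariance — deflation is
never used. Missing-by-design data are grouped by administered item
subset, which makes anchored concurrent calibration of overlapping forms
automatic. Identification is sum-zero over the estimated items, optionally
re-centred on an anchor subset. Optimisation is quasi-Newton (L-BFGS) on
the analytic gradient, gradient tolerance 1e−8, at most 500 iterations.
Items without score variance are excluded with a warning; extreme persons
contribute no conditional information and are dropped from the likelihood.

Person abilities given fixed difficulties are per-person maximum
likelihood (root of the score equation); perfect and zero scores have no
finite estimate and are flagged excluded, with no bias correction applied —
a documented limitation. Andersen's likelihood-ratio test compares
subgroup calibrations (raw-score mean split by default; median or explicit
groups also accepted) against the pooled one with df = (G−1)(k−1); Wald
tests compare per-item difficulties between the two subsamples after
putting both on the shared sum-zero metric. Test information is
Σ p(1−p) on a θ grid (default −6…6, step 0.01); person-separation
reliability is (var(θ̂) − mean SE²)/var(θ̂), floored at zero.

## LLTM and LLTM-plus-error

Both explanatory models are fitted by marginal maximum likelihood with the
fixed effects on the easiness scale (logit P = θ_v + c + Σ_j q_ij b_j);
reported difficulties are the negated linear predictors, so both scales
are available and clearly labelled. The person-only LLTM integrates θ by
Gauss–Hermite quadrature with 61 nodes; plain (non-adaptive) quadrature at
this node count reproduces a 121-node reference within 0.02 logits on the
study-sized fixtures in the test suite, which is why the simpler scheme
was chosen. Gradients are analytic (posterior-weighted score residuals),
so the saturated per-item variant — the unrestricted marginal Rasch model
used for AIC/BIC comparison — also fits quickly.

The LLTM-plus-error adds a per-item residual ε_i, giving crossed person ×
item random effects. Its marginal likelihood uses the Laplace
approximation at the joint random-effect mode, found by damped Newton
steps whose linear solves use a Schur complement on the (small) item
block, so one evaluation costs O(nk + k³). Because the Laplace
approximation carries a small negative bias relative to exact quadrature,
the zero-variance boundary is treated as an explicit candidate evaluated
with the exact person-only likelihood: if the interior Laplace solution
does not beat it, the boundary fit (ε variance 0) is returned. This
guarantees the nesting inequality — the error model never fits worse than
the plain LLTM — at the cost of slightly conservative detection of very
small residual variances. Variance components are parameterised as
log-standard deviations (no explicit lower bound needed); parameter counts
include variance components (LLTM: m+2 with intercept; plus-error: m+3).

Bootstrap standard errors are parametric: responses are simulated from the
fitted model on the observed design (same persons, same missingness), the
model is refitted, and replicate standard deviations are reported; refit
failures are dropped and more than 20% of them is an error. BIC uses the
number of *observed (administered) responses* as its sample size, matching
the convention that treats each response, not each person, as an
observation in these crossed designs.

## Simulator and form assembly

Simulated respondents draw θ from Normal(0, 1) by default (the standard
marginal-ML convention); responses are Bernoulli at the Rasch probability.
Item residuals, when requested, are drawn once per item per replication —
they shift an item's difficulty for everyone, which is what an item-level
ε means. The study preset assembles Form A (models 3, 4, 6, 8, 10, 12; 30
items) and Form B (models 3, 5, 7, 8, 9, 11, 13; 35 items) with the ten
model-3/model-8 items as anchors, and allocates 396 and 174 persons by
fixed counts (uniform random allocation is available). Flat-information
forms are assembled by drawing a fixed number of items uniformly without
replacement from each half-logit difficulty bin; under-filled bins warn
and contribute what they have — on the shipped 49-item reference pool the
[−2, −1.5) bin holds only two items, so the default draw yields 23 items.

What the simulator does *not* emulate: guessing and slipping, response
times, learning or fatigue across positions, and any dependence of
responses beyond the single ability dimension. Passing recovery tests on
simulated data therefore shows the estimators are correct under the
model's own assumptions, not that real respondents satisfy them.

## Reference calibration

`ansig.reference` ships the published estimates from the generator's field
calibration: 49 per-item Rasch difficulties with standard errors, the
per-model LLTM and LLTM-plus-error predictions with bootstrap SEs, the
operator coefficient sets of both explanatory fits, per-form
person-separation reliabilities and the external-test correlations. These
are inputs (for simulation, assembly, prediction and validity reporting),
not quantities the package re-estimates. Recomputing the maximum Form B
test information from the two-decimal published difficulties gives 5.87 at
θ = −0.20; summing two-decimal coefficient tables likewise reproduces the
published per-model predictions only to about ±0.015 — both are input
rounding, not model disagreement, and the test suite uses tolerances sized
accordingly (set from the printed precision before comparison, not tuned).

## Problem sizes used in the test suite

Simulation-based tests use 300–1000 persons and 15–55 items per
replication, with 20–200 replications depending on the statistic: these
sizes give Monte-Carlo error comfortably inside the asserted bands while
keeping the whole suite in a few minutes. Type-I error checks for the
Andersen and Wald tests use 200 replications of 300 persons × 15 items;
LLTM coefficient coverage uses 100 replications at n = 1000; information
criterion selection uses 50 (residual variance 1) and 20 (residual
variance 0) replications at n = 300.

## Known limitations

- Solvers assume a single consistent rule; deliberately ambiguous stems
  (multiple inconsistent parameterizations) are reported as errors, not
  resolved.
- No distractor generation: items are open-ended, as in the study design.
- Person estimation is plain ML without bias correction; extreme scores
  get no estimate.
- The Laplace-based error model is conservative near zero residual
  variance (see above) and, like any Laplace fit, slightly biases variance
  components downward for small samples.
- Q-matrix entries are taken as known design inputs; the package does not
  estimate them from data.
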