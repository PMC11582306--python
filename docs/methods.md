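# Methods

## Model structure

All models share the forward map `pi* = f(Phi)` from true-category
probabilities (and bias parameters) to observed randomized-response
profile probabilities.

**Transition matrices.** A single symmetric RR question has
`P(2x2) = [[p, q], [q, p]]` with `q = 1 - p`; `p` is the probability
that the recorded answer equals the true one. Designs sharing a
transition matrix are statistically equivalent (Warner-type and
unrelated-question setups both reduce to this form). `p = 1` is direct
questioning; `p = .5` is uninformative and is flagged, not rejected.
Multi-question designs take Kronecker products of per-question
matrices; labels are concatenated with the first-listed question
varying slowest, `n` before `y` (so the two-question rows read
nn, ny, yn, yy). A non-randomized variable enters as an identity
factor. Only symmetric designs with one shared `p` per
ever/last-year pair are supported; the general asymmetric 2x2 form is
accepted for single questions.

**Ever/last-year (ELY).** Two questions on the same attribute. The
true profile `ny` (never carrier, yet last-year carrier) is a
structural zero and is removed from the category space (never encoded
as a zero-probability column), leaving categories
`nn` = never, `yn` = former, `yy` = last-year and the 4x3 matrix whose
last-year column is `(q^2, qp, pq, p^2)'`. The lost column is the
design's free degree of freedom.

**Sub-samples.** One question, two groups with complementary
randomization probabilities; the model is formulated on conditional
per-block probabilities, so each sub-sample is its own multinomial and
block column sums are 1. Under adherence `pi*_{n|1} + pi*_{n|2} = 1`;
an excess flags all-"no" cheating.

**Bias structures.**

- *CDM*: an appended category `c` whose column is the all-"no"
  indicator within each block. Carrier prevalence becomes the interval
  `[tau_y, tau_y + tau_c]`.
- *SP-no*: `pi* = (1 - theta) P pi + theta e_allno`. With
  `tau_c = theta`, `tau = (1 - theta) pi` the CDM and SP-no are exact
  reparameterizations: equal maximized likelihoods, equal G2 and AIC.
  The closed-form correspondence (and its inverse) is implemented for
  the sub-samples design in the three identifying variants
  `theta_n = theta_y`, `theta_n = 0`, `theta_y = 0`.
- *SP(last-year)*: three mutually exclusive classes per category —
  SP-no sayers (`theta`), last-year editors (`theta_yy->yn`, defined
  for `yy` categories only: they follow the randomizer but report `yn`
  whenever the randomized pair is `yy`), and adherents. This
  reproduces the 4x3 matrix with the bias parameters inside; note the
  editing term is *not* scaled by `1 - theta`. With extra questions
  the edit operator acts on the ELY factor of the Kronecker product;
  with two ELY sets one shared parameter gives each set its own
  mutually exclusive editor class (a `yy/yy` respondent is an editor
  of either set with probability `theta_yy->yn` each), which requires
  `theta + 2 theta_yy->yn <= 1`.
- For a pure multiple-questions design the SP-no model is identified
  by a log-linear constraint on the true-profile distribution:
  independence (main effects only) for two questions, no three-way
  interaction for three. ELY-based designs leave the joint adherent
  categories unrestricted — their degrees of freedom come from the
  structural zeros. Free per-category `theta` is rejected as
  unidentified.

**Misreport fraction.** `theta` is not the fraction of misreported
answers: an SP-no sayer only misreports when the randomizer required
"yes". The fraction is
`theta (1 - pi_y)(1 - p_nn) + theta pi_y p_nn`.

## Estimation

The multinomial kernel `ln l = n' ln pi*` is maximized (product
multinomial over blocks for sub-samples; the block totals drop out of
the conditional formulation). Category probabilities are estimated
through a softmax map with the first category as reference; `theta`
and `theta_yy->yn` are estimated on their natural scales, `theta`
bounded to `[-0.5, 1]` so that sampling fluctuation below zero is
representable, `theta_yy->yn` to `[0, 1]`.

Optimization: L-BFGS-B from 20 starts (first start uniform, the rest
random; seeded, ties broken by the earlier start), followed by an
SLSQP polish on the natural scale (probabilities on the simplex with
non-negativity constraints on `pi*`). The polish matters: softmax
coordinates can only approach a simplex-boundary maximum as
`beta -> -inf`, so a quasi-Newton stop on the unconstrained scale sits
strictly inside the simplex; sparse profile tables (e.g. 16 profiles
from ~1,000 respondents) do place MLEs on the boundary, and the polish
reaches them exactly. Boundary solutions are flagged on the result.
Fits on probability vectors (non-integer "counts") are supported; this
is how pseudo-true parameter values of misspecified models are
computed exactly.

Degrees of freedom: `df = (profiles - blocks) - k` with `k` the number
of free identified parameters (simplex dimensions plus bias
parameters). `G2 = 2 n' ln(n / n_hat)` with the `0 ln 0 = 0`
convention; `df = 0` yields no p-value. AIC is `2k - 2 ln l` on the
kernel; because the multinomial coefficient is dropped and parameter
counting conventions vary, only AIC *differences* between models
fitted to the same data are meaningful, and only those are asserted in
tests.

Standard errors: delta method. The observed information is the central
finite-difference Hessian (step 1e-4) of the negative kernel on the
unconstrained scale at the MLE; its pseudo-inverse is propagated
through the central-difference Jacobian (step 1e-6) of the map to the
natural parameters. At boundary solutions the information is singular
in the collapsed directions; SEs there are reported but flagged
(`se_available`, `boundary`). The Hessian/Jacobian helpers are small
hand-written routines — the package deliberately has no automatic
differentiation dependency.

The likelihood-ratio test used throughout (power study, model
screening) is `2 (ln l_alt - ln l_null) = G2_null - G2_alt` on
`k_alt - k_null` df. For detecting `theta` it is referred to
chi-squared with 1 df at alpha = .05; negative `theta` estimates are
retained, making the test two-sided. A Wald variant
(`(theta_hat / se)^2`) is available behind a flag. The test, alpha and
replication counts are this package's choices; they are not prescribed
by the design itself.

## Simulator

Respondent-level, fully vectorized, one seeded generator with a fixed
draw order (categories, class uniforms, true-response evasion,
randomizer flips, recorded-response evasion) so counts are bit-stable
under a seed. A single uniform per respondent assigns the mutually
exclusive classes: `[0, theta)` SP-no, then one `theta_yy->yn`-wide
slot per ELY set for the editor classes (inactive slots act adherent),
matching the transition-matrix semantics exactly; SP-no membership is
independent of the true category. Each question is then flipped
independently with probability `q`. Sub-samples splits the sample in
half, the second half answering with the complementary probability.

Item-specific evasion supports two stages:

- `true_response` (default): a carrier of the flagged item answers it
  as a non-carrier with the given probability, before randomization.
  This is algebraically a deflated item prevalence, so in a joint
  model a saturated add-on question absorbs it completely — the
  mechanism behind the sensitivity result that excess evasion on an
  add-on question underestimates that item's prevalence without
  biasing the ELY categories or `theta`.
- `recorded_response`: a randomizer-required "yes" on the flagged item
  is replaced by "no" after randomization. At high rates this pushes
  the item's observed yes-rate below the randomization floor `q`,
  which no prevalence value can mimic, and the deficit then leaks into
  `theta`. Exposed for studying exactly that failure mode.

What the simulator does *not* emulate: respondent covariates, panel
structure, partial adherence (classes are all-or-nothing),
question-order effects, or differential `p` within an ELY pair.
Passing recovery tests therefore show correctness of the estimator
under the model's own assumptions, not robustness to their violation
(except for the item-evasion sensitivity analysis, which is one
deliberate misspecification).

## Power study

For each grid cell: simulate, fit null and SP-no, record LR rejections
of `theta = 0`. Conditions follow the ELY power setup: all-never
prevalence `pi_never`, remaining categories sharing
`(1 - pi_never)/k`, `p = 5/6` per question. Cells draw independent
sub-seeds from the master seed, so any cell is reproducible in
isolation. Power loops default to 2 optimizer starts per fit (the
cell models have at most 9 free parameters and well-behaved
likelihoods; spot checks against 20-start fits agree).

`efficiency_compare` additionally contrasts (a) the empirical standard
error of the last-year prevalence estimate under the ELY design versus
a lone last-year question at matched `n` — the ELY design wins because
the ever question carries information about the same attribute — and
(b) power at `p = 2/3` versus `p = 5/6` — randomization closer to 1/2
detects evasion better, at the usual cost in prevalence precision.

## Numerical choices and test scales

- Column sums of constructed matrices are validated to 1e-12 per
  block; probability vectors to 1e-8.
- Optimizer: L-BFGS-B `gtol` 1e-10 / `ftol` 1e-14, SLSQP `ftol` 1e-14;
  inadmissible parameter points (a nonpositive `pi*` at an observed
  profile) get a large finite penalty rather than an exception.
- Log-linear SP-no fits (no boundary issues in the loglinear scale)
  polish with Nelder-Mead instead of SLSQP.
- Monte-Carlo test scales, chosen for stable verdicts at practical
  runtimes: type-I calibration 1,000 reps (3-sigma band around .05);
  power checks 200-400 reps against wide (±.1 or directional) bands;
  recovery at n = 100,000 within 3 standard errors; simulator-vs-
  forward agreement at n = 10^6 within 4 binomial standard errors;
  sensitivity analysis 40-60 reps at n = 4,000.
- The bundled survey fits are deterministic: identical output for any
  optimizer seed tried.

## Known limitations

- Absolute AIC values are convention-dependent (see above); compare
  models, not tables printed elsewhere.
- SEs at boundary solutions are degenerate in the collapsed direction;
  a bootstrap would be the honest alternative and is not implemented.
- One fit statistic worth knowing about: for the elite-athlete survey
  the nine-category null model's MLE lies on the simplex boundary; a
  softmax-only optimizer that stops early reports a deviance near 9.45
  at a boundary-adjacent stall point, whereas the true optimum (found
  by the polish stage, and confirmed by EM and direct simplex search)
  has G2 = 9.00. This package reports the true optimum.
- Polytomous sensitive questions, unequal sub-sample `p`, covariate
  regression models and Bayesian estimation are out of scope.
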