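# Methods

`mmchoice` implements the quantitative machinery of a benefit–risk discrete
choice experiment (DCE) for relapsed/refractory multiple myeloma (RRMM)
treatment preferences: experimental design, a synthetic respondent
simulator, error-component logit estimation, and the derived preference
metrics. This note records the models, the defaults and why they were
chosen, and the limits of what the simulation-based tests demonstrate.

## Attribute catalog

Treatments are described by eight attributes: three benefits — overall
response rate (ORR, 25–85%), duration of response (DOR, 3–15 months),
overall survival (OS, 6–24 months) — four risks — peripheral neuropathy
(0–50%), temporary vision change (0–60%), cytokine release syndrome (CRS;
a high-risk level quantified as an 85% chance of any CRS vs. no risk), and
severe diarrhea (0–20%) — plus a five-level unordered administration
attribute whose bundles range from IV/SC every 3 weeks (the reference) to
the one-time CAR-T procedure package. Dummy coding against each
attribute's reference level yields 23 part-worth coefficients. Ordered
attributes carry numeric level values, which define both the preference
direction used in dominance construction (higher benefit better, lower
risk better) and the scale widths used in trade-off calculations (60 ORR
percentage points; 18 OS months).

## Random-utility model

Respondent *n*'s utility for alternative *j* in a task is

```
U_nj = x_j' (beta + sum_c z_nc gamma_c) + sigma * eta_n * 1[j = A] + eps_nj
```

with `x_j` the dummy-coded levels, `beta` the part-worths, `gamma_c`
interaction shifts for respondent characteristics `z_nc`, `eta_n ~ N(0,1)`
drawn once per respondent, and `eps_nj` independent standard Gumbel. The
error component is attached to alternative A and held constant across a
respondent's tasks. This placement is a deliberate minimal choice: in a
two-alternative forced choice, a component common to both alternatives
would cancel from every utility difference and leave `sigma`
unidentified, whereas the one-sided component induces exactly the panel
correlation that identifies it. Only the sign of `sigma` is arbitrary
(the likelihood is symmetric in `±sigma`), so the estimate is reported as
`|sigma|`.

Opt-outs are modeled as the survey collected them: the forced choice is
always made, and an independent opt-out flag is drawn per task
(default rate 0.05; the study did not report one). Opt-out is a
quality-control statistic only and never enters the likelihood.

## Experimental design

Designs are scored by the D-error of the conditional logit,
`det(I(beta)^-1)^(1/K)` with `I = sum_tasks p(1-p) d d'` and
`d = x_A - x_B`. Priors default to zero (a utility-neutral design) since
no informative priors are published. The search is coordinate exchange:
random starting level assignments (duplicate tasks and level-identical
alternative pairs re-drawn), then repeated single-cell level swaps
accepted when the D-error falls, for up to 20 sweeps (10 in the pipeline
default), best of 2 restarts. On toy catalogs small enough to enumerate,
the search attains the exhaustive minimum; on the full catalog it is a
local optimizer, which is all a D-efficient claim requires.

The 36 experimental tasks are split into 3 blocks of 12 by a greedy rule:
each task joins the non-full block where it least increases the sum over
attributes of squared deviations of within-block level counts from
uniform. Two validity tasks are appended per block: a stability repeat
(an exact copy of the block's third task) and a dominance task built from
a random experimental task by setting one alternative to the best level
of every ordered attribute while holding administration equal — the
administration attribute has no defensible objective ordering, so it is
never allowed to decide dominance.

## Synthetic respondents

The simulator reproduces the published sample composition: 296
respondents in six country strata (US 100, UK 49, Italy 45, Germany 43,
France 39, Spain 20; other totals are scaled by largest remainder),
caregiver probability 0.84, male 0.52, per-country age distributions
(normal with the published means/SDs, truncated to the observed 38–85
range), prior treatment lines on 2–8 with median 3 (the pmf reproduces
the published 59% with 2–3 lines and ~15% with 5+), and the published
response-status and fatigue distributions. Covariates are drawn
independently within respondent; real data would show correlations (e.g.
age with caregiver status) that the simulator does not attempt.

Blocks are assigned round-robin for exact balance. Choices are drawn by
utility maximization under the model above, so simulated data match the
estimator's assumptions exactly. Consequently the passing recovery and
coverage tests demonstrate internal correctness of the estimation
machinery — not robustness to the misspecifications real choice data
carry (lexicographic responders, attribute non-attendance, scale
heterogeneity across countries).

The default data-generating part-worths set each attribute's utility
range proportional to the study's published relative-importance scores,
scaled by 0.05 so the largest range (ORR) is ~1.5 on the logit scale — a
typical signal-to-noise level for health-preference DCEs — and
`sigma = 0.8`.

## Estimation

The panel simulated log-likelihood averages, per respondent, the product
over tasks of binary logit probabilities across quasi-random draws of
`eta`, and sums the log averages. Draws are scrambled Halton, seeded,
500 per respondent by default, and antithetic (each draw paired with its
negation): this halves integration variance and makes the simulated
likelihood exactly symmetric in the sign of `sigma`, so relabeling the
two alternatives leaves the part-worths invariant up to optimizer
tolerance. Optimization is BFGS with the analytic gradient; part-worths
start at zero and `sigma` at 0.5 — zero is a stationary point of the
`sigma`-symmetric likelihood, so a quasi-Newton started exactly there
cannot reliably leave it. Convergence requires either the optimizer's
own success flag or a final gradient max-norm below 1e-3 (BFGS can stop
with a precision-loss status once float precision of the likelihood is
exhausted). Standard errors come from the inverse numerical Hessian
(central differences of the analytic gradient); a respondent-clustered
sandwich covariance is optional. Validity tasks are excluded from the
likelihood by default — they are engagement checks, and a stability
repeat would double-count its source task. A `fix_sigma` option fits the
nested plain conditional logit, used for boundary-correct
likelihood-ratio tests of the error component: the Wald z on `sigma` is
not asymptotically normal at `sigma = 0` (the information vanishes
there), so tests of "no error component" use the LR statistic against
its 50:50 mixture of 0 and chi-square-1 null.

## Importance scores and trade-offs

RAI for attribute *k* is `100 * range_k / sum_j range_j`, where the range
is max minus min over the attribute's level utilities with the reference
included at zero; the scores are conditional on the level ranges shown
and sum to 100. Confidence intervals are Krinsky–Robb: coefficient
vectors drawn from the estimated multivariate normal (nearest-PSD repair
with a warning if needed), the score recomputed per draw, and 2.5/97.5
percentiles reported.

The minimal acceptable benefit for a risk change is

```
MAB = (u(from_level) - u(to_level)) / (range_benefit / scale_width)
```

i.e. the benefit attribute's utility is linearized over its full level
range (per ORR point: `range_ORR / 60`; per OS month: `range_OS / 18`).
This linearization is adopted because it makes the full-range identity
`MAB = (range_risk / range_benefit) * scale_width` hold exactly, which
reproduces every published trade-off value directly from the published
importance scores (e.g. 11.9 / 29.8 × 60 = 23.96 ≈ 23.9 ORR points for
CRS) — strong internal evidence that this is the computation behind the
published figures. A non-default `piecewise` mode inverts the benefit
attribute's piecewise-linear utility instead; the two coincide whenever
the estimated benefit utilities are linear in the level values. The
administration trade-off is the same formula applied to the utility
difference between the CAR-T bundle and the IV/SC every-3-weeks
reference. Krinsky–Robb intervals propagate the fit covariance through
the same formula.

## Heterogeneity

One binary characteristic at a time is interacted with all 23 attribute
levels in a joint fit; the indicator-0 group takes the base part-worths
and the indicator-1 group base plus interaction. Group-specific RAI
propagates the joint covariance through Krinsky–Robb. Interaction
z-statistics are nominal and flagged exploratory; no multiplicity
correction is applied, as none is part of the analysis being modeled.
Fitting one characteristic per model avoids inventing a joint
multi-covariate specification that the modeled analysis never states.

## Numerical choices and problem sizes

- Optimizer gradient tolerance 1e-6; D-error exchange acceptance
  threshold 1e-12; singular information matrices yield +inf D-error with
  a warning rather than an exception.
- Simulated likelihoods use the log-sum-exp trick over draws; logit
  residuals use `expit` to avoid overflow.
- Monte Carlo experiment sizes in the test suite: parameter recovery
  uses 20 replicates of 500 respondents × 12 tasks on the full catalog
  with 200 draws per fit; interval coverage uses 200 replicates of 500
  respondents × 8 tasks on a reduced 3-attribute catalog with 64 draws —
  sizes chosen to keep the full suite a few minutes while leaving the
  binomial tolerances meaningful.
- Ties in simulated utilities resolve to alternative A; they occur with
  probability zero under Gumbel noise.
- Reports round percentages and months to 1 decimal, matching the
  presentation scale of the published tables.

## Known limitations

- The estimator and simulator share one model family; no protection
  against (or measurement of) real-world misspecification is claimed.
- The error-component placement (alternative A, respondent-constant) is
  one of several specifications consistent with a brief "error-component
  logit" description; published appendix formulas, if available, should
  supersede it.
- `sigma` near zero is weakly identified (n^¼ rate); Wald inference on
  it is unreliable there, and the package's tests use likelihood-ratio
  checks instead.
- The D-efficient search is heuristic on large catalogs; only toy
  instances carry an optimality guarantee.
- Willingness-to-pay is out of scope (the catalog has no cost
  attribute), as are latent-class and random-coefficient mixed logit.
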