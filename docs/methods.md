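# Methods

## The task

`mfarm` implements a three-armed explore/exploit bandit task ("Maggie's
Farm": trees as bandits, apple sizes as rewards) together with the full
analysis stack used to study individual differences in exploration.

On every trial three bandits are shown, drawn from four types that differ in
generative mean and in the number of *initial samples* displayed before the
first choice:

| type             | initial samples | overall mean mu_overall              |
|------------------|-----------------|--------------------------------------|
| certain-standard | 3               | 4.5 or 6.5 (uniform)                 |
| standard         | 1               | certain + offset, offset ~ U{-2,-1,+1,+2} |
| novel            | 0               | (certain or standard, uniform) + offset |
| low-value        | 1               | min(other three) - 1                 |

Each bandit's true mean mu_i is drawn as N(mu_overall, 1.4^2); rewards are
N(mu_i, 0.8^2), truncated to [2, 10], then rounded half-up to an integer.
The notation N(mu, 0.8) is interpreted with 0.8 (and 1.4) as **standard
deviations**; a config flag (`dispersion_is_variance`) flips the
interpretation if needed. The short horizon allows 1 draw, the long horizon
6; a session holds 200 trials per horizon, built from 100 unique
configurations per horizon, each duplicated (identical bandits and initial
samples, re-randomized display positions) so duplicate-pair choice
consistency can be computed. Duplicates are kept within the same horizon so
per-horizon consistency is well defined.

Constraint handling: the low-value bandit's single initial sample must be
strictly smaller than every other displayed sample. We draw it directly
from its conditional distribution (a rounded value below m corresponds to a
continuous truncated-Gaussian draw below m - 0.5), which is distributionally
identical to rejection resampling but loop-free. When the constraint is
unsatisfiable (another bandit already shows the smallest possible apple, 2)
only the bandit realizations are redrawn; the type subset and the overall
means — in particular the 4.5/6.5 anchor — are drawn once per trial, so the
constraint cannot distort their marginal distributions.

Three of the four types appear per trial. The low-value bandit is included
with probability `p_low_value` (default 0.75, which equals a uniform draw
over the four 3-subsets); the parameter exists because the design
deliberately oversamples low-value trials when a higher rate is wanted.

The **high-value** label goes to the certain-standard/standard bandit with
the higher mean of initial samples; exact ties break to the lower display
position (deterministic and documented; ties are rare because samples are
integers).

## Beliefs

All choice models share Gaussian conjugate beliefs over each bandit's mean:
prior N(Q0, sigma0^2), known observation sd fixed at the generative reward
dispersion (0.8). The observation sd is a model constant, not a fitted
parameter. Integer rewards are treated as real observations; no
discretization correction is applied (the rounding bias is small relative
to the 0.8 observation sd and identical across bandits).

## Choice models

The model zoo crosses three "complex" strategies with two heuristics:

* **Thompson sampling** — P(choose i) = P(posterior draw of i exceeds all
  others). Computed exactly for independent Gaussian posteriors by 1-D
  Gauss–Hermite quadrature over arm i's draw (default 12–24 nodes; error
  < 1e-4 at 12 nodes on task-scale posteriors, verified against a 10^6-draw
  Monte-Carlo oracle). A common-random-number MC mode exists as well; the
  quadrature path is used during optimization because it is deterministic
  and smooth.
* **UCB** — decision value V_i = Q_i + information_bonus * s_i, softmax with
  precision `inv_temp`.
* **Hybrid** — probability-level mixture w * UCB + (1 - w) * Thompson, with
  w shared across horizons.
* **Novelty bonus eta** — added to the decision value (UCB) or posterior
  mean (Thompson) of any arm with zero observations; once an arm has been
  sampled within a trial the bonus no longer applies (the bonus is the
  intrinsic reward of choosing a *novel* option).
* **Value-free random exploration epsilon** — final-probability mixture
  p' = (1 - eps) p + eps/3, uniform over all three displayed bandits.

{Thompson, UCB, hybrid} x {plain, +eps, +eta, +eps+eta} gives 12 models;
four reduced baselines (uniform random, eps-greedy on posterior means,
softmax on posterior means, novelty-only) complete the 16-model space. The
exact composition of the published 16-model space is not fully enumerated in
the available text, so the zoo is config-extensible; it provably contains
the winning (Thompson+eta+eps) and runner-up (UCB+eta+eps) models.

Simulation samples choices exactly (a Thompson agent draws one posterior
sample per arm and takes the argmax) rather than through the probability
vector. Long-horizon trials update beliefs with each observed outcome before
the next draw.

## Fitting

Only first draws enter the likelihood (200 per horizon). Per-horizon
parameters (epsilon, eta, sigma0, info_bonus, inv_temp) are fitted jointly
for both horizons; Q0 and w are shared. Estimation is MAP with weakly
informative priors chosen on the task's natural scales (the published prior
choices are in supplementary material not available here):

| parameter   | prior              | bounds        |
|-------------|--------------------|---------------|
| epsilon     | Beta(1.2, 3)       | (0, 1)        |
| eta         | half-N(sd 3)       | [0, 10]       |
| sigma0      | half-N(sd 2)       | [0.05, 5]     |
| Q0          | N(5, 2)            | [0, 10]       |
| info_bonus  | half-N(sd 2)       | [0, 5]        |
| inv_temp    | Gamma(2, scale 1)  | [0.01, 20]    |
| w           | Beta(1.2, 1.2)     | (0, 1)        |

The optimizer is bounded L-BFGS-B from Latin-hypercube multi-starts
(default 10; the recovery analyses use 2–3, which pilot runs showed reach
the same optimum on this likelihood surface), relative tolerance 1e-7,
deterministic given the seed. BIC = k ln(n) - 2 lnL uses the unpenalized
log-likelihood at the MAP point with n = number of first draws (400).
Choice probabilities are floored at 1e-10 before logs.

Model comparison ranks mean BIC (lower is better) and tests each model
against the winner with the same Shapiro-gated paired tests as the
behavioural analyses. Model recovery simulates sessions per generating
model, refits the whole zoo, and tabulates best-BIC frequencies into a
confusion matrix P(fit | gen); the inversion matrix P(gen | fit) follows by
Bayes' rule, which under the design's uniform generating frequencies is a
column normalization.

## Synthetic cohorts

The cohort generator emulates the study population rather than any real
participant: each synthetic participant gets generating parameters for the
winning model, a latent continuous impulsivity trait z ~ N(0,1) (a stand-in
for questionnaire totals — items are not simulated), and age / IQ
covariates.

* epsilon lives on the logit scale: logit(eps_h) = a_h + slope * z +
  noise * e_h, with the intercepts a_h solved (quadrature + root bracketing)
  so the population means hit the published horizon values 0.099 / 0.134,
  and (slope, noise) calibrated by Monte-Carlo bisection so that
  corr(z, mean eps) hits the target link (default 0.26) within 0.02 while
  the total logit sd stays at `epsilon_logit_sd`.
* eta and sigma0 are log-normal around their published means
  (1.919 / 2.884 and 1.085 / 1.186); Q0 ~ N(5, 0.5).
* Short/long values of each parameter are correlated 0.7 within participant
  (they are fitted separately but co-vary across people).
* Age ~ N(38, 12) (clipped at 18) and IQ ~ N(9, 3) each correlate -0.1 with
  the trait, so partial-correlation code paths are exercised non-trivially.

Population dispersions (logit-eps sd 0.7, log-eta sd 0.4, log-sigma0 sd
0.25, Q0 sd 0.5) are this package's own choices of a plausible
individual-differences spread; the deposited data, not the text, would pin
them down. What the generator does **not** emulate: reaction times,
questionnaire item structure, attention checks, learning or fatigue across
blocks, and any misspecification of the choice model itself — passing
recovery tests therefore show that the pipeline is correct and well-powered
under the assumed generative family, not that the model family is right for
real humans.

## Statistics

* Paired comparisons: Shapiro test on the differences at alpha = 0.05 gates
  paired t vs Wilcoxon signed-rank (the gate level is this package's choice;
  the study names the gate, not its level). Effect sizes: Cohen's d =
  mean(diff)/sd(diff), or Wilcoxon r = |Z|/sqrt(N) with Z from the
  normal approximation with tie correction and N = non-zero pairs; zero
  differences are discarded (wilcox convention — documented because the V
  statistic depends on it).
* Partial correlation: residualize both variables on the covariates (with
  intercept) and correlate the residuals; df = n - 2 - k with a `df_extra`
  knob for alternative published df conventions.
* Repeated-measures ANOVA with 2 within-levels and a continuous
  between-participant score: exact sum/difference decomposition — between
  effect = slope of participant means on the (centered) score, horizon main
  effect = intercept of the long-short differences, interaction = slope of
  the differences; eta_p^2 = SS_eff/(SS_eff + SS_err). Exactness for two
  within-levels is verified against a long-format least-squares oracle.
* Power analysis by simulation, as in the study's design: bivariate-normal
  samples for correlation designs, unit-sd difference scores for paired
  designs, two-sided tests at alpha = 0.05, default 10,000 (acceptance:
  100,000) replicates. `minimal_n` bisects the simulated power curve with a
  fixed seed per curve (common random numbers) so the curve is effectively
  monotone.

## Problem sizes and numerical choices

The recovery analyses in the test suite use the sizes the registered design
prescribes where feasible and scaled-down versions elsewhere, chosen as this
package's own balance of precision against desk-scale compute: parameter
recovery at 100 (spread epsilon) and 50 (horizon ordering) simulated
participants with full 400-trial sessions; model recovery at 20 simulations
per generating model against the full 16-model zoo; the trait-link
end-to-end analysis at N = 200 with the null calibration at 200 replicate
cohorts of 30 participants and 30 trials per horizon (type-I calibration
does not depend on the trial count); the directional horizon battery at the
study's full N = 580. Degenerate inputs (all-zero paired differences,
constant between-scores, participants with no expected-value entry in a
horizon) are flagged or dropped pairwise rather than silently propagated.

## Known limitations

* Thompson probabilities assume independent Gaussian posteriors (true under
  the conjugate belief model).
* The eps-greedy-on-means baseline has a piecewise-constant likelihood in
  (Q0, sigma0); its fits rely on the multi-start rather than gradient
  information.
* The published 16-model list, prior choices, and partial-correlation df
  bookkeeping are supplementary details not available to this
  implementation; the package's choices are documented above and exposed as
  configuration.
* `read_sessions` reconstructs sessions from the documented CSV schema; the
  deposited raw-data schemas would need a column-mapping layer (supported in
  principle, never required by the tests).
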