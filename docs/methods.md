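# Methods

`rarecomp` supports facility-level safety comparisons in which a small
"treatment" arm (rural surgical/obstetrical facilities) is compared to a
much larger "control" arm (referral centres) on *rare* adverse-event
outcomes. Four statistical ingredients interact: penalized logistic
regression that survives separation, noninferiority testing with a
principled margin, risk stratification with E-value sensitivity analysis,
and a simulation-based power engine. This note records the models, the
defaults and why, the numerical choices, and what the synthetic cohorts do
and do not emulate.

## The regression engines

The outcome model is logistic: for visit $i$ with arm indicator $x_i$
(rural = 1) and covariates $z_i$,

$$\operatorname{logit} \Pr(Y_i = 1) = \beta_0 + \beta_1 x_i + \gamma' z_i ,$$

so $e^{\beta_1}$ is the adjusted odds ratio of an adverse event at a rural
versus referral facility.

**Maximum likelihood.** Newton iteration (equivalently IRLS) on the
binomial log-likelihood. With rare events and an arm imbalance of 5–20%
rural, complete or quasi-separation is a practical risk: the MLE then
does not exist and the iteration diverges along a direction of the
parameter space. The engine flags separation when any non-intercept
coefficient exceeds 15 in absolute value (an odds ratio beyond $e^{15}$
has no epidemiological reading and, empirically, Newton's score converges
by likelihood-tail underflow near $|\beta| \approx 38$ under complete
separation — a norm threshold of $10^3$ is never reached within a bounded
iteration count) or when every working weight $\pi_i(1-\pi_i)$ falls below
$10^{-6}$ (all fitted probabilities pinned at 0/1, i.e. perfect
prediction). A flagged fit reports the last iterate with
`converged=False`.

**Firth penalty.** The Firth engine maximizes
$\ell^*(\beta) = \ell(\beta) + \tfrac12 \log \det I(\beta)$ with
$I(\beta) = X' W X$ — the Jeffreys-prior penalty. The modified score is

$$U^*_r(\beta) = \sum_i \bigl( y_i - \pi_i + h_i(\tfrac12 - \pi_i) \bigr) x_{ir},$$

with $h_i$ the hat diagonal of the weighted design. The estimate is finite
for every dataset (all-events, no-events, complete separation) and
bias-reduced for rare events. Newton steps use the unpenalized information
as the Hessian approximation, with step-halving whenever a step fails to
increase $\ell^*$. Convergence: max |score| < 1e-8 or max coefficient
change < 1e-8, at most 100 iterations. Warm starts (marginal
Haldane-smoothed log-odds for the intercept; the unconstrained solution
for constrained refits) roughly halve iteration counts and change nothing
else.

Closed-form anchors used as test oracles: intercept-only Firth gives event
probability $(k + \tfrac12)/(n + 1)$; a single binary covariate gives the
Haldane-corrected log odds ratio
$\log\frac{(a+\frac12)(d+\frac12)}{(b+\frac12)(c+\frac12)}$. Both are
checked to 1e-6, alongside direct grid maximization of $\ell^*$ and
statsmodels' Logit for the MLE engine.

**Tests on one coefficient.** Wald: $z = (\hat\beta - \beta_0)/\mathrm{SE}$
with a normal reference (SEs from the inverse information at the
optimum). Penalized likelihood ratio:
$\Lambda = 2\{\ell^*(\hat\beta) - \ell^*(\tilde\beta)\}$ where
$\tilde\beta$ maximizes $\ell^*$ with the named coefficient held fixed
(implemented as an offset; the penalty keeps the *full* design's
information, including the fixed column — conventions differ between
implementations, so this one is stated explicitly and pinned by a
grid-search oracle in the tests). Two-sided p-values use $\chi^2_1$;
one-sided p-values use the signed root
$r = \operatorname{sign}(\hat\beta - \beta_0)\sqrt{\Lambda}$ against a
normal reference, i.e. half the two-sided p on the side of the
alternative. The signed-root convention is what makes a one-sided
likelihood-ratio noninferiority test on the Firth coefficient possible.

## Noninferiority

Superiority tests cannot establish that rural care is *as safe*; the
noninferiority null is $H_0: \tau_t - \tau_c \ge \delta$ against
$H_1: \tau_t - \tau_c < \delta$ for arm event proportions $\tau$.

**Margin.** $\delta$ is half the 95% margin of error of the observed
control-minus-treatment difference (Wald form:
$m = 1.96\sqrt{\tau_t(1-\tau_t)/n_t + \tau_c(1-\tau_c)/n_c}$, so
$\delta = m/2$); a reported "$\pm m$" can be supplied directly. The
symmetric Wald interval is used deliberately — the rule is defined on the
"±" margin of error — rather than Newcombe/score intervals. A difference
of 0.3% ± 0.1% therefore selects $\delta$ = 0.05%.

**On the odds-ratio scale.** The proportion margin is carried onto the
log-odds scale through the control proportion:
$\delta_{\mathrm{logOR}} = \log \frac{(\tau_c+\delta)/(1-\tau_c-\delta)}{\tau_c/(1-\tau_c)}$,
the log odds ratio of lifting the control rate by $\delta$. This is one
defensible mapping (it is exact when covariates are null and approximately
collapsible for rare outcomes); it is a package convention, stated here
because no single standard exists. The adjusted-OR test is then a
one-sided test of $H_0: \beta_1 \ge \delta_{\mathrm{logOR}}$ — Wald for
the MLE engine, signed-root penalized LRT for the Firth engine. The
default one-sided level is 0.025 (clinical-trial convention),
configurable. $\delta = 0$ degenerates, by construction and by test, to
the ordinary one-sided superiority test.

## Risk stratification and E-values

Comorbidity gradings are built from coded diagnoses that overlap the
adverse events themselves, so the package never adjusts for comorbidity
level inside the outcome model. It stratifies instead: five *cumulative*
strata, subset($k$) = visits with comorbidity level ≤ $k$, subset(4) the
full cohort. Profiles report per-arm sample sizes, event proportions,
covariate means/SDs or proportions, and (when individual indicator
columns are present) per-event proportions, so that the rarer low-risk
strata are visible in any power budgeting.

E-values quantify unmeasured confounding: for a risk ratio
$\mathrm{RR} \ge 1$, $E = \mathrm{RR} + \sqrt{\mathrm{RR}(\mathrm{RR}-1)}$
(reciprocal first when RR < 1). With outcomes all below a few percent the
adjusted OR is identified with RR (the default); a $\sqrt{\mathrm{OR}}$
conversion is available for common outcomes. The CI E-value uses the
limit closer to 1 and is 1 when the interval crosses 1.

## Synthetic cohorts

A scenario preset fixes the study conditions: total visits, rural
fraction, and per-arm event proportions, taken from the built-in tables
for hernia repair, appendectomy, colonoscopy and cesarean delivery across
the five cumulative comorbidity strata, or supplied by the user.
Simulation draws the two arms separately: the arm split is the
*deterministic* rounding $n_r = \operatorname{round}(f\,n)$ (volumes are
population quantities; a binomial draw would only add Monte Carlo
variance), events are per-row Bernoulli with the arm's proportion, and
covariates are drawn independently of the outcome — **null covariates**.
The facility effect is therefore entirely in the two proportions, which
is exactly the hypothesis the power analysis entertains.

Default covariate marginals are package choices (the scenario tables do
not pin them): age normal with procedure-typical mean/SD (e.g. 35 ± 18
for appendectomy, 60 ± 12 for colonoscopy), income decile N(5.5, 2.8²),
sex and laparoscopy Bernoulli, gravidity approximated N(2, 1.2²),
emergency cesarean Bernoulli(0.4). Because the covariates are null, power
is insensitive to these values — a property the suite verifies by moving
them and comparing. Cesarean designs exclude sex (constant column). The
simulated `comorbidity_level` column is a uniform label over 0..cl_max
for stratification plumbing; the stratum is already fixed by the preset.

What the generator does *not* emulate: covariate–outcome association,
within-hospital clustering, coding variation between facilities, repeat
visits per patient, or event-severity differences. Green tests show the
inferential machinery is correct under the stated sampling model, not
that real administrative data meet that model.

Adverse-event derivation from coded visits is separate from simulation: an
event fires for an index visit iff any visit of the same patient dated
within [index, index + 30] days (both ends inclusive; day-0 codes can be
excluded by flag) carries a code matching an event's code-prefix set.
Code sets are user-supplied; none are bundled.

## The power engine

For each replication: simulate a cohort, fit `event ~ arm + covariates`,
test the arm coefficient against zero — two-sided Wald for MLE, two-sided
penalized LRT for Firth — and count p < α (default 0.05). Power is the
rejection fraction; its binomial SE is always reported. Failed MLE fits
(single-class outcome, separation, non-convergence) count as
*non-rejections* and are tallied in `failed_fits`: discarding them would
condition on an outcome of the data and bias power upward. Replication
seeds derive from the root seed independently of engine, so engine
comparisons are paired on identical cohorts.

The minimum-n search doubles from the low end of the grid (default
1000–100,000) until the target power (default 0.8) is reached, then
bisects the bracketing pair to a resolution of 10 — the granularity at
which the scenario tables quote minimum n. Monotonicity of power in n is
assumed; coarse-grid decreases beyond 3 pooled MC SEs are warned about.
If the grid's upper end falls short the result is the ">grid_hi"
sentinel. Per-point seeds are a deterministic function of (root seed, n),
so the search path cannot perturb results.

Problem sizes in the shipped tests and acceptance script: 1000
replications at the available n for the headline power values (binomial
SE ≤ 0.016), 200 replications for the ~52,000-visit colonoscopy scenario,
and 250–300 replications per grid point for minimum-n searches — sizes at
which every reported comparison has its Monte Carlo error stated
alongside. Unit tests run far smaller configurations chosen to exercise
invariants, not to estimate power precisely.

## Known limitations

- No hierarchical/random-intercept models: between-hospital heterogeneity
  within an arm is out of scope.
- Wald confidence intervals only; no profile-penalized-likelihood CIs, no
  exact or score-based (Farrington–Manning) noninferiority variants.
- The proportion-to-log-OR margin mapping is a convention (above); other
  mappings would shift the margin slightly for strongly prognostic
  covariates.
- The combined any-event indicator ignores event severity; per-event
  proportions should always accompany it.
- Comorbidity level is an input column; deriving it from raw codes is a
  proprietary grouping and is not attempted.
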