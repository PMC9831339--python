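# Methods

## Task design

Each trial presents 8 beads drawn from a hidden box whose majority:minority
color ratio is 51:49, 60:40 or 90:10; the observer reports 9 probability
estimates (one before the first bead, one after each draw) and a final
binary box choice. Beads are coded 1 = majority color (the color of the
true hidden box) and 0 = minority; the displayed color is assigned at
random per trial and carried as a presentation attribute.

Evidence order is summarized by the signed evidence asymmetry, the dot
product of the 0/1 bead vector with [-3.5, -2.5, -1.5, -0.5, 0.5, 1.5, 2.5,
3.5]: negative when majority beads are front-loaded, positive when
back-loaded, zero for balanced sequences (the weights sum to zero, so the
all-majority sequence scores 0). Sequences are organized as mirror-opposite
pairs — same ratio, same bead count, reversed order, hence equal and
opposite asymmetry — so that final-estimate differences between pair
members isolate order effects.

A generated design has 55 trials in five 11-trial blocks with fixed ratio
order (60:40, 90:10, 51:49, 60:40, 90:10) and 26 distinct sequences: a
shared set of 16 (7 mirror pairs + the all-majority sequence + one
6-majority palindrome) appearing in both the 60:40 and 90:10 conditions, 6
unique to 60:40 (3 pairs), 4 unique to 51:49 (2 pairs), none unique to
90:10. The 51:49 block reuses 3 shared pairs and the shared palindrome.
The all-majority sequence is repeated 7 times in 90:10 — the single
repeated sequence, flagged so analyses can average over its repeats.
Majority-bead counts are drawn from per-set ranges (shared: 5–7, 60:40
unique: 3–5, 51:49 unique: 4–5) so each condition's count distribution is
close to what random draws from its box would produce; exact simultaneous
matching for a sequence set shared between a 60:40 and a 90:10 box is
impossible, so the shared set compromises between the two binomial means.
Within blocks, sequence order, block split and colors are seeded
random draws; the same seed reproduces the same design bit for bit.

## Belief-updating models

The weighted Bayesian model updates in log-odds space,
`logit(post) = ω1·logit(prior) + ω2(l)·s·LLR(l)`, where s = ±1 is the bead's
color relative to the true box and LLR(l) = ln(majority/minority) is the
per-bead evidence strength (0.04, 0.405, 2.197 for the three ratios). The
prior on draw d is the posterior after draw d−1. ω1 < 1 yields geometric
discounting of older evidence (final logit = Σ ω1^(8−d)·ω2·s_d·LLR), hence
recency bias and prior-dependent updating; ω1 = ω2 = 1 is the path-
independent ideal observer. The compared family crosses {ω1 fixed at 1,
free} × {ω2 absent, shared, condition-wise} (six variants, 0–4 free
parameters; the four-parameter ω1 + 3·ω2(l) variant is the winning model in
this literature) plus two heuristic non-updating references: report fixed
certainty c toward the last bead's color (no-prior) or toward the modal
color so far (observed-proportion; exact ties → 0.5). The heuristics carry
a single fitted certainty c ∈ (0.5, 1), shared across conditions. The
family is declared in a YAML registry (`variants.yaml`) and is extensible.

Reported probabilities are clipped to [0.001, 0.999], mirroring a slider
with 0.1% resolution; raw log-odds are retained internally and model
predictions are clipped identically so fits compare like with like.

## Noisy-sampling model

The agent represents the log-odds of prior and likelihood with additive
zero-mean Gaussian noise (variances σ²_prior, σ²_likelihood(l)), while the
environment distribution of those log-odds has variances ω²_prior,
ω²_likelihood(l). Optimal inference shrinks a noisy representation r by
γ = ω²/(ω²+σ²), leaving conditional variance Σ² = ω²σ²/(ω²+σ²); converting
the Gaussian belief over log-odds to a reportable probability divides the
mean by a correction ρ = 1 + (3/π²)·Σ² ≥ 1. The net update weight is γ/ρ
and the transmitted response noise has variance (γσ/ρ)². The deterministic
part is therefore *exactly* the weighted Bayesian model with ω1 = γp/ρp and
ω2(l) = γl(l)/ρl(l); sampled posteriors additionally carry the summed
response noise and are propagated as the next draw's prior.

Two numerical notes:

* The correction ρ approximates the logistic-Gaussian integral
  ∫ logistic(z)·N(z; γr, Σ²) dz. Both the linear form (default) and a
  square-root variant `rho_form="sqrt"` bracket the exact integral (linear
  errs low, sqrt errs high; both within ~6% relative error for Σ² ≤ 0.6);
  `logistic_gaussian_integral` provides the exact quadrature used to
  validate whichever form is configured.
* The transmitted noise (γσ/ρ)² is *not* monotone in σ²: it rises while
  σ² ≲ ω² and falls again as full discounting (γ → 0) silences the noisy
  channel. A consequence explored below is that the agent's response
  variability is nearly invariant to σ²_prior.

Fitting fixes the four ω² parameters (group-level grid search over the full
4-dimensional product grid, selecting the lowest pooled BIC; the default
single-point "grid" uses the selected values ω²_prior = ω²_51 = ω²_60 = 0.2,
ω²_90 = 0.6) and estimates the four σ² per participant by RMSE on the
deterministic mean prediction — the noise realization is never part of the
objective.

## Fitting and model comparison

Models are fitted per participant by bounded L-BFGS-B minimization of the
RMSE between predicted and reported post-draw probabilities (8 per trial;
the pre-draw estimate defines each trial's starting prior; trials ending in
an incorrect choice are excluded). Bounds are [0, 20] with uniform random
restarts (100 by default; reduced counts are used in the test suite's
simulation studies) and the lowest-RMSE restart wins, ties broken by the
lexicographically smallest parameter vector. BIC = n·ln(Σerr²/n) + l·ln(n)
with Σerr² floored at 10⁻¹²·n so degenerate perfect fits stay finite.

Group-level selection treats each participant's model identity as a random
effect: log evidences ≈ −BIC/2 enter a variational Dirichlet scheme whose
posterior yields expected model frequencies and exceedance probabilities
(via Monte Carlo over the Dirichlet); the Bayes omnibus risk compares the
free energy of this model against the null of equal frequencies, and the
protected exceedance probability is PXP = (1−BOR)·EP + BOR/K.

Participant screens run in order: (i) mean response time above 350 ms when
response times exist; (ii) at least 15 of 22 correct final choices in each
of the 60:40 and 90:10 conditions (the binomial bound at 68%); (iii) the
random-estimates regression — estimates on slider cursor start and ideal
Bayesian estimate, exclusion iff the cursor coefficient is significant at
α = 0.05 and the Bayesian one is not; (iv) exclusion when a heuristic model
wins the individual BIC comparison on the 60:40/90:10 data (51:49 evidence
is too weak to discriminate heuristics from updating).

## Model-agnostic measures

* **Mean final estimate difference**: back-loaded minus front-loaded final
  estimate per mirror pair (both members correct), averaged. Palindromic
  sequences are their own mirror and are skipped; the repeated sequence's
  estimates are averaged into one pseudo-trial first.
* **Evidence asymmetry slope**: OLS slope (with intercept) of pair
  differences on |asymmetry|, pooled across conditions.
* **Prior-dependent updating slope**: OLS slope of the signed logit update
  on the signed logit prior with condition intercepts. The condition
  adjustment matters: evidence strength sets both the typical prior
  magnitude and the constant update size, so pooling without it confounds
  the between-condition trend with the within-condition effect; with it the
  ideal observer's slope is exactly 0, underweighting gives negative and
  overweighting positive slopes. Saturated reports (at the slider bounds)
  and estimates of exactly 0/1 are dropped as uninformative in log-odds.
* **Response variance**: for every prefix (length 1–8) identical in
  condition and displayed bead colors, across retained trials, with ≥3
  instantiations, the sample variance (n−1) of the terminal logit estimate
  in a fixed color frame (p(blue box), so instantiations from different
  hidden boxes are comparable); median over fragments per condition, mean
  of condition medians. With homogeneous late noise of variance σ² the
  measure averages ≈ 0.83·σ² — the attenuation reflects the median over
  many small-sample (often 3-instance) fragment variances, whose
  distribution is left-skewed — and is proportional across σ², which is
  what the correlational analyses need.

Nonparametric inference uses the Wilcoxon signed-rank and rank-sum tests,
Cliff's δ = P(x>y) − P(x<y), Spearman correlation, and a partial Spearman
(rank-transform, residualize on the covariate ranks, Pearson on residuals).

## Synthetic cohorts

The generator stands in for participant data and defines the conditions all
simulation studies run under. Each participant gets an own seeded design
instance and an agent:

* Weighted-Bayesian population: ω1 ~ N(0.92, 0.08) truncated to [0, 1.3] —
  mild average underweighting with most values above 0.75 — and
  ω2(60:40) ~ N(0.51, 0.18) truncated positive, scaled ×3.0 for 51:49 and
  ×0.6 for 90:10 (weak evidence overweighted, strong underweighted, the
  ordering reported for fitted likelihood weights in this task family).
* Noisy-sampling population: σ²_prior ~ N(0.015, 0.01) truncated to
  [5·10⁻⁴, 0.06] and σ²_likelihood(l) ~ N(m_l, 0.5·m_l) with m =
  (0.05, 0.18, 1.2), calibrated so the implied weights match the
  weighted-Bayes population above (ω1 ∈ [0.77, 1.0], ω2(60:40) ≈ 0.5,
  ω2(90:10) ≈ 0.3) at the fixed environment variances.
* Response level: "late" Gaussian noise (SD 0.3 in log-odds by default) is
  added to reported estimates only and never propagates into subsequent
  priors; final choices follow the sign of the final internal log-odds with
  a 1.5% lapse rate, matching the typical wrong-choice exclusion rate.
  Slider cursor starts are uniform, so the random-estimates screen can run
  on synthetic data.
* Questionnaires: PDI global scores follow a truncated exponential
  (scale 55, range 0–336, matching published norms of roughly mean 59 and
  heavy right tail) linked to ω1 through a Gaussian copula on ranks with
  target Spearman −0.25 by default; a two-group variant samples high/low
  PDI groups with an ω1 shift of 0.044, which corresponds to Cliff's
  δ ≈ 0.30 for normal populations with SD 0.08. Paranoia Checklist
  frequency scores are copula-linked to PDI (ρ ≈ 0.8).

One population assumption deserves emphasis. For pure noisy-sampling
agents, simulated fragment-matched response variance turns out to be nearly
invariant to σ²_prior: the optimal shrinkage damps accumulated noise at
almost exactly the rate fresh noise is injected (trajectory variance after
d draws is Σ_k ω1^{2k}·ε², and both ε² and 1−ω1² scale with σ² in the
relevant range). Rational compensation, in other words, hides internal
noise from this observable. The empirically observed positive covariation
between prior noise and response variance therefore has to enter the
synthetic population through the response channel: when
`late_noise_coupling` is set, a participant's late-noise variance is
coupling·σ²_prior — individuals with imprecise internal representations
also report more noisily. With coupling 2.0 a 200-participant cohort shows
σ²_prior–response-variance rank correlations around +0.25, close to
reported values, while leaving ω1 recovery unbiased (late noise does not
bias the fits; see below). Cohorts without the coupling are available for
studying the pure model.

What passing tests on these cohorts show — and do not show: they establish
that the pipeline recovers the structure it simulates under realistic noise
levels, trial counts and population spreads; they cannot establish that
real participants follow these generative laws, and features of real data
such as response times, learning across blocks, item-level questionnaire
structure, or non-Gaussian report noise are not emulated.

## Parameter recovery and the matched-noise range

Recovery agents draw parameters uniformly between the 10th and 90th
percentile of a fitted population, simulate the task, receive late noise at
each grid level (keeping their parameters across levels), and are refitted
with the standard pipeline; the report is the percent deviation
100·(recovered−true)/true per parameter. The noise range "matching" a
cohort is found by bootstrapping (1000 resamples by default) a 95% CI for
the cohort's group-median response variance and keeping the noise levels
whose simulated mean-of-medians (10 sets of agents by default) falls inside
it. Because simulated response variance rises steeply (≈ 0.83·SD²) while
the CI of a median over a homogeneous cohort is only a few percent wide, a
coarse grid can straddle the interval; an optional second pass rescans a
finer grid between the bracketing levels. Within the matched range the mean
percent deviation of ω1 stays within ±10% — late response noise inflates
fit scatter but does not masquerade as base-rate neglect, which is the
argument for trusting fitted ω1 in noisy data. Poorly identified parameters
(notably ω2(90:10), whose predictions saturate) degrade faster at high
noise.

Problem sizes in the shipped test suite are scaled to keep the full run in
minutes: recovery uses 50 agents × 20 restarts, model recovery 50
participants × 8 models × 10 restarts, and the headline-correlation cohort
200 participants with 10 restarts; the defaults in the library (100
restarts, 10 sets × 267 agents) match the study-scale procedure.

## Questionnaires

PDI: 21 items, each endorsed yes/no; endorsed items add 1 + distress +
preoccupation + conviction (each 1–5), so items score 0 or 4–16 and the
global score spans 0–336. Group cutoffs recompute from published norms
(58.9 ± 48.0): high > 82.9, low < 34.9, strict inequalities. Paranoia
Checklist: 18 items × three 1–5 sub-scales; the frequency total drives the
secondary cutoffs (> 17.15 / < 6.65), taken as given constants. Note that
with a 1–5 frequency scale the minimum total is 18, so the low cutoff is
only reachable for instruments scored from 0; the screen is exposed as a
pure threshold function so either convention can be fed to it.

## Known limitations

* The design generator reproduces the stated composition constraints, not
  the study's literal sequence list; majority-count distribution matching
  is approximate by necessity.
* RMSE fitting treats all estimates as equally informative; no trial-level
  likelihood model (and hence no hierarchical fitting) is provided.
* The volatility-based account of prior underweighting is out of scope and
  present only as this documented stub: under perceived environmental
  volatility an optimal agent also discounts its prior near inferred change
  points, but in this stable task the account adds parameters without
  distinct predictions for the measures computed here, and no
  implementation is included.
* The exceedance probability uses Monte Carlo rather than closed forms
  (exact only for K = 2), and the group BIC of the noisy-sampling grid
  search counts 4 free parameters per participant, treating the grid point
  itself as cost-free.
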