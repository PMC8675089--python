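# Methods

## Utility model and choice rule

Player B's utility integrates guilt aversion and inequity aversion.  With
belief `τ` and payoffs `(x_A, x_B)` for Cooperate, `(y_A, y_B)` for Defect:

    u_B(Cooperate) = x_B − α·|x_A − x_B|
    u_B(Defect)    = y_B − γ·τ·(x_A − y_A) − α·|y_A − y_B|

`τ·(x_A − y_A)` is the shortfall B believes A expects to suffer if B
defects; it is non-negative whenever the trust ordering `y_A < z_A < x_A`
holds, so `γ ≥ 0` is an aversion.  Choice is softmax with inverse
temperature fixed at 1 (the conventional identification choice when payoffs
carry the scale; the per-yen β coefficients absorb the temperature).  The
utility difference expands exactly into the linear index
`β0 + β1·Reward + β2·Guilt + β3·Inequity` with `β1` the reward weight,
`β2 = γ`, `β3 = α`; a property test verifies the two formulations agree to
machine precision on random trials.

The 10-model space crosses {with, without} Guilt against {no inequity,
combined |·| inequity, advantageous only, disadvantageous only, both split
terms}, always keeping Reward and an intercept.  Split terms are oriented
so positive values mean Defect produces more of that inequity type, making
every coefficient interpretable as an aversion with expected positive sign,
and so the identity `Inequity = Ip + In` holds exactly.

## Trial-design generation

The canonical design has 45 trials with belief frequencies
{0.60: 7, 0.70: 5, 0.80: 13, 0.90: 11, 1.00: 9}, all payoffs integer
multiples of 10 yen in [100, 1000], both payoff orderings per trial, and a
maximum absolute pairwise Pearson correlation among Reward/Guilt/Inequity
below 0.30.  The default generator is rejection sampling (about 80% of
random draws already satisfy the 0.30 constraint; the error path reports
the best correlation achieved when a tighter threshold exhausts the
budget).  Beliefs are stored as fractions in [0, 1], matching their role as
probabilities in the utility formula.  Trial presentation order is
randomized per participant by the cohort generator, not stored in the
design.

A second mode, `method="exchange"`, exists for model-discrimination
studies.  Random payoff tables leave the combined-inequity model nearly
collinear with its split-term rivals (the |·| kinks rarely activate with
opposite signs) and Guilt partially correlated with the advantageous split
term, so 45 choices cannot reliably distinguish the generating model from
same-size rivals.  The exchange mode runs a single-trial simulated
annealer that (i) enforces the 0.30 constraint plus a 0.35 bound on
reward/guilt correlations with the split terms, and (ii) maximizes a local
T-optimality-style criterion: the smallest weighted-residual likelihood gap
between the generating model and each one-term rival, with logistic weights
evaluated at reference effect sizes (γ, α, reward weight) =
(0.030, 0.015, 0.005).  This raises per-participant selection accuracy
from roughly chance-among-rivals (~50%) to ~85–90% in simulation.

## Synthetic cohorts

The generator emulates the study conditions so every downstream stage can
be validated against known ground truth:

* **Sensitivities.** `γ` and `α` are log-normal (positivity; sex shifts are
  multiplicative).  Defaults: female `γ` median 0.0020 with the male median
  double that (see mediation below), `σ_log = 0.7`; `α` medians 0.0018
  (men) / 0.0036 (women), `σ_log = 0.7`; reward weight log-normal around
  0.003 per yen (`σ_log = 0.3`); intercept Normal(−0.2, 0.3).  The scales
  sit on the order-1e-3 per-yen range where yen-denominated logistic
  fits of this game land; the
  factor-2 sex shift gives a Welch contrast on fitted `β(Guilt)` at 26+26
  that is significant in roughly half to three-quarters of cohorts —
  deliberate moderate power, matching the borderline significance such a
  sample produces — while 200 participants at 450 trials recover `γ` with
  rank correlation above 0.9.
* **Mediator.** A scalar "connectivity" surrogate `M = a·male + ε`,
  `ε ~ N(0, 0.5²)`, `a = 1`.  Log guilt sensitivity is composed as
  `log γ = log(base) + b·M + c′·male + …` with defaults `b = ln 2`,
  `c′ = 0`: the entire sex difference in `γ` flows through `M` (complete
  mediation), and `a·b = ln 2` yields the factor-2 median shift.
* **Covariates.** Big Five and socioeconomic items are Gaussian with
  per-sex means/SDs typical of a large adult online sample (built-in
  defaults); ordinal items are rounded and floored at 0 but otherwise
  unmodelled (only their regression roles matter).
  Agreeableness raises `log γ` in both sexes (default 0.15 per SD) and
  Conscientiousness in men only (0.25 per SD), giving the
  covariate-interaction regression known signals to recover.
* **Questionnaire.** Three ordinal items (1–5) from a Gaussian copula with
  latent correlation 0.4 to standardized `log γ`, thresholded at normal
  quintiles.  Five-level discretization attenuates the observable rank
  correlation slightly below the latent target.
* **Strong-effects preset** (`strong_effects_config`): homogeneous large
  sensitivities (γ 0.030, α 0.015, reward weight 0.005, `σ_log = 0.2`) with
  an intercept that cancels the mean log-odds.  Without centering, strong
  effects saturate choices and destroy the information needed for model
  discrimination; with it, each component moves the log-odds by more than
  one SD while choices stay stochastic.

What the generator does **not** emulate: trial-order or learning effects,
belief heterogeneity (τ is experimenter-fixed), non-linear guilt responses
(e.g. inverted-U in τ), ordinal measurement structure of SES items, and
any real connectivity dynamics — the mediator is a scalar stand-in.
Passing tests therefore show the *machinery* is correct and calibrated,
not that real populations obey these distributions.

## Estimation

Firth's bias-reduced logistic regression maximizes
`ℓ(β) + ½·log det I(β)` via Newton/IRLS with the hat-value-corrected score
`U*_j = Σ_i (y_i − π_i + h_i(½ − π_i)) x_ij` and step-halving to keep the
penalized objective monotone.  Convergence: relative penalized-likelihood
change < 1e-8, max 100 iterations; non-convergence is flagged on the
result, never raised.  Estimates stay finite under complete separation,
which matters because saturated participants (cooperation rate near 0 or
1) are common at realistic sensitivities.  Plain MLE shares the same IRLS
path without the penalty and is cross-checked against statsmodels in the
tests.  Standard errors come from the inverse unpenalized Fisher
information at the estimate; reported log-likelihood is the unpenalized
value, so BIC = k·ln n − 2ℓ̂ and McFadden's R² = 1 − ℓ̂/ℓ̂₀ (intercept-only
closed form) are comparable across methods.

Cross-validation: each repeat draws one random equal partition of the
trials into 3 folds (remainders distributed round-robin), fits on two
folds, accumulates held-out negative log-likelihood on the third, rotating;
scores are averaged over repeats (default 500; the test profile uses
10–50).  "Bootstrap" repetition is read as repeated random partitions; a
resampling-with-replacement variant is available via
`partition="bootstrap"`.  Held-out probabilities are clipped at 1e-12 so a
saturated fit cannot contribute an infinite score.  The best model
minimizes mean predictive NLL; ties break toward fewer parameters, then
lexicographic name.

## Group inference

* **Sex contrasts**: Welch's t with Satterthwaite df (scipy), men − women
  for `β(Guilt)`, women − men for `β(Inequity)`, following the analyses'
  coding convention (men = 1 for guilt, women = 1 for inequity).
* **Questionnaire**: Pearson correlations by default (ordinal items treated
  numerically); Spearman behind a flag.
* **Covariate regression**: OLS of `β(Guilt)` on the 11 covariates plus 11
  Sex-interaction terms.  Covariates are z-scored by default so
  coefficients are comparable across scales (raw mode available); an
  intercept is included by default and the main Sex term excluded (the
  interactions already carry the sex contrast), both toggleable.  No multiplicity
  correction is applied to the 22-coefficient table by default
  (Benjamini–Hochberg can be applied downstream); adjusted R² is reported
  as computed.  A condition number above 1e8 triggers a warning naming the
  most collinear column pair.
* **Mediation**: three-variable path model estimated by OLS; the indirect
  effect `a·b` gets a case-resampling percentile bootstrap CI (default
  10,000 draws) and a two-sided bootstrap p-value; BCa (jackknife
  acceleration) behind a flag.  For linear models `c − c′ = a·b` holds
  exactly on every dataset, so testing `a·b` is testing `c − c′`; the
  three-test convention (a, b, and a·b all significant) is evaluated and
  reported.  Bootstrap resamples that lose all variation in the group
  indicator are redrawn.

## Pipeline and reproducibility

`run_pipeline` chains design → cohort → fits → model selection → group
statistics into a run directory with a JSON report, SHA-256 manifest and a
deterministic log (no wall-clock).  The master seed fans out to stages via
counter-indexed seed sequences (`SeedSequence([master, stage_index])`), so
adding a stage never perturbs earlier streams; identical config + seed
reproduce the directory byte for byte.  The interaction regression is off
by default in the pipeline (it needs hundreds of participants to be
well-posed against 23 parameters) and mediation is skipped below 10
participants.

Problem sizes used by the validation suite: 45-trial designs throughout
(450 trials only for the recovery sharpening check), cohorts of 12–600
participants, 50 CV repeats, and 200–10,000 bootstrap draws — sizes chosen
so the full suite documents every claim it makes while remaining quick to
run.

## Known limitations

* Inverse temperature is not estimable separately from the payoff scale;
  it is fixed at 1 by convention and absorbed in the β scale.
* Per-participant discrimination between combined and split inequity
  models from 45 choices is intrinsically weak on generic designs; the
  exchange design mode exists precisely because this is a property of the
  design, not the fitter.
* The mediator is a scalar surrogate; no image-based or multilevel
  mediation is attempted, and the mediation model is linear-Gaussian.
* Adjusted R² of the 22-term interaction regression can be negative on
  null-ish data; it is reported as computed.
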