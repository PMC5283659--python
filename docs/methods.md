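# Methods

## The problem being modelled

Household interview surveys under-represent people who are hard to reach,
and heavier drinkers are believed to be among them. The continuum-of-
resistance model turns the fielding paradata (number of interviewer contact
attempts before a productive interview) into a bias adjustment: sampled
adults who never responded are assumed to behave like the participants who
needed the most attempts (7+). The package simulates a survey in which that
mechanism is *true by construction*, so the adjustment's behaviour — when
it is unbiased, how it fails — can be studied quantitatively.

## Generative model

One latent **resistance** score per sampled adult,

    R = Σ loadings(demographics) + Normal(0, σ),   σ = 1 by default,

drives the whole fielding process. Demographics (sex, three age bands,
economic activity, income and deprivation quintiles, nine regions) are
drawn independently from fixed marginals; survey year is a label split into
equal thirds.

**Fielding** has two stages, reflecting that refusal and non-contact are
different phenomena:

1. *willingness*: ever cooperates with probability
   `logistic(w₀ − w₁·R)`;
2. *contact*: a willing person is interviewed on attempt *t* with
   probability `logistic(c₀ + esc·(1 − ρ^(t−1)) − c₁·R)`, capped at 18
   attempts; willing people never contacted within the cap are
   non-respondents, and only participants' attempt counts are retained
   (as in real paradata).

The rising, saturating hazard (esc > 0, 0 ≤ ρ < 1) matters: repeated calls
are increasingly appointments made after first contact, so the real
attempts distribution is *underdispersed* relative to the geometric
distribution a constant per-attempt probability would give. A constant
hazard cannot produce mean 4.44 with SD 2.84 at all — any geometric
mixture with that mean has SD above 3.3 — which is why the escalation
parameters exist.

**Interview weights** mimic a survey non-response weight by cell-based
inverse response propensity within sex × age group × region (54 cells),
rescaled to mean 1 over participants. An age cell with sampled adults but
no participants is merged with its next-older neighbour (next-younger for
the oldest band) before weighting; the collapse is logged.

**Drinking** is drawn after fielding, conditional on demographics and the
realised contact group, with non-participants assigned the hard-to-contact
(7+) group's model — this is exactly the continuum-of-resistance
assumption, so the adjustment's target is well-defined and the embedded
conditional effects are recoverable by regression on the observed group.
An optional `nonparticipant_excess` log-odds term breaks the assumption on
purpose (non-participants drinking *more* than the 7+ group) for
mis-specification experiments.

For each sex the five nested binary outcomes — drinks nowadays ⊇ drank
last week ⊇ exceeded the daily guideline ⊇ heavy episodic; exceeded the
weekly guideline ⊆ drinks nowadays — have logistic models
`logit p = α + β·demographics + γ·1[7+ group]`. A single uniform per
person is compared against the nested exceedance probabilities, so every
indicator's conditional log-odds is exactly its configured model and the
nesting can never be violated (probability orderings are clipped in the
rare numerical corner, with a log warning). Continuous variables are then
drawn *within the band the indicators fix*:

* heaviest-day units: scaled beta below the daily threshold, beta between
  daily and episodic thresholds, shifted gamma above;
* weekly units: scaled beta below the weekly threshold, shifted gamma
  above, with a slightly heavier tail for the 7+ group (the group's extra
  volume is partly within-band, not only a higher exceedance rate);
* drinking days: `1 + BetaBinomial(6, a, b)` among last-week drinkers,
  with group-specific (a, b) — the hard-to-contact drink on *fewer* days —
  the beta-binomial's overdispersion reproducing the bimodal
  weekend-vs-daily drinking pattern (SD ≈ 2 on a 1–7 scale).

Non-drinkers and non-last-week drinkers have zeros throughout, and stay in
the denominators of the exceedance indicators. Item non-response is
missing-completely-at-random at 1.2% per item among participants (a
missing drinks-nowadays screener blanks the dependent items).

## Calibration (frozen in `defaults.py`)

The packaged defaults were fitted once, in three stages, and are not
runtime-tuned:

1. resistance loadings set so the participant 7+ shares by age
   (≈24%/11% for 18–34/55+), work status and region match the published
   gradient;
2. the five fielding parameters (w₀, w₁, c₀, c₁, esc, ρ) fitted by
   Nelder-Mead on simulated moments (n = 200,000, common random numbers)
   against: response rate 58%, mean attempts 4.44, SD 2.84, weighted 7+
   share 18.8%, 90% within 8 attempts. The 7+ share is matched as a
   *weighted* share because the published table is interview-weighted; the
   attempts mean/SD and the within-8 share are unweighted over
   participant rows;
3. drinking intercepts α and per-outcome demographic scales, per sex,
   solved exactly (expectation over a large simulated participant sample,
   no Monte-Carlo noise) so that the weighted group prevalences hit the
   published values — e.g. heavy episodic 20.1%/24.3% for men and
   11.8%/17.2% for women in the 1–6/7+ groups — while the conditional
   group effects γ stay pinned at the published fully adjusted odds
   ratios (women: 1.19 daily, 1.23 heavy episodic; men: 1.12, 1.10; drinks
   nowadays 1.14 men / 0.96 women; weekly 1.09 / 1.05). The gap between
   each outcome's marginal group contrast and its conditional γ is carried
   by demographic confounding (the young, in-work and London adults who
   need more calls also drink more per occasion), which is what makes the
   unadjusted > fully-adjusted OR attenuation come out naturally.

## Estimators

* Weighted proportions/means use Σw·x/Σw; the descriptive SD is the
  population form √(Σw·(x−m)²/Σw).
* Chi-squared: Pearson on the weighted contingency table after rescaling
  weights to sum to the unweighted n, no continuity correction.
* t-test: Welch on weighted means, variance = Bessel-corrected weighted
  variance / Kish effective n ((Σw)²/Σw²); exactly the classical Welch
  test under unit weights.
* Logistic regressions: weighted ML (weights rescaled to mean 1 over the
  complete cases), factor-coded covariates, reference group 1–6 calls,
  Wald 95% CIs. Complete-case per model. Model-based SEs are used by
  design (sandwich/replicate variance is out of scope); with non-constant
  weights they understate sampling variance by roughly the weights'
  squared coefficient of variation (~2% here), so null-coverage tests use
  a 90% floor rather than the nominal 95%.
* The adjustment `p̂·r + ĥ·(1−r)` uses the overall response proportion
  r = participants / sampled adults by default (a fixed r can be supplied);
  differences and percentage changes are computed from unrounded
  intermediates and rounded only for display.

## What the generator does and does not emulate

Emulated: the fielding moments and their demographic gradients; weighted
drinking levels per sex and contact group; conditional group effects given
the full covariate set; heavier, less frequent drinking among the
hard-to-contact; item non-response at a low rate.

Not emulated: household clustering and design effects (weights are
cell-based, not a design weight), correlation between demographics (age
and work status are drawn independently), year trends, interviewer
effects, under-reporting relative to sales, 16–17-year-olds, and any
informative item non-response. Passing tests therefore demonstrate the
pipeline's correctness and the adjustment's properties *under the model*,
not the behaviour of any real survey's estimates.

## Numerical and design choices

* Boundary consumption values equal to a threshold do **not** exceed it
  (strict `>`), matching "more than X units" read literally.
* Attempts cap 18; capped-out willing people are non-respondents with no
  attempts recorded.
* One top-level seed is split deterministically per stage (population /
  fielding / drinking), so identical (config, seed) gives byte-identical
  datasets and tables.
* The 2×2 single-predictor logistic fit reproduces the contingency-table
  cross-product ratio to 1e-8 (used as an oracle in the tests).
* Full-precision CSVs are always written; markdown twins round to the
  conventional 1 decimal place with "<0.001" p-values.
* Analysis drivers use n = 44,303 (the default sample), five replicate
  seeds for calibration summaries, and n = 100,000 × 10 seeds for the
  validity simulation — sizes at which Monte-Carlo error is well below
  every tolerance checked.

## Known limitations

* The adjustment's validity simulation shows exactness only under
  exchangeability; with `nonparticipant_excess > 0` it under-corrects, and
  nothing in the data can reveal by how much — that is the model's
  fundamental, untestable assumption.
* Model-based regression SEs (see above) are slightly anti-conservative
  under non-constant weights.
* The marginal (weighted-table) odds ratio and the unadjusted model OR
  printed by `regression_table` differ whenever weights differ by group;
  both are reported so the convention gap stays visible.
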