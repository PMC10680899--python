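# Methods

`ehrisk` studies how to predict a downstream disease among patients who
already have a predisposing condition, using only longitudinal coded
health records.  The canonical instance is hepatocellular carcinoma (HCC)
risk among patients with nonalcoholic fatty liver disease (NAFLD), but
every component is generic over code vocabularies and outcome definitions.
This note records the models, the assumptions behind them, the defaults,
and what the synthetic experiments do and do not demonstrate.

## Cohort definition

A patient enters the precondition cohort on the date of their first
abnormal index-lab value, provided they have at least two abnormal values
whose first-to-last span strictly exceeds 183 days ("more than six
months").  Abnormality is sex-thresholded (ALT: > 40 IU/mL for men,
> 31 IU/mL for women).  The "more than six months" rule is read as a
condition on the overall span of abnormal values rather than on one
consecutive pair — the weaker, more inclusive reading — and is
configurable.  Exclusions are applied in a fixed order so attrition tables
are deterministic: age under 18 at index, less than five years of
post-index data, then confounder code sets (each set configurable as
"any time" or "before index"; hepatitis-like sets default to any time,
alcoholism-like sets to before index).  Ages are integer floors of
elapsed years; all internal time arithmetic is in integer days with
1 year = 365.25 days.

A separate case-control assembly supports pretraining: for each case,
`ratio` controls are sampled without replacement, matched exactly on sex
and within ±5 years of age at first encounter and ±1 year of record
duration.  The tolerances are conventions, not estimates, and are
arguments of `build_case_control`.

## Censoring-aware horizon labeling

Time-to-event outcomes are converted to a binary "event within 10 years
of index" label.  Patients censored before the horizon without an event
are *excluded*, not labeled negative — their label is undefined, and
treating them as negatives would bias any classifier trained on them.
Events within 2 years of the index are excluded as likely prevalent
rather than incident disease, and events before the index are excluded
outright.  Boundary conventions (documented, config-overridable): "within
10 years" is inclusive at the horizon, an event exactly at the 2-year gap
counts as positive, and a negative label requires strictly more than 10
years of event-free observation.

The type-I-error study (below) checks that this formulation supports
valid association tests despite the exclusions.

## Propensity matching

Labeled cohorts are heavily imbalanced and, worse, positives and negatives
differ systematically in observation pattern (an event ends the record).
Before model training, each masking group is rebalanced 1:1 by greedy
nearest-neighbour matching on the logit of a logistic propensity model
with three covariates: mean inter-encounter interval, its sample (n−1)
standard deviation, and encounter count, all standardized.  Positives are
processed in descending propensity; ties break by patient id; there is no
caliper by default.  Matching is re-run for every masking length because
the mask changes the encounter pattern the covariates are computed from.

## Backward masking

Slowly progressing diseases leave telltale codes in the record before the
formal diagnosis code appears.  To keep models from exploiting this
delayed-diagnosis leakage, all encounters within `mask_years` of the
patient's endpoint (diagnosis date for events, last encounter for
censored patients) are removed before training, over the grid
{0.5, 1, 2, 4} years.  Removal is strict: an encounter exactly at
`endpoint − mask_years` is retained, which makes masked encounter sets
nested across the grid.  Patients whose masked record becomes empty are
dropped from training with a logged count.  Retained history is measured
from the first encounter (switchable to the index date).

## The attention sequence classifier

The longitudinal model is a two-level attention recurrent classifier.
Codes are embedded in R^m and summed per encounter into visit vectors
v_i.  Two independent GRU streams of equal hidden size p process the
visit sequence most-recent-first (so recent history dominates the
recurrent state): one produces a scalar per visit, softmax-normalized
into encounter attention α; the other is projected to R^m and
tanh-bounded into variable attention β_i.  The patient context is
c = Σ_i α_i (β_i ⊙ v_i) and a two-class softmax head gives the risk
probability.  Because c is linear in the visit vectors, the
positive-class logit decomposes exactly as

    logit⁺ = b⁺ + Σ_{i,k} ω(i,k),   ω(i,k) = α_i · w⁺ · (β_i ⊙ E[code_k]),

so every code occurrence has a signed additive contribution score — this
identity is asserted to 1e-4 in the tests and is the basis of all feature
ranking.  Demographics (sex, age decade at each encounter) are injected
as ordinary codes into every visit.

Defaults: embedding 24, hidden 24, Adam at 1e-3, 25 epochs, batch 32,
sequences truncated to the most recent 128 encounters, optional
validation split with early stopping (patience 5).  The implementation is
pure NumPy in float64 with hand-written backpropagation; gradients are
finite-difference-checked in the test suite, and a fixed seed makes
training bit-reproducible.  Code dictionaries map codes to contiguous ids
with id 0 reserved for unknowns; a dictionary is built on the union of
cohorts and frozen before any pretraining so that embeddings stay aligned
during finetuning.

## The baseline survival comparator

The comparator is a feed-forward discrete-time survival network that sees
only index-date information: age, sex, the index-lab value, and presence
indicators for configured codes at or before the index.  It outputs a
probability mass function over 10+ yearly bins plus an open tail bin and
is trained on the censoring-aware first-hitting-time likelihood
(−log P(bin) for events, −log P(T beyond the censoring bin) for censored
patients; censoring past the closed bins contributes the tail mass).
It is a single-event model — death is folded into censoring — and uses
the likelihood term only, without a ranking loss.  Its 10-year risk is
the cumulative mass inside the horizon, which puts it on the same AUC
scale as the classifier.  Defaults: two hidden layers of 64 ReLU units,
Adam 1e-3, 60 epochs, features standardized internally.

Comparing the two models on identical stratified folds of the same
matched cohort isolates the value of time-varying covariates: when the
simulated hazard is driven by post-index code onsets the sequence model
wins by a wide margin, and when the hazard is fully determined at
baseline the two agree closely.

## Transfer learning

Small target cohorts (tens of positives) cannot support a sequence model
from random initialization.  The suite pretrains the full model on a
large related cohort, then finetunes *all* layers on the target's
training folds, with the shared frozen dictionary.  The paired comparison
(scratch vs. finetuned on identical folds and seeds) is summarized by the
mean AUC difference and a one-sided paired t-test for the finetuned AUCs
being larger.

## Sex-bias cross-evaluation

To measure how covariate imbalance between sexes affects performance, one
stratified fold split is shared across a train-group × test-group grid
({all, male, female} × {all, male, female}).  Each cell trains on the
train-group members of the training folds and pools held-out predictions
over the test-group members, so cells differ only in group composition,
not split noise.  With disjoint sex-specific risk codes in the generator,
cross-sex cells degrade by construction and both-sex training dominates
on mixed test data.

## Attention aggregation

Contribution scores are aggregated in two stages: mean per (patient,
code) across the encounters where the code occurs, then mean across
patients — so a patient with many occurrences does not dominate.
Encounters lacking the code contribute no record (not a zero); this is
the natural reading of "across encounters" and is switchable by adding
explicit zero records.  Codes seen in fewer than 10 patients are dropped
from cohort rankings.  The per-patient display filter keeps a code iff
any of its scores falls strictly outside the patient's pooled
[25th, 75th] percentile band (percentiles by linear interpolation); with
a degenerate band nothing is kept.

## The synthetic generator

Because the motivating data are proprietary, all experiments run on a
generator that reproduces the statistical structure the strategies
target, with full ground truth retained:

* encounters are a homogeneous Poisson process per patient, with a
  mean-preserving log-normal spread (σ = 0.8) of per-patient visit rates —
  without this heterogeneity, encounter count alone would separate the
  classes and matching would have no overlapping support to work with;
* the index lab is drawn at every encounter, abnormal with probability
  `abnormal_prob` (values uniform above the sex threshold when abnormal,
  uniform below otherwise — only the flag matters downstream);
* the event hazard lives on a yearly grid from the index date:
  logit(h_j) = logit(h0) + Σ active log-hazard-ratios, where each effect
  code is carried by half of patients, becomes active at a random onset
  (post-index by default; at baseline in the parity scenarios), appears
  in each subsequent encounter with probability 0.7, and may have
  different log-HRs per sex;
* telltale codes start appearing Exp(mean `telltale_lead_years`) before
  the diagnosis date, each with per-encounter probability 0.5, and only
  in event patients — the leakage gradient backward masking removes;
* censoring is a per-year geometric hazard truncating the planned
  observation span; an event ends the record at the diagnosis encounter;
* all randomness flows from one seed through per-patient spawned
  sub-streams, so cohorts are byte-identical across runs and independent
  of iteration order.

Scenario families fix the study conditions once: `rare_incidence_scenario`
(h0 = 2×10⁻⁴/year, the target-cohort regime of roughly 2 events per 1000
patients at 10 years), `trajectory_scenario` (post-index onsets, log-HRs
1.6/1.2/−1.2, h0 = 0.015), `telltale_scenario` (adds two telltale codes
with a 2-year mean lead), `sex_bias_scenario` (two risk codes with log-HR
2.0 in one sex and 0 in the other), and `null_scenario` (one designated
code with zero effect, baseline onsets, no censoring, 12-year spans, so
every indexed patient is labelable and exposure is measurable at the
index).  Experiments deliberately use scenarios with elevated incidence:
at the rare-incidence default a desk-scale cohort would contain too few
events to train any model, and the claims under test concern the
strategies, not the absolute event rate.

What the generator does **not** emulate: real code vocabularies and their
co-occurrence structure, visit-level correlation (care episodes,
seasonality), informative censoring, measurement drift, competing risk of
death as a distinct outcome, and coding-practice variation across sites.
Passing tests therefore show that each strategy behaves as designed when
its target structure is present — not that any particular AUC level will
be attained on real records.

## The type-I-error study

The claim under test is about the labeling formulation, not the network,
so the Monte Carlo study uses a closed-form Rao score test in a logistic
model: per replicate, a null cohort is simulated, indexed, and labeled;
the exposure is presence of the designated code at or before the index
date (baseline exposure, so the post-event truncation of records cannot
induce spurious association); the score statistic for adding the exposure
to an intercept-only model is referred to χ²₁.  Over 1000 replicates at
α = 0.05 the rejection rate must lie inside the 2-SE binomial band
[0.037, 0.063].  Replicates where the label or exposure is constant are
not evaluable and are excluded from the denominator (they are rare under
the null scenario's conditions).

## Numerical choices and problem sizes

Float64 throughout; softmax is computed with max-subtraction; masked
softmax positions are excluded exactly rather than by large negative
constants; probability clamps at 1e-12 guard the likelihoods.  Ties in
matching and aggregation break on patient id / code string so every
output is order-independent.  The integration checks run at desk scale,
chosen as the package's own defaults: n = 2000 patients (3 seeds, 5-fold)
for the time-varying-covariate comparison, n = 1500 (3 seeds, 3-fold,
reduced epochs) for the masking sweep, 1200-source/400-target for
transfer (the target holds ≲ 40 positives; the size-dependence of the
gain is checked at target sizes 400/800/1600), n = 2000 for the sex-bias
grid, 1000 replicates for the type-I study, and n = 10000 for survival
calibration.  For the 10-bin calibration check, the per-bin "within 2
standard errors" check is applied jointly: all 10 fitted hazards must
lie within 3 SE and at least 8 of 10 within 2 SE (ten simultaneous 2-SE
checks would fail by chance alone about a third of the time), plus the
10-year risk must match the closed form 1−(1−h)¹⁰ within 0.02.

## Known limitations

* The sequence model can still read residual observation-pattern signal
  (record length, visit density) that propensity matching reduces but
  does not erase; this mirrors the real-data situation and inflates
  absolute AUCs slightly relative to the code signal alone.
* The survival comparator is intentionally minimal (no competing risks,
  no ranking loss, no time-varying inputs); it is a baseline, not a
  production survival model.
* Greedy 1:1 matching discards most negatives; with few positives the
  matched cohorts are small and fold-level AUCs correspondingly noisy —
  the experiments always report means over folds and seeds.
* The CLI covers the standard pipeline; programmatic use is the primary
  interface for anything beyond it.
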