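# Methods

## The estimands

Administrative ascertainment of a comorbidity is treated as a diagnostic
test against the medical record as reference standard. For each stratum
(ICD era, Indigenous status) and lookback window the paired statuses form a
2×2 table (tp, fp, fn, tn) from which the package reports, as percentages to
one decimal (round half away from zero):

- observed agreement (tp+tn)/n, sensitivity tp/(tp+fn), specificity
  tn/(tn+fp), PPV tp/(tp+fp), NPV tn/(tn+fn);
- Cohen's κ = (p_o − p_e)/(1 − p_e), p_e = [(tp+fp)(tp+fn) +
  (fn+tn)(fp+tn)]/n²;
- net under/over-estimation (Sensitivity/PPV − 1)×100, algebraically the
  relative difference between the test-positive and reference-positive
  margins; negative values mean administrative undercounting.

Measures with empty denominators are reported as NaN and flagged, never as
zero. `ConcordanceReport.under_over` is computed from the unrounded
proportions; the standalone `under_over_estimation(sens, ppv)` operation
takes already-printed percentages, which is how published tables derive
their under/over columns (the two can differ by one unit in the last
decimal, e.g. 363/380 − 1 = −4.47% → −4.5 while 91.1/95.3 → −4.4).

Paired prevalence differences (administrative vs medical record in the same
patients) use McNemar's test, (fn−fp)²/(fn+fp) against χ²(1) without
continuity correction; below 25 discordant pairs the p-value comes from the
exact two-sided binomial. Between-era comparisons (independent samples) use
Pearson chi-square on each measure's own success/failure 2×2. For the
under/over statistic no textbook two-sample test exists; the package uses a
z on log(Sens/PPV) = log(test⁺ margin) − log(ref⁺ margin) with delta-method
variance treating the table as multinomial (the two margins are correlated
through the shared tp cell), and provides a seeded percentile bootstrap
(2,000 resamples) as a labelled cross-check. Neither construction is claimed
to be the one used in any particular published analysis. A simulation in the
test suite confirms the z-test's type-I error is ≈5% under the null.

## Ascertainment conventions

A lookback window of w years is the half-open calendar interval
[index_date − w years, index_date), with the index admission always included
via the index-only component — so status is non-decreasing in window length
by construction. Calendar arithmetic maps Feb-29 anchors to Feb-28. Window
membership uses the admission date, not the separation date. Every record is
code-matched under its own ICD version (cutover 1999-07-01): a 1997 record
in the history of an ICD-10-era index is searched for 250-codes, not
E-codes. Diabetes codes are category-prefix matches (250 / E10–E14) over the
principal plus up to 20 secondary diagnosis fields; malformed codes match
nothing and never abort the pipeline. `first_ever_chd` uses the principal
diagnosis field only, consistent with index selection; whether real-world
analyses should also consider secondary-field CHD history is a judgement
call this package leaves to the caller.

Index selection takes the earliest in-window admission with a CHD principal
diagnosis; same-day ties break on the lowest admission id, making the cohort
invariant to input row order. The ≥25% Indigenous rule is evaluated with
integer arithmetic over all supplied records (the caller controls the
history horizon). Reference diabetes is positive when documented present or
drug-treated; "not recorded" without drugs is counted as no diabetes and
flagged, and a switch drops those rows for the sensitivity analysis.

## Predictor modelling

False negatives are defined among reference-positives, false positives among
reference-negatives, both at the index-only window. Candidate covariates are
banded as in validation practice: length of stay 1–2/3–5/≥6 days, age
25–50/51–65/66–79, Charlson 0/1–4/≥5, comorbidity count 0–3/4–7/≥8 (both
excluding diabetes). Screening is Pearson chi-square, replaced by Fisher's
exact for 2×2 tables with any expected count below 5 (the conventional
rule). Variables passing the screen at p<0.05 (0.1 available as a
sensitivity entry rule) enter a maximum-likelihood logistic model as
indicator contrasts against fixed reference levels (emergency admission, no
death, ≥6-day stay, other-CHD principal diagnosis, ≥8 comorbidities, ...).
Wald 95% CIs are reported; separation or non-convergence flags the result
rather than silently emitting estimates. Age and sex are not forced into the
model when not univariably significant. When nothing passes the screen — the
expected situation for the rare false-positive outcome — no multivariable
model is fitted.

The Charlson index uses the Quan et al. (2005) ICD-9-CM/ICD-10 coding
algorithm shipped as package data, with the original Charlson weights and
the usual severity hierarchy (complicated diabetes over uncomplicated,
severe over mild liver disease, metastasis over malignancy); the diabetes
categories are excluded by default since diabetes is the condition under
validation.

## The synthetic-data generator

The generator emulates the data-generating context of a two-era linked
validation sample. Defaults (era sizes 1685 and 2258; eras 1998 and
2002–04; 16-year histories; per-admission coding sensitivity 0.91 in ICD-9
records and 0.815 in ICD-10 records; true prevalence 0.22/0.29 in
non-Indigenous and 0.45/0.56 in Indigenous patients by era; Indigenous
proportion 0.015/0.23; per-record Indigenous flagging probability 0.7) are
fixed to the study conditions the design targets. Quantities no validation
report states are free parameters set once to field-plausible values:
admission rate 0.4/person-year (×1.5 for diabetics, reflecting higher
hospitalization in diabetes), per-admission miscoding probability 0.015
(matching observed index false-positive rates of 1.3–1.8%), and a 2.5%
"not recorded" rate among non-diabetics. Prior admissions follow a
homogeneous Poisson process; a prior admission may carry a CHD principal
diagnosis only when dated outside every era window, preserving exactly one
index-eligible CHD admission per sampled era. When a diabetes code is
carried it occupies a uniformly chosen secondary field, since diabetes is a
comorbidity here. By default the medical record is an error-free reference
for diabetics (p_doc_present = 1), so concordance estimands equal the coding
parameters and parameter-recovery tests are exact; documentation error
options exist for robustness studies.

What the generator does **not** emulate: person-level correlation in
miscoding — false positives are i.i.d. per admission, so simulated
specificity declines faster with lookback than real data, where miscoding
is plausibly concentrated in borderline patients; realistic population
margins (age/sex/case-mix tables are schematic); mortality-register
records; and duplicate-person handling across overlapping sampling frames.
Passing tests therefore demonstrate correctness of the machinery and of the
closed-form relationships, not calibration to any real jurisdiction's
coding behaviour.

A closed-form oracle accompanies the generator: with per-admission coding
probability p and K prior admissions in the window, detection probability is
1−(1−p)^(K+1), so expected lookback sensitivity is Σ_k pmf(K=k)(1−(1−p)^(k+1)).
The acceptance suite checks the Monte-Carlo pipeline estimate against this
expectation at n = 20,000 within three binomial standard errors.

## Problem sizes and numerical choices

Test-suite simulations use 120–200 patients per era for structural checks,
20,000 for parameter recovery, 500 replicates for logistic CI coverage and
1,000 for oracle sweeps — sizes chosen so each statistical assertion has the
power its tolerance implies. Rounding is half-away-from-zero at one decimal
throughout reporting. All randomness flows from a single integer seed per
generator call; identical config and seed reproduce byte-identical tables,
and the pipeline writes a manifest recording the seed and per-stage
row counts (input = retained + excluded for every exclusion reason).
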