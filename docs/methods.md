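# Methods

## Problem and model

Prescription databases record antidepressant (AD) dispensations but not
symptoms, so "remission" must be approximated from prescribing behaviour. The
construct implemented here: a *new depression episode* is a new AD
prescription with no AD in the previous six months; a patient is *in
remission* when, after completing treatment of that first episode, they
require no new AD prescription for at least six months; interrupting
treatment for less than six months does not count as sustained remission.
`rxremit` turns this into a deterministic classifier and validates it against
a binary reference standard (a psychiatrist's chart review) with the standard
diagnostic-validity apparatus.

## Calendar and coverage conventions

* Day resolution throughout; month thresholds are fixed day counts
  (1 month = 30 d, so 6 months = 180 d, 18 months = 540 d). All five
  thresholds are `EpisodeCriteria` fields and can be overridden; defaults are
  washout 180 d, minimum treatment 60 d (strict `>`), follow-up 540 d
  (inclusive `≥`), remission gap 180 d (inclusive), within-episode gap 180 d.
  Strictness mirrors the construct's wording: "more than 60 days" vs "at
  least six months / 18 months".
* A dispensation covers the half-open interval
  `[dispense_date, dispense_date + days_supply)`. Overlapping supplies are
  unioned, not stockpiled: overlap days count once, which keeps coverage
  order-invariant. Coverage may extend past the observation end; covered days
  are not clipped to the window.
* Gaps are whole days between a coverage end (exclusive) and the next
  dispense date, so back-to-back refills (`end == next start`) are
  contiguous.

## Episode detection and the remission label

The index prescription is the earliest AD dispensation with (a) at least
`washout_days` elapsed since the start of observation and (b) no AD coverage
anywhere in the preceding `washout_days`. Requirement (a) makes the washout
*observed*: a patient whose record begins 30 days before their first AD
cannot demonstrate six clean months and is `NOT_EVALUABLE`
(`INSUFFICIENT_WASHOUT_OBSERVATION`) rather than assumed clean. This is
deliberately stricter than taking registry absence as absence of treatment.

Coverage segments separated by gaps shorter than `within_episode_gap_days`
are merged into one episode; a longer gap ends it. Eligibility uses the
merged episode: covered days must strictly exceed `min_treatment_days`, and
the observation window must span at least `followup_days` from the episode
start.

The remission label is anchored at the **first treatment completion** — the
end of the first contiguous coverage block, i.e. the first day the patient is
off medication:

* an AD dispensation strictly within `remission_gap_days` of that day ⇒
  `NO_REMISSION` (`RESTART_WITHIN_GAP`): the patient could only interrupt
  treatment for less than six months;
* otherwise, if the window still contains a full `remission_gap_days` after
  completion ⇒ `REMISSION` (`GAP_OBSERVED`);
* otherwise ⇒ `NOT_EVALUABLE` (`CENSORED`): the patient stopped too close to
  the end of observation for the gap to be decidable.

Anchoring at the first completion rather than the merged episode end is a
deliberate design choice: if the label were judged only at the merged end,
any restart within six months would extend the episode, the restart category
could never occur, and the three-way outcome would degenerate. Under this
convention *any* interruption followed by a restart within six months is a
failed remission, which is the literal reading of the construct; the merged
episode still governs eligibility, so treatment resumed after a short
interruption counts toward the 60-day minimum. Only the first eligible
episode per patient is labelled. A restart of exactly the gap length is
remission (inclusive "at least"); the six-month gap may coincide with the
washout of a later episode, which is out of scope for labelling.

Consequences worth knowing: classification is invariant to non-AD rows and to
input row order; extending the observation window can only turn
`NOT_EVALUABLE` into a decided label, never flip a decided one; appending a
dispensation strictly inside the post-completion gap can never create a
remission. These are enforced as property tests, alongside an independent
day-grid oracle (a boolean per-day coverage simulation that re-derives every
label by scanning) run over randomized small timelines.

## Validity statistics and CI conventions

All statistics are closed-form functions of the 2×2 table (tp, fp, fn, tn):
S, Sp, PPV, NPV, false-positive rate = 1−S, false-negative rate = 1−Sp,
PPR = S/(1−Sp) (∞ when Sp = 1, reported as infinite rather than raised),
NPR = (1−S)/Sp, κ = (P₀−Pₑ)/(1−Pₑ), φ = (tp·tn−fp·fn)/√(row×col products),
two-item Cronbach's α = 2(1 − (v₁+v₂)/v_total) with population variances,
McNemar χ² = (|fp−fn|−c)²/(fp+fn) with optional continuity correction
(0 by convention when fp+fn = 0), AUC = (S+Sp)/2. Zero-denominator statistics
are reported as undefined (`None`), never as 0. Closed forms are verified in
the test suite to 1e−12 against brute-force computation on expanded 0/1 label
vectors and against statsmodels / scikit-learn implementations.

Proportion CIs are Wald, clamped to [0, 1], in two conventions:

* **standard** (default): own denominator, full-precision estimate,
  z = Φ⁻¹(1−α/2).
* **as_published**: the convention that replicates interval estimates as
  printed in validation reports of this kind — the total sample size n in the
  SE for every statistic, the point estimate rounded to the printed 0.1%
  precision (3 decimals as a proportion) entering both the centre and the SE,
  z = 1.96, and presentation rounding half away from zero. For κ the SE is
  √(P₀(1−P₀)/n)/(1−Pₑ) with P₀ and Pₑ at printed precision around the
  unrounded κ. This mode reproduces the published interval bounds for
  specificity, PPV, NPV, the false-negative rate, κ (73.1–92.6) and the
  cohort prevalence; replication mode is a faithfulness feature, not a
  recommendation — `standard` intervals are never narrower.

Two historically printed upper bounds (sensitivity 96.9, false positives
11.9) sit exactly one rounding step below what any consistent Wald evaluation
yields (96.98 → 97.0 and 11.98 → 12.0); they are reproducible only by
truncation, which contradicts the other ten bounds, so the package reports
97.0/12.0. Similarly, a printed McNemar value of 58.1 (49.7–66.5) matches no
McNemar statistic of the table (the standard χ² is 1/11 ≈ 0.09; the printed
CI's shape suggests a transposed proportion row), and a printed AUC of 91.2
differs from (S+Sp)/2 = 91.5; the package computes the standard quantities
and does not target those two values. The more common Fleiss–Cohen–Everitt
κ ASE is available via `kappa_se="fleiss"`. Cronbach's α is reported without
a CI.

The design-stage sample size is n = ⌈z²p(1−p)/d²⌉; at p = 0.54, d = 0.085,
α = 0.05 it gives 133, the size of the validation sample.

## Synthetic cohorts

The generator emulates a primary-care AD cohort under the validated study's
conditions; defaults (fixed a priori, not tuned): true remission prevalence
0.546, classifier sensitivity 0.925 and specificity 0.906 versus the
reference, 1080-day observation windows starting within two years of
2003-01-01, index offset uniform in [180, 360] days, 2–4 contiguous
dispensations of 28–90 days' supply totalling more than 60 days, drug codes
drawn from common AD ATC codes, and an occasional non-AD dispensation (rate
0.3) to exercise the ATC filter. Patients destined to be classifier-negative
restart after a uniform 30–179 day gap (comfortably inside the 180-day
boundary); classifier-positive patients stop with at least 210 days of window
remaining (comfortably outside it). Reference labels are the simulated true
status; discordant patients carry a free-text reason sampled with the
chart-review frequencies (false positives: dysthymia ×2, recurrent
depression, adaptive disorder, vital occurrence; false negatives: dysthymia
×4, adaptive disorder, recurrent depression).

`generate_exact_table` assigns cell membership deterministically (randomizing
only dates, supplies and codes), and the test suite validates the guarantee
through the real classifier rather than by construction. `generate_cohort`
draws cell membership from the configured probabilities; parameter recovery
(mean realized Se/Sp within 1 percentage point of target over 200 cohorts of
n = 1000) is part of the test suite. All randomness flows from one seeded
`numpy` generator; the CLI records the seed in the output metadata.

What the generator does **not** emulate: drug switching and augmentation,
dosing, seasonality, age/gender stratification, fill reversals, and patients
who would fail eligibility (every synthetic patient is evaluable). Passing
tests therefore demonstrate the algorithm's and statistics' correctness under
clean, decidable timelines, not the classifier's field performance on messy
registry data — the misclassification structure is imposed, not emergent.

## Problem sizes and numerics

The exact-table replication runs at the validation sample's n = 133; cohort
simulations run at the source cohort's n = 4,572 (sub-second); parameter
recovery uses 200 replicates of n = 1,000. Oracle-equivalence tolerances are
1e−12 (closed form vs label vectors) and 1e−9 (vs third-party
implementations); presentation rounding is half away from zero, applied only
at output. Degenerate inputs (empty cohorts, all-not-evaluable summaries,
zero-variance items, empty tables) return `None`/undefined rather than
raising where a report is still meaningful, and raise `ValueError` where no
statistic exists.
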