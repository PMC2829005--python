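"""Synthetic pharmacy-claims cohorts with known remission misclassification.

The generator emulates the study conditions of a primary-care antidepressant
cohort: each patient has an observation window of about three years, a first
antidepressant episode starting after at least six observed drug-free months,
a contiguous course of 2-4 dispensations exceeding the 60-day treatment
minimum, and then either a terminal prescription-free gap of well over six
months (the classifier will call REMISSION) or a restart 30-179 days after
completing treatment (NO_REMISSION).  The chart-review reference label is the
patient's simulated true clinical status, so the index-vs-reference
misclassification structure is controlled exactly (``generate_exact_table``)
or in distribution (``generate_cohort``).

Discordant patients carry a free-text ``reason`` drawn from the clinical
causes observed in chart review (dysthymia, recurrent depression, adaptive
disorder, vital occurrence) with stratum-specific frequencies.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .io import (
    ANTIDEPRESSANT_ATC_PREFIX,
    EpisodeCriteria,
    PatientTimeline,
    Prescription,
    ReferenceAssessment,
)

__all__ = ["SyntheticConfig", "generate_cohort", "generate_exact_table"]

#: Calendar anchor for simulated observation windows.
BASE_DATE = dt.date(2003, 1, 1)

#: Antidepressant ATC codes sampled for dispensations.
AD_CODES = ("N06AB03", "N06AB05", "N06AB06", "N06AX16", "N06AA09")

#: A non-antidepressant code sprinkled into timelines (exercises the ATC filter).
OTHER_CODE = "N02BE01"

# Discordance reasons with chart-review frequencies per stratum.
FP_REASONS = ("dysthymia", "dysthymia", "recurrent depression", "adaptive disorder", "vital occurrence")
FN_REASONS = ("dysthymia", "dysthymia", "dysthymia", "dysthymia", "adaptive disorder", "recurrent depression")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for cohort simulation.

    Defaults are the validated cohort's conditions: remission prevalence
    54.6%, classifier sensitivity 92.5% and specificity 90.6% against chart
    review, three-year observation windows, 28-90 day supplies.
    """

    n_patients: int
    true_remission_prob: float = 0.546
    sensitivity_target: float = 0.925
    specificity_target: float = 0.906
    observation_days: int = 1080
    supply_days_range: tuple[int, int] = (28, 90)
    seed: int = 0
    criteria: EpisodeCriteria = field(default_factory=EpisodeCriteria)

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name in ("true_remission_prob", "sensitivity_target", "specificity_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.supply_days_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid supply_days_range {self.supply_days_range}")
        c = self.criteria
        # the window must fit washout + treatment + a decided remission gap
        if self.observation_days < c.washout_days + c.min_treatment_days + c.remission_gap_days + 60:
            raise ValueError("observation_days too short for the episode criteria")
        if self.observation_days < c.followup_days + c.washout_days:
            raise ValueError("observation_days cannot accommodate the follow-up filter")


def _build_timeline(
    rng: np.random.Generator,
    patient_id: str,
    algorithm_positive: bool,
    config: SyntheticConfig,
) -> PatientTimeline:
    """One synthetic timeline the classifier will label REMISSION (positive) or not."""
    c = config.criteria
    obs_days = config.observation_days
    lo, hi = config.supply_days_range

    obs_start = BASE_DATE + dt.timedelta(days=int(rng.integers(0, 731)))
    obs_end = obs_start + dt.timedelta(days=obs_days)

    # Index offset: after the observed washout, early enough for follow-up and
    # for the remission gap (plus a 30-day safety margin) to be decidable.
    max_index = min(obs_days - c.followup_days, obs_days - c.remission_gap_days - 30 - c.min_treatment_days - hi)
    max_index = min(max_index, c.washout_days + 180)
    if max_index < c.washout_days:
        raise ValueError("observation window cannot fit an eligible episode")
    index_offset = int(rng.integers(c.washout_days, max_index + 1))

    # Contiguous treatment course: 2-4 dispensations, strictly over the
    # covered-day minimum, leaving room for a decidable post-treatment gap.
    max_treat = obs_days - index_offset - c.remission_gap_days - 30
    supplies: list[int] = []
    n_rx = int(rng.integers(2, 5))
    while len(supplies) < n_rx or sum(supplies) <= c.min_treatment_days:
        supplies.append(int(rng.integers(lo, hi + 1)))
    while sum(supplies) > max_treat and len(supplies) > 1:
        supplies.pop()
    if sum(supplies) <= c.min_treatment_days or sum(supplies) > max_treat:
        # fall back to a single qualifying course
        supplies = [min(max_treat, max(c.min_treatment_days + 1, lo))]

    prescriptions: list[Prescription] = []
    day = index_offset
    for supply in supplies:
        date = obs_start + dt.timedelta(days=day)
        code = AD_CODES[int(rng.integers(0, len(AD_CODES)))]
        prescriptions.append(Prescription(patient_id, code, date, supply))
        day += supply
    completion = day  # first day off medication

    if not algorithm_positive:
        # restart within the remission gap; further refills may follow
        gap = int(rng.integers(30, c.remission_gap_days))
        day = completion + gap
        while day + lo <= obs_days and len(prescriptions) < 12:
            supply = int(rng.integers(lo, hi + 1))
            code = AD_CODES[int(rng.integers(0, len(AD_CODES)))]
            prescriptions.append(
                Prescription(patient_id, code, obs_start + dt.timedelta(days=day), supply)
            )
            day += supply
            if rng.random() < 0.5:
                break

    # occasional non-antidepressant dispensation
    if rng.random() < 0.3:
        other_day = int(rng.integers(0, obs_days))
        prescriptions.append(
            Prescription(
                patient_id, OTHER_CODE, obs_start + dt.timedelta(days=other_day), 30
            )
        )

    return PatientTimeline(patient_id, prescriptions, obs_start, obs_end)


def _assessment(
    rng: np.random.Generator, patient_id: str, reference: int, discordant: bool
) -> ReferenceAssessment:
    reason = None
    if discordant:
        pool = FN_REASONS if reference == 1 else FP_REASONS
        reason = pool[int(rng.integers(0, len(pool)))]
    return ReferenceAssessment(patient_id, reference, reason)


def _emit(
    rng: np.random.Generator,
    cells: list[tuple[int, int]],
    config: SyntheticConfig,
) -> tuple[list[PatientTimeline], list[ReferenceAssessment]]:
    """Build patients from (algorithm_positive, reference) cell assignments."""
    order = rng.permutation(len(cells))
    width = max(4, len(str(max(len(cells), 1))))
    timelines, assessments = [], []
    for rank, idx in enumerate(order):
        algo_pos, reference = cells[idx]
        pid = f"P{rank + 1:0{width}d}"
        timelines.append(_build_timeline(rng, pid, bool(algo_pos), config))
        assessments.append(
            _assessment(rng, pid, reference, discordant=algo_pos != reference)
        )
    return timelines, assessments


def generate_exact_table(
    tp: int,
    fp: int,
    fn: int,
    tn: int,
    seed: int = 0,
    config: SyntheticConfig | None = None,
) -> tuple[list[PatientTimeline], list[ReferenceAssessment]]:
    """A cohort whose classifier-vs-reference 2x2 table equals (tp, fp, fn, tn).

    Cell membership is deterministic; dates, supplies and drug codes are
    randomized from ``seed``.  The guarantee is validated against the real
    classifier in the test suite, not assumed by construction.
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    n = tp + fp + fn + tn
    if config is None:
        config = SyntheticConfig(n_patients=n, seed=seed)
    rng = np.random.default_rng(seed)
    cells = (
        [(1, 1)] * tp + [(1, 0)] * fp + [(0, 1)] * fn + [(0, 0)] * tn
    )
    return _emit(rng, cells, config)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[PatientTimeline], list[ReferenceAssessment]]:
    """A cohort drawn from the configured prevalence / sensitivity / specificity.

    Each patient's true status is Bernoulli(``true_remission_prob``); the
    timeline is built so the classifier agrees with the truth with probability
    ``sensitivity_target`` (true remission) or ``specificity_target`` (true
    non-remission).
    """
    rng = np.random.default_rng(config.seed)
    cells: list[tuple[int, int]] = []
    for _ in range(config.n_patients):
        truth = int(rng.random() < config.true_remission_prob)
        if truth:
            algo = int(rng.random() < config.sensitivity_target)
        else:
            algo = int(rng.random() >= config.specificity_target)
        cells.append((algo, truth))
    return _emit(rng, cells, config)
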