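"""Remission-by-approximation: episode detection and classification.

The database definition of a new depression episode is a first antidepressant
(AD) prescription preceded by at least six observed AD-free months.  Treatment
coverage is the union of the dispensation intervals; gaps shorter than six
months join the same episode.  A patient is in remission when, after completing
treatment, no new AD prescription occurs for at least six months; a patient who
interrupts treatment for less than six months (i.e. restarts within the gap) is
not in sustained remission.  Patients failing an eligibility filter — no
episode, insufficient observed washout, not more than 60 covered treatment
days, or under 18 months of follow-up from episode start — are not evaluable.

Operationally the remission label is anchored at the *first treatment
completion*: the end of the first contiguous block of coverage.  A restart
within ``remission_gap_days`` of that date yields NO_REMISSION; a fully
observed AD-free gap of at least ``remission_gap_days`` yields REMISSION; if
the observation window closes before either is decided the patient is censored.
Eligibility (the covered-day minimum) is evaluated on the merged episode, so
treatment resumed after a short interruption still counts toward it.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import Enum

from .io import (
    ANTIDEPRESSANT_ATC_PREFIX,
    EpisodeCriteria,
    PatientTimeline,
)

__all__ = [
    "Label",
    "Rationale",
    "Episode",
    "RemissionCall",
    "CohortSummary",
    "detect_index_episode",
    "meets_minimum_treatment",
    "has_followup",
    "classify_remission",
    "classify_cohort",
]


class Label(str, Enum):
    REMISSION = "REMISSION"
    NO_REMISSION = "NO_REMISSION"
    NOT_EVALUABLE = "NOT_EVALUABLE"


class Rationale(str, Enum):
    NO_EPISODE = "NO_EPISODE"
    INSUFFICIENT_WASHOUT_OBSERVATION = "INSUFFICIENT_WASHOUT_OBSERVATION"
    MIN_TREATMENT_FAIL = "MIN_TREATMENT_FAIL"
    INSUFFICIENT_FOLLOWUP = "INSUFFICIENT_FOLLOWUP"
    GAP_OBSERVED = "GAP_OBSERVED"
    RESTART_WITHIN_GAP = "RESTART_WITHIN_GAP"
    CENSORED = "CENSORED"


#: Rationales that imply a NOT_EVALUABLE label.
NOT_EVALUABLE_RATIONALES = frozenset(
    {
        Rationale.NO_EPISODE,
        Rationale.INSUFFICIENT_WASHOUT_OBSERVATION,
        Rationale.MIN_TREATMENT_FAIL,
        Rationale.INSUFFICIENT_FOLLOWUP,
        Rationale.CENSORED,
    }
)


@dataclass(frozen=True)
class Episode:
    """A detected first treatment episode.

    ``treatment_segments`` are maximal contiguous coverage intervals (half-open
    date pairs); ``treatment_end`` is the exclusive end of the last segment of
    the merged episode, while ``completion_date`` is the exclusive end of the
    *first* segment — the first day the patient was off medication, from which
    the remission gap is measured.
    """

    patient_id: str
    episode_start: dt.date
    treatment_segments: tuple[tuple[dt.date, dt.date], ...]
    treatment_end: dt.date
    covered_days: int
    interruptions: tuple[tuple[dt.date, dt.date], ...]

    @property
    def completion_date(self) -> dt.date:
        return self.treatment_segments[0][1]


@dataclass(frozen=True)
class RemissionCall:
    patient_id: str
    label: Label
    rationale: Rationale
    episode: Episode | None = None

    def __post_init__(self):
        not_evaluable = self.rationale in NOT_EVALUABLE_RATIONALES
        if (self.label is Label.NOT_EVALUABLE) != not_evaluable:
            raise ValueError(
                f"label {self.label} inconsistent with rationale {self.rationale}"
            )


def _merged_coverage(timeline: PatientTimeline, atc_prefix: str):
    """Union of AD coverage intervals as sorted disjoint (start, end) ordinal pairs."""
    intervals = sorted(
        (rx.dispense_date.toordinal(), rx.coverage_end.toordinal())
        for rx in timeline.antidepressants(atc_prefix)
    )
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def detect_index_episode(
    timeline: PatientTimeline,
    criteria: EpisodeCriteria = EpisodeCriteria(),
    *,
    atc_prefix: str = ANTIDEPRESSANT_ATC_PREFIX,
) -> Episode | None:
    """Find the earliest new episode: an AD prescription with observed washout.

    The index prescription must be preceded by at least ``washout_days`` of
    observed, AD-coverage-free time (so at least ``washout_days`` must separate
    the start of observation from the index date).  Subsequent coverage
    segments separated by gaps shorter than ``within_episode_gap_days`` join
    the episode; a longer gap ends it.  Returns ``None`` when no prescription
    qualifies.
    """
    segments = _merged_coverage(timeline, atc_prefix)
    if not segments:
        return None
    obs_start = timeline.observation_start.toordinal()

    index_pos = None
    for i, (s, _e) in enumerate(segments):
        if s - obs_start < criteria.washout_days:
            continue
        prev_end = segments[i - 1][1] if i > 0 else None
        if prev_end is not None and s - prev_end < criteria.washout_days:
            continue
        index_pos = i
        break
    if index_pos is None:
        return None

    included = [segments[index_pos]]
    for s, e in segments[index_pos + 1:]:
        if s - included[-1][1] < criteria.within_episode_gap_days:
            included.append([s, e])
        else:
            break

    to_date = dt.date.fromordinal
    interruptions = tuple(
        (to_date(a_end), to_date(b_start))
        for (_, a_end), (b_start, _) in zip(included, included[1:])
    )
    return Episode(
        patient_id=timeline.patient_id,
        episode_start=to_date(included[0][0]),
        treatment_segments=tuple((to_date(s), to_date(e)) for s, e in included),
        treatment_end=to_date(included[-1][1]),
        covered_days=sum(e - s for s, e in included),
        interruptions=interruptions,
    )


def meets_minimum_treatment(
    episode: Episode, criteria: EpisodeCriteria = EpisodeCriteria()
) -> bool:
    """True iff the episode strictly exceeds the covered-day minimum (> 60 days)."""
    return episode.covered_days > criteria.min_treatment_days


def has_followup(
    episode: Episode,
    timeline: PatientTimeline,
    criteria: EpisodeCriteria = EpisodeCriteria(),
) -> bool:
    """True iff at least ``followup_days`` of observation follow the episode start."""
    elapsed = (timeline.observation_end - episode.episode_start).days
    return elapsed >= criteria.followup_days


def classify_remission(
    timeline: PatientTimeline,
    criteria: EpisodeCriteria = EpisodeCriteria(),
    *,
    atc_prefix: str = ANTIDEPRESSANT_ATC_PREFIX,
) -> RemissionCall:
    """Label one patient REMISSION / NO_REMISSION / NOT_EVALUABLE with a rationale."""
    pid = timeline.patient_id
    ads = timeline.antidepressants(atc_prefix)
    if not ads:
        return RemissionCall(pid, Label.NOT_EVALUABLE, Rationale.NO_EPISODE)

    episode = detect_index_episode(timeline, criteria, atc_prefix=atc_prefix)
    if episode is None:
        return RemissionCall(
            pid, Label.NOT_EVALUABLE, Rationale.INSUFFICIENT_WASHOUT_OBSERVATION
        )
    if not meets_minimum_treatment(episode, criteria):
        return RemissionCall(
            pid, Label.NOT_EVALUABLE, Rationale.MIN_TREATMENT_FAIL, episode
        )
    if not has_followup(episode, timeline, criteria):
        return RemissionCall(
            pid, Label.NOT_EVALUABLE, Rationale.INSUFFICIENT_FOLLOWUP, episode
        )

    completion = episode.completion_date
    restart = next(
        (rx.dispense_date for rx in ads if rx.dispense_date >= completion), None
    )
    if restart is not None and (restart - completion).days < criteria.remission_gap_days:
        return RemissionCall(pid, Label.NO_REMISSION, Rationale.RESTART_WITHIN_GAP, episode)
    observed_gap = (timeline.observation_end - completion).days
    if observed_gap >= criteria.remission_gap_days:
        return RemissionCall(pid, Label.REMISSION, Rationale.GAP_OBSERVED, episode)
    return RemissionCall(pid, Label.NOT_EVALUABLE, Rationale.CENSORED, episode)


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level tally of remission calls with the remission prevalence.

    Prevalence is REMISSION / (REMISSION + NO_REMISSION); NOT_EVALUABLE
    patients are excluded from the denominator.  ``prevalence`` is ``None``
    when no patient is evaluable.
    """

    n_total: int
    n_remission: int
    n_no_remission: int
    n_not_evaluable: int
    rationale_counts: tuple[tuple[str, int], ...]

    @property
    def n_evaluable(self) -> int:
        return self.n_remission + self.n_no_remission

    @property
    def prevalence(self) -> float | None:
        if self.n_evaluable == 0:
            return None
        return self.n_remission / self.n_evaluable

    def prevalence_interval(self, alpha: float = 0.05, ci_convention: str = "standard"):
        """Wald confidence interval for the prevalence (None when undefined)."""
        if self.n_evaluable == 0:
            return None
        from .validity import prevalence_ci

        return prevalence_ci(
            self.n_remission, self.n_evaluable, alpha=alpha, ci_convention=ci_convention
        )


def classify_cohort(
    timelines,
    criteria: EpisodeCriteria = EpisodeCriteria(),
    *,
    atc_prefix: str = ANTIDEPRESSANT_ATC_PREFIX,
) -> tuple[list[RemissionCall], CohortSummary]:
    """Classify every timeline and summarize the cohort."""
    calls = [
        classify_remission(tl, criteria, atc_prefix=atc_prefix) for tl in timelines
    ]
    counts: dict[Rationale, int] = {}
    for c in calls:
        counts[c.rationale] = counts.get(c.rationale, 0) + 1
    summary = CohortSummary(
        n_total=len(calls),
        n_remission=sum(c.label is Label.REMISSION for c in calls),
        n_no_remission=sum(c.label is Label.NO_REMISSION for c in calls),
        n_not_evaluable=sum(c.label is Label.NOT_EVALUABLE for c in calls),
        rationale_counts=tuple(
            sorted((r.value, n) for r, n in counts.items())
        ),
    )
    return calls, summary
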