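"""Shared fixtures and the independent day-grid oracle for the classifier."""

from __future__ import annotations

import datetime as dt

import pytest

from rxremit import ConfusionTable, EpisodeCriteria, PatientTimeline, Prescription

D0 = dt.date(2004, 1, 1)


def make_timeline(
    rx_days: list[tuple[int, int]],
    *,
    obs: tuple[int, int] = (0, 900),
    patient_id: str = "X",
    drug_code: str = "N06AB03",
) -> PatientTimeline:
    """Timeline from (day-offset, days-supply) pairs relative to a base date."""
    prescriptions = [
        Prescription(patient_id, drug_code, D0 + dt.timedelta(days=day), supply)
        for day, supply in rx_days
    ]
    return PatientTimeline(
        patient_id,
        prescriptions,
        D0 + dt.timedelta(days=obs[0]),
        D0 + dt.timedelta(days=obs[1]),
    )


def day_grid_label(
    timeline: PatientTimeline,
    criteria: EpisodeCriteria,
    atc_prefix: str = "N06A",
) -> tuple[str, str]:
    """Brute-force day-by-day simulation of coverage; returns (label, rationale).

    Independent of the interval arithmetic in rxremit.episodes: coverage is
    materialized on a boolean day grid and every rule is applied by scanning.
    """
    obs0 = timeline.observation_start.toordinal()
    obs1 = timeline.observation_end.toordinal()
    ads = [rx for rx in timeline.prescriptions if rx.drug_code.startswith(atc_prefix)]
    if not ads:
        return ("NOT_EVALUABLE", "NO_EPISODE")

    horizon = max(rx.dispense_date.toordinal() + rx.days_supply for rx in ads)
    grid_end = max(obs1, horizon) + criteria.within_episode_gap_days + 1
    covered = [False] * (grid_end - obs0)
    for rx in ads:
        start = rx.dispense_date.toordinal()
        for d in range(start, start + rx.days_supply):
            covered[d - obs0] = True
    dispense_days = sorted(rx.dispense_date.toordinal() for rx in ads)

    index = None
    for t in dispense_days:
        if t - obs0 < criteria.washout_days:
            continue
        if any(covered[d - obs0] for d in range(t - criteria.washout_days, t)):
            continue
        index = t
        break
    if index is None:
        return ("NOT_EVALUABLE", "INSUFFICIENT_WASHOUT_OBSERVATION")

    # walk forward from the index counting covered days; an uncovered run of at
    # least within_episode_gap_days (or running out of coverage) ends the episode
    covered_days = 0
    completion = None
    d = index
    while True:
        if covered[d - obs0]:
            covered_days += 1
            d += 1
            continue
        if completion is None:
            completion = d
        next_covered = None
        for u in range(d - obs0, grid_end - obs0):
            if covered[u]:
                next_covered = u + obs0
                break
        if next_covered is None or next_covered - d >= criteria.within_episode_gap_days:
            break
        d = next_covered
    if completion is None:  # pragma: no cover - coverage always ends on the grid
        completion = d

    if covered_days <= criteria.min_treatment_days:
        return ("NOT_EVALUABLE", "MIN_TREATMENT_FAIL")
    if obs1 - index < criteria.followup_days:
        return ("NOT_EVALUABLE", "INSUFFICIENT_FOLLOWUP")

    restart = next((t for t in dispense_days if t >= completion), None)
    if restart is not None and restart - completion < criteria.remission_gap_days:
        return ("NO_REMISSION", "RESTART_WITHIN_GAP")
    if obs1 - completion >= criteria.remission_gap_days:
        return ("REMISSION", "GAP_OBSERVED")
    return ("NOT_EVALUABLE", "CENSORED")


@pytest.fixture
def criteria() -> EpisodeCriteria:
    return EpisodeCriteria()


@pytest.fixture
def validation_table() -> ConfusionTable:
    """The 74/5/6/48 chart-review validation table used throughout."""
    return ConfusionTable(74, 5, 6, 48)
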