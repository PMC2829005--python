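"""Domain types and file I/O for prescription timelines and reference assessments.

The on-disk formats are deliberately minimal, plain CSV:

* prescriptions: ``patient_id,drug_code,dispense_date,days_supply`` with optional
  per-patient ``observation_start,observation_end`` columns (ISO-8601 dates);
* reference assessments: ``patient_id,reference_remission[,reason]``;
* remission calls: ``patient_id,label,episode_start,treatment_end,rationale``.

Antidepressants are identified by ATC prefix (``N06A`` by default); rows for other
drugs are retained on the timeline but flagged, so classification can ignore them.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

#: ATC prefix identifying antidepressant dispensations.
ANTIDEPRESSANT_ATC_PREFIX = "N06A"


class FormatError(ValueError):
    """A file does not conform to the expected tabular format (e.g. missing column)."""


class RowError(ValueError):
    """A single row violates an invariant; carries the 1-based file line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _parse_date(value, *, line: int | None = None) -> dt.date:
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise RowError(f"unparseable ISO-8601 date {value!r}", line) from exc


@dataclass(frozen=True)
class Prescription:
    """One dispensation event covering ``[dispense_date, dispense_date + days_supply)``."""

    patient_id: str
    drug_code: str
    dispense_date: dt.date
    days_supply: int

    def __post_init__(self):
        if self.days_supply < 1:
            raise ValueError(
                f"days_supply must be >= 1, got {self.days_supply} "
                f"(patient {self.patient_id})"
            )

    @property
    def coverage_end(self) -> dt.date:
        """Exclusive end of the coverage interval (first uncovered day)."""
        return self.dispense_date + dt.timedelta(days=self.days_supply)

    def is_antidepressant(self, atc_prefix: str = ANTIDEPRESSANT_ATC_PREFIX) -> bool:
        return self.drug_code.startswith(atc_prefix)


@dataclass
class PatientTimeline:
    """All prescriptions for one patient plus their observation window.

    Prescriptions are kept sorted by dispense date (ties broken by drug code) so
    that timeline construction is invariant to input row order.
    """

    patient_id: str
    prescriptions: list[Prescription]
    observation_start: dt.date
    observation_end: dt.date

    def __post_init__(self):
        if self.observation_start >= self.observation_end:
            raise ValueError(
                f"observation_start must precede observation_end "
                f"(patient {self.patient_id})"
            )
        for rx in self.prescriptions:
            if rx.patient_id != self.patient_id:
                raise ValueError(
                    f"prescription for {rx.patient_id} on timeline {self.patient_id}"
                )
            if not (self.observation_start <= rx.dispense_date <= self.observation_end):
                raise ValueError(
                    f"dispense {rx.dispense_date} outside observation window "
                    f"[{self.observation_start}, {self.observation_end}] "
                    f"(patient {self.patient_id})"
                )
        self.prescriptions = sorted(
            self.prescriptions, key=lambda r: (r.dispense_date, r.drug_code, r.days_supply)
        )

    def antidepressants(
        self, atc_prefix: str = ANTIDEPRESSANT_ATC_PREFIX
    ) -> list[Prescription]:
        return [rx for rx in self.prescriptions if rx.is_antidepressant(atc_prefix)]


@dataclass(frozen=True)
class EpisodeCriteria:
    """Day-count thresholds parameterizing episode detection and remission.

    Month-based thresholds use the fixed convention 1 month = 30 days, hence
    6 months = 180 days and 18 months = 540 days.

    washout_days
        Antidepressant-free observed time required before an index prescription
        for it to open a *new* episode (default 180).
    min_treatment_days
        Covered treatment days required for eligibility; strict inequality,
        i.e. the episode must exceed this (default 60).
    followup_days
        Minimum observation from episode start needed to assign a subgroup
        (default 540 = 12-month study period + 6-month follow-up).
    remission_gap_days
        Prescription-free gap after completing treatment that defines remission
        (default 180).
    within_episode_gap_days
        Gaps between coverage intervals shorter than this join the same episode
        (default 180).
    """

    washout_days: int = 180
    min_treatment_days: int = 60
    followup_days: int = 540
    remission_gap_days: int = 180
    within_episode_gap_days: int = 180

    def __post_init__(self):
        for name in (
            "washout_days",
            "min_treatment_days",
            "followup_days",
            "remission_gap_days",
            "within_episode_gap_days",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {value!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "EpisodeCriteria":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise FormatError(f"unknown criteria field(s): {sorted(unknown)}")
        return cls(**{k: int(v) for k, v in mapping.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "EpisodeCriteria":
        """Load criteria from a YAML or JSON mapping (YAML is a JSON superset)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if data is None:
            return cls()
        if not isinstance(data, Mapping):
            raise FormatError(f"{path}: expected a mapping of criteria fields")
        # allow the criteria to live under a 'criteria:' key of a larger config
        if "criteria" in data and isinstance(data["criteria"], Mapping):
            data = data["criteria"]
        return cls.from_mapping(data)


@dataclass(frozen=True)
class ReferenceAssessment:
    """Chart-review remission judgment for one patient (the reference standard)."""

    patient_id: str
    reference_remission: int
    reason: str | None = None

    def __post_init__(self):
        if self.reference_remission not in (0, 1):
            raise ValueError(
                f"reference_remission must be 0 or 1, got "
                f"{self.reference_remission!r} (patient {self.patient_id})"
            )


PRESCRIPTION_COLUMNS = ("patient_id", "drug_code", "dispense_date", "days_supply")
ASSESSMENT_COLUMNS = ("patient_id", "reference_remission")
CALL_COLUMNS = ("patient_id", "label", "episode_start", "treatment_end", "rationale")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_prescriptions(
    path: str | Path,
    *,
    atc_prefix: str = ANTIDEPRESSANT_ATC_PREFIX,
    observation_windows: Mapping[str, tuple[dt.date, dt.date]] | None = None,
) -> list[PatientTimeline]:
    """Read a prescriptions CSV into one :class:`PatientTimeline` per patient.

    Observation windows are taken from, in order of precedence: the
    ``observation_windows`` mapping, optional ``observation_start`` /
    ``observation_end`` columns, or (last resort) the span of the patient's own
    dispensations.  The last fallback provides no observed washout before the
    first prescription, so such patients will typically be NOT_EVALUABLE.

    Row numbers in errors are 1-based file lines (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, PRESCRIPTION_COLUMNS, path)
    has_window_cols = "observation_start" in df.columns and "observation_end" in df.columns

    rows_by_patient: dict[str, list[Prescription]] = {}
    windows: dict[str, tuple[dt.date, dt.date]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        pid = str(row.patient_id)
        date = _parse_date(row.dispense_date, line=line)
        try:
            supply = int(str(row.days_supply))
        except ValueError:
            raise RowError(f"non-integer days_supply {row.days_supply!r}", line) from None
        if supply < 1:
            raise RowError(f"days_supply must be >= 1, got {supply}", line)
        rows_by_patient.setdefault(pid, []).append(
            Prescription(pid, str(row.drug_code), date, supply)
        )
        if has_window_cols:
            win = (
                _parse_date(row.observation_start, line=line),
                _parse_date(row.observation_end, line=line),
            )
            prior = windows.setdefault(pid, win)
            if prior != win:
                raise RowError(
                    f"inconsistent observation window for patient {pid}", line
                )

    timelines = []
    for pid, rxs in rows_by_patient.items():
        if observation_windows is not None and pid in observation_windows:
            start, end = observation_windows[pid]
        elif pid in windows:
            start, end = windows[pid]
        else:
            start = min(r.dispense_date for r in rxs)
            end = max(r.coverage_end for r in rxs)
        timelines.append(PatientTimeline(pid, rxs, start, end))
    timelines.sort(key=lambda t: t.patient_id)
    return timelines


def write_prescriptions(timelines: Iterable[PatientTimeline], path: str | Path) -> None:
    """Write timelines back to the prescriptions CSV (with observation window columns)."""
    records = []
    for tl in timelines:
        for rx in tl.prescriptions:
            records.append(
                {
                    "patient_id": rx.patient_id,
                    "drug_code": rx.drug_code,
                    "dispense_date": rx.dispense_date.isoformat(),
                    "days_supply": rx.days_supply,
                    "observation_start": tl.observation_start.isoformat(),
                    "observation_end": tl.observation_end.isoformat(),
                }
            )
    columns = list(PRESCRIPTION_COLUMNS) + ["observation_start", "observation_end"]
    pd.DataFrame(records, columns=columns).to_csv(path, index=False)


def read_assessments(path: str | Path) -> list[ReferenceAssessment]:
    """Read the reference-standard CSV; duplicate patient ids are an error."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ASSESSMENT_COLUMNS, path)
    has_reason = "reason" in df.columns
    seen: set[str] = set()
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        pid = str(row.patient_id)
        if pid in seen:
            raise RowError(f"duplicate patient_id {pid!r}", line)
        seen.add(pid)
        label_raw = str(row.reference_remission).strip()
        if label_raw not in ("0", "1"):
            raise RowError(
                f"reference_remission must be 0 or 1, got {label_raw!r}", line
            )
        reason = str(row.reason).strip() if has_reason else ""
        out.append(ReferenceAssessment(pid, int(label_raw), reason or None))
    return out


def write_assessments(assessments: Iterable[ReferenceAssessment], path: str | Path) -> None:
    records = [
        {
            "patient_id": a.patient_id,
            "reference_remission": a.reference_remission,
            "reason": a.reason or "",
        }
        for a in assessments
    ]
    pd.DataFrame(records, columns=["patient_id", "reference_remission", "reason"]).to_csv(
        path, index=False
    )


def write_calls(calls: Iterable, path: str | Path) -> None:
    """Write remission calls to CSV; round-trips losslessly through :func:`read_calls`."""
    records = []
    for c in calls:
        ep = c.episode
        records.append(
            {
                "patient_id": c.patient_id,
                "label": c.label.value,
                "episode_start": ep.episode_start.isoformat() if ep else "",
                "treatment_end": ep.completion_date.isoformat() if ep else "",
                "rationale": c.rationale.value,
            }
        )
    pd.DataFrame(records, columns=list(CALL_COLUMNS)).to_csv(path, index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a calls CSV back as a DataFrame (labels/rationales as strings)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, CALL_COLUMNS, path)
    return df


def write_json(data: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
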