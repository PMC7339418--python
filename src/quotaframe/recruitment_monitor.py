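"""Survey-record ingestion, attrition accounting and daily progress reports.

Each survey attempt yields one record: demographics, the site where it
happened, completion status (with a reason when the survey was abandoned)
and duration in minutes.  The monitor turns a pile of records into (a) a
completion summary — commenced minus incompletes by reason equals the final
analysable n — and (b) a per-stratum progress report against the frame's
integer targets, flagging over-recruited strata so field coordinators can
correct course the next day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .strata_frame import (
    MIN_ELIGIBLE_AGE,
    SES_CATEGORIES,
    StrataTargets,
    Stratum,
    band_for_age,
    sorted_strata,
)

__all__ = [
    "SurveyRecord",
    "CompletionSummary",
    "ProgressReport",
    "DurationStats",
    "INCOMPLETE_REASONS",
    "RESIDENCE_CATEGORIES",
    "ingest_records",
    "completion_summary",
    "progress_report",
    "duration_stats",
    "possible_duplicates",
]

INCOMPLETE_REASONS = ("left_time", "technical", "discomfort", "other")
RESIDENCE_CATEGORIES = ("town_city", "indigenous_community", "parkland_scrub", "other")


@dataclass(frozen=True)
class SurveyRecord:
    """One survey attempt.

    Demographics may be absent on incomplete attempts (the participant may
    have left before providing them); ``incomplete_reason`` is present iff
    ``status == "incomplete"``.
    """

    record_id: str
    date: date
    site_id: str
    status: str  # complete | incomplete
    gender: Optional[str] = None
    age: Optional[float] = None
    ses: Optional[str] = None
    incomplete_reason: Optional[str] = None
    duration_min: Optional[float] = None
    residence: Optional[str] = None
    income_band: Optional[str] = None
    language_at_home: Optional[bool] = None
    education_year10: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.status not in ("complete", "incomplete"):
            raise ValueError(f"bad status {self.status!r}")
        if (self.incomplete_reason is not None) != (self.status == "incomplete"):
            raise ValueError(
                "incomplete_reason must be present exactly when status=incomplete"
            )
        if self.incomplete_reason is not None and self.incomplete_reason not in INCOMPLETE_REASONS:
            raise ValueError(f"bad incomplete reason {self.incomplete_reason!r}")
        if self.age is not None and self.age < MIN_ELIGIBLE_AGE:
            raise ValueError(f"age {self.age} below eligibility threshold")
        if self.duration_min is not None and self.duration_min <= 0:
            raise ValueError("duration must be positive when present")
        if self.ses is not None and self.ses not in SES_CATEGORIES:
            raise ValueError(f"bad SES {self.ses!r}")

    @property
    def stratum(self) -> Optional[Stratum]:
        if self.gender is None or self.age is None or self.ses is None:
            return None
        return Stratum(self.gender, band_for_age(self.age).label, self.ses)


def _opt(v, cast):
    return None if pd.isna(v) else cast(v)


def ingest_records(
    path: str | Path, rejects_path: str | Path | None = None
) -> tuple[list[SurveyRecord], pd.DataFrame]:
    """Load survey records from CSV, validating row by row.

    Malformed rows and under-age rows are collected into a rejects table
    (written to ``rejects_path`` when given) rather than aborting the load;
    a duplicate record id is a hard error because it means the same attempt
    was synced twice.
    """
    df = pd.read_csv(path, encoding="utf-8")
    if df["record_id"].duplicated().any():
        dupes = df.loc[df["record_id"].duplicated(), "record_id"].unique()
        raise ValueError(f"duplicate record ids: {list(map(str, dupes))[:5]}")
    records: list[SurveyRecord] = []
    rejects: list[dict] = []
    for _, row in df.iterrows():
        try:
            age = _opt(row.get("age"), float)
            if age is not None and age < MIN_ELIGIBLE_AGE:
                rejects.append({"record_id": row["record_id"], "reason": "eligibility"})
                continue
            lang = row.get("language_at_home")
            edu = row.get("education_year10")
            records.append(
                SurveyRecord(
                    record_id=str(row["record_id"]),
                    date=date.fromisoformat(str(row["date"])),
                    site_id=str(row["site_id"]),
                    status=str(row["status"]),
                    gender=_opt(row.get("gender"), str),
                    age=age,
                    ses=_opt(row.get("ses"), str),
                    incomplete_reason=_opt(row.get("incomplete_reason"), str),
                    duration_min=_opt(row.get("duration_min"), float),
                    residence=_opt(row.get("residence"), str),
                    income_band=_opt(row.get("income_band"), str),
                    language_at_home=None if pd.isna(lang) else bool(lang),
                    education_year10=None if pd.isna(edu) else bool(edu),
                )
            )
        except (ValueError, KeyError, TypeError) as exc:
            rejects.append({"record_id": row.get("record_id"), "reason": str(exc)})
    rej = pd.DataFrame(rejects, columns=["record_id", "reason"])
    if rejects_path is not None:
        rej.to_csv(rejects_path, index=False)
    return records, rej


@dataclass
class CompletionSummary:
    """Attrition accounting: ``final_n = commenced - sum(incompletes)``."""

    commenced: int
    incomplete_by_reason: dict[str, int]
    final_n: int


def completion_summary(records: Iterable[SurveyRecord]) -> CompletionSummary:
    records = list(records)
    reasons: dict[str, int] = {}
    for r in records:
        if r.status == "incomplete":
            reasons[r.incomplete_reason] = reasons.get(r.incomplete_reason, 0) + 1
    commenced = len(records)
    return CompletionSummary(
        commenced=commenced,
        incomplete_by_reason=reasons,
        final_n=commenced - sum(reasons.values()),
    )


@dataclass
class ProgressReport:
    """Recruitment progress against the frame, as of a calendar date.

    Only completed surveys dated on/before ``as_of`` count.  Completed
    records whose demographics fall outside the frame land in
    ``other_bucket`` and are flagged rather than dropped.
    """

    as_of: date
    rows: pd.DataFrame  # gender, age_band, ses, recruited, target, remaining, over
    other_bucket: int
    fraction_of_target: float
    flags: list[str] = field(default_factory=list)


def progress_report(
    records: Iterable[SurveyRecord], targets: StrataTargets, as_of: date
) -> ProgressReport:
    counts: dict[Stratum, int] = {s: 0 for s in targets.targets}
    other = 0
    for r in records:
        if r.status != "complete" or r.date > as_of:
            continue
        s = r.stratum
        if s is None or s not in counts:
            other += 1
            continue
        counts[s] += 1
    rows = []
    flags = []
    for s in sorted_strata(targets.targets):
        t = targets.targets[s]
        got = counts[s]
        over = got > t
        if over:
            flags.append(f"over-sampled {s}: recruited {got} against target {t}")
        rows.append(
            {
                "gender": s.gender,
                "age_band": s.age_band,
                "ses": s.ses,
                "recruited": got,
                "target": t,
                "remaining": max(0, t - got),
                "over": over,
            }
        )
    if other:
        flags.append(f"{other} complete record(s) outside the frame")
    total_got = sum(counts.values())
    frac = total_got / targets.n_target if targets.n_target else 0.0
    return ProgressReport(
        as_of=as_of,
        rows=pd.DataFrame(rows),
        other_bucket=other,
        fraction_of_target=frac,
        flags=flags,
    )


@dataclass
class DurationStats:
    n: int
    mean: float
    sd: Optional[float]  # sample SD (n-1); absent for a single duration
    min: float
    max: float


def duration_stats(records: Iterable[SurveyRecord]) -> Optional[DurationStats]:
    """Survey duration summary over every record carrying a duration,
    complete or not.  Sample standard deviation (n-1 denominator);
    rounding to 2 decimals belongs to the report layer, not here."""
    durs = np.array(
        [r.duration_min for r in records if r.duration_min is not None], dtype=float
    )
    if durs.size == 0:
        warnings.warn("no durations recorded", stacklevel=2)
        return None
    return DurationStats(
        n=int(durs.size),
        mean=float(durs.mean()),
        sd=float(durs.std(ddof=1)) if durs.size > 1 else None,
        min=float(durs.min()),
        max=float(durs.max()),
    )


def possible_duplicates(records: Iterable[SurveyRecord]) -> pd.DataFrame:
    """Heuristic repeat-participation screen.

    Participants are anonymous (no names recorded), so true duplicates are
    undetectable; this flags records sharing (site, date, gender, age, ses)
    as *possible* repeats only.  Treat the output as a lead, not a finding.
    """
    rows = [
        {
            "record_id": r.record_id,
            "site_id": r.site_id,
            "date": r.date,
            "gender": r.gender,
            "age": r.age,
            "ses": r.ses,
        }
        for r in records
        if r.status == "complete"
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    keys = ["site_id", "date", "gender", "age", "ses"]
    dup_mask = df.duplicated(subset=keys, keep=False) & df[keys].notna().all(axis=1)
    return df[dup_mask].sort_values(keys).reset_index(drop=True)
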