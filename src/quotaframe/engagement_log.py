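"""Analysis of the researcher-to-organisation contact effort.

Recruiting organisations as survey sites is itself fieldwork: every email,
phone call, text, meeting and social-media message to a prospective site is
logged.  This module tallies contacts per channel, compares mean contact
effort between organisations that ultimately participated and those that
declined (restricted, when asked, to contacts made before the agree/decline
decision), and provides the Welch unequal-variance two-sample t-test used
for that comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .site_registry import OrgRecord

__all__ = [
    "CHANNELS",
    "ContactEvent",
    "ChannelCounts",
    "GroupEffort",
    "WelchResult",
    "load_contacts",
    "contact_counts",
    "contacts_by_participation",
    "welch_t",
]

CHANNELS = ("email", "phone", "text", "meeting", "facebook")


@dataclass(frozen=True)
class ContactEvent:
    """One logged interaction with an organisation.

    ``duration_hours`` is recorded for phone calls and meetings only.
    ``before_agreement`` marks contacts made before the organisation agreed
    or declined (set at ingest by comparing the contact date with the
    letter-of-support or decline date).
    """

    org_id: str
    date: date
    channel: str
    duration_hours: Optional[float] = None
    before_agreement: bool = True

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.duration_hours is not None and self.duration_hours < 0:
            raise ValueError("duration must be >= 0 when present")


def load_contacts(
    path: str | Path, orgs: Iterable[OrgRecord] | None = None
) -> list[ContactEvent]:
    """Read the contact log CSV: ``org_id, date, channel, duration_hours,
    before_agreement``.

    When ``before_agreement`` is absent from the file and ``orgs`` is
    supplied, the flag is derived from the organisation's letter-of-support
    date (contacts strictly before that date count as pre-agreement; an
    organisation with no letter date keeps all contacts pre-agreement).
    """
    df = pd.read_csv(path, encoding="utf-8")
    letter_dates = {}
    if orgs is not None:
        letter_dates = {
            o.id: o.letter_of_support_date
            for o in orgs
            if o.letter_of_support_date is not None
        }
    events = []
    for _, row in df.iterrows():
        d = date.fromisoformat(str(row["date"]))
        oid = str(row["org_id"])
        if "before_agreement" in df.columns and not pd.isna(row["before_agreement"]):
            before = bool(row["before_agreement"])
        else:
            cutoff = letter_dates.get(oid)
            before = True if cutoff is None else d < cutoff
        dur = row.get("duration_hours")
        events.append(
            ContactEvent(
                org_id=oid,
                date=d,
                channel=str(row["channel"]),
                duration_hours=None if pd.isna(dur) else float(dur),
                before_agreement=before,
            )
        )
    return events


@dataclass
class ChannelCounts:
    by_channel: dict[str, int]
    total: int


def contact_counts(log: Iterable[ContactEvent]) -> ChannelCounts:
    """Exact integer tallies per channel; total is their sum."""
    by: dict[str, int] = {c: 0 for c in CHANNELS}
    for e in log:
        by[e.channel] += 1
    return ChannelCounts(by_channel=by, total=sum(by.values()))


@dataclass
class GroupEffort:
    """Mean engagement effort for participating vs declining organisations.

    ``contacts_*`` are per-organisation contact counts; ``phone_hours_*``
    are per-organisation summed phone durations.  Means to 2 decimals;
    the raw per-organisation vectors are kept for testing.
    """

    mean_contacts_participated: float
    mean_contacts_declined: float
    mean_phone_hours_participated: float
    mean_phone_hours_declined: float
    contacts_participated: list[float]
    contacts_declined: list[float]
    phone_hours_participated: list[float]
    phone_hours_declined: list[float]


def contacts_by_participation(
    log: Iterable[ContactEvent],
    orgs: Iterable[OrgRecord],
    pre_agreement_only: bool = True,
) -> GroupEffort:
    """Per-group mean contact counts and phone hours.

    Groups are the approached organisations, split by participation.  An
    approached organisation with no logged contacts contributes zero — it
    was still part of the recruitment effort.  Contacts naming an unknown
    organisation are a hard error.
    """
    orgs = list(orgs)
    known = {o.id for o in orgs}
    n_contacts: dict[str, float] = {o.id: 0.0 for o in orgs if o.approached}
    phone_hours: dict[str, float] = {o.id: 0.0 for o in orgs if o.approached}
    for e in log:
        if e.org_id not in known:
            raise ValueError(f"contact references unknown org {e.org_id!r}")
        if pre_agreement_only and not e.before_agreement:
            continue
        if e.org_id in n_contacts:
            n_contacts[e.org_id] += 1
            if e.channel == "phone" and e.duration_hours is not None:
                phone_hours[e.org_id] += e.duration_hours

    part_ids = [o.id for o in orgs if o.approached and o.participated]
    decl_ids = [o.id for o in orgs if o.approached and not o.participated]
    cp = [n_contacts[i] for i in part_ids]
    cd = [n_contacts[i] for i in decl_ids]
    hp = [phone_hours[i] for i in part_ids]
    hd = [phone_hours[i] for i in decl_ids]

    def mean(v: Sequence[float]) -> float:
        return round(float(np.mean(v)), 2) if len(v) else float("nan")

    return GroupEffort(
        mean_contacts_participated=mean(cp),
        mean_contacts_declined=mean(cd),
        mean_phone_hours_participated=mean(hp),
        mean_phone_hours_declined=mean(hd),
        contacts_participated=cp,
        contacts_declined=cd,
        phone_hours_participated=hp,
        phone_hours_declined=hd,
    )


@dataclass
class WelchResult:
    t: float
    df: float
    p: float

    def __str__(self) -> str:  # report layer mimics the field convention
        return f"t = {self.t:.2f}, df = {self.df:.2f}, p = {self.p:.2f}"


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Welch unequal-variance two-sample t-test, two-sided.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch–Satterthwaite degrees of freedom.  Zero variance in both groups
    with equal means returns t = 0, p = 1 by convention; fewer than two
    observations in either group is an error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(na + nb - 2), p=1.0)
        raise ValueError("zero variance with unequal means: t undefined")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))
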