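"""Recruitment sites, their client demographics, and the organisation
referral network.

A *site* is an organisation or public location where surveying happens; it
reports how many clients it currently serves per stratum, and which SES
categories it can plausibly recruit (an adult-education site reaches
students, a homelessness service reaches people with no fixed address, and
general-community sites such as shopping malls or festivals reach anyone).
Organisation engagement is tracked separately as :class:`OrgRecord` rows:
whether each organisation was approached, whether it participated
(participation = receipt of a letter of support), and who referred it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

from .strata_frame import (
    NAMED_SES,
    SES_CATEGORIES,
    Stratum,
    parse_age_band,
    sorted_strata,
)

__all__ = [
    "SITE_TYPES",
    "DEFAULT_SES_ELIGIBILITY",
    "Site",
    "SiteRegistry",
    "OrgRecord",
    "ReferralSummary",
    "load_sites",
    "load_orgs",
    "eligibility_matrix",
    "summarize_referrals",
    "referral_graph",
]

SITE_TYPES: tuple[str, ...] = (
    "indigenous_health_service",
    "community_group",
    "indigenous_adult_education",
    "unemployment_service",
    "public_housing_service",
    "homelessness_service",
    "mental_health_service",
    "aod_service",
    "childcare",
    "hobby_group",
    "cultural_group",
    "public_event",
    "public_space",
)

#: Default SES eligibility per site type.  The rule is known only by example
#: (education sites take the student quota, unemployment services the
#: unemployed quota, ...), so this ships as an editable mapping.
DEFAULT_SES_ELIGIBILITY: dict[str, frozenset[str]] = {
    "indigenous_health_service": frozenset(NAMED_SES),
    "community_group": frozenset(NAMED_SES),
    "indigenous_adult_education": frozenset({"student"}),
    "unemployment_service": frozenset({"unemployed"}),
    "public_housing_service": frozenset({"unemployed", "full_time_worker"}),
    "homelessness_service": frozenset({"homeless"}),
    "mental_health_service": frozenset(NAMED_SES),
    "aod_service": frozenset(NAMED_SES),
    "childcare": frozenset(NAMED_SES),
    "hobby_group": frozenset(NAMED_SES),
    "cultural_group": frozenset(NAMED_SES),
    "public_event": frozenset(SES_CATEGORIES),
    "public_space": frozenset(SES_CATEGORIES),
}


@dataclass(frozen=True)
class Site:
    """A recruitment site with its current client table.

    ``is_general`` marks sites likely to contain general community members
    (shopping malls, festivals); these receive the residual-category quotas
    and act as the spill-over destination when services cannot cover a
    stratum.  ``general_capacity`` is the notional number of people such a
    site can reach.
    """

    id: str
    name: str
    type: str
    eligible_ses: frozenset[str]
    client_counts: Mapping[Stratum, int] = field(default_factory=dict)
    is_general: bool = False
    general_capacity: int = 500

    def __post_init__(self) -> None:
        if self.type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.type!r}")
        for ses in self.eligible_ses:
            if ses not in SES_CATEGORIES:
                raise ValueError(f"unknown SES label {ses!r} for site {self.id}")
        for s, n in self.client_counts.items():
            if n < 0:
                raise ValueError(f"negative client count for {s} at site {self.id}")


class SiteRegistry:
    """Ordered collection of sites with unique ids."""

    def __init__(self, sites: Iterable[Site] = ()):
        self._sites: dict[str, Site] = {}
        for site in sites:
            self.add(site)

    def add(self, site: Site) -> None:
        if site.id in self._sites:
            raise ValueError(f"duplicate site id {site.id!r}")
        self._sites[site.id] = site

    def __iter__(self):
        return iter(self._sites.values())

    def __len__(self) -> int:
        return len(self._sites)

    def __getitem__(self, site_id: str) -> Site:
        return self._sites[site_id]

    def __contains__(self, site_id: str) -> bool:
        return site_id in self._sites

    @property
    def general_sites(self) -> list[Site]:
        return [s for s in self if s.is_general]


def _parse_stratum_column(col: str) -> Optional[Stratum]:
    parts = col.split(":")
    if len(parts) != 3:
        return None
    gender, band, ses = (p.strip() for p in parts)
    return Stratum(gender, parse_age_band(band).label, ses)


def load_sites(path: str | Path) -> SiteRegistry:
    """Read a site registry CSV.

    Columns: ``site_id, name, type, is_general, eligible_ses`` (pipe-
    separated SES labels; blank means the type default) plus optional
    ``general_capacity`` and one column per stratum count, headed
    ``gender:age_band:ses`` (e.g. ``male:16-24:unemployed``).
    """
    df = pd.read_csv(path, encoding="utf-8")
    if df.empty:
        import warnings

        warnings.warn(f"site registry {path} is empty", stacklevel=2)
        return SiteRegistry()

    meta_cols = {"site_id", "name", "type", "is_general", "eligible_ses", "general_capacity"}
    stratum_cols = {}
    for col in df.columns:
        if col in meta_cols:
            continue
        s = _parse_stratum_column(col)
        if s is None:
            raise ValueError(f"unrecognised column {col!r} in site registry")
        stratum_cols[col] = s

    registry = SiteRegistry()
    for _, row in df.iterrows():
        site_type = str(row["type"])
        raw_elig = row.get("eligible_ses")
        if pd.isna(raw_elig) or str(raw_elig).strip() == "":
            eligible = DEFAULT_SES_ELIGIBILITY.get(site_type, frozenset(NAMED_SES))
        else:
            eligible = frozenset(x.strip() for x in str(raw_elig).split("|") if x.strip())
        counts = {}
        for col, s in stratum_cols.items():
            v = row[col]
            if pd.isna(v):
                continue
            n = int(v)
            if n:
                counts[s] = n
        kwargs = {}
        if "general_capacity" in df.columns and not pd.isna(row.get("general_capacity")):
            kwargs["general_capacity"] = int(row["general_capacity"])
        registry.add(
            Site(
                id=str(row["site_id"]),
                name=str(row["name"]),
                type=site_type,
                eligible_ses=eligible,
                client_counts=counts,
                is_general=bool(row["is_general"]) if "is_general" in df.columns else False,
                **kwargs,
            )
        )
    return registry


def eligibility_matrix(
    registry: SiteRegistry, frame: Iterable[Stratum]
) -> dict[Stratum, set[str]]:
    """Map each stratum to the set of site ids that may recruit it.

    A service site is eligible when the stratum's SES is in its eligibility
    set and it reports clients in that stratum; general-community sites are
    eligible for every stratum (and are the only destination for ``general``
    strata, absent client counts).  Strata with no eligible site map to the
    empty set — recorded, not fatal; the allocator handles the shortfall.
    """
    out: dict[Stratum, set[str]] = {}
    for stratum in sorted_strata(frame):
        eligible: set[str] = set()
        for site in registry:
            if site.is_general:
                eligible.add(site.id)
                continue
            if stratum.ses in site.eligible_ses and site.client_counts.get(stratum, 0) > 0:
                eligible.add(site.id)
        out[stratum] = eligible
    return out


# ---------------------------------------------------------------------------
# organisation engagement


@dataclass(frozen=True)
class OrgRecord:
    """Engagement status of one organisation.

    ``participated`` means a letter of support was received; it implies
    ``approached``.  ``referred_by`` holds the ids of organisations that
    referred this one to the study (snowball recruitment of sites).
    """

    id: str
    approached: bool
    participated: bool
    referred_by: frozenset[str] = frozenset()
    letter_of_support_date: Optional[date] = None

    def __post_init__(self) -> None:
        if self.participated and not self.approached:
            raise ValueError(
                f"org {self.id}: participated implies approached"
            )


def load_orgs(path: str | Path) -> list[OrgRecord]:
    """Read the organisation table CSV: ``org_id, approached, participated,
    referred_by`` (pipe-separated), ``letter_date`` (ISO-8601, optional)."""
    df = pd.read_csv(path, encoding="utf-8")
    orgs = []
    seen = set()
    for _, row in df.iterrows():
        oid = str(row["org_id"])
        if oid in seen:
            raise ValueError(f"duplicate org id {oid!r}")
        seen.add(oid)
        referred = row.get("referred_by")
        refs = (
            frozenset(x.strip() for x in str(referred).split("|") if x.strip())
            if not pd.isna(referred)
            else frozenset()
        )
        letter = row.get("letter_date")
        orgs.append(
            OrgRecord(
                id=oid,
                approached=bool(row["approached"]),
                participated=bool(row["participated"]),
                referred_by=refs,
                letter_of_support_date=(
                    date.fromisoformat(str(letter)) if not pd.isna(letter) else None
                ),
            )
        )
    return orgs


@dataclass
class ReferralSummary:
    """Engagement outcome tallies.

    Display percentages are truncated (floored) to 1 decimal — the
    convention of the reference engagement reports this summary mirrors
    (e.g. 32/77 shown as 41.5%).  The integer numerators and denominators
    are carried alongside, so exact rates are always recoverable."""

    approached: int
    participated: int
    participation_rate_pct: float
    participating_referrers: int
    participating_referrer_pct: float
    nonparticipating_referrers: int
    nonparticipating_referrer_pct: float


def _out_degree(orgs: Iterable[OrgRecord]) -> dict[str, int]:
    deg = {o.id: 0 for o in orgs}
    for o in orgs:
        for ref in o.referred_by:
            if ref in deg:
                deg[ref] += 1
    return deg


def summarize_referrals(orgs: Iterable[OrgRecord]) -> ReferralSummary:
    """Tally approached/participated organisations and, within each group,
    the share that referred at least one other organisation."""
    orgs = list(orgs)
    deg = _out_degree(orgs)
    approached = [o for o in orgs if o.approached]
    participated = [o for o in approached if o.participated]
    declined = [o for o in approached if not o.participated]

    def pct(num: int, den: int) -> float:
        # floor to 1 decimal; guard float error so exact ratios stay exact
        return math.floor(100.0 * num / den * 10 + 1e-9) / 10 if den else 0.0

    p_ref = sum(1 for o in participated if deg[o.id] > 0)
    np_ref = sum(1 for o in declined if deg[o.id] > 0)
    return ReferralSummary(
        approached=len(approached),
        participated=len(participated),
        participation_rate_pct=pct(len(participated), len(approached)),
        participating_referrers=p_ref,
        participating_referrer_pct=pct(p_ref, len(participated)),
        nonparticipating_referrers=np_ref,
        nonparticipating_referrer_pct=pct(np_ref, len(declined)),
    )


def referral_graph(orgs: Iterable[OrgRecord]) -> nx.DiGraph:
    """Directed referral graph: edge referrer -> referee.

    Node attributes: ``participated`` flag and ``out_degree`` (used as node
    size when drawing).  Dangling references are a hard error.  Cycles are
    legitimate — mutual referral happens.
    """
    orgs = list(orgs)
    ids = {o.id for o in orgs}
    g = nx.DiGraph()
    for o in orgs:
        g.add_node(o.id, participated=o.participated)
    for o in orgs:
        for ref in o.referred_by:
            if ref not in ids:
                raise ValueError(f"org {o.id} referred by unknown org {ref!r}")
            g.add_edge(ref, o.id)
    for node in g.nodes:
        g.nodes[node]["out_degree"] = g.out_degree(node)
    return g


def export_edge_list(g: nx.DiGraph, path: str | Path) -> None:
    pd.DataFrame(list(g.edges), columns=["referrer", "referee"]).to_csv(
        path, index=False
    )
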