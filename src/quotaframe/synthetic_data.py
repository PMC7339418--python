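"""Synthetic communities for end-to-end pipeline testing.

No individual-level data accompany the study design this package
implements, so every pipeline stage is exercised on generated inputs: a
finite population whose strata proportions match a given census profile,
service sites whose client tables are draws from that population, a
recruitment process that fills allocated quotas with attrition, and an
organisation-engagement log with a snowball referral digraph.

Everything is seed-deterministic.  Generator defaults emulate the study
conditions: an urban community of ~1860 eligible adults (the survey's 706
completes were 37.9% of it), attrition 24/730, log-normal survey durations
around 14.8 minutes, and engagement effort of ~22 vs ~17 contacts for
participating vs declining organisations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .quota_allocator import (
    AllocationPlan,
    allocate,
    allocate_residual,
    build_potential_table,
)
from .recruitment_monitor import (
    INCOMPLETE_REASONS,
    RESIDENCE_CATEGORIES,
    SurveyRecord,
)
from .site_registry import (
    OrgRecord,
    Site,
    SiteRegistry,
    eligibility_matrix,
)
from .strata_frame import (
    AGE_BANDS,
    GENDERS,
    CensusProfile,
    StrataTargets,
    Stratum,
    compute_strata_targets,
    sorted_strata,
)

__all__ = [
    "SiteSpec",
    "CommunitySpec",
    "default_census_profile",
    "default_spec",
    "gen_population",
    "gen_service_clients",
    "simulate_recruitment",
    "gen_engagement_fixture",
    "run_end_to_end",
    "end_to_end_fixture",
]

# Census gender x age-band percentages of the eligible (16+) population for
# the reference community, and its categorical marginals.
_CENSUS_CELL_PCT: dict[tuple[str, str], float] = {
    ("female", "16-24"): 12.24,
    ("female", "25-44"): 20.67,
    ("female", "45-64"): 14.65,
    ("female", "65+"): 4.24,
    ("male", "16-24"): 14.87,
    ("male", "25-44"): 18.73,
    ("male", "45-64"): 12.35,
    ("male", "65+"): 2.25,
}

# SES composition within each age band.  The census reference publishes the
# cell masses but not the SES split, so these shares are a fixed modelling
# choice: students concentrate in 16-24, workforce categories in the middle
# bands, and nearly everyone 65+ falls in the residual `general` category.
_SES_SPLIT_BY_BAND: dict[str, dict[str, float]] = {
    "16-24": {"full_time_worker": 0.15, "student": 0.35, "unemployed": 0.20, "homeless": 0.05, "general": 0.25},
    "25-44": {"full_time_worker": 0.35, "student": 0.08, "unemployed": 0.18, "homeless": 0.05, "general": 0.34},
    "45-64": {"full_time_worker": 0.35, "student": 0.02, "unemployed": 0.15, "homeless": 0.05, "general": 0.43},
    "65+": {"full_time_worker": 0.05, "student": 0.00, "unemployed": 0.05, "homeless": 0.03, "general": 0.87},
}

INCOME_BANDS: tuple[str, ...] = (
    "0-149", "150-299", "300-399", "400-599", "600-799", "800-999", "1000+",
)
# Weekly personal income distribution with median band 400-599.
_INCOME_PROBS: tuple[float, ...] = (0.10, 0.18, 0.15, 0.25, 0.14, 0.09, 0.09)

_RESIDENCE_PROBS: tuple[float, ...] = (0.891, 0.057, 0.014, 0.038)


def default_census_profile() -> CensusProfile:
    """Reference census profile: printed cell masses x modelled SES split."""
    props: dict[Stratum, float] = {}
    for (gender, band), cell_pct in _CENSUS_CELL_PCT.items():
        for ses, share in _SES_SPLIT_BY_BAND[band].items():
            p = cell_pct / 100.0 * share
            if p > 0:
                props[Stratum(gender, band, ses)] = p
    # absorb float round-off into the largest stratum so the sum is exactly 1
    gap = 1.0 - sum(props.values())
    biggest = max(props, key=props.get)
    props[biggest] += gap
    return CensusProfile(
        strata_proportions=props,
        population_size=1863,
        income_distribution=dict(zip(INCOME_BANDS, _INCOME_PROBS)),
        language_at_home=0.067,
        education_year10=0.8027,
    )


@dataclass(frozen=True)
class SiteSpec:
    """Blueprint for one synthetic site.

    ``coverage`` is the probability that an eligible community member is a
    current client of this site (per stratum when a mapping is given).
    """

    name: str
    type: str
    coverage: float | Mapping[str, float] = 0.3
    eligible_ses: Optional[frozenset[str]] = None
    is_general: bool = False
    general_capacity: int = 2000

    def coverage_for(self, ses: str) -> float:
        if isinstance(self.coverage, Mapping):
            return float(self.coverage.get(ses, 0.0))
        return float(self.coverage)


@dataclass
class CommunitySpec:
    """Parameters of the simulated community and recruitment process."""

    population_size: int = 1863
    census: CensusProfile = field(default_factory=default_census_profile)
    site_specs: list[SiteSpec] = field(default_factory=list)
    attendance_rate: float = 0.9  # chance a sampled client shows up at all
    attrition_p: float = 24.0 / 730.0
    attrition_reasons: dict[str, float] = field(
        default_factory=lambda: {"left_time": 12 / 24, "technical": 4 / 24, "discomfort": 8 / 24}
    )
    # log-minutes parameters giving mean ~14.8 min, SD ~6.3 min
    duration_mu: float = 2.6083
    duration_sigma: float = 0.4108
    max_age: int = 90  # ceiling for the open 65+ band
    seed: int = 20190701

    def __post_init__(self) -> None:
        if not (0.0 <= self.attrition_p <= 1.0):
            raise ValueError("attrition_p must be a probability")
        if not (0.0 <= self.attendance_rate <= 1.0):
            raise ValueError("attendance_rate must be a probability")
        rs = sum(self.attrition_reasons.values())
        if self.attrition_reasons and abs(rs - 1.0) > 1e-9:
            raise ValueError(f"attrition reason distribution sums to {rs}, not 1")
        for sp in self.site_specs:
            for ses in ("full_time_worker", "student", "unemployed", "homeless", "general"):
                if sp.coverage_for(ses) > 1.0:
                    raise ValueError(f"site {sp.name}: coverage > 1 for {ses}")


def _default_site_specs() -> list[SiteSpec]:
    return [
        SiteSpec("Community health service", "indigenous_health_service", 0.35),
        SiteSpec("Neighbourhood community group", "community_group", 0.25),
        SiteSpec("Adult education college", "indigenous_adult_education", 0.6),
        SiteSpec("Employment service", "unemployment_service", 0.5),
        SiteSpec("Housing support service", "public_housing_service", 0.3),
        SiteSpec("Hostel outreach", "homelessness_service", 0.7),
        SiteSpec("Mental health service", "mental_health_service", 0.2),
        SiteSpec("Drug and alcohol service", "aod_service", 0.2),
        SiteSpec("Shopping mall stall", "public_space", 0.5, is_general=True, general_capacity=3000),
        SiteSpec("Community festival", "public_event", 0.4, is_general=True, general_capacity=2000),
    ]


def default_spec(**overrides) -> CommunitySpec:
    spec = CommunitySpec(site_specs=_default_site_specs())
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# population


def gen_population(spec: CommunitySpec) -> pd.DataFrame:
    """Draw a finite population matching the census profile.

    Strata memberships are a single multinomial draw over census
    proportions; ages are uniform within bands (the open 65+ band truncated
    at ``spec.max_age``); income band, language-at-home and Year-10 flags
    are independent draws from the census marginals.
    """
    spec.census.validate()
    rng = np.random.default_rng(spec.seed)
    strata = sorted_strata(spec.census.strata_proportions)
    probs = np.array([spec.census.strata_proportions[s] for s in strata])
    counts = rng.multinomial(spec.population_size, probs / probs.sum())

    frames = []
    next_id = 0
    for s, n in zip(strata, counts):
        if n == 0:
            continue
        band = next(b for b in AGE_BANDS if b.label == s.age_band)
        hi = band.upper if band.upper is not None else spec.max_age
        ages = rng.integers(band.lower, hi + 1, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": np.arange(next_id, next_id + n),
                    "gender": s.gender,
                    "age_band": s.age_band,
                    "age": ages,
                    "ses": s.ses,
                }
            )
        )
        next_id += n
    pop = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["individual_id", "gender", "age_band", "age", "ses"]
    )
    n = len(pop)
    income = spec.census.income_distribution or dict(zip(INCOME_BANDS, _INCOME_PROBS))
    bands = list(income)
    pop["income_band"] = rng.choice(bands, size=n, p=np.array(list(income.values())))
    pop["language_at_home"] = rng.random(n) < (spec.census.language_at_home or 0.0)
    pop["education_year10"] = rng.random(n) < (spec.census.education_year10 or 0.0)
    pop["residence"] = rng.choice(RESIDENCE_CATEGORIES, size=n, p=_RESIDENCE_PROBS)
    return pop


# ---------------------------------------------------------------------------
# service client tables


def gen_service_clients(
    population: pd.DataFrame, spec: CommunitySpec
) -> SiteRegistry:
    """Build the site registry by sampling each site's clients from the
    population.

    Per site and stratum, each eligible individual is a client with the
    site's coverage probability (so client tables overlap across sites, as
    real service populations do).  The registry carries a ``members``
    mapping (site id -> stratum -> individual ids) used by
    :func:`simulate_recruitment`; the reported ``client_counts`` are the
    member counts.
    """
    from .site_registry import DEFAULT_SES_ELIGIBILITY

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    registry = SiteRegistry()
    members: dict[str, dict[Stratum, np.ndarray]] = {}
    by_stratum = {
        Stratum(g, b, s): grp["individual_id"].to_numpy()
        for (g, b, s), grp in population.groupby(["gender", "age_band", "ses"])
    }
    for i, sp in enumerate(spec.site_specs):
        sid = f"site{i:02d}"
        eligible = sp.eligible_ses
        if eligible is None:
            eligible = DEFAULT_SES_ELIGIBILITY.get(sp.type, frozenset())
        site_members: dict[Stratum, np.ndarray] = {}
        counts: dict[Stratum, int] = {}
        for stratum, ids in by_stratum.items():
            cov = sp.coverage_for(stratum.ses)
            reachable = sp.is_general or stratum.ses in eligible
            if not reachable or cov <= 0.0 or ids.size == 0:
                continue
            mask = rng.random(ids.size) < cov
            chosen = ids[mask]
            if chosen.size:
                site_members[stratum] = chosen
                if not sp.is_general or stratum.ses == "general":
                    # general sites do not report client lists; their
                    # non-general members only matter for spill recruitment
                    counts[stratum] = int(chosen.size)
        registry.add(
            Site(
                id=sid,
                name=sp.name,
                type=sp.type,
                eligible_ses=frozenset(eligible) | ({"general"} if sp.is_general else set()),
                client_counts={} if sp.is_general else counts,
                is_general=sp.is_general,
                general_capacity=sp.general_capacity,
            )
        )
        members[sid] = site_members
    registry.members = members  # type: ignore[attr-defined]
    return registry


# ---------------------------------------------------------------------------
# recruitment simulation


_STUDY_START = date(2019, 7, 1)
_N_COLLECTION_DAYS = 36


def simulate_recruitment(
    plan: AllocationPlan,
    registry: SiteRegistry,
    population: pd.DataFrame,
    spec: CommunitySpec,
    seed: Optional[int] = None,
) -> list[SurveyRecord]:
    """Run the fieldwork implied by an allocation plan.

    For each (site, stratum) quota, that many distinct synthetic attendees
    are drawn from the site's members in the stratum; nobody completes the
    survey twice (tracked by synthetic id — a capability the anonymous real
    fieldwork lacked).  Each commenced survey is independently incomplete
    with probability ``spec.attrition_p`` (reason from the configured
    distribution) and gets a log-normal duration in minutes.  A quota
    exceeding the site's remaining attendees recruits what exists and logs
    the shortfall in ``plan.log``.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed if seed is None else seed, 2])
    )
    members: Mapping[str, Mapping[Stratum, np.ndarray]] = getattr(
        registry, "members", {}
    )
    pop = population.set_index("individual_id")
    surveyed: set[int] = set()
    records: list[SurveyRecord] = []
    reasons = list(spec.attrition_reasons) or ["other"]
    reason_p = (
        np.array([spec.attrition_reasons[r] for r in reasons])
        if spec.attrition_reasons
        else np.array([1.0])
    )
    rid = 0
    for (sid, stratum), quota in sorted(
        plan.quotas.items(), key=lambda kv: (kv[0][0], kv[0][1].sort_key)
    ):
        pool = members.get(sid, {}).get(stratum, np.empty(0, dtype=int))
        pool = np.array([i for i in pool if i not in surveyed], dtype=int)
        if spec.attendance_rate < 1.0 and pool.size:
            pool = pool[rng.random(pool.size) < spec.attendance_rate]
        k = min(quota, pool.size)
        if k < quota:
            plan.log.append(
                f"shortfall at {sid} / {stratum}: wanted {quota}, attendees {k}"
            )
        if k == 0:
            continue
        chosen = rng.choice(pool, size=k, replace=False)
        surveyed.update(int(c) for c in chosen)
        incomplete = rng.random(k) < spec.attrition_p
        durations = np.exp(rng.normal(spec.duration_mu, spec.duration_sigma, size=k))
        day_offsets = rng.integers(0, _N_COLLECTION_DAYS, size=k)
        for j, ind in enumerate(chosen):
            row = pop.loc[int(ind)]
            status = "incomplete" if incomplete[j] else "complete"
            reason = (
                reasons[rng.choice(len(reasons), p=reason_p)]
                if incomplete[j]
                else None
            )
            records.append(
                SurveyRecord(
                    record_id=f"r{rid:06d}",
                    date=_STUDY_START + timedelta(days=int(day_offsets[j]) * 3),
                    site_id=sid,
                    status=status,
                    gender=str(row["gender"]),
                    age=float(row["age"]),
                    ses=str(row["ses"]),
                    incomplete_reason=reason,
                    duration_min=float(max(durations[j], 1.0)),
                    residence=str(row["residence"]),
                    income_band=str(row["income_band"]),
                    language_at_home=bool(row["language_at_home"]),
                    education_year10=bool(row["education_year10"]),
                )
            )
            rid += 1
    return records


# ---------------------------------------------------------------------------
# engagement fixture


def gen_engagement_fixture(
    seed: int,
    n_approached: int = 77,
    n_participated: int = 32,
    mean_contacts_participated: float = 22.1,
    mean_contacts_declined: float = 17.2,
    referral_p: float = 0.45,
) -> tuple[list[OrgRecord], pd.DataFrame]:
    """Synthetic organisation table and contact log.

    Referrals form a simple random digraph (each organisation referred by an
    earlier-approached one with probability ``referral_p``); per-organisation
    contact counts are Poisson with group-specific means, channels drawn
    with the empirical channel mix, phone durations exponential (mean 0.05 h
    per call).  Returns (org records, contacts DataFrame).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    ids = [f"org{i:02d}" for i in range(n_approached)]
    participated = set(rng.choice(n_approached, size=n_participated, replace=False))
    referred_by: dict[str, set[str]] = {i: set() for i in ids}
    for i in range(1, n_approached):
        if rng.random() < referral_p:
            referred_by[ids[i]].add(ids[int(rng.integers(0, i))])
    orgs = []
    start = date(2019, 1, 15)
    for i, oid in enumerate(ids):
        took_part = i in participated
        orgs.append(
            OrgRecord(
                id=oid,
                approached=True,
                participated=took_part,
                referred_by=frozenset(referred_by[oid]),
                letter_of_support_date=(
                    start + timedelta(days=int(rng.integers(30, 150)))
                    if took_part
                    else None
                ),
            )
        )
    channel_mix = np.array([610, 539, 33, 34, 1], dtype=float)
    channel_mix /= channel_mix.sum()
    channels = ("email", "phone", "text", "meeting", "facebook")
    rows = []

    def add_contact(org_id: str, d: date, before: bool) -> None:
        ch = channels[rng.choice(len(channels), p=channel_mix)]
        rows.append(
            {
                "org_id": org_id,
                "date": d.isoformat(),
                "channel": ch,
                "duration_hours": (
                    round(float(rng.exponential(0.05)), 3)
                    if ch in ("phone", "meeting")
                    else None
                ),
                "before_agreement": before,
            }
        )

    for org in orgs:
        lam = mean_contacts_participated if org.participated else mean_contacts_declined
        cutoff = org.letter_of_support_date
        # engagement effort concentrates before the agree/decline decision
        pre_days = (cutoff - start).days if cutoff is not None else 270
        for _ in range(int(rng.poisson(lam))):
            add_contact(org.id, start + timedelta(days=int(rng.integers(0, pre_days))), True)
        if cutoff is not None:
            # coordination during data collection continues after agreement
            for _ in range(int(rng.poisson(5.0))):
                add_contact(
                    org.id,
                    cutoff + timedelta(days=int(rng.integers(0, 120))),
                    False,
                )
    contacts = pd.DataFrame(
        rows, columns=["org_id", "date", "channel", "duration_hours", "before_agreement"]
    )
    return orgs, contacts


# ---------------------------------------------------------------------------
# end-to-end


def run_end_to_end(
    spec: CommunitySpec | None = None,
    n_target: int = 700,
    attrition: Optional[float] = None,
) -> dict:
    """Full pipeline on one synthetic community.

    population -> service client tables -> strata targets -> randomized
    allocation (named strata) + proportional residual allocation (general
    strata) -> recruitment simulation -> representativeness report.

    Returns a dict with every intermediate artefact.
    """
    from .representativeness import compare_to_census

    spec = spec or default_spec()
    if attrition is not None:
        spec = replace(spec, attrition_p=attrition)
    population = gen_population(spec)
    registry = gen_service_clients(population, spec)
    targets = compute_strata_targets(spec.census, n_target)
    frame = list(targets.targets)
    table = build_potential_table(registry, frame)
    elig = eligibility_matrix(registry, frame)
    named = StrataTargets(
        n_target=sum(t for s, t in targets.targets.items() if s.ses != "general"),
        targets={s: t for s, t in targets.targets.items() if s.ses != "general"},
        raw={s: r for s, r in targets.raw.items() if s.ses != "general"},
    )
    plan = allocate(named, table, elig, seed=spec.seed, registry=registry)
    residual = {s: t for s, t in targets.targets.items() if s.ses == "general"}
    plan = allocate_residual(plan, registry, residual)
    records = simulate_recruitment(plan, registry, population, spec)
    report = compare_to_census(records, spec.census)
    return {
        "spec": spec,
        "population": population,
        "registry": registry,
        "targets": targets,
        "table": table,
        "eligibility": elig,
        "plan": plan,
        "records": records,
        "report": report,
    }


def _write_census(profile: CensusProfile, outdir: Path) -> None:
    rows = [
        {"gender": s.gender, "age_band": s.age_band, "ses": s.ses, "proportion": p}
        for s, p in sorted(
            profile.strata_proportions.items(), key=lambda kv: kv[0].sort_key
        )
    ]
    pd.DataFrame(rows).to_csv(outdir / "census.csv", index=False)
    marginals = {
        "population_size": profile.population_size,
        "income_distribution": profile.income_distribution,
        "language_at_home": profile.language_at_home,
        "education_year10": profile.education_year10,
    }
    (outdir / "census_marginals.json").write_text(
        json.dumps(marginals, indent=2), encoding="utf-8"
    )


def _write_sites(registry: SiteRegistry, outdir: Path) -> None:
    strata = sorted_strata(
        {s for site in registry for s in site.client_counts}
    )
    rows = []
    for site in registry:
        row = {
            "site_id": site.id,
            "name": site.name,
            "type": site.type,
            "is_general": site.is_general,
            "eligible_ses": "|".join(sorted(site.eligible_ses)),
            "general_capacity": site.general_capacity,
        }
        for s in strata:
            row[f"{s.gender}:{s.age_band}:{s.ses}"] = site.client_counts.get(s, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "sites.csv", index=False)


def _write_records(records: Sequence[SurveyRecord], outdir: Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "date": r.date.isoformat(),
                "site_id": r.site_id,
                "status": r.status,
                "gender": r.gender,
                "age": r.age,
                "ses": r.ses,
                "incomplete_reason": r.incomplete_reason,
                "duration_min": r.duration_min,
                "residence": r.residence,
                "income_band": r.income_band,
                "language_at_home": r.language_at_home,
                "education_year10": r.education_year10,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "records.csv", index=False)


def end_to_end_fixture(
    spec: CommunitySpec | None = None,
    outdir: str | Path = "fixture",
    n_target: int = 700,
) -> Path:
    """Write a complete, internally consistent input bundle to ``outdir``:
    census.csv (+ marginals JSON), sites.csv, records.csv, orgs.csv,
    contacts.csv and plan.csv, all loadable by the pipeline's readers."""
    spec = spec or default_spec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = run_end_to_end(spec, n_target=n_target)
    _write_census(spec.census, outdir)
    _write_sites(result["registry"], outdir)
    _write_records(result["records"], outdir)
    result["plan"].to_frame().to_csv(outdir / "plan.csv", index=False)
    orgs, contacts = gen_engagement_fixture(seed=spec.seed)
    pd.DataFrame(
        [
            {
                "org_id": o.id,
                "approached": o.approached,
                "participated": o.participated,
                "referred_by": "|".join(sorted(o.referred_by)),
                "letter_date": (
                    o.letter_of_support_date.isoformat()
                    if o.letter_of_support_date
                    else None
                ),
            }
            for o in orgs
        ]
    ).to_csv(outdir / "orgs.csv", index=False)
    contacts.to_csv(outdir / "contacts.csv", index=False)
    meta = {
        "seed": spec.seed,
        "population_size": spec.population_size,
        "n_target": n_target,
        "unmet": {str(s): v for s, v in result["plan"].unmet.items()},
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
    return outdir
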