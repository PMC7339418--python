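"""Shared fixtures: the printed reference tables and small registries."""

from __future__ import annotations

from datetime import date

import pytest

from quotaframe.site_registry import OrgRecord, Site, SiteRegistry
from quotaframe.strata_frame import CensusProfile, Stratum

# Gender x age-band composition of the reference census and the achieved
# sample (counts; total 706).
CELLS = [
    ("female", "16-24"),
    ("female", "25-44"),
    ("female", "45-64"),
    ("female", "65+"),
    ("male", "16-24"),
    ("male", "25-44"),
    ("male", "45-64"),
    ("male", "65+"),
]
SAMPLE_COUNTS = dict(zip(CELLS, [89, 145, 103, 35, 99, 131, 88, 16]))
CENSUS_PCT = dict(zip(CELLS, [12.24, 20.67, 14.65, 4.24, 14.87, 18.73, 12.35, 2.25]))
PRINTED_SAMPLE_PCT = dict(
    zip(CELLS, [12.61, 20.54, 14.59, 4.96, 14.02, 18.56, 12.46, 2.27])
)
PRINTED_DIFF_PCT = dict(
    zip(CELLS, [0.37, -0.13, -0.06, 0.72, -0.85, -0.18, 0.12, 0.01])
)
# Three of the printed male differences (-0.18, 0.12, 0.01) cannot be
# recovered from the printed counts and two-decimal census percentages by
# any rounding convention: subtracting the printed census values gives
# -0.17, 0.11 and 0.02.  The source evidently subtracted unrounded census
# proportions, so those cells reproduce only to one unit in the last digit.
DERIVABLE_DIFF_CELLS = [c for c in CELLS if c not in
                        {("male", "25-44"), ("male", "45-64"), ("male", "65+")}]


@pytest.fixture
def census_cells_profile() -> CensusProfile:
    """Eight-cell census profile (gender x age, SES collapsed to general)."""
    return CensusProfile(
        strata_proportions={
            Stratum(g, b, "general"): p / 100.0 for (g, b), p in CENSUS_PCT.items()
        },
        population_size=1863,
        income_distribution={"0-299": 0.3, "300-599": 0.4, "600+": 0.3},
        language_at_home=0.067,
        education_year10=0.8027,
    )


@pytest.fixture
def small_registry() -> SiteRegistry:
    s = Stratum("male", "16-24", "unemployed")
    return SiteRegistry(
        [
            Site(
                id="svcA",
                name="Employment service A",
                type="unemployment_service",
                eligible_ses=frozenset({"unemployed"}),
                client_counts={s: 30},
            ),
            Site(
                id="svcB",
                name="Employment service B",
                type="unemployment_service",
                eligible_ses=frozenset({"unemployed"}),
                client_counts={s: 10},
            ),
            Site(
                id="mall",
                name="Shopping mall",
                type="public_space",
                eligible_ses=frozenset(
                    {"full_time_worker", "student", "unemployed", "homeless", "general"}
                ),
                is_general=True,
                general_capacity=100,
            ),
        ]
    )


def make_engagement_orgs() -> list[OrgRecord]:
    """77 approached organisations, 32 participating; 16 of the 32 and 19 of
    the 45 decliners have at least one outgoing referral."""
    ids = [f"o{i:02d}" for i in range(77)]
    participating = set(ids[:32])
    referrers = ids[:16] + ids[32 : 32 + 19]  # 16 participating + 19 declining
    referred_by: dict[str, set[str]] = {i: set() for i in ids}
    # hang every referrer's outgoing edge off the last few orgs (which are
    # themselves non-referrers: nobody lists them as a referrer)
    sinks = ids[60:]
    for k, ref in enumerate(referrers):
        referred_by[sinks[k % len(sinks)]].add(ref)
    return [
        OrgRecord(
            id=i,
            approached=True,
            participated=i in participating,
            referred_by=frozenset(referred_by[i]),
            letter_of_support_date=date(2019, 5, 1) if i in participating else None,
        )
        for i in ids
    ]


@pytest.fixture
def engagement_orgs() -> list[OrgRecord]:
    return make_engagement_orgs()
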