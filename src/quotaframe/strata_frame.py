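"""Census-anchored sampling frame: strata, census profiles and integer quotas.

The sampling frame is the cross of age band (16–24, 25–44, 45–64, 65+),
gender (female/male) and socioeconomic status (full-time worker, student,
unemployed, homeless, plus a residual ``general`` category carrying the
population mass outside the named strata).  A :class:`CensusProfile` holds
the census proportion of the eligible population in each stratum, and
:func:`compute_strata_targets` turns a target sample size into integer
per-stratum quotas by largest-remainder (Hamilton) apportionment, which
conserves the total exactly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "AgeBand",
    "Stratum",
    "CensusProfile",
    "StrataTargets",
    "ProfileDiagnostics",
    "AGE_BANDS",
    "GENDERS",
    "SES_CATEGORIES",
    "NAMED_SES",
    "band_for_age",
    "parse_age_band",
    "load_census_profile",
    "compute_strata_targets",
    "validate_profile",
    "largest_remainder_apportion",
]

GENDERS: tuple[str, ...] = ("female", "male")

#: SES categories; ``general`` is the residual for population portions that
#: fall outside the four named strata (e.g. part-time employment).
SES_CATEGORIES: tuple[str, ...] = (
    "full_time_worker",
    "student",
    "unemployed",
    "homeless",
    "general",
)
NAMED_SES: tuple[str, ...] = SES_CATEGORIES[:-1]

MIN_ELIGIBLE_AGE = 16

_SUM_TOL = 1e-6


@dataclass(frozen=True, order=True)
class AgeBand:
    """A closed age band; ``upper`` is ``None`` for the open-ended 65+ band."""

    lower: int
    upper: Optional[int]
    label: str = field(compare=False)

    def contains(self, age: float) -> bool:
        if age < self.lower:
            return False
        return self.upper is None or age <= self.upper


AGE_BANDS: tuple[AgeBand, ...] = (
    AgeBand(16, 24, "16-24"),
    AgeBand(25, 44, "25-44"),
    AgeBand(45, 64, "45-64"),
    AgeBand(65, None, "65+"),
)

_BAND_BY_LABEL = {b.label: b for b in AGE_BANDS}
_BAND_INDEX = {b.label: i for i, b in enumerate(AGE_BANDS)}


def parse_age_band(label: str) -> AgeBand:
    """Resolve an age-band label; en dash, em dash and hyphen all accepted."""
    norm = (
        str(label)
        .strip()
        .replace("–", "-")
        .replace("—", "-")
        .replace(" ", "")
    )
    if norm not in _BAND_BY_LABEL:
        raise ValueError(
            f"unknown age band {label!r}; expected one of {sorted(_BAND_BY_LABEL)}"
        )
    return _BAND_BY_LABEL[norm]


def band_for_age(age: float) -> AgeBand:
    """Band containing ``age``; bands are closed on the left, so 25 -> 25-44."""
    if age < MIN_ELIGIBLE_AGE:
        raise ValueError(f"age {age} below minimum eligible age {MIN_ELIGIBLE_AGE}")
    for band in AGE_BANDS:
        if band.contains(age):
            return band
    raise AssertionError("unreachable: bands cover [16, inf)")


@dataclass(frozen=True)
class Stratum:
    """One cell of the sampling frame: age band x gender x SES."""

    gender: str
    age_band: str
    ses: str

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        object.__setattr__(self, "age_band", parse_age_band(self.age_band).label)
        if self.ses not in SES_CATEGORIES:
            raise ValueError(
                f"unknown SES category {self.ses!r}; expected one of {SES_CATEGORIES}"
            )

    @property
    def sort_key(self) -> tuple[int, int, int]:
        return (
            GENDERS.index(self.gender),
            _BAND_INDEX[self.age_band],
            SES_CATEGORIES.index(self.ses),
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.gender}/{self.age_band}/{self.ses}"


def sorted_strata(strata: Iterable[Stratum]) -> list[Stratum]:
    """Canonical stratum order: gender, then age band, then SES."""
    return sorted(strata, key=lambda s: s.sort_key)


@dataclass
class CensusProfile:
    """Census proportions per stratum plus marginal categorical distributions.

    This is the reference standard both for strata targets and for the
    post-hoc representativeness assessment.  ``strata_proportions`` are
    fractions of the eligible population and must sum to 1 (the residual
    ``general`` category included).
    """

    strata_proportions: dict[Stratum, float]
    population_size: Optional[int] = None
    income_distribution: Optional[dict[str, float]] = None
    language_at_home: Optional[float] = None
    education_year10: Optional[float] = None

    def validate(self, tol: float = _SUM_TOL) -> None:
        for s, p in self.strata_proportions.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"proportion for {s} out of [0,1]: {p}")
        total = sum(self.strata_proportions.values())
        if self.strata_proportions and abs(total - 1.0) > tol:
            raise ValueError(
                f"strata proportions sum to {total:.6f}; residual {1.0 - total:+.6f}"
            )
        if self.income_distribution is not None:
            isum = sum(self.income_distribution.values())
            if abs(isum - 1.0) > 1e-4:
                raise ValueError(f"income distribution sums to {isum:.6f}, not 1")

    def gender_age_percentages(self) -> dict[tuple[str, str], float]:
        """Census % per (gender, age band) cell, SES marginalised out."""
        cells: dict[tuple[str, str], float] = {}
        for s, p in self.strata_proportions.items():
            key = (s.gender, s.age_band)
            cells[key] = cells.get(key, 0.0) + 100.0 * p
        return cells

    def strata(self) -> list[Stratum]:
        return sorted_strata(self.strata_proportions)


@dataclass
class StrataTargets:
    """Integer per-stratum quotas for a chosen sample size.

    Invariant: ``sum(targets.values()) == n_target`` exactly, and every
    integer target is within 1 of its unrounded quota.
    """

    n_target: int
    targets: dict[Stratum, int]
    raw: dict[Stratum, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gender": s.gender,
                "age_band": s.age_band,
                "ses": s.ses,
                "raw": self.raw[s],
                "target": self.targets[s],
            }
            for s in sorted_strata(self.targets)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# apportionment


def largest_remainder_apportion(
    raw: Mapping[Stratum, float], n_total: int
) -> dict[Stratum, int]:
    """Hamilton apportionment: floor every quota, then hand the leftover
    units to the largest fractional remainders.  Ties break by canonical
    stratum order so results are reproducible."""
    order = sorted_strata(raw)
    floors = {s: math.floor(raw[s]) for s in order}
    leftover = n_total - sum(floors.values())
    if leftover < 0:  # only possible with inconsistent inputs
        raise ValueError("raw quotas exceed the total; proportions sum past 1")
    by_remainder = sorted(
        order, key=lambda s: (-(raw[s] - floors[s]), s.sort_key)
    )
    out = dict(floors)
    for s in by_remainder[:leftover]:
        out[s] += 1
    return out


def _half_even_apportion(
    raw: Mapping[Stratum, float], n_total: int
) -> dict[Stratum, int]:
    # Banker's rounding per cell, then repair the total deterministically so
    # conservation still holds (adjust the cells that distort quotas least).
    order = sorted_strata(raw)
    out = {s: int(round(raw[s])) for s in order}
    while sum(out.values()) > n_total:
        cands = [s for s in order if out[s] > 0]
        s = min(cands, key=lambda s: (raw[s] - (out[s] - 1), s.sort_key))
        out[s] -= 1
    while sum(out.values()) < n_total:
        s = min(order, key=lambda s: ((out[s] + 1) - raw[s], s.sort_key))
        out[s] += 1
    return out


def compute_strata_targets(
    profile: CensusProfile,
    n_target: int,
    rounding: str = "largest_remainder",
) -> StrataTargets:
    """Multiply the target sample size by each stratum's census proportion
    and round to integers, conserving ``n_target`` exactly.

    Parameters
    ----------
    profile:
        Validated census profile.
    n_target:
        Desired total sample size (persons), >= 1.
    rounding:
        ``"largest_remainder"`` (default, Hamilton) or ``"half_even"``.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    profile.validate()
    raw = {s: n_target * p for s, p in profile.strata_proportions.items()}
    if rounding == "largest_remainder":
        targets = largest_remainder_apportion(raw, n_target)
    elif rounding == "half_even":
        targets = _half_even_apportion(raw, n_target)
    else:
        raise ValueError(f"unknown rounding method {rounding!r}")
    n_nonzero = sum(1 for p in profile.strata_proportions.values() if p > 0)
    if n_target < n_nonzero:
        warnings.warn(
            f"n_target={n_target} below the {n_nonzero} nonzero strata; "
            "some targets are zero",
            stacklevel=2,
        )
    return StrataTargets(n_target=n_target, targets=targets, raw=raw)


# ---------------------------------------------------------------------------
# I/O and diagnostics


def _detect_scale(total: float) -> float:
    """Proportions accepted as percentages or fractions, auto-detected."""
    if abs(total - 100.0) <= 1.0:
        return 100.0
    return 1.0


def load_census_profile(
    path: str | Path,
    marginals_path: str | Path | None = None,
    normalize: bool = False,
    expected_strata: Sequence[Stratum] | None = None,
    tol: float = _SUM_TOL,
) -> CensusProfile:
    """Read a census profile from CSV (columns gender, age_band, ses,
    proportion) or JSON.

    Percent-scale inputs (summing near 100) are detected and divided by 100.
    With ``normalize=False`` (strict, the default) proportions must sum to 1
    within ``tol`` after rescaling; otherwise they are renormalised.
    ``expected_strata``, when given, makes absent strata a hard error.
    """
    path = Path(path)
    marginals: dict = {}
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        rows = pd.DataFrame(payload["strata"])
        marginals = {k: v for k, v in payload.items() if k != "strata"}
    else:
        rows = pd.read_csv(path, encoding="utf-8")
    required = {"gender", "age_band", "ses", "proportion"}
    missing_cols = required - set(rows.columns)
    if missing_cols:
        raise ValueError(f"census profile missing columns: {sorted(missing_cols)}")

    props: dict[Stratum, float] = {}
    for _, row in rows.iterrows():
        s = Stratum(str(row["gender"]), str(row["age_band"]), str(row["ses"]))
        if s in props:
            raise ValueError(f"duplicate stratum row: {s}")
        p = float(row["proportion"])
        if math.isnan(p):
            raise ValueError(f"missing proportion for stratum {s}")
        props[s] = p

    if expected_strata is not None:
        absent = [s for s in expected_strata if s not in props]
        if absent:
            raise ValueError(
                "missing stratum rows: " + ", ".join(str(s) for s in absent)
            )

    total = sum(props.values())
    scale = _detect_scale(total)
    props = {s: p / scale for s, p in props.items()}
    total = sum(props.values())
    if abs(total - 1.0) > tol:
        if normalize:
            props = {s: p / total for s, p in props.items()}
        else:
            raise ValueError(
                f"strata proportions sum to {total:.6f}; residual {1.0 - total:+.6f} "
                "(pass normalize=True to rescale)"
            )

    if marginals_path is not None:
        marginals.update(
            json.loads(Path(marginals_path).read_text(encoding="utf-8"))
        )

    income = marginals.get("income_distribution")
    if income is not None:
        isum = sum(income.values())
        if abs(isum - 100.0) <= 1.0:  # percent scale
            income = {k: v / 100.0 for k, v in income.items()}
        income = dict(income)

    profile = CensusProfile(
        strata_proportions=props,
        population_size=marginals.get("population_size"),
        income_distribution=income,
        language_at_home=marginals.get("language_at_home"),
        education_year10=marginals.get("education_year10"),
    )
    profile.validate(tol=tol)
    return profile


@dataclass
class Finding:
    code: str
    message: str


@dataclass
class ProfileDiagnostics:
    findings: list[Finding]

    @property
    def ok(self) -> bool:
        return not self.findings

    def __iter__(self):
        return iter(self.findings)


def validate_profile(profile: CensusProfile) -> ProfileDiagnostics:
    """Report-only diagnostics: sum deviations, zero-proportion strata and
    absent marginals.  Never raises, never mutates the profile."""
    findings: list[Finding] = []
    if not profile.strata_proportions:
        findings.append(Finding("no_strata", "profile defines no strata"))
    else:
        total = sum(profile.strata_proportions.values())
        if abs(total - 1.0) > _SUM_TOL:
            findings.append(
                Finding(
                    "sum_deviation",
                    f"strata proportions sum to {total:.6f} (residual {1.0 - total:+.6f})",
                )
            )
        for s in profile.strata():
            if profile.strata_proportions[s] == 0.0:
                findings.append(Finding("zero_proportion", f"stratum {s} has proportion 0"))
    if profile.income_distribution is None:
        findings.append(Finding("missing_marginal", "income marginal absent"))
    elif abs(sum(profile.income_distribution.values()) - 1.0) > 1e-4:
        findings.append(Finding("income_sum", "income distribution does not sum to 1"))
    if profile.language_at_home is None:
        findings.append(Finding("missing_marginal", "language-at-home marginal absent"))
    if profile.education_year10 is None:
        findings.append(Finding("missing_marginal", "education marginal absent"))
    return ProfileDiagnostics(findings)
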