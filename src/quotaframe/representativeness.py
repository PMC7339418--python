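"""Post-hoc representativeness assessment against the census profile.

Compares the achieved (complete-record) sample with the census reference:
per-(gender, age band) sample percentages with signed differences, plot-
ready population-pyramid data, and categorical marginals that were *not*
used in the stratification (weekly income band, Indigenous language at
home, Year-10 completion) — agreement on those is the stronger evidence
that quota recruitment reached a representative cross-section.

Percentages are always recomputed from counts; differences are computed on
unrounded percentages and rounded last, so a printed table can be
reproduced exactly from its count column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .recruitment_monitor import SurveyRecord
from .strata_frame import AGE_BANDS, GENDERS, CensusProfile, band_for_age

__all__ = [
    "RepresentativenessReport",
    "strata_percentages",
    "compare_to_census",
    "compare_counts_to_census",
    "categorical_comparison",
    "median_income_band",
    "pyramid_data",
    "category_percentages",
]

Cell = tuple[str, str]  # (gender, age_band)


def _complete(records: Iterable[SurveyRecord]) -> list[SurveyRecord]:
    return [r for r in records if r.status == "complete"]


def _cell_counts(records: Iterable[SurveyRecord]) -> dict[Cell, int]:
    counts: dict[Cell, int] = {}
    for r in _complete(records):
        if r.gender is None or r.age is None:
            continue
        key = (r.gender, band_for_age(r.age).label)
        counts[key] = counts.get(key, 0) + 1
    return counts


def strata_percentages(
    records: Iterable[SurveyRecord],
) -> dict[Cell, tuple[int, float]]:
    """(n, unrounded %) per gender x age-band cell among complete records."""
    counts = _cell_counts(records)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no complete records with demographics")
    return {cell: (n, 100.0 * n / total) for cell, n in counts.items()}


@dataclass
class RepresentativenessReport:
    """Per-cell sample-vs-census comparison plus categorical marginals.

    ``rows`` columns: gender, age_band, n, sample_pct, census_pct, diff_pct
    (signed sample - census, rounded to 2 decimals after subtraction).
    ``flagged`` lists sample cells absent from the census reference.
    """

    rows: pd.DataFrame
    total_n: int
    max_abs_diff: float
    mean_abs_diff: float
    categorical: dict[str, tuple[float, Optional[float], Optional[float]]] = field(
        default_factory=dict
    )
    flagged: list[str] = field(default_factory=list)


def compare_counts_to_census(
    counts: Mapping[Cell, int], census_pct: Mapping[Cell, float]
) -> RepresentativenessReport:
    """Core comparison from raw cell counts and census percentages.

    Differences are formed on unrounded sample percentages; the summary
    max/mean |diff| use the unrounded values as well.
    """
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty sample")
    rows = []
    abs_diffs = []
    flagged = []
    cells = [(g, b.label) for g in GENDERS for b in AGE_BANDS]
    # keep any extra cells present in the data
    for cell in counts:
        if cell not in cells:
            cells.append(cell)
    for cell in cells:
        n = counts.get(cell, 0)
        if n == 0 and cell not in census_pct:
            continue
        sample_pct = 100.0 * n / total
        cpct = census_pct.get(cell)
        if cpct is None:
            flagged.append(f"cell {cell} absent from census reference")
            diff = None
        else:
            diff = sample_pct - cpct
            abs_diffs.append(abs(diff))
        rows.append(
            {
                "gender": cell[0],
                "age_band": cell[1],
                "n": n,
                "sample_pct": round(sample_pct, 2),
                "census_pct": round(cpct, 2) if cpct is not None else None,
                "diff_pct": round(diff, 2) if diff is not None else None,
            }
        )
    return RepresentativenessReport(
        rows=pd.DataFrame(rows),
        total_n=total,
        max_abs_diff=max(abs_diffs) if abs_diffs else 0.0,
        mean_abs_diff=sum(abs_diffs) / len(abs_diffs) if abs_diffs else 0.0,
        flagged=flagged,
    )


def compare_to_census(
    records: Iterable[SurveyRecord], profile: CensusProfile
) -> RepresentativenessReport:
    """Full report: gender x age cells plus whichever categorical marginals
    both the sample and the census profile carry."""
    records = list(records)
    report = compare_counts_to_census(
        _cell_counts(records), profile.gender_age_percentages()
    )
    for var, census_val in (
        ("language_at_home", profile.language_at_home),
        ("education_year10", profile.education_year10),
    ):
        try:
            sample_pct, cpct, diff = categorical_comparison(records, profile, var)
        except ValueError:
            continue
        report.categorical[var] = (sample_pct, cpct, diff)
    return report


def categorical_comparison(
    records: Iterable[SurveyRecord], profile: CensusProfile, variable: str
) -> tuple[float, Optional[float], Optional[float]]:
    """% of complete records with the flag set, vs the census marginal.

    Returns (sample %, census %, signed difference), percentages to 2
    decimals.  The variable being entirely unrecorded is an error —
    reporting 0% for a never-asked question would be misleading.
    """
    if variable not in ("language_at_home", "education_year10"):
        raise ValueError(f"unknown categorical variable {variable!r}")
    vals = [getattr(r, variable) for r in _complete(records)]
    known = [v for v in vals if v is not None]
    if not known:
        raise ValueError(f"variable {variable} entirely missing from records")
    sample_pct = round(100.0 * sum(known) / len(known), 2)
    census_prop = getattr(profile, variable)
    if census_prop is None:
        return sample_pct, None, None
    cpct = round(100.0 * census_prop, 2)
    return sample_pct, cpct, round(sample_pct - cpct, 2)


def median_income_band(
    records: Iterable[SurveyRecord], band_order: Sequence[str]
) -> dict[str, Optional[str]]:
    """Median weekly-income band, per gender and overall.

    The median of an ordered categorical is the band containing the 50th
    percentile; for even n the lower median is taken (position ceil(n/2) in
    the ordered sequence).  Returns None entries when no income was
    recorded for a group.
    """
    order = {b: i for i, b in enumerate(band_order)}
    groups: dict[str, list[str]] = {"overall": []}
    for r in _complete(records):
        if r.income_band is None:
            continue
        if r.income_band not in order:
            raise ValueError(f"income band {r.income_band!r} not in band_order")
        groups["overall"].append(r.income_band)
        if r.gender is not None:
            groups.setdefault(r.gender, []).append(r.income_band)
    if not groups["overall"]:
        import warnings

        warnings.warn("all income values missing", stacklevel=2)
        return {"overall": None}
    out: dict[str, Optional[str]] = {}
    for g, vals in groups.items():
        ranked = sorted(vals, key=order.__getitem__)
        out[g] = ranked[(len(ranked) + 1) // 2 - 1]  # lower median
    return out


def pyramid_data(report: RepresentativenessReport) -> pd.DataFrame:
    """Plot-ready population-pyramid table.

    One row per (gender, age band) with sample % and census %; female rows
    carry negated ``plot_*`` values so they extend left of the axis.
    """
    if report.rows.empty:
        return pd.DataFrame(
            columns=[
                "gender", "age_band", "sample_pct", "census_pct",
                "plot_sample_pct", "plot_census_pct",
            ]
        )
    df = report.rows[["gender", "age_band", "sample_pct", "census_pct"]].copy()
    sign = df["gender"].map({"female": -1.0, "male": 1.0})
    df["plot_sample_pct"] = df["sample_pct"] * sign
    df["plot_census_pct"] = df["census_pct"] * sign
    return df


def plot_pyramid(report: RepresentativenessReport, path: str) -> None:
    """Render the pyramid (sample bars against census outline) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pyramid_data(report)
    bands = [b.label for b in AGE_BANDS]
    fig, ax = plt.subplots(figsize=(6, 4))
    y = range(len(bands))
    for gender, color in (("female", "#444444"), ("male", "#bbbbbb")):
        sub = df[df["gender"] == gender].set_index("age_band")
        vals = [sub["plot_sample_pct"].get(b, 0.0) for b in bands]
        cens = [sub["plot_census_pct"].get(b, 0.0) for b in bands]
        ax.barh(list(y), vals, color=color, label=f"{gender} (sample)")
        ax.plot(cens, list(y), "k.--", linewidth=1)
    ax.set_yticks(list(y), bands)
    ax.set_xlabel("% of sample (females left, males right)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def category_percentages(
    values: Iterable[Optional[str]], decimals: int = 1
) -> pd.DataFrame:
    """Count/percentage table over a categorical field (e.g. recruitment
    site category or reported residence), descending by count."""
    vals = [v for v in values if v is not None]
    if not vals:
        return pd.DataFrame(columns=["category", "n", "pct"])
    counts = pd.Series(vals).value_counts()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "category": counts.index,
            "n": counts.values,
            "pct": [round(100.0 * int(n) / total, decimals) for n in counts.values],
        }
    ).reset_index(drop=True)
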