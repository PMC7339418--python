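"""Frame construction, census-profile I/O and integer apportionment."""

from __future__ import annotations

import itertools
import json
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quotaframe.strata_frame import (
    AGE_BANDS,
    CensusProfile,
    Stratum,
    band_for_age,
    compute_strata_targets,
    largest_remainder_apportion,
    load_census_profile,
    parse_age_band,
    sorted_strata,
    validate_profile,
)

from conftest import CELLS, CENSUS_PCT


def oracle_apportion(raw: dict, n: int) -> dict:
    """Independent largest-remainder oracle: enumerate which strata get the
    leftover units by maximising the total fractional remainder captured
    (ties resolved lexicographically by canonical order)."""
    order = sorted_strata(raw)
    floors = {s: math.floor(raw[s]) for s in order}
    k = n - sum(floors.values())
    best = None
    for combo in itertools.combinations(range(len(order)), k):
        score = sum(raw[order[i]] - floors[order[i]] for i in combo)
        key = (-score, combo)
        if best is None or key < best[0]:
            best = (key, combo)
    out = dict(floors)
    for i in best[1]:
        out[order[i]] += 1
    return out


class TestAgeBands:
    @pytest.mark.parametrize(
        "age,label",
        [(16, "16-24"), (24, "16-24"), (25, "25-44"), (44, "25-44"),
         (45, "45-64"), (64, "45-64"), (65, "65+"), (90, "65+")],
    )
    def test_closed_left_binning(self, age, label):
        assert band_for_age(age).label == label

    def test_under_sixteen_is_ineligible(self):
        with pytest.raises(ValueError):
            band_for_age(15)

    def test_dash_variants_accepted(self):
        assert parse_age_band("16–24").label == "16-24"  # en dash
        assert parse_age_band("25—44").label == "25-44"  # em dash
        assert parse_age_band("65+").label == "65+"

    def test_bands_are_disjoint_and_ordered(self):
        for a, b in zip(AGE_BANDS, AGE_BANDS[1:]):
            assert a.upper is not None and a.upper + 1 == b.lower


class TestCensusProfileIO:
    def test_printed_cell_percentages_load_and_sum_to_one(self, tmp_path):
        rows = "gender,age_band,ses,proportion\n" + "\n".join(
            f"{g},{b},general,{p}" for (g, b), p in CENSUS_PCT.items()
        )
        path = tmp_path / "census.csv"
        path.write_text(rows, encoding="utf-8")
        profile = load_census_profile(path)
        assert sum(profile.strata_proportions.values()) == pytest.approx(1.0, abs=1e-9)
        s = Stratum("female", "16-24", "general")
        assert profile.strata_proportions[s] == pytest.approx(0.1224)

    def test_single_stratum_profile_is_valid(self, tmp_path):
        path = tmp_path / "census.csv"
        path.write_text("gender,age_band,ses,proportion\nfemale,25-44,general,1.0")
        profile = load_census_profile(path)
        assert len(profile.strata_proportions) == 1

    def test_strict_mode_reports_the_residual(self, tmp_path):
        path = tmp_path / "census.csv"
        path.write_text(
            "gender,age_band,ses,proportion\n"
            "female,25-44,general,0.5\nmale,25-44,general,0.4"
        )
        with pytest.raises(ValueError, match=r"\+0\.10"):
            load_census_profile(path)
        profile = load_census_profile(path, normalize=True)
        assert sum(profile.strata_proportions.values()) == pytest.approx(1.0)

    def test_missing_expected_stratum_names_it(self, tmp_path):
        path = tmp_path / "census.csv"
        path.write_text("gender,age_band,ses,proportion\nfemale,25-44,general,1.0")
        with pytest.raises(ValueError, match="male/25-44/general"):
            load_census_profile(
                path,
                expected_strata=[
                    Stratum("female", "25-44", "general"),
                    Stratum("male", "25-44", "general"),
                ],
            )

    def test_marginals_sidecar(self, tmp_path):
        path = tmp_path / "census.csv"
        path.write_text("gender,age_band,ses,proportion\nfemale,25-44,general,1.0")
        sidecar = tmp_path / "marginals.json"
        sidecar.write_text(json.dumps({
            "population_size": 1863,
            "income_distribution": {"low": 0.5, "high": 0.5},
            "language_at_home": 0.067,
            "education_year10": 0.8027,
        }))
        profile = load_census_profile(path, marginals_path=sidecar)
        assert profile.population_size == 1863
        assert validate_profile(profile).ok


class TestValidateProfile:
    def test_complete_profile_has_no_findings(self, census_cells_profile):
        assert validate_profile(census_cells_profile).ok

    def test_missing_income_marginal_is_reported(self, census_cells_profile):
        census_cells_profile.income_distribution = None
        diag = validate_profile(census_cells_profile)
        assert any("income marginal absent" in f.message for f in diag)

    def test_empty_profile_is_reported(self):
        diag = validate_profile(CensusProfile(strata_proportions={}))
        assert any(f.code == "no_strata" for f in diag)


class TestStrataTargets:
    def test_raw_quota_is_size_times_proportion(self, census_cells_profile):
        t = compute_strata_targets(census_cells_profile, 700)
        assert t.raw[Stratum("female", "16-24", "general")] == pytest.approx(85.68)

    def test_printed_frame_apportionment(self, census_cells_profile):
        t = compute_strata_targets(census_cells_profile, 700)
        expected = dict(zip(CELLS, [86, 145, 102, 30, 104, 131, 86, 16]))
        got = {(s.gender, s.age_band): q for s, q in t.targets.items()}
        assert got == expected
        assert sum(t.targets.values()) == 700

    def test_symmetric_split(self):
        profile = CensusProfile(
            strata_proportions={
                Stratum("female", "25-44", "general"): 0.5,
                Stratum("male", "25-44", "general"): 0.5,
            }
        )
        t = compute_strata_targets(profile, 100)
        assert set(t.targets.values()) == {50}

    def test_half_even_rounding_also_conserves(self, census_cells_profile):
        t = compute_strata_targets(census_cells_profile, 700, rounding="half_even")
        assert sum(t.targets.values()) == 700

    def test_small_n_warns_not_errors(self, census_cells_profile):
        with pytest.warns(UserWarning, match="nonzero strata"):
            t = compute_strata_targets(census_cells_profile, 3)
        assert sum(t.targets.values()) == 3

    @given(
        props=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
        n=st.integers(1, 500),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_and_quota_property(self, props, n):
        """For any frame, integer targets sum to n exactly and each stays
        within 1 of its raw quota (Hamilton's quota property)."""
        total = sum(props)
        strata = [
            Stratum("female", AGE_BANDS[i % 4].label,
                    ["full_time_worker", "student", "unemployed", "homeless",
                     "general"][i % 5])
            for i in range(len(props))
        ]
        profile = CensusProfile(
            strata_proportions={s: p / total for s, p in zip(strata, props)}
        )
        t = compute_strata_targets(profile, n)
        assert sum(t.targets.values()) == n
        for s in strata:
            assert abs(t.targets[s] - t.raw[s]) < 1

    def test_matches_enumeration_oracle_on_small_frames(self):
        strata = [
            Stratum("female", b.label, "general") for b in AGE_BANDS
        ] + [Stratum("male", b.label, "general") for b in AGE_BANDS[:2]]
        raws = [
            [3.4, 2.1, 0.7, 1.9, 4.6, 2.3],
            [0.5, 0.5, 0.5, 0.5, 0.5, 0.5],  # all-tied remainders
            [1.25, 1.25, 1.25, 1.25, 2.5, 2.5],
        ]
        for raw_vals in raws:
            n = round(sum(raw_vals))
            raw = dict(zip(strata, raw_vals))
            assert largest_remainder_apportion(raw, n) == oracle_apportion(raw, n)

    def test_doubling_a_proportion_never_lowers_its_target(self):
        """Weak monotonicity, by enumeration over small frames."""
        import numpy as np

        rng = np.random.default_rng(7)
        bands = [b.label for b in AGE_BANDS]
        for _ in range(50):
            k = int(rng.integers(2, 5))
            props = rng.random(k) + 0.05
            strata = [Stratum("male", bands[i], "general") for i in range(k)]
            for n in (7, 23):
                base = dict(zip(strata, props / props.sum()))
                t0 = compute_strata_targets(
                    CensusProfile(strata_proportions=base), n
                ).targets
                boosted = props.copy()
                boosted[0] *= 2
                t1 = compute_strata_targets(
                    CensusProfile(
                        strata_proportions=dict(zip(strata, boosted / boosted.sum()))
                    ),
                    n,
                ).targets
                assert t1[strata[0]] >= t0[strata[0]]
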