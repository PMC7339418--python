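"""Randomized quota allocation: invariants, distribution, residuals,
rebalancing."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quotaframe.quota_allocator import (
    allocate,
    allocate_residual,
    build_potential_table,
    check_conservation,
    derive_day_seed,
    rebalance,
    PotentialTable,
)
from quotaframe.site_registry import Site, SiteRegistry, eligibility_matrix
from quotaframe.strata_frame import StrataTargets, Stratum

UNEMP = Stratum("male", "16-24", "unemployed")
GEN_F = Stratum("female", "25-44", "general")


def _targets(d: dict) -> StrataTargets:
    return StrataTargets(
        n_target=sum(d.values()), targets=dict(d), raw={s: float(v) for s, v in d.items()}
    )


def enumeration_mean(avail: list[int], n_draw: int) -> np.ndarray:
    """Exhaustive oracle: mean per-site counts over all ways of drawing
    ``n_draw`` labelled units from pooled availability (<= 8 units)."""
    units = [i for i, a in enumerate(avail) for _ in range(a)]
    assert len(units) <= 8
    sums = np.zeros(len(avail))
    n_combos = 0
    for combo in itertools.combinations(range(len(units)), n_draw):
        for u in combo:
            sums[units[u]] += 1
        n_combos += 1
    return sums / n_combos


class TestPotentialTable:
    def test_reported_clients_become_rows(self, small_registry):
        table = build_potential_table(small_registry, [UNEMP])
        assert ("svcA", UNEMP, 30) in table.rows
        assert table.total_by_stratum[UNEMP] == 40

    def test_zero_count_sites_contribute_no_rows(self):
        registry = SiteRegistry(
            [Site(id="s", name="S", type="community_group",
                  eligible_ses=frozenset({"unemployed"}), client_counts={})]
        )
        assert build_potential_table(registry, [UNEMP]).rows == []

    def test_general_sites_contribute_capacity_for_general_strata(self, small_registry):
        table = build_potential_table(small_registry, [UNEMP, GEN_F])
        assert ("mall", GEN_F, 100) in table.rows

    def test_nonpositive_row_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            PotentialTable(rows=[("s", UNEMP, 0)])


class TestAllocate:
    def test_single_site_gets_whole_quota(self, small_registry):
        registry = SiteRegistry([small_registry["svcA"]])
        table = build_potential_table(registry, [UNEMP])
        elig = eligibility_matrix(registry, [UNEMP])
        plan = allocate(_targets({UNEMP: 10}), table, elig, seed=1)
        assert plan.quotas[("svcA", UNEMP)] == 10
        assert plan.unmet == {}

    def test_shortfall_recorded_when_fallback_off(self, small_registry):
        table = build_potential_table(small_registry, [UNEMP])
        elig = eligibility_matrix(small_registry, [UNEMP])
        targets = _targets({UNEMP: 45})  # availability is 40 + mall
        with pytest.warns(UserWarning, match="unmet"):
            plan = allocate(targets, table, elig, seed=1, general_fallback=False)
        drawn = sum(
            q for (sid, s), q in plan.quotas.items() if sid in ("svcA", "svcB")
        )
        assert drawn == 40
        assert plan.unmet[UNEMP] == 5
        assert check_conservation(plan, targets)

    def test_shortfall_spills_to_general_sites(self, small_registry):
        table = build_potential_table(small_registry, [UNEMP])
        elig = eligibility_matrix(small_registry, [UNEMP])
        targets = _targets({UNEMP: 45})
        plan = allocate(targets, table, elig, seed=1, registry=small_registry)
        assert plan.quotas[("mall", UNEMP)] == 5
        assert plan.unmet == {}

    def test_uncovered_stratum_is_fully_unmet_with_warning(self):
        registry = SiteRegistry(
            [Site(id="cc", name="CC", type="childcare",
                  eligible_ses=frozenset({"student"}))]
        )
        table = build_potential_table(registry, [UNEMP])
        elig = eligibility_matrix(registry, [UNEMP])
        targets = _targets({UNEMP: 7})
        with pytest.warns(UserWarning, match="unmet"):
            plan = allocate(targets, table, elig, seed=3, general_fallback=False)
        assert plan.unmet[UNEMP] == 7

    def test_seed_determinism(self, small_registry):
        table = build_potential_table(small_registry, [UNEMP])
        elig = eligibility_matrix(small_registry, [UNEMP])
        t = _targets({UNEMP: 25})
        a = allocate(t, table, elig, seed=42, registry=small_registry)
        b = allocate(t, table, elig, seed=42, registry=small_registry)
        assert a.quotas == b.quotas and a.log == b.log

    @given(
        avail=st.lists(st.integers(0, 12), min_size=1, max_size=4),
        target=st.integers(0, 20),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=300, deadline=None)
    def test_invariants_hold_for_any_instance(self, avail, target, seed):
        """Conservation, eligibility and without-replacement for arbitrary
        small instances and seeds."""
        sites = [
            Site(id=f"s{i}", name=f"S{i}", type="community_group",
                 eligible_ses=frozenset({"unemployed"}),
                 client_counts={UNEMP: a} if a else {})
            for i, a in enumerate(avail)
        ]
        registry = SiteRegistry(sites)
        table = build_potential_table(registry, [UNEMP])
        elig = eligibility_matrix(registry, [UNEMP])
        targets = _targets({UNEMP: target})
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plan = allocate(targets, table, elig, seed=seed, general_fallback=False)
        assert check_conservation(plan, targets)
        for (sid, s), q in plan.quotas.items():
            assert q <= registry[sid].client_counts.get(s, 0)  # without replacement
            assert sid in elig[s]  # eligibility

    def test_mean_allocation_matches_hypergeometric_expectation(self):
        """Monte-Carlo means vs the exhaustive-enumeration oracle on a
        <= 8-unit instance (availability 5 and 3, draw 4)."""
        avail = [5, 3]
        n_draw = 4
        expected = enumeration_mean(avail, n_draw)
        # oracle equals the closed-form hypergeometric mean
        np.testing.assert_allclose(
            expected, [n_draw * a / sum(avail) for a in avail], atol=1e-12
        )
        sites = [
            Site(id=f"s{i}", name=f"S{i}", type="community_group",
                 eligible_ses=frozenset({"unemployed"}), client_counts={UNEMP: a})
            for i, a in enumerate(avail)
        ]
        registry = SiteRegistry(sites)
        table = build_potential_table(registry, [UNEMP])
        elig = eligibility_matrix(registry, [UNEMP])
        targets = _targets({UNEMP: n_draw})
        n_runs = 2000
        sums = np.zeros(2)
        for seed in range(n_runs):
            plan = allocate(targets, table, elig, seed=seed)
            sums += [plan.quotas.get((f"s{i}", UNEMP), 0) for i in range(2)]
        means = sums / n_runs
        # per-site variance of a hypergeometric count
        N = sum(avail)
        var = [
            n_draw * (a / N) * (1 - a / N) * (N - n_draw) / (N - 1) for a in avail
        ]
        se = np.sqrt(np.array(var) / n_runs)
        assert np.all(np.abs(means - expected) <= 3 * se)


class TestResidual:
    def _registry(self, caps):
        return SiteRegistry(
            [
                Site(id=f"g{i}", name=f"G{i}", type="public_space",
                     eligible_ses=frozenset({"general"}), is_general=True,
                     general_capacity=c)
                for i, c in enumerate(caps)
            ]
        )

    def _empty_plan(self):
        from quotaframe.quota_allocator import AllocationPlan

        return AllocationPlan(quotas={}, seed=0)

    def test_equal_capacities_split_evenly(self):
        plan = allocate_residual(self._empty_plan(), self._registry([50, 50]), {GEN_F: 20})
        assert plan.quotas[("g0", GEN_F)] == 10
        assert plan.quotas[("g1", GEN_F)] == 10

    def test_two_to_one_capacities(self):
        plan = allocate_residual(self._empty_plan(), self._registry([100, 50]), {GEN_F: 21})
        assert plan.quotas[("g0", GEN_F)] == 14
        assert plan.quotas[("g1", GEN_F)] == 7

    def test_zero_residual_is_identity(self):
        base = self._empty_plan()
        plan = allocate_residual(base, self._registry([50]), {GEN_F: 0})
        assert plan.quotas == {}

    def test_no_general_site_is_fatal(self):
        registry = SiteRegistry(
            [Site(id="s", name="S", type="community_group",
                  eligible_ses=frozenset({"unemployed"}))]
        )
        with pytest.raises(ValueError, match="no general-community site"):
            allocate_residual(self._empty_plan(), registry, {GEN_F: 5})

    def test_non_general_stratum_rejected(self):
        with pytest.raises(ValueError, match="non-general"):
            allocate_residual(self._empty_plan(), self._registry([50]), {UNEMP: 5})


class TestRebalance:
    def _setup(self, small_registry):
        table = build_potential_table(small_registry, [UNEMP])
        elig = eligibility_matrix(small_registry, [UNEMP])
        targets = _targets({UNEMP: 20})
        plan = allocate(targets, table, elig, seed=11, registry=small_registry)
        return table, elig, targets, plan

    def test_over_recruitment_flags_and_zeroes_quota(self, small_registry):
        table, elig, _, plan = self._setup(small_registry)
        targets = _targets({UNEMP: 86})
        new = rebalance(plan, {UNEMP: 89}, targets, table, elig)
        assert new.over_recruited[UNEMP] == 3
        assert sum(q for (s, st_), q in new.quotas.items() if st_ == UNEMP) == 0

    def test_exactly_met_targets_give_empty_plan(self, small_registry):
        table, elig, targets, plan = self._setup(small_registry)
        new = rebalance(plan, {UNEMP: 20}, targets, table, elig)
        assert new.total_quota() == 0
        assert new.over_recruited == {}

    def test_no_progress_equals_fresh_allocation_on_derived_seed(self, small_registry):
        table, elig, targets, plan = self._setup(small_registry)
        new = rebalance(plan, {UNEMP: 0}, targets, table, elig,
                        registry=small_registry, day_index=4)
        direct = allocate(targets, table, elig,
                          seed=derive_day_seed(11, 4), registry=small_registry)
        assert new.quotas == direct.quotas

    def test_day_seeds_differ_but_are_reproducible(self):
        assert derive_day_seed(11, 1) != derive_day_seed(11, 2)
        assert derive_day_seed(11, 1) == derive_day_seed(11, 1)
        assert 0 <= derive_day_seed(11, 1) < 2**31
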