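"""Randomized allocation of stratum quotas to eligible recruitment sites.

The central mechanism: each organisation reports how many clients it
currently serves per stratum; pooling those reports gives a *table of
potential participants*.  For every stratum, the target quota is filled by
drawing that many units uniformly at random **without replacement** from
the stratum's pooled potential participants across its eligible sites; a
site's quota is the number of units drawn from it.  Equivalently the vector
of per-site quotas is a multivariate hypergeometric draw, so across seeds
E[quota(site)] = target x available(site) / total_available — sites are
visited in proportion to where the population actually is.

Residual (``general``-SES) quotas go to general-community sites
proportionally to capacity, and a daily rebalance recomputes remaining
quotas from recruitment progress with a deterministically derived seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .site_registry import SiteRegistry
from .strata_frame import (
    Stratum,
    StrataTargets,
    largest_remainder_apportion,
    sorted_strata,
)

__all__ = [
    "PotentialTable",
    "AllocationPlan",
    "build_potential_table",
    "allocate",
    "allocate_residual",
    "rebalance",
    "derive_day_seed",
]


@dataclass
class PotentialTable:
    """Pooled availability: one row per (site, stratum) with a positive
    client count."""

    rows: list[tuple[str, Stratum, int]]

    def __post_init__(self) -> None:
        for site_id, stratum, n in self.rows:
            if n <= 0:
                raise ValueError(
                    f"non-positive availability {n} for ({site_id}, {stratum})"
                )

    @property
    def total_by_stratum(self) -> dict[Stratum, int]:
        totals: dict[Stratum, int] = {}
        for _, stratum, n in self.rows:
            totals[stratum] = totals.get(stratum, 0) + n
        return totals

    def sites_for(self, stratum: Stratum) -> list[tuple[str, int]]:
        """(site_id, available) pairs for a stratum, in site-id order."""
        return sorted(
            [(sid, n) for sid, s, n in self.rows if s == stratum],
            key=lambda t: t[0],
        )


@dataclass
class AllocationPlan:
    """Per-(site, stratum) integer quotas plus shortfall accounting.

    Invariant (conservation): for every stratum,
    ``sum of quotas over sites + unmet[stratum] == target[stratum]``.
    """

    quotas: dict[tuple[str, Stratum], int]
    seed: Optional[int]
    unmet: dict[Stratum, int] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)
    over_recruited: dict[Stratum, int] = field(default_factory=dict)

    def quota_by_stratum(self, stratum: Stratum) -> dict[str, int]:
        return {
            sid: q for (sid, s), q in self.quotas.items() if s == stratum and q > 0
        }

    def total_quota(self) -> int:
        return sum(self.quotas.values())

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "site_id": sid,
                "gender": s.gender,
                "age_band": s.age_band,
                "ses": s.ses,
                "quota": q,
            }
            for (sid, s), q in sorted(
                self.quotas.items(), key=lambda kv: (kv[0][1].sort_key, kv[0][0])
            )
            if q > 0
        ]
        return pd.DataFrame(rows, columns=["site_id", "gender", "age_band", "ses", "quota"])


def build_potential_table(
    registry: SiteRegistry, frame: Iterable[Stratum] | None = None
) -> PotentialTable:
    """Pool every site's reported client counts into availability rows.

    General-community sites carry no client lists; for ``general`` strata
    they contribute their configured ``general_capacity`` instead (split
    evenly over the general strata present in the frame, when given).
    """
    rows: list[tuple[str, Stratum, int]] = []
    for site in registry:
        for stratum, n in site.client_counts.items():
            if n > 0:
                rows.append((site.id, stratum, int(n)))
    if frame is not None:
        general_strata = [s for s in sorted_strata(frame) if s.ses == "general"]
        covered = {(sid, s) for sid, s, _ in rows}
        if general_strata:
            for site in registry.general_sites:
                per = max(1, site.general_capacity // len(general_strata))
                for s in general_strata:
                    if (site.id, s) not in covered:
                        rows.append((site.id, s, per))
    return PotentialTable(rows=rows)


def _spill_to_general(
    registry: SiteRegistry, amount: int
) -> dict[str, int]:
    """Split an overflow over general sites proportionally to capacity."""
    gens = sorted(registry.general_sites, key=lambda s: s.id)
    if not gens or amount <= 0:
        return {}
    caps = np.array([s.general_capacity for s in gens], dtype=float)
    raw = amount * caps / caps.sum()
    floors = np.floor(raw).astype(int)
    left = amount - int(floors.sum())
    order = np.lexsort((np.arange(len(gens)), -(raw - floors)))
    out = dict(zip((s.id for s in gens), floors))
    for i in order[:left]:
        out[gens[i].id] += 1
    return {k: v for k, v in out.items() if v > 0}


def allocate(
    targets: StrataTargets,
    table: PotentialTable,
    eligibility: Mapping[Stratum, set[str]],
    seed: int,
    registry: SiteRegistry | None = None,
    general_fallback: bool = True,
) -> AllocationPlan:
    """Fill each stratum's quota by sampling without replacement from the
    pooled table of potential participants at eligible sites.

    Strata are processed independently in canonical order; the same seed
    always yields the same plan.  When a stratum's target exceeds its
    pooled availability the surplus spills to general-community sites
    (``general_fallback``, requires ``registry``) or is recorded in
    ``unmet`` — never silently dropped.
    """
    rng = np.random.default_rng(seed)
    quotas: dict[tuple[str, Stratum], int] = {}
    unmet: dict[Stratum, int] = {}
    log: list[str] = []

    for stratum in sorted_strata(targets.targets):
        target = targets.targets[stratum]
        if target <= 0:
            continue
        eligible = eligibility.get(stratum, set())
        avail = [(sid, n) for sid, n in table.sites_for(stratum) if sid in eligible]
        total = sum(n for _, n in avail)
        n_draw = min(target, total)
        if n_draw > 0:
            counts = rng.multivariate_hypergeometric(
                [n for _, n in avail], n_draw
            )
            for (sid, _), q in zip(avail, counts):
                if q > 0:
                    quotas[(sid, stratum)] = quotas.get((sid, stratum), 0) + int(q)
                    log.append(f"draw {stratum}: site {sid} += {int(q)}")
        shortfall = target - n_draw
        if shortfall > 0:
            spilled = 0
            if general_fallback and registry is not None:
                spill = _spill_to_general(registry, shortfall)
                for sid, q in spill.items():
                    quotas[(sid, stratum)] = quotas.get((sid, stratum), 0) + q
                    log.append(f"spill {stratum}: site {sid} += {q}")
                spilled = sum(spill.values())
            if shortfall - spilled > 0:
                unmet[stratum] = shortfall - spilled
                log.append(f"unmet {stratum}: {shortfall - spilled}")
                import warnings

                warnings.warn(
                    f"stratum {stratum}: target {target} exceeds availability; "
                    f"{shortfall - spilled} unmet",
                    stacklevel=2,
                )
    return AllocationPlan(quotas=quotas, seed=seed, unmet=unmet, log=log)


def allocate_residual(
    plan: AllocationPlan,
    registry: SiteRegistry,
    residual_targets: Mapping[Stratum, int],
) -> AllocationPlan:
    """Distribute residual (``general``-SES) quotas over general-community
    sites proportionally to configured capacity, largest-remainder rounded.

    Returns a new plan; the input plan is not mutated.  No general site is
    a hard error when any residual quota is positive.
    """
    for s in residual_targets:
        if s.ses != "general":
            raise ValueError(f"residual target on non-general stratum {s}")
    total_residual = sum(residual_targets.values())
    new = AllocationPlan(
        quotas=dict(plan.quotas),
        seed=plan.seed,
        unmet=dict(plan.unmet),
        log=list(plan.log),
        over_recruited=dict(plan.over_recruited),
    )
    if total_residual == 0:
        return new
    gens = sorted(registry.general_sites, key=lambda s: s.id)
    if not gens:
        raise ValueError("no general-community site to receive residual quotas")
    caps = np.array([g.general_capacity for g in gens], dtype=float)
    share = caps / caps.sum()
    for stratum in sorted_strata(residual_targets):
        t = residual_targets[stratum]
        if t <= 0:
            continue
        raw = t * share
        floors = np.floor(raw).astype(int)
        left = t - int(floors.sum())
        order = np.lexsort((np.arange(len(gens)), -(raw - floors)))
        alloc = floors.copy()
        for i in order[:left]:
            alloc[i] += 1
        for g, q in zip(gens, alloc):
            if q > 0:
                new.quotas[(g.id, stratum)] = new.quotas.get((g.id, stratum), 0) + int(q)
                new.log.append(f"residual {stratum}: site {g.id} += {int(q)}")
    return new


def derive_day_seed(base_seed: int, day_index: int) -> int:
    """Deterministic fresh seed for the day-``day_index`` rebalance."""
    ss = np.random.SeedSequence([int(base_seed), int(day_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def rebalance(
    plan: AllocationPlan,
    progress: Mapping[Stratum, int],
    targets: StrataTargets,
    table: PotentialTable,
    eligibility: Mapping[Stratum, set[str]],
    registry: SiteRegistry | None = None,
    day_index: int = 1,
    general_fallback: bool = True,
) -> AllocationPlan:
    """Daily correction: recompute remaining quotas from recruitment progress.

    Remaining quota per stratum is ``max(0, target - recruited)``;
    over-recruited strata get zero and are flagged in ``over_recruited``.
    Remaining quotas are re-spread with the same random mechanism under a
    fresh seed derived from ``(plan.seed, day_index)``, so the daily chain
    is reproducible from the base seed alone.
    """
    for s, n in progress.items():
        if n < 0:
            raise ValueError(f"negative recruited count for {s}")
    remaining: dict[Stratum, int] = {}
    raw: dict[Stratum, float] = {}
    over: dict[Stratum, int] = {}
    for s, t in targets.targets.items():
        got = progress.get(s, 0)
        remaining[s] = max(0, t - got)
        raw[s] = float(remaining[s])
        if got > t:
            over[s] = got - t
    rem_targets = StrataTargets(
        n_target=sum(remaining.values()), targets=remaining, raw=raw
    )
    new_seed = derive_day_seed(plan.seed if plan.seed is not None else 0, day_index)
    new = allocate(
        rem_targets,
        table,
        eligibility,
        seed=new_seed,
        registry=registry,
        general_fallback=general_fallback,
    )
    new.over_recruited = over
    for s, n in over.items():
        new.log.append(f"over-sampled {s}: +{n}")
    return new


def check_conservation(plan: AllocationPlan, targets: StrataTargets) -> bool:
    """True iff per-stratum quotas plus unmet equal the target everywhere."""
    per: dict[Stratum, int] = {s: 0 for s in targets.targets}
    for (_, s), q in plan.quotas.items():
        per[s] = per.get(s, 0) + q
    return all(
        per.get(s, 0) + plan.unmet.get(s, 0) == t for s, t in targets.targets.items()
    )
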