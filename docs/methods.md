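# Methods

## Model and procedure

`quotaframe` operationalises stratified quota recruitment for populations
with no individual-level sampling frame.  The census reference supplies,
for each stratum *s* (age band × gender × SES), the proportion
*p<sub>s</sub>* of the eligible (16+) population; the method consists of
target apportionment, randomized site allocation, monitored fieldwork, and
post-hoc representativeness assessment.  The assumptions worth stating
explicitly:

- **The census is the truth standard.**  Targets and the final assessment
  are both anchored to the same profile; the method cannot detect bias that
  the census itself carries (e.g. census undercount of people sleeping
  rough).
- **Service client tables proxy attendance.**  Allocation assumes an
  organisation's reported per-stratum client counts are proportional to
  the recruitment opportunities it offers.  Counts are treated as current
  and disjoint *within* a site, but people may appear at several sites.
- **Quota sampling is not probability sampling.**  No inclusion
  probabilities exist, so no design weights are produced; the output is a
  quota-balanced convenience sample whose margins match the census by
  construction, with representativeness of *unstratified* variables
  checked empirically afterwards.

## Apportionment

Raw quotas *q<sub>s</sub> = n·p<sub>s</sub>* are rounded by
largest-remainder (Hamilton) apportionment: floor everything, then give
the leftover units to the largest fractional remainders.  This conserves
the total exactly and satisfies the quota property (|t − q| < 1
everywhere).  Ties between equal remainders break deterministically by
canonical stratum order (gender, age band, SES).  A round-half-even mode
exists behind a flag; it repairs the total after rounding by adjusting the
cells whose quotas it distorts least.  Hamilton apportionment is not
immune to population-paradox behaviour in general, but on the small frames
used here enumeration tests find the intended weak monotonicity (doubling
a stratum's proportion never lowers its integer target).

## Randomized allocation

Each stratum's quota is filled by drawing without replacement from the
stratum's pooled availability across eligible sites — equivalently the
per-site quota vector is a single multivariate-hypergeometric draw
(`numpy.random.Generator.multivariate_hypergeometric`).  Strata are
processed independently in canonical order from one seeded generator, so a
plan is a pure function of (targets, table, eligibility, seed).
Per-stratum independence is distributionally identical to a globally
interleaved draw, because draws for different strata touch disjoint unit
pools.

Residual (`general`-SES) quotas are allocated deterministically to
general-community sites proportionally to configured capacity (largest
remainder), not randomly: capacity at a shopping mall is notional, and a
deterministic split is easier to audit in the field.  Shortfalls in named
strata spill to general sites when the fallback flag is on (default),
mirroring recruitment of hard-to-reach strata at public spaces; otherwise
they are recorded as unmet, never silently dropped.

Daily rebalancing recomputes remaining quotas (`max(0, target −
recruited)`; over-recruited strata flagged and zeroed) and re-spreads them
with the same mechanism under a seed derived as
`SeedSequence([base_seed, day_index])`, so the whole daily chain replays
from the base seed.  Because progress is reported per stratum (not per
site), the rebalance draws against the original availability table.

## Monitoring conventions

- Age bands are closed on the left: a 25-year-old is in 25–44; minimum
  eligible age 16 (younger rows are rejected at ingest with reason
  `eligibility`).
- Only completed surveys count toward strata progress and
  representativeness; the analysis set is commenced − incomplete.
- Durations use the sample standard deviation (n−1); a single duration has
  no SD.  Rounding to 2 decimals happens in report layers only.
- Participants are anonymous, so repeat participation is undetectable; the
  monitor ships a clearly-labelled heuristic that flags records sharing
  (site, date, gender, age, SES) as *possible* repeats only.

## Representativeness conventions

- Percentages are always recomputed from counts; printed aggregates are
  never trusted (count columns and text summaries in published tables can
  disagree).
- Differences are **signed** (sample − census), computed on unrounded
  percentages and rounded last; an |diff| summary accompanies them.
- The median income band is the band containing the 50th percentile of the
  ordered categorical; for even n the lower median is used.
- Pyramid tables negate female values so they plot left of the axis.
- Referral-summary display percentages are floored (truncated) to one
  decimal, the convention of the engagement reports this summary mirrors;
  exact integer counts are carried alongside.  Generic category tables
  (`category_percentages`) round normally to one decimal.

## Welch t-test

Implemented directly: t = (x̄₁ − x̄₂)/√(s₁²/n₁ + s₂²/n₂) with
Welch–Satterthwaite degrees of freedom and a two-sided p from the t
distribution.  Both groups constant and equal gives t = 0, p = 1 by
convention; groups smaller than 2 are an error.  Tests cross-check against
`scipy.stats.ttest_ind(equal_var=False)` and a literal formula
transcription to 1e−10.

## Synthetic communities

The generator exists so the pipeline is testable end-to-end without any
external data.  What it emulates, and its defaults:

| parameter | default | why |
| --- | --- | --- |
| `population_size` | 1863 | an urban community where ~706 completes are ~38% of the eligible population |
| census cell masses | 12.24/20.67/14.65/4.24 (F), 14.87/18.73/12.35/2.25 (M) % | the reference census gender×age profile |
| SES split within bands | fixed table (see `synthetic_data._SES_SPLIT_BY_BAND`) | the census reference publishes no SES×cell split; chosen once as a plausible urban profile (students concentrated in 16–24, ~87% of 65+ in `general`) |
| `attrition_p` | 24/730 ≈ 0.0329 | observed incomplete rate |
| attrition reasons | 12/24, 4/24, 8/24 | observed reason mix (time, technical, discomfort) |
| duration model | log-normal, μ=2.6083, σ=0.4108 (log-minutes) | matches a ~14.8 min mean, ~6.3 min SD |
| income bands | 7 bands, median at $400–599 | reference median income band |
| `language_at_home` | 0.067, `education_year10` 0.8027 | census marginals |
| residence mix | 89.1/5.7/1.4/3.8 % | reported residence distribution |
| `attendance_rate` | 0.9 | not all clients appear during collection windows |
| 65+ age ceiling | 90 | the census gives only band masses; ages uniform within bands |

Site membership is Bernoulli(coverage) per individual, so client tables
overlap across sites as real service populations do.  Recruitment draws
distinct attendees per (site, stratum) quota and never surveys the same
synthetic individual twice — an idealisation the anonymous real fieldwork
could not enforce.  Attrition is independent of stratum by default (a
stratum-dependent mode exists for robustness testing).  Engagement
fixtures use a simple random referral digraph and Poisson contact counts
with group-specific means (~22 participating vs ~17 declining); no
realistic social-network model for snowball dynamics is attempted.

What passing tests on synthetic data therefore show: the *pipeline*
recovers what it was fed — apportionment conserves, allocation follows the
hypergeometric law, attrition accounting closes, and a sample recruited
exactly at quota matches the census within the integer-rounding bound
(max cell |diff| ≤ 100·8/(2n) plus rounding slack, ≈0.62 pp at n = 700).
What they cannot show: that real organisations report accurate client
counts, that attendance is unbiased within strata, or that the census
itself is right — the field-validity questions no simulation settles.

## Problem sizes

Statistical tests run at sizes chosen to make Monte-Carlo error small
relative to the asserted bounds: allocator distribution checks use 1000+
seeded runs against exhaustive enumeration on ≤8-unit instances;
population-share checks use N = 100,000 (3-binomial-SE bands); attrition
calibration uses 500 replicates of a 730-commenced recruitment (3 SE ≈
0.65 persons around the expected 706).

## Known limitations

- Eligibility defaults per site type are an editable mapping, not field
  truth; real deployments should supply their own.
- Rebalancing cannot subtract per-site exhaustion because progress is
  tracked per stratum; a site could in principle be re-allocated people it
  already recruited late in a campaign with tight availability.
- The half-even rounding mode trades the quota property for banker's
  rounding; largest remainder is the default for a reason.
- `CensusProfile` marginals (income, language, education) are scalars or a
  single distribution — no joint distribution with strata, so synthetic
  marginals are independent of stratum.
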