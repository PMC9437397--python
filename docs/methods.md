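# Methods

## Scope and model

`eyesurvey` plans and validates two-stage cluster surveys that estimate the
proportion of school children needing eye-care services. The estimand is a
single prevalence *P* for a defined region; schools are the primary sampling
units and a fixed quota of children per school is the second stage. The
toolkit covers design (sample size, school selection), analysis (prevalence
with cluster-robust uncertainty), and Monte-Carlo verification of the
design's statistical contract. It deliberately does not do hypothesis-test
power calculations, finite-population corrections, age-stratified
allocation, or condition-specific epidemiology — designs sized for overall
service need are too small to give precise estimates of individual eye
diseases, and the toolkit surfaces exactly that through wide achieved
precision rather than pretending otherwise.

## Sample-size chain

Base size: `n0 = Z²·P(1−P)/(r·P)²` with the half-width expressed as a
fraction *r* of the prevalence. Then multiplicatively:

1. `n_deff = n0 × DEFF` — cluster-design variance inflation;
2. `n_infl = n_deff × (1 + nonresponse_rate)` — non-participation and
   absenteeism compensation;
3. `n_final = ceil(n_infl)`, `n_clusters = ceil(n_final / m)`.

Parameters, defaults and rationale:

| parameter | default | meaning |
| --- | --- | --- |
| `z` | 1.96 | two-sided 95% confidence multiplier; configurable via a confidence level |
| `rel_precision` | 0.20 | CI half-width as a fraction of *P* |
| `deff` | 2.0 | conservative design effect for clusters of 100 children |
| `nonresponse_rate` | 0.20 | pooled non-participation + absenteeism fraction |
| `cluster_size` | 100 | children examined per school visit (a one-day team workload) |

Two conventions are deliberate. **Non-response is compensated by
multiplication** with `1 + rate` (×1.2), not division by `1 − rate` (×1.25):
multiplication is what reproduces the published planning figures this
toolkit's fixture mirrors. **Rounding is always up** (children and
clusters), the conservative standard for sample sizes. A stated "80% power"
accompanies such calculators in the planning literature but has no term in a
precision-based formula; it is treated as metadata and never enters the
computation.

`achievable_precision` inverts the chain:
`r = z·sqrt(DEFF·(1+nr)·(1−p)/(n·p))`, answering "what precision can I get
from the n children I can actually reach?" — the relevant question when the
number of recruitable schools is capped. `adjusted_sample_size` returns the
smallest integer n whose implied precision meets the request (verified
against brute-force search in the test suite).

### Fixture prevalences and documented discrepancies

The packaged fixture stores the published GBD-super-region prevalences as
printed, rounded to 0.1%. The published sample sizes were computed from
unrounded inputs, so recomputation from the printed values does not land
exactly: 990 vs 988 (p = 18.9%), 5680 vs 5675 (p = 3.9%), both within 0.3%;
1126 (p = 17.0%) is exact. The published 10 777 implies an input prevalence
of ≈ 2.094%, not the printed 2.0% (which yields 11 295); the reporting
module flags it as not reproducible from printed inputs instead of matching
it. The flag threshold is a relative discrepancy of 0.5%.

## Two-stage sampling

**Stage 1 — systematic PPS.** Enrollments are cumulated in frame order,
the interval is `I = N/k`, one uniform start `u ∈ [0, I)` is drawn, and the
schools containing `u + j·I` (j = 0..k−1) are selected. Chosen over PPS with
replacement because it is the standard rapid-survey implementation and
naturally produces the multi-hit behaviour of very large schools (a school
spanning several intervals hosts several clusters). Frame order is taken as
given — users may pre-sort geographically for implicit stratification; the
toolkit imposes none. Zero-enrollment schools are retained in the frame but
can never be selected (they are flagged on load).

**Stage 2 — fixed quota.** `m × clusters_assigned` children are drawn
without replacement. The two stages cancel, so every child in the frame has
inclusion probability `k·m/N` (self-weighting) provided
`m ≤ enrollment ≤ I`; `inclusion_probability` raises outside that window
rather than returning a wrong number. A school smaller than its quota is
examined completely and the **shortfall** is recorded on the allocation —
the alternative (merging with a neighbouring school) would invent linkage
structure the design does not specify, and a visible shortfall tells the
planner precisely where precision is being lost. When year-group rosters are
available the quota is spread equally across year groups by
largest-remainder apportionment (ties to earlier groups), capped at group
size with the excess redistributed equally among the remaining groups.

One seeded `numpy` generator drives each invocation and the seed is embedded
in every artifact; identical seeds reproduce allocations and rosters
byte-for-byte.

## Estimation

With c clusters and cluster proportions `p_i`, the default estimate is the
unweighted mean `p̂ = mean(p_i)` — unbiased under the self-weighting design
and free of weight bookkeeping. When clusters differ materially in size
(shortfalls, absenteeism) an examined-count-weighted ratio estimate is
available (`weights="examined"`). The standard error is the between-cluster
(cluster-robust) form

```
se² = c/(c−1) · Σ (wᵢ(pᵢ − p̂))² / (Σ wᵢ)²
```

which reduces to `sd(p_i)/√c` for equal weights. Intervals use a Student-t
quantile on c − 1 degrees of freedom by default — few clusters is the
realistic regime — with a normal quantile available to match the sizing
formula. Bounds are truncated to [0, 1] after construction; the achieved
relative precision is computed from the untruncated half-width
(`q·se/p̂`), so a degenerate truncation cannot make a hopeless design look
precise. The empirical design effect is `se²/(p̂(1−p̂)/n_total)`, the ratio
of the cluster-design variance to the binomial variance at the same total n;
it is NaN when p̂ is 0 or 1. A single cluster yields a point estimate with
NaN uncertainty fields rather than an error.

## Synthetic populations and Monte-Carlo validation

School-level heterogeneity is generated by a **beta-binomial** construction:
school prevalence `π_s ~ Beta(p(1−ρ)/ρ, (1−p)(1−ρ)/ρ)` (π_s ≡ p at ρ = 0),
child outcomes iid Bernoulli(π_s) within school. This gives marginal
prevalence p and pairwise within-school correlation exactly ρ in closed
form; a logit-normal mixture would serve equally but has no closed-form ICC.
Because a without-replacement subsample of iid outcomes is itself iid, an
m-child cluster mean has variance `p(1−p)(1+(m−1)ρ)/m` exactly — the
equal-cluster-size DEFF identity the validation harness tests.

Default enrollment law: lognormal with arithmetic mean 500 and log-sd 0.8,
truncated below at 20 — broad enough to produce both multi-hit large schools
and shortfall small schools, the two edge cases a planner must expect. Real
frames differ in ways the generator does not emulate: enrollment may
correlate with prevalence (urban/rural gradients), outcomes may cluster
within classrooms below the school level, and absenteeism may be outcome-
dependent; passing tests therefore validate the design logic, not any
particular country's data. Non-response is simulated as independent
child-level Bernoulli thinning at the pooled rate; there is no school-level
refusal model.

`monte_carlo_validate` draws a fresh population per replicate (seeds spawned
from one `SeedSequence`), runs the full sampling + estimation pipeline, and
reports: empirical DEFF (across-replicate variance of p̂ over the binomial
variance at the mean total n), CI coverage, mean achieved relative
precision, and bias. Coverage is assessed against the superpopulation
`p_true`, not each finite population's realised prevalence — the two differ
noticeably in small populations, and the superpopulation is the planning
estimand.

**Validation conditions.** The reference check uses p = 0.17, ρ = 1/99,
60 schools of 250 pupils, 30 clusters of 100, zero non-response,
1000 replicates: enrollments are equal so no school exceeds the interval
(which would correlate clusters within a school) and every school can fill a
cluster, isolating the DEFF law `1 + 99/99 = 2.0` and nominal 95% coverage.
The precision check sizes the survey with the calculator (1126 children, 12
clusters at p = 17%), simulates 500 replicates with 20% absenteeism, and uses
normal quantiles to match the sizing formula; mean relative half-width comes
out ≈ 18.5%, inside the ±20% target, because thinning to ~80 examined per
cluster also lowers the realised DEFF to `1 + 79ρ ≈ 1.8`, below the assumed
2.0. When the true ICC exceeds the assumption the promise fails — the test
suite demonstrates the miss at ρ = 0.06 — mirroring the caution that
confidence in the estimate drops where fewer schools or more clustered
outcomes prevail. These replicate counts keep the whole validation suite in
tens of seconds while leaving Monte-Carlo error well inside the asserted
tolerances (≈ 4.5% relative for a variance ratio at 1000 reps, ≈ 0.7 pp for
coverage).

## Numerical and degenerate-input choices

- Prevalence must lie strictly in (0, 1): at the boundaries the relative
  half-width `r·P` is zero and the formula is undefined.
- ICC = 1 is rejected (degenerate Beta); ICC = 0 bypasses the Beta draw.
- Composite scenarios sum components on the proportion scale before sizing;
  a mismatch between components and a stated total beyond 0.001 is an error.
- Systematic-PPS boundary points (`searchsorted` side `right`) assign a
  point falling exactly on a cumulative boundary to the next school with
  positive enrollment, so zero-enrollment schools are unselectable.
- Empty clusters after absenteeism thinning are dropped (probability
  ≈ 10⁻⁷⁰ at the default rates; guarded for pathological rates).
- CLI exit codes: 2 for usage errors, 1 for validation/computation failures.

## Known limitations

- The unweighted cluster-mean estimator assumes the self-weighting design
  was actually followed; for certainty (multi-hit) schools whose quotas
  exhaust the roster, weights drift and the examined-weighted option should
  be used.
- The empirical-DEFF estimate from a single survey is very noisy below ~30
  clusters; the Monte-Carlo harness, not a single survey, is the right tool
  for checking a DEFF assumption.
- No spatial correlation between schools, no replacement-school protocol,
  no longitudinal monitoring — out of scope for a one-off rapid assessment.
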