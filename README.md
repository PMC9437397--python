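# eyesurvey

A planning toolkit for **school-based eye-health cluster surveys**: rapid
assessments that estimate the proportion of school children in a region who
need eye-care services (vision impairment, mostly uncorrected refractive
error, plus non-vision-impairing conditions such as allergic eye disease and
conjunctivitis). It is written for survey planners, programme implementers
and biostatisticians designing such surveys, and provides:

- a **sample-size engine** with design-effect and non-response adjustments,
  the inverse (achievable-precision) problem, and DEFF sensitivity tables;
- a **two-stage sampling engine**: schools selected by systematic
  probability-proportionate-to-size (PPS) sampling from a Ministry-of-Education
  style enrollment frame, then a fixed quota of children per school — a
  self-weighting design;
- a **cluster-survey estimator**: prevalence with cluster-robust standard
  errors, t-based confidence intervals, empirical design effect and achieved
  relative precision;
- a **Monte-Carlo validation harness** that simulates whole surveys on
  synthetic beta-binomial school populations and verifies the design's
  statistical contract (design effect, CI coverage, precision).

## The statistics

The required simple-random-sample size to estimate a prevalence *P* with
confidence multiplier *Z* and half-width *d* is

```
n = Z² · P · (1 − P) / d²,        d = r · P  (relative precision)
```

with defaults Z = 1.96 (95% CI) and r = 0.20 (half-width ±20% of the
prevalence). Because *d* is relative, rarer outcomes need *larger* samples.
The base size is multiplied by a design effect (DEFF, default 2.0 for
clusters of m = 100 children — via the equal-cluster identity
`DEFF = 1 + (m − 1)ρ` this corresponds to an intracluster correlation
ρ = 1/99) and inflated by an anticipated 20% non-participation/absenteeism
rate; the result is rounded up and split into clusters of 100.

Schools are selected by cumulative-size systematic PPS: with interval
`I = N / k` (N total enrollment, k clusters) and a uniform random start, a
school of enrollment *e* is selected with probability proportional to *e*;
very large schools can be selected more than once, and a school smaller than
the quota is examined in full with the shortfall reported. Combined with the
fixed second-stage quota, every child has inclusion probability `k·m/N`.

## Worked example

```
$ eyesurvey samplesize --prevalence 17 --unit percent
{
  "results": [
    {
      "p": 0.17,
      "n_base": 468.90117647058815,
      "n_deff": 937.8023529411763,
      "n_inflated": 1125.3628235294116,
      "n_final": 1126,
      "n_clusters": 12,
      "achieved_precision": 0.1999434043839402,
      ...
    }
  ]
}
```

At 17% prevalence, 468.9 children would suffice under simple random
sampling; doubling for the cluster design (937.8) and adding 20% for
non-response gives 1126 children, i.e. 12 school clusters of 100, and the
1126 children deliver a CI half-width of 19.99% of the prevalence — just
inside the ±20% target.

`eyesurvey scenarios` rebuilds the regional planning tables from the
packaged GBD-super-region prevalence fixture. The composite prevalences sum
exactly (17.0 + 1.9 = 18.9% and 2.0 + 1.9 = 3.9%), and the sample-size table
carries a documented-discrepancy column against the published figures, which
were computed from unrounded prevalences: recomputing from the printed
values gives 990 vs 988 (+0.2%) and 5680 vs 5675 (+0.09%), while the
published 10 777 implies an input prevalence of ≈2.09% rather than the
printed 2.0% and is flagged `reproducible_from_printed = False` rather than
matched.

The same calculation is available in Python:

```python
from eyesurvey import DesignParameters, adjusted_sample_size

res = adjusted_sample_size(0.17, DesignParameters())
print(res.n_final, res.n_clusters)   # 1126 12
```

and the full simulation loop:

```python
from eyesurvey import (DesignParameters, EnrollmentLaw, PopulationSpec,
                       monte_carlo_validate)

spec = PopulationSpec(n_schools=60,
                      enrollment_law=EnrollmentLaw(kind="fixed", size=250),
                      p_true=0.17, icc=1/99)
rep = monte_carlo_validate(spec, DesignParameters(nonresponse_rate=0.0),
                           n_clusters=30, reps=1000, seed=1)
print(round(rep.empirical_deff, 2), rep.coverage)   # 2.02 0.954
```

## Layout

| module | contents |
| --- | --- |
| `eyesurvey.design` | sample-size chain, achievable precision, DEFF sensitivity, scenario tables |
| `eyesurvey.frame` | school frame I/O, systematic PPS, second-stage sampling, inclusion probabilities |
| `eyesurvey.estimation` | cluster-level prevalence estimator, empirical DEFF, achieved precision |
| `eyesurvey.simulate` | beta-binomial populations, survey simulation, Monte-Carlo validation |
| `eyesurvey.report` | packaged prevalence fixture and planning-table reproduction |
| `eyesurvey.cli` | `eyesurvey` command with `samplesize / sample / estimate / simulate / validate / scenarios` |

See `docs/methods.md` for the model, its assumptions, and the design choices.
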