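"""Synthetic school populations and Monte-Carlo validation of the design.

The intracluster correlation is induced by a beta-binomial construction:
each school's latent prevalence is drawn from ``Beta(a, b)`` with
``a = p (1 - rho) / rho`` and ``b = (1 - p)(1 - rho) / rho``, so the marginal
child-level prevalence is ``p`` and the pairwise within-school outcome
correlation is exactly ``rho``; child outcomes are independent Bernoulli
draws at the school's latent prevalence.  At ``rho = 0`` every school shares
the marginal prevalence.  For equal examined cluster sizes ``m`` this yields
the textbook identity ``DEFF = 1 + (m - 1) rho`` — at ``m = 100`` a
correlation of ``1/99`` gives a design effect of 2.0, the planning default.

``monte_carlo_validate`` replays the whole pipeline — population generation,
systematic PPS school selection, second-stage child sampling, optional
absenteeism thinning, cluster-level estimation — over many replicates and
reports the empirical design effect, CI coverage against the superpopulation
prevalence, achieved relative precision, and bias.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .design import DesignParameters
from .estimation import ClusterResult, SurveyEstimate, cluster_prevalence_estimate
from .frame import SchoolFrame, SchoolRecord, pps_systematic_sample, second_stage_sample

__all__ = [
    "EnrollmentLaw",
    "PopulationSpec",
    "SyntheticPopulation",
    "ValidationReport",
    "generate_population",
    "simulate_survey",
    "monte_carlo_validate",
]


@dataclass(frozen=True)
class EnrollmentLaw:
    """School-enrollment distribution descriptor.

    ``kind='fixed'`` gives every school ``size`` pupils.  ``kind='lognormal'``
    draws lognormal enrollments with the given arithmetic ``mean`` and log-scale
    ``sigma``, truncated below at ``minimum`` — a broad, right-skewed law that
    produces both very large schools (multi-hit PPS selections) and small
    schools (cluster shortfalls), the two edge cases a planner must expect.
    """

    kind: Literal["fixed", "lognormal"] = "lognormal"
    size: int = 500
    mean: float = 500.0
    sigma: float = 0.8
    minimum: int = 20

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "lognormal"):
            raise ValueError(f"unknown enrollment law {self.kind!r}")
        if self.kind == "fixed" and self.size < 1:
            raise ValueError("fixed enrollment must be >= 1")
        if self.kind == "lognormal" and (self.mean <= 0 or self.sigma <= 0):
            raise ValueError("lognormal enrollment needs mean > 0 and sigma > 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.size, dtype=int)
        # parametrise by arithmetic mean: mu = log(mean) - sigma^2/2
        mu = math.log(self.mean) - self.sigma**2 / 2
        draws = rng.lognormal(mu, self.sigma, size=n)
        return np.maximum(np.round(draws).astype(int), self.minimum)

    @classmethod
    def parse(cls, text: str) -> "EnrollmentLaw":
        """Parse ``'fixed:250'`` or ``'lognormal:500:0.8'``."""
        parts = text.split(":")
        if parts[0] == "fixed" and len(parts) == 2:
            return cls(kind="fixed", size=int(parts[1]))
        if parts[0] == "lognormal" and len(parts) in (2, 3):
            sigma = float(parts[2]) if len(parts) == 3 else 0.8
            return cls(kind="lognormal", mean=float(parts[1]), sigma=sigma)
        raise ValueError(f"cannot parse enrollment law {text!r}")


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for a synthetic school population."""

    n_schools: int = 40
    enrollment_law: EnrollmentLaw = field(default_factory=EnrollmentLaw)
    p_true: float = 0.17
    icc: float = 1 / 99
    seed: int | np.random.SeedSequence | None = None

    def __post_init__(self) -> None:
        if self.n_schools < 1:
            raise ValueError(f"n_schools must be >= 1, got {self.n_schools}")
        if not 0 < self.p_true < 1:
            raise ValueError(f"p_true must lie in (0, 1), got {self.p_true}")
        if not 0 <= self.icc < 1:
            raise ValueError(
                f"icc must lie in [0, 1), got {self.icc} "
                "(icc = 1 makes the Beta mixing distribution degenerate)"
            )


@dataclass(frozen=True)
class SyntheticPopulation:
    """A realised school population with child-level binary outcomes."""

    schools: tuple[SchoolRecord, ...]
    outcomes: tuple[np.ndarray, ...]  # one 0/1 vector per school, roster order
    school_prevalence: tuple[float, ...]  # latent per-school prevalences
    p_true: float
    icc: float

    @property
    def frame(self) -> SchoolFrame:
        return SchoolFrame(self.schools)

    @property
    def n_children(self) -> int:
        return sum(s.enrollment for s in self.schools)

    @property
    def realized_prevalence(self) -> float:
        """Finite-population prevalence actually realised (vs superpopulation
        ``p_true``)."""
        pos = sum(int(o.sum()) for o in self.outcomes)
        return pos / self.n_children


def generate_population(spec: PopulationSpec) -> SyntheticPopulation:
    """Draw a synthetic population from the beta-binomial model."""
    rng = np.random.default_rng(spec.seed)
    enroll = spec.enrollment_law.sample(rng, spec.n_schools)
    if spec.icc > 0:
        a = spec.p_true * (1 - spec.icc) / spec.icc
        b = (1 - spec.p_true) * (1 - spec.icc) / spec.icc
        pis = rng.beta(a, b, size=spec.n_schools)
    else:
        pis = np.full(spec.n_schools, spec.p_true)
    schools = tuple(
        SchoolRecord(school_id=f"S{i:04d}", enrollment=int(e))
        for i, e in enumerate(enroll)
    )
    outcomes = tuple(
        (rng.random(int(e)) < pi).astype(np.int8) for e, pi in zip(enroll, pis)
    )
    return SyntheticPopulation(
        schools=schools,
        outcomes=outcomes,
        school_prevalence=tuple(float(x) for x in pis),
        p_true=spec.p_true,
        icc=spec.icc,
    )


def simulate_survey(
    population: SyntheticPopulation,
    params: DesignParameters,
    n_clusters: int,
    seed: int | np.random.Generator | None = None,
    confidence: float = 0.95,
    quantile: Literal["t", "normal"] = "t",
) -> SurveyEstimate:
    """Run one full survey on a synthetic population.

    Systematic PPS selects schools; the second stage draws the cluster quota
    per school; each selected child is then present with probability
    ``1 - nonresponse_rate`` (independent Bernoulli absenteeism); the
    cluster-level estimator is applied to examined children.  A multi-hit
    school's quota is split into its assigned clusters for analysis.
    """
    rng = np.random.default_rng(seed)
    frame = population.frame
    by_id = {s.school_id: i for i, s in enumerate(population.schools)}
    allocations = pps_systematic_sample(
        frame, n_clusters, seed=rng, cluster_size=params.cluster_size
    )
    results: list[ClusterResult] = []
    for alloc in allocations:
        i = by_id[alloc.school_id]
        school = population.schools[i]
        chosen = second_stage_sample(
            school, params.cluster_size, seed=rng,
            clusters_assigned=alloc.clusters_assigned,
        )
        rng.shuffle(chosen)
        # split a multi-hit school's draw into its clusters
        parts = np.array_split(chosen, alloc.clusters_assigned)
        for j, part in enumerate(parts):
            if params.nonresponse_rate > 0:
                present = rng.random(part.size) < 1 - params.nonresponse_rate
                part = part[present]
            if part.size == 0:
                continue  # an entirely absent cluster carries no data
            outcomes = population.outcomes[i][part]
            results.append(
                ClusterResult(
                    school_id=f"{school.school_id}#{j}" if len(parts) > 1 else school.school_id,
                    n_examined=int(part.size),
                    n_positive=int(outcomes.sum()),
                )
            )
    return cluster_prevalence_estimate(
        results, confidence=confidence, quantile=quantile
    )


@dataclass(frozen=True)
class ValidationReport:
    """Monte-Carlo summary of the design's statistical contract."""

    reps: int
    coverage: float
    mean_rel_precision: float
    empirical_deff: float
    bias: float
    mean_p_hat: float
    sd_p_hat: float
    mean_se: float
    mean_n_total: float
    p_true: float
    confidence: float
    seed: int | None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def monte_carlo_validate(
    spec: PopulationSpec,
    params: DesignParameters,
    n_clusters: int,
    reps: int = 1000,
    seed: int | None = None,
    confidence: float = 0.95,
    quantile: Literal["t", "normal"] = "t",
) -> ValidationReport:
    """Replicate population generation + survey ``reps`` times and summarise.

    ``empirical_deff`` is the across-replicate variance of ``p_hat`` divided
    by the binomial variance ``p(1-p)/n`` at the mean estimate and mean total
    examined — the variance-ratio definition of the design effect.  Coverage
    is assessed against the superpopulation ``p_true`` (each replicate draws a
    fresh population, so the superpopulation is the estimand).
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    ss = np.random.SeedSequence(seed)
    pop_seeds, svy_seeds = ss.spawn(2)
    pop_children = pop_seeds.spawn(reps)
    svy_children = svy_seeds.spawn(reps)
    p_hats = np.empty(reps)
    n_totals = np.empty(reps)
    covered = np.empty(reps, dtype=bool)
    rels = np.empty(reps)
    ses = np.empty(reps)
    for r in range(reps):
        pop = generate_population(dataclasses.replace(spec, seed=pop_children[r]))
        est = simulate_survey(
            pop, params, n_clusters,
            seed=np.random.default_rng(svy_children[r]),
            confidence=confidence, quantile=quantile,
        )
        p_hats[r] = est.p_hat
        n_totals[r] = est.n_total
        covered[r] = est.ci_low <= spec.p_true <= est.ci_high
        rels[r] = est.achieved_rel_precision
        ses[r] = est.se
    mean_p = float(p_hats.mean())
    srs_var = mean_p * (1 - mean_p) / float(n_totals.mean())
    emp_deff = float(p_hats.var(ddof=1)) / srs_var if reps > 1 else float("nan")
    return ValidationReport(
        reps=reps,
        coverage=float(covered.mean()),
        mean_rel_precision=float(np.nanmean(rels)),
        empirical_deff=emp_deff,
        bias=mean_p - spec.p_true,
        mean_p_hat=mean_p,
        sd_p_hat=float(p_hats.std(ddof=1)) if reps > 1 else float("nan"),
        mean_se=float(np.nanmean(ses)),
        mean_n_total=float(n_totals.mean()),
        p_true=spec.p_true,
        confidence=confidence,
        seed=seed,
    )
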