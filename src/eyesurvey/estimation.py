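"""Prevalence estimation from completed cluster-survey data.

The analysis unit is the cluster (one school visit): ``n_positive`` of
``n_examined`` children met the condition definition.  Because the two-stage
design is self-weighting, the point estimate is the unweighted mean of
cluster proportions; when clusters differ in size (shortfalls, absenteeism)
an examined-count-weighted ratio estimate is available instead.  Uncertainty
comes from the between-cluster variance — the standard cluster-robust
estimator — with a Student-t quantile on ``c - 1`` degrees of freedom by
default, since few clusters is the realistic regime for rapid assessments.
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterResult",
    "SurveyEstimate",
    "cluster_prevalence_estimate",
    "estimate_deff",
    "achieved_relative_precision",
    "load_results",
]


@dataclass(frozen=True)
class ClusterResult:
    """Examination outcome of one cluster."""

    school_id: str
    n_examined: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.n_examined < 1:
            raise ValueError(
                f"cluster {self.school_id!r}: n_examined must be >= 1, "
                f"got {self.n_examined}"
            )
        if not 0 <= self.n_positive <= self.n_examined:
            raise ValueError(
                f"cluster {self.school_id!r}: n_positive ({self.n_positive}) "
                f"must lie in [0, n_examined={self.n_examined}]"
            )

    @property
    def proportion(self) -> float:
        return self.n_positive / self.n_examined


@dataclass(frozen=True)
class SurveyEstimate:
    """Prevalence estimate with cluster-robust uncertainty.

    ``se``, the CI bounds, ``deff_hat`` and ``achieved_rel_precision`` are NaN
    when undefined (a single cluster, or a degenerate 0/1 estimate for the
    DEFF).  ``half_width`` is the CI half-width before truncation to [0, 1];
    ``achieved_rel_precision`` is ``half_width / p_hat``.
    """

    p_hat: float
    se: float
    ci_low: float
    ci_high: float
    half_width: float
    deff_hat: float
    achieved_rel_precision: float
    n_total: int
    n_clusters: int
    confidence: float

    @property
    def se_defined(self) -> bool:
        return not math.isnan(self.se)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _point_estimate(
    props: np.ndarray, sizes: np.ndarray, weights: Literal["equal", "examined"]
) -> tuple[float, np.ndarray]:
    if weights == "equal":
        w = np.ones_like(props)
    elif weights == "examined":
        w = sizes.astype(float)
    else:
        raise ValueError(f"weights must be 'equal' or 'examined', got {weights!r}")
    return float(np.sum(w * props) / np.sum(w)), w


def cluster_prevalence_estimate(
    results: Sequence[ClusterResult],
    confidence: float = 0.95,
    quantile: Literal["t", "normal"] = "t",
    weights: Literal["equal", "examined"] = "equal",
) -> SurveyEstimate:
    """Estimate prevalence and its uncertainty from cluster results.

    With equal weights, ``p_hat`` is the mean of cluster proportions and
    ``se = sd(cluster proportions) / sqrt(c)``.  With examined-count weights
    the ratio estimator and its linearised cluster SE
    ``se^2 = c/(c-1) * sum(w_i^2 (p_i - p_hat)^2) / (sum w_i)^2`` are used
    (identical to the equal-weight formula when all ``w_i`` are equal).
    The CI is ``p_hat ± q * se`` truncated to [0, 1], with ``q`` a Student-t
    quantile on ``c - 1`` df (default) or a normal quantile.
    """
    results = list(results)
    if not results:
        raise ValueError("no cluster results supplied")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must lie in (0, 1), got {confidence}")
    props = np.array([r.proportion for r in results])
    sizes = np.array([r.n_examined for r in results])
    c = len(results)
    n_total = int(sizes.sum())
    p_hat, w = _point_estimate(props, sizes, weights)

    if c < 2:
        se = hw = lo = hi = arp = dhat = float("nan")
        return SurveyEstimate(
            p_hat=p_hat, se=se, ci_low=lo, ci_high=hi, half_width=hw,
            deff_hat=dhat, achieved_rel_precision=arp,
            n_total=n_total, n_clusters=c, confidence=confidence,
        )

    se2 = c / (c - 1) * float(np.sum((w * (props - p_hat)) ** 2)) / float(np.sum(w)) ** 2
    se = math.sqrt(se2)
    alpha = 1 - confidence
    if quantile == "t":
        q = float(stats.t.ppf(1 - alpha / 2, df=c - 1))
    elif quantile == "normal":
        q = float(stats.norm.ppf(1 - alpha / 2))
    else:
        raise ValueError(f"quantile must be 't' or 'normal', got {quantile!r}")
    hw = q * se
    lo, hi = max(0.0, p_hat - hw), min(1.0, p_hat + hw)
    if 0.0 < p_hat < 1.0:
        dhat = se2 / (p_hat * (1.0 - p_hat) / n_total)
    else:
        dhat = float("nan")
    arp = hw / p_hat if p_hat > 0 else float("nan")
    return SurveyEstimate(
        p_hat=p_hat, se=se, ci_low=lo, ci_high=hi, half_width=hw,
        deff_hat=dhat, achieved_rel_precision=arp,
        n_total=n_total, n_clusters=c, confidence=confidence,
    )


def estimate_deff(
    results: Sequence[ClusterResult],
    weights: Literal["equal", "examined"] = "equal",
) -> float:
    """Empirical design effect: the cluster-design variance of ``p_hat``
    divided by the binomial (simple-random-sampling) variance at the same
    total sample size, ``se^2 / (p_hat (1 - p_hat) / n_total)``.

    NaN when ``p_hat`` is 0 or 1 (SRS variance degenerates).
    """
    est = cluster_prevalence_estimate(results, weights=weights)
    if est.n_clusters < 2:
        raise ValueError("need >= 2 clusters to estimate a design effect")
    return est.deff_hat


def achieved_relative_precision(estimate: SurveyEstimate) -> float:
    """CI half-width as a fraction of the estimated prevalence.

    This is the quantity the sizing formula promises to keep at or below the
    requested relative precision (±20% of prevalence by default).
    """
    if not estimate.p_hat > 0:
        raise ValueError("relative precision undefined at p_hat = 0")
    return estimate.half_width / estimate.p_hat


def load_results(source: str | Path | io.IOBase | pd.DataFrame) -> list[ClusterResult]:
    """Read cluster results from CSV (columns ``school_id``, ``n_examined``,
    ``n_positive``; ``#`` comments allowed)."""
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, comment="#", dtype={"school_id": str})
    for col in ("school_id", "n_examined", "n_positive"):
        if col not in df.columns:
            raise ValueError(f"results file is missing required column {col!r}")
    return [
        ClusterResult(str(r.school_id), int(r.n_examined), int(r.n_positive))
        for r in df.itertuples()
    ]
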