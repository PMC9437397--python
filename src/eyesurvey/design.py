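"""Sample-size engine for school-based eye-health cluster surveys.

A rapid-assessment survey estimates the proportion *P* of school children who
need eye-care services (vision impairment plus non-vision-impairing eye
conditions).  The required simple-random-sample size for estimating *P* with a
confidence multiplier *Z* and an absolute half-width *d* is

    n = Z^2 * P * (1 - P) / d^2

where the half-width is taken in *relative* terms, d = r * P, with r the
desired relative precision (default ±20% of the prevalence).  The base size is
then inflated multiplicatively by a design effect (DEFF, default 2.0, chosen
conservatively for clusters of 100 children) to account for within-school
correlation of outcomes, and by an anticipated non-participation/absenteeism
rate (default 20%).  The final size is rounded up, and divided into clusters
of ``cluster_size`` children.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "DesignParameters",
    "PrevalenceScenario",
    "SampleSizeResult",
    "base_sample_size",
    "adjusted_sample_size",
    "achievable_precision",
    "deff_sensitivity",
    "scenario_table",
]

#: tolerance for component prevalences summing to a composite total
COMPONENT_SUM_TOL = 0.001


@dataclass(frozen=True)
class DesignParameters:
    """Statistical knobs of the survey design.

    Parameters
    ----------
    z
        Confidence multiplier (two-sided); 1.96 for a 95% confidence interval.
    rel_precision
        Desired CI half-width as a fraction of the prevalence (r in d = r*P).
    deff
        Design effect: variance inflation of the cluster design relative to
        simple random sampling of the same size.
    nonresponse_rate
        Anticipated non-participation and absenteeism fraction; the sample is
        inflated by ``(1 + nonresponse_rate)`` to compensate.
    cluster_size
        Number of children examined per cluster (one school visit).
    """

    z: float = 1.96
    rel_precision: float = 0.20
    deff: float = 2.0
    nonresponse_rate: float = 0.20
    cluster_size: int = 100

    def __post_init__(self) -> None:
        if not self.z > 0:
            raise ValueError(f"z must be positive, got {self.z}")
        if not 0 < self.rel_precision < 1:
            raise ValueError(
                f"rel_precision must lie in (0, 1), got {self.rel_precision}"
            )
        if self.deff < 1:
            raise ValueError(f"deff must be >= 1, got {self.deff}")
        if not 0 <= self.nonresponse_rate < 1:
            raise ValueError(
                f"nonresponse_rate must lie in [0, 1), got {self.nonresponse_rate}"
            )
        if int(self.cluster_size) != self.cluster_size or self.cluster_size < 1:
            raise ValueError(
                f"cluster_size must be a positive integer, got {self.cluster_size}"
            )
        object.__setattr__(self, "cluster_size", int(self.cluster_size))

    @classmethod
    def from_confidence(cls, confidence: float = 0.95, **kwargs) -> "DesignParameters":
        """Build parameters with ``z`` set from a two-sided confidence level."""
        if not 0 < confidence < 1:
            raise ValueError(f"confidence must lie in (0, 1), got {confidence}")
        z = float(stats.norm.ppf(1 - (1 - confidence) / 2))
        return cls(z=z, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "DesignParameters":
        """Load parameter defaults from a YAML or JSON config file.

        Recognised keys are the field names; a ``confidence`` key may be given
        instead of ``z``.  Unknown keys raise.
        """
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if not isinstance(raw, Mapping):
            raise ValueError(f"config {path} must contain a mapping")
        raw = dict(raw)
        confidence = raw.pop("confidence", None)
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        if confidence is not None:
            if "z" in raw:
                raise ValueError("give either 'z' or 'confidence', not both")
            return cls.from_confidence(confidence, **raw)
        return cls(**raw)

    def replace(self, **changes) -> "DesignParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class PrevalenceScenario:
    """A labelled prevalence scenario (region and condition group).

    ``components`` optionally breaks the prevalence into additive condition
    groups (e.g. vision impairment + non-vision-impairing conditions); they
    must sum to ``p`` within ``COMPONENT_SUM_TOL`` on the proportion scale.
    """

    label: str
    p: float
    components: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError(
                f"prevalence must lie strictly in (0, 1), got {self.p!r} "
                f"for scenario {self.label!r}"
            )
        if self.components is not None:
            total = sum(self.components.values())
            if abs(total - self.p) > COMPONENT_SUM_TOL:
                raise ValueError(
                    f"scenario {self.label!r}: components sum to {total:.4f}, "
                    f"stated total is {self.p:.4f} (tolerance {COMPONENT_SUM_TOL})"
                )
            object.__setattr__(self, "components", dict(self.components))

    @classmethod
    def from_components(
        cls, label: str, components: Mapping[str, float]
    ) -> "PrevalenceScenario":
        """Compose a scenario by summing condition-group proportions."""
        return cls(label=label, p=sum(components.values()), components=components)


@dataclass(frozen=True)
class SampleSizeResult:
    """Output of the sample-size chain, children unless noted.

    ``n_base`` is the unrounded simple-random-sample size; ``n_deff``
    multiplies in the design effect; ``n_inflated`` adds the non-response
    compensation; ``n_final`` is the ceiling; ``n_clusters`` the number of
    school clusters needed; ``achieved_precision`` the relative half-width
    actually implied by ``n_final``.
    """

    p: float
    n_base: float
    n_deff: float
    n_inflated: float
    n_final: int
    n_clusters: int
    achieved_precision: float
    params: DesignParameters

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        return d


def base_sample_size(p: float, z: float = 1.96, rel_precision: float = 0.20) -> float:
    """Unrounded SRS sample size ``n = z^2 p (1-p) / (r p)^2``.

    The half-width is relative (d = rel_precision * p), so the required size
    *decreases* as prevalence rises: rare conditions need more children for
    the same proportional accuracy.
    """
    if not 0 < p < 1:
        raise ValueError(f"prevalence must lie strictly in (0, 1), got {p}")
    if not z > 0:
        raise ValueError(f"z must be positive, got {z}")
    if not 0 < rel_precision < 1:
        raise ValueError(f"rel_precision must lie in (0, 1), got {rel_precision}")
    d = rel_precision * p
    return z * z * p * (1.0 - p) / (d * d)


def _as_scenario(scenario: PrevalenceScenario | float) -> PrevalenceScenario:
    if isinstance(scenario, PrevalenceScenario):
        return scenario
    return PrevalenceScenario(label=f"p={scenario:g}", p=float(scenario))


def adjusted_sample_size(
    scenario: PrevalenceScenario | float,
    params: DesignParameters = DesignParameters(),
) -> SampleSizeResult:
    """Full sizing chain: base SRS size, DEFF inflation, non-response
    inflation, ceiling, and cluster count.

    Non-response is compensated multiplicatively, ``n_deff * (1 + rate)``.
    Rounding is conservative (ceiling) for both children and clusters.
    """
    scenario = _as_scenario(scenario)
    n_base = base_sample_size(scenario.p, params.z, params.rel_precision)
    n_deff = n_base * params.deff
    n_inflated = n_deff * (1.0 + params.nonresponse_rate)
    n_final = math.ceil(n_inflated)
    n_clusters = math.ceil(n_final / params.cluster_size)
    achieved = achievable_precision(n_final, scenario.p, params)
    return SampleSizeResult(
        p=scenario.p,
        n_base=n_base,
        n_deff=n_deff,
        n_inflated=n_inflated,
        n_final=n_final,
        n_clusters=n_clusters,
        achieved_precision=achieved,
        params=params,
    )


def achievable_precision(
    n_available: float,
    p: float,
    params: DesignParameters = DesignParameters(),
) -> float:
    """Relative precision achievable with ``n_available`` children.

    Algebraic inverse of the sizing chain:
    ``r = z * sqrt(deff * (1 + nonresponse) * (1 - p) / (n * p))``.
    Useful when the number of recruitable schools caps the sample: fewer
    schools means a wider interval, quantified here.
    """
    if n_available < 1:
        raise ValueError(f"n_available must be >= 1, got {n_available}")
    if not 0 < p < 1:
        raise ValueError(f"prevalence must lie strictly in (0, 1), got {p}")
    return params.z * math.sqrt(
        params.deff * (1.0 + params.nonresponse_rate) * (1.0 - p) / (n_available * p)
    )


def deff_sensitivity(
    scenario: PrevalenceScenario | float,
    params: DesignParameters = DesignParameters(),
    deff_values: Sequence[float] = (1.0, 1.5, 2.0, 2.5, 3.0),
) -> list[SampleSizeResult]:
    """Model the effect of the assumed design effect on the sample size.

    Returns one :class:`SampleSizeResult` per candidate DEFF, all other
    parameters held fixed; ``deff = 1`` reproduces the unclustered design.
    """
    for deff in deff_values:
        if deff < 1:
            raise ValueError(f"deff must be >= 1, got {deff}")
    return [
        adjusted_sample_size(scenario, params.replace(deff=float(deff)))
        for deff in deff_values
    ]


def scenario_table(
    scenarios: Iterable[PrevalenceScenario],
    params: DesignParameters = DesignParameters(),
) -> pd.DataFrame:
    """Sample-size table for a list of prevalence scenarios, in input order.

    Composite scenarios (with condition-group components) are sized at the
    component sum; the components are echoed in a ``components`` column.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("scenario list is empty")
    rows = []
    for sc in scenarios:
        res = adjusted_sample_size(sc, params)
        rows.append(
            {
                "label": sc.label,
                "p": sc.p,
                "components": (
                    "; ".join(f"{k}={v:.4f}" for k, v in sc.components.items())
                    if sc.components
                    else ""
                ),
                "n_base": res.n_base,
                "n_deff": res.n_deff,
                "n_inflated": res.n_inflated,
                "n_final": res.n_final,
                "n_clusters": res.n_clusters,
                "achieved_precision": res.achieved_precision,
            }
        )
    return pd.DataFrame(rows)
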