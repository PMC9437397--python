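"""School sampling frame and two-stage self-weighting selection.

Schools are the primary sampling units, selected with probability
proportionate to enrollment (PPS) by the systematic cumulative-size method:
enrollments are cumulated in frame order, the sampling interval is
``I = total_enrollment / n_clusters``, a single uniform start ``u`` on
``[0, I)`` is drawn, and the schools containing the points ``u + k*I`` are
selected.  A school whose enrollment exceeds the interval can be hit more
than once and then hosts several clusters; a school smaller than the cluster
quota contributes all of its pupils and records a shortfall.

At the second stage a fixed quota of children per cluster is drawn without
replacement, which makes the design self-weighting: every enrolled child in
the frame has overall inclusion probability ``n_clusters * cluster_size /
total_enrollment`` regardless of school size (for schools between the cluster
quota and the interval).  Where year-group rosters are available the quota is
spread equally across year groups.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchoolRecord",
    "SchoolFrame",
    "ClusterAllocation",
    "CertaintySelectionError",
    "load_frame",
    "pps_systematic_sample",
    "second_stage_sample",
    "inclusion_probability",
]


class CertaintySelectionError(ValueError):
    """A school's enrollment exceeds the sampling interval, so the single-draw
    inclusion-probability formula does not apply (the school is selected with
    certainty, possibly multiple times)."""


@dataclass(frozen=True)
class SchoolRecord:
    """One school in the sampling frame."""

    school_id: str
    enrollment: int
    name: str = ""
    year_group_counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.enrollment < 0 or int(self.enrollment) != self.enrollment:
            raise ValueError(
                f"school {self.school_id!r}: enrollment must be a non-negative "
                f"integer, got {self.enrollment!r}"
            )
        object.__setattr__(self, "enrollment", int(self.enrollment))
        if self.year_group_counts is not None:
            ygc = {str(k): int(v) for k, v in self.year_group_counts.items()}
            if any(v < 0 for v in ygc.values()):
                raise ValueError(
                    f"school {self.school_id!r}: negative year-group count"
                )
            if sum(ygc.values()) != self.enrollment:
                raise ValueError(
                    f"school {self.school_id!r}: year-group counts sum to "
                    f"{sum(ygc.values())}, enrollment is {self.enrollment}"
                )
            object.__setattr__(self, "year_group_counts", ygc)


@dataclass(frozen=True)
class SchoolFrame:
    """An ordered school sampling frame.

    Frame order is taken as given — no implicit sorting — so users may
    pre-sort geographically for implicit stratification.
    """

    records: tuple[SchoolRecord, ...]

    def __init__(self, records: Iterable[SchoolRecord]):
        object.__setattr__(self, "records", tuple(records))
        ids = [r.school_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate school_id values: {sorted(dupes)}")

    @property
    def total_enrollment(self) -> int:
        return sum(r.enrollment for r in self.records)

    @property
    def zero_enrollment_ids(self) -> list[str]:
        """Schools retained in the frame but unselectable (enrollment 0)."""
        return [r.school_id for r in self.records if r.enrollment == 0]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def school(self, school_id: str) -> SchoolRecord:
        for r in self.records:
            if r.school_id == school_id:
                return r
        raise KeyError(f"school {school_id!r} not in frame")


@dataclass(frozen=True)
class ClusterAllocation:
    """Clusters assigned to one selected school.

    ``children_to_sample`` is ``clusters_assigned * cluster_size`` capped at
    enrollment; ``shortfall`` is the uncapped excess — pupils the design asked
    for that the school cannot supply.  Shortfalls are surfaced (not silently
    absorbed) so planners can see where precision is lost.
    """

    school_id: str
    clusters_assigned: int
    children_to_sample: int
    shortfall: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_frame(source: str | Path | io.IOBase | pd.DataFrame) -> SchoolFrame:
    """Read a school frame from CSV (columns ``school_id``, ``enrollment``,
    optional ``name`` and year-group columns ``yg_*``).

    Lines starting with ``#`` are treated as comments.  Year-group counts, when
    present, must sum to the enrollment row-wise.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, comment="#", dtype={"school_id": str})
    for col in ("school_id", "enrollment"):
        if col not in df.columns:
            raise ValueError(f"frame is missing required column {col!r}")
    yg_cols = [c for c in df.columns if c.startswith("yg_")]
    records = []
    for idx, row in df.iterrows():
        ygc = None
        if yg_cols:
            vals = row[yg_cols]
            if vals.notna().any():
                ygc = {c: int(vals[c]) for c in yg_cols if pd.notna(vals[c])}
        try:
            records.append(
                SchoolRecord(
                    school_id=str(row["school_id"]),
                    enrollment=int(row["enrollment"]),
                    name=str(row.get("name", "") or ""),
                    year_group_counts=ygc,
                )
            )
        except ValueError as exc:
            raise ValueError(f"frame row {idx}: {exc}") from exc
    return SchoolFrame(records)


def sampling_interval(frame: SchoolFrame, n_clusters: int) -> float:
    """Systematic-PPS sampling interval ``total_enrollment / n_clusters``."""
    if n_clusters < 1:
        raise ValueError(f"n_clusters must be >= 1, got {n_clusters}")
    total = frame.total_enrollment
    if total <= 0:
        raise ValueError("frame has zero total enrollment; nothing to sample")
    if n_clusters > total:
        raise ValueError(
            f"n_clusters ({n_clusters}) exceeds total enrollment ({total})"
        )
    return total / n_clusters


def pps_systematic_sample(
    frame: SchoolFrame,
    n_clusters: int,
    seed: int | np.random.Generator | None = None,
    cluster_size: int = 100,
) -> list[ClusterAllocation]:
    """Select schools by systematic PPS (cumulative size, fixed interval,
    random start).

    Each of the ``n_clusters`` selection points lands in exactly one school's
    enrollment span, so allocations always sum to ``n_clusters``; a school
    spanning several points hosts several clusters.  Per draw, a school's
    selection probability is ``enrollment / total_enrollment``.
    """
    if not frame.records:
        raise ValueError("empty sampling frame")
    interval = sampling_interval(frame, n_clusters)
    rng = np.random.default_rng(seed)
    enroll = np.array([r.enrollment for r in frame.records], dtype=float)
    cum = np.cumsum(enroll)
    start = rng.uniform(0.0, interval)
    points = start + interval * np.arange(n_clusters)
    # side='right': a point on a boundary belongs to the next nonzero span
    idx = np.searchsorted(cum, points, side="right")
    hit_idx, hit_counts = np.unique(idx, return_counts=True)
    allocations = []
    for i, k in zip(hit_idx, hit_counts):
        rec = frame.records[int(i)]
        asked = int(k) * int(cluster_size)
        take = min(asked, rec.enrollment)
        allocations.append(
            ClusterAllocation(
                school_id=rec.school_id,
                clusters_assigned=int(k),
                children_to_sample=take,
                shortfall=asked - take,
            )
        )
    assert sum(a.clusters_assigned for a in allocations) == n_clusters
    return allocations


def _equal_quota(capacities: Sequence[int], quota: int) -> np.ndarray:
    """Split ``quota`` as equally as possible across groups, capping at group
    capacity and redistributing any excess over the remaining groups.

    Uses largest-remainder apportionment; with equal fractional remainders the
    earlier groups take the extra unit.
    """
    caps = np.asarray(capacities, dtype=int)
    alloc = np.zeros_like(caps)
    remaining = int(quota)
    active = caps > 0
    while remaining > 0 and active.any():
        n_active = int(active.sum())
        base, extra = divmod(remaining, n_active)
        want = np.zeros_like(caps)
        want[active] = base
        want[np.flatnonzero(active)[:extra]] += 1
        room = caps - alloc
        give = np.minimum(want, room)
        if give.sum() == 0:
            break
        alloc += give
        remaining -= int(give.sum())
        active &= alloc < caps
    return alloc


def second_stage_sample(
    school: SchoolRecord,
    cluster_size: int,
    seed: int | np.random.Generator | None = None,
    clusters_assigned: int = 1,
) -> np.ndarray:
    """Select pupils within one selected school.

    The quota is ``cluster_size * clusters_assigned``.  An undersized school
    returns its full roster (a census — the shortfall is visible on the
    :class:`ClusterAllocation`).  With year-group rosters the quota is spread
    equally across year groups (largest-remainder apportionment, capped at
    group size with redistribution) and drawn by simple random sampling within
    each group; otherwise a simple random sample of the whole roster is drawn.
    Returned indices are positions 0..enrollment-1 on the roster, with
    year groups laid out consecutively in roster order.
    """
    if school.enrollment == 0:
        raise ValueError(f"school {school.school_id!r} has no pupils enrolled")
    quota = int(cluster_size) * int(clusters_assigned)
    if quota < 1:
        raise ValueError("quota must be >= 1")
    if school.enrollment <= quota:
        return np.arange(school.enrollment)
    rng = np.random.default_rng(seed)
    if school.year_group_counts:
        groups = list(school.year_group_counts.items())
        counts = [c for _, c in groups]
        alloc = _equal_quota(counts, quota)
        offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
        chosen = [
            off + rng.choice(cnt, size=int(k), replace=False)
            for (off, cnt, k) in zip(offsets, counts, alloc)
            if k > 0
        ]
        return np.sort(np.concatenate(chosen))
    return np.sort(rng.choice(school.enrollment, size=quota, replace=False))


def inclusion_probability(
    frame: SchoolFrame,
    n_clusters: int,
    cluster_size: int,
    school_id: str,
) -> float:
    """Overall inclusion probability of a child at the given school.

    For a school with ``cluster_size <= enrollment <= interval`` the two
    stages cancel — ``(n_clusters * e / N) * (m / e) = n_clusters * m / N`` —
    the self-weighting property: the value is the same for every school.
    Outside that window the formula breaks: a school larger than the interval
    is a certainty (possibly multi-hit) selection
    (:class:`CertaintySelectionError`), and one smaller than the cluster quota
    is censused at stage two.
    """
    interval = sampling_interval(frame, n_clusters)
    rec = frame.school(school_id)
    if rec.enrollment > interval:
        raise CertaintySelectionError(
            f"school {school_id!r}: enrollment {rec.enrollment} exceeds the "
            f"sampling interval {interval:.1f}; selection is certain and the "
            "single-draw formula does not apply"
        )
    if rec.enrollment < cluster_size:
        raise ValueError(
            f"school {school_id!r}: enrollment {rec.enrollment} is below the "
            f"cluster size {cluster_size}; the second stage is a census and "
            "the child-level probability is enrollment-dependent"
        )
    return n_clusters * cluster_size / frame.total_enrollment
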