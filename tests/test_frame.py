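"""Frame loading, systematic PPS selection, second-stage sampling, and the
self-weighting inclusion probabilities — including seeded Monte-Carlo checks
of the selection probabilities."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eyesurvey import (
    CertaintySelectionError,
    SchoolFrame,
    SchoolRecord,
    inclusion_probability,
    load_frame,
    pps_systematic_sample,
    second_stage_sample,
)
from eyesurvey.frame import _equal_quota


def csv_frame(text: str) -> SchoolFrame:
    return load_frame(io.StringIO(text))


class TestLoadFrame:
    def test_total_enrollment(self):
        frame = csv_frame("school_id,enrollment\nA,300\nB,100\nC,100\n")
        assert frame.total_enrollment == 500
        assert len(frame) == 3

    def test_duplicate_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate school_id"):
            csv_frame("school_id,enrollment\nA,300\nA,100\n")

    def test_negative_enrollment_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            csv_frame("school_id,enrollment\nA,-5\n")

    def test_missing_column_named(self):
        with pytest.raises(ValueError, match="enrollment"):
            csv_frame("school_id,size\nA,300\n")

    def test_year_group_mismatch_names_row(self):
        with pytest.raises(ValueError, match="row 1"):
            csv_frame(
                "school_id,enrollment,yg_1,yg_2\nA,100,50,50\nB,100,40,50\n"
            )

    def test_zero_enrollment_retained_and_flagged(self):
        frame = csv_frame("school_id,enrollment\nA,300\nZ,0\n")
        assert len(frame) == 2
        assert frame.zero_enrollment_ids == ["Z"]


class TestPPSSystematic:
    def test_interval_divides_spans_exactly(self, abc_frame):
        # interval 100 divides A's 300-pupil span: allocation is start-free
        for seed in range(50):
            allocs = pps_systematic_sample(abc_frame, 5, seed=seed)
            by_id = {a.school_id: a.clusters_assigned for a in allocs}
            assert by_id == {"A": 3, "B": 1, "C": 1}

    def test_single_school(self):
        frame = SchoolFrame([SchoolRecord("only", 500)])
        (alloc,) = pps_systematic_sample(frame, 1, seed=0)
        assert alloc.school_id == "only"
        assert alloc.clusters_assigned == 1

    def test_equal_schools_one_cluster_each(self):
        frame = SchoolFrame([SchoolRecord(f"S{i}", 200) for i in range(7)])
        allocs = pps_systematic_sample(frame, 7, seed=3)
        assert all(a.clusters_assigned == 1 for a in allocs)
        assert len(allocs) == 7

    def test_shortfall_recorded_for_undersized_school(self):
        frame = SchoolFrame([SchoolRecord("small", 80)])
        (alloc,) = pps_systematic_sample(frame, 1, seed=0, cluster_size=100)
        assert alloc.children_to_sample == 80
        assert alloc.shortfall == 20

    def test_errors(self, abc_frame):
        with pytest.raises(ValueError):
            pps_systematic_sample(SchoolFrame([]), 1)
        with pytest.raises(ValueError, match="exceeds total enrollment"):
            pps_systematic_sample(abc_frame, 501)

    def test_determinism(self, ten_school_frame):
        a = pps_systematic_sample(ten_school_frame, 6, seed=42)
        b = pps_systematic_sample(ten_school_frame, 6, seed=42)
        assert a == b

    @given(
        st.lists(st.integers(min_value=0, max_value=2000), min_size=1, max_size=15),
        st.integers(min_value=1, max_value=20),
        st.integers(min_value=0, max_value=10_000),
    )
    @settings(deadline=None, derandomize=True, max_examples=80)
    def test_allocation_conservation(self, enrollments, n_clusters, seed):
        if sum(enrollments) < n_clusters:
            return
        frame = SchoolFrame(
            [SchoolRecord(f"S{i}", e) for i, e in enumerate(enrollments)]
        )
        allocs = pps_systematic_sample(frame, n_clusters, seed=seed)
        assert sum(a.clusters_assigned for a in allocs) == n_clusters
        selected = {a.school_id for a in allocs}
        assert not selected & set(frame.zero_enrollment_ids)

    def test_expected_hits_match_enrollment_share(self, ten_school_frame):
        """Monte Carlo: mean cluster count per school equals
        n_clusters * enrollment / total within 3 standard errors."""
        reps, k = 4000, 6
        total = ten_school_frame.total_enrollment
        hits = np.zeros((reps, len(ten_school_frame)))
        index = {r.school_id: i for i, r in enumerate(ten_school_frame)}
        rng = np.random.default_rng(2024)
        for r in range(reps):
            for a in pps_systematic_sample(ten_school_frame, k, seed=rng):
                hits[r, index[a.school_id]] = a.clusters_assigned
        mean = hits.mean(axis=0)
        se = hits.std(axis=0, ddof=1) / np.sqrt(reps)
        expected = np.array(
            [k * rec.enrollment / total for rec in ten_school_frame]
        )
        assert np.all(np.abs(mean - expected) <= 3 * np.maximum(se, 1e-9))


class TestSecondStage:
    def test_equal_year_group_apportionment(self):
        school = SchoolRecord(
            "S", 450, year_group_counts={f"yg_{i}": 75 for i in range(1, 7)}
        )
        idx = second_stage_sample(school, 100, seed=0)
        assert idx.size == 100
        # quota split (17,17,17,17,16,16) across consecutive 75-pupil groups
        counts = np.histogram(idx, bins=np.arange(0, 451, 75))[0]
        assert counts.tolist() == [17, 17, 17, 17, 16, 16]
        assert np.unique(idx).size == 100

    def test_undersized_school_census(self):
        school = SchoolRecord("S", 80)
        idx = second_stage_sample(school, 100, seed=0)
        assert idx.tolist() == list(range(80))

    def test_srs_cardinality(self):
        school = SchoolRecord("S", 1000)
        idx = second_stage_sample(school, 100, seed=1)
        assert idx.size == 100
        assert np.unique(idx).size == 100
        assert idx.min() >= 0 and idx.max() < 1000

    def test_multi_cluster_quota(self):
        school = SchoolRecord("big", 1000)
        idx = second_stage_sample(school, 100, seed=5, clusters_assigned=3)
        assert idx.size == 300
        assert np.unique(idx).size == 300

    def test_empty_school_rejected(self):
        with pytest.raises(ValueError, match="no pupils"):
            second_stage_sample(SchoolRecord("empty", 0), 100)

    def test_determinism(self):
        school = SchoolRecord("S", 600, year_group_counts={"a": 300, "b": 300})
        a = second_stage_sample(school, 100, seed=9)
        b = second_stage_sample(school, 100, seed=9)
        assert np.array_equal(a, b)

    def test_quota_cap_redistributes(self):
        # a tiny year group is capped at its size; the excess goes elsewhere
        alloc = _equal_quota([10, 200, 200], 100)
        assert alloc.tolist() == [10, 45, 45]
        assert alloc.sum() == 100

    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=8),
        st.integers(min_value=1, max_value=200),
    )
    @settings(deadline=None, derandomize=True, max_examples=80)
    def test_quota_conservation_and_caps(self, caps, quota):
        alloc = _equal_quota(caps, quota)
        assert (alloc <= np.asarray(caps)).all()
        assert alloc.sum() == min(quota, sum(caps))


class TestInclusionProbability:
    def test_self_weighting_value(self):
        frame = SchoolFrame(
            [SchoolRecord(f"S{i}", 500) for i in range(20)]
        )  # total 10,000
        for sid in ("S0", "S7", "S19"):
            assert inclusion_probability(frame, 10, 100, sid) == pytest.approx(0.1)

    def test_linear_in_clusters(self, ten_school_frame):
        p1 = inclusion_probability(ten_school_frame, 2, 80, "S4")
        p2 = inclusion_probability(ten_school_frame, 4, 80, "S4")
        assert p2 == pytest.approx(2 * p1)

    def test_certainty_selection_flagged(self):
        frame = SchoolFrame(
            [SchoolRecord("huge", 5000)] + [SchoolRecord(f"S{i}", 200) for i in range(10)]
        )
        with pytest.raises(CertaintySelectionError):
            inclusion_probability(frame, 10, 100, "huge")

    def test_undersized_school_flagged(self, ten_school_frame):
        with pytest.raises(ValueError, match="below the cluster size"):
            inclusion_probability(ten_school_frame, 2, 100, "S3")  # enrollment 80

    def test_child_selection_frequency_uniform_across_schools(self):
        """Monte Carlo self-weighting: each child's empirical selection
        frequency matches n_clusters*m/total regardless of school size."""
        sizes = [200, 250, 300, 350, 400]  # all >= m and <= interval (500)
        frame = SchoolFrame(
            [SchoolRecord(f"S{i}", e) for i, e in enumerate(sizes)]
        )
        k, m, reps = 3, 50, 4000
        total = frame.total_enrollment
        target = k * m / total
        counts = [np.zeros(e) for e in sizes]
        index = {r.school_id: i for i, r in enumerate(frame)}
        rng = np.random.default_rng(7)
        for _ in range(reps):
            for a in pps_systematic_sample(frame, k, seed=rng, cluster_size=m):
                i = index[a.school_id]
                chosen = second_stage_sample(
                    frame.records[i], m, seed=rng,
                    clusters_assigned=a.clusters_assigned,
                )
                counts[i][chosen] += 1
        for i, e in enumerate(sizes):
            freq = counts[i].mean() / reps
            q = k * e / total  # school-hit probability; count is m when hit
            se = m * np.sqrt(q * (1 - q) / reps) / e
            assert abs(freq - target) <= 3 * se, (i, freq, target)
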