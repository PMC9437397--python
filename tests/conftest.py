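import pytest

from eyesurvey import SchoolFrame, SchoolRecord


@pytest.fixture
def abc_frame() -> SchoolFrame:
    """Three schools, enrollments 300/100/100: the interval at 5 clusters is
    100, so the hit pattern is the same for every random start."""
    return SchoolFrame(
        [
            SchoolRecord("A", 300),
            SchoolRecord("B", 100),
            SchoolRecord("C", 100),
        ]
    )


@pytest.fixture
def ten_school_frame() -> SchoolFrame:
    enrollments = [120, 340, 560, 80, 900, 210, 430, 150, 670, 290]
    return SchoolFrame(
        [SchoolRecord(f"S{i}", e) for i, e in enumerate(enrollments)]
    )
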