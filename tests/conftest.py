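import pytest

import agrowth as ag


@pytest.fixture(scope="session")
def ref() -> ag.ReferenceSet:
    """A complete synthetic reference bundle (18 curves, fixed seed)."""
    return ag.generate_reference(7)


@pytest.fixture()
def simple_curve() -> ag.ReferenceCurve:
    """A tiny two-node identity-mode curve for interpolation arithmetic."""
    return ag.ReferenceCurve("height", "male", [
        ag.LMSNode(age=2.0, L=1.0, M=80.0, S=0.04),
        ag.LMSNode(age=3.0, L=1.0, M=86.0, S=0.04),
    ])


@pytest.fixture()
def boxcox_curve() -> ag.ReferenceCurve:
    """A two-node Box-Cox-mode curve with varying L."""
    return ag.ReferenceCurve("weight", "male", [
        ag.LMSNode(age=2.0, L=-1.2, M=12.0, S=0.10),
        ag.LMSNode(age=3.0, L=-1.0, M=13.0, S=0.12),
    ])


def minimal_csv_text() -> str:
    """A minimal valid bundle: one height/male curve spanning its domain."""
    return (
        "parameter,sex,age_years,L,M,S\n"
        "height,male,0.0,1.0,47.0,2.0\n"
        "height,male,20.0,1.0,131.0,5.5\n"
    )
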