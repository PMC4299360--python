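import pytest

from cowmorph import (
    ACoAShape,
    ACoAState,
    SubjectVesselRecord,
    load_fixture,
    reconstruct_from_crosstab,
)


def make_record(**overrides) -> SubjectVesselRecord:
    """A fully normal subject record; override fields as needed."""
    base = dict(
        subject_id="S0001",
        a1_left=2.0,
        a1_right=2.0,
        acoa_state=ACoAState.PRESENT,
        acoa_shape=ACoAShape.SINGLE_TUBULAR,
        pcoa_left=1.2,
        pcoa_right=1.2,
        p1_left=2.0,
        p1_right=2.0,
        dual_pca_left=False,
        dual_pca_right=False,
        trigeminal_variant=False,
    )
    base.update(overrides)
    return SubjectVesselRecord(**base)


@pytest.fixture(scope="session")
def t1_profiles():
    """The full 2246-subject cohort reconstructed from the cross-tabulation."""
    return reconstruct_from_crosstab(load_fixture("T1"))
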