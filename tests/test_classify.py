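import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cowmorph import (
    A1Status,
    ACoAShape,
    ACoAState,
    AnteriorType,
    COWCategory,
    ClassificationError,
    NOT_VISUALIZED,
    PCASideType,
    PosteriorType,
    classify_a1,
    classify_anterior,
    classify_cow,
    classify_pca_side,
    classify_posterior,
    classify_subject,
)

from conftest import make_record

N, M, H, A = (
    A1Status.NORMAL,
    A1Status.MILD_VARIATION,
    A1Status.HYPOPLASIA,
    A1Status.ABSENT,
)


class TestClassifyA1:
    @pytest.mark.parametrize(
        "left, right, expected",
        [
            (2.0, 2.0, (N, N)),  # symmetric, both well developed
            (2.2, 1.5, (N, M)),  # difference 0.7 mm in the mild band
            (2.2, 1.0, (N, H)),  # 1.0 < 2.2/2: under half the contralateral
            (2.0, NOT_VISUALIZED, (N, A)),  # no image on one side
            (NOT_VISUALIZED, NOT_VISUALIZED, (A, A)),
            (0.4, 2.0, (A, N)),  # sub-threshold caliber counts as absent
            (2.2, 1.7, (N, M)),  # difference exactly 0.5 mm: mild (inclusive)
            (2.2, 1.2, (N, M)),  # difference exactly 1.0 mm: mild (inclusive)
            (3.0, 1.7, (N, H)),  # gap > 1.0 mm although caliber > half
            (1.8, 0.85, (N, H)),  # mild band and half-rule overlap: severe wins
            (1.2, 1.3, (N, N)),  # small but balanced pair stays normal
        ],
    )
    def test_rules(self, left, right, expected):
        assert classify_a1(left, right) == expected

    def test_symmetry(self):
        l, r = classify_a1(2.2, 1.0)
        r2, l2 = classify_a1(1.0, 2.2)
        assert (l, r) == (l2, r2)

    def test_monotone_in_shrinking_caliber(self):
        """Shrinking one side against a fixed 2.2 mm contralateral can only
        escalate its status, never step back toward normal."""
        severities = [
            classify_a1(2.2, d)[1].severity for d in np.arange(2.2, 0.05, -0.05)
        ]
        assert severities == sorted(severities)
        path = [classify_a1(2.2, d)[1] for d in (1.5, 1.0, 0.4)]
        assert path == [M, H, A]


class TestClassifyAnterior:
    @pytest.mark.parametrize(
        "statuses, acoa, expected",
        [
            ((N, N), ACoAState.PRESENT, AnteriorType.I),
            ((N, M), ACoAState.PRESENT, AnteriorType.II),
            ((N, H), ACoAState.PRESENT, AnteriorType.III),
            ((N, A), ACoAState.PRESENT, AnteriorType.IV),
            ((A, A), ACoAState.ABSENT, AnteriorType.IV),  # A1 absence decides
            ((N, N), ACoAState.ABSENT, AnteriorType.V1),
            ((N, H), ACoAState.ABSENT, AnteriorType.V2),
            ((M, N), ACoAState.ABSENT, AnteriorType.V2),
            # an unclear ACoA cannot be confirmed to close the ring
            ((N, N), ACoAState.UNCLEAR, AnteriorType.V1),
            ((H, N), ACoAState.UNCLEAR, AnteriorType.V2),
        ],
    )
    def test_rules(self, statuses, acoa, expected):
        assert classify_anterior(statuses, acoa) is expected


class TestClassifyPCASide:
    @pytest.mark.parametrize(
        "p1, contra, pcoa, dual, expected",
        [
            (2.0, 2.0, 1.2, False, PCASideType.ADULT),
            (1.4, 1.5, 1.6, False, PCASideType.FTP_I),  # P1 < ipsilateral PCoA
            (0.8, 2.0, 1.6, False, PCASideType.FTP_II),  # and < half contralateral
            (NOT_VISUALIZED, 2.0, 1.8, False, PCASideType.FTP_III),
            (2.0, 2.0, 1.2, True, PCASideType.FTP_IV),
            (1.5, 2.0, 1.5, False, PCASideType.ADULT),  # P1 == PCoA: adult
            (2.0, 2.0, NOT_VISUALIZED, False, PCASideType.ADULT),  # no PCoA
            (0.8, NOT_VISUALIZED, 1.6, False, PCASideType.FTP_I),  # no contra to halve
        ],
    )
    def test_rules(self, p1, contra, pcoa, dual, expected):
        assert classify_pca_side(p1, contra, pcoa, dual) is expected

    def test_no_posterior_supply_is_an_error(self):
        with pytest.raises(ClassificationError, match="no posterior supply"):
            classify_pca_side(NOT_VISUALIZED, 2.0, 0.3, False)


ADULT, Q, P, DUAL = (
    PCASideType.ADULT,
    PCASideType.FTP_I,
    PCASideType.FTP_III,
    PCASideType.FTP_IV,
)
PRES, ABS = 1.2, NOT_VISUALIZED


class TestClassifyPosterior:
    @pytest.mark.parametrize(
        "pca, pcoa_l, pcoa_r, expected",
        [
            ((ADULT, ADULT), PRES, PRES, PosteriorType.a),
            ((Q, Q), PRES, PRES, PosteriorType.b),
            ((PCASideType.FTP_II, ADULT), PRES, PRES, PosteriorType.c),
            ((ADULT, ADULT), ABS, ABS, PosteriorType.d),
            ((ADULT, ADULT), PRES, ABS, PosteriorType.e),
            ((Q, ADULT), PRES, ABS, PosteriorType.f),
            ((P, ADULT), PRES, ABS, PosteriorType.g),
            ((P, ADULT), PRES, PRES, PosteriorType.h),
            ((P, Q), PRES, PRES, PosteriorType.i),
            ((P, P), 1.6, 1.6, PosteriorType.j),
            ((DUAL, ADULT), PRES, PRES, PosteriorType.k),
            ((ADULT, DUAL), ABS, PRES, PosteriorType.k),
        ],
    )
    def test_rules(self, pca, pcoa_l, pcoa_r, expected):
        assert classify_posterior(pca, pcoa_l, pcoa_r) is expected

    def test_ftp_on_side_without_pcoa_is_an_error(self):
        # a fetal-type PCA is carried by its own PCoA; without one the
        # combination is outside the typing system
        with pytest.raises(ClassificationError, match="unclassifiable"):
            classify_posterior((ADULT, Q), PRES, ABS)
        with pytest.raises(ClassificationError, match="unclassifiable"):
            classify_posterior((P, ADULT), ABS, ABS)


class TestClassifyCOW:
    @pytest.mark.parametrize(
        "anterior, posterior, category, variation",
        [
            (AnteriorType.I, PosteriorType.a, COWCategory.INTEGRAL, False),
            (AnteriorType.I, PosteriorType.d, COWCategory.PARTIAL, False),
            (AnteriorType.V1, PosteriorType.e, COWCategory.NONINTEGRAL, False),
            (AnteriorType.III, PosteriorType.a, COWCategory.INTEGRAL, True),
            (AnteriorType.I, PosteriorType.b, COWCategory.INTEGRAL, True),
            (AnteriorType.IV, PosteriorType.a, COWCategory.PARTIAL, False),
        ],
    )
    def test_rules(self, anterior, posterior, category, variation):
        assert classify_cow(anterior, posterior) == (category, variation)

    def test_every_type_pair_gets_exactly_one_category(self):
        for anterior in AnteriorType:
            for posterior in PosteriorType:
                category, _ = classify_cow(anterior, posterior)
                assert category in COWCategory


class TestClassifySubject:
    def test_fully_normal_record(self):
        profile = classify_subject(make_record())
        assert profile.anterior_type is AnteriorType.I
        assert profile.posterior_type is PosteriorType.a
        assert profile.cow_category is COWCategory.INTEGRAL
        assert not profile.variation_flag

    def test_composed_nonintegral_record(self):
        record = make_record(
            a1_right=NOT_VISUALIZED, pcoa_left=NOT_VISUALIZED, pcoa_right=NOT_VISUALIZED
        )
        profile = classify_subject(record)
        assert profile.anterior_type is AnteriorType.IV
        assert profile.posterior_type is PosteriorType.d
        assert profile.cow_category is COWCategory.NONINTEGRAL

    def test_dual_pca_dominates_posterior(self):
        profile = classify_subject(make_record(dual_pca_left=True))
        assert profile.posterior_type is PosteriorType.k

    def test_invalid_record_is_rejected(self):
        with pytest.raises(ValueError, match="a1_left"):
            classify_subject(make_record(a1_left=-1.0))

    diameter = st.one_of(st.none(), st.floats(min_value=0.05, max_value=4.0))

    @given(
        a1_l=diameter,
        a1_r=diameter,
        pcoa_l=diameter,
        pcoa_r=diameter,
        p1_l=diameter,
        p1_r=diameter,
        acoa=st.sampled_from(list(ACoAState)),
        dual_l=st.booleans(),
        dual_r=st.booleans(),
    )
    @settings(max_examples=300, derandomize=True)
    def test_exhaustive_and_deterministic(
        self, a1_l, a1_r, pcoa_l, pcoa_r, p1_l, p1_r, acoa, dual_l, dual_r
    ):
        """Any valid record maps to exactly one profile (or one declared
        error), and the mapping is a pure function."""
        shape = (
            ACoAShape.SINGLE_TUBULAR if acoa is ACoAState.PRESENT else ACoAShape.NONE
        )
        record = make_record(
            a1_left=a1_l,
            a1_right=a1_r,
            acoa_state=acoa,
            acoa_shape=shape,
            pcoa_left=pcoa_l,
            pcoa_right=pcoa_r,
            p1_left=p1_l,
            p1_right=p1_r,
            dual_pca_left=dual_l,
            dual_pca_right=dual_r,
        )
        try:
            first = classify_subject(record)
        except ClassificationError:
            with pytest.raises(ClassificationError):
                classify_subject(record)
            return
        assert first == classify_subject(record)
        assert first.anterior_type in AnteriorType
        assert first.posterior_type in PosteriorType
        assert first.cow_category in COWCategory
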