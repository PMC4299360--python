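"""Deterministic typing rules for the circle of Willis.

Every function here is pure.  The rules operate on diameters in millimetres
with a single absence convention: a vessel that is not visualized, or whose
caliber is below 0.5 mm, is regarded as absent (it cannot provide effective
collateral perfusion).

Rule summary
------------
A1 status (per side, against the contralateral side; most severe wins):
    ABSENT       not visualized or < 0.5 mm
    HYPOPLASIA   smaller side under half the contralateral caliber, or
                 smaller side of a pair differing by more than 1.0 mm
    MILD         smaller side of a pair differing by 0.5-1.0 mm (inclusive)
    NORMAL       otherwise; the larger side of an asymmetric pair is NORMAL
Anterior type: A1 statuses x ACoA patency -> I, II, III, IV, V1, V2.
PCA side type: P1 vs ipsilateral PCoA and contralateral P1 -> adult or one
    of the four fetal-type-PCA (FTP) subtypes.
Posterior type: per-side PCA types x PCoA patency -> a..k.
COW category: anterior + posterior integrity -> integral / partial /
    nonintegral, with a hypoplasia-based variation flag on integral rings.
"""

from __future__ import annotations

from .model import (
    ABSENCE_THRESHOLD_MM,
    A1Status,
    ACoAState,
    AnteriorType,
    COWCategory,
    NOT_VISUALIZED,
    PCASideType,
    PosteriorType,
    SideDiameter,
    SubjectTypeProfile,
    SubjectVesselRecord,
    validate_record,
)

__all__ = [
    "ClassificationError",
    "is_absent",
    "classify_a1",
    "classify_anterior",
    "classify_pca_side",
    "classify_posterior",
    "classify_cow",
    "classify_subject",
]


class ClassificationError(ValueError):
    """A vessel combination the typing system does not cover."""


def is_absent(diameter: SideDiameter, threshold: float = ABSENCE_THRESHOLD_MM) -> bool:
    """True if the vessel is regarded as absent (no image or < 0.5 mm)."""
    return diameter is NOT_VISUALIZED or diameter < threshold


def _a1_side_status(own: SideDiameter, contra: SideDiameter) -> A1Status:
    if is_absent(own):
        return A1Status.ABSENT
    if is_absent(contra):
        # own is the only visualized side; asymmetry rules need a pair
        return A1Status.NORMAL
    if own >= contra:
        return A1Status.NORMAL
    diff = contra - own
    # boundary tolerance far below the 3-decimal measurement precision, so
    # a difference of exactly 0.5 or 1.0 mm lands in the inclusive mild band
    eps = 1e-9
    if own < contra / 2.0 - eps or diff > 1.0 + eps:
        return A1Status.HYPOPLASIA
    if diff >= 0.5 - eps:
        return A1Status.MILD_VARIATION
    return A1Status.NORMAL


def classify_a1(
    a1_left: SideDiameter, a1_right: SideDiameter
) -> tuple[A1Status, A1Status]:
    """Grade both ACA-A1 segments.

    Asymmetry rules apply to the smaller side only: the larger side of an
    asymmetric pair is NORMAL unless itself below the absence threshold.
    When both apply (difference band and half-contralateral), the more
    severe class wins.
    """
    return _a1_side_status(a1_left, a1_right), _a1_side_status(a1_right, a1_left)


def classify_anterior(
    a1_status: tuple[A1Status, A1Status], acoa_state: ACoAState
) -> AnteriorType:
    """Type the anterior half-ring from A1 statuses and ACoA patency.

    A1 absence decides type IV outright, whatever the ACoA looks like.
    An unclear ACoA counts as not patent: it cannot be confirmed to close
    the ring, so such subjects fall in the nonintegral types.
    """
    left, right = a1_status
    worst = max(left, right, key=lambda s: s.severity)
    if worst is A1Status.ABSENT:
        return AnteriorType.IV
    patent = acoa_state is ACoAState.PRESENT
    if worst is A1Status.NORMAL:
        return AnteriorType.I if patent else AnteriorType.V1
    if not patent:
        return AnteriorType.V2
    if worst is A1Status.MILD_VARIATION:
        return AnteriorType.II
    return AnteriorType.III


def classify_pca_side(
    p1: SideDiameter,
    p1_contra: SideDiameter,
    pcoa: SideDiameter,
    dual_pca: bool,
) -> PCASideType:
    """Type one posterior cerebral artery.

    Adult type: P1 present and at least as wide as the ipsilateral PCoA
    (a missing PCoA with a present P1 is also adult).  FTP subtypes: I
    (P1 present but narrower than the PCoA), II (additionally under half
    the contralateral P1), III (P1 absent, PCA formed by PCoA extension),
    IV (dual PCA).  A P1 exactly equal to the PCoA is adult: fetal type
    requires the PCoA to be strictly wider.

    Raises
    ------
    ClassificationError
        If P1 and PCoA are both absent without a dual PCA — the side would
        have no posterior supply at all, which the record cannot represent.
    """
    if dual_pca:
        return PCASideType.FTP_IV
    p1_absent = is_absent(p1)
    pcoa_present = not is_absent(pcoa)
    if p1_absent:
        if pcoa_present:
            return PCASideType.FTP_III
        raise ClassificationError(
            "no posterior supply on side: P1 and PCoA both absent without dual PCA"
        )
    if pcoa_present and p1 < pcoa:
        if not is_absent(p1_contra) and p1 < p1_contra / 2.0:
            return PCASideType.FTP_II
        return PCASideType.FTP_I
    return PCASideType.ADULT


def classify_posterior(
    pca: tuple[PCASideType, PCASideType],
    pcoa_left: SideDiameter,
    pcoa_right: SideDiameter,
) -> PosteriorType:
    """Type the posterior half-ring from per-side PCA types and PCoA patency.

    A dual PCA on either side is type k regardless of the rest.  With both
    PCoAs patent the ring is integral (a, b, c) unless a pure FTP is
    involved (h, i, j); with one or no patent PCoA the ring is nonintegral
    (d, e, f, g).

    Raises
    ------
    ClassificationError
        For combinations outside the typing system, e.g. a quasi- or
        pure-FTP side whose own PCoA is absent (an FTP needs its PCoA).
    """
    left, right = pca
    if PCASideType.FTP_IV in (left, right):
        return PosteriorType.k
    pres_l = not is_absent(pcoa_left)
    pres_r = not is_absent(pcoa_right)
    n_quasi = sum(t.is_quasi_ftp for t in (left, right))
    n_pure = sum(t.is_pure_ftp for t in (left, right))
    n_adult = sum(t is PCASideType.ADULT for t in (left, right))

    if pres_l and pres_r:
        if n_adult == 2:
            return PosteriorType.a
        if n_quasi == 2:
            return PosteriorType.b
        if n_quasi == 1 and n_adult == 1:
            return PosteriorType.c
        if n_pure == 1 and n_adult == 1:
            return PosteriorType.h
        if n_pure == 1 and n_quasi == 1:
            return PosteriorType.i
        return PosteriorType.j  # n_pure == 2
    if not pres_l and not pres_r:
        if n_adult == 2:
            return PosteriorType.d
        raise ClassificationError(
            f"unclassifiable posterior pattern: ({left.value}, {right.value}) "
            "with both PCoAs absent"
        )
    # exactly one PCoA patent
    present_side = left if pres_l else right
    other_side = right if pres_l else left
    if other_side is not PCASideType.ADULT:
        raise ClassificationError(
            f"unclassifiable posterior pattern: {other_side.value} on the side "
            "whose PCoA is absent"
        )
    if present_side is PCASideType.ADULT:
        return PosteriorType.e
    if present_side.is_quasi_ftp:
        return PosteriorType.f
    return PosteriorType.g  # pure FTP on the patent side


def classify_cow(
    anterior: AnteriorType, posterior: PosteriorType
) -> tuple[COWCategory, bool]:
    """Categorize ring integrity and flag developmental variation.

    Returns ``(category, variation_flag)``.  The flag is defined for
    integral rings only (False otherwise): it marks hypoplasia-based
    variation — anterior type III, or a quasi-FTP posterior (b or c).
    """
    if anterior.is_integral and posterior.is_integral:
        variation = anterior is AnteriorType.III or posterior in (
            PosteriorType.b,
            PosteriorType.c,
        )
        return COWCategory.INTEGRAL, variation
    if not anterior.is_integral and not posterior.is_integral:
        return COWCategory.NONINTEGRAL, False
    return COWCategory.PARTIAL, False


def classify_subject(record: SubjectVesselRecord) -> SubjectTypeProfile:
    """Run the full typing pipeline on one validated record."""
    problems = validate_record(record)
    if problems:
        raise ValueError(
            f"invalid record {record.subject_id}: " + "; ".join(problems)
        )
    a1_l, a1_r = classify_a1(record.a1_left, record.a1_right)
    anterior = classify_anterior((a1_l, a1_r), record.acoa_state)
    pca_l = classify_pca_side(
        record.p1_left, record.p1_right, record.pcoa_left, record.dual_pca_left
    )
    pca_r = classify_pca_side(
        record.p1_right, record.p1_left, record.pcoa_right, record.dual_pca_right
    )
    posterior = classify_posterior((pca_l, pca_r), record.pcoa_left, record.pcoa_right)
    category, variation = classify_cow(anterior, posterior)
    return SubjectTypeProfile(
        subject_id=record.subject_id,
        a1_status_left=a1_l,
        a1_status_right=a1_r,
        anterior_type=anterior,
        pca_left=pca_l,
        pca_right=pca_r,
        posterior_type=posterior,
        cow_category=category,
        variation_flag=variation,
    )
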