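"""Domain types for circle-of-Willis (COW) vessel measurements and typing.

The circle of Willis is the arterial ring at the base of the brain joining
the anterior circulation (anterior cerebral arteries, A1 segments, anterior
communicating artery) to the posterior circulation (posterior cerebral
arteries, P1 segments, posterior communicating arteries).  A subject record
holds side-specific diameters in millimetres plus presence flags; a typing
profile holds the categorical labels the classifier assigns.

Diameters use ``float`` millimetres; a vessel that produces no (or a
non-consecutive) angiographic image is the distinguished state
:data:`NOT_VISUALIZED`, encoded as ``None``.  ``None`` is *not* the same as
0.0 mm: a zero diameter is rejected by validation as ambiguous, because
sub-threshold vessels are treated as absent rather than zero-width.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

#: Diameter threshold (mm) below which a vessel is regarded as absent:
#: below this caliber it cannot sustain effective collateral perfusion.
ABSENCE_THRESHOLD_MM = 0.5

#: Distinguished state for a vessel with no angiographic image.
NOT_VISUALIZED = None

#: A side-specific diameter: millimetres, or NOT_VISUALIZED (None).
SideDiameter = Optional[float]


class _LabeledEnum(enum.Enum):
    """Enum whose values are stable text labels (parse/format round-trip)."""

    def __str__(self) -> str:
        return self.value

    @classmethod
    def parse(cls, label: str):
        for member in cls:
            if member.value == label:
                return member
        raise ValueError(f"{cls.__name__}: unknown label {label!r}")


class A1Status(_LabeledEnum):
    """Developmental status of one ACA-A1 segment, ordered by severity.

    NORMAL: caliber >= 1.5 mm with left/right difference under 0.5 mm.
    MILD_VARIATION: the smaller side when the difference is 0.5-1.0 mm.
    HYPOPLASIA: caliber below half the contralateral homologue.
    ABSENT: no image, or caliber below the 0.5 mm absence threshold.
    """

    NORMAL = "Normal"
    MILD_VARIATION = "Mild variation"
    HYPOPLASIA = "Hypoplasia"
    ABSENT = "Absence"

    @property
    def severity(self) -> int:
        return _A1_SEVERITY[self]

    def __lt__(self, other: "A1Status") -> bool:
        return self.severity < other.severity

    def __le__(self, other: "A1Status") -> bool:
        return self.severity <= other.severity

    def __gt__(self, other: "A1Status") -> bool:
        return self.severity > other.severity

    def __ge__(self, other: "A1Status") -> bool:
        return self.severity >= other.severity


_A1_SEVERITY = {
    A1Status.NORMAL: 0,
    A1Status.MILD_VARIATION: 1,
    A1Status.HYPOPLASIA: 2,
    A1Status.ABSENT: 3,
}


class ACoAState(_LabeledEnum):
    """Patency of the anterior communicating artery on angiography."""

    PRESENT = "present"
    ABSENT = "absent"
    UNCLEAR = "unclear"


class ACoAShape(_LabeledEnum):
    """Morphological shape of a patent ACoA (NONE iff not patent)."""

    SINGLE_TUBULAR = "single-tubular"
    DOUBLE_BRANCH = "double-branch"
    Y_PATTERN = "Y-pattern"
    WINDOW_PATTERN = "window-pattern"
    AMPULLA = "ampulla"
    CIRCLE_PATTERN = "circle-pattern"
    NONE = "none"


class PCASideType(_LabeledEnum):
    """Per-side posterior cerebral artery type.

    ADULT: P1 present and at least as wide as the ipsilateral PCoA.
    FTP_I / FTP_II: quasi-fetal-type PCA — P1 present but narrower than the
        PCoA (FTP_II additionally under half the contralateral P1).
    FTP_III: pure fetal-type — P1 absent, the PCA formed by PCoA extension.
    FTP_IV: dual PCA fed by both the basilar and internal carotid arteries.
    """

    ADULT = "Adult"
    FTP_I = "FTP-I"
    FTP_II = "FTP-II"
    FTP_III = "FTP-III"
    FTP_IV = "FTP-IV"

    @property
    def is_quasi_ftp(self) -> bool:
        return self in (PCASideType.FTP_I, PCASideType.FTP_II)

    @property
    def is_pure_ftp(self) -> bool:
        return self is PCASideType.FTP_III

    @property
    def is_ftp(self) -> bool:
        return self is not PCASideType.ADULT


class AnteriorType(_LabeledEnum):
    """Anterior half-ring type from A1 balance and ACoA patency.

    I-III are integral (ACoA patent): balanced, mildly unbalanced,
    hypoplastic.  IV (an A1 absent), V1 (balanced, ACoA absent) and
    V2 (unbalanced, ACoA absent) are nonintegral.
    """

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V1 = "V1"
    V2 = "V2"

    @property
    def is_integral(self) -> bool:
        return self in (AnteriorType.I, AnteriorType.II, AnteriorType.III)

    @property
    def is_balanced(self) -> bool:
        """Balanced A1 development (types I and V1)."""
        return self in (AnteriorType.I, AnteriorType.V1)


class PosteriorType(_LabeledEnum):
    """Posterior half-ring type from per-side PCA types and PCoA patency.

    a-c are integral (both PCoAs patent): adult/adult, bilateral quasi-FTP,
    unilateral quasi-FTP.  d-k are nonintegral: PCoA absence patterns,
    pure-FTP patterns, and the dual-PCA pattern k.
    """

    a = "a"
    b = "b"
    c = "c"
    d = "d"
    e = "e"
    f = "f"
    g = "g"
    h = "h"
    i = "i"
    j = "j"
    k = "k"

    @property
    def is_integral(self) -> bool:
        return self in (PosteriorType.a, PosteriorType.b, PosteriorType.c)


class COWCategory(_LabeledEnum):
    """Overall ring integrity: both, exactly one, or neither half integral."""

    INTEGRAL = "integral"
    PARTIAL = "partial"
    NONINTEGRAL = "nonintegral"


@dataclass(frozen=True)
class SubjectVesselRecord:
    """Raw per-subject vessel measurements for both sides.

    Diameters are millimetres or NOT_VISUALIZED (None); booleans flag the
    dual-PCA variant per side and the rare persistent trigeminal artery
    (carried as an annotation only).
    """

    subject_id: str
    a1_left: SideDiameter
    a1_right: SideDiameter
    acoa_state: ACoAState
    acoa_shape: ACoAShape
    pcoa_left: SideDiameter
    pcoa_right: SideDiameter
    p1_left: SideDiameter
    p1_right: SideDiameter
    dual_pca_left: bool = False
    dual_pca_right: bool = False
    trigeminal_variant: bool = False


@dataclass(frozen=True)
class SubjectTypeProfile:
    """Classified labels for one subject: every typing output of the rules."""

    subject_id: str
    a1_status_left: A1Status
    a1_status_right: A1Status
    anterior_type: AnteriorType
    pca_left: PCASideType
    pca_right: PCASideType
    posterior_type: PosteriorType
    cow_category: COWCategory
    variation_flag: bool


_DIAMETER_FIELDS = (
    "a1_left", "a1_right", "pcoa_left", "pcoa_right", "p1_left", "p1_right",
)


def validate_record(record: SubjectVesselRecord) -> list[str]:
    """Check a record against the data-model invariants.

    Returns a list of human-readable violation descriptions, each naming
    the offending field; an empty list means the record is well formed.
    Violations are data, not exceptions: callers decide how to react.
    A pure function — identical input yields the identical list.
    """
    violations: list[str] = []
    for name in _DIAMETER_FIELDS:
        value = getattr(record, name)
        if value is NOT_VISUALIZED:
            continue
        if not isinstance(value, (int, float)):
            violations.append(f"{name}: diameter must be a number or NOT_VISUALIZED")
        elif value < 0:
            violations.append(f"{name}: negative diameter {value} mm")
        elif value == 0:
            violations.append(
                f"{name}: 0.0 mm is ambiguous; use NOT_VISUALIZED for an absent vessel"
            )
    if record.acoa_state is ACoAState.PRESENT:
        if record.acoa_shape is ACoAShape.NONE:
            violations.append(
                "acoa_shape: must name a shape when acoa_state is present"
            )
    else:
        if record.acoa_shape is not ACoAShape.NONE:
            violations.append(
                f"acoa_shape: must be none when acoa_state is "
                f"{record.acoa_state.value}, got {record.acoa_shape.value}"
            )
    return violations
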