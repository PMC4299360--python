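"""Cohort aggregation: contingency tables and headline proportions.

All aggregations are order-invariant functions of a list of
:class:`~cowmorph.model.SubjectTypeProfile`.  Margins are always recomputed
from the cell counts, never stored independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    A1Status,
    AnteriorType,
    COWCategory,
    PCASideType,
    PosteriorType,
    SubjectTypeProfile,
)

__all__ = [
    "ContingencyTable",
    "CohortSummary",
    "crosstab_cow",
    "table_balance_integrity",
    "table_a1_by_side",
    "table_a1var_sides_by_pca",
    "table_acoa_patency",
    "summarize",
]

ANTERIOR_ORDER = tuple(t.value for t in AnteriorType)
POSTERIOR_ORDER = tuple(t.value for t in PosteriorType)
A1_ORDER = tuple(s.value for s in A1Status)
PCA_ORDER = tuple(t.value for t in PCASideType)


@dataclass(frozen=True)
class ContingencyTable:
    """A labeled rectangular count table with optional ordinal scores."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray
    row_scores: Optional[tuple[float, ...]] = None
    col_scores: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"counts shape {counts.shape} does not match labels "
                f"({len(self.row_labels)} x {len(self.col_labels)})"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def cell(self, row: str, col: str) -> int:
        return int(
            self.counts[self.row_labels.index(row), self.col_labels.index(col)]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )


def _crosstab(
    pairs: Iterable[tuple[str, str]],
    row_labels: Sequence[str],
    col_labels: Sequence[str],
) -> np.ndarray:
    ri = {label: i for i, label in enumerate(row_labels)}
    ci = {label: j for j, label in enumerate(col_labels)}
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=int)
    for row, col in pairs:
        counts[ri[row], ci[col]] += 1
    return counts


def crosstab_cow(profiles: Sequence[SubjectTypeProfile]) -> ContingencyTable:
    """Anterior type (I..V2) by posterior type (a..k) cross-tabulation."""
    counts = _crosstab(
        ((p.anterior_type.value, p.posterior_type.value) for p in profiles),
        ANTERIOR_ORDER,
        POSTERIOR_ORDER,
    )
    return ContingencyTable(ANTERIOR_ORDER, POSTERIOR_ORDER, counts)


def table_balance_integrity(
    profiles: Sequence[SubjectTypeProfile],
) -> ContingencyTable:
    """A1 balance (balanced {I, V1} vs unbalanced) by anterior integrity, 2x2."""
    rows = ("A1 balanced", "A1 unbalanced")
    cols = ("integral", "nonintegral")
    pairs = (
        (
            rows[0] if p.anterior_type.is_balanced else rows[1],
            cols[0] if p.anterior_type.is_integral else cols[1],
        )
        for p in profiles
    )
    return ContingencyTable(rows, cols, _crosstab(pairs, rows, cols))


def table_a1_by_side(profiles: Sequence[SubjectTypeProfile]) -> ContingencyTable:
    """Side (L, R) by A1 status; one observation per subject per side."""
    rows = ("L", "R")
    pairs = [("L", p.a1_status_left.value) for p in profiles]
    pairs += [("R", p.a1_status_right.value) for p in profiles]
    return ContingencyTable(rows, A1_ORDER, _crosstab(pairs, rows, A1_ORDER))


def _variation_sides(
    profile: SubjectTypeProfile,
) -> tuple[tuple[A1Status, PCASideType], tuple[A1Status, PCASideType]]:
    """Split one A1-variation subject into (normal-lateral, variation-lateral).

    The milder side plays the "normal lateral" role (its own status is kept,
    so a bilaterally varied subject contributes no Normal-row observation).
    Equal severities tie-break to the left side as the normal lateral.
    """
    left = (profile.a1_status_left, profile.pca_left)
    right = (profile.a1_status_right, profile.pca_right)
    if profile.a1_status_right.severity >= profile.a1_status_left.severity:
        return left, right
    return right, left


def table_a1var_sides_by_pca(
    profiles: Sequence[SubjectTypeProfile],
) -> ContingencyTable:
    """Among A1-variation subjects: each side's A1 status by its PCA type.

    Every subject with at least one non-normal A1 contributes two
    observations, one for its normal (milder) lateral and one for its
    variation lateral, each tabulated under that side's own A1 status and
    PCA type.  Rows carry scores 1..4 (severity) and columns 0..4 (the
    adult column being the reference) for trend testing.
    """
    pairs: list[tuple[str, str]] = []
    for p in profiles:
        if p.a1_status_left is A1Status.NORMAL and p.a1_status_right is A1Status.NORMAL:
            continue
        for status, pca in _variation_sides(p):
            pairs.append((status.value, pca.value))
    counts = _crosstab(pairs, A1_ORDER, PCA_ORDER)
    return ContingencyTable(
        A1_ORDER,
        PCA_ORDER,
        counts,
        row_scores=(1.0, 2.0, 3.0, 4.0),
        col_scores=(0.0, 1.0, 2.0, 3.0, 4.0),
    )


def table_acoa_patency(profiles: Sequence[SubjectTypeProfile]) -> ContingencyTable:
    """A1 variation (vs balanced) by ACoA patency, 2x2, from anterior types.

    The profile does not carry the raw ACoA state, but the anterior type
    encodes it: I/II/III imply a patent ACoA, V1/V2 a non-patent one.  Type
    IV (an absent A1) is typed without regard to the ACoA and is counted as
    patent here, which is the allocation the source cohort's margins imply
    (all its A1-absent subjects had a patent ACoA).
    """
    rows = ("A1 variation", "A1 balanced")
    cols = ("ACoA patent", "ACoA not patent")
    pairs = []
    for p in profiles:
        row = rows[1] if p.anterior_type.is_balanced else rows[0]
        patent = p.anterior_type in (
            AnteriorType.I,
            AnteriorType.II,
            AnteriorType.III,
            AnteriorType.IV,
        )
        pairs.append((row, cols[0] if patent else cols[1]))
    return ContingencyTable(rows, cols, _crosstab(pairs, rows, cols))


@dataclass(frozen=True)
class CohortSummary:
    """Headline counts for one classified cohort; proportions on demand."""

    n_total: int
    n_integral: int
    n_partial: int
    n_nonintegral: int
    n_nonvariation_integral: int
    n_anterior_integral: int
    n_posterior_integral: int
    n_a1_variation: int
    n_ftp_subjects: int

    @property
    def n_posterior_nonintegral(self) -> int:
        return self.n_total - self.n_posterior_integral

    def proportions(self) -> dict[str, float]:
        """Full-precision fractions of the cohort (render at 2 dp percent)."""
        n = self.n_total
        return {
            "integral": self.n_integral / n,
            "partial": self.n_partial / n,
            "nonintegral": self.n_nonintegral / n,
            "nonvariation_integral": self.n_nonvariation_integral / n,
            "anterior_integral": self.n_anterior_integral / n,
            "posterior_integral": self.n_posterior_integral / n,
            "posterior_nonintegral": self.n_posterior_nonintegral / n,
            "a1_variation": self.n_a1_variation / n,
            "ftp_subjects": self.n_ftp_subjects / n,
        }

    def percentages(self) -> dict[str, float]:
        return {k: round(100.0 * v, 2) for k, v in self.proportions().items()}


def summarize(profiles: Sequence[SubjectTypeProfile]) -> CohortSummary:
    """Count every headline partition of a classified cohort."""
    if not profiles:
        raise ValueError("empty cohort")
    n_int = sum(p.cow_category is COWCategory.INTEGRAL for p in profiles)
    n_par = sum(p.cow_category is COWCategory.PARTIAL for p in profiles)
    n_non = sum(p.cow_category is COWCategory.NONINTEGRAL for p in profiles)
    return CohortSummary(
        n_total=len(profiles),
        n_integral=n_int,
        n_partial=n_par,
        n_nonintegral=n_non,
        n_nonvariation_integral=sum(
            p.cow_category is COWCategory.INTEGRAL and not p.variation_flag
            for p in profiles
        ),
        n_anterior_integral=sum(p.anterior_type.is_integral for p in profiles),
        n_posterior_integral=sum(p.posterior_type.is_integral for p in profiles),
        n_a1_variation=sum(
            p.a1_status_left is not A1Status.NORMAL
            or p.a1_status_right is not A1Status.NORMAL
            for p in profiles
        ),
        n_ftp_subjects=sum(p.pca_left.is_ftp or p.pca_right.is_ftp for p in profiles),
    )
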