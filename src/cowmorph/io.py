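"""Delimited-text formats for subject records, profiles, and tables.

The subject CSV dialect: one row per subject, a mandatory header, diameters
in millimetres with three decimal places, an empty cell or ``NA`` for a
vessel that was not visualized, and booleans as ``0``/``1``.  Unknown
columns are preserved and ignored.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .aggregate import ContingencyTable
from .model import (
    A1Status,
    ACoAShape,
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
    "SUBJECT_COLUMNS",
    "PROFILE_COLUMNS",
    "read_subjects",
    "write_subjects",
    "read_profiles",
    "profiles_to_frame",
    "write_table",
    "table_to_json",
]

SUBJECT_COLUMNS = (
    "subject_id",
    "a1_left_mm",
    "a1_right_mm",
    "acoa_state",
    "acoa_shape",
    "pcoa_left_mm",
    "pcoa_right_mm",
    "p1_left_mm",
    "p1_right_mm",
    "dual_pca_left",
    "dual_pca_right",
    "trigeminal_variant",
)

PROFILE_COLUMNS = (
    "a1_status_left",
    "a1_status_right",
    "anterior_type",
    "pca_left",
    "pca_right",
    "posterior_type",
    "cow_category",
    "variation_flag",
)

_NA_TOKENS = ("", "NA")


def _parse_diameter(cell: str, row: int, column: str) -> SideDiameter:
    text = cell.strip()
    if text in _NA_TOKENS:
        return NOT_VISUALIZED
    try:
        return float(text)
    except ValueError:
        raise ValueError(
            f"row {row}, column {column}: unparseable diameter {cell!r}"
        ) from None


def _parse_bool(cell: str, row: int, column: str) -> bool:
    text = cell.strip()
    if text in ("0", "1"):
        return text == "1"
    raise ValueError(f"row {row}, column {column}: expected 0 or 1, got {cell!r}")


def _format_diameter(value: SideDiameter) -> str:
    return "NA" if value is NOT_VISUALIZED else f"{value:.3f}"


def read_subjects(path: Union[str, Path]) -> list[SubjectVesselRecord]:
    """Read and validate a subject CSV.

    Raises ``ValueError`` naming any missing required column, any
    unparseable cell (with its row and column), and — after parsing — all
    per-row data-model violations, each prefixed with its row number.
    Row numbers count data rows from 1.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SUBJECT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    records: list[SubjectVesselRecord] = []
    problems: list[str] = []
    for position, (_, row) in enumerate(frame.iterrows(), start=1):
        record = SubjectVesselRecord(
            subject_id=row["subject_id"].strip(),
            a1_left=_parse_diameter(row["a1_left_mm"], position, "a1_left_mm"),
            a1_right=_parse_diameter(row["a1_right_mm"], position, "a1_right_mm"),
            acoa_state=ACoAState.parse(row["acoa_state"].strip()),
            acoa_shape=ACoAShape.parse(row["acoa_shape"].strip()),
            pcoa_left=_parse_diameter(row["pcoa_left_mm"], position, "pcoa_left_mm"),
            pcoa_right=_parse_diameter(row["pcoa_right_mm"], position, "pcoa_right_mm"),
            p1_left=_parse_diameter(row["p1_left_mm"], position, "p1_left_mm"),
            p1_right=_parse_diameter(row["p1_right_mm"], position, "p1_right_mm"),
            dual_pca_left=_parse_bool(row["dual_pca_left"], position, "dual_pca_left"),
            dual_pca_right=_parse_bool(
                row["dual_pca_right"], position, "dual_pca_right"
            ),
            trigeminal_variant=_parse_bool(
                row["trigeminal_variant"], position, "trigeminal_variant"
            ),
        )
        for violation in validate_record(record):
            problems.append(f"row {position}: {violation}")
        records.append(record)
    if problems:
        raise ValueError("invalid subject file:\n" + "\n".join(problems))
    return records


def subjects_to_frame(records: Iterable[SubjectVesselRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "a1_left_mm": _format_diameter(r.a1_left),
            "a1_right_mm": _format_diameter(r.a1_right),
            "acoa_state": r.acoa_state.value,
            "acoa_shape": r.acoa_shape.value,
            "pcoa_left_mm": _format_diameter(r.pcoa_left),
            "pcoa_right_mm": _format_diameter(r.pcoa_right),
            "p1_left_mm": _format_diameter(r.p1_left),
            "p1_right_mm": _format_diameter(r.p1_right),
            "dual_pca_left": int(r.dual_pca_left),
            "dual_pca_right": int(r.dual_pca_right),
            "trigeminal_variant": int(r.trigeminal_variant),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(SUBJECT_COLUMNS))


def write_subjects(
    records: Iterable[SubjectVesselRecord], path: Union[str, Path]
) -> None:
    """Write records as subject CSV (3-decimal diameters, NA for absent)."""
    subjects_to_frame(records).to_csv(path, index=False)


def profiles_to_frame(profiles: Iterable[SubjectTypeProfile]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": p.subject_id,
            "a1_status_left": p.a1_status_left.value,
            "a1_status_right": p.a1_status_right.value,
            "anterior_type": p.anterior_type.value,
            "pca_left": p.pca_left.value,
            "pca_right": p.pca_right.value,
            "posterior_type": p.posterior_type.value,
            "cow_category": p.cow_category.value,
            "variation_flag": int(p.variation_flag),
        }
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=["subject_id", *PROFILE_COLUMNS])


def read_profiles(path: Union[str, Path]) -> list[SubjectTypeProfile]:
    """Read a profile CSV (the output of the classify command)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("subject_id", *PROFILE_COLUMNS) if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    profiles = []
    for _, row in frame.iterrows():
        profiles.append(
            SubjectTypeProfile(
                subject_id=row["subject_id"],
                a1_status_left=A1Status.parse(row["a1_status_left"]),
                a1_status_right=A1Status.parse(row["a1_status_right"]),
                anterior_type=AnteriorType.parse(row["anterior_type"]),
                pca_left=PCASideType.parse(row["pca_left"]),
                pca_right=PCASideType.parse(row["pca_right"]),
                posterior_type=PosteriorType.parse(row["posterior_type"]),
                cow_category=COWCategory.parse(row["cow_category"]),
                variation_flag=row["variation_flag"].strip() == "1",
            )
        )
    return profiles


def write_table(table: ContingencyTable, path: Union[str, Path]) -> None:
    """Render a contingency table as TSV with labeled rows and columns."""
    table.to_dataframe().to_csv(path, sep="\t")


def table_to_json(table: ContingencyTable) -> dict:
    payload: dict = {
        "row_labels": list(table.row_labels),
        "col_labels": list(table.col_labels),
        "counts": table.counts.tolist(),
        "grand_total": table.grand_total,
    }
    if table.row_scores is not None:
        payload["row_scores"] = list(table.row_scores)
    if table.col_scores is not None:
        payload["col_scores"] = list(table.col_scores)
    return payload
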