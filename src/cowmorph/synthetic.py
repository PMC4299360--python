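"""Synthetic cohorts: printed-table reconstructions and stochastic sampling.

Two kinds of test input are produced here:

* **Deterministic reconstructions** of the published cross-tabulations.
  Each printed table ships as a delimited-text fixture inside the package;
  :func:`reconstruct_from_crosstab` expands an anterior-by-posterior count
  table into an ordered list of categorical subject profiles whose
  re-aggregation reproduces the table exactly.
* **Stochastic measurement-level cohorts**: :func:`sample_cohort` draws an
  (anterior, posterior) label pair per subject and then draws diameters
  from that pair's admissible region, so the deterministic classifier
  recovers the drawn labels by construction.  This is the driver of the
  classifier round-trip property.

The tables are mutually inconsistent in a few cells (see
``data/discrepancies.json``); each statistic is therefore computed from its
own source table, as in the original analysis, and no master cohort is
forced to satisfy every table simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
import json
import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from .aggregate import ContingencyTable
from .classify import classify_cow
from .model import (
    ABSENCE_THRESHOLD_MM,
    A1Status,
    ACoAShape,
    ACoAState,
    AnteriorType,
    NOT_VISUALIZED,
    PCASideType,
    PosteriorType,
    SubjectTypeProfile,
    SubjectVesselRecord,
)

__all__ = [
    "FIXTURE_IDS",
    "load_fixture",
    "load_discrepancies",
    "reconstruct_from_crosstab",
    "DiameterModel",
    "CohortSpec",
    "sample_cohort",
]

_FIXTURE_FILES = {
    "T1": "table1.tsv",
    "T2": "table2.tsv",
    "T3": "table3.tsv",
    "T4": "table4.tsv",
    "T5": "table5.tsv",
    "T6": "table6.tsv",
    "S34": "sec34.tsv",
    "P1S": "p1_sides.tsv",
}

FIXTURE_IDS = tuple(_FIXTURE_FILES)

# ordinal scores used by the published trend tests on these fixtures
_FIXTURE_SCORES: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "T6": ((1.0, 2.0, 3.0, 4.0), (0.0, 1.0, 2.0, 3.0, 4.0)),
    "S34": ((1.0, 2.0, 3.0, 4.0), (1.0, 0.0)),
}


def load_fixture(fixture_id: str) -> ContingencyTable:
    """Load one packaged printed-table fixture as a ContingencyTable.

    Identifiers: T1 (anterior x posterior), T2 (balance x integrity),
    T3 (side x A1 status), T4 (ACoA shape census), T5 (posterior census),
    T6 (A1-variation sides x PCA type), S34 (subject A1 status x FTP
    formation), P1S (side x P1 status).  Ordinal scores used by the
    published trend analyses are attached where applicable.
    """
    try:
        filename = _FIXTURE_FILES[fixture_id]
    except KeyError:
        raise KeyError(
            f"unknown fixture {fixture_id!r}; expected one of {FIXTURE_IDS}"
        ) from None
    with resources.files("cowmorph.data").joinpath(filename).open() as handle:
        frame = pd.read_csv(handle, sep="\t", index_col=0)
    scores = _FIXTURE_SCORES.get(fixture_id, (None, None))
    return ContingencyTable(
        row_labels=tuple(str(r) for r in frame.index),
        col_labels=tuple(str(c) for c in frame.columns),
        counts=frame.to_numpy(dtype=int),
        row_scores=scores[0],
        col_scores=scores[1],
    )


def load_discrepancies() -> dict:
    """The packaged notes on known internal inconsistencies of the tables."""
    with resources.files("cowmorph.data").joinpath("discrepancies.json").open() as fh:
        return json.load(fh)


# Canonical per-side fills used when only the (anterior, posterior) pair is
# known: the side-level detail is chosen to be consistent with the pair.
_CANONICAL_A1: dict[AnteriorType, tuple[A1Status, A1Status]] = {
    AnteriorType.I: (A1Status.NORMAL, A1Status.NORMAL),
    AnteriorType.II: (A1Status.NORMAL, A1Status.MILD_VARIATION),
    AnteriorType.III: (A1Status.NORMAL, A1Status.HYPOPLASIA),
    AnteriorType.IV: (A1Status.NORMAL, A1Status.ABSENT),
    AnteriorType.V1: (A1Status.NORMAL, A1Status.NORMAL),
    AnteriorType.V2: (A1Status.NORMAL, A1Status.HYPOPLASIA),
}

_CANONICAL_PCA: dict[PosteriorType, tuple[PCASideType, PCASideType]] = {
    PosteriorType.a: (PCASideType.ADULT, PCASideType.ADULT),
    PosteriorType.b: (PCASideType.FTP_I, PCASideType.FTP_I),
    PosteriorType.c: (PCASideType.FTP_I, PCASideType.ADULT),
    PosteriorType.d: (PCASideType.ADULT, PCASideType.ADULT),
    PosteriorType.e: (PCASideType.ADULT, PCASideType.ADULT),
    PosteriorType.f: (PCASideType.FTP_I, PCASideType.ADULT),
    PosteriorType.g: (PCASideType.FTP_III, PCASideType.ADULT),
    PosteriorType.h: (PCASideType.FTP_III, PCASideType.ADULT),
    PosteriorType.i: (PCASideType.FTP_III, PCASideType.FTP_I),
    PosteriorType.j: (PCASideType.FTP_III, PCASideType.FTP_III),
    PosteriorType.k: (PCASideType.FTP_IV, PCASideType.ADULT),
}


def profile_for_types(
    anterior: AnteriorType, posterior: PosteriorType, subject_id: str
) -> SubjectTypeProfile:
    """Build a categorical profile consistent with one label pair."""
    a1 = _CANONICAL_A1[anterior]
    pca = _CANONICAL_PCA[posterior]
    category, variation = classify_cow(anterior, posterior)
    return SubjectTypeProfile(
        subject_id=subject_id,
        a1_status_left=a1[0],
        a1_status_right=a1[1],
        anterior_type=anterior,
        pca_left=pca[0],
        pca_right=pca[1],
        posterior_type=posterior,
        cow_category=category,
        variation_flag=variation,
    )


def reconstruct_from_crosstab(
    table: ContingencyTable, id_prefix: str = "S"
) -> list[SubjectTypeProfile]:
    """Expand an anterior-by-posterior count table into subject profiles.

    Deterministic and ordered: cells are expanded row-major, so subject
    identifiers are stable and re-cross-tabulating the result reproduces
    the input table exactly.
    """
    if np.any(table.counts < 0):
        raise ValueError("negative counts cannot be reconstructed")
    profiles: list[SubjectTypeProfile] = []
    serial = 0
    for i, row in enumerate(table.row_labels):
        anterior = AnteriorType.parse(row)
        for j, col in enumerate(table.col_labels):
            posterior = PosteriorType.parse(col)
            for _ in range(int(table.counts[i, j])):
                serial += 1
                profiles.append(
                    profile_for_types(anterior, posterior, f"{id_prefix}{serial:04d}")
                )
    return profiles


@dataclass(frozen=True)
class DiameterModel:
    """Truncated normal model for one vessel class: loc/scale/bounds in mm."""

    loc: float
    scale: float
    low: float
    high: float

    def validate(self, name: str) -> None:
        if not (self.low < self.high):
            raise ValueError(f"diameter model {name}: empty truncation region")
        if self.scale <= 0:
            raise ValueError(f"diameter model {name}: scale must be positive")

    def sample(
        self,
        rng: np.random.Generator,
        low: Optional[float] = None,
        high: Optional[float] = None,
    ) -> float:
        """Inverse-CDF draw from the truncated normal, with optional
        per-draw tightening of the bounds."""
        lo = self.low if low is None else max(self.low, low)
        hi = self.high if high is None else min(self.high, high)
        if not lo < hi:
            raise ValueError(f"empty truncation region [{lo}, {hi}]")
        a = _norm.cdf((lo - self.loc) / self.scale)
        b = _norm.cdf((hi - self.loc) / self.scale)
        u = rng.uniform(a, b)
        x = self.loc + self.scale * float(_norm.ppf(u))
        return float(min(max(x, lo), hi))


#: Defaults chosen so every class's sampled diameters stay strictly inside
#: that class's region of the decision rules (the label-recovery invariant);
#: they are implementation defaults, not observed population values.
DEFAULT_DIAMETER_MODELS: dict[str, DiameterModel] = {
    "a1_normal": DiameterModel(loc=2.2, scale=0.25, low=1.6, high=3.5),
    "p1_adult": DiameterModel(loc=2.1, scale=0.15, low=1.9, high=2.5),
    "p1_quasi": DiameterModel(loc=1.45, scale=0.15, low=1.3, high=1.7),
    "pcoa_patent": DiameterModel(loc=1.0, scale=0.25, low=0.6, high=1.5),
}

# ACoA shape frequencies among patent cases, from the published shape census
_ACOA_SHAPES = (
    ACoAShape.SINGLE_TUBULAR,
    ACoAShape.DOUBLE_BRANCH,
    ACoAShape.Y_PATTERN,
    ACoAShape.WINDOW_PATTERN,
    ACoAShape.AMPULLA,
    ACoAShape.CIRCLE_PATTERN,
)
_ACOA_SHAPE_WEIGHTS = np.array([1631, 76, 22, 88, 14, 3], dtype=float)
_ACOA_SHAPE_PROBS = _ACOA_SHAPE_WEIGHTS / _ACOA_SHAPE_WEIGHTS.sum()

#: Prevalence of the persistent trigeminal artery in the study population.
TRIGEMINAL_RATE = 3 / 2246


def _uniform_probs(enum_cls) -> dict:
    members = list(enum_cls)
    return {m: 1.0 / len(members) for m in members}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the stochastic cohort generator.

    Anterior and posterior labels are drawn independently per subject from
    the given prevalence vectors; diameters are then drawn from the
    class-conditional truncated-normal models so classification recovers
    the drawn labels.  A single integer seed drives one generator stream;
    record order is generation order.
    """

    n: int
    anterior_probs: Mapping[AnteriorType, float] = field(
        default_factory=lambda: _uniform_probs(AnteriorType)
    )
    posterior_probs: Mapping[PosteriorType, float] = field(
        default_factory=lambda: _uniform_probs(PosteriorType)
    )
    diameter_models: Mapping[str, DiameterModel] = field(
        default_factory=lambda: dict(DEFAULT_DIAMETER_MODELS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size must be positive")
        for name, probs in (
            ("anterior_probs", self.anterior_probs),
            ("posterior_probs", self.posterior_probs),
        ):
            total = float(sum(probs.values()))
            if not math.isclose(total, 1.0, abs_tol=1e-12):
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} must be non-negative")
        for key in DEFAULT_DIAMETER_MODELS:
            if key not in self.diameter_models:
                raise ValueError(f"missing diameter model {key!r}")
        for key, model in self.diameter_models.items():
            model.validate(key)
        a1 = self.diameter_models["a1_normal"]
        if a1.low < 1.1:
            raise ValueError(
                "a1_normal truncation low bound must be >= 1.1 mm so that the "
                "mild-variation and hypoplasia regions are non-empty"
            )
        p1a = self.diameter_models["p1_adult"]
        p1q = self.diameter_models["p1_quasi"]
        if p1q.low <= max(p1a.high, p1q.high) / 2.0:
            raise ValueError(
                "p1_quasi low bound must exceed half the largest P1 so a "
                "quasi-fetal side is never graded FTP-II by accident"
            )
        if p1a.low <= ABSENCE_THRESHOLD_MM:
            raise ValueError("p1_adult low bound must exceed the absence threshold")
        pcoa = self.diameter_models["pcoa_patent"]
        if pcoa.low < ABSENCE_THRESHOLD_MM + 0.05:
            raise ValueError("pcoa_patent low bound must clear the absence threshold")
        if pcoa.low >= p1a.low - 0.05:
            raise ValueError(
                "pcoa_patent low bound must sit below adult P1 diameters"
            )


def _sample_a1(
    anterior: AnteriorType, models: Mapping[str, DiameterModel], rng: np.random.Generator
) -> tuple[Optional[float], Optional[float]]:
    normal = models["a1_normal"]
    base = normal.sample(rng)
    if anterior in (AnteriorType.I, AnteriorType.V1):
        other = base + rng.uniform(-0.45, 0.45)
        pair = (base, max(other, ABSENCE_THRESHOLD_MM + 0.05))
    elif anterior is AnteriorType.IV:
        pair = (base, NOT_VISUALIZED)
    else:
        if anterior is AnteriorType.II:
            grade = A1Status.MILD_VARIATION
        elif anterior is AnteriorType.III:
            grade = A1Status.HYPOPLASIA
        else:  # V2: unbalanced without ACoA; either grade qualifies
            grade = rng.choice([A1Status.MILD_VARIATION, A1Status.HYPOPLASIA])
        if grade is A1Status.MILD_VARIATION:
            offset_hi = min(1.0, base / 2.0 - 0.01)
            smaller = base - rng.uniform(0.5, offset_hi)
        else:
            smaller = rng.uniform(ABSENCE_THRESHOLD_MM + 0.05, base / 2.0 - 0.01)
        pair = (base, smaller)
    if rng.random() < 0.5:
        pair = (pair[1], pair[0])
    return pair


# per-side plan: (pca kind, pcoa patent) for the canonical orientation
_POSTERIOR_PLANS: dict[PosteriorType, tuple[tuple[str, bool], tuple[str, bool]]] = {
    PosteriorType.a: (("adult", True), ("adult", True)),
    PosteriorType.b: (("quasi", True), ("quasi", True)),
    PosteriorType.c: (("quasi", True), ("adult", True)),
    PosteriorType.d: (("adult", False), ("adult", False)),
    PosteriorType.e: (("adult", True), ("adult", False)),
    PosteriorType.f: (("quasi", True), ("adult", False)),
    PosteriorType.g: (("pure", True), ("adult", False)),
    PosteriorType.h: (("pure", True), ("adult", True)),
    PosteriorType.i: (("pure", True), ("quasi", True)),
    PosteriorType.j: (("pure", True), ("pure", True)),
    PosteriorType.k: (("dual", True), ("adult", True)),
}


def _sample_posterior(
    posterior: PosteriorType,
    models: Mapping[str, DiameterModel],
    rng: np.random.Generator,
):
    """Draw (p1_l, p1_r, pcoa_l, pcoa_r, dual_l, dual_r) for a posterior type."""
    plan = _POSTERIOR_PLANS[posterior]
    p1: list[Optional[float]] = [None, None]
    pcoa: list[Optional[float]] = [None, None]
    dual = [False, False]
    adult, quasi, patent = models["p1_adult"], models["p1_quasi"], models["pcoa_patent"]
    # first pass: P1 calibers; second pass: PCoAs, which may depend on P1
    for s, (kind, _) in enumerate(plan):
        if kind in ("adult", "dual"):
            p1[s] = adult.sample(rng)
        elif kind == "quasi":
            p1[s] = quasi.sample(rng)
        if kind == "dual":
            dual[s] = True
    for s, (kind, pcoa_patent) in enumerate(plan):
        if not pcoa_patent:
            continue
        if kind in ("adult", "dual"):
            # adult type needs P1 strictly wider than its PCoA
            pcoa[s] = patent.sample(rng, high=p1[s] - 0.05)
        elif kind == "quasi":
            # quasi-fetal type needs the PCoA strictly wider than P1
            pcoa[s] = p1[s] + rng.uniform(0.2, 0.5)
        else:  # pure fetal type: P1 absent, PCoA carries the PCA
            pcoa[s] = patent.sample(rng)
    if rng.random() < 0.5:
        p1.reverse()
        pcoa.reverse()
        dual.reverse()
    return p1[0], p1[1], pcoa[0], pcoa[1], dual[0], dual[1]


def record_for_types(
    anterior: AnteriorType,
    posterior: PosteriorType,
    rng: np.random.Generator,
    subject_id: str = "S0001",
    diameter_models: Optional[Mapping[str, DiameterModel]] = None,
) -> SubjectVesselRecord:
    """Sample one measurement record inside the region of a label pair."""
    models = diameter_models or DEFAULT_DIAMETER_MODELS
    a1_l, a1_r = _sample_a1(anterior, models, rng)
    if anterior in (AnteriorType.V1, AnteriorType.V2):
        acoa_state, acoa_shape = ACoAState.ABSENT, ACoAShape.NONE
    else:
        acoa_state = ACoAState.PRESENT
        acoa_shape = _ACOA_SHAPES[rng.choice(len(_ACOA_SHAPES), p=_ACOA_SHAPE_PROBS)]
    p1_l, p1_r, pcoa_l, pcoa_r, dual_l, dual_r = _sample_posterior(
        posterior, models, rng
    )
    return SubjectVesselRecord(
        subject_id=subject_id,
        a1_left=a1_l,
        a1_right=a1_r,
        acoa_state=acoa_state,
        acoa_shape=acoa_shape,
        pcoa_left=pcoa_l,
        pcoa_right=pcoa_r,
        p1_left=p1_l,
        p1_right=p1_r,
        dual_pca_left=dual_l,
        dual_pca_right=dual_r,
        trigeminal_variant=bool(rng.random() < TRIGEMINAL_RATE),
    )


def sample_cohort(spec: CohortSpec) -> list[SubjectVesselRecord]:
    """Draw a reproducible measurement-level cohort from a CohortSpec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ant_members = list(spec.anterior_probs)
    ant_p = np.array([spec.anterior_probs[m] for m in ant_members], dtype=float)
    post_members = list(spec.posterior_probs)
    post_p = np.array([spec.posterior_probs[m] for m in post_members], dtype=float)
    records = []
    for idx in range(spec.n):
        anterior = ant_members[rng.choice(len(ant_members), p=ant_p)]
        posterior = post_members[rng.choice(len(post_members), p=post_p)]
        records.append(
            record_for_types(
                anterior,
                posterior,
                rng,
                subject_id=f"SIM{idx + 1:05d}",
                diameter_models=spec.diameter_models,
            )
        )
    return records


def table1_marginal_spec(n: int = 2246, seed: int = 0) -> CohortSpec:
    """CohortSpec whose label prevalences are the printed cross-tabulation's
    marginal frequencies (anterior and posterior drawn independently)."""
    t1 = load_fixture("T1")
    total = t1.grand_total
    ant = {
        AnteriorType.parse(label): int(t1.row_totals[i]) / total
        for i, label in enumerate(t1.row_labels)
    }
    post = {
        PosteriorType.parse(label): int(t1.col_totals[j]) / total
        for j, label in enumerate(t1.col_labels)
    }
    return CohortSpec(n=n, anterior_probs=ant, posterior_probs=post, seed=seed)
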