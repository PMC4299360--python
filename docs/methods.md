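# Methods

## Scope and data model

The package types the circle of Willis (COW) from per-subject vessel
measurements: side-specific diameters (mm) of the ACA-A1 and PCA-P1
segments and the posterior communicating arteries (PCoA), a patency state
and shape for the anterior communicating artery (ACoA), per-side dual-PCA
flags, and a persistent-trigeminal-artery annotation. Image acquisition
and diameter extraction are out of scope: the pipeline starts at the
measurement table.

A vessel with no angiographic image is the distinguished state
`NOT_VISUALIZED`, never 0.0 mm; validation rejects zero diameters as
ambiguous. One absence convention is applied uniformly to every vessel:
below **0.5 mm** a vessel is regarded as absent, the caliber at which it
can no longer provide effective collateral perfusion. The ACoA state
*unclear* is kept distinct in the data layer and folded into "not patent"
only inside the classifier, since an unconfirmed ACoA cannot be taken to
close the anterior ring.

## Classification rules and their edge cases

The typing rules are deterministic, pure functions. Decisions taken where
the rule system is genuinely open:

- **Severity precedence.** A side can satisfy both the mild-variation
  difference band (0.5–1.0 mm) and the half-contralateral hypoplasia rule
  (e.g. 1.8 vs 0.85 mm); the more severe class wins, matching the
  escalating-severity structure of the four classes.
- **Gap > 1.0 mm with caliber above half-contralateral** (e.g. 3.0 vs
  1.7 mm) is not covered by the stated bands; it is graded hypoplasia on
  the smaller side to keep the classes exhaustive.
- **Inclusive boundaries.** A difference of exactly 0.5 or 1.0 mm is mild
  variation; a P1 exactly equal to its PCoA is adult type (fetal type
  requires the PCoA strictly wider). Boundary comparisons carry a 1e-9 mm
  tolerance — far below the 3-decimal measurement dialect — so that float
  arithmetic cannot flip an exact-boundary case.
- **A1 absence decides type IV** regardless of the ACoA; the larger side
  of an asymmetric pair is normal unless itself below the absence
  threshold; when both A1s are absent, both are graded absent.
- Two vessel combinations are declared errors rather than forced into a
  type: a side with neither P1 nor PCoA and no dual PCA (no posterior
  supply at all), and a quasi- or pure-FTP side whose own PCoA is absent
  (an FTP is carried by its PCoA).

## Aggregation

Contingency tables recompute margins from cells, never store them. The
A1-variation side table pairs, within each subject having at least one
non-normal A1, the *normal lateral* (milder side, under its own status)
with the *variation lateral*; equal severities tie-break to the left side
as the normal lateral. The reference cohort has one variation side per
subject, so the bilateral rule only matters for synthetic cohorts.

The ACoA-patency 2×2 is derived from anterior types (I/II/III patent,
V1/V2 not); type IV, which is typed without regard to the ACoA, is counted
as patent — the allocation the reference cohort's own margins imply.
Proportions are stored at full precision and rendered at two decimal
places of percent.

## Statistics

All three tests are computed from first principles; scipy supplies only
the χ² and normal distribution tails (and serves as an independent
cross-check in the test suite). The conventions are load-bearing: Pearson
χ² without continuity correction, the trend statistic as **(N−1)·r²**
(not N·r²), and the rank-sum Z from midranks with tie-corrected variance
and no continuity correction. Changing any of them breaks exact agreement
with the published values. Default ordinal scores are consecutive integers
(rows 1..R, columns 0..C−1 with the reference category first); both are
overridable, and the trend statistic is invariant under affine rescaling
of either score vector. Degenerate inputs raise: zero margins (χ²),
constant effective scores (trend), an empty group (rank-sum); a rank-sum
with all observations in one tie block reports Z = 0.

p-values are reported at full precision; a printed "P = 0.000" is read as
p < 0.0005.

## Fixtures and known inconsistencies of the source tables

Each printed table ships as its own delimited-text fixture; statistics are
computed from their own source table, as in the original analysis, because
the tables are not mutually consistent in every cell. The packaged
`data/discrepancies.json` records the known issues: the ambiguous V2 row
of the cross-tabulation (shipped as the unique allocation reconciling it
with the posterior census and the 2×2 balance table), the 1489-vs-1490
count for anterior-integral/posterior-nonintegral subjects, the
28.18%-vs-28.23% variation rate, the subject-level FTP table grouping by
A1 status rather than anterior type, and one rank-sum Z (printed 2.576,
exactly the two-sided p = 0.01 normal critical value) that the printed
counts do not support: the tie-corrected computation gives Z = 2.467 with
p = 0.0136, which rounds to the printed P = 0.01. The reproduction command
reports that target as `discrepant`, judged on the rounded p-value it
implies rather than the unreproducible printed Z.

## Synthetic cohort generator

The generator emulates the study conditions at two levels. The
*deterministic reconstruction* expands the printed cross-tabulation into
2246 categorical profiles (row-major, stable identifiers) whose
re-aggregation reproduces the table exactly; side-level detail not
determined by the (anterior, posterior) pair is filled canonically
(variation on the right side, quasi-FTP as subtype I), consistent with
the pair by construction.

The *stochastic generator* draws an (anterior, posterior) label pair per
subject — independently, by default from the cross-tabulation's marginal
frequencies — and then draws diameters from class-conditional truncated
normal models confined to the label's admissible region, so that
classification recovers the drawn labels with probability 1 (the
round-trip property the tests drive with 100 seeds across all 66 label
pairs). Defaults: normal A1 at location 2.2 mm, scale 0.25 mm, truncated
to [1.6, 3.5]; the mild side as contralateral minus a uniform 0.5–1.0 mm
offset (capped to stay above half-contralateral); the hypoplastic side
uniform between 0.55 mm and just under half-contralateral; adult P1 at
2.1 ± 0.15 mm on [1.9, 2.5]; quasi-fetal P1 on [1.3, 1.7] with its PCoA
0.2–0.5 mm wider; patent PCoA at 1.0 ± 0.25 mm on [0.6, 1.5], tightened
below the adult P1. These are implementation defaults chosen for the
label-recovery invariant, not population estimates. ACoA shapes are drawn
from the published shape census within the patent state, independent of
anterior type; the persistent trigeminal artery appears at its cohort
rate (3/2246). Spec validation rejects models whose truncation region is
empty or leaves a class's sampling region unreachable. One integer seed
drives a single `numpy` generator stream; record order is generation
order, and asymmetric patterns are mirrored left/right with probability
one half.

What the generator does **not** emulate: measurement noise and reader
disagreement, correlation between anterior and posterior variants within
a subject, the joint distribution of ACoA shape with anterior type, A2
segment variants, and any hemodynamic coupling between vessel calibers.
Passing round-trip tests therefore show that the classifier implements the
rules exactly on in-region data, not that the rules are robust to
real-world measurement error near the thresholds.

## Problem sizes

The reconstruction pipeline runs on the full 2246-subject cohort in well
under a second. Stochastic checks use cohorts of 150–2246 subjects and the
classifier round-trip uses 100 seeds × 66 label pairs; the acceptance
script's label-recovery summary uses 25 derived seeds (1650 records).

## Limitations

- The typing system is a faithful implementation of one published rule
  set; other COW classification schemes (completeness-by-0.8 mm,
  evolutionary typologies) are out of scope.
- The reconstruction carries only the information the cross-tabulation
  contains: side-level tables built from it (A1 by side, variation sides
  by PCA type) do not reproduce the corresponding printed tables, which
  therefore ship as their own fixtures.
- The rank-sum normal approximation is appropriate for the reference
  cohort's sizes; no exact or permutation variant is provided.
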