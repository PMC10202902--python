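# Methods

## The model

A master protocol evaluates several treatments across several
biomarker-defined and/or disease-defined sub-populations under one
infrastructure.  `trialcube` models its design space as a **hypercube
manifold over nominal axes**: each axis is a finite, unordered label set —
conventionally B (predictive biomarkers), T (treatments, optionally with a
control arm T0) and C (disease classifiers, i.e. tumour or tissue types) —
and the design space is the set of *active cells* of the Cartesian product
B × T × C.  Three modelling assumptions carry the whole construction:

1. **Axes are nominal.**  Element placement along an axis has no meaning;
   every derived quantity (equality, diffs, classification) is therefore
   defined on a *canonical form* that sorts axes by name and elements by
   label.  Rendering assigns uniform integer tick positions in presentation
   order.
2. **Axes are mutually exclusive.**  No label may appear on two axes (a
   drug name cannot double as a tumour type).  This is enforced at
   construction and re-checked by `validate_space`.
3. **Activity defaults to the full product.**  A space built without an
   explicit active set activates every cell (restricted treatments keep
   only their admissible cells); real protocols then deactivate cells.

Two structures extend the plain product because nominal axes alone cannot
express them:

* **Cohorts** — a composite classifier element (e.g. "All others") records
  the member labels it pools.  Members may not simultaneously exist as
  standalone elements.
* **Admissibility** — a relation of (treatment, classifier) pairs.  A
  treatment that appears in the relation is allowed *only* with its listed
  classifiers; unmentioned treatments are unrestricted.  This encodes
  per-cohort availability (a combination arm open to one tumour type) as a
  constraint rather than as a fourth axis, keeping the axes mutually
  exclusive.  Active cells must satisfy the relation; they need not exhaust
  it.

Axis count may exceed 3 (an `other` role exists for, e.g., additional omic
layers); projection and serialization are dimension-agnostic, while direct
rendering supports dimension ≤ 3 and asks for a projection first.

## Projections and design classification

Fixing one axis at one element and dropping that coordinate from every
active cell yields a `ProjectedDesign` on the residual plane, with
annotations inherited from pre-image cells.  Classification is rule-based
and deterministic:

| fixed axis | residual evidence | type |
|---|---|---|
| biomarker | ≥ 2 active classifiers | basket |
| biomarker | exactly 1 active classifier | single_cohort |
| classifier | 1 active biomarker, biomarker axis ≥ 2 elements or active control arm | enrichment |
| classifier | 1 active biomarker, singleton axis, no control | single_cohort |
| classifier | ≥ 2 active biomarkers, every subgroup on one treatment | umbrella |
| classifier | ≥ 2 active biomarkers, any subgroup on ≥ 2 treatments | matrix |
| treatment / other, missing roles, empty grid | — | undetermined |

Two of these thresholds are genuine design choices rather than forced
conclusions.  *Enrichment vs single-cohort*: a one-biomarker design is
called an enrichment only when it represents a selection — the biomarker
axis offers at least one alternative, or the treatment axis has an active
control arm; a design with singleton axes and no control is a plain single
cohort.  *Umbrella vs matrix*: the matrix label wins only on genuine
crossing (some biomarker subgroup assigned ≥ 2 treatments), since matrix
designs contain umbrellas as special cases and the more specific label is
more informative.  A projection that fixes a treatment element is computed
(it is a perfectly good slice) but always classified undetermined, because
no named design corresponds to it.  Annotations never influence
classification; they are rendering data.

Annotation flags default to the vocabulary {significant, resistant,
combination} and can be extended per space via `flags_vocabulary`.
Significance shading attaches per cell, with `annotate_slice` as a
convenience for shading a whole slice at once; whether shading is
conceptually per-cell or per-slice is underdetermined in the source
material, and the per-cell choice is strictly more expressive.

## Amendments and diffs

Five amendment kinds cover the adaptive-platform edits observed in
practice: `add_element`, `drop_element`, `merge_into_cohort`,
`restrict_treatment`, `add_treatment`.  Application is value-semantic
(inputs untouched), validated, and logged: each returned space carries the
amendment in `history`, and replaying the log on the original space
reproduces the current canonical form.  Element identity across versions is
the exact, case-sensitive label — nominal axes have no other key.  Defaults
on application: a newly added element activates its full admissible slice;
dropped or deactivated cells move their annotations to an archival mapping
(`archived_annotations`) rather than deleting them, so the history of a
dropped cohort stays recoverable; history and archives are provenance and
are excluded from canonical identity.

`diff(before, after)` produces the minimal element-level difference —
added/dropped elements per axis, cohort merges, restriction additions —
plus two residual layers that element-level amendments cannot express:
per-cell activity changes (`activated`/`deactivated`) and per-cell
annotation changes (`flags_added`/`flags_removed`).  The residuals exist
because a real adaptation can withdraw one arm from one cohort (the
colorectal monotherapy withdrawal in the packaged fixtures) without any
dimension-set edit.  `AmendmentDiff.apply` replays the implied amendments —
ordered drops → merges → element additions → treatment additions →
restrictions, so that restrictions never reference not-yet-added
classifiers — followed by the residuals, and is canonical-equal to
`after` by construction; the property suite checks this over randomized
amendment sequences, and a regression test pins the packaged adaptation to
exactly 2 added classifiers, 2 dropped, 1 merge, 1 restricted
combination-arm addition.

## Geometry

The hypersurface toolkit is deliberately elementary and exactly tested:

* `cube_vertices(n)` enumerates {−1, +1}^n (2^n points; n = 0 gives the
  single empty-signed vertex).  `cube_k_faces(n, k)` enumerates the
  C(n, k)·2^(n−k) face descriptors (k free coordinates, signs on the rest);
  tests compare against an independent brute force that enumerates
  {−1, +1, free}^n patterns, and check the solid-cube Euler relation
  Σ(−1)^k f_k = 1 for n ≤ 5.  `boundary` returns the facets: the point pair
  for the segment, the tesseract's 8 cells for n = 4.
* `stereographic`/`inverse_stereographic` use the textbook convention: unit
  sphere, pole defaulting to the north unit vector, projection onto the
  equatorial hyperplane through the centre (x ↦ x_{1..n}/(1 − x_{n+1}), with
  a Householder reflection handling arbitrary poles).  On-surface membership
  uses a relative tolerance of 1e−9 (configurable); round-trips on 1000
  seeded points stay below 1e−9 (observed ≈ 3e−15).
* The sphere↔cube correspondence has no canonical formula; we adopt the
  radial max-norm map (rescale each boundary point by half-width / max-norm,
  inverse by radius / Euclidean norm), the simplest bijection between
  concentric boundaries.  Axis-aligned face centres are its fixed points.

A nonstandard description of the 3-sphere circulates in informal accounts
(as "the ordinary 3D sphere, not just the surface"); this package uses the
standard definition throughout — the n-sphere is the boundary of the
(n+1)-ball, living in R^(n+1).

## Serialization

One canonical document format (`.design.json`, `schema_version` "1.0", no
dialect autodetection — protocols are quasi-legal documents and strictness
beats convenience).  The formal schema is published in
`docs/design-document.schema.json`; the reader validates against the same
rules with field locations in every error, and distinguishes schema errors
(exit 3 in the CLI) from domain validation failures (exit 2).  Output is
deterministic — fixed key order, sorted cell-valued sections — so two
writes of the same space are byte-identical.  Round-trips are
canonical-equal with history preserved, verified on all fixtures and 100
seeded random spaces.

## Fixtures

Fixture labels follow the source spellings, with
"Erdheim-Chester Disease (ECD)/Langerhans-Cell Histiocytosis (LCH)"
shortened to the documented label "ECD/LCH" (long form in fixture
metadata).  The pre-adaptation Vemurafenib cohort list is reconstructed
from the adaptation narrative (the named drops, the merge, the seven
"All others" members) plus the arms present throughout (NSCLC, colorectal,
cholangiocarcinoma); the original protocol's full list is not exhaustively
published, and the fixture docstring says so.  In the adapted fixture the
colorectal cohort is served by the Vemurafenib+Cetuximab arm only, encoded
as an admissibility restriction on the combination arm plus deactivation of
the monotherapy cell.

## Randomized-space generator

`random_design_space` draws small master protocols: B/T/C axes of 1–4
elements (occasionally a fourth `other` axis), an optional control arm,
~70% of admissible cells active (never zero), sporadic annotations, an
optional pooled cohort and an optional treatment restriction.  It emulates
the *structure* of protocol design spaces, not their clinical content: no
accrual, outcomes, or statistical association enter anywhere in this
package, so passing tests demonstrate structural correctness (validity,
round-trips, diff closure) and say nothing about the clinical merit of any
design.  Problem sizes throughout the suite (axes ≤ 4 elements, n ≤ 5
cubes, 1000-point round-trips, 100 random spaces) are chosen so every
property is checked exhaustively or densely while the whole suite runs in
seconds.

## Known limitations

* No statistics: the `significant` flag is an input recorded from an
  external analysis, never computed here; sample size, randomization,
  borrowing between baskets and interim logic are out of scope.
* Rendering is static and file-only (SVG/PNG); spaces of dimension > 3
  render only via projections, and 4-D objects appear only in the
  geometry gallery.
* The diff assumes the two versions share axis names and roles; renaming an
  axis between versions is not supported.
* Import from registry formats (CDISC, ClinicalTrials.gov) is a non-goal.
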