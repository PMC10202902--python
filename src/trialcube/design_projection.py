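"""Projections of a design space and classification of embedded trial designs.

Fixing one axis of the master manifold at one element and projecting onto
the residual plane recovers the familiar master-protocol designs: fixing a
biomarker and projecting onto the (treatment, classifier) plane yields a
basket trial (subgroups = tumour types sharing the mutation); fixing a
disease classifier and projecting onto the (biomarker, treatment) plane
yields enrichment, umbrella or matrix designs (subgroups = mutations).

Classification rules (deterministic, applied in order):

* fixed treatment axis, missing roles, or an empty residual grid
  -> ``undetermined``;
* fixed **biomarker**: >=2 active classifiers -> ``basket``; exactly one
  -> ``single_cohort``;
* fixed **classifier**, exactly one active biomarker -> ``enrichment`` if
  the biomarker axis offers a choice (>=2 elements, i.e. a biomarker-positive
  selection) or an active control arm exists, else ``single_cohort``;
* fixed **classifier**, >=2 active biomarkers -> ``matrix`` if any biomarker
  subgroup is assigned >=2 treatments (genuine crossing), else ``umbrella``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping, Optional

from .errors import EmptySubgroupsError, UnknownElementError
from .manifold_core import Cell, DesignSpace, NominalAxis


class DesignType(str, Enum):
    BASKET = "basket"
    UMBRELLA = "umbrella"
    ENRICHMENT = "enrichment"
    MATRIX = "matrix"
    SINGLE_COHORT = "single_cohort"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ProjectedDesign:
    """The slice of a design space at one fixed (axis, element) pair.

    ``active_grid`` holds residual cells (over ``residual_axes``) that were
    active in at least one pre-image cell of the parent; annotations of the
    pre-image cells are inherited onto the residual cells.
    """

    fixed_axes: tuple[NominalAxis, ...]
    fixed: Mapping[str, str]  # axis name -> fixed element
    residual_axes: tuple[NominalAxis, ...]
    active_grid: frozenset[Cell]
    annotations: Mapping[Cell, frozenset[str]]
    admissibility: frozenset[tuple[str, str]]
    cohorts: Mapping[str, frozenset[str]]
    design_type: "DesignType" = DesignType.UNDETERMINED

    def residual_axis_by_role(self, role: str) -> Optional[NominalAxis]:
        found = [a for a in self.residual_axes if a.role == role]
        return found[0] if len(found) == 1 else None

    def active_elements(self, axis: NominalAxis) -> tuple[str, ...]:
        """Elements of a residual axis hit by the active grid, in the axis's
        presentation order."""
        hit = {c[axis.name] for c in self.active_grid}
        return tuple(e for e in axis.elements if e in hit)

    def reembed(self) -> frozenset[Cell]:
        """Re-attach the fixed coordinates: exactly the parent's active cells
        at this slice."""
        cells = self.active_grid
        for name, element in self.fixed.items():
            cells = frozenset(c.extend(name, element) for c in cells)
        return cells


def project(space: DesignSpace, axis_name: str, element: str) -> ProjectedDesign:
    """Fix ``axis_name`` at ``element`` and project onto the residual plane.

    Annotations are carried over; the classification is computed eagerly.

    Raises :class:`UnknownElementError` for an unknown axis or element.
    """
    axis = space.axis(axis_name)  # raises UnknownElementError for bad axis
    if element not in axis:
        raise UnknownElementError(f"element {element!r} not on axis {axis_name!r}")
    residual = tuple(a for a in space.axes if a.name != axis_name)
    grid = frozenset(
        cell.drop(axis_name) for cell in space.active_cells if cell[axis_name] == element
    )
    annotations: dict[Cell, frozenset[str]] = {}
    for cell, flags in space.annotations.items():
        if cell[axis_name] == element:
            res = cell.drop(axis_name)
            annotations[res] = annotations.get(res, frozenset()) | flags
    design = ProjectedDesign(
        fixed_axes=(axis,),
        fixed={axis_name: element},
        residual_axes=residual,
        active_grid=grid,
        annotations=annotations,
        admissibility=space.admissibility,
        cohorts=dict(space.cohorts),
    )
    return replace(design, design_type=classify(design))


def classify(design: ProjectedDesign) -> DesignType:
    """Classify a projected design by the rule set in the module docstring."""
    if not design.active_grid:
        return DesignType.UNDETERMINED
    fixed_roles = {a.role for a in design.fixed_axes}
    if "treatment" in fixed_roles or "other" in fixed_roles:
        # the framework names no design for a treatment-fixed projection
        return DesignType.UNDETERMINED

    if "biomarker" in fixed_roles:
        c_axis = design.residual_axis_by_role("classifier")
        if c_axis is None:
            return DesignType.UNDETERMINED
        n_classifiers = len(design.active_elements(c_axis))
        if n_classifiers >= 2:
            return DesignType.BASKET
        return DesignType.SINGLE_COHORT

    if "classifier" in fixed_roles:
        b_axis = design.residual_axis_by_role("biomarker")
        if b_axis is None:
            return DesignType.UNDETERMINED
        active_b = design.active_elements(b_axis)
        t_axis = design.residual_axis_by_role("treatment")
        if len(active_b) == 1:
            control_active = (
                t_axis is not None
                and t_axis.control_element is not None
                and t_axis.control_element
                in {c.get(t_axis.name) for c in design.active_grid}
            )
            if b_axis.size >= 2 or control_active:
                return DesignType.ENRICHMENT
            return DesignType.SINGLE_COHORT
        # >=2 biomarker subgroups: crossing with >=2 treatments makes a matrix
        if t_axis is not None:
            for b in active_b:
                n_treat = len(
                    {
                        c[t_axis.name]
                        for c in design.active_grid
                        if c[b_axis.name] == b
                    }
                )
                if n_treat >= 2:
                    return DesignType.MATRIX
        return DesignType.UMBRELLA

    return DesignType.UNDETERMINED


def subgroups(design: ProjectedDesign) -> list[str]:
    """The design's subgroups, in axis presentation order.

    Basket subgroups are the active tumour types; umbrella/enrichment
    subgroups are the active biomarkers; a matrix design lists its
    biomarker-by-treatment pairs as ``"b:t"`` labels.

    Raises :class:`EmptySubgroupsError` for an undetermined design.
    """
    t = design.design_type
    if t == DesignType.UNDETERMINED:
        raise EmptySubgroupsError("an undetermined design has no subgroups")
    if t == DesignType.BASKET:
        return list(design.active_elements(design.residual_axis_by_role("classifier")))
    if t in (DesignType.UMBRELLA, DesignType.ENRICHMENT):
        return list(design.active_elements(design.residual_axis_by_role("biomarker")))
    if t == DesignType.MATRIX:
        b_axis = design.residual_axis_by_role("biomarker")
        t_axis = design.residual_axis_by_role("treatment")
        pairs = {(c[b_axis.name], c[t_axis.name]) for c in design.active_grid}
        return [
            f"{b}:{tr}"
            for b in b_axis.elements
            for tr in t_axis.elements
            if (b, tr) in pairs
        ]
    # single cohort: the one active subgroup label
    fixed_role = design.fixed_axes[0].role
    axis = design.residual_axis_by_role(
        "classifier" if fixed_role == "biomarker" else "biomarker"
    )
    if axis is None:
        raise EmptySubgroupsError("no subgroup-defining axis in the residual plane")
    return list(design.active_elements(axis))


def enumerate_embedded_designs(space: DesignSpace) -> list[ProjectedDesign]:
    """One projection per (axis, element) pair over the biomarker and
    classifier axes — every named trial design embedded in the manifold.
    For a 3-axis space the list has |B| + |C| entries."""
    designs = []
    for axis in space.axes:
        if axis.role in ("biomarker", "classifier"):
            for element in axis.elements:
                designs.append(project(space, axis.name, element))
    return designs
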