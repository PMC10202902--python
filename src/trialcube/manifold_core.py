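"""Design-space data model for master protocols.

A master protocol's design space ("Master Manifold") is modelled as a set of
*nominal* axes — typically B (predictive biomarkers), T (treatments,
optionally with a control arm T0) and C (disease classifiers / tumour
types) — together with the set of *active cells* of their Cartesian product.
Axes are nominal: element order carries no meaning, and no label may appear
on two axes (the dimensions are mutually exclusive).

Cells can carry annotation flags from a controlled vocabulary (by default
``significant``, ``resistant``, ``combination``), classifier elements can be
composite cohorts (e.g. an "All others" group of rare tumour types), and a
treatment can be restricted to an admissible subset of classifiers (e.g. a
combination arm available for one tumour type only).

All objects are immutable; operations return new spaces.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from .errors import (
    AxisOverlapError,
    DuplicateLabelError,
    EmptyAxisError,
    InvalidCellError,
    InvalidControlError,
    UnknownElementError,
    UnknownFlagError,
)

AXIS_ROLES = ("biomarker", "treatment", "classifier", "other")

#: Default controlled vocabulary for cell annotations.
DEFAULT_FLAGS = frozenset({"significant", "resistant", "combination"})


@dataclass(frozen=True)
class NominalAxis:
    """One labelled, order-irrelevant dimension of a design space.

    Parameters
    ----------
    name:
        Short label, e.g. ``"B"``, ``"T"``, ``"C"``.
    role:
        One of ``biomarker``, ``treatment``, ``classifier``, ``other``.
    elements:
        Distinct element labels.  Order is presentational only.
    control_element:
        Optional control arm (treatment axes only), e.g. ``"T0"``.
    """

    name: str
    role: str
    elements: tuple[str, ...]
    control_element: Optional[str] = None

    def __contains__(self, element: str) -> bool:
        return element in self.elements

    @property
    def size(self) -> int:
        return len(self.elements)


def create_axis(
    name: str,
    role: str,
    elements: Sequence[str],
    control_element: Optional[str] = None,
) -> NominalAxis:
    """Create and validate a nominal axis.

    Raises
    ------
    EmptyAxisError
        If ``elements`` is empty.
    DuplicateLabelError
        If an element label repeats.
    InvalidControlError
        If ``control_element`` is not an element, or the axis is not a
        treatment axis.
    ValueError
        If ``role`` is not a recognised axis role.
    """
    if role not in AXIS_ROLES:
        raise ValueError(f"unknown axis role {role!r}; expected one of {AXIS_ROLES}")
    elements = tuple(elements)
    if not elements:
        raise EmptyAxisError(f"axis {name!r} has no elements")
    seen = set()
    for e in elements:
        if e in seen:
            raise DuplicateLabelError(f"axis {name!r} repeats element {e!r}")
        seen.add(e)
    if control_element is not None:
        if control_element not in elements:
            raise InvalidControlError(
                f"control element {control_element!r} is not an element of axis {name!r}"
            )
        if role != "treatment":
            raise InvalidControlError(
                f"axis {name!r} has role {role!r}; only treatment axes carry a control arm"
            )
    return NominalAxis(name=name, role=role, elements=elements, control_element=control_element)


@dataclass(frozen=True, order=True)
class Cell:
    """A point of the Cartesian product underlying the manifold: one element
    per axis, stored as ``(axis_name, element)`` pairs sorted by axis name."""

    items: tuple[tuple[str, str], ...]

    @classmethod
    def of(cls, assignment: Mapping[str, str] | Iterable[tuple[str, str]]) -> "Cell":
        if isinstance(assignment, Mapping):
            pairs = assignment.items()
        else:
            pairs = assignment
        return cls(items=tuple(sorted(pairs)))

    def __getitem__(self, axis_name: str) -> str:
        for axis, element in self.items:
            if axis == axis_name:
                return element
        raise KeyError(axis_name)

    def get(self, axis_name: str, default: Optional[str] = None) -> Optional[str]:
        try:
            return self[axis_name]
        except KeyError:
            return default

    def as_dict(self) -> dict[str, str]:
        return dict(self.items)

    def drop(self, axis_name: str) -> "Cell":
        """The residual cell with one coordinate removed (used by projection)."""
        return Cell(items=tuple(p for p in self.items if p[0] != axis_name))

    def extend(self, axis_name: str, element: str) -> "Cell":
        """Re-attach a fixed coordinate (inverse of :meth:`drop`)."""
        return Cell.of(self.items + ((axis_name, element),))

    def __repr__(self) -> str:  # compact: Cell(B=BRAF, C=CSD)
        inner = ", ".join(f"{a}={e}" for a, e in self.items)
        return f"Cell({inner})"


@dataclass(frozen=True, eq=False)
class DesignSpace:
    """The Master Manifold: axes, active cells, annotations, cohorts and
    treatment admissibility.

    Instances are value-semantic and immutable.  Equality is canonical: two
    spaces whose axes differ only in element presentation order compare
    equal.  Construct through :func:`build_space`, which validates all
    invariants; the raw constructor performs no checks.
    """

    axes: tuple[NominalAxis, ...]
    active_cells: frozenset[Cell]
    annotations: Mapping[Cell, frozenset[str]] = field(default_factory=dict)
    cohorts: Mapping[str, frozenset[str]] = field(default_factory=dict)
    admissibility: frozenset[tuple[str, str]] = frozenset()
    flags_vocabulary: frozenset[str] = DEFAULT_FLAGS
    #: provenance: amendments applied since the space was built (see
    #: :mod:`trialcube.adaptation`); excluded from canonical identity.
    history: tuple = ()
    #: annotations of cells that amendments deactivated or whose elements
    #: were dropped; retained for provenance, excluded from canonical identity.
    archived_annotations: Mapping[Cell, frozenset[str]] = field(default_factory=dict)

    # -- introspection -----------------------------------------------------

    @property
    def dimension(self) -> int:
        """Number of axes (the classic B, T, C master manifold has dimension 3)."""
        return len(self.axes)

    def axis(self, name: str) -> NominalAxis:
        for a in self.axes:
            if a.name == name:
                return a
        raise UnknownElementError(f"no axis named {name!r}")

    def axis_by_role(self, role: str) -> Optional[NominalAxis]:
        """The unique axis of a role, or None (ambiguity also returns None)."""
        found = [a for a in self.axes if a.role == role]
        return found[0] if len(found) == 1 else None

    def all_cells(self) -> Iterator[Cell]:
        """The full Cartesian product of the axes."""
        names = [a.name for a in self.axes]
        for combo in itertools.product(*(a.elements for a in self.axes)):
            yield Cell.of(zip(names, combo))

    def is_valid_cell(self, cell: Cell) -> bool:
        if len(cell.items) != len(self.axes):
            return False
        for axis_name, element in cell.items:
            try:
                axis = self.axis(axis_name)
            except UnknownElementError:
                return False
            if element not in axis:
                return False
        return True

    def is_admissible(self, cell: Cell) -> bool:
        """Whether the cell respects all treatment restrictions.

        A treatment is restricted iff it appears in ``admissibility``; it is
        then allowed only with its listed classifiers.  Unmentioned
        treatments are unrestricted.
        """
        if not self.admissibility:
            return True
        t_axis = self.axis_by_role("treatment")
        c_axis = self.axis_by_role("classifier")
        if t_axis is None or c_axis is None:
            return True
        t, c = cell.get(t_axis.name), cell.get(c_axis.name)
        restricted = {pair[0] for pair in self.admissibility}
        if t not in restricted:
            return True
        return (t, c) in self.admissibility

    def flags(self, cell: Cell) -> frozenset[str]:
        return self.annotations.get(cell, frozenset())

    # -- value semantics ---------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DesignSpace):
            return NotImplemented
        return canonical_form(self) == canonical_form(other)

    def __hash__(self) -> int:
        return hash(canonical_form(self))

    def evolve(self, **changes) -> "DesignSpace":
        """Functional update preserving immutability."""
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# construction & validation
# ---------------------------------------------------------------------------


def build_space(
    axes: Sequence[NominalAxis],
    active_cells: Optional[Iterable[Cell | Mapping[str, str]]] = None,
    annotations: Optional[Mapping[Cell, Iterable[str]]] = None,
    cohorts: Optional[Mapping[str, Iterable[str]]] = None,
    admissibility: Optional[Iterable[tuple[str, str]]] = None,
    flags_vocabulary: frozenset[str] = DEFAULT_FLAGS,
) -> DesignSpace:
    """Build and validate a design space.

    If ``active_cells`` is omitted, the full Cartesian product is active
    (restricted treatments keep only their admissible cells).  Annotating an
    inactive cell is legal but emits a warning — it supports recording the
    history of dropped cohorts.

    Raises
    ------
    AxisOverlapError
        A label shared across axes, or a cohort member doubling as a
        standalone element: the nominal dimensions must be mutually
        exclusive.
    InvalidCellError
        A malformed active/annotated cell, or an active cell pairing a
        restricted treatment with an inadmissible classifier.
    UnknownFlagError
        An annotation flag outside ``flags_vocabulary``.
    UnknownElementError
        An admissibility pair referencing unknown elements.
    """
    axes = tuple(axes)
    if len(axes) < 2:
        raise ValueError("a design space needs at least 2 axes")
    names = [a.name for a in axes]
    if len(set(names)) != len(names):
        raise DuplicateLabelError(f"axis names repeat: {names}")

    _check_mutual_exclusivity(axes)

    space = DesignSpace(
        axes=axes,
        active_cells=frozenset(),
        cohorts={k: frozenset(v) for k, v in (cohorts or {}).items()},
        admissibility=frozenset(admissibility or ()),
        flags_vocabulary=frozenset(flags_vocabulary),
    )

    for label, members in space.cohorts.items():
        for axis in axes:
            hit = members & set(axis.elements)
            if hit:
                raise AxisOverlapError(
                    f"cohort {label!r} members {sorted(hit)} also appear as "
                    f"standalone elements of axis {axis.name!r}"
                )

    for t, c in space.admissibility:
        t_axis = space.axis_by_role("treatment")
        c_axis = space.axis_by_role("classifier")
        if t_axis is None or c_axis is None:
            raise UnknownElementError(
                "admissibility restrictions need a treatment and a classifier axis"
            )
        if t not in t_axis:
            raise UnknownElementError(f"admissibility treatment {t!r} not on axis {t_axis.name!r}")
        if c not in c_axis:
            raise UnknownElementError(f"admissibility classifier {c!r} not on axis {c_axis.name!r}")

    if active_cells is None:
        cells = frozenset(c for c in space.all_cells() if space.is_admissible(c))
    else:
        cells = frozenset(
            c if isinstance(c, Cell) else Cell.of(c) for c in active_cells
        )
        for cell in cells:
            if not space.is_valid_cell(cell):
                raise InvalidCellError(f"{cell!r} is not a cell of this space")
            if not space.is_admissible(cell):
                raise InvalidCellError(
                    f"active cell {cell!r} pairs a restricted treatment with an "
                    "inadmissible classifier"
                )
    space = space.evolve(active_cells=cells)

    ann: dict[Cell, frozenset[str]] = {}
    for cell, flags in (annotations or {}).items():
        if not isinstance(cell, Cell):
            cell = Cell.of(cell)
        if not space.is_valid_cell(cell):
            raise InvalidCellError(f"annotated cell {cell!r} is not a cell of this space")
        flags = frozenset(flags)
        unknown = flags - space.flags_vocabulary
        if unknown:
            raise UnknownFlagError(f"unknown flags {sorted(unknown)} on {cell!r}")
        if cell not in space.active_cells:
            warnings.warn(f"annotating inactive cell {cell!r}", stacklevel=2)
        if flags:
            ann[cell] = flags
    return space.evolve(annotations=ann)


def _check_mutual_exclusivity(axes: Sequence[NominalAxis]) -> None:
    seen: dict[str, str] = {}
    for axis in axes:
        for e in axis.elements:
            if e in seen:
                raise AxisOverlapError(
                    f"element {e!r} appears on both axis {seen[e]!r} and axis "
                    f"{axis.name!r}; the dimensions must be mutually exclusive"
                )
            seen[e] = axis.name


def annotate(space: DesignSpace, cell: Cell | Mapping[str, str], flag: str) -> DesignSpace:
    """Attach a flag to a cell; idempotent.

    Raises :class:`UnknownFlagError` for a flag outside the vocabulary and
    :class:`InvalidCellError` for a cell not belonging to the space.  A
    warning is emitted for inactive cells.
    """
    if not isinstance(cell, Cell):
        cell = Cell.of(cell)
    if flag not in space.flags_vocabulary:
        raise UnknownFlagError(
            f"flag {flag!r} not in vocabulary {sorted(space.flags_vocabulary)}"
        )
    if not space.is_valid_cell(cell):
        raise InvalidCellError(f"{cell!r} is not a cell of this space")
    if cell not in space.active_cells:
        warnings.warn(f"annotating inactive cell {cell!r}", stacklevel=2)
    ann = dict(space.annotations)
    ann[cell] = ann.get(cell, frozenset()) | {flag}
    return space.evolve(annotations=ann)


def annotate_slice(space: DesignSpace, axis_name: str, element: str, flag: str) -> DesignSpace:
    """Flag every *active* cell of a whole slice (e.g. shade all cells with
    B=BRAF as ``significant``)."""
    axis = space.axis(axis_name)
    if element not in axis:
        raise UnknownElementError(f"element {element!r} not on axis {axis_name!r}")
    out = space
    for cell in space.active_cells:
        if cell[axis_name] == element:
            out = annotate(out, cell, flag)
    return out


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_space`: hard invariant violations plus
    advisory warnings (e.g. annotated-but-inactive cells)."""

    violations: tuple[str, ...]
    warnings: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_space(space: DesignSpace) -> ValidationReport:
    """Re-check every axis and space invariant, reporting rather than
    raising.  A space built through :func:`build_space` yields an empty
    violation list."""
    violations: list[str] = []
    warns: list[str] = []

    if len(space.axes) < 2:
        violations.append("space has fewer than 2 axes")
    for axis in space.axes:
        if not axis.elements:
            violations.append(f"axis {axis.name!r} is empty")
        if len(set(axis.elements)) != len(axis.elements):
            violations.append(f"axis {axis.name!r} repeats an element label")
        if axis.control_element is not None and axis.control_element not in axis.elements:
            violations.append(
                f"axis {axis.name!r}: control {axis.control_element!r} is not an element"
            )
        if axis.control_element is not None and axis.role != "treatment":
            violations.append(f"axis {axis.name!r}: control arm on a non-treatment axis")
    try:
        _check_mutual_exclusivity(space.axes)
    except AxisOverlapError as exc:
        violations.append(str(exc))

    for cell in space.active_cells:
        if not space.is_valid_cell(cell):
            violations.append(f"active cell {cell!r} is not a valid cell")
        elif not space.is_admissible(cell):
            violations.append(
                f"active cell {cell!r} violates a treatment admissibility restriction"
            )
    for cell, flags in space.annotations.items():
        if not space.is_valid_cell(cell):
            violations.append(f"annotated cell {cell!r} is not a valid cell")
        elif cell not in space.active_cells:
            warns.append(f"annotated cell {cell!r} is not active")
        unknown = frozenset(flags) - space.flags_vocabulary
        if unknown:
            violations.append(f"cell {cell!r} carries unknown flags {sorted(unknown)}")
    for label, members in space.cohorts.items():
        for axis in space.axes:
            hit = set(members) & set(axis.elements)
            if hit:
                violations.append(
                    f"cohort {label!r} members {sorted(hit)} are standalone elements "
                    f"of axis {axis.name!r}"
                )
    return ValidationReport(violations=tuple(violations), warnings=tuple(warns))


# ---------------------------------------------------------------------------
# canonical form
# ---------------------------------------------------------------------------


def canonical_form(space: DesignSpace):
    """A hashable representation invariant under axis order and under element
    presentation order within each axis (nominal axes: placement along an
    axis carries no meaning).  History and archives are provenance and do not
    enter the canonical identity."""
    axes = tuple(
        sorted(
            (a.name, a.role, tuple(sorted(a.elements)), a.control_element)
            for a in space.axes
        )
    )
    active = tuple(sorted(c.items for c in space.active_cells))
    annotations = tuple(
        sorted((c.items, tuple(sorted(f))) for c, f in space.annotations.items() if f)
    )
    cohorts = tuple(sorted((k, tuple(sorted(v))) for k, v in space.cohorts.items()))
    admissibility = tuple(sorted(space.admissibility))
    return (axes, active, annotations, cohorts, admissibility)
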