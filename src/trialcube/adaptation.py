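"""Protocol amendments and structured diffs between design-space versions.

Adaptive platform designs change during the trial: cohorts are dropped for
insufficient accrual, slow-recruiting tumour types are folded into an
"All others" cohort, new disease classifiers are opened, and resistance can
force a treatment to be replaced by a restricted combination arm for one
tumour type.  All of these are element-level edits of the manifold's
dimension sets, captured here as five amendment kinds:

``add_element``, ``drop_element``, ``merge_into_cohort``,
``restrict_treatment``, ``add_treatment``.

Amendments are value-semantic: applying one returns a new space (with the
amendment appended to its provenance log) and never mutates the input.
:func:`diff` computes the minimal element-level difference between two
versions of a protocol, plus any residual per-cell activity changes, such
that :meth:`AmendmentDiff.apply` reproduces the later version exactly
(canonical equality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import (
    AxisOverlapError,
    EmptyAxisError,
    IncompatibleSpacesError,
    UnknownElementError,
)
from .manifold_core import Cell, DesignSpace, canonical_form

AMENDMENT_KINDS = (
    "add_element",
    "drop_element",
    "merge_into_cohort",
    "restrict_treatment",
    "add_treatment",
)


@dataclass(frozen=True)
class Amendment:
    """One protocol change.  ``payload`` shape depends on ``kind``:

    - ``add_element`` / ``drop_element``: the element label;
    - ``merge_into_cohort``: ``(member, cohort_label)``;
    - ``restrict_treatment``: ``(treatment, classifier labels)``;
    - ``add_treatment``: ``(treatment, classifier labels or None)`` —
      classifiers, when given, restrict the new arm to those tumour types.
    """

    kind: str
    axis: str
    payload: tuple

    def __post_init__(self):
        if self.kind not in AMENDMENT_KINDS:
            raise ValueError(f"unknown amendment kind {self.kind!r}")


# -- convenience constructors ----------------------------------------------


def add_element(axis: str, element: str) -> Amendment:
    return Amendment("add_element", axis, (element,))


def drop_element(axis: str, element: str) -> Amendment:
    return Amendment("drop_element", axis, (element,))


def merge_into_cohort(axis: str, member: str, cohort: str) -> Amendment:
    return Amendment("merge_into_cohort", axis, (member, cohort))


def restrict_treatment(axis: str, treatment: str, classifiers: Iterable[str]) -> Amendment:
    return Amendment("restrict_treatment", axis, (treatment, tuple(sorted(classifiers))))


def add_treatment(
    axis: str, treatment: str, classifiers: Optional[Iterable[str]] = None
) -> Amendment:
    payload_cls = None if classifiers is None else tuple(sorted(classifiers))
    return Amendment("add_treatment", axis, (treatment, payload_cls))


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------


def apply_amendment(space: DesignSpace, amendment: Amendment) -> DesignSpace:
    """Apply one amendment, returning a new validated space with the
    amendment appended to its provenance log.

    Element identity is by exact label.  Adding an element activates its
    full slice (all combinations with the other axes) subject to
    admissibility; dropping one removes its cells and archives their
    annotations; merging folds a member's cells into the cohort element.

    Raises
    ------
    UnknownElementError
        Dropping/merging/restricting a non-existent element or axis.
    AxisOverlapError
        An addition or merge creating a label collision.
    EmptyAxisError
        Dropping the last element of an axis.
    """
    handler = _HANDLERS[amendment.kind]
    out = handler(space, amendment)
    return out.evolve(history=space.history + (amendment,))


def _replace_axis(space: DesignSpace, axis_name: str, elements: tuple[str, ...]) -> DesignSpace:
    from dataclasses import replace as dc_replace

    axes = tuple(
        dc_replace(a, elements=elements) if a.name == axis_name else a for a in space.axes
    )
    return space.evolve(axes=axes)


def _assert_fresh_label(space: DesignSpace, label: str) -> None:
    for a in space.axes:
        if label in a.elements:
            raise AxisOverlapError(f"label {label!r} already exists on axis {a.name!r}")
    for cohort, members in space.cohorts.items():
        if label in members:
            raise AxisOverlapError(f"label {label!r} is already a member of cohort {cohort!r}")


def _activate_slice(space: DesignSpace, axis_name: str, element: str) -> DesignSpace:
    """Activate every admissible cell of a newly added element's slice."""
    new_cells = {
        cell
        for cell in space.all_cells()
        if cell[axis_name] == element and space.is_admissible(cell)
    }
    return space.evolve(active_cells=space.active_cells | new_cells)


def _apply_add_element(space: DesignSpace, am: Amendment) -> DesignSpace:
    (element,) = am.payload
    axis = space.axis(am.axis)
    _assert_fresh_label(space, element)
    out = _replace_axis(space, am.axis, axis.elements + (element,))
    return _activate_slice(out, am.axis, element)


def _apply_drop_element(space: DesignSpace, am: Amendment) -> DesignSpace:
    (element,) = am.payload
    axis = space.axis(am.axis)
    if element not in axis:
        raise UnknownElementError(f"element {element!r} not on axis {am.axis!r}")
    if axis.size == 1:
        raise EmptyAxisError(f"dropping {element!r} would empty axis {am.axis!r}")
    doomed = {c for c in space.active_cells if c[am.axis] == element}
    archived = dict(space.archived_annotations)
    annotations = dict(space.annotations)
    for cell in list(annotations):
        if cell[am.axis] == element:
            archived[cell] = archived.get(cell, frozenset()) | annotations.pop(cell)
    out = _replace_axis(space, am.axis, tuple(e for e in axis.elements if e != element))
    return out.evolve(
        active_cells=space.active_cells - doomed,
        annotations=annotations,
        archived_annotations=archived,
        admissibility=frozenset(p for p in space.admissibility if element not in p),
    )


def _apply_merge(space: DesignSpace, am: Amendment) -> DesignSpace:
    member, cohort = am.payload
    axis = space.axis(am.axis)
    if member not in axis:
        raise UnknownElementError(f"element {member!r} not on axis {am.axis!r}")
    if cohort not in axis.elements:
        _assert_fresh_label(space, cohort)
        out = _replace_axis(space, am.axis, tuple(e for e in axis.elements if e != member) + (cohort,))
    else:
        out = _replace_axis(space, am.axis, tuple(e for e in axis.elements if e != member))
    # fold the member's cells into the cohort element
    remapped = set()
    for cell in space.active_cells:
        if cell[am.axis] == member:
            remapped.add(cell.drop(am.axis).extend(am.axis, cohort))
        else:
            remapped.add(cell)
    annotations = dict(space.annotations)
    archived = dict(space.archived_annotations)
    for cell in list(annotations):
        if cell[am.axis] == member:
            archived[cell] = archived.get(cell, frozenset()) | annotations.pop(cell)
    cohorts = {k: frozenset(v) for k, v in space.cohorts.items()}
    cohorts[cohort] = cohorts.get(cohort, frozenset()) | {member}
    return out.evolve(active_cells=frozenset(remapped), annotations=annotations,
                      archived_annotations=archived, cohorts=cohorts)


def _apply_restrict(space: DesignSpace, am: Amendment) -> DesignSpace:
    treatment, classifiers = am.payload
    t_axis = space.axis(am.axis)
    if treatment not in t_axis:
        raise UnknownElementError(f"treatment {treatment!r} not on axis {am.axis!r}")
    c_axis = space.axis_by_role("classifier")
    if c_axis is None:
        raise UnknownElementError("no classifier axis to restrict against")
    for c in classifiers:
        if c not in c_axis:
            raise UnknownElementError(f"classifier {c!r} not on axis {c_axis.name!r}")
    admissibility = space.admissibility | {(treatment, c) for c in classifiers}
    out = space.evolve(admissibility=admissibility)
    doomed = {
        cell
        for cell in space.active_cells
        if cell[am.axis] == treatment and not out.is_admissible(cell)
    }
    annotations = dict(space.annotations)
    archived = dict(space.archived_annotations)
    for cell in doomed:
        if cell in annotations:
            archived[cell] = archived.get(cell, frozenset()) | annotations.pop(cell)
    return out.evolve(
        active_cells=space.active_cells - doomed,
        annotations=annotations,
        archived_annotations=archived,
    )


def _apply_add_treatment(space: DesignSpace, am: Amendment) -> DesignSpace:
    treatment, classifiers = am.payload
    out = _apply_add_element(space, Amendment("add_element", am.axis, (treatment,)))
    if classifiers is not None:
        out = _apply_restrict(
            out, Amendment("restrict_treatment", am.axis, (treatment, tuple(classifiers)))
        )
    return out


_HANDLERS = {
    "add_element": _apply_add_element,
    "drop_element": _apply_drop_element,
    "merge_into_cohort": _apply_merge,
    "restrict_treatment": _apply_restrict,
    "add_treatment": _apply_add_treatment,
}


def apply_amendments(space: DesignSpace, amendments: Iterable[Amendment]) -> DesignSpace:
    for am in amendments:
        space = apply_amendment(space, am)
    return space


def amendment_log(space: DesignSpace) -> list[Amendment]:
    """The ordered amendments applied since the space was built; replaying
    the log on the original space reproduces the current canonical form."""
    return list(space.history)


def replay(original: DesignSpace, log: Iterable[Amendment]) -> DesignSpace:
    return apply_amendments(original, log)


# ---------------------------------------------------------------------------
# diff
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmendmentDiff:
    """Structured element-level difference between two protocol versions.

    ``added``/``dropped`` map axis name to element sets; ``merged`` maps
    cohort label to the members newly folded in; ``restrictions`` lists
    (treatment, admissible classifier set) pairs added.  ``activated`` and
    ``deactivated`` hold residual per-cell activity changes not implied by
    the element-level amendments (e.g. withdrawing a monotherapy from one
    tumour type); ``flags_added``/``flags_removed`` likewise hold per-cell
    annotation changes.
    """

    added: dict[str, frozenset[str]] = field(default_factory=dict)
    dropped: dict[str, frozenset[str]] = field(default_factory=dict)
    merged: dict[str, frozenset[str]] = field(default_factory=dict)
    restrictions: frozenset[tuple[str, frozenset[str]]] = frozenset()
    activated: frozenset[Cell] = frozenset()
    deactivated: frozenset[Cell] = frozenset()
    flags_added: frozenset[tuple[Cell, str]] = frozenset()
    flags_removed: frozenset[tuple[Cell, str]] = frozenset()

    def is_empty(self) -> bool:
        return not (
            any(self.added.values())
            or any(self.dropped.values())
            or any(self.merged.values())
            or self.restrictions
            or self.activated
            or self.deactivated
            or self.flags_added
            or self.flags_removed
        )

    def to_amendments(self, before: DesignSpace) -> list[Amendment]:
        """The implied amendment sequence: drops, merges, restrictions of
        pre-existing treatments, then additions (restricted treatments are
        added with their restriction attached)."""
        t_axis = before.axis_by_role("treatment")
        t_name = t_axis.name if t_axis else None
        restr = {t: cls for t, cls in self.restrictions}
        out: list[Amendment] = []
        for axis, elements in self.dropped.items():
            out += [drop_element(axis, e) for e in sorted(elements)]
        for cohort, members in self.merged.items():
            axis = _cohort_axis(before, cohort)
            for m in sorted(members):
                if m not in before.axis(axis).elements:
                    # member that never existed standalone in `before`
                    out.append(add_element(axis, m))
                out.append(merge_into_cohort(axis, m, cohort))
        added_treatments = self.added.get(t_name, frozenset()) if t_name else frozenset()
        # non-treatment elements first: a restriction may reference a
        # classifier that is itself being added
        for axis, elements in sorted(self.added.items()):
            if axis == t_name:
                continue
            out += [add_element(axis, e) for e in sorted(elements)]
        for e in sorted(added_treatments):
            out.append(add_treatment(t_name, e, restr.get(e)))
        for t, cls in sorted(restr.items()):
            if t not in added_treatments:
                out.append(restrict_treatment(t_name, t, cls))
        return out

    def apply(self, before: DesignSpace) -> DesignSpace:
        """Replay the diff on ``before``: the implied amendments followed by
        the residual activity and annotation changes.  Canonical-equal to the
        ``after`` space the diff was computed from."""
        out = apply_amendments(before, self.to_amendments(before))
        active = (out.active_cells | self.activated) - self.deactivated
        annotations = {c: set(f) for c, f in out.annotations.items()}
        for cell, flag in self.flags_removed:
            annotations.get(cell, set()).discard(flag)
        for cell, flag in self.flags_added:
            annotations.setdefault(cell, set()).add(flag)
        annotations = {c: frozenset(f) for c, f in annotations.items() if f}
        return out.evolve(active_cells=active, annotations=annotations)


def _cohort_axis(space: DesignSpace, cohort: str) -> str:
    for axis in space.axes:
        if cohort in axis.elements:
            return axis.name
    c_axis = space.axis_by_role("classifier")
    if c_axis is None:
        raise UnknownElementError(f"cannot locate an axis for cohort {cohort!r}")
    return c_axis.name


def diff(before: DesignSpace, after: DesignSpace) -> AmendmentDiff:
    """Minimal element-level diff between two versions of a protocol.

    The spaces must share axis names and roles (the axes themselves are the
    stable skeleton across versions).  A new element of ``after`` that is a
    cohort label absorbing ``before`` elements counts as a merge, not an
    addition; an element of ``before`` that reappears as a cohort member in
    ``after`` counts as merged, not dropped.

    Raises :class:`IncompatibleSpacesError` on mismatched axes.
    """
    b_axes = {a.name: a for a in before.axes}
    a_axes = {a.name: a for a in after.axes}
    if set(b_axes) != set(a_axes) or any(
        b_axes[n].role != a_axes[n].role for n in b_axes
    ):
        raise IncompatibleSpacesError(
            "spaces differ in axis names or roles and cannot be diffed"
        )

    merged: dict[str, frozenset[str]] = {}
    for cohort, members in after.cohorts.items():
        new_members = members - before.cohorts.get(cohort, frozenset())
        if new_members:
            merged[cohort] = frozenset(new_members)
    all_merged_members = frozenset().union(*merged.values()) if merged else frozenset()
    new_cohort_labels = {
        cohort
        for cohort in merged
        if not any(cohort in b_axes[n].elements for n in b_axes)
    }

    added: dict[str, frozenset[str]] = {}
    dropped: dict[str, frozenset[str]] = {}
    for name in b_axes:
        b_el, a_el = set(b_axes[name].elements), set(a_axes[name].elements)
        add = frozenset(a_el - b_el - new_cohort_labels)
        drop = frozenset(b_el - a_el - all_merged_members)
        if add:
            added[name] = add
        if drop:
            dropped[name] = drop

    def _per_treatment(space: DesignSpace) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for t, c in space.admissibility:
            out.setdefault(t, set()).add(c)
        return {t: frozenset(cs) for t, cs in out.items()}

    b_restr, a_restr = _per_treatment(before), _per_treatment(after)
    restrictions = frozenset(
        (t, cls) for t, cls in a_restr.items() if b_restr.get(t) != cls
    )

    partial = AmendmentDiff(added=added, dropped=dropped, merged=merged,
                            restrictions=restrictions)
    intermediate = apply_amendments(before, partial.to_amendments(before))

    def _flag_pairs(space: DesignSpace) -> frozenset[tuple[Cell, str]]:
        return frozenset(
            (cell, flag) for cell, flags in space.annotations.items() for flag in flags
        )

    b_flags, a_flags = _flag_pairs(intermediate), _flag_pairs(after)
    return AmendmentDiff(
        added=added,
        dropped=dropped,
        merged=merged,
        restrictions=restrictions,
        activated=after.active_cells - intermediate.active_cells,
        deactivated=intermediate.active_cells - after.active_cells,
        flags_added=a_flags - b_flags,
        flags_removed=b_flags - a_flags,
    )


def assert_canonical_equal(a: DesignSpace, b: DesignSpace) -> bool:
    return canonical_form(a) == canonical_form(b)
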