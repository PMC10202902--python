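"""Reading and writing ``.design.json`` design documents.

A design document is a strict JSON file with an explicit ``schema_version``
("1.0"), a ``space`` section (axes, active cells, annotations, cohorts,
admissibility), an optional ``history`` of amendments and free-text
``metadata``.  The formal schema ships in ``docs/design-document.schema.json``;
the validator here mirrors it and reports field locations.  Output is
deterministic: two writes of the same space are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

from . import fixtures as _fixtures
from .adaptation import Amendment
from .errors import SchemaError, TrialCubeError, VersionError
from .manifold_core import Cell, DesignSpace, build_space, create_axis

SCHEMA_VERSION = "1.0"
KNOWN_VERSIONS = frozenset({"1.0"})

load_fixture = _fixtures.load_fixture
FIXTURE_NAMES = _fixtures.FIXTURE_NAMES


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def space_to_document(space: DesignSpace, metadata: Optional[dict] = None) -> dict:
    """The JSON-ready document for a space.  Axis and element order follow
    presentation order; cell-valued sections are sorted for determinism."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "metadata": metadata or {},
        "space": {
            "axes": [
                {
                    "name": a.name,
                    "role": a.role,
                    "elements": list(a.elements),
                    "control_element": a.control_element,
                }
                for a in space.axes
            ],
            "active_cells": [dict(c.items) for c in sorted(space.active_cells)],
            "annotations": [
                {"cell": dict(c.items), "flags": sorted(f)}
                for c, f in sorted(space.annotations.items())
                if f
            ],
            "cohorts": {k: sorted(v) for k, v in sorted(space.cohorts.items())},
            "admissibility": [
                {"treatment": t, "classifier": c}
                for t, c in sorted(space.admissibility)
            ],
        },
        "history": [
            {"kind": am.kind, "axis": am.axis, "payload": _payload_to_json(am.payload)}
            for am in space.history
        ],
    }
    return doc


def _payload_to_json(payload: tuple):
    return [list(p) if isinstance(p, tuple) else p for p in payload]


def _payload_from_json(payload) -> tuple:
    return tuple(tuple(p) if isinstance(p, list) else p for p in payload)


def write_design(
    space: DesignSpace, path: Union[str, Path], metadata: Optional[dict] = None
) -> Path:
    """Serialize a space to a ``.design.json`` file (bit-stable for
    identical input)."""
    path = Path(path)
    path.write_text(dumps_design(space, metadata), encoding="utf-8")
    return path


def dumps_design(space: DesignSpace, metadata: Optional[dict] = None) -> str:
    return json.dumps(space_to_document(space, metadata), indent=2, sort_keys=False,
                      ensure_ascii=False) + "\n"


# ---------------------------------------------------------------------------
# reading / validation
# ---------------------------------------------------------------------------


def _require(obj, key, types, loc, optional=False, default=None):
    if key not in obj:
        if optional:
            return default
        raise SchemaError(f"missing required field {key!r}", loc)
    val = obj[key]
    if not isinstance(val, types):
        names = types.__name__ if isinstance(types, type) else "/".join(t.__name__ for t in types)
        raise SchemaError(f"field {key!r} must be {names}, got {type(val).__name__}",
                          f"{loc}.{key}" if loc else key)
    return val


def document_to_space(doc: dict) -> DesignSpace:
    """Validate a parsed document and build the space.

    Raises :class:`VersionError` for an unknown ``schema_version`` and
    :class:`SchemaError` (with a field location) for structural or
    design-rule violations — e.g. an element label duplicated across axes
    breaks the mutual-exclusivity rule of the nominal dimensions.
    """
    if not isinstance(doc, dict):
        raise SchemaError("document root must be an object", "")
    version = _require(doc, "schema_version", str, "")
    if version not in KNOWN_VERSIONS:
        raise VersionError(
            f"unknown schema_version {version!r}; known: {sorted(KNOWN_VERSIONS)}",
            "schema_version",
        )
    space_doc = _require(doc, "space", dict, "")
    axes_doc = _require(space_doc, "axes", list, "space")
    if not axes_doc:
        raise SchemaError("at least two axes are required", "space.axes")

    axes = []
    for i, ax in enumerate(axes_doc):
        loc = f"space.axes[{i}]"
        if not isinstance(ax, dict):
            raise SchemaError("axis must be an object", loc)
        name = _require(ax, "name", str, loc)
        role = _require(ax, "role", str, loc)
        elements = _require(ax, "elements", list, loc)
        control = ax.get("control_element")
        if control is not None and not isinstance(control, str):
            raise SchemaError("control_element must be a string or null", f"{loc}.control_element")
        if not all(isinstance(e, str) for e in elements):
            raise SchemaError("elements must be strings", f"{loc}.elements")
        try:
            axes.append(create_axis(name, role, elements, control))
        except (TrialCubeError, ValueError) as exc:
            raise SchemaError(str(exc), loc) from exc

    def _cells(raw, loc):
        cells = []
        for j, c in enumerate(raw):
            if not isinstance(c, dict) or not all(
                isinstance(k, str) and isinstance(v, str) for k, v in c.items()
            ):
                raise SchemaError("cell must map axis names to elements", f"{loc}[{j}]")
            cells.append(Cell.of(c))
        return cells

    active_raw = _require(space_doc, "active_cells", list, "space", optional=True)
    active = None if active_raw is None else _cells(active_raw, "space.active_cells")

    annotations = {}
    for j, entry in enumerate(_require(space_doc, "annotations", list, "space",
                                       optional=True, default=[])):
        loc = f"space.annotations[{j}]"
        if not isinstance(entry, dict):
            raise SchemaError("annotation entry must be an object", loc)
        cell = _cells([_require(entry, "cell", dict, loc)], loc)[0]
        flags = _require(entry, "flags", list, loc)
        annotations[cell] = frozenset(flags)

    cohorts = _require(space_doc, "cohorts", dict, "space", optional=True, default={})
    for label, members in cohorts.items():
        if not isinstance(members, list) or not all(isinstance(m, str) for m in members):
            raise SchemaError("cohort members must be a list of strings",
                              f"space.cohorts.{label}")

    admissibility = []
    for j, entry in enumerate(_require(space_doc, "admissibility", list, "space",
                                       optional=True, default=[])):
        loc = f"space.admissibility[{j}]"
        if not isinstance(entry, dict):
            raise SchemaError("admissibility entry must be an object", loc)
        admissibility.append(
            (_require(entry, "treatment", str, loc), _require(entry, "classifier", str, loc))
        )

    try:
        space = build_space(
            axes,
            active_cells=active,
            annotations=annotations,
            cohorts={k: frozenset(v) for k, v in cohorts.items()},
            admissibility=admissibility,
        )
    except (TrialCubeError, ValueError) as exc:
        raise SchemaError(str(exc), "space") from exc

    history = []
    for j, entry in enumerate(_require(doc, "history", list, "", optional=True, default=[])):
        loc = f"history[{j}]"
        if not isinstance(entry, dict):
            raise SchemaError("history entry must be an object", loc)
        try:
            history.append(
                Amendment(
                    kind=_require(entry, "kind", str, loc),
                    axis=_require(entry, "axis", str, loc),
                    payload=_payload_from_json(_require(entry, "payload", list, loc)),
                )
            )
        except ValueError as exc:
            raise SchemaError(str(exc), loc) from exc
    return space.evolve(history=tuple(history))


def read_design(path: Union[str, Path]) -> DesignSpace:
    """Read and validate a ``.design.json`` file.

    Raises :class:`SchemaError` (with location) for malformed documents and
    :class:`VersionError` for unknown schema versions.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}", f"line {exc.lineno}") from exc
    return document_to_space(doc)
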