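"""Static, headless rendering of design spaces and projected designs.

Three figure families:

* :func:`render_master_manifold` — the 3-cube picture of a design space:
  a 3D lattice of unit cells at integer positions along nominal axes, with
  ``significant`` cells shaded;
* :func:`render_projection` — the 2D grid of a projected design (subgroup
  columns x treatment rows), the figure a trialist reads a basket or
  umbrella design from;
* :func:`render_hypersurface_gallery` — low-dimensional sphere/cube
  illustrations (point pair, circle/square, sphere surface/cube net).

Output is file-only (SVG or PNG) and deterministic: identical input yields
byte-identical files.  Nominal ticks are uniformly spaced in presentation
order — placement along a nominal axis carries no meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from mpl_toolkits.mplot3d.art3d import Poly3DCollection  # noqa: E402

from .design_projection import DesignType, ProjectedDesign  # noqa: E402
from .errors import UnsupportedRenderError  # noqa: E402
from .hypergeometry import cube_k_faces, cube_vertices  # noqa: E402
from .manifold_core import DesignSpace, NominalAxis  # noqa: E402

# fixed hash salt -> stable SVG clip-path ids across runs; text kept as
# text (not glyph paths) so labels remain searchable in the output
matplotlib.rcParams["svg.hashsalt"] = "trialcube"
matplotlib.rcParams["svg.fonttype"] = "none"

_STYLE = {
    "significant": {"facecolor": "#4878a8", "alpha": 0.85},
    "resistant": {"facecolor": "#c44e52", "alpha": 0.85},
    "combination": {"facecolor": "#55a868", "alpha": 0.85},
}
_PLAIN = {"facecolor": "#d9d9d9", "alpha": 0.35}


@dataclass(frozen=True)
class RenderSpec:
    """Rendering options.

    ``axis_order`` maps axis roles to spatial axes (default B->x, T->y,
    C->z); roles absent from the space are skipped and leftover spatial
    slots filled in order.  ``expand_cohorts`` appends "(incl. ...)" member
    lists to cohort tick labels.
    """

    axis_order: dict = field(
        default_factory=lambda: {"biomarker": "x", "treatment": "y", "classifier": "z"}
    )
    shading: dict = field(default_factory=lambda: dict(_STYLE))
    expand_cohorts: bool = True
    figsize: tuple[float, float] = (7.0, 6.0)
    dpi: int = 100

    def __post_init__(self):
        if len(set(self.axis_order.values())) != len(self.axis_order):
            raise ValueError("axis_order must map roles to distinct spatial axes")


def _tick_label(space_or_design, element: str, spec: RenderSpec) -> str:
    cohorts = getattr(space_or_design, "cohorts", {})
    if spec.expand_cohorts and element in cohorts:
        members = ", ".join(sorted(cohorts[element]))
        return f"{element} (incl. {members})"
    return element


def _spatial_assignment(axes: tuple[NominalAxis, ...], spec: RenderSpec) -> list[NominalAxis]:
    """Order the space's axes as (x, y, z[, ...]) per the spec's role map."""
    slots = ["x", "y", "z"]
    placed: dict[str, NominalAxis] = {}
    rest = []
    for axis in axes:
        slot = spec.axis_order.get(axis.role)
        if slot in slots and slot not in placed:
            placed[slot] = axis
        else:
            rest.append(axis)
    out = []
    for slot in slots[: len(axes)]:
        out.append(placed.pop(slot) if slot in placed else rest.pop(0))
    return out


def _unit_cube_faces(origin: np.ndarray, size: float = 0.8) -> list[np.ndarray]:
    faces = []
    for fd in cube_k_faces(3, 2):
        verts = fd.vertices(half_width=0.5)
        # order the 4 vertices of the square face around its perimeter
        free = sorted(fd.free)
        order = [0, 1, 3, 2]
        faces.append(verts[order] * size + origin)
        del free
    return faces


def render_master_manifold(
    space: DesignSpace,
    path: Union[str, Path],
    spec: Optional[RenderSpec] = None,
    title: Optional[str] = None,
) -> Path:
    """Draw a design space of dimension <= 3 as a 3D (or 2D) cell lattice.

    Active cells are drawn as small cubes at integer lattice positions;
    annotated cells take the flag's shading style (``significant`` first).
    Raises :class:`UnsupportedRenderError` above dimension 3 — project onto
    a lower-dimensional plane first.
    """
    spec = spec or RenderSpec()
    if space.dimension > 3:
        raise UnsupportedRenderError(
            f"cannot render a {space.dimension}-dimensional space directly; "
            "project it onto <=3 axes first"
        )
    path = Path(path)
    ordered = _spatial_assignment(space.axes, spec)
    index = {a.name: {e: i for i, e in enumerate(a.elements)} for a in ordered}

    fig = plt.figure(figsize=spec.figsize, dpi=spec.dpi)
    if space.dimension == 3:
        ax = fig.add_subplot(projection="3d")
        for cell in sorted(space.active_cells):
            pos = np.array([index[a.name][cell[a.name]] for a in ordered], dtype=float)
            style = _PLAIN
            for flag in ("significant", "resistant", "combination"):
                if flag in space.flags(cell):
                    style = spec.shading[flag]
                    break
            poly = Poly3DCollection(_unit_cube_faces(pos), edgecolor="#555555",
                                    linewidths=0.5, **style)
            ax.add_collection3d(poly)
        for setter, axis in zip(
            (ax.set_xticks, ax.set_yticks, ax.set_zticks), ordered
        ):
            setter(range(axis.size))
        ax.set_xticklabels([_tick_label(space, e, spec) for e in ordered[0].elements])
        ax.set_yticklabels([_tick_label(space, e, spec) for e in ordered[1].elements])
        ax.set_zticklabels([_tick_label(space, e, spec) for e in ordered[2].elements],
                           fontsize=8)
        ax.set_xlabel(f"{ordered[0].name} ({ordered[0].role})")
        ax.set_ylabel(f"{ordered[1].name} ({ordered[1].role})")
        ax.set_zlabel(f"{ordered[2].name} ({ordered[2].role})")
        ax.set_xlim(-1, ordered[0].size)
        ax.set_ylim(-1, ordered[1].size)
        ax.set_zlim(-1, ordered[2].size)
    else:  # dimension 2
        ax = fig.add_subplot()
        for cell in sorted(space.active_cells):
            x = index[ordered[0].name][cell[ordered[0].name]]
            y = index[ordered[1].name][cell[ordered[1].name]]
            style = _PLAIN
            for flag in ("significant", "resistant", "combination"):
                if flag in space.flags(cell):
                    style = spec.shading[flag]
                    break
            ax.add_patch(plt.Rectangle((x - 0.4, y - 0.4), 0.8, 0.8,
                                       edgecolor="#555555", **style))
        ax.set_xticks(range(ordered[0].size))
        ax.set_xticklabels([_tick_label(space, e, spec) for e in ordered[0].elements])
        ax.set_yticks(range(ordered[1].size))
        ax.set_yticklabels([_tick_label(space, e, spec) for e in ordered[1].elements])
        ax.set_xlim(-1, ordered[0].size)
        ax.set_ylim(-1, ordered[1].size)
        ax.set_xlabel(f"{ordered[0].name} ({ordered[0].role})")
        ax.set_ylabel(f"{ordered[1].name} ({ordered[1].role})")
    if title:
        ax.set_title(title)
    _save(fig, path)
    return path


def render_projection(
    design: ProjectedDesign,
    path: Union[str, Path],
    spec: Optional[RenderSpec] = None,
) -> Path:
    """Draw a projected design as a 2D grid: subgroup columns (classifiers
    for a basket, biomarkers otherwise) by treatment rows.  Restricted
    treatments appear only in their admissible columns (inactive cells are
    simply absent).  An undetermined design renders with a warning banner."""
    spec = spec or RenderSpec()
    if len(design.residual_axes) > 2:
        raise UnsupportedRenderError("projection rendering supports <=2 residual axes")
    path = Path(path)

    if design.design_type == DesignType.BASKET:
        col_axis = design.residual_axis_by_role("classifier")
    else:
        col_axis = design.residual_axis_by_role("biomarker") or design.residual_axes[0]
    row_axis = next((a for a in design.residual_axes if a.name != col_axis.name), None)

    cols = list(design.active_elements(col_axis))
    rows = list(row_axis.elements) if row_axis is not None else [""]

    fig, ax = plt.subplots(figsize=spec.figsize, dpi=spec.dpi)
    for j, col in enumerate(cols):
        for i, row in enumerate(rows):
            hit = any(
                c[col_axis.name] == col
                and (row_axis is None or c[row_axis.name] == row)
                for c in design.active_grid
            )
            if not hit:
                continue
            flags = frozenset()
            for cell in design.active_grid:
                if cell[col_axis.name] == col and (
                    row_axis is None or cell[row_axis.name] == row
                ):
                    flags |= design.annotations.get(cell, frozenset())
            style = _PLAIN
            for flag in ("significant", "resistant", "combination"):
                if flag in flags:
                    style = spec.shading[flag]
                    break
            ax.add_patch(plt.Rectangle((j - 0.45, i - 0.45), 0.9, 0.9,
                                       edgecolor="#555555", **style))
    ax.set_xticks(range(len(cols)))
    ax.set_xticklabels([_tick_label(design, c, spec) for c in cols],
                       rotation=30, ha="right", fontsize=8)
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels(rows)
    ax.set_xlim(-1, max(len(cols), 1))
    ax.set_ylim(-1, max(len(rows), 1))
    fixed = ", ".join(f"{k}={v}" for k, v in sorted(design.fixed.items()))
    ax.set_title(f"{design.design_type.value} design | fixed {fixed}")
    if design.design_type == DesignType.UNDETERMINED:
        ax.text(0.5, 0.98, "warning: undetermined design",
                transform=ax.transAxes, ha="center", va="top", color="#c44e52")
    _save(fig, path)
    return path


def render_hypersurface_gallery(
    out_dir: Union[str, Path], radius: float = 1.0, max_n: int = 2
) -> list[Path]:
    """Illustrations of low-dimensional hypersurfaces built from the
    geometry primitives: the point pair {c-r, c+r} (n=0), circle and square
    (n=1), sphere surface and the 6-square net of a cube (n=2)."""
    if max_n > 3:
        raise UnsupportedRenderError("gallery supports n <= 3")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    for n in range(min(max_n, 2) + 1):
        fig, (ax_s, ax_c) = plt.subplots(1, 2, figsize=(8, 4), dpi=100)
        if n == 0:
            for ax, name in ((ax_s, "0-sphere"), (ax_c, "0-cube")):
                ax.plot([-radius, radius], [0, 0], "o", color="#4878a8")
                ax.set_title(f"{name}: point pair {{c-r, c+r}}")
                ax.set_xlim(-2 * radius, 2 * radius)
        elif n == 1:
            theta = np.linspace(0, 2 * np.pi, 200)
            ax_s.plot(radius * np.cos(theta), radius * np.sin(theta), color="#4878a8")
            ax_s.set_title("1-sphere: boundary of a disc")
            ax_s.set_aspect("equal")
            square = cube_vertices(2, half_width=radius)[[0, 1, 3, 2, 0]]
            ax_c.plot(square[:, 0], square[:, 1], color="#55a868")
            ax_c.set_title("1-cube: boundary of a square")
            ax_c.set_aspect("equal")
        else:
            theta = np.linspace(0, 2 * np.pi, 60)
            phi = np.linspace(0, np.pi, 30)
            for p in phi[::4]:
                ax_s.plot(radius * np.sin(p) * np.cos(theta),
                          radius * np.sin(p) * np.sin(theta), lw=0.5, color="#4878a8")
            ax_s.set_title("2-sphere: surface of a ball (wireframe)")
            ax_s.set_aspect("equal")
            # the cube net: 6 unit squares in a cross layout, one per 2-face
            n_faces = len(cube_k_faces(3, 2))
            offsets = [(0, 0), (0, 1), (0, -1), (-1, 0), (1, 0), (0, 2)][:n_faces]
            for ox, oy in offsets:
                ax_c.add_patch(plt.Rectangle((ox - 0.5, oy - 0.5), 1, 1,
                                             facecolor="#d9d9d9", edgecolor="#555555"))
            ax_c.set_xlim(-2, 2)
            ax_c.set_ylim(-2, 3)
            ax_c.set_aspect("equal")
            ax_c.set_title(f"2-cube: net of {n_faces} squares")
        p = out_dir / f"hypersurface_n{n}.svg"
        _save(fig, p)
        paths.append(p)
    return paths


def _save(fig, path: Path) -> None:
    # Date metadata suppressed so identical input gives identical bytes
    if path.suffix == ".svg":
        fig.savefig(path, metadata={"Date": None})
    else:
        fig.savefig(path)
    plt.close(fig)
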