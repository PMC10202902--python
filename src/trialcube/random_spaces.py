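"""Pseudo-random valid design spaces, for round-trip and property testing.

Spaces are drawn to resemble small master protocols: a biomarker, a
treatment and a classifier axis (plus, occasionally, an extra "other" axis —
the framework supports dimensions beyond 3), 1-4 elements per axis, a
non-empty random subset of cells active, occasional annotations, a cohort
and a treatment restriction.  Every returned space satisfies
``validate_space`` with zero violations.
"""

from __future__ import annotations

import numpy as np

from .manifold_core import Cell, DesignSpace, build_space, create_axis, DEFAULT_FLAGS


def random_design_space(
    rng: np.random.Generator,
    max_axis_size: int = 4,
    extra_axis_prob: float = 0.2,
) -> DesignSpace:
    """Draw one valid design space from ``rng``."""
    sizes = rng.integers(1, max_axis_size + 1, size=3)
    axes = [
        create_axis("B", "biomarker", [f"b{i}" for i in range(sizes[0])]),
        create_axis(
            "T",
            "treatment",
            [f"t{i}" for i in range(sizes[1])],
            control_element="t0" if sizes[1] >= 2 and rng.random() < 0.5 else None,
        ),
        create_axis("C", "classifier", [f"c{i}" for i in range(sizes[2])]),
    ]
    if rng.random() < extra_axis_prob:
        n_extra = int(rng.integers(1, max_axis_size + 1))
        axes.append(create_axis("X", "other", [f"x{i}" for i in range(n_extra)]))

    cohorts = {}
    if rng.random() < 0.3:
        n_members = int(rng.integers(1, 4))
        cohorts["pooled"] = frozenset(f"m{i}" for i in range(n_members))
        # the cohort label must be a classifier element
        axes[2] = create_axis("C", "classifier", list(axes[2].elements) + ["pooled"])

    admissibility = []
    if rng.random() < 0.3 and axes[1].size >= 2:
        t = str(rng.choice(axes[1].elements))
        allowed = [c for c in axes[2].elements if rng.random() < 0.5]
        if allowed:
            admissibility = [(t, c) for c in allowed]

    proto = build_space(axes, cohorts=cohorts, admissibility=admissibility)
    full = sorted(c for c in proto.all_cells() if proto.is_admissible(c))
    keep = rng.random(len(full)) < 0.7
    if not keep.any():
        keep[int(rng.integers(len(full)))] = True
    active = [c for c, k in zip(full, keep) if k]

    annotations: dict[Cell, frozenset] = {}
    flags = sorted(DEFAULT_FLAGS)
    for cell in active:
        if rng.random() < 0.2:
            annotations[cell] = frozenset({str(rng.choice(flags))})

    return build_space(
        axes,
        active_cells=active,
        annotations=annotations,
        cohorts=cohorts,
        admissibility=admissibility,
    )
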