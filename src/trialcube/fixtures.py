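"""Packaged example design spaces.

Three transcriptions of published precision-oncology designs:

``melanoma_association``
    The BRAF/NRAS mutation association study across four groups of primary
    melanomas (chronic sun-induced damage, non-CSD, mucosal, acral).  BRAF
    showed a statistically significant association with the melanoma
    subtypes (those cells carry the ``significant`` flag); NRAS did not.
    Fixing B=BRAF projects out the basket design that prefigured the
    Vemurafenib melanoma study.

``vemurafenib_initial``
    The Vemurafenib basket trial in BRAF V600-mutated non-melanoma cancers
    at the start of the trial: one treatment arm across seven disease
    classifiers, with rare tumour types pooled in an "All others" cohort
    (cervical, brain tumour, head and neck, oesophageal and gastric,
    pancreatic, sarcoma, unknown primary-type carcinoma).  The full cohort
    list of the original protocol is not exhaustively published; this
    transcription covers the cohorts named by the adaptation narrative plus
    the arms that persisted throughout (NSCLC, colorectal,
    cholangiocarcinoma).

``vemurafenib_adapted``
    The same trial after adaptive amendments: ovarian and multiple-myeloma
    cohorts dropped (insufficient accrual), breast folded into "All others"
    (slow recruitment), two new classifiers opened (ECD/LCH and anaplastic
    thyroid), and — because of Vemurafenib resistance in colorectal cancer —
    a Vemurafenib+Cetuximab combination arm admissible for the colorectal
    cohort only, replacing monotherapy there.
"""

from __future__ import annotations

from .errors import UnknownFixtureError
from .manifold_core import Cell, DesignSpace, annotate_slice, build_space, create_axis

ALL_OTHERS_MEMBERS = (
    "cervical",
    "brain tumour",
    "head and neck",
    "oesophageal and gastric",
    "pancreatic",
    "sarcoma",
    "unknown primary-type carcinoma",
)


def melanoma_association() -> DesignSpace:
    axes = [
        create_axis("B", "biomarker", ["BRAF", "NRAS"]),
        create_axis("T", "treatment", ["Vemurafenib"]),
        create_axis("C", "classifier", ["CSD", "Non-CSD", "Mucosal", "Acral"]),
    ]
    space = build_space(axes)  # full 2 x 1 x 4 product active
    return annotate_slice(space, "B", "BRAF", "significant")


def vemurafenib_initial() -> DesignSpace:
    axes = [
        create_axis("B", "biomarker", ["BRAF"]),
        create_axis("T", "treatment", ["Vemurafenib"]),
        create_axis(
            "C",
            "classifier",
            [
                "NSCLC",
                "Colorectal",
                "Cholangiocarcinoma",
                "Breast",
                "Ovarian",
                "Multiple myeloma",
                "All others",
            ],
        ),
    ]
    return build_space(axes, cohorts={"All others": ALL_OTHERS_MEMBERS})


def vemurafenib_adapted() -> DesignSpace:
    axes = [
        create_axis("B", "biomarker", ["BRAF"]),
        create_axis("T", "treatment", ["Vemurafenib", "Vemurafenib+Cetuximab"]),
        create_axis(
            "C",
            "classifier",
            [
                "NSCLC",
                "Colorectal",
                "Cholangiocarcinoma",
                "ECD/LCH",
                "Anaplastic thyroid",
                "All others",
            ],
        ),
    ]
    classifiers = axes[2].elements
    active = []
    for c in classifiers:
        if c == "Colorectal":
            # resistance: colorectal receives the combination arm only
            active.append(Cell.of({"B": "BRAF", "T": "Vemurafenib+Cetuximab", "C": c}))
        else:
            active.append(Cell.of({"B": "BRAF", "T": "Vemurafenib", "C": c}))
    space = build_space(
        axes,
        active_cells=active,
        cohorts={"All others": ALL_OTHERS_MEMBERS + ("Breast",)},
        admissibility=[("Vemurafenib+Cetuximab", "Colorectal")],
    )
    combo_cell = Cell.of({"B": "BRAF", "T": "Vemurafenib+Cetuximab", "C": "Colorectal"})
    from .manifold_core import annotate

    return annotate(space, combo_cell, "combination")


FIXTURE_METADATA = {
    "melanoma_association": {
        "title": "BRAF/NRAS association across primary melanoma subtypes",
        "notes": "Shaded (significant) cells: BRAF slice; NRAS showed no "
        "statistically significant association.",
    },
    "vemurafenib_initial": {
        "title": "Vemurafenib basket trial in BRAF V600 non-melanoma cancers "
        "(start of trial)",
        "notes": "Cohort list reconstructed from the adaptation narrative; "
        "'All others' pools seven rare tumour types.",
    },
    "vemurafenib_adapted": {
        "title": "Vemurafenib basket trial after adaptive amendments",
        "notes": "ECD/LCH = Erdheim-Chester Disease / Langerhans-Cell "
        "Histiocytosis. Vemurafenib+Cetuximab is admissible for the "
        "colorectal cohort only.",
    },
}

_FIXTURES = {
    "melanoma_association": melanoma_association,
    "vemurafenib_initial": vemurafenib_initial,
    "vemurafenib_adapted": vemurafenib_adapted,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def load_fixture(name: str) -> DesignSpace:
    """Return a packaged design space by name.

    Raises :class:`UnknownFixtureError` for names outside
    :data:`FIXTURE_NAMES`.
    """
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()
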