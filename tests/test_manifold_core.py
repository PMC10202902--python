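"""Design-space data model: axes, cells, annotations, validation, canonical
form."""

import itertools

import pytest

import trialcube as tc
from trialcube.errors import (
    AxisOverlapError,
    DuplicateLabelError,
    EmptyAxisError,
    InvalidCellError,
    InvalidControlError,
    UnknownFlagError,
)
from trialcube.manifold_core import canonical_form


class TestCreateAxis:
    def test_melanoma_classifier_axis(self):
        axis = tc.create_axis("C", "classifier", ["CSD", "Non-CSD", "Mucosal", "Acral"])
        assert axis.size == 4

    def test_mutation_biomarker_axis(self):
        axis = tc.create_axis("B", "biomarker", ["BRAF", "NRAS"])
        assert axis.size == 2

    @pytest.mark.parametrize(
        "kwargs, exc",
        [
            (dict(name="T", role="treatment", elements=[]), EmptyAxisError),
            (dict(name="B", role="biomarker", elements=["BRAF", "BRAF"]), DuplicateLabelError),
            (
                dict(name="T", role="treatment", elements=["t1"], control_element="T0"),
                InvalidControlError,
            ),
            (
                dict(name="B", role="biomarker", elements=["b1", "T0"], control_element="T0"),
                InvalidControlError,  # control arms belong to treatment axes
            ),
        ],
    )
    def test_invalid_axes_rejected(self, kwargs, exc):
        with pytest.raises(exc):
            tc.create_axis(**kwargs)

    def test_control_arm_accepted_on_treatment_axis(self):
        axis = tc.create_axis("T", "treatment", ["T0", "T1"], control_element="T0")
        assert axis.control_element == "T0"


class TestBuildSpace:
    def test_full_product_active_by_default(self, melanoma):
        # 2 biomarkers x 1 treatment x 4 classifiers
        assert len(melanoma.active_cells) == 8

    def test_dimension_is_axis_count(self, melanoma):
        assert melanoma.dimension == 3

    def test_shared_label_across_axes_rejected(self):
        with pytest.raises(AxisOverlapError):
            tc.build_space(
                [
                    tc.create_axis("B", "biomarker", ["BRAF"]),
                    tc.create_axis("C", "classifier", ["BRAF"]),
                ]
            )

    def test_malformed_cell_rejected(self):
        axes = [
            tc.create_axis("B", "biomarker", ["b1"]),
            tc.create_axis("C", "classifier", ["c1"]),
        ]
        with pytest.raises(InvalidCellError):
            tc.build_space(axes, active_cells=[tc.Cell.of({"B": "b1", "C": "nope"})])
        with pytest.raises(InvalidCellError):
            tc.build_space(axes, active_cells=[tc.Cell.of({"B": "b1"})])

    def test_active_count_bounded_by_product(self, rng):
        for _ in range(20):
            s = tc.random_design_space(rng)
            product = 1
            for a in s.axes:
                product *= a.size
            assert len(s.active_cells) <= product

    def test_cohort_member_cannot_be_standalone_element(self):
        with pytest.raises(AxisOverlapError):
            tc.build_space(
                [
                    tc.create_axis("B", "biomarker", ["b1"]),
                    tc.create_axis("C", "classifier", ["Breast", "All others"]),
                ],
                cohorts={"All others": ["Breast"]},
            )


class TestAnnotate:
    def test_braf_slice_significant(self, melanoma):
        sig = [c for c, f in melanoma.annotations.items() if "significant" in f]
        assert len(sig) == 4
        assert all(c["B"] == "BRAF" for c in sig)

    def test_nras_cells_unflagged(self, melanoma):
        nras = [
            c
            for c, f in melanoma.annotations.items()
            if "significant" in f and c["B"] == "NRAS"
        ]
        assert nras == []

    def test_idempotent(self, melanoma):
        cell = next(iter(melanoma.active_cells))
        once = tc.annotate(melanoma, cell, "resistant")
        twice = tc.annotate(once, cell, "resistant")
        assert once.annotations == twice.annotations

    def test_unknown_flag_rejected(self, melanoma):
        cell = next(iter(melanoma.active_cells))
        with pytest.raises(UnknownFlagError):
            tc.annotate(melanoma, cell, "shiny")

    def test_inactive_cell_warns_not_errors(self, toy_2x2x1):
        cell = tc.Cell.of({"B": "b1", "T": "t1", "C": "c1"})
        sparse = toy_2x2x1.evolve(active_cells=toy_2x2x1.active_cells - {cell})
        with pytest.warns(UserWarning):
            annotated = tc.annotate(sparse, cell, "significant")
        report = tc.validate_space(annotated)
        assert report.ok
        assert any("not active" in w for w in report.warnings)


class TestValidateSpace:
    def test_fixtures_are_valid(self):
        for name in tc.FIXTURE_NAMES:
            report = tc.validate_space(tc.load_fixture(name))
            assert report.ok, (name, report.violations)

    def test_admissibility_violation_reported(self, vem_adapted):
        # pair the colorectal-only combination arm with a different tumour type
        bad_cell = tc.Cell.of(
            {"B": "BRAF", "T": "Vemurafenib+Cetuximab", "C": "NSCLC"}
        )
        broken = vem_adapted.evolve(active_cells=vem_adapted.active_cells | {bad_cell})
        report = tc.validate_space(broken)
        assert not report.ok
        assert any("admissibility" in v for v in report.violations)


class TestCanonicalForm:
    def test_invariant_under_element_permutation(self, melanoma):
        base = canonical_form(melanoma)
        for perm in itertools.permutations(["CSD", "Non-CSD", "Mucosal", "Acral"]):
            axes = [
                tc.create_axis("B", "biomarker", ["BRAF", "NRAS"]),
                tc.create_axis("T", "treatment", ["Vemurafenib"]),
                tc.create_axis("C", "classifier", list(perm)),
            ]
            reordered = tc.annotate_slice(tc.build_space(axes), "B", "BRAF", "significant")
            assert canonical_form(reordered) == base

    def test_differs_when_active_cells_differ(self, melanoma):
        cell = next(iter(melanoma.active_cells))
        smaller = melanoma.evolve(
            active_cells=melanoma.active_cells - {cell},
            annotations={c: f for c, f in melanoma.annotations.items() if c != cell},
        )
        assert canonical_form(smaller) != canonical_form(melanoma)

    def test_history_excluded_from_identity(self, vem_initial):
        amended = tc.apply_amendment(
            vem_initial, tc.drop_element("C", "Ovarian")
        )
        readded = tc.apply_amendment(amended, tc.add_element("C", "Ovarian"))
        # same content, different provenance
        assert len(readded.history) == 2
        assert canonical_form(readded) == canonical_form(vem_initial)
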