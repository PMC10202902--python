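"""Projection of design spaces and classification of embedded trial
designs."""

import itertools

import pytest

import trialcube as tc
from trialcube.design_projection import DesignType
from trialcube.errors import EmptySubgroupsError, UnknownElementError
from trialcube.manifold_core import canonical_form


class TestProject:
    def test_melanoma_braf_slice(self, melanoma):
        d = tc.project(melanoma, "B", "BRAF")
        assert len(d.active_grid) == 4  # 1 treatment x 4 melanoma subtypes
        assert {a.name for a in d.residual_axes} == {"T", "C"}
        assert d.design_type == DesignType.BASKET

    def test_annotations_inherited(self, melanoma):
        d = tc.project(melanoma, "B", "BRAF")
        assert all("significant" in f for f in d.annotations.values())
        d_nras = tc.project(melanoma, "B", "NRAS")
        assert not d_nras.annotations

    def test_colorectal_slice_has_combination_arm_only(self, vem_adapted):
        d = tc.project(vem_adapted, "C", "Colorectal")
        t_axis = d.residual_axis_by_role("treatment")
        assert d.active_elements(t_axis) == ("Vemurafenib+Cetuximab",)

    def test_unknown_element_rejected(self, melanoma):
        with pytest.raises(UnknownElementError):
            tc.project(melanoma, "B", "KRAS")
        with pytest.raises(UnknownElementError):
            tc.project(melanoma, "Z", "BRAF")

    def test_slicing_consistency(self, melanoma, vem_adapted):
        # every active parent cell appears in the projection at each of its
        # own coordinates
        for space in (melanoma, vem_adapted):
            for cell in space.active_cells:
                for axis_name, element in cell.items:
                    d = tc.project(space, axis_name, element)
                    assert cell.drop(axis_name) in d.active_grid

    def test_reembedding_recovers_parent_slice(self, vem_adapted):
        for axis in vem_adapted.axes:
            for element in axis.elements:
                d = tc.project(vem_adapted, axis.name, element)
                expected = frozenset(
                    c for c in vem_adapted.active_cells if c[axis.name] == element
                )
                assert d.reembed() == expected

    def test_projection_invariant_under_element_reorder(self, melanoma):
        axes = [
            tc.create_axis("B", "biomarker", ["NRAS", "BRAF"]),
            tc.create_axis("T", "treatment", ["Vemurafenib"]),
            tc.create_axis("C", "classifier", ["Acral", "Mucosal", "Non-CSD", "CSD"]),
        ]
        reordered = tc.annotate_slice(tc.build_space(axes), "B", "BRAF", "significant")
        assert canonical_form(reordered) == canonical_form(melanoma)
        d1 = tc.project(melanoma, "B", "BRAF")
        d2 = tc.project(reordered, "B", "BRAF")
        assert d1.active_grid == d2.active_grid
        assert d1.design_type == d2.design_type
        assert set(tc.subgroups(d1)) == set(tc.subgroups(d2))


def _toy_space(active_pairs, b_elements=("b1", "b2"), t_elements=("t1", "t2"),
               control=None):
    axes = [
        tc.create_axis("B", "biomarker", list(b_elements)),
        tc.create_axis("T", "treatment", list(t_elements), control_element=control),
        tc.create_axis("C", "classifier", ["c1"]),
    ]
    cells = [tc.Cell.of({"B": b, "T": t, "C": "c1"}) for b, t in active_pairs]
    return tc.build_space(axes, active_cells=cells)


# Hand-derived truth table over all 16 activity patterns of the 2x2 grid at
# a fixed classifier.  One active biomarker out of two is an enrichment
# (biomarker-positive selection); two biomarkers each on a single treatment
# form an umbrella; any biomarker assigned two treatments crosses into a
# matrix; an empty grid is undetermined.
TRUTH_TABLE = {
    frozenset(): DesignType.UNDETERMINED,
    frozenset({("b1", "t1")}): DesignType.ENRICHMENT,
    frozenset({("b1", "t2")}): DesignType.ENRICHMENT,
    frozenset({("b2", "t1")}): DesignType.ENRICHMENT,
    frozenset({("b2", "t2")}): DesignType.ENRICHMENT,
    frozenset({("b1", "t1"), ("b1", "t2")}): DesignType.ENRICHMENT,
    frozenset({("b2", "t1"), ("b2", "t2")}): DesignType.ENRICHMENT,
    frozenset({("b1", "t1"), ("b2", "t1")}): DesignType.UMBRELLA,
    frozenset({("b1", "t1"), ("b2", "t2")}): DesignType.UMBRELLA,
    frozenset({("b1", "t2"), ("b2", "t1")}): DesignType.UMBRELLA,
    frozenset({("b1", "t2"), ("b2", "t2")}): DesignType.UMBRELLA,
    frozenset({("b1", "t1"), ("b1", "t2"), ("b2", "t1")}): DesignType.MATRIX,
    frozenset({("b1", "t1"), ("b1", "t2"), ("b2", "t2")}): DesignType.MATRIX,
    frozenset({("b1", "t1"), ("b2", "t1"), ("b2", "t2")}): DesignType.MATRIX,
    frozenset({("b1", "t2"), ("b2", "t1"), ("b2", "t2")}): DesignType.MATRIX,
    frozenset({("b1", "t1"), ("b1", "t2"), ("b2", "t1"), ("b2", "t2")}): DesignType.MATRIX,
}


class TestClassify:
    def test_truth_table_is_exhaustive(self):
        all_pairs = [(b, t) for b in ("b1", "b2") for t in ("t1", "t2")]
        patterns = {
            frozenset(c)
            for r in range(5)
            for c in itertools.combinations(all_pairs, r)
        }
        assert set(TRUTH_TABLE) == patterns and len(TRUTH_TABLE) == 16

    @pytest.mark.parametrize("pattern, expected", sorted(TRUTH_TABLE.items(),
                                                         key=lambda kv: sorted(kv[0])))
    def test_classification_matches_truth_table(self, pattern, expected):
        space = _toy_space(pattern)
        d = tc.project(space, "C", "c1")
        assert d.design_type == expected

    def test_enrichment_via_control_arm(self):
        # single-biomarker axis, but an active control arm: enrichment
        space = _toy_space(
            [("b1", "T0"), ("b1", "T1")],
            b_elements=("b1",),
            t_elements=("T0", "T1"),
            control="T0",
        )
        d = tc.project(space, "C", "c1")
        assert d.design_type == DesignType.ENRICHMENT

    def test_single_element_axes_give_single_cohort(self):
        space = _toy_space([("b1", "t1")], b_elements=("b1",), t_elements=("t1",))
        designs = tc.enumerate_embedded_designs(space)
        assert len(designs) == 2
        assert all(d.design_type == DesignType.SINGLE_COHORT for d in designs)

    def test_fixed_treatment_is_undetermined(self, melanoma):
        d = tc.project(melanoma, "T", "Vemurafenib")
        assert d.design_type == DesignType.UNDETERMINED

    def test_fixed_biomarker_single_classifier_is_single_cohort(self):
        axes = [
            tc.create_axis("B", "biomarker", ["b1", "b2"]),
            tc.create_axis("T", "treatment", ["t1"]),
            tc.create_axis("C", "classifier", ["c1"]),
        ]
        d = tc.project(tc.build_space(axes), "B", "b1")
        assert d.design_type == DesignType.SINGLE_COHORT


class TestSubgroups:
    def test_melanoma_basket_subgroups_are_tumour_types(self, melanoma):
        d = tc.project(melanoma, "B", "BRAF")
        assert tc.subgroups(d) == ["CSD", "Non-CSD", "Mucosal", "Acral"]

    def test_enrichment_subgroup_is_the_biomarker(self):
        d = tc.project(_toy_space([("b1", "t1")]), "C", "c1")
        assert tc.subgroups(d) == ["b1"]

    def test_matrix_subgroups_are_biomarker_treatment_pairs(self):
        pattern = [("b1", "t1"), ("b1", "t2"), ("b2", "t1"), ("b2", "t2")]
        d = tc.project(_toy_space(pattern), "C", "c1")
        assert tc.subgroups(d) == ["b1:t1", "b1:t2", "b2:t1", "b2:t2"]

    def test_undetermined_design_has_no_subgroups(self):
        d = tc.project(_toy_space([]), "C", "c1")
        with pytest.raises(EmptySubgroupsError):
            tc.subgroups(d)


class TestEnumerate:
    def test_melanoma_count_is_b_plus_c(self, melanoma):
        designs = tc.enumerate_embedded_designs(melanoma)
        assert len(designs) == 2 + 4  # |B| + |C|

    def test_every_design_satisfies_its_invariants(self, melanoma, vem_adapted, rng):
        spaces = [melanoma, vem_adapted] + [tc.random_design_space(rng) for _ in range(10)]
        for space in spaces:
            for d in tc.enumerate_embedded_designs(space):
                fixed_names = set(d.fixed)
                assert len(d.residual_axes) == space.dimension - len(fixed_names)
                parent_active = space.active_cells
                for cell in d.active_grid:
                    extended = cell
                    for name, element in d.fixed.items():
                        extended = extended.extend(name, element)
                    assert extended in parent_active
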