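"""Amendment operations and structured diffs between protocol versions."""

import numpy as np
import pytest

import trialcube as tc
from trialcube.adaptation import AmendmentDiff, apply_amendments, replay
from trialcube.errors import (
    AxisOverlapError,
    EmptyAxisError,
    IncompatibleSpacesError,
    UnknownElementError,
)
from trialcube.manifold_core import canonical_form


class TestApplyAmendment:
    def test_drop_removes_element_and_cells(self, vem_initial):
        out = tc.apply_amendment(vem_initial, tc.drop_element("C", "Ovarian"))
        assert "Ovarian" not in out.axis("C").elements
        assert all(c["C"] != "Ovarian" for c in out.active_cells)
        assert tc.validate_space(out).ok

    def test_drop_unknown_element_rejected(self, vem_initial):
        with pytest.raises(UnknownElementError):
            tc.apply_amendment(vem_initial, tc.drop_element("C", "Prostate"))

    def test_drop_last_element_rejected(self, vem_initial):
        with pytest.raises(EmptyAxisError):
            tc.apply_amendment(vem_initial, tc.drop_element("B", "BRAF"))

    def test_merge_folds_member_into_cohort(self, vem_initial):
        out = tc.apply_amendment(
            vem_initial, tc.merge_into_cohort("C", "Breast", "All others")
        )
        assert "Breast" not in out.axis("C").elements
        assert "Breast" in out.cohorts["All others"]
        # the member's activity folds into the cohort element
        assert any(c["C"] == "All others" for c in out.active_cells)
        assert tc.validate_space(out).ok

    def test_merge_collision_rejected(self, vem_initial):
        # a cohort label colliding with an element on another axis
        with pytest.raises(AxisOverlapError):
            tc.apply_amendment(
                vem_initial, tc.merge_into_cohort("C", "Breast", "Vemurafenib")
            )

    def test_add_element_activates_its_slice(self, vem_initial):
        out = tc.apply_amendment(vem_initial, tc.add_element("C", "ECD/LCH"))
        new = {c for c in out.active_cells if c["C"] == "ECD/LCH"}
        assert len(new) == 1  # 1 biomarker x 1 treatment
        assert tc.validate_space(out).ok

    def test_add_treatment_with_restriction(self, vem_initial):
        out = tc.apply_amendment(
            vem_initial,
            tc.add_treatment("T", "Vemurafenib+Cetuximab", ["Colorectal"]),
        )
        combo_cells = {c for c in out.active_cells if c["T"] == "Vemurafenib+Cetuximab"}
        assert {c["C"] for c in combo_cells} == {"Colorectal"}
        assert ("Vemurafenib+Cetuximab", "Colorectal") in out.admissibility
        assert tc.validate_space(out).ok

    def test_restrict_deactivates_and_archives(self, vem_initial):
        annotated = tc.annotate(
            vem_initial,
            tc.Cell.of({"B": "BRAF", "T": "Vemurafenib", "C": "Ovarian"}),
            "resistant",
        )
        out = tc.apply_amendment(
            annotated, tc.restrict_treatment("T", "Vemurafenib", ["NSCLC"])
        )
        assert {c["C"] for c in out.active_cells} == {"NSCLC"}
        # the dropped cell's annotation is archived, not lost
        assert any("resistant" in f for f in out.archived_annotations.values())
        assert tc.validate_space(out).ok

    def test_inputs_never_mutated(self, vem_initial):
        before = canonical_form(vem_initial)
        tc.apply_amendment(vem_initial, tc.drop_element("C", "Ovarian"))
        tc.apply_amendment(vem_initial, tc.merge_into_cohort("C", "Breast", "All others"))
        assert canonical_form(vem_initial) == before
        assert vem_initial.history == ()


class TestAmendmentLog:
    def test_fresh_space_has_empty_log(self, vem_initial):
        assert tc.amendment_log(vem_initial) == []

    def test_log_length_counts_amendments(self, vem_initial):
        out = apply_amendments(
            vem_initial,
            [
                tc.drop_element("C", "Ovarian"),
                tc.drop_element("C", "Multiple myeloma"),
                tc.merge_into_cohort("C", "Breast", "All others"),
            ],
        )
        assert len(tc.amendment_log(out)) == 3

    def test_replay_reproduces_canonical_form(self, vem_initial):
        out = apply_amendments(
            vem_initial,
            [
                tc.drop_element("C", "Ovarian"),
                tc.add_element("C", "Anaplastic thyroid"),
                tc.add_treatment("T", "Vemurafenib+Cetuximab", ["Colorectal"]),
            ],
        )
        again = replay(vem_initial, tc.amendment_log(out))
        assert canonical_form(again) == canonical_form(out)


class TestDiff:
    def test_identity_diff_is_empty(self, vem_initial):
        assert tc.diff(vem_initial, vem_initial).is_empty()

    def test_vemurafenib_adaptation_regression(self, vem_initial, vem_adapted):
        d = tc.diff(vem_initial, vem_adapted)
        assert d.added["C"] == {"ECD/LCH", "Anaplastic thyroid"}
        assert d.added["T"] == {"Vemurafenib+Cetuximab"}
        assert d.dropped == {"C": frozenset({"Ovarian", "Multiple myeloma"})}
        assert d.merged == {"All others": frozenset({"Breast"})}
        assert d.restrictions == {
            ("Vemurafenib+Cetuximab", frozenset({"Colorectal"}))
        }
        # resistance: monotherapy withdrawn from the colorectal cohort
        assert d.deactivated == {
            tc.Cell.of({"B": "BRAF", "T": "Vemurafenib", "C": "Colorectal"})
        }

    def test_diff_roundtrip_on_fixtures(self, vem_initial, vem_adapted):
        d = tc.diff(vem_initial, vem_adapted)
        rebuilt = d.apply(vem_initial)
        assert canonical_form(rebuilt) == canonical_form(vem_adapted)

    def test_mismatched_axes_rejected(self, vem_initial, melanoma):
        with pytest.raises(IncompatibleSpacesError):
            tc.diff(vem_initial, melanoma.evolve(axes=(
                tc.create_axis("B", "classifier", ["BRAF", "NRAS"]),
            ) + melanoma.axes[1:]))

    def test_roundtrip_over_random_amendment_sequences(self, vem_initial):
        rng = np.random.default_rng(7)
        for _ in range(25):
            space = vem_initial
            n_steps = int(rng.integers(1, 5))
            for _ in range(n_steps):
                space = self._random_amendment(space, rng)
            d = tc.diff(vem_initial, space)
            rebuilt = d.apply(vem_initial)
            assert canonical_form(rebuilt) == canonical_form(space)

    @staticmethod
    def _random_amendment(space, rng):
        c_axis = space.axis("C")
        choices = ["add", "drop", "merge", "restrict"]
        kind = choices[int(rng.integers(len(choices)))]
        if kind == "add":
            label = f"new{int(rng.integers(1_000_000))}"
            return tc.apply_amendment(space, tc.add_element("C", label))
        if kind == "drop" and c_axis.size > 1:
            victim = str(rng.choice([e for e in c_axis.elements if e != "All others"]))
            return tc.apply_amendment(space, tc.drop_element("C", victim))
        if kind == "merge" and c_axis.size > 1 and "All others" in c_axis.elements:
            member = str(rng.choice([e for e in c_axis.elements if e != "All others"]))
            return tc.apply_amendment(
                space, tc.merge_into_cohort("C", member, "All others")
            )
        if kind == "restrict":
            keep = [e for e in c_axis.elements if rng.random() < 0.5]
            if keep:
                return tc.apply_amendment(
                    space, tc.restrict_treatment("T", "Vemurafenib", keep)
                )
        return space

    def test_empty_diff_object(self):
        assert AmendmentDiff().is_empty()
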