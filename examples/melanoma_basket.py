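"""Recover a basket design from the melanoma association manifold.

The packaged fixture encodes the BRAF/NRAS association study across four
primary-melanoma subtypes as a 3-cube design space: BRAF's cells carry the
``significant`` flag, NRAS's do not.  Fixing the biomarker axis at BRAF and
projecting onto the (treatment, classifier) plane yields the basket design
that prefigured the Vemurafenib melanoma study.
"""

import trialcube as tc

space = tc.load_fixture("melanoma_association")
print(f"dimension: {space.dimension}, active cells: {len(space.active_cells)}")

n_sig = sum(1 for flags in space.annotations.values() if "significant" in flags)
print(f"significant cells (all on the BRAF slice): {n_sig}")

design = tc.project(space, "B", "BRAF")
print(f"fixing B=BRAF -> design type: {design.design_type.value}")
print(f"subgroups (tumour types): {tc.subgroups(design)}")
# 8 active cells = 2 biomarkers x 1 treatment x 4 tumour types; the 4
# significant cells are the shaded BRAF slice; the basket's subgroups are
# exactly the four melanoma subtypes sharing the targeted mutation.

for d in tc.enumerate_embedded_designs(space):
    fixed = ", ".join(f"{k}={v}" for k, v in d.fixed.items())
    print(f"  embedded design at {fixed}: {d.design_type.value}")
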