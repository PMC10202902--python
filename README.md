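# trialcube

Geometric design spaces for master-protocol clinical trials.

Precision-oncology trials no longer test one drug in one disease: a master
protocol evaluates multiple treatments across multiple biomarker-defined
sub-populations and tumour types under one infrastructure.  `trialcube`
represents such a protocol's design space as a hypercube manifold over
**nominal axes** — B (biomarkers, e.g. DNA driver mutations), T (treatments,
optionally with a control arm T0) and C (disease classifiers, e.g. tumour
types) — whose active cells are the (mutation, drug, tumour-type)
combinations the protocol actually studies.  On this object the familiar
trial designs are *projections*: fixing B = b and projecting onto the (T, C)
plane yields a **basket** trial (subgroups = tumour types sharing the
mutation); fixing C = c and projecting onto the (B, T) plane yields
**enrichment**, **umbrella** or **matrix** designs (subgroups = mutations).
Adaptive protocol amendments — dropping a cohort, pooling slow recruiters
into an "All others" group, opening a new tumour type, restricting a
combination arm to one cohort — become structured edits of the dimension
sets, with a diff operation between protocol versions.

The package is a library first (`import trialcube`), with narrative scripts
in `examples/`, a thin `trialcube` CLI, headless SVG/PNG rendering of the
3-cube lattice and its 2-D projections, and an elementary hypersurface
toolkit (n-cube face lattices, stereographic and sphere↔cube maps) behind
the geometry.  It intends to support design *representation, comparison and
visualisation* for trialists and methodologists; it computes no statistics
(significance flags are inputs, not outputs).

## Worked example

The packaged `melanoma_association` fixture transcribes a mutation
association study across four primary-melanoma subtypes as a 3-cube design
space in which the BRAF slice is flagged `significant`:

```python
import trialcube as tc

space = tc.load_fixture("melanoma_association")
design = tc.project(space, "B", "BRAF")
print(design.design_type.value)   # basket
print(tc.subgroups(design))       # ['CSD', 'Non-CSD', 'Mucosal', 'Acral']
```

Running `python examples/melanoma_basket.py` prints:

```
dimension: 3, active cells: 8
significant cells (all on the BRAF slice): 4
fixing B=BRAF -> design type: basket
subgroups (tumour types): ['CSD', 'Non-CSD', 'Mucosal', 'Acral']
```

The 8 active cells are the full 2 × 1 × 4 product (two mutations, one
treatment, four tumour types); the 4 significant cells are the shaded BRAF
slice; the basket's subgroups are exactly the four melanoma subtypes that
share the targeted mutation.  `examples/vemurafenib_adaptation.py` diffs
the two packaged versions of the Vemurafenib basket trial in BRAF V600
non-melanoma cancers and prints the amendments the trial actually made —
2 classifiers added (ECD/LCH, anaplastic thyroid), 2 dropped (ovarian,
multiple myeloma), breast merged into "All others", and a
Vemurafenib+Cetuximab arm restricted to the colorectal cohort — then
replays the diff to reproduce the adapted design exactly.

## Command line

```sh
trialcube fixtures --list
trialcube fixtures --dump melanoma_association > mel.design.json
trialcube validate mel.design.json            # exit 0 / 2 (invalid) / 3 (schema)
trialcube classify mel.design.json --axis B --element BRAF
trialcube diff before.design.json after.design.json
trialcube render mel.design.json --out mel.svg
```

Design documents are strict JSON (`.design.json`); the schema is published
in `docs/design-document.schema.json` and writes are byte-deterministic.
See `docs/methods.md` for the model, the classification rules and the
package's design choices.

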