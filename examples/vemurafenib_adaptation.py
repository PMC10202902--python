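"""Diff two versions of an adaptive basket trial protocol.

The Vemurafenib basket trial in BRAF V600-mutated non-melanoma cancers was
amended mid-trial: two cohorts dropped for insufficient accrual, breast
folded into the "All others" cohort, two new disease classifiers opened,
and a Cetuximab combination arm introduced for the colorectal cohort only
(Vemurafenib resistance).  The structured diff recovers every change.
"""

import trialcube as tc

before = tc.load_fixture("vemurafenib_initial")
after = tc.load_fixture("vemurafenib_adapted")

d = tc.diff(before, after)
print("added:     ", {k: sorted(v) for k, v in sorted(d.added.items())})
print("dropped:   ", {k: sorted(v) for k, v in sorted(d.dropped.items())})
print("merged:    ", {k: sorted(v) for k, v in sorted(d.merged.items())})
print("restricted:", sorted((t, sorted(c)) for t, c in d.restrictions))
print("deactivated:", sorted(str(c) for c in d.deactivated))
# 2 classifiers added, 2 dropped, 1 cohort merge, 1 restricted combination
# arm; the deactivated cell is Vemurafenib monotherapy withdrawn from
# colorectal.

rebuilt = d.apply(before)
print("replaying the diff reproduces the adapted design:", rebuilt == after)

colorectal = tc.project(after, "C", "Colorectal")
t_axis = colorectal.residual_axis_by_role("treatment")
print("treatments available to colorectal patients:",
      colorectal.active_elements(t_axis))
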