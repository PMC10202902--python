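"""Render the fixture manifolds, their basket projections and the
hypersurface gallery as SVG files under ./figures/.

The 3D lattice view shades significant cells; the 2D projection view is the
grid a trialist reads a basket design from (subgroup columns x treatment
rows, restricted arms only in their admissible columns).
"""

from pathlib import Path

import trialcube as tc

out = Path("figures")
out.mkdir(exist_ok=True)

for name in tc.FIXTURE_NAMES:
    space = tc.load_fixture(name)
    p = tc.render_master_manifold(space, out / f"{name}.svg", title=name)
    print("wrote", p)

mel = tc.load_fixture("melanoma_association")
print("wrote", tc.render_projection(tc.project(mel, "B", "BRAF"),
                                    out / "melanoma_basket.svg"))

post = tc.load_fixture("vemurafenib_adapted")
print("wrote", tc.render_projection(tc.project(post, "B", "BRAF"),
                                    out / "vemurafenib_basket_adapted.svg"))

for p in tc.render_hypersurface_gallery(out):
    print("wrote", p)
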