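"""Hypercube combinatorics and sphere<->cube maps.

The design-space picture rests on hypersurfaces: the n-cube surface bounding
an (n+1)-dimensional solid, and stereographic projection between spheres and
flat planes.  This script enumerates faces and demonstrates the round-trip
accuracy of the projection maps.
"""

import numpy as np

import trialcube as tc
from trialcube.hypergeometry import NCube, boundary

for n in range(5):
    counts = [len(tc.cube_k_faces(n, k)) for k in range(n + 1)]
    print(f"{n}-cube k-face counts: {counts}  (facets: {counts[-2] if n else '-'})")
# e.g. the 3-cube has 8 vertices, 12 edges, 6 faces; the tesseract's
# boundary consists of 8 three-dimensional cells:
print("tesseract boundary cells:", len(boundary(NCube(4))))

rng = np.random.default_rng(0)
x = rng.normal(size=3)
x /= np.linalg.norm(x)
y = tc.stereographic(x)
back = tc.inverse_stereographic(y)
print(f"point on sphere: {np.round(x, 4)}")
print(f"stereographic image in the plane: {np.round(y, 4)}")
print(f"round-trip error: {np.max(np.abs(back - x)):.2e}")

q = tc.sphere_to_cube(x)
print(f"radial image on the cube boundary: {np.round(q, 4)} "
      f"(max-norm {np.max(np.abs(q)):.3f})")
print(f"cube->sphere round-trip error: "
      f"{np.max(np.abs(tc.cube_to_sphere(q) - x)):.2e}")
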