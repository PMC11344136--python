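"""Place equivolumetric intracortical surfaces for different local foldings.

Builds the interior volume-fraction grid used for 12-surface depth sampling
and shows where the surfaces sit for a gyral crown (outer area > inner area),
a sulcal fundus (inner > outer), and flat cortex.
"""

import numpy as np

from profilespace import depth_grid, equivolumetric_depths

alphas = depth_grid(12)
print("volume fractions (12 interior surfaces):")
print(" ", np.round(alphas, 4))

cases = {
    "gyral crown  (a_out=3, a_in=1)": (3.0, 1.0),
    "sulcal fundus (a_out=1, a_in=3)": (1.0, 3.0),
    "flat cortex  (a_out=2, a_in=2)": (2.0, 2.0),
}
for label, (a_out, a_in) in cases.items():
    rho = equivolumetric_depths(a_out, a_in, n_surfaces=12)[0]
    print(f"\n{label}: depths from the white-matter boundary")
    print(" ", np.round(rho, 4))

# The depths deviate from the even grid exactly where folding changes the
# area profile: in a gyral crown equal volume slabs are thinner near the
# (larger) pial surface, so sampling depths shift pially; in a fundus the
# reverse.  For flat cortex the rule reduces to rho = alpha.
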