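"""Plane maps of the sigma_zz shielding density for a model aromatic ring.

Scans the shielding density of the +x proton in the molecular plane and
1 a0 above it.  Positive values shield the nucleus, negative deshield;
the sign at any point follows from the direction of the current flux
relative to the nucleus, not from its tropicity.
"""

import numpy as np

import sigmadens as sd
from sigmadens.models import benzene_like_composite
from sigmadens.shielding import shielding_density

provider = benzene_like_composite()
mol = provider.molecule
proton = mol.coords[6]

for offset in (0.0, 1.0):
    spec = sd.PlaneSpec(extent_u=(-8, 8), extent_v=(-8, 8), spacing=0.25,
                        offset=offset, clamp=(-0.2, 0.2))
    scan = sd.plane_scan(
        lambda pts: shielding_density(provider, proton, "zz", pts).values,
        spec,
    )
    name = f"plane_h_zz_offset{offset:.0f}.csv"
    scan.to_csv(name)
    vals = scan.values
    print(f"offset {offset:.1f} a0 -> {name}: lattice {vals.shape}, "
          f"raw range [{vals.min():.3e}, {vals.max():.3e}], "
          f"{np.mean(vals > 0)*100:.0f}% shielding area")

# In-plane probes along +x: deshielding where the perimeter current passes
# inside the proton, shielding outside it.
for x in (4.35, 6.5):
    v = shielding_density(provider, proton, "zz", [[x, 0.0, 0.0]]).values[0]
    print(f"probe ({x:4.2f}, 0, 0): {v:+.3e} "
          f"({'shielding' if v > 0 else 'deshielding'})")
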