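"""Validate the frequency-domain diffusion solver against closed forms.

Solves the FD photon diffusion equation in a homogeneous block (mua 0.02,
musp 1.0 /mm) at 200 MHz and compares fluence amplitude and phase along a
radial line with the infinite-medium Green's function.
"""

import numpy as np

from fdhddot import SlabSolver, greens_homogeneous
from fdhddot.phantom import TISSUES, HeadPhantom, TissueProperties, default_property_table

h = 0.8
table = default_property_table()
for wl in (690, 850):
    table[("gray", wl)] = TissueProperties("gray", 0.02, 1.0, wl)
labels = np.full((125, 125, 88), TISSUES.index("gray"), dtype=np.uint8)
block = HeadPhantom(voxel_size=h, labels=labels, properties=table)

frequency = 200.0
solver = SlabSolver(block, 850, frequency)
kernel = solver._kernel(44)  # point source mid-depth

props = table[("gray", 850)]
print(" r (mm)   |solver|      |greens|     amp err   phase err (deg)")
for r_vox in (13, 25, 38):
    r = r_vox * h
    val = kernel[r_vox, 0, 44]
    ref = greens_homogeneous(props, r, frequency)
    print(f"  {r:5.1f}  {abs(val):.4e}  {abs(ref):.4e}  "
          f"{abs(abs(val)/abs(ref)-1):7.2%}   "
          f"{np.degrees(abs(np.angle(val)-np.angle(ref))):6.3f}")
# Agreement within a few percent / fractions of a degree shows the discrete
# operator reproduces the photon-density wave's attenuation and phase lag.
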