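"""Simulate one point-spread function and its image-quality metrics.

Places a +3.8 uM HbO2 / -1.8 uM HbR point perturbation at three depths,
reconstructs it noise-free through the NN3 system at 0, 400, and 800 MHz,
and prints localization error (LE), full width at half maximum (FWHM), and
full volume at half maximum (FVHM).
"""

import numpy as np

from fdhddot import build_inverse_operator, build_layered_slab, simulate_psf
from fdhddot.phantom import enumerate_channels, place_checkerboard_array
from fdhddot.sensitivity import assemble_rytov_jacobian
from fdhddot.sweep import WAVELENGTHS, _solve_optode_fields, compute_roi

phantom = build_layered_slab()
array = place_checkerboard_array(phantom)
channels = enumerate_channels(array, max_nn=3)
roi = compute_roi(phantom, array, channels)

center = np.array(phantom.grid_shape) // 2
seeds = [np.ravel_multi_index((center[0], center[1], k), phantom.grid_shape)
         for k in (5, 8, 10)]  # 11, 17, 21 mm below the surface

print("depth(mm)  f(MHz)    LE(mm)   FWHM(mm)   FVHM(mm^3)")
for f in (0.0, 400.0, 800.0):
    jacs, ops = {}, {}
    for wl in WAVELENGTHS:
        src, det = _solve_optode_fields(phantom, array, wl, f)
        jacs[wl] = assemble_rytov_jacobian(src, det, phantom, channels, f, wl, roi)
        ops[wl] = build_inverse_operator(jacs[wl].stacked())
    for seed in seeds:
        m = simulate_psf(seed, jacs, ops, phantom)
        fw = "   --  " if m.fwhm_mm is None else f"{m.fwhm_mm:7.2f}"
        fv = "    --  " if m.fvhm_mm3 is None else f"{m.fvhm_mm3:8.1f}"
        print(f"  {m.depth_mm:5.1f}   {f:6.0f}   {m.le_mm:7.2f}  {fw}   {fv}")
# LE grows with depth and shrinks with modulation frequency; resolution
# (FWHM/FVHM) changes much less — localization, not width, is where the
# phase information pays off.
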