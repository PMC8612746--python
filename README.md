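# fdhddot

Simulation study of how source **modulation frequency** shapes image quality
in **frequency-domain high-density diffuse optical tomography (FD-HD-DOT)**
of human brain function.

High-density DOT reconstructs cortical hemodynamics (ΔHbO₂, ΔHbR) from
overlapping near-infrared source–detector channels on the scalp.
Continuous-wave (CW) systems measure only intensity attenuation;
frequency-domain systems modulate the source at up to ~1 GHz and also
measure the phase delay of the photon-density wave, which carries deeper
spatial information. This package answers, at desk scale: *as modulation
frequency rises from 0 to 1000 MHz, how do localization error, resolution,
and the depth of reliable imaging change — with and without realistic
measurement noise?* It is aimed at people designing FD-DOT instruments and
reconstruction pipelines who want a transparent, fully testable model chain
instead of a subject-specific FEM stack.

## The model chain

1. **Phantom** — a five-layer slab (scalp / skull / CSF / gray / white) on a
   regular voxel grid with literature optical properties at 690 and 850 nm;
   a checkerboard optode array whose 13 mm pitch reproduces the four
   nearest-neighbor separations ≈ 13, 29, 39, 47 mm; cumulative NN3/NN4
   channel sets emulating moderate/strong dynamic range.
2. **Forward model** — frequency-domain photon diffusion
   `∇·(D∇Φ) − vμₐΦ + iωΦ = −vQ`, `D = v/[3(μₐ+μs′)]`, finite-volume
   discretization, Robin boundaries, validated against infinite-medium and
   semi-infinite Green's functions.
3. **Sensitivity** — Rytov differential data `δΦ = ln(Φ/Φ₀) = ln(I/I₀) +
   i(θ−θ₀)`; adjoint-assembled Jacobian `[∂ln I; ∂θ] = [Re(A); Im(A)] ∂μₐ`,
   verified against brute-force perturbation.
4. **Inversion** — Tikhonov-regularized pseudo-inverse with spatially
   variant scaling, `A# = L⁻¹(ÂᵀÂ + λ₁I)⁻¹Âᵀ`, `Â = AL⁻¹`, evaluated in
   measurement space; λ₁ = 0.01 and λ₂ = 0.1 (relative), one operator per
   wavelength.
5. **Noise** — empirical model `N(r,f) = (a·e^{br} + c·e^{dr})·10^{g(f−140)}`
   per wavelength and datum type (% intensity, degrees phase), coupled
   intensity/phase draws.
6. **Spectroscopy** — ΔHb ↔ Δμₐ through the 2×2 extinction matrix at
   690/850 nm (point perturbation +3.8 μM HbO₂, −1.8 μM HbR).
7. **Metrics** — point-spread functions thresholded at half maximum;
   localization error (LE, centroid distance), FWHM (longest pairwise
   distance), FVHM (volume), success rate vs depth with the 8 mm LE cutoff,
   SR50 reliable-imaging depth, full-brain-tissue volume and its FD/CW
   ratio, paired Wilcoxon FD-vs-CW tests.

See `docs/methods.md` for assumptions, numerical choices, and limitations.

## Worked example

`examples/05_single_psf.py` reconstructs a +3.8/−1.8 μM point perturbation
at three depths through the NN3 system, noise-free:

```
depth(mm)  f(MHz)    LE(mm)   FWHM(mm)   FVHM(mm^3)
   11.0        0      2.08    16.61     1536.0
   17.0        0      7.44    16.97     1552.0
   21.0        0     11.10     --         --
   11.0      400      1.78    16.25     1328.0
   17.0      400      5.98    18.33     2056.0
   21.0      400      8.82     --         --
   11.0      800      1.63    14.56     1104.0
   17.0      800      5.12    18.33     1912.0
   21.0      800      8.51     --         --
```

Localization error grows with depth and shrinks as modulation frequency
rises (2.08 → 1.63 mm at 11 mm depth; 7.44 → 5.12 mm at 17 mm), while the
PSF width changes much less — the phase measurement sharpens *where* the
activation is placed, not how wide it appears. Dashes mark recoveries
beyond the 8 mm success cutoff, where width metrics are not recorded.

The other examples each exercise one capability: phantom/array geometry
(`01`), solver-vs-Green's-function validation (`02`), the depth-steepening
of phase sensitivity with frequency (`03`), the noise model (`04`), and a
reduced frequency sweep with SR50 depths and paired statistics (`06`).

A thin CLI wraps the same library:

```bash
fdhddot phantom --outdir out/          # phantom NIfTI + optode/channel TSV
fdhddot sweep --seed 1 --outdir out/   # full sweep -> CSV/NIfTI/plots
```

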