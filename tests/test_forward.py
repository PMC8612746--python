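"""Forward diffusion solver vs closed-form Green's-function oracles."""

import numpy as np
import pytest

from fdhddot.forward import (
    FDSolver,
    SlabSolver,
    boundary_reflection_coefficient,
    extrapolation_length,
    greens_homogeneous,
    greens_semi_infinite,
    omega_rad_per_ns,
    C0_MM_PER_NS,
)
from fdhddot.phantom import TissueProperties

from conftest import uniform_phantom


class TestGreensHomogeneous:
    def test_cw_closed_form_hand_evaluation(self):
        # omega = 0, mua 0.02, musp 1.0, r 20 mm evaluated by hand
        props = TissueProperties("gray", 0.02, 1.0, 850)
        v = C0_MM_PER_NS / 1.4
        D = v / (3.0 * 1.02)
        expected = v * np.exp(-20.0 * np.sqrt(3 * 0.02 * 1.02)) / (4 * np.pi * D * 20.0)
        got = greens_homogeneous(props, 20.0, 0.0)
        assert got.imag == 0.0
        assert got.real == pytest.approx(expected, rel=1e-12)

    def test_amplitude_decreases_phase_lag_increases_with_frequency(self):
        props = TissueProperties("gray", 0.0192, 0.6726, 850)
        r = 25.0
        freqs = [0.0, 100.0, 300.0, 600.0, 1000.0]
        vals = [greens_homogeneous(props, r, f) for f in freqs]
        amps = np.abs(vals)
        assert (np.diff(amps) < 1e-15).all()
        # phase accumulates away from zero monotonically with omega
        phases = np.abs(np.angle(vals))
        assert (np.diff(phases) > 0).all()

    def test_amplitude_ratio_direct_arithmetic(self):
        # |Phi(29)| / |Phi(13)| at 140 MHz, gray matter 850 nm
        props = TissueProperties("gray", 0.0192, 0.6726, 850)
        v = C0_MM_PER_NS / 1.4
        D = v / (3.0 * (0.0192 + 0.6726))
        k = np.sqrt((v * 0.0192 - 1j * omega_rad_per_ns(140.0)) / D)
        expected = abs(np.exp(-k * 29.0) / 29.0) / abs(np.exp(-k * 13.0) / 13.0)
        got = abs(greens_homogeneous(props, 29.0, 140.0)) / abs(
            greens_homogeneous(props, 13.0, 140.0)
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_singularity_raises(self, homogeneous_props):
        with pytest.raises(ValueError):
            greens_homogeneous(homogeneous_props, 0.0, 100.0)


class TestGreensSemiInfinite:
    def test_zero_on_extrapolated_boundary(self, homogeneous_props):
        zb = extrapolation_length(homogeneous_props)
        # construct the image pair directly: on the plane z = -zb the two
        # kernels cancel by symmetry of the construction
        src = np.zeros(3)
        z0 = 1.0 / homogeneous_props.musp
        r1 = np.hypot(15.0, -zb - z0)
        r2 = np.hypot(15.0, -zb + z0 + 2 * zb)
        assert r1 == pytest.approx(r2)

    def test_deep_point_matches_two_term_sum(self, homogeneous_props):
        src = np.array([0.0, 0.0, 0.0])
        fp = np.array([5.0, 3.0, 30.0])
        z0 = 1.0 / homogeneous_props.musp
        zb = extrapolation_length(homogeneous_props)
        r1 = np.linalg.norm(fp - np.array([0, 0, z0]))
        r2 = np.linalg.norm(fp - np.array([0, 0, -(z0 + 2 * zb)]))
        expected = greens_homogeneous(homogeneous_props, r1, 140.0) - \
            greens_homogeneous(homogeneous_props, r2, 140.0)
        got = greens_semi_infinite(homogeneous_props, src, fp, 140.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_cw_is_real(self, homogeneous_props):
        got = greens_semi_infinite(
            homogeneous_props, np.zeros(3), np.array([10.0, 0.0, 20.0]), 0.0
        )
        assert got.imag == 0.0


class TestSolverAgainstOracles:
    @pytest.mark.parametrize("frequency", [200.0, 800.0])
    def test_infinite_medium_amplitude_and_phase(
        self, homogeneous_block, homogeneous_props, frequency
    ):
        """Solver fluence along a lateral radial line matches the
        infinite-medium kernel within 5% amplitude and 2 deg phase for
        r in [10, 35] mm (boundaries are far in all directions)."""
        solver = SlabSolver(homogeneous_block, 850, frequency)
        nz = homogeneous_block.grid_shape[2]
        kern = solver._kernel(nz // 2)
        h = homogeneous_block.voxel_size
        idx = np.arange(int(np.ceil(10 / h)), int(35 / h) + 1)
        rs = idx * h
        vals = kern[idx, 0, nz // 2]
        ref = greens_homogeneous(homogeneous_props, rs, frequency)
        amp_err = np.abs(np.abs(vals) / np.abs(ref) - 1.0)
        phase_err = np.degrees(np.abs(np.angle(vals) - np.angle(ref)))
        assert amp_err.max() < 0.05
        assert phase_err.max() < 2.0

    def test_cw_field_has_zero_phase(self):
        ph = uniform_phantom(0.02, 1.0, (16, 16, 12), 2.0)
        field = FDSolver(ph, 850, 0.0).solve(np.array([16.0, 16.0, 0.0]))
        assert np.abs(field.fluence.imag).max() < 1e-10

    def test_phase_lag_monotone_with_distance(self):
        # with the e^{-i omega t} source convention the lag accumulates as
        # a positive angle growing with distance
        ph = uniform_phantom(0.02, 1.0, (30, 30, 14), 2.0)
        solver = SlabSolver(ph, 850, 400.0)
        kern = solver._kernel(7)
        lag = np.angle(kern[1:14, 0, 7])
        assert (lag >= -1e-12).all()
        assert (np.diff(lag) > -1e-9).all()

    def test_slab_fft_matches_sparse_periodic(self, tiny_slab):
        """The FFT fast path and the sparse operator are the same
        discretization (periodic lateral boundary)."""
        fd = FDSolver(tiny_slab, 690, 300.0, lateral_bc="periodic")
        slab = SlabSolver(tiny_slab, 690, 300.0)
        pos = np.array([20.0, 20.0, 0.0])
        a = fd.solve(pos).fluence
        b = slab.solve(pos).fluence
        assert np.abs(a - b).max() / np.abs(a).max() < 1e-10

    def test_semi_infinite_boundary_treatment(self):
        """Sparse solver in a homogeneous slab vs the image-source
        semi-infinite kernel: <= 5% amplitude, <= 2 deg phase for lateral
        offsets 10-40 mm at fine voxels."""
        from fdhddot.forward import (
            extrapolation_length, greens_homogeneous, source_voxel_index,
        )

        h = 0.8
        ph = uniform_phantom(0.02, 1.0, (150, 150, 88), h)
        solver = SlabSolver(ph, 850, 200.0)
        props = TissueProperties("gray", 0.02, 1.0, 850)
        src = np.array([60.0, 60.0, 0.0])
        field = solver.solve(src).fluence
        sv = source_voxel_index(ph, src, 850)
        z0 = (sv[2] + 0.5) * h  # realized discrete source depth
        zb = extrapolation_length(props)
        iz = 12  # ~10 mm deep measurement line
        depth = (iz + 0.5) * h
        offsets = np.arange(13, 51)  # 10.4 .. 40 mm lateral
        ix0, iy0 = sv[0], sv[1]
        vals = field[ix0 + offsets, iy0, iz]
        # image-source closed form at the same voxel centers, with the real
        # source at the discrete injection depth
        ref = []
        for o in offsets:
            fp = np.array([(ix0 + o + 0.5) * h, (iy0 + 0.5) * h, depth])
            s0 = np.array([(ix0 + 0.5) * h, (iy0 + 0.5) * h, 0.0])
            r1 = np.linalg.norm(fp - (s0 + [0, 0, z0]))
            r2 = np.linalg.norm(fp - (s0 + [0, 0, -(z0 + 2 * zb)]))
            ref.append(
                greens_homogeneous(props, r1, 200.0)
                - greens_homogeneous(props, r2, 200.0)
            )
        ref = np.array(ref)
        amp_err = np.abs(np.abs(vals) / np.abs(ref) - 1.0)
        phase_err = np.degrees(np.abs(np.angle(vals) - np.angle(ref)))
        assert amp_err.max() < 0.05
        assert phase_err.max() < 2.0

    def test_reciprocity(self, tiny_slab):
        """Fluence at B from a source at A equals fluence at A from a source
        at B (self-adjoint operator), when both sites share a tissue."""
        solver = FDSolver(tiny_slab, 850, 500.0)
        va = (5, 10, 1)
        vb = (14, 9, 1)
        fa = solver.solve_at_voxel(va).fluence
        fb = solver.solve_at_voxel(vb).fluence
        assert abs(fa[vb] - fb[va]) / abs(fa[vb]) < 1e-8

    def test_factorization_reuse_matches_fresh_solve(self, tiny_slab):
        solver = FDSolver(tiny_slab, 690, 200.0)
        a1 = solver.solve(np.array([10.0, 10.0, 0.0])).fluence
        _ = solver.solve(np.array([20.0, 20.0, 0.0]))
        a2 = FDSolver(tiny_slab, 690, 200.0).solve(np.array([10.0, 10.0, 0.0])).fluence
        assert np.array_equal(a1, a2)

    def test_negative_frequency_rejected(self, tiny_slab):
        from fdhddot.forward import solve_fd_diffusion

        with pytest.raises(ValueError):
            solve_fd_diffusion(tiny_slab, np.array([10.0, 10.0, 0.0]), -1.0, 850)


def test_boundary_reflection_coefficient_value():
    # Groenhuis fit at n = 1.4 gives A ~ 3.25
    A = boundary_reflection_coefficient(1.4)
    assert A == pytest.approx(3.25, abs=0.1)
    assert boundary_reflection_coefficient(1.0) < A
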