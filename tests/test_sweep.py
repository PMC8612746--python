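"""Sweep orchestration: determinism, pairing statistics, reporting."""

import numpy as np
import pandas as pd
import pytest

from fdhddot.config import SweepConfig, load_config
from fdhddot.metrics import simulate_psf
from fdhddot.sweep import compare_to_cw, run_sweep


@pytest.fixture(scope="module")
def mini_config():
    """Two-frequency, single-NN sweep on the default phantom (fast)."""
    return SweepConfig(
        frequencies=(0.0, 400.0),
        nn_sets=(3,),
        noise_arms=(False, True),
        realizations=2,
        seed_mode="column",
    )


@pytest.fixture(scope="module")
def mini_summary(mini_config):
    return run_sweep(mini_config, master_seed=7)


class TestRunSweep:
    def test_cw_only_sweep_has_unit_ratios(self):
        cfg = SweepConfig(
            frequencies=(0.0,), nn_sets=(3,), noise_arms=(False,),
            seed_mode="column",
        )
        s = run_sweep(cfg, master_seed=1)
        assert set(s.records["frequency"]) == {0.0}
        assert np.allclose(s.fbt_table["fbt_ratio"].dropna(), 1.0)

    def test_reproducibility_under_master_seed(self, mini_config, mini_summary):
        again = run_sweep(mini_config, master_seed=7)
        pd.testing.assert_frame_equal(mini_summary.records, again.records)
        pd.testing.assert_frame_equal(mini_summary.sr_table, again.sr_table)

    def test_different_master_seed_changes_noise_arm_only(self, mini_config, mini_summary):
        other = run_sweep(mini_config, master_seed=8)
        nf = mini_summary.records[~mini_summary.records["noise_on"]]
        nf2 = other.records[~other.records["noise_on"]]
        pd.testing.assert_frame_equal(
            nf.reset_index(drop=True), nf2.reset_index(drop=True)
        )
        noisy = mini_summary.records[mini_summary.records["noise_on"]]["le_mm"]
        noisy2 = other.records[other.records["noise_on"]]["le_mm"]
        assert not np.allclose(
            noisy.fillna(-1).to_numpy(), noisy2.fillna(-1).to_numpy()
        )

    def test_record_layout_complete(self, mini_config, mini_summary):
        rec = mini_summary.records
        n_seeds = rec["seed_voxel"].nunique()
        # per seed: 2 frequencies x (1 noise-free + 2 noise realizations)
        assert len(rec) == n_seeds * 2 * 3
        assert set(rec["noise_on"]) == {False, True}

    def test_noise_free_matches_single_seed_chain(self, mini_config, mini_summary):
        """The batched sweep reproduces the reference single-PSF simulation
        chain exactly (noise-free arm)."""
        from fdhddot.inversion import build_inverse_operator
        from fdhddot.phantom import (
            build_layered_slab, enumerate_channels, place_checkerboard_array,
        )
        from fdhddot.sensitivity import assemble_rytov_jacobian
        from fdhddot.sweep import WAVELENGTHS, _solve_optode_fields, compute_roi

        cfg = mini_config
        phantom = build_layered_slab()
        array = place_checkerboard_array(phantom)
        channels = enumerate_channels(array, 3)
        roi = mini_summary.roi_mask
        f = 400.0
        jacs, ops = {}, {}
        for wl in WAVELENGTHS:
            src, det = _solve_optode_fields(phantom, array, wl, f)
            jacs[wl] = assemble_rytov_jacobian(
                src, det, phantom, channels, f, wl, roi
            )
            ops[wl] = build_inverse_operator(jacs[wl].stacked(), cfg.regularization())
        rec = mini_summary.records
        sel = rec[(rec["frequency"] == f) & (~rec["noise_on"])].iloc[5]
        ref = simulate_psf(int(sel["seed_voxel"]), jacs, ops, phantom)
        assert ref.le_mm == pytest.approx(sel["le_mm"], rel=1e-9)
        assert ref.depth_mm == pytest.approx(sel["depth_mm"])
        if ref.success:
            assert ref.fwhm_mm == pytest.approx(sel["fwhm_mm"], rel=1e-9)

    def test_noise_arm_matches_single_seed_chain(self, mini_config, mini_summary):
        from fdhddot.inversion import build_inverse_operator
        from fdhddot.phantom import (
            build_layered_slab, enumerate_channels, place_checkerboard_array,
        )
        from fdhddot.sensitivity import assemble_rytov_jacobian
        from fdhddot.sweep import WAVELENGTHS, _solve_optode_fields

        phantom = build_layered_slab()
        array = place_checkerboard_array(phantom)
        channels = enumerate_channels(array, 3)
        f = 400.0
        jacs, ops = {}, {}
        for wl in WAVELENGTHS:
            src, det = _solve_optode_fields(phantom, array, wl, f)
            jacs[wl] = assemble_rytov_jacobian(
                src, det, phantom, channels, f, wl, mini_summary.roi_mask
            )
            ops[wl] = build_inverse_operator(
                jacs[wl].stacked(), mini_config.regularization()
            )
        rec = mini_summary.records
        sel = rec[
            (rec["frequency"] == f) & rec["noise_on"] & (rec["realization"] == 1)
        ].iloc[3]
        ref = simulate_psf(
            int(sel["seed_voxel"]), jacs, ops, phantom,
            noise_on=True, master_seed=7, realization=1,
        )
        assert ref.le_mm == pytest.approx(sel["le_mm"], rel=1e-9)

    def test_sr50_noise_not_deeper_than_noise_free(self, mini_summary):
        sr = mini_summary.sr_table
        for f in (0.0, 400.0):
            free = sr[(sr["frequency"] == f) & (~sr["noise_on"])]["sr50_depth_mm"]
            noisy = sr[(sr["frequency"] == f) & (sr["noise_on"])]["sr50_depth_mm"]
            assert float(noisy.iloc[0]) <= float(free.iloc[0]) + 1e-9


class TestCompareToCW:
    @staticmethod
    def _paired(deltas, base=None):
        rng = np.random.default_rng(0)
        n = len(deltas)
        base = rng.uniform(1, 10, n) if base is None else np.asarray(base)
        cw = pd.DataFrame(
            {"seed_voxel": np.arange(n), "realization": 0, "le_mm": base}
        )
        fd = pd.DataFrame(
            {"seed_voxel": np.arange(n), "realization": 0, "le_mm": base + deltas}
        )
        return fd, cw

    def test_identical_samples_flagged_null(self):
        fd, cw = self._paired(np.zeros(12))
        stat, p = compare_to_cw(fd, cw)
        assert p == 1.0

    def test_uniform_improvement_gives_minimal_p(self):
        fd, cw = self._paired(-np.ones(12))
        stat, p = compare_to_cw(fd, cw)
        from scipy import stats as ss

        ref = ss.wilcoxon(-np.ones(12), alternative="two-sided")
        assert p == pytest.approx(ref.pvalue)
        assert stat == pytest.approx(ref.statistic)

    def test_matches_sign_flip_permutation_oracle(self):
        """Wilcoxon p agrees with an exhaustive sign-flip permutation of the
        signed-rank statistic on small random paired samples."""
        rng = np.random.default_rng(5)
        n = 10
        diffs = rng.normal(0.8, 1.0, n)
        fd, cw = self._paired(diffs)
        _, p = compare_to_cw(fd, cw)
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
        w_obs = ranks[diffs > 0].sum()
        total = ranks.sum()
        count = 0
        n_perm = 2**n
        for mask in range(n_perm):
            bits = np.array([(mask >> k) & 1 for k in range(n)], dtype=bool)
            w = ranks[bits].sum()
            if abs(w - total / 2) >= abs(w_obs - total / 2) - 1e-12:
                count += 1
        assert p == pytest.approx(count / n_perm, abs=0.02)

    def test_unpaired_records_raise(self):
        fd, cw = self._paired(np.ones(5))
        with pytest.raises(ValueError):
            compare_to_cw(fd.iloc[:4], cw)


class TestReporting:
    def test_report_writes_tables_and_manifest(self, mini_summary, tmp_path):
        from fdhddot.report import write_report

        write_report(mini_summary, tmp_path)
        for name in (
            "records.csv", "sr50.csv", "fbt.csv", "depth_medians.csv",
            "wilcoxon.csv", "manifest.json", "roi_mask.nii.gz",
        ):
            assert (tmp_path / name).exists(), name
        rec = pd.read_csv(tmp_path / "records.csv")
        assert len(rec) == len(mini_summary.records)

    def test_fbt_table_row_count(self, mini_summary):
        # cutoffs 1..8 x frequencies x (nn, noise) arms
        fbt = mini_summary.fbt_table
        assert len(fbt) == 8 * 2 * 2


def test_config_roundtrip_toml(tmp_path):
    text = """
[phantom]
voxel_size = 2.0
[sweep]
frequencies = [0.0, 300.0]
nn_sets = [3]
realizations = 2
[regularization]
lambda1_rel = 0.02
[noise]
noise_coupled = false
"""
    path = tmp_path / "run.toml"
    path.write_text(text)
    cfg = load_config(path)
    assert cfg.frequencies == (0.0, 300.0)
    assert cfg.nn_sets == (3,)
    assert cfg.lambda1_rel == 0.02
    assert cfg.noise_coupled is False
    assert cfg.pitch == 13.0  # untouched default
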