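"""Frequency-sweep orchestration: the full simulation experiment.

For every modulation frequency and wavelength the pipeline solves the
forward problem for all optodes, assembles the Rytov Jacobian over the
region of interest, builds the regularized inverse operator per channel
set, simulates point-spread functions for every seed voxel (noise-free and
with drawn noise realizations), computes image-quality metrics, and
aggregates success-rate curves, SR50 depths, brain-volume summaries and
paired FD-vs-CW statistics.  Everything is deterministic given the master
seed; seed voxels and frequencies are independent, and results are reduced
by keyed concatenation so they do not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import SweepConfig
from .forward import SlabSolver
from .inversion import build_inverse_operator
from .metrics import evaluate_psf, success_rate_curve, brain_volume_summary
from .noise import NoiseModelParams, derive_noise_seed, sample_noise
from .phantom import (
    HeadPhantom,
    MeasurementSet,
    OptodeArray,
    build_layered_slab,
    define_roi,
    enumerate_channels,
    place_checkerboard_array,
)
from .sensitivity import (
    Jacobian,
    assemble_rytov_jacobian,
    summed_intensity_sensitivity,
)
from .spectroscopy import ExtinctionMatrix, HbPerturbation, hb_to_mua

log = logging.getLogger("fdhddot.sweep")

WAVELENGTHS = (690, 850)


@dataclass
class SweepSummary:
    """All outputs of one frequency sweep."""

    records: pd.DataFrame  # one row per (seed, frequency, nn, arm, realization)
    sr_table: pd.DataFrame  # sr50 per (frequency, nn, noise)
    fbt_table: pd.DataFrame  # FBTV / FBT ratio per (frequency, nn, noise, cutoff)
    depth_medians: pd.DataFrame  # median metrics per depth bin
    wilcoxon_table: pd.DataFrame  # paired FD-vs-CW tests
    config: SweepConfig
    master_seed: int
    roi_mask: np.ndarray
    phantom: HeadPhantom
    array: OptodeArray


def _solve_optode_fields(
    phantom: HeadPhantom, array: OptodeArray, wavelength: int, frequency: float
):
    solver = SlabSolver(phantom, wavelength, frequency)
    src = {i: solver.solve(p) for i, p in enumerate(array.source_positions)}
    det = {i: solver.solve(p) for i, p in enumerate(array.detector_positions)}
    return src, det


def compute_roi(
    phantom: HeadPhantom,
    array: OptodeArray,
    channels: MeasurementSet,
    lateral_margin: float = 10.0,
    sensitivity_floor: float = 1e-5,
    wavelength: int = 850,
) -> np.ndarray:
    """Region of interest: optode footprint shrunk laterally, cut at depth
    by the summed continuous-wave intensity sensitivity."""
    prism = define_roi(phantom, array, None, lateral_margin, 0.0)
    src, det = _solve_optode_fields(phantom, array, wavelength, 0.0)
    jac = assemble_rytov_jacobian(
        src, det, phantom, channels, 0.0, wavelength, prism
    )
    sens = summed_intensity_sensitivity(jac, phantom.grid_shape)
    roi = define_roi(phantom, array, sens, lateral_margin, sensitivity_floor)
    log.info(
        "ROI reaches %.1f mm below the surface (sensitivity floor %g)",
        phantom.depth_map[roi].max(), sensitivity_floor,
    )
    return roi


def select_seed_voxels(
    phantom: HeadPhantom,
    array: OptodeArray,
    roi_mask: np.ndarray,
    mode: str = "patch",
    patch_size: int = 3,
    patch_spacing_vox: int = 2,
) -> np.ndarray:
    """Flat indices of the seed voxels whose point-spread functions are
    simulated: the full ROI, or one or more depth columns near the array
    center (desk-scale modes)."""
    if mode == "full":
        return np.flatnonzero(roi_mask.ravel())
    h = phantom.voxel_size
    all_pos = np.vstack([array.source_positions, array.detector_positions])
    cx, cy = all_pos[:, 0].mean(), all_pos[:, 1].mean()
    ix0 = int(np.clip(np.floor(cx / h), 0, phantom.grid_shape[0] - 1))
    iy0 = int(np.clip(np.floor(cy / h), 0, phantom.grid_shape[1] - 1))
    if mode == "column":
        offsets = [0]
    else:
        half = patch_size // 2
        offsets = [patch_spacing_vox * k for k in range(-half, half + 1)]
    cols = []
    for dx in offsets:
        for dy in offsets:
            col = np.zeros(phantom.grid_shape, dtype=bool)
            col[ix0 + dx, iy0 + dy, :] = True
            cols.append(np.flatnonzero((col & roi_mask).ravel()))
    return np.unique(np.concatenate(cols))


def _noise_vectors(
    channels4: MeasurementSet,
    seeds: np.ndarray,
    frequency: float,
    wavelength: int,
    master_seed: int,
    realizations: int,
    params: NoiseModelParams,
    coupled: bool,
    scale: float = 1.0,
):
    """Per-(seed voxel, realization) noise draws at the NN4 channel level.

    Returns (intensity, phase) arrays of shape (n_channels4, n_seeds *
    realizations); channel subsets share the same draws, so NN3 and NN4
    arms see identical noise on their common channels.
    """
    n_cols = len(seeds) * realizations
    intensity = np.empty((channels4.n_channels, n_cols))
    phase = None if frequency == 0.0 else np.empty_like(intensity)
    col = 0
    for vox in seeds:
        for r in range(realizations):
            seed = derive_noise_seed(master_seed, int(vox), frequency, wavelength, r)
            real = sample_noise(
                channels4, frequency, wavelength, seed, params, coupled, scale
            )
            intensity[:, col] = real.intensity
            if phase is not None:
                phase[:, col] = real.phase
            col += 1
    return intensity, phase


def run_sweep(config: SweepConfig, master_seed: int = 0) -> SweepSummary:
    """Run the full frequency sweep and aggregate every summary metric."""
    config.validate()
    phantom = build_layered_slab(
        config.layer_thicknesses,
        config.lateral_extent,
        config.depth_extent,
        config.voxel_size,
    )
    array = place_checkerboard_array(
        phantom, config.pitch, config.n_rows, config.n_cols
    )
    max_nn = max(config.nn_sets)
    channels = enumerate_channels(array, max_nn)
    log.info(
        "phantom %s, %d sources / %d detectors, %d NN%d channels",
        phantom.grid_shape, array.n_sources, array.n_detectors,
        channels.n_channels, max_nn,
    )
    roi = compute_roi(
        phantom, array, channels, config.lateral_margin, config.sensitivity_floor
    )
    seeds = select_seed_voxels(
        phantom, array, roi, config.seed_mode,
        config.patch_size, config.patch_spacing_vox,
    )
    log.info("ROI %d voxels, %d seed voxels", roi.sum(), len(seeds))

    extinction = ExtinctionMatrix(dict(config.extinction))
    perturbation = HbPerturbation(config.dHbO2_uM, config.dHbR_uM)
    dmua = dict(zip(WAVELENGTHS, hb_to_mua(perturbation, extinction)))
    noise_params = NoiseModelParams(dict(config.noise_coeffs))
    Einv = extinction.inverse
    reg = config.regularization()

    vox_idx = None
    positions = None
    depth_flat = phantom.depth_map.ravel()
    brain_flat = phantom.brain_mask.ravel()
    grid = phantom.grid_shape
    cx, cy, cz = phantom.voxel_centers_mm()

    arms = []  # (noise_on, realization) column layout per seed
    for noise_on in sorted(config.noise_arms):
        n_real = config.realizations if noise_on else 1
        arms.extend((noise_on, r) for r in range(n_real))

    records = []
    for frequency in config.frequencies:
        jac_by_wl: dict[int, Jacobian] = {}
        for wl in WAVELENGTHS:
            src, det = _solve_optode_fields(phantom, array, wl, frequency)
            jac_by_wl[wl] = assemble_rytov_jacobian(
                src, det, phantom, channels, frequency, wl, roi
            )
        if vox_idx is None:
            vox_idx = jac_by_wl[WAVELENGTHS[0]].voxel_indices
            ii, jj, kk = np.unravel_index(vox_idx, grid)
            positions = np.column_stack([cx[ii], cy[jj], cz[kk]])
        seed_cols = np.searchsorted(vox_idx, seeds)

        for nn in sorted(config.nn_sets):
            keep = channels.channels["nn"] <= nn
            ch_sub = channels.channels[keep]
            ms_sub = MeasurementSet(ch_sub, nn)
            hbo2_cols: dict[int, np.ndarray] = {}
            for wl in WAVELENGTHS:
                jac = (
                    jac_by_wl[wl]
                    if nn == max_nn
                    else jac_by_wl[wl].row_subset(keep, ch_sub)
                )
                A = jac.stacked()
                op = build_inverse_operator(
                    A, reg,
                    provenance={
                        "frequency": frequency, "wavelength": wl, "nn": nn,
                        "lambda1_rel": reg.lambda1_rel,
                        "lambda2_rel": reg.lambda2_rel,
                    },
                )
                # assemble the data matrix: one column per (seed, arm)
                y_clean = A[:, seed_cols] * dmua[wl]
                n_noise_real = sum(1 for a, _ in arms if a)
                Y = np.repeat(y_clean, len(arms), axis=1)
                if n_noise_real:
                    ni, nph = _noise_vectors(
                        channels, seeds, frequency, wl, master_seed,
                        n_noise_real, noise_params, config.noise_coupled,
                        config.noise_scale,
                    )
                    noise_rows = (
                        ni[keep] if nph is None else np.vstack([ni[keep], nph[keep]])
                    )
                    # columns: per seed, arms ordered noise-free first
                    noise_col = 0
                    for s in range(len(seeds)):
                        for a, (noise_on, _r) in enumerate(arms):
                            if noise_on:
                                Y[:, s * len(arms) + a] += noise_rows[:, noise_col]
                                noise_col += 1
                X = op.apply(Y)
                hbo2_cols[wl] = X
            hbo2 = Einv[0, 0] * hbo2_cols[690] + Einv[0, 1] * hbo2_cols[850]

            for s, vox in enumerate(seeds):
                true_pos = positions[seed_cols[s]]
                for a, (noise_on, r) in enumerate(arms):
                    le, w, v, success = evaluate_psf(
                        hbo2[:, s * len(arms) + a], positions, true_pos,
                        phantom.voxel_size,
                    )
                    records.append(
                        {
                            "seed_voxel": int(vox),
                            "x_mm": true_pos[0],
                            "y_mm": true_pos[1],
                            "z_mm": true_pos[2],
                            "depth_mm": depth_flat[vox],
                            "is_brain": bool(brain_flat[vox]),
                            "le_mm": np.nan if le is None else le,
                            "fwhm_mm": np.nan if w is None else w,
                            "fvhm_mm3": np.nan if v is None else v,
                            "success": success,
                            "frequency": float(frequency),
                            "nn_set": nn,
                            "noise_on": noise_on,
                            "realization": r,
                        }
                    )
        log.info("frequency %.0f MHz done (%d records)", frequency, len(records))

    rec_df = pd.DataFrame(records)
    sr_table = _sr50_table(rec_df)
    fbt_table = _fbt_table(rec_df, phantom.voxel_size)
    depth_medians = _depth_median_table(rec_df)
    wilcoxon_table = _wilcoxon_table(rec_df)
    return SweepSummary(
        records=rec_df,
        sr_table=sr_table,
        fbt_table=fbt_table,
        depth_medians=depth_medians,
        wilcoxon_table=wilcoxon_table,
        config=config,
        master_seed=master_seed,
        roi_mask=roi,
        phantom=phantom,
        array=array,
    )


def _sr50_table(records: pd.DataFrame) -> pd.DataFrame:
    """SR50 depth per (frequency, nn, noise arm); for the noise arm the
    per-realization SR50 depths are averaged (the replicate analogue of
    averaging across subject head models)."""
    rows = []
    for (f, nn, noise_on), grp in records.groupby(
        ["frequency", "nn_set", "noise_on"]
    ):
        sr50s, beyond = [], []
        for _r, sub in grp.groupby("realization"):
            curve = success_rate_curve(sub)
            sr50s.append(curve.sr50_depth_mm)
            beyond.append(curve.sr50_beyond_range)
        rows.append(
            {
                "frequency": f,
                "nn_set": nn,
                "noise_on": noise_on,
                "sr50_depth_mm": float(np.mean(sr50s)),
                "sr50_beyond_range": all(beyond),
            }
        )
    return pd.DataFrame(rows)


def _fbt_table(records: pd.DataFrame, voxel_size: float) -> pd.DataFrame:
    rows = []
    for (nn, noise_on), grp in records.groupby(["nn_set", "noise_on"]):
        tbl = brain_volume_summary(grp, voxel_size)
        tbl["nn_set"] = nn
        tbl["noise_on"] = noise_on
        rows.append(tbl)
    return pd.concat(rows, ignore_index=True)


def _depth_median_table(records: pd.DataFrame, bin_width: float = 1.0) -> pd.DataFrame:
    rec = records.copy()
    rec["depth_bin_mm"] = np.round(rec["depth_mm"] / bin_width) * bin_width
    rec["cbrt_fvhm_mm"] = np.cbrt(rec["fvhm_mm3"])
    out = (
        rec.groupby(["frequency", "nn_set", "noise_on", "depth_bin_mm"])
        .agg(
            median_le_mm=("le_mm", "median"),
            median_fwhm_mm=("fwhm_mm", "median"),
            median_cbrt_fvhm_mm=("cbrt_fvhm_mm", "median"),
            success_rate=("success", "mean"),
            n=("le_mm", "size"),
        )
        .reset_index()
    )
    return out


def compare_to_cw(
    records_fd: pd.DataFrame, records_cw: pd.DataFrame, metric: str = "le_mm"
):
    """Paired two-sided Wilcoxon signed-rank test on per-voxel metric
    differences between an FD arm and the CW arm.

    Records are paired by (seed voxel, realization); unpaired record sets
    raise.  Identical samples (all zero differences) are flagged with a
    null statistic and p = 1.
    """
    keys = ["seed_voxel", "realization"]
    fd = records_fd.set_index(keys)[metric].sort_index()
    cw = records_cw.set_index(keys)[metric].sort_index()
    if not fd.index.equals(cw.index):
        raise ValueError("FD and CW records are not paired by seed voxel")
    diff = (fd - cw).to_numpy(dtype=float)
    diff = diff[np.isfinite(diff)]
    if len(diff) == 0 or np.all(diff == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(diff, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def _wilcoxon_table(records: pd.DataFrame, metric: str = "le_mm") -> pd.DataFrame:
    rows = []
    for (nn, noise_on), grp in records.groupby(["nn_set", "noise_on"]):
        cw = grp[grp["frequency"] == 0.0]
        for f in sorted(grp["frequency"].unique()):
            if f == 0.0:
                continue
            fd = grp[grp["frequency"] == f]
            try:
                stat, p = compare_to_cw(fd, cw, metric)
            except ValueError:
                stat, p = np.nan, np.nan
            rows.append(
                {
                    "frequency": f,
                    "nn_set": nn,
                    "noise_on": noise_on,
                    "metric": metric,
                    "statistic": stat,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
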