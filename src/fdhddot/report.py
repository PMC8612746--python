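"""Rendering of sweep outputs: CSV tables, metric maps, figures, manifest."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import save_nifti, write_manifest
from .sweep import SweepSummary, _depth_median_table, _fbt_table, _sr50_table

log = logging.getLogger("fdhddot.report")


def render_tables_from_records(
    records: pd.DataFrame, voxel_size: float, outdir: Path
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if len(records) == 0:
        log.warning("empty record set; writing manifest only")
        write_manifest(outdir / "manifest.json", n_records=0)
        return
    _sr50_table(records).to_csv(outdir / "sr50.csv", index=False)
    _fbt_table(records, voxel_size).to_csv(outdir / "fbt.csv", index=False)
    _depth_median_table(records).to_csv(outdir / "depth_medians.csv", index=False)


def _plot_sr50(sr: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for (nn, noise_on), grp in sr.groupby(["nn_set", "noise_on"]):
        grp = grp.sort_values("frequency")
        ax.plot(
            grp["frequency"], grp["sr50_depth_mm"],
            marker="o",
            label=f"NN{nn} {'noise' if noise_on else 'noise-free'}",
        )
    ax.set_xlabel("modulation frequency (MHz)")
    ax.set_ylabel("50% success-rate depth (mm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_depth_medians(dm: pd.DataFrame, path: Path) -> None:
    show = [f for f in (0.0, 400.0, 800.0) if f in set(dm["frequency"])]
    fig, ax = plt.subplots(figsize=(5, 4))
    for f in show:
        grp = dm[
            (dm["frequency"] == f)
            & (dm["nn_set"] == dm["nn_set"].min())
            & (~dm["noise_on"])
        ].sort_values("depth_bin_mm")
        ax.plot(grp["depth_bin_mm"], grp["median_le_mm"], label=f"{f:.0f} MHz")
    ax.set_xlabel("depth below surface (mm)")
    ax.set_ylabel("median localization error (mm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _le_map(summary: SweepSummary, frequency: float, nn: int, noise_on: bool):
    grid = summary.phantom.grid_shape
    vol = np.full(grid, np.nan, dtype=float)
    sel = summary.records[
        (summary.records["frequency"] == frequency)
        & (summary.records["nn_set"] == nn)
        & (summary.records["noise_on"] == noise_on)
    ]
    agg = sel.groupby("seed_voxel")["le_mm"].mean()
    flat = vol.ravel()
    flat[agg.index.to_numpy()] = agg.to_numpy()
    return flat.reshape(grid)


def write_report(summary: SweepSummary, outdir: Path) -> None:
    """Write every sweep output: per-record metrics, summary tables,
    volumetric metric maps, figures and a provenance manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary.records.to_csv(outdir / "records.csv", index=False)
    summary.sr_table.to_csv(outdir / "sr50.csv", index=False)
    summary.fbt_table.to_csv(outdir / "fbt.csv", index=False)
    summary.depth_medians.to_csv(outdir / "depth_medians.csv", index=False)
    summary.wilcoxon_table.to_csv(outdir / "wilcoxon.csv", index=False)
    save_nifti(
        summary.roi_mask.astype(np.float32),
        summary.phantom.voxel_size,
        outdir / "roi_mask.nii.gz",
    )
    for nn in sorted(summary.records["nn_set"].unique()):
        f0 = sorted(summary.records["frequency"].unique())[0]
        vol = _le_map(summary, f0, int(nn), False)
        save_nifti(vol, summary.phantom.voxel_size,
                   outdir / f"le_map_nn{nn}_{f0:.0f}mhz.nii.gz")
    if len(summary.sr_table):
        _plot_sr50(summary.sr_table, outdir / "sr50_vs_frequency.png")
    if len(summary.depth_medians):
        _plot_depth_medians(summary.depth_medians, outdir / "median_le_vs_depth.png")
    write_manifest(
        outdir / "manifest.json",
        master_seed=summary.master_seed,
        config=summary.config.to_dict(),
        n_records=len(summary.records),
        n_roi_voxels=int(summary.roi_mask.sum()),
    )
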