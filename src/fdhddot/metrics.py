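"""Point-spread-function image-quality metrics.

A PSF is the reconstructed image of a single-voxel hemoglobin perturbation.
It is thresholded at half its maximum; metrics are the localization error
(distance from the true perturbation to the value-weighted centroid of the
thresholded set), the full width at half maximum (longest pairwise distance
within the set), and the full volume at half maximum (voxel count times
voxel volume).  A recovery is successful when the localization error is
below the 8-mm cutoff; the success rate per depth bin defines the reliable
imaging boundary (depth of the 50% crossing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

LE_CUTOFF_MM = 8.0


@dataclass
class PSFMetrics:
    """Image-quality record for one simulated point perturbation."""

    seed_voxel: int  # flat voxel index
    position_mm: tuple[float, float, float]
    depth_mm: float
    le_mm: float | None  # None when the thresholded PSF is empty
    fwhm_mm: float | None  # recorded only for successful recoveries
    fvhm_mm3: float | None
    success: bool
    frequency: float
    nn_set: int
    noise_on: bool
    realization: int


@dataclass
class SRCurve:
    """Success rate binned by depth, with the 50% crossing depth."""

    bin_centers_mm: np.ndarray
    success_fraction: np.ndarray
    counts: np.ndarray
    sr50_depth_mm: float
    sr50_beyond_range: bool


def threshold_half_max(values: np.ndarray) -> np.ndarray:
    """Boolean mask of entries >= half the (positive) maximum.

    Returns an all-false mask when the maximum is not positive (flagged
    empty PSF, handled by the caller as a failure record).
    """
    values = np.asarray(values, dtype=float)
    vmax = values.max() if values.size else 0.0
    if vmax <= 0:
        return np.zeros_like(values, dtype=bool)
    return values >= 0.5 * vmax


def weighted_centroid(positions: np.ndarray, values: np.ndarray) -> np.ndarray:
    w = np.asarray(values, dtype=float)
    return (np.asarray(positions, dtype=float) * w[:, None]).sum(axis=0) / w.sum()


def localization_error(
    positions: np.ndarray,
    values: np.ndarray,
    true_position: np.ndarray,
    weighted: bool = True,
) -> float:
    """Distance (mm) from the true perturbation to the PSF centroid."""
    positions = np.atleast_2d(positions)
    if len(positions) == 0:
        raise ValueError("empty PSF voxel set")
    if weighted:
        c = weighted_centroid(positions, values)
    else:
        c = positions.mean(axis=0)
    return float(np.linalg.norm(c - np.asarray(true_position, dtype=float)))


def fwhm(positions: np.ndarray) -> float:
    """Longest pairwise distance (mm) between voxel centers in the set."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    if n == 0:
        raise ValueError("empty PSF voxel set")
    if n == 1:
        return 0.0
    if n > 400:
        # the diameter is attained at convex-hull vertices
        try:
            hull = ConvexHull(positions)
            positions = positions[hull.vertices]
        except QhullError:
            pass  # degenerate (coplanar) sets fall back to the full scan
    return float(pdist(positions).max())


def fvhm(n_voxels: int, voxel_size: float) -> float:
    """Total volume (mm^3) of the thresholded PSF."""
    return float(n_voxels) * voxel_size**3


def evaluate_psf(
    hbo2_values: np.ndarray,
    positions: np.ndarray,
    true_position: np.ndarray,
    voxel_size: float,
    weighted_centroid_mode: bool = True,
) -> tuple[float | None, float | None, float | None, bool]:
    """Threshold a reconstructed HbO2 volume and compute (LE, FWHM, FVHM,
    success).  FWHM/FVHM are recorded only when LE <= cutoff; an empty
    thresholded set yields a flagged failure, not an exception."""
    mask = threshold_half_max(hbo2_values)
    if not mask.any():
        return None, None, None, False
    pos = positions[mask]
    vals = hbo2_values[mask]
    le = localization_error(pos, vals, true_position, weighted_centroid_mode)
    success = le <= LE_CUTOFF_MM
    if not success:
        return le, None, None, False
    return le, fwhm(pos), fvhm(mask.sum(), voxel_size), True


def simulate_psf(
    seed_voxel: int,
    jacobians: dict,
    operators: dict,
    phantom,
    perturbation=None,
    noise_on: bool = False,
    master_seed: int = 0,
    realization: int = 0,
    noise_params=None,
    extinction=None,
    nn_set: int | None = None,
    return_volume: bool = False,
):
    """Full simulation chain for one point perturbation.

    hemoglobin -> absorption -> forward data (+ optional noise) ->
    reconstruction per wavelength -> absorption -> hemoglobin; metrics are
    computed on the HbO2 volume.  ``jacobians`` and ``operators`` map
    wavelength (nm) to a :class:`~fdhddot.sensitivity.Jacobian` and
    :class:`~fdhddot.inversion.InverseOperator` sharing one region of
    interest and channel ordering.
    """
    from .noise import NoiseModelParams, derive_noise_seed, sample_noise
    from .phantom import MeasurementSet
    from .spectroscopy import DEFAULT_PERTURBATION, ExtinctionMatrix, hb_to_mua

    if perturbation is None:
        perturbation = DEFAULT_PERTURBATION
    if extinction is None:
        extinction = ExtinctionMatrix()
    if noise_params is None:
        noise_params = NoiseModelParams()
    wavelengths = sorted(jacobians)
    vox_idx = jacobians[wavelengths[0]].voxel_indices
    for wl in wavelengths:
        if not np.array_equal(jacobians[wl].voxel_indices, vox_idx):
            raise ValueError("jacobians must share one region of interest")
    (col,) = np.nonzero(vox_idx == seed_voxel)
    if len(col) != 1:
        raise ValueError("seed voxel outside the region of interest")
    col = int(col[0])

    dmua = dict(zip((690, 850), hb_to_mua(perturbation, extinction)))
    grid = phantom.grid_shape
    cx, cy, cz = phantom.voxel_centers_mm()
    ii, jj, kk = np.unravel_index(vox_idx, grid)
    positions = np.column_stack([cx[ii], cy[jj], cz[kk]])
    true_pos = positions[col]
    depth = float(phantom.depth_map.ravel()[seed_voxel])
    frequency = jacobians[wavelengths[0]].frequency

    xhat = {}
    for wl in wavelengths:
        jac = jacobians[wl]
        y = jac.stacked()[:, col] * dmua[wl]
        if noise_on:
            ms = MeasurementSet(jac.channels, int(jac.channels["nn"].max()))
            seed = derive_noise_seed(
                master_seed, int(seed_voxel), frequency, wl, realization
            )
            real = sample_noise(ms, frequency, wl, seed, noise_params)
            n = (
                real.intensity
                if real.phase is None
                else np.concatenate([real.intensity, real.phase])
            )
            y = y + n
        xhat[wl] = operators[wl].apply(y)

    Einv = extinction.inverse
    hbo2 = Einv[0, 0] * xhat[690] + Einv[0, 1] * xhat[850]
    le, w, v, success = evaluate_psf(
        hbo2, positions, true_pos, phantom.voxel_size
    )
    rec = PSFMetrics(
        seed_voxel=int(seed_voxel),
        position_mm=tuple(float(c) for c in true_pos),
        depth_mm=depth,
        le_mm=le,
        fwhm_mm=w,
        fvhm_mm3=v,
        success=success,
        frequency=float(frequency),
        nn_set=nn_set or int(jacobians[wavelengths[0]].channels["nn"].max()),
        noise_on=bool(noise_on),
        realization=int(realization),
    )
    if return_volume:
        return rec, hbo2
    return rec


def success_rate_curve(
    records: pd.DataFrame,
    cutoff: float = LE_CUTOFF_MM,
    bin_width: float = 1.0,
) -> SRCurve:
    """Success rate vs depth with the interpolated 50% crossing.

    ``records`` needs columns ``depth_mm`` and ``le_mm`` (NaN = empty PSF,
    counted as failure).  Success for the rate is the strict ``le < cutoff``
    reading; the crossing is the first depth where the curve falls below
    0.5 from above, linearly interpolated between populated bin centers.
    If the curve never reaches 0.5 the crossing is flagged beyond range.
    """
    depth = records["depth_mm"].to_numpy(dtype=float)
    le = records["le_mm"].to_numpy(dtype=float)
    ok = np.isfinite(le) & (le < cutoff)
    bins = np.round(depth / bin_width).astype(int)
    uniq = np.unique(bins)
    centers = uniq * bin_width
    frac = np.array([ok[bins == b].mean() for b in uniq])
    counts = np.array([(bins == b).sum() for b in uniq])

    sr50 = float(centers[-1])
    beyond = True
    for i in range(len(centers)):
        if frac[i] < 0.5:
            if i == 0:
                sr50, beyond = float(centers[0]), False
            else:
                d0, d1 = centers[i - 1], centers[i]
                f0, f1 = frac[i - 1], frac[i]
                sr50 = float(d0 + (f0 - 0.5) / (f0 - f1) * (d1 - d0))
                beyond = False
            break
    return SRCurve(centers, frac, counts, sr50, beyond)


def brain_volume_summary(
    records: pd.DataFrame,
    voxel_size: float,
    le_cutoffs=tuple(range(1, 9)),
) -> pd.DataFrame:
    """Full-brain-tissue volume (FBTV) and its ratio to continuous wave.

    ``records`` needs columns ``frequency``, ``is_brain``, ``le_mm`` and
    ``realization``; FBTV at a cutoff is the mean over realizations of the
    successfully recovered brain-voxel volume.  The ratio of each frequency
    to the frequency-0 (CW) FBTV is exactly 1 at frequency 0.
    """
    freqs = np.sort(records["frequency"].unique())
    if 0.0 not in freqs:
        raise ValueError("CW (frequency 0) records required for FBT ratios")
    vv = voxel_size**3
    rows = []
    for f in freqs:
        sub = records[records["frequency"] == f]
        n_real = max(sub["realization"].nunique(), 1)
        for cut in le_cutoffs:
            ok = (
                sub["is_brain"]
                & np.isfinite(sub["le_mm"])
                & (sub["le_mm"] < cut)
            )
            rows.append(
                {
                    "frequency": f,
                    "le_cutoff_mm": float(cut),
                    "fbtv_mm3": ok.sum() * vv / n_real,
                }
            )
    out = pd.DataFrame(rows)
    cw = out[out["frequency"] == 0.0].set_index("le_cutoff_mm")["fbtv_mm3"]
    ratios = []
    for _, row in out.iterrows():
        denom = cw.loc[row["le_cutoff_mm"]]
        ratios.append(row["fbtv_mm3"] / denom if denom > 0 else np.nan)
    out["fbt_ratio"] = ratios
    return out
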