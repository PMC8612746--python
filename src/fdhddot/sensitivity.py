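"""Rytov sensitivity matrices (adjoint assembly).

The Rytov datum for a channel is the complex log of the perturbed over the
baseline fluence at the detector; its derivative with respect to a voxel
absorption change is assembled from the source field and the detector
adjoint field (reciprocity), which is the only tractable route to the
~10^4-10^5 voxel columns needed here.  A brute-force perturbation oracle on
tiny phantoms anchors correctness in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import ForwardField
from .phantom import HeadPhantom, MeasurementSet


class DegenerateBaselineError(ZeroDivisionError):
    """Raised when a baseline measurement is zero."""


@dataclass
class Jacobian:
    """Per-wavelength sensitivity of channel data to voxel absorption.

    ``intensity`` rows are d ln(amplitude) per unit mua change (dimensionless
    per mm^-1); ``phase`` rows are radians per mm^-1 (``None`` in the
    continuous-wave case, where phase rows are dropped rather than carried
    as zeros).  Columns follow ``voxel_indices`` (flat indices into the
    phantom grid).
    """

    intensity: np.ndarray  # (n_channels, n_voxels)
    phase: np.ndarray | None
    frequency: float  # MHz
    wavelength: int  # nm
    voxel_indices: np.ndarray  # flat voxel index per column
    channels: np.ndarray  # structured channel records (MeasurementSet order)

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.intensity.shape[1]

    def stacked(self) -> np.ndarray:
        """Real system matrix: intensity rows, then phase rows (if FD)."""
        if self.phase is None:
            return self.intensity
        return np.vstack([self.intensity, self.phase])

    def row_subset(self, keep: np.ndarray, channels: np.ndarray) -> "Jacobian":
        """Jacobian restricted to a channel subset (e.g. NN3 from NN4)."""
        return Jacobian(
            intensity=self.intensity[keep],
            phase=None if self.phase is None else self.phase[keep],
            frequency=self.frequency,
            wavelength=self.wavelength,
            voxel_indices=self.voxel_indices,
            channels=channels,
        )


def baseline_measurements(
    source_fields: dict[int, ForwardField],
    detector_fields: dict[int, ForwardField],
    channels: MeasurementSet,
) -> np.ndarray:
    """Unperturbed complex datum per channel: the source field evaluated at
    the detector's injection voxel."""
    out = np.empty(channels.n_channels, dtype=np.complex128)
    for i, ch in enumerate(channels.channels):
        sfield = source_fields[int(ch["src"])]
        dvox = detector_fields[int(ch["det"])].source_voxel
        out[i] = sfield.fluence[dvox]
    return out


def assemble_rytov_jacobian(
    source_fields: dict[int, ForwardField],
    detector_fields: dict[int, ForwardField],
    phantom: HeadPhantom,
    channels: MeasurementSet,
    frequency: float,
    wavelength: int,
    roi_mask: np.ndarray | None = None,
) -> Jacobian:
    """Assemble the complex Rytov Jacobian and split it into data rows.

    The complex entry for channel (s, d) and voxel j is

        dln(Phi_s(r_d)) / dmua_j
            = -v_j * Phi_s(r_j) * Phi_d(r_j) * h^3 / (v_d * Phi_s(r_d)),

    with Phi_d the adjoint (detector-launched) field and h^3 the voxel
    volume entering through the discrete source normalization.  Real parts
    become log-intensity rows, imaginary parts phase rows; at frequency 0
    the fields are real and phase rows are dropped.
    """
    missing = [int(c) for c in np.unique(channels.channels["src"])
               if int(c) not in source_fields]
    missing += [int(c) for c in np.unique(channels.channels["det"])
                if int(c) not in detector_fields]
    if missing:
        raise KeyError(f"missing forward fields for optodes {missing}")
    if roi_mask is None:
        roi_mask = np.ones(phantom.grid_shape, dtype=bool)
    vox_idx = np.flatnonzero(roi_mask.ravel())
    h3 = phantom.voxel_size**3

    from .forward import DiffusionMedium

    med = DiffusionMedium.from_phantom(phantom, wavelength, frequency)
    v_flat = med.v.ravel()
    v_roi = v_flat[vox_idx]

    src_ids = np.unique(channels.channels["src"])
    det_ids = np.unique(channels.channels["det"])
    sflat = {int(s): source_fields[int(s)].fluence.ravel() for s in src_ids}
    dflat = {int(d): detector_fields[int(d)].fluence.ravel() for d in det_ids}
    s_roi = {s: f[vox_idx] for s, f in sflat.items()}
    d_roi = {d: f[vox_idx] for d, f in dflat.items()}

    n_ch = channels.n_channels
    J = np.empty((n_ch, len(vox_idx)), dtype=np.complex128)
    for i, ch in enumerate(channels.channels):
        s, d = int(ch["src"]), int(ch["det"])
        dvox = detector_fields[d].source_voxel
        dvox_flat = np.ravel_multi_index(dvox, phantom.grid_shape)
        y0 = sflat[s][dvox_flat]
        if y0 == 0:
            raise DegenerateBaselineError(
                f"zero baseline for channel ({s}, {d})"
            )
        J[i] = -v_roi * s_roi[s] * d_roi[d] * h3 / (v_flat[dvox_flat] * y0)
    if not np.all(np.isfinite(J)):
        raise ArithmeticError("non-finite Jacobian entries")
    is_cw = frequency == 0.0
    return Jacobian(
        intensity=np.ascontiguousarray(J.real),
        phase=None if is_cw else np.ascontiguousarray(J.imag),
        frequency=float(frequency),
        wavelength=wavelength,
        voxel_indices=vox_idx,
        channels=channels.channels.copy(),
    )


def rytov_data(
    perturbed: np.ndarray, baseline: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Differential log-amplitude and wrapped phase difference per channel.

    Returns ``(log_amp, phase)`` with the phase difference wrapped to
    (-pi, pi].
    """
    perturbed = np.asarray(perturbed, dtype=np.complex128)
    baseline = np.asarray(baseline, dtype=np.complex128)
    if np.any(baseline == 0):
        raise DegenerateBaselineError("zero baseline measurement")
    log_amp = np.log(np.abs(perturbed) / np.abs(baseline))
    dphase = np.angle(perturbed) - np.angle(baseline)
    # wrap to (-pi, pi]
    dphase = -((-dphase + np.pi) % (2.0 * np.pi) - np.pi)
    return log_amp, dphase


def summed_intensity_sensitivity(jacobian: Jacobian, grid_shape) -> np.ndarray:
    """Voxelwise sum of |log-intensity rows| over channels, normalized to a
    maximum of 1; supports the deep region-of-interest boundary."""
    total = np.abs(jacobian.intensity).sum(axis=0)
    vol = np.zeros(int(np.prod(grid_shape)))
    vol[jacobian.voxel_indices] = total
    m = vol.max()
    if m > 0:
        vol /= m
    return vol.reshape(grid_shape)
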