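"""Frequency-domain photon diffusion forward models.

Solves the frequency-domain diffusion equation

    div(D grad Phi) - v*mua*Phi + i*omega*Phi = -v*Q,      D = v / (3*(mua+musp))

on the phantom voxel grid with a Robin (partial-current) condition on
air-facing faces, for a unit-amplitude monochromatic point source placed one
transport length (1/musp) beneath the optode surface position.  Units: mm,
ns; frequencies in MHz (omega = 2*pi*f*1e-3 rad/ns); c0 = 299.792458 mm/ns.

Two numerically identical discretizations are provided:

* :class:`FDSolver` — general sparse finite-volume operator for any labeled
  voxel phantom (SuperLU factorization reused across sources).
* :class:`SlabSolver` — for laterally uniform layered slabs, the same
  operator diagonalized by a 2-D lateral FFT (periodic lateral boundary)
  with batched tridiagonal solves in depth; one kernel solve yields the
  field of every optode by lateral translation.

Closed-form homogeneous and semi-infinite medium Green's functions serve as
independent validation oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .phantom import HeadPhantom, TissueProperties

C0_MM_PER_NS = 299.792458


class NumericalFailureError(RuntimeError):
    """Raised when the linear solve fails or violates the residual bound."""


def omega_rad_per_ns(frequency_mhz: float) -> float:
    """Angular modulation frequency in rad/ns for a source frequency in MHz."""
    return 2.0 * np.pi * frequency_mhz * 1e-3


def boundary_reflection_coefficient(n_tissue: float, n_outside: float = 1.0) -> float:
    """Internal-reflection parameter A of the partial-current boundary.

    Uses the Groenhuis polynomial fit for the effective Fresnel reflectance
    at a tissue/air interface: A = (1 + r_d) / (1 - r_d) with
    r_d = -1.440/n^2 + 0.710/n + 0.668 + 0.0636*n, n = n_tissue/n_outside.
    """
    n = n_tissue / n_outside
    r_d = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_d) / (1.0 - r_d)


@dataclass
class DiffusionMedium:
    """Per-voxel coefficients of the frequency-domain diffusion operator."""

    D: np.ndarray  # diffusion coefficient, mm^2/ns
    v: np.ndarray  # speed of light in tissue, mm/ns
    mua_v: np.ndarray  # v * mua, 1/ns
    omega: float  # rad/ns
    musp: np.ndarray  # reduced scattering, mm^-1 (for source depth placement)
    boundary_A: np.ndarray  # Robin reflection parameter per voxel

    @classmethod
    def from_phantom(
        cls, phantom: HeadPhantom, wavelength: int, frequency_mhz: float
    ) -> "DiffusionMedium":
        mua = phantom.mua_volume(wavelength)
        musp = phantom.musp_volume(wavelength)
        n = phantom.refractive_index_volume(wavelength)
        v = C0_MM_PER_NS / n
        D = v / (3.0 * (mua + musp))
        A = np.vectorize(boundary_reflection_coefficient)(np.unique(n))
        A_map = dict(zip(np.unique(n), np.atleast_1d(A)))
        A_vol = np.vectorize(A_map.get)(n)
        return cls(
            D=D,
            v=v,
            mua_v=v * mua,
            omega=omega_rad_per_ns(frequency_mhz),
            musp=musp,
            boundary_A=A_vol,
        )


@dataclass
class ForwardField:
    """Photon fluence rate for one optode (source-normalized units)."""

    fluence: np.ndarray  # complex, phantom grid shape
    source_voxel: tuple[int, int, int]
    frequency: float  # MHz
    wavelength: int  # nm

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.fluence)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.fluence)


# ---------------------------------------------------------------------------
# Closed-form oracles
# ---------------------------------------------------------------------------

def greens_homogeneous(
    props: TissueProperties, r: float | np.ndarray, frequency_mhz: float
) -> np.ndarray | complex:
    """Infinite homogeneous medium Green's function.

    Phi(r) = v * Q * exp(-k_eff * r) / (4 * pi * D * r) with
    k_eff = sqrt((v*mua - i*omega) / D), root with positive real part, Q = 1.
    Reduces to the continuous-wave kernel exp(-r*sqrt(3*mua*(mua+musp)))
    * v / (4*pi*D*r) at omega = 0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive (singular at the source)")
    v = C0_MM_PER_NS / props.refractive_index
    D = v / (3.0 * (props.mua + props.musp))
    omega = omega_rad_per_ns(frequency_mhz)
    k = np.sqrt((v * props.mua - 1j * omega) / D)
    if k.real < 0:
        k = -k
    out = v * np.exp(-k * r) / (4.0 * np.pi * D * r)
    return out if out.shape else complex(out)


def extrapolation_length(props: TissueProperties, n_outside: float = 1.0) -> float:
    """Extrapolated-boundary distance z_b = 2*A*D/v = 2*A/(3*(mua+musp)), mm."""
    A = boundary_reflection_coefficient(props.refractive_index, n_outside)
    return 2.0 * A / (3.0 * (props.mua + props.musp))


def greens_semi_infinite(
    props: TissueProperties,
    source_surface_point: np.ndarray,
    field_point: np.ndarray,
    frequency_mhz: float,
) -> complex:
    """Semi-infinite medium fluence via the image-source construction.

    The physical source sits one transport length z0 = 1/musp below the
    surface point; a negative image source is mirrored about the
    extrapolated boundary at z = -z_b.  The surface is the plane z = 0 with
    +z pointing into the medium.
    """
    src = np.asarray(source_surface_point, dtype=float)
    fp = np.asarray(field_point, dtype=float)
    if fp[2] <= 0:
        raise ValueError("field point must lie inside the medium (z > 0)")
    z0 = 1.0 / props.musp
    zb = extrapolation_length(props)
    real_src = src + np.array([0.0, 0.0, z0])
    image_src = src + np.array([0.0, 0.0, -(z0 + 2.0 * zb)])
    r1 = float(np.linalg.norm(fp - real_src))
    r2 = float(np.linalg.norm(fp - image_src))
    return complex(
        greens_homogeneous(props, r1, frequency_mhz)
        - greens_homogeneous(props, r2, frequency_mhz)
    )


# ---------------------------------------------------------------------------
# General sparse finite-volume solver
# ---------------------------------------------------------------------------

def _boundary_conductance(D: np.ndarray, v: np.ndarray, A: np.ndarray, h: float):
    """Per-area conductance of a Robin face seen from the voxel center."""
    return 1.0 / (h / (2.0 * D) + 2.0 * A / v)


def assemble_operator(
    phantom: HeadPhantom,
    wavelength: int,
    frequency_mhz: float,
    lateral_bc: str = "robin",
) -> tuple[sp.csc_matrix, DiffusionMedium]:
    """Assemble the finite-volume operator M with M*Phi = b.

    M is complex symmetric: diagonal v*mua - i*omega plus face couplings;
    interior faces use the harmonic mean of the adjacent diffusion
    coefficients; air-facing faces (top and bottom of the slab, and the
    lateral faces when ``lateral_bc == 'robin'``) carry the Robin
    partial-current conductance.  ``lateral_bc == 'periodic'`` wraps the
    lateral axes instead (used to cross-check the slab FFT path).
    """
    if lateral_bc not in ("robin", "periodic"):
        raise ValueError("lateral_bc must be 'robin' or 'periodic'")
    med = DiffusionMedium.from_phantom(phantom, wavelength, frequency_mhz)
    nx, ny, nz = phantom.grid_shape
    h = phantom.voxel_size
    n = nx * ny * nz
    idx = np.arange(n).reshape(nx, ny, nz)
    D = med.D

    diag = (med.mua_v - 1j * med.omega).astype(np.complex128).ravel().copy()
    rows, cols, vals = [], [], []

    def couple(ia: np.ndarray, ib: np.ndarray, Da: np.ndarray, Db: np.ndarray):
        w = (2.0 * Da * Db / (Da + Db)) / h**2
        ia, ib, w = ia.ravel(), ib.ravel(), w.ravel()
        np.add.at(diag, ia, w)
        np.add.at(diag, ib, w)
        rows.extend([ia, ib])
        cols.extend([ib, ia])
        vals.extend([-w, -w])

    couple(idx[:-1, :, :], idx[1:, :, :], D[:-1, :, :], D[1:, :, :])
    couple(idx[:, :-1, :], idx[:, 1:, :], D[:, :-1, :], D[:, 1:, :])
    couple(idx[:, :, :-1], idx[:, :, 1:], D[:, :, :-1], D[:, :, 1:])
    if lateral_bc == "periodic":
        if nx > 2:
            couple(idx[-1, :, :], idx[0, :, :], D[-1, :, :], D[0, :, :])
        if ny > 2:
            couple(idx[:, -1, :], idx[:, 0, :], D[:, -1, :], D[:, 0, :])

    def robin(slc):
        g = _boundary_conductance(
            D[slc], med.v[slc], med.boundary_A[slc], h
        ) / h
        np.add.at(diag, idx[slc].ravel(), g.ravel())

    robin(np.s_[:, :, 0])
    robin(np.s_[:, :, -1])
    if lateral_bc == "robin":
        robin(np.s_[0, :, :])
        robin(np.s_[-1, :, :])
        robin(np.s_[:, 0, :])
        robin(np.s_[:, -1, :])

    rows = np.concatenate([np.arange(n)] + rows)
    cols = np.concatenate([np.arange(n)] + cols)
    vals = np.concatenate([diag] + vals)
    M = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return M, med


def source_voxel_index(
    phantom: HeadPhantom, optode_position: np.ndarray, wavelength: int
) -> tuple[int, int, int]:
    """Voxel holding the isotropic point source: the grid voxel nearest to
    the optode's lateral position, at depth 1/musp of the surface tissue."""
    h = phantom.voxel_size
    nx, ny, nz = phantom.grid_shape
    x, y = float(optode_position[0]), float(optode_position[1])
    ix = int(np.clip(np.floor(x / h), 0, nx - 1))
    iy = int(np.clip(np.floor(y / h), 0, ny - 1))
    surf_tissue = phantom.tissue_of(phantom.labels[ix, iy, 0])
    z0 = 1.0 / phantom.props(surf_tissue, wavelength).musp
    iz = int(np.clip(np.floor(z0 / h), 0, nz - 1))
    return ix, iy, iz


class FDSolver:
    """Sparse direct solver; the factorization is reused across sources."""

    def __init__(
        self,
        phantom: HeadPhantom,
        wavelength: int,
        frequency_mhz: float,
        lateral_bc: str = "robin",
    ):
        self.phantom = phantom
        self.wavelength = wavelength
        self.frequency = float(frequency_mhz)
        self.M, self.medium = assemble_operator(
            phantom, wavelength, frequency_mhz, lateral_bc
        )
        try:
            self._lu = spla.splu(self.M)
        except RuntimeError as exc:  # singular factorization
            raise NumericalFailureError(f"LU factorization failed: {exc}") from exc

    def solve_at_voxel(self, voxel: tuple[int, int, int]) -> ForwardField:
        nx, ny, nz = self.phantom.grid_shape
        h = self.phantom.voxel_size
        flat = np.ravel_multi_index(voxel, (nx, ny, nz))
        b = np.zeros(nx * ny * nz, dtype=np.complex128)
        b[flat] = self.medium.v.ravel()[flat] / h**3
        phi = self._lu.solve(b)
        resid = np.linalg.norm(self.M @ phi - b) / np.linalg.norm(b)
        if not np.isfinite(resid) or resid > 1e-8:
            raise NumericalFailureError(
                f"relative residual {resid:.2e} exceeds 1e-8"
            )
        if self.frequency == 0.0:
            phi = phi.real.astype(np.complex128)
        return ForwardField(
            fluence=phi.reshape(nx, ny, nz),
            source_voxel=tuple(voxel),
            frequency=self.frequency,
            wavelength=self.wavelength,
        )

    def solve(self, optode_position: np.ndarray) -> ForwardField:
        voxel = source_voxel_index(self.phantom, optode_position, self.wavelength)
        return self.solve_at_voxel(voxel)


def solve_fd_diffusion(
    phantom: HeadPhantom,
    optode_position: np.ndarray,
    frequency_mhz: float,
    wavelength: int,
    lateral_bc: str = "robin",
) -> ForwardField:
    """One-shot forward solve for a single optode position."""
    if frequency_mhz < 0:
        raise ValueError("frequency must be non-negative")
    return FDSolver(phantom, wavelength, frequency_mhz, lateral_bc).solve(
        optode_position
    )


# ---------------------------------------------------------------------------
# Layered-slab fast path (lateral FFT + batched tridiagonal depth solves)
# ---------------------------------------------------------------------------

def _thomas_batched(lower, diag, upper, rhs):
    """Solve batched tridiagonal systems; all arrays shaped (nbatch, nz)
    (lower/upper have nz-1 usable entries)."""
    nb, nz = diag.shape
    cp = np.empty((nb, nz - 1), dtype=np.complex128)
    dp = np.empty((nb, nz), dtype=np.complex128)
    cp[:, 0] = upper[:, 0] / diag[:, 0]
    dp[:, 0] = rhs[:, 0] / diag[:, 0]
    for k in range(1, nz):
        denom = diag[:, k] - lower[:, k - 1] * cp[:, k - 1]
        if k < nz - 1:
            cp[:, k] = upper[:, k] / denom
        dp[:, k] = (rhs[:, k] - lower[:, k - 1] * dp[:, k - 1]) / denom
    x = np.empty_like(dp)
    x[:, -1] = dp[:, -1]
    for k in range(nz - 2, -1, -1):
        x[:, k] = dp[:, k] - cp[:, k] * x[:, k + 1]
    return x


class SlabSolver:
    """Forward solver for laterally uniform layered slabs.

    Diagonalizes the finite-volume operator over the lateral axes with a 2-D
    FFT (periodic lateral boundary; the wrap-around contribution is
    negligible when fields decay over the lateral extent) and solves one
    tridiagonal system in depth per lateral mode.  The solution is identical
    to :class:`FDSolver` with ``lateral_bc='periodic'``.  One kernel solve
    per source depth yields every optode's field by lateral translation.
    """

    def __init__(self, phantom: HeadPhantom, wavelength: int, frequency_mhz: float):
        if frequency_mhz < 0:
            raise ValueError("frequency must be non-negative")
        lbl = phantom.labels
        if not (lbl == lbl[:1, :1, :]).all():
            raise ValueError("SlabSolver requires a laterally uniform phantom")
        self.phantom = phantom
        self.wavelength = wavelength
        self.frequency = float(frequency_mhz)
        self.medium = DiffusionMedium.from_phantom(
            phantom, wavelength, frequency_mhz
        )
        nx, ny, nz = phantom.grid_shape
        h = phantom.voxel_size
        Dz = self.medium.D[0, 0, :]
        vz = self.medium.v[0, 0, :]
        muaz = self.medium.mua_v[0, 0, :]
        Az = self.medium.boundary_A[0, 0, :]

        self._Dv = (2.0 * Dz[:-1] * Dz[1:] / (Dz[:-1] + Dz[1:])) / h**2
        lam_x = (2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(nx) / nx)) / h**2
        lam_y = (2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(ny) / ny)) / h**2
        lat = lam_x[:, None] + lam_y[None, :]  # (nx, ny)

        diag_z = (muaz - 1j * omega_rad_per_ns(self.frequency)).astype(np.complex128)
        diag_z = np.broadcast_to(diag_z, (nx * ny, nz)).copy()
        diag_z[:, :-1] += self._Dv
        diag_z[:, 1:] += self._Dv
        diag_z[:, 0] += _boundary_conductance(Dz[0], vz[0], Az[0], h) / h
        diag_z[:, -1] += _boundary_conductance(Dz[-1], vz[-1], Az[-1], h) / h
        diag_z += (Dz[None, None, :] * lat[:, :, None]).reshape(nx * ny, nz)
        self._diag = diag_z
        off = np.broadcast_to(-self._Dv, (nx * ny, nz - 1)).copy()
        self._off = off
        self._kernels: dict[int, np.ndarray] = {}

    def _kernel(self, iz_src: int) -> np.ndarray:
        """Field (full grid) of a point source at lateral voxel (0, 0)."""
        if iz_src in self._kernels:
            return self._kernels[iz_src]
        nx, ny, nz = self.phantom.grid_shape
        h = self.phantom.voxel_size
        rhs = np.zeros((nx * ny, nz), dtype=np.complex128)
        # FFT of a lateral delta at (0, 0) is 1 in every mode
        rhs[:, iz_src] = self.medium.v[0, 0, iz_src] / h**3
        # the unnormalized forward FFT of the lateral delta is v/h^3 in every
        # mode, so the plain (1/NxNy-normalized) inverse transform applies
        phi_modes = _thomas_batched(self._off, self._diag, self._off, rhs)
        phi = np.ascontiguousarray(
            np.fft.ifft2(phi_modes.reshape(nx, ny, nz), axes=(0, 1))
        )
        if self.frequency == 0.0:
            phi = phi.real.astype(np.complex128)
        self._kernels[iz_src] = phi
        return phi

    def solve(self, optode_position: np.ndarray) -> ForwardField:
        voxel = source_voxel_index(
            self.phantom, optode_position, self.wavelength
        )
        ix, iy, iz = voxel
        kernel = self._kernel(iz)
        phi = np.roll(kernel, (ix, iy), axis=(0, 1))
        return ForwardField(
            fluence=phi,
            source_voxel=voxel,
            frequency=self.frequency,
            wavelength=self.wavelength,
        )
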