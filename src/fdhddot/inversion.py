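"""Regularized pseudo-inverse image reconstruction.

The reconstruction operator is a Moore-Penrose pseudoinverse with Tikhonov
and spatially variant regularization,

    A# = L^-1 (Ahat^T Ahat + lambda1 I)^-1 Ahat^T,     Ahat = A L^-1,

with the diagonal scaling L built from diag(A^T A).  lambda1 is a fraction
(default 0.01) of the maximum singular value of Ahat^T Ahat; lambda2 a
fraction (default 0.1) of the maximum singular value of A^T A.  Two
readings of L are provided:

* ``variant='sqrt'`` (default): diag(L) = sqrt(diag(A^T A) + lambda2_rel *
  max diag), the standard spatially variant regularization that
  compensates the depth-dependent sensitivity fall-off;
* ``variant='literal'``: diag(L) = diag(A^T A) + lambda2^2 with lambda2 an
  absolute spectral fraction.  This form is dimensionally inhomogeneous and
  for realistic sensitivity scales the constant lambda2^2 term dominates
  the diagonal, which deactivates the spatial compensation the parameter
  exists to provide; it is retained for sensitivity analysis.

A# is evaluated in measurement space via the push-through identity
(Ahat^T Ahat + l1 I)^-1 Ahat^T = Ahat^T (Ahat Ahat^T + l1 I)^-1, which
avoids voxel-by-voxel matrices and is algebraically identical to the
literal voxel-space form (asserted on small instances in the tests).
Wavelengths are inverted independently: one operator per (frequency,
wavelength, channel set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla


class DegenerateJacobianError(ValueError):
    """Raised for an all-zero system matrix."""


@dataclass(frozen=True)
class RegularizationParams:
    """Relative regularization strengths (dimensionless, both > 0)."""

    lambda1_rel: float = 0.01
    lambda2_rel: float = 0.1
    variant: str = "sqrt"  # or "literal"

    def __post_init__(self) -> None:
        if self.lambda1_rel <= 0 or self.lambda2_rel <= 0:
            raise ValueError("regularization parameters must be positive")
        if self.variant not in ("literal", "sqrt"):
            raise ValueError("variant must be 'literal' or 'sqrt'")


def max_singular_value_sq(A: np.ndarray, tol: float = 1e-6, seed: int = 0) -> float:
    """Largest singular value of A^T A (== sigma_max(A)^2) by power
    iteration in measurement space, fixed-seed start vector."""
    rng = np.random.default_rng(seed)
    m = A.shape[0]
    u = rng.standard_normal(m)
    u /= np.linalg.norm(u)
    lam = 0.0
    for _ in range(500):
        w = A @ (A.T @ u)
        lam_new = float(np.linalg.norm(w))
        if lam_new == 0.0:
            return 0.0
        u = w / lam_new
        if abs(lam_new - lam) <= tol * lam_new:
            return lam_new
        lam = lam_new
    return lam


@dataclass
class InverseOperator:
    """Factored reconstruction operator x = A# y.

    Stores the column scaling, the scaled system matrix and the Cholesky
    factor of (Ahat Ahat^T + lambda1 I) instead of the dense voxel x rows
    matrix; ``matrix`` materializes A# for small instances.
    """

    L_diag: np.ndarray  # (n_voxels,)
    Ahat: np.ndarray  # (n_rows, n_voxels)
    cho: tuple  # Cholesky factor of (Ahat Ahat^T + lambda1 I)
    lambda1: float
    lambda2: float
    params: RegularizationParams
    provenance: dict

    @property
    def n_rows(self) -> int:
        return self.Ahat.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.Ahat.shape[1]

    def apply(self, y: np.ndarray) -> np.ndarray:
        """Reconstruct one vector (n_rows,) or a batch (n_rows, k)."""
        y = np.asarray(y, dtype=float)
        if y.shape[0] != self.n_rows:
            raise ValueError(
                f"row mismatch: operator has {self.n_rows} rows, data {y.shape[0]}"
            )
        w = sla.cho_solve(self.cho, y)
        x = self.Ahat.T @ w
        if x.ndim == 1:
            return x / self.L_diag
        return x / self.L_diag[:, None]

    @property
    def matrix(self) -> np.ndarray:
        """Dense A# (n_voxels x n_rows); only for small instances."""
        return self.apply(np.eye(self.n_rows))


def build_inverse_operator(
    A: np.ndarray,
    reg: RegularizationParams | None = None,
    provenance: dict | None = None,
) -> InverseOperator:
    """Build the regularized pseudo-inverse of a stacked system matrix."""
    if reg is None:
        reg = RegularizationParams()
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] < 1:
        raise DegenerateJacobianError("system matrix must be 2-D with >= 1 row")
    if not np.any(A):
        raise DegenerateJacobianError("all-zero system matrix")

    smax_ata = max_singular_value_sq(A)
    lambda2 = reg.lambda2_rel * smax_ata
    diag_ata = np.einsum("ij,ij->j", A, A)
    if reg.variant == "literal":
        L = diag_ata + lambda2**2
    else:
        L = np.sqrt(diag_ata + reg.lambda2_rel * diag_ata.max())
    # guard exact zeros (voxels with no sensitivity) against division
    L = np.where(L > 0, L, 1.0)

    Ahat = A / L[None, :]
    G = Ahat @ Ahat.T
    lambda1 = reg.lambda1_rel * max_singular_value_sq(Ahat)
    G[np.diag_indices_from(G)] += lambda1
    cho = sla.cho_factor(G, lower=True)
    return InverseOperator(
        L_diag=L,
        Ahat=Ahat,
        cho=cho,
        lambda1=float(lambda1),
        lambda2=float(lambda2),
        params=reg,
        provenance=provenance or {},
    )


def reconstruct(
    op: InverseOperator,
    y: np.ndarray,
    voxel_indices: np.ndarray | None = None,
    grid_shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Reconstruct a voxel absorption-perturbation image from data y.

    Returns the flat coefficient vector over operator columns, or a full
    volume (zeros outside the region of interest) when ``voxel_indices``
    and ``grid_shape`` are given.
    """
    x = op.apply(y)
    if voxel_indices is None:
        return x
    if grid_shape is None:
        raise ValueError("grid_shape required to scatter onto the voxel grid")
    vol = np.zeros(int(np.prod(grid_shape)))
    vol[voxel_indices] = x
    return vol.reshape(grid_shape)
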