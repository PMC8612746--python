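"""Hemoglobin <-> absorption conversion at 690 and 850 nm.

A 2x2 molar extinction matrix maps oxy-/deoxy-hemoglobin concentration
changes (uM) to absorption-coefficient changes (mm^-1) at the two
illumination wavelengths; its inverse recovers HbO2/HbR volumes from
reconstructed absorption volumes.  The embedded default values come from
the standard Prahl/OMLC compilation of molar extinction coefficients
(base-10, cm^-1 M^-1), converted to natural-log mm^-1 uM^-1; they are
configuration, not ground truth — image-shape metrics are insensitive to
the specific table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: ln(10) * 1e-6 (M -> uM) / 10 (cm^-1 -> mm^-1)
_BASE10_CM_M_TO_LN_MM_UM = np.log(10.0) * 1e-7

#: Prahl/OMLC molar extinction coefficients, base-10 cm^-1 M^-1.
_PRAHL_BASE10 = {
    ("HbO2", 690): 276.0,
    ("HbR", 690): 2051.96,
    ("HbO2", 850): 1058.0,
    ("HbR", 850): 691.32,
}

DEFAULT_EXTINCTION_MM_UM: dict[tuple[str, int], float] = {
    key: val * _BASE10_CM_M_TO_LN_MM_UM for key, val in _PRAHL_BASE10.items()
}


class ConditioningError(np.linalg.LinAlgError):
    """Raised when the extinction matrix is too ill-conditioned to invert."""


@dataclass(frozen=True)
class HbPerturbation:
    """Hemoglobin concentration perturbation (uM)."""

    dHbO2: float
    dHbR: float


#: Default functional point perturbation: +3.8 uM HbO2, -1.8 uM HbR.
DEFAULT_PERTURBATION = HbPerturbation(3.8, -1.8)


@dataclass
class ExtinctionMatrix:
    """2x2 extinction matrix E[(wavelength), (chromophore)] in mm^-1 uM^-1.

    Row order (690, 850) nm; column order (HbO2, HbR)."""

    table: dict[tuple[str, int], float] = field(
        default_factory=lambda: dict(DEFAULT_EXTINCTION_MM_UM)
    )
    max_condition: float = 100.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.table.values()):
            raise ValueError("extinction coefficients must be positive")

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.table[("HbO2", 690)], self.table[("HbR", 690)]],
                [self.table[("HbO2", 850)], self.table[("HbR", 850)]],
            ]
        )

    @property
    def inverse(self) -> np.ndarray:
        E = self.matrix
        if np.linalg.cond(E) >= self.max_condition:
            raise ConditioningError(
                f"extinction matrix condition number {np.linalg.cond(E):.1f} "
                f">= {self.max_condition}"
            )
        return np.linalg.inv(E)


def hb_to_mua(
    p: HbPerturbation, E: ExtinctionMatrix | None = None
) -> tuple[float, float]:
    """Absorption perturbations (dmua_690, dmua_850) in mm^-1."""
    if E is None:
        E = ExtinctionMatrix()
    d = E.matrix @ np.array([p.dHbO2, p.dHbR])
    return float(d[0]), float(d[1])


def mua_to_hb(
    dmua, E: ExtinctionMatrix | None = None
) -> HbPerturbation | tuple[np.ndarray, np.ndarray]:
    """Invert the spectroscopic conversion.

    Accepts a pair of scalars (returns an :class:`HbPerturbation`) or a pair
    of equally shaped arrays (returns (HbO2, HbR) volumes).
    """
    if E is None:
        E = ExtinctionMatrix()
    Einv = E.inverse
    d690 = np.asarray(dmua[0], dtype=float)
    d850 = np.asarray(dmua[1], dtype=float)
    hbo = Einv[0, 0] * d690 + Einv[0, 1] * d850
    hbr = Einv[1, 0] * d690 + Einv[1, 1] * d850
    if hbo.shape == ():
        return HbPerturbation(float(hbo), float(hbr))
    return hbo, hbr
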