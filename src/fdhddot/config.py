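"""Structured run configuration (TOML) for the frequency-sweep pipeline.

The configuration groups the phantom geometry, optode array, region of
interest, regularization, noise model, spectroscopy table and sweep
protocol.  Defaults reproduce the desk-scale study conditions: a
120 x 120 x 60 mm five-layer slab at 2 mm voxels, a 7 x 7 checkerboard
array at 13 mm pitch, modulation frequencies 0-1000 MHz in 100 MHz steps,
NN3 and NN4 channel sets, and the empirical noise model.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .inversion import RegularizationParams
from .noise import DEFAULT_NOISE_COEFFS
from .spectroscopy import DEFAULT_EXTINCTION_MM_UM

DEFAULT_FREQUENCIES = tuple(float(f) for f in range(0, 1001, 100))


@dataclass
class SweepConfig:
    # [phantom]
    layer_thicknesses: dict = field(
        default_factory=lambda: {"scalp": 4.0, "skull": 7.0, "csf": 2.0, "gray": 4.0}
    )
    lateral_extent: tuple[float, float] = (120.0, 120.0)
    depth_extent: float = 60.0
    voxel_size: float = 2.0
    # [array]
    pitch: float = 13.0
    n_rows: int = 7
    n_cols: int = 7
    # [roi]
    lateral_margin: float = 10.0
    sensitivity_floor: float = 1e-5
    # [sweep]
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    nn_sets: tuple[int, ...] = (3, 4)
    noise_arms: tuple[bool, ...] = (False, True)
    realizations: int = 3  # noise realizations per seed voxel
    seed_mode: str = "patch"  # column | patch | full
    patch_size: int = 5  # lateral patch of seed columns (patch mode)
    patch_spacing_vox: int = 2  # voxels between seed columns
    # [regularization]
    lambda1_rel: float = 0.01
    lambda2_rel: float = 0.1
    reg_variant: str = "sqrt"
    # [noise]
    noise_coeffs: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_COEFFS))
    noise_coupled: bool = True
    noise_scale: float = 1.0  # per-datum averaging factor applied to sigma
    # [spectroscopy]
    extinction: dict = field(default_factory=lambda: dict(DEFAULT_EXTINCTION_MM_UM))
    dHbO2_uM: float = 3.8
    dHbR_uM: float = -1.8

    def regularization(self) -> RegularizationParams:
        return RegularizationParams(
            self.lambda1_rel, self.lambda2_rel, self.reg_variant
        )

    def validate(self) -> None:
        if any(f < 0 for f in self.frequencies):
            raise ValueError("frequencies must be non-negative")
        if any(n not in (3, 4) for n in self.nn_sets):
            raise ValueError("nn_sets entries must be 3 or 4")
        if 0.0 not in self.frequencies:
            raise ValueError(
                "frequency 0 (CW) must be present for FD-vs-CW ratios"
            )
        if self.seed_mode not in ("column", "patch", "full"):
            raise ValueError("seed_mode must be column, patch, or full")
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")

    def to_dict(self) -> dict:
        """JSON-serializable view (tuple keys flattened to strings)."""
        out = asdict(self)
        out["noise_coeffs"] = {
            f"{wl}_{dtype}": list(v) for (wl, dtype), v in self.noise_coeffs.items()
        }
        out["extinction"] = {
            f"{chrom}_{wl}": v for (chrom, wl), v in self.extinction.items()
        }
        return out


_KEY_TABLES = {
    "phantom": (
        "layer_thicknesses", "lateral_extent", "depth_extent", "voxel_size"
    ),
    "array": ("pitch", "n_rows", "n_cols"),
    "roi": ("lateral_margin", "sensitivity_floor"),
    "sweep": (
        "frequencies", "nn_sets", "noise_arms", "realizations",
        "seed_mode", "patch_size", "patch_spacing_vox",
    ),
    "regularization": ("lambda1_rel", "lambda2_rel", "reg_variant"),
    "noise": ("noise_coupled",),
    "spectroscopy": ("dHbO2_uM", "dHbR_uM"),
}


def load_config(path: str | Path) -> SweepConfig:
    """Load a TOML run configuration; unspecified keys keep their defaults.

    Sections: [phantom], [array], [roi], [sweep], [regularization],
    [noise], [spectroscopy].  Noise coefficients may be overridden per
    wavelength and datum type as e.g.
    ``[noise.coeffs.intensity] 690 = [a, b, c, d, g]``; extinction entries
    as ``[spectroscopy.extinction] HbO2_690 = value``.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = SweepConfig()
    for section, keys in _KEY_TABLES.items():
        table = raw.get(section, {})
        for key in keys:
            if key in table:
                value = table[key]
                if isinstance(value, list):
                    value = tuple(value)
                setattr(cfg, key, value)
    for dtype in ("intensity", "phase"):
        for wl_str, coeffs in (
            raw.get("noise", {}).get("coeffs", {}).get(dtype, {}).items()
        ):
            cfg.noise_coeffs[(int(wl_str), dtype)] = tuple(coeffs)
    for key, value in raw.get("spectroscopy", {}).get("extinction", {}).items():
        chrom, wl = key.rsplit("_", 1)
        cfg.extinction[(chrom, int(wl))] = float(value)
    cfg.validate()
    return cfg


def coarse_profile() -> SweepConfig:
    """Default desk-scale sweep configuration."""
    return SweepConfig()


def full_profile() -> SweepConfig:
    """Heavier configuration: denser seed coverage and more realizations."""
    return SweepConfig(seed_mode="full", realizations=5)
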