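"""Layered head phantom, high-density optode array, and channel enumeration.

The phantom is a voxelized five-layer slab (scalp, skull, CSF, gray matter,
white matter) standing in for MRI-derived subject head models.  A flat slab
preserves the depth structure that drives every image-quality metric while
keeping a regular grid for the finite-volume diffusion solver.  Optodes are
interleaved on a checkerboard lattice whose pitch reproduces the four
nearest-neighbor source-detector separations of a high-density grid
(~13, 29, 39, 47 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TISSUES = ("scalp", "skull", "csf", "gray", "white")
WAVELENGTHS = (690, 850)

#: Baseline optical properties per (tissue, wavelength): (mua mm^-1, musp mm^-1).
#: Literature values for adult head tissue at 690 and 850 nm.
DEFAULT_PROPERTIES: dict[tuple[str, int], tuple[float, float]] = {
    ("scalp", 690): (0.0159, 0.8000),
    ("scalp", 850): (0.0190, 0.6400),
    ("skull", 690): (0.0101, 1.0000),
    ("skull", 850): (0.0139, 0.8400),
    ("csf", 690): (0.0040, 0.3000),
    ("csf", 850): (0.0040, 0.3000),
    ("gray", 690): (0.0201, 0.9727),
    ("gray", 850): (0.0192, 0.6726),
    ("white", 690): (0.0171, 1.3333),
    ("white", 850): (0.0208, 1.0107),
}

#: Refractive index of tissue (all layers) and the surrounding air.
DEFAULT_REFRACTIVE_INDEX = 1.4

#: Nearest-neighbor class separations (mm) on the 13-mm checkerboard lattice:
#: p, p*sqrt(5), 3p, p*sqrt(13).
NN_SEPARATIONS = (13.0, 29.068883707497267, 39.0, 46.87216658103186)

#: Half-width (mm) of the separation window used to assign NN classes.
NN_WINDOW = 1.0


class InvalidGeometryError(ValueError):
    """Raised for non-positive or inconsistent phantom geometry."""


class OutOfBoundsError(ValueError):
    """Raised when an optode array does not fit on the phantom surface."""


class DegenerateROIError(ValueError):
    """Raised when the requested region of interest is empty."""


@dataclass(frozen=True)
class TissueProperties:
    """Optical properties of one tissue at one wavelength."""

    tissue_label: str
    mua: float  # absorption coefficient, mm^-1
    musp: float  # reduced scattering coefficient, mm^-1
    wavelength: int  # nm
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX

    def __post_init__(self) -> None:
        if self.mua <= 0 or self.musp <= 0:
            raise ValueError("mua and musp must be positive")


def default_property_table(
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX,
) -> dict[tuple[str, int], TissueProperties]:
    """Property table with the default five-tissue values at 690 and 850 nm."""
    return {
        (tissue, wl): TissueProperties(tissue, mua, musp, wl, refractive_index)
        for (tissue, wl), (mua, musp) in DEFAULT_PROPERTIES.items()
    }


@dataclass
class HeadPhantom:
    """Voxelized labeled tissue volume.

    Axes are (x, y, z) with +z pointing into the head; voxel ``(i, j, k)``
    spans ``[i*h, (i+1)*h] x ... x [k*h, (k+1)*h]`` in mm, so the air
    interface is the plane z = 0.  ``depth_map`` holds the distance from each
    voxel center to that plane, i.e. ``(k + 0.5) * h``.
    """

    voxel_size: float
    labels: np.ndarray  # integer index into TISSUES, shape (nx, ny, nz)
    properties: dict[tuple[str, int], TissueProperties] = field(
        default_factory=default_property_table
    )

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise InvalidGeometryError("voxel_size must be positive")
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise InvalidGeometryError("labels must be a 3-D volume")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def surface_mask(self) -> np.ndarray:
        """Air-facing voxels: the k = 0 layer of the slab."""
        mask = np.zeros(self.grid_shape, dtype=bool)
        mask[:, :, 0] = True
        return mask

    @property
    def depth_map(self) -> np.ndarray:
        """Distance (mm) from each voxel center to the outer surface plane."""
        nx, ny, nz = self.grid_shape
        depth = (np.arange(nz) + 0.5) * self.voxel_size
        return np.broadcast_to(depth, (nx, ny, nz)).copy()

    @property
    def brain_mask(self) -> np.ndarray:
        gray = TISSUES.index("gray")
        white = TISSUES.index("white")
        return (self.labels == gray) | (self.labels == white)

    def tissue_of(self, label_index: int) -> str:
        return TISSUES[label_index]

    def props(self, tissue: str, wavelength: int) -> TissueProperties:
        return self.properties[(tissue, wavelength)]

    def mua_volume(self, wavelength: int) -> np.ndarray:
        """Per-voxel absorption coefficient (mm^-1)."""
        lut = np.array(
            [self.properties[(t, wavelength)].mua for t in TISSUES]
        )
        return lut[self.labels]

    def musp_volume(self, wavelength: int) -> np.ndarray:
        """Per-voxel reduced scattering coefficient (mm^-1)."""
        lut = np.array(
            [self.properties[(t, wavelength)].musp for t in TISSUES]
        )
        return lut[self.labels]

    def refractive_index_volume(self, wavelength: int) -> np.ndarray:
        lut = np.array(
            [self.properties[(t, wavelength)].refractive_index for t in TISSUES]
        )
        return lut[self.labels]

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates (mm) along each axis."""
        h = self.voxel_size
        return tuple((np.arange(n) + 0.5) * h for n in self.grid_shape)


@dataclass
class OptodeArray:
    """Source and detector positions (mm) on the phantom surface plane."""

    source_positions: np.ndarray  # (n_src, 3)
    detector_positions: np.ndarray  # (n_det, 3)

    def __post_init__(self) -> None:
        self.source_positions = np.atleast_2d(
            np.asarray(self.source_positions, dtype=float)
        )
        self.detector_positions = np.atleast_2d(
            np.asarray(self.detector_positions, dtype=float)
        )

    @property
    def n_sources(self) -> int:
        return len(self.source_positions)

    @property
    def n_detectors(self) -> int:
        return len(self.detector_positions)


@dataclass
class MeasurementSet:
    """Enumerated source-detector channels with separations and NN classes.

    The NN sets are cumulative: ``max_nn = 3`` keeps classes 1-3, ``max_nn = 4``
    keeps classes 1-4, so the NN4 channel list strictly contains the NN3 list.
    """

    channels: np.ndarray  # structured: (src, det, sep_mm, nn)
    max_nn: int

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def separations(self) -> np.ndarray:
        return self.channels["sep_mm"]

    def subset(self, max_nn: int) -> "MeasurementSet":
        """Cumulative NN subset (e.g. NN3 from an NN4 set)."""
        if max_nn > self.max_nn:
            raise ValueError("cannot extend a measurement set by subsetting")
        keep = self.channels["nn"] <= max_nn
        return MeasurementSet(self.channels[keep], max_nn)


def build_layered_slab(
    layer_thicknesses: dict[str, float] | None = None,
    lateral_extent: tuple[float, float] = (120.0, 120.0),
    depth_extent: float = 60.0,
    voxel_size: float = 2.0,
    property_table: dict[tuple[str, int], TissueProperties] | None = None,
) -> HeadPhantom:
    """Build the five-layer slab phantom.

    Parameters
    ----------
    layer_thicknesses
        Thickness (mm) of scalp, skull, csf and gray layers in anatomical
        order; the white-matter layer fills the remaining depth.  Defaults to
        scalp 4, skull 7, CSF 2, gray 4 mm.
    lateral_extent, depth_extent
        Slab size in mm.
    voxel_size
        Isotropic voxel edge (mm).  Voxels are assigned to layers by their
        center depth, so thicknesses are honored to within half a voxel.
    """
    if layer_thicknesses is None:
        layer_thicknesses = {"scalp": 4.0, "skull": 7.0, "csf": 2.0, "gray": 4.0}
    order = ("scalp", "skull", "csf", "gray")
    thick = [float(layer_thicknesses[t]) for t in order]
    if any(t <= 0 for t in thick):
        raise InvalidGeometryError("layer thicknesses must be positive")
    if voxel_size <= 0:
        raise InvalidGeometryError("voxel_size must be positive")
    lx, ly = float(lateral_extent[0]), float(lateral_extent[1])
    if lx <= 0 or ly <= 0 or depth_extent <= 0:
        raise InvalidGeometryError("extents must be positive")
    if sum(thick) >= depth_extent:
        raise InvalidGeometryError(
            "layers exceed depth_extent; no room for white matter"
        )

    nx = int(round(lx / voxel_size))
    ny = int(round(ly / voxel_size))
    nz = int(round(depth_extent / voxel_size))
    centers_z = (np.arange(nz) + 0.5) * voxel_size
    boundaries = np.cumsum(thick)  # depth of layer bottoms
    # label = number of boundaries above the voxel center; 4 -> white
    labels_z = np.searchsorted(boundaries, centers_z, side="right").astype(np.uint8)
    labels = np.broadcast_to(labels_z, (nx, ny, nz)).copy()
    return HeadPhantom(
        voxel_size=voxel_size,
        labels=labels,
        properties=property_table or default_property_table(),
    )


def place_checkerboard_array(
    phantom: HeadPhantom,
    pitch: float = 13.0,
    n_rows: int = 7,
    n_cols: int = 7,
    center: tuple[float, float] | None = None,
) -> OptodeArray:
    """Interleave sources and detectors on a checkerboard lattice.

    Sources occupy one checkerboard color, detectors the other; lateral
    positions are snapped to surface voxel centers.  A 13-mm pitch reproduces
    the four nearest-neighbor separations p, p*sqrt(5), 3p, p*sqrt(13)
    (13.00, 29.07, 39.00, 46.87 mm).
    """
    if pitch <= 0 or n_rows < 1 or n_cols < 1:
        raise InvalidGeometryError("pitch and grid size must be positive")
    h = phantom.voxel_size
    nx, ny, _ = phantom.grid_shape
    lx, ly = nx * h, ny * h
    if center is None:
        center = (lx / 2.0, ly / 2.0)
    span_x = (n_rows - 1) * pitch
    span_y = (n_cols - 1) * pitch
    x0 = center[0] - span_x / 2.0
    y0 = center[1] - span_y / 2.0
    cx, cy = phantom.voxel_centers_mm()[:2]

    def snap(val: float, centers: np.ndarray) -> float:
        return float(centers[np.argmin(np.abs(centers - val))])

    sources, detectors = [], []
    for i in range(n_rows):
        for j in range(n_cols):
            x = x0 + i * pitch
            y = y0 + j * pitch
            if not (0.0 <= x <= lx and 0.0 <= y <= ly):
                raise OutOfBoundsError(
                    f"optode at ({x:.1f}, {y:.1f}) mm outside the phantom surface"
                )
            pos = (snap(x, cx), snap(y, cy), 0.0)
            (sources if (i + j) % 2 == 0 else detectors).append(pos)
    return OptodeArray(np.array(sources), np.array(detectors))


CHANNEL_DTYPE = np.dtype(
    [("src", np.int32), ("det", np.int32), ("sep_mm", np.float64), ("nn", np.int32)]
)


def enumerate_channels(array: OptodeArray, max_nn: int = 4) -> MeasurementSet:
    """List every source-detector pair within an NN-class separation window.

    A pair belongs to class ``n`` when its lateral separation lies within
    ``NN_WINDOW`` mm of the nominal class-``n`` separation; classes above
    ``max_nn`` are dropped.
    """
    if max_nn not in (1, 2, 3, 4):
        raise ValueError("max_nn must be in 1..4")
    src = array.source_positions[:, :2]
    det = array.detector_positions[:, :2]
    d = np.linalg.norm(src[:, None, :] - det[None, :, :], axis=2)
    records = []
    for s in range(len(src)):
        for t in range(len(det)):
            sep = d[s, t]
            for n, nominal in enumerate(NN_SEPARATIONS[:max_nn], start=1):
                if abs(sep - nominal) <= NN_WINDOW + 1e-9:
                    records.append((s, t, sep, n))
                    break
    channels = np.array(records, dtype=CHANNEL_DTYPE)
    return MeasurementSet(channels, max_nn)


def define_roi(
    phantom: HeadPhantom,
    array: OptodeArray,
    summed_sensitivity: np.ndarray | None = None,
    lateral_margin: float = 10.0,
    sensitivity_floor: float = 1e-5,
) -> np.ndarray:
    """Evaluation region of interest.

    Voxels laterally inside the optode footprint shrunk by ``lateral_margin``
    on every side, intersected with voxels whose summed baseline intensity
    sensitivity is at least ``sensitivity_floor`` times its maximum (the deep
    boundary of optically accessible tissue).
    """
    all_pos = np.vstack([array.source_positions, array.detector_positions])
    xmin, ymin = all_pos[:, :2].min(axis=0) + lateral_margin
    xmax, ymax = all_pos[:, :2].max(axis=0) - lateral_margin
    if xmin > xmax or ymin > ymax:
        raise DegenerateROIError("lateral margin removes the whole footprint")
    cx, cy, _ = phantom.voxel_centers_mm()
    in_x = (cx >= xmin - 1e-9) & (cx <= xmax + 1e-9)
    in_y = (cy >= ymin - 1e-9) & (cy <= ymax + 1e-9)
    mask = np.zeros(phantom.grid_shape, dtype=bool)
    mask[np.ix_(in_x, in_y, np.ones(phantom.grid_shape[2], dtype=bool))] = True
    if summed_sensitivity is not None:
        sens = np.asarray(summed_sensitivity, dtype=float)
        if sens.shape != phantom.grid_shape:
            raise ValueError("sensitivity volume shape mismatch")
        mask &= sens >= sensitivity_floor * sens.max()
    if not mask.any():
        raise DegenerateROIError("empty region of interest")
    return mask
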