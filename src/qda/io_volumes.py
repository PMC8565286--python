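"""Volume I/O and masked voxel indexing.

All spatial data are NIfTI-1 volumes assumed to be already co-registered
across subjects (motion correction and template normalization happen
upstream).  A :class:`BrainMask` defines a fixed, documented bijection
between in-mask grid cells and rows of the masked voxel-by-time matrix,
so that correlation-row indices are reproducible across runs.

Scan order contract: in-mask voxels are enumerated column-major over
(x, y, z) with x varying fastest, all axes ascending (Fortran order of
the 3D grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "BoldVolume",
    "BrainMask",
    "TimeSeriesMatrix",
    "load_bold",
    "save_bold",
    "load_mask",
    "save_mask",
    "build_group_mask",
    "extract_timeseries",
    "map_to_grid",
    "write_map",
    "read_map",
]


def _affine(voxel_size_mm: np.ndarray, origin_mm: np.ndarray) -> np.ndarray:
    aff = np.diag([*np.asarray(voxel_size_mm, dtype=float), 1.0])
    aff[:3, 3] = np.asarray(origin_mm, dtype=float)
    return aff


@dataclass
class BoldVolume:
    """A 4D BOLD acquisition: (x, y, z, t) samples on a regular grid.

    Attributes
    ----------
    data : ndarray
        4D array in arbitrary BOLD units; no non-finite values allowed.
    voxel_size_mm : ndarray
        Edge lengths of one voxel along x, y, z (mm).
    tr_s : float
        Repetition time (temporal sampling interval) in seconds.
    origin_mm : ndarray
        World coordinate of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size_mm: np.ndarray
    tr_s: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D BOLD data, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD volume needs at least 2 timeframes")
        if self.tr_s <= 0:
            raise ValueError(f"repetition time must be positive, got {self.tr_s}")
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contain non-finite values")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class BrainMask:
    """Boolean 3D grid selecting in-brain voxels, with grid geometry."""

    grid: np.ndarray
    voxel_size_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError(f"expected 3D mask grid, got {self.grid.ndim}D")
        if self.n_voxels < 2:
            raise ValueError(
                f"mask must contain at least 2 voxels, got {self.n_voxels}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    def coordinates(self) -> np.ndarray:
        """(V, 3) integer grid coordinates of in-mask voxels in scan order.

        Scan order is column-major over (x, y, z), x fastest, ascending.
        """
        flat = np.flatnonzero(self.grid.ravel(order="F"))
        return np.column_stack(
            np.unravel_index(flat, self.grid.shape, order="F")
        ).astype(np.intp)

    def world_coordinates(self) -> np.ndarray:
        """(V, 3) world-mm coordinates of in-mask voxel centers."""
        return self.origin_mm + self.coordinates() * self.voxel_size_mm

    def check_compatible(self, shape: tuple) -> None:
        if tuple(shape[:3]) != self.grid.shape:
            raise ValueError(
                f"mask grid {self.grid.shape} does not match volume grid "
                f"{tuple(shape[:3])}"
            )


@dataclass
class TimeSeriesMatrix:
    """Masked voxel-by-time matrix: row v is the time course of voxel v.

    ``voxel_index`` records the grid coordinate of each row, following
    the mask scan order, so rows can be placed back into 3D space.
    """

    values: np.ndarray
    voxel_index: np.ndarray
    tr_s: float
    degenerate: np.ndarray | None = None  # zero-variance rows, set by standardization

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        if self.values.ndim != 2:
            raise ValueError("time-series matrix must be 2D (voxels x time)")
        if len(self.voxel_index) != self.values.shape[0]:
            raise ValueError("voxel_index length must match number of rows")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray) -> "TimeSeriesMatrix":
        return TimeSeriesMatrix(values, self.voxel_index, self.tr_s, self.degenerate)


def load_bold(path: str | Path, tr_s: float | None = None) -> BoldVolume:
    """Load a 4D BOLD NIfTI file.

    The repetition time is taken from the header time step unless
    ``tr_s`` overrides it; a non-positive header TR without an override
    is an error because temporal filtering needs a trustworthy sampling
    rate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"BOLD file not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected 4D BOLD NIfTI, got {img.ndim}D: {path}")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr_s is None:
        if header_tr <= 0:
            raise ValueError(
                f"non-positive TR ({header_tr}) in header of {path}; "
                "pass an explicit TR to override"
            )
        tr_s = header_tr
    affine = img.affine
    return BoldVolume(
        data=np.asarray(img.get_fdata(dtype=np.float64)),
        voxel_size_mm=np.asarray(zooms[:3], dtype=float),
        tr_s=tr_s,
        origin_mm=affine[:3, 3],
    )


def save_bold(vol: BoldVolume, path: str | Path) -> None:
    """Write a BOLD volume as float32 NIfTI with TR in the header."""
    aff = _affine(vol.voxel_size_mm, vol.origin_mm)
    img = nib.Nifti1Image(vol.data.astype(np.float32), aff)
    img.header.set_zooms((*vol.voxel_size_mm, vol.tr_s))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_mask(path: str | Path) -> BrainMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3D mask NIfTI, got {img.ndim}D: {path}")
    return BrainMask(
        grid=np.asarray(img.get_fdata()) > 0,
        voxel_size_mm=np.asarray(img.header.get_zooms()[:3], dtype=float),
        origin_mm=img.affine[:3, 3],
    )


def save_mask(mask: BrainMask, path: str | Path) -> None:
    aff = _affine(mask.voxel_size_mm, mask.origin_mm)
    nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), aff), str(path))


def build_group_mask(masks: list[BrainMask], coverage: float = 1.0) -> BrainMask:
    """Intersect per-subject brain masks into a group-overlap mask.

    With ``coverage=1.0`` (default) a voxel survives only if it is inside
    every subject's mask, matching the overlap of all registered brains.
    Lower coverage keeps voxels present in at least that fraction of
    subjects.
    """
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError(f"mask shape mismatch: {m.shape} vs {shape}")
    frac = np.mean([m.grid for m in masks], axis=0)
    grid = frac >= coverage - 1e-12
    return BrainMask(grid, masks[0].voxel_size_mm, masks[0].origin_mm)


def extract_timeseries(vol: BoldVolume, mask: BrainMask) -> TimeSeriesMatrix:
    """Extract the V x T masked voxel-by-time matrix in mask scan order."""
    mask.check_compatible(vol.shape)
    coords = mask.coordinates()
    values = vol.data[coords[:, 0], coords[:, 1], coords[:, 2], :]
    return TimeSeriesMatrix(values=values, voxel_index=coords, tr_s=vol.tr_s)


def map_to_grid(values: np.ndarray, mask: BrainMask, fill: float = 0.0) -> np.ndarray:
    """Place a length-V vector into a 3D grid (``fill`` outside the mask)."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (mask.n_voxels,):
        raise ValueError(
            f"expected {mask.n_voxels} values, got {values.shape}"
        )
    grid = np.full(mask.shape, fill, dtype=np.float64)
    coords = mask.coordinates()
    grid[coords[:, 0], coords[:, 1], coords[:, 2]] = values
    return grid


def write_map(values: np.ndarray, mask: BrainMask, path: str | Path) -> None:
    """Write a per-voxel map as a float32 NIfTI, 0 outside the mask.

    NaN entries (undefined voxels, e.g. degenerate time courses) are
    preserved as NaN.
    """
    grid = map_to_grid(values, mask)
    aff = _affine(mask.voxel_size_mm, mask.origin_mm)
    nib.save(nib.Nifti1Image(grid.astype(np.float32), aff), str(path))


def read_map(path: str | Path, mask: BrainMask) -> np.ndarray:
    """Read a 3D map NIfTI back into a length-V vector in mask scan order."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3D map NIfTI, got {img.ndim}D: {path}")
    mask.check_compatible(img.shape)
    grid = np.asarray(img.get_fdata(dtype=np.float64))
    coords = mask.coordinates()
    return grid[coords[:, 0], coords[:, 1], coords[:, 2]]
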