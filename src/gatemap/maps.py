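"""Density-map container, I/O and the shared map primitives.

A :class:`DensityMap` is a 3D scalar grid on a cubic lattice.  The array is
indexed ``grid[ix, iy, iz]`` and the physical position of voxel ``(i, j, k)``
is ``origin + voxel * (i, j, k)`` in Angstroms.  By convention the channel
pore axis is Z and Z = 0 lies at mid-membrane, with the extracellular side
at positive Z.

All comparisons (correlation, averaging, t statistics, FSC) require
congruent grids: same shape, same voxel size.  A trilinear resampling
utility is provided to bring externally deposited maps onto a common grid.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import gemmi
import numpy as np
from scipy import ndimage


@dataclasses.dataclass
class DensityMap:
    """3D density on a cubic grid.

    Parameters
    ----------
    grid : ndarray, shape (nx, ny, nz)
        Scalar density values; stored as float32 or float64.
    voxel : float
        Cubic voxel edge in Angstroms.
    origin : tuple of 3 floats
        Position of voxel (0, 0, 0) in Angstroms.
    """

    grid: np.ndarray
    voxel: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("density grid must be 3-dimensional")
        if not self.voxel > 0:
            raise ValueError("voxel size must be positive")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("density grid contains non-finite values")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def congruent(self, other: "DensityMap") -> bool:
        return (
            self.shape == other.shape
            and abs(self.voxel - other.voxel) < 1e-6 * self.voxel
        )

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel, self.origin)

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical x, y, z coordinates of every voxel (broadcastable)."""
        nx, ny, nz = self.shape
        x = self.origin[0] + self.voxel * np.arange(nx)[:, None, None]
        y = self.origin[1] + self.voxel * np.arange(ny)[None, :, None]
        z = self.origin[2] + self.voxel * np.arange(nz)[None, None, :]
        return x, y, z

    def z_axis(self) -> np.ndarray:
        """Z coordinate of each z-plane."""
        return self.origin[2] + self.voxel * np.arange(self.shape[2])


@dataclasses.dataclass
class Mask:
    """Boolean voxel selection congruent with a DensityMap."""

    values: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3-dimensional")
        if not self.values.any():
            raise ValueError("mask selects no voxels")


def _check_congruent(a: DensityMap, b: DensityMap) -> None:
    if not a.congruent(b):
        raise ValueError(
            f"maps are not congruent: {a.shape}@{a.voxel} vs {b.shape}@{b.voxel}"
        )


# ---------------------------------------------------------------------------
# MRC I/O (MRC2014, mode 2 floats) via gemmi
# ---------------------------------------------------------------------------

def write_map(dmap: DensityMap, path: str) -> None:
    """Write a map as MRC mode-2 with voxel size and origin in the header."""
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.asarray(dmap.grid, dtype=np.float32, order="C"))
    nx, ny, nz = dmap.shape
    ccp4.grid.unit_cell = gemmi.UnitCell(
        nx * dmap.voxel, ny * dmap.voxel, nz * dmap.voxel, 90.0, 90.0, 90.0
    )
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    # MRC2014 ORIGIN record (words 50-52)
    for word, value in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(word, value)
    ccp4.write_ccp4_map(str(path))


def read_map(path: str) -> DensityMap:
    """Read an MRC/CCP4 map; rejects non-orthogonal cells and non-cubic voxels."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    cell = ccp4.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3
        and abs(cell.beta - 90) < 1e-3
        and abs(cell.gamma - 90) < 1e-3
    ):
        raise ValueError(f"non-orthogonal cell in {path}: {cell}")
    spacing = ccp4.grid.spacing
    if max(spacing) - min(spacing) > 1e-3 * max(spacing):
        raise ValueError(f"non-cubic voxel in {path}: spacing {spacing}")
    origin = tuple(ccp4.header_float(w) for w in (50, 51, 52))
    grid = np.array(ccp4.grid.array, dtype=np.float32)
    return DensityMap(grid, float(spacing[0]), origin)


# ---------------------------------------------------------------------------
# Filtering, masking, averaging, correlation
# ---------------------------------------------------------------------------

#: width of the cosine edge of the lowpass mask, in Fourier voxels
COSINE_EDGE_VOXELS = 5


def lowpass(dmap: DensityMap, cutoff: float) -> DensityMap:
    """Lowpass filter to ``cutoff`` (A) with a soft cosine-edged Fourier mask.

    Frequencies below 1/cutoff pass unchanged; the mask rolls off over a
    cosine edge of :data:`COSINE_EDGE_VOXELS` Fourier voxels to suppress
    ringing.  The mean density (zero frequency) is always preserved.
    """
    if cutoff < 2 * dmap.voxel:
        raise ValueError(
            f"cutoff {cutoff} A below Nyquist limit {2 * dmap.voxel} A"
        )
    freqs = [np.fft.fftfreq(n, d=dmap.voxel) for n in dmap.shape]
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij", sparse=True)
    f = np.sqrt(fx**2 + fy**2 + fz**2)
    f_cut = 1.0 / cutoff
    # edge width in 1/A: one Fourier voxel = 1/(n*voxel) along each axis
    df = COSINE_EDGE_VOXELS / (max(dmap.shape) * dmap.voxel)
    filt = np.ones_like(f)
    edge = (f >= f_cut) & (f < f_cut + df)
    filt[edge] = 0.5 * (1 + np.cos(np.pi * (f[edge] - f_cut) / df))
    filt[f >= f_cut + df] = 0.0
    out = np.fft.ifftn(np.fft.fftn(dmap.grid) * filt).real
    return DensityMap(out.astype(dmap.grid.dtype, copy=False), dmap.voxel, dmap.origin)


def central_mask(dmap: DensityMap, fraction: float = 2.0 / 3.0) -> Mask:
    """Mask selecting the central ``fraction`` of Z planes (full XY).

    Used to confine map comparisons to the central part of the molecule
    along its long axis, where discrimination between conformations is
    strongest.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    nz = dmap.shape[2]
    keep = max(1, int(round(fraction * nz)))
    lo = (nz - keep) // 2
    values = np.zeros(dmap.shape, dtype=bool)
    values[:, :, lo : lo + keep] = True
    return Mask(values, f"central {fraction:.3f} of {nz} z-planes")


def average(maps: Sequence[DensityMap]) -> DensityMap:
    """Voxel-wise arithmetic mean of congruent maps."""
    if not maps:
        raise ValueError("cannot average an empty list of maps")
    first = maps[0]
    acc = np.zeros(first.shape, dtype=np.float64)
    for m in maps:
        _check_congruent(first, m)
        acc += m.grid
    acc /= len(maps)
    return DensityMap(acc, first.voxel, first.origin)


def correlation(a: DensityMap, b: DensityMap, mask: Mask | None = None) -> float:
    """Pearson correlation coefficient between two maps over masked voxels.

    Mean-subtracted and variance-normalised, hence invariant to linear
    rescaling of either map.  Raises if either map has zero variance
    inside the mask.
    """
    _check_congruent(a, b)
    if mask is not None:
        if mask.values.shape != a.shape:
            raise ValueError("mask shape does not match map shape")
        va = a.grid[mask.values].astype(np.float64)
        vb = b.grid[mask.values].astype(np.float64)
    else:
        va = a.grid.ravel().astype(np.float64)
        vb = b.grid.ravel().astype(np.float64)
    va = va - va.mean()
    vb = vb - vb.mean()
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("zero variance inside mask")
    return float(np.dot(va, vb) / (na * nb))


def section_correlations(
    a: DensityMap, b: DensityMap, mask: Mask | None = None
) -> np.ndarray:
    """Per-Z-section Pearson correlations (sections with no mask voxels -> nan)."""
    _check_congruent(a, b)
    sel = mask.values if mask is not None else np.ones(a.shape, dtype=bool)
    out = np.full(a.shape[2], np.nan)
    for k in range(a.shape[2]):
        m = sel[:, :, k]
        if m.sum() < 2:
            continue
        va = a.grid[:, :, k][m].astype(np.float64)
        vb = b.grid[:, :, k][m].astype(np.float64)
        va -= va.mean()
        vb -= vb.mean()
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            continue
        out[k] = np.dot(va, vb) / (na * nb)
    return out


def resample_to(dmap: DensityMap, reference: DensityMap) -> DensityMap:
    """Trilinearly resample ``dmap`` onto the grid of ``reference``.

    Intended for bringing deposited maps with differing voxel sizes onto a
    common grid before comparison.  Points falling outside ``dmap`` are
    filled with its mean edge value (0th-order extension).
    """
    nx, ny, nz = reference.shape
    ix = (reference.origin[0] + reference.voxel * np.arange(nx) - dmap.origin[0]) / dmap.voxel
    iy = (reference.origin[1] + reference.voxel * np.arange(ny) - dmap.origin[1]) / dmap.voxel
    iz = (reference.origin[2] + reference.voxel * np.arange(nz) - dmap.origin[2]) / dmap.voxel
    gx, gy, gz = np.meshgrid(ix, iy, iz, indexing="ij")
    out = ndimage.map_coordinates(
        np.asarray(dmap.grid, dtype=np.float64),
        np.stack([gx.ravel(), gy.ravel(), gz.ravel()]),
        order=1,
        mode="nearest",
    ).reshape(reference.shape)
    return DensityMap(out, reference.voxel, reference.origin)
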