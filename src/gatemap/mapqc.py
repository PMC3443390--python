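"""Map quality and symmetry analytics.

Fourier shell correlation (FSC) between two maps measures how far in
spatial frequency their structure agrees; the resolution is conventionally
quoted at the frequency where the curve first falls through 0.5.  Paired
with a reproducible random half-split of an ensemble, this gives the
standard half-dataset resolution estimate.

The five-fold symmetry profile quantifies, section by section along the
pore axis, how much of the azimuthal Fourier power of the density lies in
the pentamer harmonics (n = 5, 10).  For a pseudo-symmetric pentamer this
is a sensitive detector of departures from C5 — e.g. one displaced subunit
lowers the five-fold strength at exactly the sections it disturbs.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .maps import DensityMap, _check_congruent

#: minimum Fourier coefficients per FSC shell before merging outward
MIN_SHELL_COEFFS = 10


@dataclasses.dataclass
class FSCCurve:
    """Per-shell Fourier correlation and the 0.5-criterion resolution."""

    freq: np.ndarray            # shell centre frequencies, 1/A
    fsc: np.ndarray             # correlation per shell, in [-1, 1]
    n_coeffs: np.ndarray        # Fourier coefficients per (merged) shell
    shell_width: float          # nominal width, 1/A
    resolution_at_half: float   # A; 2*voxel if the curve never crosses 0.5

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"freq": self.freq, "fsc": self.fsc, "n_coeffs": self.n_coeffs})


def fsc(a: DensityMap, b: DensityMap, shell_width: float | None = None) -> FSCCurve:
    """Fourier shell correlation between two congruent maps.

    Complex Fourier coefficients are binned into spherical shells of
    ``shell_width`` (default: one Fourier voxel of the largest dimension);
    shells with fewer than 10 coefficients are merged outward.  The curve
    is real-valued: ``Re(sum a conj(b)) / sqrt(sum|a|^2 sum|b|^2)`` per
    shell.  ``resolution_at_half`` interpolates the first downward crossing
    of 0.5 linearly between shell centres.
    """
    _check_congruent(a, b)
    fa = np.fft.fftn(a.grid)
    fb = np.fft.fftn(b.grid)
    freqs = [np.fft.fftfreq(n, d=a.voxel) for n in a.shape]
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij", sparse=True)
    fmag = np.sqrt(fx**2 + fy**2 + fz**2)
    nyquist = 1.0 / (2.0 * a.voxel)
    if shell_width is None:
        shell_width = 1.0 / (max(a.shape) * a.voxel)

    shell = np.floor(fmag / shell_width).astype(int)
    usable = fmag <= nyquist
    nshell = int(shell[usable].max()) + 1
    flat_shell = shell[usable].ravel()
    num = np.bincount(flat_shell, weights=(fa * np.conj(fb)).real[usable].ravel(), minlength=nshell)
    da = np.bincount(flat_shell, weights=(np.abs(fa) ** 2)[usable].ravel(), minlength=nshell)
    db = np.bincount(flat_shell, weights=(np.abs(fb) ** 2)[usable].ravel(), minlength=nshell)
    count = np.bincount(flat_shell, minlength=nshell)

    # merge sparse shells outward
    groups: list[tuple[float, float, float, float, int]] = []
    acc = np.zeros(4)
    cnt = 0
    for s in range(nshell):
        acc += (num[s], da[s], db[s], (s + 0.5) * shell_width * count[s])
        cnt += int(count[s])
        if cnt >= MIN_SHELL_COEFFS:
            groups.append((*acc, cnt))
            acc = np.zeros(4)
            cnt = 0
    if cnt > 0 and groups:
        last = groups.pop()
        groups.append(tuple(np.add(last[:4], acc)) + (last[4] + cnt,))
    elif cnt > 0:
        groups.append((*acc, cnt))

    freq_c = np.array([g[3] / g[4] for g in groups])
    denom = np.array([np.sqrt(g[1] * g[2]) for g in groups])
    vals = np.array([g[0] for g in groups]) / np.where(denom > 0, denom, 1.0)
    vals[denom == 0] = 0.0
    counts = np.array([g[4] for g in groups], dtype=int)

    res = 2.0 * a.voxel
    below = np.where(vals < 0.5)[0]
    if below.size and below[0] > 0:
        i = below[0]
        f0, f1 = freq_c[i - 1], freq_c[i]
        v0, v1 = vals[i - 1], vals[i]
        fc = f0 + (0.5 - v0) * (f1 - f0) / (v1 - v0)
        res = float(1.0 / fc)
    elif below.size and below[0] == 0:
        res = float(1.0 / freq_c[0])
    return FSCCurve(freq_c, vals, counts, float(shell_width), res)


def half_split(items: Sequence, seed: int = 0) -> tuple[list, list]:
    """Random disjoint half-split of an ensemble (sizes differ by at most 1),
    reproducible from the seed."""
    items = list(items)
    if len(items) < 4:
        raise ValueError("need at least 4 maps to form half datasets")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    half = len(items) // 2
    a = [items[i] for i in order[:half]]
    b = [items[i] for i in order[half:]]
    return a, b


@dataclasses.dataclass
class SymmetryProfile:
    """Relative five-fold harmonic strength per 1 A section."""

    z: np.ndarray                 # section heights, A
    relative_5fold: np.ndarray    # power in n in {5, 10} over n in {1..12}
    relative_only5: np.ndarray    # power in n = 5 alone over n in {1..12}

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"z": self.z, "relative_5fold": self.relative_5fold, "relative_only5": self.relative_only5}
        )


#: angular sampling step for ring resampling, degrees
ANGULAR_STEP_DEG = 1.0


def envelope_radius(dmap: DensityMap, axis_xy: tuple[float, float]) -> float:
    """Largest radius at which the density still exceeds mean + 1 sigma —
    a simple molecular-envelope estimate used as the default annulus outer
    radius."""
    thresh = float(dmap.grid.mean() + dmap.grid.std())
    x, y, _ = dmap.coords()
    r = np.sqrt((x - axis_xy[0]) ** 2 + (y - axis_xy[1]) ** 2)
    above = dmap.grid > thresh
    if not above.any():
        return float(r.max() / 2)
    return float(np.broadcast_to(r, dmap.shape)[above].max())


def fivefold_strength(
    dmap: DensityMap,
    axis_xy: tuple[float, float] | None = None,
    z_range: tuple[float, float] | None = None,
    spacing: float = 1.0,
    annulus: tuple[float, float | None] = (8.0, None),
    harmonics: tuple[int, ...] = (5, 10),
    total_range: tuple[int, int] = (1, 12),
) -> SymmetryProfile:
    """Relative strength of the pentamer harmonic along the pore axis.

    For each section (1 A spacing by default) the density is resampled on
    rings about the axis at 1 A radial steps across the annulus and 1 deg
    angular steps; the azimuthal power spectrum is accumulated over radii
    and the five-fold strength is the power in harmonics {5, 10} divided by
    the total in n = 1..12 (n = 0, the mean, carries no symmetry
    information and is excluded).

    ``axis_xy=None`` centres the axis on the density centre of mass;
    ``annulus=(inner, None)`` extends the outer radius to the molecular
    envelope.  The profile is invariant to map scaling and to rotation
    about the axis.
    """
    if axis_xy is None:
        com = ndimage.center_of_mass(np.clip(dmap.grid, 0, None))
        axis_xy = (
            dmap.origin[0] + com[0] * dmap.voxel,
            dmap.origin[1] + com[1] * dmap.voxel,
        )
    r_in, r_out = annulus
    if r_out is None:
        r_out = envelope_radius(dmap, axis_xy)
    if r_out <= r_in:
        raise ValueError(f"annulus outer radius {r_out} <= inner radius {r_in}")
    half_x = min(axis_xy[0] - dmap.origin[0], dmap.origin[0] + dmap.voxel * (dmap.shape[0] - 1) - axis_xy[0])
    half_y = min(axis_xy[1] - dmap.origin[1], dmap.origin[1] + dmap.voxel * (dmap.shape[1] - 1) - axis_xy[1])
    if r_out > min(half_x, half_y):
        raise ValueError("annulus extends outside the map grid")
    zs_all = dmap.z_axis()
    if z_range is None:
        z_range = (zs_all[0], zs_all[-1])
    z_values = np.arange(z_range[0], z_range[1] + 1e-9, spacing)

    ang = np.radians(np.arange(0.0, 360.0, ANGULAR_STEP_DEG))
    radii = np.arange(r_in, r_out + 1e-9, 1.0)
    cos_a, sin_a = np.cos(ang), np.sin(ang)

    n_low, n_high = total_range
    rel, rel5 = [], []
    for z in z_values:
        power = np.zeros(n_high + 1)
        for r in radii:
            gx = (axis_xy[0] + r * cos_a - dmap.origin[0]) / dmap.voxel
            gy = (axis_xy[1] + r * sin_a - dmap.origin[1]) / dmap.voxel
            gz = np.full_like(gx, (z - dmap.origin[2]) / dmap.voxel)
            ring = ndimage.map_coordinates(
                np.asarray(dmap.grid, dtype=np.float64), np.stack([gx, gy, gz]), order=1, mode="nearest"
            )
            coeff = np.fft.rfft(ring)
            p = np.abs(coeff[: n_high + 1]) ** 2
            power[: len(p)] += p
        total = power[n_low : n_high + 1].sum()
        if total <= 0:
            rel.append(0.0)
            rel5.append(0.0)
        else:
            rel.append(sum(power[n] for n in harmonics if n_low <= n <= n_high) / total)
            rel5.append(power[5] / total if n_low <= 5 <= n_high else 0.0)
    return SymmetryProfile(z_values, np.asarray(rel), np.asarray(rel5))
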