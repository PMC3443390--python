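"""Sphere-probe pore-radius profiling along the channel axis.

At each axial level Z the limiting radius is the radius of the largest
sphere, centred in that Z plane near the pore axis, that touches no van
der Waals sphere of the model:

    R(z) = max over centre c in plane z of  min over atoms a of (|c - a| - vdw(a))

the classical pore-dimension algorithm of HOLE.  The in-plane maximisation
is deterministic: a coarse scan of the disc around the axis locates the
most promising cells, which are refined by local optimisation,
warm-started from the previous section when computing a profile.  The limiting diameter of the channel in
a Z window is twice the smallest limiting radius found there.

Note that sphere-probe dimensions depend on the van der Waals radii
assumed and on side-chain placement; absolute values carry ~0.5-1 A
systematic uncertainty, comparisons between conformations much less.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize

from .models import AtomicModel

#: simple element-based van der Waals radii (A); the phantom's Calpha-only
#: pseudo-atoms get an inflated radius standing in for a full residue
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "CA_PHANTOM": 2.00,
}

#: half-width of the atom-inclusion slab around each section, A
SLAB_HALF_WIDTH = 6.0
#: coarse-scan step and number of scan cells promoted to local refinement
SCAN_STEP = 0.5
N_REFINE = 4
#: the probe centre is confined within this distance of the pore axis
MAX_AXIS_OFFSET = 5.0


@dataclasses.dataclass
class PoreProfile:
    """Limiting pore radius versus axial coordinate (mid-membrane Z = 0)."""

    z: np.ndarray
    radius: np.ndarray
    center_x: np.ndarray
    center_y: np.ndarray
    occluded: np.ndarray     # True where the plane admits no positive radius

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z": self.z,
                "radius": self.radius,
                "cx": self.center_x,
                "cy": self.center_y,
                "occluded": self.occluded,
            }
        )


def _atom_radii(model: AtomicModel, radii: dict[str, float]) -> np.ndarray:
    if "element" in model.atoms.columns:
        try:
            return model.atoms["element"].map(radii).to_numpy(dtype=float)
        except (TypeError, ValueError):
            pass
    return np.full(len(model), radii.get("CA_PHANTOM", 2.0))


def _scan_starts(
    axis_xy: tuple[float, float], z: float, coords: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Deterministic coarse scan of the axis disc; the best cells seed the
    local refinement."""
    g = np.arange(-MAX_AXIS_OFFSET, MAX_AXIS_OFFSET + SCAN_STEP / 2, SCAN_STEP)
    gx, gy = np.meshgrid(axis_xy[0] + g, axis_xy[1] + g, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    inside = np.hypot(centers[:, 0] - axis_xy[0], centers[:, 1] - axis_xy[1]) <= MAX_AXIS_OFFSET
    centers = centers[inside]
    d = np.sqrt(
        (centers[:, 0, None] - coords[None, :, 0]) ** 2
        + (centers[:, 1, None] - coords[None, :, 1]) ** 2
        + (z - coords[None, :, 2]) ** 2
    )
    vals = np.min(d - radii[None, :], axis=1)
    order = np.argsort(vals)[::-1]
    return centers[order[:N_REFINE]]


def clearance(center_xy: np.ndarray, z: float, coords: np.ndarray, radii: np.ndarray) -> float:
    """Distance from a probe centre in plane z to the nearest vdW surface."""
    d = np.sqrt(
        (coords[:, 0] - center_xy[0]) ** 2
        + (coords[:, 1] - center_xy[1]) ** 2
        + (coords[:, 2] - z) ** 2
    )
    return float(np.min(d - radii))


def limiting_radius_at(
    model: AtomicModel,
    z: float,
    radii: dict[str, float] | None = None,
    axis_xy: tuple[float, float] = (0.0, 0.0),
    extra_starts: np.ndarray | None = None,
) -> tuple[float, tuple[float, float], bool]:
    """Largest-sphere radius at one axial level.

    Returns ``(radius, (cx, cy), occluded)``.  Atoms within
    :data:`SLAB_HALF_WIDTH` of the plane constrain the probe; the centre
    search scans the axis disc coarsely and refines the best cells (plus
    optional warm starts) with Nelder-Mead.  A negative best clearance is
    clamped to 0 and flagged occluded.
    """
    radii = radii or DEFAULT_RADII
    coords = model.coords()
    rv = _atom_radii(model, radii)
    sel = np.abs(coords[:, 2] - z) <= SLAB_HALF_WIDTH
    if not sel.any():
        raise ValueError(f"no atoms within {SLAB_HALF_WIDTH} A of z = {z}")
    coords = coords[sel]
    rv = rv[sel]

    starts = _scan_starts(axis_xy, z, coords, rv)
    if extra_starts is not None:
        starts = np.vstack([np.atleast_2d(extra_starts), starts])

    axis = np.asarray(axis_xy, dtype=float)

    def objective(c):
        # hard wall keeps the probe in the pore rather than outside the
        # molecule, where clearance grows without bound
        off = np.hypot(c[0] - axis[0], c[1] - axis[1])
        penalty = 1e3 * max(0.0, off - MAX_AXIS_OFFSET) ** 2
        return -clearance(c, z, coords, rv) + penalty

    best_val = -np.inf
    best_c = axis
    for c0 in starts:
        res = optimize.minimize(
            objective,
            c0,
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 200},
        )
        c = res.x
        off = np.hypot(c[0] - axis[0], c[1] - axis[1])
        if off > MAX_AXIS_OFFSET:
            # project boundary solutions back onto the allowed disc
            c = axis + (c - axis) * (MAX_AXIS_OFFSET / off)
        val = clearance(c, z, coords, rv)
        if val > best_val:
            best_val = val
            best_c = c
    occluded = best_val < 0
    return max(best_val, 0.0), (float(best_c[0]), float(best_c[1])), bool(occluded)


def pore_profile(
    model: AtomicModel,
    z_min: float = -20.0,
    z_max: float = 20.0,
    step: float = 1.0,
    radii: dict[str, float] | None = None,
    axis_xy: tuple[float, float] = (0.0, 0.0),
    warm_start: bool = True,
) -> PoreProfile:
    """Limiting radius per section from z_min to z_max.

    Each section's optimisation is warm-started from the previous
    section's best centre, which keeps the probe trajectory continuous
    through the constriction.
    """
    if z_max < z_min:
        raise ValueError("z_max must be >= z_min")
    zs = np.arange(z_min, z_max + 1e-9, step)
    radius = np.empty_like(zs)
    cx = np.empty_like(zs)
    cy = np.empty_like(zs)
    occ = np.zeros(zs.shape, dtype=bool)
    prev = None
    for i, z in enumerate(zs):
        extra = np.array(prev) if (warm_start and prev is not None) else None
        r, c, o = limiting_radius_at(model, z, radii, axis_xy, extra_starts=extra)
        radius[i], (cx[i], cy[i]), occ[i] = r, c, o
        prev = c
    return PoreProfile(zs, radius, cx, cy, occ)


def limiting_diameter(profile: PoreProfile, z_window: tuple[float, float]) -> float:
    """Twice the minimum limiting radius within a Z window."""
    sel = (profile.z >= z_window[0]) & (profile.z <= z_window[1])
    if not sel.any():
        raise ValueError("z window contains no profile points")
    return float(2.0 * profile.radius[sel].min())
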