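"""Toy pentameric-channel phantoms: atomic models and noisy map ensembles.

The phantom emulates the geometry that matters for gating analysis of a
muscle-type pentameric ligand-gated channel, at the level of detail a
~6-20 A density map can support:

* five subunits (``alpha_g``, ``gamma``, ``alpha_d``, ``delta``, ``beta``,
  clockwise viewed from the extracellular side) spaced 72 degrees about the
  pore (Z) axis;
* per subunit a four-helix membrane bundle of ideal alpha-helices
  (1.5 A rise per residue) whose innermost helix (M2) lines the pore, plus
  an extracellular proxy beta-sandwich of two parallel four-strand slabs
  (inner and outer sheet) and a short binding-site loop (loop C proxy);
* a closed state in which every M2 bows in toward the mid-membrane gate
  (the two flexing helices, alpha_g M2 radially and delta M2 tangentially,
  with larger amplitudes than the rest), and an open state in which those
  two helices straighten, the beta subunit's extracellular part shifts
  ~1 A outward with its four membrane helices tilting ~2 degrees in
  sympathy, and the alpha_g loop C rotates toward the binding pocket.

The M2 ring radius is chosen so the closed gate admits a sphere of about
6 A diameter at mid-membrane and opening widens it by roughly 1 A.

Density maps are rendered as Gaussian atom sums lowpassed to a target
resolution, and ensembles of single-"tube" reconstructions are emulated by
adding band-limited Gaussian noise to the state renders.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
import pandas as pd
from scipy import ndimage

from .maps import DensityMap, lowpass
from .models import SUBUNITS, AtomicModel

# ---------------------------------------------------------------------------
# geometry constants (A unless noted)
# ---------------------------------------------------------------------------

HELIX_RISE = 1.5            # per residue along the helix axis
HELIX_CA_RADIUS = 2.3       # Calpha ring radius of an ideal alpha-helix
HELIX_TWIST = 100.0         # degrees per residue
HELIX_NRES = 24             # membrane helix length (36 A span)
MEMBRANE_HALF = HELIX_RISE * (HELIX_NRES - 1) / 2.0   # 17.25

M2_RADIUS = 8.8             # pore-lining ring
M1_M3_RADIUS = 14.5
M4_RADIUS = 19.5
M1_OFFSET_DEG = -22.0       # azimuthal offsets within the subunit wedge
M3_OFFSET_DEG = 22.0

STRAND_NRES = 10
STRAND_RISE = 3.4
SHEET_Z0 = 22.0             # extracellular sheets span SHEET_Z0 .. +30.6
INNER_SHEET_RADIUS = 9.5
OUTER_SHEET_RADIUS = 16.0
STRAND_OFFSETS_DEG = (-15.0, -5.0, 5.0, 15.0)

LOOPC_NRES = 8
LOOPC_RADIUS = 18.0
LOOPC_Z = 40.0

#: anatomical Z windows of the phantom (A): the extracellular leaflet of the
#: membrane, and the lower ligand-binding domain where the sheet slabs pack
OUTER_LEAFLET_Z = (10.0, 17.0)
LOWER_LBD_Z = (22.0, 35.0)

#: default simulation grid: (nx, ny, nz) voxels and origin, at DEFAULT_VOXEL
DEFAULT_VOXEL = 2.0
DEFAULT_RESOLUTION = 8.0
DEFAULT_SHAPE = (32, 32, 48)
DEFAULT_ORIGIN = (-32.0, -32.0, -30.0)

#: noise s.d. relative to phantom peak, calibrated so that reference-based
#: sorting of default ensembles sits just inside its working regime
#: (>=95% correct assignment, intermediates flagged as weak preference)
CALIBRATED_SIGMA = 0.015


class State(str, enum.Enum):
    CLOSED = "closed"
    OPEN = "open"
    INTERMEDIATE = "intermediate"


@dataclasses.dataclass
class ConformationParams:
    """Per-state perturbation amplitudes applied when building a model.

    All displacement magnitudes are >= 0; a value of zero disables the
    corresponding perturbation.  ``gate_bow`` is the symmetric inward bow
    (A) shared by the non-flexing M2 helices in both states.
    """

    state_label: str = "closed"
    beta_displacement: float = 0.0   # A, rigid outward shift of beta EC part
    beta_tilt: float = 0.0           # deg, outward tilt of beta membrane helices
    m2_bend_alpha: float = 1.5       # A, radial inward bow of alpha_g M2
    m2_bend_delta: float = 2.0       # A, bow of delta M2 along delta_bow_dir
    loopC_rotation: float = 0.0      # deg, alpha_g loop C rotation toward pocket
    gate_bow: float = 1.0            # A, common inward bow of remaining M2s
    alpha_distortion: float = 1.0    # A, tangential sheet offset of the two
                                     # alpha subunits (the closed-state strain
                                     # that ligand binding relieves)
    delta_bow_dir: tuple[float, float] = (-0.6, 0.8)   # (radial, tangential)

    def __post_init__(self) -> None:
        for field in ("beta_displacement", "m2_bend_alpha", "m2_bend_delta",
                      "gate_bow", "alpha_distortion"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0")

    @classmethod
    def closed(cls) -> "ConformationParams":
        return cls(state_label="closed")

    @classmethod
    def open(
        cls,
        beta_displacement: float = 1.0,
        beta_tilt: float = 2.0,
        loopC_rotation: float = 10.0,
    ) -> "ConformationParams":
        return cls(
            state_label="open",
            beta_displacement=beta_displacement,
            beta_tilt=beta_tilt,
            m2_bend_alpha=0.0,
            m2_bend_delta=0.0,
            loopC_rotation=loopC_rotation,
            alpha_distortion=0.0,
        )

    @classmethod
    def c5(cls, bow: float = 1.2) -> "ConformationParams":
        """Exactly C5-symmetric phantom: every M2 carries the same radial
        inward bow and no subunit is distorted."""
        return cls(
            state_label="c5",
            m2_bend_alpha=bow,
            m2_bend_delta=bow,
            gate_bow=bow,
            alpha_distortion=0.0,
            delta_bow_dir=(-1.0, 0.0),
        )


@dataclasses.dataclass
class NoiseSpec:
    """Band-limited Gaussian map noise: white noise smoothed to
    ``correlation_length`` and scaled to ``sigma`` times the phantom peak."""

    sigma: float = CALIBRATED_SIGMA
    correlation_length: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")


@dataclasses.dataclass
class EnsembleSpec:
    """Conditions for a simulated ensemble of single-tube reconstructions."""

    n_maps: int = 60
    fraction_open: float = 0.5
    conformations: tuple[ConformationParams, ConformationParams] | None = None
    noise: NoiseSpec = dataclasses.field(default_factory=NoiseSpec)
    voxel: float = DEFAULT_VOXEL
    resolution: float = DEFAULT_RESOLUTION
    fraction_intermediate: float = 0.0
    exact_fractions: bool = False      # allocate state counts deterministically
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    origin: tuple[float, float, float] = DEFAULT_ORIGIN

    def __post_init__(self) -> None:
        if self.n_maps < 2:
            raise ValueError("n_maps must be >= 2")
        if not 0 <= self.fraction_open <= 1:
            raise ValueError("fraction_open must lie in [0, 1]")
        if not 0 <= self.fraction_intermediate <= 1:
            raise ValueError("fraction_intermediate must lie in [0, 1]")
        if self.conformations is None:
            self.conformations = (ConformationParams.closed(), ConformationParams.open())


@dataclasses.dataclass
class MapEnsemble:
    """Simulated single-map reconstructions with ground-truth labels."""

    maps: list[DensityMap]
    labels: list[str]
    spec: EnsembleSpec | None = None

    def __len__(self) -> int:
        return len(self.maps)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _unit(theta_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Radial and tangential unit vectors at azimuth theta."""
    t = np.radians(theta_deg)
    rhat = np.array([np.cos(t), np.sin(t), 0.0])
    that = np.array([-np.sin(t), np.cos(t), 0.0])
    return rhat, that


def _ideal_helix(axis_xy: np.ndarray, phase_deg: float = 0.0) -> np.ndarray:
    """Calpha trace of an ideal vertical alpha-helix centred on z = 0."""
    i = np.arange(HELIX_NRES)
    z = -MEMBRANE_HALF + HELIX_RISE * i
    ang = np.radians(phase_deg + HELIX_TWIST * i)
    x = axis_xy[0] + HELIX_CA_RADIUS * np.cos(ang)
    y = axis_xy[1] + HELIX_CA_RADIUS * np.sin(ang)
    return np.column_stack([x, y, z])


def _bow(coords: np.ndarray, amplitude: float, direction: np.ndarray) -> np.ndarray:
    """Quadratic bow: zero at both helix ends, ``amplitude`` at midpoint."""
    n = len(coords)
    t = np.arange(n) / (n - 1)
    w = 4.0 * t * (1.0 - t)
    return coords + amplitude * w[:, None] * direction[None, :]


def _rotate_about(coords: np.ndarray, point: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of coords about a line (point, axis)."""
    k = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    v = coords - point
    return (
        v * np.cos(a)
        + np.cross(k, v) * np.sin(a)
        + np.outer(v @ k, k) * (1 - np.cos(a))
    ) + point


def subunit_angles() -> dict[str, float]:
    """Azimuth of each subunit centre; ring order is clockwise from the
    extracellular side: alpha_g, gamma, alpha_d, delta, beta."""
    return {name: 90.0 - 72.0 * k for k, name in enumerate(SUBUNITS)}


def build_model(params: ConformationParams) -> AtomicModel:
    """Build the annotated pentamer for one conformational state.

    The unperturbed scaffold is exactly C5 symmetric; all state-dependent
    perturbations (M2 bows, beta displacement and tilt, loop C rotation)
    are applied per subunit on top of it.
    """
    angles = subunit_angles()
    records: list[tuple] = []

    for name, theta in angles.items():
        rhat, that = _unit(theta)
        chunks: dict[str, np.ndarray] = {}

        # membrane helices
        for seg, radius, offset in (
            ("M1", M1_M3_RADIUS, M1_OFFSET_DEG),
            ("M2", M2_RADIUS, 0.0),
            ("M3", M1_M3_RADIUS, M3_OFFSET_DEG),
            ("M4", M4_RADIUS, 0.0),
        ):
            r_seg, _ = _unit(theta + offset)
            axis_xy = (M4_RADIUS if seg == "M4" else radius) * r_seg[:2]
            if seg == "M4":
                axis_xy = M4_RADIUS * rhat[:2]
            chunks[seg] = _ideal_helix(np.asarray(axis_xy), phase_deg=theta)

        # M2 bow (inward = -rhat): per-subunit amplitude and direction
        if name == "alpha_g":
            amp, direction = params.m2_bend_alpha, -rhat
        elif name == "delta":
            dr, dt = params.delta_bow_dir
            direction = dr * rhat + dt * that
            direction = direction / np.linalg.norm(direction)
            amp = params.m2_bend_delta
        else:
            amp, direction = params.gate_bow, -rhat
        if amp > 0:
            chunks["M2"] = _bow(chunks["M2"], amp, direction)

        # extracellular sheets: two slabs of four vertical strands
        for seg, radius in (("inner_sheet", INNER_SHEET_RADIUS), ("outer_sheet", OUTER_SHEET_RADIUS)):
            strands = []
            for off in STRAND_OFFSETS_DEG:
                r_s, _ = _unit(theta + off)
                z = SHEET_Z0 + STRAND_RISE * np.arange(STRAND_NRES)
                xy = radius * r_s[:2]
                strands.append(np.column_stack([np.full(STRAND_NRES, xy[0]), np.full(STRAND_NRES, xy[1]), z]))
            chunks[seg] = np.vstack(strands)

        # loop C proxy: short tangential arc near the binding-site level
        arc = np.radians(theta + np.linspace(8.0, 30.0, LOOPC_NRES))
        chunks["loopC"] = np.column_stack(
            [LOOPC_RADIUS * np.cos(arc), LOOPC_RADIUS * np.sin(arc), np.full(LOOPC_NRES, LOOPC_Z)]
        )

        # state-dependent rigid perturbations
        if name in ("alpha_g", "alpha_d") and params.alpha_distortion > 0:
            for seg in ("inner_sheet", "outer_sheet"):
                chunks[seg] = chunks[seg] + params.alpha_distortion * that
        if name == "beta" and params.beta_displacement > 0:
            for seg in ("inner_sheet", "outer_sheet", "loopC"):
                chunks[seg] = chunks[seg] + params.beta_displacement * rhat
        if name == "beta" and params.beta_tilt != 0:
            pivot = np.array([M1_M3_RADIUS * rhat[0], M1_M3_RADIUS * rhat[1], -MEMBRANE_HALF])
            for seg in ("M1", "M2", "M3", "M4"):
                chunks[seg] = _rotate_about(chunks[seg], pivot, that, params.beta_tilt)
        if name == "alpha_g" and params.loopC_rotation != 0:
            anchor = chunks["loopC"][0]
            chunks["loopC"] = _rotate_about(
                chunks["loopC"], anchor, np.array([0.0, 0.0, 1.0]), params.loopC_rotation
            )

        resi = 1
        for seg in ("M1", "M2", "M3", "M4", "inner_sheet", "outer_sheet", "loopC"):
            for xyz in chunks[seg]:
                records.append((name, seg, resi, xyz[0], xyz[1], xyz[2]))
                resi += 1

    atoms = pd.DataFrame(records, columns=["subunit", "segment", "resi", "x", "y", "z"])
    meta = {
        "name": f"phantom-{params.state_label}",
        "state": params.state_label,
        "params": dataclasses.asdict(params),
        "ring_order": list(SUBUNITS),
    }
    return AtomicModel(atoms, meta)


# ---------------------------------------------------------------------------
# density rendering
# ---------------------------------------------------------------------------

#: real-space Gaussian width given to each atom before resolution lowpass
ATOM_SIGMA = 1.0


def render_density(
    model: AtomicModel,
    voxel: float = DEFAULT_VOXEL,
    resolution: float = DEFAULT_RESOLUTION,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    origin: tuple[float, float, float] = DEFAULT_ORIGIN,
) -> DensityMap:
    """Render a model as a sum of Gaussian atoms, lowpassed to ``resolution``.

    Atom density is deposited with cloud-in-cell (trilinear) weights, blurred
    with a fixed real-space Gaussian, and band-limited by the soft-edged
    Fourier lowpass.  The total integral is proportional to the atom count.
    """
    if voxel > resolution / 3.0:
        raise ValueError(
            f"voxel {voxel} A too coarse for {resolution} A resolution (need <= resolution/3)"
        )
    grid = np.zeros(shape, dtype=np.float64)
    frac = (model.coords() - np.asarray(origin)) / voxel
    base = np.floor(frac).astype(int)
    rem = frac - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (rem[:, 0] if dx else 1 - rem[:, 0])
                    * (rem[:, 1] if dy else 1 - rem[:, 1])
                    * (rem[:, 2] if dz else 1 - rem[:, 2])
                )
                ix, iy, iz = base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz
                ok = (
                    (ix >= 0) & (ix < shape[0])
                    & (iy >= 0) & (iy < shape[1])
                    & (iz >= 0) & (iz < shape[2])
                )
                np.add.at(grid, (ix[ok], iy[ok], iz[ok]), w[ok])
    grid = ndimage.gaussian_filter(grid, sigma=ATOM_SIGMA / voxel)
    dmap = DensityMap(grid, voxel, origin)
    return lowpass(dmap, resolution)


def simulate_ensemble(spec: EnsembleSpec, seed: int | None = None) -> MapEnsemble:
    """Simulate ``spec.n_maps`` noisy single-map reconstructions.

    Each map is the render of its sampled state (closed, open, or the
    closed/open average for intermediates) plus band-limited Gaussian noise.
    Fully reproducible from the seed (``spec.noise.seed`` by default).
    """
    if seed is None:
        seed = spec.noise.seed
    closed_params, open_params = spec.conformations
    renders = {
        State.CLOSED.value: render_density(
            build_model(closed_params), spec.voxel, spec.resolution, spec.shape, spec.origin
        ),
        State.OPEN.value: render_density(
            build_model(open_params), spec.voxel, spec.resolution, spec.shape, spec.origin
        ),
    }
    renders[State.INTERMEDIATE.value] = DensityMap(
        0.5 * (renders["closed"].grid + renders["open"].grid), spec.voxel, spec.origin
    )
    peaks = {k: float(v.grid.max()) for k, v in renders.items()}

    ss = np.random.SeedSequence(seed)
    label_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(spec.n_maps + 1)[1:]

    p_int = spec.fraction_intermediate
    p_open = (1.0 - p_int) * spec.fraction_open
    p_closed = 1.0 - p_int - p_open
    if spec.exact_fractions:
        n_int = round(spec.n_maps * p_int)
        n_open = round((spec.n_maps - n_int) * spec.fraction_open)
        n_closed = spec.n_maps - n_int - n_open
        labels = ["closed"] * n_closed + ["open"] * n_open + ["intermediate"] * n_int
        labels = [labels[i] for i in label_rng.permutation(spec.n_maps)]
    else:
        labels = list(
            label_rng.choice(
                ["closed", "open", "intermediate"], size=spec.n_maps, p=[p_closed, p_open, p_int]
            )
        )

    smooth_vox = spec.noise.correlation_length / spec.voxel
    maps = []
    for label, child in zip(labels, child_seeds):
        clean = renders[label]
        if spec.noise.sigma == 0:
            maps.append(clean.copy())
            continue
        rng = np.random.default_rng(child)
        white = rng.standard_normal(spec.shape)
        smooth = ndimage.gaussian_filter(white, sigma=smooth_vox)
        smooth /= smooth.std()
        grid = clean.grid + spec.noise.sigma * peaks[label] * smooth
        maps.append(DensityMap(grid, spec.voxel, spec.origin))
    return MapEnsemble(maps, labels, spec)
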