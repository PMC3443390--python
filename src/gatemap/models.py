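"""Annotated pentamer models and backbone geometry metrics.

The channel is a heteropentamer whose subunits (named ``alpha_g``, ``gamma``,
``alpha_d``, ``delta``, ``beta``) each contribute four membrane-spanning
helices (M1-M4, with M2 lining the pore) and an extracellular beta-sandwich
summarised here as inner and outer sheets.  An :class:`AtomicModel` stores
one Calpha record per residue together with its subunit and segment
annotation, which is what every geometric comparison in this package is
keyed on.

Conventions: the pore axis is Z, Z = 0 at mid-membrane, extracellular side
positive.  "Radial" means away from the pore axis in the XY plane,
"tangential" means perpendicular to radial in the XY plane
(counter-clockwise viewed from the extracellular side).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

SUBUNITS = ("alpha_g", "gamma", "alpha_d", "delta", "beta")
SEGMENTS = ("M1", "M2", "M3", "M4", "inner_sheet", "outer_sheet", "loopC", "other")

#: ring order maps subunits to PDB chain IDs A-E
CHAIN_IDS = dict(zip(SUBUNITS, "ABCDE"))


@dataclasses.dataclass
class AtomicModel:
    """Calpha model with subunit/segment annotations.

    ``atoms`` columns: subunit, segment, resi, x, y, z (Angstroms).
    """

    atoms: pd.DataFrame
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"subunit", "segment", "resi", "x", "y", "z"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise ValueError(f"model table missing columns: {sorted(missing)}")

    def select(self, subunit: str | None = None, segment: str | None = None) -> "AtomicModel":
        df = self.atoms
        if subunit is not None:
            if subunit not in set(df["subunit"]):
                raise KeyError(f"unknown subunit {subunit!r}")
            df = df[df["subunit"] == subunit]
        if segment is not None:
            if segment not in set(self.atoms["segment"]):
                raise KeyError(f"unknown segment {segment!r}")
            df = df[df["segment"] == segment]
        return AtomicModel(df.reset_index(drop=True), dict(self.meta))

    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)

    def transformed(self, func) -> "AtomicModel":
        """Return a copy with coordinates mapped through ``func((n,3)) -> (n,3)``."""
        df = self.atoms.copy()
        xyz = func(self.coords())
        df[["x", "y", "z"]] = xyz
        return AtomicModel(df, dict(self.meta))


# ---------------------------------------------------------------------------
# PDB + manifest I/O
# ---------------------------------------------------------------------------

def write_model(model: AtomicModel, pdb_path: str, manifest_path: str | None = None) -> None:
    """Write the model as a Calpha-only PDB (one chain per subunit) plus a
    JSON sidecar manifest mapping chains to subunits and residue ranges to
    segments."""
    st = gemmi.Structure()
    st.name = model.meta.get("name", "gatemap-model")
    mdl = gemmi.Model("1")
    manifest: dict = {"chains": {}, "segments": {}}
    for subunit, group in model.atoms.groupby("subunit", sort=False):
        chain_id = CHAIN_IDS.get(subunit, "X")
        chain = gemmi.Chain(chain_id)
        manifest["chains"][chain_id] = subunit
        seg_ranges: dict[str, list[int]] = {}
        for row in group.sort_values("resi").itertuples():
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(row.resi), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(row.x, row.y, row.z)
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
            chain.add_residue(res)
            lo_hi = seg_ranges.setdefault(row.segment, [int(row.resi), int(row.resi)])
            lo_hi[0] = min(lo_hi[0], int(row.resi))
            lo_hi[1] = max(lo_hi[1], int(row.resi))
        mdl.add_chain(chain)
        manifest["segments"][chain_id] = seg_ranges
    st.add_model(mdl)
    st.setup_entities()
    st.write_pdb(str(pdb_path))
    if manifest_path is None:
        manifest_path = str(Path(pdb_path).with_suffix(".json"))
    Path(manifest_path).write_text(json.dumps(manifest, indent=1))


def read_annotated_model(pdb_path: str, manifest_path: str | None = None) -> AtomicModel:
    """Read Calpha coordinates from a PDB file and resolve subunit/segment
    annotations from a JSON manifest.

    The manifest has the form
    ``{"chains": {"A": "alpha_g", ...},
    "segments": {"A": {"M1": [first_resi, last_resi], ...}, ...}}``;
    a segment may also carry a list of ``[first, last]`` ranges for
    discontinuous selections such as the sheets of a beta-sandwich.
    Residues of annotated chains not covered by any segment range are
    labelled ``other``; chains absent from the manifest raise.
    """
    if manifest_path is None:
        manifest_path = str(Path(pdb_path).with_suffix(".json"))
    manifest = json.loads(Path(manifest_path).read_text())
    st = gemmi.read_structure(str(pdb_path))
    st.setup_entities()
    records = []
    for chain in st[0]:
        if chain.name not in manifest["chains"]:
            raise KeyError(f"chain {chain.name!r} missing from annotation manifest")
        subunit = manifest["chains"][chain.name]
        seg_ranges = manifest["segments"].get(chain.name, {})
        for res in chain:
            ca = res.find_atom("CA", "*")
            if ca is None:
                continue
            resi = res.seqid.num
            segment = "other"
            for seg, ranges in seg_ranges.items():
                if ranges and not isinstance(ranges[0], (list, tuple)):
                    ranges = [ranges]
                if any(lo <= resi <= hi for lo, hi in ranges):
                    segment = seg
                    break
            records.append(
                (subunit, segment, resi, ca.pos.x, ca.pos.y, ca.pos.z)
            )
    atoms = pd.DataFrame(records, columns=["subunit", "segment", "resi", "x", "y", "z"])
    if atoms.empty:
        raise ValueError(f"no Calpha atoms found in {pdb_path}")
    return AtomicModel(atoms, {"source": str(pdb_path)})


def packaged_annotation_manifest() -> Path:
    """Path to the shipped approximate subunit/segment manifest for the
    deposited Torpedo-receptor models (PDB 4AQ5 / 4AQ9 / 2BG9).

    The residue ranges are approximate (canonical numbering, flagged in the
    file); refresh them against the deposited secondary-structure records
    before quantitative use.
    """
    return Path(__file__).parent / "data" / "torpedo_nachr_annotations_approx.json"


# ---------------------------------------------------------------------------
# Geometry metrics
# ---------------------------------------------------------------------------

def _kabsch(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares superpose ``mobile`` onto ``target`` (both (n,3))."""
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    p, q = mobile - cm, target - ct
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (rot @ p.T).T + ct


def rmsd(a: AtomicModel, b: AtomicModel, superpose: bool = False) -> float:
    """Root-mean-square Calpha deviation between two matched selections.

    With ``superpose=True`` the comparison follows an optimal rigid-body
    superposition (Kabsch); otherwise coordinates are compared in their
    given frames.  Selections must have equal residue counts in matched
    order.
    """
    pa, pb = a.coords(), b.coords()
    if pa.shape != pb.shape:
        raise ValueError(f"selection size mismatch: {pa.shape[0]} vs {pb.shape[0]}")
    if superpose:
        pa = _kabsch(pa, pb)
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def superpose_global(mobile: AtomicModel, target: AtomicModel) -> AtomicModel:
    """Whole-model least-squares superposition of ``mobile`` onto ``target``."""
    pa, pb = mobile.coords(), target.coords()
    if pa.shape != pb.shape:
        raise ValueError("models must have matching atom counts for superposition")
    cm, ct = pa.mean(axis=0), pb.mean(axis=0)
    p, q = pa - cm, pb - ct
    u, _, vt = np.linalg.svd(p.T @ q)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return mobile.transformed(lambda xyz: (rot @ (xyz - cm).T).T + ct)


def helix_axis(selection: AtomicModel) -> tuple[np.ndarray, np.ndarray]:
    """Principal axis of a helix Calpha cloud.

    Returns (centroid, unit direction) with the direction oriented toward
    the extracellular side (positive Z; ties broken toward positive X then Y).
    """
    pts = selection.coords()
    if len(pts) < 6:
        raise ValueError("need at least 6 Calpha to fit a helix axis")
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] - s[1] < 1e-9:
        raise ValueError("degenerate point cloud: no unique principal axis")
    direction = vt[0]
    for comp in (2, 0, 1):
        if abs(direction[comp]) > 1e-9:
            if direction[comp] < 0:
                direction = -direction
            break
    return pts.mean(axis=0), direction / np.linalg.norm(direction)


def tilt_angle(axis_a: np.ndarray, axis_b: np.ndarray) -> float:
    """Angle in degrees between two axis directions, folded into [0, 90]."""
    ua = np.asarray(axis_a, dtype=float)
    ub = np.asarray(axis_b, dtype=float)
    ua = ua / np.linalg.norm(ua)
    ub = ub / np.linalg.norm(ub)
    cosang = abs(float(np.dot(ua, ub)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@dataclasses.dataclass
class HelixGeometry:
    """Bend description of one helix relative to its end-to-end chord."""

    centroid: np.ndarray
    direction: np.ndarray            # chord direction, extracellular-positive
    length: float                    # chord length, A
    deviations: np.ndarray           # per-residue |deviation from chord|, A
    bend_max: float                  # max deviation, A
    bend_residue: int                # index (within selection) of the max
    bend_direction: np.ndarray       # unit vector of deviation at the max
    radial_component: float          # signed: positive = away from pore axis
    tangential_component: float      # signed: CCW positive seen from +Z

    @property
    def dominant_flexure(self) -> str:
        return "radial" if abs(self.radial_component) >= abs(self.tangential_component) else "tangential"


def _decoil(pts: np.ndarray) -> np.ndarray:
    """Smooth axis trace of a helix Calpha sequence.

    Each coordinate is fit as a cubic polynomial in residue index plus a
    sinusoid at the helical twist frequency; the polynomial part is the
    local axis.  The twist (near 100 deg/residue for alpha-helices) is
    estimated by minimising the fit residual, so the coil is removed
    without edge effects even for short segments.  For traces with no
    helical wave (e.g. collinear points) the sinusoid amplitude fits to
    ~zero and the trace reduces to the polynomial itself.
    """
    n = len(pts)
    i = np.arange(n, dtype=float)
    poly = np.column_stack([np.ones(n), i, i**2, i**3])

    def axis_for(omega_deg: float) -> tuple[np.ndarray, float]:
        w = np.radians(omega_deg) * i
        design = np.column_stack([poly, np.cos(w), np.sin(w)])
        coef, *_ = np.linalg.lstsq(design, pts, rcond=None)
        resid = pts - design @ coef
        return poly @ coef[:4], float(np.sum(resid**2))

    best = min(np.arange(80.0, 120.01, 0.25), key=lambda om: axis_for(om)[1])
    return axis_for(best)[0]


def bend_profile(selection: AtomicModel, pore_axis_xy: tuple[float, float] = (0.0, 0.0)) -> HelixGeometry:
    """Deviation of the helix axis from its end-to-end chord.

    The Calpha trace is first reduced to its smooth local-axis trace
    (:func:`_decoil`), so the reported bend measures genuine axis
    curvature rather than the ~2.3 A helical coil.  The deviation
    direction at the point of maximum bend is decomposed into radial and
    tangential components relative to the pore axis (vertical line through
    ``pore_axis_xy``), which distinguishes helices that bow in toward the
    gate from those that flex sideways.
    """
    raw = selection.coords()
    if len(raw) < 6:
        raise ValueError("need at least 6 Calpha for a bend profile")
    pts = _decoil(raw)
    chord = pts[-1] - pts[0]
    length = float(np.linalg.norm(chord))
    if length < 1e-9:
        raise ValueError("degenerate helix: coincident ends")
    u = chord / length
    if u[2] < 0:
        u = -u
    rel = pts - pts[0]
    along = rel @ u
    dev_vec = rel - np.outer(along, u)
    dev = np.linalg.norm(dev_vec, axis=1)
    imax = int(np.argmax(dev))
    bend_max = float(dev[imax])
    if bend_max > 1e-9:
        bdir = dev_vec[imax] / bend_max
    else:
        bdir = np.zeros(3)
    # local radial/tangential frame at the bending residue
    radial = pts[imax] - np.array([pore_axis_xy[0], pore_axis_xy[1], pts[imax][2]])
    rn = np.linalg.norm(radial[:2])
    if rn < 1e-9:
        rhat = np.array([1.0, 0.0, 0.0])
    else:
        rhat = np.array([radial[0] / rn, radial[1] / rn, 0.0])
    that = np.array([-rhat[1], rhat[0], 0.0])
    return HelixGeometry(
        centroid=pts.mean(axis=0),
        direction=u,
        length=length,
        deviations=dev,
        bend_max=bend_max,
        bend_residue=imax,
        bend_direction=bdir,
        radial_component=float(bend_max * np.dot(bdir, rhat)),
        tangential_component=float(bend_max * np.dot(bdir, that)),
    )


def displacement_at_level(
    a: AtomicModel, b: AtomicModel, z_level: float, window: float = 6.0
) -> float:
    """Mean Calpha displacement magnitude between two matched selections,
    restricted to residues with ``|z - z_level| <= window/2`` (z taken from
    the first selection)."""
    pa, pb = a.coords(), b.coords()
    if pa.shape != pb.shape:
        raise ValueError("selection size mismatch")
    sel = np.abs(pa[:, 2] - z_level) <= window / 2.0
    if not sel.any():
        raise ValueError(f"no Calpha within {window / 2.0} A of z = {z_level}")
    disp = pb[sel] - pa[sel]
    return float(np.linalg.norm(disp.mean(axis=0)))


def sheet_displacement_summary(closed: AtomicModel, open_: AtomicModel) -> pd.DataFrame:
    """Per-subunit inner/outer sheet displacement between two states.

    Computed in the given frames (no superposition): rmsd, the mean
    displacement vector and its magnitude, per subunit and sheet.  The
    returned table is sorted by subunit ring order, so orderings such as
    which subunit moves most can be read off directly.
    """
    rows = []
    for subunit in SUBUNITS:
        for sheet in ("inner_sheet", "outer_sheet"):
            try:
                sel_c = closed.select(subunit=subunit, segment=sheet)
                sel_o = open_.select(subunit=subunit, segment=sheet)
            except KeyError:
                continue
            if len(sel_c) == 0 or len(sel_c) != len(sel_o):
                continue
            pc, po = sel_c.coords(), sel_o.coords()
            vec = (po - pc).mean(axis=0)
            rows.append(
                {
                    "subunit": subunit,
                    "sheet": sheet,
                    "rmsd": float(np.sqrt(np.mean(np.sum((po - pc) ** 2, axis=1)))),
                    "dx": vec[0],
                    "dy": vec[1],
                    "dz": vec[2],
                    "displacement": float(np.linalg.norm(vec)),
                }
            )
    return pd.DataFrame(rows)
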