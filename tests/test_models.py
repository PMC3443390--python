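"""Model I/O, rmsd, helix axes, bend profiling and displacement metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from gatemap import models as M
from gatemap.phantom import (
    HELIX_CA_RADIUS,
    HELIX_NRES,
    HELIX_RISE,
    HELIX_TWIST,
    ConformationParams,
    build_model,
)


def make_selection(coords, segment="other", subunit="x"):
    n = len(coords)
    return M.AtomicModel(
        pd.DataFrame(
            {
                "subunit": subunit,
                "segment": segment,
                "resi": np.arange(1, n + 1),
                "x": coords[:, 0],
                "y": coords[:, 1],
                "z": coords[:, 2],
            }
        )
    )


def ideal_helix(n=20, rise=HELIX_RISE, radius=HELIX_CA_RADIUS, axis=None, origin=(0, 0, 0)):
    """Straight alpha-helix along +z (or rotated onto ``axis``)."""
    i = np.arange(n)
    ang = np.radians(HELIX_TWIST * i)
    pts = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * i])
    if axis is not None:
        axis = np.asarray(axis, dtype=float)
        axis /= np.linalg.norm(axis)
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(z, axis)
        if np.linalg.norm(v) > 1e-12:
            c = float(z @ axis)
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx / (1 + c)
            pts = pts @ rot.T
    return pts + np.asarray(origin)


class TestModelIO:
    def test_phantom_round_trip_preserves_annotations(self, closed_model, tmp_path):
        pdb = tmp_path / "closed.pdb"
        M.write_model(closed_model, pdb)
        back = M.read_annotated_model(pdb)
        assert len(back) == len(closed_model)
        merged = back.atoms.merge(
            closed_model.atoms, on=["subunit", "segment", "resi"], suffixes=("_r", "")
        )
        assert len(merged) == len(closed_model)
        np.testing.assert_allclose(
            merged[["x_r", "y_r", "z_r"]].to_numpy(),
            merged[["x", "y", "z"]].to_numpy(),
            atol=1e-2,  # PDB coordinate precision is 0.001 A
        )

    def test_unknown_selection_raises(self, closed_model):
        with pytest.raises(KeyError, match="segment"):
            closed_model.select(segment="M9")
        with pytest.raises(KeyError, match="subunit"):
            closed_model.select(subunit="epsilon")

    def test_unannotated_chain_rejected(self, closed_model, tmp_path):
        import json

        pdb = tmp_path / "m.pdb"
        M.write_model(closed_model, pdb)
        manifest = json.loads((tmp_path / "m.json").read_text())
        del manifest["chains"]["E"]
        (tmp_path / "m.json").write_text(json.dumps(manifest))
        with pytest.raises(KeyError, match="chain"):
            M.read_annotated_model(pdb)


class TestRmsd:
    def test_identical_selections_zero(self, closed_model):
        sel = closed_model.select("beta", "M2")
        assert M.rmsd(sel, sel) == 0.0

    def test_rigid_translation(self, rng):
        pts = rng.standard_normal((10, 3))
        a = make_selection(pts)
        b = make_selection(pts + np.array([1.0, 0.0, 0.0]))
        assert M.rmsd(a, b, superpose=False) == pytest.approx(1.0)
        assert M.rmsd(a, b, superpose=True) == pytest.approx(0.0, abs=1e-9)

    def test_matches_bruteforce_on_toy_coordinates(self):
        pa = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        pb = np.array([[0.5, 0, 0], [1, 0.5, 0], [0, 1, 0.5], [0.5, 0, 1]])
        expected = np.sqrt(np.mean([np.sum((x - y) ** 2) for x, y in zip(pa, pb)]))
        assert M.rmsd(make_selection(pa), make_selection(pb)) == pytest.approx(expected)

    def test_superposed_never_exceeds_fixed_frame(self, rng):
        for _ in range(5):
            a = make_selection(rng.standard_normal((12, 3)))
            b = make_selection(rng.standard_normal((12, 3)))
            assert M.rmsd(a, b, superpose=True) <= M.rmsd(a, b, superpose=False) + 1e-9

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            M.rmsd(make_selection(rng.standard_normal((5, 3))), make_selection(rng.standard_normal((6, 3))))


class TestHelixAxis:
    def test_straight_helix_axis_along_z(self):
        _, direction = M.helix_axis(make_selection(ideal_helix(20)))
        angle = np.degrees(np.arccos(abs(direction[2])))
        assert angle < 0.5
        assert direction[2] > 0  # extracellular-positive orientation

    def test_rotated_helix_axis_rotates_identically(self):
        target = np.array([np.sin(np.radians(10)), 0.0, np.cos(np.radians(10))])
        _, direction = M.helix_axis(make_selection(ideal_helix(20, axis=target)))
        assert np.degrees(np.arccos(abs(direction @ target))) < 0.5

    def test_agrees_with_cylinder_fit_oracle(self):
        # oracle: fit (axis point, direction) minimising the variance of
        # point-to-axis distances on a 20-residue ideal helix
        pts = ideal_helix(20, axis=[0.2, 0.1, 0.97])

        def cost(p):
            point = np.array([p[0], p[1], 0.0])
            d = np.array([np.sin(p[2]) * np.cos(p[3]), np.sin(p[2]) * np.sin(p[3]), np.cos(p[2])])
            rel = pts - point
            radial = rel - np.outer(rel @ d, d)
            r = np.linalg.norm(radial, axis=1)
            return np.var(r) + (np.mean(r) - HELIX_CA_RADIUS) ** 2

        res = optimize.minimize(cost, [0.0, 0.0, 0.2, 0.4], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
        oracle_dir = np.array(
            [np.sin(res.x[2]) * np.cos(res.x[3]), np.sin(res.x[2]) * np.sin(res.x[3]), np.cos(res.x[2])]
        )
        _, direction = M.helix_axis(make_selection(pts))
        assert np.degrees(np.arccos(abs(direction @ oracle_dir))) < 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            M.helix_axis(make_selection(np.zeros((4, 3))))


class TestTiltAngle:
    def test_same_axis_zero(self):
        assert M.tilt_angle([0, 0, 1], [0, 0, 1]) == 0.0

    def test_orthogonal_ninety(self):
        assert M.tilt_angle([0, 0, 1], [1, 0, 0]) == pytest.approx(90.0)

    def test_antiparallel_folds_to_zero(self):
        assert M.tilt_angle([0, 0, 1], [0, 0, -1]) == pytest.approx(0.0, abs=1e-9)

    def test_phantom_beta_tilt_recovered(self, closed_model, open_model):
        for seg in ("M1", "M2", "M3", "M4"):
            a = M.helix_axis(closed_model.select("beta", seg))[1]
            b = M.helix_axis(open_model.select("beta", seg))[1]
            assert M.tilt_angle(a, b) == pytest.approx(2.0, abs=0.2)


class TestBendProfile:
    def test_collinear_trace_has_zero_bend(self):
        pts = np.column_stack([np.zeros(12), np.zeros(12), np.linspace(0, 16, 12)])
        geom = M.bend_profile(make_selection(pts))
        assert geom.bend_max == pytest.approx(0.0, abs=1e-9)

    def test_straight_ideal_helix_has_negligible_bend(self):
        geom = M.bend_profile(make_selection(ideal_helix(24)))
        assert geom.bend_max < 0.05

    def test_alpha_g_m2_radial_bow_recovered(self, closed_model):
        geom = M.bend_profile(closed_model.select("alpha_g", "M2"))
        assert geom.bend_max == pytest.approx(1.5, rel=0.05)
        assert geom.dominant_flexure == "radial"
        assert geom.radial_component < 0  # bows inward, toward the pore

    def test_delta_m2_tangential_bow_recovered(self, closed_model):
        geom = M.bend_profile(closed_model.select("delta", "M2"))
        assert geom.bend_max == pytest.approx(2.0, rel=0.05)
        assert geom.dominant_flexure == "tangential"

    def test_open_state_flexing_helices_straight(self, open_model):
        for sub in ("alpha_g", "delta"):
            geom = M.bend_profile(open_model.select(sub, "M2"))
            assert geom.bend_max < 0.1

    def test_deviation_components_bounded_by_bend_max(self, closed_model):
        geom = M.bend_profile(closed_model.select("delta", "M2"))
        assert geom.radial_component**2 + geom.tangential_component**2 <= geom.bend_max**2 + 1e-9


class TestDisplacement:
    def test_identical_models_zero(self, closed_model):
        sel = closed_model.select("delta", "M2")
        assert M.displacement_at_level(sel, sel, z_level=10.0) == 0.0

    def test_rigid_shift_recovered_at_any_level(self, closed_model):
        sel = closed_model.select("gamma", "M1")
        shifted = sel.transformed(lambda xyz: xyz + np.array([1.0, 0, 0]))
        for z in (-10.0, 0.0, 10.0):
            assert M.displacement_at_level(sel, shifted, z) == pytest.approx(1.0)

    def test_empty_window_rejected(self, closed_model):
        sel = closed_model.select("gamma", "M1")
        with pytest.raises(ValueError, match="no Calpha"):
            M.displacement_at_level(sel, sel, z_level=200.0)

    def test_delta_m2_leaflet_displacement_matches_construction(self, closed_model, open_model):
        # tangential bow amplitude 2.0 with quadratic profile, averaged over
        # residues with |z - 10| <= 3
        sel_c = closed_model.select("delta", "M2")
        sel_o = open_model.select("delta", "M2")
        z = sel_c.coords()[:, 2]
        in_window = np.abs(z - 10.0) <= 3.0
        t = (z[in_window] + 17.25) / 34.5
        expected_mean_vector = 2.0 * np.mean(4 * t * (1 - t))
        got = M.displacement_at_level(sel_c, sel_o, z_level=10.0)
        assert got == pytest.approx(expected_mean_vector, rel=0.02)


class TestSheetSummary:
    def test_identical_models_all_zero(self, closed_model):
        table = M.sheet_displacement_summary(closed_model, closed_model)
        assert (table["rmsd"] == 0).all()
        assert (table["displacement"] == 0).all()

    def test_beta_only_phantom_shows_beta_largest_others_zero(self):
        base = ConformationParams("base", alpha_distortion=0.0)
        shifted = ConformationParams(
            "shifted", beta_displacement=1.0, alpha_distortion=0.0
        )
        table = M.sheet_displacement_summary(build_model(base), build_model(shifted))
        by_sub = table.groupby("subunit")["rmsd"].max()
        assert by_sub["beta"] == pytest.approx(1.0)
        for sub in ("alpha_g", "alpha_d", "gamma", "delta"):
            assert by_sub[sub] == pytest.approx(0.0, abs=1e-12)

    def test_closed_open_defaults_rank_beta_then_alphas(self, closed_model, open_model):
        table = M.sheet_displacement_summary(closed_model, open_model)
        inner = table[table["sheet"] == "inner_sheet"].set_index("subunit")["rmsd"]
        assert inner["beta"] == pytest.approx(1.0)
        # the relieved alpha distortion moves both alpha subunits
        assert inner["alpha_g"] == pytest.approx(1.0)
        assert inner["gamma"] == pytest.approx(0.0, abs=1e-12)


class TestInvariances:
    def test_metrics_invariant_under_joint_rigid_motion(self, closed_model, open_model, rng):
        t = np.radians(23.0)
        rot = np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])
        shift = np.array([3.0, -2.0, 5.0])
        move = lambda xyz: xyz @ rot.T + shift
        a, b = closed_model.select("beta", "M2"), open_model.select("beta", "M2")
        am, bm = a.transformed(move), b.transformed(move)
        assert M.rmsd(am, bm) == pytest.approx(M.rmsd(a, b), abs=1e-9)
        assert M.tilt_angle(
            M.helix_axis(am)[1], M.helix_axis(bm)[1]
        ) == pytest.approx(M.tilt_angle(M.helix_axis(a)[1], M.helix_axis(b)[1]), abs=1e-6)

    def test_rmsd_invariant_under_renumbering(self, closed_model):
        a = closed_model.select("beta", "M2")
        renum = M.AtomicModel(a.atoms.assign(resi=a.atoms["resi"] + 100), a.meta)
        assert M.rmsd(a, renum) == 0.0


def test_packaged_manifest_loads_with_multirange_segments(tmp_path):
    import json

    manifest = json.loads(M.packaged_annotation_manifest().read_text())
    assert manifest["approximate"] is True
    assert set(manifest["chains"].values()) == set(M.SUBUNITS)
    # multi-range sheet segments resolve correctly through the reader
    pdb = tmp_path / "toy.pdb"
    mini = make_selection(np.zeros((3, 3)), subunit="alpha_g")
    mini = M.AtomicModel(mini.atoms.assign(resi=[31, 45, 70]))
    M.write_model(mini, pdb)
    (tmp_path / "toy.json").write_text(
        json.dumps(
            {
                "chains": {"A": "alpha_g"},
                "segments": {"A": {"inner_sheet": [[30, 40], [44, 52]]}},
            }
        )
    )
    back = M.read_annotated_model(pdb)
    assert list(back.atoms["segment"]) == ["inner_sheet", "inner_sheet", "other"]
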