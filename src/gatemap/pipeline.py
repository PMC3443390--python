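"""End-to-end synthetic replay of the gating analysis.

``replay`` chains the whole pipeline on phantom data: simulate reference
and unlabelled ensembles -> sort by correlation preference -> class
averages -> voxel t-map between the classes -> half-split FSC per class ->
five-fold symmetry profiles -> model geometry metrics -> pore profiles.
Every stage is seeded from one master seed, and the report (JSON plus TSV
tables and MRC/PDB artifacts) is deterministic given the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import classify, mapqc, pore, tmap
from .maps import average, write_map
from .models import bend_profile, displacement_at_level, helix_axis, rmsd, sheet_displacement_summary, tilt_angle, write_model
from .phantom import (
    LOWER_LBD_Z,
    OUTER_LEAFLET_Z,
    ConformationParams,
    EnsembleSpec,
    NoiseSpec,
    build_model,
    render_density,
    simulate_ensemble,
)


@dataclasses.dataclass
class RunConfig:
    """Declarative configuration of a replay run."""

    seed: int = 0
    n_maps: int = 60
    n_reference_maps: int = 10
    fraction_open: float = 0.5
    fraction_intermediate: float = 0.0
    sigma: float | None = None          # None: calibrated default
    resolution_limit: float = 20.0
    central_fraction: float = 2.0 / 3.0
    p_value: float = 0.001
    write_artifacts: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _noise(sigma: float | None, seed: int) -> NoiseSpec:
    if sigma is None:
        return NoiseSpec(seed=seed)
    return NoiseSpec(sigma=sigma, seed=seed)


def replay(config: RunConfig, out_dir: str) -> dict:
    """Run the full synthetic pipeline and write a machine-readable report.

    Returns the report dictionary (also written to ``report.json``); TSV
    tables and MRC/PDB artifacts are written alongside unless
    ``write_artifacts`` is off.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def stage(name):
        t0 = time.time()

        def done(payload):
            payload["elapsed_s"] = round(time.time() - t0, 3)
            report["stages"][name] = payload

        return done

    # --- simulate ---------------------------------------------------------
    done = stage("simulate")
    closed_params = ConformationParams.closed()
    open_params = ConformationParams.open()
    model_closed = build_model(closed_params)
    model_open = build_model(open_params)
    ens_ref_closed = simulate_ensemble(
        EnsembleSpec(n_maps=config.n_reference_maps, fraction_open=0.0,
                     noise=_noise(config.sigma, config.seed * 10 + 1))
    )
    ens_ref_open = simulate_ensemble(
        EnsembleSpec(n_maps=config.n_reference_maps, fraction_open=1.0,
                     noise=_noise(config.sigma, config.seed * 10 + 2))
    )
    ensemble = simulate_ensemble(
        EnsembleSpec(n_maps=config.n_maps, fraction_open=config.fraction_open,
                     fraction_intermediate=config.fraction_intermediate,
                     noise=_noise(config.sigma, config.seed * 10 + 3))
    )
    done({"n_maps": config.n_maps, "labels": {lab: int(np.sum(np.array(ensemble.labels) == lab))
                                              for lab in set(ensemble.labels)}})

    # --- sort -------------------------------------------------------------
    done = stage("sort")
    sort_cfg = classify.SortConfig(
        resolution_limit=config.resolution_limit, central_fraction=config.central_fraction
    )
    refs = classify.build_references(ens_ref_open.maps, ens_ref_closed.maps)
    result = classify.sort_ensemble(ensemble, refs, sort_cfg)
    averages, result2, converged = classify.class_average_and_iterate(ensemble, result, sort_cfg)
    truth = np.array(ensemble.labels)
    pred = result.records["label"].to_numpy()
    pure = truth != "intermediate"
    accuracy = float(np.mean(pred[pure] == truth[pure])) if pure.any() else float("nan")
    done(
        {
            "weak_band": result.weak_band,
            "weak_fraction": result.weak_fraction,
            "accuracy_vs_truth": accuracy,
            "mean_abs_delta": float(np.mean(np.abs(result.records["delta"]))),
            "resort_converged": converged,
            "class_counts": {k: int(v) for k, v in result.counts().items()},
            "histogram": {
                "counts": result.hist_counts.tolist(),
                "edges": result.hist_edges.tolist(),
            },
        }
    )
    result.records.to_csv(out / "sort_records.tsv", sep="\t", index=False)

    # --- t-map ------------------------------------------------------------
    done = stage("tmap")
    members = {
        lab: [m for m, p in zip(ensemble.maps, pred) if p == lab] for lab in ("open", "closed")
    }
    stats_open = tmap.voxel_stats(members["open"])
    stats_closed = tmap.voxel_stats(members["closed"])
    tm = tmap.t_statistic(stats_open, stats_closed)
    regions, _ = tmap.significance_contours(tm, p=config.p_value)
    regions.to_csv(out / "tmap_regions.tsv", sep="\t", index=False)
    done(
        {
            "p": config.p_value,
            "n_regions": int(len(regions)),
            "top_regions": regions.head(4).to_dict(orient="records"),
        }
    )

    # --- FSC per class ----------------------------------------------------
    done = stage("fsc")
    fsc_payload = {}
    for lab in ("open", "closed"):
        half_a, half_b = mapqc.half_split(members[lab], seed=config.seed * 10 + 4)
        curve = mapqc.fsc(average(half_a), average(half_b))
        curve.table().to_csv(out / f"fsc_{lab}.tsv", sep="\t", index=False)
        fsc_payload[lab] = {"resolution_at_half": curve.resolution_at_half,
                            "n_half": [len(half_a), len(half_b)]}
    done(fsc_payload)

    # --- symmetry ---------------------------------------------------------
    done = stage("symmetry")
    sym_payload = {}
    for lab in ("open", "closed"):
        prof = mapqc.fivefold_strength(averages[lab], axis_xy=(0.0, 0.0), z_range=(-16.0, 50.0))
        prof.table().to_csv(out / f"symmetry_{lab}.tsv", sep="\t", index=False)
        tb = prof.table()
        sym_payload[lab] = {
            "outer_leaflet_mean": float(
                tb[(tb.z >= OUTER_LEAFLET_Z[0]) & (tb.z <= OUTER_LEAFLET_Z[1])].relative_5fold.mean()
            ),
            "lower_lbd_mean": float(
                tb[(tb.z >= LOWER_LBD_Z[0]) & (tb.z <= LOWER_LBD_Z[1])].relative_5fold.mean()
            ),
        }
    done(sym_payload)

    # --- model metrics ----------------------------------------------------
    done = stage("model_metrics")
    beta_ec_closed = model_closed.select("beta", "inner_sheet")
    beta_ec_open = model_open.select("beta", "inner_sheet")
    tilt = tilt_angle(
        helix_axis(model_closed.select("beta", "M2"))[1],
        helix_axis(model_open.select("beta", "M2"))[1],
    )
    bends = {}
    for sub in ("alpha_g", "delta"):
        geom = bend_profile(model_closed.select(sub, "M2"))
        bends[sub] = {
            "bend_max": geom.bend_max,
            "dominant_flexure": geom.dominant_flexure,
        }
    sheets = sheet_displacement_summary(model_closed, model_open)
    sheets.to_csv(out / "sheet_displacements.tsv", sep="\t", index=False)
    done(
        {
            "beta_ec_displacement": rmsd(beta_ec_closed, beta_ec_open),
            "beta_helix_tilt_deg": tilt,
            "m2_bends": bends,
            "delta_m2_leaflet_displacement": displacement_at_level(
                model_closed.select("delta", "M2"), model_open.select("delta", "M2"), z_level=10.0
            ),
        }
    )

    # --- pore -------------------------------------------------------------
    done = stage("pore")
    prof_closed = pore.pore_profile(model_closed, -18.0, 18.0)
    prof_open = pore.pore_profile(model_open, -18.0, 18.0)
    prof_closed.table().to_csv(out / "pore_closed.tsv", sep="\t", index=False)
    prof_open.table().to_csv(out / "pore_open.tsv", sep="\t", index=False)
    d_closed = pore.limiting_diameter(prof_closed, (-8.0, 8.0))
    d_open = pore.limiting_diameter(prof_open, (-8.0, 8.0))
    done(
        {
            "gate_diameter_closed": d_closed,
            "gate_diameter_open": d_open,
            "gate_diameter_increase": d_open - d_closed,
            "narrowest_z_closed": float(prof_closed.z[prof_closed.radius.argmin()]),
            "narrowest_z_open": float(prof_open.z[prof_open.radius.argmin()]),
        }
    )

    # --- artifacts --------------------------------------------------------
    if config.write_artifacts:
        write_map(averages["closed"], out / "class_avg_closed.mrc")
        write_map(averages["open"], out / "class_avg_open.mrc")
        write_map(
            type(averages["open"])(tm.t, tm.voxel, tm.origin), out / "tmap.mrc"
        )
        write_model(model_closed, out / "model_closed.pdb")
        write_model(model_open, out / "model_open.pdb")
    manifest = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "report.json"
    }
    report["artifacts"] = manifest
    report["elapsed_s"] = round(time.time() - t_start, 3)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
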