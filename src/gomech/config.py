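"""Run configuration and the stage runner behind the ``gomech`` CLI.

A :class:`RunConfig` names a stage, its input paths, a flat parameter map
(validated against the stage's schema: unknown keys are rejected, defaults
match the study constants — Poisson ratio 0.4, 25 nm box, 1.2 nm cutoff,
oxidation fraction 0.48, 300 K), an output directory and a seed.
:func:`run_stage` executes the stage, writes its artifacts under the
output directory, and returns (and writes) a JSON-serialisable report that
records the seed, parameters and input hashes for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from gomech import actin, afm, cgmd, io, migration, synth
from gomech.errors import GomechError, InvalidParameterError

#: per-stage parameter schemas: name -> default (None = required)
STAGE_SCHEMAS = {
    "simulate": {"generator": None, "kwargs": {}},
    "afm-fit": {
        "gamma": afm.DEFAULT_POISSON,
        "tip_radius_nm": afm.DEFAULT_TIP_RADIUS_NM,
        "max_depth_nm": afm.DEFAULT_MAX_DEPTH_NM,
        "spring_constant": 0.02,
        "control": None,
    },
    "actin-order": {
        "window": 32,
        "overlap": 0.5,
        "radius": 1,
        "min_area_px": 16,
    },
    "migration-stats": {"axis_x": 1.0, "axis_y": 0.0},
    "go-build": {
        "nx": 10,
        "ny": 10,
        "fraction": 0.48,
        "lattice_spacing_nm": 0.24,
    },
    "cg-analyze": {
        "box_nm": cgmd.DEFAULT_BOX_NM,
        "group_a": "actinA",
        "group_b": "actinB",
        "contact_cutoff_nm": cgmd.DEFAULT_CONTACT_CUTOFF_NM,
        "r_cut_nm": cgmd.DEFAULT_CUTOFF_NM,
        "temperature_k": 300.0,
        "bins": 40,
        "lj_mode": "plain_shift",
        "eps_r": 15.0,
    },
}


@dataclass
class RunConfig:
    """One pipeline stage invocation."""

    stage: str
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    outdir: str = "gomech_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGE_SCHEMAS:
            raise InvalidParameterError(
                f"unknown stage {self.stage!r}; known: {sorted(STAGE_SCHEMAS)}"
            )
        schema = STAGE_SCHEMAS[self.stage]
        unknown = set(self.params) - set(schema)
        if unknown:
            raise InvalidParameterError(
                f"unknown parameters for stage {self.stage!r}: {sorted(unknown)}"
            )
        merged = dict(schema)
        merged.update(self.params)
        missing = [k for k, v in merged.items() if v is None]
        if missing:
            raise InvalidParameterError(
                f"stage {self.stage!r} missing required parameters: {missing}"
            )
        self.params = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _input_hashes(inputs) -> dict:
    out = {}

    def _walk(name, val):
        if isinstance(val, dict):
            for k, v in val.items():
                _walk(f"{name}.{k}", v)
        elif isinstance(val, (list, tuple)):
            for i, v in enumerate(val):
                _walk(f"{name}[{i}]", v)
        else:
            out[name] = _hash_file(val)

    for name, val in inputs.items():
        _walk(name, val)
    return out


# ---------------------------------------------------------------------------
# stage implementations

def _stage_afm_fit(cfg: RunConfig, outdir: Path) -> dict:
    import pandas as pd

    p = cfg.params
    fits_by_group = {}
    per_curve = []
    for group, paths in cfg.inputs["curves"].items():
        fits = []
        for path in paths:
            curve = io.parse_force_curve_file(
                path,
                tip_radius_nm=p["tip_radius_nm"],
                poisson=p["gamma"],
                spring_constant=p["spring_constant"],
            )
            fit = afm.fit_hertz(curve, max_depth_nm=p["max_depth_nm"])
            fits.append(fit)
            per_curve.append(
                {
                    "group": group,
                    "file": str(path),
                    "young_modulus_kpa": fit.young_modulus_kpa,
                    "contact_z0_nm": fit.contact_z0_nm,
                    "rss_nn2": fit.rss_nn2,
                    "n_points_fit": fit.n_points_fit,
                }
            )
        fits_by_group[group] = fits
    summary = afm.group_stiffness_summary(fits_by_group, control=p["control"])
    summary.to_csv(outdir / "stiffness_summary.csv", index=False)
    (outdir / "fits.json").write_text(json.dumps(per_curve, indent=2))
    pd.DataFrame(per_curve).to_csv(outdir / "fits.csv", index=False)
    return {"groups": summary.to_dict(orient="records")}


def _stage_actin_order(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.params
    image = io.read_image(cfg.inputs["image"])
    mask = actin.make_intensity_mask(image, min_area_px=p["min_area_px"])
    field_ = actin.local_orientation(
        image, window=p["window"], overlap=p["overlap"], mask=mask
    )
    qmap = actin.order_parameter_map(field_, radius=p["radius"])
    mean_q = actin.mean_order_parameter(qmap)
    intensity = actin.mean_intensity(image, mask)

    import pandas as pd

    ny, nx = qmap.q.shape
    ii, jj = np.meshgrid(range(ny), range(nx), indexing="ij")
    pd.DataFrame(
        {
            "block_row": ii.ravel(),
            "block_col": jj.ravel(),
            "theta_rad": field_.theta.ravel(),
            "coherence": field_.coherence.ravel(),
            "q": qmap.q.ravel(),
        }
    ).to_csv(outdir / "order_parameter.csv", index=False)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(qmap.q, vmin=-1, vmax=1, cmap="viridis")
    fig.colorbar(im, ax=ax, label="q")
    ax.set_title("nematic order parameter")
    fig.savefig(outdir / "q_heatmap.png", dpi=120)
    plt.close(fig)
    return {
        "mean_q": mean_q,
        "mean_intensity": intensity,
        "n_blocks_set": int(qmap.set_mask.sum()),
    }


def _stage_migration_stats(cfg: RunConfig, outdir: Path) -> dict:
    import pandas as pd

    p = cfg.params
    axis = (p["axis_x"], p["axis_y"])
    report = {}
    stats_by_group = {}
    rows = []
    for name in ("control", "treated"):
        if name not in cfg.inputs:
            continue
        tracks = io.read_tracks_csv(cfg.inputs[name], channel_axis=axis)
        st = migration.cohort_stats(tracks)
        stats_by_group[name] = st
        report[name] = {
            "mean_um_h": st.mean,
            "sd_um_h": st.sd,
            "median_um_h": st.median,
            "n_cells": st.n_cells,
        }
        rows.extend(
            {"group": name, "cell_id": cid, "velocity_um_h": v}
            for cid, v in zip(tracks.cell_ids, st.velocities)
        )
    if "control" in stats_by_group and "treated" in stats_by_group:
        report["inhibition_percent"] = migration.inhibition_percent(
            stats_by_group["control"].mean, stats_by_group["treated"].mean
        )
    pd.DataFrame(rows).to_csv(outdir / "per_cell_velocities.csv", index=False)
    return report


def _stage_go_build(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.params
    sheet = cgmd.build_go_sheet(
        p["nx"],
        p["ny"],
        oxidation_fraction=p["fraction"],
        lattice_spacing=p["lattice_spacing_nm"],
        seed=cfg.seed,
    )
    span = sheet.positions.max(axis=0) - sheet.positions.min(axis=0)
    box = float(max(span.max() + 2.0, 1.0))
    frame = cgmd.BeadFrame(positions=sheet.positions - sheet.positions.min(axis=0) + 1.0, box=box)
    io.write_gro(outdir / "go_sheet.gro", frame, names=list(sheet.types), resname="GO")
    topology = cgmd.Topology(
        types=sheet.types,
        charges=np.zeros(sheet.n_beads),
        groups=np.full(sheet.n_beads, "GO", dtype=object),
    )
    io.write_topology(outdir / "go_topology.csv", topology)
    return {
        "n_beads": sheet.n_beads,
        "n_sp1": sheet.n_sp1,
        "n_sg4": sheet.n_beads - sheet.n_sp1,
        "oxidation_fraction": sheet.oxidation_fraction,
        "n_bonds": int(sheet.bonds.shape[0]),
    }


def _stage_cg_analyze(cfg: RunConfig, outdir: Path) -> dict:
    import pandas as pd

    p = cfg.params
    topology = io.read_topology(cfg.inputs["topology"], cfg.inputs.get("lj"))
    traj_path = str(cfg.inputs["trajectory"])
    if traj_path.endswith(".gro"):
        frame, _ = io.parse_gro(traj_path)
        frames = [frame]
    else:
        frames = io.read_xyz_frames(traj_path, box=p["box_nm"])
    ga, gb = p["group_a"], p["group_b"]

    times, dists = cgmd.com_distance_series(frames, topology, ga, gb)
    contacts = cgmd.reference_contacts(
        frames[0], topology, ga, gb, cutoff=p["contact_cutoff_nm"]
    )
    counts = np.array([cgmd.count_contacts(f, contacts) for f in frames])
    pd.DataFrame(
        {"time_ns": times, "com_distance_nm": dists, "native_contacts": counts}
    ).to_csv(outdir / "observables.csv", index=False)

    report = {
        "n_frames": len(frames),
        "com_distance_nm": {"mean": float(dists.mean()), "sd": float(dists.std())},
        "native_contacts": {
            "reference": len(contacts),
            "mean": float(counts.mean()),
            "sd": float(counts.std()),
        },
    }
    if topology.lj_params:
        lj = np.array(
            [
                cgmd.lj_energy(f, topology, (ga, gb), r_cut=p["r_cut_nm"], mode=p["lj_mode"])
                for f in frames
            ]
        )
        report["lj_energy_kjmol"] = {"mean": float(lj.mean()), "sd": float(lj.std())}
    if np.any(topology.charges != 0):
        qe = np.array(
            [
                cgmd.coulomb_energy(
                    f, topology, (ga, gb), r_cut=p["r_cut_nm"], eps_r=p["eps_r"]
                )
                for f in frames
            ]
        )
        report["coulomb_energy_kjmol"] = {"mean": float(qe.mean()), "sd": float(qe.std())}

    if len(frames) >= 100:
        landscape = cgmd.free_energy_2d(
            dists, counts.astype(float), p["bins"], p["bins"], temperature=p["temperature_k"]
        )
        io.write_landscape_csv(outdir / "free_energy.csv", landscape)
        xmin, ymin, _ = landscape.global_minimum()
        report["free_energy_minimum"] = {"com_distance_nm": xmin, "native_contacts": ymin}
    return report


def _stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.params
    name = p["generator"]
    kwargs = dict(p["kwargs"])
    kwargs.setdefault("seed", cfg.seed)
    if name == "force_curve":
        curve = synth.gen_force_curve(**kwargs)
        io.write_force_curve(outdir / "force_curve.txt", curve)
        io.write_ground_truth(outdir / "force_curve.gt.json", curve.meta["ground_truth"])
        return {"artifact": "force_curve.txt", "n_points": len(curve)}
    if name == "filament_image":
        fim = synth.gen_filament_image(**kwargs)
        io.write_image(outdir / "filaments.tiff", fim.image)
        io.write_ground_truth(outdir / "filaments.gt.json", fim.ground_truth)
        return {"artifact": "filaments.tiff", "n_filaments": int(fim.angles.size)}
    if name == "tracks":
        tracks = synth.gen_tracks(**kwargs)
        io.write_tracks_csv(outdir / "tracks.csv", tracks)
        io.write_ground_truth(outdir / "tracks.gt.json", tracks.meta["ground_truth"])
        return {"artifact": "tracks.csv", "n_cells": len(tracks.cell_ids)}
    if name == "dimer_frames":
        traj = synth.gen_dimer_frames(**kwargs)
        io.write_xyz_frames(outdir / "dimer.xyz", traj.frames)
        io.write_topology(outdir / "dimer_topology.csv", traj.topology)
        io.write_ground_truth(outdir / "dimer.gt.json", traj.ground_truth)
        return {"artifact": "dimer.xyz", "n_frames": len(traj.frames)}
    raise InvalidParameterError(f"unknown generator {name!r}")


_STAGES = {
    "simulate": _stage_simulate,
    "afm-fit": _stage_afm_fit,
    "actin-order": _stage_actin_order,
    "migration-stats": _stage_migration_stats,
    "go-build": _stage_go_build,
    "cg-analyze": _stage_cg_analyze,
}


def run_stage(config: RunConfig) -> dict:
    """Execute one stage; write report.json and artifacts under the outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        result = _STAGES[config.stage](config, outdir)
    except GomechError:
        raise
    except Exception as exc:  # annotate with stage context
        raise GomechError(f"stage {config.stage!r} failed: {exc}") from exc
    report = {
        "stage": config.stage,
        "seed": config.seed,
        "parameters": config.params,
        "input_hashes": _input_hashes(config.inputs),
        "result": result,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float) + "\n")
    return report
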