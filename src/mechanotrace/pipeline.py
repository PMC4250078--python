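"""Run configuration and the end-to-end pipeline driver.

Stages run in dependency order: simulate -> stress -> traction -> binding ->
kinetics -> pullplan. Every artifact embeds the seed and a hash of the
configuration so reruns are reproducible byte-for-byte for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bellfit import fit_kinetics_pipeline
from .errors import InvalidParameterError, PipelineDependencyError
from .io import save_trajectory
from .lipidbind import (
    HBondCriteria,
    classify_tightly_bound,
    com_distance_variance,
    count_hbonded_lipids_by_side,
    distribution_fwhm,
    lipid_volumes,
    pn_distance_traces,
    pore_diameter,
)
from .pullgeom import build_pull_plan, radial_directions
from .stressfield import StressOptions, compute_stress_grid
from .surface_io import export_surface
from .synthgen import (
    FixtureConfig,
    gen_ideal_gas,
    gen_membrane_protein_fixture,
    gen_unbinding_times,
)
from .tractionmap import compute_density_grid, extract_isosurface, integrate_traction, sample_traction

logger = logging.getLogger(__name__)

STAGES = ("simulate", "stress", "traction", "binding", "kinetics", "pullplan")


@dataclass
class RunConfig:
    """All pipeline parameters, with the documented defaults."""

    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 1
    outdir: str = "mechanotrace_out"
    # fixture
    fixture: dict = field(default_factory=dict)  # FixtureConfig overrides
    # stress stage (demo gas shares the fixture box)
    gas_particles: int = 2000
    gas_temperature: float = 310.15
    gas_frames: int = 20
    stress_spacing: float = 0.2
    stress_filter_width: float = 0.8
    # traction stage
    density_spacing: float = 0.1
    density_filter_width: float = 0.2
    iso_level: float | None = None  # None -> relative 0.5
    # binding stage
    hbond_distance: float = 0.35
    hbond_angle: float = 30.0
    occupancy_threshold: float = 0.7
    cavity_cutoff: float = 0.5
    volume_resolution: float = 0.1
    # kinetics stage
    forces: list[float] = field(default_factory=lambda: [530.0, 660.0, 830.0, 910.0, 1000.0])
    tau0: float = 441.0
    xbeta: float = 35.0
    temperature: float = 310.15
    n_lipids: int = 10
    n_reps: int = 5
    n_bootstrap: int = 200
    attempt_time_range: tuple[float, float] = (1.0, 20.0)
    # pull plan
    pull_magnitude: float = 300.0
    pull_angle: float = 45.0
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise InvalidParameterError(f"unknown stages: {sorted(unknown)}")
        if self.seed < 0:
            raise InvalidParameterError("seed must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Hash of the scientific parameters (paths and logging excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k not in ("outdir", "log_level")}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_json(path: Path, payload: dict, config: RunConfig) -> Path:
    payload = {"seed": config.seed, "config_hash": config.hash(), **payload}
    path.write_text(json.dumps(payload, indent=1, default=float))
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write all artifacts plus a manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    artifacts: list[str] = []
    stages = [s for s in STAGES if s in config.stages]

    def require(key: str, needed_by: str):
        if key not in state:
            raise PipelineDependencyError(f"stage '{needed_by}' requires the '{key}' artifact; run its stage first")
        return state[key]

    for stage in stages:
        logger.info("stage %s", stage)
        if stage == "simulate":
            fx = FixtureConfig(**config.fixture)
            traj, truth = gen_membrane_protein_fixture(fx, seed=config.seed)
            p = save_trajectory(traj, out / "fixture.h5", seed=config.seed, config_hash=config.hash())
            truth.to_json(out / "planted_truth.json")
            state.update(fixture=traj, truth=truth, fixture_config=fx)
            artifacts += [str(p), str(out / "planted_truth.json")]
        elif stage == "stress":
            fx = state.get("fixture_config") or FixtureConfig(**config.fixture)
            gas = gen_ideal_gas(
                config.gas_particles, config.gas_temperature, fx.box,
                n_frames=config.gas_frames, seed=config.seed + 1,
            )
            grid = compute_stress_grid(
                gas, StressOptions(spacing=config.stress_spacing, filter_width=config.stress_filter_width)
            )
            state["stress"] = grid
            _write_json(out / "stress_summary.json", {
                "pressure_bar": grid.pressure(),
                "mean_tensor_bar": grid.mean_tensor().tolist(),
                "shape": list(grid.shape),
            }, config)
            artifacts.append(str(out / "stress_summary.json"))
        elif stage == "traction":
            traj = require("fixture", stage)
            grid = require("stress", stage)
            protein = traj.topology.select(role=["protein", "lysine-N"])
            density = compute_density_grid(
                traj, protein, spacing=config.density_spacing, filter_width=config.density_filter_width
            )
            surface = extract_isosurface(density, level=config.iso_level, relative=config.iso_level is not None)
            surface = sample_traction(grid, surface)
            mesh = export_surface(surface, out / "traction_surface.vtk")
            net = integrate_traction(surface)
            _write_json(out / "traction_summary.json", {
                "n_vertices": surface.n_vertices,
                "area_nm2": surface.area(),
                "net_force_pN": net.tolist(),
                "mean_t_n_bar": float(np.mean(surface.t_normal)),
                "mean_t_t_bar": float(np.mean(surface.t_tangential)),
            }, config)
            artifacts += [str(mesh), str(out / "traction_summary.json")]
        elif stage == "binding":
            traj = require("fixture", stage)
            truth = require("truth", stage)
            criteria = HBondCriteria(config.hbond_distance, config.hbond_angle)
            census, summary = count_hbonded_lipids_by_side(traj, criteria)
            census.to_csv(out / "hbond_census.csv", index=False)
            records = classify_tightly_bound(
                traj, criteria, config.occupancy_threshold, config.cavity_cutoff
            )
            pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(out / "tight_bound.csv", index=False)
            traces, nearest = pn_distance_traces(traj)
            tight_ids = {r.lipid_resid for r in records}
            pooled = np.concatenate([nearest[r] for r in tight_ids]) if tight_ids else np.array([])
            volumes = lipid_volumes(traj.frames[0], traj.topology, resolution=config.volume_resolution)
            volumes.to_csv(out / "lipid_volumes.csv", header=["volume_nm3"])
            variances = com_distance_variance(traj, traj.topology.select(role=["protein", "lysine-N"]))
            variances.to_csv(out / "com_variance.csv", header=["variance_nm2"])
            diam = pore_diameter(traj.frames[0], truth.pore_ring_indices, traj.topology)
            _write_json(out / "binding_summary.json", {
                **summary,
                "n_tightly_bound": len(records),
                "n_short_inserted": sum(r.inserted_tail == "short" for r in records),
                "pooled_pn_mean_nm": float(pooled.mean()) if pooled.size else None,
                "pooled_pn_fwhm_pm": float(distribution_fwhm(pooled) * 1e3) if pooled.size else None,
                "pore_diameter_nm": diam,
            }, config)
            state["records"] = records
            artifacts += [str(out / n) for n in (
                "hbond_census.csv", "tight_bound.csv", "lipid_volumes.csv",
                "com_variance.csv", "binding_summary.json")]
        elif stage == "kinetics":
            datasets = gen_unbinding_times(
                config.forces, config.tau0, config.xbeta, config.temperature,
                config.n_lipids, config.n_reps, seed=config.seed + 2,
            )
            bell, exp_fits = fit_kinetics_pipeline(
                datasets, temperature=config.temperature,
                n_bootstrap=config.n_bootstrap, seed=config.seed + 3,
            )
            from .bellfit import barrier_estimate

            barrier = barrier_estimate(bell.tau0, config.attempt_time_range)
            _write_json(out / "kinetics_report.json", {
                "tau0_ns": bell.tau0,
                "xbeta_pm": bell.xbeta,
                "per_force": [
                    {"force_pN": float(f), "k_per_ns": e.k, "ci": e.ci}
                    for f, e in zip(bell.forces, exp_fits)
                ],
                "barrier_kT": [barrier.dg_low, barrier.dg_high],
                "attempt_time_ps": list(barrier.tauD_range),
            }, config)
            artifacts.append(str(out / "kinetics_report.json"))
        elif stage == "pullplan":
            traj = require("fixture", stage)
            records = require("records", stage)
            topo = traj.topology
            protein = topo.select(role=["protein", "lysine-N"])
            tails = []
            for r in records:
                free_tail = "long" if r.inserted_tail == "short" else "short"
                tails.append(topo.select(role=f"lipid-tail-{free_tail}", resid=r.lipid_resid))
            dirs = radial_directions(traj.frames[-1], topo, protein, tails)
            plan = build_pull_plan(config.pull_magnitude, config.pull_angle, dirs)
            _write_json(out / "pull_plan.json", {
                "magnitude_pN": plan.magnitude,
                "polar_angle_deg": plan.polar_angle,
                "directions": plan.directions.tolist(),
                "forces_pN": plan.forces.tolist(),
                "counterforce_pN": plan.counterforce.tolist(),
            }, config)
            artifacts.append(str(out / "pull_plan.json"))

    manifest = {
        "version": __version__,
        "stages": stages,
        "artifacts": sorted(artifacts),
        "config": config.to_dict(),
    }
    _write_json(out / "manifest.json", manifest, config)
    return {"state": state, "manifest": manifest, "outdir": out}
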