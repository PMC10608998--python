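"""Configuration and orchestration of the end-to-end study reproduction.

One config file (YAML, unit-suffixed keys) describes geometry, fluid,
particle, flow rates, grid, acquisition and analysis parameters; defaults
reproduce the validation study's device and conditions.  ``run_pipeline``
solves the field, advects particles, generates synthetic tracks, analyzes
them and writes the comparison report plus all intermediate artifacts.
Everything is deterministic given the config seeds: Stokes linearity lets a
single reference solve per grid be rescaled exactly to every flow rate.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import yaml

from .analysis import (ComparisonReport, compare_experiment_numerical,
                       fit_strain_rate, fit_track_strain_rate)
from .flow import (FluidProperties, FlowField2D, reynolds_number,
                   solve_depth_averaged_stokes)
from .geometry import ChannelGeometry, build_grid
from .particles import ParticleProperties, advect_through_channel
from .tracking import AcquisitionModel, generate_track_table, write_track_csv

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "numerical_strain_rate_fit"]

logger = logging.getLogger("hyperflow")

ML_PER_H = 1e-6 / 3600.0  # m^3/s per mL/h

_GEOM_KEYS = ("w_u_um", "w_c_um", "L_c_um", "h_um", "L_in_um", "L_out_um")

DEFAULT_CONFIG = {
    "geometry": {"w_u_um": 406.0, "w_c_um": 17.0, "L_c_um": 780.0,
                 "h_um": 60.0, "L_in_um": 500.0, "L_out_um": 500.0},
    "fluid": {"rho_kgm3": 1046.0, "mu_pas": 4.5e-3},
    "particle": {"d_p_um": 8.0, "rho_p_kgm3": 1080.0},
    "flow_rates_mlh": [7.9e-3, 0.035, 0.265],
    "grid": {"nx": 512, "ny": 128},
    "fit_window_um": [0.0, 500.0],
    # frame_rate_fps null = auto per flow rate (slow flows filmed at the low
    # end of the camera range, the fastest at the high end)
    "acquisition": {"frame_rate_fps": None, "pixel_size_um": 0.5,
                    "localization_sigma_um": 0.25, "fov_um": [-100.0, 550.0]},
    "release_x_um": -100.0,
    "release_y_um": [-5.0, 0.0, 5.0],
    "seed": 1234,
}


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure, carrying the partial-artifact manifest."""

    def __init__(self, stage: str, message: str, manifest=None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.manifest = list(manifest or [])


@dataclass
class PipelineConfig:
    geometry: ChannelGeometry
    fluid: FluidProperties
    particle: ParticleProperties
    flow_rates_mlh: list
    grid_nx: int = 512
    grid_ny: int = 128
    fit_window_um: tuple = (0.0, 500.0)
    frame_rate_fps: float | None = None
    pixel_size_um: float = 0.5
    localization_sigma_um: float = 0.25
    fov_um: tuple = (-100.0, 550.0)
    release_x_um: float = -100.0
    release_y_um: tuple = (-5.0, 0.0, 5.0)
    seed: int = 1234

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls.from_dict({})

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        unknown = set(d) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def block(name):
            given = d.get(name)
            if given is None:
                return dict(DEFAULT_CONFIG[name])
            missing = set(DEFAULT_CONFIG[name]) - set(given)
            if missing:
                raise ValueError(
                    f"missing required config key(s) in '{name}': {sorted(missing)}")
            extra = set(given) - set(DEFAULT_CONFIG[name])
            if extra:
                raise ValueError(f"unknown key(s) in '{name}': {sorted(extra)}")
            return dict(given)

        g = block("geometry")
        fl = block("fluid")
        pt = block("particle")
        gr = block("grid")
        acq = block("acquisition")
        geometry = ChannelGeometry.from_um(
            g["w_u_um"], g["w_c_um"], g["L_c_um"], g["h_um"],
            g["L_in_um"], g["L_out_um"])
        fluid = FluidProperties(rho=float(fl["rho_kgm3"]), mu=float(fl["mu_pas"]))
        particle = ParticleProperties(d_p=float(pt["d_p_um"]) * 1e-6,
                                      rho_p=float(pt["rho_p_kgm3"]))
        fr = acq["frame_rate_fps"]
        return cls(
            geometry=geometry, fluid=fluid, particle=particle,
            flow_rates_mlh=[float(q) for q in d.get("flow_rates_mlh",
                                                    DEFAULT_CONFIG["flow_rates_mlh"])],
            grid_nx=int(gr["nx"]), grid_ny=int(gr["ny"]),
            fit_window_um=tuple(d.get("fit_window_um",
                                      DEFAULT_CONFIG["fit_window_um"])),
            frame_rate_fps=None if fr is None else float(fr),
            pixel_size_um=float(acq["pixel_size_um"]),
            localization_sigma_um=float(acq["localization_sigma_um"]),
            fov_um=tuple(acq["fov_um"]),
            release_x_um=float(d.get("release_x_um",
                                     DEFAULT_CONFIG["release_x_um"])),
            release_y_um=tuple(d.get("release_y_um",
                                     DEFAULT_CONFIG["release_y_um"])),
            seed=int(d.get("seed", DEFAULT_CONFIG["seed"])),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def auto_frame_rate(self, Q_mlh: float) -> float:
        """Frame rate for a flow rate: configured value, else the camera's low
        end (4800 fps) for slow flows and high end (13000 fps) above 0.1 mL/h."""
        if self.frame_rate_fps is not None:
            return self.frame_rate_fps
        return 13000.0 if Q_mlh > 0.1 else 4800.0

    def window_m(self) -> tuple:
        return (self.fit_window_um[0] * 1e-6, self.fit_window_um[1] * 1e-6)


def numerical_strain_rate_fit(field: FlowField2D, fluid: FluidProperties,
                              particle: ParticleProperties, *,
                              release=( -100e-6, 0.0), window=(0.0, 500e-6)):
    """The pipeline's numerical-side fit: advect a midplane centerline tracer
    and regress its axial velocity on position over the contraction window."""
    traj = advect_through_channel(field, fluid, particle, release,
                                  x_stop=window[1] + 50e-6)
    return fit_strain_rate(traj.x, traj.u, window), traj


def run_pipeline(config: PipelineConfig, outdir) -> ComparisonReport:
    """Full study reproduction; artifacts and a logfile land in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    fh = logging.FileHandler(outdir / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler)
               for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))

    try:
        try:
            grid = build_grid(config.geometry, config.grid_nx, config.grid_ny)
            Q_ref = max(config.flow_rates_mlh) * ML_PER_H
            field_ref = solve_depth_averaged_stokes(grid, config.fluid, Q_ref)
            logger.info("solved %dx%d grid, residual %.3e",
                        config.grid_nx, config.grid_ny, field_ref.residual)
        except Exception as exc:
            raise PipelineError("solve", str(exc), manifest) from exc

        window = config.window_m()
        exp_fits, num_fits = {}, {}
        seed_seq = np.random.SeedSequence(config.seed)
        child_seeds = seed_seq.generate_state(len(config.flow_rates_mlh)) % (2 ** 31)

        for k, Q_mlh in enumerate(sorted(config.flow_rates_mlh)):
            Q = Q_mlh * ML_PER_H
            fld = field_ref.with_flow_rate(Q)
            Re = reynolds_number(config.fluid, config.geometry, Q)
            logger.info("Q = %g mL/h: Re = %.4g, fit window = [%g, %g] um",
                        Q_mlh, Re, *config.fit_window_um)

            try:
                num_fit, traj = numerical_strain_rate_fit(
                    fld, config.fluid, config.particle,
                    release=(config.release_x_um * 1e-6, 0.0), window=window)
                traj.to_dataframe().to_csv(
                    outdir / f"tracer_Q{Q_mlh:g}.csv", index=False)
                manifest.append(f"tracer_Q{Q_mlh:g}.csv")
            except Exception as exc:
                raise PipelineError("advect", str(exc), manifest) from exc

            try:
                acq = AcquisitionModel(
                    frame_rate=config.auto_frame_rate(Q_mlh),
                    pixel_size=config.pixel_size_um,
                    localization_sigma=config.localization_sigma_um,
                    field_of_view=tuple(config.fov_um),
                    seed=int(child_seeds[k]))
                releases = [(config.release_x_um * 1e-6, y * 1e-6)
                            for y in config.release_y_um]
                table = generate_track_table(fld, config.fluid, config.particle,
                                             releases, acq)
                write_track_csv(table, outdir / f"tracks_Q{Q_mlh:g}.csv")
                manifest.append(f"tracks_Q{Q_mlh:g}.csv")
            except Exception as exc:
                raise PipelineError("synth-tracks", str(exc), manifest) from exc

            try:
                fits = [fit_track_strain_rate(sub, window)
                        for _, sub in table.groupby("track_id", sort=True)]
                exp_fits[Q_mlh] = fits
                num_fits[Q_mlh] = num_fit
                logger.info("  numerical %.4g 1/s; synthetic-experimental %s",
                            num_fit.slope,
                            ", ".join(f"{f.slope:.4g}" for f in fits))
            except Exception as exc:
                raise PipelineError("analyze", str(exc), manifest) from exc

        try:
            report = compare_experiment_numerical(exp_fits, num_fits)
            report.to_csv(outdir / "report.csv")
            report.to_json(outdir / "report.json")
            manifest += ["report.csv", "report.json"]
        except Exception as exc:
            raise PipelineError("compare", str(exc), manifest) from exc
        return report
    finally:
        logger.removeHandler(fh)
        fh.close()
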