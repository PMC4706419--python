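"""Run configuration, orchestration and persistence.

A RunConfig captures everything needed to reproduce a run: morphology
parameters, schedule, pose grid, the analyses to execute, output directory
and seed.  ``run_pipeline`` executes the requested stages in dependency order
(array -> sweeps -> contact table -> analyses) and writes a manifest with the
produced files, a config hash and package versions.  Angles are degrees and
distances mm in all I/O; summary CSVs are written with 6 significant digits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .array_model import ArraySpec, MorphologyParams, ParameterError, build_default_array
from .contact_sim import HeadPose, PoseGrid, cylinder_contact_check, simulate_grid
from .inference import correlation_vs_uncertainty, group_average_maps, uniqueness
from .kinematics import KinematicCoeffs, ProtractionSchedule
from .mappings import blind_spot, guaranteed_contact_distance, reachability, yaw_from_contacts
from .sensitivity import PerturbationSpec, run_sensitivity

FLOAT_FMT = "%.6g"

ANALYSES = ("reach", "blindspot", "yawcurve", "correlate", "unique",
            "groupmaps", "sensitivity", "cylinder")


class ConfigError(ValueError):
    """Invalid run configuration; message carries the offending field."""


@dataclass
class GridSpec:
    d_max: float = 60.0
    d_step: float = 1.0
    yaw_max: float = 90.0
    yaw_step: float = 5.0
    pitch_max: float = 90.0
    pitch_step: float = 5.0

    def build(self) -> PoseGrid:
        for name in ("d_step", "yaw_step", "pitch_step"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"grid.{name} must be > 0")
        return PoseGrid(
            distances=np.arange(0.0, self.d_max + 1e-9, self.d_step),
            yaws=np.arange(-self.yaw_max, self.yaw_max + 1e-9, self.yaw_step),
            pitches=np.arange(-self.pitch_max, self.pitch_max + 1e-9, self.pitch_step),
        )


@dataclass
class RunConfig:
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    schedule: ProtractionSchedule = field(default_factory=ProtractionSchedule)
    grid: GridSpec = field(default_factory=GridSpec)
    analyses: tuple = ("reach",)
    kinematic_overrides: dict = field(default_factory=dict)
    uniqueness_tolerance: float = 5.0
    uniqueness_min_whisking: int = 0
    uncertainty_axis: str = "yaw"
    uncertainties: tuple = tuple(float(u) for u in range(0, 181, 15))
    blindspot_amplitude: float = 60.0
    blindspot_voxel_mm: float = 1.0
    cylinder_radius_mm: float = 140.0
    sensitivity_reps: int = 100
    outdir: str = "whiskscape_out"
    seed: int = 0

    def validate(self) -> None:
        for a in self.analyses:
            if a not in ANALYSES:
                raise ConfigError(f"analyses: unknown stage {a!r}; valid: {ANALYSES}")
        if self.uniqueness_tolerance <= 0:
            raise ConfigError("uniqueness_tolerance must be > 0")

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        d = plain(dataclasses.asdict(self))
        d["schedule"]["amplitude"] = self.schedule.amplitude
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            if "morphology" in d:
                m = dict(d["morphology"])
                if "pad_center" in m:
                    m["pad_center"] = tuple(m["pad_center"])
                d["morphology"] = MorphologyParams(**m)
            if "schedule" in d:
                d["schedule"] = ProtractionSchedule(**d["schedule"])
            if "grid" in d:
                d["grid"] = GridSpec(**d["grid"])
            if "analyses" in d:
                d["analyses"] = tuple(d["analyses"])
            if "uncertainties" in d:
                d["uncertainties"] = tuple(d["uncertainties"])
            return cls(**d)
        except (TypeError, ParameterError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    def hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)   # where outputs land does not affect their content
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df, path, header_lines=()):
    with open(path, "w") as f:
        for line in header_lines:
            f.write(f"# {line}\n")
        df.to_csv(f, index=False, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    header = (f"whiskscape {__version__}", f"config_hash {cfg_hash}")
    manifest = dict(config_hash=cfg_hash, version=__version__, files=[],
                    timings_s={}, counts={})

    def emit(name, df):
        path = outdir / name
        _write_csv(df, path, header)
        manifest["files"].append(name)

    t0 = time.perf_counter()
    array = build_default_array(config.morphology)
    coeffs = KinematicCoeffs.default().with_overrides(config.kinematic_overrides)
    array.to_csv(outdir / "array.csv")
    manifest["files"].append("array.csv")
    grid = config.grid.build()
    table = simulate_grid(array, coeffs, config.schedule, grid)
    manifest["counts"]["contact_records"] = int(table.n_whiskers * grid.n_poses)
    table.to_hdf5(outdir / "contact_table.h5")
    manifest["files"].append("contact_table.h5")
    manifest["timings_s"]["simulate"] = round(time.perf_counter() - t0, 3)

    for stage in config.analyses:
        t0 = time.perf_counter()
        if stage == "reach":
            summary = reachability(table)
            df = summary.thresholds.copy()
            df["guaranteed_contact_distance_mm"] = guaranteed_contact_distance(summary)
            emit("reachability.csv", df)
        elif stage == "blindspot":
            bs = blind_spot(array, coeffs, config.blindspot_amplitude,
                            config.blindspot_voxel_mm)
            pts = bs.blind_points()
            import pandas as pd
            emit("blindspot_voxels.csv",
                 pd.DataFrame(pts, columns=["x_mm", "y_mm", "z_mm"]))
            manifest["counts"]["blind_voxels"] = int(bs.blind.sum())
        elif stage == "yawcurve":
            emit("yaw_curve.csv", yaw_from_contacts(table).to_dataframe())
        elif stage == "correlate":
            curve = correlation_vs_uncertainty(table, config.uncertainty_axis,
                                               config.uncertainties)
            df = curve.r_by_row.reset_index(names="uncertainty_deg")
            emit(f"correlation_{config.uncertainty_axis}.csv", df)
        elif stage == "unique":
            res = uniqueness(table, config.uniqueness_tolerance,
                             config.uniqueness_min_whisking)
            import pandas as pd
            emit("uniqueness.csv", pd.DataFrame([dataclasses.asdict(res) | dict(
                fraction_unique=res.fraction_unique)]))
        elif stage == "groupmaps":
            for grouping in ("row", "column"):
                gm = group_average_maps(table, grouping)
                import pandas as pd
                recs = []
                for g, grp in enumerate(gm.groups):
                    for i, d in enumerate(gm.distances):
                        for j, p in enumerate(gm.pitches):
                            recs.append(dict(group=grp, d_mm=d, pitch_deg=p,
                                             mean_theta_impact_deg=gm.mean_theta[g, i, j],
                                             flag=int(gm.flags[g, i, j])))
                emit(f"groupmap_{grouping}.csv", pd.DataFrame(recs))
        elif stage == "sensitivity":
            summary = run_sensitivity(array, coeffs, reps=config.sensitivity_reps,
                                      seed=config.seed,
                                      spec=PerturbationSpec(seed=config.seed))
            emit("sensitivity.csv", summary.per_whisker)
        elif stage == "cylinder":
            poses = [HeadPose(float(d), 0.0, 0.0) for d in (5, 10, 15, 20)]
            df = cylinder_contact_check(array, coeffs, config.schedule,
                                        config.cylinder_radius_mm, poses)
            emit("cylinder_check.csv", df)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest
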