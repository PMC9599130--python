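"""Serialization: geometries and recordings to HDF5, snapshots/profiles/sweeps
to CSV, plus run manifests for provenance."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .analysis import ConcentrationProfile
from .dynamics import ParticleEnsemble, Recording, SimulationConfig
from .experiments import SweepGrid
from .geometry import Geometry, GeometryParams, geometry_from_spheres

_KIND_STR = np.array(["neuronal", "astroglial"])


def run_manifest(config_objects: dict, seeds: dict,
                 outputs: Sequence[str | Path]) -> dict:
    """Provenance record: config hash, seeds, package version, timestamps."""
    cfg_json = json.dumps(
        {k: (v.model_dump() if hasattr(v, "model_dump") else v)
         for k, v in config_objects.items()}, sort_keys=True, default=str)
    return {
        "package": "spillsim",
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": json.loads(cfg_json),
        "seeds": dict(seeds),
        "created_utc": datetime.datetime.now(datetime.timezone.utc)
        .isoformat(timespec="seconds"),
        "outputs": [str(p) for p in outputs],
    }


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def save_geometry(path: str | Path, geometry: Geometry) -> None:
    """HDF5 layout: datasets centers [n×3 μm], radii [n], kinds [n int8];
    params/seed/realized fractions as attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("centers", data=geometry.centers)
        f.create_dataset("radii", data=geometry.radii)
        f.create_dataset("kinds", data=geometry.kinds)
        f.attrs["params_json"] = geometry.params.model_dump_json()
        f.attrs["seed"] = -1 if geometry.seed is None else geometry.seed
        f.attrs["realized_alpha"] = geometry.realized_alpha
        f.attrs["realized_astro_fraction"] = geometry.realized_astro_fraction
        f.attrs["spillsim_version"] = __version__


def load_geometry(path: str | Path) -> Geometry:
    with h5py.File(path, "r") as f:
        params = GeometryParams.model_validate_json(f.attrs["params_json"])
        geom = geometry_from_spheres(f["centers"][...], f["radii"][...],
                                     f["kinds"][...], params=params)
        geom.realized_alpha = float(f.attrs["realized_alpha"])
        geom.realized_astro_fraction = float(
            f.attrs["realized_astro_fraction"])
        seed = int(f.attrs["seed"])
        geom.seed = None if seed < 0 else seed
    return geom


def geometry_to_csv(path: str | Path, geometry: Geometry) -> None:
    """Plain x,y,z,radius,kind table (μm) for interoperability/plotting."""
    df = pd.DataFrame({
        "x": geometry.centers[:, 0], "y": geometry.centers[:, 1],
        "z": geometry.centers[:, 2], "radius": geometry.radii,
        "kind": _KIND_STR[geometry.kinds],
    })
    df.to_csv(path, index=False)


def geometry_from_csv(path: str | Path,
                      params: GeometryParams | None = None) -> Geometry:
    df = pd.read_csv(path)
    kinds = (df["kind"].to_numpy() == "astroglial").astype(np.int8)
    return geometry_from_spheres(df[["x", "y", "z"]].to_numpy(),
                                 df["radius"].to_numpy(), kinds,
                                 params=params)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def save_recording(path: str | Path, recording: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config_json"] = recording.config.model_dump_json()
        f.attrs["geometry_seed"] = (-1 if recording.geometry_seed is None
                                    else recording.geometry_seed)
        f.attrs["n_rejected_steps"] = recording.n_rejected_steps
        f.attrs["extra_json"] = json.dumps(recording.extra)
        f.attrs["spillsim_version"] = __version__
        f.create_dataset("bound_count_times", data=recording.bound_count_times)
        f.create_dataset("bound_counts", data=recording.bound_counts)
        snaps = f.create_group("snapshots")
        for i, s in enumerate(recording.snapshots):
            g = snaps.create_group(f"{i:04d}")
            g.attrs["time"] = s.time
            g.create_dataset("positions", data=s.positions)
            g.create_dataset("state", data=s.state)
            g.create_dataset("shell_clock", data=s.shell_clock)
            g.create_dataset("bound_time", data=s.bound_time)


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        config = SimulationConfig.model_validate_json(f.attrs["config_json"])
        snapshots = []
        for key in sorted(f["snapshots"].keys()):
            g = f["snapshots"][key]
            snapshots.append(ParticleEnsemble(
                positions=g["positions"][...], state=g["state"][...],
                shell_clock=g["shell_clock"][...],
                bound_time=g["bound_time"][...],
                time=float(g.attrs["time"])))
        seed = int(f.attrs["geometry_seed"])
        return Recording(
            snapshots=snapshots,
            bound_count_times=f["bound_count_times"][...],
            bound_counts=f["bound_counts"][...],
            config=config,
            geometry_seed=None if seed < 0 else seed,
            n_rejected_steps=int(f.attrs["n_rejected_steps"]),
            extra=json.loads(f.attrs["extra_json"]))


def snapshot_to_csv(path: str | Path, snapshot: ParticleEnsemble) -> None:
    """x,y,z,state table; state is 'free' or 'bound'."""
    df = pd.DataFrame({
        "x": snapshot.positions[:, 0], "y": snapshot.positions[:, 1],
        "z": snapshot.positions[:, 2],
        "state": np.where(snapshot.state == 0, "free", "bound"),
    })
    df.to_csv(path, index=False)


def snapshot_to_xyz(path: str | Path, snapshot: ParticleEnsemble) -> None:
    """XYZ point-cloud text: element F for free, B for bound molecules."""
    lines = [str(snapshot.n_molecules),
             f"glutamate snapshot t={snapshot.time} ms (coordinates in um)"]
    for i in range(snapshot.n_molecules):
        el = "F" if snapshot.state[i] == 0 else "B"
        x, y, z = snapshot.positions[i]
        lines.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# analysis products
# ---------------------------------------------------------------------------

def profiles_to_csv(path: str | Path,
                    profiles: Sequence[ConcentrationProfile]) -> None:
    """Tidy long-format table (time_ms, r_um, free_uM, bound_uM, ratio, se)."""
    pd.concat([p.to_frame() for p in profiles],
              ignore_index=True).to_csv(path, index=False)


def save_profiles(path: str | Path,
                  profiles: Sequence[ConcentrationProfile]) -> None:
    """HDF5 mirror of the tidy profile table, one group per time point."""
    with h5py.File(path, "w") as f:
        f.attrs["spillsim_version"] = __version__
        for i, p in enumerate(profiles):
            g = f.create_group(f"{i:04d}")
            g.attrs["time_ms"] = p.time
            g.attrs["n_trials"] = p.n_trials
            g.create_dataset("bin_edges", data=p.bin_edges)
            g.create_dataset("free_counts", data=p.free_counts)
            g.create_dataset("bound_counts", data=p.bound_counts)
            g.create_dataset("ecs_shell_volume", data=p.ecs_shell_volume)
            if p.free_se is not None:
                g.create_dataset("free_se", data=p.free_se)
                g.create_dataset("bound_se", data=p.bound_se)


def sweep_to_csv(path: str | Path, grid: SweepGrid) -> None:
    grid.to_frame().to_csv(path, index=False)


def save_sweep(path: str | Path, grid: SweepGrid) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("psi_values", data=grid.psi_values)
        f.create_dataset("alpha_values", data=grid.alpha_values)
        f.create_dataset("timepoints", data=grid.timepoints)
        f.create_dataset("lambda_free", data=grid.lambda_free)
        f.create_dataset("lambda_bound", data=grid.lambda_bound)
        f.create_dataset("se_free", data=grid.se_free)
        f.create_dataset("se_bound", data=grid.se_bound)
        f.attrs["n_trials"] = grid.n_trials
        f.attrs["spillsim_version"] = __version__
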