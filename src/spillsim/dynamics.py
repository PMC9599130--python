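"""Brownian glutamate dynamics: release, reflecting random walk, binding.

Molecules are released uniformly inside the synaptic cleft and perform a
fixed-length isotropic random walk (step δ, time step dt = δ²/6D).  Cell
surfaces — neuronal and astroglial spheres, the two cleft membrane disks and
the arena walls — reflect specularly.  While a free molecule is within the
proximity shell (default 5 nm) of an astroglial surface it is exposed to the
first-order binding hazard 1 − exp(−dt/Ψ); binding is irreversible on the
simulated ≤5 ms window (transporter unbinding is tens of ms) and freezes the
molecule at its binding site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import _kernels
from .geometry import NM_PER_UM, Cleft, Geometry

logger = logging.getLogger(__name__)

FREE = 0
BOUND = 1


class SimulationConfig(BaseModel):
    """Simulation parameters (lengths of the walk in nm, times in ms)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_molecules: int = Field(1000, gt=0)
    D_free: float = Field(0.5, gt=0, description="free diffusivity, μm²/ms")
    psi: float = Field(1.0, gt=0, description="binding time constant Ψ, ms")
    step_length: float = Field(5.0, gt=0, description="walk step δ, nm")
    binding_shell: float = Field(5.0, gt=0,
                                 description="astroglial proximity shell, nm")
    duration: float = Field(3.0, ge=0, le=5.0,
                            description="simulated time, ms (≤5: no "
                                        "unbinding is modelled beyond that)")
    snapshot_times: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0)
    seed: int = 0
    max_reflections: int = Field(8, gt=0)
    gaussian_steps: bool = Field(
        False, description="Gaussian displacements instead of fixed-length "
                           "steps (same dt); non-default variant")
    record_every: int | None = Field(
        None, gt=0, description="steps between bound-count records "
                                "(default ≈ 256 records per run)")

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.step_length > self.binding_shell:
            raise ValueError(
                "step_length must not exceed binding_shell, otherwise the "
                "proximity shell can be jumped over in one step")
        if any(t < 0 for t in self.snapshot_times):
            raise ValueError("snapshot_times must be non-negative")
        return self

    @property
    def step_length_um(self) -> float:
        return self.step_length / NM_PER_UM

    @property
    def binding_shell_um(self) -> float:
        return self.binding_shell / NM_PER_UM

    @property
    def dt(self) -> float:
        """Time per step, ms: δ² / 6D (3-D fixed-step walk relation)."""
        return self.step_length_um ** 2 / (6.0 * self.D_free)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class ParticleEnsemble:
    """Positions and binding states of all molecules at one instant.

    Bound molecules are frozen: their ``positions`` row is the binding site.
    ``shell_clock`` is the time since a free molecule last (re-)entered the
    astroglial proximity shell; it resets to zero on leaving the shell.
    """
    positions: np.ndarray        # (n, 3) μm
    state: np.ndarray            # (n,) int8: 0 free, 1 bound
    shell_clock: np.ndarray      # (n,) ms
    bound_time: np.ndarray       # (n,) ms, NaN while free
    time: float = 0.0            # ms since release

    @property
    def n_molecules(self) -> int:
        return len(self.state)

    @property
    def n_free(self) -> int:
        return int(np.count_nonzero(self.state == FREE))

    @property
    def n_bound(self) -> int:
        return int(np.count_nonzero(self.state == BOUND))

    @property
    def bound_positions(self) -> np.ndarray:
        return self.positions[self.state == BOUND]

    def copy(self) -> "ParticleEnsemble":
        return ParticleEnsemble(self.positions.copy(), self.state.copy(),
                                self.shell_clock.copy(),
                                self.bound_time.copy(), self.time)


@dataclass
class Recording:
    """Snapshots and the bound-count time series of one simulation run."""
    snapshots: list[ParticleEnsemble]
    bound_count_times: np.ndarray
    bound_counts: np.ndarray
    config: SimulationConfig
    geometry_seed: int | None = None
    n_rejected_steps: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def times(self) -> list[float]:
        return [s.time for s in self.snapshots]

    def snapshot_at(self, time: float, atol: float | None = None) -> ParticleEnsemble:
        tol = atol if atol is not None else 0.51 * self.config.dt
        for s in self.snapshots:
            if abs(s.time - time) <= tol:
                return s
        raise KeyError(f"no snapshot at t={time} ms; have {self.times}")


class MotionResult(NamedTuple):
    positions: np.ndarray
    rejected: np.ndarray  # bool mask of steps that could not be completed


def init_release(config: SimulationConfig, cleft: Cleft,
                 seed: int | None = None,
                 rng: np.random.Generator | None = None) -> ParticleEnsemble:
    """Release molecules uniformly over the cleft cylinder volume, all free."""
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_molecules
    r = cleft.radius * np.sqrt(rng.random(n))
    theta = 2 * np.pi * rng.random(n)
    z = cleft.center[2] + cleft.half_height * (2 * rng.random(n) - 1)
    pos = np.column_stack([cleft.center[0] + r * np.cos(theta),
                           cleft.center[1] + r * np.sin(theta), z])
    return ParticleEnsemble(positions=pos,
                            state=np.zeros(n, dtype=np.int8),
                            shell_clock=np.zeros(n),
                            bound_time=np.full(n, np.nan),
                            time=0.0)


def propose_step(positions: np.ndarray, step_length: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Isotropic fixed-length displacements (step_length in μm)."""
    n = len(positions)
    z = 1 - 2 * rng.random(n)
    phi = 2 * np.pi * rng.random(n)
    s = np.sqrt(np.maximum(0.0, 1 - z * z))
    return step_length * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def resolve_motion(old_positions: np.ndarray, proposed_positions: np.ndarray,
                   geometry: Geometry,
                   max_reflections: int = 8) -> MotionResult:
    """Resolve each segment old→proposed against all reflecting surfaces.

    The first surface crossing is found, the remaining displacement is
    mirror-reflected about the local tangent plane, and the process repeats.
    Steps that cannot be completed within the reflection budget are rejected
    (the particle stays put) and flagged in the returned mask.
    """
    old = np.ascontiguousarray(np.atleast_2d(old_positions), dtype=np.float64)
    prop = np.ascontiguousarray(np.atleast_2d(proposed_positions),
                                dtype=np.float64)
    g, c = geometry.grid, geometry.cleft
    final, rejected = _kernels.resolve_motion_batch(
        old, prop, geometry.centers, geometry.radii,
        g.cell_start, g.entries, g.cell_edge, g.n_cells,
        geometry.arena_edge, c.center[0], c.center[1], c.center[2],
        c.radius, c.half_height, c.reflect_faces, max_reflections)
    if rejected.any():
        logger.debug("resolve_motion rejected %d steps", rejected.sum())
    return MotionResult(final, rejected)


def update_binding(ensemble: ParticleEnsemble, geometry: Geometry, dt: float,
                   psi: float, rng: np.random.Generator,
                   binding_shell: float = 0.005) -> ParticleEnsemble:
    """Apply one time step of the astroglial binding hazard (in place).

    Free molecules within ``binding_shell`` (μm) of an astroglial surface
    accumulate shell time and bind with probability 1 − exp(−dt/Ψ); molecules
    beyond the shell have their shell clock reset.  Bound molecules never
    unbind.
    """
    from .geometry import astro_distances

    free = ensemble.state == FREE
    if not free.any():
        return ensemble
    idx = np.flatnonzero(free)
    geom = geometry.with_grid_margin(binding_shell * 1.001)
    adist = astro_distances(ensemble.positions[idx], geom, binding_shell)
    in_shell = adist <= binding_shell
    ensemble.shell_clock[idx[~in_shell]] = 0.0
    hits = idx[in_shell]
    ensemble.shell_clock[hits] += dt
    if hits.size:
        p = 1.0 - np.exp(-dt / psi)
        bind = rng.random(hits.size) < p
        newly = hits[bind]
        ensemble.state[newly] = BOUND
        ensemble.bound_time[newly] = ensemble.time
        ensemble.shell_clock[newly] = 0.0
    return ensemble


def simulate(geometry: Geometry, config: SimulationConfig,
             seed: int | None = None) -> Recording:
    """Run a full release: init, then walk/reflect/bind until ``duration``.

    Deterministic given (geometry, seed); ``seed`` defaults to
    ``config.seed``.  Snapshots are stored at each requested time ≤ duration
    (snapped to the step grid) plus the initial state.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    seed_release, seed_walk = [int(s) & 0x7FFFFFFF for s in ss.generate_state(2)]

    ens = init_release(config, geometry.cleft, seed=seed_release)
    dt = config.dt
    n_steps = config.n_steps
    snap_steps = sorted({int(round(t / dt)) for t in config.snapshot_times
                         if t <= config.duration + 1e-12} | {0}) \
        if n_steps > 0 else [0]
    snap_steps = np.array([s for s in snap_steps if s <= n_steps],
                          dtype=np.int64)
    record_every = config.record_every or max(1, n_steps // 256)

    needed_margin = config.step_length_um + config.binding_shell_um
    geom = geometry.with_grid_margin(needed_margin * 1.001)
    g, c = geom.grid, geom.cleft

    # astroglial-only candidate index for the binding-shell test
    astro = geom.kinds == 1
    astro_centers = np.ascontiguousarray(geom.centers[astro])
    astro_radii = np.ascontiguousarray(geom.radii[astro])
    a_start, a_entries, _ = _kernels.build_grid(
        astro_centers, astro_radii, g.margin, g.cell_edge, geom.arena_edge)

    p_bind = 1.0 - np.exp(-dt / config.psi)
    gauss_sigma = np.sqrt(2.0 * config.D_free * dt)

    (snap_pos, snap_state, snap_clock, snap_bt, bound_counts, rec_times,
     n_rejected) = _kernels.run_sim(
        ens.positions, ens.state, ens.shell_clock, ens.bound_time,
        geom.centers, geom.radii, geom.kinds,
        g.cell_start, g.entries, g.cell_edge, g.n_cells, g.margin,
        astro_centers, astro_radii, a_start, a_entries,
        geom.arena_edge, c.center[0], c.center[1], c.center[2],
        c.radius, c.half_height, c.reflect_faces,
        config.step_length_um, dt, p_bind, config.binding_shell_um,
        n_steps, snap_steps, record_every,
        seed_walk, config.max_reflections, config.gaussian_steps, gauss_sigma)

    snapshots = [ParticleEnsemble(snap_pos[i].copy(), snap_state[i].copy(),
                                  snap_clock[i].copy(), snap_bt[i].copy(),
                                  time=float(snap_steps[i] * dt))
                 for i in range(len(snap_steps))]
    if n_rejected:
        logger.info("simulate: %d rejected steps out of %d",
                    n_rejected, n_steps * config.n_molecules)
    return Recording(snapshots=snapshots,
                     bound_count_times=rec_times,
                     bound_counts=bound_counts,
                     config=config,
                     geometry_seed=geometry.seed,
                     n_rejected_steps=int(n_rejected),
                     extra={"realized_alpha": geometry.realized_alpha,
                            "realized_astro_fraction":
                                geometry.realized_astro_fraction})


def msd(recording: Recording, reference: ParticleEnsemble | None = None) \
        -> tuple[np.ndarray, np.ndarray]:
    """Mean squared displacement of free molecules at each snapshot time,
    relative to the initial (release) positions."""
    ref = reference or recording.snapshots[0]
    times, values = [], []
    for snap in recording.snapshots:
        d = snap.positions - ref.positions
        times.append(snap.time)
        values.append(float(np.mean(np.sum(d * d, axis=1))))
    return np.array(times), np.array(values)
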