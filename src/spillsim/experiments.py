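"""Multi-trial orchestration and the Ψ×α parameter sweep.

Every trial generates a fresh geometry realization (the stochastic tissue is
part of the experiment) and runs one release; profiles are averaged across
trials.  The sweep evaluates the length constant λ of the free and bound
glutamate profiles over a grid of binding time constants Ψ and ECS fractions
α at selected time points.

Seed bookkeeping: trial seeds derive deterministically from ``seed_root``.
With ``paired_seeds=True`` (default) every sweep cell reuses the same trial
streams — common random numbers, which suppress sampling noise in Ψ/α trend
comparisons.  With ``paired_seeds=False`` each cell gets its own stream
family, making the (seed_root, cell, trial) → stream map injective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .analysis import (ConcentrationProfile, average_profiles,
                       length_constant, radial_profile)
from .dynamics import Recording, SimulationConfig, simulate
from .geometry import Geometry, GeometryParams, generate_geometry

logger = logging.getLogger(__name__)


class SweepSpec(BaseModel):
    """Grid specification for the Ψ×α sweep."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    psi_values: tuple[float, ...] = (0.3, 0.6, 1.0, 2.0, 4.0)
    alpha_values: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25, 0.30)
    timepoints: tuple[float, ...] = (0.3, 3.0)
    n_trials: int = Field(10, gt=0)
    base_config: SimulationConfig = SimulationConfig()
    base_geometry_params: GeometryParams = GeometryParams()
    seed_root: int = 0
    paired_seeds: bool = True
    bin_width: float = Field(25.0, gt=0, description="profile bin width, nm")
    profile_points: int = Field(100_000, ge=1000)

    @model_validator(mode="after")
    def _check(self) -> "SweepSpec":
        if not self.psi_values or not self.alpha_values or not self.timepoints:
            raise ValueError("psi_values, alpha_values and timepoints must "
                             "be non-empty")
        if any(p <= 0 for p in self.psi_values):
            raise ValueError("psi values must be positive")
        if any(not (0.1 - 1e-9 <= a <= 0.3 + 1e-9)
               for a in self.alpha_values):
            raise ValueError("alpha values must lie in the validated range "
                             "[0.1, 0.3]")
        if any(t <= 0 or t > 5.0 for t in self.timepoints):
            raise ValueError("timepoints must lie in (0, 5] ms")
        return self


@dataclass
class TrialSet:
    """Recordings and trial-averaged profiles from n independent trials."""
    recordings: list[Recording]
    geometries: list[Geometry]
    profiles: dict[float, ConcentrationProfile]       # time -> averaged
    per_trial_profiles: dict[float, list[ConcentrationProfile]]
    seed_root: int

    @property
    def n_trials(self) -> int:
        return len(self.recordings)


@dataclass
class SweepGrid:
    """λ (μm) for free and bound species over the (Ψ, α, time) grid."""
    psi_values: np.ndarray
    alpha_values: np.ndarray
    timepoints: np.ndarray
    lambda_free: np.ndarray      # (n_psi, n_alpha, n_time); NaN = undefined
    lambda_bound: np.ndarray
    se_free: np.ndarray
    se_bound: np.ndarray
    n_trials: int

    @property
    def defined_free(self) -> np.ndarray:
        return np.isfinite(self.lambda_free)

    @property
    def defined_bound(self) -> np.ndarray:
        return np.isfinite(self.lambda_bound)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, psi in enumerate(self.psi_values):
            for j, alpha in enumerate(self.alpha_values):
                for k, t in enumerate(self.timepoints):
                    for species, lam, se in (
                            ("free", self.lambda_free, self.se_free),
                            ("bound", self.lambda_bound, self.se_bound)):
                        rows.append({"psi_ms": psi, "alpha": alpha,
                                     "time_ms": t, "species": species,
                                     "lambda_um": lam[i, j, k],
                                     "se": se[i, j, k],
                                     "n_trials": self.n_trials})
        return pd.DataFrame(rows)


def _trial_seeds(seed_root: int, n_trials: int,
                 cell: tuple[int, int] | None = None) -> list[tuple[int, int, int]]:
    """(geometry, simulation, profile) seeds per trial, all below 2^31."""
    key = (seed_root,) if cell is None else (seed_root, *cell)
    out = []
    for t in range(n_trials):
        state = np.random.SeedSequence(key[0],
                                       spawn_key=key[1:] + (t,)).generate_state(3)
        out.append(tuple(int(s) & 0x7FFFFFFF for s in state))
    return out


def run_trials(geometry_params: GeometryParams, config: SimulationConfig,
               n_trials: int, seed_root: int, *,
               times: tuple[float, ...] | None = None,
               bin_width: float = 25.0, profile_points: int = 100_000,
               r_max: float | None = None,
               cell: tuple[int, int] | None = None) -> TrialSet:
    """Run ``n_trials`` independent releases, each in a fresh geometry.

    Trial seeds derive deterministically from ``seed_root``; profiles at each
    snapshot time (default: the config's snapshot times) are averaged across
    trials with per-bin standard errors.
    """
    times = tuple(times if times is not None else
                  [t for t in config.snapshot_times if t <= config.duration])
    recordings: list[Recording] = []
    geometries: list[Geometry] = []
    per_trial: dict[float, list[ConcentrationProfile]] = {t: [] for t in times}
    for trial, (g_seed, s_seed, p_seed) in enumerate(
            _trial_seeds(seed_root, n_trials, cell)):
        try:
            geometry = generate_geometry(geometry_params, g_seed)
            rec = simulate(geometry, config, seed=s_seed)
        except Exception as exc:
            raise RuntimeError(f"trial {trial} failed: {exc}") from exc
        recordings.append(rec)
        geometries.append(geometry)
        for t in times:
            snap = rec.snapshot_at(t)
            per_trial[t].append(radial_profile(
                snap, geometry, bin_width=bin_width, r_max=r_max,
                n_test_points=profile_points, seed=p_seed))
        logger.info("trial %d/%d done (bound %d/%d)", trial + 1, n_trials,
                    rec.snapshots[-1].n_bound, config.n_molecules)
    profiles = {t: average_profiles(ps) for t, ps in per_trial.items()}
    return TrialSet(recordings=recordings, geometries=geometries,
                    profiles=profiles, per_trial_profiles=per_trial,
                    seed_root=seed_root)


def sweep_psi_alpha(spec: SweepSpec) -> SweepGrid:
    """Evaluate λ(free/bound) over the Ψ×α grid at each timepoint.

    Cells whose profile never decays to 1/e (or has an empty reference bin)
    are reported as NaN and masked, never zero-filled.  Cells are independent
    jobs: results do not depend on execution order.
    """
    np_, na, nt = (len(spec.psi_values), len(spec.alpha_values),
                   len(spec.timepoints))
    shape = (np_, na, nt)
    lam_f = np.full(shape, np.nan)
    lam_b = np.full(shape, np.nan)
    se_f = np.full(shape, np.nan)
    se_b = np.full(shape, np.nan)
    duration = max(spec.timepoints)
    for i, psi in enumerate(spec.psi_values):
        for j, alpha in enumerate(spec.alpha_values):
            config = spec.base_config.model_copy(update={
                "psi": psi, "duration": duration,
                "snapshot_times": tuple(spec.timepoints)})
            gparams = spec.base_geometry_params.model_copy(
                update={"alpha_target": alpha})
            cell = None if spec.paired_seeds else (i, j)
            trials = run_trials(gparams, config, spec.n_trials,
                                spec.seed_root, times=spec.timepoints,
                                bin_width=spec.bin_width,
                                profile_points=spec.profile_points,
                                cell=cell)
            for k, t in enumerate(spec.timepoints):
                for species, lam, se in (("free", lam_f, se_f),
                                         ("bound", lam_b, se_b)):
                    try:
                        lc = length_constant(trials.profiles[t], species)
                    except ValueError:
                        continue
                    lam[i, j, k] = lc.lam if lc.defined else np.nan
                    per = []
                    for p in trials.per_trial_profiles[t]:
                        try:
                            plc = length_constant(p, species)
                            if plc.defined:
                                per.append(plc.lam)
                        except ValueError:
                            pass
                    if len(per) > 1:
                        se[i, j, k] = float(np.std(per, ddof=1)
                                            / np.sqrt(len(per)))
            logger.info("sweep cell psi=%g alpha=%g done", psi, alpha)
    return SweepGrid(psi_values=np.asarray(spec.psi_values),
                     alpha_values=np.asarray(spec.alpha_values),
                     timepoints=np.asarray(spec.timepoints),
                     lambda_free=lam_f, lambda_bound=lam_b,
                     se_free=se_f, se_bound=se_b,
                     n_trials=spec.n_trials)
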