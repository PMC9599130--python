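"""Concentration profiles, free/bound ratios and length constants.

Particles are binned into concentric spherical shells centred on the release
site (the cleft centre), starting at the cleft boundary radius (60 nm by
default).  Counts are converted to concentrations via

    C [μM] = n / (N_A · V_ECS)

with V_ECS the extracellular volume of the shell, estimated by stratified
test-point sampling.  Bound glutamate sits on astroglial surfaces; its areal
density is re-expressed volumetrically with the same ECS shell volume, so
that free and bound species are directly comparable (and their ratio equals
the raw count ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dynamics import BOUND, FREE, ParticleEnsemble
from .geometry import NM_PER_UM, Geometry, classify_points

#: μM per (molecule / μm³); 1/(N_A · 1e-21)
COUNT_TO_UM = 1.0 / 602.214076


@dataclass
class ConcentrationProfile:
    """Radial free/bound concentration profile at one time point."""
    bin_edges: np.ndarray        # (nb+1,) μm from the cleft centre
    free_counts: np.ndarray      # (nb,) mean molecules per shell
    bound_counts: np.ndarray     # (nb,)
    ecs_shell_volume: np.ndarray  # (nb,) μm³
    time: float                  # ms
    n_trials: int = 1
    n_inside_boundary: float = 0.0   # molecules at r < bin_edges[0]
    n_beyond: float = 0.0            # molecules at r >= bin_edges[-1]
    free_se: np.ndarray | None = None    # per-bin SE of free_conc over trials
    bound_se: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def boundary_radius(self) -> float:
        return float(self.bin_edges[0])

    @property
    def distance_beyond_boundary(self) -> np.ndarray:
        """Bin centres measured outward from the cleft boundary, μm."""
        return self.bin_centers - self.boundary_radius

    def _conc(self, counts: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            c = counts * COUNT_TO_UM / self.ecs_shell_volume
        return np.where(self.ecs_shell_volume > 0, c, np.nan)

    @property
    def free_conc(self) -> np.ndarray:
        """μM per bin; NaN where the shell has no estimated ECS volume."""
        return self._conc(self.free_counts)

    @property
    def bound_conc(self) -> np.ndarray:
        return self._conc(self.bound_counts)

    def to_frame(self) -> pd.DataFrame:
        ratio = free_bound_ratio(self)
        return pd.DataFrame({
            "time_ms": self.time,
            "r_um": self.bin_centers,
            "r_beyond_boundary_um": self.distance_beyond_boundary,
            "free_uM": self.free_conc,
            "bound_uM": self.bound_conc,
            "ratio": ratio,
            "free_se_uM": self.free_se if self.free_se is not None else np.nan,
            "bound_se_uM": (self.bound_se if self.bound_se is not None
                            else np.nan),
            "ecs_shell_volume_um3": self.ecs_shell_volume,
            "n_trials": self.n_trials,
        })


@dataclass(frozen=True)
class LengthConstant:
    """Distance over which a profile decays by a factor of e."""
    lam: float                    # μm; NaN when undefined
    reference_value: float        # μM at the reference (first) bin
    time: float                   # ms
    species: Literal["free", "bound"]
    defined: bool = True


def shell_ecs_volumes(geometry: Geometry, bin_edges: np.ndarray,
                      n_test_points: int, seed: int) -> np.ndarray:
    """Extracellular volume of each spherical shell, by stratified sampling.

    Points are drawn uniformly inside each shell (equal counts per shell) and
    classified against the sphere population; the ECS fraction scales the
    analytic shell volume.  Shells are assumed to lie inside the arena.
    """
    rng = np.random.default_rng(seed)
    nb = len(bin_edges) - 1
    per_shell = max(1, int(n_test_points) // nb)
    volumes = np.empty(nb)
    center = geometry.cleft.center
    for b in range(nb):
        lo3, hi3 = bin_edges[b] ** 3, bin_edges[b + 1] ** 3
        r = np.cbrt(lo3 + (hi3 - lo3) * rng.random(per_shell))
        v = rng.normal(size=(per_shell, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = center + r[:, None] * v
        codes = classify_points(pts, geometry)
        frac_ecs = np.count_nonzero(codes == 0) / per_shell
        volumes[b] = frac_ecs * 4.0 / 3.0 * np.pi * (hi3 - lo3)
    return volumes


def radial_profile(snapshot: ParticleEnsemble, geometry: Geometry,
                   bin_width: float = 25.0, r_max: float | None = None,
                   n_test_points: int = 100_000,
                   seed: int = 0) -> ConcentrationProfile:
    """Bin a snapshot into spherical shells outward from the cleft boundary.

    ``bin_width`` is in nm.  Free molecules are binned by current position,
    bound molecules by their (frozen) binding site.  Molecules inside the
    cleft boundary radius or beyond ``r_max`` are tallied separately so that
    mass balance over all categories is exact.
    """
    cleft = geometry.cleft
    if r_max is None:
        r_max = geometry.arena_edge / 2
    width = bin_width / NM_PER_UM
    nb = int(np.floor((r_max - cleft.boundary_radius) / width))
    if nb < 1:
        raise ValueError("r_max leaves no room for a single bin")
    edges = cleft.boundary_radius + width * np.arange(nb + 1)

    r = np.linalg.norm(snapshot.positions - cleft.center, axis=1)
    free = snapshot.state == FREE
    bound = snapshot.state == BOUND
    free_counts = np.histogram(r[free], bins=edges)[0].astype(float)
    bound_counts = np.histogram(r[bound], bins=edges)[0].astype(float)
    inside = float(np.count_nonzero(r < edges[0]))
    beyond = float(np.count_nonzero(r >= edges[-1]))

    volumes = shell_ecs_volumes(geometry, edges, n_test_points, seed)
    return ConcentrationProfile(bin_edges=edges, free_counts=free_counts,
                                bound_counts=bound_counts,
                                ecs_shell_volume=volumes,
                                time=snapshot.time, n_trials=1,
                                n_inside_boundary=inside, n_beyond=beyond)


def average_profiles(profiles: Sequence[ConcentrationProfile]) \
        -> ConcentrationProfile:
    """Average per-trial profiles (equal bins required); per-bin SE across
    trials is attached to the result."""
    if not profiles:
        raise ValueError("no profiles to average")
    edges = profiles[0].bin_edges
    for p in profiles[1:]:
        if not np.allclose(p.bin_edges, edges):
            raise ValueError("profiles have mismatched bins")
    n = len(profiles)
    free_c = np.stack([p.free_conc for p in profiles])
    bound_c = np.stack([p.bound_conc for p in profiles])
    with np.errstate(invalid="ignore"):
        free_se = np.nanstd(free_c, axis=0, ddof=1) / np.sqrt(n) if n > 1 \
            else np.zeros(len(edges) - 1)
        bound_se = np.nanstd(bound_c, axis=0, ddof=1) / np.sqrt(n) if n > 1 \
            else np.zeros(len(edges) - 1)
    return ConcentrationProfile(
        bin_edges=edges,
        free_counts=np.mean([p.free_counts for p in profiles], axis=0),
        bound_counts=np.mean([p.bound_counts for p in profiles], axis=0),
        ecs_shell_volume=np.mean([p.ecs_shell_volume for p in profiles],
                                 axis=0),
        time=profiles[0].time,
        n_trials=sum(p.n_trials for p in profiles),
        n_inside_boundary=float(np.mean([p.n_inside_boundary
                                         for p in profiles])),
        n_beyond=float(np.mean([p.n_beyond for p in profiles])),
        free_se=free_se, bound_se=bound_se)


def free_bound_ratio(profile: ConcentrationProfile) -> np.ndarray:
    """Per-bin free/bound concentration ratio.

    Bins with zero bound concentration yield inf (or NaN when free is also
    zero or the bin is undefined); nothing is dropped silently.  Because both
    species share the shell ECS volume, this equals the raw count ratio.
    """
    free = profile.free_counts.astype(float)
    bound = profile.bound_counts.astype(float)
    out = np.full(profile.n_bins, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bound > 0, free / np.where(bound > 0, bound, 1.0),
                       np.where(free > 0, np.inf, np.nan))
    out = np.where(np.isfinite(profile.free_conc)
                   | np.isfinite(profile.bound_conc), out, np.nan)
    return out


def window_counts(snapshot: ParticleEnsemble, geometry: Geometry,
                  r_lo: float, r_hi: float) -> tuple[int, int]:
    """(free, bound) molecule counts with r_lo <= r < r_hi from the cleft
    centre."""
    r = np.linalg.norm(snapshot.positions - geometry.cleft.center, axis=1)
    sel = (r >= r_lo) & (r < r_hi)
    n_free = int(np.count_nonzero(sel & (snapshot.state == FREE)))
    n_bound = int(np.count_nonzero(sel & (snapshot.state == BOUND)))
    return n_free, n_bound


def window_ratio(snapshots: Sequence[ParticleEnsemble], geometry: Geometry,
                 r_lo: float, r_hi: float) -> float:
    """Free/bound ratio from counts pooled over trials in a radial window.

    Returns inf when bound is zero but free is not, NaN when both are zero.
    """
    nf = nb = 0
    for s in snapshots:
        f, b = window_counts(s, geometry, r_lo, r_hi)
        nf += f
        nb += b
    if nb == 0:
        return np.inf if nf > 0 else np.nan
    return nf / nb


def length_constant(profile: ConcentrationProfile,
                    species: Literal["free", "bound"]) -> LengthConstant:
    """λ: distance at which the profile first decays to 1/e of its value in
    the first bin beyond the cleft boundary.

    The crossing radius is found by linear interpolation between the bin
    centres bracketing C0/e and measured from the reference bin centre.
    When the profile never falls below C0/e inside the binned range, λ is
    flagged undefined (NaN).
    """
    conc = profile.free_conc if species == "free" else profile.bound_conc
    c0 = conc[0]
    if not np.isfinite(c0) or c0 <= 0:
        raise ValueError(
            f"reference bin (first bin beyond the cleft boundary, "
            f"r={profile.bin_centers[0]:.4f} μm) has no defined {species} "
            "concentration")
    target = c0 / np.e
    centers = profile.bin_centers
    r0 = centers[0]
    prev_r, prev_c = r0, c0
    for i in range(1, profile.n_bins):
        ci = conc[i]
        if not np.isfinite(ci):
            continue
        if ci <= target:
            # linear interpolation between the bracketing (defined) bins
            if ci == prev_c:
                r_cross = centers[i]
            else:
                frac = (prev_c - target) / (prev_c - ci)
                r_cross = prev_r + frac * (centers[i] - prev_r)
            return LengthConstant(lam=float(r_cross - r0),
                                  reference_value=float(c0),
                                  time=profile.time, species=species)
        prev_r, prev_c = centers[i], ci
    return LengthConstant(lam=float("nan"), reference_value=float(c0),
                          time=profile.time, species=species, defined=False)


def space_average_concentration(snapshot: ParticleEnsemble,
                                geometry: Geometry, r_max: float,
                                n_test_points: int = 50_000,
                                seed: int = 0) -> float:
    """Free-glutamate concentration (μM) averaged over the ECS within
    ``r_max`` μm of the release site.

    The ECS volume of the ball is estimated by uniform test points inside it.
    """
    if r_max > geometry.arena_edge / 2:
        raise ValueError("r_max exceeds half the arena edge")
    center = geometry.cleft.center
    r = np.linalg.norm(snapshot.positions - center, axis=1)
    n_free = int(np.count_nonzero((snapshot.state == FREE) & (r <= r_max)))

    rng = np.random.default_rng(seed)
    u = rng.random(int(n_test_points))
    rad = r_max * np.cbrt(u)
    v = rng.normal(size=(int(n_test_points), 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = center + rad[:, None] * v
    frac_ecs = np.count_nonzero(classify_points(pts, geometry) == 0) \
        / len(pts)
    v_ecs = frac_ecs * 4.0 / 3.0 * np.pi * r_max ** 3
    if v_ecs == 0 or n_free == 0:
        return 0.0
    return n_free * COUNT_TO_UM / v_ecs


def bound_onset_distance(profile: ConcentrationProfile) -> float:
    """Distance beyond the cleft boundary (nm) at which the bound profile
    first becomes nonzero; NaN if no bound molecules fall in the binned
    range."""
    nz = np.flatnonzero(profile.bound_counts > 0)
    if nz.size == 0:
        return float("nan")
    return float((profile.bin_edges[nz[0]] - profile.boundary_radius)
                 * NM_PER_UM)


def mass_balance(profile: ConcentrationProfile) -> float:
    """Total molecules accounted for by the profile (bins + inside the
    boundary + beyond the binned range); exact per snapshot."""
    return float(profile.free_counts.sum() + profile.bound_counts.sum()
                 + profile.n_inside_boundary + profile.n_beyond)
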