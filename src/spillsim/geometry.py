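"""Stochastic neuropil geometry: overlapping spheres around a synaptic cleft.

The tissue is modelled as randomly scattered, overlapping spheres (neuronal or
astroglial) filling a cubic arena, with a disk-shaped synaptic cleft at the
centre that no sphere surface may approach closer than the exclusion distance.
The extracellular space (ECS) is whatever remains outside all spheres; its
volume fraction α is calibrated during generation and validated by uniform
test-point sampling.

Unit conventions: arena edge in μm; sphere radii and cleft dimensions are
configured in nm (matching how they are usually reported) and converted to μm
internally.  All arrays and derived quantities are in μm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import _kernels

NM_PER_UM = 1000.0

KIND_NEURONAL = 0
KIND_ASTROGLIAL = 1
_KIND_NAMES = {KIND_NEURONAL: "neuronal", KIND_ASTROGLIAL: "astroglial"}


class GeometryError(RuntimeError):
    """Raised when geometry generation or calibration fails."""


class GeometryParams(BaseModel):
    """Parameters of the stochastic neuropil generator.

    Lengths: ``arena_edge`` in μm; ``radius_min``, ``radius_max``,
    ``cleft_diameter``, ``cleft_height``, ``cleft_exclusion`` in nm.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    arena_edge: float = Field(4.0, gt=0, description="cube edge, μm")
    radius_min: float = Field(50.0, gt=0, description="min sphere radius, nm")
    radius_max: float = Field(300.0, gt=0, description="max sphere radius, nm")
    alpha_target: float = Field(0.2, gt=0, lt=1,
                                description="target ECS volume fraction")
    astro_fraction_target: float = Field(
        0.10, ge=0, lt=1,
        description="target astroglial share of total tissue volume")
    cleft_diameter: float = Field(120.0, gt=0, description="nm")
    cleft_height: float = Field(20.0, gt=0, description="nm")
    cleft_exclusion: float = Field(
        10.0, ge=0, description="min sphere-surface distance to the cleft, nm")
    alpha_tolerance: float = Field(0.01, gt=0)
    astro_tolerance: float = Field(0.02, gt=0)
    n_test_points: float = Field(
        100_000, ge=1000,
        description="uniform test points for fraction validation; the "
                    "calibration loop uses twice this number")
    max_spheres: int = Field(200_000, gt=0)
    grid_cell_edge: float = Field(0.1, gt=0, description="spatial index, μm")
    grid_margin: float = Field(
        0.05, gt=0,
        description="index query margin, μm; single-cell lookups are "
                    "exhaustive for surfaces within this distance")
    reflect_cleft_faces: bool = Field(
        True, description="whether the two cleft membrane disks reflect")

    @model_validator(mode="after")
    def _check(self) -> "GeometryParams":
        if self.radius_min >= self.radius_max:
            raise ValueError("radius_min must be < radius_max")
        if self.astro_fraction_target + self.alpha_target >= 1:
            raise ValueError(
                "astro_fraction_target + alpha_target must be < 1 "
                "(astroglia is part of the cellular volume)")
        half = self.arena_edge / 2 * NM_PER_UM
        if self.cleft_diameter / 2 + self.cleft_exclusion >= half \
                or self.cleft_height / 2 + self.cleft_exclusion >= half:
            raise ValueError("cleft (plus exclusion zone) must fit in arena")
        return self

    # convenience accessors in μm
    @property
    def radius_min_um(self) -> float:
        return self.radius_min / NM_PER_UM

    @property
    def radius_max_um(self) -> float:
        return self.radius_max / NM_PER_UM

    @property
    def cleft_radius_um(self) -> float:
        return self.cleft_diameter / 2 / NM_PER_UM

    @property
    def cleft_half_height_um(self) -> float:
        return self.cleft_height / 2 / NM_PER_UM

    @property
    def cleft_exclusion_um(self) -> float:
        return self.cleft_exclusion / NM_PER_UM


@dataclass(frozen=True)
class Sphere:
    """One cell element."""
    center: np.ndarray  # (3,) μm
    radius: float       # μm
    kind: Literal["neuronal", "astroglial"]


@dataclass(frozen=True)
class Cleft:
    """Disk-shaped synaptic cleft: axis along z, flat faces reflecting,
    lateral rim open to the ECS."""
    center: np.ndarray      # (3,) μm
    radius: float           # μm
    half_height: float      # μm
    reflect_faces: bool = True

    @property
    def axis(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])

    @property
    def boundary_radius(self) -> float:
        """Radial distance of the cleft rim from the release centre."""
        return self.radius


@dataclass(frozen=True)
class UniformGrid:
    """CSR cell -> candidate-sphere index over the arena."""
    cell_start: np.ndarray
    entries: np.ndarray
    cell_edge: float
    n_cells: int
    margin: float


@dataclass(frozen=True)
class VolumeFractions:
    ecs: float
    astro: float
    neuronal: float
    n_points: int
    se: float  # binomial standard error of the ECS estimate


@dataclass(frozen=True)
class SurfaceQuery:
    distance: float          # signed distance to union surface (+ in ECS)
    nearest_kind: Literal["neuronal", "astroglial", "none"]
    nearest_sphere_id: int   # -1 if none within max_radius
    astro_distance: float    # distance to nearest astroglial surface (inf if none)


@dataclass
class Geometry:
    """A realised tissue: sphere population, spatial index, cleft, arena."""
    params: GeometryParams
    centers: np.ndarray          # (n, 3) μm
    radii: np.ndarray            # (n,) μm
    kinds: np.ndarray            # (n,) int8; 0 neuronal, 1 astroglial
    cleft: Cleft
    grid: UniformGrid = field(repr=False)
    realized_alpha: float = float("nan")
    realized_astro_fraction: float = float("nan")
    seed: int | None = None

    @property
    def n_spheres(self) -> int:
        return len(self.radii)

    @property
    def arena_edge(self) -> float:
        return self.params.arena_edge

    @property
    def spheres(self) -> list[Sphere]:
        return [Sphere(self.centers[i].copy(), float(self.radii[i]),
                       _KIND_NAMES[int(self.kinds[i])])
                for i in range(self.n_spheres)]

    def with_grid_margin(self, margin: float) -> "Geometry":
        """Return self, or a copy whose index supports the requested margin."""
        if margin <= self.grid.margin:
            return self
        grid = _build_grid(self.centers, self.radii, margin,
                           self.grid.cell_edge, self.arena_edge)
        return Geometry(self.params, self.centers, self.radii, self.kinds,
                        self.cleft, grid, self.realized_alpha,
                        self.realized_astro_fraction, self.seed)


def _build_grid(centers, radii, margin, cell_edge, arena_edge) -> UniformGrid:
    cell_start, entries, nc = _kernels.build_grid(
        np.ascontiguousarray(centers, dtype=np.float64),
        np.ascontiguousarray(radii, dtype=np.float64),
        margin, cell_edge, arena_edge)
    return UniformGrid(cell_start, entries, cell_edge, nc, margin)


def _derive_seeds(seed: int, n: int) -> list[int]:
    """n independent 31-bit seeds from one root seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def sphere_cleft_clearance(geometry: Geometry) -> np.ndarray:
    """Analytic distance from each sphere surface to the cleft cylinder."""
    p = geometry.params
    c = geometry.cleft.center
    rho = np.hypot(geometry.centers[:, 0] - c[0], geometry.centers[:, 1] - c[1])
    dr = np.maximum(0.0, rho - geometry.cleft.radius)
    dz = np.maximum(0.0, np.abs(geometry.centers[:, 2] - c[2])
                    - geometry.cleft.half_height)
    del p
    return np.hypot(dr, dz) - geometry.radii


def default_cleft(params: GeometryParams) -> Cleft:
    half = params.arena_edge / 2
    return Cleft(center=np.array([half, half, half]),
                 radius=params.cleft_radius_um,
                 half_height=params.cleft_half_height_um,
                 reflect_faces=params.reflect_cleft_faces)


def generate_geometry(params: GeometryParams, seed: int) -> Geometry:
    """Generate a calibrated overlapping-sphere neuropil.

    Spheres (uniform radii, uniform centres over the arena, cleft-exclusion
    candidates redrawn) are added one at a time until the test-point ECS
    fraction reaches ``alpha_target``.  Astroglial labels are then assigned by
    thresholding per-sphere uniform marks so that the astroglial share of the
    calibration test points equals ``astro_fraction_target``; a point covered
    by both kinds counts as astroglial.  The realised fractions are measured
    on an independent test-point set and must fall within the configured
    tolerances, otherwise :class:`GeometryError` is raised.
    """
    s_place, s_calib, s_valid = _derive_seeds(seed, 3)
    n_calib = int(2 * params.n_test_points)
    rng = np.random.default_rng(s_calib)
    pts = rng.random((n_calib, 3)) * params.arena_edge

    cleft = default_cleft(params)
    cx, cy, cz = cleft.center
    centers, radii, labels, n_sph, n_uncov, status = _kernels.place_spheres(
        pts, params.arena_edge,
        params.radius_min_um, params.radius_max_um, params.alpha_target,
        cx, cy, cz, cleft.radius, cleft.half_height,
        params.cleft_exclusion_um, s_place, params.max_spheres)
    if status != _kernels.PLACE_OK:
        reason = ("sphere budget exhausted"
                  if status == _kernels.PLACE_MAX_SPHERES
                  else "candidate rejection budget exhausted")
        raise GeometryError(
            f"ECS calibration did not converge ({reason}): placed {n_sph} "
            f"spheres, uncovered fraction {n_uncov / n_calib:.4f}, "
            f"target {params.alpha_target}; the parameter combination is "
            "likely infeasible")
    centers = np.ascontiguousarray(centers)
    radii = np.ascontiguousarray(radii)
    labels = np.ascontiguousarray(labels)

    grid = _build_grid(centers, radii, params.grid_margin,
                       params.grid_cell_edge, params.arena_edge)

    # astroglia labelling: threshold per-sphere marks at the order statistic
    # matching the target astro share of total volume
    kinds = np.zeros(n_sph, dtype=np.int8)
    k = int(round(params.astro_fraction_target * n_calib))
    if k > 0 and n_sph > 0:
        min_u = _kernels.min_cover_label(
            pts, centers, radii, labels,
            grid.cell_start, grid.entries, grid.cell_edge, grid.n_cells)
        finite = np.sort(min_u[np.isfinite(min_u)])
        if k >= finite.size:
            threshold = 1.1  # all covered volume astroglial
        else:
            threshold = 0.5 * (finite[k - 1] + finite[k])
        kinds = (labels < threshold).astype(np.int8)

    geometry = Geometry(params=params, centers=centers, radii=radii,
                        kinds=kinds, cleft=cleft, grid=grid, seed=seed)
    fractions = estimate_fractions(geometry, int(params.n_test_points), s_valid)
    geometry.realized_alpha = fractions.ecs
    geometry.realized_astro_fraction = fractions.astro

    if abs(fractions.ecs - params.alpha_target) > params.alpha_tolerance:
        raise GeometryError(
            f"realised ECS fraction {fractions.ecs:.4f} misses target "
            f"{params.alpha_target} by more than {params.alpha_tolerance}")
    if abs(fractions.astro - params.astro_fraction_target) \
            > params.astro_tolerance:
        raise GeometryError(
            f"realised astroglial fraction {fractions.astro:.4f} misses "
            f"target {params.astro_fraction_target} by more than "
            f"{params.astro_tolerance}")
    return geometry


def empty_geometry(arena_edge: float = 4.0, *, cleft: Cleft | None = None,
                   params: GeometryParams | None = None) -> Geometry:
    """A sphere-free arena (α = 1), e.g. for free-diffusion checks."""
    if params is None:
        params = GeometryParams(arena_edge=arena_edge, alpha_target=0.999,
                                astro_fraction_target=0.0,
                                grid_margin=min(0.5, arena_edge / 8))
    if cleft is None:
        cleft = default_cleft(params)
    centers = np.empty((0, 3))
    radii = np.empty(0)
    grid = _build_grid(centers, radii, params.grid_margin,
                       params.grid_cell_edge, params.arena_edge)
    return Geometry(params=params, centers=centers, radii=radii,
                    kinds=np.empty(0, dtype=np.int8), cleft=cleft, grid=grid,
                    realized_alpha=1.0, realized_astro_fraction=0.0)


def geometry_from_spheres(centers, radii, kinds,
                          params: GeometryParams | None = None,
                          cleft: Cleft | None = None) -> Geometry:
    """Build a Geometry from explicit sphere arrays (used for tests and IO)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    radii = np.asarray(radii, dtype=np.float64)
    kinds = np.asarray(kinds, dtype=np.int8)
    if params is None:
        params = GeometryParams()
    if cleft is None:
        cleft = default_cleft(params)
    grid = _build_grid(centers, radii, params.grid_margin,
                       params.grid_cell_edge, params.arena_edge)
    return Geometry(params=params, centers=centers, radii=radii, kinds=kinds,
                    cleft=cleft, grid=grid)


def estimate_fractions(geometry: Geometry, n_points: int,
                       seed: int) -> VolumeFractions:
    """Classify uniform test points as ECS / astroglial / neuronal.

    A point inside at least one astroglial sphere counts as astroglial even
    if it is also inside neuronal spheres (the overlap rule favouring the
    binding surface).
    """
    rng = np.random.default_rng(seed)
    pts = rng.random((int(n_points), 3)) * geometry.arena_edge
    g = geometry.grid
    codes = _kernels.classify_points(
        pts, geometry.centers, geometry.radii, geometry.kinds,
        g.cell_start, g.entries, g.cell_edge, g.n_cells)
    n = len(pts)
    ecs = float(np.count_nonzero(codes == 0)) / n
    astro = float(np.count_nonzero(codes == 1)) / n
    neuronal = float(np.count_nonzero(codes == 2)) / n
    return VolumeFractions(ecs=ecs, astro=astro, neuronal=neuronal,
                           n_points=n, se=float(np.sqrt(ecs * (1 - ecs) / n)))


def classify_points(points: np.ndarray, geometry: Geometry) -> np.ndarray:
    """Vectorised point classification (0 ECS, 1 astroglial, 2 neuronal)."""
    pts = np.ascontiguousarray(np.atleast_2d(points), dtype=np.float64)
    g = geometry.grid
    return _kernels.classify_points(
        pts, geometry.centers, geometry.radii, geometry.kinds,
        g.cell_start, g.entries, g.cell_edge, g.n_cells)


def query_surface(point, geometry: Geometry, max_radius: float,
                  use_index: bool = True) -> SurfaceQuery:
    """Signed distance from ``point`` to the union cell surface.

    Positive distance means the point is in the ECS; a point inside any
    sphere has non-positive distance.  Spheres whose surface is farther than
    ``max_radius`` are ignored; with none in range the kind is ``"none"``.
    ``use_index=False`` performs a brute-force scan over all spheres (same
    result; used to validate the spatial index).
    """
    p = np.asarray(point, dtype=np.float64).reshape(1, 3)
    if use_index:
        g = geometry.grid
        dist, idx, adist, _ = _kernels.surface_query_batch(
            p, geometry.centers, geometry.radii, geometry.kinds,
            g.cell_start, g.entries, g.cell_edge, g.n_cells, max_radius)
        d, i, ad = float(dist[0]), int(idx[0]), float(adist[0])
    else:
        if geometry.n_spheres == 0:
            d, i, ad = np.inf, -1, np.inf
        else:
            sd = np.linalg.norm(geometry.centers - p, axis=1) - geometry.radii
            sd = np.where(sd <= max_radius, sd, np.inf)
            i = int(np.argmin(sd))
            d = float(sd[i])
            if not np.isfinite(d):
                d, i = np.inf, -1
            astro = sd[geometry.kinds == KIND_ASTROGLIAL]
            ad = float(astro.min()) if astro.size else np.inf
            if not np.isfinite(ad):
                ad = np.inf
    kind = "none" if i < 0 else _KIND_NAMES[int(geometry.kinds[i])]
    return SurfaceQuery(distance=d, nearest_kind=kind, nearest_sphere_id=i,
                        astro_distance=ad)


def astro_distances(points: np.ndarray, geometry: Geometry,
                    max_radius: float) -> np.ndarray:
    """Distance from each point to the nearest astroglial surface
    (inf where none lies within max_radius)."""
    pts = np.ascontiguousarray(np.atleast_2d(points), dtype=np.float64)
    g = geometry.grid
    _, _, adist, _ = _kernels.surface_query_batch(
        pts, geometry.centers, geometry.radii, geometry.kinds,
        g.cell_start, g.entries, g.cell_edge, g.n_cells, max_radius)
    return adist
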