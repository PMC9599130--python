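"""Release, random walk, reflections and the binding law."""

import numpy as np
import pytest
from scipy import stats

from spillsim import (Cleft, GeometryParams, SimulationConfig, empty_geometry,
                      generate_geometry, geometry_from_spheres, init_release,
                      propose_step, resolve_motion, simulate, update_binding)
from spillsim.geometry import default_cleft


@pytest.fixture(scope="module")
def short_recording(small_geometry):
    """300 molecules for 0.3 ms in the shared 2 μm tissue."""
    cfg = SimulationConfig(n_molecules=300, duration=0.3,
                           snapshot_times=(0.1, 0.2, 0.3), seed=9)
    return simulate(small_geometry, cfg), cfg


class TestConfigValidation:
    def test_step_cannot_exceed_shell(self):
        with pytest.raises(ValueError, match="binding_shell"):
            SimulationConfig(step_length=10.0, binding_shell=5.0)

    def test_duration_capped(self):
        with pytest.raises(ValueError):
            SimulationConfig(duration=20.0)

    def test_dt_follows_step_relation(self):
        cfg = SimulationConfig(step_length=5.0, D_free=0.5)
        assert cfg.dt == pytest.approx(0.005 ** 2 / (6 * 0.5))


class TestInitRelease:
    def test_all_inside_cleft_cylinder(self):
        cfg = SimulationConfig(n_molecules=1000)
        cleft = default_cleft(GeometryParams())
        ens = init_release(cfg, cleft, seed=4)
        rel = ens.positions - cleft.center
        rho = np.hypot(rel[:, 0], rel[:, 1])
        assert ens.n_molecules == 1000 and ens.n_free == 1000
        assert np.all(rho <= cleft.radius)
        assert np.all(np.abs(rel[:, 2]) <= cleft.half_height)
        assert np.all(ens.shell_clock == 0)
        assert np.all(np.isnan(ens.bound_time))

    def test_uniform_cylinder_moments(self):
        cfg = SimulationConfig(n_molecules=100_000)
        cleft = default_cleft(GeometryParams())
        ens = init_release(cfg, cleft, seed=8)
        rel = ens.positions - cleft.center
        # mean at the centre; uniform-disk E[rho^2] = R^2/2; uniform z var h²/3
        assert np.allclose(rel.mean(axis=0), 0, atol=4 * 0.06 / np.sqrt(1e5))
        rho2 = (rel[:, 0] ** 2 + rel[:, 1] ** 2).mean()
        assert rho2 == pytest.approx(cleft.radius ** 2 / 2, rel=0.02)
        assert rel[:, 2].var() == pytest.approx(cleft.half_height ** 2 / 3,
                                                rel=0.03)


class TestProposeStep:
    def test_fixed_step_length_exact(self, rng):
        pos = np.zeros((5000, 3))
        d = propose_step(pos, 0.005, rng)
        assert np.allclose(np.linalg.norm(d, axis=1), 0.005, atol=1e-15)

    def test_isotropy_moments(self, rng):
        d = propose_step(np.zeros((100_000, 3)), 1.0, rng)
        assert np.allclose(d.mean(axis=0), 0, atol=4 / np.sqrt(1e5))
        # uniform direction on the sphere: per-component variance 1/3
        assert np.allclose(d.var(axis=0), 1 / 3, rtol=0.02)


class TestResolveMotion:
    def test_no_crossing_is_identity(self, small_geometry, rng):
        from spillsim.geometry import classify_points
        pts = rng.random((5000, 3)) * 2.0
        pts = pts[classify_points(pts, small_geometry) == 0][:200]
        d = propose_step(pts, 1e-6, rng)  # tiny steps: almost never reflect
        res = resolve_motion(pts, pts + d, small_geometry)
        moved = ~res.rejected
        far = np.linalg.norm(res.positions - (pts + d), axis=1)
        assert np.mean(far[moved] < 1e-12) > 0.99

    def test_head_on_wall_is_specular_image(self):
        geom = empty_geometry(4.0)
        old = np.array([[3.9, 2.0, 2.0]])
        prop = np.array([[4.15, 2.0, 2.0]])  # 0.25 step into the +x wall
        res = resolve_motion(old, prop, geom)
        assert not res.rejected[0]
        # |final - wall| = step - distance-to-wall = 0.25 - 0.1
        assert res.positions[0, 0] == pytest.approx(4.0 - 0.15, abs=1e-8)
        assert res.positions[0, 1:] == pytest.approx([2.0, 2.0])

    def test_no_penetration_after_many_random_steps(self, small_geometry,
                                                    rng):
        from spillsim.geometry import classify_points
        g = small_geometry
        pts = rng.random((40_000, 3)) * g.arena_edge
        pts = pts[classify_points(pts, g) == 0][:10_000]
        d = propose_step(pts, 0.005, rng)
        res = resolve_motion(pts, pts + d, g)
        ok = res.positions[~res.rejected]
        # brute-force containment check against every sphere
        inside = np.zeros(len(ok), dtype=bool)
        for i in range(g.n_spheres):
            d2 = ((ok - g.centers[i]) ** 2).sum(axis=1)
            inside |= d2 < (g.radii[i] - 1e-9) ** 2
        assert not inside.any()
        assert res.rejected.mean() < 0.01


class TestUpdateBinding:
    def _clamped_geometry(self):
        # one astroglial sphere; particles parked 2 nm off its surface
        geom = geometry_from_spheres([[2.0, 2.0, 2.0]], [0.3], [1])
        pos = np.tile([2.0, 2.0, 2.302], (4000, 1))
        return geom, pos

    def test_infinite_psi_never_binds(self):
        from spillsim.dynamics import ParticleEnsemble
        geom, pos = self._clamped_geometry()
        ens = ParticleEnsemble(pos.copy(), np.zeros(len(pos), np.int8),
                               np.zeros(len(pos)), np.full(len(pos), np.nan))
        rng = np.random.default_rng(0)
        for _ in range(200):
            update_binding(ens, geom, dt=1e-3, psi=1e12, rng=rng)
        assert ens.n_bound == 0
        assert np.all(ens.shell_clock > 0)  # clocks accumulate in the shell

    @pytest.mark.parametrize("psi", [0.3, 1.0, 3.0])
    def test_clamped_binding_times_are_exponential(self, psi):
        """Particles held in the shell bind after Exp(mean=Ψ) times."""
        from spillsim.dynamics import ParticleEnsemble
        geom, pos = self._clamped_geometry()
        n = len(pos)
        ens = ParticleEnsemble(pos.copy(), np.zeros(n, np.int8),
                               np.zeros(n), np.full(n, np.nan))
        rng = np.random.default_rng(12)
        dt = psi / 400
        step = 0
        while ens.n_free > 0 and step < 6000:
            step += 1
            ens.time = step * dt
            update_binding(ens, geom, dt=dt, psi=psi, rng=rng)
        t = ens.bound_time[np.isfinite(ens.bound_time)]
        assert len(t) > 0.99 * n
        assert t.mean() == pytest.approx(psi, rel=0.1)
        res = stats.kstest(t, "expon", args=(0, psi))
        assert res.pvalue > 0.01

    def test_clock_resets_outside_shell(self):
        from spillsim.dynamics import ParticleEnsemble
        geom, _ = self._clamped_geometry()
        pos = np.array([[2.0, 2.0, 2.302], [2.0, 2.0, 2.4]])  # in / out
        ens = ParticleEnsemble(pos, np.zeros(2, np.int8), np.array([0.0, 5.0]),
                               np.full(2, np.nan))
        update_binding(ens, geom, dt=1e-3, psi=1e9,
                       rng=np.random.default_rng(0))
        assert ens.shell_clock[0] == pytest.approx(1e-3)
        assert ens.shell_clock[1] == 0.0

    def test_no_astroglia_no_binding(self, rng):
        params = GeometryParams(arena_edge=2.0, astro_fraction_target=0.0,
                                n_test_points=20_000)
        geom = generate_geometry(params, 21)
        cfg = SimulationConfig(n_molecules=200, duration=0.1, psi=0.01,
                               snapshot_times=(0.1,), seed=2)
        rec = simulate(geom, cfg)
        assert rec.snapshots[-1].n_bound == 0
        assert np.all(rec.bound_counts == 0)


class TestSimulate:
    def test_zero_duration_single_snapshot(self, small_geometry):
        cfg = SimulationConfig(n_molecules=50, duration=0.0, seed=1)
        rec = simulate(small_geometry, cfg)
        assert len(rec.snapshots) == 1
        assert rec.snapshots[0].time == 0.0
        assert rec.snapshots[0].n_bound == 0

    def test_conservation_and_monotone_bound(self, short_recording):
        rec, cfg = short_recording
        for s in rec.snapshots:
            assert s.n_free + s.n_bound == cfg.n_molecules
        assert np.all(np.diff(rec.bound_counts) >= 0)

    def test_free_particles_never_inside_spheres(self, short_recording,
                                                 small_geometry):
        rec, _ = short_recording
        g = small_geometry
        for s in rec.snapshots:
            free = s.positions[s.state == 0]
            for i in range(g.n_spheres):
                d2 = ((free - g.centers[i]) ** 2).sum(axis=1)
                assert not np.any(d2 < (g.radii[i] - 1e-9) ** 2)

    def test_bound_particles_frozen(self, small_geometry):
        cfg = SimulationConfig(n_molecules=400, duration=0.3, psi=0.05,
                               snapshot_times=(0.15, 0.3), seed=17)
        rec = simulate(small_geometry, cfg)
        s1, s2 = rec.snapshots[-2], rec.snapshots[-1]
        both = (s1.state == 1) & (s2.state == 1)
        assert both.any()
        assert np.array_equal(s1.positions[both], s2.positions[both])
        assert np.array_equal(s1.bound_time[both], s2.bound_time[both])

    def test_determinism(self, small_geometry):
        cfg = SimulationConfig(n_molecules=100, duration=0.1,
                               snapshot_times=(0.05, 0.1), seed=33)
        a = simulate(small_geometry, cfg)
        b = simulate(small_geometry, cfg)
        for sa, sb in zip(a.snapshots, b.snapshots):
            assert np.array_equal(sa.positions, sb.positions)
            assert np.array_equal(sa.state, sb.state)
        assert np.array_equal(a.bound_counts, b.bound_counts)

    def _free_space_geometry(self, edge=20.0):
        params = GeometryParams(arena_edge=edge, alpha_target=0.999,
                                astro_fraction_target=0.0,
                                reflect_cleft_faces=False,
                                grid_margin=1.0)
        return empty_geometry(edge, params=params)

    @pytest.mark.parametrize("gaussian", [False, True])
    def test_free_diffusion_msd_matches_6dt(self, gaussian):
        """Obstacle-free walk reproduces MSD = 6·D·t at 0.1/0.5/1 ms."""
        from spillsim.dynamics import msd
        geom = self._free_space_geometry()
        n = 1000 if gaussian else 3000  # gaussian mode has no fast path
        cfg = SimulationConfig(n_molecules=n, duration=1.0, D_free=0.5,
                               step_length=10.0, binding_shell=10.0,
                               snapshot_times=(0.1, 0.5, 1.0), seed=3,
                               gaussian_steps=gaussian)
        rec = simulate(geom, cfg)
        times, values = msd(rec)
        ref = rec.snapshots[0]
        for t, v, snap in zip(times[1:], values[1:], rec.snapshots[1:]):
            d2 = ((snap.positions - ref.positions) ** 2).sum(axis=1)
            se = d2.std(ddof=1) / np.sqrt(len(d2))
            assert abs(v - 6 * 0.5 * t) < 3 * se

    def test_hindered_diffusion_slower_than_free(self, default_geometry):
        """Crowded tissue (α=0.2, no uptake) reduces the effective D."""
        from spillsim.dynamics import msd
        cfg = SimulationConfig(n_molecules=400, duration=0.5, psi=1e9,
                               snapshot_times=(0.5,), seed=6)
        rec = simulate(default_geometry, cfg)
        times, values = msd(rec)
        d_eff = values[-1] / (6 * times[-1])
        assert d_eff < 0.7 * cfg.D_free
        assert d_eff > 0.05 * cfg.D_free  # still diffusing, not trapped
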