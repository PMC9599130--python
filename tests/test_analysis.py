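"""Concentration profiles, ratios, length constants and space averages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spillsim import (GeometryParams, empty_geometry, free_bound_ratio,
                      length_constant, radial_profile,
                      space_average_concentration)
from spillsim.analysis import (COUNT_TO_UM, ConcentrationProfile,
                               bound_onset_distance, mass_balance,
                               shell_ecs_volumes)
from spillsim.dynamics import ParticleEnsemble


def make_ensemble(positions, state=None, time=1.0):
    positions = np.atleast_2d(positions).astype(float)
    n = len(positions)
    state = np.zeros(n, np.int8) if state is None else np.asarray(state,
                                                                  np.int8)
    return ParticleEnsemble(positions, state, np.zeros(n),
                            np.where(state == 1, 0.5, np.nan), time=time)


def make_profile(free_conc, bound_conc, bin_width=0.025, r0=0.06, time=3.0):
    """Profile with unit shell volumes so conc == counts · COUNT_TO_UM."""
    nb = len(free_conc)
    edges = r0 + bin_width * np.arange(nb + 1)
    return ConcentrationProfile(
        bin_edges=edges,
        free_counts=np.asarray(free_conc) / COUNT_TO_UM,
        bound_counts=np.asarray(bound_conc) / COUNT_TO_UM,
        ecs_shell_volume=np.ones(nb), time=time)


class TestRadialProfile:
    def test_uniform_cloud_gives_flat_profile(self, rng):
        """Uniform molecules in an empty arena: C = n/(N_A·V) everywhere."""
        geom = empty_geometry(4.0)
        n = 50_000
        ens = make_ensemble(rng.random((n, 3)) * 4.0)
        prof = radial_profile(ens, geom, bin_width=100.0,
                              n_test_points=100_000, seed=2)
        expected = (n / 4.0 ** 3) * COUNT_TO_UM
        sel = prof.ecs_shell_volume > 0.05  # skip tiniest shells
        rel = prof.free_conc[sel] / expected
        assert np.nanmedian(rel) == pytest.approx(1.0, abs=0.05)
        assert np.all(np.abs(rel - 1) < 0.25)

    def test_mass_balance_exact(self, small_geometry, rng):
        from spillsim import SimulationConfig, simulate
        cfg = SimulationConfig(n_molecules=250, duration=0.2, psi=0.1,
                               snapshot_times=(0.2,), seed=5)
        rec = simulate(small_geometry, cfg)
        prof = radial_profile(rec.snapshots[-1], small_geometry,
                              n_test_points=10_000, seed=1)
        assert mass_balance(prof) == cfg.n_molecules

    def test_zero_bound_gives_zero_bound_profile(self, rng):
        geom = empty_geometry(4.0)
        ens = make_ensemble(rng.random((100, 3)) * 4.0)
        prof = radial_profile(ens, geom, n_test_points=10_000, seed=0)
        assert np.all(prof.bound_counts == 0)
        assert np.all(prof.bound_conc[prof.ecs_shell_volume > 0] == 0)

    def test_shell_volumes_sum_to_ecs_ball_volume(self, default_geometry,
                                                  rng):
        """Estimator consistency: Σ shell ECS volumes over all shells equals
        an independent uniform-sampling estimate of the ECS volume of the
        same ball (within sampling error)."""
        from spillsim.geometry import classify_points
        g = default_geometry
        edges = np.linspace(0.06, 2.0, 40)
        vols = shell_ecs_volumes(g, edges, 200_000, seed=9)
        # independent plain Monte Carlo over the same spherical annulus
        n = 200_000
        r = np.cbrt(edges[0] ** 3
                    + (edges[-1] ** 3 - edges[0] ** 3) * rng.random(n))
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = g.cleft.center + r[:, None] * v
        frac = np.count_nonzero(classify_points(pts, g) == 0) / n
        ball = 4 / 3 * np.pi * (edges[-1] ** 3 - edges[0] ** 3)
        assert vols.sum() == pytest.approx(frac * ball, rel=0.01)


class TestFreeBoundRatio:
    def test_ratio_equals_count_ratio(self, rng):
        """Shell volumes cancel: ratio must equal the raw count ratio."""
        nb = 30
        free = rng.integers(0, 50, nb).astype(float)
        bound = rng.integers(0, 50, nb).astype(float)
        prof = ConcentrationProfile(
            bin_edges=0.06 + 0.025 * np.arange(nb + 1),
            free_counts=free, bound_counts=bound,
            ecs_shell_volume=0.001 + rng.random(nb), time=1.0)
        ratio = free_bound_ratio(prof)
        pos = bound > 0
        assert np.allclose(ratio[pos], free[pos] / bound[pos])
        assert np.all(np.isinf(ratio[(bound == 0) & (free > 0)]))
        assert np.all(np.isnan(ratio[(bound == 0) & (free == 0)]))

    def test_all_zero_bound_means_all_undefined(self):
        prof = make_profile([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        ratio = free_bound_ratio(prof)
        assert not np.any(np.isfinite(ratio))


class TestLengthConstant:
    def test_exact_exponential_recovers_lambda(self):
        r0, lam = 0.06, 0.3
        edges = r0 + 0.025 * np.arange(79)
        centers = 0.5 * (edges[:-1] + edges[1:])
        conc = 5.0 * np.exp(-(centers - centers[0]) / lam)
        prof = make_profile(conc, conc)
        for species in ("free", "bound"):
            lc = length_constant(prof, species)
            assert lc.defined
            assert lc.lam == pytest.approx(lam, rel=0.02)
            assert lc.reference_value == pytest.approx(conc[0], rel=1e-9)

    def test_flat_profile_undefined(self):
        prof = make_profile(np.full(40, 2.0), np.full(40, 2.0))
        lc = length_constant(prof, "free")
        assert not lc.defined and np.isnan(lc.lam)

    def test_empty_reference_bin_raises_with_bin_named(self):
        prof = make_profile([0.0, 1.0, 0.5], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="reference bin"):
            length_constant(prof, "free")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(lam=st.floats(0.1, 0.5), c0=st.floats(0.5, 500.0))
    def test_recovery_within_2pc_for_fine_bins(self, lam, c0):
        width = lam / 12
        edges = 0.06 + width * np.arange(120)
        centers = 0.5 * (edges[:-1] + edges[1:])
        conc = c0 * np.exp(-(centers - centers[0]) / lam)
        prof = ConcentrationProfile(
            bin_edges=edges, free_counts=conc / COUNT_TO_UM,
            bound_counts=np.zeros_like(conc),
            ecs_shell_volume=np.ones_like(conc), time=0.3)
        lc = length_constant(prof, "free")
        assert lc.defined
        assert abs(lc.lam - lam) / lam < 0.02


class TestSpaceAverage:
    def test_closed_form_in_empty_arena(self, rng):
        geom = empty_geometry(4.0)
        center = geom.cleft.center
        # 1000 free molecules all inside r_max = 0.25
        v = rng.normal(size=(1000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pos = center + v * (0.25 * np.cbrt(rng.random((1000, 1))))
        c = space_average_concentration(make_ensemble(pos), geom, 0.25,
                                        n_test_points=100_000, seed=3)
        expected = 1000 * COUNT_TO_UM / (4 / 3 * np.pi * 0.25 ** 3)
        assert c == pytest.approx(expected, rel=0.02)

    def test_no_free_molecules_gives_zero(self):
        geom = empty_geometry(4.0)
        ens = make_ensemble(geom.cleft.center + np.array([[0.0, 0.0, 1.5]]))
        assert space_average_concentration(ens, geom, 0.3, seed=1) == 0.0

    def test_rmax_beyond_arena_rejected(self):
        geom = empty_geometry(4.0)
        ens = make_ensemble([[2.0, 2.0, 2.0]])
        with pytest.raises(ValueError):
            space_average_concentration(ens, geom, 2.5)


class TestBoundOnset:
    def test_onset_is_first_nonzero_bin_edge(self):
        prof = make_profile([1.0] * 10,
                            [0.0, 0.0, 0.0, 0.0, 2.0, 1.0, 0, 0, 0, 0],
                            bin_width=0.005)
        assert bound_onset_distance(prof) == pytest.approx(20.0)

    def test_no_bound_gives_nan(self):
        prof = make_profile([1.0] * 5, [0.0] * 5)
        assert np.isnan(bound_onset_distance(prof))
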