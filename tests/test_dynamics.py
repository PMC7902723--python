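import numpy as np
import pytest

from glvfluct.dynamics import (
    PHDriver,
    RunawayGrowthError,
    SimulationConfig,
    glv_rhs,
    ph_at,
    simulate,
    _make_rhs,
)
from glvfluct.fluctuation_experiments import bray_curtis

from conftest import make_community, make_flat_response


class TestPHDriver:
    def test_sinusoid_quarter_period(self):
        drv = PHDriver.sinusoid(6.3, 0.5, 1.0)
        assert drv.ph_at(0.25) == pytest.approx(6.8)

    def test_zero_amplitude(self):
        drv = PHDriver.sinusoid(6.3, 0.0, 1.0)
        for t in (0.0, 0.1, 1.7, 42.0):
            assert drv.ph_at(t) == 6.3

    def test_sinusoid_t0(self):
        assert PHDriver.sinusoid(6.3, 0.5, 0.2).ph_at(0.0) == pytest.approx(6.3)

    def test_clamping(self):
        drv = PHDriver.sinusoid(7.0, 2.0, 1.0, clamp_lo=5.1, clamp_hi=7.5)
        assert drv.ph_at(0.25) == 7.5
        assert drv.ph_at(0.75) == 5.1

    def test_constant(self):
        drv = PHDriver.constant(6.0)
        assert drv.ph_at(123.0) == 6.0

    def test_telegraph_levels(self):
        drv = PHDriver.telegraph(6.3, 0.5, 1.0, seed=1)
        vals = {round(drv.ph_at(t), 9) for t in np.linspace(0, 50, 500)}
        assert vals == {5.8, 6.8}

    def test_telegraph_reproducible(self):
        a = PHDriver.telegraph(6.3, 0.5, 1.0, seed=3)
        b = PHDriver.telegraph(6.3, 0.5, 1.0, seed=3)
        ts = np.linspace(0, 100, 1000)
        assert [a.ph_at(t) for t in ts] == [b.ph_at(t) for t in ts]

    def test_telegraph_holding_time(self):
        # holding times exponential with mean 1/f
        drv = PHDriver.telegraph(6.3, 0.5, 0.5, seed=7)
        drv._extend_telegraph(5000.0)
        holds = np.diff(drv._switches[:2000])
        assert np.mean(holds) == pytest.approx(2.0, rel=0.1)

    def test_validation(self):
        with pytest.raises(ValueError):
            PHDriver.sinusoid(6.3, -0.1, 1.0)
        with pytest.raises(ValueError):
            PHDriver.sinusoid(6.3, 0.5, 0.0)
        with pytest.raises(ValueError):
            PHDriver(kind="square")
        with pytest.raises(ValueError):
            PHDriver.constant(6.3).ph_at(-1.0)
        with pytest.raises(ValueError):
            ph_at(PHDriver.constant(6.3), float("nan"))


class TestSimulationConfig:
    def test_generation_time(self):
        cfg = SimulationConfig(delta=0.1)
        assert cfg.generation_time == pytest.approx(np.log(2) / 0.1)
        assert cfg.total_time == pytest.approx(100 * np.log(2) / 0.1)

    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(delta=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_ext=1e-3, s0=1e-4)
        with pytest.raises(ValueError):
            SimulationConfig(ph_min=7.5, ph_max=5.1)


class TestGlvRhs:
    def test_logistic_equilibrium(self):
        comm = make_community([(0.5, 0.1)], [[-1.0]])
        cfg = SimulationConfig(delta=0.1)
        # at S = K(1 - delta/r) the derivative vanishes
        s_star = 0.1 * (1 - 0.1 / 0.5)
        d = glv_rhs(np.array([s_star]), 6.3, comm, cfg)
        assert d[0] == pytest.approx(0.0, abs=1e-15)

    def test_zero_state(self):
        comm = make_community([(0.5, 0.1), (0.4, 0.2)],
                              [[-1.0, -0.5], [-0.5, -1.0]])
        cfg = SimulationConfig()
        assert np.all(glv_rhs(np.zeros(2), 6.3, comm, cfg) == 0.0)

    def test_complete_overlap_sum_identity(self):
        # with c12 = c21 = -1 and equal r, K the total density follows a
        # single logistic equation
        comm = make_community([(0.5, 0.1), (0.5, 0.1)],
                              [[-1.0, -1.0], [-1.0, -1.0]])
        cfg = SimulationConfig(delta=0.05)
        single = make_community([(0.5, 0.1)], [[-1.0]])
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = rng.uniform(0, 0.08, 2)
            d_pair = glv_rhs(s, 6.3, comm, cfg).sum()
            d_single = glv_rhs(np.array([s.sum()]), 6.3, single, cfg)[0]
            assert d_pair == pytest.approx(d_single, rel=1e-12, abs=1e-15)

    def test_nonfinite_state(self):
        comm = make_community([(0.5, 0.1)], [[-1.0]])
        with pytest.raises(ValueError):
            glv_rhs(np.array([np.nan]), 6.3, comm, SimulationConfig())

    def test_fast_path_matches_reference(self, panel, mod_spec):
        # the compiled kernel must agree with the plain-numpy rhs
        from glvfluct.synthetic_data import sample_assemblage

        comm = sample_assemblage(panel, 8, mod_spec,
                                 rng=np.random.default_rng(11))
        cfg = SimulationConfig()
        drv = PHDriver.sinusoid(6.3, 0.5, 0.2)
        fast = _make_rhs(comm, drv, cfg)
        rng = np.random.default_rng(1)
        for t in rng.uniform(0, 100, 25):
            s = rng.uniform(0, 0.5, 8)
            assert np.allclose(fast(t, s), glv_rhs(s, drv.ph_at(t), comm, cfg),
                               rtol=1e-12, atol=1e-15)


class TestSimulate:
    def test_single_strain_steady_state(self):
        comm = make_community([(0.5, 0.1)], [[-1.0]])
        cfg = SimulationConfig(delta=0.05)
        traj = simulate(comm, PHDriver.constant(6.3), cfg)
        assert traj.final[0] == pytest.approx(0.1 * (1 - 0.05 / 0.5), abs=1e-6)

    def test_washout(self):
        comm = make_community([(0.05, 0.1)], [[-1.0]])  # r < delta everywhere
        cfg = SimulationConfig(delta=0.1)
        traj = simulate(comm, PHDriver.constant(6.3), cfg)
        assert traj.final[0] == 0.0

    def test_all_zero_initial(self):
        comm = make_community([(0.5, 0.1), (0.4, 0.2)],
                              [[-1.0, -0.5], [-0.5, -1.0]], s0=0.0)
        traj = simulate(comm, PHDriver.constant(6.3), SimulationConfig())
        assert np.all(traj.densities == 0.0)

    def test_positivity_and_extinction_permanence(self, panel, mod_spec):
        from glvfluct.synthetic_data import sample_assemblage

        comm = sample_assemblage(panel, 10, mod_spec,
                                 rng=np.random.default_rng(2))
        traj = simulate(comm, PHDriver.constant(6.3), SimulationConfig())
        assert np.all(traj.densities >= 0.0)
        for i in range(comm.n):
            dens = traj.densities[i]
            zeros = np.flatnonzero(dens == 0.0)
            if zeros.size and zeros[0] > 0:
                assert np.all(dens[zeros[0]:] == 0.0)

    def test_zero_amplitude_equals_constant(self, panel, mod_spec):
        from glvfluct.synthetic_data import sample_assemblage

        comm = sample_assemblage(panel, 5, mod_spec,
                                 rng=np.random.default_rng(3))
        cfg = SimulationConfig()
        t_sin = simulate(comm, PHDriver.sinusoid(6.3, 0.0, 0.2), cfg)
        t_const = simulate(comm, PHDriver.constant(6.3), cfg)
        assert np.array_equal(t_sin.densities, t_const.densities)

    def test_tolerance_convergence(self, panel, mod_spec):
        from glvfluct.synthetic_data import sample_assemblage

        comm = sample_assemblage(panel, 5, mod_spec,
                                 rng=np.random.default_rng(4))
        cfg = SimulationConfig()
        drv = PHDriver.constant(6.3)
        a = simulate(comm, drv, cfg).final
        b = simulate(comm, drv, cfg.with_(rel_tol=cfg.rel_tol / 2,
                                          abs_tol=cfg.abs_tol / 2)).final
        if a.sum() > 0 and b.sum() > 0:
            assert bray_curtis(a / a.sum(), b / b.sum()) < 1e-6

    def test_random_steady_states(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            r = rng.uniform(0.2, 1.0)
            K = rng.uniform(0.05, 1.0)
            delta = rng.uniform(0.02, r * 0.8)
            comm = make_community([(r, K)], [[-1.0]])
            cfg = SimulationConfig(delta=delta)
            traj = simulate(comm, PHDriver.constant(6.3), cfg)
            assert traj.final[0] == pytest.approx(K * (1 - delta / r), abs=1e-6)

    def test_runaway_raises(self):
        comm = make_community([(0.5, 0.1), (0.5, 0.1)],
                              [[-1.0, 1.5], [1.5, -1.0]], s0=0.05)
        with pytest.raises(RunawayGrowthError):
            simulate(comm, PHDriver.constant(6.3), SimulationConfig(delta=0.05))

    def test_telegraph_driver_runs(self, panel, mod_spec):
        from glvfluct.synthetic_data import sample_assemblage

        comm = sample_assemblage(panel, 5, mod_spec,
                                 rng=np.random.default_rng(6))
        drv = PHDriver.telegraph(6.3, 0.5, 0.2, seed=1)
        traj = simulate(comm, drv, SimulationConfig())
        assert np.all(traj.densities >= 0)
        assert np.all(np.isfinite(traj.densities))

    def test_bad_horizon(self):
        comm = make_community([(0.5, 0.1)], [[-1.0]])
        with pytest.raises(ValueError):
            simulate(comm, PHDriver.constant(6.3), SimulationConfig(), T=0.0)

    def test_trajectory_frame(self):
        comm = make_community([(0.5, 0.1)], [[-1.0]])
        traj = simulate(comm, PHDriver.constant(6.3), SimulationConfig())
        df = traj.to_frame()
        assert set(df.columns) == {"time", "strain_id", "density", "ph"}
        assert len(df) == len(traj.times)

    def test_dense_window_sampling(self):
        comm = make_community([(0.5, 0.1)], [[-1.0]])
        cfg = SimulationConfig()
        traj = simulate(comm, PHDriver.constant(6.3), cfg,
                        dense_window=5.0, dense_points=65)
        w = traj.window(cfg.total_time - 5.0)
        assert len(w.times) >= 65
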