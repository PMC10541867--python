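"""Integration engine: stepper accuracy, presets, modes, ensembles."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from planktonpatch.ecosystem import BioParams, steady_state_resource
from planktonpatch.engine import (
    SimulationConfig,
    default_ensemble_config,
    log_grid,
    run_ensemble,
    run_simulation,
    soiree_config,
    step,
)
from planktonpatch.geometry import ForcingLaws, PatchShape
from planktonpatch.moments import SurroundingState, TracerMoments


@pytest.fixture(scope="module")
def soiree_traj():
    return run_simulation(soiree_config())


def _frozen_geometry_config(**overrides):
    """Config with gamma0 = kappa0 = 0: the patch never deforms or dilutes."""
    cfg = default_ensemble_config(gamma0=0.0, kappa0=0.0, tau=20.0, dt=0.01)
    return replace(cfg, **overrides) if overrides else cfg


class TestStepper:
    def test_single_step_matches_reference_integrator(self):
        cfg = soiree_config(dt=0.05)
        shape, mom, clamped = step((cfg.shape0, cfg.initial_moments), cfg, 0.0)
        assert not clamped
        # RK4 over one 0.05 d step should sit within ~dt^5 of the true flow
        from planktonpatch.engine import _rhs

        sol = solve_ivp(
            lambda t, y: _rhs(tuple(y), cfg),
            (0.0, 0.05),
            [25.0, 25.0, 1.0, 0.0249, 0.0, 0.0, 0.0],
            rtol=1e-12,
            atol=1e-14,
        )
        got = [shape.W**2, shape.L**2, mom.mean_r, mom.mean_b, mom.var_r, mom.var_b, mom.cov_rb]
        assert np.allclose(got, sol.y[:, -1], rtol=1e-9, atol=1e-12)

    def test_rk4_error_scales_as_dt4(self):
        """Richardson check against a dt/10 reference run."""
        errs = {}
        ref = run_simulation(soiree_config(tau=2.0, dt=0.005))
        for dt in (0.1, 0.05):
            tr = run_simulation(soiree_config(tau=2.0, dt=dt))
            errs[dt] = abs(tr.mean_b[-1] - ref.mean_b[-1])
        # halving dt should cut the error ~16x; require at least 8x
        assert errs[0.05] < errs[0.1] / 8.0

    def test_full_recycling_fixed_point_at_steady_state(self):
        """Patch identical to a steady surrounding never moves (alpha=1)."""
        bio = BioParams(alpha=1.0)
        rstar = steady_state_resource(bio)
        cfg = replace(
            default_ensemble_config(tau=5.0),
            bio=bio,
            surrounding=SurroundingState(mean_r=rstar, mean_b=0.0249),
            initial_moments=TracerMoments(mean_r=rstar, mean_b=0.0249),
        )
        tr = run_simulation(cfg)
        assert np.allclose(tr.mean_r, rstar, rtol=1e-12)
        assert np.allclose(tr.mean_b, 0.0249, rtol=1e-12)
        assert np.all(tr.var_r == 0.0) and np.all(tr.cov_rb == 0.0)

    def test_frozen_geometry_reduces_to_mean_field_odes(self):
        """gamma0 = kappa0 = 0: independent adaptive solve of the 2-ODE system."""
        cfg = _frozen_geometry_config()
        tr = run_simulation(cfg)
        assert np.allclose(tr.A, tr.A[0], rtol=1e-12)  # geometry frozen
        bio = cfg.bio

        def rhs(t, y):
            r, b = y
            u = bio.nu * r * b / (r + bio.k)
            return [-u + bio.alpha * bio.m * b, u - bio.m * b]

        sol = solve_ivp(rhs, (0, cfg.tau), [1.0, 0.0249], rtol=1e-11, atol=1e-13)
        assert tr.mean_r[-1] == pytest.approx(sol.y[0, -1], rel=1e-8)
        assert tr.mean_b[-1] == pytest.approx(sol.y[1, -1], rel=1e-8)
        # alpha=0: total tracer decays monotonically at the export rate
        total = tr.mean_r + tr.mean_b
        assert np.all(np.diff(total) < 0)

    def test_determinism_bit_identical(self):
        a = run_simulation(soiree_config(tau=3.0))
        b = run_simulation(soiree_config(tau=3.0))
        assert np.array_equal(a.mean_b, b.mean_b)
        assert np.array_equal(a.cov_rb, b.cov_rb)


class TestModes:
    def test_no_dilution_makes_modes_identical(self):
        """Without area growth no heterogeneity is ever produced."""
        het = run_simulation(_frozen_geometry_config(mode="heterogeneous"))
        wm = run_simulation(_frozen_geometry_config(mode="well_mixed"))
        assert np.allclose(het.mean_b, wm.mean_b, rtol=1e-8)
        assert np.all(het.var_r == 0.0)

    def test_well_mixed_pins_second_moments_to_zero(self):
        cfg = default_ensemble_config(tau=5.0, mode="well_mixed")
        tr = run_simulation(cfg)
        assert np.all(tr.var_r == 0.0) and np.all(tr.var_b == 0.0) and np.all(tr.cov_rb == 0.0)

    def test_inflated_mixing_converges_to_well_mixed(self):
        """Raising the internal-mixing rate 1e4x collapses the moment run onto
        the well-mixed means."""
        base = default_ensemble_config(gamma0=0.3, kappa0=0.3, tau=10.0)
        wm = run_simulation(replace(base, mode="well_mixed"))
        het = run_simulation(base)
        fast = run_simulation(replace(base, mixing_boost=1e4))
        gap_het = np.max(np.abs(het.mean_b - wm.mean_b))
        gap_fast = np.max(np.abs(fast.mean_b - wm.mean_b))
        assert gap_fast < 0.02 * gap_het
        assert gap_fast < 5e-4  # umol m^-3, against a bloom amplitude of ~0.4


class TestTrajectoryInvariants:
    def test_time_grid_regular_and_complete(self, soiree_traj):
        t = soiree_traj.time
        assert t[0] == 0.0 and t[-1] == pytest.approx(42.0)
        assert np.allclose(np.diff(t), 0.01)

    def test_area_monotone_nondecreasing(self, soiree_traj):
        assert np.all(np.diff(soiree_traj.A) >= 0)
        assert soiree_traj.A[-1] > soiree_traj.A[0]

    def test_moments_stay_admissible(self, soiree_traj):
        tr = soiree_traj
        assert np.all(tr.var_r >= 0) and np.all(tr.var_b >= 0)
        assert np.all(tr.cov_rb**2 <= tr.var_r * tr.var_b * (1 + 1e-9) + 1e-15)

    def test_dataframe_columns(self, soiree_traj):
        df = soiree_traj.to_dataframe()
        assert list(df.columns) == [
            "time_day", "W_km", "L_km", "S_km", "A_km2", "gamma_per_day",
            "kappa_km2_per_day", "dAdt_km2_per_day", "mean_r", "mean_b",
            "var_r", "var_b", "cov_rb",
        ]
        assert len(df) == 4201


class TestSoireePreset:
    def test_preset_values(self):
        cfg = soiree_config()
        assert (cfg.shape0.W, cfg.shape0.L) == (5.0, 5.0)
        assert (cfg.forcing.gamma0, cfg.forcing.kappa0, cfg.forcing.S0) == (0.12, 0.1, 10.0)
        assert (cfg.bio.nu, cfg.bio.m, cfg.bio.k, cfg.bio.alpha) == (1.05, 0.05, 2.0, 0.0)
        assert cfg.bio.fe_to_c == 1e-5
        assert (cfg.tau, cfg.dt, cfg.thickness, cfg.mode) == (42.0, 0.01, 10.0, "heterogeneous")
        cfg.initial_moments.validate()

    def test_surrounding_iron_is_the_biological_steady_state(self):
        cfg = soiree_config()
        assert steady_state_resource(cfg.bio) == pytest.approx(cfg.surrounding.mean_r, rel=1e-12)

    def test_fertilization_perturbation_magnitude(self):
        cfg = soiree_config()
        assert cfg.initial_moments.mean_r - cfg.surrounding.mean_r == pytest.approx(0.9)
        assert cfg.initial_moments.mean_b == cfg.surrounding.mean_b

    def test_bloom_peaks_midway_and_covariance_goes_positive(self, soiree_traj):
        tr = soiree_traj
        peak = tr.time[int(np.argmax(tr.mean_b))]
        assert 5.0 < peak < 25.0
        assert tr.cov_rb.max() > 0.0


class TestConfigValidation:
    def test_bad_windows_rejected(self):
        cfg = soiree_config()
        with pytest.raises(ValueError):
            replace(cfg, tau=-1.0)
        with pytest.raises(ValueError):
            replace(cfg, dt=100.0)
        with pytest.raises(ValueError):
            replace(cfg, thickness=0.0)
        with pytest.raises(ValueError):
            replace(cfg, mode="sideways")


class TestEnsemble:
    @pytest.fixture(scope="class")
    @staticmethod
    def tiny_grid():
        base = default_ensemble_config(tau=10.0, dt=0.02)
        return run_ensemble(log_grid(3), log_grid(3), base)

    def test_shapes_and_modes(self, tiny_grid):
        assert set(tiny_grid.lba) == {"well_mixed", "heterogeneous"}
        assert tiny_grid.lba["well_mixed"].shape == (3, 3)
        assert not tiny_grid.failures

    def test_dilution_increases_with_forcing(self, tiny_grid):
        d = tiny_grid.dilution["heterogeneous"]
        assert d[0, 0] == d.min() and d[-1, -1] == d.max()
        assert np.all(d >= 1.0)

    def test_dilution_independent_of_mode(self, tiny_grid):
        assert np.allclose(tiny_grid.dilution["heterogeneous"], tiny_grid.dilution["well_mixed"], rtol=1e-12)

    def test_long_format_dataframe(self, tiny_grid):
        df = tiny_grid.to_dataframe()
        assert len(df) == 18
        assert set(df.columns) == {"gamma0", "kappa0", "mode", "LBA_MgC", "dilution_factor"}

    def test_log_grid_spans_the_observed_range(self):
        g = log_grid(12)
        assert g[0] == pytest.approx(0.01) and g[-1] == pytest.approx(0.6)
        assert np.allclose(np.diff(np.log(g)), np.diff(np.log(g))[0])

    def test_dt_refinement_leaves_lba_unchanged(self):
        """Halving dt moves the LBA by far less than 0.1%."""
        from planktonpatch.metrics import lagrangian_biomass_anomaly

        base = default_ensemble_config(gamma0=0.3, kappa0=0.3, tau=15.0)
        lbas = []
        for dt in (0.02, 0.01):
            cfg = replace(base, dt=dt)
            tr = run_simulation(cfg)
            lbas.append(lagrangian_biomass_anomaly(tr, cfg.surrounding.mean_b, cfg.conversion))
        assert abs(lbas[1] - lbas[0]) / abs(lbas[1]) < 1e-3
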