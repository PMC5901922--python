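"""Derivative assembly, dilution bookkeeping, conservation and the
single-run / grid drivers."""

import numpy as np
import pandas as pd
import pytest

from mitoswell import (ModelParameters, Trajectory, apply_dilution,
                       apply_dilution_vector, derivatives, experiment_grid,
                       params_from_mapping, run_grid, run_simulation)
from mitoswell.simulator import TRAJECTORY_COLUMNS


def zero_transport_params(dpsi0=0.0) -> ModelParameters:
    return params_from_mapping({
        "p_ca_uniport": 0.0, "p_kh_exchange": 0.0, "p_hk_exchange": 0.0,
        "p_h_ptp": 0.0, "p_ca_ptp": 0.0, "p_k_ptp": 0.0, "p_anion_ptp": 0.0,
        "p_activator_ptp": 0.0, "a_in0_uM": 0.0, "dpsi0_mV": dpsi0,
        "t_end_s": 30.0,
    })


def equilibrium_params() -> ModelParameters:
    # equal activities on both sides, depolarized, pores closed, no activator
    return params_from_mapping({
        "dpsi0_mV": 0.0, "a_in0_uM": 0.0,
        "ca_in0_uM": 1.0, "ca_out0_uM": 1.0, "ca_background_uM": 0.0,
        "k_in0_uM": 1.0, "k_out0_uM": 1.0,
        "ph_in0": 7.0, "ph_out0": 7.0, "ah_out0_uM": 0.0,
        "t_end_s": 30.0,
    })


class TestDerivatives:
    def test_zero_rates_without_transport_or_respiration(self):
        p = zero_transport_params()
        from mitoswell.simulator import SwellingSimulator
        sim = SwellingSimulator(p)
        y = sim.initial_state()
        dy = derivatives(y, p)
        assert np.allclose(dy, 0.0, atol=1e-12)

    def test_global_equilibrium_is_a_fixed_point(self):
        p = equilibrium_params()
        from mitoswell.simulator import SwellingSimulator
        sim = SwellingSimulator(p)
        dy = derivatives(sim.initial_state(), p)
        # residual micro-rates stem from activity-coefficient rounding of
        # the initial pH adjustment; they are far below any transport scale
        assert np.allclose(dy, 0.0, atol=1e-5)

    def test_uniporter_term_matches_flux_module(self):
        """At t = 0 with pores shut, the Ca rate is the uniporter flux."""
        from mitoswell import ghk_flux
        from mitoswell.simulator import SwellingSimulator
        p = params_from_mapping({"ah_out0_uM": 0.0})
        sim = SwellingSimulator(p)
        y = sim.initial_state(ca_out_uM=1.0, k_out_uM=0.0)
        y[2] = 0.0  # no matrix K
        dy = derivatives(y, p)
        spec = p.ion_specs()["ca"]
        # activity corrections at these dilute strengths are within ~1%
        want = ghk_flux(spec, y[0], y[1], 1.0, p.constants,
                        p_eff=sim.p_ca_uni).value
        assert dy[1] == pytest.approx(want, rel=2e-2)


class TestDilution:
    def test_identity(self):
        y = np.arange(8.0)
        assert np.allclose(apply_dilution_vector(y, 2.0, 2.0), y)

    def test_ratio_and_amount_conservation(self):
        y = np.arange(1.0, 9.0)
        out = apply_dilution_vector(y, 1.0, 1.5)
        # matrix components scaled by 2/3, amounts conserved
        for idx in (1, 2, 3, 4, 5):
            assert out[idx] == pytest.approx(y[idx] * 2 / 3)
            assert out[idx] * 1.5 == pytest.approx(y[idx] * 1.0)
        # potential and cytosolic pools untouched
        assert out[0] == y[0] and out[6] == y[6] and out[7] == y[7]

    def test_mapping_variant(self):
        a = apply_dilution({"ca": 3.0}, 2.0, 3.0)
        assert a["ca"] == pytest.approx(2.0)

    def test_invalid_volumes(self):
        with pytest.raises(ValueError):
            apply_dilution_vector(np.zeros(8), 0.0, 1.0)


class TestRunSimulation:
    def test_zero_transport_trajectory_is_constant(self):
        p = zero_transport_params(dpsi0=0.0)
        traj = run_simulation(p)
        d = traj.data
        for col in ("dpsi_mV", "ca_in_uM", "k_in_uM", "pH_in", "a_in_uM"):
            assert d[col].std() == pytest.approx(0.0, abs=1e-9), col
        assert (d.p_ptp == 0).all()
        assert (d.v_rel == 0).all()

    def test_equilibrium_start_stays_fixed(self):
        traj = run_simulation(equilibrium_params())
        d = traj.data
        assert d.ca_in_uM.iloc[-1] == pytest.approx(1.0, abs=1e-5)
        assert d.k_in_uM.iloc[-1] == pytest.approx(1.0, abs=1e-5)
        assert d.pH_in.iloc[-1] == pytest.approx(7.0, abs=1e-5)
        assert abs(d.dpsi_mV.iloc[-1]) < 1e-3

    def test_mass_conservation_of_potassium_and_calcium(self, params):
        traj = run_simulation(params, t_end_s=120.0, ca_out_uM=100.0,
                              k_out_uM=0.1)
        d = traj.data
        from mitoswell.simulator import SwellingSimulator
        sim = SwellingSimulator(params)
        v_m = (1.0 + d.strain) ** 3 * sim.v_m0
        ca_total = d.ca_in_uM * v_m + d.ca_out_uM * sim.v_cyt
        k_total = d.k_in_uM * v_m + d.k_out_uM * sim.v_cyt
        assert ca_total.max() - ca_total.min() < 1e-6 * ca_total.iloc[0]
        assert k_total.max() - k_total.min() < 1e-5 * k_total.iloc[0]

    def test_trajectory_schema_and_monotonic_time(self, params):
        traj = run_simulation(params, t_end_s=10.0)
        assert list(traj.data.columns)[:len(TRAJECTORY_COLUMNS)] \
            == TRAJECTORY_COLUMNS
        assert np.all(np.diff(traj.t_s) > 0)

    def test_tolerance_robustness_of_high_calcium_outcome(self):
        """Tightening integrator tolerances does not change the reported
        opening behavior of a pore-opening run."""
        base = params_from_mapping({"ca_out0_uM": 300.0})
        tight = params_from_mapping({"ca_out0_uM": 300.0, "rtol": 5e-9,
                                     "atol": 5e-13})
        t1 = run_simulation(base)
        t2 = run_simulation(tight)
        assert t1.data.p_ptp.max() == pytest.approx(t2.data.p_ptp.max(),
                                                    rel=1e-2)
        assert t1.irreversible == t2.irreversible
        assert t1.data.v_rel.max() == pytest.approx(t2.data.v_rel.max(),
                                                    rel=1e-2)

    def test_determinism(self, params):
        a = run_simulation(params, t_end_s=20.0)
        b = run_simulation(params, t_end_s=20.0)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestRunGrid:
    def test_single_run_grid_matches_run_simulation(self, params):
        grid = experiment_grid(params, k_values_uM=(0.1,),
                               ca_values_uM=(50.0,))
        res = run_grid(params, grid=grid, t_end_s=60.0)
        assert len(res) == 1 and res[0].error is None
        direct = run_simulation(params, t_end_s=60.0, ca_out_uM=50.0,
                                k_out_uM=0.1)
        pd.testing.assert_frame_equal(res[0].trajectory.data, direct.data)

    def test_order_invariance(self, params):
        g1 = experiment_grid(params, k_values_uM=(0.1,),
                             ca_values_uM=(25.0, 75.0))
        g2 = experiment_grid(params, k_values_uM=(0.1,),
                             ca_values_uM=(75.0, 25.0))
        r1 = {r.descriptor.run_id: r.trajectory.data
              for r in run_grid(params, grid=g1, t_end_s=30.0)}
        r2 = {r.descriptor.run_id: r.trajectory.data
              for r in run_grid(params, grid=g2, t_end_s=30.0)}
        assert set(r1) == set(r2)
        for rid in r1:
            pd.testing.assert_frame_equal(r1[rid], r2[rid])

    def test_default_grid_runs_and_writes(self, params, tmp_path):
        res = run_grid(params, t_end_s=20.0, out_dir=tmp_path)
        assert len(res) == 20
        assert all(r.error is None for r in res)
        for r in res:
            assert (tmp_path / r.descriptor.output_path).exists()


class TestTrajectoryContainer:
    def test_csv_round_trip(self, params, tmp_path):
        traj = run_simulation(params, t_end_s=5.0)
        path = tmp_path / "t.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        pd.testing.assert_frame_equal(
            back.data, traj.data, check_exact=False, rtol=1e-12)

    def test_nonmonotonic_time_rejected(self):
        df = pd.DataFrame({"t_s": [0.0, 1.0, 1.0], "irreversible": False})
        with pytest.raises(ValueError):
            Trajectory(data=df)
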