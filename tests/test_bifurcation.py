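"""Continuation and bifurcation-detection tests.

The generic engine is validated on normal forms with known bifurcation
locations (fold at the origin, Hopf at the origin, cycle fold of the
subcritical Hopf normal form), then on the neural mass model itself:
equilibrium residuals, branch/grid consistency and stability of branch
points under simulation.
"""

import numpy as np
import pytest

from coolmass import bifurcation as bf
from coolmass.model_core import ModelParameters, TemperatureSpec, drift
from coolmass.simulator import SimulationConfig, simulate_deterministic


def fold_field(x, mu):
    """1-D saddle-node normal form x' = mu - x^2 (fold at mu = 0)."""
    return np.array([mu - x[0] ** 2])


def hopf_field(x, mu):
    """Planar supercritical Hopf normal form (Hopf at mu = 0)."""
    r2 = x[0] ** 2 + x[1] ** 2
    return np.array([mu * x[0] - x[1] - x[0] * r2,
                     x[0] + mu * x[1] - x[1] * r2])


def subcritical_field(x, mu):
    """Subcritical Hopf with quintic saturation: stable and unstable
    cycles coalesce at a fold of cycles at mu = -1/4."""
    r2 = x[0] ** 2 + x[1] ** 2
    amp = mu + r2 - r2 ** 2
    return np.array([amp * x[0] - x[1], x[0] + amp * x[1]])


class TestEquilibriumContinuation:
    def test_fold_normal_form(self):
        branch = bf.continue_equilibria(fold_field, np.array([1.0]), 1.0,
                                        (-0.5, 1.0), direction=-1.0,
                                        ds=0.05)
        folds = bf.detect_folds(branch)
        assert len(folds) == 1
        assert abs(folds[0].mu) < 1e-6
        assert abs(folds[0].info["eigenvalue"]) < 1e-6

    def test_monotone_branch_has_no_bifurcations(self):
        lin = lambda x, mu: np.array([mu - x[0]])
        branch = bf.continue_equilibria(lin, np.array([0.0]), 0.0,
                                        (0.0, 2.0), ds=0.1)
        assert bf.detect_folds(branch) == []
        assert bf.detect_hopf(branch) == []

    def test_hopf_normal_form(self):
        branch = bf.continue_equilibria(hopf_field, np.zeros(2), -0.5,
                                        (-0.5, 0.5), ds=0.05)
        hopfs = bf.detect_hopf(branch)
        assert len(hopfs) == 1
        assert abs(hopfs[0].mu) < 1e-6
        assert hopfs[0].info["omega"] == pytest.approx(1.0, rel=1e-4)

    def test_eigenvalues_vary_continuously(self):
        branch = bf.continue_equilibria(hopf_field, np.zeros(2), -0.5,
                                        (-0.5, 0.5), ds=0.02, ds_max=0.02)
        re = np.sort(branch.eigvals.real, axis=1)
        assert np.max(np.abs(np.diff(re, axis=0))) < 0.1


class TestCycleContinuation:
    def test_supercritical_amplitude_growth(self):
        """Near onset the cycle radius grows as sqrt(mu)."""
        branch = bf.continue_equilibria(hopf_field, np.zeros(2), -0.2,
                                        (-0.2, 0.6), ds=0.05)
        hopf = bf.detect_hopf(branch)[0]
        flow = bf.generic_flow(hopf_field, rtol=1e-9, atol=1e-11)
        cyc = bf.continue_limit_cycles(hopf_field, flow, hopf,
                                       direction=+1,
                                       mu_limits=(-0.3, 0.5),
                                       delta0=0.05, ds_max=0.1,
                                       max_points=12,
                                       settle_periods=60, perturb=20.0)
        # amplitude (max - min of x) should equal 2*sqrt(mu)
        for mu, amp in zip(cyc.mus, cyc.amplitudes):
            assert amp == pytest.approx(2.0 * np.sqrt(mu), rel=0.05)
        assert all(np.isclose(T, 2 * np.pi, rtol=1e-3)
                   for T in cyc.periods)

    def test_cycle_fold_location(self):
        """The stable/unstable cycle pair of the subcritical normal form
        annihilates at mu = -1/4."""
        hopf = bf.BifurcationPoint("hopf", 0.0, np.zeros(2),
                                   {"omega": 1.0})
        flow = bf.generic_flow(subcritical_field, rtol=1e-9, atol=1e-11)
        cyc = bf.continue_limit_cycles(subcritical_field, flow, hopf,
                                       direction=+1, continue_direction=-1,
                                       mu_limits=(-0.4, 0.3),
                                       delta0=0.05, ds=0.1, ds_max=0.2,
                                       max_points=60,
                                       settle_periods=60, perturb=20.0)
        assert cyc.lpc, "no limit point of cycles detected"
        assert cyc.lpc[0].mu == pytest.approx(-0.25, abs=2e-3)

    def test_sweep_brackets_the_cycle_fold(self):
        """Inherited-state parameter sweep agrees with the shooting fold."""
        flow = bf.generic_flow(subcritical_field, rtol=1e-9, atol=1e-11)
        # start on the stable cycle at mu = 0.05 (radius^2 ~ 1.05)
        x0 = np.array([1.02, 0.0])
        last_on, first_off = bf.bracket_lpc_by_sweep(
            subcritical_field, flow, x0, 2 * np.pi, 0.05, -0.40,
            step=0.01, settle_periods=40)
        assert first_off is not None
        assert last_on >= -0.25 - 1e-9
        assert first_off == pytest.approx(-0.25, abs=0.011)


class TestModelEquilibria:
    def test_residual_and_restart(self, params):
        temp = TemperatureSpec(T=15, T0=31, variant="SYN_INT", q_syn=1.8,
                               q_int=1.0)
        eq = bf.find_equilibrium(params, temp)
        assert np.max(np.abs(drift(eq, params.input_mean, params,
                                   temp))) < 1e-9
        # restarting from a converged point returns it unchanged
        again = bf.find_equilibrium(params, temp, guess=eq)
        assert np.allclose(again, eq, atol=1e-12)

    def test_branch_matches_pointwise_newton(self, params):
        """Continuation states agree with independent per-point solves."""
        temp = TemperatureSpec(T=15, T0=31, variant="SYN_INT", q_syn=1.8,
                               q_int=1.0)
        f = bf.make_model_field(params, temp)
        x0 = bf.find_equilibrium(params, temp)
        branch = bf.continue_equilibria(f, x0, 1.0, (1.0, 1.15), ds=0.02)
        for i in range(0, len(branch), 5):
            mu = branch.mus[i]
            direct = bf.newton_solve(lambda x: f(x, mu), branch.states[i])
            assert np.max(np.abs(direct - branch.states[i])) < 1e-6

    def test_stable_branch_points_confirmed_by_simulation(self, params):
        temp = TemperatureSpec(T=15, T0=31, variant="SYN_INT", q_syn=1.8,
                               q_int=1.0)
        f = bf.make_model_field(params, temp)
        x0 = bf.find_equilibrium(params, temp)
        branch = bf.continue_equilibria(f, x0, 1.0, (1.0, 1.1), ds=0.02)
        stable_idx = np.flatnonzero(branch.stable)[:2]
        for i in stable_idx:
            temp_i = temp.replace(q_int=float(branch.mus[i]))
            ts = simulate_deterministic(
                params, temp_i,
                SimulationConfig(duration=0.5, burn_in=0.0),
                initial_state=branch.states[i])
            eeg_eq = (branch.states[i][1] - branch.states[i][2]
                      - branch.states[i][3])
            assert np.max(np.abs(ts.values - eeg_eq)) < 1e-4


class TestScanClassification:
    def test_classifier_on_constructed_scan(self):
        """Landmarks recovered from a hand-built scan: baseline runs at
        low grid values, a mixed (bistable) window, then all-active."""
        q = np.round(np.arange(1.0, 2.001, 0.1), 2)
        n_seeds = 4
        effmag = np.full((q.size, n_seeds, 3), 0.2)
        effmag[-1] = 3.0                       # discharge anchor
        effmag[q >= 1.9] = 3.0
        mid = (q >= 1.4) & (q <= 1.6)
        effmag[mid, :2, 2] = 1.5               # some runs on the cycle
        freq = np.zeros_like(effmag)
        freq[q >= 1.9] = 1.0
        scan = bf.ScanResult(q, effmag, freq, tuple(range(n_seeds)))
        out = bf.classify_scan(scan)
        assert out["bistable_onset"] == pytest.approx(1.4)
        assert out["bistable_close"] == pytest.approx(1.7)
        assert out["discharge_reappearance"] == pytest.approx(1.9)

    def test_termination_point_logic(self):
        sweep = {"q_syn": np.array([1.0, 1.01, 1.02, 1.03]),
                 "freq": np.array([[1.0, 0.8], [0.2, 0.0],
                                   [0.0, 0.0], [0.0, 0.0]])}
        assert bf.termination_point(sweep) == pytest.approx(1.02)
        sweep["freq"][:] = 1.0
        assert np.isnan(bf.termination_point(sweep))
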