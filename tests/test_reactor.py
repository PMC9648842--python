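"""Reactor coupling, square-wave feed geometry, and integration tests."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cocultsim.core import EnzymeState, PathwayParams, SpeciesModel
from cocultsim.reactor import (
    FeedProgram,
    ReactorState,
    Trajectory,
    coculture_rhs,
    dilution_profile,
    integrate,
)


class TestDilutionProfile:
    def test_low_frequency_regime_on_off_geometry(self):
        """w=0.14, s=0.28 gives an exactly 2 h feed-on phase and a ~5 h
        feed-off phase per period (5.14 h exactly; 5 h as printed)."""
        fp = FeedProgram(mode="pulsed", D_on=0.1, w=0.14, s=0.28)
        period = 1 / 0.14
        assert fp.s * period == pytest.approx(2.0, rel=1e-10)
        assert (1 - fp.s) * period == pytest.approx(5.142857142857142, rel=1e-10)
        assert dilution_profile(1.0, fp) == 0.1
        assert dilution_profile(3.0, fp) == 0.0
        assert dilution_profile(period + 1.9, fp) == 0.1

    def test_high_frequency_regime_on_off_geometry(self):
        """w=0.33, s=0.33 gives an exactly 1 h on phase and ~2 h off."""
        fp = FeedProgram(mode="pulsed", D_on=0.1, w=0.33, s=0.33)
        period = 1 / 0.33
        assert fp.s * period == pytest.approx(1.0, rel=1e-10)
        assert (1 - fp.s) * period == pytest.approx(2.0303, rel=1e-3)

    def test_s_equal_one_is_chemostat(self):
        fp = FeedProgram(mode="pulsed", D_on=0.2, w=0.5, s=1.0)
        for t in np.linspace(0, 10, 37):
            assert dilution_profile(t, fp) == 0.2

    def test_time_average_is_duty_cycle(self):
        fp = FeedProgram(mode="pulsed", D_on=0.15, w=0.25, s=0.4)
        t = np.linspace(0, 1 / 0.25, 100001)[:-1]
        avg = np.mean([dilution_profile(tt, fp) for tt in t])
        assert avg == pytest.approx(0.4 * 0.15, rel=1e-3)
        assert fp.D_mean == pytest.approx(0.4 * 0.15)

    def test_batch_is_zero(self):
        assert dilution_profile(5.0, FeedProgram(mode="batch")) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            FeedProgram(mode="pulsed", D_on=0.1, w=0.0, s=0.5)
        with pytest.raises(ValueError):
            FeedProgram(mode="pulsed", D_on=0.1, w=0.1, s=1.5)
        with pytest.raises(ValueError):
            FeedProgram(mode="spray")


class TestCocultureRhs:
    def test_zero_biomass_only_enzymes_move(self, ecoli):
        state = ReactorState(
            t=0.0, X=np.array([0.0]), M=np.array([10.0, 0, 0]),
            E=[EnzymeState(np.array([0.2, 0.2, 0.2]))],
        )
        d = coculture_rhs(0.0, state, [ecoli], FeedProgram(mode="batch"))
        assert np.all(d.X == 0) and np.all(d.M == 0)
        assert np.any(d.E[0].psi_rel != 0)

    def test_identical_species_symmetric_derivatives(self, ecoli):
        twin = SpeciesModel("twin", ecoli.pathways, ecoli.metabolites)
        state = ReactorState(
            t=0.0, X=np.array([0.3, 0.3]), M=np.array([5.0, 1.0, 0.0]),
            E=[EnzymeState(np.array([0.5, 0.1, 0.2]))] * 2,
        )
        d = coculture_rhs(0.0, state, [ecoli, twin], FeedProgram(mode="batch"))
        assert d.X[0] == pytest.approx(d.X[1], rel=1e-12)
        assert d.E[0].psi_rel == pytest.approx(d.E[1].psi_rel, rel=1e-12)

    def test_chemostat_steady_state_is_stationary(self, monod_mono):
        """The classical Monod chemostat closed form S* = Ks D/(mu_max - D),
        X* = Yx (S_feed - S*) zeroes the joint derivative."""
        D, S_feed = 0.1, 30.0
        mu_max, Ks, Yx = 0.4356, 0.112, 0.165
        S_star = Ks * D / (mu_max - D)
        X_star = Yx * (S_feed - S_star)
        fp = FeedProgram(mode="chemostat", D_on=D, feed={"GLU": S_feed})
        state = ReactorState(
            t=0.0, X=np.array([X_star]), M=np.array([S_star, 0, 0]),
            E=[EnzymeState(np.ones(1))],
        )
        d = coculture_rhs(0.0, state, [monod_mono], fp)
        assert d.X[0] == pytest.approx(0.0, abs=1e-12)
        assert d.M[0] == pytest.approx(0.0, abs=1e-12)


class TestIntegrate:
    def test_starvation_keeps_biomass_enzymes_decay_to_baseline(self, ecoli):
        state = ReactorState(
            t=0.0, X=np.array([0.5]), M=np.zeros(3),
            E=[EnzymeState(np.array([0.9, 0.9, 0.9]))],
        )
        traj = integrate(state, [ecoli], FeedProgram(mode="batch"), 250.0,
                         report_dt=0.5)
        assert traj.X[:, 0] == pytest.approx(0.5, rel=1e-9)
        assert traj.psi_rel[0][-1] == pytest.approx(
            ecoli.psi_rel_resting, rel=1e-3
        )

    def test_washout_above_mu_max(self, ecoli, yeast):
        state = ReactorState(
            t=0.0, X=np.array([0.5, 0.5]), M=np.array([5.0, 0, 0]),
            E=[EnzymeState(sp.psi_rel_initial) for sp in (ecoli, yeast)],
        )
        # net loss rate is only D - mu ~ 0.06/h (the feed keeps glucose
        # saturating), so washout takes a few hundred hours
        fp = FeedProgram(mode="chemostat", D_on=0.5)
        traj = integrate(state, [ecoli, yeast], fp, 300.0, report_dt=0.5)
        assert traj.X[-1].sum() < 1e-4
        assert traj.X[-1].sum() < 0.01 * traj.X.sum(axis=1).max()

    def test_convergence_under_tolerance_refinement(self, ecoli):
        state = ReactorState(
            t=0.0, X=np.array([0.05]), M=np.array([20.0, 0, 0]),
            E=[EnzymeState(ecoli.psi_rel_initial)],
        )
        finals = []
        for rtol in (1e-7, 5e-8):
            traj = integrate(
                state, [ecoli], FeedProgram(mode="batch"), 30.0,
                rtol=rtol, atol=rtol * 1e-2,
            )
            finals.append(np.concatenate([traj.X[-1], traj.M[-1]]))
        scale = np.abs(finals[0]) + 1e-8
        assert np.max(np.abs(finals[0] - finals[1]) / scale) < 1e-4

    def test_batch_mass_accounting(self, ecoli):
        """Biomass plus byproducts never exceed substrate consumed; equality
        holds when the active pathway saturates the mass bound."""
        traj = integrate(
            ReactorState(
                t=0.0, X=np.array([0.05]), M=np.array([10.0, 0, 0]),
                E=[EnzymeState(ecoli.psi_rel_initial)],
            ),
            [ecoli], FeedProgram(mode="batch"), 12.0,
        )
        consumed = traj.M[0, 0] - traj.M[:, 0]
        gained = (traj.X[:, 0] - traj.X[0, 0]) + traj.M[:, 1] + traj.M[:, 2]
        assert np.all(gained <= consumed + 1e-6)

    def test_batch_mass_balance_equality_when_bound_saturated(self):
        p = PathwayParams(
            id="f", substrate="GLU", mu_max=0.4356, Ks=0.112, q_max=2.640,
            Yx=0.165, Yp={"ACE": 0.835},
        )
        sp = SpeciesModel("sat", [p])
        traj = integrate(
            ReactorState(
                t=0.0, X=np.array([0.05]), M=np.array([10.0, 0, 0]),
                E=[EnzymeState(sp.psi_rel_initial)],
            ),
            [sp], FeedProgram(mode="batch"), 15.0,
        )
        consumed = traj.M[0, 0] - traj.M[:, 0]
        gained = (traj.X[:, 0] - traj.X[0, 0]) + traj.M[:, 1]
        assert gained == pytest.approx(consumed, abs=1e-6)

    def test_single_pathway_reduces_to_plain_monod(self, monod_mono):
        """Independent oracle: a hand-coded two-ODE Monod batch integrator
        matches the full cybernetic machinery in the fixed-enzyme limit."""
        mu_max, Ks, Yx = 0.4356, 0.112, 0.165

        def monod_rhs(t, y):
            X, S = y
            mu = mu_max * S / (Ks + S) if S > 0 else 0.0
            return [mu * X, -mu / Yx * X]

        sol = solve_ivp(
            monod_rhs, (0, 20), [0.05, 8.0], rtol=1e-10, atol=1e-12,
            t_eval=np.arange(0, 20.01, 0.5),
        )
        traj = integrate(
            ReactorState(
                t=0.0, X=np.array([0.05]), M=np.array([8.0, 0, 0]),
                E=[EnzymeState(np.ones(1))],
            ),
            [monod_mono], FeedProgram(mode="batch"), 20.0, report_dt=0.5,
            rtol=1e-10, atol=1e-12,
        )
        assert traj.X[:, 0] == pytest.approx(sol.y[0], abs=1e-6)
        assert traj.M[:, 0] == pytest.approx(sol.y[1], abs=1e-6)

    def test_pulsed_approaches_periodic_orbit(self, ecoli, yeast):
        """After the transient, states one period apart differ by < 1%."""
        fp = FeedProgram(mode="pulsed", D_on=0.1, w=0.2, s=0.3)
        state = ReactorState(
            t=0.0, X=np.array([0.05, 0.05]), M=np.array([20.0, 0, 0]),
            E=[EnzymeState(sp.psi_rel_initial) for sp in (ecoli, yeast)],
        )
        traj = integrate(state, [ecoli, yeast], fp, 250.0, report_dt=0.25)
        period = 1 / 0.2
        for t0 in np.arange(250 - 5 * period, 250 - period + 0.1, period):
            i = np.searchsorted(traj.t, t0 - 1e-9)
            j = np.searchsorted(traj.t, t0 + period - 1e-9)
            a, b = traj.X[i], traj.X[j]
            assert np.all(np.abs(b - a) / (np.abs(a) + 1e-12) < 0.01)

    def test_duty_cycle_equivalence_at_high_frequency(self, monod_mono):
        """Fast pulsing with fixed s*D_on converges to the chemostat at the
        average dilution rate: the biomass deviation shrinks as w grows.
        (The residual substrate, whose relaxation time is far below any
        practical pulse period, equilibrates within each phase instead and
        is not compared.)"""
        state = ReactorState(
            t=0.0, X=np.array([0.5]), M=np.array([5.0, 0, 0]),
            E=[EnzymeState(np.ones(1))],
        )
        chem = integrate(
            state, [monod_mono],
            FeedProgram(mode="chemostat", D_on=0.1), 200.0, report_dt=1.0,
        )
        errs = []
        for w in (2.0, 8.0):
            puls = integrate(
                state, [monod_mono],
                FeedProgram(mode="pulsed", D_on=0.2, w=w, s=0.5), 200.0,
                report_dt=1.0,
            )
            errs.append(abs(puls.X[-1, 0] - chem.X[-1, 0]) / chem.X[-1, 0])
        assert errs[1] < errs[0]
        assert errs[1] < 0.02

    def test_diagnostics_satisfy_weight_normalization(self, ecoli, yeast):
        state = ReactorState(
            t=0.0, X=np.array([0.05, 0.05]), M=np.array([20.0, 0, 0]),
            E=[EnzymeState(sp.psi_rel_initial) for sp in (ecoli, yeast)],
        )
        traj = integrate(
            state, [ecoli, yeast], FeedProgram(mode="batch"), 25.0,
            report_dt=0.25,
        )
        for k in range(2):
            active = traj.mu_pathway[k].sum(axis=1) > 1e-12
            assert traj.u[k].sum(axis=1) == pytest.approx(1.0)
            assert traj.v[k][active].max(axis=1) == pytest.approx(1.0)

    def test_rejects_bad_time_span(self, ecoli):
        state = ReactorState(
            t=5.0, X=np.array([0.1]), M=np.array([1.0, 0, 0]),
            E=[EnzymeState(ecoli.psi_rel_initial)],
        )
        with pytest.raises(ValueError):
            integrate(state, [ecoli], FeedProgram(mode="batch"), 5.0)
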