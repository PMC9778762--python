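"""Torsional dynamics: potential/torque consistency, integrator physics."""

import dataclasses

import numpy as np
import pytest
from scipy.linalg import eigh

from dnaos.dynamics import (
    SimulationConfig,
    SystemState,
    binding_energies,
    coupling_torques,
    equations_rhs,
    integrate,
    max_characteristic_frequency,
    pair_binding_energy,
    total_energy,
    update_bond_states,
)
from dnaos.parameters import MechanicalParameterSet, PairParameters, apply_substitution
from dnaos.sequence import GeneSequence

HUGE = 1.0  # J, unreachably large critical energy


def resolved(gene, mech, ecr=HUGE):
    return PairParameters.from_gene(gene, mech, ecr)


class TestSubstitution:
    def test_single_site_scaled(self, gene10, mech):
        pp = resolved(gene10, mech)
        sub = apply_substitution(pp, 5, 1.05)
        assert sub.k12[4] == pytest.approx(pp.k12[4] * 1.05)
        assert sub.Ecr[4] == pytest.approx(pp.Ecr[4] * 1.05)
        mask = np.arange(10) != 4
        assert (sub.k12[mask] == pp.k12[mask]).all()
        assert (sub.Ecr[mask] == pp.Ecr[mask]).all()
        assert (sub.I1 == pp.I1).all() and (sub.K1 == pp.K1).all()

    def test_identity_at_kd_one(self, gene10, mech):
        pp = resolved(gene10, mech)
        sub = apply_substitution(pp, 3, 1.0)
        assert (sub.k12 == pp.k12).all() and (sub.Ecr == pp.Ecr).all()

    @pytest.mark.parametrize("site", [0, 11])
    def test_out_of_range(self, gene10, mech, site):
        with pytest.raises(IndexError):
            apply_substitution(resolved(gene10, mech), site, 1.05)


class TestBindingPotential:
    def test_zero_at_equilibrium(self, gene10, mech):
        pp = resolved(gene10, mech)
        state = SystemState.equilibrium(10)
        for i in (1, 5, 10):
            assert pair_binding_energy(state, pp, i) == pytest.approx(0.0, abs=1e-40)

    def test_quadratic_near_equilibrium(self, gene10, mech):
        """Small chain-1 displacement: V ~ (1/2) k_eff u^2 within 1%."""
        pp = resolved(gene10, mech)
        u = 1e-3
        i = 3
        phi1 = np.zeros(10)
        phi1[i - 1] = u
        V = binding_energies(phi1, np.full(10, np.pi), pp)[i - 1]
        k_eff = pp.k12[i - 1] * pp.R1[i - 1] * (pp.R1[i - 1] + 2 * pp.R2[i - 1])
        assert V == pytest.approx(0.5 * k_eff * u * u, rel=0.01)

    def test_torque_is_negative_gradient(self, gene10, mech):
        """Central finite differences of V match both coupling torques."""
        pp = resolved(gene10, mech)
        rng = np.random.default_rng(42)
        h = 1e-6
        scale = (pp.k12 * pp.R1 * (pp.R1 + pp.R2)).max()
        for _ in range(100):
            phi1 = rng.uniform(-2, 2, 10)
            phi2 = np.pi + rng.uniform(-2, 2, 10)
            t1, t2 = coupling_torques(phi1, phi2, pp)
            for k, (phis, torque) in enumerate(((phi1, t1), (phi2, t2))):
                hi, lo = phis.copy(), phis.copy()
                i = int(rng.integers(10))
                hi[i] += h
                lo[i] -= h
                args = [(hi, phi2), (lo, phi2)] if k == 0 else [(phi1, hi), (phi1, lo)]
                fd = (
                    binding_energies(*args[0], pp)[i] - binding_energies(*args[1], pp)[i]
                ) / (2 * h)
                assert abs(-fd - torque[i]) < 1e-6 * max(abs(torque[i]), 1e-3 * scale)

    def test_nonnegative_everywhere(self, gene10, mech):
        pp = resolved(gene10, mech)
        rng = np.random.default_rng(0)
        for _ in range(50):
            V = binding_energies(rng.uniform(-7, 7, 10), rng.uniform(-7, 7, 10), pp)
            assert (V >= 0).all()

    def test_index_out_of_range(self, gene10, mech):
        with pytest.raises(IndexError):
            pair_binding_energy(SystemState.equilibrium(10), resolved(gene10, mech), 11)


class TestEquationsRhs:
    def test_equilibrium_is_stationary(self, gene10, mech_undamped):
        pp = resolved(gene10, mech_undamped)
        cfg = SimulationConfig(F0=0.0, T=1e-12, dt=1e-14, m=1, EcrH=HUGE)
        d1, d2, a1, a2 = equations_rhs(SystemState.equilibrium(10), pp, cfg)
        assert np.abs(d1).max() == 0.0 and np.abs(d2).max() == 0.0
        # sin(pi) is ~1e-16 in floating point: zero to machine precision
        # relative to the characteristic acceleration scale w_char^2 * 1 rad
        accel_scale = max_characteristic_frequency(pp) ** 2
        assert np.abs(a1).max() <= 1e-14 * accel_scale
        assert np.abs(a2).max() <= 1e-14 * accel_scale

    def test_all_torques_off(self, gene10, mech_undamped):
        """delta=0, K=0, beta=0, F0=0: zero acceleration at any angles."""
        pp = resolved(gene10, mech_undamped)
        pp = dataclasses.replace(pp, K1=np.zeros(10), K2=np.zeros(10))
        rng = np.random.default_rng(1)
        state = SystemState(
            t=0.0,
            phi1=rng.uniform(-3, 3, 10),
            phi2=rng.uniform(-3, 3, 10),
            v1=np.zeros(10),
            v2=np.zeros(10),
            delta=np.zeros(10, dtype=np.int8),
        )
        cfg = SimulationConfig(F0=0.0, T=1e-12, dt=1e-14, m=1, EcrH=HUGE)
        _, _, a1, a2 = equations_rhs(state, pp, cfg)
        assert np.abs(a1).max() == 0.0 and np.abs(a2).max() == 0.0

    def test_single_pair_eigenfrequencies(self, mech_undamped):
        """Free small oscillation of one pair matches the 2x2 eigenvalue oracle.

        Backbone stiffness is zeroed so every pair is an exactly independent
        two-angle system; the middle pair is displaced along each linearized
        eigenmode and the observed frequency compared with sqrt(lambda).
        """
        gene = GeneSequence(tuple("AAA"))
        pp = resolved(gene, mech_undamped)
        pp = dataclasses.replace(pp, K1=np.zeros(3), K2=np.zeros(3))
        R1, R2, k12 = pp.R1[1], pp.R2[1], pp.k12[1]
        K = k12 * np.array(
            [[R1 * (R1 + 2 * R2), -R1 * R2], [-R1 * R2, R2 * (2 * R1 + R2)]]
        )
        M = np.diag([pp.I1[1], pp.I2[1]])
        evals, evecs = eigh(K, M)  # oracle: omega^2 and M-orthonormal modes
        for mode in range(2):
            omega = float(np.sqrt(evals[mode]))
            amp = 1e-3
            vec = evecs[:, mode] / np.abs(evecs[:, mode]).max()  # unit max-norm
            phi1 = np.zeros(3)
            phi2 = np.full(3, np.pi)
            phi1[1] = amp * vec[0]
            phi2[1] += amp * vec[1]
            init = SystemState(
                t=0.0, phi1=phi1, phi2=phi2, v1=np.zeros(3), v2=np.zeros(3),
                delta=np.ones(3, dtype=np.int8),
            )
            T = 12 * 2 * np.pi / omega
            dt = 1e-14
            cfg = SimulationConfig(F0=0.0, T=T, dt=dt, m=int(T / dt), EcrH=HUGE)
            traj = integrate(gene, pp, cfg, initial_state=init)
            # modal coordinate; measure frequency from interpolated zero crossings
            c = (
                M[0, 0] * evecs[0, mode] * traj.phi1[:, 1]
                + M[1, 1] * evecs[1, mode] * (traj.phi2[:, 1] - np.pi)
            )
            t = traj.times
            sign_change = np.flatnonzero(np.sign(c[:-1]) != np.sign(c[1:]))
            crossings = t[sign_change] - c[sign_change] * (
                t[sign_change + 1] - t[sign_change]
            ) / (c[sign_change + 1] - c[sign_change])
            assert len(crossings) >= 5
            omega_measured = np.pi * (len(crossings) - 1) / (crossings[-1] - crossings[0])
            assert omega_measured == pytest.approx(omega, rel=0.01)


class TestBondAutomaton:
    def _state_with_energy(self, pp, factor, i=0):
        """Open pair i on chain 1 until V_i = factor * Ecr_i (bisection)."""
        from scipy.optimize import brentq

        target = factor * pp.Ecr[i]

        def f(u):
            phi1 = np.zeros(pp.n)
            phi1[i] = u
            return binding_energies(phi1, np.full(pp.n, np.pi), pp)[i] - target

        u = brentq(f, 0.0, np.pi)
        phi1 = np.zeros(pp.n)
        phi1[i] = u
        return SystemState(
            t=0.0,
            phi1=phi1,
            phi2=np.full(pp.n, np.pi),
            v1=np.zeros(pp.n),
            v2=np.zeros(pp.n),
            delta=np.ones(pp.n, dtype=np.int8),
        )

    def test_break_restore_and_tie(self, gene10, mech):
        pp = resolved(gene10, mech, ecr=1e-22)
        state = self._state_with_energy(pp, 1.2)
        assert update_bond_states(state, pp)[0] == 0  # V > Ecr: break
        state.delta[0] = 0
        low = self._state_with_energy(pp, 0.5)
        low.delta[0] = 0
        assert update_bond_states(low, pp)[0] == 1  # V < Ecr: restore
        # exact tie: set the critical energy to the exactly-computed V
        tie = self._state_with_energy(pp, 0.7)
        V = binding_energies(tie.phi1, tie.phi2, pp)
        pp_tie = dataclasses.replace(pp, Ecr=V.copy())
        for d in (0, 1):
            tie.delta[0] = d
            assert update_bond_states(tie, pp_tie)[0] == d  # exact tie holds


class TestIntegrate:
    def test_forced_equilibrium_with_damping_stays_put(self, gene10, mech):
        cfg = SimulationConfig(F0=0.0, T=3e-12, dt=1e-14, m=30, EcrH=HUGE)
        traj = integrate(gene10, mech, cfg)
        assert np.abs(traj.phi1).max() < 1e-12
        assert np.abs(traj.phi2 - np.pi).max() < 1e-12
        assert (traj.delta == 1).all()

    def test_energy_conservation(self, gene10, mech_undamped):
        """beta=0, F0=0, no breaks: relative drift < 1e-6 over 1e4 RK4 steps."""
        pp = resolved(gene10, mech_undamped, ecr=HUGE)
        rng = np.random.default_rng(11)
        init = SystemState(
            t=0.0,
            phi1=rng.uniform(-0.3, 0.3, 10),
            phi2=np.pi + rng.uniform(-0.3, 0.3, 10),
            v1=np.zeros(10),
            v2=np.zeros(10),
            delta=np.ones(10, dtype=np.int8),
        )
        E0 = total_energy(init, pp)
        assert E0 > 0
        cfg = SimulationConfig(F0=0.0, T=5e-11, dt=5e-15, m=100, EcrH=HUGE)
        traj = integrate(gene10, pp, cfg, initial_state=init)
        E1 = total_energy(traj.final_state, pp)
        assert abs(E1 - E0) / E0 < 1e-6
        assert (traj.delta == 1).all()

    def test_substitution_identity_kd_one(self, gene10, mech):
        cfg = SimulationConfig(T=3e-12, dt=1e-14, m=50, EcrH=1e-25)
        ref = integrate(gene10, mech, cfg)
        cfg_sub = dataclasses.replace(cfg, kD=1.0, substitution_site=4)
        sub = integrate(gene10, mech, cfg_sub)
        assert (ref.phi1 == sub.phi1).all() and (ref.phi2 == sub.phi2).all()
        assert (ref.delta == sub.delta).all()

    def test_determinism(self, gene10, mech):
        cfg = SimulationConfig(T=2e-12, dt=1e-14, m=20, EcrH=1e-25)
        a = integrate(gene10, mech, cfg)
        b = integrate(gene10, mech, cfg)
        assert (a.phi1 == b.phi1).all() and (a.delta == b.delta).all()

    def test_step_halving_convergence(self, gene10, mech):
        cfg = SimulationConfig(T=3e-12, dt=1e-14, m=10, EcrH=HUGE)
        coarse = integrate(gene10, mech, cfg)
        fine = integrate(gene10, mech, dataclasses.replace(cfg, dt=5e-15))
        ref = np.abs(coarse.phi1[-1]).max()
        assert ref > 0
        assert np.abs(fine.phi1[-1] - coarse.phi1[-1]).max() < 1e-4 * ref

    def test_dt_guard(self, gene10, mech):
        w = max_characteristic_frequency(resolved(gene10, mech))
        cfg = SimulationConfig(T=1e-11, dt=0.2 / w, m=10, EcrH=HUGE)
        with pytest.raises(ValueError, match="stability guard"):
            integrate(gene10, mech, cfg)

    def test_nonfinite_abort_names_step_and_pair(self, gene10, mech):
        bad = SystemState.equilibrium(10)
        bad.phi1[2] = np.nan
        cfg = SimulationConfig(F0=0.0, T=1e-13, dt=1e-14, m=1, EcrH=HUGE)
        with pytest.raises(FloatingPointError, match="pair"):
            integrate(gene10, mech, cfg, initial_state=bad, check_every=1)
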