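"""Torsional dynamics of a double-stranded gene with bond break/restore.

The molecule is modelled as two chains of n rotating bases.  The angular
deflections phi1[i], phi2[i] obey 2n coupled Newton equations: a torsional
backbone torque from the neighbouring bases of the same chain, an
inter-strand coupling torque derived from the pair binding potential, a
damping torque -beta * dphi/dt and a periodic external torque F0 cos(w t).

Bond automaton: pair i is intact (delta[i] = 1) or broken (delta[i] = 0).
After every integration step the binding energy V_i is compared with the
pair's critical energy: V_i > Ecr[i] breaks the bond, V_i < Ecr[i] restores
it; exact equality leaves the state unchanged.  A broken bond removes the
coupling torque from the equations of motion, but V_i itself is always
evaluated with the full stiffness so that restoration can be tested.

The pair binding potential (normalised to zero at the equilibrium
(phi1, phi2) = (0, pi)) is

    V_i = k12_i * [ R1 (R1+R2) (1 - cos phi1)
                  + R2 (R1+R2) (1 + cos phi2)
                  + R1 R2 (1 + cos(phi1 - phi2)) ]

whose negative gradient supplies both chains' coupling torques; each
bracketed term is non-negative, so V_i >= 0 everywhere and the equilibrium
is a stable stationary point of the free system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .parameters import PairParameters, MechanicalParameterSet, ENERGY_UNIT
from .sequence import GeneSequence

__all__ = [
    "SimulationConfig",
    "SystemState",
    "Trajectory",
    "pair_binding_energy",
    "binding_energies",
    "coupling_torques",
    "equations_rhs",
    "update_bond_states",
    "total_energy",
    "max_characteristic_frequency",
    "integrate",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Forcing, integration and bond-threshold settings.

    All values SI.  ``EcrH`` is the hydrogen-bond critical energy in joules;
    a substituted site gets ``kD * EcrH``.  ``m`` is the number of sampling
    times t_j = j T / m used by the open-state probability estimator.
    """

    F0: float = 0.526e-22        # N m, external torque amplitude
    omega: float = 0.4e12        # 1/s, external torque angular frequency
    T: float = 3.0e-10           # s, total simulated time
    dt: float = 1.0e-14          # s, integration step
    m: int = 1000                # number of sampling times
    EcrH: float = 0.581e-22      # N m, critical break energy (protium bond)
    kD: float = 1.05             # deuterium strengthening factor
    substitution_site: int | None = None  # 1-based pair index, or None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.T < self.m * 0 or self.T <= 0:
            raise ValueError("T must be positive")
        if self.T < self.m * self.dt:
            raise ValueError("T must cover at least m steps (T >= m*dt)")
        if self.EcrH <= 0:
            raise ValueError("EcrH must be positive")
        if self.kD < 1:
            raise ValueError("kD must be >= 1")


@dataclass
class SystemState:
    """Instantaneous state: angles, angular velocities and bond flags."""

    t: float
    phi1: np.ndarray
    phi2: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    delta: np.ndarray  # 1 intact, 0 broken

    @property
    def n(self) -> int:
        return len(self.phi1)

    @classmethod
    def equilibrium(cls, n: int) -> "SystemState":
        """Rest state: phi1 = 0, phi2 = pi, zero velocities, all bonds intact."""
        return cls(
            t=0.0,
            phi1=np.zeros(n),
            phi2=np.full(n, np.pi),
            v1=np.zeros(n),
            v2=np.zeros(n),
            delta=np.ones(n, dtype=np.int8),
        )


def binding_energies(phi1: np.ndarray, phi2: np.ndarray, p: PairParameters) -> np.ndarray:
    """Vector of pair binding potentials V_i (J), >= 0, zero at (0, pi)."""
    Rsum = p.R1 + p.R2
    return p.k12 * (
        p.R1 * Rsum * (1.0 - np.cos(phi1))
        + p.R2 * Rsum * (1.0 + np.cos(phi2))
        + p.R1 * p.R2 * (1.0 + np.cos(phi1 - phi2))
    )


def pair_binding_energy(state: SystemState, params: PairParameters, i: int) -> float:
    """Binding potential of pair ``i`` (1-based), evaluated with full k12."""
    if not 1 <= i <= params.n:
        raise IndexError(f"pair index {i} out of range 1..{params.n}")
    return float(binding_energies(state.phi1, state.phi2, params)[i - 1])


def coupling_torques(
    phi1: np.ndarray, phi2: np.ndarray, p: PairParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Inter-strand torques -dV/dphi1, -dV/dphi2 (N m), full stiffness."""
    Rsum = p.R1 + p.R2
    cross = p.k12 * p.R1 * p.R2
    t1 = -p.k12 * p.R1 * Rsum * np.sin(phi1) + cross * np.sin(phi1 - phi2)
    t2 = p.k12 * p.R2 * Rsum * np.sin(phi2) + cross * np.sin(phi2 - phi1)
    return t1, t2


def _backbone_torque(phi: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Torsional torque K_i (phi_{i-1} - 2 phi_i + phi_{i+1}), one-sided ends."""
    n = len(phi)
    if n == 1:
        return np.zeros(1)
    out = np.empty(n)
    out[1:-1] = K[1:-1] * (phi[:-2] - 2.0 * phi[1:-1] + phi[2:])
    out[0] = K[0] * (phi[1] - phi[0])
    out[-1] = K[-1] * (phi[-2] - phi[-1])
    return out


def equations_rhs(
    state: SystemState,
    params: PairParameters,
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Time derivatives (dphi1, dphi2, dv1, dv2) at the state's time.

    The coupling torque of a broken pair (delta = 0) is gated off; backbone,
    damping and external torques always act.
    """
    a1, a2 = _accelerations(
        state.phi1, state.phi2, state.v1, state.v2, state.delta, state.t, params, config
    )
    return state.v1.copy(), state.v2.copy(), a1, a2


def _accelerations(phi1, phi2, v1, v2, delta, t, p: PairParameters, cfg: SimulationConfig):
    c1, c2 = coupling_torques(phi1, phi2, p)
    ext = cfg.F0 * np.cos(cfg.omega * t)
    a1 = (_backbone_torque(phi1, p.K1) + delta * c1 - p.beta1 * v1 + ext) / p.I1
    a2 = (_backbone_torque(phi2, p.K2) + delta * c2 - p.beta2 * v2 + ext) / p.I2
    return a1, a2


def update_bond_states(state: SystemState, params: PairParameters) -> np.ndarray:
    """New delta vector: break when V > Ecr, restore when V < Ecr, tie holds."""
    V = binding_energies(state.phi1, state.phi2, params)
    delta = state.delta.copy()
    delta[V > params.Ecr] = 0
    delta[V < params.Ecr] = 1
    return delta


def _backbone_energy(phi: np.ndarray, K: np.ndarray) -> float:
    """Torsional energy with link stiffness averaged between neighbours.

    Exactly consistent with the per-base torque form when K is uniform
    along the chain (the case covered by the conservation tests).
    """
    if len(phi) == 1:
        return 0.0
    Klink = 0.5 * (K[:-1] + K[1:])
    d = np.diff(phi)
    return float(0.5 * np.sum(Klink * d * d))


def total_energy(state: SystemState, params: PairParameters) -> float:
    """Kinetic + backbone + (intact) pair potential energy (J)."""
    kin = 0.5 * float(
        np.sum(params.I1 * state.v1**2) + np.sum(params.I2 * state.v2**2)
    )
    back = _backbone_energy(state.phi1, params.K1) + _backbone_energy(state.phi2, params.K2)
    pair = float(np.sum(state.delta * binding_energies(state.phi1, state.phi2, params)))
    return kin + back + pair


def max_characteristic_frequency(params: PairParameters) -> float:
    """max_i sqrt((K + k12 R (R + R')) / I) over both strands, 1/s."""
    Rsum = params.R1 + params.R2
    w1 = np.sqrt((params.K1 + params.k12 * params.R1 * Rsum) / params.I1)
    w2 = np.sqrt((params.K2 + params.k12 * params.R2 * Rsum) / params.I2)
    return float(max(w1.max(), w2.max()))


@dataclass
class Trajectory:
    """States sampled at t_j = j T / m, plus the final state."""

    times: np.ndarray            # (m,)
    phi1: np.ndarray             # (m, n)
    phi2: np.ndarray             # (m, n)
    delta: np.ndarray            # (m, n)
    final_state: SystemState

    @property
    def m(self) -> int:
        return len(self.times)

    def broken_fractions(self) -> np.ndarray:
        """q_j = broken-pair fraction at each sample time."""
        return (self.delta == 0).mean(axis=1)

    def to_frame(self):
        """Delimited-text friendly table: t, phi1[1..n], phi2[1..n], delta[1..n]."""
        import pandas as pd

        n = self.phi1.shape[1]
        cols = {"t": self.times}
        for k in range(n):
            cols[f"phi1_{k + 1}"] = self.phi1[:, k]
        for k in range(n):
            cols[f"phi2_{k + 1}"] = self.phi2[:, k]
        for k in range(n):
            cols[f"delta_{k + 1}"] = self.delta[:, k]
        return pd.DataFrame(cols)


def integrate(
    gene: GeneSequence,
    params: MechanicalParameterSet | PairParameters,
    config: SimulationConfig,
    *,
    initial_state: SystemState | None = None,
    check_every: int = 200,
) -> Trajectory:
    """Integrate the 2n-equation Cauchy problem with classical RK4.

    Starts from the equilibrium initial conditions (phi1 = 0, phi2 = pi,
    zero velocities, all bonds intact) and advances with a fixed step
    ``config.dt``; the bond automaton is applied once after each full step.
    States are recorded at the m sampling times t_j = j T / m (t = 0
    excluded).  Fully deterministic.  ``initial_state`` overrides the
    equilibrium start (used e.g. for conservation diagnostics).

    ``params`` may be a raw MechanicalParameterSet (resolved against the
    gene, with ``config.substitution_site`` applied) or an already-resolved
    PairParameters (used as-is).
    """
    if isinstance(params, MechanicalParameterSet):
        pp = PairParameters.from_gene(gene, params, config.EcrH)
        if config.substitution_site is not None:
            pp = pp.with_substitution(config.substitution_site, config.kD)
    else:
        pp = params

    dt = config.dt
    w_char = max_characteristic_frequency(pp)
    if np.isfinite(w_char) and dt > 0.05 / w_char:
        raise ValueError(
            f"dt={dt:g} s exceeds the stability guard {0.05 / w_char:g} s "
            f"(characteristic frequency {w_char:g} 1/s)"
        )

    n = gene.n
    n_steps = int(round(config.T / dt))
    m = config.m
    # step index at which each sample t_j = j T / m is taken
    sample_steps = np.rint(np.arange(1, m + 1) * (n_steps / m)).astype(int)
    sample_steps = np.clip(sample_steps, 1, n_steps)
    sample_of_step: dict[int, list[int]] = {}
    for j, s in enumerate(sample_steps):
        sample_of_step.setdefault(int(s), []).append(j)

    if initial_state is None:
        phi1 = np.zeros(n)
        phi2 = np.full(n, np.pi)
        v1 = np.zeros(n)
        v2 = np.zeros(n)
        delta = np.ones(n, dtype=np.int8)
    else:
        phi1 = initial_state.phi1.astype(float).copy()
        phi2 = initial_state.phi2.astype(float).copy()
        v1 = initial_state.v1.astype(float).copy()
        v2 = initial_state.v2.astype(float).copy()
        delta = initial_state.delta.astype(np.int8).copy()

    out_t = np.empty(m)
    out_phi1 = np.empty((m, n))
    out_phi2 = np.empty((m, n))
    out_delta = np.empty((m, n), dtype=np.int8)

    t = 0.0
    acc = _accelerations
    for step in range(1, n_steps + 1):
        # classical RK4 on (phi1, phi2, v1, v2); delta frozen within the step
        a1, b1 = acc(phi1, phi2, v1, v2, delta, t, pp, config)
        k1 = (v1, v2, a1, b1)

        th = t + 0.5 * dt
        p1 = phi1 + 0.5 * dt * k1[0]
        p2 = phi2 + 0.5 * dt * k1[1]
        u1 = v1 + 0.5 * dt * k1[2]
        u2 = v2 + 0.5 * dt * k1[3]
        a2_, b2_ = acc(p1, p2, u1, u2, delta, th, pp, config)
        k2 = (u1, u2, a2_, b2_)

        p1 = phi1 + 0.5 * dt * k2[0]
        p2 = phi2 + 0.5 * dt * k2[1]
        u1 = v1 + 0.5 * dt * k2[2]
        u2 = v2 + 0.5 * dt * k2[3]
        a3_, b3_ = acc(p1, p2, u1, u2, delta, th, pp, config)
        k3 = (u1, u2, a3_, b3_)

        tf = t + dt
        p1 = phi1 + dt * k3[0]
        p2 = phi2 + dt * k3[1]
        u1 = v1 + dt * k3[2]
        u2 = v2 + dt * k3[3]
        a4_, b4_ = acc(p1, p2, u1, u2, delta, tf, pp, config)
        k4 = (u1, u2, a4_, b4_)

        phi1 = phi1 + (dt / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        phi2 = phi2 + (dt / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        v1 = v1 + (dt / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        v2 = v2 + (dt / 6.0) * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        t = tf

        # bond automaton, once per full step
        V = binding_energies(phi1, phi2, pp)
        delta = delta.copy()
        delta[V > pp.Ecr] = 0
        delta[V < pp.Ecr] = 1

        if step % check_every == 0 or step == n_steps:
            if not (np.isfinite(phi1).all() and np.isfinite(phi2).all()):
                bad = int(np.argmax(~(np.isfinite(phi1) & np.isfinite(phi2)))) + 1
                raise FloatingPointError(
                    f"non-finite state at step {step} (t={t:g} s), pair {bad}"
                )

        for j in sample_of_step.get(step, ()):
            out_t[j] = t
            out_phi1[j] = phi1
            out_phi2[j] = phi2
            out_delta[j] = delta

    final = SystemState(t=t, phi1=phi1, phi2=phi2, v1=v1, v2=v2, delta=delta)
    return Trajectory(out_t, out_phi1, out_phi2, out_delta, final)
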