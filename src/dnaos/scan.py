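"""Open-state probability estimation and single-substitution scans.

P0 is the time-averaged broken-pair fraction of the all-protium molecule;
P_i the same quantity when pair i carries a single deuterium bond.  Both
are estimated from a trajectory as the arithmetic mean of q_j, the ratio of
broken pairs to n at the sampling times t_j = j T / m:

    P = (1/m) * sum_j q_j

A scan runs one baseline and n substituted simulations for every critical
energy in the grid; each simulation is independent and deterministic, so
the result does not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import SimulationConfig, SystemState, Trajectory, integrate
from .parameters import ENERGY_UNIT, MechanicalParameterSet, PairParameters
from .sequence import GeneSequence

log = logging.getLogger(__name__)

__all__ = [
    "broken_fraction",
    "estimate_open_state_probability",
    "OpenStateScanResult",
    "scan_substitutions",
]


def broken_fraction(state: SystemState) -> float:
    """q = (number of pairs with delta = 0) / n."""
    return float((state.delta == 0).mean())


def estimate_open_state_probability(trajectory: Trajectory | np.ndarray) -> float:
    """Arithmetic mean of the broken-pair fractions q_j over the samples."""
    if isinstance(trajectory, Trajectory):
        qs = trajectory.broken_fractions()
    else:
        qs = np.asarray(trajectory, dtype=float)
    if qs.size == 0:
        raise ValueError("empty trajectory: no sampling times")
    return float(qs.mean())


@dataclass
class OpenStateScanResult:
    """P0 and the site-by-energy matrix of substituted probabilities.

    ``energies`` are critical energies in joules; ``P0`` has one entry per
    energy; ``P`` has shape (n, len(energies)) with row i-1 holding P_i.
    """

    energies: np.ndarray
    P0: np.ndarray
    P: np.ndarray
    config: SimulationConfig

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long table: site (0 = baseline), EcrH in 1e-22 N m, P."""
        rows = []
        for e_idx, e in enumerate(self.energies):
            rows.append({"site": 0, "ecrh": e / ENERGY_UNIT, "P": self.P0[e_idx]})
            for i in range(self.n):
                rows.append(
                    {"site": i + 1, "ecrh": e / ENERGY_UNIT, "P": self.P[i, e_idx]}
                )
        return pd.DataFrame(rows)


def _single_run(
    gene: GeneSequence,
    pp: PairParameters,
    config: SimulationConfig,
) -> float:
    traj = integrate(gene, pp, config)
    return estimate_open_state_probability(traj)


def scan_substitutions(
    gene: GeneSequence,
    mech: MechanicalParameterSet,
    config: SimulationConfig,
    energies: "np.ndarray | list[float]",
    sites: "list[int] | None" = None,
) -> OpenStateScanResult:
    """Run the baseline and every single-substitution simulation per energy.

    ``energies`` are critical energies in joules, strictly positive and
    ascending.  ``sites`` restricts the scan to a subset of 1-based pair
    indices (default: all); unscanned rows are NaN.
    """
    energies = np.asarray(energies, dtype=float)
    if energies.size == 0 or (energies <= 0).any():
        raise ValueError("energies must be strictly positive")
    if (np.diff(energies) <= 0).any():
        raise ValueError("energies must be sorted ascending")
    if sites is None:
        sites = list(range(1, gene.n + 1))
    for s in sites:
        if not 1 <= s <= gene.n:
            raise IndexError(f"site {s} out of range 1..{gene.n}")

    P0 = np.empty(len(energies))
    P = np.full((gene.n, len(energies)), np.nan)
    for e_idx, e in enumerate(energies):
        cfg = SimulationConfig(
            F0=config.F0,
            omega=config.omega,
            T=config.T,
            dt=config.dt,
            m=config.m,
            EcrH=float(e),
            kD=config.kD,
            substitution_site=None,
        )
        base_pp = PairParameters.from_gene(gene, mech, float(e))
        try:
            P0[e_idx] = _single_run(gene, base_pp, cfg)
        except Exception as err:
            raise RuntimeError(
                f"baseline simulation failed at EcrH={e / ENERGY_UNIT:g}e-22 N m"
            ) from err
        log.info(
            "scan: EcrH=%.4ge-22 N m baseline P0=%.3g", e / ENERGY_UNIT, P0[e_idx]
        )
        for s in sites:
            pp = base_pp.with_substitution(s, config.kD)
            try:
                P[s - 1, e_idx] = _single_run(gene, pp, cfg)
            except Exception as err:
                raise RuntimeError(
                    f"substituted simulation failed at site {s}, "
                    f"EcrH={e / ENERGY_UNIT:g}e-22 N m"
                ) from err
        log.info("scan: EcrH=%.4ge-22 N m done (%d sites)", e / ENERGY_UNIT, len(sites))
    return OpenStateScanResult(energies=energies, P0=P0, P=P, config=config)
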