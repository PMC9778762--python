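"""Mechanical parameters of the coarse-grained torsional DNA model.

Each nitrogenous base is a rotating disk attached to its sugar-phosphate
backbone; each pair of complementary bases is coupled by an elastic
transverse bond.  Per-base quantities:

* rotational inertia ``I`` (kg m^2),
* distance ``R`` from the base's centre of inertia to the backbone (m),
* backbone torsion constant ``K`` (N m per rad),
* damping coefficient ``beta`` (J s), modelling the aqueous environment,

and a per-pair bond stiffness ``k12`` (N/m), resolved from the first-strand
base letter (the two A-T orientations share a value, as do the two G-C
orientations, since the pair is the physical object).

A single deuterium substitution at pair ``i`` strengthens that pair's bond:
``k12[i]`` and its critical break energy ``Ecr[i]`` are both scaled by the
dimensionless factor ``kD`` (default 1.05, a 5% stronger bond).

Energies are SI joules (== N m) internally; user-facing interfaces use the
conventional 1e-22 N m unit (``ENERGY_UNIT``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .sequence import GeneSequence

ENERGY_UNIT = 1e-22  # N m; critical energies are quoted in this unit

BASES = ("A", "T", "G", "C")

#: Literature-typical default coefficients, of the order used in torsional
#: DNA models.  NOT authoritative: the model is normally run with a
#: config-supplied coefficient table; these defaults exist so that toy and
#: synthetic studies are self-contained.
DEFAULT_BASE_PARAMS: dict[str, dict[str, float]] = {
    #        inertia (kg m^2)  radius (m)  torsion (N m)  k12 (N/m)
    "A": {"inertia": 7.61e-44, "radius": 5.8e-10, "torsion": 6.0e-19, "k12": 0.055},
    "T": {"inertia": 4.86e-44, "radius": 4.8e-10, "torsion": 6.0e-19, "k12": 0.055},
    "G": {"inertia": 8.22e-44, "radius": 5.7e-10, "torsion": 6.0e-19, "k12": 0.085},
    "C": {"inertia": 4.11e-44, "radius": 4.7e-10, "torsion": 6.0e-19, "k12": 0.085},
}

#: Default damping: beta ~ inertia / (1e-10 s) gives a damping time of the
#: order of the simulated interval.  A calibration knob, not a measured value.
DEFAULT_BETA = 7.0e-34  # J s


@dataclass(frozen=True)
class MechanicalParameterSet:
    """Per-base-type mechanical coefficients plus the deuterium factor kD."""

    base_params: dict[str, dict[str, float]] = field(
        default_factory=lambda: {b: dict(v) for b, v in DEFAULT_BASE_PARAMS.items()}
    )
    beta: dict[str, float] = field(default_factory=lambda: {b: DEFAULT_BETA for b in BASES})
    kD: float = 1.05

    def __post_init__(self):
        for b in BASES:
            if b not in self.base_params:
                raise ValueError(f"missing parameters for base {b}")
            for key in ("inertia", "radius", "torsion", "k12"):
                v = self.base_params[b].get(key)
                if v is None or v <= 0:
                    raise ValueError(f"parameter {key} for base {b} must be strictly positive")
            if self.beta.get(b) is None or self.beta[b] < 0:
                raise ValueError(f"damping beta for base {b} must be non-negative")
        if self.kD < 1:
            raise ValueError(f"kD must be >= 1, got {self.kD}")

    def value(self, base: str, key: str) -> float:
        return self.base_params[base][key]


@dataclass(frozen=True)
class PairParameters:
    """Per-pair arrays of resolved coefficients for a concrete gene.

    Strand 1 carries the first-strand base of each pair, strand 2 its
    complement.  ``Ecr`` is the critical break energy per pair in joules;
    a substituted pair has both ``k12`` and ``Ecr`` scaled by kD.
    """

    I1: np.ndarray
    I2: np.ndarray
    R1: np.ndarray
    R2: np.ndarray
    K1: np.ndarray
    K2: np.ndarray
    k12: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    Ecr: np.ndarray

    @property
    def n(self) -> int:
        return len(self.k12)

    @classmethod
    def from_gene(
        cls,
        gene: GeneSequence,
        mech: MechanicalParameterSet,
        EcrH: float,
    ) -> "PairParameters":
        """Resolve per-pair arrays for an all-protium molecule.

        ``EcrH`` is in joules (N m).
        """
        if EcrH <= 0:
            raise ValueError(f"critical energy must be positive, got {EcrH}")
        n = gene.n

        def arr(strand: int, key: str) -> np.ndarray:
            return np.array([mech.value(gene.base(i, strand), key) for i in range(1, n + 1)])

        def barr(strand: int) -> np.ndarray:
            return np.array([mech.beta[gene.base(i, strand)] for i in range(1, n + 1)])

        return cls(
            I1=arr(1, "inertia"),
            I2=arr(2, "inertia"),
            R1=arr(1, "radius"),
            R2=arr(2, "radius"),
            K1=arr(1, "torsion"),
            K2=arr(2, "torsion"),
            k12=arr(1, "k12"),
            beta1=barr(1),
            beta2=barr(2),
            Ecr=np.full(n, float(EcrH)),
        )

    def with_substitution(self, site: int, kD: float) -> "PairParameters":
        """Copy with a single deuterium substitution at 1-based ``site``.

        Only that pair's bond stiffness and critical energy are scaled by
        ``kD``; all other entries are untouched.
        """
        if not 1 <= site <= self.n:
            raise IndexError(f"substitution site {site} out of range 1..{self.n}")
        k12 = self.k12.copy()
        Ecr = self.Ecr.copy()
        k12[site - 1] *= kD
        Ecr[site - 1] *= kD
        return replace(self, k12=k12, Ecr=Ecr)


def apply_substitution(params: PairParameters, site: int, kD: float) -> PairParameters:
    """Functional alias for :meth:`PairParameters.with_substitution`."""
    return params.with_substitution(site, kD)
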