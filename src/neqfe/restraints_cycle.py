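"""Restraint corrections, thermodynamic-cycle assembly and repeat pooling.

An absolute binding free energy is assembled from a ligand-solvation leg,
a protein–ligand coupling leg and an analytical correction for releasing
the orientational restraints (one distance, two angles, three dihedrals)
that hold the decoupled ligand in its binding pose, to the standard-state
volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import kt_kcal

__all__ = [
    "BoreschRestraint",
    "CycleLeg",
    "boresch_dg",
    "combine_repeats",
    "assemble_cycle",
    "ABFE_SIGNS",
]

#: Standard-state volume for a 1 M solution, Å³ per molecule.
V0_STANDARD = 1660.0

#: ABFE leg sign preset: prot couples the restrained ligand in the protein,
#: solv couples the ligand in water, restr releases the restraints to
#: standard state. ΔG_bind = −ΔG_solv + ΔG_prot + ΔG_restr.
ABFE_SIGNS = {"solv": -1, "prot": +1, "restr": +1}


@dataclass(frozen=True)
class BoreschRestraint:
    """Reference geometry and force constants of a 6-DOF pose restraint.

    Harmonic potentials U = ½K(x−x₀)² in one protein–ligand distance
    (``r0`` Å, ``kr`` kcal/mol/Å²), two angles (rad, kcal/mol/rad²) and
    three dihedrals (kcal/mol/rad²).
    """

    r0: float
    thetaA0: float
    thetaB0: float
    kr: float
    kthA: float
    kthB: float
    kphiA: float
    kphiB: float
    kphiC: float
    temperature: float = 298.15
    v0: float = V0_STANDARD

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        for name in ("kr", "kthA", "kthB", "kphiA", "kphiB", "kphiC"):
            if getattr(self, name) <= 0:
                raise ValueError(f"force constant {name} must be positive")
        for name in ("thetaA0", "thetaB0"):
            th = getattr(self, name)
            if not 0 < th < math.pi:
                raise ValueError(f"{name} must lie strictly between 0 and π")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.v0 <= 0:
            raise ValueError("v0 must be positive")

    @property
    def force_constants(self) -> tuple[float, ...]:
        return (self.kr, self.kthA, self.kthB, self.kphiA, self.kphiB, self.kphiC)


def boresch_dg(r: BoreschRestraint) -> float:
    """Standard-state release free energy of a Boresch restraint (kcal/mol).

    Closed form (stiff-spring limit):

        ΔG_restr = −kT ln[ 8π² V° √(K_r K_θA K_θB K_φA K_φB K_φC)
                           / ( r0² sinθ_A0 sinθ_B0 (2πkT)³ ) ]

    Unit bookkeeping: kT is in kcal/mol, force constants in kcal/mol/Å²
    (distance) and kcal/mol/rad² (angles/dihedrals), r0 in Å and V° in Å³.
    Each harmonic degree of freedom contributes a configurational integral
    √(2πkT/K), so √(ΠK)/(2πkT)³ carries Å⁻¹ (from K_r) and V°/r0²
    carries Å — the log argument is dimensionless. The sign convention is
    the one that makes the ABFE preset (solv −, prot +, restr +) assemble a
    binding ΔG; releasing a tight restraint into 1 M standard state is
    favorable, so typical values are negative.
    """
    kt = kt_kcal(r.temperature)
    sin_a = math.sin(r.thetaA0)
    sin_b = math.sin(r.thetaB0)
    if sin_a == 0 or sin_b == 0:
        raise ValueError("sin(theta0) must be non-zero")
    num = 8.0 * math.pi**2 * r.v0 * math.sqrt(math.prod(r.force_constants))
    den = r.r0**2 * sin_a * sin_b * (2.0 * math.pi * kt) ** 3
    return -kt * math.log(num / den)


def combine_repeats(repeats: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Pool independent calculation repeats into one (ΔG, se).

    Each repeat is a ``(dg, se)`` pair; the repeat's ΔG distribution is
    taken as Normal(dg, se). The pooled estimate is the mean of the repeat
    means; the pooled uncertainty is the standard error across the mixture
    of normals:

        σ_mix² = mean(se_i²) + var(dg_i, ddof=1)    (0 between-term if n==1)
        se     = σ_mix / √n
    """
    if len(repeats) == 0:
        raise ValueError("at least one repeat required")
    dgs = np.asarray([r[0] for r in repeats], dtype=float)
    ses = np.asarray([r[1] for r in repeats], dtype=float)
    if np.any(ses < 0):
        raise ValueError("se must be non-negative")
    n = dgs.size
    between = float(np.var(dgs, ddof=1)) if n > 1 else 0.0
    sigma_mix = math.sqrt(float(np.mean(ses**2)) + between)
    return float(dgs.mean()), sigma_mix / math.sqrt(n)


@dataclass(frozen=True)
class CycleLeg:
    """One leg of the thermodynamic cycle: a signed ΔG contribution."""

    name: str
    dg: float
    se: float
    sign: int = +1

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")


def assemble_cycle(legs: Sequence[CycleLeg]) -> tuple[float, float]:
    """Sum legs into (ΔG_bind, se); se adds in quadrature.

    Use :data:`ABFE_SIGNS` for the standard decoupling cycle; duplicate leg
    names are rejected.
    """
    if len(legs) == 0:
        raise ValueError("at least one leg required")
    names = [leg.name for leg in legs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate legs: {dupes}")
    dg = sum(leg.sign * leg.dg for leg in legs)
    se = math.sqrt(sum(leg.se**2 for leg in legs))
    return float(dg), float(se)


def abfe_legs(dg_solv: tuple[float, float], dg_prot: tuple[float, float],
              dg_restr: float) -> list[CycleLeg]:
    """Build the standard ABFE legs from (dg, se) pairs and ΔG_restr."""
    return [
        CycleLeg("solv", dg_solv[0], dg_solv[1], ABFE_SIGNS["solv"]),
        CycleLeg("prot", dg_prot[0], dg_prot[1], ABFE_SIGNS["prot"]),
        CycleLeg("restr", dg_restr, 0.0, ABFE_SIGNS["restr"]),
    ]
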