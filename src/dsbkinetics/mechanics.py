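"""Chain geometry, units, and worm-like-chain mechanics.

The DNA filament under study is a 3855-bp B-DNA molecule held at a fixed
average end-to-end distance by a constant axial force.  In the low-force
regime (below ~5 pN) double-stranded DNA responds to tension by entropic
compliance and the Marko-Siggia interpolation of the worm-like chain (WLC)
relates the stretching force to the fractional extension through two
material parameters: the persistence length xi (~50 nm) and the contour
length L.

This module also owns the reduced (Lennard-Jones) unit bookkeeping of the
coarse-grained simulations: one LJ time unit tau corresponds to
sqrt(m * sigma^2 / epsilon) seconds given the model's mass, length and
energy units, and every time printed downstream flows through a single
:class:`UnitSystem` instance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

from scipy.optimize import brentq

#: Boltzmann constant in pN nm / K (CODATA 1.380649e-23 J/K).
BOLTZMANN_PN_NM_PER_K = 1.380649e-2
#: Boltzmann constant in kcal / mol / K.
BOLTZMANN_KCAL_MOL_PER_K = 1.987204259e-3

#: LAMMPS-oxDNA reduced units: mass unit in kg (100 amu), length unit in m,
#: energy unit in J.  tau = sqrt(m sigma^2 / eps) ~ 1.7075 ps.
_LJ_MASS_KG = 100 * 1.66053906892e-27
_LJ_LENGTH_M = 0.8518e-9
_LJ_ENERGY_J = 4.142e-20


def lj_time_unit_seconds(mass_kg: float = _LJ_MASS_KG,
                         length_m: float = _LJ_LENGTH_M,
                         energy_J: float = _LJ_ENERGY_J) -> float:
    """Seconds per LJ time unit from the defining sqrt(m sigma^2 / eps)."""
    return math.sqrt(mass_kg * length_m ** 2 / energy_J)


@dataclass(frozen=True)
class UnitSystem:
    """Conversion constants between reduced (LJ) and SI units.

    ``time_unit_s`` defaults to 1.7075 ps, the LAMMPS-oxDNA convention
    (mass unit 100 amu); the sqrt(m sigma^2/eps) bookkeeping reproduces it
    to ~0.1%.
    """

    length_unit_nm: float = 0.8518
    time_unit_s: float = 1.7075e-12
    boltzmann_pN_nm_per_K: float = BOLTZMANN_PN_NM_PER_K
    boltzmann_kcal_mol_per_K: float = BOLTZMANN_KCAL_MOL_PER_K

    def __post_init__(self) -> None:
        for name in ("length_unit_nm", "time_unit_s",
                     "boltzmann_pN_nm_per_K", "boltzmann_kcal_mol_per_K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def lj_to_seconds(self, t_lj: float) -> float:
        return t_lj * self.time_unit_s

    def seconds_to_lj(self, t_s: float) -> float:
        return t_s / self.time_unit_s


DEFAULT_UNITS = UnitSystem()


def contour_length(n_bp: int, rise_per_bp: float = 0.34) -> float:
    """Contour length L = n_bp * rise in nm (0.34 nm/bp B-DNA rise)."""
    if n_bp < 0:
        raise ValueError("n_bp must be non-negative")
    if rise_per_bp <= 0:
        raise ValueError("rise_per_bp must be positive")
    return n_bp * rise_per_bp


def marko_siggia_force(Ree: float, L: float, xi: float = 50.0,
                       T: float = 310.0) -> float:
    """Marko-Siggia WLC force (pN) holding extension ``Ree``.

    F = (kB T / xi) * [ 1/4 (1 - Ree/L)^-2 + Ree/L - 1/4 ]

    with all lengths in nm.  Valid for 0 <= Ree < L; diverges as the
    extension approaches the contour length.
    """
    if L <= 0 or xi <= 0 or T <= 0:
        raise ValueError("L, xi and T must be strictly positive")
    if Ree < 0:
        raise ValueError("Ree must be non-negative")
    if Ree >= L:
        raise ValueError("extension Ree must be below the contour length L")
    x = Ree / L
    kT = BOLTZMANN_PN_NM_PER_K * T
    return (kT / xi) * (0.25 * (1.0 - x) ** -2 + x - 0.25)


def wlc_extension_at_force(F: float, L: float, xi: float = 50.0,
                           T: float = 310.0) -> float:
    """Inverse of :func:`marko_siggia_force` by scalar root finding (nm).

    Convenience only; the analysis itself always works force-from-extension.
    """
    if F < 0:
        raise ValueError("force must be non-negative")
    if F == 0:
        return 0.0
    return brentq(lambda R: marko_siggia_force(R, L, xi, T) - F,
                  0.0, L * (1 - 1e-12), xtol=1e-12 * L)


def elongation_percent(Ree: float, L: float) -> float:
    """Fractional extension 100 * Ree / L."""
    if L <= 0:
        raise ValueError("L must be positive")
    if Ree < 0 or Ree > L:
        raise ValueError("Ree must lie in [0, L]")
    return 100.0 * Ree / L


@dataclass(frozen=True)
class ThermalEnergy:
    pN_nm: float
    kcal_mol: float


def thermal_energy(T: float,
                   units: UnitSystem = DEFAULT_UNITS) -> ThermalEnergy:
    """kB*T at temperature ``T`` (K), in pN nm and kcal/mol."""
    if T <= 0:
        raise ValueError("temperature must be strictly positive")
    return ThermalEnergy(pN_nm=units.boltzmann_pN_nm_per_K * T,
                         kcal_mol=units.boltzmann_kcal_mol_per_K * T)


def convert_time(t_lj: float, units: UnitSystem = DEFAULT_UNITS) -> float:
    """LJ time units -> seconds."""
    return units.lj_to_seconds(t_lj)


def convert_time_inverse(t_s: float,
                         units: UnitSystem = DEFAULT_UNITS) -> float:
    """Seconds -> LJ time units."""
    return units.seconds_to_lj(t_s)


@dataclass
class ScenarioConfig:
    """One double-strand-break scenario on the stretched filament.

    ``b_d`` is the DSB distance: the number of intact native base pairs
    between the two backbone nicks (0 = blunt break).  The axial force
    ``F_z`` is derived from the target end-to-end distance through the WLC
    unless given explicitly.  Salt is metadata (it parameterizes the
    force field, which is upstream of this analysis).
    """

    b_d: int = 0
    target_Ree: float = 1000.0
    n_bp: int = 3855
    rise_per_bp: float = 0.34
    persistence_length: float = 50.0
    temperature: float = 310.0
    salt_molar: float = 0.15
    F_z: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if not float(self.b_d).is_integer() or self.b_d < 0:
            raise ValueError("b_d must be a non-negative integer")
        self.b_d = int(self.b_d)
        L = self.contour_length
        if not 0 <= self.target_Ree < L:
            raise ValueError("target_Ree must satisfy 0 <= Ree < L")
        if self.F_z is None:
            self.F_z = marko_siggia_force(self.target_Ree, L,
                                          self.persistence_length,
                                          self.temperature)
        if self.F_z < 0:
            raise ValueError("F_z must be non-negative")

    @property
    def contour_length(self) -> float:
        return contour_length(self.n_bp, self.rise_per_bp)

    @property
    def elongation(self) -> float:
        return elongation_percent(self.target_Ree, self.contour_length)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["contour_length_nm"] = self.contour_length
        d["elongation_percent"] = self.elongation
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        keys = {"b_d", "target_Ree", "n_bp", "rise_per_bp",
                "persistence_length", "temperature", "salt_molar", "F_z"}
        return cls(**{k: v for k, v in d.items() if k in keys})
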