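"""Hydrogen-transfer energetics and TST rate constants with Wigner tunneling.

Reaction energetics are plain differences of total energies and of thermal
free-energy corrections between the reagent complex (R), the transition
structure (TS), and the product complex (P):

    dE_TS-R = E_TS - E_R            dG_TS-R = G_TS - G_R
    dE_COR  = dE_TS-R + dG_TS-R     dE_P-R  = E_P - E_R

(G here is the thermal correction to the free energy at 298.15 K, not the
full free energy: the corrected barrier is the electronic barrier plus the
difference of thermal corrections.)

The bimolecular rate constant follows conventional transition-state theory
with a Wigner tunneling factor:

    k(T) = I * (k_B T / h) * exp(-dE_COR / R T) * s * A(T)
    A(T) = 1 + (1/24) * (1.44 * nu_i / T)^2

where I is the pathway degeneracy, s converts the 1 atm standard state to
1 M (24.3 by convention), and nu_i is the magnitude of the TS imaginary
frequency in cm^-1.  The 1.44 coefficient is the conventional rounded
literal; the physical value hc/k_B = 1.4388 cm K is selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import (BOLTZMANN_J_PER_K, GAS_CONSTANT_KCAL, PLANCK_J_S,
                        STD_STATE_FACTOR, T_STANDARD, WIGNER_COEFF)
from .species import ReactionSystem, SpeciesRecord

__all__ = [
    "ReactionEnergetics",
    "RateResult",
    "activation_energy",
    "reaction_energy",
    "wigner_factor",
    "rate_constant",
    "system_rate",
    "radical_addition_energy",
]


@dataclass
class ReactionEnergetics:
    """Barrier and reaction energies of one pathway, kcal/mol."""

    de_ts_r: float
    dg_ts_r: float
    de_ts_r_cor: float
    de_p_r: float | None = None
    de_ts_p: float | None = None
    dg_p_r: float | None = None
    de_p_r_cor: float | None = None

    def __post_init__(self) -> None:
        if abs(self.de_ts_r_cor - (self.de_ts_r + self.dg_ts_r)) > 1e-9:
            raise ValueError("de_ts_r_cor != de_ts_r + dg_ts_r")
        if None not in (self.de_p_r, self.de_ts_p):
            if abs(self.de_ts_p - (self.de_ts_r - self.de_p_r)) > 1e-9:
                raise ValueError("de_ts_p != de_ts_r - de_p_r")


@dataclass
class RateResult:
    """One TST rate evaluation."""

    rate: float  # M^-1 s^-1
    tunneling_factor: float
    temperature: float
    degeneracy: int = 1
    std_state_factor: float = STD_STATE_FACTOR
    provenance: str | None = None  # e.g. hybrid-level recipes

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if self.tunneling_factor < 1:
            raise ValueError("tunneling factor must be >= 1")


def activation_energy(reagents: SpeciesRecord, ts: SpeciesRecord) -> dict:
    """Electronic barrier, thermal free-energy correction difference, and
    the corrected barrier, as ``{"de_ts_r", "dg_ts_r", "de_ts_r_cor"}``."""
    reagents.require("g_corr")
    ts.require("g_corr")
    if (reagents.level, reagents.phase) != (ts.level, ts.phase):
        raise ValueError(
            f"{reagents.label!r} and {ts.label!r} mix levels/phases"
        )
    de = ts.energy - reagents.energy
    dg = ts.g_corr - reagents.g_corr
    return {"de_ts_r": de, "dg_ts_r": dg, "de_ts_r_cor": de + dg}


def reaction_energy(reagents: SpeciesRecord, products: SpeciesRecord,
                    ts: SpeciesRecord | None = None) -> dict:
    """Reaction energy E_P - E_R (and the TS-to-product drop when a TS is
    given); the corrected value requires g_corr on both ends."""
    de_p_r = products.energy - reagents.energy
    out: dict = {"de_p_r": de_p_r, "dg_p_r": None, "de_p_r_cor": None,
                 "de_ts_p": None}
    if reagents.g_corr is not None and products.g_corr is not None:
        out["dg_p_r"] = products.g_corr - reagents.g_corr
        out["de_p_r_cor"] = de_p_r + out["dg_p_r"]
    if ts is not None:
        out["de_ts_p"] = ts.energy - products.energy
    return out


def wigner_factor(nu_imag: float, temperature: float = T_STANDARD,
                  coefficient: float = WIGNER_COEFF) -> float:
    """Wigner tunneling factor 1 + (1/24) (c nu/T)^2, dimensionless.

    ``nu_imag`` is the magnitude of the imaginary frequency in cm^-1.
    """
    if nu_imag < 0:
        raise ValueError("imaginary-frequency magnitude must be >= 0")
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    return 1.0 + (coefficient * nu_imag / temperature) ** 2 / 24.0


def rate_constant(de_cor: float, nu_imag: float = 0.0,
                  temperature: float = T_STANDARD, degeneracy: int = 1,
                  std_state_factor: float = STD_STATE_FACTOR,
                  wigner_coefficient: float = WIGNER_COEFF,
                  provenance: str | None = None) -> RateResult:
    """Bimolecular TST rate constant with Wigner tunneling (M^-1 s^-1).

    ``de_cor`` is the corrected activation energy in kcal/mol; the
    prefactor k_B T / h is evaluated with the SI defining constants.
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    if degeneracy < 1:
        raise ValueError("degeneracy must be >= 1")
    if std_state_factor <= 0:
        raise ValueError("standard-state factor must be positive")
    a_t = wigner_factor(nu_imag, temperature, wigner_coefficient)
    prefactor = BOLTZMANN_J_PER_K * temperature / PLANCK_J_S
    rate = (degeneracy * prefactor
            * math.exp(-de_cor / (GAS_CONSTANT_KCAL * temperature))
            * std_state_factor * a_t)
    return RateResult(rate=rate, tunneling_factor=a_t, temperature=temperature,
                      degeneracy=degeneracy, std_state_factor=std_state_factor,
                      provenance=provenance)


def system_rate(system: ReactionSystem, temperature: float = T_STANDARD,
                std_state_factor: float = STD_STATE_FACTOR,
                wigner_coefficient: float = WIGNER_COEFF,
                energy_level: ReactionSystem | None = None) -> RateResult:
    """Rate constant of a reaction system.

    With ``energy_level`` given, electronic energies come from that system
    (e.g. large-basis single points) while the thermal free-energy
    corrections and the imaginary frequency are carried over from
    ``system`` — the hybrid recipe used for refined barriers; the result's
    ``provenance`` records the mix.
    """
    base = activation_energy(system.reagents, system.ts)
    provenance = None
    if energy_level is not None:
        de = energy_level.ts.energy - energy_level.reagents.energy
        de_cor = de + base["dg_ts_r"]
        provenance = (f"dE from level {energy_level.ts.level}/"
                      f"{energy_level.ts.phase}; dG_TS-R and nu_i from level "
                      f"{system.ts.level}/{system.ts.phase}")
    else:
        de_cor = base["de_ts_r_cor"]
    return rate_constant(de_cor, system.ts.nu_imag, temperature,
                         system.degeneracy, std_state_factor,
                         wigner_coefficient, provenance)


def radical_addition_energy(pair: SpeciesRecord, adduct: SpeciesRecord,
                            g_available: bool = False) -> dict:
    """Energy of radical addition to an antioxidant radical.

    ``pair`` is the separated-pair (or pre-complex) reference; returns
    ``{"de_p_r", "de_p_r_cor"}``, the corrected value only when requested
    and free-energy corrections are present on both records.
    """
    de = adduct.energy - pair.energy
    out = {"de_p_r": de, "de_p_r_cor": None}
    if g_available:
        pair.require("g_corr")
        adduct.require("g_corr")
        out["de_p_r_cor"] = de + (adduct.g_corr - pair.g_corr)
    return out
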