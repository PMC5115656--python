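"""Physical constants and unit conversion registry.

All energies inside the package are kcal/mol; every other unit is defined by
its kcal/mol equivalent so that chained conversions compose exactly.
"""

from __future__ import annotations

# SI defining constants (2019 redefinition)
BOLTZMANN_J_PER_K = 1.380649e-23
PLANCK_J_S = 6.62607015e-34

# Gas constant in kcal/(mol K)
GAS_CONSTANT_KCAL = 1.98720425e-3

# Default thermodynamic temperature, K
T_STANDARD = 298.15

# Energy units expressed in kcal/mol.  eV is derived from hartree via the
# CODATA hartree->eV factor so that hartree->eV->kcal/mol composes exactly
# with the direct hartree->kcal/mol conversion.
HARTREE_TO_KCAL = 627.509474
HARTREE_TO_EV = 27.211386245988
KCAL_PER_UNIT: dict[str, float] = {
    "kcal_per_mol": 1.0,
    "hartree": HARTREE_TO_KCAL,
    "kJ_per_mol": 1.0 / 4.184,
    "eV": HARTREE_TO_KCAL / HARTREE_TO_EV,
}

# Standard-state conversion for bimolecular rates: 1 atm -> 1 M reference.
# 24.3 is the conventional rounded multiplier; the ideal-gas molar volume at
# 298.15 K (L/mol) is available for callers who prefer the physical value.
STD_STATE_FACTOR = 24.3
STD_STATE_FACTOR_IDEAL_GAS = 24.465

# Wigner tunneling coefficient (cm K): the conventional rounded literal.  The
# physical value hc/k_B = 1.4388 cm K is provided for callers who want it.
WIGNER_COEFF = 1.44
WIGNER_COEFF_PHYSICAL = 1.4388


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy between the registered units.

    Parameters
    ----------
    value : float
        Energy in ``from_unit``.
    from_unit, to_unit : str
        One of ``kcal_per_mol``, ``hartree``, ``kJ_per_mol``, ``eV``.
    """
    try:
        f = KCAL_PER_UNIT[from_unit]
    except KeyError:
        raise ValueError(f"unknown energy unit: {from_unit!r}") from None
    try:
        t = KCAL_PER_UNIT[to_unit]
    except KeyError:
        raise ValueError(f"unknown energy unit: {to_unit!r}") from None
    if from_unit == to_unit:
        return value
    return value * (f / t)
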