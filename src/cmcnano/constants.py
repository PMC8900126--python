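"""Physical constants and mass bookkeeping for substituted-cellulose monomers.

Atomic masses are CODATA-style standard atomic weights (g/mol). Substituent
mass increments are written as "group added minus hydroxyl hydrogen removed"
so that a monomer mass is the anhydroglucose base plus one increment per
substituted ring position.
"""

from __future__ import annotations

# Standard atomic weights, g/mol
M_H = 1.008
M_C = 12.011
M_N = 14.007
M_O = 15.999
M_NA = 22.990

#: Anhydroglucose repeat unit C6H10O5
M_ANHYDROGLUCOSE = 6 * M_C + 10 * M_H + 5 * M_O

#: Carboxymethyl increment, sodium-salt convention: -O-H -> -O-CH2-COO(-)Na(+)
CM_INCREMENT_SODIUM_SALT = (2 * M_C + 2 * M_H + 2 * M_O + M_NA) - M_H

#: Carboxymethyl increment, free-acid convention: -O-H -> -O-CH2-COOH
CM_INCREMENT_FREE_ACID = (2 * M_C + 3 * M_H + 2 * M_O) - M_H

#: N-octyl amide of carboxymethyl: -O-H -> -O-CH2-C(=O)-NH-C8H17
#: (uncharged; identical under both conventions)
CM8_INCREMENT = (10 * M_C + 20 * M_H + M_O + M_N) - M_H

MASS_CONVENTIONS = ("sodium_salt", "free_acid")

#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23

#: Coulomb prefactor e/(4*pi*eps0) expressed in V*nm per elementary charge,
#: so that a unit charge at 1 nm in eps_r=80 (unscreened) gives ~18 mV.
COULOMB_V_NM = 1.439964

#: Debye length prefactor at 298 K for a 1:1 electrolyte: lambda_D [nm] =
#: DEBYE_PREFACTOR_NM / sqrt(I [mol/L]).
DEBYE_PREFACTOR_NM = 0.304


def cm_increment(mass_convention: str) -> float:
    """Mass increment (g/mol) of one charged carboxymethyl group."""
    if mass_convention == "sodium_salt":
        return CM_INCREMENT_SODIUM_SALT
    if mass_convention == "free_acid":
        return CM_INCREMENT_FREE_ACID
    raise ValueError(
        f"unknown mass convention {mass_convention!r}; "
        f"expected one of {MASS_CONVENTIONS}"
    )
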