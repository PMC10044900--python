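"""Solution composition: sulfate speciation, ionic strength, pH, and the
ionic-strength correction of rate constants.

The standard Fricke medium is 1 mM FeSO4 in aqueous 0.4 M H2SO4, air
saturated ([O2] ~ 2.5e-4 M), optionally with cystamine (10^-6 to 1 M).
The first dissociation of H2SO4 is taken as complete; the second,
HSO4- <-> H+ + SO42-, is governed by a configurable equilibrium constant
(default 1.0e-2 M).  Counter-ions (the sulfate of FeSO4, cystamine's
chloride) are inert spectators that contribute to the ionic strength only.

Two distinct quantities are exposed:

* the *concentration* speciation, with exact sulfate mass balance and
  charge balance — this is what the kinetics uses;
* the reported *pH*, computed from the H+ activity with a WATEQ-style
  extended Debye–Hückel single-ion activity coefficient, which is what a
  pH measurement of 0.4 M H2SO4 (~0.46) corresponds to.  With complete
  first dissociation, -log10[H+] could never exceed ~0.40.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = ["MediumComposition", "speciate_medium", "corrected_rate",
           "AERATED_O2_M", "standard_fricke_medium"]

#: air-saturated dissolved oxygen concentration (M)
AERATED_O2_M = 2.5e-4

# WATEQ Debye-Huckel parameters for H+ at 25 C
_DH_A = 0.5092          # (M^-1/2)
_DH_B = 0.3283          # (1/(Angstrom sqrt(M)))
_H_ION_SIZE = 4.78      # Angstrom
_H_B_DOT = 0.24         # linear coefficient

_KW = 1.0e-14           # water autoprotolysis at 25 C


@dataclass(frozen=True)
class MediumComposition:
    """Analytic composition plus (after :func:`speciate_medium`) derived
    speciation.  All concentrations in mol/L at 25 C."""

    h2so4: float = 0.4
    fe2: float = 1.0e-3
    o2: float = AERATED_O2_M
    cystamine: float = 0.0
    ka2: float = 1.0e-2      #: second dissociation constant of H2SO4 (M)
    temperature_c: float = 25.0

    # derived (filled by speciate_medium)
    h_plus: float | None = None
    hso4: float | None = None
    so4: float | None = None
    ionic_strength: float | None = None
    ph: float | None = None

    @property
    def aerated(self) -> bool:
        return self.o2 > 0

    def concentrations(self) -> dict[str, float]:
        """Background reservoir concentrations keyed by species name."""
        if self.h_plus is None:
            raise ValueError("call speciate_medium() first")
        return {
            "H+": self.h_plus,
            "HSO4-": self.hso4 or 0.0,
            "SO42-": self.so4 or 0.0,
            "Fe2+": self.fe2,
            "O2": self.o2,
            "RSSR": self.cystamine,
        }


def standard_fricke_medium(cystamine: float = 0.0, aerated: bool = True,
                           **kw) -> MediumComposition:
    """The paper's standard medium: 0.4 M H2SO4, 1 mM Fe2+, O2 per aeration."""
    return speciate_medium(MediumComposition(
        o2=AERATED_O2_M if aerated else 0.0, cystamine=cystamine, **kw))


def _activity_coefficient_h(ionic_strength: float) -> float:
    """WATEQ extended Debye-Huckel single-ion activity coefficient for H+."""
    if ionic_strength <= 0:
        return 1.0
    s = math.sqrt(ionic_strength)
    log10_gamma = (-_DH_A * s / (1.0 + _DH_B * _H_ION_SIZE * s)
                   + _H_B_DOT * ionic_strength)
    return 10.0 ** log10_gamma


def speciate_medium(m: MediumComposition) -> MediumComposition:
    """Fill in [H+], [HSO4-], [SO42-], ionic strength and pH.

    Sulfate mass balance ([HSO4-]+[SO42-] = analytic H2SO4) and charge
    balance hold exactly; spectator counter-ions (FeSO4 sulfate, cystamine
    chloride) enter the ionic strength only.
    """
    for name in ("h2so4", "fe2", "o2", "cystamine"):
        if getattr(m, name) < 0:
            raise ValueError(f"negative concentration: {name}")

    c = m.h2so4
    if c == 0.0:
        h = math.sqrt(_KW)       # neutral water
        x = 0.0
    elif math.isinf(m.ka2):
        x = c                    # fully dissociated limit
        h = 2.0 * c
    else:
        # HSO4- <-> H+ + SO42- with [H+] = c + x, [SO42-] = x, [HSO4-] = c - x
        ka = m.ka2
        x = 0.5 * (-(c + ka) + math.sqrt((c + ka) ** 2 + 4.0 * ka * c))
        h = c + x
    hso4 = c - x
    so4 = x

    # ionic strength: acid speciation + FeSO4 (Fe2+ and its spectator SO42-)
    # + doubly protonated cystamine with two monovalent counter-ions
    ionic = 0.5 * (h * 1 + hso4 * 1 + so4 * 4
                   + m.fe2 * 4 + m.fe2 * 4
                   + m.cystamine * 4 + 2 * m.cystamine * 1)
    gamma = _activity_coefficient_h(ionic)
    ph = -math.log10(gamma * h)
    return replace(m, h_plus=h, hso4=hso4, so4=so4, ionic_strength=ionic, ph=ph)


def corrected_rate(k0: float, z_a: int, z_b: int, ionic_strength: float,
                   exempt: bool = False) -> float:
    """Brønsted–Bjerrum ionic-strength correction of a bimolecular rate.

    k = k0 * 10^(1.02 * zA * zB * sqrt(I) / (1 + sqrt(I))) at 25 C.
    Uncharged partners (zA*zB = 0), I = 0, or an exemption flag (the
    e-aq self-recombination, for which no ionic-strength effect is seen)
    leave k0 unchanged.
    """
    if ionic_strength < 0:
        raise ValueError("negative ionic strength")
    if exempt or z_a * z_b == 0 or ionic_strength == 0:
        return k0
    s = math.sqrt(ionic_strength)
    return k0 * 10.0 ** (1.02 * z_a * z_b * s / (1.0 + s))
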