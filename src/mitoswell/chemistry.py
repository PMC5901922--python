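"""Matrix solution chemistry: weak-acid equilibrium, ionic strength,
Debye-Hueckel activity coefficients and pH bookkeeping.

Dissociation equilibria are treated as instantaneous (much faster than
membrane transport) and recomputed from state rather than integrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import AcidParams, PhysicalConstants

__all__ = [
    "AcidParams", "IonicMixture", "weak_acid_h", "ionic_strength",
    "activity_coefficient", "activity", "ph_from_activity", "anion_fraction",
]


@dataclass
class IonicMixture:
    """A list of (label, charge, concentration-uM) triples."""

    species: list[tuple[str, int, float]] = field(default_factory=list)

    def add(self, label: str, charge: int, conc_uM: float) -> None:
        if conc_uM < 0:
            raise ValueError("concentrations must be >= 0")
        self.species.append((label, charge, conc_uM))

    @property
    def ionic_strength_uM(self) -> float:
        return ionic_strength(self)

    def activity_coefficients(
            self, constants: PhysicalConstants) -> dict[str, float]:
        i = self.ionic_strength_uM
        return {label: activity_coefficient(z, i, constants)
                for label, z, _ in self.species}


def weak_acid_h(params: AcidParams) -> float:
    """Free H+ (= A-) concentration (uM) of the weak-acid equilibrium.

    Solves the mass-action quadratic for AH <-> A- + H+ with total acid
    ``c_ah0`` and a background H+ source ``c_h_background``:

        C_H = 1/2 * { sqrt((K + C_bg)^2 + 4*K*C_AH0) - (K + C_bg) }

    which reduces to the zero-background form when C_bg = 0.
    """
    k = params.k_ahh_uM
    c0 = params.c_ah0
    cbg = params.c_h_background
    if c0 < 0 or cbg < 0:
        raise ValueError("acid concentrations must be >= 0")
    s = k + cbg
    return 0.5 * (math.sqrt(s * s + 4.0 * k * c0) - s)


def ionic_strength(mixture: IonicMixture) -> float:
    """I = 1/2 * sum(C_i * z_i^2), in uM."""
    return 0.5 * sum(c * z * z for _, z, c in mixture.species)


def activity_coefficient(z: int, ionic_strength_uM: float,
                         constants: PhysicalConstants) -> float:
    """Debye-Hueckel limiting-law activity coefficient.

    ln(gamma) = -z^2 * e^2 * kappa_D / (8*pi*eps*eps0*kB*T), with the Debye
    wavenumber kappa_D = sqrt(2*N_A*e^2*I/(eps*eps0*kB*T)) and I in mol/m^3.
    Returns 1 at I = 0; monotone decreasing in I and |z|.
    """
    if ionic_strength_uM < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength_uM == 0 or z == 0:
        return 1.0
    e = constants.electron_charge_abs
    eps = constants.water_rel_permittivity * constants.vacuum_permittivity
    kbt = constants.boltzmann_k * constants.temperature
    i_si = ionic_strength_uM * 1e-3  # uM -> mol/m^3
    kappa = math.sqrt(2.0 * constants.avogadro * e * e * i_si / (eps * kbt))
    ln_gamma = -z * z * e * e * kappa / (8.0 * math.pi * eps * kbt)
    return math.exp(ln_gamma)


def activity(gamma: float, c: float) -> float:
    """a = gamma * C."""
    if gamma < 0 or c < 0:
        raise ValueError("inputs must be >= 0")
    return gamma * c


def ph_from_activity(a_h_uM: float) -> float:
    """pH = -log10 of the molar H+ activity; input in uM."""
    if a_h_uM <= 0:
        raise ValueError("H+ activity must be positive")
    return -math.log10(a_h_uM * 1e-6)


def anion_fraction(a_h_uM: float, k_ahh_uM: float) -> float:
    """Dissociated fraction A-/(A- + AH) at free-H+ activity ``a_h_uM``."""
    if a_h_uM < 0:
        raise ValueError("H+ activity must be >= 0")
    return k_ahh_uM / (k_ahh_uM + a_h_uM)
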