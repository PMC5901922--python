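"""Trans-IMM flux laws: GHK electrodiffusion, neutral diffusion, K+/H+
exchange, PTP electrodiffusion, and Poiseuille hydrodynamic efflux.

Sign convention: every flux returned here is the NET INFLUX into the matrix
(positive = species entering).  The source literature writes fluxes as
J = J_out - J_in but sums them into matrix growth equations; the influx
convention is the one consistent with matrix concentrations rising when the
cytosol supplies ions, and is used throughout derivative assembly.

Fluxes are first-order in activity with effective permeabilities in min^-1,
so their working unit is uM/min of matrix concentration change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import GeometryParams, IonSpec, PhysicalConstants

#: |u| below which the removable singularity of the constant-field factor is
#: evaluated by series instead of u/expm1(u).
SMALL_U_THRESHOLD = 1e-4


@dataclass(frozen=True)
class FluxResult:
    """A single pathway's net influx into the matrix (uM/min)."""

    species: str
    value: float


def _field_factor(u: float) -> float:
    """u/(e^u - 1), the constant-field rectification factor; 1 at u = 0."""
    if abs(u) < SMALL_U_THRESHOLD:
        # 2nd-order Taylor expansion around the removable singularity.
        return 1.0 - u / 2.0 + u * u / 12.0
    return u / math.expm1(u)


def ghk_flux(spec: IonSpec, dpsi: float, c_in: float, c_out: float,
             constants: PhysicalConstants, p_eff: float | None = None,
             pathway: str = "uniport") -> FluxResult:
    """Constant-field (GHK) electrodiffusive net influx of an ionic species.

    Parameters
    ----------
    dpsi : membrane potential in mV, positive = matrix-negative (energized).
    c_in, c_out : matrix / cytosolic activities (uM).
    p_eff : effective permeability (min^-1); defaults to ``spec.p_uniport``
        taken as already normalized.

    The flux is ``p * (c_out - c_in*exp(u)) * u/(expm1(u))`` with
    ``u = -z*dpsi/V_T``; its ``dpsi -> 0`` limit is Fick's law
    ``p*(c_out - c_in)`` (influx-positive).  For ``|u|`` below
    :data:`SMALL_U_THRESHOLD` a series expansion avoids the 0/0.
    """
    if spec.charge_z == 0:
        raise ValueError("ghk_flux requires a charged species; "
                         "use neutral_flux for z = 0")
    if c_in < 0 or c_out < 0:
        raise ValueError("activities must be >= 0")
    p = spec.p_uniport if p_eff is None else p_eff
    u = -spec.charge_z * dpsi / constants.thermal_voltage_mV
    # exp(u) can overflow for strongly reversed potentials; the flux then
    # saturates at pure voltage-driven efflux of the matrix content.
    if u > 700.0:
        value = -p * c_in * u
    else:
        value = p * (c_out - c_in * math.exp(u)) * _field_factor(u)
    return FluxResult(species=spec.name, value=value)


def neutral_flux(p0: float, c_in: float, c_out: float,
                 species: str = "neutral") -> FluxResult:
    """Fick diffusion of a neutral species: influx = p0*(c_out - c_in)."""
    if p0 < 0:
        raise ValueError("p0 must be >= 0")
    return FluxResult(species=species, value=p0 * (c_out - c_in))


def kh_exchange_fluxes(dpsi: float, c_k_in: float, c_k_out: float,
                       c_h_in: float, c_h_out: float,
                       p_k_h0: float, p_h_k0: float,
                       constants: PhysicalConstants) -> tuple[FluxResult, FluxResult]:
    """K+/H+ exchanger fluxes: two GHK fluxes with gradient-scaled permeability.

    The effective permeabilities depend linearly on the counter-ion gradient:
    p_K,H = p_K,H0 * |c_H_out - c_H_in| (per uM of H+ gradient) and
    p_H,K = p_H,K0 * |c_K_out - c_K_in| (per mM of K+ gradient).
    """
    for c in (c_k_in, c_k_out, c_h_in, c_h_out):
        if c < 0:
            raise ValueError("activities must be >= 0")
    p_kh = p_k_h0 * abs(c_h_out - c_h_in)            # gradient in uM
    p_hk = p_h_k0 * abs(c_k_out - c_k_in) * 1e-3     # gradient in mM
    k_spec = IonSpec(name="k", charge_z=1)
    h_spec = IonSpec(name="h", charge_z=1)
    jk = ghk_flux(k_spec, dpsi, c_k_in, c_k_out, constants, p_eff=p_kh)
    jh = ghk_flux(h_spec, dpsi, c_h_in, c_h_out, constants, p_eff=p_hk)
    return jk, jh


def ptp_ion_flux(spec: IonSpec, p_ptp_open: float, n_ptp: int, dpsi: float,
                 c_in: float, c_out: float, constants: PhysicalConstants,
                 p_eff: float | None = None) -> FluxResult:
    """GHK flux through open PTPs: the single-pore flux scaled by P_open*n."""
    if not 0.0 <= p_ptp_open <= 1.0:
        raise ValueError("p_ptp_open must lie in [0, 1]")
    p = spec.p_ptp if p_eff is None else p_eff
    if p_ptp_open == 0.0 or p == 0.0:
        return FluxResult(species=spec.name, value=0.0)
    return ghk_flux(spec, dpsi, c_in, c_out, constants,
                    p_eff=p * p_ptp_open * n_ptp, pathway="ptp")


def ptp_depolarized_flux(spec: IonSpec, p_ptp_open: float, n_ptp: int,
                         c_in: float, c_out: float,
                         p0_eff: float | None = None) -> FluxResult:
    """Thermal (zero-field) diffusion through PTPs of a depolarized IMM.

    Influx = p0 * P_open * n * (c_out - c_in).  Off by default in the
    simulator (the electrodiffusive and hydrodynamic pathways dominate).
    """
    if not 0.0 <= p_ptp_open <= 1.0:
        raise ValueError("p_ptp_open must lie in [0, 1]")
    p0 = spec.p_neutral if p0_eff is None else p0_eff
    return FluxResult(species=spec.name,
                      value=p0 * p_ptp_open * n_ptp * (c_out - c_in))


def poiseuille_volume_flux(geometry: GeometryParams, p_ptp_open: float,
                           dp_imm: float) -> float:
    """Poiseuille volume efflux (m^3/s) through one open pore.

    J0 = pi*r^4*dP/(8*eta*l) with effective radius r = r0*sqrt(P_open) and
    l the IMM thickness.  Zero for closed pores or zero pressure.
    """
    if geometry.matrix_viscosity <= 0:
        raise ValueError("viscosity must be positive")
    if not 0.0 <= p_ptp_open <= 1.0:
        raise ValueError("p_ptp_open must lie in [0, 1]")
    if not math.isfinite(dp_imm):
        raise ValueError("dp_imm must be finite")
    r4 = (geometry.pore_radius_r0 ** 4) * (p_ptp_open ** 2)
    return (math.pi * r4 * dp_imm
            / (8.0 * geometry.matrix_viscosity * geometry.imm_thickness_h))


def hydrodynamic_species_efflux(j0: float, a_i: float, n_ptp: float,
                                species: str = "species") -> FluxResult:
    """Advective efflux of a species carried by the Poiseuille flow.

    ``j0`` is a volumetric turnover rate (fraction of matrix volume per
    minute); the species leaves in proportion to its matrix activity, so the
    result is the net influx -j0*a_i*n (uM/min).
    """
    if a_i < 0:
        raise ValueError("activity must be >= 0")
    return FluxResult(species=species, value=-j0 * a_i * n_ptp)
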