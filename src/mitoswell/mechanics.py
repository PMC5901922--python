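"""Membrane mechanics: osmotic pressure, prolate-spheroid geometry,
deformation-softening rigidity, quasi-static pressure balance, and the
simplified spherical relaxation model.

The matrix is a prolate spheroid with semi-axes a < c.  Osmotic pressure
excess inflates it; the IMM's elastic restoring pressure balances the
inflation quasi-statically (water equilibration is much faster than ion
transport).  The rigidity tensor components soften with deformation and
vanish at a critical strain — the +50 % volume point — beyond which the
membrane yields and swelling becomes irreversible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .config import GeometryParams, PhysicalConstants, RigidityParams


@dataclass(frozen=True)
class Deformation:
    """Axisymmetric semi-axis displacements (m); dy is slaved to dx."""

    dx: float
    dz: float

    @property
    def dy(self) -> float:
        return self.dx


@dataclass(frozen=True)
class MechanicalState:
    deformation: Deformation
    s_m: float            # m^2
    v_m: float            # m^3
    dp_os: float          # Pa
    dp_imm: float         # Pa
    rigidity_xx: float    # N/m (softened, pressure-scale applied)
    rigidity_zz: float    # N/m
    irreversible: bool


def osmotic_pressure(activities_in, activities_out,
                     constants: PhysicalConstants) -> float:
    """van 't Hoff osmotic pressure RT*sum(a_in - a_out), activities in uM,
    result in Pa.  Species lists must be aligned."""
    a_in = np.asarray(activities_in, dtype=float)
    a_out = np.asarray(activities_out, dtype=float)
    if a_in.shape != a_out.shape:
        raise ValueError("activity lists must be aligned by species")
    return float(constants.rt_pa_per_uM * np.sum(a_in - a_out))


def ellipsoid_surface_area(geom: GeometryParams, d: Deformation) -> float:
    """Surface area of the deformed prolate spheroid.

    S = 2*pi*ae^2 * (1 + (ce/(ae*f))*arcsin(f)), f = sqrt(1-(ae/ce)^2),
    with ae = a+dx, ce = c+dz.  Continuous in the sphere limit ae -> ce
    (arcsin(f)/f -> 1, S -> 4*pi*ae^2) via a series branch.
    """
    ae = geom.semi_a + d.dx
    ce = geom.semi_c + d.dz
    if ae <= 0 or ce <= 0:
        raise ValueError("deformed semi-axes must be positive")
    if ae > ce:
        raise ValueError(
            "oblate branch (a+dx > c+dz) not supported; the prolate formula "
            "requires a+dx < c+dz — use the spherical model for oblate shapes")
    f2 = 1.0 - (ae / ce) ** 2
    if f2 < 1e-12:
        # sphere limit: arcsin(f)/f = 1 + f^2/6 + 3f^4/40 + ...
        ratio = 1.0 + f2 / 6.0 + 3.0 * f2 * f2 / 40.0
        return 2.0 * math.pi * ae * ae * (1.0 + (ce / ae) * ratio)
    f = math.sqrt(f2)
    return 2.0 * math.pi * ae * ae * (1.0 + (ce / (ae * f)) * math.asin(f))


def ellipsoid_volume(geom: GeometryParams, d: Deformation) -> float:
    """V = (4/3)*pi*(a+dx)^2*(c+dz)."""
    ae = geom.semi_a + d.dx
    ce = geom.semi_c + d.dz
    if ae <= 0 or ce <= 0:
        raise ValueError("deformed semi-axes must be positive")
    return 4.0 / 3.0 * math.pi * ae * ae * ce


def rigidity_component(delta: float, g_base: float, beta: float,
                       n1: float) -> float:
    """Softening rigidity g = g_base*(1 - beta*delta^n1)/(1 + beta*delta^n1),
    floored at 0 once the component crosses zero (it vanishes, it does not
    invert).  ``delta`` >= 0 in the same length units beta is quoted in."""
    if delta < 0:
        raise ValueError("deformation must be >= 0")
    w = beta * delta ** n1
    if w >= 1.0:
        return 0.0
    return g_base * (1.0 - w) / (1.0 + w)


def membrane_pressure(d: Deformation, rigidity_xx: float, rigidity_zz: float,
                      s_m: float) -> float:
    """Restoring pressure of the deformed IMM:
    (g'xx*dx + g'yy*dy + g'zz*dz)/S_m with g'yy = g'xx."""
    if s_m <= 0:
        raise ValueError("membrane area must be positive")
    return (2.0 * rigidity_xx * d.dx + rigidity_zz * d.dz) / s_m


class MechanicsModel:
    """Quasi-static affine-deformation solver for one parameterization.

    The scalar pressure balance dP_os = dP_IMM is closed by shape-preserving
    scaling dx/a = dz/c = s.  The supportable pressure dP_IMM(s) rises from 0,
    peaks, and falls to 0 at the critical strain; pressures above the peak
    have no balancing root and the membrane yields (irreversible latch).
    """

    def __init__(self, geom: GeometryParams, rig: RigidityParams,
                 pressure_scale: float = 1.0):
        self.geom = geom
        self.rig = rig
        self.pressure_scale = pressure_scale
        if rig.recalibrate_beta:
            # anchor softening so components vanish exactly at crit_strain
            self._beta_x = (rig.crit_strain * geom.semi_a) ** (-rig.n1)
            self._beta_z = (rig.crit_strain * geom.semi_c) ** (-rig.n1)
            self._len_scale = 1.0           # deltas in meters
        else:
            self._beta_x = rig.beta0
            self._beta_z = rig.betaz
            self._len_scale = 1e9           # table betas are per nm^n1
        grid = np.linspace(0.0, rig.crit_strain, 512)
        vals = np.array([self._pressure_at(s) for s in grid])
        k = int(np.argmax(vals))
        self.max_pressure = float(vals[k])
        self.strain_at_max = float(grid[k])

    def _rigidities(self, s: float) -> tuple[float, float]:
        dx = s * self.geom.semi_a * self._len_scale
        dz = s * self.geom.semi_c * self._len_scale
        gxx = rigidity_component(dx, self.rig.g00_si, self._beta_x, self.rig.n1)
        gzz = rigidity_component(dz, self.rig.gzz0_si, self._beta_z, self.rig.n1)
        return gxx * self.pressure_scale, gzz * self.pressure_scale

    def _pressure_at(self, s: float) -> float:
        if s <= 0:
            return 0.0
        d = Deformation(dx=s * self.geom.semi_a, dz=s * self.geom.semi_c)
        gxx, gzz = self._rigidities(s)
        return membrane_pressure(d, gxx, gzz, ellipsoid_surface_area(self.geom, d))

    def state_at_strain(self, s: float, dp_os: float, dp_imm: float,
                        irreversible: bool) -> MechanicalState:
        d = Deformation(dx=s * self.geom.semi_a, dz=s * self.geom.semi_c)
        gxx, gzz = (0.0, 0.0) if irreversible else self._rigidities(s)
        return MechanicalState(
            deformation=d,
            s_m=ellipsoid_surface_area(self.geom, d),
            v_m=ellipsoid_volume(self.geom, d),
            dp_os=dp_os, dp_imm=dp_imm,
            rigidity_xx=gxx, rigidity_zz=gzz,
            irreversible=irreversible)

    def solve(self, dp_os: float, latched: bool = False) -> MechanicalState:
        """Balance dP_os against the membrane; latch once yielded."""
        crit = self.rig.crit_strain
        if latched:
            # yielded membrane: no restoring pressure, volume at the ceiling
            return self.state_at_strain(crit, dp_os, 0.0, True)
        if dp_os <= 0.0:
            return self.state_at_strain(0.0, dp_os, 0.0, False)
        if dp_os >= self.max_pressure:
            return self.state_at_strain(crit, dp_os, 0.0, True)
        try:
            s = brentq(lambda x: self._pressure_at(x) - dp_os,
                       0.0, self.strain_at_max, xtol=1e-14, rtol=1e-12)
        except ValueError as exc:  # pragma: no cover - bracketing guaranteed
            raise RuntimeError(
                f"pressure balance failed to converge at dp_os={dp_os!r} "
                f"(max supportable {self.max_pressure!r})") from exc
        return self.state_at_strain(float(s), dp_os, dp_os, False)


def solve_deformation(dp_os: float, geom: GeometryParams, rig: RigidityParams,
                      pressure_scale: float = 1.0,
                      latched: bool = False) -> MechanicalState:
    """One-shot quasi-static balance (see :class:`MechanicsModel`)."""
    return MechanicsModel(geom, rig, pressure_scale).solve(dp_os, latched)


@dataclass(frozen=True)
class SphericalRigidityParams:
    """Parameters of the simplified spherical relaxation model."""

    eta_w: float       # volume rate per unit pressure
    kappa0: float      # 1/time linear rigidity coefficient
    gamma_soft: float = 0.0   # 1/volume^m
    m_soft: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa0 < 0 or self.eta_w < 0 or self.gamma_soft < 0:
            raise ValueError("spherical-model coefficients must be >= 0")


def spherical_volume_rate(dp_os: float, dv: float,
                          p: SphericalRigidityParams) -> float:
    """dV/dt = eta*dP_os - kappa(dV)*dV with softening
    kappa = kappa0*(1 - gamma*dV^m)/(1 + gamma*dV^m), floored at 0.

    With gamma = 0 this is the linear relaxation law whose constant-pressure
    solution is V(t) = (eta/kappa0)*dP_os*(1 - exp(-kappa0*t))."""
    if dv < 0:
        raise ValueError("dv must be >= 0")
    w = p.gamma_soft * dv ** p.m_soft
    kappa = 0.0 if w >= 1.0 else p.kappa0 * (1.0 - w) / (1.0 + w)
    return p.eta_w * dp_os - kappa * dv
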