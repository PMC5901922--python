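"""Model parameterization: physical constants, membrane/transport parameters,
initial conditions, unit normalization, and the 2 x 10 experiment grid.

The parameter set mirrors the published tables for this model family:
"reduced" permeabilities for the Ca2+ uniporter, the K+/H+ exchanger and the
permeability transition pore (PTP), the pH-gating constants (alpha, n), the
respiration-activator kinetics, and the inner-membrane (IMM) rigidity tensor
constants. Source values are quoted in a mixed practical/CGS unit system with
a per-(mg protein) normalization that cannot be mapped onto SI dimensions;
internally everything is converted once, at load time, into the working unit
system

    time        minutes
    potential   millivolts
    amount      micromolar (per unit matrix volume)
    length      meters (geometry/mechanics)
    pressure    pascals

via the per-parameter factors in :data:`UNIT_CONVERSIONS`.  The overall flux
normalization (the "(mg protein)^-1" protein-mass factor) is a calibration
constant of the model; see docs/methods.md for how the defaults were fixed.
"""

from __future__ import annotations

import json
import math
import tomllib
from pathlib import Path
from typing import Iterator

from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class ConfigurationError(ValueError):
    """A config file is missing a key or holds an unusable value."""


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class PhysicalConstants(_Frozen):
    """Fundamental constants plus the (fixed per run) temperature.

    All values SI.  ``water_rel_permittivity`` enters only the Debye-Hueckel
    activity correction; 74.0 is the static permittivity of water near 310 K.
    """

    boltzmann_k: float = 1.380649e-23          # J/K
    electron_charge_abs: float = 1.602176634e-19  # C
    faraday: float = 96485.33212               # C/mol
    avogadro: float = 6.02214076e23            # 1/mol
    vacuum_permittivity: float = 8.8541878128e-12  # F/m
    water_rel_permittivity: float = 74.0
    temperature: float = 310.0                 # K

    @field_validator("*")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("physical constants must be strictly positive")
        return v

    @property
    def thermal_voltage_mV(self) -> float:
        """kB*T/|e| in millivolts (~26.71 mV at 310 K)."""
        return self.boltzmann_k * self.temperature / self.electron_charge_abs * 1e3

    @property
    def rt_pa_per_uM(self) -> float:
        """van 't Hoff factor R*T expressed as Pa per micromolar."""
        return self.boltzmann_k * self.temperature * self.avogadro * 1e-3


class IonSpec(_Frozen):
    """One transported species: charge and its reduced permeabilities.

    ``p_uniport`` and ``p_ptp`` are quoted in the source table's reduced
    units; they are multiplied by the pathway normalization factors of
    :class:`Normalization` to become first-order rates (min^-1).
    ``p_neutral`` is the zero-potential diffusion coefficient used for
    neutral species only.
    """

    name: str
    charge_z: int
    p_uniport: float = 0.0
    p_ptp: float = 0.0
    p_neutral: float = 0.0

    @field_validator("charge_z")
    @classmethod
    def _z_range(cls, v: int) -> int:
        if v not in (-1, 0, 1, 2):
            raise ValueError("charge_z must be in {-1, 0, +1, +2}")
        return v

    @field_validator("p_uniport", "p_ptp", "p_neutral")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("permeabilities must be non-negative")
        return v


class GatingParams(_Frozen):
    """pH-gate of the PTP: P = alpha*x^n/(1+alpha*x^n), x = max(pH-7, 0)."""

    alpha: float = 1.2e3
    n_exponent: float = 4.0
    n_ptp: int = 1

    @field_validator("alpha")
    @classmethod
    def _alpha_pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("alpha must be positive")
        return v

    @field_validator("n_exponent")
    @classmethod
    def _n_ge1(cls, v: float) -> float:
        if v < 1:
            raise ValueError("n_exponent must be >= 1")
        return v

    @field_validator("n_ptp")
    @classmethod
    def _nptp(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_ptp must be >= 1")
        return v


class RespirationParams(_Frozen):
    """Respiration-activator kinetics.

    ``delta_dpsi`` (mV) sets the saturation of the activator generation rate
    W_A = k_a*a_a0*(1 - exp(-dpsi/delta)); the printed 43.42 mV makes
    W_A = 0.99*k_a*a_a0 at 200 mV.
    """

    k_a: float = 1.0          # 1/min
    k_a_h: float = 1.0        # 1/min
    delta_dpsi: float = 43.42  # mV
    a_a0: float = 10.0        # uM

    @field_validator("*")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("respiration parameters must be positive")
        return v


class AcidParams(_Frozen):
    """Weak-acid (phosphate second dissociation surrogate) equilibrium."""

    pka: float = 7.20
    c_ah0: float = 50.0            # uM, cytosolic total acid pool
    c_h_background: float = 0.0    # uM

    @field_validator("c_ah0", "c_h_background")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("acid concentrations must be >= 0")
        return v

    @property
    def k_ahh_uM(self) -> float:
        """Dissociation constant in micromolar."""
        return 10.0 ** (-self.pka) * 1e6


class RigidityParams(_Frozen):
    """Deformation-softening IMM rigidity tensor components.

    ``g00``/``gzz0`` are quoted in dyn/nm (1 dyn/nm = 1e4 N/m).  With
    ``recalibrate_beta`` (default) the softening constants are re-anchored so
    the components vanish exactly at the critical strain (the +50 % volume
    point, Delta_r = crit_strain*a); the literal table values are available by
    switching the flag off.
    """

    g00: float = 0.017     # dyn/nm
    gzz0: float = 0.019    # dyn/nm
    beta0: float = 1e6     # nm^-n1
    betaz: float = 1e7     # nm^-n1
    n1: float = 4.0
    crit_strain: float = 1.5 ** (1.0 / 3.0) - 1.0
    recalibrate_beta: bool = True

    @field_validator("g00", "gzz0", "beta0", "betaz", "n1", "crit_strain")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("rigidity parameters must be positive")
        return v

    @property
    def g00_si(self) -> float:
        return self.g00 * DYN_PER_NM_TO_N_PER_M

    @property
    def gzz0_si(self) -> float:
        return self.gzz0 * DYN_PER_NM_TO_N_PER_M


class GeometryParams(_Frozen):
    """Prolate-spheroid matrix geometry and pore/membrane dimensions (SI)."""

    semi_a: float = 0.5e-6               # m
    semi_c: float = 1.0e-6               # m
    imm_thickness_h: float = 10e-9       # m
    pore_radius_r0: float = 1.5e-9       # m
    cell_to_mito_volume_ratio: float = 2.86
    matrix_viscosity: float = 0.69e-3    # Pa*s (water at 310 K)

    @field_validator("*")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("geometry parameters must be positive")
        return v

    @model_validator(mode="after")
    def _prolate(self) -> "GeometryParams":
        if not self.semi_a < self.semi_c:
            raise ValueError("prolate geometry requires semi_a < semi_c")
        return self


class InitialConditions(_Frozen):
    """Initial state shared by every run of the experiment grid."""

    dpsi0: float = 200.0                 # mV
    ca_in0: float = 0.5                  # uM
    ca_out0: float = 1.0                 # uM (grid-varied)
    k_in0: float = 0.0                   # uM
    k_out0: float = 0.1                  # uM (grid-varied)
    ph_in0: float = 6.00
    ph_out0: float = 7.00                # held constant for the whole run
    ah_out0: float = 50.0                # uM
    a_in0: float = 10.0                  # uM respiration activator
    ca_background_cytosol: float = 0.5   # uM, buffered cytosolic floor

    @field_validator("ca_in0", "ca_out0", "k_in0", "k_out0", "ah_out0",
                     "a_in0", "ca_background_cytosol")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("concentrations must be >= 0")
        return v


class Normalization(_Frozen):
    """Unit-normalization / calibration constants of the working system.

    ``uniporter_scale`` and ``exchanger_scale`` convert the table's reduced
    uniporter and K+/H+ exchanger permeabilities into min^-1;
    ``ptp_scale`` does the same for the PTP permeabilities of the small
    inorganic ions (Ca2+, K+, H+); ``organic_ptp_scale`` covers the PTP
    permeabilities of the organic species (the weak-acid anion A- and the
    neutral respiration activator), which equilibrate far more slowly;
    ``buffering_b`` is the proton-buffering divisor applied to all matrix-H+
    rates (the literal printed constant is 3e5 in the source's unit system);
    ``rigidity_pressure_scale`` maps the rigidity tensor term of the pressure
    balance into pascals; ``hydro_n_pores`` multiplies the single-pore
    Poiseuille efflux.  Defaults are the model's calibrated operating point
    (docs/methods.md).
    """

    uniporter_scale: float = 2.35e-10
    exchanger_scale: float = 0.145
    ptp_scale: float = 0.3
    organic_ptp_scale: float = 2.6e-4
    buffering_b: float = 7.0
    rigidity_pressure_scale: float = 1.68e-5
    hydro_n_pores: float = 1.0
    membrane_dielectric: float = 2.0
    enable_depolarized_ptp: bool = False

    @field_validator("uniporter_scale", "exchanger_scale", "ptp_scale",
                     "organic_ptp_scale", "buffering_b",
                     "rigidity_pressure_scale", "membrane_dielectric")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("normalization constants must be positive")
        return v


class NumericsParams(_Frozen):
    """Integrator and output controls."""

    rtol: float = 1e-8
    atol: float = 1e-12
    output_dt_s: float = 0.25
    t_end_s: float = 600.0
    transient_fraction: float = 0.10

    @field_validator("rtol", "atol", "output_dt_s", "t_end_s")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("numerics parameters must be positive")
        return v


DYN_PER_NM_TO_N_PER_M = 1e4

#: Per-parameter factors taking each quoted table value into the working unit
#: system.  The permeability classes share the pathway normalization constants
#: of :class:`Normalization` (their per-(mg protein) content is not separately
#: recoverable); geometric and gating quantities convert exactly.
UNIT_CONVERSIONS: dict[str, dict[str, object]] = {
    "p_uniport": {"from": "reduced table units", "to": "min^-1",
                  "factor": "uniporter_scale"},
    "p_exchange": {"from": "reduced table units per uM_H (K+/H+) or mM_K (H+/K+)",
                   "to": "min^-1 per uM or mM", "factor": "exchanger_scale"},
    "p_ptp": {"from": "reduced table units", "to": "min^-1",
              "factor": "ptp_scale"},
    "g_rigidity": {"from": "dyn/nm", "to": "N/m",
                   "factor": DYN_PER_NM_TO_N_PER_M},
    "length_um": {"from": "um", "to": "m", "divisor": 1e6},
    "length_nm": {"from": "nm", "to": "m", "divisor": 1e9},
    "potential": {"from": "mV", "to": "mV", "factor": 1.0},
    "concentration": {"from": "uM", "to": "uM", "factor": 1.0},
    "rate": {"from": "min^-1", "to": "min^-1", "factor": 1.0},
}

#: Default grid of cytosolic concentrations (uM).
GRID_CA_OUT_UM = (1.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 300.0, 400.0, 500.0)
GRID_K_OUT_UM = (0.1, 10.0)
#: Alternative millimolar reading of the K+ grid (available by config).
GRID_K_OUT_MM_AS_UM = (10.0, 10000.0)


class ModelParameters(_Frozen):
    """The complete, validated, unit-normalized parameter set."""

    constants: PhysicalConstants = PhysicalConstants()
    gating: GatingParams = GatingParams()
    respiration: RespirationParams = RespirationParams()
    acid: AcidParams = AcidParams()
    rigidity: RigidityParams = RigidityParams()
    geometry: GeometryParams = GeometryParams()
    initial: InitialConditions = InitialConditions()
    normalization: Normalization = Normalization()
    numerics: NumericsParams = NumericsParams()

    # Reduced permeabilities, quoted table values.
    p_ca_uniport: float = 6.43e5
    p_kh_exchange: float = 3.20e5     # per uM of |H gradient|
    p_hk_exchange: float = 3.20e5     # per mM of |K gradient|
    p_h_ptp: float = 4.30e7
    p_ca_ptp: float = 8.61e7
    p_k_ptp: float = 4.30e7
    p_anion_ptp: float = 6.43e2
    p_activator_ptp: float = 32.1
    buffering_b_literal: float = 3e5    # literal printed constant, source units
    k_grid_in_mM: bool = False
    # number density of equivalent mitochondria (1/cm^3); exposed for
    # ensemble extensions, unused by the single-organelle simulator
    n_mit_per_cm3: float = 0.0

    @field_validator("p_ca_uniport", "p_kh_exchange", "p_hk_exchange",
                     "p_h_ptp", "p_ca_ptp", "p_k_ptp", "p_anion_ptp",
                     "p_activator_ptp", "buffering_b_literal")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("permeabilities must be >= 0")
        return v

    # -- species table ------------------------------------------------------

    def ion_specs(self) -> dict[str, IonSpec]:
        """The modeled species with their quoted permeabilities."""
        return {
            "ca": IonSpec(name="ca", charge_z=2, p_uniport=self.p_ca_uniport,
                          p_ptp=self.p_ca_ptp),
            "k": IonSpec(name="k", charge_z=1, p_ptp=self.p_k_ptp),
            "h": IonSpec(name="h", charge_z=1, p_ptp=self.p_h_ptp),
            "anion": IonSpec(name="anion", charge_z=-1, p_ptp=self.p_anion_ptp),
            "activator": IonSpec(name="activator", charge_z=0,
                                 p_neutral=self.p_activator_ptp),
        }

    # -- table-symbol accessors --------------------------------------------

    def symbol(self, name: str) -> float:
        """Look up a quoted table symbol by its conventional name."""
        try:
            path = TABLE_SYMBOLS[name]
        except KeyError:
            raise KeyError(f"unknown table symbol {name!r}") from None
        obj: object = self
        for attr in path.split("."):
            obj = getattr(obj, attr)
        return obj  # type: ignore[return-value]


#: Every quoted table symbol, reachable by name from :class:`ModelParameters`.
TABLE_SYMBOLS: dict[str, str] = {
    "p_Ca,UP": "p_ca_uniport",
    "p_K,H^(0)": "p_kh_exchange",
    "p_H,K^(0)": "p_hk_exchange",
    "p_H+,PTP": "p_h_ptp",
    "p_Ca2+,PTP": "p_ca_ptp",
    "p_K+,PTP": "p_k_ptp",
    "p_A-,PTP": "p_anion_ptp",
    "p_A,PTP": "p_activator_ptp",
    "|e|": "constants.electron_charge_abs",
    "k_B": "constants.boltzmann_k",
    "dPsi_m(0)": "initial.dpsi0",
    "V_C/V_m(0)": "geometry.cell_to_mito_volume_ratio",
    "alpha": "gating.alpha",
    "n": "gating.n_exponent",
    "-log(C_H+,0^out)": "initial.ph_out0",
    "-log(C_H+,0^in)": "initial.ph_in0",
    "C_AH,0^out": "acid.c_ah0",
    "delta(dPsi_m)": "respiration.delta_dpsi",
    "C_A,0^in": "respiration.a_a0",
    "k_A": "respiration.k_a",
    "k_A,H+": "respiration.k_a_h",
    "g_00": "rigidity.g00",
    "g_zz,0": "rigidity.gzz0",
    "beta_0": "rigidity.beta0",
    "beta_z": "rigidity.betaz",
    "n_1": "rigidity.n1",
    "B": "buffering_b_literal",
}


# ---------------------------------------------------------------------------
# config file I/O
# ---------------------------------------------------------------------------

# Flat TOML key -> (section path, field) map.  Keys follow the table symbols.
_FLAT_KEYS: dict[str, tuple[str, str, float]] = {
    # (key) -> (section attr or "" for top level, field, display-per-internal divisor)
    "alpha": ("gating", "alpha", 1.0),
    "n": ("gating", "n_exponent", 1.0),
    "n_ptp": ("gating", "n_ptp", 1.0),
    "k_a": ("respiration", "k_a", 1.0),
    "k_a_h": ("respiration", "k_a_h", 1.0),
    "delta_mV": ("respiration", "delta_dpsi", 1.0),
    "a_a0_uM": ("respiration", "a_a0", 1.0),
    "pka": ("acid", "pka", 1.0),
    "c_ah0_uM": ("acid", "c_ah0", 1.0),
    "c_h_background_uM": ("acid", "c_h_background", 1.0),
    "g00": ("rigidity", "g00", 1.0),
    "gzz0": ("rigidity", "gzz0", 1.0),
    "beta0": ("rigidity", "beta0", 1.0),
    "betaz": ("rigidity", "betaz", 1.0),
    "n1": ("rigidity", "n1", 1.0),
    "crit_strain": ("rigidity", "crit_strain", 1.0),
    "recalibrate_beta": ("rigidity", "recalibrate_beta", 1.0),
    "a_um": ("geometry", "semi_a", 1e6),
    "c_um": ("geometry", "semi_c", 1e6),
    "h_nm": ("geometry", "imm_thickness_h", 1e9),
    "r0_nm": ("geometry", "pore_radius_r0", 1e9),
    "cell_to_mito_volume_ratio": ("geometry", "cell_to_mito_volume_ratio", 1.0),
    "matrix_viscosity_Pa_s": ("geometry", "matrix_viscosity", 1.0),
    "dpsi0_mV": ("initial", "dpsi0", 1.0),
    "ca_in0_uM": ("initial", "ca_in0", 1.0),
    "ca_out0_uM": ("initial", "ca_out0", 1.0),
    "k_in0_uM": ("initial", "k_in0", 1.0),
    "k_out0_uM": ("initial", "k_out0", 1.0),
    "ph_in0": ("initial", "ph_in0", 1.0),
    "ph_out0": ("initial", "ph_out0", 1.0),
    "ah_out0_uM": ("initial", "ah_out0", 1.0),
    "a_in0_uM": ("initial", "a_in0", 1.0),
    "ca_background_uM": ("initial", "ca_background_cytosol", 1.0),
    "temperature_K": ("constants", "temperature", 1.0),
    "water_rel_permittivity": ("constants", "water_rel_permittivity", 1.0),
    "uniporter_scale": ("normalization", "uniporter_scale", 1.0),
    "exchanger_scale": ("normalization", "exchanger_scale", 1.0),
    "ptp_scale": ("normalization", "ptp_scale", 1.0),
    "organic_ptp_scale": ("normalization", "organic_ptp_scale", 1.0),
    "buffering_b": ("normalization", "buffering_b", 1.0),
    "rigidity_pressure_scale": ("normalization", "rigidity_pressure_scale", 1.0),
    "hydro_n_pores": ("normalization", "hydro_n_pores", 1.0),
    "membrane_dielectric": ("normalization", "membrane_dielectric", 1.0),
    "enable_depolarized_ptp": ("normalization", "enable_depolarized_ptp", 1.0),
    "rtol": ("numerics", "rtol", 1.0),
    "atol": ("numerics", "atol", 1.0),
    "output_dt_s": ("numerics", "output_dt_s", 1.0),
    "t_end_s": ("numerics", "t_end_s", 1.0),
    "transient_fraction": ("numerics", "transient_fraction", 1.0),
    "p_ca_uniport": ("", "p_ca_uniport", 1.0),
    "p_kh_exchange": ("", "p_kh_exchange", 1.0),
    "p_hk_exchange": ("", "p_hk_exchange", 1.0),
    "p_h_ptp": ("", "p_h_ptp", 1.0),
    "p_ca_ptp": ("", "p_ca_ptp", 1.0),
    "p_k_ptp": ("", "p_k_ptp", 1.0),
    "p_anion_ptp": ("", "p_anion_ptp", 1.0),
    "p_activator_ptp": ("", "p_activator_ptp", 1.0),
    "buffering_b_literal": ("", "buffering_b_literal", 1.0),
    "k_grid_in_mM": ("", "k_grid_in_mM", 1.0),
    "n_mit_per_cm3": ("", "n_mit_per_cm3", 1.0),
}

_BOOL_KEYS = {"recalibrate_beta", "enable_depolarized_ptp", "k_grid_in_mM"}
_INT_KEYS = {"n_ptp"}


def load_config(path: str | Path) -> ModelParameters:
    """Read a flat TOML config file; unspecified keys take table defaults.

    Raises :class:`ConfigurationError` naming any unknown key, and pydantic
    validation errors for non-positive physical quantities.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigurationError(f"config file does not parse: {exc}") from exc
    return params_from_mapping(raw)


def params_from_mapping(raw: dict[str, object]) -> ModelParameters:
    """Build :class:`ModelParameters` from a flat key/value mapping."""
    sections: dict[str, dict[str, object]] = {}
    top: dict[str, object] = {}
    for key, value in raw.items():
        if key not in _FLAT_KEYS:
            raise ConfigurationError(f"unknown configuration key {key!r}")
        section, field, factor = _FLAT_KEYS[key]
        if key in _BOOL_KEYS:
            coerced: object = bool(value)
        elif key in _INT_KEYS:
            coerced = int(value)  # type: ignore[arg-type]
        else:
            coerced = float(value) / factor  # type: ignore[arg-type]
        if section:
            sections.setdefault(section, {})[field] = coerced
        else:
            top[field] = coerced
    try:
        return ModelParameters(**top, **{
            name: _SECTION_TYPES[name](**fields)
            for name, fields in sections.items()
        })
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from exc


_SECTION_TYPES = {
    "constants": PhysicalConstants,
    "gating": GatingParams,
    "respiration": RespirationParams,
    "acid": AcidParams,
    "rigidity": RigidityParams,
    "geometry": GeometryParams,
    "initial": InitialConditions,
    "normalization": Normalization,
    "numerics": NumericsParams,
}


def _exact_mul(value: float, factor: float) -> float:
    """value*factor such that dividing back by factor is bit-exact."""
    d = value * factor
    if d / factor == value:
        return d
    for candidate in (math.nextafter(d, math.inf),
                      math.nextafter(d, -math.inf)):
        if candidate / factor == value:
            return candidate
    return d


def params_to_mapping(params: ModelParameters) -> dict[str, object]:
    """Flatten a parameter set back into config-file keys (bit-exact)."""
    out: dict[str, object] = {}
    for key, (section, field, factor) in _FLAT_KEYS.items():
        obj = getattr(params, section) if section else params
        value = getattr(obj, field)
        if key in _BOOL_KEYS:
            out[key] = bool(value)
        elif key in _INT_KEYS:
            out[key] = int(value)
        else:
            out[key] = _exact_mul(float(value), factor)
    return out


def write_config(params: ModelParameters, path: str | Path) -> None:
    """Serialize a parameter set as a flat TOML file that round-trips."""
    lines = []
    for key, value in params_to_mapping(params).items():
        if isinstance(value, bool):
            lines.append(f"{key} = {'true' if value else 'false'}")
        elif isinstance(value, int):
            lines.append(f"{key} = {value}")
        else:
            lines.append(f"{key} = {_toml_float(value)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _toml_float(v: float) -> str:
    if math.isinf(v) or math.isnan(v):
        raise ConfigurationError("non-finite value in configuration")
    s = repr(v)
    # TOML floats need a decimal point or exponent.
    if "e" not in s and "E" not in s and "." not in s:
        s += ".0"
    return s


# ---------------------------------------------------------------------------
# experiment grid
# ---------------------------------------------------------------------------

class RunDescriptor(_Frozen):
    run_id: str
    k_out_uM: float
    ca_out_uM: float
    output_path: str


class ExperimentGrid(_Frozen):
    """The 2 x 10 cartesian grid of initial cytosolic K+ and Ca2+."""

    runs: tuple[RunDescriptor, ...]

    def __iter__(self) -> Iterator[RunDescriptor]:  # type: ignore[override]
        return iter(self.runs)

    def __len__(self) -> int:
        return len(self.runs)

    def to_json(self) -> str:
        return json.dumps([r.model_dump() for r in self.runs], indent=1)


def experiment_grid(
    params: ModelParameters,
    k_values_uM: tuple[float, ...] | None = None,
    ca_values_uM: tuple[float, ...] | None = None,
) -> ExperimentGrid:
    """Build the standard 20-run grid (or a restriction of it)."""
    if k_values_uM is None:
        k_values_uM = (GRID_K_OUT_MM_AS_UM if params.k_grid_in_mM
                       else GRID_K_OUT_UM)
    if ca_values_uM is None:
        ca_values_uM = GRID_CA_OUT_UM
    runs = []
    for k in k_values_uM:
        for ca in ca_values_uM:
            run_id = f"k{k:g}_ca{ca:g}"
            runs.append(RunDescriptor(
                run_id=run_id, k_out_uM=k, ca_out_uM=ca,
                output_path=f"{run_id}/trajectory.csv"))
    return ExperimentGrid(runs=tuple(runs))


def capacitance(geometry: GeometryParams, s_m: float,
                membrane_dielectric: float = 2.0,
                constants: PhysicalConstants | None = None) -> float:
    """IMM electric capacitance (F) of a membrane patch of area ``s_m`` (m^2).

    Parallel-plate form C = eps_m*eps0*S_m/h; the membrane dielectric constant
    defaults to 2 (lipid bilayer core).
    """
    if geometry.imm_thickness_h <= 0:
        raise ValueError("membrane thickness must be positive")
    if s_m < 0:
        raise ValueError("membrane area must be >= 0")
    eps0 = (constants or PhysicalConstants()).vacuum_permittivity
    return membrane_dielectric * eps0 * s_m / geometry.imm_thickness_h
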