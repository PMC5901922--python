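"""The swelling simulator: assembles the full right-hand side (membrane
potential, matrix Ca2+/K+/H+/activator/weak-acid dynamics), integrates the
stiff ODE system, and couples it to the quasi-static membrane mechanics with
volume-dilution rescaling.

Integration is operator-split: the ionic/electrical system is integrated in
short chunks with a stiff-capable adaptive method while the slow algebraic
layer (activity coefficients, osmotic pressure, quasi-static deformation and
the resulting dilution) is re-solved between chunks.  Pore gating and
respiration are instantaneous algebraic functions of the live state inside
the right-hand side.

Working units: minutes, millivolts, micromolar; geometry in SI.

Osmotic reference: the model transports a handful of species of an otherwise
osmotically balanced organelle, so the osmotic imbalance is measured relative
to the initial composition, dP_os = RT*[ (S_in(t) - S_in(0)) - (S_out(t) -
S_out(0)) ] over the modeled species; unmodeled background osmolytes hold the
t = 0 balance (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import chemistry, gating, transport
from .config import (ExperimentGrid, ModelParameters, capacitance,
                     experiment_grid)
from .mechanics import Deformation, MechanicsModel, ellipsoid_surface_area, \
    ellipsoid_volume

# state-vector layout
_DPSI, _CA_IN, _K_IN, _H_IN, _A_IN, _ACID_IN, _CA_OUT, _K_OUT = range(8)

#: trajectory CSV schema (leading columns; extra bookkeeping columns follow)
TRAJECTORY_COLUMNS = [
    "t_s", "dpsi_mV", "ca_in_uM", "k_in_uM", "pH_in", "a_in_uM",
    "p_ptp", "v_rel", "s_m_um2", "dp_os_Pa", "irreversible",
]
_EXTRA_COLUMNS = ["acid_in_uM", "ca_out_uM", "k_out_uM", "strain"]


class SimulationError(RuntimeError):
    """Integrator failure or state-invariant breach."""


@dataclass(frozen=True)
class SystemState:
    """Instantaneous state with derived volume/area (reporting container)."""

    t_s: float
    dpsi: float
    a_ca_in: float
    a_k_in: float
    a_h_in: float
    a_a_in: float
    c_acid_in: float
    c_ca_out: float
    c_k_out: float
    deformation: Deformation
    v_m: float
    s_m: float


@dataclass
class Trajectory:
    """Time series of the simulated run plus derived channels."""

    data: pd.DataFrame
    params: ModelParameters | None = None

    def __post_init__(self) -> None:
        t = self.data["t_s"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("trajectory time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.data)

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    @property
    def t_s(self) -> np.ndarray:
        return self.channel("t_s")

    @property
    def irreversible(self) -> bool:
        return bool(self.data["irreversible"].iloc[-1])

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        return cls(data=pd.read_csv(path))


@dataclass
class _Workspace:
    """Per-chunk frozen quantities of the fast algebraic layer."""

    gamma1_in: float = 1.0
    gamma2_in: float = 1.0
    gamma1_out: float = 1.0
    gamma2_out: float = 1.0
    strain: float = 0.0
    v_m: float = 0.0
    s_m: float = 0.0
    area_factor: float = 1.0
    dp_imm: float = 0.0
    dp_os: float = 0.0
    k_v: float = 0.0           # mV per uM of monovalent charge
    hydro_coeff: float = 0.0   # 1/min at P_PTP = 1 and current dp_imm
    latched: bool = False
    baseline_in: float = 0.0
    baseline_out: float = 0.0


class SwellingSimulator:
    """Single-run simulator bound to one parameter set."""

    def __init__(self, params: ModelParameters):
        self.params = params
        p = params
        n = p.normalization
        self.specs = p.ion_specs()
        # effective permeabilities, min^-1
        self.p_ca_uni = n.uniporter_scale * p.p_ca_uniport
        self.p_kh0 = n.exchanger_scale * p.p_kh_exchange
        self.p_hk0 = n.exchanger_scale * p.p_hk_exchange
        self.p_ca_ptp = n.ptp_scale * p.p_ca_ptp
        self.p_k_ptp = n.ptp_scale * p.p_k_ptp
        self.p_h_ptp = n.ptp_scale * p.p_h_ptp
        self.p_an_ptp = n.organic_ptp_scale * p.p_anion_ptp
        self.p_act_ptp = n.organic_ptp_scale * p.p_activator_ptp
        self.k_ahh = p.acid.k_ahh_uM
        self.mech = MechanicsModel(p.geometry, p.rigidity,
                                   pressure_scale=n.rigidity_pressure_scale)
        self.v_m0 = ellipsoid_volume(p.geometry, Deformation(0.0, 0.0))
        self.s_m0 = ellipsoid_surface_area(p.geometry, Deformation(0.0, 0.0))
        self.v_cyt = p.geometry.cell_to_mito_volume_ratio * self.v_m0
        # fixed cytosolic quantities
        self.c_h_out = 10.0 ** (6.0 - p.initial.ph_out0)        # uM
        self.f_an_out = chemistry.anion_fraction(self.c_h_out, self.k_ahh)
        self.c_acid_out = p.initial.ah_out0

    # -- fast algebraic layer ----------------------------------------------

    def _gammas(self, y: np.ndarray) -> tuple[float, float, float, float]:
        cst = self.params.constants
        mix_in = chemistry.IonicMixture()
        mix_in.add("ca", 2, max(y[_CA_IN], 0.0))
        mix_in.add("k", 1, max(y[_K_IN], 0.0))
        mix_in.add("h", 1, max(y[_H_IN], 0.0))
        f_in = chemistry.anion_fraction(max(y[_H_IN], 0.0), self.k_ahh)
        mix_in.add("anion", -1, f_in * max(y[_ACID_IN], 0.0))
        i_in = mix_in.ionic_strength_uM
        mix_out = chemistry.IonicMixture()
        mix_out.add("ca", 2, max(y[_CA_OUT], 0.0))
        mix_out.add("k", 1, max(y[_K_OUT], 0.0))
        mix_out.add("h", 1, self.c_h_out)
        mix_out.add("anion", -1, self.f_an_out * self.c_acid_out)
        i_out = mix_out.ionic_strength_uM
        return (chemistry.activity_coefficient(1, i_in, cst),
                chemistry.activity_coefficient(2, i_in, cst),
                chemistry.activity_coefficient(1, i_out, cst),
                chemistry.activity_coefficient(2, i_out, cst))

    def _osmotic_sums(self, y: np.ndarray, ws: _Workspace) -> tuple[float, float]:
        """Summed modeled-species activities (uM) inside and outside."""
        s_in = (ws.gamma2_in * y[_CA_IN] + ws.gamma1_in * y[_K_IN]
                + ws.gamma1_in * y[_H_IN] + y[_A_IN] + y[_ACID_IN])
        s_out = (ws.gamma2_out * y[_CA_OUT] + ws.gamma1_out * y[_K_OUT]
                 + ws.gamma1_out * self.c_h_out + self.c_acid_out)
        return s_in, s_out

    def _refresh_workspace(self, y: np.ndarray, ws: _Workspace) -> None:
        p = self.params
        ws.gamma1_in, ws.gamma2_in, ws.gamma1_out, ws.gamma2_out = self._gammas(y)
        s_in, s_out = self._osmotic_sums(y, ws)
        ws.dp_os = p.constants.rt_pa_per_uM * (
            (s_in - ws.baseline_in) - (s_out - ws.baseline_out))
        mstate = self.mech.solve(ws.dp_os, latched=ws.latched)
        ws.latched = mstate.irreversible
        ws.strain = mstate.deformation.dx / p.geometry.semi_a
        ws.v_m = mstate.v_m
        ws.s_m = mstate.s_m
        ws.area_factor = ws.s_m / self.s_m0
        ws.dp_imm = mstate.dp_imm
        cap = capacitance(p.geometry, ws.s_m,
                          p.normalization.membrane_dielectric, p.constants)
        # mV change per uM of monovalent charge moved across the IMM
        ws.k_v = p.constants.faraday * 1e-3 * ws.v_m / cap * 1e3
        # Poiseuille volumetric turnover at P_PTP = 1, per minute
        j0 = transport.poiseuille_volume_flux(p.geometry, 1.0, ws.dp_imm)
        ws.hydro_coeff = (j0 * p.normalization.hydro_n_pores / ws.v_m) * 60.0

    # -- right-hand side ----------------------------------------------------

    def _rhs(self, t: float, y: np.ndarray, ws: _Workspace) -> np.ndarray:
        p = self.params
        cst = p.constants
        n_ptp = p.gating.n_ptp
        dpsi = y[_DPSI]
        c_ca_in = max(y[_CA_IN], 0.0)
        c_k_in = max(y[_K_IN], 0.0)
        c_h_in = max(y[_H_IN], 0.0)
        c_a_in = max(y[_A_IN], 0.0)
        c_acid_in = max(y[_ACID_IN], 0.0)
        c_ca_out = max(y[_CA_OUT], p.initial.ca_background_cytosol)
        c_k_out = max(y[_K_OUT], 0.0)

        a_ca_in = ws.gamma2_in * c_ca_in
        a_k_in = ws.gamma1_in * c_k_in
        a_h_in = ws.gamma1_in * c_h_in
        a_ca_out = ws.gamma2_out * c_ca_out
        a_k_out = ws.gamma1_out * c_k_out
        a_h_out = ws.gamma1_out * self.c_h_out
        f_an_in = chemistry.anion_fraction(a_h_in, self.k_ahh)
        a_an_in = ws.gamma1_in * f_an_in * c_acid_in
        a_an_out = ws.gamma1_out * self.f_an_out * self.c_acid_out

        if a_h_in > 0.0:
            ph = chemistry.ph_from_activity(a_h_in)
        else:
            ph = 14.0  # fully depleted matrix H+: gate saturates open
        p_open = gating.ptp_open_probability(ph, p.gating)

        ar = ws.area_factor
        j_ca_uni = transport.ghk_flux(
            self.specs["ca"], dpsi, a_ca_in, a_ca_out, cst,
            p_eff=self.p_ca_uni).value * ar
        j_k_kh, j_h_hk = transport.kh_exchange_fluxes(
            dpsi, a_k_in, a_k_out, a_h_in, a_h_out,
            self.p_kh0, self.p_hk0, cst)
        j_k_kh = j_k_kh.value * ar
        j_h_hk = j_h_hk.value * ar

        if p_open > 0.0:
            j_ca_ptp = transport.ptp_ion_flux(
                self.specs["ca"], p_open, n_ptp, dpsi, a_ca_in, a_ca_out,
                cst, p_eff=self.p_ca_ptp).value * ar
            j_k_ptp = transport.ptp_ion_flux(
                self.specs["k"], p_open, n_ptp, dpsi, a_k_in, a_k_out,
                cst, p_eff=self.p_k_ptp).value * ar
            j_h_ptp = transport.ptp_ion_flux(
                self.specs["h"], p_open, n_ptp, dpsi, a_h_in, a_h_out,
                cst, p_eff=self.p_h_ptp).value * ar
            j_an_ptp = transport.ptp_ion_flux(
                self.specs["anion"], p_open, n_ptp, dpsi, a_an_in, a_an_out,
                cst, p_eff=self.p_an_ptp).value * ar
            j_act = gating.activator_ptp_flux(
                c_a_in, p_open, n_ptp, self.p_act_ptp).value * ar
            if p.normalization.enable_depolarized_ptp:
                j_ca_ptp += transport.ptp_depolarized_flux(
                    self.specs["ca"], p_open, n_ptp, a_ca_in, a_ca_out).value * ar
            hyd = ws.hydro_coeff * p_open * p_open
        else:
            j_ca_ptp = j_k_ptp = j_h_ptp = j_an_ptp = j_act = 0.0
            hyd = 0.0

        w_a = gating.activator_generation_rate(dpsi, p.respiration)
        w_h = gating.proton_generation_rate(c_a_in, p.respiration)

        j_ca = j_ca_uni + j_ca_ptp - hyd * a_ca_in
        j_k = j_k_kh + j_k_ptp - hyd * a_k_in
        j_h_ions = j_h_hk + j_h_ptp - w_h - hyd * a_h_in
        j_an = j_an_ptp - hyd * a_an_in

        b = p.normalization.buffering_b
        dy = np.empty(8)
        charge = 2.0 * j_ca + j_k + j_h_ions - j_an
        dy[_DPSI] = -ws.k_v * charge
        dy[_CA_IN] = j_ca
        dy[_K_IN] = j_k
        # incoming anions partially associate, consuming matrix H+
        dy[_H_IN] = (j_h_ions - (1.0 - f_an_in) * j_an) / b
        dy[_A_IN] = w_a - w_h + j_act - hyd * c_a_in
        dy[_ACID_IN] = j_an_ptp - hyd * c_acid_in
        vr = ws.v_m / self.v_cyt
        dy[_CA_OUT] = -j_ca * vr
        dy[_K_OUT] = -j_k * vr
        # cytosolic Ca2+ is buffered at the background floor
        if y[_CA_OUT] <= p.initial.ca_background_cytosol and dy[_CA_OUT] < 0.0:
            dy[_CA_OUT] = 0.0
        if not np.all(np.isfinite(dy)):
            bad = [nm for nm, v in zip(
                ("dpsi", "ca_in", "k_in", "h_in", "a_in", "acid_in",
                 "ca_out", "k_out"), dy) if not math.isfinite(v)]
            raise SimulationError(f"non-finite derivative in {bad} at t={t!r}")
        return dy

    # -- driver -------------------------------------------------------------

    def initial_state(self, ca_out_uM: float | None = None,
                      k_out_uM: float | None = None) -> np.ndarray:
        ini = self.params.initial
        y = np.zeros(8)
        y[_DPSI] = ini.dpsi0
        y[_CA_IN] = ini.ca_in0
        y[_K_IN] = ini.k_in0
        y[_A_IN] = ini.a_in0
        y[_ACID_IN] = 0.0
        y[_CA_OUT] = ini.ca_out0 if ca_out_uM is None else ca_out_uM
        y[_K_OUT] = ini.k_out0 if k_out_uM is None else k_out_uM
        # set matrix H+ concentration so the initial activity matches ph_in0
        y[_H_IN] = 10.0 ** (6.0 - ini.ph_in0)
        g1, _, _, _ = self._gammas(y)
        y[_H_IN] = 10.0 ** (6.0 - ini.ph_in0) / g1
        return y

    def run(self, t_end_s: float | None = None,
            ca_out_uM: float | None = None,
            k_out_uM: float | None = None) -> Trajectory:
        p = self.params
        num = p.numerics
        t_end = num.t_end_s if t_end_s is None else t_end_s
        if t_end <= 0:
            raise ValueError("t_end must be positive")
        dt_s = num.output_dt_s
        n_steps = max(1, int(round(t_end / dt_s)))
        y = self.initial_state(ca_out_uM, k_out_uM)
        ws = _Workspace()
        self._refresh_workspace(y, ws)  # sets gammas/mechanics at t = 0
        s_in0, s_out0 = self._osmotic_sums(y, ws)
        ws.baseline_in, ws.baseline_out = s_in0, s_out0
        self._refresh_workspace(y, ws)

        atol = np.full(8, num.atol)
        atol[_DPSI] = num.atol * 1e3  # mV scale vs uM scale
        rows = [self._row(0.0, y, ws)]
        dt_min = dt_s / 60.0
        for k in range(n_steps):
            sol = solve_ivp(self._rhs, (k * dt_min, (k + 1) * dt_min), y,
                            method="LSODA", args=(ws,), rtol=num.rtol,
                            atol=atol, dense_output=False)
            if not sol.success:
                raise SimulationError(
                    f"integrator failed at t={k * dt_s:.2f}s: {sol.message}; "
                    f"last state {y.tolist()}")
            y = sol.y[:, -1]
            self._guard_negatives(y, (k + 1) * dt_s)
            v_old = ws.v_m
            self._refresh_workspace(y, ws)
            if ws.v_m != v_old:
                y = apply_dilution_vector(y, v_old, ws.v_m)
            rows.append(self._row((k + 1) * dt_s, y, ws))
        df = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS + _EXTRA_COLUMNS)
        return Trajectory(data=df, params=p)

    def _guard_negatives(self, y: np.ndarray, t_s: float) -> None:
        # stiff transients near pore opening can graze zero; clip small
        # undershoots, fail on substantive ones
        for idx in (_CA_IN, _K_IN, _H_IN, _A_IN, _ACID_IN, _CA_OUT, _K_OUT):
            if y[idx] < 0.0:
                if y[idx] < -1e-6:
                    raise SimulationError(
                        f"state component {idx} went negative ({y[idx]!r}) "
                        f"at t={t_s:.2f}s")
                y[idx] = 0.0

    def _row(self, t_s: float, y: np.ndarray, ws: _Workspace) -> list:
        a_h = ws.gamma1_in * max(y[_H_IN], 0.0)
        ph = chemistry.ph_from_activity(a_h) if a_h > 0 else 14.0
        p_open = gating.ptp_open_probability(ph, self.params.gating)
        v_rel = ws.v_m / self.v_m0 - 1.0
        return [t_s, y[_DPSI], y[_CA_IN], y[_K_IN], ph, y[_A_IN], p_open,
                v_rel, ws.s_m * 1e12, ws.dp_os, ws.latched,
                y[_ACID_IN], y[_CA_OUT], y[_K_OUT], ws.strain]


def apply_dilution_vector(y: np.ndarray, v_old: float, v_new: float) -> np.ndarray:
    """Rescale matrix concentrations for a volume change (amounts conserved)."""
    if v_old <= 0 or v_new <= 0:
        raise ValueError("volumes must be positive")
    out = y.copy()
    ratio = v_old / v_new
    for idx in (_CA_IN, _K_IN, _H_IN, _A_IN, _ACID_IN):
        out[idx] *= ratio
    return out


def apply_dilution(activities: dict[str, float], v_old: float,
                   v_new: float) -> dict[str, float]:
    """Dilution rescale on a mapping of matrix activities."""
    if v_old <= 0 or v_new <= 0:
        raise ValueError("volumes must be positive")
    ratio = v_old / v_new
    return {k: v * ratio for k, v in activities.items()}


def derivatives(state: np.ndarray, params: ModelParameters,
                workspace: _Workspace | None = None) -> np.ndarray:
    """State-rate vector at ``state`` (one RHS evaluation, fresh workspace).

    Layout: [dpsi_mV, ca_in, k_in, h_in, a_in, acid_in, ca_out, k_out]."""
    sim = SwellingSimulator(params)
    ws = workspace or _Workspace()
    if workspace is None:
        sim._refresh_workspace(state, ws)
        s_in, s_out = sim._osmotic_sums(state, ws)
        ws.baseline_in, ws.baseline_out = s_in, s_out
        sim._refresh_workspace(state, ws)
    return sim._rhs(0.0, np.asarray(state, dtype=float), ws)


def run_simulation(params: ModelParameters, t_end_s: float | None = None,
                   ca_out_uM: float | None = None,
                   k_out_uM: float | None = None) -> Trajectory:
    """Integrate one run and return its trajectory."""
    return SwellingSimulator(params).run(t_end_s, ca_out_uM, k_out_uM)


@dataclass
class GridRunResult:
    descriptor: object
    trajectory: Trajectory | None
    summary: "object | None"
    error: str | None = None


def run_grid(params: ModelParameters, grid: ExperimentGrid | None = None,
             out_dir: str | Path | None = None,
             t_end_s: float | None = None) -> list[GridRunResult]:
    """Execute the experiment grid; per-run failures are isolated."""
    from .analysis import analyze_trajectory  # local import avoids a cycle
    grid = grid or experiment_grid(params)
    results: list[GridRunResult] = []
    for desc in grid:
        try:
            traj = run_simulation(params, t_end_s=t_end_s,
                                  ca_out_uM=desc.ca_out_uM,
                                  k_out_uM=desc.k_out_uM)
            summary = analyze_trajectory(traj)
            if out_dir is not None:
                path = Path(out_dir) / desc.output_path
                path.parent.mkdir(parents=True, exist_ok=True)
                traj.to_csv(path)
                (path.parent / "summary.json").write_text(summary.to_json())
            results.append(GridRunResult(desc, traj, summary))
        except SimulationError as exc:
            results.append(GridRunResult(desc, None, None, error=str(exc)))
    return results
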