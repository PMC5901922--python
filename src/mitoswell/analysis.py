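"""Trajectory analysis: oscillation period, modulation depth, PTP
full-opening time, extrema, and reversible/irreversible classification."""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.signal import detrend, find_peaks

from .simulator import Trajectory

#: default prominence for peak detection, as a fraction of the series range
DEFAULT_PROMINENCE_FRACTION = 0.05
#: "complete opening" threshold: the pH gate approaches 1 only
#: asymptotically, and complete opening is defined in the underlying model as
#: pH >= 7.5, where the default gate (alpha = 1.2e3, n = 4) evaluates to
#: 75/76.  A stricter cutoff (e.g. 0.999) would demand matrix pH ~8, beyond
#: the gate's saturating regime.
FULL_OPEN_THRESHOLD = 75.0 / 76.0


@dataclass(frozen=True)
class RunSummary:
    """Per-run observables in the units the model reports them."""

    oscillation_period_s: float | None
    modulation_depth_pct: float | None
    t_full_ptp_open_s: float | None
    max_p_ptp: float
    max_matrix_ca_uM: float
    max_v_rel: float
    final_dpsi_mV: float
    reversible: bool
    volume_returned: bool

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunSummary":
        return cls(**json.loads(text))


def oscillation_period(t_s: np.ndarray, series: np.ndarray,
                       prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
                       ) -> float | None:
    """Mean inter-peak interval (s) of a detrended series; None if fewer
    than three peaks of sufficient prominence are present."""
    t_s = np.asarray(t_s, dtype=float)
    series = np.asarray(series, dtype=float)
    if len(series) < 3:
        return None
    y = detrend(series)
    rng = float(np.ptp(y))
    # a trace whose residual is numerically negligible relative to its
    # overall excursion (constant or monotone drift) carries no period
    if rng <= 1e-9 * max(float(np.ptp(series)), 1e-300):
        return None
    peaks, _ = find_peaks(y, prominence=prominence_fraction * rng)
    if len(peaks) < 3:
        return None
    return float(np.mean(np.diff(t_s[peaks])))


def modulation_depth(series: np.ndarray, relative_to: str = "max") -> float:
    """Peak-to-trough modulation 100*(max - min)/max (or /mean), percent."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("series is empty")
    hi = float(np.max(series))
    lo = float(np.min(series))
    if hi <= 0.0:
        raise ValueError("modulation depth needs a positive maximum")
    denom = hi if relative_to == "max" else float(np.mean(series))
    return 100.0 * (hi - lo) / denom


def ptp_open_time(t_s: np.ndarray, p_ptp: np.ndarray,
                  threshold: float = FULL_OPEN_THRESHOLD) -> float | None:
    """First time P_PTP reaches ``threshold`` (linear-interpolated crossing);
    None if it never does."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    t_s = np.asarray(t_s, dtype=float)
    p = np.asarray(p_ptp, dtype=float)
    above = p >= threshold
    if not above.any():
        return None
    k = int(np.argmax(above))
    if k == 0:
        return float(t_s[0])
    t0, t1 = t_s[k - 1], t_s[k]
    p0, p1 = p[k - 1], p[k]
    if p1 == p0:
        return float(t1)
    return float(t0 + (threshold - p0) / (p1 - p0) * (t1 - t0))


def _post_transient(traj: Trajectory, transient_fraction: float) -> np.ndarray:
    t = traj.t_s
    return t >= transient_fraction * t[-1]


def classify_reversibility(traj: Trajectory,
                           volume_return_tol: float = 0.05) -> bool:
    """True (reversible) unless the mechanics latch fired during the run."""
    return not traj.irreversible


def analyze_trajectory(traj: Trajectory,
                       transient_fraction: float | None = None) -> RunSummary:
    """Extract the standard per-run observables from a trajectory.

    Period and modulation depth are estimated on the post-transient window
    (first 10 % of the run excluded by default, matching the reported
    sustained-oscillation measurements)."""
    if transient_fraction is None:
        if traj.params is not None:
            transient_fraction = traj.params.numerics.transient_fraction
        else:
            transient_fraction = 0.10
    mask = _post_transient(traj, transient_fraction)
    t = traj.t_s
    ca = traj.channel("ca_in_uM")
    dpsi = traj.channel("dpsi_mV")
    p_ptp = traj.channel("p_ptp")
    v_rel = traj.channel("v_rel")

    period = oscillation_period(t[mask], ca[mask])
    depth: float | None
    try:
        depth = modulation_depth(dpsi[mask])
    except ValueError:
        depth = None
    t_open = ptp_open_time(t, p_ptp)
    reversible = classify_reversibility(traj)
    final_v = float(v_rel[-1])
    volume_returned = bool(abs(final_v) <= 0.05)
    return RunSummary(
        oscillation_period_s=period,
        modulation_depth_pct=depth,
        t_full_ptp_open_s=t_open,
        max_p_ptp=float(np.max(p_ptp)),
        max_matrix_ca_uM=float(np.max(ca)),
        max_v_rel=float(np.max(v_rel)),
        final_dpsi_mV=float(dpsi[-1]),
        reversible=reversible,
        volume_returned=volume_returned,
    )


def grid_summary_table(results) -> "object":
    """Aggregate grid results into one row per run (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for res in results:
        desc = res.descriptor
        s = res.summary
        rows.append({
            "run_id": desc.run_id,
            "k_out_uM": desc.k_out_uM,
            "ca_out_uM": desc.ca_out_uM,
            "period_s": None if s is None else s.oscillation_period_s,
            "depth_pct": None if s is None else s.modulation_depth_pct,
            "t_open_s": None if s is None else s.t_full_ptp_open_s,
            "max_p_ptp": None if s is None else s.max_p_ptp,
            "max_matrix_ca_uM": None if s is None else s.max_matrix_ca_uM,
            "max_v_rel": None if s is None else s.max_v_rel,
            "reversible": None if s is None else s.reversible,
            "error": res.error,
        })
    return pd.DataFrame(rows)
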