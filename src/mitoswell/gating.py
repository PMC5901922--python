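"""PTP gating and respiration: pH-gated pore-opening probability,
respiration-activator generation, its PTP leak, and H+ extrusion.

P_PTP and W_A are instantaneous algebraic functions of state (their
equilibration is much faster than ion transport and swelling).
"""

from __future__ import annotations

import math

from .config import GatingParams, RespirationParams
from .transport import FluxResult


def ptp_open_probability(ph: float, gating: GatingParams) -> float:
    """Probability that a PTP is open at matrix pH ``ph``.

    P = alpha*x^n / (1 + alpha*x^n) with x = pH - 7 clamped at 0 from below,
    so pores are closed (P = 0) for any acidic-to-neutral matrix and approach
    P = 1 above pH ~7.5 for the default (alpha, n).
    """
    if not math.isfinite(ph):
        raise ValueError("pH must be finite")
    x = ph - 7.0
    if x <= 0.0:
        return 0.0
    g = gating.alpha * x ** gating.n_exponent
    return g / (1.0 + g)


def ptp_open_count(t: float, k_op: float, k_cl: float, n_total: int,
                   n_open0: float = 0.0) -> float:
    """Two-state open/close pore-count kinetics (reference implementation).

    Closed form of dn_op/dt = k_op*(n_total - n_op) - k_cl*n_op:

        n_op(t) = n_ss + (n_op(0) - n_ss)*exp(-(k_op+k_cl)*t),
        n_ss = n_total*k_op/(k_op + k_cl).

    Kept as an independent reference; the simulator gates pores by matrix pH
    instead (the rate constants are not part of the parameterization).
    """
    if k_op < 0 or k_cl < 0:
        raise ValueError("rate constants must be >= 0")
    rate = k_op + k_cl
    if rate == 0.0:
        return n_open0
    n_ss = n_total * k_op / rate
    return n_ss + (n_open0 - n_ss) * math.exp(-rate * t)


def activator_generation_rate(dpsi: float, resp: RespirationParams) -> float:
    """Generation rate of the respiration activator A (uM/min).

    W_A = k_A*a_A0*(1 - exp(-dpsi/delta)); zero at dpsi <= 0 (a depolarized
    IMM cannot drive respiration) and saturating at k_A*a_A0.
    """
    if dpsi <= 0.0:
        return 0.0
    return resp.k_a * resp.a_a0 * (1.0 - math.exp(-dpsi / resp.delta_dpsi))


def calibrate_delta(dpsi_ref: float, fraction: float) -> float:
    """Saturation constant delta such that W_A reaches ``fraction`` of its
    maximum at ``dpsi_ref``: delta = -dpsi_ref/ln(1 - fraction)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    return -dpsi_ref / math.log1p(-fraction)


def activator_ptp_flux(a_a: float, p_ptp_open: float, n_ptp: int,
                       p_a_ptp: float) -> FluxResult:
    """One-sided leak of the activator out of the matrix through open PTPs.

    Net influx = -p_A,PTP * P_open * n * a_A (always an efflux; there is no
    cytosolic activator pool).
    """
    if a_a < 0:
        raise ValueError("activity must be >= 0")
    if not 0.0 <= p_ptp_open <= 1.0:
        raise ValueError("p_ptp_open must lie in [0, 1]")
    return FluxResult(species="activator",
                      value=-p_a_ptp * p_ptp_open * n_ptp * a_a)


def proton_generation_rate(a_a: float, resp: RespirationParams) -> float:
    """Rate of respiration-driven H+ extrusion, W_H+,A = k_A,H+ * a_A.

    Each event consumes one activator molecule in the matrix and ejects one
    H+ across the IMM (the reduced co-product takes no further part).
    """
    if a_a < 0:
        raise ValueError("activity must be >= 0")
    return resp.k_a_h * a_a
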