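"""Core ODE/algebraic model of cell-free gene expression.

The model tracks three species — mRNA ``m``, immature reporter
``deGFP_dark`` and fluorescent reporter ``deGFP_mat`` — with
Michaelis-Menten transcription, translation and mRNA degradation, coupled to
two algebraic conservation laws that partition the finite pools of core RNA
polymerase (E_total) and ribosomes (R_total) between free, promoter-bound /
initiating, and elongating forms:

    dm/dt    = kcat_m * P70 * E0*S70 / (KM_70*(K70 + E0) + E0*S70)
               - kd_m * m / (KM_m + m)
    ddark/dt = kcat_p * m * R0 / (KM_R + R0) - k_mat * dark
    dmat/dt  = k_mat * dark

    E_total  = E0 + E0*S70/(K70 + E0)
               + E0*S70*P70/(KM_70*(K70 + E0) + E0*S70) * (1 + kcat_m*Lm/Cm)
    R_total  = R0 + R0*m/(KM_R + R0) * (1 + kcat_p*Lm/Cp)

The polymerase balance depends only on the (constant) plasmid concentration,
so the free-polymerase level E0 is solved once per parameter set by bracketed
root finding; the ribosome balance depends on the instantaneous mRNA level
and reduces to a quadratic in R0 solved in closed form at every right-hand
side evaluation.

Saturation of protein synthesis with increasing plasmid arises from ribosome
depletion: once the elongation demand m * (1 + kcat_p*Lm/Cp) approaches
R_total, free ribosomes crash and the rate stops growing. Transcription
never saturates in the plasmid range of interest.
"""

from __future__ import annotations

import math
import warnings
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import (
    KineticsTrace,
    ModelState,
    RateCurve,
    ResourceAllocation,
    TXTLParameters,
)

__all__ = [
    "solve_free_rnap",
    "solve_free_ribosomes",
    "holoenzyme",
    "transcription_initiation_rate",
    "ode_rhs",
    "simulate_kinetics",
    "mrna_steady_state",
    "steady_state_mrna_exact",
    "steady_state_rate",
    "linear_regime_protein_rate",
    "max_synthesis_rate",
    "rate_vs_plasmid",
]

#: Conservation solves are converged to this residual (nM).
CONSERVATION_TOL = 1e-9


# ---------------------------------------------------------------------------
# algebraic resource allocation
# ---------------------------------------------------------------------------

def holoenzyme(E0: float, params: TXTLParameters) -> float:
    """Holoenzyme concentration E70 given free core polymerase E0 (nM).

    The sigma-factor/core binding equilibrium gives
    E70 = E0 * S70_total / (K70 + E0), a saturating function of E0 bounded
    by the total sigma-70 pool.
    """
    if E0 < 0:
        raise ValueError("E0 must be non-negative")
    return E0 * params.S70_total / (params.K70 + E0)


def _rnap_conservation_residual(E0: float, p: TXTLParameters) -> float:
    """Total polymerase implied by E0, minus E_total.

    Strictly increasing in E0 on [0, E_total], so the root is unique.
    """
    e70 = E0 * p.S70_total / (p.K70 + E0)
    denom = p.KM_70 * (p.K70 + E0) + E0 * p.S70_total
    em = (E0 * p.S70_total * p.P70 / denom) * p.tx_occupancy
    return E0 + e70 + em - p.E_total


def solve_free_rnap(params: TXTLParameters, tol: float = CONSERVATION_TOL) -> ResourceAllocation:
    """Solve the polymerase conservation law for the free core level E0.

    E0 depends only on the constants and the plasmid concentration (not on
    the mRNA level), so one solve per parameter set suffices. The residual
    is bracketed on [0, E_total] and solved with Brent's method.

    Returns a :class:`ResourceAllocation` with the E-side fields
    (E0, E70, Em, S70_free) populated.
    """
    p = params
    lo, hi = 0.0, p.E_total
    f_lo = _rnap_conservation_residual(lo, p)
    f_hi = _rnap_conservation_residual(hi, p)
    if f_lo > 0 or f_hi < 0:
        raise RuntimeError(
            f"free-polymerase root not bracketed on [0, {p.E_total}] nM "
            f"(residuals {f_lo:.3g}, {f_hi:.3g})"
        )
    E0 = brentq(_rnap_conservation_residual, lo, hi, args=(p,), xtol=min(tol, 1e-12), rtol=8.9e-16)
    E70 = holoenzyme(E0, p)
    denom = p.KM_70 * (p.K70 + E0) + E0 * p.S70_total
    Em = (E0 * p.S70_total * p.P70 / denom) * p.tx_occupancy
    return ResourceAllocation(E0=E0, E70=E70, Em=Em, S70_free=p.S70_total - E70)


def solve_free_ribosomes(
    params: TXTLParameters, m: float, tol: float = CONSERVATION_TOL
) -> ResourceAllocation:
    """Solve the ribosome conservation law for free ribosomes R0 at mRNA level m.

    The balance R_total = R0 + R0*m/(KM_R + R0) * occupancy is a quadratic
    in R0:

        R0^2 + R0*(KM_R + m*occ - R_total) - KM_R*R_total = 0

    whose positive root is taken in a cancellation-safe form. ``tol`` is
    kept for interface symmetry; the closed form is exact to rounding.
    """
    if m < 0:
        raise ValueError("mRNA concentration must be non-negative")
    p = params
    b = p.KM_R + m * p.tl_occupancy - p.R_total
    c = p.KM_R * p.R_total
    disc = math.sqrt(b * b + 4.0 * c)
    # two algebraically equal forms; pick the one that avoids subtracting
    # nearly equal numbers
    R0 = (disc - b) / 2.0 if b <= 0 else 2.0 * c / (disc + b)
    R0 = min(R0, p.R_total)
    return ResourceAllocation(R0=R0, Rm=p.R_total - R0)


def allocate_resources(params: TXTLParameters, m: float) -> ResourceAllocation:
    """Full machinery partition (both polymerase and ribosome sides) at mRNA m."""
    return solve_free_rnap(params).merged(solve_free_ribosomes(params, m))


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def transcription_initiation_rate(params: TXTLParameters, E0: float | None = None) -> float:
    """Effective transcription initiation frequency k_TX (1/s).

    k_TX = kcat_m * E0*S70 / (KM_70*(K70 + E0) + E0*S70); equals kcat_m in
    the limit where free polymerase is an infinite reservoir and the
    holoenzyme saturates its Michaelis constant.
    """
    p = params
    if E0 is None:
        E0 = solve_free_rnap(p).E0
    denom = p.KM_70 * (p.K70 + E0) + E0 * p.S70_total
    return p.kcat_m * E0 * p.S70_total / denom


def ode_rhs(
    state: ModelState, params: TXTLParameters, allocation: ResourceAllocation
) -> ModelState:
    """Time derivative of the model state, given a resource allocation.

    The allocation must be consistent with ``state.m`` (its R0 solved at the
    same mRNA level). Returns the derivatives packed in a ModelState (time
    field carries dt = 1 by convention).
    """
    p = params
    E0, R0 = allocation.E0, allocation.R0
    if E0 is None or R0 is None:
        raise ValueError("allocation must carry both E0 and R0")
    denom = p.KM_70 * (p.K70 + E0) + E0 * p.S70_total
    dm = p.kcat_m * p.P70 * E0 * p.S70_total / denom - p.kd_m * state.m / (p.KM_m + state.m)
    ddark = p.kcat_p * state.m * R0 / (p.KM_R + R0) - p.k_mat * state.deGFP_dark
    dmat = p.k_mat * state.deGFP_dark
    return ModelState(m=dm, deGFP_dark=ddark, deGFP_mat=dmat, time=1.0)


def _make_rhs(params: TXTLParameters, E0: float) -> Callable[[float, np.ndarray], list]:
    """Fast RHS closure for the integrator; re-solves R0 at every call."""
    p = params
    ktx_p70 = transcription_initiation_rate(p, E0) * p.P70
    occ = p.tl_occupancy

    def rhs(t: float, y: np.ndarray) -> list:
        m = max(y[0], 0.0)
        b = p.KM_R + m * occ - p.R_total
        c = p.KM_R * p.R_total
        disc = math.sqrt(b * b + 4.0 * c)
        R0 = (disc - b) / 2.0 if b <= 0 else 2.0 * c / (disc + b)
        dm = ktx_p70 - p.kd_m * m / (p.KM_m + m)
        ddark = p.kcat_p * m * R0 / (p.KM_R + R0) - p.k_mat * y[1]
        return [dm, ddark, p.k_mat * y[1]]

    return rhs


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_kinetics(
    params: TXTLParameters,
    t_end: float,
    t_step: float = 180.0,
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> KineticsTrace:
    """Integrate the expression ODEs from a fresh reaction (all species zero).

    The stiff-capable LSODA integrator is used with tight tolerances
    (rtol 1e-8, atol 1e-9 nM); output is reported on a fixed grid every
    ``t_step`` seconds (default 180 s, matching plate-reader sampling).
    The free-polymerase level is solved once; the free-ribosome level is
    re-solved in closed form inside every right-hand-side call, so both
    conservation laws hold along the whole trajectory.

    Only the transient and steady-state phases are modelled; the late
    plateau from nutrient depletion is outside the model's scope.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    p = params
    E0 = solve_free_rnap(p).E0
    times = np.arange(0.0, t_end + 0.5 * t_step, t_step)
    if times[-1] > t_end:
        times = times[:-1]
    sol = solve_ivp(
        _make_rhs(p, E0),
        (0.0, times[-1] if times.size else t_end),
        [0.0, 0.0, 0.0],
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(f"ODE integration failed near t = {t_fail:.1f} s: {sol.message}")
    y = np.clip(sol.y, 0.0, None)  # clip integrator noise at -atol scale
    m = y[0]
    if m.size and m.max() > p.KM_m / 10.0:
        warnings.warn(
            f"simulated mRNA reached {m.max():.0f} nM, above KM_m/10 = "
            f"{p.KM_m / 10:.0f} nM; the first-order-decay reparameterization "
            "assumes KM_m >> [m]",
            UserWarning,
            stacklevel=2,
        )
    R0 = np.array([solve_free_ribosomes(p, mi).R0 for mi in m])
    return KineticsTrace(
        times=times, m=m, deGFP_dark=y[1], deGFP_mat=y[2], E0=E0, R0=R0, params=p
    )


# ---------------------------------------------------------------------------
# steady-state analysis
# ---------------------------------------------------------------------------

def mrna_steady_state(params: TXTLParameters) -> float:
    """Steady-state mRNA level, nM: k_TX/k_deg,m * P70.

    Uses the full initiation frequency (with the solved free-polymerase
    level) and the effective first-order decay rate kd_m/KM_m. Valid in the
    regime [m] << KM_m where degradation is effectively first order.
    """
    return transcription_initiation_rate(params) / params.kdeg_m * params.P70


def steady_state_mrna_exact(params: TXTLParameters) -> float:
    """Steady-state mRNA with the Michaelis-Menten degradation term kept exact.

    Balances k_TX*P70 = kd_m*m/(KM_m + m); diverges (returns inf) when the
    synthesis flux reaches the degradation Vmax kd_m.
    """
    flux = transcription_initiation_rate(params) * params.P70
    if flux >= params.kd_m:
        return math.inf
    return flux * params.KM_m / (params.kd_m - flux)


def steady_state_rate(params: TXTLParameters) -> float:
    """Regime-II protein synthesis rate, nM/s, without integrating the ODEs.

    At steady state the mature-reporter accumulation rate equals the
    synthesis flux kcat_p * m_ss * R0/(KM_R + R0) with R0 solved from the
    ribosome balance at m_ss. This closed form is what parameter fits and
    the load calculator evaluate; it matches the sliding-window slope of a
    full simulation to within a few percent.
    """
    m_ss = steady_state_mrna_exact(params)
    if math.isinf(m_ss):
        # degradation saturated: ribosome-limited ceiling kcat_p*R_total/occ
        return params.kcat_p * params.R_total / params.tl_occupancy
    R0 = solve_free_ribosomes(params, m_ss).R0
    return params.kcat_p * m_ss * R0 / (params.KM_R + R0)


def linear_regime_protein_rate(params: TXTLParameters) -> float:
    """Low-plasmid analytic rate of mature-reporter accumulation, nM/s.

    In the linear regime the reporter accumulates as
    kcat_p * kcat_m / k_deg,m * P70 * t, so the rate is the prefactor.
    """
    return params.kcat_p * params.kcat_m / params.kdeg_m * params.P70


# ---------------------------------------------------------------------------
# rate extraction and rate curves
# ---------------------------------------------------------------------------

def max_synthesis_rate(
    trace: KineticsTrace, window: float = 1800.0, burn_in: float = 1800.0
) -> float:
    """Maximum protein synthesis rate from a kinetics trace, nM/s.

    Operationalized as the maximum over the trace of the least-squares slope
    of the mature reporter in a sliding window (default 30 min), restricted
    to t >= ``burn_in`` (default 30 min) to skip the initial transient. This
    mirrors how a maximum rate is read off measured fluorescence kinetics.
    """
    t, y = trace.times, trace.deGFP_mat
    if t.size < 2 or t[-1] - max(t[0], burn_in) < 2 * window:
        raise ValueError("trace must cover at least two windows past the burn-in")
    start = int(np.searchsorted(t, burn_in))
    dt = t[1] - t[0]
    npts = max(int(round(window / dt)) + 1, 2)
    best = -math.inf
    for i in range(start, t.size - npts + 1):
        tw = t[i : i + npts]
        yw = y[i : i + npts]
        slope = np.polyfit(tw, yw, 1)[0]
        best = max(best, slope)
    return float(best)


def rate_vs_plasmid(
    params: TXTLParameters,
    plasmid_grid: Sequence[float],
    t_end: float = 4 * 3600.0,
    t_step: float = 180.0,
    window: float = 1800.0,
    linear_tol: float = 0.10,
) -> RateCurve:
    """Maximum synthesis rate across a grid of plasmid concentrations.

    Each concentration is simulated and its maximum sliding-window slope
    extracted. Points whose rate-per-plasmid stays within ``linear_tol``
    (default 10%) of the low-concentration limit are labelled "linear", the
    rest "saturated"; the through-origin slope over the linear points is
    reported as ``slope_linear``.
    """
    grid = np.asarray(list(plasmid_grid), dtype=float)
    if grid.size < 1 or np.any(np.diff(grid) < 0):
        raise ValueError("plasmid grid must be sorted")
    rates = np.empty_like(grid)
    for i, conc in enumerate(grid):
        if conc == 0.0:
            rates[i] = 0.0
            continue
        trace = simulate_kinetics(params.replace(P70=conc), t_end=t_end, t_step=t_step)
        rates[i] = max_synthesis_rate(trace, window=window)
    labels = _label_regimes(grid, rates, linear_tol)
    linear = (grid > 0) & (np.asarray(labels) == "linear")
    slope = None
    if linear.any():
        slope = float(np.sum(rates[linear] * grid[linear]) / np.sum(grid[linear] ** 2))
    return RateCurve(plasmid_concs=grid, max_rates=rates, regime_labels=labels, slope_linear=slope)


def _label_regimes(grid: np.ndarray, rates: np.ndarray, tol: float) -> list:
    """Label points linear/saturated against the low-concentration rate ratio."""
    pos = grid > 0
    if not pos.any():
        return ["linear"] * grid.size
    ref = rates[pos][0] / grid[pos][0]
    labels = []
    for conc, rate in zip(grid, rates):
        if conc == 0 or ref == 0:
            labels.append("linear")
        else:
            labels.append("linear" if abs(rate / conc - ref) <= tol * ref else "saturated")
    return labels
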