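"""Fitting model constants to kinetics and rate-curve data.

Covers the assays and fits the model is constrained by: first-order mRNA
decay (mean lifetime), first-order reporter maturation, closed-form
inversions of the steady-state relations, joint (kcat_m, kcat_p) fits to
rate-vs-plasmid curves, and part-strength tables (rate per nM plasmid in
the linear regime, normalized to the reference promoter/UTR pair).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from .model import steady_state_rate
from .params import TXTLParameters

__all__ = [
    "DecayTrace",
    "RateCurveData",
    "FitResult",
    "fit_exponential_decay",
    "fit_maturation",
    "ktx_from_mrna_steady_state",
    "kcat_product_from_rate",
    "fit_kcats_to_rate_curve",
    "part_strength_table",
]


@dataclass
class DecayTrace:
    """A decay or relaxation time series (times s, signal nM or a.u.)."""

    times: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.size != self.signal.size:
            raise ValueError("times and signal lengths differ")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")


@dataclass
class RateCurveData:
    """Measured maximum synthesis rates over a plasmid dilution series."""

    plasmid_concs: np.ndarray
    measured_max_rates: np.ndarray
    promoter_label: str = ""
    utr_label: str = ""

    def __post_init__(self) -> None:
        self.plasmid_concs = np.asarray(self.plasmid_concs, dtype=float)
        self.measured_max_rates = np.asarray(self.measured_max_rates, dtype=float)
        if self.plasmid_concs.size != self.measured_max_rates.size:
            raise ValueError("lengths differ")
        if np.any(np.diff(self.plasmid_concs) < 0):
            raise ValueError("plasmid concentrations must be sorted")


@dataclass
class FitResult:
    """Outcome of a fit: parameter estimates, residual, convergence, bounds."""

    params: dict
    rss: float
    converged: bool
    bounds: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("residual sum of squares must be non-negative")

    def to_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "rss": self.rss,
            "converged": self.converged,
            "bounds": dict(self.bounds),
            "notes": list(self.notes),
        }


# ---------------------------------------------------------------------------
# single-exponential fits
# ---------------------------------------------------------------------------

def fit_exponential_decay(trace: DecayTrace) -> FitResult:
    """Fit A*exp(-k*t); returns k (1/s), amplitude and mean lifetime 1/k.

    When every signal value is positive the fit runs as linear least squares
    in log space (exact for noiseless data); otherwise a nonlinear fit with
    a log-space initial guess is used.
    """
    t, y = trace.times, trace.signal
    if t.size < 2:
        raise ValueError("need at least 2 points")
    if not np.any(y > 0):
        raise ValueError("signal is non-positive everywhere")
    if np.all(y > 0):
        slope, intercept = np.polyfit(t, np.log(y), 1)
        k, A = -slope, math.exp(intercept)
        converged = True
    else:
        pos = y > 0
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        try:
            (A, k), _ = curve_fit(
                lambda tt, a, kk: a * np.exp(-kk * tt),
                t, y, p0=(math.exp(intercept), max(-slope, 1e-9)), maxfev=10000,
            )
            converged = True
        except RuntimeError as exc:
            raise RuntimeError(f"decay fit did not converge: {exc}") from exc
    resid = y - A * np.exp(-k * t)
    return FitResult(
        params={"k": float(k), "amplitude": float(A), "mean_lifetime": float(1.0 / k)},
        rss=float(np.sum(resid**2)),
        converged=converged,
    )


def fit_maturation(trace: DecayTrace) -> FitResult:
    """Fit the post-translation-arrest fluorescence rise F_inf*(1 - exp(-k_mat*t))."""
    t, y = trace.times, trace.signal
    if t.size < 3:
        raise ValueError("need at least 3 points")
    f_inf0 = float(y.max()) or 1.0
    # half-rise time as the k guess
    above = np.nonzero(y >= 0.5 * f_inf0)[0]
    t_half = t[above[0]] if above.size and t[above[0]] > 0 else (t[-1] / 2 or 1.0)
    try:
        (f_inf, k), _ = curve_fit(
            lambda tt, fi, kk: fi * (1.0 - np.exp(-kk * tt)),
            t, y, p0=(f_inf0, math.log(2.0) / t_half), maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"maturation fit did not converge: {exc}") from exc
    resid = y - f_inf * (1.0 - np.exp(-k * t))
    return FitResult(
        params={"k_mat": float(k), "F_inf": float(f_inf)},
        rss=float(np.sum(resid**2)),
        converged=True,
    )


# ---------------------------------------------------------------------------
# closed-form inversions of the steady-state relations
# ---------------------------------------------------------------------------

def ktx_from_mrna_steady_state(m_ss: float, plasmid: float, mean_lifetime: float) -> float:
    """Transcription initiation frequency from a measured mRNA steady state.

    Inverts m_ss = k_TX/k_deg,m * P70 with k_deg,m = 1/mean_lifetime:
    k_TX = m_ss / (plasmid * mean_lifetime), in 1/s.
    """
    if plasmid <= 0:
        raise ValueError("plasmid concentration must be positive")
    if mean_lifetime <= 0:
        raise ValueError("mean lifetime must be positive")
    if m_ss < 0:
        raise ValueError("m_ss must be non-negative")
    return m_ss / (plasmid * mean_lifetime)


def kcat_product_from_rate(max_rate: float, plasmid: float, kdeg_m: float) -> float:
    """kcat_p*kcat_m (1/s^2) from a linear-regime maximum synthesis rate.

    Inverts rate = kcat_p*kcat_m/k_deg,m * P70.
    """
    if plasmid <= 0:
        raise ValueError("plasmid concentration must be positive")
    if kdeg_m <= 0:
        raise ValueError("kdeg_m must be positive")
    if max_rate < 0:
        raise ValueError("max_rate must be non-negative")
    return max_rate * kdeg_m / plasmid


# ---------------------------------------------------------------------------
# rate-curve fitting
# ---------------------------------------------------------------------------

KCAT_BOUNDS = (1e-6, 0.5)  # 1/s; upper bound = initiation-frequency ceiling


def fit_kcats_to_rate_curve(
    data: RateCurveData,
    base_params: TXTLParameters,
    seed: int = 0,
    n_starts: int = 3,
) -> FitResult:
    """Fit (kcat_m, kcat_p) to a measured rate-vs-plasmid curve.

    The Michaelis constants are held fixed — the rate curves are only weakly
    sensitive to their magnitudes, and many (kcat, KM) pairs fit equally
    well — so promoter and UTR strength differences are absorbed entirely
    into kcat_m and kcat_p. The fit is bounded least squares in log space
    (bounds ``KCAT_BOUNDS``) against the model's regime-II steady-state
    rate, with multi-start (jitter spread one decade around the initial
    guess, seeded).

    When the measured curve never leaves the linear regime only the product
    kcat_m*kcat_p is constrained; an identifiability note is attached.
    """
    concs = data.plasmid_concs
    rates = data.measured_max_rates
    if concs.size < 4:
        raise ValueError("need at least 4 concentrations")
    if not np.any(rates > 0):
        raise ValueError("all measured rates are zero; nothing to fit")

    pos = concs > 0

    def predict(log10_kcats: np.ndarray) -> np.ndarray:
        km, kp = 10.0 ** log10_kcats
        p = base_params.replace(kcat_m=km, kcat_p=kp)
        return np.array(
            [steady_state_rate(p.replace(P70=c)) if c > 0 else 0.0 for c in concs]
        )

    def resid(x: np.ndarray) -> np.ndarray:
        return predict(x) - rates

    x0 = np.log10([base_params.kcat_m, base_params.kcat_p])
    lo, hi = np.log10(KCAT_BOUNDS[0]), np.log10(KCAT_BOUNDS[1])
    rng = np.random.default_rng(seed)
    starts = [x0] + [
        np.clip(x0 + rng.uniform(-0.5, 0.5, size=2), lo, hi) for _ in range(n_starts - 1)
    ]
    best = None
    for s in starts:
        res = least_squares(resid, s, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        if best is None or res.cost < best.cost:
            best = res
    km, kp = 10.0 ** best.x
    notes = []
    if not _curve_saturates(concs[pos], rates[pos]):
        notes.append(
            "rate curve never leaves the linear regime: only the product "
            "kcat_m*kcat_p is identifiable; individual values are not."
        )
    return FitResult(
        params={"kcat_m": float(km), "kcat_p": float(kp), "kcat_product": float(km * kp)},
        rss=float(2 * best.cost),
        converged=bool(best.status > 0),
        bounds={"kcat_m": KCAT_BOUNDS, "kcat_p": KCAT_BOUNDS},
        notes=notes,
    )


def _curve_saturates(concs: np.ndarray, rates: np.ndarray, tol: float = 0.10) -> bool:
    """True if any point's rate/plasmid falls below the low-conc limit by > tol."""
    if concs.size < 2:
        return False
    ref = rates[0] / concs[0]
    if ref == 0:
        return False
    return bool(np.any(rates / concs < (1.0 - tol) * ref))


# ---------------------------------------------------------------------------
# part strengths
# ---------------------------------------------------------------------------

SECONDS_PER_HOUR = 3600.0


def part_strength_table(
    curves: Sequence[RateCurveData],
    reference: tuple = ("P70a", "UTR1"),
    linear_tol: float = 0.10,
) -> pd.DataFrame:
    """Rate-per-plasmid strength table for a set of promoter/UTR constructs.

    For each construct the through-origin regression slope over its
    linear-regime points is reported in nM deGFP per hour per nM plasmid,
    with relative strengths normalized to the reference construct
    (default the strongest pair, P70a + UTR1). Raises if a curve has no
    linear-regime points.
    """
    rows = []
    for cur in curves:
        concs, rates = cur.plasmid_concs, cur.measured_max_rates
        pos = concs > 0
        if not pos.any():
            raise ValueError(f"{cur.promoter_label}/{cur.utr_label}: no positive concentrations")
        ref_ratio = rates[pos][0] / concs[pos][0]
        linear = pos & (np.abs(rates - ref_ratio * concs) <= linear_tol * ref_ratio * concs)
        if ref_ratio <= 0 or not linear.any():
            raise ValueError(f"{cur.promoter_label}/{cur.utr_label}: no linear-regime points")
        slope = float(
            np.sum(rates[linear] * concs[linear]) / np.sum(concs[linear] ** 2)
        )
        rows.append(
            {
                "promoter": cur.promoter_label,
                "utr": cur.utr_label,
                "rate_per_plasmid_nM_per_h_per_nM": slope * SECONDS_PER_HOUR,
                "n_linear_points": int(linear.sum()),
            }
        )
    table = pd.DataFrame(rows)
    ref_rows = table[(table["promoter"] == reference[0]) & (table["utr"] == reference[1])]
    ref_slope = (
        float(ref_rows["rate_per_plasmid_nM_per_h_per_nM"].iloc[0])
        if len(ref_rows)
        else float(table["rate_per_plasmid_nM_per_h_per_nM"].max())
    )
    table["relative_strength"] = table["rate_per_plasmid_nM_per_h_per_nM"] / ref_slope
    return table
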