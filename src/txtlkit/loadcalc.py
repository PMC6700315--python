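"""DNA load calculator: when does translation capacity saturate?

Above a construct-dependent DNA concentration, the free-ribosome pool
collapses onto the mRNA and protein synthesis stops scaling with template.
The calculator condenses the full model into a power law for that limiting
DNA concentration,

    [DNA]_lim = A * P^a * U^b * Lm^c                      (nM)

where P is the promoter strength relative to the reference promoter
(strength 1), U the UTR strength relative to the reference UTR, and Lm the
gene length in nucleotides. The published fit is
A = 250, a = -0.987, b = -0.352, c = -0.583. ``derive_power_law``
re-derives such a fit from the model itself by sweeping each variable,
locating the concentration where the rate departs 10% from linearity, and
fitting log-log lines. Budgeting across constructs is plain bookkeeping:
each construct consumes planned/limiting of the translation capacity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import steady_state_rate
from .params import TXTLParameters

__all__ = [
    "ConstructSpec",
    "PowerLawFit",
    "PUBLISHED_POWER_LAW",
    "limiting_dna",
    "find_limiting_conc",
    "derive_power_law",
    "budget_constructs",
    "LoadWarning",
]


class LoadWarning(UserWarning):
    """Combined construct load exceeds the translation capacity."""


@dataclass(frozen=True)
class ConstructSpec:
    """One DNA construct for load budgeting.

    P, U: promoter/UTR strengths relative to the reference parts (1 = as
    strong as the reference); Lm: gene length in nt; planned_conc: nM to be
    added to the reaction.
    """

    P: float = 1.0
    U: float = 1.0
    Lm: float = 800.0
    planned_conc: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.P <= 0 or self.U <= 0 or self.Lm <= 0:
            raise ValueError("P, U and Lm must be positive")
        if self.planned_conc < 0:
            raise ValueError("planned_conc must be non-negative")


@dataclass(frozen=True)
class PowerLawFit:
    """Power-law description of the limiting DNA concentration."""

    prefactor: float
    exp_P: float
    exp_U: float
    exp_Lm: float
    residuals: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.exp_P >= 0 or self.exp_U >= 0 or self.exp_Lm >= 0:
            raise ValueError("exponents must be negative: more demand lowers the limit")


#: Published fit: 250 * P^-0.987 * U^-0.352 * Lm^-0.583 (nM, Lm in nt).
PUBLISHED_POWER_LAW = PowerLawFit(prefactor=250.0, exp_P=-0.987, exp_U=-0.352, exp_Lm=-0.583)


def limiting_dna(spec: ConstructSpec, fit: PowerLawFit = PUBLISHED_POWER_LAW) -> float:
    """Limiting DNA concentration (nM) for one construct under a power-law fit."""
    return (
        fit.prefactor
        * spec.P ** fit.exp_P
        * spec.U ** fit.exp_U
        * spec.Lm ** fit.exp_Lm
    )


# ---------------------------------------------------------------------------
# model-based derivation
# ---------------------------------------------------------------------------

def find_limiting_conc(
    params: TXTLParameters,
    departure: float = 0.10,
    c_probe: float = 1e-3,
    c_max: float = 2000.0,
) -> float:
    """Plasmid concentration where the model rate departs ``departure`` from linear.

    The low-concentration slope is probed at ``c_probe`` nM; the limiting
    concentration solves rate(c) = (1 - departure) * slope0 * c by bracketed
    root finding on the closed-form regime-II rate.
    """
    slope0 = steady_state_rate(params.replace(P70=c_probe)) / c_probe

    def excess(c: float) -> float:
        return steady_state_rate(params.replace(P70=c)) - (1.0 - departure) * slope0 * c

    lo = c_probe
    hi = 2.0 * c_probe
    while excess(hi) > 0:
        hi *= 2.0
        if hi > c_max:
            raise RuntimeError(
                f"rate never departs {departure:.0%} from linearity below {c_max} nM"
            )
    return float(brentq(excess, lo, hi, xtol=1e-6))


def _loglog_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and residual RMS of log y vs log x."""
    coef, res, *_ = np.polyfit(np.log(x), np.log(y), 1, full=True)
    rms = math.sqrt(res[0] / x.size) if len(res) else 0.0
    return float(coef[0]), rms


def derive_power_law(
    base: TXTLParameters,
    promoter_strengths: Sequence[float] = tuple(np.geomspace(0.1, 1.0, 7)),
    utr_strengths: Sequence[float] = tuple(np.geomspace(0.1, 1.0, 7)),
    gene_lengths: Sequence[float] = tuple(np.geomspace(200.0, 2000.0, 7)),
    reference_length: float = 800.0,
    departure: float = 0.10,
) -> PowerLawFit:
    """Re-derive the limiting-DNA power law from the model.

    Promoter strength scales kcat_m, UTR strength scales kcat_p (the same
    convention the rate-curve fits use), and gene length enters the
    occupancy terms directly. Each variable is swept one at a time (>= 5
    points over >= 1 decade required), the limiting concentration located
    per point, and a log-log line fitted; the prefactor is normalized so the
    reference construct (P = U = 1, Lm = ``reference_length``) maps onto the
    base model's own limiting concentration.

    Default sweep ranges: strengths 0.1-1 (part sets run downward from the
    reference over about a decade per fit) and lengths 200-2000 nt (a decade
    around the 800 nt reporter gene).
    """
    sweeps = {
        "P": np.asarray(promoter_strengths, dtype=float),
        "U": np.asarray(utr_strengths, dtype=float),
        "Lm": np.asarray(gene_lengths, dtype=float),
    }
    for name, grid in sweeps.items():
        if grid.size < 5:
            raise ValueError(f"{name} sweep needs >= 5 points (got {grid.size})")
        if grid.max() / grid.min() < 10.0 - 1e-9:
            raise ValueError(f"{name} sweep must span at least one decade")

    ref = base.replace(Lm=reference_length)

    def limit_for(name: str, value: float) -> float:
        if name == "P":
            p = ref.replace(kcat_m=base.kcat_m * value)
        elif name == "U":
            p = ref.replace(kcat_p=base.kcat_p * value)
        else:
            p = ref.replace(Lm=value)
        return find_limiting_conc(p, departure=departure)

    exponents: Dict[str, float] = {}
    residuals: Dict[str, float] = {}
    for name, grid in sweeps.items():
        limits = np.array([limit_for(name, v) for v in grid])
        exponents[name], residuals[name] = _loglog_slope(grid, limits)

    ref_limit = find_limiting_conc(ref, departure=departure)
    prefactor = ref_limit / reference_length ** exponents["Lm"]
    return PowerLawFit(
        prefactor=float(prefactor),
        exp_P=exponents["P"],
        exp_U=exponents["U"],
        exp_Lm=exponents["Lm"],
        residuals=residuals,
    )


# ---------------------------------------------------------------------------
# multi-construct budgeting
# ---------------------------------------------------------------------------

def budget_constructs(
    constructs: Sequence[ConstructSpec], fit: PowerLawFit = PUBLISHED_POWER_LAW
) -> pd.DataFrame:
    """Ribosome-load bookkeeping across several co-expressed constructs.

    Each construct consumes planned_conc / limiting_dna of the translation
    capacity; the remaining limiting concentration of each construct is its
    single-construct limit scaled by the capacity left over by the others.
    A :class:`LoadWarning` is emitted when the summed load exceeds 100%.
    """
    if not constructs:
        raise ValueError("construct list is empty")
    limits = np.array([limiting_dna(s, fit) for s in constructs])
    fractions = np.array([s.planned_conc for s in constructs]) / limits
    total = float(fractions.sum())
    if total > 1.0:
        warnings.warn(
            f"planned constructs use {total:.0%} of the translation capacity; "
            "expression will saturate",
            LoadWarning,
            stacklevel=2,
        )
    rows = []
    for i, (spec, lim, frac) in enumerate(zip(constructs, limits, fractions)):
        others = total - frac
        rows.append(
            {
                "name": spec.name or f"construct_{i + 1}",
                "planned_nM": spec.planned_conc,
                "limiting_nM": float(lim),
                "load_fraction": float(frac),
                "remaining_limit_nM": float(lim * max(1.0 - others, 0.0)),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["total_load"] = total
    return out
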