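"""Biochemical parameters and core data containers for the TXTL expression model.

All concentrations are in nM and all times in seconds throughout the package;
hours appear only at reporting boundaries (e.g. part-strength tables in
deGFP/h/nM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "TXTLParameters",
    "ResourceAllocation",
    "ModelState",
    "KineticsTrace",
    "RateCurve",
    "RateLimitWarning",
]

#: Physiological ceiling on initiation rate constants (1/s): transcription
#: initiation tops out around 30 initiations per minute, and translation
#: initiation around 0.5 1/s; values above this are flagged, not rejected.
KCAT_CEILING = 0.5


class RateLimitWarning(UserWarning):
    """A rate constant exceeds its physiological ceiling (still accepted)."""


class TXTLParameters(BaseModel):
    """Constants of the three-ODE cell-free expression model.

    Defaults are the best-fit constants for the sigma-70 reference construct
    (strong promoter + strongest bacterial UTR, deGFP reporter) in the
    all-*E. coli* cell-free system, except ``k_mat``, whose default of
    1.2e-3 1/s (~14 min maturation) is a documented placeholder rather than
    a measured value; no headline quantity depends on it.

    Units: concentrations nM, times s, speeds nt/s.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    kcat_m: float = Field(6.5e-2, gt=0, description="TX rate constant, 1/s")
    KM_70: float = Field(1.0, gt=0, description="TX Michaelis constant, nM")
    K70: float = Field(0.26, gt=0, description="sigma70-core RNAP dissociation constant, nM")
    S70_total: float = Field(30.0, gt=0, description="total sigma factor 70, nM")
    E_total: float = Field(400.0, gt=0, description="total core RNA polymerase, nM")
    kd_m: float = Field(6.6, gt=0, description="mRNA degradation Vmax (k*[Rnase]), nM/s")
    KM_m: float = Field(8000.0, gt=0, description="mRNA degradation Michaelis constant, nM")
    kcat_p: float = Field(6.0e-3, gt=0, description="TL rate constant, 1/s")
    KM_R: float = Field(10.0, gt=0, description="TL Michaelis constant, nM")
    R_total: float = Field(1100.0, gt=0, description="total active ribosomes, nM")
    k_mat: float = Field(1.2e-3, gt=0, description="deGFP maturation rate, 1/s (placeholder default)")
    Cm: float = Field(10.0, gt=0, description="transcription elongation speed, nt/s")
    Cp: float = Field(2.5, gt=0, description="translation elongation speed, nt/s")
    Lm: float = Field(750.0, gt=0, description="transcribed/translated length, nt")
    P70: float = Field(0.0, ge=0, description="promoter (= plasmid) concentration, nM")

    @model_validator(mode="after")
    def _check_rate_ceilings(self) -> "TXTLParameters":
        if self.kcat_m > KCAT_CEILING:
            warnings.warn(
                f"kcat_m={self.kcat_m:g} 1/s exceeds the ~{KCAT_CEILING} 1/s "
                "ceiling on transcription initiation",
                RateLimitWarning,
                stacklevel=2,
            )
        if self.kcat_p > KCAT_CEILING:
            warnings.warn(
                f"kcat_p={self.kcat_p:g} 1/s exceeds the ~{KCAT_CEILING} 1/s "
                "ceiling on translation initiation",
                RateLimitWarning,
                stacklevel=2,
            )
        return self

    # -- derived quantities -------------------------------------------------

    @property
    def kdeg_m(self) -> float:
        """Effective first-order mRNA decay rate kd_m/KM_m, 1/s (valid for [m] << KM_m)."""
        return self.kd_m / self.KM_m

    @property
    def tx_occupancy(self) -> float:
        """Polymerases engaged per initiating polymerase: 1 + kcat_m*Lm/Cm."""
        return 1.0 + self.kcat_m * self.Lm / self.Cm

    @property
    def tl_occupancy(self) -> float:
        """Ribosomes engaged per initiating ribosome: 1 + kcat_p*Lm/Cp."""
        return 1.0 + self.kcat_p * self.Lm / self.Cp

    def replace(self, **changes: float) -> "TXTLParameters":
        """Return a validated copy with the given fields replaced."""
        return TXTLParameters(**{**self.model_dump(), **changes})


@dataclass(frozen=True)
class ResourceAllocation:
    """Partition of RNA polymerase and ribosome pools at a given mRNA level.

    The E-side fields satisfy E0 + E70 + Em = E_total and
    S70_free + E70 = S70_total; the R-side fields satisfy R0 + Rm = R_total.
    Either side may be absent (None) when only one machinery was solved.
    """

    E0: Optional[float] = None
    E70: Optional[float] = None
    Em: Optional[float] = None
    S70_free: Optional[float] = None
    R0: Optional[float] = None
    Rm: Optional[float] = None

    def merged(self, other: "ResourceAllocation") -> "ResourceAllocation":
        """Combine an E-side and an R-side allocation into one record."""
        pick = lambda a, b: b if a is None else a
        return ResourceAllocation(
            E0=pick(self.E0, other.E0),
            E70=pick(self.E70, other.E70),
            Em=pick(self.Em, other.Em),
            S70_free=pick(self.S70_free, other.S70_free),
            R0=pick(self.R0, other.R0),
            Rm=pick(self.Rm, other.Rm),
        )


@dataclass(frozen=True)
class ModelState:
    """Instantaneous state of the expression ODEs (nM; time in s)."""

    m: float
    deGFP_dark: float
    deGFP_mat: float
    time: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.deGFP_dark, self.deGFP_mat])


@dataclass
class KineticsTrace:
    """A simulated (or sampled) expression time course on a fixed grid.

    Attributes
    ----------
    times : array, s, starting at 0, strictly increasing.
    m, deGFP_dark, deGFP_mat : arrays, nM, same length as ``times``.
    E0 : free core RNA polymerase, nM (constant along the run).
    R0 : array of free-ribosome concentrations, nM, or None.
    params : the parameter set that produced the trace, or None.
    """

    times: np.ndarray
    m: np.ndarray
    deGFP_dark: np.ndarray
    deGFP_mat: np.ndarray
    E0: Optional[float] = None
    R0: Optional[np.ndarray] = None
    params: Optional[TXTLParameters] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        self.deGFP_dark = np.asarray(self.deGFP_dark, dtype=float)
        self.deGFP_mat = np.asarray(self.deGFP_mat, dtype=float)
        n = self.times.size
        if not (self.m.size == self.deGFP_dark.size == self.deGFP_mat.size == n):
            raise ValueError("all trace fields must share one length")
        if n and self.times[0] != 0.0:
            raise ValueError("trace must start at t = 0")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def total_protein(self) -> np.ndarray:
        """deGFP_dark + deGFP_mat; non-decreasing (no protein degradation)."""
        return self.deGFP_dark + self.deGFP_mat

    def state_at(self, i: int) -> ModelState:
        return ModelState(
            m=self.m[i],
            deGFP_dark=self.deGFP_dark[i],
            deGFP_mat=self.deGFP_mat[i],
            time=self.times[i],
        )


@dataclass
class RateCurve:
    """Maximum protein synthesis rate versus plasmid concentration.

    ``regime_labels`` marks each grid point "linear" (rate still proportional
    to plasmid within 10% of the low-concentration limit) or "saturated".
    ``slope_linear`` is the through-origin slope over the linear points,
    nM/s per nM plasmid.
    """

    plasmid_concs: np.ndarray
    max_rates: np.ndarray
    regime_labels: Sequence[str] = field(default_factory=list)
    slope_linear: Optional[float] = None

    def __post_init__(self) -> None:
        self.plasmid_concs = np.asarray(self.plasmid_concs, dtype=float)
        self.max_rates = np.asarray(self.max_rates, dtype=float)
        if self.plasmid_concs.size != self.max_rates.size:
            raise ValueError("plasmid_concs and max_rates lengths differ")
        if np.any(self.plasmid_concs < 0):
            raise ValueError("plasmid concentrations must be non-negative")
        if np.any(np.diff(self.plasmid_concs) < 0):
            raise ValueError("plasmid concentrations must be sorted")
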