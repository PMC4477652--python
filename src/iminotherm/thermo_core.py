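"""Core thermodynamic model of imino-proton exchange in the EX2 regime.

A hydrogen-bonded imino proton (G or U) can only exchange with water from
the transiently open state of its base pair.  When opening/closing is fast
compared to proton transfer (EX2 regime), the observed exchange rate is

    k_ex(c_cat, T) = (k_Tr,int(T) + k_Tr,ext(c_cat, T)) * K_Diss/(1 + K_Diss) + d

where ``K_Diss = exp(-(dH_diss - T*dS_diss)/(R*T))`` is the opening
equilibrium constant, ``k_Tr,int`` is an Eyring-form proton-transfer rate via
internal catalysts (neighbouring-base acceptor groups), ``k_Tr,ext`` is the
transfer rate via a dissolved external catalyst (HPO4^2-), linear in catalyst
concentration, and ``d`` is a temperature-independent dipolar
cross-relaxation contribution that appears as a low-temperature plateau.

Enthalpies are kJ/mol, entropies J/(mol K), temperatures K.  All exponents
are evaluated in consistent SI units and in log space where overflow is a
concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "R",
    "K_B",
    "H_PLANCK",
    "T20",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "BasePairThermo",
    "CatalysisModel",
    "ExchangeObservation",
    "ExchangeRateSeries",
    "k_diss",
    "gibbs_energy",
    "eyring_rate",
    "external_catalysis_rate",
    "exchange_rate_model",
    "gibbs_curve",
]

# CODATA values; fixed, not user-overridable.
R = 8.31446261815324  # gas constant, J mol^-1 K^-1
K_B = 1.380649e-23  # Boltzmann constant, J K^-1
H_PLANCK = 6.62607015e-34  # Planck constant, J s

#: Reference temperature for reported Gibbs energies (20 degC).
T20 = 293.15


def celsius_to_kelvin(t_c):
    """Convert degC to K (offset 273.15)."""
    return np.asarray(t_c, dtype=float) + 273.15


def kelvin_to_celsius(t_k):
    """Convert K to degC."""
    return np.asarray(t_k, dtype=float) - 273.15


def _check_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    return T


@dataclass(frozen=True)
class BasePairThermo:
    """Per-base-pair dissociation thermodynamics and exchange parameters.

    Parameters
    ----------
    label : str
        Nucleobase identifier, e.g. ``"G28"``; overlapped pairs fitted
        jointly carry a joint label like ``"U7/U37"``.
    dH_diss, dS_diss : float
        Enthalpy (kJ/mol) and entropy (J/(mol K)) of base-pair opening.
    dH_tr_int, dS_tr_int : float
        Activation enthalpy/entropy of the internal proton-transfer step.
    d : float
        Dipolar cross-relaxation offset, 1/s; non-negative.
    err_dH, err_dS, err_dG20 : float, optional
        Monte Carlo errors (same units as the parent quantities).
    dG20 : float, optional
        Recorded Gibbs energy at 20 degC.  When absent it is derived from
        ``dH_diss``/``dS_diss``; a recorded value takes precedence in
        construct comparisons (fit pipelines may report ``dG20`` at higher
        internal precision than the rounded ``dH``/``dS`` pair).
    averaged : bool
        True for shared-parameter fits of overlapped resonances.
    flags : tuple of str
        Quality flags, e.g. ``"not_determinable"``, ``"weak_span"``.
    """

    label: str
    dH_diss: float
    dS_diss: float
    dH_tr_int: float = 0.0
    dS_tr_int: float = 0.0
    d: float = 0.0
    err_dH: float | None = None
    err_dS: float | None = None
    err_dG20: float | None = None
    dG20: float | None = None
    averaged: bool = False
    flags: tuple = ()

    def __post_init__(self):
        if not np.isfinite(self.dH_diss) or not np.isfinite(self.dS_diss):
            raise ValueError(f"{self.label}: dH_diss/dS_diss must be finite")
        if self.d < 0:
            raise ValueError(f"{self.label}: dipolar offset d must be >= 0")
        if "/" in self.label and not self.averaged:
            object.__setattr__(self, "averaged", True)

    def gibbs20(self) -> float:
        """Gibbs energy of opening at 20 degC (recorded value if present)."""
        if self.dG20 is not None:
            return self.dG20
        return gibbs_energy(T20, self.dH_diss, self.dS_diss)


@dataclass(frozen=True)
class CatalysisModel:
    """External-catalysis (HPO4^2-) parameters.

    The transfer rate via the external catalyst is modelled from the imino
    exchange rate of the free mononucleotide (UTP or GTP) in the presence of
    the catalyst, as an Eyring-form rate scaled by a dimensionless diffusion
    correction ``d_dif`` and linearly by catalyst concentration relative to
    the reference concentration ``c_ref`` at which the NTP parameters apply.
    """

    dH_tr_ntp: float  # kJ/mol
    dS_tr_ntp: float  # J/(mol K)
    d_dif: float = 1.0
    c_ref: float = 1e-3  # mol/L
    reference_species: str = "UTP"

    def __post_init__(self):
        if self.d_dif <= 0:
            raise ValueError("d_dif must be > 0")
        if self.c_ref <= 0:
            raise ValueError("c_ref must be > 0")
        if self.reference_species not in ("UTP", "GTP"):
            raise ValueError("reference_species must be 'UTP' or 'GTP'")


@dataclass(frozen=True)
class ExchangeObservation:
    """One measured imino exchange rate at (T, catalyst concentration)."""

    T: float  # K
    c_cat: float  # mol/L
    k_ex: float  # 1/s
    sigma: float  # 1/s

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("T must be positive (kelvin)")
        if self.c_cat < 0:
            raise ValueError("c_cat must be >= 0")
        if self.k_ex < 0:
            raise ValueError("k_ex must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class ExchangeRateSeries:
    """All exchange-rate observations for one imino resonance."""

    label: str
    observations: list[ExchangeObservation] = field(default_factory=list)

    def __post_init__(self):
        self.observations = list(self.observations)

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def concentrations(self) -> np.ndarray:
        return np.unique([o.c_cat for o in self.observations])

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (T, c_cat, k_ex, sigma) as float arrays."""
        T = np.array([o.T for o in self.observations])
        c = np.array([o.c_cat for o in self.observations])
        k = np.array([o.k_ex for o in self.observations])
        s = np.array([o.sigma for o in self.observations])
        return T, c, k, s

    def subset(self, c_cat: float) -> "ExchangeRateSeries":
        obs = [o for o in self.observations if o.c_cat == c_cat]
        return ExchangeRateSeries(self.label, obs)


def k_diss(T, dH: float, dS: float):
    """Equilibrium constant of base-pair opening, K = exp(-(dH - T dS)/(RT)).

    ``dH`` in kJ/mol, ``dS`` in J/(mol K).  Strictly increasing in T whenever
    dH > 0.
    """
    T = _check_temperature(T)
    return np.exp(-(dH * 1e3 - T * dS) / (R * T))


def gibbs_energy(T, dH: float, dS: float):
    """Gibbs energy dG = dH - T*dS in kJ/mol (dS given in J/(mol K))."""
    T = _check_temperature(T)
    out = dH - T * dS / 1e3
    return float(out) if out.ndim == 0 else out


def eyring_rate(T, dH_act: float, dS_act: float):
    """Transition-state-theory rate k = (k_B T/h) exp(-(dH' - T dS')/(RT)).

    Evaluated in log space so that large barriers underflow gracefully to 0
    instead of overflowing.
    """
    T = _check_temperature(T)
    log_k = np.log(K_B * T / H_PLANCK) - (dH_act * 1e3 - T * dS_act) / (R * T)
    out = np.exp(log_k)
    return float(out) if out.ndim == 0 else out


def external_catalysis_rate(T, c_cat, cat: CatalysisModel):
    """Proton-transfer rate via the external catalyst, 1/s.

    ``d_dif * k_NTP(T) * c_cat/c_ref`` with ``k_NTP`` the Eyring-form free
    nucleotide exchange rate at the reference catalyst concentration.
    Vanishes at zero catalyst and is linear in ``c_cat``.
    """
    T = _check_temperature(T)
    c_cat = np.asarray(c_cat, dtype=float)
    if np.any(c_cat < 0):
        raise ValueError("c_cat must be >= 0")
    out = cat.d_dif * eyring_rate(T, cat.dH_tr_ntp, cat.dS_tr_ntp) * (c_cat / cat.c_ref)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def open_state_fraction(T, dH: float, dS: float):
    """K/(1+K) evaluated stably via a logistic in ln K."""
    T = _check_temperature(T)
    ln_k = -(dH * 1e3 - T * dS) / (R * T)
    return expit(ln_k)


def exchange_rate_model(T, c_cat, bp: BasePairThermo, cat: CatalysisModel):
    """Observed imino exchange rate under the EX2 model, 1/s.

    k_ex = (k_Tr,int + k_Tr,ext) * K/(1+K) + d.  In the open-state limit
    (K -> inf) this tends to k_Tr,int + k_Tr,ext + d; with vanishing transfer
    rates it tends to the dipolar offset d.
    """
    k_int = eyring_rate(T, bp.dH_tr_int, bp.dS_tr_int)
    k_ext = external_catalysis_rate(T, c_cat, cat)
    frac = open_state_fraction(T, bp.dH_diss, bp.dS_diss)
    out = np.asarray((k_int + k_ext) * frac + bp.d)
    return float(out) if out.ndim == 0 else out


def gibbs_curve(bp: BasePairThermo, T_grid: Sequence[float]) -> list[tuple[float, float]]:
    """Linear-in-T Gibbs-energy trace [(T, dG(T)), ...] for one base pair.

    Traces of base pairs whose (dH, dS) lie on a common compensation line
    dH = Tc*dS/1000 + y0 intersect at T = Tc where dG = y0.
    """
    T_grid = _check_temperature(T_grid)
    g = gibbs_energy(T_grid, bp.dH_diss, bp.dS_diss)
    return list(zip(T_grid.tolist(), np.atleast_1d(g).tolist()))
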