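"""Two-state CD melting-curve analysis with linear state baselines.

The 260 nm ellipticity of a monomolecular hairpin is modelled as a
population-weighted average of two linear baselines,

    s(T) = B_f(T) * f_folded(T) + B_u(T) * (1 - f_folded(T)),
    f_folded(T) = 1 / (1 + exp(-dG_unf(T)/(R T))),
    dG_unf(T) = dH_unf - T * dS_unf,

with the melting temperature the zero of dG_unf, Tm = 1000*dH_unf/dS_unf
(dH in kJ/mol, dS in J/(mol K)).  The six parameters (dH, dS and two
baselines) are fitted simultaneously by unweighted nonlinear least squares;
internally the transition is parameterized as (Tm, dH) for better
conditioning, with dS derived.  Baseline-corrected data give the fraction
unfolded.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.optimize import least_squares

from .thermo_core import R

__all__ = [
    "MeltingCurve",
    "MeltingFit",
    "two_state_signal",
    "fit_melting",
    "fraction_unfolded",
    "tm_from_thermo",
]


@dataclass
class MeltingCurve:
    """One CD melting curve (temperatures in K, signal in arbitrary units)."""

    T: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.T.shape != self.signal.shape:
            raise ValueError("T and signal must have equal length")
        if len(self.T) < 30:
            raise ValueError("need >= 30 points for a baseline-resolved fit")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class MeltingFit:
    """Two-state unfolding parameters plus state baselines.

    ``Tm`` is always the derived quantity 1000*dH_unf/dS_unf.  Baselines are
    (intercept, slope per K) pairs evaluated as ``intercept + slope*T`` with
    T in kelvin.
    """

    dH_unf: float  # kJ/mol
    dS_unf: float  # J/(mol K)
    baseline_folded: tuple
    baseline_unfolded: tuple
    rmse: float = float("nan")
    converged: bool = True
    flags: tuple = ()
    label: str = ""

    @property
    def Tm(self) -> float:
        return tm_from_thermo(self.dH_unf, self.dS_unf)


def tm_from_thermo(dH_unf: float, dS_unf: float) -> float:
    """Melting temperature Tm = 1000*dH_unf/dS_unf in K."""
    if dS_unf <= 0:
        raise ValueError("dS_unf must be > 0 for a defined melting point")
    return 1e3 * dH_unf / dS_unf


def folded_fraction(T, dH_unf: float, dS_unf: float):
    """Population of the folded state under the two-state model."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    dG = dH_unf * 1e3 - T * dS_unf  # J/mol
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-dG / (R * T)))


def two_state_signal(T, fit: MeltingFit):
    """Model CD signal at temperatures ``T`` (K)."""
    T = np.asarray(T, dtype=float)
    ff = folded_fraction(T, fit.dH_unf, fit.dS_unf)
    bf = fit.baseline_folded[0] + fit.baseline_folded[1] * T
    bu = fit.baseline_unfolded[0] + fit.baseline_unfolded[1] * T
    out = bf * ff + bu * (1.0 - ff)
    return float(out) if out.ndim == 0 else out


def _pack_model(T, theta):
    tm, dh, af, bf, au, bu = theta
    ds = 1e3 * dh / tm
    ff = folded_fraction(T, dh, ds)
    return (af + bf * T) * ff + (au + bu * T) * (1.0 - ff)


def _baseline_guess(T, s, frac=0.2):
    n = max(int(len(T) * frac), 3)
    cf = np.polyfit(T[:n], s[:n], 1)
    cu = np.polyfit(T[-n:], s[-n:], 1)
    return (cf[1], cf[0]), (cu[1], cu[0])


def fit_melting(curve: MeltingCurve, n_tm_starts: int = 5) -> MeltingFit:
    """Fit the six-parameter two-state model to one melting curve.

    Multi-start over Tm guesses spanning the interior of the temperature
    range; baselines initialized from the curve edges.  Curves without a
    detectable transition are flagged ``"no_transition"``; fits whose
    transition amplitude is below three times the residual rmse are flagged
    ``"broad_transition"`` (baseline-dominated, parameters unreliable).
    A warning is issued when the data do not extend at least 10 K beyond the
    fitted transition on each side.
    """
    T, s = curve.T, curve.signal

    (af, bf), (au, bu) = _baseline_guess(T, s)
    amp0 = abs((au + bu * np.median(T)) - (af + bf * np.median(T)))
    span = float(np.ptp(T))
    lo, hi = T[0] + 0.1 * span, T[-1] - 0.1 * span

    def resid(theta):
        return _pack_model(T, theta) - s

    best = None
    for tm0 in np.linspace(lo, hi, n_tm_starts):
        for dh0 in (100.0, 300.0):
            theta0 = np.array([tm0, dh0, af, bf, au, bu])
            try:
                sol = least_squares(
                    resid,
                    theta0,
                    bounds=(
                        [T[0] - 50.0, 1.0, -np.inf, -np.inf, -np.inf, -np.inf],
                        [T[-1] + 50.0, 2000.0, np.inf, np.inf, np.inf, np.inf],
                    ),
                    x_scale=[10.0, 100.0, 1.0, 0.01, 1.0, 0.01],
                    xtol=1e-13,
                    ftol=1e-13,
                    gtol=1e-13,
                    max_nfev=6000,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol

    if best is None:
        return MeltingFit(
            float("nan"), float("nan"), (af, bf), (au, bu),
            converged=False, flags=("non_convergent",), label=curve.label,
        )

    tm, dh, af, bf, au, bu = best.x
    ds = 1e3 * dh / tm
    rmse = float(np.sqrt(2.0 * best.cost / len(T)))
    flags = []

    amp = abs((au + bu * tm) - (af + bf * tm))
    scale = max(float(np.ptp(s)), 1e-300)
    floor = max(3.0 * rmse, 1e-3 * scale)
    if amp < floor:
        # amp0 is the edge-baseline separation seen in the raw data: if even
        # that is below the floor there is nothing to fit
        flags.append("no_transition" if amp0 < floor else "broad_transition")
    if not (T[0] + 1.0 < tm < T[-1] - 1.0):
        if "no_transition" not in flags:
            flags.append("no_transition")
    # transition width ~ 4 R Tm^2 / dH; warn when baselines are clipped
    width = 4.0 * R * tm**2 / (dh * 1e3)
    if tm - 0.5 * width - 10.0 < T[0] or tm + 0.5 * width + 10.0 > T[-1]:
        warnings.warn(
            f"{curve.label or 'curve'}: data span < 10 K beyond the "
            "transition on at least one side — baselines poorly constrained",
            stacklevel=2,
        )

    return MeltingFit(
        dH_unf=float(dh),
        dS_unf=float(ds),
        baseline_folded=(float(af), float(bf)),
        baseline_unfolded=(float(au), float(bu)),
        rmse=rmse,
        converged=bool(best.success) and "no_transition" not in flags,
        flags=tuple(flags),
        label=curve.label,
    )


def fraction_unfolded(curve: MeltingCurve, fit: MeltingFit):
    """Baseline-corrected, normalized fraction unfolded.

    (signal - B_f)/(B_u - B_f), clipped to [0, 1].  Points where the
    baseline separation is below the fit rmse are masked (NaN) — there the
    normalization divides noise by noise.  By construction the model value
    at T = Tm is exactly 0.5.
    """
    if not fit.converged:
        raise ValueError("fraction_unfolded requires a converged fit")
    T, s = curve.T, curve.signal
    bf = fit.baseline_folded[0] + fit.baseline_folded[1] * T
    bu = fit.baseline_unfolded[0] + fit.baseline_unfolded[1] * T
    sep = bu - bf
    noise = fit.rmse if np.isfinite(fit.rmse) else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (s - bf) / sep
    frac = np.clip(frac, 0.0, 1.0)
    frac[np.abs(sep) <= noise] = np.nan
    return list(zip(T.tolist(), frac.tolist()))
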