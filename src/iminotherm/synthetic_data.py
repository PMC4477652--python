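"""Synthetic-data generation for every stage of the pipeline.

The generators emulate the experimental design of the imino-exchange study:
exchange-rate surfaces on a temperature grid from -5 to 55 degC at two
HPO4^2- concentrations (2 and 29 mM), inversion-recovery profiles over a
log-spaced mixing-time grid, and CD melting curves with linear state
baselines.  Noise is multiplicative Gaussian on rates (default 5%, matching
how rate errors are reported) and additive Gaussian on CD signal (default
1% of the transition amplitude); recorded standard errors are truthful.
All generators are deterministic under the construct's seed.

Whole-construct parameter ladders can be drawn from a compensation line
(dH = Tc*dS/1000 + y0 + scatter), which is the positive control for the EEC
analysis and, paired with a melting truth at Tm = Tc, for the Tc ~ Tm
demonstration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import datasets
from .ir_fitting import InversionRecoveryProfile
from .melting import MeltingCurve
from .thermo_core import (
    BasePairThermo,
    CatalysisModel,
    ExchangeObservation,
    ExchangeRateSeries,
    celsius_to_kelvin,
    exchange_rate_model,
)
from .ir_fitting import ir_model

__all__ = [
    "DEFAULT_CATALYSIS",
    "ExperimentDesign",
    "MeltingTruth",
    "ConstructSpec",
    "gen_exchange_series",
    "gen_ex1_series",
    "gen_ir_profiles",
    "gen_melting_curve",
    "gen_eec_construct",
    "hsp17_preset",
]

#: Default external-catalysis parameters.  The NTP transition-state values
#: are placeholders chosen to give realistic transfer-rate magnitudes
#: (k_Tr,ext ~ 3e4 1/s at 2 mM and 20 degC); supply literature values via
#: config before analysing real data.
DEFAULT_CATALYSIS = CatalysisModel(
    dH_tr_ntp=35.0, dS_tr_ntp=-35.0, d_dif=0.3, c_ref=1e-3,
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Measurement grid and noise model of a simulated experiment."""

    seed: int
    T_grid_C: tuple = tuple(float(t) for t in range(-5, 56, 3))
    c_cat_mM: tuple = (2.0, 29.0)
    t_m_s: tuple = tuple(np.geomspace(2e-3, 2.0, 12).round(6).tolist())
    rate_noise_frac: float = 0.05
    ir_noise_sd: float = 0.01
    R1_H: float = 2.0  # imino longitudinal relaxation, 1/s
    R1_W: float = 0.3  # water longitudinal relaxation, 1/s
    max_kex: float = 150.0  # detectability ceiling for IR profiles, 1/s


@dataclass(frozen=True)
class MeltingTruth:
    """Ground truth for a simulated CD melting curve."""

    dH_unf: float  # kJ/mol
    dS_unf: float  # J/(mol K)
    baseline_folded: tuple = (-10.0, 0.012)
    baseline_unfolded: tuple = (-2.0, 0.004)
    noise_sd: float = 0.06
    T_grid_C: tuple = tuple(np.arange(0.0, 95.1, 0.5).round(2).tolist())


@dataclass
class ConstructSpec:
    """Full specification of a simulated construct."""

    name: str
    base_pairs: list[BasePairThermo]
    design: ExperimentDesign
    catalysis: CatalysisModel = DEFAULT_CATALYSIS
    eec: tuple | None = None  # (Tc K, y0 kJ/mol, scatter sd kJ/mol)
    melting: MeltingTruth | None = None


def _sigma(k_true: np.ndarray, frac: float) -> np.ndarray:
    # truthful multiplicative sigma; a 1% floor keeps weights finite on
    # noiseless data
    return np.maximum(frac, 0.01) * np.maximum(k_true, 1e-12)


def gen_exchange_series(spec: ConstructSpec) -> dict[str, ExchangeRateSeries]:
    """Forward-simulate exchange-rate series for every base pair.

    Rates are the EX2 forward model on the design grid with multiplicative
    Gaussian noise at ``design.rate_noise_frac``; the recorded sigma is the
    true noise scale.  Deterministic under the design seed.
    """
    rng = np.random.default_rng(spec.design.seed)
    T = celsius_to_kelvin(np.array(spec.design.T_grid_C))
    out = {}
    for bp in spec.base_pairs:
        obs = []
        for c_mM in spec.design.c_cat_mM:
            c = c_mM * 1e-3
            k_true = np.asarray(exchange_rate_model(T, c, bp, spec.catalysis))
            sig = _sigma(k_true, spec.design.rate_noise_frac)
            noise = rng.normal(0.0, 1.0, size=k_true.shape)
            k_obs = k_true * (1.0 + spec.design.rate_noise_frac * noise)
            k_obs = np.maximum(k_obs, 1e-12)
            for t, kk, ss in zip(T, k_obs, sig):
                obs.append(ExchangeObservation(float(t), float(c), float(kk), float(ss)))
        out[bp.label] = ExchangeRateSeries(bp.label, obs)
    return out


def gen_ex1_series(
    bp: BasePairThermo, spec: ConstructSpec
) -> ExchangeRateSeries:
    """EX1-like negative control: opening-limited, catalyst-independent rates.

    When exchange is limited by the opening step, the rate saturates at the
    opening rate and loses its catalyst-concentration dependence.  Both
    nominal concentrations are assigned the same underlying temperature
    profile (the EX2 model evaluated at the mean concentration), so a global
    EX2 fit over both datasets must show systematic per-concentration
    residual structure.
    """
    rng = np.random.default_rng(spec.design.seed + 1)
    T = celsius_to_kelvin(np.array(spec.design.T_grid_C))
    c_mean = float(np.mean(spec.design.c_cat_mM)) * 1e-3
    k_true = np.asarray(exchange_rate_model(T, c_mean, bp, spec.catalysis))
    sig = _sigma(k_true, spec.design.rate_noise_frac)
    obs = []
    for c_mM in spec.design.c_cat_mM:
        c = c_mM * 1e-3
        noise = rng.normal(0.0, 1.0, size=k_true.shape)
        k_obs = np.maximum(k_true * (1.0 + spec.design.rate_noise_frac * noise), 1e-12)
        for t, kk, ss in zip(T, k_obs, sig):
            obs.append(ExchangeObservation(float(t), float(c), float(kk), float(ss)))
    return ExchangeRateSeries(bp.label, obs)


def gen_ir_profiles(
    spec: ConstructSpec,
    overlapped_pairs: tuple = (),
) -> list[InversionRecoveryProfile]:
    """Forward-simulate inversion-recovery profiles for every base pair.

    One profile per (base pair, temperature, concentration) whose true
    exchange rate is below the detectability ceiling.  ``overlapped_pairs``
    lists (label_a, label_b) tuples whose deviations are averaged into a
    single joint profile (an unresolved double peak of equal intensities),
    labelled ``"a/b"``.
    """
    rng = np.random.default_rng(spec.design.seed + 2)
    des = spec.design
    T = celsius_to_kelvin(np.array(des.T_grid_C))
    t_m = np.array(des.t_m_s)
    bp_by_label = {bp.label: bp for bp in spec.base_pairs}
    overlapped = {lab for pair in overlapped_pairs for lab in pair}

    def deviation(bp, t_k, c):
        k_true = float(exchange_rate_model(t_k, c, bp, spec.catalysis))
        if k_true > des.max_kex:
            return None
        return ir_model(t_m, k_true, des.R1_H, des.R1_W)

    profiles = []
    for c_mM in des.c_cat_mM:
        c = c_mM * 1e-3
        for t_k in T:
            for bp in spec.base_pairs:
                if bp.label in overlapped:
                    continue
                dev = deviation(bp, t_k, c)
                if dev is None:
                    continue
                ratio = 1.0 + dev + rng.normal(0.0, des.ir_noise_sd, size=t_m.shape)
                profiles.append(
                    InversionRecoveryProfile(bp.label, float(t_k), c, t_m, ratio)
                )
            for a, b in overlapped_pairs:
                dev_a = deviation(bp_by_label[a], t_k, c)
                dev_b = deviation(bp_by_label[b], t_k, c)
                if dev_a is None or dev_b is None:
                    continue
                dev = 0.5 * (dev_a + dev_b)
                ratio = 1.0 + dev + rng.normal(0.0, des.ir_noise_sd, size=t_m.shape)
                profiles.append(
                    InversionRecoveryProfile(f"{a}/{b}", float(t_k), c, t_m, ratio)
                )
    return profiles


def gen_melting_curve(spec: ConstructSpec) -> MeltingCurve:
    """Forward-simulate the construct's CD melting curve."""
    if spec.melting is None:
        raise ValueError(f"{spec.name}: no melting truth in the spec")
    m = spec.melting
    rng = np.random.default_rng(spec.design.seed + 3)
    T = celsius_to_kelvin(np.array(m.T_grid_C))
    from .melting import MeltingFit, two_state_signal

    truth = MeltingFit(
        dH_unf=m.dH_unf,
        dS_unf=m.dS_unf,
        baseline_folded=m.baseline_folded,
        baseline_unfolded=m.baseline_unfolded,
    )
    signal = two_state_signal(T, truth) + rng.normal(0.0, m.noise_sd, size=T.shape)
    return MeltingCurve(T=T, signal=signal, label=spec.name)


def gen_eec_construct(
    n: int,
    Tc: float,
    y0: float,
    scatter: float,
    seed: int,
    dS_range: tuple = (80.0, 800.0),
    dH_tr_int: float = 55.0,
    dS_tr_int: float = 25.0,
    d: float = 1.5,
    design: ExperimentDesign | None = None,
    catalysis: CatalysisModel = DEFAULT_CATALYSIS,
    name: str = "eec-synthetic",
) -> ConstructSpec:
    """Construct whose base pairs lie on a compensation line.

    dS is drawn uniformly over ``dS_range`` (J/(mol K), spanning the
    observed range); dH = Tc*dS/1000 + y0 + N(0, scatter) in kJ/mol.  The
    construct is paired with a melting truth whose Tm equals Tc, so the
    full pipeline can demonstrate the coincidence of compensation and
    melting temperatures.  With scatter 0 the compensation fit recovers
    (Tc, y0) exactly.
    """
    if Tc <= 0:
        raise ValueError("Tc must be positive (kelvin)")
    rng = np.random.default_rng(seed)
    dS = np.sort(rng.uniform(*dS_range, size=n))
    dH = Tc * dS / 1e3 + y0 + rng.normal(0.0, scatter, size=n)
    bps = [
        BasePairThermo(
            label=f"BP{i+1:02d}",
            dH_diss=float(dH[i]),
            dS_diss=float(dS[i]),
            dH_tr_int=dH_tr_int,
            dS_tr_int=dS_tr_int,
            d=d,
        )
        for i in range(n)
    ]
    melt = MeltingTruth(dH_unf=300.0, dS_unf=300.0 * 1e3 / Tc)
    return ConstructSpec(
        name=name,
        base_pairs=bps,
        design=design or ExperimentDesign(seed=seed),
        catalysis=catalysis,
        eec=(Tc, y0, scatter),
        melting=melt,
    )


@dataclass
class FitErrorEnsemble:
    """Synthetic stand-in for a Monte Carlo fit ensemble.

    Emulates the hallmark within-fit (dH, dS) error covariance — a narrow
    ellipse tilted at a characteristic temperature slope — without running
    refits; used to calibrate the compensation validity test.  ``samples``
    columns are (dH kJ/mol, dS J/(mol K)), matching the layout the validity
    test consumes.
    """

    samples: np.ndarray


def gen_fit_error_ensemble(
    dH: float,
    dS: float,
    sd_S: float,
    slope_K: float,
    n: int,
    seed: int,
    perp_sd: float = 0.2,
) -> FitErrorEnsemble:
    """Draw an error cloud around (dH, dS) tilted at ``slope_K`` kelvin.

    dS errors are N(0, sd_S) (J/(mol K)); dH errors follow the slope
    (slope_K * dS_err/1000) plus independent N(0, perp_sd) kJ/mol, giving
    the near-unit dH-dS error correlation characteristic of exchange-model
    fits.
    """
    rng = np.random.default_rng(seed)
    s_err = rng.normal(0.0, sd_S, size=n)
    h_err = slope_K * s_err / 1e3 + rng.normal(0.0, perp_sd, size=n)
    return FitErrorEnsemble(np.column_stack([dH + h_err, dS + s_err]))


def hsp17_preset(name: str, seed: int,
                 design: ExperimentDesign | None = None) -> ConstructSpec:
    """Construct spec with the reported hsp17 / hsp17_rep parameter ladder.

    Opening parameters come from the reference tables; transfer-state
    parameters and the dipolar offset, which the tables do not list, use the
    generator defaults.  The paired melting truth is the construct's
    reported two-state unfolding parameter set.
    """
    table = datasets.construct_table(name)
    bps = [
        replace(bp, dH_tr_int=55.0, dS_tr_int=25.0, d=1.5, dG20=None)
        for bp in table.values()
    ]
    dh_unf, ds_unf = datasets.MELTING_PARAMS[name]
    return ConstructSpec(
        name=name,
        base_pairs=bps,
        design=design or ExperimentDesign(seed=seed),
        eec=None,
        melting=MeltingTruth(dH_unf=dh_unf, dS_unf=ds_unf),
    )
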