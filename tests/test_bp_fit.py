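"""Global stability fit, MC errors, van't Hoff inversion, EX2 diagnostic."""

import numpy as np
import pytest

from iminotherm.bp_fit import (
    GlobalFitConfig,
    ex2_consistency_check,
    fit_base_pair,
    fit_base_pair_shared,
    mc_errors,
    van_t_hoff_points,
)
from iminotherm.synthetic_data import (
    DEFAULT_CATALYSIS,
    ConstructSpec,
    ExperimentDesign,
    gen_ex1_series,
    gen_exchange_series,
)
from iminotherm.thermo_core import (
    BasePairThermo,
    ExchangeObservation,
    ExchangeRateSeries,
)


def _cfg(seed=5, mc=100, **kw):
    return GlobalFitConfig(
        catalysis=DEFAULT_CATALYSIS, seed=seed, mc_iterations=mc, **kw
    )


def _series_for(bp, seed, noise=0.05, T_grid=None):
    design = ExperimentDesign(seed=seed, rate_noise_frac=noise)
    if T_grid is not None:
        design = ExperimentDesign(
            seed=seed, rate_noise_frac=noise, T_grid_C=tuple(T_grid)
        )
    spec = ConstructSpec("one", [bp], design=design)
    return gen_exchange_series(spec)[bp.label]


TRUTH_5 = ("dH_diss", "dS_diss", "dH_tr_int", "dS_tr_int", "d")


def _truth_vector(bp):
    return np.array([bp.dH_diss, bp.dS_diss, bp.dH_tr_int, bp.dS_tr_int, bp.d])


class TestGlobalFit:
    @pytest.mark.parametrize("label", ["G28", "U11", "G27"])
    def test_noiseless_round_trip_recovers_all_five_parameters(
        self, noiseless_series, label
    ):
        spec, series = noiseless_series
        truth = {b.label: b for b in spec.base_pairs}[label]
        bp = fit_base_pair(series[label], _cfg())
        got = _truth_vector(bp)
        want = _truth_vector(truth)
        np.testing.assert_allclose(got, want, rtol=1e-4, atol=1e-6)

    def test_single_concentration_refused(self, noiseless_series):
        _, series = noiseless_series
        sub = series["G28"].subset(series["G28"].concentrations[0])
        with pytest.raises(ValueError, match="concentration"):
            fit_base_pair(sub, _cfg())

    def test_too_few_temperatures_refused(self, g28_truth):
        s = _series_for(g28_truth, seed=1, T_grid=[0.0, 20.0, 40.0])
        with pytest.raises(ValueError, match="temperatures"):
            fit_base_pair(s, _cfg())

    def test_flat_series_flagged_not_determinable(self, rng):
        obs = []
        for c in (2e-3, 29e-3):
            for t in np.arange(268.15, 328.2, 3.0):
                k = 1.5 * (1 + 0.03 * rng.normal())
                obs.append(ExchangeObservation(float(t), c, k, 0.045))
        bp = fit_base_pair(ExchangeRateSeries("U15", obs), _cfg())
        assert "not_determinable" in bp.flags
        assert bp.d == pytest.approx(1.5, rel=0.05)

    def test_narrow_temperature_span_warns(self, g28_truth):
        # a 12-K window around the exchange onset still fits but is flagged
        s = _series_for(
            g28_truth, seed=3, noise=0.0, T_grid=np.arange(30.0, 42.1, 2.0)
        )
        with pytest.warns(UserWarning, match="span"):
            bp = fit_base_pair(s, _cfg())
        assert "weak_span" in bp.flags

    def test_observation_order_invariance(self, noiseless_series, rng):
        _, series = noiseless_series
        s = series["G27"]
        shuffled = ExchangeRateSeries(
            s.label, [s.observations[i] for i in rng.permutation(len(s))]
        )
        a = fit_base_pair(s, _cfg())
        b = fit_base_pair(shuffled, _cfg())
        np.testing.assert_allclose(_truth_vector(a), _truth_vector(b), rtol=1e-12)


class TestSharedFit:
    def _pair(self, dG_offsets, seed):
        bps = []
        for i, off in enumerate(dG_offsets):
            # shift stability via the enthalpy at fixed entropy
            bps.append(
                BasePairThermo(
                    f"P{i}", 86.9 + off, 206.5, dH_tr_int=55.0,
                    dS_tr_int=25.0, d=1.5,
                )
            )
        design = ExperimentDesign(seed=seed, rate_noise_frac=0.02)
        spec = ConstructSpec("pair", bps, design=design)
        series = gen_exchange_series(spec)
        return bps, [series[b.label] for b in bps]

    def test_identical_truths_recovered(self):
        bps, (a, b) = self._pair([0.0, 0.0], seed=21)
        res = fit_base_pair_shared((a, b), _cfg())
        assert res.averaged
        assert res.dH_diss == pytest.approx(86.9, rel=0.05)
        assert "inconsistent_pair" not in res.flags

    def test_two_kj_apart_yields_intermediate_stability(self):
        bps, (a, b) = self._pair([-1.0, 1.0], seed=22)
        res = fit_base_pair_shared((a, b), _cfg())
        g = res.gibbs20()
        g_lo = bps[0].gibbs20()
        g_hi = bps[1].gibbs20()
        assert min(g_lo, g_hi) <= g <= max(g_lo, g_hi)

    def test_divergent_truths_flagged(self):
        # stabilities >10 kJ/mol apart with both opening transitions inside
        # the measured window: the averaged curve is visibly two-step
        bps = [
            BasePairThermo("P0", 38.8, 82.9, dH_tr_int=55.0, dS_tr_int=25.0, d=1.5),
            BasePairThermo("P1", 193.5, 561.9, dH_tr_int=55.0, dS_tr_int=25.0, d=1.5),
        ]
        spec = ConstructSpec(
            "pair", bps, design=ExperimentDesign(seed=23, rate_noise_frac=0.02)
        )
        series = gen_exchange_series(spec)
        res = fit_base_pair_shared((series["P0"], series["P1"]), _cfg())
        assert "inconsistent_pair" in res.flags

    def test_joint_labelled_series_accepted(self, noiseless_series):
        _, series = noiseless_series
        s = series["G30"]
        joint = ExchangeRateSeries("G30/G30b", list(s.observations))
        res = fit_base_pair_shared(joint, _cfg())
        assert res.averaged
        assert res.dH_diss == pytest.approx(46.1, rel=1e-3)


class TestMonteCarlo:
    def test_vanishing_noise_gives_vanishing_errors(self, g28_truth):
        s0 = _series_for(g28_truth, seed=31, noise=0.0)
        tiny = ExchangeRateSeries(
            s0.label,
            [
                ExchangeObservation(o.T, o.c_cat, o.k_ex, 1e-9 * max(o.k_ex, 1.0))
                for o in s0.observations
            ],
        )
        cfg = _cfg(mc=100)
        bp = fit_base_pair(tiny, cfg)
        ens = mc_errors(tiny, bp, cfg)
        assert ens.summary["dH_diss"] < 1e-4
        assert ens.err_dG20 < 1e-6

    def test_reported_error_stabilizes_with_iterations(self, noisy_series):
        spec, series = noisy_series
        s = series["G28"]
        bp = fit_base_pair(s, _cfg())
        e500 = mc_errors(s, bp, _cfg(mc=500)).summary["dH_diss"]
        e1000 = mc_errors(s, bp, _cfg(seed=6, mc=1000)).summary["dH_diss"]
        assert abs(e1000 - e500) / e500 < 0.05

    def test_narrow_tilted_ellipse(self, noisy_series):
        spec, series = noisy_series
        s = series["G28"]
        cfg = _cfg()
        bp = fit_base_pair(s, cfg)
        ens = mc_errors(s, bp, cfg)
        assert abs(ens.corr_HS) > 0.95
        w_major, w_minor = ens.ellipse["widths"]
        assert w_major > 5 * w_minor

    def test_gibbs_error_consistent_with_ellipse_propagation(self, noisy_series):
        spec, series = noisy_series
        s = series["U11"]
        cfg = _cfg()
        bp = fit_base_pair(s, cfg)
        ens = mc_errors(s, bp, cfg)
        cov = ens.cov_HS
        t = 293.15 / 1e3
        propagated = np.sqrt(cov[0, 0] + t**2 * cov[1, 1] - 2 * t * cov[0, 1])
        assert ens.err_dG20 == pytest.approx(propagated, rel=0.20)

    def test_wider_temperature_span_shrinks_enthalpy_error(self, g28_truth):
        errs = []
        for t_hi in (25.0, 40.0, 55.0):
            s = _series_for(
                g28_truth, seed=77, T_grid=np.arange(-5.0, t_hi + 0.1, 3.0)
            )
            cfg = _cfg(seed=78)
            bp = fit_base_pair(s, cfg)
            errs.append(mc_errors(s, bp, cfg).summary["dH_diss"])
        assert errs[0] > errs[1] > errs[2]


class TestVantHoff:
    def test_noiseless_linearization_is_exact(self, noiseless_series):
        spec, series = noiseless_series
        truth = {b.label: b for b in spec.base_pairs}["G28"]
        bp = fit_base_pair(series["G28"], _cfg())
        vh = van_t_hoff_points(series["G28"], bp, spec.catalysis)
        assert vh.r2 == pytest.approx(1.0, abs=1e-10)
        assert vh.dH_diss == pytest.approx(truth.dH_diss, rel=1e-6)
        assert vh.dS_diss == pytest.approx(truth.dS_diss, rel=1e-6)

    def test_point_at_dipolar_floor_excluded(self, noiseless_series):
        spec, series = noiseless_series
        s = series["G28"]
        bp = fit_base_pair(s, _cfg())
        doctored = ExchangeRateSeries(
            s.label,
            [ExchangeObservation(s.observations[0].T, s.observations[0].c_cat,
                                 bp.d, s.observations[0].sigma)]
            + list(s.observations[1:]),
        )
        vh = van_t_hoff_points(doctored, bp, spec.catalysis)
        assert 0 in vh.excluded

    def test_high_linearity_under_three_percent_noise(self, g28_truth):
        s = _series_for(g28_truth, seed=41, noise=0.03)
        cfg = _cfg(seed=41)
        bp = fit_base_pair(s, cfg)
        vh = van_t_hoff_points(s, bp, DEFAULT_CATALYSIS)
        assert vh.r2 > 0.99


class TestEX2Check:
    def test_ex2_simulated_data_pass(self, noisy_series):
        spec, series = noisy_series
        s = series["G27"]
        bp = fit_base_pair(s, _cfg())
        rep = ex2_consistency_check(s, bp, spec.catalysis)
        assert rep.assessable
        assert rep.passed

    def test_ex1_like_saturation_flagged(self, g28_truth):
        spec = ConstructSpec(
            "x", [g28_truth], design=ExperimentDesign(seed=51, rate_noise_frac=0.05)
        )
        s = gen_ex1_series(g28_truth, spec)
        bp = fit_base_pair(s, _cfg())
        rep = ex2_consistency_check(s, bp, spec.catalysis)
        assert rep.assessable
        assert not rep.passed

    def test_single_concentration_not_assessable(self, noisy_series):
        spec, series = noisy_series
        s = series["G28"]
        sub = s.subset(s.concentrations[0])
        bp = BasePairThermo("G28", 193.5, 561.9, 55.0, 25.0, 1.5)
        rep = ex2_consistency_check(sub, bp, spec.catalysis)
        assert not rep.assessable
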