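"""Forward-model checks: opening equilibrium, Eyring rates, composition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iminotherm.thermo_core import (
    H_PLANCK,
    K_B,
    R,
    BasePairThermo,
    CatalysisModel,
    ExchangeObservation,
    exchange_rate_model,
    external_catalysis_rate,
    eyring_rate,
    gibbs_curve,
    gibbs_energy,
    k_diss,
)


class TestKDiss:
    @pytest.mark.parametrize("T", [260.0, 293.15, 330.0])
    def test_unity_when_dG_zero(self, T):
        dS = 300.0
        assert k_diss(T, T * dS / 1e3, dS) == pytest.approx(1.0, rel=1e-12)
        assert k_diss(T, 0.0, 0.0) == 1.0

    def test_strong_cg_pair_reference_point(self):
        # independent scalar evaluation of the Boltzmann factor
        expected = math.exp(-(193.5e3 - 293.15 * 561.9) / (R * 293.15))
        assert k_diss(293.15, 193.5, 561.9) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(7.45e-6, rel=5e-3)

    @settings(derandomize=True, max_examples=50)
    @given(
        dH=st.floats(1.0, 400.0),
        dS=st.floats(0.0, 1200.0),
    )
    def test_strictly_increasing_in_T_for_positive_enthalpy(self, dH, dS):
        T = np.linspace(260.0, 340.0, 30)
        K = k_diss(T, dH, dS)
        assert np.all(np.diff(K) > 0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            k_diss(0.0, 100.0, 300.0)
        with pytest.raises(ValueError):
            k_diss(-5.0, 100.0, 300.0)


class TestGibbs:
    def test_zero_parameters_zero_energy(self):
        assert gibbs_energy(300.0, 0.0, 0.0) == 0.0

    @pytest.mark.parametrize(
        "dH,dS,expected",
        [(193.5, 561.9, 28.8), (277.8, 781.2, 48.8)],
    )
    def test_reference_rows(self, dH, dS, expected):
        assert gibbs_energy(293.15, dH, dS) == pytest.approx(expected, abs=0.05)

    def test_unit_bookkeeping(self):
        # dS enters in J/(mol K); 1000 J/(mol K) at 300 K removes 300 kJ/mol
        assert gibbs_energy(300.0, 500.0, 1000.0) == pytest.approx(200.0)


class TestEyring:
    def test_zero_barrier_gives_attempt_frequency(self):
        T = 293.15
        assert eyring_rate(T, 0.0, 0.0) == pytest.approx(K_B * T / H_PLANCK, rel=1e-12)
        assert K_B * T / H_PLANCK == pytest.approx(6.11e12, rel=1e-3)

    def test_infinite_barrier_underflows_to_zero(self):
        assert eyring_rate(293.15, 1e6, 0.0) == 0.0

    def test_log_space_oracle(self):
        T, dH, dS = 293.15, 60.0, -50.0
        expected = (K_B * T / H_PLANCK) * math.exp(
            -(dH * 1e3 - T * dS) / (R * T)
        )
        assert eyring_rate(T, dH, dS) == pytest.approx(expected, rel=1e-12)


class TestExternalCatalysis:
    def test_vanishes_without_catalyst(self, catalysis):
        assert external_catalysis_rate(293.15, 0.0, catalysis) == 0.0

    def test_linear_in_concentration(self, catalysis):
        k1 = external_catalysis_rate(300.0, 2e-3, catalysis)
        k2 = external_catalysis_rate(300.0, 4e-3, catalysis)
        assert k2 == pytest.approx(2.0 * k1, rel=1e-12)

    def test_term_by_term_oracle(self):
        cat = CatalysisModel(dH_tr_ntp=40.0, dS_tr_ntp=-20.0, d_dif=0.7, c_ref=2e-3)
        T, c = 305.0, 0.017
        expected = (
            0.7
            * (K_B * T / H_PLANCK)
            * math.exp(-(40.0e3 - T * (-20.0)) / (R * T))
            * (c / 2e-3)
        )
        assert external_catalysis_rate(T, c, cat) == pytest.approx(expected, rel=1e-12)

    def test_negative_concentration_rejected(self, catalysis):
        with pytest.raises(ValueError):
            external_catalysis_rate(300.0, -1e-3, catalysis)


def _compose_oracle(T, c, bp, cat):
    """Independent scalar composition of the EX2 exchange model."""
    k_int = (K_B * T / H_PLANCK) * math.exp(
        -(bp.dH_tr_int * 1e3 - T * bp.dS_tr_int) / (R * T)
    )
    k_ntp = (K_B * T / H_PLANCK) * math.exp(
        -(cat.dH_tr_ntp * 1e3 - T * cat.dS_tr_ntp) / (R * T)
    )
    k_ext = cat.d_dif * k_ntp * c / cat.c_ref
    K = math.exp(-(bp.dH_diss * 1e3 - T * bp.dS_diss) / (R * T))
    return (k_int + k_ext) / (1.0 + 1.0 / K) + bp.d


class TestExchangeModel:
    def test_open_state_limit(self, catalysis):
        # strongly negative opening free energy: every molecule open
        bp = BasePairThermo("x", -100.0, 0.0, 55.0, 25.0, d=1.5)
        T, c = 300.0, 5e-3
        expected = (
            eyring_rate(T, 55.0, 25.0)
            + external_catalysis_rate(T, c, catalysis)
            + 1.5
        )
        assert exchange_rate_model(T, c, bp, catalysis) == pytest.approx(
            expected, rel=1e-9
        )

    def test_vanishing_transfer_leaves_dipolar_offset(self, catalysis):
        bp = BasePairThermo("x", 50.0, 100.0, 290.0, 0.0, d=2.3)
        assert exchange_rate_model(300.0, 0.0, bp, catalysis) == pytest.approx(
            2.3, rel=1e-9
        )

    def test_composition_oracle(self, rng):
        cat = CatalysisModel(dH_tr_ntp=35.0, dS_tr_ntp=-35.0, d_dif=0.3, c_ref=1e-3)
        for _ in range(200):
            bp = BasePairThermo(
                "x",
                dH_diss=rng.uniform(20, 300),
                dS_diss=rng.uniform(50, 800),
                dH_tr_int=rng.uniform(20, 100),
                dS_tr_int=rng.uniform(-100, 100),
                d=rng.uniform(0.1, 5),
            )
            T = rng.uniform(268, 328)
            c = rng.uniform(0.0, 0.05)
            got = exchange_rate_model(T, c, bp, cat)
            want = _compose_oracle(T, c, bp, cat)
            assert got == pytest.approx(want, rel=1e-12)

    def test_monotone_in_catalyst_and_bounded_below_by_d(self, g28_truth, catalysis):
        T = np.linspace(268.0, 328.0, 21)
        prev = None
        for c in (0.0, 2e-3, 10e-3, 29e-3):
            k = exchange_rate_model(T, c, g28_truth, catalysis)
            assert np.all(k >= g28_truth.d)
            if prev is not None:
                assert np.all(k >= prev)
            prev = k


class TestGibbsCurve:
    def test_crossing_of_two_traces_matches_closed_form(self):
        a = BasePairThermo("G28", 193.5, 561.9)
        b = BasePairThermo("G27", 148.4, 416.1)
        t_cross = (a.dH_diss - b.dH_diss) / (a.dS_diss - b.dS_diss) * 1e3
        ga = dict(gibbs_curve(a, [t_cross]))[t_cross]
        gb = dict(gibbs_curve(b, [t_cross]))[t_cross]
        assert ga == pytest.approx(gb, abs=1e-9)

    def test_compensation_line_members_meet_at_tc(self):
        Tc, y0 = 322.6, 13.0
        bps = [
            BasePairThermo(f"m{i}", Tc * dS / 1e3 + y0, dS)
            for i, dS in enumerate((100.0, 400.0, 700.0))
        ]
        for bp in bps:
            (_, g), = gibbs_curve(bp, [Tc])
            assert g == pytest.approx(y0, abs=1e-9)

    def test_zero_entropy_gives_flat_trace(self):
        bp = BasePairThermo("x", 42.0, 0.0)
        vals = [g for _, g in gibbs_curve(bp, np.linspace(260, 340, 9))]
        assert vals == pytest.approx([42.0] * 9)


class TestDomainTypes:
    def test_observation_invariants(self):
        with pytest.raises(ValueError):
            ExchangeObservation(T=-1.0, c_cat=0.0, k_ex=1.0, sigma=0.1)
        with pytest.raises(ValueError):
            ExchangeObservation(T=300.0, c_cat=-1e-3, k_ex=1.0, sigma=0.1)
        with pytest.raises(ValueError):
            ExchangeObservation(T=300.0, c_cat=0.0, k_ex=1.0, sigma=0.0)

    def test_joint_label_marks_averaged(self):
        bp = BasePairThermo("U7/U37", 86.9, 206.5)
        assert bp.averaged

    def test_negative_dipolar_offset_rejected(self):
        with pytest.raises(ValueError):
            BasePairThermo("x", 50.0, 100.0, d=-0.1)
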