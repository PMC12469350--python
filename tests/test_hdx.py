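"""H/D-exchange decay fitting, intrinsic rates and protection factors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acpdyn.hdx import (R_KCAL, ExchangeFit, dg_to_logp, fit_exchange_decay,
                        intrinsic_rate, protection)
from acpdyn.io_tables import ResidueID, SeriesTable

RID = ResidueID(11, "I")


def make_series(I0, k, C, t_max=60000.0, n=101, sigma=0.0, rng=None):
    t = np.linspace(0.0, t_max, n)
    y = I0 * np.exp(-k * t) + C
    if sigma > 0:
        y = np.clip(y + rng.normal(0, sigma, n), 0, None)
    return SeriesTable(RID, t, y, x_unit="s")


class TestExchangeFit:
    def test_noiseless_recovery_to_six_digits(self):
        k_true = 0.005 / 60.0  # 0.005 min^-1
        fit = fit_exchange_decay(make_series(1.0, k_true, 0.1))
        assert fit.I0 == pytest.approx(1.0, rel=1e-6)
        assert fit.k_ex == pytest.approx(k_true, rel=1e-6)
        assert fit.C == pytest.approx(0.1, rel=1e-6)
        assert not fit.censored

    def test_flat_series_censored_with_upper_bound(self):
        fit = fit_exchange_decay(make_series(0.0, 0.0, 0.9))
        assert fit.censored
        # censored rate is the 5%-decay-over-window upper bound
        assert fit.k_ex == pytest.approx(-math.log(0.95) / 60000.0)

    def test_scale_invariance_of_rate(self):
        k_true = 1e-4
        base = make_series(1.0, k_true, 0.05)
        scaled = SeriesTable(RID, base.x, base.y * 7.3e5, x_unit="s")
        assert fit_exchange_decay(scaled).k_ex == pytest.approx(
            fit_exchange_decay(base).k_ex, rel=1e-8)

    @pytest.mark.parametrize("kt_max", [0.2, 1.0, 5.0, 20.0])
    def test_round_trip_exact_across_decay_range(self, kt_max):
        k = kt_max / 60000.0
        fit = fit_exchange_decay(make_series(2.0, k, 0.3))
        assert fit.k_ex == pytest.approx(k, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_exchange_decay(SeriesTable(RID, [0, 1, 2], [1, 0.5, 0.2]))


class TestIntrinsicRate:
    def test_pd_sweep_is_v_shaped(self):
        pds = np.arange(1.0, 7.01, 0.05)
        rates = np.array([intrinsic_rate("A", "A", "A", pD=p) for p in pds])
        minima = (np.diff(np.sign(np.diff(rates))) > 0).sum()
        assert minima == 1
        assert rates[0] > rates.min() and rates[-1] > rates.min()

    def test_rate_increases_with_temperature(self):
        temps = np.linspace(283.15, 313.15, 31)
        rates = [intrinsic_rate("A", "A", "A", pD=6.5, T=t) for t in temps]
        assert np.all(np.diff(rates) > 0)

    def test_proline_amide_rejected(self):
        with pytest.raises(ValueError, match="proline"):
            intrinsic_rate("P", "A", "A")

    def test_neighbor_corrections_change_rate(self):
        assert intrinsic_rate("I", "I", "A") < intrinsic_rate("A", "A", "A")

    def test_terminal_corrections_apply(self):
        internal = intrinsic_rate("A", "A", "A", position="internal")
        nterm = intrinsic_rate("A", "A", "A", position="nterm")
        cterm = intrinsic_rate("A", "A", "A", position="cterm")
        assert nterm != internal and cterm != internal


class TestProtection:
    def test_simple_ratio(self):
        fit = ExchangeFit(RID, I0=1.0, C=0.0, k_ex=1e-3, k_err=0.0)
        res = protection(fit, k_rc=10.0)
        assert res.P == pytest.approx(1e4)
        assert res.logP == pytest.approx(4.0)

    def test_identity_case_zero_energy(self):
        fit = ExchangeFit(RID, I0=1.0, C=0.0, k_ex=0.5, k_err=0.0)
        res = protection(fit, k_rc=0.5)
        assert res.logP == pytest.approx(0.0, abs=1e-12)
        assert res.dG_local == pytest.approx(0.0, abs=1e-12)

    def test_logp_4p2_matches_1p5x_global_free_energy(self):
        # dG at logP 4.2 and 298.15 K ~ 5.73 kcal/mol ~ 1.5 x 3.83 = 5.745
        fit = ExchangeFit(RID, I0=1.0, C=0.0, k_ex=10.0 ** -4.2, k_err=0.0)
        res = protection(fit, k_rc=1.0, T=298.15)
        assert res.dG_local == pytest.approx(5.73, abs=0.005)
        assert res.dG_local == pytest.approx(1.5 * 3.83, abs=0.02)

    @given(logp=st.floats(-2, 8), T=st.floats(280, 320))
    @settings(max_examples=50, deadline=None)
    def test_energy_identity_exact(self, logp, T):
        fit = ExchangeFit(RID, I0=1.0, C=0.0, k_ex=10.0 ** -logp, k_err=0.0)
        res = protection(fit, k_rc=1.0, T=T)
        assert res.dG_local == pytest.approx(
            math.log(10.0) * R_KCAL * T * res.logP, abs=1e-12)
        assert dg_to_logp(res.dG_local, T) == pytest.approx(res.logP, abs=1e-9)

    def test_nonpositive_inputs_rejected(self):
        fit = ExchangeFit(RID, I0=1.0, C=0.0, k_ex=0.0, k_err=0.0)
        with pytest.raises(ValueError):
            protection(fit, k_rc=1.0)
        good = ExchangeFit(RID, I0=1.0, C=0.0, k_ex=1e-3, k_err=0.0)
        with pytest.raises(ValueError):
            protection(good, k_rc=0.0)
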