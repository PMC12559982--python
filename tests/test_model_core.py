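"""Closed-form kinetics: Ca-dependent rates, equilibria, scalar relations."""

import math

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import calyxstp as cx
from calyxstp.model_core import transient_integral


def brute_equilibrium_fractions(k1, b1, k2, b2):
    """Independent oracle: chain detailed balance, plain arithmetic."""
    w_es, w_ls = 1.0, k1 / b1
    w_ts = w_ls * k2 / b2
    total = w_es + w_ls + w_ts
    return w_es / total, w_ls / total, w_ts / total


class TestPrimingRates:
    def test_rest_returns_resting_rates(self, control_blocks):
        params, _, _ = control_blocks
        assert cx.priming_rates(params, params.ca_rest) == (0.370, 0.199)

    def test_linear_rise_above_rest(self, control_blocks):
        params, _, _ = control_blocks
        k1, k2 = cx.priming_rates(params, 438e-9)
        # direct substitution: k_rest + sigma * (ca - ca_rest)
        assert k1 == pytest.approx(0.370 + 2.245e6 * 388e-9, rel=1e-12)
        assert k2 == pytest.approx(0.199 + 1.014e6 * 388e-9, rel=1e-12)

    def test_zero_slopes_give_resting_rates_everywhere(self, control_blocks):
        params, _, _ = control_blocks
        flat = replace(params, sigma1=0.0, sigma2=0.0)
        for ca in (0.0, 1e-9, 1e-6):
            assert cx.priming_rates(flat, ca) == (params.k1_rest, params.k2_rest)

    def test_clamped_at_zero_below_rest(self, control_blocks):
        params, _, _ = control_blocks
        steep = replace(params, sigma1=1e10, sigma2=1e10)
        k1, k2 = cx.priming_rates(steep, params.ca_rest / 2)
        assert k1 == 0.0 and k2 == 0.0

    def test_negative_ca_rejected(self, control_blocks):
        params, _, _ = control_blocks
        with pytest.raises(ValueError):
            cx.priming_rates(params, -1e-9)


class TestEquilibrium:
    def test_control_resting_fractions(self, control_blocks):
        params, _, _ = control_blocks
        occ = cx.equilibrium_occupancy(params, 50e-9)
        es, ls, ts = brute_equilibrium_fractions(0.370, 0.221, 0.199, 0.253)
        assert occ.ES / params.N_total == pytest.approx(es, abs=1e-12)
        assert occ.LS / params.N_total == pytest.approx(ls, abs=1e-12)
        assert occ.TS / params.N_total == pytest.approx(ts, abs=1e-12)
        # about a quarter of docking sites are empty at rest
        assert occ.ES / params.N_total == pytest.approx(0.2506, abs=5e-4)

    def test_conservation_exact(self, control_blocks):
        params, _, _ = control_blocks
        for ca in (50e-9, 130e-9, 500e-9):
            occ = cx.equilibrium_occupancy(params, ca)
            assert occ.total() == pytest.approx(params.N_total, rel=1e-12)
            assert occ.TSL == 0.0 and occ.ERS == 0.0

    def test_no_maturation_means_no_tight_state(self, control_blocks):
        params, _, _ = control_blocks
        p0 = replace(params, k2_rest=0.0, sigma2=0.0)
        assert cx.equilibrium_occupancy(p0, 50e-9).TS == 0.0

    def test_degenerate_backward_rates_are_limits(self, control_blocks):
        params, _, _ = control_blocks
        # b2 = 0: tight docking irreversible, everything matures
        occ = cx.equilibrium_occupancy(replace(params, b2=0.0), 50e-9)
        assert occ.TS == pytest.approx(params.N_total)
        # b1 = 0: no undocking, no empty sites
        occ = cx.equilibrium_occupancy(replace(params, b1=0.0), 50e-9)
        assert occ.ES == 0.0
        assert occ.TS / occ.LS == pytest.approx(0.199 / 0.253)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=50e-9, max_value=490e-9))
    def test_ts_and_frp_monotone_in_ca(self, control_blocks, ca):
        params, _, _ = control_blocks
        lo = cx.equilibrium_occupancy(params, ca)
        hi = cx.equilibrium_occupancy(params, ca + 10e-9)
        assert hi.TS >= lo.TS
        assert cx.frp_fraction(params, ca + 10e-9) >= cx.frp_fraction(params, ca)


class TestHalfMaxCa:
    def test_control_half_maximum_near_438_nm(self, control_blocks):
        params, _, _ = control_blocks
        ca_half = cx.half_max_ca(params)
        # independent oracle: plain bisection on the closed-form TS fraction
        ts = lambda ca: cx.equilibrium_occupancy(params, ca).TS / params.N_total
        target = ts(50e-9) + 0.5 * (1.0 - ts(50e-9))
        lo, hi = 50e-9, 10e-6
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if ts(mid) < target else (lo, mid)
        assert ca_half == pytest.approx(0.5 * (lo + hi), abs=0.05e-9)
        assert ca_half == pytest.approx(438e-9, abs=2e-9)

    def test_saturated_reference_returns_reference(self, control_blocks):
        params, _, _ = control_blocks
        sat = replace(params, b1=0.0, b2=0.0)
        assert cx.half_max_ca(sat, ca_ref=50e-9) == 50e-9

    def test_unbracketed_raises(self, control_blocks):
        params, _, _ = control_blocks
        flat = replace(params, sigma1=0.0, sigma2=0.0)
        with pytest.raises(ValueError):
            cx.half_max_ca(flat)


class TestFrpFraction:
    def test_resting_value(self, control_blocks):
        params, _, _ = control_blocks
        assert cx.frp_fraction(params, 50e-9) == pytest.approx(0.7494, abs=5e-4)

    def test_low_vs_high_ca_reduction(self, control_blocks):
        params, _, _ = control_blocks
        red = 1.0 - cx.frp_fraction(params, 50e-9) / cx.frp_fraction(params, 500e-9)
        assert red == pytest.approx(0.22, abs=0.01)

    def test_fast_docking_fills_all_sites(self, control_blocks):
        params, _, _ = control_blocks
        fast = replace(params, k1_rest=1e9)
        assert cx.frp_fraction(fast, 50e-9) == pytest.approx(1.0, abs=1e-6)


class TestInfluxRatio:
    def test_published_external_ca_step(self):
        assert cx.influx_ratio_mm(1.5, 2.0, 2.6) == pytest.approx(1.19, abs=0.005)

    def test_identity_and_saturation(self):
        assert cx.influx_ratio_mm(1.7, 1.7, 2.6) == 1.0
        assert cx.influx_ratio_mm(1.5, 2.0, 1e-12) == pytest.approx(1.0, rel=1e-6)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            cx.influx_ratio_mm(0.0, 2.0)


class TestEffectiveCa:
    def test_no_aps_and_before_first_ap(self, control_blocks):
        params, tp, _ = control_blocks
        assert cx.effective_ca(tp, 50e-9, [], [], 0.3) == 50e-9
        assert cx.effective_ca(tp, 50e-9, [0.1], [1.0], 0.05) == 50e-9

    def test_full_decay(self, control_blocks):
        params, tp, _ = control_blocks
        assert cx.effective_ca(tp, 50e-9, [0.0], [1.0], 1e3) == pytest.approx(
            50e-9, rel=1e-9
        )

    def test_local_component_integral_share(self, control_blocks):
        # the fast local transient carries ~16% of the Ca time integral
        _, tp, _ = control_blocks
        comp, total = transient_integral(tp)
        assert comp[0] / total == pytest.approx(0.162, abs=0.002)

    def test_integral_matches_analytic(self, control_blocks):
        params, tp, _ = control_blocks
        f = lambda t: cx.effective_ca(tp, 0.0, [0.0], [1.0], t)
        num = quad(f, 0, 20, limit=400, epsabs=1e-18, epsrel=1e-11)[0]
        _, total = transient_integral(tp)
        assert num == pytest.approx(total, rel=1e-7)

    def test_additive_superposition_vs_reset(self, control_blocks):
        _, tp, _ = control_blocks
        t = 0.105
        add = cx.effective_ca(tp, 50e-9, [0.0, 0.1], [1.0, 1.0], t)
        reset = cx.effective_ca(tp, 50e-9, [0.0, 0.1], [1.0, 1.0], t, summation="reset")
        single = cx.effective_ca(tp, 50e-9, [0.1], [1.0], t)
        first = cx.effective_ca(tp, 50e-9, [0.0], [1.0], t)
        assert reset == pytest.approx(single)
        assert add == pytest.approx(single + first - 50e-9)
        assert add >= 50e-9

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=0.0, max_value=2.0))
    def test_never_below_rest(self, control_blocks, t):
        _, tp, _ = control_blocks
        times = [0.0, 0.02, 0.4]
        scales = [1.1, 0.9, 1.0]
        assert cx.effective_ca(tp, 50e-9, times, scales, t) >= 50e-9


class TestParameterIO:
    def test_builtin_conditions_validate(self):
        for name in cx.BUILTIN_CONDITIONS:
            params, tp, idp = cx.builtin_condition(name)
            assert 0 < params.p_fusion <= 1
            assert params.N_total > 0

    def test_unknown_condition(self):
        with pytest.raises(KeyError):
            cx.builtin_condition("nope")

    def test_yaml_round_trip(self, tmp_path, control_blocks):
        path = tmp_path / "control.yaml"
        cx.dump_condition("control", path)
        params, tp, idp = cx.load_condition(path)
        ref_params, ref_tp, ref_idp = control_blocks
        assert params == ref_params
        assert tp == ref_tp
        assert idp == ref_idp

    def test_unit_tagged_concentrations(self, tmp_path):
        cx.dump_condition("control", tmp_path / "c.yaml")
        import yaml

        with open(tmp_path / "c.yaml") as fh:
            data = yaml.safe_load(fh)
        data["priming"]["ca_rest"] = "50 nM"
        with open(tmp_path / "c.yaml", "w") as fh:
            yaml.safe_dump(data, fh)
        params, _, _ = cx.load_condition(tmp_path / "c.yaml")
        assert params.ca_rest == pytest.approx(50e-9)

    def test_invariant_violations_rejected(self, control_blocks):
        params, _, _ = control_blocks
        with pytest.raises(ValueError):
            replace(params, p_fusion=1.5)
        with pytest.raises(ValueError):
            replace(params, b1=-0.1)
        with pytest.raises(ValueError):
            replace(params, N_total=0)
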