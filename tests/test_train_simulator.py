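"""Hybrid ODE/event train simulation: events, conservation, STP behaviour."""

import numpy as np
import pytest
from dataclasses import replace

import calyxstp as cx
from calyxstp.train_simulator import _integrate_interval, relax_influx_scales


class TestInfluxScales:
    def test_no_dynamics_stays_at_unity(self, control_blocks):
        _, _, idp = control_blocks
        flat = replace(idp, y_inc=0.0, z_dec=0.0)
        y, z = 1.0, 1.0
        for _ in range(5):
            y, z = cx.update_influx_scales(flat, y, z, isi=0.005)
        assert (y, z) == (1.0, 1.0)

    def test_infinite_interval_fully_relaxes(self, control_blocks):
        _, _, idp = control_blocks
        assert cx.update_influx_scales(idp, 1.3, 0.9, isi=np.inf) == (1.0, 1.0)

    def test_first_ap_kick_from_rest(self, control_blocks):
        # y = 1 + 0.39 * (1.31 - 1) with the control facilitation parameters
        _, _, idp = control_blocks
        y, z = cx.update_influx_scales(idp, 1.0, 1.0)
        assert y == pytest.approx(1.1209, abs=1e-12)
        assert z == pytest.approx(1.0 - 0.4 * (1.0 - 0.87), abs=1e-12)

    def test_relaxation_is_exponential(self, control_blocks):
        _, _, idp = control_blocks
        y, z = relax_influx_scales(idp, 1.31, 0.87, idp.tau_y)
        assert y == pytest.approx(1.0 + 0.31 * np.exp(-1.0))


class TestSimulateTrain:
    def test_first_response_is_resting_ts_times_pfusion(self, control_blocks):
        params, tp, idp = control_blocks
        res = cx.simulate_train(params, tp, idp, cx.StimulusProtocol(f_stim=100.0))
        eq = cx.equilibrium_occupancy(params, params.ca_rest)
        assert res.m[0] == pytest.approx(params.p_fusion * eq.TS, rel=1e-12)
        # control numbers: 0.22 * 2622 * 0.3300 ~ 190 vesicles
        assert res.m[0] == pytest.approx(190.3, abs=0.5)

    def test_zero_pfusion_releases_nothing(self, control_blocks):
        params, tp, idp = control_blocks
        silent = replace(params, p_fusion=0.0, kappa_TSL=0.0)
        res = cx.simulate_train(
            silent, tp, idp, cx.StimulusProtocol(f_stim=20.0, n_stim=10),
            record_trajectory=True,
        )
        assert np.all(res.m == 0.0)
        eq = cx.equilibrium_occupancy(silent, silent.ca_rest).as_array()
        # Ca transients transiently shift the equilibrium; the state returns
        # toward it and never loses vesicles
        assert res.state_trajectory.sum(axis=1) == pytest.approx(
            silent.N_total, rel=1e-6
        )
        assert res.final_state[4] == 0.0  # no refractory sites without fusion

    def test_conservation_through_events(self, control_train_200hz, control_blocks):
        params, _, _ = control_blocks
        res = cx.simulate_train(
            params, *control_blocks[1:], cx.StimulusProtocol(f_stim=200.0),
            record_trajectory=True,
        )
        totals = res.state_trajectory.sum(axis=1)
        assert np.max(np.abs(totals - params.N_total)) / params.N_total < 1e-6

    def test_pure_depression_is_monotone(self, control_blocks):
        params, tp, idp = control_blocks
        depr = replace(params, sigma1=0.0, sigma2=0.0, kappa_TSL=0.0)
        flat = replace(idp, y_inc=0.0)
        res = cx.simulate_train(depr, tp, flat, cx.StimulusProtocol(f_stim=100.0))
        assert np.all(np.diff(res.m) <= 1e-12)

    def test_facilitation_at_200hz(self, control_train_200hz):
        # net paired-pulse facilitation requires the labile tight state
        assert control_train_200hz.m[1] / control_train_200hz.m[0] > 1.0

    def test_constant_pfusion_variant_depresses(self, control_blocks):
        params, tp, idp = control_blocks
        res = cx.simulate_train(
            params, tp, idp, cx.StimulusProtocol(f_stim=200.0),
            p_fusion_cooperativity=0.0,
        )
        assert np.all(res.p_fusion_history == params.p_fusion)
        assert res.m[1] / res.m[0] < 1.0

    def test_preconditioning_reduces_initial_response(self, control_blocks):
        params, tp, idp = control_blocks
        plain = cx.simulate_train(params, tp, idp, cx.StimulusProtocol(f_stim=200.0))
        pre = cx.simulate_train(
            params, tp, idp,
            cx.StimulusProtocol(f_stim=200.0, precondition=cx.Precondition(n_pre=4)),
        )
        assert pre.m[0] < plain.m[0]
        assert pre.m[1:].max() / pre.m[0] > plain.m[1:].max() / plain.m[0]
        assert pre.m_pre.size == 4

    def test_tolerance_independence(self, control_blocks):
        params, tp, idp = control_blocks
        proto = cx.StimulusProtocol(f_stim=200.0)
        a = cx.simulate_train(params, tp, idp, proto, rtol=1e-8)
        b = cx.simulate_train(params, tp, idp, proto, rtol=5e-9)
        assert np.max(np.abs(a.m - b.m) / a.m) < 1e-4

    def test_es_occupancy_robustness(self, control_blocks):
        """Scaling k1 to keep k1*ES(rest) constant while the resting empty
        fraction varies within 15-30% leaves the release time course similar."""
        params, tp, idp = control_blocks
        ref = cx.simulate_train(params, tp, idp, cx.StimulusProtocol(f_stim=100.0))
        eq = cx.equilibrium_occupancy(params, params.ca_rest)
        flux = params.k1_rest * eq.ES
        r2 = params.k2_rest / params.b2

        pool = eq.LS + eq.TS

        def with_es_fraction(f_es):
            # keep the resting docked pool (LS+TS) and the docking flux k1*ES
            # fixed while moving the vacancy share to f_es; N_total absorbs
            # the difference and b1 restores the flux balance
            n_total = pool / (1.0 - f_es)
            es = f_es * n_total
            ls = pool / (1.0 + r2)
            k1 = flux / es
            b1 = flux / ls
            alt = replace(params, N_total=n_total, k1_rest=k1, b1=b1,
                          sigma1=params.sigma1 * k1 / params.k1_rest)
            eq_s = cx.equilibrium_occupancy(alt, alt.ca_rest)
            np.testing.assert_allclose(eq_s.ES / alt.N_total, f_es, rtol=1e-9)
            return alt

        for target in (0.15, 0.30):
            alt = with_es_fraction(target)
            res = cx.simulate_train(alt, tp, idp, cx.StimulusProtocol(f_stim=100.0))
            rel = np.abs(res.m[:10] - ref.m[:10]) / ref.m[:10]
            assert np.max(rel) < 0.10

    def test_relaxes_to_closed_form_equilibrium(self, control_blocks):
        """Long unstimulated integration from a perturbed state matches the
        closed-form equilibrium to high precision for every condition."""
        for name in cx.BUILTIN_CONDITIONS:
            params, tp, _ = cx.builtin_condition(name)
            eq = cx.equilibrium_occupancy(params, params.ca_rest).as_array()
            start = np.array([params.N_total, 0.0, 0.0, 0.0, 0.0])
            final, _ = _integrate_interval(
                params, tp, start, np.zeros(3), 0.0, 250.0, 1e-10, "DOP853"
            )
            assert np.max(np.abs(final - eq)) / params.N_total < 1e-6

    def test_invalid_inputs(self, control_blocks):
        params, tp, idp = control_blocks
        with pytest.raises(ValueError):
            cx.StimulusProtocol(f_stim=0.0)
        with pytest.raises(ValueError):
            cx.simulate_train(params, tp, idp, cx.StimulusProtocol(f_stim=10.0),
                              initial_state=[-1, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            cx.simulate_train(params, tp, idp, cx.StimulusProtocol(f_stim=10.0),
                              summation="bogus")


class TestSteadyStateRelease:
    def test_constant_train(self):
        m = np.full(40, 7.0)
        assert cx.steady_state_release(m, "last") == 7.0
        assert cx.steady_state_release(m, "mean_last5") == 7.0

    def test_decreasing_train_last(self):
        m = np.arange(40, 0, -1.0)
        assert cx.steady_state_release(m, "last") == 1.0

    def test_mean_last5_within_bounds(self, control_train_200hz):
        tail = control_train_200hz.m[35:40]
        ss = cx.steady_state_release(control_train_200hz, "mean_last5")
        assert tail.min() <= ss <= tail.max()

    def test_short_train_rejected(self):
        with pytest.raises(ValueError):
            cx.steady_state_release(np.ones(10), "mean_last5")


class TestRecovery:
    def test_full_recovery_at_long_intervals(self, control_blocks):
        params, tp, idp = control_blocks
        fr, m_test, cond = cx.simulate_recovery(
            params, tp, idp, cx.StimulusProtocol(f_stim=100.0), [1.0, 8.0, 40.0]
        )
        assert fr[-1] == pytest.approx(1.0, abs=0.02)
        assert np.all(np.diff(fr) > 0)

    def test_fast_component_after_high_frequency(self, control_blocks):
        params, tp, idp = control_blocks
        fr200, _, _ = cx.simulate_recovery(
            params, tp, idp, cx.StimulusProtocol(f_stim=200.0), [0.25]
        )
        fr20, _, _ = cx.simulate_recovery(
            params, tp, idp, cx.StimulusProtocol(f_stim=20.0), [0.25]
        )
        assert fr200[0] > fr20[0]

    def test_undefined_fraction_reported_as_nan(self, control_blocks):
        params, tp, idp = control_blocks
        silent = replace(params, p_fusion=0.0, kappa_TSL=0.0)
        fr, _, _ = cx.simulate_recovery(
            silent, tp, idp, cx.StimulusProtocol(f_stim=100.0, n_stim=10), [0.5]
        )
        assert np.isnan(fr[0])

    def test_bad_intervals_rejected(self, control_blocks):
        params, tp, idp = control_blocks
        with pytest.raises(ValueError):
            cx.simulate_recovery(params, tp, idp,
                                 cx.StimulusProtocol(f_stim=100.0), [0.5, 0.25])
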