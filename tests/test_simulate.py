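"""Simulator unit and property tests.

The binding propagator is checked against an independent numerical ODE
integration (scipy.integrate.solve_ivp) and against closed-form limits of
the two-state model; generators are checked for seeded reproducibility and
for the session structures they are meant to emulate.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from fluokit import (
    BleachSpec,
    EventSchedule,
    SensorSimParams,
    generate_event_schedule,
    generate_pr_schedule,
    simulate_binding_response,
    simulate_dose_response,
    simulate_linescan,
    simulate_photometry_session,
)


class TestBindingResponse:
    def test_zero_ligand_stays_at_baseline(self, params):
        t = np.arange(0, 10, 0.01)
        B, F = simulate_binding_response(params, np.zeros_like(t), t)
        assert np.all(B == 0)
        assert np.allclose(F, params.f0)

    def test_equilibrium_at_kd_is_half_occupancy(self, params):
        # hold L = Kd long enough to equilibrate: >= 10 / (k_on*Kd + k_off)
        rate = params.k_on * params.kd + params.k_off
        t = np.arange(0, 12.0 / rate, 0.05)
        B, F = simulate_binding_response(params, np.full_like(t, params.kd), t)
        assert B[-1] == pytest.approx(0.5, abs=1e-4)
        dff = (F[-1] - params.f0) / params.f0
        assert dff == pytest.approx(params.r_max / 2, rel=1e-3)

    def test_step_response_matches_closed_form(self, params):
        # step to 1 uM with k_on = 1e6, k_off = 0.029: rate = k_on*L + k_off
        L0 = 1e-6
        t = np.arange(0, 8, 0.001)
        B, _ = simulate_binding_response(params, np.full_like(t, L0), t)
        r = params.k_on * L0 + params.k_off
        beq = params.k_on * L0 / r
        expected = beq * (1.0 - np.exp(-r * t))
        assert np.allclose(B, expected, rtol=1e-6, atol=1e-12)

    def test_matches_ode_integrator_on_varying_ligand(self, params):
        # independent oracle: numerically integrate the mass-action ODE
        t = np.arange(0, 30, 0.01)
        L = np.where(t < 10, 0.0, np.where(t < 20, 2 * params.kd, 0.5 * params.kd))
        B, _ = simulate_binding_response(params, L, t)

        def lig(x):
            return 0.0 if x < 10 else (2 * params.kd if x < 20 else 0.5 * params.kd)

        sol = solve_ivp(
            lambda x, b: params.k_on * lig(x) * (1 - b[0]) - params.k_off * b[0],
            (0, t[-1]), [0.0], t_eval=t, max_step=0.01, rtol=1e-10, atol=1e-12,
        )
        assert np.allclose(B, sol.y[0], atol=1e-6)

    def test_negative_ligand_rejected(self, params):
        t = np.arange(0, 1, 0.1)
        with pytest.raises(ValueError, match="non-negative"):
            simulate_binding_response(params, np.full_like(t, -1e-9), t)

    @settings(max_examples=25, deadline=None)
    @given(
        k_on=st.floats(1e4, 1e8),
        k_off=st.floats(1e-3, 10.0),
        lig_kd=st.floats(0.1, 10.0),
    )
    def test_equilibrium_matches_one_site_curve(self, k_on, k_off, lig_kd):
        p = SensorSimParams(k_on=k_on, k_off=k_off)
        L0 = lig_kd * p.kd
        rate = k_on * L0 + k_off
        t_end = 12.0 / rate
        t = np.linspace(0, t_end, 500)
        B, _ = simulate_binding_response(p, np.full_like(t, L0), t)
        assert B[-1] == pytest.approx(L0 / (L0 + p.kd), abs=1e-4)
        assert np.all((B >= 0) & (B <= 1))


class TestPhotometrySession:
    def test_clean_empty_session_is_constant(self, params):
        sched = EventSchedule((), 10.0, "custom")
        rec = simulate_photometry_session(params, sched, rate=200.0)
        assert np.allclose(rec.signal, params.f0)
        assert np.allclose(rec.control, params.f0 * params.control_gain)

    def test_default_rate_matches_acquisition_system(self, params):
        sched = EventSchedule((), 2.0, "custom")
        rec = simulate_photometry_session(params, sched)
        assert rec.rate == 1017.25

    def test_seeded_sessions_are_bit_reproducible(self, noisy_params, injection_schedule):
        a = simulate_photometry_session(noisy_params, injection_schedule, rate=50.0)
        b = simulate_photometry_session(noisy_params, injection_schedule, rate=50.0)
        assert np.array_equal(a.signal, b.signal)
        assert np.array_equal(a.control, b.control)

    def test_motion_artifact_is_shared_between_channels(self):
        # multiplicative shared artifact: the channel ratio stays constant
        p = SensorSimParams(motion_sd=0.05, seed=3)
        sched = EventSchedule((), 30.0, "custom")
        rec = simulate_photometry_session(p, sched, rate=100.0)
        ratio = rec.signal / rec.control
        assert np.allclose(ratio, ratio[0], rtol=1e-12)
        assert rec.signal.std() > 0.01 * p.f0  # the artifact is actually there

    def test_ligand_only_on_signal_channel(self, params):
        sched = EventSchedule([(5.0, "injection", 0.0)], 60.0, "injection")
        rec = simulate_photometry_session(params, sched, rate=100.0)
        assert np.allclose(rec.control, rec.control[0])
        assert rec.signal[-1] > rec.signal[0] * 2


class TestLinescan:
    def test_background_only_stack(self, params):
        stack = simulate_linescan(params, 0, 8, seed=0)
        assert stack.n_pixels == 8
        assert not stack.membrane_mask_truth.any()
        assert np.ptp(stack.data.mean(axis=1)) < params.f0  # dim, unresponsive

    def test_membrane_pixels_follow_target_time_constant(self, params):
        stack = simulate_linescan(params, 3, 0, tau_true=0.5, seed=1)
        t = stack.t
        rel = np.clip(t - 0.5, 0, None)
        expected = 1.0 - np.exp(-rel / 0.5)
        expected /= expected[-1]           # min-max normalization rescales by the peak
        for i in range(3):
            y = stack.data[i]
            norm = (y - y.min()) / np.ptp(y)
            assert np.allclose(norm[t >= 0.5], expected[t >= 0.5], atol=1e-9)

    def test_reference_dye_reaches_85pct_at_latency(self, params):
        from fluokit import onset_latency

        stack = simulate_linescan(params, 2, 2, dye_latency=0.02, seed=0)
        gate = onset_latency(stack.reference.mean(axis=0), stack.rate,
                             application_time=0.5)
        assert gate.latency == pytest.approx(0.02, abs=2.0 / stack.rate)
        assert gate.passed


class TestDoseResponse:
    def test_noise_free_plate_lies_on_hill_curve(self):
        conc = np.array([1e-9, 1e-8, 1e-7, 1e-6])
        tab = simulate_dose_response(2.0, 3e-8, 1.0, conc, replicates=2, cv=0.0)
        expected = 2.0 * conc / (3e-8 + conc)
        for rep in (0, 1):
            got = tab[tab.replicate_id == rep]["response"].to_numpy()
            assert np.allclose(got, expected)

    def test_half_maximum_at_ec50(self):
        tab = simulate_dose_response(3.88, 28.65e-9, 1.0, [28.65e-9],
                                     replicates=1, cv=0.0)
        assert tab["response"].iloc[0] == pytest.approx(3.88 / 2)

    def test_default_ladder_matches_bath_protocol(self):
        tab = simulate_dose_response(1.0, 3e-8, 1.0, replicates=1)
        got = sorted(tab["concentration_M"])
        assert got == [5e-9, 10e-9, 50e-9, 100e-9, 500e-9, 1e-6, 5e-6, 10e-6]

    def test_empty_concentration_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_dose_response(1.0, 1e-8, 1.0, [], replicates=1)

    def test_seeded_plates_reproduce(self):
        a = simulate_dose_response(1.0, 1e-8, 1.0, cv=0.1, seed=9)
        b = simulate_dose_response(1.0, 1e-8, 1.0, cv=0.1, seed=9)
        assert a.equals(b)


class TestProgressiveRatio:
    def test_printed_sequence(self):
        assert generate_pr_schedule(6) == [1, 2, 4, 6, 9, 12]

    def test_tenth_criterion(self):
        # round(5*e^2 - 5) = round(31.945...) = 32
        assert generate_pr_schedule(10)[-1] == 32

    def test_zero_rewards(self):
        assert generate_pr_schedule(0) == []

    def test_matches_brute_force_and_non_decreasing(self):
        import math

        got = generate_pr_schedule(50)
        brute = []
        for i in range(1, 51):
            x = 5 * math.exp(i / 5) - 5
            frac = x - math.floor(x)
            brute.append(math.floor(x) + (1 if frac >= 0.5 else 0))
        assert got == brute
        assert all(b >= a for a, b in zip(got, got[1:]))


class TestEventSchedules:
    def test_cued_sucrose_structure(self):
        sched = generate_event_schedule("cued_sucrose", seed=0)
        tones = [(t, d) for t, lab, d in sched.events if lab == "tone"]
        accesses = [(t, d) for t, lab, d in sched.events if lab == "access"]
        assert len(tones) == 15 and len(accesses) == 15
        assert all(d == 5.0 for _, d in tones)
        assert all(d == 5.0 for _, d in accesses)
        # access starts when the tone ends
        for (tt, _), (ta, _) in zip(tones, accesses):
            assert ta == pytest.approx(tt + 5.0)
        # inter-trial intervals within the stated 45-75 s range
        itis = np.diff([t for t, _ in tones]) - 10.0
        assert np.all((itis >= 45.0) & (itis <= 75.0))

    def test_tail_lift_structure(self):
        sched = generate_event_schedule("tail_lift", seed=1)
        lifts = [(t, d) for t, lab, d in sched.events if lab == "tail_lift"]
        assert len(lifts) == 4
        assert all(d == 10.0 for _, d in lifts)
        assert lifts[0][0] == pytest.approx(300.0)          # 5-min lead-in
        assert sched.session_length - (lifts[-1][0] + 10.0) >= 300.0
        itis = np.diff([t for t, _ in lifts]) - 10.0
        assert np.all((itis >= 120.0) & (itis <= 300.0))

    def test_zero_trials_gives_bounds_only(self):
        sched = generate_event_schedule("cued_sucrose", seed=0, n_trials=0)
        assert sched.events == ()
        assert sched.session_length > 0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown schedule variant"):
            generate_event_schedule("open_field", seed=0)

    def test_operant_pr_poke_bouts_follow_criteria(self):
        sched = generate_event_schedule("operant_pr", seed=0, session_s=2000.0)
        pellets = sched.times("pellet")
        pokes = sched.times("poke")
        criteria = generate_pr_schedule(len(pellets))
        # pokes between consecutive pellets match the growing criterion
        bounds = np.concatenate(([0.0], pellets))
        for k, crit in enumerate(criteria):
            n = ((pokes > bounds[k]) & (pokes < bounds[k + 1])).sum()
            assert n == crit

    def test_event_times_strictly_increasing(self):
        for variant in ("injection", "cued_sucrose", "tail_lift",
                        "operant_fr", "operant_pr"):
            sched = generate_event_schedule(variant, seed=2)
            times = [t for t, _, _ in sched.events]
            assert all(b > a for a, b in zip(times, times[1:]))


class TestBleachSpecs:
    @pytest.mark.parametrize("kind", ["none", "power_like", "biexponential", "polynomial"])
    def test_curves_start_at_one_and_stay_positive(self, kind):
        t = np.linspace(0, 1800, 2000)
        curve = BleachSpec(kind).curve(t)
        assert curve[0] == pytest.approx(1.0)
        assert np.all(curve > 0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown bleach kind"):
            BleachSpec("linear")
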