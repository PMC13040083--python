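"""E/S computation, bleach detection, classification, dwells, mixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lumensor import (
    CLOSED,
    OPEN,
    ClassifierThresholds,
    SensorKinetics,
    Trace,
    ValidationError,
    bound_fraction,
    classify_trace,
    compute_es,
    detect_bleach,
    extract_dwells,
    fit_fret_histogram,
    preprocess_trace,
    render_trace,
    simulate_state_path,
)
from lumensor.trace import threshold_states


def _trace(I_DD, I_DA, I_AA, frame_time=0.1):
    return Trace(np.asarray(I_DD, float), np.asarray(I_DA, float),
                 np.asarray(I_AA, float), frame_time)


def _constant_trace(e, n=200, total=1000.0, sigma=0.02, seed=0, frame_time=0.1):
    rng = np.random.default_rng(seed)
    e_app = e + rng.normal(0, sigma, n)
    return _trace(total * (1 - e_app), total * e_app, np.full(n, total),
                  frame_time)


class TestComputeES:
    def test_definition_arithmetic(self):
        traj = compute_es(_trace([40.0], [60.0], [100.0]))
        assert traj.E[0] == pytest.approx(0.6)
        assert traj.S[0] == pytest.approx(0.5)

    def test_zero_acceptor_emission_gives_zero_e(self):
        traj = compute_es(_trace([50.0, 80.0], [0.0, 0.0], [100.0, 100.0]))
        assert np.allclose(traj.E_usable, 0.0)

    def test_all_zero_trace_fully_masked_and_flagged(self):
        traj = compute_es(_trace([0.0] * 5, [0.0] * 5, [0.0] * 5))
        assert traj.n_usable == 0
        assert "all_zero" in traj.flags

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_es_invariant_under_uniform_rescaling(self, scale):
        a = compute_es(_trace([40.0, 10.0], [60.0, 90.0], [100.0, 100.0]))
        b = compute_es(
            _trace(
                [40.0 * scale, 10.0 * scale],
                [60.0 * scale, 90.0 * scale],
                [100.0 * scale, 100.0 * scale],
            )
        )
        assert np.allclose(a.E, b.E)
        assert np.allclose(a.S, b.S)

    def test_round_trip_with_noiseless_simulator(self, kinetics, noiseless):
        kin = kinetics.replace(k_close_base=0.0)
        p = simulate_state_path(kin, 0.0, 60.0, 3)
        tr = render_trace(p, noiseless, kin, seed=0, efficiency_noise_sd=0.0)
        assert np.allclose(compute_es(tr).E_usable, 0.6)


class TestDetectBleach:
    def test_no_bleach_returns_full_range(self, rng):
        n = 300
        tr = _trace(
            400 + rng.normal(0, 10, n), 600 + rng.normal(0, 10, n),
            1000 + rng.normal(0, 10, n),
        )
        res = detect_bleach(tr)
        assert res.acceptor_bleach_frame is None
        assert res.donor_bleach_frame is None
        assert res.usable_end == n
        assert not res.multi_fluorophore

    def test_simulator_forced_acceptor_bleach_located(self, kinetics,
                                                      photophysics):
        p = simulate_state_path(kinetics, 5.0, 60.0, 5)
        tr = render_trace(p, photophysics, kinetics, seed=6,
                          acceptor_bleach_time=30.0, donor_bleach_time=1e9)
        res = detect_bleach(tr)
        assert res.acceptor_bleach_frame is not None
        assert abs(res.acceptor_bleach_frame - 300) <= 3
        assert res.usable_end == res.acceptor_bleach_frame

    def test_two_step_staircase_flags_multi_fluorophore(self, rng):
        n = 300
        acc = np.concatenate(
            [2000 * np.ones(100), 1000 * np.ones(100), np.zeros(100)]
        ) + rng.normal(0, 15, n)
        tr = _trace(np.full(n, 500.0), np.full(n, 500.0), acc)
        assert detect_bleach(tr).multi_fluorophore

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            detect_bleach(_trace([1.0] * 5, [1.0] * 5, [1.0] * 5))


class TestClassify:
    def test_constant_levels(self):
        assert classify_trace(compute_es(_constant_trace(0.6))) == "static_low"
        assert classify_trace(compute_es(_constant_trace(0.9))) == "static_high"

    def test_dynamic_simulated_trace(self, kinetics, photophysics):
        p = simulate_state_path(kinetics, 2.0, 60.0, 9)
        assert len(p.states) > 4
        tr = render_trace(p, photophysics, kinetics, seed=10,
                          donor_bleach_time=1e9, acceptor_bleach_time=1e9)
        assert classify_trace(compute_es(tr)) == "dynamic"

    def test_rejection_rules(self):
        # too short
        assert classify_trace(compute_es(_constant_trace(0.6, n=30))) == "rejected"
        # stoichiometry out of band (acceptor-only-like species)
        rng = np.random.default_rng(0)
        n = 200
        tr = _trace(40 + rng.normal(0, 2, n), 60 + rng.normal(0, 2, n),
                    np.full(n, 5000.0))
        assert classify_trace(compute_es(tr)) == "rejected"
        # excessive efficiency noise
        noisy = compute_es(_constant_trace(0.7, sigma=0.3, seed=2))
        assert classify_trace(noisy) == "rejected"

    def test_deterministic_and_metadata_independent(self):
        traj = compute_es(_constant_trace(0.6))
        a = classify_trace(traj, ClassifierThresholds())
        traj.metadata["note"] = "relabelled"
        assert classify_trace(traj, ClassifierThresholds()) == a


class TestDwells:
    def test_run_length_encoding_example(self):
        path = np.array([OPEN, OPEN, CLOSED, CLOSED, CLOSED, OPEN])
        d = extract_dwells(path, 0.1)
        assert d.records == [
            (OPEN, pytest.approx(0.2), True, False),
            (CLOSED, pytest.approx(0.3), False, False),
            (OPEN, pytest.approx(0.1), False, True),
        ]

    def test_constant_path_single_fully_censored_dwell(self):
        d = extract_dwells(np.zeros(50, dtype=int), 0.1)
        assert len(d) == 1
        assert d.left_censored[0] and d.right_censored[0]

    def test_duration_conservation_property(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 500))
            path = rng.integers(0, 2, n)
            d = extract_dwells(path, 0.1)
            assert d.total_duration() == pytest.approx(n * 0.1)

    def test_simulation_round_trip_closed_lifetime(self, kinetics, noiseless):
        kin = kinetics.replace(sigma_E=0.01)
        rng = np.random.default_rng(11)
        dsets = []
        for _ in range(20):
            p = simulate_state_path(kin, 5.0, 60.0, rng)
            tr = render_trace(p, noiseless, kin, seed=rng)
            traj = compute_es(tr)
            dsets.append(extract_dwells(threshold_states(traj.E_usable), 0.1))
        from lumensor import DwellSet, rates_from_dwells

        _closing, opening = rates_from_dwells(DwellSet.concatenate(dsets))
        assert opening.rate == pytest.approx(2.0, abs=3 * opening.se + 0.15)


class TestMixture:
    def test_single_gaussian_mean_recovery(self, rng):
        x = rng.normal(0.6, 0.05, 5000)
        fit = fit_fret_histogram(x, n_components=1)
        assert fit.means[0] == pytest.approx(0.6, abs=0.01)

    def test_symmetric_mixture_areas(self, rng):
        x = np.concatenate(
            [rng.normal(0.6, 0.05, 4000), rng.normal(0.9, 0.05, 4000)]
        )
        fit = fit_fret_histogram(x, n_components=2)
        assert fit.means[0] == pytest.approx(0.6, abs=0.02)
        assert fit.means[1] == pytest.approx(0.9, abs=0.02)
        assert bound_fraction(fit) == pytest.approx(0.5, abs=0.05)

    def test_apo_simulation_dominated_by_low_component(self, photophysics):
        from lumensor import simulate_titration

        kin = SensorKinetics(k_close_base=0.0)
        titr = simulate_titration(kin, photophysics, [0.0], 20, seed=21)
        pooled = np.concatenate(
            [preprocess_trace(t).E_usable for t in titr.traces[0.0]]
        )
        fit = fit_fret_histogram(pooled, n_components=1)
        assert fit.means[0] == pytest.approx(0.6, abs=0.01)

    def test_bound_fraction_requires_two_components(self, rng):
        fit = fit_fret_histogram(rng.normal(0.6, 0.05, 1000), n_components=1)
        with pytest.raises(ValidationError):
            bound_fraction(fit)

    def test_degenerate_component_hits_variance_floor(self):
        x = np.concatenate([np.full(500, 0.6), np.full(500, 0.9)])
        fit = fit_fret_histogram(x, n_components=2)
        assert fit.variance_floored
        assert np.all(fit.sds >= 0.009)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValidationError):
            fit_fret_histogram(rng.normal(0.6, 0.05, 50))
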