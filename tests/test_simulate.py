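"""Synthetic-data generator: state paths, rendering, ensembles, protocols."""

import numpy as np
import pytest
from scipy.stats import expon, kstest

from lumensor import (
    CLOSED,
    OPEN,
    ExperimentProtocol,
    Phase,
    SensorKinetics,
    ValidationError,
    atp_edta_protocol,
    compute_es,
    mg_adp_control_protocol,
    render_trace,
    simulate_state_path,
    simulate_titration,
    simulate_transport_experiment,
    simulate_vesicle_ensemble,
    two_event_mg_atp_protocol,
)
from lumensor.simulate import Vesicle


def _pooled_dwells(kinetics, conc, state, n_target, seed):
    """Collect >= n_target complete dwells of one state from long paths."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_target:
        p = simulate_state_path(kinetics, conc, 2000.0, rng)
        d = p.dwell_durations[1:-1]
        s = p.states[1:-1]
        out.extend(d[s == state].tolist())
    return np.array(out[:n_target])


class TestStatePath:
    def test_zero_closing_rate_gives_single_open_dwell(self, rng):
        kin = SensorKinetics(k_close_base=0.0)
        p = simulate_state_path(kin, 0.0, 60.0, rng)
        assert len(p.states) == 1
        assert p.states[0] == OPEN
        assert p.entry_times[0] == 0.0 and p.exit_times[0] == 60.0

    def test_closed_dwell_mean_matches_opening_rate(self, kinetics):
        d = _pooled_dwells(kinetics, 5.0, CLOSED, 10_000, seed=7)
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean() - 0.5) < 3 * se

    def test_open_dwell_mean_matches_rate_additivity(self):
        kin = SensorKinetics(k_on=0.29, k_close_base=1.3)
        d = _pooled_dwells(kin, 10.0, OPEN, 10_000, seed=8)
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean() - 1.0 / 4.2) < 3 * se

    @pytest.mark.parametrize("state,rate", [(OPEN, 2.73), (CLOSED, 2.0)])
    def test_dwells_pass_ks_against_exponential(self, kinetics, state, rate):
        """Complete dwells follow the exponential laws (KS at alpha=0.01)."""
        d = _pooled_dwells(kinetics, 5.0, state, 10_000, seed=42 + state)
        stat, p = kstest(d, expon(scale=1.0 / rate).cdf)
        assert p > 0.01

    def test_stationary_closed_occupancy(self, kinetics, rng):
        c = 5.0
        p = simulate_state_path(kinetics, c, 20_000.0, rng)
        occ = p.dwell_durations[p.states == CLOSED].sum() / p.duration
        expected = kinetics.stationary_closed_fraction(c)
        assert abs(occ - expected) < 0.01

    def test_alternation_and_contiguity_invariants(self, kinetics):
        for seed in range(5):
            p = simulate_state_path(kinetics, 3.0, 120.0, seed)
            assert np.all(p.states[1:] != p.states[:-1])
            assert np.all(p.exit_times[:-1] == p.entry_times[1:])
            assert p.entry_times[0] == 0.0
            assert p.exit_times[-1] == pytest.approx(p.duration)
            assert np.all(p.dwell_durations > 0)

    def test_rejects_invalid_inputs(self, kinetics):
        with pytest.raises(ValidationError):
            simulate_state_path(kinetics, -1.0, 10.0, 0)
        with pytest.raises(ValidationError):
            simulate_state_path(kinetics, 1.0, 0.0, 0)

    def test_determinism_bit_identical(self, kinetics):
        a = simulate_state_path(kinetics, 2.0, 60.0, 99)
        b = simulate_state_path(kinetics, 2.0, 60.0, 99)
        assert np.array_equal(a.exit_times, b.exit_times)


class TestRenderTrace:
    def test_noiseless_all_open_recovers_e_open_exactly(self, kinetics, noiseless):
        kin = kinetics.replace(k_close_base=0.0)
        p = simulate_state_path(kin, 0.0, 60.0, 0)
        tr = render_trace(p, noiseless, kin, seed=1, efficiency_noise_sd=0.0)
        traj = compute_es(tr)
        assert np.allclose(traj.E_usable, kin.E_open)
        assert np.allclose(traj.S_usable, 0.5)

    def test_forced_acceptor_bleach_contract(self, kinetics, noiseless):
        p = simulate_state_path(kinetics, 5.0, 60.0, 2)
        tr = render_trace(
            p, noiseless, kinetics, seed=3, efficiency_noise_sd=0.0,
            acceptor_bleach_time=30.0,
        )
        assert np.all(tr.I_AA[300:] == noiseless.background)
        assert np.all(tr.I_DA[300:] == noiseless.background)
        traj = compute_es(tr)
        assert np.all(traj.S[301:] > 0.9)  # donor-only stoichiometry -> 1

    def test_noisy_closed_trace_mean(self, kinetics, noiseless):
        kin = kinetics.replace(sigma_E=0.05)
        p = simulate_state_path(kin.replace(k_open=0.0), 100.0, 50.0, 4)
        assert np.all(p.states == CLOSED) or len(p.states) == 1
        tr = render_trace(p, noiseless, kin, n_frames=500, seed=5)
        e = compute_es(tr).E_usable
        se = e.std(ddof=1) / np.sqrt(len(e))
        assert abs(e.mean() - 0.9) < 3 * se

    def test_frame_window_beyond_path_errors(self, kinetics, noiseless):
        p = simulate_state_path(kinetics, 1.0, 10.0, 6)
        with pytest.raises(ValidationError):
            render_trace(p, noiseless, kinetics, n_frames=200, seed=0)

    def test_determinism(self, kinetics, photophysics):
        p = simulate_state_path(kinetics, 2.0, 60.0, 7)
        a = render_trace(p, photophysics, kinetics, seed=11)
        b = render_trace(p, photophysics, kinetics, seed=11)
        assert np.array_equal(a.I_DD, b.I_DD)
        assert np.array_equal(a.I_AA, b.I_AA)


class TestTitration:
    def test_empty_concentration_list_errors(self, kinetics, photophysics):
        with pytest.raises(ValidationError):
            simulate_titration(kinetics, photophysics, [], 5)

    def test_zero_concentration_is_open_dominated(self, photophysics):
        from lumensor import preprocess_trace

        kin = SensorKinetics(k_close_base=0.0)
        titr = simulate_titration(kin, photophysics, [0.0], 10, seed=1)
        for tr in titr.traces[0.0]:
            e = preprocess_trace(tr).E_usable  # pre-bleach frames only
            assert np.mean(e < 0.75) > 0.95

    def test_saturating_concentration_is_closed_dominated(self, kinetics,
                                                          photophysics):
        from lumensor import preprocess_trace

        titr = simulate_titration(kinetics, photophysics, [100.0], 10, seed=2)
        pooled = np.concatenate(
            [preprocess_trace(tr).E_usable for tr in titr.traces[100.0]]
        )
        # mean efficiency reflects stationary closed occupancy 0.938
        occupancy = (pooled.mean() - 0.6) / 0.3
        assert abs(occupancy - kinetics.stationary_closed_fraction(100.0)) < 0.02
        assert np.mean(pooled > 0.75) > 0.9

    def test_near_kd_traces_are_dynamic(self, kinetics, photophysics):
        titr = simulate_titration(kinetics, photophysics, [2.0], 10, seed=3)
        assert (titr.truth["n_transitions"] >= 2).all()


class TestVesicleEnsemble:
    def test_poisson_occupancy_fractions(self):
        ves = simulate_vesicle_ensemble(100_000, 0.2, 0.1, seed=10)
        n_s = np.array([v.n_sensors for v in ves])
        frac = np.mean(n_s >= 1)
        p = 1 - np.exp(-0.2)
        se = np.sqrt(p * (1 - p) / len(ves))
        assert abs(frac - p) < 3 * se
        multi = np.mean(n_s[n_s >= 1] >= 2)
        se_m = np.sqrt(0.0967 * (1 - 0.0967) / (n_s >= 1).sum())
        assert abs(multi - 0.0966689) < 3 * se_m

    def test_zero_mean_gives_empty_vesicles(self):
        ves = simulate_vesicle_ensemble(1000, 0.0, 0.0, seed=1)
        assert all(v.n_sensors == 0 and v.n_transporters == 0 for v in ves)

    @pytest.mark.parametrize("lam", [0.1, 0.2, 1.0])
    def test_copy_number_histogram_matches_poisson(self, lam):
        from scipy.stats import poisson

        ves = simulate_vesicle_ensemble(50_000, lam, 0.0, seed=int(lam * 10))
        n = np.array([v.n_sensors for v in ves])
        for k in range(4):
            p = poisson.pmf(k, lam)
            se = np.sqrt(p * (1 - p) / len(n))
            assert abs(np.mean(n == k) - p) < 3 * se + 1e-9

    def test_diameters_within_bounds_and_median(self):
        ves = simulate_vesicle_ensemble(20_000, seed=3)
        d = np.array([v.diameter for v in ves])
        assert d.min() >= 40.0 and d.max() <= 400.0
        assert abs(np.median(d) - 100.0) < 2.0

    def test_vesicle_lumenal_concentration_link(self):
        v = Vesicle(diameter=100.0, n_sensors=1, n_transporters=1,
                    n_peptides_lumen=2, orientation_ok=True)
        assert v.lumenal_concentration == pytest.approx(2 * 3.1714, rel=1e-3)
        assert v.eligible


class TestTransportProtocols:
    def _eligible(self, n=30):
        return [
            Vesicle(diameter=100.0, n_sensors=1, n_transporters=1,
                    orientation_ok=True, vesicle_id=i)
            for i in range(n)
        ]

    def _counts(self, exp):
        return exp.truth.pivot_table(
            index="vesicle_id", columns="phase_index", values="n_peptides"
        )

    def test_mg_adp_never_transports(self, kinetics, photophysics):
        exp = simulate_transport_experiment(
            self._eligible(), mg_adp_control_protocol(), kinetics,
            photophysics, n_frames_per_phase=100, seed=1,
        )
        assert (exp.truth["n_peptides"] == 0).all()

    def test_single_mg_atp_event_is_one_increment(self, kinetics, photophysics):
        exp = simulate_transport_experiment(
            self._eligible(5), two_event_mg_atp_protocol(), kinetics,
            photophysics, n_frames_per_phase=100, seed=2,
        )
        t = exp.truth
        after1 = t[t.phase_index == 1]
        assert (after1["n_peptides"] == 1).all()
        assert after1["true_concentration"].iloc[0] == pytest.approx(
            3.1714, rel=1e-3
        )
        assert (t[t.phase_index == 2]["n_peptides"] == 2).all()

    def test_atp_edta_single_turnover_until_reset(self, kinetics, photophysics):
        exp = simulate_transport_experiment(
            self._eligible(5), atp_edta_protocol(), kinetics, photophysics,
            n_frames_per_phase=100, seed=3,
        )
        counts = self._counts(exp)
        assert (counts[1] == counts[0]).all()   # second EDTA phase is futile
        assert (counts[2] == counts[0] + 1).all()  # Mg-ATP resets + transports

    def test_protocol_validation(self):
        with pytest.raises(ValidationError):
            Phase("bad", "Mg-GTP", 10.0)
        with pytest.raises(ValidationError):
            ExperimentProtocol(())
        with pytest.raises(ValidationError):
            ExperimentProtocol(
                (Phase("x", "Mg-ADP", 10.0),),
                transport_rule={("Mg-ADP", "IF"): 1},
            )

    def test_experiment_determinism(self, kinetics, photophysics):
        ves = self._eligible(3)
        kw = dict(kinetics=kinetics, phot=photophysics,
                  n_frames_per_phase=50, seed=9)
        a = simulate_transport_experiment(ves, two_event_mg_atp_protocol(), **kw)
        b = simulate_transport_experiment(ves, two_event_mg_atp_protocol(), **kw)
        for p in a.traces:
            for ta, tb in zip(a.traces[p], b.traces[p]):
                assert np.array_equal(ta.I_DA, tb.I_DA)
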