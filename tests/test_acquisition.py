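"""Jeffreys rates, exponential KL, coding-cost statistic and the detector."""

import numpy as np
import pytest
from scipy import integrate, stats

from infocond import (
    AgentParams,
    Event,
    EventLog,
    ProtocolSpec,
    adjusted_exposure,
    coding_cost_statistic,
    detect_acquisition,
    evidence_trace,
    jeffreys_rate,
    kl_exponential,
    null_calibration,
    null_p_value,
    simulate_cohort,
    simulate_session,
    spec_for_protocol,
)


def _log(tones, rewards, responses, end):
    """Hand-built session log: tones as (on, off) pairs."""
    events = [Event(0.0, "session_start")]
    for on, off in tones:
        events += [Event(float(on), "tone_on"), Event(float(off), "tone_off")]
    events += [Event(float(r), "reward") for r in rewards]
    events += [Event(float(r), "response") for r in responses]
    events.append(Event(float(end), "session_end"))
    events.sort(key=lambda e: e.time_s)
    return EventLog(session_id="handmade", events=events)


class TestAdjustedExposure:
    def test_nonoverlapping_windows_reduce_iti_exposure_exactly(self):
        # 3 rewards in ITIs, gaps > 2 s: exposure shrinks by exactly 6 s
        log = _log([(10, 20), (40, 50)], rewards=[5, 25, 30], responses=[2, 6, 26], end=60)
        tone_exp, iti_exp, n_tone, n_iti = adjusted_exposure(log, 2.0)
        assert tone_exp == pytest.approx(20.0)
        assert iti_exp == pytest.approx(40.0 - 6.0)
        # responses at 6 and 26 fall inside windows (5,7] and (25,27]
        assert n_iti == 1 and n_tone == 0

    def test_zero_window_leaves_raw_durations(self):
        log = _log([(10, 20)], rewards=[5], responses=[6], end=30)
        tone_exp, iti_exp, n_tone, n_iti = adjusted_exposure(log, 0.0)
        assert (tone_exp, iti_exp) == (10.0, 20.0)
        assert n_iti == 1

    def test_overlapping_windows_union_not_sum(self):
        log = _log([(20, 30)], rewards=[5, 6], responses=[], end=40)
        _, iti_exp, _, _ = adjusted_exposure(log, 2.0)
        assert iti_exp == pytest.approx(30.0 - 3.0)  # union (5, 8], not 4 s

    def test_window_clipped_at_state_transition(self):
        # reward 1 s before tone onset: 1 s excluded from ITI, 1 s from tone
        log = _log([(10, 20)], rewards=[9], responses=[], end=30)
        tone_exp, iti_exp, _, _ = adjusted_exposure(log, 2.0)
        assert iti_exp == pytest.approx(19.0)
        assert tone_exp == pytest.approx(9.0)

    def test_negative_window_rejected(self):
        log = _log([(10, 20)], rewards=[], responses=[], end=30)
        with pytest.raises(ValueError):
            adjusted_exposure(log, -1.0)


class TestJeffreysRate:
    def test_zero_count_has_positive_rate(self):
        est = jeffreys_rate(0, 60.0)
        assert est.point_rate_per_s == pytest.approx(0.5 / 60)
        assert est.posterior_shape == 0.5

    def test_posterior_mean(self):
        assert jeffreys_rate(119, 600.0).point_rate_per_s == pytest.approx(0.199167, abs=1e-6)

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            jeffreys_rate(10, 0.0)
        with pytest.raises(ValueError):
            jeffreys_rate(-1, 10.0)
        with pytest.raises(ValueError):
            jeffreys_rate(99.5, 10.0)


class TestKLExponential:
    @pytest.mark.parametrize("r1, r2, expected", [(3, 3, 0.0), (2, 1, 0.19315), (1, 2, 0.30685)])
    def test_known_values(self, r1, r2, expected):
        assert kl_exponential(r1, r2) == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("ratio", [0.1, 0.3, 1.0, 2.5, 10.0])
    def test_matches_numerical_integration(self, ratio):
        r1, r2 = ratio, 1.0
        # log densities expanded for numerical stability
        integrand = lambda x: r1 * np.exp(-r1 * x) * (np.log(r1 / r2) + (r2 - r1) * x)
        numeric, _ = integrate.quad(integrand, 0, np.inf)
        assert kl_exponential(r1, r2) == pytest.approx(numeric, abs=1e-6)

    def test_nonnegative_and_asymmetric(self):
        assert kl_exponential(2.0, 1.0) >= 0
        assert kl_exponential(2.0, 1.0) != kl_exponential(1.0, 2.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            kl_exponential(0.0, 1.0)


class TestCodingCostStatistic:
    def test_zero_count_and_equal_rates_give_zero(self):
        a, b = jeffreys_rate(10, 100.0), jeffreys_rate(10, 100.0)
        assert coding_cost_statistic(0, a, b) == 0.0
        assert coding_cost_statistic(50, a, b) == 0.0

    def test_scales_linearly_in_n(self):
        a, b = jeffreys_rate(19, 600.0), jeffreys_rate(39, 1200.0)
        assert coding_cost_statistic(100, a, b) == pytest.approx(
            100 * kl_exponential(a.point_rate_per_s, b.point_rate_per_s)
        )
        assert coding_cost_statistic(100, a, b) == pytest.approx(
            2 * coding_cost_statistic(50, a, b)
        )

    def test_equals_loglikelihood_ratio_of_intervals(self):
        # n*KL(l1||l2) is the exponential log-likelihood ratio between the
        # fitted tone rate and the reference rate, evaluated on intervals
        # whose total is n/l1 (algebraic identity, checked numerically)
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(5, 200)
            total = rng.uniform(1, 100)
            l1 = n / total
            l2 = rng.uniform(0.05, 5)
            ll1 = n * np.log(l1) - l1 * total
            ll2 = n * np.log(l2) - l2 * total
            assert n * kl_exponential(l1, l2) == pytest.approx(ll1 - ll2, rel=1e-9, abs=1e-9)

    def test_example_value(self):
        a, b = jeffreys_rate(199, 6000.0), jeffreys_rate(199, 11970.0)
        n = 100
        expected = n * kl_exponential(a.point_rate_per_s, b.point_rate_per_s)
        assert coding_cost_statistic(n, a, b) == pytest.approx(expected)


class TestNullPValue:
    @pytest.mark.parametrize(
        "statistic, p", [(0.0, 1.0), (3.3174, 0.01), (1.9207, 0.05)]
    )
    def test_gamma_half_tail(self, statistic, p):
        assert null_p_value(statistic) == pytest.approx(p, abs=2e-4)

    def test_equals_chi2_tail(self):
        s = 1.234
        assert null_p_value(s) == pytest.approx(stats.chi2.sf(2 * s, df=1))

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            null_p_value(-0.1)


class TestNullCalibration:
    def test_statistic_is_gamma_half_under_the_null(self):
        cal = null_calibration(seed=20, n_replicates=3000)
        assert cal.gamma_shape == pytest.approx(0.5, abs=0.05)
        assert np.mean(cal.statistics) == pytest.approx(0.5, abs=0.08)

    def test_single_checkpoint_type1_error_is_nominal(self):
        cal = null_calibration(seed=20, n_replicates=3000)
        assert cal.type1_error(0.01) == pytest.approx(0.01, abs=0.006)


class TestEvidenceTrace:
    def test_one_checkpoint_per_pellet(self):
        spec = spec_for_protocol(4)
        agent = AgentParams(baseline_rate_per_min=8.0)
        log = simulate_session(spec, agent, 17)
        trace = evidence_trace([log])
        assert len(trace) == len(log.reward_times)
        assert np.all(np.diff(trace.checkpoint_time_s) >= 0)

    def test_no_rewards_is_an_error(self):
        log = _log([(10, 20)], rewards=[], responses=[5], end=30)
        with pytest.raises(ValueError):
            evidence_trace([log])

    def test_null_trace_statistic_matches_gamma_half(self):
        # long ITIs make the reference rate precise, so the final-checkpoint
        # statistic of a never-learning agent should average ~0.5
        spec = ProtocolSpec(
            tone_duration_s=5.0, iti_mean_s=250.0, iri_mean_s=50.0, tones_per_session=8
        )
        agent = AgentParams(baseline_rate_per_min=12.0)
        vals = []
        for seed in range(150):
            log = simulate_session(spec, agent, seed)
            if len(log.reward_times) == 0:
                continue
            vals.append(evidence_trace([log]).statistic_nats[-1])
        vals = np.array(vals)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.15)

    def test_p_value_falls_after_changepoint(self):
        spec = spec_for_protocol(9)
        agent = AgentParams(10.0, 20.0, 0.0, changepoint_pellets=60)
        logs = simulate_cohort(spec, agent, 1, base_seed=77, n_sessions=1)[0]
        trace = evidence_trace(logs)
        before = trace.p_value[trace.pellet_index <= 60].min()
        after = trace.p_value[trace.pellet_index >= 90].max()
        assert after < before


class TestDetectAcquisition:
    def _trace(self, seed, changepoint=60):
        spec = spec_for_protocol(9)
        agent = AgentParams(10.0, 20.0, 0.0, changepoint_pellets=changepoint)
        logs = simulate_cohort(spec, agent, 1, base_seed=seed, n_sessions=1)[0]
        return evidence_trace(logs)

    def test_criteria_are_monotone_in_stringency(self):
        for seed in range(8):
            trace = self._trace(seed)
            pellets = {}
            for crit in ("p10", "p05", "p01", "p001"):
                res = detect_acquisition(trace, crit)
                pellets[crit] = res.pellets_to_acquisition or np.inf
            assert pellets["p001"] >= pellets["p01"] >= pellets["p05"] >= pellets["p10"]

    def test_never_significant_trace_reports_not_acquired(self):
        spec = ProtocolSpec(
            tone_duration_s=5.0, iti_mean_s=250.0, iri_mean_s=50.0, tones_per_session=8
        )
        agent = AgentParams(baseline_rate_per_min=12.0)
        n_acquired = 0
        n_traces = 0
        for seed in range(40):
            log = simulate_session(spec, agent, seed)
            if len(log.reward_times) == 0:
                continue
            n_traces += 1
            res = detect_acquisition(evidence_trace([log]), "p001")
            n_acquired += res.acquired
        assert n_traces > 20
        assert n_acquired / n_traces < 0.15

    def test_unknown_criterion_rejected(self):
        trace = self._trace(0)
        with pytest.raises(ValueError):
            detect_acquisition(trace, "p999")

    def test_direction_gate_blocks_wrong_sign(self):
        # an agent that responds MORE during tones should never satisfy the
        # tone-below-ITI criterion
        spec = spec_for_protocol(9)
        agent = AgentParams(10.0, 10.0, 30.0, changepoint_pellets=20)
        logs = simulate_cohort(spec, agent, 1, base_seed=5, n_sessions=1)[0]
        trace = evidence_trace(logs)
        below = detect_acquisition(trace, "p001", direction="tone_below_iti")
        above = detect_acquisition(trace, "p001", direction="tone_above_iti")
        assert not below.acquired
        assert above.acquired
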