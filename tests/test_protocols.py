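"""Protocol exposures, informativeness, credit assignment, learning-rate law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infocond import (
    NOT_ACQUIRED,
    ExposureSummary,
    ProtocolSpec,
    assign_credit,
    delta_H,
    expected_exposures,
    fit_k,
    informativeness,
    predicted_acquisition,
    spec_for_protocol,
)


class TestExpectedExposures:
    @pytest.mark.parametrize(
        "protocol, cum_c_min, cum_iti_min, rewards",
        [(4, 53.3, 10.7, 32), (9, 64.0, 42.7, 128), (27, 40.0, 13.3, 40)],
    )
    def test_catalog_protocols(self, protocol, cum_c_min, cum_iti_min, rewards):
        exp = expected_exposures(spec_for_protocol(protocol))
        assert exp.cum_context_s / 60 == pytest.approx(cum_c_min, abs=0.05)
        assert exp.cum_no_tone_s / 60 == pytest.approx(cum_iti_min, abs=0.05)
        assert exp.n_rewards_context == pytest.approx(rewards)

    def test_single_cycle(self):
        spec = ProtocolSpec(tone_duration_s=60, iti_mean_s=60, iri_mean_s=20, tones_per_session=1)
        exp = expected_exposures(spec)
        assert exp.cum_context_s == pytest.approx(120.0)
        assert exp.cum_tone_s + exp.cum_no_tone_s == pytest.approx(exp.cum_context_s)

    def test_negative_contingency_has_no_tone_rewards(self):
        exp = expected_exposures(spec_for_protocol(4))
        assert exp.n_rewards_tone == 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec(tone_duration_s=-1)
        with pytest.raises(ValueError):
            ProtocolSpec(iti_mean_s=0)
        with pytest.raises(ValueError):
            ProtocolSpec(tones_per_session=0)


class TestInformativeness:
    def test_minimally_informative_protocol(self):
        rep = informativeness(expected_exposures(spec_for_protocol(9)))
        assert rep.rate_no_tone_per_min == pytest.approx(3.0)
        assert rep.rate_context_per_min == pytest.approx(2.0)
        assert rep.iota == pytest.approx(1.5)

    def test_zero_contingency_conveys_no_information(self):
        rep = informativeness(expected_exposures(spec_for_protocol(5)))
        assert rep.iota == pytest.approx(1.0)
        assert rep.delta_H_nats == pytest.approx(0.0)

    def test_operant_negative_contingency(self):
        rep = informativeness(expected_exposures(spec_for_protocol(27)))
        assert rep.rate_no_tone_per_min == pytest.approx(3.0)
        assert rep.rate_context_per_min == pytest.approx(1.0)
        assert rep.iota == pytest.approx(3.0)

    def test_zero_rewards_is_an_error(self):
        bad = ExposureSummary(3200, 2560, 640, 0, 0, 0)
        with pytest.raises(ValueError):
            informativeness(bad)

    def test_zero_no_tone_exposure_is_an_error(self):
        bad = ExposureSummary(3200, 3200, 0, 10, 0, 10)
        with pytest.raises(ValueError):
            informativeness(bad)

    @given(c=st.sampled_from([0.25, 0.5, 2.0, 3.0, 4.0, 10.0]), protocol=st.sampled_from([1, 4, 9, 25, 27]))
    @settings(deadline=None, max_examples=30)
    def test_timescale_invariance(self, c, protocol):
        spec = spec_for_protocol(protocol)
        rep = informativeness(expected_exposures(spec))
        rep_scaled = informativeness(expected_exposures(spec.scaled(c)))
        assert rep_scaled.iota == pytest.approx(rep.iota, rel=1e-12)
        assert rep_scaled.delta_H_nats == pytest.approx(rep.delta_H_nats, rel=1e-12, abs=1e-12)


class TestDeltaH:
    @pytest.mark.parametrize(
        "iota, nats, bits",
        [(1.0, 0.0, 0.0), (2.0, 0.6931, 1.0), (math.e, 1.0, 1.4427)],
    )
    def test_values(self, iota, nats, bits):
        n, b = delta_H(iota)
        assert n == pytest.approx(nats, abs=1e-4)
        assert b == pytest.approx(bits, abs=1e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            delta_H(0.0)
        with pytest.raises(ValueError):
            delta_H(-1.0)

    @given(
        i1=st.floats(0.1, 50, allow_nan=False),
        i2=st.floats(0.1, 50, allow_nan=False),
    )
    @settings(deadline=None, max_examples=50)
    def test_additivity_over_ratio_composition(self, i1, i2):
        assert delta_H(i1 * i2)[0] == pytest.approx(delta_H(i1)[0] + delta_H(i2)[0], abs=1e-9)


class TestCreditAssignment:
    def test_negative_contingency_attributes_zero_to_tone(self):
        credit = assign_credit(expected_exposures(spec_for_protocol(4)))
        assert credit.p_no_tone_given_context == pytest.approx(0.2)
        assert credit.attributed_rate_tone_per_min == pytest.approx(0.0, abs=1e-9)
        assert credit.attributed_rate_no_tone_per_min == pytest.approx(3.0, abs=1e-9)

    def test_tone_never_on_is_singular(self):
        exp = ExposureSummary(1200, 0, 1200, 20, 20, 0)
        credit = assign_credit(exp)
        assert credit.singular
        assert credit.attributed_rate_tone_per_min == pytest.approx(
            credit.attributed_rate_no_tone_per_min
        )

    def test_equal_rates_attribute_everything_to_tone(self):
        # lambda_C = lambda_~T with p(~T|C)=0.5: the linear solve gives
        # (lambda, 0) -- frozen from the hand-solved 2x2 system
        exp = ExposureSummary(1000, 500, 500, 10, 5, 5)
        credit = assign_credit(exp)
        lam = 60.0 * 10 / 1000
        assert credit.attributed_rate_tone_per_min == pytest.approx(lam, abs=1e-12)
        assert credit.attributed_rate_no_tone_per_min == pytest.approx(0.0, abs=1e-12)

    @given(
        p=st.floats(0.05, 0.95),
        rate_c=st.floats(0.1, 10),
        rate_nt=st.floats(0.1, 10),
    )
    @settings(deadline=None, max_examples=50)
    def test_forward_multiplication_recovers_inputs(self, p, rate_c, rate_nt):
        cum_c = 6000.0
        exp = ExposureSummary(
            cum_c, cum_c * (1 - p), cum_c * p,
            rate_c * cum_c / 60, rate_nt * cum_c * p / 60, 0,
        )
        credit = assign_credit(exp)
        rec = credit.matrix @ np.array(
            [credit.attributed_rate_tone_per_min, credit.attributed_rate_no_tone_per_min]
        )
        assert rec[0] == pytest.approx(rate_c, rel=1e-9)
        assert rec[1] == pytest.approx(rate_nt, rel=1e-9)


class TestLearningRateLaw:
    def test_predictions(self):
        assert predicted_acquisition(2.0, 255.0) == pytest.approx(255.0)
        assert predicted_acquisition(6.0, 255.0) == pytest.approx(51.0)
        assert predicted_acquisition(1.0, 255.0) == NOT_ACQUIRED

    def test_noiseless_recovery(self):
        pts = [(i, 255.0 / (i - 1)) for i in (2, 3, 5, 9)]
        assert fit_k(pts).k == pytest.approx(255.0, rel=1e-9)
        assert fit_k(pts, "linear").k == pytest.approx(255.0, rel=1e-9)

    def test_reciprocal_rescaling_invariance(self):
        pts = [(i, 300.0 / (i - 1)) for i in (1.5, 2, 4, 8)]
        scaled = [(1 + 2 * (i - 1), n / 2) for i, n in pts]
        assert fit_k(scaled).k == pytest.approx(fit_k(pts).k, rel=1e-9)

    def test_recovery_under_multiplicative_noise(self):
        rng = np.random.default_rng(11)
        iotas = np.linspace(1.2, 9.0, 50)
        pts = [(i, 255.0 / (i - 1) * rng.lognormal(0.0, 0.2)) for i in iotas]
        assert fit_k(pts).k == pytest.approx(255.0, rel=0.10)

    def test_iota_at_or_below_one_rejected(self):
        with pytest.raises(ValueError):
            fit_k([(1.0, 100), (2.0, 255)])
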