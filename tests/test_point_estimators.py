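import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from meandiff import (
    SampleSummary,
    TwoSampleDesign,
    bonett_delta_hat,
    c_biased,
    c_prime,
    c_unbiased,
    correction_j,
    delta_param,
    delta_q_param,
    e_biased,
    e_unbiased,
    epsilon_param,
    gamma_param,
    glass_delta,
    hedges_d,
    hedges_g,
    summarize,
)

vals = st.floats(-100, 100, allow_nan=False, allow_infinity=False)
vectors = st.lists(vals, min_size=4, max_size=20).filter(lambda v: np.var(v) > 1e-6)


class TestTwoSampleStatistics:
    def test_worked_example(self, example_design):
        assert hedges_g(example_design) == pytest.approx(1 / math.sqrt(1.75), abs=1e-12)
        assert hedges_d(example_design) == pytest.approx(0.682379579593354, abs=1e-12)
        assert e_biased(example_design) == pytest.approx(1 / math.sqrt(1.75), abs=1e-12)
        assert e_unbiased(example_design) == pytest.approx(0.668264936033828, abs=1e-12)
        assert bonett_delta_hat(
            example_design.group1, example_design.group2
        ) == pytest.approx(1 / math.sqrt(1.75), abs=1e-12)

    def test_parameter_example(self, example_param_design):
        assert hedges_g(example_param_design) == pytest.approx(
            1 / math.sqrt(17 / 13), abs=1e-12
        )
        assert hedges_d(example_param_design) == pytest.approx(0.82286529714397, abs=1e-12)
        assert e_biased(example_param_design) == pytest.approx(
            math.sqrt(2.0) / math.sqrt(10 / 3), abs=1e-12
        )
        assert e_unbiased(example_param_design) == pytest.approx(
            0.674259756444758, abs=1e-12
        )

    def test_identical_samples_give_zero(self):
        d = TwoSampleDesign.from_data([1, 2, 3, 4], [1, 2, 3, 4])
        assert hedges_g(d) == 0 and hedges_d(d) == 0
        assert e_biased(d) == 0 and e_unbiased(d) == 0

    def test_zero_pooled_sd_rejected(self):
        d = TwoSampleDesign(SampleSummary(0, 0, 5), SampleSummary(1, 0, 5))
        with pytest.raises(ValueError):
            hedges_g(d)

    def test_bonett_unequal_variances(self):
        assert bonett_delta_hat(
            SampleSummary(1, 2, 5), SampleSummary(0, 1, 10)
        ) == pytest.approx(1 / math.sqrt(1.5), abs=1e-12)

    @given(vectors, st.data())
    def test_equal_n_degeneracies(self, v1, data):
        """When n1 = n2 the raw pooled, Welch and Bonett statistics coincide."""
        v2 = data.draw(
            st.lists(vals, min_size=len(v1), max_size=len(v1)).filter(
                lambda v: np.var(v) > 1e-6
            )
        )
        d = TwoSampleDesign.from_data(v1, v2)
        g = hedges_g(d)
        assert e_biased(d) == pytest.approx(g, rel=1e-9, abs=1e-12)
        assert bonett_delta_hat(d.group1, d.group2) == pytest.approx(
            g, rel=1e-9, abs=1e-12
        )

    @given(vectors, vectors)
    def test_antisymmetry(self, v1, v2):
        a = TwoSampleDesign.from_data(v1, v2)
        b = TwoSampleDesign.from_data(v2, v1)
        for fn in (hedges_g, hedges_d, e_biased, e_unbiased):
            assert fn(a) == pytest.approx(-fn(b), rel=1e-9, abs=1e-12)
        assert bonett_delta_hat(a.group1, a.group2) == pytest.approx(
            -bonett_delta_hat(b.group1, b.group2), rel=1e-9, abs=1e-12
        )

    @given(vectors, vectors, st.floats(0.01, 100.0))
    def test_scale_invariance(self, v1, v2, k):
        a = TwoSampleDesign.from_data(v1, v2)
        b = TwoSampleDesign.from_data([k * x for x in v1], [k * x for x in v2])
        for fn in (hedges_g, hedges_d, e_biased, e_unbiased):
            assert fn(a) == pytest.approx(fn(b), rel=1e-6, abs=1e-9)

    def test_corrected_smaller_in_magnitude(self, example_design):
        assert abs(e_unbiased(example_design)) < abs(e_biased(example_design))
        assert abs(hedges_d(example_design)) < abs(hedges_g(example_design))


class TestGlass:
    def test_examples(self, example_design):
        assert glass_delta(example_design.group1, example_design.group2) == 1.0
        s = summarize([1, 2, 3])
        assert glass_delta(s, s) == 0.0
        assert glass_delta(SampleSummary(1, 1, 5), SampleSummary(0, 4, 5)) == 0.5

    def test_zero_control_sd(self):
        with pytest.raises(ValueError):
            glass_delta(SampleSummary(1, 1, 5), SampleSummary(0, 0, 5))


class TestOneSample:
    def test_worked_example(self, example_one_sample):
        assert c_biased(example_one_sample, 2.0) == pytest.approx(-1.0, abs=1e-14)
        assert c_unbiased(example_one_sample, 2.0) == pytest.approx(
            -correction_j(4), abs=1e-12
        )
        assert c_prime(example_one_sample, 2.0) == pytest.approx(
            -c_unbiased(example_one_sample, 2.0), abs=0
        )

    def test_constant_at_mean_gives_zero(self, example_one_sample):
        assert c_biased(example_one_sample, 1.0) == 0.0
        assert c_unbiased(example_one_sample, 1.0) == 0.0

    def test_other_constant(self):
        s = summarize([0, 1, 2, 3, 4])
        assert c_biased(s, 0.0) == pytest.approx(2 / math.sqrt(2.5), abs=1e-12)

    @given(vectors, st.floats(-50, 50), st.floats(0.01, 100.0))
    def test_scale_invariance(self, v, const, k):
        a = c_unbiased(summarize(v), const)
        b = c_unbiased(summarize([k * x for x in v]), k * const)
        assert a == pytest.approx(b, rel=1e-6, abs=1e-9)

    def test_correction_shrinks(self, example_one_sample):
        assert abs(c_unbiased(example_one_sample, 2.0)) < abs(
            c_biased(example_one_sample, 2.0)
        )


class TestParameters:
    def test_delta(self):
        assert delta_param(1, 0, 1) == 1.0
        assert delta_param(3, 3, 2) == 0.0
        assert delta_param(1, 0, 2) == 0.5
        with pytest.raises(ValueError):
            delta_param(1, 0, 0)

    def test_epsilon(self):
        assert epsilon_param(1, 0, 1, 4, 1.0) == pytest.approx(
            1 / math.sqrt(8.5), abs=1e-12
        )
        assert epsilon_param(1, 0, 1, 4, 0.5) == pytest.approx(
            1 / math.sqrt(6), abs=1e-12
        )

    @given(st.floats(-10, 10), st.floats(-10, 10), st.floats(0.1, 10), st.floats(0.1, 10))
    def test_epsilon_collapses_to_delta_under_equal_sigma(self, mu1, mu2, sigma, r):
        assert epsilon_param(mu1, mu2, sigma, sigma, r) == pytest.approx(
            delta_param(mu1, mu2, sigma), rel=1e-9, abs=1e-12
        )

    def test_gamma(self):
        assert gamma_param(1, 2, 1) == -1.0
        assert gamma_param(3, 1, 2) == 1.0
        assert gamma_param(5, 5, 2) == 0.0

    def test_delta_q(self):
        assert delta_q_param(1, 0, 1, 4, 1.0) == pytest.approx(
            1 / math.sqrt(8.5), abs=1e-12
        )
        assert delta_q_param(1, 0, 2, 1, 1.0) == pytest.approx(
            1 / math.sqrt(2.5), abs=1e-12
        )
        assert delta_q_param(1, 0, 3, 3, 0.7) == pytest.approx(
            delta_param(1, 0, 3), abs=1e-12
        )


def test_e_unbiased_recovers_parameter_montecarlo():
    """Mean of e over many replicates matches ϵ_r within Monte Carlo error
    (n1=n2=10, sigma 1 vs 4, mean difference 1)."""
    rng = np.random.default_rng(2024)
    reps, n = 200_000, 10
    x = rng.normal(1, 1, (reps, n))
    y = rng.normal(0, 4, (reps, n))
    m1, m2 = x.mean(1), y.mean(1)
    v1, v2 = x.var(1, ddof=1), y.var(1, ddof=1)
    tw = (m1 - m2) / np.sqrt(v1 / n + v2 / n)
    f = (v1 / n + v2 / n) ** 2 / (
        v1**2 / (n**2 * (n - 1)) + v2**2 / (n**2 * (n - 1))
    )
    e = tw / np.sqrt(n / 2) * correction_j(f)
    target = epsilon_param(1, 0, 1, 4, 1.0)
    se = e.std(ddof=1) / math.sqrt(reps)
    assert abs(e.mean() - target) < 3 * se


def test_c_unbiased_recovers_parameter_montecarlo():
    rng = np.random.default_rng(2025)
    reps, n = 200_000, 10
    x = rng.normal(1, 2, (reps, n))
    c = (x.mean(1) - 0.0) / x.std(1, ddof=1) * correction_j(n - 1)
    target = gamma_param(1, 0, 2)
    se = c.std(ddof=1) / math.sqrt(reps)
    assert abs(c.mean() - target) < 3 * se
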