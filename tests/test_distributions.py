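"""Distribution table validation, sampling semantics, uncertainty records."""
from __future__ import annotations

import math

import numpy as np
import pytest

from stibnite import loads
from stibnite.distributions import (BASE_ARITY, NO_TRUNCATION, RngStream,
                                    SamplingError, sample_value, signatures,
                                    validate_distribution)
from stibnite.syntax import Call, Num


def _call(name: str, nargs: int) -> Call:
    return Call(name, tuple(Num(float(i + 1)) for i in range(nargs)))


class TestSignatureTable:
    def test_table_has_twenty_two_signatures(self):
        assert len(signatures()) == 22

    @pytest.mark.parametrize("name, arity", signatures())
    def test_every_listed_signature_validates(self, name, arity):
        args = [2.0] * arity
        if arity == BASE_ARITY[name] + 2:
            args[-2], args[-1] = 0.5, 4.0  # sane truncation window
        call = Call(name, tuple(Num(a) for a in args))
        assert validate_distribution(call) == []

    @pytest.mark.parametrize("name, arity", signatures())
    @pytest.mark.parametrize("delta", [-1, 1])
    def test_perturbed_arities_fail(self, name, arity, delta):
        bad = arity + delta
        if bad < 0 or (name, bad) in signatures():
            pytest.skip("perturbation lands on another valid signature")
        assert validate_distribution(_call(name, bad)) != []

    def test_unknown_name_rejected(self):
        assert validate_distribution(_call("weibull", 2)) != []

    def test_inverted_truncation_bounds_rejected(self):
        call = Call("normal", (Num(0.0), Num(1.0), Num(2.0), Num(-2.0)))
        assert validate_distribution(call) != []

    def test_uniform_and_bernoulli_have_no_truncated_form(self):
        assert NO_TRUNCATION == {"uniform", "bernoulli"}
        assert validate_distribution(_call("uniform", 4)) != []
        assert validate_distribution(_call("bernoulli", 3)) != []


class TestSampling:
    def test_uniform_draws_stay_in_range(self):
        rng = RngStream(42)
        draws = [sample_value("uniform", [2.5, 5.5], rng)
                 for _ in range(1000)]
        assert all(2.5 <= d <= 5.5 for d in draws)

    def test_degenerate_normal_is_exactly_the_mean(self):
        rng = RngStream(0)
        assert sample_value("normal", [0.7, 0.0], rng) == 0.7

    def test_normal_sample_mean_within_clt_bound(self):
        n = 10_000
        rng = RngStream(123)
        draws = np.array([sample_value("normal", [0.5, 0.2], rng)
                          for _ in range(n)])
        assert abs(draws.mean() - 0.5) < 3 * 0.2 / math.sqrt(n)

    def test_truncated_draws_respect_bounds(self):
        rng = RngStream(7)
        draws = [sample_value("normal", [0.5, 0.2, 0.4, 0.6], rng)
                 for _ in range(2000)]
        assert all(0.4 <= d <= 0.6 for d in draws)
        assert 0.4 <= np.mean(draws) <= 0.6

    def test_equal_seeds_give_equal_sequences(self):
        a = RngStream(99)
        b = RngStream(99)
        seq_a = [sample_value("gamma", [2.0, 3.0], a) for _ in range(1000)]
        seq_b = [sample_value("gamma", [2.0, 3.0], b) for _ in range(1000)]
        assert seq_a == seq_b

    def test_discrete_families_return_integer_valued_reals(self):
        rng = RngStream(5)
        for name, args in [("bernoulli", [0.4]), ("binomial", [10, 0.3]),
                           ("poisson", [3.0])]:
            v = sample_value(name, args, rng)
            assert v == int(v)

    def test_lognormal_parameters_are_on_the_log_scale(self):
        rng = RngStream(11)
        draws = np.array([sample_value("lognormal", [1.0, 0.25], rng)
                          for _ in range(20_000)])
        # median of exp(N(mu, sigma)) is exp(mu)
        assert np.median(draws) == pytest.approx(math.e, rel=0.05)

    @pytest.mark.parametrize("name, args", [
        ("normal", [0.0, -1.0]),
        ("cauchy", [0.0, -2.0]),
        ("bernoulli", [1.5]),
        ("exponential", [0.0]),
        ("gamma", [-1.0, 1.0]),
        ("chisquare", [0.0]),
    ])
    def test_invalid_parameter_domains_raise(self, name, args):
        with pytest.raises(SamplingError):
            sample_value(name, args, RngStream(0))

    def test_empty_truncation_window_raises(self):
        with pytest.raises(SamplingError):
            sample_value("normal", [0.0, 1.0, 5.0, 5.0], RngStream(0))


class TestUncertaintyRecords:
    def test_scalar_and_interval_attributes(self):
        m = loads("A = 1\nS1 = 2\nA.mean = 2.4\n"
                  "A.confidenceInterval = {S1, 8.2}\n")
        rec = m.uncertainty["A"]
        from stibnite.syntax import Num, Sym
        assert rec.scalars["mean"] == Num(2.4)
        assert rec.intervals["confidenceInterval"] == (Sym("S1"), Num(8.2))

    def test_standard_deviation_aliases_stdev(self):
        m1 = loads("A = 1\nA.stdev = 0.5\n")
        m2 = loads("A = 1\nA.standardDeviation = 0.5\n")
        assert m1.uncertainty["A"].scalars.keys() == \
            m2.uncertainty["A"].scalars.keys() == {"stdev"}

    def test_distribution_uri_form(self):
        m = loads('A = 1\nA.distribution is "http://example.org/d"\n')
        assert m.uncertainty["A"].distribution == "http://example.org/d"

    def test_no_uncertainty_statements_leaves_model_unchanged(self, models):
        assert models["listing02"].uncertainty == {}

    def test_unknown_attribute_is_an_error(self):
        m = loads("A = 1\nA.wibble = 2\n")
        assert any("wibble" in d.message for d in m.diagnostics.errors)

    def test_full_attribute_table_round_trips_through_model(self, models):
        rec = models["listing10"].uncertainty["A"]
        assert len(rec.scalars) == 10
        assert len(rec.intervals) == 4
        assert rec.distribution is not None
        assert rec.external_parameter == "http://example.org/parameter"
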