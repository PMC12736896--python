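import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prickleid import (
    ImpossibleObservationError,
    InconsistentPosteriorError,
    PrickleType,
    ValidationError,
    attribute,
    informed_prior,
    recover_likelihood_ratios,
    round_half_up,
    sensitivity_report,
    uniform_prior,
)
from prickleid.datasets import case_study_posteriors, case_study_prior, case_study_taxa

T1, T2 = PrickleType.T1, PrickleType.T2

taxa_st = st.integers(2, 8).map(lambda n: [f"taxon-{i}" for i in range(n)])


# exact zeros exercise zero-propagation; the positive branch stays >=1e-6
# so products with prior weights cannot underflow to a spurious 0 marginal
zero_or_unit = st.one_of(st.just(0.0), st.floats(1e-6, 1.0, allow_nan=False))


def random_prior_and_likelihoods(draw, allow_zero_lik=True):
    taxa = draw(taxa_st)
    lik_st = zero_or_unit if allow_zero_lik else st.floats(0.01, 1.0, allow_nan=False)
    lik = {t: draw(lik_st) for t in taxa}
    raw = {t: draw(st.floats(0.01, 1.0, allow_nan=False)) for t in taxa}
    prior = informed_prior(raw, name="random", normalize=True)
    return prior, lik


class TestPriors:
    def test_uniform_two_taxa(self):
        p = uniform_prior(["A", "B"])
        assert p.weights == {"A": 0.5, "B": 0.5}

    def test_uniform_sixteen_taxa_prints_006(self):
        p = uniform_prior(case_study_taxa())
        assert all(round_half_up(w, 2) == 0.06 for w in p.weights.values())

    def test_uniform_single_taxon(self):
        assert uniform_prior(["A"]).weights == {"A": 1.0}

    def test_uniform_empty_rejected(self):
        with pytest.raises(ValidationError):
            uniform_prior([])

    def test_published_informed_weights_are_valid(self):
        p = case_study_prior("historical")
        assert sum(p.weights.values()) == pytest.approx(1.0, abs=0.02)
        assert p.weights["R. sp. Tea"] == 0.0  # zero prior is allowed

    def test_normalization_scale_invariance(self):
        p = informed_prior({"A": 2.0, "B": 2.0})
        assert p.weights == {"A": 0.5, "B": 0.5}

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            informed_prior({"A": -0.1, "B": 1.1})

    def test_unnormalized_sum_rejected_when_normalize_off(self):
        with pytest.raises(ValidationError, match="sum"):
            informed_prior({"A": 0.6, "B": 0.6}, normalize=False)


class TestAttribute:
    def test_three_taxon_hand_normalization(self):
        prior = informed_prior({"a": 0.5, "b": 0.3, "c": 0.2}, normalize=False)
        res = attribute(T1, {"a": 0.2, "b": 0.5, "c": 0.3}, prior)
        assert res.posteriors["a"] == pytest.approx(10 / 31)
        assert res.posteriors["b"] == pytest.approx(15 / 31)
        assert res.posteriors["c"] == pytest.approx(6 / 31)
        assert res.map_taxon == "b"

    def test_dogmatic_prior(self):
        prior = informed_prior({"a": 1.0, "b": 0.0}, normalize=False)
        res = attribute(T1, {"a": 0.2, "b": 0.9}, prior)
        assert res.posteriors == {"a": 1.0, "b": 0.0}

    def test_case_study_forward_reconstruction(self):
        res = attribute(
            T1, case_study_posteriors("uniform", T1), case_study_prior("historical")
        )
        assert res.posteriors["R. moschata Herrm."] == pytest.approx(0.54, abs=0.005)
        assert res.map_taxon == "R. moschata Herrm."

    def test_zero_marginal_is_explicit_error(self):
        prior = uniform_prior(["a", "b"])
        with pytest.raises(ImpossibleObservationError):
            attribute(T1, {"a": 0.0, "b": 0.0}, prior)

    def test_ties_reported_and_broken_by_order(self):
        res = attribute(T1, {"a": 0.3, "b": 0.3}, uniform_prior(["a", "b"]))
        assert res.map_taxon == "a"
        assert res.ties == ("a", "b")

    @settings(deadline=None)
    @given(st.data())
    def test_posteriors_normalize_and_zeros_propagate(self, data):
        prior, lik = random_prior_and_likelihoods(data.draw)
        if sum(lik.values()) == 0:
            return
        res = attribute(T1, lik, prior)
        assert sum(res.posteriors.values()) == pytest.approx(1.0, abs=1e-9)
        for t, l in lik.items():
            if l == 0.0:
                assert res.posteriors[t] == 0.0

    @settings(deadline=None)
    @given(st.data(), st.floats(0.1, 100.0))
    def test_likelihood_scale_invariance(self, data, c):
        prior, lik = random_prior_and_likelihoods(data.draw, allow_zero_lik=False)
        a = attribute(T1, lik, prior)
        b = attribute(T1, {t: c * v for t, v in lik.items()}, prior)
        for t in lik:
            assert a.posteriors[t] == pytest.approx(b.posteriors[t], abs=1e-12)

    @settings(deadline=None)
    @given(st.data())
    def test_uniform_prior_equals_normalized_likelihood(self, data):
        prior, lik = random_prior_and_likelihoods(data.draw, allow_zero_lik=False)
        res = attribute(T1, lik, uniform_prior(list(lik)))
        s = sum(lik.values())
        for t, v in lik.items():
            assert res.posteriors[t] == pytest.approx(v / s, abs=1e-12)


class TestInversion:
    def test_uniform_prior_identity(self):
        rec = recover_likelihood_ratios(
            uniform_prior(["a", "b"]), {"a": 0.25, "b": 0.75}
        )
        assert rec.ratios["a"] == pytest.approx(0.25)
        assert rec.ratios["b"] == pytest.approx(0.75)

    def test_one_to_three_ratio_by_hand(self):
        prior = informed_prior({"a": 0.5, "b": 0.5}, normalize=False)
        rec = recover_likelihood_ratios(prior, {"a": 0.25, "b": 0.75})
        assert rec.ratios == pytest.approx({"a": 0.25, "b": 0.75})

    def test_zero_prior_zero_posterior_indeterminate(self):
        prior = informed_prior({"a": 1.0, "b": 0.0}, normalize=False)
        rec = recover_likelihood_ratios(prior, {"a": 1.0, "b": 0.0})
        assert rec.indeterminate == ("b",)

    def test_positive_posterior_on_zero_prior_inconsistent(self):
        prior = informed_prior({"a": 0.9, "b": 0.1, "c": 0.0}, normalize=False)
        with pytest.raises(InconsistentPosteriorError, match="'c'"):
            recover_likelihood_ratios(prior, {"a": 0.5, "b": 0.2, "c": 0.3})

    @settings(deadline=None)
    @given(st.data())
    def test_round_trip_recovers_likelihood_column(self, data):
        prior, lik = random_prior_and_likelihoods(data.draw, allow_zero_lik=False)
        res = attribute(T1, lik, prior)
        rec = recover_likelihood_ratios(prior, res.posteriors)
        s = sum(lik.values())
        for t, v in lik.items():
            assert rec.ratios[t] == pytest.approx(v / s, abs=1e-9)

    def test_case_study_inverse_direction(self):
        rec = recover_likelihood_ratios(
            case_study_prior("historical"), case_study_posteriors("historical", T1)
        )
        ratios = {t: rec.ratios.get(t, 0.0) for t in case_study_taxa()}
        res = attribute(T1, ratios, uniform_prior(case_study_taxa()))
        assert res.posteriors["R. moschata Herrm."] == pytest.approx(0.28, abs=0.005)


class TestSensitivity:
    def test_identical_scenarios_give_zero_shift(self):
        lik = {"a": 0.2, "b": 0.8}
        rep = sensitivity_report(
            T1, lik, [uniform_prior(["a", "b"], "u1"), uniform_prior(["a", "b"], "u2")]
        )
        assert not rep.map_changed
        assert rep.max_shift == pytest.approx(0.0)

    def test_report_composes_from_independent_attributions(self):
        lik = {"a": 0.7, "b": 0.1, "c": 0.2}
        s1 = informed_prior({"a": 0.1, "b": 0.6, "c": 0.3}, name="s1", normalize=False)
        s2 = uniform_prior(["a", "b", "c"], name="s2")
        rep = sensitivity_report(T1, lik, [s1, s2])
        r1, r2 = attribute(T1, lik, s1), attribute(T1, lik, s2)
        for t in lik:
            expected = abs(r1.posteriors[t] - r2.posteriors[t])
            assert rep.shifts[t] == pytest.approx(expected)

    def test_case_study_map_flips_between_scenarios(self):
        col = case_study_posteriors("uniform", T1)
        rep = sensitivity_report(
            T1, col,
            [case_study_prior("historical"), case_study_prior("uniform")],
        )
        maps = {r.scenario: r.map_taxon for r in rep.results}
        assert maps["historical"] == "R. moschata Herrm."
        assert maps["uniform"] == "R. canina L."
        assert rep.map_changed

    def test_single_scenario_rejected(self):
        with pytest.raises(ValidationError):
            sensitivity_report(T1, {"a": 1.0}, [uniform_prior(["a"])])
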