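import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prickleid import (
    AbundanceWeights,
    PrickleType,
    ReferenceCollection,
    TaxonMismatchError,
    ValidationError,
    apply_abundance_weighting,
    estimate_likelihoods,
    marginal_likelihood,
    uniform_prior,
)
from prickleid.datasets import case_study_posteriors, case_study_prior, case_study_taxa

from conftest import record

T1, T2, TO = PrickleType.T1, PrickleType.T2, PrickleType.TO

counts_3 = st.tuples(
    st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
)


def collection_from_counts(count_rows):
    recs = [
        record(f"taxon-{i}", t1=a, t2=b, to=c)
        for i, (a, b, c) in enumerate(count_rows)
    ]
    return ReferenceCollection(records=recs)


class TestEstimation:
    def test_degenerate_taxon_is_point_mass(self):
        table = estimate_likelihoods(
            ReferenceCollection(records=[record("A", t1=10)])
        )
        assert table.prob("A", T1) == 1.0
        assert table.prob("A", T2) == 0.0 and table.prob("A", TO) == 0.0

    def test_counts_pool_across_fragments(self):
        coll = ReferenceCollection(
            records=[record("A", t1=3, t2=1), record("A", t1=1, t2=3)]
        )
        table = estimate_likelihoods(coll)
        assert table.prob("A", T1) == pytest.approx(0.5)
        assert table.prob("A", T2) == pytest.approx(0.5)

    def test_laplace_smoothing_formula(self):
        coll = ReferenceCollection(records=[record("A", t1=1)])
        table = estimate_likelihoods(coll, smoothing_alpha=1.0)
        assert table.prob("A", T1) == pytest.approx(2 / 4)
        assert table.prob("A", T2) == pytest.approx(1 / 4)
        assert table.prob("A", TO) == pytest.approx(1 / 4)

    def test_zero_prickle_taxon_flagged_undefined(self):
        coll = ReferenceCollection(records=[record("A"), record("B", t1=2)])
        table = estimate_likelihoods(coll)
        assert "A" in table.undefined and "B" not in table.undefined

    def test_zero_prickle_taxon_defined_under_smoothing(self):
        coll = ReferenceCollection(records=[record("A")])
        table = estimate_likelihoods(coll, smoothing_alpha=1.0)
        assert table.prob("A", T1) == pytest.approx(1 / 3)

    def test_taxon_without_fragments_under_filter_rejected(self, tiny_collection):
        with pytest.raises(ValidationError, match="foetida"):
            estimate_likelihoods(tiny_collection, organ_filter="stem")

    @settings(deadline=None)
    @given(st.lists(counts_3, min_size=1, max_size=6))
    def test_rows_are_stochastic(self, rows):
        table = estimate_likelihoods(collection_from_counts(rows))
        for i, taxon in enumerate(table.taxa):
            if taxon in table.undefined:
                assert sum(rows[i]) == 0
                continue
            total = sum(table.prob(taxon, t) for t in (T1, T2, TO))
            assert total == pytest.approx(1.0, abs=1e-12)

    @given(counts_3.filter(lambda c: sum(c) > 0), st.integers(0, 49))
    def test_invariant_to_splitting_a_fragment(self, counts, split):
        a, b, c = counts
        whole = ReferenceCollection(records=[record("A", t1=a, t2=b, to=c)])
        cut = min(split, a)
        halves = ReferenceCollection(
            records=[
                record("A", t1=cut, length=2.0),
                record("A", t1=a - cut, t2=b, to=c, length=3.0),
            ]
        )
        t_whole = estimate_likelihoods(whole)
        t_halves = estimate_likelihoods(halves)
        for t in (T1, T2, TO):
            assert t_whole.prob("A", t) == pytest.approx(t_halves.prob("A", t))

    def test_invariant_to_fragment_order(self, tiny_collection):
        rev = ReferenceCollection(
            records=list(reversed(tiny_collection.records)),
            taxa=tiny_collection.taxa,
        )
        a = estimate_likelihoods(tiny_collection)
        b = estimate_likelihoods(rev)
        for taxon in a.taxa:
            for t in (T1, T2, TO):
                assert a.prob(taxon, t) == pytest.approx(b.prob(taxon, t))


class TestAbundanceWeighting:
    def test_equal_weights_is_identity(self, tiny_collection):
        table = estimate_likelihoods(tiny_collection)
        w = AbundanceWeights({t: 3.0 for t in table.taxa})
        assert apply_abundance_weighting(table, w).probs == table.probs

    def test_probabilities_unchanged_counts_scaled(self):
        coll = ReferenceCollection(
            records=[record("A", t1=4), record("B", t2=4)]
        )
        table = estimate_likelihoods(coll)
        weighted = apply_abundance_weighting(
            table, AbundanceWeights({"A": 1.0, "B": 10.0})
        )
        assert weighted.probs == table.probs
        ratio = weighted.counts[("B", T2)] / weighted.counts[("A", T1)]
        assert ratio == pytest.approx(10.0)
        assert weighted.weighting == "per_plant_abundance"

    def test_missing_weight_names_taxon(self, tiny_collection):
        table = estimate_likelihoods(tiny_collection)
        with pytest.raises(TaxonMismatchError, match="foetida"):
            apply_abundance_weighting(table, AbundanceWeights({table.taxa[0]: 1.0}))

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValidationError):
            AbundanceWeights({"A": 0.0})


class TestMarginal:
    def test_hand_arithmetic(self):
        coll = ReferenceCollection(
            records=[record("A", t1=2, t2=8), record("B", t1=4, t2=6)]
        )
        table = estimate_likelihoods(coll)
        prior = uniform_prior(["A", "B"])
        assert marginal_likelihood(table, prior, T1) == pytest.approx(0.3)

    def test_constant_likelihood_identity(self):
        coll = ReferenceCollection(
            records=[record("A", t1=3, t2=7), record("B", t1=30, t2=70)]
        )
        table = estimate_likelihoods(coll)
        prior = uniform_prior(["A", "B"])
        assert marginal_likelihood(table, prior, T1) == pytest.approx(0.3)

    def test_marginal_is_convex_combination(self, tiny_collection):
        table = estimate_likelihoods(tiny_collection)
        prior = uniform_prior(list(table.taxa))
        for t in (T1, T2, TO):
            col = list(table.column(t).values())
            m = marginal_likelihood(table, prior, t)
            assert min(col) - 1e-12 <= m <= max(col) + 1e-12

    def test_case_study_columns_give_published_marginal(self):
        # scenario-B T1 posteriors, read as likelihoods, under scenario-A priors
        col = case_study_posteriors("uniform", "T1")
        prior = case_study_prior("historical")
        m = sum(col[t] * prior.normalized[t] for t in case_study_taxa())
        assert m == pytest.approx(0.0569, abs=1e-4)

    def test_taxa_mismatch_listed(self, tiny_collection):
        table = estimate_likelihoods(tiny_collection)
        with pytest.raises(TaxonMismatchError, match="foetida"):
            marginal_likelihood(table, uniform_prior([table.taxa[0]]), T1)


def test_table_serializes_to_csv_and_json(tiny_collection, tmp_path):
    table = estimate_likelihoods(tiny_collection)
    csv_path = table.to_csv(tmp_path / "lik.csv")
    assert csv_path.read_text().splitlines()[0] == "taxon,p_T1,p_T2,p_TO"
    doc = table.to_json()
    assert set(doc["probs"]) == set(table.taxa)
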