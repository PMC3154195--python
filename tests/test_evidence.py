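import math

import numpy as np
import pytest

from bnpp.datamodel import GenotypeDataset, ModelSpec
from bnpp.evidence import (
    ModelTooLargeError,
    bnpp_posterior,
    log_evidence_bruteforce,
    log_evidence_recursive,
    model_log_likelihood,
    submodel_posteriors,
)
from bnpp.priors import PriorSpec, empty_model_prior, model_size_prior
from bnpp.scoring import HyperparameterSpec


@pytest.fixture
def two_pheno_dataset():
    """Two individuals, one case and one control: counts [1, 1]."""
    return GenotypeDataset(
        genotypes=[[0], [1]], phenotype=[0, 1], snp_ids=["S1"]
    )


class TestModelLogLikelihood:
    def test_empty_model_is_parentless_phenotype_score(self, two_pheno_dataset):
        got = model_log_likelihood(
            two_pheno_dataset, ModelSpec(), HyperparameterSpec(alpha=2)
        )
        assert got == pytest.approx(math.log(1 / 6), abs=1e-12)

    def test_parent_order_is_irrelevant(self, random_dataset_factory, default_hyper):
        ds = random_dataset_factory(seed=3)
        assert model_log_likelihood(
            ds, ModelSpec([4, 0, 2]), default_hyper
        ) == model_log_likelihood(ds, ModelSpec([2, 4, 0]), default_hyper)

    def test_perfectly_predictive_snp_beats_null(self):
        rng = np.random.default_rng(1)
        pheno = rng.integers(0, 2, 200)
        geno = np.column_stack([pheno, rng.integers(0, 3, 200)])
        ds = GenotypeDataset(geno, pheno, ["S1", "S2"])
        hyper = HyperparameterSpec(alpha=54)
        assert model_log_likelihood(ds, ModelSpec([0]), hyper) > model_log_likelihood(
            ds, ModelSpec(), hyper
        )


class TestEvidence:
    def test_size_zero_candidate_is_null_likelihood(
        self, two_pheno_dataset, default_priors
    ):
        hyper = HyperparameterSpec(alpha=2)
        b = log_evidence_recursive(two_pheno_dataset, ModelSpec(), default_priors, hyper)
        assert b.log_evidence == pytest.approx(math.log(1 / 6), abs=1e-12)
        assert len(b.submodel_terms) == 1

    def test_size_one_candidate_matches_two_term_mixture(
        self, random_dataset_factory, default_priors, default_hyper
    ):
        ds = random_dataset_factory(seed=9)
        model = ModelSpec([2])
        b = log_evidence_recursive(ds, model, default_priors, default_hyper)
        l1 = model_log_likelihood(ds, model, default_hyper)
        l0 = model_log_likelihood(ds, ModelSpec(), default_hyper)
        pi1 = model_size_prior(1, default_priors)
        expected = np.logaddexp(l1 + math.log(pi1), l0 + math.log(1 - pi1))
        assert b.log_evidence == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("size", range(6))
    def test_recursion_agrees_with_powerset_oracle(
        self, size, random_dataset_factory, default_priors, default_hyper
    ):
        ds = random_dataset_factory(n=50, n_snps=6, seed=size)
        model = ModelSpec(range(size))
        rec = log_evidence_recursive(ds, model, default_priors, default_hyper)
        brute = log_evidence_bruteforce(ds, model, default_priors, default_hyper)
        assert rec.log_evidence == pytest.approx(brute.log_evidence, abs=1e-9)
        assert rec.submodel_terms.keys() == brute.submodel_terms.keys()
        assert len(rec.submodel_terms) == 2**size

    def test_shared_cache_changes_nothing(
        self, random_dataset_factory, default_priors, default_hyper
    ):
        ds = random_dataset_factory(seed=21)
        cache: dict = {}
        models = [ModelSpec([0, 1]), ModelSpec([1, 2]), ModelSpec([0, 1, 2])]
        with_cache = [
            log_evidence_recursive(ds, m, default_priors, default_hyper, _cache=cache)
            for m in models
        ]
        without = [
            log_evidence_recursive(ds, m, default_priors, default_hyper) for m in models
        ]
        for a, b in zip(with_cache, without):
            assert a.log_evidence == b.log_evidence

    def test_oversized_candidate_refused(
        self, random_dataset_factory, default_priors, default_hyper
    ):
        ds = random_dataset_factory(n=20, n_snps=6, seed=0)
        with pytest.raises(ModelTooLargeError):
            log_evidence_recursive(ds, ModelSpec(range(6)), default_priors, default_hyper)


class TestPosterior:
    def test_equal_likelihoods_cancel_to_prior_share(
        self, default_priors, default_hyper
    ):
        # zero individuals: every submodel's log-likelihood is exactly 0, so
        # the likelihoods cancel and posterior = pi_M / (total prior) = pi_M
        ds = GenotypeDataset(
            genotypes=np.empty((0, 4), dtype=int),
            phenotype=np.empty(0, dtype=int),
            snp_ids=list("ABCD"),
        )
        model = ModelSpec([0, 1])
        rec = bnpp_posterior(ds, model, default_priors, default_hyper)
        pi2 = model_size_prior(2, default_priors)
        total = (
            empty_model_prior(default_priors, 2)
            + 2 * model_size_prior(1, default_priors)
            + pi2
        )
        assert rec.posterior == pytest.approx(pi2 / total, rel=1e-9)

    def test_submodel_posteriors_sum_to_one(
        self, random_dataset_factory, default_priors, default_hyper
    ):
        ds = random_dataset_factory(seed=13)
        b = log_evidence_recursive(ds, ModelSpec([0, 2, 4]), default_priors, default_hyper)
        records = submodel_posteriors(b)
        assert len(records) == 8
        assert sum(r.posterior for r in records) == pytest.approx(1.0, abs=1e-9)
        assert [r.rank for r in records] == list(range(1, 9))

    def test_size_one_candidate_yields_two_records(
        self, random_dataset_factory, default_priors, default_hyper
    ):
        ds = random_dataset_factory(seed=2)
        b = log_evidence_recursive(ds, ModelSpec([1]), default_priors, default_hyper)
        records = submodel_posteriors(b)
        assert len(records) == 2
        assert sum(r.posterior for r in records) == pytest.approx(1.0, abs=1e-12)

    def test_redundant_partner_loses_to_parsimonious_submodel(self, default_hyper):
        # phenotype duplicates S1; S2 is noise: {S1} should outrank {S1,S2}
        rng = np.random.default_rng(8)
        pheno = rng.integers(0, 2, 400)
        geno = np.column_stack([pheno, rng.integers(0, 3, 400)])
        ds = GenotypeDataset(geno, pheno, ["S1", "S2"])
        priors = PriorSpec(snp_prior=1e-4)
        b = log_evidence_recursive(ds, ModelSpec([0, 1]), priors, default_hyper)
        records = submodel_posteriors(b)
        by_model = {r.model: r for r in records}
        assert by_model[ModelSpec([0])].posterior > by_model[ModelSpec([0, 1])].posterior
        assert records[0].model == ModelSpec([0])

    def test_uninformative_data_ranking_follows_priors(
        self, default_priors, default_hyper
    ):
        ds = GenotypeDataset(
            genotypes=np.empty((0, 3), dtype=int),
            phenotype=np.empty(0, dtype=int),
            snp_ids=list("XYZ"),
        )
        b = log_evidence_recursive(ds, ModelSpec([0, 1, 2]), default_priors, default_hyper)
        records = submodel_posteriors(b)
        # null model has overwhelmingly the largest prior, then singletons...
        assert records[0].model == ModelSpec()
        assert {r.model.size for r in records[1:4]} == {1}

    def test_empty_candidate_has_no_posterior(self, two_pheno_dataset, default_priors):
        with pytest.raises(ValueError):
            bnpp_posterior(
                two_pheno_dataset, ModelSpec(), default_priors, HyperparameterSpec()
            )

    def test_snp_order_invariance_of_posterior(
        self, random_dataset_factory, default_priors, default_hyper
    ):
        ds = random_dataset_factory(seed=17)
        a = bnpp_posterior(ds, ModelSpec([3, 1]), default_priors, default_hyper)
        b = bnpp_posterior(ds, ModelSpec([1, 3]), default_priors, default_hyper)
        assert a.posterior == b.posterior
        assert a.log_likelihood == b.log_likelihood
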