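"""Bayesian linkage model: closed-form oracles, symmetries, and call logic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from bsrseq.bsa_linkage import (
    BulkCounts,
    LinkageModelConfig,
    assign_snps_to_genes,
    call_high_probability,
    estimate_prior,
    intersect_high_probability,
    linkage_posterior,
    log_bayes_factor,
    log_marginal_beta_binomial,
    posterior_from_log_bf,
    summarize_by_chromosome,
)
from bsrseq.errors import DomainError, EstimationError, UndefinedResultError
from bsrseq.synthetic_data import simulate_mixture_counts


class TestLogMarginalBetaBinomial:
    def test_empty_data_is_log_one(self):
        assert log_marginal_beta_binomial(0, 0, 1, 1) == pytest.approx(0.0)

    def test_single_observation_uniform_prior(self):
        # B(2,1)/B(1,1) = 1/2
        assert log_marginal_beta_binomial(1, 0, 1, 1) == pytest.approx(math.log(0.5))

    def test_matches_adaptive_quadrature(self):
        # integral of p^5 (1-p)^2 over [0,1] under a uniform prior
        expected, _ = quad(lambda p: p**5 * (1 - p) ** 2, 0, 1)
        got = math.exp(log_marginal_beta_binomial(5, 2, 1, 1))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_non_positive_pseudocount_rejected(self):
        with pytest.raises(DomainError):
            log_marginal_beta_binomial(1, 1, 0, 1)


class TestLinkagePosterior:
    def test_prior_degeneracy(self):
        counts = BulkCounts(5, 3, 2, 9)
        zero = linkage_posterior(counts, LinkageModelConfig(prior_linked=0.0))
        one = linkage_posterior(counts, LinkageModelConfig(prior_linked=1.0))
        assert zero.posterior == 0.0
        assert one.posterior == 1.0

    def test_fully_divergent_counts_closed_form(self):
        """(30,0,0,30): L1 = (1/31)^2, L0 = B(31,31); posterior > 0.99."""
        result = linkage_posterior(BulkCounts(30, 0, 0, 30),
                                   LinkageModelConfig(prior_linked=0.05))
        l1 = (1.0 / 31.0) ** 2
        l0 = math.exp(math.lgamma(31) * 2 - math.lgamma(62))
        expected = 0.05 * l1 / (0.05 * l1 + 0.95 * l0)
        assert result.posterior == pytest.approx(expected, abs=1e-12)
        assert result.posterior > 0.99
        assert result.high_probability

    def test_identical_bulks_favour_the_null(self):
        """(5,5,5,5): BF = B(6,6)^2 / B(11,11) < 1, so posterior < pi."""
        bf = math.exp(
            2 * (math.lgamma(6) * 2 - math.lgamma(12))
            - (math.lgamma(11) * 2 - math.lgamma(22))
        )
        assert bf < 1
        for pi in (0.05, 0.3, 0.7):
            result = linkage_posterior(BulkCounts(5, 5, 5, 5),
                                       LinkageModelConfig(prior_linked=pi))
            assert math.exp(result.log_bf) == pytest.approx(bf, rel=1e-12)
            assert result.posterior < pi

    def test_no_reads_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            linkage_posterior(BulkCounts(0, 0, 0, 0))

    @given(
        a_t=st.integers(0, 40), b_t=st.integers(0, 40),
        a_s=st.integers(0, 40), b_s=st.integers(0, 40),
    )
    @settings(max_examples=150, deadline=None)
    def test_type_and_bulk_swap_symmetry(self, a_t, b_t, a_s, b_s):
        if a_t + b_t + a_s + b_s == 0:
            return
        cfg = LinkageModelConfig()
        base = linkage_posterior(BulkCounts(a_t, b_t, a_s, b_s), cfg)
        type_swap = linkage_posterior(BulkCounts(b_t, a_t, b_s, a_s), cfg)
        bulk_swap = linkage_posterior(BulkCounts(a_s, b_s, a_t, b_t), cfg)
        assert base.log_bf == pytest.approx(type_swap.log_bf, abs=1e-10)
        assert base.log_bf == pytest.approx(bulk_swap.log_bf, abs=1e-10)
        assert base.posterior == pytest.approx(type_swap.posterior, abs=1e-10)

    @pytest.mark.parametrize("n", [10, 30, 50])
    def test_divergence_monotonicity(self, n):
        """BF is non-decreasing as the bulks move apart at fixed depth n."""
        ks = np.arange((n + 1) // 2, n + 1)
        lbf = log_bayes_factor(ks, n - ks, n - ks, ks)
        assert np.all(np.diff(lbf) >= -1e-9)

    def test_half_null_mode(self):
        cfg = LinkageModelConfig(null_mode="half")
        result = linkage_posterior(BulkCounts(3, 1, 1, 3), cfg)
        l1 = math.exp(2 * (math.lgamma(4) + math.lgamma(2) - math.lgamma(6)))
        l0 = 0.5**8
        assert math.exp(result.log_bf) == pytest.approx(l1 / l0, rel=1e-10)


class TestEstimatePrior:
    def test_unit_bayes_factor_is_a_fixed_point(self):
        # (1,0,0,1) pooled (1,1): L1 = (1/2)^2, L0 = B(2,2) = 1/6... not unit;
        # instead use zero-information sites plus one read each side of one bulk
        counts = [BulkCounts(1, 1, 0, 0)] * 20
        lbf = log_bayes_factor(1, 1, 0, 0)
        assert lbf == pytest.approx(0.0)  # single-bulk data cannot separate
        pi, info = estimate_prior(counts, LinkageModelConfig(prior_linked=0.2,
                                                             em_enabled=True))
        assert pi == pytest.approx(0.2, abs=1e-9)

    def test_recovers_planted_linked_fraction(self):
        mix = simulate_mixture_counts(n_sites=1000, linked_fraction=0.10,
                                      depth=100.0, seed=7)
        pi, info = estimate_prior(
            mix[["a_t", "b_t", "a_s", "b_s"]].to_numpy(),
            LinkageModelConfig(em_enabled=True),
        )
        assert abs(pi - 0.10) <= 0.05
        assert info["converged"]

    def test_loglik_non_decreasing(self):
        mix = simulate_mixture_counts(n_sites=400, seed=3)
        _, info = estimate_prior(
            mix[["a_t", "b_t", "a_s", "b_s"]].to_numpy(),
            LinkageModelConfig(em_enabled=True),
        )
        trace = np.array(info["loglik_trace"])
        assert np.all(np.diff(trace) >= -1e-7 * np.abs(trace[:-1]))

    def test_too_few_sites_raises(self):
        with pytest.raises(EstimationError):
            estimate_prior([BulkCounts(5, 0, 0, 5)] * 5, LinkageModelConfig())


def _scan_frame(posteriors):
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * len(posteriors),
            "pos": np.arange(1, len(posteriors) + 1) * 100,
            "type1": "A",
            "type2": "G",
            "posterior": posteriors,
        }
    )


class TestCalls:
    def test_strict_threshold(self):
        called = call_high_probability(_scan_frame([0.89, 0.90, 0.91]), 0.9)
        assert called["posterior"].tolist() == [0.91]

    def test_empty_and_zero_threshold(self):
        assert len(call_high_probability(_scan_frame([]), 0.9)) == 0
        assert len(call_high_probability(_scan_frame([0.1, 0.5]), 0.0)) == 2

    def test_intersection_by_site_and_type_pair(self):
        a = _scan_frame([0.95, 0.96, 0.97])
        b = _scan_frame([0.95, 0.96, 0.97]).iloc[1:]
        b.loc[b.index[-1], "pos"] = 999  # different site
        overlap, report = intersect_high_probability(a, b)
        assert len(overlap) == 1
        assert report == {"n_a": 3, "n_b": 2, "n_overlap": 1, "a_only": 2,
                          "b_only": 1}

    def test_intersection_type_pair_must_match(self):
        a = _scan_frame([0.95])
        b = _scan_frame([0.95])
        b["type2"] = "T"
        overlap, _ = intersect_high_probability(a, b)
        assert len(overlap) == 0

    def test_subset_intersection(self):
        a = _scan_frame([0.95, 0.96])
        b = _scan_frame([0.95, 0.96, 0.97, 0.98])
        overlap, _ = intersect_high_probability(a, b)
        assert len(overlap) == len(a)


class TestGeneAssignment:
    def test_containment_boundaries_and_overlap(self, gene_models):
        snps = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr1", "chr2"],
             "pos": [1500, 2000, 3000, 950]}
        )
        annotated, histogram = assign_snps_to_genes(snps, gene_models)
        by_pos = annotated.groupby("pos")["gene_id"].apply(
            lambda s: sorted(x for x in s if x)
        )
        assert by_pos[1500] == ["geneA", "geneB"]  # overlapping genes: both
        assert by_pos[2000] == ["geneA", "geneB"]  # inclusive end of geneA
        assert by_pos[3000] == []  # intergenic
        assert by_pos[950] == []  # past geneC's end
        assert histogram == {2: 2}  # geneA and geneB hold two SNPs each

    def test_chromosome_summary_partitions(self):
        snps = pd.DataFrame({"chrom": ["chr1"] * 3 + ["chr2"],
                             "pos": [1, 2, 3, 4]})
        counts = summarize_by_chromosome(snps, chromosomes=["chr1", "chr2", "chr3"])
        assert counts == {"chr1": 3, "chr2": 1, "chr3": 0}
        assert sum(counts.values()) == len(snps)

    def test_empty_set_all_zero(self):
        snps = pd.DataFrame({"chrom": [], "pos": []})
        counts = summarize_by_chromosome(snps, chromosomes=["chr1"])
        assert counts == {"chr1": 0}
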