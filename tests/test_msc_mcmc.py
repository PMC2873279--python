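"""Multispecies-coalescent MCMC: densities, likelihood, moves, summaries."""
import math

import numpy as np
import pandas as pd
import pytest

from junglecoal import msc_mcmc, synth
from junglecoal.coalescent import Genealogy
from junglecoal.demography import PARAM_NAMES, DemographyParams
from junglecoal.msc_mcmc import (
    ChainConfig,
    GammaPrior,
    coal_logdensity,
    jc_loglik,
    msc_stats,
    summarize_runs,
    summarize_samples,
)


def two_tip_genealogy(t, species=(0, 1)):
    g = Genealogy(2, np.array([[0, 1]]), np.array([0.0, 0.0, t]), ("C", "R"))
    masks = np.zeros(3, dtype=np.int8)
    masks[:2] = 1 << np.array(species, dtype=np.int8)
    masks[2] = masks[0] | masks[1]
    return g, masks


class TestMSCStats:
    def test_hand_built_cr_pair(self):
        """One C and one R lineage coalescing in the CR ancestor."""
        g, masks = two_tip_genealogy(0.003)
        st = msc_stats(g.times, masks, (1, 1, 0), 0.001, 0.005, 2)
        c, A = st
        assert list(c) == [0, 0, 0, 1, 0]
        # two lineages in CR from tau_cr=0.001 until 0.003: A = 1 * 0.002
        assert A == pytest.approx([0, 0, 0, 0.002, 0])

    def test_hand_built_rcg_pair(self):
        g, masks = two_tip_genealogy(0.007)
        c, A = msc_stats(g.times, masks, (1, 1, 0), 0.001, 0.005, 2)
        assert list(c) == [0, 0, 0, 0, 1]
        assert A == pytest.approx([0, 0, 0, 0.004, 0.002])

    def test_cr_coalescence_below_tau_cr_invalid(self):
        g, masks = two_tip_genealogy(0.0005)
        assert msc_stats(g.times, masks, (1, 1, 0), 0.001, 0.005, 2) is None

    def test_g_involved_below_tau_rcg_invalid(self):
        g, masks = two_tip_genealogy(0.003, species=(0, 2))
        assert msc_stats(g.times, masks, (1, 0, 1), 0.001, 0.005, 2) is None

    def test_within_species_pair_any_time(self):
        g, masks = two_tip_genealogy(0.0004, species=(0, 0))
        c, A = msc_stats(g.times, masks, (2, 0, 0), 0.001, 0.005, 2)
        assert list(c) == [1, 0, 0, 0, 0]
        assert A == pytest.approx([0.0004, 0, 0, 0, 0])

    def test_density_hand_formula(self):
        """Density of a CR coalescence: (2/theta) e^{-2 A / theta}."""
        g, masks = two_tip_genealogy(0.003)
        c, A = msc_stats(g.times, masks, (1, 1, 0), 0.001, 0.005, 2)
        theta_cr = 0.008
        expected = math.log(2 / theta_cr) - 2 * 0.002 / theta_cr
        thetas = [0.001, 0.001, 0.001, theta_cr, 0.02]
        assert coal_logdensity(c, A, thetas) == pytest.approx(expected)


class TestJCLikelihood:
    def test_identical_tips_zero_branch(self):
        g = Genealogy(2, np.array([[0, 1]]), np.array([0.0, 0.0, 0.0]), ("C", "C"))
        # one pattern "AA" with count 5
        tp = np.zeros((2, 4, 1))
        tp[:, 0, 0] = 1.0
        ll = jc_loglik(g, tp, np.array([5.0]))
        # zero branch lengths: only the root frequency 1/4 per site
        assert ll == pytest.approx(5 * math.log(0.25))

    def test_two_tip_closed_form(self):
        """P(same) and P(diff) for a two-tip tree match the JC transition
        probabilities over the total path length."""
        t = 0.07
        g = Genealogy(2, np.array([[0, 1]]), np.array([0.0, 0.0, t / 2]), ("C", "C"))
        same = np.zeros((2, 4, 1)); same[:, 0, 0] = 1.0
        diff = np.zeros((2, 4, 1)); diff[0, 0, 0] = 1.0; diff[1, 1, 0] = 1.0
        e = math.exp(-4 * t / 3)
        p_same = 0.25 * (0.25 + 0.75 * e)
        p_diff = 0.25 * (0.25 - 0.25 * e)
        assert jc_loglik(g, same, np.ones(1)) == pytest.approx(math.log(p_same))
        assert jc_loglik(g, diff, np.ones(1)) == pytest.approx(math.log(p_diff))

    def test_missing_data_marginalizes_to_one(self):
        g = Genealogy(2, np.array([[0, 1]]), np.array([0.0, 0.0, 0.1]), ("C", "C"))
        tp = np.ones((2, 4, 1))  # both tips unknown
        assert jc_loglik(g, tp, np.ones(1)) == pytest.approx(0.0)

    def test_locus_order_invariance(self, default_sim_catalog, species_map):
        cat, _ = default_sim_catalog
        loci = msc_mcmc.prepare_locus_data(cat, species_map)
        rng = np.random.default_rng(0)
        params = DemographyParams(0.003, 0.003, 0.003, 0.008, 0.016, 0.001, 0.006)
        from junglecoal.coalescent import simulate_msc

        total = 0.0
        lls = []
        for ld in loci:
            g = simulate_msc(ld.tip_species, params, rng)
            lls.append(jc_loglik(g, ld.tip_partials, ld.pattern_counts))
        assert sum(lls) == pytest.approx(sum(reversed(lls)))


def _empty_loci(n_loci=4, tips_per_species=2):
    k = 3 * tips_per_species
    tip_species = np.repeat(np.arange(3, dtype=np.int8), tips_per_species)
    return [
        msc_mcmc._LocusData(
            f"l{i}", tip_species, np.ones((k, 4, 0)), np.empty(0),
            (tips_per_species,) * 3,
        )
        for i in range(n_loci)
    ]


def _test_priors():
    means = {
        "theta_c": 0.002, "theta_r": 0.001, "theta_g": 0.003,
        "theta_cr": 0.007, "theta_rcg": 0.016,
        "tau_cr": 0.0002, "tau_rcg": 0.0063,
    }
    return {k: GammaPrior(2.0, v / 2.0) for k, v in means.items()}


class TestSamplerInternals:
    def test_caches_match_full_recomputation(self, default_sim_catalog, species_map):
        """The incremental pruning and sufficient-statistic caches must agree
        with a from-scratch evaluation after many accepted moves; this is the
        operational detailed-balance check for every kernel."""
        cat, _ = default_sim_catalog
        loci = msc_mcmc.prepare_locus_data(cat, species_map)[:8]
        sampler = msc_mcmc.MSCSampler(loci, _test_priors(), np.random.default_rng(3))
        for _ in range(150):
            sampler.iterate()
        for i, ld in enumerate(loci):
            g = sampler.genealogies[i]
            assert sampler.logliks[i] == pytest.approx(
                jc_loglik(g, ld.tip_partials, ld.pattern_counts), abs=1e-8
            )
            st = msc_stats(
                g.times, sampler.masks[i], ld.n_by_species,
                sampler.params.tau_cr, sampler.params.tau_rcg, g.n_tips,
            )
            assert st is not None
            assert (st[0] == sampler.stats[i][0]).all()
            assert np.allclose(st[1], sampler.stats[i][1])
            # masks and parents in sync with the topology
            assert (sampler.masks[i] == msc_mcmc._compute_masks(
                g, ld.tip_species)).all()
            assert (sampler.parents[i] == g.parents()).all()

    def test_acceptance_ratio_is_posterior_ratio(self):
        """Metropolis-Hastings identity for the fixed-genealogy theta kernel
        on a hand-built two-lineage state."""
        g, masks = two_tip_genealogy(0.003)
        st = msc_stats(g.times, masks, (1, 1, 0), 0.001, 0.005, 2)
        priors = _test_priors()
        for old, new in [(0.008, 0.012), (0.012, 0.008), (0.008, 0.002)]:
            def log_post(theta_cr):
                thetas = [0.002, 0.001, 0.003, theta_cr, 0.016]
                return coal_logdensity(*st, thetas) + priors["theta_cr"].logpdf(
                    theta_cr
                )

            # the kernel's log ratio (excluding the proposal Jacobian)
            c, A = st
            kernel = (
                priors["theta_cr"].logpdf(new) - priors["theta_cr"].logpdf(old)
                + c[3] * (math.log(old) - math.log(new))
                - 2.0 * A[3] * (1.0 / new - 1.0 / old)
            )
            assert kernel == pytest.approx(log_post(new) - log_post(old), rel=1e-9)

    def test_tau_ordering_never_violated(self):
        loci = _empty_loci()
        sampler = msc_mcmc.MSCSampler(loci, _test_priors(), np.random.default_rng(1))
        for _ in range(500):
            sampler.iterate()
            assert sampler.params.tau_cr <= sampler.params.tau_rcg


class TestPriorRecovery:
    def test_prior_recovered_quickly(self):
        """With empty data the parameter marginals equal the prior; short
        chain, loose tolerance (the acceptance suite runs the long version)."""
        loci = _empty_loci()
        priors = _test_priors()
        sampler = msc_mcmc.MSCSampler(loci, priors, np.random.default_rng(8))
        recs = []
        for it in range(16000):
            sampler.iterate()
            if it >= 1000:
                recs.append(sampler.params.as_array())
        df = pd.DataFrame(recs, columns=PARAM_NAMES)
        for name in PARAM_NAMES:
            assert df[name].mean() == pytest.approx(priors[name].mean, rel=0.2)


class TestSummaries:
    def test_identical_seeds_zero_dispersion(self):
        loci = _empty_loci(2)
        runs = []
        for _ in range(2):
            sampler = msc_mcmc.MSCSampler(
                loci, _test_priors(), np.random.default_rng(4)
            )
            runs.append(sampler.run(ChainConfig(50, 100, 2, 1)))
        summary = summarize_runs(runs)
        assert summary.nonconverged == []
        assert (summary.per_run_means.std(ddof=1) == 0).all()

    def test_unequal_lengths_truncated_with_warning(self, caplog):
        rng = np.random.default_rng(0)
        r1 = pd.DataFrame(rng.random((100, 7)), columns=PARAM_NAMES)
        r2 = pd.DataFrame(rng.random((80, 7)), columns=PARAM_NAMES)
        with caplog.at_level("WARNING"):
            summary = summarize_runs([r1, r2])
        assert summary.n_samples == 160
        assert "truncating" in caplog.text

    def test_credible_limit_ordering(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.exponential(1.0, (500, 7)), columns=PARAM_NAMES)
        s = summarize_samples(df)
        assert (s.table["lo"] <= s.table["median"]).all()
        assert (s.table["median"] <= s.table["hi"]).all()

    def test_retained_sample_count_matches_config(self):
        loci = _empty_loci(2)
        sampler = msc_mcmc.MSCSampler(loci, _test_priors(), np.random.default_rng(2))
        samples = sampler.run(ChainConfig(20, 100, 2, 1))
        assert len(samples) == 50  # iterations / thinning

    def test_chain_config_validation(self):
        with pytest.raises(ValueError):
            ChainConfig(burnin=0)


class TestDerivePriors:
    def test_moment_matched_means(self, default_sim_catalog, species_map):
        cat, _ = default_sim_catalog
        priors = msc_mcmc.derive_priors(cat, species_map)
        from junglecoal import popgen_stats as ps

        # ancestral thetas use pooled pi; extant thetas the identity-fraction
        # moment, which sits below pi under a shallow split
        pi_all = ps.diversity_table(
            cat, ["KOSHA", "UKO", "SHAMO", "WL", "RJF", "GJF"], method="JC69"
        ).mean
        assert priors["theta_rcg"].mean == pytest.approx(pi_all)
        pi_c = ps.diversity_table(
            cat, ["KOSHA", "UKO", "SHAMO", "WL"], method="JC69"
        ).mean
        assert priors["theta_c"].mean < pi_c
        assert priors["theta_c"].shape == 1.0
        assert all(p.mean > 0 for p in priors.values())

    def test_identity_moment_pure_population(self, rng):
        """On a single isolated population the identity moment recovers the
        simulated theta to the right order."""
        from junglecoal.msc_mcmc import _identity_theta

        theta = 0.004
        cfg = synth.SimulationConfig(
            demography=DemographyParams(
                theta, theta, theta, theta, theta, 0.05, 0.1
            ),
            locus_lengths=(600,) * 20,
            groups=(synth.GroupSpec("X", 6, 2, "C"),),
        )
        cat, _ = synth.simulate_catalog(cfg, rng)
        est = _identity_theta(cat, ["X"])
        assert est == pytest.approx(theta, rel=0.5)
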