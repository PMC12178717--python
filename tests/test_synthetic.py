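"""The coalescent generator against closed-form oracles."""

import numpy as np
import pytest
from scipy import stats

from psmckit.hetstats import heterozygosity
from psmckit.synthetic import (DemographyModel, QuartetModel, TmrcaTrack,
                               drop_mutations, sample_pairwise_tmrca,
                               simulate_quartet_sites, simulate_split_pair)


def _coal_cdf(epochs, t):
    """Analytic pairwise-coalescent CDF under piecewise-constant Ne.

    P(T <= t) = 1 - exp(-integral_0^t du / (2 N(u))); written directly from
    the survival function, independently of the sampler.
    """
    hazard = 0.0
    for k, (start, ne) in enumerate(epochs):
        end = epochs[k + 1][0] if k + 1 < len(epochs) else np.inf
        if t <= start:
            break
        hazard += (min(t, end) - start) / (2.0 * ne)
    return 1.0 - np.exp(-hazard)


class TestModelValidation:
    def test_epoch_times_must_increase(self):
        with pytest.raises(ValueError):
            DemographyModel(epochs=[(0.0, 1e4), (5.0, 1e3), (5.0, 1e4)])

    def test_first_epoch_at_zero(self):
        with pytest.raises(ValueError):
            DemographyModel(epochs=[(10.0, 1e4)])

    def test_positive_ne_required(self):
        with pytest.raises(ValueError):
            DemographyModel(epochs=[(0.0, -5.0)])

    def test_admixture_fraction_bounds(self):
        with pytest.raises(ValueError):
            DemographyModel(epochs=[(0.0, 1e4)],
                            admixture=("a", "b", 10.0, 1.5))


class TestTmrcaSampling:
    def test_no_recombination_single_segment(self):
        model = DemographyModel(epochs=[(0.0, 1e4)], r_per_gen=0.0)
        track = sample_pairwise_tmrca(model, 5000, seed=1)
        assert len(track.lengths) == 1 and track.total_length == 5000

    def test_constant_ne_mean_tmrca(self):
        # closed form: E[T] = 2N generations; 1e4 independent draws
        model = DemographyModel(epochs=[(0.0, 5000.0)])
        rng = np.random.default_rng(2)
        draws = np.array([model.coalescent_time(rng) for _ in range(10_000)])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 2 * 5000.0) < 3 * se

    def test_bottleneck_cdf_matches_analytic(self):
        epochs = [(0.0, 1e4), (2e4, 1e3), (3e4, 1e4)]
        model = DemographyModel(epochs=epochs)
        rng = np.random.default_rng(3)
        draws = np.array([model.coalescent_time(rng) for _ in range(10_000)])
        res = stats.ks_1samp(draws, lambda t: np.vectorize(
            lambda x: _coal_cdf(epochs, x))(t))
        assert res.statistic < 0.02

    def test_deterministic_given_seed(self):
        model = DemographyModel(epochs=[(0.0, 1e4)])
        t1 = sample_pairwise_tmrca(model, 200_000, seed=9)
        t2 = sample_pairwise_tmrca(model, 200_000, seed=9)
        assert np.array_equal(t1.lengths, t2.lengths)
        assert np.array_equal(t1.tmrcas, t2.tmrcas)

    def test_segment_lengths_exponential_given_tmrca(self):
        # conditional on T, inter-breakpoint distance ~ Exp(2 T r):
        # chi-square GOF on the unit-exponential transform, alpha = 0.01
        model = DemographyModel(epochs=[(0.0, 1e4)], r_per_gen=1e-8)
        lengths, tmrcas = [], []
        seed = 0
        while sum(len(x) for x in lengths) < 10_000:
            tr = sample_pairwise_tmrca(model, 10_000_000, seed=seed)
            lengths.append(tr.lengths[:-1])     # last segment is censored
            tmrcas.append(tr.tmrcas[:-1])
            seed += 1
        x = np.concatenate(lengths) * 2e-8 * np.concatenate(tmrcas)
        edges = stats.expon.ppf(np.linspace(0, 1, 21))
        edges[-1] = np.inf
        obs, _ = np.histogram(x, edges)
        expected = np.full(20, len(x) / 20)
        chi2 = ((obs - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=19)

    def test_track_invariants(self):
        with pytest.raises(ValueError):
            TmrcaTrack(lengths=np.array([5, 0]), tmrcas=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            TmrcaTrack(lengths=np.array([5]), tmrcas=np.array([-1.0]))


class TestDropMutations:
    def test_zero_mu_zero_het(self):
        model = DemographyModel(epochs=[(0.0, 1e4)])
        track = sample_pairwise_tmrca(model, 100_000, seed=4)
        cons = drop_mutations(track, mu_per_gen=0.0, seed=4)
        assert heterozygosity(cons).het_sites == 0

    def test_constant_tmrca_binomial_het_fraction(self):
        track = TmrcaTrack(lengths=np.array([1_000_000]),
                           tmrcas=np.array([20_000.0]))
        cons = drop_mutations(track, mu_per_gen=1e-8, seed=5)
        p = 1 - np.exp(-2 * 20_000 * 1e-8)
        s = heterozygosity(cons)
        se = np.sqrt(p * (1 - p) * 1_000_000)
        assert abs(s.het_sites - p * 1_000_000) < 3 * se

    def test_constant_ne_het_near_4N_mu(self):
        # E[het] = E[1 - exp(-2 T mu)] ~= 4 N mu for small theta
        N, mu = 1e4, 1e-8
        model = DemographyModel(epochs=[(0.0, N)], mu_per_gen=mu)
        track = sample_pairwise_tmrca(model, 4_000_000, seed=6)
        s = heterozygosity(drop_mutations(track, mu, seed=6))
        expected = 4 * N * mu * 4_000_000
        # segments are correlated; allow 3 SE with an effective-sample guard
        assert abs(s.het_sites - expected) < 5 * np.sqrt(expected)

    def test_deterministic_given_seed(self):
        track = TmrcaTrack(lengths=np.array([10_000]),
                           tmrcas=np.array([30_000.0]))
        c1 = drop_mutations(track, 1e-8, seed=8)
        c2 = drop_mutations(track, 1e-8, seed=8)
        assert c1.contigs == c2.contigs


class TestSplitPair:
    MODEL = DemographyModel(epochs=[(0.0, 1e4)], mu_per_gen=1e-8,
                            r_per_gen=1e-8, split_time=1e5)

    def test_cross_tmrca_never_precedes_split(self):
        _, _, cross = simulate_split_pair(self.MODEL, 500_000, seed=10)
        assert (cross.tmrcas >= 1e5).all()

    def test_missing_split_time_rejected(self):
        model = DemographyModel(epochs=[(0.0, 1e4)])
        with pytest.raises(ValueError, match="split_time"):
            simulate_split_pair(model, 1000, seed=0)

    def test_tau_zero_limit_matches_unconstrained_coalescent(self):
        # as tau -> 0 the floored (cross-population) TMRCA distribution
        # reduces to the plain pairwise coalescent: KS distance < 0.02 on
        # 1e4 independent draws against the analytic Exp(1/(2N)) CDF
        model = DemographyModel(epochs=[(0.0, 1e4)], r_per_gen=1e-8)
        draws = np.array([
            sample_pairwise_tmrca(model, 1, seed=s, floor=1e-9).tmrcas[0]
            for s in range(10_000)])
        res = stats.ks_1samp(
            draws, lambda t: 1.0 - np.exp(-np.asarray(t) / 2e4))
        assert res.statistic < 0.02

    def test_cross_het_exceeds_within_het_for_deep_split(self):
        a, b, _ = simulate_split_pair(self.MODEL, 2_000_000, seed=12)
        from psmckit.pseudodiploid import pseudo_diploid
        cross_het = heterozygosity(pseudo_diploid(a, b, 1, 2)).heterozygosity
        assert cross_het > heterozygosity(a).heterozygosity
        assert cross_het > heterozygosity(b).heterozygosity

    def test_pseudo_het_matches_cross_track_expectation(self):
        a, b, cross = simulate_split_pair(self.MODEL, 2_000_000, seed=13)
        from psmckit.pseudodiploid import pseudo_diploid
        expected = float(np.average(-np.expm1(-2e-8 * cross.tmrcas),
                                    weights=cross.lengths))
        got = heterozygosity(pseudo_diploid(a, b, 3, 4)).heterozygosity
        assert got == pytest.approx(expected, rel=0.08)

    def test_bit_reproducible(self):
        a1, b1, c1 = simulate_split_pair(self.MODEL, 300_000, seed=14)
        a2, b2, c2 = simulate_split_pair(self.MODEL, 300_000, seed=14)
        assert a1.contigs == a2.contigs and b1.contigs == b2.contigs
        assert np.array_equal(c1.tmrcas, c2.tmrcas)


class TestQuartetSites:
    def test_invalid_topology_rejected(self):
        qm = QuartetModel(ne=1e4, t12=4e4, t123=6e4, t_out=1e5)
        with pytest.raises(ValueError, match="topology"):
            simulate_quartet_sites(qm, 100, 50, seed=0, topology="((H1,H3),H2)")

    def test_swapping_h1_h2_negates_d_exactly(self):
        from psmckit.dstat import count_patterns, d_statistic
        qm = QuartetModel(ne=1e4, t12=4e4, t123=6e4, t_out=1e5, f=0.3,
                          t_admix=2e4)
        q = simulate_quartet_sites(qm, 50_000, 500, seed=1)
        a, b = count_patterns(q)
        a2, b2 = count_patterns(q.swap_h1_h2())
        assert d_statistic(a, b) == -d_statistic(a2, b2)

    def test_null_counts_binomially_balanced(self):
        from psmckit.dstat import count_patterns
        qm = QuartetModel(ne=1e4, t12=4e4, t123=6e4, t_out=1e5, f=0.0)
        q = simulate_quartet_sites(qm, 100_000, 1000, seed=2)
        a, b = count_patterns(q)
        assert a + b > 0
        assert abs(a - b) < 3 * np.sqrt(a + b)

    def test_every_site_biallelic(self):
        qm = QuartetModel(ne=1e4, t12=4e4, t123=6e4, t_out=1e5)
        q = simulate_quartet_sites(qm, 5000, 100, seed=3)
        n_distinct = np.array([len(set(row)) for row in q.alleles])
        assert (n_distinct <= 2).all() and (n_distinct >= 1).all()

    def test_blocks_assigned_by_coordinate(self):
        qm = QuartetModel(ne=1e4, t12=4e4, t123=6e4, t_out=1e5)
        q = simulate_quartet_sites(qm, 1000, 100, seed=4)
        assert np.array_equal(q.block, q.pos // 100)

    def test_reproducible(self):
        qm = QuartetModel(ne=1e4, t12=4e4, t123=6e4, t_out=1e5, f=0.1,
                          t_admix=2e4)
        q1 = simulate_quartet_sites(qm, 2000, 100, seed=5)
        q2 = simulate_quartet_sites(qm, 2000, 100, seed=5)
        assert np.array_equal(q1.alleles, q2.alleles)
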