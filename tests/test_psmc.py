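"""Unit-level checks of the coalescent HMM: grammar, binning, discretisation,
matrix identities, forward-backward against enumeration, and scaling."""

import itertools
import math

import numpy as np
import pytest

from psmckit.formats import DiploidConsensus, PsmcFasta
from psmckit.psmc import (PSMC, DemographicTrajectory,
                          discretize, divergence_readoff, emission_matrix,
                          interval_quantities, make_psmcfa, parse_pattern,
                          scale, transition_matrix, _forward_backward_py,
                          _forward_backward)


class TestPattern:
    def test_study_pattern_dimensions(self):
        p = parse_pattern("4+25*2+4+6")
        assert p.n_atomic == 64
        assert p.n_free == 28

    def test_single_interval(self):
        p = parse_pattern("1")
        assert (p.n_atomic, p.n_free) == (1, 1)

    def test_star_grammar(self):
        # "2*3" = 2 groups each spanning 3 atomic intervals
        p = parse_pattern("2*3")
        assert (p.n_atomic, p.n_free) == (6, 2)

    def test_group_assignment_order(self):
        g = parse_pattern("2+2*1+3").group_of_atomic()
        assert g.tolist() == [0, 0, 1, 2, 3, 3, 3]

    @pytest.mark.parametrize("bad", ["", "4+", "a*2", "4**2", "0", "3*0", "+4"])
    def test_malformed_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_pattern(bad)

    def test_whitespace_tolerated(self):
        assert parse_pattern("4 + 25 * 2 + 4 + 6").n_atomic == 64

    def test_spec_roundtrip(self):
        p = parse_pattern("4+25*2+4+6")
        assert parse_pattern(p.spec) == p


class TestMakePsmcfa:
    def _cons(self, seq):
        return DiploidConsensus(name="x", contigs=[("c1", seq)])

    def test_all_hom_window_is_T(self):
        assert make_psmcfa(self._cons("A" * 100)).contigs[0][1] == "T"

    def test_single_het_makes_K(self):
        assert make_psmcfa(self._cons("A" * 99 + "R")).contigs[0][1] == "K"

    def test_missing_threshold_strictly_greater(self):
        # 95% missing > 0.9 -> N; exactly 90% missing -> not N
        assert make_psmcfa(self._cons("N" * 95 + "A" * 5)).contigs[0][1] == "N"
        assert make_psmcfa(self._cons("N" * 90 + "A" * 10)).contigs[0][1] == "T"

    def test_partial_final_window_same_rule(self):
        # 20-site partial window, 19/20 = 95% missing -> N despite the het
        seq = "A" * 100 + "N" * 19 + "R"
        assert make_psmcfa(self._cons(seq)).contigs[0][1] == "TN"
        # 10/20 = 50% missing with one het among called -> K
        seq = "A" * 100 + "N" * 10 + "R" + "A" * 9
        assert make_psmcfa(self._cons(seq)).contigs[0][1] == "TK"

    def test_bin_count(self):
        p = make_psmcfa(self._cons("A" * 1001))
        assert len(p.contigs[0][1]) == 11
        assert p.bin_size == 100


class TestDiscretize:
    def test_endpoints(self):
        b = discretize(64, 15.0)
        assert b[0] == 0.0
        assert b[-1] == pytest.approx(15.0, abs=1e-12)

    def test_strictly_increasing(self):
        b = discretize(64, 15.0)
        assert (np.diff(b) > 0).all()

    def test_single_interval(self):
        b = discretize(1, 15.0)
        assert len(b) == 2


class TestHmmMatrices:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_transition_rows_and_prior_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        n = 32
        b = discretize(n, 15.0)
        lam = np.exp(rng.normal(0, 1, n))
        P, prior, tbar = transition_matrix(b, lam, 10 ** rng.uniform(-3, -1))
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-9
        assert prior.sum() == pytest.approx(1.0, abs=1e-12)
        assert (P >= 0).all()

    def test_conditional_mean_within_interval(self):
        b = discretize(16, 15.0)
        _, tbar, _ = interval_quantities(b, np.ones(16))
        assert ((tbar[:-1] > b[:-2]) & (tbar[:-1] < b[1:-1])).all()
        assert tbar[-1] > b[-2]

    def test_emission_rows(self):
        _, tbar, _ = interval_quantities(discretize(8, 15.0), np.ones(8))
        e = emission_matrix(0.05, tbar)
        assert np.allclose(e[0] + e[1], 1.0)
        assert (e[2] == 1.0).all()
        assert (np.diff(e[1]) > 0).all()   # older state, likelier het

    def test_prior_matches_analytic_exponential(self):
        # lambda = 1: P(T in [a,b)) = e^-a - e^-b
        b = discretize(10, 15.0)
        prior, _, _ = interval_quantities(b, np.ones(10))
        expected = np.exp(-b[:-1]) - np.exp(-b[1:])
        expected[-1] = np.exp(-b[-2])   # last interval extends to infinity
        assert np.allclose(prior, expected, atol=1e-12)


class TestForwardBackward:
    def _enumerate(self, obs, P, emis, pi):
        n = P.shape[0]
        tot = 0.0
        gamma = np.zeros((len(obs), n))
        xi = np.zeros((n, n))
        for path in itertools.product(range(n), repeat=len(obs)):
            p = pi[path[0]] * emis[obs[0], path[0]]
            for t in range(1, len(obs)):
                p *= P[path[t - 1], path[t]] * emis[obs[t], path[t]]
            tot += p
            for t, s in enumerate(path):
                gamma[t, s] += p
            for t in range(len(obs) - 1):
                xi[path[t], path[t + 1]] += p
        return math.log(tot), gamma / tot, xi / tot

    def test_reference_matches_enumeration(self):
        rng = np.random.default_rng(1)
        n = 3
        P = rng.random((n, n))
        P /= P.sum(axis=1, keepdims=True)
        pi = rng.random(n)
        pi /= pi.sum()
        emis = rng.random((3, n))
        emis[2] = 1.0
        obs = np.array([0, 1, 0, 2, 1, 0, 0])
        ll, g0, counts, xi, gamma = _forward_backward_py(obs, P, emis, pi)
        ll_e, gamma_e, xi_e = self._enumerate(obs, P, emis, pi)
        assert ll == pytest.approx(ll_e, rel=1e-12)
        assert np.allclose(gamma, gamma_e, atol=1e-12)
        assert np.allclose(xi, xi_e, atol=1e-12)

    def test_posteriors_sum_to_one_per_bin(self):
        rng = np.random.default_rng(2)
        b = discretize(16, 15.0)
        lam = np.exp(rng.normal(0, 0.5, 16))
        P, prior, tbar = transition_matrix(b, lam, 0.01)
        emis = emission_matrix(0.02, tbar)
        obs = rng.integers(0, 3, 500)
        _, _, _, _, gamma = _forward_backward_py(obs, P, emis, prior)
        assert np.abs(gamma.sum(axis=1) - 1).max() < 1e-9

    def test_accelerated_path_matches_reference(self):
        rng = np.random.default_rng(3)
        b = discretize(12, 15.0)
        lam = np.exp(rng.normal(0, 0.5, 12))
        P, prior, tbar = transition_matrix(b, lam, 0.02)
        emis = emission_matrix(0.03, tbar)
        obs = rng.integers(0, 3, 400).astype(np.int64)
        ll_r, g0_r, counts_r, xi_r, _ = _forward_backward_py(obs, P, emis, prior)
        ll_f, g0_f, counts_f, xi_f = _forward_backward(obs, P, emis, prior)
        assert ll_f == pytest.approx(ll_r, rel=1e-10)
        assert np.allclose(g0_f, g0_r, atol=1e-10)
        assert np.allclose(counts_f, counts_r, atol=1e-8)
        assert np.allclose(xi_f, xi_r, atol=1e-8)


class TestEmFit:
    def test_all_missing_input_rejected(self):
        p = PsmcFasta(contigs=[("c1", "N" * 50)], bin_size=100)
        with pytest.raises(ValueError, match="all bins are 'N'"):
            PSMC(p)

    def test_loglik_monotone_on_small_input(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("KTTTTTTTTN"), 3000))
        p = PsmcFasta(contigs=[("c1", seq)], bin_size=100)
        fit = PSMC(p, pattern="4+6*2+4").fit(n_iter=6)
        obj = fit.objective_trace
        assert (np.diff(obj) >= -1e-6 * np.abs(obj[:-1])).all()

    def test_multiple_contigs_supported(self):
        p = PsmcFasta(contigs=[("c1", "KTTTT" * 40), ("c2", "TTTTT" * 40)],
                      bin_size=100)
        fit = PSMC(p, pattern="2+4*2").fit(n_iter=3)
        assert fit.n_bins == 400
        assert math.isfinite(fit.loglik)

    def test_summary_mentions_key_quantities(self):
        p = PsmcFasta(contigs=[("c1", "KTTTT" * 40)], bin_size=100)
        fit = PSMC(p, pattern="2+4*2").fit(n_iter=2)
        s = fit.summary()
        assert "theta" in s and "pattern" in s and "lambda" in s


class TestScale:
    def _results(self, theta, lambdas, n=4, bin_size=100):
        from psmckit.psmc import PsmcResults, parse_pattern
        pattern = parse_pattern(f"{n}*1")
        return PsmcResults(
            theta=theta, rho=theta / 5, lambdas=np.asarray(lambdas),
            lambdas_free=np.asarray(lambdas), boundaries=discretize(n, 15.0),
            pattern=pattern, loglik=-1.0, loglik_trace=np.array([-1.0]),
            bin_size=bin_size, n_bins=100)

    def test_reference_scaling_arithmetic(self):
        # theta=0.004, mu=2e-9/yr, g=5 -> mu_gen=1e-8, N0=1000;
        # a boundary at t=1 maps to 2*N0*g = 10,000 years
        res = self._results(0.004, np.ones(4))
        traj = scale(res, mu_per_year=2e-9, g_years=5.0, s=100)
        assert traj.provenance["N0"] == pytest.approx(1000.0)
        t_of_one = np.interp(1.0, res.boundaries, traj.edges_years)
        assert t_of_one == pytest.approx(10_000.0)

    def test_doubling_mu_halves_ne_and_times(self):
        res = self._results(0.004, [1.0, 2.0, 0.5, 1.0])
        t1 = scale(res, 2e-9, 5.0, 100)
        t2 = scale(res, 4e-9, 5.0, 100)
        assert np.allclose(t2.ne, t1.ne / 2)
        assert np.allclose(t2.edges_years, t1.edges_years / 2)

    def test_flat_lambdas_flat_trajectory(self):
        res = self._results(0.004, np.ones(4))
        traj = scale(res, 2e-9, 5.0, 100)
        assert np.allclose(traj.ne, traj.provenance["N0"])


def _step_traj(edges, ne, mu=2e-9, g=5.0):
    return DemographicTrajectory(
        edges_years=np.asarray(edges, dtype=float),
        ne=np.asarray(ne, dtype=float),
        provenance={"mu_per_year": mu, "g_years": g})


class TestDivergenceReadoff:
    def test_simple_explosion_boundary(self):
        single = _step_traj([0, 100, 200, 400, 800], [1e4] * 4)
        pseudo = _step_traj([0, 100, 200, 400, 800],
                            [5e5, 5e5, 1.2e4, 1.1e4])
        est = divergence_readoff(pseudo, (single, single), c=10.0)
        assert not est.no_signal
        assert est.time_years == 200.0

    def test_no_signal_when_never_exceeding(self):
        single = _step_traj([0, 100, 800], [1e4, 1e4])
        pseudo = _step_traj([0, 100, 800], [5e3, 2e4])
        est = divergence_readoff(pseudo, (single, single), c=10.0)
        assert est.no_signal and est.time_years is None

    def test_gap_in_recent_support_blocks_older_signal(self):
        # the criterion must hold at every step more recent than the estimate
        single = _step_traj([0, 100, 200, 400], [1e4] * 3)
        pseudo = _step_traj([0, 100, 200, 400], [5e5, 1.1e4, 5e5])
        est = divergence_readoff(pseudo, (single, single), c=10.0)
        assert est.time_years == 100.0

    def test_increasing_c_weakly_decreases_estimate(self):
        # a stricter "nearly infinity" multiple can only shorten the run of
        # qualifying recent steps, hence never yields an older estimate
        single = _step_traj([0, 100, 200, 400, 800], [1e4] * 4)
        pseudo = _step_traj([0, 100, 200, 400, 800],
                            [1e6, 3e5, 1.5e5, 1.1e4])
        prev = math.inf
        for c in (2.0, 10.0, 20.0, 40.0):
            est = divergence_readoff(pseudo, (single, single), c=c)
            t = -math.inf if est.no_signal else est.time_years
            assert t <= prev
            prev = t

    def test_mismatched_scaling_rejected(self):
        a = _step_traj([0, 100, 800], [1e4, 1e4], mu=2e-9)
        b = _step_traj([0, 100, 800], [1e4, 1e4], mu=1e-9)
        with pytest.raises(ValueError, match="mu_per_year"):
            divergence_readoff(a, (b, b), c=10.0)
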