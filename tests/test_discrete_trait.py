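import math

import numpy as np
import pytest
from scipy.linalg import expm

from dodder import discrete_trait as dt
from dodder.trees import Phylogeny

from conftest import random_rooted_tree
from oracles import enumeration_loglik, quadrature_model_pp


class TestTransitionMatrix:
    def test_zero_rates_identity(self):
        m = dt.Mk2Model(0.0, 0.0)
        assert np.allclose(dt.transition_matrix(m, 3.0), np.eye(2))

    def test_symmetric_rates_closed_form(self):
        m = dt.Mk2Model(1.0, 1.0)
        P = dt.transition_matrix(m, math.log(2) / 2)
        assert P[0, 0] == pytest.approx(0.75)
        assert P[1, 1] == pytest.approx(0.75)

    def test_irreversible_closed_form(self):
        m = dt.Mk2Model(0.0, 1.0)
        P = dt.transition_matrix(m, 1.0)
        assert P[1, 1] == pytest.approx(math.exp(-1))
        assert P[0, 0] == pytest.approx(1.0)
        assert P[0, 1] == pytest.approx(0.0)

    def test_matches_matrix_exponential(self, rng):
        for _ in range(20):
            g, l = rng.exponential(1.0, size=2)
            t = rng.uniform(0, 3)
            m = dt.Mk2Model(g, l)
            Q = np.array([[-g, g], [l, -l]])
            assert np.allclose(dt.transition_matrix(m, t), expm(Q * t), atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        m = dt.Mk2Model(0.3, 2.1)
        P = dt.transition_matrix(m, 0.7)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            dt.transition_matrix(dt.Mk2Model(1, 1), -0.1)


class TestPruneLoglik:
    def test_single_branch_reduction(self):
        t = Phylogeny.from_newick("(A:0.7);")
        m = dt.Mk2Model(0.0, 1.3, root_prior_present=1.0)
        expected = math.log(dt.transition_matrix(m, 0.7)[1, 1])
        assert dt.prune_loglik(t, {"A": 1}, m) == pytest.approx(expected)

    def test_enumeration_oracle_small_trees(self, rng):
        """Pruning equals brute-force enumeration on trees of 2-5 tips."""
        for _ in range(300):
            n = int(rng.integers(2, 6))
            tree = random_rooted_tree(rng, n)
            g = float(rng.exponential(1.0))
            l = float(rng.exponential(1.0))
            if rng.uniform() < 0.3:
                g = 0.0  # exercise the irreversible branch
            root_p = float(rng.choice([1.0, 0.5, 0.8]))
            m = dt.Mk2Model(g, l, root_prior_present=root_p)
            data = {}
            for lab in tree.tip_labels:
                u = rng.uniform()
                data[lab] = None if u < 0.15 else int(u > 0.5)
            if all(v is None for v in data.values()):
                data[tree.tip_labels[0]] = 1
            a = dt.prune_loglik(tree, data, m)
            b = enumeration_loglik(tree, data, m)
            if math.isinf(a) or math.isinf(b):
                assert a == b
            else:
                assert abs(a - b) < 1e-10

    def test_total_probability_over_patterns(self, four_tip, rng):
        """Likelihoods over all 2^4 tip patterns sum to one."""
        for _ in range(10):
            m = dt.Mk2Model(float(rng.exponential(1)), float(rng.exponential(1)))
            total = 0.0
            for code in range(16):
                data = {lab: (code >> i) & 1 for i, lab in enumerate(four_tip.tip_labels)}
                total += math.exp(dt.prune_loglik(four_tip, data, m))
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_impossible_pattern_gives_neg_inf(self):
        # irreversible, zero loss rate, root fixed present, an absent tip
        t = Phylogeny.from_newick("(A:0.5,B:0.5);")
        m = dt.Mk2Model(0.0, 0.0, root_prior_present=1.0)
        assert dt.prune_loglik(t, {"A": 0, "B": 1}, m) == -math.inf

    def test_all_missing_rejected(self, cherry):
        with pytest.raises(ValueError):
            dt.prune_loglik(cherry, {"A": None, "B": None}, dt.Mk2Model(1, 1))


STRONG_NEWICK = "(((((A:0.1,B:0.1):0.15,C:0.25):0.15,D:0.4):0.2,E:0.6):0.4,F:1.0);"
STRONG_PATTERN = {"A": 1, "B": 0, "C": 0, "D": 0, "E": 0, "F": 1}


class TestRJMCMC:
    def test_seed_reproducibility(self, four_tip):
        data = {"A": 1, "B": 1, "C": 0, "D": 0}
        t1 = dt.rj_mcmc(four_tip, data, generations=300, burn_in=50, chains=2, seed=9)
        t2 = dt.rj_mcmc(four_tip, data, generations=300, burn_in=50, chains=2, seed=9)
        for a, b in zip(t1, t2):
            assert a.samples.equals(b.samples)

    def test_prior_sampling_recovers_prior(self, four_tip):
        """With the likelihood off, the chain reproduces its own priors."""
        prior = dt.RJPrior(expected_transitions=1.0,
                           tree_length=four_tip.index().tree_length)
        traces = dt.rj_mcmc(four_tip, {"A": 1, "B": 1, "C": 0, "D": 0},
                            prior=prior, generations=40_000, burn_in=1000,
                            chains=1, seed=3, prior_only=True)
        model = traces[0].column("model")
        assert abs(model.mean() - 0.5) <= 0.02
        q_loss = traces[0].column("q_loss")
        assert abs(q_loss.mean() - prior.rate_mean) / prior.rate_mean <= 0.05

    def test_posterior_model_prob_trivial_fractions(self, four_tip):
        traces = dt.rj_mcmc(four_tip, {"A": 1, "B": 1, "C": 0, "D": 0},
                            generations=200, burn_in=20, chains=1, seed=1)
        t = traces[0]
        t.samples["model"] = 1.0
        assert dt.posterior_model_prob([t]) == 1.0
        t.samples["model"] = np.tile([0.0, 1.0], 100)
        assert dt.posterior_model_prob([t]) == 0.5

    @pytest.mark.parametrize(
        "pattern,oracle_kwargs",
        [
            ({"A": 1, "B": 1, "C": 0, "D": 0}, {}),
            ({"A": 1, "B": 0, "C": 0, "D": 0}, {}),
        ],
    )
    def test_model_pp_matches_quadrature_four_tip(self, four_tip, pattern, oracle_kwargs):
        tl = four_tip.index().tree_length
        oracle = quadrature_model_pp(four_tip, pattern, rate_mean=1.0 / tl)
        traces = dt.rj_mcmc(four_tip, pattern, generations=6000, burn_in=1000,
                            chains=2, seed=42)
        assert dt.posterior_model_prob(traces) == pytest.approx(oracle, abs=0.03)

    def test_strong_signal_supports_reversibility(self):
        """A present tip nested deep inside an absent clade demands a regain."""
        tree = Phylogeny.from_newick(STRONG_NEWICK)
        traces = dt.rj_mcmc(tree, STRONG_PATTERN, generations=4000, burn_in=800,
                            chains=2, seed=11)
        assert dt.posterior_model_prob(traces) > 0.9

    def test_all_present_shrinks_loss_rate(self, fixture_tree):
        """With every tip present the loss-rate posterior sits below its prior."""
        data = {lab: 1 for lab in fixture_tree.tip_labels}
        prior = dt.RJPrior(expected_transitions=1.0,
                           tree_length=fixture_tree.index().tree_length)
        traces = dt.rj_mcmc(fixture_tree, data, prior=prior, generations=4000,
                            burn_in=800, chains=2, seed=5)
        pooled = np.concatenate([t.column("q_loss") for t in traces])
        assert pooled.mean() < prior.rate_mean
        pp = dt.posterior_model_prob(traces)
        assert 0.2 < pp < 0.8  # no strong preference for either model

    def test_all_missing_rejected(self, cherry):
        with pytest.raises(ValueError):
            dt.rj_mcmc(cherry, {"A": None, "B": None}, generations=100,
                       burn_in=10, chains=1, seed=0)


class TestAncestralStates:
    def test_root_fixed_present(self, four_tip):
        traces = dt.rj_mcmc(four_tip, {"A": 1, "B": 1, "C": 0, "D": 0},
                            generations=1000, burn_in=100, chains=1, seed=2)
        pp = dt.ancestral_state_map(traces, four_tip)
        root = four_tip.index().root
        assert pp[root] == 1.0

    def test_probabilities_are_probabilities(self, four_tip):
        traces = dt.rj_mcmc(four_tip, {"A": 1, "B": 0, "C": 1, "D": 0},
                            generations=1000, burn_in=100, chains=2, seed=8)
        pp = dt.ancestral_state_map(traces, four_tip)
        assert all(0.0 <= v <= 1.0 for v in pp.values())

    def test_cherry_of_present_tips_with_tiny_rates(self):
        tree = Phylogeny.from_newick("((A:0.05,B:0.05):0.95,C:1.0);")
        traces = dt.rj_mcmc(tree, {"A": 1, "B": 1, "C": 1},
                            generations=3000, burn_in=500, chains=1, seed=4)
        pp = dt.ancestral_state_map(traces, tree)
        mrca_ab = tree.index().mrca(["A", "B"])
        assert pp[mrca_ab] > 0.99

    def test_parent_tracks_tip_as_branch_shrinks(self):
        """With a near-zero subtending branch the parent's posterior
        converges to the observed tip state."""
        tree = Phylogeny.from_newick("((A:1e-6,B:1.0):0.5,C:1.5);")
        traces = dt.rj_mcmc(tree, {"A": 0, "B": 1, "C": 1},
                            generations=3000, burn_in=500, chains=1, seed=6)
        pp = dt.ancestral_state_map(traces, tree)
        parent = tree.index().mrca(["A", "B"])
        assert pp[parent] < 0.02

    def test_missing_tip_state_is_sampled(self, fixture_tree, neo_states):
        traces = dt.rj_mcmc(fixture_tree, neo_states, generations=500,
                            burn_in=100, chains=1, seed=7)
        pp = dt.ancestral_state_map(traces, fixture_tree)
        africana = fixture_tree.index().tip_index("Cuscuta_africana")
        assert africana in pp


class TestSensitivityScan:
    def test_single_prior_equals_one_run(self, four_tip):
        data = {"A": 1, "B": 1, "C": 0, "D": 0}
        scan = dt.sensitivity_scan(four_tip, data, expected_transitions=[1],
                                   generations=500, burn_in=100, chains=1, seed=13)
        prior = dt.RJPrior(expected_transitions=1,
                           tree_length=four_tip.index().tree_length)
        direct = dt.rj_mcmc(four_tip, data, prior=prior, generations=500,
                            burn_in=100, chains=1, seed=13)
        assert scan.loc[0, "p_reversible"] == pytest.approx(
            dt.posterior_model_prob(direct)
        )
        assert not scan.loc[0, "map_changed"]

    def test_scan_reports_per_prior_rows(self, four_tip):
        scan = dt.sensitivity_scan(four_tip, {"A": 1, "B": 1, "C": 0, "D": 0},
                                   expected_transitions=[1, 10],
                                   generations=800, burn_in=200, chains=1, seed=14)
        assert len(scan) == 2
        assert {"expected_transitions", "p_reversible", "map_changed"} <= set(scan.columns)

    def test_empty_prior_list_rejected(self, four_tip):
        with pytest.raises(ValueError):
            dt.sensitivity_scan(four_tip, {"A": 1, "B": 0, "C": 0, "D": 0},
                                expected_transitions=[])
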