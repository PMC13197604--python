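import math

import numpy as np
import pandas as pd
import pytest

from dodder import bm_corr as bm
from dodder import synthetic
from dodder.trees import Phylogeny

from conftest import random_rooted_tree
from oracles import dense_bm_loglik


def _random_theta(rng):
    return bm.BMParams(
        sigma2_x=float(rng.uniform(0.2, 3.0)),
        sigma2_y=float(rng.uniform(0.2, 3.0)),
        r=float(rng.uniform(-0.95, 0.95)),
        root_x=float(rng.normal()),
        root_y=float(rng.normal()),
    )


class TestLoglik:
    def test_dense_mvn_oracle_small_trees(self, rng):
        """Matrix-normal factorization equals the dense 2n x 2n density."""
        for _ in range(200):
            n = int(rng.integers(3, 6))
            tree = random_rooted_tree(rng, n)
            theta = _random_theta(rng)
            values = {lab: (float(rng.normal()), float(rng.normal()))
                      for lab in tree.tip_labels}
            data = bm.ContinuousPairData(values)
            assert bm.bm_loglik(tree, data, theta) == pytest.approx(
                dense_bm_loglik(tree, data, theta), abs=1e-8
            )

    def test_star_tree_reduces_to_iid_bivariate_normal(self, rng):
        n = 6
        nwk = "(" + ",".join(f"t{i}:1.0" for i in range(n)) + ");"
        tree = Phylogeny.from_newick(nwk)
        theta = _random_theta(rng)
        values = {f"t{i}": (float(rng.normal()), float(rng.normal())) for i in range(n)}
        data = bm.ContinuousPairData(values)
        from scipy.stats import multivariate_normal

        mean = np.array([theta.root_x, theta.root_y])
        iid = sum(
            multivariate_normal.logpdf(np.array(values[f"t{i}"]), mean, theta.R)
            for i in range(n)
        )
        assert bm.bm_loglik(tree, data, theta) == pytest.approx(iid, abs=1e-8)

    def test_zero_correlation_factorizes(self, three_tip, rng):
        theta = bm.BMParams(1.7, 0.4, 0.0, 0.3, -0.2)
        values = {lab: (float(rng.normal()), float(rng.normal()))
                  for lab in three_tip.tip_labels}
        data = bm.ContinuousPairData(values)
        joint = bm.bm_loglik(three_tip, data, theta)
        from scipy.stats import multivariate_normal

        C = bm.phylo_covariance(three_tip, data.taxa)
        X = data.matrix(data.taxa)
        lx = multivariate_normal.logpdf(X[:, 0], np.full(3, theta.root_x), theta.sigma2_x * C)
        ly = multivariate_normal.logpdf(X[:, 1], np.full(3, theta.root_y), theta.sigma2_y * C)
        assert joint == pytest.approx(lx + ly, abs=1e-10)

    def test_invariant_to_tip_order(self, rng):
        tree = random_rooted_tree(rng, 5)
        theta = _random_theta(rng)
        values = {lab: (float(rng.normal()), float(rng.normal()))
                  for lab in tree.tip_labels}
        a = bm.bm_loglik(tree, bm.ContinuousPairData(dict(values)), theta)
        shuffled = dict(reversed(list(values.items())))
        b = bm.bm_loglik(tree, bm.ContinuousPairData(shuffled), theta)
        assert a == pytest.approx(b, abs=1e-10)

    def test_extra_tree_tips_dropped(self, fixture_tree, rng):
        values = {lab: (float(rng.normal()), float(rng.normal()))
                  for lab in fixture_tree.tip_labels[:6]}
        data = bm.ContinuousPairData(values)
        assert np.isfinite(bm.bm_loglik(fixture_tree, data, _random_theta(rng)))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            bm.BMParams(1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            bm.BMParams(0.0, 1.0, 0.5)

    def test_too_few_tips_rejected(self, cherry):
        data = bm.ContinuousPairData({"A": (0, 0), "B": (1, 1)})
        with pytest.raises(ValueError):
            bm.bm_loglik(cherry, data, bm.BMParams(1, 1, 0.0))


class TestMCMC:
    def test_seed_reproducibility(self, fixture_tree):
        data = synthetic.simulate_bm_pair(fixture_tree, bm.BMParams(1, 1, 0.5), seed=2)
        a = bm.bm_mcmc(fixture_tree, data, generations=300, chains=2, burn_in=50, seed=21)
        b = bm.bm_mcmc(fixture_tree, data, generations=300, chains=2, burn_in=50, seed=21)
        for x, y in zip(a, b):
            assert x.samples.equals(y.samples)

    def test_prior_only_r_symmetric(self, fixture_tree):
        """Under the prior alone P[r > 0] = 0.5, validating prior odds 1."""
        data = synthetic.simulate_bm_pair(fixture_tree, bm.BMParams(1, 1, 0.5), seed=3)
        traces = bm.bm_mcmc(fixture_tree, data, generations=20_000, chains=1,
                            burn_in=1000, seed=17, prior_only=True)
        r = traces[0].column("r")
        assert abs((r > 0).mean() - 0.5) <= 0.02
        bf = bm.bayes_factor_positive(traces)
        assert 0.8 <= bf.bf <= 1.25


class TestBayesFactors:
    def _trace_with_r(self, r_values):
        from dodder.mcmc_core import PosteriorTrace

        return PosteriorTrace(pd.DataFrame({"r": np.asarray(r_values, float)}))

    def test_even_split_is_bf_one(self):
        t = self._trace_with_r([-1, 1] * 50)
        bf = bm.bayes_factor_positive(t)
        assert bf.bf == pytest.approx(1.0)
        assert bf.two_ln_bf == pytest.approx(0.0)

    def test_ninety_percent_positive(self):
        t = self._trace_with_r([1.0] * 90 + [-1.0] * 10)
        bf = bm.bayes_factor_positive(t)
        assert bf.bf == pytest.approx(9.0)
        assert bf.two_ln_bf == pytest.approx(2 * math.log(9), abs=1e-12)

    def test_saturated_continuity_rule(self):
        m = 200
        t = self._trace_with_r([0.5] * m)
        bf = bm.bayes_factor_positive(t)
        assert bf.saturated
        assert bf.bf == pytest.approx((m - 0.5) / 0.5)

    def test_positive_negative_reciprocal(self):
        t = self._trace_with_r([1.0] * 70 + [-1.0] * 30)
        pos = bm.bayes_factor_positive(t)
        neg = bm.bayes_factor_negative(t)
        assert pos.bf * neg.bf == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "value,tier",
        [(0.0, "n.s."), (2.0, "n.s."), (4.394, "*"), (6.0, "*"),
         (8.0, "***"), (-8.0, "***"), (12.0, "***"), (-4.0, "*")],
    )
    def test_tier_thresholds(self, value, tier):
        assert bm.significance_tier(value) == tier


class TestSuite:
    def _traits(self, tree, rng, stages=("sdlg", "y"), strong_stage="y"):
        rows = []
        taxa = [t for t in tree.tip_labels if t != "Ipomoea_nil"]
        for stage in stages:
            r = 0.95 if stage == strong_stage else 0.0
            import zlib

            data = synthetic.simulate_bm_pair(
                tree, bm.BMParams(1.0, 1.0, r), seed=zlib.crc32(stage.encode()) % 2**31,
                stage=stage,
            )
            for taxon in taxa:
                x, y = data.values[taxon]
                rows.append({"taxon": taxon, "stage": stage, "trait": "lutein_epoxide", "value": x})
                rows.append({"taxon": taxon, "stage": stage, "trait": "phi_psii", "value": y})
        return pd.DataFrame(rows)

    def test_shape_one_row_per_stage_pair(self, fixture_tree, rng):
        traits = self._traits(fixture_tree, rng)
        out = bm.stage_correlation_suite(
            fixture_tree, traits, stages=["sdlg", "y"],
            pairs=[("lutein_epoxide", "phi_psii")],
            generations=800, chains=1, burn_in=200, seed=1,
        )
        assert len(out) == 2
        assert set(out["stage"]) == {"sdlg", "y"}

    def test_small_stage_flagged_not_estimable_or_caution(self, fixture_tree):
        rows = [
            {"taxon": t, "stage": "sd", "trait": tr, "value": v}
            for t, v in [("Cuscuta_australis", 1.0), ("Cuscuta_cephalanthi", 2.0),
                         ("Cuscuta_polygonorum", 3.0)]
            for tr, v in [("lutein_epoxide", v), ("phi_psii", v + 0.5)]
        ]
        out = bm.stage_correlation_suite(
            fixture_tree, pd.DataFrame(rows), stages=["sd"],
            pairs=[("lutein_epoxide", "phi_psii")],
            generations=500, chains=1, burn_in=100, seed=2,
        )
        row = out.iloc[0]
        assert row["n_taxa"] == 3
        assert row["caution"]  # three-species stage: interpret with care

    def test_under_three_taxa_not_estimable(self, fixture_tree):
        rows = [
            {"taxon": "Cuscuta_australis", "stage": "f", "trait": "lutein_epoxide", "value": 1.0},
            {"taxon": "Cuscuta_australis", "stage": "f", "trait": "phi_psii", "value": 2.0},
        ]
        out = bm.stage_correlation_suite(
            fixture_tree, pd.DataFrame(rows), stages=["f"],
            pairs=[("lutein_epoxide", "phi_psii")],
            generations=500, chains=1, burn_in=100, seed=3,
        )
        assert not out.iloc[0]["estimable"]

    def test_excluded_taxa_are_dropped(self, fixture_tree, rng):
        traits = self._traits(fixture_tree, rng, stages=("y",))
        out = bm.stage_correlation_suite(
            fixture_tree, traits, stages=["y"],
            pairs=[("lutein_epoxide", "phi_psii")],
            exclude=["Cuscuta_sandwichiana"],
            generations=500, chains=1, burn_in=100, seed=4,
        )
        assert out.iloc[0]["n_taxa"] == 14  # 16 - outgroup(no data) - hybrid

    def test_planted_stage_specific_correlation_detected(self, fixture_tree, rng):
        traits = self._traits(fixture_tree, rng, stages=("sdlg", "y"), strong_stage="y")
        out = bm.stage_correlation_suite(
            fixture_tree, traits, stages=["sdlg", "y"],
            pairs=[("lutein_epoxide", "phi_psii")],
            exclude=["Cuscuta_sandwichiana"],
            generations=4000, chains=1, burn_in=800, seed=5,
        ).set_index("stage")
        assert out.loc["y", "tier"] != "n.s."
        assert out.loc["y", "r_mean"] > 0.3
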