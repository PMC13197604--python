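"""Independent oracles used by the test suite.

These deliberately avoid the package's pruning/MCMC code paths: brute-force
enumeration over interior states, dense multivariate-normal densities, and
numerical quadrature over the rate priors.
"""

import itertools
import math

import numpy as np
from scipy import integrate
from scipy.stats import multivariate_normal

from dodder.discrete_trait import Mk2Model, transition_matrix


def enumeration_loglik(tree, data, m: Mk2Model) -> float:
    """Sum over all interior-state assignments of the joint probability."""
    idx = tree.index()
    interior = [i for i in range(idx.n_nodes) if idx.children[i]]
    P = {}
    for i in range(idx.n_nodes):
        if idx.parent[i] >= 0:
            P[i] = transition_matrix(m, idx.edge_length[i])
    tip_sets = {}
    for i, lab in enumerate(idx.tip_labels):
        s = data.get(lab)
        tip_sets[i] = [0, 1] if s is None else [int(s)]
    pi = [1.0 - m.root_prior_present, m.root_prior_present]
    total = 0.0
    tip_ids = list(range(idx.n_tips))
    for interior_states in itertools.product([0, 1], repeat=len(interior)):
        assign = dict(zip(interior, interior_states))
        for tip_states in itertools.product(*[tip_sets[i] for i in tip_ids]):
            assign.update(dict(zip(tip_ids, tip_states)))
            prob = pi[assign[idx.root]]
            for i in range(idx.n_nodes):
                p = idx.parent[i]
                if p >= 0:
                    prob *= P[i][assign[p], assign[i]]
            total += prob
    return math.log(total) if total > 0 else -math.inf


def quadrature_model_pp(tree, data, rate_mean: float, p_reversible: float = 0.5,
                        root_prior_present: float = 1.0) -> float:
    """Posterior probability of the reversible model by direct integration
    of the two marginal likelihoods over the exponential rate priors."""
    from dodder.discrete_trait import prune_loglik

    def lik_irr(q):
        m = Mk2Model(0.0, q, root_prior_present)
        return math.exp(prune_loglik(tree, data, m)) * math.exp(-q / rate_mean) / rate_mean

    def lik_rev(g, q):
        m = Mk2Model(g, q, root_prior_present)
        return (
            math.exp(prune_loglik(tree, data, m))
            * math.exp(-q / rate_mean) / rate_mean
            * math.exp(-g / rate_mean) / rate_mean
        )

    upper = 40.0 * rate_mean
    m_irr, _ = integrate.quad(lik_irr, 0, upper, limit=200)
    m_rev, _ = integrate.dblquad(lik_rev, 0, upper, 0, upper)
    return p_reversible * m_rev / (p_reversible * m_rev + (1 - p_reversible) * m_irr)


def dense_bm_loglik(tree, data, theta) -> float:
    """2n x 2n multivariate normal density with covariance R kron C."""
    from dodder.bm_corr import phylo_covariance

    taxa = data.taxa
    keep = set(taxa)
    pruned = tree.drop_tips([t for t in tree.tip_labels if t not in keep])
    C = phylo_covariance(pruned, taxa)
    X = data.matrix(taxa)
    y = np.concatenate([X[:, 0], X[:, 1]])
    mean = np.concatenate(
        [np.full(len(taxa), theta.root_x), np.full(len(taxa), theta.root_y)]
    )
    return float(multivariate_normal.logpdf(y, mean, np.kron(theta.R, C)))
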