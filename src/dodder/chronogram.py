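"""Penalized-likelihood ultrametricization with correlated rates.

Converts a substitution-scaled phylogram into a relative-time chronogram
(root age 1, tips at 0).  Each branch i carries a rate r_i and a duration
tau_i; the observed branch length is modelled as a Poisson pseudo-count
``B_i = length_i * nsites`` with mean ``r_i * tau_i``, and rate variation is
smoothed by a correlated-rates roughness penalty:

    maximize  sum_i [ B_i log(r_i tau_i) - r_i tau_i ]
              - lambda * [ sum_{parent-child branch pairs} (r_i - r_j)^2
                           + Var(rates of root-adjacent branches) ]

over log-rates and node ages (ages parameterized as fractions of the parent
age, so the topology's ordering constraints hold by construction).  This is
the classic semiparametric rate-smoothing formulation used for dating in the
absence of fossil calibrations; only relative times are identifiable, hence
the fixed root age of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from dodder.trees import IndexedTree, Phylogeny, is_ultrametric

__all__ = ["RateAssignment", "pl_ultrametricize", "is_ultrametric"]


@dataclass
class RateAssignment:
    """Optimized rates and ages; node indexing follows ``Phylogeny.index()``."""

    rates: np.ndarray            # per-node (branch above), nan for root
    ages: np.ndarray             # per-node, root = 1, tips = 0
    objective: float
    objective_path: np.ndarray   # objective at each accepted optimizer iterate
    converged: bool
    n_iter: int


def _free_internal_nodes(idx: IndexedTree) -> list[int]:
    root = idx.root
    return [
        int(n)
        for n in idx.postorder
        if idx.children[int(n)] and int(n) != root
    ]


def _ages_from_fractions(idx: IndexedTree, free: list[int], frac: np.ndarray) -> np.ndarray:
    ages = np.zeros(idx.n_nodes)
    ages[idx.root] = 1.0
    fmap = dict(zip(free, frac))
    for n in idx.postorder[::-1]:  # preorder
        n = int(n)
        if n == idx.root or not idx.children[n]:
            continue
        ages[n] = ages[idx.parent[n]] * fmap[n]
    return ages


def _objective(idx: IndexedTree, B: np.ndarray, lam: float, nsites: float,
               free: list[int],
               branch_nodes: np.ndarray, pairs: list[tuple[int, int]],
               root_children: list[int], params: np.ndarray) -> float:
    k = len(branch_nodes)
    r = np.exp(np.clip(params[:k], -40.0, 40.0))
    frac = expit(params[k:])
    ages = _ages_from_fractions(idx, free, frac)
    tau = ages[idx.parent[branch_nodes]] - ages[branch_nodes]
    # Poisson pseudo-counts b = length * nsites with exposure r * tau * nsites
    mu = r * tau * nsites
    b = B[branch_nodes]
    with np.errstate(divide="ignore"):
        log_mu = np.where(b > 0, np.log(np.maximum(mu, 1e-300)), 0.0)
    loglik = float(np.sum(b * log_mu - mu))
    if not np.isfinite(loglik):
        return -1e300
    rate_of = dict(zip(branch_nodes.tolist(), r))
    rough = sum((rate_of[i] - rate_of[j]) ** 2 for i, j in pairs)
    root_rates = np.array([rate_of[c] for c in root_children])
    rough += float(np.var(root_rates))
    return loglik - lam * rough


def pl_ultrametricize(
    tree: Phylogeny,
    lam: float = 1.0,
    nsites: float = 1000.0,
    max_iter: int = 2000,
) -> tuple[Phylogeny, RateAssignment]:
    """Fit the correlated-rates penalized likelihood and return the chronogram.

    ``lam`` is the smoothing weight (larger -> more clock-like; as
    lam -> inf all rates coincide), ``nsites`` the pseudo-count scale that
    converts branch lengths into Poisson counts.  Neither changes the root
    age, which is always 1 (relative time).  Raises on non-convergence.
    """
    idx = tree.index()
    if idx.n_tips < 2:
        raise ValueError("need at least 2 tips to ultrametricize")
    B = idx.edge_length * nsites
    root = idx.root
    branch_nodes = np.array([n for n in range(idx.n_nodes) if n != root])
    free = _free_internal_nodes(idx)
    pairs = [
        (n, c)
        for n in range(idx.n_nodes)
        if n != root
        for c in idx.children[n]
    ]
    root_children = list(idx.children[root])

    # Initialization: ages proportional to mean root-to-tip depth below each
    # node (UPGMA-like), one global clock rate.
    depth = idx.node_depths()
    mean_below = np.zeros(idx.n_nodes)
    count_below = np.zeros(idx.n_nodes)
    for n in idx.postorder:
        n = int(n)
        if not idx.children[n]:
            mean_below[n], count_below[n] = depth[n], 1.0
        else:
            count_below[n] = sum(count_below[c] for c in idx.children[n])
            mean_below[n] = sum(mean_below[c] for c in idx.children[n])
    with np.errstate(invalid="ignore"):
        mean_below = mean_below / count_below
    total_depth = max(float(mean_below[root]), 1e-12)
    # age estimate: mean path length remaining below the node, rescaled so
    # the root sits at 1
    age0 = np.clip((mean_below - depth), 1e-6, None) / total_depth
    age0 = np.clip(age0, 1e-4, 1.0)
    frac0 = []
    for n in free:
        p = idx.parent[n]
        parent_age = age0[p] if p != root else 1.0
        frac0.append(np.clip(age0[n] / max(parent_age, 1e-6), 0.02, 0.98))
    ages_init = _ages_from_fractions(idx, free, np.asarray(frac0))
    dur_init = ages_init[idx.parent[branch_nodes]] - ages_init[branch_nodes]
    global_rate = max(idx.tree_length / max(float(dur_init.sum()), 1e-8), 1e-8)
    x0 = np.concatenate([np.log(np.full(len(branch_nodes), global_rate)),
                         logit(np.asarray(frac0))])

    path: list[float] = []

    def negobj(x):
        return -_objective(idx, B, lam, nsites, free, branch_nodes, pairs,
                           root_children, x)

    def cb(xk):
        path.append(-negobj(xk))

    res = minimize(negobj, x0, method="L-BFGS-B", callback=cb,
                   options={"maxiter": max_iter, "maxfun": 10 * max_iter * max(len(x0), 10)})
    if not res.success and abs(res.fun) > 1e12:
        raise RuntimeError(f"penalized-likelihood dating failed: {res.message}")

    k = len(branch_nodes)
    rates_vec = np.exp(res.x[:k])
    ages = _ages_from_fractions(idx, free, expit(res.x[k:]))
    rates = np.full(idx.n_nodes, np.nan)
    rates[branch_nodes] = rates_vec
    assignment = RateAssignment(
        rates=rates,
        ages=ages,
        objective=float(-res.fun),
        objective_path=np.asarray(path),
        converged=bool(res.success),
        n_iter=int(res.nit),
    )

    # Write durations back onto a clone; index() iteration order is stable
    # across clones, so positional mapping is safe.
    out = tree.clone()
    out_idx_nodes = list(out.dendropy_tree.leaf_node_iter()) + [
        n for n in out.dendropy_tree.preorder_node_iter() if not n.is_leaf()
    ]
    for i, node in enumerate(out_idx_nodes):
        if node.parent_node is None:
            continue
        node.edge.length = float(ages[idx.parent[i]] - ages[i])
    return out, assignment
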