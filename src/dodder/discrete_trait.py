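"""Reversible-jump test of irreversible (Dollo-style) trait loss.

A binary character (neoxanthin production: 0 = absent, 1 = present
throughout) evolves along an ultrametric phylogeny under a two-state
continuous-time Markov chain.  Two models compete:

- **irreversible** ("Dollo"): gain rate fixed to zero — once lost, the
  trait is never regained;
- **reversible**: both the loss rate and the gain rate are free, each under
  an exponential prior whose mean corresponds to a chosen expected number of
  transitions over the whole tree (rate mean = expected / tree length).

A reversible-jump MCMC moves between the two models (the posterior
frequency of each is its posterior probability) while sampling rates, and
draws one joint ancestral reconstruction per generation by backward
sampling from the pruning partials, so node posteriors are automatically
model-averaged.  The root state is fixed to "present" by default, which
makes the model comparison fair: the irreversible model is only
disadvantaged by the data, not by the root assumption.

Missing tips (taxa in the tree without phenotype data) enter the pruning
with partial likelihood (1, 1) and their states are sampled alongside the
interior nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from dodder.mcmc_core import PosteriorTrace, combine_chains, ess
from dodder.trees import IndexedTree, Phylogeny

__all__ = [
    "Mk2Model",
    "RJPrior",
    "transition_matrix",
    "prune_loglik",
    "rj_mcmc",
    "posterior_model_prob",
    "ancestral_state_map",
    "sensitivity_scan",
    "read_trait_csv",
]

ABSENT, PRESENT = 0, 1


@dataclass(frozen=True)
class Mk2Model:
    """Two-state CTMC: q_gain (0->1) and q_loss (1->0) per unit tree time."""

    q_gain: float
    q_loss: float
    root_prior_present: float = 1.0

    def __post_init__(self):
        if self.q_gain < 0 or self.q_loss < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.root_prior_present <= 1:
            raise ValueError("root prior must be a probability")

    @property
    def irreversible(self) -> bool:
        return self.q_gain == 0.0


@dataclass(frozen=True)
class RJPrior:
    """Priors of the reversible-jump analysis.

    ``expected_transitions`` sets the exponential prior mean on each free
    rate via mean = expected_transitions / tree_length, i.e. "n expected
    character changes over the whole tree".  ``p_reversible`` is the prior
    probability of the reversible model.
    """

    expected_transitions: float = 1.0
    tree_length: float = 1.0
    p_reversible: float = 0.5

    def __post_init__(self):
        if self.expected_transitions <= 0 or self.tree_length <= 0:
            raise ValueError("expected transitions and tree length must be > 0")
        if not 0 < self.p_reversible < 1:
            raise ValueError("model prior must be in (0, 1)")

    @property
    def rate_mean(self) -> float:
        return self.expected_transitions / self.tree_length


def transition_matrix(m: Mk2Model, t: float) -> np.ndarray:
    """Closed-form 2x2 transition probabilities over duration t.

    ``P00(t) = (q_loss + q_gain e^{-(q_gain+q_loss) t}) / (q_gain+q_loss)``
    etc.; for both rates zero the matrix is the identity, and for the
    irreversible model ``P11(t) = e^{-q_loss t}`` with state 0 absorbing.
    """
    if t < 0:
        raise ValueError("duration must be non-negative")
    g, l = m.q_gain, m.q_loss
    q = g + l
    if q == 0:
        return np.eye(2)
    e = np.exp(-q * t)
    return np.array(
        [
            [(l + g * e) / q, g * (1 - e) / q],
            [l * (1 - e) / q, (g + l * e) / q],
        ]
    )


def _tip_partials(idx: IndexedTree, data: Mapping[str, Optional[int]]) -> np.ndarray:
    L = np.ones((idx.n_nodes, 2))
    n_obs = 0
    for i, lab in enumerate(idx.tip_labels):
        state = data.get(lab)
        if state is None or (isinstance(state, float) and np.isnan(state)):
            continue  # missing: partial (1, 1)
        if state not in (ABSENT, PRESENT):
            raise ValueError(f"state for {lab!r} must be 0, 1 or missing")
        L[i] = 0.0
        L[i, int(state)] = 1.0
        n_obs += 1
    if n_obs == 0:
        raise ValueError("all tip states missing")
    return L


def _pruning_pass(idx: IndexedTree, L_tips: np.ndarray, m: Mk2Model):
    """Postorder partials and per-branch transition matrices."""
    L = L_tips.copy()
    P = np.empty((idx.n_nodes, 2, 2))
    for i in range(idx.n_nodes):
        if idx.parent[i] >= 0:
            P[i] = transition_matrix(m, idx.edge_length[i])
    for n in idx.postorder:
        n = int(n)
        if not idx.children[n]:
            continue
        for c in idx.children[n]:
            L[n] *= P[c] @ L[c]
    return L, P


def prune_loglik(tree: Phylogeny | IndexedTree, data: Mapping, m: Mk2Model) -> float:
    """Felsenstein-pruned log-likelihood of the tip pattern.

    Zero-probability configurations (e.g. an absent-then-present pattern
    under the irreversible model with a fixed present root and zero gain)
    return -inf rather than raising.
    """
    idx = tree.index() if isinstance(tree, Phylogeny) else tree
    L_tips = _tip_partials(idx, data)
    L, _ = _pruning_pass(idx, L_tips, m)
    pi = np.array([1.0 - m.root_prior_present, m.root_prior_present])
    lik = float(pi @ L[idx.root])
    return np.log(lik) if lik > 0 else -np.inf


def _sample_states(idx: IndexedTree, L: np.ndarray, P: np.ndarray,
                   m: Mk2Model, sampled_nodes: Sequence[int],
                   rng: np.random.Generator) -> np.ndarray:
    """Joint backward draw of node states given tips and current rates."""
    pi = np.array([1.0 - m.root_prior_present, m.root_prior_present])
    states = np.full(idx.n_nodes, -1, dtype=int)
    w = pi * L[idx.root]
    states[idx.root] = rng.choice(2, p=w / w.sum())
    for n in idx.postorder[::-1]:  # preorder
        n = int(n)
        for c in idx.children[n]:
            w = P[c][states[n]] * L[c]
            states[c] = rng.choice(2, p=w / w.sum())
    return states[list(sampled_nodes)]


def _sampled_nodes(idx: IndexedTree, data: Mapping) -> list[int]:
    """Interior nodes plus data-missing tips, in index order."""
    missing_tips = [
        i for i, lab in enumerate(idx.tip_labels)
        if data.get(lab) is None
        or (isinstance(data.get(lab), float) and np.isnan(data[lab]))
    ]
    interior = [i for i in range(idx.n_nodes) if idx.children[i]]
    return sorted(missing_tips + interior)


def rj_mcmc(
    tree: Phylogeny,
    data: Mapping[str, Optional[int]],
    prior: RJPrior | None = None,
    generations: int = 5000,
    burn_in: int = 1000,
    chains: int = 4,
    seed: int = 0,
    root_prior_present: float = 1.0,
    window: float = 2.0,
    prior_only: bool = False,
    ess_floor: float = 650.0,
) -> list[PosteriorTrace]:
    """Reversible-jump MCMC between irreversible and reversible Mk2 models.

    One move per generation: with probability 0.5 a model flip (an
    independence birth/death of q_gain drawn from its exponential prior, so
    the Hastings ratio reduces to likelihood ratio times model-prior odds),
    otherwise a multiplicative sliding-window update of one free rate.  One
    joint ancestral reconstruction is recorded per generation.

    Returns one trace per chain with columns ``model`` (1 = reversible),
    ``q_gain``, ``q_loss``, ``loglik``, and ``state_<i>`` for every interior
    node and data-missing tip (node indices follow ``tree.index()``;
    0 = absent, 1 = present).  ``prior_only`` switches the likelihood off
    (for prior-recovery validation).  A post-run ESS of q_loss below
    ``ess_floor`` is recorded as a warning in the trace metadata.
    """
    idx = tree.index()
    if prior is None:
        prior = RJPrior(tree_length=idx.tree_length)
    L_tips = _tip_partials(idx, data)
    nodes = _sampled_nodes(idx, data)
    mu = prior.rate_mean
    log_odds_rev = np.log(prior.p_reversible / (1 - prior.p_reversible))

    def loglik(m: Mk2Model) -> tuple[float, np.ndarray, np.ndarray]:
        L, P = _pruning_pass(idx, L_tips, m)
        if prior_only:
            return 0.0, L, P
        pi = np.array([1.0 - m.root_prior_present, m.root_prior_present])
        lik = float(pi @ L[idx.root])
        return (np.log(lik) if lik > 0 else -np.inf), L, P

    traces = []
    root_ss = np.random.SeedSequence(entropy=seed)
    for chain, child_ss in enumerate(root_ss.spawn(chains)):
        rng = np.random.default_rng(child_ss)
        model = Mk2Model(0.0, rng.exponential(mu), root_prior_present)
        ll, L, P = loglik(model)
        if not np.isfinite(ll):  # fall back to a state with support
            model = Mk2Model(rng.exponential(mu), model.q_loss, root_prior_present)
            ll, L, P = loglik(model)
        rows = np.empty((generations, 4 + len(nodes)))
        for gen in range(generations):
            if rng.uniform() < 0.5:
                # dimension jump
                if model.irreversible:
                    cand = Mk2Model(rng.exponential(mu), model.q_loss, root_prior_present)
                    ll_c, L_c, P_c = loglik(cand)
                    log_alpha = ll_c - ll + log_odds_rev
                else:
                    cand = Mk2Model(0.0, model.q_loss, root_prior_present)
                    ll_c, L_c, P_c = loglik(cand)
                    log_alpha = ll_c - ll - log_odds_rev
            else:
                # multiplicative rate update on one free rate
                which = "q_loss" if model.irreversible or rng.uniform() < 0.5 else "q_gain"
                old = getattr(model, which)
                new = old * np.exp(window * (rng.uniform() - 0.5))
                kw = {"q_gain": model.q_gain, "q_loss": model.q_loss,
                      "root_prior_present": root_prior_present}
                kw[which] = new
                cand = Mk2Model(**kw)
                ll_c, L_c, P_c = loglik(cand)
                log_prior_ratio = -(new - old) / mu
                log_hastings = np.log(new / old)
                log_alpha = ll_c - ll + log_prior_ratio + log_hastings
            if np.log(rng.uniform()) < min(0.0, log_alpha):
                model, ll, L, P = cand, ll_c, L_c, P_c
            states = _sample_states(idx, L, P, model, nodes, rng)
            rows[gen, :4] = (0.0 if model.irreversible else 1.0,
                             model.q_gain, model.q_loss, ll)
            rows[gen, 4:] = states
        cols = ["model", "q_gain", "q_loss", "loglik"] + [f"state_{i}" for i in nodes]
        trace = PosteriorTrace(pd.DataFrame(rows, columns=cols),
                               burn_in=burn_in, chain_id=chain,
                               meta={"seed": seed, "prior": prior,
                                     "sampled_nodes": list(nodes)})
        post_loss = trace.column("q_loss")
        trace.meta["ess_q_loss"] = ess(post_loss) if len(post_loss) >= 10 else np.nan
        traces.append(trace)
    total_ess = sum(t.meta["ess_q_loss"] for t in traces)
    if np.isfinite(total_ess) and total_ess < ess_floor:
        msg = f"combined ESS of q_loss {total_ess:.0f} below floor {ess_floor:.0f}"
        warnings.warn(msg)
        for t in traces:
            t.meta["ess_warning"] = msg
    return traces


def posterior_model_prob(traces: list[PosteriorTrace] | PosteriorTrace) -> float:
    """Posterior probability of the reversible model (pooled over chains)."""
    if isinstance(traces, PosteriorTrace):
        traces = [traces]
    pooled = np.concatenate([t.column("model") for t in traces])
    return float(pooled.mean())


def ancestral_state_map(
    traces: list[PosteriorTrace] | PosteriorTrace,
    tree: Phylogeny,
) -> dict[int, float]:
    """Per-node posterior probability of 'present', model-averaged.

    Keys are node indices of ``tree.index()`` (interior nodes and
    data-missing tips); values are the fraction of sampled generations in
    which the node carried the trait.
    """
    if isinstance(traces, PosteriorTrace):
        traces = [traces]
    nodes = traces[0].meta["sampled_nodes"]
    out = {}
    for i in nodes:
        pooled = np.concatenate([t.column(f"state_{i}") for t in traces])
        out[i] = float(pooled.mean())
    return out


def sensitivity_scan(
    tree: Phylogeny,
    data: Mapping,
    expected_transitions: Iterable[float] = (1, 2, 5, 10),
    **mcmc_kwargs,
) -> pd.DataFrame:
    """Re-run the analysis across prior means and compare reconstructions.

    One row per prior setting with the reversible-model posterior
    probability, every node posterior, and whether the maximum a posteriori
    (MAP) ancestral reconstruction differs from the first setting's.
    """
    settings = list(expected_transitions)
    if not settings:
        raise ValueError("expected_transitions must be non-empty")
    tl = tree.index().tree_length
    rows = []
    reference_map = None
    for n_exp in settings:
        prior = RJPrior(expected_transitions=n_exp, tree_length=tl)
        traces = rj_mcmc(tree, data, prior=prior, **mcmc_kwargs)
        node_pp = ancestral_state_map(traces, tree)
        map_states = {i: int(pp >= 0.5) for i, pp in node_pp.items()}
        if reference_map is None:
            reference_map = map_states
        rows.append(
            {
                "expected_transitions": n_exp,
                "p_reversible": posterior_model_prob(traces),
                "map_changed": map_states != reference_map,
                **{f"pp_node_{i}": pp for i, pp in node_pp.items()},
            }
        )
    return pd.DataFrame(rows)


def read_trait_csv(path) -> dict[str, Optional[int]]:
    """Trait CSV (taxon, state in {0, 1, NA}) -> taxon->state map."""
    df = pd.read_csv(path)
    out: dict[str, Optional[int]] = {}
    for _, row in df.iterrows():
        val = row["state"]
        out[str(row["taxon"])] = None if pd.isna(val) else int(val)
    return out
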