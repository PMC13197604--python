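"""Metropolis–Hastings machinery, posterior traces, and convergence checks.

Shared by the discrete-trait reversible-jump sampler and the bivariate
Brownian-motion sampler.  Conventions:

- one root seed per run; per-chain generators are spawned deterministically
  from it, so a run is exactly reproducible from (seed, data, schedule);
- no thinning — every generation is recorded;
- ESS uses the initial-positive-sequence truncation of the autocorrelation
  sum; split-R-hat (two halves per chain) with threshold 1.01 declares
  convergence, alongside agreement of per-chain model-indicator frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "PosteriorTrace",
    "mh_step",
    "ess",
    "split_rhat",
    "combine_chains",
    "converged",
]


@dataclass
class PosteriorTrace:
    """Generation-indexed MCMC samples for one chain (or a pooled run).

    ``samples`` has one row per generation and named columns; ``burn_in`` is
    the number of leading generations to discard in summaries.
    """

    samples: pd.DataFrame
    burn_in: int = 0
    chain_id: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.samples) <= self.burn_in:
            raise ValueError("post-burn-in length must be >= 1")

    @property
    def post(self) -> pd.DataFrame:
        return self.samples.iloc[self.burn_in :]

    def column(self, name: str) -> np.ndarray:
        return self.post[name].to_numpy()

    def to_tsv(self, path) -> None:
        df = self.samples.copy()
        df.insert(0, "generation", np.arange(len(df)))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, burn_in: int = 0, chain_id: int = 0) -> "PosteriorTrace":
        df = pd.read_csv(path, sep="\t").drop(columns=["generation"])
        return cls(df, burn_in=burn_in, chain_id=chain_id)


def mh_step(
    state,
    propose: Callable,
    log_posterior: Callable,
    rng: np.random.Generator,
    current_lp: float | None = None,
):
    """One Metropolis–Hastings step.

    ``propose(state, rng)`` returns ``(candidate, log_hastings_ratio)``; a
    candidate of None (e.g. a proposal that left the support, such as a
    negative rate) is auto-rejected.  Returns
    ``(state, log_posterior(state), accepted)`` with the log-posterior cached
    so callers do not recompute it.
    """
    if current_lp is None:
        current_lp = log_posterior(state)
    if not np.isfinite(current_lp):
        raise ValueError("log-posterior must be finite at the current state")
    candidate, log_hr = propose(state, rng)
    if candidate is None:
        return state, current_lp, False
    cand_lp = log_posterior(candidate)
    log_alpha = cand_lp - current_lp + log_hr
    if np.log(rng.uniform()) < min(0.0, log_alpha):
        return candidate, cand_lp, True
    return state, current_lp, False


def ess(x) -> float:
    """Effective sample size, n / (1 + 2 sum rho_k).

    Autocorrelations are summed while positive (initial-positive-sequence
    truncation).  Anti-correlated chains would give ESS > n; such values are
    capped at n.  A constant column is degenerate: reported as n with a
    warning, since autocorrelation is undefined.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    if np.ptp(x) == 0:
        warnings.warn("constant trace column: ESS degenerate, reporting n")
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0:
            break
        s += rho[k]
    return float(min(n / (1.0 + 2.0 * s), n))


def split_rhat(chains: list[np.ndarray]) -> float:
    """Potential scale reduction factor on split chains.

    Each chain is split in half; R-hat compares between-half and within-half
    variances.  Values near 1 indicate the chains sample the same
    distribution.
    """
    halves = []
    for c in chains:
        c = np.asarray(c, dtype=float)
        m = len(c) // 2
        if m < 2:
            raise ValueError("chains too short to split")
        halves.extend([c[:m], c[m : 2 * m]])
    m = len(halves)
    n = len(halves[0])
    means = np.array([h.mean() for h in halves])
    variances = np.array([h.var(ddof=1) for h in halves])
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def combine_chains(traces: list[PosteriorTrace]) -> PosteriorTrace:
    """Concatenate post-burn-in samples of replicate chains."""
    if not traces:
        raise ValueError("no traces to combine")
    cols = list(traces[0].samples.columns)
    for t in traces[1:]:
        if list(t.samples.columns) != cols:
            raise ValueError("traces have mismatched columns")
    pooled = pd.concat([t.post for t in traces], ignore_index=True)
    meta = {"n_chains": len(traces), "per_chain_burn_in": [t.burn_in for t in traces]}
    return PosteriorTrace(pooled, burn_in=0, chain_id=-1, meta=meta)


def converged(
    traces: list[PosteriorTrace],
    rhat_threshold: float = 1.01,
    indicator_columns: tuple = ("model",),
    indicator_tolerance: float = 0.05,
) -> bool:
    """Split-R-hat < threshold on every continuous column, and per-chain
    frequencies of any integer model-indicator column within tolerance."""
    if len(traces) < 2:
        return True
    cols = traces[0].samples.columns
    for col in cols:
        vals = [t.column(col) for t in traces]
        if col in indicator_columns:
            freqs = [v.mean() for v in vals]
            if max(freqs) - min(freqs) > indicator_tolerance:
                return False
        else:
            if np.all([np.ptp(v) == 0 for v in vals]):
                continue
            if split_rhat(vals) >= rhat_threshold:
                return False
    return True
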