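"""Outlier screening and nonparametric group comparisons.

Workflow used for both the fluorescence yields and the pigment summaries:

1. screen each response for influential observations with Cook's distance on
   a one-way cell-means model (default threshold 4, taken as an absolute
   value; the common 4/n rule is available as an option);
2. omnibus Kruskal–Wallis test across tissue stages (or stage-by-taxon
   cells), chosen over ANOVA because the underlying data are non-normal and
   unbalanced;
3. pairwise Dunn tests when the omnibus is significant;
4. Benjamini–Hochberg adjustment of all pairwise p-values.

Kruskal–Wallis runs through scipy and the BH step through statsmodels; the
Dunn test (tie-corrected z on mean ranks) is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.regression.linear_model import OLS
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupedMeasurements",
    "cooks_screen",
    "kruskal_wallis",
    "dunn_test",
    "bh_adjust",
    "compact_letter_display",
    "compare_groups",
]


@dataclass
class GroupedMeasurements:
    """A numeric response paired with a categorical grouping of equal length."""

    response: np.ndarray
    group: np.ndarray

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float)
        self.group = np.asarray(self.group)
        if len(self.response) != len(self.group):
            raise ValueError("response and group must have equal length")

    def split(self) -> dict:
        return {
            g: self.response[self.group == g]
            for g in pd.unique(self.group)
        }


def cooks_screen(
    response,
    group,
    threshold: float = 4.0,
    rule: str = "absolute",
) -> tuple[np.ndarray, np.ndarray]:
    """Flag influential observations under a one-way cell-means model.

    Fits response ~ group-mean and computes Cook's distance
    ``D_i = (r_i^2 / (p s^2)) * h_i / (1 - h_i)^2`` for every observation.
    Observations with ``D_i`` above the cutoff are removed.  ``rule``
    selects the cutoff: ``"absolute"`` uses ``threshold`` directly,
    ``"4overN"`` uses ``threshold / n``.

    Observations that are alone in their group have leverage 1 (the cell
    mean is the observation itself); their Cook's distance is degenerate and
    they are exempt from screening.

    Returns (kept_indices, removed_indices) into the input order.
    """
    response = np.asarray(response, dtype=float)
    group = np.asarray(group)
    n = len(response)
    if n == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    X = pd.get_dummies(pd.Series(group, name="g"), dtype=float).to_numpy()
    fit = OLS(response, X).fit()
    # a (near-)perfect fit has no influential points; guard against 0/0
    # blow-ups in the studentized residuals
    scale = float(np.var(response)) if np.var(response) > 0 else 1.0
    if fit.mse_resid <= 1e-12 * scale:
        return np.arange(n), np.array([], dtype=int)
    infl = fit.get_influence()
    with np.errstate(divide="ignore", invalid="ignore"):
        d = infl.cooks_distance[0]
    cutoff = threshold if rule == "absolute" else threshold / n
    if rule not in ("absolute", "4overN"):
        raise ValueError(f"unknown Cook's rule {rule!r}")
    removed = np.flatnonzero(np.isfinite(d) & (d > cutoff))
    kept = np.setdiff1d(np.arange(n), removed)
    return kept, removed


def kruskal_wallis(g: GroupedMeasurements) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-squared p-value.

    Degenerate all-identical data return (H=0, p=1) rather than erroring.
    """
    samples = [v for v in g.split().values() if len(v) > 0]
    if len(samples) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    H, p = sps.kruskal(*samples)
    return float(H), float(p)


def dunn_test(g: GroupedMeasurements, adjust: str = "bh") -> pd.DataFrame:
    """Pairwise Dunn tests on the mean midranks of every group pair.

    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))`` with
    tie correction ``T = sum(t^3 - t) / (12 (N - 1))``; two-sided normal
    p-values, adjusted by ``adjust`` in {"bh", "holm", "bonferroni",
    "none"}.  Pairs involving an empty group are omitted.
    """
    split = g.split()
    groups = [k for k, v in split.items() if len(v) > 0]
    pooled = np.concatenate([split[k] for k in groups])
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    # mean rank per group
    mean_rank, sizes, start = {}, {}, 0
    for k in groups:
        n_k = len(split[k])
        mean_rank[k] = ranks[start : start + n_k].mean()
        sizes[k] = n_k
        start += n_k
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    for a, b in combinations(groups, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        if adjust == "bh":
            out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
        elif adjust == "none":
            out["p_adj"] = out["p_raw"]
        elif adjust in ("holm", "bonferroni"):
            out["p_adj"] = multipletests(out["p_raw"], method=adjust)[1]
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compact_letter_display(pairs: pd.DataFrame, groups, alpha: float = 0.05) -> dict:
    """Greedy letter assignment: groups sharing a letter are not
    significantly different (adjusted p > alpha).

    Insert-and-absorb over the non-significance adjacency: each letter names
    a maximal clique-ish set grown greedily in group order.  Used only for
    display, so the greedy choice (first-fit) is acceptable and documented.
    """
    groups = list(groups)
    ns = {g: {g} for g in groups}  # non-significant neighbours (incl. self)
    for _, r in pairs.iterrows():
        if r["p_adj"] > alpha:
            ns[r["group_a"]].add(r["group_b"])
            ns[r["group_b"]].add(r["group_a"])
    letter_sets: list[set] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if s <= ns[g] and all(g in ns[m] for m in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in sorted(s, key=groups.index):
            out[g] += letter
    return out


def compare_groups(
    df: pd.DataFrame,
    response: str,
    group: str,
    by: str | None = None,
    alpha: float = 0.05,
    adjust: str = "bh",
    cooks_threshold: float = 4.0,
    cooks_rule: str = "absolute",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen, omnibus-test and post-hoc a tidy table, optionally per stratum.

    Returns (omnibus table, pairwise table).  Rows with missing response are
    ignored; Cook's screening uses species-by-stage cells when ``by`` is
    given (the screen is within stratum).
    """
    omnibus_rows, pairwise_frames = [], []
    strata = [(None, df)] if by is None else list(df.groupby(by))
    for stratum, sub in strata:
        sub = sub.dropna(subset=[response])
        if sub[group].nunique() < 2 or len(sub) < 3:
            continue
        resp = sub[response].to_numpy(float)
        grp = sub[group].to_numpy()
        kept, removed = cooks_screen(resp, grp, cooks_threshold, cooks_rule)
        gm = GroupedMeasurements(resp[kept], grp[kept])
        if len(pd.unique(gm.group)) < 2:
            continue
        H, p = kruskal_wallis(gm)
        omnibus_rows.append(
            {"stratum": stratum, "response": response, "H": H, "p": p,
             "n": len(kept), "n_removed": len(removed)}
        )
        if p <= alpha:
            pw = dunn_test(gm, adjust=adjust)
            pw.insert(0, "stratum", stratum)
            pairwise_frames.append(pw)
    omnibus = pd.DataFrame(omnibus_rows)
    pairwise = (
        pd.concat(pairwise_frames, ignore_index=True)
        if pairwise_frames
        else pd.DataFrame(columns=["stratum", "group_a", "group_b", "z", "p_raw", "p_adj"])
    )
    return omnibus, pairwise
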