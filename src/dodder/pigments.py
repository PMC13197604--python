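"""Pigment summaries from per-sample HPLC concentrations.

All concentrations are nmol per gram fresh weight (nmol g^-1 FW); an absent
chromatogram peak is recorded as 0.  Summary quantities:

- total chlorophyll = Chl a + Chl b;
- total carotenoids = V + A + Z + N + L + alpha-car + beta-car (lutein
  epoxide is a distinct cycle member and deliberately NOT included);
- total xanthophylls = V + A + Z + N + L;
- VAZ (xanthophyll-cycle pool) = V + A + Z;
- NVZ fraction = (N + V + Z) / total carotenoids.

Carotenoids are normalized by total carotenoids rather than by chlorophyll,
because chlorophyll approaches zero in the holoparasitic *C. purpurata* and
a per-chlorophyll ratio would be meaningless there.
"""

from __future__ import annotations

from dataclasses import dataclass

import math
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "CAROTENOIDS",
    "XANTHOPHYLLS",
    "PigmentProfile",
    "total_chlorophyll",
    "chl_ab_ratio",
    "total_carotenoids",
    "total_xanthophylls",
    "vaz",
    "nvz_fraction",
    "normalize_by_total",
    "score_neoxanthin_presence",
    "summarize_table",
    "read_pigment_csv",
]

#: The seven constituents of "total carotenoids" (lutein epoxide excluded).
CAROTENOIDS = (
    "violaxanthin",
    "antheraxanthin",
    "zeaxanthin",
    "neoxanthin",
    "lutein",
    "alpha_carotene",
    "beta_carotene",
)

#: The five xanthophylls.
XANTHOPHYLLS = ("violaxanthin", "antheraxanthin", "zeaxanthin", "neoxanthin", "lutein")

PIGMENT_COLUMNS = ("chl_a", "chl_b") + CAROTENOIDS[:5] + ("lutein_epoxide",) + CAROTENOIDS[5:]


@dataclass(frozen=True)
class PigmentProfile:
    species: str
    individual: str
    stage: str
    chl_a: float = 0.0
    chl_b: float = 0.0
    violaxanthin: float = 0.0
    antheraxanthin: float = 0.0
    zeaxanthin: float = 0.0
    neoxanthin: float = 0.0
    lutein: float = 0.0
    lutein_epoxide: float = 0.0
    alpha_carotene: float = 0.0
    beta_carotene: float = 0.0

    def __post_init__(self):
        for name in PIGMENT_COLUMNS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def total_chlorophyll(p: PigmentProfile) -> float:
    return p.chl_a + p.chl_b


def chl_ab_ratio(p: PigmentProfile) -> Optional[float]:
    """Chl a : Chl b; missing (None) when Chl b is zero — never infinity."""
    if p.chl_b == 0:
        return None
    return p.chl_a / p.chl_b


def total_carotenoids(p: PigmentProfile) -> float:
    return sum(getattr(p, c) for c in CAROTENOIDS)


def total_xanthophylls(p: PigmentProfile) -> float:
    return sum(getattr(p, c) for c in XANTHOPHYLLS)


def vaz(p: PigmentProfile) -> float:
    """Xanthophyll-cycle pool: violaxanthin + antheraxanthin + zeaxanthin."""
    return p.violaxanthin + p.antheraxanthin + p.zeaxanthin


def nvz_fraction(p: PigmentProfile) -> Optional[float]:
    tot = total_carotenoids(p)
    if tot == 0:
        return None
    return (p.neoxanthin + p.violaxanthin + p.zeaxanthin) / tot


def normalize_by_total(p: PigmentProfile) -> dict[str, Optional[float]]:
    """Each carotenoid as a fraction of total carotenoids.

    The seven constituents sum to 1; lutein epoxide is reported as a fraction
    too but sits outside the constituent sum.  Zero total -> all missing.
    """
    tot = total_carotenoids(p)
    names = CAROTENOIDS + ("lutein_epoxide",)
    if tot == 0:
        return {name: None for name in names}
    return {name: getattr(p, name) / tot for name in names}


def score_neoxanthin_presence(
    profiles: Iterable[PigmentProfile],
    detection_threshold: float = 0.0,
    all_taxa: Optional[Iterable[str]] = None,
) -> dict[str, Optional[int]]:
    """Per-taxon neoxanthin presence: 1 if detectable in ANY sample.

    A taxon is scored present iff any replicate of any life stage has
    neoxanthin above ``detection_threshold`` (default 0: any positive
    quantified peak counts; HPLC detection limits are instrument-specific,
    hence configurable).  Taxa listed in ``all_taxa`` but with no profiles
    are returned as missing (None) — e.g. a tip kept in the phylogeny
    without pigment sampling, whose state the phylogenetic model infers.
    """
    states: dict[str, Optional[int]] = {t: None for t in (all_taxa or [])}
    for p in profiles:
        detected = p.neoxanthin > detection_threshold
        prev = states.get(p.species)
        states[p.species] = int(bool(prev) or detected)
    return states


def summarize_table(df: pd.DataFrame) -> pd.DataFrame:
    """Row-wise summaries for a pigment table (columns as PigmentProfile)."""
    rows = []
    for rec in df.to_dict("records"):
        p = PigmentProfile(**{k: rec[k] for k in ("species", "individual", "stage") + PIGMENT_COLUMNS})
        fracs = normalize_by_total(p)
        rows.append(
            {
                "species": p.species,
                "individual": p.individual,
                "stage": p.stage,
                "total_chlorophyll": total_chlorophyll(p),
                "chl_ab_ratio": chl_ab_ratio(p),
                "total_carotenoids": total_carotenoids(p),
                "total_xanthophylls": total_xanthophylls(p),
                "vaz": vaz(p),
                "nvz_fraction": nvz_fraction(p),
                **{f"frac_{k}": v for k, v in fracs.items()},
            }
        )
    out = pd.DataFrame(rows)
    return out.astype({c: float for c in out.columns if c.startswith(("total", "chl", "vaz", "nvz", "frac"))}, errors="ignore")


def read_pigment_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"species", "individual", "stage", *PIGMENT_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pigment table missing columns: {sorted(missing)}")
    if (df[list(PIGMENT_COLUMNS)] < 0).any().any():
        raise ValueError("pigment concentrations must be >= 0")
    return df


def profiles_from_table(df: pd.DataFrame) -> list[PigmentProfile]:
    cols = ("species", "individual", "stage") + PIGMENT_COLUMNS
    return [PigmentProfile(**{k: rec[k] for k in cols}) for rec in df.to_dict("records")]
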