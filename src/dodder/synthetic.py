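"""Simulators for every input the pipeline consumes.

Nothing here reproduces real measurements: the fixture chronogram is a
SYNTHETIC stand-in whose topology follows the accepted subgeneric
classification of *Cuscuta* (four monophyletic subgenera, with the
*Monogynella* lineage diverging first and subg. *Grammica* sister to
subg. *Cuscuta* + *Pachystigma*) but whose branch lengths are invented
smooth node ages, root scaled to 1.  The measurement simulators emulate
the statistical structure of the study design — 14-16 species by six
tissue stages by a few replicates, U-shaped ontogenetic profiles of
photosynthetic yields, non-negative stage/clade-dependent pigment
concentrations, a holoparasite with no chlorophyll and no fluorescence
signal — so the whole analysis chain can be exercised and validated
without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dodder.bm_corr import BMParams, ContinuousPairData
from dodder.pigments import CAROTENOIDS, PIGMENT_COLUMNS
from dodder.trees import Phylogeny

__all__ = [
    "FIXTURE_NEWICK",
    "SUBGENERA",
    "SimulationConfig",
    "fixture_tree",
    "fixture_neoxanthin_states",
    "simulate_binary_trait",
    "simulate_bm_pair",
    "simulate_measurements",
]

# Synthetic 16-taxon chronogram: 14 phenotyped Cuscuta species, the
# unsampled Cuscuta_africana (subg. Pachystigma), and the autotrophic
# outgroup Ipomoea_nil.  Node ages are invented (root = 1); within
# subg. Grammica the resolution groups species by section, with the
# remaining arbitrary choices fixed here once.
FIXTURE_NEWICK = (
    "(Ipomoea_nil:1.0,(Cuscuta_monogyna:0.85,"
    "((Cuscuta_epithymum:0.55,Cuscuta_africana:0.55):0.15,"
    "(Cuscuta_purpurata:0.6,((Cuscuta_californica:0.25,Cuscuta_denticulata:0.25):0.27,"
    "(Cuscuta_gracillima:0.45,(Cuscuta_costaricensis:0.4,"
    "((Cuscuta_indecora:0.18,Cuscuta_tasmanica:0.18):0.16,"
    "((Cuscuta_cephalanthi:0.15,Cuscuta_compacta:0.15):0.13,"
    "(Cuscuta_sandwichiana:0.12,(Cuscuta_australis:0.07,"
    "Cuscuta_polygonorum:0.07):0.05):0.16):0.06):0.06):0.05):0.07):0.08):0.1):0.15):0.15);"
)

SUBGENERA: dict[str, tuple[str, ...]] = {
    "Monogynella": ("Cuscuta_monogyna",),
    "Cuscuta": ("Cuscuta_epithymum",),
    "Pachystigma": ("Cuscuta_africana",),
    "Grammica": (
        "Cuscuta_californica",
        "Cuscuta_costaricensis",
        "Cuscuta_australis",
        "Cuscuta_polygonorum",
        "Cuscuta_sandwichiana",
        "Cuscuta_denticulata",
        "Cuscuta_gracillima",
        "Cuscuta_indecora",
        "Cuscuta_tasmanica",
        "Cuscuta_cephalanthi",
        "Cuscuta_compacta",
        "Cuscuta_purpurata",
    ),
    "outgroup": ("Ipomoea_nil",),
}

STAGES_CUSCUTA = ("sdlg", "y", "o", "h", "f", "sd")

#: Holoparasitic species: no chlorophyll, no fluorescence signal.
HOLOPARASITE = "Cuscuta_purpurata"


@dataclass
class SimulationConfig:
    """Knobs of the full-input simulation (defaults emulate the study design)."""

    seed: int = 0
    replicates: int = 3                      # individuals per species x stage
    noise_sd: float = 0.02                   # additive yield noise
    pigment_cv: float = 0.15                 # pigment noise, fraction of mean
    q_gain: float = 1.0                      # per unit tree time
    q_loss: float = 2.0
    bm: BMParams = field(default_factory=lambda: BMParams(1.0, 1.0, 0.8))
    pigment_noise: str = "truncnorm"         # or "lognormal"


def fixture_tree() -> Phylogeny:
    """The packaged synthetic 16-tip chronogram (root age 1, ultrametric)."""
    return Phylogeny.from_newick(FIXTURE_NEWICK)


def fixture_neoxanthin_states() -> dict[str, int | None]:
    """Synthetic per-taxon neoxanthin presence pattern.

    Emulates the qualitative pattern of the genus: present in the outgroup
    and in subg. *Monogynella*, absent throughout subg. *Cuscuta* and in
    eight of the twelve *Grammica* species, present in the nested
    *Cleistogrammica* group (C. australis, C. polygonorum, C. sandwichiana)
    and in C. cephalanthi, and missing (unsampled, inferred by the model)
    for *C. africana*.
    """
    present = {
        "Ipomoea_nil",
        "Cuscuta_monogyna",
        "Cuscuta_australis",
        "Cuscuta_polygonorum",
        "Cuscuta_sandwichiana",
        "Cuscuta_cephalanthi",
    }
    states: dict[str, int | None] = {}
    for tip in fixture_tree().tip_labels:
        states[tip] = None if tip == "Cuscuta_africana" else int(tip in present)
    return states


# ---------------------------------------------------------------------------
# binary-trait simulation

def simulate_binary_trait(
    tree: Phylogeny,
    q_gain: float,
    q_loss: float,
    root_state: int = 1,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, int], np.ndarray, int]:
    """Forward CTMC simulation of a binary trait along every branch.

    Exponential waiting times between events; returns (tip states,
    per-node true states indexed as ``tree.index()``, realized number of
    transitions over the whole tree).  ``seed`` may be a Generator so that
    replicate simulations can share one stream.
    """
    if q_gain < 0 or q_loss < 0:
        raise ValueError("rates must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = tree.index()
    states = np.full(idx.n_nodes, -1, dtype=int)
    states[idx.root] = int(root_state)
    n_events = 0
    rate = {0: q_gain, 1: q_loss}  # rate of leaving each state
    for n in idx.postorder[::-1]:  # preorder
        n = int(n)
        for c in idx.children[n]:
            s, remaining = states[n], idx.edge_length[c]
            while rate[s] > 0:
                wait = rng.exponential(1.0 / rate[s])
                if wait >= remaining:
                    break
                remaining -= wait
                s = 1 - s
                n_events += 1
            states[c] = s
    tips = {lab: int(states[i]) for i, lab in enumerate(idx.tip_labels)}
    return tips, states, n_events


# ---------------------------------------------------------------------------
# Brownian-motion simulation

def simulate_bm_pair(
    tree: Phylogeny,
    theta: BMParams,
    seed: int = 0,
    stage: str = "",
) -> ContinuousPairData:
    """Root-to-tip simulation of two correlated Brownian traits.

    Each branch adds a bivariate Gaussian increment with covariance
    ``R * duration``; tip values therefore carry exactly the phylogenetic
    covariance structure the likelihood assumes.
    """
    rng = np.random.default_rng(seed)
    idx = tree.index()
    chol = np.linalg.cholesky(theta.R)
    vals = np.zeros((idx.n_nodes, 2))
    vals[idx.root] = (theta.root_x, theta.root_y)
    for n in idx.postorder[::-1]:  # preorder
        n = int(n)
        for c in idx.children[n]:
            step = chol @ rng.standard_normal(2) * math.sqrt(max(idx.edge_length[c], 0.0))
            vals[c] = vals[n] + step
    values = {lab: tuple(vals[i]) for i, lab in enumerate(idx.tip_labels)}
    return ContinuousPairData(values, stage=stage)


# ---------------------------------------------------------------------------
# measurement tables

#: Stage-level target yields (fv_fm, phi_psii, phi_npq): the U-shaped
#: ontogeny — high in seedling/young stem, low in old stem, intermediate in
#: haustorium/flower, high again in developing seed; outgroup leaf highest.
YIELD_PROFILE: dict[str, tuple[float, float, float]] = {
    "sdlg": (0.65, 0.50, 0.25),
    "y": (0.60, 0.55, 0.25),
    "o": (0.35, 0.25, 0.35),
    "h": (0.45, 0.35, 0.30),
    "f": (0.50, 0.40, 0.30),
    "sd": (0.60, 0.45, 0.25),
    "leaf": (0.80, 0.65, 0.20),
}

#: Stage multipliers for the chlorophyll/lutein-like pigments (U-shaped)
#: and the inverse pattern used for beta-carotene.
STAGE_SCALE = {"sdlg": 1.0, "y": 1.1, "o": 0.45, "h": 0.7, "f": 0.8, "sd": 1.0, "leaf": 2.5}

#: Baseline pigment concentrations, nmol per g fresh weight.
PIGMENT_BASE = {
    "chl_a": 120.0,
    "chl_b": 40.0,
    "violaxanthin": 8.0,
    "antheraxanthin": 2.0,
    "zeaxanthin": 3.0,
    "neoxanthin": 5.0,
    "lutein": 20.0,
    "lutein_epoxide": 6.0,
    "alpha_carotene": 1.5,
    "beta_carotene": 10.0,
}


def _yields_to_raw_f(t1: float, t2: float, t3: float, F_m: float = 1000.0):
    """Invert the three yield formulas back to an (F_o, F_m, F_s, F'_m) quadruple."""
    F_o = (1.0 - t1) * F_m
    F_s = F_m * (1.0 - t2 - t3)
    F_m_prime = F_s / (1.0 - t2) if t2 < 1 else F_s
    return F_o, F_m, F_s, F_m_prime


def simulate_measurements(
    species: list[str] | None = None,
    config: SimulationConfig | None = None,
    neoxanthin_states: dict[str, int | None] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fluorescence and pigment tables for species x stage x replicate.

    Yield targets follow :data:`YIELD_PROFILE` with additive Gaussian noise,
    then are back-converted into raw F quadruples that reproduce them
    exactly under :func:`dodder.fluorescence.derive_table` (a zero-noise run
    therefore round-trips the stage means).  Pigments are stage- and
    clade-scaled draws truncated at zero; neoxanthin follows the planted
    per-taxon presence pattern (positive only in seedling and young stem of
    'present' species, zero elsewhere).  The holoparasite contributes no
    fluorescence rows and no chlorophyll.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    if species is None:
        species = [t for t in fixture_tree().tip_labels if t != "Cuscuta_africana"]
    if neoxanthin_states is None:
        neoxanthin_states = fixture_neoxanthin_states()
    clade_scale = {}
    for sp in species:
        if sp in SUBGENERA["outgroup"]:
            clade_scale[sp] = 1.6
        elif sp in SUBGENERA["Monogynella"]:
            clade_scale[sp] = 1.3
        else:
            clade_scale[sp] = 0.7 + 0.6 * rng.uniform()

    fluor_rows, pig_rows = [], []
    for sp in species:
        stages = ("o", "y", "leaf") if sp in SUBGENERA["outgroup"] else STAGES_CUSCUTA
        for stage in stages:
            t1m, t2m, t3m = YIELD_PROFILE[stage]
            for rep in range(config.replicates):
                individual = f"{sp}_{rep + 1}"
                if sp != HOLOPARASITE:
                    t1 = float(np.clip(t1m + rng.normal(0, config.noise_sd), 0.01, 0.95))
                    t2 = float(np.clip(t2m + rng.normal(0, config.noise_sd), 0.01, 0.95))
                    t3 = float(np.clip(t3m + rng.normal(0, config.noise_sd), 0.01, 0.98 - t2))
                    F_o, F_m, F_s, F_mp = _yields_to_raw_f(t1, t2, t3)
                    fluor_rows.append(
                        {"species": sp, "individual": individual, "stage": stage,
                         "F_o": F_o, "F_m": F_m, "F_s": F_s, "F_m_prime": F_mp}
                    )
                row = {"species": sp, "individual": individual, "stage": stage}
                for pig, base in PIGMENT_BASE.items():
                    scale = STAGE_SCALE[stage]
                    if pig == "beta_carotene":  # inverse ontogenetic pattern
                        scale = max(STAGE_SCALE["y"] + STAGE_SCALE["o"] - scale * 0.8, 0.2)
                    mean = base * scale * clade_scale[sp]
                    if sp == HOLOPARASITE and pig in ("chl_a", "chl_b"):
                        mean = 0.0
                    if pig == "neoxanthin":
                        present = bool(neoxanthin_states.get(sp))
                        mean = mean if (present and stage in ("sdlg", "y", "leaf")) else 0.0
                    if mean == 0.0:
                        row[pig] = 0.0
                    elif config.pigment_noise == "lognormal":
                        sd = math.sqrt(math.log(1 + config.pigment_cv**2))
                        row[pig] = float(mean * rng.lognormal(-0.5 * sd * sd, sd))
                    else:
                        row[pig] = float(max(rng.normal(mean, config.pigment_cv * mean), 0.0))
                pig_rows.append(row)
    fluor = pd.DataFrame(fluor_rows)
    pig = pd.DataFrame(pig_rows, columns=["species", "individual", "stage", *PIGMENT_COLUMNS])
    return fluor, pig
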