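"""Ground-truth simulators for every pipeline stage.

Three generators with a shared seeded configuration:

* a pure-birth (Yule) ultrametric species tree;
* Brownian-motion traits on that tree with tunable Pagel's lambda;
* a sporulation/colonization experiment generated from the Smith-Fretwell
  budget ``R = A / W0^b`` with known allocation distribution, scaling
  exponent, host effects, and multiplicative replicate noise, emitted in the
  same CSV schema the biomass module consumes (ergosterol is back-computed
  through the forward calibration so the inversion is exercised end to end).

Defaults mirror the greenhouse design the analysis modules target: 14
fungal species x 4 plant hosts x 5 replicate pots.  All positive quantities
(A, W0, Walpha, host effects, noise) are lognormal so the trade-off stays
exactly linear on logs.  One global seed fans out to per-stage substreams,
so each stage can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from sporetrade.biomass import (
    COLONIZATION_COLUMNS,
    ConversionConstants,
    DEFAULT_CONSTANTS,
    dry_mass_to_hyphal_length,
)
from sporetrade.phylo_signal import lambda_covariance, tree_covariance


@dataclass
class SimulationConfig:
    """Seeds and true parameters of the synthetic study.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    lognormal replicate noise; ``host_effect_sd`` the standard deviation (in
    log10 units) of the per-host multiplier on spore output; ``walpha_corr``
    the correlation between log body size and log allocation.  ``logA_mean``
    etc. are base-10 log means/sds of ug-scale quantities.
    """

    seed: int = 0
    n_species: int = 14
    birth_rate: float = 1.0
    lambda_true: float = 1.0
    sigma2: float = 1.0
    root_state: float = 0.0
    b_true: float = 1.0
    logA_mean: float = 1.0       # A ~ 10 ug per g soil
    logA_sd: float = 0.5
    logW0_mean: float = -0.5     # W0 ~ 0.3 ug, a mid-size AMF spore
    logW0_sd: float = 0.75       # spans roughly the observed 3-4 decades
    n_hosts: int = 4
    n_replicates: int = 5
    noise_cv: float = 0.3
    host_effect_sd: float = 0.2
    logWalpha_mean: float = 2.0  # ~100 ug mycelium per g substrate
    logWalpha_sd: float = 0.5
    walpha_corr: float = 0.5
    w0_on_tree: bool = False
    root_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if not (0.0 <= self.lambda_true <= 1.0):
            raise ValueError("lambda_true must lie in [0, 1]")
        if self.b_true <= 0:
            raise ValueError("b_true must be positive")
        for name in ("birth_rate", "sigma2", "logA_sd", "logW0_sd", "noise_cv",
                     "host_effect_sd", "logWalpha_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (-1.0 <= self.walpha_corr <= 1.0):
            raise ValueError("walpha_corr must lie in [-1, 1]")
        if not (0.0 <= self.root_fraction <= 1.0):
            raise ValueError("root_fraction must lie in [0, 1]")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent substream for one named stage, derived from the seed."""
        stage_key = int.from_bytes(stage.encode(), "little") % (2**31)
        return np.random.default_rng(np.random.SeedSequence((self.seed, stage_key)))

    def species_labels(self) -> list[str]:
        width = len(str(self.n_species))
        return [f"sp{i + 1:0{width}d}" for i in range(self.n_species)]


def simulate_tree(config: SimulationConfig) -> dendropy.Tree:
    """Ultrametric pure-birth tree with ``n_species`` tips.

    Standard Yule construction: with k extant lineages the next speciation
    waits Exp(k * birth_rate) and splits a uniformly chosen lineage; tip
    branches run to the present.  Deterministic given the seed.
    """
    rng = config.rng("tree")
    n = config.n_species
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    birth_time = {tree.seed_node: 0.0}
    t = 0.0
    active = [tree.seed_node]
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (k * config.birth_rate))
        node = active.pop(rng.integers(k))
        node.edge.length = t - birth_time.pop(node)
        for _ in range(2):
            child = node.new_child()
            birth_time[child] = t
            active.append(child)
    # one final waiting time so terminal branches are positive
    t += rng.exponential(1.0 / (n * config.birth_rate))
    labels = config.species_labels()
    rng.shuffle(active)
    for label, node in zip(labels, active):
        node.edge.length = t - birth_time.pop(node)
        node.taxon = taxa.new_taxon(label)
    tree.seed_node.edge.length = None
    return tree


def simulate_bm_trait(tree: dendropy.Tree, config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> pd.Series:
    """One trait drawn from lambda-transformed Brownian motion on the tree.

    Tip values are multivariate normal with mean ``root_state`` and
    covariance ``sigma2 * C_lambda``; ``sigma2 = 0`` degenerates to the root
    state at every tip.
    """
    if rng is None:
        rng = config.rng("trait")
    C, labels = tree_covariance(tree)
    V = config.sigma2 * lambda_covariance(C, config.lambda_true)
    if config.sigma2 == 0:
        x = np.full(len(labels), float(config.root_state))
    else:
        L = np.linalg.cholesky(V + 1e-12 * np.eye(len(labels)))
        x = config.root_state + L @ rng.standard_normal(len(labels))
    return pd.Series(x, index=labels, name="trait")


def _lognormal_factor(rng, sd_log10: float, size) -> np.ndarray:
    """Multiplier 10**N(0, sd); mean-one in log space (median one)."""
    if sd_log10 == 0:
        return np.ones(size)
    return 10.0 ** rng.normal(0.0, sd_log10, size)


def _cv_noise(rng, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    s2 = math.log1p(cv * cv)
    return rng.lognormal(-0.5 * s2, math.sqrt(s2), size)


def simulate_allocation_experiment(
    config: SimulationConfig,
    tree: dendropy.Tree | None = None,
    constants: ConversionConstants = DEFAULT_CONSTANTS,
) -> tuple[pd.DataFrame, dict]:
    """Colonization records generated from the Smith-Fretwell budget.

    Per species: spore mass W0 (lognormal, optionally BM-evolved on the
    tree), budget A lognormal, expected output ``R = A / W0^b_true``, body
    mass Walpha lognormal with correlation ``walpha_corr`` to A.  Per host:
    a multiplicative effect on R.  Per replicate: mean-one lognormal noise
    on R and on body size.  Body mass is split into root and soil
    compartments by ``root_fraction`` and encoded as ergosterol and soil
    hyphal length through the forward calibration, so downstream conversion
    recovers it.  Returns the records plus a ground-truth manifest.
    """
    rng = config.rng("experiment")
    species = [lf.taxon.label for lf in tree.leaf_node_iter()] if tree is not None \
        else config.species_labels()
    n_sp = len(species)

    if config.w0_on_tree:
        if tree is None:
            raise ValueError("w0_on_tree requires a tree")
        bm = simulate_bm_trait(tree, dataclasses.replace(
            config, sigma2=config.logW0_sd**2, root_state=config.logW0_mean),
            rng=config.rng("w0"))
        logW0 = bm.reindex(species).to_numpy()
    else:
        logW0 = config.logW0_mean + config.logW0_sd * rng.standard_normal(n_sp)
    logA = config.logA_mean + config.logA_sd * rng.standard_normal(n_sp)

    zA = (logA - config.logA_mean) / config.logA_sd if config.logA_sd > 0 \
        else np.zeros(n_sp)
    eps = rng.standard_normal(n_sp)
    zW = config.walpha_corr * zA + math.sqrt(1.0 - config.walpha_corr**2) * eps
    logWalpha = config.logWalpha_mean + config.logWalpha_sd * zW

    W0 = 10.0 ** logW0
    A = 10.0 ** logA
    Walpha = 10.0 ** logWalpha
    R_expected = A / W0 ** config.b_true

    host_labels = [f"host{h + 1}" for h in range(config.n_hosts)]
    host_effect = _lognormal_factor(rng, config.host_effect_sd, config.n_hosts)

    rows = []
    for i, sp in enumerate(species):
        for h, host in enumerate(host_labels):
            r_noise = _cv_noise(rng, config.noise_cv, config.n_replicates)
            w_noise = _cv_noise(rng, config.noise_cv, config.n_replicates)
            for rep in range(config.n_replicates):
                R_rep = R_expected[i] * host_effect[h] * r_noise[rep]
                Wa_rep = Walpha[i] * w_noise[rep]
                total_len = dry_mass_to_hyphal_length(Wa_rep, constants)
                root_len = config.root_fraction * total_len
                soil_len = total_len - root_len
                ergosterol = (constants.ergosterol_slope * root_len
                              + constants.ergosterol_intercept)
                rows.append((sp, host, rep + 1, ergosterol, soil_len, R_rep))

    records = pd.DataFrame(rows, columns=list(COLONIZATION_COLUMNS))
    truth = {
        "config": dataclasses.asdict(config),
        "species": species,
        "W0_ug": dict(zip(species, W0.tolist())),
        "A_ug_per_g": dict(zip(species, A.tolist())),
        "Walpha_ug": dict(zip(species, Walpha.tolist())),
        "R_expected_per_g": dict(zip(species, R_expected.tolist())),
        "host_effect": dict(zip(host_labels, host_effect.tolist())),
    }
    return records, truth


_FIXTURE_SPECIES = [
    # species, family, morph, shape, inner range(s); outer ranges derived
    ("Glomus parvum", "Glomeraceae", "default", "globose", (40.0, 60.0), None),
    ("Glomus medium", "Glomeraceae", "default", "globose", (80.0, 120.0), None),
    ("Funneliformis latus", "Glomeraceae", "default", "subglobose",
     (120.0, 160.0), (90.0, 110.0)),
    ("Gigaspora grandis", "Gigasporaceae", "default", "globose", (260.0, 340.0), None),
    ("Scutellospora ovalis", "Gigasporaceae", "default", "subglobose",
     (200.0, 280.0), (150.0, 190.0)),
    ("Acaulospora tenuis", "Acaulosporaceae", "default", "globose", (100.0, 140.0), None),
    ("Ambispora duplex", "Ambisporaceae", "glomoid", "globose", (60.0, 90.0), None),
    ("Ambispora duplex", "Ambisporaceae", "acaulosporoid", "globose",
     (150.0, 210.0), None),
    ("Paraglomus minutum", "Paraglomeraceae", "default", "globose", (70.0, 95.0), None),
    ("Diversispora media", "Diversisporaceae", "default", "subglobose",
     (110.0, 150.0), (85.0, 105.0)),
]


def make_fixture_trait_table(path=None, config: SimulationConfig | None = None
                             ) -> pd.DataFrame:
    """Small deterministic spore-trait table for tests and docs.

    Contains globose, subglobose, and one dimorphic species; every outer
    range strictly contains its inner range.  Seeded jitter (from
    ``config.seed``) perturbs the ranges without violating invariants.
    """
    rng = (config or SimulationConfig()).rng("fixture")
    rows = []
    for species, family, morph, shape, inner_long, inner_short in _FIXTURE_SPECIES:
        jit = rng.uniform(0.95, 1.05)

        def pair(p, scale=1.0):
            return (round(p[0] * jit * scale, 1), round(p[1] * jit * scale, 1))

        il = pair(inner_long)
        ol = (round(il[0] * 0.8, 1), round(il[1] * 1.2, 1))
        row = {
            "species": species, "family": family, "morph": morph, "shape": shape,
            "inner_low_long": il[0], "inner_high_long": il[1],
            "outer_low_long": ol[0], "outer_high_long": ol[1],
            "inner_low_short": None, "inner_high_short": None,
            "outer_low_short": None, "outer_high_short": None,
        }
        if inner_short is not None:
            isrt = pair(inner_short)
            osrt = (round(isrt[0] * 0.8, 1), round(isrt[1] * 1.2, 1))
            row.update(inner_low_short=isrt[0], inner_high_short=isrt[1],
                       outer_low_short=osrt[0], outer_high_short=osrt[1])
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def trait_table_from_w0(w0_by_species: dict[str, float],
                        config: SimulationConfig | None = None) -> pd.DataFrame:
    """Spore-trait rows whose derived masses equal the given W0 values (ug).

    Inverts the geometry chain: mass -> volume (via the spore density
    constant) -> diameter, then writes a symmetric inner range around that
    diameter so the midpoint reproduces it exactly.  Alternating species are
    subglobose with a short axis 0.8x the long one, volume-matched.
    """
    rng = (config or SimulationConfig()).rng("trait_table")
    rows = []
    for i, (sp, w0) in enumerate(w0_by_species.items()):
        volume = w0 / 3.64e-7
        subglobose = i % 3 == 2
        half = rng.uniform(0.05, 0.15)
        if subglobose:
            d_long = (6.0 * volume / (math.pi * 0.8**2)) ** (1.0 / 3.0)
            d_short = 0.8 * d_long
        else:
            d_long = (6.0 * volume / math.pi) ** (1.0 / 3.0)
            d_short = None
        row = {
            "species": sp, "family": "Simulaceae", "morph": "default",
            "shape": "subglobose" if subglobose else "globose",
            "inner_low_long": d_long * (1 - half), "inner_high_long": d_long * (1 + half),
            "outer_low_long": d_long * (1 - 2 * half), "outer_high_long": d_long * (1 + 2 * half),
            "inner_low_short": None, "inner_high_short": None,
            "outer_low_short": None, "outer_high_short": None,
        }
        if subglobose:
            row.update(
                inner_low_short=d_short * (1 - half), inner_high_short=d_short * (1 + half),
                outer_low_short=d_short * (1 - 2 * half), outer_high_short=d_short * (1 + 2 * half),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_experiment_bundle(config: SimulationConfig, out_dir,
                            constants: ConversionConstants = DEFAULT_CONSTANTS
                            ) -> dict[str, Path]:
    """Write tree, trait table, colonization CSV and truth manifest to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(config)
    records, truth = simulate_allocation_experiment(config, tree=tree,
                                                    constants=constants)
    paths = {
        "tree": out / "tree.newick",
        "colonization": out / "colonization.csv",
        "traits": out / "spore_traits.csv",
        "manifest": out / "manifest.json",
    }
    tree.write(path=str(paths["tree"]), schema="newick",
               suppress_rooting=True, unquoted_underscores=True)
    records.to_csv(paths["colonization"], index=False)
    trait_table_from_w0(truth["W0_ug"], config).to_csv(paths["traits"], index=False)
    paths["manifest"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths
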