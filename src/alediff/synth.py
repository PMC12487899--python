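"""Synthetic data generators for the full analysis pipeline.

The study's real inputs (zoo census records, wild life tables,
time-calibrated phylogenies, trait databases) are access-restricted or
compiled from many sources, so each pipeline stage is validated here on
data simulated with known truth:

* individual-level age records per species and sex drawn from Siler
  hazards, left-truncated at the age at first reproduction and partially
  right-censored — the structure of managed-population census extracts;
* species traits and responses on a simulated pure-birth phylogeny with
  known regression coefficients beta, Pagel's lambda, residual variance
  and per-species measurement SDs, matching the weighted BPGLS
  observation model;
* allometric body-mass/testis-mass tables under a power law with known
  exponent gamma, for the gamma = -beta2/beta1 identity check.

Default mortality presets: "mammal-like" is a slow life history
(background hazard 0.01/yr, late shallow senescence) and "bird-like" a
faster one (higher background hazard, steeper senescence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .siler import SilerParams, sample_ages_at_death

__all__ = [
    "PRESETS",
    "SpeciesSpec",
    "SimulationSpec",
    "simulate_tree",
    "simulate_species_records",
    "simulate_phylo_response",
    "simulate_allometry",
]

PRESETS = {
    "mammal-like": SilerParams(a0=-2.0, a1=1.0, c=0.01, b0=-5.5, b1=0.15),
    "bird-like": SilerParams(a0=-1.5, a1=1.2, c=0.03, b0=-4.5, b1=0.25),
}


@dataclass
class SpeciesSpec:
    """Ground truth for one simulated species."""

    name: str
    params_f: SilerParams
    params_m: SilerParams
    alpha: float = 2.0
    n_per_sex: int = 500
    censoring_fraction: float = 0.2


@dataclass
class SimulationSpec:
    """Ground truth for a multi-species simulated study."""

    species: list = field(default_factory=list)
    seed: int = 0


def simulate_tree(
    n_tips: int, seed: int = 0, *, depth: float = 100.0, prefix: str = "sp"
) -> dendropy.Tree:
    """Ultrametric pure-birth tree with ``n_tips`` tips labelled
    ``{prefix}1..{prefix}N``, rescaled to the requested root-to-tip depth."""
    rng = np.random.default_rng(seed)
    # Yule process: start with 2 lineages, split a random lineage at
    # exponential waiting times; branch lengths accrue on live lineages.
    n_alive = 2
    children: dict = {0: None, 1: None}
    lengths = {0: 0.0, 1: 0.0}
    parent = {0: -1, 1: -1}
    next_id = 2
    alive = [0, 1]
    while n_alive < n_tips:
        dt = rng.exponential(1.0 / n_alive)
        for node in alive:
            lengths[node] += dt
        split = alive[rng.integers(n_alive)]
        a, b = next_id, next_id + 1
        next_id += 2
        for ch in (a, b):
            lengths[ch] = 0.0
            parent[ch] = split
        children[split] = (a, b)
        children[a] = children[b] = None
        alive.remove(split)
        alive.extend([a, b])
        n_alive += 1
    dt = rng.exponential(1.0 / n_alive)
    for node in alive:
        lengths[node] += dt

    tip_names = iter(f"{prefix}{i + 1}" for i in range(n_tips))

    def newick(node):
        if children[node] is None:
            return f"{next(tip_names)}:{lengths[node]:.10g}"
        a, b = children[node]
        return f"({newick(a)},{newick(b)}):{lengths[node]:.10g}"

    tree_str = f"({newick(0)},{newick(1)});"
    tree = dendropy.Tree.get(data=tree_str, schema="newick")
    cur_depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= depth / cur_depth
    return tree


def simulate_species_records(spec: SimulationSpec) -> pd.DataFrame:
    """Individual age records for every species in ``spec``.

    Per sex, ages at death are drawn from the species' truncated Siler
    model; a ``censoring_fraction`` of individuals is converted to
    right-censored records at an age uniform between entry and death
    (animals alive at extraction).  Entry age is the species' alpha.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for sp in spec.species:
        for sex, params in (("female", sp.params_f), ("male", sp.params_m)):
            deaths = sample_ages_at_death(
                params, sp.alpha, sp.n_per_sex, rng
            )
            n_cens = int(round(sp.censoring_fraction * sp.n_per_sex))
            censored = np.zeros(sp.n_per_sex, dtype=bool)
            if n_cens:
                idx = rng.choice(sp.n_per_sex, size=n_cens, replace=False)
                censored[idx] = True
            end = deaths.copy()
            end[censored] = sp.alpha + rng.uniform(size=n_cens) * (
                deaths[censored] - sp.alpha
            )
            end = np.maximum(end, sp.alpha + 1e-6)
            frames.append(
                pd.DataFrame(
                    {
                        "species": sp.name,
                        "sex": sex,
                        "entry_age": sp.alpha,
                        "end_age": end,
                        "event": np.where(censored, "censored", "death"),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_phylo_response(
    tree: dendropy.Tree,
    X,
    beta,
    lam: float,
    sigma2: float,
    sds=None,
    seed: int = 0,
    *,
    taxa=None,
) -> np.ndarray:
    """Response under the weighted BPGLS generating model.

    y = X beta + u + m with u ~ MVN(0, sigma2 * C(lambda)) the
    phylogenetically structured residual and m independent per-species
    observation noise with SDs ``sds`` (the layer the regression weights
    absorb).  ``taxa`` gives the row order; defaults to sp1..spN.
    """
    from .phylo import lambda_transform, phylo_correlation

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if taxa is None:
        taxa = [f"sp{i + 1}" for i in range(n)]
    C = lambda_transform(phylo_correlation(tree, taxa), lam)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(C + 1e-10 * np.eye(n))
    u = np.sqrt(sigma2) * (chol @ rng.standard_normal(n))
    m = np.zeros(n)
    if sds is not None:
        m = np.asarray(sds, dtype=float) * rng.standard_normal(n)
    return X @ np.asarray(beta, dtype=float) + u + m


def simulate_allometry(
    tree: dendropy.Tree,
    alpha_scale: float = 1.2,
    gamma: float = 1.1,
    noise: float = 0.1,
    seed: int = 0,
    *,
    mean_log_female_mass: float = 8.0,
    sd_log_female_mass: float = 2.0,
    testis_scale: float = 0.005,
    testis_gamma: float = 0.8,
) -> pd.DataFrame:
    """Species body and testis masses under phylogenetic power laws.

    Female mass is lognormal across species with phylogenetic
    correlation; male mass follows M_m = alpha_scale * M_f^gamma and
    testis mass T = testis_scale * M_m^testis_gamma, each with
    phylogenetically correlated lognormal deviations of SD ``noise`` on
    the log scale (``noise=0`` gives the exact power law).
    """
    from .phylo import phylo_correlation

    if gamma <= 0:
        raise ValueError("gamma must be positive")
    taxa = sorted(
        (leaf.taxon.label for leaf in tree.leaf_node_iter()),
        key=lambda s: (len(s), s),
    )
    n = len(taxa)
    C = phylo_correlation(tree, taxa)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(C + 1e-10 * np.eye(n))

    def corr_noise(scale):
        return scale * (chol @ rng.standard_normal(n))

    log_mf = mean_log_female_mass + corr_noise(sd_log_female_mass)
    log_mm = np.log(alpha_scale) + gamma * log_mf + corr_noise(noise)
    log_t = np.log(testis_scale) + testis_gamma * log_mm + corr_noise(noise)
    return pd.DataFrame(
        {
            "species": taxa,
            "female_mass": np.exp(log_mf),
            "male_mass": np.exp(log_mm),
            "testis_mass": np.exp(log_t),
        }
    )
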