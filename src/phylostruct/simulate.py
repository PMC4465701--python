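"""Synthetic metacommunities with known ground truth.

The generator emulates the structure of a latitudinally arranged snake
metacommunity: a Yule (pure-birth) species pool whose major clades have
latitudinally shifted ranges, Brownian-motion morphometric traits with an
additive habitat effect on clade-level optima, and presence/absence
communities assembled from each site's latitudinal species pool through a
tunable habitat filter acting on a phylogenetically conserved habitat-
affinity trait.

Dials (all in :class:`SimulationParams`):

``sigma2``  Brownian rate per unit-length edge (log-trait scale).
``beta``    additive habitat effect: habitat-linked log-traits of a clade
            are shifted by ``+beta`` (forest-affine clades) or ``-beta``.
``phi``     habitat filter strength; inclusion weight is
            ``exp(-phi * (affinity - habitat)^2 / 2)``; ``phi = 0`` gives
            uniform (neutral) sampling from the pool.
``gamma``   latitudinal clade turnover; species range half-width is
            ``span / (1 + gamma)``, so ``gamma = 0`` puts every species in
            every pool.

The default parameters follow the shape of the motivating study system:
182 species, 12 sites (6 forest / 6 non-forest) between 3.1 and 29.7
degrees S, site richness 9-61.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .community import Metacommunity, TraitTable, TRAIT_NAMES
from .phylogeny import Phylogeny

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_phylogeny",
    "simulate_traits",
    "simulate_metacommunity",
    "simulate_dataset",
    "snakelike_params",
]

#: Traits whose clade-level optima receive the additive habitat effect.
HABITAT_LINKED_TRAITS = ("TL", "CAM", "VS")

#: Rough positive scales for back-transforming log-traits (mm or counts).
TRAIT_BASELINES = {"SVL": 500.0, "TL": 120.0, "CAM": 45.0, "HL": 20.0,
                   "HW": 10.0, "HH": 8.0, "VS": 170.0, "SS": 60.0}

_SNAKELIKE_LATITUDES = (3.1, 11.52, 14.78, 24.53, 25.78, 28.23,
                        8.83, 10.37, 15.8, 22.25, 29.43, 29.68)
_SNAKELIKE_HABITATS = ("forest",) * 6 + ("non_forest",) * 6


@dataclass
class SimulationParams:
    """Knobs of the synthetic metacommunity generator (see module docs)."""

    n_species: int = 182
    n_sites: int = 12
    habitats: tuple[str, ...] | None = None
    latitudes: tuple[float, ...] | None = None
    latitude_range: tuple[float, float] = (3.1, 29.7)
    richness_range: tuple[int, int] = (9, 61)
    n_clades: int = 4
    sigma2: float = 0.1
    beta: float = 0.0
    affinity_sigma2: float = 0.02
    phi: float = 0.0
    gamma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2 or self.n_sites < 1:
            raise ValueError("n_species >= 2 and n_sites >= 1 required")
        if self.phi < 0 or self.gamma < 0 or self.sigma2 < 0:
            raise ValueError("phi, gamma and sigma2 must be non-negative")
        if self.richness_range[0] < 1 or self.richness_range[0] > self.richness_range[1]:
            raise ValueError("invalid richness range")
        if self.habitats is None:
            if self.n_sites == 12 and self.latitudes is None:
                self.habitats = _SNAKELIKE_HABITATS
            else:
                self.habitats = tuple(
                    "forest" if i % 2 == 0 else "non_forest"
                    for i in range(self.n_sites))
        if self.latitudes is None:
            if self.n_sites == 12 and self.habitats == _SNAKELIKE_HABITATS:
                self.latitudes = _SNAKELIKE_LATITUDES
            else:
                lo, hi = self.latitude_range
                self.latitudes = tuple(np.linspace(lo, hi, self.n_sites))
        if len(self.habitats) != self.n_sites or len(self.latitudes) != self.n_sites:
            raise ValueError("habitats/latitudes must match n_sites")


def snakelike_params(**overrides) -> SimulationParams:
    """The default preset: 12 sites, 6 forest / 6 non-forest, 182 species."""
    return replace(SimulationParams(), **overrides)


@dataclass
class GroundTruth:
    """What the generator knows that the analyses must recover."""

    clade_of: pd.Series          # species -> clade index
    clade_affinity: pd.Series    # clade index -> +1 (forest) / -1
    affinity: pd.Series          # species-level conserved affinity trait
    latent_traits: pd.DataFrame  # species x traits, log scale, pre-noise
    range_center: pd.Series      # species latitudinal range centers
    range_halfwidth: float
    site_weights: pd.DataFrame | None = None  # species x sites inclusion weights


@dataclass
class SyntheticDataset:
    phylogeny: Phylogeny
    traits: TraitTable
    metacommunity: Metacommunity
    params: SimulationParams
    truth: GroundTruth


def _species_labels(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"sp{str(i + 1).zfill(width)}" for i in range(n)]


def simulate_phylogeny(n: int, seed: int | np.random.Generator = 0) -> Phylogeny:
    """Yule (pure-birth) topology with ``n`` tips labelled sp001...

    Grown forward in time: starting from a root bifurcation, a uniformly
    chosen extant lineage splits until ``n`` tips exist, giving ``n - 1``
    internal bifurcations.  Branch lengths are set to 1 (they are ignored
    downstream anyway: all distances are node counts).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n < 2:
        raise ValueError("need at least 2 species")
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = True
    leaves = [tree.seed_node]
    while len(leaves) < n:
        k = int(rng.integers(len(leaves)))
        node = leaves.pop(k)
        left = node.new_child(edge_length=1.0)
        right = node.new_child(edge_length=1.0)
        leaves.extend([left, right])
    labels = _species_labels(n)
    for label, leaf in zip(labels, tree.leaf_node_iter()):
        leaf.taxon = taxon_namespace.new_taxon(label=label)
    return Phylogeny(tree)


def _major_clades(phylogeny: Phylogeny, n_clades: int) -> pd.Series:
    """Partition tips into clades by repeatedly opening the largest subtree."""
    root = phylogeny.tree.seed_node
    frontier = [root]
    while len(frontier) < n_clades:
        frontier.sort(key=lambda nd: -len(nd.leaf_nodes()))
        node = frontier.pop(0)
        children = node.child_nodes()
        if not children:  # cannot split a tip further
            frontier.append(node)
            break
        frontier = frontier + children
    mapping = {}
    for idx, node in enumerate(frontier):
        for leaf in node.leaf_iter():
            mapping[leaf.taxon.label] = idx
    return pd.Series(mapping, name="clade").sort_index()


def _brownian(phylogeny: Phylogeny, sigma2: float,
              rng: np.random.Generator) -> pd.Series:
    """One Brownian trait on unit-length edges, root value 0."""
    sd = float(np.sqrt(sigma2))
    values: dict[int, float] = {}
    root = phylogeny.tree.seed_node
    values[id(root)] = 0.0
    out = {}
    for node in phylogeny.tree.preorder_node_iter():
        if node is root:
            continue
        values[id(node)] = values[id(node.parent_node)] + rng.normal(0.0, sd)
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out).sort_index()


def simulate_traits(phylogeny: Phylogeny, sigma2: float = 0.1,
                    beta: float = 0.0, n_clades: int = 4,
                    affinity_sigma2: float = 0.02,
                    seed: int | np.random.Generator = 0,
                    ) -> tuple[TraitTable, GroundTruth]:
    """Brownian log-traits with an additive habitat effect on clade optima.

    Each of the eight morphometric traits evolves independently by
    Brownian motion on unit-length edges (rate ``sigma2``).  Major clades
    alternate habitat affinity (+1 forest / -1 non-forest); the
    habitat-linked traits of each clade are shifted by ``beta *
    affinity`` on the log scale, and a conserved affinity trait (clade
    affinity plus low-rate Brownian noise) is recorded as ground truth.
    Log-traits are mapped into positive morphometric ranges by
    ``baseline * exp(x)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clade_of = _major_clades(phylogeny, n_clades)
    clade_ids = sorted(clade_of.unique())
    signs = np.ones(len(clade_ids))
    signs[rng.permutation(len(clade_ids))[: len(clade_ids) // 2]] = -1.0
    clade_affinity = pd.Series(signs, index=clade_ids)
    affinity = (clade_of.map(clade_affinity)
                + _brownian(phylogeny, affinity_sigma2, rng))

    latent = {}
    for trait in TRAIT_NAMES:
        x = _brownian(phylogeny, sigma2, rng)
        if trait in HABITAT_LINKED_TRAITS and beta != 0.0:
            x = x + beta * clade_of.map(clade_affinity)
        latent[trait] = x
    latent = pd.DataFrame(latent)
    values = {t: TRAIT_BASELINES[t] * np.exp(latent[t]) for t in TRAIT_NAMES}
    table = TraitTable(pd.DataFrame(values, index=latent.index))
    truth = GroundTruth(clade_of=clade_of, clade_affinity=clade_affinity,
                        affinity=affinity, latent_traits=latent,
                        range_center=pd.Series(dtype=float),
                        range_halfwidth=np.nan)
    return table, truth


def simulate_metacommunity(phylogeny: Phylogeny, truth: GroundTruth,
                           params: SimulationParams,
                           rng: np.random.Generator | None = None,
                           ) -> tuple[Metacommunity, GroundTruth]:
    """Assemble habitat-filtered communities from latitudinal pools.

    Each species' latitudinal range is centred near its clade's centre
    (clade centres are spread across the gradient) with half-width
    ``span / (1 + gamma)``; a site's regional pool is every species whose
    range covers the site's latitude.  Membership is then drawn without
    replacement with weight ``exp(-phi (affinity - habitat)^2 / 2)`` until
    the site's target richness (uniform in ``richness_range``, capped at
    the pool size) is reached.
    """
    rng = rng or np.random.default_rng(params.seed + 1)
    species = phylogeny.tips
    n = len(species)
    lo, hi = min(params.latitudes), max(params.latitudes)
    span = max(hi - lo, 1e-9)
    clade_ids = sorted(truth.clade_of.unique())
    centers = np.linspace(lo, hi, len(clade_ids) + 2)[1:-1]
    clade_center = pd.Series(centers[rng.permutation(len(clade_ids))],
                             index=clade_ids)
    center = (truth.clade_of.map(clade_center)
              + rng.normal(0.0, 0.15 * span, size=n))
    center = center.loc[species]
    halfwidth = span / (1.0 + params.gamma)

    site_names = [f"site{str(i + 1).zfill(2)}" for i in range(params.n_sites)]
    lat = pd.Series(params.latitudes, index=site_names, dtype=float)
    hab = pd.Series(params.habitats, index=site_names)
    hsign = hab.map({"forest": 1.0, "non_forest": -1.0})

    aff = truth.affinity.loc[species].to_numpy()
    presence = pd.DataFrame(0, index=site_names, columns=species, dtype=int)
    pools: dict[str, set[str]] = {}
    weights = pd.DataFrame(index=species, columns=site_names, dtype=float)
    rmin, rmax = params.richness_range
    for site in site_names:
        in_pool = np.abs(center.to_numpy() - lat[site]) <= halfwidth
        pool = [s for s, ok in zip(species, in_pool) if ok]
        if len(pool) < rmin:
            raise ValueError(
                f"pool of {site} has {len(pool)} species, below the minimum "
                f"target richness {rmin}; lower gamma or the richness range")
        pools[site] = set(pool)
        w = np.exp(-params.phi * (aff[in_pool] - hsign[site]) ** 2 / 2.0)
        weights.loc[:, site] = 0.0
        weights.loc[pool, site] = w / w.sum()
        target = int(rng.integers(rmin, rmax + 1))
        target = min(target, len(pool))
        # weighted sampling without replacement (exponential-key trick)
        keys = rng.exponential(size=len(pool)) / w
        chosen = np.asarray(pool)[np.argsort(keys)[:target]]
        presence.loc[site, chosen] = 1
    mc = Metacommunity(presence, hab, lat, pools=pools)
    truth = replace(truth, range_center=center, range_halfwidth=halfwidth,
                    site_weights=weights)
    return mc, truth


def simulate_dataset(params: SimulationParams | None = None,
                     **overrides) -> SyntheticDataset:
    """One fully consistent synthetic dataset with its ground truth."""
    params = replace(params, **overrides) if params else SimulationParams(**overrides)
    rng = np.random.default_rng(params.seed)
    phy = simulate_phylogeny(params.n_species, rng)
    traits, truth = simulate_traits(
        phy, sigma2=params.sigma2, beta=params.beta,
        n_clades=params.n_clades, affinity_sigma2=params.affinity_sigma2,
        seed=rng)
    mc, truth = simulate_metacommunity(phy, truth, params, rng=rng)
    return SyntheticDataset(phylogeny=phy, traits=traits, metacommunity=mc,
                            params=params, truth=truth)
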