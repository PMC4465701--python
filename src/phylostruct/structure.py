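"""Within-community phylogenetic structure: MPD, MNTD, NRI and NTI.

The net relatedness index (NRI) and nearest taxon index (NTI) are sign-
flipped standardized effect sizes of the mean pairwise distance (MPD) and
mean nearest-taxon distance (MNTD) of the species at a site, relative to a
null distribution obtained by drawing random communities of the same
richness from the site's regional species pool (equivalent to shuffling the
tip labels of the pool subtree for presence/absence data).  Positive values
indicate phylogenetic clustering, negative values overdispersion; |z| >
1.96 is flagged as significant under the normal approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .community import Metacommunity
from .config import AnalysisConfig
from .phylogeny import Phylogeny, node_count_distances

__all__ = [
    "mpd",
    "mntd",
    "null_metric_distribution",
    "structure_index",
    "PhylogeneticStructureModel",
    "PhylogeneticStructureResults",
]


def _indices_of(species, D: DistanceMatrix) -> np.ndarray:
    pos = {name: i for i, name in enumerate(D.ids)}
    try:
        return np.array([pos[s] for s in species], dtype=int)
    except KeyError as exc:
        raise KeyError(f"species not in distance matrix: {exc}") from exc


def mpd(species, D: DistanceMatrix) -> float:
    """Mean pairwise distance among ``species`` (NaN for singletons)."""
    idx = _indices_of(species, D)
    r = len(idx)
    if r < 2:
        return math.nan
    sub = D.data[np.ix_(idx, idx)]
    return sub.sum() / (r * (r - 1))


def mntd(species, D: DistanceMatrix) -> float:
    """Mean distance from each member to its nearest co-occurring relative."""
    idx = _indices_of(species, D)
    r = len(idx)
    if r < 2:
        return math.nan
    sub = D.data[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _metric_on_subsets(metric: str, D: np.ndarray, subsets: np.ndarray,
                       chunk: int = 2048) -> np.ndarray:
    """Vectorized MPD/MNTD over an (n_subsets, richness) index array."""
    if metric not in ("mpd", "mntd"):
        raise ValueError(f"unknown metric {metric!r}")
    r = subsets.shape[1]
    eye = np.eye(r, dtype=bool)
    out = np.empty(len(subsets))
    for start in range(0, len(subsets), chunk):  # chunked to bound memory
        block = subsets[start:start + chunk]
        sub = D[block[:, :, None], block[:, None, :]]
        if metric == "mpd":
            out[start:start + chunk] = sub.sum(axis=(1, 2)) / (r * (r - 1))
        else:
            sub = np.where(eye, np.inf, sub)
            out[start:start + chunk] = sub.min(axis=2).mean(axis=1)
    return out


def null_metric_distribution(metric: str, richness: int, pool_D: DistanceMatrix,
                             n_rand: int, rng: np.random.Generator,
                             exhaustive: bool = False) -> np.ndarray:
    """Null metric values for random communities drawn from the pool.

    Each draw is a uniform random ``richness``-subset of the pool; for
    presence/absence data this is equivalent to shuffling the tip labels of
    the pool subtree while holding richness fixed.  With
    ``exhaustive=True`` every subset is enumerated instead (intended for
    small pools; the result is then the full null population).
    """
    n_pool = len(pool_D.ids)
    if richness > n_pool:
        raise ValueError(f"richness {richness} exceeds pool size {n_pool}")
    if richness < 2:
        raise ValueError("null distribution undefined for richness < 2")
    D = pool_D.data
    if exhaustive:
        subsets = np.array(list(itertools.combinations(range(n_pool), richness)))
    else:
        # vectorized sampling without replacement: smallest `richness` keys
        keys = rng.random((n_rand, n_pool))
        subsets = np.argpartition(keys, richness - 1, axis=1)[:, :richness]
    return _metric_on_subsets(metric, D, subsets)


def structure_index(site_species, pool, metric: str,
                    n_rand: int, rng: np.random.Generator,
                    z_critical: float = 1.96,
                    exhaustive: bool = False) -> dict:
    """One NRI (metric='mpd') or NTI (metric='mntd') record for a site.

    ``pool`` is the regional pool as either a :class:`Phylogeny` (its
    node-count distances are computed here) or a precomputed
    :class:`skbio.DistanceMatrix` over the pool species.

    The index is ``-(obs - mean_null) / sd_null`` so that clustering
    (observed metric below the null mean) is positive.  Monte-Carlo nulls
    use the sample (n-1) standard deviation; exhaustive enumeration uses
    the population form, since it is the complete null population.  A rank
    p-value (fraction of null values <= observed, +1 corrected) is emitted
    alongside the z-based significance flag.
    """
    pool_D = pool if isinstance(pool, DistanceMatrix) else node_count_distances(pool)
    site_species = list(site_species)
    obs = mpd(site_species, pool_D) if metric == "mpd" else mntd(site_species, pool_D)
    rec = {
        "richness": len(site_species),
        "pool_size": len(pool_D.ids),
        "obs": obs,
        "null_mean": math.nan,
        "null_sd": math.nan,
        "index": math.nan,
        "rank_p": math.nan,
        "significant": False,
        "degenerate": False,
    }
    if len(site_species) < 2:
        rec["degenerate"] = True
        return rec
    null = null_metric_distribution(metric, len(site_species), pool_D,
                                    n_rand, rng, exhaustive=exhaustive)
    mean = float(null.mean())
    sd = float(null.std(ddof=0 if exhaustive else 1))
    rec["null_mean"], rec["null_sd"] = mean, sd
    if sd == 0.0:
        rec["degenerate"] = True
        return rec
    z = -(obs - mean) / sd
    rec["index"] = z
    rec["rank_p"] = (np.sum(null <= obs) + 1) / (len(null) + 1)
    rec["significant"] = abs(z) > z_critical
    return rec


class PhylogeneticStructureModel:
    """NRI/NTI analysis of a metacommunity against regional-pool nulls.

    Parameters
    ----------
    metacommunity :
        Presence/absence communities with habitat and latitude metadata.
        If it carries per-site pools, nulls are drawn from each site's pool
        subtree; otherwise from the full metacommunity tree.
    phylogeny :
        Rooted topology covering every pooled/observed species; distances
        are node counts.
    """

    def __init__(self, metacommunity: Metacommunity, phylogeny: Phylogeny):
        missing = set(metacommunity.species) - set(phylogeny.tips)
        if missing:
            raise ValueError(f"species missing from tree: {sorted(missing)}")
        self.metacommunity = metacommunity
        self.phylogeny = phylogeny

    def fit(self, config: AnalysisConfig | None = None,
            exhaustive: bool = False) -> "PhylogeneticStructureResults":
        config = config or AnalysisConfig()
        rows = {}
        mc = self.metacommunity
        # cache pool distance matrices: many sites often share a pool
        dist_cache: dict[frozenset, DistanceMatrix] = {}
        for k, site in enumerate(mc.sites):
            pool = frozenset(mc.pool_of(site)) & set(self.phylogeny.tips)
            if pool not in dist_cache:
                tree = (self.phylogeny if pool == set(self.phylogeny.tips)
                        else self.phylogeny.subtree(pool))
                dist_cache[pool] = node_count_distances(tree)
            pool_D = dist_cache[pool]
            row = {}
            for metric, name in (("mpd", "NRI"), ("mntd", "NTI")):
                rec = structure_index(
                    mc.species_at(site), pool_D, metric,
                    config.n_randomizations_structure,
                    config.rng(offset=1000 + k),
                    z_critical=config.z_critical, exhaustive=exhaustive,
                )
                row["richness"] = rec["richness"]
                row["pool_size"] = rec["pool_size"]
                for key in ("obs", "null_mean", "null_sd", "rank_p"):
                    row[f"{name}_{key}"] = rec[key]
                row[name] = rec["index"]
                row[f"{name}_significant"] = rec["significant"]
                row[f"{name}_degenerate"] = rec["degenerate"]
            rows[site] = row
        table = pd.DataFrame.from_dict(rows, orient="index")
        table.index.name = "site"
        return PhylogeneticStructureResults(self, table, config)


@dataclass
class PhylogeneticStructureResults:
    """Per-site NRI/NTI table plus the configuration that produced it."""

    model: PhylogeneticStructureModel
    table: pd.DataFrame
    config: AnalysisConfig

    @property
    def nri(self) -> pd.Series:
        return self.table["NRI"]

    @property
    def nti(self) -> pd.Series:
        return self.table["NTI"]

    def summary(self) -> str:
        cols = ["richness", "pool_size", "NRI", "NRI_significant",
                "NTI", "NTI_significant"]
        header = (
            "Phylogenetic community structure (node-count distances)\n"
            f"null: {self.config.n_randomizations_structure} randomizations, "
            f"seed {self.config.seed}; |z| > {self.config.z_critical} flagged\n"
        )
        return header + self.table[cols].round(3).to_string()

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.config.seed} "
                     f"n_rand={self.config.n_randomizations_structure} "
                     f"z_critical={self.config.z_critical}\n")
            self.table.to_csv(fh)
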