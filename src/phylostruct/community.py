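"""Metacommunity and trait tables: containers, CSV readers, validation.

The composition table is strictly presence/absence (the analyses are
presence-only by design).  Site metadata carry a two-level habitat factor
(``forest`` / ``non_forest``) and a latitude in absolute decimal degrees
south; degree-minute strings such as ``3°6'S`` are converted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Metacommunity",
    "TraitTable",
    "TRAIT_NAMES",
    "parse_latitude",
    "read_composition",
    "read_traits",
    "validate_dataset",
    "ValidationReport",
]

HABITATS = ("forest", "non_forest")

#: The eight morphometric traits: six linear measurements (mm) and two
#: scale counts (species means, so possibly non-integer).
TRAIT_NAMES = ("SVL", "TL", "CAM", "HL", "HW", "HH", "VS", "SS")

_DMS_RE = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*(?:[°ºo]\s*(\d+(?:\.\d+)?)?)?\s*(?:['’′]\s*(\d+(?:\.\d+)?))?"
    r"\s*[\"”″'’′]*\s*([NSns]?)\s*$"
)


def parse_latitude(value) -> float:
    """Parse a latitude into absolute decimal degrees.

    Accepts plain numbers (returned as their absolute value) and
    degree-minute[-second] strings like ``"24°32'S"`` → ``24.5333``.
    """
    if isinstance(value, (int, float, np.floating, np.integer)):
        if np.isnan(value):
            raise ValueError("latitude is missing")
        return abs(float(value))
    m = _DMS_RE.match(str(value))
    if not m:
        raise ValueError(f"unparseable latitude: {value!r}")
    deg = float(m.group(1))
    minutes = float(m.group(2) or 0.0)
    seconds = float(m.group(3) or 0.0)
    if minutes >= 60 or seconds >= 60:
        raise ValueError(f"minutes/seconds out of range in {value!r}")
    return deg + minutes / 60.0 + seconds / 3600.0


def _norm_name(name: str) -> str:
    return str(name).strip().replace(" ", "_")


class Metacommunity:
    """Sites × species presence/absence with per-site metadata.

    Parameters
    ----------
    presence :
        DataFrame indexed by site name, species as columns, entries in
        {0, 1}.
    habitat :
        Mapping or Series site → ``"forest"`` / ``"non_forest"``.
    latitude :
        Mapping or Series site → latitude (absolute decimal degrees, or a
        DMS string).
    pools :
        Optional mapping site → iterable of species names forming that
        site's regional pool.  Present species must be contained in the
        pool.
    """

    def __init__(self, presence: pd.DataFrame, habitat, latitude, pools=None):
        presence = presence.copy()
        presence.index = [_norm_name(s) for s in presence.index]
        presence.columns = [_norm_name(s) for s in presence.columns]
        if presence.index.duplicated().any():
            raise ValueError("duplicate site names")
        if presence.columns.duplicated().any():
            raise ValueError("duplicate species names")
        vals = presence.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = sorted(set(vals[~np.isin(vals, (0, 1))].tolist()))
            raise ValueError(f"non-binary presence values: {bad}")
        presence = presence.astype(int)
        richness = presence.sum(axis=1)
        if (richness == 0).any():
            empty = list(presence.index[richness == 0])
            raise ValueError(f"sites with no species: {empty}")
        never_seen = presence.columns[presence.sum(axis=0) == 0]
        if len(never_seen):
            presence = presence.drop(columns=never_seen)

        hab = pd.Series(dict(habitat) if isinstance(habitat, Mapping) else habitat)
        hab.index = [_norm_name(s) for s in hab.index]
        lat = pd.Series(dict(latitude) if isinstance(latitude, Mapping) else latitude)
        lat.index = [_norm_name(s) for s in lat.index]
        missing = [s for s in presence.index if s not in hab.index or s not in lat.index]
        if missing:
            raise ValueError(f"sites lacking metadata: {missing}")
        hab = hab.loc[presence.index].astype(str)
        bad_hab = sorted(set(hab) - set(HABITATS))
        if bad_hab:
            raise ValueError(f"unknown habitat labels: {bad_hab} (expected {HABITATS})")
        lat = lat.loc[presence.index].map(parse_latitude).astype(float)

        self.presence = presence
        self.habitat = hab
        self.latitude = lat
        self.pools: dict[str, frozenset[str]] | None = None
        if pools is not None:
            norm_pools = {
                _norm_name(site): frozenset(_norm_name(sp) for sp in members)
                for site, members in pools.items()
            }
            for site in presence.index:
                if site not in norm_pools:
                    raise ValueError(f"no pool given for site {site}")
                present = set(self.species_at(site))
                extra = present - norm_pools[site]
                if extra:
                    raise ValueError(
                        f"site {site}: present species not in its pool: {sorted(extra)}"
                    )
            self.pools = {s: norm_pools[s] for s in presence.index}

    # -- accessors -----------------------------------------------------

    @property
    def sites(self) -> list[str]:
        return list(self.presence.index)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def richness(self) -> pd.Series:
        return self.presence.sum(axis=1)

    def species_at(self, site: str) -> list[str]:
        row = self.presence.loc[site]
        return list(row.index[row == 1])

    def pool_of(self, site: str) -> frozenset[str]:
        """Regional pool for ``site`` (all observed species if none given)."""
        if self.pools is not None:
            return self.pools[site]
        return frozenset(self.species)

    def habitat_dummy(self) -> pd.Series:
        """Habitat as a 0/1 dummy (forest = 1)."""
        return (self.habitat == "forest").astype(int)

    def relative_composition(self) -> pd.DataFrame:
        """Species × sites matrix with each site column summing to 1."""
        W = self.presence.T.astype(float)
        return W / W.sum(axis=0)

    def restrict_sites(self, sites: Iterable[str]) -> "Metacommunity":
        sites = [_norm_name(s) for s in sites]
        pools = {s: self.pools[s] for s in sites} if self.pools else None
        return Metacommunity(self.presence.loc[sites], self.habitat.loc[sites],
                             self.latitude.loc[sites], pools)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<Metacommunity: {len(self.sites)} sites x "
                f"{len(self.species)} species>")


@dataclass
class TraitTable:
    """Species × trait values; all strictly positive.

    ``data`` is indexed by species with the eight morphometric columns,
    plus a derived ``robustness`` column once
    :func:`phylostruct.traits.derive_robustness` has been applied.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = [_norm_name(s) for s in df.index]
        missing = [c for c in TRAIT_NAMES if c not in df.columns]
        if missing:
            raise ValueError(f"missing trait columns: {missing}")
        base = df[list(TRAIT_NAMES)]
        if (base.to_numpy() <= 0).any() or base.isna().any().any():
            raise ValueError("trait values must be strictly positive")
        if df.index.duplicated().any():
            raise ValueError("duplicate species in trait table")
        self.data = df

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)


def read_composition(path, metadata_path=None) -> Metacommunity:
    """Read a sites × species presence CSV into a :class:`Metacommunity`.

    Metadata (``habitat`` and ``latitude`` columns) may live either in the
    composition file itself or in a companion CSV indexed by site.
    """
    df = pd.read_csv(path, index_col=0)
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, index_col=0)
    else:
        meta_cols = [c for c in df.columns if c.lower() in ("habitat", "latitude")]
        if len(meta_cols) < 2:
            raise ValueError(
                "composition file lacks habitat/latitude columns and no "
                "metadata file was given"
            )
        meta = df[meta_cols]
        meta.columns = [c.lower() for c in meta.columns]
        df = df.drop(columns=meta_cols)
    meta.columns = [c.lower() for c in meta.columns]
    for col in ("habitat", "latitude"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks a {col!r} column")
    return Metacommunity(df, meta["habitat"], meta["latitude"])


def read_traits(path) -> TraitTable:
    """Read a species × traits CSV (one species per row, 8 trait columns)."""
    return TraitTable(pd.read_csv(path, index_col=0))


@dataclass
class ValidationReport:
    """Cross-dataset consistency findings, split by severity."""

    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal

    def __str__(self) -> str:
        lines = [f"FATAL: {m}" for m in self.fatal]
        lines += [f"WARNING: {m}" for m in self.warnings]
        return "\n".join(lines) if lines else "all checks passed"


def validate_dataset(phylogeny, metacommunity: Metacommunity,
                     traits: TraitTable | None = None) -> ValidationReport:
    """Check that tree, composition, pools and traits name the same species.

    Community species missing from the tree are fatal (no distances can be
    computed); unobserved tree tips and species lacking trait data are
    warnings — trait analyses simply restrict to sites with full coverage.
    """
    report = ValidationReport()
    tree_tips = set(phylogeny.tips)
    observed = set(metacommunity.species)

    missing_from_tree = sorted(observed - tree_tips)
    if missing_from_tree:
        report.fatal.append(
            f"species in communities but not on the tree: {missing_from_tree}"
        )
    unobserved = sorted(tree_tips - observed)
    if metacommunity.pools is not None:
        pooled = set().union(*metacommunity.pools.values())
        unobserved = sorted(tree_tips - observed - pooled)
        pool_missing = sorted(pooled - tree_tips)
        if pool_missing:
            report.fatal.append(
                f"pool species not on the tree: {pool_missing}"
            )
    if unobserved:
        report.warnings.append(f"tree tips never observed: {unobserved}")

    if traits is not None:
        lacking = sorted(observed - set(traits.species))
        if lacking:
            affected = [
                site for site in metacommunity.sites
                if set(metacommunity.species_at(site)) & set(lacking)
            ]
            report.warnings.append(
                f"species lacking trait data: {lacking}; affected sites "
                f"(excluded from trait analyses): {affected}"
            )
    return report
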