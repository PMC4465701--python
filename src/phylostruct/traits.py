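"""Trait convergence across habitats and its phylogenetic d-separation.

The community trait matrix T holds, per site, the presence-weighted mean
of range-standardized species traits.  Convergence along the habitat
gradient is the matrix correlation rho(TE) between Euclidean
dissimilarities of T rows and a 0/1 habitat-mismatch matrix E; its null
distribution is built by shuffling species identities over trait rows and
rebuilding T each time (the null of "traits unrelated to which species is
which").  rho(PT) correlates trait structure with phylogeny-weighted
composition (matrix P), and the partial rho(TE.P) asks whether the
trait-habitat association survives controlling for phylogenetic
composition: if rho(TE) is significant but rho(TE.P) is not, the
convergence is attributable to phylogenetic niche conservatism
(habitat filters selecting whole clades).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .community import Metacommunity, TraitTable, TRAIT_NAMES
from .config import AnalysisConfig
from .fuzzy import MatrixP, bray_curtis, build_matrix_P
from .phylogeny import Phylogeny

__all__ = [
    "derive_robustness",
    "standardize_traits",
    "build_matrix_T",
    "env_dissimilarity",
    "trait_dissimilarity",
    "matrix_correlation",
    "partial_matrix_correlation",
    "permutation_test_TE",
    "rho_PT",
    "rho_TE_given_P",
    "optimal_trait_subset",
    "Verdict",
    "dsep_verdict",
    "TraitConvergenceModel",
    "TraitConvergenceResults",
]


def derive_robustness(traits: TraitTable) -> TraitTable:
    """Add ``robustness``: stoutness after controlling for body size.

    Defined as the residual of the least-squares fit of log(CAM) on
    log(SVL) across species, so a species fatter than the allometric
    expectation for its length gets a positive value.
    """
    df = traits.data
    if len(df) < 3:
        raise ValueError("robustness fit needs at least 3 species")
    x = np.log(df["SVL"].to_numpy(dtype=float))
    y = np.log(df["CAM"].to_numpy(dtype=float))
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    out = df.copy()
    out["robustness"] = resid
    return TraitTable(out)


def standardize_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Range each trait to [0, 1] across species: (x - min)/(max - min).

    Needed to mix millimetre measurements with scale counts on one scale.
    Constant traits carry no between-species information and are dropped
    with a warning.  Idempotent on already-ranged columns.
    """
    if len(traits) < 2:
        raise ValueError("standardization needs at least 2 species")
    lo, hi = traits.min(axis=0), traits.max(axis=0)
    constant = list(traits.columns[lo == hi])
    if constant:
        warnings.warn(f"dropping constant traits: {constant}", stacklevel=2)
        traits = traits.drop(columns=constant)
        lo, hi = lo.drop(constant), hi.drop(constant)
    return (traits - lo) / (hi - lo)


def build_matrix_T(B_hat: pd.DataFrame, metacommunity: Metacommunity,
                   trait_subset=None) -> pd.DataFrame:
    """Sites × traits community-weighted means of standardized traits.

    ``T = W_rel^T @ B_hat`` where W_rel columns are presence/richness:
    each site row is the plain average of its species' standardized trait
    values.  Every species present at an included site must have traits.
    """
    if trait_subset is not None:
        missing = [t for t in trait_subset if t not in B_hat.columns]
        if missing:
            raise KeyError(f"unknown traits: {missing}")
        B_hat = B_hat[list(trait_subset)]
    lacking = set(metacommunity.species) - set(B_hat.index)
    if lacking:
        raise ValueError(
            f"species without trait values: {sorted(lacking)}; restrict the "
            "metacommunity to fully covered sites first"
        )
    W = metacommunity.relative_composition()  # species x sites, cols sum 1
    B = B_hat.reindex(W.index)
    T = W.to_numpy().T @ B.to_numpy()
    return pd.DataFrame(T, index=W.columns, columns=B.columns)


def env_dissimilarity(metacommunity: Metacommunity) -> DistanceMatrix:
    """0/1 habitat mismatch between sites (0 same class, 1 different)."""
    h = metacommunity.habitat_dummy().to_numpy()
    E = (h[:, None] != h[None, :]).astype(float)
    if E.sum() == 0:
        raise ValueError("single habitat class: environmental dissimilarity "
                         "is all-zero and the correlation is undefined")
    return DistanceMatrix(E, ids=metacommunity.sites)


def trait_dissimilarity(T: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between community trait rows."""
    return DistanceMatrix(squareform(pdist(T.to_numpy())), ids=list(T.index))


def _lower(D: DistanceMatrix) -> np.ndarray:
    m = D.data
    return m[np.tril_indices_from(m, k=-1)]


def matrix_correlation(D_X: DistanceMatrix, D_Y: DistanceMatrix) -> float:
    """Pearson correlation of the strictly-lower-triangle entries."""
    if list(D_X.ids) != list(D_Y.ids):
        raise ValueError("dissimilarity matrices must share site ordering")
    x, y = _lower(D_X), _lower(D_Y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a dissimilarity matrix")
    return float(np.corrcoef(x, y)[0, 1])


def partial_matrix_correlation(D_T, D_E, D_P) -> float:
    """Partial correlation of T and E triangles controlling for P.

    ``r_TE.P = (r_TE - r_TP r_EP) / sqrt((1-r_TP^2)(1-r_EP^2))``.
    A constant conditioning matrix carries no information, so the partial
    correlation degenerates to the plain correlation of T and E.
    """
    r_te = matrix_correlation(D_T, D_E)
    if _lower(D_P).std() == 0:
        return r_te
    r_tp = matrix_correlation(D_T, D_P)
    r_ep = matrix_correlation(D_E, D_P)
    denom = math.sqrt((1 - r_tp ** 2) * (1 - r_ep ** 2))
    if denom == 0:
        raise ValueError("perfect collinearity with the controlled matrix")
    return (r_te - r_tp * r_ep) / denom


@dataclass
class MatrixCorrelation:
    """A matrix correlation with its permutation test."""

    rho: float
    p: float
    n_perm: int
    scheme: str
    conditioned_on: str | None = None

    def __str__(self) -> str:
        cond = f" | {self.conditioned_on}" if self.conditioned_on else ""
        return (f"rho{cond} = {self.rho:.3f}, p = {self.p:.4f} "
                f"({self.n_perm} permutations, {self.scheme})")


def _perm_p(null: np.ndarray, observed: float) -> float:
    return (np.sum(null >= observed - 1e-12) + 1) / (len(null) + 1)


def permutation_test_TE(B_hat: pd.DataFrame, metacommunity: Metacommunity,
                        trait_subset=None, n_perm: int = 9999,
                        rng: np.random.Generator | None = None,
                        scheme: str = "species") -> MatrixCorrelation:
    """rho(TE) with a permutation null.

    One-sided (convergence = high rho).  The default null shuffles species
    identities over trait rows and rebuilds T each draw; ``scheme="site"``
    gives the classical Mantel site-shuffle instead.
    """
    rng = rng or np.random.default_rng()
    D_E = env_dissimilarity(metacommunity)
    T = build_matrix_T(B_hat, metacommunity, trait_subset)
    obs = matrix_correlation(trait_dissimilarity(T), D_E)
    null = np.empty(n_perm)
    if scheme == "species":
        for k in range(n_perm):
            Bp = pd.DataFrame(
                B_hat.to_numpy()[rng.permutation(len(B_hat))],
                index=B_hat.index, columns=B_hat.columns)
            Tp = build_matrix_T(Bp, metacommunity, trait_subset)
            try:
                null[k] = matrix_correlation(trait_dissimilarity(Tp), D_E)
            except ValueError:  # degenerate draw (constant T): no structure
                null[k] = -np.inf
    elif scheme == "site":
        D_T = trait_dissimilarity(T)
        x = _lower(D_T)
        m = D_E.data
        n = m.shape[0]
        for k in range(n_perm):
            perm = rng.permutation(n)
            Dp = DistanceMatrix(m[np.ix_(perm, perm)], ids=list(D_E.ids))
            null[k] = float(np.corrcoef(x, _lower(Dp))[0, 1])
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    return MatrixCorrelation(rho=obs, p=_perm_p(null, obs), n_perm=n_perm,
                             scheme=scheme)


def rho_PT(matrix_p: MatrixP, B_hat: pd.DataFrame,
           metacommunity: Metacommunity, trait_subset=None,
           n_perm: int = 9999,
           rng: np.random.Generator | None = None) -> MatrixCorrelation:
    """Correlation of phylogenetic and trait community structure.

    Bray-Curtis dissimilarities of matrix-P site columns against Euclidean
    dissimilarities of T rows; null by species-identity shuffling of trait
    rows (P is fixed — the question is whether traits track the phylogenetic
    composition).
    """
    rng = rng or np.random.default_rng()
    sites = metacommunity.sites
    D_P = bray_curtis(matrix_p.P[sites])
    T = build_matrix_T(B_hat, metacommunity, trait_subset)
    obs = matrix_correlation(D_P, trait_dissimilarity(T))
    null = np.empty(n_perm)
    for k in range(n_perm):
        Bp = pd.DataFrame(B_hat.to_numpy()[rng.permutation(len(B_hat))],
                          index=B_hat.index, columns=B_hat.columns)
        Tp = build_matrix_T(Bp, metacommunity, trait_subset)
        try:
            null[k] = matrix_correlation(D_P, trait_dissimilarity(Tp))
        except ValueError:
            null[k] = -np.inf
    return MatrixCorrelation(rho=obs, p=_perm_p(null, obs), n_perm=n_perm,
                             scheme="species")


def rho_TE_given_P(B_hat: pd.DataFrame, metacommunity: Metacommunity,
                   matrix_p: MatrixP, trait_subset=None, n_perm: int = 999,
                   rng: np.random.Generator | None = None) -> MatrixCorrelation:
    """Partial rho(TE.P) with a species-shuffle permutation null.

    Traits are shuffled over species, T and every T-dependent term are
    rebuilt each draw; D_E and D_P stay fixed.
    """
    rng = rng or np.random.default_rng()
    sites = metacommunity.sites
    D_E = env_dissimilarity(metacommunity)
    D_P = bray_curtis(matrix_p.P[sites])
    T = build_matrix_T(B_hat, metacommunity, trait_subset)
    obs = partial_matrix_correlation(trait_dissimilarity(T), D_E, D_P)
    null = np.empty(n_perm)
    for k in range(n_perm):
        Bp = pd.DataFrame(B_hat.to_numpy()[rng.permutation(len(B_hat))],
                          index=B_hat.index, columns=B_hat.columns)
        Tp = build_matrix_T(Bp, metacommunity, trait_subset)
        try:
            null[k] = partial_matrix_correlation(trait_dissimilarity(Tp), D_E, D_P)
        except ValueError:
            null[k] = -np.inf
    return MatrixCorrelation(rho=obs, p=_perm_p(null, obs), n_perm=n_perm,
                             scheme="species", conditioned_on="P")


def optimal_trait_subset(B_hat: pd.DataFrame, metacommunity: Metacommunity,
                         mode: str = "exhaustive") -> tuple[tuple[str, ...], float]:
    """Trait subset maximizing rho(TE).

    Exhaustive over all non-empty subsets (feasible for <= 12 traits);
    ``mode="greedy"`` grows the subset by best single addition instead.
    Ties break toward smaller subsets, then lexicographically.
    """
    D_E = env_dissimilarity(metacommunity)
    names = list(B_hat.columns)

    def score(subset: tuple[str, ...]) -> float:
        T = build_matrix_T(B_hat, metacommunity, subset)
        try:
            return matrix_correlation(trait_dissimilarity(T), D_E)
        except ValueError:  # zero trait variance for this subset
            return -np.inf

    if mode == "exhaustive":
        if len(names) > 12:
            raise ValueError("exhaustive search limited to 12 traits; "
                             "use mode='greedy'")
        best: tuple[tuple[str, ...], float] | None = None
        for r in range(1, len(names) + 1):
            for subset in itertools.combinations(names, r):
                rho = score(subset)
                if best is None or rho > best[1] + 1e-12:
                    best = (subset, rho)
        assert best is not None
        return best
    if mode == "greedy":
        current: tuple[str, ...] = ()
        current_rho = -np.inf
        while True:
            candidates = [c for c in names if c not in current]
            if not candidates:
                break
            scored = [(tuple(sorted(current + (c,))), c) for c in candidates]
            best_subset, _ = max(((s, score(s)) for s, _ in scored),
                                 key=lambda t: t[1])
            best_rho = score(best_subset)
            if best_rho > current_rho + 1e-12:
                current, current_rho = best_subset, best_rho
            else:
                break
        return current, current_rho
    raise ValueError(f"unknown mode {mode!r}")


class Verdict(str, Enum):
    """Outcome of the d-separation test for trait convergence."""

    NICHE_CONSERVATISM = "niche_conservatism_supported"
    INDEPENDENT_CONVERGENCE = "convergence_independent_of_phylogeny"
    NO_CONVERGENCE = "no_convergence"


def dsep_verdict(te: MatrixCorrelation, te_given_p: MatrixCorrelation,
                 alpha: float = 0.05) -> Verdict:
    """d-separation logic for the causal chain habitat → phylogeny → traits.

    A significant rho(TE) that collapses once phylogenetic composition is
    controlled (rho(TE.P) non-significant) indicates the habitat filter
    acts on phylogenetically conserved traits (niche conservatism); if the
    partial correlation stays significant the convergence is independent
    of phylogeny; no significant rho(TE) means no detectable convergence.
    """
    if te.p >= alpha:
        return Verdict.NO_CONVERGENCE
    if te_given_p.p < alpha:
        return Verdict.INDEPENDENT_CONVERGENCE
    return Verdict.NICHE_CONSERVATISM


class TraitConvergenceModel:
    """Full trait-convergence analysis of a metacommunity.

    Restricts to sites whose species all have trait data, derives the
    allometric robustness trait, range-standardizes, optionally searches
    for the convergence-maximizing trait subset, and runs the rho(TE),
    rho(PT) and rho(TE.P) permutation tests plus the d-separation verdict.
    """

    def __init__(self, metacommunity: Metacommunity, phylogeny: Phylogeny,
                 traits: TraitTable, add_robustness: bool = True):
        covered = [
            site for site in metacommunity.sites
            if set(metacommunity.species_at(site)) <= set(traits.species)
        ]
        if len(covered) < 3:
            raise ValueError("need at least 3 sites with full trait coverage")
        self.all_sites = metacommunity.sites
        self.metacommunity = metacommunity.restrict_sites(covered)
        self.phylogeny = phylogeny
        if add_robustness and "robustness" not in traits.data.columns:
            traits = derive_robustness(traits)
        self.traits = traits

    def fit(self, config: AnalysisConfig | None = None,
            subset_mode: str = "exhaustive",
            trait_subset=None) -> "TraitConvergenceResults":
        config = config or AnalysisConfig()
        mc = self.metacommunity
        present = sorted(set(mc.species))
        B = self.traits.data.loc[present]
        B_hat = standardize_traits(B)
        if trait_subset is None:
            subset, subset_rho = optimal_trait_subset(B_hat, mc, mode=subset_mode)
        else:
            subset = tuple(trait_subset)
            T = build_matrix_T(B_hat, mc, subset)
            subset_rho = matrix_correlation(trait_dissimilarity(T),
                                            env_dissimilarity(mc))
        mp = build_matrix_P(self.phylogeny.subtree(present), mc)
        te = permutation_test_TE(B_hat, mc, subset,
                                 n_perm=config.n_permutations_convergence,
                                 rng=config.rng(offset=2001))
        pt = rho_PT(mp, B_hat, mc, subset,
                    n_perm=config.n_permutations_convergence,
                    rng=config.rng(offset=2002))
        te_p = rho_TE_given_P(B_hat, mc, mp, subset,
                              n_perm=config.n_permutations_dsep,
                              rng=config.rng(offset=2003))
        verdict = dsep_verdict(te, te_p, alpha=config.alpha)
        T = build_matrix_T(B_hat, mc, subset)
        return TraitConvergenceResults(
            sites=mc.sites, trait_subset=subset, subset_rho=subset_rho,
            T=T, te=te, pt=pt, te_given_p=te_p, verdict=verdict,
            config=config)


@dataclass
class TraitConvergenceResults:
    """rho statistics, chosen trait subset and the d-separation verdict."""

    sites: list[str]
    trait_subset: tuple[str, ...]
    subset_rho: float
    T: pd.DataFrame
    te: MatrixCorrelation
    pt: MatrixCorrelation
    te_given_p: MatrixCorrelation
    verdict: Verdict
    config: AnalysisConfig

    def summary(self) -> str:
        return "\n".join([
            "Trait convergence across habitats",
            f"sites with full trait coverage: {', '.join(self.sites)}",
            f"convergence-maximizing traits: {{{', '.join(self.trait_subset)}}}",
            f"rho(TE)   = {self.te.rho:.3f}  p = {self.te.p:.4f}",
            f"rho(PT)   = {self.pt.rho:.3f}  p = {self.pt.p:.4f}",
            f"rho(TE.P) = {self.te_given_p.rho:.3f}  p = {self.te_given_p.p:.4f}",
            f"verdict (alpha={self.config.alpha}): {self.verdict.value}",
        ])

    def to_csv(self, path) -> None:
        rows = []
        for name, mc_ in (("rho_TE", self.te), ("rho_PT", self.pt),
                          ("rho_TE.P", self.te_given_p)):
            rows.append({"test": name, "rho": mc_.rho, "p": mc_.p,
                         "n_perm": mc_.n_perm, "scheme": mc_.scheme,
                         "subset": "+".join(self.trait_subset),
                         "sites": ";".join(self.sites),
                         "seed": self.config.seed})
        with open(path, "w") as fh:
            fh.write(f"# seed={self.config.seed} verdict={self.verdict.value}\n")
            pd.DataFrame(rows).to_csv(fh, index=False)
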