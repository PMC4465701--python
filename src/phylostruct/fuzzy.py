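"""Phylogenetic fuzzy-weighting and principal coordinates of phylogenetic
structure (PCPS).

Each species distributes one unit of "belonging" across all species in
proportion to phylogenetic similarity (a fuzzy set), turning the
presence/absence composition into a phylogeny-weighted composition matrix
P.  Bray-Curtis dissimilarities between the site columns of P, ordinated
by classical PCoA, yield PCPS axes: orthogonal gradients of clade-level
composition across the metacommunity.  The number of axes worth keeping is
chosen by relating cumulative axis sets to environmental predictors with a
db-RDA-style F statistic and keeping the set that maximizes F.

Similarity is 1 - d/max(d) on node-count distances, which maps the bounded
topological distances onto [0, 1]; no correction is applied for negative
PCoA eigenvalues — non-positive axes are simply dropped and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .community import Metacommunity
from .phylogeny import Phylogeny, node_count_distances

__all__ = [
    "phylo_similarity",
    "fuzzy_weights",
    "build_matrix_P",
    "MatrixP",
    "bray_curtis",
    "pcoa",
    "db_rda",
    "select_pcps",
    "PCPSModel",
    "PCPSResults",
]


def phylo_similarity(D: DistanceMatrix) -> pd.DataFrame:
    """Species × species similarity ``s_ij = 1 - d_ij / max(d)``.

    The diagonal is exactly 1 and the most distant pair has similarity 0.
    Invariant under uniform rescaling of all distances.
    """
    dmax = D.data.max()
    if dmax == 0:
        raise ValueError("degenerate distance matrix (all zero)")
    S = 1.0 - D.data / dmax
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=list(D.ids), columns=list(D.ids))


def fuzzy_weights(S: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize similarities: ``q_ij = s_ij / sum_k s_kj``.

    Column j says how species j's unit of belonging is spread over all
    species (including itself); every column sums to 1.
    """
    colsum = S.sum(axis=0)
    return S / colsum


@dataclass
class MatrixP:
    """Phylogeny-weighted species composition with its building blocks.

    ``P`` is species × sites with unit column sums; ``S`` and ``Q`` are the
    intermediate similarity and fuzzy-weight matrices.
    """

    S: pd.DataFrame
    Q: pd.DataFrame
    P: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(self.P.index)

    @property
    def sites(self) -> list[str]:
        return list(self.P.columns)


def build_matrix_P(phylogeny: Phylogeny, metacommunity: Metacommunity) -> MatrixP:
    """Fuzzy-weight the composition by phylogenetic similarity.

    Composition columns are first standardized to relative frequencies
    (each site sums to 1), then ``P = Q @ W_rel``.  Because Q is
    column-stochastic, P columns also sum to 1.  On a star phylogeny Q is
    the identity and P reduces to the relative composition.
    """
    missing = set(metacommunity.species) - set(phylogeny.tips)
    if missing:
        raise ValueError(f"species missing from tree: {sorted(missing)}")
    D = node_count_distances(phylogeny)
    S = phylo_similarity(D)
    Q = fuzzy_weights(S)
    W = metacommunity.relative_composition()  # species x sites, columns sum 1
    W = W.reindex(index=Q.columns, fill_value=0.0)
    P = Q.to_numpy() @ W.to_numpy()
    P = pd.DataFrame(P, index=Q.index, columns=W.columns)
    return MatrixP(S=S, Q=Q, P=P)


def bray_curtis(P: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between the site columns of P."""
    X = P.to_numpy().T
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    return DistanceMatrix(squareform(pdist(X, metric="braycurtis")),
                          ids=list(P.columns))


def pcoa(dissimilarity: DistanceMatrix):
    """Classical scaling (PCoA) keeping only positive eigenvalues.

    Double-centers ``-0.5 * d^2``, eigendecomposes, and returns
    ``(scores, eigenvalues, n_dropped)`` where scores are site × axis
    coordinates scaled by sqrt(eigenvalue), eigenvalues are the positive
    ones in decreasing order, and ``n_dropped`` counts the non-positive
    eigenvalues discarded (no Cailliez/Lingoes correction).  The sign of
    each axis is fixed by making its first non-zero score positive.
    """
    d = dissimilarity.data
    n = d.shape[0]
    A = -0.5 * d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10 if len(eigval) else 0.0
    keep = eigval > tol
    n_dropped = int((~keep).sum())
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    scores = eigvec * np.sqrt(eigval)
    for k in range(scores.shape[1]):  # reproducible axis orientation
        col = scores[:, k]
        nz = np.flatnonzero(np.abs(col) > tol)
        if nz.size and col[nz[0]] < 0:
            scores[:, k] = -col
    return scores, eigval, n_dropped


def _design(predictors: pd.DataFrame) -> np.ndarray:
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def db_rda(axes: np.ndarray, predictors: pd.DataFrame, n_perm: int = 999,
           rng: np.random.Generator | None = None) -> dict:
    """Redundancy statistic of ordination axes on environmental predictors.

    Pools explained and total sums of squares over the (column-centered)
    axes: ``R2 = SS_fit / SS_tot`` and ``F = (R2/q) / ((1-R2)/(n-q-1))``.
    The permutation p shuffles the site rows of the predictors.  With a
    single axis this reduces exactly to an ordinary OLS R2/F.
    """
    Y = np.asarray(axes, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Y = Y - Y.mean(axis=0)
    X = _design(predictors)
    n, q = X.shape[0], X.shape[1] - 1
    if q >= n - 1:
        raise ValueError("too many predictors for the number of sites")

    def r2_of(Xd: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
        fit = Xd @ beta
        ss_tot = (Y ** 2).sum()
        return float((fit ** 2).sum() / ss_tot) if ss_tot > 0 else 0.0

    r2 = r2_of(X)
    F = (r2 / q) / ((1.0 - r2) / (n - q - 1)) if r2 < 1.0 else np.inf
    p = np.nan
    if n_perm and rng is not None:
        Xp = np.asarray(predictors, dtype=float)
        if Xp.ndim == 1:
            Xp = Xp[:, None]
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if r2_of(_design(Xp[perm])) >= r2 - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return {"R2": r2, "F": F, "p": p, "df": (q, n - q - 1)}


def select_pcps(scores: np.ndarray, predictors: pd.DataFrame) -> tuple[int, list[dict]]:
    """Number of leading PCPS axes that maximizes the db-RDA F.

    Evaluates axes 1..k for every k and returns the F-maximizing k (ties
    broken toward fewer axes, i.e. lower residual variation per the
    selection rule) along with the per-k statistics.
    """
    stats = []
    for k in range(1, scores.shape[1] + 1):
        res = db_rda(scores[:, :k], predictors, n_perm=0)
        res["k"] = k
        stats.append(res)
    best = stats[0]
    # F is monotone in R2 here (same predictors for every k), so ties are
    # detected on R2, which stays numerically stable as R2 -> 1 where F
    # explodes; strict improvement required, so ties keep fewer axes.
    for res in stats[1:]:
        if res["F"] > best["F"] and res["R2"] > best["R2"] + 1e-9:
            best = res
    return best["k"], stats


class PCPSModel:
    """PCPS ordination of a metacommunity on a phylogeny.

    ``fit()`` builds matrix P, computes Bray-Curtis dissimilarities between
    sites, ordinates them by PCoA and, if predictors are supplied, selects
    the number of axes by F-maximization.
    """

    def __init__(self, metacommunity: Metacommunity, phylogeny: Phylogeny):
        self.metacommunity = metacommunity
        self.phylogeny = phylogeny

    def fit(self, predictors: pd.DataFrame | None = None) -> "PCPSResults":
        mp = build_matrix_P(self.phylogeny, self.metacommunity)
        bc = bray_curtis(mp.P)
        scores, eigval, n_dropped = pcoa(bc)
        sites = self.metacommunity.sites
        axis_names = [f"PCPS{k + 1}" for k in range(scores.shape[1])]
        site_scores = pd.DataFrame(scores, index=sites, columns=axis_names)
        frac = eigval / eigval.sum() if eigval.size else eigval
        selected_k, selection = None, None
        if predictors is not None:
            selected_k, selection = select_pcps(scores, predictors)
        # species scores: similarity-weighted averages of site scores
        # (plotting convenience, not a canonical PCoA projection)
        P = mp.P.to_numpy()
        w = P / P.sum(axis=1, keepdims=True)
        species_scores = pd.DataFrame(w @ scores, index=mp.species,
                                      columns=axis_names)
        return PCPSResults(matrix_p=mp, dissimilarity=bc,
                           site_scores=site_scores,
                           species_scores=species_scores,
                           eigenvalues=pd.Series(eigval, index=axis_names),
                           fraction=pd.Series(frac, index=axis_names),
                           n_dropped_axes=n_dropped,
                           selected_k=selected_k, selection_table=selection)


@dataclass
class PCPSResults:
    """PCPS axes, eigenvalue spectrum and (optional) axis selection."""

    matrix_p: MatrixP
    dissimilarity: DistanceMatrix
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    eigenvalues: pd.Series
    fraction: pd.Series
    n_dropped_axes: int
    selected_k: int | None = None
    selection_table: list | None = None

    @property
    def n_axes(self) -> int:
        return self.site_scores.shape[1]

    def summary(self) -> str:
        lines = [
            "Principal coordinates of phylogenetic structure (PCPS)",
            f"{len(self.site_scores)} sites, {self.n_axes} positive axes "
            f"({self.n_dropped_axes} non-positive dropped)",
            "axis  eigenvalue  fraction  cumulative",
        ]
        cum = 0.0
        for name in self.site_scores.columns:
            cum += self.fraction[name]
            lines.append(f"{name:>5}  {self.eigenvalues[name]:10.5f}  "
                         f"{self.fraction[name]:8.3f}  {cum:10.3f}")
        if self.selected_k is not None:
            lines.append(f"axes retained by F-maximization: {self.selected_k}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_axes={self.n_axes} dropped={self.n_dropped_axes}\n")
            self.site_scores.to_csv(fh)

    def plot(self, ax=None, lineage_map: pd.Series | None = None,
             habitat: pd.Series | None = None):
        """Ordination plot of the first two axes (sites and species)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        xs = self.site_scores.iloc[:, 0]
        ys = (self.site_scores.iloc[:, 1] if self.n_axes > 1
              else pd.Series(0.0, index=xs.index))
        if habitat is not None:
            for hab, marker in (("forest", "^"), ("non_forest", "o")):
                sel = habitat == hab
                ax.scatter(xs[sel], ys[sel], marker=marker, s=60,
                           label=hab, color="0.4", edgecolor="k")
        else:
            ax.scatter(xs, ys, marker="s", s=60, color="0.4", edgecolor="k")
        sx = self.species_scores.iloc[:, 0]
        sy = (self.species_scores.iloc[:, 1] if self.n_axes > 1
              else pd.Series(0.0, index=sx.index))
        if lineage_map is not None:
            lineages = sorted(set(lineage_map.reindex(sx.index).dropna()))
            cmap = plt.get_cmap("tab10")
            for i, lin in enumerate(lineages):
                sel = lineage_map.reindex(sx.index) == lin
                ax.scatter(sx[sel], sy[sel], s=12, color=cmap(i % 10), label=lin)
        else:
            ax.scatter(sx, sy, s=8, color="tab:blue", alpha=0.5)
        ax.set_xlabel(f"PCPS1 ({self.fraction.iloc[0]:.0%})")
        if self.n_axes > 1:
            ax.set_ylabel(f"PCPS2 ({self.fraction.iloc[1]:.0%})")
        ax.legend(fontsize=8)
        return ax
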