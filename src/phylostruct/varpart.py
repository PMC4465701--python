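"""OLS fits and two-set variation partitioning.

Used to relate per-site structure indices (NRI, NTI) and PCPS axis scores
to the habitat dummy and latitude, and to split the explained variance
into unique and shared fractions of the two predictor sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RegressionResult", "ols_fit", "VarpartResult", "varpart_two"]


@dataclass
class RegressionResult:
    """Summary of a least-squares fit with its whole-model F test."""

    params: pd.Series
    r2: float
    adj_r2: float
    F: float
    df_num: int
    df_den: int
    p: float

    def __str__(self) -> str:
        return (f"R2 = {self.r2:.3f} (adj {self.adj_r2:.3f}), "
                f"F_{self.df_num},{self.df_den} = {self.F:.3f}, p = {self.p:.4g}")


def _as_matrix(X) -> pd.DataFrame:
    if X is None:
        return pd.DataFrame()
    if isinstance(X, pd.Series):
        return X.to_frame()
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def ols_fit(y, X) -> RegressionResult:
    """OLS of ``y`` on predictors ``X`` with an intercept."""
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, q = len(y), X.shape[1]
    if n <= q + 1:
        raise ValueError(f"{n} observations cannot support {q} predictors")
    design = sm.add_constant(X.reset_index(drop=True), has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    if q == 0:  # intercept-only null model
        return RegressionResult(params=fit.params, r2=0.0, adj_r2=0.0,
                                F=0.0, df_num=0, df_den=n - 1, p=1.0)
    return RegressionResult(
        params=fit.params, r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj), F=float(fit.fvalue),
        df_num=int(fit.df_model), df_den=int(fit.df_resid),
        p=float(fit.f_pvalue),
    )


@dataclass
class VarpartResult:
    """Unique/shared/residual variance fractions for two predictor sets.

    Fractions ``a`` (unique to set 1), ``b`` (shared), ``c`` (unique to
    set 2) and ``d`` (residual) are reported for both the raw R² form
    (which sums to 1 exactly) and the adjusted-R² form (whose fractions
    may be negative; they are reported as computed, never clipped).
    Marginal R² values of each set alone are included because "how much
    does latitude explain by itself" is often the quantity quoted.
    """

    raw: dict
    adjusted: dict
    marginal_r2: dict
    full: RegressionResult
    only_1: RegressionResult
    only_2: RegressionResult
    labels: tuple[str, str]

    def percent(self, fraction: str, form: str = "raw") -> int:
        return round(getattr(self, form)[fraction] * 100)

    def __str__(self) -> str:
        l1, l2 = self.labels
        lines = [f"Variation partitioning: [{l1}] vs [{l2}]",
                 "fraction            raw     adjusted"]
        for key, desc in (("a", f"unique {l1}"), ("b", "shared"),
                          ("c", f"unique {l2}"), ("d", "residual")):
            lines.append(f"{desc:<16} {self.raw[key]:8.3f} "
                         f"{self.adjusted[key]:8.3f}")
        lines.append(f"marginal R2: {l1} = {self.marginal_r2[l1]:.3f}, "
                     f"{l2} = {self.marginal_r2[l2]:.3f}")
        return "\n".join(lines)


def varpart_two(y, X1, X2, labels: tuple[str, str] = ("set1", "set2")) -> VarpartResult:
    """Partition variance of ``y`` between predictor sets X1 and X2.

    ``a = R2(full) - R2(X2)``, ``c = R2(full) - R2(X1)``,
    ``b = R2(full) - a - c``, ``d = 1 - R2(full)``; computed with both raw
    and adjusted R².  With X2 empty this degenerates to a plain OLS on X1.
    """
    X1, X2 = _as_matrix(X1), _as_matrix(X2)
    if X2.shape[1] == 0:
        full = ols_fit(y, X1)
        raw = {"a": full.r2, "b": 0.0, "c": 0.0, "d": 1 - full.r2}
        adj = {"a": full.adj_r2, "b": 0.0, "c": 0.0, "d": 1 - full.adj_r2}
        return VarpartResult(raw=raw, adjusted=adj,
                             marginal_r2={labels[0]: full.r2, labels[1]: 0.0},
                             full=full, only_1=full,
                             only_2=ols_fit(y, pd.DataFrame(index=range(len(y)))),
                             labels=labels)
    both = pd.concat([X1.reset_index(drop=True), X2.reset_index(drop=True)],
                     axis=1)
    # X1 == X2 collinear limit: keep one copy of any duplicated column
    dup = both.T.duplicated().to_numpy() | both.columns.duplicated()
    both = both.loc[:, ~dup]
    full = ols_fit(y, both)
    only_1 = ols_fit(y, X1)
    only_2 = ols_fit(y, X2)

    def fractions(r2f, r21, r22):
        a = r2f - r22
        c = r2f - r21
        return {"a": a, "b": r2f - a - c, "c": c, "d": 1 - r2f}

    return VarpartResult(
        raw=fractions(full.r2, only_1.r2, only_2.r2),
        adjusted=fractions(full.adj_r2, only_1.adj_r2, only_2.adj_r2),
        marginal_r2={labels[0]: only_1.r2, labels[1]: only_2.r2},
        full=full, only_1=only_1, only_2=only_2, labels=labels,
    )
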