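"""Phylogenetic generalized least squares regression.

Regresses a species-level response (a shape or form PC axis, or centroid
size) on ecological covariates while modelling residual covariance as
Brownian motion on the phylogeny: ``resid ~ N(0, sigma2 * C)`` with ``C``
the shared-path-length matrix.  The reported "correlation" is the signed
square root of the GLS coefficient of determination computed about the
phylogenetic (GLS intercept-only) mean -- the scalar the field reports
alongside PGLS P-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .phylo import Phylogeny, phylo_vcv, prune_to_taxa

__all__ = ["PGLS", "PGLSResults", "pgls_fit"]


@dataclass
class PGLSResults:
    """GLS estimates, uncertainties and diagnostics of one PGLS fit."""

    params: np.ndarray  # intercept first
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    correlation: float  # sign(slope) * sqrt(GLS R^2); single-predictor fits
    r2: float
    df_resid: int
    n_used: int
    sigma2: float
    names: list

    @property
    def slope(self) -> float:
        return float(self.params[1])

    def summary(self) -> str:
        head = (
            f"PGLS (BM residuals), n = {self.n_used}, df = {self.df_resid}, "
            f"R2_GLS = {self.r2:.4f}, correlation = {self.correlation:.4f}"
        )
        rows = [
            f"  {name:>12s}  beta={b: .6g}  se={s:.4g}  t={t: .4f}  P={p:.4g}"
            for name, b, s, t, p in zip(
                self.names, self.params, self.bse, self.tvalues, self.pvalues
            )
        ]
        return "\n".join([head] + rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.params, "se": self.bse, "t": self.tvalues, "P": self.pvalues},
            index=self.names,
        )


class PGLS:
    """Phylogenetic regression model: ``y ~ 1 + X`` with BM residuals.

    Parameters
    ----------
    y, X : pandas Series/DataFrame aligned by species code, or arrays in
        tree tip order.  Species with any missing value among y and X are
        dropped pairwise, and the tree is pruned to the remainder.
    tree : Phylogeny
    """

    def __init__(self, y, X, tree: Phylogeny):
        tips = tree.tip_labels
        if isinstance(y, pd.Series) or isinstance(X, (pd.Series, pd.DataFrame)):
            y = pd.Series(y) if not isinstance(y, pd.Series) else y
            X = pd.DataFrame(X)
            df = pd.concat([y.rename("__y__"), X], axis=1, join="inner")
            df = df.loc[[t for t in tips if t in df.index]].dropna()
            if df.empty:
                raise ValueError("no species shared between data and tree")
            self.names = ["intercept"] + [str(c) for c in X.columns]
            y_arr = df["__y__"].to_numpy(dtype=float)
            X_arr = df.drop(columns="__y__").to_numpy(dtype=float)
            keep = list(df.index)
        else:
            y_arr = np.asarray(y, dtype=float)
            X_arr = np.asarray(X, dtype=float)
            if X_arr.ndim == 1:
                X_arr = X_arr[:, None]
            ok = np.isfinite(y_arr) & np.all(np.isfinite(X_arr), axis=1)
            y_arr, X_arr = y_arr[ok], X_arr[ok]
            keep = [t for t, o in zip(tips, ok) if o]
            self.names = ["intercept"] + [f"x{j + 1}" for j in range(X_arr.shape[1])]
        if len(keep) < X_arr.shape[1] + 2:
            raise ValueError(
                f"only {len(keep)} species with complete data; need at least "
                f"{X_arr.shape[1] + 2}"
            )
        subtree = tree if len(keep) == len(tips) else prune_to_taxa(tree, keep)
        vcv = phylo_vcv(subtree)
        order = [keep.index(t) for t in vcv.tip_order]
        self.y = y_arr[order]
        self.X = X_arr[order]
        self.C = vcv.C
        self.species = vcv.tip_order

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, response: str, predictors, tree: Phylogeny
    ) -> "PGLS":
        predictors = [predictors] if isinstance(predictors, str) else list(predictors)
        return cls(data[response], data[predictors], tree)

    def fit(self) -> PGLSResults:
        y, C = self.y, self.C
        n = len(y)
        D = np.column_stack([np.ones(n), self.X])
        p = D.shape[1]
        if np.linalg.matrix_rank(D) < p:
            raise ValueError("rank-deficient design matrix")
        cho = cho_factor(C, lower=True)
        CinvD = cho_solve(cho, D)
        XtCiX = D.T @ CinvD
        beta = np.linalg.solve(XtCiX, CinvD.T @ y)
        resid = y - D @ beta
        rss = float(resid @ cho_solve(cho, resid))
        df = n - p
        sigma2 = rss / df
        cov_beta = sigma2 * np.linalg.inv(XtCiX)
        bse = np.sqrt(np.diag(cov_beta))
        tvals = beta / bse
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
        # GLS R^2 about the phylogenetic mean
        ones = np.ones(n)
        Cinv1 = cho_solve(cho, ones)
        mu = float(y @ Cinv1 / (ones @ Cinv1))
        r0 = y - mu
        tss = float(r0 @ cho_solve(cho, r0))
        r2 = 1.0 - rss / tss if tss > 0 else np.nan
        slope_sign = np.sign(beta[1]) if p > 1 else 1.0
        corr = float(slope_sign * np.sqrt(max(r2, 0.0)))
        return PGLSResults(
            params=beta, bse=bse, tvalues=tvals, pvalues=pvals,
            correlation=corr, r2=r2, df_resid=df, n_used=n, sigma2=sigma2,
            names=self.names,
        )


def pgls_fit(y, X, tree: Phylogeny) -> PGLSResults:
    """Convenience wrapper: ``PGLS(y, X, tree).fit()``."""
    return PGLS(y, X, tree).fit()
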