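"""Group discrimination and variance partitioning of shape data.

Canonical variates analysis (CVA) finds the axes maximizing among-group
relative to pooled within-group variance; with raw Procrustes coordinates
the data are first projected onto leading PCs so the within-group
covariance is invertible.  Procrustes ANOVA partitions summed squared
tangent-space (Procrustes) distances into between/within-group components
with a Goodall-type F ratio and an unrestricted label-permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

__all__ = ["GroupModel", "AnovaTable", "cva", "procrustes_anova"]


@dataclass
class GroupModel:
    """CVA result: canonical scores and among-group variance shares."""

    cv_scores: np.ndarray  # (n, g-1)
    cv_proportions: np.ndarray  # percent of among-group variance per axis
    eigenvalues: np.ndarray
    loadings: np.ndarray  # (g-1, retained) canonical vectors in PC basis
    groups: list
    retained_pcs: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.cv_scores,
            columns=[f"CV{j + 1}" for j in range(self.cv_scores.shape[1])],
        )
        df.insert(0, "group", self.groups)
        return df


def _as_matrix(data) -> np.ndarray:
    X = np.asarray(data, dtype=float)
    if X.ndim == 3:  # (n, k, 2) landmark stacks
        X = X.reshape(X.shape[0], -1)
    elif X.ndim == 1:
        X = X[:, None]
    return X


def cva(data, groups, retain: int | None = None, max_retain: int = 30) -> GroupModel:
    """Canonical variates analysis of species means (or any observations).

    Parameters
    ----------
    data : (n, p) matrix, (n, k, 2) landmark stack, or PC scores
    groups : group label per observation (g >= 2 groups, all non-empty)
    retain : dimensionality of the PC projection used to stabilize the
        within-group covariance; default ``min(n - g, max_retain, rank)``
    """
    X = _as_matrix(data)
    groups = list(groups)
    n = X.shape[0]
    if len(groups) != n:
        raise ValueError("one group label per observation required")
    levels = list(dict.fromkeys(groups))
    g = len(levels)
    if g < 2:
        raise ValueError("CVA needs at least 2 groups")
    lab = np.asarray(groups)
    counts = {lv: int((lab == lv).sum()) for lv in levels}
    if min(counts.values()) < 1:
        raise ValueError("every group needs at least 1 observation")

    # project onto leading PCs so W is invertible
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if retain is None:
        retain = max(1, min(n - g, max_retain, rank))
    retain = min(retain, rank)
    P = Xc @ Vt[:retain].T  # (n, retain)

    grand = P.mean(axis=0)
    W = np.zeros((retain, retain))
    B = np.zeros((retain, retain))
    for lv in levels:
        sub = P[lab == lv]
        m = sub.mean(axis=0)
        d = sub - m
        W += d.T @ d
        B += len(sub) * np.outer(m - grand, m - grand)
    dof_w = n - g
    if dof_w < 1 or np.linalg.matrix_rank(W) < retain:
        # name the first deficient dimension for the caller
        r = np.linalg.matrix_rank(W)
        raise ValueError(
            f"pooled within-group covariance singular at dimension {r + 1}; "
            f"lower `retain` (currently {retain})"
        )
    W /= dof_w
    B /= max(g - 1, 1)
    # generalized symmetric eigenproblem B v = l W v  <=>  eig of W^-1 B
    evals, evecs = eigh(B, W)
    order = np.argsort(evals)[::-1][: g - 1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    scores = P @ evecs
    total = evals.sum()
    props = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    return GroupModel(
        cv_scores=scores,
        cv_proportions=props,
        eigenvalues=evals,
        loadings=evecs.T,
        groups=groups,
        retained_pcs=retain,
    )


@dataclass
class AnovaTable:
    """Goodall-type Procrustes ANOVA with permutation inference."""

    SS_between: float
    SS_within: float
    SS_total: float
    df_between: int
    df_within: int
    F: float
    p_value: float
    n_perm: int
    seed: object = None

    def summary(self) -> str:
        return (
            f"Procrustes ANOVA: F_{self.df_between},{self.df_within} = "
            f"{self.F:.4f}, P = {self.p_value:.4g} "
            f"(SS_b = {self.SS_between:.6g}, SS_w = {self.SS_within:.6g}, "
            f"{self.n_perm} permutations)"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SS": [self.SS_between, self.SS_within, self.SS_total],
                "df": [self.df_between, self.df_within, self.df_between + self.df_within],
                "F": [self.F, np.nan, np.nan],
                "P": [self.p_value, np.nan, np.nan],
            },
            index=["between", "within", "total"],
        )


def _ss_between(Xs: np.ndarray, starts: np.ndarray, counts: np.ndarray, grand_term: float):
    sums = np.add.reduceat(Xs, starts, axis=0)
    return float(((sums**2).sum(axis=1) / counts).sum() - grand_term)


def procrustes_anova(data, factor, n_perm: int = 999, seed=None) -> AnovaTable:
    """One-way Procrustes ANOVA of aligned shapes (or ln CS) by a factor.

    SS are summed squared tangent-space Euclidean distances; F is Goodall's
    ratio of between/within mean squares; P comes from unrestricted random
    permutation of the group labels (add-one rule).
    """
    X = _as_matrix(getattr(data, "aligned", data))
    factor = np.asarray(list(factor))
    N = X.shape[0]
    if len(factor) != N:
        raise ValueError("one factor level per observation required")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    levels, inverse = np.unique(factor, return_inverse=True)
    g = len(levels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(inverse).astype(float)
    order = np.argsort(inverse, kind="stable")
    Xs = X[order]
    starts = np.concatenate([[0], np.cumsum(counts.astype(int))[:-1]])

    grand = X.mean(axis=0)
    ss_total = float(((X - grand) ** 2).sum())
    grand_term = float((X.sum(axis=0) ** 2).sum()) / N
    ss_b = _ss_between(Xs, starts, counts, grand_term)
    ss_w = ss_total - ss_b
    df_b, df_w = g - 1, N - g
    if df_w < 1:
        raise ValueError("no within-group degrees of freedom")
    F_obs = (ss_b / df_b) / (ss_w / df_w)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        Xp = Xs[rng.permutation(N)]
        ss_b_p = _ss_between(Xp, starts, counts, grand_term)
        ss_w_p = ss_total - ss_b_p
        F_p = (ss_b_p / df_b) / (ss_w_p / df_w)
        if F_p >= F_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return AnovaTable(
        SS_between=ss_b, SS_within=ss_w, SS_total=ss_total,
        df_between=df_b, df_within=df_w, F=float(F_obs), p_value=float(p),
        n_perm=n_perm, seed=seed,
    )
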