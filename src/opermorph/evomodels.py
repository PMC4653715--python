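"""Maximum-likelihood trait-evolution models on phylogenies.

Six candidate models for a continuous species-level trait are supported:

=========  ========================================================  ======
model      covariance of the tip values                              extra
=========  ========================================================  ======
BM         ``sigma2 * C``                                            --
WN         ``sigma2 * I`` (no phylogenetic covariance)               --
lambda     off-diagonal of ``C`` multiplied by ``lambda``            lambda
delta      elementwise power of ``C``, height preserved              delta
EB         ``(exp(a*C) - 1)/a`` (ACDC; a > 0 allowed)                a
OU         stationary Ornstein-Uhlenbeck on the depth matrix         alpha
=========  ========================================================  ======

For every model the log-likelihood is the Gaussian GLS likelihood

    lnL = -1/2 [ n ln(2 pi) + ln|sigma2 V| + (x - z0 1)' (sigma2 V)^-1 (x - z0 1) ]

with the root state ``z0`` and rate ``sigma2`` profiled analytically and
any remaining scalar parameter optimized by bounded search with grid
restarts.  Estimation is ML (not REML), so BM and WN carry 2 free
parameters and the transform models 3; model comparison uses AICc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .phylo import PARAM_BOUNDS, Phylogeny, phylo_vcv, transform_covariance

__all__ = [
    "ContinuousTraitModel",
    "ModelFit",
    "ModelComparison",
    "SignalResult",
    "fit_trait_model",
    "aicc",
    "compare_models",
    "blomberg_k",
    "pagel_lambda_signal",
    "ancestral_states_bm",
    "ratematrix",
    "sim_traits",
]

MODELS = ("BM", "OU", "WN", "EB", "delta", "lambda")
_EXTRA_NAME = {"OU": "alpha_ou", "EB": "a_eb", "delta": "delta", "lambda": "lambda"}


def _profiled_loglik(x: np.ndarray, V: np.ndarray):
    """GLS log-likelihood with analytically profiled root state and rate."""
    n = len(x)
    try:
        cho = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular phylogenetic covariance (duplicate zero-length tips?)"
        ) from exc
    ones = np.ones(n)
    Vinv1 = cho_solve(cho, ones)
    denom = ones @ Vinv1
    z0 = float(x @ Vinv1 / denom)
    r = x - z0
    q = float(r @ cho_solve(cho, r))
    if q <= 0:
        raise ValueError("zero residual variation; likelihood is degenerate")
    sigma2 = q / n
    logdetV = 2.0 * np.sum(np.log(np.diag(cho[0])))
    lnL = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdetV + n)
    return float(lnL), z0, float(sigma2)


def aicc(lnL: float, k_params: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k_params + 1:
        raise ValueError("AICc requires n > k + 1")
    return 2 * k_params - 2 * lnL + 2 * k_params * (k_params + 1) / (n - k_params - 1)


@dataclass
class ModelFit:
    """ML fit of one trait-evolution model (a Results object)."""

    model: str
    sigma2: float
    z0: float
    lnL: float
    k_params: int
    n: int
    AICc: float
    extra: dict = field(default_factory=dict)
    at_bound: bool = False

    def summary(self) -> str:
        lines = [
            f"Trait-evolution model: {self.model}  (n = {self.n} tips)",
            f"  lnL     = {self.lnL:.4f}",
            f"  AICc    = {self.AICc:.4f}  (k = {self.k_params})",
            f"  sigma^2 = {self.sigma2:.6g}",
            f"  z0      = {self.z0:.6g}",
        ]
        for name, val in self.extra.items():
            lines.append(f"  {name:7s} = {val:.6g}")
        if self.at_bound:
            lines.append("  warning: parameter estimate at its search bound")
        return "\n".join(lines)


class ContinuousTraitModel:
    """Single-trait macroevolutionary model on a phylogeny.

    Parameters
    ----------
    x : array or pandas Series
        Species values; a Series is aligned to the tree by its index.
    tree : Phylogeny
    model : one of BM, OU, WN, EB, delta, lambda
    """

    def __init__(self, x, tree: Phylogeny, model: str = "BM"):
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
        self.model = model
        self.tree = tree
        vcv = phylo_vcv(tree)
        if isinstance(x, pd.Series):
            x = x.reindex(vcv.tip_order).to_numpy(dtype=float)
        else:
            x = np.asarray(x, dtype=float)
        if len(x) != len(vcv.tip_order):
            raise ValueError("trait vector length does not match tip count")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite trait values")
        if len(x) < 3:
            raise ValueError("need at least 3 species")
        self.x = x
        self.C = vcv.C
        self.T = vcv.T

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, column: str, tree: Phylogeny, model="BM"):
        return cls(data[column], tree, model=model)

    def _V(self, param: float | None) -> np.ndarray:
        if self.model == "BM":
            return self.C
        if self.model == "WN":
            return np.eye(len(self.x))
        return transform_covariance(self.C, self.model, param)

    def loglike(self, param: float | None = None) -> float:
        return _profiled_loglik(self.x, self._V(param))[0]

    def fit(self, n_restarts: int = 5) -> ModelFit:
        n = len(self.x)
        if self.model in ("BM", "WN"):
            lnL, z0, s2 = _profiled_loglik(self.x, self._V(None))
            k = 2
            return ModelFit(
                model=self.model, sigma2=s2, z0=z0, lnL=lnL, k_params=k, n=n,
                AICc=aicc(lnL, k, n) if n > k + 1 else np.nan,
            )
        lo, hi = PARAM_BOUNDS[self.model]
        if self.model == "EB":
            lo, hi = lo / self.T, hi / self.T
        def nll(p: float) -> float:
            try:
                return -_profiled_loglik(self.x, self._V(p))[0]
            except (ValueError, np.linalg.LinAlgError):
                return np.inf

        # bounded Brent from a coarse grid of restarts
        grid = np.linspace(lo, hi, n_restarts + 2)[1:-1]
        best_p, best_f = None, np.inf
        for i in range(len(grid)):
            a = lo if i == 0 else grid[i - 1]
            b = hi if i == len(grid) - 1 else grid[i + 1]
            res = optimize.minimize_scalar(
                nll, bounds=(a, b), method="bounded",
                options={"xatol": 1e-10 * (hi - lo)},
            )
            if res.fun < best_f:
                best_p, best_f = float(res.x), float(res.fun)
        # the exact boundary values are admissible too (e.g. lambda = 0 or 1)
        for p in (lo, hi):
            f = nll(p)
            if f < best_f:
                best_p, best_f = p, f
        lnL, z0, s2 = _profiled_loglik(self.x, self._V(best_p))
        k = 3
        span = hi - lo
        at_bound = best_p - lo < 1e-6 * span or hi - best_p < 1e-6 * span
        return ModelFit(
            model=self.model, sigma2=s2, z0=z0, lnL=lnL, k_params=k, n=n,
            AICc=aicc(lnL, k, n) if n > k + 1 else np.nan,
            extra={_EXTRA_NAME[self.model]: best_p},
            at_bound=at_bound,
        )


def fit_trait_model(x, tree: Phylogeny, model: str = "BM") -> ModelFit:
    """Convenience wrapper: ``ContinuousTraitModel(x, tree, model).fit()``."""
    return ContinuousTraitModel(x, tree, model=model).fit()


@dataclass
class ModelComparison:
    """AICc comparison across candidate model fits of one trait."""

    fits: list
    dAICc: np.ndarray
    akaike_weights: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [f.model for f in self.fits],
                "LogL": [f.lnL for f in self.fits],
                "AICc": [f.AICc for f in self.fits],
                "dAICc": self.dAICc,
                "AkaikeWeight": self.akaike_weights,
            }
        )

    @property
    def best(self) -> ModelFit:
        return self.fits[int(np.argmin([f.AICc for f in self.fits]))]

    def summary(self) -> str:
        return self.to_frame().to_string(index=False, float_format="%.4f")


def compare_models(fits) -> ModelComparison:
    """Delta-AICc and Akaike weights across fits of the same data."""
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    a = np.array([f.AICc if isinstance(f, ModelFit) else float(f) for f in fits])
    d = a - a.min()
    w = np.exp(-0.5 * d)
    w = w / w.sum()
    if not all(isinstance(f, ModelFit) for f in fits):
        fits = [
            f if isinstance(f, ModelFit) else ModelFit(
                model=str(i), sigma2=np.nan, z0=np.nan, lnL=np.nan, k_params=0,
                n=0, AICc=float(f),
            )
            for i, f in enumerate(fits)
        ]
    return ModelComparison(fits=fits, dAICc=d, akaike_weights=w)


# ----------------------------------------------------------------------
# phylogenetic signal
# ----------------------------------------------------------------------


@dataclass
class SignalResult:
    K: float = np.nan
    p_value: float = np.nan
    lambda_hat: float = np.nan
    lnL_lambda: float = np.nan

    def summary(self) -> str:
        parts = []
        if np.isfinite(self.K):
            parts.append(f"Blomberg's K = {self.K:.4f} (P = {self.p_value:.4g})")
        if np.isfinite(self.lambda_hat):
            parts.append(
                f"Pagel's lambda = {self.lambda_hat:.4f} (lnL = {self.lnL_lambda:.4f})"
            )
        return "\n".join(parts)


def blomberg_k(x, tree: Phylogeny, n_perm: int = 999, seed=None) -> SignalResult:
    """Blomberg's K with a tip-permutation significance test.

    K compares the observed ratio of non-phylogenetic to phylogenetic mean
    squared error, MSE0/MSE, with its Brownian-motion expectation on the same
    tree; K = 1 is the BM expectation, K < 1 indicates less signal.  The
    permutation P randomizes tip values and counts permutations whose
    phylogenetic MSE is at most the observed one (add-one rule).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    vcv = phylo_vcv(tree)
    C = vcv.C
    if isinstance(x, pd.Series):
        x = x.reindex(vcv.tip_order).to_numpy(dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    n = len(x)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in trait values")
    cho = cho_factor(C, lower=True)
    ones = np.ones(n)
    Cinv1 = cho_solve(cho, ones)
    s1 = ones @ Cinv1

    def mses(v: np.ndarray):
        a = float(v @ Cinv1 / s1)
        r = v - a
        mse0 = float(r @ r) / (n - 1)
        mse = float(r @ cho_solve(cho, r)) / (n - 1)
        return mse0, mse

    mse0, mse = mses(x)
    expected = (np.trace(C) - n / s1) / (n - 1)
    K = (mse0 / mse) / expected
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        _, mse_p = mses(rng.permutation(x))
        if mse_p <= mse:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return SignalResult(K=float(K), p_value=float(p))


def pagel_lambda_signal(x, tree: Phylogeny) -> SignalResult:
    """ML Pagel's lambda as a phylogenetic-signal estimate."""
    fit = fit_trait_model(x, tree, model="lambda")
    return SignalResult(lambda_hat=fit.extra["lambda"], lnL_lambda=fit.lnL)


# ----------------------------------------------------------------------
# ancestral states, rate matrix, simulation
# ----------------------------------------------------------------------


def ancestral_states_bm(x, tree: Phylogeny) -> np.ndarray:
    """GLS/ML ancestral-state reconstruction under Brownian motion.

    Returns one value per node in the tree's node order (tips keep their
    observed values); the root estimate equals the profiled GLS mean.
    """
    vcv = phylo_vcv(tree)
    if isinstance(x, pd.Series):
        x = x.reindex(vcv.tip_order).to_numpy(dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    C = vcv.C
    cho = cho_factor(C, lower=True)
    ones = np.ones(len(x))
    Cinv1 = cho_solve(cho, ones)
    z0 = float(x @ Cinv1 / (ones @ Cinv1))
    # covariance of every node with every tip = depth of their MRCA, which
    # for node v and tip t is the depth of v's ancestor on the path to t
    masks = tree.descendant_tip_masks()
    depths = tree.depths()
    n_nodes, n_tips = masks.shape
    cov = np.zeros((n_nodes, n_tips))
    w = tree.lengths.copy()
    w[0] = 0.0
    # shared path(root->v, root->t) = sum of edge lengths above common ancestors
    anc = np.zeros((n_nodes, n_nodes), dtype=bool)  # anc[u, v]: u on root-path of v
    for v in range(n_nodes):
        u = v
        while u != -1:
            anc[u, v] = True
            u = tree.parent[u]
    for u in range(n_nodes):
        if u == 0:
            continue
        below_v = anc[u]  # nodes whose root path includes edge above u
        cov[below_v] += w[u] * masks[u]
    states = z0 + cov @ cho_solve(cho, x - z0)
    states[tree.tip_indices] = x
    return states


def ratematrix(X, tree: Phylogeny) -> np.ndarray:
    """Evolutionary variance-covariance matrix of m traits under BM.

    GLS estimator about the phylogenetic mean with divisor n - 1,
    ``R = (X - 1 a')' C^-1 (X - 1 a') / (n - 1)``, equal to the mean outer
    product of the standardized independent contrasts.
    """
    vcv = phylo_vcv(tree)
    if isinstance(X, pd.DataFrame):
        X = X.reindex(vcv.tip_order).to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    if n != len(vcv.tip_order):
        raise ValueError("trait matrix rows do not match tree tips")
    if n <= m:
        warnings.warn("fewer species than traits; rate matrix is rank deficient")
    cho = cho_factor(vcv.C, lower=True)
    ones = np.ones(n)
    Cinv1 = cho_solve(cho, ones)
    a = (X.T @ Cinv1) / (ones @ Cinv1)
    Xc = X - a
    R = Xc.T @ cho_solve(cho, Xc) / (n - 1)
    return 0.5 * (R + R.T)


def sim_traits(tree: Phylogeny, R, z0=0.0, n_sims: int = 1, seed=None) -> np.ndarray:
    """Simulate multivariate Brownian motion along the tree.

    Evolution proceeds from the root to the tips; each branch adds a
    zero-mean multivariate normal increment with covariance ``R`` times the
    branch length.  One child generator is spawned per simulation index, so
    replicate *i* is reproducible regardless of how many replicates are
    drawn.  Returns an array of shape ``(n_sims, n_tips, m)``.
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    m = R.shape[0]
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() < -1e-10 * max(eigvals.max(), 1.0):
        raise ValueError("rate matrix R must be positive semidefinite")
    L = np.linalg.cholesky(R + np.eye(m) * max(eigvals.max(), 1.0) * 1e-12)
    z0 = np.broadcast_to(np.asarray(z0, dtype=float), (m,))
    edges = np.arange(1, tree.n_nodes)  # child-node index per edge
    sqrt_len = np.sqrt(tree.lengths[edges])
    # P[t, e] = 1 if edge e lies on the root-to-tip path of tip t; tip rows
    # follow the tree's tip_labels order
    P = tree.descendant_tip_masks()[edges].T.astype(float)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_sims)
    out = np.empty((n_sims, tree.n_tips, m))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        incr = rng.standard_normal((len(edges), m)) @ L.T
        incr *= sqrt_len[:, None]
        out[i] = z0 + P @ incr
    return out
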