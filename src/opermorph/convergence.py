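"""Pairwise distance-contrast analysis for morphological convergence.

For every species pair the observed morphological distance (Euclidean in
the retained shape space) is compared with the distribution of the same
pair's distance in Brownian-motion simulations run with the evolutionary
rate matrix estimated from the data.  A pair is flagged convergent when its
observed distance falls below the lower 95% bound of that simulated
distribution -- estimated by bootstrap over the simulation replicates --
so under the null about 2.5% of pairs are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import pdist

from .evomodels import ratematrix, sim_traits
from .phylo import Phylogeny, cophenetic_distances, phylo_vcv, prune_to_taxa

__all__ = ["DistanceContrast", "distance_contrast_analysis"]


@dataclass
class DistanceContrast:
    """Observed vs BM-simulated pairwise morphological distances."""

    pairs: list  # (species_a, species_b)
    morph_dist: np.ndarray
    phylo_dist: np.ndarray
    sim_mean: np.ndarray
    diff: np.ndarray  # observed - mean simulated
    lower95: np.ndarray
    convergent: np.ndarray  # bool per pair
    convergent_count: int
    expected_count: float
    n_sims: int
    n_boot: int
    seed: object = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_a": [p[0] for p in self.pairs],
                "species_b": [p[1] for p in self.pairs],
                "phylo_dist": self.phylo_dist,
                "morph_dist": self.morph_dist,
                "sim_mean": self.sim_mean,
                "diff": self.diff,
                "lower95": self.lower95,
                "convergent": self.convergent,
            }
        )

    def summary(self) -> str:
        return (
            f"{self.convergent_count} of {len(self.pairs)} species pairs more "
            f"similar than the BM lower-95% bound "
            f"(null expectation {self.expected_count:.1f}; "
            f"{self.n_sims} simulations, {self.n_boot} bootstrap replicates)"
        )

    def hexbin_table(self, gridsize: int = 8) -> pd.DataFrame:
        """Hex-binned (phylo_dist, morph_dist) summary for plotting."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        hb = ax.hexbin(self.phylo_dist, self.morph_dist, gridsize=gridsize)
        centers = hb.get_offsets()
        counts = hb.get_array()
        plt.close(fig)
        return pd.DataFrame(
            {"phylo_dist": centers[:, 0], "morph_dist": centers[:, 1], "count": counts}
        )


def distance_contrast_analysis(
    species_scores,
    tree: Phylogeny,
    exclude=(),
    n_sims: int = 1000,
    n_boot: int = 1000,
    seed=None,
) -> DistanceContrast:
    """Count species pairs morphologically closer than expected under BM.

    Parameters
    ----------
    species_scores : DataFrame indexed by species code, or array in tip order
        Retained shape-space axes (species means).
    exclude : labels removed from both data and tree before the analysis
        (e.g. a single outlier species).
    n_sims : BM simulation replicates (>= 100).
    n_boot : bootstrap replicates over the simulations (>= 100) for the
        per-pair lower 95% bound.
    """
    if n_sims < 100 or n_boot < 100:
        raise ValueError("n_sims and n_boot must be >= 100")
    exclude = list(exclude)
    missing = set(exclude) - set(tree.tip_labels)
    if missing:
        raise ValueError(f"excluded label(s) not in tree: {sorted(missing)}")
    keep = [t for t in tree.tip_labels if t not in exclude]
    if exclude:
        tree = prune_to_taxa(tree, keep)
    vcv = phylo_vcv(tree)
    if isinstance(species_scores, pd.DataFrame):
        X = species_scores.reindex(vcv.tip_order).to_numpy(dtype=float)
    else:
        X = np.asarray(species_scores, dtype=float)
        if exclude:
            raise ValueError("pass a DataFrame when using `exclude`")
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape

    obs = pdist(X)
    if np.all(obs == 0):
        warnings.warn("all species have identical scores; distances degenerate")
    Dphy, order = cophenetic_distances(tree)
    phylo = Dphy[np.triu_indices(n, k=1)]
    pairs = [(order[i], order[j]) for i, j in zip(*np.triu_indices(n, k=1))]

    R = ratematrix(X, tree)
    # GLS phylogenetic mean as the root state
    cho = cho_factor(vcv.C, lower=True)
    ones = np.ones(n)
    Cinv1 = cho_solve(cho, ones)
    z0 = (X.T @ Cinv1) / (ones @ Cinv1)

    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])
    sims = sim_traits(tree, R, z0=z0, n_sims=n_sims, seed=seed)
    D = np.stack([pdist(sims[s]) for s in range(n_sims)])  # (n_sims, n_pairs)
    sim_mean = D.mean(axis=0)
    diff = obs - sim_mean

    # bootstrap estimate of each pair's lower 2.5% simulated-distance bound
    acc = np.zeros(D.shape[1])
    for _ in range(n_boot):
        idx = rng.integers(0, n_sims, n_sims)
        acc += np.percentile(D[idx], 2.5, axis=0)
    lower95 = acc / n_boot

    convergent = obs < lower95
    return DistanceContrast(
        pairs=pairs,
        morph_dist=obs,
        phylo_dist=phylo,
        sim_mean=sim_mean,
        diff=diff,
        lower95=lower95,
        convergent=convergent,
        convergent_count=int(convergent.sum()),
        expected_count=0.025 * len(pairs),
        n_sims=n_sims,
        n_boot=n_boot,
        seed=seed,
    )
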