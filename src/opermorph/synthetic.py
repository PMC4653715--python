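"""Synthetic study generator with known ground truth.

Emulates the structure of an opercle-outline comparative study: a
species-level phylogeny (pure-birth, height 1), an opercle-like template
outline, a small orthonormal basis of smooth boundary deformation modes,
latent shape scores evolved on the tree under chosen trait-evolution
models, per-species specimen replicates with digitizing noise, ecological
covariates tied to latent axes at known slopes, and feeding-group labels
with optional planted mean shifts.  Defaults mirror the study scale: 54
species, 416 specimens, 100 semilandmarks per outline, 6 feeding-preference
and 7 feeding-mode groups, 7 covariates.  Every operation is reproducible
from its seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import signed_area
from .io import (
    FEEDING_MODES,
    FEEDING_PREFERENCES,
    CovariateTable,
    OutlineSpec,
    write_covariates,
    write_newick,
    write_tps,
)
from .phylo import Phylogeny, phylo_vcv, transform_covariance

__all__ = [
    "SyntheticDataset",
    "simulate_tree",
    "make_template_outline",
    "make_deformation_basis",
    "simulate_shape_evolution",
    "generate_specimens",
    "generate_covariates",
    "assign_groups",
    "make_dataset",
]

#: default per-latent-dimension generating models: a strong BM axis, a
#: tips-concentrated delta axis and a weaker lambda axis, echoing the mixed
#: model support seen for empirical opercle shape axes
DEFAULT_SHAPE_MODELS = (
    {"model": "BM", "sigma2": 0.040},
    {"model": "delta", "sigma2": 0.015, "param": 3.0},
    {"model": "lambda", "sigma2": 0.006, "param": 0.8},
)

#: default covariate slopes against named latent dimensions (0-based) with
#: BM residual standard deviations; counts/ratios are transformed afterwards
DEFAULT_COVARIATES = {
    "d13C": {"dim": 0, "slope": 0.0, "resid_sd": 1.5, "baseline": -18.0},
    "d15N": {"dim": 0, "slope": 8.0, "resid_sd": 1.0, "baseline": 6.0},
    "grnDa": {"dim": 1, "slope": 0.0, "resid_sd": 2.0, "baseline": 10.0},
    "grnVa": {"dim": 1, "slope": 0.0, "resid_sd": 3.0, "baseline": 14.0},
    "mean_rl": {"dim": 1, "slope": 4.0, "resid_sd": 0.4, "baseline": 1.2},
    "GLTL": {"dim": 1, "slope": -3.0, "resid_sd": 0.3, "baseline": 1.0},
    "ER": {"dim": 0, "slope": -2.0, "resid_sd": 0.2, "baseline": 1.1},
}


def simulate_tree(n_tips: int = 54, seed=None, birth_rate: float = 1.0) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` tips, height rescaled to 1."""
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = np.random.default_rng(seed)
    # grow tips; record (parent, birth_time) per node, then assign lengths
    parent = [-1, 0, 0]
    btime = [0.0, 0.0, 0.0]  # time each node's subtending edge starts
    tips = [1, 2]
    t = 0.0
    while len(tips) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        split = tips.pop(rng.integers(len(tips)))
        for _ in range(2):
            parent.append(split)
            btime.append(t)
            tips.append(len(parent) - 1)
    t += rng.exponential(1.0 / (birth_rate * len(tips)))  # stem to present
    parent = np.asarray(parent)
    lengths = np.zeros(len(parent))
    labels: list = [None] * len(parent)
    tipset = set(tips)
    end = {i: t for i in tips}
    for i in range(1, len(parent)):
        children = np.flatnonzero(parent == i)
        stop = btime[children[0]] if len(children) else end[i]
        lengths[i] = stop - btime[i]
    height = t
    lengths /= height
    for rank, i in enumerate(sorted(tipset)):
        labels[i] = f"sp{rank:04d}"
    return Phylogeny(parent, lengths, labels)


def make_template_outline(
    k: int = 100, aspect: float = 1.35, notch_depth: float = 0.18
) -> np.ndarray:
    """Opercle-like smooth closed curve with one dorsal curvature maximum.

    A slightly egg-shaped ellipse (anteroposterior axis ``aspect`` times the
    dorsoventral axis) carrying one localized dorsal bump whose apex is the
    homologous start point.  Points are ordered clockwise.  Deterministic.
    """
    if k < 20:
        raise ValueError("k must be >= 20")
    theta = np.pi / 2 - 2 * np.pi * np.arange(k) / k  # clockwise from the top
    r = 1.0 + notch_depth * np.exp(-0.5 * ((np.mod(theta - np.pi / 2 + np.pi, 2 * np.pi) - np.pi) / 0.18) ** 2)
    x = aspect * r * np.cos(theta)
    y = r * np.sin(theta) * (1.0 + 0.08 * np.cos(theta))  # mild egg asymmetry
    pts = np.column_stack([x, y])
    assert signed_area(pts) < 0
    return pts


def make_deformation_basis(template: np.ndarray, d: int = 3) -> np.ndarray:
    """Orthonormal smooth boundary modes as flattened (2k,) vectors.

    Mode j displaces each boundary point along its outward normal by a
    low-order sinusoid of the boundary position (frequencies start at 2: one
    full cycle is translation-like and would be absorbed by Procrustes
    centering).  The fields are projected off the similarity-transform
    subspace of the template (translations, rotation, scaling) and
    Gram-Schmidt orthonormalized, so each mode is pure shape change --
    dilation-diminution style dorsoventral/anteroposterior deformations.
    """
    k = len(template)
    nxt = np.roll(template, -1, axis=0)
    prev = np.roll(template, 1, axis=0)
    tang = nxt - prev
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.column_stack([tang[:, 1], -tang[:, 0]])  # outward for clockwise
    s = np.arange(k) / k
    fields = []
    for j in range(d):
        freq = 2 + j // 2
        phase = 0.0 if j % 2 == 0 else np.pi / 2
        amp = np.cos(2 * np.pi * freq * s + phase)
        fields.append((normal * amp[:, None]).reshape(-1))
    B = np.array(fields, dtype=float)
    # similarity-transform subspace of the template (orthonormalized)
    centered = template - template.mean(axis=0)
    sim = np.array(
        [
            np.tile([1.0, 0.0], k),  # x translation
            np.tile([0.0, 1.0], k),  # y translation
            centered.reshape(-1),  # scaling
            np.column_stack([-centered[:, 1], centered[:, 0]]).reshape(-1),  # rotation
        ]
    )
    for i in range(len(sim)):
        for h in range(i):
            sim[i] -= (sim[i] @ sim[h]) * sim[h]
        sim[i] /= np.linalg.norm(sim[i])
    # Gram-Schmidt against the similarity subspace, then among the fields
    for j in range(d):
        for v in sim:
            B[j] -= (B[j] @ v) * v
        for i in range(j):
            B[j] -= (B[j] @ B[i]) * B[i]
        norm = np.linalg.norm(B[j])
        if norm < 1e-12:
            raise ValueError("degenerate deformation basis")
        B[j] /= norm
    return B


def simulate_shape_evolution(
    tree: Phylogeny,
    template: np.ndarray,
    basis: np.ndarray,
    models=DEFAULT_SHAPE_MODELS,
    seed=None,
):
    """Evolve latent shape scores on the tree and deform the template.

    Each latent dimension follows its own model (BM/OU/EB/delta/lambda) via
    the corresponding covariance transform; species shapes are
    ``template + sum_j score_j * field_j``.  Returns ``(mean_shapes, scores)``
    where ``mean_shapes`` maps species code to a (k, 2) outline and
    ``scores`` is a DataFrame of the true latent values.
    """
    models = list(models)
    d = len(models)
    if d > len(basis):
        raise ValueError("more model dimensions than basis fields")
    vcv = phylo_vcv(tree)
    n = len(vcv.tip_order)
    rng = np.random.default_rng(seed)
    scores = np.zeros((n, d))
    for j, spec in enumerate(models):
        model = spec["model"]
        sigma2 = spec["sigma2"]
        if sigma2 == 0:
            continue
        V = vcv.C if model == "BM" else transform_covariance(
            vcv.C, model, spec["param"]
        )
        L = np.linalg.cholesky(sigma2 * V + np.eye(n) * 1e-12)
        scores[:, j] = L @ rng.standard_normal(n)
    k = len(template)
    # clip displacements that would fold the outline through itself
    radius = np.linalg.norm(template - template.mean(axis=0), axis=1)
    max_disp = 0.45 * radius.min()
    mean_shapes = {}
    for i, sp in enumerate(vcv.tip_order):
        disp = (scores[i] @ basis[:d]).reshape(k, 2)
        mag = np.linalg.norm(disp, axis=1).max()
        if mag > max_disp:
            warnings.warn(
                f"species {sp}: deformation clipped to avoid self-intersection"
            )
            disp *= max_disp / mag
        mean_shapes[sp] = template + disp
    return mean_shapes, pd.DataFrame(
        scores, index=vcv.tip_order, columns=[f"latent{j}" for j in range(d)]
    )


def _specimen_counts(n_species: int, total: int, lo: int, hi: int, rng) -> np.ndarray:
    """Per-species replicate counts in [lo, hi] summing exactly to ``total``."""
    if total is None:
        return rng.integers(lo, hi + 1, n_species)
    if not n_species * lo <= total <= n_species * hi:
        raise ValueError("total specimens incompatible with per-species range")
    counts = np.full(n_species, lo)
    extra = total - counts.sum()
    room = np.full(n_species, hi - lo)
    while extra > 0:
        i = rng.integers(n_species)
        if room[i] > 0:
            counts[i] += 1
            room[i] -= 1
            extra -= 1
    return counts


def generate_specimens(
    mean_shapes: dict,
    tree: Phylogeny,
    n_per_species=(5, 10),
    total: int | None = 416,
    noise_sd: float = 0.003,
    size_sigma2: float = 0.25,
    base_log_cs: float = 3.0,
    allometry: pd.Series | None = None,
    allometry_coef: float = 0.0,
    within_species_cs_sd: float = 0.08,
    seed=None,
):
    """Specimen outlines around each species mean, TPS-writable.

    Species centroid sizes are log-normal: ln CS evolves as BM on the tree
    (rate ``size_sigma2``) around ``base_log_cs``, optionally coupled to a
    latent shape dimension (``allometry_coef * allometry``).  Each specimen
    scales the species shape by its own CS draw and adds independent
    isotropic coordinate noise of standard deviation ``noise_sd`` (in
    species-mean shape units, i.e. relative to a unit-radius outline).
    Returns ``(specimens, truth)`` with specimens a list of
    :class:`OutlineSpec`.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    vcv = phylo_vcv(tree)
    species = vcv.tip_order
    if set(species) - set(mean_shapes):
        raise ValueError("mean shape missing for some species")
    n_sp = len(species)
    L = np.linalg.cholesky(size_sigma2 * vcv.C + np.eye(n_sp) * 1e-12)
    log_cs = base_log_cs + L @ rng.standard_normal(n_sp)
    if allometry_coef and allometry is not None:
        log_cs = log_cs + allometry_coef * allometry.reindex(species).to_numpy()
    if isinstance(n_per_species, int):
        counts = np.full(n_sp, n_per_species)
    else:
        lo, hi = n_per_species
        counts = _specimen_counts(n_sp, total, lo, hi, rng)
    if counts.min() < 1:
        raise ValueError("n_per_species must be >= 1")
    from .geometry import centroid_size as _cs

    specimens = []
    for i, sp in enumerate(species):
        shape = np.asarray(mean_shapes[sp], dtype=float)
        unit = shape / _cs(shape)
        for r in range(counts[i]):
            cs = np.exp(log_cs[i] + within_species_cs_sd * rng.standard_normal())
            # noise is relative to the specimen's own scale
            pts = cs * (unit + rng.normal(0.0, noise_sd, unit.shape))
            specimens.append(
                OutlineSpec(points=pts, specimen_id=f"{sp}_{r + 1:02d}", species_code=sp)
            )
    truth = {
        "log_cs_species": dict(zip(species, map(float, log_cs))),
        "counts": dict(zip(species, map(int, counts))),
        "noise_sd": noise_sd,
        "size_sigma2": size_sigma2,
        "allometry_coef": allometry_coef,
    }
    return specimens, truth


def generate_covariates(
    tree: Phylogeny,
    scores: pd.DataFrame,
    spec: dict = None,
    groups: pd.DataFrame | None = None,
    seed=None,
) -> CovariateTable:
    """Covariates = slope x latent score + BM residual on the tree.

    Gill-raker counts are rounded and floored at zero; ER and GLTL are made
    positive by exponentiating their linear predictor (so the recorded slope
    acts on the log scale).  Ground-truth slopes live in ``spec``.
    """
    spec = dict(DEFAULT_COVARIATES if spec is None else spec)
    vcv = phylo_vcv(tree)
    species = vcv.tip_order
    n = len(species)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(vcv.C + np.eye(n) * 1e-12)
    data = {"species_code": species}
    for name, cfg in spec.items():
        dim = f"latent{cfg['dim']}" if isinstance(cfg["dim"], int) else cfg["dim"]
        if dim not in scores.columns:
            raise ValueError(f"unknown latent dimension {dim!r} for covariate {name}")
        latent = scores[dim].reindex(species).to_numpy()
        resid = cfg["resid_sd"] * (L @ rng.standard_normal(n))
        lin = cfg["slope"] * latent + resid
        if name in ("grnDa", "grnVa"):
            vals = np.maximum(np.round(cfg.get("baseline", 0.0) + lin), 0.0)
        elif name in ("ER", "GLTL"):
            # positivity by construction; the slope acts on the log scale
            vals = cfg.get("baseline", 1.0) * np.exp(lin)
        else:
            vals = cfg.get("baseline", 0.0) + lin
        data[name] = vals
    df = pd.DataFrame(data)
    if groups is not None:
        df = df.merge(groups, left_on="species_code", right_index=True, how="left")
    return CovariateTable(df)


def assign_groups(
    tree: Phylogeny,
    n_groups: int,
    labels=None,
    scheme: str = "clade",
    seed=None,
) -> pd.Series:
    """Assign each species to one of ``n_groups`` groups.

    ``scheme="clade"`` slices the tip order (a tree traversal) into
    contiguous blocks, giving phylogenetically clustered groups;
    ``scheme="random"`` shuffles.  Every group is non-empty.
    """
    tips = tree.tip_labels
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if n_groups > len(tips):
        raise ValueError("more groups than species")
    if labels is None:
        labels = [f"group{j}" for j in range(n_groups)]
    if len(labels) != n_groups:
        raise ValueError("label count must equal n_groups")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(tips))
    if scheme == "random":
        idx = rng.permutation(idx)
    blocks = np.array_split(idx, n_groups)
    out = [None] * len(tips)
    for j, block in enumerate(blocks):
        for i in block:
            out[i] = labels[j]
    return pd.Series(out, index=tips, name="group")


@dataclass
class SyntheticDataset:
    """A complete synthetic study bundle with recorded ground truth."""

    tree: Phylogeny
    template: np.ndarray
    basis: np.ndarray
    mean_shapes: dict
    scores: pd.DataFrame
    specimens: list
    covariates: CovariateTable
    feeding_preference: pd.Series
    feeding_mode: pd.Series
    true_params: dict = field(default_factory=dict)

    def write_bundle(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tps(self.specimens, outdir / "specimens.tps")
        write_newick(self.tree, outdir / "tree.nwk")
        write_covariates(self.covariates, outdir / "covariates.csv")
        (outdir / "truth.json").write_text(json.dumps(self.true_params, indent=2))


def make_dataset(
    n_species: int = 54,
    n_specimens: int = 416,
    k: int = 100,
    shape_models=DEFAULT_SHAPE_MODELS,
    covariate_spec: dict = None,
    noise_sd: float = 0.003,
    group_shift: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a full study-scale synthetic dataset (the default emulates
    54 species / 416 specimens / 100 semilandmarks / 6+7 feeding groups).

    ``group_shift`` plants a feeding-preference mean shift along the first
    deformation field (zero by default, so group tests are null).
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(8)
    tree = simulate_tree(n_species, seed=seeds[0])
    template = make_template_outline(k=k)
    basis = make_deformation_basis(template, d=max(3, len(list(shape_models))))
    mean_shapes, scores = simulate_shape_evolution(
        tree, template, basis, models=shape_models, seed=seeds[1]
    )
    pref = assign_groups(
        tree, 6, labels=list(FEEDING_PREFERENCES), scheme="clade", seed=seeds[2]
    ).rename("feeding_preference")
    mode = assign_groups(
        tree, 7, labels=list(FEEDING_MODES), scheme="random", seed=seeds[3]
    ).rename("feeding_mode")
    if group_shift:
        k_pts = len(template)
        pref_levels = list(FEEDING_PREFERENCES)
        for sp in mean_shapes:
            j = pref_levels.index(pref[sp])
            offset = group_shift * (j - (len(pref_levels) - 1) / 2)
            mean_shapes[sp] = mean_shapes[sp] + (offset * basis[0]).reshape(k_pts, 2)
    specimens, spec_truth = generate_specimens(
        mean_shapes, tree, total=n_specimens, noise_sd=noise_sd, seed=seeds[4]
    )
    groups = pd.concat([pref, mode], axis=1)
    covariates = generate_covariates(
        tree, scores, spec=covariate_spec, groups=groups, seed=seeds[5]
    )
    cov_spec = dict(DEFAULT_COVARIATES if covariate_spec is None else covariate_spec)
    true_params = {
        "seed": seed,
        "n_species": n_species,
        "k": k,
        "shape_models": list(shape_models),
        "covariate_slopes": {name: cfg["slope"] for name, cfg in cov_spec.items()},
        "group_shift": group_shift,
        "specimens": spec_truth,
    }
    return SyntheticDataset(
        tree=tree, template=template, basis=basis, mean_shapes=mean_shapes,
        scores=scores, specimens=specimens, covariates=covariates,
        feeding_preference=pref, feeding_mode=mode, true_params=true_params,
    )
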