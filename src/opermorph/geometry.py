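"""Outline resampling, Procrustes superimposition and shape-space ordination.

The morphometric protocol: each closed opercle outline is resampled to ``k``
equidistant semilandmarks (arc length along the piecewise-linear curve),
traversed clockwise from a homologous start point at the dorsal curvature
maximum.  Configurations are then superimposed by generalized Procrustes
analysis (translation, unit-centroid-size scaling, rotation without
reflection) and ordinated by PCA of the flattened aligned coordinates
(shape space) or of the coordinates plus ln centroid size (form space).
Semilandmarks are treated as fixed points after resampling; no sliding is
performed.  Tangent-space projection is taken as the identity (small
variation assumption).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import OutlineSpec

__all__ = [
    "LandmarkConfiguration",
    "ProcrustesAlignment",
    "ShapeSpace",
    "centroid_size",
    "signed_area",
    "resample_outline",
    "detect_start_point",
    "gpa",
    "procrustes_distance",
    "shape_pca",
    "form_pca",
    "broken_stick",
    "species_mean_shapes",
    "axis_shape_model",
]


@dataclass
class LandmarkConfiguration:
    """One specimen's k ordered semilandmarks plus its centroid size."""

    coords: np.ndarray
    centroid_size: float = None  # type: ignore[assignment]
    specimen_id: str = ""
    species_code: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (k, 2)")
        if self.centroid_size is None:
            self.centroid_size = centroid_size(self.coords)

    @property
    def k(self) -> int:
        return len(self.coords)


def centroid_size(coords) -> float:
    """CS = sqrt(sum of squared distances of the points from their centroid)."""
    coords = np.asarray(coords, dtype=float)
    return float(np.sqrt(((coords - coords.mean(axis=0)) ** 2).sum()))


def signed_area(points) -> float:
    """Shoelace signed area; negative for clockwise traversal (y up)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _circular_smooth(pts: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return pts
    kernel = np.ones(window) / window
    out = np.empty_like(pts)
    pad = window // 2
    for c in range(2):
        ext = np.concatenate([pts[-pad:, c], pts[:, c], pts[:pad, c]])
        out[:, c] = np.convolve(ext, kernel, mode="valid")[: len(pts)]
    return out


def detect_start_point(outline, smooth: int | None = None) -> int:
    """Index of the discrete-curvature maximum on the dorsal (upper-y) half.

    Curvature at a vertex is estimated as the absolute exterior turning angle
    divided by the mean length of the two adjacent edges; ties are broken by
    the lowest index.  Emulates placing a type II landmark at the curvature
    maximum of the dorsal margin.  Because vertex-level curvature is dominated
    by digitizing noise at realistic point densities, curvature is measured on
    a circularly smoothed copy of the outline (moving-average window
    ``smooth``, default ``max(1, k // 20)`` rounded to odd); the returned
    index always refers to the original vertices.
    """
    pts = outline.points if isinstance(outline, OutlineSpec) else np.asarray(outline, float)
    n = len(pts)
    if n < 5:
        raise ValueError("need at least 5 outline points to detect a start point")
    if smooth is None:
        smooth = max(1, n // 20)
    smooth = int(smooth) | 1  # odd
    pts = _circular_smooth(pts, smooth)
    prev = np.roll(pts, 1, axis=0)
    nxt = np.roll(pts, -1, axis=0)
    e1 = pts - prev
    e2 = nxt - pts
    l1 = np.hypot(e1[:, 0], e1[:, 1])
    l2 = np.hypot(e2[:, 0], e2[:, 1])
    cross = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    dot = (e1 * e2).sum(axis=1)
    angle = np.abs(np.arctan2(cross, dot))
    scale2 = max((l1.max() * l2.max()), 1e-300)
    if np.all(np.abs(cross) < 1e-12 * scale2):
        raise ValueError("all outline points are collinear")
    with np.errstate(divide="ignore", invalid="ignore"):
        curv = np.where((l1 + l2) > 0, angle / (0.5 * (l1 + l2)), 0.0)
    dorsal = pts[:, 1] >= pts[:, 1].mean()
    if not dorsal.any():  # degenerate; fall back to the whole outline
        dorsal = np.ones(n, dtype=bool)
    masked = np.where(dorsal, curv, -np.inf)
    best = masked.max()
    return int(np.flatnonzero(masked >= best - 1e-12 * max(best, 1.0))[0])


def resample_outline(
    outline,
    k: int,
    start: int | str = "curvature",
    orientation: str = "clockwise",
    max_k: int = 10000,
) -> LandmarkConfiguration:
    """Resample a closed outline to ``k`` arc-length-equidistant semilandmarks.

    Parameters
    ----------
    outline : OutlineSpec or (n, 2) array
    k : number of semilandmarks (>= 3)
    start : vertex index of the homologous start point, or ``"curvature"``
        to place it at the dorsal curvature maximum
    orientation : traversal direction of the output; ``"clockwise"`` makes
        the signed area negative (the digitizing convention)
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    if k > max_k:
        raise ValueError(f"k={k} exceeds the configured maximum {max_k}")
    if isinstance(outline, OutlineSpec):
        pts = outline.points
        sid, sp = outline.specimen_id, outline.species_code
    else:
        pts = np.asarray(outline, dtype=float)
        sid = sp = ""
    n = len(pts)
    if n < 3 or len(np.unique(pts, axis=0)) < 3:
        raise ValueError("degenerate outline: fewer than 3 distinct points")
    start_idx = detect_start_point(pts) if start == "curvature" else int(start)
    if orientation == "clockwise" and signed_area(pts) > 0:
        # reverse traversal, keeping the start vertex at its place
        pts = np.vstack([pts[start_idx:], pts[:start_idx]])
        pts = np.vstack([pts[:1], pts[1:][::-1]])
    else:
        pts = np.vstack([pts[start_idx:], pts[:start_idx]])
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = cum[-1]
    if perimeter <= 0:
        raise ValueError("degenerate outline: zero perimeter")
    targets = np.arange(k) * perimeter / k
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return LandmarkConfiguration(
        coords=np.column_stack([x, y]), specimen_id=sid, species_code=sp
    )


# ----------------------------------------------------------------------
# Procrustes superimposition
# ----------------------------------------------------------------------


@dataclass
class ProcrustesAlignment:
    """Output of generalized Procrustes analysis.

    ``aligned`` holds n configurations, each centered at the origin with unit
    centroid size; ``centroid_sizes`` keeps the pre-scaling sizes.
    """

    aligned: np.ndarray  # (n, k, 2)
    mean_shape: np.ndarray  # (k, 2)
    centroid_sizes: np.ndarray  # (n,)
    iterations: int
    converged: bool
    specimen_ids: list = None  # type: ignore[assignment]
    species_codes: list = None  # type: ignore[assignment]

    @property
    def n(self) -> int:
        return len(self.aligned)

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def flattened(self) -> np.ndarray:
        return self.aligned.reshape(self.n, -1)


def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rotation R (no reflection) minimizing ||A @ R - B||_F."""
    U, _, Vt = np.linalg.svd(A.T @ B)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    return U @ D @ Vt


def _center_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    c = coords - coords.mean(axis=0)
    cs = np.sqrt((c**2).sum())
    if cs == 0:
        raise ValueError("configuration with zero centroid size")
    return c / cs, float(cs)


def gpa(configs, tol: float = 1e-10, max_iter: int = 200) -> ProcrustesAlignment:
    """Generalized Procrustes analysis of equal-k landmark configurations.

    Iteratively centers each configuration at the origin, scales it to unit
    centroid size, rotates it onto the running consensus (reflections
    disallowed), and re-estimates the consensus until its displacement falls
    below ``tol``.  The consensus is re-standardized each round, so the
    result is invariant (up to one global rotation) to input order.
    """
    configs = list(configs)
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    arrs, sizes, sids, sps = [], [], [], []
    for c in configs:
        if isinstance(c, LandmarkConfiguration):
            a, cs = _center_scale(c.coords)
            sids.append(c.specimen_id)
            sps.append(c.species_code)
        else:
            a, cs = _center_scale(np.asarray(c, dtype=float))
            sids.append("")
            sps.append("")
        arrs.append(a)
        sizes.append(cs)
    k = arrs[0].shape[0]
    if any(a.shape[0] != k for a in arrs):
        raise ValueError("all configurations must share the same k")
    X = np.stack(arrs)
    consensus = X[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(len(X)):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        new = X.mean(axis=0)
        new, _ = _center_scale(new)
        shift = np.sqrt(((new - consensus) ** 2).sum())
        consensus = new
        if shift < tol:
            converged = True
            break
    # final pass so every configuration is rotated to the converged consensus
    for i in range(len(X)):
        X[i] = X[i] @ _optimal_rotation(X[i], consensus)
    return ProcrustesAlignment(
        aligned=X,
        mean_shape=X.mean(axis=0),
        centroid_sizes=np.asarray(sizes),
        iterations=iterations,
        converged=converged,
        specimen_ids=sids,
        species_codes=sps,
    )


def procrustes_distance(a, b) -> float:
    """Procrustes distance after optimal translation, scaling and rotation.

    Both shapes are centered and scaled to unit centroid size, the optimal
    rotation (reflection disallowed) is applied, and the root summed squared
    difference is returned.  Symmetric; zero iff the shapes are similar.
    """
    A = a.coords if isinstance(a, LandmarkConfiguration) else np.asarray(a, float)
    B = b.coords if isinstance(b, LandmarkConfiguration) else np.asarray(b, float)
    if A.shape != B.shape:
        raise ValueError("shapes must share the same k")
    A, _ = _center_scale(A)
    B, _ = _center_scale(B)
    R = _optimal_rotation(B, A)
    return float(np.sqrt(((A - B @ R) ** 2).sum()))


# ----------------------------------------------------------------------
# ordination
# ----------------------------------------------------------------------


@dataclass
class ShapeSpace:
    """PCA of flattened Procrustes coordinates (optionally plus ln CS)."""

    scores: np.ndarray  # (n, m)
    loadings: np.ndarray  # (m, p) rows are eigenvectors
    eigenvalues: np.ndarray
    proportions: np.ndarray
    mean: np.ndarray  # column means of the input matrix
    is_form_space: bool = False

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    @property
    def effective_dim(self) -> int:
        """Nonzero shape dimensions: min(n - 1, 2k - 4) in shape space
        (Procrustes superimposition removes 2 translations, 1 rotation and
        1 scaling degree of freedom); one more for the ln CS column in form
        space."""
        n = self.scores.shape[0]
        p = self.loadings.shape[1]
        return min(n - 1, p - 4 + (1 if self.is_form_space else 0))


def _pca(X: np.ndarray, is_form_space: bool) -> ShapeSpace:
    n = X.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 observations")
    mean = X.mean(axis=0)
    Xc = X - mean
    total = (Xc**2).sum()
    if total <= 0:
        raise ValueError("zero total variance")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    m = min(n - 1, X.shape[1])
    U, s, Vt, eig = U[:, :m], s[:m], Vt[:m], eig[:m]
    # sign convention: the largest-magnitude loading of each axis is positive
    for j in range(m):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    scores = U * s
    return ShapeSpace(
        scores=scores,
        loadings=Vt,
        eigenvalues=eig,
        proportions=eig / eig.sum(),
        mean=mean,
        is_form_space=is_form_space,
    )


def shape_pca(alignment) -> ShapeSpace:
    """PCA of the covariance of flattened aligned coordinates (shape space)."""
    X = alignment.flattened() if isinstance(alignment, ProcrustesAlignment) else np.asarray(alignment, float)
    return _pca(X, is_form_space=False)


def form_pca(alignment, centroid_sizes=None) -> ShapeSpace:
    """PCA of [aligned coordinates, ln centroid size] (Procrustes form space)."""
    if isinstance(alignment, ProcrustesAlignment):
        X = alignment.flattened()
        cs = alignment.centroid_sizes
    else:
        X = np.asarray(alignment, float)
        cs = np.asarray(centroid_sizes, float)
    if np.any(cs <= 0):
        raise ValueError("all centroid sizes must be positive in form space")
    return _pca(np.column_stack([X, np.log(cs)]), is_form_space=True)


def broken_stick(eigenvalues) -> tuple[np.ndarray, np.ndarray]:
    """Broken-stick expected variance proportions and per-axis significance.

    With p axes, the expected proportion of axis j (1-based) is
    ``b_j = (1/p) * sum_{i=j}^{p} 1/i``; an axis is flagged significant when
    its observed proportion exceeds its broken-stick expectation.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size == 0:
        raise ValueError("empty eigenvalue vector")
    if np.any(eig < 0) or eig.sum() <= 0:
        raise ValueError("eigenvalues must be >= 0 and not all zero")
    p = eig.size
    inv = 1.0 / np.arange(1, p + 1)
    expected = np.cumsum(inv[::-1])[::-1] / p
    observed = eig / eig.sum()
    return expected, observed > expected


def species_mean_shapes(alignment: ProcrustesAlignment, species=None):
    """Tangent-space species means of aligned coordinates plus mean CS.

    Returns ``(configs, mean_cs)``: one re-centered
    :class:`LandmarkConfiguration` per species (in first-appearance order)
    and a dict of arithmetic mean centroid sizes.
    """
    labels = list(species) if species is not None else list(alignment.species_codes)
    if len(labels) != alignment.n or any(not s for s in labels):
        raise ValueError("every specimen needs a species label")
    order = list(dict.fromkeys(labels))
    configs, mean_cs = [], {}
    lab = np.asarray(labels)
    for sp in order:
        idx = np.flatnonzero(lab == sp)
        mean = alignment.aligned[idx].mean(axis=0)
        mean = mean - mean.mean(axis=0)
        configs.append(
            LandmarkConfiguration(coords=mean, specimen_id=sp, species_code=sp)
        )
        mean_cs[sp] = float(alignment.centroid_sizes[idx].mean())
    return configs, mean_cs


def axis_shape_model(mean_shape, loading, score: float) -> np.ndarray:
    """Deform the mean shape along one PC: mean + score * loading."""
    mean = np.asarray(mean_shape, dtype=float)
    flat = mean.reshape(-1)
    loading = np.asarray(loading, dtype=float)
    if loading.shape != flat.shape:
        raise ValueError("loading dimension does not match flattened coordinates")
    return (flat + score * loading).reshape(mean.shape)
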